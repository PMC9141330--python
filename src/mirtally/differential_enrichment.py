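"""Two-group negative-binomial exact-test differential enrichment.

Classic workflow: libraries are equalized to a common size (geometric
mean of totals), a single common dispersion is estimated by maximizing
the NB conditional log-likelihood, each feature is tested with a
conditional exact test (two-sided p by doubling the smaller tail, point
mass included, capped at 1), p-values are BH-adjusted, and features are
classified ENRICHED / DEPLETED / NS from fold change and FDR thresholds.

Conditioning note: if per-library counts are iid NB(size r = 1/phi) with
a common mean, the group sum is NB with size n_g/phi, and the conditional
law of one group's sum given the overall total s is beta-binomial
(n = s, a = n_a/phi, b = n_b/phi); the exact test sums that distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom, norm

from .mir_quantification import CountMatrix, cpm

PHI_GRID_LO = 1e-4
PHI_GRID_HI = 4.0


@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion phi (variance = mu + phi * mu^2)."""

    phi: float
    method: str = "conditional-ml-grid-golden"

    def __post_init__(self) -> None:
        if not math.isfinite(self.phi) or self.phi < 0:
            raise ValueError("phi must be finite and >= 0")


@dataclass(frozen=True)
class TestConfig:
    __test__ = False  # not a pytest class, despite the name

    fdr_threshold: float = 0.01
    fc_up: float = 2.0
    fc_down: float = 0.5
    pseudo_count: float = 0.5  # CPM added to both group means for fold change
    use_raw_p: bool = False  # classify on raw p instead of BH-adjusted q
    big_total: int = 5000  # totals above this use the normal tail approximation

    def __post_init__(self) -> None:
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be >= 0")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.fc_up < 1 or not (0 < self.fc_down <= 1):
            raise ValueError("require fc_up >= 1 and fc_down in (0, 1]")


@dataclass
class EnrichmentResult:
    feature: str
    mean_cpm_a: float
    mean_cpm_b: float
    fold_change: float  # group B over group A
    log2fc: float
    p_value: float
    fdr: float
    classification: str  # ENRICHED / DEPLETED / NS


# ---------------------------------------------------------------------------
# library equalization
# ---------------------------------------------------------------------------


@dataclass
class EqualizedCounts:
    pseudo: np.ndarray  # integer pseudo-counts at the common library size
    common_size: float
    factors: np.ndarray  # per-sample scaling factors applied


def equalize_libraries(matrix: CountMatrix) -> EqualizedCounts:
    """Scale every library to the geometric mean of the totals.

    Pseudo-counts are rounded half-to-even to integers, the form the
    conditional exact test requires (it assumes equal library sizes).
    """
    totals = matrix.counts.sum(axis=0).astype(float)
    for sample, total in zip(matrix.sample_ids, totals):
        if total == 0:
            raise ValueError(f"sample {sample!r} has zero total counts")
    common = float(np.exp(np.mean(np.log(totals))))
    factors = common / totals
    pseudo = np.round(matrix.counts * factors).astype(np.int64)
    return EqualizedCounts(pseudo=pseudo, common_size=common, factors=factors)


# ---------------------------------------------------------------------------
# common dispersion
# ---------------------------------------------------------------------------


def _conditional_loglik(
    phi: float, group_blocks: list[np.ndarray], group_totals: list[np.ndarray]
) -> float:
    """Summed per-feature NB log-likelihood conditional on within-group totals."""
    r = 1.0 / phi
    total = 0.0
    for block, z in zip(group_blocks, group_totals):
        n_features, n = block.shape
        if n < 2:
            continue  # a single-sample group contributes exactly zero
        total += float(
            gammaln(block + r).sum()
            - n_features * n * gammaln(r)
            + n_features * gammaln(n * r)
            - gammaln(z + n * r).sum()
        )
    return total


def _golden_max(f, lo: float, hi: float, rtol: float) -> float:
    """Golden-section maximization on a log-scaled bracket."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = math.log(lo), math.log(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(math.exp(c)), f(math.exp(d))
    while (b - a) > rtol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(math.exp(d))
    return math.exp((a + b) / 2.0)


def estimate_common_dispersion(
    pseudo: np.ndarray,
    groups: Sequence[Sequence[int]],
    *,
    grid_points: int = 30,
    rtol: float = 1e-4,
) -> DispersionEstimate:
    """Maximize the summed conditional NB log-likelihood over phi.

    Coarse log-spaced grid on [1e-4, 4] refined by golden-section search.
    Features with all-zero counts are excluded; at least one group must
    have >= 2 samples.
    """
    pseudo = np.asarray(pseudo)
    keep = pseudo.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("no feature with positive counts")
    if not any(len(g) >= 2 for g in groups):
        raise ValueError("need at least one group with >= 2 samples")
    blocks = [pseudo[keep][:, list(g)].astype(float) for g in groups]
    totals = [b.sum(axis=1) for b in blocks]

    def objective(phi: float) -> float:
        return _conditional_loglik(phi, blocks, totals)

    grid = np.geomspace(PHI_GRID_LO, PHI_GRID_HI, grid_points)
    values = np.array([objective(p) for p in grid])
    best = int(values.argmax())
    if best == 0:
        return DispersionEstimate(phi=float(grid[0]))
    if best == len(grid) - 1:
        return DispersionEstimate(phi=float(grid[-1]))
    phi = _golden_max(objective, grid[best - 1], grid[best + 1], rtol)
    return DispersionEstimate(phi=float(phi))


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


def _betabinom_pmf(s: int, r_a: float, r_b: float) -> np.ndarray:
    """Conditional split pmf over x = 0..s via a multiplicative recurrence.

    w(x) ~ C(x + r_a - 1, x) * C(s - x + r_b - 1, s - x); the recurrence
    w(x+1) = w(x) * (x + r_a)(s - x) / ((x + 1)(s - x - 1 + r_b)) avoids
    differencing large log-gamma values, keeping the enumeration accurate
    to ~1e-14 even for large shape parameters.  Weights are rescaled on
    the fly to dodge overflow.
    """
    x = np.arange(s, dtype=float)
    ratios = ((x + r_a) * (s - x)) / ((x + 1.0) * (s - x - 1.0 + r_b))
    w = np.empty(s + 1)
    w[0] = 1.0
    current = 1.0
    for i in range(s):
        current *= ratios[i]
        if current > 1e250 or (0.0 < current < 1e-250):
            w[: i + 1] /= current
            current = 1.0
        w[i + 1] = current
    total = math.fsum(w)
    return w / total


def nb_exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    phi: float,
    *,
    big_total: int = 5000,
) -> float:
    """Two-sided conditional exact test p-value for a two-group split.

    Conditional on s = sum(a) + sum(b), the group-A sum follows a
    beta-binomial(n=s, a=n_a/phi, b=n_b/phi); p = min(1, 2 * min(lower
    tail, upper tail)) with the observed point mass in both tails.  For
    s > ``big_total`` the tails use a normal approximation with
    continuity correction (documented approximation); phi = 0 uses the
    exact binomial limit.
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("negative counts")
    n_a, n_b = len(counts_a), len(counts_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need at least one sample")
    ya = int(counts_a.sum())
    yb = int(counts_b.sum())
    s = ya + yb
    if s == 0:
        return 1.0
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if phi == 0.0:
        prob = n_a / (n_a + n_b)
        p_low = float(binom.cdf(ya, s, prob))
        p_high = float(binom.sf(ya - 1, s, prob))
        return min(1.0, 2.0 * min(p_low, p_high))
    r_a, r_b = n_a / phi, n_b / phi
    if s <= big_total:
        pmf = _betabinom_pmf(s, r_a, r_b)
        p_low = math.fsum(pmf[: ya + 1])
        p_high = math.fsum(pmf[ya:])
        return min(1.0, 2.0 * min(p_low, p_high))
    mean = s * r_a / (r_a + r_b)
    var = s * r_a * r_b * (r_a + r_b + s) / ((r_a + r_b) ** 2 * (r_a + r_b + 1.0))
    sd = math.sqrt(var)
    p_low = float(norm.cdf((ya + 0.5 - mean) / sd))
    p_high = float(norm.sf((ya - 0.5 - mean) / sd))
    return min(1.0, 2.0 * min(p_low, p_high))


# ---------------------------------------------------------------------------
# multiple testing and classification
# ---------------------------------------------------------------------------


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def classify(fold_change: float, fdr: float, cfg: TestConfig) -> str:
    """Volcano-style call: ENRICHED / DEPLETED when both gates pass, else NS."""
    if fdr < cfg.fdr_threshold:
        if fold_change >= cfg.fc_up:
            return "ENRICHED"
        if fold_change <= cfg.fc_down:
            return "DEPLETED"
    return "NS"


def run_enrichment(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    cfg: Optional[TestConfig] = None,
    *,
    dispersion: Optional[float] = None,
) -> tuple[list[EnrichmentResult], DispersionEstimate]:
    """Full two-group workflow on the samples of ``group_a`` vs ``group_b``.

    Fold change is group B over group A, computed from pseudo-counted
    group-mean CPMs so zero-count features stay finite.
    """
    cfg = cfg or TestConfig()
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    sub_ids = [matrix.sample_ids[i] for i in cols_a + cols_b]
    sub = CountMatrix(
        feature_names=list(matrix.feature_names),
        sample_ids=sub_ids,
        counts=matrix.counts[:, cols_a + cols_b],
        groups={s: matrix.groups[s] for s in sub_ids},
    )
    eq = equalize_libraries(sub)
    idx_a = list(range(len(cols_a)))
    idx_b = list(range(len(cols_a), len(cols_a) + len(cols_b)))
    if dispersion is None:
        est = estimate_common_dispersion(eq.pseudo, [idx_a, idx_b])
    else:
        est = DispersionEstimate(phi=dispersion, method="fixed")
    p_values = np.array(
        [
            nb_exact_test(
                eq.pseudo[f, idx_a], eq.pseudo[f, idx_b], est.phi, big_total=cfg.big_total
            )
            for f in range(eq.pseudo.shape[0])
        ]
    )
    q_values = bh_fdr(p_values)
    cpm_matrix = cpm(sub)
    mean_a = cpm_matrix.group_mean(group_a)
    mean_b = cpm_matrix.group_mean(group_b)
    fc = (mean_b + cfg.pseudo_count) / (mean_a + cfg.pseudo_count)
    results = []
    for f, name in enumerate(matrix.feature_names):
        gate = p_values[f] if cfg.use_raw_p else q_values[f]
        results.append(
            EnrichmentResult(
                feature=name,
                mean_cpm_a=float(mean_a[f]),
                mean_cpm_b=float(mean_b[f]),
                fold_change=float(fc[f]),
                log2fc=float(np.log2(fc[f])),
                p_value=float(p_values[f]),
                fdr=float(q_values[f]),
                classification=classify(float(fc[f]), float(gate), cfg),
            )
        )
    return results, est


def results_table(results: Sequence[EnrichmentResult]):
    """Results as a pandas DataFrame (machine-readable volcano table)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "mean_cpm_a": [r.mean_cpm_a for r in results],
            "mean_cpm_b": [r.mean_cpm_b for r in results],
            "fold_change": [r.fold_change for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "class": [r.classification for r in results],
        }
    )
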