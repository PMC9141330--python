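"""Published reference data bundled with the package.

``TOP10_ABUNDANCE`` holds the published top-10 mean-CPM abundance rows
for the four profiled populations (Mk, MkMP, PLT, PLP) of the deposited
study libraries (GEO accession GSE138887).  Each row is
(miR name, mean CPM, NCBI gene IDs).  These serve as worked examples for
the composition-ranking operations; the full libraries are not bundled.
"""

from __future__ import annotations

TOP10_ABUNDANCE: dict[str, list[tuple[str, int, str]]] = {
    "Mk": [
        ("miR-191-5p", 231441, "406966"),
        ("miR-486-5p", 195803, "723876"),
        ("miR-99b-5p", 164315, "407056"),
        ("miR-146b-5p", 65671, "574447"),
        ("miR-26a-5p", 39625, "407015/407016"),
        ("let-7f-5p", 23623, "406888/406889"),
        ("miR-126-5p", 22642, "406913"),
        ("miR-146a-5p", 21993, "406938"),
        ("miR-21-5p", 20197, "406991"),
        ("miR-148a-3p", 17054, "406940"),
    ],
    "MkMP": [
        ("miR-486-5p", 164087, "723876"),
        ("miR-191-5p", 117782, "406966"),
        ("miR-26a-5p", 91774, "407015/407016"),
        ("let-7f-5p", 68251, "406888/406889"),
        ("miR-92a-3p", 44480, "407048/407049"),
        ("miR-126-5p", 44218, "406913"),
        ("miR-22-3p", 43152, "407004"),
        ("miR-21-5p", 38617, "406991"),
        ("miR-146b-5p", 34455, "574447"),
        ("miR-181a-5p", 33752, "406995/406996"),
    ],
    "PLT": [
        ("miR-191-5p", 263871, "406966"),
        ("miR-486-5p", 80546, "723876"),
        ("let-7f-5p", 76283, "406888/406889"),
        ("miR-99b-5p", 71050, "407056"),
        ("miR-10a-5p", 54139, "406902"),
        ("miR-26a-5p", 51712, "407015/407016"),
        ("miR-146a-5p", 43647, "406938"),
        ("miR-92a-3p", 43032, "407048/407049"),
        ("miR-146b-5p", 25104, "574447"),
        ("miR-181a-5p", 23932, "406995/406996"),
    ],
    "PLP": [
        ("miR-191-5p", 162495, "406966"),
        ("miR-486-5p", 146874, "723876"),
        ("miR-26a-5p", 84857, "407015/407016"),
        ("let-7f-5p", 64288, "406888/406889"),
        ("miR-146b-5p", 49986, "574447"),
        ("miR-126-5p", 43506, "406913"),
        ("miR-99b-5p", 42826, "407056"),
        ("miR-21-5p", 40419, "406991"),
        ("miR-22-3p", 32727, "407004"),
        ("miR-181a-5p", 25520, "406995/406996"),
    ],
}


def top10_cpm(group: str) -> list[tuple[str, float]]:
    """(miR name, published mean CPM) rows for one population."""
    return [(name, float(cpm)) for name, cpm, _gene in TOP10_ABUNDANCE[group]]
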