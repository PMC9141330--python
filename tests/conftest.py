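import numpy as np
import pytest

from mirtally.io_formats import MatureMiR, SampleManifest, SmallRNARead
from mirtally.read_processing import TrimParams

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@pytest.fixture
def params() -> TrimParams:
    return TrimParams(adapter=ADAPTER)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def small_reference() -> list[MatureMiR]:
    return [
        MatureMiR(name="hsa-miR-22-3p", sequence="AAGCTGCCAGTTGAAGAACTGT"),
        MatureMiR(name="hsa-miR-486-5p", sequence="TCCTGTACTGAGCTGCCCCGAG"),
        MatureMiR(name="hsa-mir-19b-1-3p", sequence="TGTGCAAATCCATGCAAAACTGA"),
        MatureMiR(name="hsa-mir-19b-2-3p", sequence="TGTGCAAATCCATGCAAAACTGA"),
    ]


def make_read(sequence: str, quality: int = 38, read_id: str = "r") -> SmallRNARead:
    return SmallRNARead(read_id=read_id, sequence=sequence, qualities=[quality] * len(sequence))


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


@pytest.fixture
def manifest_1sample(tmp_path) -> SampleManifest:
    return SampleManifest(entries=[("s1", str(tmp_path / "s1.fastq"), "G1")])
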