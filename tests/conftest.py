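import numpy as np
import pytest

from ladkit.gatc import GatcFragmentMap, GenomeSequence, build_fragment_map


@pytest.fixture
def toy_fragment_map() -> GatcFragmentMap:
    """Fragments [0,3), [3,10), [10,14) on a 14 bp chromosome."""
    return build_fragment_map(GenomeSequence("chrT", "GGATCAAAGATCCC"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    return "".join(rng.choice(list(alphabet), size=length))


def make_track(scores, chrom="chrT", frag_len=100):
    """A score track over uniform-length fragments; NaN entries are missing."""
    from ladkit.damid import DamidScoreTrack

    scores = np.asarray(scores, dtype=float)
    n = scores.size
    bounds = np.arange(n + 1) * frag_len
    frags = np.column_stack([bounds[:-1], bounds[1:]])
    fm = GatcFragmentMap(chrom, int(n * frag_len), bounds[1:-1], frags)
    missing = ~np.isfinite(scores)
    return DamidScoreTrack(fm, scores, missing)
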