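import sys

import pytest

from mimicscan.alignment import ScoringScheme
from mimicscan.io_formats import PipelineConfig
from mimicscan.synthetic import generate_study

sys.setrecursionlimit(100_000)


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def study():
    """The default synthetic study at seed 0: 37 antigens, 74 excised
    15-mer epitopes, ~10^5-residue proteome with 5 mimics planted at each
    divergence level d = 0..4."""
    return generate_study(seed=0)


def brute_force_local_score(a_idx, b_idx, sub, gap_first: int = 12,
                            gap_extend: int = 1) -> int:
    """Independent oracle: exhaustive enumeration of every local alignment
    (all start pairs, all match/gap column sequences with affine gap costs).
    Alignments are scored when they end on a match column; leading/trailing
    gap columns only lower a local score, so this loses no optima."""
    best = 0
    la, lb = len(a_idx), len(b_idx)

    def rec(i, j, score, state):
        nonlocal best
        if state == 0 and score > best:
            best = score
        if i < la and j < lb:
            rec(i + 1, j + 1, score + sub[a_idx[i], b_idx[j]], 0)
        if i < la:
            rec(i + 1, j, score - (gap_extend if state == 1 else gap_first), 1)
        if j < lb:
            rec(i, j + 1, score - (gap_extend if state == 2 else gap_first), 2)

    for i in range(la):
        for j in range(lb):
            rec(i + 1, j + 1, int(sub[a_idx[i], b_idx[j]]), 0)
    return int(best)
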