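import numpy as np
import pytest

from nanopost.model import ChainState, ForceFieldParams


def make_saw_chain(n: int, seed: int = 0, bond: float = 0.97,
                   min_sep: float = 0.95, S_p: float = None,
                   post_clearance: float = 2.35) -> np.ndarray:
    """Self-avoiding random chain built by rejection: consecutive beads at
    the given bond length, all pairs at least ``min_sep`` apart.

    A geometric construction (no Boltzmann sampling) that yields a valid,
    non-overlapping test configuration with moderate energies, so that
    finite-difference force checks are not drowned in roundoff.  When
    ``S_p`` is given the chain additionally keeps every bead at least
    ``post_clearance`` from every lattice node in the yz plane (so it
    threads the array without grazing a post).
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    if S_p is not None:
        pos[0, 1:] = S_p / 2.0  # start at a cell centre
    i = 1
    while i < n:
        d = rng.normal(size=3)
        d *= bond / np.linalg.norm(d)
        cand = pos[i - 1] + d
        if i >= 2 and np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) <= min_sep:
            continue
        if S_p is not None:
            yz = cand[1:] - np.round(cand[1:] / S_p) * S_p
            if np.hypot(*yz) < post_clearance:
                continue
        pos[i] = cand
        i += 1
    return pos


@pytest.fixture
def flexible_params() -> ForceFieldParams:
    return ForceFieldParams()


@pytest.fixture
def stiff_params() -> ForceFieldParams:
    return ForceFieldParams(stiffness=20.0)


@pytest.fixture
def saw_chain() -> ChainState:
    return ChainState(make_saw_chain(20, seed=42))
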