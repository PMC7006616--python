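"""Shared fixtures: small synthetic scenarios generated at test time."""

import numpy as np
import pytest

from chlamytrack import SimScenario, SubPop


@pytest.fixture(scope="session")
def straight_scenario() -> SimScenario:
    """Well-separated straight swimmers at 20 µm/s (no heading noise)."""
    return SimScenario(
        n_cells=20, n_frames=40, field_width_px=512, field_height_px=512,
        subpopulations=[SubPop("s20", 1.0, 20.0, 0.0, 0.0)],
        min_separation_px=40, noise_sd=0.0, seed=101,
    )


@pytest.fixture(scope="session")
def fidelity_scenario() -> SimScenario:
    """20 wiggly swimmers that stay well separated for a whole 30-s clip."""
    return SimScenario(
        n_cells=20, n_frames=225, field_width_px=512, field_height_px=512,
        subpopulations=[SubPop("wt", 1.0, 5.0, 0.0, 1.0)],
        min_separation_px=80, noise_sd=0.0, seed=7,
    )


def brute_force_assignment(cost: np.ndarray) -> float:
    """Exhaustive-permutation minimum total cost (independent oracle)."""
    from itertools import permutations

    n = cost.shape[0]
    best = np.inf
    for perm in permutations(range(n)):
        total = sum(cost[i, perm[i]] for i in range(n))
        best = min(best, total)
    return best
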