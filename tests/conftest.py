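import numpy as np
import pytest

from dyam.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient default-condition cohort shared across tests."""
    return generate_cohort(CohortConfig(n_patients=120, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def brute_force_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int, offsets) -> np.ndarray:
    """Exhaustive symmetric co-occurrence enumeration (test oracle)."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    counts = np.zeros((n_levels, n_levels))
    for idx in np.ndindex(*levels.shape):
        if not mask[idx]:
            continue
        for off in offsets:
            for sign in (1, -1):
                nbr = tuple(i + sign * d for i, d in zip(idx, off))
                if all(0 <= c < s for c, s in zip(nbr, levels.shape)) and mask[nbr]:
                    counts[levels[idx], levels[nbr]] += 1
    total = counts.sum()
    return counts / total if total else counts
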