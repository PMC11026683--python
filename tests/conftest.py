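import numpy as np
import pytest

from capdyn import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """1 subject per cell, 200 frames, 144 voxels, 6 states, noise 0.3."""
    design = sc.CohortDesign(
        n_per_cell=1, n_frames=200, grid_shape=(6, 6, 4), noise_sd=0.3, seed=7
    )
    manifest, scans, truth = sc.generate_cohort(design)
    return design, manifest, scans, truth


@pytest.fixture(scope="session")
def small_frames(small_cohort):
    """Concatenated (N, m) frame stack + aligned true state labels."""
    design, manifest, scans, truth = small_cohort
    X = np.vstack([scans[s].data.T for s in manifest.subject_id])
    states = np.concatenate([truth.sequences[s] for s in manifest.subject_id])
    return X, states


def match_states(labels, truth_labels, K):
    """Best 1-based label permutation (Hungarian) and agreement fraction."""
    from scipy.optimize import linear_sum_assignment

    C = np.zeros((K, K))
    for a, b in zip(labels, truth_labels):
        C[a - 1, b - 1] += 1
    r, c = linear_sum_assignment(-C)
    mapping = {ri + 1: ci + 1 for ri, ci in zip(r, c)}
    agreement = C[r, c].sum() / len(labels)
    return mapping, agreement
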