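"""Calibration and recovery experiments on synthetic cohorts.

Reusable study-condition experiments: voxelwise type-I calibration of the
between-condition ISC contrast, sensitivity/false-discovery measurement
against a planted ISC difference, and the eye-gaze group-test analogues.
Each function runs the full pipeline on freshly generated data and returns
plain numbers, so the same code backs the test suite and the reproduction
script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eyeisc import (detect_fixations, drift_correct, eisc_group_test,
                     eisc_pairwise, window_heatmaps)
from .inference import build_contrast_design, isc_condition_contrast
from .synthetic import (CohortSpec, EffectRegion, GazeSpec, displaced_sequence,
                        make_attractor_sequence, simulate_bold_cohort,
                        simulate_gaze, weight_for_isc)


@dataclass
class CalibrationResult:
    type_one_rate: float      # fraction of null p-values < alpha
    p_values: np.ndarray      # pooled voxelwise permutation p-values
    n_simulations: int
    alpha: float


def _cohort(c_a: float, c_b: float, n_subjects: int, n_trs: int,
            grid: tuple[int, int, int], box, noise_sd: float, seed: int):
    regions = []
    for cond, c in (("genetic", c_a), ("nongenetic", c_b)):
        if c > 0:
            regions.append(EffectRegion(box=box, condition=cond,
                                        weight=weight_for_isc(c, noise_sd)))
    spec = CohortSpec(n_subjects=n_subjects, n_trs=n_trs, grid_shape=grid,
                      noise_sd=noise_sd, effect_regions=regions, seed=seed)
    return simulate_bold_cohort(spec)


def contrast_type_one_calibration(n_simulations: int = 200, n_subjects: int = 8,
                                  n_trs: int = 150, n_permutations: int = 200,
                                  grid: tuple[int, int, int] = (4, 4, 2),
                                  shared_isc: float = 0.3, alpha: float = 0.05,
                                  seed: int = 0) -> CalibrationResult:
    """Voxelwise type-I error of the condition contrast under the null.

    The null cohort carries a belief-independent stimulus component (true
    ISC ``shared_isc`` in both conditions from one common course — every
    viewing shows the same movie), so any detection is a false positive;
    the pooled voxelwise p-values should be uniform and their sub-``alpha``
    fraction close to ``alpha``.
    """
    rng = np.random.default_rng(seed)
    box = ((0, grid[0]), (0, grid[1]), (0, grid[2]))
    pooled = []
    for _ in range(n_simulations):
        sim_seed = int(rng.integers(2**31))
        spec = CohortSpec(
            n_subjects=n_subjects, n_trs=n_trs, grid_shape=grid, noise_sd=0.8,
            effect_regions=[EffectRegion(box=box, condition="both",
                                         weight=weight_for_isc(shared_isc, 0.8))],
            seed=sim_seed)
        runs, _ = simulate_bold_cohort(spec)
        design = build_contrast_design(runs)
        sm = isc_condition_contrast(design, n_permutations=n_permutations,
                                    seed=int(rng.integers(2**31)))
        pooled.append(sm.p)
    p = np.concatenate(pooled)
    return CalibrationResult(type_one_rate=float(np.mean(p < alpha)),
                             p_values=p, n_simulations=n_simulations,
                             alpha=alpha)


@dataclass
class RecoveryResult:
    sensitivity: float            # fraction of planted voxels in the FDR mask
    false_discovery_rate: float   # false positives / all positives
    false_positive_rate: float    # false positives / non-planted voxels
    n_planted: int
    n_detected: int


def contrast_recovery(c_a: float = 0.5, c_b: float = 0.1, n_subjects: int = 12,
                      n_trs: int = 300, n_permutations: int = 1000,
                      grid: tuple[int, int, int] = (8, 8, 4),
                      box=((2, 6), (2, 6), (0, 4)), q: float = 0.05,
                      seed: int = 0) -> RecoveryResult:
    """Recovery of a planted between-condition ISC difference.

    Both conditions share stimulus-locked signal in the same voxel box, but
    with couplings giving true ISC ``c_a`` vs ``c_b``; the FDR mask of the
    contrast is scored against the planted difference mask.
    """
    runs, truth = _cohort(c_a, c_b, n_subjects, n_trs, grid, box, 0.8, seed)
    design = build_contrast_design(runs)
    sm = isc_condition_contrast(design, n_permutations=n_permutations,
                                seed=seed + 1, q=q)
    planted = truth.difference_mask
    detected = sm.mask
    tp = int((detected & planted).sum())
    fp = int((detected & ~planted).sum())
    return RecoveryResult(
        sensitivity=tp / max(int(planted.sum()), 1),
        false_discovery_rate=fp / max(tp + fp, 1),
        false_positive_rate=fp / max(int((~planted).sum()), 1),
        n_planted=int(planted.sum()), n_detected=tp + fp)


def _gaze_pipeline(displacement_deg: float, n_per_group: int, duration_s: float,
                   n_permutations: int, seed: int) -> float:
    """Full gaze pipeline on one synthetic cohort; returns the group-test p."""
    seq = make_attractor_sequence(duration_s, seed=seed + 10_000)
    spec = GazeSpec(duration_s=duration_s,
                    attractors={"genetic": seq, "nongenetic": seq}, seed=seed)
    if displacement_deg:
        spec.mixture = {"nongenetic": (
            displaced_sequence(seq, displacement_deg, fraction=1.0,
                               seed=seed + 20_000), 0.5)}
    recs = simulate_gaze(spec, {"genetic": n_per_group,
                                "nongenetic": n_per_group})
    fixsets = [detect_fixations(r.t, r.x, r.y, recording_id=r.recording_id,
                                group=r.group) for r in recs]
    fixsets = drift_correct(fixsets)
    stacks = [window_heatmaps(fs, duration_s=duration_s) for fs in fixsets]
    matrix = eisc_pairwise(stacks)
    return eisc_group_test(matrix, n_permutations=n_permutations,
                           seed=seed + 1).p_value


def eyeisc_null_calibration(n_simulations: int = 100, n_per_group: int = 6,
                            duration_s: float = 12.0,
                            n_permutations: int = 2000,
                            alpha: float = 0.05, seed: int = 0) -> float:
    """False-positive rate of the gaze group test on null cohorts."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_simulations):
        p = _gaze_pipeline(0.0, n_per_group, duration_s, n_permutations,
                           int(rng.integers(2**31 - 30_000)))
        hits += p < alpha
    return hits / n_simulations


def eyeisc_planted_detection(displacement_deg: float = 5.0,
                             n_per_group: int = 20, duration_s: float = 20.0,
                             n_permutations: int = 2000,
                             seed: int = 0) -> float:
    """p-value of the gaze group test with a planted attractor displacement."""
    return _gaze_pipeline(displacement_deg, n_per_group, duration_s,
                          n_permutations, seed)
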