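"""Permutation inference on ISC maps.

Voxelwise significance of pooled pairwise ISC (one-group, circular-shift
surrogate null), the between-condition contrast on Fisher-Z pair values
with a subject-level exchangeability null, Benjamini-Hochberg FDR, minimum
cluster-extent filtering, and the max-p conjunction (intersection-union)
test.

The contrast null deserves a note.  Pair correlations are not independent
(pairs share subjects), so permuting pair labels would be invalid.  The
exchangeable unit under the null "belief condition does not matter" is the
subject: a permutation swaps the genetic and non-genetic session sets of a
random subset of subjects, and the pooled pair statistic is rebuilt.  A
swap involving exactly one member of a pair turns both of that pair's
condition entries into mixed-condition correlations, so the design
precomputes all four tensors (AA, BB, AB, BA) once and every permutation is
pure indexing — no correlation is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .isc import (FISHER_CLAMP, BoldRun, PairCorrelationTensor, PairSet,
                  _pair_correlations, enumerate_pairs, index_runs,
                  standardized_data)


@dataclass
class StatMap:
    """Per-voxel statistic, permutation p, and FDR-thresholded mask."""

    stat: np.ndarray
    p: np.ndarray
    q: float
    p_cutoff: float          # largest rejected p (adaptive BH threshold)
    stat_threshold: float    # smallest |stat| among rejected voxels
    mask: np.ndarray
    tail: str
    n_permutations: int
    seed: int
    grid_shape: tuple[int, int, int] | None = None

    def volume(self, values: np.ndarray | None = None) -> np.ndarray:
        """Reshape a flat per-voxel array (default: the statistic) to 3-D."""
        if self.grid_shape is None:
            raise ValueError("no grid shape recorded")
        v = self.stat if values is None else values
        return np.asarray(v).reshape(self.grid_shape)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: reject p_(1..k) for the largest k with
    p_(k) <= k*q/m.  Returns (boolean mask, largest rejected p; NaN if none).

    NaN p-values are ignored (never rejected) and excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    flat = p.ravel()
    valid = np.flatnonzero(~np.isnan(flat))
    m = valid.size
    if m == 0:
        return mask, float("nan")
    order = valid[np.argsort(flat[valid], kind="stable")]
    sorted_p = flat[order]
    crit = (np.arange(1, m + 1) / m) * q
    below = np.flatnonzero(sorted_p <= crit)
    if below.size == 0:
        return mask, float("nan")
    k = below[-1] + 1
    mask.ravel()[order[:k]] = True
    return mask, float(sorted_p[k - 1])


def cluster_filter(mask: np.ndarray, min_extent_voxels: int = 64,
                   connectivity: int = 6) -> np.ndarray:
    """Drop connected components smaller than ``min_extent_voxels``.

    ``connectivity`` in {6, 18, 26} (face / face+edge / full neighbours);
    the default 64-voxel extent corresponds to a 4 x 4 x 4 block.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("cluster_filter expects a 3-D mask")
    if min_extent_voxels < 1:
        raise ValueError("min_extent_voxels must be >= 1")
    structure = _connectivity_structure(connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.astype(bool).copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_extent_voxels
    keep[0] = False
    return keep[labels]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def conjunction_max_p(p_map_a: np.ndarray, p_map_b: np.ndarray,
                      q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Intersection-union conjunction: voxelwise max p, then BH-FDR at q."""
    p_map_a = np.asarray(p_map_a, dtype=float)
    p_map_b = np.asarray(p_map_b, dtype=float)
    if p_map_a.shape != p_map_b.shape:
        raise ValueError("p-map shapes differ")
    conj = np.fmax(p_map_a, p_map_b)
    conj[np.isnan(p_map_a) | np.isnan(p_map_b)] = np.nan
    mask, _ = bh_fdr(conj, q)
    return conj, mask


@dataclass
class ContrastDesign:
    """Matched-pair ISC contrast between two conditions.

    ``z_aa[v, k]``/``z_bb[v, k]`` are the k-th matched pair's Fisher-Z
    values within condition A/B; ``z_ab``/``z_ba`` are the mixed-condition
    correlations (first subject's A session vs second's B session, and the
    reverse) needed to rebuild the statistic under subject-level condition
    swaps.  ``subj_i``/``subj_j`` give each pair's subject indices.
    """

    z_aa: np.ndarray
    z_bb: np.ndarray
    z_ab: np.ndarray
    z_ba: np.ndarray
    subj_i: np.ndarray
    subj_j: np.ndarray
    pairs_a: PairSet
    pairs_b: PairSet
    condition_a: str
    condition_b: str
    n_subjects: int
    grid_shape: tuple[int, int, int] | None = None
    exchange_unit: str = "subject"

    @property
    def n_pairs(self) -> int:
        return self.z_aa.shape[1]


def build_contrast_design(runs: Sequence[BoldRun], condition_a: str = "genetic",
                          condition_b: str = "nongenetic") -> ContrastDesign:
    """Precompute all within- and mixed-condition pair correlations."""
    lookup = index_runs(runs)
    subjects = sorted({r.subject_id for r in runs})
    sessions = sorted({r.session_index for r in runs
                      if r.condition == condition_a})
    n_sess = len(sessions)
    subj_pos = {s: i for i, s in enumerate(subjects)}
    pairs_a = enumerate_pairs(len(subjects), n_sess, condition_a)
    pairs_b = enumerate_pairs(len(subjects), n_sess, condition_b)

    std = {}
    for (subj, cond, sess), run in lookup.items():
        std[(subj, cond, sess)] = standardized_data(run)
    n_vox = next(iter(std.values())).shape[0]
    n_pairs = len(pairs_a)
    tensors = {k: np.empty((n_vox, n_pairs)) for k in ("aa", "bb", "ab", "ba")}
    subj_i = np.empty(n_pairs, dtype=int)
    subj_j = np.empty(n_pairs, dtype=int)
    for col, ((pi, sa), (pj, sb)) in enumerate(pairs_a.pairs):
        si, sj = subjects[pi], subjects[pj]
        subj_i[col], subj_j[col] = pi, pj
        for key, (ci, cj) in (("aa", (condition_a, condition_a)),
                              ("bb", (condition_b, condition_b)),
                              ("ab", (condition_a, condition_b)),
                              ("ba", (condition_b, condition_a))):
            r = _pair_correlations(std[(si, ci, sa)], std[(sj, cj, sb)])
            tensors[key][:, col] = np.arctanh(
                np.clip(r, -1 + FISHER_CLAMP, 1 - FISHER_CLAMP))
    grid = runs[0].mask.shape if runs[0].mask is not None else None
    return ContrastDesign(z_aa=tensors["aa"], z_bb=tensors["bb"],
                          z_ab=tensors["ab"], z_ba=tensors["ba"],
                          subj_i=subj_i, subj_j=subj_j,
                          pairs_a=pairs_a, pairs_b=pairs_b,
                          condition_a=condition_a, condition_b=condition_b,
                          n_subjects=len(subjects), grid_shape=grid)


def design_from_tensors(tensor_a: PairCorrelationTensor,
                        tensor_b: PairCorrelationTensor) -> ContrastDesign:
    """Degenerate design from two matched tensors only (no mixed pairs).

    Sufficient for the observed statistic; permutations then treat a
    single-member swap as exchanging the pair's A and B values, which is
    exact only when the two tensors carry all condition information (e.g.
    precomputed summaries).  Prefer :func:`build_contrast_design` on runs.
    """
    if tensor_a.z.shape != tensor_b.z.shape:
        raise ValueError("tensors are not matched")
    pa = tensor_a.pairs
    subj_i = np.array([p[0][0] for p in pa.pairs])
    subj_j = np.array([p[1][0] for p in pa.pairs])
    return ContrastDesign(z_aa=tensor_a.z, z_bb=tensor_b.z,
                          z_ab=tensor_a.z, z_ba=tensor_b.z,
                          subj_i=subj_i, subj_j=subj_j,
                          pairs_a=pa, pairs_b=tensor_b.pairs,
                          condition_a=pa.condition,
                          condition_b=tensor_b.pairs.condition,
                          n_subjects=pa.n_subjects)


def _paired_t(delta: np.ndarray) -> np.ndarray:
    """Row-wise one-sample t of voxel x pair differences."""
    n = delta.shape[1]
    mean = delta.mean(axis=1)
    sd = delta.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where((sd == 0) & (mean == 0), 0.0, t)  # exactly-equal tensors


def isc_condition_contrast(design: ContrastDesign, n_permutations: int = 1000,
                           seed: int = 0, q: float = 0.05) -> StatMap:
    """Between-condition ISC contrast with a subject-exchange permutation null.

    Observed statistic: per voxel, one-sample t of the matched-pair Fisher-Z
    differences (z_A - z_B).  Null: each permutation swaps the condition
    labels of a random subset of subjects and rebuilds the pooled statistic
    from the precomputed tensors.  Two-sided p with the (1+k)/(1+n) floor,
    then BH-FDR at ``q``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if design.n_pairs == 0:
        raise ValueError("design has no matched pairs")
    d_same = design.z_aa - design.z_bb          # no swap (or both swapped: sign flips)
    d_cross = design.z_ba - design.z_ab         # exactly the first subject swapped
    n_pairs = design.n_pairs
    missing = (np.isnan(d_same).any(axis=1) | np.isnan(d_cross).any(axis=1))

    t_obs = _paired_t(d_same)
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_permutations, design.n_subjects))
    fi = flips[:, design.subj_i]                # (n_perm, n_pairs)
    fj = flips[:, design.subj_j]
    same = fi == fj
    # signed selection weights for each permutation and pair
    w_same = np.where(same, 1 - 2 * fi, 0).T.astype(float)    # (n_pairs, n_perm)
    w_cross = np.where(~same, 2 * fi - 1, 0).T.astype(float)
    a_same = np.abs(w_same)
    a_cross = 1.0 - a_same

    ds = np.nan_to_num(d_same)
    dc = np.nan_to_num(d_cross)
    mean_p = (ds @ w_same + dc @ w_cross) / n_pairs
    meansq_p = (ds ** 2 @ a_same + dc ** 2 @ a_cross) / n_pairs
    var_p = (meansq_p - mean_p ** 2) * (n_pairs / (n_pairs - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_perm = mean_p / np.sqrt(var_p / n_pairs)
    t_perm = np.where(np.isclose(var_p, 0.0) & (mean_p == 0), 0.0, t_perm)

    exceed = (np.abs(t_perm) >= np.abs(t_obs)[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (1.0 + n_permutations)
    p[missing] = np.nan
    t_obs = t_obs.copy()
    t_obs[missing] = np.nan
    mask, cutoff = bh_fdr(p, q)
    thr = float(np.min(np.abs(t_obs[mask]))) if mask.any() else float("nan")
    return StatMap(stat=t_obs, p=p, q=q, p_cutoff=cutoff, stat_threshold=thr,
                   mask=mask, tail="two-sided", n_permutations=n_permutations,
                   seed=seed, grid_shape=design.grid_shape)


def isc_one_group_test(runs: Sequence[BoldRun], pairs: PairSet,
                       n_permutations: int = 500, seed: int = 0,
                       q: float = 0.05, min_shift: int = 10) -> StatMap:
    """One-group ISC significance against a circular-time-shift null.

    Statistic: per-voxel mean Fisher-Z over all pairs.  Surrogates circularly
    shift every run by an independent random offset (>= ``min_shift`` TRs),
    destroying stimulus-locked alignment while preserving autocorrelation;
    one-sided p (mean z > 0) with the (1+k)/(1+n) floor, then BH-FDR.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    lookup = index_runs(runs)
    cond = pairs.condition
    std = {key[::2]: standardized_data(run) for key, run in lookup.items()
           if key[1] == cond}
    n_vox, n_trs = next(iter(std.values())).shape
    if min_shift >= n_trs - min_shift:
        raise ValueError("min_shift too large for run length")
    pair_keys = [((i, a), (j, b)) for (i, a), (j, b) in pairs.pairs]

    def mean_z(data: dict) -> np.ndarray:
        acc = np.zeros(n_vox)
        for (ka, kb) in pair_keys:
            r = _pair_correlations(data[ka], data[kb])
            acc += np.arctanh(np.clip(r, -1 + FISHER_CLAMP, 1 - FISHER_CLAMP))
        return acc / len(pair_keys)

    obs = mean_z(std)
    rng = np.random.default_rng(seed)
    keys = list(std)
    exceed = np.zeros(n_vox)
    for _ in range(n_permutations):
        shifts = rng.integers(min_shift, n_trs - min_shift, size=len(keys))
        shifted = {k: np.roll(std[k], int(s), axis=1)
                   for k, s in zip(keys, shifts)}
        exceed += mean_z(shifted) >= obs
    p = (1.0 + exceed) / (1.0 + n_permutations)
    mask, cutoff = bh_fdr(p, q)
    thr = float(np.min(obs[mask])) if mask.any() else float("nan")
    grid = runs[0].mask.shape if runs[0].mask is not None else None
    return StatMap(stat=obs, p=p, q=q, p_cutoff=cutoff, stat_threshold=thr,
                   mask=mask, tail="greater", n_permutations=n_permutations,
                   seed=seed, grid_shape=grid)
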