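"""Inter-subject correlation of eye gaze (eyeISC).

Fixations are detected from raw gaze samples with velocity/acceleration
thresholds (30 deg/s, 4000 deg/s^2), mean drift is removed by rigidly
shifting each recording's fixation cloud onto the grand mean, fixations are
rendered as truncated Gaussian heatmaps (sigma 1 deg, radius 3 sigma) in
2 s windows, heatmap pairs are correlated per window, and the group
question -- do both-believers-in-genetic pairs synchronize their gaze more
than both-believers-in-adoption pairs? -- is answered with a recording-label
permutation test on the pairwise mean eyeISC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .isc import FISHER_CLAMP, fisher_z_inv


@dataclass
class FixationSet:
    """Detected fixations of one recording: onset s, duration s, x/y deg."""

    recording_id: int
    group: str
    onsets: np.ndarray
    durations: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def mean_location(self) -> np.ndarray:
        return np.array([self.x.mean(), self.y.mean()])


@dataclass
class HeatmapStack:
    """Per-window gaze density grids of one recording (unit mass/fixation)."""

    recording_id: int
    group: str
    maps: np.ndarray           # (n_windows, ny, nx)
    missing: np.ndarray        # (n_windows,) True where no fixation fell
    grid_res_deg: float
    screen_extent: tuple[float, float]


@dataclass
class EiscMatrix:
    """Window x recording-pair Fisher-Z gaze correlations."""

    z: np.ndarray              # (n_windows, n_pairs), NaN = missing
    pair_index: list[tuple[int, int]]
    groups: list[str]          # per recording
    recording_ids: list[int]

    @property
    def pair_classes(self) -> list[str]:
        """'both-<g>' when the pair shares group g, else 'mixed'."""
        out = []
        for i, j in self.pair_index:
            gi, gj = self.groups[i], self.groups[j]
            out.append(f"both-{gi}" if gi == gj else "mixed")
        return out


def detect_fixations(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                     valid: np.ndarray | None = None,
                     velocity_thresh: float = 30.0,
                     accel_thresh: float = 4000.0,
                     min_duration_s: float = 0.02,
                     recording_id: int = 0, group: str = "") -> FixationSet:
    """Velocity/acceleration-threshold saccade detection.

    Samples whose gaze speed exceeds ``velocity_thresh`` (deg/s) or whose
    acceleration magnitude exceeds ``accel_thresh`` (deg/s^2) are saccade
    samples; maximal runs of the remaining valid samples become fixations at
    their centroid.  Invalid samples (blinks) split fixations.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if valid is None:
        valid = np.ones(t.shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(x) & np.isfinite(y)
    empty = FixationSet(recording_id, group, *(np.empty(0),) * 4)
    if t.size < 3:
        return empty

    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    ax = np.gradient(vx, t)
    ay = np.gradient(vy, t)
    accel = np.hypot(ax, ay)
    keep = valid & (speed <= velocity_thresh) & (accel <= accel_thresh)

    onsets, durations, xs, ys = [], [], [], []
    dt_med = float(np.median(np.diff(t)))
    boundaries = np.flatnonzero(np.diff(keep.astype(int)))
    starts = ([0] if keep[0] else []) + [b + 1 for b in boundaries if keep[b + 1]]
    ends = [b + 1 for b in boundaries if keep[b]] + ([t.size] if keep[-1] else [])
    for s, e in zip(starts, ends):
        dur = t[e - 1] - t[s] + dt_med
        if dur < min_duration_s:
            continue
        onsets.append(t[s])
        durations.append(dur)
        xs.append(x[s:e].mean())
        ys.append(y[s:e].mean())
    if not onsets:
        return empty
    return FixationSet(recording_id, group, np.array(onsets),
                       np.array(durations), np.array(xs), np.array(ys))


def drift_correct(fixation_sets: Sequence[FixationSet]) -> list[FixationSet]:
    """Rigidly shift each recording so its mean fixation hits the grand mean.

    The grand mean is the average of per-recording mean fixation locations;
    after correction every recording's mean equals it exactly.
    """
    if not fixation_sets:
        raise ValueError("need at least one fixation set")
    means = np.array([fs.mean_location for fs in fixation_sets])
    grand = means.mean(axis=0)
    out = []
    for fs, m in zip(fixation_sets, means):
        dx, dy = grand - m
        out.append(replace(fs, x=fs.x + dx, y=fs.y + dy))
    return out


def _truncated_gaussian_kernel(sigma_deg: float, radius_sigmas: float,
                               grid_res: float) -> np.ndarray:
    """Unit-sum Gaussian stamp truncated at ``radius_sigmas``."""
    r_cells = int(math.ceil(radius_sigmas * sigma_deg / grid_res))
    ax = (np.arange(-r_cells, r_cells + 1)) * grid_res
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    d2 = gx ** 2 + gy ** 2
    k = np.exp(-d2 / (2.0 * sigma_deg ** 2))
    k[np.sqrt(d2) > radius_sigmas * sigma_deg] = 0.0
    return k / k.sum()


def window_heatmaps(fixations: FixationSet, duration_s: float,
                    window_s: float = 2.0, sigma_deg: float = 1.0,
                    radius_sigmas: float = 3.0, grid_res_deg: float = 0.25,
                    screen_extent: tuple[float, float] = (24.0, 18.0),
                    duration_weighted: bool = False) -> HeatmapStack:
    """Per-window fixation heatmaps (sum of truncated unit-mass Gaussians).

    ``ceil(duration_s / window_s)`` windows; a fixation contributes to every
    window it overlaps.  The kernel is normalized to unit mass over its
    truncated support, so total map mass equals the number of contributing
    fixations except for clipping at the screen edge.  With
    ``duration_weighted`` each contribution is scaled by the fixation's
    overlap (s) with the window.
    """
    if grid_res_deg > sigma_deg / 2:
        raise ValueError("grid resolution must be <= sigma/2")
    n_windows = int(math.ceil(duration_s / window_s))
    w, h = screen_extent
    nx = int(round(w / grid_res_deg))
    ny = int(round(h / grid_res_deg))
    maps = np.zeros((n_windows, ny, nx))
    kernel = _truncated_gaussian_kernel(sigma_deg, radius_sigmas, grid_res_deg)
    r_cells = kernel.shape[0] // 2
    for on, dur, fx, fy in zip(fixations.onsets, fixations.durations,
                               fixations.x, fixations.y):
        w0 = max(int(on // window_s), 0)
        w1 = min(int((on + dur - 1e-12) // window_s), n_windows - 1)
        ci = int(round(fy / grid_res_deg - 0.5))
        cj = int(round(fx / grid_res_deg - 0.5))
        i0, i1 = ci - r_cells, ci + r_cells + 1
        j0, j1 = cj - r_cells, cj + r_cells + 1
        ki0, kj0 = max(-i0, 0), max(-j0, 0)
        ki1 = kernel.shape[0] - max(i1 - ny, 0)
        kj1 = kernel.shape[1] - max(j1 - nx, 0)
        i0, j0 = max(i0, 0), max(j0, 0)
        i1, j1 = min(i1, ny), min(j1, nx)
        if i0 >= i1 or j0 >= j1:
            continue
        stamp = kernel[ki0:ki1, kj0:kj1]
        for wi in range(w0, w1 + 1):
            if duration_weighted:
                overlap = (min(on + dur, (wi + 1) * window_s)
                           - max(on, wi * window_s))
                maps[wi, i0:i1, j0:j1] += stamp * max(overlap, 0.0)
            else:
                maps[wi, i0:i1, j0:j1] += stamp
    missing = maps.reshape(n_windows, -1).sum(axis=1) == 0
    return HeatmapStack(fixations.recording_id, fixations.group, maps,
                        missing, grid_res_deg, screen_extent)


def eisc_pairwise(stacks: Sequence[HeatmapStack]) -> EiscMatrix:
    """Pearson r between heatmaps of every recording pair, per window.

    Windows missing (or spatially constant) in either recording are NaN.
    """
    if len(stacks) < 2:
        raise ValueError("need at least 2 recordings")
    shapes = {s.maps.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError("heatmap grids differ between recordings")
    n_windows = stacks[0].maps.shape[0]
    flat = np.stack([s.maps.reshape(n_windows, -1) for s in stacks])
    mu = flat.mean(axis=2, keepdims=True)
    sd = flat.std(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        zmaps = (flat - mu) / sd
    bad = np.broadcast_to(sd == 0, zmaps.shape)
    zmaps = np.where(bad, np.nan, zmaps)
    for k, s in enumerate(stacks):
        zmaps[k, s.missing] = np.nan

    n_rec, _, n_cells = zmaps.shape
    pair_index = [(i, j) for i in range(n_rec) for j in range(i + 1, n_rec)]
    z = np.empty((n_windows, len(pair_index)))
    filled = np.nan_to_num(zmaps)
    ok = ~np.isnan(zmaps[:, :, 0])
    for col, (i, j) in enumerate(pair_index):
        r = np.einsum("wc,wc->w", filled[i], filled[j]) / n_cells
        r = np.clip(r, -1 + FISHER_CLAMP, 1 - FISHER_CLAMP)
        zw = np.arctanh(r)
        zw[~(ok[i] & ok[j])] = np.nan
        z[:, col] = zw
    return EiscMatrix(z=z, pair_index=pair_index,
                      groups=[s.group for s in stacks],
                      recording_ids=[s.recording_id for s in stacks])


def pair_mean_eisc(matrix: EiscMatrix) -> np.ndarray:
    """Per-pair mean eyeISC: tanh of the mean Fisher-Z over valid windows."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mz = np.nanmean(matrix.z, axis=0)
    return np.tanh(mz)


@dataclass
class EiscGroupResult:
    group_means: dict[str, float]
    observed_difference: float
    p_value: float
    n_permutations: int
    seed: int


def eisc_group_test(matrix: EiscMatrix, n_permutations: int = 100000,
                    seed: int = 0, chunk: int = 2000) -> EiscGroupResult:
    """Permutation test of the same-group mean-eyeISC difference.

    Statistic: mean pairwise mean-eyeISC over both-in-group-A pairs minus
    the both-in-group-B mean (mixed pairs excluded).  The null permutes
    recording group labels and rebuilds both same-group classes; p is the
    two-sided (1+k)/(1+n) exceedance of |difference|.
    """
    groups = matrix.groups
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    ga, gb = labels
    if groups.count(ga) < 2 or groups.count(gb) < 2:
        raise ValueError("each group needs at least 2 recordings")
    vals = pair_mean_eisc(matrix)
    pi = np.array([p[0] for p in matrix.pair_index])
    pj = np.array([p[1] for p in matrix.pair_index])
    lab = np.array([g == ga for g in groups])

    def group_diff(lab_rows: np.ndarray) -> np.ndarray:
        both_a = lab_rows[:, pi] & lab_rows[:, pj]
        both_b = ~lab_rows[:, pi] & ~lab_rows[:, pj]
        va = np.where(np.isnan(vals), 0, vals)
        cnt = ~np.isnan(vals)
        mean_a = (both_a * va * cnt).sum(1) / np.maximum((both_a & cnt).sum(1), 1)
        mean_b = (both_b * va * cnt).sum(1) / np.maximum((both_b & cnt).sum(1), 1)
        return mean_a - mean_b

    obs = float(group_diff(lab[None, :])[0])
    mean_a = float(np.nanmean(vals[(lab[pi]) & (lab[pj])]))
    mean_b = float(np.nanmean(vals[(~lab[pi]) & (~lab[pj])]))

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        perms = np.stack([rng.permutation(lab) for _ in range(k)])
        diffs = group_diff(perms)
        exceed += int(np.sum(np.abs(diffs) >= abs(obs) - 1e-15))
        done += k
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return EiscGroupResult(group_means={ga: mean_a, gb: mean_b},
                           observed_difference=obs, p_value=p,
                           n_permutations=n_permutations, seed=seed)


@dataclass
class GazeQcResult:
    passed: bool
    blink_fraction: float
    short_interruption_fraction: float


def qc_gaze(t: np.ndarray, valid: np.ndarray,
            fixations: FixationSet | None = None,
            max_blink_fraction: float = 0.10,
            max_interruption_s: float = 1.0) -> GazeQcResult:
    """Recording quality filter.

    Rejects recordings whose blink (invalid-sample) fraction exceeds 10% of
    the duration, or in which the majority of blink/saccade interruptions
    last 1 s or more.
    """
    t = np.asarray(t, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    blink_frac = float(1.0 - valid.mean()) if valid.size else 1.0

    # interruption = any maximal stretch not covered by a fixation
    interruptions = []
    if fixations is not None and len(fixations):
        cursor = t[0]
        for on, dur in zip(fixations.onsets, fixations.durations):
            if on > cursor:
                interruptions.append(on - cursor)
            cursor = max(cursor, on + dur)
        if t[-1] > cursor:
            interruptions.append(t[-1] - cursor)
    if interruptions:
        short_frac = float(np.mean(np.array(interruptions) < max_interruption_s))
    else:
        short_frac = 1.0
    passed = blink_frac <= max_blink_fraction and short_frac > 0.5
    return GazeQcResult(passed=passed, blink_fraction=blink_frac,
                        short_interruption_fraction=short_frac)
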