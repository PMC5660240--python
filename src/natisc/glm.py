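"""GLM localizer for the moral-dilemma decision task.

A deliberately minimal two-level pipeline: a decision-vs-baseline boxcar
regressor (identity revelation to button press) convolved with the
canonical double-gamma HRF, discrete-cosine drift columns below the 128 s
high-pass cutoff, per-voxel OLS at the first level, and a one-sample
second-level test with sign-flip permutations whose family-wise correction
uses the maximum TFCE (threshold-free cluster enhancement) statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import gammaln

from .isc import BoldRun, dct_drift_basis
from .inference import StatMap, _connectivity_structure


@dataclass
class EventTable:
    """Decision events: onset (identity revelation) to offset (button press),
    in seconds from run start."""

    onsets: np.ndarray
    offsets: np.ndarray
    n_trs: int
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.onsets.shape != self.offsets.shape:
            raise ValueError("onsets and offsets differ in length")
        dur = self.n_trs * self.tr_seconds
        if self.onsets.size:
            order = np.argsort(self.onsets)
            on, off = self.onsets[order], self.offsets[order]
            if np.any(on < 0) or np.any(off > dur):
                raise ValueError("events outside the run")
            if np.any(off <= on):
                raise ValueError("event offsets must exceed onsets")
            if np.any(on[1:] < off[:-1]):
                raise ValueError("overlapping events")


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list[str]
    highpass_s: float

    @property
    def decision_column(self) -> int:
        return self.names.index("decision")


@dataclass
class TfceParams:
    """TFCE exponents and integration step (conventional E=0.5, H=2)."""

    extent_exponent: float = 0.5
    height_exponent: float = 2.0
    dh: float | None = None      # None -> max(|stat|)/100
    connectivity: int = 26

    def validate(self) -> None:
        if self.extent_exponent <= 0 or self.height_exponent <= 0:
            raise ValueError("TFCE exponents must be > 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")


def double_gamma_hrf(dt: float, duration_s: float = 32.0,
                     peak_delay_s: float = 6.0, undershoot_delay_s: float = 16.0,
                     undershoot_ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, peak-normalized.

    Difference of two unit-scale gamma densities (shape = delay), the
    convention of the mainstream fMRI analysis suites.
    """
    t = np.arange(0, duration_s, dt)

    def gamma_pdf(x, shape):
        with np.errstate(divide="ignore"):
            logp = (shape - 1) * np.log(np.maximum(x, 1e-12)) - x - gammaln(shape)
        out = np.exp(logp)
        out[x <= 0] = 0.0
        return out

    h = gamma_pdf(t, peak_delay_s) - gamma_pdf(t, undershoot_delay_s) / undershoot_ratio
    return h / h.max()


def build_design(events: EventTable, highpass_s: float = 128.0,
                 oversample: int = 16) -> DesignMatrix:
    """Boxcar convolved with the canonical HRF, plus drift basis + intercept.

    The boxcar is built on an oversampled grid (TR/``oversample``), convolved,
    then sampled at the TR onsets; drift columns are the discrete cosines with
    periods longer than ``highpass_s``.
    """
    dt = events.tr_seconds / oversample
    n_fine = events.n_trs * oversample
    boxcar = np.zeros(n_fine)
    for on, off in zip(events.onsets, events.offsets):
        boxcar[int(round(on / dt)):int(round(off / dt))] = 1.0
    hrf = double_gamma_hrf(dt)
    reg = np.convolve(boxcar, hrf)[:n_fine][::oversample] * dt
    drift = dct_drift_basis(events.n_trs, events.tr_seconds, 1.0 / highpass_s)
    cols = [reg, *drift.T, np.ones(events.n_trs)]
    names = ["decision"] + [f"drift_{k}" for k in range(1, drift.shape[1] + 1)]
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=names,
                        highpass_s=highpass_s)


def fit_first_level(run: BoldRun, design: DesignMatrix) -> np.ndarray:
    """Per-voxel OLS; returns the decision-regressor coefficient map."""
    X = design.matrix
    if X.shape[0] != run.n_trs:
        raise ValueError(f"design has {X.shape[0]} rows, run has {run.n_trs} TRs")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design; most collinear columns: "
            f"{design.names[i]!r} and {design.names[j]!r}")
    beta = np.linalg.lstsq(X, run.data.T, rcond=None)[0]
    return beta[design.decision_column]


def tfce_score(stat_volume: np.ndarray,
               params: TfceParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3-D statistic volume.

    For each voxel, sum over heights h (step dh) of extent(h)^E * h^H * dh,
    where extent(h) is the size of the voxel's supporting cluster at
    threshold h.  Negative values are enhanced on the negated volume and
    returned with negative sign.
    """
    params = params or TfceParams()
    params.validate()
    vol = np.asarray(stat_volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("tfce_score expects a 3-D volume")
    vmax = np.max(np.abs(vol)) if vol.size else 0.0
    if vmax == 0:
        return np.zeros_like(vol)
    dh = params.dh if params.dh is not None else vmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be > 0")
    structure = _connectivity_structure(params.connectivity)

    def one_sided(v: np.ndarray) -> np.ndarray:
        out = np.zeros_like(v)
        top = v.max()
        if top <= 0:
            return out
        # midpoint rule: O(dh^2) quadrature bias instead of O(dh)
        heights = np.arange(dh / 2, top, dh)
        for h in heights:
            sup = v >= h
            if not sup.any():
                break
            labels, n = ndimage.label(sup, structure=structure)
            extents = np.bincount(labels.ravel())
            extents[0] = 0
            out += (extents[labels] ** params.extent_exponent) * h ** params.height_exponent * dh
        return out

    return one_sided(vol) - one_sided(-vol)


def second_level_test(contrast_maps: np.ndarray, n_permutations: int = 5000,
                      seed: int = 0, params: TfceParams | None = None,
                      alpha: float = 0.05, tail: str = "greater") -> StatMap:
    """One-sample second-level test with sign-flip + max-TFCE FWE correction.

    ``contrast_maps`` is (n_subjects, nx, ny, nz).  The observed one-sample
    t volume is TFCE-enhanced; each permutation flips map signs, rebuilds t
    and TFCE, and contributes its volume-wise maximum; corrected p per voxel
    compares the observed enhancement to that max distribution.
    """
    maps = np.asarray(contrast_maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("contrast_maps must be (n_maps, nx, ny, nz)")
    n = maps.shape[0]
    if n < 5:
        raise ValueError("need at least 5 maps for a permutation second level")
    params = params or TfceParams()

    def t_volume(data: np.ndarray) -> np.ndarray:
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n))
        return np.nan_to_num(t)

    t_obs = t_volume(maps)
    if tail == "greater":
        enh_obs = np.maximum(tfce_score(t_obs, params), 0.0)
    elif tail == "two-sided":
        enh_obs = np.abs(tfce_score(t_obs, params))
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")

    rng = np.random.default_rng(seed)
    max_null = np.empty(n_permutations)
    for k in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_perm = t_volume(maps * signs[:, None, None, None])
        enh = tfce_score(t_perm, params)
        max_null[k] = np.max(enh) if tail == "greater" else np.max(np.abs(enh))
    exceed = (max_null[None, None, None, :] >= enh_obs[..., None]).sum(axis=-1)
    p = (1.0 + exceed) / (1.0 + n_permutations)
    mask = p < alpha
    thr = float(np.min(np.abs(t_obs[mask]))) if mask.any() else float("nan")
    return StatMap(stat=t_obs.ravel(), p=p.ravel(), q=alpha,
                   p_cutoff=alpha, stat_threshold=thr, mask=mask.ravel(),
                   tail=tail, n_permutations=n_permutations, seed=seed,
                   grid_shape=maps.shape[1:])
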