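"""Synthetic cohorts with known ground truth.

Emulates the two-belief ("genetic" vs "nongenetic" sisters) movie-viewing
design: every subject watches the same stimulus twice per condition, so
same-condition cross-subject pairs share a condition-specific stimulus
component while everything else is subject noise.  The shared-to-noise
coupling w sets the true pairwise ISC analytically:

    c = w^2 * var(s) / (w^2 * var(s) + noise_sd^2)

with the shared course s standardized to unit variance.  The generator also
produces gaze streams with group-specific spatial attractors, rigid-body
motion traces, heart/breathing rate traces and 5 Hz continuous ratings, so
the whole pipeline is testable without any acquired data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .isc import CONDITIONS, BoldRun


@dataclass
class EffectRegion:
    """A voxel box carrying shared stimulus signal.

    ``box`` is ((x0, x1), (y0, y1), (z0, z1)), half-open 0-based index
    ranges; ``weight`` is the coupling w in [0, 1).  ``condition`` may be a
    belief condition (its own stimulus course, synchronizing only
    same-condition viewings) or ``"both"`` for a belief-independent
    component: one course shared by all four viewings, which is the correct
    null model when the belief manipulation is assumed not to matter (every
    viewing shows the same stimulus).
    """

    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    condition: str
    weight: float


@dataclass
class CohortSpec:
    """Design of a synthetic BOLD cohort (defaults follow the study layout:
    2 viewings per condition, 712 TRs of 2 s)."""

    n_subjects: int
    sessions_per_condition: int = 2
    n_trs: int = 712
    tr_seconds: float = 2.0
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    effect_regions: list[EffectRegion] = field(default_factory=list)
    noise_sd: float = 1.0
    stimulus_cutoff_hz: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sessions_per_condition < 1:
            raise ValueError("sessions_per_condition must be >= 1")
        if self.n_trs < 2:
            raise ValueError("n_trs must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(s < 1 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive dimensions")
        for reg in self.effect_regions:
            if reg.condition not in CONDITIONS + ("both",):
                raise ValueError(f"effect_regions: unknown condition {reg.condition!r}")
            if not 0 <= reg.weight < 1:
                raise ValueError("effect_regions: weight must satisfy 0 <= w < 1")
            for (lo, hi), dim in zip(reg.box, self.grid_shape):
                if not (0 <= lo < hi <= dim):
                    raise ValueError(f"effect_regions: box {reg.box} outside grid "
                                     f"{self.grid_shape}")

    @property
    def run_duration_s(self) -> float:
        return self.n_trs * self.tr_seconds

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class GroundTruth:
    """Per-voxel true ISC by condition and the planted-difference mask."""

    isc: dict[str, np.ndarray]  # condition -> flat (n_voxels,) true ISC
    weights: dict[str, np.ndarray]
    difference_mask: np.ndarray  # flat boolean, True where w differs
    grid_shape: tuple[int, int, int]


def weight_for_isc(c: float, noise_sd: float = 1.0) -> float:
    """Coupling w that yields true pairwise ISC ``c`` at unit stimulus variance."""
    if not 0 <= c < 1:
        raise ValueError("target ISC must be in [0, 1)")
    return noise_sd * math.sqrt(c / (1.0 - c))


def lowpass_noise(rng: np.random.Generator, n_samples: int, dt: float,
                  cutoff_hz: float, size: int = 1) -> np.ndarray:
    """Unit-variance Gaussian noise with spectral content below ``cutoff_hz``.

    Mimics the slow autocorrelated course of naturalistic BOLD; returns
    (size, n_samples), each row standardized to mean 0, variance 1.
    """
    white = rng.standard_normal((size, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=dt)
    spec[:, freqs > cutoff_hz] = 0.0
    spec[:, 0] = 0.0  # remove DC
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _region_flat_indices(reg: EffectRegion, grid_shape) -> np.ndarray:
    idx = np.zeros(grid_shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = reg.box
    idx[x0:x1, y0:y1, z0:z1] = True
    return np.flatnonzero(idx.ravel())


def simulate_bold_cohort(spec: CohortSpec) -> tuple[list[BoldRun], GroundTruth]:
    """Generate ``n_subjects * 2 * sessions_per_condition`` BOLD runs.

    Each condition draws one shared smooth stimulus course per voxel; a
    voxel inside an effect region with coupling w carries
    ``w * s_k(t) + noise`` in condition k.  The two same-condition viewings
    of one subject share s but have independent noise, which is exactly what
    makes same-condition cross-subject pairs correlated.  Equal seeds give
    bit-identical cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_vox = spec.n_voxels
    mask = np.ones(spec.grid_shape, dtype=bool)

    weights = {c: np.zeros(n_vox) for c in CONDITIONS + ("both",)}
    for reg in spec.effect_regions:
        flat = _region_flat_indices(reg, spec.grid_shape)
        weights[reg.condition][flat] = reg.weight

    # one shared stimulus draw per condition plus one belief-independent
    # course common to all viewings, only where each is needed
    stimulus = {}
    for cond in CONDITIONS + ("both",):
        active = np.flatnonzero(weights[cond])
        s = np.zeros((n_vox, spec.n_trs))
        if active.size:
            s[active] = lowpass_noise(rng, spec.n_trs, spec.tr_seconds,
                                      spec.stimulus_cutoff_hz, size=active.size)
        stimulus[cond] = s

    truth_isc = {}
    for cond in CONDITIONS:
        w2 = weights[cond] ** 2 + weights["both"] ** 2
        truth_isc[cond] = w2 / (w2 + spec.noise_sd ** 2)
    diff = weights[CONDITIONS[0]] != weights[CONDITIONS[1]]

    common = weights["both"][:, None] * stimulus["both"]
    runs: list[BoldRun] = []
    perspectives = ("donor", "recipient")
    for subj in range(spec.n_subjects):
        for cond in CONDITIONS:
            shared = weights[cond][:, None] * stimulus[cond] + common
            for sess in range(spec.sessions_per_condition):
                noise = spec.noise_sd * rng.standard_normal((n_vox, spec.n_trs))
                runs.append(BoldRun(
                    subject_id=subj, condition=cond, session_index=sess,
                    data=shared + noise, mask=mask, tr_seconds=spec.tr_seconds,
                    perspective=perspectives[sess % 2]))
    truth = GroundTruth(isc=truth_isc, weights=weights, difference_mask=diff,
                        grid_shape=spec.grid_shape)
    return runs, truth


# ---------------------------------------------------------------------------
# gaze


@dataclass
class Attractor:
    """One spatial gaze attractor active over a time window (seconds)."""

    t_start: float
    t_end: float
    x_deg: float
    y_deg: float
    spread_deg: float = 1.0


@dataclass
class GazeSpec:
    """Synthetic eye-gaze design in degrees of visual angle.

    ``attractors`` maps group label -> time-ordered attractor list covering
    the recording; fixations land near the active attractor with the given
    spread and dwell ~ Gamma(2, mean ``dwell_mean_s``).  ``drift_deg`` maps
    recording index -> constant (dx, dy) offset added to every sample.
    """

    duration_s: float
    attractors: dict[str, list[Attractor]]
    sampling_rate: float = 250.0
    screen_extent: tuple[float, float] = (24.0, 18.0)
    dwell_mean_s: float = 0.35
    saccade_duration_s: float = 0.03
    jitter_deg: float = 0.01
    drift_deg: dict[int, tuple[float, float]] = field(default_factory=dict)
    #: group -> (alternative attractor sequence, per-dwell probability of
    #: following it).  Members of the group choose independently, so the
    #: mixture lowers within-group gaze agreement — a shared deterministic
    #: shift would not, because every member would shift together.
    mixture: dict[str, tuple[list[Attractor], float]] = field(
        default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.dwell_mean_s <= 0:
            raise ValueError("dwell_mean_s must be > 0")
        w, h = self.screen_extent
        for group, seq in self.attractors.items():
            for att in seq:
                if not (0 <= att.x_deg <= w and 0 <= att.y_deg <= h):
                    raise ValueError(
                        f"attractor for group {group!r} outside screen extent")
                if att.t_end <= att.t_start:
                    raise ValueError("attractor window must have positive length")


@dataclass
class GazeRecording:
    recording_id: int
    group: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    drift_deg: tuple[float, float] = (0.0, 0.0)


def make_attractor_sequence(duration_s: float, screen_extent=(24.0, 18.0),
                            mean_window_s: float = 4.0, spread_deg: float = 1.0,
                            seed: int = 0) -> list[Attractor]:
    """Random attractor itinerary: piecewise-constant points of interest."""
    rng = np.random.default_rng(seed)
    w, h = screen_extent
    seq, t = [], 0.0
    while t < duration_s:
        span = rng.uniform(0.5 * mean_window_s, 1.5 * mean_window_s)
        seq.append(Attractor(t, min(t + span, duration_s),
                             rng.uniform(0.15 * w, 0.85 * w),
                             rng.uniform(0.15 * h, 0.85 * h), spread_deg))
        t += span
    return seq


def displaced_sequence(seq: list[Attractor], dx_deg: float,
                       fraction: float = 0.5, seed: int = 1) -> list[Attractor]:
    """Copy of an attractor sequence with a subset shifted by ``dx_deg`` in x."""
    rng = np.random.default_rng(seed)
    out = []
    for att in seq:
        shift = dx_deg if rng.random() < fraction else 0.0
        out.append(Attractor(att.t_start, att.t_end, att.x_deg + shift,
                             att.y_deg, att.spread_deg))
    return out


def _active_attractor(seq: list[Attractor], t: float) -> Attractor:
    for att in seq:
        if att.t_start <= t < att.t_end:
            return att
    return seq[-1]


def simulate_gaze(spec: GazeSpec,
                  n_recordings_per_group: dict[str, int]) -> list[GazeRecording]:
    """Generate fixation/saccade gaze streams with group-specific attractors.

    Supports unbalanced groups.  Each recording alternates dwells at the
    active attractor with short linear saccades; per-recording constant
    drift is added last so drift correction can be verified exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration_s * spec.sampling_rate))
    t_grid = np.arange(n_samples) / spec.sampling_rate
    w, h = spec.screen_extent
    recs: list[GazeRecording] = []
    rec_id = 0
    for group, n_rec in n_recordings_per_group.items():
        seq = spec.attractors[group]
        alt_seq, alt_prob = spec.mixture.get(group, (None, 0.0))

        def pick(t: float) -> Attractor:
            if alt_seq is not None and rng.random() < alt_prob:
                return _active_attractor(alt_seq, t)
            return _active_attractor(seq, t)

        for _ in range(n_rec):
            x = np.empty(n_samples)
            y = np.empty(n_samples)
            t = 0.0
            att = pick(0.0)
            cx = np.clip(att.x_deg + rng.normal(0, att.spread_deg), 0, w)
            cy = np.clip(att.y_deg + rng.normal(0, att.spread_deg), 0, h)
            while t < spec.duration_s:
                dwell = rng.gamma(2.0, spec.dwell_mean_s / 2.0)
                i0 = int(t * spec.sampling_rate)
                i1 = min(int((t + dwell) * spec.sampling_rate) + 1, n_samples)
                x[i0:i1] = cx
                y[i0:i1] = cy
                t += dwell
                if t >= spec.duration_s:
                    break
                att = pick(t)
                nx = np.clip(att.x_deg + rng.normal(0, att.spread_deg), 0, w)
                ny = np.clip(att.y_deg + rng.normal(0, att.spread_deg), 0, h)
                j0 = min(int(t * spec.sampling_rate), n_samples - 1)
                j1 = min(int((t + spec.saccade_duration_s) * spec.sampling_rate) + 1,
                         n_samples)
                frac = np.linspace(0, 1, max(j1 - j0, 1))
                x[j0:j1] = cx + frac * (nx - cx)
                y[j0:j1] = cy + frac * (ny - cy)
                t += spec.saccade_duration_s
                cx, cy = nx, ny
            x += rng.normal(0, spec.jitter_deg, n_samples)
            y += rng.normal(0, spec.jitter_deg, n_samples)
            dx, dy = spec.drift_deg.get(rec_id, (0.0, 0.0))
            recs.append(GazeRecording(
                recording_id=rec_id, group=group, t=t_grid,
                x=x + dx, y=y + dy, valid=np.ones(n_samples, dtype=bool),
                drift_deg=(dx, dy)))
            rec_id += 1
    return recs


# ---------------------------------------------------------------------------
# ancillary streams (motion, physiology, continuous ratings)


@dataclass
class AncillaryData:
    """Per-run motion tables plus physiological and rating traces.

    ``motion[i]`` is the (n_trs, 6) rigid-body table of ``runs[i]`` in the
    cohort's run order (3 translations mm, 3 rotations rad); heart and
    breathing are per-TR rates (bpm / breaths-per-min); valence in [-1, 1]
    and arousal in [0, 1] sampled at 5 Hz.
    """

    motion: list[np.ndarray]
    heart_rate: np.ndarray      # (n_runs, n_trs)
    breathing_rate: np.ndarray  # (n_runs, n_trs)
    valence: np.ndarray         # (n_runs, n_rating_samples), 5 Hz
    arousal: np.ndarray
    rating_hz: float = 5.0


def simulate_ancillary(spec: CohortSpec, motion_step_mm: float = 0.01,
                       motion_step_rad: float = 2e-4,
                       motion_spikes: dict[int, tuple[int, float]] | None = None,
                       zero_motion: bool = False) -> AncillaryData:
    """Motion random walks, smooth rate traces, and 5 Hz rating traces.

    ``motion_spikes`` maps run index -> (TR index, mm) for an instantaneous
    x-translation step; ``zero_motion`` produces identically-zero tables
    (downstream framewise displacement is then exactly 0).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)  # independent of the BOLD stream
    n_runs = spec.n_subjects * 2 * spec.sessions_per_condition
    n_rating = int(round(spec.n_trs * spec.tr_seconds * 5.0))

    motion = []
    for i in range(n_runs):
        if zero_motion:
            m = np.zeros((spec.n_trs, 6))
        else:
            steps = np.hstack([
                rng.normal(0, motion_step_mm, (spec.n_trs, 3)),
                rng.normal(0, motion_step_rad, (spec.n_trs, 3))])
            steps[0] = 0.0
            m = np.cumsum(steps, axis=0)
        if motion_spikes and i in motion_spikes:
            tr, mm = motion_spikes[i]
            m[tr:, 0] += mm
        motion.append(m)

    heart = 62.0 + 4.0 * lowpass_noise(rng, spec.n_trs, spec.tr_seconds, 0.02,
                                       size=n_runs)
    breath = 15.0 + 2.0 * lowpass_noise(rng, spec.n_trs, spec.tr_seconds, 0.02,
                                        size=n_runs)
    heart = np.clip(heart, 40.0, None)
    breath = np.clip(breath, 6.0, None)
    valence = np.tanh(lowpass_noise(rng, n_rating, 0.2, 0.05, size=n_runs))
    arousal = 0.5 + 0.5 * np.tanh(lowpass_noise(rng, n_rating, 0.2, 0.05,
                                                size=n_runs))
    return AncillaryData(motion=motion, heart_rate=heart, breathing_rate=breath,
                         valence=valence, arousal=arousal)
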