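"""Pairwise inter-subject correlation (ISC) of BOLD time series.

The central object of a naturalistic-viewing analysis: for every pair of
subjects who watched the same stimulus under the same belief condition,
correlate their voxel time courses, variance-stabilize with the Fisher Z
transform, and summarize on the Z scale.  This module covers run cleaning
(confound + high-pass projection), pair enumeration, the voxel x pair
correlation tensor, full run x run similarity matrices, and mean-ISC maps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CONDITIONS = ("genetic", "nongenetic")
PERSPECTIVES = ("donor", "recipient", "none")

#: correlations are clamped to |r| <= 1 - FISHER_CLAMP before atanh
FISHER_CLAMP = 1e-7


@dataclass
class BoldRun:
    """One subject x session BOLD run, mask-flattened.

    ``data`` is voxels x TRs (only in-mask voxels, 0-based flat order of the
    3-D boolean ``mask``); volume geometry travels with ``affine``.
    """

    subject_id: int
    condition: str
    session_index: int
    data: np.ndarray
    mask: np.ndarray
    tr_seconds: float = 2.0
    perspective: str = "none"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldRun.data must be 2-D (voxels x TRs)")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun.data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]


@dataclass
class PairSet:
    """Cross-subject session pairs pooled within one condition.

    Each pair is ``((subject_i, session_a), (subject_j, session_b))`` with
    ``i < j``; all sessions-squared combinations of the two subjects'
    same-condition viewings are pooled, giving
    ``sessions**2 * N*(N-1)/2`` pairs.  Pair order is deterministic, so the
    k-th pair of one condition's PairSet is matched to the k-th pair of the
    other's (same subjects, same session slots).
    """

    pairs: list[tuple[tuple[int, int], tuple[int, int]]]
    condition: str
    n_subjects: int
    sessions_per_condition: int

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PairCorrelationTensor:
    """Voxel x pair Fisher-Z correlations for one PairSet.

    Zero-variance voxel-pairs are stored as NaN (missing), never zero.
    """

    z: np.ndarray
    pairs: PairSet
    analysis_id: str = ""

    @property
    def n_voxels(self) -> int:
        return self.z.shape[0]


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    run_labels: list[tuple[int, str, int]]  # (subject, condition, session)


def fisher_z(r, clamp: float = FISHER_CLAMP):
    """Fisher Z transform z = atanh(r), with |r| clamped to 1 - ``clamp``.

    Raises ``ValueError`` when |r| exceeds 1 by more than numerical noise.
    """
    r = np.asarray(r, dtype=float)
    finite = np.isfinite(r)
    if np.any(np.abs(np.atleast_1d(r)[np.atleast_1d(finite)]) > 1 + 1e-9):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(r, -1 + clamp, 1 - clamp))
    return out if out.ndim else float(out)


def fisher_z_inv(z):
    """Inverse Fisher transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


def dct_drift_basis(n_trs: int, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine low-frequency basis for drift below ``cutoff_hz``.

    Column k (k >= 1) is cos(pi*k*(2t+1)/(2T)) with frequency k/(2*T*TR).
    All components below the cutoff are returned plus one guard component at
    or just above it, so the stop band [0, cutoff] is fully spanned even for
    drift whose phase the cosine terms alone represent poorly (no intercept).
    """
    if cutoff_hz < 0:
        raise ValueError("cutoff_hz must be >= 0")
    if cutoff_hz == 0:
        return np.empty((n_trs, 0))
    t = np.arange(n_trs)
    k_max = int(np.floor(2.0 * n_trs * tr_seconds * cutoff_hz)) + 1
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_trs)) for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_trs, 0))
    return np.column_stack(cols)


def clean_bold(run: BoldRun, confounds: np.ndarray | None = None,
               highpass_hz: float = 0.01) -> BoldRun:
    """Residualize a run on confounds and a low-frequency drift basis.

    A single joint least-squares projection on [intercept | confounds |
    discrete-cosine basis below ``highpass_hz``]; the residuals are exactly
    orthogonal to every regressor.  Rank-deficient designs fall back to the
    pseudoinverse with a warning.
    """
    X_parts = [np.ones((run.n_trs, 1))]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != run.n_trs:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, run has {run.n_trs} TRs")
        X_parts.append(confounds)
    if highpass_hz > 0:
        X_parts.append(dct_drift_basis(run.n_trs, run.tr_seconds, highpass_hz))
    X = np.column_stack(X_parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient confound matrix; using pseudoinverse",
                      RuntimeWarning, stacklevel=2)
    beta = np.linalg.lstsq(X, run.data.T, rcond=None)[0]
    resid = run.data - (X @ beta).T
    return replace(run, data=resid)


def build_friston24(motion: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body parameters to the 24-regressor motion model.

    Columns 1-6 the parameters, 7-12 their backward differences (first row
    zero), 13-24 the elementwise squares of columns 1-12.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 columns")
    if motion.shape[0] < 2:
        raise ValueError("motion table needs at least 2 rows")
    diffs = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    first12 = np.hstack([motion, diffs])
    return np.hstack([first12, first12 ** 2])


def enumerate_pairs(n_subjects: int, sessions_per_condition: int,
                    condition: str) -> PairSet:
    """Enumerate all cross-subject same-condition session pairs.

    Pooling both viewings of each subject against both viewings of every
    other subject gives ``sessions**2 * N*(N-1)/2`` pairs (1740 for N=30,
    two viewings per condition).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if sessions_per_condition < 1:
        raise ValueError("need at least 1 session per condition")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    pairs = [((i, a), (j, b))
             for i, j in itertools.combinations(range(n_subjects), 2)
             for a in range(sessions_per_condition)
             for b in range(sessions_per_condition)]
    return PairSet(pairs=pairs, condition=condition, n_subjects=n_subjects,
                   sessions_per_condition=sessions_per_condition)


def index_runs(runs: Sequence[BoldRun]) -> dict[tuple[int, str, int], BoldRun]:
    """Map (subject, condition, session) -> run; duplicates are an error."""
    out: dict[tuple[int, str, int], BoldRun] = {}
    for run in runs:
        key = (run.subject_id, run.condition, run.session_index)
        if key in out:
            raise ValueError(f"duplicate run {key}")
        out[key] = run
    return out


def standardized_data(run: BoldRun) -> np.ndarray:
    """Per-voxel z-scored time series; zero-variance voxels become NaN rows."""
    x = run.data
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    # constant voxels leave rounding residue ~eps*|mu|; treat those as flat
    flat = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[np.broadcast_to(flat, z.shape)] = np.nan
    return z


def _pair_correlations(std_a: np.ndarray, std_b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of two standardized voxel x time matrices."""
    n_t = std_a.shape[1]
    r = np.einsum("vt,vt->v", std_a, std_b) / n_t
    return np.clip(r, -1.0, 1.0, out=r)


def pairwise_isc(runs: Sequence[BoldRun], pairs: PairSet,
                 analysis_id: str = "") -> PairCorrelationTensor:
    """Per-voxel Pearson r for every pair in ``pairs``, Fisher-Z transformed.

    Pairs referencing a zero-variance voxel in either run get NaN at that
    voxel; downstream means skip missing entries.
    """
    lookup = index_runs(runs)
    cond = pairs.condition
    n_trs = {run.n_trs for run in lookup.values()}
    if len(n_trs) != 1:
        raise ValueError("all runs must have the same number of TRs")
    std_cache: dict[tuple[int, int], np.ndarray] = {}

    def std(subj: int, sess: int) -> np.ndarray:
        key = (subj, sess)
        if key not in std_cache:
            run = lookup.get((subj, cond, sess))
            if run is None:
                raise KeyError(f"missing run (subject {subj}, {cond}, session {sess})")
            std_cache[key] = standardized_data(run)
        return std_cache[key]

    n_vox = next(iter(lookup.values())).n_voxels
    z = np.empty((n_vox, len(pairs)))
    for col, ((i, a), (j, b)) in enumerate(pairs.pairs):
        r = _pair_correlations(std(i, a), std(j, b))
        z[:, col] = np.arctanh(np.clip(r, -1 + FISHER_CLAMP, 1 - FISHER_CLAMP))
    return PairCorrelationTensor(z=z, pairs=pairs, analysis_id=analysis_id)


def mean_isc(tensor: PairCorrelationTensor) -> np.ndarray:
    """Mean ISC map: tanh of the per-voxel mean Fisher-Z over valid pairs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
        mz = np.nanmean(tensor.z, axis=1)
    return np.tanh(mz)


def assemble_similarity_matrix(runs: Sequence[BoldRun],
                               voxel: int | None = None) -> SimilarityMatrix:
    """Run x run similarity matrix (mean-over-voxel Pearson r, or one voxel).

    Includes within-subject cross-session cells; diagonal is exactly 1.
    For 30 subjects x 4 sessions this is the 120 x 120 matrix of the full
    two-belief x two-perspective design.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    labels = [(r.subject_id, r.condition, r.session_index) for r in runs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate run labels")
    n = len(runs)
    values = np.eye(n)
    std = [standardized_data(r) for r in runs]
    if voxel is not None:
        std = [s[voxel:voxel + 1] for s in std]
    for i in range(n):
        for j in range(i + 1, n):
            r = _pair_correlations(std[i], std[j])
            values[i, j] = values[j, i] = np.nanmean(r)
    return SimilarityMatrix(values=values, run_labels=labels)
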