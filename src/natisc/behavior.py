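"""Ancillary statistics: motion QC, similarity permutation tests, TOST
equivalence, Mantel test, and time-point-wise rating comparisons.

These are the controls that bracket the main ISC result: framewise
displacement verifies that head motion is acceptable and not condition
dependent, physiological-rate similarity rules out autonomic explanations,
TOST demonstrates equivalence (not mere absence of difference) of closeness
ratings, and the Mantel test asks whether rating similarity follows the
condition structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import bh_fdr
from .isc import FISHER_CLAMP


@dataclass
class FDTrace:
    """Framewise displacement (mm) per TR plus the standard QC summaries."""

    fd: np.ndarray
    mean_fd: float
    fraction_below: float      # fraction of TRs with FD < threshold
    threshold_mm: float
    passes_qc: bool            # >= 90% of TRs below threshold


def framewise_displacement(motion: np.ndarray, rotation_radius_mm: float = 50.0,
                           threshold_mm: float = 0.5,
                           qc_fraction: float = 0.9) -> FDTrace:
    """FD_t = sum |d translations| + radius * sum |d rotations|; first value 0.

    Expects (T, 6): three translations in mm then three rotations in rad;
    rotations are converted to mm on a ``rotation_radius_mm`` sphere.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be (T, 6)")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.concatenate([[0.0], d[:, :3].sum(axis=1)
                         + rotation_radius_mm * d[:, 3:].sum(axis=1)])
    frac = float(np.mean(fd < threshold_mm))
    return FDTrace(fd=fd, mean_fd=float(fd.mean()), fraction_below=frac,
                   threshold_mm=threshold_mm, passes_qc=frac >= qc_fraction)


@dataclass
class SimilarityTestResult:
    t: float
    p_two_sided: float
    p_greater: float
    n_permutations: int
    seed: int


def similarity_perm_test(data: np.ndarray, labels: np.ndarray,
                         mode: str = "scalar-distance",
                         n_permutations: int = 5000,
                         seed: int = 0) -> SimilarityTestResult:
    """Do same-condition pairs look more alike in one condition than the other?

    Builds a recording-pair similarity — negative absolute difference of
    scalars (``scalar-distance``, e.g. mean FD) or Fisher-Z trace correlation
    (``trace-correlation``, e.g. heart-rate traces) — and contrasts
    same-condition-A against same-condition-B pair similarities with a
    two-sample t.  The null permutes recording labels.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("need exactly two condition labels")
    counts = [(labels == u).sum() for u in uniq]
    if min(counts) < 2:
        raise ValueError("need at least 2 recordings per condition")

    n = len(labels)
    if mode == "scalar-distance":
        if data.ndim != 1:
            raise ValueError("scalar-distance mode expects 1-D data")
        sim = -np.abs(data[:, None] - data[None, :])
    elif mode == "trace-correlation":
        if data.ndim != 2:
            raise ValueError("trace-correlation mode expects (R, T) data")
        r = np.corrcoef(data)
        sim = np.arctanh(np.clip(r, -1 + FISHER_CLAMP, 1 - FISHER_CLAMP))
    else:
        raise ValueError("mode must be 'scalar-distance' or 'trace-correlation'")

    iu, ju = np.triu_indices(n, 1)
    vals = sim[iu, ju]
    is_a = labels == uniq[0]

    def t_stat(mask_a: np.ndarray) -> float:
        aa = vals[mask_a[iu] & mask_a[ju]]
        bb = vals[~mask_a[iu] & ~mask_a[ju]]
        va = aa.var(ddof=1) if aa.size > 1 else 0.0
        vb = bb.var(ddof=1) if bb.size > 1 else 0.0
        se = np.sqrt(va / aa.size + vb / bb.size)
        if se == 0:
            return 0.0
        return float((aa.mean() - bb.mean()) / se)

    t_obs = t_stat(is_a)
    rng = np.random.default_rng(seed)
    ge = abs_ge = 0
    for _ in range(n_permutations):
        t_p = t_stat(rng.permutation(is_a))
        ge += t_p >= t_obs - 1e-15
        abs_ge += abs(t_p) >= abs(t_obs) - 1e-15
    return SimilarityTestResult(
        t=t_obs,
        p_two_sided=(1.0 + abs_ge) / (1.0 + n_permutations),
        p_greater=(1.0 + ge) / (1.0 + n_permutations),
        n_permutations=n_permutations, seed=seed)


@dataclass
class TostResult:
    """Two one-sided tests of equivalence on the standardized d scale."""

    d: float
    delta: float
    n: int
    df: int
    t_upper: float      # tests d >= +delta, lower-tail p
    p_upper: float
    t_lower: float      # tests d <= -delta, upper-tail p
    p_lower: float
    alpha: float
    equivalent: bool


def tost_equivalence(d: float | None = None, delta_bound: float = 0.68,
                     n: int = 30, alpha: float = 0.05,
                     mean_diff: float | None = None,
                     sd: float | None = None) -> TostResult:
    """One-sample/paired TOST: t = (d -+ delta) * sqrt(n), df = n - 1.

    Accepts either the standardized effect ``d`` directly or raw
    ``mean_diff`` and ``sd`` (then d = mean_diff / sd and the raw bounds are
    delta * sd).  Equivalence is declared when both one-sided p < alpha.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if delta_bound <= 0:
        raise ValueError("delta_bound must be > 0")
    if d is None:
        if mean_diff is None or sd is None or sd <= 0:
            raise ValueError("provide d, or mean_diff with positive sd")
        d = mean_diff / sd
    df = n - 1
    sqrt_n = np.sqrt(n)
    t_upper = (d - delta_bound) * sqrt_n
    t_lower = (d + delta_bound) * sqrt_n
    p_upper = float(stats.t.cdf(t_upper, df))
    p_lower = float(stats.t.sf(t_lower, df))
    return TostResult(d=float(d), delta=delta_bound, n=n, df=df,
                      t_upper=float(t_upper), p_upper=p_upper,
                      t_lower=float(t_lower), p_lower=p_lower, alpha=alpha,
                      equivalent=(p_upper < alpha and p_lower < alpha))


def one_sided_t_p(t: float, df: int, tail: str = "greater") -> float:
    """One-sided p for a t statistic (convenience for reported statistics)."""
    if tail == "greater":
        return float(stats.t.sf(t, df))
    if tail == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError("tail must be 'greater' or 'less'")


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int


def mantel_test(matrix_a: np.ndarray, matrix_b: np.ndarray,
                n_permutations: int = 5000, seed: int = 0,
                tail: str = "greater") -> MantelResult:
    """Mantel test: correlation of two similarity matrices under joint
    row/column permutation of one of them.

    r is the Pearson correlation of the strict upper triangles;
    p = (1 + #{r_perm >= r}) / (1 + n_permutations) for the default
    'greater' tail ('two-sided' uses |r_perm| >= |r|).
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    for m in (a, b):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Mantel inputs must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("Mantel inputs must be symmetric")
    if a.shape != b.shape:
        raise ValueError("Mantel inputs must have equal size")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)

    def tri_corr(bm: np.ndarray) -> float:
        return float(np.corrcoef(a[iu], bm[iu])[0, 1])

    r_obs = tri_corr(b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_p = tri_corr(b[np.ix_(perm, perm)])
        if tail == "greater":
            exceed += r_p >= r_obs - 1e-15
        else:
            exceed += abs(r_p) >= abs(r_obs) - 1e-15
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations, seed=seed)


def block_average_to_trs(trace: np.ndarray, rate_hz: float = 5.0,
                         tr_seconds: float = 2.0) -> np.ndarray:
    """Average a fast rating trace into TR-length blocks (rows preserved)."""
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    per_tr = int(round(rate_hz * tr_seconds))
    n_trs = trace.shape[1] // per_tr
    out = trace[:, :n_trs * per_tr].reshape(trace.shape[0], n_trs, per_tr)
    return out.mean(axis=2)


def timepoint_perm_test(ratings_a: np.ndarray, ratings_b: np.ndarray,
                        n_permutations: int = 1000, seed: int = 0,
                        q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample permutation t at every time point, BH-FDR over time.

    Returns (per-timepoint two-sided p, corrected significance mask).
    """
    a = np.atleast_2d(np.asarray(ratings_a, dtype=float))
    b = np.atleast_2d(np.asarray(ratings_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("trace lengths differ between groups")
    na, nb = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])

    def t_vec(data_a: np.ndarray, data_b: np.ndarray) -> np.ndarray:
        se = np.sqrt(data_a.var(axis=0, ddof=1) / data_a.shape[0]
                     + data_b.var(axis=0, ddof=1) / data_b.shape[0])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (data_a.mean(axis=0) - data_b.mean(axis=0)) / se
        return np.nan_to_num(t)

    t_obs = t_vec(a, b)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(a.shape[1])
    for _ in range(n_permutations):
        idx = rng.permutation(na + nb)
        t_p = t_vec(pooled[idx[:na]], pooled[idx[na:]])
        exceed += np.abs(t_p) >= np.abs(t_obs) - 1e-15
    p = (1.0 + exceed) / (1.0 + n_permutations)
    mask, _ = bh_fdr(p, q)
    return p, mask
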