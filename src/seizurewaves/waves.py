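"""Travelling-wave estimation from coherence phase.

The chain implemented here is deliberately conservative: an electrode pair
only contributes a group delay if a contiguous run of significantly coherent
bins at least 3 Hz wide exists inside 1-13 Hz *and* the phase-versus-frequency
line beats a constant model (F-test, p < 0.05); a window only yields a wave if
at least half the electrodes have defined delays *and* the fitted 2D plane
beats the constant model.  No speed or direction is ever reported from an
invalid fit.

Delay convention: positive delay means the electrode lags the reference, so
the fitted delay gradient points toward latest arrival and the four-quadrant
angle of ``(b1, b2)`` marks the direction of the wave source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coherence import CoherogramSet
from .recordings import (
    INTERVALS,
    AnalysisWindow,
    ElectrodeLayout,
    assign_interval,
)

__all__ = [
    "DelayEstimate",
    "DelayMap",
    "PlaneWaveFit",
    "IntervalSummary",
    "DistanceRegression",
    "group_delay",
    "delay_series",
    "build_delay_map",
    "fit_plane",
    "direction_consistency",
    "direction_difference",
    "coherence_vs_distance",
    "summarize_intervals",
    "group_test",
]


@dataclass(frozen=True)
class DelayEstimate:
    """Group delay (s) between an electrode and a reference.

    Positive values mean the electrode lags the reference.  ``defined`` is
    False when no qualifying coherent band existed or the phase-line fit was
    not significant; undefined estimates carry ``value = nan``.
    """

    value: float
    defined: bool
    band_used: tuple[float, float] | None = None
    fit_p: float = np.nan


@dataclass
class DelayMap:
    """Per-window delays of every electrode relative to a reference."""

    window: AnalysisWindow
    reference: str
    delays: dict[str, DelayEstimate]

    @property
    def n_defined(self) -> int:
        return sum(d.defined for d in self.delays.values())

    @property
    def n_total(self) -> int:
        return len(self.delays)


@dataclass
class PlaneWaveFit:
    """2D plane fit ``D = b0 + b1*X + b2*Y`` of delays over positions.

    ``speed = 1/sqrt(b1^2 + b2^2)`` (mm/s for delays in s, positions in mm);
    ``source_direction = atan2(b2, b1)`` points toward the largest delays,
    i.e. away from earliest arrival.  Invalid fits carry NaN speed/direction.
    """

    b0: float = np.nan
    b1: float = np.nan
    b2: float = np.nan
    fit_p: float = np.nan
    speed: float = np.nan
    source_direction: float = np.nan
    valid: bool = False
    n_defined: int = 0
    n_total: int = 0
    window: AnalysisWindow | None = None
    scale: str = ""


@dataclass
class IntervalSummary:
    """Valid-wave statistics pooled over one seizure interval."""

    interval: str
    n_waves: int
    direction_consistency: float = np.nan
    mean_speed: float = np.nan
    ci_consistency: tuple[float, float] = (np.nan, np.nan)
    ci_speed: tuple[float, float] = (np.nan, np.nan)
    empty: bool = True


@dataclass
class DistanceRegression:
    """OLS line of band-averaged coherence versus pair distance."""

    interval: str
    slope: float
    left_intercept: float   # fitted value at the minimum observed distance
    right_intercept: float  # fitted value at the maximum observed distance
    d_min: float = np.nan
    d_max: float = np.nan
    n_pairs: int = 0


# ---------------------------------------------------------------------------
# Group delay from the phase of the coherence
# ---------------------------------------------------------------------------


def _significant_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def group_delay(
    cg: CoherogramSet,
    window_index: int,
    band: tuple[float, float] = (1.0, 13.0),
    min_band: float = 3.0,
    p_threshold: float = 0.05,
) -> DelayEstimate:
    """Group delay for one window from the slope of phase versus frequency.

    Searches 1-13 Hz for a contiguous run of significant bins spanning at
    least ``min_band`` Hz (longest run wins; ties go to the lowest
    frequency), unwraps the coherence phase across that run, and fits a line
    to phase versus frequency.  The delay is ``slope / (2*pi)``; it is
    defined only when the line improves on a constant model at
    ``p < p_threshold`` (F-test).
    """
    f = cg.freq_axis
    sel = (f >= band[0]) & (f <= band[1])
    fb = f[sel]
    mask = cg.sig_mask[window_index, sel]
    runs = _significant_runs(mask)
    # keep runs spanning >= min_band Hz
    runs = [r for r in runs if fb[r[1] - 1] - fb[r[0]] >= min_band - 1e-9]
    if not runs:
        return DelayEstimate(np.nan, False)
    lengths = [r[1] - r[0] for r in runs]
    best = max(lengths)
    # longest run; tie broken by lowest frequency (runs are in ascending order)
    run = next(r for r, L in zip(runs, lengths) if L == best)
    i0, i1 = run
    freqs = fb[i0:i1]
    ph = np.unwrap(cg.phase[window_index, sel][i0:i1])
    n = len(freqs)
    # OLS line and F-test against the constant model
    fc = freqs - freqs.mean()
    slope = float(np.dot(fc, ph - ph.mean()) / np.dot(fc, fc))
    resid = ph - ph.mean() - slope * fc
    sse1 = float(np.dot(resid, resid))
    sse0 = float(np.dot(ph - ph.mean(), ph - ph.mean()))
    if sse1 <= 1e-30 * max(sse0, 1.0):
        p = 0.0
    else:
        fstat = (sse0 - sse1) / (sse1 / (n - 2))
        p = float(stats.f.sf(fstat, 1, n - 2))
    if p >= p_threshold:
        return DelayEstimate(np.nan, False, (freqs[0], freqs[-1]), p)
    return DelayEstimate(slope / (2 * np.pi), True, (freqs[0], freqs[-1]), p)


def delay_series(
    cg: CoherogramSet,
    band: tuple[float, float] = (1.0, 13.0),
    min_band: float = 3.0,
) -> list[DelayEstimate]:
    """Group delay of a pair for every window of its coherogram."""
    return [group_delay(cg, w, band, min_band) for w in range(cg.n_windows)]


def build_delay_map(
    delays_by_pair: dict[tuple[str, str], DelayEstimate],
    window: AnalysisWindow,
    scale: str,
    reference: str,
) -> DelayMap:
    """Assemble one window's delay map from per-pair delay estimates.

    ``micro`` scale: keys are ``(reference, electrode)`` pairs, one delay per
    non-reference microelectrode; the reference itself enters with delay 0.

    ``macro`` scale: keys are ``(micro_id, macro_id)`` pairs; each
    macroelectrode's delay is the mean over its *defined* micro-pair delays,
    undefined if none are defined.  The reference label then names the
    microarray as a whole and does not appear in the map.
    """
    delays: dict[str, DelayEstimate] = {}
    if scale == "micro":
        delays[reference] = DelayEstimate(0.0, True, None, 0.0)
        for (ref, other), est in delays_by_pair.items():
            if ref != reference:
                raise ValueError(
                    f"micro delay pair ({ref}, {other}) does not use the "
                    f"reference {reference!r}"
                )
            delays[other] = est
    elif scale == "macro":
        by_macro: dict[str, list[float]] = {}
        for (_micro, macro), est in delays_by_pair.items():
            vals = by_macro.setdefault(macro, [])
            if est.defined:
                vals.append(est.value)
        for macro, vals in by_macro.items():
            if vals:
                delays[macro] = DelayEstimate(float(np.mean(vals)), True)
            else:
                delays[macro] = DelayEstimate(np.nan, False)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return DelayMap(window=window, reference=reference, delays=delays)


# ---------------------------------------------------------------------------
# Plane-wave fit
# ---------------------------------------------------------------------------


def _irls_bisquare(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively reweighted least squares with Tukey bisquare weights.

    Returns (coefficients, final weights).  Scale is 4.685 * MAD-based sigma,
    re-estimated each iteration.  Falls back to OLS when residuals are
    (numerically) zero.
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones(len(y))
    for _ in range(max_iter):
        resid = y - X @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        sigma = mad / 0.6745
        if sigma <= 1e-12 * max(1.0, float(np.abs(y).max())):
            return beta, np.ones(len(y))
        u = resid / (4.685 * sigma)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() < X.shape[1]:  # degenerate downweighting
            w = np.ones(len(y))
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw + 1e-15 * np.eye(X.shape[1]), Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    return beta, w


def fit_plane(
    dmap: DelayMap,
    layout: ElectrodeLayout,
    robust: bool = True,
    min_defined_fraction: float = 0.5,
    p_threshold: float = 0.05,
) -> PlaneWaveFit:
    """Fit ``D = b0 + b1*X + b2*Y`` to a window's defined delays.

    Robust (IRLS, Tukey bisquare) by default; ``robust=False`` gives plain
    least squares.  A fit is valid only if at least half the electrodes have
    defined delays and the plane beats the constant model (F-test on the
    final weighted fit, p < 0.05).  Speed and source direction are derived
    only for valid fits.
    """
    ids = [i for i, d in dmap.delays.items() if d.defined]
    y = np.array([dmap.delays[i].value for i in ids])
    n_total = dmap.n_total
    n_def = len(ids)
    out = PlaneWaveFit(n_defined=n_def, n_total=n_total, window=dmap.window)
    if n_def < 3:
        return out
    pos = np.array([layout.positions[layout.index(i)] for i in ids])
    X = np.column_stack([np.ones(n_def), pos[:, 0], pos[:, 1]])
    if np.linalg.matrix_rank(X) < 3:
        return out
    if robust:
        beta, w = _irls_bisquare(X, y)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        w = np.ones(n_def)
    # F-test of the plane against the constant model, on the final weights
    sw = np.sqrt(w)
    yw = sw * y
    Xw = X * sw[:, None]
    resid1 = yw - Xw @ beta
    sse1 = float(resid1 @ resid1)
    mu0 = float((w @ y) / w.sum()) if w.sum() > 0 else float(np.mean(y))
    resid0 = sw * (y - mu0)
    sse0 = float(resid0 @ resid0)
    dof = n_def - 3
    if dof <= 0:
        p = 0.0 if sse1 < 1e-30 else np.nan
    elif sse1 <= 1e-28 * max(sse0, 1.0):
        p = 0.0
    else:
        fstat = ((sse0 - sse1) / 2.0) / (sse1 / dof)
        p = float(stats.f.sf(fstat, 2, dof))
    out.b0, out.b1, out.b2 = (float(b) for b in beta)
    out.fit_p = p
    valid = (n_def / n_total >= min_defined_fraction) and np.isfinite(p) and (
        p < p_threshold
    )
    out.valid = bool(valid)
    if valid:
        gradient = np.hypot(out.b1, out.b2)
        if gradient > 0:
            out.speed = 1.0 / gradient
            out.source_direction = float(np.arctan2(out.b2, out.b1))
        else:
            out.valid = False
    return out


# ---------------------------------------------------------------------------
# Circular statistics and summaries
# ---------------------------------------------------------------------------


def direction_consistency(angles: np.ndarray) -> float:
    """Phase-locking value: modulus of the mean unit phasor of the angles.

    1 means perfectly aligned directions, values near 0 a uniform spread
    (expectation ~ sqrt(pi)/(2*sqrt(N)) for N uniform angles).
    """
    angles = np.asarray(angles, float)
    if angles.size == 0:
        warnings.warn("direction_consistency of empty set is undefined",
                      stacklevel=2)
        return np.nan
    return float(np.abs(np.mean(np.exp(1j * angles))))


def direction_difference(theta_a: float, theta_b: float) -> float:
    """Signed circular difference ``theta_a - theta_b`` wrapped to (-pi, pi]."""
    d = (theta_a - theta_b) % (2 * np.pi)
    if d > np.pi:
        d -= 2 * np.pi
    return float(d)


def coherence_vs_distance(
    distances_mm: np.ndarray,
    coherences: np.ndarray,
    interval: str = "",
) -> DistanceRegression:
    """OLS regression of band-averaged coherence on pair distance.

    Summarised by the slope and by the fitted values at the minimum and
    maximum observed distances (left and right intercepts).
    """
    d = np.asarray(distances_mm, float)
    c = np.asarray(coherences, float)
    keep = np.isfinite(d) & np.isfinite(c)
    d, c = d[keep], c[keep]
    if len(d) < 3:
        raise ValueError("need at least 3 pairs for the distance regression")
    if np.ptp(d) <= 0:
        raise ValueError("zero distance range: slope undefined")
    slope, intercept = np.polyfit(d, c, 1)
    return DistanceRegression(
        interval=interval,
        slope=float(slope),
        left_intercept=float(intercept + slope * d.min()),
        right_intercept=float(intercept + slope * d.max()),
        d_min=float(d.min()),
        d_max=float(d.max()),
        n_pairs=int(len(d)),
    )


def summarize_intervals(
    fits: list[PlaneWaveFit],
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> dict[str, IntervalSummary]:
    """Per-interval direction consistency, mean speed and bootstrap CIs.

    Windows are assigned to Pre/Early/Middle/Late by the normalised time of
    their centre (Middle overlaps Early and Late).  Only valid fits
    contribute.  95% CIs use percentile bootstrap with ``n_boot`` resamples.
    """
    rng = np.random.default_rng(rng)
    out: dict[str, IntervalSummary] = {}
    for name in INTERVALS:
        sel = [
            f
            for f in fits
            if f.valid
            and f.window is not None
            and name in assign_interval(f.window.normalized_time)
        ]
        if not sel:
            out[name] = IntervalSummary(interval=name, n_waves=0, empty=True)
            continue
        ang = np.array([f.source_direction for f in sel])
        spd = np.array([f.speed for f in sel])
        n = len(sel)
        boot_dc = np.empty(n_boot)
        boot_sp = np.empty(n_boot)
        idx = rng.integers(0, n, size=(n_boot, n))
        for b in range(n_boot):
            boot_dc[b] = np.abs(np.mean(np.exp(1j * ang[idx[b]])))
            boot_sp[b] = np.mean(spd[idx[b]])
        out[name] = IntervalSummary(
            interval=name,
            n_waves=n,
            direction_consistency=direction_consistency(ang),
            mean_speed=float(np.mean(spd)),
            ci_consistency=tuple(np.percentile(boot_dc, [2.5, 97.5])),
            ci_speed=tuple(np.percentile(boot_sp, [2.5, 97.5])),
            empty=False,
        )
    return out


def group_test(
    pre_values: np.ndarray, seizure_values: np.ndarray
) -> float:
    """Two-sided two-sample t-test between pre-seizure and seizure statistics.

    The seizure group pools the Early/Middle/Late per-run values (so with
    ``n`` runs the group sizes are ``n`` versus ``3n``).  P values are
    reported uncorrected.  Returns NaN (with a warning) when both groups are
    constant with different means; identical constant groups give p = 1.
    """
    a = np.asarray(pre_values, float)
    b = np.asarray(seizure_values, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        warnings.warn("degenerate variance: t-test undefined", stacklevel=2)
        return np.nan
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
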