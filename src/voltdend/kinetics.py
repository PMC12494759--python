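"""GEVI characterization from voltage-clamp fluorescence traces.

Photobleaching is corrected by dividing the trace by a three-term
exponential fit of its baseline samples.  Response kinetics are quantified
by fitting the onset-aligned piecewise model

    F(t) = c + k exp((t - t0) lambda) * (t > t0) + k * (t <= t0)

(or its dual-exponential extension with a second ``k2, lambda2`` component,
ordered fast-first) where the onset time ``t0`` is fitted together with the
other coefficients.  F-V curves are summarized by an ordinary least-squares
regression over the subthreshold voltage range.  Screening metrics are the
green/red brightness ratio and the photostability (area under the
initial-fluorescence-normalized trace, so a constant trace scores 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "BleachFit",
    "correct_photobleach",
    "OnsetExpFit",
    "fit_onset_exponential",
    "FVCurve",
    "compute_fv_curve",
    "step_responses",
    "ScreenMetrics",
    "screen_metrics",
]


@dataclass
class BleachFit:
    amplitudes: np.ndarray  # (3,)
    taus_s: np.ndarray  # (3,)
    residual_rms: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.amplitudes[:, None] * np.exp(-t[None, :] / self.taus_s[:, None])).sum(axis=0)


def correct_photobleach(
    trace: np.ndarray,
    times: np.ndarray,
    baseline_mask: np.ndarray | None = None,
    n_terms: int = 3,
) -> tuple[np.ndarray, np.ndarray, BleachFit]:
    """Divide a trace by a three-term exponential fit of its baseline.

    ``baseline_mask`` selects the samples used for the fit (exclude evoked
    responses); the whole trace is corrected.  The time constants are fitted
    by nonlinear least squares with log-spaced initialization across the
    record, amplitudes by linear projection at each step (a separable /
    variable-projection formulation, robust without user-supplied guesses).

    Returns ``(corrected, fitted_curve, BleachFit)`` with
    ``corrected = raw / fitted_curve``.
    """
    y = np.asarray(trace, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("trace and times must have equal length")
    mask = np.ones(len(y), dtype=bool) if baseline_mask is None else np.asarray(baseline_mask, bool)
    if mask.sum() < 100:
        raise ValueError("need at least 100 baseline samples")
    tm, ym = t[mask], y[mask]
    span = max(tm.max() - tm.min(), 1e-9)
    log_tau0 = np.log(np.geomspace(span / 50, span * 5, n_terms))

    def amplitudes(log_tau: np.ndarray) -> np.ndarray:
        e = np.exp(-tm[:, None] / np.exp(log_tau)[None, :])
        a, *_ = np.linalg.lstsq(e, ym, rcond=None)
        return a

    def resid(log_tau: np.ndarray) -> np.ndarray:
        e = np.exp(-tm[:, None] / np.exp(log_tau)[None, :])
        a, *_ = np.linalg.lstsq(e, ym, rcond=None)
        return e @ a - ym

    sol = least_squares(resid, log_tau0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(
            "photobleach fit did not converge "
            f"(initial taus {np.exp(log_tau0).round(4).tolist()} s, status {sol.status})"
        )
    taus = np.exp(sol.x)
    amps = amplitudes(sol.x)
    fit = BleachFit(
        amplitudes=amps,
        taus_s=taus,
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )
    curve = fit(t)
    if np.any(curve <= 0):
        raise RuntimeError("fitted bleach curve is not strictly positive")
    return y / curve, curve, fit


@dataclass
class OnsetExpFit:
    """Coefficients of the piecewise onset-exponential model."""

    c: float  # plateau fluorescence
    k: float  # (fast) component amplitude
    lam: float  # (fast) rate constant, 1/s, negative for decay
    t0: float  # fitted onset time, s
    model: str  # "single" | "dual"
    residual_rms: float
    k2: float | None = None
    lam2: float | None = None  # slow component (e.g. residual photobleaching)
    degenerate: bool = False

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        dt = t - self.t0
        out = np.full_like(t, self.c + self.k)
        after = dt > 0
        out[after] = self.c + self.k * np.exp(dt[after] * self.lam)
        if self.model == "dual":
            out[~after] += self.k2
            out[after] += self.k2 * np.exp(dt[after] * self.lam2)
        return out


def _onset_design(t: np.ndarray, t0: float, lams: np.ndarray) -> np.ndarray:
    dt = t - t0
    after = dt > 0
    cols = [np.ones_like(t)]
    for lam in lams:
        col = np.ones_like(t)
        col[after] = np.exp(dt[after] * lam)
        cols.append(col)
    return np.stack(cols, axis=1)


def fit_onset_exponential(
    trace: np.ndarray,
    times: np.ndarray,
    model: str = "single",
    window: tuple[float, float] | None = None,
) -> OnsetExpFit:
    """Fit the onset-exponential model; the onset time t0 is a coefficient.

    For the dual model the components are ordered fast-first
    (``|lambda| >= |lambda2|``).  A flat trace under the dual model falls
    back to the single model with ``degenerate=True``.
    """
    if model not in ("single", "dual"):
        raise ValueError("model must be 'single' or 'dual'")
    y = np.asarray(trace, dtype=float)
    t = np.asarray(times, dtype=float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        y, t = y[sel], t[sel]
    if len(y) < 10:
        raise ValueError("too few samples in the fit window")
    scale = max(np.abs(y).max(), 1e-12)
    flat = np.ptp(y) < 1e-9 * scale
    if flat:
        fit = OnsetExpFit(
            c=float(y.mean()), k=0.0, lam=-1.0, t0=float(t[0]), model="single",
            residual_rms=float(np.std(y)), degenerate=(model == "dual"),
        )
        return fit

    # initialization: onset at the steepest change of the (smoothed) trace
    from scipy.ndimage import gaussian_filter1d

    dy = np.gradient(gaussian_filter1d(y, max(1.0, len(y) / 500)))
    i0 = int(np.argmax(np.abs(dy)))
    t0_init = float(t[i0])
    span = t[-1] - t0_init if t[-1] > t0_init else (t[-1] - t[0])
    lam0 = 3.0 / max(span, 1e-9)
    n_exp = 1 if model == "single" else 2

    def unpack(p):
        t0 = p[0]
        lams = -np.exp(p[1 : 1 + n_exp])
        return t0, lams

    def resid(p):
        t0, lams = unpack(p)
        e = _onset_design(t, t0, lams)
        a, *_ = np.linalg.lstsq(e, y, rcond=None)
        return e @ a - y

    # multi-start over rate-constant scales: exponential sums are notoriously
    # ill-conditioned, a single start frequently lands in a local minimum
    if model == "single":
        starts = [np.array([t0_init, np.log(lam0 * s)]) for s in (1.0, 10.0, 100.0)]
    else:
        starts = [
            np.array([t0_init, np.log(lam0 * f), np.log(lam0 * s)])
            for f, s in ((20.0, 1.0), (100.0, 3.0), (500.0, 10.0), (1000.0, 1.0))
        ]
    lo = np.full(1 + n_exp, -np.inf)
    hi = np.full(1 + n_exp, np.inf)
    lo[0], hi[0] = t[0], t[-1]
    best = None
    for p0 in starts:
        sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    t0, lams = unpack(best.x)
    e = _onset_design(t, t0, lams)
    a, *_ = np.linalg.lstsq(e, y, rcond=None)
    rms = float(np.sqrt(np.mean((e @ a - y) ** 2)))
    if model == "single":
        return OnsetExpFit(c=float(a[0]), k=float(a[1]), lam=float(lams[0]), t0=float(t0),
                           model="single", residual_rms=rms)
    order = np.argsort(-np.abs(lams))  # fast first
    lams, amps = lams[order], a[1:][order]
    return OnsetExpFit(
        c=float(a[0]), k=float(amps[0]), lam=float(lams[0]), t0=float(t0),
        model="dual", residual_rms=rms, k2=float(amps[1]), lam2=float(lams[1]),
    )


@dataclass
class FVCurve:
    voltages_mv: np.ndarray
    responses_pct: np.ndarray  # dF/F0, percent
    subthreshold_range_mv: tuple[float, float]
    slope_pct_per_mv: float
    intercept_pct: float
    r_squared: float
    n_subthreshold: int


def compute_fv_curve(
    step_responses_: list[tuple[float, float]] | np.ndarray,
    subthreshold_range_mv: tuple[float, float],
) -> FVCurve:
    """OLS slope and R^2 of the F-V relation over the subthreshold range.

    ``step_responses_`` are ``(voltage mV, dF/F0 %)`` pairs; only points
    inside the (inclusive) subthreshold range enter the regression.
    """
    arr = np.asarray(step_responses_, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need >= 2 (voltage, response) pairs")
    v, r = arr[:, 0], arr[:, 1]
    lo, hi = subthreshold_range_mv
    sel = (v >= lo) & (v <= hi)
    if sel.sum() < 3:
        raise ValueError(f"only {int(sel.sum())} points in the subthreshold range (need >= 3)")
    res = linregress(v[sel], r[sel])
    return FVCurve(
        voltages_mv=v,
        responses_pct=r,
        subthreshold_range_mv=subthreshold_range_mv,
        slope_pct_per_mv=float(res.slope),
        intercept_pct=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_subthreshold=int(sel.sum()),
    )


def step_responses(
    fluor: np.ndarray,
    volt: np.ndarray,
    sample_rate: float,
    hold_mv: float = -70.0,
    smooth_ms: float = 47.6,
    plateau_fraction: float = 0.25,
) -> np.ndarray:
    """Steady-state dF/F0 (%) per voltage step of a clamp recording.

    The fluorescence trace is smoothed by a moving average (47.6 ms) and the
    plateau is read as the mean over the last ``plateau_fraction`` of each
    step.  F0 is the mean fluorescence at the holding potential.  Returns
    ``(n_steps, 2)`` pairs of (step voltage mV, response %).
    """
    f = np.asarray(fluor, dtype=float)
    v = np.asarray(volt, dtype=float)
    k = max(1, int(round(smooth_ms / 1000 * sample_rate)))
    fs = uniform_filter1d(f, size=k, mode="nearest")
    at_hold = np.isclose(v, hold_mv)
    if not at_hold.any():
        raise ValueError("no samples at the holding potential; cannot define F0")
    # median: hold samples within half a smoothing window of a step edge are
    # contaminated by the moving average
    f0 = float(np.median(fs[at_hold]))
    # contiguous runs away from hold
    changed = (~at_hold).astype(int)
    starts = np.flatnonzero(np.diff(np.concatenate([[0], changed])) == 1)
    stops = np.flatnonzero(np.diff(np.concatenate([changed, [0]])) == -1) + 1
    out = []
    for a, b in zip(starts, stops):
        if b - a < 10:
            continue
        # exclude the half smoothing window at the step end, where the moving
        # average already mixes in post-step samples
        hi = max(a + 1, b - k // 2 - 1)
        lo = max(a, hi - max(1, int(round((b - a) * plateau_fraction))))
        out.append((float(np.median(v[a:b])), float((fs[lo:hi].mean() / f0 - 1.0) * 100.0)))
    return np.asarray(out)


@dataclass
class ScreenMetrics:
    brightness: float  # green/red ratio
    photostability: float  # normalized AUC (constant trace -> 1)


def screen_metrics(green: np.ndarray, red: np.ndarray, n_frames: int) -> ScreenMetrics:
    """Brightness (green/red ratio) and photostability (normalized AUC)."""
    g = np.asarray(green, dtype=float)[:n_frames]
    r = np.asarray(red, dtype=float)[:n_frames]
    if len(g) < n_frames or len(r) < n_frames:
        raise ValueError("traces shorter than n_frames")
    if r.mean() <= 0:
        raise ValueError("red reference has non-positive mean")
    if g[0] <= 0:
        raise ValueError("green trace starts at a non-positive value")
    gn = g / g[0]
    auc = float(np.trapezoid(gn, dx=1.0 / (n_frames - 1)))
    return ScreenMetrics(brightness=float(g.mean() / r.mean()), photostability=auc)
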