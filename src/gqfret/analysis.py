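"""Ratiometric FRET trace analysis.

Implements the photometry analysis chain used for every condition: ratio
computation with donor bleed-through correction, affine normalization
(baseline window pinned to 1, pre-washout window to 0 or 2 depending on the
direction of the response), windowed one- and two-step exponential fitting
with a bounded onset delay, SNR, percent-distribution metrics, Hill
dose-response fitting, sigmoid half-time (T50), and mean +/- SEM summaries.

Fixed analysis windows (seconds, relative to the agonist mark):

===========  ==========
Step 1_ON    0 - 1.2
Step 2_ON    1.3 - 15
Step 1_OFF   0 - 3.6
Step 2_OFF   3.7 - 30
===========  ==========
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import DataError, FitError, NormalizationError, ValidationError

__all__ = [
    "ON_WINDOWS",
    "OFF_WINDOWS",
    "FretrTrace",
    "NormalizedTrace",
    "StepFit",
    "DoseResponseFit",
    "SummaryRow",
    "compute_fretr",
    "normalize_trace",
    "fit_two_step",
    "fit_single_step",
    "compute_snr",
    "percent_metrics",
    "fit_dose_response",
    "fit_t50",
    "summarize",
]

ON_WINDOWS = ((0.0, 1.2), (1.3, 15.0))
OFF_WINDOWS = ((0.0, 3.6), (3.7, 30.0))
BASELINE_WINDOW_S = 5.0
PLATEAU_WINDOW_S = 5.0
DELAY_MAX_S = 0.5


@dataclass(frozen=True)
class FretrTrace:
    t: np.ndarray
    fretr: np.ndarray
    t_on: float = math.nan
    t_off: float = math.nan

    def __post_init__(self):
        if len(self.t) != len(self.fretr):
            raise ValidationError("t and fretr must share length")


@dataclass(frozen=True)
class NormalizedTrace:
    t: np.ndarray
    value: np.ndarray
    direction: str
    t_on: float
    t_off: float


@dataclass(frozen=True)
class StepFit:
    """Windowed exponential decomposition of one trace."""

    mode: str                 # "ON" | "OFF"
    delay: float
    tau1: float
    amp1: float
    tau2: float | None = None
    amp2: float | None = None
    windows: tuple = ()
    residual_norm: float = math.nan
    flags: tuple = ()


@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float
    hill: float
    top: float
    bottom: float
    flags: tuple = ()


@dataclass(frozen=True)
class SummaryRow:
    condition: str
    metric: str
    mean: float
    sem: float
    n: int


def compute_fretr(channels, cfactor: float = 0.45) -> FretrTrace:
    """FRETr = (YFPc - cFactor * CFPc) / CFPc, elementwise."""
    cfp = np.asarray(channels.cfp_c, dtype=float)
    yfp = np.asarray(channels.yfp_c, dtype=float)
    bad = np.flatnonzero(cfp <= 0)
    if bad.size:
        raise DataError(f"non-positive donor sample at index {bad[0]}",
                        index=int(bad[0]))
    return FretrTrace(t=np.asarray(channels.t, dtype=float),
                      fretr=(yfp - cfactor * cfp) / cfp,
                      t_on=getattr(channels, "t_on", math.nan),
                      t_off=getattr(channels, "t_off", math.nan))


def _window_mean(t, y, lo, hi, what):
    sel = (t >= lo - 1e-9) & (t < hi - 1e-9)
    if not np.any(sel):
        raise ValidationError(f"no samples in the {what} window [{lo}, {hi})")
    return float(np.mean(y[sel]))


def normalize_trace(trace: FretrTrace, direction: str,
                    baseline_window: float = BASELINE_WINDOW_S,
                    plateau_window: float = PLATEAU_WINDOW_S,
                    ) -> NormalizedTrace:
    """Affine normalization to the two anchor windows.

    The mean over ``baseline_window`` seconds before the agonist mark maps
    to 1; the mean over ``plateau_window`` seconds before washout maps to 0
    (decreasing response) or 2 (increasing response).
    """
    if direction not in ("decrease", "increase"):
        raise ValidationError(f"unknown direction {direction!r}")
    if not (math.isfinite(trace.t_on) and math.isfinite(trace.t_off)):
        raise ValidationError("trace needs agonist on/off marks")
    if trace.t_on - trace.t[0] < baseline_window - 1e-9:
        raise ValidationError("insufficient baseline before the agonist mark")
    b = _window_mean(trace.t, trace.fretr, trace.t_on - baseline_window,
                     trace.t_on, "baseline")
    p = _window_mean(trace.t, trace.fretr, trace.t_off - plateau_window,
                     trace.t_off, "plateau")
    if abs(b - p) < 1e-12 * max(1.0, abs(b)):
        raise NormalizationError("zero dynamic range: baseline == plateau")
    if direction == "decrease":
        value = (trace.fretr - p) / (b - p)
    else:
        value = 1.0 + (trace.fretr - b) / (p - b)
    return NormalizedTrace(t=trace.t, value=value, direction=direction,
                           t_on=trace.t_on, t_off=trace.t_off)


def _exp_model(t, yinf, amp, tau, t0, slope):
    tt = np.maximum(t - t0, 0.0)
    return yinf + amp * np.exp(-tt / tau) + slope * t


def _fit_exp_window(trel, y, delay_max=0.0, drift=False):
    """Single-exponential least squares with bounded onset delay.

    Multi-start over three log-spaced initial time constants; the best
    residual wins.  ``drift`` adds a linear term (used for the step-1 window
    to absorb leakage of the much slower second step).
    """
    span = float(trel[-1] - trel[0]) if len(trel) > 1 else 1.0
    scale = float(np.ptp(y)) or 1e-6
    best = None
    for tau0 in (span / 30.0, span / 6.0, span):
        p = lmfit.Parameters()
        p.add("yinf", value=float(y[-1]), min=float(y.min()) - 3 * scale,
              max=float(y.max()) + 3 * scale)
        p.add("amp", value=float(y[0] - y[-1]) or 0.5 * scale,
              min=-3 * scale, max=3 * scale)
        p.add("tau", value=tau0, min=1e-4, max=3.0 * span)
        if delay_max > 0:
            p.add("t0", value=min(0.45 * delay_max, span / 10),
                  min=0.0, max=delay_max)
        else:
            p.add("t0", value=0.0, vary=False)
        p.add("slope", value=0.0, vary=drift,
              min=-2 * scale / span, max=2 * scale / span)
        try:
            out = lmfit.minimize(
                lambda pars: _exp_model(trel, pars["yinf"], pars["amp"],
                                        pars["tau"], pars["t0"],
                                        pars["slope"]) - y,
                p, method="leastsq")
        except Exception:
            continue
        if math.isfinite(out.chisqr) and (best is None
                                          or out.chisqr < best.chisqr):
            best = out
    if best is None:
        raise FitError("exponential fit did not converge in any start")
    flags = []
    resid_sd = math.sqrt(best.chisqr / max(len(y) - 1, 1))
    v = best.params
    if abs(v["amp"].value) < max(5.0 * resid_sd, 1e-9):
        flags.append("unidentifiable")
    if v["tau"].value >= 0.99 * v["tau"].max or v["tau"].value <= 1.2e-4:
        flags.append("tau_at_bound")
    return (float(v["tau"].value), float(v["amp"].value),
            float(v["t0"].value), float(v["yinf"].value), resid_sd,
            tuple(flags))


def _window_data(trace: NormalizedTrace, mark: float, lo: float, hi: float):
    sel = (trace.t >= mark + lo - 1e-9) & (trace.t <= mark + hi + 1e-9)
    if np.count_nonzero(sel) < 4:
        raise ValidationError(
            f"trace does not cover the fit window [{lo}, {hi}] after the mark")
    return trace.t[sel] - mark, trace.value[sel]


def fit_two_step(trace: NormalizedTrace, mode: str,
                 windows: tuple | None = None,
                 strip_slow: bool = True) -> StepFit:
    """Two single-exponential window fits (step 1 and step 2).

    The step-2 window is fitted first (zero delay, anchored at its own
    start).  With ``strip_slow`` (default) the fitted slow component is
    extrapolated into the step-1 window and subtracted before the step-1
    fit -- classic exponential peeling, which removes the slow step's
    leakage into the short fast window.  Step 1 includes a bounded
    non-negative onset delay.  No continuity is imposed at the window
    boundary.
    """
    if mode not in ("ON", "OFF"):
        raise ValidationError("mode must be 'ON' or 'OFF'")
    mark = trace.t_on if mode == "ON" else trace.t_off
    w1, w2 = windows or (ON_WINDOWS if mode == "ON" else OFF_WINDOWS)
    t1, y1 = _window_data(trace, mark, *w1)
    t2, y2 = _window_data(trace, mark, *w2)
    tau2, amp2, _, yinf2, r2, f2 = _fit_exp_window(t2 - w2[0], y2)
    # backcasting an exponential that decays within the gap between the
    # windows would explode; in that case the "slow" fit has captured a fast
    # tail and stripping is meaningless
    can_strip = strip_slow and math.exp(w2[0] / tau2) < 5.0
    if can_strip:
        tau1 = amp1 = delay = r1 = None
        f1 = ()
        prev = (math.inf, math.inf)
        # alternate stripping until both time constants settle; poorly
        # separated components converge geometrically, so cap the rounds
        for _ in range(30):
            slow1 = yinf2 + amp2 * np.exp(-(t1 - w2[0]) / tau2)
            tau1, amp1, delay, _, r1, f1 = _fit_exp_window(
                y=y1 - slow1, trel=t1, delay_max=DELAY_MAX_S)
            fast2 = amp1 * np.exp(-np.maximum(t2 - delay, 0.0) / tau1)
            tau2, amp2, _, yinf2, r2, f2 = _fit_exp_window(
                t2 - w2[0], y2 - fast2)
            if abs(tau1 - prev[0]) < 1e-3 * tau1 and \
                    abs(tau2 - prev[1]) < 1e-3 * tau2:
                break
            prev = (tau1, tau2)
    else:
        tau1, amp1, delay, _, r1, f1 = _fit_exp_window(
            t1, y1, delay_max=DELAY_MAX_S, drift=True)
    flags = tuple(f"step1:{f}" for f in f1) + tuple(f"step2:{f}" for f in f2)
    return StepFit(mode=mode, delay=delay, tau1=tau1, amp1=abs(amp1),
                   tau2=tau2, amp2=abs(amp2), windows=(w1, w2),
                   residual_norm=math.hypot(r1, r2), flags=flags)


def fit_single_step(trace: NormalizedTrace, mode: str,
                    window: tuple | None = None) -> StepFit:
    """One exponential (with bounded delay) over the full post-mark span."""
    if mode not in ("ON", "OFF"):
        raise ValidationError("mode must be 'ON' or 'OFF'")
    mark = trace.t_on if mode == "ON" else trace.t_off
    if window is None:
        hi = (trace.t_off - trace.t_on) if mode == "ON" else \
            (trace.t[-1] - trace.t_off)
        window = (0.0, float(hi))
    t, y = _window_data(trace, mark, *window)
    tau, amp, delay, _, resid, flags = _fit_exp_window(
        t, y, delay_max=DELAY_MAX_S)
    return StepFit(mode=mode, delay=delay, tau1=tau, amp1=abs(amp),
                   windows=(window,), residual_norm=resid, flags=flags)


def compute_snr(trace: FretrTrace, baseline_window: float = BASELINE_WINDOW_S,
                mode: str = "sem") -> float:
    """Maximum response amplitude over the baseline standard error.

    ``mode='sem'`` (default) reads "standard error of the baseline" as
    SD / sqrt(n) over the baseline window; ``mode='sd'`` uses the raw SD.
    Returns ``inf`` when the baseline has zero variability.
    """
    if mode not in ("sem", "sd"):
        raise ValidationError("SNR mode must be 'sem' or 'sd'")
    if not math.isfinite(trace.t_on):
        raise ValidationError("trace needs an agonist mark")
    sel = (trace.t >= trace.t_on - baseline_window - 1e-9) & \
        (trace.t < trace.t_on - 1e-9)
    base = trace.fretr[sel]
    if base.size < 2:
        raise ValidationError("baseline window too short for SNR")
    sd = float(np.std(base, ddof=1))
    se = sd / math.sqrt(base.size) if mode == "sem" else sd
    resp = trace.fretr[trace.t >= trace.t_on - 1e-9]
    amp = float(np.max(np.abs(resp - base.mean())))
    if se == 0.0:
        return math.inf
    return amp / se


def percent_metrics(fit: StepFit | None = None, kind: str = "two_step_on",
                    max_amplitude: float | None = None,
                    cell_trace: NormalizedTrace | None = None,
                    group_trace: NormalizedTrace | None = None,
                    window_s: float = 2.5) -> dict:
    """Percent-distribution metrics.

    - ``two_step_on`` / ``two_step_off``: 100 * step amplitude / maximum
      response amplitude, per fitted step, remainder reported.
    - ``single_step_on``: 100 * (cell's mean pre-washout deviation from 1) /
      (group-average trace's mean pre-washout deviation from 1).
    - ``single_step_off``: 100 * deactivation amplitude / maximum activation
      amplitude.
    """
    if kind in ("two_step_on", "two_step_off"):
        if fit is None or max_amplitude is None:
            raise ValidationError(f"{kind} needs a fit and max_amplitude")
        if max_amplitude == 0:
            raise ValidationError("undefined percentages: zero max amplitude")
        p1 = 100.0 * fit.amp1 / max_amplitude
        p2 = 100.0 * (fit.amp2 or 0.0) / max_amplitude
        return {"step1_pct": p1, "step2_pct": p2,
                "remainder_pct": 100.0 - p1 - p2}
    if kind == "single_step_on":
        if cell_trace is None or group_trace is None:
            raise ValidationError("single_step_on needs cell and group traces")
        def _dev(tr):
            sel = (tr.t >= tr.t_off - window_s - 1e-9) & (tr.t < tr.t_off - 1e-9)
            if not np.any(sel):
                raise ValidationError("no samples in the pre-washout window")
            return float(np.mean(np.abs(tr.value[sel] - 1.0)))
        g = _dev(group_trace)
        if g == 0:
            raise ValidationError("undefined percentage: flat group average")
        return {"pct_on": 100.0 * _dev(cell_trace) / g}
    if kind == "single_step_off":
        if fit is None or max_amplitude is None:
            raise ValidationError("single_step_off needs a fit and max_amplitude")
        if max_amplitude == 0:
            raise ValidationError("undefined percentages: zero max amplitude")
        return {"pct_off": 100.0 * fit.amp1 / max_amplitude}
    raise ValidationError(f"unknown percent metric kind {kind!r}")


def _hill(c, bottom, top, ec50, hill):
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / np.maximum(c, 1e-30)) ** hill)


def fit_dose_response(conc, resp, fix_bottom: bool = True) -> DoseResponseFit:
    """Four-parameter logistic (Hill) fit of a concentration-response series.

    With ``fix_bottom`` the lower asymptote is pinned to 0 (normalized
    responses).  The response at EC50 equals (top + bottom) / 2 by model
    construction.  An EC50 outside the tested range is flagged.
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if conc.size < 4:
        raise ValidationError("need at least 4 concentrations")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be > 0")
    p = lmfit.Parameters()
    p.add("bottom", value=0.0, vary=not fix_bottom)
    p.add("top", value=float(np.max(resp)))
    p.add("ec50", value=float(np.exp(np.mean(np.log(conc)))), min=1e-12)
    p.add("hill", value=1.0, min=0.05, max=10.0)
    out = lmfit.minimize(
        lambda pars: _hill(conc, pars["bottom"], pars["top"], pars["ec50"],
                           pars["hill"]) - resp,
        p, method="leastsq")
    if not out.success:
        raise FitError("dose-response fit failed", diagnostics=out.message)
    v = out.params
    flags = ()
    if not (conc.min() <= v["ec50"].value <= conc.max()):
        flags = ("extrapolated_ec50",)
    return DoseResponseFit(ec50=float(v["ec50"].value), hill=float(v["hill"].value),
                           top=float(v["top"].value),
                           bottom=float(v["bottom"].value), flags=flags)


def fit_t50(t, y, residual_threshold: float = 0.15) -> tuple:
    """Half-time of a sigmoidal activation curve via logistic fitting.

    Returns ``(t50, flags)``; a residual RMS above ``residual_threshold``
    of the fitted amplitude flags a non-sigmoid input.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValidationError("need at least 5 samples for a T50 fit")
    p = lmfit.Parameters()
    p.add("base", value=float(y[0]))
    p.add("amp", value=float(y[-1] - y[0]) or 1e-6)
    p.add("t50", value=float(t[np.argmin(np.abs(y - 0.5 * (y[0] + y[-1])))]))
    p.add("width", value=max(float(t[-1] - t[0]) / 20.0, 1e-6), min=1e-9)

    def resid(pars):
        return pars["base"] + pars["amp"] / (
            1.0 + np.exp(-(t - pars["t50"]) / pars["width"])) - y

    out = lmfit.minimize(resid, p, method="leastsq")
    if not out.success:
        raise FitError("T50 fit failed", diagnostics=out.message)
    rms = math.sqrt(out.chisqr / t.size)
    amp = abs(out.params["amp"].value)
    flags = ("non_sigmoid",) if amp == 0 or rms > residual_threshold * amp else ()
    return float(out.params["t50"].value), flags


def summarize(values_by_metric: dict, condition: str,
              n1_sem: float = math.nan) -> list:
    """Mean +/- SEM rows per metric (SEM = SD / sqrt(n); n=1 -> ``n1_sem``)."""
    rows = []
    for metric, vals in values_by_metric.items():
        v = np.asarray([x for x in vals if x is not None and np.isfinite(x)],
                       dtype=float)
        if v.size == 0:
            continue
        sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 \
            else n1_sem
        rows.append(SummaryRow(condition=condition, metric=metric,
                               mean=float(v.mean()), sem=sem, n=int(v.size)))
    return rows
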