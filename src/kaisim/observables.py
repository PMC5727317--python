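"""Trajectory reduction and parameter sweeps.

Summary quantities of a run: the oscillation amplitude of the ensemble
phosphorylation level (a robust percentile range), the period from the
peak of the Fourier spectrum, and the ATPase activity (ADP released per
CI subunit per day in the KaiA/KaiB-free condition).  Sweep drivers
repeat simulations over parameter grids with independent seeds and
summarize mean +/- standard error per grid point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams, Trajectory
from .simulate import SimControl, simulate

__all__ = [
    "OscillationSummary",
    "ActivityPoint",
    "SweepResult",
    "amplitude",
    "period_fft",
    "summarize",
    "atpase_activity",
    "sweep_amplitude_period",
    "phase_diagram",
    "kaiA_threshold",
    "activity_frequency_slope",
]

logger = logging.getLogger(__name__)

#: minimal post-transient window (h) for amplitude estimation
MIN_WINDOW = 200.0
#: amplitude above which a run is classified as oscillating
OSC_THRESHOLD = 0.1
#: spectral peak must exceed this multiple of the median power
PEAK_SNR = 5.0

#: parameters accepted as sweep axes
SWEEP_AXES = ("q0", "delta0", "f0", "A_T", "B_T")


@dataclass(frozen=True)
class OscillationSummary:
    """Amplitude, spectral peak frequency and period of one trajectory."""

    amplitude: float
    f_p: float  # h^-1; nan when no spectral peak
    tau: float  # h; nan when no spectral peak
    oscillating: bool

    @property
    def f_p_per_day(self) -> float:
        return self.f_p * 24.0


@dataclass(frozen=True)
class ActivityPoint:
    """One point of the ATPase-activity / rhythm-frequency correlation."""

    f0: float
    atpase_activity: float  # ADP per CI subunit per 24 h, KaiA/KaiB-free
    f_p_day: float          # rhythm frequency (day^-1), oscillatory condition


@dataclass
class SweepResult:
    """Tidy per-run points plus a per-grid-point summary table."""

    axis: str
    points: pd.DataFrame    # one row per (value, seed)
    summary: pd.DataFrame   # one row per value: mean/SE of amplitude, tau


def _post_transient(series, times, transient):
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    keep = times >= transient
    return series[keep], times[keep]


def amplitude(series, times, transient: float) -> float:
    """Oscillation amplitude: 97.5th minus 2.5th percentile after the transient.

    Percentiles rather than extremes keep the estimate robust to the
    1/sqrt(N) ensemble noise of small runs.
    """
    s, t = _post_transient(series, times, transient)
    if len(t) < 2 or t[-1] - t[0] < MIN_WINDOW - 1e-6:
        raise ValueError(f"post-transient span must cover >= {MIN_WINDOW} h")
    lo, hi = np.percentile(s, [2.5, 97.5])
    return float(hi - lo)


def period_fft(series, sample_every: float, transient: float,
               times=None) -> tuple[float, float]:
    """Spectral peak frequency and period of a sampled series.

    The post-transient series is mean-removed, Hann-windowed and Fourier
    transformed; the peak bin (excluding the zero bin) is refined by
    quadratic interpolation of log power.  When the peak power is less
    than ``PEAK_SNR`` times the median spectral power the series is
    treated as non-oscillating and (nan, nan) is returned.

    Returns ``(f_p, tau)`` in h^-1 and h.
    """
    series = np.asarray(series, dtype=float)
    if times is None:
        times = np.arange(len(series)) * sample_every
    s, _ = _post_transient(series, times, transient)
    n = len(s)
    if n < 16:
        raise ValueError("series too short for spectral analysis")
    s = (s - s.mean()) * np.hanning(n)
    power = np.abs(np.fft.rfft(s)) ** 2
    freqs = np.fft.rfftfreq(n, d=sample_every)
    power[0] = 0.0
    ipk = int(np.argmax(power[1:])) + 1
    med = float(np.median(power[1:]))
    if med <= 0 or power[ipk] < PEAK_SNR * med:
        return (math.nan, math.nan)
    # quadratic interpolation on log power around the peak bin
    f_p = freqs[ipk]
    if 1 <= ipk < len(power) - 1 and power[ipk - 1] > 0 and power[ipk + 1] > 0:
        lm, l0, lp = np.log(power[ipk - 1: ipk + 2])
        denom = lm - 2.0 * l0 + lp
        if denom < 0:
            shift = 0.5 * (lm - lp) / denom
            f_p = freqs[ipk] + shift * (freqs[1] - freqs[0])
    return (float(f_p), float(1.0 / f_p))


def summarize(traj: Trajectory, transient: float | None = None) -> OscillationSummary:
    """Amplitude + spectral period of a trajectory's ensemble D series."""
    transient = traj.control.transient if transient is None else transient
    amp = amplitude(traj.Dbar, traj.times, transient)
    f_p, tau = period_fft(traj.Dbar, traj.sample_every, transient, times=traj.times)
    return OscillationSummary(
        amplitude=amp, f_p=f_p, tau=tau, oscillating=amp > OSC_THRESHOLD
    )


def atpase_activity(params: ModelParams, control: SimControl) -> float:
    """ADP released per CI subunit per 24 h in the KaiA/KaiB-free condition.

    Counts Pi-release events over the post-transient window, divided by
    the 6*N CI subunits and the window length in days.  Requires
    A_T = B_T = 0, matching how hydrolysis turnover is assayed without
    the binding partners.
    """
    if params.A_T != 0 or params.B_T != 0:
        raise ValueError("ATPase activity is defined in the A_T = B_T = 0 condition")
    traj = simulate(params, control)
    keep = traj.times >= control.transient
    window = traj.times[keep][-1] - traj.times[keep][0]
    # releases[i] counts events in the interval ending at times[i]
    events = traj.releases[keep][1:].sum()
    return float(events / (6.0 * params.N) / (window / 24.0))


def _seed_list(seeds) -> list[int]:
    if isinstance(seeds, (int, np.integer)):
        return list(range(int(seeds)))
    return [int(s) for s in seeds]


def sweep_amplitude_period(
    params: ModelParams,
    axis: str,
    values,
    seeds,
    control: SimControl | None = None,
) -> SweepResult:
    """Amplitude and period as one parameter is varied, seed-averaged.

    ``seeds`` is either an iterable of seeds or an integer count.  Every
    other parameter stays at its value in ``params``.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    control = control or SimControl()
    seeds = _seed_list(seeds)
    rows = []
    for v in values:
        p = params.replace(**{axis: float(v)})
        for sd in seeds:
            traj = simulate(p, control.replace(seed=sd))
            summ = summarize(traj)
            rows.append({
                "axis": axis, "value": float(v), "seed": sd,
                "amplitude": summ.amplitude, "tau": summ.tau,
                "f_p": summ.f_p, "oscillating": summ.oscillating,
            })
    points = pd.DataFrame(rows)
    grp = points.groupby("value")
    summary = grp.agg(
        amplitude_mean=("amplitude", "mean"),
        amplitude_se=("amplitude", "sem"),
        tau_mean=("tau", "mean"),
        tau_se=("tau", "sem"),
        n_oscillating=("oscillating", "sum"),
    ).reset_index()
    return SweepResult(axis=axis, points=points, summary=summary)


def phase_diagram(
    params: ModelParams,
    AT_ratios,
    BT_ratios,
    seeds,
    control: SimControl | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Amplitude grid over the (A_T/C6T, B_T/C6T) plane.

    Returns the tidy grid (one row per point per seed) and a summary dict
    with the KaiA onset threshold: at the largest scanned B ratio, the
    smallest A ratio whose mean amplitude exceeds half the mean amplitude
    at (A_T/C6T = 2, B_T/C6T = 20) -- the reference oscillatory corner.
    """
    control = control or SimControl()
    seeds = _seed_list(seeds)
    rows = []
    for br in BT_ratios:
        for ar in AT_ratios:
            p = params.with_ratios(A_ratio=float(ar), B_ratio=float(br))
            for sd in seeds:
                traj = simulate(p, control.replace(seed=sd))
                amp = amplitude(traj.Dbar, traj.times, control.transient)
                rows.append({"A_ratio": float(ar), "B_ratio": float(br),
                             "seed": sd, "amplitude": amp})
    grid = pd.DataFrame(rows)
    summary = {"threshold_A_ratio": math.nan, "reference_amplitude": math.nan}
    br_ref = max(BT_ratios)
    sub = grid[grid.B_ratio == br_ref].groupby("A_ratio")["amplitude"].mean()
    # reference amplitude at the standard oscillatory condition (2, 20);
    # simulated separately when that corner is not part of the grid
    if 2.0 in sub.index and float(br_ref) == 20.0:
        ref = float(sub.loc[2.0])
    else:
        p_ref = params.with_ratios(A_ratio=2.0, B_ratio=20.0)
        ref = float(np.mean([
            amplitude(t.Dbar, t.times, control.transient)
            for t in (simulate(p_ref, control.replace(seed=sd)) for sd in seeds)
        ]))
    summary["reference_amplitude"] = ref
    above = sub[sub > 0.5 * ref]
    if len(above):
        summary["threshold_A_ratio"] = float(above.index.min())
    return grid, summary


def kaiA_threshold(
    params: ModelParams,
    AT_ratios,
    seeds,
    control: SimControl | None = None,
    BT_ratio: float = 20.0,
) -> tuple[float, pd.DataFrame]:
    """Onset threshold of the KaiA ratio at fixed B_T/C6T.

    Scans A_T/C6T, seed-averages the amplitude, and returns the smallest
    ratio whose amplitude exceeds half the amplitude at the largest
    scanned ratio (the fully oscillatory end), plus the scan table.
    """
    grid, _ = phase_diagram(params, AT_ratios, [BT_ratio], seeds, control)
    mean_amp = grid.groupby("A_ratio")["amplitude"].mean()
    ref = float(mean_amp.loc[max(AT_ratios)])
    above = mean_amp[mean_amp > 0.5 * ref]
    threshold = float(above.index.min()) if len(above) else math.nan
    return threshold, grid


def activity_frequency_slope(
    params: ModelParams,
    f0_values,
    seeds,
    control_osc: SimControl | None = None,
    control_act: SimControl | None = None,
) -> tuple[list[ActivityPoint], float]:
    """ATPase-activity vs rhythm-frequency correlation across f0.

    For each intrinsic hydrolysis frequency f0: the ATPase activity is
    measured with A_T = B_T = 0 (non-oscillatory assay condition) and the
    rhythm frequency f_p (converted to day^-1) in the oscillatory
    condition, seed-averaged.  Returns the points and the ordinary
    least-squares slope of f_p against activity, in day^-1 per
    (ADP per CI per day).  Non-oscillating points are dropped with a
    warning.
    """
    if len(f0_values) < 4:
        raise ValueError("need >= 4 f0 values spanning the oscillatory range")
    control_osc = control_osc or SimControl()
    control_act = control_act or SimControl(t_end=300.0, transient=50.0, dt=0.005)
    seeds = _seed_list(seeds)
    free_params_base = params.replace(A_T=0.0, B_T=0.0)
    points: list[ActivityPoint] = []
    for f0 in f0_values:
        act = atpase_activity(
            free_params_base.replace(f0=float(f0)), control_act
        )
        fps = []
        for sd in seeds:
            traj = simulate(params.replace(f0=float(f0)), control_osc.replace(seed=sd))
            summ = summarize(traj)
            if summ.oscillating and math.isfinite(summ.f_p):
                fps.append(summ.f_p_per_day)
        if not fps:
            logger.warning("f0 = %g gives no sustained rhythm; point dropped", f0)
            continue
        points.append(ActivityPoint(
            f0=float(f0), atpase_activity=act, f_p_day=float(np.mean(fps))
        ))
    if len(points) < 2:
        raise RuntimeError("fewer than two oscillating points; cannot fit a slope")
    x = np.array([p.atpase_activity for p in points])
    y = np.array([p.f_p_day for p in points])
    slope = float(np.polyfit(x, y, 1)[0])
    return points, slope
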