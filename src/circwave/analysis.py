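"""Derived haemodynamic quantities.

Covers the solver-comparison error metrics, systolic/diastolic indices,
foot-to-foot pulse wave velocity (the clinical carotid-femoral arterial
stiffness index) and wave intensity analysis (WIA).

WIA uses the time-derivative convention: with co-located pressure ``p`` and
velocity ``U`` and local wave speed ``c``,

    dP+- = (dp/dt -+... ) -> dI+ = (dp/dt + rho c dU/dt)^2 / (4 rho c)
           dI- = -(dp/dt - rho c dU/dt)^2 / (4 rho c),

so the net intensity dI = dI+ + dI- = (dp/dt)(dU/dt) carries units
W m^-2 s^-2.  A pure forward wave (dp = rho c dU) has dI- identically
zero; a pure backward wave has dI+ identically zero.  After the forward
compression wave (FCW) of early ejection, the first sustained negative
lobe is the backward compression wave (BCW), the primary reflected wave;
the end-systolic positive lobe is the forward expansion wave (FEW).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import MMHG

__all__ = [
    "SignalTrace",
    "BenchmarkReport",
    "WIAResult",
    "HaemodynamicIndices",
    "error_metrics",
    "detect_foot",
    "pulse_wave_velocity",
    "wave_intensity",
    "wia_features",
    "haemodynamic_indices",
]


@dataclass
class SignalTrace:
    """A uniformly sampled signal with units (one cardiac cycle, usually)."""

    samples: np.ndarray
    dt: float
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def in_mmhg(self) -> np.ndarray:
        return self.samples / MMHG

    def shifted(self, tau: float) -> "SignalTrace":
        """Circular shift by tau seconds (periodic signal)."""
        n = int(round(tau / self.dt))
        return SignalTrace(np.roll(self.samples, n), self.dt, self.units, self.label)


@dataclass
class BenchmarkReport:
    """Per-tube solver-agreement errors (RMS and relative)."""

    tubes: list[str]
    eps_p_mmhg: dict[str, float]
    eps_q_ml_s: dict[str, float]
    delta_p_pct: dict[str, float]
    delta_q_pct: dict[str, float]
    n_samples: int
    T: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            {t: [self.eps_p_mmhg[t], self.eps_q_ml_s[t],
                 self.delta_p_pct[t], self.delta_q_pct[t]] for t in self.tubes},
            index=["eps_p_mmHg", "eps_q_ml_s", "delta_p_pct", "delta_q_pct"])

    def max_delta_p(self) -> float:
        return max(self.delta_p_pct.values())

    def max_delta_q(self) -> float:
        return max(self.delta_q_pct.values())


@dataclass
class WIAResult:
    dI_plus: SignalTrace
    dI_minus: SignalTrace
    dI_net: SignalTrace


@dataclass
class HaemodynamicIndices:
    p_sys: float   # mmHg
    p_dia: float   # mmHg
    p_pulse: float  # mmHg
    pwv: float = float("nan")  # m/s


# ---------------------------------------------------------------------------

def error_metrics(trace_a: SignalTrace, trace_ref: SignalTrace,
                  kind: str = "pressure"):
    """RMS error and mean relative error between a trace and a reference.

    The two quantities use different normalizations: pressure errors are
    normalized pointwise by the reference sample, flow errors by the
    reference trace's maximum (pointwise normalization is meaningless where
    flow crosses zero).  Values returned in the trace's own units and %.
    """
    a = trace_a.samples
    r = trace_ref.samples
    if a.size != r.size or abs(trace_a.dt - trace_ref.dt) > 1e-12:
        raise ValueError("traces must share length and sampling")
    d = a - r
    eps = float(np.sqrt(np.mean(d * d)))
    if kind == "pressure":
        if np.any(r == 0.0):
            raise ValueError("pointwise relative pressure error undefined at zero reference")
        delta = float(np.mean(np.abs(d / r))) * 100.0
    elif kind == "flow":
        ref_max = float(np.max(r))
        if ref_max <= 0.0:
            raise ValueError("flow normalization needs a positive reference maximum")
        delta = float(np.mean(np.abs(d) / ref_max)) * 100.0
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return eps, delta


def detect_foot(p: SignalTrace, window: tuple[float, float] | None = None,
                smooth: int = 0) -> float:
    """Foot of the systolic upstroke: max of the 2nd time derivative.

    ``window`` restricts the search (seconds, on the trace's time axis);
    ``smooth`` applies a centred moving average of that many samples first
    (for noisy traces).  The signal is treated as periodic.
    """
    x = p.samples.astype(float)
    if np.ptp(x) < 1e-12:
        raise ValueError("flat trace: no upstroke to detect")
    if smooth > 1:
        kern = np.ones(smooth) / smooth
        n = x.size
        x = np.convolve(np.concatenate([x[-smooth:], x, x[:smooth]]), kern,
                        mode="same")[smooth:smooth + n]
    d2 = (np.roll(x, -1) - 2.0 * x + np.roll(x, 1)) / p.dt**2
    t = p.t
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if not np.any(mask):
            raise ValueError("empty search window")
        idx = np.flatnonzero(mask)[np.argmax(d2[mask])]
    else:
        # the foot sits between the onset of the systolic upstroke and the
        # point of steepest rise: walk back from the maximum upslope to
        # where the slope has decayed to 2% of its peak, then take the
        # maximum curvature inside that window (first sample on ties)
        d1 = (np.roll(x, -1) - np.roll(x, 1)) / (2.0 * p.dt)
        # the systolic upstroke is the first strong rise after the
        # diastolic minimum; a reflected secondary rise can be steeper
        # than the primary one, so a global slope maximum is not reliable
        i_min = int(np.argmin(x))
        strong = d1 >= 0.6 * d1.max()
        order = (np.arange(x.size) + i_min) % x.size
        i_start = int(order[np.argmax(strong[order])])
        # local slope maximum of that rise (walk forward while increasing)
        i_up = i_start
        while d1[(i_up + 1) % x.size] > d1[i_up]:
            i_up = (i_up + 1) % x.size
        thresh = 0.02 * d1[i_up]
        back_max = min(x.size - 2, int(round(0.3 / p.dt)))
        back = 1
        while back < back_max and d1[(i_up - back) % x.size] > thresh:
            back += 1
        back = min(back + int(round(0.02 / p.dt)), back_max)  # small margin
        cand = np.arange(i_up - back, i_up + 2) % x.size
        d2c = d2[cand]
        # earliest sample within numerical tolerance of the curvature peak
        # (a constant-curvature rise has its foot at the rise onset)
        idx = int(cand[np.argmax(d2c >= d2c.max() * (1.0 - 1e-6))])
    return float(t[idx])


def pulse_wave_velocity(p_prox: SignalTrace, p_dist: SignalTrace,
                        path_length_m: float,
                        window_prox=None, window_dist=None) -> float:
    """Foot-to-foot PWV = path length / pulse transit time [m/s]."""
    t0 = detect_foot(p_prox, window_prox)
    t1 = detect_foot(p_dist, window_dist)
    transit = t1 - t0
    if transit <= 0:
        # feet may wrap across the cycle boundary for periodic traces
        transit += p_prox.samples.size * p_prox.dt
    if transit <= 0:
        raise ValueError("non-positive pulse transit time")
    return path_length_m / transit


def _ddt(x: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference time derivative of a periodic signal."""
    return (np.roll(x, -1) - np.roll(x, 1)) / (2.0 * dt)


def wave_intensity(p: SignalTrace, U: SignalTrace, rho: float, c: float) -> WIAResult:
    """Forward/backward wave intensity decomposition [W m^-2 s^-2].

    ``p`` in Pa, ``U`` in m/s, ``c`` the local wave speed at the probe.
    """
    if p.samples.size != U.samples.size:
        raise ValueError("pressure and velocity traces must be co-located and synchronous")
    if c <= 0:
        raise ValueError("wave speed must be positive")
    dpdt = _ddt(p.samples, p.dt)
    dudt = _ddt(U.samples, U.dt)
    zc = rho * c
    fwd = dpdt + zc * dudt
    bwd = dpdt - zc * dudt
    dI_plus = fwd * fwd / (4.0 * zc)
    dI_minus = -bwd * bwd / (4.0 * zc)
    unit = "W m^-2 s^-2"
    return WIAResult(
        dI_plus=SignalTrace(dI_plus, p.dt, unit, "dI+"),
        dI_minus=SignalTrace(dI_minus, p.dt, unit, "dI-"),
        dI_net=SignalTrace(dI_plus + dI_minus, p.dt, unit, "dI"),
    )


def wia_features(res: WIAResult, ejection_onset: float,
                 onset_threshold: float = 0.01) -> dict:
    """BCW onset delay after ejection onset and FCW/BCW/FEW peak intensities.

    The BCW onset is the first sample after ejection onset where dI- falls
    below ``onset_threshold`` (default 1%) of the peak backward intensity.
    """
    dt = res.dI_net.dt
    t = res.dI_net.t
    dim = res.dI_minus.samples
    dip = res.dI_plus.samples
    after = t >= ejection_onset
    if not np.any(after):
        raise ValueError("ejection onset beyond trace")
    peak_b = float(np.max(-dim[after]))
    if peak_b <= 0:
        raise ValueError("no backward (negative) wave lobe found")
    idxs = np.flatnonzero(after)
    i_peak_bcw = int(idxs[np.argmax(-dim[idxs])])
    # BCW onset: the backward intensity between ejection and the BCW peak
    # first passes through a trough (residual diastolic backward content),
    # then rises into the reflected lobe.  The onset is the last sample
    # still within `onset_threshold` of that trough baseline.
    win = idxs[idxs <= i_peak_bcw]
    mags = -dim[win]
    baseline = float(np.min(mags))
    thr = baseline + onset_threshold * (peak_b - baseline)
    below = np.flatnonzero(mags <= thr)
    if below.size == 0:
        raise ValueError("no backward lobe crosses the onset threshold")
    onset_idx = int(win[below[-1]])
    bcw_onset = float(t[onset_idx])
    # FCW peak: forward intensity in early ejection (before BCW peak decay);
    # FEW: forward lobe in late systole (after the FCW has subsided).
    i_peak_b = i_peak_bcw
    i_fcw = int(np.flatnonzero(after)[np.argmax(dip[after])])
    peak_fcw = float(dip[i_fcw])
    # FEW: largest forward peak at least 100 ms after the FCW peak
    late = t >= t[i_fcw] + 0.1
    peak_few = float(np.max(dip[late])) if np.any(late) else float("nan")
    return {
        "bcw_delay_s": bcw_onset - ejection_onset,
        "peak_fcw": peak_fcw,
        "peak_bcw": float(-dim[i_peak_b]),
        "peak_few": peak_few,
        "t_fcw_peak": float(t[i_fcw]),
        "t_bcw_peak": float(t[i_peak_b]),
    }


def haemodynamic_indices(aortic_p: SignalTrace, pwv: float = float("nan")) -> HaemodynamicIndices:
    """Systolic/diastolic/pulse pressure (mmHg) of one converged cycle."""
    p = aortic_p.in_mmhg() if aortic_p.units == "Pa" else aortic_p.samples
    p_sys = float(np.max(p))
    p_dia = float(np.min(p))
    return HaemodynamicIndices(p_sys=p_sys, p_dia=p_dia,
                               p_pulse=p_sys - p_dia, pwv=pwv)
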