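"""Light-driven ion-pump classification from external-pH traces.

An outward proton pump expressed in *E. coli* acidifies the external medium
under illumination; adding the protonophore CCCP dissipates the proton
gradient and abolishes the light-induced pH change.  A construct is called
an outward H+ pump when its trace acidifies and the CCCP control retains
less than a configurable fraction (default 20%) of the pH change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PumpTrace", "PumpMetrics", "analyze_trace", "classify_pump"]

#: CCCP control must retain less than this fraction of the light-induced
#: pH change for the pump call ("almost eliminated" operationalised)
DEFAULT_CCCP_RATIO = 0.2

#: fraction of the light window used for the initial-rate slope
INITIAL_RATE_FRACTION = 0.2

#: pre-light baseline length in seconds
BASELINE_SECONDS = 10.0


@dataclass
class PumpTrace:
    """External pH vs time with an illumination window."""

    times: np.ndarray  # s
    ph: np.ndarray
    light_window: tuple[float, float]  # (on_s, off_s)
    cccp: bool = False
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.ph.shape:
            raise ValueError("times and ph must have equal length")
        on, off = self.light_window
        if not on < off:
            raise ValueError("light_window must satisfy on < off")


@dataclass
class PumpMetrics:
    delta_ph: float  # pH(light off) - pre-light baseline
    initial_rate: float  # pH/s over the first part of the window
    recovery: float  # post-light relaxation amplitude
    direction: str  # acidifying | alkalizing | none
    baseline: float
    baseline_sd: float
    label: str = ""


def _moving_median(y: np.ndarray, width: int) -> np.ndarray:
    from scipy.ndimage import median_filter

    return median_filter(y, size=width, mode="nearest")


def analyze_trace(trace: PumpTrace, smooth_width: int = 0) -> PumpMetrics:
    """Baseline-referenced pH-change metrics for one trace.

    Baseline is the mean pH over the final 10 s before light-on (or all
    available pre-light samples); ``delta_ph`` is the pH at light-off minus
    that baseline; the initial rate is the least-squares slope over the first
    20% of the window.  The direction is called only when ``|delta_ph|``
    exceeds three pre-light standard deviations.
    """
    t, ph = trace.times, trace.ph
    if smooth_width and smooth_width > 1:
        ph = _moving_median(ph, smooth_width)
    on, off = trace.light_window
    if on < t[0] or off > t[-1]:
        raise ValueError("light window lies outside the recorded trace")
    in_window = (t >= on) & (t <= off)
    if in_window.sum() < 5:
        raise ValueError("need at least 5 samples inside the light window")

    pre = (t < on) & (t >= on - BASELINE_SECONDS)
    if not pre.any():
        pre = t < on
    if not pre.any():
        raise ValueError("no pre-light samples for the baseline")
    baseline = float(ph[pre].mean())
    baseline_sd = float(ph[pre].std(ddof=0))

    ph_off = float(ph[t <= off][-1])
    delta_ph = ph_off - baseline

    early = in_window & (t <= on + INITIAL_RATE_FRACTION * (off - on))
    if early.sum() >= 2:
        slope = float(np.polyfit(t[early], ph[early], 1)[0])
    else:
        slope = float("nan")

    post = t > off
    recovery = float(ph[post][-1] - ph_off) if post.any() else 0.0

    threshold = 3.0 * baseline_sd
    if abs(delta_ph) <= threshold:
        direction = "none"
    elif delta_ph < 0:
        direction = "acidifying"
    else:
        direction = "alkalizing"
    return PumpMetrics(
        delta_ph=delta_ph,
        initial_rate=slope,
        recovery=recovery,
        direction=direction,
        baseline=baseline,
        baseline_sd=baseline_sd,
        label=trace.label,
    )


def classify_pump(
    test: PumpMetrics,
    cccp_control: PumpMetrics,
    ratio_threshold: float = DEFAULT_CCCP_RATIO,
) -> dict:
    """Call a construct an outward H+ pump, or not.

    Requires (i) an acidifying light response and (ii) a CCCP control whose
    pH change is below ``ratio_threshold`` of the test response — the
    protonophore dissipates a genuine proton gradient.
    """
    if test.delta_ph == 0.0:
        return {
            "call": "not_confirmed",
            "reason": "no light-induced pH change",
            "cccp_ratio": float("nan"),
        }
    ratio = abs(cccp_control.delta_ph) / abs(test.delta_ph)
    if test.direction == "acidifying" and ratio < ratio_threshold:
        return {"call": "outward_H_pump", "reason": "", "cccp_ratio": ratio}
    reason = (
        "pH change not acidifying"
        if test.direction != "acidifying"
        else f"CCCP retains {ratio:.0%} of the response"
    )
    return {"call": "not_confirmed", "reason": reason, "cccp_ratio": ratio}
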