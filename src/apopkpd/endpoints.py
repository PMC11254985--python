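"""Per-subject exposure and clinical-response endpoints.

Exposure endpoints (non-compartmental): AUC over 0-90 min (trapezoid,
ng*min/mL), Cmax (ng/mL), Tmax (min, earliest grid time attaining the max).

Response endpoints, from the UPDRS change-from-baseline profile and the
minimum clinically important change (MCIC, a positive number of points;
a subject responds while the change is at or below ``-mcic``):

* time to response — first down-crossing of ``-mcic`` (linear interpolation
  between grid points); ``None`` for non-responders;
* response duration — total time in [0, 90] min spent at or below ``-mcic``,
  crossings interpolated;
* AUEC 0-90 — positive trapezoidal integral of the score *improvement*
  (``-delta``), points*min;
* maximal change — minimum of the profile (<= 0) and its earliest time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import InvalidParameterError
from .profiles import InvalidProfileError, TimeProfile

EVALUATION_WINDOW_MIN = 90.0


@dataclass(frozen=True)
class EndpointRecord:
    """Exposure + response endpoints for one simulated subject."""

    subject_id: int
    auc_0_90: float
    cmax: float
    tmax: float
    time_to_response: Optional[float]
    response_duration: float
    auec_0_90: float
    max_change: float
    time_to_max_change: float
    responder_flag: bool


def _window(profile: TimeProfile, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    t, v = profile.times_min, profile.values
    if t[-1] < t_end - 1e-9:
        raise InvalidProfileError(f"profile must cover [0, {t_end}] min; ends at {t[-1]}")
    mask = t <= t_end + 1e-9
    return t[mask], v[mask]


def exposure_metrics(cp: TimeProfile, t_end: float = EVALUATION_WINDOW_MIN) -> tuple[float, float, float]:
    """Return (auc_0_90, cmax, tmax) from a plasma profile covering 90 min."""
    t, v = _window(cp, t_end)
    i = int(np.argmax(v))
    return float(np.trapezoid(v, t)), float(v[i]), float(t[i])


def ce_response_threshold(ec50: float, baseline_b0: float, emax: float, hill_g: float, mcic: float) -> float:
    """Effect-site concentration at which the change equals -mcic.

    Inverts the Hill function: ``EC50 * (mcic / (B0*Emax - mcic))^(1/g)``.
    A subject is a responder iff its peak Ce reaches this concentration.
    """
    if not 0 < mcic < baseline_b0 * emax:
        raise InvalidParameterError("mcic must lie in (0, B0*Emax)")
    return ec50 * (mcic / (baseline_b0 * emax - mcic)) ** (1.0 / hill_g)


def _crossings(t: np.ndarray, v: np.ndarray, level: float) -> tuple[Optional[float], float]:
    """First down-crossing time and total time with v <= level.

    Crossing times are linearly interpolated between grid points, so their
    precision exceeds the grid resolution.
    """
    below = v <= level
    if not below.any():
        return None, 0.0
    first: Optional[float] = None
    duration = 0.0
    entry: Optional[float] = None
    for i in range(t.size):
        if below[i] and entry is None:
            if i == 0 or v[i] == level:
                entry = t[i]
            else:  # interpolate the down-crossing within (t[i-1], t[i])
                frac = (level - v[i - 1]) / (v[i] - v[i - 1])
                entry = t[i - 1] + frac * (t[i] - t[i - 1])
            if first is None:
                first = entry
        elif not below[i] and entry is not None:
            frac = (level - v[i - 1]) / (v[i] - v[i - 1])
            duration += t[i - 1] + frac * (t[i] - t[i - 1]) - entry
            entry = None
    if entry is not None:
        duration += t[-1] - entry
    return first, duration


def response_metrics(
    delta_updrs: TimeProfile, mcic: float, t_end: float = EVALUATION_WINDOW_MIN
) -> tuple[Optional[float], float, float, float, float, bool]:
    """Return (time_to_response, response_duration, auec_0_90, max_change,
    time_to_max_change, responder_flag) from a change-from-baseline profile.
    """
    if not mcic > 0:
        raise InvalidParameterError(f"mcic must be strictly positive, got {mcic}")
    t, v = _window(delta_updrs, t_end)
    if np.any(v > 1e-9):
        raise InvalidProfileError("change-from-baseline profile must be <= 0")
    time_to_response, duration = _crossings(t, v, -mcic)
    i = int(np.argmin(v))
    auec = float(np.trapezoid(-v, t))
    return time_to_response, duration, auec, float(v[i]), float(t[i]), time_to_response is not None


def subject_endpoints(
    subject_id: int,
    cp: TimeProfile,
    delta_updrs: TimeProfile,
    mcic: float,
    t_end: float = EVALUATION_WINDOW_MIN,
) -> EndpointRecord:
    """Bundle exposure and response endpoints for one subject."""
    auc, cmax, tmax = exposure_metrics(cp, t_end)
    ttr, dur, auec, mx, tmx, resp = response_metrics(delta_updrs, mcic, t_end)
    return EndpointRecord(
        subject_id=subject_id,
        auc_0_90=auc,
        cmax=cmax,
        tmax=tmax,
        time_to_response=ttr,
        response_duration=dur,
        auec_0_90=auec,
        max_change=mx,
        time_to_max_change=tmx,
        responder_flag=resp,
    )


def endpoints_to_frame(records: list[EndpointRecord]) -> pd.DataFrame:
    """Per-subject endpoint table; missing time_to_response stays missing
    (NaN in memory, empty field in CSV), never zero."""
    frame = pd.DataFrame([vars(r) for r in records])
    frame["time_to_response"] = frame["time_to_response"].astype(float)
    return frame
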