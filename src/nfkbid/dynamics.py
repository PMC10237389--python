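"""Qualitative response regimes under tonic TNF stimulation.

Depending on the strength of the two negative feedbacks the model responds
to a sustained TNF step with damped oscillations settling on a stable
stimulated steady state, limit-cycle (sustained) oscillations — smooth or
relaxation-like "spiky" —, a single overshoot to an elevated plateau (no
oscillations, e.g. when the A20 feedback is removed, k2 = 0), or
near-perfect adaptation, where nuclear NF-κB returns close to its
pre-stimulus level despite the persisting input.

Classification is metric-based and auditable: NF-κB peaks are detected on a
dense trajectory, and the label follows from the late-window oscillation
amplitude (sustained vs converged), the duty cycle of elevated NF-κB
(spiky vs smooth), the number of peaks, and the adaptation index
(final NFκBn / first-peak NFκBn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .model import simulate, stimulated_fixed_point
from .parameters import ParameterSet
from .protocols import make_tonic

__all__ = ["PeakList", "RegimeLabel", "find_peaks", "classify_response",
           "REGIMES"]

REGIMES = ("no_oscillation", "damped_oscillations", "sustained_oscillations",
           "spiky_oscillations", "near_perfect_adaptation")

#: minimum peak prominence, as a fraction of the signal's global range
PROMINENCE_FRAC = 0.01
#: late-window amplitude below this fraction of the first-peak amplitude
#: counts as converged (damped)
DAMPED_FRAC = 0.01
#: adaptation index (final / first peak) below this is near-perfect adaptation
ADAPTATION_INDEX = 0.1
#: sustained oscillations are "spiky" (relaxation-like) when the late-window
#: NFκBn floor drops below this fraction of the total NF-κB pool: the orbit
#: then has a slow segment with NFκBn ≈ 0 and a fast spike away from it
SPIKY_FLOOR = 0.05


@dataclass(frozen=True)
class PeakList:
    """Local maxima of a trajectory, with sub-grid quadratic refinement."""

    times_h: np.ndarray
    values: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return self.times_h.size


def find_peaks(trajectory, column: str = "NFkBn") -> PeakList:
    """Detect local maxima of one trajectory column.

    Peaks must have prominence ≥ 1% of the signal's global range; peak times
    are refined by a quadratic fit through the three samples around each
    maximum and reported in hours.
    """
    if isinstance(trajectory, pd.DataFrame):
        t_min = trajectory["time_min"].to_numpy()
        x = trajectory[column].to_numpy()
    else:
        t_min, x = (np.asarray(a, dtype=float) for a in trajectory)
    if x.size < 2:
        raise ValueError("trajectory must have at least 2 samples")
    rng = float(x.max() - x.min())
    if rng == 0.0:
        return PeakList(np.empty(0), np.empty(0), np.empty(0))
    idx, props = _scipy_find_peaks(x, prominence=PROMINENCE_FRAC * rng)
    times, vals = [], []
    for i in idx:
        if 0 < i < x.size - 1:
            # vertex of the parabola through the three points around i
            y0, y1, y2 = x[i - 1], x[i], x[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -1.0, 1.0))
            dt = 0.5 * (t_min[i + 1] - t_min[i - 1])
            times.append(t_min[i] + shift * dt)
            vals.append(y1 - 0.25 * (y0 - y2) * shift)
        else:
            times.append(t_min[i])
            vals.append(x[i])
    return PeakList(np.asarray(times) / 60.0, np.asarray(vals),
                    props["prominences"])


@dataclass(frozen=True)
class RegimeLabel:
    """One regime label plus the metrics it was derived from."""

    label: str
    metrics: dict
    peaks: PeakList
    confident: bool = True


def classify_response(
    params: ParameterSet,
    horizon_hours: float = 48.0,
    onset_hours: float = 1.0,
    genotype: str = "WT",
    grid_step_min: float = 0.5,
) -> RegimeLabel:
    """Simulate tonic TNF from rest and classify the NF-κB response.

    TNF switches on at ``onset_hours`` (peak times are absolute simulation
    times, so the default onset of 1 h places the first response peak
    shortly after t = 1 h).
    """
    protocol = make_tonic(horizon_min=horizon_hours * 60.0,
                          onset_min=onset_hours * 60.0)
    traj = simulate(params, protocol.stimulus, genotype=genotype,
                    grid_step_min=grid_step_min)
    t = traj["time_min"].to_numpy()
    x = traj["NFkBn"].to_numpy()
    peaks = find_peaks(traj)

    late = t >= t[-1] - 0.25 * (t[-1] - t[0])
    late_amp = float(x[late].max() - x[late].min())
    first_peak = float(peaks.values[0]) if len(peaks) else float(x.max())
    final = float(x[-1])
    baseline = float(x[0])
    first_amp = first_peak - baseline
    adaptation = final / first_peak if first_peak > 0 else np.nan
    above = x[late] > ADAPTATION_INDEX * x.max()
    duty = float(np.mean(above))
    late_floor = float(x[late].min())
    fp = stimulated_fixed_point(params, genotype=genotype)

    metrics = {
        "n_peaks": len(peaks),
        "first_peak": first_peak,
        "final_NFkBn": final,
        "late_amplitude": late_amp,
        "late_amplitude_frac": late_amp / first_amp if first_amp > 0 else np.nan,
        "adaptation_index": adaptation,
        "late_duty_cycle": duty,
        "late_floor": late_floor,
        "fixed_point_stable": fp.stable,
        "fixed_point_NFkBn": float(fp.state[2]),
    }

    sustained = first_amp > 0 and late_amp >= DAMPED_FRAC * first_amp
    if sustained:
        label = "spiky_oscillations" if late_floor < SPIKY_FLOOR \
            else "sustained_oscillations"
    elif adaptation < ADAPTATION_INDEX and len(peaks) >= 1 \
            and first_amp > 0.1:
        label = "near_perfect_adaptation"
    elif len(peaks) >= 2:
        label = "damped_oscillations"
    else:
        label = "no_oscillation"

    # flag labels whose deciding metric sits within 25% of its threshold
    frac = metrics["late_amplitude_frac"]
    confident = True
    if np.isfinite(frac) and 0.75 * DAMPED_FRAC < frac < 1.25 * DAMPED_FRAC:
        confident = False
    if 0.75 * ADAPTATION_INDEX < adaptation < 1.25 * ADAPTATION_INDEX:
        confident = False
    if sustained and 0.75 * SPIKY_FLOOR < late_floor < 1.25 * SPIKY_FLOOR:
        confident = False
    return RegimeLabel(label=label, metrics=metrics, peaks=peaks,
                       confident=confident)
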