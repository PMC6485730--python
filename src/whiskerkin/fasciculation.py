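"""Spectral quantification of spontaneous whisker fasciculations.

Denervated whisker pad muscle produces small spontaneous oscillations of
the whiskers at roughly 5-8 Hz. This module computes a variance-normalized
periodogram of stimulus-free angle records, the mean power in a frequency
band (default 5-8 Hz), peak-to-peak amplitude, and day-by-day / treatment
summaries.

Normalization: the periodogram is scaled so that the sum of power over all
bins equals the variance of the linearly detrended signal (a Parseval
identity, asserted by the validation stage). Band power is the *mean* power
over the bins inside the closed band; this convention is tagged in the
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend as _detrend

from .traceio import AngleTrace, SessionSet, ValidationError
from .kinematics import fill_missing


@dataclass
class PowerSpectrum:
    """One-sided periodogram of an angle record.

    ``power`` is in deg^2 per bin; summing over all bins returns the
    variance of the detrended signal.
    """

    frequency_hz: np.ndarray
    power_deg2: np.ndarray
    record_length_s: float
    normalization: str = "bin-sum-equals-variance"
    detrend: str = "linear"

    @property
    def total_power(self) -> float:
        return float(self.power_deg2.sum())

    def dominant_frequency(self) -> float:
        """Frequency of the largest non-DC bin."""
        i = 1 + int(np.argmax(self.power_deg2[1:]))
        return float(self.frequency_hz[i])


@dataclass
class BandPowerResult:
    subject_id: str
    day: float
    band_lo_hz: float
    band_hi_hz: float
    mean_power_deg2: float
    n_trials: int


def power_spectrum(trace: AngleTrace, detrend: str = "linear") -> PowerSpectrum:
    """Periodogram of a stimulus-free record (>= 1 s)."""
    if trace.stim_duration_ms > 0:
        raise ValidationError(
            "fasciculation spectra require stimulus-free records "
            f"(trace has a {trace.stim_duration_ms}-ms stimulus)"
        )
    dt_s = trace.sample_period_ms / 1000.0
    n = trace.angle_deg.size
    length_s = n * dt_s
    if length_s < 1.0:
        raise ValidationError(f"record of {length_s:.3f} s is shorter than 1 s")
    y = fill_missing(trace)
    if detrend == "linear":
        y = _detrend(y, type="linear")
    elif detrend == "constant":
        y = y - y.mean()
    elif detrend != "none":
        raise ValidationError(f"unknown detrend method {detrend!r}")
    spec = np.fft.rfft(y)
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freq = np.fft.rfftfreq(n, dt_s)
    return PowerSpectrum(
        frequency_hz=freq,
        power_deg2=power,
        record_length_s=length_s,
        detrend=detrend,
    )


def band_power(spectrum: PowerSpectrum, lo_hz: float = 5.0, hi_hz: float = 8.0) -> float:
    """Mean power (deg^2) over the bins with lo <= f <= hi (inclusive)."""
    if lo_hz >= hi_hz:
        raise ValidationError("band_power requires lo < hi")
    sel = (spectrum.frequency_hz >= lo_hz) & (spectrum.frequency_hz <= hi_hz)
    if not sel.any():
        raise ValidationError(
            f"no frequency bins inside [{lo_hz}, {hi_hz}] Hz "
            f"(resolution {1.0 / spectrum.record_length_s:.3g} Hz)"
        )
    return float(spectrum.power_deg2[sel].mean())


def p2p_amplitude(trace: AngleTrace, robust: bool = False) -> float:
    """Peak-to-peak amplitude (deg): max - min, or the 99th - 1st percentile
    in robust mode (preferred on noisy records)."""
    y = fill_missing(trace)
    if robust:
        return float(np.percentile(y, 99) - np.percentile(y, 1))
    return float(np.max(y) - np.min(y))


def fasciculation_time_course(
    session: SessionSet,
    band: tuple[float, float] = (5.0, 8.0),
    conditions: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band power over days, averaged within and then between subjects.

    Uses only stimulus-free traces (``stim_duration_ms == 0``).
    ``conditions`` optionally labels each subject (e.g. vehicle vs.
    antagonist); every subject must then be labeled. Returns
    ``(per_subject, group)`` tables; the group table carries mean +/- SE per
    (condition, day).
    """
    lo, hi = band
    spont = [t for t in session.traces if t.stim_duration_ms == 0]
    if not spont:
        raise ValidationError("session contains no stimulus-free traces")
    rows = []
    for t in sorted(spont, key=lambda t: (t.subject_id, t.day, t.trial_index)):
        if conditions is not None and t.subject_id not in conditions:
            raise ValidationError(f"missing condition label for subject {t.subject_id}")
        rows.append({
            "subject": t.subject_id,
            "day": t.day,
            "condition": conditions[t.subject_id] if conditions else "all",
            "trial": t.trial_index,
            "band_power_deg2": band_power(power_spectrum(t), lo, hi),
            "p2p_deg": p2p_amplitude(t, robust=True),
        })
    per_trial = pd.DataFrame(rows)
    per_subject = (
        per_trial.groupby(["condition", "subject", "day"], as_index=False)
        .agg(mean_power_deg2=("band_power_deg2", "mean"),
             p2p_deg=("p2p_deg", "mean"),
             n_trials=("band_power_deg2", "size"))
    )
    per_subject["band_lo_hz"] = lo
    per_subject["band_hi_hz"] = hi
    grp_rows = []
    for (cond, day), g in per_subject.groupby(["condition", "day"]):
        vals = g["mean_power_deg2"].to_numpy(dtype=float)
        grp_rows.append({
            "condition": cond,
            "day": day,
            "mean_power_deg2": float(vals.mean()),
            "se_power_deg2": (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            ),
            "n_subjects": int(g["subject"].nunique()),
            "se_flagged_n1": vals.size == 1,
        })
    group = pd.DataFrame(grp_rows).sort_values(["condition", "day"]).reset_index(drop=True)
    return per_subject, group
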