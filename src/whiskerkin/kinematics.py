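"""Per-response kinematic metrics and duration-response analysis.

The five metrics of an evoked whisker response, measured relative to a
pre-stimulus baseline (mean angle over the 200 ms before onset):

* **peak amplitude** (deg) — maximum baseline-subtracted angle within the
  response window (onset to onset + 2000 ms);
* **peak velocity** (deg/s) — maximum of the first derivative after
  Savitzky-Golay smoothing of the trace;
* **time to peak** (ms) — time of the amplitude maximum after onset;
* **half-width** (ms) — full width at half maximum, with the two crossings
  flanking the peak located by linear interpolation (censored when the
  response has not decayed below half maximum by trace end);
* **persistence index** (unitless in [0, 1]) — for the long (1000 ms)
  stimulus only, the response amplitude at stimulus offset (mean over the
  final 10 ms of the stimulus) divided by peak amplitude. Higher values
  mean less fatigable responses.

Traces whose peak does not exceed ``noise_criterion_mult`` times the
baseline standard deviation are flagged as non-responses and get null time
metrics. Replicates are averaged within subject before metric extraction
(per-replicate metrics are retained for dispersion estimates), then
summarized across subjects.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .traceio import AngleTrace, Config, SessionSet, ValidationError

METRIC_COLUMNS = [
    "peak_amplitude_deg",
    "peak_velocity_deg_per_s",
    "time_to_peak_ms",
    "half_width_ms",
    "persistence_index",
]


class MissingDataError(ValidationError):
    """A trace has a run of missing frames too long to interpolate."""


@dataclass
class KinematicMetrics:
    """Metrics of one (possibly replicate-averaged) evoked response."""

    peak_amplitude_deg: float
    peak_velocity_deg_per_s: float | None
    time_to_peak_ms: float | None
    half_width_ms: float | None
    persistence_index: float | None
    baseline_deg: float
    no_response: bool = False
    half_width_censored: bool = False
    n_trials_averaged: int = 1

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ResponseDurationFamily:
    """Per-duration metric summaries for one subject and day.

    ``table`` has one row per protocol duration with the metric computed on
    the replicate-averaged trace plus the across-replicate SE and replicate
    count; durations absent from the data are flagged.
    """

    subject_id: str
    day: float
    table: pd.DataFrame

    def amplitude(self, duration_ms: float) -> float:
        row = self.table.loc[self.table["stim_duration_ms"] == duration_ms]
        if row.empty or bool(row["absent"].iloc[0]):
            raise KeyError(f"no data for duration {duration_ms} ms")
        return float(row["peak_amplitude_deg"].iloc[0])


@dataclass
class GroupSummary:
    """Across-subject summary: per-day mean +/- SE for each metric.

    SE is sd / sqrt(n) with sample sd; for n = 1 the SE is reported as 0
    and flagged. Per-subject values are retained for direction counts
    ("k/n subjects increased vs. baseline").
    """

    summary: pd.DataFrame
    per_subject: pd.DataFrame
    n_subjects: int
    se_undefined: bool = False


# ---------------------------------------------------------------------------
# trace-level helpers
# ---------------------------------------------------------------------------


def fill_missing(trace: AngleTrace, max_run: int = 5) -> np.ndarray:
    """Return the angle series with masked runs <= ``max_run`` interpolated.

    Longer runs mean the trial is unusable and raise MissingDataError.
    Edge runs are extended from the nearest valid sample.
    """
    if not trace.mask.any():
        return trace.angle_deg.copy()
    mask = trace.mask
    # locate runs of consecutive masked samples
    idx = np.flatnonzero(mask)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    longest = max(len(run) for run in splits)
    if longest > max_run:
        raise MissingDataError(
            f"masked run of {longest} samples exceeds the {max_run}-sample limit"
        )
    valid = np.flatnonzero(~mask)
    if valid.size == 0:
        raise MissingDataError("trace is fully masked")
    out = trace.angle_deg.copy()
    out[mask] = np.interp(np.flatnonzero(mask), valid, trace.angle_deg[valid])
    return out


def baseline_angle(trace: AngleTrace, pre_window_ms: float = 200.0) -> float:
    """Mean angle over [onset - window, onset), ignoring masked samples."""
    return _baseline_stats(trace, pre_window_ms)[0]


def _baseline_stats(trace: AngleTrace, pre_window_ms: float) -> tuple[float, float]:
    t = trace.times_ms
    sel = (t >= trace.stim_onset_ms - pre_window_ms) & (t < trace.stim_onset_ms)
    sel &= ~trace.mask
    if not sel.any():
        raise ValidationError("no usable samples in the pre-stimulus baseline window")
    vals = trace.angle_deg[sel]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd


def smooth_and_differentiate(
    trace: AngleTrace, window_samples: int = 11, polyorder: int = 3
) -> np.ndarray:
    """Velocity series (deg/s): Savitzky-Golay smoothing, then the sample
    derivative (central differences; one-sided at the edges)."""
    if window_samples % 2 == 0 or window_samples < polyorder + 2:
        raise ValidationError("window must be odd and >= polyorder + 2")
    y = fill_missing(trace)
    if y.size <= window_samples:
        raise ValidationError(
            f"trace length {y.size} must exceed smoothing window {window_samples}"
        )
    smoothed = savgol_filter(y, window_samples, polyorder, mode="interp")
    return np.gradient(smoothed, trace.sample_period_ms) * 1000.0


def average_traces(traces: list[AngleTrace]) -> AngleTrace:
    """Pointwise mean of replicate traces, ignoring masked samples."""
    if not traces:
        raise ValidationError("cannot average an empty trace group")
    first = traces[0]
    for t in traces[1:]:
        if (
            t.angle_deg.size != first.angle_deg.size
            or t.sample_period_ms != first.sample_period_ms
            or t.stim_onset_ms != first.stim_onset_ms
            or t.stim_duration_ms != first.stim_duration_ms
        ):
            raise ValidationError("traces to average must share shape, period and stimulus")
    stack = np.ma.masked_array(
        np.stack([np.where(t.mask, 0.0, t.angle_deg) for t in traces]),
        mask=np.stack([t.mask for t in traces]),
    )
    mean = stack.mean(axis=0)
    return AngleTrace(
        subject_id=first.subject_id,
        day=first.day,
        trial_index=-1,
        stim_duration_ms=first.stim_duration_ms,
        stim_onset_ms=first.stim_onset_ms,
        angle_deg=np.where(mean.mask, np.nan, mean.data) if np.ma.is_masked(mean) else np.asarray(mean),
        sample_period_ms=first.sample_period_ms,
    )


# ---------------------------------------------------------------------------
# metric extraction
# ---------------------------------------------------------------------------


def _half_crossings(
    t: np.ndarray, rel: np.ndarray, i_peak: int, level: float
) -> tuple[float | None, float | None]:
    """Interpolated times where ``rel`` crosses ``level`` flanking the peak."""
    up = None
    for i in range(i_peak, 0, -1):
        if rel[i - 1] < level <= rel[i]:
            frac = (level - rel[i - 1]) / (rel[i] - rel[i - 1])
            up = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    down = None
    for i in range(i_peak, rel.size - 1):
        if rel[i] >= level > rel[i + 1]:
            frac = (rel[i] - level) / (rel[i] - rel[i + 1])
            down = t[i] + frac * (t[i + 1] - t[i])
            break
    return up, down


def extract_metrics(
    trace: AngleTrace, config: Config | None = None, n_trials_averaged: int = 1
) -> KinematicMetrics:
    """Extract the five kinematic metrics from one trace.

    The trace may be a single trial or a replicate average. With
    ``config.response_sign = -1`` the same extractor measures retractions
    (negative-going responses).
    """
    cfg = config or Config()
    y = fill_missing(trace, cfg.max_missing_run) * cfg.response_sign
    signed = dataclasses.replace(trace, angle_deg=y, mask=np.zeros_like(trace.mask))
    base, base_sd = _baseline_stats(signed, cfg.baseline_window_ms)
    t = trace.times_ms
    onset = trace.stim_onset_ms
    win = (t >= onset) & (t <= onset + cfg.response_window_ms)
    rel = y - base
    i_win = np.flatnonzero(win)
    i_peak = i_win[int(np.argmax(rel[win]))]
    peak = float(rel[i_peak])
    if peak < 0:
        peak = 0.0
    no_response = peak <= cfg.noise_criterion_mult * base_sd
    vel = smooth_and_differentiate(signed, cfg.sg_window, cfg.sg_polyorder)
    peak_velocity = float(np.max(vel[win]))
    if no_response:
        return KinematicMetrics(
            peak_amplitude_deg=peak,
            peak_velocity_deg_per_s=None,
            time_to_peak_ms=None,
            half_width_ms=None,
            persistence_index=None,
            baseline_deg=base * cfg.response_sign,
            no_response=True,
            n_trials_averaged=n_trials_averaged,
        )
    time_to_peak = float(t[i_peak] - onset)
    up, down = _half_crossings(t, rel, i_peak, peak / 2.0)
    censored = down is None or up is None
    half_width = None if censored else float(down - up)
    persistence = None
    if trace.stim_duration_ms == cfg.long_stim_ms and peak > 0:
        offset = onset + trace.stim_duration_ms
        tail = (t > offset - cfg.persistence_tail_ms) & (t <= offset)
        if tail.any():
            persistence = float(np.clip(np.mean(rel[tail]) / peak, 0.0, 1.0))
    return KinematicMetrics(
        peak_amplitude_deg=peak,
        peak_velocity_deg_per_s=peak_velocity,
        time_to_peak_ms=time_to_peak,
        half_width_ms=half_width,
        persistence_index=persistence,
        baseline_deg=base * cfg.response_sign,
        no_response=False,
        half_width_censored=censored,
        n_trials_averaged=n_trials_averaged,
    )


# ---------------------------------------------------------------------------
# families and summaries
# ---------------------------------------------------------------------------


def duration_family(
    traces: list[AngleTrace],
    config: Config | None = None,
    durations_ms: list[float] | None = None,
) -> ResponseDurationFamily:
    """Build the duration-response family for one subject and day.

    Replicates of each duration are averaged before metric extraction;
    the across-replicate SE of each metric is reported alongside. A
    protocol duration with no trials is flagged absent.
    """
    cfg = config or Config()
    if not traces:
        raise ValidationError("duration_family needs at least one trace")
    subject = traces[0].subject_id
    day = traces[0].day
    by_dur: dict[float, list[AngleTrace]] = {}
    for tr in traces:
        if tr.subject_id != subject or tr.day != day:
            raise ValidationError("duration_family expects one subject/day")
        if tr.stim_duration_ms > 0:
            by_dur.setdefault(tr.stim_duration_ms, []).append(tr)
    wanted = sorted(durations_ms) if durations_ms else sorted(by_dur)
    rows = []
    for dur in wanted:
        group = by_dur.get(dur, [])
        if not group:
            rows.append({"stim_duration_ms": dur, "absent": True, "n_replicates": 0})
            continue
        avg_metrics = extract_metrics(average_traces(group), cfg, len(group))
        row: dict = {"stim_duration_ms": dur, "absent": False, "n_replicates": len(group)}
        row.update({k: avg_metrics.as_dict()[k] for k in METRIC_COLUMNS})
        row["no_response"] = avg_metrics.no_response
        per_rep = [extract_metrics(tr, cfg, 1) for tr in group]
        for col in METRIC_COLUMNS:
            vals = np.array(
                [m.as_dict()[col] for m in per_rep if m.as_dict()[col] is not None],
                dtype=float,
            )
            row[col + "_se"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            )
        rows.append(row)
    return ResponseDurationFamily(subject_id=subject, day=day, table=pd.DataFrame(rows))


def sensitivity_threshold(
    family: ResponseDurationFamily, criterion_deg: float = 1.0
) -> float | None:
    """Smallest protocol duration whose mean peak amplitude reaches the
    criterion; None when censored (no duration qualifies)."""
    tab = family.table
    if (~tab["absent"]).sum() < 2:
        raise ValidationError("sensitivity threshold needs >= 2 durations")
    for _, row in tab.sort_values("stim_duration_ms").iterrows():
        if row["absent"]:
            continue
        if row["peak_amplitude_deg"] >= criterion_deg:
            return float(row["stim_duration_ms"])
    return None


def percent_of_baseline(post_value: float, baseline_value: float) -> float:
    """Post/baseline ratio as a percentage, to 3 significant figures."""
    if baseline_value <= 0:
        raise ValidationError("baseline value must be > 0")
    return float(f"{100.0 * post_value / baseline_value:.3g}")


def subject_metrics_table(
    session: SessionSet, config: Config | None = None
) -> pd.DataFrame:
    """Per (subject, day, duration) metrics on replicate-averaged traces."""
    cfg = config or Config()
    rows = []
    for (subject, day, dur), group in session.groups().items():
        if dur <= 0:
            continue
        m = extract_metrics(average_traces(group), cfg, len(group))
        row = {"subject": subject, "day": day, "stim_duration_ms": dur,
               "n_replicates": len(group), "no_response": m.no_response,
               "baseline_deg": m.baseline_deg}
        row.update({k: m.as_dict()[k] for k in METRIC_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(per_subject: pd.DataFrame, baseline_day: float | None = None) -> GroupSummary:
    """Across-subject mean +/- SE per day for each metric.

    ``per_subject`` needs columns ``subject``, ``day`` and metric columns.
    When ``baseline_day`` is given, direction counts ("k/n subjects above
    their own baseline") are added per day and metric.
    """
    metrics = [c for c in METRIC_COLUMNS if c in per_subject.columns]
    if per_subject.empty:
        raise ValidationError("group_summary needs at least one subject")
    n = per_subject["subject"].nunique()
    se_undefined = n == 1
    if se_undefined:
        warnings.warn("SE undefined for a single subject; reported as 0", stacklevel=2)
    rows = []
    for day, g in per_subject.groupby("day"):
        row: dict = {"day": day, "n_subjects": g["subject"].nunique()}
        for col in metrics:
            vals = g[col].dropna().to_numpy(dtype=float)
            row[col + "_mean"] = float(np.mean(vals)) if vals.size else np.nan
            row[col + "_se"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            )
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
    if baseline_day is not None:
        base = per_subject[per_subject["day"] == baseline_day].set_index("subject")
        counts = []
        for day, g in per_subject.groupby("day"):
            row = {"day": day}
            for col in metrics:
                joined = g.set_index("subject")[col].dropna()
                common = joined.index.intersection(base.index)
                k = int((joined.loc[common] > base.loc[common, col]).sum())
                row[col + "_increased"] = f"{k}/{len(common)}"
            counts.append(row)
        summary = summary.merge(pd.DataFrame(counts), on="day")
    return GroupSummary(
        summary=summary, per_subject=per_subject.copy(), n_subjects=n,
        se_undefined=se_undefined,
    )
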