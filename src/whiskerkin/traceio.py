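"""Readers, writers, validation and configuration for on-disk formats.

Two table formats are supported:

* **traces CSV** — long format, one row per video frame:
  ``subject,day,trial,stim_duration_ms,stim_onset_ms,time_ms,angle_deg``
  (UTF-8, '.' decimal, times in ms from trial start, angle in degrees with
  protraction positive). Missing frames are empty/NaN angle cells and are
  carried through as masked samples.
* **DE TSV** — one row per transcript:
  ``transcript_id, gene_id, log2_fc, qval_wt[_day<k>]..., lrt_flag,
  tpm_<tissue>_<day>_<arm>...``

Configuration is a flat YAML key/value file; :func:`load_config` fills
defaults, warns on unknown keys and rejects type mismatches.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("whiskerkin")

TRACE_COLUMNS = [
    "subject",
    "day",
    "trial",
    "stim_duration_ms",
    "stim_onset_ms",
    "time_ms",
    "angle_deg",
]

DE_REQUIRED_COLUMNS = ["transcript_id", "gene_id", "log2_fc", "lrt_flag"]


class SchemaError(ValueError):
    """An input table does not have the documented columns."""


class ValidationError(ValueError):
    """An input table has the right shape but inconsistent content."""


class ConfigError(ValueError):
    """A configuration value has the wrong type or an invalid combination."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class AngleTrace:
    """One trial's whisker angle time series with stimulus annotation.

    ``day`` is days relative to the lesion (negative = prelesion); it is a
    real number so that sub-day timepoints (e.g. +6 h = 0.25) fit. Angle is
    in degrees, protraction positive. ``mask`` marks missing frames
    (True = missing); masked values are NaN in ``angle_deg``.
    """

    subject_id: str
    day: float
    trial_index: int
    stim_duration_ms: float
    stim_onset_ms: float
    angle_deg: np.ndarray
    sample_period_ms: float = 2.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if self.angle_deg.ndim != 1 or self.angle_deg.size < 2:
            raise ValidationError("angle sequence must be 1-D with length >= 2")
        if self.sample_period_ms <= 0:
            raise ValidationError("sample_period_ms must be positive")
        if self.stim_duration_ms < 0:
            raise ValidationError("stim_duration_ms must be >= 0")
        if self.mask is None:
            self.mask = np.isnan(self.angle_deg)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.angle_deg.shape:
                raise ValidationError("mask shape must match angle shape")
        span = (self.angle_deg.size - 1) * self.sample_period_ms
        if not (0 <= self.stim_onset_ms <= span):
            raise ValidationError(
                f"stim_onset_ms={self.stim_onset_ms} outside recorded span [0, {span}]"
            )
        valid = self.angle_deg[~self.mask]
        if not np.all(np.isfinite(valid)):
            raise ValidationError("non-masked samples must be finite")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.angle_deg.size) * self.sample_period_ms

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def duration_ms(self) -> float:
        return (self.angle_deg.size - 1) * self.sample_period_ms

    def key(self) -> tuple:
        return (self.subject_id, self.day, self.stim_duration_ms)


@dataclass
class SessionSet:
    """Collection of traces grouped by (subject, day, stimulus duration).

    ``protocol`` records the stimulus protocol: duration list, replicates
    per duration and trial length. Spontaneous (stimulus-free) traces carry
    ``stim_duration_ms == 0`` and are excluded from the protocol duration
    list.
    """

    traces: list[AngleTrace]
    protocol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, group in self.groups().items():
            if not group:
                raise ValidationError(f"empty trace group {key}")
            n = {t.angle_deg.size for t in group}
            dt = {t.sample_period_ms for t in group}
            if len(n) > 1 or len(dt) > 1:
                raise ValidationError(
                    f"traces in group {key} differ in length or sample period"
                )

    def groups(self) -> dict[tuple, list[AngleTrace]]:
        out: dict[tuple, list[AngleTrace]] = {}
        for t in sorted(self.traces, key=lambda t: (t.subject_id, t.day, t.stim_duration_ms, t.trial_index)):
            out.setdefault(t.key(), []).append(t)
        return out

    def subjects(self) -> list[str]:
        return sorted({t.subject_id for t in self.traces})

    def days(self) -> list[float]:
        return sorted({t.day for t in self.traces})

    def select(self, subject=None, day=None, stim_duration_ms=None) -> list[AngleTrace]:
        out = []
        for t in sorted(self.traces, key=lambda t: (t.subject_id, t.day, t.stim_duration_ms, t.trial_index)):
            if subject is not None and t.subject_id != subject:
                continue
            if day is not None and t.day != day:
                continue
            if stim_duration_ms is not None and t.stim_duration_ms != stim_duration_ms:
                continue
            out.append(t)
        return out

    def __len__(self) -> int:
        return len(self.traces)


@dataclass
class DETable:
    """Transcript-level differential-expression results for one tissue.

    Wraps a DataFrame with unique ``transcript_id``, a signed ``log2_fc``
    (injured vs. control), per-day Wald q-values (``qval_wt`` or
    ``qval_wt_day<k>``), an LRT significance flag and >= 1 normalized TPM
    column named ``tpm_<tissue>_<day>_<arm>``.
    """

    frame: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in DE_REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"DE table missing column(s): {', '.join(missing)}")
        if not self.qval_columns():
            raise SchemaError("DE table needs a qval_wt or qval_wt_day<k> column")
        if not self.tpm_columns():
            raise SchemaError("DE table needs at least one tpm_* column")
        dup = df["transcript_id"][df["transcript_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                "duplicate transcript ids: " + ", ".join(sorted(set(dup.astype(str))))
            )
        for col in self.qval_columns():
            q = df[col].to_numpy(dtype=float)
            if np.any((q < 0) | (q > 1) | ~np.isfinite(q)):
                raise ValidationError(f"{col} values must lie in [0, 1]")
        for col in self.tpm_columns():
            v = df[col].to_numpy(dtype=float)
            if np.any(v < 0):
                raise ValidationError(f"{col} values must be >= 0")
        self.frame = df.reset_index(drop=True)

    def qval_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c == "qval_wt" or c.startswith("qval_wt_day")]

    def tpm_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("tpm_")]

    def qval_column(self, day) -> str:
        """Column holding the Wald q-values for ``day``."""
        named = f"qval_wt_day{day:g}" if isinstance(day, float) else f"qval_wt_day{day}"
        if named in self.frame.columns:
            return named
        if "qval_wt" in self.frame.columns:
            return "qval_wt"
        raise ValidationError(f"no Wald q-value column for day {day} in table {self.name!r}")

    def indexed(self) -> pd.DataFrame:
        return self.frame.set_index("transcript_id")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# traces CSV
# ---------------------------------------------------------------------------


def read_traces(path, schema: Mapping[str, str] | None = None) -> SessionSet:
    """Read a long-format trace CSV into a validated :class:`SessionSet`.

    ``schema`` may rename columns (maps canonical name -> file column).
    Rows are ordered deterministically by (subject, day, duration, trial,
    time) regardless of file order; NaN angle cells become masked samples.
    """
    path = Path(path)
    df = pd.read_csv(path)
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"traces CSV missing column: {col}")
    df = df.sort_values(
        ["subject", "day", "stim_duration_ms", "trial", "time_ms"], kind="mergesort"
    )
    traces: list[AngleTrace] = []
    n_masked = 0
    for (subject, day, dur, trial), g in df.groupby(
        ["subject", "day", "stim_duration_ms", "trial"], sort=True
    ):
        t = g["time_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"non-monotonic time within trial (subject={subject}, day={day}, "
                f"duration={dur}, trial={trial})"
            )
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValidationError(
                f"mixed sample periods within trial (subject={subject}, day={day}, "
                f"duration={dur}, trial={trial})"
            )
        onset = g["stim_onset_ms"].to_numpy(dtype=float)
        if not np.allclose(onset, onset[0]):
            raise ValidationError("stim_onset_ms must be constant within a trial")
        angle = g["angle_deg"].to_numpy(dtype=float)
        tr = AngleTrace(
            subject_id=str(subject),
            day=float(day),
            trial_index=int(trial),
            stim_duration_ms=float(dur),
            stim_onset_ms=float(onset[0]),
            angle_deg=angle,
            sample_period_ms=float(dts[0]),
        )
        n_masked += tr.n_missing
        traces.append(tr)
    protocol = _infer_protocol(traces)
    logger.info(
        "read_traces: %d traces, %d masked samples from %s", len(traces), n_masked, path
    )
    return SessionSet(traces=traces, protocol=protocol)


def _infer_protocol(traces: Sequence[AngleTrace]) -> dict:
    durations = sorted({t.stim_duration_ms for t in traces if t.stim_duration_ms > 0})
    counts = {}
    for t in traces:
        if t.stim_duration_ms > 0:
            counts[t.key()] = counts.get(t.key(), 0) + 1
    return {
        "durations_ms": durations,
        "replicates": max(counts.values()) if counts else 0,
        "trial_length_ms": max(t.duration_ms for t in traces),
    }


def write_traces(session: SessionSet, path) -> None:
    """Write a SessionSet back to the canonical long CSV dialect.

    Floats use 6 significant digits so that a read/write round trip is
    byte-stable.
    """
    rows = []
    for t in sorted(
        session.traces,
        key=lambda t: (t.subject_id, t.day, t.stim_duration_ms, t.trial_index),
    ):
        times = t.times_ms
        for i in range(t.angle_deg.size):
            rows.append(
                (
                    t.subject_id,
                    t.day,
                    t.trial_index,
                    t.stim_duration_ms,
                    t.stim_onset_ms,
                    times[i],
                    np.nan if t.mask[i] else t.angle_deg[i],
                )
            )
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# DE TSV
# ---------------------------------------------------------------------------


def read_de_table(path, name: str | None = None) -> DETable:
    """Read a transcript-level DE TSV into a validated :class:`DETable`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    table = DETable(frame=df, name=name or path.stem)
    logger.info("read_de_table: %d transcripts from %s", len(table), path)
    return table


def write_de_table(table: DETable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Analysis parameters with documented defaults.

    Smoothing: Savitzky–Golay window of 11 samples (22 ms at 500 frames/s),
    polynomial order 3. Baseline: mean over the 200 ms before stimulus
    onset. Response search window: 2000 ms from onset. Persistence index is
    computed for the long (1000 ms) stimulus from the mean over the final
    10 ms of the stimulus. Fasciculation band: 5–8 Hz. DE filter: Wald
    q <= 0.05, |log2 FC| >= 1 (fold change 2), LRT membership required.
    """

    sg_window: int = 11
    sg_polyorder: int = 3
    baseline_window_ms: float = 200.0
    response_window_ms: float = 2000.0
    long_stim_ms: float = 1000.0
    persistence_tail_ms: float = 10.0
    noise_criterion_mult: float = 3.0
    sensitivity_criterion_deg: float = 1.0
    max_missing_run: int = 5
    band_lo_hz: float = 5.0
    band_hi_hz: float = 8.0
    fc_min: float = 2.0
    alpha: float = 0.05
    require_lrt: bool = True
    response_sign: int = 1  # +1 protraction analysis, -1 retraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window < self.sg_polyorder + 2:
            raise ConfigError(
                "sg_window must be odd and >= sg_polyorder + 2 "
                f"(got window={self.sg_window}, polyorder={self.sg_polyorder})"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.fc_min < 1:
            raise ConfigError("fc_min must be >= 1")
        if self.band_lo_hz >= self.band_hi_hz:
            raise ConfigError("band_lo_hz must be < band_hi_hz")


def load_config(path=None) -> Config:
    """Load a YAML key/value config; fill defaults, warn on unknown keys."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must be a flat key/value mapping")
        data = loaded
    if "band" in data:  # convenience: band: [lo, hi]
        lo, hi = data.pop("band")
        data["band_lo_hz"], data["band_hi_hz"] = float(lo), float(hi)
    fields = {f.name: f for f in dataclasses.fields(Config)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            warnings.warn(f"unknown config key ignored: {key}", stacklevel=2)
            continue
        ftype = str(fields[key].type)
        is_bool = isinstance(value, bool)
        if ftype == "int" and (is_bool or not isinstance(value, (int, np.integer))):
            raise ConfigError(f"config key {key!r} must be an integer, got {value!r}")
        if ftype == "float" and (is_bool or not isinstance(value, (int, float, np.floating))):
            raise ConfigError(f"config key {key!r} must be a number, got {value!r}")
        if ftype == "bool" and not is_bool:
            raise ConfigError(f"config key {key!r} must be a boolean, got {value!r}")
        kwargs[key] = value
    cfg = Config(**kwargs)
    logger.info("config: %s", {f.name: getattr(cfg, f.name) for f in dataclasses.fields(Config)})
    return cfg


def config_dict(cfg: Config) -> dict:
    return dataclasses.asdict(cfg)
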