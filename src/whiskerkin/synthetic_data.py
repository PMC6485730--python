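"""Synthetic whisker-angle sessions and DE tables with planted truth.

The evoked-twitch waveform is a phenomenological model with independently
controllable phenotype axes:

* stimulus sensitivity — Hill-saturating amplitude
  ``A(d) = A_max * d^h / (d^h + d50^h)`` of the stimulus duration ``d``;
* rise speed / peak velocity — exponential rise with time constant
  ``tau_rise`` (initial slope, hence peak velocity, is ``A / tau_rise``);
* fatigability — multiplicative adaptation
  ``p + (1 - p) * exp(-u / tau_fatigue)`` decaying to the plateau fraction
  ``p`` (the true persistence level) while the stimulus is on;
* offset — exponential decay with ``tau_decay`` after stimulus end.

The drive is the stimulus shifted by ``latency``: with ``u`` the time since
onset + latency, the noise-free response is

``r(u) = A(d) * (1 - exp(-u/tau_rise)) * (p + (1-p) exp(-u/tau_fatigue))``
for ``0 <= u <= d``, then ``r(d) * exp(-(u-d)/tau_decay)``.

Spontaneous fasciculations are either a pure tone (exact peak-to-peak) or
narrowband Gaussian noise band-limited to 5-8 Hz. Calibrated primitives
(``target_peak_deg`` rescaling, a Gaussian bump with exact FWHM) let tests
set a metric's ground truth directly.

Everything is deterministic given seeds; per-trace seeds are derived from a
master seed with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .traceio import AngleTrace, DETable, SessionSet, ValidationError

DEFAULT_DURATIONS_MS = (1.0, 3.0, 5.0, 10.0, 20.0, 50.0, 100.0, 1000.0)
_DENSE_DT_MS = 0.1


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class TwitchParams:
    """Generative parameters of one evoked-twitch condition."""

    a_max_deg: float = 10.0
    d50_ms: float = 10.0
    hill: float = 2.0
    tau_rise_ms: float = 20.0
    tau_fatigue_ms: float = 400.0
    tau_decay_ms: float = 100.0
    plateau_fraction: float = 1.0
    latency_ms: float = 10.0
    noise_sd_deg: float = 0.0
    target_peak_deg: float | None = None

    def __post_init__(self) -> None:
        for name in ("tau_rise_ms", "tau_fatigue_ms", "tau_decay_ms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 <= self.plateau_fraction <= 1:
            raise ValidationError("plateau_fraction must lie in [0, 1]")
        if self.a_max_deg < 0 or self.hill <= 0 or self.d50_ms <= 0:
            raise ValidationError("a_max_deg >= 0, hill > 0, d50_ms > 0 required")
        if self.noise_sd_deg < 0 or self.latency_ms < 0:
            raise ValidationError("noise_sd_deg and latency_ms must be >= 0")


@dataclass
class FasciculationParams:
    """Generative parameters of spontaneous fasciculation oscillations."""

    f0_hz: float = 6.5
    p2p_deg: float = 2.45
    mode: str = "pure-tone"  # or "narrowband"
    band_hz: tuple[float, float] = (5.0, 8.0)
    phase_jitter_sd: float = 0.0  # rad / sqrt(s)
    noise_sd_deg: float = 0.0
    duration_s: float = 3.0
    sample_period_ms: float = 2.0

    def __post_init__(self) -> None:
        nyquist = 500.0 / self.sample_period_ms
        if not 0 < self.f0_hz < nyquist:
            raise ValidationError(f"f0_hz must lie in (0, {nyquist}) Hz")
        if self.p2p_deg < 0:
            raise ValidationError("p2p_deg must be >= 0")
        if self.mode not in ("pure-tone", "narrowband"):
            raise ValidationError(f"unknown fasciculation mode {self.mode!r}")


@dataclass
class CohortSpec:
    """A longitudinal cohort: subjects x days x durations x replicates.

    ``day_twitch`` maps each day to the group-mean twitch parameters;
    ``day_fasc`` (optional) adds stimulus-free fasciculation trials.
    Between-subject variability: log-normal with coefficient of variation
    ``cv`` on the amplitude parameter, truncated-normal (at a small positive
    floor) on time constants and latency, truncated-normal within [0, 1]
    with ``cv_plateau`` on the plateau fraction.
    """

    n_subjects: int = 9
    days: Sequence[float] = (-1.0,)
    day_twitch: Mapping[float, TwitchParams] = field(default_factory=dict)
    day_fasc: Mapping[float, FasciculationParams] | None = None
    durations_ms: Sequence[float] = DEFAULT_DURATIONS_MS
    replicates: int = 8
    cv: float = 0.3
    cv_plateau: float | None = None  # defaults to 0.1, or 0 when cv == 0
    fasc_trials: int = 3
    trial_length_ms: float = 3000.0
    stim_onset_ms: float = 500.0
    sample_period_ms: float = 2.0
    subject_prefix: str = "m"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if any(d <= 0 for d in self.durations_ms):
            raise ValidationError("stimulus durations must be positive")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.cv_plateau is None:
            self.cv_plateau = 0.0 if self.cv == 0 else 0.1
        for day in self.days:
            if day not in self.day_twitch:
                raise ValidationError(f"day_twitch missing parameters for day {day}")


@dataclass
class DESimSpec:
    """Planted two-tissue DE tables.

    Planted overlap structure: ``n_sig_a``/``n_sig_b`` truly regulated
    transcripts per tissue with ``n_common`` shared ids (shared transcripts
    get concordant signs). If the explicit counts are None they are derived
    from ``fraction_de``. True DE transcripts get Wald q-values well below
    ``alpha`` and an LRT flag; null transcripts get uniform q-values,
    N(0, ``null_log2fc_sd``) fold changes and an ``alpha``-rate LRT flag, so
    false positives through the full filter chain are bounded by ``alpha``.
    """

    n_transcripts: int = 3000
    fraction_de: float = 0.1
    n_sig_a: int | None = None
    n_sig_b: int | None = None
    n_common: int | None = None
    log2fc_shape: float = 2.0  # gamma shape of |log2FC| - 1 for true DE
    log2fc_scale: float = 0.4
    null_log2fc_sd: float = 0.3
    tpm_log_mean: float = 3.0
    tpm_log_sd: float = 1.2
    alpha: float = 0.05
    days_a: Sequence[int] = (1, 3, 7)
    days_b: Sequence[int] = (3,)
    tissue_a: str = "w"
    tissue_b: str = "s"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValidationError("n_transcripts must be >= 1")
        if not 0 <= self.fraction_de <= 1:
            raise ValidationError("fraction_de must lie in [0, 1]")
        n_de = int(round(self.fraction_de * self.n_transcripts))
        if self.n_sig_a is None:
            self.n_sig_a = n_de
        if self.n_sig_b is None:
            self.n_sig_b = n_de
        if self.n_common is None:
            self.n_common = min(self.n_sig_a, self.n_sig_b) // 2
        if self.n_common > min(self.n_sig_a, self.n_sig_b):
            raise ValidationError(
                f"infeasible overlap: n_common={self.n_common} exceeds "
                f"min(n_sig_a, n_sig_b)={min(self.n_sig_a, self.n_sig_b)}"
            )
        if self.n_sig_a + self.n_sig_b - self.n_common > self.n_transcripts:
            raise ValidationError("planted union exceeds n_transcripts")


# ---------------------------------------------------------------------------
# twitch generator
# ---------------------------------------------------------------------------


def _hill_amplitude(params: TwitchParams, stim_duration_ms: float) -> float:
    d, d50, h = stim_duration_ms, params.d50_ms, params.hill
    if d <= 0:
        return 0.0
    return params.a_max_deg * d**h / (d**h + d50**h)


def _envelope(u: np.ndarray, d: float, params: TwitchParams) -> np.ndarray:
    """Unit-amplitude waveform as a function of u = time since onset+latency."""
    p = params.plateau_fraction
    tr, tf, td = params.tau_rise_ms, params.tau_fatigue_ms, params.tau_decay_ms
    r = np.zeros_like(u, dtype=float)
    on = (u >= 0) & (u <= d)
    r[on] = (1.0 - np.exp(-u[on] / tr)) * (p + (1.0 - p) * np.exp(-u[on] / tf))
    after = u > d
    r_end = (1.0 - np.exp(-d / tr)) * (p + (1.0 - p) * np.exp(-d / tf))
    r[after] = r_end * np.exp(-(u[after] - d) / td)
    return r


def twitch_waveform(
    params: TwitchParams, stim_duration_ms: float, t_since_onset_ms: np.ndarray
) -> np.ndarray:
    """Noise-free evoked response evaluated at times relative to stimulus onset."""
    u = np.asarray(t_since_onset_ms, dtype=float) - params.latency_ms
    y = _hill_amplitude(params, stim_duration_ms) * _envelope(u, stim_duration_ms, params)
    if params.target_peak_deg is not None:
        peak, _ = dense_peak(params, stim_duration_ms)
        if peak > 0:
            y = y * (params.target_peak_deg / peak)
    return y


def dense_peak(params: TwitchParams, stim_duration_ms: float) -> tuple[float, float]:
    """Noise-free maximum and its time since onset, on a 0.1-ms grid."""
    horizon = params.latency_ms + stim_duration_ms + 8 * params.tau_decay_ms
    t = np.arange(0.0, horizon + _DENSE_DT_MS, _DENSE_DT_MS)
    u = t - params.latency_ms
    y = _hill_amplitude(params, stim_duration_ms) * _envelope(u, stim_duration_ms, params)
    i = int(np.argmax(y))
    return float(y[i]), float(t[i])


def calibrate_latency_for_time_to_peak(
    params: TwitchParams, stim_duration_ms: float, target_time_to_peak_ms: float
) -> TwitchParams:
    """Adjust latency so the dense-grid peak falls at the target time.

    The peak time is latency + (shape-determined interior peak), so the
    calibration is a single exact shift.
    """
    _, tpk = dense_peak(params, stim_duration_ms)
    shape_peak = tpk - params.latency_ms
    new_latency = target_time_to_peak_ms - shape_peak
    if new_latency < 0:
        raise ValidationError(
            f"target time-to-peak {target_time_to_peak_ms} ms unreachable: waveform "
            f"peaks {shape_peak:.2f} ms after drive onset"
        )
    return dataclasses.replace(params, latency_ms=new_latency)


def simulate_twitch(
    params: TwitchParams,
    stim_duration_ms: float,
    stim_onset_ms: float = 500.0,
    trial_length_ms: float = 3000.0,
    sample_period_ms: float = 2.0,
    seed: int | np.random.SeedSequence | None = 0,
    subject_id: str = "sim",
    day: float = 0.0,
    trial_index: int = 0,
) -> AngleTrace:
    """Simulate one evoked-response trial as an :class:`AngleTrace`."""
    if stim_duration_ms < 0:
        raise ValidationError("stimulus duration must be >= 0")
    if stim_onset_ms + stim_duration_ms > trial_length_ms:
        raise ValidationError("stimulus extends past the end of the trial")
    n = int(round(trial_length_ms / sample_period_ms))
    t = np.arange(n) * sample_period_ms
    y = twitch_waveform(params, stim_duration_ms, t - stim_onset_ms)
    if params.noise_sd_deg > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sd_deg, size=n)
    return AngleTrace(
        subject_id=subject_id,
        day=day,
        trial_index=trial_index,
        stim_duration_ms=stim_duration_ms,
        stim_onset_ms=stim_onset_ms,
        angle_deg=y,
        sample_period_ms=sample_period_ms,
    )


def gaussian_bump(
    peak_deg: float,
    fwhm_ms: float,
    stim_onset_ms: float = 500.0,
    time_to_peak_ms: float | None = None,
    trial_length_ms: float = 3000.0,
    sample_period_ms: float = 2.0,
    noise_sd_deg: float = 0.0,
    seed: int | None = 0,
    subject_id: str = "sim",
    day: float = 0.0,
    trial_index: int = 0,
    stim_duration_ms: float = 1000.0,
) -> AngleTrace:
    """Calibrated primitive: Gaussian transient with exact analytic FWHM.

    ``angle(t) = peak * exp(-4 ln2 (t - t_peak)^2 / fwhm^2)`` with the peak
    placed ``time_to_peak_ms`` after onset (default 2 FWHM, far enough that
    the pre-stimulus baseline window sees a negligible tail).
    """
    if fwhm_ms <= 0:
        raise ValidationError("fwhm_ms must be > 0")
    if time_to_peak_ms is None:
        time_to_peak_ms = 2.0 * fwhm_ms
    n = int(round(trial_length_ms / sample_period_ms))
    t = np.arange(n) * sample_period_ms
    center = stim_onset_ms + time_to_peak_ms
    y = peak_deg * np.exp(-4.0 * np.log(2.0) * (t - center) ** 2 / fwhm_ms**2)
    if noise_sd_deg > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd_deg, size=n)
    return AngleTrace(
        subject_id=subject_id,
        day=day,
        trial_index=trial_index,
        stim_duration_ms=stim_duration_ms,
        stim_onset_ms=stim_onset_ms,
        angle_deg=y,
        sample_period_ms=sample_period_ms,
    )


def gaussian_peak_velocity(peak_deg: float, fwhm_ms: float) -> float:
    """Analytic maximum |derivative| (deg/s) of the Gaussian-bump primitive:
    ``peak * sqrt(2k) * exp(-1/2)`` with ``k = 4 ln2 / fwhm^2`` per ms."""
    k = 4.0 * np.log(2.0) / fwhm_ms**2
    return peak_deg * np.sqrt(2.0 * k) * np.exp(-0.5) * 1000.0


# ---------------------------------------------------------------------------
# fasciculation generator
# ---------------------------------------------------------------------------


def simulate_fasciculation(
    params: FasciculationParams,
    seed: int | np.random.SeedSequence | None = 0,
    subject_id: str = "sim",
    day: float = 0.0,
    trial_index: int = 0,
) -> AngleTrace:
    """Simulate a stimulus-free fasciculation record (stim_duration_ms = 0).

    Pure-tone mode yields ``(p2p/2) sin(2 pi f0 t + phi)`` (exact
    peak-to-peak on the continuous waveform); narrowband mode band-limits
    white Gaussian noise to ``band_hz`` via FFT masking and rescales so the
    1st-99th percentile range equals ``p2p_deg``.
    """
    dt_s = params.sample_period_ms / 1000.0
    n = int(round(params.duration_s / dt_s))
    t = np.arange(n) * dt_s
    rng = np.random.default_rng(seed)
    if params.p2p_deg == 0:
        x = np.zeros(n)
    elif params.mode == "pure-tone":
        phase = 2.0 * np.pi * params.f0_hz * t
        if params.phase_jitter_sd > 0:
            steps = rng.normal(0.0, params.phase_jitter_sd * np.sqrt(dt_s), size=n)
            phase = phase + np.cumsum(steps)
        x = (params.p2p_deg / 2.0) * np.sin(phase)
    else:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freq = np.fft.rfftfreq(n, dt_s)
        lo, hi = params.band_hz
        spec[(freq < lo) | (freq > hi)] = 0.0
        x = np.fft.irfft(spec, n)
        span = np.percentile(x, 99) - np.percentile(x, 1)
        if span > 0:
            x = x * (params.p2p_deg / span)
    if params.noise_sd_deg > 0:
        x = x + rng.normal(0.0, params.noise_sd_deg, size=n)
    return AngleTrace(
        subject_id=subject_id,
        day=day,
        trial_index=trial_index,
        stim_duration_ms=0.0,
        stim_onset_ms=0.0,
        angle_deg=x,
        sample_period_ms=params.sample_period_ms,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


def _subject_factors(spec: CohortSpec, rng: np.random.Generator) -> dict:
    """Per-subject multiplicative deviations from the day means."""
    if spec.cv <= 0:
        amp, tr, tf, td, lat = 1.0, 1.0, 1.0, 1.0, 1.0
    else:
        sigma = np.sqrt(np.log(1.0 + spec.cv**2))
        amp = float(rng.lognormal(-0.5 * sigma**2, sigma))  # mean 1
        def trunc_normal() -> float:
            for _ in range(100):
                v = rng.normal(1.0, spec.cv)
                if v > 0.05:
                    return float(v)
            return 0.05
        tr, tf, td, lat = (trunc_normal() for _ in range(4))
    if spec.cv_plateau <= 0:
        plateau = 1.0
    else:
        for _ in range(100):
            plateau = float(rng.normal(1.0, spec.cv_plateau))
            if plateau > 0:
                break
        else:
            plateau = 1.0
    return {"amp": amp, "tau_rise": tr, "tau_fatigue": tf, "tau_decay": td,
            "latency": lat, "plateau": plateau}


def _apply_factors(params: TwitchParams, f: dict) -> TwitchParams:
    return dataclasses.replace(
        params,
        a_max_deg=params.a_max_deg * f["amp"],
        target_peak_deg=(None if params.target_peak_deg is None
                         else params.target_peak_deg * f["amp"]),
        tau_rise_ms=params.tau_rise_ms * f["tau_rise"],
        tau_fatigue_ms=params.tau_fatigue_ms * f["tau_fatigue"],
        tau_decay_ms=params.tau_decay_ms * f["tau_decay"],
        latency_ms=params.latency_ms * f["latency"],
        plateau_fraction=min(1.0, params.plateau_fraction * f["plateau"]),
    )


def simulate_session(spec: CohortSpec) -> SessionSet:
    """Simulate a full cohort; reproducible for a fixed master seed."""
    traces: list[AngleTrace] = []
    root = np.random.SeedSequence(spec.seed)
    subject_ss = root.spawn(spec.n_subjects)
    for si in range(spec.n_subjects):
        subject = f"{spec.subject_prefix}{si + 1:02d}"
        factors = _subject_factors(spec, np.random.default_rng(subject_ss[si]))
        for di, day in enumerate(spec.days):
            params = _apply_factors(spec.day_twitch[day], factors)
            for ui, dur in enumerate(spec.durations_ms):
                for rep in range(spec.replicates):
                    trace_seed = np.random.SeedSequence(
                        entropy=spec.seed, spawn_key=(1, si, di, ui, rep)
                    )
                    traces.append(
                        simulate_twitch(
                            params,
                            stim_duration_ms=dur,
                            stim_onset_ms=spec.stim_onset_ms,
                            trial_length_ms=spec.trial_length_ms,
                            sample_period_ms=spec.sample_period_ms,
                            seed=trace_seed,
                            subject_id=subject,
                            day=day,
                            trial_index=rep,
                        )
                    )
            if spec.day_fasc is not None and day in spec.day_fasc:
                fp = spec.day_fasc[day]
                fp = dataclasses.replace(fp, p2p_deg=fp.p2p_deg * factors["amp"])
                for rep in range(spec.fasc_trials):
                    trace_seed = np.random.SeedSequence(
                        entropy=spec.seed, spawn_key=(2, si, di, rep)
                    )
                    traces.append(
                        simulate_fasciculation(
                            fp, seed=trace_seed, subject_id=subject, day=day,
                            trial_index=rep,
                        )
                    )
    protocol = {
        "durations_ms": list(spec.durations_ms),
        "replicates": spec.replicates,
        "trial_length_ms": spec.trial_length_ms,
    }
    return SessionSet(traces=traces, protocol=protocol)


# ---------------------------------------------------------------------------
# DE table generator
# ---------------------------------------------------------------------------


def simulate_de_tables(spec: DESimSpec) -> tuple[DETable, DETable, dict]:
    """Generate two tissue DE tables with planted overlap structure.

    Returns ``(table_a, table_b, truth)`` where ``truth`` records the
    planted significant sets, the common set and the planted signs.
    """
    rng = np.random.default_rng(spec.seed)
    ids = np.array([f"ENSMUST{i:08d}" for i in range(spec.n_transcripts)])
    genes = np.array([f"gene{i:05d}" for i in range(spec.n_transcripts)])
    order = rng.permutation(spec.n_transcripts)
    common_idx = order[: spec.n_common]
    a_only_idx = order[spec.n_common : spec.n_sig_a]
    b_only_idx = order[spec.n_sig_a : spec.n_sig_a + (spec.n_sig_b - spec.n_common)]
    set_a = np.concatenate([common_idx, a_only_idx]).astype(int)
    set_b = np.concatenate([common_idx, b_only_idx]).astype(int)

    signs = rng.choice([-1.0, 1.0], size=spec.n_transcripts)

    def build(tissue: str, days: Sequence[int], de_idx: np.ndarray) -> pd.DataFrame:
        n = spec.n_transcripts
        is_de = np.zeros(n, dtype=bool)
        is_de[de_idx] = True
        lfc = rng.normal(0.0, spec.null_log2fc_sd, size=n)
        mag = 1.0 + rng.gamma(spec.log2fc_shape, spec.log2fc_scale, size=n)
        lfc[is_de] = signs[is_de] * mag[is_de]
        lrt = rng.random(n) < spec.alpha
        lrt[is_de] = True
        df = pd.DataFrame({
            "transcript_id": ids,
            "gene_id": genes,
            "log2_fc": lfc,
            "lrt_flag": lrt,
        })
        for day in days:
            q = rng.uniform(0.0, 1.0, size=n)
            q[is_de] = 10.0 ** rng.uniform(-6.0, np.log10(spec.alpha / 2.0), size=is_de.sum())
            df[f"qval_wt_day{day}"] = q
        base = rng.lognormal(spec.tpm_log_mean, spec.tpm_log_sd, size=n)
        ramp = {d: min(1.0, 0.4 + 0.2 * d) for d in days}  # expression grows over days
        for day in days:
            df[f"tpm_{tissue}_{day}_sham"] = base * rng.lognormal(0.0, 0.1, size=n)
            df[f"tpm_{tissue}_{day}_injured"] = (
                base * 2.0 ** (lfc * ramp[day]) * rng.lognormal(0.0, 0.1, size=n)
            )
        return df

    table_a = DETable(build(spec.tissue_a, spec.days_a, set_a), name=spec.tissue_a)
    table_b = DETable(build(spec.tissue_b, spec.days_b, set_b), name=spec.tissue_b)
    truth = {
        "sig_a": set(ids[set_a]),
        "sig_b": set(ids[set_b]),
        "common": set(ids[common_idx.astype(int)]),
        "signs": {ids[i]: float(signs[i]) for i in np.union1d(set_a, set_b)},
    }
    return table_a, table_b, truth
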