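"""Synthetic hybrid EEG/NIRS recordings with task structure.

Emulates a three-session mental-task experiment: per session 30 cued trials
(10 each of mental arithmetic MA, word chain WC, and relaxed baseline BL),
each trial being a 2-s instruction, a 5-s task period, and a 13-15 s rest.
The generator reproduces the statistical structure the downstream analysis
assumes:

* EEG -- band-limited theta/alpha/beta oscillations with fixed spatial
  patterns over 10 frontal channels on a pink-noise background. During task
  windows the oscillation envelopes are attenuated (event-related
  desynchronization, ERD) or amplified (ERS) by class-dependent fractions.
* EOG -- blink/saccade pulse trains on two bipolar channels, leaking into
  frontal EEG channels with configurable propagation coefficients.
* NIRS -- 9 prefrontal channels; per task trial an HbO increase shaped as a
  canonical double-gamma haemodynamic response convolved with the 5-s task
  boxcar, with HbR a delayed, scaled negative copy; Mayer-wave (0.1 Hz),
  respiratory (0.3 Hz) and cardiac (1.1 Hz) sinusoids, slow drift, and white
  noise on top. Optionally emitted as dual-wavelength optical density via the
  forward Beer-Lambert model so the inversion can be exercised end to end.

Everything is driven by a single integer seed; identical configuration gives
bit-identical output. Per-session streams use seed + session_id so sessions
are reproducible yet independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

CLASSES = ("MA", "WC", "BL")

#: Filter-bank passbands (Hz) shared with the feature stage.
EEG_BANDS: Dict[str, Tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

EEG_CHANNELS = (
    "AFp1", "AFp2", "AFF1h", "AFF2h", "AFF5h", "AFF6h", "F3", "F4", "F7", "F8",
)
EOG_CHANNELS = ("VEOG", "HEOG")
NIRS_CHANNELS = tuple(f"CH{i}" for i in range(1, 10))


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class Trial:
    label: str
    instruction_onset_s: float
    task_onset_s: float
    task_len_s: float
    rest_len_s: float


@dataclass(frozen=True)
class ParadigmSchedule:
    """Labelled trial timing for one session."""

    session_id: int
    pre_rest_s: float
    post_rest_s: float
    trials: Tuple[Trial, ...]

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials])

    @property
    def task_onsets_s(self) -> np.ndarray:
        return np.array([t.task_onset_s for t in self.trials])

    @property
    def duration_s(self) -> float:
        last = self.trials[-1]
        return last.task_onset_s + last.task_len_s + last.rest_len_s + self.post_rest_s

    def class_counts(self) -> Dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass(frozen=True)
class ContinuousRecording:
    """One modality's channels x samples stream with event markers."""

    modality: str  # EEG | EOG | NIRS-OD | NIRS-Hb
    fs: float
    channel_labels: Tuple[str, ...]
    data: np.ndarray  # channels x samples
    units: str
    markers: Tuple[Tuple[int, str], ...]  # (sample_index, label)

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be channels x samples matching channel_labels")


def _default_erd_depth() -> Dict[str, Dict[str, float]]:
    # Fractional amplitude reduction of the band oscillation during the task.
    return {
        "MA": {"alpha": 0.50, "beta": 0.30},
        "WC": {"alpha": 0.45, "beta": 0.40},
        "BL": {},
    }


def _default_ers_gain() -> Dict[str, Dict[str, float]]:
    return {"MA": {"theta": 0.40}, "WC": {}, "BL": {}}


def _default_hrf_amp() -> Dict[str, np.ndarray]:
    # Peak HbO amplitude per NIRS channel, mol/L. WC is left-lateralised.
    ma = np.full(9, 1.0e-6)
    wc = np.array([1.2, 1.2, 1.1, 1.0, 0.9, 0.7, 0.6, 0.5, 0.5]) * 1.0e-6
    return {"MA": ma, "WC": wc, "BL": np.zeros(9)}


def _default_noise() -> Dict[str, float]:
    return {
        "pink_eeg_uv": 16.0,      # broadband pink background std per channel
        "mayer_molar": 8.0e-7,    # 0.1 Hz systemic oscillation
        "respiration_molar": 2.0e-7,  # 0.3 Hz
        "cardiac_molar": 1.0e-7,  # 1.1 Hz
        "white_nirs_molar": 3.0e-6,
        "drift_molar": 1.0e-6,    # very slow (<0.01 Hz) baseline wander
    }


def _default_osc_amp() -> Dict[str, float]:
    return {"theta": 1.5, "alpha": 2.0, "beta": 1.25}  # uV pattern scale


def _default_eog_propagation() -> Dict[str, float]:
    return {
        "AFp1": 0.15, "AFp2": 0.15,
        "AFF1h": 0.08, "AFF2h": 0.08, "AFF5h": 0.08, "AFF6h": 0.08,
        "F3": 0.04, "F4": 0.04, "F7": 0.04, "F8": 0.04,
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults encode the experimental paradigm (3 sessions x 30 trials, 2-s
    instruction, 5-s task, 13-15 s rest) and effect sizes chosen so that
    unimodal decoding accuracies fall in the 75-85% range typical of
    frontal mental-task BCIs.
    """

    seed: int = 0
    n_sessions: int = 3
    n_trials_per_class: int = 10
    classes: Tuple[str, ...] = CLASSES
    fs_eeg: float = 200.0
    fs_nirs: float = 12.5
    pre_rest_s: float = 60.0
    post_rest_s: float = 60.0
    instruction_s: float = 2.0
    task_s: float = 5.0
    rest_range_s: Tuple[float, float] = (13.0, 15.0)
    erd_depth: Dict[str, Dict[str, float]] = field(default_factory=_default_erd_depth)
    ers_gain: Dict[str, Dict[str, float]] = field(default_factory=_default_ers_gain)
    osc_amp_uv: Dict[str, float] = field(default_factory=_default_osc_amp)
    hrf_amp: Dict[str, np.ndarray] = field(default_factory=_default_hrf_amp)
    hbr_ratio: float = 0.3
    hbr_delay_s: float = 0.5
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    noise: Dict[str, float] = field(default_factory=_default_noise)
    eog_rate_hz: float = 0.1
    eog_amp_uv: float = 100.0
    eog_propagation: Dict[str, float] = field(default_factory=_default_eog_propagation)
    session_drift: float = 0.35
    trial_jitter: float = 0.5
    ramp_s: float = 0.5
    emit_optical_density: bool = False

    def validate(self) -> None:
        if self.n_sessions < 1 or self.n_trials_per_class < 1:
            raise ConfigurationError("need at least one session and one trial per class")
        if not (0 < self.fs_nirs and 0 < self.fs_eeg):
            raise ConfigurationError("sampling rates must be positive")
        for cls, bands in self.erd_depth.items():
            for band, frac in bands.items():
                if not 0.0 <= frac <= 1.0:
                    raise ConfigurationError(
                        f"erd_depth[{cls}][{band}]={frac} outside [0, 1]")
        for cls, bands in self.ers_gain.items():
            for band, frac in bands.items():
                if frac < 0.0:
                    raise ConfigurationError(f"ers_gain[{cls}][{band}]={frac} negative")
        if not 0.0 <= self.hbr_ratio <= 1.0:
            raise ConfigurationError("hbr_ratio must lie in [0, 1]")
        if not self.rest_range_s[0] <= self.rest_range_s[1]:
            raise ConfigurationError("rest_range_s must be ordered")

    def scaled_effects(self, erd_scale: float = 1.0, hrf_scale: float = 1.0) -> "SimConfig":
        """Copy of the config with all class effects multiplied by scalars."""
        erd = {c: {b: min(1.0, v * erd_scale) for b, v in bands.items()}
               for c, bands in self.erd_depth.items()}
        ers = {c: {b: v * erd_scale for b, v in bands.items()}
               for c, bands in self.ers_gain.items()}
        hrf = {c: np.asarray(a, float) * hrf_scale for c, a in self.hrf_amp.items()}
        return replace(self, erd_depth=erd, ers_gain=ers, hrf_amp=hrf)

    def null_effects(self) -> "SimConfig":
        """Copy with every class effect zeroed (no signal, noise only)."""
        return self.scaled_effects(0.0, 0.0)


@dataclass
class Session:
    """One session's schedule plus simulated recordings."""

    session_id: int
    schedule: ParadigmSchedule
    recordings: Dict[str, ContinuousRecording]  # keys: eeg, eog, nirs


# ---------------------------------------------------------------------------
# schedule


def make_schedule(config: SimConfig, session_id: int) -> ParadigmSchedule:
    """Seeded random task order with paradigm timing for one session."""
    config.validate()
    if session_id < 0 or session_id >= config.n_sessions:
        raise ConfigurationError(f"session_id {session_id} outside 0..{config.n_sessions - 1}")
    rng = np.random.default_rng(config.seed + session_id)
    labels = np.repeat(np.array(config.classes), config.n_trials_per_class)
    rng.shuffle(labels)
    rests = rng.uniform(*config.rest_range_s, size=labels.size)

    trials: List[Trial] = []
    t = config.pre_rest_s
    for label, rest in zip(labels, rests):
        trials.append(Trial(
            label=str(label),
            instruction_onset_s=t,
            task_onset_s=t + config.instruction_s,
            task_len_s=config.task_s,
            rest_len_s=float(rest),
        ))
        t += config.instruction_s + config.task_s + rest
    return ParadigmSchedule(
        session_id=session_id,
        pre_rest_s=config.pre_rest_s,
        post_rest_s=config.post_rest_s,
        trials=tuple(trials),
    )


# ---------------------------------------------------------------------------
# haemodynamic response


def double_gamma_hrf(
    t: np.ndarray | float,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma impulse response, unit peak amplitude.

    Difference of two gamma densities with modes at ``peak_s`` and
    ``undershoot_s`` (unit scale), renormalised so the maximum over a dense
    grid equals 1. Causal: value at t = 0 is exactly 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("double_gamma_hrf is causal; t must be >= 0")

    def raw(x: np.ndarray) -> np.ndarray:
        pos = spstats.gamma.pdf(x, a=peak_s + 1.0, scale=1.0)
        neg = spstats.gamma.pdf(x, a=undershoot_s + 1.0, scale=1.0)
        return pos - undershoot_ratio * neg

    from scipy.optimize import minimize_scalar

    grid = np.linspace(0.0, peak_s + 4.0 * undershoot_s, 4096)
    t_coarse = grid[np.argmax(raw(grid))]
    res = minimize_scalar(lambda x: -raw(np.asarray(x)),
                          bounds=(max(0.0, t_coarse - 1.0), t_coarse + 1.0),
                          method="bounded", options={"xatol": 1e-10})
    scale = raw(np.asarray(res.x))
    return raw(t) / scale


def _hrf_trial_kernel(config: SimConfig, fs: float) -> np.ndarray:
    """Task-evoked HbO waveform: 5-s boxcar convolved with the HRF, peak 1."""
    dt = 1.0 / fs
    dur = config.task_s + config.hrf_peak_s + 3.0 * config.hrf_undershoot_s
    t = np.arange(0.0, dur, dt)
    h = double_gamma_hrf(t, config.hrf_peak_s, config.hrf_undershoot_s)
    box = np.ones(max(1, int(round(config.task_s * fs))))
    resp = np.convolve(h, box)[: t.size] * dt
    return resp / resp.max()


# ---------------------------------------------------------------------------
# helpers


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    n = n_samples
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _band_source(rng: np.random.Generator, band: Tuple[float, float], fs: float,
                 n_samples: int) -> np.ndarray:
    """Unit-variance band-limited Gaussian oscillation."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / sd if sd > 0 else x


def _task_envelope(times: np.ndarray, schedule: ParadigmSchedule,
                   gain_by_label: Mapping[str, float], ramp_s: float,
                   trial_gain_jitter: Optional[np.ndarray] = None) -> np.ndarray:
    """Multiplicative envelope: 1 at rest, `gain` during tasks, cosine ramps.

    ``trial_gain_jitter`` scales each trial's deviation from unit gain,
    modelling trial-to-trial variability of task engagement.
    """
    env = np.ones_like(times)
    for ti, trial in enumerate(schedule.trials):
        g = gain_by_label.get(trial.label, 1.0)
        if trial_gain_jitter is not None:
            g = 1.0 + (g - 1.0) * trial_gain_jitter[ti]
        if g == 1.0:
            continue
        t0, t1 = trial.task_onset_s, trial.task_onset_s + trial.task_len_s
        # raised-cosine transition of width ramp_s centred on the edges
        up = np.clip((times - (t0 - ramp_s / 2)) / ramp_s, 0.0, 1.0)
        down = np.clip(((t1 + ramp_s / 2) - times) / ramp_s, 0.0, 1.0)
        w = (0.5 - 0.5 * np.cos(np.pi * up)) * (0.5 - 0.5 * np.cos(np.pi * down))
        env *= 1.0 + (g - 1.0) * w
    return env


def _session_drift_factors(config: SimConfig, session_id: int, size: int) -> np.ndarray:
    """Per-session multiplicative jitter of effect topographies."""
    if config.session_drift == 0.0:
        return np.ones(size)
    rng = np.random.default_rng((config.seed, session_id, 3))
    return np.clip(1.0 + config.session_drift * rng.standard_normal(size), 0.1, None)


# ---------------------------------------------------------------------------
# EEG + EOG


def simulate_eeg(schedule: ParadigmSchedule, config: SimConfig
                 ) -> Tuple[ContinuousRecording, ContinuousRecording]:
    """Simulate frontal EEG (uV) and the two EOG channels for one session.

    Each filter-bank band has one band-limited source mixed into the 10
    channels through a fixed, dataset-level spatial pattern; during task
    windows the source envelope is scaled by ``1 - erd_depth[class][band]``
    (or ``1 + ers_gain``) with 0.5-s cosine ramps at the edges.
    """
    config.validate()
    fs = config.fs_eeg
    n = int(math.ceil(schedule.duration_s * fs)) + 1
    times = np.arange(n) / fs
    rng = np.random.default_rng((config.seed, schedule.session_id, 1))
    pattern_rng = np.random.default_rng((config.seed, 4))  # dataset-level

    n_ch = len(EEG_CHANNELS)
    eeg = config.noise["pink_eeg_uv"] * _pink_noise(rng, n_ch, n)

    drift = _session_drift_factors(config, schedule.session_id, len(EEG_BANDS) * n_ch)
    n_trials = len(schedule.trials)
    for bi, (band, edges) in enumerate(EEG_BANDS.items()):
        source = _band_source(rng, edges, fs, n)
        jitter = np.clip(
            1.0 + config.trial_jitter * rng.standard_normal(n_trials), 0.0, 2.0)
        gain_by_label: Dict[str, float] = {}
        for cls in config.classes:
            g = 1.0
            g *= 1.0 - config.erd_depth.get(cls, {}).get(band, 0.0)
            g *= 1.0 + config.ers_gain.get(cls, {}).get(band, 0.0)
            if g != 1.0:
                gain_by_label[cls] = g
        env = _task_envelope(times, schedule, gain_by_label, config.ramp_s, jitter)
        pattern = config.osc_amp_uv[band] * (
            0.6 + 0.4 * pattern_rng.random(n_ch)) * np.sign(
            pattern_rng.standard_normal(n_ch))
        pattern = pattern * drift[bi * n_ch:(bi + 1) * n_ch]
        eeg += np.outer(pattern, source * env)

    # EOG: blink pulses on VEOG, signed saccade pulses on HEOG
    eog = 2.0 * rng.standard_normal((2, n))
    n_events = rng.poisson(config.eog_rate_hz * schedule.duration_s)
    for _ in range(n_events):
        t0 = rng.uniform(0, schedule.duration_s)
        width = rng.uniform(0.1, 0.25)
        pulse = config.eog_amp_uv * np.exp(-0.5 * ((times - t0) / width) ** 2)
        eog[0] += pulse
        eog[1] += rng.choice([-0.5, 0.5]) * pulse

    leak = np.array([config.eog_propagation.get(ch, 0.0) for ch in EEG_CHANNELS])
    eeg += np.outer(leak, eog[0]) + 0.5 * np.outer(leak, eog[1])

    markers = tuple(
        (int(round(t.task_onset_s * fs)), t.label) for t in schedule.trials)
    eeg_rec = ContinuousRecording("EEG", fs, EEG_CHANNELS, eeg, "uV", markers)
    eog_rec = ContinuousRecording("EOG", fs, EOG_CHANNELS, eog, "uV", markers)
    return eeg_rec, eog_rec


# ---------------------------------------------------------------------------
# NIRS


def simulate_nirs(schedule: ParadigmSchedule, config: SimConfig) -> ContinuousRecording:
    """Simulate 9-channel NIRS for one session.

    Returns chromophore concentrations (modality ``NIRS-Hb``, 18 channels:
    ``CHi_HbO`` then ``CHi_HbR``, mol/L), or dual-wavelength optical density
    (modality ``NIRS-OD``) when ``config.emit_optical_density`` is set.
    """
    config.validate()
    fs = config.fs_nirs
    n = int(math.ceil(schedule.duration_s * fs)) + 1
    times = np.arange(n) / fs
    rng = np.random.default_rng((config.seed, schedule.session_id, 2))

    kernel = _hrf_trial_kernel(config, fs)
    n_ch = len(NIRS_CHANNELS)
    drift_fac = _session_drift_factors(config, schedule.session_id, n_ch)

    hbo = np.zeros((n_ch, n))
    jitter = np.clip(
        1.0 + config.trial_jitter * rng.standard_normal(len(schedule.trials)),
        0.0, 2.0)
    for ti, trial in enumerate(schedule.trials):
        amp = np.asarray(config.hrf_amp.get(trial.label, np.zeros(n_ch)), float)
        if not np.any(amp):
            continue
        start = int(round(trial.task_onset_s * fs))
        stop = min(n, start + kernel.size)
        hbo[:, start:stop] += np.outer(amp * drift_fac * jitter[ti],
                                       kernel[: stop - start])

    delay = int(round(config.hbr_delay_s * fs))
    hbr = -config.hbr_ratio * np.roll(hbo, delay, axis=1)
    if delay > 0:
        hbr[:, :delay] = 0.0

    noise = np.zeros((n_ch, n))
    for amp_key, freq in (("mayer_molar", 0.1), ("respiration_molar", 0.3),
                          ("cardiac_molar", 1.1)):
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        noise += config.noise[amp_key] * np.sin(
            2 * np.pi * freq * times[None, :] + phases[:, None])
    phases = rng.uniform(0, 2 * np.pi, n_ch)
    noise += config.noise["drift_molar"] * np.sin(
        2 * np.pi * 0.004 * times[None, :] + phases[:, None])
    noise += config.noise["white_nirs_molar"] * rng.standard_normal((n_ch, n))

    hbo_total = hbo + noise
    hbr_total = hbr - 0.5 * noise  # systemic noise is partially anti-correlated

    markers = tuple(
        (int(round(t.task_onset_s * fs)), t.label) for t in schedule.trials)

    if config.emit_optical_density:
        from hbcikit.preprocess import OpticsConfig, forward_mbll

        optics = OpticsConfig()
        od = forward_mbll(hbo_total, hbr_total, optics)  # (2*n_ch, n)
        labels = tuple(
            f"{ch}_{int(wl)}nm" for ch in NIRS_CHANNELS for wl in optics.wavelengths)
        return ContinuousRecording("NIRS-OD", fs, labels, od, "a.u.", markers)

    labels = tuple(f"{ch}_HbO" for ch in NIRS_CHANNELS) + tuple(
        f"{ch}_HbR" for ch in NIRS_CHANNELS)
    data = np.vstack([hbo_total, hbr_total])
    return ContinuousRecording("NIRS-Hb", fs, labels, data, "mol/L", markers)


def split_chromophores(rec: ContinuousRecording
                       ) -> Tuple[ContinuousRecording, ContinuousRecording]:
    """Split an 18-channel NIRS-Hb recording into (HbO, HbR) recordings."""
    if rec.modality != "NIRS-Hb":
        raise ValueError("expected a NIRS-Hb recording")
    hbo_idx = [i for i, c in enumerate(rec.channel_labels) if c.endswith("_HbO")]
    hbr_idx = [i for i, c in enumerate(rec.channel_labels) if c.endswith("_HbR")]
    hbo = ContinuousRecording(
        "HbO", rec.fs,
        tuple(rec.channel_labels[i].removesuffix("_HbO") for i in hbo_idx),
        rec.data[hbo_idx], rec.units, rec.markers)
    hbr = ContinuousRecording(
        "HbR", rec.fs,
        tuple(rec.channel_labels[i].removesuffix("_HbR") for i in hbr_idx),
        rec.data[hbr_idx], rec.units, rec.markers)
    return hbo, hbr


# ---------------------------------------------------------------------------
# dataset


def simulate_dataset(config: SimConfig) -> List[Session]:
    """Simulate all sessions of one synthetic subject."""
    config.validate()
    sessions = []
    for sid in range(config.n_sessions):
        schedule = make_schedule(config, sid)
        eeg, eog = simulate_eeg(schedule, config)
        nirs = simulate_nirs(schedule, config)
        sessions.append(Session(
            session_id=sid,
            schedule=schedule,
            recordings={"eeg": eeg, "eog": eog, "nirs": nirs},
        ))
    return sessions
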