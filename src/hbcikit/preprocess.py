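"""Signal conditioning: filtering, EOG correction, decimation, Beer-Lambert
inversion, epoching, and baseline correction.

The default EEG chain is band-pass 1-40 Hz -> EOG correction -> decimation to
100 Hz; the NIRS chain is Beer-Lambert inversion (when the input is optical
density) -> 0.01-0.2 Hz sixth-order zero-phase Butterworth. Both streams are
then cut into [-5, 5] s epochs around task onset and baseline-corrected by
the mean over [-5, -2] s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from hbcikit.simgen import (
    ContinuousRecording,
    ParadigmSchedule,
    Session,
    split_chromophores,
)


class ParameterError(ValueError):
    """Invalid filter/epoching parameters."""


class AlignmentError(ValueError):
    """Recordings that must be time-aligned are not."""


class TruncationError(ValueError):
    """An epoch window extends beyond the recorded data."""


@dataclass(frozen=True)
class OpticsConfig:
    """Constants of the modified Beer-Lambert law.

    ``extinction[i][j]`` is the molar extinction coefficient of chromophore j
    (0 = HbO, 1 = HbR) at wavelength i, in 1/(mol/L * cm). Defaults use the
    standard tabulated values at 760/850 nm, a 3 cm source-detector
    separation, and a differential pathlength factor of 6 at both
    wavelengths.
    """

    wavelengths: Tuple[float, float] = (760.0, 850.0)
    extinction: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (586.0, 1548.52),   # 760 nm: (HbO, HbR)
        (1058.0, 691.32),   # 850 nm
    )
    distance_cm: float = 3.0
    dpf: Tuple[float, float] = (6.0, 6.0)

    def matrix(self) -> np.ndarray:
        """Per-wavelength pathlength-scaled extinction matrix (2x2)."""
        e = np.asarray(self.extinction, dtype=float)
        scale = self.distance_cm * np.asarray(self.dpf, dtype=float)
        return e * scale[:, None]

    def validate(self) -> None:
        if self.distance_cm <= 0 or any(d <= 0 for d in self.dpf):
            raise ParameterError("distance_cm and dpf must be positive")
        if np.linalg.cond(np.asarray(self.extinction, float)) >= 1e6:
            raise ParameterError("extinction matrix is numerically singular")


@dataclass
class EpochSet:
    """Trials x channels x samples cut around task onsets."""

    data: np.ndarray          # (n_trials, n_channels, n_samples)
    times: np.ndarray         # seconds relative to task onset; contains 0
    fs: float
    labels: np.ndarray        # one label per trial
    session_ids: np.ndarray
    modality: str             # EEG | HbO | HbR
    channel_labels: Tuple[str, ...]

    def __post_init__(self):
        n, c, t = self.data.shape
        if self.times.size != t or self.labels.size != n or self.session_ids.size != n:
            raise ValueError("inconsistent EpochSet shapes")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, idx: np.ndarray) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], labels=self.labels[idx],
                       session_ids=self.session_ids[idx])

    def class_mask(self, classes: Sequence[str]) -> np.ndarray:
        return np.isin(self.labels, list(classes))


def concat_epochs(parts: Sequence[EpochSet]) -> EpochSet:
    first = parts[0]
    for p in parts[1:]:
        if p.modality != first.modality or p.channel_labels != first.channel_labels:
            raise ValueError("cannot concatenate mismatched epoch sets")
        if not np.allclose(p.times, first.times):
            raise ValueError("epoch time axes differ")
    return replace(
        first,
        data=np.concatenate([p.data for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
        session_ids=np.concatenate([p.session_ids for p in parts]),
    )


# ---------------------------------------------------------------------------
# filtering


def _bandpass_sos(low: float, high: float, order: int, fs: float) -> np.ndarray:
    if not 0 < low < high < fs / 2:
        raise ParameterError(f"band ({low}, {high}) Hz invalid for fs={fs}")
    if order % 2 != 0:
        raise ParameterError("overall band-pass order must be even")
    return sps.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(recording: ContinuousRecording, low: float, high: float,
             order: int = 4, zero_phase: bool = True) -> ContinuousRecording:
    """Butterworth band-pass of the stated overall order.

    ``zero_phase`` applies the filter forward and backward (squared
    magnitude, no phase distortion), which is how the slow haemodynamic band
    (0.01-0.2 Hz, order 6) is filtered.
    """
    sos = _bandpass_sos(low, high, order, recording.fs)
    if zero_phase:
        out = sps.sosfiltfilt(sos, recording.data, axis=1)
    else:
        out = sps.sosfilt(sos, recording.data, axis=1)
    return replace(recording, data=out)


def remove_eog(eeg: ContinuousRecording, eog: ContinuousRecording,
               method: str = "regression", ica_corr_threshold: float = 0.7,
               seed: int = 0) -> ContinuousRecording:
    """Remove ocular artefact leakage from the EEG.

    ``regression`` subtracts the least-squares projection of each EEG channel
    onto the EOG channels. ``ica`` unmixes the EEG with fixed-point ICA and
    zeroes components whose absolute correlation with any EOG channel exceeds
    ``ica_corr_threshold``. ``none`` returns the EEG unchanged (the analysis
    must also run uncorrected).
    """
    if method == "none":
        return eeg
    if eeg.fs != eog.fs or eeg.data.shape[1] != eog.data.shape[1]:
        raise AlignmentError("EEG and EOG must share rate and length")
    X = eeg.data  # (ch, n)
    E = eog.data
    if method == "regression":
        # X_clean = X - B E with B = X E^T (E E^T)^-1
        B = np.linalg.lstsq(E.T, X.T, rcond=None)[0].T
        return replace(eeg, data=X - B @ E)
    if method == "ica":
        from sklearn.decomposition import FastICA

        ica = FastICA(n_components=X.shape[0], random_state=seed,
                      whiten="unit-variance", max_iter=1000)
        sources = ica.fit_transform(X.T)  # (n, comps)
        keep = np.ones(sources.shape[1], dtype=bool)
        for k in range(sources.shape[1]):
            for e in E:
                r = np.corrcoef(sources[:, k], e)[0, 1]
                if np.abs(r) > ica_corr_threshold:
                    keep[k] = False
        cleaned = sources.copy()
        cleaned[:, ~keep] = 0.0
        recon = ica.inverse_transform(cleaned).T
        return replace(eeg, data=recon)
    raise ParameterError(f"unknown EOG method {method!r}")


def decimate(recording: ContinuousRecording, target_fs: float,
             numtaps: int = 129) -> ContinuousRecording:
    """Anti-alias FIR low-pass (cutoff 0.8 x new Nyquist) then downsample.

    The filter is applied forward-backward so markers stay aligned; marker
    sample indices are divided by the decimation factor.
    """
    ratio = recording.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ParameterError(
            f"fs {recording.fs} not an integer multiple of target {target_fs}")
    k = int(round(ratio))
    if k == 1:
        return recording
    taps = sps.firwin(numtaps, 0.8 * (target_fs / 2), fs=recording.fs)
    filtered = sps.filtfilt(taps, [1.0], recording.data, axis=1)
    out = filtered[:, ::k]
    markers = tuple((int(round(i / k)), lab) for i, lab in recording.markers)
    return replace(recording, data=out, fs=target_fs, markers=markers)


# ---------------------------------------------------------------------------
# Beer-Lambert


def forward_mbll(hbo: np.ndarray, hbr: np.ndarray,
                 optics: OpticsConfig) -> np.ndarray:
    """Forward modified Beer-Lambert model.

    Maps chromophore concentration changes (mol/L) for ``n`` channels to
    optical-density changes at both wavelengths, interleaved per channel as
    (ch1@wl1, ch1@wl2, ch2@wl1, ...).
    """
    optics.validate()
    A = optics.matrix()  # (2 wavelengths, 2 chromophores)
    conc = np.stack([hbo, hbr], axis=1)        # (ch, 2, n)
    od = np.einsum("wc,kcn->kwn", A, conc)     # (ch, 2, n)
    return od.reshape(-1, hbo.shape[1])


def mbll(od: ContinuousRecording, optics: OpticsConfig
         ) -> Tuple[ContinuousRecording, ContinuousRecording]:
    """Invert the modified Beer-Lambert law.

    Solves, per channel and sample,
    ``dOD(lambda) = [e_HbO(lambda) dC_HbO + e_HbR(lambda) dC_HbR] * L * DPF(lambda)``
    for the two concentration changes. Expects the two wavelengths of each
    channel as adjacent rows (``<name>_<wl>nm``).
    """
    optics.validate()
    if od.data.shape[0] % 2 != 0:
        raise ParameterError("optical-density recording needs two wavelengths per channel")
    n_ch = od.data.shape[0] // 2
    A = optics.matrix()
    Ainv = np.linalg.inv(A)
    stacked = od.data.reshape(n_ch, 2, -1)     # (ch, wavelength, n)
    conc = np.einsum("cw,kwn->kcn", Ainv, stacked)
    base = tuple(lbl.split("_")[0] for lbl in od.channel_labels[::2])
    hbo = ContinuousRecording("HbO", od.fs, base, conc[:, 0], "mol/L", od.markers)
    hbr = ContinuousRecording("HbR", od.fs, base, conc[:, 1], "mol/L", od.markers)
    return hbo, hbr


# ---------------------------------------------------------------------------
# epoching


def _epoch_offsets(fs: float, window: Tuple[float, float]) -> Tuple[np.ndarray, np.ndarray]:
    """Integer sample offsets covering the closed window, time 0 on-grid.

    The number of samples is ``round(span * fs) + 1``; when the window edges
    do not fall on the sample grid (e.g. +-5 s at 12.5 Hz) the grid starts at
    ``ceil(window[0] * fs)`` so that offset 0 (the marker sample) is always
    included.
    """
    t0, t1 = window
    n = int(round((t1 - t0) * fs)) + 1
    start = int(np.ceil(t0 * fs - 1e-9))
    offsets = np.arange(start, start + n)
    return offsets, offsets / fs


def epoch(recording: ContinuousRecording, schedule: ParadigmSchedule,
          window: Tuple[float, float] = (-5.0, 5.0),
          modality: Optional[str] = None) -> EpochSet:
    """Cut one epoch per scheduled trial around its task-onset marker."""
    if len(recording.markers) != len(schedule.trials):
        raise AlignmentError("marker count does not match schedule trials")
    offsets, times = _epoch_offsets(recording.fs, window)
    n_samples = recording.data.shape[1]
    bad = [i for i, (m, _) in enumerate(recording.markers)
           if m + offsets[0] < 0 or m + offsets[-1] >= n_samples]
    if bad:
        raise TruncationError(
            f"epoch window {window} exceeds recording bounds for trials {bad}")
    idx = np.array([m for m, _ in recording.markers])[:, None] + offsets[None, :]
    data = recording.data[:, idx]                    # (ch, trials, samples)
    data = np.transpose(data, (1, 0, 2)).copy()
    labels = schedule.labels
    return EpochSet(
        data=data, times=times, fs=recording.fs, labels=labels,
        session_ids=np.full(labels.size, schedule.session_id),
        modality=modality or recording.modality,
        channel_labels=recording.channel_labels,
    )


def baseline_correct(epochs: EpochSet,
                     interval: Tuple[float, float] = (-5.0, -2.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline interval."""
    mask = (epochs.times >= interval[0]) & (epochs.times <= interval[1])
    if not mask.any():
        raise ParameterError(f"baseline interval {interval} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


# ---------------------------------------------------------------------------
# full chain


@dataclass
class PreprocConfig:
    """Parameters of the conditioning chain."""

    eeg_band: Tuple[float, float] = (1.0, 40.0)
    eeg_filter_order: int = 4
    eeg_zero_phase: bool = True
    eog_method: str = "regression"   # none | regression | ica
    eeg_target_fs: float = 100.0
    nirs_band: Tuple[float, float] = (0.01, 0.2)
    nirs_filter_order: int = 6
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    window: Tuple[float, float] = (-5.0, 5.0)
    baseline: Tuple[float, float] = (-5.0, -2.0)
    ica_seed: int = 0


def preprocess_session(session: Session, cfg: Optional[PreprocConfig] = None
                       ) -> Dict[str, EpochSet]:
    """Run the full conditioning chain on one session.

    Returns baseline-corrected epoch sets keyed ``EEG``, ``HbO``, ``HbR``.
    """
    cfg = cfg or PreprocConfig()
    eeg = bandpass(session.recordings["eeg"], *cfg.eeg_band,
                   order=cfg.eeg_filter_order, zero_phase=cfg.eeg_zero_phase)
    eeg = remove_eog(eeg, session.recordings["eog"], method=cfg.eog_method,
                     seed=cfg.ica_seed)
    eeg = decimate(eeg, cfg.eeg_target_fs)

    nirs = session.recordings["nirs"]
    if nirs.modality == "NIRS-OD":
        hbo, hbr = mbll(nirs, cfg.optics)
    else:
        hbo, hbr = split_chromophores(nirs)
    hbo = bandpass(hbo, *cfg.nirs_band, order=cfg.nirs_filter_order, zero_phase=True)
    hbr = bandpass(hbr, *cfg.nirs_band, order=cfg.nirs_filter_order, zero_phase=True)

    out = {}
    for name, rec in (("EEG", eeg), ("HbO", hbo), ("HbR", hbr)):
        ep = epoch(rec, session.schedule, cfg.window, modality=name)
        out[name] = baseline_correct(ep, cfg.baseline)
    return out


def preprocess_dataset(sessions: Sequence[Session],
                       cfg: Optional[PreprocConfig] = None) -> Dict[str, EpochSet]:
    """Preprocess every session and concatenate epochs across sessions."""
    per_session: List[Dict[str, EpochSet]] = [
        preprocess_session(s, cfg) for s in sessions]
    return {
        name: concat_epochs([d[name] for d in per_session])
        for name in ("EEG", "HbO", "HbR")
    }
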