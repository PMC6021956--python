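"""Feature extraction: filter-bank CSP log-variance and NIRS window stats.

EEG epochs are re-filtered into theta (4-8 Hz), alpha (8-13 Hz) and beta
(13-30 Hz) copies; within each band, common spatial patterns are fitted on a
class pair and the log-variance of the first and last three CSP components
over the 0-5 s task window forms the feature vector (3 bands x 6 components
= 18 features). For each chromophore, the mean and least-squares slope of
the 0-2, 2-4 and 4-5 s sub-windows of every channel give 9 x 3 x 2 = 54
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as spla
from scipy import signal as sps

from hbcikit.preprocess import EpochSet, ParameterError


@dataclass(frozen=True)
class FeatureSpec:
    """What to extract from each modality."""

    eeg_bands: Tuple[Tuple[str, float, float], ...] = (
        ("theta", 4.0, 8.0), ("alpha", 8.0, 13.0), ("beta", 13.0, 30.0))
    csp_keep: int = 3                     # pairs: first k and last k components
    eeg_window: Tuple[float, float] = (0.0, 5.0)
    band_filter_order: int = 4
    nirs_windows: Tuple[Tuple[float, float], ...] = ((0.0, 2.0), (2.0, 4.0), (4.0, 5.0))
    nirs_stats: Tuple[str, ...] = ("mean", "slope")
    slope_method: str = "lstsq"           # lstsq | endpoint

    def validate_for(self, epochs: EpochSet) -> None:
        for name, lo, hi in self.eeg_bands:
            if not 0 < lo < hi < epochs.fs / 2:
                raise ParameterError(f"band {name} ({lo}-{hi} Hz) outside (0, fs/2)")
        if 2 * self.csp_keep > len(epochs.channel_labels):
            raise ParameterError("csp_keep pairs exceed channel count")


@dataclass
class FeatureMatrix:
    """Trials x features with labels, session ids and feature provenance."""

    values: np.ndarray
    labels: np.ndarray
    session_ids: np.ndarray
    feature_names: Tuple[str, ...]

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.values.shape != (self.labels.size, len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return replace(self, values=self.values[idx], labels=self.labels[idx],
                       session_ids=self.session_ids[idx])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        df.insert(1, "session_id", self.session_ids)
        return df

    def save_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filter bank


def filter_bank(epochs: EpochSet, spec: Optional[FeatureSpec] = None
                ) -> Dict[str, EpochSet]:
    """Zero-phase band-pass copies of the epochs, one per filter-bank band."""
    spec = spec or FeatureSpec()
    out: Dict[str, EpochSet] = {}
    for name, lo, hi in spec.eeg_bands:
        if not 0 < lo < hi < epochs.fs / 2:
            raise ParameterError(f"band {name} ({lo}-{hi} Hz) outside (0, fs/2)")
        sos = sps.butter(spec.band_filter_order, [lo, hi], btype="bandpass",
                         fs=epochs.fs, output="sos")
        out[name] = replace(epochs, data=sps.sosfiltfilt(sos, epochs.data, axis=2))
    return out


# ---------------------------------------------------------------------------
# CSP


@dataclass
class CSPModel:
    """Spatial filters from joint diagonalization of two class covariances.

    Columns of ``filters`` solve the generalized eigenproblem
    ``S1 w = lambda (S1 + S2) w``; eigenvalues (sorted descending, in [0,1])
    are the fraction of whitened variance explained by class 1 along each
    filter. The first/last ``keep`` columns maximize variance for class 1 /
    class 2 respectively.
    """

    filters: np.ndarray          # (channels, channels), columns are filters
    eigenvalues: np.ndarray
    selected: np.ndarray         # column indices used for features
    class_pair: Tuple[str, str]
    channel_labels: Tuple[str, ...]

    @property
    def selected_filters(self) -> np.ndarray:
        return self.filters[:, self.selected]


def csp_from_covariances(S1: np.ndarray, S2: np.ndarray, keep: int = 3,
                         reg: float = 1e-9) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CSP filters for a pair of class covariance matrices.

    Returns ``(W, eigenvalues, selected)`` with eigenvalues of
    ``S1 w = lambda (S1+S2) w`` sorted descending and
    ``W.T @ (S1+S2) @ W = I``. A rank-deficient pooled covariance is
    regularized by adding ``reg * trace/d`` to its diagonal (with a warning).
    """
    d = S1.shape[0]
    pooled = S1 + S2
    if np.linalg.matrix_rank(pooled) < d or np.linalg.cond(pooled) > 1e12:
        warnings.warn("pooled covariance is rank deficient; regularizing", RuntimeWarning)
        pooled = pooled + reg * np.trace(pooled) / d * np.eye(d)
    vals, vecs = spla.eigh(S1, pooled)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, 1.0)
    W = vecs[:, order]
    # reproducible sign: largest-magnitude entry of each filter positive
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    W = W * signs
    selected = np.concatenate([np.arange(keep), np.arange(d - keep, d)])
    return W, vals, selected


def _window_mask(times: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    return (times >= window[0]) & (times <= window[1])


def fit_csp(epochs: EpochSet, class_pair: Tuple[str, str],
            window: Tuple[float, float] = (0.0, 5.0), keep: int = 3,
            trace_norm: bool = True) -> CSPModel:
    """Fit CSP on one band's epochs for a class pair.

    By default each trial's covariance over the window is trace-normalized
    before averaging within class, so trials contribute equally regardless of
    their broadband power. ``trace_norm=False`` averages raw covariances,
    which makes the fitted log-variance features exactly invariant to an
    invertible channel mixing (trace normalization preserves this only up to
    per-trial power ratios).
    """
    tmask = _window_mask(epochs.times, window)
    if tmask.sum() < len(epochs.channel_labels):
        raise ParameterError("window has fewer samples than channels")
    covs = {}
    for cls in class_pair:
        idx = np.flatnonzero(epochs.labels == cls)
        if idx.size < 2:
            raise ParameterError(f"need >= 2 trials of class {cls!r}")
        acc = np.zeros((len(epochs.channel_labels),) * 2)
        for i in idx:
            X = epochs.data[i][:, tmask]
            C = X @ X.T
            acc += C / np.trace(C) if trace_norm else C
        covs[cls] = acc / idx.size
    W, vals, selected = csp_from_covariances(covs[class_pair[0]], covs[class_pair[1]],
                                             keep=keep)
    return CSPModel(W, vals, selected, tuple(class_pair), epochs.channel_labels)


def csp_features(band_epochs: Mapping[str, EpochSet],
                 models: Mapping[str, CSPModel],
                 spec: Optional[FeatureSpec] = None) -> FeatureMatrix:
    """Log-variance of the selected CSP components, concatenated over bands."""
    spec = spec or FeatureSpec()
    cols: List[np.ndarray] = []
    names: List[str] = []
    ref: Optional[EpochSet] = None
    for band, _, _ in spec.eeg_bands:
        epochs = band_epochs[band]
        model = models[band]
        if model.channel_labels != epochs.channel_labels:
            raise ParameterError(f"channel mismatch between model and epochs ({band})")
        ref = ref or epochs
        tmask = _window_mask(epochs.times, spec.eeg_window)
        Wsel = model.selected_filters                       # (ch, k)
        proj = np.einsum("ck,nct->nkt", Wsel, epochs.data[:, :, tmask])
        cols.append(np.log(proj.var(axis=2, ddof=0)))
        names.extend(f"{band}/CSP{j + 1}" for j in model.selected)
    assert ref is not None
    return FeatureMatrix(np.hstack(cols), ref.labels.copy(),
                         ref.session_ids.copy(), tuple(names))


# ---------------------------------------------------------------------------
# NIRS window statistics


def _nirs_window_mask(times: np.ndarray, window: Tuple[float, float],
                      closed_end: bool) -> np.ndarray:
    lo, hi = window
    if closed_end:
        return (times >= lo - 1e-9) & (times <= hi + 1e-9)
    return (times >= lo - 1e-9) & (times < hi - 1e-9)


def _chromophore_features(epochs: EpochSet, spec: FeatureSpec) -> FeatureMatrix:
    n, c, _ = epochs.data.shape
    last = len(spec.nirs_windows) - 1
    cols: List[np.ndarray] = []
    names: List[str] = []
    for wi, window in enumerate(spec.nirs_windows):
        mask = _nirs_window_mask(epochs.times, window, closed_end=(wi == last))
        if mask.sum() < 2:
            raise ParameterError(f"window {window} has fewer than 2 samples")
        seg = epochs.data[:, :, mask]                  # (n, c, m)
        t = epochs.times[mask]
        for stat in spec.nirs_stats:
            if stat == "mean":
                vals = seg.mean(axis=2)
            elif stat == "slope":
                if spec.slope_method == "endpoint":
                    vals = (seg[:, :, -1] - seg[:, :, 0]) / (t[-1] - t[0])
                else:
                    tc = t - t.mean()
                    vals = (seg * tc).sum(axis=2) / (tc ** 2).sum()
            else:
                raise ParameterError(f"unknown NIRS stat {stat!r}")
            cols.append(vals)
            names.extend(
                f"{ch}/{window[0]:g}-{window[1]:g}s/{stat}"
                for ch in epochs.channel_labels)
    return FeatureMatrix(np.hstack(cols), epochs.labels.copy(),
                         epochs.session_ids.copy(), tuple(names))


def nirs_features(hbo: EpochSet, hbr: EpochSet,
                  spec: Optional[FeatureSpec] = None
                  ) -> Tuple[FeatureMatrix, FeatureMatrix]:
    """Mean and slope per channel and sub-window, for HbO and HbR.

    Sub-windows are half-open ``[t0, t1)`` except the last, which is closed
    so the windows exactly partition the task period. Slopes are
    least-squares linear-fit coefficients in (units)/s by default; an
    endpoint-difference variant is available via ``spec.slope_method``.
    """
    spec = spec or FeatureSpec()
    if hbo.n_trials != hbr.n_trials or not np.array_equal(hbo.labels, hbr.labels):
        raise ParameterError("HbO and HbR epoch sets are not aligned")
    return _chromophore_features(hbo, spec), _chromophore_features(hbr, spec)
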