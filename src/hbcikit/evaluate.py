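"""Evaluation: offline and pseudo-online cross-validation, learning curves,
information transfer rate, modality-comparison statistics, and descriptive
time-frequency (ERD/S) maps.

Offline performance is a repeated stratified k-fold cross-validation (10 x 5
by default) over the pooled trials of a class pair; all data-dependent
fitting (CSP filters, base and meta sLDAs) happens inside each training
fold. Pseudo-online evaluation trains on chronologically earlier sessions
and tests on the last one (``causal``), or leaves one session out
(``session_cv``).
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from hbcikit.classify import fit_meta, fit_slda, predict_meta, predict_slda
from hbcikit.features import (
    FeatureMatrix,
    FeatureSpec,
    csp_features,
    filter_bank,
    fit_csp,
    nirs_features,
)
from hbcikit.preprocess import EpochSet, ParameterError

MODALITIES = ("EEG", "NIRS", "hBCI")


@dataclass
class CVResult:
    """Accuracies and pooled predictions of one evaluation run."""

    mode: str                      # offline | pseudo_online | learning_curve
    modality: str                  # EEG | NIRS | hBCI
    class_pair: Tuple[str, str]
    fold_accuracies: np.ndarray    # (repetitions, folds) or (folds,)
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_sizes: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))


# ---------------------------------------------------------------------------
# shared fold fitting


@dataclass
class PreparedPair:
    """Per-trial material for one class pair, ready for fold-wise fitting."""

    class_pair: Tuple[str, str]
    labels: np.ndarray
    session_ids: np.ndarray
    band_epochs: Dict[str, EpochSet]        # band -> EEG epochs (pair trials)
    nirs_fms: Dict[str, FeatureMatrix]      # HbR / HbO feature matrices
    spec: FeatureSpec


def prepare_pair(epochs: Mapping[str, EpochSet], class_pair: Tuple[str, str],
                 spec: Optional[FeatureSpec] = None) -> PreparedPair:
    """Band-filter the EEG once and extract per-trial NIRS features once.

    Both operations are per-trial independent, so they can be shared across
    folds without information leakage; CSP and all classifiers are refitted
    inside every training fold.
    """
    spec = spec or FeatureSpec()
    eeg = epochs["EEG"]
    mask = eeg.class_mask(class_pair)
    if mask.sum() < 4:
        raise ParameterError("need at least 2 trials per class")
    eeg_pair = eeg.subset(np.flatnonzero(mask))
    spec.validate_for(eeg_pair)
    hbo_fm, hbr_fm = nirs_features(
        epochs["HbO"].subset(np.flatnonzero(mask)),
        epochs["HbR"].subset(np.flatnonzero(mask)), spec)
    return PreparedPair(
        class_pair=tuple(class_pair),
        labels=eeg_pair.labels,
        session_ids=eeg_pair.session_ids,
        band_epochs=filter_bank(eeg_pair, spec),
        nirs_fms={"HbO": hbo_fm, "HbR": hbr_fm},
        spec=spec,
    )


def fit_predict_split(prep: PreparedPair, train_idx: np.ndarray,
                      test_idx: np.ndarray, inner_folds: int = 5,
                      seed: int = 0, meta_mode: str = "cv",
                      modalities: Sequence[str] = MODALITIES
                      ) -> Dict[str, np.ndarray]:
    """Fit on the training trials only; return test predictions per modality."""
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    assert np.intersect1d(train_idx, test_idx).size == 0, "train/test overlap"

    spec = prep.spec
    train_fms: Dict[str, FeatureMatrix] = {}
    test_fms: Dict[str, FeatureMatrix] = {}
    if "EEG" in modalities or "hBCI" in modalities:
        models = {
            band: fit_csp(ep.subset(train_idx), prep.class_pair,
                          window=spec.eeg_window, keep=spec.csp_keep)
            for band, ep in prep.band_epochs.items()
        }
        train_band = {b: ep.subset(train_idx) for b, ep in prep.band_epochs.items()}
        test_band = {b: ep.subset(test_idx) for b, ep in prep.band_epochs.items()}
        train_fms["EEG"] = csp_features(train_band, models, spec)
        test_fms["EEG"] = csp_features(test_band, models, spec)
    for chromo in ("HbR", "HbO"):
        train_fms[chromo] = prep.nirs_fms[chromo].subset(train_idx)
        test_fms[chromo] = prep.nirs_fms[chromo].subset(test_idx)

    preds: Dict[str, np.ndarray] = {}
    if "EEG" in modalities:
        model = fit_slda(train_fms["EEG"], prep.class_pair)
        preds["EEG"] = predict_slda(model, test_fms["EEG"])[1]
    if "NIRS" in modalities:
        meta = fit_meta(train_fms, prep.class_pair, combination=("HbR", "HbO"),
                        inner_folds=inner_folds, mode=meta_mode, seed=seed)
        preds["NIRS"] = predict_meta(meta, test_fms)[1]
    if "hBCI" in modalities:
        meta = fit_meta(train_fms, prep.class_pair,
                        combination=("EEG", "HbR", "HbO"),
                        inner_folds=inner_folds, mode=meta_mode, seed=seed)
        preds["hBCI"] = predict_meta(meta, test_fms)[1]
    return preds


# ---------------------------------------------------------------------------
# offline cross-validation


def crossvalidate_offline(epochs: Mapping[str, EpochSet],
                          class_pair: Tuple[str, str],
                          spec: Optional[FeatureSpec] = None,
                          repetitions: int = 10, folds: int = 5,
                          seed: int = 0, inner_folds: int = 5,
                          meta_mode: str = "cv",
                          modalities: Sequence[str] = MODALITIES
                          ) -> Dict[str, CVResult]:
    """Repeated stratified k-fold cross-validation (default 10 x 5)."""
    prep = prepare_pair(epochs, class_pair, spec)
    n = prep.labels.size
    min_class = min(int((prep.labels == c).sum()) for c in class_pair)
    if min_class < folds:
        raise ParameterError(
            f"cannot stratify {folds} folds with only {min_class} trials per class")

    accs = {m: np.zeros((repetitions, folds)) for m in modalities}
    y_true = {m: [] for m in modalities}
    y_pred = {m: [] for m in modalities}
    sizes = []
    # canonical trial order (content-keyed) so fold membership -- and hence
    # every accuracy -- is exactly invariant to the input trial ordering
    first_band = next(iter(prep.band_epochs.values()))
    keys = [hashlib.sha1(first_band.data[i].tobytes()).hexdigest()
            for i in range(n)]
    canon = np.argsort(np.asarray(keys), kind="stable")
    # stratify on class x session so per-session signal drift cannot
    # anti-correlate between training and test folds; fall back to plain
    # class stratification when the per-session cells are too small
    strata = np.char.add(prep.labels.astype(str),
                         prep.session_ids.astype(str))
    if np.unique(strata, return_counts=True)[1].min() < folds:
        strata = prep.labels
    strata = strata[canon]
    for rep in range(repetitions):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed * 1009 + rep) % (2 ** 31))
        for fi, (tr, te) in enumerate(skf.split(np.zeros(n), strata)):
            tr, te = canon[tr], canon[te]
            preds = fit_predict_split(prep, tr, te, inner_folds=inner_folds,
                                      seed=seed, meta_mode=meta_mode,
                                      modalities=modalities)
            sizes.append(te.size)
            for m in modalities:
                accs[m][rep, fi] = np.mean(preds[m] == prep.labels[te])
                y_true[m].append(prep.labels[te])
                y_pred[m].append(preds[m])
    return {
        m: CVResult("offline", m, tuple(class_pair), accs[m],
                    np.concatenate(y_true[m]), np.concatenate(y_pred[m]),
                    np.array(sizes))
        for m in modalities
    }


def pseudo_online(epochs: Mapping[str, EpochSet], class_pair: Tuple[str, str],
                  spec: Optional[FeatureSpec] = None, mode: str = "causal",
                  seed: int = 0, inner_folds: int = 5, meta_mode: str = "cv",
                  modalities: Sequence[str] = MODALITIES
                  ) -> Dict[str, CVResult]:
    """Session-wise evaluation emulating online use.

    ``causal``: train on all sessions but the last, test on the last.
    ``session_cv``: leave-one-session-out (each session is the test set once).
    """
    prep = prepare_pair(epochs, class_pair, spec)
    sessions = np.unique(prep.session_ids)
    if sessions.size < 2:
        raise ParameterError("pseudo-online evaluation needs at least 2 sessions")
    if mode == "causal":
        splits = [(np.flatnonzero(prep.session_ids != sessions[-1]),
                   np.flatnonzero(prep.session_ids == sessions[-1]))]
    elif mode == "session_cv":
        splits = [(np.flatnonzero(prep.session_ids != s),
                   np.flatnonzero(prep.session_ids == s)) for s in sessions]
    else:
        raise ParameterError(f"unknown pseudo-online mode {mode!r}")

    accs = {m: [] for m in modalities}
    y_true = {m: [] for m in modalities}
    y_pred = {m: [] for m in modalities}
    sizes = []
    for tr, te in splits:
        preds = fit_predict_split(prep, tr, te, inner_folds=inner_folds,
                                  seed=seed, meta_mode=meta_mode,
                                  modalities=modalities)
        sizes.append(te.size)
        for m in modalities:
            accs[m].append(np.mean(preds[m] == prep.labels[te]))
            y_true[m].append(prep.labels[te])
            y_pred[m].append(preds[m])
    return {
        m: CVResult("pseudo_online", m, tuple(class_pair), np.array(accs[m]),
                    np.concatenate(y_true[m]), np.concatenate(y_pred[m]),
                    np.array(sizes))
        for m in modalities
    }


def learning_curve(epochs: Mapping[str, EpochSet], class_pair: Tuple[str, str],
                   n_train_grid: Sequence[int], resamples: int = 20,
                   spec: Optional[FeatureSpec] = None, seed: int = 0,
                   inner_folds: int = 5, modality: str = "hBCI"
                   ) -> Dict[int, Dict[str, float | np.ndarray]]:
    """Accuracy on the last session as a function of training-set size.

    For each ``n`` in the grid, ``resamples`` stratified subsets of size
    ``n`` are drawn from the earlier sessions' trials, the pipeline is
    trained on each subset and tested on the last session.
    """
    prep = prepare_pair(epochs, class_pair, spec)
    sessions = np.unique(prep.session_ids)
    if sessions.size < 2:
        raise ParameterError("learning curve needs at least 2 sessions")
    pool = np.flatnonzero(prep.session_ids != sessions[-1])
    test_idx = np.flatnonzero(prep.session_ids == sessions[-1])
    per_class = {c: pool[prep.labels[pool] == c] for c in class_pair}

    rng = np.random.default_rng(seed)
    out: Dict[int, Dict[str, float | np.ndarray]] = {}
    for n in n_train_grid:
        n_per = n // len(class_pair)
        if n_per < 1:
            raise ParameterError(f"n_train={n} is fewer than 1 trial per class")
        if any(n_per > v.size for v in per_class.values()):
            raise ParameterError(f"n_train={n} exceeds available training trials")
        accs = np.zeros(resamples)
        for r in range(resamples):
            chosen = np.sort(np.concatenate([
                rng.choice(v, size=n_per, replace=False)
                for v in per_class.values()]))
            preds = fit_predict_split(prep, chosen, test_idx,
                                      inner_folds=inner_folds, seed=seed,
                                      modalities=(modality,))
            accs[r] = np.mean(preds[modality] == prep.labels[test_idx])
        out[n] = {"mean": float(accs.mean()), "sd": float(accs.std()),
                  "accuracies": accs}
    return out


# ---------------------------------------------------------------------------
# information transfer rate


@dataclass(frozen=True)
class ITRResult:
    P: float
    N: int
    m: float              # decisions per minute
    bits_per_min: float


def itr(P: float, N: int = 2, trial_len_s: float = 5.0) -> ITRResult:
    """Information transfer rate in bits/min.

    ``ITR = m * (log2 N + P log2 P + (1-P) log2((1-P)/(N-1)))`` with
    ``m = 60 / trial_len_s`` decisions per minute and ``0 log2 0 = 0``.
    """
    if not 0.0 < P <= 1.0:
        raise ValueError("accuracy P must lie in (0, 1]")
    if N < 2:
        raise ValueError("need at least 2 commands")
    if trial_len_s <= 0:
        raise ValueError("trial length must be positive")
    m = 60.0 / trial_len_s
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1.0 - P) * np.log2((1.0 - P) / (N - 1))
    return ITRResult(P=float(P), N=int(N), m=m, bits_per_min=float(m * bits))


# ---------------------------------------------------------------------------
# statistics


@dataclass
class StatsReport:
    friedman_statistic: float
    friedman_p: float
    conditions: Tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    pairwise: pd.DataFrame   # columns: pair, p_raw, p_adjusted


def compare_modalities(table: pd.DataFrame | np.ndarray,
                       columns: Optional[Sequence[str]] = None) -> StatsReport:
    """Friedman omnibus plus pairwise Wilcoxon signed-rank with BH-FDR.

    ``table`` holds one row per subject and one column per condition
    (e.g. EEG, NIRS, hBCI accuracies).
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(np.asarray(table),
                          columns=columns or [f"cond{i}" for i in
                                              range(np.asarray(table).shape[1])])
    if df.shape[0] < 3 or df.shape[1] < 3:
        raise ParameterError("need >= 3 subjects and >= 3 conditions")
    cols = [df[c].to_numpy(dtype=float) for c in df.columns]
    if any(np.ptp(c) == 0 for c in cols):
        warnings.warn("a condition column is constant; tests may be degenerate",
                      RuntimeWarning)
    if np.allclose(df.to_numpy(dtype=float), df.to_numpy(dtype=float)[:, [0]]):
        warnings.warn("all condition columns are identical; omnibus test is "
                      "degenerate (statistic 0)", RuntimeWarning)
        stat, p = 0.0, 1.0
    else:
        stat, p = spstats.friedmanchisquare(*cols)

    rows = []
    for a, b in itertools.combinations(df.columns, 2):
        diff = df[a].to_numpy(dtype=float) - df[b].to_numpy(dtype=float)
        if np.all(diff == 0):
            p_raw = 1.0
        else:
            method = "exact" if (diff.size <= 25 and not np.any(diff == 0)) else "approx"
            p_raw = float(spstats.wilcoxon(diff, method=method,
                                           correction=(method == "approx")).pvalue)
        rows.append({"pair": f"{a} vs {b}", "p_raw": p_raw})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adjusted"] = benjamini_hochberg(pairwise["p_raw"].to_numpy())
    return StatsReport(
        friedman_statistic=float(stat), friedman_p=float(p),
        conditions=tuple(df.columns),
        means=df.mean(axis=0).to_numpy(), sds=df.std(axis=0, ddof=1).to_numpy(),
        pairwise=pairwise,
    )


def benjamini_hochberg(p_raw: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, >= raw)."""
    return multipletests(np.asarray(p_raw, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# chance level and null calibration


def chance_level(n_trials: int, alpha: float = 0.05) -> float:
    """Smallest accuracy whose exact binomial tail under p=0.5 is < alpha.

    ``alpha >= 1`` returns 0 (any accuracy passes); when no achievable count
    reaches significance the threshold saturates at 1.0.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if alpha >= 1.0:
        return 0.0
    ks = np.arange(n_trials + 2)
    tails = spstats.binom.sf(ks - 1, n_trials, 0.5)  # P(X >= k)
    k = int(ks[np.argmax(tails < alpha)])
    return min(k, n_trials) / n_trials


def binomial_null_interval(n: int, alpha: float = 0.05, p: float = 0.5
                           ) -> Tuple[float, float]:
    """Central exact-binomial interval for an accuracy under the null."""
    lo = spstats.binom.ppf(alpha / 2, n, p) / n
    hi = spstats.binom.isf(alpha / 2, n, p) / n
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# descriptive time-frequency maps


@dataclass
class TFMap:
    frequencies: np.ndarray
    times: np.ndarray
    values: np.ndarray       # dB relative to the baseline interval, (f, t)
    window_ms: float
    step_ms: float
    pad_ratio: int


def ersp(epochs: EpochSet, window_ms: float = 1000.0, step_ms: float = 80.0,
         pad_ratio: int = 2, baseline: Tuple[float, float] = (-5.0, -2.0),
         channels: Optional[Sequence[str]] = None
         ) -> Tuple[Dict[str, TFMap], Dict[str, TFMap]]:
    """Event-related spectral perturbation maps per class.

    Hann-tapered sliding-window power spectra (zero-padded by ``pad_ratio``)
    are averaged over trials and channels; values are
    ``10 log10(P(t, f) / mean_baseline P(f))``. Also returns class-difference
    maps against the baseline class ``BL`` when present (dB subtraction).
    """
    win = int(round(window_ms / 1000.0 * epochs.fs))
    step = max(1, int(round(step_ms / 1000.0 * epochs.fs)))
    n_t = epochs.data.shape[2]
    if win >= n_t:
        raise ParameterError("window longer than the epoch")
    half = win // 2
    centers = np.arange(half, n_t - (win - half) + 1, step)
    times = epochs.times[centers]
    base_cols = np.flatnonzero((times >= baseline[0]) & (times <= baseline[1]))
    if base_cols.size == 0:
        raise ParameterError("baseline interval contains no window centers")

    if channels is not None:
        ch_idx = [epochs.channel_labels.index(c) for c in channels]
    else:
        ch_idx = list(range(len(epochs.channel_labels)))
    taper = np.hanning(win)
    nfft = win * pad_ratio
    freqs = np.fft.rfftfreq(nfft, d=1.0 / epochs.fs)

    maps: Dict[str, TFMap] = {}
    for cls in np.unique(epochs.labels):
        data = epochs.data[epochs.labels == cls][:, ch_idx, :]
        P = np.zeros((freqs.size, centers.size))
        for j, c in enumerate(centers):
            seg = data[:, :, c - half: c - half + win] * taper
            spec = np.fft.rfft(seg, n=nfft, axis=2)
            P[:, j] = np.mean(np.abs(spec) ** 2, axis=(0, 1))
        base = P[:, base_cols].mean(axis=1, keepdims=True)
        values = 10.0 * np.log10(P / base)
        maps[cls] = TFMap(freqs, times, values, window_ms, step_ms, pad_ratio)

    diffs: Dict[str, TFMap] = {}
    if "BL" in maps:
        for cls, tf in maps.items():
            if cls == "BL":
                continue
            diffs[f"{cls}-BL"] = TFMap(freqs, times,
                                       tf.values - maps["BL"].values,
                                       window_ms, step_ms, pad_ratio)
    return maps, diffs
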