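"""Dataset container, run configuration, and the command-line surface.

The on-disk dataset container is a directory with a versioned JSON manifest,
one ``.npy`` array per recording (sha256-checksummed), and a tab-separated
event table per session. Preprocessed epochs use the same manifest scheme.
The CLI chains the stages::

    hbcikit simulate  --config run.yaml --seed 1 --out work/
    hbcikit preprocess --in work/raw --out work/epochs
    hbcikit features  --in work/epochs --out work/features --pair MA-BL
    hbcikit evaluate  --in work/epochs --out work/report.json --pair MA-BL
    hbcikit report    --in work/report.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Sequence, Tuple

import click
import numpy as np
import yaml

from hbcikit import evaluate as ev
from hbcikit import simgen
from hbcikit.features import FeatureSpec, csp_features, filter_bank, fit_csp, nirs_features
from hbcikit.preprocess import EpochSet, PreprocConfig, preprocess_session
from hbcikit.simgen import ContinuousRecording, ParadigmSchedule, Session, SimConfig, Trial

MANIFEST_NAME = "manifest.json"
CONTAINER_VERSION = 1

log = logging.getLogger("hbcikit")


class ContainerError(IOError):
    """Corrupt, missing, or unsupported dataset container."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# raw dataset container


def write_container(sessions: Sequence[Session], path: str | Path) -> Path:
    """Write sessions (schedules + recordings) to a checksummed container."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {
        "format": "hbcikit-dataset", "version": CONTAINER_VERSION, "sessions": []}
    for sess in sessions:
        entry: Dict[str, Any] = {
            "session_id": sess.session_id,
            "schedule": {
                "pre_rest_s": sess.schedule.pre_rest_s,
                "post_rest_s": sess.schedule.post_rest_s,
                "trials": [dataclasses.asdict(t) for t in sess.schedule.trials],
            },
            "recordings": {},
        }
        for name, rec in sess.recordings.items():
            fname = f"s{sess.session_id:02d}_{name}.npy"
            np.save(root / fname, rec.data)
            entry["recordings"][name] = {
                "file": fname,
                "modality": rec.modality,
                "fs": rec.fs,
                "units": rec.units,
                "channel_labels": list(rec.channel_labels),
                "markers": [[int(i), lab] for i, lab in rec.markers],
                "sha256": _sha256(root / fname),
            }
        export_events(sess.schedule, root / f"s{sess.session_id:02d}_events.tsv")
        entry["events"] = f"s{sess.session_id:02d}_events.tsv"
        manifest["sessions"].append(entry)
    (root / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return root


def read_container(path: str | Path) -> List[Session]:
    """Read a dataset container back, validating version and checksums."""
    root = Path(path)
    mpath = root / MANIFEST_NAME
    if not mpath.exists():
        raise ContainerError(f"no manifest at {mpath}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("version") != CONTAINER_VERSION:
        raise ContainerError(
            f"unsupported container version {manifest.get('version')} "
            f"(supported: {CONTAINER_VERSION})")
    sessions = []
    for entry in manifest["sessions"]:
        sched = entry["schedule"]
        schedule = ParadigmSchedule(
            session_id=entry["session_id"],
            pre_rest_s=sched["pre_rest_s"],
            post_rest_s=sched["post_rest_s"],
            trials=tuple(Trial(**t) for t in sched["trials"]),
        )
        recordings = {}
        for name, meta in entry["recordings"].items():
            fpath = root / meta["file"]
            if _sha256(fpath) != meta["sha256"]:
                raise ContainerError(f"checksum mismatch for {fpath}")
            recordings[name] = ContinuousRecording(
                modality=meta["modality"], fs=meta["fs"],
                channel_labels=tuple(meta["channel_labels"]),
                data=np.load(fpath), units=meta["units"],
                markers=tuple((int(i), lab) for i, lab in meta["markers"]),
            )
        sessions.append(Session(entry["session_id"], schedule, recordings))
    return sessions


def export_events(schedule: ParadigmSchedule, path: str | Path) -> Path:
    """Plain TSV event table: onset_s, duration_s, label, session_id."""
    path = Path(path)
    lines = ["onset_s\tduration_s\tlabel\tsession_id"]
    for t in schedule.trials:
        lines.append(
            f"{t.task_onset_s:.6f}\t{t.task_len_s:.6f}\t{t.label}\t{schedule.session_id}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# epochs container


def write_epochs(epoch_sets: Mapping[str, EpochSet], path: str | Path) -> Path:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {
        "format": "hbcikit-epochs", "version": CONTAINER_VERSION, "modalities": {}}
    for name, ep in epoch_sets.items():
        fname = f"epochs_{name}.npy"
        np.save(root / fname, ep.data)
        manifest["modalities"][name] = {
            "file": fname,
            "sha256": _sha256(root / fname),
            "fs": ep.fs,
            "times": ep.times.tolist(),
            "labels": ep.labels.tolist(),
            "session_ids": np.asarray(ep.session_ids).tolist(),
            "modality": ep.modality,
            "channel_labels": list(ep.channel_labels),
        }
    (root / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return root


def read_epochs(path: str | Path) -> Dict[str, EpochSet]:
    root = Path(path)
    mpath = root / MANIFEST_NAME
    if not mpath.exists():
        raise ContainerError(
            f"no epochs manifest at {mpath}; run `hbcikit preprocess` first")
    manifest = json.loads(mpath.read_text())
    if manifest.get("version") != CONTAINER_VERSION or \
            manifest.get("format") != "hbcikit-epochs":
        raise ContainerError("unsupported epochs container")
    out = {}
    for name, meta in manifest["modalities"].items():
        fpath = root / meta["file"]
        if _sha256(fpath) != meta["sha256"]:
            raise ContainerError(f"checksum mismatch for {fpath}")
        out[name] = EpochSet(
            data=np.load(fpath),
            times=np.asarray(meta["times"]),
            fs=meta["fs"],
            labels=np.asarray(meta["labels"]),
            session_ids=np.asarray(meta["session_ids"]),
            modality=meta["modality"],
            channel_labels=tuple(meta["channel_labels"]),
        )
    return out


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class ClassifyConfig:
    inner_folds: int = 5
    meta_mode: str = "cv"          # cv | naive


@dataclass
class EvalConfig:
    repetitions: int = 10
    folds: int = 5
    pseudo_mode: str = "causal"    # causal | session_cv
    itr_trial_len_s: float = 5.0
    alpha: float = 0.05
    class_pairs: Tuple[Tuple[str, str], ...] = (("MA", "BL"), ("WC", "BL"))


@dataclass
class RunConfig:
    """Full, serializable configuration of one analysis run."""

    seed: int = 0
    simulation: SimConfig = field(default_factory=SimConfig)
    preprocessing: PreprocConfig = field(default_factory=PreprocConfig)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    classification: ClassifyConfig = field(default_factory=ClassifyConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        def build(dc_type, section: Mapping[str, Any]):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(section) - names
            if unknown:
                raise ValueError(
                    f"unknown keys {sorted(unknown)} in {dc_type.__name__}")
            kwargs = {}
            for key, value in section.items():
                if isinstance(value, list):
                    value = tuple(tuple(v) if isinstance(v, list) else v
                                  for v in value)
                kwargs[key] = value
            return dc_type(**kwargs)

        sections = {
            "simulation": SimConfig, "preprocessing": PreprocConfig,
            "features": FeatureSpec, "classification": ClassifyConfig,
            "evaluation": EvalConfig,
        }
        unknown = set(raw) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown top-level config keys {sorted(unknown)}")
        kwargs: Dict[str, Any] = {"seed": int(raw.get("seed", 0))}
        for name, dc_type in sections.items():
            if name in raw:
                kwargs[name] = build(dc_type, raw[name])
        cfg = cls(**kwargs)
        cfg.simulation.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def echo(self) -> Dict[str, Any]:
        """JSON-safe dump of the exact configuration."""
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean(self)


# ---------------------------------------------------------------------------
# evaluation driver


def run_evaluation(epoch_sets: Mapping[str, EpochSet], cfg: RunConfig,
                   mode: str = "both",
                   class_pairs: Optional[Sequence[Tuple[str, str]]] = None
                   ) -> Dict[str, Any]:
    """Offline + pseudo-online accuracies, ITRs and statistics for each pair."""
    ec = cfg.evaluation
    report: Dict[str, Any] = {"config": cfg.echo(), "results": {}}
    for pair in class_pairs or ec.class_pairs:
        key = f"{pair[0]}-{pair[1]}"
        entry: Dict[str, Any] = {}
        t0 = time.perf_counter()
        if mode in ("offline", "both"):
            res = ev.crossvalidate_offline(
                epoch_sets, pair, spec=cfg.features,
                repetitions=ec.repetitions, folds=ec.folds, seed=cfg.seed,
                inner_folds=cfg.classification.inner_folds,
                meta_mode=cfg.classification.meta_mode)
            entry["offline"] = {
                m: {
                    "mean_accuracy": r.mean_accuracy,
                    "std_accuracy": r.std_accuracy,
                    "fold_accuracies": r.fold_accuracies.tolist(),
                    "itr_bits_per_min": ev.itr(
                        max(r.mean_accuracy, 1e-12), 2,
                        ec.itr_trial_len_s).bits_per_min,
                } for m, r in res.items()
            }
        if mode in ("pseudo-online", "both"):
            res = ev.pseudo_online(
                epoch_sets, pair, spec=cfg.features, mode=ec.pseudo_mode,
                seed=cfg.seed, inner_folds=cfg.classification.inner_folds,
                meta_mode=cfg.classification.meta_mode)
            entry["pseudo_online"] = {
                m: {
                    "mean_accuracy": r.mean_accuracy,
                    "std_accuracy": r.std_accuracy,
                    "fold_accuracies": r.fold_accuracies.tolist(),
                    "itr_bits_per_min": ev.itr(
                        max(r.mean_accuracy, 1e-12), 2,
                        ec.itr_trial_len_s).bits_per_min,
                } for m, r in res.items()
            }
        n_pair = int(np.isin(epoch_sets["EEG"].labels, list(pair)).sum())
        entry["n_trials"] = n_pair
        entry["chance_level"] = ev.chance_level(n_pair, ec.alpha)
        log.info("pair %s evaluated in %.1f s", key, time.perf_counter() - t0)
        report["results"][key] = entry
    return report


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def cli(verbose: bool) -> None:
    """Hybrid EEG-NIRS BCI analysis pipeline."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def _load_config(config: Optional[str], seed: Optional[int]) -> RunConfig:
    cfg = RunConfig.from_yaml(config) if config else RunConfig()
    if seed is not None:
        cfg.seed = seed
        cfg.simulation.seed = seed
    return cfg


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def simulate(config: Optional[str], seed: Optional[int], out: str) -> None:
    """Generate the synthetic dataset and write the raw container."""
    cfg = _load_config(config, seed)
    t0 = time.perf_counter()
    sessions = simgen.simulate_dataset(cfg.simulation)
    write_container(sessions, Path(out) / "raw")
    (Path(out) / "config.yaml").write_text(yaml.safe_dump(cfg.echo()))
    log.info("simulate: seed=%s, %d sessions, %.1f s", cfg.seed, len(sessions),
             time.perf_counter() - t0)
    click.echo(f"wrote raw dataset to {Path(out) / 'raw'}")


@cli.command(name="preprocess")
@click.option("--in", "inp", type=click.Path(exists=True), required=True,
              help="Directory containing the raw container.")
@click.option("--out", type=click.Path(), required=True)
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--eog", type=click.Choice(["none", "regression", "ica"]),
              default=None, help="Override the EOG-correction method.")
def preprocess_cmd(inp: str, out: str, config: Optional[str],
                   eog: Optional[str]) -> None:
    """Condition and epoch the raw recordings."""
    cfg = _load_config(config, None)
    if eog:
        cfg.preprocessing.eog_method = eog
    sessions = read_container(inp)
    t0 = time.perf_counter()
    per = [preprocess_session(s, cfg.preprocessing) for s in sessions]
    from hbcikit.preprocess import concat_epochs
    merged = {name: concat_epochs([d[name] for d in per])
              for name in ("EEG", "HbO", "HbR")}
    write_epochs(merged, out)
    log.info("preprocess: %d sessions, %.1f s", len(sessions),
             time.perf_counter() - t0)
    click.echo(f"wrote epochs to {out}")


@cli.command(name="features")
@click.option("--in", "inp", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--pair", type=click.Choice(["MA-BL", "WC-BL"]), default="MA-BL")
@click.option("--config", type=click.Path(exists=True), default=None)
def features_cmd(inp: str, out: str, pair: str, config: Optional[str]) -> None:
    """Export feature tables (CSP fitted on all trials of the pair)."""
    cfg = _load_config(config, None)
    epoch_sets = read_epochs(inp)
    class_pair = tuple(pair.split("-"))
    spec = cfg.features
    eeg = epoch_sets["EEG"]
    idx = np.flatnonzero(eeg.class_mask(class_pair))
    bands = filter_bank(eeg.subset(idx), spec)
    models = {b: fit_csp(ep, class_pair, spec.eeg_window, spec.csp_keep)
              for b, ep in bands.items()}
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    csp_features(bands, models, spec).save_tsv(out_dir / f"eeg_{pair}.tsv")
    hbo_fm, hbr_fm = nirs_features(
        epoch_sets["HbO"].subset(idx), epoch_sets["HbR"].subset(idx), spec)
    hbo_fm.save_tsv(out_dir / f"hbo_{pair}.tsv")
    hbr_fm.save_tsv(out_dir / f"hbr_{pair}.tsv")
    click.echo(f"wrote feature tables to {out_dir}")


@cli.command(name="evaluate")
@click.option("--in", "inp", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--mode", type=click.Choice(["offline", "pseudo-online", "both"]),
              default="both")
@click.option("--pair", type=click.Choice(["MA-BL", "WC-BL", "all"]), default="all")
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
def evaluate_cmd(inp: str, out: str, mode: str, pair: str,
                 config: Optional[str], seed: Optional[int]) -> None:
    """Run offline/pseudo-online evaluation and write the JSON report."""
    cfg = _load_config(config, seed)
    epoch_sets = read_epochs(inp)
    pairs = None if pair == "all" else [tuple(pair.split("-"))]
    try:
        report = run_evaluation(epoch_sets, cfg, mode=mode, class_pairs=pairs)
    except Exception as exc:  # surface a clean error and nonzero exit
        raise click.ClickException(str(exc))
    Path(out).parent.mkdir(parents=True, exist_ok=True)
    Path(out).write_text(json.dumps(report, indent=1, sort_keys=True))
    click.echo(f"wrote report to {out}")


@cli.command(name="report")
@click.option("--in", "inp", type=click.Path(exists=True), required=True)
def report_cmd(inp: str) -> None:
    """Print a human-readable summary of an evaluation report."""
    report = json.loads(Path(inp).read_text())
    for pair, entry in report.get("results", {}).items():
        click.echo(f"== {pair} ==")
        for mode in ("offline", "pseudo_online"):
            if mode not in entry:
                continue
            click.echo(f"  {mode}:")
            for modality, res in entry[mode].items():
                click.echo(
                    f"    {modality:5s} accuracy {100 * res['mean_accuracy']:5.1f} "
                    f"+- {100 * res['std_accuracy']:4.1f} %  "
                    f"ITR {res['itr_bits_per_min']:.2f} bits/min")
        click.echo(f"  chance level ({entry['n_trials']} trials): "
                   f"{100 * entry['chance_level']:.1f} %")


if __name__ == "__main__":
    cli()
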