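"""End-to-end seizure-detection pipeline.

Stages: load or simulate records -> FLHF denoise -> fractal-dimension
features (one whole-record vector for selection, plus a K-sub-window
sequence per record for the recurrent classifier) -> stratified 80/20
split -> GBSO feature selection on the training split only -> TAENN
training on the masked features -> prediction and confusion-matrix
metrics on the held-out split.  A single master seed fans out to every
stochastic stage through numpy child seeds, so a run is a pure function
of its config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import flhf, fd_features, gbso, taenn
from .eval_metrics import classification_metrics, confusion_counts, one_vs_rest_report
from .signal_io import FEATURE_NAMES, LabeledDataset, Signal
from .synth_eeg import SynthConfig, generate_labeled_dataset

logger = logging.getLogger(__name__)


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    key = sum(ord(ch) * 131**i for i, ch in enumerate(stage)) % (2**31)
    return int(np.random.SeedSequence(master, spawn_key=(key,)).generate_state(1)[0]
               % (2**31))


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults are the package's study conditions."""

    synth: SynthConfig | None = None          # data source: synthetic
    bonn_dir: str | None = None               # ... or a directory of Bonn files
    class_grouping: dict[str, list[str]] | None = None  # Bonn sets -> classes
    edf_dir: str | None = None                # ... or a directory of EDF records
    edf_channels: list[str] | str = "all"     # channels whose features are
                                              # concatenated per record (a
                                              # modeling choice, flagged here)
    denoise: flhf.DenoiseConfig = field(default_factory=flhf.DenoiseConfig)
    k_max: int = 8
    seq_len: int = 4
    gbso: gbso.GBSOConfig = field(default_factory=gbso.GBSOConfig)
    taenn: taenn.TAENNHyper = field(default_factory=taenn.TAENNHyper)
    train_fraction: float = 0.8
    n_records: int = 200
    seizure_fraction: float = 0.5
    use_selection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_dataset(
    dataset: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified split: per class, round(train_fraction * n) to training."""
    by_class: dict[str, list[int]] = {c: [] for c in dataset.class_names}
    for i, (_, lab) in enumerate(dataset.instances):
        by_class[lab].append(i)
    for c, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has {len(idx)} instance(s); need >= 2")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in dataset.class_names:
        idx = np.array(by_class[c])
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both splits non-empty
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train = LabeledDataset([dataset.instances[i] for i in sorted(train_idx)],
                           class_names=list(dataset.class_names))
    test = LabeledDataset([dataset.instances[i] for i in sorted(test_idx)],
                          class_names=list(dataset.class_names))
    return train, test


def extract_record_features(
    signal: Signal | list[Signal], cfg: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Denoise one record; return (whole-record vector, K x d sequence).

    A multi-channel record (a list of Signals) yields the per-channel
    features concatenated along the feature axis.
    """
    channels = signal if isinstance(signal, list) else [signal]
    wholes, seq_parts = [], []
    for ch in channels:
        filtered, _ = flhf.flhf_denoise(ch, cfg.denoise)
        wholes.append(fd_features.extract_features(filtered, cfg.k_max).as_array())
        n = len(filtered)
        K = cfg.seq_len
        sub_len = n // K
        seq = np.empty((K, len(FEATURE_NAMES)))
        for k in range(K):
            window = filtered.samples[k * sub_len:(k + 1) * sub_len]
            seq[k] = fd_features.extract_features(window, cfg.k_max).as_array()
        seq_parts.append(seq)
    return np.concatenate(wholes), np.concatenate(seq_parts, axis=1)


def _load_records(cfg: PipelineConfig) -> LabeledDataset:
    if cfg.synth is not None:
        synth = SynthConfig(**{**asdict_synth(cfg.synth), "seed": child_seed(cfg.seed, "synth")})
        return generate_labeled_dataset(cfg.n_records, cfg.seizure_fraction, synth)
    if cfg.bonn_dir is not None:
        from .signal_io import read_bonn_segment
        if not cfg.class_grouping:
            raise ValueError("class grouping required for a Bonn-directory source")
        instances = []
        root = Path(cfg.bonn_dir)
        for label, prefixes in cfg.class_grouping.items():
            files = sorted(p for p in root.iterdir()
                           if p.suffix.lower() in (".txt", ".TXT")
                           and p.stem[0].upper() in [pre.upper() for pre in prefixes])
            if not files:
                raise ValueError(
                    f"class grouping: no files for class {label!r} "
                    f"(prefixes {prefixes}) in {root}"
                )
            for p in files:
                sig = read_bonn_segment(p)
                sig.class_label = label
                instances.append((sig, label))
        return LabeledDataset(instances)
    if cfg.edf_dir is not None:
        import pandas as pd

        from .signal_io import read_edf_channels
        root = Path(cfg.edf_dir)
        labels_csv = root / "labels.csv"
        if not labels_csv.exists():
            raise ValueError(f"EDF source needs {labels_csv} (record_id,label)")
        df = pd.read_csv(labels_csv)
        labels = dict(zip(df["record_id"].astype(str), df["label"].astype(str)))
        instances = []
        for p in sorted(root.glob("*.edf")):
            if p.stem not in labels:
                raise ValueError(f"{p.name} has no entry in {labels_csv}")
            chans = read_edf_channels(p, cfg.edf_channels)
            lab = labels[p.stem]
            for ch in chans:
                ch.class_label = lab
            instances.append((chans, lab))
        return LabeledDataset(instances)
    raise ValueError("config needs a data source (synth, bonn_dir or edf_dir)")


def asdict_synth(s: SynthConfig) -> dict:
    return {k: getattr(s, k) for k in (
        "fs", "duration", "spectral_exponent", "ictal_band",
        "ictal_amplitude_ratio", "spike_rate", "noise_sd", "seed")}


def featurize_dataset(records: LabeledDataset, cfg: PipelineConfig):
    """Per-record (whole vector, sequence) pairs, labels preserved."""
    whole_rows, seq_rows, labels = [], [], []
    for sig, lab in records.instances:
        whole, seq = extract_record_features(sig, cfg)
        whole_rows.append(whole)
        seq_rows.append(seq)
        labels.append(lab)
    return np.array(whole_rows), np.array(seq_rows), labels


#: Bonn benchmark case presets: class grouping by set letter.  Bonn file
#: stems start with Z (set A), O (B), N (C), F (D), S (E); the groupings
#: below are expressed in set letters and translated via BONN_SET_PREFIX.
BONN_SET_PREFIX = {"A": "Z", "B": "O", "C": "N", "D": "F", "E": "S"}
BONN_CASES = {
    "I": {"normal": ["A"], "seizure": ["E"]},
    "II": {"normal": ["B"], "seizure": ["E"]},
    "III": {"normal": ["C"], "seizure": ["E"]},
    "IV": {"normal": ["D"], "seizure": ["E"]},
    "V": {"normal": ["A"], "seizure": ["D"]},
    "VI": {"normal": ["A", "B"], "seizure": ["E"]},
    "VII": {"normal": ["C", "D"], "seizure": ["E"]},
    "VIII": {"normal": ["A", "C", "D"], "seizure": ["E"]},
    "IX": {"normal": ["B", "C", "D"], "seizure": ["E"]},
    "X": {"normal": ["A", "B", "C", "D"], "seizure": ["E"]},
    "XI": {"A": ["A"], "D": ["D"], "E": ["E"]},
    "XII": {"AB": ["A", "B"], "CD": ["C", "D"], "E": ["E"]},
}


def bonn_case_grouping(case: str) -> dict[str, list[str]]:
    """Class grouping (label -> file-stem prefixes) for a Bonn case preset."""
    if case not in BONN_CASES:
        raise KeyError(f"unknown Bonn case {case!r}; presets: {sorted(BONN_CASES)}")
    return {lab: [BONN_SET_PREFIX[s] for s in sets]
            for lab, sets in BONN_CASES[case].items()}


def run_pipeline(cfg: PipelineConfig) -> tuple[dict, "taenn.TrainedModel"]:
    """Execute the full pipeline; return (JSON-ready run report, model)."""
    t0 = time.time()
    report: dict = {"config": {"seed": cfg.seed,
                               "train_fraction": cfg.train_fraction,
                               "k_max": cfg.k_max, "seq_len": cfg.seq_len,
                               "use_selection": cfg.use_selection,
                               "denoise": {"depth": cfg.denoise.depth,
                                           "threshold_rule": cfg.denoise.threshold_rule,
                                           "normalization": cfg.denoise.normalization},
                               "gbso": {k: getattr(cfg.gbso, k) for k in (
                                   "N", "it_max", "G_max", "G_min", "f", "l",
                                   "jump_prob", "binarize_threshold", "alpha",
                                   "wrapper_k", "cv_folds")},
                               "taenn": {k: getattr(cfg.taenn, k) for k in (
                                   "hidden_size", "dropout_rate", "theta", "rho",
                                   "vartheta", "epochs", "l1_lambda",
                                   "grad_clip_norm", "seq_len", "class_weighting")}},
                   "stages": {}}

    records = _load_records(cfg)
    report["stages"]["data"] = {"n_records": len(records),
                                "classes": records.class_names,
                                "runtime_s": round(time.time() - t0, 3)}

    t1 = time.time()
    whole, seqs, labels = featurize_dataset(records, cfg)
    report["stages"]["features"] = {"n_features": whole.shape[1],
                                    "runtime_s": round(time.time() - t1, 3)}

    idx_ds = LabeledDataset([(i, lab) for i, lab in enumerate(labels)],
                            class_names=records.class_names)
    train_ds, test_ds = split_dataset(idx_ds, cfg.train_fraction,
                                      child_seed(cfg.seed, "split"))
    train_idx = [i for i, _ in train_ds.instances]
    test_idx = [i for i, _ in test_ds.instances]
    report["stages"]["split"] = {"n_train": len(train_idx), "n_test": len(test_idx)}

    t2 = time.time()
    if cfg.use_selection:
        sel_cfg = gbso.GBSOConfig(**{**{k: getattr(cfg.gbso, k) for k in (
            "N", "it_max", "G_max", "G_min", "f", "l", "jump_prob",
            "binarize_threshold", "alpha", "wrapper_k", "cv_folds",
            "l_b", "u_b")}, "seed": child_seed(cfg.seed, "gbso")})
        sel_train = LabeledDataset(
            [(whole[i], labels[i]) for i in train_idx],
            class_names=records.class_names)
        sel = gbso.gbso_select(sel_train, sel_cfg)
        mask = sel.mask
        report["stages"]["selection"] = {
            "mask": mask.tolist(),
            "selected_features": [n for n, m in zip(FEATURE_NAMES, mask) if m],
            "n_before": int(mask.size), "n_after": int(mask.sum()),
            "best_fitness": sel.best_fitness,
            "runtime_s": round(time.time() - t2, 3)}
    else:
        mask = np.ones(whole.shape[1], dtype=bool)
        report["stages"]["selection"] = {"mask": mask.tolist(),
                                         "n_before": int(mask.size),
                                         "n_after": int(mask.size),
                                         "skipped": True}

    t3 = time.time()
    hyper = taenn.TAENNHyper(**{**{k: getattr(cfg.taenn, k) for k in (
        "hidden_size", "dropout_rate", "theta", "rho", "vartheta", "epochs",
        "l1_lambda", "grad_clip_norm", "seq_len", "class_weighting")},
        "seed": child_seed(cfg.seed, "taenn")})
    train_fit = LabeledDataset(
        [(seqs[i][:, mask], labels[i]) for i in train_idx],
        class_names=records.class_names)
    model = taenn.taenn_train(train_fit, hyper)
    report["stages"]["train"] = {"epochs": hyper.epochs,
                                 "final_loss": model.history["loss"][-1],
                                 "runtime_s": round(time.time() - t3, 3)}

    y_true = [labels[i] for i in test_idx]
    pred_labels, _ = taenn.taenn_predict(model, [seqs[i][:, mask] for i in test_idx])
    if len(records.class_names) == 2:
        positive = ("seizure" if "seizure" in records.class_names
                    else records.class_names[-1])
        counts = confusion_counts(y_true, pred_labels, positive)
        metrics = classification_metrics(counts).as_dict()
        report["metrics"] = metrics
        report["confusion"] = {"TP": counts.TP, "TN": counts.TN,
                               "FP": counts.FP, "FN": counts.FN,
                               "positive_class": positive}
    else:
        report["metrics"] = one_vs_rest_report(y_true, pred_labels,
                                               records.class_names)
    report["runtime_s"] = round(time.time() - t0, 3)
    return report, model


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
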