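"""End-to-end experiment orchestration.

``run_experiment`` executes the whole pipeline — simulate (or load) →
denoise → window → multifused features → per-fold standardization and
codebook → MEMM training → leave-one-subject-out evaluation — from one
declarative config.  Feature standardization and the codebook are fitted
on training folds only, so no test-subject data influences them.

A single global seed fans out to per-stage seeds through a documented
rule (:func:`derive_seed`): ``SeedSequence([global_seed, crc32(stage)])``
reduced below 2**31, so each stage is independently reproducible.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.preprocessing import StandardScaler

from .errors import EmptyInputError
from .evaluation import EvaluationReport, evaluate_predictions, loocv_folds
from .features import MultifusedFeatureExtractor
from .codebook import CodebookQuantizer
from .io import read_dataset
from .memm import MEMMClassifier, save_model
from .preprocess import apply_filter, segment_windows, zscore_channels
from .synthetic import generate_dataset, preset_profiles


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    crc = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(global_seed), crc])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    The defaults describe the reference synthetic experiment: the
    ``sports6`` preset, 8 subjects, 60 s recordings at 100 Hz, median
    filtering (kernel 5), 4 s windows with 50% overlap, the default
    feature sizes, a 64-symbol codebook and the Adam-trained MEMM.
    """

    # data
    preset: str = "sports6"
    data_manifest: str | None = None  # when set, load instead of simulate
    n_subjects: int = 8
    duration_s: float = 60.0
    sampling_rate_hz: float = 100.0
    # preprocessing
    filter_kind: str = "median"  # median | savgol | hampel | none
    filter_params: dict = field(default_factory=dict)
    normalize: bool = False
    window_seconds: float = 4.0
    window_overlap: float = 0.5
    # features
    lbp_neighbors: int = 4
    wht_coeffs: int = 8
    czt_bins: int = 8
    # codebook / observations
    codebook_size: int = 64
    observation_mode: str = "symbol"  # symbol | dense
    # MEMM training
    optimizer: str = "adam"  # adam | adadelta
    lr: float = 5e-5
    l2: float = 1e-3
    max_epochs: int = 2000
    # global
    seed: int = 42

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _prepare_sequences(recordings, config: ExperimentConfig):
    """Filter, window and featurize each recording.

    Returns ``(sequences, extractor)`` where each sequence is a dict with
    the recording's subject, per-window labels and feature rows.  Windows
    of one recording stay in temporal order — they form one observation
    sequence for the MEMM.
    """
    extractor = MultifusedFeatureExtractor(
        lbp_neighbors=config.lbp_neighbors,
        wht_coeffs=config.wht_coeffs,
        czt_bins=config.czt_bins,
    )
    sequences = []
    for rec in recordings:
        filtered = apply_filter(rec.samples, config.filter_kind,
                                **config.filter_params)
        if config.normalize:
            filtered = zscore_channels(filtered)
        rec = type(rec)(
            subject_id=rec.subject_id,
            sampling_rate_hz=rec.sampling_rate_hz,
            channels=rec.channels,
            samples=filtered,
            labels=rec.labels,
        )
        windows = segment_windows(rec, config.window_seconds,
                                  config.window_overlap)
        if not windows:
            continue
        extractor.channel_names = rec.channels
        if not hasattr(extractor, "layout_"):
            extractor.fit(windows)
        features = extractor.transform(windows)
        sequences.append(
            {
                "subject": rec.subject_id,
                "labels": np.array([w.label for w in windows], dtype=str),
                "features": features,
            }
        )
    if not sequences:
        raise EmptyInputError("no recording produced any window")
    return sequences, extractor


def _run_fold(train_seqs, test_seqs, config: ExperimentConfig,
              codebook_seed: int):
    """Fit scaler, codebook and classifier on training sequences only;
    return (per-sequence predictions, fitted classifier, quantizer)."""
    scaler = StandardScaler()
    scaler.fit(np.vstack([s["features"] for s in train_seqs]))

    quantizer = None
    if config.observation_mode == "symbol":
        quantizer = CodebookQuantizer(
            n_symbols=config.codebook_size, random_state=codebook_seed
        )
        quantizer.fit(scaler.transform(
            np.vstack([s["features"] for s in train_seqs])
        ))

    def observations(seq):
        dense = scaler.transform(seq["features"])
        if quantizer is not None:
            return quantizer.transform(dense)
        return dense

    clf = MEMMClassifier(
        observation_mode=config.observation_mode,
        n_symbols=config.codebook_size
        if config.observation_mode == "symbol" else None,
        optimizer=config.optimizer,
        lr=config.lr,
        l2=config.l2,
        max_epochs=config.max_epochs,
    )
    clf.fit([observations(s) for s in train_seqs],
            [s["labels"] for s in train_seqs])
    predictions = [clf.predict([observations(s)])[0] for s in test_seqs]
    return predictions, clf, quantizer


def run_experiment(config: ExperimentConfig | None = None,
                   out_dir=None) -> EvaluationReport:
    """Run the full pipeline under leave-one-subject-out evaluation.

    Deterministic for a fixed config.  When ``out_dir`` is given, writes
    ``report.json``, ``confusion.csv``, per-fold model JSON files and a
    plain-text log with per-fold timing.
    """
    config = config or ExperimentConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = []

    if config.data_manifest:
        recordings = read_dataset(config.data_manifest)
    else:
        recordings = generate_dataset(
            preset_profiles(config.preset),
            n_subjects=config.n_subjects,
            duration_s=config.duration_s,
            fs=config.sampling_rate_hz,
            seed=derive_seed(config.seed, "data"),
        )
    sequences, _ = _prepare_sequences(recordings, config)

    subjects = [s["subject"] for s in sequences]
    folds = loocv_folds(subjects)
    labels = sorted({lab for s in sequences for lab in s["labels"]})
    codebook_seed = derive_seed(config.seed, "codebook")

    all_true, all_pred = [], []
    fold_assignments = {}
    for fold_id, (train_subjects, test_subjects) in enumerate(folds):
        t0 = time.perf_counter()
        train_seqs = [s for s in sequences if s["subject"] in train_subjects]
        test_seqs = [s for s in sequences if s["subject"] in test_subjects]
        try:
            predictions, clf, _ = _run_fold(
                train_seqs, test_seqs, config, codebook_seed
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'fold-train/predict' failed in fold {fold_id} "
                f"(test subject {test_subjects[0]})"
            ) from exc
        for seq, pred in zip(test_seqs, predictions):
            all_true.append(seq["labels"])
            all_pred.append(pred)
        for subj in test_subjects:
            fold_assignments[subj] = fold_id
        elapsed = time.perf_counter() - t0
        log_lines.append(
            f"fold {fold_id} test={test_subjects[0]} "
            f"windows={sum(len(s['labels']) for s in test_seqs)} "
            f"time={elapsed:.2f}s"
        )
        if out_dir is not None:
            save_model(clf.model_, out_dir / f"model_fold{fold_id}.json")

    report = evaluate_predictions(
        np.concatenate(all_true), np.concatenate(all_pred), labels,
        fold_assignments,
    )
    if out_dir is not None:
        report.to_json(out_dir / "report.json")
        report.confusion_frame().to_csv(out_dir / "confusion.csv")
        config.to_yaml(out_dir / "config.yaml")
        (out_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return report
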