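"""End-to-end composition: detect -> featurize -> train -> vote -> evaluate.

These helpers wire the pipeline stages together for benchmark runs and for
the breed x feature x architecture comparison grid.  Each stage stays usable
on its own; nothing here adds behaviour beyond composition and bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chickcall.detect import DetectorConfig, detect_in_clip, extract_call_audio
from chickcall.errors import DataError
from chickcall.features import build_mel_bank, featurize
from chickcall.models import ModelConfig, TrainConfig, build_model, predict_calls, train
from chickcall.preprocess import WindowSpec
from chickcall.sexing import (
    ChickRecord, SplitManifest, evaluate, majority_vote, split_by_chick,
)
from chickcall.synth import CallParams, StudyChick, generate_study

log = logging.getLogger(__name__)


@dataclass
class CallInventory:
    """Detected call audio for one bird (earliest-first)."""

    record: ChickRecord
    call_audio: list  # list[AudioClip], aligned with record.call_segments


def build_inventories(
    chicks: list[StudyChick],
    detector: DetectorConfig | None = None,
    window: WindowSpec | None = None,
) -> list[CallInventory]:
    """Run detection on each bird's recording and keep only the call audio."""
    inventories = []
    for chick in chicks:
        segments, filtered = detect_in_clip(chick.clip, config=detector, window=window)
        record = ChickRecord(
            chick_id=chick.chick_id, breed=chick.breed, sex=chick.sex,
            call_segments=segments,
        )
        audio = [extract_call_audio(filtered, s) for s in segments]
        inventories.append(CallInventory(record=record, call_audio=audio))
    return inventories


def features_for_pairs(
    inventories: list[CallInventory],
    pairs: list[tuple[str, int]],
    feature_kind: str,
    window: WindowSpec | None = None,
    bank=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack features and binary labels (cock=1) for (chick_id, call_idx) pairs."""
    by_id = {inv.record.chick_id: inv for inv in inventories}
    xs, ys = [], []
    for cid, idx in pairs:
        inv = by_id[cid]
        call = inv.call_audio[idx]
        xs.append(featurize(call, feature_kind, window=window, bank=bank).values)
        ys.append(1 if inv.record.sex == "cock" else 0)
    if not xs:
        raise DataError("no calls in the requested partition")
    return np.stack(xs), np.array(ys)


@dataclass
class BenchmarkResult:
    call_accuracy: float
    chick_accuracy: float
    history: object
    evaluation: dict
    manifest: SplitManifest
    n_train: int = 0
    n_val: int = 0
    n_test: int = 0


def run_benchmark(
    n_chicks_per_sex: int = 20,
    sex_offset_hz: float = 400.0,
    feature_kind: str = "mfcc_logfbank",
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    calls_per_chick: int = 45,
    n_votes: int = 41,
    test_fraction: float = 0.2,
) -> BenchmarkResult:
    """Synthetic single-breed study, end to end.

    Generates one recording per bird with the given per-sex fundamental
    offset, detects and featurizes calls, trains a classifier on a
    bird-disjoint split, and scores both per-call test accuracy and
    majority-vote accuracy over ``n_votes`` calls of each test bird.
    """
    if model_config is None:
        model_config = ModelConfig(architecture="cnn", width_multiplier=0.125, seed=seed)
    if train_config is None:
        train_config = TrainConfig(max_epochs=40, patience=10, seed=seed)

    params = CallParams(sex_offset_hz=sex_offset_hz)
    chicks, _ = generate_study(
        n_chicks_per_sex, breed_profiles={"S": sex_offset_hz},
        calls_per_chick=calls_per_chick, seed=seed, params=params,
    )
    inventories = build_inventories(chicks)
    records = [inv.record for inv in inventories]
    manifest = split_by_chick(records, test_fraction_per_sex=test_fraction, seed=seed)

    window = WindowSpec.for_sample_rate(chicks[0].clip.sample_rate)
    bank = build_mel_bank(sample_rate=chicks[0].clip.sample_rate)
    x_train, y_train = features_for_pairs(inventories, manifest.partitions["train"],
                                          feature_kind, window, bank)
    x_val, y_val = features_for_pairs(inventories, manifest.partitions["validation"],
                                      feature_kind, window, bank)

    classifier = build_model(model_config, x_train.shape[1:])
    classifier, history = train(classifier, (x_train, y_train), (x_val, y_val), train_config)

    # per-call accuracy over the manifest's test partition
    test_pairs = manifest.partitions["test"]
    x_test, _ = features_for_pairs(inventories, test_pairs, feature_kind, window, bank)
    _, labels = predict_calls(classifier, x_test)
    call_predictions = {
        pair: ("cock" if lab == 1 else "hen") for pair, lab in zip(test_pairs, labels)
    }

    # chick-level majority vote over the earliest n_votes calls of each test bird
    vote_results = []
    by_id = {inv.record.chick_id: inv for inv in inventories}
    for cid in sorted(manifest.chick_ids("test")):
        inv = by_id[cid]
        feats = np.stack([
            featurize(c, feature_kind, window=window, bank=bank).values
            for c in inv.call_audio[:n_votes]
        ])
        _, vote_labels = predict_calls(classifier, feats)
        vote_results.append(
            majority_vote(vote_labels.tolist(), chick_id=cid, true_sex=inv.record.sex)
        )

    evaluation = evaluate(manifest, call_predictions, records, vote_results)
    return BenchmarkResult(
        call_accuracy=evaluation["call_accuracy"],
        chick_accuracy=evaluation["chick_accuracy"],
        history=history, evaluation=evaluation, manifest=manifest,
        n_train=len(x_train), n_val=len(x_val), n_test=len(x_test),
    )


def run_experiment_grid(
    n_chicks_per_sex: int,
    breed_profiles: dict[str, float] | None = None,
    feature_kinds=("spectrogram", "cepstrogram", "mfcc_logfbank"),
    architectures=("cnn", "gru", "crnn", "twostream", "resnet50"),
    width_multiplier: float = 0.125,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-comparison grid: breed x feature x architecture accuracies."""
    rows = []
    profiles = breed_profiles or None
    from chickcall.synth import DEFAULT_BREED_PROFILES

    for breed, offset in (profiles or DEFAULT_BREED_PROFILES).items():
        for kind in feature_kinds:
            for arch in architectures:
                res = run_benchmark(
                    n_chicks_per_sex=n_chicks_per_sex, sex_offset_hz=offset,
                    feature_kind=kind,
                    model_config=ModelConfig(architecture=arch,
                                             width_multiplier=width_multiplier, seed=seed),
                    train_config=train_config, seed=seed,
                )
                rows.append({
                    "breed": breed, "feature": kind, "architecture": arch,
                    "call_accuracy": res.call_accuracy,
                    "chick_accuracy": res.chick_accuracy,
                })
                log.info("grid %s/%s/%s: call %.3f chick %.3f", breed, kind, arch,
                         res.call_accuracy, res.chick_accuracy)
    return pd.DataFrame(rows)
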