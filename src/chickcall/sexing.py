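"""Chick-level dataset construction and majority-vote sex decisions.

Calls of one chick are highly similar, so scattering them across training and
test sets inflates test accuracy: the split must be by bird, never by call.
``split_by_chick`` holds out whole birds (stratified by breed and sex) and
only then samples calls into train/validation/test partitions, keeping the
sexes balanced and the partitions in the study's 5 : 1 : 2.5 call proportions.

A bird's sex is decided by majority vote over an odd number of its calls
(41 by default): with per-call accuracy p > 1/2 the vote amplifies accuracy
toward the binomial tail P(Bin(41, p) >= 21).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chickcall.detect import CallSegment
from chickcall.errors import DataError, InsufficientCallsError, ParameterError
from chickcall.preprocess import AudioClip

SEXES = ("cock", "hen")
DEFAULT_N_VOTES = 41
#: per-sex call-count proportions of the study protocol (train : val : test)
PARTITION_PROPORTIONS = {"train": 5.0, "validation": 1.0, "test": 2.5}


@dataclass
class ChickRecord:
    """One bird: identity, labels and its detected call inventory."""

    chick_id: str
    breed: str
    sex: str
    call_segments: list[CallSegment] = field(default_factory=list)
    clip: AudioClip | None = None  # filtered recording the segments index into

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ParameterError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass
class SplitManifest:
    """Identity-safe partition of (chick_id, call_index) pairs."""

    partitions: dict[str, list[tuple[str, int]]]
    seed: int | None = None

    def chick_ids(self, *names: str) -> set[str]:
        out: set[str] = set()
        for name in names:
            out |= {cid for cid, _ in self.partitions[name]}
        return out

    def counts_by_sex(self, records: list["ChickRecord"]) -> pd.DataFrame:
        sex_of = {r.chick_id: r.sex for r in records}
        rows = []
        for part, pairs in self.partitions.items():
            c = Counter(sex_of[cid] for cid, _ in pairs)
            rows.append({"partition": part, "cock": c.get("cock", 0), "hen": c.get("hen", 0)})
        return pd.DataFrame(rows)


@dataclass
class VoteResult:
    """Per-call predictions and the majority decision for one bird."""

    chick_id: str
    per_call_labels: list[str]
    cock_votes: int
    hen_votes: int
    decided_sex: str
    true_sex: str | None = None

    @property
    def n_calls(self) -> int:
        return self.cock_votes + self.hen_votes


def _as_sex_labels(labels) -> list[str]:
    out = []
    for v in labels:
        if isinstance(v, str):
            if v not in SEXES:
                raise ParameterError(f"label {v!r} is not a sex")
            out.append(v)
        else:
            out.append("cock" if int(v) == 1 else "hen")
    return out


def majority_vote(per_call_labels, chick_id: str = "", true_sex: str | None = None) -> VoteResult:
    """Strict-majority decision over an odd number of per-call labels."""
    labels = _as_sex_labels(per_call_labels)
    n = len(labels)
    if n == 0 or n % 2 == 0:
        raise ParameterError(f"vote needs an odd number of calls, got {n}")
    cocks = sum(1 for v in labels if v == "cock")
    hens = n - cocks
    return VoteResult(
        chick_id=chick_id, per_call_labels=labels,
        cock_votes=cocks, hen_votes=hens,
        decided_sex="cock" if cocks > hens else "hen",
        true_sex=true_sex,
    )


def split_by_chick(
    records: list[ChickRecord],
    test_fraction_per_sex: float = 0.2,
    seed: int | None = None,
    n_train_per_sex: int | None = None,
    n_val_per_sex: int | None = None,
    n_test_per_sex: int | None = None,
) -> SplitManifest:
    """Hold out whole birds as test subjects, then sample calls.

    Test birds are drawn per breed and per sex at ``test_fraction_per_sex``;
    train/validation calls come only from the remaining birds.  Unless
    explicit per-sex call budgets are given, partition sizes follow the
    5 : 1 : 2.5 study proportions scaled to what the smaller sex provides.
    """
    rng = np.random.default_rng(seed)
    by_sex = {s: [r for r in records if r.sex == s] for s in SEXES}
    for s, rs in by_sex.items():
        if len(rs) < 2:
            raise ParameterError(f"need >= 2 chicks of sex {s!r}, got {len(rs)}")

    test_ids: set[str] = set()
    breeds = sorted({r.breed for r in records})
    for breed in breeds:
        for s in SEXES:
            group = sorted(r.chick_id for r in records if r.breed == breed and r.sex == s)
            if not group:
                continue
            k = int(round(test_fraction_per_sex * len(group)))
            if k < 1 or k >= len(group):
                raise ParameterError(
                    f"test fraction {test_fraction_per_sex} leaves an empty partition "
                    f"for breed {breed!r} sex {s!r} ({len(group)} chicks)"
                )
            test_ids |= set(rng.choice(group, size=k, replace=False).tolist())

    pools = {}
    for s in SEXES:
        train_pool = [(r.chick_id, i) for r in by_sex[s] if r.chick_id not in test_ids
                      for i in range(len(r.call_segments))]
        test_pool = [(r.chick_id, i) for r in by_sex[s] if r.chick_id in test_ids
                     for i in range(len(r.call_segments))]
        pools[s] = (train_pool, test_pool)

    min_train_pool = min(len(p[0]) for p in pools.values())
    min_test_pool = min(len(p[1]) for p in pools.values())
    if n_train_per_sex is None:
        n_train_per_sex = int(min_train_pool * 5 / 6)
    if n_val_per_sex is None:
        n_val_per_sex = min(min_train_pool - n_train_per_sex, max(1, n_train_per_sex // 5))
    if n_test_per_sex is None:
        n_test_per_sex = min(min_test_pool, max(1, n_train_per_sex // 2))
    if n_train_per_sex + n_val_per_sex > min_train_pool:
        raise ParameterError(
            f"requested {n_train_per_sex}+{n_val_per_sex} calls per sex but only "
            f"{min_train_pool} available from training chicks"
        )
    if n_test_per_sex > min_test_pool:
        raise ParameterError(
            f"requested {n_test_per_sex} test calls per sex but only {min_test_pool} available"
        )

    partitions = {"train": [], "validation": [], "test": []}
    for s in SEXES:
        train_pool, test_pool = pools[s]
        picked = rng.choice(len(train_pool), size=n_train_per_sex + n_val_per_sex, replace=False)
        partitions["train"] += [train_pool[i] for i in picked[:n_train_per_sex]]
        partitions["validation"] += [train_pool[i] for i in picked[n_train_per_sex:]]
        picked_t = rng.choice(len(test_pool), size=n_test_per_sex, replace=False)
        partitions["test"] += [test_pool[i] for i in picked_t]
    return SplitManifest(partitions=partitions, seed=seed)


def sex_chick(
    classifier,
    chick_calls: list[AudioClip],
    feature_kind: str,
    n_votes: int = DEFAULT_N_VOTES,
    chick_id: str = "",
    true_sex: str | None = None,
    window=None,
    bank=None,
) -> VoteResult:
    """Featurize the bird's earliest ``n_votes`` calls, classify, vote."""
    from chickcall.features import featurize
    from chickcall.models import predict_calls

    if n_votes % 2 == 0:
        raise ParameterError(f"n_votes must be odd, got {n_votes}")
    if len(chick_calls) < n_votes:
        raise InsufficientCallsError(chick_id, len(chick_calls), n_votes)
    feats = np.stack([
        featurize(c, feature_kind, window=window, bank=bank).values
        for c in chick_calls[:n_votes]
    ])
    _, labels = predict_calls(classifier, feats)
    return majority_vote(labels.tolist(), chick_id=chick_id, true_sex=true_sex)


def evaluate(
    manifest: SplitManifest,
    call_predictions: dict[tuple[str, int], str],
    records: list[ChickRecord],
    vote_results: list[VoteResult] | None = None,
) -> dict:
    """Accuracy tables for the test partition.

    ``call_predictions`` maps (chick_id, call_index) -> predicted sex and must
    cover every test pair; ``vote_results`` (optional) adds the chick-level
    table.  Output is independent of dict/list ordering.
    """
    info = {r.chick_id: r for r in records}
    test_pairs = manifest.partitions["test"]
    missing = [p for p in test_pairs if p not in call_predictions]
    if missing:
        raise DataError(f"predictions missing for {len(missing)} test calls, e.g. {missing[:5]}")

    rows = []
    for cid, idx in sorted(test_pairs):
        rec = info[cid]
        pred = call_predictions[(cid, idx)]
        rows.append({
            "chick_id": cid, "call_index": idx, "breed": rec.breed,
            "true_sex": rec.sex, "predicted_sex": pred, "correct": pred == rec.sex,
        })
    per_call = pd.DataFrame(rows)
    out = {
        "per_call": per_call,
        "call_accuracy": float(per_call["correct"].mean()),
        "call_accuracy_by_breed": per_call.groupby("breed")["correct"].mean(),
        "confusion": pd.crosstab(per_call["true_sex"], per_call["predicted_sex"]),
    }
    if vote_results is not None:
        chick_rows = [{
            "chick_id": v.chick_id,
            "true_sex": v.true_sex if v.true_sex is not None else info[v.chick_id].sex,
            "decided_sex": v.decided_sex,
            "cock_votes": v.cock_votes, "hen_votes": v.hen_votes,
        } for v in sorted(vote_results, key=lambda v: v.chick_id)]
        per_chick = pd.DataFrame(chick_rows)
        per_chick["correct"] = per_chick["decided_sex"] == per_chick["true_sex"]
        out["per_chick"] = per_chick
        out["chick_accuracy"] = float(per_chick["correct"].mean())
    return out


def chick_accuracy_from_call_accuracy(p: float, n_votes: int = DEFAULT_N_VOTES) -> float:
    """Binomial-tail prediction of vote accuracy from per-call accuracy."""
    from scipy.stats import binom

    return float(binom.sf(n_votes // 2, n_votes, p))
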