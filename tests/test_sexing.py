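"""Bird-level splits, majority voting and evaluation."""

import numpy as np
import pytest
from scipy.stats import binom

from chickcall.detect import CallSegment
from chickcall.errors import DataError, InsufficientCallsError, ParameterError
from chickcall.preprocess import WindowSpec
from chickcall.sexing import (
    ChickRecord,
    chick_accuracy_from_call_accuracy,
    evaluate,
    majority_vote,
    sex_chick,
    split_by_chick,
)


def make_records(n_per_sex=10, calls_each=12, breed="A"):
    window = WindowSpec()
    records = []
    for sex in ("cock", "hen"):
        for i in range(n_per_sex):
            segs = [CallSegment.from_frames(100 * k, 100 * k + 40, window)
                    for k in range(calls_each)]
            records.append(ChickRecord(f"{breed}_{sex}_{i}", breed, sex, segs))
    return records


class TestMajorityVote:
    def test_unanimous(self):
        assert majority_vote(["hen"] * 41).decided_sex == "hen"

    def test_strict_majority(self):
        labels = ["cock"] * 21 + ["hen"] * 20
        vote = majority_vote(labels)
        assert vote.decided_sex == "cock"
        assert (vote.cock_votes, vote.hen_votes) == (21, 20)

    def test_even_count_rejected(self):
        with pytest.raises(ParameterError):
            majority_vote(["cock"] * 40)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        labels = ["cock"] * 25 + ["hen"] * 16
        for _ in range(5):
            shuffled = list(rng.permutation(labels))
            assert majority_vote(shuffled).decided_sex == "cock"

    def test_integer_labels_accepted(self):
        vote = majority_vote([1, 1, 0])
        assert vote.decided_sex == "cock"

    def test_monte_carlo_matches_binomial_tail(self):
        """Vote accuracy at per-call p=0.7, n=41 equals P(Bin(41,0.7) >= 21)."""
        p, n, reps = 0.7, 41, 10_000
        rng = np.random.default_rng(7)
        correct = 0
        for _ in range(reps):
            calls = rng.random(n) < p  # True = correct call-level prediction
            labels = np.where(calls, "cock", "hen")  # true sex: cock
            if majority_vote(labels.tolist()).decided_sex == "cock":
                correct += 1
        mc = correct / reps
        expected = binom.sf(n // 2, n, p)  # independent closed-form oracle
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(mc - expected) <= 3 * se
        assert chick_accuracy_from_call_accuracy(p, n) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.6, 0.7, 0.85])
    def test_vote_amplifies_per_call_accuracy(self, p):
        assert chick_accuracy_from_call_accuracy(p, 41) >= p


class TestSplitByChick:
    def test_no_chick_in_both_test_and_trainval(self):
        records = make_records()
        for seed in range(5):
            manifest = split_by_chick(records, seed=seed)
            assert manifest.chick_ids("test") & manifest.chick_ids("train", "validation") == set()

    def test_seeded_determinism(self):
        records = make_records()
        a = split_by_chick(records, seed=9)
        b = split_by_chick(records, seed=9)
        assert a.partitions == b.partitions

    def test_sexes_balanced_in_every_partition(self):
        records = make_records()
        counts = split_by_chick(records, seed=1).counts_by_sex(records)
        assert (counts["cock"] == counts["hen"]).all()

    def test_partition_proportions_follow_study_ratios(self):
        records = make_records(n_per_sex=10, calls_each=12)
        manifest = split_by_chick(records, seed=2)
        n_train = len(manifest.partitions["train"])
        n_val = len(manifest.partitions["validation"])
        assert n_train > 0 and n_val > 0
        assert 3 <= n_train / n_val <= 7  # near the 5:1 study ratio

    def test_too_few_chicks_rejected(self):
        with pytest.raises(ParameterError):
            split_by_chick(make_records(n_per_sex=1))

    def test_fraction_leaving_empty_partition_rejected(self):
        with pytest.raises(ParameterError):
            split_by_chick(make_records(n_per_sex=3), test_fraction_per_sex=0.99)


class _ConstantCock:
    """Stub classifier: always predicts cock with probability 0.9."""

    feature_shape = (110, 52)

    def eval(self):
        return self

    def __call__(self, x):
        from chickcall.nn import Tensor

        return Tensor(np.full((x.shape[0], 1), 3.0))  # logit 3 -> p ~ 0.95


class TestSexChick:
    def _calls(self, n):
        from chickcall.synth import CallParams, generate_call

        rng = np.random.default_rng(3)
        return [generate_call(CallParams(), rng, sex="hen") for _ in range(n)]

    def test_constant_classifier_decides_cock(self):
        calls = self._calls(7)
        vote = sex_chick(_ConstantCock(), calls, "mfcc_logfbank", n_votes=7,
                         chick_id="c1", true_sex="hen")
        assert vote.decided_sex == "cock"
        assert vote.n_calls == 7

    def test_insufficient_calls_error_names_shortfall(self):
        calls = self._calls(3)
        with pytest.raises(InsufficientCallsError) as err:
            sex_chick(_ConstantCock(), calls, "mfcc_logfbank", n_votes=41, chick_id="cX")
        assert err.value.available == 3
        assert err.value.required == 41

    def test_even_vote_count_rejected(self):
        with pytest.raises(ParameterError):
            sex_chick(_ConstantCock(), self._calls(4), "mfcc_logfbank", n_votes=4)


class TestEvaluate:
    def _setup(self):
        records = make_records(n_per_sex=3, calls_each=4)
        manifest = split_by_chick(records, test_fraction_per_sex=0.34, seed=0)
        truth = {r.chick_id: r.sex for r in records}
        return records, manifest, truth

    def test_perfect_predictions_score_one(self):
        records, manifest, truth = self._setup()
        preds = {pair: truth[pair[0]] for pair in manifest.partitions["test"]}
        out = evaluate(manifest, preds, records)
        assert out["call_accuracy"] == 1.0

    def test_all_cock_on_balanced_truth_scores_half(self):
        records, manifest, truth = self._setup()
        preds = {pair: "cock" for pair in manifest.partitions["test"]}
        out = evaluate(manifest, preds, records)
        assert out["call_accuracy"] == pytest.approx(0.5)

    def test_prediction_order_irrelevant(self):
        records, manifest, truth = self._setup()
        pairs = manifest.partitions["test"]
        preds = {pair: truth[pair[0]] for pair in pairs}
        reordered = dict(reversed(list(preds.items())))
        a = evaluate(manifest, preds, records)
        b = evaluate(manifest, reordered, records)
        assert a["call_accuracy"] == b["call_accuracy"]
        assert a["per_call"].equals(b["per_call"])

    def test_missing_coverage_reported(self):
        records, manifest, truth = self._setup()
        preds = {pair: truth[pair[0]] for pair in manifest.partitions["test"][:-1]}
        with pytest.raises(DataError):
            evaluate(manifest, preds, records)
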