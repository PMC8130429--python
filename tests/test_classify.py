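"""Classifier components: truth-set intersection, features, threshold logic.

Full-size training behaviour (1500 calls, 100 bootstraps) is exercised in
the acceptance suite; here the estimator runs at reduced size.
"""

import warnings

import numpy as np
import pytest

from svenrich.classify import (
    FeatureSchema,
    OperatingPointForest,
    PrCurve,
    TruthLabelSet,
    classify,
    extract_features,
    intersect_truthsets,
    select_threshold,
    train_classifier,
)
from svenrich.filters import DbEntry, overlaps
from svenrich.model import Breakend, BreakpointCall, SVClass, Side, canonicalize
from svenrich.simulate import SimScenario, simulate_truthset


def simple_call(pos_a, pos_b=None, chrom="chr1", call_id="c", **annotations):
    pos_b = pos_b or pos_a + 1000
    defaults = {"dist_simple_repeat": 1000.0, "dist_gap": 1000.0,
                "dist_segmental_duplication": 1000.0}
    defaults.update(annotations)
    return BreakpointCall(call_id, Breakend(chrom, pos_a, Side.LEFT),
                          Breakend(chrom, pos_b, Side.RIGHT), SVClass.DEL,
                          caller_features={"support": 5.0, "mapq": 50.0,
                                           "read_length": 8000.0, "score": 0.8},
                          annotations=defaults)


class TestIntersectTruthsets:
    def test_partner_in_both_sets_required(self):
        s1 = [simple_call(100, call_id="a")]
        s2 = [simple_call(150, call_id="b")]
        s3 = [simple_call(120, call_id="c")]
        assert len(intersect_truthsets(s1, s2, s3, window=100)) == 1
        assert intersect_truthsets(s1, s2, s3, window=10) == []

    def test_partner_in_only_one_set_insufficient(self):
        s1 = [simple_call(100)]
        s2 = [simple_call(150)]
        s3 = [simple_call(90_000)]
        assert intersect_truthsets(s1, s2, s3, window=100) == []

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert intersect_truthsets([], [simple_call(1)], [simple_call(1)]) == []

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(31)
        def rand_set(n, tag):
            return [simple_call(int(rng.integers(1, 50_000)), call_id=f"{tag}{i}")
                    for i in range(n)]
        s1, s2, s3 = rand_set(60, "a"), rand_set(60, "b"), rand_set(60, "c")
        got = {c.id for c in intersect_truthsets(s1, s2, s3, window=100)}
        expected = set()
        for c1 in s1:
            e1 = canonicalize(c1)
            in2 = any(overlaps(e1, DbEntry("-", canonicalize(c2).end_a,
                                           canonicalize(c2).end_b), 100) for c2 in s2)
            in3 = any(overlaps(e1, DbEntry("-", canonicalize(c3).end_a,
                                           canonicalize(c3).end_b), 100) for c3 in s3)
            if in2 and in3:
                expected.add(c1.id)
        assert got == expected


class TestFeatureSchema:
    def test_annotation_feature_passthrough(self):
        schema = FeatureSchema(log_distances=False)
        call = simple_call(100, dist_simple_repeat=0.0)
        vec = dict(zip(schema.names, schema.vector(call)))
        assert vec["dist_simple_repeat"] == 0.0

    def test_determinism(self):
        schema = FeatureSchema()
        a, b = simple_call(100), simple_call(100)
        assert np.array_equal(schema.vector(a), schema.vector(b))

    def test_translocation_length_uses_sentinel_cap(self):
        schema = FeatureSchema()
        tra = BreakpointCall("t", Breakend("chr1", 100, Side.LEFT),
                             Breakend("chr2", 100, Side.RIGHT), SVClass.TRA,
                             caller_features={"support": 3, "mapq": 50,
                                              "read_length": 5000, "score": 0.7},
                             annotations={"dist_simple_repeat": 10.0, "dist_gap": 10.0,
                                          "dist_segmental_duplication": 10.0})
        vec = dict(zip(schema.names, schema.vector(tra)))
        assert vec["sv_length"] == schema.length_cap
        assert len(schema.vector(tra)) == len(schema.names)

    def test_missing_caller_feature_uses_default(self):
        call = simple_call(100)
        call.caller_features.pop("score")
        vec = dict(zip(FeatureSchema().names, extract_features(call)))
        assert vec["score"] == 0.0

    def test_unknown_feature_name_rejected(self):
        schema = FeatureSchema(caller_feature_names=("nonexistent",),
                               caller_feature_defaults={})
        with pytest.raises(KeyError, match="nonexistent"):
            schema.vector(simple_call(100))

    def test_unannotated_call_rejected_with_feature_name(self):
        call = simple_call(100)
        call.annotations.clear()
        with pytest.raises(KeyError, match="dist_simple_repeat"):
            extract_features(call)


class TestSelectThreshold:
    CURVE = PrCurve([(0.1, 0.90, 0.999), (0.5, 0.96, 0.995), (0.9, 0.99, 0.90)])

    def test_smallest_threshold_meeting_precision(self):
        assert select_threshold(self.CURVE, 0.96, 0.995) == 0.5

    def test_unreachable_precision_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="max-precision"):
            t = select_threshold(self.CURVE, 0.999, 0.995)
        assert t == 0.9

    def test_all_points_exceed_targets(self):
        assert select_threshold(self.CURVE, 0.5, 0.5) == 0.1

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(PrCurve([]), 0.9, 0.9)


@pytest.fixture(scope="module")
def trained_small():
    labelset = simulate_truthset(SimScenario(seed=19, n_truth=400))
    model, curve, metrics = train_classifier(labelset, seed=19,
                                             n_bootstrap=10, n_estimators=100)
    return labelset, model, curve, metrics


class TestTraining:
    def test_single_class_input_rejected(self):
        calls = [simple_call(100 + i, call_id=f"c{i}") for i in range(50)]
        labelset = TruthLabelSet([(c, True) for c in calls])
        with pytest.raises(ValueError, match="single class"):
            train_classifier(labelset, seed=0)

    def test_too_small_input_rejected(self):
        calls = [simple_call(100 + i, call_id=f"c{i}") for i in range(10)]
        labelset = TruthLabelSet([(c, i % 2 == 0) for i, c in enumerate(calls)])
        with pytest.raises(ValueError, match=">= 30"):
            train_classifier(labelset, seed=0)

    def test_same_seed_reproduces_model_exactly(self):
        labelset = simulate_truthset(SimScenario(seed=7, n_truth=200))
        runs = []
        for _ in range(2):
            model, curve, metrics = train_classifier(
                labelset, seed=7, n_bootstrap=5, n_estimators=50)
            scored = classify(model, labelset.calls[:50])
            runs.append((metrics["threshold"], curve.points,
                         [c.annotations["rf_score"] for c in scored]))
        assert runs[0] == runs[1]

    def test_pr_curve_endpoints(self, trained_small):
        """At threshold 0 everything is positive: recall 1, precision = prevalence."""
        labelset, model, curve, _ = trained_small
        t0, p0, r0 = curve.points[0]
        assert t0 == 0.0
        assert r0 == 1.0
        prevalence = labelset.labels.mean()
        assert p0 == pytest.approx(prevalence, abs=0.05)

    def test_monotonicity_in_threshold(self, trained_small):
        labelset, model, _, _ = trained_small
        X = model.schema.matrix(labelset.calls)
        scores = model.estimator.decision_function(X)
        n_true = [int(np.sum(scores >= t)) for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert n_true == sorted(n_true, reverse=True)

    def test_score_at_threshold_labels_true(self, trained_small):
        _, model, _, _ = trained_small
        est = model.estimator
        X = np.zeros((1, len(model.schema.names)))
        score = est.decision_function(X)[0]
        expected = score >= est.threshold_
        assert est.predict(X)[0] == expected

    def test_label_swap_follows_feature_swap(self):
        """Swapping the class-conditional distributions swaps the labels."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(6, 1, (100, 3))])
        y = np.array([False] * 100 + [True] * 100)
        est = OperatingPointForest(n_estimators=50, n_bootstrap=5, random_state=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
            pred_orig = est.predict(X)
            est_sw = OperatingPointForest(n_estimators=50, n_bootstrap=5, random_state=3)
            est_sw.fit(X, ~y)
            pred_sw = est_sw.predict(X)
        assert np.mean(pred_orig == ~pred_sw) > 0.95

    def test_classify_requires_matching_schema(self, trained_small):
        _, model, _, _ = trained_small
        call = simple_call(100)
        call.annotations.clear()
        with pytest.raises(KeyError, match="schema mismatch"):
            classify(model, [call])
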