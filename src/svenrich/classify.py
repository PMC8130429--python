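"""Random-forest false-positive classification of SV calls.

A truth label set is built by window-intersecting independent call sets
(positives = junctions confirmed by all three platforms), features are
extracted from caller evidence plus repeat-distance annotations, and a
random forest is trained with a precision-recall operating point:

* the labeled set is split 2/3 train - 1/3 held-out (stratified, seeded);
* 100 bootstrap rounds re-partition the training portion 90%-10% and
  accumulate a mean precision-recall curve over a fixed threshold grid;
* the decision threshold is the smallest one whose bootstrap-mean precision
  reaches the target (default 96% precision / 99.5% recall operating point);
* the final forest is refit on the full training portion and evaluated once
  on the held-out third.

The estimator core (:class:`OperatingPointForest`) follows the scikit-learn
protocol (``fit``/``predict``/``get_params``) and composes with sklearn
pipelines; module-level functions adapt it to :class:`BreakpointCall`
objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, check_X_y

from .filters import DbEntry, overlaps
from .model import BreakpointCall, PipelineConfig, Side, canonicalize


# ---------------------------------------------------------------------------
# truth-set construction

def intersect_truthsets(set_1: Sequence[BreakpointCall],
                        set_2: Sequence[BreakpointCall],
                        set_3: Sequence[BreakpointCall],
                        window: int = 100) -> list:
    """Calls from ``set_1`` with a window-overlap partner in both other sets.

    Mirrors building a high-confidence germline truth set by intersecting
    call sets from three sequencing platforms; each junction appears once in
    the output.
    """
    for name, s in (("set_1", set_1), ("set_2", set_2), ("set_3", set_3)):
        if not s:
            warnings.warn(f"intersect_truthsets: {name} is empty", stacklevel=2)
    def entries(calls):
        out: dict = {}
        for c in calls:
            cc = canonicalize(c)
            out.setdefault((cc.end_a.chrom, cc.end_b.chrom), []).append(
                DbEntry(c.sample_id or "-", cc.end_a, cc.end_b))
        return out

    e2, e3 = entries(set_2), entries(set_3)
    result, seen = [], set()
    for call in set_1:
        c = canonicalize(call)
        key = c.junction_key
        if key in seen:
            continue
        pair = (c.end_a.chrom, c.end_b.chrom)
        if any(overlaps(c, e, window) for e in e2.get(pair, ())) and \
           any(overlaps(c, e, window) for e in e3.get(pair, ())):
            seen.add(key)
            result.append(call)
    return result


def label_against_truth(calls: Sequence[BreakpointCall],
                        positives: Sequence[BreakpointCall],
                        window: int = 100) -> "TruthLabelSet":
    """Label calls true/false by window-overlap with a positive truth set."""
    pos_entries: dict = {}
    for p in positives:
        cp = canonicalize(p)
        pos_entries.setdefault((cp.end_a.chrom, cp.end_b.chrom), []).append(
            DbEntry(p.sample_id or "-", cp.end_a, cp.end_b))
    items = []
    for call in calls:
        c = canonicalize(call)
        hit = any(overlaps(c, e, window)
                  for e in pos_entries.get((c.end_a.chrom, c.end_b.chrom), ()))
        items.append((call, hit))
    return TruthLabelSet(items)


@dataclass
class TruthLabelSet:
    """Labeled calls for classifier training: [(call, is_true), ...]."""

    items: list

    def __post_init__(self) -> None:
        for _, label in self.items:
            if not isinstance(label, (bool, np.bool_)):
                raise ValueError("labels must be boolean")

    @property
    def calls(self) -> list:
        return [c for c, _ in self.items]

    @property
    def labels(self) -> np.ndarray:
        return np.array([bool(l) for _, l in self.items])

    def __len__(self) -> int:
        return len(self.items)


# ---------------------------------------------------------------------------
# feature extraction

_ORIENT_CLASSES = (
    (Side.LEFT, Side.RIGHT),
    (Side.RIGHT, Side.LEFT),
    (Side.LEFT, Side.LEFT),
    (Side.RIGHT, Side.RIGHT),
)

_DISTANCE_FEATURES = ("dist_simple_repeat", "dist_gap", "dist_segmental_duplication")


@dataclass
class FeatureSchema:
    """Ordered feature extraction rules for SV calls.

    Default features cover the three evidence groups used for false-positive
    classification: read evidence (support count, mapping quality, read
    length, caller score), SV geometry (length with a cap for
    translocations, orientation one-hot) and repeat context (log1p distances
    to simple repeats, gaps and segmental duplications). Missing caller
    features fall back to documented defaults.
    """

    caller_feature_names: tuple = ("support", "mapq", "read_length", "score")
    caller_feature_defaults: Mapping[str, float] = field(
        default_factory=lambda: {"support": 0.0, "mapq": 0.0,
                                 "read_length": 0.0, "score": 0.0})
    length_cap: float = 1e8
    log_distances: bool = True
    include_orientation: bool = True
    include_distances: bool = True

    @property
    def names(self) -> list:
        names = list(self.caller_feature_names) + ["sv_length"]
        if self.include_orientation:
            names += [f"orient_{a.value[0]}{b.value[0]}" for a, b in _ORIENT_CLASSES]
        if self.include_distances:
            names += list(_DISTANCE_FEATURES)
        return names

    def vector(self, call: BreakpointCall) -> np.ndarray:
        c = canonicalize(call)
        values = []
        for name in self.caller_feature_names:
            if name in c.caller_features:
                values.append(float(c.caller_features[name]))
            elif name in self.caller_feature_defaults:
                values.append(float(self.caller_feature_defaults[name]))
            else:
                raise KeyError(f"unknown caller feature {name!r} with no default")
        length = c.length
        values.append(float(min(length, self.length_cap)) if length is not None
                      else self.length_cap)
        if self.include_orientation:
            pair = (c.end_a.side, c.end_b.side)
            values += [1.0 if pair == oc else 0.0 for oc in _ORIENT_CLASSES]
        if self.include_distances:
            for name in _DISTANCE_FEATURES:
                if name not in c.annotations:
                    raise KeyError(
                        f"call {c.id}: missing annotation {name!r}; run annotate_calls first")
                d = float(c.annotations[name])
                values.append(np.log1p(d) if self.log_distances else d)
        return np.asarray(values, dtype=float)

    def matrix(self, calls: Iterable[BreakpointCall]) -> np.ndarray:
        rows = [self.vector(c) for c in calls]
        if not rows:
            return np.empty((0, len(self.names)))
        return np.vstack(rows)


def extract_features(call: BreakpointCall, schema: Optional[FeatureSchema] = None) -> np.ndarray:
    return (schema or FeatureSchema()).vector(call)


# ---------------------------------------------------------------------------
# estimator

@dataclass
class PrCurve:
    """Bootstrap-mean precision/recall over a fixed threshold grid."""

    points: list  # [(threshold, precision, recall), ...] ascending threshold

    def __post_init__(self) -> None:
        for _, p, r in self.points:
            if not (0 <= p <= 1 and 0 <= r <= 1):
                raise ValueError("precision and recall must lie in [0, 1]")


def select_threshold(curve: PrCurve, target_precision: float,
                     target_recall: float) -> float:
    """Smallest threshold whose bootstrap-mean precision meets the target.

    When that point also meets the recall target it is the exact operating
    point; otherwise the nearest feasible point is returned with a warning.
    If no point reaches the precision target, the threshold of the
    maximum-precision point is returned with a warning.
    """
    if not curve.points:
        raise ValueError("empty precision-recall curve")
    feasible = [(t, p, r) for t, p, r in curve.points if p >= target_precision]
    if not feasible:
        t, p, r = max(curve.points, key=lambda x: (x[1], -x[0]))
        warnings.warn(
            f"no threshold reaches precision {target_precision:.3f}; "
            f"using max-precision point (t={t:.3f}, p={p:.3f}, r={r:.3f})",
            stacklevel=2)
        return t
    t, p, r = min(feasible, key=lambda x: x[0])
    if r < target_recall:
        warnings.warn(
            f"operating point reaches precision {p:.3f} but recall {r:.3f} < "
            f"target {target_recall:.3f}; using nearest feasible point",
            stacklevel=2)
    return t


def _precision_recall_at(scores, y, thresholds):
    """Vectorized precision/recall of (score >= t) over a threshold grid."""
    scores = np.asarray(scores)
    y = np.asarray(y, dtype=bool)
    pred = scores[None, :] >= thresholds[:, None]
    tp = (pred & y[None, :]).sum(axis=1).astype(float)
    fp = (pred & ~y[None, :]).sum(axis=1).astype(float)
    fn = ((~pred) & y[None, :]).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 1.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 1.0)
    return precision, recall


class OperatingPointForest(BaseEstimator, ClassifierMixin):
    """Random forest with a bootstrapped precision-recall operating point.

    Parameters
    ----------
    n_estimators : trees in the forest (default 500).
    target_precision, target_recall : operating point on the bootstrap-mean
        precision-recall curve (defaults 0.96 / 0.995).
    test_fraction : held-out fraction for final evaluation (default 1/3).
    n_bootstrap : bootstrap rounds for the curve (default 100), each a
        seeded 90%-10% re-partition of the training portion.
    bootstrap_test_fraction : test share within each bootstrap round (0.1).
    threshold_grid : score thresholds scanned for the curve.
    random_state : seed controlling split, bootstraps and forests; fixing it
        makes labels, curve and threshold bit-reproducible.

    Fitted attributes (trailing underscore): ``forest_``, ``threshold_``,
    ``pr_curve_``, ``holdout_precision_``, ``holdout_recall_``,
    ``holdout_accuracy_``, ``metadata_``.
    """

    def __init__(self, n_estimators: int = 500,
                 target_precision: float = 0.96,
                 target_recall: float = 0.995,
                 test_fraction: float = 1 / 3,
                 n_bootstrap: int = 100,
                 bootstrap_test_fraction: float = 0.1,
                 threshold_grid: Optional[np.ndarray] = None,
                 min_samples: int = 30,
                 random_state: Optional[int] = None):
        self.n_estimators = n_estimators
        self.target_precision = target_precision
        self.target_recall = target_recall
        self.test_fraction = test_fraction
        self.n_bootstrap = n_bootstrap
        self.bootstrap_test_fraction = bootstrap_test_fraction
        self.threshold_grid = threshold_grid
        self.min_samples = min_samples
        self.random_state = random_state

    def _grid(self) -> np.ndarray:
        if self.threshold_grid is not None:
            return np.asarray(self.threshold_grid, dtype=float)
        return np.round(np.linspace(0.0, 1.0, 201), 5)

    def _make_forest(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            random_state=int(seed),
            n_jobs=1,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y, dtype=bool))
        if len(y) < self.min_samples:
            raise ValueError(f"need >= {self.min_samples} labeled calls, got {len(y)}")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        ss = np.random.SeedSequence(self.random_state)
        split_seed, boot_seed, forest_seed = (
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=self.test_fraction, stratify=y,
            random_state=split_seed)

        grid = self._grid()
        prec_acc = np.zeros_like(grid)
        rec_acc = np.zeros_like(grid)
        boot_rng = np.random.SeedSequence(boot_seed).spawn(self.n_bootstrap)
        for b in range(self.n_bootstrap):
            seed_b = int(boot_rng[b].generate_state(1)[0] % (2**31 - 1))
            Xb_tr, Xb_te, yb_tr, yb_te = train_test_split(
                X_tr, y_tr, test_size=self.bootstrap_test_fraction,
                stratify=y_tr, random_state=seed_b)
            forest = self._make_forest(seed_b).fit(Xb_tr, yb_tr)
            scores = forest.predict_proba(Xb_te)[:, list(forest.classes_).index(True)]
            p, r = _precision_recall_at(scores, yb_te, grid)
            prec_acc += p
            rec_acc += r
        prec_acc /= self.n_bootstrap
        rec_acc /= self.n_bootstrap
        self.pr_curve_ = PrCurve(
            [(float(t), float(p), float(r)) for t, p, r in zip(grid, prec_acc, rec_acc)])
        self.threshold_ = float(select_threshold(
            self.pr_curve_, self.target_precision, self.target_recall))

        self.forest_ = self._make_forest(forest_seed).fit(X_tr, y_tr)
        self.classes_ = np.array([False, True])
        te_scores = self._scores(X_te)
        te_pred = te_scores >= self.threshold_
        tp = int(np.sum(te_pred & y_te))
        fp = int(np.sum(te_pred & ~y_te))
        fn = int(np.sum(~te_pred & y_te))
        tn = int(np.sum(~te_pred & ~y_te))
        self.holdout_precision_ = tp / (tp + fp) if tp + fp else 1.0
        self.holdout_recall_ = tp / (tp + fn) if tp + fn else 1.0
        self.holdout_accuracy_ = (tp + tn) / len(y_te)
        self.metadata_ = {
            "seed": self.random_state,
            "n_trees": self.n_estimators,
            "n_train": int(len(y_tr)),
            "n_test": int(len(y_te)),
            "n_bootstrap": self.n_bootstrap,
            "split": f"{1 - self.test_fraction:.3f}/{self.test_fraction:.3f} stratified",
        }
        return self

    def _scores(self, X) -> np.ndarray:
        proba = self.forest_.predict_proba(X)
        idx = list(self.forest_.classes_).index(True)
        return proba[:, idx]

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        s = self._scores(np.asarray(X))
        return np.column_stack([1 - s, s])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        """Label = (score >= threshold); a score exactly at the threshold is true."""
        return self.decision_function(X) >= self.threshold_


# ---------------------------------------------------------------------------
# call-level wrappers

@dataclass
class ClassifierModel:
    """Trained forest + decision threshold + frozen feature schema."""

    estimator: OperatingPointForest
    schema: FeatureSchema

    FORMAT_VERSION = 1

    @property
    def threshold(self) -> float:
        return self.estimator.threshold_

    def save(self, path: str) -> None:
        import joblib

        joblib.dump({"format_version": self.FORMAT_VERSION,
                     "estimator": self.estimator,
                     "schema": self.schema}, path)

    @classmethod
    def load(cls, path: str) -> "ClassifierModel":
        import joblib

        payload = joblib.load(path)
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model archive version in {path}")
        return cls(estimator=payload["estimator"], schema=payload["schema"])


def train_classifier(labels: TruthLabelSet,
                     config: Optional[PipelineConfig] = None,
                     seed: Optional[int] = None,
                     schema: Optional[FeatureSchema] = None,
                     **estimator_params) -> tuple:
    """Train the operating-point forest on a labeled call set.

    Returns ``(ClassifierModel, PrCurve, holdout_metrics)`` where the
    metrics dict reports precision, recall and accuracy on the held-out
    third.
    """
    config = config or PipelineConfig()
    schema = schema or FeatureSchema()
    est = OperatingPointForest(
        target_precision=config.operating_precision,
        target_recall=config.operating_recall,
        random_state=seed,
        **estimator_params,
    )
    X = schema.matrix(labels.calls)
    est.fit(X, labels.labels)
    model = ClassifierModel(estimator=est, schema=schema)
    metrics = {
        "precision": est.holdout_precision_,
        "recall": est.holdout_recall_,
        "accuracy": est.holdout_accuracy_,
        "threshold": est.threshold_,
        **est.metadata_,
    }
    return model, est.pr_curve_, metrics


def classify(model: ClassifierModel, calls: Sequence[BreakpointCall]) -> list:
    """Score calls and label them true/false at the model threshold.

    Returns new calls with ``rf_score`` and ``rf_label`` (1.0/0.0) added to
    their annotations (serialized to VCF INFO as RF_SCORE / RF_LABEL).
    """
    from dataclasses import replace

    if not calls:
        return []
    try:
        X = model.schema.matrix(calls)
    except KeyError as exc:
        raise KeyError(f"feature schema mismatch: {exc}") from exc
    scores = model.estimator.decision_function(X)
    out = []
    for call, score in zip(calls, scores):
        ann = dict(call.annotations)
        ann["rf_score"] = float(score)
        ann["rf_label"] = 1.0 if score >= model.threshold else 0.0
        out.append(replace(call, annotations=ann))
    return out
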