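"""MILES embedding and per-SV-type random-forest classification.

Bags are mapped into a bag-to-instance similarity space: entry (i, j) is the
absolute (L1) distance between the mean instance vector of bag i and reference
instance j, where the reference instances are all instances of the training
bags. A random forest trained on this embedding yields a bag-level classifier.
Performance is estimated by leave-one-patient-out cross-validation (all bags
of one patient form the test fold; the embedding reference and normalization
statistics come from the training folds only), and the operating point is the
probability threshold maximizing recall subject to a minimum precision on the
pooled CV predictions.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .features import Bag, FeatureSchema, apply_minmax, fit_minmax

logger = logging.getLogger("tadmil")

BAG_CAP = 700
MIN_PRECISION = 0.5
RF_PARAMS = {"n_estimators": 100, "max_features": "sqrt"}


def mean_instance(X: np.ndarray) -> np.ndarray:
    """Element-wise mean of a bag's instance vectors."""
    if X.shape[0] == 0:
        raise ValueError("empty bag has no mean instance")
    return X.mean(axis=0)


def miles_embed(
    bag_matrices: Sequence[np.ndarray],
    reference_instances: np.ndarray,
    metric: str = "l1",
) -> np.ndarray:
    """Bag-to-instance similarity matrix: distance from each bag's mean
    instance to every reference instance."""
    if not len(bag_matrices):
        return np.zeros((0, reference_instances.shape[0]))
    means = np.vstack([mean_instance(X) for X in bag_matrices])
    if means.shape[1] != reference_instances.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: bags have {means.shape[1]}, "
            f"reference instances have {reference_instances.shape[1]}"
        )
    dist = cdist(means, reference_instances, metric="cityblock" if metric == "l1" else "euclidean")
    return dist


def subsample_bags(bags: Sequence[Bag], cap: int = BAG_CAP, seed: int = 0) -> list[Bag]:
    """Uniformly subsample to at most ``cap`` bags, preserving the class
    ratio as closely as possible. Deterministic under the seed."""
    if len(bags) <= cap:
        return list(bags)
    rng = np.random.default_rng(seed)
    pos = [b for b in bags if b.label == 1]
    neg = [b for b in bags if b.label == 0]
    n_pos = int(round(cap * len(pos) / len(bags)))
    n_pos = min(max(n_pos, cap - len(neg)), len(pos), cap)
    n_neg = cap - n_pos
    keep: list[Bag] = []
    for group, n in ((pos, n_pos), (neg, n_neg)):
        idx = rng.choice(len(group), size=n, replace=False)
        keep.extend(group[i] for i in sorted(idx))
    keep.sort(key=lambda b: (b.sv_type, b.patient, b.pair.sv_id, b.pair.gene_id))
    logger.info("subsampled %d bags to %d (cap %d)", len(bags), len(keep), cap)
    return keep


@dataclass
class CVPrediction:
    pair_id: str
    patient: str
    y_true: int
    proba: float
    #: whether the bag was part of the class-balanced CV set (AUC is computed
    #: on these) or an extra labeled bag of the held-out patient scored for
    #: operating-point selection and downstream analyses
    in_balanced: bool = True


@dataclass
class ModelBundle:
    """A trained per-SV-type classifier with everything needed to embed and
    score unseen bags identically."""

    sv_type: str
    model: RandomForestClassifier
    schema: FeatureSchema
    minmax: tuple[np.ndarray, np.ndarray]
    reference_instances: np.ndarray
    reference_ids: list[tuple[str, int]]  # (pair_id, instance index within bag)
    metric: str = "l1"
    operating_point: Optional[float] = None
    cv_predictions: list[CVPrediction] = field(default_factory=list)
    version: int = 1

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ModelBundle":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def _normalize_and_embed(
    train_bags: Sequence[Bag], test_bags: Sequence[Bag], metric: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray], list[tuple[str, int]]]:
    """Fit normalization on training bags, build the reference instance set
    from them, and embed both sides."""
    stacked = np.vstack([b.X for b in train_bags])
    mn, mx = fit_minmax(stacked)
    train_X = [apply_minmax(b.X, mn, mx) for b in train_bags]
    test_X = [apply_minmax(b.X, mn, mx) for b in test_bags]
    refs = np.vstack(train_X)
    ref_ids = [
        (b.pair_id, i) for b in train_bags for i in range(b.X.shape[0])
    ]
    E_train = miles_embed(train_X, refs, metric)
    E_test = miles_embed(test_X, refs, metric)
    return E_train, E_test, refs, (mn, mx), ref_ids


def train_model(
    bags: Sequence[Bag],
    sv_type: str,
    rf_params: Optional[dict] = None,
    seed: int = 0,
    metric: str = "l1",
    schema: Optional[FeatureSchema] = None,
) -> ModelBundle:
    """Train the final classifier on all given bags of one SV type."""
    labels = np.array([b.label for b in bags])
    if len(set(labels.tolist())) < 2:
        raise ValueError(f"{sv_type}: need both classes to train")
    E, _, refs, minmax, ref_ids = _normalize_and_embed(bags, [], metric)
    rf = RandomForestClassifier(random_state=seed, **(rf_params or RF_PARAMS))
    rf.fit(E, labels)
    return ModelBundle(
        sv_type=sv_type,
        model=rf,
        schema=schema,
        minmax=minmax,
        reference_instances=refs,
        reference_ids=ref_ids,
        metric=metric,
    )


def leave_one_patient_out_cv(
    bags: Sequence[Bag],
    sv_type: str,
    seed: int = 0,
    rf_params: Optional[dict] = None,
    metric: str = "l1",
    evaluation_bags: Optional[Sequence[Bag]] = None,
) -> list[CVPrediction]:
    """Pooled leave-one-patient-out predictions.

    Every fold re-fits normalization and rebuilds the embedding reference
    from the training patients only, so no information from the held-out
    patient leaks into the model. ``evaluation_bags`` may carry the full
    (unbalanced) labeled bag set: every fold additionally scores the held-out
    patient's extra bags, flagged ``in_balanced=False``, mirroring clinical
    use where all of a new patient's pairs are ranked.
    """
    patients = sorted({b.patient for b in bags})
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out CV needs >= 2 patients")
    extras_by_patient: dict[str, list[Bag]] = {}
    if evaluation_bags is not None:
        core_ids = {b.pair_id for b in bags}
        for b in evaluation_bags:
            if b.pair_id not in core_ids:
                extras_by_patient.setdefault(b.patient, []).append(b)
    predictions: list[CVPrediction] = []
    for patient in patients:
        test = [b for b in bags if b.patient == patient]
        extra = extras_by_patient.get(patient, [])
        flags = [True] * len(test) + [False] * len(extra)
        test = test + extra
        train = [b for b in bags if b.patient != patient]
        train_labels = np.array([b.label for b in train])
        if len(set(train_labels.tolist())) < 2:
            only = float(train_labels[0]) if len(train_labels) else 0.5
            logger.warning(
                "fold %s/%s: single-class training data; constant prediction", sv_type, patient
            )
            predictions.extend(
                CVPrediction(b.pair_id, patient, b.label, only, f)
                for b, f in zip(test, flags)
            )
            continue
        E_train, E_test, _, _, _ = _normalize_and_embed(train, test, metric)
        rf = RandomForestClassifier(random_state=seed, **(rf_params or RF_PARAMS))
        rf.fit(E_train, train_labels)
        proba = rf.predict_proba(E_test)[:, list(rf.classes_).index(1)]
        predictions.extend(
            CVPrediction(b.pair_id, patient, b.label, float(p), f)
            for b, p, f in zip(test, proba, flags)
        )
    return predictions


def compute_auc(cv_predictions: Sequence[CVPrediction]) -> float:
    """Rank-based (Mann-Whitney) AUC over pooled CV predictions; ties count
    one half."""
    y = [p.y_true for p in cv_predictions]
    s = [p.proba for p in cv_predictions]
    if len(set(y)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(y, s))


def select_operating_point(
    cv_predictions: Sequence[CVPrediction], min_precision: float = MIN_PRECISION
) -> Optional[float]:
    """The probability threshold maximizing recall subject to a minimum
    precision on pooled CV predictions. Recall ties resolve to the higher
    precision, then to the lower threshold.

    A call is positive when probability >= threshold. Returns None (with a
    warning) when no threshold reaches the precision floor.
    """
    y = np.array([p.y_true for p in cv_predictions])
    s = np.array([p.proba for p in cv_predictions])
    n_pos = int(y.sum())
    if n_pos == 0:
        logger.warning("no positive bags; operating point undefined")
        return None
    best: Optional[tuple[float, float, float]] = None  # (recall, precision, -threshold)
    for t in np.unique(s):
        calls = s >= t
        tp = int((calls & (y == 1)).sum())
        if calls.sum() == 0:
            continue
        precision = tp / calls.sum()
        recall = tp / n_pos
        if precision >= min_precision:
            cand = (recall, precision, -float(t))
            if best is None or cand > best:
                best = cand
    if best is None:
        logger.warning("no threshold reaches precision %.2f", min_precision)
        return None
    return -best[2]


def predict(bundle: ModelBundle, new_bags: Sequence[Bag]) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and operating-point calls for unseen bags encoded with
    the bundle's schema."""
    if not new_bags:
        return np.zeros(0), np.zeros(0, dtype=bool)
    for b in new_bags:
        if b.X.shape[1] != bundle.reference_instances.shape[1]:
            raise ValueError(
                f"bag {b.pair_id}: {b.X.shape[1]} features, bundle expects "
                f"{bundle.reference_instances.shape[1]}"
            )
    mn, mx = bundle.minmax
    X = [apply_minmax(b.X, mn, mx) for b in new_bags]
    E = miles_embed(X, bundle.reference_instances, bundle.metric)
    proba = bundle.model.predict_proba(E)[:, list(bundle.model.classes_).index(1)]
    threshold = bundle.operating_point if bundle.operating_point is not None else 0.5
    return proba, proba >= threshold


def rf_instance_importance(bundle: ModelBundle) -> list[tuple[float, str, int]]:
    """Per-reference-instance importance, descending.

    The forest's impurity importances (which sum to 1) live on embedding
    columns; each column corresponds to one reference instance.
    """
    imp = bundle.model.feature_importances_
    ranked = sorted(
        zip(imp.tolist(), (pid for pid, _ in bundle.reference_ids), (i for _, i in bundle.reference_ids)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    return ranked


def fit_sv_type_model(
    bags: Sequence[Bag],
    sv_type: str,
    seed: int = 0,
    min_precision: float = MIN_PRECISION,
    rf_params: Optional[dict] = None,
    metric: str = "l1",
    cap: int = BAG_CAP,
    evaluation_bags: Optional[Sequence[Bag]] = None,
) -> ModelBundle:
    """Subsample, cross-validate, pick the operating point, and train the
    final model for one SV type.

    The operating point is selected on the pooled predictions of all labeled
    bags (``evaluation_bags``) when given; with only balanced bags, the
    precision floor is met trivially at the base rate and the threshold
    degenerates to the minimum score.
    """
    of_type = [b for b in bags if b.sv_type == sv_type]
    of_type = subsample_bags(of_type, cap=cap, seed=seed)
    eval_of_type = (
        [b for b in evaluation_bags if b.sv_type == sv_type] if evaluation_bags is not None else None
    )
    cv = leave_one_patient_out_cv(
        of_type, sv_type, seed=seed, rf_params=rf_params, metric=metric,
        evaluation_bags=eval_of_type,
    )
    bundle = train_model(of_type, sv_type, rf_params=rf_params, seed=seed, metric=metric)
    bundle.cv_predictions = cv
    bundle.operating_point = select_operating_point(cv, min_precision)
    return bundle
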