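"""Dataset assembly, the classifier zoo, evaluation, and cluster filtering.

The classifier distinguishes true homology (H) from non-homology (NH)
clusters from their ten MSA attributes.  Five base learners (a small
feed-forward network, a linear-kernel SVM, a 10-tree random forest,
Gaussian Naive Bayes and logistic regression) are complemented by two
stacking meta-classifiers whose meta-learner is a small feed-forward
network fed the out-of-fold (10-fold) class probabilities of the base
learners — one stack including logistic regression among its bases, one
without.

Two training-set compositions are supported: EQUAL (the five generative
classes in equal counts) and PROP (half H, the other half split equally
among the four NH flavours); either is then split 80/10/10 into
train/validation/test by unstratified random sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cluster_io import Cluster, Provenance
from .features import FEATURE_NAMES, AminoClassScheme, DEFAULT_SCHEME, feature_table
from .msa_align import AlignParams
from .randomness import RandomnessParams

logger = logging.getLogger(__name__)

MODEL_KINDS = (
    "mlp",
    "svm",
    "random_forest",
    "naive_bayes",
    "logistic",
    "stack_with_lr",
    "stack_without_lr",
)

#: provenance classes making up the EQUAL composition
EQUAL_CLASSES = (
    Provenance.H_SYNTH,
    Provenance.NH_RANDOM,
    Provenance.NH_EVOLVED_0,
    Provenance.NH_EVOLVED_25,
    Provenance.NH_EVOLVED_50,
)
NH_CLASSES = EQUAL_CLASSES[1:]


@dataclass(frozen=True)
class DatasetSpec:
    scheme: Literal["EQUAL", "PROP"] = "EQUAL"
    n_total: int = 500
    seed: int = 0

    def class_counts(self) -> dict[Provenance, int]:
        if self.n_total == 0:
            return {c: 0 for c in EQUAL_CLASSES}
        if self.scheme == "EQUAL":
            if self.n_total % 5:
                raise ValueError("EQUAL composition needs n_total divisible by 5")
            per = self.n_total // 5
            return {c: per for c in EQUAL_CLASSES}
        if self.scheme == "PROP":
            if self.n_total % 8:
                raise ValueError("PROP composition needs n_total divisible by 8")
            counts = {Provenance.H_SYNTH: self.n_total // 2}
            counts.update({c: self.n_total // 8 for c in NH_CLASSES})
            return counts
        raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.8
    valid_frac: float = 0.1
    test_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.valid_frac + self.test_frac
        if not np.isclose(total, 1.0):
            raise ValueError(f"split fractions sum to {total}, not 1")


@dataclass
class TrainedModel:
    """A fitted classifier with its frozen feature schema."""

    kind: str
    estimator: object
    feature_schema: tuple[str, ...] = FEATURE_NAMES
    seed: int = 0

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_schema if f not in table.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        return table.loc[:, list(self.feature_schema)].to_numpy(dtype=float)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._matrix(table))

    def predict_proba_h(self, table: pd.DataFrame) -> np.ndarray | None:
        """P(H) per row, or None if the estimator has no probabilities."""
        if not hasattr(self.estimator, "predict_proba"):
            return None
        proba = self.estimator.predict_proba(self._matrix(table))
        classes = list(self.estimator.classes_)
        return proba[:, classes.index("H")]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "kind": self.kind,
                "estimator": self.estimator,
                "feature_schema": self.feature_schema,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        return cls(**payload)


@dataclass(frozen=True)
class EvaluationReport:
    accuracy: float
    confusion: pd.DataFrame  # rows: true H/NH, cols: predicted H/NH
    per_class: pd.DataFrame  # precision/recall per class

    @property
    def n_instances(self) -> int:
        return int(self.confusion.to_numpy().sum())


def assemble_dataset(
    h: list[Cluster],
    nh_by_type: dict[Provenance, list[Cluster]],
    spec: DatasetSpec,
    scheme: AminoClassScheme = DEFAULT_SCHEME,
    rparams: RandomnessParams | None = None,
    align_params: AlignParams | None = None,
) -> pd.DataFrame:
    """Sample the requested composition from the pools and featurize it."""
    counts = spec.class_counts()
    pools = {Provenance.H_SYNTH: h, **nh_by_type}
    rng = np.random.default_rng(spec.seed)
    chosen: list[Cluster] = []
    shortfalls = []
    for prov, n_needed in counts.items():
        pool = pools.get(prov, [])
        if len(pool) < n_needed:
            shortfalls.append(f"{prov.value}: need {n_needed}, have {len(pool)}")
            continue
        idx = rng.choice(len(pool), size=n_needed, replace=False)
        chosen.extend(pool[int(i)] for i in sorted(idx))
    if shortfalls:
        raise ValueError("insufficient cluster pools: " + "; ".join(shortfalls))
    if not chosen:
        return pd.DataFrame(
            columns=["cluster_id", *FEATURE_NAMES, "label", "provenance"]
        )
    return feature_table(
        chosen, scheme=scheme, rparams=rparams, align_params=align_params
    )


def split(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Unstratified random 80/10/10 partition; remainder goes to train."""
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    n_valid = int(np.floor(spec.valid_frac * n))
    n_test = int(np.floor(spec.test_frac * n))
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    valid_idx = order[:n_valid]
    test_idx = order[n_valid : n_valid + n_test]
    train_idx = order[n_valid + n_test :]
    return (
        table.iloc[np.sort(train_idx)].reset_index(drop=True),
        table.iloc[np.sort(valid_idx)].reset_index(drop=True),
        table.iloc[np.sort(test_idx)].reset_index(drop=True),
    )


def _hidden_units(n_features: int, n_classes: int = 2) -> int:
    # the conventional 'a' sizing: (attributes + classes) / 2
    return max(1, (n_features + n_classes) // 2)


def _base_estimators(seed: int, n_features: int) -> dict[str, object]:
    h = _hidden_units(n_features)
    return {
        "mlp": Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=(h,),
                        solver="sgd",
                        learning_rate_init=0.1,
                        momentum=0.05,
                        nesterovs_momentum=False,
                        max_iter=3000,
                        random_state=seed,
                    ),
                ),
            ]
        ),
        "svm": Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    # Platt-calibrated so the stack can consume probabilities
                    CalibratedClassifierCV(
                        SVC(kernel="linear", C=1.0, random_state=seed),
                        ensemble=False,
                    ),
                ),
            ]
        ),
        "random_forest": RandomForestClassifier(
            n_estimators=10, random_state=seed
        ),
        "naive_bayes": GaussianNB(),
        "logistic": Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(C=1e8, max_iter=1000)),
            ]
        ),
    }


def _meta_mlp(seed: int, n_inputs: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(_hidden_units(n_inputs),),
        solver="sgd",
        learning_rate_init=0.3,
        momentum=0.2,
        nesterovs_momentum=False,
        max_iter=500,
        random_state=seed,
    )


def build_estimator(kind: str, seed: int = 0, n_features: int = len(FEATURE_NAMES)):
    """Unfitted estimator for one model kind (see MODEL_KINDS)."""
    bases = _base_estimators(seed, n_features)
    if kind in bases:
        return bases[kind]
    if kind in ("stack_with_lr", "stack_without_lr"):
        names = ["mlp", "random_forest", "naive_bayes", "svm"]
        if kind == "stack_with_lr":
            names.insert(1, "logistic")
        estimators = [(n, bases[n]) for n in names]
        return StackingClassifier(
            estimators=estimators,
            final_estimator=_meta_mlp(seed, 2 * len(names)),
            cv=10,
            stack_method="predict_proba",
            n_jobs=None,
        )
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def train(
    kind: str,
    train_table: pd.DataFrame,
    seed: int = 0,
    feature_schema: Sequence[str] = FEATURE_NAMES,
) -> TrainedModel:
    """Fit one classifier on a labeled feature table (H vs NH)."""
    y = train_table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table contains a single class")
    schema = tuple(feature_schema)
    estimator = build_estimator(kind, seed=seed, n_features=len(schema))
    X = train_table.loc[:, list(schema)].to_numpy(dtype=float)
    estimator.fit(X, y)
    return TrainedModel(
        kind=kind, estimator=estimator, feature_schema=schema, seed=seed
    )


def evaluate(model: TrainedModel, table: pd.DataFrame) -> EvaluationReport:
    """Accuracy, confusion matrix and per-class precision/recall."""
    y_true = table["label"].to_numpy()
    y_pred = model.predict(table)
    labels = ["H", "NH"]
    confusion = pd.DataFrame(
        0, index=labels, columns=labels, dtype=int
    )
    for t, p in zip(y_true, y_pred):
        confusion.loc[t, p] += 1
    total = confusion.to_numpy().sum()
    accuracy = float(np.trace(confusion.to_numpy()) / total)
    rows = {}
    for lab in labels:
        tp = confusion.loc[lab, lab]
        predicted = confusion[lab].sum()
        actual = confusion.loc[lab].sum()
        rows[lab] = {
            "precision": float(tp / predicted) if predicted else np.nan,
            "recall": float(tp / actual) if actual else np.nan,
            "support": int(actual),
        }
    return EvaluationReport(
        accuracy=accuracy,
        confusion=confusion,
        per_class=pd.DataFrame(rows).T,
    )


def learning_curve(
    kind: str,
    train_table: pd.DataFrame,
    valid_table: pd.DataFrame,
    fractions: Sequence[float] = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0),
    n_bootstrap: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrapped validation-accuracy curve over training-set fractions.

    Each replicate resamples floor(fraction × n) training rows with
    replacement (redrawing until both classes appear), refits, and
    scores the fixed validation set; the envelope is the min/max over
    replicates.
    """
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(train_table)
    records = []
    for frac in fractions:
        size = max(2, int(np.floor(frac * n)))
        accs = []
        for rep in range(n_bootstrap):
            if frac == 1.0 and n_bootstrap == 1:
                # degenerate curve: identical to a plain train+evaluate
                sample, model_seed = train_table, seed
            else:
                while True:
                    idx = rng.integers(0, n, size=size)
                    sample = train_table.iloc[idx]
                    if sample["label"].nunique() == 2:
                        break
                model_seed = int(rng.integers(0, 2**31 - 1))
            model = train(kind, sample, seed=model_seed)
            accs.append(evaluate(model, valid_table).accuracy)
        records.append(
            {
                "fraction": frac,
                "n_train": size,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "min_accuracy": float(np.min(accs)),
                "max_accuracy": float(np.max(accs)),
            }
        )
    return pd.DataFrame(records)


def feature_ablation(
    kind: str,
    train_table: pd.DataFrame,
    valid_table: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Validation accuracy of single-feature models, one row per feature."""
    records = []
    for feat in FEATURE_NAMES:
        model = train(kind, train_table, seed=seed, feature_schema=(feat,))
        acc = evaluate(model, valid_table).accuracy
        records.append({"feature": feat, "accuracy": acc})
    return pd.DataFrame(records)


@dataclass
class FilterResult:
    kept: list[Cluster]
    removed: list[Cluster]
    quarantined: list[tuple[Cluster, str]]
    manifest: pd.DataFrame


def filter_clusters(
    model: TrainedModel,
    clusters: Iterable[Cluster],
    threshold: float = 0.5,
    scheme: AminoClassScheme = DEFAULT_SCHEME,
    rparams: RandomnessParams | None = None,
    align_params: AlignParams | None = None,
) -> FilterResult:
    """Partition clusters into kept (predicted H) and removed (predicted NH).

    When the model exposes class probabilities, a cluster is kept iff
    P(H) ≥ threshold; otherwise the hard label decides.  Clusters whose
    features cannot be computed are quarantined, never silently dropped.
    """
    kept, removed, quarantined = [], [], []
    manifest_rows = []
    for cluster in clusters:
        try:
            table = feature_table(
                [cluster],
                scheme=scheme,
                rparams=rparams,
                align_params=align_params,
                with_labels=False,
            )
        except Exception as exc:  # noqa: BLE001 - quarantine any failure
            logger.warning(
                "quarantining cluster %s: %s", cluster.cluster_id, exc
            )
            quarantined.append((cluster, str(exc)))
            manifest_rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "predicted": "QUARANTINED",
                    "p_homology": np.nan,
                    "decision": "quarantine",
                }
            )
            continue
        proba = model.predict_proba_h(table)
        if proba is not None:
            p_h = float(proba[0])
            is_h = p_h >= threshold
        else:
            p_h = np.nan
            is_h = model.predict(table)[0] == "H"
        (kept if is_h else removed).append(cluster)
        manifest_rows.append(
            {
                "cluster_id": cluster.cluster_id,
                "predicted": "H" if is_h else "NH",
                "p_homology": p_h,
                "decision": "keep" if is_h else "remove",
            }
        )
    return FilterResult(
        kept=kept,
        removed=removed,
        quarantined=quarantined,
        manifest=pd.DataFrame(manifest_rows),
    )
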