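"""Two-stage neural inference: acute classification, then quantification.

Each test is summarized by the feature vector X_IN = per-condition average
normalized signals x_m plus the reagent batch ID (RID) and fabrication
batch ID (FID), which let the networks absorb batch-to-batch gain shifts.
An initial classifier decides whether the sample lies in the hsCRP range
(< 10 mg/L) or the acute-inflammation range (> 10 mg/L, where the sandwich
channel's hook effect makes naive quantification fold high concentrations
back onto low readings). hsCRP-range tests are routed to a quantification
network trained with a mean-squared-logarithmic-error objective — the
network regresses z = ln(1 + c), so squared error on z *is* the MSLE and
the inverse transform exp(z) - 1 enforces non-negative concentrations.
Acute tests are reported as acute with the classifier's sigmoid output as
the confidence score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import stratify_risk
from .feature_selection import TrainingSet, stratified_folds, ACUTE_THRESHOLD_MG_L
from .image_processing import SignalTable
from .nn import MLP, NetworkConfig

__all__ = [
    "NetworkConfig",
    "Preprocessing",
    "ModelBundle",
    "PredictionResult",
    "msle",
    "encode_batches",
    "build_feature_vector",
    "train_classifier",
    "train_quantifier",
    "train_quantifier_arrays",
    "train_model_bundle",
    "hyperparameter_search",
    "predict",
    "baseline_regression",
]


def msle(y_true, y_pred) -> float:
    """Mean-squared logarithmic error, mean of (ln(1+yhat) - ln(1+y))^2."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("msle: inputs must have equal length")
    if np.any(y_true < 0) or np.any(y_pred < 0):
        raise ValueError("msle: inputs must be >= 0")
    return float(np.mean((np.log1p(y_pred) - np.log1p(y_true)) ** 2))


def encode_batches(
    rid: np.ndarray,
    fid: np.ndarray,
    rid_categories: list | None = None,
    fid_categories: list | None = None,
) -> np.ndarray:
    """One-hot encode RID and FID labels (integer IDs carry no ordinality)."""
    rid = np.asarray(rid)
    fid = np.asarray(fid)
    rcats = sorted(set(rid.tolist())) if rid_categories is None else rid_categories
    fcats = sorted(set(fid.tolist())) if fid_categories is None else fid_categories
    for val in rid:
        if val not in rcats:
            raise ValueError(f"unseen RID value {val!r}")
    for val in fid:
        if val not in fcats:
            raise ValueError(f"unseen FID value {val!r}")
    R = np.column_stack([(rid == c).astype(float) for c in rcats])
    F = np.column_stack([(fid == c).astype(float) for c in fcats])
    return np.column_stack([R, F])


@dataclass
class Preprocessing:
    """Feature standardization + batch encoding, fit on training data only."""

    conditions: list[str]
    spot_subset: list[tuple[int, int]]
    mean: np.ndarray
    std: np.ndarray
    rid_categories: list
    fid_categories: list

    @classmethod
    def fit(
        cls,
        training: TrainingSet,
        spot_subset: list[tuple[int, int]] | None = None,
        conditions: list[str] | None = None,
    ) -> "Preprocessing":
        """Fit scaling/encoding on training data.

        ``spot_subset`` is the normalization pool. When omitted it defaults
        to the spots of the selected ``conditions`` (a membrane carrying
        only those channels), or the full grid if no conditions are named.
        """
        if spot_subset is not None:
            spots = list(spot_subset)
        elif conditions is not None:
            keep = set(conditions)
            spots = [
                rc
                for rc, cond in zip(training.spots, training.spot_conditions)
                if cond in keep
            ]
        else:
            spots = list(training.spots)
        X_cond, conds = training.condition_features(spots, conditions)
        mean = X_cond.mean(axis=0)
        std = X_cond.std(axis=0)
        std[std == 0] = 1.0
        return cls(
            conditions=conds,
            spot_subset=spots,
            mean=mean,
            std=std,
            rid_categories=sorted(set(training.rid.tolist())),
            fid_categories=sorted(set(training.fid.tolist())),
        )

    def transform_training(self, training: TrainingSet) -> np.ndarray:
        X_cond, _ = training.condition_features(self.spot_subset, self.conditions)
        B = encode_batches(
            training.rid, training.fid, self.rid_categories, self.fid_categories
        )
        return np.column_stack([(X_cond - self.mean) / self.std, B])

    def transform_test(
        self, signal_table: SignalTable, rid: int, fid: int
    ) -> np.ndarray:
        x = build_feature_vector(signal_table, self, rid, fid)
        return x[None, :]

    @property
    def n_features(self) -> int:
        return len(self.conditions) + len(self.rid_categories) + len(
            self.fid_categories
        )

    def to_dict(self) -> dict:
        return {
            "conditions": self.conditions,
            "spot_subset": [list(rc) for rc in self.spot_subset],
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "rid_categories": self.rid_categories,
            "fid_categories": self.fid_categories,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessing":
        return cls(
            conditions=list(d["conditions"]),
            spot_subset=[tuple(rc) for rc in d["spot_subset"]],
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            rid_categories=list(d["rid_categories"]),
            fid_categories=list(d["fid_categories"]),
        )


def build_feature_vector(
    signal_table: SignalTable,
    preprocessing: Preprocessing,
    rid: int,
    fid: int,
) -> np.ndarray:
    """X_IN for one test: standardized x_m over the bundle's spots + RID/FID.

    Normalization uses the same spot subset fed to the model, so a membrane
    fabricated with only the selected spots produces identical features.
    """
    if not signal_table.qc_pass:
        raise ValueError(
            f"test {signal_table.test_id!r} failed QC: {signal_table.qc_reasons}"
        )
    x_m = signal_table.condition_averages(preprocessing.spot_subset)
    missing = [c for c in preprocessing.conditions if c not in x_m.index]
    if missing:
        raise ValueError(f"missing condition(s) in signal table: {missing}")
    vals = x_m.loc[preprocessing.conditions].to_numpy()
    z = (vals - preprocessing.mean) / preprocessing.std
    B = encode_batches(
        np.array([rid]), np.array([fid]),
        preprocessing.rid_categories, preprocessing.fid_categories,
    )
    return np.concatenate([z, B[0]])


# ---------------------------------------------------------------------------
# training


def train_quantifier_arrays(X: np.ndarray, y: np.ndarray,
                            config: NetworkConfig | None = None) -> MLP:
    """Fit the quantification net on prepared features; target z = ln(1+c)."""
    config = config or NetworkConfig()
    if config.loss != "mse":
        raise ValueError("the quantifier uses the MSLE (squared-log) objective")
    if len(X) == 0:
        raise ValueError("empty training subset")
    model = MLP(config)
    model.fit(X, np.log1p(np.asarray(y, dtype=float)))
    return model


def train_quantifier(
    training: TrainingSet,
    preprocessing: Preprocessing,
    config: NetworkConfig | None = None,
) -> MLP:
    """Train the concentration regressor on hsCRP-range tests only.

    Acute samples are excluded: the quantifier's job is the 0-10 mg/L range
    and the classifier guards its input. Minimizing squared error on
    ln(1 + c) is exactly the MSLE objective on concentrations.
    """
    hs = ~training.acute
    if not hs.any():
        raise ValueError("no hsCRP-range tests to train the quantifier")
    X = preprocessing.transform_training(training.subset_tests(hs))
    return train_quantifier_arrays(X, training.concentration[hs], config)


def train_classifier(
    training: TrainingSet,
    preprocessing: Preprocessing,
    config: NetworkConfig | None = None,
) -> MLP:
    """Train the acute-vs-hsCRP classifier (sigmoid output = P(acute)).

    Acute training examples are typically rare (a handful among hundreds),
    so the binary cross-entropy is class-weighted to balance the two
    classes.
    """
    y = training.acute.astype(float)
    if len(set(y.tolist())) < 2:
        raise ValueError("classifier training needs both classes present")
    config = config or NetworkConfig(loss="bce")
    if config.loss != "bce":
        raise ValueError("the classifier uses the bce loss")
    X = preprocessing.transform_training(training)
    w = np.where(y == 1, len(y) / (2 * y.sum()), len(y) / (2 * (len(y) - y.sum())))
    model = MLP(config)
    model.fit(X, y, sample_weight=w)
    return model


# ---------------------------------------------------------------------------
# bundle + prediction


@dataclass
class ModelBundle:
    """Deployable model: feature subset, preprocessing, and both networks."""

    preprocessing: Preprocessing
    classifier: MLP
    quantifier: MLP
    classifier_config: NetworkConfig
    quantifier_config: NetworkConfig
    metadata: dict = field(default_factory=dict)

    @property
    def spot_subset(self) -> list[tuple[int, int]]:
        return self.preprocessing.spot_subset

    @property
    def conditions(self) -> list[str]:
        return self.preprocessing.conditions

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        doc = {
            "preprocessing": self.preprocessing.to_dict(),
            "classifier_config": self.classifier_config.__dict__ | {
                "hidden": list(self.classifier_config.hidden)
            },
            "quantifier_config": self.quantifier_config.__dict__ | {
                "hidden": list(self.quantifier_config.hidden)
            },
            "metadata": self.metadata,
        }
        (directory / "bundle.json").write_text(json.dumps(doc, indent=1))
        np.savez(directory / "classifier.npz", **self.classifier.to_arrays())
        np.savez(directory / "quantifier.npz", **self.quantifier.to_arrays())

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        doc = json.loads((directory / "bundle.json").read_text())
        ccfg = NetworkConfig(**{**doc["classifier_config"],
                                "hidden": tuple(doc["classifier_config"]["hidden"])})
        qcfg = NetworkConfig(**{**doc["quantifier_config"],
                                "hidden": tuple(doc["quantifier_config"]["hidden"])})
        with np.load(directory / "classifier.npz") as z:
            clf = MLP.from_arrays(dict(z), ccfg)
        with np.load(directory / "quantifier.npz") as z:
            quant = MLP.from_arrays(dict(z), qcfg)
        return cls(
            Preprocessing.from_dict(doc["preprocessing"]),
            clf,
            quant,
            ccfg,
            qcfg,
            doc.get("metadata", {}),
        )


def train_model_bundle(
    training: TrainingSet,
    spot_subset: list[tuple[int, int]] | None = None,
    conditions: list[str] | None = None,
    classifier_config: NetworkConfig | None = None,
    quantifier_config: NetworkConfig | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Fit preprocessing, classifier and quantifier into one bundle."""
    from dataclasses import replace

    # a small, strongly regularized classifier places the acute decision
    # boundary smoothly across the wide feature gap between the hsCRP range
    # and the spiked acute cluster, instead of wherever a high-variance fit
    # happens to land
    classifier_config = classifier_config or NetworkConfig(
        loss="bce", hidden=(16,), dropout=0.0, l2=1e-2, epochs=3000,
        patience=400, seed=seed,
    )
    quantifier_config = quantifier_config or NetworkConfig(seed=seed)
    if classifier_config.seed != seed:
        classifier_config = replace(classifier_config, seed=seed)
    if quantifier_config.seed != seed:
        quantifier_config = replace(quantifier_config, seed=seed + 1)
    prep = Preprocessing.fit(training, spot_subset, conditions)
    clf = train_classifier(training, prep, classifier_config)
    quant = train_quantifier(training, prep, quantifier_config)
    return ModelBundle(
        prep, clf, quant, classifier_config, quantifier_config,
        metadata={"n_train": training.n_train, "seed": seed},
    )


@dataclass
class PredictionResult:
    """Routed inference output for one test."""

    mode: str  # "quantified" or "acute"
    concentration: float | None  # mg/L, quantified mode
    confidence: float  # P(acute) from the classifier
    risk_stratum: str

    def __post_init__(self) -> None:
        if self.mode not in ("quantified", "acute"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1]")
        if self.mode == "quantified" and (
            self.concentration is None or self.concentration < 0
        ):
            raise ValueError("quantified mode requires concentration >= 0")


def predict(
    bundle: ModelBundle,
    signal_table: SignalTable,
    rid: int | None = None,
    fid: int | None = None,
    threshold: float = 0.5,
) -> PredictionResult:
    """Classify-then-quantify routing for one QC-passing test."""
    rid = signal_table.rid if rid is None else rid
    fid = signal_table.fid if fid is None else fid
    X = bundle.preprocessing.transform_test(signal_table, rid, fid)
    p_acute = float(bundle.classifier.predict_proba(X)[0])
    if p_acute >= threshold:
        return PredictionResult("acute", None, p_acute, "acute")
    conc = float(max(np.expm1(bundle.quantifier.decision_function(X)[0]), 0.0))
    return PredictionResult("quantified", conc, p_acute, stratify_risk(conc).label)


# ---------------------------------------------------------------------------
# hyper-parameter search


def hyperparameter_search(
    training: TrainingSet,
    search_space: dict[str, list],
    n_draws: int,
    k: int = 5,
    seed: int = 0,
    spot_subset: list[tuple[int, int]] | None = None,
    conditions: list[str] | None = None,
):
    """Random search over NetworkConfig axes, scored by k-fold CV MSLE.

    ``search_space`` maps NetworkConfig field names (e.g. ``hidden``,
    ``dropout``, ``l2``, ``batch_size``, ``loss``) to candidate lists; each
    draw samples every axis uniformly. Returns ``(best_config, table)``
    where the table holds one row per draw with its CV MSLE and R^2.
    """
    import pandas as pd
    from dataclasses import replace

    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    folds = stratified_folds(training.concentration, training.fid, k, seed)
    prep = Preprocessing.fit(training, spot_subset, conditions)
    spots = prep.spot_subset
    conds = prep.conditions
    from .feature_selection import _cv_quantifier_score

    rows = []
    best_cfg, best_msle = None, np.inf
    for draw in range(n_draws):
        params = {
            name: values[rng.integers(len(values))]
            for name, values in sorted(search_space.items())
        }
        cfg = replace(NetworkConfig(seed=seed), **params)
        m, r2 = _cv_quantifier_score(training, spots, conds, cfg, folds)
        rows.append({"draw": draw, **params, "cv_msle": m, "cv_r2": r2})
        if m < best_msle:
            best_cfg, best_msle = cfg, m
    return best_cfg, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# baseline


@dataclass
class BaselineModel:
    """Ordinary least squares from X_IN to concentration.

    The first (reference) level of each one-hot batch block carries a zero
    coefficient: with an intercept present the full one-hot blocks are
    structurally collinear, so the reference levels are absorbed into it.
    """

    coef: np.ndarray
    intercept: float
    preprocessing: Preprocessing

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept

    def predict_table(self, signal_table: SignalTable, rid=None, fid=None) -> float:
        rid = signal_table.rid if rid is None else rid
        fid = signal_table.fid if fid is None else fid
        X = self.preprocessing.transform_test(signal_table, rid, fid)
        return float(self.predict_features(X)[0])


def baseline_regression(
    training: TrainingSet,
    spot_subset: list[tuple[int, int]] | None = None,
    conditions: list[str] | None = None,
) -> BaselineModel:
    """Standard multi-variable linear regression baseline (hsCRP range).

    Fit by least squares; a rank-deficient design triggers a warning and a
    pseudoinverse solution.
    """
    hs = ~training.acute
    if not hs.any():
        raise ValueError("empty training set")
    prep = Preprocessing.fit(training, spot_subset, conditions)
    X = prep.transform_training(training.subset_tests(hs))
    # drop the reference level of each one-hot batch block (collinear with
    # the intercept by construction)
    n_cond = len(prep.conditions)
    rid_ref = n_cond
    fid_ref = n_cond + len(prep.rid_categories)
    keep = [i for i in range(X.shape[1]) if i not in (rid_ref, fid_ref)]
    A = np.column_stack([X[:, keep], np.ones(len(X))])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient design; using pseudoinverse fit")
    beta, *_ = np.linalg.lstsq(A, training.concentration[hs], rcond=None)
    coef = np.zeros(X.shape[1])
    coef[keep] = beta[:-1]
    return BaselineModel(coef=coef, intercept=float(beta[-1]),
                         preprocessing=prep)
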