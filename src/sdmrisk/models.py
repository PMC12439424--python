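"""The four suitability learners behind one fit/predict contract.

GLM is an unpenalized binomial logistic regression on linear terms; RF a
probability random forest; BRT stochastic gradient-boosted trees; SVM an
RBF margin classifier with Platt probability calibration. GLM and SVM run
behind a standardizing scaler. All return the class-1 (presence)
probability, so every map lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grid import EnvStack, RasterGrid
from .occurrences import SplitSet

log = logging.getLogger(__name__)

ALGORITHMS = ("GLM", "RF", "BRT", "SVM")


def _make_estimator(algorithm: str, seed: int, hyperparameters: dict | None):
    hp = dict(hyperparameters or {})
    if algorithm == "GLM":
        hp.setdefault("C", np.inf)  # unpenalized maximum likelihood
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, **hp))
    if algorithm == "RF":
        hp.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=seed, **hp)
    if algorithm == "BRT":
        hp.setdefault("n_estimators", 200)
        hp.setdefault("learning_rate", 0.05)
        hp.setdefault("subsample", 0.75)
        return GradientBoostingClassifier(random_state=seed, **hp)
    if algorithm == "SVM":
        # Platt-calibrated RBF margin classifier
        return make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(SVC(random_state=seed, **hp), ensemble=False))
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class FittedModel:
    """A trained learner plus the metadata needed to reuse it safely."""

    algorithm: str
    replicate_id: int
    predictor_names: list[str]
    estimator: object
    n_presence: int = 0
    n_background: int = 0
    seed: int = 0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Presence probability for rows of the training predictor set."""
        missing = [n for n in self.predictor_names if n not in X.columns]
        if missing:
            raise KeyError(f"missing predictors: {missing}")
        Xs = X[self.predictor_names]
        if not np.all(np.isfinite(Xs.to_numpy(dtype=float))):
            raise ValueError("non-finite predictor values")
        proba = self.estimator.predict_proba(Xs)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]

    def metadata(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "replicate_id": self.replicate_id,
            "predictor_names": self.predictor_names,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "seed": self.seed,
        }


def fit(algorithm: str, X: pd.DataFrame, y: np.ndarray, replicate_id: int = 0,
        seed: int = 0, hyperparameters: dict | None = None) -> FittedModel:
    """Fit one learner on presence (1) / background (0) training rows."""
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training data")
    if not np.all(np.isfinite(X.to_numpy(dtype=float))):
        raise ValueError("non-finite predictor values in training data")
    if len(np.unique(y)) < 2:
        raise ValueError("training data holds a single class")
    est = _make_estimator(algorithm, seed, hyperparameters)
    est.fit(X, y.astype(int))
    return FittedModel(algorithm, replicate_id, list(X.columns), est,
                       n_presence=int(y.sum()), n_background=int((y == 0).sum()),
                       seed=seed)


def fit_split(algorithm: str, split: SplitSet, stack: EnvStack,
              predictor_names: list[str] | None = None, seed: int = 0,
              hyperparameters: dict | None = None) -> FittedModel:
    """Fit a learner on one replicate's training partition of a stack."""
    X, y = split.training_xy(stack)
    if predictor_names is not None:
        X = X[predictor_names]
    ok = np.all(np.isfinite(X.to_numpy(dtype=float)), axis=1)
    return fit(algorithm, X[ok], y[ok], split.replicate_id, seed, hyperparameters)


def predict_map(model: FittedModel, stack: EnvStack) -> RasterGrid:
    """Project a fitted model over a stack into a probability surface."""
    missing = [n for n in model.predictor_names if n not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks predictor layers: {missing}")
    df = stack.to_frame()[model.predictor_names]
    return stack.map_from_values(model.predict(df))


@dataclass
class ModelSet:
    """All (algorithm x replicate) fits, with per-cell failures recorded."""

    models: list[FittedModel] = field(default_factory=list)
    failures: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)


def fit_all(splits: list[SplitSet], stack: EnvStack,
            algorithms: tuple[str, ...] = ALGORITHMS,
            predictor_names: list[str] | None = None, seed: int = 0,
            hyperparameters: dict[str, dict] | None = None) -> ModelSet:
    """Fit every algorithm on every replicate; failures are logged, not fatal."""
    if not splits or not algorithms:
        raise ValueError("need at least one split and one algorithm")
    out = ModelSet()
    for split in splits:
        for alg in algorithms:
            alg_tag = sum(ord(c) for c in alg)  # stable across interpreter runs
            sub_seed = (seed * 1009 + split.replicate_id * 97 + alg_tag) % (2**31)
            try:
                out.models.append(fit_split(
                    alg, split, stack, predictor_names, sub_seed,
                    (hyperparameters or {}).get(alg)))
            except Exception as exc:  # noqa: BLE001 - error-isolation contract
                log.warning("fit failed for %s replicate %d: %s",
                            alg, split.replicate_id, exc)
                out.failures.append((alg, split.replicate_id, str(exc)))
    if not out.models:
        raise RuntimeError("every model fit failed")
    return out
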