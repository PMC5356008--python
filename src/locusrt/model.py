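"""ε-SVR retention model over locus vectors.

The regression function is f(x) = Σ_i β_i K(s_i, x) + b with the RBF kernel
K(u, v) = exp(−γ‖u − v‖²), fitted by minimizing the regularized risk
C·Σ L_ε(y_i − f(x_i)) + ½‖w‖² where L_ε is the ε-insensitive loss (residuals
inside the ε tube cost nothing). Hyperparameters (C, γ, ε) are selected by
exhaustive grid search under k-fold internal cross-validation on the
training RTs; the solver is libsvm via scikit-learn.

Because locus vectors are binary, ‖u − v‖² is the number of differing
entries, so the kernel depends only on how many (position, residue) loci two
peptides share. No feature scaling is applied — the inputs are already
{0, 1}.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import encoding
from .errors import ModelCompatibilityError, ModelFormatError, TrainingError
from .peptides import AMINO_ACIDS, Peptide, RTDataset

MODEL_FORMAT = "locusrt-svr"
MODEL_FORMAT_VERSION = 1

#: libsvm stopping tolerance, recorded in every model file.
DEFAULT_SOLVER_TOL = 1e-3


def rbf_kernel(u: Sequence[float], v: Sequence[float], gamma: float) -> float:
    """exp(−γ‖u − v‖²) for a single pair of equal-length vectors.

    For binary vectors the squared distance is the Hamming distance, so the
    value is exp(−γ · #differing entries); it is symmetric and in (0, 1].
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    d2 = float(np.sum((u - v) ** 2))
    return float(np.exp(-gamma * d2))


@dataclass(frozen=True)
class SVRHyperparams:
    """One (C, γ, ε) grid point.

    C is the regularization (punishment) constant trading empirical error
    against flatness; γ the RBF radius parameter; ε the tube size in minutes.
    """

    C: float
    gamma: float
    epsilon: float

    def __post_init__(self) -> None:
        for name in ("C", "gamma", "epsilon"):
            v = float(getattr(self, name))
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class HyperparamGrid:
    """Exhaustive search ranges with k-fold internal cross-validation.

    The default ranges are C ∈ {2^i : i = −8..8}, γ ∈ {2^i : i = −8..8},
    ε ∈ {10^i : i = −3..−1} with 3 folds. All fields can be overridden.
    """

    C_values: tuple[float, ...] = tuple(2.0**i for i in range(-8, 9))
    gamma_values: tuple[float, ...] = tuple(2.0**i for i in range(-8, 9))
    epsilon_values: tuple[float, ...] = tuple(10.0**i for i in range(-3, 0))
    folds: int = 3
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.C_values and self.gamma_values and self.epsilon_values):
            raise ValueError("grid must be nonempty in every dimension")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def default(cls) -> "HyperparamGrid":
        return cls()

    @classmethod
    def coarse(cls, cv_seed: int = 0) -> "HyperparamGrid":
        """A small sub-grid of the default ranges for quick desk-scale runs."""
        return cls(
            C_values=(2.0**4, 2.0**6, 2.0**8),
            gamma_values=(2.0**-8, 2.0**-6, 2.0**-4),
            epsilon_values=(1e-2, 1e-1),
            cv_seed=cv_seed,
        )

    def points(self) -> Iterable[SVRHyperparams]:
        """Grid points in ascending (C, γ, ε) order.

        Iterating smallest-first makes the strict-improvement argmin below
        break ties toward the smallest C, then γ, then ε — the smoother
        model.
        """
        for C, g, e in itertools.product(
            sorted(self.C_values), sorted(self.gamma_values), sorted(self.epsilon_values)
        ):
            yield SVRHyperparams(C=C, gamma=g, epsilon=e)

    def size(self) -> int:
        return len(self.C_values) * len(self.gamma_values) * len(self.epsilon_values)

    def to_dict(self) -> dict:
        return {
            "C_values": list(self.C_values),
            "gamma_values": list(self.gamma_values),
            "epsilon_values": list(self.epsilon_values),
            "folds": self.folds,
            "cv_seed": self.cv_seed,
        }


@dataclass
class TrainedModel:
    """A fitted ε-SVR in dual form, plus its encoding provenance.

    Predictions are computed as f(x) = Σ β_i exp(−γ‖s_i − x‖²) + b from the
    stored support vectors s_i and dual coefficients β_i, so a model loaded
    from disk predicts through exactly the same arithmetic as a freshly
    trained one.
    """

    hyperparams: SVRHyperparams
    support_vectors: np.ndarray  # (n_sv, 500) binary
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    cv_score: float | None = None  # mean CV MSE at the chosen grid point
    training_size: int = 0
    solver_tol: float = DEFAULT_SOLVER_TOL
    grid: dict | None = None
    alphabet: str = AMINO_ACIDS
    flattening: str = encoding.FLATTENING

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()
        if self.support_vectors.ndim != 2 or self.support_vectors.shape[1] != encoding.N_FEATURES:
            raise ValueError(
                f"support vectors must be (n, {encoding.N_FEATURES}), "
                f"got {self.support_vectors.shape}"
            )
        if len(self.dual_coef) != len(self.support_vectors):
            raise ValueError("dual_coef length must match support vector count")

    def check_provenance(self) -> None:
        if self.alphabet != AMINO_ACIDS or self.flattening != encoding.FLATTENING:
            raise ModelCompatibilityError(
                "model encoding provenance (alphabet/flattening) does not match "
                "this encoder; refusing to predict"
            )


def _fit_svr(X: np.ndarray, y: np.ndarray, hp: SVRHyperparams, tol: float) -> SVR:
    svr = SVR(kernel="rbf", C=hp.C, gamma=hp.gamma, epsilon=hp.epsilon, tol=tol)
    svr.fit(X, y)
    return svr


def grid_search_train(
    train: RTDataset,
    grid: HyperparamGrid | None = None,
    *,
    solver_tol: float = DEFAULT_SOLVER_TOL,
) -> TrainedModel:
    """Select (C, γ, ε) by k-fold CV mean squared error and refit.

    Every grid point is scored on the same fold assignment (a random
    permutation drawn once from ``grid.cv_seed``), the argmin point is
    refitted on the full training set, and ties go to the smallest C, then
    γ, then ε. Deterministic given the seed.
    """
    if grid is None:
        grid = HyperparamGrid.default()
    n = len(train)
    if n < grid.folds:
        raise TrainingError(
            f"need at least {grid.folds} training peptides for "
            f"{grid.folds}-fold cross-validation, got {n}"
        )
    X = encoding.encode_batch(train.peptides)
    y = train.rts

    splits = list(
        KFold(n_splits=grid.folds, shuffle=True, random_state=grid.cv_seed).split(X)
    )
    best_hp: SVRHyperparams | None = None
    best_mse = np.inf
    for hp in grid.points():
        fold_mse = []
        for tr_idx, va_idx in splits:
            svr = _fit_svr(X[tr_idx], y[tr_idx], hp, solver_tol)
            resid = svr.predict(X[va_idx]) - y[va_idx]
            fold_mse.append(float(np.mean(resid**2)))
        mse = float(np.mean(fold_mse))
        if mse < best_mse:  # strict: first (smallest) point wins ties
            best_mse = mse
            best_hp = hp

    final = _fit_svr(X, y, best_hp, solver_tol)
    return TrainedModel(
        hyperparams=best_hp,
        support_vectors=final.support_vectors_,
        dual_coef=final.dual_coef_[0],
        intercept=float(final.intercept_[0]),
        cv_score=best_mse,
        training_size=n,
        solver_tol=solver_tol,
        grid=grid.to_dict(),
    )


def predict(model: TrainedModel, peptides: Iterable[Peptide | str]) -> np.ndarray:
    """Predict RTs (minutes) for peptides; order follows the input.

    Independent of batch composition: each row depends only on its own
    locus vector. Raises :class:`ModelCompatibilityError` when the model was
    built under a different encoding provenance.
    """
    model.check_provenance()
    X = encoding.encode_batch(peptides)
    if X.shape[0] == 0:
        return np.zeros(0, dtype=float)
    if len(model.support_vectors) == 0:
        # every training residual inside the epsilon tube: constant function
        return np.full(X.shape[0], model.intercept, dtype=float)
    K = _sk_rbf(X, model.support_vectors, gamma=model.hyperparams.gamma)
    return K @ model.dual_coef + model.intercept


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a model as a self-describing JSON document.

    Support vectors are binary, so each is stored as the sorted indices of
    its one-entries; floats are written with full round-trip precision.
    """
    doc = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "alphabet": model.alphabet,
        "flattening": model.flattening,
        "n_features": encoding.N_FEATURES,
        "hyperparams": {
            "C": model.hyperparams.C,
            "gamma": model.hyperparams.gamma,
            "epsilon": model.hyperparams.epsilon,
        },
        "solver_tol": model.solver_tol,
        "cv_score": model.cv_score,
        "training_size": model.training_size,
        "grid": model.grid,
        "intercept": model.intercept,
        "dual_coef": model.dual_coef.tolist(),
        "support_vectors": [
            np.flatnonzero(sv).tolist() for sv in model.support_vectors
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`.

    Raises :class:`ModelFormatError` on corrupt or unrecognized files. A
    provenance mismatch is *not* an error here — it surfaces as a
    :class:`ModelCompatibilityError` when the model is asked to predict.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    try:
        if doc["format"] != MODEL_FORMAT:
            raise ModelFormatError(f"not a {MODEL_FORMAT} file: {path}")
        if doc["format_version"] != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported model format version {doc['format_version']}"
            )
        n_features = doc["n_features"]
        svs = np.zeros((len(doc["support_vectors"]), n_features))
        for i, ones in enumerate(doc["support_vectors"]):
            svs[i, ones] = 1.0
        hp = SVRHyperparams(**doc["hyperparams"])
        return TrainedModel(
            hyperparams=hp,
            support_vectors=svs,
            dual_coef=np.array(doc["dual_coef"], dtype=float),
            intercept=float(doc["intercept"]),
            cv_score=doc.get("cv_score"),
            training_size=int(doc.get("training_size", 0)),
            solver_tol=float(doc.get("solver_tol", DEFAULT_SOLVER_TOL)),
            grid=doc.get("grid"),
            alphabet=doc["alphabet"],
            flattening=doc["flattening"],
        )
    except (KeyError, TypeError, IndexError, ValueError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"malformed model file {path}: {exc}") from exc
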