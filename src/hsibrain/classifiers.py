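"""The six supervised pixel classifiers and their coarse hyperparameter search.

Model kinds
-----------
``svm_l``    linear-kernel SVM (one-vs-one, pairwise-coupled Platt posteriors)
``svm_rbf``  RBF-kernel SVM (cost C and kernel width gamma)
``rf``       random forest (posteriors = tree-vote fractions)
``knn_e``    k-nearest-neighbour, Euclidean metric (neighbour-vote posteriors)
``knn_c``    k-nearest-neighbour, cosine metric
``dnn``      two-hidden-layer dense network, ReLU, SGD lr 0.1, 300 epochs

Every model emits per-pixel posteriors over the four tissue classes
(NT, TT, BV, BG) on the probability simplex. Hyperparameters are chosen per
fold by a coarse grid search maximising validation macro F1 with the BG
class excluded; ties go to the lowest-complexity grid point.

``ebeae``/``nebeae`` (linear/non-linear endmember-abundance unmixing) are
registered names whose published per-class settings are kept in
:data:`UNMIXING_SETTINGS`, but no estimator is provided for them here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .core import CLASS_CODES, HSCube, PixelDataset
from .metrics import macro_f1_no_bg

MODEL_KINDS = ("svm_l", "svm_rbf", "rf", "knn_e", "knn_c", "dnn")

# recognised but not provided here: endmember-abundance unmixing models
UNMIXING_KINDS = ("ebeae", "nebeae")

# Published per-class settings for the unmixing-based model kinds, recorded
# for configuration completeness; the estimators themselves are external.
UNMIXING_SETTINGS = {
    "endmembers": {"NT": 2, "TT": 2, "BV": 1, "BG": 3},
    "rho": {"NT": 0.3, "TT": 0.2, "BG": 0.01},
}


@dataclass
class HyperparamGrid:
    """Coarse search grids per model kind (log-decade / arithmetic ladders)."""

    svm_c: tuple[float, ...] = tuple(10.0**e for e in range(-3, 4))
    svm_gamma: tuple[float, ...] = tuple(10.0**e for e in range(-3, 4))
    rf_trees: tuple[int, ...] = tuple(range(50, 501, 50))
    knn_neighbors: tuple[int, ...] = tuple(range(1, 40, 2))
    dnn_hidden: tuple[int, ...] = (16, 32, 64, 128, 256)

    def points(self, kind: str) -> list[dict]:
        """Grid points for one model kind, in increasing-complexity order."""
        if kind == "svm_l":
            return [{"C": c} for c in sorted(self.svm_c)]
        if kind == "svm_rbf":
            return [
                {"C": c, "gamma": g}
                for c, g in product(sorted(self.svm_c), sorted(self.svm_gamma))
            ]
        if kind == "rf":
            return [{"n_estimators": t} for t in sorted(self.rf_trees)]
        if kind in ("knn_e", "knn_c"):
            return [{"n_neighbors": n} for n in sorted(self.knn_neighbors)]
        if kind == "dnn":
            return [{"hidden_size": h} for h in sorted(self.dnn_hidden)]
        raise ValueError(f"unknown model kind {kind!r}")


class SpectralClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style front end over the six pixel classifiers.

    Parameters mirror the per-kind hyperparameters; only the ones relevant
    to ``kind`` are used. ``predict_proba`` always returns four columns in
    class-code order (NT, TT, BV, BG); classes absent from training get
    probability zero.
    """

    def __init__(
        self,
        kind: str = "knn_e",
        C: float = 1.0,
        gamma: float | str = "scale",
        n_estimators: int = 100,
        n_neighbors: int = 5,
        hidden_size: int = 64,
        random_state: int | None = None,
    ) -> None:
        self.kind = kind
        self.C = C
        self.gamma = gamma
        self.n_estimators = n_estimators
        self.n_neighbors = n_neighbors
        self.hidden_size = hidden_size
        self.random_state = random_state

    def _build(self):
        if self.kind == "svm_l":
            return SVC(
                kernel="linear", C=self.C, probability=True,
                random_state=self.random_state,
            )
        if self.kind == "svm_rbf":
            return SVC(
                kernel="rbf", C=self.C, gamma=self.gamma, probability=True,
                random_state=self.random_state,
            )
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=self.random_state
            )
        if self.kind == "knn_e":
            return KNeighborsClassifier(
                n_neighbors=self.n_neighbors, metric="euclidean"
            )
        if self.kind == "knn_c":
            return KNeighborsClassifier(
                n_neighbors=self.n_neighbors, metric="cosine"
            )
        if self.kind == "dnn":
            # fixed training recipe: 2 hidden layers, ReLU, SGD lr 0.1,
            # mini-batch 128, full 300 epochs (no early stopping). Feature
            # standardization in front of the net keeps lr 0.1 stable and
            # plays the normalisation role batch-norm layers would.
            return make_pipeline(
                StandardScaler(),
                MLPClassifier(
                    hidden_layer_sizes=(self.hidden_size, self.hidden_size),
                    activation="relu",
                    solver="sgd",
                    learning_rate_init=0.1,
                    batch_size=128,
                    max_iter=300,
                    n_iter_no_change=300,
                    tol=0.0,
                    random_state=self.random_state,
                ),
            )
        if self.kind in UNMIXING_KINDS:
            raise NotImplementedError(
                f"{self.kind!r} is a registered unmixing model kind; its "
                "estimator is not provided by this package (settings in "
                "UNMIXING_SETTINGS)"
            )
        raise ValueError(
            f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}"
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate training set: a single class present")
        self.estimator_ = self._build()
        with warnings.catch_warnings():
            # the DNN runs a fixed epoch budget by design; SVC's LIBSVM-style
            # probability coupling is the calibration this model kind wants
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            self.estimator_.fit(X, y)
        self.classes_ = self.estimator_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        """Posteriors over the 4 canonical classes, renormalized to simplex."""
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"model trained on {self.n_features_in_} bands, got {X.shape[1]}"
            )
        raw = self.estimator_.predict_proba(X)
        probs = np.zeros((len(X), len(CLASS_CODES)))
        for j, code in enumerate(self.estimator_.classes_):
            probs[:, CLASS_CODES.index(int(code))] = raw[:, j]
        probs = np.clip(probs, 0.0, None)
        sums = probs.sum(axis=1, keepdims=True)
        # all-zero rows (possible for degenerate inputs) become uniform
        probs = np.where(sums > 0, probs / np.where(sums > 0, sums, 1.0), 0.25)
        return probs

    def predict(self, X):
        probs = self.predict_proba(X)
        return np.array(CLASS_CODES)[np.argmax(probs, axis=1)]


def train_model(
    kind: str,
    train: PixelDataset,
    hyperparams: dict | None = None,
    seed: int | None = None,
) -> SpectralClassifier:
    """Fit one model kind on a (reduced, balanced) training set."""
    clf = SpectralClassifier(kind=kind, random_state=seed, **(hyperparams or {}))
    clf.fit(train.spectra, train.labels)
    return clf


def predict_map(
    model: SpectralClassifier, cube: HSCube
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every pixel of a normalized cube.

    Returns
    -------
    probs : ndarray, (rows, cols, 4)
        Per-pixel posteriors in class-code order (NT, TT, BV, BG).
    class_map : ndarray, (rows, cols)
        Argmax class codes.
    """
    if cube.stage != "normalized":
        raise ValueError("predict_map expects a normalized cube")
    flat = model.predict_proba(cube.pixels())
    probs = flat.reshape(cube.rows, cube.cols, len(CLASS_CODES))
    class_map = np.array(CLASS_CODES)[np.argmax(flat, axis=1)].reshape(
        cube.rows, cube.cols
    )
    return probs, class_map


def coarse_search(
    kind: str,
    train: PixelDataset,
    val: PixelDataset,
    grid: HyperparamGrid | None = None,
    seed: int | None = None,
) -> tuple[dict, float]:
    """Pick the grid point maximising validation macro F1 (BG excluded).

    The grid is scanned in increasing-complexity order and a point must
    strictly beat the incumbent, so ties resolve to the smallest C/gamma/
    trees/neighbours/hidden size.
    """
    grid = grid or HyperparamGrid()
    if len(val) == 0:
        raise ValueError("empty validation set")
    best_hp: dict | None = None
    best_score = -np.inf
    for hp in grid.points(kind):
        model = train_model(kind, train, hp, seed=seed)
        pred = model.predict(val.spectra)
        score = macro_f1_no_bg(pred, val.labels)
        if score > best_score:
            best_score, best_hp = score, hp
    assert best_hp is not None
    return best_hp, float(best_score)
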