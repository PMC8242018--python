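"""Fuzzy Adaptive Resonance Theory clustering for analog inputs.

FuzzyART learns hyper-rectangular category templates from inputs in
[0, 1]^d.  Each input x is complement coded, I = (x, 1 - x), which fixes
its L1 norm at d and prevents category proliferation.  Committed
categories compete through the choice function

    T_j = |I ^ w_j| / (alpha + |w_j|)        (^ = componentwise min),

and the winner must also pass the vigilance test

    M_j = |I ^ w_j| / |I| >= rho

to resonate; a resonating category learns

    w_j <- beta (I ^ w_j) + (1 - beta) w_j,

so with fast learning (beta = 1) a category's weight is exactly the
componentwise min of every input it ever absorbed — the corners of the
smallest box containing its members.  If no category passes vigilance, a
new one is committed with w = I.  Higher vigilance rho therefore means
smaller boxes and more, finer categories.

Training presents rows in their given (chronological) order each epoch
and stops when an epoch changes no assignment and no weight; with
beta = 1 the updates are exact min operations, so exact comparison is a
safe convergence test.  Prediction never updates weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: sentinel returned by strict prediction when no category passes vigilance
UNCOMMITTED = -1


@dataclass(frozen=True)
class FuzzyARTParams:
    """rho: vigilance in [0, 1]; alpha: choice parameter > 0;
    beta: learning rate in (0, 1]; max_epochs: presentation cap."""

    rho: float = 0.73
    alpha: float = 0.001
    beta: float = 1.0
    max_epochs: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def complement_code(x: np.ndarray) -> np.ndarray:
    """Map x in [0, 1]^d to I = (x, 1 - x); |I| = d exactly."""
    x = np.asarray(x, dtype=float)
    if ((x < 0) | (x > 1)).any() or not np.isfinite(x).all():
        raise ValueError("inputs must lie in [0, 1]")
    return np.concatenate([x, 1.0 - x], axis=-1)


def choice_value(I: np.ndarray, w: np.ndarray, alpha: float) -> float:
    """T = |I ^ w| / (alpha + |w|)."""
    return float(np.minimum(I, w).sum() / (alpha + w.sum()))


def match_value(I: np.ndarray, w: np.ndarray) -> float:
    """M = |I ^ w| / |I|, in [0, 1]."""
    return float(np.minimum(I, w).sum() / I.sum())


class FuzzyART:
    """Unsupervised FuzzyART clusterer.

    Attributes after :meth:`fit`:

    d_            input dimension (before complement coding)
    W_            (n_categories, 2 d) weight matrix
    assignments_  training category index per row
    epochs_run_   epochs actually presented
    converged_    True if an epoch passed with no change
    events_       list of (category, row, w_before, w_after) learning
                  events (commits included), recorded only when
                  ``fit(..., record_events=True)``
    """

    def __init__(self, params: FuzzyARTParams | None = None) -> None:
        self.params = params or FuzzyARTParams()

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, record_events: bool = False) -> "FuzzyART":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2D array")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        coded = complement_code(X)
        n, d = X.shape
        p = self.params
        weights: list[np.ndarray] = []
        assignments = np.full(n, UNCOMMITTED, dtype=np.int64)
        self.events_: list[tuple[int, int, np.ndarray, np.ndarray]] | None \
            = [] if record_events else None

        epochs = 0
        converged = False
        for _ in range(p.max_epochs):
            epochs += 1
            changed = False
            for i in range(n):
                I = coded[i]
                j, w_new = self._resonate(I, weights)
                if j is None:
                    j = len(weights)
                    weights.append(I.copy())
                    changed = True
                    if self.events_ is not None:
                        self.events_.append((j, i, np.ones_like(I), I.copy()))
                else:
                    if not np.array_equal(w_new, weights[j]):
                        if self.events_ is not None:
                            self.events_.append((j, i, weights[j].copy(),
                                                 w_new.copy()))
                        weights[j] = w_new
                        changed = True
                if assignments[i] != j:
                    assignments[i] = j
                    changed = True
            if not changed:
                converged = True
                break

        self.d_ = d
        self.W_ = np.array(weights)
        self.assignments_ = assignments
        self.epochs_run_ = epochs
        self.converged_ = converged
        return self

    def _resonate(self, I: np.ndarray, weights: list[np.ndarray]
                  ) -> tuple[int | None, np.ndarray | None]:
        """Pick the resonating category for one input, or None to commit.

        Candidates are scanned in descending choice value, ties broken
        toward the lowest category index; the first to pass vigilance
        wins and its updated weight is returned (not yet applied).
        """
        if not weights:
            return None, None
        p = self.params
        W = np.array(weights)
        inter = np.minimum(I, W).sum(axis=1)
        T = inter / (p.alpha + W.sum(axis=1))
        order = np.argsort(-T, kind="stable")     # stable -> lowest index wins ties
        norm_I = I.sum()
        for j in order:
            M = inter[j] / norm_I
            if M >= p.rho:
                w_new = p.beta * np.minimum(I, W[j]) + (1 - p.beta) * W[j]
                return int(j), w_new
        return None, None

    # -- inference --------------------------------------------------------

    @property
    def n_categories(self) -> int:
        return len(self.W_)

    def predict(self, X: np.ndarray, mode: str = "nearest"
                ) -> tuple[np.ndarray, np.ndarray]:
        """Assign rows to trained categories without any weight update.

        ``nearest`` (default) returns the argmax-choice category
        regardless of vigilance, with its match value so callers can
        filter; ``strict`` requires the vigilance test and returns the
        UNCOMMITTED sentinel (with the best match value) otherwise.
        """
        if mode not in ("nearest", "strict"):
            raise ValueError("mode must be 'nearest' or 'strict'")
        if not hasattr(self, "W_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.d_:
            raise ValueError("dimension mismatch with the fitted model")
        coded = complement_code(X)
        p = self.params
        labels = np.empty(len(X), dtype=np.int64)
        matches = np.empty(len(X))
        norms = self.W_.sum(axis=1)
        for i, I in enumerate(coded):
            inter = np.minimum(I, self.W_).sum(axis=1)
            T = inter / (p.alpha + norms)
            M = inter / I.sum()
            order = np.argsort(-T, kind="stable")
            if mode == "nearest":
                j = int(order[0])
                labels[i], matches[i] = j, M[j]
            else:
                labels[i] = UNCOMMITTED
                matches[i] = M[int(order[0])]
                for j in order:
                    if M[j] >= p.rho:
                        labels[i], matches[i] = int(j), M[int(j)]
                        break
        return labels, matches

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"params": {"rho": self.params.rho, "alpha": self.params.alpha,
                          "beta": self.params.beta,
                          "max_epochs": self.params.max_epochs},
               "d": self.d_, "epochs_run": self.epochs_run_,
               "converged": self.converged_,
               "W": self.W_.tolist(),
               "assignments": self.assignments_.tolist()}
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FuzzyART":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        model = cls(FuzzyARTParams(**doc["params"]))
        model.d_ = int(doc["d"])
        model.W_ = np.array(doc["W"], dtype=float)
        model.assignments_ = np.array(doc["assignments"], dtype=np.int64)
        model.epochs_run_ = int(doc["epochs_run"])
        model.converged_ = bool(doc["converged"])
        return model
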