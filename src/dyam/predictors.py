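"""The two sub-learners of the fusion model.

* :class:`ElasticNetLogisticModel` — elasticnet-penalized logistic regression
  on fixed-length feature vectors (saga solver, C = 0.1, l1_ratio = 0.5,
  balanced class weights), with feature standardization fit on training data.
* :class:`AttentionMILClassifier` — attention-pooled multiple-instance
  logistic regression on variable-length bags of instances (lesions) sharing
  a patient-level label.  A single logistic scorer is shared across
  instances; a small gated network (tanh hidden layer, size 32) produces
  per-instance attention logits that compete through a softmax, and the bag
  score is the attention-weighted sum of instance probabilities.  Trained
  full-batch with Adam on balanced binary cross-entropy.

Both follow the sklearn estimator protocol (``fit`` / ``predict_proba`` /
``get_params``) so they compose with pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._optim import Adam, balanced_weights, bce_grad, sigmoid

__all__ = [
    "ElasticNetLogisticModel",
    "AttentionMILClassifier",
    "fit_elasticnet",
    "fit_mil_attention",
    "score",
]


class ElasticNetLogisticModel(BaseEstimator, ClassifierMixin):
    """Elasticnet logistic regression with train-fold standardization.

    Parameters mirror the reference configuration: ``C=0.1``,
    ``l1_ratio=0.5``, saga solver and balanced class weights.
    """

    def __init__(self, C: float = 0.1, l1_ratio: float = 0.5,
                 class_weight: str | None = "balanced", standardize: bool = True,
                 max_iter: int = 5000, tol: float = 1e-6, random_state: int = 0):
        self.C = C
        self.l1_ratio = l1_ratio
        self.class_weight = class_weight
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(X).any():
            raise ValueError("X contains missing entries")
        if len(np.unique(y)) < 2:
            raise ValueError("y must contain both classes")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        self.scaler_ = StandardScaler() if self.standardize else None
        Xs = self.scaler_.fit_transform(X) if self.scaler_ is not None else X
        self.lr_ = LogisticRegression(
            solver="saga", C=self.C, l1_ratio=self.l1_ratio,
            class_weight=self.class_weight if self.class_weight != "none" else None,
            max_iter=self.max_iter, tol=self.tol, random_state=self.random_state,
        )
        self.lr_.fit(Xs, y)
        self.classes_ = self.lr_.classes_
        self.coef_ = self.lr_.coef_
        self.intercept_ = self.lr_.intercept_
        return self

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def decision_function(self, X):
        return self.lr_.decision_function(self._transform(X))

    def predict_proba(self, X):
        return self.lr_.predict_proba(self._transform(X))

    def predict(self, X):
        return self.lr_.predict(self._transform(X))


class AttentionMILClassifier(BaseEstimator, ClassifierMixin):
    """Attention-pooled multiple-instance logistic regression.

    Bags are sequences of (k_i, d) instance matrices with one binary label
    per bag.  The bag score is sum_i a_i * sigmoid(w . x_i + b) with
    attention a = softmax(u . tanh(V x_i + c)); all parameters are shared
    across instances and optimized jointly.
    """

    def __init__(self, hidden_size: int = 32, learning_rate: float = 0.005,
                 steps: int = 250, l2: float = 0.005,
                 class_weight: str | None = "balanced", standardize: bool = True,
                 random_state: int = 0):
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.steps = steps
        self.l2 = l2
        self.class_weight = class_weight
        self.standardize = standardize
        self.random_state = random_state

    # -- bag plumbing ------------------------------------------------------
    @staticmethod
    def _check_bags(bags) -> tuple[list[np.ndarray], int]:
        checked = []
        dims = set()
        for i, bag in enumerate(bags):
            arr = np.asarray(bag, dtype=float)
            if arr.ndim != 2 or arr.shape[0] == 0:
                raise ValueError(f"bag {i} must be a nonempty (k, d) matrix")
            checked.append(arr)
            dims.add(arr.shape[1])
        if len(dims) != 1:
            raise ValueError(f"ragged instance feature lengths across bags: {sorted(dims)}")
        return checked, dims.pop()

    def _pad(self, bags: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        n = len(bags)
        kmax = max(b.shape[0] for b in bags)
        d = bags[0].shape[1]
        X = np.zeros((n, kmax, d))
        mask = np.zeros((n, kmax), dtype=bool)
        for i, b in enumerate(bags):
            X[i, : b.shape[0]] = b
            mask[i, : b.shape[0]] = True
        return X, mask

    # -- forward pass ------------------------------------------------------
    def _forward(self, X, mask):
        w, b, V, c, u, e = self.params_
        z = X @ w + b  # (n, K) instance logits
        p = sigmoid(z)
        h = np.tanh(X @ V.T + c)  # (n, K, hidden)
        t = h @ u + e  # (n, K) attention logits
        t = np.where(mask, t, -np.inf)
        tmax = t.max(axis=1, keepdims=True)
        expt = np.where(mask, np.exp(t - tmax), 0.0)
        a = expt / expt.sum(axis=1, keepdims=True)
        s = (a * np.where(mask, p, 0.0)).sum(axis=1)
        return s, a, p, h, z

    def fit(self, bags, y):
        bags, d = self._check_bags(bags)
        y = np.asarray(y, dtype=float)
        if len(y) != len(bags):
            raise ValueError("number of bags and labels differ")
        if len(np.unique(y)) < 2:
            raise ValueError("y must contain both classes")
        all_instances = np.vstack(bags)
        self.scaler_ = StandardScaler() if self.standardize else None
        if self.scaler_ is not None:
            self.scaler_.fit(all_instances)
            bags = [self.scaler_.transform(b) for b in bags]
        X, mask = self._pad(bags)
        rng = np.random.default_rng(self.random_state)
        hid = self.hidden_size
        self.params_ = [
            rng.normal(0.0, 0.1, d),          # w
            np.zeros(1),                       # b
            rng.normal(0.0, 0.1, (hid, d)),    # V
            np.zeros(hid),                     # c
            rng.normal(0.0, 0.1, hid),         # u
            np.zeros(1),                       # e
        ]
        weights = balanced_weights(y) if self.class_weight == "balanced" else np.ones(len(y))
        opt = Adam(self.params_, lr=self.learning_rate, l2=self.l2)
        self.loss_curve_ = []
        for _ in range(self.steps):
            s, a, p, h, z = self._forward(X, mask)
            loss, ds = bce_grad(s, y, weights)
            self.loss_curve_.append(loss)
            # risk branch
            dz = ds[:, None] * a * p * (1 - p) * mask  # (n, K)
            gw = np.einsum("nk,nkd->d", dz, X)
            gb = np.array([dz.sum()])
            # attention branch (softmax jacobian folded in)
            dt = ds[:, None] * a * (np.where(mask, p, 0.0) - s[:, None]) * mask
            gu = np.einsum("nk,nkh->h", dt, h)
            ge = np.array([dt.sum()])
            dpre = dt[..., None] * self.params_[4] * (1 - h**2)  # (n, K, hidden)
            gV = np.einsum("nkh,nkd->hd", dpre, X)
            gc = dpre.sum(axis=(0, 1))
            opt.step([gw, gb, gV, gc, gu, ge])
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d
        return self

    def _prepare(self, bags):
        bags, d = self._check_bags(bags)
        if d != self.n_features_in_:
            raise ValueError("instance feature length differs from training")
        if self.scaler_ is not None:
            bags = [self.scaler_.transform(b) for b in bags]
        return self._pad(bags)

    def predict_proba(self, bags):
        X, mask = self._prepare(bags)
        s, *_ = self._forward(X, mask)
        return np.column_stack([1 - s, s])

    def predict(self, bags):
        return (self.predict_proba(bags)[:, 1] >= 0.5).astype(int)

    def attention_weights(self, bags) -> list[np.ndarray]:
        """Normalized per-instance attention for each bag (sums to 1)."""
        X, mask = self._prepare(bags)
        _, a, *_ = self._forward(X, mask)
        return [a[i, mask[i]] for i in range(len(a))]


# -- thin functional wrappers ---------------------------------------------

def fit_elasticnet(X, y, **config) -> ElasticNetLogisticModel:
    """Fit the elasticnet logistic scorer (see :class:`ElasticNetLogisticModel`)."""
    return ElasticNetLogisticModel(**config).fit(X, y)


def fit_mil_attention(bags, y, **config) -> AttentionMILClassifier:
    """Fit the attention-MIL bag scorer (see :class:`AttentionMILClassifier`)."""
    return AttentionMILClassifier(**config).fit(bags, y)


def score(model, X) -> np.ndarray:
    """Probability of response from any fitted scorer."""
    return model.predict_proba(X)[:, 1]
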