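"""DyAM: dynamic attention with masking for multimodal late fusion.

Each modality block (three CT lesion sites, PD-L1/IHC texture + TPS,
genomics) has its own risk head — a logistic model mapping the block's
feature vector to a probability — and its own attention head mapping the
same vector to an unnormalized attention logit.  Attention logits compete
through a softmax taken over the modalities a patient actually has; absent
modalities are masked to zero attention before normalization, so the overall
score

    s = sum_m a_m * r_m,   sum over present modalities of a = 1

is a convex combination of per-modality risks and missing data contributes
nothing.  When a patient has exactly one modality the softmax over a
singleton pins its attention at 1, so the attention gate is effectively
bypassed and the overall score equals that modality's risk.  All heads are
trained jointly, full-batch, with Adam on balanced binary cross-entropy.

Input convention: ``X`` is a sequence of per-modality matrices of shape
(n_patients, d_m); a patient missing a modality carries a NaN row in that
block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._optim import Adam, balanced_weights, bce_grad, sigmoid
from .records import MODALITIES, MultimodalRecord

__all__ = ["DyAMClassifier", "DyAMOutput", "stack_cohort", "fit_dyam", "forward"]


@dataclass
class DyAMOutput:
    """Per-patient model readout: overall score, partial risks, attention.

    ``attention`` is zero for absent modalities and sums to 1 over present
    ones; ``partial_risks`` is NaN where the modality is absent.
    """

    overall_score: float
    partial_risks: dict[str, float]
    attention: dict[str, float]


def _as_blocks(X) -> list[np.ndarray]:
    blocks = [np.asarray(b, dtype=float) for b in X]
    if not blocks:
        raise ValueError("need at least one modality block")
    n = {b.shape[0] for b in blocks}
    if len(n) != 1:
        raise ValueError("modality blocks disagree on number of patients")
    for b in blocks:
        if b.ndim != 2:
            raise ValueError("each modality block must be 2-D (patients x features)")
    return blocks


def _presence(blocks: list[np.ndarray]) -> np.ndarray:
    """(n, M) mask; a patient has a modality iff its row has no NaN."""
    return np.column_stack([~np.isnan(b).any(axis=1) for b in blocks])


class DyAMClassifier(BaseEstimator, ClassifierMixin):
    """Masked dynamic-attention fusion of per-modality logistic risk heads.

    Parameters
    ----------
    learning_rate, steps, l2 : training configuration (Adam, full batch,
        pytorch-style weight decay).  Defaults 0.01 / 125 / 0.001.
    gate : if False the attention heads are removed and present modalities
        are weighted equally — the simple risk-averaging baseline.
    attention_hidden : optional hidden width for a tanh-gated attention head;
        the default (None) is a linear map to the attention logit.
    modality_names : labels used in :class:`DyAMOutput`; defaults to the
        canonical five-modality list when it fits.
    """

    def __init__(self, learning_rate: float = 0.01, steps: int = 125,
                 l2: float = 0.001, class_weight: str | None = "balanced",
                 gate: bool = True, attention_hidden: int | None = None,
                 standardize: bool = True, random_state: int = 0,
                 modality_names: Sequence[str] | None = None):
        self.learning_rate = learning_rate
        self.steps = steps
        self.l2 = l2
        self.class_weight = class_weight
        self.gate = gate
        self.attention_hidden = attention_hidden
        self.standardize = standardize
        self.random_state = random_state
        self.modality_names = modality_names

    # -- plumbing ----------------------------------------------------------
    def _names(self, m: int) -> list[str]:
        if self.modality_names is not None:
            if len(self.modality_names) != m:
                raise ValueError("modality_names length mismatch")
            return list(self.modality_names)
        return list(MODALITIES) if m == len(MODALITIES) else [f"mod{i}" for i in range(m)]

    def _standardize_fit(self, blocks, present):
        self.means_, self.scales_ = [], []
        for b, pres in zip(blocks, present.T):
            rows = b[pres]
            if rows.size == 0:
                raise ValueError("a modality is absent in every training patient")
            mu = rows.mean(axis=0)
            sd = rows.std(axis=0)
            sd[sd == 0] = 1.0
            if not self.standardize:
                mu, sd = np.zeros_like(mu), np.ones_like(sd)
            self.means_.append(mu)
            self.scales_.append(sd)

    def _standardize_apply(self, blocks, present):
        out = []
        for b, mu, sd, pres in zip(blocks, self.means_, self.scales_, present.T):
            z = (b - mu) / sd
            z[~pres] = 0.0  # masked rows never reach the loss; zero keeps math finite
            out.append(z)
        return out

    # -- forward -----------------------------------------------------------
    def _heads(self, blocks):
        """Risk probabilities R and attention logits T, both (n, M)."""
        R, T = [], []
        for b, head in zip(blocks, self.heads_):
            R.append(sigmoid(b @ head["w"] + head["b"][0]))
            if not self.gate:
                T.append(np.zeros(b.shape[0]))
            elif self.attention_hidden is None:
                T.append(b @ head["v"] + head["c"][0])
            else:
                h = np.tanh(b @ head["V"].T + head["cvec"])
                T.append(h @ head["u"] + head["e"][0])
        return np.column_stack(R), np.column_stack(T)

    @staticmethod
    def _attend(T, present):
        T = np.where(present, T, -np.inf)
        tmax = T.max(axis=1, keepdims=True)
        expt = np.where(present, np.exp(T - tmax), 0.0)
        return expt / expt.sum(axis=1, keepdims=True)

    def forward_components(self, X, present=None):
        """(scores, attention, risks, presence) for a block sequence.

        ``present`` optionally overrides the NaN-derived presence mask; rows
        flagged absent are masked to zero attention regardless of their
        feature values.
        """
        blocks = _as_blocks(X)
        present = _presence(blocks) if present is None else np.asarray(present, dtype=bool)
        if not present.any(axis=1).all():
            raise ValueError("a patient has every modality absent")
        blocks = self._standardize_apply(blocks, present)
        R, T = self._heads(blocks)
        A = self._attend(T, present)
        S = (A * np.where(present, R, 0.0)).sum(axis=1)
        return S, A, R, present

    # -- training ----------------------------------------------------------
    def fit(self, X, y, present=None):
        blocks = _as_blocks(X)
        y = np.asarray(y, dtype=float)
        if len(y) != blocks[0].shape[0]:
            raise ValueError("label count mismatch")
        if len(np.unique(y)) < 2:
            raise ValueError("y must contain both classes")
        present = _presence(blocks) if present is None else np.asarray(present, dtype=bool)
        if not present.any(axis=1).all():
            raise ValueError("a training patient has every modality absent")
        m = len(blocks)
        self.modality_names_ = self._names(m)
        self._standardize_fit(blocks, present)
        Z = self._standardize_apply(blocks, present)
        rng = np.random.default_rng(self.random_state)
        self.heads_ = []
        flat: list[np.ndarray] = []
        for b in Z:
            d = b.shape[1]
            head = {"w": rng.normal(0, 0.1, d), "b": np.zeros(1)}
            if self.gate:
                if self.attention_hidden is None:
                    head["v"] = rng.normal(0, 0.1, d)
                    head["c"] = np.zeros(1)
                else:
                    hid = self.attention_hidden
                    head["V"] = rng.normal(0, 0.1, (hid, d))
                    head["cvec"] = np.zeros(hid)
                    head["u"] = rng.normal(0, 0.1, hid)
                    head["e"] = np.zeros(1)
            self.heads_.append(head)
            flat.extend(head.values())
        weights = balanced_weights(y) if self.class_weight == "balanced" else np.ones(len(y))
        opt = Adam(flat, lr=self.learning_rate, l2=self.l2)
        self.loss_curve_ = []
        for _ in range(self.steps):
            R, T = self._heads(Z)
            A = self._attend(T, present)
            S = (A * np.where(present, R, 0.0)).sum(axis=1)
            loss, ds = bce_grad(S, y, weights)
            self.loss_curve_.append(loss)
            grads = []
            dT_all = ds[:, None] * A * (np.where(present, R, 0.0) - S[:, None])
            dR_all = ds[:, None] * A  # zero where absent
            for k, (b, head) in enumerate(zip(Z, self.heads_)):
                dz = dR_all[:, k] * R[:, k] * (1 - R[:, k])
                grads.append(b.T @ dz)  # w
                grads.append(np.array([dz.sum()]))  # b
                if self.gate:
                    dt = dT_all[:, k]
                    if self.attention_hidden is None:
                        grads.append(b.T @ dt)  # v
                        grads.append(np.array([dt.sum()]))  # c
                    else:
                        h = np.tanh(b @ head["V"].T + head["cvec"])
                        dpre = dt[:, None] * head["u"] * (1 - h**2)  # (n, hid)
                        grads.append(dpre.T @ b)  # V
                        grads.append(dpre.sum(axis=0))  # cvec
                        grads.append(h.T @ dt)  # u
                        grads.append(np.array([dt.sum()]))  # e
            opt.step(grads)
        self.classes_ = np.array([0, 1])
        self.n_modalities_ = m
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X, present=None):
        S, *_ = self.forward_components(X, present=present)
        return np.column_stack([1 - S, S])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def explain(self, X, present=None) -> list[DyAMOutput]:
        """Per-patient overall score, partial risks and attention weights."""
        S, A, R, present = self.forward_components(X, present=present)
        out = []
        for i in range(len(S)):
            risks = {
                name: (float(R[i, k]) if present[i, k] else float("nan"))
                for k, name in enumerate(self.modality_names_)
            }
            att = {name: float(A[i, k]) for k, name in enumerate(self.modality_names_)}
            out.append(DyAMOutput(float(S[i]), risks, att))
        return out


def stack_cohort(cohort: Sequence[MultimodalRecord], modalities=MODALITIES):
    """Stack a cohort of records into per-modality blocks with NaN-masked rows."""
    n = len(cohort)
    dims: dict[str, int] = {}
    vectors: list[dict[str, np.ndarray]] = []
    for rec in cohort:
        row = {}
        for mod, has in rec.presence_mask.items():
            if mod in modalities and has:
                v = rec.modality_vector(mod)
                if mod in dims and dims[mod] != v.size:
                    raise ValueError(f"inconsistent feature length for modality {mod!r}")
                dims[mod] = v.size
                row[mod] = v
        vectors.append(row)
    missing = [m for m in modalities if m not in dims]
    if missing:
        raise ValueError(f"modalities absent from every record: {missing}")
    blocks = []
    for mod in modalities:
        block = np.full((n, dims[mod]), np.nan)
        for i, row in enumerate(vectors):
            if mod in row:
                block[i] = row[mod]
        blocks.append(block)
    return blocks


def fit_dyam(cohort: Sequence[MultimodalRecord], **config) -> DyAMClassifier:
    """Fit DyAM directly on a cohort of :class:`MultimodalRecord`."""
    blocks = stack_cohort(cohort)
    y = np.array([rec.response for rec in cohort])
    return DyAMClassifier(modality_names=MODALITIES, **config).fit(blocks, y)


def forward(model: DyAMClassifier, record: MultimodalRecord) -> DyAMOutput:
    """Run a fitted model on one patient record."""
    # build one-row blocks matching the fitted dimensionalities
    rows = []
    pres = record.presence_mask
    for mod, mu in zip(model.modality_names_, model.means_):
        if pres.get(mod, False):
            v = record.modality_vector(mod)
            if v.size != mu.size:
                raise ValueError(f"feature length mismatch for modality {mod!r}")
            rows.append(v[None, :])
        else:
            rows.append(np.full((1, mu.size), np.nan))
    return model.explain(rows)[0]
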