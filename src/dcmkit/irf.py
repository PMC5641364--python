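"""Item response functions for the G-DINA model family.

Six endorsement-probability models are supported. Writing K_j* for the
number of criteria an item measures and ``alpha*`` for the reduced profile
restricted to those criteria:

========  ========  ======================================================
model     link      linear predictor on the link scale
========  ========  ======================================================
GDINA     identity  intercept + mains + all interactions (2**K_j* terms)
ACDM      identity  intercept + main effects only
LLM       logit     intercept + main effects only
RRUM      log       intercept + main effects only
DINA      identity  intercept + single top-order interaction ("and" gate)
DINO      identity  intercept + shared main effect of any criterion ("or")
========  ========  ======================================================

The canonical internal representation is the saturated identity-link table
of the 2**K_j* class probabilities; every reduced model is a constraint
structure over that table (a design matrix on its link scale). This makes
Wald restrictions, expansion to the saturated form, and equivalence checks
uniform across models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .latent import reduce_profile

__all__ = [
    "MODELS",
    "REDUCED_MODELS",
    "ItemParams",
    "n_model_params",
    "design_matrix",
    "link_fn",
    "inv_link_fn",
    "endorsement_probability",
    "class_probability_table",
    "expand_to_gdina",
    "discrimination_index",
]

MODELS = ("GDINA", "ACDM", "LLM", "RRUM", "DINA", "DINO")
REDUCED_MODELS = ("ACDM", "LLM", "RRUM", "DINA", "DINO")

MODEL_LINKS = {
    "GDINA": "identity",
    "ACDM": "identity",
    "DINA": "identity",
    "DINO": "identity",
    "LLM": "logit",
    "RRUM": "log",
}

_PROB_TOL = 1e-9


def n_model_params(model: str, kstar: int) -> int:
    """Number of free coefficients of ``model`` for an item measuring kstar criteria."""
    if model == "GDINA":
        return 2**kstar
    if model in ("ACDM", "LLM", "RRUM"):
        return kstar + 1
    if model in ("DINA", "DINO"):
        return 2
    raise ValueError(f"unknown model tag {model!r}")


def _reduced_profiles(kstar: int) -> np.ndarray:
    """All 2**kstar reduced profiles, binary counting, first criterion = LSB."""
    ids = np.arange(2**kstar)
    return ((ids[:, None] >> np.arange(kstar)) & 1).astype(np.int8)


def design_matrix(model: str, kstar: int) -> np.ndarray:
    """Design matrix M (2**kstar x p) with link(P) = M @ coeffs row-wise.

    Rows are reduced profiles in binary-counting order. GDINA columns are
    indexed by criterion subsets in the same binary-counting order, so for
    kstar = 2 the coefficient vector reads (intercept, main1, main2,
    interaction12).
    """
    if kstar < 1:
        raise ValueError("kstar must be >= 1")
    profiles = _reduced_profiles(kstar)
    if model == "GDINA":
        cols = []
        for s in range(2**kstar):
            members = [(k, None) for k in range(kstar) if (s >> k) & 1]
            if not members:
                cols.append(np.ones(2**kstar))
            else:
                col = np.ones(2**kstar)
                for k, _ in members:
                    col = col * profiles[:, k]
                cols.append(col)
        return np.column_stack(cols)
    if model in ("ACDM", "LLM", "RRUM"):
        return np.column_stack([np.ones(2**kstar), profiles])
    if model == "DINA":
        return np.column_stack([np.ones(2**kstar), profiles.prod(axis=1)])
    if model == "DINO":
        return np.column_stack([np.ones(2**kstar), profiles.max(axis=1)])
    raise ValueError(f"unknown model tag {model!r}")


def link_fn(link: str):
    if link == "identity":
        return lambda p: np.asarray(p, dtype=float)
    if link == "logit":
        return logit
    if link == "log":
        return np.log
    raise ValueError(f"unknown link {link!r}")


def inv_link_fn(link: str):
    if link == "identity":
        return lambda e: np.asarray(e, dtype=float)
    if link == "logit":
        return expit
    if link == "log":
        return np.exp
    raise ValueError(f"unknown link {link!r}")


@dataclass(frozen=True)
class ItemParams:
    """Coefficients of one item under one model of the family.

    ``coeffs`` live on the model's link scale (identity for GDINA, ACDM,
    DINA, DINO; logit for LLM; log for RRUM), ordered as the corresponding
    :func:`design_matrix` columns. Construction validates the coefficient
    count and that every latent class's endorsement probability lies in
    [0, 1]; out-of-range parameter sets raise instead of being clipped.
    """

    model: str
    qrow: np.ndarray
    coeffs: np.ndarray
    item_id: str = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model tag {self.model!r}")
        qrow = np.asarray(self.qrow, dtype=np.int8)
        if qrow.ndim != 1 or not np.isin(qrow, (0, 1)).all():
            raise ValueError("qrow must be a binary vector")
        if qrow.sum() < 1:
            raise ValueError("item must measure at least one criterion")
        coeffs = np.asarray(self.coeffs, dtype=float)
        kstar = int(qrow.sum())
        expected = n_model_params(self.model, kstar)
        if coeffs.shape != (expected,):
            raise ValueError(
                f"{self.model} with K_j*={kstar} needs {expected} coefficients, "
                f"got {coeffs.shape}"
            )
        object.__setattr__(self, "qrow", qrow)
        object.__setattr__(self, "coeffs", coeffs)
        probs = inv_link_fn(self.link)(design_matrix(self.model, kstar) @ coeffs)
        if (probs < -_PROB_TOL).any() or (probs > 1 + _PROB_TOL).any():
            raise ValueError(
                f"parameters give endorsement probabilities outside [0, 1]: "
                f"range [{probs.min():.6g}, {probs.max():.6g}]"
            )

    @property
    def link(self) -> str:
        return MODEL_LINKS[self.model]

    @property
    def kstar(self) -> int:
        return int(self.qrow.sum())

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "model": self.model,
            "link": self.link,
            "qrow": self.qrow.tolist(),
            "coeffs": self.coeffs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemParams":
        return cls(
            model=d["model"],
            qrow=np.asarray(d["qrow"]),
            coeffs=np.asarray(d["coeffs"], dtype=float),
            item_id=d.get("item_id"),
        )

    def __eq__(self, other):
        return (
            isinstance(other, ItemParams)
            and self.model == other.model
            and np.array_equal(self.qrow, other.qrow)
            and np.array_equal(self.coeffs, other.coeffs)
        )


def class_probability_table(params: ItemParams) -> np.ndarray:
    """Endorsement probability for each of the 2**K_j* reduced profiles."""
    M = design_matrix(params.model, params.kstar)
    probs = inv_link_fn(params.link)(M @ params.coeffs)
    return np.clip(probs, 0.0, 1.0)  # only rounds off link-scale noise <= _PROB_TOL


def reduced_class_index(profile, qrow) -> int:
    """Index of a full profile's reduced profile in binary-counting order."""
    sub = reduce_profile(profile, qrow)
    return int((sub.astype(np.int64) << np.arange(sub.size)).sum())


def endorsement_probability(params: ItemParams, profile) -> float:
    """P(X_j = 1 | profile) under the item's model."""
    table = class_probability_table(params)
    return float(table[reduced_class_index(profile, params.qrow)])


def expand_to_gdina(params: ItemParams) -> ItemParams:
    """Rewrite any family member as an exactly equivalent saturated GDINA item.

    Evaluates the reduced model at every reduced profile and solves the
    (invertible) saturated design for the identity-link coefficients, so the
    class-wise probabilities are preserved to machine precision.
    """
    if params.model == "GDINA":
        return params
    probs = class_probability_table(params)
    M = design_matrix("GDINA", params.kstar)
    coeffs = np.linalg.solve(M, probs)
    return ItemParams("GDINA", params.qrow, coeffs, item_id=params.item_id)


def discrimination_index(params: ItemParams) -> float:
    """P(X=1 | all measured criteria present) - P(X=1 | none present).

    The item-quality index used for screening: the probability gap between
    respondents possessing all of the item's measured criteria and
    respondents possessing none of them.
    """
    table = class_probability_table(params)
    return float(table[-1] - table[0])
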