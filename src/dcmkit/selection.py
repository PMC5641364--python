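"""Per-item Wald comparison of reduced models against the saturated G-DINA.

For an item measuring K_j* >= 2 criteria, each reduced family member is a
set of restrictions on the saturated vector of 2**K_j* class endorsement
probabilities: the restricted vector must lie in the column space of the
candidate's design matrix on the candidate's link scale. With theta the
unrestricted (saturated) estimate and Sigma its covariance, the Wald
statistic

    W = (R f(theta))' (R D Sigma D' R')^{-1} (R f(theta))

uses R spanning the left null space of the candidate design, f the
candidate link, and D the delta-method Jacobian of f; W is asymptotically
chi-square with df = 2**K_j* - p_candidate restrictions under the null
that the reduced model holds.

Selection rule: a candidate is *acceptable* when its Wald test is
non-significant (p > alpha, no significant loss of fit relative to the
saturated model); among acceptable candidates the one with the largest
p-value is selected; if none is acceptable the saturated G-DINA is kept.
Items measuring a single criterion are labelled G-DINA without testing
(all family members coincide there).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space

from .estimation import GDINAEstimator
from .irf import REDUCED_MODELS, design_matrix

__all__ = [
    "WaldResult",
    "SelectionRecord",
    "restriction_matrix",
    "wald_reduced_vs_saturated",
    "select_item_model",
    "select_all_items",
    "selection_summary",
]


class WaldResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


@dataclass
class SelectionRecord:
    """Wald tests and the selected model for one item."""

    item_id: str
    kstar: int
    tests: dict = field(default_factory=dict)  # model tag -> WaldResult
    selected: str = "GDINA"

    def to_row(self) -> dict:
        row = {"item_id": self.item_id, "kstar": self.kstar,
               "selected": self.selected}
        for tag, res in self.tests.items():
            row[f"{tag}_stat"] = res.statistic
            row[f"{tag}_df"] = res.df
            row[f"{tag}_p"] = res.pvalue
        return row


_CAND_LINK = {"ACDM": "identity", "DINA": "identity", "DINO": "identity",
              "LLM": "logit", "RRUM": "log"}


def restriction_matrix(candidate: str, kstar: int) -> np.ndarray:
    """Rows spanning the left null space of the candidate's design matrix.

    ``R @ f(p) == 0`` exactly when the link-transformed probability vector
    lies in the candidate's column space, i.e. when the reduced model holds.
    """
    M = design_matrix(candidate, kstar)
    R = null_space(M.T).T
    if R.shape[0] != 2**kstar - M.shape[1]:
        raise RuntimeError("restriction matrix rank mismatch")
    return R


def wald_reduced_vs_saturated(fitted: GDINAEstimator, X, item_id,
                              candidate: str,
                              covariance: np.ndarray = None) -> WaldResult:
    """Wald test of one reduced candidate against the saturated fit of an item.

    ``fitted`` must have the item fitted under the saturated G-DINA (the
    unrestricted estimate). ``covariance`` may carry a precomputed OPG
    covariance of the saturated table to avoid recomputation.
    """
    j = fitted.q_.item_index(item_id) if isinstance(item_id, str) else int(item_id)
    if fitted.assignment_[j] != "GDINA":
        raise ValueError("Wald selection requires a saturated fit for the item")
    kstar = fitted.q_.kstar(j)
    if kstar < 2:
        raise ValueError("item measures one criterion; all models coincide")
    if candidate not in REDUCED_MODELS:
        raise ValueError(f"unknown candidate {candidate!r}")

    theta = fitted.prob_tables_[j]
    if covariance is None:
        full, slices = fitted.joint_covariance(X)
        covariance = full[slices[j], slices[j]]

    link = _CAND_LINK[candidate]
    if link == "identity":
        f = theta
        D = np.eye(theta.size)
    elif link == "logit":
        f = np.log(theta) - np.log1p(-theta)
        D = np.diag(1.0 / (theta * (1.0 - theta)))
    else:  # log
        f = np.log(theta)
        D = np.diag(1.0 / theta)

    R = restriction_matrix(candidate, kstar)
    r = R @ f
    V = R @ D @ covariance @ D.T @ R.T
    try:
        W = float(r @ np.linalg.solve(V, r))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"singular restricted covariance for item "
            f"{fitted.q_.item_ids[j]!r}, candidate {candidate}"
        ) from None
    df = R.shape[0]
    return WaldResult(W, df, float(stats.chi2.sf(W, df)))


def select_item_model(fitted: GDINAEstimator, X, item_id,
                      alpha: float = 0.05,
                      covariance: np.ndarray = None) -> SelectionRecord:
    """Apply the Wald selection rule to one item."""
    j = fitted.q_.item_index(item_id) if isinstance(item_id, str) else int(item_id)
    item_id = fitted.q_.item_ids[j]
    kstar = fitted.q_.kstar(j)
    rec = SelectionRecord(item_id=item_id, kstar=kstar)
    if kstar < 2:
        rec.selected = "GDINA"
        return rec
    if covariance is None:
        full, slices = fitted.joint_covariance(X)
        covariance = full[slices[j], slices[j]]
    for cand in REDUCED_MODELS:
        rec.tests[cand] = wald_reduced_vs_saturated(
            fitted, X, j, cand, covariance=covariance
        )
    acceptable = {tag: res for tag, res in rec.tests.items()
                  if res.pvalue > alpha}
    if acceptable:
        rec.selected = max(acceptable, key=lambda tag: acceptable[tag].pvalue)
    else:
        rec.selected = "GDINA"
    return rec


def select_all_items(fitted: GDINAEstimator, X,
                     alpha: float = 0.05) -> list[SelectionRecord]:
    full, slices = fitted.joint_covariance(X)
    return [select_item_model(fitted, X, j, alpha=alpha,
                              covariance=full[slices[j], slices[j]])
            for j in range(fitted.q_.n_items)]


def selection_summary(records) -> dict:
    """Tally of selected model tags over a set of selection/screening records."""
    counts = Counter(getattr(r, "selected", None) or r["selected"]
                     for r in records)
    return {tag: counts.get(tag, 0)
            for tag in ("GDINA", "ACDM", "LLM", "RRUM", "DINA", "DINO")}


def selection_report(records) -> pd.DataFrame:
    """Selection results as a table mirroring a per-item report."""
    return pd.DataFrame([r.to_row() for r in records])
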