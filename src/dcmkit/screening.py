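"""Item screening: S-X² fit, differential item functioning, and the
iterative exclusion loop that produces the final instrument.

Three per-item screens are applied, mirroring common practice for
criterion-referenced instruments:

* **discrimination** — the all-vs-none endorsement-probability gap; items
  below the cut (default 0.45, strict ``<``) are flagged;
* **S-X² item fit** (Orlando–Thissen) — observed vs model-expected
  endorsement within rest-score groups, chi-square after collapsing sparse
  groups; items with p < 0.05 are flagged;
* **DIF Wald test** — the studied item's saturated parameters are
  estimated separately in two manifest groups (all other items anchored
  equal), and equality of the two parameter vectors is tested with
  df = 2**K_j*.

The screening loop refits, re-selects models, recomputes the three
screens, drops every flagged item simultaneously, and repeats until a
round drops nothing. A drop that would leave a criterion unmeasured is
vetoed (the item is retained with a ``forced-keep`` flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import GDINAEstimator, _validate_responses
from .irf import discrimination_index, n_model_params
from .latent import QMatrix
from .selection import select_all_items

__all__ = [
    "TestResult",
    "ScreeningRecord",
    "sx2_item_fit",
    "dif_wald",
    "screen_items",
    "screening_loop",
]


class TestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float

    @property
    def computable(self) -> bool:
        return np.isfinite(self.pvalue)


NOT_COMPUTABLE = TestResult(np.nan, np.nan, np.nan)


@dataclass
class ScreeningRecord:
    """One item's screening outcome within a round (a per-item report row)."""

    item_id: str
    selected: str
    discrimination: float
    sx2: TestResult = NOT_COMPUTABLE
    dif: dict = field(default_factory=dict)  # grouping name -> TestResult
    decision: str = "keep"
    reasons: tuple = ()
    forced_keep: bool = False

    def to_row(self) -> dict:
        row = {
            "item_id": self.item_id,
            "selected": self.selected,
            "discrimination": self.discrimination,
            "sx2_stat": self.sx2.statistic,
            "sx2_df": self.sx2.df,
            "sx2_p": self.sx2.pvalue,
        }
        for name, res in self.dif.items():
            row[f"dif_{name}_stat"] = res.statistic
            row[f"dif_{name}_df"] = res.df
            row[f"dif_{name}_p"] = res.pvalue
        row["decision"] = self.decision
        row["reasons"] = ";".join(self.reasons)
        row["forced_keep"] = self.forced_keep
        return row


# ---------------------------------------------------------------------------
# S-X² item fit
# ---------------------------------------------------------------------------


def _rest_score_dist(tables, group_index, skip: int) -> np.ndarray:
    """(C, J) rest-score pmf per latent class, recursion over the other items."""
    J, C = group_index.shape
    P = np.empty((J, C))
    for j in range(J):
        P[j] = tables[j][group_index[j]]
    dist = np.zeros((C, J))  # scores 0 .. J-1 on the J-1 remaining items
    dist[:, 0] = 1.0
    top = 0
    for j in range(J):
        if j == skip:
            continue
        p = P[j][:, None]
        new = dist * (1 - p)
        new[:, 1:top + 2] += dist[:, :top + 1] * p
        dist = new
        top += 1
    return dist


def sx2_item_fit(X, fitted: GDINAEstimator, item_id,
                 min_expected: float = 1.0) -> TestResult:
    """Orlando–Thissen S-X² fit statistic for one item.

    Respondents are grouped by their raw total on the remaining J-1 items
    (rest score); the model-expected endorsement proportion per score group
    comes from the fitted latent class model via the Lord–Wingersky
    score-distribution recursion; adjacent score groups are collapsed until
    both expected cells (endorse / not endorse) reach ``min_expected``.
    Requires complete responses; df = groups - free item parameters.
    """
    j = fitted.q_.item_index(item_id) if isinstance(item_id, str) else int(item_id)
    vals, mask = _validate_responses(X, fitted.q_.n_items)
    if not mask.all():
        complete = mask.all(axis=1)
        vals = vals[complete]
        if vals.shape[0] == 0:
            return NOT_COMPUTABLE
    J = vals.shape[1]
    rest = vals.sum(axis=1) - vals[:, j]
    x = vals[:, j]

    dist = _rest_score_dist(fitted.prob_tables_, fitted.group_index_, j)
    pi = fitted.class_props_
    p_item = fitted.prob_tables_[j][fitted.group_index_[j]]
    denom = pi @ dist                      # P(rest score = s)
    numer = (pi * p_item) @ dist           # P(rest = s, item endorsed)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(denom > 0, numer / np.maximum(denom, 1e-300), 0.0)

    n_s = np.bincount(rest.astype(int), minlength=J).astype(float)
    o_s = np.bincount(rest.astype(int), weights=x, minlength=J)

    groups = [[s] for s in range(J) if n_s[s] > 0]
    if len(groups) < 2:
        return NOT_COMPUTABLE

    def cells(g):
        n = sum(n_s[s] for s in g)
        o = sum(o_s[s] for s in g)
        exp = sum(n_s[s] * e[s] for s in g)
        return n, o, exp

    # collapse the sparsest group into its smaller neighbour until all
    # expected cells reach the floor
    while len(groups) > 2:
        stats_g = [cells(g) for g in groups]
        bad = [i for i, (n, _, exp) in enumerate(stats_g)
               if min(exp, n - exp) < min_expected]
        if not bad:
            break
        i = bad[0]
        if i == 0:
            tgt = 1
        elif i == len(groups) - 1:
            tgt = i - 1
        else:
            tgt = i - 1 if stats_g[i - 1][0] <= stats_g[i + 1][0] else i + 1
        lo, hi = min(i, tgt), max(i, tgt)
        groups[lo:hi + 1] = [groups[lo] + groups[hi]]

    statistic = 0.0
    for g in groups:
        n, o, exp = cells(g)
        exp = min(max(exp, 1e-10), n - 1e-10)
        statistic += (o - exp) ** 2 * n / (exp * (n - exp))

    n_par = n_model_params(fitted.assignment_[j], fitted.q_.kstar(j))
    df = len(groups) - n_par
    if df < 1:
        return NOT_COMPUTABLE
    return TestResult(float(statistic), float(df),
                      float(stats.chi2.sf(statistic, df)))


# ---------------------------------------------------------------------------
# DIF Wald test
# ---------------------------------------------------------------------------


def dif_wald(X, groups, q: QMatrix, item_id, *, min_group: int = 50,
             estimator_kwargs: dict = None) -> TestResult:
    """Wald test of parameter equality for one item across two groups.

    The studied item is duplicated into one reference-group and one
    focal-group column (responses of the other group set missing) and the
    model refitted with every other item anchored; the two saturated
    parameter vectors are then compared with W = d'(V_R + V_F)^{-1} d,
    df = 2**K_j*.
    """
    j = q.item_index(item_id) if isinstance(item_id, str) else int(item_id)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("DIF requires exactly two groups")
    in_focal = groups == labels[1]
    n_ref, n_foc = int((~in_focal).sum()), int(in_focal.sum())
    if min(n_ref, n_foc) < min_group:
        warnings.warn(
            f"group sizes {n_ref}/{n_foc} below the stability floor "
            f"{min_group}; DIF not computed for item {q.item_ids[j]}",
            stacklevel=2,
        )
        return NOT_COMPUTABLE

    Xext = np.column_stack([X, X[:, j]])
    Xext[in_focal, j] = np.nan       # original column becomes reference-only
    Xext[~in_focal, -1] = np.nan     # appended column is focal-only
    qext = QMatrix(
        np.vstack([q.entries, q.entries[j]]),
        item_ids=q.item_ids + (f"{q.item_ids[j]}__focal",),
        criterion_ids=q.criterion_ids,
    )
    kwargs = dict(estimator_kwargs or {})
    est = GDINAEstimator(qext, models="GDINA", **kwargs).fit(Xext)
    p_ref = est.prob_tables_[j]
    p_foc = est.prob_tables_[-1]
    full, slices = est.joint_covariance(Xext)
    sl_r, sl_f = slices[j], slices[qext.n_items - 1]
    V = (full[sl_r, sl_r] + full[sl_f, sl_f]
         - full[sl_r, sl_f] - full[sl_f, sl_r])
    d = p_ref - p_foc
    W = float(d @ np.linalg.solve(V, d))
    df = 2 ** q.kstar(j)
    return TestResult(W, float(df), float(stats.chi2.sf(W, df)))


# ---------------------------------------------------------------------------
# screening round and loop
# ---------------------------------------------------------------------------


def screen_items(X, q: QMatrix, dif_groups: dict = None, *,
                 alpha: float = 0.05, disc_cut: float = 0.45,
                 min_group: int = 50, bh_correction: bool = False,
                 estimator_kwargs: dict = None) -> list[ScreeningRecord]:
    """One screening round: fit, select models, compute the three screens.

    ``dif_groups`` maps grouping names (e.g. "sex") to binary label vectors.
    Returns one :class:`ScreeningRecord` per item with keep/drop decisions;
    ``keep`` iff discrimination >= disc_cut and S-X² p >= 0.05 and every DIF
    p >= alpha. With ``bh_correction`` the S-X²/DIF p-values are
    Benjamini–Hochberg adjusted across items before flagging (off by
    default: the raw per-item rule).
    """
    kwargs = dict(estimator_kwargs or {})
    sat = GDINAEstimator(q, models="GDINA", **kwargs).fit(X)
    records_sel = select_all_items(sat, X, alpha=alpha)
    assignment = [r.selected for r in records_sel]
    fit = GDINAEstimator(q, models=assignment, **kwargs).fit(X)

    recs = []
    for j in range(q.n_items):
        rec = ScreeningRecord(
            item_id=q.item_ids[j],
            selected=assignment[j],
            discrimination=discrimination_index(fit.item_params_[j]),
            sx2=sx2_item_fit(X, fit, j),
        )
        for name, g in (dif_groups or {}).items():
            rec.dif[name] = dif_wald(X, g, q, j, min_group=min_group,
                                     estimator_kwargs=kwargs)
        recs.append(rec)

    sx2_p = _maybe_bh([r.sx2.pvalue for r in recs]) if bh_correction \
        else [r.sx2.pvalue for r in recs]
    dif_p = {}
    for name in (dif_groups or {}):
        ps = [r.dif[name].pvalue for r in recs]
        dif_p[name] = _maybe_bh(ps) if bh_correction else ps

    for i, rec in enumerate(recs):
        rec.reasons = screening_reasons(
            rec.discrimination, sx2_p[i],
            {name: dif_p[name][i] for name in dif_p},
            disc_cut=disc_cut, alpha=alpha)
        rec.decision = "drop" if rec.reasons else "keep"
    return recs


def screening_reasons(discrimination, sx2_p, dif_p: dict = None, *,
                      disc_cut: float = 0.45,
                      alpha: float = 0.05) -> tuple:
    """Reason codes determining an item's keep/drop decision.

    Keep iff discrimination >= disc_cut (the cut is a strict ``<`` flag),
    S-X² p >= 0.05, and every DIF p >= alpha; non-computable (NaN)
    p-values never flag.
    """
    reasons = []
    if discrimination < disc_cut:
        reasons.append("low_discrimination")
    if np.isfinite(sx2_p) and sx2_p < 0.05:
        reasons.append("poor_fit")
    for name, p in (dif_p or {}).items():
        if np.isfinite(p) and p < alpha:
            reasons.append(f"dif_{name}")
    return tuple(reasons)


def _maybe_bh(pvals):
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    out = p.copy()
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def screening_loop(X, q: QMatrix, dif_groups: dict = None, *,
                   alpha: float = 0.05, disc_cut: float = 0.45,
                   min_group: int = 50, max_rounds: int = None,
                   estimator_kwargs: dict = None):
    """Iterate screening rounds until no item is dropped.

    Returns ``(final_q, rounds)`` where ``rounds`` is the audit trail: a
    list of per-round lists of :class:`ScreeningRecord`. All flagged items
    in a round are dropped simultaneously, except drops that would leave a
    criterion unmeasured, which are vetoed and marked ``forced_keep``.
    """
    X = np.asarray(X, dtype=float)
    if q.n_items < 2:
        raise ValueError("screening needs at least two items")
    cur_q = q
    cur_cols = np.arange(q.n_items)
    cur_groups = dict(dif_groups or {})
    rounds = []
    max_rounds = max_rounds or q.n_items
    for _ in range(max_rounds):
        recs = screen_items(
            X[:, cur_cols], cur_q, cur_groups, alpha=alpha,
            disc_cut=disc_cut, min_group=min_group,
            estimator_kwargs=estimator_kwargs,
        )
        drop_idx = [i for i, r in enumerate(recs) if r.decision == "drop"]
        keep_mask = np.ones(cur_q.n_items, dtype=bool)
        keep_mask[drop_idx] = False
        # veto drops that would uncover a criterion, re-adding the dropped
        # item with the largest discrimination for that criterion first
        while True:
            cov = cur_q.entries[keep_mask].sum(axis=0) if keep_mask.any() \
                else np.zeros(cur_q.n_criteria)
            bare = np.flatnonzero(cov == 0)
            if bare.size == 0:
                break
            k = bare[0]
            candidates = [i for i in np.flatnonzero(~keep_mask)
                          if cur_q.entries[i, k] == 1]
            best = max(candidates, key=lambda i: recs[i].discrimination)
            keep_mask[best] = True
            recs[best].decision = "keep"
            recs[best].forced_keep = True
            warnings.warn(
                f"item {cur_q.item_ids[best]} retained despite flags "
                f"{recs[best].reasons}: criterion "
                f"{cur_q.criterion_ids[k]} would be unmeasured",
                stacklevel=2,
            )
        rounds.append(recs)
        if keep_mask.all():
            break
        cur_cols = cur_cols[keep_mask]
        cur_q = QMatrix(
            cur_q.entries[keep_mask],
            item_ids=tuple(np.array(cur_q.item_ids)[keep_mask]),
            criterion_ids=cur_q.criterion_ids,
        )
    return cur_q, rounds


def screening_report(records) -> pd.DataFrame:
    """Screening records as a per-item report table."""
    return pd.DataFrame([r.to_row() for r in records])
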