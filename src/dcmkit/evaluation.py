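"""Psychometric evaluation: reliability, classification consistency, and
diagnostic accuracy of the threshold classification.

Classical test theory reliability (Cronbach's alpha, Guttman split-half)
is computed on the sum-score scale; model-based reliability is a
simulation estimate of symptom-level classification consistency (the
probability that two independent administrations to the same respondent
yield the same criterion classification). Validation-sample metrics are
the usual 2x2 quantities — sensitivity, specificity, diagnostic odds
ratio with a log-normal Wald CI — plus the Mann–Whitney AUC of a
continuous score, and a pooled-variance two-sample comparison with
Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimation import GDINAEstimator, _item_prob_matrix
from .scoring import symptom_marginals

__all__ = [
    "cronbach_alpha",
    "guttman_split_half",
    "classification_consistency",
    "DiagnosticAccuracy",
    "diagnostic_accuracy",
    "mann_whitney_auc",
    "two_group_comparison",
    "score_correlations",
]


def _score_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-d matrix with at least two items")
    return X


def cronbach_alpha(X) -> float:
    """alpha = J/(J-1) * (1 - sum of item variances / total-score variance)."""
    X = _score_matrix(X)
    J = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(J / (J - 1) * (1 - item_var / total_var))


def guttman_split_half(X) -> float:
    """Guttman split-half: 2 (s²_total - s²_A - s²_B) / s²_total with the
    odd-even item split."""
    X = _score_matrix(X)
    total = X.sum(axis=1)
    total_var = total.var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; split-half undefined")
    a = X[:, 0::2].sum(axis=1)
    b = X[:, 1::2].sum(axis=1)
    return float(2 * (total_var - a.var(ddof=1) - b.var(ddof=1)) / total_var)


def classification_consistency(fitted: GDINAEstimator, reps: int = 2000,
                               seed: int = 0) -> np.ndarray:
    """Simulation-based test–retest agreement per criterion.

    Draws ``reps`` latent classes from the fitted class proportions,
    simulates two independent response vectors per class from the fitted
    item response functions, classifies each replicate on every criterion
    by EAP marginal >= 0.5, and reports the per-criterion agreement rate.
    Deterministic given ``seed``.
    """
    import warnings as _w

    if reps < 100:
        _w.warn("fewer than 100 replicates gives an unstable consistency "
                "estimate", stacklevel=2)
    rng = np.random.default_rng(seed)
    space = fitted.space_
    P = _item_prob_matrix(fitted.prob_tables_, fitted.group_index_)  # (J, C)
    classes = rng.choice(space.n_classes, size=reps, p=fitted.class_props_)
    probs = P[:, classes].T  # (reps, J)
    x1 = (rng.random(probs.shape) < probs).astype(float)
    x2 = (rng.random(probs.shape) < probs).astype(float)
    m1 = symptom_marginals(fitted.predict_proba(x1), space) >= 0.5
    m2 = symptom_marginals(fitted.predict_proba(x2), space) >= 0.5
    return (m1 == m2).mean(axis=0)


@dataclass
class DiagnosticAccuracy:
    """2x2 diagnostic accuracy of a binary prediction against a reference."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    dor: float
    dor_ci: tuple
    dor_p: float
    auc: float = np.nan
    haldane_corrected: bool = False

    def to_dict(self) -> dict:
        return {
            "counts": {"TP": self.tp, "FN": self.fn, "TN": self.tn,
                       "FP": self.fp},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "dor": self.dor,
            "dor_ci": list(self.dor_ci),
            "dor_p": self.dor_p,
            "auc": self.auc,
            "haldane_corrected": self.haldane_corrected,
        }


def mann_whitney_auc(scores, truth) -> float:
    """AUC as the Mann–Whitney probability that a positive case scores
    higher than a negative case (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos, neg = scores[truth], scores[~truth]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def diagnostic_accuracy(predicted, truth, scores=None) -> DiagnosticAccuracy:
    """Confusion counts, sensitivity/specificity, DOR with log-normal Wald
    95% CI (Haldane 0.5 correction on zero cells, flagged), and the
    Mann–Whitney AUC when a continuous score is supplied."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth lengths differ")
    if truth.all() or (~truth).all():
        raise ValueError("both classes must be present in the reference")
    tp = int((predicted & truth).sum())
    fn = int((~predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())
    fp = int((predicted & ~truth).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)

    cells = np.array([tp, fn, tn, fp], dtype=float)
    haldane = (cells == 0).any()
    if haldane:
        cells = cells + 0.5
    a, b, c, d = cells
    log_dor = np.log(a * c / (b * d))
    se = np.sqrt((1 / cells).sum())
    ci = (float(np.exp(log_dor - 1.96 * se)), float(np.exp(log_dor + 1.96 * se)))
    p = float(2 * stats.norm.sf(abs(log_dor) / se))

    auc = np.nan
    if scores is not None:
        auc = mann_whitney_auc(scores, truth)
    return DiagnosticAccuracy(tp=tp, fn=fn, tn=tn, fp=fp,
                              sensitivity=float(sens), specificity=float(spec),
                              dor=float(np.exp(log_dor)), dor_ci=ci, dor_p=p,
                              auc=auc, haldane_corrected=bool(haldane))


def two_group_comparison(scores_a, scores_b):
    """Pooled-variance two-sample t-test plus Cohen's d.

    Returns ``(t, df, p, d)`` with df = n_a + n_b - 2 and
    d = mean difference / pooled SD.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var <= 0:
        raise ValueError("zero pooled variance; comparison undefined")
    sp = np.sqrt(pooled_var)
    t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / a.size + 1 / b.size))
    p = float(2 * stats.t.sf(abs(t), df))
    d = (a.mean() - b.mean()) / sp
    return float(t), int(df), p, float(d)


def pooled_t_from_summaries(mean_a, sd_a, n_a, mean_b, sd_b, n_b):
    """Pooled two-sample t and Cohen's d from printed group summaries."""
    df = n_a + n_b - 2
    sp = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df)
    t = (mean_a - mean_b) / (sp * np.sqrt(1 / n_a + 1 / n_b))
    return float(t), int(df), float(2 * stats.t.sf(abs(t), df)), \
        float((mean_a - mean_b) / sp)


def score_correlations(x, y) -> float:
    """Pearson correlation between two score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])
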