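"""Marginal maximum likelihood (EM) estimation of G-DINA family models.

The observed data are an n x J binary response matrix; the latent datum is
each respondent's class among the 2**K symptom profiles. The marginal
likelihood integrates the latent class out:

    L = prod_i sum_c pi_c prod_j P_jc^{x_ij} (1 - P_jc)^{1 - x_ij},

where pi is the structural distribution over classes and P_jc the item
response function of item j evaluated at class c's profile. EM alternates
the usual E-step (class posteriors by Bayes' rule) with per-item M-steps:
closed form for the saturated identity-link table, small constrained
optimisations for reduced models. Missing responses (NaN) are marginalised
out of the per-respondent likelihood, not imputed.

``GDINAEstimator`` follows the scikit-learn estimator protocol: all
configuration in ``__init__``, data only in :meth:`fit`, fitted attributes
with a trailing underscore, and ``predict_proba`` returning the class
posterior for new respondents.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .irf import ItemParams, design_matrix, inv_link_fn
from .latent import LatentClassSpace, QMatrix, enumerate_classes

__all__ = [
    "GDINAEstimator",
    "em_fit",
    "class_posteriors",
    "parameter_covariance",
    "read_responses",
    "write_responses",
]


def _validate_responses(X, n_items: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (values with NaN->0, observed mask); raise on non-binary cells."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("responses must be a 2-d matrix")
    if X.shape[1] != n_items:
        raise ValueError(
            f"responses have {X.shape[1]} columns but the Q-matrix has "
            f"{n_items} items"
        )
    if X.shape[0] == 0:
        raise ValueError("responses are empty")
    mask = ~np.isnan(X)
    vals = np.where(mask, X, 0.0)
    if not np.isin(vals, (0.0, 1.0)).all():
        bad = np.argwhere(mask & ~np.isin(X, (0.0, 1.0)))[0]
        raise ValueError(
            f"non-binary response {X[bad[0], bad[1]]!r} at respondent "
            f"{bad[0]}, item column {bad[1]}"
        )
    return vals, mask.astype(float)


def _group_index(q: QMatrix, space: LatentClassSpace) -> np.ndarray:
    """(J, 2**K) map from latent class to each item's reduced-profile index."""
    K = space.n_criteria
    out = np.empty((q.n_items, space.n_classes), dtype=np.int64)
    for j in range(q.n_items):
        measured = np.flatnonzero(q.entries[j])
        sub = space.profiles[:, measured].astype(np.int64)
        out[j] = (sub << np.arange(measured.size)).sum(axis=1)
    return out


def _item_prob_matrix(tables, group_index) -> np.ndarray:
    """(J, C) endorsement probabilities per item and latent class."""
    J, C = group_index.shape
    P = np.empty((J, C))
    for j in range(J):
        P[j] = tables[j][group_index[j]]
    return P


# ---------------------------------------------------------------------------
# per-item weighted Bernoulli M-steps
# ---------------------------------------------------------------------------


def _weighted_ll(table, R, N) -> float:
    p = np.clip(table, 1e-12, 1 - 1e-12)
    return float(R @ np.log(p) + (N - R) @ np.log1p(-p))


def _mstep_gdina(R, N, bound) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(N > 0, R / np.maximum(N, 1e-300), 0.5)
    return np.clip(p, bound, 1 - bound)


def _mstep_reduced(model, kstar, R, N, bound, monotone, x0):
    """Maximise sum_g R_g log p_g + (N_g - R_g) log(1-p_g) over coefficients."""
    M = design_matrix(model, kstar)
    link = {"ACDM": "identity", "DINA": "identity", "DINO": "identity",
            "LLM": "logit", "RRUM": "log"}[model]
    inv = inv_link_fn(link)

    def negll(c):
        p = np.clip(inv(M @ c), 1e-12, 1 - 1e-12)
        return -(R @ np.log(p) + (N - R) @ np.log1p(-p))

    def grad(c):
        eta = M @ c
        p = np.clip(inv(eta), 1e-12, 1 - 1e-12)
        if link == "identity":
            d = (R - N * p) / (p * (1 - p))
        elif link == "logit":
            d = R - N * p
        else:  # log
            d = (R - N * p) / (1 - p)
        return -(M.T @ d)

    n_par = M.shape[1]
    bounds = [(None, None)] * n_par
    if monotone:
        bounds = [(None, None)] + [(0.0, None)] * (n_par - 1)

    constraints = []
    if link == "identity":
        constraints = [
            {"type": "ineq", "fun": lambda c: M @ c - bound, "jac": lambda c: M},
            {"type": "ineq", "fun": lambda c: (1 - bound) - M @ c,
             "jac": lambda c: -M},
        ]
    elif link == "log":
        constraints = [
            {"type": "ineq", "fun": lambda c: np.log(1 - bound) - M @ c,
             "jac": lambda c: -M},
        ]

    if constraints:
        res = minimize(negll, x0, jac=grad, method="SLSQP", bounds=bounds,
                       constraints=constraints,
                       options={"maxiter": 80, "ftol": 1e-10})
    else:
        res = minimize(negll, x0, jac=grad, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-8})
    return res.x


def _init_coeffs(model, kstar, table, monotone):
    """Feasible starting coefficients roughly matching a probability table."""
    p0 = float(np.clip(table[0], 0.02, 0.6))
    p1 = float(np.clip(table[-1], p0 + 0.05, 0.98))
    if model in ("DINA", "DINO"):
        return np.array([p0, p1 - p0])
    if model == "ACDM":
        return np.concatenate([[p0], np.full(kstar, (p1 - p0) / kstar)])
    if model == "LLM":
        from scipy.special import logit as _logit
        return np.concatenate(
            [[_logit(p0)], np.full(kstar, (_logit(p1) - _logit(p0)) / kstar)]
        )
    if model == "RRUM":
        return np.concatenate(
            [[np.log(p0)], np.full(kstar, (np.log(p1) - np.log(p0)) / kstar)]
        )
    raise ValueError(model)


class GDINAEstimator(BaseEstimator):
    """G-DINA family latent class model fitted by EM.

    Parameters
    ----------
    q : QMatrix
        Item-by-criterion incidence matrix; defines J and K.
    models : str or sequence of str, default "GDINA"
        Item response model per item ("GDINA", "ACDM", "LLM", "RRUM",
        "DINA", "DINO"); a single tag applies to every item. Items
        measuring one criterion are always fitted saturated (all family
        members coincide at K_j* = 1).
    monotone : bool, default True
        Constrain reduced-model main effects to be non-negative, so
        endorsement probabilities are non-decreasing in the profile
        partial order. The saturated table is estimated unconstrained.
    structure : {"saturated", "independent", "uniform", "fixed"}, default "saturated"
        Structural model for the class proportions. "saturated" estimates
        all 2**K proportions with Laplace smoothing; "independent" fits
        one prevalence per criterion and sets the proportions to their
        product; "uniform" fixes them at 1/2**K; "fixed" uses
        ``fixed_class_props`` unchanged.
    fixed_class_props : array, optional
        Class proportions used when ``structure == "fixed"``.
    max_iter : int, default 1000
    tol_param : float, default 1e-4
        Convergence: max absolute change of any item-class probability or
        class proportion.
    tol_loglik : float, default 1e-7
        Convergence additionally requires the log-likelihood gain to fall
        below this.
    smoothing : float, default 1e-10
        Laplace smoothing added to each class's expected count; keeps the
        saturated structural model away from empty-class collapse.
    prob_bound : float, default 1e-4
        Item probabilities are kept in [prob_bound, 1 - prob_bound] by
        constrained updates (never by post-hoc clipping of a fit result).
    random_state : int, default 0
        Seed for the perturbed-sample-mean initialisation.
    init_spread : float, default 0.4
        Width of the initial probability ramp from the no-criteria class
        to the all-criteria class.

    Attributes
    ----------
    item_params_ : list of ItemParams
    class_props_ : (2**K,) ndarray
    loglik_ : float
    loglik_path_ : (n_iter,) ndarray, non-decreasing
    n_iter_ : int
    converged_ : bool
    space_ : LatentClassSpace
    warnings_ : list of str
    """

    def __init__(self, q, models="GDINA", *, monotone=True,
                 structure="saturated", fixed_class_props=None,
                 max_iter=1000, tol_param=1e-4, tol_loglik=1e-7,
                 smoothing=1e-10, prob_bound=1e-4, random_state=0,
                 init_spread=0.4):
        self.q = q
        self.models = models
        self.monotone = monotone
        self.structure = structure
        self.fixed_class_props = fixed_class_props
        self.max_iter = max_iter
        self.tol_param = tol_param
        self.tol_loglik = tol_loglik
        self.smoothing = smoothing
        self.prob_bound = prob_bound
        self.random_state = random_state
        self.init_spread = init_spread

    # -- assignment handling -------------------------------------------------

    def _assignment(self):
        J = self.q.n_items
        if isinstance(self.models, str):
            tags = [self.models] * J
        else:
            tags = list(self.models)
            if len(tags) != J:
                raise ValueError("one model tag per item required")
        out = []
        for j, tag in enumerate(tags):
            kstar = self.q.kstar(j)
            if kstar == 1:
                out.append("GDINA")  # all family members coincide
            else:
                if tag not in ("GDINA", "ACDM", "LLM", "RRUM", "DINA", "DINO"):
                    raise ValueError(f"unknown model tag {tag!r} for item {j}")
                out.append(tag)
        return out

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y=None):
        q = self.q
        if not isinstance(q, QMatrix):
            q = QMatrix(np.asarray(q))
        if (q.entries.sum(axis=0) < 1).any():
            raise ValueError(
                "every criterion must be measured by at least one item "
                "for estimation"
            )
        vals, mask = _validate_responses(X, q.n_items)
        n, J = vals.shape
        space = enumerate_classes(q.n_criteria)
        C = space.n_classes
        gidx = _group_index(q, space)
        assignment = self._assignment()
        bound = self.prob_bound
        rng = np.random.default_rng(self.random_state)
        warns: list[str] = []

        obs_n = mask.sum(axis=0)
        with np.errstate(invalid="ignore"):
            means = np.where(obs_n > 0, (vals * mask).sum(axis=0) / obs_n, 0.5)
        for j in range(J):
            if means[j] <= bound or means[j] >= 1 - bound:
                warns.append(
                    f"item {q.item_ids[j]}: (nearly) constant responses; "
                    f"boundary-safe update applied"
                )
                warnings.warn(warns[-1], stacklevel=2)

        # initial tables: perturbed sample means ramped by profile count
        tables = []
        for j in range(J):
            kstar = q.kstar(j)
            counts = _group_counts(kstar)
            ramp = self.init_spread * (counts / kstar - 0.5)
            noise = rng.uniform(-0.02, 0.02, size=2**kstar)
            tables.append(np.clip(means[j] + ramp + noise, bound, 1 - bound))

        coeffs_cache = {}
        for j in range(J):
            if assignment[j] != "GDINA":
                coeffs_cache[j] = _init_coeffs(
                    assignment[j], q.kstar(j), tables[j], self.monotone
                )
                M = design_matrix(assignment[j], q.kstar(j))
                tables[j] = np.clip(
                    inv_link_fn(_LINK[assignment[j]])(M @ coeffs_cache[j]),
                    bound, 1 - bound,
                )

        if self.structure not in ("saturated", "independent", "uniform",
                                  "fixed"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "fixed":
            if self.fixed_class_props is None:
                raise ValueError("structure='fixed' requires fixed_class_props")
            pi = np.asarray(self.fixed_class_props, dtype=float)
            if pi.shape != (C,) or pi.min() < 0 or abs(pi.sum() - 1) > 1e-8:
                raise ValueError("fixed_class_props must be a length-2**K simplex")
        else:
            pi = np.full(C, 1.0 / C)

        Xobs = vals * mask
        Xmis = (1 - vals) * mask
        loglik_path = []
        converged = False
        prev_ll = -np.inf

        for it in range(self.max_iter):
            P = _item_prob_matrix(tables, gidx)
            logP = np.log(P)
            log1mP = np.log1p(-P)
            # (n, C) complete-data log-likelihood given class
            L = Xobs @ logP + Xmis @ log1mP
            joint = L + np.log(pi)
            norm = logsumexp(joint, axis=1)
            post = np.exp(joint - norm[:, None])
            ll = float(norm.sum())
            loglik_path.append(ll)

            # expected counts: per item j, class c
            Nc = mask.T @ post          # (J, C)
            Rc = Xobs.T @ post          # (J, C)

            max_delta = 0.0
            for j in range(J):
                kstar = q.kstar(j)
                G = 2**kstar
                N = np.bincount(gidx[j], weights=Nc[j], minlength=G)
                R = np.bincount(gidx[j], weights=Rc[j], minlength=G)
                if assignment[j] == "GDINA":
                    new = _mstep_gdina(R, N, bound)
                else:
                    c_new = _mstep_reduced(
                        assignment[j], kstar, R, N, bound, self.monotone,
                        coeffs_cache[j],
                    )
                    M = design_matrix(assignment[j], kstar)
                    cand = np.clip(
                        inv_link_fn(_LINK[assignment[j]])(M @ c_new),
                        bound, 1 - bound,
                    )
                    # generalised EM guard: never accept a worse item update
                    if _weighted_ll(cand, R, N) >= _weighted_ll(tables[j], R, N):
                        coeffs_cache[j] = c_new
                        new = cand
                    else:
                        new = tables[j]
                max_delta = max(max_delta, float(np.abs(new - tables[j]).max()))
                tables[j] = new

            if self.structure == "saturated":
                new_pi = (post.sum(axis=0) + self.smoothing)
                new_pi /= new_pi.sum()
                max_delta = max(max_delta, float(np.abs(new_pi - pi).max()))
                pi = new_pi
            elif self.structure == "independent":
                prev = np.clip((post @ space.profiles) .mean(axis=0),
                               bound, 1 - bound)
                new_pi = np.where(space.profiles == 1, prev, 1 - prev
                                  ).prod(axis=1)
                new_pi /= new_pi.sum()
                max_delta = max(max_delta, float(np.abs(new_pi - pi).max()))
                pi = new_pi
            # "uniform" and "fixed": pi unchanged

            if it > 0 and max_delta < self.tol_param \
                    and abs(ll - prev_ll) < self.tol_loglik:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll

        if not converged:
            warns.append(f"EM did not converge in {self.max_iter} iterations")

        # final E-step quantities at the converged parameters
        P = _item_prob_matrix(tables, gidx)
        L = Xobs @ np.log(P) + Xmis @ np.log1p(-P)
        norm = logsumexp(L + np.log(pi), axis=1)

        self.space_ = space
        self.q_ = q
        self.assignment_ = assignment
        self.class_props_ = pi
        self.prob_tables_ = tables
        self.group_index_ = gidx
        self.loglik_ = float(norm.sum())
        self.loglik_path_ = np.asarray(loglik_path)
        self.n_iter_ = len(loglik_path)
        self.converged_ = converged
        self.warnings_ = warns
        self.item_params_ = [
            self._params_for(j, tables[j], coeffs_cache.get(j)) for j in range(J)
        ]
        return self

    def _params_for(self, j, table, coeffs):
        model = self.assignment_[j]
        qrow = self.q_.entries[j]
        if model == "GDINA":
            M = design_matrix("GDINA", int(qrow.sum()))
            coeffs = np.linalg.solve(M, table)
        return ItemParams(model, qrow, coeffs, item_id=self.q_.item_ids[j])

    # -- inference -----------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "class_props_"):
            raise RuntimeError("estimator is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probability over the 2**K latent classes per respondent."""
        self._check_fitted()
        vals, mask = _validate_responses(X, self.q_.n_items)
        all_missing = mask.sum(axis=1) == 0
        if all_missing.any():
            warnings.warn(
                f"{int(all_missing.sum())} respondent(s) have no observed "
                f"responses; their posterior equals the class proportions",
                stacklevel=2,
            )
        P = _item_prob_matrix(self.prob_tables_, self.group_index_)
        L = (vals * mask) @ np.log(P) + ((1 - vals) * mask) @ np.log1p(-P)
        joint = L + np.log(self.class_props_)
        post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
        return post

    def score(self, X, y=None) -> float:
        """Mean marginal log-likelihood per respondent."""
        self._check_fitted()
        vals, mask = _validate_responses(X, self.q_.n_items)
        P = _item_prob_matrix(self.prob_tables_, self.group_index_)
        L = (vals * mask) @ np.log(P) + ((1 - vals) * mask) @ np.log1p(-P)
        return float(logsumexp(L + np.log(self.class_props_), axis=1).mean())

    def loglik_of(self, X) -> float:
        return self.score(X) * np.asarray(X).shape[0]

    # -- covariance ----------------------------------------------------------

    def item_score_matrix(self, X, j: int) -> np.ndarray:
        """Per-respondent score of the marginal log-likelihood w.r.t. item j's
        saturated probability table (n x 2**K_j*)."""
        self._check_fitted()
        vals, mask = _validate_responses(X, self.q_.n_items)
        post = self.predict_proba(X)
        table = self.prob_tables_[j]
        G = table.size
        # posterior mass per reduced group
        mass = np.zeros((post.shape[0], G))
        for g in range(G):
            mass[:, g] = post[:, self.group_index_[j] == g].sum(axis=1)
        p = table[None, :]
        resid = (vals[:, [j]] - p) / (p * (1 - p))
        return mass * resid * mask[:, [j]]

    def score_components(self, X):
        """Per-respondent score of the marginal log-likelihood w.r.t. every
        item's saturated table and (when estimated) the class proportions.

        Returns ``(S, item_slices)``: the n x P score matrix and, per item,
        the slice of columns holding its table parameters. Class-proportion
        columns (C - 1 free parameters) are appended after the item blocks
        for the saturated structural model.
        """
        self._check_fitted()
        vals, mask = _validate_responses(X, self.q_.n_items)
        post = self.predict_proba(X)
        n = vals.shape[0]
        slices = []
        cols = []
        start = 0
        for j in range(self.q_.n_items):
            table = self.prob_tables_[j]
            G = table.size
            mass = np.zeros((n, G))
            for g in range(G):
                mass[:, g] = post[:, self.group_index_[j] == g].sum(axis=1)
            p = table[None, :]
            resid = (vals[:, [j]] - p) / (p * (1 - p))
            cols.append(mass * resid * mask[:, [j]])
            slices.append(slice(start, start + G))
            start += G
        if self.structure == "saturated":
            pi = self.class_props_
            cols.append(post[:, 1:] / pi[1:] - (post[:, [0]] / pi[0]))
        elif self.structure == "independent":
            marg = post @ self.space_.profiles  # E[alpha_k | x_i]
            prev = np.clip(self.class_props_ @ self.space_.profiles,
                           1e-10, 1 - 1e-10)
            cols.append((marg - prev) / (prev * (1 - prev)))
        return np.concatenate(cols, axis=1), slices

    def joint_covariance(self, X, ridge: float = 1e-10):
        """Covariance blocks of every item's saturated table from the inverse
        of the joint OPG (empirical information) over all free parameters.

        Accounts for cross-parameter correlation (other items, structural
        proportions) that per-item blocks alone would miss. Returns
        ``(full_cov, item_slices)``.
        """
        S, slices = self.score_components(X)
        info = S.T @ S
        scale = np.trace(info) / info.shape[0] + 1.0
        cov = np.linalg.pinv(info + ridge * scale * np.eye(info.shape[0]),
                             hermitian=True)
        return cov, slices

    def item_covariance(self, X, j: int, ridge: float = 1e-8):
        """OPG (empirical information) covariance of item j's saturated table.

        Returns (covariance, regularized_flag); singular information is
        ridge-regularised and flagged.
        """
        S = self.item_score_matrix(X, j)
        info = S.T @ S
        flag = False
        if np.linalg.cond(info) > 1e12:
            info = info + ridge * (np.trace(info) / info.shape[0] + 1.0) * np.eye(
                info.shape[0]
            )
            flag = True
            warnings.warn(
                f"singular information for item {self.q_.item_ids[j]}; "
                f"ridge-regularised inverse used",
                stacklevel=2,
            )
        return np.linalg.inv(info), flag

    # -- serialisation -------------------------------------------------------

    def to_json(self, path=None, *, extra=None) -> str:
        self._check_fitted()
        payload = {
            "item_params": [p.to_dict() for p in self.item_params_],
            "class_props": self.class_props_.tolist(),
            "loglik": self.loglik_,
            "n_iter": self.n_iter_,
            "converged": self.converged_,
            "config": {
                "models": self.assignment_,
                "monotone": self.monotone,
                "structure": self.structure,
                "max_iter": self.max_iter,
                "tol_param": self.tol_param,
                "tol_loglik": self.tol_loglik,
                "prob_bound": self.prob_bound,
                "random_state": self.random_state,
            },
        }
        if extra:
            payload.update(extra)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


_LINK = {"GDINA": "identity", "ACDM": "identity", "DINA": "identity",
         "DINO": "identity", "LLM": "logit", "RRUM": "log"}


def _group_counts(kstar: int) -> np.ndarray:
    ids = np.arange(2**kstar)
    return ((ids[:, None] >> np.arange(kstar)) & 1).sum(axis=1)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def em_fit(responses, q: QMatrix, assignment="GDINA", **config) -> GDINAEstimator:
    """Fit the model by EM; returns the fitted :class:`GDINAEstimator`."""
    return GDINAEstimator(q, models=assignment, **config).fit(responses)


def class_posteriors(responses, fitted: GDINAEstimator) -> np.ndarray:
    """Per-respondent posterior over the 2**K latent classes."""
    return fitted.predict_proba(responses)


def parameter_covariance(responses, fitted: GDINAEstimator) -> list:
    """Per-item OPG covariance blocks of the saturated probability tables."""
    return [fitted.item_covariance(responses, j)[0]
            for j in range(fitted.q_.n_items)]


def read_responses(path) -> "pd.DataFrame":
    """Read a respondents x items CSV (header = item ids, cells 0/1/NA)."""
    import pandas as pd

    df = pd.read_csv(path)
    arr = df.to_numpy(dtype=float)
    mask = ~np.isnan(arr)
    if not np.isin(arr[mask], (0.0, 1.0)).all():
        raise ValueError("response CSV contains non-binary cells")
    return df


def write_responses(X, item_ids, path) -> None:
    import pandas as pd

    pd.DataFrame(np.asarray(X, dtype=float), columns=list(item_ids)).to_csv(
        path, index=False
    )
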