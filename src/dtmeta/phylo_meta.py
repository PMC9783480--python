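"""Phylogenetic correlation matrices and the multilevel REML meta-analysis.

The model for effect sizes y_i is

    y_i = mu [+ beta * moderator_i] + u_species(i) + s_study(i) + o_i + e_i

with u ~ MVN(0, sigma2_phylo * A) for the species-level phylogenetic effect,
s ~ iid N(0, sigma2_study), o ~ iid N(0, sigma2_obs), and e_i ~ N(0, v_i)
with the sampling variances v_i = boot_sd_i^2 treated as known.  Variance
components are estimated by REML on the log-variance scale with analytic
gradients; fixed effects by GLS at the REML variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import EffectSize, MetaFit, PhyloCorrelation, Phylogeny
from .errors import FitError

__all__ = [
    "grafen_branch_lengths",
    "phylo_correlation",
    "MultilevelModel",
    "fit_meta",
    "subgroup_fits",
    "variance_partition",
]


# ---------------------------------------------------------------------------
# Phylogenetic correlation
# ---------------------------------------------------------------------------

def grafen_branch_lengths(tree) -> None:
    """Assign Grafen heights (exponent 1) in place, scaled to unit depth.

    Each internal node's height is (number of descendant tips - 1), scaled by
    the root height; edge lengths are parent-child height differences.  The
    resulting tree is ultrametric with root-to-tip depth 1.
    """
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._n_tips = 1
            node._grafen_h = 0.0
        else:
            node._n_tips = sum(ch._n_tips for ch in node.child_nodes())
            node._grafen_h = float(node._n_tips - 1)
    root_h = tree.seed_node._grafen_h
    if root_h <= 0:
        raise ValueError("Grafen scaling needs a tree with at least 2 tips")
    for node in tree.preorder_node_iter():
        node._grafen_h /= root_h
        if node.parent_node is not None:
            node.edge.length = node.parent_node._grafen_h - node._grafen_h


def _equal_branch_lengths(tree) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = 1.0


def phylo_correlation(
    phylo: Phylogeny,
    tips: Optional[Sequence[str]] = None,
    branch_rule: str = "grafen",
) -> PhyloCorrelation:
    """Brownian-motion correlation matrix from a rooted tree.

    If the tree carries no branch lengths they are assigned per
    ``branch_rule`` ("grafen" height scaling, default, or "equal").  The
    correlation between two tips is depth(MRCA) / sqrt(depth_i * depth_j),
    which reduces to the shared-depth fraction on an ultrametric tree.  When
    ``tips`` is given the tree is pruned to those tips before branch lengths
    are (re)assigned.
    """
    tree = phylo.tree.clone(depth=1)
    if tips is not None:
        labels = set(tips)
        present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = sorted(labels - present)
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        tree.retain_taxa_with_labels(sorted(labels))
    if not phylo.has_branch_lengths:
        if branch_rule == "grafen":
            grafen_branch_lengths(tree)
        elif branch_rule == "equal":
            _equal_branch_lengths(tree)
        else:
            raise ValueError(f"unknown branch_rule {branch_rule!r}")

    # node depths from the root
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._depth = 0.0
        else:
            node._depth = node.parent_node._depth + (node.edge.length or 0.0)

    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {lab: i for i, lab in enumerate(labels)}
    depth = np.array([leaf._depth for leaf in leaves])
    if np.any(depth <= 0):
        raise ValueError("zero root-to-tip depth; cannot normalize correlations")
    n = len(labels)

    # collect tip indices per subtree, fill pair entries at each MRCA
    cov = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tips = [index[node.taxon.label]]
            continue
        groups = [ch._tips for ch in node.child_nodes()]
        d = node._depth
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a])
                ib = np.asarray(groups[b])
                cov[np.ix_(ia, ib)] = d
                cov[np.ix_(ib, ia)] = d
        node._tips = [i for g in groups for i in g]
    corr = cov / np.sqrt(np.outer(depth, depth))
    np.fill_diagonal(corr, 1.0)
    pc = PhyloCorrelation(tuple(labels), corr)
    if tips is not None:
        pc = pc.submatrix(list(tips))
    return pc


# ---------------------------------------------------------------------------
# REML multilevel model
# ---------------------------------------------------------------------------

_LOG_FLOOR = math.log(1e-12)


class MultilevelModel:
    """REML machinery for a fixed design; reusable across permutation refits.

    Parameters are the three random-effect variances on the log scale.  The
    marginal covariance is V = s2_phylo*A + s2_study*S + s2_obs*I + diag(v)
    where A is the effect-level phylogenetic correlation and S the same-study
    indicator.
    """

    def __init__(self, y: np.ndarray, v: np.ndarray, X: np.ndarray,
                 A: np.ndarray, S: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.X = np.asarray(X, dtype=float)
        n = self.y.size
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.v.shape != (n,) or self.X.shape[0] != n:
            raise ValueError("shape mismatch")
        self.A = np.asarray(A, dtype=float)
        self.S = np.asarray(S, dtype=float)
        self.I = np.eye(n)
        self.n = n
        self._G = (self.A, self.S, self.I)

    @staticmethod
    def _small_inv(M: np.ndarray):
        """Inverse and log-determinant of a tiny SPD matrix (p <= 2 fast path)."""
        p = M.shape[0]
        if p == 1:
            m = M[0, 0]
            if m <= 0:
                raise np.linalg.LinAlgError("X'V^-1X not positive definite")
            return np.array([[1.0 / m]]), math.log(m)
        if p == 2:
            det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
            if det <= 0 or M[0, 0] <= 0:
                raise np.linalg.LinAlgError("X'V^-1X not positive definite")
            inv = np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det
            return inv, math.log(det)
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        return np.linalg.inv(M), logdet

    def _decompose(self, sigma2: np.ndarray):
        from scipy.linalg.lapack import dpotrf, dpotri

        V = sigma2[0] * self.A + sigma2[1] * self.S
        V.flat[:: self.n + 1] += sigma2[2] + self.v
        c, info = dpotrf(V, 1, 0, 0)  # lower Cholesky
        if info != 0:
            raise np.linalg.LinAlgError("V not positive definite")
        logdet_v = 2.0 * float(np.sum(np.log(c.diagonal())))
        Vi, info = dpotri(c, 1)
        if info != 0:
            raise np.linalg.LinAlgError("inversion of V failed")
        Vi = np.tril(Vi) + np.tril(Vi, -1).T  # dpotri fills the lower triangle only
        ViX = Vi @ self.X
        XtViX = self.X.T @ ViX
        XtViX_inv, logdet_x = self._small_inv(XtViX)
        beta = XtViX_inv @ (ViX.T @ self.y)
        resid = self.y - self.X @ beta
        Py = Vi @ resid  # X'Vi r = 0 at the GLS solution
        return Vi, ViX, XtViX_inv, logdet_v, logdet_x, beta, resid, Py

    def reml_nll(self, theta: np.ndarray) -> float:
        sigma2 = np.exp(theta)
        _, _, _, ldv, ldx, _, resid, Py = self._decompose(sigma2)
        return 0.5 * (ldv + ldx + float(resid @ Py))

    def reml_nll_grad(self, theta: np.ndarray):
        sigma2 = np.exp(theta)
        Vi, ViX, XtViX_inv, ldv, ldx, _, resid, Py = self._decompose(sigma2)
        nll = 0.5 * (ldv + ldx + float(resid @ Py))
        # P = Vi - ViX (X'ViX)^-1 ViX'
        P = Vi - ViX @ (XtViX_inv @ ViX.T)
        grad = np.empty(3)
        for j, G in enumerate(self._G):
            tr = float(np.sum(P * G))
            quad = float(Py @ (G @ Py))
            # d nll / d theta_j = 0.5*(tr - quad) * sigma2_j  (chain rule)
            grad[j] = 0.5 * (tr - quad) * sigma2[j]
        return nll, grad

    def gls(self, sigma2: np.ndarray):
        """Fixed effects and their covariance at given variance components."""
        _, _, XtViX_inv, _, _, beta, _, _ = self._decompose(
            np.asarray(sigma2, dtype=float))
        return beta, XtViX_inv

    def _starts(self, n_restarts: int, warm: Optional[np.ndarray]):
        tau = max(float(np.var(self.y)) - float(np.mean(self.v)), 1e-6)
        base = math.log(tau / 3.0)
        starts = []
        if warm is not None:
            starts.append(np.asarray(warm, dtype=float))
        starts.append(np.full(3, base))
        starts.append(np.array([base + 2.0, base - 2.0, base]))
        starts.append(np.array([base - 4.0, base + 1.0, base + 1.0]))
        starts.append(np.array([base + 1.0, base + 1.0, base - 4.0]))
        starts.append(np.full(3, base - 6.0))
        return starts[: max(1, n_restarts + (warm is not None))]

    def fit(self, n_restarts: int = 3, warm_start: Optional[np.ndarray] = None,
            maxiter: int = 200, ftol: float = 1e-12, gtol: float = 1e-9):
        """Return ``(theta_hat, nll, converged)`` over restarted L-BFGS-B runs."""
        ub = math.log(max(10.0 * float(np.var(self.y)) + 1.0, 10.0))
        bounds = [(_LOG_FLOOR, ub)] * 3
        best = None
        # legacy interface: far lower per-call overhead than minimize()
        factr = ftol / np.finfo(float).eps
        for x0 in self._starts(n_restarts, warm_start):
            x, f, info = optimize.fmin_l_bfgs_b(
                self.reml_nll_grad, np.clip(x0, _LOG_FLOOR, ub),
                bounds=bounds, maxiter=maxiter, factr=factr, pgtol=gtol,
            )
            if best is None or f < best[1] - 1e-12:
                best = (x, f, info["warnflag"] == 0)
        return best[0], float(best[1]), bool(best[2])


def satterthwaite_df(model: MultilevelModel, sigma2: Sequence[float],
                     coef_index: int = 0) -> float:
    """Satterthwaite effective degrees of freedom for one fixed effect.

    Propagates REML variance-component uncertainty (inverse observed
    information, numeric Hessian on the variance scale) through the gradient
    of the coefficient's squared SE.  Returns ``inf`` when the information is
    degenerate (e.g. all components on the boundary), in which case a normal
    reference is appropriate.
    """
    s2 = np.maximum(np.asarray(sigma2, dtype=float), 0.0)
    _, ViX, C, *_ = model._decompose(s2)
    g = np.empty(3)
    for j, G in enumerate(model._G):
        M = ViX.T @ G @ ViX  # -d(X'V^-1 X)/d sigma2_j
        g[j] = (C @ M @ C)[coef_index, coef_index]

    def nll(s: np.ndarray) -> float:
        return model.reml_nll(np.log(np.maximum(s, 1e-14)))

    h = np.maximum(1e-8, 1e-3 * s2)
    H = np.zeros((3, 3))
    for a in range(3):
        ea = np.zeros(3); ea[a] = h[a]
        for b in range(a, 3):
            eb = np.zeros(3); eb[b] = h[b]
            H[a, b] = H[b, a] = (
                nll(s2 + ea + eb) - nll(s2 + ea - eb)
                - nll(s2 - ea + eb) + nll(s2 - ea - eb)
            ) / (4.0 * h[a] * h[b])
    try:
        cov_s2 = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return math.inf
    var_c = float(g @ cov_s2 @ g)
    c = float(C[coef_index, coef_index])
    if var_c <= 0 or not math.isfinite(var_c):
        return math.inf
    return 2.0 * c * c / var_c


def _expand_corr(effects: Sequence[EffectSize],
                 corr: Optional[PhyloCorrelation]) -> np.ndarray:
    species = [e.species for e in effects]
    if corr is None:
        uniq = sorted(set(species))
        corr = PhyloCorrelation.identity(uniq)
    idx = {sp: i for i, sp in enumerate(corr.species)}
    missing = sorted(set(species) - idx.keys())
    if missing:
        raise FitError(f"species missing from correlation matrix: {missing}")
    ix = np.array([idx[sp] for sp in species])
    return corr.matrix[np.ix_(ix, ix)]


def build_model(
    effects: Sequence[EffectSize],
    corr: Optional[PhyloCorrelation] = None,
    moderator: Optional[str] = None,
    moderator_values: Optional[np.ndarray] = None,
) -> MultilevelModel:
    """Assemble the design for ``fit_meta`` from effect-size rows."""
    effects = list(effects)
    if len(effects) < 2:
        raise FitError("need at least 2 effects")
    missing_w = [e.dataset_id for e in effects if e.boot_sd is None]
    if missing_w:
        raise FitError(f"effects without sampling variance: {missing_w}")
    y = np.array([e.ln_slope for e in effects])
    v = np.array([e.boot_sd**2 for e in effects])
    n = len(effects)
    X = np.ones((n, 1))
    if moderator is not None:
        if moderator_values is not None:
            m = np.asarray(moderator_values, dtype=float)
        else:
            m = np.array([getattr(e, moderator) for e in effects], dtype=float)
        if np.ptp(m) == 0:
            raise FitError("singular design: moderator has no variation")
        X = np.column_stack([X, m])
    A = _expand_corr(effects, corr)
    studies = np.array([e.study_id for e in effects])
    S = (studies[:, None] == studies[None, :]).astype(float)
    return MultilevelModel(y, v, X, A, S)


def fit_meta(
    effects: Sequence[EffectSize],
    corr: Optional[PhyloCorrelation] = None,
    moderator: Optional[str] = None,
    *,
    moderator_values: Optional[np.ndarray] = None,
    fix_sigma2: Optional[Sequence[float]] = None,
    n_restarts: int = 3,
    warm_start: Optional[np.ndarray] = None,
    maxiter: int = 200,
    compute_df: bool = True,
) -> MetaFit:
    """Fit the multilevel meta-analytic model by REML.

    With ``moderator`` (an EffectSize field name, normally ``"sdtd"``) the
    model includes that covariate and the reported z statistic tests its
    coefficient; otherwise the pooled mean is tested.  ``fix_sigma2`` skips
    REML and fits GLS at the given variance components (used for degenerate
    closed-form checks).
    """
    model = build_model(effects, corr, moderator, moderator_values)
    if fix_sigma2 is not None:
        sigma2 = np.asarray(fix_sigma2, dtype=float)
        if np.any(sigma2 < 0):
            raise FitError("fixed variance components must be >= 0")
        theta = np.log(np.maximum(sigma2, 1e-300))
        nll = model.reml_nll(theta)
        converged = True
    else:
        theta, nll, converged = model.fit(n_restarts=n_restarts,
                                          warm_start=warm_start, maxiter=maxiter)
        sigma2 = np.exp(theta)
        sigma2 = np.where(sigma2 < 1e-10, 0.0, sigma2)
    beta, cov = model.gls(np.asarray(sigma2, float))
    se = np.sqrt(np.diag(cov))
    test_idx = 1 if moderator is not None else 0
    z = float(beta[test_idx] / se[test_idx])
    fit = MetaFit(
        mu_hat=float(beta[0]),
        se_mu=float(se[0]),
        sigma2_phylo=float(sigma2[0]),
        sigma2_study=float(sigma2[1]),
        sigma2_obs=float(sigma2[2]),
        z_stat=z,
        n_effects=model.n,
        converged=converged,
        loglik_reml=float(-nll) if nll == nll else math.nan,
        moderator=moderator,
        p_param=float(2.0 * stats.norm.sf(abs(z))),
    )
    if moderator is not None:
        fit.beta_hat = float(beta[1])
        fit.se_beta = float(se[1])
    if compute_df and fix_sigma2 is None:
        fit.df = satterthwaite_df(model, sigma2, coef_index=test_idx)
    fit._theta = theta  # stashed for warm-started refits
    return fit


def subgroup_fits(
    effects: Sequence[EffectSize],
    corr: Optional[PhyloCorrelation] = None,
    group_field: str = "order_name",
    adjust: str = "holm",
    min_group: int = 2,
    **fit_kwargs,
):
    """Per-group pooled fits with a table-wide multiplicity adjustment.

    Groups with fewer than ``min_group`` effects are skipped with a notice.
    Returns ``(table, fits, skipped)`` where ``table`` is a DataFrame with
    one row per fitted group including raw and adjusted p-values.
    """
    from statsmodels.stats.multitest import multipletests

    groups: dict = {}
    for e in effects:
        groups.setdefault(getattr(e, group_field), []).append(e)
    fits, skipped, rows = {}, [], []
    for name in sorted(groups):
        members = groups[name]
        if len(members) < min_group:
            skipped.append((name, f"only {len(members)} effect(s)"))
            continue
        sub_corr = corr.submatrix(sorted({e.species for e in members})) if corr is not None else None
        fit = fit_meta(members, sub_corr, **fit_kwargs)
        fits[name] = fit
        rows.append(
            {
                "group": name,
                "n_effects": fit.n_effects,
                "mean_effect": fit.mu_hat,
                "se": fit.se_mu,
                "z": fit.z_stat,
                "p_raw": fit.p_perm if fit.p_perm is not None else fit.p_param,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        _, p_adj, _, _ = multipletests(table["p_raw"].to_numpy(), method=adjust)
        table["p_adj"] = p_adj
    return table, fits, skipped


def variance_partition(fit: MetaFit) -> Optional[dict]:
    """Shares of the estimated random-effect variances; None if all zero."""
    comps = {
        "phylo": fit.sigma2_phylo,
        "study": fit.sigma2_study,
        "obs": fit.sigma2_obs,
    }
    total = sum(comps.values())
    if total <= 0:
        return None
    return {k: val / total for k, val in comps.items()}
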