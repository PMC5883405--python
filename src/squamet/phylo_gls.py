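"""Phylogenetic generalized least squares with Pagel's lambda.

Under Brownian trait evolution on a rooted tree the expected covariance of
two tips is the shared root-to-MRCA path length; Pagel's lambda scales the
off-diagonal of that matrix, interpolating between phylogenetic
independence (lambda = 0) and the full Brownian structure (lambda = 1).
GLS fits here use maximum likelihood (not REML) so log-likelihoods are
comparable across fixed-effect structures and between OLS and PGLS fits.

Provides: covariance construction, the lambda transform, GLS fitting,
profile-ML estimation of lambda with a likelihood-drop confidence interval,
AIC ranking and the likelihood-ratio test, sequential (Type-I) factorial
ANOVA in the whitened space, a pooled two-sample t-test, and Brownian
maximum-likelihood ancestral state reconstruction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .trait_data import Phylogeny

logger = logging.getLogger("squamet")

_DIAG_JITTER = 1e-10


class GLSError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Covariance
# ---------------------------------------------------------------------------


@dataclass
class PhyloCovariance:
    """Brownian tip covariance: entry (i, j) is the root-to-MRCA path length."""

    matrix: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.species):
            raise GLSError("covariance shape does not match species list")
        self.matrix = m


def vcv_from_tree(phylo: Phylogeny) -> PhyloCovariance:
    """Shared-path-length covariance in the tree's leaf order.

    Computed in one postorder sweep: when children merge at a node of depth
    d, every cross-child tip pair gets covariance d; diagonals are tip
    depths.
    """
    tree = phylo.tree
    tips = list(tree.leaf_node_iter())
    index = {id(lf): i for i, lf in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            V[i, i] = depth[id(node)]
            below[id(node)] = [i]
        else:
            groups = [below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            V[i, j] = V[j, i] = d
            below[id(node)] = [i for g in groups for i in g]
    return PhyloCovariance(V, [lf.taxon.label for lf in tips])


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries by lambda, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise GLSError(f"lambda must lie in [0, 1], got {lam}")
    V = np.asarray(V, dtype=float)
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def _chol(V: np.ndarray) -> np.ndarray:
    try:
        return cholesky(V, lower=True)
    except np.linalg.LinAlgError:
        pass
    except Exception:
        pass
    logger.warning("covariance not positive definite; adding %g to diagonal", _DIAG_JITTER)
    return cholesky(V + _DIAG_JITTER * np.eye(V.shape[0]), lower=True)


# ---------------------------------------------------------------------------
# GLS fit
# ---------------------------------------------------------------------------


@dataclass
class GLSFit:
    """A fitted (P)GLS regression.

    ``sigma2`` is the ML scale (r' V^-1 r / n); coefficient standard errors
    use the unbiased scale so the V = I case reproduces OLS exactly.  AIC
    counts the coefficients, the scale, and lambda when it was estimated.
    """

    response: str
    term_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalues: np.ndarray
    lambda_: float | None
    lambda_ci: tuple[float, float] | None
    lambda_estimated: bool
    sigma2: float
    lnL: float
    aic: float
    r2: float
    n: int
    p: int
    residuals: np.ndarray
    _y: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return self.p + 1 + (1 if self.lambda_estimated else 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "coef": self.coef,
                "se": self.se,
                "t": self.tstat,
                "p": self.pvalues,
            }
        )


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray | None = None,
    term_names: list[str] | None = None,
    response: str = "y",
    lambda_: float | None = None,
    lambda_ci: tuple[float, float] | None = None,
    lambda_estimated: bool = False,
) -> GLSFit:
    """ML generalized least squares of y on X with error covariance sigma2*V.

    V = None means the identity (ordinary least squares).  r2 is computed in
    the whitened space against the whitened-intercept null.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise GLSError("y and X have different lengths")
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{i}" for i in range(p)]
    if V is None:
        L = None
        yw, Xw = y, X
        logdet = 0.0
    else:
        V = np.asarray(V, dtype=float)
        L = _chol(V)
        yw = solve_triangular(L, y, lower=True)
        Xw = solve_triangular(L, X, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if np.linalg.matrix_rank(Xw) < p:
        raise GLSError("design matrix is rank deficient")
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    rw = yw - Xw @ beta
    rss = float(rw @ rw)
    sigma2_ml = rss / n
    lnL = -0.5 * (n * math.log(2 * math.pi) + n * math.log(max(sigma2_ml, 1e-300)) + logdet + n)
    dof = n - p
    sigma2_ub = rss / dof if dof > 0 else 0.0
    cov = sigma2_ub * np.linalg.inv(XtX)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = 2.0 * stats.t.sf(np.abs(tval), dof) if dof > 0 else np.full(p, np.nan)
    # whitened-space r2 against the GLS intercept-only null
    ones = np.ones(n)
    onesw = ones if V is None else solve_triangular(L, ones, lower=True)
    mu = float(onesw @ yw) / float(onesw @ onesw)
    tss = float(np.sum((yw - mu * onesw) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    n_params = p + 1 + (1 if lambda_estimated else 0)
    aic = -2.0 * lnL + 2.0 * n_params
    return GLSFit(
        response=response,
        term_names=list(term_names),
        coef=beta,
        se=se,
        tstat=np.asarray(tval, dtype=float),
        pvalues=np.asarray(pval, dtype=float),
        lambda_=lambda_,
        lambda_ci=lambda_ci,
        lambda_estimated=lambda_estimated,
        sigma2=sigma2_ml,
        lnL=float(lnL),
        aic=float(aic),
        r2=float(r2),
        n=n,
        p=p,
        residuals=y - X @ beta,
        _y=y,
    )


def _profile_lnL(lam: float, y, X, V) -> float:
    fit = gls_fit(y, X, lambda_transform(V, lam))
    return fit.lnL


def fit_lambda_ml(
    y: np.ndarray,
    X: np.ndarray,
    tree_or_V,
    term_names: list[str] | None = None,
    response: str = "y",
    grid_size: int = 101,
) -> GLSFit:
    """Profile-ML estimate of Pagel's lambda on [0, 1].

    A coarse grid locates the optimum, a bounded scalar search refines it
    (tolerance 1e-8; ties broken toward smaller lambda), and the 95% CI is
    the profile set {lambda : lnL >= lnL_max - 1.92}.  AIC counts lambda as
    one extra parameter.
    """
    V = tree_or_V.matrix if isinstance(tree_or_V, PhyloCovariance) else None
    if V is None:
        V = vcv_from_tree(tree_or_V).matrix if isinstance(tree_or_V, Phylogeny) else np.asarray(tree_or_V, dtype=float)
    grid = np.linspace(0.0, 1.0, grid_size)
    lnls = np.array([_profile_lnL(g, y, X, V) for g in grid])
    if not np.all(np.isfinite(lnls)):
        raise GLSError("lambda profile likelihood is not finite on the grid")
    i = int(np.argmax(lnls))  # argmax returns the first (smallest-lambda) tie
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    best_lam, best_lnl = grid[i], lnls[i]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda g: -_profile_lnL(g, y, X, V),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise GLSError(f"lambda optimization failed: {res.message}")
        if -res.fun > best_lnl:
            best_lam, best_lnl = float(res.x), float(-res.fun)
    ci = _lambda_profile_ci(y, X, V, grid, lnls, best_lam, best_lnl)
    fit = gls_fit(
        y,
        X,
        lambda_transform(V, best_lam),
        term_names=term_names,
        response=response,
        lambda_=best_lam,
        lambda_ci=ci,
        lambda_estimated=True,
    )
    return fit


def _lambda_profile_ci(y, X, V, grid, lnls, lam_hat, lnl_hat) -> tuple[float, float]:
    """95% profile CI: lambda with lnL within 1.92 (= chi2_1 0.95 / 2) of the max."""
    cut = lnl_hat - 1.92

    def g(lam):
        return _profile_lnL(lam, y, X, V) - cut

    inside = lnls >= cut
    lo, hi = 0.0, 1.0
    if not inside[0]:
        # bracket the lower crossing between the last outside and first inside point
        j = int(np.argmax(inside))
        a, b = grid[j - 1], grid[j] if grid[j] <= lam_hat else lam_hat
        lo = float(optimize.brentq(g, a, b, xtol=1e-6)) if g(a) < 0 <= g(b) else grid[j]
    if not inside[-1]:
        j = len(inside) - 1 - int(np.argmax(inside[::-1]))
        a = grid[j] if grid[j] >= lam_hat else lam_hat
        b = grid[j + 1]
        hi = float(optimize.brentq(g, a, b, xtol=1e-6)) if g(b) < 0 <= g(a) else grid[j]
    return (min(lo, lam_hat), max(hi, lam_hat))


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float


def aic_compare(fits: list[GLSFit]) -> list[tuple[GLSFit, float]]:
    """Rank fits of the same response by AIC; returns (fit, delta-AIC) ascending."""
    if not fits:
        raise GLSError("no fits to compare")
    y0 = fits[0]._y
    for f in fits[1:]:
        if f._y is None or y0 is None or f._y.shape != y0.shape or not np.allclose(f._y, y0):
            raise GLSError("fits do not share the same response data")
    ranked = sorted(fits, key=lambda f: f.aic)
    best = ranked[0].aic
    return [(f, f.aic - best) for f in ranked]


def likelihood_ratio_test(nested: GLSFit, full: GLSFit) -> TestResult:
    """2*(lnL_full - lnL_nested) against chi-squared with the parameter-count
    difference as df.  The statistic is floored at 0 (boundary cases)."""
    df = full.n_params - nested.n_params
    if df <= 0:
        raise GLSError("'full' model must have more parameters than 'nested'")
    stat = max(0.0, 2.0 * (full.lnL - nested.lnL))
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Sequential ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Type-I (sequential) ANOVA rows plus the residual row."""

    rows: list[dict]
    residual: dict
    lambda_: float | None
    response: str

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "source": r["term"],
                "df": r["df"],
                "SS": r["SS"],
                "MS": r["MS"],
                "F": r["F"],
                "P": r["P"],
            }
            for r in self.rows
        ]
        recs.append(
            {
                "source": "Residuals",
                "df": self.residual["df"],
                "SS": self.residual["SS"],
                "MS": self.residual["MS"],
                "F": np.nan,
                "P": np.nan,
            }
        )
        return pd.DataFrame(recs)


def _term_column(term: str, data: pd.DataFrame) -> np.ndarray:
    """A single design column for a term; ':' denotes an interaction product."""
    col = np.ones(len(data))
    for part in term.split(":"):
        if part not in data.columns:
            raise GLSError(f"term variable {part!r} not in data")
        v = np.asarray(data[part], dtype=float)
        col = col * v
    return col


def sequential_anova(
    response: str,
    ordered_terms: list[str],
    data: pd.DataFrame,
    tree_or_V,
    lambda_policy="ml",
) -> AnovaTable:
    """Sequential-SS factorial ANOVA in the whitened space.

    Each term contributes one column (binary factors are 0/1-coded); its SS
    is the drop in whitened RSS when added in order.  F uses the residual
    mean square of the full model.  ``lambda_policy`` is a number in [0, 1]
    or ``"ml"`` (lambda estimated once, on the full model).
    """
    y = np.asarray(data[response], dtype=float)
    n = len(y)
    cols = [_term_column(t, data) for t in ordered_terms]
    for t, c in zip(ordered_terms, cols):
        if np.ptp(c) < 1e-12 and ":" not in t:
            raise GLSError(f"factor/covariate {t!r} has a single observed level")
    X_full = np.column_stack([np.ones(n)] + cols)
    if isinstance(tree_or_V, Phylogeny):
        V0 = vcv_from_tree(tree_or_V).matrix
    elif isinstance(tree_or_V, PhyloCovariance):
        V0 = tree_or_V.matrix
    elif tree_or_V is None:
        V0 = np.eye(n)
    else:
        V0 = np.asarray(tree_or_V, dtype=float)
    if lambda_policy == "ml":
        full = fit_lambda_ml(y, X_full, PhyloCovariance(V0, list(range(n))))
        lam = full.lambda_
    else:
        lam = float(lambda_policy)
    V = lambda_transform(V0, lam)
    L = _chol(V)
    yw = solve_triangular(L, y, lower=True)
    ones_w = solve_triangular(L, np.ones(n), lower=True)

    def rss_of(design_w: np.ndarray) -> float:
        beta, _, _, _ = np.linalg.lstsq(design_w, yw, rcond=None)
        r = yw - design_w @ beta
        return float(r @ r)

    Xw_all = solve_triangular(L, X_full, lower=True)
    rss_prev = rss_of(ones_w[:, None])
    ss = []
    for k in range(1, X_full.shape[1]):
        rss_k = rss_of(Xw_all[:, : k + 1])
        ss.append(max(rss_prev - rss_k, 0.0))
        rss_prev = rss_k
    rss_full = rss_prev
    df_res = n - X_full.shape[1]
    ms_res = rss_full / df_res
    rows = []
    for t, s in zip(ordered_terms, ss):
        ms = s / 1.0
        F = ms / ms_res
        rows.append(
            {"term": t, "df": 1, "SS": s, "MS": ms, "F": F, "P": float(stats.f.sf(F, 1, df_res))}
        )
    return AnovaTable(
        rows=rows,
        residual={"df": df_res, "SS": rss_full, "MS": ms_res},
        lambda_=lam,
        response=response,
    )


# ---------------------------------------------------------------------------
# Pooled t-test and ancestral states
# ---------------------------------------------------------------------------


def pooled_t_test(group_a, group_b) -> TestResult:
    """Two-sample pooled-variance t-test; df = n1 + n2 - 2, two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise GLSError("both groups need at least 2 values")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, df, 1.0)
        raise GLSError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(float(res.statistic), df, float(res.pvalue))


def asr_brownian(phylo: Phylogeny, tip_values: dict[str, float]) -> dict[str, float]:
    """ML Brownian ancestral states at every internal node.

    The root is the GLS mean (1'V^-1 x)/(1'V^-1 1); other nodes are the
    conditional (BLUP/ML) estimates mu + c'V^-1(x - mu), where c holds the
    shared path lengths between the node and each tip.  Internal nodes
    without labels are keyed "node<i>" in preorder.
    """
    pc = vcv_from_tree(phylo)
    missing = [s for s in pc.species if s not in tip_values]
    if missing:
        raise GLSError(f"missing tip values: {missing}")
    x = np.array([float(tip_values[s]) for s in pc.species])
    V = pc.matrix
    L = _chol(V)
    Vinv_x_minus = cho_solve((L, True), x)
    ones = np.ones(len(x))
    Vinv_1 = cho_solve((L, True), ones)
    mu = float(ones @ Vinv_x_minus) / float(ones @ Vinv_1)
    w = cho_solve((L, True), x - mu * ones)
    tree = phylo.tree
    tips = list(tree.leaf_node_iter())
    index = {id(lf): i for i, lf in enumerate(tips)}
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length or 0.0)
    # tip set below each node
    below: dict[int, set[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = {index[id(node)]}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.child_nodes()))
    out: dict[str, float] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        counter += 1
        label = node.label if node.label else f"node{counter}"
        D = below[id(node)]
        j = next(iter(D))
        c = np.empty(len(x))
        for i in range(len(x)):
            c[i] = depth[id(node)] if i in D else V[j, i]
        out[label] = mu + float(c @ w)
    return out
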