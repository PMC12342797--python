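"""Phylogenetic generalized least squares (PGLS) under Brownian motion.

Regression of a per-species response (here, the percentage-point
difference in proportional IRG loss between a crop and its wild
relative) on explanatory variables, with residual covariance
proportional to shared phylogenetic branch length: under Brownian
motion, Cov[y_i, y_j] = sigma^2 * C[i, j] where C[i, j] is the length
of the root-to-MRCA path shared by tips i and j.

The fit is exact GLS via Cholesky whitening:

    beta_hat   = (X' C^-1 X)^-1 X' C^-1 y
    sigma2_hat = r' C^-1 r / (n - p)        (r = y - X beta_hat)
    SE_k       = sqrt(sigma2_hat * [(X' C^-1 X)^-1]_kk)

with Wald t statistics beta_hat/SE on n − p degrees of freedom.  No
branch-length transformation (e.g. Pagel's lambda) is estimated: the
covariance is pure Brownian; an optional ``lam`` argument rescales the
off-diagonal as a fixed extension, default 1 (off).

Variance inflation factors are computed on the raw (non-phylogenetic)
design, as a plain initial linear model would: VIF_k = 1/(1 − R²_k)
from regressing predictor k on the remaining predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.linalg import solve_triangular

__all__ = [
    "load_tree",
    "bm_covariance",
    "PGLSFit",
    "gls_fit",
    "vif",
    "PGLSSuite",
    "run_pgls_suite",
    "PREDICTOR_NAMES",
]

#: Canonical explanatory variables for the crop trait table.
PREDICTOR_NAMES: tuple[str, ...] = (
    "life_history",
    "irg_repertoire_size",
    "assembly_genome_size",
    "pct_genes_duplicated",
    "divergence_time_from_wild",
    "time_since_domestication",
    "min_crop_cycle",
    "world_area_harvested",
)


def load_tree(source: str, *, is_path: bool = True) -> dendropy.Tree:
    """Read a rooted newick tree and validate branch lengths.

    Every non-root edge must carry a finite, non-negative length; a
    missing length raises rather than silently defaulting to zero.
    """
    if is_path:
        tree = dendropy.Tree.get(path=source, schema="newick")
    else:
        tree = dendropy.Tree.get(data=source, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge may be lengthless
            continue
        if edge.length is None:
            raise ValueError(
                f"newick edge above {_edge_label(edge)} has no branch length"
            )
        if not np.isfinite(edge.length) or edge.length < 0:
            raise ValueError(
                f"newick edge above {_edge_label(edge)} has invalid length {edge.length}"
            )
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def _edge_label(edge: dendropy.Edge) -> str:
    node = edge.head_node
    if node.taxon is not None:
        return repr(node.taxon.label)
    return "an internal node"


def bm_covariance(
    tree: dendropy.Tree, tips: list[str], lam: float = 1.0
) -> np.ndarray:
    """Brownian-motion covariance structure of the requested tips.

    ``C[i, j]`` is the root-to-MRCA shared path length of tips i and j
    (the diagonal holds root-to-tip distances).  Symmetric and positive
    semi-definite by construction; scale (the Brownian rate) is left to
    the GLS fit.  ``lam`` optionally applies a fixed Pagel-style
    rescaling of the off-diagonal shared paths (1 = pure Brownian, the
    default; 0 = star phylogeny); it is an extension knob, never
    estimated.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lam must lie in [0, 1]")
    taxa = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = [t for t in tips if t not in taxa]
    if missing:
        raise ValueError(f"tips not found in tree: {missing}")

    # depth of every node from the root
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = float(node.edge.length or 0.0)
        else:
            depth[node] = depth[node.parent_node] + float(node.edge.length or 0.0)

    # ancestor sets for MRCA lookup
    anc: dict[str, list[dendropy.Node]] = {}
    for t in tips:
        chain = []
        node = taxa[t]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[t] = chain

    n = len(tips)
    C = np.zeros((n, n), dtype=float)
    for i, ti in enumerate(tips):
        C[i, i] = depth[taxa[ti]]
        anc_i = set(anc[ti])
        for j in range(i + 1, n):
            mrca = next(node for node in anc[tips[j]] if node in anc_i)
            C[i, j] = C[j, i] = lam * depth[mrca]
    return C


@dataclass
class PGLSFit:
    """Result of one GLS fit: per-term Wald statistics plus fit summaries."""

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    sigma2_hat: float
    log_likelihood: float
    df_resid: int
    vif: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "t": self.t_values,
                "p": self.p_values,
            }
        )


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    terms: list[str] | None = None,
) -> PGLSFit:
    """Generalized least squares with known covariance structure C.

    Reduces to OLS when ``C`` is the identity.  Raises on rank-deficient
    designs and non-positive-definite covariances.  With ``n = p + 1``
    the fit is still produced (df = 1) with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n or C.shape != (n, n):
        raise ValueError("inconsistent shapes for y, X, C")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if n == p + 1:
        warnings.warn("only one residual degree of freedom; inference is fragile")

    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc

    # whiten: solve L z = v  =>  z = L^-1 v
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)

    if np.linalg.matrix_rank(Xw) < p:
        raise ValueError("design matrix is rank deficient")

    XtX = Xw.T @ Xw
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    df = n - p
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_vals = 2.0 * sp_stats.t.sf(np.abs(t_vals), df)

    # Gaussian log-likelihood at beta_hat with the ML variance rss/n
    logdet_C = 2.0 * float(np.log(np.diag(L)).sum())
    sigma2_ml = rss / n if rss > 0 else 0.0
    if sigma2_ml > 0:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet_C + n)
    else:
        loglik = float("inf")

    if terms is None:
        terms = [f"x{k}" for k in range(p)]
    return PGLSFit(
        terms=list(terms),
        coefficients=beta,
        standard_errors=se,
        t_values=np.asarray(t_vals, dtype=float),
        p_values=np.asarray(p_vals, dtype=float),
        sigma2_hat=sigma2,
        log_likelihood=float(loglik),
        df_resid=df,
    )


def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors from ordinary auxiliary regressions.

    For each predictor k, regress it (with intercept) on the remaining
    predictors and report 1/(1 − R²).  Perfect collinearity yields
    ``inf``.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF requires at least 2 predictors")
    out: dict[str, float] = {}
    for k in X.columns:
        yk = X[k].to_numpy(dtype=float)
        others = X.drop(columns=[k]).to_numpy(dtype=float)
        A = np.column_stack([np.ones(len(yk)), others])
        coef, _, rank, _ = np.linalg.lstsq(A, yk, rcond=None)
        resid = yk - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yk - yk.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"predictor {k!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        out[k] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class PGLSSuite:
    """Bivariate fits per predictor, one multivariate fit, and VIFs."""

    bivariate: dict[str, PGLSFit]
    multivariate: PGLSFit
    vif: dict[str, float]

    def bivariate_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.bivariate):
            fit = self.bivariate[name]
            fr = fit.to_frame()
            fr.insert(0, "model", f"bivariate:{name}")
            rows.append(fr)
        return pd.concat(rows, ignore_index=True)


def run_pgls_suite(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    response: str = "response",
    predictors: list[str] | None = None,
    tip_rename: dict[str, str] | None = None,
    id_column: str = "crop_id",
) -> PGLSSuite:
    """Fit all bivariate models, the multivariate model, and VIFs.

    ``tip_rename`` maps trait-table ids to tree tip labels for crops
    represented in the tree by a proxy relative.  Results are invariant
    to the row order of ``table``.
    """
    table = table.sort_values(id_column).reset_index(drop=True)
    if predictors is None:
        predictors = [
            c for c in table.columns if c not in (id_column, response)
        ]
    ids = table[id_column].astype(str).tolist()
    tips = [tip_rename.get(i, i) if tip_rename else i for i in ids]
    C = bm_covariance(tree, tips)

    y = table[response].to_numpy(dtype=float)
    if table[predictors + [response]].isna().any().any():
        raise ValueError("missing values in fitted columns")
    n = len(y)

    bivariate: dict[str, PGLSFit] = {}
    for name in predictors:
        X = np.column_stack([np.ones(n), table[name].to_numpy(dtype=float)])
        bivariate[name] = gls_fit(y, X, C, terms=["intercept", name])

    Xm = np.column_stack(
        [np.ones(n)] + [table[p].to_numpy(dtype=float) for p in predictors]
    )
    multivariate = gls_fit(y, Xm, C, terms=["intercept"] + list(predictors))
    vifs = vif(table[list(predictors)]) if len(predictors) >= 2 else {}
    multivariate.vif = vifs
    return PGLSSuite(bivariate=bivariate, multivariate=multivariate, vif=vifs)
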