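"""Network logistic regression: design construction, IRLS fit, inference.

The model regresses a binary outcome on covariates, node levels, and one
per-individual edge feature per network edge:

    logit P(Y=1) = b0 + sum_s a_s Z_s + sum_i b_i x_i
                   + sum_{i<j} I_ij g_ij E_ij

where ``I_ij`` restricts edge terms to pairs connected in the topology and
``E_ij`` is either the KDE-based PMI estimate (PMINR) or the standardized
node cross-product (PMNR, the linear-correlation comparator).  Per-term Wald
tests identify which nodes or edges carry signal; a likelihood-ratio test
against the covariates-only model tests the whole network at once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .network import NetworkTopology
from .pmi import EdgeFeatureMatrix, pmi_features

logger = logging.getLogger(__name__)

__all__ = [
    "SampleData",
    "DesignSpec",
    "NetworkRegressionFit",
    "pmnr_features",
    "build_design",
    "fit_logistic",
    "wald_tests",
    "lrt_global",
    "fit_pminr",
]

#: IRLS stopping rules
MAX_ITER = 100
SCORE_TOL = 1e-8
LOGLIK_RTOL = 1e-10
#: a standardized-scale coefficient beyond this flags (quasi-)separation
SEPARATION_BOUND = 15.0


class SeparationWarning(UserWarning):
    """Emitted when a logistic fit shows signs of complete/quasi-separation."""


@dataclass(frozen=True)
class SampleData:
    """Samples-by-nodes matrix, binary response, optional covariates.

    ``X`` columns must be named; they are reordered to the topology's node
    order at design time.
    """

    X: pd.DataFrame
    y: np.ndarray
    Z: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        uniq = np.unique(y)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"response must be binary 0/1, saw values {uniq}")
        if len(y) != len(self.X):
            raise ValueError("X and y row counts differ")
        if self.Z is not None and len(self.Z) != len(y):
            raise ValueError("Z and y row counts differ")
        object.__setattr__(self, "y", y.astype(float))

    @property
    def n(self) -> int:
        return len(self.y)

    def node_matrix(self, topology: NetworkTopology) -> np.ndarray:
        """Node columns in topology order (by name)."""
        missing = [nm for nm in topology.node_names if nm not in self.X.columns]
        if missing:
            raise KeyError(f"sample matrix lacks node column(s) {missing}")
        return self.X.loc[:, list(topology.node_names)].to_numpy(dtype=float)


@dataclass(frozen=True)
class DesignSpec:
    """Term names and roles of a network design matrix.

    Column order is ``[intercept | covariates | nodes | edges]``.
    """

    covariate_names: tuple[str, ...]
    node_names: tuple[str, ...]
    edge_names: tuple[str, ...]
    intercept: bool = True

    def __post_init__(self) -> None:
        names = self.term_names
        if len(set(names)) != len(names):
            raise ValueError("term names must be unique")

    @property
    def term_names(self) -> tuple[str, ...]:
        head = ("(Intercept)",) if self.intercept else ()
        return head + self.covariate_names + self.node_names + self.edge_names

    @property
    def roles(self) -> tuple[str, ...]:
        head = ("intercept",) if self.intercept else ()
        return (
            head
            + ("covariate",) * len(self.covariate_names)
            + ("node",) * len(self.node_names)
            + ("edge",) * len(self.edge_names)
        )

    @property
    def n_columns(self) -> int:
        return len(self.term_names)

    @property
    def network_df(self) -> int:
        """Degrees of freedom of the whole-network LRT: nodes + edges."""
        return len(self.node_names) + len(self.edge_names)


@dataclass
class NetworkRegressionFit:
    """Fitted network logistic model with Wald and likelihood-ratio inference."""

    spec: DesignSpec
    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    n_iter: int
    wald: pd.DataFrame | None = None
    lrt_statistic: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None
    warnings_: list[str] = field(default_factory=list)

    def summary_frame(self, bonferroni: bool = False) -> pd.DataFrame:
        """Tidy per-term table: term, role, estimate, se, z, p."""
        table = self.wald if self.wald is not None else wald_tests(self)
        out = table.copy()
        if bonferroni:
            m = self.spec.network_df
            out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
        return out


def pmnr_features(X: np.ndarray, topology: NetworkTopology) -> EdgeFeatureMatrix:
    """Standardized cross-product edge features (linear-correlation baseline).

    ``E_ij,l = (x_il - mean_i)(x_jl - mean_j) / (s_i s_j)`` with sample
    standard deviations; the column mean equals the Pearson correlation of the
    two nodes up to the ``(N-1)/N`` factor, so each individual carries its own
    additive share of the linear connection strength.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != topology.n_nodes:
        raise ValueError(f"X must be N x {topology.n_nodes}")
    sd = X.std(axis=0, ddof=1)
    bad = np.where(sd <= 0)[0]
    if bad.size:
        raise ValueError(f"degenerate node {topology.node_names[bad[0]]!r}: zero variance")
    centered = (X - X.mean(axis=0)) / sd
    edges = topology.edge_list()
    if edges:
        values = np.column_stack([centered[:, i] * centered[:, j] for i, j in edges])
    else:
        values = np.empty((X.shape[0], 0))
    return EdgeFeatureMatrix(values, tuple(edges), tuple(topology.edge_names()))


def build_design(
    data: SampleData,
    topology: NetworkTopology,
    edge_features: EdgeFeatureMatrix,
) -> tuple[np.ndarray, DesignSpec]:
    """Assemble the design matrix ``[1 | Z | nodes | edges]``."""
    Xn = data.node_matrix(topology)
    ef = edge_features.values
    if ef.shape[0] != data.n:
        raise ValueError("edge feature rows do not match sample rows")
    if tuple(edge_features.edge_index) != tuple(topology.edge_list()):
        raise ValueError("edge feature columns do not match topology edges")
    blocks = [np.ones((data.n, 1))]
    cov_names: tuple[str, ...] = ()
    if data.Z is not None and data.Z.shape[1] > 0:
        blocks.append(data.Z.to_numpy(dtype=float))
        cov_names = tuple(map(str, data.Z.columns))
    blocks.append(Xn)
    if ef.shape[1]:
        blocks.append(ef)
    design = np.hstack(blocks)
    spec = DesignSpec(
        covariate_names=cov_names,
        node_names=tuple(topology.node_names),
        edge_names=tuple(edge_features.edge_names),
    )
    assert design.shape[1] == spec.n_columns
    return design, spec


def _check_collinearity(design: np.ndarray, names: tuple[str, ...]) -> None:
    # rank via QR; name the dependent columns from small R diagonals
    r = np.linalg.qr(design, mode="r")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 1.0
    dependent = [names[k] for k in np.where(diag < 1e-9 * scale)[0]]
    if dependent:
        raise np.linalg.LinAlgError(
            f"singular design: collinear term(s) {dependent}"
        )


def fit_logistic(
    design: np.ndarray,
    y: np.ndarray,
    spec: DesignSpec | None = None,
    ridge: float = 0.0,
) -> NetworkRegressionFit:
    """Maximum-likelihood logistic fit via iteratively reweighted least squares.

    Stops when the largest score component drops below 1e-8 or the relative
    log-likelihood change drops below 1e-10, up to 100 iterations.  The
    coefficient covariance is the inverse observed information.  A fit whose
    standardized-scale coefficients exceed 15, or that fails to converge, is
    flagged (complete or quasi-separation) rather than silently returned; a
    small ridge (``ridge=1e-4``) can be passed to stabilize such fits.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = design.shape
    if y.size != n:
        raise ValueError("design and y row counts differ")
    if not np.isin(np.unique(y), [0.0, 1.0]).all():
        raise ValueError("y must be binary 0/1")
    if spec is None:
        spec = DesignSpec((), tuple(f"x{j}" for j in range(1, k)), ())
    names = spec.term_names
    if len(names) != k:
        raise ValueError("spec does not match design width")
    if n <= k:
        warnings.warn(
            f"only {n} observations for {k} parameters; fit may be unstable",
            UserWarning,
            stacklevel=2,
        )
    _check_collinearity(design, names)

    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = design @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = design.T @ (y - mu) - ridge * beta
        info = design.T @ (design * w[:, None]) + ridge * np.eye(k)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta = design @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if ridge:
            ll -= 0.5 * ridge * float(beta @ beta)
        if np.max(np.abs(score)) < SCORE_TOL or (
            np.isfinite(ll_old) and abs(ll - ll_old) < LOGLIK_RTOL * (abs(ll_old) + 1.0)
        ):
            converged = True
            break
        ll_old = ll

    eta = design @ beta
    mu = expit(eta)
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    w = mu * (1.0 - mu)
    info = design.T @ (design * w[:, None]) + ridge * np.eye(k)
    cov = np.linalg.pinv(info)
    cov = 0.5 * (cov + cov.T)

    col_scale = design.std(axis=0, ddof=0)
    col_scale[col_scale == 0] = 1.0
    if np.max(np.abs(beta * col_scale)) > SEPARATION_BOUND:
        converged = False
    fit = NetworkRegressionFit(
        spec=spec,
        coefficients=beta,
        covariance=cov,
        loglik=loglik,
        converged=converged,
        n_obs=n,
        n_iter=it,
    )
    if not converged:
        msg = "logistic fit flagged non-converged (possible complete/quasi-separation)"
        fit.warnings_.append(msg)
        warnings.warn(msg, SeparationWarning, stacklevel=2)
    fit.wald = wald_tests(fit)
    return fit


def wald_tests(fit: NetworkRegressionFit) -> pd.DataFrame:
    """Per-term Wald table: ``z = estimate/se``, two-sided normal p-value."""
    se = np.sqrt(np.maximum(np.diag(fit.covariance), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.coefficients / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": fit.spec.term_names,
            "role": fit.spec.roles,
            "estimate": fit.coefficients,
            "se": se,
            "z": z,
            "p": p,
        }
    )
    if not fit.converged:
        table.attrs["warning"] = "non-converged fit; Wald p-values unreliable"
    return table


def lrt_global(
    full_fit: NetworkRegressionFit, data: SampleData
) -> tuple[float, int, float]:
    """Whole-network likelihood-ratio test.

    Compares the full model to the intercept+covariates-only reduction on the
    same rows; the statistic ``2 (l_full - l_reduced)`` is referred to a
    chi-square with ``#nodes + #edges`` degrees of freedom.
    """
    spec = full_fit.spec
    df = spec.network_df
    if df == 0:
        return 0.0, 0, 1.0
    blocks = [np.ones((data.n, 1))]
    if data.Z is not None and data.Z.shape[1] > 0:
        blocks.append(data.Z.to_numpy(dtype=float))
    reduced_design = np.hstack(blocks)
    reduced_spec = DesignSpec(spec.covariate_names, (), ())
    reduced = fit_logistic(reduced_design, data.y, reduced_spec)
    stat = max(2.0 * (full_fit.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df))
    if not (full_fit.converged and reduced.converged):
        logger.warning("LRT computed from a non-converged fit")
    return stat, df, p


def fit_pminr(
    data: SampleData,
    topology: NetworkTopology,
    method: str = "pmi",
    grid_mode: bool = True,
    standardize_edges: bool = False,
    ridge: float = 0.0,
    bonferroni: bool = False,
) -> NetworkRegressionFit:
    """Fit the network regression end to end.

    ``method="pmi"`` builds KDE-based PMI edge features (PMINR);
    ``method="product"`` builds standardized cross-products (PMNR).  The
    returned fit carries the Wald table and the whole-network LRT.
    """
    if method not in ("pmi", "product"):
        raise ValueError(f"unknown method {method!r}; expected 'pmi' or 'product'")
    Xn = data.node_matrix(topology)
    if method == "pmi":
        ef = pmi_features(Xn, topology, grid_mode=grid_mode)
    else:
        ef = pmnr_features(Xn, topology)
    if standardize_edges and ef.values.size:
        v = ef.values
        sd = v.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        ef = EdgeFeatureMatrix((v - v.mean(axis=0)) / sd, ef.edge_index, ef.edge_names)
    design, spec = build_design(data, topology, ef)
    fit = fit_logistic(design, data.y, spec, ridge=ridge)
    fit.lrt_statistic, fit.lrt_df, fit.lrt_p = lrt_global(fit, data)
    if bonferroni:
        fit.wald = fit.summary_frame(bonferroni=True)
    return fit
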