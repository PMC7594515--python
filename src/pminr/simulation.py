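"""Monte-Carlo evaluation of type-I error and power for network regression.

The data-generating process mirrors a case-control co-expression study on a
known pathway topology:

* Node values are multivariate normal with unit variances and edge-wise
  correlations drawn uniformly from {0.10, 0.15, ..., 0.55}; the covariance
  matrix is redrawn until positive definite.
* Four dependence scenarios — ``linear`` (plain Gaussian), ``quadratic``
  (``x_j = a*x_i^2 + eps``), ``sine`` (``x_j = a*sin(x_i) + eps``) and
  ``sine_squared`` (``x_j = a*sin(x_i)^2 + eps``) — set the shape of the
  connection on a designated edge.
* The binary response follows a zero-intercept logistic model whose linear
  predictor collects node effects ``beta*x_i`` and edge effects
  ``gamma*e_ij`` with the generator-side edge term ``e_ij = x_i*x_j``
  (linear/quadratic) or ``a*g(x_i)*x_j`` for the sine-type scenarios.
* Effect targets (which node and/or edge carries signal) are redrawn each
  replicate, so the operating characteristics average over the topology.

Each replicate fits both PMINR (PMI edge features) and PMNR (product-moment
edge features) and records whether the designated node's Wald test, the
designated edge's Wald test, and the global LRT reject at the 5% level; under
a null configuration the tested node/edge is a randomly chosen no-effect
target.  Rejection proportions are aggregated with binomial Monte-Carlo
standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .network import NetworkTopology
from .regression import SampleData, fit_pminr

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "EffectMap",
    "OperatingCharacteristics",
    "sample_covariance",
    "simulate_nodes",
    "simulate_response",
    "pick_targets",
    "run_operating_characteristics",
]

SCENARIOS = ("linear", "quadratic", "sine", "sine_squared")
SITUATIONS = ("null", "node_only", "edge_only", "node_edge_on_edge", "node_edge_off_edge")

#: edge correlations are drawn uniformly from this ladder
RHO_CHOICES = np.arange(0.10, 0.551, 0.05).round(2)
PD_EIG_TOL = 1e-10
MAX_COV_ATTEMPTS = 1000

_NONLINEAR_G: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "quadratic": np.square,
    "sine": np.sin,
    "sine_squared": lambda t: np.sin(t) ** 2,
}


@dataclass(frozen=True)
class EffectMap:
    """Which node/edge carries signal in a replicate, and which are tested.

    ``node``/``edge`` are the targets with nonzero coefficients (``None``
    under the null); ``tested_node``/``tested_edge`` are the terms whose Wald
    p-values the harness records — under the null these are randomly selected
    no-effect targets.
    """

    node: int | None = None
    edge: tuple[int, int] | None = None
    tested_node: int | None = None
    tested_edge: tuple[int, int] | None = None

    def coefficients(
        self, topology: NetworkTopology, beta: float, gamma: float
    ) -> tuple[np.ndarray, dict[tuple[int, int], float]]:
        betas = np.zeros(topology.n_nodes)
        gammas: dict[tuple[int, int], float] = {}
        if self.node is not None:
            betas[self.node] = beta
        if self.edge is not None:
            if not topology.has_edge(*self.edge):
                raise ValueError(f"effect on non-edge pair {self.edge}")
            gammas[self.edge] = gamma
        return betas, gammas


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation design.

    Defaults reproduce the study conditions: node effect ``beta = 0.3``, edge
    effect ``gamma = 0.2`` for the linear and quadratic scenarios and 0.6 for
    the sine-type ones, nonlinear strength ``alpha = 1.0``, zero intercept,
    targets redrawn per replicate, covariance redrawn per replicate.
    """

    topology: NetworkTopology
    scenario: str = "linear"
    situation: str = "null"
    n: int = 500
    replicates: int = 1000
    beta: float = 0.3
    gamma: float | None = None
    alpha: float = 1.0
    seed: int = 0
    random_targets: bool = True
    fixed_targets: EffectMap | None = None
    redraw_covariance: bool = True
    methods: tuple[str, ...] = ("pmi", "product")
    level: float = 0.05
    grid_mode: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.situation not in SITUATIONS:
            raise ValueError(f"unknown situation {self.situation!r}")
        if self.n < 50:
            raise ValueError("n must be at least 50")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if not self.random_targets and self.fixed_targets is None:
            raise ValueError("fixed-target mode requires fixed_targets")
        if self.gamma is None:
            default = 0.2 if self.scenario in ("linear", "quadratic") else 0.6
            object.__setattr__(self, "gamma", default)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Rejection proportions per method and test, with Monte-Carlo SE."""

    table: pd.DataFrame
    n_failures: int = 0

    def proportion(self, method: str, test: str) -> float:
        row = self.table[(self.table.method == method) & (self.table.test == test)]
        return float(row["proportion"].iloc[0])

    def se(self, method: str, test: str) -> float:
        row = self.table[(self.table.method == method) & (self.table.test == test)]
        return float(row["se"].iloc[0])


def sample_covariance(
    topology: NetworkTopology, rng: np.random.Generator
) -> np.ndarray:
    """Unit-diagonal covariance with random edge correlations.

    Off-diagonal ``(i, j)`` is a draw from {0.10, 0.15, ..., 0.55} when the
    pair is an edge and zero otherwise; the whole matrix is redrawn until its
    smallest eigenvalue is positive.
    """
    p = topology.n_nodes
    edges = topology.edge_list()
    for _ in range(MAX_COV_ATTEMPTS):
        sigma = np.eye(p)
        if edges:
            rhos = rng.choice(RHO_CHOICES, size=len(edges))
            for (i, j), rho in zip(edges, rhos):
                sigma[i, j] = sigma[j, i] = rho
        if np.linalg.eigvalsh(sigma).min() > PD_EIG_TOL:
            return sigma
    raise RuntimeError(
        f"no positive-definite covariance found in {MAX_COV_ATTEMPTS} attempts; "
        "the topology may be too dense for the correlation ladder"
    )


def simulate_nodes(
    config: SimulationConfig,
    sigma: np.ndarray,
    rng: np.random.Generator,
    nonlinear_edge: tuple[int, int] | None = None,
) -> np.ndarray:
    """Draw the N x p node matrix.

    All scenarios start from ``N_p(0, sigma)``.  Nonlinear scenarios then
    overwrite the designated edge's second node as ``x_j = alpha*g(x_i) +
    eps`` with ``eps ~ N(0, 1)`` and ``g`` the scenario's transform, so the
    dependence along that edge is purely nonlinear.
    """
    X = rng.multivariate_normal(
        np.zeros(config.topology.n_nodes), sigma, size=config.n, method="cholesky"
    )
    if config.scenario != "linear" and nonlinear_edge is not None:
        i, j = nonlinear_edge
        g = _NONLINEAR_G[config.scenario]
        X[:, j] = config.alpha * g(X[:, i]) + rng.standard_normal(config.n)
    return X


def generator_edge_term(
    X: np.ndarray, edge: tuple[int, int], scenario: str, alpha: float
) -> np.ndarray:
    """Generator-side edge value entering the response model.

    ``x_i * x_j`` for the linear scenario; ``alpha * g(x_i) * x_j`` for the
    nonlinear scenarios, matching how the dependence was generated.
    """
    i, j = edge
    if scenario == "linear":
        return X[:, i] * X[:, j]
    return alpha * _NONLINEAR_G[scenario](X[:, i]) * X[:, j]


def simulate_response(
    X: np.ndarray,
    topology: NetworkTopology,
    effect_map: EffectMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the binary response from the zero-intercept logistic generator.

    ``logit P(Y=1) = sum_i beta_i x_i + sum_{ij} gamma_ij e_ij`` with the
    generator-side edge term from :func:`generator_edge_term`.  With all
    effects zero the groups are balanced in expectation.
    """
    betas, gammas = effect_map.coefficients(topology, config.beta, config.gamma)
    eta = X @ betas
    for edge, g in gammas.items():
        eta = eta + g * generator_edge_term(X, edge, config.scenario, config.alpha)
    prob = expit(eta)
    return (rng.random(X.shape[0]) < prob).astype(float)


def pick_targets(
    topology: NetworkTopology, situation: str, rng: np.random.Generator
) -> EffectMap:
    """Draw effect (and tested) targets for one replicate.

    ``node_only``: one random node.  ``edge_only``: one random edge.
    ``node_edge_on_edge``: a random edge plus one of its endpoints.
    ``node_edge_off_edge``: a random edge plus a node not incident to it.
    ``null``: no effects; a random node and edge are still drawn as the
    no-effect targets whose tests estimate the type-I error.
    """
    if situation not in SITUATIONS:
        raise ValueError(f"unknown situation {situation!r}")
    edges = topology.edge_list()
    if not edges and situation != "node_only":
        raise ValueError(f"situation {situation!r} needs at least one edge")

    def rand_node() -> int:
        return int(rng.integers(topology.n_nodes))

    def rand_edge() -> tuple[int, int]:
        return edges[int(rng.integers(len(edges)))]

    if situation == "null":
        return EffectMap(tested_node=rand_node(), tested_edge=rand_edge())
    if situation == "node_only":
        node = rand_node()
        return EffectMap(node=node, tested_node=node, tested_edge=rand_edge())
    if situation == "edge_only":
        edge = rand_edge()
        return EffectMap(edge=edge, tested_node=rand_node(), tested_edge=edge)
    if situation == "node_edge_on_edge":
        edge = rand_edge()
        node = edge[int(rng.integers(2))]
        return EffectMap(node=node, edge=edge, tested_node=node, tested_edge=edge)
    # node_edge_off_edge
    for _ in range(1000):
        edge = rand_edge()
        node = rand_node()
        if node not in edge:
            return EffectMap(node=node, edge=edge, tested_node=node, tested_edge=edge)
    raise ValueError("topology admits no node off the chosen edge")


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator,
    sigma: np.ndarray | None = None,
) -> tuple[SampleData, EffectMap]:
    """One replicate's data: covariance, targets, nodes, response.

    ``sigma`` overrides the per-replicate covariance draw (fixed-covariance
    mode)."""
    topo = config.topology
    if config.random_targets:
        effects = pick_targets(topo, config.situation, rng)
    else:
        effects = config.fixed_targets
    if sigma is None:
        sigma = sample_covariance(topo, rng)
    nonlinear_edge = effects.edge if effects.edge is not None else effects.tested_edge
    X = simulate_nodes(config, sigma, rng, nonlinear_edge=nonlinear_edge)
    y = simulate_response(X, topo, effects, config, rng)
    data = SampleData(X=pd.DataFrame(X, columns=list(topo.node_names)), y=y)
    return data, effects


def _edge_term_name(topology: NetworkTopology, edge: tuple[int, int]) -> str:
    i, j = min(edge), max(edge)
    return f"{topology.node_names[i]}~{topology.node_names[j]}"


def run_operating_characteristics(config: SimulationConfig) -> OperatingCharacteristics:
    """Estimate rejection proportions over the configured replicates.

    Per-replicate RNG streams are spawned deterministically from the master
    seed, so results are reproducible and independent of execution order.
    Replicates whose fits fail outright are excluded from the denominator and
    tallied; more than 5% failures triggers a warning.
    """
    topo = config.topology
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.replicates)
    fixed_sigma = None
    if not config.redraw_covariance:
        sigma_rng = np.random.Generator(np.random.PCG64(master.spawn(1)[0]))
        fixed_sigma = sample_covariance(topo, sigma_rng)
    tests = ("node", "edge", "global")
    hits = {(m, t): 0 for m in config.methods for t in tests}
    used = 0
    failures = 0

    for r in range(config.replicates):
        rng = np.random.Generator(np.random.PCG64(streams[r]))
        try:
            data, effects = simulate_dataset(config, rng, sigma=fixed_sigma)
            node_term = topo.node_names[effects.tested_node]
            edge_term = _edge_term_name(topo, effects.tested_edge)
            results = {}
            for method in config.methods:
                fit = fit_pminr(
                    data, topo, method=method, grid_mode=config.grid_mode
                )
                table = fit.wald.set_index("term")
                results[method] = {
                    "node": float(table.loc[node_term, "p"]),
                    "edge": float(table.loc[edge_term, "p"]),
                    "global": fit.lrt_p,
                }
        except Exception as exc:  # noqa: BLE001 - replicate-level containment
            failures += 1
            logger.warning("replicate %d failed: %s", r, exc)
            continue
        used += 1
        for method, ps in results.items():
            for t in tests:
                if ps[t] < config.level:
                    hits[(method, t)] += 1

    if failures > 0.05 * config.replicates:
        logger.warning(
            "%d of %d replicates failed and were excluded", failures, config.replicates
        )
    rows = []
    for method in config.methods:
        for t in tests:
            prop = hits[(method, t)] / used if used else np.nan
            se = np.sqrt(prop * (1 - prop) / used) if used else np.nan
            rows.append(
                {
                    "scenario": config.scenario,
                    "situation": config.situation,
                    "n": config.n,
                    "method": {"pmi": "PMINR", "product": "PMNR"}.get(method, method),
                    "test": t,
                    "rejections": hits[(method, t)],
                    "replicates": used,
                    "proportion": prop,
                    "se": se,
                }
            )
    return OperatingCharacteristics(pd.DataFrame(rows), n_failures=failures)


def run_grid(
    base: SimulationConfig, sample_sizes: tuple[int, ...]
) -> pd.DataFrame:
    """Run one configuration across a grid of sample sizes; tidy long table."""
    frames = []
    for k, n in enumerate(sample_sizes):
        cfg = replace(base, n=n, seed=base.seed + k + 1)
        frames.append(run_operating_characteristics(cfg).table)
    return pd.concat(frames, ignore_index=True)
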