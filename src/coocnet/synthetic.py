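"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its ``seed`` argument: identical
seeds give bit-identical outputs.  Randomness always flows through a
dedicated :func:`numpy.random.default_rng` stream constructed inside the
operation, never through global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, TAXONOMY_COLUMNS


class SimulationError(ValueError):
    pass


@dataclass
class PlantedGraph:
    """Ground-truth conditional-dependence graph for count simulation.

    ``edges`` maps sorted index pairs ``(i, j)`` to the signed
    partial-association magnitude placed in the precision matrix.
    """

    n_taxa: int
    edges: dict
    precision: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.precision, dtype=float)
        if P.shape != (self.n_taxa, self.n_taxa):
            raise SimulationError("precision shape mismatch")
        if not np.allclose(P, P.T):
            raise SimulationError("precision must be symmetric")
        off = set(self.edges)
        for i in range(self.n_taxa):
            for j in range(i + 1, self.n_taxa):
                nz = P[i, j] != 0
                if nz != ((i, j) in off):
                    raise SimulationError(
                        f"precision support disagrees with edge set at ({i}, {j})"
                    )
        self.precision = P

    @property
    def edge_set(self) -> set:
        return set(self.edges)

    def edge_frame(self, taxon_ids=None) -> pd.DataFrame:
        ids = taxon_ids or [f"taxon_{i:04d}" for i in range(self.n_taxa)]
        rows = [
            {
                "taxon_i": ids[i],
                "taxon_j": ids[j],
                "sign": "+" if m > 0 else "-",
                "magnitude": abs(m),
            }
            for (i, j), m in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "sign", "magnitude"])


def generate_planted_graph(
    n_taxa: int,
    edge_density: float,
    positive_fraction: float = 0.5,
    magnitude_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    min_eigenvalue: float = 0.1,
) -> PlantedGraph:
    """Draw an Erdos-Renyi signed precision graph, then inflate the diagonal
    until the smallest eigenvalue reaches ``min_eigenvalue``.

    ``edge_density`` may be 0 (empty graph) but must be < 1.
    """
    if not (0 <= edge_density < 1):
        raise SimulationError("edge_density must be in [0, 1)")
    lo, hi = magnitude_range
    if lo <= 0 or hi < lo:
        raise SimulationError("magnitudes must be positive")
    if not (0 <= positive_fraction <= 1):
        raise SimulationError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    P = np.zeros((n_taxa, n_taxa))
    edges: dict = {}
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            if rng.random() < edge_density:
                mag = rng.uniform(lo, hi)
                sgn = 1.0 if rng.random() < positive_fraction else -1.0
                # a positive partial association corresponds to a negative
                # off-diagonal precision entry
                edges[(i, j)] = sgn * mag
                P[i, j] = P[j, i] = -sgn * mag
    np.fill_diagonal(P, 1.0)
    for _ in range(100):
        mn = np.linalg.eigvalsh(P).min()
        if mn >= min_eigenvalue:
            return PlantedGraph(n_taxa=n_taxa, edges=edges, precision=P, seed=seed)
        np.fill_diagonal(P, np.diag(P) * 1.1)
    raise SimulationError(
        "could not reach positive-definiteness in 100 diagonal-inflation steps"
    )


def _default_taxonomy(taxon_ids, rng: np.random.Generator) -> pd.DataFrame:
    """Nested random taxonomy: every taxon fully classified as bacteria."""
    n = len(taxon_ids)
    n_class = max(2, n // 20)
    n_order = max(3, n // 10)
    n_family = max(4, n // 5)
    n_genus = max(5, n // 2)
    cls = rng.integers(0, n_class, n)
    # children drawn within the parent to keep ranks nested
    order = cls * n_order + rng.integers(0, n_order, n)
    family = order * n_family + rng.integers(0, n_family, n)
    genus = family * n_genus + rng.integers(0, n_genus, n)
    tax = pd.DataFrame(
        {
            "domain": "Bacteria",
            "class": [f"c{v}" for v in cls],
            "order": [f"o{v}" for v in order],
            "family": [f"f{v}" for v in family],
            "genus": [f"g{v}" for v in genus],
            "species": [f"s{i}" for i in range(n)],
        },
        index=pd.Index(taxon_ids, name="taxon_id"),
    )
    return tax[list(TAXONOMY_COLUMNS)]


def simulate_counts(
    graph: PlantedGraph,
    n_samples: int,
    mean_depth: int = 10_000,
    depth_dispersion: float = 0.3,
    batch_labels=None,
    batch_effects=None,
    seed: int = 0,
    base_log_abundance: np.ndarray | None = None,
    sample_prefix: str = "sample",
) -> AbundanceTable:
    """Logistic-normal -> multinomial count table from a planted graph.

    Latent log-abundances are multivariate normal with covariance equal to
    the inverse planted precision; per-sample compositions come from a
    softmax, and integer counts from a multinomial draw at a lognormal
    library depth scaled by the sample's batch multiplier.
    """
    if n_samples < 2:
        raise SimulationError("need at least 2 samples")
    if mean_depth <= 0:
        raise SimulationError("mean_depth must be positive")
    if depth_dispersion < 0:
        raise SimulationError("depth_dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    p = graph.n_taxa
    cov = np.linalg.inv(graph.precision)
    mu = (
        np.zeros(p)
        if base_log_abundance is None
        else np.asarray(base_log_abundance, dtype=float)
    )
    latent = rng.multivariate_normal(mu, cov, size=n_samples, method="cholesky")
    comp = np.exp(latent - latent.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)

    if batch_labels is None:
        batch_labels = ["batch0"] * n_samples
    batch_labels = list(batch_labels)
    if len(batch_labels) != n_samples:
        raise SimulationError("batch_labels length mismatch")
    batch_effects = dict(batch_effects or {})
    mult = np.array([float(batch_effects.get(b, 1.0)) for b in batch_labels])
    if np.any(mult <= 0):
        raise SimulationError("batch multipliers must be positive")

    depths = rng.lognormal(
        mean=math.log(mean_depth), sigma=depth_dispersion, size=n_samples
    )
    depths = np.maximum(1, np.round(depths * mult)).astype(np.int64)

    counts = np.empty((p, n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depths[s], comp[s])

    taxon_ids = [f"taxon_{i:04d}" for i in range(p)]
    sample_ids = [f"{sample_prefix}_{s:04d}" for s in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=taxon_ids, columns=sample_ids)
    counts_df.index.name = "taxon_id"
    taxonomy = _default_taxonomy(taxon_ids, rng)
    metadata = pd.DataFrame(
        {
            "population": "SIM",
            "biomass_g": np.nan,
            "batch": batch_labels,
            "run_group": sample_ids,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return AbundanceTable(counts_df, taxonomy, metadata)


def simulate_biomass_groups(
    tables,
    mode: str = "per-group-graph",
    link_params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach continuous wet-biomass values to samples.

    ``per-group-graph`` takes one table per intended quantile group (counts
    from group-specific planted graphs) and draws biomass inside disjoint,
    increasing ranges so empirical quartiles recover the groups.
    ``covariate-link`` takes a single table and draws biomass from a
    monotone link on a per-sample community summary (default: log library
    size), ``biomass = exp(slope * z + noise_sd * eps) * scale``.
    """
    rng = np.random.default_rng(seed)
    if mode == "per-group-graph":
        if isinstance(tables, AbundanceTable):
            tables = [tables]
        n_total = sum(t.n_samples for t in tables)
        if n_total < 8:
            raise SimulationError("need at least 8 samples for quartile grouping")
        rows = []
        for g, table in enumerate(tables):
            # disjoint group ranges (g, g+1) guarantee quantile recovery
            vals = g + rng.uniform(0.05, 0.95, size=table.n_samples)
            for sid, v in zip(table.sample_ids, vals):
                rows.append((sid, 100.0 * v, f"G{g + 1}"))
        meta = pd.DataFrame(
            rows, columns=["sample_id", "biomass_g", "true_group"]
        ).set_index("sample_id")
        return meta
    if mode == "covariate-link":
        table = tables[0] if isinstance(tables, (list, tuple)) else tables
        if table.n_samples < 8:
            raise SimulationError("need at least 8 samples for quartile grouping")
        params = dict(link_params or {})
        slope = float(params.get("slope", 1.0))
        noise_sd = float(params.get("noise_sd", 0.25))
        scale = float(params.get("scale", 100.0))
        summary = params.get("summary", "log_depth")
        if callable(summary):
            z = np.asarray(summary(table), dtype=float)
        elif summary == "log_depth":
            z = np.log1p(table.counts.sum(axis=0).to_numpy(dtype=float))
        elif summary == "richness":
            z = (table.counts.to_numpy() > 0).sum(axis=0).astype(float)
        else:
            raise SimulationError(f"unknown summary {summary!r}")
        sd = z.std()
        z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
        eps = rng.standard_normal(table.n_samples)
        biomass = scale * np.exp(slope * z + noise_sd * eps)
        return pd.DataFrame(
            {"biomass_g": biomass},
            index=pd.Index(table.sample_ids, name="sample_id"),
        )
    raise SimulationError(f"unknown mode {mode!r}")


@dataclass
class AssemblySimSpec:
    """Parameters for the presence-absence assembly generator."""

    mode: str  # "niche" | "stochastic"
    n_sites: int
    pool_size: int
    seed: int = 0
    # stochastic mode: per-species occupancy probabilities
    prevalence: float | np.ndarray = 0.5
    # niche mode: 1-D Gaussian-response gradient
    gradient_range: tuple[float, float] = (0.0, 1.0)
    tolerance_scale: float = 0.1  # median niche width (fraction of gradient)
    tolerance_log_sd: float = 1.5  # lognormal spread of widths across species

    def __post_init__(self) -> None:
        if self.mode not in ("niche", "stochastic"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.pool_size <= 0:
            raise SimulationError("pool_size must be positive")
        if self.n_sites <= 0:
            raise SimulationError("n_sites must be positive")


def generate_assembly_community(spec: AssemblySimSpec) -> pd.DataFrame:
    """Presence-absence site x species matrix under the requested regime.

    Stochastic mode draws independent Bernoulli occupancy with
    species-specific prevalence.  Niche mode places sites evenly on a 1-D
    gradient and sets the occupancy probability of species ``s`` at site
    ``j`` to ``exp(-(x_j - mu_s)^2 / (2 sigma_s^2))``; niche widths are
    lognormal across species, which yields the heterogeneous prevalences
    responsible for power-law-like zeta decline.
    """
    rng = np.random.default_rng(spec.seed)
    n, S = spec.n_sites, spec.pool_size
    if spec.mode == "stochastic":
        p = np.broadcast_to(np.asarray(spec.prevalence, dtype=float), (S,))
        if np.any((p < 0) | (p > 1)):
            raise SimulationError("prevalence outside [0, 1]")
        prob = np.tile(p, (n, 1))
    else:
        lo, hi = spec.gradient_range
        x = np.linspace(lo, hi, n)
        mu = rng.uniform(lo, hi, S)
        width = (hi - lo) * spec.tolerance_scale
        sigma = width * rng.lognormal(0.0, spec.tolerance_log_sd, S)
        with np.errstate(over="ignore"):
            prob = np.exp(-((x[:, None] - mu[None, :]) ** 2) / (2.0 * sigma[None, :] ** 2))
    pres = (rng.random((n, S)) < prob).astype(np.int8)
    return pd.DataFrame(
        pres,
        index=pd.Index([f"site_{j:03d}" for j in range(n)], name="site"),
        columns=[f"sp_{s:04d}" for s in range(S)],
    )


def generate_topology_table(
    n_groups: int,
    reps_per_group: int,
    beta: np.ndarray,
    theta: np.ndarray,
    seed: int = 0,
):
    """Standard-normal features plus ordinal labels drawn from the
    proportional-odds model ``logit P(Y <= j) = theta_j - x . beta``.

    Returns ``(X, y)`` with ``y`` in ``{1, ..., len(theta) + 1}``.
    """
    beta = np.asarray(beta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if len(theta) and np.any(np.diff(theta) <= 0):
        raise SimulationError("theta must be strictly increasing")
    if n_groups != len(theta) + 1:
        raise SimulationError("n_groups must equal len(theta) + 1")
    rng = np.random.default_rng(seed)
    n = reps_per_group * n_groups
    X = rng.standard_normal((n, len(beta)))
    eta = X @ beta
    # cumulative P(Y <= j | x), j = 1..J-1
    cum = 1.0 / (1.0 + np.exp(-(theta[None, :] - eta[:, None])))
    u = rng.random(n)
    y = 1 + (u[:, None] > cum).sum(axis=1)
    return X, y
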