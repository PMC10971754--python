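"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: taxonomy ranks, most to least inclusive; ``domain`` is used only for the
#: bacteria filter and is not a conglomeration target.
RANKS = ("class", "order", "family", "genus", "species")
TAXONOMY_COLUMNS = ("domain",) + RANKS

METADATA_COLUMNS = ("population", "biomass_g", "batch", "run_group")


class TableError(ValueError):
    """Raised when an abundance table violates its structural invariants."""


@dataclass
class AbundanceTable:
    """A taxa x samples count matrix with taxonomy and sample metadata.

    Parameters
    ----------
    counts
        Non-negative matrix, rows indexed by taxon ID, columns by sample ID.
        Counts may be fractional after replicate-run averaging.
    taxonomy
        Per-taxon rank labels indexed by taxon ID.  Missing labels are NaN.
    metadata
        Per-sample metadata indexed by sample ID with columns
        ``population``, ``biomass_g``, ``batch`` and ``run_group``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise TableError(f"duplicated taxon IDs: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise TableError(f"duplicated sample IDs: {dups[:5]}")
        vals = self.counts.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise TableError("negative counts")
        if not self.metadata.index.equals(self.counts.columns):
            # allow same set, different order: realign; reject mismatched sets
            if set(self.metadata.index) != set(self.counts.columns):
                raise TableError("metadata rows do not match sample IDs")
            self.metadata = self.metadata.loc[self.counts.columns]
        missing = self.counts.index.difference(self.taxonomy.index)
        if len(missing):
            # taxa without taxonomy rows get all-NaN labels
            filler = pd.DataFrame(
                np.nan, index=missing, columns=self.taxonomy.columns
            )
            self.taxonomy = pd.concat([self.taxonomy, filler])
        self.taxonomy = self.taxonomy.loc[self.counts.index]

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            self.counts.copy(), self.taxonomy.copy(), self.metadata.copy()
        )

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        sample_ids = list(sample_ids)
        return AbundanceTable(
            self.counts.loc[:, sample_ids],
            self.taxonomy.copy(),
            self.metadata.loc[sample_ids],
        )

    def subset_taxa(self, taxon_ids) -> "AbundanceTable":
        taxon_ids = list(taxon_ids)
        return AbundanceTable(
            self.counts.loc[taxon_ids],
            self.taxonomy.loc[taxon_ids],
            self.metadata.copy(),
        )


@dataclass
class SignedNetwork:
    """Undirected signed network over taxa.

    ``edges`` maps a sorted taxon-ID pair to a signed, nonzero weight.
    """

    nodes: list
    edges: dict
    selected_lambda: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        clean = {}
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            if w == 0:
                raise ValueError(f"zero-weight edge ({u!r}, {v!r})")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint outside node set: ({u!r}, {v!r})")
            key = (u, v) if str(u) <= str(v) else (v, u)
            clean[key] = w
        self.edges = clean

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=float(w), sign="+" if w > 0 else "-")
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_i": u, "taxon_j": v, "weight": w, "sign": "+" if w > 0 else "-"}
            for (u, v), w in sorted(self.edges.items(), key=lambda kv: kv[0])
        ]
        return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "weight", "sign"])


#: the per-network topology measures recorded for each ensemble replicate
TOPOLOGY_MEASURES = (
    "total_nodes",
    "total_edges",
    "positive_edges",
    "negative_edges",
    "pos_neg_ratio",
    "average_path_length",
    "heterogeneity",
    "modularity",
    "average_degree",
    "clustering_coefficient",
)


@dataclass
class TopologyRecord:
    total_nodes: int
    total_edges: int
    positive_edges: int
    negative_edges: int
    pos_neg_ratio: Optional[float]
    average_path_length: Optional[float]
    heterogeneity: float
    modularity: float
    average_degree: float
    clustering_coefficient: float
    replicate_id: Optional[int] = None
    group: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.positive_edges + self.negative_edges != self.total_edges:
            raise ValueError("positive + negative edges must equal total edges")
        if not (0.0 <= self.clustering_coefficient <= 1.0 + 1e-12):
            raise ValueError("clustering coefficient outside [0, 1]")

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in TOPOLOGY_MEASURES}
        d["replicate_id"] = self.replicate_id
        d["group"] = self.group
        d["seed"] = self.seed
        return d


@dataclass
class QuantileAssignment:
    """Sample -> biomass-quantile label plus the cut points that define it."""

    labels: pd.Series
    cut_points: np.ndarray

    def __post_init__(self) -> None:
        cp = np.asarray(self.cut_points, dtype=float)
        if np.any(np.diff(cp) < 0):
            raise ValueError("cut points must be non-decreasing")
        self.cut_points = cp

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class OrdinalFit:
    """Proportional-odds logistic regression fit."""

    feature_names: list
    beta: np.ndarray
    theta: np.ndarray
    se_beta: np.ndarray
    se_theta: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    aic: float
    n_obs: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.theta) > 1 and np.any(np.diff(self.theta) <= 0):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def n_params(self) -> int:
        return len(self.beta) + len(self.theta)


@dataclass
class ZetaDecline:
    """Zeta-diversity decline with model fits and an assembly verdict."""

    orders: np.ndarray
    zeta: np.ndarray
    zeta_sd: np.ndarray
    retention: np.ndarray  # ratio zeta_{i+1}/zeta_i, NaN where undefined
    exp_fit: Optional[dict] = None  # intercept, slope, aic
    pow_fit: Optional[dict] = None
    verdict: Optional[str] = None  # "stochastic" | "niche"
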