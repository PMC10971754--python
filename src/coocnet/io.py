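"""TSV / GraphML / YAML / JSON input-output and the run configuration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datatypes import AbundanceTable, SignedNetwork, TAXONOMY_COLUMNS

logger = logging.getLogger(__name__)


class IOError_(ValueError):
    pass


def _read_tsv(path, numeric: bool = False) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 1 or any(h == "" for h in header):
        raise IOError_(f"{path}: malformed header")
    seen: set = set()
    for h in header[1:]:
        if h in seen:
            raise IOError_(f"{path}: duplicated column IDs ['{h}']")
        seen.add(h)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise IOError_(f"{path}: duplicated row IDs {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].tolist()
        raise IOError_(f"{path}: duplicated column IDs {dups[:5]}")
    if numeric:
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise IOError_(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                )
            df[col] = converted
    return df


def read_abundance(counts_path, taxonomy_path=None, metadata_path=None) -> AbundanceTable:
    """Load the three TSVs into an :class:`AbundanceTable`.

    The counts TSV has taxa as rows and samples as columns, first column =
    taxon ID.  Taxonomy and metadata are optional; missing pieces get
    empty/NaN defaults.
    """
    counts = _read_tsv(counts_path, numeric=True)
    if taxonomy_path is not None:
        taxonomy = _read_tsv(taxonomy_path)
        missing_cols = [c for c in TAXONOMY_COLUMNS if c not in taxonomy.columns]
        for c in missing_cols:
            taxonomy[c] = np.nan
        taxonomy = taxonomy[list(TAXONOMY_COLUMNS)]
    else:
        taxonomy = pd.DataFrame(
            np.nan, index=counts.index, columns=list(TAXONOMY_COLUMNS)
        )
    if metadata_path is not None:
        metadata = _read_tsv(metadata_path)
        if "biomass_g" in metadata.columns:
            metadata["biomass_g"] = pd.to_numeric(
                metadata["biomass_g"], errors="coerce"
            )
        for col in ("population", "batch", "run_group"):
            if col not in metadata.columns:
                metadata[col] = (
                    metadata.index if col == "run_group" else "unknown"
                )
    else:
        metadata = pd.DataFrame(
            {
                "population": "unknown",
                "biomass_g": np.nan,
                "batch": "batch0",
                "run_group": counts.columns,
            },
            index=counts.columns,
        )
    return AbundanceTable(counts, taxonomy, metadata)


def write_abundance(table: AbundanceTable, counts_path, taxonomy_path=None, metadata_path=None) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="taxon_id")
    if taxonomy_path is not None:
        table.taxonomy.to_csv(taxonomy_path, sep="\t", index_label="taxon_id")
    if metadata_path is not None:
        table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def write_network(net: SignedNetwork, edgelist_path=None, graphml_path=None) -> None:
    """Edge-list TSV (taxon_i, taxon_j, weight, sign) and/or GraphML with
    sign and weight as edge attributes."""
    if edgelist_path is not None:
        net.edge_frame().to_csv(edgelist_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(net.to_networkx(), graphml_path)


def read_network_edgelist(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_i": str, "taxon_j": str})
    expected = ["taxon_i", "taxon_j", "weight", "sign"]
    if list(df.columns) != expected:
        raise IOError_(f"{path}: expected columns {expected}")
    return df


def read_network(edgelist_path, nodes=None) -> SignedNetwork:
    df = read_network_edgelist(edgelist_path)
    edges = {
        (r.taxon_i, r.taxon_j): float(r.weight) for r in df.itertuples()
    }
    if nodes is None:
        nodes = sorted({t for pair in edges for t in pair})
    return SignedNetwork(nodes=list(nodes), edges=edges)


def write_results(tables: dict, out_dir) -> None:
    """Write a name -> DataFrame mapping as TSVs under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


@dataclass
class RunConfig:
    """Validated configuration for the full pipeline."""

    abundance: str
    taxonomy: str | None = None
    metadata: str | None = None
    out_dir: str = "coocnet_out"
    ranks: list = field(default_factory=lambda: ["order", "family", "genus", "species"])
    n_quantiles: int = 4
    ensemble_n_per: int = 50
    ensemble_n_reps: int = 100
    pseudocount: float | None = None
    n_lambda: int = 20
    min_ratio: float = 0.01
    stability_reps: int = 20
    instability_threshold: float = 0.05
    r_max: float = 0.9
    p_threshold: float = 0.01
    zeta_orders: list = field(default_factory=lambda: [3, 5, 10, 20, 50])
    zeta_sample_size: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise IOError_(f"unknown config keys: {sorted(unknown)}")
        if "abundance" not in raw:
            raise IOError_("config must name an abundance table")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise IOError_("seed must be an integer")
        for name in ("abundance", "taxonomy", "metadata"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise IOError_(f"{name} file not found: {path}")

    def to_dict(self) -> dict:
        return asdict(self)
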