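"""Abundance-table filtering, normalization, conglomeration and grouping.

The canonical pipeline order is fixed:

    rare-filter -> batch-normalize -> average-runs -> rare-filter
    -> keep-bacteria -> (optional) conglomerate

Each step returns a new :class:`~coocnet.datatypes.AbundanceTable` and
appends a provenance record describing what was removed or rescaled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, QuantileAssignment, RANKS

logger = logging.getLogger(__name__)

#: total-count threshold below or at which a taxon is a singleton/doubleton
RARE_TOTAL = 2.0

#: domain labels treated as non-bacterial contamination
_NON_BACTERIAL = ("eukaryo", "archae", "mitochondri", "chloroplast")


class PreprocessError(ValueError):
    pass


def remove_rare_taxa(table: AbundanceTable, provenance: list | None = None) -> AbundanceTable:
    """Drop taxa whose total count over all samples is <= 2."""
    totals = table.counts.sum(axis=1)
    keep = totals > RARE_TOTAL
    dropped = table.counts.index[~keep].tolist()
    out = table.subset_taxa(table.counts.index[keep])
    if provenance is not None:
        provenance.append(
            {
                "step": "remove_rare_taxa",
                "n_dropped": len(dropped),
                "dropped_taxa": dropped,
                "n_taxa_after": out.n_taxa,
            }
        )
    return out


def normalize_by_batch(table: AbundanceTable, provenance: list | None = None) -> AbundanceTable:
    """Total-sum scale every sample to the global median raw library size.

    Scaling is applied batch by batch (each batch requires a label), so the
    per-batch scale factors are auditable; zero-total samples are left
    untouched and flagged.
    """
    if table.metadata["batch"].isna().any():
        raise PreprocessError("every sample needs a batch label")
    depths = table.counts.sum(axis=0)
    target = float(depths[depths > 0].median()) if (depths > 0).any() else 0.0
    factors = {}
    counts = table.counts.astype(float).copy()
    zero_samples = []
    for batch, cols in table.metadata.groupby("batch", observed=True).groups.items():
        for sid in cols:
            d = depths[sid]
            if d == 0:
                zero_samples.append(sid)
                factors[sid] = np.nan
                continue
            factors[sid] = target / float(d)
            counts[sid] = counts[sid] * (target / float(d))
    if zero_samples:
        logger.warning("all-zero samples left unnormalized: %s", zero_samples)
    out = AbundanceTable(counts, table.taxonomy.copy(), table.metadata.copy())
    if provenance is not None:
        provenance.append(
            {
                "step": "normalize_by_batch",
                "target_depth": target,
                "scale_factors": factors,
                "zero_samples": zero_samples,
            }
        )
    return out


def average_replicate_runs(table: AbundanceTable, provenance: list | None = None) -> AbundanceTable:
    """Average counts over replicate sequencing runs of the same sample.

    Columns sharing a ``run_group`` label are replaced by their per-taxon
    arithmetic mean; metadata must agree within a group (same population,
    biomass and batch), otherwise the group spans different biological
    samples and is an error.  The rare-taxon filter is re-applied because
    averaging can push totals back to or below the singleton/doubleton
    threshold.
    """
    meta = table.metadata
    if meta["run_group"].isna().any():
        raise PreprocessError("every sample needs a run_group label")
    new_cols = {}
    new_meta_rows = []
    for group, sids in meta.groupby("run_group", sort=False).groups.items():
        sids = list(sids)
        sub = meta.loc[sids, ["population", "biomass_g", "batch"]]
        for col in ("population", "biomass_g"):
            vals = sub[col].dropna().unique()
            if len(vals) > 1:
                raise PreprocessError(
                    f"run group {group!r} spans different biological samples "
                    f"({col} = {vals.tolist()})"
                )
        new_cols[group] = table.counts[sids].mean(axis=1)
        row = sub.iloc[0].to_dict()
        row["run_group"] = group
        new_meta_rows.append((group, row))
    counts = pd.DataFrame(new_cols)
    counts.index.name = table.counts.index.name
    metadata = pd.DataFrame(
        {g: r for g, r in new_meta_rows}
    ).T.reindex(counts.columns)
    metadata.index.name = "sample_id"
    metadata["biomass_g"] = pd.to_numeric(metadata["biomass_g"])
    merged = AbundanceTable(counts, table.taxonomy.copy(), metadata)
    if provenance is not None:
        provenance.append(
            {
                "step": "average_replicate_runs",
                "n_samples_before": table.n_samples,
                "n_samples_after": merged.n_samples,
            }
        )
    return remove_rare_taxa(merged, provenance)


def keep_bacteria(table: AbundanceTable, provenance: list | None = None) -> AbundanceTable:
    """Retain only taxa whose domain label is bacterial.

    Eukaryotic, archaeal, mitochondrial and chloroplast taxa are removed;
    taxa with no domain label are dropped and logged.
    """
    if "domain" not in table.taxonomy.columns:
        raise PreprocessError("taxonomy has no domain column")
    domain = table.taxonomy["domain"].astype("string").str.lower()
    # organelle contamination can also be flagged at deeper ranks
    other = table.taxonomy.drop(columns="domain").astype("string").apply(
        lambda col: col.str.lower()
    )
    organelle = other.apply(
        lambda col: col.str.contains("mitochondri|chloroplast", na=False)
    ).any(axis=1)
    missing = domain.isna()
    non_bact = domain.str.contains("|".join(_NON_BACTERIAL), na=False)
    is_bact = domain.str.contains("bacteria", na=False) & ~non_bact & ~organelle
    keep = is_bact.fillna(False).to_numpy(dtype=bool)
    if missing.any():
        logger.info(
            "dropping %d taxa without a domain label", int(missing.sum())
        )
    dropped = table.counts.index[~keep].tolist()
    out = table.subset_taxa(table.counts.index[keep])
    if provenance is not None:
        provenance.append(
            {
                "step": "keep_bacteria",
                "n_dropped": len(dropped),
                "dropped_taxa": dropped,
                "n_missing_domain": int(missing.sum()),
            }
        )
    return out


def conglomerate(table: AbundanceTable, rank: str, provenance: list | None = None) -> AbundanceTable:
    """Sum counts over taxa sharing a label at ``rank``.

    Taxa unclassified at the rank are dropped; their total mass is
    reported through provenance so the loss is auditable.
    """
    if rank not in RANKS:
        raise PreprocessError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if rank not in table.taxonomy.columns:
        raise PreprocessError(f"rank {rank!r} absent from taxonomy")
    labels = table.taxonomy[rank]
    classified = labels.notna() & (labels.astype(str).str.strip() != "")
    dropped_mass = float(table.counts.loc[~classified].to_numpy().sum())
    counts = table.counts.loc[classified].groupby(
        labels[classified], sort=True
    ).sum()
    counts.index.name = "taxon_id"
    # taxonomy of a conglomerated row: ranks at or above the target that are
    # constant within the group; deeper ranks become undefined
    keep_ranks = list(RANKS[: RANKS.index(rank) + 1])
    tax_rows = {}
    grouped = table.taxonomy.loc[classified].groupby(labels[classified], sort=True)
    for label, sub in grouped:
        row = {}
        for col in table.taxonomy.columns:
            if col == "domain" or col in keep_ranks:
                vals = sub[col].dropna().unique()
                row[col] = vals[0] if len(vals) == 1 else np.nan
            else:
                row[col] = np.nan
        row[rank] = label
        tax_rows[label] = row
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index").reindex(
        counts.index
    )[list(table.taxonomy.columns)]
    out = AbundanceTable(counts, taxonomy, table.metadata.copy())
    if provenance is not None:
        provenance.append(
            {
                "step": "conglomerate",
                "rank": rank,
                "n_taxa_after": out.n_taxa,
                "n_unclassified_dropped": int((~classified).sum()),
                "unclassified_mass": dropped_mass,
            }
        )
    return out


def assign_quantiles(metadata: pd.DataFrame, k: int = 4) -> QuantileAssignment:
    """Bin samples into ``k`` biomass-quantile groups.

    Cut points sit at the empirical ``1/k .. (k-1)/k`` quantiles.  The
    lowest group is closed above by the first cut (``<=``); later groups
    are lower-exclusive / upper-inclusive, so ties at a cut always fall in
    the lower group.
    """
    if k < 1:
        raise PreprocessError("k must be >= 1")
    biomass = pd.to_numeric(metadata["biomass_g"], errors="coerce")
    usable = biomass.dropna()
    if usable.empty:
        raise PreprocessError("all biomass values missing")
    if len(usable) < k:
        raise PreprocessError(f"need at least {k} samples with biomass")
    cuts = np.quantile(usable.to_numpy(), [q / k for q in range(1, k)])
    labels = pd.Series(pd.NA, index=metadata.index, dtype="object")
    for sid, b in usable.items():
        g = int(np.searchsorted(cuts, b, side="left")) + 1
        labels[sid] = f"Q{g}"
    return QuantileAssignment(labels=labels, cut_points=cuts)


def to_presence_absence(table: AbundanceTable) -> pd.DataFrame:
    """Binary site x species matrix: 1 iff the count is strictly positive.

    Samples become "sites" (rows); all-zero taxa are retained.
    """
    pa = (table.counts > 0).astype(np.int8).T
    pa.index.name = "site"
    return pa


def run_preprocessing(
    table: AbundanceTable, rank: str | None = None
) -> tuple[AbundanceTable, list]:
    """Full fixed-order preprocessing pipeline; returns table + provenance."""
    provenance: list = []
    t = remove_rare_taxa(table, provenance)
    t = normalize_by_batch(t, provenance)
    t = average_replicate_runs(t, provenance)
    t = keep_bacteria(t, provenance)
    if rank is not None:
        t = conglomerate(t, rank, provenance)
    return t, provenance
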