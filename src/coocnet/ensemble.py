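"""Subsampled network ensembles per group and cross-group comparisons."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceTable, TOPOLOGY_MEASURES
from .inference import infer_network
from .topology import topology_record

logger = logging.getLogger(__name__)

#: (threshold, code) pairs matching the figure-legend star convention
SIGNIFICANCE_CODES = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


class EnsembleError(ValueError):
    pass


def significance_code(p: float) -> str:
    for threshold, code in SIGNIFICANCE_CODES:
        if p <= threshold:
            return code
    return "ns"


@dataclass
class EnsembleResult:
    records: dict  # group label -> list[TopologyRecord]
    n_per: int
    n_reps: int
    master_seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in sorted(self.records, key=str):
            for rec in self.records[group]:
                rows.append(rec.as_dict())
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Mean/sd of every measure per group."""
        df = self.to_frame()
        return df.groupby("group")[list(TOPOLOGY_MEASURES)].agg(["mean", "std"])


def _replicate_seed(master_seed: int, group_index: int, rep: int) -> int:
    """Counter-mode derivation: independent of group execution order."""
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(group_index, rep)
    )
    return int(ss.generate_state(1)[0])


def run_ensemble(
    table: AbundanceTable,
    groups: pd.Series,
    n_per: int = 50,
    n_reps: int = 100,
    seed: int = 0,
    inference_options: dict | None = None,
) -> EnsembleResult:
    """Per group and replicate: subsample ``n_per`` samples without
    replacement, infer a network, record its topology."""
    inference_options = dict(inference_options or {})
    groups = groups.dropna()
    labels = sorted(groups.unique(), key=str)
    for label in labels:
        size = int((groups == label).sum())
        if size < n_per:
            raise EnsembleError(
                f"group {label!r} has {size} samples, fewer than n_per={n_per}"
            )
    records: dict = {}
    for gi, label in enumerate(labels):
        member_ids = sorted(groups.index[groups == label], key=str)
        recs = []
        for rep in range(n_reps):
            rep_seed = _replicate_seed(seed, gi, rep)
            rng = np.random.default_rng(rep_seed)
            chosen = rng.choice(len(member_ids), size=n_per, replace=False)
            sample_ids = [member_ids[i] for i in chosen]
            assert len(set(sample_ids)) == n_per
            sub = table.subset_samples(sample_ids)
            net = infer_network(sub, seed=rep_seed, **inference_options)
            recs.append(
                topology_record(
                    net,
                    replicate_id=rep,
                    group=str(label),
                    seed=rep_seed,
                    louvain_seed=rep_seed % (2**31),
                )
            )
        records[str(label)] = recs
        logger.info("group %s: %d replicate networks done", label, n_reps)
    return EnsembleResult(records=records, n_per=n_per, n_reps=n_reps, master_seed=seed)


def compare_groups(result: EnsembleResult, metric: str):
    """Kruskal-Wallis across groups plus pairwise two-sided rank-sum tests.

    Returns ``(overall_p, pairwise)`` where ``pairwise`` is a DataFrame
    with columns group_a, group_b, p, code.  Degenerate all-tied data gets
    p = 1 by convention.
    """
    if metric not in TOPOLOGY_MEASURES:
        raise EnsembleError(f"unknown metric {metric!r}")
    df = result.to_frame()
    values = {
        g: sub[metric].dropna().to_numpy(dtype=float)
        for g, sub in df.groupby("group")
    }
    values = {g: v for g, v in values.items() if v.size}
    if len(values) < 2:
        raise EnsembleError("need at least 2 groups with non-missing values")
    if all(v.size == 0 for v in values.values()):
        raise EnsembleError(f"metric {metric!r} all-missing")
    arrays = list(values.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        overall_p = 1.0
    else:
        overall_p = float(stats.kruskal(*arrays).pvalue)
    rows = []
    labels = sorted(values, key=str)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va, vb = values[a], values[b]
            both = np.concatenate([va, vb])
            if np.all(both == both[0]):
                p = 1.0
            else:
                p = float(
                    stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
                )
            rows.append({"group_a": a, "group_b": b, "p": p, "code": significance_code(p)})
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "p", "code"])
    return overall_p, pairwise


def compare_all_metrics(result: EnsembleResult, holm: bool = False) -> pd.DataFrame:
    """One comparison table over every measure (S4-Table-like).

    ``holm`` applies a Holm correction to each metric's pairwise p-values;
    it is off by default because raw star codes are the reference output.
    """
    rows = []
    for metric in TOPOLOGY_MEASURES:
        try:
            overall_p, pairwise = compare_groups(result, metric)
        except EnsembleError:
            continue
        rows.append(
            {
                "metric": metric,
                "test": "kruskal-wallis",
                "group_a": "all",
                "group_b": "all",
                "p": overall_p,
                "code": significance_code(overall_p),
            }
        )
        if holm and len(pairwise):
            order = np.argsort(pairwise["p"].to_numpy())
            m = len(pairwise)
            adj = pairwise["p"].to_numpy().copy()
            running = 0.0
            for rank, idx in enumerate(order):
                adj[idx] = min(1.0, max(running, (m - rank) * pairwise["p"].iloc[idx]))
                running = adj[idx]
            pairwise = pairwise.assign(
                p=adj, code=[significance_code(p) for p in adj]
            )
        for _, r in pairwise.iterrows():
            rows.append(
                {
                    "metric": metric,
                    "test": "wilcoxon-rank-sum",
                    "group_a": r["group_a"],
                    "group_b": r["group_b"],
                    "p": r["p"],
                    "code": r["code"],
                }
            )
    return pd.DataFrame(rows)
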