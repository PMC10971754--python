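import numpy as np
import pandas as pd
import pytest

from coocnet.datatypes import AbundanceTable, TableError
from coocnet.preprocess import (
    PreprocessError,
    assign_quantiles,
    average_replicate_runs,
    conglomerate,
    keep_bacteria,
    normalize_by_batch,
    remove_rare_taxa,
    run_preprocessing,
    to_presence_absence,
)
from conftest import make_table


class TestRemoveRareTaxa:
    def test_singleton_removed(self):
        t = make_table([[1.0, 0.0], [5.0, 5.0]])
        out = remove_rare_taxa(t)
        assert out.taxon_ids == ["t1"]

    def test_doubleton_boundary(self):
        t = make_table([[2.0, 0.0], [3.0, 0.0]])
        out = remove_rare_taxa(t)
        assert out.taxon_ids == ["t1"]

    def test_exactly_one_survivor(self):
        t = make_table([[1.0, 0.0], [2.0, 0.0], [2.0, 3.0]])
        out = remove_rare_taxa(t)
        assert out.n_taxa == 1

    def test_order_preserved(self):
        t = make_table([[5, 5], [1, 0], [4, 4], [3, 3]])
        out = remove_rare_taxa(t)
        assert out.taxon_ids == ["t0", "t2", "t3"]


class TestNormalizeByBatch:
    def test_equal_depths_proportions_unchanged(self):
        t = make_table([[4.0, 4.0], [6.0, 6.0]])
        out = normalize_by_batch(t)
        props = out.counts / out.counts.sum(axis=0)
        expected = t.counts / t.counts.sum(axis=0)
        assert np.allclose(props, expected)

    def test_identical_proportions_identical_after(self):
        # depths 100 and 400, same composition -> identical columns after
        t = make_table([[25.0, 100.0], [75.0, 300.0]])
        out = normalize_by_batch(t)
        assert np.allclose(out.counts["s0"], out.counts["s1"])
        # both scaled to the median depth (250): column totals equal
        assert np.allclose(out.counts.sum(axis=0), 250.0)

    def test_zero_sample_untouched(self):
        t = make_table([[0.0, 5.0], [0.0, 5.0]])
        out = normalize_by_batch(t)
        assert (out.counts["s0"] == 0).all()

    def test_missing_batch_rejected(self):
        t = make_table([[1.0, 2.0], [3.0, 4.0]])
        t.metadata.loc["s0", "batch"] = np.nan
        with pytest.raises(PreprocessError):
            normalize_by_batch(t)


class TestAverageReplicateRuns:
    def _with_runs(self):
        t = make_table([[10.0, 20.0, 7.0], [4.0, 8.0, 9.0]])
        t.metadata["run_group"] = ["bio1", "bio1", "bio2"]
        return t

    def test_arithmetic_mean(self):
        out = average_replicate_runs(self._with_runs())
        assert out.counts.loc["t0", "bio1"] == 15.0
        assert out.counts.loc["t0", "bio2"] == 7.0

    def test_second_rare_pass(self):
        # averaging (3, 1) -> 2, which the second filter must remove
        t = make_table([[3.0, 1.0], [10.0, 10.0]])
        t.metadata["run_group"] = ["bio1", "bio1"]
        out = average_replicate_runs(t)
        assert out.taxon_ids == ["t1"]

    def test_group_of_one_identity(self):
        t = make_table([[5.0, 6.0], [7.0, 8.0]])
        out = average_replicate_runs(t)
        assert np.allclose(out.counts.to_numpy(), t.counts.to_numpy())

    def test_inconsistent_group_rejected(self):
        t = make_table([[5.0, 6.0], [7.0, 8.0]])
        t.metadata["run_group"] = ["bio1", "bio1"]
        t.metadata["biomass_g"] = [1.0, 2.0]
        with pytest.raises(PreprocessError):
            average_replicate_runs(t)


class TestKeepBacteria:
    def test_chloroplast_removed(self):
        t = make_table([[9, 9], [9, 9]])
        t.taxonomy.loc["t0", "domain"] = "Eukaryota"
        t.taxonomy.loc["t0", "class"] = "Chloroplast"
        out = keep_bacteria(t)
        assert out.taxon_ids == ["t1"]

    def test_chloroplast_under_bacterial_domain_removed(self):
        t = make_table([[9, 9], [9, 9]])
        t.taxonomy.loc["t0", "order"] = "Chloroplast"
        out = keep_bacteria(t)
        assert out.taxon_ids == ["t1"]

    def test_bacteria_retained(self):
        t = make_table([[9, 9]])
        assert keep_bacteria(t).n_taxa == 1

    def test_mixed_counts(self):
        t = make_table(np.full((5, 2), 9.0))
        t.taxonomy.loc[["t3", "t4"], "domain"] = "Archaea"
        assert keep_bacteria(t).n_taxa == 3

    def test_missing_domain_dropped(self):
        t = make_table([[9, 9], [9, 9]])
        t.taxonomy.loc["t0", "domain"] = np.nan
        assert keep_bacteria(t).taxon_ids == ["t1"]


class TestConglomerate:
    def test_family_additivity(self):
        t = make_table([[3.0, 1.0], [4.0, 2.0]])
        t.taxonomy["family"] = ["famA", "famA"]
        out = conglomerate(t, "family")
        assert out.counts.loc["famA"].tolist() == [7.0, 3.0]

    def test_unclassified_dropped(self):
        t = make_table([[3.0, 1.0], [4.0, 2.0]])
        t.taxonomy.loc["t0", "family"] = np.nan
        out = conglomerate(t, "family")
        assert out.n_taxa == 1

    def test_column_totals_conserved(self):
        t = make_table(np.arange(12, dtype=float).reshape(4, 3))
        t.taxonomy["genus"] = ["g1", "g1", "g2", "g2"]
        out = conglomerate(t, "genus")
        assert np.allclose(out.counts.sum(axis=0), t.counts.sum(axis=0))

    def test_associativity_genus_then_family(self, rng):
        counts = rng.integers(0, 50, size=(12, 5)).astype(float)
        t = make_table(counts)
        t.taxonomy["family"] = [f"f{i % 3}" for i in range(12)]
        # genus nested within family so the two routes agree
        t.taxonomy["genus"] = [f"f{i % 3}_g{i % 6}" for i in range(12)]
        via_genus = conglomerate(conglomerate(t, "genus"), "family")
        direct = conglomerate(t, "family")
        assert np.allclose(
            via_genus.counts.sort_index().to_numpy(),
            direct.counts.sort_index().to_numpy(),
        )

    def test_unknown_rank_rejected(self):
        t = make_table([[1.0, 1.0]])
        with pytest.raises(PreprocessError):
            conglomerate(t, "kingdom")


class TestAssignQuantiles:
    def _meta(self, biomass):
        return pd.DataFrame(
            {"biomass_g": biomass},
            index=[f"s{i}" for i in range(len(biomass))],
        )

    def test_one_to_eight_splits_evenly(self):
        quant = assign_quantiles(self._meta(range(1, 9)), k=4)
        assert quant.group_sizes().tolist() == [2, 2, 2, 2]

    def test_k1_single_group(self):
        quant = assign_quantiles(self._meta([5.0, 1.0, 3.0, 9.0]), k=1)
        assert set(quant.labels) == {"Q1"}

    def test_interval_convention_ties_go_low(self):
        # a value exactly at a cut point lands in the lower group
        quant = assign_quantiles(self._meta([1, 2, 3, 4, 5, 6, 7, 8]), k=2)
        cut = quant.cut_points[0]
        at_cut = [f"s{i}" for i, b in enumerate(range(1, 9)) if b == cut]
        for sid in at_cut:
            assert quant.labels[sid] == "Q1"

    def test_reference_cut_points_fixture(self):
        # the reference interval convention: <=63.92 / (63.92,125] / (125,211] / >211
        cuts = np.array([63.92, 125.0, 211.0])
        values = [63.92, 63.93, 125.0, 125.5, 211.0, 300.0]
        expected = ["Q1", "Q2", "Q2", "Q3", "Q3", "Q4"]
        got = [f"Q{int(np.searchsorted(cuts, b, side='left')) + 1}" for b in values]
        assert got == expected

    def test_all_missing_rejected(self):
        with pytest.raises(PreprocessError):
            assign_quantiles(self._meta([np.nan, np.nan, np.nan, np.nan]), k=4)

    def test_sizes_near_equal_random(self, rng):
        biomass = rng.gamma(2.0, 50.0, size=101)
        quant = assign_quantiles(self._meta(biomass), k=4)
        sizes = quant.group_sizes()
        assert sizes.max() - sizes.min() <= 1


class TestPresenceAbsence:
    def test_rule(self):
        t = make_table([[2.0, 0.0], [1.0, 1.0]])
        pa = to_presence_absence(t)
        assert pa.to_numpy().T.tolist() == [[1, 0], [1, 1]]

    def test_fractional_counts_present(self):
        t = make_table([[0.5, 0.0]])
        assert to_presence_absence(t).to_numpy().tolist() == [[1], [0]]

    def test_all_zero_taxon_retained(self):
        t = make_table([[0.0, 0.0], [1.0, 1.0]])
        pa = to_presence_absence(t)
        assert "t0" in pa.columns
        assert pa["t0"].sum() == 0


class TestPipelineOrder:
    def test_full_pipeline_idempotent_up_to_scale(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 30, size=(20, 10)).astype(float))
        once, _ = run_preprocessing(t)
        twice, _ = run_preprocessing(once)
        assert once.taxon_ids == twice.taxon_ids
        # proportions identical; only the global scale may change
        p1 = once.counts / once.counts.sum(axis=0)
        p2 = twice.counts / twice.counts.sum(axis=0)
        assert np.allclose(p1, p2)

    def test_provenance_records_every_step(self):
        t = make_table(np.full((5, 6), 4.0))
        _, prov = run_preprocessing(t)
        steps = [p["step"] for p in prov]
        assert steps == [
            "remove_rare_taxa",
            "normalize_by_batch",
            "average_replicate_runs",
            "remove_rare_taxa",
            "keep_bacteria",
        ]


class TestTableInvariants:
    def test_duplicate_taxon_rejected(self):
        with pytest.raises(TableError):
            make_table([[1.0, 2.0], [3.0, 4.0]], taxon_ids=["a", "a"])

    def test_negative_counts_rejected(self):
        with pytest.raises(TableError):
            make_table([[-1.0, 2.0]])

    def test_metadata_mismatch_rejected(self):
        t = make_table([[1.0, 2.0]])
        bad_meta = t.metadata.rename(index={"s0": "zz"})
        with pytest.raises(TableError):
            AbundanceTable(t.counts, t.taxonomy, bad_meta)
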