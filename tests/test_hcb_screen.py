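import numpy as np
import pandas as pd
import pytest

import pahfate.synthetic_data as sd
from pahfate.errors import InputError
from pahfate.hcb_screen import (
    RANKS,
    HCBList,
    TaxonTable,
    enrichment_screen,
    filter_hcb,
    hcb_share,
    parse_lineage,
    rarefy,
    relative_abundance,
)


def make_table(counts: dict, genera: dict, meta: dict | None = None) -> TaxonTable:
    """Small hand-built table; counts: taxon -> list per sample."""
    samples = meta or {
        f"S{i}": {"layer": "SML", "fraction": "PA", "treatment": "PAH",
                  "timepoint": "T24", "replicate": f"R{i}"}
        for i in range(1, len(next(iter(counts.values()))) + 1)
    }
    cdf = pd.DataFrame(counts, index=list(samples)).T
    tax = pd.DataFrame(
        [("Bacteria", "P", "C", "O", "F", genera[t], "") for t in counts],
        index=list(counts), columns=list(RANKS),
    )
    mdf = pd.DataFrame(samples).T
    return TaxonTable(cdf, tax, mdf)


class TestParsing:
    def test_parse_lineage_strips_silva_prefixes(self):
        lin = parse_lineage("d__Bacteria;p__Proteobacteria;c__Gamma;o__Alt;"
                            "f__Pseudoalteromonadaceae;g__Pseudoalteromonas")
        assert lin[0] == "Bacteria"
        assert lin[5] == "Pseudoalteromonas"
        assert lin[6] == ""  # padded species

    def test_alignment_validation(self):
        t = make_table({"a": [1, 2]}, {"a": "X"})
        with pytest.raises(InputError):
            TaxonTable(t.counts, t.taxonomy.iloc[:0], t.sample_meta)

    def test_negative_counts_rejected(self):
        t = make_table({"a": [1, 2]}, {"a": "X"})
        bad = t.counts.copy()
        bad.iloc[0, 0] = -1
        with pytest.raises(InputError):
            TaxonTable(bad, t.taxonomy, t.sample_meta)


class TestRarefy:
    def test_column_sums_equal_depth(self):
        t = make_table({"a": [500, 800], "b": [700, 300]}, {"a": "X", "b": "Y"})
        out = rarefy(t, depth=1000, seed=0)
        assert (out.sample_sums() == 1000).all()

    def test_sample_at_depth_unchanged(self):
        t = make_table({"a": [600, 100], "b": [400, 200]}, {"a": "X", "b": "Y"})
        with pytest.warns(UserWarning, match="below depth"):
            out = rarefy(t, depth=1000, seed=0)
        # first sample totals exactly 1000 -> column passes through unchanged
        assert out.counts.iloc[:, 0].tolist() == [600, 400]

    def test_shallow_samples_dropped_with_warning(self):
        t = make_table({"a": [600, 100], "b": [400, 200]}, {"a": "X", "b": "Y"})
        with pytest.warns(UserWarning, match="below depth"):
            out = rarefy(t, depth=500, seed=0)
        assert out.n_samples == 1

    def test_deterministic_for_seed(self):
        t = make_table({"a": [5000, 800], "b": [7000, 3000]}, {"a": "X", "b": "Y"})
        a = rarefy(t, depth=2000, seed=42).counts
        b = rarefy(t, depth=2000, seed=42).counts
        c = rarefy(t, depth=2000, seed=43).counts
        assert a.equals(b)
        assert not a.equals(c)

    def test_expected_proportion_preserved(self):
        # taxon at true proportion 0.3; hypergeometric draws are unbiased
        t = make_table({"a": [30_000], "b": [70_000]}, {"a": "X", "b": "Y"},
                       meta={"S1": {"layer": "SML", "fraction": "PA",
                                    "treatment": "PAH", "timepoint": "T24",
                                    "replicate": "R1"}})
        props = [
            rarefy(t, depth=10_000, seed=s).counts.loc["a", "S1"] / 10_000
            for s in range(200)
        ]
        assert np.mean(props) == pytest.approx(0.3, rel=0.01)

    def test_depth_validation(self):
        t = make_table({"a": [10, 10]}, {"a": "X"})
        with pytest.raises(InputError):
            rarefy(t, depth=0)
        with pytest.raises(InputError):
            rarefy(t, depth=100)


class TestRelativeAbundance:
    def test_single_taxon(self):
        t = make_table({"a": [50, 10]}, {"a": "X"})
        props = relative_abundance(t)
        assert (props.loc["X"] == 1.0).all()

    def test_proportions(self):
        t = make_table({"a": [30, 1], "b": [70, 1]}, {"a": "X", "b": "Y"})
        props = relative_abundance(t)
        assert props["S1"].tolist() == pytest.approx([0.3, 0.7])
        assert props.sum(axis=0).tolist() == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_unassigned_pooled_into_unclassified(self):
        t = make_table({"a": [30, 5], "b": [70, 5]}, {"a": "", "b": "Y"})
        props = relative_abundance(t)
        assert "unclassified" in props.index
        assert props.loc["unclassified", "S1"] == pytest.approx(0.3)

    def test_empty_sample_rejected(self):
        t = make_table({"a": [3, 0]}, {"a": "X"})
        with pytest.raises(InputError, match="empty"):
            relative_abundance(t)


class TestHCBFilter:
    def test_named_genera_matched(self):
        t = make_table(
            {"a": [5, 5], "b": [5, 5], "c": [5, 5]},
            {"a": "Sulfitobacter", "b": "SAR11_clade", "c": "Pseudoalteromonas"},
        )
        out = filter_hcb(t, HCBList.default())
        assert set(out.counts.index) == {"a", "c"}

    def test_genus_unassigned_never_matches(self):
        t = make_table({"a": [5, 5]}, {"a": ""})
        assert filter_hcb(t, HCBList.default()).n_taxa == 0

    def test_empty_hcb_list_rejected(self):
        with pytest.raises(InputError):
            HCBList.from_iterable([])

    def test_filter_is_pointwise_over_disjoint_lists(self):
        t = make_table(
            {"a": [5, 5], "b": [5, 5], "c": [5, 5]},
            {"a": "Colwellia", "b": "Alteromonas", "c": "SAR11_clade"},
        )
        la = HCBList.from_iterable(["Colwellia"])
        lb = HCBList.from_iterable(["Alteromonas"])
        lab = HCBList.from_iterable(["Colwellia", "Alteromonas"])
        union = set(filter_hcb(t, la).counts.index) | set(filter_hcb(t, lb).counts.index)
        assert union == set(filter_hcb(t, lab).counts.index)

    def test_matching_case_insensitive(self):
        t = make_table({"a": [5, 5]}, {"a": "colwellia"})
        assert filter_hcb(t, HCBList.default()).n_taxa == 1


class TestEnrichmentScreen:
    @staticmethod
    def _two_arm_table(pah_counts, ctrl_counts, genera):
        counts, meta = {}, {}
        for t in genera:
            counts[t] = []
        for i, arm_counts in enumerate((pah_counts, ctrl_counts)):
            arm = "PAH" if i == 0 else "CONTROL"
            for r, rep in enumerate(arm_counts):
                sid = f"{arm}{r}"
                meta[sid] = {"layer": "SML", "fraction": "PA", "treatment": arm,
                             "timepoint": "T24", "replicate": f"R{r}"}
                for t, v in zip(genera, rep):
                    counts[t].append(v)
        cdf = pd.DataFrame(counts, index=list(meta)).T
        tax = pd.DataFrame(
            [("Bacteria", "P", "C", "O", "F", genera[t], "") for t in genera],
            index=list(genera), columns=list(RANKS))
        return TaxonTable(cdf, tax, pd.DataFrame(meta).T)

    def test_equal_abundance_fold_one(self):
        t = self._two_arm_table(
            pah_counts=[[50, 50], [50, 50]], ctrl_counts=[[50, 50], [50, 50]],
            genera={"a": "X", "b": "Y"})
        out = enrichment_screen(t).set_index("taxon")
        assert out.loc["X", "fold_change"] == pytest.approx(1.0)

    def test_printed_abundance_fold(self):
        # control 3.7 %, treatment 25.6 % -> +6.92
        t = self._two_arm_table(
            pah_counts=[[256, 744], [256, 744]],
            ctrl_counts=[[37, 963], [37, 963]],
            genera={"a": "Pseudoalteromonas", "b": "Other"})
        out = enrichment_screen(t).set_index("taxon")
        assert out.loc["Pseudoalteromonas", "fold_change"] == pytest.approx(
            6.9189189, abs=1e-6)

    def test_absent_taxon_excluded(self):
        t = self._two_arm_table(
            pah_counts=[[100, 0], [100, 0]], ctrl_counts=[[100, 0], [100, 0]],
            genera={"a": "X", "b": "Y"})
        out = enrichment_screen(t)
        assert "Y" not in set(out["taxon"])

    def test_zero_arm_uses_pseudo_proportion(self):
        t = self._two_arm_table(
            pah_counts=[[90, 10], [90, 10]], ctrl_counts=[[0, 100], [0, 100]],
            genera={"a": "X", "b": "Y"})
        out = enrichment_screen(t).set_index("taxon")
        # pseudo = half the smallest nonzero proportion (0.1) = 0.05
        assert out.loc["X", "fold_change"] == pytest.approx(0.9 / 0.05)

    def test_single_replicate_gives_nan_p(self):
        t = self._two_arm_table(
            pah_counts=[[60, 40]], ctrl_counts=[[30, 70]],
            genera={"a": "X", "b": "Y"})
        with pytest.warns(UserWarning, match="single replicate"):
            out = enrichment_screen(t)
        assert out["p_value"].isna().all()
        assert np.isfinite(out["fold_change"]).all()

    def test_missing_arm_stratum_skipped(self):
        t = self._two_arm_table(
            pah_counts=[[60, 40], [55, 45]], ctrl_counts=[[30, 70], [35, 65]],
            genera={"a": "X", "b": "Y"})
        meta = t.sample_meta.copy()
        meta["treatment"] = "PAH"  # no control arm anywhere
        t2 = TaxonTable(t.counts, t.taxonomy, meta)
        with pytest.warns(UserWarning, match="skipped"):
            out = enrichment_screen(t2)
        assert out.empty

    def test_recovers_injected_enrichment_direction(self):
        sc = sd.scenario_single_enrichment(seed=3)
        table = sd.simulate_asv_table(sc)
        out = enrichment_screen(table, hcb_only=True).set_index("taxon")
        assert out.loc["Pseudoalteromonas", "fold_change"] > 3
        assert out.loc["Pseudoalteromonas", "p_value"] < 0.05


def test_hcb_share_fraction():
    t = make_table({"a": [30, 10], "b": [70, 90]},
                   {"a": "Colwellia", "b": "SAR11_clade"})
    share = hcb_share(t, HCBList.default())
    assert share.tolist() == pytest.approx([0.3, 0.1])


def test_archaea_dropped():
    counts = {"a": [5, 5], "b": [5, 5]}
    t = make_table(counts, {"a": "X", "b": "Y"})
    tax = t.taxonomy.copy()
    tax.loc["a", "domain"] = "Archaea"
    t2 = TaxonTable(t.counts, tax, t.sample_meta)
    assert t2.drop_archaea().n_taxa == 1
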