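import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pahfate.synthetic_data as sd
from pahfate.errors import BelowLOQError, InputError, MissingBenchmarkError
from pahfate.partitioning import PartitionContext
from pahfate.removal import (
    Attribution,
    attribute_removal,
    benchmark_correct,
    compute_removal,
    percent_decrease,
    removal_rate,
    replicate_rates,
    summarize_by_class,
)


def _conc_df(rows):
    return pd.DataFrame(
        rows,
        columns=["compound", "layer", "treatment", "replicate",
                 "time_h", "conc_ng_L", "below_loq"],
    )


class TestElementaryRates:
    def test_rate_arithmetic(self):
        assert removal_rate(200.0, 126.08, 24.0) == pytest.approx(3.08, abs=1e-9)

    def test_no_change_zero_rate(self):
        assert removal_rate(150.0, 150.0, 24.0) == 0.0

    def test_negative_preserved(self):
        assert removal_rate(100.0, 110.0, 24.0) == pytest.approx(-0.41667, abs=1e-4)

    def test_invalid_dt(self):
        with pytest.raises(InputError):
            removal_rate(1.0, 0.5, 0.0)

    def test_below_loq_not_computable(self):
        with pytest.raises(BelowLOQError):
            removal_rate(np.nan, 0.5, 24.0)

    @given(c0=st.floats(1e-3, 1e3), c1=st.floats(0, 1e3), s=st.floats(0.01, 100))
    def test_rate_linear_in_concentration_scale(self, c0, c1, s):
        r = removal_rate(c0, c1, 24.0)
        assert removal_rate(s * c0, s * c1, 24.0) == pytest.approx(s * r, rel=1e-9)

    @pytest.mark.parametrize(
        "c0,c1,expected", [(100, 47.8, 52.2), (37.0, 37.0, 0.0), (100, 0, 100.0)]
    )
    def test_percent_decrease(self, c0, c1, expected):
        assert percent_decrease(c0, c1) == pytest.approx(expected)

    def test_percent_decrease_needs_positive_c0(self):
        with pytest.raises(InputError):
            percent_decrease(0.0, 0.0)


class TestBenchmarkCorrection:
    @staticmethod
    def _bottle(conc_by_compound_t):
        rows = []
        for compound, (c0, c1) in conc_by_compound_t.items():
            rows.append([compound, "SML", "PAH", "R1", 0.0, c0, False])
            rows.append([compound, "SML", "PAH", "R1", 24.0, c1, False])
        return _conc_df(rows)

    def test_benchmark_series_becomes_constant(self):
        df = self._bottle({"phenanthrene": (100.0, 80.0), "pyrene": (200.0, 100.0)})
        out = benchmark_correct(df)
        bench = out[out["compound"] == "phenanthrene"]
        assert bench["conc_ng_L"].tolist() == pytest.approx([100.0, 100.0])

    def test_worked_example(self):
        # C_i: 200 -> 100, benchmark: 100 -> 80 => corrected C_i(t1) = 125
        df = self._bottle({"phenanthrene": (100.0, 80.0), "pyrene": (200.0, 100.0)})
        reps = replicate_rates(df, benchmark="phenanthrene")
        row = reps[reps["compound"] == "pyrene"].iloc[0]
        assert row["c_t1"] == pytest.approx(125.0)
        assert row["rate_ng_L_h"] == pytest.approx((200 - 125) / 24)

    def test_common_loss_cancels_exactly(self, registry):
        lam = 0.8
        df = self._bottle({c.name: (200.0, 200.0 * lam) for c in registry})
        reps = replicate_rates(df, benchmark="phenanthrene")
        assert reps["rate_ng_L_h"].abs().max() <= 1e-9

    def test_missing_benchmark_is_error(self):
        df = self._bottle({"pyrene": (200.0, 100.0)})
        with pytest.raises(MissingBenchmarkError):
            benchmark_correct(df)

    def test_zero_benchmark_is_error(self):
        df = self._bottle({"phenanthrene": (100.0, 0.0), "pyrene": (200.0, 100.0)})
        with pytest.raises(MissingBenchmarkError):
            benchmark_correct(df)


class TestAttribution:
    def test_large_decrease_small_bound(self):
        assert (
            attribute_removal(52.2, 0.09) is Attribution.BIODEGRADATION_DOMINANT
        )

    def test_zero_decrease(self):
        assert attribute_removal(0.0, 0.09) is Attribution.NO_REMOVAL

    def test_bound_covers_decrease(self):
        assert attribute_removal(5.0, 0.09) is Attribution.SORPTION_POSSIBLE

    def test_equality_is_sorption(self):
        assert attribute_removal(9.0, 0.09) is Attribution.SORPTION_POSSIBLE


class TestPipelineOnSyntheticTruth:
    def test_first_order_roundtrip_noiseless(self, registry):
        """Two-point estimator equals C0*(1-exp(-k dt))/dt on noiseless decay."""
        k = 0.0123
        c0 = 180.0
        df = _conc_df(
            [["pyrene", "SML", "PAH", "R1", 0.0, c0, False],
             ["pyrene", "SML", "PAH", "R1", 24.0, c0 * np.exp(-k * 24), False]]
        )
        reps = replicate_rates(df)
        expected = c0 * (1 - np.exp(-k * 24)) / 24
        assert reps["rate_ng_L_h"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_sorption_only_never_biodegradation(self, registry):
        """Biomass doubling without biodegradation: everything is explained
        by repartitioning and no compound may be called biodegraded."""
        ctx0 = PartitionContext.from_field(cells_per_L=8e8, doc_uM=60)
        contexts = {
            "SML": (ctx0, ctx0.scale_biomass(2.0)),
            "SSL": (ctx0, ctx0.scale_biomass(2.0)),
        }
        design = sd.IncubationDesign(registry=registry)
        fate = sd.FateParameters(k_bio={}, contexts=contexts, k_wall=0.0,
                                 noise_cv=0.0)
        df = sd.simulate_incubation(design, fate)
        res = compute_removal(df, registry=registry, contexts=contexts)
        assert not (res["attribution"] == Attribution.BIODEGRADATION_DOMINANT.value).any()

    def test_paper_like_sml_hmw_all_biodegradation(self, registry, noiseless_conc,
                                                   paper_like_noiseless):
        sc = paper_like_noiseless
        res = compute_removal(noiseless_conc, registry=registry,
                              contexts=sc.fate.contexts)
        hmw = {c.name for c in registry.by_class("HMW")}
        sel = res[(res["layer"] == "SML") & (res["treatment"] == "PAH")
                  & res["compound"].isin(hmw)]
        assert len(sel) == 10
        assert (sel["attribution"] == Attribution.BIODEGRADATION_DOMINANT.value).all()


class TestSummaries:
    def test_class_summary_values(self, registry):
        res = pd.DataFrame([
            {"compound": "pyrene", "layer": "SML", "treatment": "PAH",
             "rate_mean": 0.29, "percent_decrease": 3.0},
            {"compound": "benzo(a)pyrene", "layer": "SML", "treatment": "PAH",
             "rate_mean": 3.08, "percent_decrease": 30.0},
            {"compound": "fluorene", "layer": "SML", "treatment": "PAH",
             "rate_mean": -0.05, "percent_decrease": -0.5},
        ])
        out = summarize_by_class(res, registry).set_index("weight_class")
        assert out.loc["HMW", "rate_mean"] == pytest.approx((0.29 + 3.08) / 2)
        assert out.loc["HMW", "rate_min"] == pytest.approx(0.29)
        assert out.loc["HMW", "rate_max"] == pytest.approx(3.08)
        assert bool(out.loc["LMW", "any_negative"])
        # empty classes are absent, not zero
        assert set(out.index) == {"LMW", "HMW"}

    def test_replicate_aggregation_mean_sd(self):
        df = _conc_df(
            [["pyrene", "SML", "PAH", "R1", 0.0, 200.0, False],
             ["pyrene", "SML", "PAH", "R1", 24.0, 150.0, False],
             ["pyrene", "SML", "PAH", "R2", 0.0, 200.0, False],
             ["pyrene", "SML", "PAH", "R2", 24.0, 160.0, False]]
        )
        out = compute_removal(df)
        rates = np.array([50.0, 40.0]) / 24
        assert out["n_reps"].iloc[0] == 2
        assert out["rate_mean"].iloc[0] == pytest.approx(rates.mean())
        assert out["rate_sd"].iloc[0] == pytest.approx(rates.std(ddof=1))

    def test_below_loq_replicate_dropped_with_warning(self):
        df = _conc_df(
            [["pyrene", "SML", "PAH", "R1", 0.0, 200.0, False],
             ["pyrene", "SML", "PAH", "R1", 24.0, 150.0, False],
             ["pyrene", "SML", "PAH", "R2", 0.0, np.nan, True],
             ["pyrene", "SML", "PAH", "R2", 24.0, 160.0, False]]
        )
        with pytest.warns(UserWarning, match="below"):
            reps = replicate_rates(df)
        assert len(reps) == 1
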