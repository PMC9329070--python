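"""Dissolved-phase removal rates and their attribution.

A two-timepoint bottle incubation yields, per compound and bottle, a
removal rate ``(C_t0 - C_t1) / dt`` in ng L-1 h-1 and a percent decrease
relative to the initial concentration.  Rates are computed per replicate
bottle and then summarised as mean +/- sd.

Two corrections/diagnostics surround the raw rates:

* **Benchmark correction** removes bottle-common losses (wall sorption,
  handling, extraction artifacts) by normalising every compound to a
  reference compound measured in the same bottle, by default
  phenanthrene.  Per bottle, the scale ``s(t) = C_bench(t)/C_bench(t0)``
  is divided out of all concentrations, so any loss shared by all
  analytes cancels exactly and the corrected benchmark series is
  constant.  The exact transformation is this package's reconstruction
  of the benchmarking idea: ratio normalisation is the simplest map that
  exactly cancels multiplicative common losses.
* **Sorption attribution** compares the observed percent decrease with
  the repartitioning bound from :mod:`pahfate.partitioning`; a decrease
  that repartitioning to growing organic-matter pools could fully
  explain is labelled ``SORPTION_POSSIBLE``, anything larger
  ``BIODEGRADATION_DOMINANT``, and decreases within measurement noise
  ``NO_REMOVAL``.

Negative rates (apparent production) are retained and flagged rather
than truncated, so class means stay unbiased.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .compounds import CompoundRegistry, WeightClass
from .errors import BelowLOQError, InputError, MissingBenchmarkError
from .inference import DEFAULT_EXACT_THRESHOLD, mann_whitney
from .partitioning import PartitionContext, sorption_artifact_bound

__all__ = [
    "Attribution",
    "IncubationMeasurement",
    "RemovalResult",
    "CONC_COLUMNS",
    "DEFAULT_BENCHMARK",
    "read_concentrations",
    "write_concentrations",
    "removal_rate",
    "percent_decrease",
    "benchmark_correct",
    "replicate_rates",
    "aggregate_rates",
    "compute_removal",
    "attribute_removal",
    "summarize_by_class",
    "compare_layers",
]

CONC_COLUMNS = ["compound", "layer", "treatment", "replicate",
                "time_h", "conc_ng_L", "below_loq"]
_BOTTLE_KEY = ["layer", "treatment", "replicate"]

DEFAULT_BENCHMARK = "phenanthrene"

#: Percent decrease at or below which a result is called NO_REMOVAL.
DEFAULT_NOISE_THRESHOLD_PCT = 2.0


class Attribution(str, enum.Enum):
    BIODEGRADATION_DOMINANT = "BIODEGRADATION_DOMINANT"
    SORPTION_POSSIBLE = "SORPTION_POSSIBLE"
    NO_REMOVAL = "NO_REMOVAL"


@dataclass(frozen=True)
class IncubationMeasurement:
    """One dissolved-phase concentration observation in one bottle."""

    compound: str
    layer: str
    treatment: str
    replicate: str
    time_h: float
    conc_ng_L: float
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise InputError("time_h must be >= 0")
        if not self.below_loq and self.conc_ng_L < 0:
            raise InputError("concentration must be >= 0")


@dataclass(frozen=True)
class RemovalResult:
    """Per-compound removal summary for one layer/treatment condition."""

    compound: str
    layer: str
    treatment: str
    n_reps: int
    rate_mean: float
    rate_sd: float
    percent_decrease: float
    benchmarked: bool
    sorption_bound: float
    attribution: Attribution


# ---------------------------------------------------------------------------
# I/O

def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Read a long-format concentration CSV (``#`` comment lines allowed)."""
    df = pd.read_csv(path, comment="#")
    return validate_concentrations(df)


def write_concentrations(df: pd.DataFrame, path: str | Path,
                         header_note: str | None = None) -> None:
    validate_concentrations(df)
    with open(path, "w", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=False)


def validate_concentrations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CONC_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"concentration table missing column(s): {', '.join(missing)}")
    out = df.loc[:, CONC_COLUMNS].copy()
    out["time_h"] = pd.to_numeric(out["time_h"], errors="raise")
    out["conc_ng_L"] = pd.to_numeric(out["conc_ng_L"], errors="raise")
    if out["below_loq"].dtype != bool:
        out["below_loq"] = (
            out["below_loq"].astype(str).str.strip().str.casefold()
            .map({"true": True, "false": False, "1": True, "0": False})
        )
        if out["below_loq"].isna().any():
            raise InputError("below_loq must be boolean")
    if (out["time_h"] < 0).any():
        raise InputError("time_h must be >= 0")
    quantified = ~out["below_loq"]
    if (out.loc[quantified, "conc_ng_L"] < 0).any():
        raise InputError("quantified concentrations must be >= 0")
    return out


# ---------------------------------------------------------------------------
# Elementary operations

def removal_rate(c_t0: float, c_t1: float, dt_h: float) -> float:
    """Removal rate ``(c_t0 - c_t1) / dt`` in ng L-1 h-1.

    Negative values (apparent production) are returned as-is; callers
    flag them.  ``dt_h`` must be strictly positive and both
    concentrations quantified (NaN marks below-LOQ input).
    """
    if dt_h <= 0:
        raise InputError(f"dt must be > 0, got {dt_h}")
    if np.isnan(c_t0) or np.isnan(c_t1):
        raise BelowLOQError("removal rate undefined for below-LOQ measurements")
    return (c_t0 - c_t1) / dt_h


def percent_decrease(c_t0: float, c_t1: float) -> float:
    """Percent decrease ``100 * (c_t0 - c_t1) / c_t0`` (requires ``c_t0 > 0``)."""
    if not c_t0 > 0:
        raise InputError(f"initial concentration must be > 0, got {c_t0}")
    return 100.0 * (c_t0 - c_t1) / c_t0


def benchmark_correct(df: pd.DataFrame, benchmark: str = DEFAULT_BENCHMARK) -> pd.DataFrame:
    """Normalise all concentrations to a benchmark compound, per bottle.

    For every bottle (layer, treatment, replicate) and timepoint ``t``,
    concentrations are divided by ``s(t) = C_bench(t) / C_bench(t0)``.
    Losses common to every compound in the bottle cancel exactly; the
    corrected benchmark series is constant at its t0 value.

    Raises
    ------
    MissingBenchmarkError
        If the benchmark is absent, below LOQ or zero at any
        (bottle, timepoint) present in the table.
    """
    df = validate_concentrations(df)
    is_bench = df["compound"].str.casefold() == benchmark.casefold()
    bench = df.loc[is_bench]
    if bench.empty:
        raise MissingBenchmarkError(f"benchmark compound {benchmark!r} not in table")
    if bench["below_loq"].any() or (bench["conc_ng_L"] <= 0).any():
        raise MissingBenchmarkError(
            f"benchmark {benchmark!r} unquantified or zero in at least one bottle"
        )
    key = _BOTTLE_KEY + ["time_h"]
    if bench.duplicated(key).any():
        raise InputError(f"duplicate benchmark rows for a bottle/timepoint")

    bench = bench[key + ["conc_ng_L"]].rename(columns={"conc_ng_L": "_bench"})
    t0 = bench.groupby(_BOTTLE_KEY)["time_h"].min().rename("_t0").reset_index()
    bench = bench.merge(t0, on=_BOTTLE_KEY)
    b0 = (
        bench.loc[bench["time_h"] == bench["_t0"], _BOTTLE_KEY + ["_bench"]]
        .rename(columns={"_bench": "_bench0"})
    )
    bench = bench.merge(b0, on=_BOTTLE_KEY)
    bench["_scale"] = bench["_bench"] / bench["_bench0"]

    out = df.merge(bench[key + ["_scale"]], on=key, how="left")
    if out["_scale"].isna().any():
        missing = out.loc[out["_scale"].isna(), key].drop_duplicates()
        raise MissingBenchmarkError(
            f"benchmark {benchmark!r} missing for bottle/timepoint(s):\n{missing}"
        )
    out["conc_ng_L"] = out["conc_ng_L"] / out["_scale"]
    return out.drop(columns="_scale")


# ---------------------------------------------------------------------------
# Table-level pipeline

def replicate_rates(df: pd.DataFrame, benchmark: str | None = None) -> pd.DataFrame:
    """Per-replicate removal rates between the first and last timepoint.

    Optionally benchmark-corrects first (``benchmark`` name or None for
    raw concentrations).  Replicates with a below-LOQ endpoint are
    dropped with a warning.  Returns columns ``compound, layer,
    treatment, replicate, dt_h, c_t0, c_t1, rate_ng_L_h,
    percent_decrease, negative, benchmarked``.
    """
    df = validate_concentrations(df)
    benchmarked = benchmark is not None
    if benchmarked:
        df = benchmark_correct(df, benchmark)

    rows = []
    for (compound, layer, treatment, replicate), grp in df.groupby(
        ["compound"] + _BOTTLE_KEY, sort=False
    ):
        times = np.sort(grp["time_h"].unique())
        if times.size < 2:
            raise InputError(
                f"{compound}/{layer}/{treatment}/{replicate}: "
                "need at least two timepoints"
            )
        t0, t1 = times[0], times[-1]
        g0 = grp[grp["time_h"] == t0]
        g1 = grp[grp["time_h"] == t1]
        if len(g0) != 1 or len(g1) != 1:
            raise InputError(
                f"{compound}/{layer}/{treatment}/{replicate}: "
                "duplicate measurements at a timepoint"
            )
        if bool(g0["below_loq"].iloc[0]) or bool(g1["below_loq"].iloc[0]):
            warnings.warn(
                f"{compound}/{layer}/{treatment}/{replicate}: endpoint below "
                "LOQ, replicate dropped", stacklevel=2,
            )
            continue
        c0 = float(g0["conc_ng_L"].iloc[0])
        c1 = float(g1["conc_ng_L"].iloc[0])
        rate = removal_rate(c0, c1, t1 - t0)
        rows.append({
            "compound": compound, "layer": layer, "treatment": treatment,
            "replicate": replicate, "dt_h": t1 - t0, "c_t0": c0, "c_t1": c1,
            "rate_ng_L_h": rate,
            "percent_decrease": percent_decrease(c0, c1) if c0 > 0 else np.nan,
            "negative": rate < 0,
            "benchmarked": benchmarked,
        })
    if not rows:
        raise InputError("no computable replicate rates in table")
    return pd.DataFrame(rows)


def attribute_removal(
    percent_dec: float,
    sorption_bound: float,
    noise_threshold_pct: float = DEFAULT_NOISE_THRESHOLD_PCT,
) -> Attribution:
    """Classify a percent decrease against the repartitioning bound.

    ``NO_REMOVAL`` when the decrease is within the noise threshold;
    ``SORPTION_POSSIBLE`` when repartitioning alone could produce it
    (bound compared with a 1e-9 percentage-point tolerance so that a
    decrease exactly equal to the bound is not over-attributed);
    ``BIODEGRADATION_DOMINANT`` otherwise.
    """
    if np.isnan(percent_dec):
        return Attribution.NO_REMOVAL
    if percent_dec <= noise_threshold_pct:
        return Attribution.NO_REMOVAL
    if sorption_bound * 100.0 >= percent_dec - 1e-9:
        return Attribution.SORPTION_POSSIBLE
    return Attribution.BIODEGRADATION_DOMINANT


def aggregate_rates(
    rep_rates: pd.DataFrame,
    registry: CompoundRegistry | None = None,
    contexts: Mapping[str, tuple[PartitionContext, PartitionContext] | PartitionContext]
    | None = None,
    noise_threshold_pct: float = DEFAULT_NOISE_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Summarise replicate rates as mean +/- sd and attribute removal.

    ``contexts`` maps layer -> PartitionContext (constant pools) or a
    ``(t0, t1)`` pair; with a registry it enables the per-compound
    repartitioning bound, otherwise the bound is 0 (constant pools).
    """
    def bound_for(compound: str, layer: str) -> float:
        if registry is None or contexts is None or layer not in contexts:
            return 0.0
        ctx = contexts[layer]
        if isinstance(ctx, PartitionContext):
            return 0.0
        ctx0, ctx1 = ctx
        return sorption_artifact_bound(registry.get(compound), ctx0, ctx1)

    rows = []
    for (compound, layer, treatment), grp in rep_rates.groupby(
        ["compound", "layer", "treatment"], sort=False
    ):
        rates = grp["rate_ng_L_h"].to_numpy()
        pdec = float(grp["percent_decrease"].mean())
        bound = bound_for(compound, layer)
        rows.append({
            "compound": compound, "layer": layer, "treatment": treatment,
            "n_reps": len(grp),
            "rate_mean": float(rates.mean()),
            "rate_sd": float(rates.std(ddof=1)) if len(rates) > 1 else np.nan,
            "percent_decrease": pdec,
            "benchmarked": bool(grp["benchmarked"].all()),
            "sorption_bound": bound,
            "attribution": attribute_removal(pdec, bound, noise_threshold_pct).value,
        })
    return pd.DataFrame(rows)


def compute_removal(
    df: pd.DataFrame,
    benchmark: str | None = None,
    registry: CompoundRegistry | None = None,
    contexts=None,
    noise_threshold_pct: float = DEFAULT_NOISE_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Convenience chain: replicate rates -> aggregated removal summary."""
    return aggregate_rates(
        replicate_rates(df, benchmark=benchmark),
        registry=registry, contexts=contexts,
        noise_threshold_pct=noise_threshold_pct,
    )


def summarize_by_class(
    results: pd.DataFrame, registry: CompoundRegistry
) -> pd.DataFrame:
    """Per (layer, treatment, weight class) summary of compound mean rates.

    Empty classes are simply absent from the output (never reported as
    zero); all-negative classes are flagged via ``any_negative``.
    """
    res = results.copy()
    res["weight_class"] = [
        registry.get(c).weight_class.value for c in res["compound"]
    ]
    rows = []
    for (layer, treatment, wclass), grp in res.groupby(
        ["layer", "treatment", "weight_class"], sort=False
    ):
        rates = grp["rate_mean"].to_numpy()
        rows.append({
            "layer": layer, "treatment": treatment, "weight_class": wclass,
            "n_compounds": len(grp),
            "rate_mean": float(rates.mean()),
            "rate_sd": float(rates.std(ddof=1)) if len(rates) > 1 else np.nan,
            "rate_min": float(rates.min()),
            "rate_max": float(rates.max()),
            "any_negative": bool((rates < 0).any()),
        })
    return pd.DataFrame(rows)


def compare_layers(
    rep_rates: pd.DataFrame,
    registry: CompoundRegistry,
    treatment: str = "PAH",
    layers: tuple[str, str] = ("SML", "SSL"),
    pool: str = "class",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> pd.DataFrame:
    """Mann-Whitney comparisons of removal rates between two layers.

    ``pool="class"`` pools per-replicate rates across the compounds of
    each weight class (plus the per-replicate HMW sum as ``SUM_HMW``);
    ``pool="compound"`` compares each compound's replicate rates.  Both
    pooling conventions are exposed because with only two bottles per
    condition a per-compound exact test cannot reach p < 0.05 on its own.
    """
    if pool not in {"class", "compound"}:
        raise InputError(f"unknown pooling mode {pool!r}")
    sub = rep_rates[rep_rates["treatment"] == treatment].copy()
    if sub.empty:
        raise InputError(f"no rates for treatment {treatment!r}")
    sub["weight_class"] = [registry.get(c).weight_class.value for c in sub["compound"]]
    a, b = layers

    def groups(pool_key: str, value: str) -> tuple[np.ndarray, np.ndarray]:
        g = sub[sub[pool_key] == value]
        return (
            g.loc[g["layer"] == a, "rate_ng_L_h"].to_numpy(),
            g.loc[g["layer"] == b, "rate_ng_L_h"].to_numpy(),
        )

    comparisons: list[tuple[str, np.ndarray, np.ndarray]] = []
    if pool == "class":
        for wc in (WeightClass.LMW.value, WeightClass.HMW.value):
            comparisons.append((wc, *groups("weight_class", wc)))
        hmw = sub[sub["weight_class"] == WeightClass.HMW.value]
        sums = hmw.groupby(["layer", "replicate"])["rate_ng_L_h"].sum().reset_index()
        comparisons.append((
            "SUM_HMW",
            sums.loc[sums["layer"] == a, "rate_ng_L_h"].to_numpy(),
            sums.loc[sums["layer"] == b, "rate_ng_L_h"].to_numpy(),
        ))
    else:
        for compound in sub["compound"].unique():
            comparisons.append((compound, *groups("compound", compound)))

    rows = []
    for label, ga, gb in comparisons:
        if ga.size == 0 or gb.size == 0:
            warnings.warn(f"{label}: one layer has no rates, comparison skipped",
                          stacklevel=2)
            continue
        res = mann_whitney(ga, gb, exact_threshold=exact_threshold)
        rows.append({
            "group": label, "treatment": treatment,
            f"n_{a}": res.n1, f"n_{b}": res.n2,
            "U": res.statistic, "p_value": res.p_value,
            "method": res.method.value,
            "significant_0p05": res.p_value <= 0.05,
        })
    return pd.DataFrame(rows)
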