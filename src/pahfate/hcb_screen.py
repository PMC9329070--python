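"""Screening ASV tables for hydrocarbonoclastic bacteria (HCB).

The screen takes an ASV count table (taxa x samples), a SILVA-style
seven-rank taxonomy and per-sample metadata (layer, size fraction,
treatment, timepoint, replicate), and asks whether genera known to
degrade hydrocarbons become enriched after PAH exposure.

Workflow: rarefy all samples to a common depth (default: the minimum
sample sum, subsampling without replacement), aggregate counts to genus
level as relative abundances, restrict to a curated HCB genus list, and
per (layer, fraction) stratum compare treatment against control arms
with gtools-convention fold changes and t-tests.

Taxa whose genus rank is unassigned are pooled into an ``unclassified``
bin for relative abundances and can never match the HCB list (matching
is genus-level by design, assuming shared metabolism within a genus).
Archaea are discarded before analysis by default (typically < 1 % of
reads in the data this targets); the removal is toggleable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError
from .inference import fold_change, t_test

__all__ = [
    "RANKS",
    "TaxonTable",
    "HCBList",
    "parse_lineage",
    "read_counts_tsv",
    "read_taxonomy_tsv",
    "read_sample_meta",
    "rarefy",
    "relative_abundance",
    "filter_hcb",
    "enrichment_screen",
    "hcb_share",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

META_COLUMNS = ("layer", "fraction", "treatment", "timepoint", "replicate")

_SILVA_PREFIX = re.compile(r"^[dkpcofgs]__")


def _norm(name: str) -> str:
    return str(name).strip().casefold()


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-separated lineage into the seven standard ranks.

    SILVA-style ``g__`` prefixes are stripped; missing trailing ranks are
    padded with empty strings; placeholders such as ``uncultured`` are
    kept verbatim (they simply never match an HCB genus).
    """
    parts = [(_SILVA_PREFIX.sub("", p.strip())) for p in str(lineage).split(";")]
    parts = [p for p in parts]
    if len(parts) > len(RANKS):
        parts = parts[: len(RANKS)]
    parts += [""] * (len(RANKS) - len(parts))
    return tuple(parts)


@dataclass
class TaxonTable:
    """ASV counts with taxonomy and sample metadata.

    Attributes
    ----------
    counts
        Non-negative integer DataFrame, taxa (rows) x samples (columns).
    taxonomy
        DataFrame indexed like ``counts`` with the seven rank columns.
    sample_meta
        DataFrame indexed by sample id with columns
        ``layer, fraction, treatment, timepoint, replicate``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.taxonomy.index):
            raise InputError("taxonomy rows must match count rows")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise InputError("sample metadata rows must match count columns")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise InputError(f"sample metadata missing column(s): {missing}")
        missing_ranks = [r for r in RANKS if r not in self.taxonomy.columns]
        if missing_ranks:
            raise InputError(f"taxonomy missing rank column(s): {missing_ranks}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise InputError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_taxa(self, taxa: Sequence[str]) -> "TaxonTable":
        idx = self.counts.index.intersection(taxa)
        return TaxonTable(self.counts.loc[idx], self.taxonomy.loc[idx],
                          self.sample_meta)

    def subset_samples(self, samples: Sequence[str]) -> "TaxonTable":
        keep = [s for s in self.counts.columns if s in set(samples)]
        return TaxonTable(self.counts[keep], self.taxonomy,
                          self.sample_meta.loc[keep])

    def drop_archaea(self) -> "TaxonTable":
        keep = self.taxonomy["domain"].map(_norm) != "archaea"
        return TaxonTable(self.counts.loc[keep], self.taxonomy.loc[keep],
                          self.sample_meta)


# ---------------------------------------------------------------------------
# I/O

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Counts TSV: taxa rows x sample columns, first column the taxon id."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise InputError(f"empty count table: {path}")
    return df


def read_taxonomy_tsv(path: str | Path) -> pd.DataFrame:
    """Taxonomy TSV: ``taxon_id<TAB>lineage`` -> seven-rank DataFrame."""
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, header=0)
    lineages = raw.iloc[:, 0]
    recs = [parse_lineage(s) for s in lineages]
    return pd.DataFrame(recs, index=raw.index, columns=list(RANKS))


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Sample metadata CSV indexed by ``sample_id``."""
    df = pd.read_csv(path, comment="#", index_col=0, dtype=str)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"sample metadata missing column(s): {missing}")
    return df


def load_taxon_table(counts_path, taxonomy_path, meta_path,
                     drop_archaea: bool = True) -> TaxonTable:
    counts = read_counts_tsv(counts_path)
    taxonomy = read_taxonomy_tsv(taxonomy_path)
    meta = read_sample_meta(meta_path)
    try:
        taxonomy = taxonomy.loc[counts.index]
        meta = meta.loc[counts.columns]
    except KeyError as exc:
        raise InputError(f"counts/taxonomy/metadata mismatch: {exc}") from exc
    table = TaxonTable(counts, taxonomy, meta)
    return table.drop_archaea() if drop_archaea else table


@dataclass(frozen=True)
class HCBList:
    """Curated set of hydrocarbonoclastic genera (names normalised)."""

    genera: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genera:
            raise InputError("HCB genus list must be non-empty")
        object.__setattr__(self, "genera", frozenset(_norm(g) for g in self.genera))

    def __contains__(self, genus: str) -> bool:
        return _norm(genus) in self.genera

    def __len__(self) -> int:
        return len(self.genera)

    @classmethod
    def from_iterable(cls, genera: Iterable[str], source: str = "") -> "HCBList":
        return cls(frozenset(genera), source)

    @classmethod
    def from_file(cls, path: str | Path) -> "HCBList":
        names = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                names.append(line)
        return cls(frozenset(names), source=str(path))

    @classmethod
    def default(cls) -> "HCBList":
        text = resources.files("pahfate.data").joinpath("hcb_genera.txt").read_text("utf-8")
        names = [ln.split("#", 1)[0].strip() for ln in text.splitlines()]
        return cls(frozenset(n for n in names if n), source="shipped hcb_genera.txt")


# ---------------------------------------------------------------------------
# Operations

def rarefy(table: TaxonTable, depth: int | None = None, seed: int = 0) -> TaxonTable:
    """Subsample every sample to a common depth, without replacement.

    ``depth=None`` uses the minimum sample sum.  Samples with fewer reads
    than ``depth`` are dropped with a warning.  The multivariate
    hypergeometric draw preserves expected proportions exactly and is
    deterministic for a fixed seed.
    """
    sums = table.sample_sums()
    if depth is None:
        depth = int(sums.min())
    if depth < 1:
        raise InputError(f"rarefaction depth must be >= 1, got {depth}")
    keep = sums.index[sums >= depth].tolist()
    dropped = [s for s in table.counts.columns if s not in set(keep)]
    if not keep:
        raise InputError(f"all samples have fewer than {depth} reads")
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sub = table.subset_samples(keep)
    out = {}
    for sample in sub.counts.columns:
        col = sub.counts[sample].to_numpy()
        total = int(col.sum())
        if total == depth:
            out[sample] = col.copy()
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=sub.counts.index)
    return TaxonTable(counts, sub.taxonomy, sub.sample_meta)


def relative_abundance(table: TaxonTable, level: str = "genus") -> pd.DataFrame:
    """Aggregate counts to a rank and convert to per-sample proportions.

    Taxa unassigned at ``level`` are pooled into an ``unclassified`` bin.
    Every column of the result sums to 1; empty samples are an error.
    """
    if level not in RANKS:
        raise InputError(f"unknown taxonomic rank {level!r}")
    sums = table.sample_sums()
    if (sums == 0).any():
        empty = sums.index[sums == 0].tolist()
        raise InputError(f"empty sample(s): {empty}")
    labels = table.taxonomy[level].astype(str).str.strip()
    labels = labels.where(labels != "", "unclassified")
    agg = table.counts.groupby(labels.values).sum()
    return agg / sums


def filter_hcb(table: TaxonTable, hcb: HCBList | None = None) -> TaxonTable:
    """Retain exactly the taxa whose genus matches the HCB list.

    Matching is case-insensitive at genus rank; genus-unassigned taxa
    never match.  An empty result is allowed.
    """
    if hcb is None:
        hcb = HCBList.default()
    keep = table.taxonomy["genus"].map(lambda g: _norm(g) in hcb.genera if g else False)
    return TaxonTable(table.counts.loc[keep.values], table.taxonomy.loc[keep.values],
                      table.sample_meta)


def _pseudo_proportion(stratum_props: pd.DataFrame) -> float:
    """Half the minimum nonzero proportion in the stratum (fold-change floor)."""
    vals = stratum_props.to_numpy()
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise DegenerateDataError("stratum has no nonzero proportions")
    return float(nonzero.min()) / 2.0


def enrichment_screen(
    table: TaxonTable,
    hcb: HCBList | None = None,
    level: str = "genus",
    strata: Sequence[str] = ("layer", "fraction"),
    treatment_col: str = "treatment",
    arms: tuple[str, str] = ("PAH", "CONTROL"),
    timepoint: str | None = None,
    paired: bool = False,
    hcb_only: bool = False,
) -> pd.DataFrame:
    """Treatment-vs-control enrichment of taxa within each stratum.

    For every stratum (unique combination of ``strata`` metadata values)
    the mean relative abundance of each taxon at ``level`` is compared
    between the two arms: gtools-convention fold change (positive =
    enriched in the first arm) and a t-test p-value when both arms have
    at least two replicates (Welch by default; ``paired=True`` pairs
    replicates by their sorted order, requiring equal arm sizes).

    Taxa with zero mean abundance in one arm use a pseudo-proportion of
    half the smallest nonzero proportion observed in the stratum; taxa
    absent from both arms are excluded.  Strata missing an arm are
    skipped with a warning.
    """
    meta = table.sample_meta
    if timepoint is not None:
        samples = meta.index[meta["timepoint"] == timepoint]
        table = table.subset_samples(samples)
        meta = table.sample_meta
    props = relative_abundance(table, level=level)
    if hcb_only:
        if hcb is None:
            hcb = HCBList.default()
        taxa_of_interest = [t for t in props.index if _norm(t) in hcb.genera]
    else:
        taxa_of_interest = list(props.index)

    rows = []
    warned_single = False
    for stratum_vals, sm in meta.groupby(list(strata), sort=False):
        if not isinstance(stratum_vals, tuple):
            stratum_vals = (stratum_vals,)
        arm_a = sm.index[sm[treatment_col] == arms[0]].tolist()
        arm_b = sm.index[sm[treatment_col] == arms[1]].tolist()
        if not arm_a or not arm_b:
            warnings.warn(
                f"stratum {dict(zip(strata, stratum_vals))}: arm missing, skipped",
                stacklevel=2,
            )
            continue
        sp = props[arm_a + arm_b]
        pseudo = _pseudo_proportion(sp)
        for taxon in taxa_of_interest:
            mean_a = float(sp.loc[taxon, arm_a].mean())
            mean_b = float(sp.loc[taxon, arm_b].mean())
            if mean_a == 0.0 and mean_b == 0.0:
                continue
            fc = fold_change(max(mean_a, pseudo), max(mean_b, pseudo))
            p = np.nan
            if len(arm_a) >= 2 and len(arm_b) >= 2:
                xa = sp.loc[taxon, arm_a].to_numpy()
                xb = sp.loc[taxon, arm_b].to_numpy()
                try:
                    p = t_test(np.sort(xa), np.sort(xb), paired=paired).p_value \
                        if paired else t_test(xa, xb).p_value
                except DegenerateDataError:
                    p = np.nan
            elif not warned_single:
                warnings.warn(
                    "single replicate in an arm: fold changes reported, "
                    "p-values empty", stacklevel=2,
                )
                warned_single = True
            rows.append({
                **dict(zip(strata, stratum_vals)),
                "taxon": taxon,
                f"n_{arms[0]}": len(arm_a), f"n_{arms[1]}": len(arm_b),
                f"mean_{arms[0]}": mean_a, f"mean_{arms[1]}": mean_b,
                "fold_change": fc, "p_value": p,
            })
    return pd.DataFrame(rows)


def hcb_share(table: TaxonTable, hcb: HCBList | None = None) -> pd.Series:
    """Per-sample fraction of reads belonging to HCB genera."""
    sub = filter_hcb(table, hcb)
    totals = table.sample_sums()
    return sub.counts.sum(axis=0) / totals
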