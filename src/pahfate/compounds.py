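"""PAH compound registry and molecular-weight classification.

The dissolved-phase analyses track 13 polycyclic aromatic hydrocarbons
(PAHs) quantifiable by GC-MS after solid-phase extraction.  Compounds
with four or more fused rings are classed as high molecular weight
(HMW); those with two or three rings as low molecular weight (LMW).
Naphthalene, acenaphthene and acenaphthylene are too volatile for the
extraction procedure and, while representable, are excluded from default
analyses.

Octanol-water partition coefficients (log Kow) drive every sorption
estimate downstream; the shipped values are literature defaults and can
be overridden with a user property table (CSV with columns
``name,n_rings,log_kow,mw``).
"""

from __future__ import annotations

import csv
import enum
import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .errors import InputError, InvalidStructureError

__all__ = [
    "WeightClass",
    "PAHCompound",
    "CompoundRegistry",
    "classify_weight_class",
    "load_registry",
    "default_registry",
    "VOLATILE_PAHS",
]

#: Minimum fused-ring count for the high-molecular-weight class.
HMW_MIN_RINGS = 4

#: Two-to-three-ring PAHs excluded from quantitative analysis because the
#: extraction procedure is not quantitative for volatile compounds.
VOLATILE_PAHS = frozenset({"naphthalene", "acenaphthene", "acenaphthylene"})

_REQUIRED_COLUMNS = ("name", "n_rings", "log_kow", "mw")


class WeightClass(str, enum.Enum):
    """Molecular-weight class of a PAH (LMW: 2-3 rings; HMW: >= 4 rings)."""

    LMW = "LMW"
    HMW = "HMW"


def classify_weight_class(n_rings: int) -> WeightClass:
    """Classify a PAH as LMW or HMW from its fused-ring count.

    Parameters
    ----------
    n_rings
        Number of fused rings; every PAH has at least two.

    Returns
    -------
    WeightClass
        ``HMW`` when ``n_rings >= 4``, else ``LMW``.

    Raises
    ------
    InvalidStructureError
        If ``n_rings < 2`` (not a PAH).
    """
    n = int(n_rings)
    if n < 2:
        raise InvalidStructureError(
            f"a PAH has at least two fused rings, got n_rings={n_rings!r}"
        )
    return WeightClass.HMW if n >= HMW_MIN_RINGS else WeightClass.LMW


@dataclass(frozen=True)
class PAHCompound:
    """One aromatic compound with structural and partitioning properties.

    Attributes
    ----------
    name
        Canonical compound identifier (lower case by convention).
    n_rings
        Number of fused rings (>= 2).
    log_kow
        Decimal log of the octanol-water partition constant (dimensionless).
    mw
        Molecular weight in g/mol.
    """

    name: str
    n_rings: int
    log_kow: float
    mw: float

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise InputError("compound name must be non-empty")
        classify_weight_class(self.n_rings)  # validates n_rings >= 2
        if not self.mw > 0:
            raise InputError(f"{self.name}: molecular weight must be > 0, got {self.mw}")

    @property
    def weight_class(self) -> WeightClass:
        return classify_weight_class(self.n_rings)

    @property
    def volatile(self) -> bool:
        """True for PAHs the extraction chemistry cannot quantify."""
        return self.name.strip().casefold() in VOLATILE_PAHS


@dataclass
class CompoundRegistry:
    """Ordered, name-unique collection of :class:`PAHCompound`."""

    compounds: list[PAHCompound] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.compounds:
            key = c.name.casefold()
            if key in seen:
                raise InputError(f"duplicate compound name: {c.name!r}")
            seen.add(key)

    def __iter__(self) -> Iterator[PAHCompound]:
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    def __contains__(self, name: str) -> bool:
        return any(c.name.casefold() == name.casefold() for c in self.compounds)

    def get(self, name: str) -> PAHCompound:
        for c in self.compounds:
            if c.name.casefold() == name.casefold():
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def by_class(self, weight_class: WeightClass | str) -> list[PAHCompound]:
        wc = WeightClass(weight_class)
        return [c for c in self.compounds if c.weight_class is wc]

    def analysis_compounds(self) -> list[PAHCompound]:
        """Compounds entering quantitative analyses (volatile PAHs excluded)."""
        return [c for c in self.compounds if not c.volatile]

    def add(self, compound: PAHCompound) -> None:
        if compound.name in self:
            raise InputError(f"duplicate compound name: {compound.name!r}")
        self.compounds.append(compound)


def _parse_rows(rows: Iterable[dict], strict: bool) -> CompoundRegistry:
    compounds: list[PAHCompound] = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        try:
            compound = PAHCompound(
                name=row["name"].strip(),
                n_rings=int(row["n_rings"]),
                log_kow=float(row["log_kow"]),
                mw=float(row["mw"]),
            )
        except (TypeError, ValueError, KeyError) as exc:
            if isinstance(exc, InputError):
                raise
            raise InputError(f"property table row {i}: {exc}") from exc
        if strict and compound.volatile:
            warnings.warn(
                f"{compound.name} is volatile and excluded from default "
                "analyses (kept in the registry, flagged)",
                stacklevel=3,
            )
        compounds.append(compound)
    return CompoundRegistry(compounds)


def load_registry(path: str | Path, strict: bool = False) -> CompoundRegistry:
    """Load a compound property table (CSV, ``#`` comment lines allowed).

    Required columns: ``name,n_rings,log_kow,mw``.  Duplicate names,
    missing columns and non-numeric properties raise :class:`InputError`.
    With ``strict=True`` volatile PAHs (naphthalene, acenaphthene,
    acenaphthylene) are flagged with a warning but kept.
    """
    text = Path(path).read_text(encoding="utf-8")
    return _registry_from_text(text, strict=strict)


def _registry_from_text(text: str, strict: bool = False) -> CompoundRegistry:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise InputError("empty property table")
    reader = csv.DictReader(io.StringIO("\n".join(lines)))
    missing = [c for c in _REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise InputError(f"property table missing column(s): {', '.join(missing)}")
    return _parse_rows(reader, strict=strict)


def default_registry() -> CompoundRegistry:
    """The shipped 13-compound registry (3 LMW + 10 HMW)."""
    text = resources.files("pahfate.data").joinpath("pah_properties.csv").read_text("utf-8")
    return _registry_from_text(text)
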