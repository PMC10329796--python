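"""Domain types and I/O for family-level species counts.

A flora is summarized as one row per botanical family: the number of
accepted native species (``n_total``) and the number of those recorded
as food plants (``x_used``).  Species-level checklists are aggregated to
this form after filtering to native records and deduplicating names.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ORIGIN_VALUES",
    "SpeciesRecord",
    "FamilyCount",
    "FloraTable",
    "ModelConfig",
    "ValidationFinding",
    "SchemaError",
    "ValidationError",
    "aggregate_species",
    "read_species_csv",
    "write_species_csv",
    "read_counts_csv",
    "write_counts_csv",
    "load_reference_counts",
    "load_reference_table",
    "validate_table",
]

ORIGIN_VALUES = ("native", "naturalized", "exotic", "cultivated", "unknown")

SPECIES_COLUMNS = ("scientific_name", "family", "origin", "is_food_use", "source_ref")
COUNTS_COLUMNS = ("family", "n_total", "x_used")


class SchemaError(ValueError):
    """A CSV file does not match the expected column schema."""


class ValidationError(ValueError):
    """Input data violate a domain invariant."""


def _norm_name(name: str) -> str:
    return " ".join(name.split()).lower()


def _norm_family(family: str) -> str:
    return " ".join(family.split()).title()


@dataclass(frozen=True)
class SpeciesRecord:
    """One checklist entry for an accepted species binomial."""

    scientific_name: str
    family: str
    origin: str
    is_food_use: bool
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not self.scientific_name.strip():
            raise ValidationError("scientific_name must be non-empty")
        if not self.family.strip():
            raise ValidationError("family must be non-empty")
        if self.origin not in ORIGIN_VALUES:
            raise ValidationError(f"unknown origin value: {self.origin!r}")


@dataclass(frozen=True)
class FamilyCount:
    """Native species count and food-use count for one family."""

    family: str
    n_total: int
    x_used: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError(
                f"family {self.family!r}: n_total must be >= 1, got {self.n_total}"
            )
        if not 0 <= self.x_used <= self.n_total:
            raise ValidationError(
                f"family {self.family!r}: require 0 <= x_used <= n_total, "
                f"got x_used={self.x_used}, n_total={self.n_total}"
            )


@dataclass(frozen=True)
class FloraTable:
    """Ordered family counts plus overall totals (N, X)."""

    families: tuple[FamilyCount, ...]
    N_total: int
    X_total: int

    @classmethod
    def from_counts(cls, families: Sequence[FamilyCount]) -> "FloraTable":
        fams = tuple(families)
        names = [f.family for f in fams]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate family names: {dup}")
        return cls(
            families=fams,
            N_total=sum(f.n_total for f in fams),
            X_total=sum(f.x_used for f in fams),
        )

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def get(self, family: str) -> FamilyCount:
        for f in self.families:
            if f.family == family:
                return f
        raise KeyError(family)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [f.family for f in self.families],
                "n_total": [f.n_total for f in self.families],
                "x_used": [f.x_used for f in self.families],
            }
        )


@dataclass(frozen=True)
class ModelConfig:
    """Interval-model settings shared by the whole analysis.

    Parameters
    ----------
    level
        Two-sided credibility/confidence level (default 0.95).
    idm_s
        Imprecision parameter of the Imprecise Dirichlet Model.  The
        default of 4 reproduces the published reference table.
    global_convention
        ``"paper_compat"`` computes the overall-flora interval with the
        IDM form for both models (matching the published total row);
        ``"per_model"`` applies each model's own form to the totals.
    bayes_variant
        ``"exceedance"`` is the published pair-of-beta construction;
        ``"posterior"`` uses the single Beta(x+1, n-x+1) posterior and
        is provided for methodological comparison only.
    """

    level: float = 0.95
    idm_s: int = 4
    global_convention: str = "paper_compat"
    bayes_variant: str = "exceedance"

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValidationError(f"level must be in (0, 1), got {self.level}")
        if self.idm_s < 1:
            raise ValidationError(f"idm_s must be >= 1, got {self.idm_s}")
        if self.global_convention not in ("paper_compat", "per_model"):
            raise ValidationError(
                f"global_convention must be 'paper_compat' or 'per_model', "
                f"got {self.global_convention!r}"
            )
        if self.bayes_variant not in ("exceedance", "posterior"):
            raise ValidationError(
                f"bayes_variant must be 'exceedance' or 'posterior', "
                f"got {self.bayes_variant!r}"
            )


@dataclass(frozen=True)
class ValidationFinding:
    """One detected invariant violation (kind, human-readable message)."""

    kind: str
    message: str


def aggregate_species(records: Iterable[SpeciesRecord]) -> FloraTable:
    """Aggregate a species checklist to per-family counts.

    Only records with origin ``native`` are retained; naturalized,
    exotic, cultivated and unknown-origin records are dropped.  Retained
    records are deduplicated on the whitespace/case-normalized binomial;
    a species counts as food-used when any of its duplicate records is
    food-flagged.
    """
    records = list(records)
    if not records:
        raise ValidationError("no species records supplied")

    # species key -> (family, food flag); union the flag across duplicates
    species: dict[str, list] = {}
    for rec in records:
        if rec.origin != "native":
            continue
        key = _norm_name(rec.scientific_name)
        fam = _norm_family(rec.family)
        if key in species:
            species[key][1] = species[key][1] or rec.is_food_use
        else:
            species[key] = [fam, rec.is_food_use]

    if not species:
        raise ValidationError("no native records after filtering")

    n_by_family: dict[str, int] = {}
    x_by_family: dict[str, int] = {}
    for fam, food in species.values():
        n_by_family[fam] = n_by_family.get(fam, 0) + 1
        x_by_family[fam] = x_by_family.get(fam, 0) + int(food)

    counts = [
        FamilyCount(family=fam, n_total=n_by_family[fam], x_used=x_by_family[fam])
        for fam in sorted(n_by_family)
    ]
    return FloraTable.from_counts(counts)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f", ""}


def _parse_bool(value, path, row: int) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS or s == "nan":
        return False
    raise ValidationError(f"{path}, row {row}: cannot parse is_food_use value {value!r}")


def read_species_csv(path) -> list[SpeciesRecord]:
    """Read a species-level checklist CSV.

    Required columns: ``scientific_name, family, origin, is_food_use``;
    ``source_ref`` is optional.  Origin strings outside the known set
    map to ``unknown``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SPECIES_COLUMNS[:4], path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        origin = str(row.origin).strip().lower()
        if origin not in ORIGIN_VALUES:
            origin = "unknown"
        try:
            records.append(
                SpeciesRecord(
                    scientific_name=str(row.scientific_name),
                    family=str(row.family),
                    origin=origin,
                    is_food_use=_parse_bool(row.is_food_use, path, i),
                    source_ref=str(getattr(row, "source_ref", "")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
    return records


def write_species_csv(records: Iterable[SpeciesRecord], path) -> None:
    records = list(records)
    df = pd.DataFrame(
        {
            "scientific_name": [r.scientific_name for r in records],
            "family": [r.family for r in records],
            "origin": [r.origin for r in records],
            "is_food_use": [r.is_food_use for r in records],
            "source_ref": [r.source_ref for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_counts_csv(path) -> FloraTable:
    """Read a family counts CSV (columns family, n_total, x_used)."""
    df = pd.read_csv(path)
    _require_columns(df, COUNTS_COLUMNS, path)
    if len(df) == 0:
        raise ValidationError(f"{path}: no families in counts file")
    counts = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            counts.append(
                FamilyCount(
                    family=str(row.family),
                    n_total=int(row.n_total),
                    x_used=int(row.x_used),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
    return FloraTable.from_counts(counts)


def write_counts_csv(table: FloraTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def _reference_frame() -> pd.DataFrame:
    ref = importlib.resources.files("florabias.data") / "reference_counts.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_reference_counts() -> FloraTable:
    """Return the bundled reference flora (230 families, N=32740, X=254)."""
    df = _reference_frame()
    counts = [
        FamilyCount(family=str(r.family), n_total=int(r.n_total), x_used=int(r.x_used))
        for r in df.itertuples(index=False)
    ]
    return FloraTable.from_counts(counts)


def load_reference_table() -> pd.DataFrame:
    """Bundled reference table including published bounds and statuses.

    Columns: family, n_total, x_used, bayes_lower, bayes_upper,
    status_bayes, idm_lower, idm_upper, status_idm.  Bounds are the
    published 7-decimal values; used by tests and ``reproduce-paper``.
    """
    return _reference_frame()


def validate_table(table: FloraTable) -> list[ValidationFinding]:
    """Check FloraTable invariants, returning findings (empty = valid)."""
    findings: list[ValidationFinding] = []
    names = [f.family for f in table.families]
    for dup in sorted({n for n in names if names.count(n) > 1}):
        findings.append(
            ValidationFinding("duplicate family", f"family {dup!r} appears more than once")
        )
    for f in table.families:
        if f.x_used > f.n_total:
            findings.append(
                ValidationFinding(
                    "count violation",
                    f"family {f.family!r}: x_used {f.x_used} > n_total {f.n_total}",
                )
            )
    n_sum = sum(f.n_total for f in table.families)
    x_sum = sum(f.x_used for f in table.families)
    if table.N_total != n_sum:
        findings.append(
            ValidationFinding(
                "total mismatch", f"N_total {table.N_total} != sum of n_total {n_sum}"
            )
        )
    if table.X_total != x_sum:
        findings.append(
            ValidationFinding(
                "total mismatch", f"X_total {table.X_total} != sum of x_used {x_sum}"
            )
        )
    return findings
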