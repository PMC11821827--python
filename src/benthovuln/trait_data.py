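"""Domain types and ingestion for trait tables and mass-mortality records.

A mass mortality event (MME) record quantifies abnormal mortality of one
species population at a site and year, as a percentage of colonies or
individuals dead, recorded in 10% steps. Records carry one or more mortality
drivers, each either abiotic (temperature anomaly, storm, ...) or biotic
(disease, predator outbreak, ...). A functional entity (FE) groups the
species sharing an identical combination of values across all ten traits;
FEs, not species, are the unit of every trait-volume computation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .schema import TraitSchema

__all__ = [
    "ABIOTIC_DRIVERS",
    "BIOTIC_DRIVERS",
    "ALL_DRIVERS",
    "ValidationError",
    "TraitTable",
    "MortalityRecord",
    "FunctionalEntity",
    "RedundancySummary",
    "classify_severity",
    "read_trait_table",
    "write_trait_table",
    "read_mortality_records",
    "write_mortality_records",
    "build_functional_entities",
    "summarize_redundancy",
    "impacted_fe_ids",
    "species_to_fe",
]

# Controlled driver vocabulary: nine driver variables. The two residual
# classes are disambiguated by suffix so that a label alone determines
# whether the driver is abiotic or biotic.
ABIOTIC_DRIVERS = frozenset(
    {"temperature anomaly", "storm", "pollution", "turbidity increase", "other abiotic"}
)
BIOTIC_DRIVERS = frozenset(
    {"disease", "mucilage coverage", "predator outbreak", "other biotic"}
)
ALL_DRIVERS = ABIOTIC_DRIVERS | BIOTIC_DRIVERS

VALID_PERCENTS = frozenset(range(10, 101, 10))


class ValidationError(ValueError):
    """Raised when input data violate the declared schema or vocabulary."""


def classify_severity(percent_mortality: int) -> str:
    """Map a quantified mortality percentage to its severity class.

    low: below 30%; moderate: 30-60% inclusive; severe: above 60%. The
    classes partition the admissible values {10, 20, ..., 100}.
    """
    if percent_mortality not in VALID_PERCENTS:
        raise ValidationError(
            f"percent_mortality must be a multiple of 10 in [10, 100], got {percent_mortality!r}"
        )
    if percent_mortality < 30:
        return "low"
    if percent_mortality <= 60:
        return "moderate"
    return "severe"


@dataclass(frozen=True)
class MortalityRecord:
    """One quantified MME observation on a single species population."""

    species: str
    phylum: str
    year: int
    longitude: float
    latitude: float
    depth_range: str
    habitat: str
    drivers: frozenset[str]
    percent_mortality: int

    def __post_init__(self) -> None:
        if not self.drivers:
            raise ValidationError(f"record for {self.species}: empty driver set")
        unknown = set(self.drivers) - ALL_DRIVERS
        if unknown:
            raise ValidationError(
                f"record for {self.species}: unknown driver label(s) {sorted(unknown)}"
            )
        classify_severity(self.percent_mortality)  # validates range/step

    @property
    def severity(self) -> str:
        return classify_severity(self.percent_mortality)

    @property
    def driver_class(self) -> str:
        """'abiotic', 'biotic', or 'combination' (drivers of both classes)."""
        has_a = bool(self.drivers & ABIOTIC_DRIVERS)
        has_b = bool(self.drivers & BIOTIC_DRIVERS)
        if has_a and has_b:
            return "combination"
        return "abiotic" if has_a else "biotic"


class TraitTable:
    """Validated species x trait table with a phylum per species.

    Thin wrapper over a pandas DataFrame indexed by species name, with a
    ``phylum`` column followed by one column per trait code. Construction
    validates every value against the schema vocabulary; missing values are
    rejected rather than imputed.
    """

    def __init__(self, df: pd.DataFrame, schema: TraitSchema):
        expected = ["phylum"] + schema.codes
        missing_cols = [c for c in expected if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"trait table missing column(s): {missing_cols}")
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate species: {dups}")
        df = df[expected].copy()
        df.index = df.index.astype(str)
        for trait in schema:
            col = df[trait.code]
            if col.isna().any():
                bad = sorted(df.index[col.isna()])
                raise ValidationError(f"trait {trait.code}: missing value for species {bad}")
            col = col.astype(str)
            invalid = ~col.isin(trait.categories)
            if invalid.any():
                sp = df.index[invalid][0]
                raise ValidationError(
                    f"trait {trait.code}: value {col[invalid].iloc[0]!r} for species "
                    f"{sp!r} not in vocabulary {list(trait.categories)}"
                )
            df[trait.code] = col
        if df["phylum"].isna().any():
            raise ValidationError("missing phylum value(s)")
        self.df = df
        self.schema = schema

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def n_species(self) -> int:
        return len(self.df)

    def phylum(self, species: str) -> str:
        return str(self.df.at[species, "phylum"])

    def signature(self, species: str) -> tuple[str, ...]:
        return tuple(self.df.loc[species, self.schema.codes])

    def __contains__(self, species: str) -> bool:
        return species in self.df.index

    def __len__(self) -> int:
        return len(self.df)


def read_trait_table(csv_source, schema: TraitSchema) -> TraitTable:
    """Read and validate a trait table CSV (columns: species, phylum, A..J)."""
    df = pd.read_csv(csv_source, dtype=str)
    if "species" not in df.columns:
        raise ValidationError("trait CSV must have a 'species' column")
    df = df.set_index("species")
    return TraitTable(df, schema)


def write_trait_table(table: TraitTable, path_or_buf) -> None:
    """Write a trait table back to CSV; inverse of :func:`read_trait_table`."""
    out = table.df.reset_index().rename(columns={"index": "species"})
    out.to_csv(path_or_buf, index=False)


_MORTALITY_FIELDS = [
    "species",
    "phylum",
    "year",
    "longitude",
    "latitude",
    "depth_range",
    "habitat",
    "drivers",
    "percent_mortality",
]


def read_mortality_records(csv_source) -> tuple[list[MortalityRecord], int]:
    """Read a mortality-record CSV.

    Returns the quantified records and the count of rows whose
    ``percent_mortality`` is blank (events observed but not quantified);
    those rows are excluded from all downstream analysis.
    """
    if hasattr(csv_source, "read"):
        fh = csv_source
        close = False
    else:
        fh = open(csv_source, newline="", encoding="utf-8")
        close = True
    try:
        reader = csv.DictReader(fh)
        missing = [c for c in _MORTALITY_FIELDS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"mortality CSV missing column(s): {missing}")
        records: list[MortalityRecord] = []
        unquantified = 0
        for i, row in enumerate(reader, start=2):
            pct_raw = (row["percent_mortality"] or "").strip()
            if pct_raw == "":
                unquantified += 1
                continue
            try:
                pct = int(float(pct_raw))
                if float(pct_raw) != pct:
                    raise ValueError
            except ValueError:
                raise ValidationError(f"line {i}: percent_mortality {pct_raw!r} is not an integer")
            drivers = frozenset(d.strip() for d in row["drivers"].split(";") if d.strip())
            try:
                rec = MortalityRecord(
                    species=row["species"].strip(),
                    phylum=row["phylum"].strip(),
                    year=int(row["year"]),
                    longitude=float(row["longitude"]),
                    latitude=float(row["latitude"]),
                    depth_range=row["depth_range"].strip(),
                    habitat=row["habitat"].strip(),
                    drivers=drivers,
                    percent_mortality=pct,
                )
            except ValidationError as exc:
                raise ValidationError(f"line {i}: {exc}") from exc
            records.append(rec)
        return records, unquantified
    finally:
        if close:
            fh.close()


def write_mortality_records(
    records: Iterable[MortalityRecord], path_or_buf, n_unquantified: int = 0
) -> None:
    """Write records to CSV; optionally append blank-percent placeholder rows."""
    if hasattr(path_or_buf, "write"):
        fh, close = path_or_buf, False
    else:
        fh, close = open(path_or_buf, "w", newline="", encoding="utf-8"), True
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_MORTALITY_FIELDS)
        last = None
        for rec in records:
            writer.writerow(
                [
                    rec.species,
                    rec.phylum,
                    rec.year,
                    repr(rec.longitude),
                    repr(rec.latitude),
                    rec.depth_range,
                    rec.habitat,
                    ";".join(sorted(rec.drivers)),
                    rec.percent_mortality,
                ]
            )
            last = rec
        for _ in range(n_unquantified):
            ref = last
            writer.writerow(
                [
                    ref.species if ref else "unknown",
                    ref.phylum if ref else "unknown",
                    ref.year if ref else 2000,
                    repr(ref.longitude) if ref else "0.0",
                    repr(ref.latitude) if ref else "38.0",
                    "",
                    "",
                    "temperature anomaly",
                    "",
                ]
            )
    finally:
        if close:
            fh.close()


@dataclass(frozen=True)
class FunctionalEntity:
    """A unique ten-trait signature and the species that share it."""

    fe_id: str
    signature: tuple[str, ...]
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"{self.fe_id}: FE with no member species")

    @property
    def n_species(self) -> int:
        return len(self.members)


def build_functional_entities(table: TraitTable) -> list[FunctionalEntity]:
    """Group species into FEs by identical trait signature.

    FE ids are assigned in lexicographic signature order (FE001, FE002, ...)
    so the construction is deterministic and invariant to row order.
    """
    groups: dict[tuple[str, ...], set[str]] = {}
    for sp in table.species:
        groups.setdefault(table.signature(sp), set()).add(sp)
    fes = []
    for i, sig in enumerate(sorted(groups), start=1):
        fes.append(
            FunctionalEntity(fe_id=f"FE{i:03d}", signature=sig, members=frozenset(groups[sig]))
        )
    return fes


@dataclass(frozen=True)
class RedundancySummary:
    """Counts describing functional redundancy (species sharing an FE)."""

    n_species: int
    n_fes: int
    n_singletons: int
    mean_species_per_fe: float
    max_species_per_fe: int

    @property
    def singleton_share(self) -> float:
        return self.n_singletons / self.n_fes


def summarize_redundancy(fes: Sequence[FunctionalEntity]) -> RedundancySummary:
    if not fes:
        raise ValidationError("cannot summarize an empty FE list")
    sizes = [fe.n_species for fe in fes]
    return RedundancySummary(
        n_species=sum(sizes),
        n_fes=len(fes),
        n_singletons=sum(1 for s in sizes if s == 1),
        mean_species_per_fe=sum(sizes) / len(fes),
        max_species_per_fe=max(sizes),
    )


def species_to_fe(fes: Sequence[FunctionalEntity]) -> dict[str, str]:
    """Species name -> fe_id lookup."""
    out: dict[str, str] = {}
    for fe in fes:
        for sp in fe.members:
            out[sp] = fe.fe_id
    return out


def impacted_fe_ids(
    records: Iterable[MortalityRecord], fes: Sequence[FunctionalEntity]
) -> set[str]:
    """FE ids with at least one member species present in the records.

    A single impacted member marks the whole FE as vulnerable: redundancy
    within an FE is no protection if any of its species suffered mortality.
    """
    lookup = species_to_fe(fes)
    impacted: set[str] = set()
    unknown: set[str] = set()
    for rec in records:
        fe_id = lookup.get(rec.species)
        if fe_id is None:
            unknown.add(rec.species)
        else:
            impacted.add(fe_id)
    if unknown:
        raise ValidationError(f"record species absent from trait table: {sorted(unknown)}")
    return impacted
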