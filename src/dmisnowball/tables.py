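"""Tabular domain types and delimited-text I/O.

Two tables drive the pipeline:

* a **fertility table** — one row per (plant, trait) measurement from the
  allelism experiment (pollen fertility as a proportion in [0, 1], seed
  fertility as seeds/fruit >= 0), with the plant's genotype class and
  maternal family;
* a **QTL inventory** — one row per sterility QTL per interspecific cross,
  with its effect size Δ% (percent change vs the fertile SL parent, <= 0
  for sterility loci), dominance D in [−1, 0], and co-localization links
  between the two crosses.

Files are comma- or tab-delimited UTF-8 text with a header row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

GENOTYPES = ("SL", "IL_HH", "IL_PP", "IL_HP", "IL_PH")
TRAITS = ("pollen", "seed")
CROSSES = ("SHxSL", "SPxSL")

#: terminal branch carrying lineage-specific mutations of each cross
CROSS_TERMINAL_BRANCH = {"SHxSL": "c", "SPxSL": "d"}


class TableError(ValueError):
    """Row-addressed validation failure in a delimited input table."""


@dataclass(frozen=True)
class FertilityMeasurement:
    plant_id: str
    genotype: str
    maternal_family: str
    trait: str
    value: float

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise TableError(f"unknown genotype {self.genotype!r}")
        if self.trait not in TRAITS:
            raise TableError(f"unknown trait {self.trait!r}")
        if self.trait == "pollen" and not (0.0 <= self.value <= 1.0):
            raise TableError(
                f"pollen fertility must be a proportion in [0,1], got {self.value}"
            )
        if self.trait == "seed" and self.value < 0:
            raise TableError(f"seed fertility must be >= 0, got {self.value}")


@dataclass(frozen=True)
class QTLRecord:
    """One sterility QTL detected in one interspecific cross."""

    qtl_id: str
    cross: str
    trait: str
    chromosome: int
    delta_pct: float
    dominance_D: Optional[float] = None
    colocal_partner: Optional[str] = None
    pollen_confounded: bool = False

    def __post_init__(self) -> None:
        if self.cross not in CROSSES:
            raise TableError(f"unknown cross {self.cross!r}")
        if self.trait not in TRAITS:
            raise TableError(f"unknown trait {self.trait!r}")
        if not 1 <= int(self.chromosome) <= 12:
            raise TableError(f"chromosome must be 1..12, got {self.chromosome}")
        if self.delta_pct > 0:
            raise TableError(
                f"delta_pct must be <= 0 for sterility loci, got {self.delta_pct}"
            )
        if self.dominance_D is not None and not -1.0 <= self.dominance_D <= 0.0:
            raise TableError(f"dominance_D must lie in [-1, 0], got {self.dominance_D}")


@dataclass(frozen=True)
class RunConfig:
    """Reproducibility knobs shared across the randomized operations."""

    seed: int = 0
    n_boot: int = 500
    n_binom_iter: int = 1000
    mc_reps: int = 20000
    small_p_mode: bool = True

    def __post_init__(self) -> None:
        for name in ("n_boot", "n_binom_iter", "mc_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")


FERTILITY_COLUMNS = ["plant_id", "genotype", "maternal_family", "trait", "value"]


def read_fertility_table(path) -> list[FertilityMeasurement]:
    """Read and validate a fertility table; errors name the offending row."""
    df = _read_delimited(path)
    missing = set(FERTILITY_COLUMNS) - set(df.columns)
    if missing:
        raise TableError(f"fertility table missing columns: {sorted(missing)}")
    records: list[FertilityMeasurement] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        try:
            rec = FertilityMeasurement(
                plant_id=str(row["plant_id"]),
                genotype=str(row["genotype"]),
                maternal_family=str(row["maternal_family"]),
                trait=str(row["trait"]),
                value=float(row["value"]),
            )
        except (TableError, ValueError) as exc:
            raise TableError(f"row {idx + 2}: {exc}") from exc
        key = (rec.plant_id, rec.trait)
        if key in seen:
            raise TableError(f"row {idx + 2}: duplicate (plant, trait) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_fertility_table(records: Iterable[FertilityMeasurement], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def fertility_frame(records: Iterable[FertilityMeasurement]) -> pd.DataFrame:
    """Tidy DataFrame view of fertility measurements."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


INVENTORY_COLUMNS = [
    "qtl_id",
    "cross",
    "trait",
    "chromosome",
    "delta_pct",
    "dominance_D",
    "colocal_partner",
    "pollen_confounded",
]


def read_inventory(path) -> list[QTLRecord]:
    """Read a per-cross QTL inventory; checks colocal_partner symmetry."""
    df = _read_delimited(path)
    missing = set(INVENTORY_COLUMNS) - set(df.columns)
    if missing:
        raise TableError(f"inventory missing columns: {sorted(missing)}")
    records: list[QTLRecord] = []
    for idx, row in df.iterrows():
        dom = row["dominance_D"]
        partner = row["colocal_partner"]
        try:
            rec = QTLRecord(
                qtl_id=str(row["qtl_id"]),
                cross=str(row["cross"]),
                trait=str(row["trait"]),
                chromosome=int(row["chromosome"]),
                delta_pct=float(row["delta_pct"]),
                dominance_D=None if pd.isna(dom) or dom == "" else float(dom),
                colocal_partner=None if pd.isna(partner) or partner == "" else str(partner),
                pollen_confounded=str(row["pollen_confounded"]).strip().lower()
                in ("true", "1", "yes"),
            )
        except (TableError, ValueError) as exc:
            raise TableError(f"row {idx + 2}: {exc}") from exc
        records.append(rec)
    validate_colocal_symmetry(records)
    return records


def validate_colocal_symmetry(records: list[QTLRecord]) -> None:
    by_id = {r.qtl_id: r for r in records}
    if len(by_id) != len(records):
        raise TableError("duplicate qtl_id in inventory")
    for rec in records:
        if rec.colocal_partner is None:
            continue
        partner = by_id.get(rec.colocal_partner)
        if partner is None:
            raise TableError(
                f"{rec.qtl_id}: colocal_partner {rec.colocal_partner!r} not in inventory"
            )
        if partner.colocal_partner != rec.qtl_id:
            raise TableError(
                f"colocal_partner not symmetric between {rec.qtl_id} and {partner.qtl_id}"
            )
        if partner.cross == rec.cross:
            raise TableError(
                f"{rec.qtl_id}: colocal partner must come from the other cross"
            )


def write_inventory(records: Iterable[QTLRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)
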