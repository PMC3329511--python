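"""Species-level trait tables.

The unit of analysis is a mammalian genus represented by a single species,
described by adult brain mass, adult female body mass, gestation length,
postnatal time to weaning, and two dichotomised life-history covariates:
limb biomechanics (whether the hindlimb can assume a plantigrade standing
position) and dietary profile (carnivore / omnivore / herbivore).

Derived variables follow the conventions of broad-scale allometry: all
continuous variables are log10-transformed, and time to weaning is carried
both postnatally and post conception (gestation + postnatal weaning age),
the latter being the developmentally more meaningful clock.  Dummy codes:
``lb_code`` = 1 for non-plantigrade species, ``dp_code`` = 1 for
non-carnivorous (omnivorous or herbivorous) species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AggregationError, EmptyTableError, SchemaError, ValidationError

RAW_COLUMNS = [
    "species",
    "order",
    "brain_mass_g",
    "body_mass_g",
    "gestation_d",
    "wean_postnatal_d",
    "limb",
    "diet",
]

NUMERIC_COLUMNS = ["brain_mass_g", "body_mass_g", "gestation_d", "wean_postnatal_d"]

LIMB_CATEGORIES = ("plantigrade", "non_plantigrade")
DIET_CATEGORIES = ("carnivore", "omnivore", "herbivore")

#: diets pooled as "non-carnivore" for the dietary-profile dummy
NON_CARNIVORE_DIETS = ("omnivore", "herbivore")

DERIVED_COLUMNS = [
    "wean_pc_d",
    "log_brain",
    "log_body",
    "log_wean_pc",
    "log_wean_pn",
    "lb_code",
    "dp_code",
]


@dataclass(frozen=True)
class SpeciesRecord:
    """Raw per-species trait values (masses in grams, times in days)."""

    species: str
    order: str
    brain_mass_g: float
    body_mass_g: float
    gestation_d: float
    wean_postnatal_d: float
    limb: str
    diet: str

    def __post_init__(self) -> None:
        for field in ("brain_mass_g", "body_mass_g", "gestation_d", "wean_postnatal_d"):
            value = getattr(self, field)
            if not (value > 0) or not math.isfinite(value):
                raise ValidationError(
                    f"species {self.species!r}: {field} must be positive and finite, got {value!r}"
                )
        if self.limb not in LIMB_CATEGORIES:
            raise ValidationError(
                f"species {self.species!r}: limb must be one of {LIMB_CATEGORIES}, got {self.limb!r}"
            )
        if self.diet not in DIET_CATEGORIES:
            raise ValidationError(
                f"species {self.species!r}: diet must be one of {DIET_CATEGORIES}, got {self.diet!r}"
            )


@dataclass(frozen=True)
class DerivedRecord(SpeciesRecord):
    """Species record with post-conception weaning, log10 variables and dummy codes."""

    wean_pc_d: float = float("nan")
    log_brain: float = float("nan")
    log_body: float = float("nan")
    log_wean_pc: float = float("nan")
    log_wean_pn: float = float("nan")
    lb_code: int = 0
    dp_code: int = 0


def derive_variables(record: SpeciesRecord) -> DerivedRecord:
    """Populate post-conception weaning time, log10 transforms and dummy codes.

    Deterministic and idempotent in the raw fields: the derived values are
    pure functions of the raw ones.
    """
    wean_pc = record.gestation_d + record.wean_postnatal_d
    return DerivedRecord(
        species=record.species,
        order=record.order,
        brain_mass_g=record.brain_mass_g,
        body_mass_g=record.body_mass_g,
        gestation_d=record.gestation_d,
        wean_postnatal_d=record.wean_postnatal_d,
        limb=record.limb,
        diet=record.diet,
        wean_pc_d=wean_pc,
        log_brain=math.log10(record.brain_mass_g),
        log_body=math.log10(record.body_mass_g),
        log_wean_pc=math.log10(wean_pc),
        log_wean_pn=math.log10(record.wean_postnatal_d),
        lb_code=int(record.limb == "non_plantigrade"),
        dp_code=int(record.diet in NON_CARNIVORE_DIETS),
    )


def _derive_frame(raw: pd.DataFrame) -> pd.DataFrame:
    df = raw.copy()
    df["wean_pc_d"] = df["gestation_d"] + df["wean_postnatal_d"]
    df["log_brain"] = np.log10(df["brain_mass_g"])
    df["log_body"] = np.log10(df["body_mass_g"])
    df["log_wean_pc"] = np.log10(df["wean_pc_d"])
    df["log_wean_pn"] = np.log10(df["wean_postnatal_d"])
    df["lb_code"] = (df["limb"] == "non_plantigrade").astype(int)
    df["dp_code"] = df["diet"].isin(NON_CARNIVORE_DIETS).astype(int)
    return df


class TraitTable:
    """An ordered, validated collection of species trait records.

    Internally a :class:`pandas.DataFrame` with the eight raw columns plus
    the derived columns; row order is preserved from the source.
    """

    def __init__(self, raw: pd.DataFrame, provenance: str = "memory"):
        missing = [c for c in RAW_COLUMNS if c not in raw.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if len(raw) == 0:
            raise EmptyTableError(f"trait table {provenance!r} has no data rows")
        raw = raw.loc[:, RAW_COLUMNS].reset_index(drop=True)
        for col in NUMERIC_COLUMNS:
            values = pd.to_numeric(raw[col], errors="coerce")
            bad = raw.loc[values.isna() | ~(values > 0) | ~np.isfinite(values), "species"]
            if len(bad):
                raise ValidationError(
                    f"column {col!r} must be positive and finite; offending species: "
                    + ", ".join(map(str, bad.tolist()))
                )
            raw[col] = values.astype(float)
        bad_limb = raw.loc[~raw["limb"].isin(LIMB_CATEGORIES), "species"]
        if len(bad_limb):
            raise ValidationError(
                "limb category must be plantigrade/non_plantigrade; offending species: "
                + ", ".join(map(str, bad_limb.tolist()))
            )
        bad_diet = raw.loc[~raw["diet"].isin(DIET_CATEGORIES), "species"]
        if len(bad_diet):
            raise ValidationError(
                "diet category must be carnivore/omnivore/herbivore; offending species: "
                + ", ".join(map(str, bad_diet.tolist()))
            )
        dup = raw["species"][raw["species"].duplicated()]
        if len(dup):
            raise ValidationError("duplicate species names: " + ", ".join(map(str, dup.unique())))
        self._df = _derive_frame(raw)
        self.provenance = provenance

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def species(self) -> list[str]:
        return self._df["species"].tolist()

    @property
    def records(self) -> list[DerivedRecord]:
        return [
            derive_variables(SpeciesRecord(**{c: row[c] for c in RAW_COLUMNS}))
            for _, row in self._df.iterrows()
        ]

    def to_frame(self) -> pd.DataFrame:
        """Raw + derived columns as a DataFrame (copy)."""
        return self._df.copy()

    def column(self, name: str) -> np.ndarray:
        if name not in self._df.columns:
            raise SchemaError(f"unknown trait-table column {name!r}")
        return self._df[name].to_numpy()

    def subset(self, mask) -> "TraitTable":
        sub = self._df.loc[np.asarray(mask), RAW_COLUMNS]
        return TraitTable(sub, provenance=self.provenance)

    def drop_species(self, name: str) -> "TraitTable":
        if name not in set(self._df["species"]):
            raise ValidationError(f"species {name!r} not present in table")
        keep = self._df["species"] != name
        return self.subset(keep.to_numpy())

    def category_counts(self) -> dict[str, int]:
        """Counts of each limb and diet category (useful for sample audits)."""
        out: dict[str, int] = {}
        for cat in LIMB_CATEGORIES:
            out[cat] = int((self._df["limb"] == cat).sum())
        for cat in DIET_CATEGORIES:
            out[cat] = int((self._df["diet"] == cat).sum())
        return out

    def write(self, path, sep: str = ",") -> None:
        self._df.loc[:, RAW_COLUMNS].to_csv(path, sep=sep, index=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        return self._df.loc[:, RAW_COLUMNS].equals(other._df.loc[:, RAW_COLUMNS])

    def __repr__(self) -> str:
        return f"TraitTable(n={self.n}, provenance={self.provenance!r})"


def read_trait_table(path, dialect: str | None = None) -> TraitTable:
    """Read a delimited trait table (comma or tab, auto-detected by default).

    The header must name the eight raw columns of :data:`RAW_COLUMNS`.
    """
    try:
        if dialect is None:
            with open(path) as fh:
                header = fh.readline()
            dialect = "\t" if header.count("\t") > header.count(",") else ","
        raw = pd.read_csv(path, sep=dialect, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise EmptyTableError(f"trait table {path!r} is empty") from exc
    return TraitTable(raw, provenance=str(path))


def aggregate_to_genus(
    table: TraitTable,
    genus_of: Mapping[str, str],
    log_scale_means: bool = False,
) -> TraitTable:
    """Collapse congeneric species to one record per genus.

    Continuous variables are averaged on the raw scale by default (logs are
    then recomputed); set ``log_scale_means=True`` to average the log10
    values instead.  Categorical fields must agree across congeners.
    """
    df = table.to_frame()
    unmapped = [s for s in df["species"] if s not in genus_of]
    if unmapped:
        raise ValidationError("species without genus mapping: " + ", ".join(unmapped))
    df = df.assign(_genus=[genus_of[s] for s in df["species"]])

    rows = []
    seen: set[str] = set()
    for genus in df["_genus"]:
        if genus in seen:
            continue
        seen.add(genus)
        members = df[df["_genus"] == genus]
        if len(members) == 1:
            rows.append(members.iloc[0].loc[RAW_COLUMNS])
            continue
        for cat_col in ("limb", "diet"):
            if members[cat_col].nunique() != 1:
                raise AggregationError(
                    f"genus {genus!r}: conflicting {cat_col} categories "
                    f"{sorted(members[cat_col].unique())}"
                )
        merged = members.iloc[0].loc[RAW_COLUMNS].copy()
        merged["species"] = genus
        for col in NUMERIC_COLUMNS:
            if log_scale_means:
                merged[col] = 10 ** float(np.mean(np.log10(members[col])))
            else:
                merged[col] = float(members[col].mean())
        rows.append(merged)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return TraitTable(out, provenance=table.provenance)
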