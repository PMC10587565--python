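"""Readers, writers, and validation for the tabular formats used throughout.

Conventions
-----------
* Geochemistry and incubation tables are comma-separated, UTF-8, ``.`` decimal.
* ASV count and taxonomy tables are tab-separated (the common amplicon-pipeline
  export format): counts have ASVs as rows and samples as columns; in memory
  they are oriented samples x ASVs.
* Depth is in centimeters below seafloor (cmbsf), positive downward, at the
  midpoint of each sediment section.
* Missing values are empty cells and stay missing (NaN); they are never
  silently converted to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["core_id", "depth_cmbsf", "ch4_mM", "so4_mM", "h2s_uM", "porosity"]
PROFILE_OPTIONAL = ["toc_pct", "c_to_n", "d13c_org_permil"]
INCUBATION_COLUMNS = [
    "vial_id",
    "treatment_bes_mM",
    "day",
    "ch4_ppm",
    "co2_ppm",
    "d13ch4_permil",
]
TAXONOMY_RANKS = ["domain", "phylum", "class", "order", "family", "genus"]


class ValidationError(ValueError):
    """A table violates one of the documented schema invariants."""


@dataclass
class DepthProfile:
    """Per-core table of depth-indexed porewater geochemistry.

    ``data`` holds one row per sediment section with at least the columns in
    :data:`PROFILE_COLUMNS`. Depth must increase strictly within each core,
    concentrations must be non-negative, and porosity must lie in (0, 1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = validate_profile(self.data)

    @property
    def core_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["core_id"]))

    def core(self, core_id: str) -> pd.DataFrame:
        """Rows of a single core, sorted by depth."""
        sub = self.data[self.data["core_id"] == core_id]
        if sub.empty:
            raise KeyError(f"no core {core_id!r} in profile")
        return sub.reset_index(drop=True)


@dataclass
class IncubationSeries:
    """Headspace gas and isotope time series for one incubation vial."""

    vial_id: str
    treatment_bes_mM: float
    day: np.ndarray
    ch4_ppm: np.ndarray
    co2_ppm: np.ndarray
    d13ch4_permil: np.ndarray

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.ch4_ppm = np.asarray(self.ch4_ppm, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        self.d13ch4_permil = np.asarray(self.d13ch4_permil, dtype=float)
        if np.any(np.diff(self.day) < 0):
            raise ValidationError(f"vial {self.vial_id}: days must be non-decreasing")
        if np.any(self.day < 0):
            raise ValidationError(f"vial {self.vial_id}: negative day")
        for name in ("ch4_ppm", "co2_ppm"):
            vals = getattr(self, name)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValidationError(f"vial {self.vial_id}: negative {name}")

    def __len__(self) -> int:
        return len(self.day)


@dataclass
class ASVTable:
    """Integer amplicon counts, oriented samples x ASVs, with optional
    per-sample metadata (core_id, depth_cmbsf)."""

    counts: pd.DataFrame
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any() or c.columns.duplicated().any():
            raise ValidationError("duplicate sample or ASV labels in count table")
        arr = c.to_numpy()
        if np.any(arr < 0):
            raise ValidationError("negative ASV count")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("fractional ASV count")
        self.counts = c.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class TaxonomyTable:
    """Rank assignments (domain .. genus) per ASV; missing ranks are NaN."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in TAXONOMY_RANKS if r not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy table missing rank columns: {missing}")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate asv_id in taxonomy table")

    def rank(self, rank: str) -> pd.Series:
        if rank not in TAXONOMY_RANKS:
            raise ValidationError(f"unknown rank {rank!r}; valid: {TAXONOMY_RANKS}")
        return self.data[rank]


@dataclass
class GuildDefinition:
    """Mapping from guild name to a list of (rank, taxon) matchers.

    A guild claims every ASV whose taxonomy matches ANY of its matchers
    (exact string match at that rank). Guilds include the methane-cycling
    archaea (methanogens/ANME) and sulfate reducers by default.
    """

    guilds: Mapping[str, Sequence[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.guilds)
        if len(set(names)) != len(names):
            raise ValidationError("duplicate guild names")
        for name, matchers in self.guilds.items():
            for rank, _taxon in matchers:
                if rank not in TAXONOMY_RANKS:
                    raise ValidationError(
                        f"guild {name!r}: matcher rank {rank!r} is not one of {TAXONOMY_RANKS}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GuildDefinition":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls({g: [(m["rank"], m["taxon"]) for m in ms] for g, ms in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            g: [{"rank": r, "taxon": t} for r, t in ms] for g, ms in self.guilds.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# Default guild file: methane-cycling archaeal orders and the major
# sulfate-reducer groups reported from organic-rich coastal sediment.
DEFAULT_GUILDS = GuildDefinition(
    {
        "methanogens_anme": [
            ("order", "ANME-1"),
            ("order", "ANME-1b"),
            ("order", "Methanosarciniales"),
            ("order", "Methanosarcinales"),
            ("order", "Methanomicrobiales"),
            ("order", "Methanofastidiosales"),
            ("order", "Methanomassiliicoccales"),
            ("order", "Methanocellales"),
        ],
        "sulfate_reducers": [
            ("genus", "Desulfatiglans"),
            ("genus", "SEEP-SRB1"),
            ("genus", "Sva0081 sediment group"),
            ("class", "Desulfobacteria"),
        ],
    }
)


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------


def validate_profile(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a depth-profile table and return it with numeric dtypes.

    Raises :class:`ValidationError` naming the offending column/row for:
    missing mandatory columns, non-numeric cells, non-increasing or duplicate
    depths within a core, negative concentrations, porosity outside (0, 1).
    """
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"profile missing mandatory columns: {missing}")
    df = df.copy()
    numeric = [c for c in PROFILE_COLUMNS + PROFILE_OPTIONAL if c in df.columns]
    numeric.remove("core_id")
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col]).astype(float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric value in column {col!r}: {exc}") from exc
    for core_id, sub in df.groupby("core_id", sort=False):
        depths = sub["depth_cmbsf"].to_numpy()
        diffs = np.diff(depths)
        if np.any(diffs <= 0):
            bad = depths[1:][diffs <= 0][0]
            raise ValidationError(
                f"core {core_id!r}: depth must be strictly increasing; "
                f"violation at depth {bad:g} cmbsf"
            )
    for col in ("ch4_mM", "so4_mM", "h2s_uM"):
        vals = df[col]
        if (vals.dropna() < 0).any():
            row = df.index[vals < 0][0]
            raise ValidationError(f"negative {col} at row {row}")
    por = df["porosity"].dropna()
    if ((por <= 0) | (por >= 1)).any():
        raise ValidationError("porosity must lie strictly in (0, 1)")
    return df


def read_profile(path: str | Path) -> DepthProfile:
    """Read a depth-profile CSV (schema: core_id,depth_cmbsf,ch4_mM,so4_mM,
    h2s_uM,porosity[,toc_pct,c_to_n,d13c_org_permil])."""
    df = pd.read_csv(path, float_precision="round_trip")
    return DepthProfile(df)


def write_profile(profile: DepthProfile, path: str | Path) -> None:
    # %.17g guarantees bit-exact float round-trips through the CSV
    profile.data.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# incubations
# ---------------------------------------------------------------------------


def read_incubations(path: str | Path) -> list[IncubationSeries]:
    """Read an incubation CSV (one row per vial x timepoint) into per-vial
    series. The BES treatment must be constant within each vial."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in INCUBATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"incubation table missing columns: {missing}")
    out = []
    for vial_id, sub in df.groupby("vial_id", sort=False):
        doses = sub["treatment_bes_mM"].unique()
        if len(doses) != 1:
            raise ValidationError(
                f"vial {vial_id!r}: treatment must be constant, got {sorted(doses)}"
            )
        sub = sub.sort_values("day")
        out.append(
            IncubationSeries(
                vial_id=str(vial_id),
                treatment_bes_mM=float(doses[0]),
                day=sub["day"].to_numpy(float),
                ch4_ppm=sub["ch4_ppm"].to_numpy(float),
                co2_ppm=sub["co2_ppm"].to_numpy(float),
                d13ch4_permil=sub["d13ch4_permil"].to_numpy(float),
            )
        )
    return out


def write_incubations(series: Iterable[IncubationSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "vial_id": s.vial_id,
                    "treatment_bes_mM": s.treatment_bes_mM,
                    "day": s.day,
                    "ch4_ppm": s.ch4_ppm,
                    "co2_ppm": s.co2_ppm,
                    "d13ch4_permil": s.d13ch4_permil,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# ASV / taxonomy tables
# ---------------------------------------------------------------------------


def read_asv_table(
    counts_path: str | Path, taxonomy_path: str | Path
) -> tuple[ASVTable, TaxonomyTable]:
    """Read a TSV count table (rows = ASVs, columns = samples) and a TSV
    taxonomy table, align them, and orient counts samples x ASVs.

    ASVs present in the counts but absent from the taxonomy get an all-missing
    taxonomy row with a logged warning.
    """
    counts_raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts_raw.index.name = None
    table = ASVTable(counts_raw.T)

    tax_raw = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    tax_raw.index.name = None
    tax_raw = tax_raw.reindex(columns=TAXONOMY_RANKS)
    missing = [a for a in table.asv_ids if a not in tax_raw.index]
    if missing:
        logger.warning(
            "%d ASVs absent from taxonomy table; assigning all-missing ranks "
            "(first few: %s)",
            len(missing),
            missing[:5],
        )
    tax = TaxonomyTable(tax_raw.reindex(table.asv_ids))
    return table, tax


def write_asv_table(
    table: ASVTable, taxonomy: TaxonomyTable, counts_path: str | Path, taxonomy_path: str | Path
) -> None:
    out = table.counts.T.copy()
    out.index.name = "asv_id"
    out.to_csv(counts_path, sep="\t")
    tax = taxonomy.data.copy()
    tax.index.name = "asv_id"
    tax.to_csv(taxonomy_path, sep="\t")
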