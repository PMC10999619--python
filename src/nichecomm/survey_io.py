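"""Data model and I/O for quadrat vegetation surveys.

The atomic datum is one species observation in one 1 m x 1 m quadrat:
site, transect, degradation stage, quadrat, species, mean height,
fractional cover and abundance (individuals or clumps).  Surveys follow
a space-for-time design with three degradation stages (S1 healthy swamp
wetland, S2 slightly degraded wet meadow, S3 degraded dry meadow).

Also ships a transcription of the published species-by-stage table
(importance value, Levins niche width and stable-group ID for 46
species) used throughout as a verification fixture.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

STAGES = ("S1", "S2", "S3")

ABSENT = "—"  # em dash: species absent from a stage in the fixture table

_FIXTURE_NAME = "published_species_table.csv"
_FIXTURE_SHA256 = "4cfa419787e1a9b806c94bdafc0a5852f53befbf7518ae7d4f8af6b1f700d792"

_SURVEY_COLUMNS = (
    "site",
    "transect",
    "stage",
    "quadrat",
    "species",
    "height",
    "cover",
    "abundance",
)


class SurveyError(ValueError):
    """Base class for survey input problems."""


class SchemaError(SurveyError):
    """The input file is missing required columns."""


class ValidationError(SurveyError):
    """A row violates a field invariant; the message names the row."""


class FixtureIntegrityError(RuntimeError):
    """The packaged species table does not match its recorded checksum."""


def canonicalize_species(name: str) -> str:
    """Canonicalize a Latin binomial: collapse whitespace, capitalize the
    genus, lower-case the remaining tokens.  Infraspecific rank markers
    ("subsp.", "var.") and their epithets are retained."""
    tokens = re.sub(r"\s+", " ", name.strip()).split(" ")
    if not tokens or not tokens[0]:
        raise ValidationError("empty species name")
    return " ".join([tokens[0].capitalize()] + [t.lower() for t in tokens[1:]])


@dataclass(frozen=True)
class QuadratRecord:
    """One species observation in one quadrat.

    ``cover`` is a fraction in [0, 1]; ``height`` is positive in whatever
    length unit the survey declares (only relative heights are used
    downstream); ``abundance`` counts individuals or clumps.
    """

    site_id: str
    transect_id: str
    stage: str
    quadrat_id: str
    species: str
    height: float
    cover: float
    abundance: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not 0.0 <= self.cover <= 1.0:
            raise ValidationError(f"cover {self.cover} outside [0, 1] for {self.species!r}")
        if self.height <= 0:
            raise ValidationError(f"non-positive height {self.height} for {self.species!r}")
        if self.abundance < 0:
            raise ValidationError(f"negative abundance {self.abundance} for {self.species!r}")


def read_survey_records(
    path: str | Path,
    cover_unit: Literal["auto", "fraction", "percent"] = "auto",
) -> list[QuadratRecord]:
    """Read a survey CSV into validated :class:`QuadratRecord` objects.

    The CSV must carry the header ``site,transect,stage,quadrat,species,
    height,cover,abundance``.  With ``cover_unit="auto"`` a ``#
    cover_unit: percent`` comment line, or any cover value above 1,
    switches percent-to-fraction conversion on.  Duplicate (stage,
    quadrat, species) keys are rejected.
    """
    path = Path(path)
    declared_unit = None
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
        if head.startswith("#"):
            m = re.search(r"cover_unit\s*:\s*(\w+)", head)
            if m:
                declared_unit = m.group(1).lower()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    unit = cover_unit
    if unit == "auto":
        if declared_unit in ("percent", "fraction"):
            unit = declared_unit
        elif (df["cover"] > 1.0).any():
            unit = "percent"
        else:
            unit = "fraction"
    if unit == "percent":
        bad = df.index[(df["cover"] < 0) | (df["cover"] > 100)]
        if len(bad):
            raise ValidationError(f"row {bad[0] + 2}: percent cover outside [0, 100]")
        df = df.assign(cover=df["cover"] / 100.0)

    records: list[QuadratRecord] = []
    seen: dict[tuple, int] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based plus header line
        try:
            rec = QuadratRecord(
                site_id=str(row["site"]),
                transect_id=str(row["transect"]),
                stage=str(row["stage"]),
                quadrat_id=str(row["quadrat"]),
                species=canonicalize_species(str(row["species"])),
                height=float(row["height"]),
                cover=float(row["cover"]),
                abundance=int(row["abundance"]),
            )
        except ValidationError as err:
            raise ValidationError(f"row {rowno}: {err}") from None
        key = (rec.stage, rec.quadrat_id, rec.species)
        if key in seen:
            raise ValidationError(
                f"row {rowno}: duplicate (stage, quadrat, species) key {key} "
                f"first seen at row {seen[key]}"
            )
        seen[key] = rowno
        records.append(rec)
    return records


def write_survey_records(records: Iterable[QuadratRecord], path: str | Path) -> None:
    """Write records to CSV (cover as fraction); inverse of
    :func:`read_survey_records` on canonicalized records."""
    df = pd.DataFrame(
        [
            {
                "site": r.site_id,
                "transect": r.transect_id,
                "stage": r.stage,
                "quadrat": r.quadrat_id,
                "species": r.species,
                "height": r.height,
                "cover": r.cover,
                "abundance": r.abundance,
            }
            for r in records
        ],
        columns=list(_SURVEY_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Published species-by-stage table (verification fixture)
# ---------------------------------------------------------------------------


@dataclass
class SpeciesStageTable:
    """Species x stage table of importance values, Levins niche widths
    and stable-module group IDs (a-e), one row per species.

    ``data`` columns: species_no, species, then iv/b/grp per stage
    (NaN / None where the species is absent from a stage).
    """

    data: pd.DataFrame

    def present(self, species: str, stage: str) -> bool:
        return not np.isnan(self._cell(species, stage, "b"))

    def iv(self, species: str, stage: str) -> float:
        return self._cell(species, stage, "iv")

    def width(self, species: str, stage: str) -> float:
        return self._cell(species, stage, "b")

    def group(self, species: str, stage: str) -> str | None:
        row = self._row(species)
        val = row[f"grp_{stage.lower()}"]
        return None if val is None or (isinstance(val, float) and np.isnan(val)) else val

    def species_names(self) -> list[str]:
        return list(self.data["species"])

    def species_present(self, stage: str) -> set[str]:
        col = f"b_{stage.lower()}"
        return set(self.data.loc[self.data[col].notna(), "species"])

    def species_number(self, species: str) -> int:
        return int(self._row(species)["species_no"])

    def stage_partition(self, stage: str) -> dict[str, str]:
        """Module assignment implied by the group-ID column for one stage.

        Species carrying a stable-group letter share that letter as their
        module; species present but unassigned ("N/A") are placed in
        per-species singleton modules, since the table says nothing about
        which module they occupy.
        """
        part: dict[str, str] = {}
        for _, row in self.data.iterrows():
            if pd.isna(row[f"b_{stage.lower()}"]):
                continue
            grp = row[f"grp_{stage.lower()}"]
            if grp is None or pd.isna(grp) or grp == "N/A":
                part[row["species"]] = f"_{row['species_no']}"
            else:
                part[row["species"]] = str(grp)
        return part

    def _row(self, species: str) -> pd.Series:
        hit = self.data[self.data["species"] == species]
        if hit.empty:
            raise KeyError(f"species {species!r} not in table")
        return hit.iloc[0]

    def _cell(self, species: str, stage: str, what: str) -> float:
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        val = self._row(species)[f"{what}_{stage.lower()}"]
        return float(val) if pd.notna(val) else float("nan")


def load_species_table_fixture() -> SpeciesStageTable:
    """Load the packaged 46-species table, verifying its checksum."""
    ref = resources.files("nichecomm").joinpath(f"data/{_FIXTURE_NAME}")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"{_FIXTURE_NAME}: checksum {digest} != expected {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), dtype=str, keep_default_na=False)
    out = pd.DataFrame({"species_no": df["species_no"].astype(int), "species": df["species"]})
    for st in ("s1", "s2", "s3"):
        for col in (f"iv_{st}", f"b_{st}"):
            out[col] = pd.to_numeric(df[col].replace(ABSENT, None), errors="coerce")
        out[f"grp_{st}"] = df[f"grp_{st}"].replace(ABSENT, None)
    nos = sorted(out["species_no"])
    if len(out) != 46 or nos != list(range(1, 47)):
        raise FixtureIntegrityError("species table must have species_no 1..46")
    return SpeciesStageTable(out)


@dataclass(frozen=True)
class TaxonCounts:
    n_species: int
    n_genera: int


def count_taxa(table: SpeciesStageTable) -> TaxonCounts:
    """Distinct species and distinct genera (first token of the binomial)."""
    names = {canonicalize_species(s) for s in table.species_names()}
    if not names:
        raise SurveyError("empty species table")
    genera = {n.split(" ")[0] for n in names}
    return TaxonCounts(n_species=len(names), n_genera=len(genera))


# ---------------------------------------------------------------------------
# Community (utilization) matrices
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Species x resource-state utilization for one degradation stage.

    Resource states are sampling units (quadrats, or transects pooling
    their quadrats); ``values`` are raw utilization measures and
    ``profiles`` the row-normalized proportions p_ij feeding the niche
    breadth and overlap indices.
    """

    stage: str
    species: list[str]
    states: list[str]
    values: np.ndarray  # (n_species, n_states), non-negative

    @property
    def r(self) -> int:
        return len(self.states)

    @property
    def profiles(self) -> np.ndarray:
        sums = self.values.sum(axis=1, keepdims=True)
        return self.values / sums

    def profile(self, species: str) -> np.ndarray:
        return self.profiles[self.species.index(species)]


def _iv_component(sub: pd.DataFrame) -> pd.Series:
    """Within-quadrat importance component: mean of relative height,
    relative cover and relative abundance among co-occurring species."""
    rel = sub[["height", "cover", "abundance"]].div(
        sub[["height", "cover", "abundance"]].sum(axis=0), axis=1
    )
    return rel.fillna(0.0).mean(axis=1)


def community_matrix(
    records: Sequence[QuadratRecord],
    stage: str,
    state_def: Literal["quadrat", "transect"] = "quadrat",
    measure: Literal["abundance", "iv_component"] = "abundance",
) -> CommunityMatrix:
    """Build the species x state utilization matrix for one stage.

    States are the stage's quadrats (default) or its transects (summing
    over their quadrats).  Species absent from every state are dropped;
    rows are kept unnormalized in ``values`` and normalized on demand.
    """
    rows = [r for r in records if r.stage == stage]
    if not rows:
        raise SurveyError(f"no records at stage {stage!r}")
    df = pd.DataFrame(
        {
            "state": [r.quadrat_id if state_def == "quadrat" else r.transect_id for r in rows],
            "quadrat": [r.quadrat_id for r in rows],
            "species": [r.species for r in rows],
            "height": [r.height for r in rows],
            "cover": [r.cover for r in rows],
            "abundance": [r.abundance for r in rows],
        }
    )
    if measure == "abundance":
        df["value"] = df["abundance"].astype(float)
    elif measure == "iv_component":
        df["value"] = df.groupby("quadrat", group_keys=False).apply(
            _iv_component, include_groups=False
        )
    else:
        raise ValueError(f"unknown measure {measure!r}")

    wide = (
        df.pivot_table(index="species", columns="state", values="value", aggfunc="sum")
        .fillna(0.0)
        .sort_index()
    )
    wide = wide.reindex(sorted(wide.columns), axis=1)
    if wide.shape[1] < 2:
        raise SurveyError(
            f"stage {stage!r} has {wide.shape[1]} resource state(s); "
            "niche breadth needs at least 2"
        )
    keep = wide.sum(axis=1) > 0
    wide = wide.loc[keep]
    return CommunityMatrix(
        stage=stage,
        species=list(wide.index),
        states=[str(c) for c in wide.columns],
        values=wide.to_numpy(dtype=float),
    )
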