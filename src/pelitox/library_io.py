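"""Validated containers and text readers for the reporter library and plate data.

The interchange formats are small delimited text tables:

* plate export (long form, canonical): CSV ``well,time_min,channel,value``
  with channels ``OD600`` and ``GFP``; a wide dialect (one column per time
  point) is accepted by the reader only.
* plate map: CSV ``well,role,orf,compound,concentration_mg_L,replicate``.
* biomarker library: TSV ``orf,gene,category,go_terms`` with ``go_terms``
  semicolon-joined. Lines starting with ``#`` are comments.

Well identifiers follow the 384-well convention (e.g. ``P01-A01``) but are
treated as opaque strings throughout. Times are minutes, concentrations mg/L.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATEGORIES = ("general", "chemical", "DNA", "oxidative", "protein")
ROLES = ("reporter", "internal_control", "blank_control", "vehicle_control")
CHANNELS = ("OD600", "GFP")
#: gene name of the housekeeping internal-control reporter
HOUSEKEEPING = "PGK1"

_CATEGORY_BY_LOWER = {c.lower(): c for c in CATEGORIES}

LAYOUT_COLUMNS = ["well", "role", "orf", "compound", "concentration_mg_L", "replicate"]


class ValidationError(ValueError):
    """Raised when an input table violates the documented contracts."""


@dataclasses.dataclass(frozen=True)
class BiomarkerEntry:
    orf_id: str
    gene_name: str
    category: str
    ontology_terms: frozenset[str]


class BiomarkerLibrary:
    """The reporter library: ORFs, one stress category each, ontology terms.

    The study library has 74 entries spanning the five stress categories
    (general, chemical, DNA, oxidative, protein); the size is not enforced
    so user-supplied libraries of any size work.
    """

    def __init__(self, entries: Iterable[BiomarkerEntry]):
        entries = list(entries)
        seen: set[str] = set()
        for e in entries:
            if e.orf_id in seen:
                raise ValidationError(f"duplicate orf_id {e.orf_id!r} in library")
            seen.add(e.orf_id)
            if e.category not in CATEGORIES:
                raise ValidationError(
                    f"unknown category {e.category!r} for {e.orf_id}; "
                    f"allowed: {', '.join(CATEGORIES)}"
                )
        if not entries:
            raise ValidationError("library is empty")
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def orfs(self) -> list[str]:
        return [e.orf_id for e in self.entries]

    @property
    def categories(self) -> dict[str, str]:
        """orf_id -> category."""
        return {e.orf_id: e.category for e in self.entries}

    def members(self, category: str) -> set[str]:
        category = normalize_category(category)
        return {e.orf_id for e in self.entries if e.category == category}

    def term_map(self) -> dict[str, set[str]]:
        """ontology term -> set of annotated ORFs."""
        out: dict[str, set[str]] = {}
        for e in self.entries:
            for t in e.ontology_terms:
                out.setdefault(t, set()).add(e.orf_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orf": [e.orf_id for e in self.entries],
                "gene": [e.gene_name for e in self.entries],
                "category": [e.category for e in self.entries],
                "go_terms": [";".join(sorted(e.ontology_terms)) for e in self.entries],
            }
        )


def normalize_category(label: str) -> str:
    """Map a category label to the canonical vocabulary, case-insensitively."""
    key = str(label).strip().lower()
    if key not in _CATEGORY_BY_LOWER:
        raise ValidationError(
            f"unknown category {label!r}; allowed values: {', '.join(CATEGORIES)}"
        )
    return _CATEGORY_BY_LOWER[key]


def read_library(path: str | Path) -> BiomarkerLibrary:
    """Read a TSV biomarker-library table (columns orf, gene, category, go_terms)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = {"orf", "gene", "category", "go_terms"} - set(df.columns)
    if missing:
        raise ValidationError(f"library table missing columns: {sorted(missing)}")
    entries = [
        BiomarkerEntry(
            orf_id=row.orf,
            gene_name=row.gene,
            category=normalize_category(row.category),
            ontology_terms=frozenset(t for t in row.go_terms.split(";") if t),
        )
        for row in df.itertuples()
    ]
    return BiomarkerLibrary(entries)


def write_library(library: BiomarkerLibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


def load_default_library() -> BiomarkerLibrary:
    """The bundled 74-reporter fixture library.

    Gene names are plausible yeast stress reporters; systematic ORF ids are
    synthetic placeholders. Replace via :func:`read_library` for real assays.
    """
    ref = resources.files("pelitox").joinpath("data/biomarkers_74_synthetic.tsv")
    with resources.as_file(ref) as p:
        return read_library(p)


class PlateLayout:
    """Maps wells to roles, reporter ORFs, compound, concentration, replicate.

    Roles: ``reporter`` (library strain under treatment), ``internal_control``
    (housekeeping PGK1 strain), ``blank_control`` (no yeast; carries material
    optical background only), ``vehicle_control`` (library strain in vehicle,
    compound empty, concentration 0).
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        missing = set(LAYOUT_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"plate map missing columns: {sorted(missing)}")
        df["well"] = df["well"].astype(str)
        df["role"] = df["role"].astype(str)
        df["orf"] = df["orf"].fillna("").astype(str)
        df["compound"] = df["compound"].fillna("").astype(str)
        df["concentration_mg_L"] = pd.to_numeric(df["concentration_mg_L"]).fillna(0.0)
        df["replicate"] = pd.to_numeric(df["replicate"]).fillna(1).astype(int)
        if df["well"].duplicated().any():
            dups = df.loc[df["well"].duplicated(), "well"].tolist()
            raise ValidationError(f"duplicate wells in plate map: {dups[:5]}")
        bad_roles = sorted(set(df["role"]) - set(ROLES))
        if bad_roles:
            raise ValidationError(f"unknown roles {bad_roles}; allowed: {ROLES}")
        if (df["concentration_mg_L"] < 0).any():
            raise ValidationError("negative concentrations in plate map")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be positive")
        blank_with_yeast = df[(df["role"] == "blank_control") & (df["orf"] != "")]
        if len(blank_with_yeast):
            raise ValidationError(
                f"blank_control wells must have empty orf: {blank_with_yeast['well'].tolist()[:5]}"
            )
        for role in ("reporter", "vehicle_control", "internal_control"):
            sub = df[(df["role"] == role) & (df["orf"] == "")]
            if len(sub):
                raise ValidationError(
                    f"{role} wells must name an orf: {sub['well'].tolist()[:5]}"
                )
        vc = df[df["role"] == "vehicle_control"]
        if (vc["compound"] != "").any() or (vc["concentration_mg_L"] != 0).any():
            raise ValidationError("vehicle_control wells must have no compound and concentration 0")
        self.frame = df.reset_index(drop=True)

    @property
    def wells(self) -> list[str]:
        return self.frame["well"].tolist()

    def condition_keys(self) -> pd.Series:
        """Per-well (compound, concentration) key used to match blanks."""
        return pd.Series(
            list(zip(self.frame["compound"], self.frame["concentration_mg_L"])),
            index=self.frame["well"],
        )

    def validate_against_library(self, library: BiomarkerLibrary) -> None:
        known = set(library.orfs) | {HOUSEKEEPING}
        reporters = self.frame[self.frame["role"].isin(["reporter", "vehicle_control"])]
        unknown = sorted(set(reporters["orf"]) - known)
        if unknown:
            raise ValidationError(
                f"layout references ORFs absent from the library: {unknown[:10]}"
            )


def read_plate_map(path: str | Path) -> PlateLayout:
    df = pd.read_csv(path, dtype={"well": str, "role": str, "orf": str, "compound": str})
    return PlateLayout(df)


def write_plate_map(layout: PlateLayout, path: str | Path) -> None:
    layout.frame.to_csv(path, index=False, float_format="%.10g")


@dataclasses.dataclass
class PlateTimeSeries:
    """OD600 and GFP readings per well on a shared uniform time grid (minutes).

    Readings may be <= 0 (instrument noise); downstream code floors rather
    than assumes positivity.
    """

    time_min: np.ndarray
    od: pd.DataFrame  # wells x time
    gfp: pd.DataFrame  # wells x time
    layout: PlateLayout

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        if self.time_min.ndim != 1 or len(self.time_min) < 2:
            raise ValidationError("time grid must be 1-D with >= 2 points")
        steps = np.diff(self.time_min)
        if (steps <= 0).any():
            raise ValidationError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            bad = self.time_min[1:][~np.isclose(steps, steps[0], rtol=0, atol=1e-9)]
            raise ValidationError(f"nonuniform time grid at t = {bad.tolist()}")
        if self.od.shape != self.gfp.shape:
            raise ValidationError("od and gfp matrices differ in shape")
        if not (self.od.index.equals(self.gfp.index) and self.od.columns.equals(self.gfp.columns)):
            raise ValidationError("od and gfp must share wells and time grid")
        if len(self.od.columns) != len(self.time_min):
            raise ValidationError("matrix columns do not match the time grid")
        if not (np.isfinite(self.od.to_numpy()).all() and np.isfinite(self.gfp.to_numpy()).all()):
            raise ValidationError("non-finite readings in plate data")
        layout_wells = set(self.layout.wells)
        extra = sorted(set(self.od.index) - layout_wells)
        if extra:
            raise ValidationError(f"wells in data but absent from layout: {extra[:10]}")

    @property
    def wells(self) -> list[str]:
        return list(self.od.index)


def _pivot_channel(df: pd.DataFrame, channel: str) -> pd.DataFrame:
    sub = df[df["channel"] == channel]
    mat = sub.pivot(index="well", columns="time_min", values="value")
    if mat.isna().any().any():
        holes = [
            (w, t)
            for w, row in mat.iterrows()
            for t in mat.columns[row.isna()]
        ]
        raise ValidationError(f"missing {channel} readings at (well, time_min): {holes[:10]}")
    return mat.sort_index(axis=1)


def read_plate_export(
    path: str | Path, layout: PlateLayout, dialect: str = "long"
) -> PlateTimeSeries:
    """Read a plate-reader export (long form, or wide with one column per time).

    Every (well, time, channel) cell must be present; missing cells are an
    error, never an imputation.
    """
    df = pd.read_csv(path)
    if dialect == "wide":
        id_cols = ["well", "channel"]
        missing = set(id_cols) - set(df.columns)
        if missing:
            raise ValidationError(f"wide export missing columns: {sorted(missing)}")
        df = df.melt(id_vars=id_cols, var_name="time_min", value_name="value")
        df["time_min"] = pd.to_numeric(df["time_min"])
    elif dialect == "long":
        missing = {"well", "time_min", "channel", "value"} - set(df.columns)
        if missing:
            raise ValidationError(f"long export missing columns: {sorted(missing)}")
    else:
        raise ValidationError(f"unknown export dialect {dialect!r}")
    df["well"] = df["well"].astype(str)
    unknown = sorted(set(df["channel"]) - set(CHANNELS))
    if unknown:
        raise ValidationError(f"unknown channel labels {unknown}; expected {CHANNELS}")
    od = _pivot_channel(df, "OD600")
    gfp = _pivot_channel(df, "GFP")
    if not od.columns.equals(gfp.columns) or not od.index.sort_values().equals(
        gfp.index.sort_values()
    ):
        raise ValidationError("OD600 and GFP channels do not cover the same (well, time) cells")
    gfp = gfp.loc[od.index]
    time = od.columns.to_numpy(dtype=float)
    return PlateTimeSeries(time_min=time, od=od, gfp=gfp, layout=layout)


def write_plate_export(
    plate: PlateTimeSeries, path: str | Path, dialect: str = "long"
) -> None:
    """Write a plate export in the canonical long form (or the wide dialect)."""
    frames = []
    for channel, mat in (("OD600", plate.od), ("GFP", plate.gfp)):
        long = mat.reset_index(names="well").melt(
            id_vars="well", var_name="time_min", value_name="value"
        )
        long.insert(2, "channel", channel)
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["well", "time_min", "channel"], kind="mergesort")
    if dialect == "long":
        out.to_csv(path, index=False, float_format="%.12g")
    elif dialect == "wide":
        wide = out.pivot(index=["well", "channel"], columns="time_min", values="value")
        wide.reset_index().to_csv(path, index=False, float_format="%.12g")
    else:
        raise ValidationError(f"unknown export dialect {dialect!r}")
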