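"""Synthetic plate experiments emulating the reporter-library study design.

The generator emulates 74 reporters x 5 compounds x 6 concentrations
(32, 8, 2, 0.5, 0.125, 0.031 mg/L; four-fold steps) x 3 replicates with
blank, vehicle, and housekeeping (PGK1) controls, OD600/GFP read every
5 min over 2 h. Per-(compound, ORF) effects follow a Hill dose dependence,

    plateau(c) = max_ln_i * c^hill / (ec50^hill + c^hill),

and induction ramps linearly in time from 0 at t = 0 to plateau(c) at
t = T, so the time-averaged |ln I| is plateau/2 in closed form — the
analytic oracle for pipeline recovery tests. Growth is logistic; material
optical interference is modeled as concentration-proportional additive OD
and GFP backgrounds identical in blank wells, making blank subtraction
exactly sufficient. Noise is multiplicative mean-one lognormal at a stated
CV. All outputs are deterministic functions of (truth, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pelitox.library_io import (
    HOUSEKEEPING,
    BiomarkerLibrary,
    PlateLayout,
    PlateTimeSeries,
    write_library,
    write_plate_export,
    write_plate_map,
)

STUDY_CONCENTRATIONS = (0.031, 0.125, 0.5, 2.0, 8.0, 32.0)
STUDY_COMPOUNDS = (
    "GO-untreated",
    "GO-UV",
    "GO-thermal",
    "GO-45min-sonicated",
    "GO-2.5h-sonicated",
)
TIME_GRID = tuple(float(t) for t in range(0, 121, 5))  # minutes

#: reference-compound category 4PL parameters (A, B, C mg/L, D)
MMC_PARAMS = (1.0, 1.2, 0.5, 4.0)  # genotoxicity reference, DNA category
H2O2_PARAMS = (1.0, 1.5, 2.0, 3.5)  # oxidative reference


@dataclasses.dataclass
class OrfEffect:
    """Programmed response of one reporter to one compound."""

    max_ln_i: float
    ec50: float  # mg/L
    hill: float

    @property
    def responsive(self) -> bool:
        return self.max_ln_i != 0.0

    def plateau(self, concentration: float) -> float:
        c = float(concentration)
        if c <= 0 or not self.responsive:
            return 0.0
        ch = c**self.hill
        return self.max_ln_i * ch / (self.ec50**self.hill + ch)


@dataclasses.dataclass
class GrowthModel:
    od0: float = 0.1
    rate: float = 0.02  # per minute
    capacity: float = 1.2

    def od(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.capacity / (
            1.0 + (self.capacity / self.od0 - 1.0) * np.exp(-self.rate * t)
        )


@dataclasses.dataclass
class NoiseModel:
    cv: float = 0.05  # multiplicative CV on every reading
    # Material optical interference, kept below ~20% of the minimum cellular
    # signal at the top study concentration (32 mg/L): an assay whose blanks
    # swamped the reporter signal would not be interpretable at all.
    od_background_per_mg_L: float = 0.001  # material absorbance
    gfp_background_per_mg_L: float = 0.3  # material autofluorescence

    def od_background(self, concentration: float) -> float:
        return self.od_background_per_mg_L * float(concentration)

    def gfp_background(self, concentration: float) -> float:
        return self.gfp_background_per_mg_L * float(concentration)


@dataclasses.dataclass
class SyntheticTruth:
    """Full generator parameterization, recorded for recovery tests."""

    effects: dict  # compound -> orf -> OrfEffect
    growth: GrowthModel = dataclasses.field(default_factory=GrowthModel)
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    basal_gfp_per_od: float = 200.0
    seed: int = 1

    def effect(self, compound: str, orf: str) -> OrfEffect | None:
        return self.effects.get(compound, {}).get(orf)

    def plateau(self, compound: str, orf: str, concentration: float) -> float:
        eff = self.effect(compound, orf)
        return 0.0 if eff is None else eff.plateau(concentration)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "basal_gfp_per_od": self.basal_gfp_per_od,
            "growth": dataclasses.asdict(self.growth),
            "noise": dataclasses.asdict(self.noise),
            "effects": {
                comp: {orf: dataclasses.asdict(e) for orf, e in by_orf.items()}
                for comp, by_orf in self.effects.items()
            },
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            effects={
                comp: {orf: OrfEffect(**e) for orf, e in by_orf.items()}
                for comp, by_orf in doc["effects"].items()
            },
            growth=GrowthModel(**doc["growth"]),
            noise=NoiseModel(**doc["noise"]),
            basal_gfp_per_od=doc["basal_gfp_per_od"],
            seed=doc["seed"],
        )


#: per-compound generator settings emulating the study narrative: DNA stress
#: dominant everywhere; the long-sonicated (smallest) material most potent,
#: responding well below the lowest studied concentration.
_COMPOUND_PROFILES = {
    "GO-untreated": dict(potency=1.0, ec50_range=(0.3, 8.0)),
    "GO-UV": dict(potency=1.2, ec50_range=(0.2, 6.0)),
    "GO-thermal": dict(potency=1.0, ec50_range=(0.3, 8.0)),
    "GO-45min-sonicated": dict(potency=1.05, ec50_range=(0.25, 8.0)),
    "GO-2.5h-sonicated": dict(potency=1.8, ec50_range=(0.002, 0.02)),
}
_CATEGORY_RESPONSE_P = {
    "DNA": 0.8,
    "oxidative": 0.6,
    "chemical": 0.55,
    "general": 0.5,
    "protein": 0.45,
}


def default_truth(
    library: BiomarkerLibrary,
    seed: int = 1,
    compounds: tuple[str, ...] = STUDY_COMPOUNDS,
    cv: float = 0.05,
) -> SyntheticTruth:
    """Study-design truth: per-compound responsive ORF sets and Hill effects."""
    rng = np.random.default_rng(seed)
    effects: dict[str, dict[str, OrfEffect]] = {}
    for comp in compounds:
        prof = _COMPOUND_PROFILES.get(comp, dict(potency=1.0, ec50_range=(0.5, 12.0)))
        potency = prof["potency"]
        lo, hi = prof["ec50_range"]
        by_orf: dict[str, OrfEffect] = {}
        for entry in library:
            p_resp = min(0.95, _CATEGORY_RESPONSE_P[entry.category] * potency)
            if comp == "GO-2.5h-sonicated":
                p_resp = 0.9
            if rng.random() >= p_resp:
                continue
            magnitude = potency * rng.lognormal(mean=0.095, sigma=0.45)
            if rng.random() < 0.15:
                magnitude *= -0.6  # downregulated reporter
            ec50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            hill = float(rng.uniform(0.9, 2.0))
            by_orf[entry.orf_id] = OrfEffect(
                max_ln_i=float(magnitude), ec50=ec50, hill=hill
            )
        effects[comp] = by_orf
    return SyntheticTruth(effects=effects, noise=NoiseModel(cv=cv), seed=seed)


def null_truth(
    library: BiomarkerLibrary,
    seed: int = 1,
    compounds: tuple[str, ...] = STUDY_COMPOUNDS,
    cv: float = 0.05,
) -> SyntheticTruth:
    """No programmed effects anywhere: the null-calibration condition."""
    return SyntheticTruth(
        effects={comp: {} for comp in compounds},
        noise=NoiseModel(cv=cv),
        seed=seed,
    )


def _well_ids(n: int) -> list[str]:
    """Sequential 384-well ids, P01-A01 .. spilling onto further plates."""
    ids = []
    rows = "ABCDEFGHIJKLMNOP"
    for i in range(n):
        plate, pos = divmod(i, 384)
        ids.append(f"P{plate + 1:02d}-{rows[pos // 24]}{pos % 24 + 1:02d}")
    return ids


def simulate_plate(
    truth: SyntheticTruth,
    library: BiomarkerLibrary,
    compounds: tuple[str, ...] | None = None,
    concentrations: tuple[float, ...] = STUDY_CONCENTRATIONS,
    replicates: int = 3,
    time_min: tuple[float, ...] = TIME_GRID,
    seed: int | None = None,
) -> PlateTimeSeries:
    """Simulate the full plate experiment for the given design.

    Emits, per (compound, concentration) condition and per replicate, one
    reporter well per library ORF plus one housekeeping internal-control
    well and one blank well; the vehicle condition (no compound, 0 mg/L)
    gets the same complement with reporter wells in the vehicle_control role.
    """
    if compounds is None:
        compounds = tuple(sorted(truth.effects))
    if any(c <= 0 for c in concentrations):
        raise ValueError("design concentrations must be positive")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    t = np.asarray(time_min, dtype=float)
    T = t[-1] - t[0]

    conditions = [(comp, float(c)) for comp in compounds for c in concentrations]
    conditions.append(("", 0.0))

    rows = []  # layout rows
    plateaus = []  # per-well programmed ln I plateau at this concentration
    has_yeast = []
    concs = []
    for comp, c in conditions:
        role = "vehicle_control" if comp == "" else "reporter"
        for rep in range(1, replicates + 1):
            for entry in library:
                rows.append(("", role, entry.orf_id, comp, c, rep))
                plateaus.append(truth.plateau(comp, entry.orf_id, c))
                has_yeast.append(True)
                concs.append(c)
            rows.append(("", "internal_control", HOUSEKEEPING, comp, c, rep))
            plateaus.append(0.0)
            has_yeast.append(True)
            concs.append(c)
            rows.append(("", "blank_control", "", comp, c, rep))
            plateaus.append(0.0)
            has_yeast.append(False)
            concs.append(c)

    wells = _well_ids(len(rows))
    layout = PlateLayout(
        pd.DataFrame(
            [(w, *r[1:]) for w, r in zip(wells, rows)],
            columns=["well", "role", "orf", "compound", "concentration_mg_L", "replicate"],
        )
    )

    plateaus = np.asarray(plateaus)[:, None]
    yeast = np.asarray(has_yeast)[:, None].astype(float)
    concs = np.asarray(concs)[:, None]
    od_pure = truth.growth.od(t)[None, :]
    ln_i = plateaus * ((t - t[0]) / T)[None, :]

    od_clean = yeast * od_pure + truth.noise.od_background_per_mg_L * concs
    gfp_clean = (
        yeast * od_pure * truth.basal_gfp_per_od * np.exp(ln_i)
        + truth.noise.gfp_background_per_mg_L * concs
    )
    if truth.noise.cv > 0:
        sigma = np.sqrt(np.log1p(truth.noise.cv**2))
        shape = od_clean.shape
        od_clean = od_clean * np.exp(
            sigma * rng.standard_normal(shape) - sigma**2 / 2
        )
        gfp_clean = gfp_clean * np.exp(
            sigma * rng.standard_normal(shape) - sigma**2 / 2
        )
    od = pd.DataFrame(od_clean, index=wells, columns=t)
    gfp = pd.DataFrame(gfp_clean, index=wells, columns=t)
    return PlateTimeSeries(time_min=t, od=od, gfp=gfp, layout=layout)


def simulate_reference(
    compound: str = "MMC",
    params: tuple[float, float, float, float] | None = None,
    concentrations: tuple[float, ...] = STUDY_CONCENTRATIONS,
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Clean (or noisy) category-level concentration-PELI table for a
    reference standard (MMC-like genotoxicant or H2O2-like oxidant)."""
    if params is None:
        if compound.upper() == "MMC":
            params = MMC_PARAMS
        elif compound.upper() == "H2O2":
            params = H2O2_PARAMS
        else:
            raise ValueError(f"no default parameters for reference {compound!r}")
    a, b, c0, d = params
    x = np.asarray(concentrations, dtype=float)
    y = a + (d - a) / (1.0 + (c0 / x) ** b)
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(cv**2))
        y = y * np.exp(sigma * rng.standard_normal(len(y)) - sigma**2 / 2)
    return pd.DataFrame({"concentration_mg_L": x, "peli": y, "compound": compound})


def correlated_noise(x, r: float, rng: np.random.Generator) -> np.ndarray:
    """Draw y with population correlation ``r`` against the fixed vector x."""
    x = np.asarray(x, dtype=float)
    z = (x - x.mean()) / x.std()
    return r * z + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(len(x))


def _h2o2_standard_curve() -> pd.DataFrame:
    doses = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0])
    folds = 1.0 + 3.0 * doses / (doses + 5.0)  # saturating, strictly monotone
    return pd.DataFrame({"dose_mg_L": doses, "fold": folds})


def simulate_phenotypes(
    truth: SyntheticTruth,
    library: BiomarkerLibrary,
    concentrations: tuple[float, ...] = (8.0, 32.0),
    replicates: int = 3,
    comet_replicates: int = 4,
    cells_per_replicate: int = 25,
    time_min: tuple[float, ...] = TIME_GRID,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """ROS kinetics and comet per-cell tables tied to the molecular truth.

    ROS fold change is an affine function of the mean programmed oxidative
    plateau (fold = 1 + 2.5 * effect); comet % Tail DNA shifts with the mean
    DNA-category plateau at the top concentration. Returns the input tables
    the phenotype readers consume plus a ``truth`` table of programmed values.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed + 101)
    t = np.asarray(time_min, dtype=float)
    oxi = sorted(library.members("oxidative"))
    dna = sorted(library.members("DNA"))
    compounds = sorted(truth.effects)

    blank = 50.0 + 0.1 * t
    stained = blank + 100.0 + 2.0 * t
    ros_rows = []
    truth_rows = []
    for ts, label in ((blank, "blank_control"), (stained, "stained_control")):
        for tm, v in zip(t, ts):
            ros_rows.append(("", 0.0, label, 0, tm, v))
    sigma = np.sqrt(np.log1p(truth.noise.cv**2)) if truth.noise.cv > 0 else 0.0
    for comp in compounds:
        for c in concentrations:
            e_ox = float(np.mean([truth.plateau(comp, o, c) for o in oxi]))
            fold_true = 1.0 + 2.5 * e_ox
            chemical = blank + 0.5 * c  # compound autofluorescence, no yeast
            for tm, v in zip(t, chemical):
                ros_rows.append((comp, c, "chemical_control", 0, tm, v))
            for rep in range(1, replicates + 1):
                factor = (
                    np.exp(sigma * rng.standard_normal() - sigma**2 / 2)
                    if sigma > 0
                    else 1.0
                )
                treated = chemical + fold_true * factor * (stained - blank)
                for tm, v in zip(t, treated):
                    ros_rows.append((comp, c, "treated", rep, tm, v))
            truth_rows.append((comp, c, "ros_fold", fold_true))

    comet_rows = []
    base_mean, base_sd = 8.0, 4.0
    for rep in range(1, comet_replicates + 1):
        for cell, v in enumerate(
            rng.normal(base_mean, base_sd, cells_per_replicate), start=1
        ):
            comet_rows.append(("control", rep, cell, float(np.clip(v, 0, 100))))
    top = max(STUDY_CONCENTRATIONS)
    for comp in compounds:
        e_dna = float(np.mean([truth.plateau(comp, o, top) for o in dna]))
        shift = 30.0 * e_dna
        truth_rows.append((comp, top, "tail_shift", shift))
        for rep in range(1, comet_replicates + 1):
            for cell, v in enumerate(
                rng.normal(base_mean + shift, base_sd + 1.0, cells_per_replicate),
                start=1,
            ):
                comet_rows.append((comp, rep, cell, float(np.clip(v, 0, 100))))

    return {
        "ros": pd.DataFrame(
            ros_rows,
            columns=["compound", "concentration_mg_L", "role", "replicate",
                     "time_min", "fluorescence"],
        ),
        "comet": pd.DataFrame(
            comet_rows, columns=["compound", "replicate", "cell", "tail_pct"]
        ),
        "h2o2_standard": _h2o2_standard_curve(),
        "truth": pd.DataFrame(
            truth_rows, columns=["compound", "concentration_mg_L", "quantity", "value"]
        ),
    }


def write_dataset(
    truth: SyntheticTruth,
    library: BiomarkerLibrary,
    outdir: str | Path,
    **simulate_kwargs,
) -> dict[str, Path]:
    """Write a complete synthetic dataset in the CSV dialects the readers consume.

    Emits plate.csv, platemap.csv, library.tsv, reference tables, phenotype
    tables, and truth.json alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plate = simulate_plate(truth, library, **simulate_kwargs)
    paths = {
        "plate": outdir / "plate.csv",
        "plate_map": outdir / "platemap.csv",
        "library": outdir / "library.tsv",
        "reference_dna": outdir / "reference_mmc.csv",
        "reference_oxidative": outdir / "reference_h2o2.csv",
        "ros": outdir / "ros.csv",
        "comet": outdir / "comet.csv",
        "h2o2_standard": outdir / "h2o2_standard.csv",
        "truth": outdir / "truth.json",
    }
    write_plate_export(plate, paths["plate"])
    write_plate_map(plate.layout, paths["plate_map"])
    write_library(library, paths["library"])
    simulate_reference("MMC", seed=truth.seed).to_csv(
        paths["reference_dna"], index=False, float_format="%.12g"
    )
    simulate_reference("H2O2", seed=truth.seed).to_csv(
        paths["reference_oxidative"], index=False, float_format="%.12g"
    )
    pheno = simulate_phenotypes(truth, library)
    pheno["ros"].to_csv(paths["ros"], index=False, float_format="%.12g")
    pheno["comet"].to_csv(paths["comet"], index=False, float_format="%.12g")
    pheno["h2o2_standard"].to_csv(
        paths["h2o2_standard"], index=False, float_format="%.12g"
    )
    truth.to_json(paths["truth"])
    return paths
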