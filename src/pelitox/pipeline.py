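"""End-to-end orchestration: plates in, endpoint tables and reports out.

Stage order mirrors the assay workflow: induction normalization -> PELI
tables -> 4PL concentration-response with censored PELI1.5 and toxic
equivalents -> enrichment (category GSEA, ontology overrepresentation) ->
multivariate summaries (correlation-distance HCL, PCA) -> phenotypic
anchoring correlations. Every stochastic step draws from seeds derived
deterministically from the single root seed, so a run is bit-reproducible
from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

import pelitox
from pelitox import dose_response, enrichment, induction, multivariate, peli, phenotype
from pelitox.library_io import (
    BiomarkerLibrary,
    ValidationError,
    load_default_library,
    read_library,
    read_plate_export,
    read_plate_map,
)

CATEGORY_ORDER = ["chemical", "general", "DNA", "oxidative", "protein"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage and offending entity."""


class RunConfig(BaseModel):
    """Configuration of one analysis run (YAML-serializable)."""

    plate: Path
    plate_map: Path
    library: Optional[Path] = None  # default: bundled 74-reporter fixture
    term_map: Optional[Path] = None  # default: library's own annotations
    reference_dna: Optional[Path] = None  # MMC-like concentration-PELI table
    reference_oxidative: Optional[Path] = None  # H2O2-like table
    ros: Optional[Path] = None
    comet: Optional[Path] = None
    h2o2_standard: Optional[Path] = None
    out_dir: Path = Path("pelitox_run")

    peli_threshold: float = 1.5
    aggregation: str = "geometric"
    drift_correction: bool = True
    od_floor: float = induction.OD_FLOOR
    p_floor: float = induction.P_FLOOR
    conc_range: tuple[float, float] = dose_response.STUDY_RANGE
    n_perm: int = 1000
    gsea_weighting: str = "abs_dev"
    linkage: str = "average"
    bh_correction: bool = False
    seed: int

    @field_validator("peli_threshold")
    @classmethod
    def _threshold_gt_one(cls, v: float) -> float:
        if v <= 1:
            raise ValueError("peli_threshold must be > 1")
        return v

    def config_hash(self) -> str:
        doc = json.loads(self.model_dump_json())
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()


def _derived_seed(root: int, label: str) -> int:
    return (root * 100003 + zlib.crc32(label.encode())) % (2**31)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write tidy tables plus a JSON manifest.

    Returns the manifest dict. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest: dict = {
        "version": pelitox.__version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "config_hash": config.config_hash(),
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except (ValidationError, ValueError, KeyError, OSError) as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return deco

    @stage("load")
    def loaded():
        library = (
            read_library(config.library) if config.library else load_default_library()
        )
        layout = read_plate_map(config.plate_map)
        layout.validate_against_library(library)
        plate = read_plate_export(config.plate, layout)
        return library, plate

    library, plate = loaded

    @stage("induction")
    def ind():
        table = induction.induction_table(
            plate,
            drift_correction=config.drift_correction,
            od_floor=config.od_floor,
            p_floor=config.p_floor,
        )
        _write_csv(table, out / "ln_i.csv")
        return table

    outputs["ln_i"] = "ln_i.csv"

    @stage("peli")
    def pel():
        table = peli.peli_table(ind, library, method=config.aggregation)
        _write_csv(table, out / "peli.csv")
        mat = peli.profile_matrix(ind)
        mat.to_csv(out / "profile_matrix.csv", float_format="%.12g")
        return table, mat

    peli_frame, profile_mat = pel
    outputs["peli"] = "peli.csv"
    outputs["profile_matrix"] = "profile_matrix.csv"

    @stage("dose_response")
    def dr():
        fits: dict[tuple[str, str], dose_response.DoseResponseFit] = {}
        endpoints: dict[tuple[str, str], dose_response.Peli15Endpoint] = {}
        fit_rows, ep_rows = [], []
        sub = peli_frame[peli_frame["level"].isin(["category", "total"])]
        for (compound, key), grp in sub.groupby(["compound", "key"], sort=True):
            pts = grp.sort_values("concentration_mg_L")
            fit = dose_response.fit_4pl(
                pts["concentration_mg_L"].to_numpy(),
                pts["peli"].to_numpy(),
                seed=_derived_seed(config.seed, f"4pl|{compound}|{key}"),
                c_range=config.conc_range,
                compound=compound,
                key=key,
            )
            fits[(compound, key)] = fit
            fit_rows.append(
                (compound, key, fit.A, fit.B, fit.C, fit.D, fit.sse, fit.status)
            )
            try:
                ep = dose_response.peli15(
                    fit, c_range=config.conc_range, threshold=config.peli_threshold
                )
            except ValidationError:
                ep = None  # baseline above threshold: no valid endpoint
            endpoints[(compound, key)] = ep
            ep_rows.append(
                (
                    compound,
                    key,
                    ep.value if ep and ep.censor != "above_range" else "",
                    ep.censor if ep else "invalid",
                    ep.render() if ep else "invalid",
                )
            )
        _write_csv(
            pd.DataFrame(
                fit_rows,
                columns=["compound", "key", "A", "B", "C", "D", "sse", "status"],
            ),
            out / "fits.csv",
        )
        _write_csv(
            pd.DataFrame(
                ep_rows, columns=["compound", "key", "value_mg_L", "censor", "rendered"]
            ),
            out / "endpoints.csv",
        )
        return fits, endpoints

    fits, endpoints = dr
    outputs["fits"] = "fits.csv"
    outputs["endpoints"] = "endpoints.csv"

    @stage("teq")
    def teq():
        refs = {}
        if config.reference_dna:
            refs["DNA"] = pd.read_csv(config.reference_dna)
        if config.reference_oxidative:
            refs["oxidative"] = pd.read_csv(config.reference_oxidative)
        if not refs:
            return {}
        ref_fits = {
            cat: dose_response.fit_4pl(
                tbl["concentration_mg_L"].to_numpy(),
                tbl["peli"].to_numpy(),
                seed=_derived_seed(config.seed, f"ref|{cat}"),
                c_range=config.conc_range,
                key=cat,
            )
            for cat, tbl in refs.items()
        }
        rows = []
        results: dict[tuple[str, str], dose_response.ToxicEquivalentComponent] = {}
        compounds = sorted({c for c, _ in endpoints})
        for compound in compounds:
            total_ep = endpoints.get((compound, "total"))
            for cat, name in (("DNA", "geno-TEQ1.5"), ("oxidative", "oxi-TEQ1.5")):
                if cat not in ref_fits or total_ep is None:
                    continue
                comp_fit = fits.get((compound, cat))
                if comp_fit is None:
                    continue
                res = dose_response.compute_teq(
                    comp_fit, total_ep, ref_fits[cat],
                    reference_range=config.conc_range,
                )
                results[(compound, name)] = res
                rows.append(
                    (compound, name,
                     "" if res.value is None else res.value,
                     res.censor, res.render())
                )
        _write_csv(
            pd.DataFrame(
                rows, columns=["compound", "endpoint", "value_mg_L", "censor", "rendered"]
            ),
            out / "teq.csv",
        )
        return results

    teq_results = teq
    outputs["teq"] = "teq.csv"

    @stage("summary")
    def summary():
        compounds = sorted({c for c, _ in endpoints})
        rows = []
        for compound in compounds:
            row = {"compound": compound}
            for cat in CATEGORY_ORDER + ["total"]:
                ep = endpoints.get((compound, cat))
                row[cat] = ep.render() if ep else "N/A"
            for name in ("geno-TEQ1.5", "oxi-TEQ1.5"):
                res = teq_results.get((compound, name))
                row[name] = res.render() if res else ""
            rows.append(row)
        df = pd.DataFrame(rows)
        _write_csv(df, out / "summary_peli15.csv")
        return df

    summary_frame = summary
    outputs["summary"] = "summary_peli15.csv"

    @stage("enrichment")
    def enrich():
        gsea_rows = []
        conditions = (
            peli_frame[peli_frame["level"] == "orf"][
                ["compound", "concentration_mg_L"]
            ]
            .drop_duplicates()
            .sort_values(["compound", "concentration_mg_L"])
        )
        for compound, conc in conditions.itertuples(index=False):
            sub = peli_frame[
                (peli_frame["compound"] == compound)
                & (peli_frame["concentration_mg_L"] == conc)
                & (peli_frame["level"] == "orf")
            ]
            orf_pelis = dict(zip(sub["key"], sub["peli"]))
            for cat in CATEGORY_ORDER:
                members = library.members(cat) & set(orf_pelis)
                if len(members) < 2:
                    continue
                res = enrichment.gsea_category(
                    orf_pelis,
                    members,
                    n_perm=config.n_perm,
                    seed=_derived_seed(config.seed, f"gsea|{compound}|{conc:g}|{cat}"),
                    weighting=config.gsea_weighting,
                    set_id=cat,
                )
                gsea_rows.append(
                    (compound, conc, cat, res.statistic, res.p_value,
                     res.n_permutations, "*" if res.significant else "")
                )
        _write_csv(
            pd.DataFrame(
                gsea_rows,
                columns=["compound", "concentration_mg_L", "category", "es",
                         "p_value", "n_permutations", "flag"],
            ),
            out / "gsea.csv",
        )

        term_map = (
            enrichment.read_term_map(config.term_map) if config.term_map else None
        )
        noa_frames = []
        top = conditions["concentration_mg_L"].max()
        for compound in sorted(conditions["compound"].unique()):
            try:
                active = peli.activated_orfs(
                    peli_frame, compound, top, threshold=config.peli_threshold
                )
            except ValidationError:
                continue
            results = enrichment.ontology_enrichment(
                active, library, term_map=term_map,
                correction="bh" if config.bh_correction else None,
            )
            df = enrichment.results_frame(results)
            df.insert(0, "compound", compound)
            df.insert(1, "concentration_mg_L", top)
            noa_frames.append(df)
        noa = (
            pd.concat(noa_frames, ignore_index=True)
            if noa_frames
            else pd.DataFrame(
                columns=["compound", "concentration_mg_L", "set_id", "statistic",
                         "p_value", "n_permutations", "test_set_size",
                         "reference_size", "overlap", "significant", "flag"]
            )
        )
        _write_csv(noa, out / "ontology.csv")

    enrich
    outputs["gsea"] = "gsea.csv"
    outputs["ontology"] = "ontology.csv"

    @stage("multivariate")
    def multi():
        cond = multivariate.cluster(profile_mat, axis="columns", method=config.linkage)
        (out / "dendrogram_conditions.nwk").write_text(multivariate.to_newick(cond))
        bio = multivariate.cluster(profile_mat, axis="rows", method=config.linkage)
        (out / "dendrogram_biomarkers.nwk").write_text(multivariate.to_newick(bio))
        res = multivariate.pca(profile_mat)
        scores = res.scores.reset_index(names="condition").melt(
            id_vars="condition", var_name="component", value_name="score"
        )
        _write_csv(scores, out / "pca_scores.csv")
        _write_csv(
            pd.DataFrame(
                {
                    "component": [f"PC{i + 1}" for i in range(len(res.variance_fractions))],
                    "variance_fraction": res.variance_fractions,
                }
            ),
            out / "pca_variance.csv",
        )
        return res

    multi
    outputs["dendrogram_conditions"] = "dendrogram_conditions.nwk"
    outputs["dendrogram_biomarkers"] = "dendrogram_biomarkers.nwk"
    outputs["pca_scores"] = "pca_scores.csv"
    outputs["pca_variance"] = "pca_variance.csv"

    @stage("phenotype")
    def pheno():
        corr_rows = []
        if config.ros:
            ros = pd.read_csv(config.ros)
            folds = _ros_endpoints(ros, config)
            _write_csv(folds, out / "ros_endpoints.csv")
            outputs["ros_endpoints"] = "ros_endpoints.csv"
            for key, label in (("oxidative", "PELI_oxi"), ("total", "PELI_total")):
                lvl = "category" if key != "total" else "total"
                pel = peli_frame[
                    (peli_frame["level"] == lvl) & (peli_frame["key"] == key)
                ][["compound", "concentration_mg_L", "peli"]]
                j = folds.merge(pel, on=["compound", "concentration_mg_L"])
                if len(j) >= 3 and j["fold"].var() > 0 and j["peli"].var() > 0:
                    r, p = phenotype.correlate(j["fold"], j["peli"])
                    corr_rows.append((f"ROS_fold~{label}", r, p, len(j)))
        if config.comet:
            comet = pd.read_csv(config.comet)
            calls = _comet_endpoints(comet)
            _write_csv(calls, out / "comet_calls.csv")
            outputs["comet_calls"] = "comet_calls.csv"
            top = peli_frame["concentration_mg_L"].max()
            pel = peli_frame[
                (peli_frame["level"] == "category")
                & (peli_frame["key"] == "DNA")
                & (peli_frame["concentration_mg_L"] == top)
            ][["compound", "peli"]]
            j = calls.merge(pel, on="compound")
            if len(j) >= 3 and j["delta_tail_pct"].var() > 0 and j["peli"].var() > 0:
                r, p = phenotype.correlate(j["delta_tail_pct"], j["peli"])
                corr_rows.append(("TailDNA~PELI_geno", r, p, len(j)))
        _write_csv(
            pd.DataFrame(corr_rows, columns=["pair", "r", "p_value", "n"]),
            out / "correlations.csv",
        )

    pheno
    outputs["correlations"] = "correlations.csv"

    manifest["outputs"] = outputs
    manifest["n_conditions"] = int(
        peli_frame[["compound", "concentration_mg_L"]].drop_duplicates().shape[0]
    )
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def _ros_endpoints(ros: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-(compound, concentration) ROS fold changes and H2O2 equivalents."""
    ros = ros.assign(
        concentration_mg_L=ros["concentration_mg_L"].astype(float)
    )
    t_blank = ros[ros["role"] == "blank_control"].sort_values("time_min")
    t_stain = ros[ros["role"] == "stained_control"].sort_values("time_min")
    if not len(t_blank) or not len(t_stain):
        raise ValidationError("ROS table needs blank_control and stained_control rows")
    grid = t_blank["time_min"].to_numpy()
    blank = t_blank["fluorescence"].to_numpy()
    stained = t_stain["fluorescence"].to_numpy()
    curve = None
    if config.h2o2_standard:
        std = pd.read_csv(config.h2o2_standard)
        curve = list(zip(std["dose_mg_L"], std["fold"]))
    rows = []
    treated = ros[ros["role"] == "treated"]
    for (comp, conc), grp in treated.groupby(["compound", "concentration_mg_L"], sort=True):
        chem = ros[
            (ros["role"] == "chemical_control")
            & (ros["compound"] == comp)
            & (ros["concentration_mg_L"] == conc)
        ].sort_values("time_min")["fluorescence"].to_numpy()
        if not len(chem):
            raise ValidationError(f"no chemical_control for ({comp}, {conc} mg/L)")
        folds = [
            phenotype.ros_fold_change(
                grid,
                rep_grp.sort_values("time_min")["fluorescence"].to_numpy(),
                stained, chem, blank,
            )
            for _, rep_grp in grp.groupby("replicate")
        ]
        fold = float(np.mean(folds))
        if curve:
            eq = phenotype.h2o2_equivalent(fold, curve)
            rows.append((comp, conc, fold, eq.value, eq.censor))
        else:
            rows.append((comp, conc, fold, "", ""))
    return pd.DataFrame(
        rows,
        columns=["compound", "concentration_mg_L", "fold", "h2o2_equiv_mg_L", "censor"],
    )


def _comet_endpoints(comet: pd.DataFrame) -> pd.DataFrame:
    """Per-compound comet positivity calls against the pooled control cells."""
    ctrl = comet[comet["compound"] == "control"]["tail_pct"].to_numpy()
    if not len(ctrl):
        raise ValidationError("comet table needs rows with compound == 'control'")
    rows = []
    for comp, grp in comet[comet["compound"] != "control"].groupby("compound", sort=True):
        call = phenotype.comet_positivity(grp["tail_pct"].to_numpy(), ctrl)
        rows.append(
            (comp, call.mean_tail_pct,
             call.mean_tail_pct - call.control_mean_tail_pct,
             call.p_value, call.positive)
        )
    return pd.DataFrame(
        rows,
        columns=["compound", "mean_tail_pct", "delta_tail_pct", "p_value", "positive"],
    )
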