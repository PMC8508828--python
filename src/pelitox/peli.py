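"""The protein expression level index (PELI) and toxicity positivity calls.

PELI summarizes a reporter's time-integrated differential expression over
the 2 h exposure window:

    PELI_ORF = exp( (1/T) * integral_0^T |ln I(t)| dt )

so a no-effect trajectory (ln I = 0) gives PELI = 1, and the published
positivity threshold PELI > 1.5 corresponds to a ~50% average fold
alteration. Stress-category and library-total PELIs aggregate member ORFs
by geometric mean (equivalently, exp of the mean integrated |ln I|); an
arithmetic-mean alternative is selectable. The exact index formula is a
single strategy function (`peli_from_trajectory`) so an alternative
definition can be substituted without touching callers.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from pelitox.induction import InductionProfile
from pelitox.library_io import BiomarkerLibrary, ValidationError

#: PELI positivity threshold used identically at ORF, category and total level
PELI_THRESHOLD = 1.5


def peli_from_trajectory(time_min: np.ndarray, ln_i: np.ndarray) -> float:
    """PELI of one trajectory: exp of the time-averaged |ln I| (trapezoid)."""
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(ln_i, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValidationError("PELI needs at least 2 time points")
    if t.shape != y.shape:
        raise ValidationError("time grid and ln_i lengths differ")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValidationError("time grid must be increasing")
    return float(np.exp(np.trapezoid(np.abs(y), t) / span))


def peli_orf(profile: InductionProfile) -> float:
    return peli_from_trajectory(profile.time_min, profile.ln_i)


def peli_aggregate(
    orf_pelis: Mapping[str, float],
    members: Iterable[str],
    method: str = "geometric",
) -> float:
    """Category/total PELI over member ORFs (geometric mean by default)."""
    members = list(members)
    if not members:
        raise ValidationError("empty member set in PELI aggregation")
    missing = sorted(set(members) - set(orf_pelis))
    if missing:
        raise ValidationError(f"members without ORF-level PELI: {missing[:10]}")
    vals = np.array([orf_pelis[m] for m in members], dtype=float)
    if method == "geometric":
        return float(np.exp(np.mean(np.log(vals))))
    if method == "arithmetic":
        return float(np.mean(vals))
    raise ValidationError(f"unknown aggregation method {method!r}")


def classify_toxicity(peli: float, threshold: float = PELI_THRESHOLD) -> bool:
    """Positive toxicity call iff PELI strictly exceeds the threshold."""
    return bool(peli > threshold)


def peli_table(
    induction: pd.DataFrame,
    library: BiomarkerLibrary,
    method: str = "geometric",
) -> pd.DataFrame:
    """ORF-, category-, and total-level PELI per (compound, concentration).

    ``induction`` is the tidy table from :func:`pelitox.induction.induction_table`.
    Tidy output columns: ``compound, concentration_mg_L, level, key, peli``.
    """
    cat_by_orf = library.categories
    rows = []
    for (compound, conc), grp in induction.groupby(
        ["compound", "concentration_mg_L"], sort=True
    ):
        orf_pelis: dict[str, float] = {}
        for orf, sub in grp.groupby("orf", sort=True):
            sub = sub.sort_values("time_min")
            orf_pelis[orf] = peli_from_trajectory(
                sub["time_min"].to_numpy(), sub["ln_i"].to_numpy()
            )
        for orf in sorted(orf_pelis):
            rows.append((compound, conc, "orf", orf, orf_pelis[orf]))
        by_cat: dict[str, list[str]] = {}
        for orf in orf_pelis:
            cat = cat_by_orf.get(orf)
            if cat is not None:
                by_cat.setdefault(cat, []).append(orf)
        for cat in sorted(by_cat):
            rows.append(
                (compound, conc, "category", cat,
                 peli_aggregate(orf_pelis, by_cat[cat], method=method))
            )
        lib_members = [o for o in orf_pelis if o in cat_by_orf]
        if lib_members:
            rows.append(
                (compound, conc, "total", "total",
                 peli_aggregate(orf_pelis, lib_members, method=method))
            )
    return pd.DataFrame(
        rows, columns=["compound", "concentration_mg_L", "level", "key", "peli"]
    )


def activated_orfs(
    peli_frame: pd.DataFrame,
    compound: str,
    concentration: float,
    threshold: float = PELI_THRESHOLD,
) -> set[str]:
    """ORFs with PELI_ORF > threshold for one condition (the enrichment test set)."""
    sub = peli_frame[
        (peli_frame["compound"] == compound)
        & (peli_frame["concentration_mg_L"] == concentration)
        & (peli_frame["level"] == "orf")
    ]
    if not len(sub):
        raise ValidationError(
            f"no ORF-level PELI rows for ({compound!r}, {concentration} mg/L)"
        )
    return set(sub.loc[sub["peli"] > threshold, "key"])


def profile_matrix(induction: pd.DataFrame) -> pd.DataFrame:
    """Biomarker x condition matrix of time-averaged ln I (heatmap/HCL/PCA input).

    Columns are labelled ``compound@concentration``; values are the mean ln I
    over the exposure window (unclipped — clip only for display).
    """
    df = induction.copy()
    df["condition"] = [
        f"{c}@{g:g}" for c, g in zip(df["compound"], df["concentration_mg_L"])
    ]
    mat = df.pivot_table(
        index="orf", columns="condition", values="ln_i", aggfunc="mean"
    )
    if mat.isna().any().any():
        raise ValidationError("profile matrix has missing (orf, condition) cells")
    return mat
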