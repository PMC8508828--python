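"""Phenotypic endpoints (ROS fold change, comet % Tail DNA) and their
correlation with molecular PELI endpoints.

ROS: DCFDA fluorescence kinetics over the 2 h window are summarized by AUC;
fold change = (AUC(treated) - AUC(chemical control)) /
(AUC(stained control) - AUC(blank medium control)), and folds are mapped to
H2O2 equivalents by monotone inverse interpolation of a standard curve.

Genotoxicity: per-cell % Tail DNA; a treatment is positive when its mean
significantly exceeds the untreated control (one-sided Welch t-test,
p < 0.05).

Molecular-phenotypic anchoring uses the Pearson correlation with the
two-sided t-transform p-value on n - 2 degrees of freedom.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from pelitox.library_io import ValidationError


@dataclasses.dataclass
class EquivalentDose:
    """Interpolated reference dose (mg/L), censored when off the curve."""

    value: float
    censor: str  # "interval" | "below_range" | "above_range"


@dataclasses.dataclass
class CometCall:
    mean_tail_pct: float
    control_mean_tail_pct: float
    p_value: float
    positive: bool


def auc(time_min, values) -> float:
    t = np.asarray(time_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or len(t) < 2:
        raise ValidationError("AUC needs matched series with >= 2 points")
    return float(np.trapezoid(v, t))


def ros_fold_change(
    time_min,
    treated,
    stained_control,
    chemical_control=None,
    blank_control=None,
) -> float:
    """Background-corrected ROS production fold change over the exposure window.

    ``chemical_control`` (probe + compound, no yeast) corrects compound
    autofluorescence/quench; ``blank_control`` (probe only, no yeast) sets
    the stained-control baseline. Omitted controls default to zero signal.
    """
    t = np.asarray(time_min, dtype=float)
    zero = np.zeros_like(t)
    chemical_control = zero if chemical_control is None else chemical_control
    blank_control = zero if blank_control is None else blank_control
    denom = auc(t, stained_control) - auc(t, blank_control)
    if denom <= 0:
        raise ValidationError("stained-control AUC must exceed the blank AUC")
    return (auc(t, treated) - auc(t, chemical_control)) / denom


def h2o2_equivalent(fold: float, standard_curve) -> EquivalentDose:
    """Map a ROS fold change onto the H2O2 dose axis of a standard curve.

    ``standard_curve`` is a sequence of (dose mg/L, fold) pairs, strictly
    monotone in fold once sorted by dose. Folds outside the curve are
    reported as censored bounds at the corresponding end.
    """
    curve = sorted((float(d), float(f)) for d, f in standard_curve)
    if len(curve) < 3:
        raise ValidationError("standard curve needs >= 3 points")
    doses = np.array([d for d, _ in curve])
    folds = np.array([f for _, f in curve])
    diffs = np.diff(folds)
    if (diffs > 0).all():
        pass
    elif (diffs < 0).all():
        doses, folds = doses[::-1], folds[::-1]
    else:
        raise ValidationError("standard curve is not monotone in dose")
    if fold < folds[0]:
        return EquivalentDose(value=float(doses[0]), censor="below_range")
    if fold > folds[-1]:
        return EquivalentDose(value=float(doses[-1]), censor="above_range")
    return EquivalentDose(value=float(np.interp(fold, folds, doses)), censor="interval")


def comet_positivity(treatment_cells, control_cells, alpha: float = 0.05) -> CometCall:
    """Genotoxicity call from per-cell % Tail DNA (one-sided Welch t-test)."""
    treat = np.asarray(treatment_cells, dtype=float)
    ctrl = np.asarray(control_cells, dtype=float)
    if len(treat) < 2 or len(ctrl) < 2:
        raise ValidationError("comet test needs >= 2 cells per group")
    if treat.var(ddof=1) == 0 and ctrl.var(ddof=1) == 0:
        # degenerate: no within-group spread at all
        p = 0.0 if treat.mean() > ctrl.mean() else 1.0
    else:
        p = float(
            stats.ttest_ind(
                treat, ctrl, equal_var=False, alternative="greater"
            ).pvalue
        )
    return CometCall(
        mean_tail_pct=float(treat.mean()),
        control_mean_tail_pct=float(ctrl.mean()),
        p_value=p,
        positive=p < alpha,
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("correlate needs two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("correlation needs >= 3 paired points")
    if x.var() == 0 or y.var() == 0:
        raise ValidationError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
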