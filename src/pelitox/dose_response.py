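"""4PL concentration-response fitting, the censored PELI1.5 endpoint, and TEQs.

The increasing four-parameter logistic

    y(x) = A + (D - A) / (1 + (C / x)^B)

is fit by bounded least squares on log-concentration with deterministic
multi-start initialization (quantile-spaced midpoint guesses with seeded
jitter). A is the baseline PELI (>= 1), D the plateau, C the midpoint in
mg/L, B the slope.

PELI1.5 is the concentration where the fitted curve crosses the positivity
threshold 1.5, inverted analytically. It is censored against the studied
concentration range (0.031-32 mg/L in the study design): ``above_range``
("N/A") when the curve never reaches 1.5 within range, ``below_range``
("<c_min") when the response already exceeds 1.5 at the lowest studied
concentration.

Toxic equivalents (geno-TEQ1.5 vs mitomycin C, oxi-TEQ1.5 vs H2O2) evaluate
the sample's category-level 4PL at its total-level PELI1.5 concentration and
invert the reference compound's same-category 4PL at that response level.
Censored PELI1.5 endpoints propagate to censored TEQ bounds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from pelitox.library_io import ValidationError

#: study concentration range (mg/L) used for censoring
STUDY_RANGE = (0.031, 32.0)

# parameter bounds: A baseline, B slope, C midpoint (mg/L), D plateau
BOUNDS_A = (1.0, 3.0)
BOUNDS_B = (0.1, 10.0)
BOUNDS_D = (1.0, 50.0)
DEGENERATE_SPAN = 0.05


@dataclasses.dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with diagnostics."""

    A: float
    B: float
    C: float
    D: float
    sse: float
    status: str  # "fitted" | "degenerate"
    compound: str = ""
    key: str = ""

    def __call__(self, x) -> np.ndarray | float:
        return fourpl(x, self.A, self.B, self.C, self.D)


@dataclasses.dataclass
class Peli15Endpoint:
    """PELI1.5 in mg/L, or a censoring bound against the studied range."""

    value: float | None
    censor: str  # "interval" | "above_range" | "below_range"
    c_range: tuple[float, float] = STUDY_RANGE

    def render(self) -> str:
        if self.censor == "above_range":
            return "N/A"
        if self.censor == "below_range":
            return f"<{self.c_range[0]:g}"
        return f"{self.value:.2f}"


@dataclasses.dataclass
class ToxicEquivalentComponent:
    """TEQ in mg/L of the reference compound, possibly a censored bound."""

    value: float | None
    censor: str  # "interval" | "greater_than" | "less_than" | "not_available"

    def render(self) -> str:
        if self.censor == "not_available":
            return "N/A"
        prefix = {"greater_than": ">", "less_than": "<", "interval": ""}[self.censor]
        return f"{prefix}{self.value:.2f}"


def fourpl(x, a: float, b: float, c: float, d: float):
    x = np.asarray(x, dtype=float)
    out = a + (d - a) / (1.0 + (c / x) ** b)
    return float(out) if out.ndim == 0 else out


def fit_4pl(
    concentrations,
    pelis,
    n_starts: int = 8,
    seed: int = 0,
    c_range: tuple[float, float] = STUDY_RANGE,
    compound: str = "",
    key: str = "",
) -> DoseResponseFit:
    """Bounded least-squares 4PL fit with deterministic multistart.

    Requires >= 4 distinct positive concentrations and finite responses.
    Flat responses (plateau - baseline < 0.05) are flagged ``degenerate``.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(pelis, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("concentrations and responses differ in length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite inputs to 4PL fit")
    if (x <= 0).any():
        raise ValidationError("concentrations must be positive")
    if len(np.unique(x)) < 4:
        raise ValidationError("4PL fit needs >= 4 distinct concentrations")

    c_lo, c_hi = c_range[0] / 10.0, c_range[1] * 10.0
    lb = np.array([BOUNDS_A[0], BOUNDS_B[0], np.log(c_lo), BOUNDS_D[0]])
    ub = np.array([BOUNDS_A[1], BOUNDS_B[1], np.log(c_hi), BOUNDS_D[1]])

    def resid(theta):
        a, b, logc, d = theta
        return fourpl(x, a, b, np.exp(logc), d) - y

    a0 = float(np.clip(y.min(), *BOUNDS_A))
    d0 = float(np.clip(y.max(), *BOUNDS_D))
    rng = np.random.default_rng(seed)
    c_starts = np.geomspace(x.min(), x.max(), n_starts) * np.exp(
        rng.normal(0.0, 0.1, n_starts)
    )
    c_starts = np.clip(c_starts, c_lo * 1.001, c_hi * 0.999)

    best = None
    for c0 in c_starts:
        theta0 = np.clip([a0, 1.0, np.log(c0), d0], lb + 1e-12, ub - 1e-12)
        sol = least_squares(
            resid, theta0, bounds=(lb, ub), method="trf",
            ftol=1e-14, xtol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a, b, logc, d = best.x
    sse = float(2.0 * best.cost)
    status = "degenerate" if (d - a) < DEGENERATE_SPAN else "fitted"
    return DoseResponseFit(
        A=float(a), B=float(b), C=float(np.exp(logc)), D=float(d),
        sse=sse, status=status, compound=compound, key=key,
    )


def invert_4pl(fit: DoseResponseFit, y: float) -> float:
    """Concentration at which the fitted (increasing, B > 0) curve equals y."""
    if not (fit.A < y < fit.D):
        raise ValidationError(
            f"response {y} outside the invertible range ({fit.A}, {fit.D})"
        )
    return float(fit.C / ((fit.D - fit.A) / (y - fit.A) - 1.0) ** (1.0 / fit.B))


def peli15(
    fit: DoseResponseFit,
    c_range: tuple[float, float] = STUDY_RANGE,
    threshold: float = 1.5,
) -> Peli15Endpoint:
    """The censored PELI1.5 endpoint from a fitted (or degenerate) 4PL.

    The below-range check runs first: a saturated response (above the
    threshold at every studied concentration) fits with baseline A > 1.5,
    which is an identifiability artifact, not an invalid assay — the data
    say "already positive at c_min", rendered "<c_min".
    """
    c_min, c_max = c_range
    if fit(c_min) >= threshold:
        return Peli15Endpoint(value=c_min, censor="below_range", c_range=c_range)
    if fit.A >= threshold:
        # unreachable for increasing curves (y(c_min) > A); defensive guard
        raise ValidationError(
            f"invalid fit: baseline A={fit.A:.3f} at or above the threshold {threshold}"
        )
    if fit(c_max) <= threshold:
        return Peli15Endpoint(value=None, censor="above_range", c_range=c_range)
    return Peli15Endpoint(
        value=invert_4pl(fit, threshold), censor="interval", c_range=c_range
    )


def compute_teq(
    sample_category_fit: DoseResponseFit,
    total_endpoint: Peli15Endpoint,
    reference_fit: DoseResponseFit,
    reference_range: tuple[float, float] = STUDY_RANGE,
) -> ToxicEquivalentComponent:
    """Toxic equivalent of the sample at its PELI1.5 in reference-compound mg/L.

    The sample's category-level response p* is read off at its total-level
    PELI1.5 concentration; the reference compound's same-category 4PL is then
    inverted at p*. A ``below_range`` PELI1.5 yields a ">" lower bound
    (evaluated at c_min); p* outside the reference's response range yields a
    censored bound at the corresponding end of ``reference_range``.
    """
    if total_endpoint.censor == "above_range":
        return ToxicEquivalentComponent(value=None, censor="not_available")
    if reference_fit.status == "degenerate":
        raise ValidationError("reference fit is degenerate; TEQ undefined")
    c_eval = total_endpoint.value  # below_range endpoints carry value = c_min
    p_star = float(sample_category_fit(c_eval))
    lower_bound = total_endpoint.censor == "below_range"

    ref_lo = float(reference_fit(reference_range[0]))
    ref_hi = float(reference_fit(reference_range[1]))
    if p_star >= ref_hi:
        return ToxicEquivalentComponent(value=reference_range[1], censor="greater_than")
    if p_star <= ref_lo:
        return ToxicEquivalentComponent(value=reference_range[0], censor="less_than")
    value = invert_4pl(reference_fit, p_star)
    return ToxicEquivalentComponent(
        value=value, censor="greater_than" if lower_bound else "interval"
    )
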