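"""4PL fitting, analytic PELI1.5 inversion, censoring, and toxic equivalents."""

import numpy as np
import pytest

from pelitox.dose_response import (
    DoseResponseFit,
    compute_teq,
    fit_4pl,
    fourpl,
    invert_4pl,
    peli15,
)
from pelitox.library_io import ValidationError

CONCS = np.array([0.031, 0.125, 0.5, 2.0, 8.0, 32.0])


def _fit(a, b, c, d, **kw):
    return DoseResponseFit(A=a, B=b, C=c, D=d, sse=0.0, status="fitted", **kw)


def test_noise_free_parameters_recovered():
    y = fourpl(CONCS, 1.0, 1.0, 2.0, 3.0)
    fit = fit_4pl(CONCS, y)
    assert fit.status == "fitted"
    for got, true in zip((fit.A, fit.B, fit.C, fit.D), (1.0, 1.0, 2.0, 3.0)):
        assert got == pytest.approx(true, rel=1e-4)


def test_flat_response_is_degenerate():
    fit = fit_4pl(CONCS, np.ones_like(CONCS))
    assert fit.status == "degenerate"


def test_fit_input_contracts():
    with pytest.raises(ValidationError, match="4 distinct"):
        fit_4pl([1.0, 1.0, 2.0, 2.0], [1.0, 1.0, 2.0, 2.0])
    with pytest.raises(ValidationError, match="finite"):
        fit_4pl([1.0, 2.0, 4.0, 8.0], [1.0, np.nan, 2.0, 2.0])


def test_analytic_inversion_of_known_curve():
    ep = peli15(_fit(1.0, 1.0, 2.0, 3.0))
    assert ep.censor == "interval"
    assert ep.value == pytest.approx(2.0 / 3.0, abs=1e-12)


def test_plateau_below_threshold_censors_above_range():
    ep = peli15(_fit(1.0, 1.0, 2.0, 1.4))
    assert ep.censor == "above_range"
    assert ep.value is None
    assert ep.render() == "N/A"


def test_response_above_threshold_at_cmin_censors_below_range():
    ep = peli15(_fit(1.0, 1.0, 0.0005, 6.0))
    assert ep.censor == "below_range"
    assert ep.value == pytest.approx(0.031)
    assert ep.render() == "<0.031"


def test_saturated_baseline_above_threshold_censors_below_range():
    """A response above 1.5 at every studied concentration fits with
    baseline A > 1.5; that is the '<c_min' case, not an invalid assay."""
    ep = peli15(_fit(1.6, 1.0, 2.0, 3.0))
    assert ep.censor == "below_range"
    assert ep.render() == "<0.031"


@pytest.mark.parametrize(
    "params",
    [(1.0, 1.0, 2.0, 3.0), (1.0, 2.0, 0.8, 6.0), (1.1, 0.7, 5.0, 2.5)],
)
def test_fit_then_invert_round_trip_on_noise_free_data(params):
    """peli15(fit_4pl(samples from a 4PL with A < 1.5 < D)) recovers the
    analytic crossing concentration within 1e-6."""
    a, b, c, d = params
    y = fourpl(CONCS, a, b, c, d)
    fit = fit_4pl(CONCS, y)
    ep = peli15(fit)
    analytic = c / ((d - a) / (1.5 - a) - 1.0) ** (1.0 / b)
    assert ep.censor == "interval"
    assert ep.value == pytest.approx(analytic, abs=1e-6)


def test_fitted_curves_are_monotone_and_inversion_unique():
    y = fourpl(CONCS, 1.0, 2.0, 1.0, 4.0)
    fit = fit_4pl(CONCS, y)
    xs = np.geomspace(0.01, 100, 300)
    curve = fit(xs)
    assert (np.diff(curve) > 0).all()
    x_star = invert_4pl(fit, 2.0)
    assert fit(x_star) == pytest.approx(2.0, abs=1e-9)


def test_midpoint_recovery_under_multiplicative_noise():
    """Median recovered C over 50 noisy datasets within 15% of truth."""
    a, b, c, d = 1.0, 2.0, 0.8, 6.0
    clean = fourpl(CONCS, a, b, c, d)
    cs = []
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        noisy = clean * np.exp(0.03 * rng.standard_normal(len(CONCS)))
        cs.append(fit_4pl(CONCS, noisy, seed=seed).C)
    assert abs(np.median(cs) - c) / c < 0.15


class TestToxicEquivalents:
    reference = _fit(1.0, 1.0, 1.0, 3.0, key="DNA")

    def test_analytic_inversion_oracle(self):
        """Category PELI of 2.0 at the sample's PELI1.5 inverted through the
        reference (A=1, B=1, C=1, D=3) gives exactly 1.0 mg/L."""
        from pelitox.dose_response import Peli15Endpoint

        total = Peli15Endpoint(value=0.5, censor="interval")
        sample_cat = _fit(1.0, 1.0, 0.5, 3.0)  # f(0.5) = 2.0
        res = compute_teq(sample_cat, total, self.reference)
        assert res.censor == "interval"
        assert res.value == pytest.approx(1.0, abs=1e-9)

    def test_reference_self_equivalence(self):
        from pelitox.dose_response import Peli15Endpoint

        ep = peli15(self.reference)
        total = Peli15Endpoint(value=ep.value, censor="interval")
        res = compute_teq(self.reference, total, self.reference)
        assert res.value == pytest.approx(ep.value, abs=1e-9)

    def test_below_range_endpoint_propagates_to_greater_bound(self):
        from pelitox.dose_response import Peli15Endpoint

        total = Peli15Endpoint(value=0.031, censor="below_range")
        sample_cat = _fit(1.0, 1.0, 0.01, 3.0)  # strong response at c_min
        res = compute_teq(sample_cat, total, self.reference)
        assert res.censor == "greater_than"
        assert res.render().startswith(">")

    def test_target_above_reference_range_is_a_greater_bound(self):
        from pelitox.dose_response import Peli15Endpoint

        total = Peli15Endpoint(value=8.0, censor="interval")
        sample_cat = _fit(1.0, 1.0, 0.001, 10.0)  # response ~10 >> reference plateau
        res = compute_teq(sample_cat, total, self.reference)
        assert res.censor == "greater_than"

    def test_above_range_endpoint_gives_na(self):
        from pelitox.dose_response import Peli15Endpoint

        total = Peli15Endpoint(value=None, censor="above_range")
        res = compute_teq(_fit(1.0, 1.0, 1.0, 2.0), total, self.reference)
        assert res.censor == "not_available"
        assert res.render() == "N/A"


def test_censoring_states_are_mutually_exclusive():
    for params in [(1.0, 1.0, 2.0, 3.0), (1.0, 1.0, 2.0, 1.4), (1.0, 1.0, 0.0005, 6.0)]:
        ep = peli15(_fit(*params))
        states = [ep.censor == "interval", ep.censor == "above_range", ep.censor == "below_range"]
        assert sum(states) == 1
        assert (ep.value is None) == (ep.censor == "above_range")
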