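"""Generator determinism, closed-form oracles, and programmed-quantity recovery."""

import filecmp
import json

import numpy as np
import pytest

from pelitox.dose_response import fit_4pl, peli15
from pelitox.induction import induction_table
from pelitox.peli import peli_table
from pelitox.synthetic_data import (
    NoiseModel,
    OrfEffect,
    SyntheticTruth,
    correlated_noise,
    default_truth,
    null_truth,
    simulate_phenotypes,
    simulate_plate,
    simulate_reference,
    write_dataset,
)

STUDY = (0.031, 0.125, 0.5, 2.0, 8.0, 32.0)


def test_null_plate_yields_zero_ln_i_everywhere(small_library):
    truth = null_truth(small_library, cv=0.0)
    plate = simulate_plate(
        truth, small_library, concentrations=STUDY, replicates=3
    )
    table = induction_table(plate)
    assert np.abs(table.ln_i).max() < 1e-12


def test_single_responsive_orf_matches_closed_form_through_pipeline(small_library):
    """max_ln_i = 1 with a saturating dose and linear time ramp: the
    time-averaged |ln I| is plateau/2, so PELI = e^0.5 via the full path."""
    orf = small_library.orfs[0]
    truth = SyntheticTruth(
        effects={"X": {orf: OrfEffect(max_ln_i=1.0, ec50=1e-4, hill=1.0)}},
        noise=NoiseModel(cv=0.0),
        seed=9,
    )
    plate = simulate_plate(truth, small_library, concentrations=STUDY, replicates=3)
    frame = peli_table(induction_table(plate), small_library)
    got = frame[
        (frame.level == "orf") & (frame.key == orf) & (frame.concentration_mg_L == 32.0)
    ].peli.iloc[0]
    plateau = truth.plateau("X", orf, 32.0)
    assert got == pytest.approx(np.exp(plateau / 2.0), abs=1e-6)
    assert got == pytest.approx(np.exp(0.5), abs=1e-4)


def test_noise_free_pipeline_reproduces_every_programmed_peli(small_library):
    """Full-pipeline identity: every ORF's recovered PELI equals
    exp(plateau/2) up to quadrature error."""
    rng = np.random.default_rng(30)
    effects = {
        o: OrfEffect(
            max_ln_i=float(rng.uniform(-1.5, 1.5)),
            ec50=float(rng.uniform(0.1, 10.0)),
            hill=float(rng.uniform(0.9, 2.0)),
        )
        for o in small_library.orfs[:6]
    }
    truth = SyntheticTruth(effects={"X": effects}, noise=NoiseModel(cv=0.0), seed=12)
    plate = simulate_plate(truth, small_library, concentrations=STUDY, replicates=2)
    frame = peli_table(induction_table(plate), small_library)
    orf_rows = frame[frame.level == "orf"]
    for row in orf_rows.itertuples():
        plateau = truth.plateau("X", row.key, row.concentration_mg_L)
        assert row.peli == pytest.approx(np.exp(abs(plateau) / 2.0), abs=1e-6)


def test_seeded_dataset_export_is_byte_identical(tmp_path, small_library):
    truth = default_truth(small_library, seed=5, compounds=("GO-untreated", "GO-UV"))
    a = write_dataset(truth, small_library, tmp_path / "a", replicates=2)
    b = write_dataset(truth, small_library, tmp_path / "b", replicates=2)
    for key in a:
        assert filecmp.cmp(a[key], b[key], shallow=False), key


def test_truth_json_round_trip(tmp_path, small_library):
    truth = default_truth(small_library, seed=8)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = SyntheticTruth.from_json(path)
    assert back.seed == truth.seed
    assert back.noise == truth.noise
    assert back.effects == truth.effects
    json.loads(path.read_text())  # valid JSON


def test_reference_with_low_plateau_censors_above_range():
    tbl = simulate_reference(params=(1.0, 1.0, 2.0, 1.4), compound="weak")
    fit = fit_4pl(tbl.concentration_mg_L.to_numpy(), tbl.peli.to_numpy())
    assert peli15(fit).censor == "above_range"


def test_reference_analytic_inversion():
    """(A=1, B=1, C=1, D=3): the 1.5-crossing is at C/((D-A)/0.5 - 1) = 1/3."""
    tbl = simulate_reference(params=(1.0, 1.0, 1.0, 3.0), compound="ref")
    fit = fit_4pl(tbl.concentration_mg_L.to_numpy(), tbl.peli.to_numpy())
    ep = peli15(fit)
    assert ep.censor == "interval"
    assert ep.value == pytest.approx(1.0 / 3.0, abs=1e-6)


def test_programmed_correlation_is_recovered():
    rng_x = np.random.default_rng(1)
    x = rng_x.uniform(1, 5, 10)
    medians = {}
    for r_true in (0.75, 0.0):
        rs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = correlated_noise(x, r_true, rng)
            rs.append(np.corrcoef(x, y)[0, 1])
        medians[r_true] = np.median(rs)
    assert abs(medians[0.75] - 0.75) < 0.15
    assert abs(medians[0.0]) < 0.1

    rng = np.random.default_rng(0)
    y_exact = correlated_noise(x, 1.0, rng)
    assert np.corrcoef(x, y_exact)[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_phenotype_tables_carry_programmed_effects(small_library):
    truth = default_truth(small_library, seed=3, cv=0.0)
    pheno = simulate_phenotypes(truth, small_library)
    assert set(pheno) == {"ros", "comet", "h2o2_standard", "truth"}
    ros, tr = pheno["ros"], pheno["truth"]
    # recovered fold for one condition matches the programmed value exactly
    comp = sorted(truth.effects)[0]
    fold_true = tr[
        (tr.compound == comp) & (tr.quantity == "ros_fold") & (tr.concentration_mg_L == 8.0)
    ].value.iloc[0]
    from pelitox.pipeline import _ros_endpoints, RunConfig  # noqa: F401
    from pelitox.phenotype import ros_fold_change

    grid = ros[ros.role == "blank_control"].sort_values("time_min")
    t = grid.time_min.to_numpy()
    blank = grid.fluorescence.to_numpy()
    stained = ros[ros.role == "stained_control"].sort_values("time_min").fluorescence.to_numpy()
    chem = ros[
        (ros.role == "chemical_control") & (ros.compound == comp) & (ros.concentration_mg_L == 8.0)
    ].sort_values("time_min").fluorescence.to_numpy()
    treated = ros[
        (ros.role == "treated") & (ros.compound == comp)
        & (ros.concentration_mg_L == 8.0) & (ros.replicate == 1)
    ].sort_values("time_min").fluorescence.to_numpy()
    got = ros_fold_change(t, treated, stained, chem, blank)
    assert got == pytest.approx(fold_true, abs=1e-9)


def test_invalid_design_concentration_rejected(small_library):
    truth = null_truth(small_library)
    with pytest.raises(ValueError, match="positive"):
        simulate_plate(truth, small_library, concentrations=(0.0, 1.0, 2.0, 4.0))
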