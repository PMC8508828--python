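"""Reader/writer contracts for plate exports, plate maps, and the library."""

import numpy as np
import pandas as pd
import pytest

from pelitox.library_io import (
    PlateLayout,
    ValidationError,
    normalize_category,
    read_library,
    read_plate_export,
    write_plate_export,
)
from pelitox.synthetic_data import SyntheticTruth, simulate_plate, NoiseModel


def _layout_two_wells() -> PlateLayout:
    return PlateLayout(
        pd.DataFrame(
            [
                ("A1", "reporter", "YTEST000W", "X", 1.0, 1),
                ("A2", "blank_control", "", "X", 1.0, 1),
            ],
            columns=["well", "role", "orf", "compound", "concentration_mg_L", "replicate"],
        )
    )


def _long_table(times) -> pd.DataFrame:
    rows = []
    for well in ("A1", "A2"):
        for t in times:
            rows.append((well, t, "OD600", 0.1 + 0.001 * t))
            rows.append((well, t, "GFP", 5.0 + 0.1 * t))
    return pd.DataFrame(rows, columns=["well", "time_min", "channel", "value"])


def test_long_form_parse_preserves_shape(tmp_path):
    times = [5.0 * i for i in range(25)]
    path = tmp_path / "plate.csv"
    _long_table(times).to_csv(path, index=False)
    plate = read_plate_export(path, _layout_two_wells())
    assert plate.od.shape == (2, 25)
    assert plate.gfp.shape == (2, 25)
    assert np.allclose(plate.time_min, times)


def test_missing_cell_is_an_error_naming_the_pair(tmp_path):
    times = [0.0, 5.0, 10.0]
    df = _long_table(times)
    df = df[~((df.well == "A2") & (df.time_min == 5.0) & (df.channel == "GFP"))]
    path = tmp_path / "plate.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match=r"A2.*5"):
        read_plate_export(path, _layout_two_wells())


def test_nonuniform_grid_error_names_offending_times(tmp_path):
    df = _long_table([0.0, 5.0, 12.0])
    path = tmp_path / "plate.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="12"):
        read_plate_export(path, _layout_two_wells())


def test_unknown_channel_and_foreign_well_are_errors(tmp_path):
    df = _long_table([0.0, 5.0])
    path = tmp_path / "bad_channel.csv"
    df.assign(channel=df.channel.replace({"GFP": "FITC"})).to_csv(path, index=False)
    with pytest.raises(ValidationError, match="FITC"):
        read_plate_export(path, _layout_two_wells())
    path2 = tmp_path / "bad_well.csv"
    df.assign(well=df.well.replace({"A2": "Z9"})).to_csv(path2, index=False)
    with pytest.raises(ValidationError):
        read_plate_export(path2, _layout_two_wells())


@pytest.mark.parametrize("dialect", ["long", "wide"])
def test_write_read_round_trip_is_lossless(tmp_path, small_library, dialect):
    truth = SyntheticTruth(
        effects={"X": {}}, noise=NoiseModel(cv=0.05), seed=3
    )
    plate = simulate_plate(
        truth, small_library, compounds=("X",), concentrations=(1.0, 4.0),
        replicates=2, time_min=(0.0, 5.0, 10.0, 15.0),
    )
    path = tmp_path / f"plate_{dialect}.csv"
    write_plate_export(plate, path, dialect=dialect)
    back = read_plate_export(path, plate.layout, dialect=dialect)
    od_a = plate.od.sort_index()
    od_b = back.od.sort_index()
    np.testing.assert_allclose(od_a.to_numpy(), od_b.to_numpy(), rtol=1e-10)
    np.testing.assert_allclose(
        plate.gfp.sort_index().to_numpy(), back.gfp.sort_index().to_numpy(), rtol=1e-10
    )


def test_library_read_normalizes_categories_and_rejects_bad_input(tmp_path):
    path = tmp_path / "lib.tsv"
    path.write_text(
        "orf\tgene\tcategory\tgo_terms\n"
        "Y1\tG1\tgeneral\ta;b\n"
        "Y2\tG2\tChemical\ta\n"
        "Y3\tG3\tDNA\t\n"
        "Y4\tG4\tOxidative\tc\n"
        "Y5\tG5\tPROTEIN\t\n"
    )
    lib = read_library(path)
    assert len(lib) == 5
    assert {e.category for e in lib} == {"general", "chemical", "DNA", "oxidative", "protein"}

    bad = tmp_path / "bad.tsv"
    bad.write_text("orf\tgene\tcategory\tgo_terms\nY1\tG1\tthermal\t\n")
    with pytest.raises(ValidationError, match="general, chemical, DNA, oxidative, protein"):
        read_library(bad)

    dup = tmp_path / "dup.tsv"
    dup.write_text(
        "orf\tgene\tcategory\tgo_terms\nY1\tG1\tDNA\t\nY1\tG2\tDNA\t\n"
    )
    with pytest.raises(ValidationError, match="duplicate"):
        read_library(dup)


def test_bundled_fixture_has_74_reporters_partitioned_into_five_categories(library74):
    assert len(library74) == 74
    sizes = {c: len(library74.members(c)) for c in ("general", "chemical", "DNA", "oxidative", "protein")}
    assert sum(sizes.values()) == 74
    assert all(v > 0 for v in sizes.values())
    assert normalize_category("dna") == "DNA"


def test_layout_rejects_reporters_absent_from_library(small_library):
    layout = PlateLayout(
        pd.DataFrame(
            [("A1", "reporter", "YNOPE001W", "X", 1.0, 1)],
            columns=["well", "role", "orf", "compound", "concentration_mg_L", "replicate"],
        )
    )
    with pytest.raises(ValidationError, match="YNOPE001W"):
        layout.validate_against_library(small_library)


def test_layout_role_contracts():
    with pytest.raises(ValidationError, match="blank_control"):
        PlateLayout(
            pd.DataFrame(
                [("A1", "blank_control", "Y1", "X", 1.0, 1)],
                columns=["well", "role", "orf", "compound", "concentration_mg_L", "replicate"],
            )
        )
    with pytest.raises(ValidationError, match="vehicle_control"):
        PlateLayout(
            pd.DataFrame(
                [("A1", "vehicle_control", "Y1", "X", 1.0, 1)],
                columns=["well", "role", "orf", "compound", "concentration_mg_L", "replicate"],
            )
        )
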