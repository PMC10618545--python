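"""Readers, writers, domain-type validation and round trips."""

import numpy as np
import pandas as pd
import pytest

from spheroscreen.plate import (
    ClinicalRecord,
    PlateValidationError,
    SchemaError,
    ScreenDataset,
    WellFeatures,
    normalize_well,
    read_clinical,
    read_dss_matrix,
    read_well_features,
    write_clinical,
    write_dss_matrix,
)
from spheroscreen.simulate import default_drug_library, generate_clinical, ScreenConfig

WELL_HEADER = ("plate_id,well,sample_id,format,timepoint_h,role,drug_id,conc_nM,"
               "tmrm_volume,popo1_volume,popo1_area,hoechst_volume,hoechst_area,"
               "caspase_volume,inv_brightfield_intensity")


def _write(tmp_path, rows, header=WELL_HEADER):
    path = tmp_path / "wells.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestWellFeaturesIO:
    def test_row_count_preserved(self, tmp_path):
        path = _write(tmp_path, [
            "P1,A01,S1,3D,2,neg_control,,,50,5,2,30,100,,15",
            "P1,C05,S1,3D,72,treatment,carboplatin,100,40,5,2,30,100,,25",
        ])
        wells = read_well_features(path)
        assert len(wells) == 2
        assert wells[1].drug_id == "carboplatin"
        assert wells[1].conc_nM == 100

    def test_missing_required_column_names_it(self, tmp_path):
        header = WELL_HEADER.replace("tmrm_volume,", "")
        path = _write(tmp_path, ["P1,A01,S1,3D,2,neg_control,,,5,2,30,100,,15"],
                      header=header)
        with pytest.raises(SchemaError, match="tmrm_volume"):
            read_well_features(path)

    def test_negative_aggregate_names_well(self, tmp_path):
        path = _write(tmp_path, ["P1,B03,S1,3D,2,neg_control,,,-5,5,2,30,100,,15"])
        with pytest.raises(PlateValidationError, match="B03"):
            read_well_features(path)

    def test_unknown_column_ignored(self, tmp_path):
        path = _write(tmp_path,
                      ["P1,A01,S1,3D,2,neg_control,,,50,5,2,30,100,,15,junk"],
                      header=WELL_HEADER + ",mystery")
        wells = read_well_features(path)
        assert len(wells) == 1
        assert not hasattr(wells[0], "mystery")

    def test_screen_dataset_round_trip(self, tmp_path, small_screen):
        dataset, _ = small_screen
        dataset.save(tmp_path / "bundle")
        loaded = ScreenDataset.load(tmp_path / "bundle")
        assert len(loaded.wells) == len(dataset.wells)
        assert all(a == b for a, b in zip(dataset.wells, loaded.wells))
        assert loaded.platemap.entries == dataset.platemap.entries
        assert [r.patient_id for r in loaded.clinical] == \
               [r.patient_id for r in dataset.clinical]


class TestWellValidation:
    def test_treatment_requires_drug_and_dose(self):
        with pytest.raises(PlateValidationError, match="treatment well"):
            WellFeatures(plate_id="P", well="A01", sample_id="S", format="3D",
                         timepoint_h=72, role="treatment", tmrm_volume=1)

    def test_control_must_not_carry_drug(self):
        with pytest.raises(PlateValidationError, match="control well"):
            WellFeatures(plate_id="P", well="A01", sample_id="S", format="3D",
                         timepoint_h=72, role="neg_control",
                         drug_id="carboplatin", tmrm_volume=1)

    @pytest.mark.parametrize("raw,expected", [("A1", "A01"), ("a01", "A01"),
                                              ("P24", "P24"), ("h12", "H12")])
    def test_well_normalization(self, raw, expected):
        assert normalize_well(raw) == expected

    @pytest.mark.parametrize("bad", ["Q01", "A00", "A25", "AA1", "7", ""])
    def test_invalid_addresses(self, bad):
        with pytest.raises(PlateValidationError):
            normalize_well(bad)


class TestClinicalIO:
    def test_cohort_round_trip(self, tmp_path):
        records = generate_clinical(ScreenConfig(), 1)
        path = tmp_path / "clinical.csv"
        write_clinical(records, path)
        loaded = read_clinical(path)
        assert len(loaded) == 16
        assert loaded == records

    def test_na_passthrough(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,sample_ids,recist,pfi_months,excluded\n"
                        "PT01,PT01-T,CR,,False\n")
        (rec,) = read_clinical(path)
        assert rec.pfi_months is None
        assert rec.recist == "CR"

    def test_duplicate_patient_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id\nPT01\nPT01\n")
        with pytest.raises(PlateValidationError, match="duplicate"):
            read_clinical(path)


class TestDSSMatrix:
    def _results(self):
        return pd.DataFrame({
            "sample_id": ["S1", "S2"] * 3,
            "drug_id": ["d1", "d1", "d2", "d2", "d3", "d3"],
            "dss": [10.123456789, 0.0, 25.5, 3.3, 8.0, np.nan],
            "qc_pass": [True] * 5 + [False],
        })

    def test_shape(self, tmp_path):
        path = tmp_path / "m.csv"
        write_dss_matrix(self._results(), path)
        mat = read_dss_matrix(path)
        assert mat.shape == (3, 2)

    def test_qc_failure_is_empty_not_zero(self, tmp_path):
        path = tmp_path / "m.csv"
        write_dss_matrix(self._results(), path)
        mat = read_dss_matrix(path)
        assert np.isnan(mat.loc["d3", "S2"])
        assert mat.loc["d1", "S2"] == 0.0  # a true zero survives

    def test_round_trip_six_decimals(self, tmp_path):
        path = tmp_path / "m.csv"
        res = self._results()
        write_dss_matrix(res, path)
        mat = read_dss_matrix(path)
        assert mat.loc["d1", "S1"] == pytest.approx(10.123456789, abs=1e-6)

    def test_conflicting_duplicates_rejected(self, tmp_path):
        res = pd.DataFrame({"sample_id": ["S1", "S1"], "drug_id": ["d1", "d1"],
                            "dss": [1.0, 2.0], "qc_pass": [True, True]})
        with pytest.raises(PlateValidationError, match="duplicate"):
            write_dss_matrix(res, tmp_path / "m.csv")


def test_drug_library_default_invariants():
    lib = default_drug_library()
    assert len(lib.table) == 58
    for drug in lib.drug_ids:
        concs = lib.concentrations(drug)
        assert len(concs) == 5
        assert np.all(np.diff(concs) > 0)
    assert lib.concentrations("A-1331852")[0] == pytest.approx(0.5)
    assert lib.concentrations("A-1331852")[-1] == pytest.approx(1000.0)
    assert lib.concentrations("carboplatin")[0] == pytest.approx(10.0)
    assert lib.concentrations("carboplatin")[-1] == pytest.approx(100000.0)
    assert lib.concentrations("afatinib")[0] == pytest.approx(0.2)


def test_platemap_never_silently_drops_wells(small_screen):
    dataset, _ = small_screen
    missing = dataset.missing_wells()
    assert len(missing) == 0  # simulated bundle is complete
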