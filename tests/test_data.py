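"""Data model, validation and CSV round-trips."""

import pandas as pd
import pytest

from pollenrisk.data import (SchemaError, ValidationError,
                             load_builtin_fixtures, read_dataset,
                             write_dataset)


class TestBuiltinFixtures:
    def test_twelve_nests_with_printed_scalars(self, bundle):
        assert bundle.nest_ids == [f"A{i}" for i in range(1, 13)]
        assert bundle.nest("A1").provision_mass_mg == pytest.approx(246.50)
        assert bundle.nest("A5").energetic_value_kj_g == pytest.approx(18.77)

    def test_pollen_sums_within_printed_rounding(self, bundle):
        sums = bundle.pollen.groupby("nest_id")["proportion_pct"].sum()
        assert ((sums >= 99.5) & (sums <= 100.5)).all()

    def test_taxa_and_substance_inventory(self, bundle):
        assert bundle.pollen["taxon"].nunique() == 28
        # every catalog substance has a positive LOQ and LD50
        assert (bundle.substances["loq_ng_g"] > 0).all()
        assert (bundle.substances["ld50_ug_bee"] > 0).all()
        assert len(bundle.substances) == 12

    def test_unknown_nest_raises(self, bundle):
        with pytest.raises(KeyError):
            bundle.nest("A13")

    def test_absent_pair_is_not_detected(self, bundle):
        # boscalid was not found in nest A4; the matrix fills it with 0
        assert not bundle.is_detected("A4", "boscalid")
        assert bundle.residue_matrix().loc["A4", "boscalid"] == 0.0
        assert bundle.is_detected("A4", "dimethoate")


class TestRoundTrip:
    def test_write_read_is_identity(self, bundle, tmp_path):
        paths = write_dataset(bundle, tmp_path)
        again = read_dataset(paths["pollen"], paths["residues"],
                             paths["substances"], paths["nests"])
        for name in ("pollen", "residues", "substances", "nests"):
            pd.testing.assert_frame_equal(getattr(bundle, name),
                                          getattr(again, name))

    def test_rewrite_is_byte_identical(self, bundle, tmp_path):
        first = write_dataset(bundle, tmp_path / "a")
        again = read_dataset(first["pollen"], first["residues"],
                             first["substances"], first["nests"])
        second = write_dataset(again, tmp_path / "b")
        for name, p in first.items():
            assert p.read_bytes() == second[name].read_bytes()

    def test_synthetic_bundle_round_trips(self, synthetic_bundle, tmp_path):
        paths = write_dataset(synthetic_bundle, tmp_path)
        again = read_dataset(paths["pollen"], paths["residues"],
                             paths["substances"], paths["nests"],
                             paths["landscape"])
        assert again.landscape is not None
        assert len(again.pollen) == len(synthetic_bundle.pollen)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestValidation:
    def _paths(self, tmp_path, pollen=None, residues=None, substances=None,
               nests=None):
        fx = load_builtin_fixtures()
        out = write_dataset(fx, tmp_path)
        return {
            "pollen": pollen or out["pollen"],
            "residues": residues or out["residues"],
            "substances": substances or out["substances"],
            "nests": nests or out["nests"],
        }

    def test_missing_column_names_it(self, tmp_path):
        bad = _write(tmp_path, "bad.csv", "nest_id,taxon\nA1,Poaceae\n")
        paths = self._paths(tmp_path, pollen=bad)
        with pytest.raises(SchemaError, match="proportion_pct"):
            read_dataset(**paths)

    def test_empty_file_is_rejected_without_partial_bundle(self, tmp_path):
        bad = _write(tmp_path, "empty.csv", "")
        paths = self._paths(tmp_path, pollen=bad)
        with pytest.raises(ValidationError):
            read_dataset(**paths)

    def test_out_of_range_proportion_lists_row(self, tmp_path):
        bad = _write(tmp_path, "p.csv",
                     "nest_id,taxon,proportion_pct\nA1,Poaceae,135.0\n")
        paths = self._paths(tmp_path, pollen=bad)
        with pytest.raises(ValidationError, match="A1.*Poaceae"):
            read_dataset(**paths)

    def test_duplicate_residue_pair_rejected(self, tmp_path):
        bad = _write(tmp_path, "r.csv",
                     "nest_id,substance,concentration_ng_g\n"
                     "A1,boscalid,5.0\nA1,boscalid,6.0\n")
        paths = self._paths(tmp_path, residues=bad)
        with pytest.raises(ValidationError, match="duplicate pair"):
            read_dataset(**paths)

    def test_uncataloged_substance_rejected(self, tmp_path):
        bad = _write(tmp_path, "r.csv",
                     "nest_id,substance,concentration_ng_g\nA1,unlistedcide,5.0\n")
        paths = self._paths(tmp_path, residues=bad)
        with pytest.raises(ValidationError, match="unlistedcide"):
            read_dataset(**paths)

    def test_empty_concentration_cell_means_not_detected(self, tmp_path):
        table = _write(tmp_path, "r.csv",
                       "nest_id,substance,concentration_ng_g\n"
                       "A1,boscalid,5.0\nA2,boscalid,\n")
        paths = self._paths(tmp_path, residues=table)
        b = read_dataset(**paths)
        assert b.is_detected("A1", "boscalid")
        assert not b.is_detected("A2", "boscalid")

    def test_dash_variants_normalized_on_read(self, tmp_path):
        table = _write(tmp_path, "p.csv",
                       "nest_id,taxon,proportion_pct\n"
                       "A1,Vicia–group,100.0\n")
        fx = write_dataset(load_builtin_fixtures(), tmp_path)
        nests = _write(tmp_path, "n.csv",
                       "nest_id,provision_mass_mg,energetic_value_kj_g\n"
                       "A1,100.0,18.0\n")
        empty_res = _write(tmp_path, "r.csv",
                           "nest_id,substance,concentration_ng_g\n")
        b = read_dataset(table, empty_res, fx["substances"], nests)
        assert list(b.pollen["taxon"]) == ["Vicia-group"]
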