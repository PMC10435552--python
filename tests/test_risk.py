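"""Toxic-unit Risk Index and residue summaries."""

import numpy as np
import pandas as pd
import pytest

from pollenrisk.risk import (detection_summary, pesticide_risk_index,
                             resolve_ld50, risk_index_table, substance_median)


def _catalog(**entries):
    rows = [{"substance": s, "classes": "F", "loq_ng_g": 1.0,
             "ld50_ug_bee": v, "ld50_bound": b}
            for s, (v, b) in entries.items()]
    return pd.DataFrame(rows)


def _residues(nest_id, **conc):
    return pd.DataFrame([{"nest_id": nest_id, "substance": s,
                          "concentration_ng_g": c} for s, c in conc.items()])


class TestResolveLd50:
    @pytest.mark.parametrize("ug,bound,expected_ng,expected_flag", [
        (0.10, False, 100.0, False),      # dimethoate, exact
        (25.00, True, 25000.0, True),     # azoxystrobin, "> 25.00"
        (1.0, False, 1000.0, False),
    ])
    def test_unit_conversion_and_bound_flag(self, ug, bound, expected_ng,
                                            expected_flag):
        ng, flag = resolve_ld50(ug, bound)
        assert ng == pytest.approx(expected_ng)
        assert flag is expected_flag

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            resolve_ld50(0.0)


class TestRiskIndex:
    def test_single_term_product(self):
        res = pesticide_risk_index(_residues("N", x=100.0), "N", 200.0,
                                   _catalog(x=(10.0, "exact")))
        assert res.risk_index == pytest.approx(0.002)
        assert res.toxic_units == {"x": pytest.approx(0.002)}

    def test_no_detections_is_zero(self):
        res = pesticide_risk_index(_residues("other", x=5.0), "N", 200.0,
                                   _catalog(x=(10.0, "exact")))
        assert res.risk_index == 0.0
        assert res.n_substances == 0

    def test_nest_a12_matches_hand_summed_equation(self, bundle):
        # independent oracle: the six printed terms of the equation,
        # concentration [ng/g] x 0.23190 g / LD50 [ng/bee], summed by hand
        m = 0.23190
        oracle = (0.22 * m / 14530 + 5.90 * m / 100000 + 2.08 * m / 102300
                  + 6.55 * m / 110900 + 3.00 * m / 100 + 1.33 * m / 50)
        res = pesticide_risk_index(bundle.residues, "A12", 231.90,
                                   bundle.substances)
        assert res.n_substances == 6
        assert res.risk_index == pytest.approx(oracle, rel=1e-9)

    def test_missing_catalog_entry_named(self):
        with pytest.raises(KeyError, match="mystery"):
            pesticide_risk_index(_residues("N", mystery=1.0), "N", 100.0,
                                 _catalog(x=(1.0, "exact")))

    def test_sum_of_toxic_units_is_exact(self, bundle):
        for nid in bundle.nest_ids:
            res = pesticide_risk_index(bundle.residues, nid,
                                       bundle.nest(nid).provision_mass_mg,
                                       bundle.substances)
            assert res.risk_index == pytest.approx(sum(res.toxic_units.values()),
                                                   rel=1e-12)
            assert all(tu <= res.risk_index + 1e-15
                       for tu in res.toxic_units.values())

    def test_linearity_in_concentrations_and_ld50(self):
        cat = _catalog(x=(10.0, "exact"), y=(1.0, "exact"))
        res1 = pesticide_risk_index(_residues("N", x=100.0, y=3.0), "N", 200.0, cat)
        res2 = pesticide_risk_index(_residues("N", x=200.0, y=6.0), "N", 200.0, cat)
        assert res2.risk_index == pytest.approx(2 * res1.risk_index)
        cat2 = _catalog(x=(20.0, "exact"), y=(2.0, "exact"))
        res3 = pesticide_risk_index(_residues("N", x=100.0, y=3.0), "N", 200.0, cat2)
        assert res3.risk_index == pytest.approx(res1.risk_index / 2)

    def test_adding_detection_never_decreases(self):
        cat = _catalog(x=(10.0, "exact"), y=(1.0, "exact"))
        without = pesticide_risk_index(_residues("N", x=100.0), "N", 200.0, cat)
        with_extra = pesticide_risk_index(_residues("N", x=100.0, y=0.5),
                                          "N", 200.0, cat)
        assert with_extra.risk_index > without.risk_index

    @pytest.mark.parametrize("larger", [30.0, 100.0, 1e6])
    def test_bounded_ld50_gives_upper_bound_tu(self, larger):
        # replacing a "> 25" bound by any larger true value shrinks the TU
        at_bound = pesticide_risk_index(_residues("N", x=50.0), "N", 200.0,
                                        _catalog(x=(25.0, "greater_than")))
        replaced = pesticide_risk_index(_residues("N", x=50.0), "N", 200.0,
                                        _catalog(x=(larger, "exact")))
        assert at_bound.upper_bound_substances == ("x",)
        assert replaced.risk_index < at_bound.risk_index

    def test_table_covers_every_nest(self, bundle):
        table = risk_index_table(bundle)
        assert list(table["nest_id"]) == bundle.nest_ids
        assert (table["risk_index"] > 0).all()


class TestResidueSummaries:
    @pytest.mark.parametrize("substance,n,pct", [
        ("acetamiprid", 9, 75.0),
        ("prosulfocarb", 1, 100.0 / 12),
    ])
    def test_detection_summary(self, bundle, substance, n, pct):
        got_n, got_pct = detection_summary(bundle, substance)
        assert got_n == n
        assert got_pct == pytest.approx(pct)

    def test_unknown_substance_raises(self, bundle):
        with pytest.raises(KeyError):
            detection_summary(bundle, "imaginarium")

    @pytest.mark.parametrize("substance,median", [
        ("azoxystrobin", 10.60),
        ("dimethoate", 4.35),
        ("chlorothalonil", 2.15),   # single detection: min = max = median
    ])
    def test_substance_medians(self, bundle, substance, median):
        assert substance_median(bundle, substance) == pytest.approx(median,
                                                                    abs=0.005)

    def test_median_without_detection_is_domain_error(self, bundle):
        extra = bundle.substances.copy()
        extra.loc[len(extra)] = ["ghosticide", "F", 1.0, 1.0, "exact"]
        from pollenrisk.data import Bundle
        b = Bundle(bundle.pollen, bundle.residues, extra, bundle.nests)
        assert detection_summary(b, "ghosticide") == (0, 0.0)
        with pytest.raises(ValueError, match="no detections"):
            substance_median(b, "ghosticide")
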