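"""Risk-metric arithmetic, identities and the 17-group campaign assessment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmrisk import constants as C
from pmrisk import risk as rk
from pmrisk.deposition import DepositionFractions, regional_fractions


class TestEDI:
    def test_zero_concentration(self, adult):
        assert rk.edi(0.0, adult) == 0.0

    def test_adult_at_campaign_mean(self, adult):
        # arithmetic oracle: 1.17e3 * 15.7 * 0.1 / 60.6
        assert rk.edi(1.17e3, adult) == pytest.approx(30.3, abs=0.1)

    def test_linearity_in_inhalation_rate(self, adult):
        doubled = rk.AgeGroupParams("x", adult.IR * 2, adult.BW, adult.T)
        assert rk.edi(500.0, doubled) == pytest.approx(2 * rk.edi(500.0, adult))


class TestHQ:
    def test_unit_ratio(self):
        tdi_pg = 100.0 * C.PG_PER_UG
        assert rk.hq(tdi_pg) == pytest.approx(1.0)

    def test_adult_value(self, adult):
        assert rk.hq(30.3) == pytest.approx(3.03e-7, rel=0.01)

    def test_identity_hq_times_tdi_equals_edi(self, adult):
        e = rk.edi(937.2, adult)
        assert rk.hq(e) * 100.0 * C.PG_PER_UG == pytest.approx(e, rel=1e-12)


class TestMOE:
    def test_unit_ratio(self):
        noael_pg = 10.0 * C.PG_PER_MG
        value, flagged = rk.moe(noael_pg, "SCCP")
        assert value == pytest.approx(1.0)
        assert flagged  # 1 < 1000

    def test_adult_sccp_value(self):
        value, flagged = rk.moe(30.3, "SCCP")
        assert value == pytest.approx(3.3e8, rel=0.01)
        assert not flagged

    def test_zero_edi_reported_infinite(self):
        value, flagged = rk.moe(0.0, "MCCP")
        assert math.isinf(value) and not flagged

    def test_identity_moe_times_edi_equals_noael(self):
        e = 123.4
        value, _ = rk.moe(e, "LCCP")
        assert value * e == pytest.approx(100.0 * C.PG_PER_MG, rel=1e-12)


class TestDEDandEQ:
    def test_ded_zero(self, adult):
        assert rk.ded(0.0, adult) == 0.0

    def test_ded_adult_value(self, adult):
        assert rk.ded(1.43e13, adult) == pytest.approx(3.7e11, rel=0.01)

    def test_ded_inverse_in_body_weight(self, adult):
        heavier = rk.AgeGroupParams("x", adult.IR, adult.BW * 2, adult.T)
        assert rk.ded(1e13, heavier) == pytest.approx(rk.ded(1e13, adult) / 2)

    def test_spins_per_cigarette(self):
        assert rk.RiskConstants().spins_per_cigarette == pytest.approx(6.175e14)

    def test_eq_unit_cigarette(self, adult):
        rc = rk.RiskConstants().spins_per_cigarette / adult.IR
        assert rk.eq_cigarettes(rc, adult) == pytest.approx(1.0)

    def test_eq_adult_order_of_magnitude(self, adult):
        # ~0.36 whole-airway cigarettes/day at the campaign mean
        assert rk.eq_cigarettes(1.43e13, adult) == pytest.approx(0.36, abs=0.01)

    def test_eq_independent_of_bw_and_t(self, adult):
        other = rk.AgeGroupParams("x", adult.IR, adult.BW * 2, adult.T / 2)
        assert rk.eq_cigarettes(1e13, other) == rk.eq_cigarettes(1e13, adult)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    conc=st.floats(min_value=0.0, max_value=1e6),
    scale=st.floats(min_value=0.1, max_value=10.0),
)
def test_metrics_homogeneous_degree_one(conc, scale):
    p = rk.AgeGroupParams("x", 15.0, 60.0, 0.1)
    assert rk.edi(conc * scale, p) == pytest.approx(scale * rk.edi(conc, p), rel=1e-9)
    assert rk.ded(conc * scale, p) == pytest.approx(scale * rk.ded(conc, p), rel=1e-9)
    assert rk.eq_cigarettes(conc * scale, p) == pytest.approx(
        scale * rk.eq_cigarettes(conc, p), rel=1e-9
    )


class TestApplyDeposition:
    def _body_table(self, adult):
        return pd.DataFrame(
            [
                {"group": adult.label, "analyte": "CPs", "statistic": "mean",
                 "metric": "EDI", "region": "whole-body", "value": 30.3},
                {"group": adult.label, "analyte": "EPFR", "statistic": "mean",
                 "metric": "EQ", "region": "whole-body", "value": 0.36},
            ]
        )

    def test_pure_head_airway(self, adult):
        df = DepositionFractions(IF=1.0, HA=1.0, TB=0.0, AR=0.0)
        out = rk.apply_deposition(self._body_table(adult), df)
        ha = out.query("region == 'HA' and metric == 'EDI'")["value"].iloc[0]
        assert ha == 30.3

    def test_regional_sum_bounded_by_whole_body(self, adult):
        df = regional_fractions(1.0)
        out = rk.apply_deposition(self._body_table(adult), df)
        regional = out[out["region"].isin(["HA", "TB", "AR"])]
        assert regional.groupby("metric")["value"].sum().le(30.3 + 1e-9).all()

    def test_adult_eq_regional_ordering(self, adult):
        # head airway > alveolar > tracheobronchial for ~1 um particles,
        # matching the published regional pattern of cigarette equivalents
        df = regional_fractions(1.0)
        out = rk.apply_deposition(self._body_table(adult), df)
        eq = out[out["metric"] == "EQ"].set_index("region")["value"]
        assert eq["HA"] > eq["AR"] > eq["TB"]


class TestAssessCampaign:
    def test_constant_campaign_equals_single_day(self, age_groups):
        conc = pd.DataFrame({"SCCP": [100.0] * 5, "EPFR": [1e13] * 5})
        out = rk.assess_campaign(conc, age_groups)
        adult_edi = out.query(
            "group == '18-44 years' and metric == 'EDI' and statistic == 'mean'"
        )["value"].iloc[0]
        assert adult_edi == pytest.approx(100.0 * 15.7 * 0.1 / 60.6)

    def test_hq_below_one_at_printed_means(self, age_groups):
        conc = pd.DataFrame({"CPs": [1.17e3] * 3})
        out = rk.assess_campaign(conc, age_groups, radical_analytes=())
        hqs = out[out["metric"] == "HQ"]["value"]
        assert len(hqs) == 2 * 17
        assert (hqs < 1).all()

    def test_children_rank_highest_in_ded(self, age_groups):
        # ordering oracle: DED tracks IR/BW, maximal for young children
        conc = pd.DataFrame({"EPFR": [1.43e13] * 3})
        out = rk.assess_campaign(conc, age_groups)
        ded = out.query("metric == 'DED' and statistic == 'median'").set_index("group")[
            "value"
        ]
        top = ded.idxmax()
        assert top in {"9 months-1 year", "1-2 years", "2-3 years", "3-4 years"}

    def test_row_count_is_17_by_analytes(self, age_groups):
        conc = pd.DataFrame({"SCCP": [10.0] * 4, "MCCP": [10.0] * 4})
        out = rk.assess_campaign(conc, age_groups)
        assert out.groupby(["group", "analyte"]).ngroups == 17 * 2

    def test_missing_analyte_is_explicit_error(self, age_groups):
        conc = pd.DataFrame({"SCCP": [np.nan] * 4})
        with pytest.raises(ValueError, match="no observations"):
            rk.assess_campaign(conc, age_groups)

    def test_wrong_group_count_rejected(self):
        conc = pd.DataFrame({"SCCP": [10.0] * 4})
        with pytest.raises(ValueError, match="17"):
            rk.assess_campaign(conc, rk.default_age_groups()[:5])
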