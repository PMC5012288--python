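"""Biodiesel quality indices, the ASTM screen, and the screening report."""

import numpy as np
import pytest

from algascreen.fame import FameProfile, methyl_ester_mass
from algascreen.growth import GrowthFit
from algascreen.indices import (
    astm_screen,
    cetane_number,
    cold_filter_plugging_point,
    compute_indices,
    degree_of_unsaturation,
    iodine_value,
    long_chain_saturation_factor,
    round_half_away,
    saponification_value,
    screen_table,
)
from algascreen.io import load_printed_index_table


def pure(label):
    return FameProfile("pure", {label: 100.0})


class TestSaponificationValue:
    def test_pure_palmitate(self):
        assert saponification_value(pure("C16:0")) == pytest.approx(
            560 * 100 / methyl_ester_mass("C16:0"), rel=1e-12
        )
        assert saponification_value(pure("C16:0")) == pytest.approx(207.06, abs=0.01)

    def test_pure_oleate(self):
        assert saponification_value(pure("C18:1")) == pytest.approx(188.87, abs=0.01)

    def test_linear_in_composition(self):
        mix = FameProfile("mix", {"C16:0": 50.0, "C18:1": 50.0})
        expected = 0.5 * (saponification_value(pure("C16:0")) + saponification_value(pure("C18:1")))
        assert saponification_value(mix) == pytest.approx(expected, rel=1e-12)


class TestIodineValue:
    def test_saturated_is_zero(self):
        assert iodine_value(FameProfile("s", {"C12:0": 40.0, "C16:0": 60.0})) == 0.0

    def test_pure_oleate(self):
        assert iodine_value(pure("C18:1")) == pytest.approx(
            254 * 1 * 100 / methyl_ester_mass("C18:1"), rel=1e-12
        )
        assert iodine_value(pure("C18:1")) == pytest.approx(85.67, abs=0.01)

    def test_pure_hexadecatetraenoate(self):
        assert iodine_value(pure("C16:4(n-3)")) == pytest.approx(387.2, abs=0.1)


class TestCetaneNumber:
    def test_component_weighted_pure_palmitate(self):
        expected = -7.8 + 0.302 * methyl_ester_mass("C16:0")
        assert cetane_number(pure("C16:0")) == pytest.approx(expected, rel=1e-12)
        assert cetane_number(pure("C16:0")) == pytest.approx(73.88, abs=0.01)

    def test_aggregate_pure_palmitate(self):
        cn = cetane_number(pure("C16:0"), method="aggregate_sv_iv")
        assert cn == pytest.approx(46.3 + 5458 / 207.057, abs=0.01)

    def test_double_bonds_lower_cn_under_both_methods(self):
        for method in ("component_weighted", "aggregate_sv_iv"):
            assert cetane_number(pure("C18:0"), method) > cetane_number(
                pure("C18:1"), method
            ) > cetane_number(pure("C18:2"), method)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            cetane_number(pure("C16:0"), method="astm_graph")


class TestDegreeOfUnsaturation:
    @pytest.mark.parametrize(
        "abund, expected",
        [
            ({"C18:1": 100.0}, 100.0),
            ({"C18:2": 100.0}, 200.0),
            ({"C18:1": 50.0, "C18:2": 25.0, "C16:0": 25.0}, 100.0),
            ({"C16:0": 100.0}, 0.0),
        ],
    )
    def test_weighted_sum(self, abund, expected):
        assert degree_of_unsaturation(FameProfile("s", abund)) == pytest.approx(expected)


class TestLcsfAndCfpp:
    def test_no_long_saturated_chains(self):
        assert long_chain_saturation_factor(pure("C18:1")) == 0.0

    def test_pure_palmitate(self):
        assert long_chain_saturation_factor(pure("C16:0")) == pytest.approx(10.0)

    def test_weighted_sum_saturated_only(self):
        prof = FameProfile("s", {"C16:0": 50.0, "C18:0": 10.0, "C18:1": 40.0})
        assert long_chain_saturation_factor(prof) == pytest.approx(0.1 * 50 + 0.5 * 10)

    def test_cfpp_line(self):
        assert cold_filter_plugging_point(0.0) == pytest.approx(-16.477)
        assert cold_filter_plugging_point(2.0) - cold_filter_plugging_point(1.0) == pytest.approx(3.1417)

    @pytest.mark.parametrize(
        "lcsf, reported", [(0.55, -15), (8.94, 12), (8.26, 9)]
    )
    def test_printed_study_rows(self, lcsf, reported):
        assert int(round_half_away(cold_filter_plugging_point(lcsf))) == reported

    def test_printed_table_reproduced_for_every_row(self):
        table = load_printed_index_table()
        for _, row in table.iterrows():
            cfpp = cold_filter_plugging_point(row["lcsf"])
            assert int(round_half_away(cfpp)) == int(row["cfpp_printed"]), row["strain"]


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected", [(0.5, 1), (-0.5, -1), (2.5, 3), (-2.5, -3), (2.4, 2), (-14.749, -15)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestAstmScreen:
    def test_pass_fail_and_boundaries(self):
        def screen(cn, iv):
            idx = compute_indices(pure("C16:0"))
            idx = type(idx)(strain_id="x", sv=idx.sv, iv=iv, cn=cn, du=0, lcsf=0, cfpp=0)
            return astm_screen(idx)

        assert screen(59.4, 51.9).overall_pass  # a strongly passing strain
        s = screen(18.9, 207.0)  # fails both
        assert not s.cn_pass and not s.iv_pass
        s = screen(47.0, 120.0)  # inclusive thresholds
        assert s.cn_pass and s.iv_pass and s.overall_pass

    def test_linear_indices(self):
        # SV, IV, DU, LCSF are linear in composition
        p = FameProfile("p", {"C16:0": 70.0, "C18:2": 30.0})
        q = FameProfile("q", {"C18:1": 60.0, "C18:0": 40.0})
        alpha = 0.3
        mixed = FameProfile(
            "m",
            {
                k: alpha * p.abundances.get(k, 0) + (1 - alpha) * q.abundances.get(k, 0)
                for k in set(p.abundances) | set(q.abundances)
            },
        )
        for f in (saponification_value, iodine_value, degree_of_unsaturation, long_chain_saturation_factor):
            assert f(mixed) == pytest.approx(
                alpha * f(p) + (1 - alpha) * f(q), rel=1e-9, abs=1e-9
            )

    def test_fully_saturated_profiles_pass_cn(self):
        for label in ("C12:0", "C16:0", "C18:0", "C24:0"):
            prof = pure(label)
            assert iodine_value(prof) == 0.0
            assert degree_of_unsaturation(prof) == 0.0
            assert cetane_number(prof, "component_weighted") > 47
            assert cetane_number(prof, "aggregate_sv_iv") > 47


class TestScreenTable:
    @staticmethod
    def _fit(sid, mu):
        return GrowthFit(sid, mu, 24 * np.log(2) / mu, (0, 4), 0.99, 4)

    def test_ranking_counts_and_exclusions(self):
        profiles = [
            FameProfile("fast_good", {"C16:0": 60.0, "C18:1": 40.0}),
            FameProfile("slow_good", {"C16:0": 50.0, "C18:1": 50.0}),
            FameProfile("high_iv", {"C16:4(n-3)": 80.0, "C16:0": 20.0}),
            FameProfile("orphan_profile", {"C16:0": 100.0}),
        ]
        fits = [
            self._fit("fast_good", 1.2),
            self._fit("slow_good", 0.6),
            self._fit("high_iv", 1.1),
            self._fit("orphan_fit", 0.9),
        ]
        res = screen_table(profiles, fits)
        assert res.exclusions == {
            "orphan_fit": "no FAME profile",
            "orphan_profile": "no growth fit",
        }
        t = res.table
        assert list(t["strain"][:2]) == ["fast_good", "slow_good"]  # pass group first
        hi = t[t["strain"] == "high_iv"].iloc[0]
        assert not hi["iv_pass"] and not hi["astm_pass"]  # flagged, not dropped
        counts = res.counts
        assert counts["n_strains"] == 3
        assert counts["n_fast_growers"] == 2
        assert counts["n_astm_pass"] == int(t["astm_pass"].sum())

    def test_empty_inputs(self):
        res = screen_table([], [])
        assert len(res.table) == 0
        assert res.counts["n_astm_pass"] == 0
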