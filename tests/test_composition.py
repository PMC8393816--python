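"""mol% decomposition, double-bond ratio panels, aggregates, carnitine panel."""

import numpy as np
import pandas as pd
import pytest

from conftest import NOISELESS, ratio_frame
from lipidshift import normalize
from lipidshift.composition import (
    DEFAULT_CARBON_BINS,
    RatioSpec,
    carnitine_panel,
    double_bond_ratio,
    group_aggregate,
    mol_percent,
)
from lipidshift.synthetic import EffectSpec, NoiseSpec, StudyDesign, simulate_dataset


def _collapsed(panel, effects=None, seed=0, noiseless=False, n_bio=4):
    design = StudyDesign(n_bio=n_bio, n_tech=2)
    noise = NoiseSpec(seed=seed, **(NOISELESS if noiseless else {}))
    table = simulate_dataset(design, panel, effects, noise)
    return normalize.collapse_technical(normalize.normalize_to_standard(table, panel))


class TestMolPercent:
    def test_single_species_class_is_100(self):
        df = ratio_frame({("mock", 1): {"lyso-PE C20:3": 0.37}})
        out = mol_percent(df)
        assert out["mol_percent"].iloc[0] == pytest.approx(100.0)

    def test_proportions(self):
        df = ratio_frame(
            {("mock", 1): {"PCaa C36:2": 2.0, "PCaa C36:4": 2.0, "PCaa C38:4": 4.0}}
        )
        out = mol_percent(df).set_index("analyte")["mol_percent"]
        assert out["PCaa C36:2"] == pytest.approx(25.0)
        assert out["PCaa C38:4"] == pytest.approx(50.0)

    def test_scale_invariance(self):
        base = {("mock", 1): {"PCaa C36:2": 1.0, "PCaa C36:4": 3.0}}
        doubled = {("mock", 1): {"PCaa C36:2": 2.0, "PCaa C36:4": 6.0}}
        a = mol_percent(ratio_frame(base))["mol_percent"]
        b = mol_percent(ratio_frame(doubled))["mol_percent"]
        np.testing.assert_allclose(a, b)

    def test_sums_to_100_per_sample_and_class(self, small_panel):
        out = mol_percent(_collapsed(small_panel, seed=5))
        from lipidshift.composition import _annotate

        sums = _annotate(out).groupby(["sample_id", "lipid_class", "linkage"])[
            "mol_percent"
        ].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_zero_class_sum_flagged(self, caplog):
        import logging

        df = ratio_frame({("mock", 1): {"PCaa C36:2": 0.0, "PCaa C36:4": 0.0}})
        with caplog.at_level(logging.WARNING):
            out = mol_percent(df)
        assert out.empty


class TestDoubleBondRatio:
    SPEC = RatioSpec("PCae X:4/X:6", "PC", "ae", (4,), (6,))

    def _panel_with_db(self):
        from lipidshift.nomenclature import AnalytePanel, LipidClass, LipidSpecies, Linkage

        species = [
            LipidSpecies(LipidClass.PC, Linkage.AE, 36, 4),
            LipidSpecies(LipidClass.PC, Linkage.AE, 38, 4),
            LipidSpecies(LipidClass.PC, Linkage.AE, 38, 6),
            LipidSpecies(LipidClass.PC, Linkage.AA, 36, 4),
        ]
        return AnalytePanel(species, {("PC", "ae"): "IS PCae", ("PC", "aa"): "IS PCaa"})

    def test_identical_groups_give_100_percent(self):
        panel = self._panel_with_db()
        ratios = _collapsed(panel, noiseless=True)
        res = double_bond_ratio(ratios, self.SPEC, "APPswe", "mock", "mitochondria")
        assert res.percent_of_control == pytest.approx(100.0)
        assert res.p_value == pytest.approx(1.0)

    def test_numerator_doubled_gives_200_percent(self):
        panel = self._panel_with_db()
        eff = EffectSpec().set("mitochondria", "PCae X:4", 2.0)
        ratios = _collapsed(panel, effects=eff, noiseless=True)
        res = double_bond_ratio(ratios, self.SPEC, "APPswe", "mock", "mitochondria")
        assert res.percent_of_control == pytest.approx(200.0)

    def test_self_ratio_is_identically_100(self):
        panel = self._panel_with_db()
        spec = RatioSpec("X:4/X:4", "PC", "ae", (4,), (4,))
        ratios = _collapsed(panel, seed=9)
        res = double_bond_ratio(ratios, spec, "APPswe", "mock", "homogenate")
        assert res.percent_of_control == pytest.approx(100.0)
        assert res.p_value == pytest.approx(1.0)

    def test_combined_linkage_pools_aa_and_ae(self):
        panel = self._panel_with_db()
        eff = EffectSpec().set("mitochondria", "PCaa C36:4", 4.0)
        ratios = _collapsed(panel, effects=eff, noiseless=True)
        spec_ax = RatioSpec("PCax X:4/X:6", "PC", "ax", (4,), (6,))
        spec_ae = RatioSpec("PCae X:4/X:6", "PC", "ae", (4,), (6,))
        r_ax = double_bond_ratio(ratios, spec_ax, "APPswe", "mock", "mitochondria")
        r_ae = double_bond_ratio(ratios, spec_ae, "APPswe", "mock", "mitochondria")
        assert r_ae.percent_of_control == pytest.approx(100.0)
        assert r_ax.percent_of_control > 100.0

    def test_knockdown_of_denominator_raises_ratio(self):
        panel = self._panel_with_db()
        eff = EffectSpec().set("mitochondria", "PCae X:6", 0.8)
        ratios = _collapsed(panel, effects=eff, seed=3, n_bio=7)
        res = double_bond_ratio(ratios, self.SPEC, "APPswe", "mock", "mitochondria")
        assert res.percent_of_control > 100.0

    def test_empty_db_set_rejected(self):
        panel = self._panel_with_db()
        ratios = _collapsed(panel)
        with pytest.raises(ValueError, match="empty"):
            double_bond_ratio(
                ratios, RatioSpec("bad", "PC", "ae", (), (6,)), "APPswe", "mock", "homogenate"
            )

    def test_unmatched_db_set_rejected(self):
        panel = self._panel_with_db()
        ratios = _collapsed(panel)
        with pytest.raises(ValueError, match="no panel species"):
            double_bond_ratio(
                ratios,
                RatioSpec("bad", "PC", "ae", (11,), (6,)),
                "APPswe",
                "mock",
                "homogenate",
            )


class TestGroupAggregate:
    def test_uniform_planted_effect_hits_every_level(self, small_panel):
        eff = EffectSpec().set("mitochondria", "PCae", 1.3)
        ratios = _collapsed(small_panel, effects=eff, noiseless=True)
        out = group_aggregate(
            ratios, "double_bonds", "PC", "ae", "APPswe", "mock", "mitochondria"
        )
        np.testing.assert_allclose(out["fold_change"], 1.3, rtol=1e-12)

    def test_double_bond_groups_partition_class_signal(self, small_panel):
        ratios = _collapsed(small_panel, seed=2)
        from lipidshift.composition import _annotate

        ann = _annotate(ratios)
        pcae = ann[(ann["lipid_class"] == "PC") & (ann["linkage"] == "ae")]
        by_db = pcae.groupby(["sample_id", "double_bonds"])["ratio"].sum()
        total = pcae.groupby("sample_id")["ratio"].sum()
        np.testing.assert_allclose(by_db.groupby("sample_id").sum(), total)

    def test_carbon_bins_echo_config(self, small_panel):
        ratios = _collapsed(small_panel, seed=2)
        out = group_aggregate(
            ratios, "carbon_bin", "PC", "aa", "APPswe", "mock", "homogenate",
            carbon_bins=DEFAULT_CARBON_BINS,
        )
        assert set(out["level"]).issubset({"short", "mid", "long"})
        # the small panel's PCaa species are C36 -> all mid-chain
        assert list(out["level"]) == ["mid"]


class TestCarnitinePanel:
    def _frame(self, control, treated):
        values = {}
        for grp, reps in (("mock", control), ("APPswe", treated)):
            for i, rep in enumerate(reps, start=1):
                values[(grp, i)] = rep
        return ratio_frame(values)

    def test_minimal_panel_per_replicate_values(self):
        # C0=2, C2=1, C3=1: C0/C2 = 2, C2+C3 = 2, C0/(C2+C3) = 1, CX/(C2+C3) = 1
        rep_c = {"C0": 2.0, "C2": 1.0, "C3": 1.0}
        rep_t = {"C0": 4.0, "C2": 2.0, "C3": 2.0}  # x2 overall scale
        df = self._frame([rep_c, rep_c], [rep_t, rep_t])
        out = carnitine_panel(df, "APPswe", "mock", "homogenate").set_index("metric")
        # absolute sums double ...
        assert out.loc["C2+C3", "fold_change"] == pytest.approx(2.0)
        # ... but every ratio is invariant to the global scale
        for metric in ("C0/C2", "CX/(C2+C3)", "C0/(C2+C3)"):
            assert out.loc[metric, "fold_change"] == pytest.approx(1.0)

    def test_noiseless_planted_c2_c3_increase(self, small_panel):
        eff = EffectSpec()
        eff.set("homogenate", "C2", 1.5)
        eff.set("homogenate", "C3", 1.5)
        ratios = _collapsed(small_panel, effects=eff, noiseless=True)
        out = carnitine_panel(ratios, "APPswe", "mock", "homogenate").set_index("metric")
        assert out.loc["C2+C3", "fold_change"] == pytest.approx(1.5, rel=1e-12)
        assert out.loc["C0/C2", "fold_change"] == pytest.approx(1 / 1.5, rel=1e-12)
        assert out.loc["(C16+C18)/C2", "fold_change"] == pytest.approx(1 / 1.5, rel=1e-12)

    def test_missing_c3_flags_dependent_ratios(self):
        rep = {"C0": 2.0, "C2": 1.0}
        df = self._frame([rep, rep], [rep, rep])
        out = carnitine_panel(df, "APPswe", "mock", "homogenate").set_index("metric")
        assert out.loc["Codd/C3", "flag"] == "not_evaluable"
        assert out.loc["C0/C2", "flag"] == ""

    def test_no_carnitines_raises(self):
        df = ratio_frame({("mock", 1): {"PCaa C36:4": 1.0}})
        with pytest.raises(ValueError, match="carnitine"):
            carnitine_panel(df, "APPswe", "mock", "homogenate")
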