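"""Fold change / SEM / Student-t statistics and the trend classification."""

import numpy as np
import pandas as pd
import pytest

from conftest import ratio_frame
from lipidshift.differential import (
    LABELS,
    classify,
    species_stats,
    volcano_table,
)
from lipidshift.io import read_table, write_table

A, B = "PCaa C36:4", "PCaa C36:2"


def _frame_two_groups(control, treated, analyte=A):
    values = {}
    for i, v in enumerate(control, start=1):
        values[("mock", i)] = {**values.get(("mock", i), {}), analyte: v}
    for i, v in enumerate(treated, start=1):
        values[("APPswe", i)] = {**values.get(("APPswe", i), {}), analyte: v}
    return ratio_frame(values)


class TestSpeciesStats:
    def test_identity_contrast_is_null(self):
        df = _frame_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = species_stats(df, "APPswe", "mock", "homogenate").iloc[0]
        assert out["fold_change"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_pooled_t_closed_form(self):
        # pooled variance of {1,2,3} vs {4,5,6} is 1, se = sqrt(2/3),
        # t = 3/se = 3.674, df = 4 -> two-tailed p = 0.02131
        df = _frame_two_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out = species_stats(df, "APPswe", "mock", "homogenate").iloc[0]
        assert out["fold_change"] == pytest.approx(2.5)
        assert out["p_value"] == pytest.approx(0.02131, abs=2e-4)
        assert out["sem"] == pytest.approx(1.0 / 2.0 / np.sqrt(3))

    def test_degenerate_equal_constant_groups(self):
        df = _frame_two_groups([2.0, 2.0], [2.0, 2.0])
        out = species_stats(df, "APPswe", "mock", "homogenate").iloc[0]
        assert out["p_value"] == 1.0
        assert out["flag"] == "degenerate"

    def test_zero_control_mean_not_evaluable(self):
        df = _frame_two_groups([0.0, 0.0], [1.0, 2.0])
        out = species_stats(df, "APPswe", "mock", "homogenate").iloc[0]
        assert out["flag"] == "not_evaluable"
        assert np.isnan(out["fold_change"])

    def test_requires_two_replicates(self):
        df = _frame_two_groups([1.0], [2.0])
        with pytest.raises(ValueError, match="replicates"):
            species_stats(df, "APPswe", "mock", "homogenate")


class TestClassify:
    def test_unit_fold_change_is_unchanged(self):
        df = _frame_two_groups([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        st = species_stats(df, "APPswe", "mock", "homogenate")
        cls = classify(st)
        assert cls.labels["label"].iloc[0] == "unchanged"

    def test_trend_definition_single_species(self):
        st = pd.DataFrame(
            {
                "analyte": [A],
                "compartment": ["homogenate"],
                "fold_change": [1.3],
                "sem": [0.1],
                "p_value": [0.2],
                "n_treated": [7],
                "n_control": [7],
                "flag": [""],
            }
        )
        cls = classify(st)
        assert cls.avg_sem == pytest.approx(0.1)
        assert cls.labels["label"].iloc[0] == "trend_up"

    def test_significant_beats_trend_and_direction(self):
        st = pd.DataFrame(
            {
                "analyte": [A, B],
                "compartment": "homogenate",
                "fold_change": [1.5, 0.7],
                "sem": [0.1, 0.1],
                "p_value": [0.01, 0.04],
                "n_treated": 7,
                "n_control": 7,
                "flag": "",
            }
        )
        labels = classify(st).labels.set_index("analyte")["label"]
        assert labels[A] == "significant_up"
        assert labels[B] == "significant_down"

    def test_partition_is_exhaustive_and_exclusive(self, small_dataset, small_panel):
        from lipidshift import normalize

        ratios = normalize.collapse_technical(
            normalize.normalize_to_standard(small_dataset, small_panel)
        )
        st = species_stats(ratios, "APPswe", "mock", "mitochondria")
        cls = classify(st)
        assert sum(cls.counts().values()) == len(st)
        assert set(cls.labels["label"]).issubset(set(LABELS))

    def test_invariant_to_ordering_and_uniform_rescaling(self, small_dataset, small_panel):
        from lipidshift import normalize

        ratios = normalize.collapse_technical(
            normalize.normalize_to_standard(small_dataset, small_panel)
        )
        st1 = species_stats(ratios, "APPswe", "mock", "homogenate")
        shuffled = ratios.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuffled["ratio"] *= 5.0  # uniform rescale of every ratio
        st2 = species_stats(shuffled, "APPswe", "mock", "homogenate")
        l1 = classify(st1).labels.sort_values("analyte").reset_index(drop=True)
        l2 = classify(st2).labels.sort_values("analyte").reset_index(drop=True)
        pd.testing.assert_frame_equal(l1, l2)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            classify(pd.DataFrame(columns=["analyte", "compartment", "sem", "flag"]))


class TestVolcano:
    def _stats_and_cls(self):
        df = _frame_two_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        df2 = _frame_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], analyte=B)
        st = species_stats(pd.concat([df, df2]), "APPswe", "mock", "homogenate")
        return st, classify(st)

    def test_axis_values(self):
        st, cls = self._stats_and_cls()
        v = volcano_table(st, cls).set_index("analyte")
        assert v.loc[B, "log2_fold_change"] == pytest.approx(0.0)
        assert v.loc[B, "effect"] == pytest.approx(0.0)
        # p = 1 for the identical vectors, -log10(1) = 0
        assert v.loc[B, "neg_log10_p"] == pytest.approx(0.0)
        assert v.loc[A, "neg_log10_p"] == pytest.approx(-np.log10(st.set_index("analyte").loc[A, "p_value"]))

    def test_alpha_guide_line_height(self):
        # a species at exactly p = 0.05 sits on the volcano's dashed line
        st, cls = self._stats_and_cls()
        st.loc[0, "p_value"] = 0.05
        v = volcano_table(st, cls)
        assert v.loc[0, "neg_log10_p"] == pytest.approx(1.301, abs=1e-3)

    def test_zero_p_clamped_with_note(self):
        st, cls = self._stats_and_cls()
        st.loc[0, "p_value"] = 0.0
        v = volcano_table(st, cls)
        assert np.isfinite(v.loc[0, "neg_log10_p"])
        assert v.loc[0, "flag"] == "p_clamped"

    def test_export_round_trip(self, tmp_path):
        st, cls = self._stats_and_cls()
        v = volcano_table(st, cls)
        path = tmp_path / "volcano.tsv"
        write_table(v, path, {"seed": 0})
        back = read_table(path)
        back["flag"] = back["flag"].fillna("")
        pd.testing.assert_frame_equal(back, v, check_exact=False, rtol=1e-9)
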