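"""Per-species contrast statistics and trend/significance classification.

For every analyte of one compartment the contrast (treated vs. control) is
summarized as an x-fold change with the control mean fixed at 1: each treated
replicate's normalized ratio is divided by the control-group mean, the fold
change is the mean of those scaled values and the SEM their standard error.
The p-value comes from a classical pooled-variance two-tailed Student t-test
on the unscaled per-replicate ratios (no multiple-testing correction in the
primary analysis; a Benjamini-Hochberg column is carried as supplementary
output).

Classification mirrors the volcano-plot reading: a species is *significant*
when p <= alpha (direction from the sign of fold_change - 1) and otherwise a
*trend* when its effect strength |fold_change - 1| exceeds the average SEM of
the analysis set, the value drawn as the dashed guide lines next to 0 in the
volcano plots.  The average SEM is computed over whatever analysis set is
passed in — the whole panel for the panel-wide view, one lipid class for the
per-class views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import _value_column

__all__ = [
    "LABELS",
    "species_stats",
    "classify",
    "Classification",
    "volcano_table",
    "contrast_arrays",
]

LABELS = (
    "significant_up",
    "significant_down",
    "trend_up",
    "trend_down",
    "unchanged",
)


def contrast_arrays(
    ratios: pd.DataFrame,
    treated: str,
    control: str,
    compartment: str,
    value: str | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pivot a collapsed ratio table into aligned (analytes, treated, control)
    replicate matrices of shape (n_analytes, n_replicates)."""
    value = value or _value_column(ratios)
    sub = ratios[ratios["compartment"] == compartment]
    if sub.empty:
        raise ValueError(f"no records for compartment {compartment!r}")
    if "tech_replicate" in ratios.columns:
        raise ValueError(
            "species_stats expects a technically collapsed table; "
            "run collapse_technical first"
        )
    wide = sub.pivot_table(
        index="analyte", columns=["group", "bio_replicate"], values=value,
        sort=False,
    )
    for grp in (treated, control):
        if grp not in wide.columns.get_level_values(0):
            raise ValueError(f"group {grp!r} absent in compartment {compartment!r}")
    t = wide[treated]
    c = wide[control]
    if t.shape[1] < 2 or c.shape[1] < 2:
        raise ValueError("both groups need >= 2 biological replicates")
    return list(wide.index), t.to_numpy(), c.to_numpy()


def _pooled_t_p(t_mat: np.ndarray, c_mat: np.ndarray) -> np.ndarray:
    """Two-tailed pooled-variance Student t p-values row-wise; degenerate rows
    (zero variance in both groups) give p = 1 for equal means, p = 0 otherwise."""
    import warnings

    with warnings.catch_warnings():
        # degenerate (zero-variance) rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(t_mat, c_mat, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    var_t = np.nanvar(t_mat, axis=1, ddof=1)
    var_c = np.nanvar(c_mat, axis=1, ddof=1)
    degenerate = (var_t == 0) & (var_c == 0)
    if degenerate.any():
        equal = np.nanmean(t_mat, axis=1) == np.nanmean(c_mat, axis=1)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def species_stats(
    ratios: pd.DataFrame,
    treated: str,
    control: str,
    compartment: str,
) -> pd.DataFrame:
    """Per-species fold change, SEM, and Student-t p for one contrast in one
    compartment.

    Returns a table with columns (analyte, compartment, fold_change, sem,
    p_value, n_treated, n_control, flag); flag is '' normally,
    'not_evaluable' when the control mean is zero, 'degenerate' when both
    groups have zero variance.
    """
    analytes, t_mat, c_mat = contrast_arrays(ratios, treated, control, compartment)
    n_t = t_mat.shape[1]
    n_c = c_mat.shape[1]

    import warnings

    c_mean = np.nanmean(c_mat, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scaled_t = t_mat / c_mean[:, None]
        fold = np.nanmean(scaled_t, axis=1)
        sem = np.nanstd(scaled_t, axis=1, ddof=1) / np.sqrt(n_t)
    p = _pooled_t_p(t_mat, c_mat)

    flag = np.where(c_mean == 0, "not_evaluable", "")
    var_t = np.nanvar(t_mat, axis=1, ddof=1)
    var_c = np.nanvar(c_mat, axis=1, ddof=1)
    flag = np.where((var_t == 0) & (var_c == 0) & (flag == ""), "degenerate", flag)

    not_eval = flag == "not_evaluable"
    fold[not_eval] = np.nan
    sem[not_eval] = np.nan
    p[not_eval] = np.nan

    return pd.DataFrame(
        {
            "analyte": analytes,
            "compartment": compartment,
            "fold_change": fold,
            "sem": sem,
            "p_value": p,
            "n_treated": n_t,
            "n_control": n_c,
            "flag": flag,
        }
    )


@dataclass
class Classification:
    """Label table plus the average SEM that defines the trend guide lines."""

    labels: pd.DataFrame
    avg_sem: float
    alpha: float

    def counts(self) -> dict[str, int]:
        c = self.labels["label"].value_counts()
        return {label: int(c.get(label, 0)) for label in LABELS}

    @property
    def changed(self) -> pd.DataFrame:
        """Species labeled trend or significant, either direction."""
        return self.labels[self.labels["label"] != "unchanged"]


def classify(stats_table: pd.DataFrame, alpha: float = 0.05) -> Classification:
    """Assign exactly one of the five labels to every species of one
    compartment/contrast analysis set.

    avg_sem is the mean SEM over the evaluable species of the set; species
    flagged not-evaluable are labeled 'unchanged' and excluded from avg_sem.
    """
    if stats_table.empty:
        raise ValueError("classify: empty stats table")
    if stats_table["compartment"].nunique() > 1:
        raise ValueError("classify expects a single compartment per call")
    evaluable = stats_table["flag"] != "not_evaluable"
    if not evaluable.any():
        raise ValueError("classify: no evaluable species")
    avg_sem = float(stats_table.loc[evaluable, "sem"].mean())

    effect = stats_table["fold_change"] - 1.0
    significant = (stats_table["p_value"] <= alpha) & (effect != 0) & evaluable
    trend = (~significant) & (effect.abs() > avg_sem) & evaluable

    label = np.full(len(stats_table), "unchanged", dtype=object)
    label[significant & (effect > 0)] = "significant_up"
    label[significant & (effect < 0)] = "significant_down"
    label[trend & (effect > 0)] = "trend_up"
    label[trend & (effect < 0)] = "trend_down"

    out = stats_table[["analyte", "compartment"]].copy()
    out["label"] = label
    return Classification(labels=out, avg_sem=avg_sem, alpha=alpha)


def volcano_table(
    stats_table: pd.DataFrame, classification: Classification
) -> pd.DataFrame:
    """Plot-ready table: effect coordinate (log2 fold change, 0 at no change),
    -log10(p), labels, and the +/- avg_sem guide value on the effect scale.

    p = 0 (from degenerate comparisons) is clamped to the smallest positive
    float before the logarithm and noted in the flag column.
    """
    merged = stats_table.merge(
        classification.labels, on=["analyte", "compartment"], validate="one_to_one"
    )
    tiny = np.finfo(float).tiny
    clamped = merged["p_value"] == 0
    p = merged["p_value"].clip(lower=tiny)
    with np.errstate(divide="ignore"):
        merged["log2_fold_change"] = np.log2(merged["fold_change"])
    merged["effect"] = merged["fold_change"] - 1.0
    merged["neg_log10_p"] = -np.log10(p)
    merged["avg_sem"] = classification.avg_sem
    merged.loc[clamped, "flag"] = (
        merged.loc[clamped, "flag"].replace("", "p_clamped")
    )
    # supplementary BH-adjusted p-values (not used for classification)
    ok = merged["p_value"].notna()
    merged["p_bh"] = np.nan
    if ok.any():
        merged.loc[ok, "p_bh"] = multipletests(
            merged.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    cols = [
        "analyte",
        "compartment",
        "fold_change",
        "effect",
        "log2_fold_change",
        "p_value",
        "neg_log10_p",
        "p_bh",
        "label",
        "avg_sem",
        "flag",
    ]
    return merged[cols]
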