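"""Internal-standard normalization and the matrix-effect QC metric.

The processing order follows standard SRM practice: for every injection
(technical replicate) each analyte's counts-per-second signal is divided by
the signal of its class internal standard in the same injection, and the
resulting lipid/standard ratios are then averaged over the technical
triplicate of each biological sample.  Averaging ratios (not raw intensities)
makes the collapse commute with normalization exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nomenclature import AnalytePanel

__all__ = [
    "collapse_technical",
    "normalize_to_standard",
    "matrix_effect_qc",
    "QCReport",
]

log = logging.getLogger(__name__)

SAMPLE_KEYS = ["sample_id", "compartment", "group", "bio_replicate"]


def _value_column(table: pd.DataFrame) -> str:
    for col in ("mol_percent", "ratio", "intensity"):
        if col in table.columns:
            return col
    raise KeyError(
        "table has none of the value columns 'mol_percent', 'ratio', 'intensity'"
    )


def collapse_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Average the value column over technical replicates per (sample, analyte).

    Missing values within a triplicate are averaged over the present values
    with a logged warning; a (sample, analyte) with no values at all is
    dropped, also with a warning.  The output has no technical-replicate
    column.
    """
    value = _value_column(table)
    if "tech_replicate" not in table.columns:
        return table.copy()
    n_missing = int(table[value].isna().sum())
    if n_missing:
        log.warning(
            "collapse_technical: %d missing %s value(s); averaging over the "
            "present technical replicates",
            n_missing,
            value,
        )
    grouped = table.groupby(SAMPLE_KEYS + ["analyte"], sort=False, dropna=False)[value]
    out = grouped.mean().reset_index()
    dropped = out[value].isna()
    if dropped.any():
        log.warning(
            "collapse_technical: dropping %d (sample, analyte) record(s) with "
            "zero technical replicates",
            int(dropped.sum()),
        )
        out = out[~dropped].reset_index(drop=True)
    return out


def normalize_to_standard(
    table: pd.DataFrame, panel: AnalytePanel
) -> pd.DataFrame:
    """Divide each analyte's intensity by its class internal standard.

    Works per injection when a ``tech_replicate`` column is present.  An
    optional per-sample ``scale`` column (e.g. a protein-amount adjustment)
    divides analyte intensities before normalization.  Standards themselves
    are excluded from the output.  If a standard is zero or absent in an
    injection, every analyte of that standard's class is flagged invalid for
    that injection and excluded, with a warning.

    Zero analyte intensity yields ratio 0.0 and is retained: a zero SRM signal
    is informative, only a broken standard invalidates.
    """
    keys = SAMPLE_KEYS + (["tech_replicate"] if "tech_replicate" in table.columns else [])
    std_map = panel.standard_map()
    std_names = set(panel.standard_names)

    work = table.copy()
    if "scale" in work.columns:
        is_std = work["analyte"].isin(std_names)
        work.loc[~is_std, "intensity"] = (
            work.loc[~is_std, "intensity"] / work.loc[~is_std, "scale"]
        )

    standards = work.loc[
        work["analyte"].isin(std_names), keys + ["analyte", "intensity"]
    ].rename(columns={"analyte": "_standard", "intensity": "_std_intensity"})
    if standards.duplicated(subset=keys + ["_standard"]).any():
        raise ValueError("duplicate standard records per injection")

    species = work[work["analyte"].isin(std_map)].copy()
    unknown = set(work["analyte"]) - std_names - set(std_map)
    if unknown:
        log.warning(
            "normalize_to_standard: %d analyte(s) not in panel ignored: %s",
            len(unknown),
            sorted(unknown)[:5],
        )
    species["_standard"] = species["analyte"].map(std_map)
    species = species.merge(standards, on=keys + ["_standard"], how="left")
    std_vals = species["_std_intensity"].to_numpy()

    invalid = ~(std_vals > 0) | np.isnan(std_vals)
    if invalid.any():
        bad = species.loc[invalid, keys + ["_standard"]].drop_duplicates()
        log.warning(
            "normalize_to_standard: standard zero/absent in %d injection-class "
            "combination(s); affected analytes flagged invalid and excluded",
            len(bad),
        )
    species["ratio"] = np.where(invalid, np.nan, species["intensity"] / std_vals)
    out = species.loc[~invalid, keys + ["analyte", "ratio"]].reset_index(drop=True)
    return out


@dataclass
class QCReport:
    """Matrix-effect QC: percent change of mean standard intensity per
    non-reference group vs. the reference group.

    ``per_standard`` has one row per (compartment, standard, group) with the
    signed percent change; ``summary`` aggregates the absolute changes per
    compartment and pooled.
    """

    per_standard: pd.DataFrame
    summary: pd.DataFrame

    @property
    def max_abs_change(self) -> float:
        return float(self.per_standard["pct_change"].abs().max())

    @property
    def mean_abs_change(self) -> float:
        return float(self.per_standard["pct_change"].abs().mean())


def matrix_effect_qc(
    table: pd.DataFrame, panel: AnalytePanel, reference_group: str
) -> QCReport:
    """Quantify matrix effects from the internal standards.

    For each standard, compartment and non-reference group the metric is the
    percent change of the mean standard intensity relative to the reference
    group: ``(group - reference) / reference * 100``.  Standards missing in a
    group are reported as not-evaluable (NaN), never as 0.
    """
    groups = table["group"].unique()
    if len(groups) < 2:
        raise ValueError("matrix_effect_qc needs at least two groups")
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in table")

    std = table[table["analyte"].isin(panel.standard_names)]
    means = (
        std.groupby(["compartment", "analyte", "group"], sort=True)["intensity"]
        .mean()
        .unstack("group")
    )
    rows = []
    for (comp, analyte), row in means.iterrows():
        ref = row.get(reference_group, np.nan)
        for grp in groups:
            if grp == reference_group:
                continue
            val = row.get(grp, np.nan)
            if np.isnan(ref) or ref == 0 or np.isnan(val):
                pct = np.nan
            else:
                pct = (val - ref) / ref * 100.0
            rows.append(
                {
                    "compartment": comp,
                    "standard": analyte,
                    "group": grp,
                    "pct_change": pct,
                    "evaluable": not np.isnan(pct),
                }
            )
    per_standard = pd.DataFrame(rows)

    def _agg(df: pd.DataFrame) -> pd.Series:
        vals = df["pct_change"].abs()
        return pd.Series(
            {
                "max_abs_pct_change": vals.max(),
                "mean_abs_pct_change": vals.mean(),
                "n_standards": int(df["evaluable"].sum()),
            }
        )

    per_comp = (
        per_standard.groupby("compartment", sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    pooled = _agg(per_standard).to_frame().T
    pooled.insert(0, "compartment", "pooled")
    summary = pd.concat([per_comp, pooled], ignore_index=True)
    return QCReport(per_standard=per_standard, summary=summary)
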