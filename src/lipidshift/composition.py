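"""Within-class composition: mol%, double-bond ratio panels, saturation and
chain-length aggregates, and the carnitine carrier panel.

mol% expresses each species as a percentage of the summed normalized signal of
its (class, linkage) group per sample, so class-level abundance shifts cancel
and only redistribution within the class remains.  Ratio panels (e.g.
``PCae X:4 / PCae X:6``) are formed per biological replicate and then
contrasted, which is what makes reporting a SEM on the ratio meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import contrast_arrays
from .nomenclature import AcylCarnitine, AnalytePanel, LipidSpecies, parse_analyte
from .normalize import SAMPLE_KEYS, _value_column

__all__ = [
    "mol_percent",
    "RatioSpec",
    "RatioResult",
    "double_bond_ratio",
    "group_aggregate",
    "carnitine_panel",
    "DEFAULT_CARBON_BINS",
]

log = logging.getLogger(__name__)

# chain-length bins over the summed sn-1+sn-2 carbons
DEFAULT_CARBON_BINS = ((None, 33, "short"), (34, 39, "mid"), (40, None, "long"))


def _annotate(ratios: pd.DataFrame) -> pd.DataFrame:
    """Attach parsed class/linkage/carbons/double-bond columns."""
    out = ratios.copy()
    parsed = {name: parse_analyte(name) for name in out["analyte"].unique()}
    out["lipid_class"] = out["analyte"].map(
        {n: p.class_key[0] for n, p in parsed.items()}
    )
    out["linkage"] = out["analyte"].map({n: p.class_key[1] for n, p in parsed.items()})
    out["carbons"] = out["analyte"].map(
        {
            n: (p.carbons if isinstance(p, LipidSpecies) else p.chain_length)
            for n, p in parsed.items()
        }
    )
    out["double_bonds"] = out["analyte"].map(
        {
            n: (p.double_bonds if isinstance(p, LipidSpecies) else np.nan)
            for n, p in parsed.items()
        }
    )
    return out


def mol_percent(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-sample share (in %) of each species within its (class, linkage) set.

    Carnitines form their own group so the partition covers the whole panel.
    A sample whose class sum is zero has all species of that class flagged
    not-evaluable (dropped with a warning).
    """
    value = _value_column(ratios)
    keys = SAMPLE_KEYS + (
        ["tech_replicate"] if "tech_replicate" in ratios.columns else []
    )
    ann = _annotate(ratios)
    class_sum = ann.groupby(keys + ["lipid_class", "linkage"], sort=False)[
        value
    ].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * ann[value] / class_sum
    bad = class_sum == 0
    if bad.any():
        log.warning(
            "mol_percent: %d record(s) in sample/class groups with zero class "
            "sum flagged not-evaluable",
            int(bad.sum()),
        )
    out = ann.loc[~bad, keys + ["analyte"]].copy()
    out["mol_percent"] = pct[~bad]
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class RatioSpec:
    """A double-bond ratio panel entry: summed signal of the numerator
    double-bond set over the denominator set within one class.

    ``linkage`` may be 'aa', 'ae', 'lyso' or 'ax' (diacyl and ether pooled,
    as in the combined ``PCax X:4/X:6`` panels)."""

    name: str
    lipid_class: str
    linkage: str
    numerator_db: tuple[int, ...]
    denominator_db: tuple[int, ...]

    def linkages(self) -> tuple[str, ...]:
        return ("aa", "ae") if self.linkage == "ax" else (self.linkage,)


@dataclass
class RatioResult:
    """A contrasted per-replicate ratio: mean as % of the control mean
    (control = 100%), SEM in percentage points, pooled Student-t p."""

    name: str
    percent_of_control: float
    sem_percent: float
    p_value: float
    n_treated: int
    n_control: int
    treated_values: np.ndarray
    control_values: np.ndarray
    flag: str = ""


def _contrast_per_replicate(
    name: str,
    per_sample: pd.DataFrame,
    treated: str,
    control: str,
    compartment: str,
) -> RatioResult:
    """Contrast a per-sample scalar series (column 'value')."""
    from scipy import stats as sstats

    sub = per_sample[per_sample["compartment"] == compartment]
    t = sub.loc[sub["group"] == treated, "value"].to_numpy(dtype=float)
    c = sub.loc[sub["group"] == control, "value"].to_numpy(dtype=float)
    t = t[~np.isnan(t)]
    c = c[~np.isnan(c)]
    if len(t) == 0 or len(c) == 0 or np.nanmean(c) == 0:
        return RatioResult(name, np.nan, np.nan, np.nan, len(t), len(c), t, c,
                           flag="not_evaluable")
    c_mean = c.mean()
    scaled = t / c_mean * 100.0
    if len(t) >= 2 and len(c) >= 2:
        if t.var(ddof=1) == 0 and c.var(ddof=1) == 0:
            p = 1.0 if t.mean() == c.mean() else 0.0
        else:
            import warnings

            with warnings.catch_warnings():
                # near-identical replicate values (e.g. noiseless simulations)
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(sstats.ttest_ind(t, c, equal_var=True).pvalue)
        sem = float(scaled.std(ddof=1) / np.sqrt(len(t)))
    else:
        p, sem = np.nan, np.nan
    return RatioResult(
        name=name,
        percent_of_control=float(scaled.mean()),
        sem_percent=sem,
        p_value=p,
        n_treated=len(t),
        n_control=len(c),
        treated_values=t,
        control_values=c,
    )


def double_bond_ratio(
    ratios: pd.DataFrame,
    spec: RatioSpec,
    treated: str,
    control: str,
    compartment: str,
) -> RatioResult:
    """Per-replicate ratio of summed signals over two double-bond sets.

    Replicates whose denominator sum is zero are excluded with a warning; if
    all replicates are excluded the result is flagged not-evaluable.
    """
    if not spec.numerator_db or not spec.denominator_db:
        raise ValueError(f"ratio spec {spec.name!r}: empty double-bond set")
    ann = _annotate(ratios)
    keys = SAMPLE_KEYS
    in_class = (ann["lipid_class"] == spec.lipid_class) & ann["linkage"].isin(
        spec.linkages()
    )
    num_mask = in_class & ann["double_bonds"].isin(spec.numerator_db)
    den_mask = in_class & ann["double_bonds"].isin(spec.denominator_db)
    if not num_mask.any() or not den_mask.any():
        raise ValueError(
            f"ratio spec {spec.name!r}: no panel species match "
            f"{spec.lipid_class}{spec.linkage} db sets "
            f"{spec.numerator_db}/{spec.denominator_db}"
        )
    value = _value_column(ratios)
    num = ann[num_mask].groupby(keys, sort=False)[value].sum()
    den = ann[den_mask].groupby(keys, sort=False)[value].sum()
    per_sample = pd.concat(
        {"num": num, "den": den}, axis=1
    ).reset_index()
    zero_den = per_sample["den"] == 0
    if zero_den.any():
        log.warning(
            "double_bond_ratio %s: excluding %d replicate(s) with zero denominator",
            spec.name,
            int(zero_den.sum()),
        )
    per_sample = per_sample[~zero_den]
    per_sample["value"] = per_sample["num"] / per_sample["den"]
    return _contrast_per_replicate(spec.name, per_sample, treated, control, compartment)


def group_aggregate(
    ratios: pd.DataFrame,
    by: str,
    lipid_class: str,
    linkage: str,
    treated: str,
    control: str,
    compartment: str,
    carbon_bins=DEFAULT_CARBON_BINS,
) -> pd.DataFrame:
    """Summed-signal fold change vs. control per double-bond count or
    chain-length bin within one (class, linkage) set.

    ``by`` is 'double_bonds' or 'carbon_bin'.  Empty levels are omitted.
    Returns one row per level with percent_of_control, sem, p and n.
    """
    if by not in ("double_bonds", "carbon_bin"):
        raise ValueError(f"unknown grouping {by!r}")
    ann = _annotate(ratios)
    linkages = ("aa", "ae") if linkage == "ax" else (linkage,)
    sub = ann[(ann["lipid_class"] == lipid_class) & ann["linkage"].isin(linkages)]
    if sub.empty:
        raise ValueError(f"no species for class {lipid_class}{linkage}")
    sub = sub.copy()
    if by == "carbon_bin":
        def _bin(c: float) -> str | None:
            for lo, hi, name in carbon_bins:
                if (lo is None or c >= lo) and (hi is None or c <= hi):
                    return name
            return None

        sub["level"] = sub["carbons"].map(_bin)
        sub = sub[sub["level"].notna()]
    else:
        sub["level"] = sub["double_bonds"].astype(int)

    value = _value_column(ratios)
    rows = []
    for level, df in sub.groupby("level", sort=True):
        per_sample = (
            df.groupby(SAMPLE_KEYS, sort=False)[value].sum().rename("value").reset_index()
        )
        res = _contrast_per_replicate(
            f"{lipid_class}{linkage} {by}={level}",
            per_sample,
            treated,
            control,
            compartment,
        )
        rows.append(
            {
                "level": level,
                "percent_of_control": res.percent_of_control,
                "fold_change": res.percent_of_control / 100.0,
                "sem_percent": res.sem_percent,
                "p_value": res.p_value,
                "n_treated": res.n_treated,
                "n_control": res.n_control,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# carnitine carrier panel
# ---------------------------------------------------------------------------

CARNITINE_METRICS = (
    "C0",
    "C2",
    "C3",
    "C2+C3",
    "Ceven",
    "Codd",
    "CX",
    "C0/C2",
    "Ceven/C2",
    "Codd/C3",
    "CX/(C2+C3)",
    "C0/(C2+C3)",
    "(C16+C18)/C2",
)


def carnitine_panel(
    ratios: pd.DataFrame,
    treated: str,
    control: str,
    compartment: str,
) -> pd.DataFrame:
    """Carnitine carrier metrics contrasted treated vs. control.

    Per biological replicate: C0, C2, C3 are single-analyte signals;
    Ceven sums even-chain acyl-carnitines with chain >= 4 (C2 excluded, it is
    the denominator of its own ratios); Codd sums odd chains >= 5 (C3
    excluded); CX sums all acyl-carnitines (chain >= 2, free carnitine C0
    never counts).  Ratios are formed per replicate, then contrasted as % of
    control with a pooled Student-t p.  Metrics whose inputs are absent or
    whose denominator is zero are flagged not-evaluable.
    """
    value = _value_column(ratios)
    carn = ratios[
        ratios["analyte"].str.fullmatch(r"C\s*\d+", case=False, na=False)
    ].copy()
    if carn.empty:
        raise ValueError("no carnitine analytes in table")
    carn["chain"] = carn["analyte"].map(
        lambda n: parse_analyte(n).chain_length
    )

    wide = carn.pivot_table(
        index=SAMPLE_KEYS, columns="chain", values=value, sort=False
    )
    chains = list(wide.columns)

    def col(n: int) -> pd.Series | None:
        return wide[n] if n in wide.columns else None

    def ssum(predicate) -> pd.Series:
        cols = [c for c in chains if predicate(c)]
        return wide[cols].sum(axis=1) if cols else pd.Series(0.0, index=wide.index)

    base: dict[str, pd.Series | None] = {
        "C0": col(0),
        "C2": col(2),
        "C3": col(3),
        "Ceven": ssum(lambda c: c >= 4 and c % 2 == 0),
        "Codd": ssum(lambda c: c >= 5 and c % 2 == 1),
        "CX": ssum(lambda c: c >= 2),
    }
    if base["C2"] is not None and base["C3"] is not None:
        base["C2+C3"] = base["C2"] + base["C3"]
    else:
        base["C2+C3"] = None
    c16, c18 = col(16), col(18)
    base["C16+C18"] = c16 + c18 if (c16 is not None and c18 is not None) else None

    def ratio(num: str, den: str) -> pd.Series | None:
        a, b = base.get(num), base.get(den)
        if a is None or b is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            r = a / b
        return r.where(b != 0)

    metrics: dict[str, pd.Series | None] = {
        "C0": base["C0"],
        "C2": base["C2"],
        "C3": base["C3"],
        "C2+C3": base["C2+C3"],
        "Ceven": base["Ceven"],
        "Codd": base["Codd"],
        "CX": base["CX"],
        "C0/C2": ratio("C0", "C2"),
        "Ceven/C2": ratio("Ceven", "C2"),
        "Codd/C3": ratio("Codd", "C3"),
        "CX/(C2+C3)": ratio("CX", "C2+C3"),
        "C0/(C2+C3)": ratio("C0", "C2+C3"),
        "(C16+C18)/C2": ratio("C16+C18", "C2"),
    }

    idx = wide.index.to_frame(index=False)
    rows = []
    for name in CARNITINE_METRICS:
        series = metrics[name]
        if series is None:
            rows.append(
                {
                    "metric": name,
                    "percent_of_control": np.nan,
                    "fold_change": np.nan,
                    "sem_percent": np.nan,
                    "p_value": np.nan,
                    "n_treated": 0,
                    "n_control": 0,
                    "flag": "not_evaluable",
                }
            )
            continue
        per_sample = idx.copy()
        per_sample["value"] = series.to_numpy()
        res = _contrast_per_replicate(name, per_sample, treated, control, compartment)
        rows.append(
            {
                "metric": name,
                "percent_of_control": res.percent_of_control,
                "fold_change": res.percent_of_control / 100.0,
                "sem_percent": res.sem_percent,
                "p_value": res.p_value,
                "n_treated": res.n_treated,
                "n_control": res.n_control,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows)
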