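"""Cross-compartment comparison: the Fisher-exact shift test on up/down counts
and the Venn partition of changed species.

The shift test asks whether the proportion of increased vs. decreased species
(trend or significant, either way) differs between two compartments — the
2x2 table has compartments as rows and {increased, decreased} as columns.
The two-sided Fisher p uses the minimum-likelihood convention: the sum of
hypergeometric point probabilities of every table with the same margins whose
probability does not exceed that of the observed table (the convention of
standard statistical software).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["fisher_exact", "ShiftResult", "shift_test", "VennPartition", "venn_partition"]

# relative tolerance guarding floating-point ties among point probabilities
_TIE_RTOL = 1e-12


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums the hypergeometric probabilities (margins fixed) of all tables whose
    point probability is <= that of the observed table, within relative
    tolerance 1e-12 to absorb float ties.  An all-zero table has p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError(f"negative counts in table {t.tolist()}")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1 = a + b          # row-1 margin
    c1 = a + c          # column-1 margin
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * (1.0 + _TIE_RTOL)
    if mask.all():
        return 1.0
    return min(float(pmf[mask].sum()), 1.0)


@dataclass
class ShiftResult:
    """2x2 up/down counts across two compartments and the Fisher-exact p.

    ``table`` rows are the two compartments, columns (increased, decreased);
    counts are of species labeled trend or significant.  ``p_value`` is NaN
    (not evaluable) when a compartment has no changed species at all.
    """

    compartments: tuple[str, str]
    table: np.ndarray
    p_value: float

    def as_dict(self) -> dict:
        return {
            "compartments": list(self.compartments),
            "increased": [int(self.table[0, 0]), int(self.table[1, 0])],
            "decreased": [int(self.table[0, 1]), int(self.table[1, 1])],
            "p_value": None if np.isnan(self.p_value) else float(self.p_value),
        }


def _updown_counts(labels) -> tuple[int, int]:
    lab = labels["label"]
    up = int(lab.isin(["trend_up", "significant_up"]).sum())
    down = int(lab.isin(["trend_down", "significant_down"]).sum())
    return up, down


def shift_test(labels_a, labels_b) -> ShiftResult:
    """Fisher-exact comparison of increased/decreased species counts between
    two compartments' label tables (same analysis set)."""
    _check_aligned(labels_a, labels_b)
    up_a, down_a = _updown_counts(labels_a)
    up_b, down_b = _updown_counts(labels_b)
    table = np.array([[up_a, down_a], [up_b, down_b]], dtype=np.int64)
    comp_a = str(labels_a["compartment"].iloc[0])
    comp_b = str(labels_b["compartment"].iloc[0])
    if (up_a + down_a == 0) or (up_b + down_b == 0):
        p = float("nan")
    else:
        p = fisher_exact(table)
    return ShiftResult(compartments=(comp_a, comp_b), table=table, p_value=p)


@dataclass
class VennPartition:
    """Partition of the changed-species union of two compartments.

    Direction is the label direction (up/down, trend or significant pooled);
    every changed species falls in exactly one cell."""

    a_only_up: list[str]
    a_only_down: list[str]
    b_only_up: list[str]
    b_only_down: list[str]
    shared_up: list[str]
    shared_down: list[str]
    shared_opposite: list[str]

    def counts(self) -> dict[str, int]:
        return {
            "a_only_up": len(self.a_only_up),
            "a_only_down": len(self.a_only_down),
            "b_only_up": len(self.b_only_up),
            "b_only_down": len(self.b_only_down),
            "shared_up": len(self.shared_up),
            "shared_down": len(self.shared_down),
            "shared_opposite": len(self.shared_opposite),
        }

    @property
    def total(self) -> int:
        return sum(self.counts().values())


def _check_aligned(labels_a, labels_b) -> None:
    set_a = set(labels_a["analyte"])
    set_b = set(labels_b["analyte"])
    if set_a != set_b:
        missing = sorted(set_a ^ set_b)
        raise ValueError(
            f"label tables cover different analyte sets; differing analytes: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )


def _direction(label: str) -> int:
    if label in ("trend_up", "significant_up"):
        return 1
    if label in ("trend_down", "significant_down"):
        return -1
    return 0


def venn_partition(labels_a, labels_b) -> VennPartition:
    """Assign every species changed in either compartment to one Venn cell."""
    _check_aligned(labels_a, labels_b)
    dir_a = {r.analyte: _direction(r.label) for r in labels_a.itertuples()}
    dir_b = {r.analyte: _direction(r.label) for r in labels_b.itertuples()}
    cells = VennPartition([], [], [], [], [], [], [])
    for analyte in sorted(dir_a):
        da, db = dir_a[analyte], dir_b[analyte]
        if da == 0 and db == 0:
            continue
        if da != 0 and db == 0:
            (cells.a_only_up if da > 0 else cells.a_only_down).append(analyte)
        elif da == 0 and db != 0:
            (cells.b_only_up if db > 0 else cells.b_only_down).append(analyte)
        elif da == db:
            (cells.shared_up if da > 0 else cells.shared_down).append(analyte)
        else:
            cells.shared_opposite.append(analyte)
    return cells
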