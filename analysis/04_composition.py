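"""Within-class composition: mol% re-analysis and double-bond ratio panels.

mol% removes class-level abundance shifts, isolating redistribution within
each class.  The double-bond ratio panels (X:4 over X:6, X:4 over X:5+X:6)
proxy the omega-6/omega-3 balance: arachidonic acid carries four double
bonds, EPA five, DHA six.

Writes results/volcano_molpct_<compartment>.tsv and results/ratio_panels.tsv.
"""

from pathlib import Path

import pandas as pd

from lipidshift.composition import RatioSpec, double_bond_ratio, group_aggregate, mol_percent
from lipidshift.differential import classify, species_stats, volcano_table
from lipidshift.io import read_table, write_table

OUT = Path(__file__).resolve().parents[1] / "results"
TREATED, CONTROL = "APPswe", "mock"

RATIO_PANEL = [
    RatioSpec("PCae X:4/X:6", "PC", "ae", (4,), (6,)),
    RatioSpec("PCae X:4/(X:5+X:6)", "PC", "ae", (4,), (5, 6)),
    RatioSpec("PCax X:4/X:6", "PC", "ax", (4,), (6,)),
    RatioSpec("PEaa X:4/X:6", "PE", "aa", (4,), (6,)),
]


def main() -> None:
    ratios = read_table(OUT / "ratios.tsv")

    molp = mol_percent(ratios)
    for comp in ("mitochondria", "homogenate"):
        stats = species_stats(molp, TREATED, CONTROL, comp)
        cls = classify(stats)
        write_table(volcano_table(stats, cls), OUT / f"volcano_molpct_{comp}.tsv")
        n_changed = len(cls.changed)
        print(f"mol% {comp}: {n_changed} species past the guide lines")

    rows = []
    print("\ndouble-bond ratio panels (mitochondria, % of mock +/- SEM):")
    for spec in RATIO_PANEL:
        res = double_bond_ratio(ratios, spec, TREATED, CONTROL, "mitochondria")
        rows.append(
            {
                "name": res.name,
                "percent_of_control": res.percent_of_control,
                "sem_percent": res.sem_percent,
                "p_value": res.p_value,
            }
        )
        star = "*" if res.p_value <= 0.05 else " "
        print(
            f"  {res.name:<22} {res.percent_of_control:6.1f}% +/- "
            f"{res.sem_percent:4.1f}%  p = {res.p_value:.3g} {star}"
        )
    write_table(pd.DataFrame(rows), OUT / "ratio_panels.tsv")

    agg = group_aggregate(
        ratios, "double_bonds", "PE", "aa", TREATED, CONTROL, "mitochondria"
    )
    write_table(agg, OUT / "peaa_by_double_bonds.tsv")
    print("\nPEaa summed fold change by double-bond count (mitochondria):")
    for row in agg.itertuples():
        print(f"  {int(row.level)} double bonds: {row.fold_change:.2f}x  p = {row.p_value:.3g}")


if __name__ == "__main__":
    main()
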