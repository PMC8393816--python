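"""Carnitine carrier panel in total cell homogenate.

C2 (acetyl-) and C3 (propionyl-) carnitine are beta-oxidation end products;
free carnitine (C0) and the long acyl-carnitines feed the shuttle.  Falling
C0/C2-type ratios with rising C2+C3 indicate increased beta-oxidation
throughput or an altered carnitine shuttle.

Writes results/carnitine_panel.tsv.
"""

from pathlib import Path

from lipidshift.composition import carnitine_panel
from lipidshift.io import read_table, write_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ratios = read_table(OUT / "ratios.tsv")
    panel = carnitine_panel(ratios, "APPswe", "mock", "homogenate")
    write_table(panel, OUT / "carnitine_panel.tsv")
    print("carnitine carrier panel, homogenate (% of mock):")
    for row in panel.itertuples():
        if row.flag:
            print(f"  {row.metric:<14} not evaluable")
            continue
        star = "*" if row.p_value <= 0.05 else " "
        print(
            f"  {row.metric:<14} {row.percent_of_control:6.1f}% +/- "
            f"{row.sem_percent:4.1f}%  p = {row.p_value:.3g} {star}"
        )


if __name__ == "__main__":
    main()
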