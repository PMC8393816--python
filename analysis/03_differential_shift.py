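"""Per-species differential statistics and the compartment shift test.

For each compartment: fold change (mock mean = 1), SEM, pooled Student-t p,
and the five-way classification (significant up/down at p <= 0.05, trend
up/down past the average-SEM guide line, unchanged).  Then the Fisher-exact
shift test on the up/down counts between mitochondria and homogenate, and
the Venn partition of changed species.

Writes results/volcano_<compartment>.tsv, results/shift_test.json.
"""

import json
from pathlib import Path

from lipidshift.compare import shift_test, venn_partition
from lipidshift.differential import classify, species_stats, volcano_table
from lipidshift.io import read_table, write_table

OUT = Path(__file__).resolve().parents[1] / "results"
TREATED, CONTROL = "APPswe", "mock"


def main() -> None:
    ratios = read_table(OUT / "ratios.tsv")
    labels = {}
    for comp in ("mitochondria", "homogenate"):
        stats = species_stats(ratios, TREATED, CONTROL, comp)
        cls = classify(stats, alpha=0.05)
        write_table(volcano_table(stats, cls), OUT / f"volcano_{comp}.tsv")
        labels[comp] = cls.labels
        counts = cls.counts()
        up = counts["trend_up"] + counts["significant_up"]
        down = counts["trend_down"] + counts["significant_down"]
        print(
            f"{comp:<12} avg SEM {cls.avg_sem:.3f} | "
            f"{up} species up ({counts['significant_up']} significant), "
            f"{down} down ({counts['significant_down']} significant), "
            f"{counts['unchanged']} unchanged"
        )

    shift = shift_test(labels["mitochondria"], labels["homogenate"])
    venn = venn_partition(labels["mitochondria"], labels["homogenate"])
    print(
        f"\nshift test (mito {shift.table[0].tolist()} vs hom "
        f"{shift.table[1].tolist()}): Fisher p = {shift.p_value:.3g}"
    )
    print(f"venn cells: {venn.counts()}")
    payload = {"shift_test": shift.as_dict(), "venn": venn.counts()}
    with open(OUT / "shift_test.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
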