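"""Internal-standard normalization and matrix-effect QC.

Checks that the spiked deuterated standards behave comparably across
genotypes (matrix effect of a few percent at most), then divides every
analyte by its class standard per injection and averages the technical
triplicates.  Writes results/ratios.tsv and results/matrix_qc.tsv.
"""

from pathlib import Path

from lipidshift.io import read_measurements, write_table
from lipidshift.normalize import collapse_technical, matrix_effect_qc, normalize_to_standard
from lipidshift.synthetic import default_panel

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = default_panel()
    table = read_measurements(OUT / "measurements.tsv")

    qc = matrix_effect_qc(table, panel, reference_group="mock")
    write_table(qc.summary, OUT / "matrix_qc.tsv")
    print("matrix-effect QC (percent change of standard means vs. mock):")
    for row in qc.summary.itertuples():
        print(
            f"  {row.compartment:<12} max |change| {row.max_abs_pct_change:5.2f}%  "
            f"mean |change| {row.mean_abs_pct_change:5.2f}%"
        )

    ratios = collapse_technical(normalize_to_standard(table, panel))
    write_table(ratios, OUT / "ratios.tsv")
    print(f"\nnormalized {ratios['analyte'].nunique()} analytes; wrote {OUT / 'ratios.tsv'}")


if __name__ == "__main__":
    main()
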