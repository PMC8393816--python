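"""Generate the synthetic study dataset.

Simulates the full design — homogenate and mitochondria compartments, mock
vs. APPswe groups, n = 7 biological replicates in technical triplicate, the
226-analyte default panel — under a planted-effect scenario with the broad
structure of an amyloidogenic cell model: widespread mitochondrial increases
(strongest in PE classes), knocked-down polyunsaturated plasmalogens, and
elevated C2/C3/C5 carnitines in homogenate.

Writes results/measurements.tsv and results/panel.tsv.
"""

from pathlib import Path

from lipidshift.io import write_table
from lipidshift.synthetic import (
    NoiseSpec,
    StudyDesign,
    appswe_like_effects,
    default_panel,
    simulate_dataset,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = default_panel()
    design = StudyDesign()
    table = simulate_dataset(design, panel, appswe_like_effects(), NoiseSpec(seed=SEED))
    OUT.mkdir(exist_ok=True)
    panel.to_file(OUT / "panel.tsv")
    write_table(table, OUT / "measurements.tsv", {"seed": SEED})
    n_samples = table["sample_id"].nunique()
    print(
        f"simulated {len(table)} intensities: {len(panel)} analytes "
        f"(+{len(panel.standard_names)} standards) x {n_samples} samples "
        f"x {design.n_tech} technical replicates"
    )
    print(f"wrote {OUT / 'measurements.tsv'} and {OUT / 'panel.tsv'}")


if __name__ == "__main__":
    main()
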