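import numpy as np
import pandas as pd
import pytest

from lipidshift.nomenclature import (
    AcylCarnitine,
    AnalytePanel,
    LipidClass,
    LipidSpecies,
    Linkage,
)
from lipidshift.synthetic import NoiseSpec, StudyDesign, default_panel, simulate_dataset

NOISELESS = dict(
    biological_cv=0.0,
    technical_cv=0.0,
    standard_matrix_amplitude=0.0,
    standard_technical_cv=0.0,
)


@pytest.fixture(scope="session")
def panel226() -> AnalytePanel:
    return default_panel()


@pytest.fixture()
def small_panel() -> AnalytePanel:
    """A compact panel: a few PCaa/PCae species plus the minimal carnitine set."""
    species = [
        LipidSpecies(LipidClass.PC, Linkage.AA, 36, 2),
        LipidSpecies(LipidClass.PC, Linkage.AA, 36, 4),
        LipidSpecies(LipidClass.PC, Linkage.AE, 36, 4),
        LipidSpecies(LipidClass.PC, Linkage.AE, 38, 6),
        LipidSpecies(LipidClass.PE, Linkage.LYSO, 20, 3),
        AcylCarnitine(0),
        AcylCarnitine(2),
        AcylCarnitine(3),
        AcylCarnitine(16),
        AcylCarnitine(18),
    ]
    standards = {
        ("PC", "aa"): "IS PCaa",
        ("PC", "ae"): "IS PCae",
        ("PE", "lyso"): "IS lyso-PE",
        ("carnitine", "short"): "IS carn short",
        ("carnitine", "long"): "IS carn long",
    }
    return AnalytePanel(species, standards)


@pytest.fixture()
def small_design() -> StudyDesign:
    return StudyDesign(n_bio=4, n_tech=3)


@pytest.fixture()
def small_dataset(small_panel, small_design) -> pd.DataFrame:
    return simulate_dataset(small_design, small_panel, None, NoiseSpec(seed=7))


def flat_pc_panel(n_species: int) -> AnalytePanel:
    """Many distinct PCaa species behind one standard, for calibration runs."""
    species = []
    carbons = 10
    while len(species) < n_species:
        for db in range(13):
            if len(species) >= n_species:
                break
            species.append(LipidSpecies(LipidClass.PC, Linkage.AA, carbons, db))
        carbons += 2
    return AnalytePanel(species, {("PC", "aa"): "IS PC"})


def ratio_frame(values: dict, compartment: str = "homogenate") -> pd.DataFrame:
    """Build a collapsed RatioTable from {(group, bio): {analyte: ratio}}."""
    rows = []
    for (group, bio), analytes in values.items():
        for analyte, ratio in analytes.items():
            rows.append(
                {
                    "sample_id": f"{compartment}:{group}:{bio}",
                    "compartment": compartment,
                    "group": group,
                    "bio_replicate": bio,
                    "analyte": analyte,
                    "ratio": float(ratio),
                }
            )
    return pd.DataFrame(rows)
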