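"""Synthetic measurement tables with the statistical structure the pipeline assumes.

The generator emulates the output of a triplicate SRM (selected reaction
monitoring) acquisition of a two-compartment, two-genotype cell-culture study:
for every (compartment, group, biological replicate, technical replicate,
analyte) one counts-per-second intensity is produced, plus the intensities of
the spiked per-class internal standards.

Noise model
-----------
Multiplicative log-normal throughout, parametrized by coefficients of
variation.  A biological factor is drawn once per (sample, analyte) and shared
by the sample's technical replicates; a technical factor is drawn
independently per injection.  Log-normal factors are mean-1
(``mu = -sigma^2/2``), so a planted fold change is also the expectation of the
generated fold change.  Internal standards are spiked at a fixed amount and
carry only technical noise (tighter than analyte noise, see ``NoiseSpec``)
plus a small per-group multiplicative "matrix effect" shift that exercises the
QC metric downstream.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` children, in the fixed order
(baselines, biological, technical, standards, matrix), so identical seeds give
bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import (
    AcylCarnitine,
    Analyte,
    AnalytePanel,
    LipidSpecies,
    parse_analyte,
)

__all__ = [
    "StudyDesign",
    "EffectSpec",
    "NoiseSpec",
    "PanelConfig",
    "default_panel",
    "simulate_dataset",
    "appswe_like_effects",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the study: 2 compartments x 2 genotypes x n=7
    biological replicates measured in technical triplicate by default."""

    compartments: tuple[str, ...] = ("homogenate", "mitochondria")
    groups: tuple[str, ...] = ("mock", "APPswe")
    reference_group: str = "mock"
    n_bio: int = 7
    n_tech: int = 3

    def __post_init__(self) -> None:
        if self.n_bio < 2:
            raise ValueError(f"n_bio must be >= 2, got {self.n_bio}")
        if self.n_tech < 1:
            raise ValueError(f"n_tech must be >= 1, got {self.n_tech}")
        if self.reference_group not in self.groups:
            raise ValueError(
                f"reference group {self.reference_group!r} not among groups {self.groups}"
            )
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("duplicate compartment labels")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes, as CVs on the positive scale.

    ``standard_matrix_amplitude`` is the expected absolute relative shift of a
    standard's intensity in a non-reference group (the matrix effect);
    the default 0.012 mirrors an average matrix effect of ~1.2%.
    ``standard_technical_cv`` is the repeatability of the spiked standards,
    tighter than analyte noise because the spiked amount is constant.
    """

    biological_cv: float = 0.15
    technical_cv: float = 0.05
    standard_matrix_amplitude: float = 0.012
    standard_technical_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("biological_cv", "technical_cv", "standard_technical_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.standard_matrix_amplitude < 0:
            raise ValueError("standard_matrix_amplitude must be >= 0")


class SelectorError(ValueError):
    """An effect selector matched no species in the panel."""


@dataclass
class EffectSpec:
    """Planted fold changes, keyed by (compartment, selector).

    Selector grammar (case-sensitive on class tokens, as in the panel dialect):

    - exact analyte name: ``"PEaa C38:3"``, ``"C2"``
    - class+linkage: ``"PCaa"``, ``"PCae"``, ``"lyso-PC"``, ``"PEaa"``,
      ``"PEae"``, ``"lyso-PE"``, ``"PG"``, ``"carnitine"``
    - class+linkage restricted to a double-bond count: ``"PCae X:4"``
      (every PCae species with 4 double bonds), mirroring the panel notation.

    Unselected species default to fold change 1.0; overlapping selectors
    compose multiplicatively.
    """

    effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (comp, sel), fc in self.effects.items():
            if fc <= 0:
                raise ValueError(
                    f"fold change must be > 0, got {fc} for ({comp!r}, {sel!r})"
                )

    def set(self, compartment: str, selector: str, fold_change: float) -> "EffectSpec":
        if fold_change <= 0:
            raise ValueError("fold change must be > 0")
        self.effects[(compartment, selector)] = fold_change
        return self

    @staticmethod
    def _match(selector: str, species: Sequence[Analyte]) -> list[str]:
        sel = selector.strip()
        # class selector with optional double-bond restriction, e.g. "PCae X:4"
        m_db = None
        class_token = sel
        if " X:" in sel:
            class_token, db_part = sel.split(" X:")
            m_db = int(db_part)
        names: list[str] = []
        for sp in species:
            if sp.name == sel:
                return [sp.name]
            if isinstance(sp, AcylCarnitine):
                if class_token.lower() in ("carnitine", "carnitines") and m_db is None:
                    names.append(sp.name)
                continue
            cls, link = sp.class_key
            token = f"lyso-{cls}" if link == "lyso" else (cls if cls == "PG" else cls + link)
            if token == class_token and (m_db is None or sp.double_bonds == m_db):
                names.append(sp.name)
        return names

    def resolve(self, panel: AnalytePanel, compartment: str) -> dict[str, float]:
        """Per-analyte fold changes for one compartment; raises SelectorError
        for selectors that match nothing."""
        out = {name: 1.0 for name in panel.species_names}
        for (comp, sel), fc in self.effects.items():
            if comp != compartment:
                continue
            matched = self._match(sel, panel.species)
            if not matched:
                raise SelectorError(
                    f"effect selector {sel!r} (compartment {comp!r}) matched no "
                    "species in the panel"
                )
            for name in matched:
                out[name] *= fc
        return out


# ---------------------------------------------------------------------------
# default panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelConfig:
    """Per-class carbon/double-bond grids for the default reconstructed panel.

    Ranges are inclusive; carbons step by 2 (even sum compositions).  The
    default grids yield 226 analytes in total (the documented default panel
    size): PCaa 49, PCae 49, lyso-PC 20, PEaa 35, PEae 35, lyso-PE 9, PG 10,
    carnitines 19.
    """

    lipid_grids: Mapping[tuple[str, str], tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=lambda: {
            ("PC", "aa"): ((30, 42), (0, 6)),
            ("PC", "ae"): ((30, 42), (0, 6)),
            ("PC", "lyso"): ((16, 24), (0, 3)),
            ("PE", "aa"): ((34, 42), (0, 6)),
            ("PE", "ae"): ((36, 44), (0, 6)),
            ("PE", "lyso"): ((18, 22), (0, 2)),
            ("PG", "aa"): ((34, 36), (1, 5)),
        }
    )
    carnitine_chains: tuple[int, ...] = (
        0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 20,
    )
    standards: Mapping[tuple[str, str], str] = field(
        default_factory=lambda: {
            ("PC", "aa"): "IS 06:0 PC",
            ("PC", "ae"): "IS 12:0 diether PC",
            ("PC", "lyso"): "IS 19:0 lyso-PC",
            ("PE", "aa"): "IS 08:0 PE",
            ("PE", "ae"): "IS 08:0 PE-ae",
            ("PE", "lyso"): "IS 14:0 lyso-PE",
            ("PG", "aa"): "IS 17:0-14:1 PG",
            ("carnitine", "short"): "IS octanoyl-carnitine-d3",
            ("carnitine", "long"): "IS palmitoyl-carnitine-d3",
        }
    )


def default_panel(config: PanelConfig | None = None) -> AnalytePanel:
    """Build the default analyte panel from per-class composition grids.

    The study's appendix-level species list is reconstructed as dense grids
    per (class, linkage); duplicates collapse by name (set semantics).
    """
    from .nomenclature import Linkage, LipidClass

    config = config or PanelConfig()
    species: list[Analyte] = []
    for (cls, link), ((c_lo, c_hi), (d_lo, d_hi)) in config.lipid_grids.items():
        if c_lo > c_hi or d_lo > d_hi:
            raise ValueError(
                f"empty carbon/double-bond range for ({cls}, {link}): "
                f"carbons {c_lo}..{c_hi}, db {d_lo}..{d_hi}"
            )
        for c in range(c_lo, c_hi + 1, 2):
            for d in range(d_lo, d_hi + 1):
                species.append(LipidSpecies(LipidClass(cls), Linkage(link), c, d))
    if len(config.carnitine_chains) == 0:
        raise ValueError("empty carnitine chain list")
    for n in config.carnitine_chains:
        species.append(AcylCarnitine(n))
    return AnalytePanel(species, config.standards)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Log-normal factors with expectation exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = _lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_dataset(
    design: StudyDesign,
    panel: AnalytePanel,
    effects: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Generate a long-format measurement table.

    Returns one row per (compartment, group, biological replicate, technical
    replicate, analyte), analytes covering all panel species plus the internal
    standards.  The expectation of a planted species in a non-reference group
    equals the reference expectation times the planted fold change.
    """
    effects = effects or EffectSpec()
    noise = noise or NoiseSpec()

    ss = np.random.SeedSequence(noise.seed)
    s_base, s_bio, s_tech, s_std, s_matrix = ss.spawn(5)
    rng_base = np.random.default_rng(s_base)
    rng_bio = np.random.default_rng(s_bio)
    rng_tech = np.random.default_rng(s_tech)
    rng_std = np.random.default_rng(s_std)
    rng_matrix = np.random.default_rng(s_matrix)

    species_names = panel.species_names
    std_names = panel.standard_names
    n_sp = len(species_names)
    n_std = len(std_names)

    # species baseline abundances: log-uniform over ~2 decades of cps
    base = 10.0 ** rng_base.uniform(3.0, 5.0, size=n_sp)
    std_base = np.full(n_std, 1.0e4)

    # planted fold-change matrix per (compartment, group, species)
    fc = np.ones((len(design.compartments), len(design.groups), n_sp))
    for ci, comp in enumerate(design.compartments):
        resolved = effects.resolve(panel, comp)
        vec = np.array([resolved[name] for name in species_names])
        for gi, grp in enumerate(design.groups):
            if grp != design.reference_group:
                fc[ci, gi, :] = vec

    # matrix-effect shift per (compartment, group, standard); zero in the
    # reference group.  Normal with E|shift| = amplitude.
    shift = np.zeros((len(design.compartments), len(design.groups), n_std))
    if noise.standard_matrix_amplitude > 0:
        sd = noise.standard_matrix_amplitude * math.sqrt(math.pi / 2.0)
        for ci in range(len(design.compartments)):
            for gi, grp in enumerate(design.groups):
                if grp != design.reference_group:
                    shift[ci, gi, :] = rng_matrix.normal(0.0, sd, size=n_std)

    records: list[pd.DataFrame] = []
    for ci, comp in enumerate(design.compartments):
        for gi, grp in enumerate(design.groups):
            for b in range(1, design.n_bio + 1):
                sample_id = f"{comp}:{grp}:{b}"
                bio = _mean_one_lognormal(rng_bio, noise.biological_cv, n_sp)
                expect = base * fc[ci, gi, :] * bio
                for t in range(1, design.n_tech + 1):
                    tech = _mean_one_lognormal(rng_tech, noise.technical_cv, n_sp)
                    std_tech = _mean_one_lognormal(
                        rng_std, noise.standard_technical_cv, n_std
                    )
                    intensity = np.concatenate(
                        [
                            expect * tech,
                            std_base * (1.0 + shift[ci, gi, :]) * std_tech,
                        ]
                    )
                    records.append(
                        pd.DataFrame(
                            {
                                "sample_id": sample_id,
                                "compartment": comp,
                                "group": grp,
                                "bio_replicate": b,
                                "tech_replicate": t,
                                "analyte": species_names + std_names,
                                "intensity": intensity,
                            }
                        )
                    )
    table = pd.concat(records, ignore_index=True)
    return table


def appswe_like_effects() -> EffectSpec:
    """A planted-effect scenario with the broad structure of the study system.

    Mitochondria: widespread increases across the glycerophospholipid classes,
    strongest for PE species, with the polyunsaturated (X:5/X:6) plasmalogens
    spared so the double-bond ratio panels respond.  Homogenate: mostly flat,
    with decreases in highly unsaturated plasmalogens and increases in the
    beta-oxidation end products C2/C3 (plus C5) among the carnitines.

    This is a synthetic scenario for demonstrations and end-to-end runs, not a
    reconstruction of any measured dataset.
    """
    eff = EffectSpec()
    mito, hom = "mitochondria", "homogenate"
    for link in ("PCaa", "PCae"):
        eff.set(mito, link, 1.20)
    eff.set(mito, "lyso-PC", 1.15)
    eff.set(mito, "PEaa", 1.35)
    eff.set(mito, "PEae", 1.40)
    eff.set(mito, "lyso-PE", 1.25)
    # knock down the highly unsaturated species -> X:4/X:6 ratios rise
    eff.set(mito, "PCae X:5", 0.75)
    eff.set(mito, "PCae X:6", 0.70)
    eff.set(mito, "PEae X:5", 0.80)
    eff.set(mito, "PEaa X:6", 0.70)
    eff.set(hom, "PCae X:5", 0.85)
    eff.set(hom, "PCae X:4", 0.90)
    eff.set(hom, "C2", 1.50)
    eff.set(hom, "C3", 1.50)
    eff.set(hom, "C5", 1.30)
    return eff
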