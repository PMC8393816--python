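"""One-shot pipeline runner: simulate/read -> normalize -> collapse ->
per-compartment differential + composition panels -> cross-compartment
shift tests and Venn partition, with all tables written as delimited text and
a machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import compare, composition, differential, normalize, synthetic
from .io import RunConfig, read_measurements, write_table
from .nomenclature import AcylCarnitine, AnalytePanel
from .synthetic import EffectSpec, NoiseSpec, StudyDesign, default_panel

log = logging.getLogger(__name__)


def _stage(name: str, df=None):
    n = "" if df is None else f" ({len(df)} records)"
    log.info("stage %s done%s", name, n)


def _effects_from_config(cfg: RunConfig) -> EffectSpec:
    eff = EffectSpec()
    for key, fc in cfg.effects.items():
        comp, sel = key.split("/", 1)
        eff.set(comp, sel, float(fc))
    return eff


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written to
    ``<outdir>/summary.json``).  Deterministic given the config seed."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.meta()

    try:
        panel = (
            default_panel()
            if config.panel == "default"
            else AnalytePanel.from_file(config.panel)
        )
        _stage("panel", panel.species)
    except Exception as exc:
        raise RuntimeError(f"stage 'panel' failed: {exc}") from exc

    try:
        if config.simulate:
            design = StudyDesign(
                compartments=config.compartments,
                groups=(config.control, config.treated),
                reference_group=config.control,
                n_bio=config.n_bio,
                n_tech=config.n_tech,
            )
            noise = NoiseSpec(
                biological_cv=config.biological_cv,
                technical_cv=config.technical_cv,
                standard_matrix_amplitude=config.standard_matrix_amplitude,
                seed=config.seed,
            )
            measurements = synthetic.simulate_dataset(
                design, panel, _effects_from_config(config), noise
            )
        else:
            measurements = read_measurements(config.measurements)
        _stage("measurements", measurements)
    except Exception as exc:
        raise RuntimeError(f"stage 'measurements' failed: {exc}") from exc

    try:
        qc = normalize.matrix_effect_qc(measurements, panel, config.control)
        write_table(qc.per_standard, outdir / "matrix_qc.tsv", meta)
        write_table(qc.summary, outdir / "matrix_qc_summary.tsv", meta)
        ratios = normalize.normalize_to_standard(measurements, panel)
        collapsed = normalize.collapse_technical(ratios)
        write_table(collapsed, outdir / "ratios.tsv", meta)
        _stage("normalize", collapsed)
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc

    summary: dict = {
        "config": config.config_hash(),
        "seed": config.seed,
        "panel_size": len(panel),
        "alpha": config.alpha,
        "compartments": {},
        "matrix_qc": {
            "max_abs_pct_change": qc.max_abs_change,
            "mean_abs_pct_change": qc.mean_abs_change,
        },
    }

    labels_by_comp: dict[str, pd.DataFrame] = {}
    for comp in config.compartments:
        try:
            stats_t = differential.species_stats(
                collapsed, config.treated, config.control, comp
            )
            cls = differential.classify(stats_t, alpha=config.alpha)
            volcano = differential.volcano_table(stats_t, cls)
            write_table(stats_t, outdir / f"stats_{comp}.tsv", meta)
            write_table(volcano, outdir / f"volcano_{comp}.tsv", meta)

            molp = composition.mol_percent(collapsed)
            stats_m = differential.species_stats(
                molp, config.treated, config.control, comp
            )
            cls_m = differential.classify(stats_m, alpha=config.alpha)
            write_table(
                differential.volcano_table(stats_m, cls_m),
                outdir / f"volcano_molpct_{comp}.tsv",
                meta,
            )

            labels_by_comp[comp] = cls.labels
            summary["compartments"][comp] = {
                "labels": cls.counts(),
                "labels_molpct": cls_m.counts(),
                "avg_sem": cls.avg_sem,
                "avg_sem_molpct": cls_m.avg_sem,
            }
            _stage(f"differential[{comp}]", stats_t)
        except Exception as exc:
            raise RuntimeError(f"stage 'differential[{comp}]' failed: {exc}") from exc

    # double-bond ratio panels
    try:
        ratio_rows = []
        specs = [
            composition.RatioSpec(**spec) if isinstance(spec, dict) else spec
            for spec in config.ratio_specs
        ]
        for comp in config.compartments:
            for spec in specs:
                res = composition.double_bond_ratio(
                    collapsed, spec, config.treated, config.control, comp
                )
                ratio_rows.append(
                    {
                        "compartment": comp,
                        "name": res.name,
                        "percent_of_control": res.percent_of_control,
                        "sem_percent": res.sem_percent,
                        "p_value": res.p_value,
                        "flag": res.flag,
                    }
                )
        if ratio_rows:
            write_table(pd.DataFrame(ratio_rows), outdir / "ratio_panels.tsv", meta)
            summary["ratio_panels"] = ratio_rows
        _stage("ratio panels")
    except Exception as exc:
        raise RuntimeError(f"stage 'ratio_panels' failed: {exc}") from exc

    # carnitine carrier panel (only where carnitines are present)
    try:
        if any(isinstance(sp, AcylCarnitine) for sp in panel.species):
            for comp in config.compartments:
                carn = composition.carnitine_panel(
                    collapsed, config.treated, config.control, comp
                )
                write_table(carn, outdir / f"carnitine_{comp}.tsv", meta)
            _stage("carnitine panel")
    except Exception as exc:
        raise RuntimeError(f"stage 'carnitine' failed: {exc}") from exc

    # cross-compartment shift test + Venn
    try:
        if len(config.compartments) == 2:
            comp_a, comp_b = config.compartments
            shift = compare.shift_test(labels_by_comp[comp_a], labels_by_comp[comp_b])
            venn = compare.venn_partition(
                labels_by_comp[comp_a], labels_by_comp[comp_b]
            )
            summary["shift_test"] = shift.as_dict()
            summary["venn"] = venn.counts()
            venn_rows = [
                {"cell": cell, "analyte": analyte}
                for cell, members in vars(venn).items()
                for analyte in members
            ]
            write_table(pd.DataFrame(venn_rows), outdir / "venn_members.tsv", meta)
            _stage("compare")
    except Exception as exc:
        raise RuntimeError(f"stage 'compare' failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
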