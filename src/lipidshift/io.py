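"""File formats and run configuration.

Measurement files are long (tidy) delimited text with a header row
(sample_id, compartment, group, bio_replicate, tech_replicate, analyte,
intensity); comma or tab dialect is auto-detected.  Output tables are TSV
with ``#``-prefixed provenance header lines (config hash, seed, version).
Run configuration is a flat YAML mapping validated before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = [
    "read_measurements",
    "write_table",
    "read_table",
    "RunConfig",
    "SchemaError",
]

REQUIRED_COLUMNS = [
    "sample_id",
    "compartment",
    "group",
    "bio_replicate",
    "tech_replicate",
    "analyte",
    "intensity",
]
KEY_COLUMNS = ["sample_id", "tech_replicate", "analyte"]


class SchemaError(ValueError):
    """Malformed measurement file or configuration."""


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise SchemaError(f"{path}: empty file")


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format measurement table."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "tech_replicate"]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad = pd.to_numeric(df["intensity"], errors="coerce").isna() & df["intensity"].notna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise SchemaError(f"{path}: non-numeric intensity at file row(s) {rows}")
    df["intensity"] = pd.to_numeric(df["intensity"])
    keys = [c for c in KEY_COLUMNS if c in df.columns]
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]
        raise SchemaError(f"{path}: duplicate {tuple(keys)} keys at file row(s) {rows}")
    return df


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a TSV with ``#`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# lipidshift {__version__}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Configuration of a one-shot pipeline run.

    ``panel`` is a panel-file path or "default"; ``effects`` maps
    "compartment/selector" keys to planted fold changes and is only used with
    ``simulate=True``; ``scope`` chooses the analysis set for the average-SEM
    guide lines ("panel" or "class").
    """

    treated: str = "APPswe"
    control: str = "mock"
    alpha: float = 0.05
    scope: str = "panel"
    panel: str = "default"
    measurements: str | None = None
    simulate: bool = True
    seed: int = 0
    n_bio: int = 7
    n_tech: int = 3
    compartments: tuple[str, ...] = ("homogenate", "mitochondria")
    biological_cv: float = 0.15
    technical_cv: float = 0.05
    standard_matrix_amplitude: float = 0.012
    effects: dict = field(default_factory=dict)
    ratio_specs: list = field(default_factory=list)
    carbon_bins: tuple = ((None, 33, "short"), (34, 39, "mid"), (40, None, "long"))
    outdir: str = "results/run"

    def validate(self) -> None:
        if self.treated == self.control:
            raise SchemaError("treated and control groups must differ")
        if not 0 < self.alpha < 1:
            raise SchemaError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.scope not in ("panel", "class"):
            raise SchemaError(f"scope must be 'panel' or 'class', got {self.scope!r}")
        if not self.simulate and not self.measurements:
            raise SchemaError("either simulate=true or a measurements path is required")
        if self.n_bio < 2 or self.n_tech < 1:
            raise SchemaError("n_bio must be >= 2 and n_tech >= 1")
        for key, fc in self.effects.items():
            if "/" not in key:
                raise SchemaError(
                    f"effect key {key!r} must be 'compartment/selector'"
                )
            comp = key.split("/", 1)[0]
            if comp not in self.compartments:
                raise SchemaError(
                    f"effect key {key!r} references unknown compartment {comp!r}"
                )
            if not (isinstance(fc, (int, float)) and fc > 0):
                raise SchemaError(f"effect {key!r}: fold change must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a flat mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "compartments" in raw:
            raw["compartments"] = tuple(raw["compartments"])
        if "carbon_bins" in raw:
            raw["carbon_bins"] = tuple(tuple(b) for b in raw["carbon_bins"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {"config": self.config_hash(), "seed": self.seed}
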