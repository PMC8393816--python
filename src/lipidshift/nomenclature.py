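"""Analyte naming for targeted shotgun lipidomics panels.

Species are reported at the sum-composition level: ``PCaa C36:4`` is a diacyl
phosphatidylcholine whose two fatty-acyl chains together carry 36 carbons and
4 double bonds.  The dialect covers diacyl (``aa``), ether/plasmalogen (``ae``)
and lyso glycerophospholipids of the PC/PE/PG classes, plus acyl-carnitines
(``C2`` = acetyl-carnitine, ``C0`` = free carnitine).  Phosphatidylglycerol may
also be written with explicit chains (``PG 18:2/16:0``); the chains are summed
into the sum composition and retained as an annotation.

Everything downstream (class sums for mol%, double-bond ratio panels,
chain-length aggregates, the carnitine carrier metrics) keys on the attributes
parsed here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "LipidClass",
    "Linkage",
    "LipidSpecies",
    "AcylCarnitine",
    "Analyte",
    "AnalytePanel",
    "LipidNameError",
    "parse_lipid",
    "parse_carnitine",
    "parse_analyte",
]

MAX_DOUBLE_BONDS = 12
MAX_CARNITINE_CHAIN = 26


class LipidNameError(ValueError):
    """Raised when an analyte name cannot be parsed; names the offending token."""


class LipidClass(str, Enum):
    PC = "PC"
    PE = "PE"
    PG = "PG"


class Linkage(str, Enum):
    AA = "aa"      # both chains ester-bound (diacyl)
    AE = "ae"      # sn-1 ether/enolether bound (plasmalogen)
    LYSO = "lyso"  # single chain


@dataclass(frozen=True, order=True)
class LipidSpecies:
    """A glycerophospholipid at sum-composition resolution.

    ``chains`` optionally records an explicit chain pair such as (18, 2, 16, 0)
    for ``PG 18:2/16:0``; it is an annotation and does not take part in
    identity, which is (class, linkage, carbons, double_bonds).
    """

    lipid_class: LipidClass
    linkage: Linkage
    carbons: int
    double_bonds: int
    chains: tuple | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise LipidNameError(f"carbons must be >= 2, got {self.carbons}")
        if not 0 <= self.double_bonds <= MAX_DOUBLE_BONDS:
            raise LipidNameError(
                f"double_bonds must be in [0, {MAX_DOUBLE_BONDS}], got {self.double_bonds}"
            )

    @property
    def name(self) -> str:
        """Canonical rendering, e.g. ``PCaa C36:4``, ``lyso-PE C20:3``, ``PG C34:2``."""
        comp = f"C{self.carbons}:{self.double_bonds}"
        if self.linkage is Linkage.LYSO:
            return f"lyso-{self.lipid_class.value} {comp}"
        if self.lipid_class is LipidClass.PG and self.linkage is Linkage.AA:
            return f"PG {comp}"  # the customary spelling omits the diacyl token
        return f"{self.lipid_class.value}{self.linkage.value} {comp}"

    @property
    def class_key(self) -> tuple[str, str]:
        """The (class, linkage) pair that defines the normalization/mol% group."""
        return (self.lipid_class.value, self.linkage.value)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True, order=True)
class AcylCarnitine:
    """Carnitine analyte; chain_length 0 is free carnitine and is never counted
    as an acyl-carnitine."""

    chain_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.chain_length <= MAX_CARNITINE_CHAIN:
            raise LipidNameError(
                f"carnitine chain_length must be in [0, {MAX_CARNITINE_CHAIN}], "
                f"got {self.chain_length}"
            )

    @property
    def name(self) -> str:
        return f"C{self.chain_length}"

    @property
    def is_even(self) -> bool:
        return self.chain_length % 2 == 0

    @property
    def is_acyl(self) -> bool:
        """True for genuine acyl-carnitines (chain >= 2); C0 is free carnitine."""
        return self.chain_length >= 2

    @property
    def class_key(self) -> tuple[str, str]:
        return ("carnitine", "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


Analyte = Union[LipidSpecies, AcylCarnitine]

# "PCaa C40:1", "PC aa C40:1", "lyso-PC C16:0", "Lyso PE C20:3", "PG C34:2", "PGaa C34:2"
_LYSO_RE = re.compile(
    r"^\s*lyso[\s-]*(?P<cls>PC|PE|PG)\s*C?(?P<c>\d+)\s*:\s*(?P<db>\d+)\s*$",
    re.IGNORECASE,
)
_DIACYL_RE = re.compile(
    r"^\s*(?P<cls>PC|PE|PG)\s*(?P<link>aa|ae)?\s+?C?(?P<c>\d+)\s*:\s*(?P<db>\d+)\s*$",
    re.IGNORECASE,
)
_PG_CHAINS_RE = re.compile(
    r"^\s*PG\s*(?P<c1>\d+)\s*:\s*(?P<d1>\d+)\s*/\s*(?P<c2>\d+)\s*:\s*(?P<d2>\d+)\s*$",
    re.IGNORECASE,
)
# tolerate the no-space spelling "PCaaC40:1" as well
_DIACYL_TIGHT_RE = re.compile(
    r"^\s*(?P<cls>PC|PE|PG)(?P<link>aa|ae)\s*C?(?P<c>\d+)\s*:\s*(?P<db>\d+)\s*$",
    re.IGNORECASE,
)
_CARNITINE_RE = re.compile(r"^\s*C\s*(?P<n>\d+)\s*$", re.IGNORECASE)


def parse_lipid(name: str) -> LipidSpecies:
    """Parse a glycerophospholipid name in the panel dialect.

    Accepts ``PCaa C36:4`` and ``PC aa C36:4`` (canonical is the former),
    ``lyso-PC C16:0`` / ``Lyso PC C16:0``, ``PG C34:2`` (linkage defaults to
    diacyl for PG) and the explicit-chain form ``PG 18:2/16:0``.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError(f"empty or non-text lipid name: {name!r}")

    m = _PG_CHAINS_RE.match(name)
    if m:
        c1, d1, c2, d2 = (int(m.group(g)) for g in ("c1", "d1", "c2", "d2"))
        return LipidSpecies(
            LipidClass.PG, Linkage.AA, c1 + c2, d1 + d2, chains=(c1, d1, c2, d2)
        )

    m = _LYSO_RE.match(name)
    if m:
        cls = LipidClass(m.group("cls").upper())
        return LipidSpecies(cls, Linkage.LYSO, int(m.group("c")), int(m.group("db")))

    m = _DIACYL_RE.match(name) or _DIACYL_TIGHT_RE.match(name)
    if m:
        cls = LipidClass(m.group("cls").upper())
        link = m.group("link")
        if link is None:
            if cls is not LipidClass.PG:
                raise LipidNameError(
                    f"missing linkage token (aa/ae/lyso) in {name!r}"
                )
            linkage = Linkage.AA
        else:
            linkage = Linkage(link.lower())
        return LipidSpecies(cls, linkage, int(m.group("c")), int(m.group("db")))

    # build a helpful error naming the offending token
    head = re.match(r"\s*(lyso[\s-]*)?(PC|PE|PG)(\w*)", name, re.IGNORECASE)
    if head and head.group(3) and head.group(3).lower() not in ("aa", "ae"):
        raise LipidNameError(
            f"unknown linkage token {head.group(3)!r} in lipid name {name!r}"
        )
    raise LipidNameError(f"unparseable lipid name: {name!r}")


def parse_carnitine(name: str) -> AcylCarnitine:
    """Parse a carnitine name ``C<number>``; zero padding is accepted
    (``C02`` == ``C2``)."""
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError(f"empty or non-text carnitine name: {name!r}")
    m = _CARNITINE_RE.match(name)
    if not m:
        suffix = name.strip()[1:] if name.strip()[:1].upper() == "C" else name.strip()
        raise LipidNameError(
            f"carnitine name must be 'C<number>', got non-numeric suffix {suffix!r} "
            f"in {name!r}"
        )
    return AcylCarnitine(int(m.group("n")))


def parse_analyte(name: str) -> Analyte:
    """Parse either dialect; carnitines win for bare ``C<number>`` names."""
    if _CARNITINE_RE.match(name):
        return parse_carnitine(name)
    return parse_lipid(name)


class AnalytePanel:
    """The analyte list of a run plus the analyte -> internal-standard mapping.

    Each species maps to exactly one internal standard, keyed by its
    (class, linkage) group; carnitines split into a short-chain group (served
    by an octanoyl-type standard, chain <= 10) and a long-chain group
    (palmitoyl-type, chain > 10).
    """

    CARNITINE_SHORT_MAX = 10

    def __init__(
        self,
        species: Sequence[Analyte],
        standards: Mapping[tuple[str, str], str],
    ) -> None:
        deduped: dict[str, Analyte] = {}
        for sp in species:
            deduped.setdefault(sp.name, sp)
        self.species: list[Analyte] = list(deduped.values())
        self.standards: dict[tuple[str, str], str] = dict(standards)
        for sp in self.species:
            key = self.standard_group(sp)
            if key not in self.standards:
                raise LipidNameError(
                    f"no internal standard defined for group {key} (species {sp.name})"
                )

    @staticmethod
    def standard_group(analyte: Analyte) -> tuple[str, str]:
        if isinstance(analyte, AcylCarnitine):
            if analyte.chain_length <= AnalytePanel.CARNITINE_SHORT_MAX:
                return ("carnitine", "short")
            return ("carnitine", "long")
        return analyte.class_key

    def __len__(self) -> int:
        return len(self.species)

    def __contains__(self, analyte: Analyte | str) -> bool:
        name = analyte if isinstance(analyte, str) else analyte.name
        return name in self.species_names

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    @property
    def standard_names(self) -> list[str]:
        return sorted(set(self.standards.values()))

    @property
    def lipids(self) -> list[LipidSpecies]:
        return [sp for sp in self.species if isinstance(sp, LipidSpecies)]

    @property
    def carnitines(self) -> list[AcylCarnitine]:
        return [sp for sp in self.species if isinstance(sp, AcylCarnitine)]

    def standard_for(self, analyte: Analyte | str) -> str:
        if isinstance(analyte, str):
            analyte = parse_analyte(analyte)
        return self.standards[self.standard_group(analyte)]

    def standard_map(self) -> dict[str, str]:
        """analyte name -> standard name for every species in the panel."""
        return {sp.name: self.standard_for(sp) for sp in self.species}

    # -- panel file: two-column delimited text (analyte_name, standard_name) --

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("analyte_name\tstandard_name\n")
            for sp in self.species:
                fh.write(f"{sp.name}\t{self.standard_for(sp)}\n")

    @classmethod
    def from_file(cls, path) -> "AnalytePanel":
        species: list[Analyte] = []
        standards: dict[tuple[str, str], str] = {}
        with open(path) as fh:
            header = fh.readline()
            if "analyte_name" not in header:
                raise LipidNameError(
                    f"panel file {path} must start with an "
                    "'analyte_name<TAB>standard_name' header"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = re.split(r"[\t,]", line)
                if len(parts) != 2:
                    raise LipidNameError(
                        f"panel file line {lineno}: expected two columns, got {line!r}"
                    )
                analyte = parse_analyte(parts[0])
                species.append(analyte)
                key = cls.standard_group(analyte)
                prev = standards.setdefault(key, parts[1])
                if prev != parts[1]:
                    raise LipidNameError(
                        f"panel file line {lineno}: group {key} mapped to two "
                        f"standards ({prev!r}, {parts[1]!r})"
                    )
        return cls(species, standards)


def render_names(species: Iterable[Analyte]) -> list[str]:
    return [sp.name for sp in species]
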