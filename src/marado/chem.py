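"""Molecular formulas, adduct arithmetic and fragment catalogues for trehalose lipids.

Maradolipids are 6,6'-di-O-acyltrehaloses: a trehalose head group esterified
with two fatty acyl chains at the 6 and 6' positions.  Lysomaradolipids carry a
single acyl group.  Because the 6 and 6' positions are chemically equivalent
there is no sn1/sn2 distinction -- ``Mar(a/b)`` and ``Mar(b/a)`` denote the same
species and are stored in a canonical (ascending) acyl order.

All ions handled here are singly charged.  Ion m/z values include the electron
mass, so that e.g. an ``[M+Na]+`` adduct is ``M + m(Na) - m(e)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Mapping

__all__ = [
    "MolecularFormula",
    "AcylChain",
    "TrehaloseLipid",
    "Adduct",
    "FragmentSpec",
    "ADDUCTS",
    "TREHALOSE",
    "WATER",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "build_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "theoretical_fragments",
    "parse_lipid_name",
]

# CODATA/IUPAC monoisotopic atomic masses (Da); C-12 defines the scale.
ATOMIC_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
}

ELECTRON_MASS = 0.00054858  # Da
#: mass of H+ (a proton as transferred in (de)protonation), Da
PROTON_MASS = ATOMIC_MASSES["H"] - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised when formula arithmetic would produce a chemically impossible result."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element-count map restricted to the elements occurring in trehalose lipids.

    Supports addition and subtraction; subtraction that would drive any element
    count negative raises :class:`FormulaError` rather than silently clamping.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ATOMIC_MASSES:
                raise FormulaError(f"unsupported element: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n}")
            if n > 0:
                clean[el] = n
        if sum(clean.values()) < 1:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", dict(clean))

    @classmethod
    def from_str(cls, s: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``'C40H74O13'``."""
        counts: dict[str, int] = {}
        for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", s):
            if not el:
                continue
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        return cls(counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count: {self} - {other}"
                )
        return MolecularFormula(merged)

    @property
    def mass(self) -> float:
        """Monoisotopic (exact) mass in Da."""
        return sum(ATOMIC_MASSES[el] * n for el, n in self.counts.items())

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        order = ["C", "H"] + sorted(k for k in self.counts if k not in ("C", "H"))
        out = []
        for el in order:
            n = self.counts.get(el, 0)
            if n:
                out.append(el + (str(n) if n > 1 else ""))
        return "".join(out)


TREHALOSE = MolecularFormula.from_str("C12H22O11")
WATER = MolecularFormula.from_str("H2O")


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass of *f* in Da."""
    return f.mass


@total_ordering
@dataclass(frozen=True)
class AcylChain:
    """A fatty acyl chain, named ``carbons:DBE`` (e.g. ``14:0``, ``18:1``).

    ``dbe`` is the total double-bond-equivalent count of the chain; a
    cyclopropane ring contributes one DBE, so a 2-octylcyclopropyl-octanoyl
    chain is a 19:1 chain with ``cyclopropane=True`` and has exactly the
    formula of a straight-chain 19:1.  ``branched`` and ``cyclopropane`` are
    informational: they never change the formula.
    """

    carbons: int
    dbe: int
    branched: bool = False
    cyclopropane: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise FormulaError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.dbe < 0:
            raise FormulaError(f"negative DBE: {self.dbe}")
        if 2 * self.carbons - 2 * self.dbe < 1:
            raise FormulaError(f"impossible acyl chain {self.carbons}:{self.dbe}")

    @property
    def free_acid(self) -> MolecularFormula:
        """Formula of the free fatty acid C_n H_(2n-2*DBE) O2."""
        return MolecularFormula(
            {"C": self.carbons, "H": 2 * self.carbons - 2 * self.dbe, "O": 2}
        )

    @property
    def label(self) -> str:
        return f"{self.carbons}:{self.dbe}"

    def _key(self) -> tuple[int, int]:
        return (self.carbons, self.dbe)

    def __lt__(self, other: "AcylChain") -> bool:
        return self._key() < other._key()

    def __eq__(self, other: object) -> bool:
        # branched/cyclopropane flags are informational; two chains with the
        # same (carbons, DBE) are formula-identical and compare equal
        if not isinstance(other, AcylChain):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())


@dataclass(frozen=True)
class TrehaloseLipid:
    """A maradolipid (``Mar``, two acyls) or lysomaradolipid (``LysoMar``, one acyl)."""

    lipid_class: str  # "Mar" | "LysoMar"
    acyls: tuple[AcylChain, ...]

    def __post_init__(self) -> None:
        if self.lipid_class not in ("Mar", "LysoMar"):
            raise ValueError(f"unknown lipid class: {self.lipid_class!r}")
        expected = 2 if self.lipid_class == "Mar" else 1
        if len(self.acyls) != expected:
            raise ValueError(
                f"{self.lipid_class} requires {expected} acyl(s), got {len(self.acyls)}"
            )
        # 6 and 6' positions are equivalent: canonical ascending order
        object.__setattr__(self, "acyls", tuple(sorted(self.acyls)))

    @property
    def name(self) -> str:
        inner = "/".join(a.label for a in self.acyls)
        return f"{self.lipid_class}({inner})"

    @property
    def formula(self) -> MolecularFormula:
        return build_formula(self)

    @property
    def mass(self) -> float:
        return self.formula.mass

    @property
    def total_carbons(self) -> int:
        """Total acyl carbons (the homologous-series coordinate)."""
        return sum(a.carbons for a in self.acyls)

    @property
    def total_dbe(self) -> int:
        return sum(a.dbe for a in self.acyls)


def build_formula(lipid: TrehaloseLipid) -> MolecularFormula:
    """Ester formula: trehalose + sum of free fatty acids - one water per ester bond."""
    f = TREHALOSE
    for acyl in lipid.acyls:
        f = f + acyl.free_acid - WATER
    return f


_LIPID_NAME_RE = re.compile(
    r"^(Mar|LysoMar)\(\s*(\d+):(\d+)\s*(?:/\s*(\d+):(\d+)\s*)?\)$"
)


def parse_lipid_name(name: str) -> TrehaloseLipid:
    """Parse shorthand such as ``'Mar(14:0/18:1)'`` or ``'LysoMar(17:0)'``."""
    m = _LIPID_NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse lipid name: {name!r}")
    cls = m.group(1)
    acyls = [AcylChain(int(m.group(2)), int(m.group(3)))]
    if m.group(4) is not None:
        acyls.append(AcylChain(int(m.group(4)), int(m.group(5))))
    return TrehaloseLipid(cls, tuple(acyls))


@dataclass(frozen=True)
class Adduct:
    """An ionizing adduct; ``m/z = M + shift`` with the electron mass folded into *shift*."""

    name: str
    shift: float  # Da
    charge: int  # +1 or -1

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged species are supported")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


def _nh4_shift() -> float:
    return ATOMIC_MASSES["N"] + 4 * ATOMIC_MASSES["H"] - ELECTRON_MASS


def _formate_shift() -> float:
    # HCOO- attachment: + CHO2 + electron
    return ATOMIC_MASSES["C"] + ATOMIC_MASSES["H"] + 2 * ATOMIC_MASSES["O"] + ELECTRON_MASS


#: The five adducts observed for trehalose lipids.  "FA" in [M+FA-H]- is
#: formate from the formic-acid mobile phase, not a fatty acid.
ADDUCTS: Mapping[str, Adduct] = {
    "[M+NH4]+": Adduct("[M+NH4]+", _nh4_shift(), +1),
    "[M+Na]+": Adduct("[M+Na]+", ATOMIC_MASSES["Na"] - ELECTRON_MASS, +1),
    "[M+H]+": Adduct("[M+H]+", PROTON_MASS, +1),
    "[M+FA-H]-": Adduct("[M+FA-H]-", _formate_shift(), -1),
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, -1),
}


def get_adduct(name: str) -> Adduct:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise ValueError(f"unknown adduct: {name!r}") from None


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of the singly charged adduct ion of a neutral of mass *neutral_mass* (Da)."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return neutral_mass + adduct.shift


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

#: Diagnostic trehalose head-group fragments (theoretical values, negative mode)
TREHALOSE_FRAGMENT_H2O = (TREHALOSE - WATER).mass - PROTON_MASS  # 323.0984
TREHALOSE_FRAGMENT_2H2O = (TREHALOSE - WATER - WATER).mass - PROTON_MASS  # 305.0878


@dataclass(frozen=True)
class FragmentSpec:
    """One theoretical fragment: its kind, m/z, charge and (if acyl-derived) the acyl."""

    kind: str
    mz: float
    charge: int
    acyl: AcylChain | None = None

    @property
    def label(self) -> str:
        if self.acyl is not None:
            return self.kind.replace("RCOOH", f"{self.acyl.label}(COOH)").replace(
                "RCOO", f"FA({self.acyl.label})"
            ).replace("RCO", f"{self.acyl.label}(CO)")
        return self.kind


def theoretical_fragments(
    lipid: TrehaloseLipid, adduct: Adduct | str
) -> list[FragmentSpec]:
    """Theoretical fragment catalogue for *lipid* ionized as *adduct*.

    Negative mode (formate or deprotonated precursor): the formate adduct first
    collapses to [M-H]-, which loses either fatty acid as a neutral
    ([M-RCOOH]-) or as the free carboxylate ([RCOO]-), and finally yields the
    trehalose head-group fragments [Tre-H2O-H]- (m/z 323.0984) and, for
    diacyl species only, [Tre-2H2O-H]- (m/z 305.0878).  Symmetric lipids such
    as Mar(14:0/14:0) produce a single neutral-loss fragment.

    Positive mode yields only [M-H2O+H]+ and the acylium ions [RCO]+.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    M = lipid.mass
    frags: list[FragmentSpec] = []
    seen: set[tuple[str, AcylChain | None]] = set()

    def add(kind: str, mz: float, charge: int, acyl: AcylChain | None = None) -> None:
        key = (kind, acyl)
        if key in seen:  # symmetric lipids: one loss fragment, not two
            return
        seen.add(key)
        frags.append(FragmentSpec(kind, mz, charge, acyl))

    if adduct.charge < 0:
        add("[M-H]-", M - PROTON_MASS, -1)
        for acyl in lipid.acyls:
            if lipid.lipid_class == "Mar":
                # for LysoMar the acyl neutral loss coincides with [Tre-H2O-H]-
                add("[M-RCOOH]-", M - acyl.free_acid.mass - PROTON_MASS, -1, acyl)
            add("[RCOO]-", acyl.free_acid.mass - PROTON_MASS, -1, acyl)
        add("[Tre-H2O-H]-", TREHALOSE_FRAGMENT_H2O, -1)
        if lipid.lipid_class == "Mar":
            # for LysoMar the doubly dehydrated head fragment is not observed
            add("[Tre-2H2O-H]-", TREHALOSE_FRAGMENT_2H2O, -1)
    else:
        add("[M-H2O+H]+", M - WATER.mass + PROTON_MASS, +1)
        for acyl in lipid.acyls:
            # acylium RCO+ = free acid - OH, as a cation
            oh = ATOMIC_MASSES["O"] + ATOMIC_MASSES["H"]
            add("[RCO]+", acyl.free_acid.mass - oh - ELECTRON_MASS, +1, acyl)
    return frags
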