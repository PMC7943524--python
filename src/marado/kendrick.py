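"""Kendrick mass, Kendrick mass defect (KMD) and referenced KMD (RKMD) filtering.

The Kendrick scale rescales m/z so that one CH2 unit weighs exactly 14:

    KM   = m/z * 14 / 14.015650
    KMD  = KM - floor(KM)
    RKMD = (KMD - reference KMD) / 0.013399

The divisor 0.013399 is the Kendrick mass defect of H2: each double bond
removes one H2, so within a lipid class the RKMD of a species with *d* double
bonds sits at the integer -d, regardless of chain length.  The reference KMD
(0.6094) is that of the [M+FA-H]- adduct of the fully saturated 32-carbon
maradolipid, Mar(32:0); features whose RKMD falls within a tolerance of an
allowed integer are retained as candidate class members.

The floor convention for the nominal Kendrick mass is deliberate: it is the
convention that yields the reference value 0.6094 from m/z 863.5737.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem import AcylChain, TrehaloseLipid, adduct_mz

__all__ = [
    "CH2_KENDRICK_FACTOR",
    "H2_KMD",
    "KendrickValues",
    "KendrickConfig",
    "kendrick_mass",
    "kendrick_mass_defect",
    "rkmd",
    "rkmd_filter",
    "mar32_reference_kmd",
    "lyso_reference_kmd",
]

#: exact CH2 rescaling ratio
CH2_KENDRICK_FACTOR = 14.0 / 14.015650

#: Kendrick mass defect of one H2 unit (the per-double-bond RKMD step), ~0.013399
H2_KMD = 0.013399


def kendrick_mass(mz: float) -> float:
    """Kendrick mass: m/z rescaled so CH2 = 14 exactly."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return mz * CH2_KENDRICK_FACTOR


def kendrick_mass_defect(mz: float) -> float:
    """KMD = KM - floor(KM), in [0, 1)."""
    km = kendrick_mass(mz)
    return km - math.floor(km)


def mar32_reference_kmd() -> float:
    """Reference KMD: the [M+FA-H]- adduct of Mar(32:0) (printed as 0.6094).

    Mar(32:0) is computed as the 16:0/16:0 composition; every Mar(32:0)
    composition shares the formula C44H82O13 and hence the same KMD.
    """
    lipid = TrehaloseLipid("Mar", (AcylChain(16, 0), AcylChain(16, 0)))
    return kendrick_mass_defect(adduct_mz(lipid.mass, "[M+FA-H]-"))


def lyso_reference_kmd() -> float:
    """Reference KMD for the lysomaradolipid screen: LysoMar(17:0) formate adduct.

    Lysomaradolipids carry one oxygen fewer than maradolipids per CH2 ladder,
    so the diacyl reference does not apply; any saturated LysoMar anchors the
    same homologous grid (all saturated members share this KMD exactly).
    """
    lipid = TrehaloseLipid("LysoMar", (AcylChain(17, 0),))
    return kendrick_mass_defect(adduct_mz(lipid.mass, "[M+FA-H]-"))


@dataclass(frozen=True)
class KendrickValues:
    """KM/KMD/RKMD triple attached to a retained feature."""

    km: float
    kmd: float
    rkmd: float


@dataclass(frozen=True)
class KendrickConfig:
    """Parameters of the RKMD candidate filter.

    ``allowed_integers`` are the RKMD integers accepted by the filter; they are
    non-positive because each double bond lowers the KMD by one H2 defect.
    """

    reference_kmd: float = field(default_factory=mar32_reference_kmd)
    divisor: float = H2_KMD
    tolerance: float = 0.1
    allowed_integers: tuple[int, ...] = (0, -1, -2, -3, -4)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("RKMD tolerance must be positive")
        if self.divisor <= 0:
            raise ValueError("RKMD divisor must be positive")


def rkmd(kmd: float, config: KendrickConfig | None = None) -> float:
    """Referenced KMD: (KMD - reference) / H2 defect."""
    config = config or KendrickConfig()
    return (kmd - config.reference_kmd) / config.divisor


def kendrick_values(mz: float, config: KendrickConfig | None = None) -> KendrickValues:
    config = config or KendrickConfig()
    km = kendrick_mass(mz)
    kmd = km - math.floor(km)
    return KendrickValues(km, kmd, rkmd(kmd, config))


def rkmd_filter(features, config: KendrickConfig | None = None):
    """Retain features whose RKMD is within tolerance of an allowed integer.

    *features* is a sequence of objects carrying an ``mz`` attribute (typically
    :class:`~marado.library.FeatureRecord`).  The retained features are
    returned in input order with :class:`KendrickValues` attached via their
    ``kendrick`` attribute; the filter is idempotent.
    """
    config = config or KendrickConfig()
    retained = []
    for feat in features:
        kv = kendrick_values(feat.mz, config)
        if any(abs(kv.rkmd - k) <= config.tolerance for k in config.allowed_integers):
            if hasattr(feat, "kendrick"):
                feat.kendrick = kv
            retained.append(feat)
    return retained
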