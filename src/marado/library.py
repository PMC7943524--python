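"""Theoretical candidate library, MS1 feature matching and replicate alignment.

The candidate list enumerates every trehalose lipid that can be assembled from
a fatty-acid pool: all unordered acyl pairs (with repetition) for maradolipids,
all single acyls for lysomaradolipids.  Isobaric compositions -- e.g.
Mar(16:0/16:0) and Mar(15:0/17:0), both C44H82O13 -- are deliberately kept as
distinct entries; MS1 matching preserves the ambiguity for later resolution by
fragments, standards or trendlines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import AcylChain, Adduct, TrehaloseLipid, adduct_mz, get_adduct
from .kendrick import KendrickValues

__all__ = [
    "FattyAcidPool",
    "default_fatty_acid_pool",
    "CandidateEntry",
    "FeatureRecord",
    "CandidateMatch",
    "AlignmentTolerances",
    "ConsensusFeature",
    "generate_library",
    "library_to_frame",
    "match_features",
    "align_replicates",
    "MAR_RT_WINDOW",
    "LYSO_RT_WINDOW",
]

#: Default class retention-time windows on the reversed-phase gradient (min)
MAR_RT_WINDOW = (12.0, 17.0)
LYSO_RT_WINDOW = (2.5, 6.5)


@dataclass(frozen=True)
class FattyAcidPool:
    """The acyl chains allowed in generated candidates.

    Chains are deduplicated on (carbons, DBE): branched and straight chains of
    equal composition are formula-identical and would generate the same
    candidate masses.
    """

    chains: tuple[AcylChain, ...]

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("fatty-acid pool must not be empty")
        seen: set[tuple[int, int]] = set()
        unique = []
        for c in self.chains:
            key = (c.carbons, c.dbe)
            if key in seen:
                continue
            seen.add(key)
            unique.append(c)
        object.__setattr__(self, "chains", tuple(sorted(unique)))


def default_fatty_acid_pool() -> FattyAcidPool:
    """C13-C20 chains with 0-2 double-bond equivalents.

    The C15:0 and C17:0 entries are flagged branched (iso-methyl), the
    predominant forms in dauer-larva glycolipids; the flag is informational
    and does not alter any mass.
    """
    chains = []
    for n in range(13, 21):
        for d in range(0, 3):
            branched = d == 0 and n in (15, 17)
            chains.append(AcylChain(n, d, branched=branched))
    return FattyAcidPool(tuple(chains))


@dataclass(frozen=True)
class CandidateEntry:
    """One theoretical (lipid, adduct) pair with its exact m/z."""

    lipid: TrehaloseLipid
    adduct: Adduct
    mz: float


@dataclass
class FeatureRecord:
    """One aligned MS1 feature from 4D peak picking."""

    mz: float
    rt: float  # min
    drift_time: float | None = None  # ms
    ccs: float | None = None  # A^2, optional until calibrated
    abundance: float = 0.0
    polarity: str = "negative"
    replicate: int = 0
    kendrick: KendrickValues | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"RT must be non-negative, got {self.rt}")
        if self.drift_time is not None and self.drift_time <= 0:
            raise ValueError(f"drift time must be positive, got {self.drift_time}")


@dataclass
class CandidateMatch:
    """A feature matched to a library entry, with accumulating evidence flags."""

    feature: FeatureRecord
    candidate: CandidateEntry
    mz_error_mda: float
    mz_error_ppm: float
    within_rt_window: bool
    kendrick: KendrickValues | None = None
    fragments_confirmed: bool = False
    retained_fragments: list = field(default_factory=list)
    diagnostic_coelution: bool = False
    trendline_supported: bool | None = None
    standard_matched: str | None = None


def generate_library(
    pool: FattyAcidPool,
    classes: Iterable[str] = ("Mar", "LysoMar"),
    adducts: Iterable[Adduct | str] = ("[M+FA-H]-",),
) -> list[CandidateEntry]:
    """Enumerate candidates: k(k+1)/2 maradolipids and k lysomaradolipids per adduct."""
    adduct_objs = [get_adduct(a) if isinstance(a, str) else a for a in adducts]
    lipids: list[TrehaloseLipid] = []
    for cls in classes:
        if cls == "Mar":
            for a, b in itertools.combinations_with_replacement(pool.chains, 2):
                lipids.append(TrehaloseLipid("Mar", (a, b)))
        elif cls == "LysoMar":
            for a in pool.chains:
                lipids.append(TrehaloseLipid("LysoMar", (a,)))
        else:
            raise ValueError(f"unknown lipid class: {cls!r}")
    return [
        CandidateEntry(lipid, adduct, adduct_mz(lipid.mass, adduct))
        for lipid in lipids
        for adduct in adduct_objs
    ]


def library_to_frame(library: Sequence[CandidateEntry]) -> pd.DataFrame:
    """Tabular export: name, formula, adduct, m/z."""
    return pd.DataFrame(
        {
            "name": [e.lipid.name for e in library],
            "formula": [str(e.lipid.formula) for e in library],
            "adduct": [e.adduct.name for e in library],
            "mz": [round(e.mz, 4) for e in library],
        }
    )


_CLASS_RT_WINDOWS = {"Mar": MAR_RT_WINDOW, "LysoMar": LYSO_RT_WINDOW}


def match_features(
    features: Sequence[FeatureRecord],
    library: Sequence[CandidateEntry],
    mz_tolerance: float = 0.005,
    rt_windows: dict[str, tuple[float, float]] | None = None,
    require_rt_window: bool = True,
) -> list[CandidateMatch]:
    """All (feature, candidate) pairs within the m/z tolerance and class RT window.

    A feature may match several isobaric candidates; the ambiguity is kept.
    """
    windows = rt_windows or _CLASS_RT_WINDOWS
    matches: list[CandidateMatch] = []
    for feat in features:
        for cand in library:
            if feat.polarity != cand.adduct.polarity:
                continue
            dmz = feat.mz - cand.mz
            if abs(dmz) > mz_tolerance:
                continue
            lo, hi = windows.get(cand.lipid.lipid_class, (0.0, float("inf")))
            in_window = lo <= feat.rt <= hi
            if require_rt_window and not in_window:
                continue
            matches.append(
                CandidateMatch(
                    feature=feat,
                    candidate=cand,
                    mz_error_mda=dmz * 1e3,
                    mz_error_ppm=dmz / cand.mz * 1e6,
                    within_rt_window=in_window,
                    kendrick=feat.kendrick,
                )
            )
    return matches


@dataclass(frozen=True)
class AlignmentTolerances:
    """Vendor-style composite tolerances for replicate alignment.

    RT tolerance is relative + absolute (default +-10% + 0.5 min), drift-time
    tolerance relative (+-1.5%), mass tolerance ppm + absolute
    (+-15 ppm + 2.0 mDa).
    """

    rt_relative: float = 0.10
    rt_absolute: float = 0.5  # min
    drift_relative: float = 0.015
    mz_ppm: float = 15.0
    mz_absolute: float = 0.002  # Da

    def rt_tol(self, rt: float) -> float:
        return self.rt_relative * rt + self.rt_absolute

    def drift_tol(self, dt: float) -> float:
        return self.drift_relative * dt

    def mz_tol(self, mz: float) -> float:
        return self.mz_ppm * 1e-6 * mz + self.mz_absolute


@dataclass
class ConsensusFeature:
    """Cross-replicate consensus with means, SDs and replicate coverage."""

    mz: float
    rt: float
    drift_time: float | None
    mz_sd: float
    rt_sd: float
    drift_sd: float
    abundance: float
    n_replicates: int
    in_all_replicates: bool
    members: list[FeatureRecord]


def align_replicates(
    replicates: Sequence[Sequence[FeatureRecord]],
    tolerances: AlignmentTolerances | None = None,
) -> list[ConsensusFeature]:
    """Greedy centroid grouping of features across replicates.

    Features are visited in order of descending abundance and joined to the
    first existing group whose centroid lies within all three tolerances;
    otherwise they seed a new group.  The procedure is deterministic.
    """
    tol = tolerances or AlignmentTolerances()
    if not replicates:
        return []
    n_reps = len(replicates)
    all_feats: list[FeatureRecord] = [f for rep in replicates for f in rep]
    all_feats.sort(key=lambda f: (-f.abundance, f.mz, f.rt))

    groups: list[list[FeatureRecord]] = []
    centroids: list[tuple[float, float, float | None]] = []
    for feat in all_feats:
        placed = False
        for gi, (cmz, crt, cdt) in enumerate(centroids):
            if abs(feat.mz - cmz) > tol.mz_tol(cmz):
                continue
            if abs(feat.rt - crt) > tol.rt_tol(crt):
                continue
            if cdt is not None and feat.drift_time is not None:
                if abs(feat.drift_time - cdt) > tol.drift_tol(cdt):
                    continue
            groups[gi].append(feat)
            members = groups[gi]
            dts = [f.drift_time for f in members if f.drift_time is not None]
            centroids[gi] = (
                float(np.mean([f.mz for f in members])),
                float(np.mean([f.rt for f in members])),
                float(np.mean(dts)) if dts else None,
            )
            placed = True
            break
        if not placed:
            groups.append([feat])
            centroids.append((feat.mz, feat.rt, feat.drift_time))

    out: list[ConsensusFeature] = []
    for members in groups:
        mzs = np.array([f.mz for f in members])
        rts = np.array([f.rt for f in members])
        dts = np.array([f.drift_time for f in members if f.drift_time is not None])
        reps = {f.replicate for f in members}
        out.append(
            ConsensusFeature(
                mz=float(mzs.mean()),
                rt=float(rts.mean()),
                drift_time=float(dts.mean()) if dts.size else None,
                mz_sd=float(mzs.std(ddof=0)),
                rt_sd=float(rts.std(ddof=0)),
                drift_sd=float(dts.std(ddof=0)) if dts.size else 0.0,
                abundance=float(np.mean([f.abundance for f in members])),
                n_replicates=len(reps),
                in_all_replicates=len(reps) == n_reps,
                members=members,
            )
        )
    return out
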