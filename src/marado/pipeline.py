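"""Full identification cascade and result/record I/O.

The cascade narrows an MS1 feature list to annotated trehalose lipids:

1. RKMD filter (Kendrick chain, tolerance +-0.1 around allowed integers);
2. class retention-time window;
3. match against the computer-generated candidate library (+-5 mDa);
4. DIA fragment confirmation (diagnostic trehalose fragments + acyl-specific
   fragments, Pearson r > 0.9 against the precursor EIC);
5. authentic-standard matching on m/z, RT and CCS;
6. homologous-series trendline validation.

Every stage can only shrink the candidate set; per-stage counts are logged.
Annotations carry an MSI confidence level: 1 requires a standard match, 2
requires fragment or trendline evidence, 3 is m/z-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import (
    FragmentSpec,
    TREHALOSE_FRAGMENT_2H2O,
    parse_lipid_name,
    theoretical_fragments,
)
from .dia import ReconstructedSpectrum, assign_fragments, diagnostic_screen
from .kendrick import KendrickConfig, lyso_reference_kmd, rkmd_filter
from .library import (
    CandidateEntry,
    CandidateMatch,
    FeatureRecord,
    LYSO_RT_WINDOW,
    MAR_RT_WINDOW,
    default_fatty_acid_pool,
    generate_library,
    match_features,
)
from .standards import StandardRow, StandardsTable, default_standards
from .trendlines import (
    DEFAULT_CCS_TOLERANCE,
    DEFAULT_RT_TOLERANCE,
    HomologSeriesKey,
    validate_candidate,
)

__all__ = [
    "PipelineConfig",
    "AnnotationResult",
    "IdentificationReport",
    "match_standard",
    "identify",
    "identify_lyso",
    "read_feature_table",
    "write_feature_table",
    "write_results",
    "write_massbank",
    "write_msp",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tolerances, windows and energies of the identification cascade."""

    mz_tolerance: float = 0.005  # Da, MS1 match
    rt_window_mar: tuple[float, float] = MAR_RT_WINDOW
    rt_window_lyso: tuple[float, float] = LYSO_RT_WINDOW
    kendrick: KendrickConfig = field(default_factory=KendrickConfig)
    kendrick_lyso: KendrickConfig = field(
        default_factory=lambda: KendrickConfig(reference_kmd=lyso_reference_kmd())
    )
    correlation_threshold: float = 0.9
    collision_energy_mar: float = 20.0  # most informative for diacyl species
    collision_energy_lyso: float = 10.0  # non-targeted lyso search
    collision_energy_lyso_confirm: float = 20.0  # acyl fragments for structure
    rt_tolerance: float = DEFAULT_RT_TOLERANCE  # relative, standards + trendlines
    ccs_tolerance: float = DEFAULT_CCS_TOLERANCE
    require_fragments_for_level2: bool = True

    def rt_windows(self) -> dict[str, tuple[float, float]]:
        return {"Mar": self.rt_window_mar, "LysoMar": self.rt_window_lyso}


@dataclass
class AnnotationResult:
    """One annotated feature with its ranked candidate(s) and MSI level."""

    feature: FeatureRecord
    candidates: list[CandidateMatch]
    msi_level: int
    spectrum: ReconstructedSpectrum | None = None

    @property
    def best(self) -> CandidateMatch:
        return self.candidates[0]

    @property
    def name(self) -> str:
        return self.best.candidate.lipid.name


@dataclass
class IdentificationReport:
    results: list[AnnotationResult]
    stage_counts: dict[str, int]


def match_standard(
    feature: FeatureRecord,
    standards: StandardsTable,
    mz_tolerance: float = 0.005,
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
    ccs_tolerance: float = DEFAULT_CCS_TOLERANCE,
) -> StandardRow | None:
    """Match a feature to an authentic standard on m/z, RT and CCS jointly.

    All three dimensions must agree (m/z absolutely, RT and CCS relatively);
    among several qualifying standards the one nearest in combined normalized
    distance wins -- this is what separates the isobars Mar(16:0/16:0) and
    Mar(15:0/17:0) by their RT.
    """
    if feature.ccs is None:
        return None
    best: tuple[float, StandardRow] | None = None
    for row in standards:
        if row.polarity != feature.polarity or row.ccs is None:
            continue
        dmz = abs(feature.mz - row.mz)
        drt = abs(feature.rt - row.rt) / row.rt
        dccs = abs(feature.ccs - row.ccs) / row.ccs
        if dmz > mz_tolerance or drt > rt_tolerance or dccs > ccs_tolerance:
            continue
        dist = math.sqrt(
            (dmz / mz_tolerance) ** 2
            + (drt / rt_tolerance) ** 2
            + (dccs / ccs_tolerance) ** 2
        )
        if best is None or dist < best[0]:
            best = (dist, row)
    return best[1] if best else None


def _fragment_evidence(
    match: CandidateMatch, spectrum: ReconstructedSpectrum
) -> tuple[bool, bool, list]:
    """(diagnostic head fragments seen, candidate-specific acyl fragment seen, retained)."""
    lipid = match.candidate.lipid
    retained_kinds = {frag.kind for frag, _, _ in spectrum.peaks}
    if lipid.lipid_class == "Mar":
        diagnostic = {"[Tre-H2O-H]-", "[Tre-2H2O-H]-"} <= retained_kinds
    else:
        diagnostic = "[Tre-H2O-H]-" in retained_kinds
    own_acyl_mz = {
        round(f.mz, 4)
        for f in theoretical_fragments(lipid, match.candidate.adduct)
        if f.kind in ("[RCOO]-", "[M-RCOOH]-", "[RCO]+")
    }
    acyl_hits = [
        (frag, apex, r)
        for frag, apex, r in spectrum.peaks
        if round(frag.mz, 4) in own_acyl_mz
    ]
    return diagnostic, len(acyl_hits) > 0, acyl_hits


def _annotate(
    features: Sequence[FeatureRecord],
    frames: pd.DataFrame | None,
    library: Sequence[CandidateEntry],
    standards: StandardsTable | None,
    config: PipelineConfig,
    lipid_class: str,
    collision_energy: float,
    trend_standards: StandardsTable | None = None,
    kendrick_config: KendrickConfig | None = None,
) -> IdentificationReport:
    counts: dict[str, int] = {"features_in": len(features)}
    lib_pols = {e.adduct.polarity for e in library}
    feat_pols = {f.polarity for f in features}
    if feat_pols - lib_pols:
        raise ValueError(
            f"feature polarity {feat_pols} does not match library {lib_pols}"
        )

    # 1. RKMD filter
    after_rkmd = rkmd_filter(features, kendrick_config or config.kendrick)
    counts["after_rkmd"] = len(after_rkmd)

    # 2. class RT window
    lo, hi = config.rt_windows()[lipid_class]
    in_window = [f for f in after_rkmd if lo <= f.rt <= hi]
    counts["after_rt_window"] = len(in_window)

    # 3. library match (ambiguity over isobars preserved)
    lib = [e for e in library if e.lipid.lipid_class == lipid_class]
    matches = match_features(
        in_window, lib, config.mz_tolerance, config.rt_windows()
    )
    by_feature: dict[int, list[CandidateMatch]] = {}
    for m in matches:
        by_feature.setdefault(id(m.feature), []).append(m)
    counts["after_library_match"] = len(by_feature)

    # trendline models from the standards (single-field values)
    trend_source = trend_standards if trend_standards is not None else standards
    trend_models = (
        trend_source.trendline_models(adduct="[M+FA-H]-") if trend_source else {}
    )

    results: list[AnnotationResult] = []
    n_frag = n_std = n_trend = 0
    for feature in in_window:
        cands = by_feature.get(id(feature))
        if not cands:
            continue

        spectrum: ReconstructedSpectrum | None = None
        if frames is not None and len(frames) and feature.drift_time is not None:
            all_frags = {}
            for m in cands:
                for f in theoretical_fragments(m.candidate.lipid, m.candidate.adduct):
                    all_frags[round(f.mz, 4)] = f
            if lipid_class == "LysoMar":
                # probe the diacyl-only head fragment: its coelution marks a
                # maradolipid mis-sorted into the lyso RT window
                probe = FragmentSpec("[Tre-2H2O-H]-", TREHALOSE_FRAGMENT_2H2O, -1)
                all_frags.setdefault(round(probe.mz, 4), probe)
            try:
                spectrum = assign_fragments(
                    feature,
                    sorted(all_frags.values(), key=lambda f: f.mz),
                    frames,
                    threshold=config.correlation_threshold,
                    collision_energy=collision_energy,
                )
            except ValueError:
                spectrum = None

        std_row = (
            match_standard(
                feature, standards, config.mz_tolerance,
                config.rt_tolerance, config.ccs_tolerance,
            )
            if standards
            else None
        )

        any_frag = False
        for m in cands:
            if spectrum is not None:
                diag, acyl, hits = _fragment_evidence(m, spectrum)
                m.diagnostic_coelution = diag
                m.retained_fragments = hits
                m.fragments_confirmed = diag and acyl
                any_frag |= m.fragments_confirmed
            lipid = m.candidate.lipid
            key = HomologSeriesKey(
                lipid.lipid_class, lipid.total_dbe, m.candidate.adduct.name
            )
            models = trend_models.get(key, {})
            verdict = validate_candidate(
                lipid.total_carbons,
                feature.rt,
                feature.ccs,
                models.get("rt"),
                models.get("ccs"),
                config.rt_tolerance,
                config.ccs_tolerance,
            )
            m.trendline_supported = verdict.supported if verdict.has_model else None
            if std_row is not None and lipid.name == std_row.name:
                m.standard_matched = std_row.name

        # rank: standard match, then fragment evidence, then |m/z error|
        cands.sort(
            key=lambda m: (
                m.standard_matched is None,
                not m.fragments_confirmed,
                -len(m.retained_fragments),
                abs(m.mz_error_mda),
            )
        )
        best = cands[0]
        if best.standard_matched:
            level = 1
        elif best.fragments_confirmed or best.trendline_supported:
            level = 2
        elif not config.require_fragments_for_level2 and best.diagnostic_coelution:
            level = 2
        else:
            level = 3

        n_frag += int(any_frag)
        n_std += int(std_row is not None)
        n_trend += int(bool(best.trendline_supported))
        results.append(AnnotationResult(feature, cands, level, spectrum))

    counts["with_fragment_evidence"] = n_frag
    counts["standard_matched"] = n_std
    counts["trendline_supported"] = n_trend
    counts["annotated"] = len(results)
    return IdentificationReport(results, counts)


def identify(
    features: Sequence[FeatureRecord],
    frames: pd.DataFrame | None = None,
    library: Sequence[CandidateEntry] | None = None,
    standards: StandardsTable | None = None,
    config: PipelineConfig | None = None,
) -> IdentificationReport:
    """Run the maradolipid identification cascade on negative-mode MS1 features."""
    config = config or PipelineConfig()
    if library is None:
        library = generate_library(default_fatty_acid_pool(), ("Mar",), ("[M+FA-H]-",))
    if standards is None:
        standards = default_standards()
    return _annotate(
        features, frames, library, standards, config,
        lipid_class="Mar", collision_energy=config.collision_energy_mar,
    )


def identify_lyso(
    features: Sequence[FeatureRecord],
    frames: pd.DataFrame | None = None,
    library: Sequence[CandidateEntry] | None = None,
    config: PipelineConfig | None = None,
    trend_standards: StandardsTable | None = None,
) -> IdentificationReport:
    """Lysomaradolipid cascade: early RT window, mono-dehydrated head fragment only.

    Features whose reconstructed spectra show *both* trehalose head fragments
    co-eluting are diacyl species, not lyso forms, and are excluded.  Isomer
    pairs at the same m/z (two chromatographic peaks) are reported as two
    distinct annotations.  There are no authentic lyso standards, so MSI
    level 1 is unreachable here; trendlines may come from measured reference
    values via *trend_standards*.
    """
    config = config or PipelineConfig()
    if library is None:
        library = generate_library(
            default_fatty_acid_pool(), ("LysoMar",), ("[M+FA-H]-",)
        )
    report = _annotate(
        features, frames, library, None, config,
        lipid_class="LysoMar",
        collision_energy=config.collision_energy_lyso_confirm,
        trend_standards=trend_standards,
        kendrick_config=config.kendrick_lyso,
    )
    kept = []
    demoted = 0
    for res in report.results:
        if res.spectrum is not None:
            kinds = {f.kind for f, _, _ in res.spectrum.peaks}
            if "[Tre-2H2O-H]-" in kinds and "[Tre-H2O-H]-" in kinds:
                demoted += 1  # both head fragments -> diacyl (Mar) hint
                continue
        kept.append(res)
    report.results = kept
    report.stage_counts["demoted_to_mar"] = demoted
    report.stage_counts["annotated"] = len(kept)
    return report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = {
    "mz": True,  # required
    "rt": True,
    "drift_time": False,
    "ccs": False,
    "abundance": False,
    "polarity": False,
    "replicate": False,
}


def read_feature_table(path: str | Path) -> list[FeatureRecord]:
    """Read an MS1 feature table (CSV).  Required columns: ``mz``, ``rt``."""
    df = pd.read_csv(path)
    for col, required in _FEATURE_COLUMNS.items():
        if required and col not in df.columns:
            raise ValueError(f"feature table {path}: missing required column {col!r}")
    features = []
    for i, row in df.iterrows():
        line = i + 2  # header + 1-based
        try:
            features.append(
                FeatureRecord(
                    mz=float(row["mz"]),
                    rt=float(row["rt"]),
                    drift_time=float(row["drift_time"])
                    if "drift_time" in df.columns and pd.notna(row["drift_time"])
                    else None,
                    ccs=float(row["ccs"])
                    if "ccs" in df.columns and pd.notna(row["ccs"])
                    else None,
                    abundance=float(row.get("abundance", 0.0) or 0.0),
                    polarity=str(row.get("polarity", "negative")),
                    replicate=int(row.get("replicate", 0) or 0),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"feature table {path}, line {line}: {exc}") from exc
    return features


def write_feature_table(features: Sequence[FeatureRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mz": [round(f.mz, 6) for f in features],
            "rt": [round(f.rt, 6) for f in features],
            "drift_time": [
                round(f.drift_time, 6) if f.drift_time is not None else np.nan
                for f in features
            ],
            "ccs": [round(f.ccs, 6) if f.ccs is not None else np.nan for f in features],
            "abundance": [f.abundance for f in features],
            "polarity": [f.polarity for f in features],
            "replicate": [f.replicate for f in features],
        }
    ).to_csv(path, index=False)


def results_to_frame(results: Sequence[AnnotationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        best = res.best
        rows.append(
            {
                "name": best.candidate.lipid.name,
                "adduct": best.candidate.adduct.name,
                "mz": round(res.feature.mz, 4),
                "theoretical_mz": round(best.candidate.mz, 4),
                "mz_error_mda": round(best.mz_error_mda, 2),
                "rt": round(res.feature.rt, 3),
                "ccs": round(res.feature.ccs, 2) if res.feature.ccs else np.nan,
                "msi_level": res.msi_level,
                "rkmd": round(best.kendrick.rkmd, 3) if best.kendrick else np.nan,
                "fragments_confirmed": best.fragments_confirmed,
                "n_retained_fragments": res.spectrum.n_peaks if res.spectrum else 0,
                "trendline_supported": best.trendline_supported,
                "standard_matched": best.standard_matched or "",
                "n_isobaric_candidates": len(res.candidates),
                "all_candidates": ";".join(
                    m.candidate.lipid.name for m in res.candidates
                ),
            }
        )
    return pd.DataFrame(rows)


def write_results(results: Sequence[AnnotationResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def write_massbank(
    spectrum: ReconstructedSpectrum,
    path: str | Path,
    name: str = "unknown trehalose lipid",
    accession: str = "MSBNK-XXXX-0000001",
    formula: str | None = None,
    ion_mode: str = "NEGATIVE",
) -> None:
    """Write a reconstructed DIA spectrum as a MassBank-style record."""
    peaks = [(f.mz, inten) for f, inten, _ in spectrum.peaks]
    base = max((i for _, i in peaks), default=1.0)
    lines = [
        f"ACCESSION: {accession}",
        f"RECORD_TITLE: {name}; UHPLC-IM-Q-ToF; MS2; CE: {spectrum.collision_energy:g} eV",
        f"CH$NAME: {name}",
    ]
    if formula:
        lines.append(f"CH$FORMULA: {formula}")
    lines += [
        "AC$INSTRUMENT_TYPE: LC-ESI-QTOF",
        "AC$MASS_SPECTROMETRY: MS_TYPE MS2",
        f"AC$MASS_SPECTROMETRY: ION_MODE {ion_mode}",
        f"AC$MASS_SPECTROMETRY: COLLISION_ENERGY {spectrum.collision_energy:g} eV",
        f"MS$FOCUSED_ION: PRECURSOR_M/Z {spectrum.precursor_mz:.4f}",
        f"PK$NUM_PEAK: {len(peaks)}",
        "PK$PEAK: m/z int. rel.int.",
    ]
    for mz, inten in peaks:
        lines.append(f"  {mz:.4f} {inten:.1f} {max(1, round(999 * inten / base))}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def write_msp(
    spectrum: ReconstructedSpectrum, path: str | Path, name: str = "unknown"
) -> None:
    """Write a reconstructed spectrum in NIST MSP format."""
    lines = [
        f"NAME: {name}",
        f"PRECURSORMZ: {spectrum.precursor_mz:.4f}",
        f"RETENTIONTIME: {spectrum.precursor_rt:.3f}",
        f"COLLISIONENERGY: {spectrum.collision_energy:g}",
        f"Num Peaks: {spectrum.n_peaks}",
    ]
    for frag, inten, _ in spectrum.peaks:
        lines.append(f"{frag.mz:.4f} {inten:.1f}")
    Path(path).write_text("\n".join(lines) + "\n")
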