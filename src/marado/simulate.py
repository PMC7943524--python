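"""Ground-truthed synthetic LC-IM-MS datasets with alternating-energy frames.

The generator emulates the acquisition the analysis modules assume: each
planted species appears in the low-energy frames as a 2D Gaussian peak in
(RT, drift time), centered at its RT and at the arrival time implied by its
CCS through the single-field calibration; its fragments appear in the
high-energy frames sharing the precursor's RT elution profile and the
precursor's drift position (drift separation happens before fragmentation).
Fragment intensities follow energy-dependent profiles: neutral-loss fragments
appear at 20 eV but not 40 eV, acyl carboxylate and trehalose head fragments
peak at 40 eV.

Decoy interferences probe the specificity of each filter: features off the
RKMD grid, diagnostic-fragment lookalikes at shifted RT (to challenge the
correlation gate), and co-drifting ions just outside the m/z window.

Every random draw flows from the explicit seed; the same config yields
byte-identical frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    FragmentSpec,
    TREHALOSE_FRAGMENT_H2O,
    TrehaloseLipid,
    adduct_mz,
    get_adduct,
    parse_lipid_name,
    theoretical_fragments,
)
from .ccs import DriftGasState, SingleFieldCalibration, ccs_to_arrival_time
from .dia import FRAME_COLUMNS
from .library import FeatureRecord
from .standards import MARADOLIPID_STANDARDS, StandardRow

__all__ = [
    "GroundTruthSpecies",
    "SimulationConfig",
    "default_calibration",
    "default_fragment_profile",
    "standards_ground_truth",
    "simulate_dataset",
    "inject_decoys",
]


def default_calibration(
    beta: float = 0.02, t_fix_ms: float = 0.5, gas: DriftGasState | None = None
) -> SingleFieldCalibration:
    """A plausible drift-tube single-field calibration (t_A ~ 28-33 ms for lipids)."""
    return SingleFieldCalibration(beta=beta, t_fix_ms=t_fix_ms, gas=gas or DriftGasState())


def default_fragment_profile(
    lipid: TrehaloseLipid, adduct: str = "[M+FA-H]-"
) -> dict[float, dict[str, float]]:
    """Energy-dependent fragment intensities as fractions of the precursor apex.

    Keys of the inner dicts are fragment labels from
    :func:`~marado.chem.theoretical_fragments`.  Neutral-loss fragments
    ([M-RCOOH]-) are present only at 20 eV; 40 eV gives the highest
    carboxylate and trehalose head-fragment intensities; 10 eV leaves mostly
    the deprotonated precursor plus a weak mono-dehydrated head fragment.
    """
    frags = theoretical_fragments(lipid, adduct)
    profile: dict[float, dict[str, float]] = {10.0: {}, 20.0: {}, 40.0: {}}
    for frag in frags:
        if frag.kind == "[M-H]-":
            profile[10.0][frag.label] = 0.35
            profile[20.0][frag.label] = 0.40
        elif frag.kind == "[M-RCOOH]-":
            profile[20.0][frag.label] = 0.30
        elif frag.kind == "[RCOO]-":
            profile[20.0][frag.label] = 0.40
            profile[40.0][frag.label] = 0.80
        elif frag.kind == "[Tre-H2O-H]-":
            profile[10.0][frag.label] = 0.15
            profile[20.0][frag.label] = 0.50
            profile[40.0][frag.label] = 0.90
        elif frag.kind == "[Tre-2H2O-H]-":
            profile[20.0][frag.label] = 0.40
            profile[40.0][frag.label] = 0.80
        elif frag.kind in ("[M-H2O+H]+", "[RCO]+"):
            profile[20.0][frag.label] = 0.50
            profile[40.0][frag.label] = 0.70
    return profile


@dataclass(frozen=True)
class GroundTruthSpecies:
    """One planted lipid with its true position and fragment behavior."""

    lipid: TrehaloseLipid
    adduct: str
    rt: float  # min
    ccs: float  # A^2
    abundance: float = 1000.0
    fragment_profile: Mapping[float, Mapping[str, float]] | None = None

    @property
    def mz(self) -> float:
        return adduct_mz(self.lipid.mass, self.adduct)

    def profile(self) -> Mapping[float, Mapping[str, float]]:
        if self.fragment_profile is not None:
            return self.fragment_profile
        return default_fragment_profile(self.lipid, self.adduct)


@dataclass(frozen=True)
class SimulationConfig:
    """Grid, peak-shape, noise, calibration and decoy settings.

    Defaults reflect the study conditions the analysis assumes: ~0.03 min RT
    sampling with ~0.05 min Gaussian peak sigma (3-4 s wide LC peaks), 0.1 ms
    drift sampling with 0.2 ms drift sigma, an 18-min run, 1 % multiplicative
    intensity noise with a small uniform noise floor.
    """

    seed: int = 0
    rt_step: float = 0.03  # min
    drift_step: float = 0.1  # ms
    rt_sigma: float = 0.05  # min
    drift_sigma: float = 0.2  # ms
    noise_sigma: float = 0.01  # log-normal multiplicative sigma
    noise_floor: float = 1.0  # counts, uniform [0, floor)
    run_duration: float = 18.0  # min
    collision_energies: tuple[float, ...] = (20.0,)
    precursor_survival: float = 1.0  # precursor fraction in low-energy frames
    min_intensity: float = 0.5  # discard generated points below this
    n_decoy_features: int = 0
    n_decoy_fragments: int = 0
    n_decoy_interferences: int = 0
    decoy_rt_shift: float = 0.5  # min, RT offset of decoy fragments
    calibration: SingleFieldCalibration = field(default_factory=default_calibration)

    def rt_grid(self) -> np.ndarray:
        return np.round(
            np.arange(0.0, self.run_duration + self.rt_step / 2, self.rt_step), 6
        )


def _gaussian_blob(
    cfg: SimulationConfig,
    rt0: float,
    dt0: float,
    mz: float,
    apex: float,
    energy: str,
    ce: float,
    rng: np.random.Generator,
    n_sigma: float = 4.0,
) -> pd.DataFrame:
    """Points of one 2D Gaussian peak snapped to the global RT/drift grids."""
    grid = cfg.rt_grid()
    lo = np.searchsorted(grid, rt0 - n_sigma * cfg.rt_sigma)
    hi = np.searchsorted(grid, rt0 + n_sigma * cfg.rt_sigma, side="right")
    rts = grid[lo:hi]
    dts = np.round(
        np.arange(
            cfg.drift_step * math.floor((dt0 - n_sigma * cfg.drift_sigma) / cfg.drift_step),
            dt0 + n_sigma * cfg.drift_sigma + cfg.drift_step / 2,
            cfg.drift_step,
        ),
        6,
    )
    dts = dts[dts > 0]
    rr, dd = np.meshgrid(rts, dts, indexing="ij")
    inten = apex * np.exp(
        -0.5 * ((rr - rt0) / cfg.rt_sigma) ** 2
        - 0.5 * ((dd - dt0) / cfg.drift_sigma) ** 2
    )
    if cfg.noise_sigma > 0:
        inten = inten * np.exp(rng.normal(0.0, cfg.noise_sigma, inten.shape))
    if cfg.noise_floor > 0:
        inten = inten + rng.uniform(0.0, cfg.noise_floor, inten.shape)
    mask = inten >= cfg.min_intensity
    return pd.DataFrame(
        {
            "rt_min": rr[mask],
            "dt_ms": dd[mask],
            "mz": mz,
            "intensity": inten[mask],
            "energy": energy,
            "ce_ev": ce,
        }
    )


def simulate_dataset(
    species: Sequence[GroundTruthSpecies], config: SimulationConfig
) -> tuple[pd.DataFrame, list[FeatureRecord], pd.DataFrame]:
    """Generate (frames, feature table, ground-truth manifest) for *species*.

    The feature table lists each species at its apex values, with the CCS a
    feature would obtain from the same single-field calibration the frames
    were generated with (an exact roundtrip).  The manifest records every
    planted truth and, when decoys are requested, every decoy.
    """
    rng = np.random.default_rng(config.seed)
    parts: list[pd.DataFrame] = []
    features: list[FeatureRecord] = []
    manifest_rows: list[dict] = []

    for sp in species:
        if not (0.0 <= sp.rt <= config.run_duration):
            raise ValueError(
                f"species RT {sp.rt} min outside the {config.run_duration} min run"
            )
        adduct = get_adduct(sp.adduct)
        dt0 = ccs_to_arrival_time(sp.ccs, config.calibration, sp.mz, adduct.charge)
        frag_mz = {f.label: f.mz for f in theoretical_fragments(sp.lipid, sp.adduct)}
        profile = sp.profile()
        for ce in config.collision_energies:
            parts.append(
                _gaussian_blob(
                    config, sp.rt, dt0, sp.mz,
                    sp.abundance * config.precursor_survival, "low", ce, rng,
                )
            )
            for label, fraction in profile.get(ce, {}).items():
                if fraction <= 0 or label not in frag_mz:
                    continue
                parts.append(
                    _gaussian_blob(
                        config, sp.rt, dt0, frag_mz[label],
                        sp.abundance * fraction, "high", ce, rng,
                    )
                )
        features.append(
            FeatureRecord(
                mz=sp.mz,
                rt=sp.rt,
                drift_time=dt0,
                ccs=sp.ccs,
                abundance=sp.abundance,
                polarity=adduct.polarity,
            )
        )
        manifest_rows.append(
            {
                "kind": "species",
                "name": sp.lipid.name,
                "adduct": sp.adduct,
                "mz": sp.mz,
                "rt": sp.rt,
                "drift_time": dt0,
                "ccs": sp.ccs,
                "abundance": sp.abundance,
            }
        )

    frames = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=list(FRAME_COLUMNS))
    )

    if config.n_decoy_features or config.n_decoy_fragments or config.n_decoy_interferences:
        frames, decoy_features, decoy_rows = inject_decoys(
            frames, config, species=species, rng=rng
        )
        features.extend(decoy_features)
        manifest_rows.extend(decoy_rows)

    manifest = pd.DataFrame(manifest_rows)
    frames = frames.sort_values(["ce_ev", "energy", "rt_min", "dt_ms", "mz"]).reset_index(
        drop=True
    )
    return frames, features, manifest


def _rkmd_violating_mz(rng: np.random.Generator) -> float:
    """Random m/z whose RKMD is far (> 0.25) from every small non-positive integer."""
    from .kendrick import KendrickConfig, kendrick_values

    cfg = KendrickConfig()
    while True:
        mz = rng.uniform(600.0, 950.0)
        kv = kendrick_values(mz, cfg)
        if all(abs(kv.rkmd - k) > 0.25 for k in range(-45, 1)):
            return float(mz)


def inject_decoys(
    frames: pd.DataFrame,
    config: SimulationConfig,
    species: Sequence[GroundTruthSpecies] = (),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[FeatureRecord], list[dict]]:
    """Add decoy interferences to *frames*; returns (frames, decoy features, manifest rows).

    Three decoy kinds:

    * ``decoy_feature`` -- MS1 features at m/z violating the RKMD grid,
      planted inside the maradolipid RT window (the RKMD filter must reject
      them);
    * ``decoy_fragment`` -- ions at the diagnostic head-fragment m/z but
      shifted in RT relative to a real precursor (the correlation gate must
      reject them);
    * ``decoy_interference`` -- co-drifting, co-eluting ions 0.2 Da outside a
      precursor's m/z window (EIC extraction must exclude them).
    """
    rng = rng or np.random.default_rng(config.seed)
    parts = [frames]
    decoy_features: list[FeatureRecord] = []
    manifest_rows: list[dict] = []
    calib = config.calibration

    for _ in range(config.n_decoy_features):
        mz = _rkmd_violating_mz(rng)
        rt = float(rng.uniform(12.0, 17.0))
        dt = float(rng.uniform(25.0, 35.0))
        abundance = float(rng.uniform(200.0, 800.0))
        for ce in config.collision_energies:
            parts.append(_gaussian_blob(config, rt, dt, mz, abundance, "low", ce, rng))
        from .ccs import arrival_time_to_ccs

        decoy_features.append(
            FeatureRecord(
                mz=mz, rt=rt, drift_time=dt,
                ccs=arrival_time_to_ccs(dt, calib, mz, -1),
                abundance=abundance, polarity="negative",
            )
        )
        manifest_rows.append(
            {"kind": "decoy_feature", "name": "", "adduct": "", "mz": mz,
             "rt": rt, "drift_time": dt, "ccs": float("nan"), "abundance": abundance}
        )

    anchors = list(species)
    for i in range(config.n_decoy_fragments):
        if anchors:
            sp = anchors[i % len(anchors)]
            adduct = get_adduct(sp.adduct)
            dt0 = ccs_to_arrival_time(sp.ccs, calib, sp.mz, adduct.charge)
            rt = sp.rt + config.decoy_rt_shift * (1 if i % 2 == 0 else -1)
        else:
            dt0 = float(rng.uniform(25.0, 35.0))
            rt = float(rng.uniform(2.0, 16.0))
        rt = float(np.clip(rt, 0.2, config.run_duration - 0.2))
        abundance = float(rng.uniform(100.0, 400.0))
        for ce in config.collision_energies:
            parts.append(
                _gaussian_blob(
                    config, rt, dt0, TREHALOSE_FRAGMENT_H2O, abundance, "high", ce, rng
                )
            )
        manifest_rows.append(
            {"kind": "decoy_fragment", "name": "", "adduct": "",
             "mz": TREHALOSE_FRAGMENT_H2O, "rt": rt, "drift_time": dt0,
             "ccs": float("nan"), "abundance": abundance}
        )

    for i in range(config.n_decoy_interferences):
        if anchors:
            sp = anchors[i % len(anchors)]
            adduct = get_adduct(sp.adduct)
            dt0 = ccs_to_arrival_time(sp.ccs, calib, sp.mz, adduct.charge)
            mz = sp.mz + 0.2
            rt = sp.rt
        else:
            dt0 = float(rng.uniform(25.0, 35.0))
            mz = float(rng.uniform(600.0, 950.0))
            rt = float(rng.uniform(2.0, 16.0))
        abundance = float(rng.uniform(100.0, 400.0))
        for ce in config.collision_energies:
            parts.append(_gaussian_blob(config, rt, dt0, mz, abundance, "low", ce, rng))
            parts.append(_gaussian_blob(config, rt, dt0, mz, abundance, "high", ce, rng))
        manifest_rows.append(
            {"kind": "decoy_interference", "name": "", "adduct": "", "mz": mz,
             "rt": rt, "drift_time": dt0, "ccs": float("nan"), "abundance": abundance}
        )

    out = pd.concat(parts, ignore_index=True)
    return out, decoy_features, manifest_rows


def standards_ground_truth(
    adduct: str = "[M+FA-H]-",
    abundance: float = 1000.0,
    rows: Sequence[StandardRow] = MARADOLIPID_STANDARDS,
) -> list[GroundTruthSpecies]:
    """Ground-truth species for the authentic standards at their reference RT/CCS."""
    out = []
    for row in rows:
        if row.adduct != adduct or row.ccs is None:
            continue
        out.append(
            GroundTruthSpecies(
                lipid=parse_lipid_name(row.name),
                adduct=adduct,
                rt=row.rt,
                ccs=row.ccs,
                abundance=abundance,
            )
        )
    return out
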