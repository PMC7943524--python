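"""EIC extraction, smoothing, correlation gating and the diagnostic screen."""

import numpy as np
import pandas as pd
import pytest

from marado.chem import (
    TREHALOSE_FRAGMENT_2H2O,
    TREHALOSE_FRAGMENT_H2O,
    parse_lipid_name,
    theoretical_fragments,
)
from marado.dia import (
    EICTrace,
    assign_fragments,
    detect_peaks,
    diagnostic_screen,
    extract_eic,
    pearson_correlation,
    read_frames,
    smooth_trace,
    write_frames,
)
from marado.simulate import (
    GroundTruthSpecies,
    SimulationConfig,
    simulate_dataset,
)


def trace(rt, inten, **kw):
    defaults = dict(mz_center=800.0, mz_width=0.05, drift_center=None,
                    drift_width=None, energy="high")
    defaults.update(kw)
    return EICTrace(np.asarray(rt, float), np.asarray(inten, float), **defaults)


def frame_df(rows):
    return pd.DataFrame(
        rows, columns=["rt_min", "dt_ms", "mz", "intensity", "energy", "ce_ev"]
    )


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        t = trace(np.arange(10) * 0.1, np.full(10, 5.0))
        assert np.allclose(smooth_trace(t, 3).intensity, 5.0)

    def test_single_spike_becomes_plateau(self):
        t = trace(np.arange(7) * 0.1, [0, 0, 0, 3, 0, 0, 0])
        sm = smooth_trace(t, 3)
        assert np.allclose(sm.intensity, [0, 0, 1, 1, 1, 0, 0])

    def test_gaussian_area_preserved_apex_reduced(self):
        rt = np.arange(0, 3, 0.05)
        inten = 100 * np.exp(-0.5 * ((rt - 1.5) / 0.1) ** 2)
        sm = smooth_trace(trace(rt, inten), 3)
        assert sm.intensity.max() < inten.max()
        assert sm.intensity.sum() == pytest.approx(inten.sum(), rel=1e-3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(trace([0, 1, 2], [1, 2, 3]), 4)


class TestExtractEic:
    def test_empty_frames_give_all_zero_trace(self):
        t = extract_eic(frame_df([]), 800.0)
        assert t.rt.size == 0

    def test_single_point_inside_windows(self):
        frames = frame_df([(5.0, 30.0, 800.0, 42.0, "high", 20.0)])
        t = extract_eic(frames, 800.0, 0.05, 30.0, 2.0, "high")
        assert t.intensity.tolist() == [42.0]

    def test_point_outside_half_width_excluded(self):
        frames = frame_df(
            [
                (5.0, 30.0, 800.026, 42.0, "high", 20.0),  # outside +-0.025
                (5.0, 30.0, 800.024, 7.0, "high", 20.0),  # inside
            ]
        )
        t = extract_eic(frames, 800.0, 0.05, 30.0, 2.0, "high")
        assert t.intensity.tolist() == [7.0]

    def test_zero_filling_on_grid(self):
        frames = frame_df(
            [
                (5.0, 30.0, 800.0, 10.0, "high", 20.0),
                (5.1, 30.0, 900.0, 99.0, "high", 20.0),  # other m/z defines grid point
            ]
        )
        t = extract_eic(frames, 800.0, 0.05, 30.0, 2.0, "high")
        assert t.rt.tolist() == [5.0, 5.1]
        assert t.intensity.tolist() == [10.0, 0.0]

    def test_additivity_over_frame_partition(self):
        rng = np.random.default_rng(0)
        rows = [
            (round(rt, 3), 30.0, 800.0 + rng.uniform(-0.02, 0.02), rng.uniform(1, 10),
             "high", 20.0)
            for rt in np.repeat(np.arange(5.0, 5.5, 0.1), 4)
        ]
        frames = frame_df(rows)
        a, b = frames.iloc[::2], frames.iloc[1::2]
        grid = np.unique(frames["rt_min"])
        total = extract_eic(frames, 800.0, rt_grid=grid).intensity
        parts = (
            extract_eic(a, 800.0, rt_grid=grid).intensity
            + extract_eic(b, 800.0, rt_grid=grid).intensity
        )
        assert np.allclose(total, parts)

    def test_frames_roundtrip_through_csv(self, tmp_path):
        frames = frame_df([(5.0, 30.0, 800.0, 10.0, "low", 20.0)])
        path = tmp_path / "frames.csv"
        write_frames(frames, path)
        back = read_frames(path)
        pd.testing.assert_frame_equal(back, frames)


class TestPearson:
    def test_identical_traces(self):
        t = trace([0, 1, 2, 3, 4], [1, 5, 9, 5, 1])
        assert pearson_correlation(t, t) == pytest.approx(1.0)

    def test_perfectly_anticorrelated(self):
        a = trace([0, 1, 2, 3, 4], [1, 2, 3, 4, 5])
        b = trace([0, 1, 2, 3, 4], [5, 4, 3, 2, 1])
        assert pearson_correlation(a, b) == pytest.approx(-1.0)

    def test_shifted_gaussian_below_threshold(self):
        """r for a Gaussian vs itself shifted by 2 sigma, against a direct-sum oracle."""
        rt = np.arange(0, 4, 0.05)
        sigma, mu = 0.2, 2.0
        g1 = np.exp(-0.5 * ((rt - mu) / sigma) ** 2)
        g2 = np.exp(-0.5 * ((rt - mu - 2 * sigma) / sigma) ** 2)
        # independent direct-summation Pearson
        n = rt.size
        num = n * np.sum(g1 * g2) - np.sum(g1) * np.sum(g2)
        den = np.sqrt(n * np.sum(g1**2) - np.sum(g1) ** 2) * np.sqrt(
            n * np.sum(g2**2) - np.sum(g2) ** 2
        )
        oracle = num / den
        got = pearson_correlation(trace(rt, g1), trace(rt, g2))
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got < 0.9

    def test_zero_variance_is_nan(self):
        a = trace([0, 1, 2, 3, 4], [1, 1, 1, 1, 1])
        b = trace([0, 1, 2, 3, 4], [1, 5, 9, 5, 1])
        assert np.isnan(pearson_correlation(a, b))

    def test_too_few_points_is_nan(self):
        a = trace([0, 1, 2], [1, 2, 1])
        assert np.isnan(pearson_correlation(a, a))


class TestDetectPeaks:
    def test_monotone_trace_has_no_interior_peaks(self):
        assert detect_peaks(trace(np.arange(6), np.arange(6.0))) == []

    def test_two_separated_gaussians(self):
        rt = np.arange(0, 8, 0.05)
        inten = 10 * np.exp(-0.5 * ((rt - 2) / 0.1) ** 2) + 5 * np.exp(
            -0.5 * ((rt - 6) / 0.1) ** 2
        )
        peaks = detect_peaks(trace(rt, inten), min_height=1.0)
        assert len(peaks) == 2
        assert peaks[0][0] == pytest.approx(2.0, abs=0.05)
        assert peaks[1][0] == pytest.approx(6.0, abs=0.05)

    def test_all_zero_trace(self):
        assert detect_peaks(trace(np.arange(6), np.zeros(6))) == []


class TestAssignFragments:
    def test_true_fragments_retained_with_high_r(self, single_species_dataset):
        species, config, frames, features = single_species_dataset
        frags = theoretical_fragments(species[0].lipid, "[M+FA-H]-")
        planted = {
            f.label for f in frags
            if species[0].profile()[20.0].get(f.label, 0) > 0
        }
        spec = assign_fragments(features[0], frags, frames, collision_energy=20.0)
        retained = {f.label for f, _, _ in spec.peaks}
        assert retained == planted
        assert all(r > 0.99 for _, _, r in spec.peaks)
        assert [f.mz for f, _, _ in spec.peaks] == sorted(
            f.mz for f, _, _ in spec.peaks
        )

    def test_decoy_fragment_far_in_rt_rejected(self):
        lipid = parse_lipid_name("Mar(14:0/14:0)")
        species = [GroundTruthSpecies(lipid, "[M+FA-H]-", 12.94, 284.40, 1000.0)]
        config = SimulationConfig(seed=5, n_decoy_fragments=2, decoy_rt_shift=0.5)
        frames, features, manifest = simulate_dataset(species, config)
        frags = theoretical_fragments(lipid, "[M+FA-H]-")
        spec = assign_fragments(features[0], frags, frames, collision_energy=20.0)
        # the decoy sits at 323.0984 but 0.5 min (10 sigma) away: the diagnostic
        # fragment of the true species must still be retained, the decoy ignored
        heads = [r for f, _, r in spec.peaks if f.kind == "[Tre-H2O-H]-"]
        assert len(heads) == 1 and heads[0] > 0.9

    def test_strict_threshold_empties_spectrum(self, single_species_dataset):
        species, config, frames, features = single_species_dataset
        frags = theoretical_fragments(species[0].lipid, "[M+FA-H]-")
        spec = assign_fragments(
            features[0], frags, frames, threshold=1.0, collision_energy=20.0
        )
        assert spec.n_peaks == 0  # strict inequality r > 1 never holds

    def test_missing_precursor_rejected(self, single_species_dataset):
        _, _, frames, features = single_species_dataset
        ghost = features[0].__class__(mz=700.0, rt=5.0, drift_time=30.0)
        with pytest.raises(ValueError):
            assign_fragments(ghost, [], frames, collision_energy=20.0)


@pytest.fixture(scope="module")
def two_energy_dataset():
    lipid = parse_lipid_name("Mar(14:0/18:1)")
    species = [GroundTruthSpecies(lipid, "[M+FA-H]-", 14.35, 294.37, 1000.0)]
    config = SimulationConfig(seed=9, collision_energies=(20.0, 40.0))
    frames, features, _ = simulate_dataset(species, config)
    return lipid, frames, features


class TestEnergyProfiles:

    def test_neutral_losses_only_at_20_ev(self, two_energy_dataset):
        lipid, frames, features = two_energy_dataset
        frags = theoretical_fragments(lipid, "[M+FA-H]-")
        at20 = assign_fragments(features[0], frags, frames, collision_energy=20.0)
        at40 = assign_fragments(features[0], frags, frames, collision_energy=40.0)
        kinds20 = {f.kind for f, _, _ in at20.peaks}
        kinds40 = {f.kind for f, _, _ in at40.peaks}
        assert "[M-RCOOH]-" in kinds20
        assert "[M-RCOOH]-" not in kinds40
        assert "[RCOO]-" in kinds20 and "[RCOO]-" in kinds40


class TestDiagnosticScreen:
    def test_mar_and_lyso_hints(self):
        species = [
            GroundTruthSpecies(
                parse_lipid_name("Mar(14:0/14:0)"), "[M+FA-H]-", 14.0, 284.40, 1000.0
            ),
            GroundTruthSpecies(
                parse_lipid_name("LysoMar(17:0)"), "[M+FA-H]-", 4.0, 247.44, 800.0
            ),
        ]
        frames, _, _ = simulate_dataset(species, SimulationConfig(seed=13))
        hints = diagnostic_screen(frames, collision_energy=20.0, min_height=10.0)
        by_hint = {h["hint"]: h["rt"] for h in hints}
        assert by_hint["Mar"] == pytest.approx(14.0, abs=0.1)
        assert by_hint["LysoMar"] == pytest.approx(4.0, abs=0.1)

    def test_no_trehalose_lipids_no_hints(self):
        frames = frame_df([(5.0, 30.0, 800.0, 100.0, "high", 20.0)])
        assert diagnostic_screen(frames, collision_energy=20.0) == []
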