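"""Plate simulator: kinetic structure, determinism and conservation laws."""

import numpy as np
import pytest

from nucleokit.library import enzyme_for_simulation
from nucleokit.simulate import (
    ConfigurationError,
    DyeModel,
    SimConfig,
    Trajectory,
    make_ladder,
    render_fluorescence,
    simulate_plate,
    simulate_progress,
)
from nucleokit.substrates import EnzymeSpec, SubstrateSpec

from conftest import make_config


class TestProgressCurves:
    def test_no_enzyme_is_flat(self, subs):
        cfg = make_config(subs["S_blunt"])
        tr = simulate_progress(cfg, rng=np.random.default_rng(0))
        assert np.all(tr.primary_nt == 80.0)
        assert np.all(tr.secondary_nt == 0.0)

    def test_fully_blocked_with_enzyme_is_valid_not_error(self, subs, exo3):
        # no accessible site at full purity: the negative-control phenotype
        cfg = make_config(subs["S_b3b3"], exo3, 40.0, purity=1.0)
        tr = simulate_progress(cfg, rng=np.random.default_rng(0))
        assert np.all(tr.primary_nt == 80.0)

    def test_deterministic_front_matches_closed_form(self, subs, exo3):
        cfg = make_config(
            subs["S_b3"], exo3, 10.0, deterministic=True, purity=1.0, protected_window_nt=0
        )
        tr = simulate_progress(cfg, rng=np.random.default_rng(0))
        speed = exo3.base_rate * 10.0
        expect = np.maximum(80.0 - speed * tr.time_s, 0.0)
        assert np.all(np.abs(tr.primary_nt[0] - expect) <= 1.0)

    def test_stochastic_mean_converges_to_closed_form(self, subs, exo3):
        """Population mean tracks the mean-field front within 2% mid-reaction."""
        cfg = make_config(
            subs["S_b3"], exo3, 10.0, purity=1.0, protected_window_nt=0,
            n_molecules=10_000, n_replicates=1,
        )
        tr = simulate_progress(cfg, rng=np.random.default_rng(7))
        expect = np.maximum(80.0 - exo3.base_rate * 10.0 * tr.time_s, 0.0)
        mid = (expect > 20) & (expect < 70)  # away from the completion boundary
        rel = np.abs(tr.primary_nt[0][mid] - expect[mid]) / expect[mid]
        assert rel.max() < 0.02

    def test_per_molecule_conservation_and_monotonicity(self, subs, exo3):
        cfg = make_config(subs["S_b3"], exo3, 10.0, n_molecules=200, n_replicates=1)
        tr = simulate_progress(cfg, rng=np.random.default_rng(3), return_molecules=True)
        L = 80
        prev = None
        for grp in tr.molecules[0]:
            Rt, Rb = grp["R_top"], grp["R_bottom"]
            for t in tr.time_s[::5]:
                ds = ((Rt > t) & (Rb > t)).sum(axis=1)
                resected = ((Rt <= t) | (Rb <= t)).sum(axis=1)
                assert np.all(ds + resected == L)
            # per-molecule duplex length never increases
            ds_path = np.array([((Rt > t) & (Rb > t)).sum(axis=1) for t in tr.time_s])
            assert np.all(np.diff(ds_path, axis=0) <= 0)

    def test_blocked_control_asymptotic_loss_band(self, subs, exo3):
        """Doubly-blocked substrate + enzyme loses 15-20% of signal (purity)."""
        cfg = make_config(
            subs["S_b3b3"], exo3, 40.0, duration_s=7200.0, dye=DyeModel(bleach_rate=0.0)
        )
        rng = np.random.default_rng(5)
        tr = simulate_progress(cfg, rng=rng)
        F = render_fluorescence(tr, cfg.dye, 50.0, rng=rng, noise_sd=0.0)
        loss = float((1 - F[:, -1] / F[:, 0]).mean())
        assert 0.15 <= loss <= 0.20

    def test_polymerase_non_decreasing_and_hard_stop(self, subs):
        kf = enzyme_for_simulation("Klenow")
        cfg = make_config(
            subs["pt_primer20"], kf, 1.0, polymerase_hard_stop=52, duration_s=7200.0
        )
        tr = simulate_progress(cfg, rng=np.random.default_rng(11))
        assert np.all(np.diff(tr.primary_nt, axis=1) >= 0)
        assert tr.primary_nt.max() <= 52.0
        assert tr.primary_nt[:, -1] == pytest.approx(52.0, abs=0.5)

    def test_primer_beyond_hairpin_extends_fully(self, subs):
        kf = enzyme_for_simulation("Klenow")
        cfg = make_config(
            subs["pt_primer60"], kf, 1.0, polymerase_hard_stop=52, duration_s=14400.0
        )
        tr = simulate_progress(cfg, rng=np.random.default_rng(11))
        assert tr.primary_nt[:, -1] == pytest.approx(80.0, abs=0.5)

    def test_distributive_mode_matches_exponential_decay(self, subs):
        dnase = enzyme_for_simulation("DNase I")
        cfg = make_config(subs["S_blunt"], dnase, 16.0, n_molecules=20_000, n_replicates=1)
        tr = simulate_progress(cfg, rng=np.random.default_rng(2))
        expect = 80.0 * np.exp(-dnase.base_rate * 16.0 * tr.time_s)
        assert np.max(np.abs(tr.primary_nt[0] - expect)) < 1.0


class TestRendering:
    def test_background_only_when_no_dna(self):
        dye = DyeModel(bleach_rate=2e-4)
        t = np.arange(0, 1000, 50.0)
        tr = Trajectory(t, np.zeros((1, t.size)), np.zeros((1, t.size)),
                        SubstrateSpec(name="blank"), "flat")
        F = render_fluorescence(tr, dye, 50.0, noise_sd=0.0)
        assert np.allclose(F[0], dye.background * np.exp(-dye.bleach_rate * t))

    def test_constant_length_no_bleach_is_constant(self, subs, quiet_dye):
        cfg = make_config(subs["S_blunt"], dye=quiet_dye)
        tr = simulate_progress(cfg, rng=np.random.default_rng(0))
        F = render_fluorescence(tr, quiet_dye, 50.0, noise_sd=0.0)
        assert np.ptp(F) == 0.0

    def test_saturation_clips_above_cap(self):
        dye = DyeModel()
        m = np.array([0.5, 1.0, 2.4, 2.5, 5.0, 50.0])
        s = dye.saturate(m)
        assert np.allclose(s[:4], m[:4])  # identity below the cap
        assert s[-1] < 2.5 * 1.6  # plateaus near 1.5x the cap
        assert np.all(np.diff(s) >= 0)


class TestPlateAssembly:
    def test_same_seed_identical_matrix(self, subs, exo3):
        cfg = SimConfig(substrate=subs["S_b3"], enzyme=exo3, enzyme_conc=10.0)
        ladder = make_ladder("resection")
        p1 = simulate_plate([cfg], ladder, seed=1)
        p2 = simulate_plate([cfg], ladder, seed=1)
        assert p1.data.equals(p2.data)
        assert p1.wellmap.equals(p2.wellmap)

    def test_ladder_only_plate_flat_up_to_noise_and_bleach(self, subs):
        cfg = SimConfig(substrate=subs["S_blunt"], noise_sd=0.0)
        plate = simulate_plate([cfg], make_ladder("resection"), seed=2)
        # detrend the shared bleaching; every well should then be constant
        t = plate.times
        for w in plate.data.columns:
            y = plate.data[w].to_numpy() * np.exp(cfg.dye.bleach_rate * t)
            assert np.ptp(y) / y[0] < 1e-9

    def test_missing_ladder_roles_raise(self, subs, exo3):
        cfg = SimConfig(substrate=subs["S_b3"], enzyme=exo3, enzyme_conc=10.0)
        bad = make_ladder("resection")
        bad.members = bad.members[:2]  # only two lengths, no 0-point
        with pytest.raises(ConfigurationError) as err:
            simulate_plate([cfg], bad, seed=0)
        assert "ladder" in str(err.value)

    def test_sample_wells_have_matched_controls(self, subs, exo3):
        cfg = SimConfig(substrate=subs["S_b3"], enzyme=exo3, enzyme_conc=10.0)
        plate = simulate_plate([cfg], make_ladder("resection"), seed=0)
        wm = plate.wellmap
        for row in wm[wm["role"] == "sample"].itertuples():
            assert row.control_well
            ctrl = wm[wm["well"] == row.control_well].iloc[0]
            assert ctrl["role"] == "control" and ctrl["substrate"] == row.substrate
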