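"""Simulator contracts: fixed points, determinism, conservation, spectra."""

import json
import warnings

import numpy as np
import pytest

from patternfit import stability as st
from patternfit.simulators import (CahnHilliardParams, EWParams,
                                   GrayScottParams, GrowthTruncationWarning,
                                   KTParams, LSystemSpec, StochasticGrowthConfig,
                                   TuringParams, build_estimation_dataset,
                                   build_selection_dataset, generate_l_system,
                                   regenerate_row, rewrite,
                                   simulate_cahn_hilliard,
                                   simulate_edwards_wilkinson,
                                   simulate_gray_scott, simulate_growth,
                                   simulate_kt, simulate_phase_field,
                                   simulate_turing, simulate_turing_batch)
from patternfit.simulators.phase_field import PhaseFieldParams


class TestTuring:
    def test_zero_state_is_fixed_point(self):
        zeros = np.zeros((32, 32))
        u = simulate_turing(TuringParams(f_v=0.9, g_v=0.8, q=0.0),
                            init=(zeros, zeros), steps=500, size=32)
        assert np.all(u == 0.0)

    def test_patterned_wavenumber_matches_theory(self):
        p = TuringParams(f_v=0.9078, g_v=0.8018)
        u = simulate_turing(p, seed=3, size=64, method="imex", dt=0.25,
                            steps=2400)
        k = st.dominant_wavenumber(u)
        assert abs(k - st.kmax_closed(p)) / st.kmax_closed(p) < 0.25

    def test_no_band_decays(self):
        # strong inhibitor feedback: det(J) > 0, tr(J) < 0, and the band
        # condition D_v f_u - D_u g_v > 2 sqrt(D_u D_v det J) fails
        p = TuringParams(f_v=1.5, g_v=0.9)
        assert st.growth_rate(0.0, p) < 0
        assert not st.has_positive_band(p)
        u = simulate_turing(p, seed=0, size=32, steps=3000)
        assert np.max(np.abs(u)) < 0.01  # below the init amplitude

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate_turing(TuringParams(f_v=0.9, g_v=0.8), dt=1.0, size=32)

    def test_batch_matches_parameter_count_and_determinism(self):
        fv = np.array([0.85, 0.9]); gv = np.array([0.7, 0.8])
        u1 = simulate_turing_batch(fv, gv, seeds=[1, 2], size=32, t_final=50)
        u2 = simulate_turing_batch(fv, gv, seeds=[1, 2], size=32, t_final=50)
        assert u1.shape == (2, 32, 32)
        assert np.array_equal(u1, u2)


class TestGrayScott:
    def test_homogeneous_fixed_point(self):
        snaps = simulate_gray_scott(GrayScottParams(capture_times=(50, 100)),
                                    size=32, perturb=False)
        for s in snaps:
            assert np.all(s == 0.0)  # v stays at the trivial state

    def test_snapshots_evolve(self):
        snaps = simulate_gray_scott(
            GrayScottParams(capture_times=(500, 1500, 3000)), seed=1, size=48)
        assert len(snaps) == 3
        for a in range(len(snaps)):
            for b in range(a + 1, len(snaps)):
                assert not np.allclose(snaps[a], snaps[b])

    def test_empty_capture_list(self):
        assert simulate_gray_scott(GrayScottParams(capture_times=()),
                                   size=32) == []

    def test_decreasing_capture_times_rejected(self):
        with pytest.raises(ValueError):
            GrayScottParams(capture_times=(100, 50))


class TestKT:
    def test_zero_amplitudes_freeze_state(self):
        p = KTParams(act_amp=0.0, inh_amp=0.0, steps=20)
        u1 = simulate_kt(p, seed=5, size=32)
        u2 = simulate_kt(KTParams(act_amp=0.0, inh_amp=0.0, steps=0),
                         seed=5, size=32)
        assert np.array_equal(u1, u2)

    def test_output_within_clip_bounds(self):
        u = simulate_kt(KTParams(steps=100), seed=2, size=48)
        assert u.min() >= 0.0 and u.max() <= 1.0

    def test_classic_regime_selects_finite_wavenumber(self):
        u = simulate_kt(KTParams(steps=300), seed=7, size=64)
        k = st.dominant_wavenumber(u)
        assert 0 < k < np.pi

    def test_kernel_too_large_rejected(self):
        with pytest.raises(ValueError):
            simulate_kt(KTParams(inh_radius=40.0), size=32)


class TestGrowth:
    def test_eden_occupies_one_cell_per_event(self):
        n = 57
        g = simulate_growth(StochasticGrowthConfig(model="eden", events=n,
                                                   seed=1), size=64)
        assert int(g.sum()) == n + 1

    def test_dla_single_particle_adjacent_to_seed(self):
        g = simulate_growth(StochasticGrowthConfig(model="dla", events=1,
                                                   seed=3), size=64)
        assert int(g.sum()) == 2
        ys, xs = np.nonzero(g)
        assert abs(ys[0] - ys[1]) + abs(xs[0] - xs[1]) == 1

    def test_determinism(self):
        cfg = StochasticGrowthConfig(model="dla", events=30, seed=11)
        assert np.array_equal(simulate_growth(cfg, size=64),
                              simulate_growth(cfg, size=64))

    def test_truncation_warning_at_edge(self):
        with pytest.warns(GrowthTruncationWarning):
            simulate_growth(StochasticGrowthConfig(model="eden", events=600,
                                                   seed=0), size=16)


class TestEdwardsWilkinson:
    def test_flat_no_noise_stays_flat(self):
        u = simulate_edwards_wilkinson(EWParams(noise_amp=0.0, steps=200),
                                       size=32)
        assert np.all(u == 0.0)

    def test_mean_drift_within_sampling_bound(self):
        p = EWParams(noise_amp=1.0, dt=0.1, steps=500, seed=9)
        h = simulate_edwards_wilkinson(p, size=32)
        # spatial mean = mean of all summed noise increments:
        # sd = amp*sqrt(dt*steps/Ncells)
        sd = p.noise_amp * np.sqrt(p.dt * p.steps / 32**2)
        assert abs(h.mean()) < 5 * sd

    def test_interface_width_grows(self):
        widths = []
        for steps in (50, 400):
            ws = [simulate_edwards_wilkinson(
                EWParams(noise_amp=1.0, steps=steps, seed=s), size=32).std()
                for s in range(20)]
            widths.append(np.mean(ws))
        assert widths[1] > widths[0]

    def test_stability_invariant_enforced(self):
        with pytest.raises(ValueError):
            EWParams(nu=4.0, dt=0.1)


class TestLSystem:
    def test_identity_rewriting(self):
        spec = LSystemSpec(axiom="F", productions={}, iterations=3)
        assert rewrite(spec) == "F"

    def test_single_substitution(self):
        spec = LSystemSpec(axiom="F", productions={"F": "F[+F]F"}, iterations=1)
        assert rewrite(spec) == "F[+F]F"

    def test_double_substitution(self):
        spec = LSystemSpec(axiom="F", productions={"F": "F[+F]F"}, iterations=2)
        assert rewrite(spec) == "F[+F]F[+F[+F]F]F[+F]F"

    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(ValueError):
            LSystemSpec(productions={"F": "F[+F"})

    def test_rendering_stays_in_raster(self):
        spec = LSystemSpec(axiom="F", productions={"F": "F[+F]F[-F]F"},
                           iterations=4, angle=25.0)
        g = generate_l_system(spec, size=128)
        assert g.shape == (128, 128)
        assert set(np.unique(g)) <= {0.0, 1.0}
        assert g.sum() > 0


class TestPhaseField:
    def test_uniform_phase_is_stationary(self):
        p = PhaseFieldParams(noise_amp=0.0, nucleus_radius=0.0, steps=50)
        u = simulate_phase_field(p, size=32)
        assert np.allclose(u, 0.0)

    def test_replicates_differ_only_by_seed(self):
        a = simulate_phase_field(PhaseFieldParams(seed=1, steps=150), size=32)
        b = simulate_phase_field(PhaseFieldParams(seed=2, steps=150), size=32)
        assert not np.array_equal(a, b)

    def test_phase_bounds(self):
        u = simulate_phase_field(PhaseFieldParams(seed=4, steps=300), size=48)
        assert u.min() >= 0.0 and u.max() <= 1.0


class TestCahnHilliard:
    def test_mass_conservation(self):
        p = CahnHilliardParams(seed=2, steps=500)
        from patternfit.simulators._common import uniform_noise
        init = 0.1 + uniform_noise((48, 48), 0.1, 2)
        out = simulate_cahn_hilliard(p, init=init)
        assert abs(out.mean() - init.mean()) < 1e-8

    def test_zero_state_fixed(self):
        out = simulate_cahn_hilliard(CahnHilliardParams(steps=100),
                                     init=np.zeros((32, 32)))
        assert np.all(out == 0.0)

    def test_coarsening_lowers_spectral_centroid(self):
        # domain growth shifts spectral weight to lower wavenumbers; the
        # power-weighted centroid resolves the shift below one radial bin
        def centroid(field):
            k, P = st.radial_power_spectrum(field)
            P = P.copy()
            P[0] = 0.0
            return float((k * P).sum() / P.sum())
        early = simulate_cahn_hilliard(CahnHilliardParams(seed=5, steps=200),
                                       size=64)
        late = simulate_cahn_hilliard(CahnHilliardParams(seed=5, steps=8000),
                                      size=64)
        assert centroid(late) < centroid(early)


class TestManifests:
    def test_default_selection_composition(self):
        m = build_selection_dataset(seed=0)
        comp = m.composition
        assert comp == {"turing": 228, "kt": 288, "gray_scott": 486,
                        "edwards_wilkinson": 99, "eden": 182, "dla": 300,
                        "l_system": 133, "phase_field": 83}
        assert len(m) == 1799

    def test_empty_config(self):
        assert len(build_selection_dataset(config={}, seed=0)) == 0

    def test_custom_count_distinct_params(self):
        m = build_selection_dataset(config={"turing": 5}, seed=1)
        assert len(m) == 5
        assert m.rows["param_json"].nunique() == 5

    def test_estimation_dataset_defaults(self):
        m = build_estimation_dataset(seed=0)
        assert (m.rows["split"] == "train").sum() == 9700
        assert (m.rows["split"] == "val").sum() == 600
        params = [json.loads(s) for s in m.rows["param_json"]]
        fv = np.array([p["f_v"] for p in params])
        gv = np.array([p["g_v"] for p in params])
        assert fv.min() >= 0.6 and fv.max() <= 1.0
        assert gv.min() >= 0.6 and gv.max() <= 1.0

    def test_estimation_no_train_rows(self):
        m = build_estimation_dataset(n_train=0, n_val=10, seed=0)
        assert len(m) == 10 and set(m.rows["split"]) == {"val"}

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            build_estimation_dataset(box=((-0.5, 1.0), (0.6, 1.0)))

    def test_row_regeneration_reproduces_image(self, tmp_path):
        m = build_selection_dataset(config={"eden": 2, "l_system": 1},
                                    out_dir=tmp_path, seed=3, render=True,
                                    size=48)
        from patternfit.imaging import read_image
        for _, row in m.rows.iterrows():
            on_disk = read_image(row["path"])
            again = regenerate_row(row, size=48)
            assert np.array_equal(np.round(on_disk.pixels * 255),
                                  np.round(again.pixels * 255))

    def test_manifest_csv_roundtrip(self, tmp_path):
        from patternfit.simulators import DatasetManifest
        m = build_selection_dataset(config={"turing": 3}, seed=0)
        m.to_csv(tmp_path / "m.csv")
        back = DatasetManifest.from_csv(tmp_path / "m.csv")
        assert back.rows["param_json"].tolist() == m.rows["param_json"].tolist()
        sidecar = json.loads((tmp_path / "m.composition.json").read_text())
        assert sidecar["total"] == 3
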