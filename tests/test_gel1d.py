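"""1D active-gel solver: velocity equation, conservative transport, regimes."""

import numpy as np
import pytest

from actogel.gel1d import (
    Field1D,
    GelParams,
    StimulusProtocol,
    classify_spatial,
    initial_field_1d,
    local_activation_experiment,
    mean_rho,
    memory_correlation,
    simulate_1d,
    transport_step_1d,
    velocity_step_1d,
)
from conftest import empty_cortex_1d, rho_bump_1d


class TestVelocityStep:
    def test_uniform_actomyosin_drives_no_flow(self, gel):
        v = np.zeros(gel.N)
        for _ in range(50):
            v = velocity_step_1d(v, 0.7 * np.ones(gel.N), gel, dt=0.5)
        assert np.abs(v).max() < 1e-14

    @pytest.mark.parametrize("n_mode,F", [(1, 0.5), (3, 1.2)])
    def test_fourier_mode_steady_state_closed_form(self, gel, n_mode, F):
        # forced with F sin(kx), the steady state is F sin(kx)/(1 + lam^2 k^2)
        k = 2 * np.pi * n_mode / gel.L
        x = gel.grid()
        forcing = F * np.sin(k * x)
        v = np.zeros(gel.N)
        for _ in range(3000):
            v = velocity_step_1d(v, np.ones(gel.N), gel, dt=0.5, forcing=forcing)
        expect = forcing / (1.0 + gel.lam**2 * k**2)
        assert np.abs(v - expect).max() < 1e-10 * np.abs(expect).max()

    def test_gaussian_bump_drives_convergent_antisymmetric_flow(self, gel):
        x = gel.grid()
        c = gel.L / 2
        m = 0.1 + np.exp(-0.5 * ((x - c) / 2.0) ** 2)
        v = np.zeros(gel.N)
        for _ in range(500):
            v = velocity_step_1d(v, m, gel, dt=0.5)
        # flow points toward the bump from both sides
        left, right = x < c, x > c
        assert v[left][np.argmax(m[left])] > 0
        assert v[right][np.argmax(m[right])] < 0
        # antisymmetric about the bump centre
        assert np.abs(v + v[::-1]).max() < 1e-10 * np.abs(v).max()

    def test_nan_input_rejected(self, gel):
        v = np.zeros(gel.N)
        v[0] = np.nan
        with pytest.raises(FloatingPointError):
            velocity_step_1d(v, np.ones(gel.N), gel, dt=0.1)


class TestTransportStep:
    def test_identity_without_flow_or_diffusion(self, gel):
        rng = np.random.default_rng(1)
        c = rng.uniform(0.1, 1.0, gel.N)
        out = transport_step_1d(c, np.zeros(gel.N), D=0.0, dt=0.2, dx=gel.dx)
        assert np.array_equal(out, c)

    @pytest.mark.parametrize("limiter", ["upwind", "vanleer"])
    def test_mass_conserved_over_many_steps(self, gel, limiter):
        rng = np.random.default_rng(2)
        c = rng.uniform(0.1, 1.0, gel.N)
        v = 0.3 * np.sin(4 * np.pi * gel.grid() / gel.L)
        total0 = c.sum()
        for _ in range(1000):
            c = transport_step_1d(c, v, D=0.05, dt=0.2, dx=gel.dx, limiter=limiter)
        assert abs(c.sum() - total0) < 1e-10 * total0

    def test_uniform_advection_translates_profile(self, gel):
        # Gaussian advected at constant speed vs the exact translated profile
        x = gel.grid()
        sig = 5.0
        v0 = 0.5
        c = np.exp(-0.5 * ((x - gel.L / 3) / sig) ** 2)
        n_steps, dt = 400, 0.2
        out = c.copy()
        for _ in range(n_steps):
            out = transport_step_1d(out, v0 * np.ones(gel.N), D=0.0, dt=dt, dx=gel.dx)
        shift = v0 * n_steps * dt
        dev = (x - gel.L / 3 - shift + gel.L / 2) % gel.L - gel.L / 2
        exact = np.exp(-0.5 * (dev / sig) ** 2)
        # limited scheme: no phase error, bounded extremum clipping
        assert x[out.argmax()] == pytest.approx(x[exact.argmax()], abs=gel.dx)
        assert np.abs(out - exact).max() < 0.1 * exact.max()
        assert out.min() > -1e-12  # positivity


class TestSimulate1D:
    def test_uniform_dynamics_match_reaction_ode(self, chem, gel):
        # sigma' = 0 with uniform data: spatial means follow the well-mixed ODE
        from scipy.integrate import solve_ivp

        from actogel.kinetics import rm_rate, rr_rate

        p = chem.with_(S=0.02)
        gp = gel.with_(sigma_prime=0.0, N=64)
        init = Field1D(x=gp.grid(), r=0.2 * np.ones(64), m=0.1 * np.ones(64),
                       v=np.zeros(64))
        kymo = simulate_1d(init, p, gp, 0.02, t_end=300)
        sol = solve_ivp(
            lambda t, y: [rr_rate(y[0], y[1], p), rm_rate(y[0], y[1], p)],
            (0, 300), [0.2, 0.1], t_eval=kymo.time.values, rtol=1e-10, atol=1e-12,
        )
        assert np.abs(kymo.r.values.mean(axis=1) - sol.y[0]).max() < 2e-3
        assert np.abs(kymo.m.values.mean(axis=1) - sol.y[1]).max() < 2e-3

    def test_no_turing_patterns_with_fast_activator_diffusion(self, chem, gel):
        # activator diffusing faster than inhibitor cannot pattern without stress
        p = chem.with_(S=0.01)
        gp = gel.with_(sigma_prime=0.0, N=100)
        init = initial_field_1d(gp, p, seed=4, noise_amplitude=1e-2)
        kymo = simulate_1d(init, p, gp, 0.01, t_end=600, seed=4)
        m_fin = kymo.m.values[-1]
        assert m_fin.std() / m_fin.mean() < 1e-3

    def test_localized_peak_with_rhoa_flanks_at_high_contractility(self, chem, gel):
        gp = gel.with_(sigma_prime=80.0)
        kymo = simulate_1d(rho_bump_1d(gp, chem), chem, gp, 0.0, t_end=500)
        label, _ = classify_spatial(kymo, chem)
        assert label == "localized-contraction"
        m_fin, r_fin = kymo.m.values[-1], kymo.r.values[-1]
        assert m_fin.max() > 10 * m_fin.min()
        # RhoA sits beside, not on top of, the actomyosin peak
        i_m, i_r = m_fin.argmax(), r_fin.argmax()
        x = kymo.x.values
        sep = abs(x[i_r] - x[i_m])
        assert 0 < min(sep, gp.L - sep) < gp.lam

    def test_actomyosin_advection_required_for_pattern(self, chem, gel):
        gp = gel.with_(sigma_prime=100.0)
        kymo = simulate_1d(rho_bump_1d(gp, chem), chem, gp, 0.0, t_end=500,
                           advect_m=False)
        m_fin = kymo.m.values[-1]
        assert m_fin.std() / m_fin.mean() < 0.05  # uniform steady state

    def test_nearby_peaks_merge(self, chem, gel):
        # two localized contractions closer than lam attract and merge
        gp = gel.with_(sigma_prime=80.0)
        frac = 0.45 * gp.lam / gp.L
        init = rho_bump_1d(gp, chem, centers=(0.5 - frac, 0.5 + frac))
        kymo = simulate_1d(init, chem, gp, 0.0, t_end=800)
        from scipy.signal import find_peaks

        m_fin = kymo.m.values[-1]
        peaks, _ = find_peaks(np.tile(m_fin, 2), prominence=0.2 * m_fin.max())
        n_peaks = len([pk for pk in peaks if pk < gp.N])
        assert n_peaks == 1

    def test_blowup_detection_raises(self, chem, gel):
        gp = gel.with_(sigma_prime=80.0, N=32)
        init = Field1D(x=gp.grid(), r=np.full(32, 1e5), m=np.full(32, 1e5),
                       v=np.zeros(32))
        with pytest.raises(FloatingPointError):
            simulate_1d(init, chem.with_(S=1.0), gp, 1.0, t_end=50)


class TestSpatialClassification:
    def test_excitable_uniform_at_low_contractility(self, chem, gel):
        p = chem.with_(S=0.002)
        gp = gel.with_(sigma_prime=5.0)
        kymo = simulate_1d(empty_cortex_1d(gp), p, gp, 0.002, t_end=1200)
        assert classify_spatial(kymo, p)[0] == "excitable"

    def test_pulsatile_flows_at_high_contractility(self, chem, gel):
        p = chem.with_(S=0.01)
        gp = gel.with_(sigma_prime=80.0)
        kymo = simulate_1d(empty_cortex_1d(gp), p, gp, 0.01, t_end=1200)
        assert classify_spatial(kymo, p)[0] == "pulsatile-flows"

    def test_propagating_waves_at_moderate_contractility(self, chem, gel):
        p = chem.with_(S=0.01)
        gp = gel.with_(sigma_prime=50.0)
        kymo = simulate_1d(empty_cortex_1d(gp), p, gp, 0.01, t_end=1200)
        assert classify_spatial(kymo, p)[0] == "propagating-waves"

    def test_manufactured_stationary_peak_is_localized(self, chem, gel):
        # synthetic kymograph with a fixed sharp peak
        import xarray as xr

        x = gel.grid()
        t = np.arange(0.0, 400.0)
        m = 0.1 + np.exp(-0.5 * ((x - gel.L / 2) / 3.0) ** 2)
        M = np.tile(m, (len(t), 1))
        kymo = xr.Dataset(
            {"m": (("time", "x"), M), "r": (("time", "x"), 0.1 * M),
             "v": (("time", "x"), np.zeros_like(M)),
             "strain_rate": (("time", "x"), np.zeros_like(M))},
            coords={"time": t, "x": x}, attrs={"L": gel.L},
        )
        assert classify_spatial(kymo)[0] == "localized-contraction"


class TestLocalActivation:
    # response classes of a transient central RhoA stimulus (checked together
    # with runtime bounds in the acceptance suite; here the protocol details)

    def test_no_stimulus_leaves_rest_state(self, gel):
        kymo, label = local_activation_experiment(
            gel.with_(sigma_prime=25.0), S_in=0.0, t_end=300)
        assert label == "soliton"  # trivially "no pattern left behind"
        assert kymo.r.values[-1].max() < 1e-2

    def test_memory_correlation_conventions(self, gel):
        import xarray as xr

        x = gel.grid()
        t = np.arange(0.0, 200.0)
        stim = StimulusProtocol.boxcar(0.03, 60.0, 80.0, 0.0, 100.0)
        ind = stim.indicator(x)
        # r proportional to the boxcar: perfect correlation
        R = np.tile(0.2 + 0.5 * ind, (len(t), 1))
        kymo = xr.Dataset({"r": (("time", "x"), R)}, coords={"time": t, "x": x})
        assert memory_correlation(kymo, stim) == pytest.approx(1.0)
        # spatially constant r: zero by convention
        kymo2 = xr.Dataset({"r": (("time", "x"), np.full((len(t), len(x)), 0.3))},
                           coords={"time": t, "x": x})
        assert memory_correlation(kymo2, stim) == pytest.approx(0.0, abs=1e-12)

    def test_mean_rho_equals_trapezoid_oracle(self, gel):
        import xarray as xr

        x = gel.grid()
        t = np.arange(0.0, 10.0)
        profile = 0.2 + 0.1 * np.sin(2 * np.pi * x / gel.L)
        kymo = xr.Dataset({"r": (("time", "x"), np.tile(profile, (len(t), 1)))},
                          coords={"time": t, "x": x})
        # uniform periodic grid: trapezoidal mean equals the plain mean
        expect = np.trapezoid(np.append(profile, profile[0]),
                              dx=gel.dx) / gel.L
        assert mean_rho(kymo, 5.0) == pytest.approx(expect, rel=1e-12)


class TestStimulusProtocol:
    def test_boxcar_window_in_space_and_time(self):
        s = StimulusProtocol.boxcar(0.03, 10.0, 20.0, 50.0, 150.0)
        x = np.array([5.0, 15.0, 25.0])
        assert np.allclose(s(x, 100.0), [0.0, 0.03, 0.0])
        assert np.allclose(s(x, 200.0), 0.0)
        assert np.allclose(s(x, 10.0), 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol.uniform(-0.01)


class TestRefinementAndOnset:
    @pytest.mark.parametrize("N", [150, 300])
    def test_wave_label_stable_under_grid_refinement(self, chem, N):
        p = chem.with_(S=0.01)
        gp = GelParams(sigma_prime=50.0, N=N)
        kymo = simulate_1d(empty_cortex_1d(gp), p, gp, 0.01, t_end=1000)
        assert classify_spatial(kymo, p)[0] == "propagating-waves"

    @pytest.mark.parametrize("N", [150, 300])
    def test_localized_label_stable_under_grid_refinement(self, chem, N):
        gp = GelParams(sigma_prime=80.0, N=N)
        kymo = simulate_1d(rho_bump_1d(gp, chem), chem, gp, 0.0, t_end=500)
        assert classify_spatial(kymo, chem)[0] == "localized-contraction"

    def test_onset_frequency_and_wavelength_match_dispersion(self, chem):
        # growing stage of a noise-seeded run: the dominant spatial mode and
        # its rotation frequency agree with the fastest-growing eigenmode
        from actogel.linstab import dispersion, select_fixed_point

        p = chem.with_(S=0.01)
        gp = GelParams(sigma_prime=60.0)
        fp = select_fixed_point(p)
        d = dispersion(fp, p, gp)
        rng = np.random.default_rng(3)
        init = Field1D(x=gp.grid(),
                       r=fp.r * (1 + 1e-3 * rng.standard_normal(gp.N)),
                       m=fp.m * np.ones(gp.N), v=np.zeros(gp.N))
        kymo = simulate_1d(init, p, gp, 0.01, t_end=400)
        R = kymo.r.values - fp.r
        spec = np.abs(np.fft.rfft(R[250:350], axis=1)).mean(axis=0)
        spec[0] = 0.0
        n_dom = int(spec.argmax())
        k_meas = 2 * np.pi * n_dom / gp.L
        mode = np.fft.rfft(R, axis=1)[:, n_dom]
        phase = np.unwrap(np.angle(mode[250:350]))
        freq = abs(np.polyfit(np.arange(100.0), phase, 1)[0])
        assert abs(k_meas - d.k_star) / d.k_star < 0.15
        assert abs(freq - d.frequency) / d.frequency < 0.15
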