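"""Integrator correctness: diffusion oracle, splitting, conservation."""

import numpy as np
import pytest

import nucactin as na
from nucactin.geometry import CYTOPLASM, NUCLEUS
from nucactin.parameters import CYTOPLASMIC_SPECIES, NUCLEAR_SPECIES
from nucactin.scenarios import DEFAULT_SEED_CONCENTRATIONS, _uniform_state


def zero_rate_params(params):
    return params.replace(
        gamma_Gc=0, gamma_Fc=0, alpha_Xi_c=0, gamma_Xi_c=0, alpha_Xi_n=0,
        gamma_Xi_n=1e-8, alpha_Ups_c=0, gamma_Ups_c=1e-8, alpha_Ups_n=1e-9,
        gamma_Ups_n=0, alpha_Theta_c=0, gamma_Theta_c=0, mu1=0, mu2=0,
        beta_Pc=0, beta_Pn=0, beta_Cc=0, beta_Cn=0, beta_Xi_c=1e-8, beta_Ups_n=0,
    )


class TestDiffusionStep:
    def test_uniform_field_is_fixed_point(self, toy_domain):
        field = 2.5 * (toy_domain.mask == CYTOPLASM)
        out = na.diffusion_step(field.astype(float), toy_domain, CYTOPLASM,
                                D=0.05, dt=0.01)
        np.testing.assert_allclose(out, field, atol=1e-12)

    def test_zero_diffusivity_is_identity(self, toy_domain, random_state):
        out = na.diffusion_step(random_state["F_c"], toy_domain, CYTOPLASM,
                                D=0.0, dt=0.01)
        np.testing.assert_array_equal(out, random_state["F_c"])

    def test_mass_preserved(self, toy_domain, random_state):
        f = random_state["G_c"]
        out = na.diffusion_step(f, toy_domain, CYTOPLASM, D=0.05, dt=0.01)
        assert out.sum() == pytest.approx(f.sum(), rel=1e-12)

    def test_cosine_eigenmode_decay_matches_closed_form(self):
        """cos(pi x / L) on a rectangle decays at rate D (pi/L)^2."""
        nx, ny = 201, 10
        domain = na.make_rectangle_domain(
            nx, ny, extent=((-1.0, 1.0), (0.0, 20.0 / 201)))
        L = 2.0
        D, dt, T = 0.1, 0.01, 1.0
        mode = np.cos(np.pi * (domain.xc - (-1.0)) / L)
        field = np.tile(mode, (ny, 1)) + 2.0
        ws = na.DiffusionWorkspace(domain)
        for _ in range(int(T / dt)):
            field = na.diffusion_step(field, domain, CYTOPLASM, D, dt, ws)
        amp0, ampT = 1.0, float((field.max() - field.min()) / 2)
        rate = -np.log(ampT / amp0) / T
        expected = D * (np.pi / L) ** 2
        assert rate == pytest.approx(expected, rel=0.01)


class TestStep:
    def test_null_model_uniform_state_is_stationary(self, toy_domain, params):
        p = zero_rate_params(params)
        state = _uniform_state(toy_domain, DEFAULT_SEED_CONCENTRATIONS)
        spec = na.default_transfer_spec(p)
        cfg = na.SolverConfig(dt=0.01, t_end=1.0)
        out, clips, limited = na.step(state, toy_domain, p, spec, cfg)
        assert out.t == pytest.approx(0.01)
        assert clips == 0 and limited == 0
        for name in CYTOPLASMIC_SPECIES + NUCLEAR_SPECIES:
            np.testing.assert_allclose(out[name], state[name], atol=1e-10)

    def test_pure_decay_matches_scalar_recurrence(self, toy_domain, params):
        gamma = 0.3
        p = zero_rate_params(params).replace(gamma_Theta_c=gamma)
        state = _uniform_state(toy_domain, dict(DEFAULT_SEED_CONCENTRATIONS,
                                                Theta_c=1.0))
        spec = na.default_transfer_spec(p)
        cfg = na.SolverConfig(dt=0.01, t_end=1.0)
        k = 20
        cur = state
        for i in range(k):
            cur, _, _ = na.step(cur, toy_domain, p, spec, cfg, _step_no=i)
        mask = toy_domain.mask == CYTOPLASM
        observed = cur["Theta_c"][mask].mean()
        assert observed == pytest.approx((1 - gamma * cfg.dt) ** k, rel=1e-12)
        assert observed == pytest.approx(np.exp(-gamma * k * cfg.dt), rel=2 * gamma * cfg.dt)

    def test_semi_implicit_matches_fine_explicit_reference(self, params, geometry):
        """50 coarse semi-implicit steps vs a dt/100 fully explicit run."""
        domain = na.build_domain(geometry, 41, 41)
        seed = _uniform_state(domain, DEFAULT_SEED_CONCENTRATIONS)
        seed.fields["E_c"] = na.initialize_catalytic_field(domain, geometry)
        spec = na.default_transfer_spec(params)
        cfg = na.SolverConfig(dt=0.01, t_end=0.5)
        # smooth out the artificial uniform seed before comparing schemes
        state0 = na.run(seed, domain, params, spec,
                        cfg.replace(t_end=5.0), snapshot_times=(5.0,)).snapshots[-1]
        state0.t = 0.0
        ref = na.explicit_reference_run(state0, domain, params, spec,
                                        dt=cfg.dt / 100, n_steps=50 * 100)
        final = na.run(state0, domain, params, spec, cfg,
                       snapshot_times=(0.5,)).snapshots[-1]
        for name in CYTOPLASMIC_SPECIES + NUCLEAR_SPECIES:
            label = CYTOPLASM if name.endswith("_c") else NUCLEUS
            semi = domain.compartment_mean(final[name], label)
            expl = domain.compartment_mean(ref[name], label)
            if abs(expl) < 1e-12:
                assert abs(semi) < 1e-12
            else:
                assert semi == pytest.approx(expl, rel=0.005), name


class TestRun:
    def test_zero_duration_returns_initial_state_only(self, toy_domain, params):
        state = _uniform_state(toy_domain, DEFAULT_SEED_CONCENTRATIONS)
        spec = na.default_transfer_spec(params)
        traj = na.run(state, toy_domain, params, spec,
                      na.SolverConfig(dt=0.01, t_end=0.0), snapshot_times=(0.0,))
        assert len(traj.summary) == 1
        assert traj.summary["t"].iloc[0] == 0.0
        assert len(traj.snapshots) == 1

    def test_conserved_totals_and_constant_catalytic_mass(self, toy_domain, params, geometry):
        state = _uniform_state(toy_domain, DEFAULT_SEED_CONCENTRATIONS)
        state.fields["E_c"] = na.initialize_catalytic_field(toy_domain, geometry)
        spec = na.default_transfer_spec(params)
        traj = na.run(state, toy_domain, params, spec,
                      na.SolverConfig(dt=0.01, t_end=20.0))
        s = traj.summary
        for col in ("total_actin", "total_cofilin", "total_profilin", "total_E"):
            t0 = s[col].iloc[0]
            assert (s[col] - t0).abs().max() / t0 < 1e-3, col
        assert s["total_E"].nunique() == 1 or \
            (s["total_E"] - s["total_E"].iloc[0]).abs().max() < 1e-12

    def test_summary_times_strictly_increasing_from_zero(self, toy_domain, params):
        state = _uniform_state(toy_domain, DEFAULT_SEED_CONCENTRATIONS)
        spec = na.default_transfer_spec(params)
        traj = na.run(state, toy_domain, params, spec,
                      na.SolverConfig(dt=0.01, t_end=2.0, output_every=50))
        t = traj.summary["t"].to_numpy()
        assert t[0] == 0.0
        assert np.all(np.diff(t) > 0)
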