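"""Integrator correctness: fixed points, damping limits, energy behaviour,
determinism and the compiled kernel's agreement with the reference forces."""

import numpy as np
import pytest
from scipy import stats

import beadchain as bc
from beadchain import _kernel
from beadchain.forcefield import conservative_forces
from beadchain.simulator import auto_substeps, _kernel_args

from conftest import single_particle_topology


class TestSingleParticle:
    def test_terminal_velocity_under_constant_force(self):
        # m dv/dt = F - kv v has terminal speed F/kv; the split_damping
        # update must reach it to 1e-6 relative after >= 20 relaxation times
        mass, kv, F = 1e-3, 0.5, 1e-2
        topo = single_particle_topology(mass)
        ff = bc.ForceField(kv=kv)
        dt = 1e-5  # kv*dt/m = 5e-3, well resolved
        n_steps = 4000  # 20 relaxation times of m/kv = 2 ms
        kick = np.array([[F, 0.0, 0.0]])
        state = (topo.positions, np.zeros((1, 3)))
        for _ in range(n_steps):
            state = bc.integrate_step(state, topo, ff, kick_forces=kick, dt=dt)
        v = state[1][0, 0]
        assert abs(v - F / kv) / (F / kv) < 1e-6

    def test_terminal_velocity_is_exact_fixed_point(self):
        mass, kv, F = 1e-6, 2.0, 3e-2
        topo = single_particle_topology(mass)
        ff = bc.ForceField(kv=kv)
        kick = np.array([[F, 0.0, 0.0]])
        v0 = np.array([[F / kv, 0.0, 0.0]])
        # even at kv*dt/m >> 1 the terminal velocity is preserved exactly
        _, v1 = bc.integrate_step((topo.positions, v0), topo, ff,
                                  kick_forces=kick, dt=1e-3)
        assert v1[0, 0] == pytest.approx(F / kv, rel=1e-12)

    def test_overdamped_stationary_velocity_matches_scaled_kicks(self):
        # deep overdamped limit (m/kv << dt): each component relaxes to
        # (kr/kv) * P within the step, so the stationary velocity sample is
        # the kick distribution rescaled by kr/kv
        mass, kv, kr = 8.8e-12, 1e-4, 1e-2
        topo = single_particle_topology(mass)
        ff = bc.ForceField(kv=kv, kr=kr)
        forcing = bc.ForcingModel("laplace", kr=kr, seed=21)
        config = bc.SimulationConfig(n_steps=1200, equilibration_steps=200,
                                     record_stride=1, seed=21)
        traj = bc.run_simulation(topo, ff, forcing, config)
        v = traj.velocities[:, 0, :].ravel()
        ref = (kr / kv) * bc.sample_noise(bc.ForcingModel("laplace", seed=99),
                                          1000).ravel()
        assert stats.ks_2samp(v, ref).pvalue > 0.01
        assert np.abs(v).mean() == pytest.approx(kr / kv, rel=0.1)


class TestChainDynamics:
    def test_equilibrium_is_fixed_point(self, small_topo, ff_default):
        state = (small_topo.positions, np.zeros_like(small_topo.positions))
        x1, v1 = bc.integrate_step(state, small_topo, ff_default, dt=1e-4)
        assert np.array_equal(x1, small_topo.positions)
        assert np.all(v1 == 0.0)

    @pytest.mark.parametrize("integrator", ["split_damping", "verlet"])
    def test_energy_conservation_undamped(self, integrator):
        # kick-free, damping-free: both modes reduce to velocity-Verlet,
        # which must hold the energy to a small bounded drift
        chain = bc.ChainSpec(n_beads=3, anchor_separation=0.04)
        ff = bc.ForceField(kv=0.0)
        topo = bc.build_topology(chain, bc.BeadSpec(), ff,
                                 mass_per_particle=1e-3)
        rng = np.random.default_rng(4)
        topo.positions[topo.mobile_mask] += rng.normal(
            0, 1e-3, topo.positions[topo.mobile_mask].shape)
        e0 = sum(bc.system_energy((topo.positions, np.zeros_like(topo.positions)),
                                  topo, ff))
        config = bc.SimulationConfig(timestep=1e-4, n_steps=2000,
                                     equilibration_steps=0, record_stride=100,
                                     integrator=integrator)
        traj = bc.run_simulation(topo, ff, None, config)
        energies = [sum(bc.system_energy((traj.positions[f], traj.velocities[f]),
                                         topo, ff))
                    for f in range(traj.n_frames)]
        assert np.max(np.abs(np.array(energies) - e0)) / e0 < 1e-4

    def test_pure_dissipation_free_particle_drains_completely(self):
        # without bonds the kinetic energy decays as exp(-2 kv t / m)
        topo = single_particle_topology(1e-6)
        ff = bc.ForceField(kv=0.05, kr=0.0)
        state = (topo.positions, np.array([[0.1, -0.05, 0.02]]))
        ke = lambda v: float(np.sum(v**2) * 1e-6 / 2)
        ke0 = ke(state[1])
        history = [ke0]
        for _ in range(60):  # 300 velocity relaxation times
            state = bc.integrate_step(state, topo, ff, dt=1e-4)
            history.append(ke(state[1]))
        assert history[-1] < 1e-12 * ke0
        assert all(b <= a for a, b in zip(history, history[1:]))

    def test_pure_dissipation_chain_decays_monotonically(self):
        # a velocity-perturbed chain sheds its kinetic energy monotonically;
        # the residue is slow overdamped creep of the softest bending modes,
        # orders of magnitude below the initial energy but not zero on this
        # horizon
        ff = bc.ForceField(kv=0.05, kr=0.0)
        topo = bc.build_topology(bc.ChainSpec(n_beads=3, anchor_separation=0.04),
                                 bc.BeadSpec(), ff, mass_per_particle=1e-6)
        rng = np.random.default_rng(8)
        v0 = rng.normal(0, 0.1, topo.positions.shape)
        v0[~topo.mobile_mask] = 0.0
        ke = lambda v: float(np.sum(topo.masses[:, None] * v**2) / 2)
        state = (topo.positions.copy(), v0)
        ke0 = ke(state[1])
        history = [ke0]
        for _ in range(800):
            state = bc.integrate_step(state, topo, ff, dt=1e-4)
            history.append(ke(state[1]))
        assert history[-1] < 1e-8 * ke0
        assert all(b <= a for a, b in zip(history, history[1:]))

    def test_frame_count_and_times(self, small_topo, ff_calibrated):
        forcing = bc.ForcingModel("laplace", kr=ff_calibrated.kr, seed=2)
        config = bc.SimulationConfig(n_steps=4000, equilibration_steps=1000,
                                     record_stride=10, seed=2)
        traj = bc.run_simulation(small_topo, ff_calibrated, forcing, config)
        assert traj.n_frames == 300
        dt_frames = np.diff(traj.times)
        assert np.allclose(dt_frames, 10 * 1e-4)
        assert traj.frame_interval == pytest.approx(1e-3)

    def test_bit_for_bit_determinism(self, small_topo, ff_calibrated):
        def run():
            forcing = bc.ForcingModel("laplace", kr=ff_calibrated.kr, seed=13)
            config = bc.SimulationConfig(n_steps=1500, equilibration_steps=300,
                                         record_stride=7, seed=13)
            return bc.run_simulation(small_topo, ff_calibrated, forcing, config)

        a, b = run(), run()
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_anchors_never_move_and_state_stays_finite(self, short_chain_run,
                                                       small_topo):
        anchors = ~short_chain_run.mobile_mask
        assert np.all(short_chain_run.positions[:, anchors, :]
                      == small_topo.positions[None, anchors, :])
        assert np.all(short_chain_run.velocities[:, anchors, :] == 0.0)
        assert np.all(np.isfinite(short_chain_run.positions))
        assert np.all(np.isfinite(short_chain_run.velocities))

    def test_explicit_verlet_blows_up_in_stiff_damping_regime(self):
        # kv*dt/m >> 1 makes the textbook scheme unstable; the failure must
        # surface as a diagnostic error, not silent NaNs
        topo = single_particle_topology(1e-10)
        ff = bc.ForceField(kv=1e-2)
        forcing = bc.ForcingModel("gaussian", kr=1e-2, seed=5)
        config = bc.SimulationConfig(n_steps=200, equilibration_steps=0,
                                     record_stride=10, integrator="verlet",
                                     n_substeps=1, seed=5)
        with pytest.raises(bc.IntegrationBlowupError) as err:
            bc.run_simulation(topo, ff, forcing, config)
        assert err.value.step > 0


class TestKernelAgainstReference:
    @pytest.mark.parametrize("seed", [0, 3])
    def test_bonded_forces_match_pure_numpy(self, small_topo, seed):
        rng = np.random.default_rng(seed)
        x = small_topo.positions + rng.normal(0, 2e-3, small_topo.positions.shape)
        x[~small_topo.mobile_mask] = small_topo.positions[~small_topo.mobile_mask]
        ref = conservative_forces(small_topo, x)
        f = np.zeros_like(x)
        (masses, mobile, lin_idx, lin_k, lin_rest, ang_idx, ang_k,
         str_idx, str_k, str_rest) = _kernel_args(small_topo, bc.ForceField())
        _kernel.bonded_forces(x, f, mobile, lin_idx, lin_k, lin_rest,
                              ang_idx, ang_k, str_idx, str_k, str_rest)
        assert np.allclose(f, ref, rtol=1e-12, atol=1e-18)

    def test_auto_substeps_scales_with_stiffness(self, ff_default, study_topo):
        n_table = auto_substeps(study_topo, ff_default, 1e-4)
        n_calib = auto_substeps(study_topo, bc.study_forcefield("calibrated"),
                                1e-4)
        assert n_calib == 1
        assert n_table > n_calib  # weakly damped printed value needs substeps
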