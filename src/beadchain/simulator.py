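"""Time integration of the kicked, damped bead chain.

The model is Newtonian dynamics under the bonded forces, viscous damping and
a random kick force redrawn once per timestep and held constant within it
(zeroth-order hold).  With the default parameter set the velocity relaxation
time m/kv is far below the timestep, i.e. the dynamics is deeply overdamped:
the default ``split_damping`` integrator therefore embeds the damping in the
velocity updates exactly (each half-update solves m dv/dt = F - kv v in
closed form with F frozen), which is stable for arbitrarily strong damping
and degenerates to plain velocity-Verlet as kv -> 0.  A textbook ``verlet``
mode (damping treated as an explicit force) is also provided.

Stiff bonds are resolved by subdividing each timestep into equal substeps
(the kick stays frozen); the substep count is chosen automatically from a
per-particle stiffness/damping stability bound unless given explicitly.

Coordinate convention: y is the vertical (airflow/gravity) axis of the
experiment, z points out of the X-ray detector plane.  SI units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import _kernel
from .chain import ChainTopology
from .errors import IntegrationBlowupError, ValidationError
from .forcefield import ForceField, ForcingModel, potential_energy

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "run_simulation",
    "integrate_step",
    "system_energy",
]

_MODE_CODE = {"split_damping": _kernel.SPLIT_DAMPING, "verlet": _kernel.VERLET}


@dataclass(frozen=True)
class SimulationConfig:
    """Run-length, recording and integrator settings.

    Defaults follow the study protocol: 1e-4 s timesteps, 4e5 steps with the
    first 1e5 discarded as equilibration, recording every 100 steps.
    ``n_substeps=None`` selects the substep count automatically from the
    stability heuristic in :func:`auto_substeps`.
    """

    timestep: float = 1e-4
    n_steps: int = 400_000
    equilibration_steps: int = 100_000
    record_stride: int = 100
    seed: int = 0
    integrator: str = "split_damping"
    n_substeps: Optional[int] = None

    def __post_init__(self) -> None:
        if self.timestep <= 0 or not np.isfinite(self.timestep):
            raise ValidationError(f"timestep must be positive, got {self.timestep!r}")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if not (0 <= self.equilibration_steps < self.n_steps):
            raise ValidationError("need 0 <= equilibration_steps < n_steps")
        if self.record_stride < 1:
            raise ValidationError("record_stride must be >= 1")
        if self.integrator not in _MODE_CODE:
            raise ValidationError(
                f"integrator must be one of {tuple(_MODE_CODE)}, got {self.integrator!r}")
        if self.n_substeps is not None and self.n_substeps < 1:
            raise ValidationError("n_substeps must be >= 1 when given")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Trajectory:
    """Recorded post-equilibration time series of the chain state.

    ``positions`` and ``velocities`` have shape (frames, particles, 3); the
    velocities are the integrator's instantaneous velocities at the recorded
    steps (finite-difference, experiment-comparable velocities are derived
    downstream in :mod:`beadchain.analysis`).
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    kinds: list
    radii: np.ndarray
    masses: np.ndarray
    config: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_particles(self) -> int:
        return len(self.kinds)

    @property
    def frame_interval(self) -> float:
        if "timestep" in self.config:
            return float(self.config["timestep"]) * int(self.config.get("record_stride", 1))
        if self.n_frames > 1:
            return float(np.diff(self.times).mean())
        return float("nan")

    @property
    def crimp_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == "crimp"])

    @property
    def mobile_mask(self) -> np.ndarray:
        return np.array([k != "anchor" for k in self.kinds])


def particle_stiffness_bounds(topology: ChainTopology) -> np.ndarray:
    """Upper-bound stiffness (N/m) felt by each particle, for stability.

    Sums incident linear and string stiffnesses plus the geometric stiffness
    of each incident angular bond, k_theta / arm^2 per arm (doubled at the
    centre particle which closes both arms).
    """
    k = np.zeros(topology.n_particles)
    for (i, j), kk in zip(topology.linear_bonds, topology.linear_k):
        k[i] += kk
        k[j] += kk
    for row, kt in zip(topology.angular_bonds, topology.angular_k):
        i, j, k2 = row
        # use rest-length arms as the scale
        arm = topology.linear_rest.mean()
        k[i] += kt / arm**2
        k[k2] += kt / arm**2
        k[j] += 2 * kt / arm**2
    for (a, p), kk in zip(topology.string_bonds, topology.string_k):
        k[p] += kk
    return k


def auto_substeps(topology: ChainTopology, forces: ForceField,
                  dt: float, cap: int = 65536) -> int:
    """Smallest power-of-two substep count satisfying the stability bound.

    For each mobile particle with stiffness bound k and damping rate
    gamma = kv/m, the substep h must satisfy the overdamped position-update
    bound k*h/kv <= 0.5 when the particle's velocity fully relaxes within a
    substep (gamma*h >= 4), or the oscillatory bound sqrt(k/m)*h <= 0.5
    otherwise.  Blow-up detection in :func:`run_simulation` backstops the
    heuristic.
    """
    kbound = particle_stiffness_bounds(topology)
    mobile = topology.mobile_mask
    n_sub = 1
    while n_sub <= cap:
        h = dt / n_sub
        ok = True
        for k, m, mob in zip(kbound, topology.masses, mobile):
            if not mob or k == 0:
                continue
            gamma = forces.kv / m
            if gamma * h >= 4.0:
                if k * h / forces.kv > 0.5:
                    ok = False
                    break
            else:
                if np.sqrt(k / m) * h > 0.5:
                    ok = False
                    break
        if ok:
            return n_sub
        n_sub *= 2
    raise ValidationError(
        "no stable substep count below the cap; the stiffness/damping/"
        "timestep combination is too extreme")


def _kernel_args(topology: ChainTopology, forces: ForceField):
    mobile = topology.mobile_mask.astype(np.bool_)
    return (
        topology.masses.astype(float), mobile,
        topology.linear_bonds.astype(np.int64), topology.linear_k.astype(float),
        topology.linear_rest.astype(float),
        topology.angular_bonds.astype(np.int64), topology.angular_k.astype(float),
        topology.string_bonds.astype(np.int64), topology.string_k.astype(float),
        topology.string_rest.astype(float),
    )


def _kick_block(forcing: Optional[ForcingModel], topology: ChainTopology,
                n_steps: int) -> np.ndarray:
    """Kick *forces* for a block of steps, zeros for untargeted particles."""
    n = topology.n_particles
    out = np.zeros((n_steps, n, 3))
    if forcing is None or forcing.kr == 0:
        return out
    if forcing.targets == "beads_only":
        targets = topology.bead_indices
    else:
        targets = np.flatnonzero(topology.mobile_mask)
    amp = forcing.sample_block(n_steps, len(targets))
    out[:, targets, :] = forcing.kr * amp
    return out


def integrate_step(
    state: tuple[np.ndarray, np.ndarray],
    topology: ChainTopology,
    forces: ForceField,
    kick_forces: Optional[np.ndarray] = None,
    dt: float = 1e-4,
    integrator: str = "split_damping",
    n_substeps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one timestep; returns the new (positions, velocities).

    ``kick_forces`` is the (n, 3) kick force array held constant over the
    step (zeros if omitted).  Raises :class:`IntegrationBlowupError` if the
    state leaves the finite range.  This is the small-scale reference entry
    point; long runs should use :func:`run_simulation`.
    """
    x0, v0 = state
    x = np.array(x0, dtype=float)
    v = np.array(v0, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise ValidationError("non-finite input state")
    n = topology.n_particles
    kicks = np.zeros((1, n, 3))
    if kick_forces is not None:
        kicks[0] = kick_forces
    _kernel.run_block(x, v, *_kernel_args(topology, forces), kicks,
                      float(forces.kv), float(dt), int(n_substeps),
                      _MODE_CODE[integrator])
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise IntegrationBlowupError(0, float(np.nanmax(np.abs(kicks))),
                                     float(np.nanmax(np.abs(v[np.isfinite(v)]),
                                                     initial=0.0)))
    return x, v


def run_simulation(
    topology: ChainTopology,
    forces: ForceField,
    forcing: Optional[ForcingModel],
    config: SimulationConfig,
    kick_block_steps: int = 20_000,
) -> Trajectory:
    """Integrate the chain and return the post-equilibration trajectory.

    Kicks are drawn in blocks from the forcing model's seeded stream (order:
    step, particle, component), so a run is bit-for-bit reproducible for a
    given (topology, forces, forcing seed, config).  Frames are recorded at
    every ``record_stride``-th step from ``equilibration_steps`` onward,
    after the step has completed.  Anchor rows never change.
    """
    if forcing is not None:
        forcing.reset()
    n_sub = config.n_substeps or auto_substeps(topology, forces, config.timestep)
    mode = _MODE_CODE[config.integrator]
    dt = config.timestep
    x = topology.positions.copy().astype(float)
    v = np.zeros_like(x)
    args = _kernel_args(topology, forces)

    rec_steps = np.arange(config.equilibration_steps, config.n_steps,
                          config.record_stride)
    n_frames = len(rec_steps)
    out_x = np.empty((n_frames, topology.n_particles, 3))
    out_v = np.empty_like(out_x)
    frame = 0
    step = 0
    equil, stride = config.equilibration_steps, config.record_stride
    while step < config.n_steps:
        block = min(kick_block_steps, config.n_steps - step)
        kicks = _kick_block(forcing, topology, block)
        done = 0
        while done < block:
            g0 = step + done  # next global step to execute
            if g0 < equil:
                # run through the equilibration boundary (or block end)
                target = min(step + block, equil) - 1
                record = False
            else:
                # align each kernel call to end exactly on a recording step
                s_next = equil + -(-(g0 - equil) // stride) * stride
                target = min(s_next, step + block - 1)
                record = target == s_next
            count = target - g0 + 1
            _kernel.run_block(x, v, *args, kicks[done:done + count],
                              float(forces.kv), float(dt), int(n_sub), mode)
            done += count
            if record:
                out_x[frame] = x
                out_v[frame] = v
                frame += 1
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
            fin_v = v[np.isfinite(v)]
            fin_k = kicks[np.isfinite(kicks)]
            raise IntegrationBlowupError(
                step + block,
                float(np.max(np.abs(fin_k), initial=0.0)),
                float(np.max(np.abs(fin_v), initial=0.0)))
        step += block

    times = (rec_steps + 1) * dt
    return Trajectory(
        times=times[:frame],
        positions=out_x[:frame],
        velocities=out_v[:frame],
        kinds=list(topology.kinds),
        radii=topology.radii.copy(),
        masses=topology.masses.copy(),
        config={**config.to_dict(), "n_substeps_used": int(n_sub)},
        meta={
            "forcefield": forces.to_dict(),
            "forcing": forcing.to_dict() if forcing is not None else None,
        },
    )


def system_energy(
    state: tuple[np.ndarray, np.ndarray],
    topology: ChainTopology,
    forces: ForceField,
) -> tuple[float, float]:
    """(kinetic, potential) energy in joules of a state.

    Kinetic energy sums 1/2 m |v|^2 over mobile particles; potential energy
    is the bonded potential of :func:`beadchain.forcefield.potential_energy`.
    """
    x, v = state
    mob = topology.mobile_mask
    ke = 0.5 * float(np.sum(topology.masses[mob, None] * np.asarray(v)[mob] ** 2))
    pe = potential_energy(topology, x)
    return ke, pe
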