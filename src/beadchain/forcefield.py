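"""Force laws and stochastic forcing for the bead-chain model.

Four deterministic force laws act on the chain:

- a linear (stretch) bond between adjacent spheres, harmonic about the
  contact distance ``rb + rt``;
- an angular (bend) bond on each triple of adjacent particles, harmonic in
  the bend angle about the straight configuration ``theta = pi``;
- a string bond tying each end crimp to a fixed anchor: zero force while
  slack, linear restoring beyond the string's rest length;
- a viscous damping force ``-kv * v`` on every mobile particle.

On top of these, every timestep each targeted particle receives a random
"kick" force ``kr * P`` per Cartesian component, a zeroth-order-held stand-in
for grain buffeting in the fluidized bed.  ``P`` is drawn from a standard
normal (``gaussian``) or a standard Laplace built from two uniforms
(``laplace``): ``P = -log U1`` if ``U2 <= 0.5`` else ``+log U1``.

All deterministic bonded forces are exact negative gradients of the
potentials exposed alongside them, which the test-suite verifies by central
differences; the Laplace construction is verified against its analytic
moments and by Kolmogorov-Smirnov.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "ForceField",
    "ForcingModel",
    "linear_bond_force",
    "angular_bond_force",
    "string_anchor_force",
    "damping_force",
    "kick_force",
    "sample_noise",
    "conservative_forces",
    "potential_energy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForceField:
    """Bond, damping and kick coefficients (SI units).

    kl : linear bond stiffness, N/m
    ka : angular bond strength, N/rad -- the end-particle force magnitude is
         ka*|theta - pi| for arms at rest length (see note below)
    ks : string bond stiffness, N/m
    kv : damping coefficient, N s/m
    kr : kick force magnitude scale, N

    Defaults are the source parameter table.  Note the printed damping
    1e-4 N s/m yields a terminal speed kr/kv = 100 m/s, three orders of
    magnitude above the experimental tracer speeds; the study describes
    calibrating kv so the simulated mean speed matches experiment, which the
    :mod:`beadchain.presets` module provides (kv = 0.1 N s/m).
    """

    kl: float = 1.0
    ka: float = 1e-2
    ks: float = 5.0
    kv: float = 1e-4
    kr: float = 1e-2

    def __post_init__(self) -> None:
        for name in ("kl", "ka", "ks", "kv", "kr"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be >= 0 and finite, got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)


class ForcingModel:
    """Seeded generator of per-timestep kick amplitudes.

    Parameters
    ----------
    kind : 'gaussian' or 'laplace'
        Shape of the per-component amplitude distribution; both have unit
        scale parameter so ``kr`` carries all magnitude scaling.
    kr : float
        Kick force magnitude (N); copied into the kick force on evaluation.
    seed : int
        Seed fixed at construction; the stream order is (step, particle,
        component), with the two uniforms of each Laplace draw innermost,
        so a run is reproducible bit-for-bit for a given seed.
    targets : 'all' or 'beads_only'
        Which mobile particles are kicked.  Default kicks every mobile
        particle (crimps are immersed in the grains just as beads are);
        'beads_only' reproduces the narrower reading that only the resin
        beads are driven.
    """

    KINDS = ("gaussian", "laplace")
    TARGETS = ("all", "beads_only")

    def __init__(self, kind: str = "laplace", kr: float = 1e-2,
                 seed: int = 0, targets: str = "all"):
        if kind not in self.KINDS:
            raise ValidationError(f"kind must be one of {self.KINDS}, got {kind!r}")
        if targets not in self.TARGETS:
            raise ValidationError(f"targets must be one of {self.TARGETS}, got {targets!r}")
        if kr < 0 or not np.isfinite(kr):
            raise ValidationError(f"kr must be >= 0 and finite, got {kr!r}")
        self.kind = kind
        self.kr = float(kr)
        self.seed = int(seed)
        self.targets = targets
        self._rng = np.random.default_rng(self.seed)

    def reset(self) -> None:
        """Rewind the stream to its seeded origin."""
        self._rng = np.random.default_rng(self.seed)

    def sample_block(self, n_steps: int, n_particles: int) -> np.ndarray:
        """Draw kick amplitudes for a block of steps, shape (steps, particles, 3)."""
        shape = (n_steps, n_particles, 3)
        if self.kind == "gaussian":
            return self._rng.standard_normal(shape)
        u = self._rng.random(shape + (2,))
        return _laplace_from_uniforms(u[..., 0], u[..., 1])

    def to_dict(self) -> dict:
        return {"kind": self.kind, "kr": self.kr, "seed": self.seed,
                "targets": self.targets}


def _laplace_from_uniforms(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """Standard Laplace amplitudes from two independent uniforms.

    ``P = -log U1`` (positive) when ``U2 <= 0.5``, ``+log U1`` (negative)
    otherwise; U2 decides the sign with equal probability.
    """
    return np.where(u2 <= 0.5, -np.log(u1), np.log(u1))


def sample_noise(model: ForcingModel, n: int) -> np.ndarray:
    """Draw ``n`` dimensionless kick amplitude 3-vectors from the model."""
    return model.sample_block(1, n)[0]


# ---------------------------------------------------------------------------
# Individual force laws (reference implementations)
# ---------------------------------------------------------------------------

def linear_bond_force(R: float, rb: float, rt: float, kl: float,
                      rhat: np.ndarray) -> np.ndarray:
    """Stretch-bond force on a particle whose neighbour lies along ``rhat``.

    Harmonic about the contact distance ``rb + rt``: zero at equilibrium,
    pulls the particle toward its neighbour (+rhat) when stretched and pushes
    it away when compressed.  ``R`` is the centre-centre distance.  At
    ``R = 0`` the direction is undefined; a zero force is returned with a
    logged warning.
    """
    rhat = np.asarray(rhat, dtype=float)
    if R == 0:
        logger.warning("coincident bond partners: linear bond direction "
                       "undefined, returning zero force")
        return np.zeros(3)
    if R < 0:
        raise ValidationError(f"distance R must be >= 0, got {R}")
    return kl * (R - (rb + rt)) * rhat


def string_anchor_force(ell: float, ell0: float, ks: float,
                        ellhat: np.ndarray) -> np.ndarray:
    """String force on the end particle; ``ellhat`` points anchor -> particle.

    Zero while slack (ell <= ell0), linear restoring ``-ks (ell - ell0)``
    toward the anchor beyond; continuous at ell0.
    """
    if ell < 0:
        raise ValidationError(f"distance ell must be >= 0, got {ell}")
    if ell <= ell0:
        return np.zeros(3)
    return -ks * (ell - ell0) * np.asarray(ellhat, dtype=float)


def damping_force(v: np.ndarray, kv: float) -> np.ndarray:
    """Viscous damping ``-kv * v`` applied to every mobile particle."""
    return -kv * np.asarray(v, dtype=float)


def kick_force(P: np.ndarray, kr: float) -> np.ndarray:
    """Kick force ``kr * P`` in the fixed Cartesian frame (held for one step)."""
    return kr * np.asarray(P, dtype=float)


def angular_bond_force(
    pos_i: np.ndarray, pos_j: np.ndarray, pos_k: np.ndarray, ka: float,
    arm_rest: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bend-bond forces on the triple (i, j, k) with centre particle j.

    The bond is harmonic in the angle theta at j, with straight (theta = pi)
    equilibrium, and derives from the potential ``U = 1/2 k_theta
    (theta - pi)^2`` with the energy constant ``k_theta = ka * arm_rest``
    (``arm_rest`` defaults to the mean of the two current arm lengths, making
    the end-force magnitude exactly ``ka * |theta - pi|``).  End forces are
    perpendicular to their arms, in the bond plane, directed so as to
    straighten the triple; the centre particle receives minus their sum, so
    the triple exerts no net force.  Exactly zero at theta = pi, where the
    bond plane is undefined but no torque is needed.
    """
    r1 = np.asarray(pos_i, float) - np.asarray(pos_j, float)
    r2 = np.asarray(pos_k, float) - np.asarray(pos_j, float)
    L1 = np.linalg.norm(r1)
    L2 = np.linalg.norm(r2)
    if L1 == 0 or L2 == 0:
        raise ValidationError("zero-length arm in angular bond")
    if arm_rest is None:
        arm_rest = 0.5 * (L1 + L2)
    k_theta = ka * arm_rest
    ct = float(np.clip(r1 @ r2 / (L1 * L2), -1.0, 1.0))
    theta = np.arccos(ct)
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    # fac = (dU/dtheta)/sin(theta); finite limit -k_theta as theta -> pi
    fac = -k_theta if st < 1e-8 else k_theta * (theta - np.pi) / st
    f_i = fac / L1 * (r2 / L2 - ct * r1 / L1)
    f_k = fac / L2 * (r1 / L1 - ct * r2 / L2)
    return f_i, -(f_i + f_k), f_k


# ---------------------------------------------------------------------------
# Whole-topology assembly (pure-numpy reference; the simulator kernel is
# cross-checked against this in the tests)
# ---------------------------------------------------------------------------

def conservative_forces(topology, positions: np.ndarray) -> np.ndarray:
    """Assembled bonded + string forces at given positions, (n, 3) array.

    Anchors are force-exempt: their rows are zeroed.  Damping and kicks are
    not included (they are velocity/noise terms, not functions of position).
    """
    x = np.asarray(positions, dtype=float)
    f = np.zeros_like(x)
    for (i, j), kk, rest in zip(topology.linear_bonds, topology.linear_k,
                                topology.linear_rest):
        d = x[j] - x[i]
        R = np.linalg.norm(d)
        if R == 0:
            logger.warning("coincident particles %d,%d in linear bond", i, j)
            continue
        fij = kk * (R - rest) * d / R  # force on i, toward j when stretched
        f[i] += fij
        f[j] -= fij
    for (i, j, k), k_theta in zip(topology.angular_bonds, topology.angular_k):
        fi, fj, fk = _angular_from_energy_constant(x[i], x[j], x[k], k_theta)
        f[i] += fi
        f[j] += fj
        f[k] += fk
    for (a, p), kk, rest in zip(topology.string_bonds, topology.string_k,
                                topology.string_rest):
        d = x[p] - x[a]
        ell = np.linalg.norm(d)
        if ell > rest:
            f[p] -= kk * (ell - rest) * d / ell
    f[~topology.mobile_mask] = 0.0
    return f


def _angular_from_energy_constant(pi_, pj_, pk_, k_theta):
    r1 = pi_ - pj_
    r2 = pk_ - pj_
    L1 = np.linalg.norm(r1)
    L2 = np.linalg.norm(r2)
    ct = float(np.clip(r1 @ r2 / (L1 * L2), -1.0, 1.0))
    theta = np.arccos(ct)
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    fac = -k_theta if st < 1e-8 else k_theta * (theta - np.pi) / st
    f_i = fac / L1 * (r2 / L2 - ct * r1 / L1)
    f_k = fac / L2 * (r1 / L1 - ct * r2 / L2)
    return f_i, -(f_i + f_k), f_k


def potential_energy(topology, positions: np.ndarray) -> float:
    """Total bonded potential energy (J) at given positions.

    Sum of 1/2 kl (R - rest)^2 over linear bonds, 1/2 k_theta (theta - pi)^2
    over angular bonds and 1/2 ks (ell - ell0)^2 over taut strings; the exact
    integral of :func:`conservative_forces`.
    """
    x = np.asarray(positions, dtype=float)
    u = 0.0
    for (i, j), kk, rest in zip(topology.linear_bonds, topology.linear_k,
                                topology.linear_rest):
        R = np.linalg.norm(x[j] - x[i])
        u += 0.5 * kk * (R - rest) ** 2
    for (i, j, k), k_theta in zip(topology.angular_bonds, topology.angular_k):
        r1 = x[i] - x[j]
        r2 = x[k] - x[j]
        ct = np.clip(r1 @ r2 / (np.linalg.norm(r1) * np.linalg.norm(r2)), -1.0, 1.0)
        u += 0.5 * k_theta * (np.arccos(ct) - np.pi) ** 2
    for (a, p), kk, rest in zip(topology.string_bonds, topology.string_k,
                                topology.string_rest):
        ell = np.linalg.norm(x[p] - x[a])
        if ell > rest:
            u += 0.5 * kk * (ell - rest) ** 2
    return float(u)
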