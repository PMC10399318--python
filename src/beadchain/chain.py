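"""Chain construction: bead geometry, density balancing and topology building.

The physical chain alternates hollow 3D-printed resin beads (spheres with a
short cylindrical protrusion, strung on silk thread) with small metal crimp
cylinders that act as radio-opaque tracers.  In the discrete-element model
both are plain spheres: beads of radius ``rb`` and crimps of radius ``rt``,
joined by linear (stretch) and angular (bend) bonds, with the two end crimps
tied to fixed anchors by slack-then-linear string bonds.

Two levels of description coexist deliberately: the *density* calculations
use the full printed geometry (shell, protrusion, bore) because they answer a
fabrication question, while the *topology* used for simulation reduces each
element to a sphere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .errors import InfeasibleError, ValidationError

__all__ = [
    "BeadSpec",
    "ChainSpec",
    "ChainTopology",
    "build_topology",
    "effective_bead_density",
    "wall_thickness_for_target_density",
    "chain_contact_length",
]

#: Sphere radius used for the crimp tracers in the discrete-element model.
#: The physical crimps are 2 mm cylinders, but the model represents them as
#: 1.5 mm diameter spheres.
DEFAULT_CRIMP_MODEL_RADIUS = 7.5e-4

#: Particle density used to assign masses, as printed in the source parameter
#: table (kg/m^3).  The value is physically implausible (it yields ~6e-10 kg
#: beads) but is the stated parameterization; it places the dynamics deep in
#: the overdamped regime.  Override via ``mass_per_particle`` if desired.
DEFAULT_PARTICLE_DENSITY = 5e-3


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValidationError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class BeadSpec:
    """Geometry and material of one printed resin bead.

    Lengths in metres, density in kg/m^3.  Defaults are the study bead:
    a 6 mm hollow sphere with 0.4 mm walls, a 1.5 mm x 1.5 mm cylindrical
    protrusion, a 1 mm threading bore, printed at 1.23 g/cm^3.
    """

    outer_diameter: float = 6e-3
    wall_thickness: float = 0.4e-3
    protrusion_length: float = 1.5e-3
    protrusion_diameter: float = 1.5e-3
    bore_diameter: float = 1e-3
    material_density: float = 1230.0

    def __post_init__(self) -> None:
        _require_positive(
            outer_diameter=self.outer_diameter,
            wall_thickness=self.wall_thickness,
            protrusion_length=self.protrusion_length,
            protrusion_diameter=self.protrusion_diameter,
            bore_diameter=self.bore_diameter,
            material_density=self.material_density,
        )
        if self.wall_thickness > self.radius:
            raise ValidationError(
                "wall_thickness exceeds the sphere radius; use wall_thickness "
                "== radius for a solid bead"
            )
        if not (self.bore_diameter < self.protrusion_diameter < self.outer_diameter):
            raise ValidationError(
                "expected bore_diameter < protrusion_diameter < outer_diameter"
            )

    @property
    def radius(self) -> float:
        return self.outer_diameter / 2.0


@dataclass(frozen=True)
class ChainSpec:
    """Layout of the alternating bead/crimp chain and its suspension.

    ``n_beads`` resin beads alternate with ``n_beads + 1`` crimps; the end
    crimps are tied to two fixed anchors by strings of rest length
    ``string_segment_length`` that exert force only when taut.  ``n_beads = 0``
    is permitted for geometry-only calculations (a bare crimp), but a
    simulatable topology requires at least one bead.
    """

    n_beads: int = 14
    crimp_length: float = 1.4e-3
    crimp_diameter: float = 2e-3
    slack_length: float = 3.4e-3
    string_segment_length: float = 1.2e-2
    anchor_separation: float = 0.101

    def __post_init__(self) -> None:
        if self.n_beads < 0 or int(self.n_beads) != self.n_beads:
            raise ValidationError(f"n_beads must be a non-negative integer, got {self.n_beads!r}")
        for name in ("crimp_length", "crimp_diameter", "slack_length",
                     "string_segment_length"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be >= 0 and finite, got {v!r}")
        _require_positive(anchor_separation=self.anchor_separation)

    @property
    def n_crimps(self) -> int:
        return self.n_beads + 1


# ---------------------------------------------------------------------------
# Density balancing
# ---------------------------------------------------------------------------

def effective_bead_density(bead: BeadSpec) -> float:
    """Mean density of a hollow bead over its spherical envelope (kg/m^3).

    The material volume is the spherical shell plus the protrusion cylinder
    minus the threading bore.  The bore removes material where it crosses
    solid resin: through the two wall caps (``2 * wall_thickness``) and along
    the protrusion.  The envelope is the outer sphere, the volume the bead
    displaces when buried in grains that cannot enter it.
    """
    R = bead.radius
    w = min(bead.wall_thickness, R)
    v_envelope = 4.0 / 3.0 * math.pi * R**3
    v_shell = v_envelope - 4.0 / 3.0 * math.pi * (R - w) ** 3
    v_protrusion = math.pi * (bead.protrusion_diameter / 2.0) ** 2 * bead.protrusion_length
    bore_length = 2.0 * w + bead.protrusion_length
    v_bore = math.pi * (bead.bore_diameter / 2.0) ** 2 * bore_length
    return (v_shell + v_protrusion - v_bore) * bead.material_density / v_envelope


def wall_thickness_for_target_density(bead: BeadSpec, target: float) -> float:
    """Invert :func:`effective_bead_density` for the wall thickness (m).

    Finds the wall thickness at which the hollow bead's effective density
    equals ``target`` to 1e-9 relative, by root-finding on the (monotone over
    the physical range) thickness-density relation.  ``bead.wall_thickness``
    is ignored.  Raises :class:`InfeasibleError` when the target lies outside
    the densities reachable between vanishing walls and a solid bead.
    """
    if not (0.0 < target < bead.material_density):
        raise InfeasibleError(
            f"target density {target} kg/m^3 outside (0, material density "
            f"{bead.material_density})"
        )
    R = bead.radius

    def f(w: float) -> float:
        trial = BeadSpec(
            outer_diameter=bead.outer_diameter,
            wall_thickness=w,
            protrusion_length=bead.protrusion_length,
            protrusion_diameter=bead.protrusion_diameter,
            bore_diameter=bead.bore_diameter,
            material_density=bead.material_density,
        )
        return effective_bead_density(trial) - target

    lo, hi = 1e-12 * R, R
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise InfeasibleError(
            f"target density {target} kg/m^3 not reachable for this geometry "
            f"(achievable range ~[{flo + target:.4g}, {fhi + target:.4g}])"
        )
    return brentq(f, lo, hi, rtol=1e-12, xtol=1e-15)


def chain_contact_length(
    chain: ChainSpec, bead: BeadSpec, n_crimps: Optional[int] = None
) -> float:
    """End-to-end chain length with every element in contact (m).

    ``n_beads * (sphere diameter + protrusion length) + n_crimps * crimp
    length + slack``.  This is the fabrication-geometry length; the simulated
    sphere-contact span is reported by :meth:`ChainTopology.contact_span` and
    the two are not reconciled (they disagree in the source description).
    """
    if n_crimps is None:
        n_crimps = chain.n_crimps
    if n_crimps < 0:
        raise ValidationError("n_crimps must be >= 0")
    return (
        chain.n_beads * (bead.outer_diameter + bead.protrusion_length)
        + n_crimps * chain.crimp_length
        + chain.slack_length
    )


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class ChainTopology:
    """Particles and bonds of the discrete-element chain.

    Particle order is reading order along the chain: left anchor, then the
    mobile particles alternating crimp/bead (starting and ending with a
    crimp), then the right anchor.  Anchors are immobile, have zero radius
    and are exempt from forces; they carry a nominal positive mass so that
    mass arrays stay well defined.

    Bond tables are integer index arrays into the particle list:

    - ``linear_bonds``: (nb, 2) consecutive mobile pairs, stiffness
      ``linear_k`` (N/m), rest length ``linear_rest`` (m, = rb + rt).
    - ``angular_bonds``: (na, 3) consecutive mobile triples with the centre
      particle second; ``angular_k`` holds the *energy* constant
      k_theta = ka * mean arm rest length (J/rad^2), so the end-particle
      force magnitude is ka*|theta - pi| when the arms sit at rest length.
    - ``string_bonds``: (2, 2) rows (anchor index, end-particle index) with
      stiffness ``string_k`` (N/m) and rest length ``string_rest`` (m);
      slack below the rest length.
    """

    kinds: list  # "anchor" | "crimp" | "bead", per particle
    radii: np.ndarray
    masses: np.ndarray
    positions: np.ndarray  # (n, 3)
    linear_bonds: np.ndarray
    linear_k: np.ndarray
    linear_rest: np.ndarray
    angular_bonds: np.ndarray
    angular_k: np.ndarray
    string_bonds: np.ndarray
    string_k: np.ndarray
    string_rest: np.ndarray
    taut: bool = False
    meta: dict = field(default_factory=dict)

    # -- counts and index helpers ------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.kinds)

    @property
    def n_beads(self) -> int:
        return self.kinds.count("bead")

    @property
    def n_crimps(self) -> int:
        return self.kinds.count("crimp")

    @property
    def mobile_mask(self) -> np.ndarray:
        return np.array([k != "anchor" for k in self.kinds])

    @property
    def anchor_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == "anchor"])

    @property
    def crimp_indices(self) -> np.ndarray:
        """Particle indices of the crimps, in order along the chain."""
        return np.array([i for i, k in enumerate(self.kinds) if k == "crimp"])

    @property
    def bead_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == "bead"])

    @property
    def total_mass(self) -> float:
        return float(self.masses[self.mobile_mask].sum())

    def contact_span(self) -> float:
        """Straight-chain span of the simulated spheres, end surface to end
        surface: sum of bond rest lengths plus the two end-crimp radii."""
        return float(self.linear_rest.sum() + self.radii[self.crimp_indices[0]]
                     + self.radii[self.crimp_indices[-1]])

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "particles": [
                {
                    "kind": k,
                    "radius": float(r),
                    "mass": float(m),
                    "position": [float(c) for c in p],
                }
                for k, r, m, p in zip(self.kinds, self.radii, self.masses, self.positions)
            ],
            "linear_bonds": [
                {"i": int(i), "j": int(j), "k": float(kk), "rest": float(r)}
                for (i, j), kk, r in zip(self.linear_bonds, self.linear_k, self.linear_rest)
            ],
            "angular_bonds": [
                {"i": int(i), "j": int(j), "k": int(kk), "k_theta": float(kt)}
                for (i, j, kk), kt in zip(self.angular_bonds, self.angular_k)
            ],
            "string_bonds": [
                {"anchor": int(a), "particle": int(p), "k": float(kk), "rest": float(r)}
                for (a, p), kk, r in zip(self.string_bonds, self.string_k, self.string_rest)
            ],
            "taut": bool(self.taut),
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainTopology":
        parts = d["particles"]
        lin = d["linear_bonds"]
        ang = d["angular_bonds"]
        stb = d["string_bonds"]
        return cls(
            kinds=[p["kind"] for p in parts],
            radii=np.array([p["radius"] for p in parts], dtype=float),
            masses=np.array([p["mass"] for p in parts], dtype=float),
            positions=np.array([p["position"] for p in parts], dtype=float),
            linear_bonds=np.array([[b["i"], b["j"]] for b in lin], dtype=np.int64).reshape(-1, 2),
            linear_k=np.array([b["k"] for b in lin], dtype=float),
            linear_rest=np.array([b["rest"] for b in lin], dtype=float),
            angular_bonds=np.array([[b["i"], b["j"], b["k"]] for b in ang],
                                   dtype=np.int64).reshape(-1, 3),
            angular_k=np.array([b["k_theta"] for b in ang], dtype=float),
            string_bonds=np.array([[b["anchor"], b["particle"]] for b in stb],
                                  dtype=np.int64).reshape(-1, 2),
            string_k=np.array([b["k"] for b in stb], dtype=float),
            string_rest=np.array([b["rest"] for b in stb], dtype=float),
            taut=bool(d.get("taut", False)),
            meta=dict(d.get("meta", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChainTopology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_topology(
    chain: ChainSpec,
    bead: BeadSpec,
    forces: "ForceField",  # noqa: F821 - forward ref, see forcefield module
    *,
    crimp_model_radius: float = DEFAULT_CRIMP_MODEL_RADIUS,
    particle_density: float = DEFAULT_PARTICLE_DENSITY,
    mass_per_particle: Optional[Sequence[float] | float] = None,
) -> ChainTopology:
    """Construct the simulated chain topology.

    The chain is laid out straight along the anchor-anchor axis (x), centred
    between the anchors, with every linear bond at its rest length rb + rt.
    Masses come from ``particle_density`` and each particle's model radius,
    or from ``mass_per_particle`` (a scalar for all mobile particles, or a
    ``(crimp_mass, bead_mass)`` pair).

    If the anchor separation exceeds the chain's straight span plus both
    string rest lengths the configuration is necessarily taut; it is still
    built but flagged (``topology.taut``) and a warning is emitted.
    """
    if chain.n_beads < 1:
        raise ValidationError("a simulatable chain needs at least one bead")
    _require_positive(crimp_model_radius=crimp_model_radius)

    rb = bead.radius
    rt = crimp_model_radius
    n_beads = chain.n_beads
    n_mobile = 2 * n_beads + 1
    n = n_mobile + 2

    kinds = ["anchor"] + ["crimp" if i % 2 == 0 else "bead" for i in range(n_mobile)] + ["anchor"]
    radii = np.array([0.0] + [rt if i % 2 == 0 else rb for i in range(n_mobile)] + [0.0])

    if mass_per_particle is None:
        masses = particle_density * 4.0 / 3.0 * math.pi * radii**3
    elif np.isscalar(mass_per_particle):
        masses = np.full(n, float(mass_per_particle))
    else:
        m_crimp, m_bead = (float(v) for v in mass_per_particle)
        masses = np.array([m_crimp if k == "crimp" else m_bead for k in kinds])
    # anchors never move; give them the largest mobile mass so every mass > 0
    mobile = np.array([k != "anchor" for k in kinds])
    masses = np.where(mobile, masses, masses[mobile].max())
    if np.any(masses <= 0):
        raise ValidationError("all particle masses must be positive; "
                              "check particle_density / mass_per_particle")

    rest = rb + rt
    span = (n_mobile - 1) * rest
    xs = np.linspace(-span / 2.0, span / 2.0, n_mobile)
    positions = np.zeros((n, 3))
    positions[1:-1, 0] = xs
    positions[0] = (-chain.anchor_separation / 2.0, 0.0, 0.0)
    positions[-1] = (chain.anchor_separation / 2.0, 0.0, 0.0)

    mob = np.arange(1, n - 1)
    linear_bonds = np.column_stack([mob[:-1], mob[1:]])
    linear_k = np.full(len(linear_bonds), forces.kl)
    linear_rest = np.full(len(linear_bonds), rest)

    angular_bonds = np.column_stack([mob[:-2], mob[1:-1], mob[2:]])
    # energy constant k_theta = ka * mean arm rest length, so that the
    # end-particle force magnitude equals ka*|theta - pi| at rest-length arms
    angular_k = np.full(len(angular_bonds), forces.ka * rest)

    string_bonds = np.array([[0, 1], [n - 1, n - 2]])
    string_k = np.full(2, forces.ks)
    string_rest = np.full(2, chain.string_segment_length)

    taut = chain.anchor_separation > span + 2 * rt + 2 * chain.string_segment_length
    if taut:
        warnings.warn(
            "anchor separation exceeds chain span + string capacity: the "
            "chain is taut beyond the strings' rest lengths", stacklevel=2
        )

    return ChainTopology(
        kinds=kinds,
        radii=radii,
        masses=masses,
        positions=positions,
        linear_bonds=linear_bonds,
        linear_k=linear_k,
        linear_rest=linear_rest,
        angular_bonds=angular_bonds,
        angular_k=angular_k,
        string_bonds=string_bonds,
        string_k=string_k,
        string_rest=string_rest,
        taut=taut,
        meta={
            "chain": asdict(chain),
            "bead": asdict(bead),
            "crimp_model_radius": crimp_model_radius,
            "particle_density": particle_density,
        },
    )
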