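"""Compiled inner loop of the simulator.

The jitted functions here mirror the pure-numpy reference implementations in
:mod:`beadchain.forcefield` (the test-suite asserts agreement on random
configurations); they exist only for speed.  All state is passed explicitly
so the compiled code holds no module-level physics constants.
"""

import numpy as np
from numba import njit

#: integrator mode codes
SPLIT_DAMPING = 0
VERLET = 1


@njit(cache=True)
def bonded_forces(x, f, mobile, lin_idx, lin_k, lin_rest,
                  ang_idx, ang_k, str_idx, str_k, str_rest):
    """Assemble linear + angular + string forces into ``f`` (overwritten)."""
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for b in range(lin_idx.shape[0]):
        i = lin_idx[b, 0]
        j = lin_idx[b, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        R = np.sqrt(dx * dx + dy * dy + dz * dz)
        if R > 0.0:
            c = lin_k[b] * (R - lin_rest[b]) / R
            f[i, 0] += c * dx
            f[i, 1] += c * dy
            f[i, 2] += c * dz
            f[j, 0] -= c * dx
            f[j, 1] -= c * dy
            f[j, 2] -= c * dz
    for b in range(ang_idx.shape[0]):
        i = ang_idx[b, 0]
        j = ang_idx[b, 1]
        k = ang_idx[b, 2]
        r1x = x[i, 0] - x[j, 0]
        r1y = x[i, 1] - x[j, 1]
        r1z = x[i, 2] - x[j, 2]
        r2x = x[k, 0] - x[j, 0]
        r2y = x[k, 1] - x[j, 1]
        r2z = x[k, 2] - x[j, 2]
        L1 = np.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
        L2 = np.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
        if L1 == 0.0 or L2 == 0.0:
            continue
        ct = (r1x * r2x + r1y * r2y + r1z * r2z) / (L1 * L2)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        # fac = (dU/dtheta)/sin(theta); -> -k_theta as theta -> pi
        if st < 1e-8:
            fac = -ang_k[b]
        else:
            fac = ang_k[b] * (theta - np.pi) / st
        fix = fac / L1 * (r2x / L2 - ct * r1x / L1)
        fiy = fac / L1 * (r2y / L2 - ct * r1y / L1)
        fiz = fac / L1 * (r2z / L2 - ct * r1z / L1)
        fkx = fac / L2 * (r1x / L1 - ct * r2x / L2)
        fky = fac / L2 * (r1y / L1 - ct * r2y / L2)
        fkz = fac / L2 * (r1z / L1 - ct * r2z / L2)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz
    for b in range(str_idx.shape[0]):
        a = str_idx[b, 0]
        p = str_idx[b, 1]
        dx = x[p, 0] - x[a, 0]
        dy = x[p, 1] - x[a, 1]
        dz = x[p, 2] - x[a, 2]
        ell = np.sqrt(dx * dx + dy * dy + dz * dz)
        if ell > str_rest[b]:
            c = -str_k[b] * (ell - str_rest[b]) / ell
            f[p, 0] += c * dx
            f[p, 1] += c * dy
            f[p, 2] += c * dz
    for i in range(n):
        if not mobile[i]:
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = 0.0


@njit(cache=True)
def run_block(x, v, masses, mobile, lin_idx, lin_k, lin_rest,
              ang_idx, ang_k, str_idx, str_k, str_rest,
              kicks, kv, dt, n_sub, mode):
    """Advance ``kicks.shape[0]`` timesteps in place.

    ``kicks`` holds the *force* (N) per step/particle/component, zero for
    untargeted particles; it is held constant across the substeps of its
    step.  ``mode`` selects the integrator:

    - SPLIT_DAMPING: kick-drift-kick where each half velocity update is the
      exact solution of m dv/dt = F - kv v with F frozen, so the scheme is
      stable under arbitrarily strong damping and reduces to velocity-Verlet
      as kv -> 0.
    - VERLET: velocity-Verlet with the damping force evaluated explicitly
      (the textbook scheme; unstable when kv*dt/m is large).
    """
    n = x.shape[0]
    f = np.zeros((n, 3))
    h = dt / n_sub
    n_steps = kicks.shape[0]
    # exact exponential damping decay over half a substep, per particle
    c_half = np.empty(n)
    for i in range(n):
        c_half[i] = np.exp(-kv * (h / 2.0) / masses[i]) if kv > 0.0 else 1.0
    for step in range(n_steps):
        for _ in range(n_sub):
            bonded_forces(x, f, mobile, lin_idx, lin_k, lin_rest,
                          ang_idx, ang_k, str_idx, str_k, str_rest)
            for i in range(n):
                if not mobile[i]:
                    continue
                for d in range(3):
                    F = f[i, d] + kicks[step, i, d]
                    if mode == SPLIT_DAMPING:
                        if kv > 0.0:
                            v[i, d] = v[i, d] * c_half[i] + (F / kv) * (1.0 - c_half[i])
                        else:
                            v[i, d] += F * (h / 2.0) / masses[i]
                    else:  # VERLET
                        v[i, d] += (F - kv * v[i, d]) * (h / 2.0) / masses[i]
            for i in range(n):
                if mobile[i]:
                    x[i, 0] += v[i, 0] * h
                    x[i, 1] += v[i, 1] * h
                    x[i, 2] += v[i, 2] * h
            bonded_forces(x, f, mobile, lin_idx, lin_k, lin_rest,
                          ang_idx, ang_k, str_idx, str_k, str_rest)
            for i in range(n):
                if not mobile[i]:
                    continue
                for d in range(3):
                    F = f[i, d] + kicks[step, i, d]
                    if mode == SPLIT_DAMPING:
                        if kv > 0.0:
                            v[i, d] = v[i, d] * c_half[i] + (F / kv) * (1.0 - c_half[i])
                        else:
                            v[i, d] += F * (h / 2.0) / masses[i]
                    else:
                        v[i, d] += (F - kv * v[i, d]) * (h / 2.0) / masses[i]
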