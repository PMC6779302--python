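"""Numba-compiled inner loops (plane-strain element assembly, IB transfers).

These duplicate, in scalar 2-D form, exactly the physics of the vectorized
reference implementations in `materials`/`ibfe`; the test suite asserts
agreement to roundoff between the two paths.  Everything here is an
optimisation detail: the public API never exposes this module.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected to be present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


LAW_LEAFLET_ANT = 0
LAW_LEAFLET_POST = 1
LAW_MYOCARDIUM = 2


@njit(cache=True, fastmath=False)
def _phi(r: float) -> float:
    r = abs(r)
    if r < 1.0:
        return (3.0 - 2.0 * r + np.sqrt(1.0 + 4.0 * r - 4.0 * r * r)) / 8.0
    if r < 2.0:
        return (5.0 - 2.0 * r - np.sqrt(-7.0 + 12.0 * r - 4.0 * r * r)) / 8.0
    return 0.0


@njit(cache=True)
def spread_forces_jit(forces, points, n, h):
    f = np.zeros((2, n, n))
    inv_h2 = 1.0 / (h * h)
    for p in range(points.shape[0]):
        gx = (points[p, 0] / h) % n
        gy = (points[p, 1] / h) % n
        ix0 = int(np.floor(gx)) - 1
        iy0 = int(np.floor(gy)) - 1
        for a in range(4):
            wx = _phi(gx - (ix0 + a))
            if wx == 0.0:
                continue
            i = (ix0 + a) % n
            for b in range(4):
                wy = _phi(gy - (iy0 + b))
                if wy == 0.0:
                    continue
                j = (iy0 + b) % n
                w = wx * wy * inv_h2
                f[0, i, j] += w * forces[p, 0]
                f[1, i, j] += w * forces[p, 1]
    return f


@njit(cache=True)
def interpolate_velocity_jit(u, points, n, h):
    U = np.zeros((points.shape[0], 2))
    for p in range(points.shape[0]):
        gx = (points[p, 0] / h) % n
        gy = (points[p, 1] / h) % n
        ix0 = int(np.floor(gx)) - 1
        iy0 = int(np.floor(gy)) - 1
        for a in range(4):
            wx = _phi(gx - (ix0 + a))
            if wx == 0.0:
                continue
            i = (ix0 + a) % n
            for b in range(4):
                wy = _phi(gy - (iy0 + b))
                if wy == 0.0:
                    continue
                j = (iy0 + b) % n
                w = wx * wy
                U[p, 0] += w * u[0, i, j]
                U[p, 1] += w * u[1, i, j]
    return U


@njit(cache=True)
def assemble_tri_forces_jit(
    chi, tris, dm_inv, area, law, contractile, f0, s0,
    leaf_C1, leaf_av, leaf_bv,  # length-2 arrays: anterior, posterior
    a, b, af, bf, as_, bs, afs, bfs,
    beta_s, T_active, kpa, forces,
):
    """Accumulate -dE/dchi for all triangles (plane-strain, one-point quad).

    Returns the index of the first inverted element, or -1.
    """
    m = tris.shape[0]
    for e in range(m):
        n0, n1, n2 = tris[e, 0], tris[e, 1], tris[e, 2]
        d00 = chi[n1, 0] - chi[n0, 0]
        d10 = chi[n1, 1] - chi[n0, 1]
        d01 = chi[n2, 0] - chi[n0, 0]
        d11 = chi[n2, 1] - chi[n0, 1]
        # F2 = Ds @ Dm_inv
        F00 = d00 * dm_inv[e, 0, 0] + d01 * dm_inv[e, 1, 0]
        F01 = d00 * dm_inv[e, 0, 1] + d01 * dm_inv[e, 1, 1]
        F10 = d10 * dm_inv[e, 0, 0] + d11 * dm_inv[e, 1, 0]
        F11 = d10 * dm_inv[e, 0, 1] + d11 * dm_inv[e, 1, 1]
        J = F00 * F11 - F01 * F10
        if J <= 0.0:
            return e
        logI3 = 2.0 * np.log(J)
        invJ = 1.0 / J
        # (F^-T) in-plane block
        G00 = F11 * invJ
        G01 = -F10 * invJ
        G10 = -F01 * invJ
        G11 = F00 * invJ
        fx, fy = f0[e, 0], f0[e, 1]
        # F f0
        Ff0 = F00 * fx + F01 * fy
        Ff1 = F10 * fx + F11 * fy
        I4f = Ff0 * Ff0 + Ff1 * Ff1

        P00 = P01 = P10 = P11 = 0.0
        if law[e] == LAW_MYOCARDIUM:
            I1 = F00 * F00 + F01 * F01 + F10 * F10 + F11 * F11 + 1.0
            iso = a * np.exp(b * (I1 - 3.0))
            P00 = iso * F00 - a * G00
            P01 = iso * F01 - a * G01
            P10 = iso * F10 - a * G10
            P11 = iso * F11 - a * G11
            if I4f > 1.0:
                g = I4f - 1.0
                cf = 2.0 * af * g * np.exp(bf * g * g)
                P00 += cf * Ff0 * fx
                P01 += cf * Ff0 * fy
                P10 += cf * Ff1 * fx
                P11 += cf * Ff1 * fy
            sx, sy = s0[e, 0], s0[e, 1]
            Fs0 = F00 * sx + F01 * sy
            Fs1 = F10 * sx + F11 * sy
            I4s = Fs0 * Fs0 + Fs1 * Fs1
            if I4s > 1.0:
                g = I4s - 1.0
                cs = 2.0 * as_ * g * np.exp(bs * g * g)
                P00 += cs * Fs0 * sx
                P01 += cs * Fs0 * sy
                P10 += cs * Fs1 * sx
                P11 += cs * Fs1 * sy
            I8 = Ff0 * Fs0 + Ff1 * Fs1
            c8 = afs * I8 * np.exp(bfs * I8 * I8)
            # F (f x s + s x f)
            P00 += c8 * (Ff0 * sx + Fs0 * fx)
            P01 += c8 * (Ff0 * sy + Fs0 * fy)
            P10 += c8 * (Ff1 * sx + Fs1 * fx)
            P11 += c8 * (Ff1 * sy + Fs1 * fy)
            if contractile[e] and T_active > 0.0:
                ca = J * T_active
                P00 += ca * Ff0 * fx
                P01 += ca * Ff0 * fy
                P10 += ca * Ff1 * fx
                P11 += ca * Ff1 * fy
        else:
            li = law[e]
            C1 = leaf_C1[li]
            P00 = 2.0 * C1 * (F00 - G00)
            P01 = 2.0 * C1 * (F01 - G01)
            P10 = 2.0 * C1 * (F10 - G10)
            P11 = 2.0 * C1 * (F11 - G11)
            if I4f > 1.0:
                g = I4f - 1.0
                cc = 2.0 * leaf_av[li] * g * np.exp(leaf_bv[li] * g * g)
                P00 += cc * Ff0 * fx
                P01 += cc * Ff0 * fy
                P10 += cc * Ff1 * fx
                P11 += cc * Ff1 * fy
        blog = beta_s * logI3
        P00 += blog * G00
        P01 += blog * G01
        P10 += blog * G10
        P11 += blog * G11

        sc = area[e] * kpa
        # H = area * P @ Dm_inv^T
        H00 = sc * (P00 * dm_inv[e, 0, 0] + P01 * dm_inv[e, 0, 1])
        H01 = sc * (P00 * dm_inv[e, 1, 0] + P01 * dm_inv[e, 1, 1])
        H10 = sc * (P10 * dm_inv[e, 0, 0] + P11 * dm_inv[e, 0, 1])
        H11 = sc * (P10 * dm_inv[e, 1, 0] + P11 * dm_inv[e, 1, 1])
        forces[n1, 0] -= H00
        forces[n1, 1] -= H10
        forces[n2, 0] -= H01
        forces[n2, 1] -= H11
        forces[n0, 0] += H00 + H01
        forces[n0, 1] += H10 + H11
    return -1


@njit(cache=True)
def chord_forces_jit(chi, chords, L0, C, A, kpa, forces):
    for c in range(chords.shape[0]):
        i, j = chords[c, 0], chords[c, 1]
        dx = chi[j, 0] - chi[i, 0]
        dy = chi[j, 1] - chi[i, 1]
        d = np.sqrt(dx * dx + dy * dy)
        lam = d / L0[c]
        if lam <= 1.0:
            continue
        t = 2.0 * C * (lam - 1.0 / (lam * lam)) * kpa * A
        fx = t * dx / d
        fy = t * dy / d
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[j, 0] -= fx
        forces[j, 1] -= fy
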