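"""Compiled core of the voxel Monte Carlo photon transport.

Single serial numba kernel: photons march voxel-by-voxel with
boundary-aware ray stepping; free paths are sampled in dimensionless
optical depth; absorption removes mu_a/mu_t of the packet weight at
each collision; scattering follows Henyey-Greenstein with the local
anisotropy; refractive-index mismatch triggers Snell/Fresnel events at
voxel faces (ambient n = 1 outside the grid).  Fluence is tallied with
the track-length estimator (sum of weight x path per voxel).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = 1e30
_MAX_EVENTS = 50_000_000  # hard cap per photon against pathological loops


@njit(cache=True, inline="always")
def _fresnel(n1, n2, ci, rnd):
    """Return (reflect?, cos of transmitted angle). ci = |cos incidence|."""
    if n1 == n2:
        return False, ci
    sin2t = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if sin2t >= 1.0:  # total internal reflection
        return True, 0.0
    ct = np.sqrt(1.0 - sin2t)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    if rnd < 0.5 * (rs * rs + rp * rp):
        return True, 0.0
    return False, ct


@njit(cache=True)
def transport_kernel(
    labels,
    mua,
    mus,
    g,
    nref,
    pos,
    dirs,
    wts,
    seed,
    weight_threshold,
    roulette_survival,
    mismatch,
    dx,
):
    """Trace all photons; returns (raw fluence tally, absorbed, escaped).

    The fluence tally is sum(weight * path_mm) per voxel; the caller
    divides by voxel volume and photon count.
    """
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    fluence = np.zeros((nx, ny, nz))
    absorbed = 0.0
    escaped = 0.0
    n_photons = pos.shape[0]

    for ip in range(n_photons):
        px = pos[ip, 0]
        py = pos[ip, 1]
        pz = pos[ip, 2]
        ux = dirs[ip, 0]
        uy = dirs[ip, 1]
        uz = dirs[ip, 2]
        w = wts[ip]
        if w <= 0.0:
            continue

        ix = min(max(int(px / dx), 0), nx - 1)
        iy = min(max(int(py / dx), 0), ny - 1)
        iz = min(max(int(pz / dx), 0), nz - 1)

        # specular entry through the illuminated face (ambient n = 1)
        if mismatch and pz == 0.0 and uz > 0.0:
            n2 = nref[labels[ix, iy, iz]]
            refl, ct = _fresnel(1.0, n2, uz, np.random.random())
            if refl:
                escaped += w
                continue
            scale = 1.0 / n2
            ux *= scale
            uy *= scale
            uz = ct
            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm

        tau = -np.log(np.random.random())
        alive = True
        events = 0
        while alive:
            events += 1
            if events > _MAX_EVENTS:
                escaped += w
                break
            lab = labels[ix, iy, iz]
            mt = mua[lab] + mus[lab]

            if ux > 0.0:
                tx = ((ix + 1) * dx - px) / ux
            elif ux < 0.0:
                tx = (ix * dx - px) / ux
            else:
                tx = _BIG
            if uy > 0.0:
                ty = ((iy + 1) * dx - py) / uy
            elif uy < 0.0:
                ty = (iy * dx - py) / uy
            else:
                ty = _BIG
            if uz > 0.0:
                tz = ((iz + 1) * dx - pz) / uz
            elif uz < 0.0:
                tz = (iz * dx - pz) / uz
            else:
                tz = _BIG
            db = min(tx, min(ty, tz))
            if db < 0.0:
                db = 0.0
            dcol = tau / mt if mt > 0.0 else _BIG

            if dcol <= db:
                # collision inside this voxel
                fluence[ix, iy, iz] += w * dcol
                px += ux * dcol
                py += uy * dcol
                pz += uz * dcol
                frac = mua[lab] / mt
                absorbed += w * frac
                w *= 1.0 - frac
                if w <= 0.0:
                    break
                # Henyey-Greenstein deflection about the current direction
                gg = g[lab]
                if gg > 1e-6 or gg < -1e-6:
                    s = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                    ct = (1.0 + gg * gg - s * s) / (2.0 * gg)
                else:
                    ct = 1.0 - 2.0 * np.random.random()
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                st = np.sqrt(1.0 - ct * ct)
                phi = 2.0 * np.pi * np.random.random()
                cp = np.cos(phi)
                sp = np.sin(phi)
                if uz > 0.99999 or uz < -0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    tmpx = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    tmpy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz = -den * st * cp + uz * ct
                    ux = tmpx
                    uy = tmpy
                norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
                tau = -np.log(np.random.random())
                # Russian roulette on low-weight packets
                if w < weight_threshold:
                    if np.random.random() < roulette_survival:
                        w /= roulette_survival
                    else:
                        break
                continue

            # fly to the nearest voxel face
            fluence[ix, iy, iz] += w * db
            tau -= mt * db
            if tau < 0.0:
                tau = 0.0
            px += ux * db
            py += uy * db
            pz += uz * db

            # which face was hit, and the neighbour index
            if db == tx:
                axis = 0
                step = 1 if ux > 0.0 else -1
                px = (ix + 1) * dx if step == 1 else ix * dx  # snap to face
                jx, jy, jz = ix + step, iy, iz
            elif db == ty:
                axis = 1
                step = 1 if uy > 0.0 else -1
                py = (iy + 1) * dx if step == 1 else iy * dx
                jx, jy, jz = ix, iy + step, iz
            else:
                axis = 2
                step = 1 if uz > 0.0 else -1
                pz = (iz + 1) * dx if step == 1 else iz * dx
                jx, jy, jz = ix, iy, iz + step

            outside = jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz
            if not mismatch:
                if outside:
                    escaped += w
                    break
                ix, iy, iz = jx, jy, jz
                continue

            n1 = nref[lab]
            n2 = 1.0 if outside else nref[labels[jx, jy, jz]]
            if n1 == n2:
                if outside:
                    escaped += w
                    break
                ix, iy, iz = jx, jy, jz
                continue

            ci = ux if axis == 0 else (uy if axis == 1 else uz)
            if ci < 0.0:
                ci = -ci
            refl, ct = _fresnel(n1, n2, ci, np.random.random())
            if refl:
                if axis == 0:
                    ux = -ux
                elif axis == 1:
                    uy = -uy
                else:
                    uz = -uz
                continue
            # refract: scale transverse components, set normal to cos(theta_t)
            scale = n1 / n2
            if axis == 0:
                sgn = 1.0 if ux > 0.0 else -1.0
                uy *= scale
                uz *= scale
                ux = sgn * ct
            elif axis == 1:
                sgn = 1.0 if uy > 0.0 else -1.0
                ux *= scale
                uz *= scale
                uy = sgn * ct
            else:
                sgn = 1.0 if uz > 0.0 else -1.0
                ux *= scale
                uy *= scale
                uz = sgn * ct
            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
            if outside:
                escaped += w
                break
            ix, iy, iz = jx, jy, jz

    return fluence, absorbed, escaped
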