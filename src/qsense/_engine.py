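"""Batch photon-transport engine (single implementation, two compilations).

``_run_batch_impl`` is written in nopython-compatible Python and compiled
with numba for production runs; the uncompiled function is kept as a
bit-identical interpreted reference (`engine="python"`), since numba's
``np.random`` reproduces NumPy's legacy MT19937 stream exactly.

Polarization bookkeeping is the meridian-plane method: the Stokes vector
of each photon is referenced to the plane spanned by its direction and
the depth axis.  A scattering event rotates the Stokes vector by the
azimuth psi into the scattering plane, applies the single-sphere Mueller
matrix, and rotates into the meridian plane of the new direction.  Frames
are carried as explicit orthonormal vectors (e_par, e_perp, k), which
makes the rotation angles plain dot products and gives a well-defined
limiting convention when the direction passes through the poles (the
previous transverse frame is kept).

Scattering elements are reconstructed at the sampled angle from linearly
interpolated complex amplitudes, so every per-event Mueller matrix is an
exact Jones pair and a fully polarized photon stays fully polarized to
rounding error.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# tally indices
T_DETECTED = 0
T_REFL_UNDET = 1
T_TRANSMITTED = 2
T_ABSORBED = 3
T_EVENT_CAP = 4
T_ROULETTE = 5
T_REJECT_FAIL = 6
N_TALLY = 7

N_EVENT_BINS = 64

_ROULETTE_WMIN = 1e-4
_ROULETTE_P = 0.1


def _run_batch_impl(
    seed,
    n_photons,
    mu_a,
    mu_s,
    thickness,
    k0x, k0y, k0z,
    e0x, e0y, e0z,
    f0x, f0y, f0z,
    s0i, s0q, s0u, s0v,
    cdf,
    reS1, imS1, reS2, imS2,
    env,
    collect_radius, cos_accept,
    event_cap, max_rejection,
    binary_absorption,
    fresnel, n_rel, entry_refl,
    det, tallies, bins_s, bins_n,
):
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    n_t = reS1.shape[1]
    inv_pi = (n_t - 1) / math.pi
    r2max = collect_radius * collect_radius
    dop_dev = 0.0

    for _ in range(n_photons):
        if fresnel and entry_refl > 0.0:
            if np.random.random() < entry_refl:
                tallies[T_REFL_UNDET] += 1  # specular glare, never entered
                continue
        x = 0.0
        y = 0.0
        z = 0.0
        kx, ky, kz = k0x, k0y, k0z
        ex, ey, ez = e0x, e0y, e0z
        fx, fy, fz = f0x, f0y, f0z
        si, sq, su, sv = s0i, s0q, s0u, s0v
        w = 1.0
        nev = 0

        while True:
            u = np.random.random()
            step = -math.log(1.0 - u) / mu_t
            zn = z + step * kz

            if zn < 0.0:
                # reaches the top surface
                tlen = z / (-kz)
                xx = x + tlen * kx
                yy = y + tlen * ky
                if fresnel:
                    ci = -kz
                    st2 = n_rel * math.sqrt(max(0.0, 1.0 - ci * ci))
                    if st2 >= 1.0:
                        rbar = 1.0
                        rp = 1.0
                        rs = 1.0
                        rpp = 1.0
                        rss = 1.0
                    else:
                        ct2 = math.sqrt(1.0 - st2 * st2)
                        rs = (n_rel * ci - ct2) / (n_rel * ci + ct2)
                        rp = (ci - n_rel * ct2) / (ci + n_rel * ct2)
                        rpp = rp * rp
                        rss = rs * rs
                        ip = 0.5 * (si + sq)
                        is_ = 0.5 * (si - sq)
                        rbar = (rpp * ip + rss * is_) / si
                    if np.random.random() < rbar:
                        # internal reflection: fold Stokes, flip direction
                        ip = 0.5 * (si + sq)
                        is_ = 0.5 * (si - sq)
                        ipn = rpp * ip
                        isn = rss * is_
                        inew = ipn + isn
                        sq = (ipn - isn) / inew
                        su = rp * rs * su / inew
                        sv = rp * rs * sv / inew
                        si = 1.0
                        x, y, z = xx, yy, 0.0
                        kz = -kz
                        # meridian frame of the flipped direction
                        pn = math.sqrt(kx * kx + ky * ky)
                        if pn * pn > 1e-24:
                            fx2 = ky / pn
                            fy2 = -kx / pn
                            ex = fy2 * kz
                            ey = -fx2 * kz
                            ez = fx2 * ky - fy2 * kx
                            fx, fy, fz = fx2, fy2, 0.0
                        else:
                            ez = -ez
                        continue
                    # transmitted out of the top: refract and attenuate
                    ct2 = math.sqrt(1.0 - st2 * st2)
                    tp = 1.0 - rpp
                    ts = 1.0 - rss
                    ip = 0.5 * (si + sq)
                    is_ = 0.5 * (si - sq)
                    ipn = tp * ip
                    isn = ts * is_
                    inew = ipn + isn
                    sq = (ipn - isn) / inew
                    amp = math.sqrt(tp * ts)
                    su = amp * su / inew
                    sv = amp * sv / inew
                    si = 1.0
                    pn = math.sqrt(kx * kx + ky * ky)
                    if pn > 1e-12:
                        kx = kx / pn * st2
                        ky = ky / pn * st2
                    kz = -ct2
                # detection decision
                if xx * xx + yy * yy <= r2max and (-kz) >= cos_accept:
                    d2 = 1.0 - kx * kx
                    if d2 > 1e-18:
                        dn = math.sqrt(d2)
                        dpx = d2 / dn
                        dpy = -kx * ky / dn
                        dpz = -kx * kz / dn
                        cosd = dpx * ex + dpy * ey + dpz * ez
                        sind = dpx * fx + dpy * fy + dpz * fz
                        rr = math.sqrt(cosd * cosd + sind * sind)
                        if rr > 0.0:
                            cosd /= rr
                            sind /= rr
                        c2 = cosd * cosd - sind * sind
                        s2 = 2.0 * cosd * sind
                        qd = sq * c2 + su * s2
                        ud = -sq * s2 + su * c2
                    else:
                        qd = sq
                        ud = su
                    det[0] += w * si
                    det[1] += w * qd
                    det[2] += w * ud
                    det[3] += w * sv
                    det[4] += w
                    dop = math.sqrt(qd * qd + ud * ud + sv * sv) / si
                    dev = abs(1.0 - dop)
                    if dev > dop_dev:
                        dop_dev = dev
                    bi = nev
                    if bi > N_EVENT_BINS - 1:
                        bi = N_EVENT_BINS - 1
                    bins_s[bi, 0] += w * si
                    bins_s[bi, 1] += w * qd
                    bins_s[bi, 2] += w * ud
                    bins_s[bi, 3] += w * sv
                    bins_n[bi] += 1
                    tallies[T_DETECTED] += 1
                else:
                    tallies[T_REFL_UNDET] += 1
                break

            if zn > thickness:
                if fresnel:
                    ci = kz
                    st2 = n_rel * math.sqrt(max(0.0, 1.0 - ci * ci))
                    if st2 >= 1.0:
                        rbar = 1.0
                        rp = 1.0
                        rs = 1.0
                        rpp = 1.0
                        rss = 1.0
                    else:
                        ct2 = math.sqrt(1.0 - st2 * st2)
                        rs = (n_rel * ci - ct2) / (n_rel * ci + ct2)
                        rp = (ci - n_rel * ct2) / (ci + n_rel * ct2)
                        rpp = rp * rp
                        rss = rs * rs
                        ip = 0.5 * (si + sq)
                        is_ = 0.5 * (si - sq)
                        rbar = (rpp * ip + rss * is_) / si
                    if np.random.random() < rbar:
                        tlen = (thickness - z) / kz
                        x = x + tlen * kx
                        y = y + tlen * ky
                        z = thickness
                        ip = 0.5 * (si + sq)
                        is_ = 0.5 * (si - sq)
                        ipn = rpp * ip
                        isn = rss * is_
                        inew = ipn + isn
                        sq = (ipn - isn) / inew
                        su = rp * rs * su / inew
                        sv = rp * rs * sv / inew
                        si = 1.0
                        kz = -kz
                        pn = math.sqrt(kx * kx + ky * ky)
                        if pn * pn > 1e-24:
                            fx2 = ky / pn
                            fy2 = -kx / pn
                            ex = fy2 * kz
                            ey = -fx2 * kz
                            ez = fx2 * ky - fy2 * kx
                            fx, fy, fz = fx2, fy2, 0.0
                        else:
                            ez = -ez
                        continue
                tallies[T_TRANSMITTED] += 1
                break

            x += step * kx
            y += step * ky
            z = zn

            if mu_a > 0.0:
                if binary_absorption:
                    if np.random.random() < mu_a / mu_t:
                        tallies[T_ABSORBED] += 1
                        break
                else:
                    w *= mu_s / mu_t
                    if w < _ROULETTE_WMIN:
                        if np.random.random() < _ROULETTE_P:
                            w /= _ROULETTE_P
                        else:
                            tallies[T_ROULETTE] += 1
                            break

            # fresh particle size for this event
            u = np.random.random()
            ri = 0
            while cdf[ri] < u:
                ri += 1

            # rejection sampling of (theta, psi) against P(theta,psi)
            accepted = False
            ct = 0.0
            psi = 0.0
            s11 = 0.0
            s12 = 0.0
            rs1 = 0.0
            is1 = 0.0
            rs2 = 0.0
            is2 = 0.0
            c2p = 0.0
            s2p = 0.0
            for _it in range(max_rejection):
                u1 = np.random.random()
                u2 = np.random.random()
                u3 = np.random.random()
                ct = 1.0 - 2.0 * u1
                th = math.acos(ct)
                psi = 2.0 * math.pi * u2
                ff = th * inv_pi
                i0 = int(ff)
                if i0 > n_t - 2:
                    i0 = n_t - 2
                fr = ff - i0
                rs1 = reS1[ri, i0] * (1.0 - fr) + reS1[ri, i0 + 1] * fr
                is1 = imS1[ri, i0] * (1.0 - fr) + imS1[ri, i0 + 1] * fr
                rs2 = reS2[ri, i0] * (1.0 - fr) + reS2[ri, i0 + 1] * fr
                is2 = imS2[ri, i0] * (1.0 - fr) + imS2[ri, i0 + 1] * fr
                a1 = rs1 * rs1 + is1 * is1
                a2 = rs2 * rs2 + is2 * is2
                s11 = 0.5 * (a2 + a1)
                s12 = 0.5 * (a2 - a1)
                c2p = math.cos(2.0 * psi)
                s2p = math.sin(2.0 * psi)
                p = s11 * si + s12 * (sq * c2p + su * s2p)
                if p > 0.0 and u3 * env[ri] * si < p:
                    accepted = True
                    break
            if not accepted:
                tallies[T_REJECT_FAIL] += 1
                break

            s33 = rs2 * rs1 + is2 * is1
            s34 = is2 * rs1 - rs2 * is1

            # rotate by psi into the scattering plane
            q1 = sq * c2p + su * s2p
            u1s = -sq * s2p + su * c2p
            # single-sphere Mueller matrix
            inew = s11 * si + s12 * q1
            qm = s12 * si + s11 * q1
            um = s33 * u1s + s34 * sv
            vm = -s34 * u1s + s33 * sv

            # update direction and transverse frame
            cp = math.cos(psi)
            sp = math.sin(psi)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            ax = cp * ex + sp * fx
            ay = cp * ey + sp * fy
            az = cp * ez + sp * fz
            nkx = ct * kx + st * ax
            nky = ct * ky + st * ay
            nkz = ct * kz + st * az
            norm = math.sqrt(nkx * nkx + nky * nky + nkz * nkz)
            nkx /= norm
            nky /= norm
            nkz /= norm
            apx = ct * ax - st * kx
            apy = ct * ay - st * ky
            apz = ct * az - st * kz
            dot = apx * nkx + apy * nky + apz * nkz
            apx -= dot * nkx
            apy -= dot * nky
            apz -= dot * nkz
            norm = math.sqrt(apx * apx + apy * apy + apz * apz)
            apx /= norm
            apy /= norm
            apz /= norm
            bpx = nky * apz - nkz * apy
            bpy = nkz * apx - nkx * apz
            bpz = nkx * apy - nky * apx

            # rotate from the scattering plane into the new meridian plane
            pn2 = nkx * nkx + nky * nky
            if pn2 > 1e-24:
                inv = 1.0 / math.sqrt(pn2)
                mfx = nky * inv
                mfy = -nkx * inv
                mex = mfy * nkz
                mey = -mfx * nkz
                mez = mfx * nky - mfy * nkx
                cosg = mex * apx + mey * apy + mez * apz
                sing = mex * bpx + mey * bpy + mez * bpz
                rr = math.sqrt(cosg * cosg + sing * sing)
                cosg /= rr
                sing /= rr
                c2g = cosg * cosg - sing * sing
                s2g = 2.0 * cosg * sing
                qn = qm * c2g + um * s2g
                un = -qm * s2g + um * c2g
                ex, ey, ez = mex, mey, mez
                fx, fy, fz = mfx, mfy, 0.0
            else:
                # pole: keep the scattering-plane frame as the reference
                qn = qm
                un = um
                ex, ey, ez = apx, apy, apz
                fx, fy, fz = bpx, bpy, bpz

            kx, ky, kz = nkx, nky, nkz
            inv = 1.0 / inew
            sq = qn * inv
            su = un * inv
            sv = vm * inv
            si = 1.0

            nev += 1
            if nev > event_cap:
                tallies[T_EVENT_CAP] += 1
                break

    det[5] = dop_dev


run_batch_python = _run_batch_impl
run_batch_numba = njit(cache=True)(_run_batch_impl)
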