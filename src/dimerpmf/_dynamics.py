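"""Overdamped Langevin integrator for the quasi-2D toy membrane (numba kernel).

State: L lipid discs (unwrapped planar coordinates) and P in {0, 1, 2} rigid
elliptical bodies, each a ring of M particles, parameterized by centre of
mass and in-plane angle.  All pair interactions are purely repulsive
harmonic soft cores with the minimum-image convention in a periodic square
box.  Positions are kept unwrapped (diffusion observables stay meaningful);
all distances are evaluated through the minimum image.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_brownian(
    seed,
    n_equil,
    n_steps,
    stride,
    lipid_xy,  # (L, 2) float64, in-place start state
    com,  # (P, 2)
    angle,  # (P,)
    body_ref,  # (P, M, 2)
    box,
    dt,
    temperature,
    gamma,
    gamma_com,
    gamma_rot,
    eps,
    sig_ll,
    sig_lr,
    sig_rr,
    k_umb,
    d0,
    kappa,  # (P,) effective torsion constants
    ref_angle,  # (P,)
    att_a,  # inter-protein cohesion well depth (0 disables)
    att_w,  # cohesion range
    k_perp,  # transverse (off-axis) position restraint (0 disables)
):
    np.random.seed(seed)
    L = lipid_xy.shape[0]
    P = com.shape[0]
    M = body_ref.shape[1] if P > 0 else 0

    n_rec = (n_steps + stride - 1) // stride
    rec_lip = np.empty((n_rec, L, 2))
    rec_com = np.empty((n_rec, P, 2))
    rec_ang = np.empty((n_rec, P))
    rec_t = np.empty(n_rec)

    ring = np.empty((P, M, 2))
    f_lip = np.empty((L, 2))
    f_ring = np.empty((P, M, 2))
    f_com = np.empty((P, 2))
    torque = np.empty(P)

    sig_ll2 = sig_ll * sig_ll
    sig_lr2 = sig_lr * sig_lr
    sig_rr2 = sig_rr * sig_rr
    mob_l = dt / gamma
    noi_l = np.sqrt(2.0 * temperature * dt / gamma)
    mob_c = dt / gamma_com
    noi_c = np.sqrt(2.0 * temperature * dt / gamma_com)
    mob_a = dt / gamma_rot
    noi_a = np.sqrt(2.0 * temperature * dt / gamma_rot)

    irec = 0
    total = n_equil + n_steps
    for step in range(total):
        # rigid ring particle positions from (com, angle)
        for p in range(P):
            c = np.cos(angle[p])
            s = np.sin(angle[p])
            for m in range(M):
                bx = body_ref[p, m, 0]
                by = body_ref[p, m, 1]
                ring[p, m, 0] = com[p, 0] + c * bx - s * by
                ring[p, m, 1] = com[p, 1] + s * bx + c * by

        for i in range(L):
            f_lip[i, 0] = 0.0
            f_lip[i, 1] = 0.0
        for p in range(P):
            f_com[p, 0] = 0.0
            f_com[p, 1] = 0.0
            torque[p] = 0.0
            for m in range(M):
                f_ring[p, m, 0] = 0.0
                f_ring[p, m, 1] = 0.0

        # lipid-lipid soft repulsion
        for i in range(L):
            xi = lipid_xy[i, 0]
            yi = lipid_xy[i, 1]
            for j in range(i + 1, L):
                dx = xi - lipid_xy[j, 0]
                dy = yi - lipid_xy[j, 1]
                dx -= box * np.rint(dx / box)
                dy -= box * np.rint(dy / box)
                r2 = dx * dx + dy * dy
                if r2 < sig_ll2 and r2 > 1e-14:
                    r = np.sqrt(r2)
                    f = eps * (1.0 - r / sig_ll) / (sig_ll * r)
                    fx = f * dx
                    fy = f * dy
                    f_lip[i, 0] += fx
                    f_lip[i, 1] += fy
                    f_lip[j, 0] -= fx
                    f_lip[j, 1] -= fy

        # lipid-ring repulsion
        for i in range(L):
            xi = lipid_xy[i, 0]
            yi = lipid_xy[i, 1]
            for p in range(P):
                for m in range(M):
                    dx = xi - ring[p, m, 0]
                    dy = yi - ring[p, m, 1]
                    dx -= box * np.rint(dx / box)
                    dy -= box * np.rint(dy / box)
                    r2 = dx * dx + dy * dy
                    if r2 < sig_lr2 and r2 > 1e-14:
                        r = np.sqrt(r2)
                        f = eps * (1.0 - r / sig_lr) / (sig_lr * r)
                        fx = f * dx
                        fy = f * dy
                        f_lip[i, 0] += fx
                        f_lip[i, 1] += fy
                        f_ring[p, m, 0] -= fx
                        f_ring[p, m, 1] -= fy

        # ring-ring interaction between distinct bodies: soft-core repulsion
        # plus a short-range Gaussian cohesion well centred at contact
        att_cut2 = (sig_rr + 3.0 * att_w) * (sig_rr + 3.0 * att_w)
        for p in range(P):
            for q in range(p + 1, P):
                for m in range(M):
                    for m2 in range(M):
                        dx = ring[p, m, 0] - ring[q, m2, 0]
                        dy = ring[p, m, 1] - ring[q, m2, 1]
                        dx -= box * np.rint(dx / box)
                        dy -= box * np.rint(dy / box)
                        r2 = dx * dx + dy * dy
                        if r2 > 1e-14:
                            f = 0.0
                            if r2 < sig_rr2:
                                r = np.sqrt(r2)
                                f += eps * (1.0 - r / sig_rr) / (sig_rr * r)
                            if att_a > 0.0 and r2 < att_cut2:
                                r = np.sqrt(r2)
                                u = (r - sig_rr) / att_w
                                f -= att_a * u * np.exp(-0.5 * u * u) / (att_w * r)
                            if f != 0.0:
                                fx = f * dx
                                fy = f * dy
                                f_ring[p, m, 0] += fx
                                f_ring[p, m, 1] += fy
                                f_ring[q, m2, 0] -= fx
                                f_ring[q, m2, 1] -= fy

        # reduce ring-particle forces to COM force + torque
        for p in range(P):
            for m in range(M):
                fx = f_ring[p, m, 0]
                fy = f_ring[p, m, 1]
                f_com[p, 0] += fx
                f_com[p, 1] += fy
                torque[p] += (ring[p, m, 0] - com[p, 0]) * fy - (ring[p, m, 1] - com[p, 1]) * fx

        # harmonic umbrella on the inter-COM separation
        if k_umb > 0.0 and P == 2:
            dx = com[1, 0] - com[0, 0]
            dy = com[1, 1] - com[0, 1]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            d = np.sqrt(dx * dx + dy * dy)
            if d > 1e-12:
                fmag = -k_umb * (d - d0)  # along increasing separation, on body 1
                ux = dx / d
                uy = dy / d
                f_com[1, 0] += fmag * ux
                f_com[1, 1] += fmag * uy
                f_com[0, 0] -= fmag * ux
                f_com[0, 1] -= fmag * uy

        # transverse restraint keeping the approach collinear (restraining the
        # bodies at *relative positions*, not merely at a scalar distance)
        if k_perp > 0.0 and P == 2:
            dy = com[1, 1] - com[0, 1]
            dy -= box * np.rint(dy / box)
            f_com[1, 1] -= k_perp * dy
            f_com[0, 1] += k_perp * dy

        # torque-only rotational restraint (rigid-body reduction)
        for p in range(P):
            if kappa[p] > 0.0:
                dphi = angle[p] - ref_angle[p]
                torque[p] -= kappa[p] * np.sin(dphi) * np.cos(dphi)

        # overdamped updates
        for i in range(L):
            if not (np.isfinite(f_lip[i, 0]) and np.isfinite(f_lip[i, 1])):
                return rec_t, rec_lip, rec_com, rec_ang, step + 1
            lipid_xy[i, 0] += mob_l * f_lip[i, 0] + noi_l * np.random.normal()
            lipid_xy[i, 1] += mob_l * f_lip[i, 1] + noi_l * np.random.normal()
        for p in range(P):
            if not (np.isfinite(f_com[p, 0]) and np.isfinite(f_com[p, 1]) and np.isfinite(torque[p])):
                return rec_t, rec_lip, rec_com, rec_ang, step + 1
            com[p, 0] += mob_c * f_com[p, 0] + noi_c * np.random.normal()
            com[p, 1] += mob_c * f_com[p, 1] + noi_c * np.random.normal()
            angle[p] += mob_a * torque[p] + noi_a * np.random.normal()

        idx = step - n_equil
        if idx >= 0 and idx % stride == 0:
            rec_t[irec] = (step + 1) * dt
            for i in range(L):
                rec_lip[irec, i, 0] = lipid_xy[i, 0]
                rec_lip[irec, i, 1] = lipid_xy[i, 1]
            for p in range(P):
                rec_com[irec, p, 0] = com[p, 0]
                rec_com[irec, p, 1] = com[p, 1]
                rec_ang[irec, p] = angle[p]
            irec += 1

    return rec_t, rec_lip, rec_com, rec_ang, -1
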