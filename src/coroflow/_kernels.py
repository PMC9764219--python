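"""Compiled time-marching core of the 1D solver.

Everything in here operates on the flattened mesh arrays assembled by
:mod:`coroflow.solver`.  The interior of every computational segment is
advanced with a two-step MacCormack predictor (forward-space) / corrector
(backward-space) sweep of the mass/momentum equations; boundary nodes are
then closed with characteristic couplings: prescribed-flow inlet,
3-unknown Newton at bifurcations (mass + total-pressure continuity +
characteristic compatibility), 2-unknown Newton at stenosis interfaces
(flow continuity + total-pressure jump equal to the stenosis pressure-loss
element), and scalar Newton at Windkessel terminals (implicit-Euler RC
update coupled through the forward characteristic).

Status codes written to ``out[0]``: 0 ok, 1 CFL violation, 2 NaN or
non-positive area, 3 Newton failure.
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_CFL = 1
STATUS_NAN = 2
STATUS_NEWTON = 3

_NEWTON_MAX = 60
_NEWTON_RTOL = 1e-13


@njit(cache=True, inline="always")
def _wave_c(beta_i, sqA0_i, A, rho):
    # c = sqrt(beta * sqrt(A) / (2 rho)); beta_i stored as beta, sqA0 unused
    return math.sqrt(beta_i * math.sqrt(A) / (2.0 * rho))


@njit(cache=True, inline="always")
def _press(beta_i, sqA0_i, A, pext):
    return pext + beta_i * (math.sqrt(A) - sqA0_i)


@njit(cache=True)
def _interp_periodic(xt, xq, tau):
    # xt spans [0, T] with xq[0] == xq[-1]
    n = len(xt)
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xt[mid] <= tau:
            lo = mid
        else:
            hi = mid
    w = (tau - xt[lo]) / (xt[hi] - xt[lo])
    return xq[lo] * (1.0 - w) + xq[hi] * w


@njit(cache=True)
def _inlet_solve(A0g, W, qin, beta_i, sqA0_i, rho):
    """Solve u(A) - 4c(A) = W with u = qin/A for the inlet area."""
    A = A0g
    for _ in range(_NEWTON_MAX):
        c = _wave_c(beta_i, sqA0_i, A, rho)
        f = qin / A - 4.0 * c - W
        df = -qin / (A * A) - c / A
        dA = -f / df
        if A + dA <= 0.0:
            dA = -0.5 * A
        A += dA
        if abs(dA) < _NEWTON_RTOL * A:
            return A
    return -1.0


@njit(cache=True)
def _terminal_solve(Ag, W, beta_i, sqA0_i, rho, pext, R, C, Pold, dt):
    """Windkessel terminal: P_tube(A) = (C/dt*Pold + Q(A)) / (C/dt + 1/R),
    with Q(A) = A*(W - 4c(A)) from the forward characteristic."""
    denom = C / dt + 1.0 / R
    A = Ag
    for _ in range(_NEWTON_MAX):
        c = _wave_c(beta_i, sqA0_i, A, rho)
        u = W - 4.0 * c
        Qb = A * u
        f = _press(beta_i, sqA0_i, A, pext) - (C / dt * Pold + Qb) / denom
        df = beta_i / (2.0 * math.sqrt(A)) - (u - c) / denom
        dA = -f / df
        if A + dA <= 0.0:
            dA = -0.5 * A
        A += dA
        if abs(dA) < _NEWTON_RTOL * A:
            return A
    return -1.0


@njit(cache=True)
def _junction_solve(Ap, A1, A2, Wp, W1, W2,
                    bp, sp, b1, s1, b2, s2, rho, pext, xout):
    """Bifurcation: unknowns (Ap, A1, A2) after eliminating Q through the
    characteristics; equations are mass conservation and total-pressure
    continuity parent->child1, parent->child2."""
    for _ in range(_NEWTON_MAX):
        cp = _wave_c(bp, sp, Ap, rho)
        c1 = _wave_c(b1, s1, A1, rho)
        c2 = _wave_c(b2, s2, A2, rho)
        up = Wp - 4.0 * cp
        u1 = W1 + 4.0 * c1
        u2 = W2 + 4.0 * c2
        Qp = Ap * up
        Q1 = A1 * u1
        Q2 = A2 * u2
        TPp = _press(bp, sp, Ap, pext) + 0.5 * rho * up * up
        TP1 = _press(b1, s1, A1, pext) + 0.5 * rho * u1 * u1
        TP2 = _press(b2, s2, A2, pext) + 0.5 * rho * u2 * u2
        f1 = Qp - Q1 - Q2
        f2 = TPp - TP1
        f3 = TPp - TP2
        # Jacobian
        dQp = up - cp
        dQ1 = u1 + c1
        dQ2 = u2 + c2
        dTPp = bp / (2.0 * math.sqrt(Ap)) - rho * up * cp / Ap
        dTP1 = b1 / (2.0 * math.sqrt(A1)) + rho * u1 * c1 / A1
        dTP2 = b2 / (2.0 * math.sqrt(A2)) + rho * u2 * c2 / A2
        # solve 3x3 [[dQp,-dQ1,-dQ2],[dTPp,-dTP1,0],[dTPp,0,-dTP2]] x = -f
        a11 = dQp
        a12 = -dQ1
        a13 = -dQ2
        a21 = dTPp
        a22 = -dTP1
        a31 = dTPp
        a33 = -dTP2
        det = (a11 * a22 * a33 - a12 * a21 * a33 - a13 * a22 * a31)
        if det == 0.0:
            return False
        r1 = -f1
        r2 = -f2
        r3 = -f3
        dAp = (r1 * a22 * a33 - a12 * r2 * a33 - a13 * a22 * r3) / det
        dA1 = (a11 * r2 * a33 - r1 * a21 * a33 + a13 * (a21 * r3 - a31 * r2)) / det
        dA2 = (a11 * a22 * r3 - a12 * (a21 * r3 - a31 * r2) - r1 * a22 * a31) / det
        # damping: keep areas positive
        damp = 1.0
        while damp > 1e-4 and (Ap + damp * dAp <= 0.0 or
                               A1 + damp * dA1 <= 0.0 or
                               A2 + damp * dA2 <= 0.0):
            damp *= 0.5
        Ap += damp * dAp
        A1 += damp * dA1
        A2 += damp * dA2
        if (abs(dAp) < _NEWTON_RTOL * Ap and abs(dA1) < _NEWTON_RTOL * A1
                and abs(dA2) < _NEWTON_RTOL * A2):
            xout[0] = Ap
            xout[1] = A1
            xout[2] = A2
            return True
    return False


@njit(cache=True)
def _stenosis_solve(Au, Ad, Wu, Wd, bu, su, bd, sd,
                    ka, kb, kd, qprev, dt, rho, pext, xout):
    """Stenosis interface: unknowns (A_up, A_down); flow continuity is
    built in through Q = A_up * u_up(A_up); the total-pressure jump equals
    dPs(Q) = ka*Q + kb*|Q|*Q + kd*(Q - qprev)/dt."""
    for _ in range(_NEWTON_MAX):
        cu = _wave_c(bu, su, Au, rho)
        cd = _wave_c(bd, sd, Ad, rho)
        uu = Wu - 4.0 * cu
        ud = Wd + 4.0 * cd
        Qb = Au * uu
        f1 = Qb - Ad * ud
        dPs = ka * Qb + kb * abs(Qb) * Qb + kd * (Qb - qprev) / dt
        TPu = _press(bu, su, Au, pext) + 0.5 * rho * uu * uu
        TPd = _press(bd, sd, Ad, pext) + 0.5 * rho * ud * ud
        f2 = TPu - TPd - dPs
        dQdAu = uu - cu
        ddPs = ka + 2.0 * kb * abs(Qb) + kd / dt
        a11 = dQdAu
        a12 = -(ud + cd)
        a21 = (bu / (2.0 * math.sqrt(Au)) - rho * uu * cu / Au
               - ddPs * dQdAu)
        a22 = -(bd / (2.0 * math.sqrt(Ad)) + rho * ud * cd / Ad)
        det = a11 * a22 - a12 * a21
        if det == 0.0:
            return False
        dAu = (-f1 * a22 + f2 * a12) / det
        dAd = (-f2 * a11 + f1 * a21) / det
        damp = 1.0
        while damp > 1e-4 and (Au + damp * dAu <= 0.0 or
                               Ad + damp * dAd <= 0.0):
            damp *= 0.5
        Au += damp * dAu
        Ad += damp * dAd
        if abs(dAu) < _NEWTON_RTOL * Au and abs(dAd) < _NEWTON_RTOL * Ad:
            xout[0] = Au
            xout[1] = Ad
            return True
    return False


@njit(cache=True)
def advance(A, Q, beta, sqA0,
            off, nn, dxs,
            junc, sseg, scoef, sqprev,
            tcs, tR, tC, tP,
            qin_t, qin_q, Tper,
            t0, dt, nsteps,
            rho, alpha, cf, pext, cfl,
            closed_ends,
            rec_nodes, rec_every,
            recT, recP, recQ, recA,
            meanA_prev, sumA,
            As, Qs, An, Qn,
            out):
    ncs = len(off)
    nj = len(junc)
    ns = len(sseg)
    nt = len(tcs)
    nprobe = len(rec_nodes)
    N = len(A)
    xout3 = np.empty(3)
    xout2 = np.empty(2)
    nrec = 0
    dev_sum = 0.0
    dev_cnt = 0.0
    max_ratio = 0.0

    for step in range(nsteps):
        tnew = t0 + (step + 1) * dt
        # ---- interior MacCormack sweep -------------------------------
        for cs in range(ncs):
            o = off[cs]
            n = nn[cs]
            h = dxs[cs]
            lam = dt / h
            smax = 0.0
            # predictor (forward differences), nodes o .. o+n-2
            for i in range(o, o + n - 1):
                Ai = A[i]
                Qi = Q[i]
                Aip = A[i + 1]
                Qip = Q[i + 1]
                Pi = _press(beta[i], sqA0[i], Ai, pext)
                Pip = _press(beta[i + 1], sqA0[i + 1], Aip, pext)
                Fi = alpha * Qi * Qi / Ai
                Fip = alpha * Qip * Qip / Aip
                As[i] = Ai - lam * (Qip - Qi)
                Qs[i] = Qi - lam * (Fip - Fi) \
                    - dt * ((Ai / rho) * (Pip - Pi) / h + cf * Qi / Ai)
                ui = abs(Qi / Ai)
                s = ui + _wave_c(beta[i], sqA0[i], Ai, rho)
                if s > smax:
                    smax = s
            ratio = smax * dt / (cfl * h)
            if ratio > max_ratio:
                max_ratio = ratio
            # corrector (backward differences of starred), interior nodes
            for i in range(o + 1, o + n - 1):
                if As[i] <= 0.0 or As[i - 1] <= 0.0:
                    out[0] = STATUS_NAN
                    out[1] = max_ratio
                    out[2] = dev_sum
                    out[3] = dev_cnt
                    return nrec
                Psi = _press(beta[i], sqA0[i], As[i], pext)
                Psim = _press(beta[i - 1], sqA0[i - 1], As[i - 1], pext)
                Fsi = alpha * Qs[i] * Qs[i] / As[i]
                Fsim = alpha * Qs[i - 1] * Qs[i - 1] / As[i - 1]
                An[i] = 0.5 * (A[i] + As[i] - lam * (Qs[i] - Qs[i - 1]))
                Qn[i] = 0.5 * (Q[i] + Qs[i] - lam * (Fsi - Fsim)
                               - dt * ((As[i] / rho) * (Psi - Psim) / h
                                       + cf * Qs[i] / As[i]))
            An[o] = A[o]
            Qn[o] = Q[o]
            An[o + n - 1] = A[o + n - 1]
            Qn[o + n - 1] = Q[o + n - 1]
            if closed_ends:
                # conservative half-cell updates with wall flux 0;
                # numerical mass flux F_{i+1/2} = (Q_{i+1} + Qs_i)/2
                fl = 0.5 * (Q[o + 1] + Qs[o])
                An[o] = A[o] - lam * fl
                Qn[o] = 0.0
                fr = 0.5 * (Q[o + n - 1] + Qs[o + n - 2])
                An[o + n - 1] = A[o + n - 1] + lam * fr
                Qn[o + n - 1] = 0.0
        if max_ratio > 1.0:
            out[0] = STATUS_CFL
            out[1] = max_ratio
            out[2] = dev_sum
            out[3] = dev_cnt
            return nrec
        for i in range(N):
            A[i] = An[i]
            Q[i] = Qn[i]

        if not closed_ends:
            # ---- inlet (root comp segment start) ---------------------
            o0 = off[0]
            qin = _interp_periodic(qin_t, qin_q, tnew % Tper)
            ci = _wave_c(beta[o0 + 1], sqA0[o0 + 1], A[o0 + 1], rho)
            W = Q[o0 + 1] / A[o0 + 1] - 4.0 * ci
            Anew = _inlet_solve(A[o0], W, qin, beta[o0], sqA0[o0], rho)
            if Anew <= 0.0:
                out[0] = STATUS_NEWTON
                out[1] = max_ratio
                out[2] = dev_sum
                out[3] = dev_cnt
                return nrec
            A[o0] = Anew
            Q[o0] = qin

            # ---- junctions -------------------------------------------
            for j in range(nj):
                p = junc[j, 0]
                c1 = junc[j, 1]
                c2 = junc[j, 2]
                ip = off[p] + nn[p] - 1
                i1 = off[c1]
                i2 = off[c2]
                kp = ip - 1
                k1 = i1 + 1
                k2 = i2 + 1
                Wp = Q[kp] / A[kp] + 4.0 * _wave_c(beta[kp], sqA0[kp], A[kp], rho)
                W1 = Q[k1] / A[k1] - 4.0 * _wave_c(beta[k1], sqA0[k1], A[k1], rho)
                W2 = Q[k2] / A[k2] - 4.0 * _wave_c(beta[k2], sqA0[k2], A[k2], rho)
                okj = _junction_solve(A[ip], A[i1], A[i2], Wp, W1, W2,
                                      beta[ip], sqA0[ip], beta[i1], sqA0[i1],
                                      beta[i2], sqA0[i2], rho, pext, xout3)
                if not okj:
                    out[0] = STATUS_NEWTON
                    out[1] = max_ratio
                    out[2] = dev_sum
                    out[3] = dev_cnt
                    return nrec
                A[ip] = xout3[0]
                A[i1] = xout3[1]
                A[i2] = xout3[2]
                Q[ip] = A[ip] * (Wp - 4.0 * _wave_c(beta[ip], sqA0[ip], A[ip], rho))
                Q[i1] = A[i1] * (W1 + 4.0 * _wave_c(beta[i1], sqA0[i1], A[i1], rho))
                Q[i2] = A[i2] * (W2 + 4.0 * _wave_c(beta[i2], sqA0[i2], A[i2], rho))

            # ---- stenosis interfaces ---------------------------------
            for s in range(ns):
                up = sseg[s, 0]
                dn = sseg[s, 1]
                iu = off[up] + nn[up] - 1
                idn = off[dn]
                ku = iu - 1
                kd = idn + 1
                Wu = Q[ku] / A[ku] + 4.0 * _wave_c(beta[ku], sqA0[ku], A[ku], rho)
                Wd = Q[kd] / A[kd] - 4.0 * _wave_c(beta[kd], sqA0[kd], A[kd], rho)
                oks = _stenosis_solve(A[iu], A[idn], Wu, Wd,
                                      beta[iu], sqA0[iu], beta[idn], sqA0[idn],
                                      scoef[s, 0], scoef[s, 1], scoef[s, 2],
                                      sqprev[s], dt, rho, pext, xout2)
                if not oks:
                    out[0] = STATUS_NEWTON
                    out[1] = max_ratio
                    out[2] = dev_sum
                    out[3] = dev_cnt
                    return nrec
                A[iu] = xout2[0]
                A[idn] = xout2[1]
                qi = A[iu] * (Wu - 4.0 * _wave_c(beta[iu], sqA0[iu], A[iu], rho))
                Q[iu] = qi
                Q[idn] = qi
                sqprev[s] = qi

            # ---- Windkessel terminals --------------------------------
            for k in range(nt):
                cs = tcs[k]
                ie = off[cs] + nn[cs] - 1
                ke = ie - 1
                W = Q[ke] / A[ke] + 4.0 * _wave_c(beta[ke], sqA0[ke], A[ke], rho)
                Anew = _terminal_solve(A[ie], W, beta[ie], sqA0[ie], rho, pext,
                                       tR[k], tC[k], tP[k], dt)
                if Anew <= 0.0:
                    out[0] = STATUS_NEWTON
                    out[1] = max_ratio
                    out[2] = dev_sum
                    out[3] = dev_cnt
                    return nrec
                A[ie] = Anew
                Q[ie] = Anew * (W - 4.0 * _wave_c(beta[ie], sqA0[ie], Anew, rho))
                tP[k] = _press(beta[ie], sqA0[ie], Anew, pext)

        # ---- diagnostics ---------------------------------------------
        bad = False
        for i in range(N):
            if not (A[i] > 0.0) or not np.isfinite(Q[i]):
                bad = True
                break
        if bad:
            out[0] = STATUS_NAN
            out[1] = max_ratio
            out[2] = dev_sum
            out[3] = dev_cnt
            return nrec
        for i in range(N):
            sumA[i] += A[i]
            dev_sum += abs(A[i] - meanA_prev[i]) / meanA_prev[i]
        dev_cnt += N
        if step % rec_every == 0:
            for p in range(nprobe):
                i = rec_nodes[p]
                recP[nrec, p] = _press(beta[i], sqA0[i], A[i], pext)
                recQ[nrec, p] = Q[i]
                recA[nrec, p] = A[i]
            recT[nrec] = tnew
            nrec += 1

    out[0] = STATUS_OK
    out[1] = max_ratio
    out[2] = dev_sum
    out[3] = dev_cnt
    return nrec
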