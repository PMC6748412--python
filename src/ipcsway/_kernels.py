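"""Numba hot loops for the simulator and the delayed switching Kalman filter.

Everything here works on unpacked scalars so the per-sample filter step stays
allocation-free.  The public modules (:mod:`ipcsway.model`,
:mod:`ipcsway.geometry`, :mod:`ipcsway.kalman`, :mod:`ipcsway.simulate`)
wrap these kernels behind typed interfaces; the pure-Python step operations
in :mod:`ipcsway.kalman` provide an independent slow path that the test
suite checks against these kernels.

Conventions shared with the rest of the package:

* state vector is (tilt angle, angular velocity) in radians / rad s^-1;
* the passive drift matrix is ``A = [[0, 1], [a21, a22]]`` with
  ``a21 = m g h (1 - K) / I`` and ``a22 = -B / I``;
* the delayed (active) drift matrix is ``A_tau = [[0, 0], [at21, at22]]``
  with ``at21 = -m g h P / I`` and ``at22 = -D / I``;
* process noise enters at the acceleration row with intensity ``sigma``
  (``Q = diag(0, sigma^2)``);
* a vertical switching line (a = 0.5) is flagged explicitly instead of
  carrying an infinite slope through ``tan``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Objective value returned when the filter diverges; finite so that
# derivative-free optimizers can still rank candidates.
DIVERGED = 1.0e12

# Variant codes shared with ipcsway.model.ModelVariant
ISDDE = 0
SDDE = 1
SDE = 2


@njit(cache=True)
def discretize_scalar(a21, a22, at21, at22, q, dt):
    """Exact zero-order-hold discretization over an interval ``dt``.

    Returns the 11-tuple
    ``(ad11, ad12, ad21, ad22, td11, td12, td21, td22, qd11, qd12, qd22)``
    where ``Ad = expm(A dt)``, ``Td = [int_0^dt expm(A s) ds] @ A_tau``
    (inversion-free, so a singular ``A`` is fine) and ``Qd`` is the
    process-noise integral ``int_0^dt expm(A s) Q expm(A s)^T ds`` with
    ``Q = diag(0, q)``.

    Everything is evaluated with scalar Taylor recurrences at a halved
    step plus the doubling identities ``Ad(2h) = Ad(h)^2``,
    ``J(2h) = (I + Ad(h)) J(h)`` and
    ``Qd(2h) = Qd(h) + Ad(h) Qd(h) Ad(h)^T``.  Strictly allocation-free,
    because this runs once per threshold traversal inside the filter
    loop.  ``dt <= 0`` returns the identity / zero-matrix limit.
    """
    if dt <= 0.0:
        return (1.0, 0.0, 0.0, 1.0,
                0.0, 0.0, 0.0, 0.0,
                0.0, 0.0, 0.0)
    # scaling: bring the infinity norm of A*h below 0.25
    nrm = max(1.0, abs(a21) + abs(a22)) * dt
    sq = 0
    while nrm > 0.25:
        nrm *= 0.5
        sq += 1
    h = dt / 2.0 ** sq

    # running Taylor term T_k = A^k h^k / k! (A = [[0, 1], [a21, a22]]),
    # accumulated into Ad = sum T_k and J = sum T_k h/(k+1)
    t11 = 1.0; t12 = 0.0; t21 = 0.0; t22 = 1.0
    ad11 = 1.0; ad12 = 0.0; ad21 = 0.0; ad22 = 1.0
    j11 = h; j12 = 0.0; j21 = 0.0; j22 = h
    # Qd term D_k = C_k h^k / k! with C_1 = Q = diag(0, q) and the
    # derivative recurrence C_{k+1} = A C_k + C_k A^T
    d11 = 0.0; d12 = 0.0; d22 = q * h
    qd11 = 0.0; qd12 = 0.0; qd22 = d22
    for k in range(1, 14):
        hk = h / k
        n11 = t12 * a21 * hk
        n12 = (t11 + t12 * a22) * hk
        n21 = t22 * a21 * hk
        n22 = (t21 + t22 * a22) * hk
        t11 = n11; t12 = n12; t21 = n21; t22 = n22
        ad11 += t11; ad12 += t12; ad21 += t21; ad22 += t22
        hj = h / (k + 1)
        j11 += t11 * hj; j12 += t12 * hj
        j21 += t21 * hj; j22 += t22 * hj
        if q > 0.0:
            e11 = 2.0 * d12
            e12 = d22 + a21 * d11 + a22 * d12
            e22 = 2.0 * (a21 * d12 + a22 * d22)
            d11 = e11 * hj; d12 = e12 * hj; d22 = e22 * hj
            qd11 += d11; qd12 += d12; qd22 += d22

    # undo the scaling by repeated doubling
    for _ in range(sq):
        n11 = qd11 + (ad11 * ad11 * qd11 + 2.0 * ad11 * ad12 * qd12
                      + ad12 * ad12 * qd22)
        n12 = qd12 + (ad11 * ad21 * qd11
                      + (ad11 * ad22 + ad12 * ad21) * qd12
                      + ad12 * ad22 * qd22)
        n22 = qd22 + (ad21 * ad21 * qd11 + 2.0 * ad21 * ad22 * qd12
                      + ad22 * ad22 * qd22)
        qd11 = n11; qd12 = n12; qd22 = n22
        m11 = j11 + ad11 * j11 + ad12 * j21
        m12 = j12 + ad11 * j12 + ad12 * j22
        m21 = j21 + ad21 * j11 + ad22 * j21
        m22 = j22 + ad21 * j12 + ad22 * j22
        j11 = m11; j12 = m12; j21 = m21; j22 = m22
        b11 = ad11 * ad11 + ad12 * ad21
        b12 = ad11 * ad12 + ad12 * ad22
        b21 = ad21 * ad11 + ad22 * ad21
        b22 = ad21 * ad12 + ad22 * ad22
        ad11 = b11; ad12 = b12; ad21 = b21; ad22 = b22

    # Td = J @ A_tau; only the second column of J enters because the
    # first row of A_tau is zero
    td11 = j12 * at21
    td12 = j12 * at22
    td21 = j22 * at21
    td22 = j22 * at22
    return (ad11, ad12, ad21, ad22,
            td11, td12, td21, td22,
            qd11, qd12, qd22)


@njit(cache=True, inline="always")
def is_active_scalar(p, v, alpha, vertical, r):
    """Activation condition on a lagged phase point (p, v).

    Strict inequalities as in the activation rule: the point must lie
    outside the insensitivity radius AND on the active side of the
    switching line.  ``vertical`` marks the singular a = 0.5 geometry,
    taken as the limit from above (line clause true off the axis).
    """
    if p * p + v * v <= r * r:
        return False
    if vertical:
        return p != 0.0
    return p * (v - alpha * p) > 0.0


@njit(cache=True)
def crossing_scalar(up, uv, vp, vv, alpha, vertical, r, dt, switching_off):
    """Threshold crossing between consecutive lagged states u -> v.

    Returns ``(cp, cv, dtm)``: the interpolated crossing point and the
    time for the lagged state to reach it.  For switching ON the roles of
    u and v are traded before applying the switching-off formulas, but the
    time split is always measured from the true earlier point u.
    """
    du = vp - up
    dv = vv - uv
    seg2 = du * du + dv * dv
    if seg2 < 1e-300:
        return up, uv, 0.0
    # role trade for switching on: formulas below reference the "v" side
    fup, fuv, fvp, fvv = up, uv, vp, vv
    if not switching_off:
        fup, fuv, fvp, fvv = vp, vv, up, uv
    fdu = fvp - fup
    fdv = fvv - fuv
    degen = False
    if abs(fdu) < 1e-14 * (abs(fdv) + 1.0):
        # vertical segment in phase space: slope m undefined
        degen = True
        m = 0.0
    else:
        m = fdv / fdu
    cp = 0.0
    cv = 0.0
    if degen:
        cp = 0.5 * (up + vp)
        cv = 0.5 * (uv + vv)
    elif fvp * fvp + fvv * fvv <= r * r:
        # destination-side point inside the insensitivity radius:
        # first-order interpolation onto the circle
        den = 2.0 * (fvp + m * fvv)
        if abs(den) < 1e-14:
            cp = 0.5 * (up + vp)
            cv = 0.5 * (uv + vv)
        else:
            cp = (r * r + fvp * fvp + 2.0 * m * fvp * fvv - fvv * fvv) / den
            cv = m * cp - m * fvp + fvv
    elif (fvp > 0.0 and fvv < 0.0 and fup < 0.0 and fuv < 0.0) or \
         (fvp < 0.0 and fvv > 0.0 and fup > 0.0 and fuv > 0.0):
        # quadrant pattern: traversing the axis u = 0
        cp = 0.0
        cv = fvv - m * fvp
    else:
        # traversing the switching line x' = alpha x
        if vertical or abs(alpha - m) < 1e-14 * (abs(alpha) + abs(m) + 1.0):
            # parallel (or singular vertical) line: midpoint fallback
            cp = 0.5 * (up + vp)
            cv = 0.5 * (uv + vv)
        else:
            cp = (fvv - m * fvp) / (alpha - m)
            cv = m * cp - m * fvp + fvv
    # distance-proportional time split, measured from the original u;
    # the crossing lies on the segment line, so a projection gives the
    # fraction directly.  Clamp so both sub-intervals stay non-negative.
    t = ((cp - up) * du + (cv - uv) * dv) / seg2
    if t < 0.0:
        t = 0.0
        cp = up
        cv = uv
    elif t > 1.0:
        t = 1.0
        cp = vp
        cv = vv
    return cp, cv, t * dt


@njit(cache=True, inline="always")
def _lag_state(j, dt, tau, kf, kc, frac, x0, xd0, xdd0, bufp, bufv,
               last, compat):
    """Lagged state at time j*dt - tau.

    Quadratic backward extrapolation before the first measurement; linear
    interpolation of the corrected-state buffer afterwards.  ``last`` is
    the newest available buffer index; out-of-range lags clamp to it.
    """
    t = j * dt
    if t <= tau + 1e-12:
        d = t - tau
        return x0 + xd0 * d + xdd0 * d * d, xd0 + 2.0 * xdd0 * d
    i1 = j - kf
    i2 = j - kc
    if i1 > last:
        i1 = last
    if i2 > last:
        i2 = last
    if i1 < 0:
        i1 = 0
    if i2 < 0:
        i2 = 0
    if compat:
        p = bufp[i1] + (bufp[i1] - bufp[i2]) * frac
        v = bufv[i1] + (bufv[i1] - bufv[i2]) * frac
    else:
        p = bufp[i1] + (bufp[i2] - bufp[i1]) * frac
        v = bufv[i1] + (bufv[i2] - bufv[i1]) * frac
    return p, v


@njit(cache=True)
def filter_minus2ll(y, dt, a21, a22, at21, at22, q, eps, alpha, vertical,
                    r, tau, x0, xd0, xdd0, mu, variant, compat, p0diag,
                    innov, filtp, filtv):
    """-2 log-likelihood of ``y`` under the delayed switching filter.

    ``innov``, ``filtp``, ``filtv`` are caller-allocated arrays of length
    ``len(y)`` that receive the innovations and corrected state means
    (the corrected means double as the delay buffer).  ``p0diag`` is the
    diagonal value of the initial state covariance.  Returns
    ``(minus2ll, n_traversals)``; a diverged pass returns ``DIVERGED``.
    """
    n = y.shape[0]
    (ad11, ad12, ad21, ad22,
     td11, td12, td21, td22,
     qd11, qd12, qd22) = discretize_scalar(a21, a22, at21, at22, q, dt)
    lam = tau / dt
    kf = int(np.floor(lam))
    kc = int(np.ceil(lam))
    frac = lam - kf
    mp = x0
    mv = xd0
    p11 = p0diag
    p12 = 0.0
    p22 = p0diag
    m2 = 0.0
    ln2pi = np.log(2.0 * np.pi)
    ntrav = 0
    for i in range(n):
        # --- correction with y[i] -------------------------------------
        s = p11 + eps
        if not (s > 1e-300 and np.isfinite(s)):
            return DIVERGED, ntrav
        e = y[i] - (mp + mu)
        m2 += ln2pi + np.log(s) + e * e / s
        g1 = p11 / s
        g2 = p12 / s
        mp += g1 * e
        mv += g2 * e
        n11 = p11 - g1 * p11
        n12 = p12 - g1 * p12
        n22 = p22 - g2 * p12
        p11 = n11
        p12 = n12
        p22 = n22
        if p11 < 0.0:
            p11 = 0.0
        if p22 < 0.0:
            p22 = 0.0
        innov[i] = e
        filtp[i] = mp
        filtv[i] = mv
        if not (np.isfinite(mp) and abs(mp) < 1e10):
            return DIVERGED, ntrav
        if i == n - 1:
            break
        # --- prediction to i+1 ----------------------------------------
        if variant == SDE:
            nmp = ad11 * mp + ad12 * mv
            nmv = ad21 * mp + ad22 * mv
            c11 = (ad11 * ad11 * p11 + 2.0 * ad11 * ad12 * p12
                   + ad12 * ad12 * p22 + qd11)
            c12 = (ad11 * ad21 * p11 + (ad11 * ad22 + ad12 * ad21) * p12
                   + ad12 * ad22 * p22 + qd12)
            c22 = (ad21 * ad21 * p11 + 2.0 * ad21 * ad22 * p12
                   + ad22 * ad22 * p22 + qd22)
            mp, mv, p11, p12, p22 = nmp, nmv, c11, c12, c22
            continue
        upp, upv = _lag_state(i, dt, tau, kf, kc, frac, x0, xd0, xdd0,
                              filtp, filtv, i, compat)
        vpp, vpv = _lag_state(i + 1, dt, tau, kf, kc, frac, x0, xd0, xdd0,
                              filtp, filtv, i, compat)
        if variant == SDDE:
            au = True
            av = True
        else:
            au = is_active_scalar(upp, upv, alpha, vertical, r)
            av = is_active_scalar(vpp, vpv, alpha, vertical, r)
        if au == av:
            if av:
                # fully active step, lagged input at interval end
                nmp = ad11 * mp + ad12 * mv + td11 * vpp + td12 * vpv
                nmv = ad21 * mp + ad22 * mv + td21 * vpp + td22 * vpv
                c11 = (ad11 * ad11 * p11 + 2.0 * ad11 * ad12 * p12
                       + ad12 * ad12 * p22
                       + td11 * td11 * p11 + 2.0 * td11 * td12 * p12
                       + td12 * td12 * p22 + qd11)
                c12 = (ad11 * ad21 * p11
                       + (ad11 * ad22 + ad12 * ad21) * p12
                       + ad12 * ad22 * p22
                       + td11 * td21 * p11
                       + (td11 * td22 + td12 * td21) * p12
                       + td12 * td22 * p22 + qd12)
                c22 = (ad21 * ad21 * p11 + 2.0 * ad21 * ad22 * p12
                       + ad22 * ad22 * p22
                       + td21 * td21 * p11 + 2.0 * td21 * td22 * p12
                       + td22 * td22 * p22 + qd22)
            else:
                nmp = ad11 * mp + ad12 * mv
                nmv = ad21 * mp + ad22 * mv
                c11 = (ad11 * ad11 * p11 + 2.0 * ad11 * ad12 * p12
                       + ad12 * ad12 * p22 + qd11)
                c12 = (ad11 * ad21 * p11
                       + (ad11 * ad22 + ad12 * ad21) * p12
                       + ad12 * ad22 * p22 + qd12)
                c22 = (ad21 * ad21 * p11 + 2.0 * ad21 * ad22 * p12
                       + ad22 * ad22 * p22 + qd22)
            mp, mv, p11, p12, p22 = nmp, nmv, c11, c12, c22
            continue
        # threshold traversal inside the interval: two-step prediction
        ntrav += 1
        off = au
        cp, cv, dtm = crossing_scalar(upp, upv, vpp, vpv, alpha, vertical,
                                      r, dt, off)
        dtp = dt - dtm
        (b11, b12, b21, b22,
         e11, e12, e21, e22,
         r11, r12, r22) = discretize_scalar(a21, a22, at21, at22, q, dtm)
        (f11, f12, f21, f22,
         h11, h12, h21, h22,
         s11, s12, s22) = discretize_scalar(a21, a22, at21, at22, q, dtp)
        if off:
            # active over dt-, lagged input u; then passive over dt+
            m1p = b11 * mp + b12 * mv + e11 * upp + e12 * upv
            m1v = b21 * mp + b22 * mv + e21 * upp + e22 * upv
            c11 = (b11 * b11 * p11 + 2.0 * b11 * b12 * p12
                   + b12 * b12 * p22
                   + e11 * e11 * p11 + 2.0 * e11 * e12 * p12
                   + e12 * e12 * p22 + r11)
            c12 = (b11 * b21 * p11 + (b11 * b22 + b12 * b21) * p12
                   + b12 * b22 * p22
                   + e11 * e21 * p11 + (e11 * e22 + e12 * e21) * p12
                   + e12 * e22 * p22 + r12)
            c22 = (b21 * b21 * p11 + 2.0 * b21 * b22 * p12
                   + b22 * b22 * p22
                   + e21 * e21 * p11 + 2.0 * e21 * e22 * p12
                   + e22 * e22 * p22 + r22)
            nmp = f11 * m1p + f12 * m1v
            nmv = f21 * m1p + f22 * m1v
            d11 = (f11 * f11 * c11 + 2.0 * f11 * f12 * c12
                   + f12 * f12 * c22 + s11)
            d12 = (f11 * f21 * c11 + (f11 * f22 + f12 * f21) * c12
                   + f12 * f22 * c22 + s12)
            d22 = (f21 * f21 * c11 + 2.0 * f21 * f22 * c12
                   + f22 * f22 * c22 + s22)
        else:
            # passive over dt-, then active over dt+ with the crossing
            # point as lagged input
            m1p = b11 * mp + b12 * mv
            m1v = b21 * mp + b22 * mv
            c11 = (b11 * b11 * p11 + 2.0 * b11 * b12 * p12
                   + b12 * b12 * p22 + r11)
            c12 = (b11 * b21 * p11 + (b11 * b22 + b12 * b21) * p12
                   + b12 * b22 * p22 + r12)
            c22 = (b21 * b21 * p11 + 2.0 * b21 * b22 * p12
                   + b22 * b22 * p22 + r22)
            nmp = f11 * m1p + f12 * m1v + h11 * cp + h12 * cv
            nmv = f21 * m1p + f22 * m1v + h21 * cp + h22 * cv
            d11 = (f11 * f11 * c11 + 2.0 * f11 * f12 * c12
                   + f12 * f12 * c22
                   + h11 * h11 * c11 + 2.0 * h11 * h12 * c12
                   + h12 * h12 * c22 + s11)
            d12 = (f11 * f21 * c11 + (f11 * f22 + f12 * f21) * c12
                   + f12 * f22 * c22
                   + h11 * h21 * c11 + (h11 * h22 + h12 * h21) * c12
                   + h12 * h22 * c22 + s12)
            d22 = (f21 * f21 * c11 + 2.0 * f21 * f22 * c12
                   + f22 * f22 * c22
                   + h21 * h21 * c11 + 2.0 * h21 * h22 * c12
                   + h22 * h22 * c22 + s22)
        mp, mv, p11, p12, p22 = nmp, nmv, d11, d12, d22
    if not np.isfinite(m2):
        return DIVERGED, ntrav
    return m2, ntrav


@njit(cache=True)
def simulate_kernel(noise, fine_dt, a21, a22, at21, at22, sigma, alpha,
                    vertical, r, lagsteps, x0, xd0, pos, vel):
    """Euler-Maruyama integration of the delayed switching pendulum.

    ``pos`` and ``vel`` are pre-allocated arrays of length ``len(noise)+1``.
    The delay buffer is the trajectory itself; the pre-history before one
    lag interval holds the initial state constant.  Returns -1, or the
    step index at which the state blew up (> 1e8).
    """
    n = noise.shape[0]
    pos[0] = x0
    vel[0] = xd0
    sq = np.sqrt(fine_dt)
    for i in range(n):
        j = i - lagsteps
        if j >= 0:
            lp = pos[j]
            lv = vel[j]
        else:
            lp = x0
            lv = xd0
        acc = a21 * pos[i] + a22 * vel[i]
        if is_active_scalar(lp, lv, alpha, vertical, r):
            acc += at21 * lp + at22 * lv
        vel[i + 1] = vel[i] + acc * fine_dt + sigma * sq * noise[i]
        pos[i + 1] = pos[i] + vel[i] * fine_dt
        if abs(pos[i + 1]) > 1e8:
            return i + 1
    return -1
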