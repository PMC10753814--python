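"""Numba hot path: matrix elements, table sampling, pgen, and the spawn/death
sweep of the FCIQMC iteration.

Determinants are int64 bit masks (least-significant bit = spin–orbital 0,
spatial orbital ``p >> 1``, spin ``p & 1``).  All sampling semantics here are
exhaustively cross-checked against the pure-Python reference implementations
in :mod:`pchbmc.determinants` and the path-enumeration oracle in
:mod:`pchbmc.oracle` by the test suite.

Scheme method codes: 0 = unif, 1 = fast (unconstrained, discard invalid),
2 = full (occupancy-constrained, renormalized).
"""

import numpy as np
from numba import njit

UNIF, FAST, FULL = 0, 1, 2

_TINY = 1e-14


# ---------------------------------------------------------------------------
# bit utilities
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _occupied(det, p):
    return (det >> p) & 1


@njit(cache=True)
def _occ_fill(det, n, out):
    cnt = 0
    for p in range(n):
        if (det >> p) & 1:
            out[cnt] = p
            cnt += 1
    return cnt


@njit(cache=True)
def _count_spin(occ, nocc, sigma):
    c = 0
    for t in range(nocc):
        if occ[t] & 1 == sigma:
            c += 1
    return c


@njit(cache=True)
def _nth_empty_spin(det, n, sigma, m):
    for p in range(sigma, n, 2):
        if not (det >> p) & 1:
            if m == 0:
                return p
            m -= 1
    return -1


@njit(cache=True)
def _nth_empty_any(det, n, m):
    for p in range(n):
        if not (det >> p) & 1:
            if m == 0:
                return p
            m -= 1
    return -1


@njit(cache=True)
def _gamma(det, a, i):
    """(-1)^n with n = occupied spin-orbitals strictly between a and i."""
    lo, hi = (a, i) if a < i else (i, a)
    sign = 1
    for p in range(lo + 1, hi):
        if (det >> p) & 1:
            sign = -sign
    return sign


# ---------------------------------------------------------------------------
# matrix elements (Slater-Condon + spin-exchange S^2 part)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _diag_el(det, n, h, g, e_nuc, occ, nocc):
    e = e_nuc
    for t in range(nocc):
        p = occ[t] >> 1
        e += h[p, p]
    for t in range(nocc):
        pt = occ[t] >> 1
        st = occ[t] & 1
        for u in range(t):
            pu = occ[u] >> 1
            e += g[pt, pt, pu, pu]
            if st == occ[u] & 1:
                e -= g[pt, pu, pu, pt]
    return e


@njit(cache=True)
def _single_el(det, h, g, i, a, occ, nocc):
    """Signed <D(a<-i)|H|D>; caller guarantees same spin, i occupied, a empty."""
    pi = i >> 1
    pa = a >> 1
    si = i & 1
    val = h[pa, pi]
    for t in range(nocc):
        r = occ[t]
        if r == i:
            continue
        pr = r >> 1
        val += g[pa, pi, pr, pr]
        if r & 1 == si:
            val -= g[pa, pr, pr, pi]
    return _gamma(det, a, i) * val


@njit(cache=True)
def _double_phase(det, i, j, a, b):
    """Composite phase: transposition i->a on det, then j->b on the result."""
    sign = _gamma(det, a, i)
    mid = (det & ~(np.int64(1) << i)) | (np.int64(1) << a)
    sign *= _gamma(mid, b, j)
    return sign


@njit(cache=True)
def _double_el(det, g, i, j, a, b):
    """Signed <D(ab<-ij)|H|D> with i<j, a<b canonical."""
    if i > j:
        i, j = j, i
    if a > b:
        a, b = b, a
    val = 0.0
    if (a & 1) == (i & 1) and (b & 1) == (j & 1):
        val += g[a >> 1, i >> 1, b >> 1, j >> 1]
    if (a & 1) == (j & 1) and (b & 1) == (i & 1):
        val -= g[a >> 1, j >> 1, b >> 1, i >> 1]
    if val == 0.0:
        return 0.0
    return _double_phase(det, i, j, a, b) * val


@njit(cache=True)
def _s2_diag(det, n):
    """S_z(S_z-1) + (open-shell alpha count)."""
    na = 0
    nb = 0
    nos = 0
    for p in range(0, n, 2):
        oa = (det >> p) & 1
        ob = (det >> (p + 1)) & 1
        na += oa
        nb += ob
        if oa == 1 and ob == 0:
            nos += 1
    sz = 0.5 * (na - nb)
    return sz * (sz - 1.0) + nos


@njit(cache=True)
def _apply_op(det, create, p):
    """Second-quantized operator application; returns (det, sign), sign 0 if killed."""
    bit = np.int64(1) << p
    below = 0
    for q in range(p):
        if (det >> q) & 1:
            below += 1
    if create:
        if det & bit:
            return det, 0
        det |= bit
    else:
        if not det & bit:
            return det, 0
        det &= ~bit
    return det, (-1 if below & 1 else 1)


@njit(cache=True)
def _s2_exchange_el(det, i, j, a, b):
    """<D(ab<-ij)|S^2|D> — nonzero only for spin-exchange doubles."""
    if i > j:
        i, j = j, i
    if a > b:
        a, b = b, a
    pi, pj = i >> 1, j >> 1
    pa, pb = a >> 1, b >> 1
    si, sj = i & 1, j & 1
    sa, sb = a & 1, b & 1
    if pi == pj:
        return 0.0
    ok = (pa == pi and sa != si and pb == pj and sb != sj) or (
        pa == pj and sa != sj and pb == pi and sb != si
    )
    if not ok or si == sj:
        return 0.0
    # identify the spatial orbital flipping beta->alpha ("u") and alpha->beta ("v")
    if si == 1:
        u, v = pi, pj
    else:
        u, v = pj, pi
    # apply a+_{u alpha} a_{u beta} a+_{v beta} a_{v alpha} right-to-left
    d = det
    sign = 1
    d, s = _apply_op(d, False, 2 * v)
    if s == 0:
        return 0.0
    sign *= s
    d, s = _apply_op(d, True, 2 * v + 1)
    if s == 0:
        return 0.0
    sign *= s
    d, s = _apply_op(d, False, 2 * u + 1)
    if s == 0:
        return 0.0
    sign *= s
    d, s = _apply_op(d, True, 2 * u)
    if s == 0:
        return 0.0
    sign *= s
    return float(sign)


# ---------------------------------------------------------------------------
# alias + constrained draws
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _alias_draw(probs, cutoff, alias, off, n, rng):
    u = rng.random() * n
    k = int(u)
    if k >= n:
        k = n - 1
    if u - k < cutoff[off + k]:
        return k
    return alias[off + k]


@njit(cache=True)
def _mass_on_occ(probs, off, occ, nocc):
    s = 0.0
    for t in range(nocc):
        s += probs[off + occ[t]]
    return s


@njit(cache=True)
def _draw_restricted_occ(probs, off, occ, nocc, mass, rng):
    target = rng.random() * mass
    acc = 0.0
    last = -1
    for t in range(nocc):
        p = probs[off + occ[t]]
        if p > 0.0:
            acc += p
            last = occ[t]
            if acc >= target:
                return last
    return last


@njit(cache=True)
def _draw_restricted_empty(det, probs, off, n, mass, rng):
    target = rng.random() * mass
    acc = 0.0
    last = -1
    for k in range(n):
        if not (det >> k) & 1:
            p = probs[off + k]
            if p > 0.0:
                acc += p
                last = k
                if acc >= target:
                    return last
    return last


@njit(cache=True)
def _constrained_occ(det, probs, cutoff, alias, off, n, occ, nocc, mass,
                     thr, cap, rng):
    if mass >= thr:
        for _ in range(cap):
            k = _alias_draw(probs, cutoff, alias, off, n, rng)
            if (det >> k) & 1:
                return k
    return _draw_restricted_occ(probs, off, occ, nocc, mass, rng)


@njit(cache=True)
def _constrained_empty(det, probs, cutoff, alias, off, n, mass, thr, cap, rng):
    if mass >= thr:
        for _ in range(cap):
            k = _alias_draw(probs, cutoff, alias, off, n, rng)
            if not (det >> k) & 1:
                return k
    return _draw_restricted_empty(det, probs, off, n, mass, rng)


# ---------------------------------------------------------------------------
# single excitation sampling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sample_single_impl(det, n, si, sa, s1p, s1c, s1a, s1ok,
                        s2p, s2c, s2a, s2ok, thr, cap, rng, occ, nocc):
    nsp = n // 2
    # --- particle I ---
    if si == UNIF:
        i = occ[int(rng.random() * nocc) % nocc]
        p_i = 1.0 / nocc
    elif si == FAST:
        if s1ok == 0:
            return -1, -1, 0, 1.0
        i = _alias_draw(s1p, s1c, s1a, 0, n, rng)
        p_i = s1p[i]
        if not (det >> i) & 1:
            return i, -1, 0, p_i
    else:
        mass = _mass_on_occ(s1p, 0, occ, nocc)
        if mass <= _TINY:
            return -1, -1, 0, 1.0
        i = _constrained_occ(det, s1p, s1c, s1a, 0, n, occ, nocc, mass,
                             thr, cap, rng)
        p_i = s1p[i] / mass
    # --- hole A (same spin as I) ---
    sg = i & 1
    n_emp = nsp - _count_spin(occ, nocc, sg)
    off = i * n
    if sa == UNIF:
        if n_emp == 0:
            return i, -1, 0, p_i
        a = _nth_empty_spin(det, n, sg, int(rng.random() * n_emp) % n_emp)
        p_a = 1.0 / n_emp
    elif sa == FAST:
        if s2ok[i] == 0:
            return i, -1, 0, p_i
        a = _alias_draw(s2p, s2c, s2a, off, n, rng)
        p_a = s2p[off + a]
        if (det >> a) & 1:
            return i, a, 0, p_i * p_a
    else:
        if s2ok[i] == 0:
            return i, -1, 0, p_i
        mass = 1.0 - _mass_on_occ(s2p, off, occ, nocc)
        if mass <= _TINY:
            return i, -1, 0, p_i
        a = _constrained_empty(det, s2p, s2c, s2a, off, n, mass, thr, cap, rng)
        p_a = s2p[off + a] / mass
    return i, a, 1, p_i * p_a


@njit(cache=True)
def sample_single_once(det, n, si, sa, s1p, s1c, s1a, s1ok,
                       s2p, s2c, s2a, s2ok, thr, cap, rng):
    occ = np.empty(64, dtype=np.int64)
    nocc = _occ_fill(det, n, occ)
    return _sample_single_impl(det, n, si, sa, s1p, s1c, s1a, s1ok,
                               s2p, s2c, s2a, s2ok, thr, cap, rng, occ, nocc)


@njit(cache=True)
def pgen_single(det, n, si, sa, s1p, s2p, i, a, occ, nocc):
    """Exact generation probability of the (already valid) single a<-i."""
    nsp = n // 2
    if si == UNIF:
        p_i = 1.0 / nocc
    elif si == FAST:
        p_i = s1p[i]
    else:
        p_i = s1p[i] / _mass_on_occ(s1p, 0, occ, nocc)
    sg = i & 1
    off = i * n
    if sa == UNIF:
        n_emp = nsp - _count_spin(occ, nocc, sg)
        p_a = 1.0 / n_emp
    elif sa == FAST:
        p_a = s2p[off + a]
    else:
        p_a = s2p[off + a] / (1.0 - _mass_on_occ(s2p, off, occ, nocc))
    return p_i * p_a


# ---------------------------------------------------------------------------
# double excitation sampling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _uniform_hole_counts(occ, nocc, n, si_spin, sj_spin):
    """(count for first hole, spin restriction flag) under uniform selection."""
    nsp = n // 2
    nea = nsp - _count_spin(occ, nocc, 0)
    neb = nsp - _count_spin(occ, nocc, 1)
    if si_spin == sj_spin:
        return (nea if si_spin == 0 else neb), nea, neb
    return nea + neb, nea, neb


@njit(cache=True)
def _sample_double_impl(det, n, di, dj, da, db,
                        d1p, d1c, d1a, d1ok,
                        d2p, d2c, d2a, d2ok,
                        d3p, d3c, d3a, d3ok,
                        d4p, d4c, d4a, d4ok,
                        thr, cap, rng, occ, nocc):
    # --- first particle I ---
    if di == UNIF:
        i = occ[int(rng.random() * nocc) % nocc]
        p_path = 1.0 / nocc
    elif di == FAST:
        if d1ok == 0:
            return -1, -1, -1, -1, 0, 1.0
        i = _alias_draw(d1p, d1c, d1a, 0, n, rng)
        p_path = d1p[i]
        if not (det >> i) & 1:
            return i, -1, -1, -1, 0, p_path
    else:
        mass1 = _mass_on_occ(d1p, 0, occ, nocc)
        if mass1 <= _TINY:
            return -1, -1, -1, -1, 0, 1.0
        i = _constrained_occ(det, d1p, d1c, d1a, 0, n, occ, nocc, mass1,
                             thr, cap, rng)
        p_path = d1p[i] / mass1
    # --- second particle J ---
    off2 = i * n
    if dj == UNIF:
        if nocc < 2:
            return i, -1, -1, -1, 0, p_path
        m = int(rng.random() * (nocc - 1)) % (nocc - 1)
        # m-th occupied spin-orbital, skipping i
        cnt = 0
        j = -1
        for t in range(nocc):
            if occ[t] != i:
                if cnt == m:
                    j = occ[t]
                    break
                cnt += 1
        p_path /= (nocc - 1)
    elif dj == FAST:
        if d2ok[i] == 0:
            return i, -1, -1, -1, 0, p_path
        j = _alias_draw(d2p, d2c, d2a, off2, n, rng)
        p_path *= d2p[off2 + j]
        if not (det >> j) & 1:
            return i, j, -1, -1, 0, p_path
    else:
        if d2ok[i] == 0:
            return i, -1, -1, -1, 0, p_path
        mass2 = _mass_on_occ(d2p, off2, occ, nocc)
        if mass2 <= _TINY:
            return i, -1, -1, -1, 0, p_path
        j = _constrained_occ(det, d2p, d2c, d2a, off2, n, occ, nocc, mass2,
                             thr, cap, rng)
        p_path *= d2p[off2 + j] / mass2
    # --- first hole A ---
    si_spin = i & 1
    sj_spin = j & 1
    off3 = (i * n + j) * n
    if da == UNIF:
        cA, nea, neb = _uniform_hole_counts(occ, nocc, n, si_spin, sj_spin)
        if cA == 0:
            return i, j, -1, -1, 0, p_path
        m = int(rng.random() * cA) % cA
        if si_spin == sj_spin:
            a = _nth_empty_spin(det, n, si_spin, m)
        else:
            a = _nth_empty_any(det, n, m)
        p_path /= cA
    elif da == FAST:
        if d3ok[i * n + j] == 0:
            return i, j, -1, -1, 0, p_path
        a = _alias_draw(d3p, d3c, d3a, off3, n, rng)
        p_path *= d3p[off3 + a]
        if (det >> a) & 1:
            return i, j, a, -1, 0, p_path
    else:
        if d3ok[i * n + j] == 0:
            return i, j, -1, -1, 0, p_path
        mass3 = 1.0 - _mass_on_occ(d3p, off3, occ, nocc)
        if mass3 <= _TINY:
            return i, j, -1, -1, 0, p_path
        a = _constrained_empty(det, d3p, d3c, d3a, off3, n, mass3, thr, cap, rng)
        p_path *= d3p[off3 + a] / mass3
    # --- second hole B ---
    off4 = ((i * n + j) * n + a) * n
    if db == UNIF:
        nsp = n // 2
        if si_spin == sj_spin:
            sb = si_spin
            cB = (nsp - _count_spin(occ, nocc, sb)) - 1
        else:
            sb = 1 - (a & 1)
            cB = nsp - _count_spin(occ, nocc, sb)
        if cB <= 0:
            return i, j, a, -1, 0, p_path
        m = int(rng.random() * cB) % cB
        # m-th empty of spin sb, skipping a
        b = -1
        cnt = 0
        for p in range(sb, n, 2):
            if p != a and not (det >> p) & 1:
                if cnt == m:
                    b = p
                    break
                cnt += 1
        p_path /= cB
    elif db == FAST:
        if d4ok[(i * n + j) * n + a] == 0:
            return i, j, a, -1, 0, p_path
        b = _alias_draw(d4p, d4c, d4a, off4, n, rng)
        p_path *= d4p[off4 + b]
        if (det >> b) & 1:
            return i, j, a, b, 0, p_path
    else:
        if d4ok[(i * n + j) * n + a] == 0:
            return i, j, a, -1, 0, p_path
        mass4 = 1.0 - _mass_on_occ(d4p, off4, occ, nocc)
        if mass4 <= _TINY:
            return i, j, a, -1, 0, p_path
        b = _constrained_empty(det, d4p, d4c, d4a, off4, n, mass4, thr, cap, rng)
        p_path *= d4p[off4 + b] / mass4
    pg = pgen_double(det, n, di, dj, da, db, d1p, d2p, d3p, d4p,
                     i, j, a, b, occ, nocc)
    return i, j, a, b, 1, pg


@njit(cache=True)
def sample_double_once(det, n, di, dj, da, db,
                       d1p, d1c, d1a, d1ok,
                       d2p, d2c, d2a, d2ok,
                       d3p, d3c, d3a, d3ok,
                       d4p, d4c, d4a, d4ok,
                       thr, cap, rng):
    occ = np.empty(64, dtype=np.int64)
    nocc = _occ_fill(det, n, occ)
    return _sample_double_impl(det, n, di, dj, da, db,
                               d1p, d1c, d1a, d1ok, d2p, d2c, d2a, d2ok,
                               d3p, d3c, d3a, d3ok, d4p, d4c, d4a, d4ok,
                               thr, cap, rng, occ, nocc)


@njit(cache=True)
def pgen_double(det, n, di, dj, da, db, d1p, d2p, d3p, d4p,
                i, j, a, b, occ, nocc):
    """Total generation probability of the target reached by ab<-ij: sums the
    two particle orders and the two hole orders (p(I|J) != p(J|I) in general,
    so each path uses its own conditional, renormalized where constrained)."""
    # particle factor
    if di == FULL:
        mass1 = _mass_on_occ(d1p, 0, occ, nocc)
    else:
        mass1 = 1.0
    pp = 0.0
    for order in range(2):
        x, y = (i, j) if order == 0 else (j, i)
        if di == UNIF:
            px = 1.0 / nocc
        elif di == FAST:
            px = d1p[x]
        else:
            px = d1p[x] / mass1
        if dj == UNIF:
            py = 1.0 / (nocc - 1)
        elif dj == FAST:
            py = d2p[x * n + y]
        else:
            py = d2p[x * n + y] / _mass_on_occ(d2p, x * n, occ, nocc)
        pp += px * py
    # hole factor (rows for (i,j) and (j,i) are identical by W symmetry)
    off3 = (i * n + j) * n
    si_spin = i & 1
    sj_spin = j & 1
    nsp = n // 2
    if da == FULL:
        mass3 = 1.0 - _mass_on_occ(d3p, off3, occ, nocc)
    else:
        mass3 = 1.0
    ph = 0.0
    for order in range(2):
        u, v = (a, b) if order == 0 else (b, a)
        if da == UNIF:
            if si_spin == sj_spin:
                cA = nsp - _count_spin(occ, nocc, si_spin)
            else:
                cA = 2 * nsp - nocc
            pu = 1.0 / cA
        elif da == FAST:
            pu = d3p[off3 + u]
        else:
            pu = d3p[off3 + u] / mass3
        off4 = ((i * n + j) * n + u) * n
        if db == UNIF:
            if si_spin == sj_spin:
                cB = (nsp - _count_spin(occ, nocc, si_spin)) - 1
            else:
                sbv = 1 - (u & 1)
                cB = nsp - _count_spin(occ, nocc, sbv)
            pv = 1.0 / cB
        elif db == FAST:
            pv = d4p[off4 + v]
        else:
            pv = d4p[off4 + v] / (1.0 - _mass_on_occ(d4p, off4, occ, nocc))
        ph += pu * pv
    return pp * ph


# ---------------------------------------------------------------------------
# batch draws (for audits and goodness-of-fit tests)
# ---------------------------------------------------------------------------

@njit(cache=True)
def sample_single_batch(det, n, si, sa, s1p, s1c, s1a, s1ok,
                        s2p, s2c, s2a, s2ok, thr, cap, n_draws, rng):
    out = np.empty((n_draws, 3), dtype=np.int64)
    pg = np.empty(n_draws)
    occ = np.empty(64, dtype=np.int64)
    nocc = _occ_fill(det, n, occ)
    for k in range(n_draws):
        i, a, st, p = _sample_single_impl(det, n, si, sa, s1p, s1c, s1a, s1ok,
                                          s2p, s2c, s2a, s2ok, thr, cap, rng,
                                          occ, nocc)
        out[k, 0] = i
        out[k, 1] = a
        out[k, 2] = st
        pg[k] = p
    return out, pg


@njit(cache=True)
def sample_double_batch(det, n, di, dj, da, db,
                        d1p, d1c, d1a, d1ok,
                        d2p, d2c, d2a, d2ok,
                        d3p, d3c, d3a, d3ok,
                        d4p, d4c, d4a, d4ok,
                        thr, cap, n_draws, rng):
    out = np.empty((n_draws, 5), dtype=np.int64)
    pg = np.empty(n_draws)
    occ = np.empty(64, dtype=np.int64)
    nocc = _occ_fill(det, n, occ)
    for k in range(n_draws):
        i, j, a, b, st, p = _sample_double_impl(
            det, n, di, dj, da, db,
            d1p, d1c, d1a, d1ok, d2p, d2c, d2a, d2ok,
            d3p, d3c, d3a, d3ok, d4p, d4c, d4a, d4ok,
            thr, cap, rng, occ, nocc)
        out[k, 0] = i
        out[k, 1] = j
        out[k, 2] = a
        out[k, 3] = b
        out[k, 4] = st
        pg[k] = p
    return out, pg


# ---------------------------------------------------------------------------
# FCIQMC spawn/death sweep
# ---------------------------------------------------------------------------

@njit(cache=True)
def _is_occupied_det(sorted_dets, det):
    lo = np.searchsorted(sorted_dets, det)
    return lo < sorted_dets.size and sorted_dets[lo] == det


@njit(cache=True)
def spawn_batch(dets, amps, sorted_dets, n, h, g, e_nuc, jpen, s2_shift,
                eref, shift, dtau, p1, n_add,
                si, sa, di, dj, da, db,
                s1p, s1c, s1a, s1ok, s2p, s2c, s2a, s2ok,
                d1p, d1c, d1a, d1ok, d2p, d2c, d2a, d2ok,
                d3p, d3c, d3a, d3ok, d4p, d4c, d4a, d4ok,
                thr, cap, rng):
    """One spawn + death sweep over a walker batch.

    Returns (post-death amplitudes, spawned determinants, spawned signed
    amplitudes, stats).  stats = [attempts_1, valid_1, attempts_2, valid_2,
    max |H|/pgen singles, max |H|/pgen doubles, initiator-discarded spawns,
    max |H_ii - E_ref|].  Annihilation (merging) is done by the caller.
    """
    nw = dets.size
    new_amps = np.empty(nw)
    tot_att = 0
    for w in range(nw):
        a_ = abs(amps[w])
        tot_att += int(np.ceil(a_)) if a_ > 0 else 0
    sp_dets = np.empty(tot_att, dtype=np.int64)
    sp_amps = np.empty(tot_att)
    nsp_cnt = 0
    stats = np.zeros(8)
    occ = np.empty(64, dtype=np.int64)
    p2 = 1.0 - p1
    for w in range(nw):
        det = dets[w]
        amp = amps[w]
        nocc = _occ_fill(det, n, occ)
        absamp = abs(amp)
        natt = int(np.ceil(absamp))
        w_att = absamp / natt if natt > 0 else 0.0
        is_init = absamp > n_add
        for _t in range(natt):
            single = rng.random() < p1
            if single:
                stats[0] += 1
                i, a, st, pgen = _sample_single_impl(
                    det, n, si, sa, s1p, s1c, s1a, s1ok,
                    s2p, s2c, s2a, s2ok, thr, cap, rng, occ, nocc)
                if st == 0:
                    continue
                stats[1] += 1
                hel = _single_el(det, h, g, i, a, occ, nocc)
                child = (det & ~(np.int64(1) << i)) | (np.int64(1) << a)
                pn = p1
                cls = 0
            else:
                stats[2] += 1
                i, j, a, b, st, pgen = _sample_double_impl(
                    det, n, di, dj, da, db,
                    d1p, d1c, d1a, d1ok, d2p, d2c, d2a, d2ok,
                    d3p, d3c, d3a, d3ok, d4p, d4c, d4a, d4ok,
                    thr, cap, rng, occ, nocc)
                if st == 0:
                    continue
                stats[3] += 1
                hel = _double_el(det, g, i, j, a, b)
                if jpen != 0.0:
                    hel += jpen * _s2_exchange_el(det, i, j, a, b)
                child = (det & ~(np.int64(1) << i) & ~(np.int64(1) << j)) \
                    | (np.int64(1) << a) | (np.int64(1) << b)
                pn = p2
                cls = 1
            if hel == 0.0:
                continue
            ratio = abs(hel) / pgen
            if cls == 0:
                if ratio > stats[4]:
                    stats[4] = ratio
            else:
                if ratio > stats[5]:
                    stats[5] = ratio
            pspawn = dtau * w_att * abs(hel) / (pn * pgen)
            if pspawn < 1.0:
                if rng.random() >= pspawn:
                    continue
                mag = 1.0
            else:
                mag = pspawn
            if not is_init and not _is_occupied_det(sorted_dets, child):
                stats[6] += 1
                continue
            sgn = -1.0 if (hel > 0.0) == (amp > 0.0) else 1.0
            sp_dets[nsp_cnt] = child
            sp_amps[nsp_cnt] = sgn * mag
            nsp_cnt += 1
        hdiag = _diag_el(det, n, h, g, e_nuc, occ, nocc)
        if jpen != 0.0:
            hdiag += jpen * (_s2_diag(det, n) - s2_shift)
        if abs(hdiag - eref) > stats[7]:
            stats[7] = abs(hdiag - eref)
        new_amps[w] = amp * (1.0 - dtau * (hdiag - eref - shift))
    return new_amps, sp_dets[:nsp_cnt], sp_amps[:nsp_cnt], stats
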