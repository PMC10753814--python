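"""Slater determinants as bit masks, Slater–Condon matrix elements, and Ŝ².

A determinant is a plain Python ``int`` bit mask over spin–orbitals
(little-endian: spin–orbital 0 is the least significant bit).  Spin–orbital
``P`` maps to spatial orbital ``P >> 1`` with spin ``P & 1`` (0 = alpha,
1 = beta) — the interleaved convention of :mod:`pchbmc.integrals`.

The functions here are the readable reference implementation; the numba kernel
in :mod:`pchbmc._kernel` re-implements the hot subset and is cross-checked
against this module exhaustively in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import IntegralTable

__all__ = [
    "Excitation",
    "det_from_occ",
    "occ_tuple",
    "det_string",
    "gamma_sign",
    "apply_excitation",
    "excitation_between",
    "enumerate_connected",
    "slater_condon",
    "diagonal_element",
    "s2_matrix_element",
]


def spatial(p: int) -> int:
    return p >> 1

def spin(p: int) -> int:
    return p & 1


@dataclass(frozen=True)
class Excitation:
    """A single (``A <- I``) or double (``AB <- IJ``) orbital replacement.

    ``particles`` are spin–orbitals occupied in the source determinant,
    ``holes`` are empty ones; both are stored in canonical ascending order
    (``I < J``, ``A < B``).  Particles and holes are pairwise disjoint.  Single
    excitations conserve spin; doubles conserve total S_z.
    """

    particles: tuple[int, ...]
    holes: tuple[int, ...]

    def __post_init__(self):
        ps, hs = self.particles, self.holes
        if len(ps) not in (1, 2) or len(ps) != len(hs):
            raise ValueError("excitation must have 1 or 2 particle/hole pairs")
        if len(set(ps)) != len(ps) or len(set(hs)) != len(hs) or set(ps) & set(hs):
            raise ValueError("particle/hole indices must be pairwise distinct")
        if sorted(ps) != list(ps) or sorted(hs) != list(hs):
            raise ValueError("indices must be in canonical ascending order")
        if len(ps) == 1:
            if spin(ps[0]) != spin(hs[0]):
                raise ValueError("single excitations must conserve spin")
        else:
            if sum(spin(p) for p in ps) != sum(spin(h) for h in hs):
                raise ValueError("double excitations must conserve S_z")

    @property
    def kind(self) -> str:
        return "single" if len(self.particles) == 1 else "double"


def det_from_occ(occ) -> int:
    """Bit mask from an iterable of occupied spin–orbital indices."""
    mask = 0
    for p in occ:
        if p < 0:
            raise ValueError("negative spin-orbital index")
        bit = 1 << p
        if mask & bit:
            raise ValueError(f"spin-orbital {p} occupied twice")
        mask |= bit
    return mask


def occ_tuple(det: int) -> tuple[int, ...]:
    """Occupied spin–orbital indices in increasing order."""
    out = []
    p = 0
    while det:
        if det & 1:
            out.append(p)
        det >>= 1
        p += 1
    return tuple(out)


def det_string(det: int, n_spatial: int) -> str:
    """Render as an occupation string |2,u,d,0,...> for logs."""
    sym = []
    for i in range(n_spatial):
        a = bool(det & (1 << (2 * i)))
        b = bool(det & (1 << (2 * i + 1)))
        sym.append({(True, True): "2", (True, False): "u",
                    (False, True): "d", (False, False): "0"}[(a, b)])
    return "|" + ",".join(sym) + ">"


def gamma_sign(det: int, a: int, i: int) -> int:
    """Fermionic phase (-1)^n for the replacement ``a <- i`` on ``det``.

    ``n`` counts occupied spin–orbitals strictly between ``min(a, i)`` and
    ``max(a, i)`` in the source determinant, excluding ``a`` and ``i``.
    """
    lo, hi = (a, i) if a < i else (i, a)
    mask = ((1 << hi) - 1) & ~((1 << (lo + 1)) - 1)
    n = (det & mask).bit_count()
    return -1 if n & 1 else 1


def apply_excitation(det: int, exc: Excitation) -> int:
    for p in exc.particles:
        if not det & (1 << p):
            raise ValueError(f"particle {p} not occupied in determinant")
        det &= ~(1 << p)
    for h in exc.holes:
        if det & (1 << h):
            raise ValueError(f"hole {h} already occupied in determinant")
        det |= 1 << h
    return det


def excitation_between(det_i: int, det_j: int) -> Excitation | None:
    """The excitation mapping ``det_i`` to ``det_j``; None if they differ in
    more than two spin–orbitals (or are identical)."""
    diff = det_i ^ det_j
    particles = occ_tuple(det_i & diff)
    holes = occ_tuple(det_j & diff)
    if len(particles) != len(holes) or not 1 <= len(particles) <= 2:
        return None
    return Excitation(particles=particles, holes=holes)


def _phase(det: int, exc: Excitation) -> int:
    """Composite Fermionic phase via sequential single-style transpositions:
    first I -> A on the source, then J -> B on the intermediate."""
    i, a = exc.particles[0], exc.holes[0]
    sign = gamma_sign(det, a, i)
    if exc.kind == "double":
        mid = (det & ~(1 << i)) | (1 << a)
        j, b = exc.particles[1], exc.holes[1]
        sign *= gamma_sign(mid, b, j)
    return sign


def diagonal_element(det: int, integrals: IntegralTable) -> float:
    """<D|H|D>: one-electron sum plus Coulomb-minus-exchange pair sums + E_nuc."""
    h, g = integrals.h, integrals.g
    occ = occ_tuple(det)
    e = integrals.e_nuc
    for p in occ:
        e += h[spatial(p), spatial(p)]
    for k, p in enumerate(occ):
        for q in occ[:k]:
            e += g[spatial(p), spatial(p), spatial(q), spatial(q)]
            if spin(p) == spin(q):
                e -= g[spatial(p), spatial(q), spatial(q), spatial(p)]
    return float(e)


def slater_condon(det: int, exc: Excitation | None, integrals: IntegralTable) -> float:
    """Signed Hamiltonian matrix element <D'|H|D> for ``D' = exc(D)``.

    ``exc=None`` gives the diagonal.  Determinant pairs differing in more than
    two spin–orbitals have a vanishing element by the Slater–Condon rules (use
    :func:`excitation_between`, which returns None for those).
    """
    if exc is None:
        return diagonal_element(det, integrals)
    for p in exc.particles:
        if not det & (1 << p):
            raise ValueError("excitation invalid for determinant: particle empty")
    for hole in exc.holes:
        if det & (1 << hole):
            raise ValueError("excitation invalid for determinant: hole occupied")
    h, g = integrals.h, integrals.g
    if exc.kind == "single":
        i, a = exc.particles[0], exc.holes[0]
        val = h[spatial(a), spatial(i)]
        for r in occ_tuple(det):
            if r == i:
                continue
            val += g[spatial(a), spatial(i), spatial(r), spatial(r)]
            if spin(r) == spin(i):
                val -= g[spatial(a), spatial(r), spatial(r), spatial(i)]
        return float(_phase(det, exc) * val)
    i, j = exc.particles
    a, b = exc.holes
    val = 0.0
    if spin(a) == spin(i) and spin(b) == spin(j):
        val += g[spatial(a), spatial(i), spatial(b), spatial(j)]
    if spin(a) == spin(j) and spin(b) == spin(i):
        val -= g[spatial(a), spatial(j), spatial(b), spatial(i)]
    return float(_phase(det, exc) * val)


def enumerate_connected(det: int, n_spin: int) -> list[Excitation]:
    """Every spin-allowed single and S_z-conserving double from ``det``,
    each exactly once in canonical order (I < J, A < B); deterministic."""
    occ = [p for p in occ_tuple(det) if p < n_spin]
    empty = [p for p in range(n_spin) if not det & (1 << p)]
    out: list[Excitation] = []
    for i in occ:
        for a in empty:
            if spin(i) == spin(a):
                out.append(Excitation(particles=(i,), holes=(a,)))
    for ii, i in enumerate(occ):
        for j in occ[ii + 1:]:
            sz = spin(i) + spin(j)
            for ai, a in enumerate(empty):
                for b in empty[ai + 1:]:
                    if spin(a) + spin(b) == sz:
                        out.append(Excitation(particles=(i, j), holes=(a, b)))
    return out


# ---------------------------------------------------------------------------
# Spin-squared operator
# ---------------------------------------------------------------------------

def _apply_ops(det: int, ops) -> tuple[int, int]:
    """Apply ``(create?, index)`` second-quantized operators right-to-left,
    returning (resulting determinant, sign); sign 0 if annihilated."""
    sign = 1
    for create, p in reversed(ops):
        bit = 1 << p
        below = (det & (bit - 1)).bit_count()
        if create:
            if det & bit:
                return 0, 0
            det |= bit
        else:
            if not det & bit:
                return 0, 0
            det &= ~bit
        if below & 1:
            sign = -sign
    return det, sign


def n_open_alpha(det: int, n_spatial: int) -> int:
    """Alpha-occupied spatial orbitals whose beta partner is empty."""
    count = 0
    for i in range(n_spatial):
        if det & (1 << (2 * i)) and not det & (1 << (2 * i + 1)):
            count += 1
    return count


def s2_matrix_element(det: int, exc: Excitation | None, n_spatial: int) -> float:
    """Matrix element of Ŝ² in the determinant basis.

    Diagonal: ``S_z(S_z - 1) + n_alpha^OS`` (equivalently
    ``S_z(S_z + 1) + n_beta^OS``), from ``Ŝ² = Ŝ₊Ŝ₋ + Ŝ_z² - Ŝ_z``.
    Off-diagonal: only spin-exchange doubles ``i_a j_b <- i_b j_a`` between two
    singly occupied spatial orbitals contribute, with unit magnitude and a
    Fermionic phase.  Single excitations never couple through Ŝ².
    """
    if exc is None:
        occ = occ_tuple(det)
        na = sum(1 for p in occ if spin(p) == 0)
        nb = len(occ) - na
        sz = (na - nb) / 2.0
        return sz * (sz - 1.0) + n_open_alpha(det, n_spatial)
    if exc.kind == "single":
        return 0.0
    (i_, j_), (a_, b_) = exc.particles, exc.holes
    # exchange type: same spatial pair, spins crossed
    pair_p = {(spatial(i_), spin(i_)), (spatial(j_), spin(j_))}
    pair_h = {(spatial(a_), 1 - spin(a_)), (spatial(b_), 1 - spin(b_))}
    if pair_p != pair_h or spatial(i_) == spatial(j_):
        return 0.0
    # the contributing S+S- term a^+_{ia} a_{ib} a^+_{jb} a_{ja}: identify which
    # spatial orbital flips beta->alpha (that is "i") and which alpha->beta ("j")
    if spin(i_) == 1:
        si, sj = spatial(i_), spatial(j_)
    else:
        si, sj = spatial(j_), spatial(i_)
    ops = [(True, 2 * si), (False, 2 * si + 1), (True, 2 * sj + 1), (False, 2 * sj)]
    new, sign = _apply_ops(det, ops)
    if sign == 0:
        return 0.0
    assert new == apply_excitation(det, exc)
    return float(sign)


def hamiltonian_element(
    det: int,
    exc: Excitation | None,
    integrals: IntegralTable,
    spin_penalty_j: float = 0.0,
    s_target: float | None = None,
) -> float:
    """Matrix element of ``H + J (Ŝ² - s(s+1))`` (plain H when ``J = 0``)."""
    val = slater_condon(det, exc, integrals)
    if spin_penalty_j != 0.0:
        val += spin_penalty_j * s2_matrix_element(det, exc, integrals.n_spatial)
        if exc is None and s_target is not None:
            val -= spin_penalty_j * s_target * (s_target + 1.0)
    return val


def spins_of_det(det: int) -> tuple[int, int]:
    """(n_alpha, n_beta) of a determinant."""
    na = nb = 0
    for p in occ_tuple(det):
        if spin(p) == 0:
            na += 1
        else:
            nb += 1
    return na, nb
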