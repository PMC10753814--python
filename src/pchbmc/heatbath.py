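"""Precomputed heat-bath (PCHB) excitation generation.

Doubles are weighted by the determinant-independent magnitude of their
two-electron matrix element, ``W_IJ^AB = |g_AIBJ - g_AJBI|`` (spin-blocked
terms zeroed); singles by the contracted bound
``S_I^A = |h_AI| + sum_R (|g_AIRR| + |g_ARRI|)`` with ``R`` over *all*
spin–orbitals, which upper-bounds the true single-excitation element for every
determinant (triangle inequality) and approximates it well in localized
orbital bases.  Both weight tensors are Hermitian: ``W_IJ^AB = W_AB^IJ`` and
``S_I^A = S_A^I``.

Each index slot (particle I, J; hole A, B) can be sampled

* ``unif``  — uniformly over the valid (occupied/empty) set, O(1);
* ``fast``  — from the unconstrained precomputed alias table, O(1), draws
  hitting an invalid orbital are discarded;
* ``full``  — from the occupancy-constrained, renormalized distribution
  (rejection redraw from the same alias table, with a direct fallback).

A scheme is written ``sI:sA/dI-dJ:dA-dB``, e.g. ``unif:full/unif-full:full-full``.

Generalized-active-space (GAS) constraints enter as supergroup-parametrized
weight tensors: any index quadruple whose particle transfer leaves the allowed
supergroup set gets weight zero before normalization.  A spin penalty
``J (S^2 - s(s+1))`` modifies only exchange-type doubles, whose weight becomes
``|g_AIBJ - g_AJBI + J|``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .determinants import Excitation, occ_tuple, slater_condon, enumerate_connected
from .integrals import IntegralTable, OrbitalBasis
from .sampling import DEFAULT_MASS_THRESHOLD, REDRAW_CAP, build_alias, DiscreteDist

__all__ = [
    "SchemeSpec",
    "SinglesTables",
    "DoublesTables",
    "HeatbathTables",
    "GasSpec",
    "GasTables",
    "ExcitationDraw",
    "doubles_weight",
    "singles_weight",
    "build_tables",
    "sample_single",
    "sample_double",
    "pgen_of_single",
    "pgen_of_double",
    "exact_single_pgen",
    "audit_valid_rate",
    "uniform_reference",
    "BENCHMARK_SCHEMES",
    "save_tables",
    "load_tables",
]

_METHODS = {"unif": 0, "fast": 1, "full": 2}
_METHOD_NAMES = {v: k for k, v in _METHODS.items()}

#: tensors beyond this spin-orbital count would need pair-compressed storage
_MAX_NSPIN_DENSE = 40


@dataclass(frozen=True)
class SchemeSpec:
    """Per-slot sampling methods, printed as ``sI:sA/dI-dJ:dA-dB``."""

    singles: tuple[str, str] = ("unif", "full")
    doubles: tuple[str, str, str, str] = ("unif", "full", "full", "full")
    spin_penalty_j: float = 0.0

    def __post_init__(self):
        for m in (*self.singles, *self.doubles):
            if m not in _METHODS:
                raise ValueError(f"unknown sampling method {m!r}")

    @classmethod
    def parse(cls, text: str, spin_penalty_j: float = 0.0) -> "SchemeSpec":
        try:
            s_part, d_part = text.strip().split("/")
            s_i, s_a = s_part.split(":")
            d_particles, d_holes = d_part.split(":")
            d_i, d_j = d_particles.split("-")
            d_a, d_b = d_holes.split("-")
        except ValueError as exc:
            raise ValueError(f"cannot parse scheme string {text!r}") from exc
        return cls(singles=(s_i, s_a), doubles=(d_i, d_j, d_a, d_b),
                   spin_penalty_j=spin_penalty_j)

    def __str__(self) -> str:
        s_i, s_a = self.singles
        d_i, d_j, d_a, d_b = self.doubles
        return f"{s_i}:{s_a}/{d_i}-{d_j}:{d_a}-{d_b}"

    @property
    def codes(self) -> tuple[int, int, int, int, int, int]:
        return tuple(_METHODS[m] for m in (*self.singles, *self.doubles))


#: the sampling-scheme combinations benchmarked in this work
BENCHMARK_SCHEMES = [
    "unif:unif/unif-unif:fast-fast",
    "unif:unif/full-full:fast-fast",
    "unif:fast/unif-unif:fast-fast",
    "unif:fast/unif-fast:fast-fast",
    "unif:fast/full-full:fast-fast",
    "unif:full/unif-full:fast-fast",
    "unif:full/unif-full:full-full",
    "unif:full/full-full:fast-fast",
    "full:full/full-full:fast-fast",
    "full:full/full-full:full-full",
]


@dataclass(frozen=True)
class ExcitationDraw:
    """One sampled excitation attempt.

    ``valid=False`` marks a discarded fast-weighted draw that hit an occupied
    hole / empty particle (or a dead-ended constrained path); ``pgen`` is then
    the probability of the realized invalid path, otherwise the total
    generation probability of the target determinant (all index orderings)."""

    excitation: Excitation | None
    pgen: float
    valid: bool


def _spins(n_spin):
    idx = np.arange(n_spin)
    return idx >> 1, idx & 1


def doubles_weight(i, j, a, b, integrals: IntegralTable,
                   j_penalty: float = 0.0) -> float:
    """PCHB weight of the double ``ab <- ij`` (spin–orbital indices).

    The magnitude of the two-electron matrix element without the Fermionic
    phase; exchange-type quadruples pick up the spin penalty.
    """
    if len({i, j, a, b}) != 4:
        return 0.0
    sp = [p >> 1 for p in (i, j, a, b)]
    sg = [p & 1 for p in (i, j, a, b)]
    if sg[0] + sg[1] != sg[2] + sg[3]:
        return 0.0
    g = integrals.g
    t = 0.0
    if sg[2] == sg[0] and sg[3] == sg[1]:
        t += g[sp[2], sp[0], sp[3], sp[1]]
    if sg[2] == sg[1] and sg[3] == sg[0]:
        t -= g[sp[2], sp[1], sp[3], sp[0]]
    if j_penalty != 0.0:
        if sp[2] == sp[0] and sp[3] == sp[1] and sg[2] != sg[0] and sg[3] != sg[1]:
            t += j_penalty
        if sp[2] == sp[1] and sp[3] == sp[0] and sg[2] != sg[1] and sg[3] != sg[0]:
            t -= j_penalty
    return abs(t)


def singles_weight(i, a, integrals: IntegralTable) -> float:
    """Contracted singles weight ``S_I^A`` (same-spin spin–orbitals).

    Contraction runs over all spin–orbitals R: the Coulomb column enters once
    per spin of R, the exchange column only for R of the excitation's spin.
    """
    if i == a:
        return 0.0
    if (i & 1) != (a & 1):
        raise ValueError("singles conserve spin: I and A must have equal spin")
    pi, pa = i >> 1, a >> 1
    h, g = integrals.h, integrals.g
    s = abs(h[pa, pi])
    for r in range(integrals.n_spatial):
        s += 2.0 * abs(g[pa, pi, r, r]) + abs(g[pa, r, r, pi])
    return float(s)


def _w_tensor(integrals: IntegralTable, n_spin: int, j_penalty: float) -> np.ndarray:
    """Dense W[I, J, A, B] over spin-orbital quadruples."""
    sp, sg = _spins(n_spin)
    g = integrals.g
    spI = sp[:, None, None, None]
    spJ = sp[None, :, None, None]
    spA = sp[None, None, :, None]
    spB = sp[None, None, None, :]
    sgI = sg[:, None, None, None]
    sgJ = sg[None, :, None, None]
    sgA = sg[None, None, :, None]
    sgB = sg[None, None, None, :]
    t = g[spA, spI, spB, spJ] * ((sgA == sgI) & (sgB == sgJ)) \
        - g[spA, spJ, spB, spI] * ((sgA == sgJ) & (sgB == sgI))
    if j_penalty != 0.0:
        tau = ((spA == spI) & (spB == spJ) & (sgA != sgI) & (sgB != sgJ)).astype(float) \
            - ((spA == spJ) & (spB == spI) & (sgA != sgJ) & (sgB != sgI)).astype(float)
        t = t + j_penalty * tau
    w = np.abs(t)
    w *= (sgI + sgJ) == (sgA + sgB)  # total S_z conservation
    idx = np.arange(n_spin)
    eye = idx[:, None] == idx[None, :]
    w[eye, :, :] = 0.0  # I == J
    w[:, :, eye] = 0.0  # A == B
    w *= ~eye[:, None, None, :]  # I == B
    w *= ~eye[None, :, :, None]  # J == A
    w *= ~eye[:, None, :, None]  # I == A
    w *= ~eye[None, :, None, :]  # J == B
    return w


def _s_matrix(integrals: IntegralTable, n_spin: int) -> np.ndarray:
    """Dense S[I, A] singles-weight matrix (zero across spins and on diagonal)."""
    n_sp = integrals.n_spatial
    g, h = integrals.g, integrals.h
    coul = 2.0 * np.abs(g).diagonal(axis1=2, axis2=3).sum(axis=-1)  # sum_r 2|g_airr|
    exch = np.abs(g).diagonal(axis1=1, axis2=2).sum(axis=-1)  # sum_r |g_arri| -> [a, i]
    s_spatial = np.abs(h) + coul + exch
    s = np.zeros((n_spin, n_spin))
    sp, sg = _spins(n_spin)
    same_spin = sg[:, None] == sg[None, :]
    s[same_spin] = s_spatial[sp[:, None], sp[None, :]][same_spin]
    np.fill_diagonal(s, 0.0)
    return s


def _normalize_rows(w2d: np.ndarray):
    """Row-normalize; returns (probs, ok flags). All-zero rows stay zero."""
    sums = w2d.sum(axis=1)
    ok = (sums > 0).astype(np.uint8)
    probs = np.where(sums[:, None] > 0, w2d / np.where(sums[:, None] > 0,
                                                       sums[:, None], 1.0), 0.0)
    return probs, ok


def _alias_rows(probs2d: np.ndarray, ok: np.ndarray):
    n_rows, n = probs2d.shape
    cutoff = np.ones((n_rows, n))
    alias = np.tile(np.arange(n, dtype=np.int64), (n_rows, 1))
    for r in range(n_rows):
        if ok[r]:
            t = build_alias(DiscreteDist(probs=probs2d[r]))
            cutoff[r] = t.cutoff
            alias[r] = t.alias
    return cutoff, alias


@dataclass
class SinglesTables:
    """Precomputed singles weights with marginal/conditional alias structures."""

    S: np.ndarray
    p_i: np.ndarray
    cut_i: np.ndarray
    alias_i: np.ndarray
    ok_i: int
    p_a: np.ndarray  # flat (n*n), row I
    cut_a: np.ndarray
    alias_a: np.ndarray
    ok_a: np.ndarray

    @property
    def n_spin(self) -> int:
        return self.p_i.size

    @property
    def kernel_args(self):
        return (self.p_i, self.cut_i, self.alias_i, self.ok_i,
                self.p_a, self.cut_a, self.alias_a, self.ok_a)


@dataclass
class DoublesTables:
    """Precomputed doubles weights W_IJ^AB and the four chained alias levels."""

    W: np.ndarray
    p1: np.ndarray
    cut1: np.ndarray
    alias1: np.ndarray
    ok1: int
    p2: np.ndarray
    cut2: np.ndarray
    alias2: np.ndarray
    ok2: np.ndarray
    p3: np.ndarray
    cut3: np.ndarray
    alias3: np.ndarray
    ok3: np.ndarray
    p4: np.ndarray
    cut4: np.ndarray
    alias4: np.ndarray
    ok4: np.ndarray

    @property
    def n_spin(self) -> int:
        return self.p1.size

    @property
    def kernel_args(self):
        return (self.p1, self.cut1, self.alias1, self.ok1,
                self.p2, self.cut2, self.alias2, self.ok2,
                self.p3, self.cut3, self.alias3, self.ok3,
                self.p4, self.cut4, self.alias4, self.ok4)


@dataclass
class HeatbathTables:
    """Bundle of singles + doubles tables for one (super)group of determinants."""

    basis: OrbitalBasis
    singles: SinglesTables
    doubles: DoublesTables
    spin_penalty_j: float = 0.0
    mass_threshold: float = DEFAULT_MASS_THRESHOLD
    redraw_cap: int = REDRAW_CAP

    @property
    def n_spin(self) -> int:
        return self.basis.n_spin


def _build_singles(s: np.ndarray) -> SinglesTables:
    n = s.shape[0]
    row_sums = s.sum(axis=1)
    total = row_sums.sum()
    if total > 0:
        p_i = row_sums / total
        t = build_alias(DiscreteDist(probs=p_i))
        cut_i, alias_i = t.cutoff, t.alias
        ok_i = 1
    else:
        p_i = np.zeros(n)
        cut_i = np.ones(n)
        alias_i = np.arange(n, dtype=np.int64)
        ok_i = 0
    p_a, ok_a = _normalize_rows(s)
    cut_a, alias_a = _alias_rows(p_a, ok_a)
    return SinglesTables(S=s, p_i=p_i, cut_i=cut_i, alias_i=alias_i, ok_i=ok_i,
                         p_a=p_a.ravel(), cut_a=cut_a.ravel(),
                         alias_a=alias_a.ravel(), ok_a=ok_a)


def _build_doubles(w: np.ndarray) -> DoublesTables:
    n = w.shape[0]
    # p(I) ∝ Σ_JAB, p(J|I) ∝ Σ_AB, p(A|IJ) ∝ Σ_B, p(B|IJA) ∝ W
    sum_b = w.reshape(n * n * n, n)  # rows (I,J,A)
    p4, ok4 = _normalize_rows(sum_b)
    cut4, alias4 = _alias_rows(p4, ok4)
    sum_ab = w.sum(axis=3).reshape(n * n, n)  # rows (I,J) over A
    p3, ok3 = _normalize_rows(sum_ab)
    cut3, alias3 = _alias_rows(p3, ok3)
    sum_jab = w.sum(axis=(2, 3))  # (I, J)
    p2, ok2 = _normalize_rows(sum_jab)
    cut2, alias2 = _alias_rows(p2, ok2)
    row = sum_jab.sum(axis=1)
    total = row.sum()
    if total > 0:
        p1 = row / total
        t = build_alias(DiscreteDist(probs=p1))
        cut1, alias1 = t.cutoff, t.alias
        ok1 = 1
    else:
        p1 = np.zeros(n)
        cut1 = np.ones(n)
        alias1 = np.arange(n, dtype=np.int64)
        ok1 = 0
    return DoublesTables(W=w,
                         p1=p1, cut1=cut1, alias1=alias1, ok1=ok1,
                         p2=p2.ravel(), cut2=cut2.ravel(), alias2=alias2.ravel(),
                         ok2=ok2,
                         p3=p3.ravel(), cut3=cut3.ravel(), alias3=alias3.ravel(),
                         ok3=ok3,
                         p4=p4.ravel(), cut4=cut4.ravel(), alias4=alias4.ravel(),
                         ok4=ok4)


# ---------------------------------------------------------------------------
# GAS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GasSpec:
    """Generalized active space: a partition of the spatial orbitals into
    subspaces with (min, max) particle counts each."""

    spaces: tuple[tuple[int, ...], ...]
    min_occ: tuple[int, ...]
    max_occ: tuple[int, ...]

    def __post_init__(self):
        flat = [o for sp in self.spaces for o in sp]
        if len(flat) != len(set(flat)):
            raise ValueError("GAS spaces must be disjoint")
        if not (len(self.spaces) == len(self.min_occ) == len(self.max_occ)):
            raise ValueError("per-space bound lists must match the partition")
        for sp, lo, hi in zip(self.spaces, self.min_occ, self.max_occ):
            if not 0 <= lo <= hi or hi > 2 * len(sp):
                raise ValueError("invalid GAS occupation bounds")

    def validate_cover(self, n_spatial: int):
        flat = sorted(o for sp in self.spaces for o in sp)
        if flat != list(range(n_spatial)):
            raise ValueError("GAS spaces must cover all spatial orbitals")

    def space_of(self, n_spatial: int) -> np.ndarray:
        out = np.full(n_spatial, -1, dtype=np.int64)
        for k, sp in enumerate(self.spaces):
            for o in sp:
                out[o] = k
        return out

    def supergroups(self, n_elec: int) -> list[tuple[int, ...]]:
        """All allowed particle distributions, lexicographically ordered."""
        caps = [min(hi, 2 * len(sp)) for sp, hi in zip(self.spaces, self.max_occ)]
        ranges = [range(lo, hi + 1) for lo, hi in zip(self.min_occ, caps)]
        return sorted(sg for sg in itertools.product(*ranges) if sum(sg) == n_elec)

    def supergroup_of(self, det: int, n_spatial: int) -> tuple[int, ...]:
        space = self.space_of(n_spatial)
        counts = [0] * len(self.spaces)
        for p in occ_tuple(det):
            counts[space[p >> 1]] += 1
        return tuple(counts)


@dataclass
class GasTables:
    """One :class:`HeatbathTables` per supergroup."""

    gas: GasSpec
    basis: OrbitalBasis
    by_supergroup: dict[tuple[int, ...], HeatbathTables]

    def lookup(self, det: int) -> HeatbathTables:
        sg = self.gas.supergroup_of(det, self.basis.n_spatial)
        if sg not in self.by_supergroup:
            raise KeyError(f"determinant supergroup {sg} violates the GAS spec")
        return self.by_supergroup[sg]


def _gas_allowed_masks(gas: GasSpec, basis: OrbitalBasis, sg: tuple[int, ...]):
    """(singles mask [I,A], doubles mask [I,J,A,B]) of GAS-allowed transfers."""
    n = basis.n_spin
    space = gas.space_of(basis.n_spatial)
    so_space = space[np.arange(n) >> 1]
    n_spaces = len(gas.spaces)
    onehot = np.zeros((n, n_spaces), dtype=np.int64)
    onehot[np.arange(n), so_space] = 1
    caps = np.array([min(hi, 2 * len(sp)) for sp, hi in
                     zip(gas.spaces, gas.max_occ)])
    lows = np.array(gas.min_occ)
    base = np.array(sg)

    d1 = onehot[:, None, :]  # I
    h1 = onehot[None, :, :]  # A
    new_s = base[None, None, :] - d1 + h1
    singles_ok = np.all((new_s >= lows) & (new_s <= caps), axis=-1)

    dI = onehot[:, None, None, None, :]
    dJ = onehot[None, :, None, None, :]
    hA = onehot[None, None, :, None, :]
    hB = onehot[None, None, None, :, :]
    new_d = base[None, None, None, None, :] - dI - dJ + hA + hB
    doubles_ok = np.all((new_d >= lows) & (new_d <= caps), axis=-1)
    return singles_ok, doubles_ok


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_tables(
    basis: OrbitalBasis,
    integrals: IntegralTable,
    gas: GasSpec | None = None,
    spin_penalty_j: float = 0.0,
    mass_threshold: float = DEFAULT_MASS_THRESHOLD,
    redraw_cap: int = REDRAW_CAP,
) -> HeatbathTables | GasTables:
    """Precompute all PCHB weights and alias tables (one set per supergroup
    when a GAS spec is given)."""
    n = basis.n_spin
    if n > _MAX_NSPIN_DENSE:
        raise ValueError(
            f"dense PCHB tables limited to {_MAX_NSPIN_DENSE} spin-orbitals "
            f"(requested {n})")
    w = _w_tensor(integrals, n, spin_penalty_j)
    s = _s_matrix(integrals, n)
    if gas is None:
        return HeatbathTables(basis=basis, singles=_build_singles(s),
                              doubles=_build_doubles(w),
                              spin_penalty_j=spin_penalty_j,
                              mass_threshold=mass_threshold,
                              redraw_cap=redraw_cap)
    gas.validate_cover(basis.n_spatial)
    out: dict[tuple[int, ...], HeatbathTables] = {}
    for sg in gas.supergroups(basis.n_elec):
        s_ok, d_ok = _gas_allowed_masks(gas, basis, sg)
        out[sg] = HeatbathTables(
            basis=basis,
            singles=_build_singles(s * s_ok),
            doubles=_build_doubles(w * d_ok),
            spin_penalty_j=spin_penalty_j,
            mass_threshold=mass_threshold,
            redraw_cap=redraw_cap,
        )
    return GasTables(gas=gas, basis=basis, by_supergroup=out)


# ---------------------------------------------------------------------------
# sampling wrappers over the numba kernel
# ---------------------------------------------------------------------------

def _codes(scheme: SchemeSpec):
    return scheme.codes


def sample_single(det: int, tables: HeatbathTables, scheme: SchemeSpec,
                  rng: np.random.Generator) -> ExcitationDraw:
    """Draw one single excitation attempt from ``det``."""
    si, sa = scheme.codes[:2]
    t = tables.singles
    i, a, st, pgen = _kernel.sample_single_once(
        np.int64(det), t.n_spin, si, sa, *t.kernel_args,
        tables.mass_threshold, tables.redraw_cap, rng)
    if st == 0:
        return ExcitationDraw(excitation=None, pgen=float(pgen), valid=False)
    return ExcitationDraw(
        excitation=Excitation(particles=(int(i),), holes=(int(a),)),
        pgen=float(pgen), valid=True)


def sample_double(det: int, tables: HeatbathTables, scheme: SchemeSpec,
                  rng: np.random.Generator) -> ExcitationDraw:
    """Draw one double excitation attempt from ``det``.

    ``pgen`` of a valid draw sums every index ordering (2 particle x 2 hole)
    producing the same target determinant, with the renormalized conditional
    of each path."""
    di, dj, da, db = scheme.codes[2:]
    t = tables.doubles
    i, j, a, b, st, pgen = _kernel.sample_double_once(
        np.int64(det), t.n_spin, di, dj, da, db, *t.kernel_args,
        tables.mass_threshold, tables.redraw_cap, rng)
    if st == 0:
        return ExcitationDraw(excitation=None, pgen=float(pgen), valid=False)
    i, j = sorted((int(i), int(j)))
    a, b = sorted((int(a), int(b)))
    return ExcitationDraw(
        excitation=Excitation(particles=(i, j), holes=(a, b)),
        pgen=float(pgen), valid=True)


def pgen_of_single(det: int, i: int, a: int, tables: HeatbathTables,
                   scheme: SchemeSpec) -> float:
    occ = np.array(occ_tuple(det), dtype=np.int64)
    t = tables.singles
    si, sa = scheme.codes[:2]
    return float(_kernel.pgen_single(np.int64(det), t.n_spin, si, sa,
                                     t.p_i, t.p_a, i, a, occ, occ.size))


def pgen_of_double(det: int, exc: Excitation, tables: HeatbathTables,
                   scheme: SchemeSpec) -> float:
    occ = np.array(occ_tuple(det), dtype=np.int64)
    t = tables.doubles
    di, dj, da, db = scheme.codes[2:]
    (i, j), (a, b) = exc.particles, exc.holes
    return float(_kernel.pgen_double(np.int64(det), t.n_spin, di, dj, da, db,
                                     t.p1, t.p2, t.p3, t.p4,
                                     i, j, a, b, occ, occ.size))


def exact_single_pgen(det: int, a: int, i: int, basis: OrbitalBasis,
                      integrals: IntegralTable) -> float:
    """The exact determinant-dependent singles law: proportional to the true
    matrix element magnitude, normalized over all valid singles from ``det``.

    Raises when the law degenerates (all singles vanish, e.g. from the
    mean-field reference in canonical orbitals: the Brillouin condition)."""
    singles = [e for e in enumerate_connected(det, basis.n_spin)
               if e.kind == "single"]
    if not any(e.particles[0] == i and e.holes[0] == a for e in singles):
        raise ValueError("A <- I is not a valid single excitation of det")
    mags = {e: abs(slater_condon(det, e, integrals)) for e in singles}
    total = sum(mags.values())
    if total < 1e-8:
        raise ValueError("degenerate exact singles law: all matrix elements "
                         "vanish (Brillouin-type determinant)")
    target = next(e for e in singles
                  if e.particles[0] == i and e.holes[0] == a)
    return mags[target] / total


def approx_single_hole_law(det: int, i: int, tables: HeatbathTables) -> np.ndarray:
    """The precomputed hole law p(A|I) restricted to empty same-spin orbitals
    of ``det`` and renormalized (for comparison with the exact law)."""
    n = tables.n_spin
    row = tables.singles.p_a[i * n:(i + 1) * n].copy()
    for p in range(n):
        if det >> p & 1:
            row[p] = 0.0
    total = row.sum()
    if total <= 0:
        raise ValueError("no empty same-spin hole available")
    return row / total


def audit_valid_rate(
    dets,
    tables: HeatbathTables,
    scheme: SchemeSpec,
    n_draws: int,
    rng: np.random.Generator,
) -> dict:
    """Population-weighted Monte-Carlo estimate of the valid-excitation rate.

    ``dets`` is an iterable of determinants or (determinant, weight) pairs.
    Returns per-class rates with binomial standard errors.
    """
    items = []
    for d in dets:
        if isinstance(d, tuple):
            items.append((d[0], float(d[1])))
        else:
            items.append((d, 1.0))
    if not items:
        raise ValueError("empty determinant sample")
    weights = np.array([w for _, w in items])
    weights = weights / weights.sum()
    counts = rng.multinomial(n_draws, weights)
    out = {}
    for cls, codes in (("singles", scheme.codes[:2]), ("doubles", scheme.codes[2:])):
        valid = 0
        total = 0
        for (det, _w), m in zip(items, counts):
            if m == 0:
                continue
            if cls == "singles":
                t = tables.singles
                res, _pg = _kernel.sample_single_batch(
                    np.int64(det), tables.n_spin, *codes, *t.kernel_args,
                    tables.mass_threshold, tables.redraw_cap, int(m), rng)
                valid += int((res[:, 2] == 1).sum())
            else:
                t = tables.doubles
                res, _pg = _kernel.sample_double_batch(
                    np.int64(det), tables.n_spin, *codes, *t.kernel_args,
                    tables.mass_threshold, tables.redraw_cap, int(m), rng)
                valid += int((res[:, 4] == 1).sum())
            total += int(m)
        rate = valid / total
        se = np.sqrt(max(rate * (1 - rate), 1e-300) / total)
        out[cls] = {"rate": rate, "se": se, "n": total}
    return out


def uniform_reference(basis: OrbitalBasis) -> dict:
    """The unconstrained uniform reference probabilities quoted alongside the
    PCHB distributions: ``1/n_orb`` per spin–orbital for a particle pick and
    ``1/(n_orb^sigma - N_e^sigma)`` for an empty alpha-orbital hole pick."""
    return {
        "particle": 1.0 / basis.n_spin,
        "empty_alpha_hole": 1.0 / (basis.n_spatial - basis.n_alpha),
    }


# ---------------------------------------------------------------------------
# cache (simple binary container for reuse across runs of one FCIDUMP)
# ---------------------------------------------------------------------------

def cache_key(integrals: IntegralTable, scheme: SchemeSpec,
              gas: GasSpec | None = None) -> str:
    import hashlib

    m = hashlib.sha256()
    m.update(integrals.checksum().encode())
    m.update(str(scheme.spin_penalty_j).encode())
    m.update(repr(gas).encode())
    return m.hexdigest()[:16]


def save_tables(tables: HeatbathTables, path):
    t, d = tables.singles, tables.doubles
    np.savez_compressed(
        path,
        meta=np.array([tables.basis.n_spatial, tables.basis.n_elec,
                       tables.basis.ms2], dtype=np.int64),
        jpen=np.array([tables.spin_penalty_j]),
        S=t.S, p_i=t.p_i, cut_i=t.cut_i, alias_i=t.alias_i,
        ok_i=np.array([t.ok_i]), p_a=t.p_a, cut_a=t.cut_a, alias_a=t.alias_a,
        ok_a=t.ok_a,
        W=d.W, p1=d.p1, cut1=d.cut1, alias1=d.alias1, ok1=np.array([d.ok1]),
        p2=d.p2, cut2=d.cut2, alias2=d.alias2, ok2=d.ok2,
        p3=d.p3, cut3=d.cut3, alias3=d.alias3, ok3=d.ok3,
        p4=d.p4, cut4=d.cut4, alias4=d.alias4, ok4=d.ok4,
    )


def load_tables(path) -> HeatbathTables:
    z = np.load(path)
    n_spatial, n_elec, ms2 = (int(x) for x in z["meta"])
    basis = OrbitalBasis(n_spatial, n_elec, ms2)
    singles = SinglesTables(S=z["S"], p_i=z["p_i"], cut_i=z["cut_i"],
                            alias_i=z["alias_i"], ok_i=int(z["ok_i"][0]),
                            p_a=z["p_a"], cut_a=z["cut_a"],
                            alias_a=z["alias_a"], ok_a=z["ok_a"])
    doubles = DoublesTables(W=z["W"], p1=z["p1"], cut1=z["cut1"],
                            alias1=z["alias1"], ok1=int(z["ok1"][0]),
                            p2=z["p2"], cut2=z["cut2"], alias2=z["alias2"],
                            ok2=z["ok2"],
                            p3=z["p3"], cut3=z["cut3"], alias3=z["alias3"],
                            ok3=z["ok3"],
                            p4=z["p4"], cut4=z["cut4"], alias4=z["alias4"],
                            ok4=z["ok4"])
    return HeatbathTables(basis=basis, singles=singles, doubles=doubles,
                          spin_penalty_j=float(z["jpen"][0]))
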