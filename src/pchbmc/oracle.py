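"""Brute-force references: dense FCI on tiny spaces and exhaustive
generation-probability enumeration for sampler audits.

Everything here is deliberately simple, pure-Python and independent of the
numba sampling kernel: the enumeration walks every slot ordering and draw
outcome of a sampling scheme and aggregates probabilities per target
determinant, providing the unbiasedness reference
``sum_targets pgen + P(invalid) = 1``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .determinants import (
    Excitation,
    excitation_between,
    hamiltonian_element,
    occ_tuple,
    s2_matrix_element,
    slater_condon,
)
from .heatbath import GasSpec, HeatbathTables, SchemeSpec
from .integrals import IntegralTable, OrbitalBasis

__all__ = [
    "FciSolution",
    "enumerate_determinants",
    "dense_hamiltonian",
    "dense_s2",
    "fci_dense",
    "s2_spectrum_check",
    "brute_force_pgen",
]

_MAX_BASIS = 20000
_TINY = 1e-14  # mirrors the kernel's dead-end threshold


@dataclass
class FciSolution:
    """Full-CI eigensolution on an explicitly enumerated determinant basis."""

    dets: list[int]
    energies: np.ndarray
    vectors: np.ndarray

    @property
    def ground_energy(self) -> float:
        return float(self.energies[0])

    @property
    def ground_vector(self) -> np.ndarray:
        return self.vectors[:, 0]

    def ground_space(self, tol: float = 1e-8) -> np.ndarray:
        """All eigenvectors degenerate with the ground state (columns)."""
        mask = self.energies <= self.energies[0] + tol
        return self.vectors[:, mask]


def enumerate_determinants(n_spatial: int, n_elec: int, ms2: int,
                           gas: GasSpec | None = None) -> list[int]:
    """All determinants at fixed (n_elec, S_z), in lexicographic bit order."""
    n_alpha = (n_elec + ms2) // 2
    n_beta = (n_elec - ms2) // 2
    if not (0 <= n_alpha <= n_spatial and 0 <= n_beta <= n_spatial):
        raise ValueError("incompatible electron/spin counts")
    dets = []
    for occ_a in itertools.combinations(range(n_spatial), n_alpha):
        mask_a = sum(1 << (2 * i) for i in occ_a)
        for occ_b in itertools.combinations(range(n_spatial), n_beta):
            det = mask_a + sum(1 << (2 * i + 1) for i in occ_b)
            dets.append(det)
    if gas is not None:
        allowed = set(gas.supergroups(n_elec))
        dets = [d for d in dets
                if gas.supergroup_of(d, n_spatial) in allowed]
    return sorted(dets)


def dense_hamiltonian(dets: list[int], integrals: IntegralTable,
                      spin_penalty_j: float = 0.0,
                      s_target: float | None = None) -> np.ndarray:
    """Assemble <D_i|H|D_j> (optionally S^2-penalized) over an explicit basis."""
    nd = len(dets)
    h = np.zeros((nd, nd))
    for i in range(nd):
        h[i, i] = hamiltonian_element(dets[i], None, integrals,
                                      spin_penalty_j, s_target)
        for j in range(i + 1, nd):
            exc = excitation_between(dets[i], dets[j])
            if exc is None:
                continue
            v = hamiltonian_element(dets[i], exc, integrals,
                                    spin_penalty_j, s_target)
            h[i, j] = v
            h[j, i] = v
    return h


def dense_s2(dets: list[int], n_spatial: int) -> np.ndarray:
    nd = len(dets)
    m = np.zeros((nd, nd))
    for i in range(nd):
        m[i, i] = s2_matrix_element(dets[i], None, n_spatial)
        for j in range(i + 1, nd):
            exc = excitation_between(dets[i], dets[j])
            if exc is None:
                continue
            v = s2_matrix_element(dets[i], exc, n_spatial)
            m[i, j] = v
            m[j, i] = v
    return m


def fci_dense(basis: OrbitalBasis, integrals: IntegralTable,
              n_elec: int | None = None, ms2: int | None = None,
              spin_penalty_j: float = 0.0, s_target: float | None = None,
              gas: GasSpec | None = None) -> FciSolution:
    """Dense full-CI diagonalization (symmetric eigendecomposition).

    With ``spin_penalty_j`` the operator ``H + J (S^2 - s(s+1))`` is
    diagonalized instead, which is how spin purification is validated at desk
    scale.
    """
    if n_elec is None:
        n_elec = basis.n_elec
    if ms2 is None:
        ms2 = basis.ms2
    n_alpha = (n_elec + ms2) // 2
    n_beta = (n_elec - ms2) // 2
    size = math.comb(basis.n_spatial, n_alpha) * math.comb(basis.n_spatial,
                                                           n_beta)
    if size > _MAX_BASIS:
        raise ValueError(f"determinant basis too large ({size})")
    dets = enumerate_determinants(basis.n_spatial, n_elec, ms2, gas=gas)
    h = dense_hamiltonian(dets, integrals, spin_penalty_j, s_target)
    energies, vectors = scipy.linalg.eigh(h)
    return FciSolution(dets=dets, energies=energies, vectors=vectors)


def s2_spectrum_check(basis: OrbitalBasis, n_elec: int | None = None,
                      ms2: int | None = None) -> np.ndarray:
    """Eigenvalues of the dense S^2 matrix — must all be S(S+1) integers."""
    if n_elec is None:
        n_elec = basis.n_elec
    if ms2 is None:
        ms2 = basis.ms2
    dets = enumerate_determinants(basis.n_spatial, n_elec, ms2)
    return np.linalg.eigvalsh(dense_s2(dets, basis.n_spatial))


# ---------------------------------------------------------------------------
# exhaustive path enumeration of the sampling schemes
# ---------------------------------------------------------------------------

def _branches(method, row, det, want_occupied, occ, n_spin,
              uniform_candidates=None):
    """(branches, invalid_prob) of one slot draw.

    ``row`` is the unconstrained probability row for this slot; for uniform
    methods ``uniform_candidates`` lists the valid picks.
    """
    if method == "unif":
        cand = uniform_candidates
        if not cand:
            return [], 1.0
        return [(k, 1.0 / len(cand)) for k in cand], 0.0
    if row.sum() <= 0.0:  # all-zero row: the attempt dead-ends
        return [], 1.0
    if method == "fast":
        branches = []
        invalid = 0.0
        for k in range(n_spin):
            p = row[k]
            if p <= 0.0:
                continue
            hit = bool(det >> k & 1) == want_occupied
            if hit:
                branches.append((k, p))
            else:
                invalid += p
        return branches, invalid
    # full: restrict + renormalize
    mass = sum(row[k] for k in range(n_spin)
               if bool(det >> k & 1) == want_occupied)
    if mass <= _TINY:
        return [], 1.0
    return [(k, row[k] / mass) for k in range(n_spin)
            if bool(det >> k & 1) == want_occupied and row[k] > 0.0], 0.0


def brute_force_pgen(det: int, tables: HeatbathTables, scheme: SchemeSpec,
                     kind: str) -> tuple[dict[int, float], float]:
    """Exhaustive enumeration of one excitation class.

    Walks every slot ordering and draw outcome of the scheme, summing path
    probabilities per final determinant; returns ``(targets, P(invalid))``
    with ``sum(targets.values()) + P(invalid) == 1`` up to round-off.
    """
    n = tables.n_spin
    n_spatial = n // 2
    occ = list(occ_tuple(det))
    nocc = len(occ)
    targets: dict[int, float] = {}
    invalid = 0.0

    if kind == "single":
        si, sa = scheme.singles
        s1 = tables.singles.p_i
        branches_i, miss = _branches(si, s1, det, True, occ, n,
                                     uniform_candidates=occ)
        invalid += miss
        for i, p_i in branches_i:
            row = tables.singles.p_a[i * n:(i + 1) * n]
            sg = i & 1
            empties = [p for p in range(sg, n, 2) if not det >> p & 1]
            br_a, miss_a = _branches(sa, row, det, False, occ, n,
                                     uniform_candidates=empties)
            invalid += p_i * miss_a
            for a, p_a in br_a:
                tgt = (det & ~(1 << i)) | (1 << a)
                targets[tgt] = targets.get(tgt, 0.0) + p_i * p_a
        return targets, invalid

    if kind != "double":
        raise ValueError("kind must be 'single' or 'double'")
    di, dj, da, db = scheme.doubles
    t = tables.doubles
    br_i, miss = _branches(di, t.p1, det, True, occ, n, uniform_candidates=occ)
    invalid += miss
    for i, p_i in br_i:
        row2 = t.p2[i * n:(i + 1) * n]
        occ_no_i = [p for p in occ if p != i]
        br_j, miss_j = _branches(dj, row2, det, True, occ, n,
                                 uniform_candidates=occ_no_i)
        invalid += p_i * miss_j
        for j, p_j in br_j:
            pref_ij = p_i * p_j
            row3 = t.p3[(i * n + j) * n:(i * n + j) * n + n]
            if (i & 1) == (j & 1):
                cand_a = [p for p in range(i & 1, n, 2) if not det >> p & 1]
            else:
                cand_a = [p for p in range(n) if not det >> p & 1]
            br_a, miss_a = _branches(da, row3, det, False, occ, n,
                                     uniform_candidates=cand_a)
            invalid += pref_ij * miss_a
            for a, p_a in br_a:
                pref = pref_ij * p_a
                off4 = ((i * n + j) * n + a) * n
                row4 = t.p4[off4:off4 + n]
                if (i & 1) == (j & 1):
                    cand_b = [p for p in range(i & 1, n, 2)
                              if p != a and not det >> p & 1]
                else:
                    sb = 1 - (a & 1)
                    cand_b = [p for p in range(sb, n, 2)
                              if not det >> p & 1]
                br_b, miss_b = _branches(db, row4, det, False, occ, n,
                                         uniform_candidates=cand_b)
                invalid += pref * miss_b
                for b, p_b in br_b:
                    tgt = ((det & ~(1 << i) & ~(1 << j)) | (1 << a) | (1 << b))
                    targets[tgt] = targets.get(tgt, 0.0) + pref * p_b
    return targets, invalid
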