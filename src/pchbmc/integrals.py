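"""Molecular integrals, FCIDUMP I/O and self-contained model-Hamiltonian fixtures.

Conventions
-----------
* Spatial orbitals are 0-based internally and 1-based in FCIDUMP records.
* Two-electron integrals are stored in chemist notation ``g[p, q, r, s] = (pq|rs)``
  as a dense real tensor with the full 8-fold permutational symmetry
  ``(pq|rs) = (qp|rs) = (pq|sr) = (qp|sr) = (rs|pq) = (sr|pq) = (rs|qp) = (sr|qp)``.
* Spin–orbital index of spatial orbital ``i`` with spin sigma is ``2i`` (alpha) /
  ``2i + 1`` (beta) — interleaved, so spatial locality is contiguous.
* All energies are in hartree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrbitalBasis",
    "IntegralTable",
    "read_fcidump",
    "write_fcidump",
    "gen_hubbard_chain",
    "gen_local_integrals",
    "gen_anderson_impurity",
    "to_mean_field_basis",
]

#: records with |value| below this are omitted when writing
_WRITE_CUTOFF = 1e-12
#: symmetry-equivalent duplicate records must agree to this tolerance
_DUPLICATE_TOL = 1e-10


@dataclass(frozen=True)
class OrbitalBasis:
    """Active-space dimensions: orbital count, electron count and spin projection.

    Parameters
    ----------
    n_spatial:
        Number of spatial orbitals.
    n_elec:
        Number of electrons.
    ms2:
        Twice the spin projection, ``2 S_z = n_alpha - n_beta``.
    irreps:
        Per-spatial-orbital point-group symmetry label (1-based, as in the
        FCIDUMP file).  Stored but not used for screening.
    """

    n_spatial: int
    n_elec: int
    ms2: int = 0
    irreps: tuple[int, ...] = field(default=())
    isym: int = 1

    def __post_init__(self):
        if self.n_spatial < 1:
            raise ValueError("need at least one spatial orbital")
        if not 0 <= self.n_elec <= self.n_spin:
            raise ValueError(f"n_elec={self.n_elec} outside [0, {self.n_spin}]")
        if (self.n_elec + self.ms2) % 2 != 0:
            raise ValueError("n_elec + ms2 must be even")
        if abs(self.ms2) > self.n_elec:
            raise ValueError("|ms2| cannot exceed n_elec")
        if self.irreps and len(self.irreps) != self.n_spatial:
            raise ValueError("irreps length must equal n_spatial")
        if not self.irreps:
            object.__setattr__(self, "irreps", (1,) * self.n_spatial)

    @property
    def n_spin(self) -> int:
        return 2 * self.n_spatial

    @property
    def n_alpha(self) -> int:
        return (self.n_elec + self.ms2) // 2

    @property
    def n_beta(self) -> int:
        return (self.n_elec - self.ms2) // 2


def _g_perms(p, q, r, s):
    return (
        (p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
        (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p),
    )


def _g_canonical(p, q, r, s):
    return min(_g_perms(p, q, r, s))


@dataclass
class IntegralTable:
    """One- and two-electron integrals over spatial orbitals, plus core energy.

    ``h`` is symmetric (real orbitals), ``g`` carries the 8-fold permutational
    symmetry; both are dense, which is fine at desk scale.
    """

    h: np.ndarray
    g: np.ndarray
    e_nuc: float = 0.0

    @property
    def n_spatial(self) -> int:
        return self.h.shape[0]

    @classmethod
    def zeros(cls, n_spatial: int, e_nuc: float = 0.0) -> "IntegralTable":
        return cls(
            h=np.zeros((n_spatial, n_spatial)),
            g=np.zeros((n_spatial,) * 4),
            e_nuc=e_nuc,
        )

    def set_g(self, p, q, r, s, value):
        """Assign ``(pq|rs)`` and all 8 symmetry-equivalent entries."""
        for idx in _g_perms(p, q, r, s):
            self.g[idx] = value

    def symmetrize(self):
        """Average ``h`` and ``g`` over their permutational symmetry in place."""
        self.h = (self.h + self.h.T) / 2.0
        g = self.g
        g = (g + g.transpose(1, 0, 2, 3)) / 2.0
        g = (g + g.transpose(0, 1, 3, 2)) / 2.0
        g = (g + g.transpose(2, 3, 0, 1)) / 2.0
        self.g = g

    def validate(self, tol: float = 1e-12):
        n = self.n_spatial
        if self.h.shape != (n, n) or self.g.shape != (n, n, n, n):
            raise ValueError("inconsistent integral array shapes")
        if not np.allclose(self.h, self.h.T, atol=tol, rtol=0.0):
            raise ValueError("h is not symmetric")
        g = self.g
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(g, g.transpose(perm), atol=tol, rtol=0.0):
                raise ValueError("g violates 8-fold permutational symmetry")

    def checksum(self) -> str:
        """Stable content hash used to key precomputed-table caches."""
        import hashlib

        m = hashlib.sha256()
        m.update(np.ascontiguousarray(self.h).tobytes())
        m.update(np.ascontiguousarray(self.g).tobytes())
        m.update(np.float64(self.e_nuc).tobytes())
        return m.hexdigest()[:16]


# ---------------------------------------------------------------------------
# FCIDUMP (Molpro-style) I/O
# ---------------------------------------------------------------------------

def _parse_header(lines):
    """Parse the &FCI namelist; returns (fields dict, index of first record line)."""
    header = ""
    end = None
    for k, line in enumerate(lines):
        header += " " + line.strip()
        if "/" in line or re.search(r"&END", line, re.IGNORECASE):
            end = k + 1
            break
    if end is None:
        raise ValueError("FCIDUMP header: no terminating '/' found")
    if not re.match(r"\s*&FCI\b", header, re.IGNORECASE):
        raise ValueError(f"FCIDUMP header must start with &FCI, got: {lines[0]!r}")
    body = re.sub(r"(?i)&END", "", header.split("/")[0])
    body = re.sub(r"(?i)\s*&FCI\b", "", body)
    fields = {}
    for m in re.finditer(r"([A-Za-z0-9_]+)\s*=\s*([^=]*?)(?=[A-Za-z0-9_]+\s*=|$)", body):
        key = m.group(1).upper()
        vals = [v for v in re.split(r"[,\s]+", m.group(2).strip()) if v]
        try:
            fields[key] = [int(v) for v in vals]
        except ValueError as exc:
            raise ValueError(f"FCIDUMP header: cannot parse {key} in line {lines[0]!r}") from exc
    for key in ("NORB", "NELEC", "MS2"):
        if key not in fields or not fields[key]:
            raise ValueError(f"FCIDUMP header: missing {key}")
    return fields, end


def read_fcidump(path) -> tuple[OrbitalBasis, IntegralTable]:
    """Read a Molpro-style FCIDUMP file.

    Missing records are zero; symmetry-equivalent duplicate records must agree
    within 1e-10 or a ``ValueError`` is raised.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    fields, start = _parse_header(lines)
    norb = fields["NORB"][0]
    basis = OrbitalBasis(
        n_spatial=norb,
        n_elec=fields["NELEC"][0],
        ms2=fields["MS2"][0],
        irreps=tuple(fields.get("ORBSYM", [1] * norb)),
        isym=fields.get("ISYM", [1])[0],
    )
    table = IntegralTable.zeros(norb)
    seen_g: dict[tuple, float] = {}
    seen_h: dict[tuple, float] = {}
    for line in lines[start:]:
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed FCIDUMP record: {line!r}")
        try:
            value = float(parts[0].replace("D", "E").replace("d", "e"))
            i, j, k, l = (int(p) for p in parts[1:])
        except ValueError as exc:
            raise ValueError(f"malformed FCIDUMP record: {line!r}") from exc
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise ValueError(f"orbital index {idx} outside [1, {norb}] in: {line!r}")
        if i == j == k == l == 0:
            table.e_nuc = value
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise ValueError(f"malformed one-electron record: {line!r}")
            key = (min(i, j) - 1, max(i, j) - 1)
            if key in seen_h and abs(seen_h[key] - value) > _DUPLICATE_TOL:
                raise ValueError(f"conflicting duplicate h record: {line!r}")
            seen_h[key] = value
            table.h[i - 1, j - 1] = value
            table.h[j - 1, i - 1] = value
        else:
            if 0 in (i, j, k, l):
                raise ValueError(f"malformed two-electron record: {line!r}")
            key = _g_canonical(i - 1, j - 1, k - 1, l - 1)
            if key in seen_g and abs(seen_g[key] - value) > _DUPLICATE_TOL:
                raise ValueError(f"conflicting duplicate g record: {line!r}")
            seen_g[key] = value
            table.set_g(i - 1, j - 1, k - 1, l - 1, value)
    return basis, table


def write_fcidump(basis: OrbitalBasis, integrals: IntegralTable, path):
    """Write the canonical FCIDUMP dialect.

    One representative per 8-fold symmetry class; entries below 1e-12 omitted;
    core energy record last.
    """
    integrals.validate(tol=1e-9)
    n = basis.n_spatial
    if integrals.n_spatial != n:
        raise ValueError("basis and integral table disagree on n_spatial")
    with open(path, "w") as fh:
        orbsym = ",".join(str(s) for s in basis.irreps)
        fh.write(
            f"&FCI NORB={n},NELEC={basis.n_elec},MS2={basis.ms2},\n"
            f" ORBSYM={orbsym},\n ISYM={basis.isym},\n/\n"
        )
        for p in range(n):
            for q in range(p + 1):
                for r in range(p + 1):
                    s_max = q if r == p else r
                    for s in range(s_max + 1):
                        v = integrals.g[p, q, r, s]
                        if abs(v) >= _WRITE_CUTOFF:
                            fh.write(f"{v:23.16e} {p + 1:3d} {q + 1:3d} {r + 1:3d} {s + 1:3d}\n")
        for p in range(n):
            for q in range(p + 1):
                v = integrals.h[p, q]
                if abs(v) >= _WRITE_CUTOFF:
                    fh.write(f"{v:23.16e} {p + 1:3d} {q + 1:3d}   0   0\n")
        fh.write(f"{integrals.e_nuc:23.16e}   0   0   0   0\n")


# ---------------------------------------------------------------------------
# Model-Hamiltonian fixtures
# ---------------------------------------------------------------------------

def gen_hubbard_chain(
    n_sites: int,
    t: float = 1.0,
    u: float = 4.0,
    periodic: bool = False,
    n_elec: int | None = None,
    ms2: int | None = None,
) -> tuple[OrbitalBasis, IntegralTable]:
    """Hubbard chain in a site basis: ``h(i, i±1) = -t``, ``(ii|ii) = U``.

    Defaults to half filling (``n_elec = n_sites``) with the lowest compatible
    spin projection.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if t < 0:
        raise ValueError("hopping t must be >= 0")
    if n_elec is None:
        n_elec = n_sites
    if ms2 is None:
        ms2 = n_elec % 2
    table = IntegralTable.zeros(n_sites)
    for i in range(n_sites - 1):
        table.h[i, i + 1] = table.h[i + 1, i] = -t
    if periodic and n_sites > 2:
        table.h[0, n_sites - 1] = table.h[n_sites - 1, 0] = -t
    for i in range(n_sites):
        table.g[i, i, i, i] = u
    return OrbitalBasis(n_sites, n_elec, ms2), table


def gen_local_integrals(
    n_spatial: int,
    n_elec: int,
    decay_len: float,
    seed: int,
    ms2: int | None = None,
) -> tuple[OrbitalBasis, IntegralTable]:
    """Random integrals with exponential spatial decay emulating localized MOs.

    Orbitals sit on a 1-D lattice with unit spacing.  Base magnitudes are drawn
    from a seeded stream (independent of ``decay_len``) and damped by
    ``exp(-d / decay_len)`` where ``d`` is the relevant inter-orbital distance:
    ``|i - j|`` for ``h`` and, for ``(pq|rs)``, the largest of ``|p - q|``,
    ``|r - s|`` and the distance between the two pair centroids.  Identical
    seeds give bit-identical tables; ``decay_len = inf`` disables the damping.
    """
    if not decay_len > 0:
        raise ValueError("decay_len must be > 0")
    if ms2 is None:
        ms2 = n_elec % 2
    rng = np.random.default_rng(seed)
    table = IntegralTable.zeros(n_spatial)

    a = rng.normal(scale=0.5, size=(n_spatial, n_spatial))
    h = (a + a.T) / 2.0
    dist = np.abs(np.subtract.outer(np.arange(n_spatial), np.arange(n_spatial)))
    h = h * np.exp(-dist / decay_len)
    # keep a well-separated diagonal so mean-field solutions are non-degenerate
    h[np.diag_indices(n_spatial)] = np.linspace(-1.0, 1.0, n_spatial) + rng.normal(
        scale=0.1, size=n_spatial
    )
    table.h = (h + h.T) / 2.0

    for p in range(n_spatial):
        for q in range(p + 1):
            for r in range(p + 1):
                s_max = q if r == p else r
                for s in range(s_max + 1):
                    base = rng.uniform(-1.0, 1.0)
                    d = max(
                        abs(p - q),
                        abs(r - s),
                        abs((p + q) / 2.0 - (r + s) / 2.0),
                    )
                    table.set_g(p, q, r, s, base * np.exp(-d / decay_len))
    # geminal repulsion kept positive so half filling is the physical regime
    for p in range(n_spatial):
        table.g[p, p, p, p] = abs(table.g[p, p, p, p]) + 0.5
    table.symmetrize()
    return OrbitalBasis(n_spatial, n_elec, ms2), table


def gen_anderson_impurity(
    n_bath: int,
    u: float = 4.0,
    hybridization: float = 0.5,
    eps_imp: float = -2.0,
    bath_halfwidth: float = 1.0,
    n_elec: int | None = None,
    ms2: int | None = None,
) -> tuple[OrbitalBasis, IntegralTable]:
    """Single-impurity Anderson model: orbital 0 is the impurity.

    The impurity carries the on-site repulsion ``U`` and hybridizes with every
    bath orbital; bath orbitals are mutually uncoupled, so the Hamiltonian only
    contains single excitations, and only between impurity and bath.
    """
    n = n_bath + 1
    if n_elec is None:
        n_elec = n if n % 2 == 0 else n + 1
    if ms2 is None:
        ms2 = n_elec % 2
    table = IntegralTable.zeros(n)
    table.h[0, 0] = eps_imp
    if n_bath > 0:
        energies = np.linspace(-bath_halfwidth, bath_halfwidth, n_bath)
        for k in range(n_bath):
            table.h[k + 1, k + 1] = energies[k]
            table.h[0, k + 1] = table.h[k + 1, 0] = hybridization
    table.g[0, 0, 0, 0] = u
    return OrbitalBasis(n, n_elec, ms2), table


def gen_hund_pair(
    u: float = 2.0,
    u_direct: float = 1.0,
    k_exchange: float = 0.5,
    t: float = 0.05,
) -> tuple[OrbitalBasis, IntegralTable]:
    """Two degenerate orbitals with Hund coupling: a triplet ground state.

    On-site repulsion ``U``, inter-orbital direct repulsion ``U'``, exchange
    ``K > 0`` and a small hopping ``t``.  In the S_z = 0 determinant sector the
    lowest state has S = 1 (Hund's rule), which makes this the minimal fixture
    for spin-purification tests: penalizing Ŝ² re-orders the spectrum so the
    open-shell singlet becomes the ground state.
    """
    table = IntegralTable.zeros(2)
    table.h[0, 1] = table.h[1, 0] = -t
    table.g[0, 0, 0, 0] = u
    table.g[1, 1, 1, 1] = u
    table.set_g(0, 0, 1, 1, u_direct)
    table.set_g(0, 1, 1, 0, k_exchange)
    return OrbitalBasis(2, 2, 0), table


def to_mean_field_basis(
    basis: OrbitalBasis,
    integrals: IntegralTable,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> IntegralTable:
    """Transform integrals to canonical closed-shell mean-field orbitals.

    Solves restricted Hartree–Fock by plain SCF iteration (dense, desk scale)
    and rotates ``h`` and ``g`` into the canonical MO basis, in which single
    excitations from the mean-field determinant have vanishing Hamiltonian
    matrix elements (Brillouin condition).
    """
    if basis.n_elec % 2 != 0 or basis.ms2 != 0:
        raise ValueError("mean-field transform requires a closed shell")
    nocc = basis.n_elec // 2
    h, g = integrals.h, integrals.g
    _, c = np.linalg.eigh(h)
    fock = h
    for _ in range(max_iter):
        cocc = c[:, :nocc]
        dm = 2.0 * cocc @ cocc.T
        coul = np.einsum("pqrs,rs->pq", g, dm)
        exch = np.einsum("prqs,rs->pq", g, dm)
        fock_new = h + coul - 0.5 * exch
        if np.max(np.abs(fock_new - fock)) < tol and _ > 0:
            fock = fock_new
            break
        fock = fock_new
        _, c = np.linalg.eigh(fock)
    _, c = np.linalg.eigh(fock)
    h_mo = c.T @ h @ c
    g_mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", g, c, c, c, c, optimize=True)
    out = IntegralTable(h=h_mo, g=g_mo, e_nuc=integrals.e_nuc)
    out.symmetrize()
    return out
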