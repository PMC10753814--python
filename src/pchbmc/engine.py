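"""FCIQMC walker dynamics: spawn, death, annihilation, initiator control,
shift and time-step adaptation, and projected-energy estimation.

The stochastic wave function is a signed real amplitude per determinant.  Each
iteration every walker makes ``ceil(|c|)`` excitation attempts (single with
probability p1, double with p2), spawning onto the proposed determinant with
magnitude ``dtau |H_ij| / (p_n pgen)`` and sign ``-sign(H_ij) sign(parent)``;
the diagonal death step scales amplitudes by ``1 - dtau (H_ii - E_ref - S)``;
annihilation merges same-determinant contributions by signed summation.
Spawns (and merged amplitudes) below magnitude one are stochastically rounded,
which keeps the population sparse while remaining unbiased in expectation.

The initiator rule discards spawns from parents with ``|c| <= n_add`` onto
unoccupied determinants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .analysis import blocking_error, ratio_estimate
from .determinants import (
    enumerate_connected,
    hamiltonian_element,
    occ_tuple,
)
from .heatbath import GasTables, HeatbathTables, SchemeSpec
from .integrals import IntegralTable, OrbitalBasis

__all__ = [
    "WalkerPopulation",
    "RunState",
    "RunResult",
    "reference_determinant",
    "propagate_iteration",
    "update_shift",
    "update_dtau_p1p2",
    "projected_energy",
    "run_fciqmc",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class WalkerPopulation:
    """Signed walker amplitudes keyed by determinant (parallel sorted arrays)."""

    dets: np.ndarray
    amps: np.ndarray

    @classmethod
    def from_dict(cls, d: dict[int, float]) -> "WalkerPopulation":
        items = sorted((k, v) for k, v in d.items() if v != 0.0)
        dets = np.array([k for k, _ in items], dtype=np.int64)
        amps = np.array([v for _, v in items], dtype=float)
        return cls(dets=dets, amps=amps)

    def as_dict(self) -> dict[int, float]:
        return {int(d): float(a) for d, a in zip(self.dets, self.amps)}

    @property
    def n_walkers(self) -> float:
        return float(np.abs(self.amps).sum())

    @property
    def n_occupied(self) -> int:
        return int(self.dets.size)

    def amplitude(self, det: int) -> float:
        k = np.searchsorted(self.dets, det)
        if k < self.dets.size and self.dets[k] == det:
            return float(self.amps[k])
        return 0.0

    def initiator_flags(self, n_add: float) -> np.ndarray:
        return np.abs(self.amps) > n_add


@dataclass
class RunState:
    """Mutable per-run dynamical parameters."""

    shift: float = 0.0
    dtau: float = 0.005
    p1: float = 0.5
    iteration: int = 0
    max_ratio_1: float = 0.0  # running max |H|/pgen, singles
    max_ratio_2: float = 0.0  # running max |H|/pgen, doubles
    max_diag: float = 0.0  # running max |H_ii - E_ref| over visited determinants
    variable_shift: bool = False
    frozen: bool = False

    @property
    def p2(self) -> float:
        return 1.0 - self.p1


def reference_determinant(basis: OrbitalBasis, integrals: IntegralTable) -> int:
    """Greedy minimum-diagonal determinant.

    Electrons are placed one at a time (alternating spins up to the required
    S_z) into the spin–orbital with the lowest incremental diagonal energy
    ``h_ii + sum_occ (J - K)``.  Reduces to the aufbau determinant when the
    one-electron diagonal dominates and to the Néel configuration for
    repulsive lattice models, both of which have far better ground-state
    overlap than naive tie-breaking."""
    h, g = integrals.h, integrals.g
    n = basis.n_spatial
    occ: list[int] = []
    # alternate spin placement so the repulsion bookkeeping sees both spins
    seq = []
    na, nb = basis.n_alpha, basis.n_beta
    while na or nb:
        if na >= nb and na:
            seq.append(0)
            na -= 1
        elif nb:
            seq.append(1)
            nb -= 1
    det = 0
    for sg in seq:
        best, best_e = -1, None
        for i in range(n):
            p = 2 * i + sg
            if det >> p & 1:
                continue
            e = h[i, i]
            for q in occ:
                e += g[i, i, q >> 1, q >> 1]
                if q & 1 == sg:
                    e -= g[i, q >> 1, q >> 1, i]
            if best_e is None or e < best_e - 1e-12:
                best, best_e = p, e
        det |= 1 << best
        occ.append(best)
    return det


def _tables_for(tables, det: int) -> HeatbathTables:
    if isinstance(tables, GasTables):
        return tables.lookup(det)
    return tables


def _annihilate(parent_dets, parent_amps, spawn_dets, spawn_amps,
                rng: np.random.Generator) -> WalkerPopulation:
    """Signed merge in deterministic (sorted) order + stochastic rounding of
    sub-unit amplitudes; zero entries are dropped."""
    alldets = np.concatenate([parent_dets, spawn_dets])
    allamps = np.concatenate([parent_amps, spawn_amps])
    uniq, inv = np.unique(alldets, return_inverse=True)
    merged = np.zeros(uniq.size)
    np.add.at(merged, inv, allamps)
    mag = np.abs(merged)
    small = (mag < 1.0) & (mag > 0.0)
    if np.any(small):
        keep = rng.random(int(small.sum())) < mag[small]
        rounded = np.where(keep, np.sign(merged[small]), 0.0)
        merged[small] = rounded
    nz = merged != 0.0
    return WalkerPopulation(dets=uniq[nz], amps=merged[nz])


def propagate_iteration(
    pop: WalkerPopulation,
    state: RunState,
    tables,
    scheme: SchemeSpec,
    basis: OrbitalBasis,
    integrals: IntegralTable,
    rng: np.random.Generator,
    e_ref: float,
    n_add: float = 3.0,
    s_target: float | None = None,
) -> tuple[WalkerPopulation, dict]:
    """One full FCIQMC iteration (excitation generation, spawn, death,
    annihilation) on the whole population."""
    if pop.n_occupied == 0:
        raise RuntimeError("population extinction")
    n = basis.n_spin
    jpen = scheme.spin_penalty_j
    if s_target is None:
        s_target = basis.ms2 / 2.0
    s2_shift = s_target * (s_target + 1.0)
    gas = tables.gas if isinstance(tables, GasTables) else None

    groups: list[tuple[HeatbathTables, np.ndarray]] = []
    if gas is None:
        groups.append((tables, np.arange(pop.n_occupied)))
    else:
        sgs = [gas.supergroup_of(int(d), basis.n_spatial) for d in pop.dets]
        for sg in sorted(set(sgs)):
            idx = np.array([k for k, s in enumerate(sgs) if s == sg])
            groups.append((tables.by_supergroup[sg], idx))

    new_amps = np.empty_like(pop.amps)
    sp_dets_all, sp_amps_all = [], []
    stats = np.zeros(8)
    for tb, idx in groups:
        si, sa, di, dj, da, db = scheme.codes
        amps_out, sp_d, sp_a, st = _kernel.spawn_batch(
            pop.dets[idx], pop.amps[idx], pop.dets, n,
            integrals.h, integrals.g, integrals.e_nuc, jpen, s2_shift,
            e_ref, state.shift, state.dtau, state.p1, float(n_add),
            si, sa, di, dj, da, db,
            *tb.singles.kernel_args, *tb.doubles.kernel_args,
            tb.mass_threshold, tb.redraw_cap, rng)
        new_amps[idx] = amps_out
        sp_dets_all.append(sp_d)
        sp_amps_all.append(sp_a)
        for k in (0, 1, 2, 3, 6):
            stats[k] += st[k]
        for k in (4, 5, 7):  # per-class maxima, not counts
            stats[k] = max(stats[k], st[k])
    sp_dets = np.concatenate(sp_dets_all) if sp_dets_all else np.empty(0, np.int64)
    sp_amps = np.concatenate(sp_amps_all) if sp_amps_all else np.empty(0)
    if gas is not None and sp_dets.size:
        allowed = set(gas.supergroups(basis.n_elec))
        ok = np.array([gas.supergroup_of(int(d), basis.n_spatial) in allowed
                       for d in sp_dets])
        sp_dets, sp_amps = sp_dets[ok], sp_amps[ok]

    new_pop = _annihilate(pop.dets, new_amps, sp_dets, sp_amps, rng)
    state.iteration += 1
    if not state.frozen:
        state.max_ratio_1 = max(state.max_ratio_1, float(stats[4]))
        state.max_ratio_2 = max(state.max_ratio_2, float(stats[5]))
        state.max_diag = max(state.max_diag, float(stats[7]))
    diag = {
        "attempts_1": int(stats[0]), "valid_1": int(stats[1]),
        "attempts_2": int(stats[2]), "valid_2": int(stats[3]),
        "max_ratio_1": float(stats[4]), "max_ratio_2": float(stats[5]),
        "initiator_discards": int(stats[6]),
        "n_spawned": int(sp_dets.size),
    }
    return new_pop, diag


def update_shift(state: RunState, n_w_now: float, n_w_prev: float,
                 damping: float = 0.05, interval: int = 5,
                 target_pop: float | None = None,
                 restore: float = 0.0) -> float:
    """Damped first-order population-control update
    ``S <- S - zeta/(A dtau) ln(N_now / N_prev)``; returns the new shift.

    With ``restore > 0`` a weak term ``- restore/(A dtau) ln(N_now / target)``
    pulls the stationary population onto the target instead of wherever the
    growth phase happened to overshoot; it vanishes at ``N_w = target`` and so
    does not move the stationary shift."""
    if n_w_now <= 0 or n_w_prev <= 0:
        raise ValueError("walker populations must be positive")
    state.shift -= damping / (interval * state.dtau) * math.log(n_w_now / n_w_prev)
    if restore > 0.0 and target_pop:
        state.shift -= restore / (interval * state.dtau) * math.log(n_w_now / target_pop)
    return state.shift


def update_dtau_p1p2(state: RunState, damping: float = 0.05,
                     p_floor: float = 0.01) -> RunState:
    """Move dtau and the class probabilities toward the worst-case-balance
    fixed point: p1 : p2 = M1 : M2 and ``dtau = 1 / max_n(M_n / p_n)``, where
    ``M_n`` is the running class maximum of ``|H| / pgen``.  The damped update
    keeps every previously seen spawn magnitude below one at the fixed point;
    frozen after the settling window."""
    if state.frozen:
        return state
    m1, m2 = state.max_ratio_1, state.max_ratio_2
    if m1 <= 0.0 and m2 <= 0.0:
        return state
    if m1 <= 0.0:
        p1_t = p_floor
    elif m2 <= 0.0:
        p1_t = 1.0 - p_floor
    else:
        p1_t = min(max(m1 / (m1 + m2), p_floor), 1.0 - p_floor)
    state.p1 += damping * (p1_t - state.p1)
    worst = max(m1 / state.p1, m2 / (1.0 - state.p1))
    dtau_t = 1.0 / worst
    # the spawn rule alone does not bound the diagonal death factor; keep
    # |dtau (H_ii - E_ref - S)| below one as well so amplitudes cannot blow up
    death_scale = state.max_diag + abs(state.shift)
    if death_scale > 0.0:
        dtau_t = min(dtau_t, 0.9 / death_scale)
    state.dtau += damping * (dtau_t - state.dtau)
    return state


def projected_energy(pop: WalkerPopulation, ref_det: int,
                     basis: OrbitalBasis, integrals: IntegralTable,
                     spin_penalty_j: float = 0.0,
                     s_target: float | None = None) -> float:
    """Mixed estimator ``E = H_ref,ref + sum_j H_ref,j c_j / c_ref``."""
    c_ref = pop.amplitude(ref_det)
    if c_ref == 0.0:
        raise ValueError("reference determinant unoccupied")
    conn = _ref_connections(ref_det, basis, integrals, spin_penalty_j, s_target)
    num = sum(v * pop.amplitude(d) for d, v in conn.items())
    e0 = hamiltonian_element(ref_det, None, integrals, spin_penalty_j, s_target)
    return float(e0 + num / c_ref)


def _ref_connections(ref_det, basis, integrals, jpen=0.0, s_target=None):
    conn = {}
    for exc in enumerate_connected(ref_det, basis.n_spin):
        v = hamiltonian_element(ref_det, exc, integrals, jpen, s_target)
        if v != 0.0:
            tgt = ref_det
            for p in exc.particles:
                tgt &= ~(1 << p)
            for h in exc.holes:
                tgt |= 1 << h
            conn[tgt] = v
    return conn


@dataclass
class RunResult:
    """Energies, error bars and per-iteration series of one FCIQMC run."""

    scheme: str
    seed: int
    ref_det: int
    e_ref: float
    shift_energy: float
    shift_error: float
    proj_energy: float
    proj_error: float
    series: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "e_ref": self.e_ref,
            "shift_energy": self.shift_energy,
            "shift_error": self.shift_error,
            "proj_energy": self.proj_energy,
            "proj_error": self.proj_error,
            **{k: v for k, v in self.diagnostics.items()},
        }


def save_checkpoint(path, pop: WalkerPopulation, state: RunState,
                    rng: np.random.Generator):
    """Persist population + run state + rng state so a run can resume."""
    import pickle

    rng_state = pickle.dumps(rng.bit_generator.state)
    np.savez(path, dets=pop.dets, amps=pop.amps,
             scalars=np.array([state.shift, state.dtau, state.p1,
                               state.max_ratio_1, state.max_ratio_2,
                               state.max_diag]),
             flags=np.array([state.iteration, int(state.variable_shift),
                             int(state.frozen)], dtype=np.int64),
             rng_state=np.frombuffer(rng_state, dtype=np.uint8))


def load_checkpoint(path) -> tuple[WalkerPopulation, RunState,
                                   np.random.Generator]:
    import pickle

    z = np.load(path)
    pop = WalkerPopulation(dets=z["dets"].astype(np.int64), amps=z["amps"])
    sc, fl = z["scalars"], z["flags"]
    state = RunState(shift=float(sc[0]), dtau=float(sc[1]), p1=float(sc[2]),
                     max_ratio_1=float(sc[3]), max_ratio_2=float(sc[4]),
                     max_diag=float(sc[5]), iteration=int(fl[0]),
                     variable_shift=bool(fl[1]), frozen=bool(fl[2]))
    rng = np.random.default_rng()
    rng.bit_generator.state = pickle.loads(z["rng_state"].tobytes())
    return pop, state, rng


def run_fciqmc(
    basis: OrbitalBasis,
    integrals: IntegralTable,
    tables,
    scheme: SchemeSpec | str,
    seed: int = 1,
    target_pop: float = 5000.0,
    n_settle: int = 800,
    n_measure: int = 2000,
    n_measure_tau: float | None = None,
    n_measure_cap: int = 12000,
    grow_max: int = 20000,
    n_add: float = 3.0,
    init_pop: float = 10.0,
    shift_damping: float = 0.1,
    shift_interval: int = 2,
    pop_restore: float = 0.01,
    dtau0: float = 0.002,
    ref_det: int | None = None,
    s_target: float | None = None,
    log_file=None,
) -> RunResult:
    """Complete FCIQMC run: growth to the target population at fixed shift,
    a settling window with dtau/p1/p2 adaptation, then a measurement window
    with all dynamical parameters frozen.

    Energies are reported two ways: the mean shift (population-control
    estimator) and the projected (mixed) estimator, both with reblocked error
    bars.
    """
    if isinstance(scheme, str):
        scheme = SchemeSpec.parse(scheme)
    rng = np.random.default_rng(seed)
    if ref_det is None:
        ref_det = reference_determinant(basis, integrals)
    jpen = scheme.spin_penalty_j
    if s_target is None:
        s_target = basis.ms2 / 2.0
    e_ref = hamiltonian_element(ref_det, None, integrals, jpen,
                                s_target if jpen else None)
    conn = _ref_connections(ref_det, basis, integrals, jpen,
                            s_target if jpen else None)

    state = RunState(dtau=dtau0)
    pop = WalkerPopulation.from_dict({ref_det: init_pop})
    series = {k: [] for k in ("iteration", "shift", "n_w", "e_num", "e_den",
                              "valid_rate_1", "valid_rate_2")}
    n_w_prev = pop.n_walkers
    shift_start = None
    measure_start = None
    total_valid = np.zeros(2)
    total_att = np.zeros(2)
    it = 0
    header_written = False
    while True:
        it += 1
        pop, diag = propagate_iteration(pop, state, tables, scheme, basis,
                                        integrals, rng, e_ref, n_add,
                                        s_target if jpen else None)
        update_dtau_p1p2(state)
        n_w = pop.n_walkers
        if n_w <= 0:
            raise RuntimeError("population extinction")
        if not state.variable_shift and n_w >= target_pop:
            state.variable_shift = True
            shift_start = it
            # seed the shift with the current projected correlation energy so
            # the damped update only has to track fluctuations, not absorb the
            # full growth rate; fall back to the instantaneous growth estimate
            den = pop.amplitude(ref_det)
            if den != 0.0:
                state.shift = sum(v * pop.amplitude(d)
                                  for d, v in conn.items()) / den
            elif n_w_prev > 0 and n_w > n_w_prev:
                state.shift = -math.log(n_w / n_w_prev) / state.dtau
        # every iteration while settling, every `shift_interval` when frozen
        interval = shift_interval if state.frozen else 1
        if state.variable_shift and it % interval == 0:
            update_shift(state, n_w, n_w_prev, shift_damping, interval,
                         target_pop=target_pop, restore=pop_restore)
            n_w_prev = n_w
        elif not state.variable_shift:
            n_w_prev = n_w
        if shift_start is not None and measure_start is None \
                and it >= shift_start + n_settle:
            state.frozen = True
            measure_start = it
            if n_measure_tau is not None:
                # slowly-sampled schemes adapt to a small dtau and correlate
                # over ~1/dtau iterations; scale the window accordingly so the
                # reblocked error bars stay reliable for every scheme
                n_measure = min(n_measure_cap,
                                max(n_measure, int(n_measure_tau / state.dtau)))
        if measure_start is not None:
            num = sum(v * pop.amplitude(d) for d, v in conn.items())
            den = pop.amplitude(ref_det)
            series["iteration"].append(it)
            series["shift"].append(state.shift)
            series["n_w"].append(n_w)
            series["e_num"].append(num)
            series["e_den"].append(den)
            a1, a2 = max(diag["attempts_1"], 1), max(diag["attempts_2"], 1)
            series["valid_rate_1"].append(diag["valid_1"] / a1)
            series["valid_rate_2"].append(diag["valid_2"] / a2)
            total_valid += (diag["valid_1"], diag["valid_2"])
            total_att += (diag["attempts_1"], diag["attempts_2"])
            if log_file is not None:
                if not header_written:
                    log_file.write(f"# scheme={scheme} seed={seed} "
                                   f"dtau={state.dtau:.6g} p1={state.p1:.6g}\n")
                    log_file.write("iteration\tshift\tn_w\te_num\te_den\n")
                    header_written = True
                log_file.write(f"{it}\t{state.shift:.10g}\t{n_w:.10g}\t"
                               f"{num:.10g}\t{den:.10g}\n")
            if it >= measure_start + n_measure - 1:
                break
        if measure_start is None and it >= grow_max:
            raise RuntimeError("population failed to reach the target "
                               f"within {grow_max} iterations")
    arr = {k: np.asarray(v) for k, v in series.items()}
    shift_e = e_ref + float(arr["shift"].mean())
    shift_err = blocking_error(arr["shift"])
    ratio, ratio_err = ratio_estimate(arr["e_num"], arr["e_den"])
    proj_e = e_ref + ratio
    diagnostics = {
        "dtau": state.dtau,
        "p1": state.p1,
        "mean_n_w": float(arr["n_w"].mean()),
        "valid_rate_1": float(total_valid[0] / max(total_att[0], 1)),
        "valid_rate_2": float(total_valid[1] / max(total_att[1], 1)),
        "n_iterations": it,
    }
    return RunResult(
        scheme=str(scheme), seed=seed, ref_det=ref_det, e_ref=float(e_ref),
        shift_energy=shift_e, shift_error=float(shift_err),
        proj_energy=float(proj_e), proj_error=float(ratio_err),
        series=arr, diagnostics=diagnostics,
    )
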