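"""Walker dynamics: propagation, annihilation, adaptation, estimators."""

import numpy as np
import pytest

import pchbmc as pm
from pchbmc.analysis import blocking_error, ratio_estimate, reblock
from pchbmc.engine import (
    RunState,
    WalkerPopulation,
    _annihilate,
    propagate_iteration,
    update_dtau_p1p2,
    update_shift,
)
from pchbmc.determinants import hamiltonian_element


def test_annihilation_removes_cancelling_contributions(rng):
    pop = _annihilate(np.array([5], dtype=np.int64), np.array([3.0]),
                      np.array([5], dtype=np.int64), np.array([-3.0]), rng)
    assert pop.n_occupied == 0


def test_annihilation_merges_by_signed_sum(rng):
    pop = _annihilate(np.array([5, 9], dtype=np.int64), np.array([3.0, 2.0]),
                      np.array([5, 5], dtype=np.int64), np.array([2.0, -1.0]),
                      rng)
    assert pop.as_dict() == {5: 4.0, 9: 2.0}


def test_stationarity_with_matched_shift(rng):
    """No off-diagonal couplings + shift = H_ii - E_ref: amplitude is exactly
    preserved through an iteration."""
    basis, ints = pm.gen_hubbard_chain(2, t=0.0, u=4.0)
    tables = pm.build_tables(basis, ints)
    scheme = pm.SchemeSpec.parse("unif:unif/unif-unif:fast-fast")
    ref = pm.reference_determinant(basis, ints)
    e_ref = hamiltonian_element(ref, None, ints)
    state = RunState(shift=0.0, dtau=0.05)
    pop = WalkerPopulation.from_dict({ref: 7.0})
    pop, diag = propagate_iteration(pop, state, tables, scheme, basis, ints,
                                    rng, e_ref)
    assert pop.as_dict() == {ref: 7.0}
    assert diag["n_spawned"] == 0


def test_one_iteration_expectation_matches_dense_projector(local3):
    """E[c'] = (1 - dtau (H - E_ref - S)) c over one iteration, averaged over
    many independent runs (3 sigma)."""
    basis, ints = local3
    tables = pm.build_tables(basis, ints)
    scheme = pm.SchemeSpec.parse("unif:full/unif-full:full-full")
    sol = pm.fci_dense(basis, ints)
    dets = sol.dets
    from pchbmc.oracle import dense_hamiltonian

    h = dense_hamiltonian(dets, ints)
    ref = dets[0]
    e_ref = hamiltonian_element(ref, None, ints)
    c0 = np.zeros(len(dets))
    c0[0] = 20.0
    c0[3] = -10.0
    dtau = 0.02
    expect = c0 - dtau * (h - e_ref * np.eye(len(dets))) @ c0
    start = {dets[0]: 20.0, dets[3]: -10.0}
    n_rep = 1500
    acc = np.zeros(len(dets))
    rng = np.random.default_rng(777)
    index = {d: k for k, d in enumerate(dets)}
    for _ in range(n_rep):
        state = RunState(shift=0.0, dtau=dtau, p1=0.5)
        pop = WalkerPopulation.from_dict(dict(start))
        pop, _ = propagate_iteration(pop, state, tables, scheme, basis, ints,
                                     rng, e_ref, n_add=0.0)
        for d, a in pop.as_dict().items():
            acc[index[d]] += a
    mean = acc / n_rep
    # conservative per-component scale for the 3-sigma band
    se = 3.0 * np.sqrt(np.abs(expect).max()) / np.sqrt(n_rep) + 0.02
    assert np.abs(mean - expect).max() < 3 * se


def test_update_shift_properties():
    state = RunState(shift=-1.0, dtau=0.1)
    assert update_shift(state, 100.0, 100.0) == -1.0  # unchanged
    before = state.shift
    update_shift(state, 120.0, 100.0)
    assert state.shift < before  # growing population pushes the shift down
    with pytest.raises(ValueError):
        update_shift(state, 0.0, 100.0)


def test_update_dtau_p1p2_fixed_points():
    state = RunState(dtau=0.01, p1=0.5)
    state.max_ratio_1 = 4.0
    state.max_ratio_2 = 4.0
    for _ in range(3000):
        update_dtau_p1p2(state)
    assert state.p1 == pytest.approx(0.5, abs=1e-6)
    # equal maxima: dtau = 1 / (M1 + M2)
    assert state.dtau == pytest.approx(1.0 / 8.0, rel=1e-4)
    # singles ratio 9x doubles: p1/p2 -> 9 and worst-case spawns stay <= 1
    state2 = RunState(dtau=0.01, p1=0.5)
    state2.max_ratio_1 = 9.0
    state2.max_ratio_2 = 1.0
    for _ in range(5000):
        update_dtau_p1p2(state2)
    assert state2.p1 / (1 - state2.p1) == pytest.approx(9.0, rel=1e-3)
    assert state2.dtau * state2.max_ratio_1 / state2.p1 <= 1.0 + 1e-9
    assert state2.dtau * state2.max_ratio_2 / (1 - state2.p1) <= 1.0 + 1e-9
    # frozen state never moves
    state2.frozen = True
    d, p = state2.dtau, state2.p1
    update_dtau_p1p2(state2)
    assert (state2.dtau, state2.p1) == (d, p)


def test_projected_energy_on_exact_eigenvector(hubbard4):
    basis, ints = hubbard4
    sol = pm.fci_dense(basis, ints)
    amps = {d: 1000.0 * c for d, c in zip(sol.dets, sol.ground_vector)
            if abs(c) > 1e-12}
    pop = WalkerPopulation.from_dict(amps)
    ref = max(amps, key=lambda d: abs(amps[d]))
    e = pm.projected_energy(pop, ref, basis, ints)
    assert e == pytest.approx(sol.ground_energy, abs=1e-9)


def test_projected_energy_reference_only(hubbard4):
    basis, ints = hubbard4
    ref = pm.reference_determinant(basis, ints)
    pop = WalkerPopulation.from_dict({ref: 50.0})
    assert pm.projected_energy(pop, ref, basis, ints) == pytest.approx(
        hamiltonian_element(ref, None, ints))
    with pytest.raises(ValueError):
        pm.projected_energy(pop, ref ^ 3, basis, ints)


# ---------------------------------------------------------------------------
# blocking analysis
# ---------------------------------------------------------------------------

def test_blocking_iid_series():
    rng = np.random.default_rng(42)
    x = rng.normal(size=2 ** 14)
    err = blocking_error(x)
    assert err == pytest.approx(1.0 / np.sqrt(x.size), rel=0.20)


def test_blocking_ar1_series():
    rng = np.random.default_rng(43)
    phi = 0.9
    n = 2 ** 15
    eps = rng.normal(size=n)
    x = np.empty(n)
    x[0] = eps[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    var = 1.0 / (1 - phi ** 2)
    exact = np.sqrt(var * (1 + phi) / (1 - phi) / n)
    assert blocking_error(x) == pytest.approx(exact, rel=0.25)


def test_blocking_constant_series():
    assert blocking_error(np.full(64, 3.14)) == 0.0


def test_blocking_rejects_short_series():
    with pytest.raises(ValueError):
        blocking_error(np.arange(8))


def test_ratio_estimate_recovers_known_ratio():
    rng = np.random.default_rng(44)
    den = 10.0 + rng.normal(size=4096) * 0.5
    num = 3.0 * den + rng.normal(size=4096)
    f, err = ratio_estimate(num, den)
    assert f == pytest.approx(3.0, abs=3 * max(err, 1e-4))
    assert err > 0


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def test_hubbard_dimer_run_matches_closed_form(hubbard2):
    basis, ints = hubbard2
    tables = pm.build_tables(basis, ints)
    res = pm.run_fciqmc(basis, ints, tables, "unif:full/unif-full:full-full",
                        seed=3, target_pop=500, n_settle=400, n_measure=1500)
    exact = (4 - np.sqrt(32)) / 2
    assert abs(res.shift_energy - exact) < 3 * res.shift_error
    assert abs(res.proj_energy - exact) < 3 * res.proj_error
    # walker-number control: long-run mean within 10% of target
    assert abs(res.diagnostics["mean_n_w"] - 500) < 50


def test_run_is_deterministic_for_fixed_seed(hubbard2):
    basis, ints = hubbard2
    tables = pm.build_tables(basis, ints)
    kw = dict(seed=11, target_pop=300, n_settle=200, n_measure=300)
    r1 = pm.run_fciqmc(basis, ints, tables, "unif:fast/unif-unif:fast-fast", **kw)
    r2 = pm.run_fciqmc(basis, ints, tables, "unif:fast/unif-unif:fast-fast", **kw)
    assert r1.shift_energy == r2.shift_energy
    assert np.array_equal(r1.series["n_w"], r2.series["n_w"])


def test_spin_penalty_run_targets_singlet_sector():
    """With the Hund-coupled pair (triplet ground state) and a strong penalty,
    the dynamics converge to the penalized operator's singlet ground state."""
    from pchbmc.integrals import gen_hund_pair

    basis, ints = gen_hund_pair()
    jpen = 1.5
    sol = pm.fci_dense(basis, ints, spin_penalty_j=jpen, s_target=0.0)
    sol0 = pm.fci_dense(basis, ints)
    assert sol.ground_energy > sol0.ground_energy  # the triplet got lifted
    tables = pm.build_tables(basis, ints, spin_penalty_j=jpen)
    scheme = pm.SchemeSpec(singles=("unif", "full"),
                           doubles=("unif", "full", "full", "full"),
                           spin_penalty_j=jpen)
    # project onto the dominant determinant of the penalized ground state:
    # the closed-shell aufbau det has tiny overlap with the open-shell singlet
    ref = sol.dets[int(np.argmax(np.abs(sol.ground_vector)))]
    res = pm.run_fciqmc(basis, ints, tables, scheme, seed=9, target_pop=1500,
                        n_settle=400, n_measure=1500, s_target=0.0,
                        ref_det=ref)
    assert abs(res.shift_energy - sol.ground_energy) < 3 * res.shift_error
    assert abs(res.proj_energy - sol.ground_energy) < 3 * res.proj_error


def test_gas_run_matches_gas_restricted_fci():
    basis, ints = pm.gen_anderson_impurity(n_bath=3, u=4.0, hybridization=0.5,
                                           n_elec=4)
    gas = pm.GasSpec(spaces=((0,), (1, 2, 3)), min_occ=(0, 0), max_occ=(2, 6))
    sol = pm.fci_dense(basis, ints, gas=gas)
    gt = pm.build_tables(basis, ints, gas=gas)
    ref = sol.dets[int(np.argmax(np.abs(sol.ground_vector)))]
    res = pm.run_fciqmc(basis, ints, gt, "unif:full/unif-full:full-full",
                        seed=4, target_pop=3000, n_settle=500, n_measure=1500,
                        ref_det=ref)
    assert abs(res.proj_energy - sol.ground_energy) < 3 * res.proj_error


def test_population_extinction_raises(rng, hubbard2):
    basis, ints = hubbard2
    tables = pm.build_tables(basis, ints)
    scheme = pm.SchemeSpec.parse("unif:unif/unif-unif:fast-fast")
    state = RunState()
    pop = WalkerPopulation.from_dict({})
    with pytest.raises(RuntimeError, match="extinction"):
        propagate_iteration(pop, state, tables, scheme, basis, ints, rng, 0.0)


def test_checkpoint_round_trip_resumes_identically(tmp_path, hubbard2, rng):
    """Saving and restoring (population, run state, rng) reproduces the
    exact continuation of a run."""
    from pchbmc.engine import load_checkpoint, save_checkpoint

    basis, ints = hubbard2
    tables = pm.build_tables(basis, ints)
    scheme = pm.SchemeSpec.parse("unif:full/unif-full:full-full")
    ref = pm.reference_determinant(basis, ints)
    e_ref = hamiltonian_element(ref, None, ints)
    state = RunState(dtau=0.02)
    pop = WalkerPopulation.from_dict({ref: 20.0})
    for _ in range(30):
        pop, _ = propagate_iteration(pop, state, tables, scheme, basis, ints,
                                     rng, e_ref)
    path = tmp_path / "chk.npz"
    save_checkpoint(path, pop, state, rng)
    pop2, state2, rng2 = load_checkpoint(path)
    assert state2 == state
    a, _ = propagate_iteration(pop, state, tables, scheme, basis, ints, rng,
                               e_ref)
    b, _ = propagate_iteration(pop2, state2, tables, scheme, basis, ints,
                               rng2, e_ref)
    assert np.array_equal(a.dets, b.dets)
    assert np.array_equal(a.amps, b.amps)
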