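"""PCHB weights, precomputed tables, sampling schemes, GAS and spin penalty."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import pchbmc as pm
from pchbmc import _kernel
from pchbmc.determinants import Excitation, excitation_between, slater_condon
from pchbmc.heatbath import (
    SchemeSpec,
    approx_single_hole_law,
    pgen_of_double,
    pgen_of_single,
    load_tables,
    save_tables,
)
from pchbmc.oracle import brute_force_pgen, enumerate_determinants

ALL_SCHEMES = [SchemeSpec.parse(s) for s in pm.BENCHMARK_SCHEMES]


def test_scheme_string_round_trip():
    for text in pm.BENCHMARK_SCHEMES:
        assert str(SchemeSpec.parse(text)) == text
    with pytest.raises(ValueError):
        SchemeSpec.parse("unif:full/unif-full")
    with pytest.raises(ValueError):
        SchemeSpec.parse("slow:full/unif-full:full-full")


def test_doubles_weight_spin_blocking(local3):
    _, ints = local3
    # opposite-spin, non-exchange quadruple: exchange integral spin-blocked
    i, j, a, b = 0, 3, 2, 5  # 0a,1b -> 1a,2b
    w = pm.doubles_weight(i, j, a, b, ints)
    assert w == pytest.approx(abs(ints.g[1, 0, 2, 1]), abs=1e-14)
    # S_z-violating pattern
    assert pm.doubles_weight(0, 2, 1, 3, ints) == 0.0
    # repeated index
    assert pm.doubles_weight(0, 3, 0, 5, ints) == 0.0


def test_doubles_weight_hermiticity_exhaustive(local3, local3_tables):
    w = local3_tables.doubles.W
    assert np.array_equal(w, w.transpose(2, 3, 0, 1))
    assert np.array_equal(w, w.transpose(1, 0, 2, 3))
    assert np.all(w >= 0)


def test_hubbard_exchange_quadruple_with_penalty(hubbard2):
    _, ints = hubbard2
    # spatial-conserving exchange 1a 2b <- 1b 2a; g_1221 = 0 in a Hubbard chain
    w = pm.doubles_weight(1, 2, 0, 3, ints, j_penalty=0.5)
    assert w == pytest.approx(0.5)


def test_penalized_weight_equals_penalized_element_magnitude(local3, local3_dets):
    """|W| must equal |<j|H + J S^2|i>| for every connected double."""
    _, ints = local3
    jpen = 0.37
    from pchbmc.determinants import s2_matrix_element

    for d1 in local3_dets:
        for d2 in local3_dets:
            exc = excitation_between(d1, d2)
            if exc is None or exc.kind != "double":
                continue
            w = pm.doubles_weight(*exc.particles, *exc.holes, ints,
                                  j_penalty=jpen)
            el = slater_condon(d1, exc, ints) \
                + jpen * s2_matrix_element(d1, exc, 3)
            assert w == pytest.approx(abs(el), abs=1e-12)


def test_w_tensor_matches_scalar_weights_with_penalty(local3):
    basis, ints = local3
    tb = pm.build_tables(basis, ints, spin_penalty_j=0.9)
    n = basis.n_spin
    for q in itertools.product(range(n), repeat=4):
        assert tb.doubles.W[q] == pytest.approx(
            pm.doubles_weight(*q, ints, j_penalty=0.9), abs=1e-13)


def test_singles_weight_bounds_every_matrix_element(local3, local3_dets):
    _, ints = local3
    for det in local3_dets:
        for exc in pm.enumerate_connected(det, 6):
            if exc.kind != "single":
                continue
            el = abs(slater_condon(det, exc, ints))
            s = pm.singles_weight(exc.particles[0], exc.holes[0], ints)
            assert el <= s + 1e-12


def test_singles_weight_symmetry_and_hubbard_value(local3, hubbard2):
    _, ints = local3
    for i in range(6):
        for a in range(i % 2, 6, 2):
            if a == i:
                continue
            assert pm.singles_weight(i, a, ints) == pm.singles_weight(a, i, ints)
    _, hub = hubbard2
    assert pm.singles_weight(0, 2, hub) == pytest.approx(1.0)  # S = t
    with pytest.raises(ValueError):
        pm.singles_weight(0, 3, hub)  # spin flip


def test_constant_weight_tables_are_uniform():
    """A constant-W synthetic table must give exactly uniform rows."""
    basis = pm.OrbitalBasis(3, 4, 0)
    ints = pm.IntegralTable.zeros(3)
    for p in range(3):
        for q in range(3):
            ints.h[p, q] = 1.0 if p != q else 0.0
    tb = pm.build_tables(basis, ints)
    n = basis.n_spin
    # singles: every same-spin off-diagonal weight equals |h| = 1
    for i in range(n):
        row = tb.singles.p_a[i * n:(i + 1) * n]
        nz = row[row > 0]
        assert np.allclose(nz, nz[0])
        assert nz.size == 2  # two same-spin partners
    assert np.allclose(tb.singles.p_i, 1.0 / n)


@pytest.mark.parametrize("scheme", ALL_SCHEMES, ids=pm.BENCHMARK_SCHEMES)
def test_total_probability_all_dets_all_schemes(scheme, local3_tables,
                                                local3_dets):
    """Law of total probability: sum of pgen over targets plus P(invalid) is
    one, exhaustively for every determinant of the space."""
    for det in local3_dets:
        for kind in ("single", "double"):
            targets, p_inv = brute_force_pgen(det, local3_tables, scheme, kind)
            assert sum(targets.values()) + p_inv == pytest.approx(1.0,
                                                                  abs=1e-10)


@pytest.mark.parametrize("scheme", ALL_SCHEMES, ids=pm.BENCHMARK_SCHEMES)
def test_sampler_pgen_agrees_with_enumeration(scheme, local3, local3_tables,
                                              local3_dets):
    """The pgen reported by the kernel equals the oracle's path-enumeration
    total for every reachable target (doubles and singles)."""
    for det in local3_dets[::4]:
        targets, _ = brute_force_pgen(det, local3_tables, scheme, "double")
        for tgt, p_ref in targets.items():
            exc = excitation_between(det, tgt)
            assert pgen_of_double(det, exc, local3_tables, scheme) \
                == pytest.approx(p_ref, abs=1e-12)
        targets, _ = brute_force_pgen(det, local3_tables, scheme, "single")
        for tgt, p_ref in targets.items():
            exc = excitation_between(det, tgt)
            assert pgen_of_single(det, exc.particles[0], exc.holes[0],
                                  local3_tables, scheme) \
                == pytest.approx(p_ref, abs=1e-12)


def test_unif_unif_single_pgen_is_counting(local3_tables, local3_dets):
    scheme = SchemeSpec.parse("unif:unif/unif-unif:fast-fast")
    det = local3_dets[0]
    occ = pm.occ_tuple(det)
    draw = pm.sample_single(det, local3_tables, scheme,
                            np.random.default_rng(0))
    assert draw.valid
    i = draw.excitation.particles[0]
    n_empty_sigma = 3 - sum(1 for p in occ if (p & 1) == (i & 1))
    assert draw.pgen == pytest.approx(1.0 / len(occ) / n_empty_sigma)


@pytest.mark.parametrize("schtext", ["unif:full/unif-full:fast-fast",
                                     "unif:fast/full-full:full-full"])
def test_empirical_frequencies_match_enumeration(schtext, local3_tables,
                                                 local3_dets, rng):
    scheme = SchemeSpec.parse(schtext)
    det = local3_dets[3]
    n = local3_tables.n_spin
    n_draws = 100000
    for kind in ("single", "double"):
        targets, p_inv = brute_force_pgen(det, local3_tables, scheme, kind)
        keys = sorted(targets)
        counts = dict.fromkeys(keys, 0)
        n_invalid = 0
        if kind == "single":
            res, _ = _kernel.sample_single_batch(
                np.int64(det), n, *scheme.codes[:2],
                *local3_tables.singles.kernel_args,
                local3_tables.mass_threshold, local3_tables.redraw_cap,
                n_draws, rng)
            for i, a, st in res:
                if st == 0:
                    n_invalid += 1
                else:
                    counts[int(det & ~(1 << i) | (1 << a))] += 1
        else:
            res, _ = _kernel.sample_double_batch(
                np.int64(det), n, *scheme.codes[2:],
                *local3_tables.doubles.kernel_args,
                local3_tables.mass_threshold, local3_tables.redraw_cap,
                n_draws, rng)
            for i, j, a, b, st in res:
                if st == 0:
                    n_invalid += 1
                else:
                    counts[int(det & ~(1 << i) & ~(1 << j)
                               | (1 << a) | (1 << b))] += 1
        obs = np.array([counts[k] for k in keys] + [n_invalid], dtype=float)
        expect = np.array([targets[k] for k in keys] + [p_inv]) * n_draws
        sel = expect > 0
        assert sps.chisquare(obs[sel], expect[sel]).pvalue > 1e-3


def test_exact_single_pgen_normalization(local3, local3_dets):
    basis, ints = local3
    det = local3_dets[5]
    total = 0.0
    for exc in pm.enumerate_connected(det, basis.n_spin):
        if exc.kind == "single":
            total += pm.exact_single_pgen(det, exc.holes[0], exc.particles[0],
                                          basis, ints)
    assert total == pytest.approx(1.0, abs=1e-12)


def test_exact_single_pgen_brillouin_degenerate_law_errors():
    basis, ints = pm.gen_local_integrals(4, 4, decay_len=2.0, seed=5, ms2=0)
    from pchbmc.integrals import to_mean_field_basis

    mo = to_mean_field_basis(basis, ints)
    ref = pm.reference_determinant(basis, mo)
    i = pm.occ_tuple(ref)[0]
    a = next(p for p in range(basis.n_spin)
             if not ref >> p & 1 and (p & 1) == (i & 1))
    with pytest.raises(ValueError, match="degenerate"):
        pm.exact_single_pgen(ref, a, i, basis, mo)


def test_approximate_singles_law_improves_with_locality():
    """Total-variation distance between the contracted hole law and the exact
    determinant-dependent law shrinks as the integrals localize."""
    tvs = {}
    for lam in (4.0, 1.0, 0.3):
        basis, ints = pm.gen_local_integrals(6, 6, decay_len=lam, seed=21)
        tb = pm.build_tables(basis, ints)
        det = pm.reference_determinant(basis, ints)
        vals = []
        for i in pm.occ_tuple(det):
            approx = approx_single_hole_law(det, i, tb)
            mags = np.zeros(basis.n_spin)
            for a in range(i & 1, basis.n_spin, 2):
                if det >> a & 1 or a == i:
                    continue
                exc = Excitation(particles=(i,), holes=(a,))
                mags[a] = abs(slater_condon(det, exc, ints))
            if mags.sum() < 1e-10:
                continue
            vals.append(0.5 * np.abs(mags / mags.sum() - approx).sum())
        tvs[lam] = np.mean(vals)
    assert tvs[0.3] < tvs[1.0] < tvs[4.0]


def test_locality_of_second_particle_law():
    """p(J|I) decays with spatial distance on localized integrals."""
    basis, ints = pm.gen_local_integrals(8, 8, decay_len=0.5, seed=13)
    tb = pm.build_tables(basis, ints)
    n = basis.n_spin
    row = tb.doubles.p2[0:n]  # I = first orbital, alpha
    dist = np.arange(n) >> 1
    per_orb = np.array([row[dist == d].sum() / max((dist == d).sum(), 1)
                        for d in range(8)])
    near = per_orb[:2].max()
    far = per_orb[5:].max()
    assert far < near / 10
    slope = np.polyfit(np.arange(8), np.log(per_orb + 1e-300), 1)[0]
    assert slope < 0


def test_no_starved_excitation(local3, local3_tables, local3_dets):
    """Every nonzero matrix element has nonzero pgen under every scheme."""
    _, ints = local3
    for scheme in ALL_SCHEMES:
        for det in local3_dets[::6]:
            for kind in ("single", "double"):
                targets, _ = brute_force_pgen(det, local3_tables, scheme, kind)
                for exc in pm.enumerate_connected(det, 6):
                    if exc.kind != kind:
                        continue
                    if slater_condon(det, exc, ints) == 0.0:
                        continue
                    tgt = pm.apply_excitation(det, exc)
                    assert targets.get(tgt, 0.0) > 0.0


# ---------------------------------------------------------------------------
# GAS
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def anderson():
    basis, ints = pm.gen_anderson_impurity(n_bath=3, u=4.0, hybridization=0.5,
                                           n_elec=4)
    gas = pm.GasSpec(spaces=((0,), (1, 2, 3)), min_occ=(0, 0), max_occ=(2, 6))
    return basis, ints, gas


def test_anderson_gas_bath_particle_probability_zero(anderson):
    basis, ints, gas = anderson
    gt = pm.build_tables(basis, ints, gas=gas)
    assert sorted(gt.by_supergroup) == [(0, 4), (1, 3), (2, 2)]
    tb = gt.by_supergroup[(2, 2)]
    # bath spin-orbitals can never start a valid single from a full impurity
    assert np.all(tb.singles.p_i[2:] == 0.0)
    np.testing.assert_allclose(tb.singles.p_i[:2], 0.5)


def test_gas_forbidden_excitations_have_zero_probability(anderson):
    basis, ints, gas = anderson
    gt = pm.build_tables(basis, ints, gas=gas)
    scheme = SchemeSpec.parse("unif:full/unif-full:full-full")
    det = pm.det_from_occ([0, 1, 2, 3])  # impurity full + first bath full
    tb = gt.lookup(det)
    allowed = set(gas.supergroups(basis.n_elec))
    targets, _ = brute_force_pgen(det, tb, scheme, "single")
    for tgt, p in targets.items():
        if p > 0:
            assert gas.supergroup_of(tgt, basis.n_spatial) in allowed


def test_single_space_gas_equals_plain_tables(anderson):
    basis, ints, _ = anderson
    cas = pm.GasSpec(spaces=((0, 1, 2, 3),), min_occ=(0,), max_occ=(8,))
    gt = pm.build_tables(basis, ints, gas=cas)
    tb_cas = next(iter(gt.by_supergroup.values()))
    tb = pm.build_tables(basis, ints)
    assert np.array_equal(tb_cas.doubles.W, tb.doubles.W)
    assert np.array_equal(tb_cas.singles.S, tb.singles.S)


def test_gas_spec_validation():
    with pytest.raises(ValueError):
        pm.GasSpec(spaces=((0,), (0, 1)), min_occ=(0, 0), max_occ=(2, 4))
    with pytest.raises(ValueError):
        pm.GasSpec(spaces=((0,),), min_occ=(0,), max_occ=(3,))


# ---------------------------------------------------------------------------
# spin penalty
# ---------------------------------------------------------------------------

def test_spin_penalty_prefers_opposite_spin_pairs():
    basis, ints = pm.gen_local_integrals(4, 4, decay_len=1.5, seed=11, ms2=0)
    n = basis.n_spin
    opp_mass, exch_mass = [], []
    for jpen in (0.0, 2.0, 8.0):
        tb = pm.build_tables(basis, ints, spin_penalty_j=jpen)
        row = tb.doubles.p2[0:n]
        assert row.sum() == pytest.approx(1.0, abs=1e-12)
        opp_mass.append(row[1::2].sum())
        off3 = (0 * n + 3) * n
        p3 = tb.doubles.p3[off3:off3 + n]
        exch_mass.append(p3[1] + p3[2])  # the two exchange-completing holes
    assert opp_mass[0] < opp_mass[1] < opp_mass[2]
    assert exch_mass[0] < exch_mass[1] < exch_mass[2]


# ---------------------------------------------------------------------------
# audits, uniform references, cache
# ---------------------------------------------------------------------------

def test_constrained_scheme_valid_rate_is_one(local3_tables, local3_dets, rng):
    scheme = SchemeSpec.parse("unif:full/unif-full:full-full")
    rep = pm.audit_valid_rate(local3_dets[:6], local3_tables, scheme, 20000,
                              rng)
    assert rep["singles"]["rate"] == 1.0
    assert rep["doubles"]["rate"] == 1.0


def test_fast_hole_valid_rate_below_one(hubbard4, hubbard4_tables, rng):
    # both electrons of sites 1-2 present: the weighted neighbor holes of an
    # occupied alpha are partly occupied themselves, so fast draws can miss
    basis, ints = hubbard4
    det = pm.det_from_occ([0, 1, 2, 3])
    scheme = SchemeSpec.parse("unif:fast/unif-unif:fast-fast")
    rep = pm.audit_valid_rate([det], hubbard4_tables, scheme, 20000, rng)
    assert rep["singles"]["rate"] < 1.0


def test_uniform_reference_probabilities():
    assert pm.uniform_reference(pm.OrbitalBasis(60, 60, 0)) == {
        "particle": 1.0 / 120, "empty_alpha_hole": 1.0 / 30}
    assert pm.uniform_reference(pm.OrbitalBasis(110, 14, 0))["particle"] \
        == 1.0 / 220


def test_table_cache_round_trip(tmp_path, local3, local3_tables):
    path = tmp_path / "tables.npz"
    save_tables(local3_tables, path)
    tb = load_tables(path)
    assert np.array_equal(tb.doubles.W, local3_tables.doubles.W)
    assert np.array_equal(tb.singles.p_a, local3_tables.singles.p_a)
    assert tb.basis.n_elec == local3_tables.basis.n_elec
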