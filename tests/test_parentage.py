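import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dogwoodkin as dk
from dogwoodkin import benchmarks as bm
from dogwoodkin.io import MISSING
from dogwoodkin.parentage import ScanError, _gap_scan
from dogwoodkin.similarity import UndefinedSimilarity

from conftest import M, toy_matrix


def pohl_oracle(x, y):
    num = den = 0
    for a, b in zip(x, y):
        if a == M or b == M:
            continue
        den += 1
        if (a, b) in ((0, 2), (2, 0)):
            num += 1
    return num / den if den else np.nan


def ep_oracle(p1, p2):
    out = []
    for a, b in zip(p1, p2):
        if a in (0, 2) and b in (0, 2):
            out.append((a + b) // 2)
        else:
            out.append(M)
    return np.array(out, dtype=np.int8)


# ---------------------------------------------------------------------------
# P_OHL and expected progeny
# ---------------------------------------------------------------------------

def test_pohl_examples():
    x = np.array([0, 2, 1, 0], dtype=np.int8)
    y = np.array([2, 2, 0, M], dtype=np.int8)
    assert dk.pohl(x, y, min_overlap=1) == pytest.approx(1 / 3)
    assert dk.pohl(x, x, min_overlap=1) == 0.0
    with pytest.raises(UndefinedSimilarity):
        dk.pohl(x, y, min_overlap=4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_pohl_and_ep_match_oracles(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 3, 80).astype(np.int8)
    y = rng.integers(0, 3, 80).astype(np.int8)
    x[rng.random(80) < 0.1] = M
    y[rng.random(80) < 0.1] = M
    assert dk.pohl(x, y, min_overlap=1) == pytest.approx(pohl_oracle(x, y))
    assert dk.pohl(x, y, min_overlap=1) == dk.pohl(y, x, min_overlap=1)
    if np.any(np.isin(x, (0, 2)) & np.isin(y, (0, 2))):
        assert np.array_equal(dk.expected_progeny(x, y), ep_oracle(x, y))


def test_expected_progeny_mendelian_forcing():
    p1 = np.array([0, 0, 2], dtype=np.int8)
    p2 = np.array([0, 2, 2], dtype=np.int8)
    assert dk.expected_progeny(p1, p2).tolist() == [0, 1, 2]
    with pytest.raises(UndefinedSimilarity):
        dk.expected_progeny(np.ones(5, dtype=np.int8),
                            np.ones(5, dtype=np.int8))


def test_expected_progeny_locus_count(rng):
    # p(hom) = 0.7 per parent -> EP defined at ~0.49 of loci
    m = 5000
    p1 = rng.choice([0, 1, 2], m, p=[0.35, 0.3, 0.35]).astype(np.int8)
    p2 = rng.choice([0, 1, 2], m, p=[0.35, 0.3, 0.35]).astype(np.int8)
    n_ep = (dk.expected_progeny(p1, p2) != MISSING).sum()
    assert n_ep == pytest.approx(0.49 * m, rel=0.06)


def test_true_parent_offspring_pohl_is_zero_without_error():
    mat, planted = bm.dyad_benchmark(seed=40, error_rate=0.0,
                                     missing_rate=0.0)
    for parent, child in planted:
        assert dk.pohl(mat.genotypes_of(parent),
                       mat.genotypes_of(child)) == 0.0


def test_pohl_matrix_matches_scalar(rng):
    calls = rng.integers(0, 3, size=(8, 120)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = M
    P, W = dk.pohl_matrix(calls)
    for i in range(8):
        for j in range(8):
            assert P[i, j] == pytest.approx(
                pohl_oracle(calls[i], calls[j]), nan_ok=True)


# ---------------------------------------------------------------------------
# Dixon test
# ---------------------------------------------------------------------------

def test_dixon_far_outlier_is_significant():
    rng = np.random.default_rng(0)
    comp = rng.normal(1.0, 0.01, 29)
    assert dk.dixon_test(0.0, comp, tail="min", seed=1) < 0.001
    assert dk.dixon_test(2.0, comp, tail="max", seed=1) < 0.001


def test_dixon_duplicate_minimum_not_significant():
    rng = np.random.default_rng(0)
    comp = np.sort(rng.normal(1.0, 0.05, 29))
    assert dk.dixon_test(comp[0], comp, tail="min", seed=1) > 0.05


def test_dixon_degenerate_and_wrong_tail():
    comp = np.full(29, 0.5)
    assert dk.dixon_test(0.5, comp, tail="min", seed=1) == 1.0
    comp2 = np.linspace(0, 1, 29)
    with pytest.warns(UserWarning, match="claimed tail"):
        assert dk.dixon_test(0.5, comp2, tail="min", seed=1) == 1.0
    with pytest.raises(ValueError):
        dk.dixon_test(0.0, comp2[:10], tail="min", seed=1)


def test_dixon_monte_carlo_stability():
    rng = np.random.default_rng(3)
    comp = rng.normal(0.5, 0.1, 29)
    cand = 0.1
    ps = [dk.dixon_test(cand, comp, tail="min", seed=s) for s in (1, 2, 3)]
    assert ps[0] == dk.dixon_test(cand, comp, tail="min", seed=1)
    assert max(ps) - min(ps) < 0.01


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def test_dyad_scan_recovers_planted_pairs():
    mat, planted = bm.dyad_benchmark(seed=21)
    res = dk.dyad_scan(mat, seed=5)
    sig = {frozenset(c.pair) for c in res.significant}
    want = {frozenset(p) for p in planted}
    assert len(sig & want) >= 9
    assert not sig - want
    assert res.gap_scan.p_value < 0.05
    # candidates are sorted ascending and the rule-of-thumb scale holds
    for c in res.significant:
        assert c.pohl < dk.parentage.POHL_RULE_OF_THUMB


def test_dyad_scan_error_free_pairs_all_significant():
    mat, planted = bm.dyad_benchmark(seed=22, error_rate=0.0,
                                     missing_rate=0.0)
    res = dk.dyad_scan(mat, seed=5)
    sig = {frozenset(c.pair) for c in res.significant}
    assert sig == {frozenset(p) for p in planted}
    assert all(c.pohl == 0.0 for c in res.significant)


def test_dyad_scan_roles_and_clone_exclusion():
    mat, planted = bm.dyad_benchmark(seed=23)
    parent, child = planted[0]
    meta = {a: dk.AccessionMeta(a, "all") for a in mat.accessions}
    meta[parent] = dk.AccessionMeta(parent, "parent", date=1950)
    meta[child] = dk.AccessionMeta(child, "offspring", date=1990)
    res = dk.dyad_scan(mat, meta=meta, seed=5)
    hit = [c for c in res.significant if frozenset(c.pair) ==
           frozenset((parent, child))]
    assert hit and hit[0].orientation == (parent, child)
    # excluding the pair as a clone group removes it from candidacy
    cg = dk.CloneGroups(groups=[[parent, child]], threshold=0.995,
                        representatives=[parent])
    res2 = dk.dyad_scan(mat, clones=cg, seed=5)
    assert all(frozenset(c.pair) != frozenset((parent, child))
               for c in res2.candidates)


def test_dyad_scan_too_few_pairs():
    mat, _ = bm.dyad_benchmark(seed=24)
    small = mat.take_accessions(mat.accessions[:6])
    with pytest.raises(ScanError):
        dk.dyad_scan(small, seed=1)


def test_structure_warning_on_two_pool_population():
    """Two strongly differentiated subspecies pools: within-pool pairs share
    most background, depressing P_OHL below 0.02 for many pairs."""
    from dogwoodkin.simulate import (PoolSpec, SimConfig, apply_error_model,
                                     individuals_to_matrix, simulate_founders)
    config = SimConfig(
        n_contigs=5, markers_per_contig=100,
        n_species_diagnostic_per_contig=0,
        n_subspecies_diagnostic_per_contig=90,
        pools={"kousa_chinensis": PoolSpec("kousa", 25),
               "kousa_kousa": PoolSpec("kousa", 5)},
        seed=7)
    fs = simulate_founders(config)
    inds = {i.id: i for pool in fs.founders.values() for i in pool}
    mat = apply_error_model(individuals_to_matrix(inds, fs.marker_map),
                            0.003, 0.02, np.random.default_rng(8))
    with pytest.warns(UserWarning, match="population structure"):
        res = dk.dyad_scan(mat, seed=5)
    assert res.structure_warning


def test_triad_scan_recovers_planted_trios():
    mat, planted = bm.triad_benchmark(seed=31)
    res = dk.triad_scan(mat, seed=5)
    sig = {(frozenset(c.parents), c.offspring) for c in res.significant}
    want = {(frozenset((a, b)), o) for a, b, o in planted}
    assert len(sig & want) >= 9
    assert not sig - want


def test_triad_scan_error_free_gd_zero():
    mat, planted = bm.triad_benchmark(seed=32, n_unrelated=30, n_trios=5,
                                      error_rate=0.0, missing_rate=0.0)
    res = dk.triad_scan(mat, seed=5)
    by_key = {(frozenset(c.parents), c.offspring): c for c in res.candidates}
    for a, b, o in planted:
        c = by_key[(frozenset((a, b)), o)]
        assert c.gd == 0.0 and c.significant


def test_gap_scan_locates_planted_gap():
    rng = np.random.default_rng(1)
    values = np.concatenate([np.full(5, 0.001), 0.05 + 0.01 * rng.random(95)])
    scan = _gap_scan(values, rng, null_seed=0, n_reps=20_000)
    assert scan.n_below == 5
    assert scan.p_value < 0.05
    assert scan.gap_index < len(scan.gaps) // 2
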