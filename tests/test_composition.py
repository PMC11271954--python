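import math

import numpy as np
import pandas as pd
import pytest

import dogwoodkin as dk
from dogwoodkin import benchmarks as bm
from dogwoodkin.composition import PanelError, SpeciesPanel, _l_values
from dogwoodkin.io import MISSING

from conftest import M, toy_matrix


def make_panel(species, ids, alleles, positions=None, contig="chr1",
               call_rate=1.0):
    n = len(ids)
    return SpeciesPanel(species=species, markers=pd.DataFrame({
        "id": ids,
        "contig": [contig] * n,
        "position": positions if positions is not None
        else [100 * (i + 1) for i in range(n)],
        "species_allele": alleles,
        "call_rate": [call_rate] * n,
    }))


def l_oracle(calls, alt_is_species):
    """Per-locus L scoring by explicit case analysis."""
    out = []
    for c, alt in zip(calls, alt_is_species):
        if c == M:
            out.append(0.0)
        elif c == 1:
            out.append(0.5)
        else:
            hom_species = (c == 2) == alt
            out.append(1.0 if hom_species else 0.0)
    return np.array(out)


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------

def three_group_fixture():
    # 6 markers x 6 accessions (2 refs per species)
    # mk0: kousa-specific (kousa 0/0, others 2/2) -> species allele = ref
    # mk1: florida-specific via alt
    # mk2: het in one reference -> excluded
    # mk3: all groups fixed same -> excluded
    # mk4: polymorphic within kousa -> excluded
    # mk5: nuttallii-specific
    calls = np.array([
        # fl1 fl2 ko1 ko2 nu1 nu2
        [2, 2, 0, 0, 2, 2],   # mk0
        [2, 2, 0, 0, 0, 0],   # mk1
        [2, 2, 1, 0, 0, 0],   # mk2
        [0, 0, 0, 0, 0, 0],   # mk3
        [2, 2, 0, 2, 0, 0],   # mk4
        [0, 0, 0, 0, 2, 2],   # mk5
    ], dtype=np.int8).T
    mat = toy_matrix(calls, accessions=["fl1", "fl2", "ko1", "ko2",
                                        "nu1", "nu2"])
    groups = {"florida": ["fl1", "fl2"], "kousa": ["ko1", "ko2"],
              "nuttallii": ["nu1", "nu2"]}
    return mat, groups


def test_select_species_markers_odd_group_out():
    mat, groups = three_group_fixture()
    panels = dk.select_species_markers(mat, groups)
    assert list(panels["kousa"].markers["id"]) == ["mk0"]
    assert panels["kousa"].markers["species_allele"].iloc[0] == "ref"
    assert list(panels["florida"].markers["id"]) == ["mk1"]
    assert panels["florida"].markers["species_allele"].iloc[0] == "alt"
    assert list(panels["nuttallii"].markers["id"]) == ["mk5"]
    # panels are disjoint
    ids = [set(p.markers["id"]) for p in panels.values()]
    assert not (ids[0] & ids[1]) and not (ids[0] & ids[2])


def test_select_species_markers_validation():
    mat, groups = three_group_fixture()
    groups["kousa"] = ["ko1"]
    with pytest.raises(PanelError):
        dk.select_species_markers(mat, groups)


def test_select_species_markers_recovers_planted_panels(rng):
    noisy, truth, refs, clean = bm.backcross_cohort(seed=13, n_bc2=2,
                                                    loci_per_species=300)
    panels = dk.select_species_markers(noisy, refs)
    fs_truth = {sp: set(df["id"]) for sp, df in
                _planted_truth(seed=13).items()}
    for sp, panel in panels.items():
        got = set(panel.markers["id"])
        assert got <= fs_truth[sp]          # no false diagnostic markers
        assert len(got) > 0.85 * len(fs_truth[sp])  # most survive the noise


def _planted_truth(seed):
    from dogwoodkin.benchmarks import hybrid_config
    from dogwoodkin.simulate import simulate_founders
    config = hybrid_config(loci_per_species=300, n_kousa_founders=14,
                           seed=seed)
    return simulate_founders(config).species_truth


def test_panel_fixation_reverifiable_from_matrix():
    noisy, truth, refs, clean = bm.backcross_cohort(seed=14, n_bc2=2,
                                                    loci_per_species=300,
                                                    error_rate=0.0,
                                                    missing_rate=0.0)
    panels = dk.select_species_markers(clean, refs)
    lookup = pd.Series(np.arange(clean.n_markers),
                       index=clean.markers["id"])
    for sp, panel in panels.items():
        cols = lookup[panel.markers["id"]].to_numpy()
        own = clean.calls[np.ix_([clean.accession_index(a)
                                  for a in refs[sp]], cols)]
        alt_is_sp = (panel.markers["species_allele"] == "alt").to_numpy()
        assert np.all(own == np.where(alt_is_sp, 2, 0))


# ---------------------------------------------------------------------------
# Panel equalization
# ---------------------------------------------------------------------------

def test_equalize_panels_to_smallest():
    rng = np.random.default_rng(0)
    panels = {}
    for sp, n in (("florida", 40), ("kousa", 35), ("nuttallii", 28)):
        panels[sp] = make_panel(
            sp, [f"{sp}{i}" for i in range(n)], ["alt"] * n,
            positions=sorted(rng.choice(range(1, 20000), n, replace=False)),
            call_rate=1.0)
        panels[sp].markers["call_rate"] = rng.uniform(0.8, 1.0, n)
    eq = dk.equalize_panels(panels)
    assert {len(p) for p in eq.values()} == {28}
    # already-equal panels pass through unchanged
    again = dk.equalize_panels(eq)
    for sp in eq:
        assert again[sp].markers.equals(eq[sp].markers)


def test_equalize_window_cap_removes_lowest_call_rate():
    # 5 markers in one 500-bp bin, cap 3: the 2 lowest call rates go first
    big = make_panel("florida", [f"f{i}" for i in range(5)], ["alt"] * 5,
                     positions=[10, 20, 30, 40, 450])
    big.markers["call_rate"] = [0.99, 0.80, 0.95, 0.85, 0.90]
    small = make_panel("kousa", ["k0", "k1", "k2"], ["alt"] * 3)
    eq = dk.equalize_panels({"florida": big, "kousa": small})
    assert list(eq["florida"].markers["id"]) == ["f0", "f2", "f4"]
    assert len(eq["kousa"]) == 3


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def pure_fixture():
    # 2 markers per species panel; accession hom for kousa alleles
    ids = ["f0", "f1", "k0", "k1", "n0", "n1"]
    calls = np.array([[0, 0, 2, 2, 0, 0],     # pure kousa
                      [1, 1, 1, 1, 0, 0]],    # F1 kousa x florida
                     dtype=np.int8)
    mat = toy_matrix(calls, accessions=["pure_k", "f1_hyb"])
    mat.markers["id"] = ids
    panels = {
        "florida": make_panel("florida", ["f0", "f1"], ["alt", "alt"]),
        "kousa": make_panel("kousa", ["k0", "k1"], ["alt", "alt"]),
        "nuttallii": make_panel("nuttallii", ["n0", "n1"], ["alt", "alt"]),
    }
    return mat, panels


def test_composition_pure_and_f1():
    mat, panels = pure_fixture()
    pure = dk.composition(mat, "pure_k", panels)
    assert pure.percentages == {"florida": 0.0, "kousa": 100.0,
                                "nuttallii": 0.0}
    f1 = dk.composition(mat, "f1_hyb", panels)
    assert f1.percentages["kousa"] == pytest.approx(50.0)
    assert f1.percentages["florida"] == pytest.approx(50.0)
    assert f1.percentages["nuttallii"] == 0.0
    assert sum(f1.percentages.values()) == pytest.approx(100.0)


def test_composition_zero_signal_flagged():
    mat, panels = pure_fixture()
    zero = mat.take_accessions(["pure_k"])
    zero.calls[:] = M
    res = dk.composition(zero, "pure_k", panels)
    assert not res.defined
    assert all(math.isnan(v) for v in res.percentages.values())


def test_composition_matches_per_locus_oracle(rng):
    noisy, truth, refs, clean = bm.backcross_cohort(seed=15, n_bc2=5,
                                                    loci_per_species=300)
    panels = dk.equalize_panels(dk.select_species_markers(noisy, refs))
    lookup = pd.Series(np.arange(noisy.n_markers), index=noisy.markers["id"])
    acc = "BC2_03"
    sums = {}
    for sp, panel in panels.items():
        cols = lookup[panel.markers["id"]].to_numpy()
        calls = noisy.genotypes_of(acc)[cols]
        alt_is_sp = (panel.markers["species_allele"] == "alt").to_numpy()
        sums[sp] = l_oracle(calls, alt_is_sp).sum()
    res = dk.composition(noisy, acc, panels)
    total = sum(sums.values())
    for sp in panels:
        assert res.l_sums[sp] == pytest.approx(sums[sp])
        assert res.percentages[sp] == pytest.approx(100 * sums[sp] / total)


def test_composition_invariant_under_marker_permutation(rng):
    mat, panels = pure_fixture()
    shuffled = {}
    for sp, p in panels.items():
        perm = p.markers.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled[sp] = SpeciesPanel(sp, perm)
    a = dk.composition(mat, "f1_hyb", panels).percentages
    b = dk.composition(mat, "f1_hyb", shuffled).percentages
    assert a == b


# ---------------------------------------------------------------------------
# Introgression segments
# ---------------------------------------------------------------------------

def test_segments_min_run_and_singletons():
    # panel of 8 loci on one contig; donor carrier runs: [3 loci], [1 locus]
    calls = np.array([[1, 1, 1, 0, 0, 1, 0, 0]], dtype=np.int8)
    mat = toy_matrix(calls, accessions=["x"],
                     positions=[100, 200, 300, 400, 500, 600, 700, 800])
    mat.markers["id"] = [f"d{i}" for i in range(8)]
    panel = make_panel("nuttallii", [f"d{i}" for i in range(8)], ["alt"] * 8,
                       positions=[100, 200, 300, 400, 500, 600, 700, 800])
    rep = dk.introgression_segments(mat, "x", {"nuttallii": panel},
                                    min_run=3)
    assert len(rep.segments) == 1
    seg = rep.segments[0]
    assert (seg.start, seg.end, seg.n_loci, seg.zygosity) == (100, 300, 3,
                                                              "all-het")
    assert len(rep.singletons) == 1
    assert rep.singletons["position"].iloc[0] == 600


def test_segments_hom_block_zygosity_and_contig_boundary():
    calls = np.array([[2, 2, 2, 1, 1, 1]], dtype=np.int8)
    mat = toy_matrix(calls, accessions=["x"],
                     contigs=["c1", "c1", "c1", "c2", "c2", "c2"],
                     positions=[100, 200, 300, 100, 200, 300])
    mat.markers["id"] = [f"d{i}" for i in range(6)]
    panel = SpeciesPanel("nuttallii", pd.DataFrame({
        "id": [f"d{i}" for i in range(6)],
        "contig": ["c1", "c1", "c1", "c2", "c2", "c2"],
        "position": [100, 200, 300, 100, 200, 300],
        "species_allele": ["alt"] * 6,
        "call_rate": [1.0] * 6,
    }))
    rep = dk.introgression_segments(mat, "x", {"nuttallii": panel},
                                    min_run=3)
    assert len(rep.segments) == 2  # never a segment across the boundary
    zyg = {s.contig: s.zygosity for s in rep.segments}
    assert zyg == {"c1": "all-hom", "c2": "all-het"}


def test_segment_caller_matches_truth_blocks():
    noisy, truth, refs, clean = bm.backcross_cohort(
        seed=16, n_bc2=5, loci_per_species=300, error_rate=0.0,
        missing_rate=0.0)
    panels = dk.select_species_markers(clean, refs)
    panel = panels["nuttallii"]
    lookup = pd.Series(np.arange(clean.n_markers), index=clean.markers["id"])
    for acc in [a for a in clean.accessions if a.startswith("BC2")]:
        rep = dk.introgression_segments(clean, acc, {"nuttallii": panel},
                                        min_run=3)
        donor = truth.donor_mask(acc, "nuttallii")
        # recompute truth runs over panel loci per contig
        expected = []
        for contig, sub in panel.markers.groupby("contig", sort=False):
            sub = sub.sort_values("position")
            carrier = donor[lookup[sub["id"]].to_numpy()]
            pos = sub["position"].to_numpy()
            i = 0
            while i < len(carrier):
                if carrier[i]:
                    j = i
                    while j + 1 < len(carrier) and carrier[j + 1]:
                        j += 1
                    if j - i + 1 >= 3:
                        expected.append((contig, pos[i], pos[j], j - i + 1))
                    i = j + 1
                else:
                    i += 1
        got = [(s.contig, s.start, s.end, s.n_loci) for s in rep.segments]
        assert got == expected


# ---------------------------------------------------------------------------
# Coverage gaps
# ---------------------------------------------------------------------------

def test_panel_coverage_gaps():
    # equally spaced 1 Mb apart -> no gaps >= 3 Mb
    dense = make_panel("florida", [f"f{i}" for i in range(10)],
                       ["alt"] * 10,
                       positions=[i * 1_000_000 + 1 for i in range(10)])
    res = dk.panel_coverage_gaps(dense)
    assert all(v == 0 for v in res["counts"].values())
    # planted 6 Mb void -> one gap in the 5+ bin
    sparse = make_panel("florida", ["a", "b", "c"], ["alt"] * 3,
                        positions=[1_000_000, 2_000_000, 8_000_000])
    res2 = dk.panel_coverage_gaps(sparse)
    assert res2["counts"][(5.0, math.inf)] == 1
    assert res2["counts"][(3.0, 5.0)] == 0
    assert res2["max_gap_mb"] == pytest.approx(6.0)
    # a contig with < 2 loci is skipped
    single = make_panel("kousa", ["z"], ["alt"], positions=[5])
    res3 = dk.panel_coverage_gaps(single)
    assert res3["max_gap_mb"] == 0.0
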