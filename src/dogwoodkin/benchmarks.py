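"""Standard synthetic study conditions used by the test suite and examples.

Each builder fixes the marker composition, sample sizes, and noise levels of
one benchmark population and returns the simulated matrix together with its
ground truth. All are deterministic under their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .pedigree import PedigreeNode, backcross_chain
from .simulate import (
    FounderSet,
    PoolSpec,
    SimConfig,
    SimTruth,
    apply_error_model,
    apply_pedigree,
    individuals_to_matrix,
    simulate_founders,
)


def background_only_config(n_markers: int = 3000, pool: str = "kousa_kousa",
                           n_founders: int = 100, seed: int = 0,
                           error_rate: float = 0.003,
                           missing_rate: float = 0.02) -> SimConfig:
    """A single-pool population with only polymorphic background markers --
    the regime of a within-species diversity panel."""
    if n_markers % 10:
        raise ValueError("n_markers must be a multiple of 10 contigs")
    return SimConfig(
        n_contigs=10,
        markers_per_contig=n_markers // 10,
        n_species_diagnostic_per_contig=0,
        n_subspecies_diagnostic_per_contig=0,
        pools={pool: PoolSpec("kousa", n_founders)},
        error_rate=error_rate,
        missing_rate=missing_rate,
        seed=seed,
    )


def clone_pairs_benchmark(seed: int, n_pairs: int = 200,
                          n_markers: int = 3000,
                          error_rate: float = 0.003,
                          missing_rate: float = 0.02,
                          ) -> tuple[GenotypeMatrix, SimTruth]:
    """``n_pairs`` founders each with one clone, plus genotyping noise.

    Every (founder, clone) pair is a true clone pair; founder-founder pairs
    are unrelated.
    """
    config = background_only_config(n_markers=n_markers, n_founders=n_pairs,
                                    seed=seed, error_rate=error_rate,
                                    missing_rate=missing_rate)
    founder_set = simulate_founders(config)
    nodes = []
    for i in range(n_pairs):
        nodes.append(PedigreeNode(f"F{i:03d}", "founder", species="kousa"))
        nodes.append(PedigreeNode(f"C{i:03d}", "clone", parents=(f"F{i:03d}",)))
    clean, truth = apply_pedigree(nodes, founder_set, seed=seed + 1)
    noisy = apply_error_model(clean, error_rate, missing_rate,
                              np.random.default_rng(seed + 2))
    return noisy, truth


def dyad_benchmark(seed: int, n_unrelated: int = 60, n_pairs: int = 10,
                   n_markers: int = 3000, error_rate: float = 0.003,
                   missing_rate: float = 0.02,
                   ) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """The standard dyad power benchmark.

    ``n_unrelated`` unrelated accessions plus ``n_pairs`` parent-offspring
    pairs whose second parents are withheld from the output matrix (so each
    planted pair is a dyad, not a triad). Returns the noisy matrix and the
    list of planted (parent, offspring) id pairs.
    """
    n_founders = n_unrelated + 2 * n_pairs  # parents + hidden mates
    config = background_only_config(n_markers=n_markers, n_founders=n_founders,
                                    seed=seed, error_rate=error_rate,
                                    missing_rate=missing_rate)
    founder_set = simulate_founders(config)
    nodes = [PedigreeNode(f"U{i:02d}", "founder", species="kousa")
             for i in range(n_unrelated)]
    planted = []
    for i in range(n_pairs):
        nodes.append(PedigreeNode(f"P{i:02d}", "founder", species="kousa"))
        nodes.append(PedigreeNode(f"H{i:02d}", "founder", species="kousa"))
        nodes.append(PedigreeNode(f"O{i:02d}", "cross",
                                  parents=(f"P{i:02d}", f"H{i:02d}")))
        planted.append((f"P{i:02d}", f"O{i:02d}"))
    clean, truth = apply_pedigree(nodes, founder_set, seed=seed + 1)
    visible = [a for a in clean.accessions if not a.startswith("H")]
    clean = clean.take_accessions(visible)
    noisy = apply_error_model(clean, error_rate, missing_rate,
                              np.random.default_rng(seed + 2))
    return noisy, planted


def unrelated_benchmark(seed: int, n_accessions: int = 60,
                        n_markers: int = 3000, error_rate: float = 0.003,
                        missing_rate: float = 0.02) -> GenotypeMatrix:
    """A fully unrelated population (no planted relationships)."""
    config = background_only_config(n_markers=n_markers,
                                    n_founders=n_accessions, seed=seed,
                                    error_rate=error_rate,
                                    missing_rate=missing_rate)
    founder_set = simulate_founders(config)
    inds = {ind.id: ind for ind in founder_set.founders["kousa_kousa"]}
    clean = individuals_to_matrix(inds, founder_set.marker_map)
    return apply_error_model(clean, error_rate, missing_rate,
                             np.random.default_rng(seed + 2))


def triad_benchmark(seed: int, n_unrelated: int = 60, n_trios: int = 10,
                    n_markers: int = 3000, error_rate: float = 0.003,
                    missing_rate: float = 0.02,
                    ) -> tuple[GenotypeMatrix, list[tuple[str, str, str]]]:
    """The standard triad power benchmark: both parents of each planted
    offspring are present. Returns the noisy matrix and the planted
    (parent1, parent2, offspring) triples."""
    n_founders = n_unrelated + 2 * n_trios
    config = background_only_config(n_markers=n_markers, n_founders=n_founders,
                                    seed=seed, error_rate=error_rate,
                                    missing_rate=missing_rate)
    founder_set = simulate_founders(config)
    nodes = [PedigreeNode(f"U{i:02d}", "founder", species="kousa")
             for i in range(n_unrelated)]
    planted = []
    for i in range(n_trios):
        a, b, o = f"Pa{i:02d}", f"Pb{i:02d}", f"O{i:02d}"
        nodes.append(PedigreeNode(a, "founder", species="kousa"))
        nodes.append(PedigreeNode(b, "founder", species="kousa"))
        nodes.append(PedigreeNode(o, "cross", parents=(a, b)))
        planted.append((a, b, o))
    clean, truth = apply_pedigree(nodes, founder_set, seed=seed + 1)
    noisy = apply_error_model(clean, error_rate, missing_rate,
                              np.random.default_rng(seed + 2))
    return noisy, planted


def hybrid_config(loci_per_species: int = 2703, n_kousa_founders: int = 70,
                  seed: int = 0, error_rate: float = 0.003,
                  missing_rate: float = 0.02) -> SimConfig:
    """Interspecific regime: species-diagnostic loci only, matching the
    scale of an ancestry-informative marker panel (default 2703 per
    species)."""
    n_contigs = 10
    per_contig = -(-3 * loci_per_species // n_contigs)  # ceil
    return SimConfig(
        n_contigs=n_contigs,
        markers_per_contig=per_contig,
        n_species_diagnostic_per_contig=per_contig,
        n_subspecies_diagnostic_per_contig=0,
        pools={
            "florida": PoolSpec("florida", 12),
            "kousa": PoolSpec("kousa", n_kousa_founders),
            "nuttallii": PoolSpec("nuttallii", 8),
        },
        error_rate=error_rate,
        missing_rate=missing_rate,
        seed=seed,
    )


def backcross_cohort(seed: int, n_bc2: int = 50,
                     loci_per_species: int = 2703,
                     error_rate: float = 0.003, missing_rate: float = 0.02,
                     reference_sizes: tuple[int, int, int] = (10, 10, 6),
                     ) -> tuple[GenotypeMatrix, SimTruth,
                                dict[str, list[str]], GenotypeMatrix]:
    """A BC2 cohort with species reference accessions.

    One *C. kousa* x *C. nuttallii* F1 is backcrossed to fresh kousa
    founders; its BC1 offspring is backcrossed again to give ``n_bc2``
    independent BC2 individuals. Returns (noisy matrix, truth, reference
    groups, clean matrix).
    """
    config = hybrid_config(loci_per_species=loci_per_species,
                           n_kousa_founders=reference_sizes[1] + n_bc2 + 2,
                           seed=seed, error_rate=error_rate,
                           missing_rate=missing_rate)
    founder_set = simulate_founders(config)

    nf, nk, nn = reference_sizes
    nodes = []
    refs: dict[str, list[str]] = {"florida": [], "kousa": [], "nuttallii": []}
    for i in range(nf):
        nodes.append(PedigreeNode(f"Fref{i:02d}", "founder", species="florida"))
        refs["florida"].append(f"Fref{i:02d}")
    for i in range(nk):
        nodes.append(PedigreeNode(f"Kref{i:02d}", "founder", species="kousa"))
        refs["kousa"].append(f"Kref{i:02d}")
    for i in range(nn):
        nodes.append(PedigreeNode(f"Nref{i:02d}", "founder", species="nuttallii"))
        refs["nuttallii"].append(f"Nref{i:02d}")

    nodes.append(PedigreeNode("K0", "founder", species="kousa"))
    nodes.append(PedigreeNode("N0", "founder", species="nuttallii"))
    nodes.append(PedigreeNode("F1", "cross", parents=("K0", "N0")))
    nodes.append(PedigreeNode("K1", "founder", species="kousa"))
    nodes.append(PedigreeNode("BC1", "cross", parents=("F1", "K1")))
    for i in range(n_bc2):
        nodes.append(PedigreeNode(f"K2_{i:02d}", "founder", species="kousa"))
        nodes.append(PedigreeNode(f"BC2_{i:02d}", "cross",
                                  parents=("BC1", f"K2_{i:02d}")))
    clean, truth = apply_pedigree(nodes, founder_set, seed=seed + 1)
    noisy = apply_error_model(clean, error_rate, missing_rate,
                              np.random.default_rng(seed + 2))
    return noisy, truth, refs, clean


def subspecies_benchmark(seed: int, n_per_class: int = 20,
                         n_refs: int = 4, n_diagnostic_per_contig: int = 30,
                         error_rate: float = 0.003,
                         missing_rate: float = 0.02,
                         ) -> tuple[GenotypeMatrix, dict[str, list[str]],
                                    dict[str, str]]:
    """Subspecies classification benchmark.

    ``n_per_class`` pure chinensis, pure kousa, and F1 subspecies-hybrid
    accessions plus ``n_refs`` reference accessions per subspecies. Returns
    the noisy matrix, the reference id groups, and the true class of every
    non-reference accession.
    """
    config = SimConfig(
        n_contigs=10,
        markers_per_contig=300,
        n_species_diagnostic_per_contig=0,
        n_subspecies_diagnostic_per_contig=n_diagnostic_per_contig,
        pools={
            "kousa_chinensis": PoolSpec("kousa", n_refs + n_per_class * 2),
            "kousa_kousa": PoolSpec("kousa", n_refs + n_per_class * 2),
        },
        error_rate=error_rate,
        missing_rate=missing_rate,
        seed=seed,
    )
    founder_set = simulate_founders(config)
    nodes = []
    refs = {"chinensis": [], "kousa": []}
    for i in range(n_refs):
        nodes.append(PedigreeNode(f"Cref{i:02d}", "founder",
                                  species="kousa_chinensis"))
        refs["chinensis"].append(f"Cref{i:02d}")
        nodes.append(PedigreeNode(f"Kref{i:02d}", "founder",
                                  species="kousa_kousa"))
        refs["kousa"].append(f"Kref{i:02d}")
    true_class = {}
    for i in range(n_per_class):
        c, k, h = f"C{i:02d}", f"K{i:02d}", f"H{i:02d}"
        nodes.append(PedigreeNode(c, "founder", species="kousa_chinensis"))
        nodes.append(PedigreeNode(k, "founder", species="kousa_kousa"))
        nodes.append(PedigreeNode(f"Cm{i:02d}", "founder",
                                  species="kousa_chinensis"))
        nodes.append(PedigreeNode(f"Km{i:02d}", "founder",
                                  species="kousa_kousa"))
        nodes.append(PedigreeNode(h, "cross",
                                  parents=(f"Cm{i:02d}", f"Km{i:02d}")))
        true_class[c] = "chinensis"
        true_class[k] = "kousa"
        true_class[h] = "hybrid"
    clean, truth = apply_pedigree(nodes, founder_set, seed=seed + 1)
    noisy = apply_error_model(clean, error_rate, missing_rate,
                              np.random.default_rng(seed + 2))
    return noisy, refs, true_class
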