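"""Pedigreed genotype simulator with tracked ancestry.

Emulates the data regime the analyses in this package assume: three species
pools (*C. florida*, *C. kousa*, *C. nuttallii*) with fixed species-
diagnostic alleles, two *C. kousa* subspecies pools with fixed
subspecies-diagnostic alleles over a shared polymorphic background,
Mendelian meiosis with Poisson crossovers, clones/sports, and a RADseq-like
genotyping error and missingness model. Phase and per-locus founder-species
ancestry are tracked internally so simulated accessions come with ground
truth (realized ancestry fractions, donor blocks, clone groups).

The error model directions are deliberately asymmetric -- a homozygote can
only be miscalled as a heterozygote, and a heterozygote as either homozygote
-- so that a single miscall can never turn a true parent-offspring locus
into an opposite-homozygote pair, reproducing the empirical scale of
true-dyad P_OHL (a few per mille) and true-clone GS (just under 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .pedigree import PedigreeError, PedigreeNode, topological_order

SPECIES = ("florida", "kousa", "nuttallii")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PoolSpec:
    """A founder pool: which species it belongs to and how many founders."""

    species: str
    n_founders: int

    def __post_init__(self):
        if self.species not in SPECIES:
            raise SimulationError(f"unknown species {self.species!r}")
        if self.n_founders < 1:
            raise SimulationError("pool needs at least one founder")


def _default_pools() -> dict[str, PoolSpec]:
    return {
        "florida": PoolSpec("florida", 10),
        "kousa_chinensis": PoolSpec("kousa", 10),
        "kousa_kousa": PoolSpec("kousa", 10),
        "nuttallii": PoolSpec("nuttallii", 6),
    }


@dataclass
class SimConfig:
    """Simulation parameters.

    Marker counts are per contig; ``n_species_diagnostic_per_contig`` is
    split as evenly as possible across the three species. Whatever remains
    of ``markers_per_contig`` after the diagnostic loci is polymorphic
    background with per-species allele frequencies drawn from
    ``Beta(*background_beta)`` (the two kousa subspecies pools share their
    background frequencies). Crossovers per contig per meiosis are Poisson
    with mean ``crossover_rate`` at uniform positions. ``error_rate`` and
    ``missing_rate`` are per-call probabilities.
    """

    n_contigs: int = 10
    contig_length_bp: int = 10_000_000
    markers_per_contig: int = 300
    n_species_diagnostic_per_contig: int = 270
    n_subspecies_diagnostic_per_contig: int = 30
    pools: dict[str, PoolSpec] = field(default_factory=_default_pools)
    background_beta: tuple[float, float] = (0.8, 0.8)
    crossover_rate: float = 1.5
    error_rate: float = 0.003
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        n_diag = (self.n_species_diagnostic_per_contig
                  + self.n_subspecies_diagnostic_per_contig)
        if n_diag > self.markers_per_contig:
            raise SimulationError(
                "diagnostic marker counts exceed markers_per_contig")
        if self.n_subspecies_diagnostic_per_contig > 0:
            kousa_pools = [p for p in self.pools.values()
                           if p.species == "kousa"]
            if len(kousa_pools) != 2:
                raise SimulationError(
                    "subspecies-diagnostic markers need exactly two kousa "
                    "pools")

    @property
    def n_background_per_contig(self) -> int:
        return (self.markers_per_contig
                - self.n_species_diagnostic_per_contig
                - self.n_subspecies_diagnostic_per_contig)


@dataclass
class Individual:
    """Phased genotype with per-haplotype founder-species ancestry labels.

    ``haplotypes`` is ``(2, n_markers)`` of 0/1 alt-allele indicators;
    ``ancestry`` is ``(2, n_markers)`` of indices into :data:`SPECIES`.
    """

    id: str
    haplotypes: np.ndarray
    ancestry: np.ndarray
    pool: str | None = None

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int8)


@dataclass
class FounderSet:
    """Founder individuals plus the marker map and planted diagnostic truth."""

    config: SimConfig
    marker_map: pd.DataFrame  # id, contig, position, ref, alt, role
    founders: dict[str, list[Individual]]  # pool -> individuals
    species_truth: dict[str, pd.DataFrame]  # species -> id/contig/position/species_allele
    subspecies_truth: pd.DataFrame  # id, chinensis_allele, kousa_allele

    def individual(self, accession: str) -> Individual:
        for pool in self.founders.values():
            for ind in pool:
                if ind.id == accession:
                    return ind
        raise KeyError(accession)

    @property
    def contig_slices(self) -> list[tuple[str, slice]]:
        out = []
        contigs = self.marker_map["contig"].to_numpy()
        start = 0
        for i in range(1, len(contigs) + 1):
            if i == len(contigs) or contigs[i] != contigs[start]:
                out.append((contigs[start], slice(start, i)))
                start = i
        return out


@dataclass
class SimTruth:
    """Ground truth emitted next to a simulated genotype matrix."""

    pedigree: list[PedigreeNode]
    clone_groups: list[list[str]]
    realized_ancestry: pd.DataFrame  # accession x species, percentages
    individuals: dict[str, Individual]
    marker_map: pd.DataFrame

    def donor_mask(self, accession: str, species: str) -> np.ndarray:
        """Boolean per-marker mask: accession carries >= 1 haplotype of
        ``species`` ancestry at the locus."""
        code = SPECIES.index(species)
        return (self.individuals[accession].ancestry == code).any(axis=0)


def _split_across_species(n: int) -> dict[str, int]:
    base, extra = divmod(n, len(SPECIES))
    return {sp: base + (1 if i < extra else 0)
            for i, sp in enumerate(SPECIES)}


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None) -> FounderSet:
    """Simulate the founder pools and the marker map.

    Species-diagnostic loci are fixed homozygous for the species allele in
    the owning species' pools and for the other allele everywhere else;
    subspecies-diagnostic loci likewise separate the two kousa pools.
    Background loci are in Hardy-Weinberg proportions within pools.
    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m_per = config.markers_per_contig
    n_total = m_per * config.n_contigs
    spec_counts = _split_across_species(config.n_species_diagnostic_per_contig)

    contigs, positions, roles = [], [], []
    for c in range(config.n_contigs):
        name = f"contig{c:02d}"
        pos = np.sort(rng.choice(
            np.arange(1, config.contig_length_bp + 1), size=m_per,
            replace=False))
        role = np.array(
            [f"diag_{sp}" for sp in SPECIES for _ in range(spec_counts[sp])]
            + ["diag_ssp"] * config.n_subspecies_diagnostic_per_contig
            + ["background"] * config.n_background_per_contig)
        rng.shuffle(role)
        contigs.extend([name] * m_per)
        positions.append(pos)
        roles.append(role)
    positions = np.concatenate(positions)
    roles = np.concatenate(roles)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_total)) % 4
    marker_map = pd.DataFrame({
        "id": [f"m{k:05d}" for k in range(n_total)],
        "contig": contigs,
        "position": positions,
        "ref": bases[ref_idx],
        "alt": bases[alt_idx],
        "role": roles,
    })

    # orientation of the diagnostic allele (True: alt is the marked allele)
    alt_is_marked = rng.random(n_total) < 0.5
    # per-species background allele frequencies (kousa pools share)
    bg = roles == "background"
    freqs = {sp: np.where(bg, rng.beta(*config.background_beta, n_total), 0.0)
             for sp in SPECIES}

    founders: dict[str, list[Individual]] = {}
    for pool_name, spec in config.pools.items():
        hap_freq = np.zeros(n_total)
        hap_freq[bg] = freqs[spec.species][bg]
        for sp in SPECIES:
            d = roles == f"diag_{sp}"
            marked = np.where(alt_is_marked, 1.0, 0.0)
            own = spec.species == sp
            hap_freq[d] = (marked if own else 1.0 - marked)[d]
        dssp = roles == "diag_ssp"
        if dssp.any():
            # chinensis pool carries the marked allele, every other pool the
            # alternative
            chin = pool_name == "kousa_chinensis"
            marked = np.where(alt_is_marked, 1.0, 0.0)
            hap_freq[dssp] = (marked if chin else 1.0 - marked)[dssp]
        code = SPECIES.index(spec.species)
        inds = []
        for k in range(spec.n_founders):
            haps = (rng.random((2, n_total)) < hap_freq).astype(np.int8)
            anc = np.full((2, n_total), code, dtype=np.int8)
            inds.append(Individual(id=f"{pool_name}_{k:02d}",
                                   haplotypes=haps, ancestry=anc,
                                   pool=pool_name))
        founders[pool_name] = inds

    def allele_name(mask_alt: np.ndarray) -> np.ndarray:
        return np.where(mask_alt, "alt", "ref")

    species_truth = {}
    for sp in SPECIES:
        d = np.flatnonzero(roles == f"diag_{sp}")
        df = marker_map.iloc[d][["id", "contig", "position"]].reset_index(drop=True)
        df["species_allele"] = allele_name(alt_is_marked[d])
        species_truth[sp] = df
    dssp = np.flatnonzero(roles == "diag_ssp")
    subspecies_truth = pd.DataFrame({
        "id": marker_map["id"].iloc[dssp].to_numpy(),
        "chinensis_allele": allele_name(alt_is_marked[dssp]),
        "kousa_allele": allele_name(~alt_is_marked[dssp]),
    })
    return FounderSet(config=config, marker_map=marker_map,
                      founders=founders, species_truth=species_truth,
                      subspecies_truth=subspecies_truth)


def make_gamete(parent: Individual, founder_set: FounderSet,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One recombined gamete (allele vector, ancestry vector).

    Per contig, a Poisson(``crossover_rate``) number of breakpoints is drawn
    uniformly on (0, contig length); the gamete alternates between the two
    parental haplotypes at the breakpoints, carrying ancestry labels along.
    """
    config = founder_set.config
    n = parent.haplotypes.shape[1]
    gamete = np.empty(n, dtype=np.int8)
    ancestry = np.empty(n, dtype=np.int8)
    pos_all = founder_set.marker_map["position"].to_numpy()
    for _, sl in founder_set.contig_slices:
        pos = pos_all[sl]
        k = rng.poisson(config.crossover_rate)
        breaks = np.sort(rng.uniform(0, config.contig_length_bp, size=k))
        start = rng.integers(2)
        hap_at = (start + np.searchsorted(breaks, pos)) % 2
        idx = np.arange(sl.start, sl.stop)
        gamete[sl] = parent.haplotypes[hap_at, idx]
        ancestry[sl] = parent.ancestry[hap_at, idx]
    return gamete, ancestry


def apply_pedigree(nodes: list[PedigreeNode], founder_set: FounderSet,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[GenotypeMatrix, SimTruth]:
    """Realize a pedigree into genotypes with tracked ancestry.

    Founder nodes draw successive unused founders from the pool (or species)
    named by their label. ``cross`` unites one gamete from each parent;
    ``self`` two gametes from one parent; ``op`` a maternal gamete with a
    gamete from a randomly drawn founder of the assumed pollen pool;
    ``clone``/``apomict`` copy the parent genotype. The returned matrix is
    error-free; apply :func:`apply_error_model` afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    order = topological_order(nodes)
    config = founder_set.config

    def pools_for(label: str) -> list[str]:
        if label in founder_set.founders:
            return [label]
        pools = [p for p, spec in config.pools.items()
                 if spec.species == label]
        if not pools:
            raise PedigreeError(f"no founder pool for label {label!r}")
        return pools

    used: dict[str, int] = {}
    individuals: dict[str, Individual] = {}

    def next_founder(label: str) -> Individual:
        for pool in pools_for(label):
            k = used.get(pool, 0)
            if k < len(founder_set.founders[pool]):
                used[pool] = k + 1
                return founder_set.founders[pool][k]
        raise SimulationError(
            f"founder pool(s) for {label!r} exhausted; enlarge the pool")

    def random_founder(label: str) -> Individual:
        pools = pools_for(label)
        pool = pools[int(rng.integers(len(pools)))]
        inds = founder_set.founders[pool]
        return inds[int(rng.integers(len(inds)))]

    clone_edges = []
    for node in order:
        if node.kind == "founder":
            src = next_founder(node.species)
            ind = Individual(id=node.id, haplotypes=src.haplotypes.copy(),
                             ancestry=src.ancestry.copy(), pool=src.pool)
        elif node.kind == "cross":
            g1 = make_gamete(individuals[node.parents[0]], founder_set, rng)
            g2 = make_gamete(individuals[node.parents[1]], founder_set, rng)
            ind = Individual(id=node.id,
                             haplotypes=np.stack([g1[0], g2[0]]),
                             ancestry=np.stack([g1[1], g2[1]]))
        elif node.kind == "self":
            p = individuals[node.parents[0]]
            g1 = make_gamete(p, founder_set, rng)
            g2 = make_gamete(p, founder_set, rng)
            ind = Individual(id=node.id,
                             haplotypes=np.stack([g1[0], g2[0]]),
                             ancestry=np.stack([g1[1], g2[1]]))
        elif node.kind == "op":
            pollen_label = node.pollen_species
            if pollen_label is None:
                raise PedigreeError(f"{node.id}: OP node without an assumed "
                                    "pollen species")
            g1 = make_gamete(individuals[node.parents[0]], founder_set, rng)
            g2 = make_gamete(random_founder(pollen_label), founder_set, rng)
            ind = Individual(id=node.id,
                             haplotypes=np.stack([g1[0], g2[0]]),
                             ancestry=np.stack([g1[1], g2[1]]))
        else:  # clone / apomict
            p = individuals[node.parents[0]]
            ind = Individual(id=node.id, haplotypes=p.haplotypes.copy(),
                             ancestry=p.ancestry.copy(), pool=p.pool)
            clone_edges.append((node.parents[0], node.id))
        individuals[node.id] = ind

    # clone groups: connected components over clone/apomict edges
    groups: list[set[str]] = []
    for a, b in clone_edges:
        hit = [g for g in groups if a in g or b in g]
        merged = set().union(*hit) if hit else set()
        merged.update((a, b))
        groups = [g for g in groups if g not in hit] + [merged]

    ancestry_rows = []
    for node in order:
        anc = individuals[node.id].ancestry
        fractions = [(anc == SPECIES.index(sp)).mean() * 100.0
                     for sp in SPECIES]
        ancestry_rows.append([node.id] + fractions)
    realized = pd.DataFrame(ancestry_rows,
                            columns=["accession"] + list(SPECIES))

    matrix = individuals_to_matrix(
        {n.id: individuals[n.id] for n in order}, founder_set.marker_map)
    truth = SimTruth(pedigree=list(nodes),
                     clone_groups=sorted(sorted(g) for g in groups),
                     realized_ancestry=realized,
                     individuals=individuals,
                     marker_map=founder_set.marker_map)
    return matrix, truth


def individuals_to_matrix(individuals: dict[str, Individual],
                          marker_map: pd.DataFrame) -> GenotypeMatrix:
    """Assemble an unphased dosage matrix from phased individuals."""
    accessions = list(individuals)
    calls = np.stack([individuals[a].dosage for a in accessions])
    return GenotypeMatrix(
        calls=calls,
        markers=marker_map[["id", "contig", "position", "ref", "alt"]].copy(),
        accessions=accessions)


def apply_error_model(matrix: GenotypeMatrix, error_rate: float,
                      missing_rate: float,
                      rng: np.random.Generator | int | None = None,
                      ) -> GenotypeMatrix:
    """Apply per-call missingness and genotyping error (pure function).

    Independently per call: with probability ``missing_rate`` the call is
    set MISSING; otherwise with probability ``error_rate`` it is miscalled
    -- a heterozygote to one of the two homozygotes with equal probability,
    a homozygote to a heterozygote.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    G = matrix.calls.copy()
    shape = G.shape
    miss = rng.random(shape) < missing_rate
    err = (rng.random(shape) < error_rate) & ~miss
    flip = rng.random(shape) < 0.5
    het = G == 1
    hom = (G == 0) | (G == 2)
    G = np.where(err & het, np.where(flip, 0, 2), G)
    G = np.where(err & hom, 1, G)
    G = np.where(miss, MISSING, G).astype(np.int8)
    return GenotypeMatrix(calls=G, markers=matrix.markers.copy(),
                          accessions=list(matrix.accessions))
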