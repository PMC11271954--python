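"""Modified Gower similarity, clone detection, and the theoretical self GS.

The similarity between two accessions is the mean per-locus score over loci
genotyped in both: 1 for identical genotypes, 0.5 when they share exactly one
allele (hom vs het), 0 for opposite homozygotes. With dosage coding the score
is ``1 - |x - y| / 2``, so the whole pairwise matrix reduces to indicator
matrix products. Clonal accessions (sports, mislabeled duplicates, apomicts)
are expected to differ only by genotyping error, so their GS sits just below
1; the conventional calling threshold is GS > 0.995.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import MISSING, GenotypeMatrix, accession_missing_rate

logger = logging.getLogger(__name__)


class UndefinedSimilarity(ValueError):
    """Raised when a pair shares fewer genotyped loci than ``min_overlap``."""


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise GS matrix with shared-genotyped-locus counts.

    ``values[i, j]`` is NaN where the overlap is below the ``min_overlap``
    used to build it. ``overlap[i, j]`` counts loci genotyped in both.
    """

    accessions: list[str]
    values: np.ndarray
    overlap: np.ndarray

    def dissimilarity(self) -> np.ndarray:
        """``1 - GS`` for downstream distance consumers (NJ, PCO)."""
        return 1.0 - self.values

    def pair(self, a: str, b: str) -> float:
        i = self.accessions.index(a)
        j = self.accessions.index(b)
        return float(self.values[i, j])


@dataclass
class CloneGroups:
    """Partition of putative clones at a GS threshold (single linkage).

    Each group has >= 2 members; ``representatives`` holds one member per
    group (lowest missing rate, ties broken lexicographically) for use in
    de-duplicated downstream analyses.
    """

    groups: list[list[str]]
    threshold: float
    representatives: list[str]

    def unique_accessions(self, all_accessions: list[str]) -> list[str]:
        """All accessions with non-representative clone members dropped."""
        drop = {m for g, rep in zip(self.groups, self.representatives)
                for m in g if m != rep}
        return [a for a in all_accessions if a not in drop]

    def group_of(self, accession: str) -> list[str] | None:
        for g in self.groups:
            if accession in g:
                return g
        return None


def gower_similarity(x: np.ndarray, y: np.ndarray, min_overlap: int = 100) -> float:
    """Modified Gower similarity between two dosage vectors.

    Raises :class:`UndefinedSimilarity` when fewer than ``min_overlap`` loci
    are genotyped in both vectors.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("genotype vectors differ in length")
    w = (x != MISSING) & (y != MISSING)
    n = int(w.sum())
    if n < min_overlap:
        raise UndefinedSimilarity(
            f"only {n} shared genotyped loci (min_overlap={min_overlap})")
    s = 1.0 - np.abs(x[w].astype(float) - y[w].astype(float)) / 2.0
    return float(s.mean())


def similarity_matrix(matrix: GenotypeMatrix, min_overlap: int = 100,
                      ) -> SimilarityMatrix:
    """All-pairs modified Gower similarity (vectorized).

    Pairs with overlap below ``min_overlap`` are NaN rather than a
    misleadingly extreme value. The diagonal is 1 wherever an accession has
    at least one genotyped locus.
    """
    if matrix.n_accessions < 2:
        raise ValueError("similarity_matrix needs at least 2 accessions")
    G = matrix.calls
    V = (G != MISSING).astype(np.float64)
    A = [(G == d).astype(np.float64) for d in (0, 1, 2)]
    W = V @ V.T
    # sum over loci of |x - y| restricted to jointly-genotyped loci
    D = (A[0] @ A[1].T + A[1] @ A[0].T + A[1] @ A[2].T + A[2] @ A[1].T
         + 2.0 * (A[0] @ A[2].T + A[2] @ A[0].T))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(W > 0, (W - 0.5 * D) / W, np.nan)
    values[W < min_overlap] = np.nan
    np.fill_diagonal(values, np.where(np.diag(W) > 0, 1.0, np.nan))
    return SimilarityMatrix(
        accessions=list(matrix.accessions),
        values=values,
        overlap=W.astype(np.int64),
    )


def clone_groups(sim: SimilarityMatrix, threshold: float = 0.995,
                 matrix: GenotypeMatrix | None = None) -> CloneGroups:
    """Single-linkage clone groups: connected components of GS > threshold.

    Multi-member groups may contain pairs at or below the threshold joined
    through intermediates (transitivity); these are logged. If ``matrix`` is
    given, group representatives are the members with the lowest missing
    rate; otherwise the lexicographically smallest id.
    """
    vals = sim.values
    n = len(sim.accessions)
    adj = np.triu(np.nan_to_num(vals, nan=-1.0) > threshold, k=1)
    comp_n, labels = connected_components(csr_matrix(adj), directed=False)
    groups = []
    for c in range(comp_n):
        members = [sim.accessions[i] for i in np.flatnonzero(labels == c)]
        if len(members) >= 2:
            groups.append(sorted(members))
    groups.sort()

    if matrix is not None:
        miss = accession_missing_rate(matrix)
        reps = [min(g, key=lambda a: (miss[a], a)) for g in groups]
    else:
        reps = [g[0] for g in groups]

    for g in groups:
        idx = [sim.accessions.index(a) for a in g]
        sub = vals[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), 1)
        weak = (sub[iu] <= threshold) | np.isnan(sub[iu])
        if weak.any():
            logger.info(
                "clone group %s joined by single linkage: %d within-group "
                "pair(s) at or below GS %.3f", g, int(weak.sum()), threshold)
    return CloneGroups(groups=groups, threshold=threshold, representatives=reps)


def expected_self_gs(x: np.ndarray) -> float:
    """Expected GS between a genotype and one of its selfed offspring.

    Homozygous parental loci are transmitted unchanged (score 1). Each
    heterozygous locus segregates 1/4 : 1/2 : 1/4, and a homozygous offspring
    genotype scores 0.5 against the heterozygous parent, so the locus
    contributes 0.75 in expectation. With heterozygous fraction ``h`` among
    non-missing loci the expectation is ``1 - h / 4`` -- the basis for
    distinguishing a true self (noticeably lower GS) from an apomict or sport
    (GS near 1).
    """
    x = np.asarray(x)
    called = x != MISSING
    n = int(called.sum())
    if n == 0:
        raise UndefinedSimilarity("all calls missing")
    h = float((x[called] == 1).mean())
    return 1.0 - h / 4.0
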