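"""Parent-offspring dyad and triad discovery from biallelic genotypes.

A true parent transmits one allele at every locus, so a parent-offspring
pair can never be opposite homozygotes (AA vs BB) except through genotyping
error. The dyad statistic P_OHL is the proportion of jointly-genotyped loci
in opposite homozygous states; true pairs sit near 0, unrelated pairs form a
cloud well above. For triads, an expected progeny genotype (EP) is forced by
Mendelian rules at loci homozygous in both candidate parents, and the Gower
dissimilarity (GD) between EP and a candidate offspring plays the same role.

Significance is assigned by ordering the pooled statistic values, locating
the largest gap in the first half of the ordered list, testing that gap as a
high outlier against 29 randomly sampled other gaps (Dixon ratio test,
Monte-Carlo calibrated), and, when the gap is significant, testing each
candidate below the gap as a low outlier against the 29 lowest values above
the gap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import MISSING, AccessionMeta, GenotypeMatrix
from .similarity import CloneGroups, UndefinedSimilarity

logger = logging.getLogger(__name__)

#: Rule-of-thumb ceiling for true-dyad P_OHL reported in the literature;
#: reported alongside results but never used to assign significance.
POHL_RULE_OF_THUMB = 0.010


class ScanError(ValueError):
    """Raised when a dyad/triad scan precondition fails."""


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def pohl(x: np.ndarray, y: np.ndarray, min_overlap: int = 100) -> float:
    """Proportion of jointly-genotyped loci in opposite homozygous states."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("genotype vectors differ in length")
    w = (x != MISSING) & (y != MISSING)
    n = int(w.sum())
    if n < min_overlap:
        raise UndefinedSimilarity(
            f"only {n} shared genotyped loci (min_overlap={min_overlap})")
    xs, ys = x[w], y[w]
    opp = ((xs == 0) & (ys == 2)) | ((xs == 2) & (ys == 0))
    return float(opp.mean())


def pohl_matrix(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs P_OHL and overlap counts for a dosage matrix (vectorized)."""
    A0 = (G == 0).astype(np.float64)
    A2 = (G == 2).astype(np.float64)
    V = (G != MISSING).astype(np.float64)
    opp = A0 @ A2.T + A2 @ A0.T
    W = V @ V.T
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(W > 0, opp / W, np.nan)
    return P, W


def expected_progeny(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Mendelian-forced progeny genotype at loci homozygous in both parents.

    Returns a vector with the EP dosage at defined loci and MISSING
    elsewhere (loci where either parent is heterozygous or missing).
    Raises :class:`UndefinedSimilarity` when no locus is defined.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("genotype vectors differ in length")
    hom = np.isin(p1, (0, 2)) & np.isin(p2, (0, 2))
    ep = np.full(p1.shape, MISSING, dtype=np.int8)
    # (0,0)->0, (2,2)->2, (0,2)/(2,0)->1: the mean dosage of the two parents
    ep[hom] = ((p1[hom].astype(np.int16) + p2[hom].astype(np.int16)) // 2).astype(np.int8)
    if not hom.any():
        raise UndefinedSimilarity("no locus homozygous in both parents")
    return ep


# ---------------------------------------------------------------------------
# Dixon outlier test (Monte-Carlo calibrated r22 ratio)
# ---------------------------------------------------------------------------

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _r22(sorted_vals: np.ndarray, tail: str) -> float:
    """Dixon's r22 ratio on an ascending sample (numerator skips 2 values
    at the tested end, denominator skips 2 at the opposite end)."""
    x = sorted_vals
    if tail == "min":
        den = x[-3] - x[0]
        num = x[2] - x[0]
    else:
        den = x[-1] - x[2]
        num = x[-1] - x[-3]
    if den == 0:
        return np.nan
    return float(num / den)


def _null_r22(n: int, n_reps: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the r22 statistic for a
    standard-normal sample of size ``n`` (cached; low/high tails coincide
    by symmetry)."""
    key = (n, n_reps, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_reps, n))
        draws.sort(axis=1)
        den = draws[:, -1] - draws[:, 2]
        num = draws[:, -1] - draws[:, -3]
        stats = np.where(den > 0, num / den, np.nan)
        _NULL_CACHE[key] = np.sort(stats[np.isfinite(stats)])
    return _NULL_CACHE[key]


def dixon_test(candidate_value: float, comparison_values: np.ndarray,
               tail: str = "min", seed: int | None = None,
               n_reps: int = 100_000) -> float:
    """P-value for the candidate being an outlier among 29 comparison values.

    The candidate is pooled with the 29 comparison values and Dixon's r22
    ratio is computed on the ordered sample of 30; the p-value is the
    fraction of Monte-Carlo standard-normal null samples with a ratio at
    least as extreme. A candidate not on the claimed tail yields p = 1 with
    a warning, as does a fully degenerate (all-identical) sample.
    """
    comparison_values = np.asarray(comparison_values, dtype=float)
    if comparison_values.size != 29:
        raise ValueError("dixon_test requires exactly 29 comparison values")
    if tail not in ("min", "max"):
        raise ValueError("tail must be 'min' or 'max'")
    pooled = np.sort(np.append(comparison_values, candidate_value))
    if pooled[0] == pooled[-1]:
        return 1.0
    on_tail = (candidate_value <= pooled[0] if tail == "min"
               else candidate_value >= pooled[-1])
    if not on_tail:
        warnings.warn("candidate is not on the claimed tail; p = 1",
                      stacklevel=2)
        return 1.0
    stat = _r22(pooled, tail)
    if not np.isfinite(stat):
        return 1.0
    null = _null_r22(pooled.size, n_reps, 0 if seed is None else int(seed))
    # fraction of null statistics as or more extreme (larger ratio = more
    # extreme for both tails, by construction of r22)
    return float(np.mean(null >= stat))


# ---------------------------------------------------------------------------
# Gap scan machinery shared by dyads and triads
# ---------------------------------------------------------------------------

@dataclass
class GapScan:
    """Ordered statistic values, their consecutive gaps, and the tested gap."""

    values: np.ndarray
    gaps: np.ndarray
    gap_index: int
    gap_size: float
    p_value: float

    @property
    def n_below(self) -> int:
        """Number of candidates at or below the tested gap."""
        return self.gap_index + 1


@dataclass
class DyadCandidate:
    pair: tuple[str, str]
    pohl: float
    n_loci: int
    p_value: float | None = None
    significant: bool = False
    orientation: tuple[str, str] | None = None  # (parent, offspring)


@dataclass
class TriadCandidate:
    parents: tuple[str, str]
    offspring: str
    gd: float
    n_ep_loci: int
    p_value: float | None = None
    significant: bool = False


@dataclass
class ScanResult:
    candidates: list
    gap_scan: GapScan
    structure_warning: bool = False

    @property
    def significant(self) -> list:
        return [c for c in self.candidates if c.significant]


def _gap_scan(values: np.ndarray, rng: np.ndarray, null_seed: int,
              n_reps: int) -> GapScan:
    """Locate the largest gap in the first half of the ascending values and
    Dixon-test it (high tail) against 29 gaps sampled from the rest."""
    order = np.sort(values)
    gaps = np.diff(order)
    n_gaps = gaps.size
    if n_gaps < 30:
        raise ScanError(f"need >= 31 candidates for the gap test, got "
                        f"{values.size}")
    half = gaps[: n_gaps // 2]
    gap_index = int(np.argmax(half))  # earliest index on ties
    rest = np.delete(np.arange(n_gaps), gap_index)
    sample = gaps[rng.choice(rest, size=29, replace=False)]
    p = dixon_test(gaps[gap_index], sample, tail="max", seed=null_seed,
                   n_reps=n_reps)
    return GapScan(values=order, gaps=gaps, gap_index=gap_index,
                   gap_size=float(gaps[gap_index]), p_value=p)


def _second_dixon(values_sorted: np.ndarray, scan: GapScan, alpha: float,
                  null_seed: int, n_reps: int) -> np.ndarray:
    """Per-candidate low-tail Dixon p-values for every value below the gap,
    each against the 29 lowest values above the gap."""
    k = scan.n_below
    above = values_sorted[k: k + 29]
    if above.size < 29:
        raise ScanError("fewer than 29 values above the gap")
    return np.array([
        dixon_test(v, above, tail="min", seed=null_seed, n_reps=n_reps)
        for v in values_sorted[:k]
    ])


# ---------------------------------------------------------------------------
# Dyad scan
# ---------------------------------------------------------------------------

def _eligible_pairs(accessions: list[str],
                    meta: dict[str, AccessionMeta] | None,
                    clones: CloneGroups | None) -> list[tuple[int, int]]:
    def role(a: str) -> str:
        if meta is None or a not in meta:
            return "all"
        return meta[a].role

    clone_sets = [set(g) for g in clones.groups] if clones is not None else []

    pairs = []
    for i, j in combinations(range(len(accessions)), 2):
        a, b = accessions[i], accessions[j]
        ra, rb = role(a), role(b)
        # one member must be able to act as parent and the other as offspring
        if not ((ra in ("parent", "all") and rb in ("offspring", "all"))
                or (rb in ("parent", "all") and ra in ("offspring", "all"))):
            continue
        if any(a in s and b in s for s in clone_sets):
            continue
        pairs.append((i, j))
    return pairs


def dyad_scan(matrix: GenotypeMatrix,
              meta: dict[str, AccessionMeta] | None = None,
              alpha: float = 0.05, min_overlap: int = 100,
              clones: CloneGroups | None = None,
              seed: int | None = None, n_reps: int = 100_000) -> ScanResult:
    """Scan all role-eligible accession pairs for parent-offspring dyads.

    Pairs within a supplied clone group are excluded (a clone trivially has
    P_OHL near 0 but is not a parent). A structure warning is raised when
    more than 25% of pairs fall below P_OHL 0.02, the signature of strong
    subpopulation differentiation depressing the statistic.
    """
    rng = np.random.default_rng(seed)
    null_seed = int(rng.integers(2**31)) if seed is not None else 0

    pairs = _eligible_pairs(matrix.accessions, meta, clones)
    if len(pairs) < 31:
        raise ScanError(f"need >= 31 eligible pairs, got {len(pairs)}")

    P, W = pohl_matrix(matrix.calls)
    candidates = []
    for i, j in pairs:
        if W[i, j] < min_overlap:
            logger.info("pair (%s, %s) below min_overlap, skipped",
                        matrix.accessions[i], matrix.accessions[j])
            continue
        candidates.append(DyadCandidate(
            pair=(matrix.accessions[i], matrix.accessions[j]),
            pohl=float(P[i, j]), n_loci=int(W[i, j])))
    if len(candidates) < 31:
        raise ScanError(f"need >= 31 pairs above min_overlap, got "
                        f"{len(candidates)}")

    values = np.array([c.pohl for c in candidates])
    structure_warning = bool(np.mean(values < 0.02) > 0.25)
    if structure_warning:
        warnings.warn(
            "more than 25% of pairs have P_OHL < 0.02: strong population "
            "structure may depress the statistic and mask the dyad gap",
            stacklevel=2)

    candidates.sort(key=lambda c: c.pohl)
    scan = _gap_scan(values, rng, null_seed, n_reps)

    if scan.p_value < alpha:
        sorted_vals = np.array([c.pohl for c in candidates])
        pvals = _second_dixon(sorted_vals, scan, alpha, null_seed, n_reps)
        for c, p in zip(candidates[: scan.n_below], pvals):
            c.p_value = float(p)
            c.significant = bool(p < alpha)
            if c.significant and meta is not None:
                c.orientation = _orient(c.pair, meta)
    return ScanResult(candidates=candidates, gap_scan=scan,
                      structure_warning=structure_warning)


def _orient(pair: tuple[str, str],
            meta: dict[str, AccessionMeta]) -> tuple[str, str] | None:
    """Assign (parent, offspring) from dates or asymmetric roles."""
    a, b = pair
    ma, mb = meta.get(a), meta.get(b)
    if ma and mb and ma.date is not None and mb.date is not None \
            and ma.date != mb.date:
        return (a, b) if ma.date < mb.date else (b, a)
    ra = ma.role if ma else "all"
    rb = mb.role if mb else "all"
    if ra == "parent" and rb != "parent":
        return (a, b)
    if rb == "parent" and ra != "parent":
        return (b, a)
    if ra == "offspring" and rb != "offspring":
        return (b, a)
    if rb == "offspring" and ra != "offspring":
        return (a, b)
    return None


# ---------------------------------------------------------------------------
# Triad scan
# ---------------------------------------------------------------------------

def triad_scan(matrix: GenotypeMatrix,
               meta: dict[str, AccessionMeta] | None = None,
               alpha: float = 0.05, min_ep_loci: int = 100,
               seed: int | None = None, n_reps: int = 100_000) -> ScanResult:
    """Scan (parent pair, offspring) combinations for true triads.

    For every unordered pair of parent-eligible accessions the expected
    progeny genotype is built, and the Gower dissimilarity between it and
    each offspring-eligible accession (restricted to EP loci genotyped in
    the offspring) is pooled into one ordered list; the gap + paired Dixon
    machinery then mirrors the dyad scan.
    """
    rng = np.random.default_rng(seed)
    null_seed = int(rng.integers(2**31)) if seed is not None else 0

    def role(a: str) -> str:
        if meta is None or a not in meta:
            return "all"
        return meta[a].role

    parent_idx = [i for i, a in enumerate(matrix.accessions)
                  if role(a) in ("parent", "all")]
    offspring_idx = [i for i, a in enumerate(matrix.accessions)
                     if role(a) in ("offspring", "all")]
    G = matrix.calls
    candidates = []
    for i, j in combinations(parent_idx, 2):
        p1, p2 = G[i], G[j]
        hom = np.isin(p1, (0, 2)) & np.isin(p2, (0, 2))
        if not hom.any():
            continue
        ep = ((p1[hom].astype(np.int16) + p2[hom].astype(np.int16)) // 2)
        sub = G[:, hom]
        valid = sub != MISSING
        n_loci = valid.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            diff = np.abs(sub.astype(np.int16) - ep[None, :])
            gd = np.where(valid, diff, 0).sum(axis=1) / (2.0 * n_loci)
        for o in offspring_idx:
            if o == i or o == j or n_loci[o] < min_ep_loci:
                continue
            candidates.append(TriadCandidate(
                parents=(matrix.accessions[i], matrix.accessions[j]),
                offspring=matrix.accessions[o],
                gd=float(gd[o]), n_ep_loci=int(n_loci[o])))

    if len(candidates) < 31:
        raise ScanError(f"need >= 31 eligible triads, got {len(candidates)}")

    candidates.sort(key=lambda c: c.gd)
    values = np.array([c.gd for c in candidates])
    scan = _gap_scan(values, rng, null_seed, n_reps)

    if scan.p_value < alpha:
        pvals = _second_dixon(values, scan, alpha, null_seed, n_reps)
        for c, p in zip(candidates[: scan.n_below], pvals):
            c.p_value = float(p)
            c.significant = bool(p < alpha)
    return ScanResult(candidates=candidates, gap_scan=scan)
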