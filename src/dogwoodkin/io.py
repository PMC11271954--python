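"""Genotype matrix containers, file I/O, per-marker statistics, and marker filters.

Genotypes are stored as alternate-allele dosage: 0 (hom ref, "AA"),
1 (het, "AB"), 2 (hom alt, "BB"), with :data:`MISSING` (-1) for no call.
Only biallelic SNP/Indel markers are supported; multi-allelic VCF records
are skipped (and counted) on load.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in the dosage encoding.
MISSING: int = -1

MARKER_COLUMNS = ["id", "contig", "position", "ref", "alt"]


class GenotypeFormatError(ValueError):
    """Raised for malformed or inconsistent genotype input."""


@dataclass(frozen=True)
class Marker:
    """A single biallelic SNP or Indel marker.

    ``position`` is 1-based, as read from VCF. ``ref_allele`` and
    ``alt_allele`` are arbitrary allele labels (single bases for SNPs,
    longer strings for Indels).
    """

    id: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: str = "SNP"

    def __post_init__(self):
        if self.position < 0:
            raise GenotypeFormatError(f"marker {self.id}: negative position")
        if self.ref_allele == self.alt_allele:
            raise GenotypeFormatError(f"marker {self.id}: ref == alt allele")


@dataclass
class GenotypeMatrix:
    """Accessions x markers matrix of biallelic dosage calls.

    Attributes
    ----------
    calls
        ``(n_accessions, n_markers)`` int8 array with values in
        ``{0, 1, 2, MISSING}``.
    markers
        DataFrame with columns ``id, contig, position, ref, alt``
        (``variant_class`` optional), one row per marker, in call order.
    accessions
        Accession identifiers, in row order of ``calls``.
    """

    calls: np.ndarray
    markers: pd.DataFrame
    accessions: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.markers = self.markers.reset_index(drop=True)
        self.accessions = list(self.accessions)
        self.validate()

    def validate(self) -> None:
        n_acc, n_mark = self.calls.shape
        if n_acc != len(self.accessions):
            raise GenotypeFormatError("calls rows != number of accessions")
        if n_mark != len(self.markers):
            raise GenotypeFormatError("calls columns != number of markers")
        if len(set(self.accessions)) != n_acc:
            raise GenotypeFormatError("duplicate accession ids")
        ids = self.markers["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise GenotypeFormatError(f"duplicate marker id {dup!r}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeFormatError("calls contain values outside {0,1,2,MISSING}")

    # -- convenience -----------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def accession_index(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(f"accession {accession!r} not in matrix") from None

    def genotypes_of(self, accession: str) -> np.ndarray:
        """Dosage vector for one accession."""
        return self.calls[self.accession_index(accession)]

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the marker positions in ``index`` (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            calls=self.calls[:, index].copy(),
            markers=self.markers.iloc[index].reset_index(drop=True),
            accessions=list(self.accessions),
        )

    def take_accessions(self, accessions: list[str]) -> "GenotypeMatrix":
        rows = [self.accession_index(a) for a in accessions]
        return GenotypeMatrix(
            calls=self.calls[rows, :].copy(),
            markers=self.markers.copy(),
            accessions=list(accessions),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and np.array_equal(self.calls, other.calls)
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
        )


@dataclass(frozen=True)
class AccessionMeta:
    """Per-accession metadata for parentage and grouping analyses.

    ``role`` controls dyad/triad candidacy: ``parent`` (only a possible
    parent), ``offspring`` (only a possible offspring), or ``all`` (both).
    ``group`` is an optional species/subspecies reference label and ``date``
    an optional year of origin used to orient significant dyads
    (older accession = parent).
    """

    id: str
    role: str = "all"
    group: str | None = None
    date: int | None = None

    def __post_init__(self):
        if self.role not in ("parent", "offspring", "all"):
            raise GenotypeFormatError(f"invalid role {self.role!r} for {self.id}")


def read_metadata(path: str | os.PathLike) -> dict[str, AccessionMeta]:
    """Read accession metadata from CSV with columns id, role, group, date."""
    df = pd.read_csv(path, dtype={"id": str})
    out = {}
    for row in df.itertuples(index=False):
        date = getattr(row, "date", None)
        if date is not None and pd.isna(date):
            date = None
        group = getattr(row, "group", None)
        if group is not None and pd.isna(group):
            group = None
        out[row.id] = AccessionMeta(
            id=row.id,
            role=getattr(row, "role", "all"),
            group=group,
            date=int(date) if date is not None else None,
        )
    return out


def write_metadata(meta: dict[str, AccessionMeta], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(m.id, m.role, m.group, m.date) for m in meta.values()],
        columns=["id", "role", "group", "date"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_GT_TO_DOSAGE = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": MISSING, ".|.": MISSING, ".": MISSING,
}
_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def load_matrix(path: str | os.PathLike, format: str = "vcf") -> GenotypeMatrix:
    """Load a genotype matrix from a VCF (GT field) or tabular text file.

    Multi-allelic VCF records are skipped; the number skipped is logged.
    """
    if format == "vcf":
        return _load_vcf(path)
    if format == "table":
        return _load_table(path)
    raise ValueError(f"unknown format {format!r}")


def _variant_class(ref: str, alt: str) -> str:
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "Indel"


def _load_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, records = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dosage.astype(np.int8))
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        records.append((mid, v.CHROM, v.POS, v.REF, v.ALT[0],
                        _variant_class(v.REF, v.ALT[0])))
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic records in %s", n_skipped, path)
    markers = pd.DataFrame(records, columns=MARKER_COLUMNS + ["variant_class"])
    calls = (np.vstack(rows).T if rows
             else np.empty((len(accessions), 0), dtype=np.int8))
    mat = GenotypeMatrix(calls=calls, markers=markers, accessions=accessions)
    mat.n_skipped_multiallelic = n_skipped
    return mat


def _load_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "contig": str})
    for col in MARKER_COLUMNS:
        if col not in df.columns:
            raise GenotypeFormatError(f"table missing column {col!r}")
    accessions = [c for c in df.columns if c not in MARKER_COLUMNS]
    calls = (
        df[accessions]
        .apply(pd.to_numeric, errors="coerce")
        .fillna(MISSING)
        .to_numpy()
        .T.astype(np.int8)
    )
    markers = df[MARKER_COLUMNS].copy()
    markers["variant_class"] = [
        _variant_class(r, a) for r, a in zip(markers["ref"], markers["alt"])
    ]
    return GenotypeMatrix(calls=calls, markers=markers, accessions=accessions)


def save_matrix(matrix: GenotypeMatrix, path: str | os.PathLike,
                format: str = "vcf") -> None:
    """Write a genotype matrix as a minimal spec-conformant VCF or a tab table."""
    if format == "vcf":
        _save_vcf(matrix, path)
    elif format == "table":
        _save_table(matrix, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _save_vcf(matrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in pd.unique(matrix.markers["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + matrix.accessions
        fh.write("\t".join(header) + "\n")
        for j, m in enumerate(matrix.markers.itertuples(index=False)):
            gts = [_DOSAGE_TO_GT[int(d)] for d in matrix.calls[:, j]]
            fh.write("\t".join(
                [str(m.contig), str(m.position), str(m.id), str(m.ref),
                 str(m.alt), ".", ".", ".", "GT"] + gts) + "\n")


def _save_table(matrix, path) -> None:
    df = matrix.markers[MARKER_COLUMNS].copy()
    calls = matrix.calls.T.astype(object)
    for i, acc in enumerate(matrix.accessions):
        col = calls[:, i]
        df[acc] = [("NA" if c == MISSING else int(c)) for c in col]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-marker statistics and filters
# ---------------------------------------------------------------------------

def marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, missingness, and heterozygote frequency.

    MAF is computed from allele counts over non-missing calls
    (``min(p, 1-p)`` with ``p`` the alt-allele frequency); ``het_rate`` is the
    heterozygote fraction among non-missing calls; ``missing_rate`` is over
    all accessions. Markers with zero non-missing calls get NaN maf/het_rate.
    """
    G = matrix.calls
    called = G != MISSING
    n_called = called.sum(axis=0)
    n_acc = G.shape[0]
    dosage_sum = np.where(called, G, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, dosage_sum / (2.0 * n_called), np.nan)
        het = np.where(n_called > 0, (G == 1).sum(axis=0) / n_called, np.nan)
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame(
        {
            "id": matrix.markers["id"].to_numpy(),
            "maf": maf,
            "missing_rate": (n_acc - n_called) / n_acc,
            "het_rate": het,
            "n_called": n_called,
        }
    )


def accession_missing_rate(matrix: GenotypeMatrix) -> pd.Series:
    """Fraction of missing calls per accession."""
    rate = (matrix.calls == MISSING).mean(axis=1)
    return pd.Series(rate, index=matrix.accessions)


def filter_markers(matrix: GenotypeMatrix, maf_min: float = 0.05,
                   missing_max: float = 0.10, het_max: float = 0.90,
                   ) -> GenotypeMatrix:
    """Keep markers with MAF >= maf_min, missingness <= missing_max and
    heterozygote frequency <= het_max (conjunctive; order immaterial)."""
    for name, t in (("maf_min", maf_min), ("missing_max", missing_max),
                    ("het_max", het_max)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    stats = marker_stats(matrix)
    # all-missing markers have undefined maf/het; treat them as 0 so they
    # fail any positive MAF floor but pass a no-op (0, 1, 1) filter
    keep = (
        (stats["maf"].fillna(0.0) >= maf_min)
        & (stats["missing_rate"] <= missing_max)
        & (stats["het_rate"].fillna(0.0) <= het_max)
    )
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_markers removed %d of %d markers", removed,
                    matrix.n_markers)
    return matrix.take_markers(np.flatnonzero(keep.to_numpy()))


def thin_by_window(matrix: GenotypeMatrix, window_bp: int = 500) -> GenotypeMatrix:
    """Keep one marker per non-overlapping ``window_bp`` bin per contig.

    Bins are half-open 0-based intervals anchored at position 0 of each
    contig; within a bin the marker with the highest heterozygote frequency
    wins (ties: lowest missing rate, then smallest position).
    """
    if matrix.markers["position"].isna().any():
        raise GenotypeFormatError("thin_by_window requires marker positions")
    stats = marker_stats(matrix)
    df = matrix.markers[["contig", "position"]].copy()
    df["het"] = stats["het_rate"].fillna(-1.0).to_numpy()
    df["miss"] = stats["missing_rate"].to_numpy()
    df["bin"] = (df["position"].astype(np.int64) - 1) // int(window_bp)
    df["orig"] = np.arange(len(df))
    best = (
        df.sort_values(["het", "miss", "position"],
                       ascending=[False, True, True], kind="mergesort")
        .groupby(["contig", "bin"], sort=False)
        .head(1)
    )
    keep = np.sort(best["orig"].to_numpy())
    return matrix.take_markers(keep)


def _pairwise_r2(G: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls."""
    x, y = G[:, i], G[:, j]
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(matrix: GenotypeMatrix, r2_max: float = 0.5,
             window_markers: int = 100, step_markers: int = 10,
             ) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on dosage correlation.

    Within each window of ``window_markers`` consecutive retained markers,
    any pair with squared Pearson correlation > ``r2_max`` loses its member
    with the higher missing rate (tie: later position). The window slides by
    ``step_markers``; full passes repeat until no marker is removed.
    Zero-variance pairs count as uncorrelated.
    """
    order = np.lexsort(
        (matrix.markers["position"].to_numpy(),
         matrix.markers["contig"].to_numpy())
    )
    sorted_mat = matrix.take_markers(order)
    G = sorted_mat.calls
    miss = (G == MISSING).mean(axis=0)
    pos = sorted_mat.markers["position"].to_numpy()
    contig = sorted_mat.markers["contig"].to_numpy()

    alive = np.ones(G.shape[1], dtype=bool)
    changed = True
    while changed:
        changed = False
        idx_alive = np.flatnonzero(alive)
        start = 0
        while start < len(idx_alive):
            window = idx_alive[start:start + window_markers]
            for a_i in range(len(window)):
                i = window[a_i]
                if not alive[i]:
                    continue
                for b_i in range(a_i + 1, len(window)):
                    j = window[b_i]
                    if not alive[j] or contig[i] != contig[j]:
                        continue
                    if _pairwise_r2(G, i, j) > r2_max:
                        if miss[i] > miss[j] or (miss[i] == miss[j]
                                                 and pos[i] > pos[j]):
                            alive[i] = False
                            changed = True
                            break
                        alive[j] = False
                        changed = True
                if not alive[i]:
                    continue
            start += step_markers
    survivors_sorted = np.flatnonzero(alive)
    # report in the matrix's original marker order
    keep_orig = np.sort(order[survivors_sorted])
    return matrix.take_markers(keep_orig)


def random_thin(matrix: GenotypeMatrix, n_target: int = 1000,
                seed: int | None = None) -> GenotypeMatrix:
    """Uniform random subsample of markers without replacement (order kept)."""
    if n_target > matrix.n_markers:
        raise ValueError(
            f"n_target {n_target} exceeds marker count {matrix.n_markers}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(matrix.n_markers, size=n_target, replace=False))
    return matrix.take_markers(keep)
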