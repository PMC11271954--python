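"""Species-diagnostic marker panels, hybrid composition, and introgression.

A species-diagnostic marker is fixed for one allele in one species'
reference accessions and fixed for the alternative allele in every other
reference group. Scoring an accession at such a locus with
L = 1 (homozygous species allele), 0.5 (heterozygous), 0 (homozygous other
allele or missing) and normalizing the per-species sums gives the
interspecific composition percentages; runs of consecutive donor-carrying
panel loci along a contig delimit introgression segments in backcross
material.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class PanelError(ValueError):
    """Raised for invalid reference groups or panel inputs."""


@dataclass
class SpeciesPanel:
    """Diagnostic markers for one species.

    ``markers`` has columns ``id, contig, position, species_allele,
    call_rate`` where ``species_allele`` is ``"ref"`` or ``"alt"``
    (the allele fixed in this species' references).
    """

    species: str
    markers: pd.DataFrame

    def __len__(self) -> int:
        return len(self.markers)

    def to_tsv(self, path) -> None:
        out = self.markers.copy()
        out.insert(0, "species", self.species)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class CompositionResult:
    """Per-accession interspecific composition.

    ``percentages`` sum to 100 over species when any informative signal is
    present; ``defined`` is False (and percentages NaN) when every panel
    locus scored 0.
    """

    accession: str
    percentages: dict[str, float]
    l_sums: dict[str, float]
    n_informative: int
    call_rate: float
    defined: bool


@dataclass
class IntrogressionSegment:
    accession: str
    donor: str
    contig: str
    start: int
    end: int
    n_loci: int
    zygosity: str  # all-het | all-hom | mixed

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start > end")


@dataclass
class SegmentReport:
    segments: list[IntrogressionSegment]
    singletons: pd.DataFrame  # runs shorter than min_run: putative errors


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------

def select_species_markers(matrix: GenotypeMatrix,
                           reference_groups: dict[str, list[str]],
                           presence_min: float = 0.88,
                           ) -> dict[str, SpeciesPanel]:
    """Select species-diagnostic markers from reference accessions.

    A marker qualifies when (a) it is non-missing in at least
    ``presence_min`` of the pooled reference accessions, (b) every
    non-missing reference call is homozygous, (c) each group is fixed for a
    single allele, and (d) the groups are not all fixed for the same allele.
    With three or more groups a marker is assigned to the unique group fixed
    for the minority allele pattern (the odd group out); with exactly two
    groups it is assigned to the group fixed for the rarer allele across the
    pooled references (ties to the lexicographically smaller group label).
    """
    if len(reference_groups) < 2:
        raise PanelError("need at least 2 reference groups")
    for sp, accs in reference_groups.items():
        if len(accs) < 2:
            raise PanelError(f"reference group {sp!r} has fewer than 2 "
                             "accessions")

    rows = {sp: [matrix.accession_index(a) for a in accs]
            for sp, accs in reference_groups.items()}
    all_rows = [i for idx in rows.values() for i in idx]
    G = matrix.calls[all_rows]
    called = G != MISSING
    presence = called.mean(axis=0)
    all_hom = ~np.any(G == 1, axis=0)

    # per-group fixation: group calls all equal (ignoring missing)
    group_allele: dict[str, np.ndarray] = {}
    group_fixed: dict[str, np.ndarray] = {}
    for sp in reference_groups:
        sub = matrix.calls[rows[sp]]
        subc = sub != MISSING
        any_called = subc.any(axis=0)
        lo = np.where(subc, sub, np.int8(3)).min(axis=0)
        hi = np.where(subc, sub, np.int8(-2)).max(axis=0)
        group_fixed[sp] = any_called & (lo == hi)
        group_allele[sp] = np.where(group_fixed[sp], lo, MISSING)

    species = sorted(reference_groups)
    alleles = np.stack([group_allele[sp] for sp in species])  # (g, m)
    fixed_all = np.all(np.stack([group_fixed[sp] for sp in species]), axis=0)
    polymorphic_between = fixed_all & (alleles.max(axis=0) != alleles.min(axis=0))
    qualifies = (presence >= presence_min) & all_hom & polymorphic_between

    n_alt_groups = (alleles == 2).sum(axis=0)
    panels: dict[str, SpeciesPanel] = {}
    marker_cols = matrix.markers[["id", "contig", "position"]]
    call_rate = (matrix.calls[all_rows] != MISSING).mean(axis=0)

    for gi, sp in enumerate(species):
        if len(species) == 2:
            # assign to the group fixed for the rarer pooled allele
            sub = matrix.calls[all_rows]
            p_alt = np.where(
                (sub != MISSING).sum(axis=0) > 0,
                np.where(sub != MISSING, sub, 0).sum(axis=0)
                / (2.0 * np.maximum((sub != MISSING).sum(axis=0), 1)), 0.5)
            own_allele = alleles[gi]
            own_freq = np.where(own_allele == 2, p_alt, 1.0 - p_alt)
            other_freq = 1.0 - own_freq
            mine = qualifies & ((own_freq < other_freq)
                                | ((own_freq == other_freq) & (gi == 0)))
        else:
            # odd group out: this group's allele differs from every other
            others = [alleles[gj] for gj in range(len(species)) if gj != gi]
            mine = qualifies & np.all(
                np.stack([alleles[gi] != o for o in others]), axis=0)
            # and the remaining groups agree with each other
            if len(others) > 1:
                ref = others[0]
                mine &= np.all(np.stack([o == ref for o in others[1:]]),
                               axis=0)
        idx = np.flatnonzero(mine)
        df = marker_cols.iloc[idx].reset_index(drop=True).copy()
        df["species_allele"] = np.where(alleles[gi][idx] == 2, "alt", "ref")
        df["call_rate"] = call_rate[idx]
        panels[sp] = SpeciesPanel(species=sp, markers=df)
        logger.info("panel %s: %d diagnostic markers", sp, len(df))
    return panels


def equalize_panels(panels: dict[str, SpeciesPanel], window_bp: int = 500,
                    per_window_cap: int = 3) -> dict[str, SpeciesPanel]:
    """Reduce all panels to the size of the smallest.

    Larger panels are trimmed by first capping markers per ``window_bp``
    genomic bin at ``per_window_cap`` (keeping the highest call rate), then
    removing the lowest-call-rate markers (ties: later position) until every
    panel matches the smallest panel's size.
    """
    if any(len(p) == 0 for p in panels.values()):
        raise PanelError("cannot equalize: empty panel present")
    target = min(len(p) for p in panels.values())
    out = {}
    for sp, panel in panels.items():
        df = panel.markers.copy()
        if len(df) > target:
            df["_bin"] = (df["position"].astype(np.int64) - 1) // int(window_bp)
            ranked = df.sort_values(["call_rate", "position"],
                                    ascending=[False, True], kind="mergesort")
            df["_rank"] = ranked.groupby(["contig", "_bin"], sort=False) \
                                .cumcount().reindex(df.index)
            over_cap = df[df["_rank"] >= per_window_cap]
            # drop cap violators lowest call rate first, but never overshoot
            n_drop = min(len(over_cap), len(df) - target)
            drop_idx = over_cap.sort_values(
                ["call_rate", "position"], ascending=[True, False],
                kind="mergesort").index[:n_drop]
            df = df.drop(index=drop_idx)
            if len(df) > target:
                extra = df.sort_values(["call_rate", "position"],
                                       ascending=[True, False],
                                       kind="mergesort") \
                          .index[: len(df) - target]
                df = df.drop(index=extra)
            df = df.drop(columns=["_bin", "_rank"]).sort_index() \
                   .reset_index(drop=True)
        out[sp] = SpeciesPanel(species=sp, markers=df)
    return out


# ---------------------------------------------------------------------------
# Composition scoring
# ---------------------------------------------------------------------------

def _l_values(matrix: GenotypeMatrix, accession: str,
              panel: SpeciesPanel) -> np.ndarray:
    """Per-locus L scores (1 / 0.5 / 0; missing scores 0) in panel order."""
    idx = matrix.markers.set_index("id").index
    lookup = pd.Series(np.arange(matrix.n_markers), index=idx)
    cols = lookup.reindex(panel.markers["id"])
    if cols.isna().any():
        missing = panel.markers["id"][cols.isna().to_numpy()].iloc[0]
        raise PanelError(f"panel marker {missing!r} not in matrix")
    calls = matrix.genotypes_of(accession)[cols.to_numpy(dtype=int)]
    alt_is_species = (panel.markers["species_allele"] == "alt").to_numpy()
    dos = calls.astype(float)
    L = np.where(alt_is_species, dos / 2.0, 1.0 - dos / 2.0)
    L[calls == MISSING] = 0.0
    return L


def composition(matrix: GenotypeMatrix, accession: str,
                panels: dict[str, SpeciesPanel]) -> CompositionResult:
    """Interspecific composition of one accession from equal-sized panels."""
    sizes = {len(p) for p in panels.values()}
    if len(sizes) > 1:
        logger.warning("panels are not equal-sized: %s",
                       {sp: len(p) for sp, p in panels.items()})
    l_sums, n_inf, n_called, n_total = {}, 0, 0, 0
    for sp, panel in panels.items():
        L = _l_values(matrix, accession, panel)
        l_sums[sp] = float(L.sum())
        n_inf += int((L > 0).sum())
        idx = matrix.markers.set_index("id").index
        lookup = pd.Series(np.arange(matrix.n_markers), index=idx)
        cols = lookup.reindex(panel.markers["id"]).to_numpy(dtype=int)
        n_called += int((matrix.genotypes_of(accession)[cols] != MISSING).sum())
        n_total += len(panel)
    total = sum(l_sums.values())
    defined = total > 0
    percentages = {
        sp: (100.0 * l_sums[sp] / total if defined else math.nan)
        for sp in panels
    }
    return CompositionResult(
        accession=accession, percentages=percentages, l_sums=l_sums,
        n_informative=n_inf, call_rate=n_called / max(n_total, 1),
        defined=defined)


def composition_table(matrix: GenotypeMatrix,
                      panels: dict[str, SpeciesPanel],
                      accessions: list[str] | None = None) -> pd.DataFrame:
    """Composition of many accessions as a tidy DataFrame."""
    accessions = accessions if accessions is not None else matrix.accessions
    rows = []
    for a in accessions:
        r = composition(matrix, a, panels)
        row = {"accession": a, "n_informative": r.n_informative,
               "call_rate": r.call_rate}
        for sp in panels:
            row[f"perc_{sp}"] = r.percentages[sp]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Introgression segments and coverage gaps
# ---------------------------------------------------------------------------

def introgression_segments(matrix: GenotypeMatrix, accession: str,
                           panels: dict[str, SpeciesPanel],
                           min_run: int = 3) -> SegmentReport:
    """Runs of consecutive donor-allele-carrying panel loci along contigs.

    Within each donor panel, loci are ordered by position per contig; maximal
    runs of loci with L >= 0.5 of length >= ``min_run`` become segments
    (span = positions of the flanking supporting loci). Shorter runs are
    reported as singleton putative genotyping errors, mirroring the rule that
    isolated single donor alleles are not treated as introgressions.
    """
    segments = []
    single_rows = []
    for sp, panel in panels.items():
        L_all = _l_values(matrix, accession, panel)
        df = panel.markers[["id", "contig", "position"]].copy()
        df["L"] = L_all
        for contig, sub in df.groupby("contig", sort=False):
            sub = sub.sort_values("position", kind="mergesort")
            carrier = (sub["L"] >= 0.5).to_numpy()
            pos = sub["position"].to_numpy()
            lvals = sub["L"].to_numpy()
            i = 0
            while i < len(carrier):
                if not carrier[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < len(carrier) and carrier[j + 1]:
                    j += 1
                run_l = lvals[i:j + 1]
                n = j - i + 1
                if n >= min_run:
                    if np.all(run_l == 1.0):
                        zyg = "all-hom"
                    elif np.all(run_l == 0.5):
                        zyg = "all-het"
                    else:
                        zyg = "mixed"
                    segments.append(IntrogressionSegment(
                        accession=accession, donor=sp, contig=str(contig),
                        start=int(pos[i]), end=int(pos[j]), n_loci=n,
                        zygosity=zyg))
                else:
                    for k in range(i, j + 1):
                        single_rows.append(
                            (accession, sp, str(contig), int(pos[k]),
                             float(lvals[k])))
                i = j + 1
    singles = pd.DataFrame(
        single_rows,
        columns=["accession", "donor", "contig", "position", "L"])
    return SegmentReport(segments=segments, singletons=singles)


def panel_coverage_gaps(panel: SpeciesPanel,
                        bins: list[tuple[float, float]] = ((3.0, 5.0),
                                                           (5.0, math.inf)),
                        ) -> dict:
    """Counts of inter-locus gaps per size bin (in Mb) and the maximum gap.

    Contigs with fewer than two panel loci cannot contain a gap and are
    skipped (logged).
    """
    counts = {b: 0 for b in bins}
    max_gap = 0.0
    for contig, sub in panel.markers.groupby("contig", sort=False):
        if len(sub) < 2:
            logger.info("contig %s has <2 panel loci, skipped", contig)
            continue
        pos = np.sort(sub["position"].to_numpy())
        gaps_mb = np.diff(pos) / 1e6
        if gaps_mb.size:
            max_gap = max(max_gap, float(gaps_mb.max()))
        for lo, hi in bins:
            counts[(lo, hi)] += int(((gaps_mb >= lo) & (gaps_mb < hi)).sum())
    return {"counts": counts, "max_gap_mb": max_gap}
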