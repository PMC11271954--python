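"""Subspecies-diagnostic marker panels and KASP-style in-silico scoring.

*Cornus kousa* splits into ssp. *chinensis* (Chinese origin) and ssp.
*kousa* (Japanese/Korean origin), distinguished by fixed marker differences.
A small panel of such markers, scored 0 (hom chinensis allele), 0.5 (het),
1 (hom kousa allele), yields a mean kousa-allele fraction per accession that
classifies it as ssp. chinensis, ssp. hybrid, or ssp. kousa. Missing panel
calls are excluded from the mean (physical assay reads have no
missing-scores-zero convention, unlike the interspecific L scoring).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


class SubspeciesPanelError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticMarker:
    """A marker with a fixed allele difference between the two subspecies."""

    id: str
    chinensis_allele: str  # "ref" or "alt"
    kousa_allele: str
    call_rate: float = math.nan

    def __post_init__(self):
        if self.chinensis_allele == self.kousa_allele:
            raise SubspeciesPanelError(
                f"{self.id}: identical alleles for both subspecies")


@dataclass
class PanelScore:
    accession: str
    values: dict[str, float]  # marker id -> 0 / 0.5 / 1 / nan
    mean: float
    subspecies_class: str


def select_diagnostic_markers(matrix: GenotypeMatrix,
                              chinensis_refs: list[str],
                              kousa_refs: list[str],
                              n_panel: int | None = 7,
                              ) -> list[DiagnosticMarker]:
    """Markers with fixed homozygous differences between the subspecies.

    Candidates must be homozygous for one allele in every non-missing
    chinensis reference call and homozygous for the other allele in every
    non-missing kousa reference call. Qualifying markers are ranked by call
    rate over the pooled references and the top ``n_panel`` returned
    (``None`` returns the full diagnostic set; a short supply is returned
    whole with a warning).
    """
    for name, refs in (("chinensis", chinensis_refs), ("kousa", kousa_refs)):
        if len(refs) < 2:
            raise SubspeciesPanelError(
                f"{name} reference set needs >= 2 accessions")

    def fixed_allele(refs):
        sub = matrix.calls[[matrix.accession_index(a) for a in refs]]
        called = sub != MISSING
        any_called = called.any(axis=0)
        lo = np.where(called, sub, np.int8(3)).min(axis=0)
        hi = np.where(called, sub, np.int8(-2)).max(axis=0)
        fixed_hom = any_called & (lo == hi) & ((lo == 0) | (lo == 2))
        return fixed_hom, lo

    chi_fixed, chi_allele = fixed_allele(chinensis_refs)
    kou_fixed, kou_allele = fixed_allele(kousa_refs)
    diagnostic = chi_fixed & kou_fixed & (chi_allele != kou_allele)

    pooled = matrix.calls[[matrix.accession_index(a)
                           for a in chinensis_refs + kousa_refs]]
    call_rate = (pooled != MISSING).mean(axis=0)

    idx = np.flatnonzero(diagnostic)
    order = idx[np.lexsort((idx, -call_rate[idx]))]
    markers = [
        DiagnosticMarker(
            id=str(matrix.markers["id"].iloc[i]),
            chinensis_allele="alt" if chi_allele[i] == 2 else "ref",
            kousa_allele="alt" if kou_allele[i] == 2 else "ref",
            call_rate=float(call_rate[i]),
        )
        for i in order
    ]
    if n_panel is not None and len(markers) < n_panel:
        warnings.warn(
            f"only {len(markers)} diagnostic markers qualify "
            f"(requested {n_panel}); returning all", stacklevel=2)
        return markers
    return markers if n_panel is None else markers[:n_panel]


def classify(mean_kousa_fraction: float, low: float = 0.10,
             high: float = 0.90) -> str:
    """Class from the mean kousa-allele fraction.

    Below ``low`` -> chinensis; above ``high`` -> kousa; the boundary values
    themselves fall in the hybrid band (configurable convention).
    NaN -> undetermined.
    """
    if math.isnan(mean_kousa_fraction):
        return "undetermined"
    if not 0.0 <= mean_kousa_fraction <= 1.0:
        raise ValueError("mean must be in [0, 1]")
    if mean_kousa_fraction < low:
        return "chinensis"
    if mean_kousa_fraction > high:
        return "kousa"
    return "hybrid"


def _marker_values(matrix: GenotypeMatrix, accession: str,
                   panel: list[DiagnosticMarker]) -> dict[str, float]:
    lookup = pd.Series(np.arange(matrix.n_markers),
                       index=matrix.markers["id"])
    values = {}
    for m in panel:
        if m.id not in lookup.index:
            raise SubspeciesPanelError(f"panel marker {m.id!r} not in matrix")
        call = int(matrix.genotypes_of(accession)[lookup[m.id]])
        if call == MISSING:
            values[m.id] = math.nan
        else:
            dos = call / 2.0  # alt-allele fraction of the genotype
            values[m.id] = dos if m.kousa_allele == "alt" else 1.0 - dos
    return values


def score_panel(matrix: GenotypeMatrix, accession: str,
                panel: list[DiagnosticMarker], low: float = 0.10,
                high: float = 0.90) -> PanelScore:
    """Score one accession on a subspecies panel (0 / 0.5 / 1 per marker,
    mean over non-missing, class from :func:`classify`)."""
    values = _marker_values(matrix, accession, panel)
    arr = np.array(list(values.values()))
    ok = ~np.isnan(arr)
    mean = float(arr[ok].mean()) if ok.any() else math.nan
    return PanelScore(accession=accession, values=values, mean=mean,
                      subspecies_class=classify(mean, low, high))


def diagnostic_mean(matrix: GenotypeMatrix, accession: str,
                    full_set: list[DiagnosticMarker]) -> float:
    """Mean kousa-allele fraction over the full diagnostic marker set --
    the full-data membership proxy that a small assay panel is judged
    against."""
    values = _marker_values(matrix, accession, full_set)
    arr = np.array(list(values.values()))
    ok = ~np.isnan(arr)
    if not ok.any():
        return math.nan
    return float(arr[ok].mean())


def concordance(panel_classes: dict[str, str],
                reference_classes: dict[str, str]) -> tuple[float, pd.DataFrame]:
    """Agreement fraction between two class assignments plus a per-accession
    table listing disagreements."""
    shared = sorted(set(panel_classes) & set(reference_classes))
    if not shared:
        raise SubspeciesPanelError("no accessions in common")
    rows = [(a, panel_classes[a], reference_classes[a],
             panel_classes[a] == reference_classes[a]) for a in shared]
    table = pd.DataFrame(rows, columns=["accession", "panel_class",
                                        "reference_class", "agree"])
    return float(table["agree"].mean()), table


def score_table(matrix: GenotypeMatrix, accessions: list[str],
                panel: list[DiagnosticMarker]) -> pd.DataFrame:
    """Per-accession panel values / mean / class, one row per accession --
    the tabular analog of a panel heat map (NaN marks missing calls)."""
    rows = []
    for a in accessions:
        s = score_panel(matrix, a, panel)
        row = {"accession": a, **s.values, "mean": s.mean,
               "class": s.subspecies_class}
        rows.append(row)
    return pd.DataFrame(rows)
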