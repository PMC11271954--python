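"""Pedigree descriptions: founders, crosses, selfs, open pollination, clones.

A pedigree is a DAG of :class:`PedigreeNode`. Founders carry a species (or
subspecies pool) label; derived nodes reference their parents. Open
pollination (OP) nodes have an unsampled pollen parent whose species is
assumed -- in the dogwood breeding context OP events in *C. kousa* blocks are
assumed to be pollinations by *C. kousa*.
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import pandas as pd

NODE_KINDS = ("founder", "cross", "self", "op", "clone", "apomict")


class PedigreeError(ValueError):
    """Raised for cyclic, incomplete, or malformed pedigrees."""


@dataclass(frozen=True)
class PedigreeNode:
    """One individual in a pedigree.

    ``kind`` is one of ``founder`` (no parents, ``species`` required),
    ``cross`` (two parents), ``self`` (one parent), ``op`` (mother +
    assumed ``pollen_species``), ``clone`` / ``apomict`` (one parent,
    genetically identical progeny).
    """

    id: str
    kind: str
    parents: tuple[str, ...] = ()
    species: str | None = None
    pollen_species: str | None = None

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise PedigreeError(f"{self.id}: unknown node kind {self.kind!r}")
        n_expected = {"founder": 0, "cross": 2, "self": 1, "op": 1,
                      "clone": 1, "apomict": 1}[self.kind]
        if len(self.parents) != n_expected:
            raise PedigreeError(
                f"{self.id}: kind {self.kind!r} takes {n_expected} parent(s), "
                f"got {len(self.parents)}")
        if self.kind == "founder" and not self.species:
            raise PedigreeError(f"{self.id}: founder without species label")


def topological_order(nodes: list[PedigreeNode]) -> list[PedigreeNode]:
    """Nodes sorted parents-first; raises :class:`PedigreeError` on cycles
    or references to undefined parents."""
    by_id = {n.id: n for n in nodes}
    if len(by_id) != len(nodes):
        raise PedigreeError("duplicate node ids in pedigree")
    for n in nodes:
        for p in n.parents:
            if p not in by_id:
                raise PedigreeError(f"{n.id}: unknown parent {p!r}")
    ts = TopologicalSorter({n.id: set(n.parents) for n in nodes})
    try:
        order = list(ts.static_order())
    except CycleError as exc:
        raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc
    return [by_id[i] for i in order]


def parse_pedigree(source: str | pd.DataFrame) -> list[PedigreeNode]:
    """Parse a pedigree from CSV (or an equivalent DataFrame).

    Columns: ``id, type, parent1, parent2``. ``type`` is one of the node
    kinds, with founders written ``founder:<species>`` and OP nodes
    optionally ``op:<pollen_species>`` (pollen species may also be supplied
    at evaluation time).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype=str)
    nodes = []
    for row in df.itertuples(index=False):
        kind_spec = row.type.strip()
        kind, _, label = kind_spec.partition(":")
        parents = tuple(
            p for p in (getattr(row, "parent1", None), getattr(row, "parent2", None))
            if p is not None and not pd.isna(p) and str(p).strip() != "")
        nodes.append(PedigreeNode(
            id=str(row.id),
            kind=kind,
            parents=parents,
            species=label or None if kind == "founder" else None,
            pollen_species=label or None if kind == "op" else None,
        ))
    topological_order(nodes)  # validates
    return nodes


def expected_composition(nodes: list[PedigreeNode],
                         recurrent_species_for_op: str | None = None,
                         species: list[str] | None = None,
                         ) -> dict[str, dict[str, float]]:
    """Pedigree-expected species percentages for every node.

    Founders are 100% their own species. A cross averages its parents'
    vectors; a self, clone, or apomict copies its parent's vector; an OP
    node averages the mother's vector with the pure vector of the assumed
    pollen species (per-node ``pollen_species`` wins over the global
    ``recurrent_species_for_op`` default). Under repeated backcrossing the
    donor percentage halves each generation: 50, 25, 12.5, 6.25, ...
    """
    order = topological_order(nodes)
    if species is None:
        species = sorted({n.species for n in order if n.kind == "founder"}
                         | {n.pollen_species for n in order
                            if n.kind == "op" and n.pollen_species}
                         | ({recurrent_species_for_op}
                            if recurrent_species_for_op else set()))
    pure = {s: {t: (100.0 if t == s else 0.0) for t in species}
            for s in species}

    comp: dict[str, dict[str, float]] = {}
    for n in order:
        if n.kind == "founder":
            if n.species not in pure:
                raise PedigreeError(f"{n.id}: founder species {n.species!r} "
                                    "not in species list")
            comp[n.id] = dict(pure[n.species])
        elif n.kind == "cross":
            a, b = (comp[p] for p in n.parents)
            comp[n.id] = {s: (a[s] + b[s]) / 2.0 for s in species}
        elif n.kind in ("self", "clone", "apomict"):
            comp[n.id] = dict(comp[n.parents[0]])
        elif n.kind == "op":
            pollen = n.pollen_species or recurrent_species_for_op
            if pollen is None:
                raise PedigreeError(
                    f"{n.id}: OP node needs a pollen species (none assumed)")
            if pollen not in pure:
                raise PedigreeError(f"{n.id}: pollen species {pollen!r} "
                                    "not in species list")
            mother = comp[n.parents[0]]
            comp[n.id] = {s: (mother[s] + pure[pollen][s]) / 2.0
                          for s in species}
    return comp


def backcross_chain(recurrent: str, donor: str, n_backcrosses: int,
                    ) -> list[PedigreeNode]:
    """Convenience pedigree: F1 = recurrent x donor, then ``n_backcrosses``
    successive crosses to fresh recurrent-species founders (BC1, BC2, ...)."""
    nodes = [
        PedigreeNode("R0", "founder", species=recurrent),
        PedigreeNode("D0", "founder", species=donor),
        PedigreeNode("F1", "cross", parents=("R0", "D0")),
    ]
    prev = "F1"
    for g in range(1, n_backcrosses + 1):
        rec = f"R{g}"
        nodes.append(PedigreeNode(rec, "founder", species=recurrent))
        nodes.append(PedigreeNode(f"BC{g}", "cross", parents=(prev, rec)))
        prev = f"BC{g}"
    return nodes
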