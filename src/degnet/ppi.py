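"""Protein–protein interaction subnetwork extraction and chromosome co-location.

Validated genes are dropped into a background PPI edge list; the direct
seed–seed interaction pairs (and, for context, first-neighbor edges) are
extracted, and each interacting pair is classified as lying on the same or
different chromosomes — the observable behind cis/trans regulatory arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .types import GeneRecord

logger = logging.getLogger(__name__)

__all__ = ["InteractionPair", "Subnetwork", "extract_subnetwork", "classify_pairs",
           "write_circos_links"]

Edge = tuple[str, str]


def _norm(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionPair:
    """An unordered interacting gene pair with chromosome co-location."""

    gene_a: str
    gene_b: str
    chrom_a: str | None
    chrom_b: str | None
    colocation: str  # same_chromosome | different_chromosomes | unknown


@dataclass(frozen=True)
class Subnetwork:
    """Seed-centred PPI subnetwork: seed–seed pairs plus first-neighbor context."""

    seed_edges: tuple[Edge, ...]
    neighbor_edges: tuple[Edge, ...]
    roles: dict[str, str]  # gene → "seed" | "neighbor"

    @property
    def edges(self) -> tuple[Edge, ...]:
        return self.seed_edges + self.neighbor_edges


def extract_subnetwork(
    background: list[Edge], seeds, include_neighbors: bool = True
) -> Subnetwork:
    """Trace seed genes through a background PPI edge list.

    Returns direct seed–seed edges and, when ``include_neighbors``,
    seed–neighbor edges with the neighbor role marked. Neighbor–neighbor
    edges are never included. An empty result (no seed touches the
    background) is returned with a warning, not an error.
    """
    if not background:
        raise ValueError("empty PPI background")
    seeds = set(seeds)
    seed_edges: list[Edge] = []
    neigh_edges: list[Edge] = []
    roles: dict[str, str] = {}
    seen: set[Edge] = set()
    for a, b in background:
        if a == b:
            continue
        e = _norm(a, b)
        if e in seen:
            continue
        seen.add(e)
        in_a, in_b = a in seeds, b in seeds
        if in_a and in_b:
            seed_edges.append(e)
            roles[a] = roles[b] = "seed"
        elif include_neighbors and (in_a or in_b):
            neigh_edges.append(e)
            s, n = (a, b) if in_a else (b, a)
            roles[s] = "seed"
            roles.setdefault(n, "neighbor")
    if not seed_edges and not neigh_edges:
        logger.warning("extract_subnetwork: no seed gene touches the background network")
    return Subnetwork(tuple(sorted(seed_edges)), tuple(sorted(neigh_edges)), roles)


def classify_pairs(
    pairs: list[Edge], locations: dict[str, GeneRecord]
) -> list[InteractionPair]:
    """Classify interacting pairs by chromosome label equality.

    ``unknown`` exactly when either gene lacks a location record.
    """
    out = []
    for a, b in pairs:
        a, b = _norm(a, b)
        ra, rb = locations.get(a), locations.get(b)
        ca = ra.chromosome if ra else None
        cb = rb.chromosome if rb else None
        if ca is None or cb is None:
            colo = "unknown"
        elif ca == cb:
            colo = "same_chromosome"
        else:
            colo = "different_chromosomes"
        out.append(InteractionPair(a, b, ca, cb, colo))
    return out


def write_circos_links(
    pairs: list[InteractionPair], locations: dict[str, GeneRecord], path: str | Path
) -> None:
    """Circos-style link file: chrom_a start_a end_a chrom_b start_b end_b."""
    with open(path, "w") as fh:
        for p in pairs:
            if p.colocation == "unknown":
                continue
            ra, rb = locations[p.gene_a], locations[p.gene_b]
            fh.write(f"{ra.chromosome}\t{ra.start}\t{ra.end}\t"
                     f"{rb.chromosome}\t{rb.start}\t{rb.end}\n")
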