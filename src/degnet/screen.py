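"""RPKM normalization, expression filtering and the paired-consistency DEG screen.

The screen is deliberately not a statistical test: a gene is called
differentially expressed only when *every* tumor/adjacent pair individually
shows a fold change above threshold and an RPKM difference above threshold,
in the same direction. With three pairs this per-pair consistency requirement
is the multiple-replicate filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PairedExpressionSet

logger = logging.getLogger(__name__)

__all__ = ["DEGRecord", "rpkm", "rpkm_matrix", "filter_mapped", "screen_paired", "degs_to_frame"]


@dataclass(frozen=True)
class DEGRecord:
    """One screened gene: direction plus oriented per-pair fold changes and differences.

    ``per_pair_fc`` and ``per_pair_diff`` are oriented so that larger is more
    differential: tumor/adjacent and tumor−adjacent for up-regulated genes,
    the reciprocal/negated quantities for down-regulated genes. ``mean_fc``
    is the geometric mean of the per-pair fold changes.
    """

    gene_id: str
    direction: str  # "up" | "down"
    per_pair_fc: tuple[float, ...]
    per_pair_diff: tuple[float, ...]

    @property
    def mean_fc(self) -> float:
        finite = [f for f in self.per_pair_fc if math.isfinite(f)]
        if not finite:
            return math.inf
        return float(np.exp(np.mean(np.log(finite))))


def rpkm(exon_reads: float, mapped_reads_millions: float, exon_length_kb: float) -> float:
    """Reads per kilobase of exon per million mapped reads.

    ``exon_reads / (mapped_reads_millions * exon_length_kb)``.
    """
    if exon_reads < 0:
        raise ValueError(f"exon_reads must be >= 0, got {exon_reads}")
    if mapped_reads_millions <= 0:
        raise ValueError(f"mapped reads (millions) must be > 0, got {mapped_reads_millions}")
    if exon_length_kb <= 0:
        raise ValueError(f"exon length (kb) must be > 0, got {exon_length_kb}")
    return exon_reads / (mapped_reads_millions * exon_length_kb)


def rpkm_matrix(counts: PairedExpressionSet) -> PairedExpressionSet:
    """Convert a counts matrix to RPKM using per-gene lengths and per-sample library size.

    Library size is the column sum of the count matrix, in millions.
    """
    if counts.unit != "counts":
        raise ValueError("rpkm_matrix expects a counts matrix")
    if counts.gene_lengths_kb is None:
        raise ValueError("counts matrix has no gene lengths; cannot compute RPKM")
    lib_millions = counts.values.sum(axis=0) / 1e6
    if (lib_millions <= 0).any():
        bad = lib_millions.index[lib_millions <= 0].tolist()
        raise ValueError(f"zero library size in samples {bad}")
    lengths = counts.gene_lengths_kb.loc[counts.values.index]
    vals = counts.values.div(lib_millions, axis=1).div(lengths, axis=0)
    return PairedExpressionSet(
        values=vals, pairs=list(counts.pairs), unit="rpkm",
        gene_lengths_kb=counts.gene_lengths_kb,
    )


def filter_mapped(
    expr: PairedExpressionSet, min_rpkm: float = 0.5, mode: str = "any"
) -> PairedExpressionSet:
    """Keep genes expressed at RPKM >= ``min_rpkm`` (inclusive boundary).

    ``mode="any"`` keeps a gene expressed above threshold in at least one
    sample; ``mode="all"`` requires every sample.
    """
    if expr.unit != "rpkm":
        raise ValueError("filter_mapped expects RPKM values")
    if mode == "any":
        keep = (expr.values >= min_rpkm).any(axis=1)
    elif mode == "all":
        keep = (expr.values >= min_rpkm).all(axis=1)
    else:
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_mapped: removed %d of %d genes below RPKM %.3g (%s-sample rule)",
                    removed, len(keep), min_rpkm, mode)
    return expr.subset_genes(list(expr.values.index[keep]))


def _oriented_fc(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """hi/lo with the 0-denominator convention: hi>0,lo=0 → +inf; hi=lo=0 → 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0),
                      np.where(hi > 0, np.inf, 0.0))
    return fc


def screen_paired(
    expr: PairedExpressionSet,
    fc_threshold: float = 1.5,
    diff_threshold: float = 10.0,
    mode: str = "all_pairs",
) -> list[DEGRecord]:
    """Per-pair consistency DEG screen on an RPKM matrix.

    A gene is UP iff in every pair tumor/adjacent > ``fc_threshold`` AND
    tumor − adjacent > ``diff_threshold``; DOWN with roles swapped. A zero
    adjacent value with positive tumor value passes the fold condition
    (ratio treated as +inf); a gene at zero in both samples of a pair fails.
    ``mode="mean"`` instead requires the geometric-mean fold change and mean
    difference to clear the thresholds.
    """
    if expr.unit != "rpkm":
        raise ValueError("screen_paired expects RPKM values")
    if expr.n_pairs == 0:
        raise ValueError("no tumor/adjacent pairs")
    if fc_threshold <= 0 or diff_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    if mode not in ("all_pairs", "mean"):
        raise ValueError(f"mode must be 'all_pairs' or 'mean', got {mode!r}")

    ca = expr.tumor_matrix().to_numpy(dtype=float)
    adj = expr.adjacent_matrix().to_numpy(dtype=float)

    fc_up = _oriented_fc(ca, adj)
    fc_dn = _oriented_fc(adj, ca)
    diff_up = ca - adj
    diff_dn = adj - ca

    if mode == "all_pairs":
        up = (fc_up > fc_threshold).all(axis=1) & (diff_up > diff_threshold).all(axis=1)
        down = (fc_dn > fc_threshold).all(axis=1) & (diff_dn > diff_threshold).all(axis=1)
    else:
        with np.errstate(divide="ignore"):
            gm_up = np.exp(np.mean(np.ma.log(fc_up).filled(-np.inf), axis=1))
            gm_dn = np.exp(np.mean(np.ma.log(fc_dn).filled(-np.inf), axis=1))
        up = (gm_up > fc_threshold) & (diff_up.mean(axis=1) > diff_threshold)
        down = (gm_dn > fc_threshold) & (diff_dn.mean(axis=1) > diff_threshold)

    records: list[DEGRecord] = []
    genes = expr.genes
    for i in np.flatnonzero(up):
        records.append(DEGRecord(genes[i], "up", tuple(fc_up[i]), tuple(diff_up[i])))
    for i in np.flatnonzero(down):
        records.append(DEGRecord(genes[i], "down", tuple(fc_dn[i]), tuple(diff_dn[i])))
    records.sort(key=lambda r: r.gene_id)
    return records


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    """Tabulate DEG records (one row per gene; per-pair columns fc_i / diff_i)."""
    if not records:
        return pd.DataFrame(columns=["gene_id", "direction", "mean_fc"]).set_index("gene_id")
    n = len(records[0].per_pair_fc)
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, "direction": r.direction, "mean_fc": r.mean_fc}
        for i in range(n):
            row[f"fc_{i + 1}"] = r.per_pair_fc[i]
            row[f"diff_{i + 1}"] = r.per_pair_diff[i]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
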