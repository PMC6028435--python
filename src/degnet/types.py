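"""Core domain types shared across the pipeline.

The pipeline's substrate is a gene x sample expression matrix with explicit
tumor/adjacent-normal pairing (``PairedExpressionSet``), plus lightweight
records for gene locations, gene-set collections, clinical phenotypes and
cohort summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "SamplePair",
    "PairedExpressionSet",
    "CohortSummary",
    "GeneSetCollection",
    "ClinicalTable",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round for display with ties away from zero (half-up), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneRecord:
    """A gene's identifier, exon length and chromosomal placement.

    ``length_kb`` is the summed exon length in kilobases used by RPKM
    normalization; coordinates are 0-based half-open and only the chromosome
    label is used downstream (cis/trans co-location).
    """

    gene_id: str
    length_kb: float = 1.0
    chromosome: str = ""
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.length_kb <= 0:
            raise ValueError(f"gene {self.gene_id}: length_kb must be > 0, got {self.length_kb}")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) > end ({self.end})"
            )


@dataclass(frozen=True)
class SamplePair:
    """One patient's (tumor sample, matched adjacent-normal sample)."""

    patient_id: str
    tumor_sample: str
    adjacent_sample: str

    def __post_init__(self) -> None:
        if self.tumor_sample == self.adjacent_sample:
            raise ValueError(
                f"patient {self.patient_id}: tumor and adjacent samples must differ"
            )


@dataclass
class PairedExpressionSet:
    """Gene x sample expression matrix with tumor/adjacent pairing metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with one column per sample. Non-negative.
    pairs
        One :class:`SamplePair` per patient; every referenced sample must be a
        column of ``values``.
    unit
        ``"counts"`` or ``"rpkm"`` — states what the matrix holds.
    """

    values: pd.DataFrame
    pairs: list[SamplePair]
    unit: str = "rpkm"
    gene_lengths_kb: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "rpkm"):
            raise ValueError(f"unit must be 'counts' or 'rpkm', got {self.unit!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene ids: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        cols = set(self.values.columns)
        for p in self.pairs:
            for s in (p.tumor_sample, p.adjacent_sample):
                if s not in cols:
                    raise ValueError(f"pair {p.patient_id}: sample {s!r} not in matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def tumor_matrix(self) -> pd.DataFrame:
        """Tumor samples only, one column per pair, in pair order."""
        return self.values[[p.tumor_sample for p in self.pairs]]

    def adjacent_matrix(self) -> pd.DataFrame:
        """Adjacent-normal samples only, aligned with :meth:`tumor_matrix`."""
        return self.values[[p.adjacent_sample for p in self.pairs]]

    def subset_genes(self, genes: list[str]) -> "PairedExpressionSet":
        lengths = None
        if self.gene_lengths_kb is not None:
            lengths = self.gene_lengths_kb.loc[genes]
        return PairedExpressionSet(
            values=self.values.loc[genes], pairs=list(self.pairs), unit=self.unit,
            gene_lengths_kb=lengths,
        )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort descriptives: patient count, age mean/SD and TNM tallies.

    ``sd_age`` is the sample standard deviation (n-1 denominator).
    ``display()`` rounds half-up to one decimal for reporting.
    """

    n_patients: int
    mean_age: float
    sd_age: float
    tnm_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def display(self) -> str:
        return (
            f"n={self.n_patients}, age {round_half_up(self.mean_age, 1)} "
            f"± {round_half_up(self.sd_age, 1)} years"
        )


class GeneSetCollection:
    """An ordered collection of named gene sets (GO/KEGG terms from a GMT)."""

    def __init__(self, terms: list[tuple[str, str, list[str]]]):
        seen: set[str] = set()
        self._terms: list[tuple[str, str, tuple[str, ...]]] = []
        for term_id, name, members in terms:
            if term_id in seen:
                raise ValueError(f"duplicate term_id {term_id!r}")
            seen.add(term_id)
            # preserve order, drop within-term duplicates
            uniq = tuple(dict.fromkeys(members))
            self._terms.append((term_id, name, uniq))

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms)

    def members(self, term_id: str) -> tuple[str, ...]:
        for tid, _, m in self._terms:
            if tid == term_id:
                return m
        raise KeyError(term_id)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, _, m in self._terms:
            out.update(m)
        return out


@dataclass
class ClinicalTable:
    """Per-patient clinical phenotypes for association testing.

    Columns: ``tumor_size`` (ordinal T category 1-4), optional
    ``tumor_size_cm`` (continuous), ``node`` (0/1), ``metastasis`` (0/1),
    ``stage`` (ordinal 1-4). Indexed by unique patient/sample id.
    """

    data: pd.DataFrame

    ORDINAL_RANGES = {
        "tumor_size": (1, 4),
        "node": (0, 1),
        "metastasis": (0, 1),
        "stage": (1, 4),
    }

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate patient ids in clinical table")
        for col, (lo, hi) in self.ORDINAL_RANGES.items():
            if col in self.data.columns:
                v = self.data[col].dropna()
                bad = v[(v < lo) | (v > hi)]
                if len(bad):
                    raise ValueError(
                        f"clinical column {col!r}: values outside [{lo},{hi}]: "
                        f"{bad.index.tolist()}"
                    )

    @property
    def patients(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def phenotypes(self) -> list[str]:
        return [c for c in self.data.columns if c in self.ORDINAL_RANGES or c == "tumor_size_cm"]

    def vector(self, phenotype: str) -> pd.Series:
        return self.data[phenotype]


def as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)
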