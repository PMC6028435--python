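"""Readers and writers for every file format the pipeline touches.

All formats are plain text: expression TSV (samples in columns, genes in
rows), GMT gene sets, two-column PPI edge lists, BED-like gene locations,
clinical TSV and qPCR Ct tables. Sample pairing follows the ``<patient>ca`` /
``<patient>adj`` column-naming convention used for paired tumor/adjacent
designs; an explicit pairing TSV overrides it.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ClinicalTable,
    CohortSummary,
    GeneRecord,
    GeneSetCollection,
    PairedExpressionSet,
    SamplePair,
)

logger = logging.getLogger(__name__)

_PAIR_RE = re.compile(r"^(?P<patient>.+?)(?P<tissue>ca|adj)$")


def infer_pairs(samples: list[str]) -> list[SamplePair]:
    """Recover (patient, tumor, adjacent) pairs from ``<patient>ca``/``<patient>adj`` names.

    Raises ``ValueError`` naming the orphan sample if any mate is missing or a
    sample does not follow the convention.
    """
    by_patient: dict[str, dict[str, str]] = {}
    for s in samples:
        m = _PAIR_RE.match(s)
        if not m:
            raise ValueError(
                f"sample {s!r} does not follow the '<patient>ca'/'<patient>adj' convention"
            )
        by_patient.setdefault(m["patient"], {})[m["tissue"]] = s
    pairs = []
    for patient in sorted(by_patient, key=_natural_key):
        mates = by_patient[patient]
        if set(mates) != {"ca", "adj"}:
            missing = ({"ca", "adj"} - set(mates)).pop()
            present = next(iter(mates.values()))
            raise ValueError(
                f"unpaired sample {present!r}: no matching '{patient}{missing}'"
            )
        pairs.append(SamplePair(patient, mates["ca"], mates["adj"]))
    return pairs


def _natural_key(s: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s)]


def read_expression(
    path: str | Path,
    unit: str = "rpkm",
    pairing: str | Path | None = None,
    length_column: str = "length_kb",
) -> PairedExpressionSet:
    """Read a gene x sample expression TSV into a :class:`PairedExpressionSet`.

    First column is gene_id; remaining columns are samples. A column named
    ``length_kb`` (configurable) is treated as per-gene exon length, not a
    sample. Pairing is inferred from sample names unless an explicit two/three
    column pairing TSV (patient_id, tumor_sample, adjacent_sample) is given.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    lengths = None
    if length_column in df.columns:
        lengths = df[length_column].astype(float)
        df = df.drop(columns=[length_column])
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    if pairing is not None:
        ptab = pd.read_csv(pairing, sep="\t", dtype=str)
        pairs = [
            SamplePair(r.patient_id, r.tumor_sample, r.adjacent_sample)
            for r in ptab.itertuples()
        ]
    else:
        pairs = infer_pairs(list(df.columns))
    return PairedExpressionSet(values=df, pairs=pairs, unit=unit, gene_lengths_kb=lengths)


def write_expression(expr: PairedExpressionSet, path: str | Path) -> None:
    df = expr.values.copy()
    if expr.gene_lengths_kb is not None:
        df = df.copy()
        df.insert(0, "length_kb", expr.gene_lengths_kb)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term_id <tab> description <tab> member genes...

    Duplicate members within a term are dropped (logged); lines with fewer
    than three fields raise with their line number.
    """
    terms: list[tuple[str, str, list[str]]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: GMT line has {len(fields)} fields, need >=3")
        term_id, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
        if len(set(members)) < len(members):
            logger.info("term %s: dropped %d duplicate members", term_id, len(members) - len(set(members)))
        terms.append((term_id, desc, members))
    if not terms:
        logger.warning("%s: empty GMT file, returning empty collection", path)
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, name, members in collection:
            fh.write("\t".join([term_id, name, *members]) + "\n")


def read_ppi(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list into an undirected, deduplicated edge list.

    Self-loops are dropped (logged); (A,B) and (B,A) collapse to one edge.
    Edges are returned with endpoints sorted within each pair, in first-seen
    order.
    """
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_loops = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{i}: malformed PPI line {line!r}")
            a, b = fields[0], fields[1]
            if a == b:
                n_loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key not in seen:
                seen.add(key)
                edges.append(key)
    if n_loops:
        logger.info("%s: dropped %d self-loop edge(s)", path, n_loops)
    return edges


def write_ppi(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_gene_locations(path: str | Path) -> dict[str, GeneRecord]:
    """Read BED-like locations (chromosome, start, end, gene_id; 0-based half-open)."""
    out: dict[str, GeneRecord] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{i}: BED-like line needs 4 fields")
            chrom, start, end, gene_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if gene_id in out:
                raise ValueError(f"{path}:{i}: duplicate gene_id {gene_id!r}")
            out[gene_id] = GeneRecord(
                gene_id=gene_id, chromosome=chrom, start=start, end=end,
                length_kb=max((end - start) / 1000.0, 1e-9),
            )
    return out


def write_gene_locations(records: dict[str, GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records.values():
            fh.write(f"{rec.chromosome}\t{rec.start}\t{rec.end}\t{rec.gene_id}\n")


def read_clinical(path: str | Path, index_col: str = "patient_id") -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={index_col: str})
    df = df.set_index(index_col)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table: patient, gene, tissue (ca|adj), ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    required = {"patient", "gene", "tissue", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    bad = set(df["tissue"]) - {"ca", "adj"}
    if bad:
        raise ValueError(f"{path}: tissue labels must be 'ca'/'adj', got {sorted(bad)}")
    return df


def summarize_cohort(clinical: ClinicalTable, ages: pd.Series | None = None) -> CohortSummary:
    """Cohort descriptives: n, mean and sample SD (n-1) of age, TNM tallies.

    Ages come either from an ``age`` column of the clinical table or from the
    ``ages`` argument. Fewer than two ages leaves the SD undefined → error.
    """
    if ages is None:
        if "age" not in clinical.data.columns:
            raise ValueError("no ages: clinical table has no 'age' column and none given")
        ages = clinical.data["age"]
    ages = pd.Series(ages).astype(float)
    if len(ages) < 2:
        raise ValueError(f"need >=2 ages for a sample SD, got {len(ages)}")
    tnm: dict[str, dict[str, int]] = {}
    for col, prefix in (("t", "T"), ("n", "N"), ("m", "M"), ("stage", "Stage")):
        if col in clinical.data.columns:
            counts = clinical.data[col].value_counts().sort_index()
            tnm[col] = {f"{prefix}{int(k)}": int(v) for k, v in counts.items()}
    return CohortSummary(
        n_patients=len(clinical.data),
        mean_age=float(np.mean(ages)),
        sd_age=float(np.std(ages, ddof=1)),
        tnm_counts=tnm,
    )


def load_cohort_table() -> ClinicalTable:
    """The packaged 16-patient stage I PTC cohort table (clinical descriptives)."""
    ref = resources.files("degnet.data").joinpath("ptc_cohort_table1.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"patient_id": str}).set_index("patient_id")
    return ClinicalTable(df.rename(columns={"tumor_diameter_cm": "tumor_size_cm"})
                           .rename(columns={"t": "t", "n": "n", "m": "m"}))
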