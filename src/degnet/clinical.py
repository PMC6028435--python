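"""Association of gene expression with clinical phenotypes.

Spearman rank correlation (mid-ranks for ties, two-sided p from the
t-approximation, exact permutation p available at very small n) against
ordinal phenotypes — tumor size (T category or continuous cm), lymph-node
status, distant metastasis, TNM stage — plus a two-group t-test of
expression split by distant-metastasis status.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = ["AssociationResult", "spearman", "ttest_groups", "associate",
           "encode_tnm", "association_grid"]

# default ordinal encodings: T1-T4 → 1-4, N0/N1 → 0/1, M0/M1 → 0/1, stage I-IV → 1-4
DEFAULT_ENCODING = {
    "t": {f"T{i}": i for i in range(1, 5)},
    "n": {"N0": 0, "N1": 1},
    "m": {"M0": 0, "M1": 1},
    "stage": {"I": 1, "II": 2, "III": 3, "IV": 4},
}


@dataclass(frozen=True)
class AssociationResult:
    gene_id: str
    phenotype: str
    rho: float
    p: float
    n: int
    method: str  # spearman | ttest
    t_statistic: float | None = None
    stars: str = ""


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    rho is the Pearson correlation of mid-ranks (average ranks for ties);
    p comes from the t-approximation ``t = rho*sqrt((n-2)/(1-rho^2))`` with
    n-2 df, or from exact permutation enumeration when ``exact`` and n <= 9.
    Constant input is an undefined correlation → error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise ValueError("exact permutation p only for n <= 9")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def ttest_groups(values, group, variant: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test of ``values`` split by binary ``group``.

    Welch (Satterthwaite df) by default; ``variant="student"`` pools
    variances. Each group needs >= 2 observations.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    a = values[group == labels[0]]
    b = values[group == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"each group needs >=2 members ({len(a)} vs {len(b)})")
    if variant not in ("welch", "student"):
        raise ValueError(f"variant must be 'welch' or 'student', got {variant!r}")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def encode_tnm(df: pd.DataFrame, encoding: dict | None = None) -> pd.DataFrame:
    """Map string T/N/M/stage labels to the ordinal codes used for association.

    Already-numeric columns pass through. Output columns: tumor_size, node,
    metastasis, stage (plus tumor_size_cm when present).
    """
    enc = encoding or DEFAULT_ENCODING
    out = pd.DataFrame(index=df.index)
    mapping = [("t", "tumor_size"), ("n", "node"), ("m", "metastasis"), ("stage", "stage")]
    for src, dst in mapping:
        col = src if src in df.columns else dst if dst in df.columns else None
        if col is None:
            continue
        v = df[col]
        if v.dtype == object:
            v = v.map(enc[src])
            if v.isna().any():
                raise ValueError(f"column {col!r}: unmapped labels")
        out[dst] = v.astype(float)
    if "tumor_size_cm" in df.columns:
        out["tumor_size_cm"] = df["tumor_size_cm"].astype(float)
    return out


PHENOTYPES = ("tumor_size", "node", "metastasis", "stage")


def associate(
    expr: pd.DataFrame,
    clinical: ClinicalTable,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    tumor_size_col: str = "tumor_size",
    ttest_variant: str = "welch",
) -> list[AssociationResult]:
    """Per-gene association of expression with each clinical phenotype.

    Spearman against tumor size (ordinal T category by default, continuous cm
    via ``tumor_size_col="tumor_size_cm"``), node, metastasis and stage; plus
    a two-group t-test of expression split by metastasis. Samples are the
    intersection of matrix columns and clinical rows (logged). Constant
    phenotypes are skipped with a warning; absent genes recorded untested.
    """
    common = [s for s in expr.columns if s in set(clinical.data.index)]
    if len(common) < 3:
        raise ValueError(f"need >=3 aligned samples, got {len(common)}")
    if len(common) < expr.shape[1]:
        logger.info("associate: using %d of %d samples present in the clinical table",
                    len(common), expr.shape[1])
    cdata = clinical.data.loc[common]
    genes = list(genes) if genes is not None else list(expr.index)

    phenos = [tumor_size_col] + [p for p in PHENOTYPES[1:]]
    results: list[AssociationResult] = []
    for gene in genes:
        if gene not in expr.index:
            logger.warning("associate: gene %s absent from matrix, recorded untested", gene)
            results.append(AssociationResult(gene, "all", np.nan, np.nan, 0, "untested"))
            continue
        x = expr.loc[gene, common].to_numpy(dtype=float)
        for pheno in phenos:
            if pheno not in cdata.columns:
                continue
            y = cdata[pheno].to_numpy(dtype=float)
            mask = ~np.isnan(y)
            if np.ptp(y[mask]) == 0:
                logger.warning("associate: phenotype %s constant, skipped for %s", pheno, gene)
                continue
            rho, p = spearman(x[mask], y[mask])
            name = "tumor_size" if pheno == "tumor_size_cm" else pheno
            results.append(AssociationResult(gene, name, rho, p, int(mask.sum()),
                                             "spearman", None, _stars(p)))
        if "metastasis" in cdata.columns:
            y = cdata["metastasis"].to_numpy(dtype=float)
            mask = ~np.isnan(y)
            if np.ptp(y[mask]) > 0 and min((y[mask] == 0).sum(), (y[mask] == 1).sum()) >= 2:
                t, p = ttest_groups(x[mask], y[mask], variant=ttest_variant)
                results.append(AssociationResult(gene, "metastasis_ttest", np.nan, p,
                                                 int(mask.sum()), "ttest", t, _stars(p)))
    return results


def association_grid(results: list[AssociationResult]) -> pd.DataFrame:
    """Gene x phenotype grid of r and two-sided P with significance stars."""
    rows = {}
    for r in results:
        if r.method != "spearman":
            continue
        rows.setdefault(r.gene_id, {})[f"{r.phenotype}_r"] = round(r.rho, 3)
        rows[r.gene_id][f"{r.phenotype}_P"] = f"{r.p:.3g}{r.stars}"
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
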