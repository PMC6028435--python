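"""Validation-cohort differential expression, qPCR relative quantification and
discovery/validation concordance.

The cohort stage applies the decision rule p < 0.05 AND fold change > 1.5
(up) or < 2/3 (down), tumor over normal, to a large unpaired two-group count
matrix. The per-gene p-value comes from a two-sided Welch t-test on log2
counts-per-million with a 0.5 pseudocount — a documented, self-contained
two-group test; externally computed p-values (from any DE engine) can be
supplied instead and only the decision rule is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ValidationRecord", "cohort_de", "ddct", "paired_ct_test", "concordance"]


@dataclass(frozen=True)
class ValidationRecord:
    """Direction of one gene in discovery vs validation assays."""

    gene_id: str
    discovery_direction: str        # up | down
    cohort_direction: str           # up | down | ns | untested
    cohort_p: float
    cohort_fc: float
    pcr_direction: str | None = None  # up | down | ns
    concordant: bool = False
    note: str = ""


def _cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size in cohort matrix")
    return (counts + pseudocount).div(lib, axis=1) * 1e6


def cohort_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    p_threshold: float = 0.05,
    fc_up: float = 1.5,
    fc_down: float = 2.0 / 3.0,
    p_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group tumor-vs-normal DE call on a count matrix.

    ``groups`` maps each sample (column) to ``"tumor"`` or ``"normal"``; both
    groups need >= 2 samples. Fold change is mean(tumor CPM)/mean(normal CPM).
    Returns a DataFrame indexed by gene with columns p, fc, direction where
    direction is ``up`` (p < p_threshold and fc > fc_up), ``down``
    (p < p_threshold and fc < fc_down) or ``ns`` — all strict inequalities.
    ``p_values`` substitutes externally computed per-gene p-values for the
    built-in Welch test.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    bad = set(groups) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"group labels must be 'tumor'/'normal', got {sorted(bad)}")
    tum = counts.columns[groups == "tumor"]
    nor = counts.columns[groups == "normal"]
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError(f"each group needs >=2 samples (tumor={len(tum)}, normal={len(nor)})")

    cpm = _cpm(counts)
    fc = cpm[tum].mean(axis=1) / cpm[nor].mean(axis=1)
    if p_values is not None:
        p = p_values.reindex(counts.index)
        if p.isna().any():
            raise ValueError("external p-values missing for some genes")
    else:
        logcpm = np.log2(cpm)
        t, p_arr = stats.ttest_ind(
            logcpm[tum], logcpm[nor], axis=1, equal_var=False
        )
        p = pd.Series(p_arr, index=counts.index)
        # zero-variance genes (all-identical values) give nan; call them ns
        p = p.fillna(1.0)

    direction = pd.Series("ns", index=counts.index)
    direction[(p < p_threshold) & (fc > fc_up)] = "up"
    direction[(p < p_threshold) & (fc < fc_down)] = "down"
    return pd.DataFrame({"p": p, "fc": fc, "direction": direction})


def ddct(
    ct_target_case: float, ct_ref_case: float,
    ct_target_ctrl: float, ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) in each tissue; the case dCt is
    normalized to the control dCt and expressed as a power of two.
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    dct_case = ct_target_case - ct_ref_case
    dct_ctrl = ct_target_ctrl - ct_ref_ctrl
    return float(2.0 ** (-(dct_case - dct_ctrl)))


def paired_ct_test(ct_table: pd.DataFrame, gene: str, variant: str = "ttest",
                   alpha: float = 0.05) -> dict:
    """Per-gene paired test on dCt values across patients.

    ``ct_table`` has columns patient, gene, tissue (ca|adj), ct_target,
    ct_reference. The per-patient dCt (target - reference) in tumor is
    compared with the matched adjacent dCt by a paired two-sided t-test
    (``variant="ttest"``) or Wilcoxon signed-rank (``variant="wilcoxon"``).
    Returns direction (up/down/ns), p, mean relative expression (2^-ddCt).
    """
    sub = ct_table[ct_table["gene"] == gene]
    piv = sub.pivot_table(index="patient", columns="tissue",
                          values=["ct_target", "ct_reference"], aggfunc="mean")
    piv = piv.dropna()
    if len(piv) < 2:
        raise ValueError(f"gene {gene}: need >=2 complete patients, got {len(piv)}")
    dct_ca = piv[("ct_target", "ca")] - piv[("ct_reference", "ca")]
    dct_adj = piv[("ct_target", "adj")] - piv[("ct_reference", "adj")]
    ddct_vals = dct_ca - dct_adj          # negative → higher expression in tumor
    t = float("nan")
    if variant == "ttest":
        t, p = stats.ttest_rel(dct_ca, dct_adj)
    elif variant == "wilcoxon":
        if np.allclose(ddct_vals, 0):
            p = 1.0
        else:
            _, p = stats.wilcoxon(ddct_vals)
    else:
        raise ValueError(f"variant must be 'ttest' or 'wilcoxon', got {variant!r}")
    rel = float(np.mean(2.0 ** (-ddct_vals)))
    if p < alpha:
        direction = "up" if float(np.mean(ddct_vals)) < 0 else "down"
    else:
        direction = "ns"
    return {"gene_id": gene, "p": float(p), "t": float(t), "relative_expression": rel,
            "direction": direction, "n": int(len(piv))}


def concordance(
    discovery: dict[str, str],
    cohort: pd.DataFrame,
    pcr: dict[str, str] | None = None,
) -> list[ValidationRecord]:
    """Compare per-gene discovery direction with cohort (and optional qPCR) calls.

    ``discovery`` maps gene_id → up/down; ``cohort`` is the ``cohort_de``
    output. A gene absent from the cohort matrix is recorded as untested with
    a warning. ``concordant`` requires the cohort direction — and the qPCR
    direction when given — to equal the discovery direction; an opposite
    cohort call is flagged "reversed".
    """
    records = []
    for gene, disc_dir in sorted(discovery.items()):
        pcr_dir = pcr.get(gene) if pcr is not None else None
        if gene not in cohort.index:
            logger.warning("concordance: gene %s absent from cohort matrix", gene)
            records.append(ValidationRecord(gene, disc_dir, "untested", np.nan, np.nan,
                                            pcr_dir, False, "absent from cohort"))
            continue
        row = cohort.loc[gene]
        c_dir = str(row["direction"])
        ok = c_dir == disc_dir
        note = ""
        if c_dir in ("up", "down") and c_dir != disc_dir:
            note = "reversed"
        if pcr_dir is not None:
            ok = ok and (pcr_dir == disc_dir)
            if pcr_dir in ("up", "down") and pcr_dir != disc_dir:
                note = (note + ";" if note else "") + "pcr_reversed"
        records.append(ValidationRecord(gene, disc_dir, c_dir, float(row["p"]),
                                        float(row["fc"]), pcr_dir, bool(ok), note))
    return records


def concordance_summary(records: list[ValidationRecord]) -> dict:
    tested = [r for r in records if r.cohort_direction != "untested"]
    return {
        "n_selected": len(records),
        "n_tested": len(tested),
        "n_cohort_concordant": sum(r.cohort_direction == r.discovery_direction for r in tested),
        "n_concordant": sum(r.concordant for r in records),
    }


def records_to_frame(records: list[ValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"gene_id": r.gene_id, "discovery_direction": r.discovery_direction,
         "cohort_direction": r.cohort_direction, "cohort_p": r.cohort_p,
         "cohort_fc": r.cohort_fc, "pcr_direction": r.pcr_direction or "",
         "concordant": r.concordant, "note": r.note}
        for r in records
    ]).set_index("gene_id") if records else pd.DataFrame()
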