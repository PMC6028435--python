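"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is seed-deterministic and emits a truth table sufficient to
score the downstream stage it feeds. The discovery generator plants fold
changes on negative-binomial counts; counts are realized as a Gamma–Poisson
mixture whose per-gene Gamma draw is shared between the tumor and adjacent
sample of the same patient, so that biological gene-level variation is
patient-level (and cancels within a pair) while marginal counts remain NB
with the configured dispersion. Pathway files plant high-degree hub nodes
carrying differentially expressed genes; clinical phenotypes are discretized
from a Gaussian copula calibrated so the population Spearman correlation with
the planted gene's expression equals the requested value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .types import ClinicalTable, GeneRecord, GeneSetCollection, PairedExpressionSet, SamplePair

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_paired_discovery",
    "simulate_validation_cohort",
    "simulate_pathways",
    "simulate_gene_sets",
    "simulate_ppi_and_locations",
    "simulate_clinical",
    "simulate_ct_table",
    "simulate_bundle",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults the tests run under.

    The discovery arm mirrors a 3-pair paired tumor/adjacent design with a
    planted 4-fold effect at a 30-RPKM baseline on NB counts (dispersion 0.1,
    ~10 M mapped reads per sample); the validation arm is a 60-vs-10 unpaired
    cohort (a desk-scale version of a 513-vs-59 cohort); pathway bundles plant
    degree-``hub_degree`` hub nodes on up-regulated DEGs; the clinical cohort
    plants Spearman correlations between designated genes and ordinal
    phenotypes.
    """

    seed: int = 0
    # discovery
    n_genes: int = 12000
    n_pairs: int = 3
    planted_up: int = 60
    planted_down: int = 40
    effect_fold: float = 4.0
    baseline_rpkm: float = 30.0
    nb_dispersion: float = 0.1
    library_millions: float = 10.0
    patient_sd: float = 0.1          # lognormal sd of the per-patient scale factor
    # validation cohort
    n_tumor: int = 60
    n_normal: int = 10
    # pathways
    n_pathways: int = 5
    pathway_size: int = 12
    planted_hub_count: int = 5
    hub_degree: int = 8
    deg_leaves_per_pathway: int = 2
    # ppi / locations
    ppi_background_edges: int = 300
    planted_pair_count: int = 3
    # clinical
    n_clinical_samples: int = 500
    planted_rho: dict = field(default_factory=lambda: {
        "tumor_size": 0.5, "node": 0.5, "metastasis": 0.0, "stage": 0.5,
    })

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pairs", "n_tumor", "n_normal", "n_pathways",
                     "pathway_size", "planted_hub_count", "n_clinical_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.planted_up + self.planted_down > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.pathway_size < max(self.hub_degree - 1, 0) + 2 * self.deg_leaves_per_pathway + 1:
            raise ValueError("pathway_size too small for hub_degree and DEG leaves")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_truth(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene truth: direction (up/down/null), baseline RPKM, exon length.

    Planted genes sit at exactly ``baseline_rpkm`` in normal tissue; null
    genes draw a lognormal baseline spanning the mapped-gene filter boundary.
    Null baselines are rescaled so that the transcriptome's total
    RPKM x length equals one million per million mapped reads — i.e. a
    normal sample's realized library size matches the nominal sequencing
    depth and recomputed RPKM agrees with the planted baselines. This keeps
    the planted fold changes a ~1% composition perturbation, as in real bulk
    RNA-seq, rather than letting them inflate the tumor library totals.
    """
    rng = config.rng(0)
    genes = _gene_ids(config.n_genes)
    direction = np.array(["null"] * config.n_genes, dtype=object)
    n_planted = config.planted_up + config.planted_down
    if config.effect_fold > 1 and n_planted:
        planted = rng.choice(config.n_genes, size=n_planted, replace=False)
        direction[planted[: config.planted_up]] = "up"
        direction[planted[config.planted_up:]] = "down"
    baseline = rng.lognormal(mean=2.0, sigma=2.0, size=config.n_genes)
    baseline[direction != "null"] = config.baseline_rpkm
    length_kb = rng.uniform(0.5, 5.0, size=config.n_genes)
    null_mask = direction == "null"
    planted_total = float((baseline * length_kb)[~null_mask].sum())
    null_total = float((baseline * length_kb)[null_mask].sum())
    if null_total > 0:
        target = max(1e6 - planted_total, 0.0)
        baseline[null_mask] *= target / null_total
    return pd.DataFrame({
        "gene_id": genes, "direction": direction,
        "baseline_rpkm": baseline, "length_kb": length_kb,
    }).set_index("gene_id")


def _fold_vector(truth: pd.DataFrame, effect_fold: float) -> np.ndarray:
    fold = np.ones(len(truth))
    fold[truth["direction"] == "up"] = effect_fold
    fold[truth["direction"] == "down"] = 1.0 / effect_fold
    return fold


def simulate_paired_discovery(
    config: SimulationConfig, truth: pd.DataFrame | None = None
) -> tuple[PairedExpressionSet, pd.DataFrame]:
    """Paired tumor/adjacent NB count matrix plus the planting truth table.

    Counts are Gamma–Poisson: per gene and patient one Gamma draw (shape
    1/dispersion) sets the shared biological baseline; the tumor sample's mean
    is multiplied by the planted fold. Samples are named ``<i>ca``/``<i>adj``.
    """
    if truth is None:
        truth = make_truth(config)
    rng = config.rng(1)
    n_g = len(truth)
    mu_counts = (truth["baseline_rpkm"] * truth["length_kb"]).to_numpy() * config.library_millions
    fold = _fold_vector(truth, config.effect_fold)

    cols: dict[str, np.ndarray] = {}
    pairs: list[SamplePair] = []
    for p in range(1, config.n_pairs + 1):
        patient_factor = rng.lognormal(mean=0.0, sigma=config.patient_sd)
        # shared per-(gene, patient) biological mean, Gamma with mean mu_counts
        if config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, scale=mu_counts * config.nb_dispersion)
        else:
            lam = mu_counts.copy()
        lam = lam * patient_factor
        cols[f"{p}adj"] = rng.poisson(lam)
        cols[f"{p}ca"] = rng.poisson(lam * fold)
        pairs.append(SamplePair(str(p), f"{p}ca", f"{p}adj"))

    order = [s for p in range(1, config.n_pairs + 1) for s in (f"{p}ca", f"{p}adj")]
    values = pd.DataFrame(cols, index=truth.index)[order].astype(float)
    expr = PairedExpressionSet(values=values, pairs=pairs, unit="counts",
                               gene_lengths_kb=truth["length_kb"].astype(float))
    return expr, truth


def simulate_validation_cohort(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Unpaired two-group validation counts (tumor vs normal) on the same genes.

    Per-sample Gamma draws are independent (different patients), so counts are
    marginally NB with the configured dispersion in both groups.
    """
    rng = config.rng(2)
    mu_counts = (truth["baseline_rpkm"] * truth["length_kb"]).to_numpy() * config.library_millions
    fold = _fold_vector(truth, config.effect_fold)

    def draw(mu: np.ndarray, n: int, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for i in range(1, n + 1):
            if config.nb_dispersion > 0:
                shape = 1.0 / config.nb_dispersion
                lam = rng.gamma(shape, scale=mu * config.nb_dispersion)
            else:
                lam = mu
            out[f"{prefix}{i}"] = rng.poisson(lam)
        return out

    cols = {**draw(mu_counts * fold, config.n_tumor, "T"),
            **draw(mu_counts, config.n_normal, "N")}
    counts = pd.DataFrame(cols, index=truth.index).astype(float)
    groups = pd.Series(["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
                       index=counts.columns)
    return counts, groups


# ---------------------------------------------------------------------------
# pathway bundles


def planted_hub_genes(config: SimulationConfig, truth: pd.DataFrame) -> list[str]:
    """The up-regulated planted genes designated as hub-node genes."""
    up = sorted(truth.index[truth["direction"] == "up"])
    if config.planted_hub_count > len(up):
        raise ValueError(
            f"planted_hub_count={config.planted_hub_count} exceeds the "
            f"{len(up)} planted up-regulated genes (hubs sit on up-DEGs)")
    rng = config.rng(3)
    idx = rng.choice(len(up), size=config.planted_hub_count, replace=False)
    return [up[i] for i in sorted(idx)]


def _kgml(pathway_id: str, entries: list[tuple[int, str, str]],
          relations: list[tuple[int, int, str]]) -> str:
    lines = [f'<?xml version="1.0"?>\n<pathway name="{pathway_id}" title="{pathway_id}">']
    for eid, etype, name in entries:
        lines.append(f'  <entry id="{eid}" type="{etype}" name="{name}"/>')
    for e1, e2, subtype in relations:
        lines.append(f'  <relation entry1="{e1}" entry2="{e2}" type="PPrel">')
        lines.append(f'    <subtype name="{subtype}" value="--&gt;"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def simulate_pathways(
    config: SimulationConfig, truth: pd.DataFrame, out_dir: str | Path
) -> tuple[list[Path], list[str]]:
    """Write pathway XML files planting high-degree DEG hub nodes.

    Each pathway carries one hub entry (an up-regulated planted gene) wired to
    ``hub_degree - 1`` spoke entries in its own pathway plus one entry in the
    next pathway (so every hub node's integrated degree equals ``hub_degree``
    when ``hub_degree >= 2``, and hubs span pathways, exercising node
    merging). Non-hub planted DEGs appear only in degree-1 leaf entries;
    background nodes top out at degree 2, so the top-decile degree cut
    recovers exactly the planted hubs. One compound entry per pathway
    exercises the parser's non-gene drop rule.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(4)
    hubs = planted_hub_genes(config, truth)
    nulls = sorted(truth.index[truth["direction"] == "null"])
    non_hub_degs = sorted(set(truth.index[truth["direction"] != "null"]) - set(hubs))

    n_bg_per_pw = config.pathway_size - 1 - config.deg_leaves_per_pathway
    null_pool = list(rng.permutation(nulls))
    deg_pool = list(rng.permutation(non_hub_degs))

    paths: list[Path] = []
    spoke_names: list[list[str]] = []
    pathway_defs = []
    for i in range(config.n_pathways):
        hub = hubs[i % len(hubs)]
        bg = [null_pool.pop() for _ in range(n_bg_per_pw)]
        leaves = [deg_pool.pop() if deg_pool else null_pool.pop()
                  for _ in range(config.deg_leaves_per_pathway)]
        pathway_defs.append((f"pw{i + 1}", hub, bg, leaves))
        spoke_names.append(bg)

    for i, (pid, hub, bg, leaves) in enumerate(pathway_defs):
        entries: list[tuple[int, str, str]] = []
        relations: list[tuple[int, int, str]] = []
        eid = 1
        ids: dict[str, int] = {}

        def add(name: str, etype: str = "gene") -> int:
            nonlocal eid
            if name in ids:
                return ids[name]
            entries.append((eid, etype, name))
            ids[name] = eid
            eid += 1
            return ids[name]

        hub_id = add(hub)
        n_spokes = max(config.hub_degree - 1, 0) if config.hub_degree >= 2 else config.hub_degree
        spokes = bg[:n_spokes]
        partners = bg[n_spokes:]
        for s in spokes:
            relations.append((hub_id, add(s), "activation"))
        for b in partners:
            add(b)
        # leaf entries carrying non-hub DEGs, each tied once to a background partner
        for j, leaf in enumerate(leaves):
            partner = partners[j % len(partners)] if partners else spokes[j % len(spokes)]
            relations.append((add(leaf), ids[partner], "expression"))
        if len(partners) >= 2:
            relations.append((ids[partners[0]], ids[partners[1]], "binding/association"))
        # cross-pathway appearance of the previous hub (counts toward its degree)
        if config.hub_degree >= 2 and config.n_pathways > 1:
            prev_hub = pathway_defs[(i - 1) % config.n_pathways][1]
            if prev_hub not in ids:
                target = spokes[0] if spokes else partners[0]
                relations.append((add(prev_hub), ids[target], "activation"))
        # a compound entry with a relation: dropped by the parser
        comp_id = add(f"cpd:C{i:05d}", etype="compound")
        relations.append((hub_id, comp_id, "compound"))

        path = out_dir / f"{pid}.xml"
        path.write_text(_kgml(pid, entries, relations))
        paths.append(path)
    return paths, hubs


def simulate_gene_sets(
    config: SimulationConfig, truth: pd.DataFrame,
    n_terms: int = 20, term_size: int = 40, n_enriched: int = 2,
    planted_fraction: float = 0.5,
) -> GeneSetCollection:
    """A GMT-style collection with terms enriched for the planted DEGs.

    ``n_enriched`` terms draw ``planted_fraction`` of their members from the
    planted DEGs; the rest draw uniformly from null genes.
    """
    rng = config.rng(5)
    degs = sorted(truth.index[truth["direction"] != "null"])
    nulls = sorted(truth.index[truth["direction"] == "null"])
    terms = []
    for t in range(n_terms):
        if t < n_enriched and degs:
            n_deg = min(int(round(planted_fraction * term_size)), len(degs))
            members = list(rng.choice(degs, size=n_deg, replace=False))
            members += list(rng.choice(nulls, size=term_size - n_deg, replace=False))
        else:
            members = list(rng.choice(nulls, size=min(term_size, len(nulls)), replace=False))
        terms.append((f"TERM{t:03d}", f"synthetic term {t}", sorted(members)))
    return GeneSetCollection(terms)


# ---------------------------------------------------------------------------
# PPI and chromosome locations


def simulate_ppi_and_locations(
    config: SimulationConfig, truth: pd.DataFrame, hubs: list[str] | None = None
) -> tuple[list[tuple[str, str]], dict[str, GeneRecord], list[tuple[str, str]]]:
    """Random PPI background plus planted seed–seed edges and gene locations.

    Planted interacting pairs are drawn among the hub genes, sharing one gene
    across two pairs (the paper-like A–B, A–C, D–E motif when counts allow);
    their genes are placed on pairwise different chromosomes. Returns
    (edges, locations, planted_pairs).
    """
    rng = config.rng(6)
    genes = list(truth.index)
    if hubs is None:
        hubs = planted_hub_genes(config, truth)

    planted_pairs: list[tuple[str, str]] = []
    k = config.planted_pair_count
    if k and len(hubs) >= 2:
        if k >= 3 and len(hubs) >= 5:
            planted_pairs = [(hubs[0], hubs[1]), (hubs[0], hubs[2]), (hubs[3], hubs[4])]
            extra = k - 3
        else:
            extra = k
        pool = [tuple(sorted(p)) for p in zip(hubs[:-1], hubs[1:])]
        for p in pool:
            if extra <= 0:
                break
            if tuple(sorted(p)) not in {tuple(sorted(q)) for q in planted_pairs}:
                planted_pairs.append(p)
                extra -= 1
    planted_pairs = [tuple(sorted(p)) for p in planted_pairs]

    edges: list[tuple[str, str]] = list(planted_pairs)
    seen = set(planted_pairs)
    while len(edges) < len(planted_pairs) + config.ppi_background_edges:
        a, b = rng.choice(len(genes), size=2, replace=False)
        e = tuple(sorted((genes[a], genes[b])))
        if e not in seen:
            seen.add(e)
            edges.append(e)

    chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    locations: dict[str, GeneRecord] = {}
    # planted pair genes first, on pairwise distinct chromosomes
    pair_genes = sorted({g for p in planted_pairs for g in p})
    for i, g in enumerate(pair_genes):
        start = int(rng.integers(1_000, 5_000_000))
        locations[g] = GeneRecord(g, chromosome=chroms[i % len(chroms)],
                                  start=start, end=start + int(rng.integers(1_000, 100_000)))
    for g in genes:
        if g in locations:
            continue
        start = int(rng.integers(1_000, 5_000_000))
        locations[g] = GeneRecord(g, chromosome=str(rng.choice(chroms)),
                                  start=start, end=start + int(rng.integers(1_000, 100_000)))
    return edges, locations, planted_pairs


# ---------------------------------------------------------------------------
# clinical cohort

PHENOTYPE_PROBS = {
    "tumor_size": (0.4, 0.3, 0.2, 0.1),
    "node": (0.55, 0.45),
    "metastasis": (0.9, 0.1),
    "stage": (0.4, 0.3, 0.2, 0.1),
}
PHENOTYPE_START = {"tumor_size": 1, "node": 0, "metastasis": 0, "stage": 1}

_CALIBRATION_CACHE: dict[tuple, float] = {}


def _induced_spearman(r: float, probs: tuple[float, ...], z1: np.ndarray,
                      e2: np.ndarray) -> float:
    z2 = r * z1 + np.sqrt(max(1.0 - r * r, 0.0)) * e2
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    cat = np.searchsorted(cuts, z2)
    rho, _ = stats.spearmanr(z1, cat)
    return float(rho)


def calibrate_latent_r(target_rho: float, probs: tuple[float, ...],
                       mc_n: int = 200_000) -> float:
    """Latent Gaussian correlation giving Spearman ``target_rho`` after discretization.

    Solved by bisection against a fixed-seed Monte Carlo estimate of the
    induced Spearman correlation; cached per (rho, probs).
    """
    key = (round(float(target_rho), 6), tuple(np.round(probs, 6)))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    if target_rho == 0:
        _CALIBRATION_CACHE[key] = 0.0
        return 0.0
    sign = np.sign(target_rho)
    target = abs(float(target_rho))
    mc = np.random.default_rng(987654321)
    z1 = mc.standard_normal(mc_n)
    e2 = mc.standard_normal(mc_n)
    max_rho = _induced_spearman(1.0, probs, z1, e2)
    if target > max_rho:
        raise ValueError(
            f"planted Spearman {target_rho} unattainable: discretization caps it at "
            f"{sign * max_rho:.3f} for category probabilities {probs}"
        )
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _induced_spearman(mid, probs, z1, e2) < target:
            lo = mid
        else:
            hi = mid
    r = float(sign * 0.5 * (lo + hi))
    _CALIBRATION_CACHE[key] = r
    return r


def simulate_clinical_expression(
    config: SimulationConfig, truth: pd.DataFrame, n_extra_genes: int = 10
) -> pd.DataFrame:
    """Expression (log-scale CPM-like) for the clinical cohort's tumor samples.

    Rows are the phenotype-designated genes (one planted DEG per phenotype)
    plus ``n_extra_genes`` null genes; columns are ``P1..Pn`` samples.
    """
    rng = config.rng(7)
    genes = clinical_gene_map(config, truth)
    extra = sorted(truth.index[truth["direction"] == "null"])[:n_extra_genes]
    rows = sorted(set(genes.values()) | set(extra))
    vals = rng.lognormal(mean=3.0, sigma=1.0, size=(len(rows), config.n_clinical_samples))
    cols = [f"P{i}" for i in range(1, config.n_clinical_samples + 1)]
    return pd.DataFrame(vals, index=rows, columns=cols)


def clinical_gene_map(config: SimulationConfig, truth: pd.DataFrame) -> dict[str, str]:
    """Deterministic assignment of one planted gene per phenotype."""
    planted = sorted(truth.index[truth["direction"] != "null"])
    if not planted:
        planted = sorted(truth.index)
    phenos = sorted(config.planted_rho)
    return {ph: planted[i % len(planted)] for i, ph in enumerate(phenos)}


def simulate_clinical(
    config: SimulationConfig, expr: pd.DataFrame, truth: pd.DataFrame | None = None,
    gene_map: dict[str, str] | None = None,
) -> tuple[ClinicalTable, pd.DataFrame]:
    """Ordinal clinical phenotypes with planted Spearman correlations.

    For each phenotype, the designated gene's expression ranks are mapped to
    normal scores, mixed with Gaussian noise at the calibrated latent
    correlation, and the latent variable is discretized at the phenotype's
    category probabilities. Returns the clinical table (patients = matrix
    columns) and a truth frame (phenotype, gene, planted_rho).
    """
    if gene_map is None:
        if truth is None:
            raise ValueError("need truth or an explicit gene_map")
        gene_map = clinical_gene_map(config, truth)
    rng = config.rng(8)
    n = expr.shape[1]
    data: dict[str, np.ndarray] = {}
    truth_rows = []
    for pheno in sorted(config.planted_rho):
        rho = float(config.planted_rho[pheno])
        gene = gene_map[pheno]
        if gene not in expr.index:
            raise ValueError(f"clinical gene {gene} absent from expression matrix")
        probs = PHENOTYPE_PROBS[pheno]
        r = calibrate_latent_r(rho, probs)
        ranks = stats.rankdata(expr.loc[gene].to_numpy(dtype=float))
        z1 = stats.norm.ppf((ranks - 0.5) / n)
        latent = r * z1 + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n)
        cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
        data[pheno] = np.searchsorted(cuts, latent) + PHENOTYPE_START[pheno]
        truth_rows.append({"phenotype": pheno, "gene_id": gene, "planted_rho": rho})
    table = ClinicalTable(pd.DataFrame(data, index=list(expr.columns)))
    return table, pd.DataFrame(truth_rows).set_index("phenotype")


def simulate_ct_table(
    config: SimulationConfig, truth: pd.DataFrame, genes: list[str],
    n_patients: int = 16, ct_noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Paired qPCR Ct table consistent with the planted directions.

    Reference Ct ~ 15, adjacent-tissue target Ct ~ 22; the tumor target Ct is
    shifted by -log2(fold) for up-regulated genes (+ for down), plus Gaussian
    measurement noise.
    """
    rng = config.rng(9)
    rows = []
    log2_fold = np.log2(config.effect_fold)
    for gene in genes:
        direction = truth.loc[gene, "direction"] if gene in truth.index else "null"
        shift = {"up": -log2_fold, "down": log2_fold}.get(str(direction), 0.0)
        for p in range(1, n_patients + 1):
            base = 22.0 + rng.normal(0, 0.5)
            for tissue, delta in (("adj", 0.0), ("ca", shift)):
                rows.append({
                    "patient": str(p), "gene": gene, "tissue": tissue,
                    "ct_target": base + delta + rng.normal(0, ct_noise_sd),
                    "ct_reference": 15.0 + rng.normal(0, ct_noise_sd),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full bundle


def simulate_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus truth tables into ``out_dir``.

    Returns a name → path map of everything written.
    """
    from . import io as dio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    truth = make_truth(config)
    discovery, _ = simulate_paired_discovery(config, truth)
    files["discovery_counts"] = out_dir / "discovery_counts.tsv"
    dio.write_expression(discovery, files["discovery_counts"])

    counts, groups = simulate_validation_cohort(config, truth)
    files["validation_counts"] = out_dir / "validation_counts.tsv"
    counts.index.name = "gene_id"
    counts.to_csv(files["validation_counts"], sep="\t", float_format="%.6g")
    files["validation_groups"] = out_dir / "validation_groups.tsv"
    groups.rename("group").to_frame().rename_axis("sample").to_csv(
        files["validation_groups"], sep="\t")

    pw_dir = out_dir / "pathways"
    pw_paths, hubs = simulate_pathways(config, truth, pw_dir)
    files["pathway_dir"] = pw_dir
    files["truth_hubs"] = out_dir / "truth_hubs.tsv"
    pd.Series(hubs, name="gene_id").to_csv(files["truth_hubs"], sep="\t", index=False)

    collection = simulate_gene_sets(config, truth)
    files["gene_sets"] = out_dir / "gene_sets.gmt"
    dio.write_gmt(collection, files["gene_sets"])

    edges, locations, planted_pairs = simulate_ppi_and_locations(config, truth, hubs)
    files["ppi"] = out_dir / "ppi.tsv"
    dio.write_ppi(edges, files["ppi"])
    files["locations"] = out_dir / "locations.bed"
    dio.write_gene_locations(locations, files["locations"])
    files["truth_pairs"] = out_dir / "truth_pairs.tsv"
    pd.DataFrame(planted_pairs, columns=["gene_a", "gene_b"]).to_csv(
        files["truth_pairs"], sep="\t", index=False)

    clin_expr = simulate_clinical_expression(config, truth)
    files["clinical_expression"] = out_dir / "clinical_expression.tsv"
    clin_expr.index.name = "gene_id"
    clin_expr.to_csv(files["clinical_expression"], sep="\t", float_format="%.6g")
    clinical, clin_truth = simulate_clinical(config, clin_expr, truth)
    files["clinical"] = out_dir / "clinical.tsv"
    dio.write_clinical(clinical, files["clinical"])
    files["truth_clinical"] = out_dir / "truth_clinical.tsv"
    clin_truth.to_csv(files["truth_clinical"], sep="\t")

    ct = simulate_ct_table(config, truth, hubs)
    files["ct_table"] = out_dir / "ct_table.tsv"
    ct.to_csv(files["ct_table"], sep="\t", index=False, float_format="%.4f")

    files["truth_genes"] = out_dir / "truth_genes.tsv"
    truth.to_csv(files["truth_genes"], sep="\t", float_format="%.6g")
    return files
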