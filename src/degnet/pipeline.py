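"""End-to-end pipeline driver.

Runs the discovery-to-validation stages in order — paired DEG screen, term
enrichment, integrated pathway network and hub selection, validation-cohort
concordance, PPI/chromosome classification, clinical association — from a
YAML config naming inputs and thresholds (defaults are the screen's standard
values). Every output is a sorted, fixed-format TSV, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import clinical as clin_mod
from . import enrichment as enr_mod
from . import io as dio
from . import network as net_mod
from . import ppi as ppi_mod
from . import screen as scr_mod
from . import simulate as sim_mod
from . import validation as val_mod

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_THRESHOLDS", "run_pipeline"]

DEFAULT_THRESHOLDS = {
    "min_rpkm": 0.5,
    "mapped_mode": "any",
    "fc_threshold": 1.5,
    "diff_threshold": 10.0,
    "screen_mode": "all_pairs",
    "enrich_alpha": 0.05,
    "top_fraction": 0.10,
    "p_threshold": 0.05,
    "fc_up": 1.5,
    "fc_down": 2.0 / 3.0,
}

FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Run every stage and write the result bundle to disk.

    ``config`` (YAML path or dict) holds ``seed``, ``out_dir``, optional
    ``simulate: true`` with a ``sim`` block of :class:`SimulationConfig`
    overrides, an ``inputs`` block of file paths, a ``thresholds`` block and
    ``allow_partial``. With ``allow_partial: true`` a stage whose inputs are
    missing is skipped with a warning; otherwise any stage error aborts the
    run naming the stage. Returns a name → path map of outputs.
    """
    cfg = _load_config(config)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    out_dir = Path(out_dir or cfg.get("out_dir", "degnet_results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **(cfg.get("thresholds") or {})}
    allow_partial = bool(cfg.get("allow_partial", False))

    inputs = {k: Path(v) for k, v in (cfg.get("inputs") or {}).items()}
    if cfg.get("simulate"):
        sim_cfg = sim_mod.SimulationConfig(**{"seed": seed, **(cfg.get("sim") or {})})
        inputs = sim_mod.simulate_bundle(sim_cfg, out_dir / "inputs")
    outputs: dict[str, Path] = {}
    log_lines = [f"seed: {seed}"]
    log_lines += [f"threshold {k}: {v}" for k, v in sorted(thresholds.items())]

    def have(*names: str) -> bool:
        return all(n in inputs and Path(inputs[n]).exists() for n in names)

    def skip(stage: str, needed: str) -> None:
        if allow_partial:
            logger.warning("stage %s skipped: missing input %s", stage, needed)
            log_lines.append(f"stage {stage}: SKIPPED (missing {needed})")
        else:
            raise StageError(stage, FileNotFoundError(needed))

    # ---- screen ----------------------------------------------------------
    deg_records: list[scr_mod.DEGRecord] = []
    deg_directions: dict[str, str] = {}
    if have("discovery_counts"):
        try:
            expr = dio.read_expression(inputs["discovery_counts"], unit="counts")
            rpkm = scr_mod.rpkm_matrix(expr)
            mapped = scr_mod.filter_mapped(rpkm, thresholds["min_rpkm"],
                                           mode=thresholds["mapped_mode"])
            deg_records = scr_mod.screen_paired(
                mapped, thresholds["fc_threshold"], thresholds["diff_threshold"],
                mode=thresholds["screen_mode"])
            deg_directions = {r.gene_id: r.direction for r in deg_records}
            outputs["degs"] = out_dir / "degs.tsv"
            scr_mod.degs_to_frame(deg_records).to_csv(
                outputs["degs"], sep="\t", float_format=FLOAT_FMT)
            log_lines.append(
                f"stage screen: {len(mapped.genes)} mapped genes, "
                f"{sum(r.direction == 'up' for r in deg_records)} up / "
                f"{sum(r.direction == 'down' for r in deg_records)} down DEGs")
        except Exception as e:  # noqa: BLE001 - abort with stage name
            raise StageError("screen", e) from e
    else:
        skip("screen", "discovery_counts")
        mapped = None

    # ---- enrichment ------------------------------------------------------
    if have("gene_sets") and deg_records:
        try:
            collection = dio.read_gmt(inputs["gene_sets"])
            universe = sorted(set(mapped.genes) & collection.all_genes())
            for direction in ("up", "down"):
                query = sorted(g for g, d in deg_directions.items() if d == direction)
                results = enr_mod.enrich(query, collection, universe,
                                         alpha=thresholds["enrich_alpha"])
                key = f"enrichment_{direction}"
                outputs[key] = out_dir / f"{key}.tsv"
                enr_mod.results_to_frame(results).to_csv(
                    outputs[key], sep="\t", float_format=FLOAT_FMT)
            log_lines.append(f"stage enrichment: universe {len(universe)} genes")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("enrichment", e) from e
    elif not have("gene_sets"):
        skip("enrichment", "gene_sets")

    # ---- network ---------------------------------------------------------
    hub_genes: list[str] = []
    if have("pathway_dir"):
        try:
            paths = sorted(Path(inputs["pathway_dir"]).glob("*.xml"))
            if not paths:
                raise FileNotFoundError(f"no pathway XML in {inputs['pathway_dir']}")
            graphs = [net_mod.parse_pathway(p) for p in paths]
            graph = net_mod.integrate(graphs)
            net_mod.mark_degs(graph, deg_directions)
            selection = net_mod.select_hub_degs(graph, thresholds["top_fraction"])
            hub_genes = list(selection.hub_genes)
            outputs["network_nodes"] = out_dir / "network_nodes.tsv"
            outputs["network_edges"] = out_dir / "network_edges.tsv"
            net_mod.write_network_tables(graph, outputs["network_nodes"],
                                         outputs["network_edges"])
            outputs["hub_genes"] = out_dir / "hub_genes.tsv"
            with open(outputs["hub_genes"], "w") as fh:
                fh.write("gene_id\tdirection\n")
                for g in selection.hub_genes_up:
                    fh.write(f"{g}\tup\n")
                for g in selection.hub_genes_down:
                    fh.write(f"{g}\tdown\n")
            log_lines.append(
                f"stage network: {graph.n_nodes} nodes, {graph.n_edges} edges, "
                f"{len(selection.top_nodes)} top-degree nodes "
                f"(cutoff degree {selection.cutoff_degree}), {len(hub_genes)} hub DEGs")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("network", e) from e
    else:
        skip("network", "pathway_dir")

    # ---- validation ------------------------------------------------------
    validated: list[str] = []
    selected = hub_genes or sorted(deg_directions)
    if have("validation_counts", "validation_groups") and selected:
        try:
            counts = pd.read_csv(inputs["validation_counts"], sep="\t", index_col=0)
            counts.index = counts.index.astype(str)
            groups = pd.read_csv(inputs["validation_groups"], sep="\t",
                                 index_col=0)["group"]
            de = val_mod.cohort_de(counts, groups, thresholds["p_threshold"],
                                   thresholds["fc_up"], thresholds["fc_down"])
            pcr = None
            if have("ct_table"):
                ct = dio.read_ct_table(inputs["ct_table"])
                pcr = {}
                for gene in selected:
                    if gene in set(ct["gene"]):
                        pcr[gene] = val_mod.paired_ct_test(ct, gene)["direction"]
            records = val_mod.concordance(
                {g: deg_directions[g] for g in selected if g in deg_directions},
                de, pcr)
            validated = sorted(r.gene_id for r in records if r.concordant)
            outputs["validation"] = out_dir / "validation.tsv"
            val_mod.records_to_frame(records).to_csv(
                outputs["validation"], sep="\t", float_format=FLOAT_FMT)
            s = val_mod.concordance_summary(records)
            log_lines.append(
                f"stage validation: {s['n_selected']} selected, {s['n_tested']} tested, "
                f"{s['n_concordant']} concordant")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("validation", e) from e
    elif not have("validation_counts", "validation_groups"):
        skip("validation", "validation_counts/validation_groups")

    # ---- ppi / chromosomes ----------------------------------------------
    seeds = validated or hub_genes
    if have("ppi", "locations") and seeds:
        try:
            edges = dio.read_ppi(inputs["ppi"])
            locations = dio.read_gene_locations(inputs["locations"])
            sub = ppi_mod.extract_subnetwork(edges, seeds)
            pairs = ppi_mod.classify_pairs(list(sub.seed_edges), locations)
            outputs["ppi_edges"] = out_dir / "ppi_edges.tsv"
            with open(outputs["ppi_edges"], "w") as fh:
                fh.write("gene_a\tgene_b\trole_b\n")
                for a, b in sub.seed_edges:
                    fh.write(f"{a}\t{b}\tseed\n")
                for a, b in sub.neighbor_edges:
                    role_b = sub.roles.get(b, "neighbor")
                    fh.write(f"{a}\t{b}\t{role_b}\n")
            outputs["ppi_pairs"] = out_dir / "ppi_pairs.tsv"
            with open(outputs["ppi_pairs"], "w") as fh:
                fh.write("gene_a\tgene_b\tchrom_a\tchrom_b\tcolocation\n")
                for p in pairs:
                    fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.chrom_a or ''}\t"
                             f"{p.chrom_b or ''}\t{p.colocation}\n")
            outputs["circos_links"] = out_dir / "circos_links.tsv"
            ppi_mod.write_circos_links(pairs, locations, outputs["circos_links"])
            log_lines.append(
                f"stage ppi: {len(sub.seed_edges)} seed-seed pairs, "
                f"{len(sub.neighbor_edges)} neighbor edges")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("ppi", e) from e
    elif not have("ppi", "locations"):
        skip("ppi", "ppi/locations")

    # ---- clinical --------------------------------------------------------
    if have("clinical", "clinical_expression"):
        try:
            clin = dio.read_clinical(inputs["clinical"])
            cexpr = pd.read_csv(inputs["clinical_expression"], sep="\t", index_col=0)
            cexpr.index = cexpr.index.astype(str)
            results = clin_mod.associate(cexpr, clin, genes=sorted(cexpr.index))
            outputs["clinical_associations"] = out_dir / "clinical_associations.tsv"
            rows = pd.DataFrame([
                {"gene_id": r.gene_id, "phenotype": r.phenotype, "rho": r.rho,
                 "p": r.p, "n": r.n, "method": r.method, "stars": r.stars}
                for r in results
            ])
            rows.sort_values(["gene_id", "phenotype"]).to_csv(
                outputs["clinical_associations"], sep="\t", index=False,
                float_format=FLOAT_FMT)
            log_lines.append(f"stage clinical: {len(rows)} associations")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("clinical", e) from e
    else:
        skip("clinical", "clinical/clinical_expression")

    outputs["run_log"] = out_dir / "run_log.txt"
    outputs["run_log"].write_text("\n".join(log_lines) + "\n")
    return outputs
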