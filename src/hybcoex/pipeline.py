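"""End-to-end pipeline: simulate -> preprocess -> classify -> network ->
preserve -> diffcor -> hubs -> enrich, with a run manifest.

Each stage reads the fixed-name files produced by earlier stages inside the
output directory, so stages can also be run individually from the CLI.  All
randomized stages derive their seed deterministically from the root seed and
the stage name, making two runs with identical config and seed byte-identical.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffcor as dc
from . import enrichment as en
from . import fertility as fc
from . import network as nw
from . import preprocess as pp
from .io_core import (
    ExpressionMatrix,
    HYBRID_POPULATIONS,
    MOTILITY_TRAITS,
    PipelineConfig,
    derive_seed,
    log,
    read_bed,
    read_expression_tsv,
    read_gmt,
    read_probe_annotation,
    read_sample_table,
    relative_testis_weight,
    write_config,
    write_expression_tsv,
    write_probe_annotation,
    write_sample_table,
    Interval,
    AnnotationBundle,
    write_bed,
    write_gmt,
    FLOAT_FMT,
)
from .synthetic import AnnotationConfig, SimulationConfig, simulate_annotations, simulate_dataset


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_table(df: pd.DataFrame, path: Path, comment: str) -> None:
    """TSV with a leading '#' header naming units and conventions."""
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _run_stage(name: str, fn, *args, **kwargs):
    t0 = time.time()
    log.info("stage %s: start", name)
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - abort with stage name and cause
        raise PipelineStageError(name, exc) from exc
    log.info("stage %s: done in %.1fs", name, time.time() - t0)
    return result


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(
    out_dir: Path, sim_config: SimulationConfig, ann_config: AnnotationConfig | None = None
) -> None:
    """Write all pipeline input fixtures plus the planted-truth tables."""
    out_dir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(sim_config)
    bundle = simulate_annotations(data.truth, ann_config, seed=sim_config.seed)

    write_expression_tsv(data.combined("raw"), out_dir / "expression_raw.tsv")
    write_expression_tsv(data.combined("background"), out_dir / "background.tsv")
    write_probe_annotation(data.annotation, out_dir / "probe_annotation.tsv")
    write_sample_table(data.samples, out_dir / "samples.tsv")

    truth = data.truth
    truth_genes = pd.DataFrame(
        {
            "gene_id": truth.module_of_gene.index,
            "module": truth.module_of_gene.to_numpy(),
            "loading": truth.loadings.to_numpy(),
            "disrupted": truth.module_of_gene.index.isin(truth.disrupted_genes),
        }
    )
    _write_table(truth_genes, out_dir / "truth_genes.tsv",
                 "planted truth: module index (-1 = background), signed loading")
    truth_samples = pd.DataFrame(
        {
            "sample_id": truth.class_of_sample.index,
            "planted_class": truth.class_of_sample.to_numpy(),
            "axis_value": truth.axis_value.to_numpy(),
        }
    )
    _write_table(truth_samples, out_dir / "truth_samples.tsv",
                 "planted truth: fertility class and aberrant-expression axis value")

    write_bed(
        [bundle.gene_positions[g] for g in sorted(bundle.gene_positions)],
        out_dir / "gene_positions.bed",
    )
    for name, ivs in bundle.interval_sets.items():
        write_bed(ivs, out_dir / f"regions_{name}.bed")
    for category, sets in bundle.gene_sets.items():
        write_gmt(sets, out_dir / f"sets_{category}.gmt")


def load_annotation_bundle(in_dir: Path) -> AnnotationBundle:
    positions = {}
    for iv in read_bed(in_dir / "gene_positions.bed"):
        positions[iv.name] = iv
    interval_sets = {}
    for path in sorted(in_dir.glob("regions_*.bed")):
        interval_sets[path.stem.removeprefix("regions_")] = read_bed(path)
    gene_sets = {}
    for path in sorted(in_dir.glob("sets_*.gmt")):
        gene_sets[path.stem.removeprefix("sets_")] = read_gmt(path)
    return AnnotationBundle(positions, interval_sets, gene_sets)


def stage_preprocess(in_dir: Path, out_dir: Path, cfg: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fg, bg = read_expression_tsv(
        in_dir / "expression_raw.tsv", in_dir / "background.tsv"
    )
    annot = read_probe_annotation(in_dir / "probe_annotation.tsv")
    samples = read_sample_table(in_dir / "samples.tsv")

    ppp = cfg.preprocess
    corrected = pp.background_correct_half(fg, bg, ppp.offset)
    kept, thresholds = pp.filter_expressed(
        corrected, annot, ppp.negctrl_quantile, ppp.brightness_factor,
        ppp.min_sample_fraction,
    )
    filtered = corrected.subset_probes(kept)
    normalized = pp.quantile_normalize(pp.log2_transform(filtered))
    batches = pd.Series(samples["batch"].to_numpy(), index=samples["sample_id"])
    adjusted = pp.eb_batch_adjust(normalized, batches)

    pca_res = pp.pca(adjusted)
    # Advisory only: genuinely aberrant-expression samples are expected to sit
    # far out on PC1, so flagged samples are reported, never auto-removed.
    outliers = pp.flag_outlier_samples(pca_res, ppp.outlier_k_mad)
    if outliers:
        log.warning("%d samples flagged by the MAD rule on PC1/PC2 (advisory)",
                    len(outliers))

    write_expression_tsv(adjusted, out_dir / "expression_preprocessed.tsv")
    scores = pca_res.scores.reset_index(names="sample_id")
    _write_table(scores, out_dir / "pca_scores.tsv",
                 "PCA scores (SVD of probe-standardized log2 expression), unitless")
    _write_table(
        pd.DataFrame({"component": [f"PC{k+1}" for k in range(len(pca_res.explained_fraction))],
                      "explained_fraction": pca_res.explained_fraction}),
        out_dir / "pca_explained.tsv",
        "fraction of variance explained per principal component, in [0,1]",
    )
    _write_table(pd.DataFrame({"sample_id": outliers}), out_dir / "pca_outliers.tsv",
                 "samples removed by the MAD outlier rule on PC1/PC2")


def stage_classify(in_dir: Path, out_dir: Path, cfg: PipelineConfig) -> None:
    samples = read_sample_table(in_dir / "samples.tsv")
    scores = _read_table(out_dir / "pca_scores.tsv")
    pc1 = pd.Series(scores["PC1"].to_numpy(), index=scores["sample_id"])
    classification = fc.classify_fertility(samples[samples["sample_id"].isin(pc1.index)])
    classification = fc.split_expression_class(classification, pc1)
    _write_table(
        classification, out_dir / "classification.tsv",
        "fertility classes from relative testis weight (g/g) and sperm count; "
        "SFNE/SFAE split by genome-wide expression PC1",
    )


def _load_preprocessed(out_dir: Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    expr = read_expression_tsv(
        out_dir / "expression_preprocessed.tsv", scale_tag="batch_adjusted"
    )
    classification = _read_table(out_dir / "classification.tsv")
    return expr, classification


def _fertile_by_population(
    expr: ExpressionMatrix, classification: pd.DataFrame
) -> dict[str, list[str]]:
    out = {}
    for pop in HYBRID_POPULATIONS:
        mask = (classification["population"] == pop) & (
            classification["fertility_class"] == "fertile"
        )
        out[pop] = [
            s for s in classification.loc[mask, "sample_id"] if s in expr.sample_ids
        ]
    return out


def stage_network(in_dir: Path, out_dir: Path, cfg: PipelineConfig) -> nw.ConsensusNetwork:
    expr, classification = _load_preprocessed(out_dir)
    annot = read_probe_annotation(in_dir / "probe_annotation.tsv")
    samples = read_sample_table(in_dir / "samples.tsv")
    fertile = _fertile_by_population(expr, classification)
    pooled_fertile = expr.subset_samples(fertile["F2"] + fertile["HZ"])

    kept = nw.connectivity_filter(pooled_fertile, cfg.network.beta)
    cohorts = {
        pop: expr.subset_probes(kept).subset_samples(ids)
        for pop, ids in fertile.items()
    }
    diagnostics = nw.pick_soft_threshold(
        nw.pearson_matrix(pooled_fertile.subset_probes(kept).values)
    )
    net = nw.build_consensus_network(cohorts, cfg.network)

    probe_to_gene = pd.Series(
        annot["gene_id"].to_numpy(), index=annot["probe_id"]
    )
    assignment_table = pd.DataFrame(
        {
            "probe_id": net.assignment.index,
            "gene_id": probe_to_gene.reindex(net.assignment.index).to_numpy(),
            "module": net.assignment.to_numpy(),
        }
    )
    _write_table(assignment_table, out_dir / "module_assignment.tsv",
                 "consensus module labels; 0 = unassigned bin")
    _write_table(diagnostics, out_dir / "soft_threshold.tsv",
                 "soft-threshold diagnostics: scale-free fit R2, mean/median connectivity")

    for pop, mes in net.eigengenes.items():
        _write_table(mes.reset_index(names="sample_id"),
                     out_dir / f"eigengenes_{pop}.tsv",
                     "module eigengenes (unit variance over samples), fertile cohort")
        _write_table(net.kme[pop].reset_index(names="probe_id"),
                     out_dir / f"kme_{pop}.tsv",
                     "module membership kME: Pearson cor(probe, eigengene) in [-1,1]")

    # module-trait correlations over all hybrid samples
    hybrids = classification.loc[
        classification["fertility_class"] != "pure", "sample_id"
    ]
    hybrids = [s for s in hybrids if s in expr.sample_ids]
    expr_h = expr.subset_samples(hybrids).subset_probes(net.probes)
    mes_all, _ = nw.eigengene_matrix(expr_h, net.assignment)
    samples_idx = samples.set_index("sample_id")
    traits = pd.DataFrame(
        {
            "relative_testis_weight": relative_testis_weight(samples),
            "sperm_count": samples_idx["sperm_count"],
        }
    ).reindex(hybrids)
    for t in MOTILITY_TRAITS:
        if t in samples_idx.columns:
            traits[t] = samples_idx[t].reindex(hybrids)
    trait_table = nw.module_trait_correlation(mes_all, traits)
    _write_table(trait_table, out_dir / "module_trait.tsv",
                 "Pearson r and two-sided p between module eigengenes (all hybrids) and traits")
    _write_table(mes_all.reset_index(names="sample_id"), out_dir / "eigengenes_all.tsv",
                 "module eigengenes over all hybrid samples (unit variance)")
    return net


def _load_network_inputs(out_dir: Path) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    expr, classification = _load_preprocessed(out_dir)
    assignment_table = _read_table(out_dir / "module_assignment.tsv")
    assignment = pd.Series(
        assignment_table["module"].to_numpy(),
        index=assignment_table["probe_id"],
    )
    return expr, classification, assignment


TEST_GROUPS = ("intermediate", "SFNE", "SFAE")


def _group_samples(
    classification: pd.DataFrame, expr: ExpressionMatrix, pop: str, group: str
) -> list[str]:
    if group == "intermediate":
        mask = (classification["population"] == pop) & (
            classification["fertility_class"] == "intermediate"
        )
    else:
        mask = (classification["population"] == pop) & (
            classification["expression_class"] == group
        )
    return [s for s in classification.loc[mask, "sample_id"] if s in expr.sample_ids]


def stage_preserve(in_dir: Path, out_dir: Path, cfg: PipelineConfig) -> None:
    from . import preservation as pv

    expr, classification, assignment = _load_network_inputs(out_dir)
    expr = expr.subset_probes(list(assignment.index))
    fertile = _fertile_by_population(expr, classification)

    reports = []
    for pop in HYBRID_POPULATIONS:
        discovery = expr.subset_samples(fertile[pop])
        for group in TEST_GROUPS:
            ids = _group_samples(classification, expr, pop, group)
            if len(ids) < 5:
                log.warning("preservation: %s/%s has <5 samples, skipped", pop, group)
                continue
            test = expr.subset_samples(ids)
            seed = derive_seed(cfg.seed, f"preserve:{pop}:{group}")
            rep = pv.preservation_report(
                discovery, test, assignment, cfg.preservation, cfg.network.beta, seed
            )
            rep = rep.reset_index()
            rep.insert(0, "population", pop)
            rep.insert(1, "test_group", group)
            reports.append(rep)
    _write_table(pd.concat(reports, ignore_index=True), out_dir / "preservation.tsv",
                 "module preservation: observed statistics, permutation Z, Z_summary "
                 "(>=10 strong, 2-10 weak, <2 none), median rank, one-sided p-values")


def stage_diffcor(in_dir: Path, out_dir: Path, cfg: PipelineConfig) -> None:
    expr, classification, assignment = _load_network_inputs(out_dir)
    expr = expr.subset_probes(list(assignment.index))
    fertile = _fertile_by_population(expr, classification)

    gene_tables, module_tables = [], []
    for pop in HYBRID_POPULATIONS:
        ref = expr.subset_samples(fertile[pop])
        for group in ("SFNE", "SFAE"):
            ids = _group_samples(classification, expr, pop, group)
            if len(ids) < 5:
                log.warning("diffcor: %s/%s has <5 samples, skipped", pop, group)
                continue
            test = expr.subset_samples(ids)
            seed = derive_seed(cfg.seed, f"diffcor:{pop}:{group}")
            genes = dc.gene_median_lfc(ref, test, assignment, cfg.diffcor, seed)
            genes.insert(0, "population", pop)
            genes.insert(1, "test_group", group)
            gene_tables.append(genes)
            summary = dc.module_summary(genes)
            summary.insert(0, "population", pop)
            summary.insert(1, "test_group", group)
            module_tables.append(summary)
    _write_table(pd.concat(gene_tables, ignore_index=True), out_dir / "diffcor_genes.tsv",
                 "per-gene median log2 fold change of within-module |correlation| "
                 "(test vs fertile reference), permutation p, loss/reversal flag")
    _write_table(pd.concat(module_tables, ignore_index=True), out_dir / "diffcor_modules.tsv",
                 "percent of module genes with significant loss or reversal of coexpression")


def stage_hubs(in_dir: Path, out_dir: Path, cfg: PipelineConfig,
               net: nw.ConsensusNetwork | None = None) -> pd.DataFrame:
    if net is None:
        net = _rebuild_network(in_dir, out_dir, cfg)
    annot = read_probe_annotation(in_dir / "probe_annotation.tsv")
    probe_to_gene = pd.Series(annot["gene_id"].to_numpy(), index=annot["probe_id"])
    hubs = en.identify_hubs(net, probe_to_gene, cfg.hubs)

    bundle = load_annotation_bundle(in_dir)
    flagged: set[str] = set()
    diffcor_path = out_dir / "diffcor_genes.tsv"
    if diffcor_path.exists():
        genes = _read_table(diffcor_path)
        flagged_probes = genes.loc[genes["flag"] != "none", "probe_id"]
        flagged = set(probe_to_gene.reindex(flagged_probes).dropna()) - {""}
    hubs = en.annotate_hub_table(hubs, bundle, flagged)
    _write_table(hubs, out_dir / "hubs.tsv",
                 "hub genes per module (kME rule and top intramodular degree); "
                 "flags: differential correlation, cell-type sets, interval overlap")

    # edge list export at the hub edge threshold (consensus TOM)
    iu = np.triu_indices(len(net.probes), k=1)
    strong = net.consensus[iu] >= cfg.hubs.edge_threshold
    probes_arr = np.array(net.probes)
    edges = pd.DataFrame(
        {
            "probe_a": probes_arr[iu[0][strong]],
            "probe_b": probes_arr[iu[1][strong]],
            "tom": net.consensus[iu][strong],
        }
    )
    _write_table(edges, out_dir / "edges.tsv",
                 "consensus TOM edges at or above the hub edge threshold")
    return hubs


def _rebuild_network(in_dir: Path, out_dir: Path, cfg: PipelineConfig) -> nw.ConsensusNetwork:
    """Recreate the in-memory network (TOMs, kME) from persisted stage outputs."""
    expr, classification, assignment = _load_network_inputs(out_dir)
    fertile = _fertile_by_population(expr, classification)
    cohorts = {
        pop: expr.subset_probes(list(assignment.index)).subset_samples(ids)
        for pop, ids in fertile.items()
    }
    correlations = {p: nw.pearson_matrix(m.values) for p, m in cohorts.items()}
    toms = {
        p: nw.tom_from_adjacency(nw.signed_adjacency(c, cfg.network.beta))
        for p, c in correlations.items()
    }
    cons = nw.consensus_tom(toms, cfg.network.calibration_quantile)
    net = nw.ConsensusNetwork(
        params=cfg.network,
        probes=list(assignment.index),
        correlations=correlations,
        toms=toms,
        consensus=cons,
        assignment=assignment,
    )
    for pop, mat in cohorts.items():
        mes, pves = nw.eigengene_matrix(mat, assignment)
        net.eigengenes[pop] = mes
        net.prop_var_explained[pop] = pves
        net.kme[pop] = nw.kme(mat, mes)
    return net


def stage_enrich(in_dir: Path, out_dir: Path, cfg: PipelineConfig) -> None:
    annot = read_probe_annotation(in_dir / "probe_annotation.tsv")
    probe_to_gene = pd.Series(annot["gene_id"].to_numpy(), index=annot["probe_id"])
    expr, _, assignment = _load_network_inputs(out_dir)
    bundle = load_annotation_bundle(in_dir)

    universe_expressed = set(probe_to_gene.reindex(expr.probe_ids).dropna()) - {""}
    assigned = assignment[assignment != nw.UNASSIGNED]
    module_genes = {
        int(m): set(probe_to_gene.reindex(assigned.index[assigned == m]).dropna()) - {""}
        for m in sorted(assigned.unique())
    }
    universe_module = set().union(*module_genes.values()) if module_genes else set()

    tables = []
    for category, sets in bundle.gene_sets.items():
        tables.append(
            en.set_overrepresentation(
                module_genes, sets, universe_expressed,
                cfg.enrichment.term_min, cfg.enrichment.term_max, category,
            )
        )
    _write_table(pd.concat(tables, ignore_index=True), out_dir / "enrichment_sets.tsv",
                 "one-sided Fisher over-representation of gene sets in modules; "
                 "BH-corrected q per category")

    hubs = _read_table(out_dir / "hubs.tsv")
    hub_genes = set(hubs["gene_id"].dropna()) - {""}
    rows = []
    for region_name, intervals in bundle.interval_sets.items():
        region_genes = en.genes_in_intervals(bundle.gene_positions, intervals)
        for uni_name, universe in (
            ("expressed", universe_expressed), ("module_assigned", universe_module),
        ):
            if not universe:
                continue
            seed = derive_seed(cfg.seed, f"enrich:{region_name}:{uni_name}")
            res = en.permutation_region_enrichment(
                hub_genes & universe, universe, region_genes & universe,
                cfg.enrichment.n_draws, seed,
            )
            rows.append(
                {
                    "region_set": region_name,
                    "universe": uni_name,
                    "observed": res.observed,
                    "null_quantile_95": res.null_quantile_95,
                    "empirical_p": res.empirical_p,
                    "significant": res.significant,
                    "n_draws": res.n_draws,
                    "universe_size": res.universe_size,
                    "hub_set_size": res.hub_set_size,
                }
            )
    _write_table(pd.DataFrame(rows), out_dir / "region_enrichment.tsv",
                 "hub-gene enrichment in genomic region sets: observed count vs "
                 "95% quantile of random same-size draws")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def write_manifest(out_dir: Path, cfg: PipelineConfig) -> None:
    lines = [f"seed = {cfg.seed}"]
    cfg_path = out_dir / "config_used.txt"
    write_config(cfg, cfg_path)
    for path in sorted(out_dir.glob("*.tsv")):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        lines.append(f"checksum.{path.name} = {digest}")
    (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(
    cfg: PipelineConfig,
    in_dir: str | Path,
    out_dir: str | Path,
    simulate_first: bool = False,
    sim_config: SimulationConfig | None = None,
) -> None:
    """Run every stage in order and write the manifest."""
    cfg.validate()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if simulate_first:
        sim = sim_config or SimulationConfig(seed=cfg.seed)
        _run_stage("simulate", stage_simulate, in_dir, sim)
    _run_stage("preprocess", stage_preprocess, in_dir, out_dir, cfg)
    _run_stage("classify", stage_classify, in_dir, out_dir, cfg)
    net = _run_stage("network", stage_network, in_dir, out_dir, cfg)
    _run_stage("preserve", stage_preserve, in_dir, out_dir, cfg)
    _run_stage("diffcor", stage_diffcor, in_dir, out_dir, cfg)
    _run_stage("hubs", stage_hubs, in_dir, out_dir, cfg, net)
    _run_stage("enrich", stage_enrich, in_dir, out_dir, cfg)
    write_manifest(out_dir, cfg)
    log.info("pipeline complete: %s", out_dir)
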