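"""Synthetic two-population testis expression datasets with planted ground truth.

The generative model is linear-Gaussian on the log2 scale.  For gene g in
module m, sample s::

    x_gs = mu_g + lambda_g * f_{m,s} + c_g * A_s + gamma_{g,b(s)} + delta_{g,b(s)} * eps_gs

with per-sample module factor scores f ~ N(0,1) drawn independently per
population (two cohorts sharing one consensus architecture), gene loadings
lambda drawn from a configurable range with one orientation sign per module,
an "aberrant expression" axis c_g switched on (A_s > 0) only in planted SFAE
samples, and per-batch location (gamma) and noise-scale (delta) effects.

Planted disruption in subfertile samples either *decouples* a fraction of a
module's genes (the factor term is replaced by an independent normal draw of
the same variance) or *reverses* it (the loading sign is negated).

Two fertility phenotypes (relative testis weight, sperm count) are driven by
a subset of module factors and affinely rescaled per planted class so that
fertile hybrids land within 1 SD of the pure-sample mean, intermediate
hybrids stay inside the pure range but exceed 1 SD, and subfertile hybrids
fall outside the pure range.

Raw-intensity fixtures for the preprocessing stage are produced by
exponentiation plus an additive background, so the background-correction /
filtering / normalization steps see realistic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    AnnotationBundle,
    ConfigError,
    ExpressionMatrix,
    Interval,
    MOTILITY_TRAITS,
    log,
    stage_rng,
    validate_probe_annotation,
    validate_sample_table,
)

HYBRID_CLASSES = ("fertile", "intermediate", "SFNE", "SFAE")


@dataclass
class ClassSizes:
    """Hybrid samples per planted class for one mapping population."""

    fertile: int
    intermediate: int
    sfne: int
    sfae: int

    def total(self) -> int:
        return self.fertile + self.intermediate + self.sfne + self.sfae


@dataclass
class SimulationConfig:
    n_modules: int = 15
    module_size_range: tuple[int, int] = (50, 300)
    module_sizes: tuple[int, ...] | None = None  # overrides the range if given
    n_background_genes: int = 400
    class_sizes: dict[str, ClassSizes] = field(
        default_factory=lambda: {
            "F2": ClassSizes(102, 92, 69, 37),
            "HZ": ClassSizes(79, 41, 38, 17),
        }
    )
    n_pure_per_subspecies: int = 16
    n_batches: int = 2  # per mapping population; pure groups are one batch each
    loading_range: tuple[float, float] = (0.2, 0.98)
    noise_sd: float = 0.4
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    batch_location_sd: float = 0.3
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    phenotype_weights: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "rtw": {0: 1.0, 1: 0.8, 2: -0.8},
            "sperm_count": {0: 0.8, 3: 1.0, 4: -0.8},
        }
    )
    phenotype_noise_sd: float = 0.5
    disruption_spec: dict[int, tuple[str, float]] = field(
        default_factory=lambda: {1: ("decouple", 1.0), 2: ("reverse", 0.5)}
    )
    sfae_axis_effect: float = 5.0
    axis_gene_fraction: float = 0.4
    axis_loading_sd: float = 0.4
    n_negative_controls: int = 100
    duplicate_probe_fraction: float = 0.1
    negctrl_log2_mean: float = 5.0
    negctrl_log2_sd: float = 0.3
    background_mean: float = 60.0
    background_sd: float = 5.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_modules < 1:
            raise ConfigError("n_modules must be >= 1")
        if self.module_sizes is not None:
            if len(self.module_sizes) != self.n_modules:
                raise ConfigError("module_sizes length must equal n_modules")
            if any(m < 2 for m in self.module_sizes):
                raise ConfigError("module sizes must be >= 2")
        if self.n_pure_per_subspecies < 2:
            raise ConfigError(
                "need >= 2 pure samples per subspecies (classification needs "
                "pure mean, SD and range)"
            )
        for pop, sizes in self.class_sizes.items():
            if sizes.total() < 4:
                raise ConfigError(f"population {pop} has too few samples")
        for m, (mode, frac) in self.disruption_spec.items():
            if not 0 <= m < self.n_modules:
                raise ConfigError(f"disruption_spec refers to unknown module {m}")
            if mode not in ("decouple", "reverse"):
                raise ConfigError(f"unknown disruption mode {mode!r}")
            if not 0 < frac <= 1:
                raise ConfigError("disruption gene_fraction must be in (0,1]")
        if self.noise_sd <= 0 or self.phenotype_noise_sd <= 0:
            raise ConfigError("noise SDs must be > 0")
        if not (0 < self.loading_range[0] <= self.loading_range[1] <= 1):
            raise ConfigError("loading_range must satisfy 0 < low <= high <= 1")
        if self.sfae_axis_effect < 0:
            raise ConfigError("sfae_axis_effect must be >= 0")
        return self


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated dataset."""

    module_of_gene: pd.Series  # gene_id -> module index, -1 = background
    loadings: pd.Series  # gene_id -> signed loading (0 for background)
    module_orientation: np.ndarray  # sign per module
    disrupted_modules: dict[int, tuple[str, float]]
    disrupted_genes: set[str]
    factor_scores: pd.DataFrame  # samples x modules (pre-disruption)
    axis_loadings: pd.Series  # gene_id -> c_g (0 outside the axis gene set)
    axis_value: pd.Series  # sample_id -> A_s
    class_of_sample: pd.Series  # sample_id -> planted class (or pure label)
    phenotype_weights: dict[str, dict[int, float]]
    batch_of_sample: pd.Series
    batch_location: pd.DataFrame  # genes x batches (gamma)
    batch_scale: pd.DataFrame  # genes x batches (delta)
    probe_to_gene: pd.Series  # probe_id -> gene_id ('' for negative controls)


@dataclass
class SimulatedDataset:
    log2: dict[str, ExpressionMatrix]  # population -> clean log2-scale matrix
    raw: dict[str, ExpressionMatrix]  # raw-intensity foreground fixtures
    background: dict[str, ExpressionMatrix]
    annotation: pd.DataFrame
    samples: pd.DataFrame
    truth: SimulationTruth

    def combined(self, which: str = "log2") -> ExpressionMatrix:
        """Concatenate the per-population matrices along samples."""
        mats = getattr(self, which)
        frames = [m.data for m in mats.values()]
        tag = next(iter(mats.values())).scale_tag
        return ExpressionMatrix(pd.concat(frames, axis=1), tag)


def _stratified_normal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Jittered normal quantiles, standardized; guarantees a wide sample range."""
    u = (np.arange(n) + 0.5) / n
    z = stats.norm.ppf(u) + rng.normal(0.0, 0.15, n)
    z = rng.permutation(z)
    return (z - z.mean()) / z.std(ddof=1)


def _rank_unit(x: np.ndarray) -> np.ndarray:
    """Map values to (0,1) by rank, preserving order."""
    r = stats.rankdata(x)
    return (r - 0.5) / len(x)


def _assign_phenotypes(
    cfg: SimulationConfig,
    latent: pd.DataFrame,  # hybrid samples x traits, factor-driven latent scores
    classes: pd.Series,  # hybrid sample -> planted class
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map latent trait scores into class-consistent phenotype values.

    Returns (pure trait z-scores frame, hybrid trait z-scores frame); z-scores
    are relative to the pure-sample mean/SD.  The map is affine (rank-affine
    for the out-of-band classes) within each class, so trait/factor
    correlations keep their planted sign.
    """
    n_pure = 2 * cfg.n_pure_per_subspecies
    traits = list(latent.columns)
    pure_z = pd.DataFrame(
        {t: _stratified_normal(n_pure, rng) for t in traits},
        index=[f"pure{i:03d}" for i in range(n_pure)],
    )
    lo = float(pure_z.min().min())
    hi = float(pure_z.max().max())
    if hi < 1.5 or lo > -1.5:
        raise ConfigError(
            "pure-sample phenotype range too narrow to place intermediate "
            "hybrids; increase n_pure_per_subspecies"
        )

    hyb_z = pd.DataFrame(0.0, index=latent.index, columns=traits)
    fertile = classes == "fertile"
    inter = classes == "intermediate"
    subf = classes.isin(["SFNE", "SFAE"])

    # fertile: both traits within +-0.85 SD of the pure mean
    for t in traits:
        lat = latent.loc[fertile, t].to_numpy()
        scale = 0.85 / max(np.abs(lat).max(), 1e-12)
        hyb_z.loc[fertile, t] = lat * scale

    # intermediate: both traits inside the pure range, the trait with the
    # larger latent excursion pushed past 1 SD
    if inter.any():
        lat = latent.loc[inter, traits].to_numpy()
        primary = np.abs(lat).argmax(axis=1)
        for j, t in enumerate(traits):
            is_p = primary == j
            z = np.empty(is_p.sum() + (~is_p).sum())
            u = _rank_unit(lat[:, j])
            band_hi = min(hi, -lo) - 0.15
            z_primary = np.sign(lat[:, j]) * (1.05 + (band_hi - 1.05) * u)
            z_secondary = 0.85 * lat[:, j] / max(np.abs(lat[:, j]).max(), 1e-12)
            z = np.where(is_p, z_primary, z_secondary)
            hyb_z.loc[inter, t] = z

    # subfertile: low relative testis weight outside the pure range; SFAE
    # samples additionally have low sperm count (most severe phenotype)
    if subf.any():
        lat = latent.loc[subf, traits[0]].to_numpy()
        u = _rank_unit(lat)
        hyb_z.loc[subf, traits[0]] = lo - 0.3 - 1.2 * (1 - u)
        sfae = classes[subf] == "SFAE"
        lat2 = latent.loc[subf, traits[1]].to_numpy()
        z2 = 0.85 * lat2 / max(np.abs(lat2).max(), 1e-12)
        u2 = _rank_unit(lat2)
        z2 = np.where(sfae.to_numpy(), lo - 0.3 - 1.2 * (1 - u2), z2)
        hyb_z.loc[subf, traits[1]] = z2

    return pure_z, hyb_z


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the full two-population dataset plus planted truth."""
    cfg.validate()
    rng = stage_rng(cfg.seed, "simulate")

    # ----- genes, modules, loadings -------------------------------------
    if cfg.module_sizes is not None:
        sizes = np.asarray(cfg.module_sizes, dtype=int)
    else:
        # sorted descending: low-index modules (phenotype drivers, disruption
        # targets) are the large ones, as in real testis coexpression data
        sizes = np.sort(
            rng.integers(
                cfg.module_size_range[0], cfg.module_size_range[1] + 1, cfg.n_modules
            )
        )[::-1]
    n_genes = int(sizes.sum()) + cfg.n_background_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
    module_of_gene = np.full(n_genes, -1, dtype=int)
    pos = 0
    for m, sz in enumerate(sizes):
        module_of_gene[pos : pos + sz] = m
        pos += sz

    orientation = rng.choice([-1.0, 1.0], cfg.n_modules)
    lam = np.zeros(n_genes)
    in_mod = module_of_gene >= 0
    lam[in_mod] = rng.uniform(*cfg.loading_range, in_mod.sum())
    lam[in_mod] *= orientation[module_of_gene[in_mod]]

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_genes)

    axis_mask = rng.random(n_genes) < cfg.axis_gene_fraction
    c = np.zeros(n_genes)
    c[axis_mask] = rng.normal(0.0, cfg.axis_loading_sd, axis_mask.sum())

    disrupted_gene_mask = np.zeros(n_genes, dtype=bool)
    disrupt_mode = {}
    for m, (mode, frac) in cfg.disruption_spec.items():
        members = np.where(module_of_gene == m)[0]
        k = max(1, int(round(frac * len(members))))
        sel = rng.choice(members, size=k, replace=False)
        disrupted_gene_mask[sel] = True
        disrupt_mode[m] = (mode, frac)

    # ----- samples -------------------------------------------------------
    sample_rows = []
    for pop, sizes_c in cfg.class_sizes.items():
        for cls, n in (
            ("fertile", sizes_c.fertile),
            ("intermediate", sizes_c.intermediate),
            ("SFNE", sizes_c.sfne),
            ("SFAE", sizes_c.sfae),
        ):
            for i in range(n):
                sample_rows.append((pop, cls))
    for sub in ("pure_dom", "pure_mus"):
        for i in range(cfg.n_pure_per_subspecies):
            sample_rows.append((sub, "pure"))

    pops = np.array([r[0] for r in sample_rows])
    classes = np.array([r[1] for r in sample_rows])
    sample_ids = np.array(
        [f"{p}_{c}_{i:03d}" for i, (p, c) in enumerate(zip(pops, classes))]
    )
    n_samples = len(sample_ids)

    batch = np.empty(n_samples, dtype=object)
    for pop in cfg.class_sizes:
        idx = np.where(pops == pop)[0]
        batch[idx] = [f"{pop}_b{rng.integers(cfg.n_batches)}" for _ in idx]
    for sub in ("pure_dom", "pure_mus"):
        batch[pops == sub] = f"{sub}_b0"
    batch_names = sorted(set(batch))

    gamma = rng.normal(0.0, cfg.batch_location_sd, (n_genes, len(batch_names)))
    delta = rng.uniform(*cfg.batch_scale_range, (n_genes, len(batch_names)))
    batch_idx = np.array([batch_names.index(b) for b in batch])

    # ----- factor scores and expression ----------------------------------
    factors = np.zeros((n_samples, cfg.n_modules))
    for pop in np.unique(pops):
        idx = pops == pop
        factors[idx] = rng.normal(0.0, 1.0, (idx.sum(), cfg.n_modules))

    axis_value = np.where(classes == "SFAE", cfg.sfae_axis_effect, 0.0)
    subfertile = np.isin(classes, ("SFNE", "SFAE"))

    # structural signal per gene/sample
    fac_term = lam[:, None] * factors[:, module_of_gene].T  # genes x samples
    fac_term[~in_mod, :] = 0.0
    for m, (mode, _frac) in disrupt_mode.items():
        sel = disrupted_gene_mask & (module_of_gene == m)
        cols = np.where(subfertile)[0]
        if mode == "decouple":
            z = rng.normal(0.0, 1.0, (sel.sum(), len(cols)))
            fac_term[np.ix_(sel, cols)] = lam[sel, None] * z
        else:  # reverse
            fac_term[np.ix_(sel, cols)] *= -1.0

    structural = (
        mu[:, None]
        + fac_term
        + c[:, None] * axis_value[None, :]
        + gamma[:, batch_idx]
    )

    # ----- probes (one per gene + duplicates + negative controls) --------
    dup_mask = rng.random(n_genes) < cfg.duplicate_probe_fraction
    probe_gene_idx = np.concatenate([np.arange(n_genes), np.where(dup_mask)[0]])
    probe_ids = np.array(
        [f"p_{gene_ids[i]}_1" for i in range(n_genes)]
        + [f"p_{gene_ids[i]}_2" for i in np.where(dup_mask)[0]]
    )
    noise = rng.normal(0.0, cfg.noise_sd, (len(probe_ids), n_samples))
    noise *= delta[probe_gene_idx][:, batch_idx]
    x = structural[probe_gene_idx] + noise

    nc_ids = np.array([f"NC{i:04d}" for i in range(cfg.n_negative_controls)])
    nc = rng.normal(
        cfg.negctrl_log2_mean, cfg.negctrl_log2_sd,
        (cfg.n_negative_controls, n_samples),
    )
    all_probe_ids = np.concatenate([probe_ids, nc_ids])
    x_all = np.vstack([x, nc])

    # ----- phenotypes -----------------------------------------------------
    hybrid = ~np.isin(pops, ("pure_dom", "pure_mus"))
    traits = list(cfg.phenotype_weights)
    latent = pd.DataFrame(0.0, index=sample_ids[hybrid], columns=traits)
    eta = rng.normal(0.0, cfg.phenotype_noise_sd, (hybrid.sum(), len(traits)))
    for j, t in enumerate(traits):
        for m, w in cfg.phenotype_weights[t].items():
            latent[t] += w * factors[hybrid, m]
        latent[t] += eta[:, j]
    pure_z, hyb_z = _assign_phenotypes(
        cfg, latent, pd.Series(classes[hybrid], index=sample_ids[hybrid]), rng
    )

    rtw_mean, rtw_sd = 0.0080, 0.0008
    sperm_mean, sperm_sd = 4.0e7, 5.0e6
    body = rng.normal(20.0, 1.5, n_samples).clip(14.0, None)
    z_rtw = np.empty(n_samples)
    z_sperm = np.empty(n_samples)
    z_rtw[hybrid] = hyb_z[traits[0]].to_numpy()
    z_sperm[hybrid] = hyb_z[traits[1]].to_numpy()
    z_rtw[~hybrid] = pure_z[traits[0]].to_numpy()
    z_sperm[~hybrid] = pure_z[traits[1]].to_numpy()
    rtw = rtw_mean + rtw_sd * z_rtw
    sperm = (sperm_mean + sperm_sd * z_sperm).clip(0.0)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": pops,
            "batch": batch,
            "body_weight": body,
            "testis_weight": rtw * body,
            "sperm_count": sperm,
        }
    )
    # motility traits available only for the HZ cohort (missing elsewhere)
    hz = pops == "HZ"
    for k, t in enumerate(MOTILITY_TRAITS):
        vals = np.full(n_samples, np.nan)
        driver = factors[hz, k % cfg.n_modules]
        vals[hz] = 10.0 + 2.0 * driver + rng.normal(0.0, 1.5, hz.sum())
        samples[t] = vals
    samples = validate_sample_table(samples)

    annotation = validate_probe_annotation(
        pd.DataFrame(
            {
                "probe_id": all_probe_ids,
                "gene_id": np.concatenate(
                    [gene_ids[probe_gene_idx], [""] * cfg.n_negative_controls]
                ),
                "is_negative_control": np.concatenate(
                    [np.zeros(len(probe_ids), bool), np.ones(len(nc_ids), bool)]
                ),
            }
        )
    )

    # ----- per-population matrices (log2 + raw fixtures) ------------------
    log2_mats, raw_mats, bg_mats = {}, {}, {}
    for pop in list(cfg.class_sizes) + ["pure_dom", "pure_mus"]:
        idx = np.where(pops == pop)[0]
        frame = pd.DataFrame(
            x_all[:, idx], index=all_probe_ids, columns=sample_ids[idx]
        )
        log2_mats[pop] = ExpressionMatrix(frame, "log2")
        bg = rng.normal(
            cfg.background_mean, cfg.background_sd, frame.shape
        ).clip(1.0)
        raw = np.power(2.0, frame.to_numpy()) + bg
        raw_mats[pop] = ExpressionMatrix(
            pd.DataFrame(raw, index=all_probe_ids, columns=sample_ids[idx]), "raw"
        )
        bg_mats[pop] = ExpressionMatrix(
            pd.DataFrame(bg, index=all_probe_ids, columns=sample_ids[idx]), "raw"
        )

    truth = SimulationTruth(
        module_of_gene=pd.Series(module_of_gene, index=gene_ids),
        loadings=pd.Series(lam, index=gene_ids),
        module_orientation=orientation,
        disrupted_modules=disrupt_mode,
        disrupted_genes=set(gene_ids[disrupted_gene_mask]),
        factor_scores=pd.DataFrame(
            factors, index=sample_ids,
            columns=[f"M{m}" for m in range(cfg.n_modules)],
        ),
        axis_loadings=pd.Series(c, index=gene_ids),
        axis_value=pd.Series(axis_value, index=sample_ids),
        class_of_sample=pd.Series(
            np.where(hybrid, classes, "pure"), index=sample_ids
        ),
        phenotype_weights=cfg.phenotype_weights,
        batch_of_sample=pd.Series(batch, index=sample_ids),
        batch_location=pd.DataFrame(gamma, index=gene_ids, columns=batch_names),
        batch_scale=pd.DataFrame(delta, index=gene_ids, columns=batch_names),
        probe_to_gene=pd.Series(
            np.concatenate([gene_ids[probe_gene_idx], [""] * len(nc_ids)]),
            index=all_probe_ids,
        ),
    )
    log.info(
        "simulated %d genes (%d modules), %d probes, %d samples",
        n_genes, cfg.n_modules, len(all_probe_ids), n_samples,
    )
    return SimulatedDataset(log2_mats, raw_mats, bg_mats, annotation, samples, truth)


def preservation_calibration_config(seed: int = 0) -> SimulationConfig:
    """Study conditions for the module-preservation calibration experiment.

    Modules sized 150-300 (the range in which inter-cohort connectivity
    statistics are informative at these sample sizes), one fully decoupled
    module, and the aberrant-expression axis switched off so that module
    disruption is the only planted difference between fertile and subfertile
    samples.
    """
    return SimulationConfig(
        seed=seed,
        module_size_range=(150, 300),
        disruption_spec={1: ("decouple", 1.0)},
        sfae_axis_effect=0.0,
    )


# ---------------------------------------------------------------------------
# Synthetic annotations: genome positions, interval sets, gene sets
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    chromosomes: tuple[str, ...] = tuple(
        [f"chr{i}" for i in range(1, 20)] + ["chrX"]
    )
    chrom_length: int = 120_000_000
    gene_length: int = 10_000
    region_base_fraction: float = 0.10
    region_multiplier: float = 3.0
    region_target_modules: tuple[int, ...] = (0, 1)
    hub_loading_decile: float = 0.9  # |loading| quantile defining hub candidates
    jaccard_targets: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "term": {0: 0.5, 1: 0.5, 3: 0.5},
            "cell_type": {0: 0.4, 2: 0.4},
            "qtt": {1: 0.5, 4: 0.5},
        }
    )
    n_control_sets: int = 3

    def validate(self) -> "AnnotationConfig":
        if not 0 < self.region_base_fraction < 1:
            raise ConfigError("region_base_fraction must be in (0,1)")
        if self.region_multiplier < 0:
            raise ConfigError("region_multiplier must be >= 0")
        if self.region_multiplier * self.region_base_fraction > 1:
            raise ConfigError(
                "region_multiplier * region_base_fraction exceeds 1: requested "
                "enrichment is infeasible"
            )
        return self


def _membership_intervals(
    genes: np.ndarray, positions: Mapping[str, Interval], name: str, pad: int
) -> list[Interval]:
    """Merged padded intervals covering the given genes."""
    ivs = sorted(
        (positions[g].chrom, max(0, positions[g].start - pad), positions[g].end + pad)
        for g in genes
    )
    merged: list[list] = []
    for chrom, s, e in ivs:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return [
        Interval(chrom, s, e, f"{name}_{i}")
        for i, (chrom, s, e) in enumerate(merged)
    ]


def simulate_annotations(
    truth: SimulationTruth,
    cfg: AnnotationConfig | None = None,
    seed: int = 0,
) -> AnnotationBundle:
    """Build a synthetic AnnotationBundle aligned with the planted truth.

    Genes are placed uniformly on a synthetic genome.  Two interval sets
    (``gwas_sterility`` and ``eqtl_hotspots``) are built so that hub-candidate
    genes (top decile of |loading|) of the target modules are included with
    probability ``multiplier * base_fraction`` while other genes enter at the
    base fraction.  Gene sets are built to hit configurable Jaccard overlaps
    with chosen modules; size-matched random control sets are added.
    """
    cfg = (cfg or AnnotationConfig()).validate()
    rng = stage_rng(seed, "annotations")
    genes = np.asarray(truth.module_of_gene.index)
    n = len(genes)

    chrom = rng.choice(cfg.chromosomes, n)
    start = rng.integers(0, cfg.chrom_length - cfg.gene_length, n)
    positions = {
        g: Interval(c, int(s), int(s) + cfg.gene_length, g)
        for g, c, s in zip(genes, chrom, start)
    }

    module_of = truth.module_of_gene
    abs_lam = truth.loadings.abs()
    hub_candidates = set()
    for m in cfg.region_target_modules:
        members = module_of.index[module_of == m]
        if len(members) == 0:
            raise ConfigError(f"region_target_modules refers to empty module {m}")
        cut = abs_lam[members].quantile(cfg.hub_loading_decile)
        hub_candidates.update(members[abs_lam[members] >= cut])

    interval_sets = {}
    for set_name in ("gwas_sterility", "eqtl_hotspots"):
        p = np.full(n, cfg.region_base_fraction)
        is_hub = np.isin(genes, list(hub_candidates))
        p[is_hub] = min(1.0, cfg.region_multiplier * cfg.region_base_fraction)
        chosen = genes[rng.random(n) < p]
        interval_sets[set_name] = _membership_intervals(
            chosen, positions, set_name, pad=2 * cfg.gene_length
        )

    gene_sets: dict[str, dict[str, list[str]]] = {}
    for category, targets in cfg.jaccard_targets.items():
        sets: dict[str, list[str]] = {}
        for m, j in targets.items():
            members = list(module_of.index[module_of == m])
            if not members:
                raise ConfigError(f"jaccard target refers to empty module {m}")
            size = len(members)
            overlap = int(round(2 * size * j / (1 + j)))
            overlap = min(overlap, size)
            inside = list(rng.choice(members, overlap, replace=False))
            outside_pool = list(module_of.index[module_of != m])
            outside = list(rng.choice(outside_pool, size - overlap, replace=False))
            sets[f"{category}_M{m}"] = inside + outside
        set_size = int(np.median([len(s) for s in sets.values()])) if sets else 50
        for k in range(cfg.n_control_sets):
            sets[f"{category}_control{k}"] = list(
                rng.choice(genes, set_size, replace=False)
            )
        gene_sets[category] = sets

    return AnnotationBundle(
        gene_positions=positions, interval_sets=interval_sets, gene_sets=gene_sets
    )
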