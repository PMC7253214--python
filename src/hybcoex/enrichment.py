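"""Hub-gene identification and gene-set / genomic-region enrichment.

Hubs per module are the union of (a) probes whose kME, combined across the
two cohorts, reaches a threshold and (b) the top-N probes by intramodular
degree in each cohort, where degree counts module partners with TOM edge
weight at or above a threshold.  Over-representation of gene sets in modules
uses one-sided Fisher (hypergeometric) tests with Benjamini-Hochberg
correction per annotation category; hub enrichment in genomic regions uses a
random-draw permutation test with a 95%-quantile decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import AnnotationBundle, HubParams, Interval, log
from .network import UNASSIGNED, ConsensusNetwork


# ---------------------------------------------------------------------------
# Hub genes
# ---------------------------------------------------------------------------

def identify_hubs(
    network: ConsensusNetwork,
    probe_to_gene: pd.Series,
    hub_params: HubParams | None = None,
) -> pd.DataFrame:
    """Hub probes/genes per module via the kME rule and the top-degree rule.

    kME across cohorts is combined by ``hub_params.combine_rule`` (min: both
    cohorts must pass).  Intramodular degree counts module partners with TOM
    >= edge_threshold; ties break by higher summed TOM, then probe id.  A gene
    is a hub iff any of its probes is.
    """
    hp = hub_params or HubParams()
    hp.validate()
    probes = np.array(network.probes)
    assignment = network.assignment
    pops = sorted(network.kme)

    rows = []
    for m in sorted(set(assignment[assignment != UNASSIGNED])):
        members = assignment.index[assignment == m]
        midx = np.where(np.isin(probes, members))[0]
        col = f"ME{m}"
        kmes = np.column_stack(
            [network.kme[pop].loc[members, col].to_numpy() for pop in pops]
        )
        combined = kmes.min(axis=1) if hp.combine_rule == "min" else kmes.mean(axis=1)
        kme_hub = set(np.asarray(members)[combined >= hp.kme_threshold])

        degree_hub: set[str] = set()
        top_n = hp.top_n_degree
        if len(members) <= top_n:
            log.warning(
                "module %d smaller than top_n_degree: all members degree-eligible", m
            )
        for pop in pops:
            tom = network.toms[pop][np.ix_(midx, midx)]
            off = tom - np.eye(len(midx))  # remove the self edge
            degree = (off >= hp.edge_threshold).sum(axis=1)
            strength = off.sum(axis=1)
            order = sorted(
                range(len(midx)),
                key=lambda i: (-degree[i], -strength[i], str(np.asarray(members)[i])),
            )
            degree_hub.update(np.asarray(members)[order[:top_n]])

        for probe in sorted(kme_hub | degree_hub):
            rows.append(
                {
                    "probe_id": probe,
                    "gene_id": probe_to_gene.get(probe, ""),
                    "module": m,
                    "is_kme_hub": probe in kme_hub,
                    "is_degree_hub": probe in degree_hub,
                }
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "module", "is_kme_hub", "is_degree_hub"]
    )


# ---------------------------------------------------------------------------
# Fisher / hypergeometric over-representation
# ---------------------------------------------------------------------------

def fisher_overlap(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher test for a k-overlap of a size-K module
    with a size-n set in a size-N universe.

    Returns (odds ratio, upper-tail hypergeometric p).  The odds ratio uses a
    0.5 continuity correction when any 2x2 cell is empty.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and k >= K + n - N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return odds, min(p, 1.0)


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def set_overrepresentation(
    module_genes: dict[int, set[str]],
    gene_sets: dict[str, list[str]],
    universe: set[str],
    term_min: int = 11,
    term_max: int = 499,
    category: str = "term",
) -> pd.DataFrame:
    """Fisher over-representation of each gene set in each module.

    Sets are intersected with the universe first; only sets whose intersected
    size lies in [term_min, term_max] are tested.  BH correction is applied
    across all tests in this call (one family per category).
    """
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    rows = []
    for set_name, genes in gene_sets.items():
        in_universe = set(genes) & universe
        if not in_universe:
            log.info("set %s has no overlap with the universe: skipped", set_name)
            continue
        if not term_min <= len(in_universe) <= term_max:
            continue
        for m, members in module_genes.items():
            mod = members & universe
            k = len(mod & in_universe)
            odds, p = fisher_overlap(k, len(mod), len(in_universe), N)
            rows.append(
                {
                    "category": category,
                    "set_name": set_name,
                    "module": m,
                    "overlap": k,
                    "set_size": len(in_universe),
                    "module_size": len(mod),
                    "universe_size": N,
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "category", "set_name", "module", "overlap", "set_size",
            "module_size", "universe_size", "odds_ratio", "p",
        ],
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# Genomic intervals
# ---------------------------------------------------------------------------

def genes_in_intervals(
    gene_positions: dict[str, Interval], intervals: list[Interval]
) -> set[str]:
    """Genes with any basepair overlap with any interval (0-based half-open)."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    hits = set()
    for gene, pos in gene_positions.items():
        for iv in by_chrom.get(pos.chrom, ()):
            if max(pos.start, iv.start) < min(pos.end, iv.end):
                hits.add(gene)
                break
    return hits


@dataclass
class RegionEnrichmentResult:
    observed: int
    null_quantile_95: float
    empirical_p: float
    significant: bool
    n_draws: int
    universe_size: int
    hub_set_size: int


def permutation_region_enrichment(
    hub_genes: set[str],
    universe: list[str] | set[str],
    region_genes: set[str],
    n_draws: int = 10000,
    seed: int = 0,
) -> RegionEnrichmentResult:
    """Random-draw enrichment of hub genes within a region gene set.

    Null: ``n_draws`` samples of ``|hub_genes|`` genes without replacement
    from the universe, counting members of ``region_genes``.  Significance:
    observed >= the 95% null quantile (smallest value with >= 95% of draws at
    or below it).  Also reports p = (1 + #{draws >= observed}) / (n_draws + 1).
    """
    universe = sorted(set(universe))
    hubs = set(hub_genes) & set(universe)
    if len(hub_genes) > len(universe):
        raise ValueError("hub set larger than universe")
    rng = np.random.default_rng(seed)
    region_mask = np.isin(np.array(universe), sorted(region_genes & set(universe)))
    observed = len(hubs & region_genes)

    k = len(hubs)
    counts = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        draw = rng.choice(len(universe), size=k, replace=False)
        counts[d] = int(region_mask[draw].sum())
    q95 = float(np.quantile(counts, 0.95, method="inverted_cdf"))
    p = (1.0 + np.sum(counts >= observed)) / (n_draws + 1.0)
    return RegionEnrichmentResult(
        observed=observed,
        null_quantile_95=q95,
        empirical_p=float(p),
        significant=bool(observed > 0 and observed >= q95),
        n_draws=n_draws,
        universe_size=len(universe),
        hub_set_size=k,
    )


# ---------------------------------------------------------------------------
# Hub annotation flags (differential correlation, cell types, intervals)
# ---------------------------------------------------------------------------

def annotate_hub_table(
    hubs: pd.DataFrame,
    bundle: AnnotationBundle,
    diffcor_flagged_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Add per-hub flags: differentially correlated, in any cell-type set,
    inside sterility or hotspot intervals."""
    out = hubs.copy()
    cell_genes: set[str] = set()
    for genes in bundle.gene_sets.get("cell_type", {}).values():
        cell_genes.update(genes)
    sterility = genes_in_intervals(
        bundle.gene_positions, bundle.interval_sets.get("gwas_sterility", [])
    )
    hotspots = genes_in_intervals(
        bundle.gene_positions, bundle.interval_sets.get("eqtl_hotspots", [])
    )
    flagged = diffcor_flagged_genes or set()
    out["diff_correlated"] = out["gene_id"].isin(flagged)
    out["in_cell_type_set"] = out["gene_id"].isin(cell_genes)
    out["in_sterility_region"] = out["gene_id"].isin(sterility)
    out["in_eqtl_hotspot"] = out["gene_id"].isin(hotspots)
    return out
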