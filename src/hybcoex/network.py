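"""Signed consensus weighted gene coexpression network construction.

Pipeline: Pearson correlation per cohort -> signed soft-threshold adjacency
a_ij = ((1 + cor_ij)/2)^beta -> topological overlap matrix (TOM) ->
quantile-calibrated consensus TOM (componentwise minimum) -> average-linkage
clustering of the TOM dissimilarity -> adaptive tree cut into modules ->
eigengene-based merging of close modules -> module eigengenes, kME and
module-trait correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_core import ExpressionMatrix, NetworkParams, ShapeError, log

UNASSIGNED = 0  # the gray "bin" label


# ---------------------------------------------------------------------------
# Correlation / adjacency / TOM primitives
# ---------------------------------------------------------------------------

def pearson_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation matrix, clipped to [-1, 1]."""
    Z = standardize_rows(values)
    n = values.shape[1]
    C = (Z @ Z.T) / (n - 1)
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit variance (ddof=1)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if (sd <= 0).any():
        raise ValueError("zero-variance rows must be removed before correlation")
    return (values - mean) / sd


def signed_adjacency(correlation: np.ndarray, beta: int) -> np.ndarray:
    """Signed network adjacency a_ij = ((1 + cor_ij)/2)^beta, diagonal 1."""
    A = ((1.0 + correlation) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    return adjacency.sum(axis=1) - np.diag(adjacency)


def connectivity_filter(
    matrix: ExpressionMatrix, beta: int, rule: str = "median"
) -> list[str]:
    """Keep probes whose soft connectivity strictly exceeds the median (or mean).

    Computed on the pooled fertile samples given in ``matrix``.  Zero-variance
    probes are dropped (logged) before the correlation step and never kept.
    """
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    ok = sd > 0
    if not ok.all():
        log.warning("connectivity filter dropping %d zero-variance probes",
                    int((~ok).sum()))
    probes = np.array(matrix.probe_ids)[ok]
    if len(probes) < 3:
        raise ValueError("need >= 3 probes with variance for the connectivity filter")
    k = connectivity(signed_adjacency(pearson_matrix(values[ok]), beta))
    cutoff = np.median(k) if rule == "median" else k.mean()
    kept = probes[k > cutoff]
    if len(kept) == 0:
        log.warning("connectivity filter kept no probes (all k equal?)")
    return list(kept)


def pick_soft_threshold(
    correlation: np.ndarray,
    candidate_betas: list[int] | None = None,
    n_bins: int = 10,
    plateau_rtol: float = 0.05,
) -> pd.DataFrame:
    """Soft-threshold diagnostics: scale-free fit R^2, mean/median connectivity.

    The recommended beta (column ``recommended``) is the lowest candidate
    whose median connectivity differs from the next candidate's by less than
    ``plateau_rtol`` (relative) -- the "low plateau" rule.  The final choice
    stays with the user.
    """
    if candidate_betas is None:
        candidate_betas = list(range(1, 13))
    if len(candidate_betas) < 2:
        raise ValueError("need >= 2 candidate betas")
    rows = []
    for beta in candidate_betas:
        k = connectivity(signed_adjacency(correlation, beta))
        rows.append(
            {
                "beta": beta,
                "scale_free_r2": _scale_free_fit(k, n_bins),
                "mean_k": k.mean(),
                "median_k": float(np.median(k)),
            }
        )
    table = pd.DataFrame(rows)
    rec_idx = len(table) - 1
    med = table["median_k"].to_numpy()
    for i in range(len(med) - 1):
        if med[i] <= 0:
            rec_idx = i
            break
        if abs(med[i + 1] - med[i]) / med[i] < plateau_rtol:
            rec_idx = i
            break
    table["recommended"] = False
    table.loc[rec_idx, "recommended"] = True
    return table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """R^2 of the log-log regression of binned frequency on connectivity."""
    k = k[k > 0]
    if len(k) < n_bins:
        return np.nan
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return np.nan
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = counts > 0
    x, y = np.log10(centers[ok]), np.log10(counts[ok])
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    L_ij sums shared-neighbor adjacency a_iu * a_uj over u != i, j; the
    diagonal is 1.
    """
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def consensus_tom(
    toms: dict[str, np.ndarray], calibration_quantile: float = 0.95
) -> np.ndarray:
    """Quantile-calibrated componentwise-minimum consensus TOM.

    Each cohort's TOM is multiplicatively rescaled so its off-diagonal
    ``calibration_quantile`` quantile equals the across-cohort mean of those
    quantiles; the consensus entry is the minimum of the calibrated TOMs.
    """
    mats = list(toms.values())
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ShapeError("population TOMs differ in shape")
    iu = np.triu_indices(shape[0], k=1)
    quants = np.array([np.quantile(m[iu], calibration_quantile) for m in mats])
    target = quants.mean()
    out = np.full(shape, np.inf)
    for m, q in zip(mats, quants):
        scale = target / q if q > 0 else 1.0
        np.minimum(out, np.clip(m * scale, 0.0, 1.0), out=out)
    np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# Clustering and module detection
# ---------------------------------------------------------------------------

def average_linkage_cluster(dissimilarity: np.ndarray) -> np.ndarray:
    """UPGMA dendrogram (scipy linkage matrix) from a square dissimilarity."""
    D = np.asarray(dissimilarity, dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if np.isnan(D).any():
        raise ValueError("dissimilarity contains NaN")
    D = D.copy()
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


def dynamic_tree_cut(
    dendrogram: np.ndarray,
    dissimilarity: np.ndarray,
    deep_split: int = 0,
    min_module_size: int = 50,
) -> np.ndarray:
    """Adaptive branch decomposition of an average-linkage dendrogram.

    The base cut height is placed in the widest gap of the sorted merge
    heights, searched above a floor quantile that drops as ``deep_split``
    grows (0 = most conservative: only the upper half of merges is searched,
    so the cut lands between the within-branch and between-branch height
    regimes).  Branches below the cut smaller than ``min_module_size`` start
    unassigned; a second, medoid-based stage then assigns each unassigned
    object to the closest module provided its medoid dissimilarity falls
    within that module's own radius.  Labels are positive integers ordered by
    decreasing module size; 0 marks unassigned objects.
    """
    n = dissimilarity.shape[0]
    if min_module_size > n:
        log.warning("min_module_size exceeds object count: nothing assigned")
        return np.zeros(n, dtype=int)
    heights = np.sort(dendrogram[:, 2])
    floor_q = 0.5 - 0.1 * deep_split
    start = int(np.floor(floor_q * (len(heights) - 1)))
    gaps = np.diff(heights[start:])
    if len(gaps) == 0 or gaps.max() <= 0:
        cut = float(heights[-1])
    else:
        i = start + int(np.argmax(gaps))
        cut = float((heights[i] + heights[i + 1]) / 2)
    raw = fcluster(dendrogram, t=cut, criterion="distance")

    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: (-sizes[c], c))
    for new, c in enumerate(kept, start=1):
        labels[raw == c] = new

    if not kept:
        log.warning("no branch reached min_module_size; all objects unassigned")
        return labels

    # medoid stage: absorb borderline objects within a module's own radius
    medoids, radii = {}, {}
    for m in range(1, len(kept) + 1):
        idx = np.where(labels == m)[0]
        sub = dissimilarity[np.ix_(idx, idx)]
        med_local = int(np.argmin(sub.sum(axis=1)))
        medoids[m] = idx[med_local]
        radii[m] = float(sub[med_local].max())
    unassigned = np.where(labels == 0)[0]
    for i in unassigned:
        d = {m: dissimilarity[i, medoids[m]] for m in medoids}
        m_best = min(d, key=lambda m: (d[m], m))
        if d[m_best] <= radii[m_best]:
            labels[i] = m_best
    return relabel_by_size(labels)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber module labels 1..K by decreasing size (ties: old label order)."""
    out = np.zeros_like(labels)
    sizes = pd.Series(labels[labels != UNASSIGNED]).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# Eigengenes, kME, merging
# ---------------------------------------------------------------------------

def module_eigengene(
    values: np.ndarray, member_idx: np.ndarray
) -> tuple[np.ndarray, float]:
    """First principal component of a module's standardized expression.

    Returns the eigengene as a unit-variance vector over samples, oriented so
    the mean kME of member probes is non-negative, plus the proportion of
    member variance it explains (mean squared kME).
    """
    if len(member_idx) < 2:
        raise ValueError("module eigengene needs >= 2 member probes")
    Z = standardize_rows(values[member_idx])
    n = Z.shape[1]
    G = Z.T @ Z  # samples x samples Gram; top eigenvector = first right SV
    w, V = np.linalg.eigh(G)
    v0 = V[:, -1]
    sd = v0.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate module: eigengene has zero variance")
    me = (v0 - v0.mean()) / sd
    kme_members = (Z @ me) / (n - 1)
    if kme_members.mean() < 0:
        me = -me
        kme_members = -kme_members
    return me, float(np.mean(kme_members**2))


def eigengene_matrix(
    matrix: ExpressionMatrix, assignment: pd.Series
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Eigengenes (samples x modules) for every assigned module label."""
    values = matrix.values
    probes = np.array(matrix.probe_ids)
    mes, pves = {}, {}
    for m in sorted(set(assignment[assignment != UNASSIGNED])):
        idx = np.where(np.isin(probes, assignment.index[assignment == m]))[0]
        me, pve = module_eigengene(values, idx)
        mes[f"ME{m}"] = me
        pves[m] = pve
    return pd.DataFrame(mes, index=matrix.sample_ids), pves


def kme(matrix: ExpressionMatrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Module membership kME: Pearson cor of each probe with each eigengene.

    Zero-variance probes get kME 0 (logged).
    """
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    ok = sd > 0
    if not ok.all():
        log.warning("kME set to 0 for %d zero-variance probes", int((~ok).sum()))
    me = eigengenes.reindex(matrix.sample_ids).to_numpy()
    me_z = (me - me.mean(axis=0)) / me.std(axis=0, ddof=1)
    out = np.zeros((values.shape[0], me.shape[1]))
    Z = np.zeros_like(values)
    Z[ok] = standardize_rows(values[ok])
    out = (Z @ me_z) / (values.shape[1] - 1)
    out[~ok] = 0.0
    np.clip(out, -1.0, 1.0, out=out)
    return pd.DataFrame(out, index=matrix.probe_ids, columns=eigengenes.columns)


def merge_close_modules(
    matrices: dict[str, ExpressionMatrix],
    assignment: pd.Series,
    merge_height: float = 0.2,
    max_rounds: int = 20,
) -> pd.Series:
    """Iteratively merge modules whose consensus eigengene dissimilarity is low.

    The consensus dissimilarity between two modules is the max over cohorts of
    1 - cor(ME_a, ME_b); average-linkage groups cut at ``merge_height`` are
    merged, eigengenes recomputed, and the process repeats to a fixed point.
    """
    assignment = assignment.copy()
    for _ in range(max_rounds):
        modules = sorted(set(assignment[assignment != UNASSIGNED]))
        if len(modules) < 2:
            break
        diss = np.zeros((len(modules), len(modules)))
        for pop, mat in matrices.items():
            mes, _ = eigengene_matrix(mat, assignment)
            cor = np.corrcoef(mes.to_numpy().T)
            diss = np.maximum(diss, 1.0 - cor)
        np.fill_diagonal(diss, 0.0)
        if diss[np.triu_indices(len(modules), 1)].min() > merge_height:
            break
        Z = average_linkage_cluster(diss)
        groups = fcluster(Z, t=merge_height, criterion="distance")
        mapping = {}
        for g in np.unique(groups):
            members = [modules[i] for i in np.where(groups == g)[0]]
            target = min(members)
            for m in members:
                mapping[m] = target
        if all(mapping[m] == m for m in modules):
            break
        assignment = assignment.map(lambda m: mapping.get(m, UNASSIGNED))
    return pd.Series(
        relabel_by_size(assignment.to_numpy()), index=assignment.index
    )


# ---------------------------------------------------------------------------
# Module-trait correlations
# ---------------------------------------------------------------------------

def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided p between each eigengene and each trait.

    Samples with a missing trait are dropped pairwise; p comes from
    t = r sqrt((n-2)/(1-r^2)) on n-2 df.  Constant traits give missing r/p.
    """
    rows = []
    for me_name in eigengenes.columns:
        for trait in traits.columns:
            paired = pd.concat(
                [eigengenes[me_name], traits[trait]], axis=1, join="inner"
            ).dropna()
            n = len(paired)
            r = p = np.nan
            if n >= 4:
                x, y = paired.iloc[:, 0], paired.iloc[:, 1]
                if x.std(ddof=1) > 0 and y.std(ddof=1) > 0:
                    r = float(np.corrcoef(x, y)[0, 1])
                    if abs(r) >= 1.0:
                        p = 0.0
                    else:
                        t = r * np.sqrt((n - 2) / (1.0 - r**2))
                        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            rows.append(
                {"module": me_name, "trait": trait, "n": n, "r": r, "p": p}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end consensus network construction
# ---------------------------------------------------------------------------

@dataclass
class ConsensusNetwork:
    """Consensus network over two (or more) cohorts sharing a probe set."""

    params: NetworkParams
    probes: list[str]
    correlations: dict[str, np.ndarray]
    toms: dict[str, np.ndarray]
    consensus: np.ndarray
    assignment: pd.Series  # probe -> module label (0 = bin)
    eigengenes: dict[str, pd.DataFrame] = field(default_factory=dict)
    prop_var_explained: dict[str, dict[int, float]] = field(default_factory=dict)
    kme: dict[str, pd.DataFrame] = field(default_factory=dict)

    def module_sizes(self) -> pd.Series:
        assigned = self.assignment[self.assignment != UNASSIGNED]
        return assigned.value_counts().sort_index()


def build_consensus_network(
    matrices: dict[str, ExpressionMatrix], params: NetworkParams
) -> ConsensusNetwork:
    """Construct the signed consensus network from per-cohort fertile data."""
    params.validate()
    probe_sets = [m.probe_ids for m in matrices.values()]
    if any(p != probe_sets[0] for p in probe_sets[1:]):
        raise ShapeError("cohorts must share an identical, ordered probe set")

    # drop probes with zero variance in any cohort
    ok = np.ones(len(probe_sets[0]), dtype=bool)
    for mat in matrices.values():
        ok &= mat.values.std(axis=1, ddof=1) > 0
    if not ok.all():
        log.warning("dropping %d zero-variance probes", int((~ok).sum()))
    probes = [p for p, k in zip(probe_sets[0], ok) if k]
    matrices = {pop: m.subset_probes(probes) for pop, m in matrices.items()}

    correlations = {p: pearson_matrix(m.values) for p, m in matrices.items()}
    toms = {
        p: tom_from_adjacency(signed_adjacency(c, params.beta))
        for p, c in correlations.items()
    }
    cons = consensus_tom(toms, params.calibration_quantile)

    diss = 1.0 - cons
    np.fill_diagonal(diss, 0.0)
    dendro = average_linkage_cluster(diss)
    labels = dynamic_tree_cut(
        dendro, diss, params.deep_split, params.min_module_size
    )
    assignment = pd.Series(labels, index=probes)
    assignment = merge_close_modules(matrices, assignment, params.merge_height)
    log.info(
        "consensus network: %d modules, %d/%d probes assigned",
        assignment.max(), int((assignment != UNASSIGNED).sum()), len(probes),
    )

    net = ConsensusNetwork(
        params=params,
        probes=probes,
        correlations=correlations,
        toms=toms,
        consensus=cons,
        assignment=assignment,
    )
    for pop, mat in matrices.items():
        mes, pves = eigengene_matrix(mat, assignment)
        net.eigengenes[pop] = mes
        net.prop_var_explained[pop] = pves
        net.kme[pop] = kme(mat, mes)
    return net
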