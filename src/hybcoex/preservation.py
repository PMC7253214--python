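"""Permutation-based module preservation between a discovery and a test cohort.

Seven preservation statistics are computed per module: four *density*
statistics evaluated in the test cohort (meanCor, meanAdj, propVarExplained,
meanSignedKME) and three *connectivity* statistics comparing cohorts
(cor_kIM, cor_kME, cor_cor).  A permutation null replaces the module by
random same-size gene sets drawn from all network probes; per statistic a Z
score is formed, Z_density / Z_connectivity are the medians of their groups,
and Z_summary is their mean.  Z_summary >= 10, 2-10 and < 2 indicate strong,
weak and absent preservation.  A second permutation run yields one-sided
empirical p-values for all seven statistics; a module counts as significantly
preserved only if every statistic is significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, PreservationParams, log
from .network import UNASSIGNED, standardize_rows

DENSITY_STATS = ("meanCor", "meanAdj", "propVarExplained", "meanSignedKME")
CONNECTIVITY_STATS = ("cor_kIM", "cor_kME", "cor_cor")
STAT_NAMES = DENSITY_STATS + CONNECTIVITY_STATS


def _top_component(Z: np.ndarray) -> np.ndarray:
    """Unit-variance first principal component of row-standardized data.

    Works on the smaller Gram matrix for speed; orientation: mean correlation
    of rows with the component is non-negative.
    """
    m, n = Z.shape
    if m <= n:
        G = (Z @ Z.T) / (n - 1)
        w, V = np.linalg.eigh(G)
        u = V[:, -1]
        me = Z.T @ u
    else:
        G = Z.T @ Z
        w, V = np.linalg.eigh(G)
        me = V[:, -1]
    sd = me.std(ddof=1)
    if sd <= 0:
        return np.zeros(n)
    me = (me - me.mean()) / sd
    if (Z @ me).mean() < 0:
        me = -me
    return me


def _pearson_vec(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa <= 0 or sb <= 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _module_stats(
    Zd: np.ndarray, Zt: np.ndarray, idx: np.ndarray, beta: int
) -> dict[str, float]:
    """All seven preservation statistics for the gene set ``idx``."""
    nd, nt = Zd.shape[1], Zt.shape[1]
    sub_d, sub_t = Zd[idx], Zt[idx]
    cor_d = np.clip(sub_d @ sub_d.T / (nd - 1), -1.0, 1.0)
    cor_t = np.clip(sub_t @ sub_t.T / (nt - 1), -1.0, 1.0)
    iu = np.triu_indices(len(idx), k=1)

    adj_t = ((1.0 + cor_t[iu]) / 2.0) ** beta
    me_t = _top_component(sub_t)
    kme_t = sub_t @ me_t / (nt - 1)

    adj_d_full = ((1.0 + cor_d) / 2.0) ** beta
    adj_t_full = ((1.0 + cor_t) / 2.0) ** beta
    kim_d = adj_d_full.sum(axis=1) - 1.0  # diagonal adjacency is 1
    kim_t = adj_t_full.sum(axis=1) - 1.0
    me_d = _top_component(sub_d)
    kme_d = sub_d @ me_d / (nd - 1)

    return {
        "meanCor": float(cor_t[iu].mean()),
        "meanAdj": float(adj_t.mean()),
        "propVarExplained": float(np.mean(kme_t**2)),
        "meanSignedKME": float(kme_t.mean()),
        "cor_kIM": _pearson_vec(kim_d, kim_t),
        "cor_kME": _pearson_vec(kme_d, kme_t),
        "cor_cor": _pearson_vec(cor_d[iu], cor_t[iu]),
    }


def _prepare(
    discovery: ExpressionMatrix, test: ExpressionMatrix, assignment: pd.Series
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray], list[str]]:
    if discovery.probe_ids != test.probe_ids:
        raise ValueError("discovery and test cohorts must share the probe set")
    probes = np.array(discovery.probe_ids)
    sd_d = discovery.values.std(axis=1, ddof=1)
    sd_t = test.values.std(axis=1, ddof=1)
    ok = (sd_d > 0) & (sd_t > 0)
    if not ok.all():
        log.warning("preservation: dropping %d zero-variance probes", int((~ok).sum()))
    probes = probes[ok]
    Zd = standardize_rows(discovery.values[ok])
    Zt = standardize_rows(test.values[ok])

    modules: dict[int, np.ndarray] = {}
    assignment = assignment.reindex(probes)
    for m in sorted(set(assignment[assignment.notna() & (assignment != UNASSIGNED)])):
        idx = np.where((assignment == m).to_numpy())[0]
        if len(idx) < 3:
            log.warning("module %s smaller than 3 after filtering: skipped", m)
            continue
        modules[int(m)] = idx
    return Zd, Zt, modules, list(probes)


def preservation_statistics(
    discovery: ExpressionMatrix,
    test: ExpressionMatrix,
    assignment: pd.Series,
    beta: int = 5,
) -> pd.DataFrame:
    """Observed preservation statistics per module (no permutation)."""
    Zd, Zt, modules, _ = _prepare(discovery, test, assignment)
    rows = {
        m: _module_stats(Zd, Zt, idx, beta) for m, idx in modules.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")[list(STAT_NAMES)]
    out.index.name = "module"
    return out


def _null_draws(
    Zd: np.ndarray,
    Zt: np.ndarray,
    size: int,
    n_perm: int,
    beta: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n_probes = Zd.shape[0]
    out = np.empty((n_perm, len(STAT_NAMES)))
    for p in range(n_perm):
        idx = rng.choice(n_probes, size=size, replace=False)
        stats = _module_stats(Zd, Zt, idx, beta)
        out[p] = [stats[s] for s in STAT_NAMES]
    return out


def median_rank(observed: pd.DataFrame) -> pd.Series:
    """Rank-based relative preservation (1 = most preserved).

    Modules are ranked per observed statistic (descending); the median rank
    across density statistics and across connectivity statistics are averaged.
    """
    ranks = observed.rank(ascending=False, method="average")
    dens = ranks[list(DENSITY_STATS)].median(axis=1)
    conn = ranks[list(CONNECTIVITY_STATS)].median(axis=1)
    return (dens + conn) / 2.0


def permutation_z(
    discovery: ExpressionMatrix,
    test: ExpressionMatrix,
    assignment: pd.Series,
    params: PreservationParams | None = None,
    beta: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Z scores, Z_summary, preservation flag and median rank."""
    params = params or PreservationParams()
    Zd, Zt, modules, _ = _prepare(discovery, test, assignment)
    rng = np.random.default_rng(seed)
    observed = preservation_statistics(discovery, test, assignment, beta)

    rows = {}
    for m, idx in modules.items():
        null = _null_draws(Zd, Zt, len(idx), params.n_perm_z, beta, rng)
        mu = np.nanmean(null, axis=0)
        sd = np.nanstd(null, axis=0, ddof=1)
        obs = observed.loc[m].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (obs - mu) / sd
        degenerate = sd == 0
        if degenerate.any():
            log.warning("module %d: zero permutation SD for %s; Z set to +inf",
                        m, [STAT_NAMES[i] for i in np.where(degenerate)[0]])
            z[degenerate] = np.inf
        row = {f"Z_{s}": z[i] for i, s in enumerate(STAT_NAMES)}
        row["Z_density"] = float(np.median(z[: len(DENSITY_STATS)]))
        row["Z_connectivity"] = float(np.median(z[len(DENSITY_STATS):]))
        row["Z_summary"] = (row["Z_density"] + row["Z_connectivity"]) / 2.0
        zs = row["Z_summary"]
        row["preserved_flag"] = (
            "strong" if zs >= 10 else ("weak" if zs >= 2 else "none")
        )
        rows[m] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    out["median_rank"] = median_rank(observed)
    return observed.join(out)


def permutation_significance(
    discovery: ExpressionMatrix,
    test: ExpressionMatrix,
    assignment: pd.Series,
    params: PreservationParams | None = None,
    beta: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """One-sided permutation p-values for all seven statistics per module.

    p = (1 + #{perm >= observed}) / (n_perm + 1); a module is significantly
    preserved only if every statistic has p < alpha.
    """
    params = params or PreservationParams()
    Zd, Zt, modules, _ = _prepare(discovery, test, assignment)
    rng = np.random.default_rng(seed)
    observed = preservation_statistics(discovery, test, assignment, beta)

    rows = {}
    for m, idx in modules.items():
        null = _null_draws(Zd, Zt, len(idx), params.n_perm_sig, beta, rng)
        obs = observed.loc[m].to_numpy()
        n_ge = np.sum(null >= obs[None, :], axis=0)
        p = (1.0 + n_ge) / (params.n_perm_sig + 1.0)
        row = {f"p_{s}": p[i] for i, s in enumerate(STAT_NAMES)}
        row["all_significant"] = bool((p < params.alpha).all())
        rows[m] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def preservation_report(
    discovery: ExpressionMatrix,
    test: ExpressionMatrix,
    assignment: pd.Series,
    params: PreservationParams | None = None,
    beta: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Full preservation report: statistics, Z scores, ranks and p-values."""
    z = permutation_z(discovery, test, assignment, params, beta, seed)
    sig = permutation_significance(
        discovery, test, assignment, params, beta, seed + 1
    )
    return z.join(sig)
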