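"""Differential correlation between a reference (fertile) and a test
(subfertile) cohort.

Two granularities:

* gene pairs -- Fisher z difference of the two correlations with a two-sided
  normal p-value and a loss / gain / reversal class;
* genes -- the median, over a gene's module partners, of the log2 fold change
  in absolute pairwise correlation, with a label-permutation empirical
  p-value and a loss / reversal flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import DiffCorParams, ExpressionMatrix, log
from .network import UNASSIGNED, pearson_matrix

ATANH_CLAMP = 1.0 - 1e-12


def fisher_z_diff(
    r_ref: np.ndarray, r_test: np.ndarray, n_ref: int, n_test: int
) -> np.ndarray:
    """z = (atanh(r_test) - atanh(r_ref)) / sqrt(1/(n_test-3) + 1/(n_ref-3))."""
    if n_ref < 5 or n_test < 5:
        raise ValueError("Fisher z difference needs >= 5 samples per cohort")
    r_ref = np.clip(np.asarray(r_ref, dtype=float), -ATANH_CLAMP, ATANH_CLAMP)
    r_test = np.clip(np.asarray(r_test, dtype=float), -ATANH_CLAMP, ATANH_CLAMP)
    se = np.sqrt(1.0 / (n_test - 3) + 1.0 / (n_ref - 3))
    return (np.arctanh(r_test) - np.arctanh(r_ref)) / se


def pairwise_diffcor(
    expr_ref: ExpressionMatrix,
    expr_test: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair correlation difference: (r_ref, r_test, z_diff, p, class).

    Classes at level ``alpha``: ``loss`` (same sign, |r| shrinks), ``gain``
    (same sign, |r| grows), ``reversal`` (sign change); ``none`` otherwise.
    """
    if expr_ref.probe_ids != expr_test.probe_ids:
        raise ValueError("cohorts must share the probe set")
    pos = {p: i for i, p in enumerate(expr_ref.probe_ids)}
    n_ref, n_test = expr_ref.shape[1], expr_test.shape[1]
    cor_ref = pearson_matrix(expr_ref.values)
    cor_test = pearson_matrix(expr_test.values)

    i_idx = np.array([pos[a] for a, _ in pairs])
    j_idx = np.array([pos[b] for _, b in pairs])
    r_ref = cor_ref[i_idx, j_idx]
    r_test = cor_test[i_idx, j_idx]
    if np.any(np.abs(r_ref) >= 1.0) or np.any(np.abs(r_test) >= 1.0):
        log.warning("|r| = 1 encountered; atanh clamped at 1 - 1e-12")
    z = fisher_z_diff(r_ref, r_test, n_ref, n_test)
    p = 2.0 * stats.norm.sf(np.abs(z))

    sign_change = np.sign(r_ref) * np.sign(r_test) < 0
    shrink = np.abs(r_test) < np.abs(r_ref)
    cls = np.where(
        p >= alpha,
        "none",
        np.where(sign_change, "reversal", np.where(shrink, "loss", "gain")),
    )
    return pd.DataFrame(
        {
            "probe_a": [a for a, _ in pairs],
            "probe_b": [b for _, b in pairs],
            "r_ref": r_ref,
            "r_test": r_test,
            "z_diff": z,
            "p": p,
            "class": cls,
        }
    )


def _median_lfc_per_gene(
    cor_ref: np.ndarray, cor_test: np.ndarray, floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """median log2(|r_test|/|r_ref|) over module partners, per gene.

    Also returns each gene's median partner correlation in both cohorts (used
    for the sign-flip call).  Absolute correlations are floored to keep the
    fold change bounded.
    """
    m = cor_ref.shape[0]
    off = ~np.eye(m, dtype=bool)
    lfc = np.log2(
        np.maximum(np.abs(cor_test), floor) / np.maximum(np.abs(cor_ref), floor)
    )
    med_lfc = np.array([np.median(lfc[i, off[i]]) for i in range(m)])
    med_ref = np.array([np.median(cor_ref[i, off[i]]) for i in range(m)])
    med_test = np.array([np.median(cor_test[i, off[i]]) for i in range(m)])
    return med_lfc, med_ref, med_test


def gene_median_lfc(
    expr_ref: ExpressionMatrix,
    expr_test: ExpressionMatrix,
    assignment: pd.Series,
    params: DiffCorParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene median log2 fold change in within-module coexpression.

    The permutation null shuffles cohort labels across the pooled samples
    (jointly for all genes, preserving gene-gene dependence) and recomputes
    the statistic; the two-sided empirical p is
    (1 + #{|perm| >= |obs|}) / (n_perm + 1).  Flags: ``loss`` when significant
    with negative median LFC and no sign flip of the median partner
    correlation, ``reversal`` when significant with a sign flip.
    """
    params = params or DiffCorParams()
    if expr_ref.probe_ids != expr_test.probe_ids:
        raise ValueError("cohorts must share the probe set")
    rng = np.random.default_rng(seed)
    probes = np.array(expr_ref.probe_ids)
    assignment = assignment.reindex(probes)

    pooled = np.hstack([expr_ref.values, expr_test.values])
    n_ref, n_test = expr_ref.shape[1], expr_test.shape[1]
    n_all = n_ref + n_test

    results = []
    modules = sorted(set(assignment[assignment.notna() & (assignment != UNASSIGNED)]))
    for m in modules:
        idx = np.where((assignment == m).to_numpy())[0]
        if len(idx) < 3:
            log.warning("module %s has <3 genes with data: skipped", m)
            continue
        block = pooled[idx]
        cor_ref = pearson_matrix(block[:, :n_ref])
        cor_test = pearson_matrix(block[:, n_ref:])
        obs, med_ref, med_test = _median_lfc_per_gene(
            cor_ref, cor_test, params.min_abs_ref_cor
        )

        exceed = np.zeros(len(idx))
        for _ in range(params.n_perm):
            perm = rng.permutation(n_all)
            pref = pearson_matrix(block[:, perm[:n_ref]])
            ptest = pearson_matrix(block[:, perm[n_ref:]])
            stat, _, _ = _median_lfc_per_gene(pref, ptest, params.min_abs_ref_cor)
            exceed += np.abs(stat) >= np.abs(obs)
        p = (1.0 + exceed) / (params.n_perm + 1.0)

        sign_flip = np.sign(med_ref) * np.sign(med_test) < 0
        flag = np.full(len(idx), "none", dtype=object)
        sig = p < params.alpha
        flag[sig & sign_flip] = "reversal"
        flag[sig & ~sign_flip & (obs < 0)] = "loss"
        results.append(
            pd.DataFrame(
                {
                    "probe_id": probes[idx],
                    "module": m,
                    "median_lfc": obs,
                    "median_ref_cor": med_ref,
                    "median_test_cor": med_test,
                    "median_sign_flip": sign_flip,
                    "empirical_p": p,
                    "flag": flag,
                }
            )
        )
    if not results:
        return pd.DataFrame(
            columns=[
                "probe_id", "module", "median_lfc", "median_ref_cor",
                "median_test_cor", "median_sign_flip", "empirical_p", "flag",
            ]
        )
    return pd.concat(results, ignore_index=True)


def module_summary(gene_results: pd.DataFrame) -> pd.DataFrame:
    """Percent of genes flagged (loss or reversal) per module."""
    rows = []
    for m, grp in gene_results.groupby("module"):
        flagged = (grp["flag"] != "none").sum()
        rows.append(
            {
                "module": m,
                "n_genes": len(grp),
                "n_flagged": int(flagged),
                "percent_flagged": 100.0 * flagged / len(grp),
            }
        )
    return pd.DataFrame(rows)
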