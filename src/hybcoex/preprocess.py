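"""Raw-intensity preprocessing: background correction, expression filtering,
quantile normalization, empirical-Bayes batch adjustment, and PCA.

The stages run, in pipeline order:

1. half-rule background correction with an additive offset,
2. negative-control based expression filtering (on the corrected scale),
3. log2 transform,
4. quantile normalization between arrays,
5. parametric empirical-Bayes location/scale batch adjustment,
6. PCA (SVD of the probe-standardized matrix) and a MAD-based
   automated outlier flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, ShapeError, log


def background_correct_half(
    foreground: ExpressionMatrix,
    background: ExpressionMatrix,
    offset: float = 50.0,
) -> ExpressionMatrix:
    """limma-style "half" background correction.

    Each value becomes ``max(F - B, 0.5) + offset``: intensities falling below
    0.5 after background subtraction are reset to 0.5, then a constant offset
    stabilizes the variance of low intensities.
    """
    if foreground.shape != background.shape or (
        foreground.probe_ids != background.probe_ids
        or foreground.sample_ids != background.sample_ids
    ):
        raise ShapeError("foreground/background shape or identifier mismatch")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    corrected = np.maximum(foreground.values - background.values, 0.5) + offset
    return foreground.with_values(corrected, "background_corrected")


def filter_expressed(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    negctrl_quantile: float = 0.98,
    brightness_factor: float = 1.10,
    min_sample_fraction: float = 0.10,
) -> tuple[list[str], np.ndarray]:
    """Keep probes detectably above negative-control background.

    Per array the threshold is ``brightness_factor`` times the
    ``negctrl_quantile`` quantile of negative-control intensities on that
    array; a probe is kept iff it reaches the threshold on at least
    ``ceil(min_sample_fraction * n_samples)`` arrays.  Negative-control probes
    are never kept.

    Returns the kept probe list and the per-array threshold vector.
    """
    annot = annotation.set_index("probe_id")
    is_nc = annot["is_negative_control"].reindex(matrix.probe_ids)
    if is_nc.isna().any():
        missing = list(is_nc.index[is_nc.isna()][:5])
        raise ValueError(f"probes without annotation: {missing}")
    nc_mask = is_nc.to_numpy(dtype=bool)
    if not nc_mask.any():
        raise ValueError("no negative-control probes on the array")

    values = matrix.values
    thresholds = brightness_factor * np.quantile(
        values[nc_mask], negctrl_quantile, axis=0
    )
    n_required = int(np.ceil(min_sample_fraction * values.shape[1]))
    n_above = (values >= thresholds[None, :]).sum(axis=1)
    keep = (n_above >= n_required) & ~nc_mask
    kept = [p for p, k in zip(matrix.probe_ids, keep) if k]
    log.info(
        "expression filter kept %d/%d probes (threshold: >= %d arrays)",
        len(kept), len(matrix.probe_ids), n_required,
    )
    return kept, thresholds


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array to share the mean-of-sorted reference distribution.

    Ties within an array receive the mean of the reference values at their
    rank positions (dense-rank averaging), so the map is well defined and
    idempotent.
    """
    values = matrix.values
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average reference over runs of tied input values
        run_start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[run_start]:
                if i - run_start > 1:
                    assigned[run_start:i] = reference[run_start:i].mean()
                run_start = i
        out[order[:, j], j] = assigned
    return matrix.with_values(out, "normalized")


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    values = matrix.values
    if (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive value at probe {matrix.probe_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}: log2 undefined"
        )
    return matrix.with_values(np.log2(values), "log2")


def eb_batch_adjust(
    matrix: ExpressionMatrix,
    batches: pd.Series,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene the data are standardized by the batch-design fit (grand mean +
    pooled residual variance); per-batch location (gamma) and scale (delta^2)
    estimates are shrunk toward a normal and an inverse-gamma prior whose
    hyperparameters are fit by method of moments across genes, iterating the
    coupled posterior equations to convergence.  No covariates are protected.

    With a single batch the input is returned unchanged.  Zero-variance genes
    are passed through unadjusted.
    """
    batches = batches.reindex(matrix.sample_ids)
    if batches.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = sorted(batches.unique())
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with <2 samples: {list(small.index)}")
    if len(levels) < 2:
        log.info("single batch: empirical-Bayes adjustment is the identity")
        return matrix.with_values(matrix.values.copy(), "batch_adjusted")

    X = matrix.values
    n_genes, n_samples = X.shape
    groups = [np.where((batches == b).to_numpy())[0] for b in levels]
    n_b = np.array([len(g) for g in groups], dtype=float)

    batch_means = np.column_stack([X[:, g].mean(axis=1) for g in groups])
    grand_mean = batch_means @ (n_b / n_samples)
    fitted = np.zeros_like(X)
    for k, g in enumerate(groups):
        fitted[:, g] = batch_means[:, [k]]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)

    constant = var_pooled <= 0
    if constant.any():
        log.warning(
            "%d zero-variance genes passed through unadjusted", int(constant.sum())
        )
    sd = np.sqrt(np.where(constant, 1.0, var_pooled))
    S = (X - grand_mean[:, None]) / sd[:, None]

    adjusted = np.empty_like(S)
    for k, g in enumerate(groups):
        s = S[:, g]
        gamma_hat = s.mean(axis=1)
        delta_hat = s.var(axis=1, ddof=1)

        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        if s2 <= 0 or tau2 <= 0:
            gamma_star, delta_star = gamma_hat, np.maximum(delta_hat, 1e-12)
        else:
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            nb = n_b[k]
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            for _ in range(max_iter):
                g_new = (tau2 * nb * gamma_hat + delta_star * gamma_bar) / (
                    tau2 * nb + delta_star
                )
                sum2 = ((s - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * sum2 + b_prior) / (nb / 2 + a_prior - 1)
                change = max(
                    np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
                )
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
        adjusted[:, g] = (s - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * sd[:, None] + grand_mean[:, None]
    out[constant] = X[constant]
    return matrix.with_values(out, "batch_adjusted")


@dataclass
class PCAResult:
    """SVD-based PCA of the probe-standardized expression matrix."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # probes x components
    explained_fraction: np.ndarray

    def component(self, k: int) -> pd.Series:
        return self.scores.iloc[:, k]


def pca(matrix: ExpressionMatrix) -> PCAResult:
    """PCA via SVD of the centered, unit-variance-scaled probe matrix.

    Zero-variance probes are dropped with a warning.  Component signs are
    fixed so the loading of largest magnitude is positive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.values
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d zero-variance probes before PCA", int((~keep).sum()))
    X = X[keep]
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)

    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    for k in range(len(s)):
        i = np.argmax(np.abs(U[:, k]))
        if U[i, k] < 0:
            U[:, k] *= -1
            Vt[k, :] *= -1
    explained = s**2 / (s**2).sum()
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(
        (s[:, None] * Vt).T, index=matrix.sample_ids, columns=comp_names
    )
    loadings = pd.DataFrame(
        U, index=np.array(matrix.probe_ids)[keep], columns=comp_names
    )
    return PCAResult(scores, loadings, explained)


def flag_outlier_samples(pca_result: PCAResult, k_mad: float = 6.0) -> list[str]:
    """Flag samples more than ``k_mad`` MADs from the median on PC1 or PC2.

    Deterministic replacement for by-eye outlier screening.
    """
    flagged: set[str] = set()
    n_comp = min(2, pca_result.scores.shape[1])
    for k in range(n_comp):
        scores = pca_result.scores.iloc[:, k]
        med = scores.median()
        mad = (scores - med).abs().median()
        if mad == 0:
            continue
        flagged.update(scores.index[(scores - med).abs() > k_mad * mad])
    return sorted(flagged)
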