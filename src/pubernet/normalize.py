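"""Mixed-model normalization of log2 expression and differential expression.

The normalization model treats the stacked (gene, sample) observations as

    y[g, s] = mu + library(s) + gene[g] + gene.animal.tissue[g, s] + e[g, s]

with the sequencing library as a fixed effect and the gene main effect
and the gene x animal x tissue interaction as random effects.  Variance
components are estimated by EM-REML on Henderson's mixed-model
equations; the adjusted expression value is the observation minus the
estimated fixed library effect (reference coding, first library as
baseline).  Removing the library effect is a per-library mean
normalization informed by the whole transcriptome, the classic
mixed-model normalization used for multi-library RNA-seq designs.

Identifiability: when every (gene, animal, tissue) cell holds a single
observation — the usual case when each sample is its own library — the
interaction variance is not separable from the residual and is absorbed
into it (``MixedModelSpec.interaction_absorbed`` is set on the fitted
spec).  When the library factor coincides with the group factor the
library effect is dropped with a warning, since adjusting for it would
remove the very contrast being tested.

Differential expression compares POST vs PRE per gene on the adjusted
scale.  The default test is Welch's two-sample t-test; a pooled variant
uses the mixed-model residual variance as the common error variance.
Reported per gene: POST mean, PRE mean, their difference
(``avg_diff = post - pre``), the study's fold-change convention
``fc = post / pre`` (a ratio of normalized means, *not* ``2**avg_diff``
— the conventional fold change is additionally emitted as ``fc_2pow``),
the p-value and a DE flag at the configured alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix


class ConvergenceError(RuntimeError):
    """EM-REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


@dataclass
class MixedModelSpec:
    """Variance components and fit diagnostics of the normalization model."""

    sigma2_gene: float | None = None
    sigma2_interaction: float | None = None
    sigma2_residual: float | None = None
    library_effects: pd.Series | None = None  # reference coding, baseline first
    library_dropped: bool = False
    interaction_absorbed: bool = False
    n_iter: int = 0
    converged: bool = False
    trace: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        for name in ("sigma2_gene", "sigma2_interaction", "sigma2_residual"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


def _check_meta(expr: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    missing = set(expr.sample_ids) - set(meta.index)
    if missing:
        raise ValueError(f"metadata missing for sample(s): {sorted(missing)}")
    return meta.loc[list(expr.sample_ids)]


def _em_reml_gene_model(
    y: np.ndarray,  # genes x samples
    x_sample: np.ndarray,  # samples x p fixed design (incl. intercept)
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, float, float, list[dict], int]:
    """EM-REML for y = Xb + Z_gene u + e on stacked observations.

    Exploits the arrow structure of the mixed-model equations: every
    gene contributes one observation per sample, so Z'Z = m I and
    Z'X = 1 a' with a the per-sample design column sums.  Returns
    (beta, sigma2_gene, sigma2_residual, trace, n_iter).
    """
    q, m = y.shape
    n = q * m
    p = x_sample.shape[1]
    a = x_sample.sum(axis=0)  # p
    b_mat = x_sample.T @ x_sample  # p x p, per-sample
    xty = x_sample.T @ y.sum(axis=0)  # p  (sum over genes of per-gene X'y)
    zty = y @ np.ones(m)  # q   (per-gene totals = Z'y)
    yty = float(np.dot(y.ravel(), y.ravel()))
    rank_x = np.linalg.matrix_rank(b_mat)

    var_y = float(np.var(y))
    s2g, s2e = max(var_y / 2, 1e-8), max(var_y / 2, 1e-8)
    trace: list[dict] = []
    floor = 1e-12
    for it in range(1, max_iter + 1):
        alpha = s2e / s2g
        d = m + alpha
        # Schur complement for the fixed block
        s_mat = q * b_mat - np.outer(a, a) * (q / d)
        rhs = xty - a * (zty.sum() / d)
        beta = np.linalg.lstsq(s_mat, rhs, rcond=None)[0]
        u = (zty - a @ beta) / d
        # tr of the gene block of the inverse MME coefficient matrix
        s_inv_a = np.linalg.lstsq(s_mat, a, rcond=None)[0]
        tr_cuu = q / d + q * float(a @ s_inv_a) / d**2
        sse = yty - float(beta @ xty) - float(u @ zty)
        s2e_new = sse / (n - rank_x)
        s2g_new = (float(u @ u) + s2e * tr_cuu) / q
        s2e_new = max(s2e_new, floor)
        s2g_new = max(s2g_new, floor)
        delta = max(abs(s2e_new - s2e), abs(s2g_new - s2g))
        trace.append({"iter": it, "sigma2_gene": s2g_new, "sigma2_residual": s2e_new})
        s2g, s2e = s2g_new, s2e_new
        if delta < tol:
            return beta, s2g, s2e, trace, it
    raise ConvergenceError(
        f"EM-REML did not converge in {max_iter} iterations", trace
    )


def fit_normalization(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[ExpressionMatrix, MixedModelSpec]:
    """Estimate variance components and remove the fixed library effect.

    Returns the adjusted log2 matrix and the fitted spec.  With a single
    library (or a library factor confounded with the group factor) the
    returned matrix equals the input.
    """
    if expr.scale != "log2":
        raise ValueError(f"expected a log2 matrix, got scale={expr.scale!r}")
    meta = _check_meta(expr, meta)
    spec = MixedModelSpec()
    libs = meta["library"].astype(str)
    lib_levels = sorted(libs.unique())
    groups = meta["group"].astype(str)

    # confounded design: the library partition refines into the group
    # partition with no extra resolution -> library effect == group effect
    lib_to_group = {
        lib: set(groups[libs == lib]) for lib in lib_levels
    }
    confounded = len(lib_levels) > 1 and len(lib_levels) == len(
        groups.unique()
    ) and all(len(v) == 1 for v in lib_to_group.values())
    if len(lib_levels) < 2 or confounded:
        if confounded:
            warnings.warn(
                "library factor is confounded with the group factor; "
                "library effect dropped from the normalization model",
                UserWarning,
                stacklevel=2,
            )
        spec.library_dropped = True
        spec.converged = True
        spec.sigma2_gene = float(np.var(expr.data.to_numpy().mean(axis=1), ddof=1))
        spec.sigma2_residual = float(
            np.var(expr.data.to_numpy() - expr.data.to_numpy().mean(axis=1, keepdims=True))
        )
        spec.library_effects = pd.Series(0.0, index=lib_levels)
        return expr, spec

    # one observation per (gene, animal, tissue) cell?
    cells = meta[["animal", "tissue"]].astype(str).agg("|".join, axis=1)
    if not cells.duplicated().any():
        spec.interaction_absorbed = True

    # fixed design per sample: intercept + library dummies (baseline first)
    x_sample = np.ones((expr.n_samples, len(lib_levels)))
    for j, lib in enumerate(lib_levels[1:], start=1):
        x_sample[:, j] = (libs == lib).to_numpy(dtype=float)

    y = expr.data.to_numpy()
    beta, s2g, s2e, trace, n_iter = _em_reml_gene_model(
        y, x_sample, tol=tol, max_iter=max_iter
    )
    lib_effect = pd.Series(0.0, index=lib_levels)
    lib_effect.iloc[1:] = beta[1:]
    per_sample_effect = libs.map(lib_effect).to_numpy(dtype=float)
    adjusted = expr.data - per_sample_effect[np.newaxis, :]

    spec.sigma2_gene = float(s2g)
    spec.sigma2_interaction = None if spec.interaction_absorbed else 0.0
    spec.sigma2_residual = float(s2e)
    spec.library_effects = lib_effect
    spec.trace = trace
    spec.n_iter = n_iter
    spec.converged = True
    spec.validate()
    return ExpressionMatrix(adjusted, scale="log2"), spec


def fold_change(post_mean: float, pre_mean: float) -> float:
    """Fold change as the ratio POST / PRE of normalized means.

    Note this is the ratio of the (log-scale) normalized means, the
    convention used in the source study's summary tables, not
    ``2**(post - pre)``.  Undefined (NaN) when ``pre_mean`` is zero.
    """
    if pre_mean == 0:
        return float("nan")
    return post_mean / pre_mean


def average_expression_difference(post_mean: float, pre_mean: float) -> float:
    """POST mean minus PRE mean on the normalized scale."""
    return post_mean - pre_mean


def test_de(
    adjusted: ExpressionMatrix,
    groups: pd.Series | dict,
    alpha: float = 0.05,
    method: str = "welch",
    residual_var: float | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided POST vs PRE test on the adjusted scale.

    Parameters
    ----------
    groups:
        Maps sample ID to ``"PRE"`` or ``"POST"``.
    method:
        ``"welch"`` (default) — Welch two-sample t-test per gene;
        ``"pooled"`` — z-test against a common error variance
        ``residual_var`` (typically the mixed-model residual).
    bh_correct:
        When True, the DE flag is applied to Benjamini-Hochberg adjusted
        p-values (off by default: the strict normalization is the
        argument for unadjusted flagging, mirroring the source study).

    Returns a DataFrame indexed by gene with columns ``post_mean``,
    ``pre_mean``, ``avg_diff``, ``fc``, ``fc_2pow``, ``p_value``,
    ``dex_flag``, ``direction``.
    """
    if adjusted.scale != "log2":
        raise ValueError(f"expected a log2 matrix, got scale={adjusted.scale!r}")
    g = pd.Series(groups)
    g = g.reindex(adjusted.sample_ids)
    if g.isna().any():
        raise ValueError("group labels missing for some samples")
    pre_cols = g.index[g == "PRE"]
    post_cols = g.index[g == "POST"]
    if len(pre_cols) == 0 or len(post_cols) == 0:
        raise ValueError("both PRE and POST groups must be non-empty")
    if method == "welch" and (len(pre_cols) < 2 or len(post_cols) < 2):
        raise ValueError("each group needs >= 2 samples (no within-group variance)")

    post = adjusted.data[post_cols].to_numpy()
    pre = adjusted.data[pre_cols].to_numpy()
    post_mean = post.mean(axis=1)
    pre_mean = pre.mean(axis=1)
    diff = post_mean - pre_mean

    if method == "welch":
        res = stats.ttest_ind(post, pre, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
        # zero-variance degenerate genes: identical groups -> p = 1
        p = np.where(np.isnan(p) & (diff == 0), 1.0, p)
    elif method == "pooled":
        if residual_var is None:
            raise ValueError("method='pooled' requires residual_var")
        se = np.sqrt(residual_var * (1 / len(post_cols) + 1 / len(pre_cols)))
        zstat = diff / se
        p = 2 * stats.norm.sf(np.abs(zstat))
    else:
        raise ValueError(f"unknown method {method!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(pre_mean != 0, post_mean / pre_mean, np.nan)
    if bh_correct:
        from .enrich import bh_adjust

        flag_p = np.asarray(bh_adjust(list(p)))
    else:
        flag_p = p
    out = pd.DataFrame(
        {
            "post_mean": post_mean,
            "pre_mean": pre_mean,
            "avg_diff": diff,
            "fc": fc,
            "fc_2pow": 2.0**diff,
            "p_value": p,
            "dex_flag": flag_p < alpha,
            "direction": np.where(diff > 0, "up", "down"),
        },
        index=adjusted.gene_ids,
    )
    out.index.name = "gene_id"
    return out
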