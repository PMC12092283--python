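"""Genome-wide difference-in-differences differential expression.

Per gene, log2 expression is modeled by ordinary least squares on the six
arm×visit cell means plus a centered %cortex nuisance covariate.  The
interactive treatment effect for a follow-up window is the half-scaled
difference-in-differences contrast of fitted cell means,

    ΔΔlogFC = (treated_late − treated_early)/2 − (placebo_late − placebo_early)/2,

tested with empirical-Bayes moderated t-statistics: per-gene residual
variances are shrunk toward a common prior estimated by moment-matching the
log residual variances against their theoretical scaled-F distribution
(trigamma inversion), and genes are reported by rank order of uncorrected p.
Genes that differ between arms at baseline (Welch t, p < 0.05) are flagged
and excluded from interpretation outputs but never from model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .containers import ARMS, DD_WINDOW_VISITS, DD_WINDOWS, VISITS, DegenerateInputError, ExpressionMatrix
from .score_stats import bh_fdr

logger = logging.getLogger(__name__)

CELLS = [f"{arm}.{visit}" for arm in ARMS for visit in VISITS]


# ---------------------------------------------------------------------------
# gene filtering and baseline screening


def iqr_filter(expr: ExpressionMatrix, keep) -> ExpressionMatrix:
    """Retain the genes with the largest interquartile range across samples.

    ``keep`` is either a count (int) or a fraction in (0, 1).  Quantiles use
    linear interpolation; ties in IQR break lexicographically by gene_id.
    Retained genes keep their original matrix order.
    """
    n_genes = expr.values.shape[0]
    if isinstance(keep, float) and 0 < keep < 1:
        keep = int(round(keep * n_genes))
    keep = int(keep)
    if keep <= 0:
        raise ValueError("keep must be positive")
    if keep > n_genes:
        raise ValueError(f"keep={keep} exceeds the {n_genes} genes present")
    arr = expr.values.to_numpy(dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75], axis=1, method="linear")
    iqr = q3 - q1
    order = np.lexsort((expr.values.index.to_numpy(), -iqr))
    chosen = set(expr.values.index.to_numpy()[order[:keep]])
    mask = expr.values.index.isin(chosen)
    return ExpressionMatrix(expr.values.loc[mask], expr.meta.copy())


def baseline_imbalance_flags(expr: ExpressionMatrix, alpha: float = 0.05) -> pd.Series:
    """Per-gene Welch t-test of baseline values between arms; flag p < alpha.

    Flags only annotate downstream tables — flagged genes stay in the fits.
    """
    meta = expr.meta
    base = meta["visit"] == "baseline"
    cols_a = meta.index[base & (meta["arm"] == ARMS[0])]
    cols_b = meta.index[base & (meta["arm"] == ARMS[1])]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both arms need >=2 baseline samples")
    res = stats.ttest_ind(
        expr.values[cols_a].to_numpy(dtype=float),
        expr.values[cols_b].to_numpy(dtype=float),
        axis=1,
        equal_var=False,
    )
    return pd.Series(res.pvalue < alpha, index=expr.values.index, name="baseline_imbalance_flag")


# ---------------------------------------------------------------------------
# per-gene linear model


@dataclass
class GeneFit:
    """OLS fits of all genes under the cell-means + centered %cortex model."""

    cell_coefs: pd.DataFrame  # genes × 6 arm.visit cell means (at average cortex)
    cortex_coef: pd.Series  # log2 per percentage point
    s2: pd.Series  # residual variance, log2²
    df_resid: int
    xtx_inv: np.ndarray  # (7×7) unscaled covariance of [cells..., cortex]

    def __post_init__(self) -> None:
        if self.df_resid <= 0:
            raise ValueError("residual df must be positive")
        if (self.s2 < -1e-12).any():
            raise ValueError("negative residual variance")


def fit_gene_models(expr: ExpressionMatrix) -> GeneFit:
    """Fit every gene by OLS on the six cell indicators plus centered %cortex."""
    meta = expr.meta
    cell = (meta["arm"].astype(str) + "." + meta["visit"].astype(str)).to_numpy()
    X = np.column_stack([(cell == c).astype(float) for c in CELLS])
    cortex = meta["pct_cortex"].to_numpy(dtype=float)
    X = np.column_stack([X, cortex - cortex.mean()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR exposes which columns are linearly dependent
        from scipy.linalg import qr

        names = [*CELLS, "pct_cortex"]
        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; confounded columns: {bad}")
    n = X.shape[0]
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ValueError("not enough samples for the 7-parameter model")

    Y = expr.values.to_numpy(dtype=float).T  # samples × genes
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y  # 7 × genes
    resid = Y - X @ B
    s2 = (resid**2).sum(axis=0) / df_resid
    genes = expr.values.index
    return GeneFit(
        cell_coefs=pd.DataFrame(B[:6].T, index=genes, columns=CELLS),
        cortex_coef=pd.Series(B[6], index=genes, name="pct_cortex"),
        s2=pd.Series(s2, index=genes, name="s2"),
        df_resid=int(df_resid),
        xtx_inv=xtx_inv,
    )


def _window_contrast_vector(window: str, scale: float) -> np.ndarray:
    if window not in DD_WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {DD_WINDOWS}")
    late, early = DD_WINDOW_VISITS[window]
    c = np.zeros(7)
    idx = {c_: k for k, c_ in enumerate(CELLS)}
    c[idx[f"felzartamab.{late}"]] += scale
    c[idx[f"felzartamab.{early}"]] -= scale
    c[idx[f"placebo.{late}"]] -= scale
    c[idx[f"placebo.{early}"]] += scale
    return c


def delta_delta_contrasts(fit: GeneFit, window: str, scale: float = 0.5) -> pd.Series:
    """Per-gene ΔΔlogFC for a window.

    ``scale=0.5`` reproduces the half-scaled reporting convention (each arm's
    change divided by two); pass ``scale=1.0`` for the plain
    difference-in-differences.  Positive values mean a larger increase in the
    treated arm.
    """
    c = _window_contrast_vector(window, scale)
    vals = fit.cell_coefs.to_numpy() @ c[:6]
    return pd.Series(vals, index=fit.cell_coefs.index, name=f"ddfc_{window}")


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


@dataclass
class EbayesHyper:
    """Prior df and prior variance of the shared residual-variance prior."""

    d0: float  # prior df, may be inf
    s0_sq: float  # prior variance, log2²

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("prior df must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be > 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_ebayes_hyper(fit: GeneFit) -> EbayesHyper:
    """Moment-match log residual variances to their scaled-F distribution.

    With true variances drawn from a scaled inverse chi-square prior
    (df d0, scale s0²), log s² is log s0² plus independent log-chi-square
    terms; the excess of var(log s²) over the known sampling component
    trigamma(d/2) identifies d0 via trigamma inversion, and the mean
    identifies s0².  No excess variance → d0 = ∞ (complete shrinkage).
    """
    s2 = fit.s2.to_numpy(dtype=float)
    pos = s2 > 0
    if pos.sum() < 10:
        raise DegenerateInputError("need >=10 genes with positive residual variance")
    d = float(fit.df_resid)
    z = np.log(s2[pos])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var() - polygamma(1, d / 2.0)  # population variance: invariant to duplicated genes
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return EbayesHyper(d0=float(d0), s0_sq=float(s0_sq))


def moderated_tests(
    fit: GeneFit,
    hyper: EbayesHyper,
    window: str,
    scale: float = 0.5,
    flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Moderated t-tests of the ΔΔ contrast for one window.

    Posterior variance s̃² = (d0·s0² + d·s²)/(d0 + d); t = ΔΔlogFC/(s̃·√v)
    with v the contrast's unscaled design variance; two-sided p on d0 + d df
    (normal when d0 = ∞); BH-FDR; rank by ascending uncorrected p with
    lexicographic gene_id tie-break.
    """
    ddfc = delta_delta_contrasts(fit, window, scale=scale)
    c = _window_contrast_vector(window, scale)
    v = float(c @ fit.xtx_inv @ c)
    if v <= 0:
        raise RuntimeError("non-positive contrast variance")
    d = float(fit.df_resid)
    s2 = fit.s2.to_numpy(dtype=float)
    if np.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0_sq)
        df_total = np.inf
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + d * s2) / (hyper.d0 + d)
        df_total = hyper.d0 + d
    t = ddfc.to_numpy() / np.sqrt(s2_post * v)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)

    tab = pd.DataFrame(
        {
            "ddfc": ddfc,
            "t": t,
            "p": p,
            "FDR": bh_fdr(p),
        },
        index=ddfc.index,
    )
    order = np.lexsort((tab.index.to_numpy(), tab["p"].to_numpy()))
    rank = np.empty(len(tab), dtype=int)
    rank[order] = np.arange(1, len(tab) + 1)
    tab["rank"] = rank
    if flags is None:
        flags = pd.Series(False, index=tab.index)
    tab["baseline_imbalance_flag"] = flags.reindex(tab.index).fillna(False).astype(bool)
    tab.attrs["window"] = window
    tab.attrs["scale"] = scale
    tab.attrs["df_total"] = df_total
    return tab


def rank_genes(
    table: pd.DataFrame,
    k: int = 20,
    direction: str | None = None,
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Top-k genes by ascending uncorrected p.

    ``direction``: 'up'/'down' keeps only positive/negative ΔΔlogFC; flagged
    (baseline-imbalanced) genes are excluded by default.
    """
    t = table
    if exclude_flagged:
        t = t[~t["baseline_imbalance_flag"]]
    if direction == "up":
        t = t[t["ddfc"] > 0]
    elif direction == "down":
        t = t[t["ddfc"] < 0]
    elif direction is not None:
        raise ValueError("direction must be 'up', 'down' or None")
    return t.sort_values("rank").head(k)


def run_dge(
    expr: ExpressionMatrix,
    keep=None,
    scale: float = 0.5,
    baseline_alpha: float = 0.05,
) -> dict:
    """Full differential-expression stage: filter, fit, moderate, contrast.

    Returns ``{"fit", "hyper", "flags", "tables": {window: ContrastTable}}``.
    """
    if keep is not None:
        expr = iqr_filter(expr, keep)
    flags = baseline_imbalance_flags(expr, alpha=baseline_alpha)
    fit = fit_gene_models(expr)
    hyper = estimate_ebayes_hyper(fit)
    tables = {w: moderated_tests(fit, hyper, w, scale=scale, flags=flags) for w in DD_WINDOWS}
    return {"fit": fit, "hyper": hyper, "flags": flags, "tables": tables}
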