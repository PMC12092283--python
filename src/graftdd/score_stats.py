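"""Score-level inference for the repeated-measures two-arm design.

Four pieces:

* **PERMANOVA omnibus test** per score category: Euclidean pseudo-F from the
  among/within partition of squared distances, p by free label permutation
  (a patient-blocked restricted mode is available).
* **Aligned-rank-transform (ART) ANOVA**: for each effect (arm, visit,
  arm×visit) the response is aligned — stripped of the estimated cell-mean
  contributions of every *other* effect — then average-ranked, and the ranked
  response is analysed under the repeated-measures model with a patient
  random intercept.  On the balanced complete design this mixed-model F-test
  is computed through the exact split-plot decomposition (whole-plot error =
  subjects within arms for the arm effect; subplot error for visit and the
  interaction), whose denominator df coincide with the Satterthwaite df.
* **Pairwise interaction contrasts** on the aligned-rank contrast scale: the
  six arm×visit cells are re-leveled into one factor, ranked, and all 15 cell
  pairs plus the three difference-in-differences windows are estimated from a
  patient-blocked mixed model on the ranks, BH-adjusted within each family.
* **Mixed-effects trajectory slopes**: score ~ arm×week with per-patient
  random intercept and slope (REML), per-arm slopes with 95% CIs and the
  arm×week interaction p; singular fits fall back to a random intercept with
  a logged downgrade flag.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .containers import ARMS, DD_WINDOW_VISITS, DegenerateInputError, ScoreTable

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    p: float
    n_permutations: int
    seed: int
    n_samples: int
    n_groups: int

    def __post_init__(self) -> None:
        assert self.p >= 1.0 / (self.n_permutations + 1) - 1e-12


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def omnibus_permanova(
    scores: pd.DataFrame,
    group_labels,
    n_perm: int = 100_000,
    seed: int = 0,
    strata=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on Euclidean distances.

    ``scores``: samples × score columns.  ``group_labels``: one label per
    sample (≥2 groups).  p = (1 + #{F* ≥ F}) / (1 + n_perm).  With ``strata``
    (e.g. patient ids) labels must be constant within each stratum and whole
    strata are permuted together, respecting repeated measures.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(group_labels)
    if len(labels) != X.shape[0]:
        raise ValueError("group_labels length must match number of samples")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if np.allclose(X, X[0], atol=0.0):
        raise DegenerateInputError("score matrix is constant; distances are all zero")

    n = X.shape[0]
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_w = _ss_within(d2, labels)
    ss_a = max(ss_total - ss_w, 0.0)
    df_a, df_w = len(groups) - 1, n - len(groups)
    if ss_w <= 0:
        raise DegenerateInputError("zero within-group variance; pseudo-F undefined")
    f_obs = (ss_a / df_a) / (ss_w / df_w)

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        blocks = pd.Series(labels).groupby(pd.Series(strata)).nunique()
        if (blocks > 1).any():
            raise ValueError("labels are not constant within strata")
        block_ids = pd.unique(strata)
        block_label = {b: labels[strata == b][0] for b in block_ids}
        base = np.array([block_label[b] for b in block_ids])

    count = 0
    for _ in range(n_perm):
        if strata is None:
            perm = labels[rng.permutation(n)]
        else:
            shuffled = base[rng.permutation(len(base))]
            lut = dict(zip(block_ids, shuffled))
            perm = np.array([lut[b] for b in strata])
        ss_w_p = _ss_within(d2, perm)
        f_p = ((ss_total - ss_w_p) / df_a) / (ss_w_p / df_w) if ss_w_p > 0 else np.inf
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(p), int(n_perm), int(seed), n, len(groups))


# ---------------------------------------------------------------------------
# aligned rank transform


def _check_factorial(data: pd.DataFrame, factors: list[str]) -> None:
    counts = data.groupby(factors, observed=True).size()
    levels = [data[f].nunique() for f in factors]
    if len(counts) != int(np.prod(levels)) or (counts < 1).any():
        raise ValueError("design has empty factorial cells; ART requires complete cells")


def art_transform(data: pd.DataFrame, response: str, factors, effect: str):
    """Align-and-rank a response for one target effect.

    ``factors`` is one or two factor column names; ``effect`` is a factor name
    or ``"A:B"`` for the two-factor interaction.  The estimated cell-mean
    contributions of every effect *except* the target are subtracted
    (alignment), then average ranks are assigned.  Returns
    ``(aligned, ranked)`` Series aligned to ``data.index``.
    """
    factors = list(factors)
    if len(factors) not in (1, 2):
        raise ValueError("art_transform supports one or two factors")
    _check_factorial(data, factors)
    y = data[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")

    if len(factors) == 1:
        (fa,) = factors
        if effect != fa:
            raise ValueError(f"unknown effect {effect!r} for single-factor data")
        cell = data.groupby(fa, observed=True)[response].transform("mean").to_numpy()
        # residual from cell means plus the factor's own effect = y - grand mean
        aligned = (y - cell) + (cell - y.mean())
    else:
        fa, fb = factors
        cell_means = data.groupby([fa, fb], observed=True)[response].mean()
        grand = cell_means.mean()  # unweighted mean of cell means
        a_eff = cell_means.groupby(level=0).mean() - grand
        b_eff = cell_means.groupby(level=1).mean() - grand
        mu_cell = cell_means.loc[list(zip(data[fa], data[fb]))].to_numpy()
        a_vec = a_eff.loc[data[fa]].to_numpy()
        b_vec = b_eff.loc[data[fb]].to_numpy()
        resid = y - mu_cell
        if effect == fa:
            aligned = resid + a_vec
        elif effect == fb:
            aligned = resid + b_vec
        elif effect in (f"{fa}:{fb}", f"{fb}:{fa}"):
            aligned = resid + (mu_cell - grand - a_vec - b_vec)
        else:
            raise ValueError(f"unknown effect {effect!r}")

    ranked = stats.rankdata(aligned)
    idx = data.index
    return pd.Series(aligned, index=idx, name="aligned"), pd.Series(ranked, index=idx, name="ranked")


# ---------------------------------------------------------------------------
# split-plot ANOVA on the balanced design


def _split_plot_anova(data: pd.DataFrame, response: str, between: str, within: str, subject: str) -> pd.DataFrame:
    """Exact mixed-design (split-plot) ANOVA for balanced complete data.

    One between-subject factor and one within-subject factor; the
    between-factor F uses subjects-within-groups as its error stratum, the
    within and interaction Fs use the subject×within residual.
    """
    wide = data.pivot_table(index=subject, columns=within, values=response, observed=True)
    if wide.isna().any().any():
        raise ValueError("unbalanced or incomplete design; each subject needs every within level")
    grp = data.drop_duplicates(subject).set_index(subject)[between]
    grp = grp.loc[wide.index]
    sizes = grp.value_counts()
    if sizes.nunique() != 1:
        raise ValueError("unbalanced design: unequal subjects per group")
    a, b, n = sizes.size, wide.shape[1], int(sizes.iloc[0])

    M = wide.to_numpy(dtype=float)
    grand = M.mean()
    subj_means = M.mean(axis=1)
    group_of = grp.to_numpy()
    group_levels = sizes.index.to_numpy()
    group_means = np.array([subj_means[group_of == g].mean() for g in group_levels])
    visit_means = M.mean(axis=0)
    cell = np.array([M[group_of == g].mean(axis=0) for g in group_levels])

    ss_a = n * b * ((group_means - grand) ** 2).sum()
    gm_of_subj = pd.Series(group_means, index=group_levels).loc[group_of].to_numpy()
    ss_subj = b * ((subj_means - gm_of_subj) ** 2).sum()
    ss_b = a * n * ((visit_means - grand) ** 2).sum()
    ss_ab = n * ((cell - group_means[:, None] - visit_means[None, :] + grand) ** 2).sum()
    ss_total = ((M - grand) ** 2).sum()
    ss_err = ss_total - ss_a - ss_subj - ss_b - ss_ab

    df = {
        between: (a - 1, a * (n - 1)),
        within: (b - 1, a * (n - 1) * (b - 1)),
        f"{between}:{within}": ((a - 1) * (b - 1), a * (n - 1) * (b - 1)),
    }
    ms_subj = ss_subj / (a * (n - 1))
    ms_err = ss_err / (a * (n - 1) * (b - 1))
    rows = []
    for effect, ss, ms_den in (
        (between, ss_a, ms_subj),
        (within, ss_b, ms_err),
        (f"{between}:{within}", ss_ab, ms_err),
    ):
        d1, d2 = df[effect]
        if ms_den <= 0:
            raise DegenerateInputError(f"zero error variance for effect {effect!r}")
        F = (ss / d1) / ms_den
        rows.append({"effect": effect, "F": F, "df_num": d1, "df_den": d2, "p": stats.f.sf(F, d1, d2)})
    return pd.DataFrame(rows).set_index("effect")


# ---------------------------------------------------------------------------
# ART-ANOVA


@dataclass
class ARTResult:
    """Per-effect ART-ANOVA F-tests plus the data needed for contrasts."""

    anova: pd.DataFrame  # index effect; F, df_num, df_den, p
    data: pd.DataFrame = field(repr=False)
    response: str = "score"
    between: str = "arm"
    within: str = "visit"
    subject: str = "patient_id"
    contrasts: pd.DataFrame | None = None


def art_anova(
    data: pd.DataFrame,
    response: str = "score",
    between: str = "arm",
    within: str = "visit",
    subject: str = "patient_id",
    effects=None,
) -> ARTResult:
    """Aligned-rank-transform ANOVA of a score under the trial model.

    For each of the three effects the response is aligned for that effect,
    average-ranked, and F-tested under the repeated-measures model with a
    patient random intercept (exact balanced split-plot computation).  The ART
    sanity property — non-target effects carry ≈0 sum of squares on each
    aligned (pre-rank) column — is checked and logged.
    """
    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant response: ART F-statistics are undefined")
    rows = []
    if effects is None:
        effects = (between, within, f"{between}:{within}")
    for effect in effects:
        aligned, ranked = art_transform(data, response, (between, within), effect)
        _log_alignment_sanity(data, aligned, between, within, effect)
        d = data.copy()
        d["_ranked"] = ranked
        tab = _split_plot_anova(d, "_ranked", between, within, subject)
        row = tab.loc[effect]
        rows.append({"effect": effect, "F": row["F"], "df_num": row["df_num"], "df_den": row["df_den"], "p": row["p"]})
    return ARTResult(anova=pd.DataFrame(rows).set_index("effect"), data=data.copy(),
                     response=response, between=between, within=within, subject=subject)


def _log_alignment_sanity(data, aligned, between, within, target) -> None:
    d = data.copy()
    d["_aligned"] = aligned
    cm = d.groupby([between, within], observed=True)["_aligned"].mean()
    grand = cm.mean()
    a_eff = cm.groupby(level=0).mean() - grand
    b_eff = cm.groupby(level=1).mean() - grand
    inter_dev = cm - grand - a_eff.reindex(cm.index, level=0) - b_eff.reindex(cm.index, level=1)
    stray = {between: float(np.abs(a_eff).max()), within: float(np.abs(b_eff).max()),
             f"{between}:{within}": float(np.abs(inter_dev).max())}
    stray.pop(target, None)
    worst = max(stray.values()) if stray else 0.0
    if worst > 1e-8:
        logger.warning("ART alignment sanity: residual non-target effect %.3g on %s-aligned column", worst, target)


def interaction_contrasts(result: ARTResult, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise arm×visit cell contrasts on the aligned-rank-contrast scale.

    The six cells are re-leveled into one factor and the raw response ranked
    (with a single factor, alignment only removes the grand mean, which ranks
    ignore).  Cell means, their standard errors and t-tests come from a mixed
    model on the ranks with a patient random intercept; p-values are
    BH-adjusted within the 15-pair family.  Three additional rows give the
    difference-in-differences window contrasts, flagged ``primary`` and
    BH-adjusted within their own family of three.
    """
    if result.anova is None:
        raise RuntimeError("interaction_contrasts requires a fitted ARTResult")
    d = result.data.copy()
    d["_cell"] = d[result.between].astype(str) + "." + d[result.within].astype(str)
    d["_rank"] = stats.rankdata(d[result.response].to_numpy(dtype=float))
    cells = [f"{a}.{v}" for a in sorted(d[result.between].unique()) for v in sorted(d[result.within].unique())]
    X = pd.get_dummies(d["_cell"], dtype=float)[cells].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mm = sm.MixedLM(d["_rank"].to_numpy(), X, groups=d[result.subject].to_numpy())
        fit = mm.fit(reml=True, method="lbfgs")
    beta = fit.fe_params
    cov = np.asarray(fit.cov_params())[: len(cells), : len(cells)]
    df_t = len(d) - len(cells)

    def _contrast(c: np.ndarray):
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df_t)
        return est, se, t, p

    rows = []
    for i, j in itertools.combinations(range(len(cells)), 2):
        c = np.zeros(len(cells))
        c[i], c[j] = 1.0, -1.0
        est, se, t, p = _contrast(c)
        rows.append({"pair": f"{cells[i]} - {cells[j]}", "kind": "cell_pair", "primary": False,
                     "estimate": est, "SE": se, "t": t, "df": df_t, "p": p})
    cell_idx = {c: k for k, c in enumerate(cells)}
    for window, (late, early) in DD_WINDOW_VISITS.items():
        c = np.zeros(len(cells))
        c[cell_idx[f"felzartamab.{late}"]] += 1.0
        c[cell_idx[f"felzartamab.{early}"]] -= 1.0
        c[cell_idx[f"placebo.{late}"]] -= 1.0
        c[cell_idx[f"placebo.{early}"]] += 1.0
        est, se, t, p = _contrast(c)
        rows.append({"pair": f"dd_{window}", "kind": "dd_window", "primary": True,
                     "estimate": est, "SE": se, "t": t, "df": df_t, "p": p})
    tab = pd.DataFrame(rows)
    tab["FDR"] = np.nan
    for kind in ("cell_pair", "dd_window"):
        m = tab["kind"] == kind
        tab.loc[m, "FDR"] = bh_fdr(tab.loc[m, "p"].to_numpy())
    result.contrasts = tab
    return tab


# ---------------------------------------------------------------------------
# mixed-effects slopes


@dataclass
class SlopeFit:
    """Per-arm linear trajectories of a score (units per week)."""

    score: str
    slopes: pd.DataFrame  # index arm; slope, SE, ci_lo, ci_hi
    interaction_p: float
    downgraded: bool  # True when the random-slope fit was singular
    var_components: dict
    _beta: np.ndarray = field(repr=False, default=None)
    _cov: np.ndarray = field(repr=False, default=None)

    def predict(self, weeks=None) -> pd.DataFrame:
        """Population trajectories with 95% CI bands, per arm."""
        if weeks is None:
            weeks = np.linspace(0.0, 52.0, 27)
        weeks = np.asarray(weeks, dtype=float)
        rows = []
        for arm in ARMS:
            z = 1.0 if arm == "felzartamab" else 0.0
            for w in weeks:
                x = np.array([1.0, z, w, z * w])
                fit = float(x @ self._beta)
                se = float(np.sqrt(x @ self._cov @ x))
                rows.append({"arm": arm, "week": w, "fit": fit, "lo": fit - 1.96 * se, "hi": fit + 1.96 * se})
        return pd.DataFrame(rows)


def fit_mixed_slopes(table: ScoreTable, score: str) -> SlopeFit:
    """REML fit of score ~ arm×week with per-patient random intercept+slope.

    Returns per-arm slopes (score units/week) with 95% CIs and the arm×week
    interaction p (Wald).  A singular random-slope covariance triggers a
    fall-back to a random-intercept-only model with ``downgraded=True``.
    """
    d = table.long(score)
    counts = d.groupby("patient_id")["week"].nunique()
    if (counts < 2).any():
        raise ValueError("every patient needs at least 2 time points")
    z = (d["arm"] == "felzartamab").astype(float).to_numpy()
    w = d["week"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(w), z, w, z * w])
    y = d["score"].to_numpy(dtype=float)
    groups = d["patient_id"].to_numpy()

    def _fit(re_design):
        """Fit and extract (beta, fe-cov, re-cov, scale); raises on a
        singular Hessian so callers can fall back."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm = sm.MixedLM(y, X, groups=groups, exog_re=re_design)
            res = mm.fit(reml=True, method="lbfgs")
            beta = np.asarray(res.fe_params, dtype=float)
            cov = np.asarray(res.cov_params())[:4, :4]
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError("non-finite fixed-effect covariance")
            return beta, cov, np.asarray(res.cov_re), float(res.scale)

    re_full = np.column_stack([np.ones_like(w), w])
    downgraded = False
    try:
        beta, cov, cov_re, scale = _fit(re_full)
        # singular random-effects covariance: slope variance (per week²) ~ 0
        if np.linalg.matrix_rank(cov_re, tol=1e-10) < 2 or np.min(np.linalg.eigvalsh(cov_re)) < -1e-8:
            raise np.linalg.LinAlgError("singular random-effects covariance")
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("random-slope fit singular for %r; downgrading to random intercept", score)
        downgraded = True
        try:
            beta, cov, cov_re, scale = _fit(np.ones((len(w), 1)))
        except (np.linalg.LinAlgError, ValueError):
            # boundary REML fit: patient-clustered OLS is the terminal fallback
            logger.warning("random-intercept fit singular for %r; using cluster-robust OLS", score)
            ols = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
            beta = np.asarray(ols.params, dtype=float)
            cov = np.asarray(ols.cov_params())
            cov_re = np.zeros((1, 1))
            scale = float(ols.scale)
    slope_rows = {}
    for arm in ARMS:
        c = np.array([0.0, 0.0, 1.0, 1.0 if arm == "felzartamab" else 0.0])
        s = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        slope_rows[arm] = {"slope": s, "SE": se, "ci_lo": s - 1.96 * se, "ci_hi": s + 1.96 * se}
    t_int = beta[3] / np.sqrt(cov[3, 3])
    p_int = 2 * stats.norm.sf(abs(t_int))
    var_components = {"re_cov": cov_re.tolist(), "resid_var": scale}
    return SlopeFit(
        score=score,
        slopes=pd.DataFrame(slope_rows).T.rename_axis("arm"),
        interaction_p=float(p_int),
        downgraded=downgraded,
        var_components=var_components,
        _beta=beta,
        _cov=cov,
    )
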