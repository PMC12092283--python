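"""Synthetic data with planted ground truth for the whole pipeline.

Three generators emulate the data a two-arm repeated-biopsy transplant trial
analysis needs:

* a **reference cohort** — a large biopsy cohort with per-sample early/full
  antibody-mediated-rejection (EABMR/FABMR) archetype scores, in which
  designated gene classes load on one of the two scores (used to test
  correlation-based gene-set derivation);
* a **cell profile panel** — per-gene log2 expression in NK cells and in
  unstimulated / IFNγ-stimulated endothelial cells (HUVECs), built so each
  planted class passes exactly its intended cell-selectivity filter;
* a **trial** — 2 arms × n patients × 3 visits (baseline, week 24, week 52)
  of log2 expression with patient random intercepts, a shared per-visit time
  drift, planted multiplicative (log2-additive) treatment effects encoded so
  the difference-in-differences contrast recovers them exactly in the
  noise-free limit, linear per-week injury trajectories with arm-specific
  slopes, and a %cortex nuisance covariate.

Every generator is deterministic given its seed; :class:`TrialTruth` records
what was planted so recovery tests can check it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .containers import (
    ARMS,
    DD_WINDOWS,
    VISIT_WEEKS,
    VISITS,
    CellProfilePanel,
    ExpressionMatrix,
    GeneSet,
    GeneSetLibrary,
    ReferenceCohort,
)

#: planted gene classes, in a fixed order
CLASSES = ("ifng_activity", "nk_activity", "endothelial", "injury_up", "injury_down", "null")
ACTIVITY_CLASSES = ("ifng_activity", "nk_activity")
INJURY_CLASSES = ("injury_up", "injury_down")


class ConfigError(ValueError):
    """Raised when generator parameters are inconsistent or out of bounds."""


@dataclass
class GeneratorConfig:
    """Tunable knobs of all three generators (log2 units throughout)."""

    # class sizes within the gene universe
    n_ifng: int = 30
    n_nk: int = 20
    n_endothelial: int = 30
    n_injury_up: int = 30
    n_injury_down: int = 20

    # reference cohort: x = baseline + loading * latent + noise
    loading_eabmr: float = 1.0
    loading_fabmr: float = 1.0
    ref_noise_sd: float = 1.0
    rho_hi: float = 0.5  # declared minimum population Spearman of loaded genes
    inter_gene_corr: float = 0.0  # shared-factor correlation among loaded genes

    # cell profiles
    base_log2: float = 8.0
    margin_log2: float = 1.0
    profile_noise_sd: float = 0.1
    nk_high_log2: float = 4.0  # NK boost for NK-expressed activity genes

    # trial
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    visit_effect_sd: float = 0.1  # shared (both-arm) drift per gene and visit
    cortex_slope_fraction: float = 0.1  # fraction of null genes sensitive to %cortex
    cortex_slope_sd: float = 0.01  # log2 per percentage point of cortex
    cortex_center: float = 70.0

    def implied_spearman(self, loading: float) -> float:
        """Population Spearman between a loaded gene and its archetype score.

        The gene is ``loading * z + noise`` with ``z`` standard normal and the
        score a monotone transform of ``z``; for a bivariate normal pair with
        Pearson correlation r the Spearman correlation is (6/π)·asin(r/2).
        """
        r = loading / np.hypot(loading, self.ref_noise_sd)
        return 6.0 / np.pi * np.arcsin(r / 2.0)

    def validate(self) -> None:
        if self.margin_log2 <= 0:
            raise ConfigError("margin_log2 must be > 0")
        if self.ref_noise_sd < 0 or self.profile_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if not 0.0 <= self.inter_gene_corr < 1.0:
            raise ConfigError("inter_gene_corr must be in [0, 1)")
        for name, loading in (("loading_eabmr", self.loading_eabmr), ("loading_fabmr", self.loading_fabmr)):
            if loading < 0:
                raise ConfigError(f"{name} must be >= 0")
            if loading > 0 and self.implied_spearman(loading) <= self.rho_hi:
                raise ConfigError(
                    f"{name}={loading} implies population Spearman "
                    f"{self.implied_spearman(loading):.3f} <= rho_hi={self.rho_hi}"
                )


@dataclass
class TrialDesign:
    """Two-arm design with a complete visit set per patient."""

    n_per_arm: int = 10
    visits: tuple = VISITS

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm must be >= 2")
        if tuple(self.visits) != VISITS:
            raise ConfigError(f"visits must be {VISITS}")


@dataclass
class TrialTruth:
    """Everything the generators planted, for recovery tests.

    ``ddfc[class][window]`` is the raw log2 difference-in-differences
    (treated-arm change minus placebo-arm change) planted on that class for
    that window; the half-scaled reporting contrast equals ``ddfc/2``.
    ``slopes[class][arm]`` is the per-week log2 trend of injury-class genes.
    """

    planted_sets: dict = field(default_factory=dict)  # class -> ordered gene list
    ddfc: dict = field(default_factory=dict)  # class -> {window: raw log2 DiD}
    slopes: dict = field(default_factory=dict)  # class -> {arm: log2 per week}
    patient_sd: float = 0.7
    resid_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cls, genes in self.planted_sets.items():
            if cls not in CLASSES:
                raise ConfigError(f"unknown planted class {cls!r}")
            for g in genes:
                if g in seen:
                    raise ConfigError(f"gene {g!r} planted in both {seen[g]!r} and {cls!r}")
                seen[g] = cls
        for cls, eff in self.ddfc.items():
            for w, v in eff.items():
                if w not in DD_WINDOWS:
                    raise ConfigError(f"unknown window {w!r}")
                if not np.isfinite(v):
                    raise ConfigError("ddfc effects must be finite")
        if self.patient_sd < 0 or self.resid_sd < 0:
            raise ConfigError("variance components must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        out: list[str] = []
        for cls in CLASSES:
            out.extend(self.planted_sets.get(cls, []))
        return out

    def class_of(self) -> dict[str, str]:
        return {g: cls for cls in CLASSES for g in self.planted_sets.get(cls, [])}

    def cell_effect(self, cls: str, arm: str, visit: str) -> float:
        """Planted arm×visit effect (log2) for a gene class, excluding injury
        trends.  Placebo and baseline cells carry no treatment effect, so the
        raw window DiD equals ``ddfc``."""
        if arm != "felzartamab" or visit == "baseline":
            return 0.0
        eff = self.ddfc.get(cls, {})
        if visit == "week24":
            return eff.get("b_w24", 0.0)
        return eff.get("b_w24", 0.0) + eff.get("w24_w52", 0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialTruth":
        return cls(**d)


def make_truth(
    n_genes: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    ddfc: dict | None = None,
    slopes: dict | None = None,
    patient_sd: float = 0.7,
    resid_sd: float = 0.5,
) -> TrialTruth:
    """Assign gene classes over a fresh gene universe and fix planted effects.

    Default effects mirror the study conditions the pipeline is meant to
    detect: a −1.0 log2 interactive suppression of both activity classes at
    week 24 that rebounds by week 52, a −0.5 log2 suppression of the
    endothelial class, and injury trajectories falling in the treated arm
    (−0.01 log2/week) while rising under placebo (+0.01 log2/week), with the
    down-regulated injury class mirrored.
    """
    config = config or GeneratorConfig()
    config.validate()
    n_planted = config.n_ifng + config.n_nk + config.n_endothelial + config.n_injury_up + config.n_injury_down
    if n_genes < n_planted + 50:
        raise ConfigError(f"n_genes={n_genes} too small for {n_planted} planted genes plus null background")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, n_genes + 1)])
    order = rng.permutation(n_genes)
    sizes = {
        "ifng_activity": config.n_ifng,
        "nk_activity": config.n_nk,
        "endothelial": config.n_endothelial,
        "injury_up": config.n_injury_up,
        "injury_down": config.n_injury_down,
    }
    planted: dict[str, list[str]] = {}
    start = 0
    for cls, size in sizes.items():
        planted[cls] = sorted(genes[order[start : start + size]].tolist())
        start += size
    planted["null"] = sorted(genes[order[start:]].tolist())

    if ddfc is None:
        ddfc = {
            "ifng_activity": {"b_w24": -1.0, "w24_w52": 1.0, "b_w52": 0.0},
            "nk_activity": {"b_w24": -1.0, "w24_w52": 1.0, "b_w52": 0.0},
            "endothelial": {"b_w24": -0.5, "w24_w52": 0.5, "b_w52": 0.0},
        }
    if slopes is None:
        slopes = {
            "injury_up": {"placebo": 0.01, "felzartamab": -0.01},
            "injury_down": {"placebo": -0.01, "felzartamab": 0.01},
        }
    return TrialTruth(
        planted_sets=planted,
        ddfc=ddfc,
        slopes=slopes,
        patient_sd=patient_sd,
        resid_sd=resid_sd,
        seed=int(seed),
    )


def generate_reference_cohort(
    n_samples: int,
    n_genes: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    truth: TrialTruth | None = None,
) -> ReferenceCohort:
    """Simulate a reference biopsy cohort with archetype scores.

    Activity-class genes load on the latent behind the EABMR score,
    endothelial genes on the FABMR latent, and all other genes on neither.
    Scores are the standard-normal CDF of the latents, hence in (0, 1) and
    monotone in them, so loaded genes correlate with the scores in Spearman
    rank terms by construction.
    """
    config = config or GeneratorConfig()
    config.validate()
    if n_samples < 20:
        raise ConfigError("n_samples must be >= 20")
    if n_genes < 200:
        raise ConfigError("n_genes must be >= 200")
    if truth is None:
        truth = make_truth(n_genes, config, seed=seed)
    genes = truth.gene_ids
    if len(genes) != n_genes:
        raise ConfigError("truth gene universe size does not match n_genes")
    rng = np.random.default_rng(seed)
    z_e = rng.standard_normal(n_samples)
    z_f = rng.standard_normal(n_samples)
    sample_ids = [f"R{i:05d}" for i in range(1, n_samples + 1)]

    cls_of = truth.class_of()
    base = rng.normal(config.base_log2, 1.0, size=len(genes))
    noise = rng.normal(0.0, config.ref_noise_sd, size=(len(genes), n_samples))
    if config.inter_gene_corr > 0:
        shared = rng.standard_normal(n_samples)
        w = np.sqrt(config.inter_gene_corr)
        noise = np.sqrt(1 - config.inter_gene_corr) * noise + w * config.ref_noise_sd * shared

    loadings = np.zeros(len(genes))
    latent = np.zeros((len(genes), n_samples))
    for i, g in enumerate(genes):
        cls = cls_of[g]
        if cls in ACTIVITY_CLASSES:
            loadings[i] = config.loading_eabmr
            latent[i] = z_e
        elif cls == "endothelial":
            loadings[i] = config.loading_fabmr
            latent[i] = z_f
    values = base[:, None] + loadings[:, None] * latent + noise

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return ReferenceCohort(
        expr=expr,
        eabmr_score=pd.Series(stats.norm.cdf(z_e), index=sample_ids, name="eabmr_score"),
        fabmr_score=pd.Series(stats.norm.cdf(z_f), index=sample_ids, name="fabmr_score"),
    )


def generate_cell_profiles(
    truth: TrialTruth,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> CellProfilePanel:
    """Build NK / HUVEC profiles so each class passes its intended filter.

    With base level b and margin m: IFNγ-inducible genes sit at
    ``huvec_ifng = b + log2(5) + m`` (five-fold over both NK cells and
    unstimulated HUVECs, with margin); NK-expressed genes get a large NK boost
    while both HUVEC columns sit at ``b − 2m`` (below the panel medians);
    endothelial genes get ``huvec_unstim = b + log2(4) + m`` (four-fold over
    NK, with margin).  All other genes sit at the base level everywhere.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    cls_of = truth.class_of()
    b, m = config.base_log2, config.margin_log2

    rows = np.empty((len(genes), 3))
    for i, g in enumerate(genes):
        cls = cls_of[g]
        if cls == "ifng_activity":
            rows[i] = (b, b, b + np.log2(5) + m)
        elif cls == "nk_activity":
            rows[i] = (b + config.nk_high_log2, b - 2 * m, b - 2 * m)
        elif cls == "endothelial":
            rows[i] = (b, b + np.log2(4) + m, b + np.log2(4) + m)
        else:
            rows[i] = (b, b, b)
    rows = rows + rng.normal(0.0, config.profile_noise_sd, size=rows.shape)
    profiles = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=list(CellProfilePanel.COLUMNS))
    return CellProfilePanel(profiles)


def generate_trial(
    design: TrialDesign,
    truth: TrialTruth,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate the trial expression matrix with metadata.

    Per-gene model (log2): baseline level + patient random intercept
    (sd ``truth.patient_sd``) + shared per-visit drift + planted arm×visit
    class effect + arm-specific linear injury trend + %cortex slope
    (medulla-sensitive genes only) + residual noise (sd ``truth.resid_sd``).
    The planted arm×visit effects are zero for placebo and at baseline, so the
    raw window difference-in-differences equals ``truth.ddfc`` and the
    half-scaled contrast equals ``truth.ddfc / 2`` exactly when noise is off.
    """
    config = config or GeneratorConfig()
    config.validate()
    design.validate()
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    if not genes:
        raise ConfigError("truth has an empty gene universe")
    cls_of = truth.class_of()
    n_pat = 2 * design.n_per_arm

    patients = [f"P{i:02d}" for i in range(1, n_pat + 1)]
    arm_of = {p: ARMS[0] if i < design.n_per_arm else ARMS[1] for i, p in enumerate(patients)}
    meta_rows = []
    for p in patients:
        for v in VISITS:
            meta_rows.append(
                {
                    "sample_id": f"{p}_{v}",
                    "patient_id": p,
                    "arm": arm_of[p],
                    "visit": v,
                    "pct_cortex": rng.uniform(40.0, 100.0),
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    G, S = len(genes), len(meta)
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    pat_int = rng.normal(0.0, truth.patient_sd, size=(G, n_pat))
    visit_drift = np.zeros((G, len(VISITS)))
    visit_drift[:, 1:] = rng.normal(0.0, config.visit_effect_sd, size=(G, len(VISITS) - 1))

    cortex_slope = np.zeros(G)
    null_idx = [i for i, g in enumerate(genes) if cls_of[g] == "null"]
    n_sens = int(round(config.cortex_slope_fraction * len(null_idx)))
    if n_sens:
        sens = rng.choice(null_idx, size=n_sens, replace=False)
        cortex_slope[sens] = rng.normal(0.0, config.cortex_slope_sd, size=n_sens)

    pat_index = {p: i for i, p in enumerate(patients)}
    visit_index = {v: i for i, v in enumerate(VISITS)}
    values = np.empty((G, S))
    cls_arr = np.array([cls_of[g] for g in genes])
    for j, (sid, row) in enumerate(meta.iterrows()):
        p, arm, visit = row["patient_id"], row["arm"], row["visit"]
        week = VISIT_WEEKS[visit]
        col = base + pat_int[:, pat_index[p]] + visit_drift[:, visit_index[visit]]
        col = col + cortex_slope * (row["pct_cortex"] - config.cortex_center)
        for cls in truth.ddfc:
            eff = truth.cell_effect(cls, arm, visit)
            if eff:
                col = col + np.where(cls_arr == cls, eff, 0.0)
        for cls, by_arm in truth.slopes.items():
            slope = by_arm.get(arm, 0.0)
            if slope:
                col = col + np.where(cls_arr == cls, slope * week, 0.0)
        values[:, j] = col
    if truth.resid_sd > 0:
        values = values + rng.normal(0.0, truth.resid_sd, size=(G, S))

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=meta.index)
    return ExpressionMatrix(expr, meta)


def simulate_null_scores(
    n_per_arm: int = 10,
    patient_sd: float = 0.7,
    resid_sd: float = 0.5,
    seed: int = 0,
    interaction: dict | None = None,
) -> pd.DataFrame:
    """Score-level simulator of the 2-arm × 3-visit design for calibration.

    Returns a long frame (sample_id index; patient_id, arm, visit, pct_cortex,
    score) under score = patient intercept + noise, optionally plus an
    ``interaction`` map {(arm, visit): shift} to plant a treatment effect.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_pat = 2 * n_per_arm
    intercepts = rng.normal(0.0, patient_sd, size=n_pat)
    for i in range(n_pat):
        p = f"P{i + 1:02d}"
        arm = ARMS[0] if i < n_per_arm else ARMS[1]
        for v in VISITS:
            y = intercepts[i] + rng.normal(0.0, resid_sd)
            if interaction:
                y += interaction.get((arm, v), 0.0)
            rows.append(
                {
                    "sample_id": f"{p}_{v}",
                    "patient_id": p,
                    "arm": arm,
                    "visit": v,
                    "pct_cortex": rng.uniform(40, 100),
                    "score": y,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def make_marker_table(truth: TrialTruth, seed: int = 0, n_decoy: int = 15) -> pd.DataFrame:
    """Emulate a single-nucleus AKI marker-gene table (gene, cell_state,
    state_class).

    Injury-class genes are assigned to kidney-injury-induced ('New') cell
    states; a decoy healthy state drawn from null genes carries
    state_class 'other' and must be screened out downstream.
    """
    rng = np.random.default_rng(seed)
    rows = []
    up = truth.planted_sets.get("injury_up", [])
    half = (len(up) + 1) // 2
    for g in up[:half]:
        rows.append({"gene": g, "cell_state": "PT_New", "state_class": "New"})
    for g in up[half:]:
        rows.append({"gene": g, "cell_state": "TAL_New", "state_class": "New"})
    for g in truth.planted_sets.get("injury_down", []):
        rows.append({"gene": g, "cell_state": "DCT_New", "state_class": "New"})
    null_genes = truth.planted_sets.get("null", [])
    if null_genes and n_decoy:
        decoys = rng.choice(null_genes, size=min(n_decoy, len(null_genes)), replace=False)
        for g in sorted(decoys):
            rows.append({"gene": g, "cell_state": "PT_healthy", "state_class": "other"})
    return pd.DataFrame(rows, columns=["gene", "cell_state", "state_class"])


def planted_library(truth: TrialTruth) -> GeneSetLibrary:
    """The planted classes (minus the null background) as a gene-set library."""
    lib = GeneSetLibrary()
    for cls in CLASSES:
        if cls == "null":
            continue
        genes = truth.planted_sets.get(cls, [])
        if genes:
            lib.add(GeneSet(name=cls, genes=list(genes), provenance=f"planted class {cls}"))
    return lib


def write_fixture_bundle(
    out_dir,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    design: TrialDesign | None = None,
    n_genes: int = 2000,
    n_ref_samples: int = 300,
) -> dict:
    """Generate a complete, self-consistent fixture bundle on disk.

    Writes the trial expression + metadata TSVs, the reference-cohort
    expression and archetype-score TSVs, the NK/HUVEC profile TSV, the planted
    gene-set GMT, the AKI marker TSV and the ground-truth JSON.  Returns the
    path map.  Everything round-trips losslessly through :mod:`graftdd.io`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or GeneratorConfig()
    design = design or TrialDesign()
    truth = make_truth(n_genes, config, seed=seed)
    ref = generate_reference_cohort(n_ref_samples, n_genes, config, seed=seed + 1, truth=truth)
    panel = generate_cell_profiles(truth, config, seed=seed + 2)
    trial = generate_trial(design, truth, config, seed=seed + 3)
    markers = make_marker_table(truth, seed=seed + 4)

    paths = {
        "expr": out / "trial_expression.tsv",
        "meta": out / "trial_metadata.tsv",
        "ref_expr": out / "reference_expression.tsv",
        "ref_scores": out / "reference_scores.tsv",
        "profiles": out / "cell_profiles.tsv",
        "gmt": out / "planted_sets.gmt",
        "markers": out / "aki_markers.tsv",
        "truth": out / "truth.json",
    }
    io.write_expression(trial, paths["expr"], paths["meta"])
    ref.expr.rename_axis("gene_id").to_csv(paths["ref_expr"], sep="\t", float_format="%.17g")
    pd.DataFrame({"eabmr_score": ref.eabmr_score, "fabmr_score": ref.fabmr_score}).rename_axis("sample_id").to_csv(
        paths["ref_scores"], sep="\t", float_format="%.17g"
    )
    io.write_cell_profiles(panel, paths["profiles"])
    io.write_gmt(planted_library(truth), paths["gmt"])
    io.write_marker_table(markers, paths["markers"])
    io.write_json(truth.to_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_reference_cohort(expr_path, scores_path) -> ReferenceCohort:
    """Read a reference cohort written by :func:`write_fixture_bundle`."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    scores = pd.read_csv(scores_path, sep="\t", index_col=0)
    return ReferenceCohort(expr=expr, eabmr_score=scores["eabmr_score"], fabmr_score=scores["fabmr_score"])
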