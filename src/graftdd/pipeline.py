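"""End-to-end pipeline: simulate → derive sets → score → score-stats → dge → enrich.

A :class:`RunConfig` (YAML-backed) names the input paths, the stages to run
and every stage parameter.  :func:`run_pipeline` executes the enabled stages
in dependency order, writes per-stage TSV/JSON artifacts under the output
directory and returns a manifest (inputs hashed, seeds, parameters,
versions).  Identical configs produce identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dge, enrichment, genesets, io, scoring, score_stats, synthdata
from .containers import ARMS, VISITS, GeneSetLibrary

logger = logging.getLogger(__name__)

STAGES = ("simulate", "derive_sets", "score", "score_stats", "dge", "enrich")


class DependencyError(RuntimeError):
    """A stage was enabled without the stage(s) it consumes."""


@dataclass
class RunConfig:
    outdir: str = "graftdd_out"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    paths: dict = field(default_factory=dict)  # expr, meta, ref_expr, ref_scores, profiles, markers, gmt
    simulate: dict = field(default_factory=lambda: {"n_genes": 2000, "n_ref_samples": 300, "n_per_arm": 10})
    score_stats: dict = field(default_factory=lambda: {"permutations": 100_000})
    dge: dict = field(default_factory=lambda: {"iqr_keep": 1000, "scale": 0.5, "baseline_alpha": 0.05})
    enrich: dict = field(default_factory=lambda: {"mode": "ora", "alpha": 0.05, "fdr_threshold": 0.05, "n_perm": 999})

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "enrich" in self.stages and "dge" not in self.stages:
            raise DependencyError("enrich requires the dge stage")
        if "score_stats" in self.stages and "score" not in self.stages:
            raise DependencyError("score_stats requires the score stage")
        if "simulate" not in self.stages:
            needed = {"expr", "meta"}
            if "derive_sets" in self.stages:
                needed |= {"ref_expr", "ref_scores", "profiles"}
            missing = [k for k in sorted(needed) if k not in self.paths]
            if missing:
                raise ValueError(f"paths missing for enabled stages: {missing}")
            absent = [k for k in sorted(needed) if not Path(self.paths[k]).exists()]
            if absent:
                raise FileNotFoundError(f"input paths do not exist: {[self.paths[k] for k in absent]}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.read_yaml(path) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def validate_inputs(expr_path, meta_path, gmt_path=None) -> list[str]:
    """Report structural problems in user-supplied inputs (report-only)."""
    report: list[str] = []
    try:
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    except Exception as exc:  # unreadable files are the whole report
        return [f"cannot read inputs: {exc}"]
    if values.index.duplicated().any():
        report.append("duplicate gene_id rows in expression matrix")
    extra = set(values.columns) - set(meta.index)
    if extra:
        report.append(f"samples in expression but not metadata: {sorted(extra)[:5]}")
    extra = set(meta.index) - set(values.columns)
    if extra:
        report.append(f"samples in metadata but not expression: {sorted(extra)[:5]}")
    for col in ("patient_id", "arm", "visit", "pct_cortex"):
        if col not in meta.columns:
            report.append(f"metadata missing column {col!r}")
    if "visit" in meta.columns and "patient_id" in meta.columns:
        per_patient = meta.groupby("patient_id")["visit"].nunique()
        short = per_patient[per_patient < len(VISITS)]
        for p, k in short.items():
            report.append(f"patient {p} has {k} visits (design expects {len(VISITS)})")
    if "arm" in meta.columns:
        bad = set(meta["arm"]) - set(ARMS)
        if bad:
            report.append(f"unknown arm levels: {sorted(bad)}")
    if gmt_path is not None:
        try:
            io.read_gmt(gmt_path)
        except Exception as exc:
            report.append(f"GMT problem: {exc}")
    return report


def _default_families(score_names) -> dict:
    fam: dict[str, list[str]] = {"abmr": [], "injury": [], "other": []}
    for name in score_names:
        if name in ("abmr_activity", "ifng_inducible_activity", "nk_expressed_activity", "abmr_endothelial"):
            fam["abmr"].append(name)
        elif name.endswith("_New") or name.startswith("aki_") or "injury" in name:
            fam["injury"].append(name)
        else:
            fam["other"].append(name)
    return {k: v for k, v in fam.items() if v}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": int(config.seed),
        "stages": {},
        "parameters": {
            "simulate": dict(config.simulate),
            "score_stats": dict(config.score_stats),
            "dge": dict(config.dge),
            "enrich": dict(config.enrich),
        },
        "inputs": {},
    }
    paths = dict(config.paths)
    truth = None

    try:
        if "simulate" in config.stages:
            sim = config.simulate
            bundle = synthdata.write_fixture_bundle(
                out / "fixture",
                seed=config.seed,
                design=synthdata.TrialDesign(n_per_arm=int(sim.get("n_per_arm", 10))),
                n_genes=int(sim.get("n_genes", 2000)),
                n_ref_samples=int(sim.get("n_ref_samples", 300)),
            )
            paths.update(bundle)
            truth = synthdata.TrialTruth.from_dict(io.read_json(bundle["truth"]))
            manifest["stages"]["simulate"] = {"outputs": bundle}

        for key in ("expr", "meta", "ref_expr", "ref_scores", "profiles", "markers", "gmt"):
            if key in paths and Path(paths[key]).exists():
                manifest["inputs"][key] = {"path": str(paths[key]), "sha256": _sha256(paths[key])}

        expr = io.read_expression(paths["expr"], paths["meta"])

        library = GeneSetLibrary()
        if "derive_sets" in config.stages:
            ref = synthdata.read_reference_cohort(paths["ref_expr"], paths["ref_scores"])
            profiles = io.read_cell_profiles(paths["profiles"])
            markers = io.read_marker_table(paths["markers"]) if "markers" in paths else None
            library = genesets.derive_all(ref, profiles, markers)
            gmt_out = out / "derived_sets.gmt"
            io.write_gmt(library, gmt_out)
            io.write_json(
                {s.name: {"n_genes": len(s), "provenance": s.provenance} for s in library},
                out / "derived_sets_provenance.json",
            )
            manifest["stages"]["derive_sets"] = {"outputs": {"gmt": str(gmt_out)}, "sizes": {s.name: len(s) for s in library}}
        elif "gmt" in paths:
            library = io.read_gmt(paths["gmt"])

        score_table = None
        if "score" in config.stages:
            if len(library) == 0:
                raise DependencyError("score requires derived sets or a gmt path")
            score_table = scoring.assemble_score_table(expr, library)
            io.write_score_table(score_table, out / "scores.tsv")
            manifest["stages"]["score"] = {"outputs": {"scores": str(out / "scores.tsv")}}

        if "score_stats" in config.stages:
            manifest["stages"]["score_stats"] = _run_score_stats(config, out, score_table)

        dge_result = None
        if "dge" in config.stages:
            dcfg = config.dge
            dge_result = dge.run_dge(
                expr,
                keep=dcfg.get("iqr_keep"),
                scale=float(dcfg.get("scale", 0.5)),
                baseline_alpha=float(dcfg.get("baseline_alpha", 0.05)),
            )
            files = {}
            for window, tab in dge_result["tables"].items():
                f = out / f"dge_{window}.tsv"
                tab.rename_axis("gene_id").to_csv(f, sep="\t", float_format="%.6g")
                files[window] = str(f)
            hyper = dge_result["hyper"]
            io.write_json({"d0": hyper.d0 if np.isfinite(hyper.d0) else "inf", "s0_sq": hyper.s0_sq}, out / "dge_hyper.json")
            manifest["stages"]["dge"] = {
                "outputs": files,
                "n_genes": int(dge_result["fit"].s2.size),
                "n_flagged": int(dge_result["flags"].sum()),
            }

        if "enrich" in config.stages:
            if dge_result is None:
                raise DependencyError("enrich requires dge results")
            ecfg = config.enrich
            injury_lib = GeneSetLibrary()
            if "markers" in paths and Path(paths["markers"]).exists():
                injury_lib = genesets.build_injury_ontology(io.read_marker_table(paths["markers"]))
            lib = injury_lib if len(injury_lib) else library
            files = {}
            for window, tab in dge_result["tables"].items():
                res = enrichment.enrich_contrast_table(
                    tab,
                    lib,
                    mode=ecfg.get("mode", "ora"),
                    alpha=float(ecfg.get("alpha", 0.05)),
                    library_name="injury_ontology" if len(injury_lib) else "user",
                    n_perm=int(ecfg.get("n_perm", 999)),
                    seed=config.seed,
                )
                f = out / f"enrichment_{window}.tsv"
                res.to_csv(f, sep="\t", index=False, float_format="%.6g")
                files[window] = str(f)
            manifest["stages"]["enrich"] = {"outputs": files, "mode": ecfg.get("mode", "ora")}

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        io.write_json(manifest, out / "manifest.json")
        raise
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _run_score_stats(config: RunConfig, out: Path, table) -> dict:
    """Omnibus PERMANOVA per score family, ART-ANOVA + contrasts per score,
    mixed-effects slopes for injury-family scores."""
    scfg = config.score_stats
    families = scfg.get("families") or _default_families(table.scores.columns)
    n_perm = int(scfg.get("permutations", 100_000))
    labels = (table.meta["arm"].astype(str) + "." + table.meta["visit"].astype(str)).to_numpy()

    permanova_rows = []
    for fam, names in families.items():
        sub = table.scores[names]
        res = score_stats.omnibus_permanova(sub, labels, n_perm=n_perm, seed=config.seed)
        permanova_rows.append({"family": fam, "pseudo_F": res.pseudo_f, "p": res.p, "n_perm": res.n_permutations})
    permanova_tab = pd.DataFrame(permanova_rows)

    anova_rows, contrast_frames = [], []
    for fam, names in families.items():
        for name in names:
            result = score_stats.art_anova(table.long(name))
            for effect, row in result.anova.iterrows():
                anova_rows.append({"score": name, "family": fam, "effect": effect, **row.to_dict()})
            ct = score_stats.interaction_contrasts(result)
            ct.insert(0, "score", name)
            ct.insert(1, "family", fam)
            contrast_frames.append(ct)
    anova_tab = pd.DataFrame(anova_rows)
    # FDR on the treatment×visit interaction, within score families
    anova_tab["FDR"] = np.nan
    inter = anova_tab["effect"] == "arm:visit"
    for fam in families:
        m = inter & (anova_tab["family"] == fam)
        if m.any():
            anova_tab.loc[m, "FDR"] = score_stats.bh_fdr(anova_tab.loc[m, "p"].to_numpy())
    contrast_tab = pd.concat(contrast_frames, ignore_index=True)

    slope_rows, traj_frames = [], []
    for name in families.get("injury", []):
        fitted = score_stats.fit_mixed_slopes(table, name)
        for arm, row in fitted.slopes.iterrows():
            slope_rows.append({"score": name, "arm": arm, **row.to_dict(),
                               "interaction_p": fitted.interaction_p, "downgraded": fitted.downgraded})
        traj = fitted.predict()
        traj.insert(0, "score", name)
        traj_frames.append(traj)
    slope_tab = pd.DataFrame(slope_rows)
    if not slope_tab.empty:
        per_score = slope_tab.drop_duplicates("score")[["score", "interaction_p"]]
        fdr = dict(zip(per_score["score"], score_stats.bh_fdr(per_score["interaction_p"].to_numpy())))
        slope_tab["interaction_FDR"] = slope_tab["score"].map(fdr)

    files = {}
    for name, tab in (
        ("permanova", permanova_tab),
        ("art_anova", anova_tab),
        ("art_contrasts", contrast_tab),
        ("slopes", slope_tab),
    ):
        f = out / f"score_stats_{name}.tsv"
        tab.to_csv(f, sep="\t", index=False, float_format="%.6g")
        files[name] = str(f)
    if traj_frames:
        f = out / "score_stats_trajectories.tsv"
        pd.concat(traj_frames, ignore_index=True).to_csv(f, sep="\t", index=False, float_format="%.6g")
        files["trajectories"] = str(f)
    return {"outputs": files, "families": families}
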