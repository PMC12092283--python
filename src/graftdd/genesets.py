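"""Derivation of the rejection-activity gene sets and the injury ontology.

Four gene sets characterizing antibody-mediated rejection (ABMR) activity are
derived from a reference biopsy cohort and an NK/HUVEC cell-profile panel:

* **activity** — the top 20 genes by Spearman correlation with the early-ABMR
  (EABMR) archetype score;
* **IFNγ-inducible activity** — top 100 EABMR-correlated genes (ρ > 0.2)
  whose IFNγ-stimulated HUVEC expression is at least five-fold (log2 5) above
  both NK cells and unstimulated HUVECs;
* **NK-expressed activity** — top 100 EABMR-correlated genes, minus genes with
  HUVEC expression above the panel median (either condition by default), then
  the top 20 by NK-cell expression;
* **endothelial** — top 100 genes by correlation with the fully-developed-ABMR
  (FABMR) score, keeping genes at least four-fold (log2 4) higher in
  unstimulated HUVECs than NK cells.

A separate injury ontology is built from a single-nucleus AKI marker table by
retaining only injury-induced ('New') cell states, one set per state plus a
collated union for enrichment.

All fold filters compare log2 differences and are inclusive at the boundary;
every sort breaks ties by gene_id so outputs are deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellProfilePanel, DegenerateInputError, GeneSet, GeneSetLibrary, ReferenceCohort

logger = logging.getLogger(__name__)

TOP_POOL = 100  # candidate pool size for the filtered derivations
ACTIVITY_SIZE = 20
NK_SET_SIZE = 20
RHO_MIN = 0.2  # Spearman floor for the IFNγ-inducible pool
FOLD_IFNG_LOG2 = np.log2(5.0)
FOLD_ENDO_LOG2 = np.log2(4.0)


def spearman_vs_score(ref: ReferenceCohort, which: str = "eabmr") -> pd.DataFrame:
    """Per-gene Spearman correlation against an archetype score.

    Average ranks handle ties.  The result is sorted by descending rho with
    lexicographic gene_id tie-break and has columns ``rho`` and ``rank``.
    """
    if which == "eabmr":
        score = ref.eabmr_score
    elif which == "fabmr":
        score = ref.fabmr_score
    else:
        raise ValueError(f"which must be 'eabmr' or 'fabmr', got {which!r}")
    if ref.expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    s = score.to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise DegenerateInputError(f"{which} score vector is constant")

    score_ranks = stats.rankdata(s)
    gene_ranks = np.apply_along_axis(stats.rankdata, 1, ref.expr.to_numpy(dtype=float))
    sr = (score_ranks - score_ranks.mean()) / score_ranks.std()
    gr = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    gsd = gene_ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (gr @ sr) / ref.expr.shape[1] / gsd
    rho = np.where(gsd == 0, 0.0, rho)  # constant gene: correlation undefined, report 0

    tab = pd.DataFrame({"rho": rho}, index=ref.expr.index)
    # descending rho, lexicographic gene_id tie-break
    tab = tab.iloc[np.lexsort((tab.index.to_numpy(), -tab["rho"].to_numpy()))]
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def _top_pool(ref: ReferenceCohort, which: str, n: int = TOP_POOL) -> pd.DataFrame:
    tab = spearman_vs_score(ref, which)
    return tab.head(n)


def _require_profiles(panel: CellProfilePanel, genes) -> pd.DataFrame:
    missing = [g for g in genes if g not in panel.profiles.index]
    if missing:
        raise ValueError(f"cell profile panel is missing {len(missing)} genes: {missing[:10]}")
    return panel.profiles.loc[list(genes)]


def derive_abmr_activity_set(ref: ReferenceCohort) -> GeneSet:
    """Top 20 genes by Spearman correlation with the EABMR score."""
    if ref.expr.shape[0] < ACTIVITY_SIZE:
        raise ValueError(f"need at least {ACTIVITY_SIZE} genes")
    tab = spearman_vs_score(ref, "eabmr").head(ACTIVITY_SIZE)
    return GeneSet(
        name="abmr_activity",
        genes=tab.index.tolist(),
        provenance=f"top {ACTIVITY_SIZE} genes by Spearman rho vs EABMR score",
    )


def derive_ifng_inducible_set(
    ref: ReferenceCohort,
    profiles: CellProfilePanel,
    numerator: str = "huvec_ifng",
) -> GeneSet:
    """IFNγ-inducible ABMR-activity genes.

    Pool: top 100 genes by EABMR Spearman rho, restricted to rho > 0.2.  The
    five-fold filter keeps genes whose ``numerator`` HUVEC condition exceeds
    both the NK profile and the other HUVEC condition by at least log2 5
    (default reading: IFNγ-stimulated HUVEC expression five-fold over NK cells
    and over unstimulated HUVECs — inducible and not NK-borne; set
    ``numerator='huvec_unstim'`` for the alternative reading of the rule).
    """
    if numerator not in ("huvec_ifng", "huvec_unstim"):
        raise ValueError("numerator must be 'huvec_ifng' or 'huvec_unstim'")
    pool = _top_pool(ref, "eabmr")
    pool = pool[pool["rho"] > RHO_MIN]
    if pool.empty:
        logger.warning("ifng_inducible: no gene passes rho > %.2f; returning empty set", RHO_MIN)
        return GeneSet(name="ifng_inducible_activity", genes=[], provenance="empty pool (no rho > 0.2)")
    prof = _require_profiles(profiles, pool.index)
    other = "huvec_unstim" if numerator == "huvec_ifng" else "huvec_ifng"
    keep = (prof[numerator] - prof["nk"] >= FOLD_IFNG_LOG2) & (prof[numerator] - prof[other] >= FOLD_IFNG_LOG2)
    genes = pool.index[keep.to_numpy()].tolist()
    if not genes:
        logger.warning("ifng_inducible: no pool gene passes the five-fold HUVEC/NK filter")
    return GeneSet(
        name="ifng_inducible_activity",
        genes=genes,
        provenance=(
            f"top {TOP_POOL} by EABMR rho, rho > {RHO_MIN}, {numerator} >= log2(5) over nk and {other}"
        ),
    )


def derive_nk_expressed_set(
    ref: ReferenceCohort,
    profiles: CellProfilePanel,
    exclude_mode: str = "either",
) -> GeneSet:
    """NK-cell-expressed ABMR-activity genes.

    Pool: top 100 genes by EABMR rho.  Genes whose HUVEC expression exceeds
    the panel's 50th percentile are removed — by default when *either* HUVEC
    condition exceeds its own panel median (``exclude_mode='both'`` requires
    both to exceed), percentiles over the whole panel with linear
    interpolation.  The survivors are cut to the top 20 by NK expression.
    """
    if exclude_mode not in ("either", "both"):
        raise ValueError("exclude_mode must be 'either' or 'both'")
    pool = _top_pool(ref, "eabmr")
    prof_all = profiles.profiles
    med_unstim = float(np.quantile(prof_all["huvec_unstim"].to_numpy(dtype=float), 0.5))
    med_ifng = float(np.quantile(prof_all["huvec_ifng"].to_numpy(dtype=float), 0.5))
    prof = _require_profiles(profiles, pool.index)
    hi_unstim = prof["huvec_unstim"] > med_unstim
    hi_ifng = prof["huvec_ifng"] > med_ifng
    drop = (hi_unstim | hi_ifng) if exclude_mode == "either" else (hi_unstim & hi_ifng)
    surv = prof[~drop.to_numpy()]
    if surv.empty:
        logger.warning("nk_expressed: every pool gene exceeds the HUVEC medians; returning empty set")
        genes: list[str] = []
    else:
        order = np.lexsort((surv.index.to_numpy(), -surv["nk"].to_numpy()))
        genes = surv.index.to_numpy()[order][:NK_SET_SIZE].tolist()
    return GeneSet(
        name="nk_expressed_activity",
        genes=genes,
        provenance=(
            f"top {TOP_POOL} by EABMR rho, drop HUVEC > panel median ({exclude_mode}), "
            f"top {NK_SET_SIZE} by NK expression"
        ),
    )


def derive_endothelial_set(ref: ReferenceCohort, profiles: CellProfilePanel) -> GeneSet:
    """ABMR-associated endothelial genes: top 100 by FABMR rho, keep genes
    four-fold (log2 4, inclusive) higher in unstimulated HUVECs than NK."""
    pool = _top_pool(ref, "fabmr")
    prof = _require_profiles(profiles, pool.index)
    keep = prof["huvec_unstim"] - prof["nk"] >= FOLD_ENDO_LOG2
    genes = pool.index[keep.to_numpy()].tolist()
    return GeneSet(
        name="abmr_endothelial",
        genes=genes,
        provenance=f"top {TOP_POOL} by FABMR rho, huvec_unstim - nk >= log2(4)",
    )


def build_injury_ontology(markers: pd.DataFrame) -> GeneSetLibrary:
    """Injury ontology from an AKI marker table (gene, cell_state, state_class).

    Retains only injury-induced ('New') cell states: one set per state for
    annotation, plus a collated union set (``aki_injury_union``) for
    enrichment.  Duplicate genes across states appear once in the union.
    """
    if markers.empty:
        raise ValueError("marker table is empty")
    lib = GeneSetLibrary()
    new = markers[markers["state_class"] == "New"]
    if new.empty:
        logger.warning("injury ontology: no 'New' cell states in marker table; empty library")
        return lib
    union: list[str] = []
    seen: set[str] = set()
    for state in sorted(new["cell_state"].unique()):
        genes = new.loc[new["cell_state"] == state, "gene"].drop_duplicates().tolist()
        lib.add(GeneSet(name=state, genes=genes, provenance=f"AKI-induced cell state {state}"))
        for g in genes:
            if g not in seen:
                seen.add(g)
                union.append(g)
    lib.add(GeneSet(name="aki_injury_union", genes=union, provenance="union of all 'New' cell-state markers"))
    return lib


def derive_all(
    ref: ReferenceCohort,
    profiles: CellProfilePanel,
    markers: pd.DataFrame | None = None,
    ifng_numerator: str = "huvec_ifng",
    nk_exclude_mode: str = "either",
) -> GeneSetLibrary:
    """Run all derivations and collect them into one library."""
    lib = GeneSetLibrary()
    lib.add(derive_abmr_activity_set(ref))
    lib.add(derive_ifng_inducible_set(ref, profiles, numerator=ifng_numerator))
    lib.add(derive_nk_expressed_set(ref, profiles, exclude_mode=nk_exclude_mode))
    lib.add(derive_endothelial_set(ref, profiles))
    if markers is not None:
        for s in build_injury_ontology(markers):
            lib.add(s)
    return lib
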