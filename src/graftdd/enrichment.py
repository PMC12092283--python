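"""Functional enrichment of differential-expression results.

Two modes against GMT-backed term libraries (including the de novo injury
ontology):

* **over-representation** of cutoff-selected genes (one-sided hypergeometric
  upper tail), optionally split by ΔΔlogFC sign;
* **rank-based set enrichment**: weighted Kolmogorov–Smirnov running-sum
  score over a signed per-gene statistic, gene-permutation null, NES
  normalized by the mean |null ES| of the same sign, permutation p with +1
  smoothing, leading-edge genes up to the running-sum extremum.

FDR is computed within each library separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetLibrary
from .score_stats import bh_fdr

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 5


@dataclass
class EnrichmentResult:
    term: str
    library: str
    k: int  # overlap (or leading-edge size in rank mode)
    K: int  # set size within the universe
    n: int  # selected genes (or 0 in rank mode)
    N: int  # universe size
    p: float
    fdr: float = np.nan
    direction: str = "both"
    es: float = np.nan
    nes: float = np.nan
    leading_edge: list = field(default_factory=list)
    overlap: list = field(default_factory=list)


def _results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "library": r.library,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "ES": r.es,
                "NES": r.nes,
                "p": r.p,
                "FDR": r.fdr,
                "direction": r.direction,
                "genes": ";".join(r.leading_edge or r.overlap),
            }
            for r in results
        ]
    )


def ora_hypergeometric(
    selected,
    universe,
    library: GeneSetLibrary,
    direction: str = "both",
    library_name: str = "library",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per term.

    ``selected`` ⊆ ``universe``; each term is intersected with the universe
    first.  p = P(X ≥ k) for X ~ Hypergeom(N, K, n); BH-FDR across the terms
    of this library.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    sel = list(dict.fromkeys(selected))
    stray = [g for g in sel if g not in uni]
    if stray:
        raise ValueError(f"selected genes outside the universe: {stray[:10]}")
    if not sel:
        logger.warning("ora: empty selection; returning no results")
        return []
    sel_set = set(sel)
    N, n = len(uni), len(sel)
    results = []
    for gs in library:
        members = [g for g in gs.genes if g in uni]
        K = len(members)
        if K == 0:
            continue
        overlap = [g for g in members if g in sel_set]
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term=gs.name, library=library_name, k=k, K=K, n=n, N=N, p=min(p, 1.0),
                direction=direction, overlap=overlap,
            )
        )
    if results:
        q = bh_fdr([r.p for r in results])
        for r, f in zip(results, q):
            r.fdr = float(f)
    return results


def _running_es(ranked_genes: np.ndarray, weights: np.ndarray, member: np.ndarray):
    """Running-sum enrichment score.

    ``member`` is a boolean mask over the ranking; hit steps are proportional
    to |stat|^weight (uniform when all weights equal), miss steps are
    −1/(N − K).  Returns (ES, running curve, extremum index).
    """
    N = len(ranked_genes)
    K = int(member.sum())
    hit_w = np.where(member, weights, 0.0)
    total = hit_w.sum()
    if total <= 0:
        hit_w = member.astype(float)
        total = hit_w.sum()
    steps = np.where(member, hit_w / total, -1.0 / (N - K))
    curve = np.cumsum(steps)
    i_max = int(np.argmax(curve))
    i_min = int(np.argmin(curve))
    es = curve[i_max] if curve[i_max] >= -curve[i_min] else curve[i_min]
    i_ext = i_max if curve[i_max] >= -curve[i_min] else i_min
    return float(es), curve, i_ext


def gsea_rank(
    stat: pd.Series,
    library: GeneSetLibrary,
    n_perm: int = 999,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = MIN_SET_SIZE,
    library_name: str = "library",
) -> list[EnrichmentResult]:
    """Weighted KS rank enrichment with a gene-permutation null.

    Genes are ordered by decreasing ``stat``; hit increments are
    |stat|^weight.  NES = ES / mean(|null ES| of the same sign); p is the
    same-sign permutation tail with +1 smoothing; the leading edge contains
    the member genes at or before the running-sum extremum (after it for
    negative ES).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    s = stat.dropna()
    if not np.all(np.isfinite(s.to_numpy(dtype=float))):
        raise ValueError("statistic must be finite")
    order = np.lexsort((s.index.to_numpy(), -s.to_numpy(dtype=float)))
    genes = s.index.to_numpy()[order]
    vals = s.to_numpy(dtype=float)[order]
    weights = np.abs(vals) ** weight if weight > 0 else np.ones_like(vals)
    N = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    results = []
    for gs in library:
        members = [g for g in gs.genes if g in pos]
        K = len(members)
        if K < min_size or K >= N:
            continue
        mask = np.zeros(N, dtype=bool)
        mask[[pos[g] for g in members]] = True
        es, curve, i_ext = _running_es(genes, weights, mask)
        if es >= 0:
            le = [g for g in genes[: i_ext + 1] if mask[pos[g]]]
        else:
            le = [g for g in genes[i_ext:] if mask[pos[g]]]

        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_idx = rng.choice(N, size=K, replace=False)
            m = np.zeros(N, dtype=bool)
            m[perm_idx] = True
            null_es[b], _, _ = _running_es(genes, weights, m)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        if es >= 0:
            extreme = np.sum(null_es[same_sign] >= es - 1e-12)
        else:
            extreme = np.sum(null_es[same_sign] <= es + 1e-12)
        p = float((1 + extreme) / (1 + int(same_sign.sum())))
        results.append(
            EnrichmentResult(
                term=gs.name, library=library_name, k=len(le), K=K, n=0, N=N,
                p=min(p, 1.0), es=es, nes=float(nes), leading_edge=le,
            )
        )
    if results:
        q = bh_fdr([r.p for r in results])
        for r, f in zip(results, q):
            r.fdr = float(f)
    return results


def summarize_enrichment(
    results: list[EnrichmentResult],
    top_gene_budget: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Rank genes by how many enriched terms carry them.

    A term counts when its FDR < threshold; a gene belongs to a term through
    its leading edge (rank mode) or overlap (cutoff mode).  Ties break by the
    gene's best (smallest) term FDR, then lexicographically.
    """
    if not results:
        raise ValueError("no enrichment results to summarize")
    counts: dict[str, int] = {}
    best: dict[str, float] = {}
    for r in results:
        if not (r.fdr < fdr_threshold):
            continue
        for g in r.leading_edge or r.overlap:
            counts[g] = counts.get(g, 0) + 1
            best[g] = min(best.get(g, np.inf), r.fdr)
    rows = [{"gene": g, "n_terms": c, "best_fdr": best[g]} for g, c in counts.items()]
    tab = pd.DataFrame(rows, columns=["gene", "n_terms", "best_fdr"])
    if tab.empty:
        return tab
    tab = tab.sort_values(["n_terms", "best_fdr", "gene"], ascending=[False, True, True], kind="mergesort")
    return tab.head(top_gene_budget).reset_index(drop=True)


def enrich_contrast_table(
    table: pd.DataFrame,
    library: GeneSetLibrary,
    mode: str = "ora",
    alpha: float = 0.05,
    exclude_flagged: bool = True,
    library_name: str = "library",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrich one ΔΔ contrast table (cutoff mode p < alpha, or rank mode).

    The output frame's ``mode`` attribute records which mode produced it.
    """
    t = table[~table["baseline_imbalance_flag"]] if exclude_flagged else table
    if mode == "ora":
        universe = t.index.tolist()
        results = []
        for direction, sub in (("down", t[(t["p"] < alpha) & (t["ddfc"] < 0)]),
                               ("up", t[(t["p"] < alpha) & (t["ddfc"] > 0)])):
            if len(sub) == 0:
                logger.warning("ora: no %s-regulated genes at p < %g", direction, alpha)
                continue
            results.extend(
                ora_hypergeometric(sub.index.tolist(), universe, library,
                                   direction=direction, library_name=library_name)
            )
    elif mode == "rank":
        results = gsea_rank(t["t"], library, n_perm=n_perm, seed=seed, library_name=library_name)
    else:
        raise ValueError("mode must be 'ora' or 'rank'")
    out = _results_frame(results)
    out.attrs["mode"] = mode
    return out
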