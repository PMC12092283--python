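"""Per-biopsy gene-set scores (pathogenesis-based transcript style).

A biopsy's score for a gene set is the arithmetic mean, over the member genes
present in the matrix, of its log2 expression minus a per-gene control mean —
the log of the geometric-mean fold change versus control.  When no control
reference is supplied, genes are centered on the cohort mean, so scores
express deviation from the cohort average instead of from an external
baseline.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import ExpressionMatrix, GeneSetLibrary, GeneSet, ScoreTable

logger = logging.getLogger(__name__)


def score_geneset(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    control: pd.Series | None = None,
) -> pd.Series:
    """Score every sample for one gene set.

    ``control`` is an optional per-gene control mean (log2) aligned by
    gene_id; absent member genes are dropped with a warning, zero overlap is
    an error naming the set.
    """
    present = [g for g in gene_set.genes if g in expr.values.index]
    absent = [g for g in gene_set.genes if g not in expr.values.index]
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the expression matrix")
    if absent:
        logger.warning("gene set %r: %d member genes absent from matrix: %s%s",
                       gene_set.name, len(absent), absent[:5], "..." if len(absent) > 5 else "")
    sub = expr.values.loc[present]
    if control is not None:
        missing = [g for g in present if g not in control.index]
        if missing:
            raise ValueError(f"control reference missing genes: {missing[:10]}")
        centered = sub.sub(control.loc[present], axis=0)
    else:
        centered = sub.sub(sub.mean(axis=1), axis=0)
    score = centered.mean(axis=0)
    score.name = gene_set.name
    return score


def assemble_score_table(
    expr: ExpressionMatrix,
    library: GeneSetLibrary,
    control: pd.Series | None = None,
) -> ScoreTable:
    """One score column per library set, in library order, joined to metadata."""
    if len(library) == 0:
        raise ValueError("gene-set library is empty")
    cols = {s.name: score_geneset(expr, s, control) for s in library}
    scores = pd.DataFrame(cols, index=expr.sample_ids)[library.names]
    return ScoreTable(scores, expr.meta.copy())
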