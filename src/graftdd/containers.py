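"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on a log2-normalized gene×sample expression matrix with
per-biopsy metadata (patient, treatment arm, follow-up visit, estimated
cortical fraction of the biopsy core), gene-set libraries, and per-biopsy
molecular score tables.  Containers are thin dataclasses over pandas objects;
validation happens at construction so downstream code can assume invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARMS = ("placebo", "felzartamab")
VISITS = ("baseline", "week24", "week52")
#: follow-up visit → weeks since trial start
VISIT_WEEKS = {"baseline": 0.0, "week24": 24.0, "week52": 52.0}
#: the three difference-in-differences windows, in reporting order
DD_WINDOWS = ("b_w24", "w24_w52", "b_w52")
#: window → (later visit, earlier visit)
DD_WINDOW_VISITS = {
    "b_w24": ("week24", "baseline"),
    "w24_w52": ("week52", "week24"),
    "b_w52": ("week52", "baseline"),
}

META_COLUMNS = ("patient_id", "arm", "visit", "pct_cortex")


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but statistically degenerate
    (constant score vector, zero residual variance everywhere, ...)."""


def validate_meta(meta: pd.DataFrame, require_complete: bool = False) -> pd.DataFrame:
    """Validate a sample-metadata frame (index = sample_id).

    Checks column presence, arm/visit levels, pct_cortex range, uniqueness of
    (patient, visit) and arm consistency per patient.  With
    ``require_complete`` every patient must have all three visits.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad_arm = set(meta["arm"]) - set(ARMS)
    if bad_arm:
        raise ValueError(f"unknown arm levels: {sorted(bad_arm)}")
    bad_visit = set(meta["visit"]) - set(VISITS)
    if bad_visit:
        raise ValueError(f"unknown visit levels: {sorted(bad_visit)}")
    pc = meta["pct_cortex"].to_numpy(dtype=float)
    if not np.all(np.isfinite(pc)) or pc.min() < 0 or pc.max() > 100:
        raise ValueError("pct_cortex must be finite and in [0, 100]")
    if meta.duplicated(subset=["patient_id", "visit"]).any():
        raise ValueError("more than one sample for the same (patient, visit)")
    arms_per_patient = meta.groupby("patient_id")["arm"].nunique()
    if (arms_per_patient > 1).any():
        raise ValueError("a patient appears in more than one arm")
    if require_complete:
        visits = meta.groupby("patient_id")["visit"].nunique()
        if (visits != len(VISITS)).any():
            raise ValueError("incomplete visit set for at least one patient")
    return meta


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes × samples) plus sample metadata.

    ``values``: DataFrame indexed by gene_id, columns = sample_id, finite.
    ``meta``: DataFrame indexed by sample_id with patient_id, arm, visit,
    pct_cortex.  Column order of ``values`` and row order of ``meta`` match.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene_id")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample_id")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite (no NaN/Inf)")
        validate_meta(self.meta)
        if set(self.meta.index) != set(self.values.columns):
            raise ValueError("metadata samples do not match expression columns")
        # keep meta aligned to the column order of the matrix
        self.meta = self.meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.meta.copy())


@dataclass
class ReferenceCohort:
    """Reference biopsy cohort with per-sample rejection-archetype scores.

    ``eabmr_score``/``fabmr_score`` are early/fully-developed antibody-mediated
    rejection archetype scores in [0, 1], one per sample, used as correlation
    anchors when deriving gene sets.
    """

    expr: pd.DataFrame  # genes × samples, log2
    eabmr_score: pd.Series  # index = sample_id
    fabmr_score: pd.Series

    def __post_init__(self) -> None:
        for name, s in (("eabmr_score", self.eabmr_score), ("fabmr_score", self.fabmr_score)):
            if len(s) != self.expr.shape[1]:
                raise ValueError(f"{name} length != number of samples")
            if not np.all(np.isfinite(s.to_numpy(dtype=float))):
                raise ValueError(f"{name} must be finite")
        self.eabmr_score = self.eabmr_score.loc[self.expr.columns]
        self.fabmr_score = self.fabmr_score.loc[self.expr.columns]


@dataclass
class CellProfilePanel:
    """Per-gene log2 summary expression in NK cells and HUVECs.

    Columns: ``nk`` (natural-killer cells), ``huvec_unstim`` (unstimulated
    endothelial cells), ``huvec_ifng`` (IFNγ-stimulated endothelial cells).
    Used as cell-selectivity filters during gene-set derivation.
    """

    profiles: pd.DataFrame  # index gene_id; columns nk, huvec_unstim, huvec_ifng

    COLUMNS = ("nk", "huvec_unstim", "huvec_ifng")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.profiles.columns]
        if missing:
            raise ValueError(f"cell profile panel missing columns: {missing}")
        arr = self.profiles[list(self.COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("cell profiles must be finite")
        if self.profiles.index.duplicated().any():
            raise ValueError("duplicate gene_id in cell profile panel")


@dataclass
class GeneSet:
    """A named, ordered, duplicate-free gene list with derivation provenance."""

    name: str
    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetLibrary:
    """Ordered collection of uniquely named gene sets, GMT-backed."""

    sets: list[GeneSet] = field(default_factory=list)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names in library")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.names:
            raise ValueError(f"duplicate gene-set name {gene_set.name!r}")
        self.sets.append(gene_set)


@dataclass
class ScoreTable:
    """Per-biopsy molecular scores (rows = sample_id) with linked metadata."""

    scores: pd.DataFrame  # index sample_id, columns score names
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate score names")
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate sample_id in score table")
        arr = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("scores must be finite")
        validate_meta(self.meta)
        if set(self.meta.index) != set(self.scores.index):
            raise ValueError("score table samples do not match metadata")
        self.meta = self.meta.loc[self.scores.index]

    def long(self, score: str) -> pd.DataFrame:
        """One score joined with metadata, plus a ``week`` column."""
        if score not in self.scores.columns:
            raise KeyError(score)
        df = self.meta.copy()
        df["score"] = self.scores[score]
        df["week"] = df["visit"].map(VISIT_WEEKS)
        return df
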