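"""Consensus vote-count filter over multi-platform miRNA target predictions.

Target-prediction algorithms disagree heavily; a standard noise filter keeps
only genes predicted by at least ``min_votes`` of the 12 platforms queried
through the miRWalk aggregator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = (
    "miRanda", "Microt4", "miRWalk", "miRDB", "miRbridge", "miRMap",
    "Pictar2", "miRNAMap", "PITA", "RNAhybrid", "RNA22", "Targetscan",
)


class SchemaError(ValueError):
    pass


@dataclass
class PredictionMatrix:
    """Binary gene x platform indicator matrix (exactly 12 platforms)."""

    genes: list[str]
    platforms: tuple[str, ...]
    votes: np.ndarray  # shape (n_genes, 12), values in {0, 1}

    def __post_init__(self) -> None:
        if len(self.platforms) != 12:
            raise SchemaError(
                f"expected 12 platform columns, got {len(self.platforms)}")
        self.votes = np.asarray(self.votes)
        if self.votes.shape != (len(self.genes), 12):
            raise SchemaError("votes shape does not match genes x platforms")
        if not np.isin(self.votes, (0, 1)).all():
            raise SchemaError("vote indicators must be 0/1")
        if len(set(self.genes)) != len(self.genes):
            raise SchemaError("gene identifiers must be unique")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *,
                   gene_column: str = "gene") -> "PredictionMatrix":
        """Build from a table of gene + 12 binary columns.

        Any non-empty / non-zero entry counts as a prediction. Duplicate
        gene rows (e.g. one row per transcript) are OR-merged with a
        logged warning.
        """
        if gene_column not in df.columns:
            raise SchemaError(f"missing gene column {gene_column!r}")
        plat_cols = [c for c in df.columns if c != gene_column]
        if len(plat_cols) != 12:
            raise SchemaError(f"expected 12 platform columns, got {len(plat_cols)}")
        def is_vote(x) -> int:
            if pd.isna(x) or x == "" or x == 0 or x == "0":
                return 0
            return 1

        votes = df[plat_cols].map(is_vote)
        votes.index = df[gene_column].astype(str)
        if votes.index.has_duplicates:
            n_dupes = int(votes.index.duplicated().sum())
            logger.warning("OR-merging %d duplicated gene rows", n_dupes)
            votes = votes.groupby(level=0, sort=False).max()
        return cls(genes=list(votes.index), platforms=tuple(plat_cols),
                   votes=votes.to_numpy())

    @classmethod
    def read_tsv(cls, path, **kw) -> "PredictionMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"), **kw)


def vote_count_targets(m: PredictionMatrix, min_votes: int = 8) -> pd.DataFrame:
    """Genes supported by at least ``min_votes`` of the 12 platforms.

    Returns a frame of (gene, votes) sorted by descending votes, then
    lexicographic gene symbol — deterministic for a given matrix.
    """
    if not 0 <= min_votes <= 12:
        raise ValueError("min_votes must lie in [0, 12]")
    totals = m.votes.sum(axis=1)
    out = pd.DataFrame({"gene": m.genes, "votes": totals})
    out = out[out["votes"] >= min_votes]
    out = out.sort_values(["votes", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return out
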