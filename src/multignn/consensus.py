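"""Consensus vote-scoring for virtual-screening candidates.

Each criterion (docking score, per-model predicted pIC50, ...) awards one
point to every candidate ranking in its top 50%: with N candidates the top
k = ceil(N/2) scores vote 1, and candidates tying the k-th best score are
promoted with it, so boundary ties can push the voted count above k. A
per-candidate multi-target flag (0/1, supplied as input) is added to the row
sum to give the total vote score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["VoteTable", "vote_points", "total_votes", "load_screening_table"]


@dataclass
class VoteTable:
    """Per-candidate points matrix, flags, and total vote scores."""

    candidates: list[str]
    criteria: list[str]
    points: pd.DataFrame               # candidates x criteria, 0/1
    multi_target: pd.Series            # 0/1 per candidate
    totals: pd.Series                  # integer per candidate

    def ranked(self) -> pd.DataFrame:
        """Candidates sorted by total score descending, stable by input order."""
        out = self.points.copy()
        out["multi_target"] = self.multi_target
        out["total"] = self.totals
        return out.sort_values("total", ascending=False, kind="stable")


def vote_points(scores, higher_is_better: bool = True) -> np.ndarray:
    """0/1 votes for the top half of a criterion's scores (ties promoted)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1-D vector")
    if np.isnan(scores).any():
        raise ValueError("missing score in criterion column")
    n = scores.size
    k = math.ceil(n / 2)
    ranked = np.sort(scores)[::-1] if higher_is_better else np.sort(scores)
    threshold = ranked[k - 1]
    votes = scores >= threshold if higher_is_better else scores <= threshold
    return votes.astype(np.int64)


def total_votes(scores: pd.DataFrame, multi_target=None,
                higher_is_better: bool | dict = True) -> VoteTable:
    """Vote every criterion column and sum points plus the multi-target flag.

    ``scores`` has one row per candidate (index = candidate id) and one
    numeric column per criterion. ``higher_is_better`` may be a single flag
    or a per-criterion dict.
    """
    if scores.isna().any().any():
        raise ValueError("missing score in criterion column")
    candidates = [str(i) for i in scores.index]
    if multi_target is None:
        flags = pd.Series(0, index=scores.index)
    else:
        flags = pd.Series(np.asarray(multi_target, dtype=np.int64),
                          index=scores.index)
        if len(flags) != len(scores):
            raise ValueError("multi_target flags length mismatch")
    points = {}
    for criterion in scores.columns:
        hib = (higher_is_better if isinstance(higher_is_better, bool)
               else higher_is_better[criterion])
        points[criterion] = vote_points(scores[criterion].to_numpy(), hib)
    points_frame = pd.DataFrame(points, index=scores.index)
    totals = points_frame.sum(axis=1) + flags
    return VoteTable(candidates=candidates, criteria=list(scores.columns),
                     points=points_frame, multi_target=flags, totals=totals)


def load_screening_table() -> tuple[pd.DataFrame, pd.Series]:
    """Bundled example: the ten top-ranked ZINC candidates against DHODH.

    Returns the criterion score table (docking score plus the five
    model-predicted pIC50 columns) and the multi-target flags derived from
    the compound-target docking network.
    """
    path = resources.files("multignn.data") / "zinc_top10_screening.csv"
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, index_col="id")
    flags = frame.pop("multi_target")
    return frame, flags
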