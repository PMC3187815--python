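"""Environment-keyword neighbor counting.

For each query, every record of an annotated sequence database (EMBL-style
free-text descriptions) is globally aligned and a record is a *valid
neighbor* when its percent similarity STRICTLY exceeds the threshold
(default 95%).  Valid neighbors are then screened for environment
keywords: "uranium" or "radionuclide" flags a uranium-associated record,
"iron" an iron-associated one.  The output mirrors the structure of a
per-clone neighbor table: number of valid neighbors annotated with
uranium, number annotated with iron.

Note the boundary asymmetry with the taxonomy classifier: neighbor
validity is strict (> 95), ladder retention is inclusive (>= 99).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .seqcore import AlignParams, Seq, all_vs_refs

#: keyword groups: flag name -> substrings that raise it
DEFAULT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "uranium": ("uranium", "radionuclide"),
    "iron": ("iron",),
}


def keyword_flags(annotation: str, keywords: Iterable[str]) -> dict[str, bool]:
    """Case-insensitive plain-substring presence of each keyword.

    No stemming or word-boundary logic: "iron" matches "irons" but not
    "environment" (which has no literal "iron" substring).
    """
    keywords = list(keywords)
    if not keywords:
        raise ValueError("keyword set is empty")
    text = annotation.lower()
    return {kw: kw.lower() in text for kw in keywords}


def _group_flags(
    annotation: str, groups: Mapping[str, Sequence[str]] = DEFAULT_KEYWORDS
) -> dict[str, bool]:
    flat = [kw for kws in groups.values() for kw in kws]
    hits = keyword_flags(annotation, flat)
    return {flag: any(hits[kw] for kw in kws) for flag, kws in groups.items()}


@dataclass(frozen=True)
class AnnotatedRecord:
    """A database sequence with its free-text annotation and derived flags."""

    seq: Seq
    annotation: str
    has_uranium: bool = field(init=False)
    has_iron: bool = field(init=False)

    def __post_init__(self) -> None:
        flags = _group_flags(self.annotation)
        object.__setattr__(self, "has_uranium", flags["uranium"])
        object.__setattr__(self, "has_iron", flags["iron"])


@dataclass(frozen=True)
class NeighborCounts:
    query_id: str
    n_valid_neighbors: int
    n_with_uranium: int
    n_with_iron: int
    threshold: float
    closest_relative_id: str = ""
    closest_similarity: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.n_with_uranium <= self.n_valid_neighbors):
            raise ValueError("uranium count outside [0, n_valid_neighbors]")
        if not (0 <= self.n_with_iron <= self.n_valid_neighbors):
            raise ValueError("iron count outside [0, n_valid_neighbors]")


def count_neighbors(
    query: Seq,
    db: Sequence[AnnotatedRecord],
    threshold: float = 95.0,
    params: AlignParams | None = None,
) -> NeighborCounts:
    """Count annotated records whose similarity strictly exceeds ``threshold``.

    A record at exactly the threshold is NOT a valid neighbor.
    """
    db = list(db)
    if not db:
        raise ValueError("annotated database is empty")
    by_id = {rec.seq.id: rec for rec in db}
    if len(by_id) != len(db):
        raise ValueError("duplicate record ids in annotated database")
    hits = all_vs_refs(query, [rec.seq for rec in db], params)
    valid = [h for h in hits if h.similarity > threshold]
    n_u = sum(1 for h in valid if by_id[h.ref_id].has_uranium)
    n_fe = sum(1 for h in valid if by_id[h.ref_id].has_iron)
    best = hits[0]
    return NeighborCounts(
        query_id=query.id,
        n_valid_neighbors=len(valid),
        n_with_uranium=n_u,
        n_with_iron=n_fe,
        threshold=threshold,
        closest_relative_id=best.ref_id,
        closest_similarity=best.similarity,
    )


def neighbor_table(
    queries: Iterable[Seq],
    db: Sequence[AnnotatedRecord],
    threshold: float = 95.0,
    params: AlignParams | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row of neighbor counts per query, input order preserved.

    ``taxonomy`` optionally maps query ids to a lineage string shown in
    the output (e.g. from the consensus classifier).  Per-query failures
    are flagged in the ``note`` column and the run continues.
    """
    rows = []
    for query in queries:
        try:
            c = count_neighbors(query, db, threshold, params)
            rows.append(
                {
                    "query_id": c.query_id,
                    "closest_relative_id": c.closest_relative_id,
                    "similarity": c.closest_similarity,
                    "taxonomy": (taxonomy or {}).get(c.query_id, ""),
                    "n_valid_neighbors": c.n_valid_neighbors,
                    "n_uranium": c.n_with_uranium,
                    "n_iron": c.n_with_iron,
                    "note": "",
                }
            )
        except Exception as exc:
            rows.append(
                {
                    "query_id": query.id,
                    "closest_relative_id": "",
                    "similarity": np.nan,
                    "taxonomy": "",
                    "n_valid_neighbors": 0,
                    "n_uranium": 0,
                    "n_iron": 0,
                    "note": str(exc),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "closest_relative_id",
            "similarity",
            "taxonomy",
            "n_valid_neighbors",
            "n_uranium",
            "n_iron",
            "note",
        ],
    )


def render_zero_as_dash(table: pd.DataFrame) -> pd.DataFrame:
    """Output dialect: zero neighbor counts are rendered as "-".

    Internal representation stays integer; this is an I/O concern only.
    """
    out = table.copy()
    for col in ("n_valid_neighbors", "n_uranium", "n_iron"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "-" if v == 0 else str(int(v)))
    return out


class EnvironmentNeighborCounter(BaseEstimator, TransformerMixin):
    """Count similar database records annotated with environment keywords.

    ``fit`` stores the annotated database; ``transform`` returns the
    per-query neighbor-count table.

    Parameters
    ----------
    threshold:
        Percent-similarity cutoff; strictly-greater comparison.
    pool_radionuclide:
        If True (default) "radionuclide" hits count toward the uranium
        column; if False only the bare "uranium" keyword does.
    """

    def __init__(
        self,
        threshold: float = 95.0,
        pool_radionuclide: bool = True,
        mismatch_cost: float = 1.0,
        gap_open_cost: float = 1.0,
        gap_extend_cost: float = 1.0,
        match_cost: float = 0.0,
    ):
        self.threshold = threshold
        self.pool_radionuclide = pool_radionuclide
        self.mismatch_cost = mismatch_cost
        self.gap_open_cost = gap_open_cost
        self.gap_extend_cost = gap_extend_cost
        self.match_cost = match_cost

    def fit(self, X: Sequence[AnnotatedRecord | tuple[Seq, str]], y=None):
        X = list(X)
        if not X:
            raise ValueError("annotated database is empty")
        records = []
        for item in X:
            if isinstance(item, AnnotatedRecord):
                seq, annotation = item.seq, item.annotation
            else:
                seq, annotation = item
            rec = AnnotatedRecord(seq=seq, annotation=annotation)
            if not self.pool_radionuclide:
                u = keyword_flags(rec.annotation, ["uranium"])["uranium"]
                object.__setattr__(rec, "has_uranium", u)
            records.append(rec)
        self.db_ = records
        return self

    def transform(
        self, X: Sequence[Seq], taxonomy: Mapping[str, str] | None = None
    ) -> pd.DataFrame:
        if not hasattr(self, "db_"):
            raise ValueError("counter is not fitted; call fit first")
        params = AlignParams(
            mismatch_cost=self.mismatch_cost,
            gap_open_cost=self.gap_open_cost,
            gap_extend_cost=self.gap_extend_cost,
            match_cost=self.match_cost,
        )
        return neighbor_table(X, self.db_, self.threshold, params, taxonomy)
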