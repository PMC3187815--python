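"""Step-wise threshold-ladder consensus-taxonomy classification.

Each query is globally aligned against every reference; the similarity
ladder 99, 98.5, 98, 97.5, 97, 96, 95, 94, 93, 92, 91, 90, 85, 80 is then
walked from the top.  At the first threshold that retains at least one
hit (similarity >= threshold, inclusive) the consensus taxonomy of the
retained hits is reported: the deepest rank on which *all* hits agree.
If hits conflict already at phylum, the consensus is just the domain
("Bacteria"); if no hit survives even 80%, the query is unassigned.

This replaces local-alignment (BLAST-style) assignment: because the
similarity is computed on a true global alignment, partial matches and
terminal gaps count against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .seqcore import (
    AlignParams,
    Seq,
    SimilarityHit,
    all_vs_refs,
)

#: canonical rank ladder, domain -> species
CANONICAL_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: default similarity thresholds, in percent, walked from highest to lowest
DEFAULT_THRESHOLDS = (
    99.0, 98.5, 98.0, 97.5, 97.0, 96.0, 95.0, 94.0,
    93.0, 92.0, 91.0, 90.0, 85.0, 80.0,
)

UNASSIGNED_LABEL = "Unassigned"


@dataclass(frozen=True)
class Lineage:
    """An ordered ranked taxonomy path; may terminate early (partial depth).

    ``ranks`` is a tuple of (rank_name, taxon_name) pairs following the
    canonical ladder domain > phylum > ... > species.  Partial lineages
    (e.g. Silva clone lineages that stop at an informal group name) simply
    stop at the last provided rank.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("lineage must contain at least the domain rank")
        if len(self.ranks) > len(CANONICAL_RANKS):
            raise ValueError("lineage deeper than the canonical rank ladder")
        for (rank, name), expected in zip(self.ranks, CANONICAL_RANKS):
            if rank != expected:
                raise ValueError(
                    f"rank order must follow {CANONICAL_RANKS}; got {rank!r} "
                    f"where {expected!r} expected"
                )
            if not name:
                raise ValueError("empty taxon name in lineage")

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "Lineage":
        if len(names) > len(CANONICAL_RANKS):
            raise ValueError(
                f"lineage of depth {len(names)} exceeds the canonical ladder"
            )
        return cls(tuple(zip(CANONICAL_RANKS, names)))

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "Lineage":
        """Parse a semicolon-joined lineage, e.g. Silva-style
        ``Bacteria;Proteobacteria;Deltaproteobacteria;...;Geobacter``."""
        names = [n.strip() for n in text.split(sep) if n.strip()]
        return cls.from_names(names)

    def to_string(self, sep: str = ";") -> str:
        return sep.join(name for _, name in self.ranks)

    @property
    def depth(self) -> int:
        return len(self.ranks)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.ranks)

    def name_at(self, rank: str) -> str | None:
        for r, n in self.ranks:
            if r == rank:
                return n
        return None


@dataclass(frozen=True)
class ThresholdLadder:
    """Strictly decreasing similarity cutoffs in (0, 100], in percent."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        ts = self.thresholds
        if not ts:
            raise ValueError("ladder must contain at least one threshold")
        if any(not (0 < t <= 100) for t in ts):
            raise ValueError("thresholds must lie in (0, 100]")
        if any(b >= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly decreasing")

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass
class ReferenceDB:
    """Reference sequences paired with their lineages, keyed by id."""

    records: dict[str, tuple[Seq, Lineage]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference database is empty")
        for rid, (seq, lineage) in self.records.items():
            if seq.id != rid:
                raise ValueError(f"record key {rid!r} != sequence id {seq.id!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[Seq, Lineage]]) -> "ReferenceDB":
        records: dict[str, tuple[Seq, Lineage]] = {}
        for seq, lineage in pairs:
            if seq.id in records:
                raise ValueError(f"duplicate reference id {seq.id!r}")
            records[seq.id] = (seq, lineage)
        return cls(records)

    def sequences(self) -> list[Seq]:
        return [seq for seq, _ in self.records.values()]

    def lineage(self, ref_id: str) -> Lineage:
        return self.records[ref_id][1]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Assignment:
    """Consensus taxonomy for one query plus the threshold that resolved it."""

    query_id: str
    consensus: Lineage | None
    resolved_threshold: float | None
    supporting_hits: list[SimilarityHit]
    status: str  # "assigned" | "unassigned"

    @property
    def best_hit(self) -> SimilarityHit | None:
        return self.supporting_hits[0] if self.supporting_hits else None

    def consensus_string(self) -> str:
        if self.consensus is None:
            return UNASSIGNED_LABEL
        return self.consensus.to_string()


def hits_at_threshold(hits: Iterable[SimilarityHit], t: float) -> list[SimilarityHit]:
    """Hits with similarity >= t (inclusive boundary)."""
    if not (0 < t <= 100):
        raise ValueError(f"threshold must be in (0, 100], got {t}")
    return [h for h in hits if h.similarity >= t]


def consensus_lineage(lineages: Sequence[Lineage]) -> Lineage:
    """Longest common prefix of the lineages along the canonical ladder.

    The consensus is over hits (a multiset), not unique taxa, and cannot
    descend past the depth of the shallowest participant.  Conflict at
    phylum leaves only the domain.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("cannot take consensus of zero lineages")
    common: list[tuple[str, str]] = []
    for level in zip(*(lin.ranks for lin in lineages)):
        names = {name for _, name in level}
        if len(names) != 1:
            break
        common.append(level[0])
    if not common:
        # lineages disagreeing even at domain: keep the shared ladder root
        raise ValueError("lineages share no common domain")
    return Lineage(tuple(common))


def classify(
    query: Seq,
    db: ReferenceDB,
    ladder: ThresholdLadder | None = None,
    params: AlignParams | None = None,
) -> Assignment:
    """Assign a consensus taxonomy to one query by walking the ladder.

    All similarities are computed once; the ladder is walked from the
    highest threshold, and the first non-empty hit set decides the
    assignment.
    """
    if ladder is None:
        ladder = ThresholdLadder()
    hits = all_vs_refs(query, db.sequences(), params)
    return classify_from_hits(query.id, hits, db, ladder)


def classify_from_hits(
    query_id: str,
    hits: Sequence[SimilarityHit],
    db: ReferenceDB,
    ladder: ThresholdLadder,
) -> Assignment:
    """Ladder walk given a precomputed similarity vector (pure function)."""
    for t in ladder:
        retained = hits_at_threshold(hits, t)
        if retained:
            consensus = consensus_lineage([db.lineage(h.ref_id) for h in retained])
            return Assignment(
                query_id=query_id,
                consensus=consensus,
                resolved_threshold=t,
                supporting_hits=list(retained),
                status="assigned",
            )
    return Assignment(
        query_id=query_id,
        consensus=None,
        resolved_threshold=None,
        supporting_hits=[],
        status="unassigned",
    )


def classify_batch(
    queries: Iterable[Seq],
    db: ReferenceDB,
    ladder: ThresholdLadder | None = None,
    params: AlignParams | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify queries in input order; per-query failures become flagged
    rows (status "failed") instead of aborting the batch.

    Returns the assignment table and a per-phylum count over assigned rows.
    """
    if ladder is None:
        ladder = ThresholdLadder()
    rows = []
    seen_ids: set[str] = set()
    for query in queries:
        if query.id in seen_ids:
            rows.append(
                {
                    "query_id": query.id,
                    "status": "failed",
                    "resolved_threshold": np.nan,
                    "consensus": "",
                    "n_supporting_hits": 0,
                    "best_hit_id": "",
                    "best_similarity": np.nan,
                    "note": "duplicate query id",
                }
            )
            continue
        seen_ids.add(query.id)
        try:
            a = classify(query, db, ladder, params)
        except Exception as exc:  # keep the batch going
            rows.append(
                {
                    "query_id": query.id,
                    "status": "failed",
                    "resolved_threshold": np.nan,
                    "consensus": "",
                    "n_supporting_hits": 0,
                    "best_hit_id": "",
                    "best_similarity": np.nan,
                    "note": str(exc),
                }
            )
            continue
        best = a.best_hit
        rows.append(
            {
                "query_id": a.query_id,
                "status": a.status,
                "resolved_threshold": (
                    a.resolved_threshold if a.resolved_threshold is not None else np.nan
                ),
                "consensus": a.consensus_string() if a.status == "assigned" else UNASSIGNED_LABEL,
                "n_supporting_hits": len(a.supporting_hits),
                "best_hit_id": best.ref_id if best else "",
                "best_similarity": best.similarity if best else np.nan,
                "note": "",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "status",
            "resolved_threshold",
            "consensus",
            "n_supporting_hits",
            "best_hit_id",
            "best_similarity",
            "note",
        ],
    )
    phyla = []
    for _, row in table.iterrows():
        if row["status"] != "assigned":
            continue
        names = [n for n in row["consensus"].split(";") if n]
        phyla.append(names[1] if len(names) > 1 else UNASSIGNED_LABEL + "_phylum")
    summary = pd.Series(phyla, dtype="object").value_counts().sort_index()
    summary.name = "n_queries"
    return table, summary


class ConsensusTaxonomyClassifier(BaseEstimator):
    """Threshold-ladder consensus taxonomy classifier.

    scikit-learn style estimator: ``fit`` stores the reference database,
    ``predict`` returns semicolon-joined consensus lineages (the string
    ``"Unassigned"`` where no threshold retains a hit).

    Parameters
    ----------
    thresholds:
        Decreasing similarity cutoffs in percent; ``None`` uses the
        default 14-step ladder 99 .. 80.
    mismatch_cost, gap_open_cost, gap_extend_cost, match_cost:
        Global-alignment penalties.
    """

    def __init__(
        self,
        thresholds: Sequence[float] | None = None,
        mismatch_cost: float = 1.0,
        gap_open_cost: float = 1.0,
        gap_extend_cost: float = 1.0,
        match_cost: float = 0.0,
    ):
        self.thresholds = thresholds
        self.mismatch_cost = mismatch_cost
        self.gap_open_cost = gap_open_cost
        self.gap_extend_cost = gap_extend_cost
        self.match_cost = match_cost

    def _align_params(self) -> AlignParams:
        return AlignParams(
            mismatch_cost=self.mismatch_cost,
            gap_open_cost=self.gap_open_cost,
            gap_extend_cost=self.gap_extend_cost,
            match_cost=self.match_cost,
        )

    def fit(self, X: Sequence[Seq], y: Sequence[Lineage | str]):
        """Store reference sequences ``X`` and their lineages ``y``."""
        X = list(X)
        y = list(y)
        if not X:
            raise ValueError("reference set is empty")
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        pairs = []
        for seq, lin in zip(X, y):
            if not isinstance(seq, Seq):
                raise TypeError("X must contain Seq records")
            if isinstance(lin, str):
                lin = Lineage.from_string(lin)
            pairs.append((seq, lin))
        self.db_ = ReferenceDB.from_pairs(pairs)
        self.ladder_ = (
            ThresholdLadder() if self.thresholds is None
            else ThresholdLadder(tuple(float(t) for t in self.thresholds))
        )
        self.n_references_ = len(self.db_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "db_"):
            raise ValueError("classifier is not fitted; call fit first")

    def assign(self, X: Sequence[Seq]) -> list[Assignment]:
        """Full per-query assignments (consensus, threshold, supporting hits)."""
        self._check_fitted()
        params = self._align_params()
        return [classify(q, self.db_, self.ladder_, params) for q in X]

    def predict(self, X: Sequence[Seq]) -> np.ndarray:
        """Semicolon-joined consensus lineage per query."""
        return np.array([a.consensus_string() for a in self.assign(X)], dtype=object)

    def predict_batch(self, X: Sequence[Seq]) -> tuple[pd.DataFrame, pd.Series]:
        """Assignment table plus per-phylum summary (error rows flagged)."""
        self._check_fitted()
        return classify_batch(X, self.db_, self.ladder_, self._align_params())
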