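"""Sequence model, global pairwise alignment, and percent similarity.

Every downstream stage (taxonomy assignment, environment-neighbor
counting) consumes the percent-similarity statistic defined here:

    similarity = 100 * identical_columns / alignment_length

computed on a minimum-penalty global (Needleman-Wunsch/Gotoh) alignment
with unit penalties for mismatch, gap opening and gap extension by
default.  Global alignment is deliberate: unlike local heuristics
(BLAST), it charges terminal gaps, so a short fragment aligned to a
full-length reference is penalised for the unsequenced remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _align_kernel

ALPHABET = "ACGTN"

_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE_TABLE[ord(_c)] = _i


@dataclass(frozen=True)
class Seq:
    """An identified nucleotide sequence over {A, C, G, T, N}.

    Lowercase input is upcased on construction; anything outside the
    alphabet is rejected.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        residues = self.residues.upper()
        if not residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """uint8 codes (A=0 .. N=4) for the alignment kernel."""
        raw = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        return _ENCODE_TABLE[raw].astype(np.uint8)


@dataclass(frozen=True)
class AlignParams:
    """Alignment penalties.

    The defaults charge 1 for a mismatch, 1 to open a gap and 1 to extend
    it (a length-L gap run costs 1 + L), and 0 for a match.
    """

    mismatch_cost: float = 1.0
    gap_open_cost: float = 1.0
    gap_extend_cost: float = 1.0
    match_cost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mismatch_cost", "gap_open_cost", "gap_extend_cost"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not math.isfinite(self.match_cost):
            raise ValueError("match_cost must be finite")


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class Alignment:
    """A global alignment: two equal-length gapped strings plus summary stats."""

    aligned_query: str
    aligned_ref: str
    cost: float
    n_identical: int
    alignment_length: int


@dataclass(frozen=True)
class SimilarityHit:
    """(query, reference, percent similarity) from one global alignment."""

    query_id: str
    ref_id: str
    similarity: float
    cost: float
    alignment_length: int


def global_align(query: Seq, ref: Seq, params: AlignParams | None = None) -> Alignment:
    """Minimum-cost global alignment of ``query`` against ``ref``.

    Gap runs cost ``gap_open_cost + L * gap_extend_cost``.  Ties are broken
    deterministically (diagonal, then gap-in-reference, then gap-in-query).
    N is never an identity and always costs a mismatch.
    """
    if params is None:
        params = DEFAULT_PARAMS
    a = query.encoded()
    b = ref.encoded()
    cost, n_identical, moves = _align_kernel.align_encoded(
        a,
        b,
        params.mismatch_cost,
        params.gap_open_cost,
        params.gap_extend_cost,
        params.match_cost,
    )
    q_chars = []
    r_chars = []
    i = j = 0
    for mv in moves:
        if mv == _align_kernel.DIAG:
            q_chars.append(query.residues[i])
            r_chars.append(ref.residues[j])
            i += 1
            j += 1
        elif mv == _align_kernel.GAP_IN_REF:
            q_chars.append(query.residues[i])
            r_chars.append("-")
            i += 1
        else:
            q_chars.append("-")
            r_chars.append(ref.residues[j])
            j += 1
    return Alignment(
        aligned_query="".join(q_chars),
        aligned_ref="".join(r_chars),
        cost=float(cost),
        n_identical=int(n_identical),
        alignment_length=len(moves),
    )


def percent_similarity(aln: Alignment, denominator: str = "columns") -> float:
    """Percent similarity of an alignment, in [0, 100].

    ``denominator="columns"`` (default) divides by the alignment length
    including gap columns, so indels reduce similarity symmetrically.
    ``denominator="shorter"`` divides by the shorter ungapped sequence
    length instead.
    """
    if aln.alignment_length <= 0:
        raise ValueError("alignment has zero length")
    if denominator == "columns":
        denom = aln.alignment_length
    elif denominator == "shorter":
        denom = min(
            len(aln.aligned_query.replace("-", "")),
            len(aln.aligned_ref.replace("-", "")),
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * aln.n_identical / denom


def similarity(query: Seq, ref: Seq, params: AlignParams | None = None) -> float:
    """Convenience: percent similarity of the optimal global alignment."""
    return percent_similarity(global_align(query, ref, params))


def all_vs_refs(
    query: Seq,
    refs: Iterable[Seq],
    params: AlignParams | None = None,
    denominator: str = "columns",
) -> list[SimilarityHit]:
    """Align ``query`` to every reference; hits sorted by descending
    similarity, ties broken by reference id."""
    refs = list(refs)
    if not refs:
        raise ValueError("reference set is empty")
    hits = []
    for ref in refs:
        aln = global_align(query, ref, params)
        hits.append(
            SimilarityHit(
                query_id=query.id,
                ref_id=ref.id,
                similarity=percent_similarity(aln, denominator),
                cost=aln.cost,
                alignment_length=aln.alignment_length,
            )
        )
    hits.sort(key=lambda h: (-h.similarity, h.ref_id))
    return hits


def recompute_alignment_cost(aln: Alignment, params: AlignParams | None = None) -> float:
    """Cost of an alignment recomputed column-by-column (consistency check)."""
    if params is None:
        params = DEFAULT_PARAMS
    cost = 0.0
    in_gap_q = in_gap_r = False
    for qc, rc in zip(aln.aligned_query, aln.aligned_ref):
        if qc == "-" and rc == "-":
            raise ValueError("all-gap column")
        if qc == "-":
            cost += params.gap_extend_cost
            if not in_gap_q:
                cost += params.gap_open_cost
            in_gap_q, in_gap_r = True, False
        elif rc == "-":
            cost += params.gap_extend_cost
            if not in_gap_r:
                cost += params.gap_open_cost
            in_gap_q, in_gap_r = False, True
        else:
            cost += params.match_cost if (qc == rc and qc != "N") else params.mismatch_cost
            in_gap_q = in_gap_r = False
    return cost
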