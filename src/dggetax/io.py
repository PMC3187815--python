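"""File formats: FASTA, taxonomy/annotation TSVs, band tables, result tables.

All tabular outputs can carry '#'-prefixed provenance header lines
(tool version, seed, parameter hash); readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .envneighbors import AnnotatedRecord, render_zero_as_dash
from .fingerprint import BandTable, ConfidenceEllipse, PCAResult
from .seqcore import Seq, SimilarityHit
from .taxclass import Lineage, ReferenceDB


class ParseError(ValueError):
    """Malformed input file; message names the file (and line if known)."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[Seq]:
    """Read a multi-record FASTA; the id is the first whitespace-delimited
    header token.  Wrapped and unwrapped sequence lines both parse."""
    path = Path(path)
    seqs: list[Seq] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            seqs.append(Seq(record.id, str(record.seq)))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[Seq], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(_BioSeq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ------------------------------------------------------------ provenance

def params_hash(params: Mapping) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None = None, params: Mapping | None = None) -> str:
    lines = [f"# dggetax v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params is not None:
        lines.append(f"# params_hash={params_hash(params)}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: str | Path, header: str | None,
               index: bool = False, float_format: str | None = "%.1f") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


# ----------------------------------------------------- taxonomy tables

def read_taxonomy_tsv(path: str | Path) -> dict[str, Lineage]:
    """``ref_id <TAB> semicolon-joined lineage`` (Silva dialect)."""
    path = Path(path)
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            rid, lineage_text = parts
            if rid in out:
                raise ParseError(f"{path}:{lineno}: duplicate reference id {rid!r}")
            try:
                out[rid] = Lineage.from_string(lineage_text)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not out:
        raise ParseError(f"{path}: no taxonomy records found")
    return out


def write_taxonomy_tsv(
    lineages: Mapping[str, Lineage], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for rid, lin in lineages.items():
            fh.write(f"{rid}\t{lin.to_string()}\n")


def read_reference_db(fasta_path: str | Path, taxonomy_path: str | Path) -> ReferenceDB:
    """Paired reference FASTA + taxonomy TSV -> ReferenceDB."""
    seqs = {s.id: s for s in read_fasta(fasta_path)}
    lineages = read_taxonomy_tsv(taxonomy_path)
    missing = set(seqs) ^ set(lineages)
    if missing:
        raise ParseError(
            f"reference FASTA and taxonomy disagree on ids: {sorted(missing)[:5]}"
        )
    return ReferenceDB({rid: (seqs[rid], lineages[rid]) for rid in seqs})


# --------------------------------------------------- annotated database

def read_annotations_tsv(path: str | Path) -> dict[str, str]:
    """``record_id <TAB> free-text annotation``."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected id<TAB>annotation")
            out[parts[0]] = parts[1]
    if not out:
        raise ParseError(f"{path}: no annotation records found")
    return out


def read_annotated_db(
    fasta_path: str | Path, annotations_path: str | Path
) -> list[AnnotatedRecord]:
    seqs = read_fasta(fasta_path)
    annotations = read_annotations_tsv(annotations_path)
    missing = [s.id for s in seqs if s.id not in annotations]
    if missing:
        raise ParseError(f"{annotations_path}: missing annotations for {missing[:5]}")
    return [AnnotatedRecord(seq=s, annotation=annotations[s.id]) for s in seqs]


def write_annotations_tsv(
    records: Iterable[AnnotatedRecord], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for rec in records:
            fh.write(f"{rec.seq.id}\t{rec.annotation}\n")


# -------------------------------------------------------- band tables

def read_band_table_tsv(path: str | Path) -> BandTable:
    """First column lane_id, second column group, remaining columns band
    intensities with band ids in the header row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 4:
        raise ParseError(f"{path}: need lane_id, group and at least 2 band columns")
    lane_col, group_col = df.columns[:2]
    df = df.set_index(lane_col)
    groups = df[group_col]
    intensities = df.drop(columns=[group_col]).astype(float)
    try:
        return BandTable(intensities=intensities, groups=groups)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_band_table_tsv(
    t: BandTable, path: str | Path, header: str | None = None
) -> None:
    df = t.intensities.copy()
    df.insert(0, "group", t.groups)
    df.index.name = "lane_id"
    _write_tsv(df, path, header, index=True, float_format="%.6g")


# ------------------------------------------------------- result tables

def write_hits_tsv(
    hits: Iterable[SimilarityHit], path: str | Path, header: str | None = None
) -> None:
    df = pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "ref_id": h.ref_id,
                "similarity": h.similarity,
                "cost": h.cost,
                "alignment_length": h.alignment_length,
            }
            for h in hits
        ]
    )
    _write_tsv(df, path, header)


def write_assignments_tsv(
    table: pd.DataFrame, path: str | Path, header: str | None = None
) -> None:
    _write_tsv(table, path, header)


def write_neighbor_tsv(
    table: pd.DataFrame, path: str | Path, header: str | None = None
) -> None:
    _write_tsv(render_zero_as_dash(table), path, header)


def write_scores_tsv(result: PCAResult, path: str | Path, header: str | None = None) -> None:
    df = result.scores.copy()
    df.index.name = "lane_id"
    _write_tsv(df, path, header, index=True, float_format="%.6f")


def write_loadings_tsv(result: PCAResult, path: str | Path, header: str | None = None) -> None:
    df = result.loadings.copy()
    df.index.name = "band_id"
    _write_tsv(df, path, header, index=True, float_format="%.6f")


def write_ellipses_tsv(
    ellipses: Mapping[str, ConfidenceEllipse], path: str | Path, header: str | None = None
) -> None:
    rows = []
    for g, e in ellipses.items():
        rows.append(
            {
                "group": g,
                "center_pc1": e.center[0],
                "center_pc2": e.center[1],
                "semi_major": e.semi_axes[0],
                "semi_minor": e.semi_axes[1],
                "angle_deg": e.angle_deg,
                "coverage": e.coverage,
                "degenerate": e.degenerate,
            }
        )
    _write_tsv(pd.DataFrame(rows), path, header, float_format="%.6f")
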