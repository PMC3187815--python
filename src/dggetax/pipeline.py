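"""End-to-end orchestration: generate -> classify -> neighbors -> fingerprint.

A single declarative YAML config drives every stage; all randomness is
derived from one seed, so identical config + seed reproduces output
byte-for-byte.  Every tabular output carries a provenance header (tool
version, seed, parameter hash).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as dio
from .envneighbors import EnvironmentNeighborCounter
from .fingerprint import (
    BandTablePCA,
    LaneNormalizer,
    plot_scores,
)
from .seqcore import AlignParams
from .synthetic_data import (
    AnnotatedDBSpec,
    BandTableSpec,
    CloneLibrarySpec,
    TaxonomySpec,
    make_annotated_db,
    make_band_table,
    make_clone_library,
    make_reference_db,
)
from .taxclass import ConsensusTaxonomyClassifier, ThresholdLadder

log = logging.getLogger("dggetax")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (usage error, exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (runtime error, exit code 1)."""


@dataclass
class RunConfig:
    """Declarative configuration for the pipeline stages.

    Paths left as ``None`` are filled in by ``run_all`` from the
    synthetic-data stage.  ``generate`` holds keyword overrides for the
    four synthetic specs (``taxonomy``, ``clones``, ``annotated``,
    ``band_table``).
    """

    seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"

    # alignment penalties
    mismatch_cost: float = 1.0
    gap_open_cost: float = 1.0
    gap_extend_cost: float = 1.0
    match_cost: float = 0.0

    # classifier
    thresholds: list[float] | None = None
    queries: str | None = None
    reference_fasta: str | None = None
    reference_taxonomy: str | None = None

    # neighbors
    neighbor_threshold: float = 95.0
    pool_radionuclide: bool = True
    annotated_fasta: str | None = None
    annotations: str | None = None

    # fingerprint
    band_table: str | None = None
    coverage: float = 0.90
    n_discriminant: int = 6
    presence_absence: bool = False
    correlation: bool = False
    plot: bool = False

    # synthetic-data overrides
    generate: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def align_params(self) -> AlignParams:
        return AlignParams(
            mismatch_cost=self.mismatch_cost,
            gap_open_cost=self.gap_open_cost,
            gap_extend_cost=self.gap_extend_cost,
            match_cost=self.match_cost,
        )

    def header(self) -> str:
        return dio.provenance_header(seed=self.seed, params=dataclasses.asdict(self))

    def out(self, name: str) -> Path:
        d = Path(self.output_dir)
        d.mkdir(parents=True, exist_ok=True)
        return d / name


def _require(cfg: RunConfig, **paths: str | None) -> dict[str, Path]:
    out = {}
    for name, p in paths.items():
        if p is None:
            raise ConfigError(f"config is missing required path {name!r}")
        path = Path(p)
        if not path.exists():
            raise ConfigError(f"{name} path does not exist: {path}")
        out[name] = path
    return out


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


def run_generate(cfg: RunConfig) -> dict[str, Path]:
    """Write the full synthetic dataset (with truth tables) and return the
    generated paths."""
    g = cfg.generate or {}
    tax_spec = TaxonomySpec(seed=cfg.seed, **g.get("taxonomy", {}))
    clone_spec = CloneLibrarySpec(seed=cfg.seed + 1, **g.get("clones", {}))
    ann_spec = AnnotatedDBSpec(seed=cfg.seed + 2, **g.get("annotated", {}))
    band_spec = BandTableSpec(seed=cfg.seed + 3, **g.get("band_table", {}))

    header = cfg.header()
    data_dir = Path(cfg.output_dir) / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: data_dir / v for k, v in {
        "reference_fasta": "references.fasta",
        "reference_taxonomy": "reference_taxonomy.tsv",
        "queries": "clones.fasta",
        "clone_truth": "clone_truth.tsv",
        "annotated_fasta": "annotated_db.fasta",
        "annotations": "annotations.tsv",
        "annotated_truth": "annotated_truth.tsv",
        "band_table": "band_table.tsv",
        "band_truth": "band_truth.tsv",
    }.items()}

    db, lineages = make_reference_db(tax_spec)
    dio.write_fasta(db.sequences(), paths["reference_fasta"])
    dio.write_taxonomy_tsv(lineages, paths["reference_taxonomy"], header=header)
    log.info("generated %d reference sequences", len(db))

    clones, clone_truth = make_clone_library(clone_spec, db)
    dio.write_fasta(clones, paths["queries"])
    dio._write_tsv(clone_truth, paths["clone_truth"], header, float_format="%.6g")
    log.info("generated %d clones", len(clones))

    records, ann_truth = make_annotated_db(ann_spec, db)
    dio.write_fasta([r.seq for r in records], paths["annotated_fasta"])
    dio.write_annotations_tsv(records, paths["annotations"], header=header)
    dio._write_tsv(ann_truth, paths["annotated_truth"], header, float_format="%.6g")
    log.info("generated %d annotated records", len(records))

    table, band_truth = make_band_table(band_spec)
    dio.write_band_table_tsv(table, paths["band_table"], header=header)
    with open(paths["band_truth"], "w") as fh:
        fh.write(header)
        fh.write("group\tband_id\n")
        for group in sorted(band_truth):
            for band in sorted(band_truth[group]):
                fh.write(f"{group}\t{band}\n")
    log.info(
        "generated band table: %d lanes x %d bands",
        *table.intensities.shape,
    )
    return paths


def run_classify(cfg: RunConfig) -> pd.DataFrame:
    """Classify every query against the reference database; writes the
    assignment table, the per-phylum summary, and the per-threshold
    resolution histogram."""
    paths = _require(
        cfg,
        queries=cfg.queries,
        reference_fasta=cfg.reference_fasta,
        reference_taxonomy=cfg.reference_taxonomy,
    )
    try:
        queries = dio.read_fasta(paths["queries"])
        db = dio.read_reference_db(paths["reference_fasta"], paths["reference_taxonomy"])
    except dio.ParseError as exc:
        raise DataError(str(exc)) from exc
    log.info("classifying %d queries against %d references", len(queries), len(db))

    clf = ConsensusTaxonomyClassifier(
        thresholds=cfg.thresholds,
        mismatch_cost=cfg.mismatch_cost,
        gap_open_cost=cfg.gap_open_cost,
        gap_extend_cost=cfg.gap_extend_cost,
        match_cost=cfg.match_cost,
    )
    clf.fit(db.sequences(), [db.lineage(r) for r in db.records])
    table, summary = clf.predict_batch(queries)

    header = cfg.header()
    dio.write_assignments_tsv(table, cfg.out("assignments.tsv"), header=header)
    summary_df = summary.rename_axis("phylum").reset_index()
    dio._write_tsv(summary_df, cfg.out("phylum_summary.tsv"), header)

    hist = (
        table.loc[table["status"] == "assigned", "resolved_threshold"]
        .value_counts()
        .sort_index(ascending=False)
        .rename_axis("threshold")
        .reset_index(name="n_queries")
    )
    n_un = int((table["status"] == "unassigned").sum())
    if n_un:
        hist = pd.concat(
            [hist, pd.DataFrame([{"threshold": "unassigned", "n_queries": n_un}])],
            ignore_index=True,
        )
    dio._write_tsv(hist, cfg.out("resolution_histogram.tsv"), header)
    n_flagged = int((table["status"] == "failed").sum())
    log.info(
        "rows in=%d, assigned=%d, unassigned=%d, flagged=%d",
        len(queries),
        int((table["status"] == "assigned").sum()),
        n_un,
        n_flagged,
    )
    for _, row in hist.iterrows():
        log.info("  threshold %s: %d queries", row["threshold"], row["n_queries"])
    return table


def run_neighbors(cfg: RunConfig) -> pd.DataFrame:
    """Count >threshold neighbors with uranium/iron annotations per query."""
    paths = _require(
        cfg,
        queries=cfg.queries,
        annotated_fasta=cfg.annotated_fasta,
        annotations=cfg.annotations,
    )
    try:
        queries = dio.read_fasta(paths["queries"])
        records = dio.read_annotated_db(paths["annotated_fasta"], paths["annotations"])
    except dio.ParseError as exc:
        raise DataError(str(exc)) from exc
    log.info(
        "counting neighbors for %d queries in %d annotated records (threshold > %s%%)",
        len(queries),
        len(records),
        cfg.neighbor_threshold,
    )
    taxonomy = None
    assignments_path = Path(cfg.output_dir) / "assignments.tsv"
    if assignments_path.exists():
        prev = pd.read_csv(assignments_path, sep="\t", comment="#")
        taxonomy = dict(zip(prev["query_id"], prev["consensus"].fillna("")))
    counter = EnvironmentNeighborCounter(
        threshold=cfg.neighbor_threshold,
        pool_radionuclide=cfg.pool_radionuclide,
        mismatch_cost=cfg.mismatch_cost,
        gap_open_cost=cfg.gap_open_cost,
        gap_extend_cost=cfg.gap_extend_cost,
        match_cost=cfg.match_cost,
    ).fit(records)
    table = counter.transform(queries, taxonomy=taxonomy)
    dio.write_neighbor_tsv(table, cfg.out("neighbors.tsv"), header=cfg.header())
    log.info("rows in=%d, rows out=%d", len(queries), len(table))
    return table


def run_fingerprint(cfg: RunConfig) -> dict[str, Any]:
    """Normalize the band table, run PCA, fit group ellipses, select the
    top discriminant bands; writes scores/loadings/ellipses/band list."""
    paths = _require(cfg, band_table=cfg.band_table)
    try:
        table = dio.read_band_table_tsv(paths["band_table"])
    except dio.ParseError as exc:
        raise DataError(str(exc)) from exc
    log.info(
        "band table: %d lanes x %d bands, groups: %s",
        *table.intensities.shape,
        dict(table.groups.value_counts()),
    )
    try:
        normalized = LaneNormalizer().transform(table)
        model = BandTablePCA(
            presence_absence=cfg.presence_absence,
            correlation=cfg.correlation,
            coverage=cfg.coverage,
        ).fit(normalized)
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    result = model.result_
    for k, frac in enumerate(result.variance_fraction[:3], start=1):
        log.info("PC%d accounts for %.1f%% of the variance", k, frac)
    for g in pd.unique(normalized.groups):
        if g not in model.ellipses_:
            log.warning("group %r has fewer than 3 lanes; ellipse skipped", g)

    header = cfg.header()
    dio.write_scores_tsv(result, cfg.out("pca_scores.tsv"), header=header)
    dio.write_loadings_tsv(result, cfg.out("pca_loadings.tsv"), header=header)
    dio.write_ellipses_tsv(model.ellipses_, cfg.out("ellipses.tsv"), header=header)

    n = min(cfg.n_discriminant, len(result.loadings))
    bands = model.discriminant_bands(axis=1, n=n)
    with open(cfg.out("discriminant_bands.tsv"), "w") as fh:
        fh.write(header)
        fh.write("rank\tband_id\tpc1_loading\n")
        for i, b in enumerate(bands, start=1):
            fh.write(f"{i}\t{b}\t{result.loadings.loc[b, 'PC1']:.6f}\n")
    log.info("top-%d PC1 bands: %s", n, ", ".join(bands))

    if cfg.plot:
        plot_scores(
            result, normalized.groups, model.ellipses_,
            path=str(cfg.out("pca_scores.svg")),
        )
    return {"result": result, "ellipses": model.ellipses_, "bands": bands}


def run_all(cfg: RunConfig) -> None:
    """Generate the synthetic dataset, then run every analysis stage on it."""
    paths = run_generate(cfg)
    cfg = dataclasses.replace(
        cfg,
        queries=str(paths["queries"]),
        reference_fasta=str(paths["reference_fasta"]),
        reference_taxonomy=str(paths["reference_taxonomy"]),
        annotated_fasta=str(paths["annotated_fasta"]),
        annotations=str(paths["annotations"]),
        band_table=str(paths["band_table"]),
    )
    run_classify(cfg)
    run_neighbors(cfg)
    run_fingerprint(cfg)
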