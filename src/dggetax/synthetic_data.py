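"""Seeded generators emulating the study's inputs.

Real inputs to this pipeline are clone libraries from excised DGGE bands,
a Silva-style reference database, an EMBL-style annotated database, and
band tables exported from gel software.  None of these are reproducible
at desk scale, so each generator here builds a synthetic counterpart with
exact ground truth:

* ``make_reference_db`` evolves an ancestral sequence down a systematic
  taxonomy tree (Jukes-Cantor-like: substitutions uniform over the three
  alternative bases, no transition/transversion bias);
* ``make_clone_library`` mutates sampled references (substitutions +
  single-base indels, optional fragment window) to mimic partial 16S
  clone reads;
* ``make_annotated_db`` attaches free-text environment annotations with
  planted uranium/iron keywords;
* ``make_band_table`` builds a two-group (uranium-rich vs control) lane
  x band intensity matrix with shared and group-specific bands,
  log-normal base intensities, multiplicative noise, and band drop-out.

All generators are deterministic under a fixed seed (byte-identical
artifacts), and lineage names are systematic ("Phylum_01", "Genus_05")
so joins against the truth tables are string-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .envneighbors import AnnotatedRecord
from .fingerprint import GROUP_CONTROL, GROUP_URANIUM, BandTable
from .seqcore import Seq
from .taxclass import CANONICAL_RANKS, Lineage, ReferenceDB

_BASES = np.array(list("ACGT"))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _substitute(codes: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Per-site substitution at ``rate``, uniform over the 3 alternatives."""
    out = codes.copy()
    hit = rng.random(len(out)) < rate
    n = int(hit.sum())
    if n:
        # shift by 1..3 mod 4 guarantees a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out, n


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


@dataclass(frozen=True)
class TaxonomySpec:
    """Shape and divergence of the synthetic reference taxonomy.

    ``divergence`` gives the expected per-site substitution probability
    separating a child taxon from its parent ancestor at each rank;
    deeper ranks must diverge less (enforced), so the similarity
    hierarchy intra-genus > intra-family > ... > intra-phylum holds by
    construction.  ``reference`` is the within-genus rate for individual
    reference sequences.
    """

    n_phyla: int = 3
    classes_per_phylum: int = 2
    orders_per_class: int = 1
    families_per_order: int = 2
    genera_per_family: int = 2
    refs_per_genus: int = 2
    ref_length: int = 550
    divergence: tuple[float, ...] = (0.20, 0.12, 0.08, 0.05, 0.018, 0.008)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in (
            "n_phyla", "classes_per_phylum", "orders_per_class",
            "families_per_order", "genera_per_family", "refs_per_genus",
        ):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.ref_length < 10:
            problems.append("ref_length must be >= 10")
        if len(self.divergence) != 6:
            problems.append(
                "divergence needs 6 rates (phylum, class, order, family, genus, reference)"
            )
        else:
            if any(not (0 < d < 0.75) for d in self.divergence):
                problems.append("divergence rates must lie in (0, 0.75)")
            if any(b >= a for a, b in zip(self.divergence, self.divergence[1:])):
                problems.append("deeper ranks must have strictly smaller divergence")
        if problems:
            raise ValueError("invalid TaxonomySpec: " + "; ".join(problems))


def make_reference_db(spec: TaxonomySpec) -> tuple[ReferenceDB, dict[str, Lineage]]:
    """Evolve references down the taxonomy tree; returns the database and
    the id -> lineage truth map."""
    spec.validate()
    rng = _rng(spec.seed)
    root = _random_sequence(rng, spec.ref_length)
    d_phy, d_cls, d_ord, d_fam, d_gen, d_ref = spec.divergence

    counters = {rank: 0 for rank in CANONICAL_RANKS[1:]}

    def next_name(rank: str) -> str:
        counters[rank] += 1
        return f"{rank.capitalize()}_{counters[rank]:02d}"

    pairs: list[tuple[Seq, Lineage]] = []
    for _ in range(spec.n_phyla):
        phy_seq, _ = _substitute(root, d_phy, rng)
        phy = next_name("phylum")
        for _ in range(spec.classes_per_phylum):
            cls_seq, _ = _substitute(phy_seq, d_cls, rng)
            cls = next_name("class")
            for _ in range(spec.orders_per_class):
                ord_seq, _ = _substitute(cls_seq, d_ord, rng)
                order = next_name("order")
                for _ in range(spec.families_per_order):
                    fam_seq, _ = _substitute(ord_seq, d_fam, rng)
                    fam = next_name("family")
                    for _ in range(spec.genera_per_family):
                        gen_seq, _ = _substitute(fam_seq, d_gen, rng)
                        genus = next_name("genus")
                        lineage = Lineage.from_names(
                            ["Bacteria", phy, cls, order, fam, genus]
                        )
                        for r in range(spec.refs_per_genus):
                            ref_seq, _ = _substitute(gen_seq, d_ref, rng)
                            rid = f"REF_{genus}_{r + 1:02d}"
                            pairs.append(
                                (Seq(rid, _codes_to_str(ref_seq)), lineage)
                            )
    db = ReferenceDB.from_pairs(pairs)
    truth = {rid: lin for rid, (_, lin) in db.records.items()}
    return db, truth


@dataclass(frozen=True)
class CloneLibrarySpec:
    """Clone-library simulation: how the sequenced clones differ from the
    references they derive from.

    ``fragment_window`` = (start, length) truncates the source reference
    before mutation, mimicking a partial 16S read; ``None`` keeps the full
    reference length.  ``genus_weights`` optionally biases which genus a
    clone is drawn from (keyed by genus name, unnormalized).
    """

    n_clones: int = 144
    mutation_rate: float = 0.01
    indel_rate: float = 0.0
    fragment_window: tuple[int, int] | None = None
    genus_weights: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_clones < 0:
            problems.append("n_clones must be >= 0")
        if not (0 <= self.mutation_rate < 1):
            problems.append("mutation_rate must be in [0, 1)")
        if not (0 <= self.indel_rate < 1):
            problems.append("indel_rate must be in [0, 1)")
        if self.fragment_window is not None:
            start, length = self.fragment_window
            if start < 0 or length < 1:
                problems.append("fragment_window must have start >= 0, length >= 1")
        if problems:
            raise ValueError("invalid CloneLibrarySpec: " + "; ".join(problems))


def make_clone_library(
    spec: CloneLibrarySpec, db: ReferenceDB
) -> tuple[list[Seq], pd.DataFrame]:
    """Mutated, optionally windowed copies of sampled references.

    Returns the clones and a truth table with the source reference, its
    lineage, and realized substitution / indel counts per clone.
    """
    spec.validate()
    if len(db) == 0:
        raise ValueError("reference database is empty")
    rng = _rng(spec.seed)

    by_genus: dict[str, list[str]] = {}
    for rid, (_, lin) in db.records.items():
        genus = lin.names[-1]
        by_genus.setdefault(genus, []).append(rid)
    genera = sorted(by_genus)
    if spec.genus_weights is not None:
        unknown = set(spec.genus_weights) - set(genera)
        if unknown:
            raise ValueError(f"genus_weights for unknown genera: {sorted(unknown)}")
        w = np.array([spec.genus_weights.get(g, 0.0) for g in genera], dtype=float)
        if w.sum() <= 0:
            raise ValueError("genus_weights sum to zero")
        w = w / w.sum()
    else:
        w = np.full(len(genera), 1.0 / len(genera))

    clones: list[Seq] = []
    rows = []
    for k in range(spec.n_clones):
        genus = genera[rng.choice(len(genera), p=w)]
        rid = by_genus[genus][rng.integers(len(by_genus[genus]))]
        src, lineage = db.records[rid]
        codes = np.array([("ACGTN".index(c)) for c in src.residues])
        if spec.fragment_window is not None:
            start, length = spec.fragment_window
            if start + length > len(codes):
                raise ValueError(
                    f"fragment_window {spec.fragment_window} outside reference "
                    f"of length {len(codes)}"
                )
            codes = codes[start : start + length]
        codes, n_sub = _substitute(codes, spec.mutation_rate, rng)
        n_indel = 0
        if spec.indel_rate > 0:
            out = []
            for c in codes:
                r = rng.random()
                if r < spec.indel_rate:
                    n_indel += 1
                    if rng.random() < 0.5:
                        continue  # deletion
                    out.append(int(rng.integers(0, 4)))  # insertion before site
                    out.append(int(c))
                else:
                    out.append(int(c))
            if not out:
                out = [int(rng.integers(0, 4))]
            codes = np.array(out)
        qid = f"CLONE_{k + 1:04d}"
        clones.append(Seq(qid, _codes_to_str(codes)))
        rows.append(
            {
                "query_id": qid,
                "source_ref_id": rid,
                "lineage": lineage.to_string(),
                "genus": genus,
                "n_sites": len(codes),
                "n_substitutions": n_sub,
                "n_indels": n_indel,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "query_id", "source_ref_id", "lineage", "genus",
            "n_sites", "n_substitutions", "n_indels",
        ],
    )
    return clones, truth


@dataclass(frozen=True)
class AnnotatedDBSpec:
    """EMBL-style annotated database: mutated relatives of the references
    with free-text isolation-source annotations carrying planted keywords."""

    n_records: int = 60
    p_uranium: float = 0.3
    p_iron: float = 0.3
    divergence_range: tuple[float, float] = (0.0, 0.15)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_records < 1:
            problems.append("n_records must be >= 1")
        for name in ("p_uranium", "p_iron"):
            if not (0 <= getattr(self, name) <= 1):
                problems.append(f"{name} must be in [0, 1]")
        lo, hi = self.divergence_range
        if not (0 <= lo <= hi < 0.75):
            problems.append("divergence_range must satisfy 0 <= lo <= hi < 0.75")
        if problems:
            raise ValueError("invalid AnnotatedDBSpec: " + "; ".join(problems))


_URANIUM_TEXTS = (
    "uranium mill tailings clone",
    "uranium-contaminated aquifer sediment",
    "radionuclide-contaminated groundwater isolate",
)
_IRON_TEXTS = (
    "iron(II)-rich seep sediment clone",
    "iron-rich creek soil bacterium",
)
_NEUTRAL_TEXTS = (
    "agricultural soil clone",
    "forest soil bacterium",
    "groundwater clone",
    "rhizosphere sample isolate",
)


def make_annotated_db(
    spec: AnnotatedDBSpec, db: ReferenceDB
) -> tuple[list[AnnotatedRecord], pd.DataFrame]:
    """Annotated records derived from the reference database; truth table
    carries the planted flags and divergence per record."""
    spec.validate()
    rng = _rng(spec.seed)
    ref_ids = sorted(db.records)
    records: list[AnnotatedRecord] = []
    rows = []
    for k in range(spec.n_records):
        rid = ref_ids[rng.integers(len(ref_ids))]
        src, _ = db.records[rid]
        codes = np.array([("ACGTN".index(c)) for c in src.residues])
        rate = rng.uniform(*spec.divergence_range)
        codes, n_sub = _substitute(codes, rate, rng)
        u = bool(rng.random() < spec.p_uranium)
        fe = bool(rng.random() < spec.p_iron)
        parts = ["uncultured bacterium from"]
        if u:
            parts.append(_URANIUM_TEXTS[rng.integers(len(_URANIUM_TEXTS))])
        if fe:
            parts.append(_IRON_TEXTS[rng.integers(len(_IRON_TEXTS))])
        if not (u or fe):
            parts.append(_NEUTRAL_TEXTS[rng.integers(len(_NEUTRAL_TEXTS))])
        annotation = " ".join(parts)
        rec_id = f"DB_{k + 1:04d}"
        rec = AnnotatedRecord(seq=Seq(rec_id, _codes_to_str(codes)), annotation=annotation)
        records.append(rec)
        rows.append(
            {
                "record_id": rec_id,
                "source_ref_id": rid,
                "divergence_rate": rate,
                "n_substitutions": n_sub,
                "has_uranium": u,
                "has_iron": fe,
                "annotation": annotation,
            }
        )
    truth = pd.DataFrame(rows)
    return records, truth


@dataclass(frozen=True)
class BandTableSpec:
    """Two-group DGGE band table.

    Shared bands appear in every lane; group-specific bands only in their
    own group's lanes (subject to drop-out, which applies to all bands).
    Intensities are log-normal base levels per band times multiplicative
    log-normal noise with the stated coefficient of variation.  Defaults
    give 40 bands per lane (within the 25-40 bands a soil-community gel
    typically shows) and 6 lanes per group.
    """

    n_uranium_lanes: int = 6
    n_control_lanes: int = 6
    n_shared_bands: int = 28
    n_specific_uranium: int = 6
    n_specific_control: int = 6
    log_intensity_mean: float = 2.0
    log_intensity_sigma: float = 0.6
    noise_cv: float = 0.35
    dropout: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_uranium_lanes < 3 or self.n_control_lanes < 3:
            problems.append("each group needs at least 3 lanes")
        if self.n_shared_bands < 1:
            problems.append("n_shared_bands must be >= 1")
        if self.n_specific_uranium < 0 or self.n_specific_control < 0:
            problems.append("specific band counts must be >= 0")
        if not (0 <= self.dropout < 1):
            problems.append("dropout must be in [0, 1)")
        if self.noise_cv < 0:
            problems.append("noise_cv must be >= 0")
        if self.log_intensity_sigma < 0:
            problems.append("log_intensity_sigma must be >= 0")
        if problems:
            raise ValueError("invalid BandTableSpec: " + "; ".join(problems))


def make_band_table(spec: BandTableSpec) -> tuple[BandTable, dict[str, set[str]]]:
    """Simulated gel export plus the truth sets of group-specific bands."""
    spec.validate()
    rng = _rng(spec.seed)
    n_bands = spec.n_shared_bands + spec.n_specific_uranium + spec.n_specific_control
    band_ids = [f"band_{i + 1:02d}" for i in range(n_bands)]
    shared = band_ids[: spec.n_shared_bands]
    u_specific = band_ids[spec.n_shared_bands : spec.n_shared_bands + spec.n_specific_uranium]
    c_specific = band_ids[spec.n_shared_bands + spec.n_specific_uranium :]

    lanes = [f"U_{i + 1:02d}" for i in range(spec.n_uranium_lanes)] + [
        f"C_{i + 1:02d}" for i in range(spec.n_control_lanes)
    ]
    groups = pd.Series(
        [GROUP_URANIUM] * spec.n_uranium_lanes + [GROUP_CONTROL] * spec.n_control_lanes,
        index=lanes,
        name="group",
    )

    base = rng.lognormal(spec.log_intensity_mean, spec.log_intensity_sigma, size=n_bands)
    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    else:
        sigma = 0.0

    X = np.zeros((len(lanes), n_bands))
    for li, lane in enumerate(lanes):
        grp = groups[lane]
        for bi, band in enumerate(band_ids):
            present = (
                band in shared
                or (grp == GROUP_URANIUM and band in u_specific)
                or (grp == GROUP_CONTROL and band in c_specific)
            )
            if not present:
                continue
            if spec.dropout > 0 and rng.random() < spec.dropout:
                continue
            noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
            X[li, bi] = base[bi] * noise

    intensities = pd.DataFrame(X, index=lanes, columns=band_ids)
    if (intensities.sum(axis=1) == 0).any():
        raise ValueError("drop-out produced an all-zero lane; lower dropout")

    years = [2006, 2007]
    metadata = pd.DataFrame(
        {
            "site": ["synthetic"] * len(lanes),
            "year": [years[i % 2] for i in range(len(lanes))],
            "replicate": ["abc"[i % 3] for i in range(len(lanes))],
        },
        index=lanes,
    )
    table = BandTable(intensities=intensities, groups=groups, metadata=metadata)
    truth = {GROUP_URANIUM: set(u_specific), GROUP_CONTROL: set(c_specific)}
    return table, truth
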