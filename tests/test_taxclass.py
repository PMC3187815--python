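"""Threshold-ladder consensus classification: ladder semantics, consensus
depth, batch behavior, and recovery of generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from dggetax.seqcore import Seq, SimilarityHit, all_vs_refs
from dggetax.taxclass import (
    DEFAULT_THRESHOLDS,
    ConsensusTaxonomyClassifier,
    Lineage,
    ReferenceDB,
    ThresholdLadder,
    classify,
    classify_batch,
    consensus_lineage,
    hits_at_threshold,
)
from dggetax.synthetic_data import CloneLibrarySpec, make_clone_library

from _oracles import random_dna


def _hit(ref_id, sim):
    return SimilarityHit("q", ref_id, sim, 0.0, 100)


def _mutate_at(seq: str, positions, rng) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestLineage:
    def test_roundtrip_and_depth(self):
        text = "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales;Geobacteraceae;Geobacter"
        lin = Lineage.from_string(text)
        assert lin.to_string() == text
        assert lin.depth == 6
        assert lin.name_at("genus") == "Geobacter"

    def test_partial_lineage_allowed(self):
        lin = Lineage.from_string("Bacteria;Acidobacteria")
        assert lin.depth == 2

    @pytest.mark.parametrize("names", [[], ["Bacteria"] * 8])
    def test_invalid_depths_rejected(self, names):
        with pytest.raises(ValueError):
            Lineage.from_names(names)


class TestThresholdLadder:
    def test_default_is_the_14_step_ladder(self):
        assert ThresholdLadder().thresholds == DEFAULT_THRESHOLDS
        assert len(DEFAULT_THRESHOLDS) == 14

    @pytest.mark.parametrize(
        "ts", [(99, 99), (80, 99), (99, 0), (99, 101), ()]
    )
    def test_invalid_ladders_rejected(self, ts):
        with pytest.raises(ValueError):
            ThresholdLadder(tuple(ts))


class TestHitsAtThreshold:
    def test_boundary_is_inclusive(self):
        hits = [_hit("a", 98.0), _hit("b", 99.2), _hit("c", 100.0), _hit("d", 99.0)]
        kept = hits_at_threshold(hits, 99)
        assert {h.ref_id for h in kept} == {"b", "c", "d"}

    def test_threshold_100_keeps_only_identity(self):
        hits = [_hit("a", 99.9), _hit("b", 100.0)]
        assert [h.ref_id for h in hits_at_threshold(hits, 100)] == ["b"]

    def test_all_below_gives_empty(self):
        assert hits_at_threshold([_hit("a", 79.9)], 80) == []

    def test_subset_monotonicity(self):
        hits = [_hit(f"r{i}", s) for i, s in enumerate([81, 85.5, 90, 95, 99.5])]
        for hi, lo in zip(DEFAULT_THRESHOLDS, DEFAULT_THRESHOLDS[1:]):
            kept_hi = {h.ref_id for h in hits_at_threshold(hits, hi)}
            kept_lo = {h.ref_id for h in hits_at_threshold(hits, lo)}
            assert kept_hi <= kept_lo


class TestConsensusLineage:
    FULL = "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales;Geobacteraceae;Geobacter"

    def test_identical_lineages_keep_full_depth(self):
        lin = Lineage.from_string(self.FULL)
        assert consensus_lineage([lin, lin, lin]).to_string() == self.FULL

    def test_phylum_conflict_leaves_domain_only(self):
        a = Lineage.from_string("Bacteria;Acidobacteria;Acidobacteriia")
        b = Lineage.from_string("Bacteria;Proteobacteria;Deltaproteobacteria")
        assert consensus_lineage([a, b]).to_string() == "Bacteria"

    def test_single_lineage_is_identity(self):
        lin = Lineage.from_string(self.FULL)
        assert consensus_lineage([lin]) == lin

    def test_stops_at_first_disagreeing_rank(self):
        a = Lineage.from_string(self.FULL)
        b = Lineage.from_string(
            "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales;Pelobacteraceae;Pelobacter"
        )
        assert (
            consensus_lineage([a, b]).to_string()
            == "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales"
        )

    def test_cannot_descend_past_shallowest_participant(self):
        full = Lineage.from_string(self.FULL)
        partial = Lineage.from_string("Bacteria;Proteobacteria")
        assert consensus_lineage([full, partial]).to_string() == "Bacteria;Proteobacteria"

    def test_adding_lineages_never_deepens_consensus(self, rng):
        pool = [
            Lineage.from_string(s)
            for s in (
                self.FULL,
                "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales;Geobacteraceae;Pelobacter",
                "Bacteria;Proteobacteria;Alphaproteobacteria",
                "Bacteria;Acidobacteria",
            )
        ]
        for _ in range(20):
            k = int(rng.integers(1, len(pool)))
            subset = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
            extra = pool[int(rng.integers(len(pool)))]
            assert consensus_lineage(subset + [extra]).depth <= consensus_lineage(subset).depth

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            consensus_lineage([])


class TestClassify:
    def test_identical_query_resolves_at_99_with_full_lineage(self, reference_db):
        db, _ = reference_db
        rid = next(iter(db.records))
        ref_seq, lineage = db.records[rid]
        query = Seq("q", ref_seq.residues)
        a = classify(query, db)
        assert a.status == "assigned"
        assert a.resolved_threshold == 99.0
        assert a.consensus.to_string() == lineage.to_string()

    def test_resolution_between_97_and_96(self, rng):
        """Two same-genus references at 96.33% similarity (11/300 planted
        substitutions, disjoint sites) resolve at threshold 96 with a
        genus-level consensus."""
        base = random_dna(rng, 300)
        lin_a = Lineage.from_string("Bacteria;P1;C1;O1;F1;G1")
        lin_b = Lineage.from_string("Bacteria;P1;C1;O1;F1;G1")
        lin_far = Lineage.from_string("Bacteria;P2;C2;O2;F2;G9")
        # scattered substitutions keep the diagonal alignment optimal
        db = ReferenceDB.from_pairs(
            [
                (Seq("refA", _mutate_at(base, range(5, 300, 27), rng)), lin_a),
                (Seq("refB", _mutate_at(base, range(17, 300, 27), rng)), lin_b),
                (Seq("refFar", random_dna(rng, 300)), lin_far),
            ]
        )
        a = classify(Seq("q", base), db)
        assert a.resolved_threshold == 96.0
        assert {h.ref_id for h in a.supporting_hits} == {"refA", "refB"}
        assert {round(h.similarity, 2) for h in a.supporting_hits} == {96.33}
        assert a.consensus.name_at("genus") == "G1"

    def test_dissimilar_query_is_unassigned(self, rng):
        lineage = Lineage.from_string("Bacteria;P1")
        db = ReferenceDB.from_pairs(
            [(Seq(f"r{i}", random_dna(rng, 300)), lineage) for i in range(5)]
        )
        query = Seq("q", random_dna(rng, 300))
        hits = all_vs_refs(query, db.sequences())
        assert all(h.similarity < 80 for h in hits)  # random DNA is far apart
        a = classify(query, db)
        assert a.status == "unassigned"
        assert a.consensus is None
        assert a.resolved_threshold is None
        assert a.supporting_hits == []

    def test_resolved_threshold_is_max_nonempty_step(self, reference_db, small_clone_library):
        """First-nonempty ladder semantics, re-verified from the raw
        similarity vector at every one of the 14 steps."""
        db, _ = reference_db
        clones, _ = small_clone_library
        ladder = ThresholdLadder()
        for query in clones[:10]:
            a = classify(query, db, ladder)
            hits = all_vs_refs(query, db.sequences())
            nonempty = [t for t in ladder if hits_at_threshold(hits, t)]
            if a.status == "assigned":
                assert a.resolved_threshold == max(nonempty)
                retained = hits_at_threshold(hits, a.resolved_threshold)
                assert {h.ref_id for h in retained} == {
                    h.ref_id for h in a.supporting_hits
                }
            else:
                assert nonempty == []


class TestClassifyBatch:
    def test_empty_query_set(self, reference_db):
        db, _ = reference_db
        table, summary = classify_batch([], db)
        assert len(table) == 0
        assert len(summary) == 0

    def test_two_phylum_library_summary(self, reference_db, small_clone_library):
        db, _ = reference_db
        clones, truth = small_clone_library
        table, summary = classify_batch(clones, db)
        assert list(table["query_id"]) == [c.id for c in clones]  # input order
        assigned = table[table["status"] == "assigned"]
        assert summary.sum() == len(assigned)
        # every assigned phylum is a real phylum of the generator truth
        true_phyla = {t.split(";")[1] for t in truth["lineage"]}
        assert set(summary.index) <= true_phyla

    def test_duplicate_query_ids_flagged_not_fatal(self, reference_db):
        db, _ = reference_db
        rid = next(iter(db.records))
        seq = db.records[rid][0]
        queries = [Seq("dup", seq.residues), Seq("dup", seq.residues)]
        table, _ = classify_batch(queries, db)
        assert list(table["status"]) == ["assigned", "failed"]
        assert "duplicate" in table.iloc[1]["note"]


class TestEstimator:
    def test_fit_predict_roundtrip(self, reference_db):
        db, _ = reference_db
        refs = db.sequences()
        lineages = [db.lineage(r.id).to_string() for r in refs]
        clf = ConsensusTaxonomyClassifier().fit(refs, lineages)
        pred = clf.predict([refs[0], refs[-1]])
        assert pred[0] == lineages[0]
        assert pred[-1] == lineages[-1]

    def test_get_set_params(self):
        clf = ConsensusTaxonomyClassifier(thresholds=[99, 90])
        params = clf.get_params()
        assert params["thresholds"] == [99, 90]
        clf.set_params(mismatch_cost=2.0)
        assert clf.mismatch_cost == 2.0

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError):
            ConsensusTaxonomyClassifier().predict([Seq("q", "ACGT")])

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            ConsensusTaxonomyClassifier().fit([], [])


class TestParameterRecovery:
    def test_assigned_depth_shrinks_with_divergence(self, reference_db):
        """Clones at 1% substitution recover their source genus; at 15%
        the mean assigned depth is strictly shallower."""
        db, _ = reference_db
        refs = db.sequences()
        lineages = [db.lineage(r.id) for r in refs]
        clf = ConsensusTaxonomyClassifier().fit(refs, lineages)

        depths = {}
        correct_genus = {}
        for rate in (0.01, 0.15):
            clones, truth = make_clone_library(
                CloneLibrarySpec(n_clones=40, mutation_rate=rate, seed=77), db
            )
            assignments = clf.assign(clones)
            d = [a.consensus.depth if a.consensus else 0 for a in assignments]
            depths[rate] = np.mean(d)
            genus_by_query = dict(zip(truth["query_id"], truth["genus"]))
            ok = [
                a.consensus is not None
                and a.consensus.name_at("genus") == genus_by_query[a.query_id]
                for a in assignments
            ]
            correct_genus[rate] = np.mean(ok)
        assert correct_genus[0.01] >= 0.95
        assert depths[0.15] < depths[0.01]
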