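"""Local alignment, E-values, the RBH rule, PSSM search, and the cascade."""
import math
import random

import numpy as np
import pytest

import copiievo as cv
from copiievo.formats import HitRecord, HitTable, SequenceRecord
from copiievo.search import bitscore, pssm_score

from oracles import sw_brute_force

AA = "ACDEFGHIKLMNPQRSTVWY"


def _hits(candidate, pairs):
    """Build a reverse-hit table from (subject, evalue) pairs."""
    table = HitTable()
    for rank, (subject, e) in enumerate(pairs):
        table.records.append(
            HitRecord(candidate, subject, 50.0, 100, 10, 0, 1, 100, 1, 100, e, 100.0,
                      raw_score=1000 - rank)
        )
    return table


class TestLocalAlign:
    def test_triple_identity_scores_twelve(self):
        # three A:A pairs at +4 each under BLOSUM62
        assert cv.local_align("AAA", "AAA").raw_score == 12

    def test_negative_pair_floors_at_zero(self):
        aln = cv.local_align("W", "P")
        assert aln.raw_score == 0
        assert aln.a_aligned == "" and aln.b_aligned == ""

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cv.local_align("", "MKV")

    def test_score_is_symmetric(self):
        rng = random.Random(7)
        scheme = cv.ScoringScheme()
        for _ in range(30):
            a = "".join(rng.choices(AA, k=rng.randint(3, 12)))
            b = "".join(rng.choices(AA, k=rng.randint(3, 12)))
            assert cv.local_align(a, b, scheme).raw_score == cv.local_align(b, a, scheme).raw_score

    def test_matches_exhaustive_recursion_on_short_pairs(self):
        rng = random.Random(99)
        scheme = cv.ScoringScheme()
        for _ in range(40):
            a = "".join(rng.choices(AA, k=rng.randint(1, 6)))
            b = "".join(rng.choices(AA, k=rng.randint(1, 6)))
            assert cv.local_align(a, b, scheme).raw_score == sw_brute_force(a, b, scheme)


class TestEvalue:
    def test_closed_form(self):
        scheme = cv.ScoringScheme(karlin_K=0.13, karlin_lambda=0.318)
        expected = 0.13 * 100 * 100 * math.exp(-0.318 * 50)
        assert cv.evalue(50, 100, 100, scheme) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_score_and_size(self):
        scheme = cv.ScoringScheme()
        assert cv.evalue(60, 100, 100, scheme) < cv.evalue(50, 100, 100, scheme)
        assert cv.evalue(50, 200, 100, scheme) == pytest.approx(
            2 * cv.evalue(50, 100, 100, scheme)
        )

    def test_vanishes_at_large_score(self):
        assert cv.evalue(10_000, 100, 100) < 1e-300


class TestSearchAll:
    def test_identical_sequence_ranks_first(self):
        db = [
            SequenceRecord("x", "t1", "SG", "C", "MKVLWAALLVTFLAGCQA"),
            SequenceRecord("y", "t2", "SG", "C", "MKVLWAALLVTFLAGCQA"[::-1]),
        ]
        q = SequenceRecord("q", "t3", "SG", "C", "MKVLWAALLVTFLAGCQA")
        table = cv.search_all([q], db)
        assert table.records[0].subject_id == "x"

    def test_single_entry_database(self):
        db = [SequenceRecord("x", "t1", "SG", "C", "MKVLWAALLVTFLAGCQA")]
        table = cv.search_all([db[0]], db)
        assert len(table) <= 1

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            cv.search_all([], [])

    def test_best_nonself_hit_shares_paralog_label(self, small_scaffold):
        """Within a simulated family, nearest neighbors share the true paralog."""
        scn = cv.load_scenario("sec24")
        scn.root_length = 200
        agree = total = 0
        for seed in range(5):
            records, _ = cv.simulate_family(small_scaffold, scn, seed)
            table = cv.search_all(records, records)
            label = {r.id: r.true_paralog for r in records}
            for q in {r.id for r in records}:
                best = next(h for h in table.by_query(q) if h.subject_id != q)
                total += 1
                agree += label[best.subject_id] == label[q]
        assert agree / total >= 0.95


class TestRbhRule:
    def test_clear_margin_is_ortholog(self):
        verdict = cv.rbh_classify("c", None, _hits("c", [("ref", 1e-80), ("other", 1e-20)]), {"ref"})
        assert verdict.is_ortholog and verdict.ratio == pytest.approx(1e60)

    def test_small_margin_unconfirmed(self):
        verdict = cv.rbh_classify("c", None, _hits("c", [("ref", 1e-12), ("other", 1e-11)]), {"ref"})
        assert not verdict.is_ortholog
        assert verdict.reason == "ambiguous-margin"

    def test_wrong_top_hit_unconfirmed_regardless_of_ratio(self):
        verdict = cv.rbh_classify("c", None, _hits("c", [("other", 1e-80), ("ref", 1e-10)]), {"ref"})
        assert not verdict.is_ortholog

    def test_no_hits(self):
        verdict = cv.rbh_classify("c", None, HitTable(), {"ref"})
        assert verdict.reason == "no-hit"

    def test_single_hit_flagged(self):
        verdict = cv.rbh_classify("c", None, _hits("c", [("ref", 1e-30)]), {"ref"})
        assert verdict.is_ortholog and "single-hit" in verdict.flags

    def test_invariant_under_evalue_scaling(self):
        pairs = [("ref", 1e-40), ("x", 1e-35), ("y", 1e-10)]
        for factor in (1.0, 1e5, 1e-5):
            scaled = [(s, e * factor) for s, e in pairs]
            verdict = cv.rbh_classify("c", None, _hits("c", scaled), {"ref"})
            assert verdict.is_ortholog == cv.rbh_classify(
                "c", None, _hits("c", pairs), {"ref"}
            ).is_ortholog

    def test_zero_evalue_top_hit_passes(self):
        verdict = cv.rbh_classify("c", None, _hits("c", [("ref", 0.0), ("x", 1e-50)]), {"ref"})
        assert verdict.is_ortholog


class TestPssm:
    def _family(self, rng, n=6, length=40):
        base = "".join(rng.choices(AA, k=length))
        recs = []
        for i in range(n):
            recs.append(SequenceRecord(f"f{i}", f"t{i}", "SG", "C", base))
        return base, recs

    def test_identical_columns_favor_consensus(self, rng):
        pyrng = random.Random(5)
        base, recs = self._family(pyrng)
        pssm = cv.build_pssm(recs, pseudocount=0.0)
        for j, residue in enumerate(base):
            col = pssm.scores[j]
            assert col.argmax() == AA.find(residue) or col[AA.find(residue)] == col.max()

    def test_large_pseudocount_flattens_scores(self):
        pyrng = random.Random(6)
        _, recs = self._family(pyrng)
        pssm = cv.build_pssm(recs, pseudocount=1e9)
        assert np.abs(pssm.scores).max() < 1e-3

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            cv.build_pssm([SequenceRecord("a", "t", "SG", "C", "MKV")])

    def test_high_gap_columns_dropped(self):
        recs = [
            SequenceRecord("a", "t1", "SG", "C", "M-KV"),
            SequenceRecord("b", "t2", "SG", "C", "M-KV"),
            SequenceRecord("c", "t3", "SG", "C", "MAKV"),
        ]
        pssm = cv.build_pssm(recs, pseudocount=1.0)
        assert pssm.width == 3

    def test_family_members_outscore_shuffled_decoys(self):
        from copiievo.simulate import DEFAULT_MODEL, evolve_sequence

        rng = np.random.default_rng(17)
        pyrng = random.Random(17)
        wins = trials = 0
        for rep in range(20):
            ancestor = "".join(pyrng.choices(AA, k=60))
            members = [
                SequenceRecord(f"m{i}", f"t{i}", "SG", "C",
                               evolve_sequence(ancestor, 0.3, DEFAULT_MODEL, rng))
                for i in range(5)
            ]
            pssm = cv.build_pssm(members[:4], pseudocount=0.5)
            target = pssm_score(pssm, members[4].residues)
            for _ in range(5):
                shuffled = list(members[4].residues)
                pyrng.shuffle(shuffled)
                trials += 1
                wins += target > pssm_score(pssm, "".join(shuffled))
        assert wins / trials >= 0.95

    def test_pssm_search_ranks_by_score(self):
        pyrng = random.Random(8)
        base, recs = self._family(pyrng)
        pssm = cv.build_pssm(recs[:4], pseudocount=0.5, source_id="fam")
        decoy = SequenceRecord("decoy", "tx", "SG", "C", "".join(pyrng.choices(AA, k=40)))
        table = cv.pssm_search(pssm, [decoy, recs[4]])
        assert table.records[0].subject_id == recs[4].id


class TestCascade:
    def _references(self, records, component, taxa):
        by_taxon = {}
        for r in records:
            by_taxon.setdefault(r.taxon, []).append(r)
        out = []
        for t in taxa:
            for ref in by_taxon.get(t, []):
                if ref.component == component:
                    out.append((ref, by_taxon[t]))
        return out

    def test_first_reference_matches_plain_rbh(self, small_sec24_family, small_scaffold):
        records, _ = small_sec24_family
        by_taxon = {}
        for r in records:
            by_taxon.setdefault(r.taxon, []).append(r)
        target = by_taxon["Amo2"]
        refs = self._references(records, "Sec24", ["Amo1"])
        result = cv.cascade_search(target, "Sec24", refs)
        assert result.is_present and result.winning_rank == 1

    def test_provenance_records_winning_reference(self, small_sec24_family):
        records, _ = small_sec24_family
        by_taxon = {}
        for r in records:
            by_taxon.setdefault(r.taxon, []).append(r)
        target = by_taxon["Amo2"]
        dead = SequenceRecord("junk", "zz", "SG", "Sec24", "W" * 50)
        refs = [(dead, [dead])] + self._references(records, "Sec24", ["Amo1"])
        result = cv.cascade_search(target, "Sec24", refs)
        assert result.is_present
        assert result.winning_rank == 2
        assert len(result.attempts) == 2

    def test_exhausted_references_reported_absent(self):
        target = [SequenceRecord("t1_A", "t1", "SG", "A", "MKVLWAALLVTFLAGCQAKVE")]
        ref = SequenceRecord("r_A", "r", "SG", "A", "WWPPWWPPWWPPWWPPWWPP")
        result = cv.cascade_search(target, "A", [(ref, [ref])])
        assert not result.is_present
        assert len(result.attempts) == 1

    def test_cascade_rescues_fast_lineage_missed_by_distant_reference(self):
        """A fast-evolving subtree is found via its neighbor, not the far reference."""
        config = cv.ScaffoldConfig(taxa_per_supergroup=2)
        scaffold = cv.build_scaffold(config)
        scn = cv.Scenario(
            name="fast", component="Sec12", base_paralog="Sec12",
            rate_multipliers=[cv.simulate.RateMultiplier("Excavata", 12.0, stem_only=True)],
            root_length=300,
        )
        cascade_hits = direct_hits = rescued = 0
        for seed in range(12):
            records, _ = cv.simulate_family(scaffold, scn, seed)
            by_taxon = {}
            for r in records:
                by_taxon.setdefault(r.taxon, []).append(r)
            target = by_taxon["Exc2"]
            near = self._references(records, "Sec12", ["Exc1"])
            far = self._references(records, "Sec12", ["Opi1"])
            direct = cv.cascade_search(target, "Sec12", far)
            casc = cv.cascade_search(target, "Sec12", near + far)
            direct_hits += direct.is_present
            cascade_hits += casc.is_present
            rescued += casc.is_present and not direct.is_present
        assert cascade_hits >= direct_hits
        assert rescued >= 1


def test_bitscore_inverts_evalue():
    scheme = cv.ScoringScheme()
    s = 80
    e = cv.evalue(s, 120, 300, scheme)
    bits = bitscore(s, scheme)
    assert e == pytest.approx(120 * 300 * 2 ** -bits, rel=1e-9)
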