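"""ORF scanning, decapeptide matching, motif grammar, cleavage and
pseudogene diagnosis."""

import numpy as np
import pytest
from Bio.Seq import Seq

from kissmine.mining import (
    GenomeSegment,
    PrecursorCandidate,
    classify_amidation,
    diagnose_pseudogene,
    find_orfs,
    predict_cleavage_sites,
    scan_decapeptides,
    score_splice_acceptors,
)

# independent codon translation for the brute-force oracle
_ORACLE_CODE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _ORACLE_CODE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


def _oracle_orfs(seq: str, min_len_nt: int):
    """Brute-force six-frame stop-to-stop scan, written independently of
    the implementation (own codon table, explicit coordinate arithmetic)."""
    out = set()
    L = len(seq)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    for strand in "+-":
        s = seq if strand == "+" else "".join(comp[c] for c in reversed(seq))
        for frame in range(3):
            codons = [
                s[p : p + 3]
                for p in range(frame, L - 2, 3)
            ]
            run = []
            run_start = frame
            pos = frame
            for c in codons:
                aa = _ORACLE_CODE.get(c, "X") if "N" not in c else "X"
                if aa == "*":
                    if 3 * len(run) >= min_len_nt:
                        a, b = run_start, run_start + 3 * len(run)
                        if strand == "-":
                            a, b = L - b, L - a
                        out.add((strand, a, b, "".join(run)))
                    run = []
                    run_start = pos + 3
                else:
                    run.append(aa)
                pos += 3
            if 3 * len(run) >= min_len_nt:
                a, b = run_start, run_start + 3 * len(run)
                if strand == "-":
                    a, b = L - b, L - a
                out.add((strand, a, b, "".join(run)))
    return out


class TestFindOrfs:
    def test_hand_example(self):
        seg = GenomeSegment(id="s", species="x", sequence="TAAAAATTTTAA")
        orfs = [
            o
            for o in find_orfs(seg, min_len_nt=6)
            if o.strand == "+" and o.frame == 0
        ]
        assert len(orfs) == 1
        orf = orfs[0]
        assert orf.aa_translation == "KF"
        assert (orf.start, orf.end) == (3, 9)
        assert orf.length_nt == 6

    def test_stop_free_99nt_single_orf(self):
        seq = "ATG" + "GCT" * 32  # 99 nt without stop in frame 0
        seg = GenomeSegment(id="s", species="x", sequence=seq)
        frame0 = [
            o for o in find_orfs(seg, min_len_nt=99) if o.strand == "+" and o.frame == 0
        ]
        assert len(frame0) == 1
        assert frame0[0].length_nt == 99
        assert len(frame0[0].aa_translation) == 33

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            GenomeSegment(id="s", species="x", sequence="")
        seg = GenomeSegment(id="s", species="x", sequence="AT")
        assert find_orfs(seg, min_len_nt=3) == []

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            GenomeSegment(id="s", species="x", sequence="ACGTQ")

    def test_n_codons_do_not_terminate(self):
        # frame 0: AAA NNN AAA -> KXK, one 9 nt ORF
        seg = GenomeSegment(id="s", species="x", sequence="AAANNNAAA")
        orfs = [
            o for o in find_orfs(seg, min_len_nt=9) if o.strand == "+" and o.frame == 0
        ]
        assert orfs[0].aa_translation == "KXK"

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=1500, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        seg = GenomeSegment(id="s", species="x", sequence=seq)
        got = {
            (o.strand, o.start, o.end, o.aa_translation)
            for o in find_orfs(seg, min_len_nt=30)
        }
        assert got == _oracle_orfs(seq, 30)

    @pytest.mark.parametrize("seed", range(3))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        rc = str(Seq(seq).reverse_complement())
        seg = GenomeSegment(id="s", species="x", sequence=seq)
        seg_rc = GenomeSegment(id="s", species="x", sequence=rc)
        L = len(seq)
        fwd = {
            (o.strand, o.start, o.end, o.aa_translation)
            for o in find_orfs(seg, min_len_nt=30)
        }
        mirrored = {
            ({"+": "-", "-": "+"}[o.strand], L - o.end, L - o.start, o.aa_translation)
            for o in find_orfs(seg_rc, min_len_nt=30)
        }
        assert fwd == mirrored


class TestScanDecapeptides:
    def _orf(self, translation):
        return type(
            "Orf",
            (),
            {
                "aa_translation": translation,
                "segment_id": "s",
                "strand": "+",
                "start": 0,
                "end": 3 * len(translation),
                "frame": 0,
                "bounded_5": True,
                "bounded_3": True,
                "length_nt": 3 * len(translation),
            },
        )()

    def test_exact_match_scores_self(self):
        hits = scan_decapeptides(
            self._orf("AAAFNFNPFGLRFAAA"), {"q": "FNFNPFGLRF"}, rel_threshold=0.9
        )
        assert len(hits) == 1
        exact = hits[0]
        selfscore = scan_decapeptides(
            self._orf("FNFNPFGLRF"), {"q": "FNFNPFGLRF"}, rel_threshold=1.0
        )[0].score
        assert exact.score == selfscore
        assert exact.best_query == "q"
        assert exact.conserved_position_substitutions == []

    def test_substitutions_positions_2_and_9(self):
        hits = scan_decapeptides(
            self._orf("FIFNPFGLGF"), {"q": "FNFNPFGLRF"}, rel_threshold=0.4
        )
        subs = {(p, e, o) for p, e, o in hits[0].conserved_position_substitutions}
        assert subs == {(2, "N", "I"), (9, "R", "G")}

    def test_substitution_position_6(self):
        hits = scan_decapeptides(
            self._orf("FKVNLLGLGF"), {"q": "FNFNPFGLRF"}, rel_threshold=0.3
        )
        subs = dict(
            (p, (e, o)) for p, e, o in hits[0].conserved_position_substitutions
        )
        assert subs[6] == ("F", "L")

    def test_wrong_query_length_rejected(self):
        with pytest.raises(ValueError):
            scan_decapeptides(self._orf("FNFNPFGLRF"), {"q": "SHORT"})

    @pytest.mark.parametrize("seed", range(3))
    def test_lowering_threshold_never_removes_hits(self, seed):
        rng = np.random.default_rng(seed)
        translation = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        orf = self._orf(translation)
        queries = {"a": "FNFNPFGLRF", "b": "YNWNSFGLRY"}
        prev = None
        for thr in (0.8, 0.6, 0.4, 0.2, 0.05):
            offsets = {h.offset for h in scan_decapeptides(orf, queries, rel_threshold=thr)}
            if prev is not None:
                assert prev <= offsets
            prev = offsets


class TestAmidationGrammar:
    @pytest.mark.parametrize(
        "context, expected",
        [
            ("GKR", "canonical"),
            ("GRR", "canonical"),
            ("GKL", "degenerate"),
            ("GKG", "degenerate"),
            ("GA", "degenerate"),
            ("AKR", "absent"),
            ("", "absent"),
        ],
    )
    def test_grammar(self, context, expected):
        translation = "XXXXGLRF" + context
        assert classify_amidation(translation, 8) == expected

    def test_g_basic_then_stop(self):
        assert classify_amidation("XXXXGLRFGR", 8, stop_after_orf=True) == "stop_type"
        assert classify_amidation("XXXXGLRFGR", 8, stop_after_orf=False) == "absent"


class TestCleavage:
    def test_single_site_length_53(self):
        translation = "AAKR" + "A" * 43 + "FNFNPFGLRF" + "GKR"
        sites, peptides = predict_cleavage_sites(translation, 47)
        assert sites == [2]
        assert [p.length for p in peptides] == [53]
        assert peptides[0].sequence.endswith("FNFNPFGLRF")

    def test_two_variants_53_and_12(self):
        # dibasic pairs placed to yield mature peptides of 53 and 12 residues
        translation = "KR" + "A" * 39 + "KK" + "A" * 2 + "FNFNPFGLRF" + "GKR"
        sites, peptides = predict_cleavage_sites(translation, 45)
        assert sorted(p.length for p in peptides) == [12, 53]
        assert [p.length for p in peptides] == [53, 12]  # longest first

    def test_no_basic_residues(self):
        sites, peptides = predict_cleavage_sites("A" * 20 + "FNFNPFGLRF", 20)
        assert sites == [] and peptides == []


class TestSpliceAcceptors:
    def test_all_pyrimidine_tract(self):
        dna = "TTCTTCCTTTCC" + "AG" + "A" * 4
        sites = score_splice_acceptors(dna, (0, len(dna)), min_cv=80)
        assert len(sites) == 1
        assert sites[0].consensus_value == 100.0
        assert sites[0].position == 12

    def test_nine_of_twelve_rejected_at_80(self):
        dna = "TTCTTCCTTAAA" + "AG" + "A" * 4
        assert score_splice_acceptors(dna, (0, len(dna)), min_cv=80) == []
        sites = score_splice_acceptors(dna, (0, len(dna)), min_cv=70)
        assert sites and sites[0].consensus_value == 75.0

    def test_purine_tract_scores_zero(self):
        dna = "AAAAAAAAAAAA" + "AG"
        assert score_splice_acceptors(dna, (0, len(dna)), min_cv=0) == []

    def test_short_interval_empty(self):
        assert score_splice_acceptors("TTTTTTTTTTAG", (0, 12), min_cv=0) == []


class TestPseudogeneDiagnosis:
    def _candidate(self, orf_nt, subs, sites, amid, upstream):
        orf = type(
            "Orf",
            (),
            {"length_nt": orf_nt, "bounded_5": True},
        )()
        hit = type(
            "Hit",
            (),
            {
                "orf": orf,
                "amidation_class": amid,
                "conserved_position_substitutions": subs,
            },
        )()
        return PrecursorCandidate(
            hit=hit,
            cleavage_sites=sites,
            upstream_stop_distance_nt=upstream,
        )

    def test_mallard_like_degenerate(self):
        cand = self._candidate(
            orf_nt=99,
            subs=[(2, "N", "I"), (9, "R", "G")],
            sites=[],
            amid="canonical",
            upstream=36,
        )
        diagnose_pseudogene(cand)
        assert cand.pseudogene_flags == {
            "short_orf",
            "no_dibasic_cleavage",
            "conserved_substitutions",
            "close_upstream_stop",
        }
        assert cand.verdict == "degenerate"

    def test_turtle_like_intact(self):
        cand = self._candidate(
            orf_nt=528, subs=[], sites=[10], amid="canonical", upstream=300
        )
        diagnose_pseudogene(cand)
        assert cand.pseudogene_flags == set()
        assert cand.verdict == "intact"

    def test_disabled_thresholds_always_intact(self):
        cand = self._candidate(
            orf_nt=30, subs=[(2, "N", "I"), (6, "F", "L")], sites=[1],
            amid="canonical", upstream=3,
        )
        diagnose_pseudogene(
            cand, short_orf_nt=0, close_stop_nt=0, max_conserved_subs=10**9
        )
        assert cand.verdict == "intact"


class TestMinerRecovery:
    def test_intact_implants_recall_precision_one(self, intact_genome, kp10):
        segments, truth = intact_genome
        from kissmine.mining import mine_genome

        found = {
            (c.hit.orf.segment_id, c.hit.orf.strand, c.hit.window_start_nt,
             c.hit.window_end_nt)
            for c in mine_genome(segments, kp10)
        }
        expected = {
            (g.segment_id, g.strand, *g.decapeptide_interval)
            for g in truth.implanted_genes
            if g.decapeptide_interval is not None
        }
        assert found == expected  # recall and precision both exactly 1

    def test_intact_implants_canonical_and_mature_length(self, intact_genome, kp10):
        segments, truth = intact_genome
        from kissmine.mining import mine_genome

        by_pos = {
            (c.hit.orf.segment_id, c.hit.window_start_nt): c
            for c in mine_genome(segments, kp10)
        }
        for g in truth.implanted_genes:
            if g.decapeptide_interval is None:
                continue
            cand = by_pos[(g.segment_id, g.decapeptide_interval[0])]
            assert cand.hit.window == g.decapeptide
            assert cand.hit.amidation_class == "canonical"
            assert g.mature_length in [p.length for p in cand.mature_peptides]
            assert cand.verdict == "intact"

    def test_degraded_implants_expected_flags(self, degraded_genome):
        segments, truth = degraded_genome
        from kissmine.mining import mine_genome

        queries = {
            g.gene_type + str(i): g.decapeptide
            for i, g in enumerate(truth.implanted_genes)
        }
        by_pos = {
            (c.hit.orf.segment_id, c.hit.window_start_nt): c
            for c in mine_genome(segments, queries)
        }
        expected_flag = {
            "premature_stop": "close_upstream_stop",
            "motif_substitution": "conserved_substitutions",
            "cleavage_loss": "no_dibasic_cleavage",
            "amidation_degeneration": "degenerate_amidation",
        }
        for g in truth.implanted_genes:
            cand = by_pos[(g.segment_id, g.decapeptide_interval[0])]
            assert expected_flag[g.degradation] in cand.pseudogene_flags

    def test_premature_stop_distance_recorded(self, degraded_genome):
        segments, truth = degraded_genome
        from kissmine.mining import mine_genome

        g = next(t for t in truth.implanted_genes if t.degradation == "premature_stop")
        assert g.upstream_stop_distance_nt == 36
        cand = next(
            c
            for c in mine_genome(segments, {"q": g.decapeptide})
            if c.hit.orf.segment_id == g.segment_id
            and c.hit.window_start_nt == g.decapeptide_interval[0]
        )
        assert cand.upstream_stop_distance_nt == 36
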