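"""PWM scoring/scanning vs exhaustive oracles, top-K selection, consensus search."""

import itertools

import numpy as np
import pytest

import mircircuit as mc
from mircircuit.motifs import IUPAC_CODES, reverse_complement_pattern
from conftest import random_dna, revcomp_oracle


def score_oracle(probs, background, window):
    """Direct per-position log2 odds sum, independent of the vectorized path."""
    total = 0.0
    for i, base in enumerate(window):
        if base not in "ACGT":
            return float("-inf")
        b = "ACGT".index(base)
        total += np.log2(probs[i][b] / background[b])
    return total


def scan_oracle(pwm, seq, offset0=0):
    """Brute-force both-strand scan of a sequence: (start, strand, score)."""
    L = len(pwm)
    out = []
    for i in range(len(seq) - L + 1):
        win = seq[i : i + L]
        for strand, w in (("+", win), ("-", revcomp_oracle(win))):
            s = score_oracle(pwm.probs, pwm.background, w)
            if np.isfinite(s):
                out.append((offset0 + i, strand, s))
    return out


def random_pwm(rng, L=None, name="M"):
    L = L or int(rng.integers(4, 10))
    counts = rng.integers(0, 20, size=(L, 4)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1.0
    return mc.pwm_from_counts(mc.MotifMatrixRecord(name, counts), pseudocount=0.25)


class TestPwmFromCounts:
    def test_pure_column_no_pseudocount(self):
        rec = mc.MotifMatrixRecord("m", np.array([[4.0, 0, 0, 0]]))
        pwm = mc.pwm_from_counts(rec, pseudocount=0)
        assert np.allclose(pwm.probs, [[1, 0, 0, 0]])

    def test_flat_column_any_pseudocount(self):
        rec = mc.MotifMatrixRecord("m", np.array([[1.0, 1, 1, 1]]))
        for pc in (0.0, 0.25, 3.0):
            assert np.allclose(mc.pwm_from_counts(rec, pc).probs, 0.25)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng)
            assert np.allclose(pwm.probs.sum(axis=1), 1.0)
            assert (pwm.probs > 0).all()


class TestLogOddsScore:
    def test_background_pwm_scores_zero(self):
        rec = mc.MotifMatrixRecord("m", np.ones((5, 4)))
        pwm = mc.pwm_from_counts(rec)
        for w in ("ACGTA", "TTTTT", "GCGCG"):
            assert mc.log_odds_score(pwm, w) == pytest.approx(0.0)

    def test_single_position_certain_base(self):
        rec = mc.MotifMatrixRecord("m", np.array([[4.0, 0, 0, 0]]))
        pwm = mc.pwm_from_counts(rec, pseudocount=0)
        assert mc.log_odds_score(pwm, "A") == pytest.approx(2.0)  # log2(4)

    def test_length_mismatch(self):
        pwm = mc.pwm_from_counts(mc.MotifMatrixRecord("m", np.ones((3, 4))))
        with pytest.raises(ValueError, match="length"):
            mc.log_odds_score(pwm, "ACGT")

    def test_max_over_all_words_is_argmax_word(self, rng):
        pwm = random_pwm(rng, L=6)
        best_word = "".join("ACGT"[int(np.argmax(row))] for row in pwm.probs)
        best = max(
            mc.log_odds_score(pwm, "".join(w))
            for w in itertools.product("ACGT", repeat=6)
        )
        assert best == pytest.approx(mc.log_odds_score(pwm, best_word))


class TestScanRegion:
    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(900 + trial)
        seq = random_dna(rng, 300, "ACGTN" if trial % 4 == 0 else "ACGT")
        genome = {"c": mc.GenomeSequence("c", seq)}
        pwm = random_pwm(rng)
        region = mc.GenomicInterval("c", 0, len(seq))
        hits = mc.scan_region(pwm, region, genome)
        got = sorted((h.site.start, h.strand, h.score) for h in hits)
        expected = sorted(scan_oracle(pwm, seq))
        assert len(got) == len(expected)
        for (gs, gd, gv), (es, ed, ev) in zip(got, expected):
            assert (gs, gd) == (es, ed)
            assert gv == pytest.approx(ev, abs=1e-9)

    def test_planted_consensus_is_top_hit(self, rng):
        word = "CCATGTTA"
        counts = np.zeros((8, 4))
        for i, b in enumerate(word):
            counts[i, "ACGT".index(b)] = 10
        pwm = mc.pwm_from_counts(mc.MotifMatrixRecord("m", counts))
        seq = random_dna(rng, 150, "AG") + word + random_dna(rng, 150, "AG")
        genome = {"c": mc.GenomeSequence("c", seq)}
        hits = mc.scan_region(pwm, mc.GenomicInterval("c", 0, len(seq)), genome)
        assert hits[0].site.start == 150 and hits[0].strand == "+"

    def test_all_n_region_empty(self):
        genome = {"c": mc.GenomeSequence("c", "N" * 60)}
        pwm = random_pwm(np.random.default_rng(0))
        assert mc.scan_region(pwm, mc.GenomicInterval("c", 0, 60), genome) == []

    def test_region_shorter_than_pwm(self):
        genome = {"c": mc.GenomeSequence("c", "ACGTACGT")}
        pwm = random_pwm(np.random.default_rng(0), L=6)
        assert mc.scan_region(pwm, mc.GenomicInterval("c", 0, 3), genome) == []

    def test_revcomp_region_mirrors_hits(self, rng):
        seq = random_dna(rng, 200)
        pwm = random_pwm(rng, L=5)
        g1 = {"c": mc.GenomeSequence("c", seq)}
        g2 = {"c": mc.GenomeSequence("c", revcomp_oracle(seq))}
        region = mc.GenomicInterval("c", 0, 200)
        h1 = mc.scan_region(pwm, region, g1)
        h2 = mc.scan_region(pwm, region, g2)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (200 - h.site.end, flip[h.strand], round(h.score, 9)) for h in h2
        )
        original = sorted((h.site.start, h.strand, round(h.score, 9)) for h in h1)
        assert original == mirrored


class TestSelectTopK:
    def _hits(self, rng, n, distinct=True):
        scores = rng.permutation(n).astype(float) if distinct else rng.integers(0, 5, n)
        out = []
        for i in range(n):
            iv = mc.GenomicInterval(f"c{int(rng.integers(1, 4))}", 10 * i + 1, 10 * i + 9)
            out.append(mc.MotifHit(f"M{i % 3}", "pri", iv, "+", float(scores[i]), 0))
        return out

    def test_fewer_than_k_returns_all(self, rng):
        hits = self._hits(rng, 10)
        assert len(mc.select_top_k(hits, 500)) == 10

    def test_selects_k_largest(self, rng):
        hits = self._hits(rng, 1000)
        top = mc.select_top_k(hits, 500)
        assert len(top) == 500
        assert min(h.score for h in top) == 500.0  # scores are 0..999

    def test_ties_match_sort_oracle_and_invariance(self, rng):
        hits = self._hits(rng, 200, distinct=False)
        oracle = sorted(
            hits, key=lambda h: (-h.score, h.site.chrom, h.site.start, h.strand, h.pwm_id)
        )[:50]
        top = mc.select_top_k(hits, 50)
        assert top == oracle
        shuffled = [hits[i] for i in rng.permutation(len(hits))]
        assert mc.select_top_k(shuffled, 50) == top  # permutation-invariant
        assert mc.select_top_k(top, 50) == top  # idempotent

    def test_k_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            mc.select_top_k(self._hits(rng, 5), 0)


def consensus_oracle(pattern, seq):
    """Brute-force IUPAC match on both strands."""
    def matches(p, w):
        return len(p) == len(w) and all(
            c in "ACGT" and c in IUPAC_CODES[q] for q, c in zip(p, w)
        )

    L = len(pattern)
    rc = reverse_complement_pattern(pattern)
    out = []
    for i in range(len(seq) - L + 1):
        w = seq[i : i + L]
        if matches(pattern, w):
            out.append((i, "+"))
        if matches(rc, w):
            out.append((i, "-"))
    return sorted(out)


class TestConsensusScan:
    def test_n_wildcard(self):
        genome = {"c": mc.GenomeSequence("c", "CCATGTTA")}
        assert mc.consensus_scan("CCATNTTN", mc.GenomicInterval("c", 0, 8), genome) == [(0, "+")]

    def test_reverse_strand_match(self, rng):
        pattern = "CCATCTTG"
        seq = random_dna(rng, 80, "AG") + revcomp_oracle(pattern) + random_dna(rng, 80, "AG")
        genome = {"c": mc.GenomeSequence("c", seq)}
        hits = mc.consensus_scan(pattern, mc.GenomicInterval("c", 0, len(seq)), genome)
        assert hits == [(80, "-")]

    def test_tiny_region_no_match(self):
        genome = {"c": mc.GenomeSequence("c", "ACG")}
        assert mc.consensus_scan("CCATNTTN", mc.GenomicInterval("c", 0, 3), genome) == []

    def test_invalid_code(self, tiny_genome):
        with pytest.raises(ValueError, match="IUPAC"):
            mc.consensus_scan("CCAT!TTN", mc.GenomicInterval("chr1", 0, 8), tiny_genome)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_oracle(self, trial):
        rng = np.random.default_rng(1300 + trial)
        pattern = "".join(rng.choice(list(IUPAC_CODES), size=int(rng.integers(4, 8))))
        seq = random_dna(rng, 400, "ACGTN" if trial % 3 == 0 else "ACGT")
        genome = {"c": mc.GenomeSequence("c", seq)}
        got = mc.consensus_scan(pattern, mc.GenomicInterval("c", 0, len(seq)), genome)
        assert got == consensus_oracle(pattern, seq)


class TestSiteCountsPerMirna:
    def _annotation(self, rows):
        transcripts, multimap = [], {}
        for pri, matures in rows:
            iv = mc.GenomicInterval("c", 0, 100)
            transcripts.append(mc.PrimiRNATranscript(pri, matures, iv, iv))
            for m in matures:
                multimap.setdefault(m, []).append(pri)
        return mc.Annotation(transcripts, multimap)

    def _hit(self, pri):
        return mc.MotifHit("M", pri, mc.GenomicInterval("c", 0, 8), "+", 1.0, 0)

    def test_no_hits_all_zero(self):
        annot = self._annotation([("p1", ["mA"]), ("p2", ["mB"])])
        assert mc.site_counts_per_mirna([], annot) == {"mA": 0, "mB": 0}

    def test_single_locus_count(self):
        annot = self._annotation([("p1", ["mA"])])
        counts = mc.site_counts_per_mirna([self._hit("p1"), self._hit("p1")], annot)
        assert counts == {"mA": 2}

    def test_two_loci_sum(self):
        annot = self._annotation([("p1", ["mA"]), ("p2", ["mA", "mB"])])
        hits = [self._hit("p1")] + [self._hit("p2")] * 3
        counts = mc.site_counts_per_mirna(hits, annot)
        assert counts["mA"] == 4 and counts["mB"] == 3

    def test_unknown_transcript(self):
        annot = self._annotation([("p1", ["mA"])])
        with pytest.raises(KeyError, match="ghost"):
            mc.site_counts_per_mirna([self._hit("ghost")], annot)


class TestPlantedMotifRecovery:
    def test_topk_hits_concentrate_in_target_regions(self):
        """Consensus instances planted only in target promoters: >= 90% of the
        top-K hits (K = number planted) fall inside target search regions."""
        rng = np.random.default_rng(7)
        # a 10-nt informative consensus keeps the expected number of chance
        # exact occurrences over the scanned space near zero, so the top-K
        # content measures recovery rather than tie-breaking luck
        syn = mc.SyntheticStudyConfig(
            n_mirnas=40, n_probes=40, n_target_mirnas=4, sites_per_target=5,
            motif_consensus="CCATGTTACG", rng_seed=7,
        )
        from mircircuit.simulate import make_genome_with_promoters, consensus_count_matrix

        genome, annot, targets, truth = make_genome_with_promoters(syn, rng)
        pwm = mc.pwm_from_counts(consensus_count_matrix(syn.motif_consensus))
        scorer = mc.GCZScoreScorer.from_genome(genome)
        hits = []
        target_pris = {p for m in targets for p in annot.mature_to_pri[m]}
        for t in annot.transcripts:
            core = mc.refine_core_promoter(t, genome, scorer=scorer)
            region = mc.promoter_search_region(core, 15_000, genome[t.promoter.chrom].length)
            hits.extend(mc.scan_region(pwm, region, genome, transcript=t.pri_id))
        k = len(truth)
        top = mc.select_top_k(hits, k)
        in_target = sum(h.transcript in target_pris for h in top)
        assert in_target / k >= 0.9
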