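"""Read scanning heuristics, evidence tallying, likelihoods, calls, evaluation."""

import numpy as np
import pytest

import markergt as mg
from markergt.genotyping import SiteTally, reverse_complement

from conftest import make_hap_panel


def _random_seq(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def snv_index():
    """2 kb reference, one SNV at offset 1000 carried by H1 of two haplotypes."""
    ref = _random_seq(2000, seed=42)
    alt = "A" if ref[1000] != "A" else "C"
    panel = make_hap_panel(ref, [(1000, ref[1000], [alt], [1, 0])], n_haplotypes=2)
    return mg.MarkerIndex.build(panel, w=19)


@pytest.fixture(scope="module")
def params():
    return mg.ScanParams(w=19, min_seed_len=80, strand_seed=7)


class TestGenotypeRead:
    def test_exact_read_across_variant_yields_single_alt_evidence(self, snv_index, params):
        h1 = mg.haplotype_sequence(snv_index.panel, 1)
        read = h1[950:1050]
        evidence = mg.genotype_read(snv_index.fm, snv_index.maw, read, params)
        assert evidence == [((0, 1000), 1)]

    def test_reverse_complement_read_recovers_same_evidence(self, snv_index, params):
        h1 = mg.haplotype_sequence(snv_index.panel, 1)
        read = reverse_complement(h1[950:1050])
        evidence = mg.genotype_read(snv_index.fm, snv_index.maw, read, params)
        assert evidence == [((0, 1000), 1)]

    def test_reference_read_yields_null_allele_evidence(self, snv_index, params):
        ref_read = snv_index.panel.reference_seqs[0][950:1050]
        evidence = mg.genotype_read(snv_index.fm, snv_index.maw, ref_read, params)
        assert evidence == [((0, 1000), 0)]

    def test_all_n_read_yields_nothing(self, snv_index, params):
        assert mg.genotype_read(snv_index.fm, snv_index.maw, "N" * 100, params) == []

    def test_read_shorter_than_min_seed_yields_nothing(self, snv_index, params):
        h1 = mg.haplotype_sequence(snv_index.panel, 1)
        assert mg.genotype_read(snv_index.fm, snv_index.maw, h1[980:1040], params) == []

    def test_site_observed_once_per_read(self, snv_index, params):
        # a long read crosses several w-checkpoints over the same marker
        h1 = mg.haplotype_sequence(snv_index.panel, 1)
        read = h1[880:1030]
        evidence = mg.genotype_read(snv_index.fm, snv_index.maw, read, params)
        sites = [site for site, _ in evidence]
        assert len(sites) == len(set(sites)) == 1

    def test_deterministic_given_seed_and_ordinal(self, snv_index, params):
        h1 = mg.haplotype_sequence(snv_index.panel, 1)
        read = h1[950:1050]
        a = mg.genotype_read(snv_index.fm, snv_index.maw, read, params, read_ordinal=5)
        b = mg.genotype_read(snv_index.fm, snv_index.maw, read, params, read_ordinal=5)
        assert a == b

    def test_chimeric_cross_chromosome_read_is_discarded(self):
        refA, refB = _random_seq(1000, seed=1), _random_seq(1000, seed=2)
        variants = [
            mg.VariantRecord(0, 960, refA[960], ["A" if refA[960] != "A" else "C"],
                             np.array([1], np.int16)),
            mg.VariantRecord(1, 40, refB[40], ["A" if refB[40] != "A" else "C"],
                             np.array([1], np.int16)),
        ]
        panel = mg.HaplotypePanel(["chrA", "chrB"], [refA, refB], variants, 1)
        idx = mg.MarkerIndex.build(panel, w=19)
        h1 = mg.haplotype_sequence(panel, 1)
        # 120 bp spanning the chrA|chrB junction inside one document: matches
        # as a single extension whose evidence covers two chromosomes
        read = h1[940:1060]
        params = mg.ScanParams(w=19, min_seed_len=80, strand_seed=3)
        exts = mg.genotyping.scan_strand(idx.fm, idx.maw, read, params, idx.n_h)
        assert any(len(e.chroms_seen) > 1 and e.matched_len >= 80 for e in exts)
        assert mg.genotype_read(idx.fm, idx.maw, read, params) == []

    def test_evidence_within_fl_oracle_for_matched_substring(self, snv_index, params):
        h1 = mg.haplotype_sequence(snv_index.panel, 1)
        read = h1[930:1080]
        exts = mg.genotyping.scan_strand(snv_index.fm, snv_index.maw, read, params, snv_index.n_h)
        for ext in exts:
            if not ext.accept(params.min_seed_len):
                continue
            oracle = {
                (mg.decode_marker(w)[0], mg.decode_marker(w)[1], mg.decode_marker(w)[2])
                for _, w in mg.fl_marker_query(snv_index.fm, snv_index.dense, ext.matched_seq)
            }
            for (chrom, off), allele in ext.evidence:
                assert (chrom, off, allele) in oracle


class TestTallyEvidence:
    def test_counting_all_reference(self):
        tallies = mg.tally_evidence([[((0, 5), 0)]] * 10)
        t = tallies[(0, 5)]
        assert (t.k, t.l) == (10, 10)

    def test_mixed_ref_and_alt(self):
        stream = [[((0, 5), 0)]] * 5 + [[((0, 5), 1)]] * 5
        t = mg.tally_evidence(stream)[(0, 5)]
        assert (t.k, t.l) == (10, 5)
        assert t.alt_counts[1] == 5

    def test_k_splits_into_l_plus_alt_counts(self):
        stream = [[((0, 1), a)] for a in [0, 1, 2, 1, 0, 2, 2]]
        t = mg.tally_evidence(stream)[(0, 1)]
        assert t.k == t.l + sum(t.alt_counts.values())


class TestGenotypeLikelihood:
    def test_epsilon_to_zero_limits(self):
        eps = 1e-15
        k = 7
        assert mg.genotype_likelihood(2, k, k, eps) == pytest.approx(1.0, abs=1e-12)
        assert mg.genotype_likelihood(1, k, k, eps) == pytest.approx(2.0**-k, rel=1e-12)
        assert mg.genotype_likelihood(0, k, k, eps) < 1e-12

    def test_homozygous_alt_dominates_all_ref_observations(self):
        l2 = mg.genotype_likelihood(2, 10, 10, 0.01)
        l1 = mg.genotype_likelihood(1, 10, 10, 0.01)
        assert l2 == pytest.approx(0.99**10, abs=1e-15)
        assert l1 == pytest.approx(2.0**-10, abs=1e-15)
        assert l2 > l1 > mg.genotype_likelihood(0, 10, 10, 0.01)

    def test_heterozygous_dominates_balanced_observations(self):
        l1 = mg.genotype_likelihood(1, 10, 5, 0.01)
        l2 = mg.genotype_likelihood(2, 10, 5, 0.01)
        assert l1 == pytest.approx(2.0**-10, abs=1e-15)
        assert l2 == pytest.approx(0.5**10 * (2 * 0.99) ** 5 * (2 * 0.01) ** 5, rel=1e-9)
        assert l1 > l2

    def test_het_is_argmax_for_balanced_counts_only(self):
        # L(1) = 2^-k for any l; it wins exactly when both homozygotes are implausible
        def argmax_g(l):
            vals = [mg.genotype_likelihood(g, 20, l, 0.01) for g in (0, 1, 2)]
            return max(range(3), key=lambda g: (vals[g], g))

        assert argmax_g(10) == 1
        assert argmax_g(0) == 0
        assert argmax_g(20) == 2

    def test_binomial_weighted_sum_is_proper(self):
        from math import comb

        for g in (0, 1, 2):
            total = sum(
                comb(8, l) * mg.genotype_likelihood(g, 8, l, 0.05) for l in range(9)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_domain_violations_are_fatal(self):
        for bad in [(3, 5, 5, 0.01), (1, 5, 6, 0.01), (1, 5, 5, 0.0), (1, 5, 5, 1.0)]:
            with pytest.raises(ValueError):
                mg.genotype_likelihood(*bad)


class TestCallers:
    @staticmethod
    def _tally(k, l, alt=1):
        t = SiteTally((0, 0))
        for _ in range(l):
            t.add(0)
        for _ in range(k - l):
            t.add(alt)
        return t

    @pytest.mark.parametrize("k,l,expected_g", [(20, 20, 2), (20, 0, 0), (20, 10, 1), (0, 0, 2)])
    def test_diploid_argmax_and_no_evidence_default(self, k, l, expected_g):
        calls = mg.call_diploid({(0, 0): self._tally(k, l)})
        assert calls[0].g == expected_g
        assert calls[0].g == max(range(3), key=lambda g: (calls[0].likelihoods[g], g))

    def test_haploid_majority_and_ref_tie(self):
        assert mg.call_haploid({(0, 0): self._tally(8, 3)})[0][1] == 1   # alt 5 > ref 3
        assert mg.call_haploid({(0, 0): self._tally(8, 4)})[0][1] == 0   # 4 = 4 tie
        assert mg.call_haploid({(0, 0): self._tally(0, 0)})[0][1] == 0   # no evidence


class TestEvaluateCalls:
    def test_precision_recall_arithmetic(self):
        truth = {(0, i): 1 for i in range(10)}          # 10 truly alt sites
        calls = [((0, i), 1) for i in range(9)] + [((0, 99), 1)]
        truth[(0, 99)] = 0                              # called alt, truly ref
        truth[(0, 9)] = 1                               # missed -> REF call
        rep = mg.evaluate_calls(calls, truth, "haploid")
        row = rep.row("All")
        assert (row.tp, row.fp, row.fn) == (9, 1, 1)
        assert row.precision == row.recall == row.f1 == pytest.approx(0.9)

    def test_het_call_at_hom_ref_site_rules(self):
        call = mg.GenotypeCall((0, 0), 1, (0.1, 0.8, 0.1), 1)
        alt = mg.evaluate_calls([call], {(0, 0): 2}, "alt_allele").row("All")
        assert (alt.tp, alt.fp, alt.fn, alt.tn) == (0, 1, 0, 1)
        het = mg.evaluate_calls([call], {(0, 0): 2}, "het_site").row("All")
        assert (het.tp, het.fp, het.fn, het.tn) == (0, 1, 0, 0)

    def test_perfect_calls_score_one(self):
        truth = {(0, i): g for i, g in enumerate([0, 1, 2, 1, 0])}
        calls = [mg.GenotypeCall((0, i), g, (0, 0, 0), 1) for i, g in enumerate([0, 1, 2, 1, 0])]
        for level in ("alt_allele", "het_site"):
            row = mg.evaluate_calls(calls, truth, level).row("All")
            assert row.precision == row.recall == 1.0

    def test_called_site_missing_from_truth_is_fatal(self):
        with pytest.raises(ValueError, match="missing from truth"):
            mg.evaluate_calls([((0, 7), 1)], {(0, 0): 0}, "haploid")

    def test_stratification_splits_by_variant_class(self):
        truth = {(0, 0): 1, (0, 1): 1}
        classes = {(0, 0): "SNV", (0, 1): "SV"}
        calls = [mg.GenotypeCall((0, 0), 1, (0, 0, 0), 1)]
        rep = mg.evaluate_calls(calls, truth, "het_site", classes)
        assert rep.row("SNV").tp == 1
        assert rep.row("SV").fn == 1
        assert rep.row("All").tp == 1 and rep.row("All").fn == 1


class TestWriteCallsVcf:
    def test_gt_conventions_and_round_trip(self, tmp_path):
        ref = _random_seq(300, seed=3)
        alt0 = "A" if ref[50] != "A" else "C"
        alt1 = "G" if ref[120] != "G" else "T"
        panel = make_hap_panel(
            ref, [(50, ref[50], [alt0], [1, 0]), (120, ref[120], [alt1], [0, 1])], 2
        )
        calls = [
            mg.GenotypeCall((0, 50), 1, (0.01, 0.9, 0.09), 1),
            mg.GenotypeCall((0, 120), 2, (0.0, 0.1, 0.9), 1),
        ]
        out = str(tmp_path / "calls.vcf")
        mg.write_calls_vcf(calls, panel, out)
        body = [l for l in open(out) if not l.startswith("#")]
        assert body[0].split("\t")[9].startswith("0/1")
        assert body[1].split("\t")[9].startswith("0/0")

        fa = tmp_path / "ref.fa"
        fa.write_text(f">chr1\n{ref}\n")
        reparsed = mg.parse_panel(out, str(fa), min_af=None, require_phased=False)
        assert {(v.chrom_id, v.ref_pos) for v in reparsed.variants} == {(0, 50), (0, 120)}
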