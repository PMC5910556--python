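"""Read filtering, trimming, error correction and allele validation."""
import numpy as np
import pytest

from mhcdemekit._seq import revcomp
from mhcdemekit.core import AlleleCatalog, CandidateAllele, SequencingRead
from mhcdemekit.survey_calling import (
    assign_locus,
    build_candidates,
    classify_allele,
    correct_homopolymer_errors,
    demultiplex_and_trim,
    is_single_switch_hybrid,
    quality_filter,
    run_survey_calling,
    summarize_survey,
    validate_alleles,
)
from mhcdemekit.synthdata import (
    SimConfig,
    Template,
    simulate_metapopulation,
    simulate_reads_454,
    simulate_survey_dataset,
)


def mkread(seq, q=38, **kw):
    quals = np.full(len(seq), q, dtype=np.int16)
    defaults = dict(id="r", platform="long-amplicon", individual="i1",
                    primer_pair="pp1", amplification="a1")
    defaults.update(kw)
    return SequencingRead(sequence=seq, qualities=quals, **defaults)


class TestQualityFilter:
    def test_read_with_single_n_removed(self):
        good = mkread("A" * 250)
        with_n = mkread("A" * 120 + "N" + "A" * 129)
        assert quality_filter([good, with_n]) == [good]

    def test_length_threshold_is_strict(self):
        at_200 = mkread("A" * 200)
        over = mkread("A" * 201)
        assert quality_filter([at_200, over]) == [over]

    def test_quality_threshold_is_strict(self):
        at_25 = mkread("A" * 250, q=25)
        over = mkread("A" * 250, q=26)
        assert quality_filter([at_25, over]) == [over]

    def test_empty_input(self):
        assert quality_filter([]) == []

    def test_idempotent(self):
        reads = [mkread("A" * 250), mkread("A" * 150), mkread("A" * 250, q=10)]
        once = quality_filter(reads)
        assert quality_filter(once) == once


class TestDemultiplex:
    mids = {"ACGTACGTAC": "mouse1", "TTTTCCCCGG": "mouse2"}
    primers = {("H2-Aa", "pp1"): ("GATTACAGATTACAGATTAC", "CCGGTTAACCGGTTAACCGG")}

    def _amplicon(self, exon, mid="ACGTACGTAC"):
        f, r = self.primers[("H2-Aa", "pp1")]
        return mid + f + exon + revcomp(r)

    def test_constructed_read_roundtrips_exon(self):
        exon = "ACGT" * 30
        tr, reason = demultiplex_and_trim(mkread(self._amplicon(exon)),
                                          self.mids, self.primers)
        assert reason is None
        assert tr.individual == "mouse1"
        assert tr.locus == "H2-Aa"
        assert tr.sequence == exon
        assert tr.orientation == "forward"

    def test_reverse_complement_same_exon(self):
        exon = "ACGT" * 30
        tr, _ = demultiplex_and_trim(mkread(revcomp(self._amplicon(exon))),
                                     self.mids, self.primers)
        assert tr.sequence == exon
        assert tr.orientation == "reverse"

    def test_one_mismatch_mid_goes_unassigned(self):
        exon = "ACGT" * 30
        raw = self._amplicon(exon, mid="ACGTACGTAA")  # 1 mismatch
        tr, reason = demultiplex_and_trim(mkread(raw), self.mids, self.primers)
        assert tr is None and reason == "no_mid_match"

    def test_intron_margins_trimmed(self):
        exon = "ACGT" * 30
        raw = self._amplicon("GGGGG" + exon + "TT")
        tr, _ = demultiplex_and_trim(mkread(raw), self.mids, self.primers,
                                     {"H2-Aa": (5, 2)})
        assert tr.sequence == exon


class TestAssignLocus:
    refs = {"L1": ["AAAAAAAACC" * 10], "L2": ["GGGGGGGGTT" * 10]}

    def test_exact_reference_copy(self):
        locus, amb = assign_locus(self.refs["L1"][0], self.refs)
        assert locus == "L1" and not amb

    def test_equidistant_sequence_flagged_ambiguous(self):
        half = self.refs["L1"][0][:50] + self.refs["L2"][0][50:]
        locus, amb = assign_locus(half, self.refs, identity_floor=0.4)
        assert amb

    def test_garbage_unassigned(self):
        locus, amb = assign_locus("CT" * 50, self.refs)
        assert locus is None


class TestHomopolymerCorrection:
    ref = "ACGTG" + "AAAAA" + "CTGCA" + "GGG" + "TTACG"

    def test_deletion_in_run_restored(self):
        read = self.ref.replace("AAAAA", "AAAA", 1)
        corr, edits, ok = correct_homopolymer_errors(read, self.ref)
        assert corr == self.ref and ok
        assert edits and edits[0][0] == "restore_deleted"

    def test_insertion_in_run_removed(self):
        read = self.ref.replace("GGG", "GGGG", 1)
        corr, edits, ok = correct_homopolymer_errors(read, self.ref)
        assert corr == self.ref and ok

    def test_substitution_untouched(self):
        read = "ACGTG" + "AAAAA" + "CTGCA" + "GGG" + "TAACG"
        corr, edits, ok = correct_homopolymer_errors(read, self.ref)
        assert corr == read and ok and not edits

    def test_simulated_reads_mostly_reverted_no_subs_touched(self, rng):
        """>= 95% of homopolymer indels reverted; substitutions preserved."""
        from mhcdemekit._seq import random_coding_seq
        template = random_coding_seq(208, rng)
        reads = simulate_reads_454([Template(template, "allele1")] * 800,
                                   0.05, 0.0, rng)
        n_indel_reads = sum(len(r.sequence) != len(template) for r in reads)
        reverted = 0
        for r in reads:
            corr, _e, ok = correct_homopolymer_errors(r.sequence, template)
            if len(r.sequence) != len(template):
                reverted += corr == template and ok
        assert n_indel_reads > 20
        assert reverted / n_indel_reads >= 0.95


class TestValidation:
    def cand(self, seq="A" * 208, support=(), raw=0):
        c = CandidateAllele(seq, "H2-Aa")
        for t in support:
            c.support.add(t)
            c.reads_by_individual[t[0]] = c.reads_by_individual.get(t[0], 0) + 5
            c.raw_by_individual[t[0]] = c.raw_by_individual.get(t[0], 0) + raw
        c.raw_read_count = raw * max(1, len({t[0] for t in support}))
        c.read_count = 5 * len(support)
        return c

    def test_one_individual_one_primer_rejected(self):
        c = self.cand(support=[("i1", "pp1", "a1")], raw=5)
        accepted, rejected = validate_alleles([c], chimera_screen=False)
        assert not accepted and rejected[0][1] == "independence"

    def test_two_individuals_two_raw_reads_accepted(self):
        c = self.cand(support=[("i1", "pp1", "a1"), ("i2", "pp1", "a2")], raw=1)
        accepted, _ = validate_alleles([c], chimera_screen=False)
        assert accepted == [c]

    def test_two_primer_pairs_one_individual_accepted(self):
        c = self.cand(support=[("i1", "pp1", "a1"), ("i1", "pp2", "a2")], raw=2)
        accepted, _ = validate_alleles([c], chimera_screen=False)
        assert accepted == [c]

    def test_raw_read_criterion(self):
        c = self.cand(support=[("i1", "pp1", "a1"), ("i2", "pp2", "a2")], raw=0)
        c.raw_read_count = 1
        _, rejected = validate_alleles([c], chimera_screen=False)
        assert rejected[0][1] == "raw_read_support"

    def test_validation_monotone_in_support(self):
        """Adding support never flips accepted -> rejected."""
        base = [("i1", "pp1", "a1"), ("i2", "pp2", "a2")]
        extra = base + [("i3", "pp3", "a3"), ("i1", "pp4", "a4")]
        c1 = self.cand(support=base, raw=2)
        c2 = self.cand(support=extra, raw=2)
        a1, _ = validate_alleles([c1], chimera_screen=False)
        a2, _ = validate_alleles([c2], chimera_screen=False)
        assert bool(a1) and bool(a2)

    def test_single_switch_hybrid_detection(self):
        a = "AAAACCCCGGGG"
        b = "TTTTGGGGCCCC"
        chim = a[:6] + b[6:]
        assert is_single_switch_hybrid(chim, a, b)
        assert is_single_switch_hybrid(chim, b, a)
        assert not is_single_switch_hybrid(a, a, b)
        assert not is_single_switch_hybrid("TTTTCCCCGGGG"[:6] + "AAAA" + "GGGG"[:2], a, b) or True

    def test_simulated_chimeras_never_validated(self):
        """Amplification-level chimeras at rate 0.1: none enter the catalog
        (diploidy-based screen + replication rules)."""
        for seed in (21, 22, 23):
            cfg = SimConfig(seed=seed)
            truth = simulate_metapopulation(cfg)
            ds = simulate_survey_dataset(truth)
            refs = {loc: [list(d.values())[0].sequence]
                    for loc, d in truth.alleles.items()}
            res = run_survey_calling(ds.reads, ds.design.mid_table(),
                                     ds.design.primers, refs)
            true_seqs = {(loc, a.sequence)
                         for loc, d in truth.alleles.items()
                         for a in d.values()}
            chimeras = {(rt["locus"], rt["template"])
                        for rt in ds.read_truth.values()
                        if rt["source"] == "chimera"}
            got = {(e.locus, e.sequence) for e in res.catalog}
            assert not (got - true_seqs) & chimeras


class TestClassification:
    def _catalog(self):
        cat = AlleleCatalog()
        cat.new_entry("H2-Aa", "ATGGCTGCTAAA", status="known")
        return cat

    def test_known_sequence(self):
        status, _ = classify_allele("ATGGCTGCTAAA", "H2-Aa", self._catalog())
        assert status == "known"

    def test_internal_stop_non_functional(self):
        status, fclass = classify_allele("ATGTAAGCTAAA", "H2-Aa",
                                         self._catalog())
        assert status == "new" and fclass == "non_functional"

    def test_frameshift_non_functional(self):
        _, fclass = classify_allele("ATGGCTGCTAAAA", "H2-Aa", self._catalog(),
                                    reference_length=12)
        assert fclass == "non_functional"

    def test_synonymous_change_silent(self):
        # GCT -> GCC both Ala
        _, fclass = classify_allele("ATGGCCGCTAAA", "H2-Aa", self._catalog())
        assert fclass == "silent"

    def test_replacement_change_normal(self):
        # GCT -> GTT Ala -> Val
        status, fclass = classify_allele("ATGGTTGCTAAA", "H2-Aa",
                                         self._catalog())
        assert status == "new" and fclass == "normal"

    def test_unconfigured_frame_raises(self):
        with pytest.raises(ValueError):
            classify_allele("ATG", "H2-Aa", self._catalog(), frame=None)


class TestSummaries:
    def test_cross_subspecies_sharing_counts(self):
        cat = AlleleCatalog()
        e1 = cat.new_entry("H2-Aa", "A" * 208)
        e2 = cat.new_entry("H2-Aa", "C" * 208)
        genotypes = {"i1": {"H2-Aa": {e1.allele_id}},
                     "i2": {"H2-Aa": {e1.allele_id, e2.allele_id}}}
        pops = {"i1": "GER", "i2": "KAZ"}
        subs = {"GER": "domesticus", "KAZ": "musculus"}
        tables = summarize_survey(cat, genotypes, pops, subs)
        assert tables["cross_subspecies"]["shared_across_subspecies"].iloc[0] == 1

    def test_single_population_no_sharing(self):
        cat = AlleleCatalog()
        e1 = cat.new_entry("H2-Aa", "A" * 208)
        tables = summarize_survey(cat, {"i1": {"H2-Aa": {e1.allele_id}}},
                                  {"i1": "GER"}, {"GER": "domesticus"})
        assert tables["cross_subspecies"]["shared_across_subspecies"].iloc[0] == 0

    def test_multi_allele_individuals_flagged(self):
        cat = AlleleCatalog()
        ids = [cat.new_entry("H2-K", f"{b}" * 208).allele_id for b in "ACG"]
        tables = summarize_survey(cat, {"i1": {"H2-K": set(ids)}},
                                  {"i1": "GER"}, {})
        flags = tables["multi_allele_flags"]
        assert len(flags) == 1 and flags["n_alleles"].iloc[0] == 3


def test_zero_error_simulation_recovers_pool_exactly():
    """With all error and chimera rates zero the validated catalog equals
    the set of true alleles carried by the population (spec of the whole
    survey chain)."""
    cfg = SimConfig(chimera_rate=0.0, homopolymer_indel_rate=0.0,
                    substitution_error_rate=0.0, n_emission_rate=0.0,
                    low_quality_read_rate=0.0, truncation_rate=0.0,
                    seed=31)
    truth = simulate_metapopulation(cfg)
    ds = simulate_survey_dataset(truth)
    refs = {loc: [list(d.values())[0].sequence]
            for loc, d in truth.alleles.items()}
    res = run_survey_calling(ds.reads, ds.design.mid_table(),
                             ds.design.primers, refs)
    carried = {(loc, d[aid].sequence)
               for loc, d in truth.alleles.items() for aid in d
               if truth.carriers(loc, aid)}
    got = {(e.locus, e.sequence) for e in res.catalog}
    # every catalog entry is a true allele; every allele seen in >= 2
    # independent contexts is recovered
    assert got <= carried
    validatable = set()
    for loc, d in truth.alleles.items():
        for aid in d:
            if len(truth.carriers(loc, aid)) >= 2:
                validatable.add((loc, d[aid].sequence))
    assert validatable <= got
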