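import numpy as np
import pytest

from plastcomp.plastome_io import AnnotatedGenome, Feature, Msa
from plastcomp.simulate import DEFAULT_SUBST_RATES, mini_config, simulate
from plastcomp.variants import (
    IndelEvent,
    build_consensus,
    call_variants,
    indel_events,
    longest_indels,
    pairwise_differences,
)

from conftest import random_seq


class TestConsensus:
    def test_majority(self):
        m = Msa(["a", "b", "c"], ["ACGT", "ACGT", "ACGA"])
        assert build_consensus(m).sequence == "ACGT"

    def test_gap_ignored_in_vote(self):
        m = Msa(["a", "b"], ["A-", "AA"])
        assert build_consensus(m).sequence == "AA"

    def test_tie_breaks_alphabetically(self):
        m = Msa(["a", "b"], ["AT", "TA"])
        assert build_consensus(m).sequence == "AA"

    def test_all_gap_columns_dropped_with_mapping(self):
        m = Msa(["a", "b"], ["A--T", "A--T"])
        cons = build_consensus(m)
        assert cons.sequence == "AT"
        assert list(cons.cons_to_col) == [0, 3]
        assert list(cons.col_to_cons) == [0, -1, -1, 1]

    def test_consensus_votes_back_the_ancestor(self):
        """With no indels, alignment columns are exactly the ancestral sites
        and the consensus reproduces the ancestor wherever the derived allele
        stays below 50% (i.e. almost everywhere)."""
        cfg = mini_config(seed=77,
                          indel_freqs={k: 0.0 for k in
                                       ("CDS", "tRNA", "rRNA", "intron", "IGS")})
        res = simulate(cfg)
        cons = build_consensus(res.msa, res.ingroup)
        anc = res.truth.ancestor_reduced
        assert len(cons.sequence) == res.msa.n_cols
        n = len(anc)
        mismatch = sum(a != b for a, b in zip(cons.sequence[:n], anc))
        # only sites where >half the ingroup carries the same derived base
        # may differ; at these rates that is a per-mille phenomenon
        assert mismatch / n < 0.005


def _toy_annotated():
    rng = np.random.default_rng(30)
    seq = random_seq(rng, 60)
    feats = [
        Feature("gene", "g1", ((5, 25),)),
        Feature("CDS", "g1", ((5, 15), (20, 25))),
        Feature("intron", "g1", ((15, 20),)),
        Feature("gene", "t1", ((35, 45),)),
        Feature("tRNA", "t1", ((35, 45),)),
    ]
    return AnnotatedGenome("ref", seq, circular=True, features=feats)


class TestCallVariants:
    def test_identical_rows_no_variants(self):
        g = _toy_annotated()
        m = Msa(["ref", "b", "c"], [g.sequence] * 3, "ref")
        vt = call_variants(m, g)
        assert vt.n_snps == 0 and vt.n_indel_sites == 0
        assert (vt.summary()[["snp_count", "indel_count"]].to_numpy() == 0).all()

    def test_class_lengths_partition_consensus(self):
        g = _toy_annotated()
        m = Msa(["ref", "b"], [g.sequence, g.sequence], "ref")
        s = call_variants(m, g).summary().set_index("region")
        total = s.loc["Consensus", "length_bp"]
        parts = s.loc[["CDS", "tRNA", "rRNA", "Intron", "IGS"], "length_bp"].sum()
        assert parts == total
        gene = s.loc[["CDS", "tRNA", "rRNA", "Intron"], "length_bp"].sum()
        assert gene == s.loc["Gene", "length_bp"]

    def test_hand_counted_sites(self):
        g = _toy_annotated()
        row2 = list(g.sequence)
        row2[6] = "A" if row2[6] != "A" else "C"    # SNP in CDS
        row2[37] = "-"                               # indel in tRNA
        m = Msa(["ref", "b", "c"], [g.sequence, "".join(row2), g.sequence], "ref")
        vt = call_variants(m, g)
        s = vt.summary().set_index("region")
        assert vt.n_snps == 1 and vt.n_indel_sites == 1
        assert s.loc["CDS", "snp_count"] == 1
        assert s.loc["tRNA", "indel_count"] == 1

    def test_row_order_and_duplicate_invariance(self):
        g = _toy_annotated()
        row2 = list(g.sequence)
        row2[6] = "A" if row2[6] != "A" else "C"
        rows = [g.sequence, "".join(row2), g.sequence]
        vt1 = call_variants(Msa(["ref", "b", "c"], rows, "ref"), g)
        vt2 = call_variants(Msa(["ref", "c", "b"],
                                [rows[0], rows[2], rows[1]], "ref"), g)
        assert (vt1.snp_sites == vt2.snp_sites).all()
        vt3 = call_variants(
            Msa(["ref", "b", "c", "d"], rows + [g.sequence], "ref"), g)
        assert (vt1.snp_sites == vt3.snp_sites).all()
        assert (vt1.indel_sites == vt3.indel_sites).all()

    def test_snp_counts_sum_over_classes(self, mini_sim):
        ref = mini_sim.genomes[mini_sim.reference_id]
        vt = call_variants(mini_sim.msa, ref, ingroup=mini_sim.ingroup)
        s = vt.summary().set_index("region")
        assert (s.loc[["CDS", "tRNA", "rRNA", "Intron", "IGS"], "snp_count"].sum()
                == s.loc["Consensus", "snp_count"])

    def test_unknown_ingroup_raises(self, mini_sim):
        ref = mini_sim.genomes[mini_sim.reference_id]
        with pytest.raises(KeyError):
            call_variants(mini_sim.msa, ref, ingroup=["nope"])


class TestClassRateRecovery:
    def test_igs_versus_cds_ratio_single_run(self):
        """With IGS substitution probability ~2.5x CDS, the measured class
        frequencies recover the ratio within wide binomial bounds."""
        cfg = mini_config(seed=41, lsc_len=20_000, ir_len=3_000, ssc_len=5_000)
        res = simulate(cfg)
        ref = res.genomes[res.reference_id]
        s = call_variants(res.msa, ref, ingroup=res.ingroup).summary().set_index("region")
        ratio = s.loc["IGS", "snp_freq_pct"] / s.loc["CDS", "snp_freq_pct"]
        true_ratio = DEFAULT_SUBST_RATES["IGS"] / DEFAULT_SUBST_RATES["CDS"]
        assert 0.6 * true_ratio < ratio < 1.6 * true_ratio

    def test_snp_frequency_unbiased_over_replicates(self):
        """Aggregated over 50 seeded replicates, per-class SNP-site frequency
        matches the configured per-class polymorphism probability within 3
        binomial standard errors."""
        counts = {"CDS": 0, "IGS": 0}
        lengths = {"CDS": 0, "IGS": 0}
        for seed in range(50):
            cfg = mini_config(seed=1000 + seed,
                              indel_freqs={k: 0.0 for k in
                                           ("CDS", "tRNA", "rRNA", "intron", "IGS")})
            res = simulate(cfg)
            ref = res.genomes[res.reference_id]
            s = call_variants(res.msa, ref,
                              ingroup=res.ingroup).summary().set_index("region")
            for cls in counts:
                counts[cls] += s.loc[cls, "snp_count"]
                lengths[cls] += s.loc[cls, "length_bp"]
        for cls in counts:
            p = DEFAULT_SUBST_RATES[cls]
            n = lengths[cls]
            se = np.sqrt(p * (1 - p) / n)
            phat = counts[cls] / n
            assert abs(phat - p) < 3 * se, (cls, phat, p, se)


class TestPairwise:
    def test_identical_rows(self):
        m = Msa(["a", "b"], ["ACGTAC", "ACGTAC"])
        assert pairwise_differences(m, "a", "b")[:2] == (0, 0)

    def test_hand_counted_snp_and_indel(self):
        m = Msa(["a", "b"], ["AACCGG", "AATC-G"])
        n_snp, n_ev, evs = pairwise_differences(m, "a", "b")
        assert n_snp == 1 and n_ev == 1
        assert evs[0].length == 1 and evs[0].gapped_samples == {"b"}

    def test_third_sample_insertion_does_not_split_event(self):
        # c's insertion sits inside b's 4-column deletion
        m = Msa(["a", "b", "c"],
                ["AAAAAA--AAAA", "AA------AAAA", "AAAAAACCAAAA"])
        n_snp, n_ev, evs = pairwise_differences(m, "a", "b")
        assert n_ev == 1 and evs[0].length == 4

    def test_unknown_sample_raises(self):
        m = Msa(["a", "b"], ["AC", "AC"])
        with pytest.raises(KeyError):
            pairwise_differences(m, "a", "zzz")


class TestIndelEvents:
    def test_longest_indels_ordering(self):
        evs = [IndelEvent(0, 3, 3, frozenset({"x"})),
               IndelEvent(10, 397, 387, frozenset({"x"})),
               IndelEvent(500, 884, 384, frozenset({"x"}))]
        top = longest_indels(evs, 3)
        assert [e.length for e in top] == [387, 384, 3]
        assert longest_indels(evs, 1)[0].length == 387
        with pytest.raises(ValueError):
            longest_indels(evs, 0)

    def test_event_extraction_groups_by_gap_pattern(self):
        m = Msa(["a", "b", "c"], ["AAAA--AA", "AA----AA", "AAAAAAAA"])
        evs = indel_events(m)
        patterns = {(e.start_col, e.end_col): e.gapped_samples for e in evs}
        assert patterns == {(2, 4): frozenset({"b"}), (4, 6): frozenset({"a", "b"})}

    def test_planted_long_deletion_recovered(self):
        """A planted clade-stem deletion is the top-ranked event and lands in
        its target gene."""
        cfg = mini_config(
            seed=55, lsc_len=20_000, ir_len=3_000, ssc_len=5_000,
            planted_indels=[("ycf2-like", 400, "stem_Acnida")],
        )
        res = simulate(cfg)
        ref = res.genomes[res.reference_id]
        n_snp, n_ev, evs = pairwise_differences(
            res.msa, "Acnida_1", "Albersia_1", annotation=ref)
        top = longest_indels(evs, 1)[0]
        assert 395 <= top.length <= 410
        assert top.feature == "ycf2-like"
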