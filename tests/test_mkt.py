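import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from oracles import fisher_by_column_enumeration
from gscortho import synthetic_data as sd
from gscortho.mkt import (
    CodonAlignment,
    apply_frequency_filter,
    build_mkt,
    consensus,
    fisher_two_tailed,
    mkt_from_alignment,
    parsimony_ancestor,
    read_codon_alignment,
    tabulate_changes,
)


def aln(ingroup, ancestor, outgroup=None):
    return CodonAlignment(ingroup=list(ingroup), ancestor=ancestor, outgroup=outgroup)


class TestTabulateChanges:
    def test_fixed_synonymous_lysine_codon(self):
        res = tabulate_changes(aln(["AAA"] * 4, "AAG"))
        (ch,) = res.changes
        assert ch.kind == "fixed"
        assert (ch.synonymous, ch.nonsynonymous) == (1.0, 0.0)

    def test_polymorphic_nonsynonymous_with_frequency(self):
        res = tabulate_changes(aln(["AAA"] * 9 + ["AAC"], "AAA"))
        (ch,) = res.changes
        assert ch.kind == "polymorphic"
        assert (ch.synonymous, ch.nonsynonymous) == (0.0, 1.0)  # K -> N
        assert ch.minor_allele_frequency == pytest.approx(0.10)

    def test_monomorphic_ancestral_column_yields_nothing(self):
        res = tabulate_changes(aln(["ATGAAA"] * 3, "ATGAAA"))
        assert res.changes == [] and res.excluded_codons == []

    def test_two_step_difference_averaged_over_pathways(self):
        # AAA -> AGG: both orders give one synonymous + one nonsynonymous step
        res = tabulate_changes(aln(["AGG"] * 4, "AAA"))
        (ch,) = res.changes
        assert ch.synonymous == pytest.approx(1.0)
        assert ch.nonsynonymous == pytest.approx(1.0)

    def test_pathway_through_stop_codon_excluded(self):
        # TTA -> TAT: the TAA intermediate is a stop, leaving only the
        # TTA -> TTT -> TAT pathway: two nonsynonymous steps
        res = tabulate_changes(aln(["TAT"] * 4, "TTA"))
        (ch,) = res.changes
        assert (ch.synonymous, ch.nonsynonymous) == (0.0, 2.0)

    def test_internal_ancestor_stop_is_error(self):
        with pytest.raises(ValueError, match="stop"):
            tabulate_changes(aln(["AAATTT"] * 2, "TAATTT"))

    def test_terminal_shared_stop_codon_tolerated(self):
        res = tabulate_changes(aln(["AAATAA"] * 2, "AAGTAA"))
        (ch,) = res.changes
        assert ch.kind == "fixed" and ch.synonymous == 1.0

    def test_ingroup_stop_allele_excludes_codon_with_warning(self):
        with pytest.warns(UserWarning, match="stop"):
            res = tabulate_changes(aln(["AAA", "AAA", "TAA"], "AAA"))
        assert res.changes == [] and res.excluded_codons == [0]

    def test_gap_codons_excluded_and_reported(self):
        res = tabulate_changes(aln(["---AAA", "AAAAAA"], "AAAAAA"))
        assert res.excluded_codons == [0]

    def test_sub_codon_gap_rejected(self):
        with pytest.raises(ValueError, match="whole codons"):
            aln(["A--AAA", "AAAAAA"], "AAAAAA")


class TestFrequencyFilter:
    def test_boundary_is_strict_less_than(self):
        cs = sd.simulate_codon_set(
            60, 50, sd.PlantedChanges(poly_nonsyn=(0.10,), poly_syn=(0.12,)), seed=5
        )
        res = tabulate_changes(aln(cs.ingroup, cs.ancestor))
        kept = apply_frequency_filter(res.changes, cutoff=0.12)
        assert len(res.changes) == 2
        assert len(kept) == 1
        assert kept[0].minor_allele_frequency == pytest.approx(0.12)

    def test_cutoff_zero_is_identity(self):
        cs = sd.simulate_codon_set(
            40, 10, sd.PlantedChanges(2, 3, (0.2, 0.3), (0.1,)), seed=6
        )
        res = tabulate_changes(aln(cs.ingroup, cs.ancestor))
        assert apply_frequency_filter(res.changes, 0.0) == res.changes

    def test_fixed_changes_untouched_by_any_cutoff(self):
        cs = sd.simulate_codon_set(40, 10, sd.PlantedChanges(4, 6), seed=7)
        res = tabulate_changes(aln(cs.ingroup, cs.ancestor))
        assert apply_frequency_filter(res.changes, 0.5) == res.changes

    @settings(max_examples=30)
    @given(st.lists(st.sampled_from([0.1, 0.2, 0.3, 0.4, 0.5]), max_size=5))
    def test_raising_cutoff_never_increases_counts(self, freqs):
        cs = sd.simulate_codon_set(
            40, 10, sd.PlantedChanges(poly_nonsyn=tuple(freqs)), seed=11
        )
        res = tabulate_changes(aln(cs.ingroup, cs.ancestor))
        previous = float("inf")
        for cutoff in (0.0, 0.15, 0.25, 0.45):
            n = len(apply_frequency_filter(res.changes, cutoff))
            assert n <= previous
            previous = n


class TestBuildMKT:
    def test_planted_neutral_table_recovered_exactly(self):
        cs = sd.simulate_codon_set(
            80, 10, sd.PlantedChanges(5, 10, (0.5,) * 4, (0.5,) * 8), seed=3
        )
        table = mkt_from_alignment(aln(cs.ingroup, cs.ancestor), freq_cutoff=0.0)
        assert (table.Dn, table.Ds, table.Pn, table.Ps) == (5.0, 10.0, 4.0, 8.0)
        assert table.ni == pytest.approx(1.0)
        assert table.alpha == pytest.approx(0.0)

    def test_strong_selection_alpha(self):
        table = build_mkt([])
        # direct arithmetic on a (20, 5, 2, 10) table
        from gscortho.mkt import SiteChange

        changes = (
            [SiteChange(i, "fixed", 0, 1) for i in range(20)]
            + [SiteChange(100 + i, "fixed", 1, 0) for i in range(5)]
            + [SiteChange(200 + i, "polymorphic", 0, 1, 0.3) for i in range(2)]
            + [SiteChange(300 + i, "polymorphic", 1, 0, 0.3) for i in range(10)]
        )
        table = build_mkt(changes)
        assert table.alpha == pytest.approx(0.95)
        assert table.ni == pytest.approx(0.05)

    def test_all_zero_table_has_undefined_ratios_and_p_one(self):
        table = build_mkt([])
        assert table.p_value == 1.0
        assert table.ni is None and table.alpha is None


class TestFisherTwoTailed:
    def test_symmetric_table_p_one(self):
        assert fisher_two_tailed(((1, 1), (1, 1))) == 1.0

    def test_fully_crossed_table_enumeration(self):
        # margins (5,5,5,5): extreme tables have probability 1/252 each
        assert fisher_two_tailed(((0, 5), (5, 0))) == pytest.approx(2 / 252)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(((1, -1), (2, 3)))

    @settings(max_examples=300)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_matches_column_margin_enumeration(self, a, b, c, d):
        assert fisher_two_tailed(((a, b), (c, d))) == pytest.approx(
            fisher_by_column_enumeration(a, b, c, d), abs=1e-12
        )

    def test_matches_scipy_on_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 9, size=4)
            mine = fisher_two_tailed(((a, b), (c, d)))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, rel=1e-9)


class TestAncestorFallback:
    def test_two_way_agreement_resolves(self):
        anc, unresolved = parsimony_ancestor("ACGT", "ACGA", "ACGA")
        assert anc == "ACGA" and unresolved == []

    def test_three_way_disagreement_unresolved(self):
        anc, unresolved = parsimony_ancestor("A", "C", "G")
        assert anc == "N" and unresolved == [0]

    def test_consensus_majority_with_tie_break(self):
        assert consensus(["AAT", "AAT", "AAC"]) == "AAT"
        assert consensus(["AC", "AG"]) == "AC"  # alphabetical tie-break


class TestAlignmentIO:
    def test_role_tagged_fasta_round_trip(self, tmp_path):
        cs = sd.simulate_codon_set(20, 4, sd.PlantedChanges(1, 1), seed=2)
        p = tmp_path / "aln.fasta"
        records = [f">in{i} role=ingroup\n{s}" for i, s in enumerate(cs.ingroup)]
        records.append(f">anc role=ancestor\n{cs.ancestor}")
        records.append(f">out role=outgroup\n{cs.outgroup}")
        p.write_text("\n".join(records) + "\n")
        parsed = read_codon_alignment(p)
        assert parsed.ingroup == cs.ingroup
        assert parsed.ancestor == cs.ancestor
        assert parsed.outgroup == cs.outgroup

    def test_missing_ancestor_rejected(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nAAA\n>b\nAAA\n")
        with pytest.raises(ValueError, match="ancestor"):
            read_codon_alignment(p)
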