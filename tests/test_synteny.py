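import pytest

from gscortho import io_core, synthetic_data as sd, synteny
from gscortho.rbbh import RBBHCall, Thresholds
from gscortho.synteny import (
    CONTRADICTED,
    NOT_VALIDATED,
    VALIDATED_ABSENT,
    AnchorSet,
    SyntenyConfig,
    classify_absence,
    flanking_anchors,
    in_silico_validation,
    locate_block,
    rescue_search,
)


@pytest.fixture(scope="module")
def linear_reference():
    return sd.random_reference(n_genes=10, n_contigs=1, seed=23)


class TestFlankingAnchors:
    def test_interior_gene_three_anchors_each_side(self, linear_reference):
        anchors = flanking_anchors("g005", linear_reference, k=3)
        assert [g.gene_id for g in anchors.upstream] == ["g004", "g003", "g002"]
        assert [g.gene_id for g in anchors.downstream] == ["g006", "g007", "g008"]
        assert not anchors.truncated

    def test_first_gene_has_empty_upstream_and_flag(self, linear_reference):
        anchors = flanking_anchors("g001", linear_reference, k=3)
        assert anchors.upstream == []
        assert [g.gene_id for g in anchors.downstream] == ["g002", "g003", "g004"]
        assert anchors.truncated

    def test_k1_single_nearest_anchor(self, linear_reference):
        anchors = flanking_anchors("g005", linear_reference, k=1)
        assert [g.gene_id for g in anchors.upstream] == ["g004"]
        assert [g.gene_id for g in anchors.downstream] == ["g006"]

    def test_gene_alone_on_contig_empty_set(self):
        ref = sd.random_reference(n_genes=1, n_contigs=1, seed=3)
        anchors = flanking_anchors("g001", ref, k=3)
        assert anchors.is_empty and anchors.truncated


class TestLocateBlock:
    def test_conserved_neighborhood_all_anchors_located(self, reference, forged):
        genomes, _ = forged
        anchors = flanking_anchors("g003", reference, k=3)
        block = locate_block(anchors, genomes["spB"], reference)
        assert len(block.upstream_located) + len(block.downstream_located) >= 4
        assert block.retained_synteny
        assert not block.end_of_contig
        assert block.interval is not None

    def test_contig_end_case_flags_split_anchors(self, reference, forged):
        genomes, _ = forged
        anchors = flanking_anchors("g005", reference, k=3)
        block = locate_block(anchors, genomes["spC"], reference)
        assert block.end_of_contig
        assert block.anchors_split_across_contigs
        assert not block.retained_synteny
        assert block.interval is None

    def test_empty_anchor_set_not_retained(self, reference, forged):
        genomes, _ = forged
        block = locate_block(
            AnchorSet("g003", [], [], truncated=True), genomes["spA"], reference
        )
        assert not block.retained_synteny and block.interval is None


class TestRescueSearch:
    def _block(self, gene_id, species, reference, genomes):
        anchors = flanking_anchors(gene_id, reference, k=3)
        return locate_block(anchors, genomes[species], reference)

    def test_split_gene_rescued_from_two_contigs(self, reference, forged):
        genomes, _ = forged
        block = self._block("g008", "spB", reference, genomes)
        ev = rescue_search(reference.gene("g008"), block, genomes["spB"])
        assert ev.rescued and ev.mode == "split"
        assert ev.n_contigs_hit >= 2
        assert ev.combined_query_coverage >= 0.8

    def test_clean_loss_not_rescued(self, reference, forged):
        genomes, _ = forged
        block = self._block("g003", "spB", reference, genomes)
        ev = rescue_search(reference.gene("g003"), block, genomes["spB"])
        assert not ev.rescued

    def test_extreme_protein_divergence_rescued_by_nucleotide_search(
        self, reference, forged
    ):
        genomes, _ = forged
        block = self._block("g010", "spC", reference, genomes)
        ev = rescue_search(reference.gene("g010"), block, genomes["spC"])
        assert ev.rescued

    def test_contig_end_stub_not_rescued(self, reference, forged):
        genomes, _ = forged
        block = self._block("g005", "spC", reference, genomes)
        ev = rescue_search(reference.gene("g005"), block, genomes["spC"])
        assert not ev.rescued
        assert ev.combined_query_coverage < 0.8


class TestClassifyAbsence:
    def test_final_statuses_match_planted_events(self, pipeline_result, forged):
        _, ledger = forged
        for row in ledger.table.itertuples(index=False):
            if row.event == "conserved":
                continue
            call = pipeline_result.absence_calls[(row.gene_id, row.species_id)]
            assert call.status == row.expected_call, (row.gene_id, row.species_id)

    def test_every_preliminary_absence_resolves_exactly_once(self, pipeline_result):
        prelim = pipeline_result.prelim_matrix.calls
        final = pipeline_result.matrix.calls
        resolved_statuses = {
            io_core.PRESENT_RESCUED,
            io_core.ABSENT_SYNTENY,
            io_core.ABSENT_NO_SYNTENY,
            io_core.UNRESOLVED_CONTIG_END,
        }
        for gid in prelim.index:
            for sp in prelim.columns:
                if prelim.at[gid, sp] == io_core.ABSENT_PRELIM:
                    assert final.at[gid, sp] in resolved_statuses

    def test_rejects_non_preliminary_input(self):
        call = RBBHCall("g", "s", io_core.PRESENT_RBBH)
        with pytest.raises(ValueError):
            classify_absence(call, None, None)

    def test_anchor_removal_degrades_retention_monotonically(
        self, reference, forged
    ):
        genomes, _ = forged
        full = flanking_anchors("g003", reference, k=3)
        target = genomes["spB"]
        previous_retained = None
        # nested anchor sets, largest first: retention may only switch on->off
        for k in (3, 2, 1, 0):
            sub = AnchorSet(
                "g003", full.upstream[:k], full.downstream[:k], truncated=k < 3
            )
            block = locate_block(sub, target, reference)
            if previous_retained is False:
                assert not block.retained_synteny
            previous_retained = block.retained_synteny


class TestInSilicoValidation:
    def test_planted_loss_validated_absent(self, reference, forged, pipeline_result):
        validated = {
            (v.gene_id, v.species_id): v for v in pipeline_result.validations
        }
        rec = validated[("g003", "spB")]
        assert rec.status == VALIDATED_ABSENT
        assert rec.interval_length > 0

    def test_present_gene_in_amplicon_contradicts_absence(self, reference, forged):
        # adversarial: validate the locus of a gene that is in fact conserved
        genomes, _ = forged
        anchors = flanking_anchors("g004", reference, k=3)
        block = locate_block(anchors, genomes["spA"], reference)
        rec = in_silico_validation(reference.gene("g004"), block, genomes["spA"])
        assert rec.status == CONTRADICTED

    def test_interval_exceeding_max_amplicon_not_validated(
        self, reference, forged
    ):
        genomes, _ = forged
        anchors = flanking_anchors("g003", reference, k=3)
        block = locate_block(anchors, genomes["spB"], reference)
        cfg = SyntenyConfig(max_amplicon=block.interval_length // 10)
        rec = in_silico_validation(
            reference.gene("g003"), block, genomes["spB"], cfg
        )
        assert rec.status == NOT_VALIDATED

    def test_requires_retained_block(self, reference, forged):
        genomes, _ = forged
        anchors = flanking_anchors("g005", reference, k=3)
        block = locate_block(anchors, genomes["spC"], reference)
        with pytest.raises(ValueError, match="retained"):
            in_silico_validation(reference.gene("g005"), block, genomes["spC"])


class TestPipelineInvariants:
    def test_no_conserved_gene_called_absent(self, pipeline_result, forged):
        """Zero false absences on the forge at moderate divergence."""
        _, ledger = forged
        final = pipeline_result.matrix.calls
        for row in ledger.table.itertuples(index=False):
            if row.event == "conserved":
                status = final.at[row.gene_id, row.species_id]
                assert status not in io_core.ABSENT_CALLS

    def test_final_matrix_matches_truth_ledger_exactly(
        self, pipeline_result, forged
    ):
        _, ledger = forged
        expected = ledger.expected_matrix()
        got = pipeline_result.matrix.calls[expected.columns].loc[expected.index]
        assert got.equals(expected)
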