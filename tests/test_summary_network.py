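import pandas as pd
import pytest

from gscortho import io_core
from gscortho.io_core import GeneAnnotationTable, PresenceMatrix
from gscortho.rbbh import naive_identity_calls
from gscortho.summary_network import (
    InteractionNetwork,
    any_absence_genes,
    category_summary,
    import_external_predictions,
    network_cooccurrence,
    per_species_summary,
)

P = io_core.PRESENT_RBBH
A = io_core.ABSENT_SYNTENY
U = io_core.UNRESOLVED_CONTIG_END


def matrix(rows, species):
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    calls.index.name = "gene_id"
    return PresenceMatrix(calls=calls)


def annotations(spec):
    rows = []
    for gid, (cats, defect) in spec.items():
        rows.append(
            {
                "gene_id": gid,
                "functional_categories": cats,
                "defect_type": defect,
                "is_focal": True,
            }
        )
    return GeneAnnotationTable(pd.DataFrame(rows))


class TestPerSpeciesSummary:
    def test_counts_and_percentages(self):
        rows = {f"g{i}": [P, A if i < 2 else P, P] for i in range(10)}
        m = matrix(rows, ["ref", "s1", "s2"])
        table = per_species_summary(m).set_index("species")
        assert table.loc["s1", "n_absent"] == 2
        assert table.loc["s1", "pct_absent"] == 20.0
        assert table.loc["s2", "n_absent"] == 0

    def test_zero_absence_matrix(self):
        m = matrix({f"g{i}": [P, P] for i in range(4)}, ["ref", "s1"])
        assert (per_species_summary(m).n_absent == 0).all()
        assert (per_species_summary(m).pct_absent == 0.0).all()

    def test_unresolved_counted_present_unless_switched(self):
        m = matrix({"g1": [P, U], "g2": [P, A]}, ["ref", "s1"])
        conservative = per_species_summary(m).set_index("species")
        inclusive = per_species_summary(m, count_unresolved_as_absent=True)
        assert conservative.loc["s1", "n_absent"] == 1
        assert inclusive.set_index("species").loc["s1", "n_absent"] == 2

    def test_percentage_consistent_with_count(self):
        rows = {f"g{i}": [P, A if i % 3 == 0 else P] for i in range(9)}
        m = matrix(rows, ["ref", "s1"])
        row = per_species_summary(m).set_index("species").loc["s1"]
        assert row.pct_absent == round(100.0 * row.n_absent / 9, 2)


class TestAnyAbsenceGenes:
    def test_all_present_empty_set(self):
        m = matrix({"g1": [P, P], "g2": [P, P]}, ["ref", "s1"])
        assert any_absence_genes(m) == set()

    def test_equals_union_over_species(self):
        rows = {"g1": [P, A, P], "g2": [P, P, A], "g3": [P, P, P]}
        m = matrix(rows, ["ref", "s1", "s2"])
        union = set()
        for sp in m.species:
            union |= {
                g for g in m.genes if m.status(g, sp) in io_core.ABSENT_CALLS
            }
        assert any_absence_genes(m) == union == {"g1", "g2"}

    def test_matches_truth_ledger_on_forge(self, pipeline_result, forged):
        _, ledger = forged
        lost = set(
            ledger.table.loc[ledger.table.event == "loss", "gene_id"]
        )
        assert any_absence_genes(pipeline_result.matrix) == lost


class TestCategorySummary:
    ANN = {
        # 3 genes in "proteasome"-like category, none absent
        "g1": (["Proteasome"], "GSC loss (cell viability)"),
        "g2": (["Proteasome"], "GSC loss (cell viability)"),
        "g3": (["Proteasome"], "GSC loss (agametic)"),
        # kinetochore-like category of 3, one absent; g4 in two categories
        "g4": (["Kinetochore", "Spindle"], "Differentiation defect"),
        "g5": (["Kinetochore"], "Differentiation defect"),
        "g6": (["Kinetochore"], "GSC loss (agametic)"),
        # uncategorised gene
        "g7": ([], "Differentiation defect"),
    }

    def _matrix(self):
        rows = {g: [P, P] for g in self.ANN}
        rows["g4"] = [P, A]
        rows["g7"] = [P, A]
        return matrix(rows, ["ref", "s1"])

    def test_category_percentages(self):
        cats, defects = category_summary(self._matrix(), annotations(self.ANN))
        cats = cats.set_index("name")
        assert cats.loc["Proteasome", "pct"] == 0.0
        assert cats.loc["Kinetochore", "n_genes"] == 3
        assert cats.loc["Kinetochore", "pct"] == 33.33
        # multi-category gene counted once per category
        assert cats.loc["Spindle", "n_with_absence"] == 1
        assert cats.loc["No functional category", "n_genes"] == 1

    def test_defect_type_percentages(self):
        _, defects = category_summary(self._matrix(), annotations(self.ANN))
        defects = defects.set_index("name")
        assert defects.loc["GSC loss (cell viability)", "pct"] == 0.0
        assert defects.loc["Differentiation defect", "n_with_absence"] == 2
        assert defects.loc["Differentiation defect", "pct"] == 66.67


class TestNetworkCooccurrence:
    def test_empty_network_gene_reports_zeros(self):
        m = matrix({"g1": [P, A]}, ["ref", "s1"])
        table, tallies = network_cooccurrence(m, InteractionNetwork({}))
        row = table.iloc[0]
        assert (row.network_size, row.n_interactors_absent,
                row.n_co_absent_same_species) == (0, 0, 0)
        assert tallies["n_with_interactions"] == 0

    def test_same_species_co_absence_counted(self):
        rows = {
            "focal": [P, A, P],
            "i1": [P, A, P],
            "i2": [P, A, A],
            "i3": [P, P, P],
        }
        m = matrix(rows, ["ref", "s1", "s2"])
        net = InteractionNetwork(
            {"focal": {("i1", "physical"), ("i2", "genetic"), ("i3", "physical")}}
        )
        table, tallies = network_cooccurrence(m, net)
        focal = table.set_index("gene_id").loc["focal"]
        assert focal.network_size == 3
        assert focal.n_interactors_absent == 2
        assert focal.n_co_absent_same_species == 2
        assert tallies["n_with_network_absences"] >= 1

    def test_uncalled_interactor_counted_unevaluated(self):
        m = matrix({"focal": [P, A]}, ["ref", "s1"])
        net = InteractionNetwork({"focal": {("ghost", "physical")}})
        table, _ = network_cooccurrence(m, net)
        row = table.iloc[0]
        assert row.n_unevaluated == 1 and row.n_evaluated == 0

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            InteractionNetwork({"g": {("g", "physical")}})


class TestImportExternalPredictions:
    def _table(self, identity):
        return pd.DataFrame(
            {
                "gene_id": ["g1"],
                "species": ["s1"],
                "target_pct_id": [identity],
                "query_pct_id": [identity],
            }
        )

    def test_identity_just_below_cutoff_absent(self):
        m = import_external_predictions(self._table(24.9))
        assert m.status("g1", "s1") == io_core.ABSENT

    def test_identity_at_cutoff_present_boundary_inclusive(self):
        m = import_external_predictions(self._table(25.0))
        assert m.status("g1", "s1") == io_core.PRESENT
        assert m.caller == "ensembl_import"

    def test_minimum_of_both_identity_columns_used(self):
        t = self._table(80.0)
        t["query_pct_id"] = [10.0]
        m = import_external_predictions(t)
        assert m.status("g1", "s1") == io_core.ABSENT

    def test_malformed_rows_skipped_with_warning(self):
        t = pd.concat([self._table(60.0), self._table("oops")])
        with pytest.warns(UserWarning, match="malformed"):
            m = import_external_predictions(t)
        assert m.status("g1", "s1") == io_core.PRESENT


class TestCallerMonotonicity:
    def test_absence_counts_shrink_with_stringency(
        self, reference, forged, pipeline_result
    ):
        """Naive threshold >= RBBH >= RBBH+synteny absences, per species."""
        genomes, _ = forged
        genes = [g.gene_id for g in reference.genes]
        naive = naive_identity_calls(genes, reference, genomes)
        for sp in genomes:
            n_naive = (naive.calls[sp] == io_core.ABSENT).sum()
            n_rbbh = (
                pipeline_result.prelim_matrix.calls[sp] == io_core.ABSENT_PRELIM
            ).sum()
            n_final = (
                pipeline_result.matrix.calls[sp].isin(io_core.ABSENT_CALLS)
            ).sum()
            assert n_naive >= n_rbbh >= n_final
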