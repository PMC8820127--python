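"""Reference numbering, residue extraction, variation summaries, copy comparison."""

import numpy as np
import pytest

from opsinsel.errors import ValidationError
from opsinsel.synthetic_data import plant_residues
from opsinsel.tuning_sites import (
    extract_site_residues,
    load_default_catalog,
    load_reference,
    map_to_reference_numbering,
    pairwise_copy_comparison,
    substitution_calls,
    variation_report,
)

# a fixed codon per amino acid, for building in-frame test CDSs
CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "E": "GAA",
    "Q": "CAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def cds_for(protein: str) -> str:
    return "".join(CODON_OF[a] for a in protein)


@pytest.fixture(scope="module")
def reference():
    return load_reference()[1]


class TestReferenceNumbering:
    def test_reference_has_its_canonical_anchor_residues(self, reference):
        assert len(reference) == 348
        # D83 (dim-light site), E113 (counterion), K296 (Schiff base),
        # W265, A299 (retinal-release site), A164
        for pos, res in [(83, "D"), (113, "E"), (296, "K"), (265, "W"),
                         (299, "A"), (164, "A")]:
            assert reference[pos - 1] == res

    def test_self_alignment_gives_identity_map(self, reference):
        numbering = map_to_reference_numbering(reference)
        assert all(numbering.mapping[i] == i for i in range(1, 349))

    def test_leading_deletion_shifts_map_by_one(self, reference):
        numbering = map_to_reference_numbering(reference[1:])
        assert all(numbering.mapping[i] == i + 1 for i in range(1, 348))

    def test_internal_deletion_preserves_flanking_numbering(self, reference):
        query = reference[:150] + reference[155:]  # drop residues 151-155
        numbering = map_to_reference_numbering(query)
        assert numbering.mapping[150] == 150
        assert numbering.mapping[151] == 156

    def test_map_strictly_increasing_and_injective(self, reference):
        query = reference[10:300]
        numbering = map_to_reference_numbering(query)
        refs = [numbering.mapping[q] for q in sorted(numbering.mapping)]
        assert all(b > a for a, b in zip(refs, refs[1:]))

    def test_non_homologous_query_flagged(self):
        numbering = map_to_reference_numbering("KKKKKKKKKK" * 3)
        assert not numbering.trusted

    def test_composition_of_numbering_maps(self, reference):
        """Mapping A->B composed with B->C equals A->C on gap-free triples."""
        a = reference[20:200]
        b = reference[10:250]
        ab = map_to_reference_numbering(a, b).mapping
        bc = map_to_reference_numbering(b, reference).mapping
        ac = map_to_reference_numbering(a, reference).mapping
        composed = {q: bc[ab[q]] for q in ab if ab[q] in bc}
        assert composed == {q: ac[q] for q in composed}


class TestExtraction:
    def test_planted_residue_is_recovered_with_call(self, reference):
        numbering = map_to_reference_numbering(reference)
        mutant = plant_residues(reference, {83: "N"}, numbering)
        table = extract_site_residues([("sp1", mutant)], positions=[83])
        assert table.loc["sp1", 83] == "N"
        calls = substitution_calls(table)
        assert calls.loc["sp1", 83] == "D83N"

    def test_all_catalog_positions_recovered_on_gap_free_scaffold(self, reference):
        catalog = load_default_catalog()
        positions = catalog.positions()
        numbering = map_to_reference_numbering(reference)
        rng = np.random.default_rng(4)
        plants = {
            pos: rng.choice([a for a in CODON_OF if a != reference[pos - 1]])
            for pos in positions
        }
        mutant = plant_residues(reference, plants, numbering)
        table = extract_site_residues([("sp1", mutant)], catalog=catalog)
        recovered = {pos: table.loc["sp1", pos] for pos in positions}
        assert recovered == plants

    def test_site_in_query_gap_marked_missing(self, reference):
        query = reference[:80] + reference[90:]  # residues 81-90 deleted
        table = extract_site_residues([("sp1", query)], positions=[83, 113])
        assert table.loc["sp1", 83] == "-"
        assert table.loc["sp1", 113] == "E"


class TestVariationReport:
    def test_residues_ordered_by_descending_frequency(self, reference):
        numbering = map_to_reference_numbering(reference)
        seqs = [
            ("sp1", plant_residues(reference, {299: "S"}, numbering)),
            ("sp2", plant_residues(reference, {299: "S"}, numbering)),
            ("sp3", reference),  # A299
        ]
        table = extract_site_residues(seqs, positions=[299, 83])
        report = variation_report(table).set_index("position")
        assert report.loc[299, "residues"] == "S/A"
        assert bool(report.loc[299, "variable"])
        assert report.loc[83, "residues"] == "D"
        assert not bool(report.loc[83, "variable"])

    def test_report_matches_brute_force_column_sets(self, reference):
        numbering = map_to_reference_numbering(reference)
        rng = np.random.default_rng(9)
        seqs = []
        for i in range(5):
            plants = {
                pos: rng.choice(list(CODON_OF))
                for pos in rng.choice([83, 96, 164, 299], size=2, replace=False)
            }
            seqs.append((f"sp{i}", plant_residues(reference, plants, numbering)))
        table = extract_site_residues(seqs, positions=[83, 96, 164, 299])
        report = variation_report(table).set_index("position")
        for pos in table.columns:
            expected = set(table[pos]) - {"-", "?"}
            assert set(report.loc[pos, "residues"].split("/")) == expected

    def test_gap_only_column_omitted(self, reference):
        table = extract_site_residues(
            [("sp1", reference[:340])], positions=[83, 345]
        )
        report = variation_report(table)
        assert 345 not in set(report["position"])


class TestCopyComparison:
    def test_identical_copies(self, reference):
        cds = cds_for(reference[:120])
        cmp = pairwise_copy_comparison(cds, cds)
        assert cmp.aa_identity_pct == 100.0
        assert cmp.nt_identity_pct == 100.0
        assert cmp.indels == []

    def test_constructed_187_of_200_pair_gives_93_5_percent(self, reference):
        prot1 = reference[:200]
        rng = np.random.default_rng(13)
        positions = rng.choice(200, size=13, replace=False)
        prot2 = list(prot1)
        for p in positions:
            prot2[p] = "W" if prot1[p] != "W" else "G"
        cmp = pairwise_copy_comparison(cds_for(prot1), cds_for("".join(prot2)))
        assert cmp.aa_identity_pct == 93.5
        assert cmp.n_aa_differences == 13
        assert cmp.aligned_aa_columns == 200

    def test_single_codon_deletion_located_in_reference_numbering(self, reference):
        # residue 83 (D) differs from both neighbors, so the deletion
        # placement is alignment-unambiguous
        prot2 = reference[:82] + reference[83:]
        cmp = pairwise_copy_comparison(cds_for(reference), cds_for(prot2))
        assert len(cmp.indels) == 1
        indel = cmp.indels[0]
        assert indel["kind"] == "deletion_in_copy2"
        assert indel["length"] == 1
        assert indel["reference_position"] == 83

    def test_deletion_inside_a_repeat_reported_within_the_run(self, reference):
        # positions 330-331 are both D: deleting either yields the same
        # alignment, so the report may name any position of the run
        prot2 = reference[:330] + reference[331:]
        cmp = pairwise_copy_comparison(cds_for(reference), cds_for(prot2))
        assert len(cmp.indels) == 1
        assert cmp.indels[0]["kind"] == "deletion_in_copy2"
        assert cmp.indels[0]["reference_position"] in (330, 331)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_copy_comparison("ATGTAAATG", "ATGAAAATG")
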