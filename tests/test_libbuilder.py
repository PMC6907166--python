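import random

import pytest
from rdkit import Chem

from markushgen.chemio import mol_from_smiles
from markushgen.errors import InvalidArgument, MissingInput
from markushgen.fixtures import assemble, packaged_tables
from markushgen.libbuilder import (
    FilterLedger,
    LibraryEntry,
    RGroupLibrary,
    build_library,
    cross_coverage,
    longest_aliphatic_chain,
    occurrence_stats,
    prepare_drug_set,
    top_k_share,
    top_list_overlap,
)
from markushgen.scaffolding import harvest_fragments

from _oracles import isomorphism_dedup


def make_table(counts: dict[str, int]):
    return occurrence_stats(
        [LibraryEntry(smiles=k, count=v) for k, v in counts.items()]
    )


class TestBuildLibrary:
    def test_fixture_ledger_and_entries(self, library_compounds, library_scaffolds):
        lib, ledger = build_library(library_compounds, library_scaffolds)
        assert ledger.harvested == 20
        assert ledger.dropped_long_chain == 1
        assert ledger.kept == len(lib.entries) == 8
        assert "*CCCCCCC" not in lib.keys

    def test_ledger_accounting_identity(self, library_compounds, library_scaffolds):
        _, ledger = build_library(library_compounds, library_scaffolds)
        assert ledger.kept == (
            ledger.harvested
            - ledger.duplicates_removed
            - ledger.dropped_deuterium
            - ledger.dropped_phosphorus
            - ledger.dropped_long_chain
        )

    def test_compounds_identical_to_scaffolds(self):
        benzene = mol_from_smiles("c1ccccc1")
        lib, ledger = build_library([Chem.Mol(benzene)], [benzene])
        assert ledger.harvested == 0
        assert lib.entries == []

    def test_deuterium_fragment_dropped(self):
        compound = mol_from_smiles("[2H]C([2H])([2H])c1ccccc1")
        lib, ledger = build_library([compound], [mol_from_smiles("c1ccccc1")])
        assert ledger.dropped_deuterium == 1
        assert lib.entries == []

    def test_phosphorus_fragment_dropped(self):
        compound = mol_from_smiles("OP(=O)(O)Cc1ccccc1")
        _, ledger = build_library([compound], [mol_from_smiles("c1ccccc1")])
        assert ledger.dropped_phosphorus == 1

    def test_filters_exclusive_first_match_wins(self):
        # deuterium AND a 7-carbon chain: counted once, under deuterium
        compound = mol_from_smiles("[2H]C(CCCCCC)c1ccccc1")
        _, ledger = build_library([compound], [mol_from_smiles("c1ccccc1")])
        assert (ledger.dropped_deuterium, ledger.dropped_long_chain) == (1, 0)

    def test_six_chain_kept_seven_chain_dropped(self):
        scaffold = mol_from_smiles("c1ccccc1")
        six = mol_from_smiles("CCCCCCc1ccccc1")
        seven = mol_from_smiles("CCCCCCCc1ccccc1")
        lib, ledger = build_library([six, seven], [scaffold])
        assert ledger.dropped_long_chain == 1
        assert lib.keys == {"*CCCCCC"}

    def test_order_invariance(self, library_compounds, library_scaffolds):
        rng = random.Random(3)
        shuffled = list(library_compounds)
        rng.shuffle(shuffled)
        lib_a, ledger_a = build_library(library_compounds, library_scaffolds)
        lib_b, ledger_b = build_library(shuffled, library_scaffolds)
        assert ledger_a == ledger_b
        assert [(e.smiles, e.count) for e in lib_a.entries] == [
            (e.smiles, e.count) for e in lib_b.entries
        ]

    def test_empty_inputs(self):
        with pytest.raises(MissingInput):
            build_library([], [])

    def test_dedup_matches_isomorphism_oracle(self, library_compounds, library_scaffolds):
        scaffold_by_match = {}
        frags = []
        for compound in library_compounds:
            for scaffold in library_scaffolds:
                if compound.HasSubstructMatch(scaffold):
                    frags.extend(harvest_fragments(compound, scaffold))
                    break
        lib, ledger = build_library(library_compounds, library_scaffolds)
        unique_oracle = isomorphism_dedup([f.graph for f in frags])
        assert ledger.harvested - ledger.duplicates_removed == unique_oracle

    def test_contexts_record_sibling_substituents(self, library_compounds, library_scaffolds):
        lib, _ = build_library(library_compounds, library_scaffolds)
        ring_contexts = {c.main_key: c for c in lib.contexts if c.kind == "ring"}
        assert "c1ccccc1" in ring_contexts
        assert {"*C", "*F", "*Cl"} <= ring_contexts["c1ccccc1"].substituents

    def test_json_roundtrip(self, tmp_path, library_compounds, library_scaffolds):
        lib, _ = build_library(library_compounds, library_scaffolds)
        path = tmp_path / "lib.json"
        lib.to_json(path)
        back = RGroupLibrary.from_json(path)
        assert back.keys == lib.keys
        assert [c.main_key for c in back.contexts] == [c.main_key for c in lib.contexts]
        lib.to_json(tmp_path / "again.json")
        assert (tmp_path / "again.json").read_bytes() == path.read_bytes()


class TestLongestAliphaticChain:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("*CCCCCC", 6),
            ("*CCCCCCC", 7),
            ("*CC(C)CC", 4),
            ("*C1CCCCC1", 0),  # ring carbons ineligible
            ("*c1ccccc1", 0),  # aromatic ineligible
            ("*CCOCC", 2),  # heteroatom breaks the chain
            ("*C", 1),
            ("*F", 0),
        ],
    )
    def test_examples(self, smiles, expected):
        assert longest_aliphatic_chain(smiles) == expected

    def test_matches_path_enumeration_oracle(self):
        # branched case checked against explicit all-simple-paths enumeration
        import itertools

        import networkx as nx

        smiles = "*CC(CC)CC(C)C"
        mol = Chem.MolFromSmiles(smiles)
        eligible = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and not a.IsInRing() and not a.GetIsAromatic()
        ]
        g = nx.Graph()
        g.add_nodes_from(eligible)
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in eligible and j in eligible:
                g.add_edge(i, j)
        best = max(
            len(path)
            for a, b in itertools.combinations_with_replacement(eligible, 2)
            for path in nx.all_simple_paths(g, a, b)
        ) if g.number_of_edges() else 1
        assert longest_aliphatic_chain(smiles) == best


class TestPrepareDrugSet:
    def test_size_and_carbon_filters(self):
        big = mol_from_smiles("C" * 60)  # MW ~ 842
        tiny = mol_from_smiles("CCO")  # MW 46, 2 carbons
        few_carbons = mol_from_smiles("OCC(O)C(O)O")  # MW > 100 but 3 carbons
        caffeine = mol_from_smiles("CN1C=NC2=C1C(=O)N(C)C(=O)N2C")
        kept = prepare_drug_set([big, tiny, few_carbons, caffeine])
        assert len(kept) == 1
        assert Chem.MolToSmiles(kept[0]) == Chem.MolToSmiles(caffeine)

    def test_salt_stripping_then_dedup_ignores_stereo(self):
        mols = [
            mol_from_smiles("C[C@H](N)c1ccccc1.Cl"),
            mol_from_smiles("C[C@@H](N)c1ccccc1"),
        ]
        assert len(prepare_drug_set(mols)) == 1


class TestOccurrenceStats:
    def test_hand_computed_percentages(self):
        table = make_table({"A": 3, "B": 2, "C": 1})
        assert list(table["key"]) == ["A", "B"]
        assert list(table["percent"]) == [60.0, 40.0]

    def test_all_singletons_empty(self):
        assert make_table({"A": 1, "B": 1}).empty

    def test_top_k_share(self):
        table = make_table({"A": 3, "B": 2})
        assert top_k_share(table, 1) == 60.0
        assert top_k_share(table, 2) == pytest.approx(100.0)
        with pytest.raises(InvalidArgument):
            top_k_share(table, 0)

    def test_full_share_bounded_by_100(self):
        table = make_table({"A": 5, "B": 4, "C": 3, "D": 2})
        assert top_k_share(table, len(table)) <= 100.0 + 1e-9


class TestCrossLibraryStats:
    def test_cross_coverage_set_arithmetic(self):
        assert cross_coverage({"a", "b", "c"}, {"b", "c", "d", "e"}) == 50.0
        assert cross_coverage({"a"}, {"a"}) == 100.0
        assert cross_coverage({"a"}, {"b"}) == 0.0
        with pytest.raises(InvalidArgument):
            cross_coverage({"a"}, set())

    def test_top_list_overlap(self):
        t1 = make_table({"A": 5, "B": 4, "C": 3})
        t2 = make_table({"B": 9, "C": 8, "D": 7})
        assert top_list_overlap(t1, t2, 3) == 2
        assert top_list_overlap(t1, t1, 3) == 3

    def test_packaged_tables_reference_statistics(self):
        t1, t2 = packaged_tables()
        assert top_list_overlap(t1, t2, 10) == 7
        assert top_k_share(t1, 10) == pytest.approx(63.0)
        assert t1.iloc[0]["name"] == "Methyl"
        assert t1.iloc[0]["percent"] == 19.9


class TestFilterLedger:
    def test_reference_headline_arithmetic(self):
        ledger = FilterLedger(
            harvested=5589,
            duplicates_removed=5183,
            dropped_deuterium=2,
            dropped_phosphorus=2,
            dropped_long_chain=133,
        )
        assert ledger.kept == 269
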