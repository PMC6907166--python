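import itertools

import pytest
from rdkit import Chem

from markushgen.chemio import canonical_key, mol_from_smiles
from markushgen.claimgen import (
    ExpandOptions,
    PositionSpec,
    build_claim,
    claim_covers,
    expand_claim,
    generalize_terms,
    render_claim_text,
)
from markushgen.fixtures import SeriesSpec, assemble, generate_series, packaged_library
from markushgen.libbuilder import LibraryEntry, RGroupLibrary, SubstituentContext
from markushgen.scaffolding import decompose, find_core


def claim_from_series(mols, tax=None):
    core = find_core(mols)
    decomps = [decompose(m, core) for m in mols]
    return build_claim(mols, core, decomps, tax)


@pytest.fixture(scope="module")
def two_position_claim():
    spec = SeriesSpec(
        core_smiles="c1cc([*:2])ccc1[*:1]",
        position_choices={"R1": ["*C", "*Cl"], "R2": ["*O", "*F", "*[H]"]},
        n=6,
        seed=5,
    )
    mols, truth = generate_series(spec)
    return claim_from_series(mols), mols, truth


class TestBuildClaim:
    def test_explicit_sets_are_union_over_compounds(self, two_position_claim):
        claim, _, truth = two_position_claim
        recovered = sorted(sorted(s.explicit) for s in claim.specs)
        expected = sorted(sorted(v) for v in truth.positions.values())
        assert recovered == expected

    def test_one_position_methyl_chloro(self):
        mols = [
            assemble(Chem.MolFromSmiles("c1ccc([*:1])cc1"), {"R1": s})
            for s in ("*C", "*Cl")
        ]
        claim = claim_from_series(mols)
        assert len(claim.specs) == 1
        assert claim.specs[0].explicit == {"*C", "*Cl"}

    def test_invariant_substituent_folds_into_core(self):
        # every member is para-methyl: the methyl is core, only X varies
        mols = [
            mol_from_smiles(s) for s in ("Cc1ccc(O)cc1", "Cc1ccc(F)cc1")
        ]
        claim = claim_from_series(mols)
        assert len(claim.specs) == 1
        assert "*C" not in claim.specs[0].explicit

    def test_identical_series_gives_zero_positions(self):
        mol = mol_from_smiles("CCOc1ccccc1")
        claim = claim_from_series([mol, Chem.Mol(mol)])
        assert claim.specs == []


class TestGeneralizeTerms:
    def test_halo_family_collapses(self, tax):
        spec = generalize_terms(PositionSpec("R1", explicit={"*F", "*Cl"}), tax)
        assert spec.terms == ["halo"]

    def test_mixed_fragments_named_individually(self, tax):
        spec = generalize_terms(PositionSpec("R1", explicit={"*C", "*OC"}), tax)
        assert spec.terms == ["methyl", "methoxy"]

    def test_hydrogen_always_first(self, tax):
        spec = generalize_terms(
            PositionSpec("R1", explicit={"*C", "*[H]", "*Cl"}), tax
        )
        assert spec.terms[0] == "hydrogen"
        assert set(spec.terms) == {"hydrogen", "methyl", "chloro"}


class TestExpandClaim:
    def test_context_rule_adds_remaining_substituents(self, two_position_claim):
        claim, _, _ = two_position_claim
        lib = RGroupLibrary(
            entries=[LibraryEntry(smiles="*OC", count=3)],
            contexts=[
                SubstituentContext(
                    main_key="c1ccccc1",
                    kind="ring",
                    substituents={"*C", "*Cl", "*OC", "*Br"},
                )
            ],
        )
        expanded = expand_claim(claim, lib)
        gained = {s.label: s.expanded for s in expanded.specs}
        # both positions sit on the benzene ring and share *C or *Cl
        assert any("*OC" in v and "*Br" in v for v in gained.values())
        for spec in expanded.specs:
            assert spec.expanded & spec.explicit == set()

    def test_no_context_match_leaves_claim_unchanged(self, two_position_claim):
        claim, _, _ = two_position_claim
        lib = RGroupLibrary(
            contexts=[
                SubstituentContext(
                    main_key="C1CCCCC1", kind="ring", substituents={"*C"}
                )
            ]
        )
        expanded = expand_claim(claim, lib)
        assert all(not s.expanded for s in expanded.specs)

    def test_input_claim_not_mutated(self, two_position_claim):
        claim, _, _ = two_position_claim
        before = {s.label: set(s.expanded) for s in claim.specs}
        expand_claim(claim, packaged_library(), ExpandOptions(basic_set=True))
        assert {s.label: set(s.expanded) for s in claim.specs} == before

    def test_basic_set_adds_reference_top10(self, two_position_claim):
        claim, _, _ = two_position_claim
        lib = packaged_library()
        expanded = expand_claim(claim, lib, ExpandOptions(basic_set=True))
        top10 = set(lib.top_fragments(10))
        for spec in expanded.specs:
            assert top10 - spec.explicit <= spec.expanded

    def test_provenance_recorded_for_every_added_fragment(self, two_position_claim):
        claim, _, _ = two_position_claim
        expanded = expand_claim(
            claim, packaged_library(), ExpandOptions(basic_set=True)
        )
        for spec in expanded.specs:
            for key in spec.expanded:
                assert f"{spec.label}:{key}" in expanded.provenance


class TestClaimCovers:
    def test_covers_every_generating_compound(self, two_position_claim):
        claim, mols, _ = two_position_claim
        assert all(claim_covers(claim, m) for m in mols)

    def test_rejects_fragment_outside_allowed_sets(self, two_position_claim):
        claim, _, _ = two_position_claim
        outsider = assemble(
            Chem.MolFromSmiles("c1cc([*:2])ccc1[*:1]"),
            {"R1": "*Br", "R2": "*O"},
        )
        assert not claim_covers(claim, outsider)

    def test_rejects_different_core(self, two_position_claim):
        claim, _, _ = two_position_claim
        assert not claim_covers(claim, mol_from_smiles("Cc1ccncc1"))

    def test_agrees_with_full_instantiation_enumeration(self):
        spec = SeriesSpec(
            core_smiles="c1cc([*:2])ccc1[*:1]",
            position_choices={"R1": ["*C", "*Cl", "*N"], "R2": ["*O", "*F"]},
            n=4,
            seed=9,
        )
        mols, _ = generate_series(spec)
        claim = claim_from_series(mols)
        allowed = {s.label: sorted(s.allowed) for s in claim.specs}
        core = Chem.MolFromSmiles("c1cc([*:2])ccc1[*:1]")
        covered_keys = set()
        labels = sorted(allowed)
        for combo in itertools.product(*(allowed[l] for l in labels)):
            inst = assemble(core, dict(zip(labels, combo)))
            covered_keys.add(canonical_key(inst).key)
        pool = [
            dict(zip(("R1", "R2"), c))
            for c in itertools.product(
                ["*C", "*Cl", "*N", "*Br"], ["*O", "*F", "*C"]
            )
        ]
        for combo in pool:
            mol = assemble(core, combo)
            assert claim_covers(claim, mol) == (
                canonical_key(mol).key in covered_keys
            )

    def test_expansion_only_widens_coverage(self):
        spec = SeriesSpec(
            core_smiles="c1ccc([*:1])cc1",
            position_choices={"R1": ["*C", "*Cl"]},
            n=2,
            seed=2,
        )
        mols, _ = generate_series(spec)
        claim = claim_from_series(mols)
        lib = RGroupLibrary(
            contexts=[
                SubstituentContext(
                    main_key="c1ccccc1",
                    kind="ring",
                    substituents={"*C", "*OC", "*F"},
                )
            ]
        )
        expanded = expand_claim(claim, lib)
        core = Chem.MolFromSmiles("c1ccc([*:1])cc1")
        for frag in ["*C", "*Cl", "*OC", "*F", "*Br", "*[H]"]:
            mol = assemble(core, {"R1": frag})
            if claim_covers(claim, mol):
                assert claim_covers(expanded, mol)


class TestRenderClaimText:
    def test_wherein_block_lists_positions_in_label_order(self, two_position_claim):
        claim, _, _ = two_position_claim
        doc = render_claim_text(claim)
        text = doc.clauses[0][1]
        assert "A compound of formula (I):" in text
        assert text.index("R1 is selected") < text.index("R2 is selected")
        assert text.count("selected from the group consisting of") == 2

    def test_terms_phrase(self, tax):
        mols = [
            assemble(Chem.MolFromSmiles("c1ccc([*:1])cc1"), {"R1": s})
            for s in ("*[H]", "*C", "*F")
        ]
        claim = claim_from_series(mols, tax)
        doc = render_claim_text(claim)
        assert (
            "R1 is selected from the group consisting of hydrogen, methyl, and fluoro"
            in doc.clauses[0][1]
        )

    def test_zero_position_claim_is_single_clause(self):
        mol = mol_from_smiles("CCOc1ccccc1")
        claim = claim_from_series([mol, Chem.Mol(mol)])
        doc = render_claim_text(claim)
        assert len(doc.clauses) == 1
        assert "A compound of formula (I)" in doc.clauses[0][1]

    def test_deterministic_byte_for_byte(self, two_position_claim):
        claim, _, _ = two_position_claim
        a = render_claim_text(claim)
        b = render_claim_text(claim)
        assert a.clauses == b.clauses
        assert a.notes == b.notes
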