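import pytest
from rdkit import Chem

from alertminer import chem_io
from alertminer.chem_io import MoleculeRecord, PatternCatalogue, ToxicityDataset
from alertminer.fragment_mining import (
    build_table,
    compile_query,
    enumerate_bondbreak,
    enumerate_circular,
    enumerate_groups,
    enumerate_paths,
    fragments_for_molecule,
    match_catalogue,
)


def mol(smiles):
    m = Chem.MolFromSmiles(smiles)
    assert m is not None
    return m


def patterns(keys):
    return sorted(k.pattern for k in keys)


class TestCircular:
    def test_benzene_one_environment_at_radius_one(self):
        assert len(enumerate_circular(mol("c1ccccc1"), 1, 1)) == 1

    def test_isolated_atom_yields_nothing(self):
        assert enumerate_circular(mol("C"), 1, 4) == set()

    def test_ethanol_three_centre_environments(self):
        frags = enumerate_circular(mol("CCO"), 1, 1)
        assert patterns(frags) == ["CC", "CCO", "CO"]

    def test_radius_nesting(self):
        # the radius-r environment of a centre is a substructure of the same
        # centre's radius-(r+1) environment
        m = mol("CCOCC(=O)NCC(C)CC")

        def env_smiles(atom_idx, r):
            env = Chem.FindAtomEnvironmentOfRadiusN(m, r, atom_idx)
            if not env:
                return None
            atoms = set()
            for b in env:
                bond = m.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            return Chem.MolFragmentToSmiles(
                m, atomsToUse=sorted(atoms), bondsToUse=list(env), canonical=True
            )

        checked = 0
        for atom in m.GetAtoms():
            for r in (1, 2, 3):
                small, big = env_smiles(atom.GetIdx(), r), env_smiles(atom.GetIdx(), r + 1)
                if small is None or big is None:
                    continue
                host = Chem.MolFromSmiles(big)
                assert host is not None
                assert host.HasSubstructMatch(compile_query(small))
                checked += 1
        assert checked > 10

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            enumerate_circular(mol("CCO"), 0, 4)
        with pytest.raises(ValueError):
            enumerate_circular(mol("CCO"), 3, 2)


class TestPaths:
    def test_ethanol_paths(self):
        assert patterns(enumerate_paths(mol("CCO"), 1, 2)) == ["CC", "CCO", "CO"]

    def test_single_atom_no_paths(self):
        assert enumerate_paths(mol("C"), 1, 7) == set()

    def test_benzene_single_bond_path(self):
        assert len(enumerate_paths(mol("c1ccccc1"), 1, 1)) == 1

    def test_heterogeneous_chain_count_matches_combinatorial_oracle(self):
        # chain of n atoms, all subpaths chemically distinct:
        # number of distinct paths with length 1..L is sum_{k=1..min(L,n-1)} (n-k)
        chain = "CONCS"  # C-O-N-C-S, n=5; every contiguous subpath is unique
        n = 5
        for L in (1, 2, 4):
            expected = sum(n - k for k in range(1, min(L, n - 1) + 1))
            assert len(enumerate_paths(mol(chain), 1, L)) == expected

    def test_homogeneous_chain_collapses_by_symmetry(self):
        # all length-k subpaths of an alkane are the same fragment
        assert len(enumerate_paths(mol("CCCCC"), 1, 3)) == 3

    def test_path_and_reverse_are_one_fragment(self):
        frags = patterns(enumerate_paths(mol("NCO"), 2, 2))
        assert frags == ["NCO"]


class TestGroups:
    def test_hexane_has_no_groups(self):
        assert enumerate_groups(mol("CCCCCC")) == set()

    def test_phenol_groups(self):
        assert patterns(enumerate_groups(mol("Oc1ccccc1"))) == ["O", "c1ccccc1"]

    def test_acetaminophen_groups(self):
        # amide (carbonyl C + O + N), phenolic hydroxyl, aromatic ring
        got = patterns(enumerate_groups(mol("CC(=O)Nc1ccc(O)cc1")))
        assert got == ["NC=O", "O", "c1ccccc1"]

    def test_plain_carbons_never_emitted_alone(self):
        for smi in ["CC(C)C", "C1CCCCC1", "CCCC"]:
            assert enumerate_groups(mol(smi)) == set()

    def test_fused_aromatic_system_is_one_pattern(self):
        frags = enumerate_groups(mol("c1ccc2ccccc2c1"))
        assert len(frags) == 1
        q = compile_query(next(iter(frags)).pattern)
        assert mol("c1ccc2ccccc2c1").HasSubstructMatch(q)


class TestBondBreak:
    def test_ethanol_fragments(self):
        assert patterns(enumerate_bondbreak(mol("CCO"), 2, 15)) == ["CC", "CCO", "CO"]

    def test_ring_with_nothing_to_break(self):
        assert patterns(enumerate_bondbreak(mol("c1ccccc1"), 2, 15)) == ["c1ccccc1"]

    def test_min_atoms_floor(self):
        assert patterns(enumerate_bondbreak(mol("CCO"), 3, 15)) == ["CCO"]

    def test_max_atoms_ceiling_excludes_whole_molecule(self):
        frags = patterns(enumerate_bondbreak(mol("CCCCCCCCCC"), 2, 5))
        assert "CCCCCCCCCC" not in frags
        assert all(Chem.MolFromSmiles(p).GetNumHeavyAtoms() <= 5 for p in frags)

    def test_fragment_cap_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="cap"):
            frags = enumerate_bondbreak(mol("CCOCCNCCOCC"), 2, 15, fragment_cap=3)
        assert len(frags) == 3


class TestSelfMatchProperty:
    @pytest.mark.parametrize("strategy", ["circular", "path", "group", "bondbreak"])
    def test_every_fragment_matches_its_source(self, strategy, small_synthetic):
        for rec in small_synthetic.dataset.records[:40]:
            m = mol(rec.smiles)
            for key in fragments_for_molecule(m, strategy):
                assert m.HasSubstructMatch(compile_query(key.pattern)), (
                    f"{strategy} fragment {key.pattern} does not match {rec.smiles}"
                )


class TestCatalogueMatching:
    def dataset(self):
        return ToxicityDataset(
            endpoint="demo",
            records=[
                MoleculeRecord("a", "CCO", 1),
                MoleculeRecord("b", "CC", 0),
            ],
        )

    def test_hydroxyl_support(self):
        cat = PatternCatalogue("cat", ["[OH]"])
        table = match_catalogue(self.dataset(), cat)
        key = next(iter(table.rows))
        sup = table.rows[key]
        assert (sup.n_sub, sup.n_sub_positive) == (1, 1)

    def test_unmatched_pattern_absent(self):
        cat = PatternCatalogue("cat", ["[F]"])
        assert len(match_catalogue(self.dataset(), cat)) == 0

    def test_catalogue_counts_all_matches(self, small_synthetic):
        ds = small_synthetic.dataset
        cat = PatternCatalogue("cat", ["[#6]"])  # any carbon: matches everything
        table = match_catalogue(ds, cat)
        sup = next(iter(table.rows.values()))
        assert sup.n_sub == ds.n_total
        assert sup.n_sub_positive == ds.n_positive


class TestBuildTable:
    def test_identical_molecules_not_double_counted(self):
        # two SMILES spellings of one molecule remain distinct records only
        # if their canonical forms differ; here use two distinct but
        # fragment-identical molecules
        ds = ToxicityDataset(
            endpoint="demo",
            records=[MoleculeRecord("a", "CCO", 1), MoleculeRecord("b", "OCCO", 0)],
        )
        table = build_table(ds, "circular")
        for sup in table.rows.values():
            assert sup.n_sub <= 2

    def test_unparseable_record_skipped(self):
        ds = ToxicityDataset(
            endpoint="demo",
            records=[MoleculeRecord("a", "CCO", 1)],
        )
        # inject a bad SMILES bypassing validation
        ds.records.append(MoleculeRecord("b", "xxx-bad", 0))
        with pytest.warns(UserWarning, match="skipping"):
            table = build_table(ds, "circular")
        assert table.n_skipped == 1
        assert len(table) > 0

    def test_two_single_molecule_classes(self):
        # benzene contributes one radius-1 environment (all centres equivalent);
        # hexane contributes two (terminal CC and internal CCC)
        ds = ToxicityDataset(
            endpoint="demo",
            records=[MoleculeRecord("a", "c1ccccc1", 1), MoleculeRecord("b", "CCCCCC", 0)],
        )
        table = build_table(ds, "circular", {"r_min": 1, "r_max": 1})
        assert len(table) == 3
        for sup in table.rows.values():
            assert sup.n_sub == 1
        positives = {k.pattern: s.n_sub_positive for k, s in table.rows.items()}
        assert positives == {"ccc": 1, "CC": 0, "CCC": 0}

    def test_support_monotone_under_dataset_growth(self, small_synthetic):
        ds = small_synthetic.dataset
        smaller = ds.subset(range(30))
        bigger = ds.subset(range(31))
        t_small = build_table(smaller, "circular")
        t_big = build_table(bigger, "circular")
        for key, sup in t_small.rows.items():
            assert t_big.rows[key].n_sub >= sup.n_sub

    def test_deterministic_for_fixed_ordering(self, small_synthetic):
        ds = small_synthetic.dataset.subset(range(25))
        t1 = build_table(ds, "path", {"l_min": 1, "l_max": 3})
        t2 = build_table(ds, "path", {"l_min": 1, "l_max": 3})
        assert list(t1.rows.items()) == list(t2.rows.items())

    def test_unknown_strategy_rejected(self, small_synthetic):
        with pytest.raises(ValueError, match="strategy"):
            build_table(small_synthetic.dataset, "quantum")
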