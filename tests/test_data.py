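import math

import numpy as np
import pytest
from scipy.stats import kstest

from islandbd import (
    CladeRecord,
    IslandDataset,
    MissingSpeciesAssignment,
    event_timeline,
    extract_island_clades,
    insert_missing_species,
    read_dataset,
    validate_dataset,
    write_dataset,
)
from islandbd.data import dataset_from_json, dataset_to_json, dataset_to_newick

from conftest import random_dataset


class TestValidation:
    def test_branching_precedes_colonization(self):
        ds = IslandDataset(30.0, 10, (CladeRecord("c", 1, "endemic_clade", 22.09, (25.0,)),))
        assert any("branching precedes colonization" in v for v in validate_dataset(ds))

    def test_colonization_predates_island(self):
        ds = IslandDataset(30.0, 10, (CladeRecord("c", 1, "endemic_singleton", 35.0),))
        assert any("predates island" in v for v in validate_dataset(ds))

    def test_table1_fixture_is_valid(self, table1):
        assert validate_dataset(table1) == []

    def test_doublet_flagged(self):
        ds = IslandDataset(
            30.0,
            10,
            (
                CladeRecord("c1", 3, "endemic_singleton", 20.0),
                CladeRecord("c2", 3, "endemic_singleton", 10.0),
            ),
        )
        assert any("mainland_species_id" in v for v in validate_dataset(ds))

    def test_validation_never_raises(self):
        ds = IslandDataset(-1.0, 10, (CladeRecord("c", 99, "weird", -5.0, (1.0, 1.0)),))
        assert len(validate_dataset(ds)) >= 3


class TestIO:
    def test_json_round_trip_random_corpus(self, tmp_path):
        rng = np.random.default_rng(7)
        for i in range(1000):
            ds = random_dataset(rng)
            if i % 20 == 0:
                path = tmp_path / f"ds_{i}.json"
                write_dataset(ds, path)
                assert read_dataset(path) == ds
            else:
                assert dataset_from_json(dataset_to_json(ds)) == ds

    def test_tsv_round_trip_matches_json(self, tmp_path, table1):
        write_dataset(table1, tmp_path / "t.tsv", format="tsv")
        write_dataset(table1, tmp_path / "t.json", format="json")
        assert read_dataset(tmp_path / "t.tsv", format="tsv") == read_dataset(tmp_path / "t.json")

    def test_missing_island_age_is_parse_error(self):
        with pytest.raises(ValueError, match="island_age"):
            dataset_from_json('{"M": 10, "clades": []}')

    def test_round_trip_preserves_ages_to_high_precision(self, table1):
        back = dataset_from_json(dataset_to_json(table1))
        for a, b in zip(table1.clades, back.clades):
            assert a.colonization_age == b.colonization_age
            assert a.branching_ages == b.branching_ages


class TestTimeline:
    def test_empty_island(self):
        tl = list(event_timeline(IslandDataset(30.0, 5, ())))
        assert [e.kind for e in tl] == ["origin", "present"]
        assert tl[-1].k_after == 0

    def test_table1_event_order_and_k(self, table1):
        tl = list(event_timeline(table1))
        cols = [e for e in tl if e.kind == "colonization"]
        assert cols[0].age == 22.09 and cols[4].age == 8.43
        assert tl[-1].k_after == 65
        ks = [e.k_after for e in tl if e.kind in ("colonization", "branching")]
        assert ks == list(range(1, 66))

    def test_tie_break_colonization_before_branching(self):
        ds = IslandDataset(
            10.0,
            5,
            (
                CladeRecord("b", 1, "endemic_clade", 8.0, (5.0,)),
                CladeRecord("a", 2, "non_endemic_singleton", 5.0),
            ),
        )
        tl = [e for e in event_timeline(ds) if e.age == 5.0]
        assert [e.kind for e in tl] == ["colonization", "branching"]


class TestNewick:
    def test_three_tip_extraction(self):
        ds = extract_island_clades(
            "((A:1,B:1):1,C:2);", {"A", "B"}, island_age=3.0, mainland_pool_M=10
        )
        (c,) = ds.clades
        assert c.colonization_age == pytest.approx(2.0)
        assert c.branching_ages == pytest.approx((1.0,))

    def test_all_island_tips_is_error(self):
        with pytest.raises(ValueError, match="non-island"):
            extract_island_clades("((A:1,B:1):1,C:2);", {"A", "B", "C"}, island_age=3.0)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            extract_island_clades("((A:1,B:2):1,C:2);", {"A", "B"}, island_age=3.0)

    def test_extraction_inverts_rendering(self, table1):
        newick, island = dataset_to_newick(table1)
        back = extract_island_clades(newick, island, island_age=30.0, mainland_pool_M=1000)
        assert back.n_clades == table1.n_clades
        for a, b in zip(table1.clades, back.clades):
            assert b.colonization_age == pytest.approx(a.colonization_age, abs=1e-9)
            assert np.allclose(b.branching_ages, a.branching_ages, atol=1e-9)

    def test_extraction_recovers_simulated_bookkeeping(self):
        from islandbd import ModelParams, simulate_iw

        p = ModelParams(0.4, 0.1, 10.0, 0.05, 0.0)
        found = 0
        for seed in range(30):
            ds = simulate_iw(p, 12.0, 6, seed=seed).dataset
            if ds.n_clades < 2 or validate_dataset(ds):
                continue
            found += 1
            newick, island = dataset_to_newick(ds)
            back = extract_island_clades(newick, island, island_age=12.0, mainland_pool_M=6)
            assert back.n_clades == ds.n_clades
            for a, b in zip(ds.clades, back.clades):
                assert b.colonization_age == pytest.approx(a.colonization_age, abs=1e-9)
                assert np.allclose(b.branching_ages, a.branching_ages, atol=1e-9)
        assert found >= 5


class TestInsertion:
    def test_zero_assignments_identity(self):
        nwk = "((A:1.0,B:1.0):1.0,C:2.0);"
        trees = insert_missing_species(nwk, [], 4, seed=0)
        assert len(trees) == 4
        for t in trees:
            ds = extract_island_clades(t, {"A", "B"}, island_age=3.0)
            assert ds.clades[0].branching_ages == pytest.approx((1.0,))

    def test_tip_count_and_ultrametricity(self, table1):
        newick, island = dataset_to_newick(table1)
        assigns = [
            MissingSpeciesAssignment("x1", "tip_branch", ("clade_1_sp1",)),
            MissingSpeciesAssignment("x2", "within_clade", ("clade_2_sp1", "clade_2_sp9")),
            MissingSpeciesAssignment("x3", "within_clade", ("clade_5_sp1", "clade_5_sp8")),
        ]
        labels = island | {"x1", "x2", "x3"}
        for t in insert_missing_species(newick, assigns, 5, seed=3):
            # extraction re-checks ultrametricity at 1e-6 relative tolerance
            back = extract_island_clades(
                t, labels, island_age=30.0, ultrametricity_rel_tol=1e-9
            )
            assert back.total_species == table1.total_species + 3

    def test_unknown_anchor_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            insert_missing_species(
                "((A:1,B:1):1,C:2);",
                [MissingSpeciesAssignment("x", "tip_branch", ("Z",))],
                1,
                seed=0,
            )

    def test_tip_branch_attachment_ages_uniform(self):
        # anchor tip A has terminal branch spanning ages (0, 1)
        nwk = "((A:1.0,B:1.0):1.0,C:2.0);"
        assigns = [MissingSpeciesAssignment("x", "tip_branch", ("A",))]
        ages = []
        for t in insert_missing_species(nwk, assigns, 1000, seed=11):
            ds = extract_island_clades(t, {"A", "B", "x"}, island_age=3.0)
            clade = next(c for c in ds.clades if c.n_species == 3)
            ages.append(min(clade.branching_ages))
        assert kstest(ages, "uniform", args=(0, 1)).pvalue > 0.01
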