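import numpy as np
import pandas as pd
import pytest
from helpers import make_freq_matrix

from evotraj.muller import (
    ROOT,
    Genotype,
    GenotypeTree,
    correct_genotype_frequencies,
    export_muller_tables,
    infer_genotype_nesting,
    select_muller_mutations,
)
from evotraj.simulate import LineageSpec, SimConfig, TreatmentSpec, simulate_experiment
from evotraj.tables import SampleSheet, compute_frequencies


def sheet_for(sample_ids, generations):
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "treatment": "host",
                "replicate": "1",
                "generations": generations,
            }
        )
    )


class TestSelectMullerMutations:
    def test_ten_percent_boundary_is_inclusive(self):
        f = make_freq_matrix([[0.02, 0.09], [0.02, 0.10]])
        assert select_muller_mutations(f) == ["m1"]

    def test_exclusion_list_honored_regardless_of_frequency(self):
        f = make_freq_matrix([[0.9, 0.9], [0.5, 0.4]])
        assert select_muller_mutations(f, exclusions=["m0"]) == ["m1"]


class TestInferNesting:
    def test_contained_trajectory_is_nested(self):
        f = make_freq_matrix(
            [[0.2, 0.8, 1.0], [0.0, 0.3, 0.9]],
            mutation_ids=["first", "second"],
        )
        tree = infer_genotype_nesting(f, {"first": "gA", "second": "gB"})
        assert tree.genotypes["gt_second"].parent == "gt_first"
        assert tree.genotypes["gt_first"].parent == ROOT

    def test_same_gene_mutations_never_nested(self):
        f = make_freq_matrix(
            [[0.2, 0.8, 1.0], [0.0, 0.3, 0.9]],
            mutation_ids=["first", "second"],
        )
        tree = infer_genotype_nesting(f, {"first": "gA", "second": "gA"})
        assert tree.genotypes["gt_second"].parent == ROOT

    def test_single_mutation_hangs_off_the_ancestor(self):
        f = make_freq_matrix([[0.2, 0.5]], mutation_ids=["only"])
        tree = infer_genotype_nesting(f, {})
        assert tree.genotypes["gt_only"].parent == ROOT
        assert tree.path_mutations("gt_only") == frozenset({"only"})


class TestCorrections:
    def test_child_capped_at_parent(self):
        # a child estimated above its parent in one sample is pulled down
        tree = GenotypeTree(sample_ids=["s0", "s1"])
        tree.genotypes["gt_p"] = Genotype(
            "gt_p", frozenset({"p"}), ROOT, np.array([0.5, 0.9])
        )
        tree.genotypes["gt_c"] = Genotype(
            "gt_c", frozenset({"c"}), "gt_p", np.array([0.65, 0.4])
        )
        tree, report = correct_genotype_frequencies(tree)
        assert tree.genotypes["gt_c"].corrected[0] == pytest.approx(0.5)
        assert report.frame.loc["gt_c", "s0"] == pytest.approx(0.15)
        assert report.flagged  # adjustment above the 0.10 flag bound

    def test_explicit_sibling_rescale_values(self):
        # two root genotypes at 0.7 and 0.6 in one sample: sum 1.3 -> 1.0
        f = make_freq_matrix(
            [[0.7, 0.1], [0.6, 0.5]], mutation_ids=["a", "b"]
        )
        tree = infer_genotype_nesting(f, {"a": "gA", "b": "gB"})
        assert tree.genotypes["gt_b"].parent == ROOT  # 0.5 > 0.1: no nesting
        tree, _ = correct_genotype_frequencies(tree)
        assert tree.genotypes["gt_a"].corrected[0] == pytest.approx(7 / 13)
        assert tree.genotypes["gt_b"].corrected[0] == pytest.approx(6 / 13)

    def test_consistent_tree_is_a_fixed_point(self):
        f = make_freq_matrix(
            [[0.8, 0.9], [0.3, 0.4]], mutation_ids=["p", "c"]
        )
        tree = infer_genotype_nesting(f, {"p": "g1", "c": "g2"})
        tree, report = correct_genotype_frequencies(tree)
        assert report.max_adjustment == 0.0

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        f = make_freq_matrix(rng.uniform(0, 1, size=(8, 5)))
        tree = infer_genotype_nesting(f, {f"m{i}": f"g{i}" for i in range(8)})
        tree, _ = correct_genotype_frequencies(tree)
        for g in tree.genotypes.values():
            g.raw = g.corrected.copy()
        tree2, report2 = correct_genotype_frequencies(tree)
        assert report2.max_adjustment == pytest.approx(0.0, abs=1e-12)

    def test_invariants_hold_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            f = make_freq_matrix(rng.uniform(0, 1, size=(10, 4)))
            tree = infer_genotype_nesting(
                f, {f"m{i}": f"g{i}" for i in range(10)}
            )
            tree, _ = correct_genotype_frequencies(tree)
            for g in tree.genotypes.values():
                parent = (
                    np.ones(4)
                    if g.parent == ROOT
                    else tree.genotypes[g.parent].corrected
                )
                assert (g.corrected <= parent + 1e-12).all()
            sheet = sheet_for([f"s{j}" for j in range(4)], np.arange(4.0))
            _, pops = export_muller_tables(tree, sheet)
            sums = pops.groupby("Generation")["Population"].sum()
            np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)


class TestExport:
    def test_exclusive_frequency_chain(self):
        f = make_freq_matrix([[0.8], [0.3]], mutation_ids=["a", "b"])
        tree = infer_genotype_nesting(f, {"a": "gA", "b": "gB"})
        tree, _ = correct_genotype_frequencies(tree)
        sheet = sheet_for(["s0"], [100.0])
        edges, pops = export_muller_tables(tree, sheet)
        pop = dict(zip(pops["Identity"], pops["Population"]))
        assert pop["gt_a"] == pytest.approx(0.5)
        assert pop["gt_b"] == pytest.approx(0.3)
        assert pop[ROOT] == pytest.approx(0.2)
        assert set(map(tuple, edges.to_numpy())) == {
            (ROOT, "gt_a"),
            ("gt_a", "gt_b"),
        }

    def test_empty_tree_exports_pure_ancestor(self):
        f = make_freq_matrix(np.zeros((0, 2)), mutation_ids=[])
        tree = infer_genotype_nesting(f, {})
        tree, _ = correct_genotype_frequencies(tree)
        sheet = sheet_for(["s0", "s1"], [10.0, 20.0])
        edges, pops = export_muller_tables(tree, sheet)
        assert len(edges) == 0
        assert (pops["Identity"] == ROOT).all()
        assert (pops["Population"] == 1.0).all()


def nested_noise_free_run():
    """One sweeping lineage, one deterministic arrival per interval.

    Every later arrival hitchhikes inside the earlier background, so the
    true nesting is the arrival chain.
    """
    spec = TreatmentSpec(
        name="host",
        sample_times=(1.0, 2.0, 3.0, 4.0, 5.0),
        lineages=(
            LineageSpec("sweep", 1.0, (0.20, 0.40, 0.60, 0.80, 0.90)),
        ),
    )
    cfg = SimConfig(
        treatments=(spec,),
        seed=23,
        deterministic_counts=True,
        observation="exact",
    )
    return simulate_experiment(cfg)


def oracle_nesting_from_truth(truth):
    """Expected parent of each mutation: the previous arrival in its lineage."""
    parents = {}
    for lineage, group in truth.mutations.groupby("lineage"):
        order = sorted(
            group["mutation_id"],
            key=lambda mid: np.flatnonzero(
                truth.frequencies.loc[mid].to_numpy() > 0
            )[0],
        )
        prev = ROOT
        for mid in order:
            parents[mid] = prev
            prev = f"gt_{mid}"
    return parents


def test_corrections_stay_small_on_paper_faithful_scenario(mouse_run):
    # on the mouse-study scenario at depth ~150, every inferred genotype
    # frequency should move by well under 0.10 during correction
    from evotraj.filtering import filter_pipeline

    table, sheet, _ = mouse_run
    filtered, _ = filter_pipeline(table, sheet)
    host = sheet.samples_in("mouse_host")
    freqs = compute_frequencies(filtered).restrict(host)
    sel = select_muller_mutations(freqs)
    # hypermutator lineages accumulate multiple hits per gene, so the
    # one-mutation-per-gene rule does not apply to this treatment
    tree = infer_genotype_nesting(
        freqs.subset_rows(sel), {}, read_depth=150
    )
    tree, report = correct_genotype_frequencies(tree)
    assert report.max_adjustment < 0.10
    assert not report.flagged


def test_nesting_reconstructs_simulated_truth_exactly():
    table, sheet, truth = nested_noise_free_run()
    freqs = compute_frequencies(table)
    gene_of = dict(zip(table.meta["mutation_id"], table.meta["gene"]))
    tree = infer_genotype_nesting(freqs, gene_of)
    expected = oracle_nesting_from_truth(truth)
    for mid, parent in expected.items():
        assert tree.genotypes[f"gt_{mid}"].parent == parent
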