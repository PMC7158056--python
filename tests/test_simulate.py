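"""Synthetic-data generators: determinism, truth records, closed-loop checks."""

import filecmp
import json

import numpy as np
import pytest
from scipy import stats

from olesuite import scenarios
from olesuite.condensation import predict
from olesuite.detect import screen
from olesuite.lipids import CultureContext, InternalStandardSpec, quantify
from olesuite.simulate import (
    make_family,
    make_genome_set,
    make_peak_table,
    make_tree_presence,
    spurious_motif_expectation,
)


def _dir_identical(d1, d2):
    names = sorted(p.name for p in d1.iterdir())
    assert names == sorted(p.name for p in d2.iterdir())
    match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
    return not mismatch and not errors


class TestGenomeSet:
    def test_same_seed_byte_identical(self, tmp_path):
        make_genome_set(8, n_positive=2, n_decoy_per_class=1, out_dir=tmp_path / "a")
        make_genome_set(8, n_positive=2, n_decoy_per_class=1, out_dir=tmp_path / "b")
        assert _dir_identical(tmp_path / "a", tmp_path / "b")

    def test_truth_counts(self):
        gs = make_genome_set(9, n_positive=3, n_decoy_per_class=2)
        positives = [g for g, info in gs.truth["genomes"].items() if info["positive"]]
        assert len(positives) == 3
        assert len(gs.truth["genomes"]) == 3 + 4 * 2

    def test_closed_loop_perfect_detection(self, pattern):
        """Zero-noise planted benchmark: detector agrees with truth exactly."""
        gs = make_genome_set(10, n_positive=4, n_decoy_per_class=2)
        table, _ = screen(gs.genomes, pattern, gs.queries)
        for _, row in table.iterrows():
            assert row["verified"] == gs.truth["genomes"][row["genome_id"]]["positive"]

    def test_spurious_motif_probability_negligible(self):
        gs = make_genome_set(12, n_positive=2, n_decoy_per_class=1)
        assert gs.truth["expected_spurious_motif_hits"] < 1e-4
        # closed form sanity: linear in residues
        assert spurious_motif_expectation(2000) == pytest.approx(
            2 * spurious_motif_expectation(1000)
        )


class TestFamily:
    def test_planted_node_counts(self):
        fam = make_family(3, block_sizes=(5, 5), within_identity=90, between_identity=40)
        assert fam.truth["expected_node_count"] == 2
        single = make_family(4, block_sizes=(4,), within_identity=100, between_identity=0)
        assert single.truth["expected_node_count"] == 1
        assert len(set(single.seqs.values())) == 1  # identity 100 -> identical members

    def test_realized_identities_near_target(self):
        for seed in range(50, 60):
            fam = make_family(seed, block_sizes=(4, 3), within_identity=85,
                              between_identity=30)
            for r in fam.truth["realized_within_identities"]:
                assert abs(r - 85) <= 2.0

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_family(1, block_sizes=(30,), within_identity=60, between_identity=0)

    def test_determinism(self, tmp_path):
        make_family(5, out_dir=tmp_path / "a")
        make_family(5, out_dir=tmp_path / "b")
        assert _dir_identical(tmp_path / "a", tmp_path / "b")


class TestTreePresence:
    def test_planted_cluster_count_and_ubiquity(self):
        from olesuite.phylo import annotate_presence, count_presence_clusters, genus_ubiquity
        import dendropy

        for k in (0, 3, 7):
            tp = make_tree_presence(60 + k, k_clusters=k)
            assert tp.truth["k_clusters"] == k
            tree = dendropy.Tree.get(data=tp.newick, schema="newick",
                                     preserve_underscores=True)
            tree, _ = annotate_presence(tree, tp.table)
            assert count_presence_clusters(tree) == k
            _, summary = genus_ubiquity(tp.table)
            assert summary["ubiquity_rate"] == 1.0

    def test_separation_infeasible_rejected(self):
        with pytest.raises(ValueError, match="separate"):
            make_tree_presence(1, genera_spec=[("A", 2), ("B", 2), ("C", 2)], k_clusters=3)

    def test_determinism(self, tmp_path):
        make_tree_presence(7, out_dir=tmp_path / "a")
        make_tree_presence(7, out_dir=tmp_path / "b")
        assert _dir_identical(tmp_path / "a", tmp_path / "b")


class TestPeakTable:
    def test_noiseless_table_reproduces_model_distribution(self):
        """Sampling error only: total variation < 0.005 at one million molecules."""
        pool, weights = scenarios.recovery_pool(), scenarios.recovery_weights()
        ps = make_peak_table(70, pool, weights, n_molecules=1_000_000, noise_cv=0.0)
        profile = quantify(
            ps.peaks, InternalStandardSpec("triacontane", 40.0), CultureContext(10.0, 1.0)
        )
        model = predict(pool, weights).joint_distribution()
        observed = profile.joint_distribution().reindex(model.index, fill_value=0.0)
        tv = 0.5 * float((observed - model).abs().sum())
        assert tv < 0.005

    def test_chi_square_consistency_of_counts(self):
        pool, weights = scenarios.recovery_pool(), scenarios.recovery_weights()
        ps = make_peak_table(71, pool, weights, n_molecules=100_000, noise_cv=0.0)
        model = predict(pool, weights).joint_distribution()
        counts = np.array([ps.truth["category_counts"][f"{c}|{k}"] for c, k in model.index])
        chi = stats.chisquare(counts, f_exp=counts.sum() * model.to_numpy())
        assert chi.pvalue > 0.01

    def test_zero_molecules_only_is_row(self):
        pool, weights = scenarios.recovery_pool(), scenarios.recovery_weights()
        ps = make_peak_table(72, pool, weights, n_molecules=0)
        assert list(ps.peaks["analyte_class"]) == ["internal_standard"]
        profile = quantify(
            ps.peaks, InternalStandardSpec("triacontane", 40.0), CultureContext(10.0, 1.0)
        )
        with pytest.raises(ValueError, match="zero total"):
            profile.joint_distribution()

    def test_same_seed_identical_csv(self, tmp_path):
        pool, weights = scenarios.recovery_pool(), scenarios.recovery_weights()
        make_peak_table(73, pool, weights, n_molecules=1000, noise_cv=0.2,
                        out_path=tmp_path / "a.csv")
        make_peak_table(73, pool, weights, n_molecules=1000, noise_cv=0.2,
                        out_path=tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_truth_suffices_for_expected_output(self, tmp_path):
        pool, weights = scenarios.recovery_pool(), scenarios.recovery_weights()
        ps = make_peak_table(74, pool, weights, n_molecules=10_000, noise_cv=0.0,
                             out_path=tmp_path / "p.csv")
        truth = json.loads((tmp_path / "p.truth.json").read_text())
        # noiseless areas are exactly the truth counts
        olefins = ps.peaks[ps.peaks["analyte_class"] == "olefin"]
        for _, row in olefins.iterrows():
            from olesuite.lipids import classify_isomer

            key = f"{row['chain_length']}|{classify_isomer(row['branch1'], row['branch2'])}"
            assert row["area"] == pytest.approx(truth["category_counts"][key])
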