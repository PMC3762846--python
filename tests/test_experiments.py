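"""Reference-design experiments and the per-contig regression baseline."""

import numpy as np
import pytest

from metablup import CountTable, SimulationConfig, simulate_dataset
from metablup.experiments import (
    contig_subset_sweep,
    contigwise_association,
    depth_subsample,
    extreme_reference,
    reference_size_sweep,
    topn_contig_prediction,
)


@pytest.fixture(scope="module")
def split_dataset():
    ds = simulate_dataset(
        SimulationConfig(n_samples=80, m_contigs=300, n_causal=300, m2=0.6, seed=555)
    )
    ref_ids = ds.sample_ids[:56]
    val_ids = ds.sample_ids[56:]
    return (
        ds.counts.subset_samples(ref_ids),
        ds.counts.subset_samples(val_ids),
        ds.phenotype_map(),
    )


class TestExtremeReference:
    PHEN = {f"s{i}": float(i + 1) for i in range(10)}

    def test_most_extreme_takes_both_tails(self):
        chosen = extreme_reference(self.PHEN, "most", 4)
        assert sorted(self.PHEN[s] for s in chosen) == [1.0, 2.0, 9.0, 10.0]

    def test_least_extreme_takes_middle_ranks(self):
        chosen = extreme_reference(self.PHEN, "least", 4)
        assert sorted(self.PHEN[s] for s in chosen) == [4.0, 5.0, 6.0, 7.0]

    def test_ties_broken_by_sample_id(self):
        phen = {"b": 1.0, "a": 1.0, "c": 2.0, "d": 3.0}
        chosen = extreme_reference(phen, "most", 2)
        assert chosen == ["a", "d"]

    def test_odd_size_for_most_rejected(self):
        with pytest.raises(ValueError, match="even"):
            extreme_reference(self.PHEN, "most", 3)


class TestDepthSubsample:
    def make_table(self):
        return CountTable(
            sample_ids=["a", "b"],
            feature_ids=["f0", "f1", "f2"],
            counts=np.array([[30, 50, 20], [10, 0, 10]]),
        )

    def test_exact_depth_per_sample(self):
        out = depth_subsample(self.make_table(), depth=40, seed=0)
        assert out.counts.sum(axis=1).tolist() == [40, 20]  # b has only 20

    def test_full_depth_unchanged(self):
        table = self.make_table()
        out = depth_subsample(table, depth=100, seed=0)
        assert np.array_equal(out.counts, table.counts)

    def test_depth_one(self):
        out = depth_subsample(self.make_table(), depth=1, seed=3)
        assert out.counts[0].sum() == 1

    def test_deterministic(self):
        a = depth_subsample(self.make_table(), depth=40, seed=9)
        b = depth_subsample(self.make_table(), depth=40, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_marginal_proportions(self):
        """Means of repeated half-depth draws track the original counts.

        Each feature's marginal is hypergeometric; over 1000 draws the mean
        count should sit within 4 standard errors of depth * p_j.
        """
        row = np.array([[200, 100, 50, 150]])
        table = CountTable(["a"], ["f0", "f1", "f2", "f3"], row)
        n_draws, depth, total = 1000, 250, row.sum()
        draws = np.array(
            [depth_subsample(table, depth, seed=s).counts[0] for s in range(n_draws)]
        )
        p = row[0] / total
        expected = depth * p
        var = depth * p * (1 - p) * (total - depth) / (total - 1)
        sem = np.sqrt(var / n_draws)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 4 * sem)


class TestReferenceSizeSweep:
    def test_grid_shape_and_determinism(self, split_dataset):
        ref, val, phen = split_dataset
        res = reference_size_sweep(ref, phen, val, phen, sizes=[10, 20], reps=3, seed=4)
        assert len(res.records) == 6
        res2 = reference_size_sweep(ref, phen, val, phen, sizes=[10, 20], reps=3, seed=4)
        assert res.records == res2.records

    def test_full_reference_single_rep(self, split_dataset):
        ref, val, phen = split_dataset
        res = reference_size_sweep(
            ref, phen, val, phen, sizes=[ref.n_samples], reps=1, seed=0
        )
        assert len(res.records) == 1
        assert -1 <= res.records[0][2] <= 1

    def test_size_bounds(self, split_dataset):
        ref, val, phen = split_dataset
        with pytest.raises(ValueError, match=">= 5"):
            reference_size_sweep(ref, phen, val, phen, sizes=[3], reps=1, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            reference_size_sweep(ref, phen, val, phen, sizes=[999], reps=1, seed=0)


class TestContigSubsetSweep:
    def test_disjoint_groups(self, split_dataset):
        ref, val, phen = split_dataset
        res = contig_subset_sweep(ref, phen, val, phen, disjoint_groups=4, seed=0)
        assert len(res.records) == 4
        sizes = {rec[0] for rec in res.records}
        assert len(sizes) == 1  # equal-sized groups

    def test_random_subsets_shape(self, split_dataset):
        ref, val, phen = split_dataset
        res = contig_subset_sweep(ref, phen, val, phen, Ns=[20, 50], reps=4, seed=1)
        assert len(res.records) == 8


class TestContigwiseAssociation:
    def test_min_read_boundary(self, rng):
        counts_ref = np.column_stack([np.full(10, 20), np.full(10, 10)])
        counts_val = np.column_stack([np.full(10, 20), np.array([9] + [10] * 9)])
        ref = CountTable([f"r{i}" for i in range(10)], ["keep", "drop"], counts_ref)
        val = CountTable([f"v{i}" for i in range(10)], ["keep", "drop"], counts_val)
        # "drop" has 99 reads in the validation population: excluded
        counts_ref[:, 0] = rng.integers(10, 40, size=10)  # give "keep" variance
        ref = CountTable([f"r{i}" for i in range(10)], ["keep", "drop"], counts_ref)
        phen = {f"r{i}": float(rng.normal()) for i in range(10)}
        models = contigwise_association(ref, phen, val, min_reads=100)
        assert models["feature_id"].tolist() == ["keep"]

    def test_slope_matches_closed_form(self):
        """Six-sample toy: per-contig slope equals the normal equations."""
        x_raw = np.array([3, 1, 4, 1, 5, 9], dtype=float)
        y = np.array([2.0, 1.0, 3.0, 1.5, 4.0, 7.0])
        counts = np.column_stack([x_raw * 100, np.full(6, 100)]).astype(int)
        ref = CountTable([f"s{i}" for i in range(6)], ["fA", "fB"], counts)
        val = CountTable(
            [f"v{i}" for i in range(6)], ["fA", "fB"], counts[::-1].copy()
        )
        phen = dict(zip(ref.sample_ids, y))
        models = contigwise_association(
            ref, phen, val, min_reads=10, use_standardised=False
        ).set_index("feature_id")
        x = counts[:, 0].astype(float)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert models.loc["fA", "slope"] == pytest.approx(slope, abs=1e-10)
        assert models.loc["fA", "intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_large_effect_contig_ranks_high(self):
        """A single strong causal contig lands in the top decile of the ranking."""
        hits = 0
        for seed in range(10):
            ds = simulate_dataset(
                SimulationConfig(
                    n_samples=60,
                    m_contigs=200,
                    n_causal=3,
                    m2=0.8,
                    sparse_effects=True,
                    seed=900 + seed,
                )
            )
            strongest = max(ds.beta, key=lambda f: abs(ds.beta[f]))
            ref_ids = ds.sample_ids[:40]
            val_ids = ds.sample_ids[40:]
            models = contigwise_association(
                ds.counts.subset_samples(ref_ids),
                ds.phenotype_map(),
                ds.counts.subset_samples(val_ids),
                min_reads=10,
            )
            rank = models.set_index("feature_id").loc[strongest, "rank"]
            hits += rank <= len(models) / 10
        assert hits >= 8

    def test_no_survivors_rejected(self, rng):
        ref = CountTable(["a", "b", "c"], ["f"], np.array([[1], [1], [1]]))
        val = CountTable(["d", "e", "f"], ["f"], np.array([[1], [1], [1]]))
        with pytest.raises(ValueError, match="no contigs"):
            contigwise_association(ref, {"a": 1.0, "b": 2.0, "c": 3.0}, val)


class TestTopNContigPrediction:
    def test_top1_equals_best_model(self, split_dataset):
        ref, val, phen = split_dataset
        models = contigwise_association(ref, phen, val, min_reads=10)
        res = topn_contig_prediction(models, val, phen, Ns=[1])
        from metablup import build_profile
        from metablup.evaluation import pearson_accuracy

        best = models.iloc[0]
        profile = build_profile(val)
        j = profile.feature_ids.index(best["feature_id"])
        pred = best["intercept"] + best["slope"] * profile.X[:, j]
        obs = np.array([phen[s] for s in val.sample_ids])
        assert res.records[0][2] == pytest.approx(
            pearson_accuracy(pred, obs), abs=1e-10
        )

    def test_one_accuracy_per_n(self, split_dataset):
        ref, val, phen = split_dataset
        models = contigwise_association(ref, phen, val, min_reads=10)
        res = topn_contig_prediction(models, val, phen, Ns=[1, 5, 20])
        assert [rec[0] for rec in res.records] == [1.0, 5.0, 20.0]

    def test_n_capped_with_warning(self, split_dataset):
        ref, val, phen = split_dataset
        models = contigwise_association(ref, phen, val, min_reads=10).head(5)
        with pytest.warns(RuntimeWarning, match="capping"):
            res = topn_contig_prediction(models, val, phen, Ns=[50])
        assert res.records[0][0] == 50.0
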