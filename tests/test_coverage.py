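import numpy as np
import pytest

from strainepi.containers import GeneMatrix
from strainepi.coverage import (
    POOR,
    WELL,
    binarize_presence,
    filter_pipeline,
    kmeans_coverage_label,
    prevalence_filter,
    sample_stats,
)
from conftest import separated_cloud_stats


def _matrix(abd, species="sp"):
    abd = np.asarray(abd, dtype=float)
    return GeneMatrix(
        species,
        [f"g{i}" for i in range(abd.shape[0])],
        [f"s{j}" for j in range(abd.shape[1])],
        abd,
    )


class TestSampleStats:
    def test_median_log_over_nonzero_only(self):
        m = _matrix(np.array([[0.0], [0.0], [np.exp(2)], [np.exp(4)]]))
        (s,) = sample_stats(m)
        assert s.n_nonzero == 2
        assert s.median_log_nonzero == pytest.approx(3.0)

    def test_all_zero_sample_gets_nan_marker(self):
        (s,) = sample_stats(_matrix(np.zeros((3, 1))))
        assert s.n_nonzero == 0
        assert np.isnan(s.median_log_nonzero)

    def test_gene_order_invariance(self, rng):
        abd = rng.random((20, 6)) * (rng.random((20, 6)) < 0.6)
        m = _matrix(abd)
        perm = rng.permutation(20)
        m2 = _matrix(abd[perm])
        for a, b in zip(sample_stats(m), sample_stats(m2)):
            assert a.n_nonzero == b.n_nonzero
            assert np.isclose(a.median_log_nonzero, b.median_log_nonzero, equal_nan=True)


class TestKmeansLabeling:
    def test_separated_clouds_recovered_exactly(self, rng):
        stats = separated_cloud_stats(rng)
        labels = kmeans_coverage_label(stats, seed=0)
        for s in stats:
            expected = WELL if s.sample_id.startswith("w") else POOR
            assert labels.labels[s.sample_id] == expected

    def test_duplicating_every_sample_keeps_labels(self, rng):
        from strainepi.coverage import SampleCoverageStats

        stats = separated_cloud_stats(rng)
        labels1 = kmeans_coverage_label(stats, seed=3)
        doubled = stats + [
            SampleCoverageStats(s.sample_id + "_dup", s.n_nonzero, s.median_log_nonzero)
            for s in stats
        ]
        labels2 = kmeans_coverage_label(doubled, seed=3)
        for s in stats:
            assert labels2.labels[s.sample_id] == labels1.labels[s.sample_id]

    def test_sample_order_invariance(self, rng):
        stats = separated_cloud_stats(rng)
        labels1 = kmeans_coverage_label(stats, seed=7)
        shuffled = [stats[i] for i in rng.permutation(len(stats))]
        labels2 = kmeans_coverage_label(shuffled, seed=7)
        assert labels1.labels == labels2.labels

    def test_fewer_than_two_eligible_all_poor(self):
        from strainepi.coverage import SampleCoverageStats

        stats = [
            SampleCoverageStats("a", 0, float("nan")),
            SampleCoverageStats("b", 5, 1.0),
        ]
        with pytest.warns(UserWarning):
            labels = kmeans_coverage_label(stats, seed=0)
        assert set(labels.labels.values()) == {POOR}

    def test_zero_observation_samples_never_clustered(self, rng):
        from strainepi.coverage import SampleCoverageStats

        stats = separated_cloud_stats(rng) + [SampleCoverageStats("empty", 0, float("nan"))]
        labels = kmeans_coverage_label(stats, seed=0)
        assert labels.labels["empty"] == POOR


class TestPrevalenceFilter:
    def test_bounds_at_large_n(self, rng):
        # thresholds at N=1262: genes seen in fewer than 6 samples, or in
        # more than 1256, are removed; counts equal to the bounds are kept
        n = 1262
        counts = {"five": 5, "six": 6, "upper": 1256, "above": 1257, "all": 1262}
        rows = []
        for c in counts.values():
            row = np.zeros(n)
            row[:c] = 1.0
            rows.append(row)
        m = GeneMatrix("sp", list(counts), [f"s{j}" for j in range(n)], np.array(rows))
        kept = prevalence_filter(m, 0.005).gene_ids
        assert kept == ["six", "upper"]

    def test_small_n_removes_nothing(self, rng):
        abd = (rng.random((8, 10)) < 0.5).astype(float)
        m = _matrix(abd)
        assert prevalence_filter(m, 0.005).gene_ids == m.gene_ids  # floor(0.05) = 0

    def test_preserves_gene_order_and_values(self, rng):
        abd = (rng.random((30, 40)) < 0.3) * rng.random((30, 40))
        m = _matrix(abd)
        out = prevalence_filter(m, 0.06)
        idx = [m.gene_ids.index(g) for g in out.gene_ids]
        assert idx == sorted(idx)
        np.testing.assert_array_equal(out.abundance, m.abundance[idx])


class TestBinarize:
    def test_definition_and_idempotence(self):
        m = _matrix(np.array([[0.0, 0.3, 7.1], [0.0, 0.0, 0.0]]))
        b = binarize_presence(m)
        np.testing.assert_array_equal(b.abundance, [[0, 1, 1], [0, 0, 0]])
        np.testing.assert_array_equal(binarize_presence(b).abundance, b.abundance)


class TestFilterPipeline:
    def test_noop_path(self, rng):
        # every sample has identical coverage statistics (columns are
        # permutations of one value vector) and all genes are mid-prevalence:
        # nothing is dropped and the output is simply the binarized input
        import warnings

        col = np.concatenate([np.zeros(10), 1.0 + np.arange(20)])
        abd = np.column_stack([col[rng.permutation(30)] for _ in range(24)])
        m = _matrix(abd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, labels = filter_pipeline(m, fraction=0.005, seed=0)
        assert out.n_samples == m.n_samples
        assert out.n_genes == m.n_genes
        np.testing.assert_array_equal(out.abundance, (m.abundance > 0).astype(float))

    def test_planted_poor_samples_dropped(self):
        from strainepi.simulate import GeneSimConfig, simulate_gene_dataset

        gm, _, truth = simulate_gene_dataset(
            GeneSimConfig(n_per_group=60, n_genes=300, seed=5)
        )
        out, labels = filter_pipeline(gm, fraction=0.005, seed=0)
        poor = set(truth["poorly_covered"])
        survivors = set(out.sample_ids)
        # most truly poor samples are dropped, most well samples kept
        assert len(survivors & poor) / len(poor) < 0.4
        well = set(gm.sample_ids) - poor
        assert len(survivors & well) / len(well) > 0.6

    def test_final_threshold_uses_post_drop_sample_count(self):
        # 250 samples of which 50 poorly covered: initial t = floor(.02*250) = 5,
        # final t = floor(.02*200) = 4.  A gene seen in 4 well + 1 poor sample
        # survives both passes only if the final pass recomputes N.
        rng = np.random.default_rng(0)
        n_well, n_poor = 200, 50
        n = n_well + n_poor
        base = np.exp(rng.normal(2, 0.3, size=(120, n)))
        mask = rng.random((120, n)) < 0.5
        abd = base * mask
        abd[:, n_well:] *= (rng.random((120, n_poor)) < 0.05)  # poor samples nearly empty
        marker = np.zeros(n)
        marker[[0, 1, 2, 3]] = 5.0   # 4 well-covered samples
        marker[n_well] = 5.0         # 1 poor sample
        abd = np.vstack([abd, marker])
        m = _matrix(abd)
        out, labels = filter_pipeline(m, fraction=0.02, seed=0)
        dropped = [s for s, l in labels.labels.items() if l == POOR]
        assert len(dropped) >= 40  # the poor block was detected
        marker_gene = f"g{m.n_genes - 1}"
        # count of the marker gene among survivors
        surviving_count = 4 - sum(f"s{j}" not in out.sample_ids for j in range(4))
        t_final = int(0.02 * out.n_samples)
        assert (marker_gene in out.gene_ids) == (surviving_count >= t_final)


def test_filtering_never_increases_dimensions(rng):
    abd = (rng.random((50, 60)) < 0.4) * rng.random((50, 60))
    m = _matrix(abd)
    out, _ = filter_pipeline(m, fraction=0.01, seed=0)
    assert out.n_genes <= m.n_genes
    assert out.n_samples <= m.n_samples
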