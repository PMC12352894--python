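"""Transform, QC, batch-correction, and clustering contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cytostrat.preprocess import (
    ClusterLabels,
    EventMatrix,
    arcsinh_transform,
    batch_mixing_entropy,
    build_knn_adjacency,
    cluster_cells,
    correct_batches,
    inverse_arcsinh,
    modularity_of,
    qc_filter,
)
from tests.conftest import make_events


class TestArcsinh:
    @pytest.mark.parametrize("x,cofactor,expected", [
        (0.0, 5.0, 0.0),
        (5.0, 5.0, np.arcsinh(1.0)),  # 0.881373...
        (10.0, 2.0, np.arcsinh(5.0)),
    ])
    def test_closed_form(self, x, cofactor, expected):
        ev = make_events([[x]], ["m"], scale="raw")
        out = arcsinh_transform(ev, cofactor)
        assert out.scale == "transformed"
        assert np.isclose(out.values[0, 0], expected)

    def test_round_trip(self, rng):
        X = rng.gamma(2.0, 20.0, size=(500, 4))
        ev = make_events(X, list("abcd"), scale="raw")
        back = inverse_arcsinh(arcsinh_transform(ev, 5.0), 5.0)
        assert np.max(np.abs(back.values - X)) < 1e-9

    def test_errors(self):
        ev = make_events([[1.0]], ["m"], scale="raw")
        with pytest.raises(ValueError, match="positive"):
            arcsinh_transform(ev, 0.0)
        t = arcsinh_transform(ev, 5.0)
        with pytest.raises(ValueError, match="transformed"):
            arcsinh_transform(t, 5.0)
        with pytest.raises(ValueError, match="negative"):
            make_events([[-1.0]], ["m"], scale="raw")


def _labels_fixture(spec):
    """spec: sample_id -> (n_cells, n_b, max_cluster_frac)."""
    rows = []
    for sid, (n, n_b, occ) in spec.items():
        big = int(round(occ * n))
        clusters = [0] * big + [1 + i % 3 for i in range(n - big)]
        lineages = ["B"] * n_b + ["T"] * (n - n_b)
        for c, l in zip(clusters, lineages):
            rows.append(dict(sample_id=sid, cluster=c, lineage=l, subset=l))
    return ClusterLabels(pd.DataFrame(rows))


class TestQcFilter:
    def test_constructed_violations(self):
        """Exactly the 3 constructed violators are removed from 10 samples."""
        samples = {f"s{i}": make_events(np.zeros((100, 1)), ["m"]) for i in range(10)}
        viability = {f"s{i}": 0.8 for i in range(10)}
        viability["s1"] = 0.49
        spec = {f"s{i}": (100, 10, 0.5) for i in range(10)}
        spec["s2"] = (100, 0, 0.5)    # zero B cells
        spec["s3"] = (100, 10, 0.95)  # 95% in one cluster
        kept, report = qc_filter(samples, viability, _labels_fixture(spec))
        assert sorted(report.removed) == ["s1", "s2", "s3"]
        assert len(kept) == 7
        reasons = report.table.set_index("sample_id")["reasons"]
        assert "viability" in reasons["s1"]
        assert "zero_b_cells" in reasons["s2"]
        assert "occupancy" in reasons["s3"]

    def test_boundaries_kept(self):
        """Viability exactly 0.50 and occupancy exactly 0.90 pass (strict rules)."""
        samples = {"a": make_events(np.zeros((100, 1)), ["m"]),
                   "b": make_events(np.zeros((100, 1)), ["m"])}
        labels = _labels_fixture({"a": (100, 10, 0.5), "b": (100, 10, 0.90)})
        kept, report = qc_filter(samples, {"a": 0.50, "b": 0.8}, labels)
        assert report.removed == []
        assert set(kept) == {"a", "b"}

    def test_missing_viability_removed_with_reason(self):
        samples = {"a": make_events(np.zeros((10, 1)), ["m"])}
        kept, report = qc_filter(samples, {})
        assert kept == {}
        assert report.table.iloc[0]["reasons"] == "unmeasured"


class TestBatchCorrection:
    def test_single_batch_identity(self, gaussian_mixture_samples):
        samples, _ = gaussian_mixture_samples(
            4, 200, [0.5, 0.5], [[0, 0], [4, 4]], seed=1)
        out = correct_batches(samples)
        for s in samples:
            assert np.array_equal(out[s].values, samples[s].values)

    def test_constant_shift_removed(self, gaussian_mixture_samples):
        """Two batches differing only by a per-marker constant shift end up
        with batch marker means within 0.05 SD."""
        shift = np.array([1.0, -0.8, 0.5])
        samples, _ = gaussian_mixture_samples(
            8, 400, [0.4, 0.3, 0.3], [[0, 0, 0], [4, 1, 0], [1, 4, 3]], seed=2,
            batch_of=lambda i: "b1" if i % 2 else "b0",
            shift_of=lambda i: shift if i % 2 else 0.0)
        out = correct_batches(samples, n_anchors=6, seed=0)
        X0 = np.vstack([out[s].values for s in out if out[s].batch == "b0"])
        X1 = np.vstack([out[s].values for s in out if out[s].batch == "b1"])
        sd = np.vstack([X0, X1]).std(axis=0)
        resid = np.abs(X0.mean(axis=0) - X1.mean(axis=0)) / sd
        assert resid.max() < 0.05

    def test_mixing_entropy_increases(self, gaussian_mixture_samples):
        shift = np.array([2.0, -2.0])
        samples, _ = gaussian_mixture_samples(
            8, 300, [0.5, 0.5], [[0, 0], [4, 4]], seed=3,
            batch_of=lambda i: "b1" if i % 2 else "b0",
            shift_of=lambda i: shift if i % 2 else 0.0)
        before = batch_mixing_entropy(samples, k=15)
        out = correct_batches(samples, n_anchors=4, seed=0)
        after = batch_mixing_entropy(out, k=15)
        assert after > before

    def test_counts_unchanged_and_batch_rename_invariance(self, gaussian_mixture_samples):
        samples, _ = gaussian_mixture_samples(
            6, 150, [0.5, 0.5], [[0, 0], [3, 3]], seed=4,
            batch_of=lambda i: "b1" if i % 2 else "b0")
        out = correct_batches(samples, n_anchors=4, seed=5)
        assert all(out[s].n_cells == samples[s].n_cells for s in samples)
        renamed = {
            s: EventMatrix(e.values.copy(), e.markers, sample_id=s, panel=e.panel,
                           batch={"b0": "z9", "b1": "a0"}[e.batch],
                           scale="transformed")
            for s, e in samples.items()}
        out2 = correct_batches(renamed, n_anchors=4, seed=5)
        for s in out:
            assert np.allclose(out[s].values, out2[s].values, atol=1e-8)


class TestClustering:
    def test_planted_lineage_recovery(self, gaussian_mixture_samples):
        """Four well-separated planted lineages are recovered (ARI >= 0.95)."""
        centers = np.zeros((4, 4))
        np.fill_diagonal(centers, 6.0)  # >= 6 SD separation at sd ~1
        samples, truth = gaussian_mixture_samples(
            6, 400, [0.4, 0.25, 0.25, 0.1], centers, sd=1.0, seed=5)
        canonical = {"T": ("m0",), "B": ("m1",), "myeloid": ("m2",), "NK": ("m3",)}
        labels = cluster_cells(samples, level="lineage",
                               lineage_markers=["m0", "m1", "m2", "m3"],
                               canonical=canonical, k_neighbors=15, seed=0)
        truth_flat = np.concatenate([truth[s] for s in samples])
        name_of = {0: "T", 1: "B", 2: "myeloid", 3: "NK"}
        ari = adjusted_rand_score([name_of[t] for t in truth_flat],
                                  labels.cells["lineage"])
        assert ari >= 0.95

    def test_determinism(self, gaussian_mixture_samples):
        samples, _ = gaussian_mixture_samples(
            4, 300, [0.5, 0.5], [[0, 0], [5, 5]], seed=6)
        l1 = cluster_cells(samples, level="lineage", lineage_markers=["m0", "m1"],
                           canonical={"T": ("m0",), "B": ("m1",)}, seed=42)
        l2 = cluster_cells(samples, level="lineage", lineage_markers=["m0", "m1"],
                           canonical={"T": ("m0",), "B": ("m1",)}, seed=42)
        assert l1.cells["cluster"].tolist() == l2.cells["cluster"].tolist()

    def test_subset_recovery_within_lineage(self, gaussian_mixture_samples):
        """Three planted subsets (4 SD apart) inside one lineage: ARI >= 0.90."""
        centers = np.array([[0, 0, 0], [4, 0, 4], [0, 4, 4]], dtype=float)
        samples, truth = gaussian_mixture_samples(
            6, 400, [0.4, 0.35, 0.25], centers, sd=1.0, seed=7)
        n_total = sum(s.n_cells for s in samples.values())
        prior = ClusterLabels(pd.DataFrame({
            "sample_id": np.concatenate(
                [[s] * samples[s].n_cells for s in samples]),
            "cluster": 0, "lineage": "T", "subset": "T"}))
        # resolution chosen to match the planted granularity; higher values
        # subdivide blobs (still valid subsets, but not the planted partition)
        labels = cluster_cells(samples, level="subset", prior_labels=prior,
                               subset_lineage="T", k_neighbors=15,
                               resolution=0.2, seed=1)
        truth_flat = np.concatenate([truth[s] for s in samples])
        ari = adjusted_rand_score(truth_flat, labels.cells["subset"])
        assert ari >= 0.90

    def test_modularity_beats_trivial_partition(self, gaussian_mixture_samples):
        samples, _ = gaussian_mixture_samples(
            4, 250, [0.5, 0.5], [[0, 0], [5, 5]], seed=8)
        X = np.vstack([samples[s].values for s in samples])
        Z = (X - X.mean(0)) / X.std(0)
        A = build_knn_adjacency(Z, 15)
        labels = cluster_cells(samples, level="lineage",
                               lineage_markers=["m0", "m1"],
                               canonical={"T": ("m0",), "B": ("m1",)}, seed=0)
        got = modularity_of(A, labels.cells["cluster"].to_numpy())
        trivial = modularity_of(A, np.zeros(A.shape[0], dtype=int))
        assert got >= trivial

    def test_too_few_cells_rejected(self, gaussian_mixture_samples):
        samples, _ = gaussian_mixture_samples(1, 10, [1.0], [[0, 0]], seed=9)
        with pytest.raises(ValueError, match="k"):
            cluster_cells(samples, level="lineage", lineage_markers=["m0", "m1"],
                          k_neighbors=30)
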