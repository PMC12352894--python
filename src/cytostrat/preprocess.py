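"""Event-level preprocessing: arcsinh transform, sample QC, batch correction,
and two-level graph-based clustering of mass-cytometry events.

The processing order mirrors a standard CyTOF workflow: raw ion counts are
variance-stabilized with ``asinh(x / cofactor)``, samples failing basic
quality rules are dropped, batch (acquisition-run) effects are removed with
an anchor-based iterative location/scale matching procedure, and cells are
clustered on a k-nearest-neighbor graph with Leiden modularity optimization,
first into major lineages (T, B, myeloid, NK) on canonical lineage markers
and then into lineage-specific subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("cytostrat")

LINEAGES = ("T", "B", "myeloid", "NK")

#: canonical markers used to call each major lineage from cluster profiles
CANONICAL_LINEAGE_MARKERS: dict[str, tuple[str, ...]] = {
    "T": ("CD3",),
    "B": ("CD19",),
    "myeloid": ("CD14", "CD11b"),
    "NK": ("CD56",),
}

DEFAULT_COFACTOR = 5.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EventMatrix:
    """One sample's cells-by-markers intensity table.

    Parameters
    ----------
    values : (n_cells, n_markers) float array on the scale given by ``scale``.
    markers : marker names, one per column.
    sample_id, panel, batch : sample annotations.
    scale : ``"raw"`` (ion-count-like, non-negative) or ``"transformed"``
        (arcsinh scale).
    """

    values: np.ndarray
    markers: list[str]
    sample_id: str
    panel: str
    batch: str = "batch0"
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.markers):
            raise ValueError("values must be (n_cells, n_markers)")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")
        if self.scale not in ("raw", "transformed"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw" and self.values.size and self.values.min() < 0:
            raise ValueError("negative values on raw scale")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def marker_column(self, marker: str) -> np.ndarray:
        return self.values[:, self.markers.index(marker)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.markers)


@dataclass
class QcReport:
    """Per-sample quality-control outcome with enumerated failure reasons."""

    table: pd.DataFrame  # sample_id, viability, n_b_cells, max_occupancy, passed, reasons

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[self.table["passed"], "sample_id"])

    @property
    def removed(self) -> list[str]:
        return list(self.table.loc[~self.table["passed"], "sample_id"])


@dataclass
class ClusterLabels:
    """Two-level cell labels for one panel's pooled events.

    ``cells`` has one row per cell with columns ``sample_id``, ``lineage``,
    ``subset`` and ``cluster`` (the raw community index).  ``profiles`` holds
    per-cluster marker medians used for lineage calling and inspection.
    """

    cells: pd.DataFrame
    profiles: pd.DataFrame = field(default_factory=pd.DataFrame)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.cells[self.cells["sample_id"] == sample_id]


# ---------------------------------------------------------------------------
# arcsinh transform
# ---------------------------------------------------------------------------

def arcsinh_transform(events: EventMatrix, cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """Variance-stabilize raw intensities with ``x -> asinh(x / cofactor)``."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if events.scale != "raw":
        raise ValueError("input already transformed")
    return replace(events, values=np.arcsinh(events.values / cofactor), scale="transformed")


def inverse_arcsinh(events: EventMatrix, cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """Invert :func:`arcsinh_transform`; exact up to floating point."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if events.scale != "transformed":
        raise ValueError("input not on transformed scale")
    return replace(events, values=np.sinh(events.values) * cofactor, scale="raw")


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def qc_filter(
    samples: dict[str, EventMatrix],
    viability: dict[str, float],
    labels: ClusterLabels | None = None,
    *,
    min_viability: float = 0.50,
    max_occupancy: float = 0.90,
) -> tuple[dict[str, EventMatrix], QcReport]:
    """Drop samples with low viability, no B cells, or one dominant cluster.

    A sample is removed iff viability < ``min_viability`` (strict), it has
    zero B cells, or more than ``max_occupancy`` (strict) of its cells sit in
    a single provisional cluster.  Boundary values (exactly 0.50 viability,
    exactly 0.90 occupancy) are kept.  A sample without a viability
    measurement is removed with reason ``"unmeasured"`` rather than silently
    kept.
    """
    rows = []
    kept: dict[str, EventMatrix] = {}
    for sid, ev in samples.items():
        reasons: list[str] = []
        viab = viability.get(sid)
        if viab is None or (isinstance(viab, float) and np.isnan(viab)):
            reasons.append("unmeasured")
            viab = np.nan
        elif viab < min_viability:
            reasons.append(f"viability<{min_viability}")
        n_b = np.nan
        occ = np.nan
        if labels is not None:
            sub = labels.for_sample(sid)
            if len(sub):
                n_b = int((sub["lineage"] == "B").sum())
                occ = sub["cluster"].value_counts(normalize=True).max()
                if n_b == 0:
                    reasons.append("zero_b_cells")
                if occ > max_occupancy:
                    reasons.append(f"occupancy>{max_occupancy}")
        passed = not reasons
        if passed:
            kept[sid] = ev
        else:
            logger.info("qc: removing sample %s (%s)", sid, ",".join(reasons))
        rows.append(
            dict(sample_id=sid, viability=viab, n_b_cells=n_b,
                 max_occupancy=occ, passed=passed, reasons=";".join(reasons))
        )
    return kept, QcReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# batch correction
# ---------------------------------------------------------------------------

def correct_batches(
    samples: dict[str, EventMatrix],
    *,
    n_anchors: int = 20,
    max_iter: int = 10,
    tol: float = 1e-3,
    correct_scale: bool = True,
    seed: int = 0,
) -> dict[str, EventMatrix]:
    """Remove batch location/scale offsets by soft-anchor matching.

    Cells from all batches are softly assigned to ``n_anchors`` cohort-wide
    anchor centroids (k-means centroids on the pooled matrix, Gaussian
    responsibilities).  Per anchor, each batch's weighted mean offset from
    the anchor's pooled mean is estimated and subtracted from its cells in
    proportion to their responsibilities; optionally a per-batch global scale
    factor towards the pooled per-marker SD is also applied.  The step
    repeats until the offsets' norm falls below ``tol`` or ``max_iter``.

    With a single batch the input is returned unchanged.  Cell and sample
    counts are never altered, only marker values.
    """
    sids = list(samples)
    if not sids:
        return {}
    for ev in samples.values():
        if ev.scale != "transformed":
            raise ValueError("batch correction expects transformed events")
    batches = sorted({samples[s].batch for s in sids})
    if len(batches) < 2:
        return dict(samples)

    X = np.vstack([samples[s].values for s in sids])
    cell_batch = np.concatenate(
        [np.full(samples[s].n_cells, batches.index(samples[s].batch)) for s in sids]
    )
    n_b = len(batches)

    # global per-batch scale matching toward pooled SD (mild, multiplicative)
    if correct_scale:
        pooled_sd = X.std(axis=0)
        pooled_sd[pooled_sd == 0] = 1.0
        for b in range(n_b):
            mask = cell_batch == b
            bsd = X[mask].std(axis=0)
            bmean = X[mask].mean(axis=0)
            ratio = np.where(bsd > 0, pooled_sd / bsd, 1.0)
            X[mask] = (X[mask] - bmean) * ratio + bmean

    min_batch = min(int((cell_batch == b).sum()) for b in range(n_b))
    if min_batch < n_anchors:
        logger.warning(
            "batch correction: smallest batch (%d cells) < n_anchors (%d); "
            "falling back to global location matching", min_batch, n_anchors)
        grand = X.mean(axis=0)
        for b in range(n_b):
            mask = cell_batch == b
            X[mask] += grand - X[mask].mean(axis=0)
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_anchors, n_init=3, random_state=seed).fit(X)
        for _ in range(max_iter):
            centers = km.cluster_centers_
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1) if X.shape[0] * n_anchors < 2e6 \
                else _sq_dists(X, centers)
            sigma2 = np.median(d2) + 1e-12
            R = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / (2 * sigma2))
            R /= R.sum(axis=1, keepdims=True)
            shift = np.zeros_like(X)
            total = 0.0
            for a in range(n_anchors):
                w = R[:, a]
                wsum = w.sum()
                if wsum < 1e-9:
                    continue
                anchor_mean = (w[:, None] * X).sum(0) / wsum
                for b in range(n_b):
                    mask = cell_batch == b
                    wb = w[mask]
                    wbsum = wb.sum()
                    if wbsum < 1e-9:
                        continue
                    batch_mean = (wb[:, None] * X[mask]).sum(0) / wbsum
                    off = batch_mean - anchor_mean
                    shift[mask] += wb[:, None] * off[None, :]
                    total += float(np.abs(off).sum()) * wbsum / len(X)
            X -= shift
            km.cluster_centers_ = _recompute_centers(X, R)
            if total < tol:
                break

    out: dict[str, EventMatrix] = {}
    start = 0
    for s in sids:
        n = samples[s].n_cells
        out[s] = replace(samples[s], values=X[start:start + n].copy())
        start += n
    return out


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    return (
        (X ** 2).sum(1, keepdims=True) - 2 * X @ C.T + (C ** 2).sum(1)[None, :]
    )


def _recompute_centers(X: np.ndarray, R: np.ndarray) -> np.ndarray:
    w = R.sum(axis=0)
    w[w == 0] = 1.0
    return (R.T @ X) / w[:, None]


def batch_mixing_entropy(
    samples: dict[str, EventMatrix], *, k: int = 30, seed: int = 0,
    max_cells: int = 20000,
) -> float:
    """Mean local batch entropy over kNN neighborhoods (higher = better mixed)."""
    sids = list(samples)
    X = np.vstack([samples[s].values for s in sids])
    batch = np.concatenate(
        [np.full(samples[s].n_cells, s_i) for s_i, s in
         ((sorted({samples[t].batch for t in sids}).index(samples[s].batch), s) for s in sids)]
    )
    if len(X) > max_cells:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(X), max_cells, replace=False)
        X, batch = X[idx], batch[idx]
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(X))).fit(X)
    _, ind = nn.kneighbors(X)
    n_b = int(batch.max()) + 1
    ent = np.zeros(len(X))
    for b in range(n_b):
        p = (batch[ind[:, 1:]] == b).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent -= np.where(p > 0, p * np.log(p), 0.0)
    return float(ent.mean())


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def build_knn_adjacency(X: np.ndarray, k: int) -> "scipy.sparse.csr_matrix":  # noqa: F821
    """Symmetrized unweighted kNN adjacency (union of directed edges)."""
    from scipy import sparse

    if X.shape[0] <= k:
        raise ValueError(f"need more than k={k} cells, got {X.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, ind = nn.kneighbors(X)
    n = X.shape[0]
    rows = np.repeat(np.arange(n), k)
    cols = ind[:, 1:].ravel()  # drop self
    A = sparse.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)
    return A


def _leiden_partition(A, resolution: float, seed: int) -> np.ndarray:
    src, dst = A.nonzero()
    keep = src < dst
    g = ig.Graph(n=A.shape[0], edges=list(zip(src[keep].tolist(), dst[keep].tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    return np.asarray(part.membership)


def _merge_small_clusters(X: np.ndarray, labels: np.ndarray, min_size: int) -> np.ndarray:
    """Merge clusters below min_size into the nearest (centroid) big cluster."""
    labels = labels.copy()
    counts = pd.Series(labels).value_counts()
    big = counts[counts >= min_size].index.to_numpy()
    if len(big) == 0:
        return np.zeros_like(labels)
    centroids = {c: X[labels == c].mean(axis=0) for c in np.unique(labels)}
    big_mat = np.vstack([centroids[c] for c in big])
    for c in counts[counts < min_size].index:
        d = ((big_mat - centroids[c]) ** 2).sum(axis=1)
        labels[labels == c] = big[int(np.argmin(d))]
    # renumber to contiguous, ordered by size then index for determinism
    order = pd.Series(labels).value_counts().sort_values(ascending=False).index
    remap = {c: i for i, c in enumerate(order)}
    return np.asarray([remap[c] for c in labels])


def modularity_of(A, labels: np.ndarray) -> float:
    src, dst = A.nonzero()
    keep = src < dst
    g = ig.Graph(n=A.shape[0], edges=list(zip(src[keep].tolist(), dst[keep].tolist())))
    return g.modularity(labels.tolist())


def cluster_cells(
    samples: dict[str, EventMatrix],
    *,
    level: str = "lineage",
    lineage_markers: list[str] | None = None,
    canonical: dict[str, tuple[str, ...]] | None = None,
    k_neighbors: int = 30,
    resolution: float = 1.0,
    min_cluster_size: int = 50,
    margin_tau: float = 0.1,
    seed: int = 0,
    prior_labels: ClusterLabels | None = None,
    subset_lineage: str | None = None,
    subset_prefix: str | None = None,
) -> ClusterLabels:
    """Graph-based clustering of pooled events at lineage or subset level.

    At ``level="lineage"`` the kNN graph is built on z-scored canonical
    lineage markers and each community is called as the lineage whose
    canonical markers have maximal mean z-scored expression; communities with
    a winning margin below ``margin_tau`` are labeled ``"unassigned"``.

    At ``level="subset"`` the graph uses the full panel on the cells of
    ``subset_lineage`` (per ``prior_labels``), producing subset labels named
    ``{subset_prefix}{index}``.
    """
    if level not in ("lineage", "subset"):
        raise ValueError("level must be 'lineage' or 'subset'")
    sids = list(samples)
    markers = samples[sids[0]].markers
    for ev in samples.values():
        if ev.scale != "transformed":
            raise ValueError("clustering expects transformed events")

    cell_sample = np.concatenate([np.full(samples[s].n_cells, i) for i, s in enumerate(sids)])
    X_full = np.vstack([samples[s].values for s in sids])

    if level == "lineage":
        use = [m for m in (lineage_markers or _default_lineage_markers(markers)) if m in markers]
        if not use:
            raise ValueError("no lineage markers present in panel")
        sel = np.arange(len(X_full))
    else:
        if prior_labels is None or subset_lineage is None:
            raise ValueError("subset level needs prior_labels and subset_lineage")
        lin = prior_labels.cells["lineage"].to_numpy()
        sel = np.where(lin == subset_lineage)[0]
        if len(sel) <= k_neighbors:
            raise ValueError(
                f"lineage {subset_lineage}: {len(sel)} cells <= k_neighbors={k_neighbors}")
        use = markers

    cols = [markers.index(m) for m in use]
    X = X_full[np.ix_(sel, cols)]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    A = build_knn_adjacency(Z, k_neighbors)
    raw = _leiden_partition(A, resolution, seed)
    raw = _merge_small_clusters(Z, raw, min_cluster_size)

    if level == "lineage":
        canon = canonical or CANONICAL_LINEAGE_MARKERS
        # z-score full canonical markers for lineage calling
        canon_markers = sorted({m for ms in canon.values() for m in ms if m in markers})
        cidx = [markers.index(m) for m in canon_markers]
        Xc = X_full[:, cidx]
        Zc = (Xc - Xc.mean(axis=0)) / np.where(Xc.std(axis=0) == 0, 1, Xc.std(axis=0))
        lineage_of_cluster: dict[int, str] = {}
        for c in np.unique(raw):
            prof = Zc[raw == c].mean(axis=0)
            scores = {}
            for lin, ms in canon.items():
                present = [canon_markers.index(m) for m in ms if m in canon_markers]
                if present:
                    scores[lin] = float(np.mean(prof[present]))
            ranked = sorted(scores.items(), key=lambda kv: -kv[1])
            if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < margin_tau:
                lineage_of_cluster[c] = "unassigned"
                logger.info("cluster %d: ambiguous lineage (margin < %.2f)", c, margin_tau)
            else:
                lineage_of_cluster[c] = ranked[0][0]
        lineage = np.asarray([lineage_of_cluster[c] for c in raw])
        cells = pd.DataFrame({
            "sample_id": [sids[i] for i in cell_sample],
            "cluster": raw,
            "lineage": lineage,
            "subset": lineage,  # placeholder until subset pass
        })
    else:
        cells = prior_labels.cells.copy()
        prefix = subset_prefix or subset_lineage[0].upper()
        names = np.asarray([f"{prefix}{c}" for c in raw])
        subset_col = cells["subset"].to_numpy(dtype=object)
        subset_col[sel] = names
        cells["subset"] = subset_col

    prof_rows = []
    for c in np.unique(raw):
        med = np.median(X_full[sel][raw == c], axis=0)
        prof_rows.append(pd.Series(med, index=markers, name=c))
    profiles = pd.DataFrame(prof_rows)
    return ClusterLabels(cells=cells, profiles=profiles)


def _default_lineage_markers(markers: list[str]) -> list[str]:
    base = ["CD3", "CD19", "CD14", "CD56", "CD11b", "CD16", "CD20"]
    found = [m for m in base if m in markers]
    return found or markers
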