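"""Sample stratification: K-means on subset proportions + IFN-I score,
anchored G0/G1/G2 labeling, PCA loadings, and one-vs-rest enrichment.

All timepoints are clustered together in a single K-means fit, so
longitudinal samples receive labels from the same model as baseline
samples.  Raw cluster indices are semantic-anchored: the cluster holding
the largest fraction of control samples becomes G0; of the remaining two,
the one with higher mean IFN-I score becomes G1 and the other G2 (ties on
IFN broken toward G2 by the granzyme-B signature, the summed proportion of
granzyme-B+ subsets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .neighborhood import NeighborhoodAbundanceMatrix, associate
from .signatures import AbundanceMatrix

logger = logging.getLogger("cytostrat")


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Samples x z-scored features (subset proportions + ifn_score)."""

    values: pd.DataFrame
    dropped_samples: list[str] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def build_features(
    abundance: AbundanceMatrix,
    ifn_scores: pd.Series,
    *,
    min_samples: int = 4,
    impute: bool = False,
) -> FeatureMatrix:
    """Join abundances with the IFN score and z-score each feature.

    Samples missing any panel (NaN in any feature) are dropped by default,
    or mean-imputed with ``impute=True``.  Zero-variance features are
    dropped with a warning.
    """
    feats = abundance.proportions.copy()
    feats["ifn_score"] = ifn_scores.reindex(feats.index)
    if impute:
        feats = feats.fillna(feats.mean())
        dropped_samples: list[str] = list(feats.index[feats.isna().any(axis=1)])
        feats = feats.dropna()
    else:
        dropped_samples = list(feats.index[feats.isna().any(axis=1)])
        feats = feats.dropna()
    if len(feats) < min_samples:
        raise ValueError(f"only {len(feats)} samples retained (< {min_samples})")
    sd = feats.std(ddof=0)
    dead = list(sd.index[sd == 0])
    if dead:
        logger.warning("dropping zero-variance features: %s", dead)
        feats = feats.drop(columns=dead)
        sd = sd.drop(dead)
    z = (feats - feats.mean()) / sd
    return FeatureMatrix(z, dropped_samples=dropped_samples, dropped_features=dead)


# ---------------------------------------------------------------------------
# K-means + anchoring
# ---------------------------------------------------------------------------

def kmeans_stratify(
    features: FeatureMatrix, k: int = 3, restarts: int = 50, seed: int = 0,
) -> tuple[pd.Series, float]:
    """k-means++ with independent restarts; returns labels and inertia."""
    X = features.values.to_numpy()
    if k > len(X):
        raise ValueError("K exceeds number of samples")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    labels = pd.Series(km.labels_, index=features.values.index, name="cluster")
    return labels, float(km.inertia_)


@dataclass
class GroupAssignment:
    """Raw cluster + anchored G0/G1/G2 label per sample, with the anchoring
    evidence (control fraction and mean IFN score per raw cluster)."""

    table: pd.DataFrame  # sample_id, cluster, group
    provenance: pd.DataFrame  # per raw cluster: control_fraction, mean_ifn, mean_gzmb

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


def anchor_group_labels(
    raw_labels: pd.Series,
    control_mask: pd.Series,
    ifn_scores: pd.Series,
    gzmb_signature: pd.Series | None = None,
) -> GroupAssignment:
    """Map raw K-means clusters to G0/G1/G2 (see module docstring)."""
    clusters = sorted(raw_labels.unique())
    if len(clusters) != 3:
        raise ValueError("anchoring requires exactly 3 clusters")
    ctrl = control_mask.reindex(raw_labels.index).fillna(False).astype(bool)
    if not ctrl.any():
        raise ValueError("no control samples to anchor G0")
    rows = {}
    for c in clusters:
        in_c = raw_labels == c
        rows[c] = dict(
            n=int(in_c.sum()),
            control_fraction=float(ctrl[in_c].mean()),
            mean_ifn=float(ifn_scores.reindex(raw_labels.index)[in_c].mean()),
            mean_gzmb=float(gzmb_signature.reindex(raw_labels.index)[in_c].mean())
            if gzmb_signature is not None else np.nan,
        )
    prov = pd.DataFrame.from_dict(rows, orient="index")
    cf = prov["control_fraction"]
    top = cf.sort_values(ascending=False)
    if len(top) > 1 and top.iloc[0] == top.iloc[1]:
        raise ValueError("ambiguous anchoring: two clusters tie on control fraction")
    g0 = top.index[0]
    rest = [c for c in clusters if c != g0]
    ifn_a, ifn_b = prov.loc[rest[0], "mean_ifn"], prov.loc[rest[1], "mean_ifn"]
    if ifn_a == ifn_b and gzmb_signature is not None:
        gz = prov.loc[rest, "mean_gzmb"]
        g2 = gz.idxmax()
        g1 = [c for c in rest if c != g2][0]
    else:
        g1 = rest[0] if ifn_a > ifn_b else rest[1]
        g2 = rest[1] if ifn_a > ifn_b else rest[0]
    mapping = {g0: "G0", g1: "G1", g2: "G2"}
    prov["anchored"] = [mapping[c] for c in prov.index]
    table = pd.DataFrame({
        "sample_id": raw_labels.index,
        "cluster": raw_labels.to_numpy(),
        "group": [mapping[c] for c in raw_labels],
    }).set_index("sample_id", drop=False)
    return GroupAssignment(table=table, provenance=prov)


def gzmb_proportion_signature(abundance: AbundanceMatrix,
                              pattern: str = "gzmB") -> pd.Series:
    """Sum of granzyme-B+ subset proportions (anchoring tie-break)."""
    cols = [c for c in abundance.proportions.columns if pattern.lower() in c.lower()]
    if not cols:
        return pd.Series(0.0, index=abundance.proportions.index)
    return abundance.proportions[cols].sum(axis=1, skipna=False)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaEmbedding:
    coordinates: pd.DataFrame      # samples x PCs
    loadings: pd.DataFrame         # features x PCs
    explained_variance_ratio: np.ndarray


def pca_embed(features: FeatureMatrix, n_components: int = 2) -> PcaEmbedding:
    """Centered PCA; each PC's sign is fixed so its largest-|loading|
    feature is positive."""
    X = features.values.to_numpy()
    n_components = min(n_components, min(X.shape))
    p = PCA(n_components=n_components).fit(X)
    comps = p.components_
    coords = p.transform(X)
    for i in range(n_components):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            coords[:, i] *= -1
    names = [f"PC{i+1}" for i in range(n_components)]
    return PcaEmbedding(
        coordinates=pd.DataFrame(coords, index=features.values.index, columns=names),
        loadings=pd.DataFrame(comps.T, index=features.values.columns, columns=names),
        explained_variance_ratio=p.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# one-vs-rest enrichment
# ---------------------------------------------------------------------------

def group_enrichment(
    abundance: AbundanceMatrix,
    assignment: GroupAssignment,
    covariates: pd.DataFrame | None = None,
    *,
    mode: str = "per-subset",
    nam: NeighborhoodAbundanceMatrix | None = None,
    fdr_q: float = 0.05,
    min_group: int = 3,
    n_perms: int = 1000,
    seed: int = 0,
):
    """One-vs-rest enrichment of each group.

    ``mode="per-subset"`` fits a covariate-adjusted linear model of each
    subset proportion on the one-vs-rest indicator with BH FDR across
    subsets; ``mode="neighborhood"`` feeds the 0/1 indicator to
    :func:`cytostrat.neighborhood.associate`.  Groups with fewer than
    ``min_group`` samples are skipped with a log message.
    """
    import statsmodels.api as sm

    groups = assignment.groups
    out: dict[str, object] = {}
    for g in sorted(groups.unique()):
        if (groups == g).sum() < min_group:
            logger.warning("group %s has <%d samples; contrast skipped", g, min_group)
            continue
        pheno = (groups == g).astype(float)
        if mode == "neighborhood":
            if nam is None:
                raise ValueError("neighborhood mode requires a NAM")
            out[g] = associate(nam, pheno, covariates, fdr_q=fdr_q,
                               n_perms=n_perms, seed=seed)
        elif mode == "per-subset":
            rows = []
            samp = abundance.proportions.index.intersection(groups.index)
            for subset in abundance.proportions.columns:
                ydf = pd.DataFrame({
                    "y": abundance.proportions.loc[samp, subset],
                    "x": pheno.loc[samp],
                })
                if covariates is not None:
                    ydf = ydf.join(pd.get_dummies(covariates.loc[samp], drop_first=True)
                                   .astype(float))
                ydf = ydf.dropna()
                X = sm.add_constant(ydf.drop(columns="y"))
                try:
                    fit = sm.OLS(ydf["y"], X).fit()
                    rows.append(dict(subset=subset, beta=fit.params["x"],
                                     p=fit.pvalues["x"]))
                except Exception:  # singular design on degenerate input
                    rows.append(dict(subset=subset, beta=np.nan, p=np.nan))
            tab = pd.DataFrame(rows).set_index("subset")
            ok = tab["p"].notna()
            tab["q"] = np.nan
            if ok.any():
                tab.loc[ok, "q"] = multipletests(tab.loc[ok, "p"], method="fdr_bh")[1]
            tab["significant"] = tab["q"] <= fdr_q
            out[g] = tab
        else:
            raise ValueError("mode must be 'per-subset' or 'neighborhood'")
    return out
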