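"""Sample-level features: subset abundances, the cytometric IFN-I score,
the simplified 5-parameter gating signature, and the co-abundance map.

The IFN-I score follows the cytometric-signature construction: per sample,
the median of MX1 and of ISG-15 over all cells of the panel carrying each
marker and the median of Siglec-1 over myeloid-lineage cells are each
standardized to the control cohort's mean and SD and summed.  A sample is
called IFN-elevated when its score strictly exceeds the control mean + 3 SD
of control scores (the threshold is a property of the reference cohort, not
a universal constant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .preprocess import ClusterLabels, EventMatrix

logger = logging.getLogger("cytostrat")

#: which panel carries each score marker, and over which cells the sample
#: median is taken ("all" cells of the panel, or one lineage)
SCORE_MARKER_SOURCE: dict[str, tuple[str, str]] = {
    "MX1": ("T", "all"),
    "ISG15": ("B", "all"),
    "SIGLEC1": ("myeloid", "myeloid"),
}


# ---------------------------------------------------------------------------
# abundance matrix
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Samples x subsets proportions; each subset is a fraction of its parent
    lineage, so a sample's subsets within one lineage sum to 1.  Lineages
    absent from a sample are missing (NaN), never zero."""

    proportions: pd.DataFrame
    subset_lineage: pd.Series  # subset -> lineage

    def lineage_columns(self, lineage: str) -> list[str]:
        return [s for s in self.proportions.columns if self.subset_lineage[s] == lineage]


def subset_proportions(
    labels_by_panel: dict[str, ClusterLabels],
    sample_ids: list[str],
    focal_lineage: dict[str, str] | None = None,
) -> AbundanceMatrix:
    """Within-lineage subset proportions per sample.

    Each panel contributes the subsets of its focal lineage (by default the
    panel's own name), with denominator the number of that lineage's cells
    in that sample on that panel.  Samples with zero cells of a lineage get
    NaN for its subsets.
    """
    cols: dict[str, dict[str, float]] = {s: {} for s in sample_ids}
    lineage_of: dict[str, str] = {}
    for panel, labels in labels_by_panel.items():
        lin = (focal_lineage or {}).get(panel, panel)
        cells = labels.cells
        lin_cells = cells[cells["lineage"] == lin]
        subsets = sorted(lin_cells["subset"].unique())
        for s in subsets:
            lineage_of[s] = lin
        counts = lin_cells.groupby(["sample_id", "subset"]).size().unstack(fill_value=0)
        for sid in sample_ids:
            if sid not in counts.index or counts.loc[sid].sum() == 0:
                for s in subsets:
                    cols[sid][s] = np.nan
                logger.info("sample %s: no %s cells on panel %s", sid, lin, panel)
                continue
            denom = counts.loc[sid].sum()
            for s in subsets:
                cols[sid][s] = counts.loc[sid].get(s, 0) / denom
    prop = pd.DataFrame.from_dict(cols, orient="index").loc[sample_ids]
    return AbundanceMatrix(prop, pd.Series(lineage_of))


# ---------------------------------------------------------------------------
# IFN-I score
# ---------------------------------------------------------------------------

@dataclass
class IfnReference:
    """Control mean/SD per score marker plus the elevation threshold
    (control-score mean + 3 SD)."""

    mean: pd.Series
    sd: pd.Series
    n_controls: int
    threshold: float
    ddof: int = 0

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"zero variance in control summaries for {bad}")


def score_marker_summaries(
    events_by_sample: dict[str, dict[str, EventMatrix]],
    labels_by_panel: dict[str, ClusterLabels],
) -> pd.DataFrame:
    """Per-sample medians of the three score markers on the transformed scale."""
    rows: dict[str, dict[str, float]] = {}
    for marker, (panel, scope) in SCORE_MARKER_SOURCE.items():
        labels = labels_by_panel.get(panel)
        for sid, per_panel in events_by_sample.items():
            ev = per_panel.get(panel)
            rows.setdefault(sid, {})
            if ev is None or marker not in ev.markers:
                rows[sid][marker] = np.nan
                continue
            x = ev.marker_column(marker)
            if scope != "all":
                if labels is None:
                    rows[sid][marker] = np.nan
                    continue
                mask = (labels.for_sample(sid)["lineage"] == scope).to_numpy()
                x = x[mask] if mask.size == x.size else x[:0]
            rows[sid][marker] = float(np.median(x)) if x.size else np.nan
    return pd.DataFrame.from_dict(rows, orient="index")


def fit_ifn_reference(control_summaries: pd.DataFrame, ddof: int = 0) -> IfnReference:
    """Fit control means/SDs (population SD by default) and the elevation
    threshold from control scores."""
    if len(control_summaries) < 2:
        raise ValueError("need at least 2 control samples")
    if control_summaries.isna().any().any():
        raise ValueError("control summaries contain missing markers")
    mu = control_summaries.mean()
    sd = control_summaries.std(ddof=ddof)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"zero variance in control summaries for {bad}")
    scores = ((control_summaries - mu) / sd).sum(axis=1)
    thr = float(scores.mean() + 3.0 * scores.std(ddof=ddof))
    return IfnReference(mean=mu, sd=sd, n_controls=len(control_summaries),
                        threshold=thr, ddof=ddof)


def ifn_score(summaries: pd.DataFrame, ref: IfnReference) -> pd.Series:
    """Sum of control-standardized marker summaries; NaN when any marker is
    missing for a sample."""
    z = (summaries[ref.mean.index] - ref.mean) / ref.sd
    score = z.sum(axis=1, skipna=False)
    missing = score.isna()
    if missing.any():
        logger.info("ifn_score: %d samples missing >=1 marker summary", int(missing.sum()))
    return score.rename("ifn_score")


def ifn_elevated(scores: pd.Series, ref: IfnReference) -> pd.Series:
    """True iff score strictly exceeds the reference threshold; missing
    scores stay missing (pd.NA), not False."""
    out = pd.Series(pd.NA, index=scores.index, dtype="boolean", name="ifn_elevated")
    ok = scores.notna()
    out[ok] = scores[ok] > ref.threshold
    return out


# ---------------------------------------------------------------------------
# simplified 5-parameter signature
# ---------------------------------------------------------------------------

@dataclass
class SimplifiedSignature:
    """Five manual-gating features per sample (percentages on 0-100 scale;
    ``neg_median_CD21_nonprolif_B`` is exactly the negated median)."""

    table: pd.DataFrame


def default_gates(
    events_by_sample: dict[str, dict[str, EventMatrix]],
    control_ids: list[str],
    markers: tuple[str, ...] = ("Ki67", "GranzymeB", "CD14", "CD16", "CD11b", "CD15"),
    percentile: float = 99.0,
) -> dict[str, float]:
    """Positivity gates at a high percentile of pooled control cells."""
    gates: dict[str, float] = {}
    for m in markers:
        vals = []
        for sid in control_ids:
            for ev in events_by_sample.get(sid, {}).values():
                if m in ev.markers:
                    vals.append(ev.marker_column(m))
        if vals:
            gates[m] = float(np.percentile(np.concatenate(vals), percentile))
    return gates


def simplified_signatures(
    events_by_sample: dict[str, dict[str, EventMatrix]],
    labels_by_panel: dict[str, ClusterLabels],
    gates: dict[str, float],
    ref: IfnReference | None = None,
) -> SimplifiedSignature:
    """Rectangular-gating signature on transformed intensities.

    Features: IFN-I score (if a reference is given), Ki67+ % of T+B cells,
    granzyme-B+ Ki67- % of T cells, median CD21 in Ki67- B cells (and its
    negation), and CD14- CD16+ CD11b+ CD15hi % of myeloid-panel events.
    """
    needed = {"Ki67", "GranzymeB", "CD14", "CD16", "CD11b", "CD15"}
    all_markers = {m for per in events_by_sample.values() for ev in per.values()
                   for m in ev.markers}
    for m in gates:
        if m not in all_markers:
            raise ValueError(f"gate marker {m} absent from every panel")
    for m in needed:
        if m not in gates:
            raise ValueError(f"missing gate for {m}")

    rows = {}
    for sid, per_panel in events_by_sample.items():
        row: dict[str, float] = {}
        # proliferative T-B: Ki67+ fraction among T and B lineage cells
        num = den = 0
        gz_num = gz_den = 0
        cd21_vals = None
        for panel in ("T", "B"):
            ev = per_panel.get(panel)
            labels = labels_by_panel.get(panel)
            if ev is None or labels is None or "Ki67" not in ev.markers:
                continue
            lin = labels.for_sample(sid)["lineage"].to_numpy()
            tb = np.isin(lin, ["T", "B"])
            ki = ev.marker_column("Ki67") > gates["Ki67"]
            den += int(tb.sum())
            num += int((tb & ki).sum())
            if panel == "T" and "GranzymeB" in ev.markers:
                t_mask = lin == "T"
                gz = ev.marker_column("GranzymeB") > gates["GranzymeB"]
                gz_den += int(t_mask.sum())
                gz_num += int((t_mask & gz & ~ki).sum())
            if panel == "B" and "CD21" in ev.markers:
                b_mask = (lin == "B") & ~ki
                cd21_vals = ev.marker_column("CD21")[b_mask]
        row["pct_proliferative_TB"] = 100.0 * num / den if den else np.nan
        row["pct_gzmB_nonprolif_T"] = 100.0 * gz_num / gz_den if gz_den else np.nan
        med = float(np.median(cd21_vals)) if cd21_vals is not None and cd21_vals.size else np.nan
        row["median_CD21_nonprolif_B"] = med
        row["neg_median_CD21_nonprolif_B"] = -med

        ev = per_panel.get("myeloid")
        if ev is not None and all(m in ev.markers for m in ("CD14", "CD16", "CD11b", "CD15")):
            ldn = (
                (ev.marker_column("CD14") <= gates["CD14"])
                & (ev.marker_column("CD16") > gates["CD16"])
                & (ev.marker_column("CD11b") > gates["CD11b"])
                & (ev.marker_column("CD15") > gates["CD15"])
            )
            row["pct_low_density_neutrophils"] = 100.0 * float(ldn.mean()) if ev.n_cells else np.nan
        else:
            row["pct_low_density_neutrophils"] = np.nan
        rows[sid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if ref is not None:
        summ = score_marker_summaries(events_by_sample, labels_by_panel)
        table.insert(0, "ifn_score", ifn_score(summ, ref))
    return SimplifiedSignature(table)


# ---------------------------------------------------------------------------
# co-abundance correlation map
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMap:
    rho: pd.DataFrame
    qvalues: pd.DataFrame
    significant: pd.DataFrame
    order: list[str]


def subset_correlation_map(
    features: pd.DataFrame, fdr_q: float = 0.05, min_samples: int = 10,
) -> CorrelationMap:
    """Pairwise-complete Spearman correlations with BH FDR over unordered
    pairs and an average-linkage hierarchical ordering on 1 - rho."""
    if len(features) < min_samples:
        raise ValueError(f"need >= {min_samples} samples")
    cols = list(features.columns)
    constant = [c for c in cols if features[c].dropna().nunique() <= 1]
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    pairs, pair_p = [], []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = cols[i], cols[j]
            sub = features[[a, b]].dropna()
            if a in constant or b in constant or len(sub) < 3:
                r, p = np.nan, np.nan
            else:
                r, p = spearmanr(sub[a], sub[b])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
            pairs.append((a, b))
            pair_p.append(p)
    pair_p = np.asarray(pair_p, dtype=float)
    ok = ~np.isnan(pair_p)
    q = np.full_like(pair_p, np.nan)
    if ok.any():
        q[ok] = multipletests(pair_p[ok], method="fdr_bh")[1]
    qmat = pd.DataFrame(np.eye(k) * 0.0, index=cols, columns=cols)
    sig = pd.DataFrame(False, index=cols, columns=cols)
    for (a, b), qv in zip(pairs, q):
        qmat.loc[a, b] = qmat.loc[b, a] = qv
        s = bool(qv <= fdr_q) if not np.isnan(qv) else False
        sig.loc[a, b] = sig.loc[b, a] = s

    usable = [c for c in cols if c not in constant]
    if len(usable) > 2:
        sub = rho.loc[usable, usable].fillna(0.0).to_numpy()
        d = np.clip(1.0 - sub, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        link = average(squareform(d, checks=False))
        order = [usable[i] for i in leaves_list(link)] + constant
    else:
        order = cols
    return CorrelationMap(rho=rho, qvalues=qmat, significant=sig, order=order)
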