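"""Synthetic multi-panel mass-cytometry cohort generator with ground truth.

Emulates a blood immunophenotyping study of lupus nephritis (LN): four
overlapping marker panels (T, B, myeloid, NK), ~40 controls plus LN patients
planted in three immunologic groups, latent cell subsets within each major
lineage, batch location/scale shifts, and a clinical table whose outcomes
are statistically coupled to the planted group.

Planted effect directions follow the target biology:

* ``G1-like`` — interferon-high: +2 control-SD shifts on the IFN-induced
  markers MX1, ISG-15 and Siglec-1 across all subsets, plus expanded
  proliferating (Ki67+) T/B/NK subsets.
* ``G2-like`` — cytotoxic-enriched: expanded granzyme-B+ T subsets, CD21-low
  naive B cells and low-density neutrophils, reduced CD21 on naive B cells,
  an intermediate and more variable IFN shift, and expanded proliferating
  subsets.
* ``G0-like`` — control-like: all effects zero.

Within-lineage subset compositions are logistic-normal: Gaussian noise on
the additive-log-ratio scale around the baseline fractions, with shared
latent per-sample factors (ifn / proliferation / cytotoxicity) that induce
correlated co-abundance blocks.  Marker values are Gaussian on the arcsinh
scale around subset templates; batch effects are additive per-marker
location shifts plus a mild scale factor; events are inverse-transformed
(``sinh(x) * cofactor``, clipped at zero) so the pipeline's own transform is
exercised on raw-scale input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .preprocess import DEFAULT_COFACTOR, LINEAGES, EventMatrix

GROUPS = ("G0-like", "G1-like", "G2-like")
SCORE_MARKERS = ("MX1", "ISG15", "SIGLEC1")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """One staining panel: which markers it carries and which separate lineages."""

    panel_name: str
    markers: list[str]
    lineage_markers: list[str]
    score_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.panel_name not in LINEAGES:
            raise ValueError(f"panel must be one of {LINEAGES}")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate markers in panel")
        if len(self.markers) > 48:
            raise ValueError("at most 48 markers per panel")
        for m in self.score_markers:
            if m not in self.markers:
                raise ValueError(f"score marker {m} not in panel")


@dataclass
class SubsetTemplate:
    """A latent cell subset: marker mean/SD profile and its baseline share of
    its lineage in a control sample.  ``mean_profile`` is on the arcsinh
    scale; markers absent from it fall back to a background level."""

    subset_name: str
    lineage: str
    mean_profile: dict[str, float]
    baseline_fraction: float
    dispersion: dict[str, float] = field(default_factory=dict)
    default_mean: float = 0.25
    default_sd: float = 0.35

    def __post_init__(self) -> None:
        if not 0 < self.baseline_fraction <= 1:
            raise ValueError("baseline_fraction must be in (0,1]")
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage}")

    def mean(self, marker: str) -> float:
        return self.mean_profile.get(marker, self.default_mean)

    def sd(self, marker: str) -> float:
        return self.dispersion.get(marker, self.default_sd)


@dataclass
class GroupEffectProfile:
    """Planted per-group effects.

    ``proportion_logfc`` maps subset name -> log fold change of its
    within-lineage fraction.  ``marker_shift`` maps ``(selector, marker)`` ->
    mean additive shift in units of the subset's marker SD, where selector is
    a subset name, a lineage name, or ``"*"`` for all subsets.
    ``marker_shift_sd`` gives optional between-sample SD of the realized
    shift (same keys, same units), modelling e.g. variable interferon tone.
    """

    group: str
    proportion_logfc: dict[str, float] = field(default_factory=dict)
    marker_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    marker_shift_sd: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        for v in list(self.proportion_logfc.values()) + list(self.marker_shift.values()):
            if not math.isfinite(v):
                raise ValueError("effects must be finite")
        if self.group == "G0-like" and (
            any(self.proportion_logfc.values()) or any(self.marker_shift.values())
        ):
            raise ValueError("G0-like must have all-zero effects")


@dataclass
class CohortDesign:
    """Cohort layout and nuisance-process settings; identical design + seed
    yields a bit-identical cohort."""

    n_controls: int = 40
    n_per_group: int = 40
    cells_per_sample: int = 1000
    n_batches: int = 4
    batch_shift_sd: float = 0.15
    batch_scale_jitter: float = 0.1
    panel_dropout_prob: float = 0.0
    timepoints: list[int] = field(default_factory=lambda: [0])
    seed: int = 0
    cofactor: float = DEFAULT_COFACTOR
    alr_sd: float = 0.3
    lineage_alr_sd: float = 0.2
    lineage_base: dict[str, float] = field(
        default_factory=lambda: {"T": 0.55, "B": 0.15, "myeloid": 0.22, "NK": 0.08})

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_per_group", "cells_per_sample", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.panel_dropout_prob <= 1:
            raise ValueError("panel_dropout_prob must be in [0,1]")


@dataclass
class GroundTruth:
    """Planted labels and realized per-sample effects (never fed to the
    pipeline except through test harnesses)."""

    sample_group: pd.Series            # sample_id -> planted group
    sample_batch: pd.Series            # sample_id -> batch
    cell_subsets: dict[tuple[str, str], np.ndarray]  # (sample, panel) -> per-cell subset
    realized_fractions: pd.DataFrame   # sample x subset within-lineage fractions
    realized_shifts: pd.DataFrame      # sample x "(marker shifts in SD units)"


# ---------------------------------------------------------------------------
# default catalog
# ---------------------------------------------------------------------------

def default_panels() -> dict[str, PanelConfig]:
    """Four overlapping panels sharing the canonical lineage markers."""
    common = ["CD3", "CD19", "CD14", "CD56", "CD11b", "CD16"]
    t = common + ["CD4", "CD8", "CD45RA", "PD1", "ICOS", "Ki67", "GranzymeB", "MX1"]
    b = common + ["CD20", "CD21", "CD11c", "CD27", "IgD", "CD38", "Ki67", "ISG15"]
    m = common + ["CD15", "CD123", "HLADR", "CD86", "SIGLEC1"]
    nk = common + ["CD57", "GranzymeB", "Ki67"]
    return {
        "T": PanelConfig("T", t, common, ["MX1"]),
        "B": PanelConfig("B", b, common, ["ISG15"]),
        "myeloid": PanelConfig("myeloid", m, common, ["SIGLEC1"]),
        "NK": PanelConfig("NK", nk, common, []),
    }


def default_templates() -> list[SubsetTemplate]:
    """~20-subset catalog across the four lineages (config-extensible)."""

    def t(name, lineage, frac, **means):
        return SubsetTemplate(name, lineage, means, frac)

    hi, mid, lo = 3.2, 2.5, 0.3
    T = dict(CD3=3.5)
    B = dict(CD19=3.5, CD20=3.0)
    M = dict(CD11b=3.0, HLADR=2.5, SIGLEC1=0.5)
    NK = dict(CD56=3.0)
    return [
        t("T0_naive_CD4", "T", 0.28, **T, CD4=hi, CD45RA=hi),
        t("T1_mem_CD4", "T", 0.20, **T, CD4=hi, CD45RA=lo),
        t("T2_naive_CD8", "T", 0.14, **T, CD8=hi, CD45RA=hi),
        t("T3_mem_CD8", "T", 0.12, **T, CD8=hi, CD45RA=lo),
        t("T4_gzmB", "T", 0.10, **T, CD8=hi, CD45RA=lo, GranzymeB=hi),
        t("T11_Tph", "T", 0.13, **T, CD4=hi, PD1=hi, ICOS=mid, CD45RA=lo),
        t("T13_gzmB_Ki67", "T", 0.03, **T, CD8=hi, GranzymeB=hi, Ki67=2.8),
        t("B0_naive", "B", 0.40, **B, IgD=3.0, CD21=2.8),
        t("B3_naive_CD21lo", "B", 0.08, **B, IgD=3.0, CD21=0.8),
        t("B2_memory", "B", 0.22, **B, CD27=2.8, CD21=2.5),
        t("B6_transitional", "B", 0.10, **B, CD38=2.8, IgD=2.5, CD21=1.5),
        t("B5_CD11c", "B", 0.10, **B, CD11c=2.8, CD21=0.5),
        t("B8_plasmablast_Ki67", "B", 0.10, CD19=3.0, CD20=0.4, CD38=3.5,
          CD27=hi, Ki67=2.5, CD21=0.3),
        t("M0_CD14_mono", "myeloid", 0.55, **M, CD14=3.5, CD86=mid),
        t("M1_CD16_mono", "myeloid", 0.13, **M, CD14=1.5, CD16=3.0),
        t("M2_cDC", "myeloid", 0.08, CD14=0.5, CD11b=1.5, HLADR=hi, SIGLEC1=0.5),
        t("M4_pDC", "myeloid", 0.07, CD14=lo, CD11b=0.5, CD123=hi, HLADR=2.8, SIGLEC1=0.5),
        t("M3_LDN", "myeloid", 0.17, CD14=lo, CD16=3.0, CD11b=hi, CD15=3.5,
          HLADR=0.8, SIGLEC1=0.5),
        t("NK0_CD56dim", "NK", 0.72, **NK, CD16=3.0, GranzymeB=mid, CD57=2.0),
        t("NK1_CD56bright", "NK", 0.14, CD56=3.8, CD16=0.5),
        t("NK4_Ki67", "NK", 0.14, **NK, Ki67=2.6, GranzymeB=2.0),
    ]


#: subsets whose fractions load on each latent co-abundance factor
FACTOR_LOADINGS: dict[str, dict[str, float]] = {
    "prolif": {"T13_gzmB_Ki67": 0.25, "B8_plasmablast_Ki67": 0.25,
               "NK4_Ki67": 0.25, "T11_Tph": 0.2},
    "cytotox": {"T4_gzmB": 0.25, "T13_gzmB_Ki67": 0.2, "NK0_CD56dim": 0.1},
    "ifn": {"B6_transitional": 0.2, "NK4_Ki67": 0.15},
}

LN2 = math.log(2.0)


def default_effects() -> list[GroupEffectProfile]:
    """Planted group effects with the target directions (see module docstring)."""
    ifn = {("*", m): 2.0 for m in SCORE_MARKERS}
    ifn_sd = {("*", m): 0.4 for m in SCORE_MARKERS}
    g1 = GroupEffectProfile(
        "G1-like",
        proportion_logfc={
            "T13_gzmB_Ki67": LN2, "B8_plasmablast_Ki67": LN2, "NK4_Ki67": LN2,
            "T11_Tph": math.log(1.8), "B6_transitional": math.log(1.8),
        },
        marker_shift=dict(ifn),
        marker_shift_sd=dict(ifn_sd),
    )
    g2 = GroupEffectProfile(
        "G2-like",
        proportion_logfc={
            "T4_gzmB": math.log(2.5), "T13_gzmB_Ki67": math.log(2.5),
            "B3_naive_CD21lo": math.log(2.2), "M3_LDN": math.log(2.2),
            "B8_plasmablast_Ki67": LN2, "T11_Tph": math.log(1.8),
        },
        marker_shift={("B3_naive_CD21lo", "CD21"): -1.5, ("B0_naive", "CD21"): -0.8}
        | {("*", m): 1.2 for m in SCORE_MARKERS},
        marker_shift_sd={("*", m): 0.8 for m in SCORE_MARKERS},
    )
    return [GroupEffectProfile("G0-like"), g1, g2]


# ---------------------------------------------------------------------------
# composition helpers
# ---------------------------------------------------------------------------

def perturbed_fractions(baseline: np.ndarray, logfc: np.ndarray) -> np.ndarray:
    """Renormalized composition after multiplying entries by exp(logfc)."""
    w = baseline * np.exp(logfc)
    return w / w.sum()


def _sample_composition(rng: np.random.Generator, baseline: np.ndarray,
                        logfc: np.ndarray, alr_sd: float) -> np.ndarray:
    """Logistic-normal draw centered at the perturbed baseline composition."""
    center = perturbed_fractions(baseline, logfc)
    logw = np.log(center) + rng.normal(0.0, alr_sd, size=len(center))
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _shift_applies(selector: str, subset: SubsetTemplate) -> bool:
    return selector == "*" or selector == subset.lineage or selector == subset.subset_name


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    design: CohortDesign,
    templates: list[SubsetTemplate] | None = None,
    effects: list[GroupEffectProfile] | None = None,
    panels: dict[str, PanelConfig] | None = None,
) -> tuple[dict[str, dict[str, EventMatrix]], pd.DataFrame, GroundTruth]:
    """Generate raw-scale event tables per sample per panel, a metadata
    table, and the planted ground truth.

    Returns ``(events, metadata, truth)`` where ``events[sample][panel]`` is
    an :class:`EventMatrix` on the raw scale.
    """
    templates = templates if templates is not None else default_templates()
    effects = effects if effects is not None else default_effects()
    panels = panels if panels is not None else default_panels()

    by_lineage: dict[str, list[SubsetTemplate]] = {lin: [] for lin in LINEAGES}
    names = set()
    for t in templates:
        by_lineage[t.lineage].append(t)
        names.add(t.subset_name)
    for lin, ts in by_lineage.items():
        if not ts:
            raise ValueError(f"no templates for lineage {lin}")
        tot = sum(t.baseline_fraction for t in ts)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"lineage {lin} baseline fractions sum to {tot}, not 1")
        if design.cells_per_sample < len(ts):
            raise ValueError("cells_per_sample smaller than subsets in a lineage")
    eff_by_group = {e.group: e for e in effects}
    for g in GROUPS:
        if g not in eff_by_group:
            raise ValueError(f"missing effect profile for {g}")
    for e in effects:
        for s in e.proportion_logfc:
            if s not in names:
                raise ValueError(f"unknown subset {s} in effects")
        for sel, m in list(e.marker_shift) + list(e.marker_shift_sd):
            if sel not in names and sel not in LINEAGES and sel != "*":
                raise ValueError(f"unknown selector {sel} in marker_shift")
            if not any(m in p.markers for p in panels.values()):
                raise ValueError(f"unknown marker {m} in marker_shift")

    # sample roster: controls + LN patients per group, replicated per timepoint
    roster = []
    pat = 0
    for _ in range(design.n_controls):
        roster.append((f"P{pat:03d}", "control", "G0-like"))
        pat += 1
    for g in ("G1-like", "G2-like", "G0-like"):
        for _ in range(design.n_per_group):
            roster.append((f"P{pat:03d}", "LN", g))
            pat += 1

    ss = np.random.SeedSequence(design.seed)
    master = np.random.default_rng(ss.spawn(1)[0])

    events: dict[str, dict[str, EventMatrix]] = {}
    meta_rows = []
    truth_group, truth_batch = {}, {}
    cell_subsets: dict[tuple[str, str], np.ndarray] = {}
    frac_rows, shift_rows = {}, {}

    # per (batch, panel, marker): location shift and scale factor
    batch_names = [f"batch{b}" for b in range(design.n_batches)]
    batch_fx = {}
    for b in batch_names:
        for pname, panel in panels.items():
            loc = master.normal(0.0, design.batch_shift_sd, size=len(panel.markers))
            scale = 1.0 + master.uniform(-design.batch_scale_jitter,
                                         design.batch_scale_jitter, size=len(panel.markers))
            batch_fx[(b, pname)] = (loc, scale)

    sample_seeds = ss.spawn(len(roster) * len(design.timepoints))
    lineage_names = list(design.lineage_base)
    lineage_base = np.array([design.lineage_base[l] for l in lineage_names])
    lineage_base = lineage_base / lineage_base.sum()

    i_seed = 0
    for patient, disease, group in roster:
        eff = eff_by_group[group]
        for tp in design.timepoints:
            sid = f"{patient}_w{tp}"
            rng = np.random.default_rng(sample_seeds[i_seed])
            i_seed += 1
            batch = batch_names[rng.integers(design.n_batches)]
            truth_group[sid] = group
            truth_batch[sid] = batch

            # realized marker shifts (SD units), shared across panels
            realized_shift: dict[tuple[str, str], float] = {}
            for key, mean_shift in eff.marker_shift.items():
                sdv = eff.marker_shift_sd.get(key, 0.0)
                realized_shift[key] = mean_shift + (rng.normal(0.0, sdv) if sdv else 0.0)
            for key, sdv in eff.marker_shift_sd.items():
                if key not in realized_shift and sdv:
                    realized_shift[key] = rng.normal(0.0, sdv)

            # latent co-abundance factors
            fvals = {f: rng.normal() for f in FACTOR_LOADINGS}

            # compositions
            lin_frac = _sample_composition(
                rng, lineage_base, np.zeros(len(lineage_base)), design.lineage_alr_sd)
            lin_frac_map = dict(zip(lineage_names, lin_frac))
            sub_frac: dict[str, np.ndarray] = {}
            for lin, ts in by_lineage.items():
                base = np.array([t.baseline_fraction for t in ts])
                logfc = np.array([
                    eff.proportion_logfc.get(t.subset_name, 0.0)
                    + sum(load.get(t.subset_name, 0.0) * fvals[f]
                          for f, load in FACTOR_LOADINGS.items())
                    for t in ts
                ])
                sub_frac[lin] = _sample_composition(rng, base, logfc, design.alr_sd)
            frac_rows[sid] = {
                t.subset_name: sub_frac[lin][j]
                for lin, ts in by_lineage.items() for j, t in enumerate(ts)
            }
            shift_rows[sid] = {f"{sel}:{m}": v for (sel, m), v in realized_shift.items()}

            # events per panel
            events[sid] = {}
            for pname, panel in panels.items():
                if design.panel_dropout_prob and rng.random() < design.panel_dropout_prob:
                    continue
                loc, scale = batch_fx[(batch, pname)]
                n = design.cells_per_sample
                # joint subset probabilities = lineage frac * within-lineage frac
                probs, subs = [], []
                for lin, ts in by_lineage.items():
                    for j, t in enumerate(ts):
                        probs.append(lin_frac_map[lin] * sub_frac[lin][j])
                        subs.append(t)
                probs = np.asarray(probs)
                probs = probs / probs.sum()
                counts = rng.multinomial(n, probs)
                blocks, labels = [], []
                for t, c in zip(subs, counts):
                    if c == 0:
                        continue
                    mu = np.array([t.mean(m) for m in panel.markers])
                    sd = np.array([t.sd(m) for m in panel.markers])
                    for (sel, m), v in realized_shift.items():
                        if m in panel.markers and _shift_applies(sel, t):
                            mi = panel.markers.index(m)
                            mu = mu.copy()
                            mu[mi] += v * sd[mi]
                    X = rng.normal(mu + loc, sd * scale, size=(c, len(panel.markers)))
                    blocks.append(X)
                    labels.extend([t.subset_name] * c)
                Xt = np.vstack(blocks)
                order = rng.permutation(len(Xt))
                Xt = np.clip(Xt[order], 0.0, None)
                labels = np.asarray(labels, dtype=object)[order]
                raw = np.sinh(Xt) * design.cofactor
                events[sid][pname] = EventMatrix(
                    raw, list(panel.markers), sample_id=sid, panel=pname,
                    batch=batch, scale="raw")
                cell_subsets[(sid, pname)] = labels

            meta_rows.append(dict(
                sample_id=sid, patient_id=patient, timepoint=tp, batch=batch,
                disease=disease, viability=float(rng.uniform(0.70, 0.98)),
                age=float(rng.normal(40, 12)),
                sex=str(rng.choice(["F", "M"], p=[0.85, 0.15])),
                ethnicity=str(rng.choice(["hispanic", "not_hispanic"], p=[0.3, 0.7])),
                race=str(rng.choice(["black", "white", "asian", "other"],
                                    p=[0.45, 0.35, 0.1, 0.1])),
            ))

    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    truth = GroundTruth(
        sample_group=pd.Series(truth_group, name="group"),
        sample_batch=pd.Series(truth_batch, name="batch"),
        cell_subsets=cell_subsets,
        realized_fractions=pd.DataFrame.from_dict(frac_rows, orient="index"),
        realized_shifts=pd.DataFrame.from_dict(shift_rows, orient="index").fillna(0.0),
    )
    return events, metadata, truth


def simulate_mixture_events(
    n_pos: int, n_neg: int, cells: int, frac: float, fold: float, seed: int = 0,
) -> tuple[dict[str, EventMatrix], pd.Series, np.ndarray]:
    """Single-panel Gaussian-mixture cohort for differential-abundance
    calibration studies: four well-separated components, with component 1 at
    baseline share ``frac`` expanded ``fold``-times in phenotype-positive
    samples (``fold=1`` gives a null cohort).

    Returns (events on transformed scale, 0/1 phenotype per sample, boolean
    mask of the planted component's cells in pooled order)."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0, 0], [4, 4, 0], [0, 4, 4], [4, 0, 4]], float)
    samples, pheno, subset = {}, {}, {}
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        f = frac * (fold if pos else 1.0)
        w = np.array([1 - f - 0.35, f, 0.2, 0.15])
        comp = rng.choice(4, size=cells, p=w / w.sum())
        X = rng.normal(centers[comp], 0.8)
        sid = f"s{i:03d}"
        samples[sid] = EventMatrix(X, ["a", "b", "c"], sample_id=sid, panel="T",
                                   scale="transformed")
        pheno[sid] = float(pos)
        subset[sid] = comp == 1
    mask = np.concatenate([subset[s] for s in samples])
    return samples, pd.Series(pheno), mask


def simulate_group_labels(
    n_controls: int, n_per_group: int, seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample roster with planted groups and demographics but no cytometry
    events — sufficient input for :func:`simulate_clinical` when only the
    clinical coupling is studied."""
    rng = np.random.default_rng(seed)
    rows, groups = [], {}
    pat = 0
    for disease, gs in [("control", ["G0-like"] * n_controls)] + [
            ("LN", [g] * n_per_group) for g in ("G1-like", "G2-like", "G0-like")]:
        for g in gs:
            sid = f"P{pat:04d}_w0"
            groups[sid] = g
            rows.append(dict(
                sample_id=sid, patient_id=f"P{pat:04d}", timepoint=0,
                batch="batch0", disease=disease,
                viability=float(rng.uniform(0.7, 0.98)),
                age=float(rng.normal(40, 12)),
                sex=str(rng.choice(["F", "M"], p=[0.85, 0.15])),
                ethnicity=str(rng.choice(["hispanic", "not_hispanic"], p=[0.3, 0.7])),
                race=str(rng.choice(["black", "white", "asian", "other"],
                                    p=[0.45, 0.35, 0.1, 0.1]))))
            pat += 1
    metadata = pd.DataFrame(rows).set_index("sample_id", drop=False)
    truth = GroundTruth(
        sample_group=pd.Series(groups, name="group"),
        sample_batch=pd.Series("batch0", index=list(groups), name="batch"),
        cell_subsets={}, realized_fractions=pd.DataFrame(),
        realized_shifts=pd.DataFrame())
    return metadata, truth


# ---------------------------------------------------------------------------
# clinical simulation
# ---------------------------------------------------------------------------

@dataclass
class ClinicalParams:
    """Effect sizes coupling clinical outcomes to the planted group.

    ``response_logor_g2`` is the log-odds offset for complete renal response
    in G2-like patients versus the rest (default ``ln(8.5)``); the intercept
    is solved so that marginal response rates match ``marginal_rates``
    (complete/partial/none, default 28 % / 24 % / 48 %).
    """

    activity_mean: dict[str, float] = field(
        default_factory=lambda: {"G0-like": 4.0, "G1-like": 8.0, "G2-like": 11.0})
    activity_sd: float = 3.0
    chronicity_mean: dict[str, float] = field(
        default_factory=lambda: {"G0-like": 5.0, "G1-like": 3.0, "G2-like": 2.5})
    chronicity_sd: float = 1.6
    proliferative_prob: dict[str, float] = field(
        default_factory=lambda: {"G0-like": 0.35, "G1-like": 0.65, "G2-like": 0.85})
    response_logor_g2: float = math.log(8.5)
    marginal_rates: tuple[float, float, float] = (0.28, 0.24, 0.48)
    upcr_ge1_fraction: float = 0.75

    def zeroed(self) -> "ClinicalParams":
        return ClinicalParams(
            activity_mean={g: 6.0 for g in GROUPS},
            chronicity_mean={g: 3.0 for g in GROUPS},
            proliferative_prob={g: 0.6 for g in GROUPS},
            response_logor_g2=0.0,
            marginal_rates=self.marginal_rates,
            upcr_ge1_fraction=self.upcr_ge1_fraction,
        )


def _solve_intercept(groups: pd.Series, logor_g2: float, target: float) -> float:
    frac_g2 = float((groups == "G2-like").mean())

    def marginal(b0: float) -> float:
        return (1 - frac_g2) * expit(b0) + frac_g2 * expit(b0 + logor_g2) - target

    return brentq(marginal, -20, 20)


def simulate_clinical(
    truth: GroundTruth,
    metadata: pd.DataFrame,
    params: ClinicalParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample clinical table coupled to the planted groups.

    Activity index is ordered in expectation G2 > G1 > G0, chronicity is
    highest in G0, and the week-52 complete-response log-odds carry a G2
    offset of ``params.response_logor_g2``.  Week-52 measurements (UPCR,
    creatinine, prednisone) are generated consistently with the drawn
    response category so the rule-based classifier reconstructs it on
    evaluable patients.  Controls carry NaN for biopsy/response fields.
    """
    params = params or ClinicalParams()
    groups = truth.sample_group
    if not set(metadata["sample_id"]).issubset(set(groups.index)):
        raise ValueError("missing group labels for some samples")
    rng = np.random.default_rng(seed)

    base = metadata[metadata["timepoint"] == metadata["timepoint"].min()]
    ln = base[base["disease"] == "LN"]
    b0 = _solve_intercept(groups.loc[ln["sample_id"]], params.response_logor_g2,
                          params.marginal_rates[0])
    p_partial_given_nc = params.marginal_rates[1] / (1.0 - params.marginal_rates[0])

    rows = []
    for sid in metadata["sample_id"]:
        g = groups.loc[sid]
        is_ln = metadata.loc[sid, "disease"] == "LN"
        if not is_ln:
            rows.append(dict(sample_id=sid, group=None))
            continue
        act = float(np.clip(round(rng.normal(params.activity_mean[g], params.activity_sd)), 0, 24))
        chron = float(np.clip(round(rng.normal(params.chronicity_mean[g], params.chronicity_sd)), 0, 12))
        prolif = bool(rng.random() < params.proliferative_prob[g])
        if rng.random() < params.upcr_ge1_fraction:
            upcr0 = 1.0 + float(rng.gamma(2.0, 1.0))
        else:
            upcr0 = float(rng.uniform(0.55, 0.99))
        creat0 = float(max(0.4, rng.normal(1.15 if g == "G2-like" else 0.9, 0.2)))
        pred0 = {"G0-like": (0.0, 10.0), "G1-like": (5.0, 20.0),
                 "G2-like": (10.0, 40.0)}[g]
        pred0 = float(rng.uniform(*pred0))

        p_complete = float(expit(b0 + (params.response_logor_g2 if g == "G2-like" else 0.0)))
        if rng.random() < p_complete:
            resp = "complete"
        else:
            resp = "partial" if rng.random() < p_partial_given_nc else "none"

        if resp == "complete":
            upcr52 = float(rng.uniform(0.05, 0.45))
            creat52 = creat0 * float(rng.uniform(0.75, 1.05))
            pred52 = float(rng.uniform(0.0, 9.5))
        elif resp == "partial":
            upcr52 = upcr0 * float(rng.uniform(0.20, 0.45))
            creat52 = creat0 * float(rng.uniform(0.80, 1.15))
            pred52 = float(rng.uniform(10.5, 15.0))
        else:
            upcr52 = upcr0 * float(rng.uniform(0.55, 1.40))
            creat52 = creat0 * float(rng.uniform(0.90, 1.40))
            pred52 = float(rng.uniform(5.0, 25.0))

        rows.append(dict(
            sample_id=sid, group=None, upcr_baseline=upcr0, upcr_wk52=upcr52,
            creatinine_baseline=creat0, creatinine_wk52=creat52,
            prednisone_baseline=pred0, prednisone_wk52=pred52,
            activity_index=act, chronicity_index=chron,
            histologic_class="proliferative" if prolif else "membranous",
            response_truth=resp,
            mmf_use=bool(rng.random() < 0.55),
        ))
    clin = pd.DataFrame(rows).set_index("sample_id", drop=False)
    for col in ("age", "sex", "ethnicity", "race"):
        clin[col] = metadata.set_index("sample_id")[col]
    clin = clin.drop(columns=["group"])
    return clin
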