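"""Readers/writers, run configuration, and the orchestrated pipeline run.

Event tables are read and written either as FCS 3.1 (float32 data segment,
one file per sample-panel, marker names in $PnS) or as CSV with a
``marker:<name>`` header convention.  A :class:`RunConfig` (YAML
round-trippable) drives the end-to-end run; every stochastic stage's seed is
derived deterministically from the master seed and recorded in the run
manifest together with SHA-256 hashes of all outputs, so identical configs
reproduce identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import preprocess as pp
from . import signatures as sig
from . import stratify as strat
from . import synthetic as syn
from .neighborhood import associate, build_graph_from_events, build_nam
from .preprocess import EventMatrix

logger = logging.getLogger("cytostrat")


# ---------------------------------------------------------------------------
# FCS 3.1 (float32, list mode)
# ---------------------------------------------------------------------------

def write_fcs(path: str | Path, events: EventMatrix) -> None:
    """Write one sample-panel event table as a minimal FCS 3.1 file."""
    X = np.asarray(events.values, dtype="<f4")
    n_cells, n_par = X.shape
    delim = "/"
    kw = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0", "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0", "$NEXTDATA": "0", "$MODE": "L", "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4", "$PAR": str(n_par), "$TOT": str(n_cells),
        "SAMPLE_ID": events.sample_id, "PANEL": events.panel,
        "BATCH": events.batch,
    }
    for i, m in enumerate(events.markers, start=1):
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1, np.ceil(X[:, i - 1].max() if n_cells else 1))))
        kw[f"$P{i}N"] = f"Ch{i}"
        kw[f"$P{i}S"] = m

    # fixed-width data offsets so TEXT length is stable while we fill them in
    def text_bytes(begin: int, end: int) -> bytes:
        items = {"$BEGINDATA": f"{begin:010d}", "$ENDDATA": f"{end:010d}", **kw}
        s = delim + delim.join(f"{k}{delim}{v}" for k, v in items.items()) + delim
        return s.encode("ascii")

    header_len = 58
    probe = text_bytes(0, 0)
    text_start = header_len
    text_end = text_start + len(probe) - 1
    data_start = text_end + 1
    data_end = data_start + X.nbytes - 1 if X.nbytes else 0
    text = text_bytes(data_start, data_end)
    assert len(text) == len(probe)

    def off(x: int) -> bytes:
        s = str(x) if x <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + off(text_start) + off(text_end) + \
        off(data_start if X.nbytes else 0) + off(data_end) + off(0) + off(0)
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(X.tobytes())


def read_fcs(path: str | Path) -> EventMatrix:
    """Read a float32 list-mode FCS 3.x file ($PnS preferred for names)."""
    raw = Path(path).read_bytes()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise ValueError(f"{path}: not an FCS file or truncated")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as e:
        raise ValueError(f"{path}: malformed header") from e
    if text_end >= len(raw):
        raise ValueError(f"{path}: truncated TEXT segment")
    text = raw[text_start:text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    kw = {parts[i]: parts[i + 1] for i in range(0, len(parts) - 1, 2)}
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if kw.get("$DATATYPE", "F") != "F":
        raise ValueError("only $DATATYPE F supported")
    begin, end = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])
    order = "<" if kw.get("$BYTEORD", "1,2,3,4").startswith("1") else ">"
    need = n_par * n_tot * 4
    buf = raw[begin:end + 1] if n_tot else b""
    if len(buf) < need:
        raise ValueError(f"{path}: truncated DATA segment")
    X = np.frombuffer(buf[:need], dtype=f"{order}f4").reshape(n_tot, n_par).astype(float)
    markers = [kw.get(f"$P{i}S") or kw.get(f"$P{i}N", f"Ch{i}")
               for i in range(1, n_par + 1)]
    return EventMatrix(
        np.clip(X, 0.0, None), markers,
        sample_id=kw.get("SAMPLE_ID", Path(path).stem),
        panel=kw.get("PANEL", "unknown"), batch=kw.get("BATCH", "batch0"),
        scale="raw")


# ---------------------------------------------------------------------------
# tabular events
# ---------------------------------------------------------------------------

def write_events_csv(path: str | Path, events: EventMatrix) -> None:
    df = pd.DataFrame(events.values, columns=[f"marker:{m}" for m in events.markers])
    df.to_csv(path, index=False)


def read_events(
    path: str | Path, fmt: str = "fcs", *,
    expected_markers: list[str] | None = None,
    sample_id: str | None = None, panel: str = "unknown", batch: str = "batch0",
) -> EventMatrix:
    """Read an event table (``fmt`` = ``"fcs"`` or ``"tabular"``) on the raw
    scale, validating marker names against an expected panel if given."""
    if fmt == "fcs":
        ev = read_fcs(path)
    elif fmt == "tabular":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("marker:")]
        if not cols:
            raise ValueError(f"{path}: no 'marker:' columns")
        markers = [c.split(":", 1)[1] for c in cols]
        ev = EventMatrix(df[cols].to_numpy(dtype=float), markers,
                         sample_id=sample_id or Path(path).stem,
                         panel=panel, batch=batch, scale="raw")
    else:
        raise ValueError("format must be 'fcs' or 'tabular'")
    if expected_markers is not None:
        unknown = [m for m in ev.markers if m not in expected_markers]
        missing = [m for m in expected_markers if m not in ev.markers]
        if unknown or missing:
            raise ValueError(
                f"{path}: marker mismatch (unknown={unknown}, missing={missing})")
    return ev


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters; serializes to YAML byte-stably."""

    master_seed: int = 0
    # cohort
    n_controls: int = 40
    n_per_group: int = 40
    cells_per_sample: int = 300
    n_batches: int = 4
    batch_shift_sd: float = 0.15
    timepoints: list[int] = field(default_factory=lambda: [0])
    # preprocess
    cofactor: float = 5.0
    k_neighbors: int = 15
    resolution: float = 1.0
    min_cluster_size: int = 50
    n_anchors: int = 20
    # neighborhood
    run_nda: bool = True
    nda_max_cells_per_sample: int = 40
    n_steps: int = 3
    n_perms: int = 400
    fdr_q: float = 0.05
    # stratify
    kmeans_k: int = 3
    restarts: int = 50

    def to_yaml(self, path: str | Path | None = None) -> str:
        s = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# orchestrated run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunResult:
    outdir: Path
    metadata: pd.DataFrame
    truth: "syn.GroundTruth"
    abundance: sig.AbundanceMatrix
    scores: pd.Series
    elevated: pd.Series
    assignment: strat.GroupAssignment
    clinical: pd.DataFrame
    responses: pd.DataFrame
    nda_global_p: float | None
    manifest: dict


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute simulate -> preprocess -> signatures -> nda -> stratify ->
    associate, writing stage outputs and a manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate
    design = syn.CohortDesign(
        n_controls=config.n_controls, n_per_group=config.n_per_group,
        cells_per_sample=config.cells_per_sample, n_batches=config.n_batches,
        batch_shift_sd=config.batch_shift_sd, timepoints=list(config.timepoints),
        seed=config.stage_seed("simulate"), cofactor=config.cofactor)
    events, metadata, truth = syn.simulate_cohort(design)
    clinical_tab = syn.simulate_clinical(truth, metadata,
                                         seed=config.stage_seed("clinical"))

    # --- preprocess: transform, QC, per-panel correction + clustering
    panels = sorted({p for per in events.values() for p in per})
    transformed: dict[str, dict[str, EventMatrix]] = {p: {} for p in panels}
    for sid, per in events.items():
        for p, ev in per.items():
            transformed[p][sid] = pp.arcsinh_transform(ev, config.cofactor)

    qc_labels = pp.cluster_cells(
        transformed["B"], level="lineage", k_neighbors=config.k_neighbors,
        resolution=config.resolution, min_cluster_size=config.min_cluster_size,
        seed=config.stage_seed("qc_cluster"))
    viability = metadata.set_index("sample_id")["viability"].to_dict()
    kept_b, qc_report = pp.qc_filter(transformed["B"], viability, qc_labels)
    kept_ids = set(kept_b)

    corrected: dict[str, dict[str, EventMatrix]] = {}
    labels_by_panel: dict[str, pp.ClusterLabels] = {}
    for p in panels:
        subset_events = {s: e for s, e in transformed[p].items() if s in kept_ids}
        corrected[p] = pp.correct_batches(
            subset_events, n_anchors=config.n_anchors,
            seed=config.stage_seed(f"batch:{p}"))
        lin = pp.cluster_cells(
            corrected[p], level="lineage", k_neighbors=config.k_neighbors,
            resolution=config.resolution, min_cluster_size=config.min_cluster_size,
            seed=config.stage_seed(f"lineage:{p}"))
        labels_by_panel[p] = pp.cluster_cells(
            corrected[p], level="subset", prior_labels=lin, subset_lineage=p,
            subset_prefix=p[0].upper(), k_neighbors=config.k_neighbors,
            resolution=config.resolution, min_cluster_size=config.min_cluster_size,
            seed=config.stage_seed(f"subset:{p}"))

    # --- signatures
    sample_ids = sorted(kept_ids)
    corrected_by_sample: dict[str, dict[str, EventMatrix]] = {s: {} for s in sample_ids}
    for p in panels:
        for s, e in corrected[p].items():
            corrected_by_sample[s][p] = e
    summaries = sig.score_marker_summaries(corrected_by_sample, labels_by_panel)
    control_ids = [s for s in sample_ids
                   if metadata.loc[s, "disease"] == "control"]
    ref = sig.fit_ifn_reference(summaries.loc[control_ids].dropna())
    scores = sig.ifn_score(summaries, ref)
    elevated = sig.ifn_elevated(scores, ref)
    abundance = sig.subset_proportions(labels_by_panel, sample_ids)
    gates = sig.default_gates(corrected_by_sample, control_ids)
    simplified = sig.simplified_signatures(corrected_by_sample, labels_by_panel,
                                           gates, ref)

    # --- neighborhood DA (T panel, LN vs control), subsampled for speed
    nda_p = None
    if config.run_nda:
        rng = np.random.default_rng(config.stage_seed("nda_subsample"))
        sub = {}
        for s, e in corrected["T"].items():
            n = min(config.nda_max_cells_per_sample, e.n_cells)
            idx = np.sort(rng.choice(e.n_cells, n, replace=False))
            sub[s] = EventMatrix(e.values[idx], e.markers, sample_id=s,
                                 panel=e.panel, batch=e.batch, scale="transformed")
        graph = build_graph_from_events(sub, k=10)
        nam = build_nam(graph, config.n_steps)
        pheno = pd.Series(
            (metadata.loc[sample_ids, "disease"] == "LN").astype(float).to_numpy(),
            index=sample_ids)
        cov = metadata.loc[sample_ids, ["age", "sex", "ethnicity", "race"]]
        nda = associate(nam, pheno, cov, n_perms=config.n_perms,
                        seed=config.stage_seed("nda"), fdr_q=config.fdr_q)
        nda_p = nda.global_p

    # --- stratify
    features = strat.build_features(abundance, scores)
    raw_labels, inertia = strat.kmeans_stratify(
        features, k=config.kmeans_k, restarts=config.restarts,
        seed=config.stage_seed("kmeans"))
    control_mask = pd.Series(
        [metadata.loc[s, "disease"] == "control" for s in features.sample_ids],
        index=features.sample_ids)
    gz = strat.gzmb_proportion_signature(abundance).reindex(features.sample_ids)
    assignment = strat.anchor_group_labels(raw_labels, control_mask, scores, gz)
    pca = strat.pca_embed(features)

    # --- associate (clinical)
    responses = clin.classify_responses(clinical_tab.loc[clinical_tab.index.intersection(
        pd.Index(sample_ids))])
    merged = assignment.table.join(clinical_tab.drop(columns="sample_id"), how="left")
    merged = merged.join(responses.drop(columns=[c for c in ("trace",) if c in responses]),
                         how="left")
    ln_eval = merged[(merged["response"].isin(["complete", "partial", "none"]))
                     & merged["group"].isin(["G0", "G1", "G2"])]
    assoc_summary = {}
    if len(ln_eval) >= 20 and ln_eval["group"].nunique() == 3:
        kw = clin.compare_groups(ln_eval["activity_index"], ln_eval["group"])
        assoc_summary["activity_kw_p"] = kw.kw_p
        try:
            m = clin.multivariable(
                (ln_eval["response"] == "complete").astype(float),
                (ln_eval["group"] == "G2").astype(float),
                ln_eval[["age", "sex"]], family="logistic")
            assoc_summary["complete_response_or_g2"] = m.coefficient
        except ValueError:
            pass

    # --- outputs + manifest
    out_files = {}
    metadata.drop(columns="sample_id").to_csv(outdir / "metadata.csv")
    qc_report.table.to_csv(outdir / "qc_report.csv", index=False)
    abundance.proportions.to_csv(outdir / "abundance.csv")
    pd.DataFrame({"ifn_score": scores, "ifn_elevated": elevated}).to_csv(
        outdir / "ifn_scores.csv")
    simplified.table.to_csv(outdir / "simplified_signatures.csv")
    assignment.table.drop(columns="sample_id").to_csv(outdir / "groups.csv")
    pca.coordinates.to_csv(outdir / "pca_coordinates.csv")
    pca.loadings.to_csv(outdir / "pca_loadings.csv")
    clinical_tab.drop(columns="sample_id").to_csv(outdir / "clinical.csv")
    responses.to_csv(outdir / "responses.csv")
    for f in sorted(outdir.glob("*.csv")):
        out_files[f.name] = _sha256(f)
    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "stage_seeds": {s: config.stage_seed(s) for s in
                        ("simulate", "clinical", "qc_cluster", "kmeans", "nda")},
        "ifn_threshold": ref.threshold,
        "kmeans_inertia": inertia,
        "nda_global_p": nda_p,
        "association": assoc_summary,
        "outputs": out_files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(outdir, metadata, truth, abundance, scores, elevated,
                     assignment, clinical_tab, responses, nda_p, manifest)
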