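"""Configuration-driven end-to-end pipeline.

Stages: acquire (simulate or ingest) -> peak detection -> marker-anchored
retention correction -> common-peak matching -> similarity -> calibration &
validation metrics -> chemometrics (PCA / HCA / OPLS-DA + VIP +
permutations) -> QAMS/ESM content comparison -> durability.  Every stage
writes plain-text tables into the output directory and the run manifest
records config, seed and library versions, so each table is recomputable
from the manifest alone.

Reproducibility: the single global seed is expanded into per-stage seeds by
fixed offsets (panel: +0, calibration: +101, permutations: +202,
durability: +303), so downstream stages can be rerun independently from
cached upstream outputs with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import (hca, oplsda, pca, permutation_test, preprocess,
                           vip, vip_markers)
from .defaults import (DURABILITY_RSD_BOUND, EXPECTED_RRT, INTERNAL_REFERENCE,
                       NAMED_ANALYTES, RETENTION_TIMES)
from .errors import HerbfpError, NotLocatedError, ValidationError
from .fingerprint import (build_reference_fingerprint, correct_retention_times,
                          match_common_peaks, similarity_table)
from .io import (read_chromatogram_csv, read_manifest, read_peak_table,
                 write_chromatogram_csv, write_manifest, write_peak_table)
from .peaks import Peak, detect_peaks, estimate_noise, lod_loq
from .quant import (CalibrationCurve, compute_rcf, durability_study,
                    esm_quantify, fit_calibration, locate_peak_by_rrt,
                    qams_quantify, relative_deviation, validation_metrics)
from .synthetic import (Chromatogram, PanelConfig, default_constituents,
                        simulate_calibration_series, simulate_panel)

__all__ = ["PipelineConfig", "RunResult", "run_pipeline",
           "chemometrics_stage", "qams_stage", "rerun_chemometrics",
           "rerun_qams"]

log = logging.getLogger("herbfp")

_SQRT2PI = float(np.sqrt(2.0 * np.pi))

STAGE_SEED_OFFSETS = {"panel": 0, "calibration": 101, "permutation": 202,
                      "durability": 303}


@dataclass
class PipelineConfig:
    """Everything needed to rerun the pipeline deterministically."""

    mode: str = "synthetic"                     # synthetic | files
    panel: PanelConfig = field(default_factory=PanelConfig)
    input_manifest: str | None = None           # files mode
    # peak detection
    min_snr: float = 5.0
    smooth_window: int = 11
    smooth_order: int = 3
    noise_region: tuple[float, float] = (1.0, 4.0)
    # fingerprint
    match_window: float = 0.1
    reference_batch: str = "S1"
    marker_search_window: float = 0.35
    marker_times: dict[str, float] = field(
        default_factory=lambda: dict(RETENTION_TIMES))
    # chemometrics
    scaling: str = "uv"
    n_clusters: int | None = None               # None -> silhouette
    linkage: str = "ward"
    n_orthogonal: int = 1
    n_permutations: int = 200
    contrast: str = "origin"                    # origin | processing
    # QAMS
    internal_ref: str = INTERNAL_REFERENCE
    qams_analytes: tuple[str, ...] = ("macrostemonoside_t",
                                      "macrostemonoside_u")
    expected_rrt: dict[str, float] = field(
        default_factory=lambda: dict(EXPECTED_RRT))
    rrt_tolerance: float = 0.005
    calibration_cv: float = 0.01
    durability_bound: float = DURABILITY_RSD_BOUND
    seed: int = 0
    make_figures: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.match_window <= 0:
            raise ValidationError("match window must be > 0")
        if self.rrt_tolerance <= 0:
            raise ValidationError("rrt tolerance must be > 0")
        if self.mode == "files" and not self.input_manifest:
            raise ValidationError("files mode needs input_manifest")
        if self.internal_ref not in self.marker_times:
            raise ValidationError(
                "internal reference analyte must be among the markers")
        for a in self.qams_analytes:
            if a not in self.expected_rrt:
                raise ValidationError(f"no expected R_t for {a}")
        if self.mode == "synthetic":
            self.panel.validate()

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_SEED_OFFSETS[stage]

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "panel" in d and isinstance(d["panel"], dict):
            d["panel"] = PanelConfig(**d["panel"])
        if "qams_analytes" in d:
            d["qams_analytes"] = tuple(d["qams_analytes"])
        if "noise_region" in d:
            d["noise_region"] = tuple(d["noise_region"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


@dataclass
class RunResult:
    outdir: Path
    config: PipelineConfig
    peak_table: object
    similarity: pd.Series
    validation: pd.DataFrame
    curves: dict[str, CalibrationCurve]
    rcf: dict[str, object]
    contents: pd.DataFrame
    durability: object
    pca: object
    hca: object
    oplsda: object
    permutation: object
    vip: pd.Series


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except HerbfpError:
                raise
            except Exception as exc:   # noqa: BLE001 - stage-named diagnostics
                raise HerbfpError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("acquire")
def _acquire(config: PipelineConfig):
    if config.mode == "synthetic":
        pc = dataclasses.replace(config.panel, seed=config.stage_seed("panel"))
        panel = simulate_panel(pc)
        return panel.chromatograms, panel.manifest
    entries = read_manifest(config.input_manifest)
    base = Path(config.input_manifest).parent
    chroms = []
    for e in entries:
        path = Path(e["file"])
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise ValidationError(f"missing chromatogram file {path}")
        chroms.append(read_chromatogram_csv(path, meta=e))
    return chroms, entries


@_stage("peaks")
def _detect_all(config: PipelineConfig, chroms: list[Chromatogram]):
    out = {}
    for c in chroms:
        out[c.meta["batch"]] = detect_peaks(
            c, min_snr=config.min_snr, smooth_window=config.smooth_window,
            smooth_order=config.smooth_order)
    return out


def _find_markers(config: PipelineConfig,
                  peak_lists: dict[str, list[Peak]]):
    """Per-batch marker apexes: nearest detected apex to each nominal marker
    time within the search window.  Markers found in every batch are kept."""
    names = sorted(config.marker_times, key=config.marker_times.get)
    per_batch: dict[str, dict[str, float]] = {}
    for batch, peaks in peak_lists.items():
        apexes = np.array([p.apex_time for p in peaks])
        found = {}
        for name in names:
            t0 = config.marker_times[name]
            if apexes.size == 0:
                continue
            j = int(np.argmin(np.abs(apexes - t0)))
            if abs(apexes[j] - t0) <= config.marker_search_window:
                found[name] = float(apexes[j])
        per_batch[batch] = found
    shared = [n for n in names
              if all(n in per_batch[b] for b in per_batch)]
    if len(shared) < 2:
        raise ValidationError(
            f"fewer than 2 markers found in every batch (got {shared})")
    markers = {b: [per_batch[b][n] for n in shared] for b in per_batch}
    reference = [config.marker_times[n] for n in shared]
    return markers, reference, shared


@_stage("fingerprint")
def _fingerprint(config: PipelineConfig, peak_lists):
    markers, reference, marker_names = _find_markers(config, peak_lists)
    corrected = correct_retention_times(peak_lists, markers, reference)
    table = match_common_peaks(corrected, config.reference_batch,
                               window=config.match_window)
    # annotate common peaks that sit on a nominal marker time
    ann = {}
    for name, t0 in config.marker_times.items():
        diffs = (table.reference_times - t0).abs()
        pid = diffs.idxmin()
        if diffs[pid] <= config.match_window:
            ann[pid] = name
    table.markers = ann
    sim = similarity_table(table, build_reference_fingerprint(table))
    return table, sim


@_stage("calibration")
def _calibration(config: PipelineConfig, chroms: list[Chromatogram]):
    """Simulated calibration series + fitted curves + validation table."""
    specs = {c.id: c for c in default_constituents()}
    seed = config.stage_seed("calibration")
    curves, series, rows = {}, {}, []
    ref_chrom = next(
        (c for c in chroms if c.meta.get("batch") == config.reference_batch),
        chroms[0])
    noise = estimate_noise(ref_chrom, config.noise_region)
    rng = np.random.default_rng(seed + 7)
    for i, name in enumerate(NAMED_ANALYTES):
        spec = specs[name]
        from .quant import _calibration_levels
        levels = _calibration_levels(spec)
        ser = simulate_calibration_series(
            spec, levels, replicate_cv=config.calibration_cv, seed=seed + i)
        curve = fit_calibration(ser, analyte=name)
        curves[name] = curve
        series[name] = ser
        sens = curve.slope / (spec.peak_sigma * _SQRT2PI)
        lod, loq = lod_loq(noise, sens)
        # replicate precision and spike recovery from simulated injections
        mid = 0.5 * (curve.c_min + curve.c_max)
        reps = spec.ideal_area(mid) * np.clip(
            1.0 + rng.normal(0.0, config.calibration_cv, size=6), 0.0, None)
        metrics = validation_metrics(
            reps,
            base=mid, spiked=mid,
            measured_total=float(np.mean(
                [esm_quantify(a, curve).content for a in
                 spec.ideal_area(2 * mid) * np.clip(
                     1.0 + rng.normal(0.0, config.calibration_cv, size=6),
                     0.0, None)])))
        rows.append((name, curve.slope, curve.intercept, curve.r_squared,
                     curve.c_min, curve.c_max, lod, loq,
                     metrics["rsd"], metrics["recovery"]))
    validation = pd.DataFrame(rows, columns=[
        "analyte", "slope", "intercept", "r_squared", "c_min", "c_max",
        "lod_ug_per_ml", "loq_ug_per_ml", "precision_rsd_percent",
        "recovery_percent"]).set_index("analyte")
    return curves, series, validation


def chemometrics_stage(areas: pd.DataFrame, groups: pd.Series,
                       config: PipelineConfig):
    """PCA + HCA + OPLS-DA/VIP/permutations on a batches x peaks matrix."""
    scaled = preprocess(areas, config.scaling)
    pca_res = pca(scaled, k=min(2, min(areas.shape[0] - 1, areas.shape[1])))
    hca_res = hca(scaled, linkage_method=config.linkage, k=config.n_clusters)
    if config.contrast == "origin":
        y = np.where(groups.loc[areas.index] == "southern",
                     "southern", "northern")
        sub = areas.index
    elif config.contrast == "processing":
        sub = areas.index[groups.loc[areas.index] != "southern"]
        y = np.where(groups.loc[sub] == "northern_freeze_dried",
                     "freeze", "heat")
    else:
        raise ValidationError(f"unknown contrast {config.contrast!r}")
    scaled_sub = (scaled if len(sub) == len(areas.index)
                  else preprocess(areas.loc[sub], config.scaling))
    model = oplsda(scaled_sub, y, n_orthogonal=config.n_orthogonal)
    perm = permutation_test(scaled_sub, y, n_perm=config.n_permutations,
                            seed=config.stage_seed("permutation"),
                            n_orthogonal=config.n_orthogonal)
    return pca_res, hca_res, model, vip(model), perm


def _group_of(entry: dict) -> str:
    if "group" in entry:
        return entry["group"]
    if entry.get("origin") == "southern":
        return "southern"
    if entry.get("processing_method") == "freeze_dried":
        return "northern_freeze_dried"
    return "northern_heat_dried"


def qams_stage(table, curves: dict[str, CalibrationCurve],
               series: dict[str, pd.DataFrame], config: PipelineConfig):
    """Per-batch ESM and QAMS contents plus their relative deviation."""
    rcf_records = {}
    for analyte in config.qams_analytes:
        rcf_records[analyte] = compute_rcf(
            series[config.internal_ref], series[analyte],
            analyte=analyte, internal_ref=config.internal_ref)
    ref_pid = table.marker_peak(config.internal_ref)
    rows = []
    for batch in table.batches:
        a_s = float(table.areas.loc[batch, ref_pid])
        t_s = float(table.apex_times.loc[batch, ref_pid])
        ref_peak = Peak(apex_time=t_s, left_bound=t_s - 0.1,
                        right_bound=t_s + 0.1, height=1.0, area=a_s,
                        snr=float("inf"))
        c_s = esm_quantify(a_s, curves[config.internal_ref]).concentration
        candidates = [
            Peak(apex_time=float(table.apex_times.loc[batch, pid]),
                 left_bound=float(table.apex_times.loc[batch, pid]) - 0.1,
                 right_bound=float(table.apex_times.loc[batch, pid]) + 0.1,
                 height=1.0, area=float(table.areas.loc[batch, pid]),
                 snr=float("inf"))
            for pid in table.peak_ids]
        rows.append((batch, config.internal_ref,
                     esm_quantify(a_s, curves[config.internal_ref]).content,
                     np.nan, np.nan))
        for analyte in config.qams_analytes:
            try:
                located = locate_peak_by_rrt(
                    candidates, ref_peak, config.expected_rrt[analyte],
                    tolerance=config.rrt_tolerance)
            except NotLocatedError as exc:
                raise HerbfpError(
                    f"stage 'qams' failed for batch {batch}: {exc}") from exc
            a_i = located.peak.area
            esm = esm_quantify(a_i, curves[analyte]).content
            qams = qams_quantify(a_i, a_s, c_s,
                                 rcf_records[analyte].mean_rcf).content
            rows.append((batch, analyte, esm, qams,
                         relative_deviation(esm, qams)))
    contents = pd.DataFrame(rows, columns=[
        "batch", "analyte", "esm_ug_per_g", "qams_ug_per_g", "rd_percent"])
    return rcf_records, contents


@_stage("figures")
def _figures(outdir: Path, pca_res, hca_res, model, vip_series, perm):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.scatter(pca_res.scores.iloc[:, 0], pca_res.scores.iloc[:, 1])
    for b in pca_res.scores.index:
        ax.annotate(b, (pca_res.scores.loc[b].iloc[0],
                        pca_res.scores.loc[b].iloc[1]), fontsize=7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.savefig(outdir / "pca_scores.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 3))
    vip_series.sort_values(ascending=False).plot.bar(ax=ax)
    ax.axhline(1.0, color="red", lw=0.8)
    fig.tight_layout()
    fig.savefig(outdir / "vip.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    perms = perm.record[perm.record["perm_id"] > 0]
    ax.scatter(perms["corr"], perms["r2y"], s=10, label="R2Y")
    ax.scatter(perms["corr"], perms["q2"], s=10, label="Q2")
    ax.scatter([1.0], [perm.original_r2y], marker="s")
    ax.scatter([1.0], [perm.original_q2], marker="s")
    ax.legend()
    ax.set_xlabel("|corr(y_perm, y)|")
    fig.savefig(outdir / "permutations.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(hca_res.heatmap.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(hca_res.leaf_order)))
    ax.set_yticklabels(hca_res.leaf_order, fontsize=7)
    fig.colorbar(im)
    fig.savefig(outdir / "hca_heatmap.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, outdir) -> RunResult:
    """Run all stages and write the report bundle into ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chroms, entries = _acquire(config)
    # always export the ingested/simulated traces for round-tripping
    chrom_dir = outdir / "chromatograms"
    chrom_dir.mkdir(exist_ok=True)
    exported = []
    for c in chroms:
        fname = f"{c.meta['batch']}.csv"
        write_chromatogram_csv(c, chrom_dir / fname)
        e = {k: v for k, v in c.meta.items()}
        e["file"] = fname
        exported.append(e)
    write_manifest(exported, chrom_dir / "manifest.json")

    peak_lists = _detect_all(config, chroms)
    table, sim = _fingerprint(config, peak_lists)
    sim.to_frame().to_csv(outdir / "similarity.csv", index_label="batch")
    write_peak_table(table, outdir / "peak_table.csv",
                     outdir / "peak_table_meta.json",
                     outdir / "apex_times.csv")

    curves, series, validation = _calibration(config, chroms)
    validation.to_csv(outdir / "validation.csv")
    pd.concat([s.assign(analyte=a) for a, s in series.items()])[
        ["analyte", "concentration", "area"]].to_csv(
        outdir / "calibration_series.csv", index=False)

    groups = pd.Series({e["batch"]: _group_of(e) for e in entries})
    try:
        pca_res, hca_res, model, vip_series, perm = chemometrics_stage(
            table.areas, groups, config)
    except HerbfpError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise HerbfpError(f"stage 'chemometrics' failed: {exc}") from exc
    pca_res.scores.to_csv(outdir / "pca_scores.csv", index_label="batch")
    pca_res.loadings.to_csv(outdir / "pca_loadings.csv", index_label="peak")
    pd.DataFrame({"cluster": hca_res.labels}).to_csv(
        outdir / "hca_clusters.csv", index_label="batch")
    (outdir / "hca_dendrogram.nwk").write_text(hca_res.newick + "\n")
    pd.DataFrame({"t": model.t}, index=model.sample_names).join(
        pd.DataFrame(model.t_ortho, index=model.sample_names,
                     columns=[f"t_ortho{j + 1}"
                              for j in range(model.t_ortho.shape[1])])
    ).to_csv(outdir / "oplsda_scores.csv", index_label="batch")
    vm = vip_markers(model)
    vip_series.to_frame().assign(
        flagged=vip_series.index.isin(vm.index)).to_csv(
        outdir / "vip.csv", index_label="peak")
    perm.record.to_csv(outdir / "permutations.csv", index=False)

    rcf_records, contents = qams_stage(table, curves, series, config)
    contents.to_csv(outdir / "contents.csv", index=False,
                    float_format="%.6f")
    dur = durability_study(
        internal_ref=next(c for c in default_constituents()
                          if c.id == config.internal_ref),
        analytes=[c for c in default_constituents()
                  if c.id in config.qams_analytes],
        area_noise_cv=config.calibration_cv,
        seed=config.stage_seed("durability"),
        bound=config.durability_bound)
    dur.records.to_csv(outdir / "durability.csv", index=False)
    dur.rsd.to_csv(outdir / "durability_rsd.csv")
    rcf_rows = [(r.analyte, r.internal_ref, r.mean_rcf, r.rcf_rsd)
                for r in rcf_records.values()]
    pd.DataFrame(rcf_rows, columns=[
        "analyte", "internal_ref", "mean_rcf", "rcf_rsd_percent"]).to_csv(
        outdir / "rcf.csv", index=False)

    manifest = {
        "herbfp_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGE_SEED_OFFSETS},
        "config": config.to_dict(),
        "versions": _library_versions(),
        "chemometrics": {
            "pca_explained": [float(v) for v in pca_res.explained[:pca_res.k]],
            "pca_q2": pca_res.q2,
            "hca_k": hca_res.k,
            "oplsda": {"r2x": model.r2x, "r2y": model.r2y, "q2": model.q2},
            "permutation_q2_intercept": perm.q2_intercept,
            "permutation_verdict": perm.verdict,
            "scaling": config.scaling,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if config.make_figures:
        try:
            _figures(outdir, pca_res, hca_res, model, vip_series, perm)
        except HerbfpError as exc:
            log.warning("figures skipped: %s", exc)

    return RunResult(
        outdir=outdir, config=config, peak_table=table, similarity=sim,
        validation=validation, curves=curves, rcf=rcf_records,
        contents=contents, durability=dur, pca=pca_res, hca=hca_res,
        oplsda=model, permutation=perm, vip=vip_series)


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "sklearn": sklearn.__version__}


def rerun_chemometrics(outdir, config: PipelineConfig, target=None):
    """Recompute the chemometrics tables from a previous run's cached peak
    table; writes into ``target`` (default: the same directory)."""
    outdir = Path(outdir)
    target = Path(target) if target else outdir
    target.mkdir(parents=True, exist_ok=True)
    table = read_peak_table(outdir / "peak_table.csv",
                            outdir / "peak_table_meta.json",
                            outdir / "apex_times.csv")
    entries = read_manifest(outdir / "chromatograms" / "manifest.json")
    groups = pd.Series({e["batch"]: _group_of(e) for e in entries})
    pca_res, hca_res, model, vip_series, perm = chemometrics_stage(
        table.areas, groups, config)
    pca_res.scores.to_csv(target / "pca_scores.csv", index_label="batch")
    pca_res.loadings.to_csv(target / "pca_loadings.csv", index_label="peak")
    pd.DataFrame({"cluster": hca_res.labels}).to_csv(
        target / "hca_clusters.csv", index_label="batch")
    perm.record.to_csv(target / "permutations.csv", index=False)
    vm = vip_markers(model)
    vip_series.to_frame().assign(
        flagged=vip_series.index.isin(vm.index)).to_csv(
        target / "vip.csv", index_label="peak")
    return pca_res, hca_res, model, vip_series, perm


def rerun_qams(outdir, config: PipelineConfig, target=None) -> pd.DataFrame:
    """Recompute the ESM/QAMS/RD table from a previous run's cached peak
    table (calibration series are re-simulated from the stage seed)."""
    outdir = Path(outdir)
    target = Path(target) if target else outdir
    target.mkdir(parents=True, exist_ok=True)
    table = read_peak_table(outdir / "peak_table.csv",
                            outdir / "peak_table_meta.json",
                            outdir / "apex_times.csv")
    specs = {c.id: c for c in default_constituents()}
    seed = config.stage_seed("calibration")
    from .quant import _calibration_levels
    series, curves = {}, {}
    for i, name in enumerate(NAMED_ANALYTES):
        spec = specs[name]
        ser = simulate_calibration_series(
            spec, _calibration_levels(spec),
            replicate_cv=config.calibration_cv, seed=seed + i)
        series[name] = ser
        curves[name] = fit_calibration(ser, analyte=name)
    _, contents = qams_stage(table, curves, series, config)
    contents.to_csv(target / "contents.csv", index=False,
                    float_format="%.6f")
    return contents
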