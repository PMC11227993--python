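"""End-to-end orchestration: simulate -> preprocess -> INT maps ->
summaries -> group statistics -> mediation -> cognitive components.

One top-level seed fans out into per-stage seeds by stable derivation, so a
single integer reproduces every artifact byte for byte.  The whole-brain
stage finds supra-threshold clusters by permutation FWE; spherical ROIs are
then centred at the significant cluster peaks — local regions are defined
by where the whole-brain comparison finds them — unless the configuration
pins explicit ROI centres.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cognitive import component_correlations, componentize, reference_stats
from .core import IntMap, Parcellation
from .intmap import compute_int_map, smooth_map
from .io import save_atlas, save_bold, save_int_map, write_tsv
from .mediation import run_model_suite, suite_to_frame
from .preprocess import framewise_displacement, preprocess_bold, qc_filter_subjects
from .roi import network_mean, roi_mean, sphere_roi, summary_table
from .stats import (cluster_fwe_perm, normality_test, pearson_bootstrap,
                    two_sample_t, voxelwise_glm_t)
from .synthetic import Cohort, CohortSpec, simulate_cohort


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class PreprocConfig:
    discard_n: int = 5
    band: tuple[float, float] = (0.01, 0.1)
    motion_threshold_mm: float = 3.0
    motion_model: str = "6"


@dataclass(frozen=True)
class IntConfig:
    fwhm_mm: float = 8.0
    include_lag0: bool = False
    auc: str = "riemann"


@dataclass(frozen=True)
class StatsConfig:
    n_boot: int = 10_000
    n_perm: int = 1000
    cluster_p: float = 0.001
    connectivity: int = 6


@dataclass(frozen=True)
class RoiDef:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 4.0


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocessing: PreprocConfig = field(default_factory=PreprocConfig)
    int_options: IntConfig = field(default_factory=IntConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    rois: Optional[tuple[RoiDef, ...]] = None  # None: derive from cluster peaks
    roi_radius_mm: float = 4.0
    mediation_group: str = "AD"  # "AD", "CN" or "all"
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["phi_by_region_and_group"] = {
            k: dict(v) for k, v in self.cohort.phi_by_region_and_group.items()}
        d["cohort"]["confound_amplitudes"] = dict(self.cohort.confound_amplitudes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw: dict = {}
        if "cohort" in d:
            kw["cohort"] = CohortSpec(**d.pop("cohort"))
        if "preprocessing" in d:
            pp = dict(d.pop("preprocessing"))
            if "band" in pp:
                pp["band"] = tuple(pp["band"])
            kw["preprocessing"] = PreprocConfig(**pp)
        if "int_options" in d:
            kw["int_options"] = IntConfig(**d.pop("int_options"))
        if "stats" in d:
            kw["stats"] = StatsConfig(**d.pop("stats"))
        if d.get("rois") is not None:
            kw["rois"] = tuple(
                RoiDef(name=r["name"], center_mm=tuple(r["center_mm"]),
                       radius_mm=r.get("radius_mm", 4.0))
                for r in d.pop("rois"))
        else:
            d.pop("rois", None)
        unknown = set(d) - {"roi_radius_mm", "mediation_group", "seed"}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kw.update(d)
        return cls(**kw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff every invariant holds; each problem names its field."""
    problems: list[str] = []
    if config.seed is None:
        problems.append("seed: a top-level seed is required")
    pp = config.preprocessing
    lo, hi = pp.band
    if not (0 < lo < hi):
        problems.append(f"preprocessing.band: need 0 < low < high, got {pp.band}")
    nyq = 1.0 / (2.0 * config.cohort.tr_s)
    if hi >= nyq:
        problems.append(f"preprocessing.band: high cutoff {hi} >= Nyquist {nyq:.4f}")
    if not (pp.motion_threshold_mm > 0):
        problems.append("preprocessing.motion_threshold_mm: must be positive")
    if pp.discard_n < 0:
        problems.append("preprocessing.discard_n: must be nonnegative")
    if pp.motion_model not in ("6", "24"):
        problems.append("preprocessing.motion_model: must be '6' or '24'")
    if not (config.int_options.fwhm_mm > 0):
        problems.append("int_options.fwhm_mm: must be positive")
    if config.int_options.auc not in ("riemann", "trapezoid"):
        problems.append("int_options.auc: must be 'riemann' or 'trapezoid'")
    st = config.stats
    if st.n_boot < 1:
        problems.append("stats.n_boot: must be >= 1")
    if st.n_perm < 100:
        problems.append("stats.n_perm: must be >= 100")
    if not (0 < st.cluster_p < 1):
        problems.append("stats.cluster_p: must lie in (0, 1)")
    if st.connectivity not in (6, 18, 26):
        problems.append("stats.connectivity: must be 6, 18 or 26")
    if not (config.roi_radius_mm > 0):
        problems.append("roi_radius_mm: must be positive")
    if config.mediation_group not in ("AD", "CN", "all"):
        problems.append("mediation_group: must be 'AD', 'CN' or 'all'")
    for roi in config.rois or ():
        if not (roi.radius_mm > 0):
            problems.append(f"rois.{roi.name}.radius_mm: must be positive")
    return problems


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31."""
    digest = zlib_crc(stage)
    return int(np.random.SeedSequence([int(master), digest]).generate_state(1)[0] % (2**31))


def zlib_crc(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())


# ---------------------------------------------------------------------------
# In-memory analysis engine (shared by run_pipeline, tests and scripts)


def subject_int_map(cohort: Cohort, subject_id: str, preproc: PreprocConfig,
                    int_options: IntConfig) -> IntMap:
    bold, conf = cohort.bold_for(subject_id)
    clean = preprocess_bold(bold, conf, n_discard=preproc.discard_n,
                            band=preproc.band, motion_model=preproc.motion_model)
    imap = compute_int_map(clean, mask=cohort.atlas.brain_mask,
                           include_lag0=int_options.include_lag0,
                           method=int_options.auc)
    if int_options.fwhm_mm:
        imap = smooth_map(imap, int_options.fwhm_mm)
    return imap


def cohort_int_maps(cohort: Cohort, preproc: PreprocConfig = PreprocConfig(),
                    int_options: IntConfig = IntConfig(),
                    subject_ids=None) -> dict[str, IntMap]:
    ids = subject_ids if subject_ids is not None else [s.id for s in cohort.subjects]
    return {sid: subject_int_map(cohort, sid, preproc, int_options) for sid in ids}


def cohort_summary(cohort: Cohort, int_maps: dict[str, IntMap],
                   rois: dict[str, object] | None = None) -> pd.DataFrame:
    """Subject x variable table: network INT means, optional ROI INT means,
    merged with the phenotype table (column order fixed)."""
    summ = summary_table(int_maps, cohort.atlas, rois)
    return summ.merge(cohort.phenotypes, on="subject", how="left")


def _roi_name_for_peak(atlas: Parcellation, peak_mm) -> str:
    idx = np.rint(atlas.geometry.mm_to_voxel(peak_mm)).astype(int)
    idx = np.clip(idx, 0, np.asarray(atlas.geometry.grid_dims) - 1)
    lab = int(atlas.labels[tuple(idx)])
    return atlas.label_names.get(lab, f"x{peak_mm[0]:+.0f}y{peak_mm[1]:+.0f}z{peak_mm[2]:+.0f}")


# ---------------------------------------------------------------------------
# run_pipeline


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, write all intermediates under ``out_dir`` and
    return the run manifest.  Any stage failure halts with the stage name
    and cause; outputs written so far are retained."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    out = Path(out_dir)
    if out.exists() and not out.is_dir():
        raise PipelineError("setup", f"{out} exists and is not a directory")
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as err:
        raise PipelineError("setup", err) from err

    manifest: dict = {
        "tool": "ntpipe",
        "version": _version,
        "config_sha256": hashlib.sha256(
            json.dumps(PipelineConfig.to_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {},
        "stages": {},
    }
    _write_json(PipelineConfig.to_dict(config), out / "config.json")

    def run_stage(name, fn):
        try:
            fn()
            manifest["stages"][name] = "ok"
        except Exception as err:
            manifest["stages"][name] = f"failed: {err}"
            _write_json(manifest, out / "manifest.json")
            raise PipelineError(name, err) from err

    state: dict = {}

    def stage_simulate():
        seed = derive_seed(config.seed, "cohort")
        manifest["stage_seeds"]["cohort"] = seed
        cohort = simulate_cohort(replace(config.cohort, seed=seed))
        state["cohort"] = cohort
        save_atlas(cohort.atlas, out / "atlas.nii.gz", out / "atlas_labels.json")
        write_tsv(cohort.phenotypes, out / "phenotypes.tsv")
        write_tsv(cohort.truth, out / "truth.tsv")
        subj_dir = out / "subjects"
        subj_dir.mkdir(exist_ok=True)
        for s in cohort.subjects:
            d = subj_dir / s.id
            d.mkdir(exist_ok=True)
            bold, conf = cohort.bold_for(s.id)
            save_bold(bold, d / "bold.nii.gz")
            write_tsv(conf, d / "confounds.tsv")

    def stage_qc():
        cohort = state["cohort"]
        kept, excluded = qc_filter_subjects(
            cohort.subjects, config.preprocessing.motion_threshold_mm)
        state["kept_ids"] = [s.id for s in kept]
        rows = []
        for s in cohort.subjects:
            _, conf = cohort.bold_for(s.id)
            fd = framewise_displacement(conf)
            rows.append({"subject": s.id, "mean_motion_mm": s.mean_motion_mm,
                         "max_fd_mm": float(fd.max()), "mean_fd_mm": float(fd.mean()),
                         "kept": s.id in state["kept_ids"]})
        write_tsv(pd.DataFrame(rows), out / "qc.tsv")
        if len(state["kept_ids"]) < 6:
            raise ValueError("fewer than 6 subjects survive motion QC")

    def stage_int_maps():
        cohort = state["cohort"]
        maps = {}
        for sid in state["kept_ids"]:
            bold, conf = cohort.bold_for(sid)
            clean = preprocess_bold(
                bold, conf, n_discard=config.preprocessing.discard_n,
                band=config.preprocessing.band,
                motion_model=config.preprocessing.motion_model)
            d = out / "subjects" / sid
            save_bold(clean, d / "clean.nii.gz")
            imap = compute_int_map(clean, mask=cohort.atlas.brain_mask,
                                   include_lag0=config.int_options.include_lag0,
                                   method=config.int_options.auc)
            imap = smooth_map(imap, config.int_options.fwhm_mm)
            save_int_map(imap, d / "int.nii.gz", d / "int.json",
                         options={"fwhm_mm": config.int_options.fwhm_mm,
                                  "include_lag0": config.int_options.include_lag0,
                                  "auc": config.int_options.auc})
            maps[sid] = imap
        state["int_maps"] = maps

    def stage_group_stats():
        cohort = state["cohort"]
        maps = state["int_maps"]
        kept = [cohort.subject(sid) for sid in state["kept_ids"]]
        summary = cohort_summary(cohort, maps)
        dmn = summary.set_index("subject").loc[state["kept_ids"]]
        cn = dmn[dmn["group"] == "CN"]["DMN_int"].to_numpy()
        ad = dmn[dmn["group"] == "AD"]["DMN_int"].to_numpy()
        test = two_sample_t(cn, ad)
        med = dmn[dmn["group"] == config.mediation_group] if config.mediation_group != "all" else dmn
        sw_w, sw_p = normality_test(med["mmse"].to_numpy(dtype=float))
        boot_seed = derive_seed(config.seed, "dmn_mmse")
        manifest["stage_seeds"]["dmn_mmse"] = boot_seed
        corr = pearson_bootstrap(med["DMN_int"].to_numpy(), med["mmse"].to_numpy(dtype=float),
                                 n_boot=config.stats.n_boot, seed=boot_seed)
        state["group_stats"] = {
            "dmn_group_test": {"t": test.t, "df": test.df, "p": test.p, "eta2": test.eta2,
                               "n_cn": int(cn.size), "n_ad": int(ad.size)},
            "mmse_shapiro": {"W": sw_w, "p": sw_p},
            "dmn_mmse_correlation": {"r": corr.r, "p_boot": corr.p_boot, "n": corr.n,
                                     "group": config.mediation_group},
        }
        _write_json(state["group_stats"], out / "group_stats.json")

        groups = [s.group for s in kept]
        ages = [s.age for s in kept]
        sexes = [s.sex for s in kept]
        ordered_maps = [maps[sid] for sid in state["kept_ids"]]
        perm_seed = derive_seed(config.seed, "cluster_perm")
        manifest["stage_seeds"]["cluster_perm"] = perm_seed
        clusters = cluster_fwe_perm(
            ordered_maps, groups, ages, sexes, cohort.atlas.geometry,
            cluster_forming_p=config.stats.cluster_p, n_perm=config.stats.n_perm,
            seed=perm_seed, connectivity=config.stats.connectivity)
        t_map, _, _ = voxelwise_glm_t(ordered_maps, groups, ages, sexes)
        state["clusters"] = clusters
        rows = [{"region": _roi_name_for_peak(cohort.atlas, c.peak_coord_mm),
                 "x_mm": c.peak_coord_mm[0], "y_mm": c.peak_coord_mm[1],
                 "z_mm": c.peak_coord_mm[2],
                 "cluster_size_voxels": c.cluster_size_voxels,
                 "peak_t": c.peak_t, "p_fwe": c.p_fwe} for c in clusters]
        write_tsv(pd.DataFrame(rows, columns=["region", "x_mm", "y_mm", "z_mm",
                                              "cluster_size_voxels", "peak_t", "p_fwe"]),
                  out / "clusters.tsv")
        state["summary_networks"] = summary

    def stage_rois_and_summary():
        cohort = state["cohort"]
        if config.rois is not None:
            roi_defs = {r.name: (r.center_mm, r.radius_mm) for r in config.rois}
        else:
            roi_defs = {}
            for c in state["clusters"]:
                if c.p_fwe < 0.05:
                    name = _roi_name_for_peak(cohort.atlas, c.peak_coord_mm)
                    roi_defs.setdefault(name, (c.peak_coord_mm, config.roi_radius_mm))
        rois = {name: sphere_roi(center, radius, cohort.atlas.geometry)
                for name, (center, radius) in roi_defs.items()}
        state["rois"] = rois
        summary = cohort_summary(cohort, state["int_maps"], rois)
        state["summary"] = summary
        write_tsv(summary, out / "summary.tsv")

    def stage_mediation():
        summary = state["summary"]
        data = summary if config.mediation_group == "all" else \
            summary[summary["group"] == config.mediation_group]
        roi_names = [n for n in state["rois"] if f"{n}_int" in summary.columns]
        med_seed = derive_seed(config.seed, "mediation")
        manifest["stage_seeds"]["mediation"] = med_seed
        suite = run_model_suite(data, roi_names=roi_names or ["AG"],
                                n_boot=config.stats.n_boot, seed=med_seed)
        state["mediation"] = suite
        frame = suite_to_frame(suite)
        write_tsv(frame, out / "mediation.tsv")
        _write_json({mid: {
            "status": oc.status, "reason": oc.reason,
            "preconditions": oc.preconditions,
            "result": None if oc.result is None else dataclasses.asdict(oc.result),
            "p_bonferroni": oc.p_bonferroni,
        } for mid, oc in suite.items()}, out / "mediation.json")

    def stage_cognition():
        summary = state["summary"]
        pheno = state["cohort"].phenotypes
        ref = reference_stats(pheno[pheno["group"] == "CN"])
        sel = summary if config.mediation_group == "all" else \
            summary[summary["group"] == config.mediation_group]
        comps = componentize(sel, ref)
        cog_seed = derive_seed(config.seed, "cognition")
        manifest["stage_seeds"]["cognition"] = cog_seed
        table = component_correlations(comps, sel["DMN_int"].to_numpy(),
                                       n_boot=config.stats.n_boot, seed=cog_seed)
        state["cognition"] = table
        write_tsv(table, out / "cognition.tsv")

    def stage_report():
        report = {
            "group_stats": state["group_stats"],
            "clusters": [dataclasses.asdict(c) for c in state["clusters"]],
            "mediation": {mid: {"status": oc.status,
                                "ab": None if oc.result is None else oc.result.ab,
                                "p": None if oc.result is None else oc.result.p,
                                "p_bonferroni": oc.p_bonferroni}
                          for mid, oc in state["mediation"].items()},
            "cognition": state["cognition"].to_dict(orient="records"),
        }
        _write_json(report, out / "report.json")

    run_stage("simulate", stage_simulate)
    run_stage("qc", stage_qc)
    run_stage("int_maps", stage_int_maps)
    run_stage("group_stats", stage_group_stats)
    run_stage("rois", stage_rois_and_summary)
    run_stage("mediation", stage_mediation)
    run_stage("cognition", stage_cognition)
    run_stage("report", stage_report)
    _write_json(manifest, out / "manifest.json")
    return manifest
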