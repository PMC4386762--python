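"""End-to-end orchestration: simulate → preprocess → metrics → GLM → inference.

:func:`analyze_band` runs the full statistical chain for one frequency
band of a cohort held in memory and returns every intermediate product;
:func:`run_full_analysis` loops it over the standard bands for a
configured run, writing maps (NIfTI), tables (TSV) and a JSON manifest
that records versions, seeds and thresholds so a run can be reproduced
bit for bit.

Per band the outputs mirror the study's figure logic: per-group
mean-effect t maps of FC and ALFF; grey-matter group means with
post-hoc tests; the control group's FC~ALFF coupling t map with its
cluster-corrected significance mask and cluster table; between-group
coupling contrasts restricted to the control-significant mask; and
ROI-level FC/ALFF summaries with one-tailed group tests.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .bands import DEFAULT_BANDS, FrequencyBand, get_band
from .cluster_inference import (
    ClusterThresholdSpec,
    estimate_fwhm,
    label_clusters,
    simulate_cluster_threshold,
)
from .coupling_glm import (
    CouplingResult,
    fit_voxelwise,
    group_contrast,
    one_sample_t_map,
    roi_summary,
)
from .fluctuation_metrics import BandMap, alff_map, global_fc_map, smooth_map, zscore_map
from .preprocess import build_nuisance, detrend, bandpass, regress_nuisance
from .summary_stats import t_critical
from .synthetic_cohort import CohortSpec, cohort_geometry, generate_cohort
from .volumes_io import (
    BoldRun,
    MaskSet,
    SubjectRecord,
    write_cohort_table,
    write_map,
    write_mask_set,
    write_bold,
    write_motion,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "analyze_band", "prepare_subjects", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full reproducible run.

    Either ``cohort_spec`` (simulate) or ``input_dir`` (load a directory
    written by the simulator / CLI) must be provided.
    """

    output_dir: str | Path = "lffcouple_run"
    cohort_spec: CohortSpec | None = None
    input_dir: str | Path | None = None
    bands: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)
    model: str = "pooled_interaction"
    voxel_p: float = 0.005
    contrast_voxel_p: float = 0.005
    alpha: float = 0.05
    cluster_iterations: int = 1000
    connectivity: str = "faces"
    n_compcor: int = 5
    map_smoothing_fwhm: float = 3.0
    seed: int = 0
    write_subject_maps: bool = False

    def __post_init__(self) -> None:
        if self.cohort_spec is None and self.input_dir is None:
            raise ValueError("provide either cohort_spec or input_dir")
        for b in self.bands:
            get_band(b)


def prepare_subjects(
    records: list[SubjectRecord],
    runs: list[BoldRun],
    masks: MaskSet,
    n_compcor: int = 5,
) -> list[BoldRun]:
    """Nuisance-regress and detrend every run (band filtering deferred).

    Motion parameters come from each subject's record when present.
    """
    by_id = {r.subject_id: r for r in records}
    prepared = []
    for run in runs:
        rec = by_id.get(run.subject_id)
        motion = rec.motion if rec is not None else None
        nuis = build_nuisance(run, masks, motion=motion, n_compcor=n_compcor)
        out = detrend(regress_nuisance(run, nuis))
        prepared.append(out)
    return prepared


@dataclass
class BandAnalysis:
    """Everything :func:`analyze_band` computes for one band."""

    band: FrequencyBand
    fc_maps: list[BandMap]
    alff_maps: list[BandMap]
    fc_z_maps: list[BandMap]
    alff_z_maps: list[BandMap]
    mean_effect_t: dict[str, dict[str, np.ndarray]]
    gm_summary: pd.DataFrame
    gm_alff_anova: tuple[float, float]
    coupling: CouplingResult
    k_min: int
    voxel_t_threshold: float
    hc_sig_mask: np.ndarray
    hc_cluster_table: pd.DataFrame
    contrasts: dict[str, dict] = dc_field(default_factory=dict)
    roi_table: pd.DataFrame | None = None
    fwhm_vox: float = 0.0


def _gm_group_anova(
    maps: list[BandMap], records: list[SubjectRecord], gm: np.ndarray
) -> tuple[float, float]:
    """One-way ANOVA across groups on subject-mean GM map values."""
    by_group: dict[str, list[float]] = {}
    by_id = {m.subject_id: m for m in maps}
    for r in records:
        vals = by_id[r.subject_id].values[gm]
        by_group.setdefault(r.group, []).append(float(np.nanmean(vals)))
    groups = [np.asarray(v) for v in by_group.values() if len(v) >= 2]
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def analyze_band(
    records: list[SubjectRecord],
    runs: list[BoldRun],
    masks: MaskSet,
    band: FrequencyBand,
    prepared: list[BoldRun] | None = None,
    model: str = "pooled_interaction",
    voxel_p: float = 0.005,
    contrast_voxel_p: float = 0.005,
    alpha: float = 0.05,
    cluster_iterations: int = 1000,
    connectivity: str = "faces",
    n_compcor: int = 5,
    seed: int = 0,
    roi_masks: dict[str, np.ndarray] | None = None,
    map_smoothing_fwhm: float = 3.0,
) -> BandAnalysis:
    """Run the complete statistical chain for one frequency band.

    ``prepared`` may carry already nuisance-regressed and detrended runs
    (so several bands can share the preprocessing); otherwise it is
    computed here.  ``seed`` drives only the cluster-threshold Monte
    Carlo.  ``roi_masks`` adds ROI-level summaries beyond the default
    whole-GM and control-significant-cluster ROIs.

    ``map_smoothing_fwhm`` (in voxels) smooths the per-subject FC and
    ALFF maps before spatial z-scoring and group modeling, mirroring the
    acquisition-space Gaussian smoothing of the emulated pipeline; the
    raw (unsmoothed) maps are kept for the ROI/GM summaries.
    """
    t0 = time.time()
    if prepared is None:
        prepared = prepare_subjects(records, runs, masks, n_compcor=n_compcor)
    brain = masks.brain

    fc_maps, alff_maps, fc_z, alff_z = [], [], [], []
    for run in prepared:
        filtered = bandpass(run, band)
        fc = global_fc_map(filtered, brain, band)
        al = alff_map(run, band, brain)
        fc_maps.append(fc)
        alff_maps.append(al)
        fc_z.append(zscore_map(smooth_map(fc, map_smoothing_fwhm)))
        alff_z.append(zscore_map(smooth_map(al, map_smoothing_fwhm)))
    logger.info(
        "band %s: %d subjects, %d brain voxels, maps in %.1fs",
        band.name,
        len(prepared),
        int(brain.sum()),
        time.time() - t0,
    )

    groups = sorted({r.group for r in records})
    mean_effect = {
        g: {
            "fc": one_sample_t_map(fc_z, records, g)[0],
            "alff": one_sample_t_map(alff_z, records, g)[0],
        }
        for g in groups
    }

    gm_summary = roi_summary(fc_maps, records, {"gm": masks.gm})
    gm_alff_anova = _gm_group_anova(alff_maps, records, masks.gm)

    coupling = fit_voxelwise(fc_z, alff_z, records, model=model)
    df = coupling.group_df("HC") if "HC" in coupling.groups else coupling.group_df(groups[0])

    # smoothness of the across-subject residual fields feeds the null model
    resid_maps = _group_demeaned(fc_z, records)
    fwhm_axes = estimate_fwhm(resid_maps, brain)
    fwhm = float(np.mean(fwhm_axes))

    k_min = simulate_cluster_threshold(
        ClusterThresholdSpec(
            mask=coupling.mask,
            fwhm_mm=fwhm,
            voxel_size_mm=1.0,
            voxel_p=voxel_p,
            alpha=alpha,
            n_iterations=cluster_iterations,
            connectivity=connectivity,
            seed=seed,
        )
    )
    t_thr = t_critical(df, voxel_p)
    ref_group = "HC" if "HC" in coupling.groups else coupling.groups[0]
    hc_labels, hc_table = label_clusters(
        coupling.t[ref_group], t_thr, connectivity=connectivity, min_size=k_min
    )
    hc_mask = hc_labels > 0

    contrasts: dict[str, dict] = {}
    roi_table = None
    if hc_mask.any() and len(coupling.groups) > 1:
        k_min_restricted = simulate_cluster_threshold(
            ClusterThresholdSpec(
                mask=hc_mask,
                fwhm_mm=fwhm,
                voxel_size_mm=1.0,
                voxel_p=contrast_voxel_p,
                alpha=alpha,
                n_iterations=cluster_iterations,
                connectivity=connectivity,
                seed=seed + 1,
            )
        )
        for g2 in coupling.groups:
            if g2 == ref_group:
                continue
            tmap, cdf = group_contrast(coupling, ref_group, g2, restrict_mask=hc_mask)
            cdf_scalar = float(cdf) if np.isscalar(cdf) else float(np.nanmin(cdf))
            c_thr = t_critical(cdf_scalar, contrast_voxel_p)
            labels, table = label_clusters(
                tmap, c_thr, connectivity=connectivity, min_size=k_min_restricted
            )
            contrasts[f"{ref_group}_vs_{g2}"] = {
                "t_map": tmap,
                "df": cdf,
                "threshold": c_thr,
                "k_min": k_min_restricted,
                "labels": labels,
                "table": table,
            }
        rois = {"gm": masks.gm, "hc_significant": hc_mask}
        if roi_masks:
            rois.update(roi_masks)
        roi_table = pd.concat(
            [
                roi_summary(fc_maps, records, rois).assign(measure="fc"),
                roi_summary(alff_maps, records, rois).assign(measure="alff"),
            ],
            ignore_index=True,
        )

    logger.info(
        "band %s: df=%s, fwhm=%.2f vox, k_min=%d, %d significant cluster(s), %.1fs",
        band.name,
        df,
        fwhm,
        k_min,
        len(hc_table),
        time.time() - t0,
    )
    return BandAnalysis(
        band=band,
        fc_maps=fc_maps,
        alff_maps=alff_maps,
        fc_z_maps=fc_z,
        alff_z_maps=alff_z,
        mean_effect_t=mean_effect,
        gm_summary=gm_summary,
        gm_alff_anova=gm_alff_anova,
        coupling=coupling,
        k_min=k_min,
        voxel_t_threshold=t_thr,
        hc_sig_mask=hc_mask,
        hc_cluster_table=hc_table,
        contrasts=contrasts,
        roi_table=roi_table,
        fwhm_vox=fwhm,
    )


def _group_demeaned(maps: list[BandMap], records: list[SubjectRecord]) -> list[np.ndarray]:
    """Subject maps minus their group mean map (across-subject residuals)."""
    by_id = {m.subject_id: m for m in maps}
    out = []
    for g in sorted({r.group for r in records}):
        ids = [r.subject_id for r in records if r.group == g]
        stack = np.stack([by_id[i].values for i in ids])
        mean = stack.mean(axis=0)
        out.extend(list(stack - mean))
    return [np.nan_to_num(m) for m in out]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute a configured run and write the report bundle.

    Produces, per band, NIfTI statistic maps and TSV tables under
    ``<output_dir>/<band>/`` plus a run manifest
    ``<output_dir>/manifest.json``.  Any stage failure raises with a
    stage-tagged message; partial outputs are retained.  Returns the
    manifest dict.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "model": config.model,
        "voxel_p": config.voxel_p,
        "contrast_voxel_p": config.contrast_voxel_p,
        "alpha": config.alpha,
        "cluster_iterations": config.cluster_iterations,
        "connectivity": config.connectivity,
        "n_compcor": config.n_compcor,
        "map_smoothing_fwhm": config.map_smoothing_fwhm,
        "bands": list(config.bands),
        "stages": {},
    }

    def stage(name):
        def wrap(fn, *args, **kwargs):
            t0 = time.time()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # re-tag with the failing stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
            return result

        return wrap

    if config.cohort_spec is not None:
        spec = config.cohort_spec
        manifest["cohort_seed"] = spec.seed
        records, runs, masks = stage("simulate")(generate_cohort, spec)
        stage("write_cohort")(write_cohort_table, records, out_dir / "cohort.tsv")
    else:
        from .volumes_io import read_bold, read_cohort_table, read_mask_set, read_motion

        input_dir = Path(config.input_dir)
        records = stage("read_cohort")(read_cohort_table, input_dir / "cohort.tsv")
        masks = stage("read_masks")(read_mask_set, input_dir / "masks")
        runs = []
        for rec in records:
            rec.motion = read_motion(input_dir / f"{rec.subject_id}_motion.tsv")
            runs.append(read_bold(input_dir / f"{rec.subject_id}_bold.nii.gz"))

    prepared = stage("preprocess")(
        prepare_subjects, records, runs, masks, config.n_compcor
    )

    affine = runs[0].affine
    manifest["n_subjects"] = len(records)
    manifest["grid"] = list(masks.shape)
    for band_name in config.bands:
        band = get_band(band_name)
        analysis = stage(f"analyze_{band_name}")(
            analyze_band,
            records,
            runs,
            masks,
            band,
            prepared=prepared,
            model=config.model,
            voxel_p=config.voxel_p,
            contrast_voxel_p=config.contrast_voxel_p,
            alpha=config.alpha,
            cluster_iterations=config.cluster_iterations,
            connectivity=config.connectivity,
            seed=config.seed,
            map_smoothing_fwhm=config.map_smoothing_fwhm,
        )
        band_dir = out_dir / band_name
        band_dir.mkdir(exist_ok=True)
        ref = "HC" if "HC" in analysis.coupling.groups else analysis.coupling.groups[0]
        write_map(analysis.coupling.t[ref], affine, band_dir / f"coupling_t_{ref}.nii.gz")
        write_map(
            analysis.hc_sig_mask.astype(float), affine, band_dir / "hc_significant_mask.nii.gz"
        )
        analysis.hc_cluster_table.to_csv(
            band_dir / "hc_clusters.tsv", sep="\t", index=False
        )
        for g, eff in analysis.mean_effect_t.items():
            write_map(eff["fc"], affine, band_dir / f"mean_effect_fc_t_{g}.nii.gz")
            write_map(eff["alff"], affine, band_dir / f"mean_effect_alff_t_{g}.nii.gz")
        analysis.gm_summary.to_csv(band_dir / "gm_fc_summary.tsv", sep="\t", index=False)
        for cname, c in analysis.contrasts.items():
            write_map(c["t_map"], affine, band_dir / f"contrast_t_{cname}.nii.gz")
            c["table"].to_csv(band_dir / f"contrast_clusters_{cname}.tsv", sep="\t", index=False)
        if analysis.roi_table is not None:
            analysis.roi_table.to_csv(band_dir / "roi_summary.tsv", sep="\t", index=False)
        if config.write_subject_maps:
            for m in analysis.fc_maps + analysis.alff_maps:
                write_map(
                    m.values, affine, band_dir / f"{m.subject_id}_{m.kind}.nii.gz"
                )
        manifest["stages"][f"analyze_{band_name}"].update(
            {
                "df": analysis.coupling.df
                if isinstance(analysis.coupling.df, int)
                else dict(analysis.coupling.df),
                "k_min": analysis.k_min,
                "voxel_t_threshold": round(analysis.voxel_t_threshold, 4),
                "fwhm_vox": round(analysis.fwhm_vox, 3),
                "n_hc_clusters": int(len(analysis.hc_cluster_table)),
                "gm_alff_anova_p": round(analysis.gm_alff_anova[1], 4),
            }
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_simulated_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write a simulated cohort to disk in the layout the CLI consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, runs, masks = generate_cohort(spec)
    write_cohort_table(records, out_dir / "cohort.tsv")
    write_mask_set(masks, out_dir / "masks")
    for rec, run in zip(records, runs):
        write_bold(run, out_dir / f"{rec.subject_id}_bold.nii.gz")
        write_motion(rec.motion, out_dir / f"{rec.subject_id}_motion.tsv")
    return out_dir
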