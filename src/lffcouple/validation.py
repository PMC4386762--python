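"""Self-validation studies: parameter recovery, error calibration and
replication of the planted group structure.

These routines re-derive the package's statistical guarantees from
scratch by simulation — nominal type-I rates of the voxel-wise tests,
familywise control of the cluster-extent correction, recovery of
planted coupling slopes, and replication of the
coupled-controls/uncoupled-patients pattern across independent
synthetic cohorts.  They back both the test suite and the
``scripts/acceptance.py`` report.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .bands import FULL_BAND
from .cluster_inference import (
    ClusterThresholdSpec,
    label_clusters,
    simulate_cluster_threshold,
)
from .coupling_glm import fit_voxelwise, standardize_covariates, _group_indicators
from .fluctuation_metrics import BandMap
from .pipeline import analyze_band
from .synthetic_cohort import (
    CohortSpec,
    cohort_geometry,
    generate_cohort,
    generate_covariates,
)
from .volumes_io import GROUPS, SubjectRecord

__all__ = [
    "synthetic_records",
    "slope_recovery_study",
    "glm_type1_study",
    "anova_type1_study",
    "fwe_calibration_study",
    "kmin_vs_smoothness_study",
    "headline_replication",
]


def synthetic_records(rng: np.random.Generator, n_per_group: int = 10) -> list[SubjectRecord]:
    """Subject records with covariates drawn from the reference cohort."""
    spec = CohortSpec(n_per_group=n_per_group)
    records = []
    for g in GROUPS:
        cov = generate_covariates(spec, g, rng, n=n_per_group)
        for i in range(n_per_group):
            records.append(
                SubjectRecord(
                    subject_id=f"{g}{i:02d}",
                    group=g,
                    age=float(cov["age"][i]),
                    gender=str(cov["gender"][i]),
                    education=float(cov["education"][i]),
                    gmv=float(cov["gmv"][i]),
                )
            )
    return records


def _maps(values: np.ndarray, records, shape, mask, kind) -> list[BandMap]:
    out = []
    for row, rec in zip(values, records):
        vol = np.full(shape, np.nan)
        vol[mask] = row
        out.append(BandMap(values=vol, band=FULL_BAND, kind=kind, subject_id=rec.subject_id))
    return out


def slope_recovery_study(
    slopes: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9),
    n_voxels: int = 200,
    noise_sd: float = 0.3,
    n_per_group: int = 10,
    seed: int = 0,
) -> dict[float, float]:
    """Mean recovered ALFF slope for planted across-subject slopes.

    At each simulated voxel the control group's FC is ``b * ALFF +
    noise``; the pooled model's mean estimated HC slope over the voxels
    is returned per planted ``b``.
    """
    rng = np.random.default_rng(seed)
    records = synthetic_records(rng, n_per_group)
    n = len(records)
    side = int(np.ceil(n_voxels ** (1 / 3))) + 2
    shape = (side, side, side)
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[:n_voxels] = True
    out = {}
    for b in slopes:
        alff = rng.standard_normal((n, n_voxels))
        fc = b * alff + noise_sd * rng.standard_normal((n, n_voxels))
        res = fit_voxelwise(
            _maps(fc, records, shape, mask, "fc_z"),
            _maps(alff, records, shape, mask, "alff_z"),
            records,
        )
        out[b] = float(np.nanmean(res.beta["HC"][mask]))
    return out


def _pooled_slope_t(records, ind, cov, alff, fc, df) -> float:
    x = np.column_stack([ind, ind * alff[:, None], cov])
    xtx = x.T @ x
    cinv = np.linalg.inv(xtx)
    b = cinv @ (x.T @ fc)
    resid = fc - x @ b
    sigma2 = float(resid @ resid) / df
    k = ind.shape[1]
    se = np.sqrt(sigma2 * cinv[k, k])
    return float(b[k] / se) if se > 0 else 0.0


def glm_type1_study(
    n_replicates: int = 10000,
    voxel_p: float = 0.005,
    seed: int = 0,
) -> float:
    """Permutation-null rejection rate of the voxel-wise coupling test.

    Per replicate a voxel's FC is generated with a real dependence on
    ALFF, then the ALFF values are permuted across subjects, destroying
    the link; the fraction of two-tailed HC-slope p-values below
    ``voxel_p`` estimates the test's realized type-I rate.
    """
    rng = np.random.default_rng(seed)
    records = synthetic_records(rng)
    ind, _ = _group_indicators(records)
    cov, _ = standardize_covariates(records)
    n = len(records)
    df = n - (2 * ind.shape[1] + cov.shape[1])
    t_crit = stats.t.isf(voxel_p / 2.0, df)
    rejections = 0
    for _ in range(n_replicates):
        alff = rng.standard_normal(n)
        fc = 0.5 * alff + 0.5 * rng.standard_normal(n)
        alff_perm = rng.permutation(alff)
        t = _pooled_slope_t(records, ind, cov, alff_perm, fc, df)
        rejections += int(abs(t) >= t_crit)
    return rejections / n_replicates


def anova_type1_study(
    n_replicates: int = 10000,
    voxel_p: float = 0.005,
    n_per_group: int = 10,
    seed: int = 0,
) -> float:
    """Label-permutation null rejection rate of the voxel one-way ANOVA."""
    rng = np.random.default_rng(seed)
    n_groups = 3
    n = n_groups * n_per_group
    df1, df2 = n_groups - 1, n - n_groups
    f_crit = stats.f.isf(voxel_p, df1, df2)
    labels = np.repeat(np.arange(n_groups), n_per_group)
    rejections = 0
    vals = rng.standard_normal((n_replicates, n))
    for v in vals:
        perm = rng.permutation(labels)  # identical distributions under H0
        groups = [v[perm == g] for g in range(n_groups)]
        grand = v.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ssb / df1) / (ssw / df2)
        rejections += int(f >= f_crit)
    return rejections / n_replicates


def fwe_calibration_study(
    mask_shape: tuple[int, int, int] = (32, 32, 32),
    fwhm_vox: float = 2.0,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    calibration_iterations: int = 2000,
    n_validation_fields: int = 1000,
    seed: int = 0,
) -> dict:
    """Familywise-error check of the Monte Carlo cluster threshold.

    ``k_min`` is calibrated on one stream of null fields, then applied
    to fresh fields from an independent stream; the fraction with any
    surviving cluster is the realized familywise error, to be compared
    with ``alpha``.
    """
    mask = np.ones(mask_shape, dtype=bool)
    k_min = simulate_cluster_threshold(
        ClusterThresholdSpec(
            mask=mask,
            fwhm_mm=fwhm_vox,
            voxel_size_mm=1.0,
            voxel_p=voxel_p,
            alpha=alpha,
            n_iterations=calibration_iterations,
            seed=seed,
        )
    )
    rng = np.random.default_rng(seed + 1)
    z_thr = stats.norm.isf(voxel_p / 2.0)
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    structure = ndimage.generate_binary_structure(3, 1)
    false_positives = 0
    for _ in range(n_validation_fields):
        field = rng.standard_normal(mask_shape)
        if sigma > 0:
            field = ndimage.gaussian_filter(field, sigma=sigma, mode="constant")
        field = (field - field.mean()) / field.std()
        supra = np.abs(field) >= z_thr
        if supra.any():
            labels, _ = ndimage.label(supra, structure=structure)
            if np.bincount(labels.ravel())[1:].max() >= k_min:
                false_positives += 1
    rate = false_positives / n_validation_fields
    band = 2.0 * np.sqrt(alpha * (1 - alpha) / n_validation_fields)
    return {"k_min": k_min, "fwe_rate": rate, "alpha": alpha, "band": band}


def kmin_vs_smoothness_study(
    fwhms: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0),
    mask_shape: tuple[int, int, int] = (32, 32, 32),
    iterations: int = 2000,
    seed: int = 0,
) -> list[int]:
    """Cluster-size thresholds over increasing null-field smoothness."""
    mask = np.ones(mask_shape, dtype=bool)
    return [
        simulate_cluster_threshold(
            ClusterThresholdSpec(
                mask=mask,
                fwhm_mm=f,
                voxel_size_mm=1.0,
                voxel_p=0.005,
                alpha=0.05,
                n_iterations=iterations,
                seed=seed,
            )
        )
        for f in fwhms
    ]


def headline_replication(
    n_replicates: int = 20,
    base_seed: int = 0,
    spec: CohortSpec | None = None,
    cluster_iterations: int = 500,
    roi_alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate the planted headline pattern over independent cohorts.

    Per replicate cohort (full-band analysis): whether the control group
    shows a cluster-corrected significant coupling region overlapping
    the planted networks; whether neither patient-like group shows any
    corrected-significant coupling cluster; and, in the planted coupled
    region, whether FC is significantly reduced (control > AD-like,
    one-tailed at ``roi_alpha``) while ALFF is not.
    """
    base = CohortSpec() if spec is None else spec
    rows = []
    for r in range(n_replicates):
        cspec = replace(base, seed=base_seed + r)
        geom = cohort_geometry(cspec)
        records, runs, masks = generate_cohort(cspec)
        analysis = analyze_band(
            records,
            runs,
            masks,
            FULL_BAND,
            cluster_iterations=cluster_iterations,
            seed=base_seed + r,
        )
        coup = geom.coupled_mask
        hc_detected = bool((analysis.hc_sig_mask & coup).any())
        patient_clusters = 0
        for g in ("MCI", "AD"):
            _, table = label_clusters(
                analysis.coupling.t[g],
                analysis.voxel_t_threshold,
                min_size=analysis.k_min,
            )
            patient_clusters += len(table)
        from .coupling_glm import roi_summary

        roi = roi_summary(analysis.fc_maps, records, {"coupled": coup})
        roi_alff = roi_summary(analysis.alff_maps, records, {"coupled": coup})
        fc_row = roi[roi.contrast == "HC_gt_AD"].iloc[0]
        alff_row = roi_alff[roi_alff.contrast == "HC_gt_AD"].iloc[0]
        rows.append(
            {
                "replicate": r,
                "seed": cspec.seed,
                "hc_detected": hc_detected,
                "n_hc_clusters": int(len(analysis.hc_cluster_table)),
                "patient_clusters": patient_clusters,
                "patients_clean": patient_clusters == 0,
                "roi_fc_p": float(fc_row.p_one_tailed),
                "roi_alff_p": float(alff_row.p_one_tailed),
                "roi_fc_reduced": bool(fc_row.p_one_tailed < roi_alpha),
                "roi_alff_preserved": bool(alff_row.p_one_tailed > roi_alpha),
                "gm_alff_anova_p": float(analysis.gm_alff_anova[1]),
                "k_min": analysis.k_min,
            }
        )
    return pd.DataFrame(rows)
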