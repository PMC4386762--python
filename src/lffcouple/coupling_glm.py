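"""Second-level voxel-wise regression of FC on ALFF across subjects.

At every voxel the spatially z-scored global-FC value is regressed on
the spatially z-scored ALFF value across subjects, with standardized
age, gender (M=1/F=0), education and grey-matter volume as nuisance
covariates.  Two model variants are provided:

* ``pooled_interaction`` (default): one GLM over all subjects with
  group-specific intercepts and group-specific ALFF slopes plus the four
  covariates (10 columns for three groups of 10, residual df = 20).
  Group slopes are tested one-sample within the model and compared
  between groups through the fitted slope covariance.
* ``per_group``: fully independent per-group fits (6 columns within a
  group of 10, df = 4); between-group slope comparisons use a
  Welch-style combination with Satterthwaite df.

The pooled variant is the default because per-group fits with four
covariates at n = 10 leave only 4 residual df, making voxel-level
thresholds impractically severe; both remain available.

The module also provides the voxel-wise one-way ANOVA across groups and
ROI-level summaries (group means ± SE with one-tailed two-sample tests
in the control > patient direction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fluctuation_metrics import BandMap
from .volumes_io import GROUPS, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "CouplingResult",
    "build_design",
    "fit_voxelwise",
    "group_contrast",
    "voxelwise_anova",
    "roi_summary",
    "one_sample_t_map",
    "standardize_covariates",
]

COVARIATES = ("age", "gender", "education", "gmv")

MODELS = ("pooled_interaction", "per_group")


@dataclass
class DesignMatrix:
    """A second-level design with labeled columns.

    ``slope_cols`` maps each group label to its ALFF-slope column index;
    ``df`` is the residual degrees of freedom.
    """

    x: np.ndarray
    labels: list[str]
    slope_cols: dict[str, int]
    df: int

    @property
    def n(self) -> int:
        return self.x.shape[0]


def standardize_covariates(records: list[SubjectRecord]) -> tuple[np.ndarray, list[str]]:
    """Standardized covariate matrix (mean 0, SD 1 over the subjects given).

    Gender is coded M=1 / F=0 before standardization.  Covariates that
    are constant over the given subjects cannot be standardized and are
    dropped with a logged warning.
    """
    raw = {
        "age": np.array([r.age for r in records], dtype=float),
        "gender": np.array([1.0 if r.gender == "M" else 0.0 for r in records]),
        "education": np.array([r.education for r in records], dtype=float),
        "gmv": np.array([r.gmv for r in records], dtype=float),
    }
    cols, labels = [], []
    for name in COVARIATES:
        v = raw[name]
        sd = v.std()
        if sd == 0:
            logger.warning("covariate %r is constant; dropped from the design", name)
            continue
        cols.append((v - v.mean()) / sd)
        labels.append(name)
    if not cols:
        return np.empty((len(records), 0)), []
    return np.column_stack(cols), labels


def _group_indicators(records: list[SubjectRecord]) -> tuple[np.ndarray, list[str]]:
    present = [g for g in GROUPS if any(r.group == g for r in records)]
    for g in present:
        if sum(r.group == g for r in records) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    ind = np.column_stack(
        [[1.0 if r.group == g else 0.0 for r in records] for g in present]
    )
    return ind, present


def build_design(
    records: list[SubjectRecord],
    alff_values: np.ndarray,
    model: str = "pooled_interaction",
):
    """Build the second-level design for one voxel's ALFF values.

    For ``pooled_interaction``: a single :class:`DesignMatrix` with one
    intercept and one ALFF-slope column per group plus the standardized
    covariates.  For ``per_group``: a dict mapping each group label to
    its own 6-column design (intercept, ALFF, covariates standardized
    within the group).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    alff_values = np.asarray(alff_values, dtype=float)
    if alff_values.shape != (len(records),):
        raise ValueError("alff_values must have one entry per record")
    if model == "pooled_interaction":
        ind, groups = _group_indicators(records)
        cov, cov_labels = standardize_covariates(records)
        slope = ind * alff_values[:, None]
        x = np.column_stack([ind, slope, cov])
        labels = (
            [f"intercept_{g}" for g in groups]
            + [f"alff_{g}" for g in groups]
            + cov_labels
        )
        slope_cols = {g: len(groups) + i for i, g in enumerate(groups)}
        df = len(records) - x.shape[1]
        if df < 1:
            raise ValueError(f"design leaves no residual df (n={len(records)})")
        return DesignMatrix(x=x, labels=labels, slope_cols=slope_cols, df=df)
    # per_group
    _, groups = _group_indicators(records)
    designs: dict[str, DesignMatrix] = {}
    for g in groups:
        sub = [r for r in records if r.group == g]
        idx = [i for i, r in enumerate(records) if r.group == g]
        cov, cov_labels = standardize_covariates(sub)
        x = np.column_stack([np.ones(len(sub)), alff_values[idx], cov])
        labels = ["intercept", "alff"] + cov_labels
        df = len(sub) - x.shape[1]
        if df < 1:
            raise ValueError(f"per-group design for {g!r} leaves no residual df")
        designs[g] = DesignMatrix(x=x, labels=labels, slope_cols={g: 1}, df=df)
    return designs


@dataclass
class CouplingResult:
    """Voxel-wise coupling-fit results.

    Per group: slope (``beta``) and t maps; ``slope_cov`` holds the
    per-voxel covariance matrix of the group slope estimates (already
    scaled by the residual variance) in the in-mask voxel order, used by
    :func:`group_contrast`.  ``df`` is a single int for the pooled model
    and a per-group dict for the per-group model.
    """

    groups: tuple[str, ...]
    model: str
    mask: np.ndarray
    beta: dict[str, np.ndarray]
    t: dict[str, np.ndarray]
    slope_cov: np.ndarray
    df: int | dict[str, int]
    n_dropped_voxels: int = 0

    def t_map(self, group: str) -> np.ndarray:
        return self.t[group]

    def group_df(self, group: str) -> int:
        return self.df if isinstance(self.df, int) else self.df[group]


def _stack_maps(
    maps: list[BandMap], records: list[SubjectRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Align maps with records and stack to (n_subjects, V) over the joint mask."""
    if len(maps) != len(records):
        raise ValueError("need exactly one map per subject record")
    by_id = {m.subject_id: m for m in maps}
    if len(by_id) != len(maps):
        raise ValueError("duplicate subject_id among maps")
    ordered = []
    for r in records:
        if r.subject_id not in by_id:
            raise ValueError(f"no map for subject {r.subject_id!r}")
        ordered.append(by_id[r.subject_id])
    shapes = {m.values.shape for m in ordered}
    if len(shapes) != 1:
        raise ValueError("maps do not share a common grid")
    stack = np.stack([m.values for m in ordered])
    return stack, np.isfinite(stack).all(axis=0)


def fit_voxelwise(
    fc_maps: list[BandMap],
    alff_maps: list[BandMap],
    records: list[SubjectRecord],
    model: str = "pooled_interaction",
    mask: np.ndarray | None = None,
) -> CouplingResult:
    """Fit the FC ~ ALFF model at every voxel of the analysis mask.

    The analysis mask is the intersection of the supplied mask (if any)
    with the voxels at which every subject has finite FC and ALFF; the
    number of voxels dropped for missing data is logged and recorded.
    A voxel where FC is identical across subjects yields slope 0, t 0.
    """
    fc, fc_mask = _stack_maps(fc_maps, records)
    alff, alff_mask = _stack_maps(alff_maps, records)
    if fc.shape != alff.shape:
        raise ValueError("FC and ALFF maps do not share a grid")
    band_names = {m.band.name for m in fc_maps} | {m.band.name for m in alff_maps}
    if len(band_names) != 1:
        raise ValueError(f"maps mix frequency bands: {sorted(band_names)}")
    analysis = fc_mask & alff_mask
    full = analysis.sum()
    if mask is not None:
        analysis &= np.asarray(mask, dtype=bool)
        full = np.asarray(mask, dtype=bool).sum()
    n_dropped = int(full - analysis.sum())
    if n_dropped:
        logger.info("dropped %d voxels with missing data from analysis mask", n_dropped)
    if not analysis.any():
        raise ValueError("analysis mask is empty")

    y_all = fc[:, analysis]  # n x V
    x_all = alff[:, analysis]
    n_vox = y_all.shape[1]
    _, groups = _group_indicators(records)
    shape = analysis.shape
    beta = {g: np.full(shape, np.nan) for g in groups}
    tmap = {g: np.full(shape, np.nan) for g in groups}
    n_groups = len(groups)
    slope_cov = np.zeros((n_vox, n_groups, n_groups))

    if model == "pooled_interaction":
        # fixed parts of the design; only the slope columns vary per voxel
        ind, _ = _group_indicators(records)
        cov, _ = standardize_covariates(records)
        base = np.column_stack([ind, cov])
        p = base.shape[1] + n_groups
        df = len(records) - p
        slope_idx = np.arange(n_groups, 2 * n_groups)
        bvals = np.empty((n_vox, n_groups))
        tvals = np.empty((n_vox, n_groups))
        for v in range(n_vox):
            slope_cols = ind * x_all[:, v : v + 1]
            x = np.column_stack([ind, slope_cols, cov])
            xtx = x.T @ x
            try:
                cinv = np.linalg.inv(xtx)
            except np.linalg.LinAlgError:
                cinv = np.linalg.pinv(xtx)
            yv = y_all[:, v]
            b = cinv @ (x.T @ yv)
            resid = yv - x @ b
            ss_res = float(resid @ resid)
            # a numerically exact fit (e.g. constant response) has no
            # residual variance: slope and t are zero by convention
            if ss_res <= 1e-12 * (float(yv @ yv) + 1.0):
                ss_res = 0.0
                b[slope_idx] = 0.0
            sigma2 = ss_res / df
            cov_slopes = sigma2 * cinv[np.ix_(slope_idx, slope_idx)]
            se = np.sqrt(np.clip(np.diag(cov_slopes), 0.0, None))
            bs = b[slope_idx]
            with np.errstate(divide="ignore", invalid="ignore"):
                tv = np.where(se > 0, bs / se, 0.0)
            bvals[v] = bs
            tvals[v] = tv
            slope_cov[v] = cov_slopes
        for i, g in enumerate(groups):
            m = np.full(shape, np.nan)
            m[analysis] = bvals[:, i]
            beta[g] = m
            m = np.full(shape, np.nan)
            m[analysis] = tvals[:, i]
            tmap[g] = m
        return CouplingResult(
            groups=tuple(groups),
            model=model,
            mask=analysis,
            beta=beta,
            t=tmap,
            slope_cov=slope_cov,
            df=int(df),
            n_dropped_voxels=n_dropped,
        )

    if model != "per_group":
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    dfs: dict[str, int] = {}
    for gi, g in enumerate(groups):
        idx = np.array([i for i, r in enumerate(records) if r.group == g])
        sub = [records[i] for i in idx]
        cov, _ = standardize_covariates(sub)
        n_g = len(idx)
        p = 2 + cov.shape[1]
        df_g = n_g - p
        if df_g < 1:
            raise ValueError(f"per-group design for {g!r} leaves no residual df")
        dfs[g] = df_g
        bvals = np.empty(n_vox)
        tvals = np.empty(n_vox)
        vvals = np.empty(n_vox)
        ones = np.ones(n_g)
        for v in range(n_vox):
            x = np.column_stack([ones, x_all[idx, v], cov])
            xtx = x.T @ x
            try:
                cinv = np.linalg.inv(xtx)
            except np.linalg.LinAlgError:
                cinv = np.linalg.pinv(xtx)
            yv = y_all[idx, v]
            b = cinv @ (x.T @ yv)
            resid = yv - x @ b
            ss_res = float(resid @ resid)
            if ss_res <= 1e-12 * (float(yv @ yv) + 1.0):
                ss_res = 0.0
                b[1] = 0.0
            sigma2 = ss_res / df_g
            var_b = sigma2 * cinv[1, 1]
            se = np.sqrt(max(var_b, 0.0))
            bvals[v] = b[1]
            tvals[v] = b[1] / se if se > 0 else 0.0
            vvals[v] = max(var_b, 0.0)
        m = np.full(shape, np.nan)
        m[analysis] = bvals
        beta[g] = m
        m = np.full(shape, np.nan)
        m[analysis] = tvals
        tmap[g] = m
        slope_cov[:, gi, gi] = vvals
    return CouplingResult(
        groups=tuple(groups),
        model=model,
        mask=analysis,
        beta=beta,
        t=tmap,
        slope_cov=slope_cov,
        df=dfs,
        n_dropped_voxels=n_dropped,
    )


def group_contrast(
    result: CouplingResult,
    g1: str,
    g2: str,
    restrict_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float | np.ndarray]:
    """t map for H0: slope(g1) = slope(g2).

    For the pooled model the contrast uses the fitted slope covariance
    (``var1 + var2 - 2 cov12``) at the pooled df; for the per-group
    model a Welch combination with Satterthwaite df (returned as a map).
    The map is evaluated only inside ``restrict_mask`` (NaN elsewhere);
    by convention this is the mask of control-significant coupling.

    Returns ``(t_map, df)``.
    """
    for g in (g1, g2):
        if g not in result.groups:
            raise ValueError(f"group {g!r} not in fitted result {result.groups}")
    mask = result.mask.copy()
    if restrict_mask is not None:
        restrict_mask = np.asarray(restrict_mask, dtype=bool)
        if (restrict_mask & ~result.mask).any():
            raise ValueError("restrict_mask must lie inside the analysis mask")
        mask &= restrict_mask
    if not mask.any():
        raise ValueError("empty restrict mask")
    i1 = result.groups.index(g1)
    i2 = result.groups.index(g2)
    # slope_cov is stored in analysis-mask voxel order
    sel = mask[result.mask]
    diff = result.beta[g1][mask] - result.beta[g2][mask]
    v1 = result.slope_cov[sel, i1, i1]
    v2 = result.slope_cov[sel, i2, i2]
    c12 = result.slope_cov[sel, i1, i2]
    var = np.clip(v1 + v2 - 2.0 * c12, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(var > 0, diff / np.sqrt(var), 0.0)
    tmap = np.full(result.mask.shape, np.nan)
    tmap[mask] = tvals
    if isinstance(result.df, int):
        return tmap, float(result.df)
    # Welch / Satterthwaite per voxel
    df1 = result.df[g1]
    df2 = result.df[g2]
    with np.errstate(divide="ignore", invalid="ignore"):
        df_vals = (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)
    df_map = np.full(result.mask.shape, np.nan)
    df_map[mask] = df_vals
    return tmap, df_map


def one_sample_t_map(
    maps: list[BandMap], records: list[SubjectRecord], group: str
) -> tuple[np.ndarray, int]:
    """One-sample t map of a group's maps against zero (mean-effect map)."""
    stack, mask = _stack_maps(maps, records)
    idx = [i for i, r in enumerate(records) if r.group == group]
    if len(idx) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 subjects")
    sub = stack[idx]
    n = len(idx)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~mask] = np.nan
    t[mask & ~np.isfinite(t)] = 0.0
    return t, n - 1


def voxelwise_anova(
    maps: list[BandMap], records: list[SubjectRecord]
) -> tuple[np.ndarray, int, int]:
    """Voxel-wise one-way ANOVA F across groups.

    Returns ``(F_map, df1, df2)``; NaN outside the joint mask.  For
    three groups of 10 the dfs are (2, 27).
    """
    stack, mask = _stack_maps(maps, records)
    _, groups = _group_indicators(records)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_total = len(records)
    grand = stack.mean(axis=0)
    ssb = np.zeros(stack.shape[1:])
    ssw = np.zeros(stack.shape[1:])
    for g in groups:
        idx = [i for i, r in enumerate(records) if r.group == g]
        sub = stack[idx]
        gmean = sub.mean(axis=0)
        ssb += len(idx) * (gmean - grand) ** 2
        ssw += ((sub - gmean) ** 2).sum(axis=0)
    df1 = len(groups) - 1
    df2 = n_total - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    f[mask & ~np.isfinite(f)] = 0.0
    f[~mask] = np.nan
    return f, df1, df2


def roi_summary(
    maps: list[BandMap],
    records: list[SubjectRecord],
    roi_masks: dict[str, np.ndarray],
    contrasts: tuple[tuple[str, str], ...] = (("HC", "AD"), ("HC", "MCI")),
) -> pd.DataFrame:
    """ROI-averaged group summaries with one-tailed group comparisons.

    For each ROI the map value is averaged per subject, then per group;
    the one-tailed two-sample t-tests run in the direction
    first-group > second-group (by default control > patient).  Returns
    a tidy frame with one row per (roi, contrast) carrying the group
    means ± SE and the test.
    """
    stack, _ = _stack_maps(maps, records)
    rows = []
    for roi_name, roi in roi_masks.items():
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != stack.shape[1:]:
            raise ValueError(f"ROI {roi_name!r} shape mismatch")
        if not roi.any():
            raise ValueError(f"ROI {roi_name!r} is empty")
        subj_means = np.nanmean(stack[:, roi], axis=1)
        by_group = {
            g: subj_means[[i for i, r in enumerate(records) if r.group == g]]
            for g in {r.group for r in records}
        }
        for g1, g2 in contrasts:
            if g1 not in by_group or g2 not in by_group:
                continue
            a, b = by_group[g1], by_group[g2]
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            t = (a.mean() - b.mean()) / se if se > 0 else 0.0
            df = na + nb - 2
            p_one = float(stats.t.sf(t, df))  # H1: g1 > g2
            rows.append(
                {
                    "roi": roi_name,
                    "contrast": f"{g1}_gt_{g2}",
                    f"mean_{g1}": a.mean(),
                    f"se_{g1}": a.std(ddof=1) / np.sqrt(na),
                    f"mean_{g2}": b.mean(),
                    f"se_{g2}": b.std(ddof=1) / np.sqrt(nb),
                    "t": float(t),
                    "df": df,
                    "p_one_tailed": p_one,
                }
            )
    return pd.DataFrame(rows)
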