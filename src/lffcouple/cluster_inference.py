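"""Monte Carlo cluster-extent correction and supporting utilities.

Cluster-extent thresholding controls the familywise error of a voxel-wise
test by requiring suprathreshold voxels to form connected clusters larger
than a minimum size ``k_min``.  ``k_min`` is calibrated on simulated null
fields: iid Gaussian noise inside the analysis mask, smoothed to the
target smoothness, re-standardized, thresholded at the voxel-level
z-quantile, with the maximum cluster size recorded per iteration.  The
smallest k whose exceedance probability is at most the familywise alpha
is the cluster-size threshold.

The module also provides connected-component cluster labeling, separable
Gaussian smoothing, and an AFNI-style first-difference smoothness
(FWHM) estimator used to feed the null simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "ClusterThresholdSpec",
    "simulate_cluster_threshold",
    "label_clusters",
    "smooth_gaussian",
    "estimate_fwhm",
    "connectivity_structure",
    "FWHM_TO_SIGMA",
]

# FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_CONNECTIVITY_ORDER = {"faces": 1, "faces_edges": 2, "faces_edges_corners": 3}


def connectivity_structure(connectivity: str) -> np.ndarray:
    """3D binary structure element for a named connectivity rule."""
    try:
        order = _CONNECTIVITY_ORDER[connectivity]
    except KeyError:
        raise ValueError(
            f"unknown connectivity {connectivity!r}; "
            f"expected one of {sorted(_CONNECTIVITY_ORDER)}"
        ) from None
    return ndimage.generate_binary_structure(3, order)


@dataclass
class ClusterThresholdSpec:
    """Parameters of the null-field Monte Carlo cluster calibration.

    ``fwhm_mm`` is the assumed isotropic smoothness of the null field;
    with ``fwhm_mm=0`` voxels are independent.  ``voxel_p`` is the
    per-voxel two-tailed p threshold, ``alpha`` the corrected familywise
    level.
    """

    mask: np.ndarray
    fwhm_mm: float = 0.0
    voxel_size_mm: float = 1.0
    voxel_p: float = 0.005
    alpha: float = 0.05
    n_iterations: int = 10000
    connectivity: str = "faces"
    seed: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3 or not self.mask.any():
            raise ValueError("mask must be a nonempty 3D binary array")
        if not (0 < self.voxel_p < 1):
            raise ValueError("voxel_p must be in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm must be >= 0")
        connectivity_structure(self.connectivity)  # validate name


def simulate_cluster_threshold(
    spec: ClusterThresholdSpec,
    return_null: bool = False,
):
    """Monte Carlo cluster-size threshold at familywise level alpha.

    Per iteration: fill the mask with iid standard normal noise, smooth
    with the specified Gaussian kernel, re-standardize to zero mean /
    unit variance inside the mask (so the voxel-level quantile stays
    nominal), threshold two-tailed at ``|z| >= z(voxel_p/2)`` and record
    the maximum connected-cluster size.  ``k_min`` is the smallest k
    with ``P(max cluster >= k) <= alpha`` over iterations.

    Returns ``k_min`` (and the null max-size sample when
    ``return_null=True``).
    """
    if spec.alpha < 1.0 / spec.n_iterations:
        raise ValueError(
            f"alpha={spec.alpha} unresolvable with {spec.n_iterations} iterations"
        )
    rng = np.random.default_rng(spec.seed)
    z_thr = stats.norm.isf(spec.voxel_p / 2.0)
    structure = connectivity_structure(spec.connectivity)
    mask = spec.mask
    n_in = int(mask.sum())
    sigma_vox = spec.fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
    field = np.zeros(mask.shape)
    max_sizes = np.zeros(spec.n_iterations, dtype=int)
    for it in range(spec.n_iterations):
        field[:] = 0.0
        field[mask] = rng.standard_normal(n_in)
        if sigma_vox > 0:
            smoothed = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="constant")
        else:
            smoothed = field
        vals = smoothed[mask]
        vals = (vals - vals.mean()) / vals.std()
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = np.abs(vals) >= z_thr
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=structure)
            max_sizes[it] = np.bincount(labels.ravel())[1:].max()
    # exceedance: smallest k with P(max >= k) <= alpha
    sorted_sizes = np.sort(max_sizes)
    k = 1
    while (sorted_sizes >= k).sum() / spec.n_iterations > spec.alpha:
        k += 1
    if return_null:
        return int(k), max_sizes
    return int(k)


def label_clusters(
    stat_map: np.ndarray,
    threshold: float,
    connectivity: str = "faces",
    two_sided: bool = True,
    min_size: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Connected components of the suprathreshold set of a statistic map.

    With ``two_sided=True`` the suprathreshold set is ``|stat| >=
    threshold``; otherwise ``stat >= threshold``.  NaNs never enter a
    cluster.  Returns a label volume (0 = background, labels following
    the table order) and a table with columns ``cluster_id, size,
    peak_stat, peak_x, peak_y, peak_z`` sorted by size descending;
    clusters smaller than ``min_size`` are removed from both.
    """
    stat = np.asarray(stat_map, dtype=float)
    finite = np.isfinite(stat)
    supra = finite & (
        (np.abs(stat) >= threshold) if two_sided else (stat >= threshold)
    )
    structure = connectivity_structure(connectivity)
    labels, n_lab = ndimage.label(supra, structure=structure)
    rows = []
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)
        size = len(idx)
        if size < min_size:
            labels[labels == lab] = 0
            continue
        vals = stat[tuple(idx.T)]
        peak_pos = idx[np.argmax(np.abs(vals) if two_sided else vals)]
        peak = stat[tuple(peak_pos)]
        rows.append((lab, size, float(peak), *map(int, peak_pos)))
    rows.sort(key=lambda r: -r[1])
    out_labels = np.zeros_like(labels)
    table_rows = []
    for new_id, (old, size, peak, px, py, pz) in enumerate(rows, start=1):
        out_labels[labels == old] = new_id
        table_rows.append(
            {
                "cluster_id": new_id,
                "size": size,
                "peak_stat": peak,
                "peak_x": px,
                "peak_y": py,
                "peak_z": pz,
            }
        )
    table = pd.DataFrame(
        table_rows,
        columns=["cluster_id", "size", "peak_stat", "peak_x", "peak_y", "peak_z"],
    )
    return out_labels, table


def smooth_gaussian(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float = 1.0,
) -> np.ndarray:
    """Separable Gaussian smoothing with kernel width given as FWHM.

    ``fwhm_mm=0`` returns the input unchanged (bitwise).  4D inputs are
    smoothed volume by volume along the first three axes.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    vol = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    if vol.ndim == 3:
        return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant")
    if vol.ndim == 4:
        sigma = (sigma_vox, sigma_vox, sigma_vox, 0.0)
        return ndimage.gaussian_filter(vol, sigma=sigma, mode="constant")
    raise ValueError("expected a 3D or 4D volume")


def estimate_fwhm(
    maps: list[np.ndarray] | np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float = 1.0,
) -> np.ndarray:
    """First-difference variance-ratio smoothness estimate per axis.

    For a Gaussian autocorrelation the lag-1 correlation ``rho`` along an
    axis relates to the equivalent smoothing-kernel FWHM by
    ``fwhm = sqrt(2 ln 2) * d / sqrt(-ln rho)`` with ``d`` the voxel
    size; ``rho`` is estimated as ``1 - var(diff) / (2 var)`` pooling all
    maps.  Unsmoothed white noise yields a small sub-voxel estimate; a
    constant map has no defined smoothness and raises.

    Returns the three per-axis FWHM values in the units of
    ``voxel_size_mm``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if isinstance(maps, np.ndarray) and maps.ndim == 3:
        maps = [maps]
    fwhm = np.zeros(3)
    for axis in range(3):
        if mask.any(axis=tuple(a for a in range(3) if a != axis)).sum() < 2:
            raise ValueError(f"mask thinner than 2 voxels along axis {axis}")
        num = 0.0
        den = 0.0
        pair_mask = None
        for m in maps:
            m = np.asarray(m, dtype=float)
            vals = m[mask]
            var = vals.var()
            if var == 0:
                raise ValueError("constant map: smoothness undefined")
            if pair_mask is None:
                sl_lo = [slice(None)] * 3
                sl_hi = [slice(None)] * 3
                sl_lo[axis] = slice(None, -1)
                sl_hi[axis] = slice(1, None)
                pair_mask = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
            diffs = m[tuple(sl_hi)][pair_mask] - m[tuple(sl_lo)][pair_mask]
            if diffs.size == 0:
                raise ValueError(f"no in-mask voxel pairs along axis {axis}")
            num += (diffs**2).mean()
            den += 2.0 * var
        rho = max(1.0 - num / den, 1e-6)
        fwhm[axis] = np.sqrt(2.0 * np.log(2.0)) * voxel_size_mm / np.sqrt(-np.log(rho))
    return fwhm
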