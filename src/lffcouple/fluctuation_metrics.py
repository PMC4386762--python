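"""Per-subject voxel-wise fluctuation measures: global FC and ALFF.

Global functional connectivity of a voxel is the mean Fisher
z-transformed Pearson correlation between its (band-filtered) time
series and every other in-mask voxel's, self-pair excluded — a
seed-free, network-free connectivity measure on the same per-voxel
footing as ALFF.

ALFF (amplitude of low-frequency fluctuations) is the mean square-root
power of the one-sided periodogram over the frequency bins of a band.
The periodogram is the plain squared-modulus DFT divided by the series
length (no taper), so ALFF is computed once from the wide-band series
and binned per band — numerically identical to computing it from each
ideally band-passed series.

Maps are spatially z-scored (in-mask mean 0, SD 1) before entering the
second-level coupling model, matching the treatment of both measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import FrequencyBand
from .volumes_io import BoldRun

__all__ = ["BandMap", "global_fc_map", "alff_map", "zscore_map"]

FISHER_EPS = 1e-7

MAP_KINDS = ("fc", "fc_z", "alff", "alff_z")


@dataclass
class BandMap:
    """A per-subject 3D statistic map tagged with its band and kind.

    ``values`` is NaN outside the analysis mask and finite inside.
    ``kind`` is one of ``fc`` (mean Fisher-z correlation), ``fc_z``
    (spatially z-scored FC), ``alff``, ``alff_z``.
    """

    values: np.ndarray
    band: FrequencyBand
    kind: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("BandMap values must be 3D")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected {MAP_KINDS}")
        inside = np.isfinite(self.values)
        if self.kind == "alff" and inside.any() and (self.values[inside] < 0).any():
            raise ValueError("ALFF values must be nonnegative inside the mask")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


def global_fc_map(
    run: BoldRun,
    brain_mask: np.ndarray,
    band: FrequencyBand,
    eps: float = FISHER_EPS,
    chunk_size: int = 1024,
) -> BandMap:
    """Voxel-wise global connectivity: mean Fisher-z correlation map.

    For voxel i, ``FC_i = (1/(V-1)) * sum_{j != i} atanh(clip(r_ij))``
    with ``r_ij`` the Pearson correlation of the filtered series and
    correlations clipped to ``±(1 - eps)`` so that perfectly synchronous
    voxels stay finite.  The V x V correlation matrix is computed in
    row chunks; a brute-force double loop over pairs gives identical
    values and serves as the test oracle.

    Raises if any in-mask voxel has zero temporal variance (such voxels
    have no defined correlation); the error lists their indices.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != run.grid:
        raise ValueError("mask shape does not match run grid")
    x = run.data[brain_mask]  # V x t
    v = x.shape[0]
    if v < 2:
        raise ValueError("need at least 2 in-mask voxels")
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        coords = np.argwhere(brain_mask)[bad[:10]]
        raise ValueError(
            f"{bad.size} in-mask voxels have zero variance after filtering; "
            f"first indices: {coords.tolist()}"
        )
    z = centered / norms[:, None]
    hi = 1.0 - eps
    self_term = np.arctanh(hi)
    fc = np.empty(v)
    for start in range(0, v, chunk_size):
        stop = min(start + chunk_size, v)
        r = z[start:stop] @ z.T
        np.clip(r, -hi, hi, out=r)
        fc[start:stop] = (np.arctanh(r).sum(axis=1) - self_term) / (v - 1)
    values = np.full(run.grid, np.nan)
    values[brain_mask] = fc
    return BandMap(values=values, band=band, kind="fc", subject_id=run.subject_id)


def alff_map(
    run: BoldRun,
    band: FrequencyBand,
    brain_mask: np.ndarray,
) -> BandMap:
    """Mean square-root periodogram power over the band's bins.

    ``run`` should be the detrended (or full-band-filtered) series; the
    band selects periodogram bins under the same half-open convention as
    the band-pass filter, so ALFF from the wide series equals ALFF from
    the ideally filtered one.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != run.grid:
        raise ValueError("mask shape does not match run grid")
    t = run.n_volumes
    keep = band.bin_mask(t, run.tr_seconds)
    x = run.data[brain_mask]  # V x t
    spec = np.fft.rfft(x, axis=1)[:, keep]
    power = np.abs(spec) ** 2 / t  # one-sided periodogram
    alff = np.sqrt(power).mean(axis=1)
    values = np.full(run.grid, np.nan)
    values[brain_mask] = alff
    return BandMap(values=values, band=band, kind="alff", subject_id=run.subject_id)


def smooth_map(band_map: BandMap, fwhm_vox: float) -> BandMap:
    """Mask-aware Gaussian smoothing of a statistic map.

    Values are smoothed only with in-mask neighbors (the smoothed field
    is renormalized by the smoothed mask indicator), so NaN outside the
    mask neither leaks in nor drags edge values toward zero.
    ``fwhm_vox=0`` returns an unchanged copy.
    """
    from .cluster_inference import smooth_gaussian

    if fwhm_vox < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_vox == 0:
        return BandMap(
            values=band_map.values.copy(),
            band=band_map.band,
            kind=band_map.kind,
            subject_id=band_map.subject_id,
        )
    mask = band_map.mask
    filled = np.where(mask, band_map.values, 0.0)
    num = smooth_gaussian(filled, fwhm_vox)
    den = smooth_gaussian(mask.astype(float), fwhm_vox)
    out = np.full(band_map.values.shape, np.nan)
    out[mask] = num[mask] / den[mask]
    kind = band_map.kind
    if kind == "alff":
        # smoothing preserves nonnegativity only up to rounding
        out[mask] = np.clip(out[mask], 0.0, None)
    return BandMap(
        values=out, band=band_map.band, kind=kind, subject_id=band_map.subject_id
    )


def zscore_map(band_map: BandMap, mask: np.ndarray | None = None) -> BandMap:
    """Spatially z-score a map: in-mask mean 0, SD 1; NaN preserved outside.

    The transform is invariant to affine rescaling of the input, which
    removes per-subject global scale before group-level modeling.
    """
    if mask is None:
        mask = band_map.mask
    else:
        mask = np.asarray(mask, dtype=bool) & band_map.mask
    vals = band_map.values[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels to z-score")
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero spatial SD: cannot z-score a constant map")
    out = np.full(band_map.values.shape, np.nan)
    out[mask] = (vals - vals.mean()) / sd
    kind = band_map.kind if band_map.kind.endswith("_z") else band_map.kind + "_z"
    return BandMap(
        values=out, band=band_map.band, kind=kind, subject_id=band_map.subject_id
    )
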