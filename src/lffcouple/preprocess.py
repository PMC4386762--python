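"""Nuisance mitigation and band decomposition of BOLD runs.

The pipeline order is fixed: (1) regression of motion parameters plus
anatomical CompCor components, (2) linear detrending, (3) ideal
frequency-domain band-pass filtering.  aCompCor extracts principal
components of the white-matter/CSF voxel pool; because those
compartments carry physiological rather than neuronal signal, their
leading temporal components are effective nuisance regressors for the
grey matter.

All three operations are linear projections, so applying any of them
twice equals applying it once, and the slow-5 / slow-4 filters
reconstruct the full band exactly (the band edges partition the FFT bin
set; see :mod:`lffcouple.bands`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bands import FrequencyBand
from .volumes_io import BoldRun, MaskSet

logger = logging.getLogger(__name__)

__all__ = [
    "NuisanceSet",
    "compcor_regressors",
    "motion_regressors",
    "build_nuisance",
    "regress_nuisance",
    "detrend",
    "bandpass",
    "preprocess_run",
]


@dataclass
class NuisanceSet:
    """A t x k matrix of nuisance regressors with column labels."""

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a t x k matrix")
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("label count must match regressor columns")
        if not np.isfinite(self.regressors).all():
            raise ValueError("regressors contain non-finite values")

    @property
    def k(self) -> int:
        return self.regressors.shape[1]

    def hstack(self, other: "NuisanceSet") -> "NuisanceSet":
        if other.k == 0:
            return self
        if self.k == 0:
            return other
        return NuisanceSet(
            np.hstack([self.regressors, other.regressors]),
            self.labels + other.labels,
        )


def _pca_components(ts: np.ndarray, n_components: int, prefix: str) -> NuisanceSet:
    """Leading temporal PCA components of a (t x V) voxel-pool matrix.

    Voxels are demeaned over time; components are scaled to unit sample
    variance.  Components whose singular value is numerically zero are
    dropped (a degenerate pool cannot support them).
    """
    t = ts.shape[0]
    if n_components == 0:
        return NuisanceSet(np.empty((t, 0)), [])
    centered = ts - ts.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    keep = min(n_components, (s > s[0] * 1e-12).sum() if s.size and s[0] > 0 else 0)
    comps = u[:, :keep] * np.sqrt(t - 1)  # unit sample variance
    labels = [f"{prefix}{i + 1}" for i in range(keep)]
    return NuisanceSet(comps, labels)


def compcor_regressors(
    run: BoldRun,
    masks: MaskSet,
    n_components: int = 5,
    separate_tissues: bool = False,
) -> NuisanceSet:
    """Anatomical CompCor nuisance components.

    By default a single PCA is run over the combined WM ∪ CSF voxel
    pool and the first ``n_components`` temporal eigenvectors are
    returned; with ``separate_tissues=True`` each compartment gets its
    own PCA and its own ``n_components`` components.
    """
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    if n_components >= run.n_volumes:
        raise ValueError("n_components must be smaller than the number of volumes")

    def pool(mask: np.ndarray) -> np.ndarray:
        return run.data[mask].T  # t x V

    if separate_tissues:
        out = NuisanceSet(np.empty((run.n_volumes, 0)), [])
        for tissue in ("wm", "csf"):
            vox = pool(masks.tissue(tissue))
            if vox.shape[1] < n_components:
                raise ValueError(
                    f"{tissue} mask has {vox.shape[1]} voxels, fewer than "
                    f"{n_components} requested components"
                )
            out = out.hstack(_pca_components(vox, n_components, f"compcor_{tissue}_"))
        return out
    vox = pool(masks.wm | masks.csf)
    if vox.shape[1] < n_components:
        raise ValueError(
            f"WM+CSF pool has {vox.shape[1]} voxels, fewer than "
            f"{n_components} requested components"
        )
    return _pca_components(vox, n_components, "compcor_")


def motion_regressors(motion: np.ndarray) -> NuisanceSet:
    """Wrap a t x 6 realignment-parameter table as nuisance regressors."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a t x 6 array")
    labels = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    return NuisanceSet(motion, labels)


def build_nuisance(
    run: BoldRun,
    masks: MaskSet,
    motion: np.ndarray | None = None,
    n_compcor: int = 5,
    separate_tissues: bool = False,
) -> NuisanceSet:
    """Default nuisance set: 6 motion parameters + CompCor components."""
    parts = NuisanceSet(np.empty((run.n_volumes, 0)), [])
    if motion is not None:
        parts = parts.hstack(motion_regressors(motion))
    parts = parts.hstack(
        compcor_regressors(run, masks, n_compcor, separate_tissues=separate_tissues)
    )
    return parts


def _drop_collinear(design: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns that are (numerically) linear combinations of earlier ones."""
    q, r, piv = _qr_pivot(design)
    tol = max(design.shape) * np.finfo(float).eps * (abs(r[0, 0]) if r.size else 0.0)
    rank = int((np.abs(np.diag(r)) > tol).sum())
    if rank == design.shape[1]:
        return design, labels
    keep = np.sort(piv[:rank])
    dropped = [labels[i] for i in piv[rank:]]
    logger.warning("dropping collinear nuisance columns: %s", dropped)
    return design[:, keep], [labels[i] for i in keep]


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def regress_nuisance(run: BoldRun, nuisance: NuisanceSet) -> BoldRun:
    """Per-voxel OLS residualization against [intercept | regressors].

    Residuals are orthogonal to every regressor column (and demeaned,
    because of the intercept).  Rank-deficient designs lose their
    collinear columns with a logged warning rather than failing.
    """
    t = run.n_volumes
    if nuisance.regressors.shape[0] != t:
        raise ValueError(
            f"nuisance rows ({nuisance.regressors.shape[0]}) do not match "
            f"run volumes ({t})"
        )
    design = np.column_stack([np.ones(t), nuisance.regressors])
    labels = ["intercept"] + list(nuisance.labels)
    design, _ = _drop_collinear(design, labels)
    y = run.data.reshape(-1, t).T  # t x V
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return run.with_data(resid.T.reshape(run.shape))


def detrend(run: BoldRun) -> BoldRun:
    """Remove the per-voxel best-fit linear trend (and mean)."""
    t = run.n_volumes
    if t < 3:
        raise ValueError("detrend needs at least 3 volumes")
    x = np.linspace(-1.0, 1.0, t)
    design = np.column_stack([np.ones(t), x])
    y = run.data.reshape(-1, t).T
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return run.with_data(resid.T.reshape(run.shape))


def bandpass(run: BoldRun, band: FrequencyBand) -> BoldRun:
    """Ideal frequency-domain band-pass filter.

    Each voxel's series is FFT'd, bins outside the band (and DC) are
    zeroed under the shared half-open bin convention, and the series is
    inverse-transformed.  Output is exactly real.
    """
    t = run.n_volumes
    keep = band.bin_mask(t, run.tr_seconds)
    y = run.data.reshape(-1, t)
    spec = np.fft.rfft(y, axis=1)
    spec[:, ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=t, axis=1)
    return run.with_data(filtered.reshape(run.shape))


def preprocess_run(
    run: BoldRun,
    masks: MaskSet,
    motion: np.ndarray | None = None,
    band: FrequencyBand | None = None,
    n_compcor: int = 5,
    separate_tissues: bool = False,
) -> BoldRun:
    """Full per-run pipeline: nuisance regression → detrend → band-pass.

    With ``band=None`` the filtering step is skipped (useful when ALFF
    is computed from the detrended series and binned per band later).
    """
    nuisance = build_nuisance(
        run, masks, motion=motion, n_compcor=n_compcor, separate_tissues=separate_tissues
    )
    logger.info(
        "preprocess %s: regress %d nuisance columns, detrend, band=%s",
        run.subject_id,
        nuisance.k,
        band.name if band is not None else "none",
    )
    out = regress_nuisance(run, nuisance)
    out = detrend(out)
    if band is not None:
        out = bandpass(out, band)
    return out
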