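"""Synthetic resting-state cohorts with planted FC–ALFF coupling.

The generator emulates a three-group dementia study (healthy controls,
MCI-like, AD-like; 10 subjects per group) on a common voxel grid, with
216 usable volumes at TR 2.08 s.  Its purpose is to make every
downstream stage testable: each subject carries two latent factors,

* a synchronization factor ``W_i`` setting how strongly grey-matter
  network voxels share their network's latent low-frequency signal, and
* an amplitude factor ``A_i`` scaling the fluctuation amplitude of
  those voxels,

and the across-subject correlation ``corr(A, W)`` within each group is
the planted FC–ALFF coupling (default 0.8 in the control-like group, 0
in the patient-like groups).  Patient-like groups get a lower mean
synchronization with *preserved* amplitude, so their grey-matter FC is
reduced while ALFF is not — the uncoupling-by-disconnection structure
the package's statistics are meant to recover.

Geometry: a cuboid brain with a thin outer CSF sheet, a grey-matter
shell containing disjoint cuboid network regions, and a white-matter
core.  The subject factors modulate only a subset of "coupled" networks
(default 2 of 4); the remaining networks, the background grey matter
and a weak global grey-matter coherence term are identical across
subjects.  This partial modulation is essential: the group-level model
consumes *spatially z-scored* maps, and a map-wide multiplicative
factor would be cancelled exactly by z-scoring, whereas a regionally
planted factor survives it (as regional effects do in real data).

White matter and CSF carry shared physiological confound signals
(removed downstream by aCompCor); every voxel receives broadband noise
and a linear drift; motion parameters are smooth random walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .bands import DEFAULT_BANDS, FULL_BAND, FrequencyBand
from .summary_stats import REFERENCE_DEMOGRAPHICS, REFERENCE_GENDER_COUNTS
from .volumes_io import GROUPS, BoldRun, MaskSet, SubjectRecord

__all__ = [
    "CohortSpec",
    "CohortGeometry",
    "cohort_geometry",
    "generate_cohort",
    "generate_covariates",
    "band_limited_noise",
    "draw_subject_latents",
    "assemble_subject_data",
]


def _reference_covariate_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group (mean, sd) for age/education/gmv plus male proportion."""
    params: dict[str, dict] = {}
    male = {
        row: counts[0] / sum(counts)
        for row, counts in zip(
            REFERENCE_GENDER_COUNTS.row_labels, REFERENCE_GENDER_COUNTS.counts
        )
    }
    for g in GROUPS:
        params[g] = {
            "age": (
                REFERENCE_DEMOGRAPHICS["age"][g].mean,
                REFERENCE_DEMOGRAPHICS["age"][g].sd,
            ),
            "education": (
                REFERENCE_DEMOGRAPHICS["education"][g].mean,
                REFERENCE_DEMOGRAPHICS["education"][g].sd,
            ),
            "gmv": (
                REFERENCE_DEMOGRAPHICS["gmv"][g].mean,
                REFERENCE_DEMOGRAPHICS["gmv"][g].sd,
            ),
            "male_p": male[g],
        }
    return params


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort.

    The defaults are the emulated study's conditions: grid 20^3, 216
    volumes at TR 2.08 s, 10 subjects per group, coupling 0.8 / 0 / 0
    and synchronization means 0.6 / 0.45 / 0.4 for HC / MCI / AD with
    identical amplitude means.  ``n_coupled_networks`` of the
    ``n_networks`` regions carry the subject factors; the rest are
    fixed anchors.  ``sync_sd`` / ``amp_sd`` are the across-subject SDs
    of the two factors, ``gm_global_sync`` the weight of the fixed
    whole-GM coherence component, ``noise_sd`` the broadband voxel
    noise SD and ``confound_sd`` the WM/CSF physiological signal scale
    (all relative to the unit-variance latent signals).
    """

    n_per_group: int = 10
    grid: tuple[int, int, int] = (20, 20, 20)
    n_volumes: int = 216
    tr_seconds: float = 2.08
    n_networks: int = 4
    n_coupled_networks: int = 2
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS
    groups: tuple[str, ...] = GROUPS
    coupling_rho: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.8, "MCI": 0.0, "AD": 0.0}
    )
    sync_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.6, "MCI": 0.45, "AD": 0.4}
    )
    amp_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 1.0, "MCI": 1.0, "AD": 1.0}
    )
    sync_sd: float = 0.18
    amp_sd: float = 0.3
    gm_global_sync: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.30, "MCI": 0.29, "AD": 0.285}
    )
    noise_sd: float = 0.2
    confound_sd: float = 1.0
    drift_sd: float = 0.5
    covariate_params: dict[str, dict] = field(default_factory=_reference_covariate_params)
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            rho = self.coupling_rho[g]
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"coupling_rho[{g}] must be in [-1, 1], got {rho}")
            if not 0.0 <= self.sync_mean[g] <= 1.0:
                raise ValueError(f"sync_mean[{g}] must be in [0, 1]")
        if not 1 <= self.n_coupled_networks <= self.n_networks:
            raise ValueError("need 1 <= n_coupled_networks <= n_networks")
        for g in self.groups:
            if not 0.0 <= self.gm_global_sync[g] < 1.0:
                raise ValueError(f"gm_global_sync[{g}] must be in [0, 1)")


@dataclass
class CohortGeometry:
    """Tissue masks plus the planted network regions.

    ``networks`` maps each grey-matter voxel to a network id (-1 for
    background GM); ``coupled_mask`` marks voxels of the
    subject-modulated networks.
    """

    masks: MaskSet
    networks: np.ndarray
    n_networks: int
    n_coupled: int

    @property
    def coupled_mask(self) -> np.ndarray:
        return (self.networks >= 0) & (self.networks < self.n_coupled)

    def network_mask(self, k: int) -> np.ndarray:
        return self.networks == k


def cohort_geometry(spec: CohortSpec) -> CohortGeometry:
    """Deterministic tissue geometry for a spec's grid.

    A margin of air surrounds a cuboid brain; its outermost voxel layer
    is CSF, the next four layers are the GM shell and the remainder is
    the WM core.  Networks are disjoint cuboids tiled (with 1-voxel
    gaps) on the top-z face of the GM shell.
    """
    nx, ny, nz = spec.grid
    margin = 3
    gm_thick = 4
    # need a nonempty WM core: n > 2*(margin + 1 + gm_thick)
    if min(spec.grid) < 2 * (margin + 1 + gm_thick) + 2:
        raise ValueError(f"grid {spec.grid} too small for the tissue geometry")

    def box(lo: int, axes_hi: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(spec.grid, dtype=bool)
        m[lo : axes_hi[0], lo : axes_hi[1], lo : axes_hi[2]] = True
        return m

    brain = box(margin, (nx - margin, ny - margin, nz - margin))
    inner = box(margin + 1, (nx - margin - 1, ny - margin - 1, nz - margin - 1))
    csf = brain & ~inner
    core = box(
        margin + 1 + gm_thick,
        (nx - margin - 1 - gm_thick, ny - margin - 1 - gm_thick, nz - margin - 1 - gm_thick),
    )
    gm = inner & ~core
    wm = core
    masks = MaskSet(brain=brain, gm=gm, wm=wm, csf=csf)

    # tile networks on the top-z GM slab
    networks = np.full(spec.grid, -1, dtype=int)
    x0, x1 = margin + 1, nx - margin - 1
    y0, y1 = margin + 1, ny - margin - 1
    z0, z1 = nz - margin - 1 - gm_thick, nz - margin - 1
    per_side = int(np.ceil(np.sqrt(spec.n_networks)))
    gap = 1
    wx = (x1 - x0 - gap * (per_side - 1)) // per_side
    wy = (y1 - y0 - gap * (per_side - 1)) // per_side
    if wx < 2 or wy < 2:
        raise ValueError(
            f"{spec.n_networks} networks do not fit in grid {spec.grid}"
        )
    k = 0
    for i in range(per_side):
        for j in range(per_side):
            if k >= spec.n_networks:
                break
            xs = x0 + i * (wx + gap)
            ys = y0 + j * (wy + gap)
            networks[xs : xs + wx, ys : ys + wy, z0:z1] = k
            k += 1
    networks[~gm] = -1
    return CohortGeometry(
        masks=masks,
        networks=networks,
        n_networks=spec.n_networks,
        n_coupled=spec.n_coupled_networks,
    )


def band_limited_noise(
    rng: np.random.Generator,
    n_signals: int,
    n_timepoints: int,
    tr_seconds: float,
    band: FrequencyBand = FULL_BAND,
) -> np.ndarray:
    """Unit-variance signals with power confined to a frequency band.

    White Gaussian noise is FFT-filtered to the band and rescaled to
    unit sample variance; returns an (n_signals, t) array.
    """
    keep = band.bin_mask(n_timepoints, tr_seconds)
    white = rng.standard_normal((n_signals, n_timepoints))
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n_timepoints, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_covariates(
    spec: CohortSpec, group: str, rng: np.random.Generator, n: int | None = None
) -> dict[str, np.ndarray]:
    """Draw covariates for ``n`` subjects of a group.

    Age, education and GMV come from normals truncated at ±4 SD (so the
    means are preserved and GMV stays positive at the reference
    parameters); gender is Bernoulli at the group's male proportion,
    encoded as ``"M"`` / ``"F"``.
    """
    if n is None:
        n = spec.n_per_group
    params = spec.covariate_params[group]
    out: dict[str, np.ndarray] = {}
    for var in ("age", "education", "gmv"):
        mean, sd = params[var]
        if sd == 0:
            out[var] = np.full(n, float(mean))
        else:
            out[var] = stats.truncnorm.rvs(
                -4.0, 4.0, loc=mean, scale=sd, size=n, random_state=rng
            )
    out["gender"] = np.where(rng.random(n) < params["male_p"], "M", "F")
    return out


def draw_subject_latents(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one subject's (W, A) synchronization and amplitude factors.

    ``W ~ Normal(sync_mean[g], sync_sd)`` clipped to [0.05, 0.95]; the
    amplitude factor is built from the same standard-normal innovation
    via the Cholesky construction
    ``A = amp_mean + amp_sd * (rho * z_W + sqrt(1 - rho^2) * z_indep)``
    so that ``corr(A, W) = coupling_rho[g]`` in expectation, floored at
    0.1 to stay positive.
    """
    rho = spec.coupling_rho[group]
    z_w = rng.standard_normal()
    z_i = rng.standard_normal()
    w = float(np.clip(spec.sync_mean[group] + spec.sync_sd * z_w, 0.05, 0.95))
    a = float(
        max(spec.amp_mean[group] + spec.amp_sd * (rho * z_w + np.sqrt(1 - rho**2) * z_i), 0.1)
    )
    return w, a


@dataclass
class SubjectIngredients:
    """Pre-drawn stochastic ingredients of one subject's run.

    Holding these fixed makes :func:`assemble_subject_data` a pure
    function of (W, A), which is what the linearity / monotonicity
    property tests exploit.
    """

    network_signals: np.ndarray  # n_networks x t, unit variance, band-limited
    global_signal: np.ndarray  # t, unit variance, band-limited
    voxel_noise: np.ndarray  # n_gm x t, unit variance, band-limited
    confounds: np.ndarray  # 3 x t, unit variance
    broadband: np.ndarray  # n_brain x t white noise (unscaled)
    drift_slopes: np.ndarray  # n_brain
    motion: np.ndarray  # t x 6 realignment parameters


def _unit_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _draw_ingredients(
    spec: CohortSpec, geom: CohortGeometry, rng: np.random.Generator
) -> SubjectIngredients:
    t, tr = spec.n_volumes, spec.tr_seconds
    n_gm = int(geom.masks.gm.sum())
    n_brain = int(geom.masks.brain.sum())
    motion = _motion_walk(rng, t)
    confounds = band_limited_noise(
        rng, 3, t, tr, band=FrequencyBand("confound", 0.005, 0.12)
    )
    # The latent model declares the neuronal signals independent of the
    # nuisance processes and of each other.  A band-limited series has
    # few effective spectral dof (~56 here), so chance sample overlaps
    # with the (equally low-frequency) motion and confound columns, and
    # among the shared signals themselves, are sizable (~0.13) and would
    # both leak through and be variably removed by the nuisance
    # regression, dominating the across-subject FC variance.  Enforce
    # the model's independence exactly in-sample: orthogonalize the
    # shared signals against [motion | confounds] and each other
    # (Gram-Schmidt, order preserved), and remove every voxel noise's
    # projection on all of these.
    nuis = np.column_stack([motion, confounds.T])
    nuis = nuis - nuis.mean(axis=0, keepdims=True)
    p_nuis, _ = np.linalg.qr(nuis)  # t x 9 orthonormal
    shared = band_limited_noise(rng, spec.n_networks + 1, t, tr)
    shared = shared - (shared @ p_nuis) @ p_nuis.T
    q, _ = np.linalg.qr(shared.T)  # t x (k+1), orthonormal columns
    shared = _unit_rows(q.T)
    gs, nets = shared[0], shared[1:]
    basis = np.column_stack([p_nuis, q / np.linalg.norm(q, axis=0, keepdims=True)])
    noise = band_limited_noise(rng, n_gm, t, tr)
    noise = _unit_rows(noise - (noise @ basis) @ basis.T)
    return SubjectIngredients(
        network_signals=nets,
        global_signal=gs,
        voxel_noise=noise,
        confounds=confounds,
        broadband=rng.standard_normal((n_brain, t)),
        drift_slopes=rng.standard_normal(n_brain),
        motion=motion,
    )


@dataclass
class CohortAnatomy:
    """Cohort-level fixed patterns shared by all subjects."""

    gm_gains: np.ndarray  # per-GM-voxel amplitude gain, U(0.8, 1.2)
    confound_loadings: np.ndarray  # n_wmcsf x 3


def _draw_anatomy(spec: CohortSpec, geom: CohortGeometry, rng: np.random.Generator) -> CohortAnatomy:
    n_gm = int(geom.masks.gm.sum())
    n_wmcsf = int((geom.masks.wm | geom.masks.csf).sum())
    return CohortAnatomy(
        gm_gains=rng.uniform(0.8, 1.2, size=n_gm),
        confound_loadings=rng.standard_normal((n_wmcsf, 3))
        * spec.confound_sd
        / np.sqrt(3.0),
    )


def assemble_subject_data(
    spec: CohortSpec,
    geom: CohortGeometry,
    anatomy: CohortAnatomy,
    ing: SubjectIngredients,
    w: float,
    a: float,
    group: str = "HC",
) -> np.ndarray:
    """Deterministically assemble one subject's 4D data from ingredients.

    A grey-matter voxel of coupled network k mixes its network signal
    with private band-limited noise at synchronization ``w`` and is
    scaled by ``a`` times the voxel gain:

        ``x = a * gain * (sqrt(1-g0^2) * (w*s_k + sqrt(1-w^2)*n) + g0*gs)``

    with ``g0`` the fixed global-GM coherence weight and ``gs`` the
    shared GM signal.  Voxels of non-coupled networks use the group-mean
    values (``sync_mean[group]``, ``amp_mean[group]``) instead of
    (w, a); background GM has no network term.  The bracketed composite
    has unit variance whatever ``w``, so amplitude and synchronization
    are separable by construction.  WM/CSF voxels carry the confound
    mixture.  All brain voxels then receive broadband noise and a
    linear drift; outside the brain the data are zero.
    """
    t = spec.n_volumes
    data = np.zeros(spec.grid + (t,))
    gm = geom.masks.gm
    g0 = spec.gm_global_sync[group]
    mix = np.sqrt(1.0 - g0**2)

    net_ids = geom.networks[gm]  # per-GM-voxel network id
    gm_data = np.empty((net_ids.size, t))
    for k in range(spec.n_networks):
        sel = net_ids == k
        if not sel.any():
            continue
        if k < spec.n_coupled_networks:
            wk, ak = w, a
        else:
            # uncoupled anchor networks: constant within group at the
            # group-mean synchronization/amplitude (no subject variation,
            # so they contribute group effects but never coupling)
            wk, ak = spec.sync_mean[group], spec.amp_mean[group]
        shared = wk * ing.network_signals[k]
        private = np.sqrt(1.0 - wk**2) * ing.voxel_noise[sel]
        gm_data[sel] = ak * anatomy.gm_gains[sel, None] * (
            mix * (shared + private) + g0 * ing.global_signal
        )
    bg = net_ids < 0
    gm_data[bg] = (
        spec.amp_mean[group]
        * anatomy.gm_gains[bg, None]
        * (mix * ing.voxel_noise[bg] + g0 * ing.global_signal)
    )
    data[gm] = gm_data

    wmcsf = geom.masks.wm | geom.masks.csf
    data[wmcsf] = anatomy.confound_loadings @ ing.confounds

    brain = geom.masks.brain
    ramp = np.linspace(-0.5, 0.5, t)
    data[brain] += (
        spec.noise_sd * ing.broadband
        + spec.drift_sd * ing.drift_slopes[:, None] * ramp
    )
    return data


def _motion_walk(rng: np.random.Generator, t: int) -> np.ndarray:
    """Smooth random-walk realignment parameters (3 trans mm, 3 rot rad)."""
    steps = rng.standard_normal((t, 6)) * np.array([0.02] * 3 + [5e-4] * 3)
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    for j in range(6):
        walk[:, j] = np.convolve(walk[:, j], kernel, mode="same")
    return walk


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], list[BoldRun], MaskSet]:
    """Generate the full cohort: records, runs and masks.

    Deterministic given ``spec.seed``: the same spec yields bit-identical
    output.  Subjects are ordered by group (as listed in ``spec.groups``)
    then by index; ids look like ``HC03``.
    """
    rng = np.random.default_rng(spec.seed)
    geom = cohort_geometry(spec)
    anatomy = _draw_anatomy(spec, geom, rng)
    records: list[SubjectRecord] = []
    runs: list[BoldRun] = []
    for group in spec.groups:
        cov = generate_covariates(spec, group, rng)
        for i in range(spec.n_per_group):
            w, a = draw_subject_latents(spec, group, rng)
            ing = _draw_ingredients(spec, geom, rng)
            data = assemble_subject_data(spec, geom, anatomy, ing, w, a, group=group)
            sid = f"{group}{i:02d}"
            motion = ing.motion
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    age=float(cov["age"][i]),
                    gender=str(cov["gender"][i]),
                    education=float(cov["education"][i]),
                    gmv=float(cov["gmv"][i]),
                    motion=motion,
                )
            )
            runs.append(
                BoldRun(
                    data=data,
                    tr_seconds=spec.tr_seconds,
                    subject_id=sid,
                )
            )
    return records, runs, geom.masks


def small_spec(**overrides) -> CohortSpec:
    """A reduced-size spec for fast exercises (tests, examples).

    Shrinks the grid and run length while keeping the planted structure;
    any field can still be overridden.
    """
    base = CohortSpec(
        n_per_group=10,
        grid=(18, 18, 18),
        n_volumes=128,
        n_networks=4,
        n_coupled_networks=2,
    )
    return replace(base, **overrides)
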