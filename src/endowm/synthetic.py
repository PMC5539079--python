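"""Synthetic input generators with planted ground truth.

Every downstream stage of the pipeline (WMH volumetrics, RHI computation,
connectivity segmentation, voxelwise FA statistics, cohort statistics) is
exercised on data produced here, so each generator records the truth it
planted: mixture parameters and lesion masks for the FLAIR-like phantom,
the true hyperemic amplitude ratio for the pulse signal, the intended
winning target per seed voxel for connectivity counts, and the latent
correlation structure for the cohort table.

The phantom is deliberately non-anatomical: nested ellipsoids (brain
containing white matter) suffice because only the *intensity statistics*
inside the WM mask matter to the histogram-based lesion quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GaussianComponent",
    "LesionSpec",
    "PhantomSpec",
    "FlairPhantom",
    "generate_phantom",
    "PatSpec",
    "PatSignal",
    "generate_pat",
    "TargetSpec",
    "ConnectivitySpec",
    "SeedConnectivity",
    "generate_connectivity",
    "CohortSpec",
    "generate_cohort",
    "FaDatasetSpec",
    "FaDataset",
    "generate_fa_dataset",
    "GeometryError",
]


class GeometryError(ValueError):
    """A planted structure does not fit inside its enclosing mask."""


# ---------------------------------------------------------------------------
# FLAIR-like phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class LesionSpec:
    """A spherical hyperintense lesion planted inside the WM mask."""

    center: tuple[int, int, int]  # voxel coordinates, 0-based
    radius: float  # voxels
    mu: float
    sigma: float

    def __post_init__(self):
        if self.radius <= 0 or self.sigma <= 0:
            raise ValueError("lesion radius and sigma must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic FLAIR-like volume.

    White-matter voxel intensities follow a two-component Gaussian mixture:
    a dominant normal-appearing-WM mode and an optional secondary
    partial-volume component.  ``secondary_weight`` is the mixing weight of
    the secondary component and must stay below 0.5 so the dominant mode
    really dominates.  Lesions are spheres (in voxel index space) drawn from
    their own Gaussian; they must lie entirely inside the WM ellipsoid.
    ``frontal_plane`` is a coronal cut index: voxels with y < frontal_plane
    form the "frontal" submask used for regionally restricted volumetrics.
    """

    grid_dims: tuple[int, int, int] = (72, 72, 72)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_shape: tuple[float, float, float] = (34.0, 34.0, 34.0)
    wm_shape: tuple[float, float, float] = (28.0, 28.0, 28.0)
    dominant: GaussianComponent = field(default_factory=lambda: GaussianComponent(100.0, 10.0))
    secondary: GaussianComponent = field(default_factory=lambda: GaussianComponent(140.0, 15.0))
    secondary_weight: float = 0.0
    lesions: tuple[LesionSpec, ...] = ()
    frontal_plane: int = 36
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if not 0.0 <= self.secondary_weight < 0.5:
            raise ValueError(
                f"secondary_weight must be in [0, 0.5) so the dominant mode "
                f"has weight > 0.5, got {self.secondary_weight}"
            )
        for b, w in zip(self.brain_shape, self.wm_shape):
            if w >= b:
                raise ValueError("wm_shape must nest strictly inside brain_shape")


@dataclass
class FlairPhantom:
    """A generated phantom with its planted truth."""

    volume: np.ndarray  # float64 intensities
    wm_mask: np.ndarray  # bool
    frontal_mask: np.ndarray  # bool, subset of wm_mask
    brain_mask: np.ndarray  # bool, defines ICV
    icv_mm3: float
    voxel_size: tuple[float, float, float]
    truth_lesion_mask: np.ndarray  # bool
    truth_lesion_volume_mm3: float
    spec: PhantomSpec


def _ellipsoid_mask(dims: Sequence[int], semi_axes: Sequence[float]) -> np.ndarray:
    center = (np.asarray(dims, dtype=float) - 1.0) / 2.0
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _sphere_mask(dims: Sequence[int], center: Sequence[float], radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius ** 2


def generate_phantom(spec: PhantomSpec) -> FlairPhantom:
    """Generate a FLAIR-like intensity volume with planted lesions.

    WM voxels outside lesions are drawn from the two-component mixture;
    lesion voxels from their lesion Gaussian; brain-but-not-WM voxels get a
    gray-matter-like filler distribution (never used by the WM-masked
    analyses); non-brain voxels are exactly zero.  Identical spec (including
    seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    dims = spec.grid_dims
    vox_mm3 = float(np.prod(spec.voxel_size))

    brain = _ellipsoid_mask(dims, spec.brain_shape)
    wm = _ellipsoid_mask(dims, spec.wm_shape)

    lesion_mask = np.zeros(dims, dtype=bool)
    for les in spec.lesions:
        sph = _sphere_mask(dims, les.center, les.radius)
        if np.any(sph & ~wm):
            raise GeometryError(
                f"lesion at {les.center} (r={les.radius}) extends outside the WM mask"
            )
        lesion_mask |= sph

    vol = np.zeros(dims, dtype=float)

    # gray-matter-like filler between brain and WM ellipsoids
    shell = brain & ~wm
    vol[shell] = rng.normal(0.7 * spec.dominant.mu, spec.dominant.sigma, shell.sum())

    # two-component mixture over normal-appearing WM
    nawm = wm & ~lesion_mask
    n_nawm = int(nawm.sum())
    is_secondary = rng.random(n_nawm) < spec.secondary_weight
    draws = np.where(
        is_secondary,
        rng.normal(spec.secondary.mu, spec.secondary.sigma, n_nawm),
        rng.normal(spec.dominant.mu, spec.dominant.sigma, n_nawm),
    )
    vol[nawm] = draws

    # planted lesions, one Gaussian per lesion sphere
    for les in spec.lesions:
        sph = _sphere_mask(dims, les.center, les.radius)
        vol[sph] = rng.normal(les.mu, les.sigma, int(sph.sum()))

    frontal = wm.copy()
    frontal[:, spec.frontal_plane:, :] = False

    return FlairPhantom(
        volume=vol,
        wm_mask=wm,
        frontal_mask=frontal,
        brain_mask=brain,
        icv_mm3=float(brain.sum()) * vox_mm3,
        voxel_size=spec.voxel_size,
        truth_lesion_mask=lesion_mask,
        truth_lesion_volume_mm3=float(lesion_mask.sum()) * vox_mm3,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Fingertip pulse-amplitude (PAT) signal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatSpec:
    """Parameters of a synthetic pulse-amplitude recording.

    The recording has three consecutive phases -- baseline, cuff occlusion,
    post-occlusion -- with a sinusoidal pulse at ``beat_rate`` whose envelope
    is ``baseline_amplitude`` times {1, occlusion_residual, hyperemia_ratio}
    per phase.  ``hyperemia_ratio`` is therefore the true post/pre amplitude
    ratio the analysis should recover.  Desk-scale default durations
    (60/30/30 s) shorten the 10/5/5-minute clinical protocol; the amplitude
    ratio is duration-invariant in the noise-free limit.  The default
    sample/beat rates are commensurate (80 samples per beat) so noise-free
    beats are sampled identically and the ratio is exact.
    """

    sample_rate: float = 100.0
    durations: tuple[float, float, float] = (60.0, 30.0, 30.0)
    beat_rate: float = 1.25
    baseline_amplitude: float = 1.0
    hyperemia_ratio: float = 1.73
    occlusion_residual: float = 0.02
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if any(d <= 0 for d in self.durations):
            raise ValueError("phase durations must be > 0")
        if self.hyperemia_ratio <= 0:
            raise ValueError("hyperemia_ratio must be > 0")
        if not 0 <= self.occlusion_residual < 0.1:
            raise ValueError("occlusion_residual must be in [0, 0.1)")


PHASE_NAMES = ("baseline", "occlusion", "post")


@dataclass
class PatSignal:
    """A phase-annotated pulse-amplitude series.

    ``phases`` maps phase name to a half-open sample-index interval
    [start, end); the three intervals are ordered and non-overlapping.
    """

    samples: np.ndarray
    sample_rate: float
    phases: dict[str, tuple[int, int]]

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        prev_end = 0
        for name in PHASE_NAMES:
            if name not in self.phases:
                raise ValueError(f"missing phase {name!r}")
            s, e = self.phases[name]
            if not (0 <= prev_end <= s < e <= len(self.samples)):
                raise ValueError(f"phase {name!r} interval [{s},{e}) invalid")
            prev_end = e

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready frame with columns time_s, amplitude, phase."""
        n = len(self.samples)
        phase = np.empty(n, dtype=object)
        phase[:] = ""
        for name, (s, e) in self.phases.items():
            phase[s:e] = name
        return pd.DataFrame(
            {
                "time_s": np.arange(n) / self.sample_rate,
                "amplitude": self.samples,
                "phase": phase,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_rate: float | None = None) -> "PatSignal":
        for col in ("time_s", "amplitude", "phase"):
            if col not in df.columns:
                raise ValueError(f"PAT table missing column {col!r}")
        if sample_rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            sample_rate = 1.0 / float(np.median(dt))
        phases = {}
        phase_col = df["phase"].to_numpy()
        for name in PHASE_NAMES:
            idx = np.flatnonzero(phase_col == name)
            if idx.size == 0:
                raise ValueError(f"PAT table has no samples in phase {name!r}")
            phases[name] = (int(idx[0]), int(idx[-1]) + 1)
        return cls(df["amplitude"].to_numpy(dtype=float), float(sample_rate), phases)


def generate_pat(spec: PatSpec) -> PatSignal:
    """Generate a three-phase pulse-amplitude series with known truth ratio."""
    fs = spec.sample_rate
    n_per_phase = [int(round(d * fs)) for d in spec.durations]
    n = sum(n_per_phase)
    t = np.arange(n) / fs

    env = np.empty(n)
    b0, b1 = n_per_phase[0], n_per_phase[0] + n_per_phase[1]
    env[:b0] = spec.baseline_amplitude
    env[b0:b1] = spec.baseline_amplitude * spec.occlusion_residual
    env[b1:] = spec.baseline_amplitude * spec.hyperemia_ratio

    samples = env * np.sin(2 * np.pi * spec.beat_rate * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        samples = samples + rng.normal(0.0, spec.noise_sd, n)

    phases = {
        "baseline": (0, b0),
        "occlusion": (b0, b1),
        "post": (b1, n),
    }
    return PatSignal(samples=samples, sample_rate=fs, phases=phases)


# ---------------------------------------------------------------------------
# Seed-to-target connectivity counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSpec:
    """A cortical target mask: its name, size, and streamline-count scale."""

    name: str
    mask_voxel_count: int
    mean_count: float
    dispersion: float = 1.0  # variance/mean of the count distribution

    def __post_init__(self):
        if self.mask_voxel_count <= 0:
            raise ValueError(f"target {self.name!r}: mask_voxel_count must be > 0")
        if self.mean_count < 0 or self.dispersion < 1.0:
            raise ValueError(f"target {self.name!r}: mean_count >= 0, dispersion >= 1 required")


@dataclass(frozen=True)
class ConnectivitySpec:
    """Seed-cluster connectivity generator parameters.

    ``assignment_truth`` names the intended winning target of each seed
    voxel.  In noise-free mode the winner receives round(mean_count)
    streamlines (at least 1) and every other target receives
    round(background_rate); in stochastic mode counts are sampled from a
    Poisson (dispersion == 1) or negative-binomial (dispersion > 1) law with
    mean ``mean_count`` for the winner and ``background_rate`` elsewhere.
    """

    targets: tuple[TargetSpec, ...]
    assignment_truth: tuple[str, ...]
    stochastic: bool = False
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.targets) < 2:
            raise ValueError("need at least 2 targets")
        names = {t.name for t in self.targets}
        if len(names) != len(self.targets):
            raise ValueError("duplicate target names")
        bad = [w for w in self.assignment_truth if w not in names]
        if bad:
            raise ValueError(f"assignment_truth names unknown target(s): {sorted(set(bad))}")
        if len(self.assignment_truth) < 1:
            raise ValueError("need at least 1 seed voxel")

    @property
    def n_seed_voxels(self) -> int:
        return len(self.assignment_truth)


@dataclass
class SeedConnectivity:
    """Per-(seed voxel, target) streamline counts.

    ``counts`` is a (n_voxels, n_targets) DataFrame indexed by voxel_id with
    one column per target; ``target_sizes`` maps target name to its mask
    voxel count; ``truth`` (optional) is the planted winning target.
    """

    counts: pd.DataFrame
    target_sizes: dict[str, int]
    truth: pd.Series | None = None

    def __post_init__(self):
        missing = [t for t in self.counts.columns if t not in self.target_sizes]
        if missing:
            raise ValueError(f"no mask size for target(s) {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("streamline counts must be >= 0")

    def to_long_frame(self) -> pd.DataFrame:
        """CSV-ready long table: voxel_id, target_name, streamline_count."""
        long = self.counts.reset_index().melt(
            id_vars="voxel_id", var_name="target_name", value_name="streamline_count"
        )
        return long.sort_values(["voxel_id", "target_name"], ignore_index=True)

    def targets_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_name": list(self.target_sizes),
                "mask_voxel_count": list(self.target_sizes.values()),
            }
        )

    @classmethod
    def from_frames(cls, counts_long: pd.DataFrame, targets: pd.DataFrame) -> "SeedConnectivity":
        for col in ("voxel_id", "target_name", "streamline_count"):
            if col not in counts_long.columns:
                raise ValueError(f"counts table missing column {col!r}")
        for col in ("target_name", "mask_voxel_count"):
            if col not in targets.columns:
                raise ValueError(f"targets table missing column {col!r}")
        wide = counts_long.pivot(
            index="voxel_id", columns="target_name", values="streamline_count"
        )
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)][0]
            raise ValueError(f"voxel {bad} is missing counts for some target")
        sizes = dict(zip(targets["target_name"], targets["mask_voxel_count"].astype(int)))
        wide.columns.name = None
        return cls(counts=wide, target_sizes=sizes)


def generate_connectivity(spec: ConnectivitySpec) -> SeedConnectivity:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_seed_voxels
    names = [t.name for t in spec.targets]
    mean_by_name = {t.name: t.mean_count for t in spec.targets}
    disp_by_name = {t.name: t.dispersion for t in spec.targets}

    counts = np.zeros((n, len(names)), dtype=int)
    truth = np.asarray(spec.assignment_truth, dtype=object)
    for j, name in enumerate(names):
        is_winner = truth == name
        if spec.stochastic:
            winner_mean = mean_by_name[name]
            lam = np.where(is_winner, winner_mean, spec.background_rate)
            counts[:, j] = _sample_counts(rng, lam, disp_by_name[name])
        else:
            win_count = max(1, int(round(mean_by_name[name])))
            bg = int(round(spec.background_rate))
            if bg >= win_count:
                raise ValueError("noise-free mode needs background_rate < winner count")
            counts[:, j] = np.where(is_winner, win_count, bg)

    df = pd.DataFrame(counts, columns=names)
    df.index = pd.RangeIndex(n, name="voxel_id")
    sizes = {t.name: t.mask_voxel_count for t in spec.targets}
    return SeedConnectivity(
        counts=df, target_sizes=sizes, truth=pd.Series(truth, index=df.index, name="truth")
    )


def _sample_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Poisson (dispersion 1) or negative-binomial counts with the given mean."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1.0:
        return rng.poisson(mean)
    # NB parameterised by mean m and variance m * dispersion
    size = mean / (dispersion - 1.0)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    p = size[pos] / (size[pos] + mean[pos])
    out[pos] = rng.negative_binomial(size[pos], p)
    return out


# ---------------------------------------------------------------------------
# Cohort table (latent Gaussian copula)
# ---------------------------------------------------------------------------

def _default_latent_corr() -> np.ndarray:
    # signs follow the reported associations: RHI-FA positive, both
    # negatively related to the Trail B - Trail A switching cost
    return np.array(
        [
            [1.00, 0.40, -0.36],
            [0.40, 1.00, -0.45],
            [-0.36, -0.45, 1.00],
        ]
    )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator: latent Gaussian over (RHI, clusterFA, TMTdiff).

    A trivariate standard normal with correlation ``latent_corr`` is mapped
    linearly to the stated marginal means/SDs; TMT-B is TMT-A plus the
    latent switching cost, and TMT-A is drawn independently.  Defaults match
    the published cohort summary: n = 36, age 63.8 (2.9) years, RHI
    1.73 (0.5), Trail B - Trail A 35.4 (15.5) s; corpus-callosum FA
    0.50 (0.06) is a field-typical value for older adults.
    """

    n: int = 36
    age_mean: float = 63.8
    age_sd: float = 2.9
    sex_ratio: float = 23.0 / 36.0  # fraction female
    latent_corr: np.ndarray = field(default_factory=_default_latent_corr)
    rhi_mean: float = 1.73
    rhi_sd: float = 0.5
    fa_mean: float = 0.50
    fa_sd: float = 0.06
    tmt_a_mean: float = 30.0
    tmt_a_sd: float = 8.0
    tmt_diff_mean: float = 35.4
    tmt_diff_sd: float = 15.5
    seed: int = 0

    def __post_init__(self):
        C = np.asarray(self.latent_corr, dtype=float)
        if C.shape != (3, 3) or not np.allclose(C, C.T):
            raise ValueError("latent_corr must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(C)[0] <= 0:
            raise ValueError(
                f"latent_corr is not positive definite:\n{C}"
            )
        if not (0 <= self.sex_ratio <= 1):
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table: id, age, sex, rhi, cluster_fa, tmt_a_s, tmt_b_s.

    RHI, cluster FA and the TMT switching cost share the latent correlation
    structure; age and sex are independent of them (associations with age or
    sex can be induced by post-processing in experiments that need them).
    Positive-valued columns are clipped away from zero; FA is clipped to
    (0, 1) -- at the default means/SDs clipping is astronomically rare.
    """
    rng = np.random.default_rng(spec.seed)
    C = np.asarray(spec.latent_corr, dtype=float)
    z = rng.multivariate_normal(np.zeros(3), C, size=spec.n, method="cholesky")

    rhi = np.clip(spec.rhi_mean + spec.rhi_sd * z[:, 0], 0.05, None)
    fa = np.clip(spec.fa_mean + spec.fa_sd * z[:, 1], 1e-3, 1 - 1e-3)
    tmt_diff = spec.tmt_diff_mean + spec.tmt_diff_sd * z[:, 2]

    age = rng.normal(spec.age_mean, spec.age_sd, spec.n)
    sex = np.where(rng.random(spec.n) < spec.sex_ratio, "F", "M")
    tmt_a = np.clip(rng.normal(spec.tmt_a_mean, spec.tmt_a_sd, spec.n), 5.0, None)
    tmt_b = np.clip(tmt_a + tmt_diff, 6.0, None)

    return pd.DataFrame(
        {
            "id": [f"S{i+1:03d}" for i in range(spec.n)],
            "age": age,
            "sex": sex,
            "rhi": rhi,
            "cluster_fa": fa,
            "tmt_a_s": tmt_a,
            "tmt_b_s": tmt_b,
        }
    )


# ---------------------------------------------------------------------------
# Skeleton-space FA dataset (for the voxelwise stage)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FaDatasetSpec:
    """Subjects x voxels FA matrix generated directly in skeleton space.

    Per-voxel baseline FA is drawn once from N(fa_mean, between_voxel_sd)
    and shared across subjects; subject values add N(0, noise_sd) noise.  A
    contiguous block of ``effect_voxels`` voxels carries a linear RHI effect
    of slope ``effect_beta`` (FA units per RHI unit) -- the planted cluster
    that the permutation analysis should detect.  A fraction ``low_fa_frac``
    of voxels is given sub-threshold mean FA so skeleton masking is
    exercised.
    """

    n_subjects: int = 36
    n_voxels: int = 500
    fa_mean: float = 0.5
    between_voxel_sd: float = 0.08
    noise_sd: float = 0.04
    effect_voxels: int = 0
    effect_beta: float = 0.0
    low_fa_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 5 or self.n_voxels < 1:
            raise ValueError("need >= 5 subjects and >= 1 voxel")
        if not (0 <= self.effect_voxels <= self.n_voxels):
            raise ValueError("effect_voxels out of range")
        if not (0 <= self.low_fa_frac < 1):
            raise ValueError("low_fa_frac must be in [0, 1)")


@dataclass
class FaDataset:
    """FA matrix plus the covariates used by the voxelwise regression."""

    fa: np.ndarray  # (n_subjects, n_voxels)
    rhi: np.ndarray
    age: np.ndarray
    sex: np.ndarray  # 0/1 (F/M)
    truth_effect_mask: np.ndarray  # bool per voxel


def generate_fa_dataset(spec: FaDatasetSpec, cohort: pd.DataFrame | None = None) -> FaDataset:
    """Generate skeleton-space FA data tied to a cohort's RHI values.

    If ``cohort`` is omitted a default cohort of ``n_subjects`` is generated
    from the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    if cohort is None:
        cohort = generate_cohort(CohortSpec(n=spec.n_subjects, seed=spec.seed))
    if len(cohort) != spec.n_subjects:
        raise ValueError(
            f"cohort has {len(cohort)} rows but spec.n_subjects = {spec.n_subjects}"
        )

    rhi = cohort["rhi"].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    sex = (cohort["sex"].to_numpy() == "M").astype(float)

    base = rng.normal(spec.fa_mean, spec.between_voxel_sd, spec.n_voxels)
    n_low = int(round(spec.low_fa_frac * spec.n_voxels))
    if n_low:
        base[-n_low:] = rng.uniform(0.05, 0.15, n_low)  # below the 0.2 skeleton cut

    fa = base[None, :] + rng.normal(0.0, spec.noise_sd, (spec.n_subjects, spec.n_voxels))

    effect_mask = np.zeros(spec.n_voxels, dtype=bool)
    if spec.effect_voxels:
        effect_mask[: spec.effect_voxels] = True
        fa[:, effect_mask] += spec.effect_beta * (rhi - rhi.mean())[:, None]

    fa = np.clip(fa, 1e-3, 1 - 1e-3)
    return FaDataset(fa=fa, rhi=rhi, age=age, sex=sex, truth_effect_mask=effect_mask)
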