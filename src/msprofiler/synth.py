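"""Synthetic progressive-MS cohorts with known ground truth.

Generates every input the profiling pipeline consumes — a clinical table
with a planted 3-profile latent structure, a labelled parcellation
volume, a reference tractogram of voxel-path streamlines, per-subject
lesion masks with profile-dependent burden and placement, and regional
grey-matter volumes carrying planted covarying components — so that each
downstream stage can be tested against the truth that generated its
input.

Default clinical calibration follows published progressive-MS cohort
summaries: three profiles (motor, cognitive,
global disability) with proportions 138:181:261 of 580, per-profile
means/SDs for EDSS, timed 25-foot walk, 9-hole peg test, SDMT and
BVMT-R, per-profile lesion burdens (cognitive > global > motor), age,
disease duration, sex and PPMS/SPMS mixing (SPMS-enriched in the global
profile). Scores are drawn from truncated normals on each measure's
legal range; EDSS is snapped to the 0–10 half-point grid.

None of this is anatomically realistic: regions are compact voxel blobs,
streamlines are digital straight lines, lesions are weighted random
voxel sets. The point is statistical structure, not anatomy.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .dconn import Tractogram

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "LabelVolume",
    "SyntheticCohort",
    "DEFAULT_CONFIG",
    "generate_clinical",
    "generate_label_volume",
    "generate_tractogram",
    "generate_lesions",
    "generate_regional_volumes",
    "simulate_cohort",
]

PROFILES = ("motor", "cognitive", "global")
MEASURES = ("edss", "t25fw", "nhpt", "sdmt", "bvmtr")

#: Published cohort-marginal per-profile SDs (motor, cognitive, global).
#: These describe the real cohort's marginal spread, which includes the
#: strong between-measure correlation of disability; drawing measures
#: independently at these SDs would overlap the profiles far more than
#: the published model's posterior certainty (mean assigned posteriors
#: 0.89-0.99) indicates. EDSS SDs derive from the printed IQRs (IQR/1.349).
MARGINAL_SCORE_SDS = {
    "edss": (1.48, 1.11, 0.37),
    "t25fw": (2.8, 5.5, 22.9),
    "nhpt": (5.7, 9.2, 19.7),
    "sdmt": (6.1, 9.3, 14.1),
    "bvmtr": (5.8, 7.8, 8.1),
}

#: Single factor applied to the marginal SDs so that independently drawn
#: measures reproduce the published profile-separation level (mean
#: assigned posterior ~0.95-0.99 and near-unambiguous classification).
SD_CALIBRATION = 0.45

# legal raw ranges per measure (truncation bounds for sampling)
_RANGES = {
    "edss": (0.0, 10.0),
    "t25fw": (0.5, np.inf),
    "nhpt": (0.5, np.inf),
    "sdmt": (0.0, np.inf),
    "bvmtr": (0.0, 36.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``score_means``/``score_sds`` map measure name -> (motor, cognitive,
    global) values. Lesion volumes are in ml; ``voxels_per_ml`` converts
    them to voxel counts on the synthetic grid.
    """

    n_subjects: int = 580
    proportions: tuple[float, float, float] = (138 / 580, 181 / 580, 261 / 580)
    score_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "edss": (4.0, 4.5, 6.0),
            "t25fw": (7.2, 9.5, 22.8),
            "nhpt": (24.3, 30.5, 38.3),
            "sdmt": (56.5, 36.8, 39.2),
            "bvmtr": (23.9, 17.6, 17.0),
        }
    )
    score_sds: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            m: tuple(s * SD_CALIBRATION for s in v) for m, v in MARGINAL_SCORE_SDS.items()
        }
    )
    lesion_ml_mean: tuple[float, float, float] = (10.799, 21.628, 18.013)
    lesion_ml_sd: tuple[float, float, float] = (14.661, 14.780, 15.349)
    voxels_per_ml: float = 8.0
    age_mean: tuple[float, float, float] = (47.9, 47.8, 49.2)
    age_sd: tuple[float, float, float] = (8.8, 9.3, 9.3)
    duration_mean: tuple[float, float, float] = (10.1, 10.0, 13.5)
    duration_sd: tuple[float, float, float] = (7.1, 8.0, 8.0)
    female_fraction: tuple[float, float, float] = (71 / 138, 93 / 181, 146 / 261)
    spms_fraction: tuple[float, float, float] = (63 / 138, 76 / 181, 164 / 261)
    n_scanners: int = 5
    # imaging-side structure
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_regions: int = 12
    region_size: int = 40
    streamlines_per_pair: int = 4
    n_planted_components: int = 3
    # per-profile mean shifts of planted component scores (profiles x components)
    planted_shifts: tuple[tuple[float, ...], ...] = (
        (0.0, 0.0, 0.0),
        (-1.2, 0.8, 0.0),
        (1.0, -0.6, 0.9),
    )
    component_amplitude: float = 0.6
    volume_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("profile proportions must be nonnegative and sum to 1")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for name, sds in self.score_sds.items():
            if min(sds) < 0:
                raise ValueError(f"negative SD for measure {name!r}")
        if min(self.lesion_ml_sd) < 0:
            raise ValueError("negative lesion-volume SD")
        if self.volume_noise_sd < 0:
            raise ValueError("volume_noise_sd must be >= 0")
        shifts = np.asarray(self.planted_shifts, dtype=float)
        if shifts.shape != (3, self.n_planted_components):
            raise ValueError(
                "planted_shifts must be 3 profiles x n_planted_components"
            )


DEFAULT_CONFIG = CohortConfig()


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery testing."""

    true_profile: np.ndarray  # (n,) indices into PROFILES
    planted_loadings: np.ndarray  # (n_components, n_regions), unit-norm rows
    planted_scores: np.ndarray  # (n, n_components), profile-shifted
    lesion_centers: np.ndarray  # (3 profiles, 3) voxel-space placement centers
    config: CohortConfig


@dataclass
class LabelVolume:
    """Integer parcellation grid: 0 = background, 1..n_regions = regions."""

    data: np.ndarray
    n_regions: int
    voxel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int32)
        labels = np.unique(self.data)
        expected = set(range(self.n_regions + 1))
        if not set(labels).issubset(expected) or not set(range(1, self.n_regions + 1)) <= set(labels):
            raise ValueError("labels must cover exactly 1..n_regions (plus background 0)")


@dataclass
class SyntheticCohort:
    """All generated inputs plus the planted truth, bundled."""

    clinical: pd.DataFrame
    truth: GroundTruth
    labels: LabelVolume
    tractogram: Tractogram
    lesions: list[np.ndarray]
    regional_volumes: pd.DataFrame


def _trunc_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_clinical(config: CohortConfig = DEFAULT_CONFIG) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a clinical table with a planted latent-profile structure.

    Each subject draws a profile from the configured proportions, then
    each measure from that profile's truncated normal. Covariates (age,
    sex, disease duration, PPMS/SPMS phenotype, scanner) are attached.
    Also plants per-subject component scores (profile-shifted standard
    normals) and unit-norm component loadings over regions, used later
    by :func:`generate_regional_volumes`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    profile = rng.choice(3, size=n, p=np.asarray(config.proportions))

    cols: dict[str, np.ndarray] = {}
    for m in MEASURES:
        lo, hi = _RANGES[m]
        vals = np.empty(n)
        for k in range(3):
            sel = profile == k
            vals[sel] = _trunc_normal(
                rng, config.score_means[m][k], config.score_sds[m][k], lo, hi, sel.sum()
            )
        if m == "edss":
            vals = np.clip(np.round(vals * 2.0) / 2.0, 0.0, 10.0)
        cols[m] = vals

    age = np.empty(n)
    duration = np.empty(n)
    sex = np.empty(n, dtype=object)
    phenotype = np.empty(n, dtype=object)
    for k in range(3):
        sel = profile == k
        nk = int(sel.sum())
        age[sel] = _trunc_normal(rng, config.age_mean[k], config.age_sd[k], 18.0, 90.0, nk)
        duration[sel] = _trunc_normal(
            rng, config.duration_mean[k], config.duration_sd[k], 0.0, np.inf, nk
        )
        sex[sel] = np.where(rng.random(nk) < config.female_fraction[k], "F", "M")
        phenotype[sel] = np.where(rng.random(nk) < config.spms_fraction[k], "SPMS", "PPMS")
    scanner = rng.integers(0, config.n_scanners, size=n)

    clinical = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            **cols,
            "age": age,
            "sex": sex,
            "disease_duration": duration,
            "phenotype": phenotype,
            "scanner": [f"scanner-{s}" for s in scanner],
        }
    )

    # planted ICA structure over regions
    k_comp, d = config.n_planted_components, config.n_regions
    loadings = rng.normal(size=(k_comp, d))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    shifts = np.asarray(config.planted_shifts)
    scores = rng.normal(size=(n, k_comp)) + shifts[profile]

    # lesion placement centers per profile: the cognitive profile's lesions
    # concentrate centrally (where streamlines between regions are densest,
    # emulating periventricular load), the global profile's mid-way, the
    # motor profile's peripherally -- so disconnection ordering
    # cognitive > global > motor emerges from placement as well as burden
    grid = np.array(config.grid_shape, dtype=float)
    centers = np.vstack([grid * 0.15, grid * 0.5, grid * 0.35])
    truth = GroundTruth(
        true_profile=profile,
        planted_loadings=loadings,
        planted_scores=scores,
        lesion_centers=centers,
        config=config,
    )
    return clinical, truth


_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def generate_label_volume(
    n_regions: int = 12,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    region_size: int = 40,
    seed: int = 0,
) -> LabelVolume:
    """Grow compact, connected, non-overlapping labelled regions.

    Seeds are placed with a minimum mutual distance, then each region
    grows by round-robin breadth-first search over unclaimed voxels up to
    ``region_size`` voxels. The rest of the grid stays background (0),
    standing in for white matter that streamlines traverse.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    shape = tuple(int(s) for s in grid_shape)
    nvox = int(np.prod(shape))
    if n_regions * region_size > nvox:
        raise ValueError(
            f"cannot pack {n_regions} regions of {region_size} voxels into grid {shape}"
        )
    rng = np.random.default_rng(seed)
    # seed placement with distance-based rejection, relaxing if needed
    min_dist = max(2.0, 0.6 * (nvox / n_regions) ** (1 / 3))
    seeds: list[np.ndarray] = []
    attempts = 0
    while len(seeds) < n_regions:
        cand = np.array([rng.integers(0, s) for s in shape])
        attempts += 1
        if all(np.linalg.norm(cand - s) >= min_dist for s in seeds):
            seeds.append(cand)
        elif attempts > 200 * n_regions:
            min_dist = max(1.0, min_dist * 0.8)
            attempts = 0
    vol = np.zeros(shape, dtype=np.int32)
    queues = []
    sizes = np.zeros(n_regions, dtype=int)
    for lab, s in enumerate(seeds, start=1):
        vol[tuple(s)] = lab
        queues.append(deque([s]))
        sizes[lab - 1] = 1
    active = True
    while active:
        active = False
        for lab in range(1, n_regions + 1):
            q = queues[lab - 1]
            if sizes[lab - 1] >= region_size or not q:
                continue
            v = q.popleft()
            nbrs = v + _NEIGHBORS
            ok = np.all((nbrs >= 0) & (nbrs < np.array(shape)), axis=1)
            order = rng.permutation(np.flatnonzero(ok))
            for idx in order:
                nb = nbrs[idx]
                if vol[tuple(nb)] == 0 and sizes[lab - 1] < region_size:
                    vol[tuple(nb)] = lab
                    sizes[lab - 1] += 1
                    q.append(nb)
            active = True
    return LabelVolume(data=vol, n_regions=n_regions)


def _digital_line(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bresenham-style 3-D voxel traversal from a to b (inclusive)."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    steps = int(np.abs(b - a).max())
    if steps == 0:
        return a[None, :].copy()
    t = np.arange(steps + 1) / steps
    pts = np.rint(a[None, :] + t[:, None] * (b - a)[None, :]).astype(int)
    return pts


def generate_tractogram(
    labels: LabelVolume,
    streamlines_per_pair: int = 4,
    jitter: float = 0.0,
    include_self: bool = False,
    seed: int = 0,
) -> Tractogram:
    """Digital-line streamlines between random voxels of each region pair.

    Every unordered pair of distinct regions (and self-pairs if
    ``include_self``) receives exactly ``streamlines_per_pair``
    streamlines. ``jitter`` > 0 bends each line through a randomly
    displaced midpoint, giving two digital segments.
    """
    if streamlines_per_pair < 0:
        raise ValueError("streamlines_per_pair must be >= 0")
    rng = np.random.default_rng(seed)
    vol = labels.data
    shape = vol.shape
    region_voxels = {
        lab: np.argwhere(vol == lab) for lab in range(1, labels.n_regions + 1)
    }
    streamlines: list[np.ndarray] = []
    endpoints: list[tuple[int, int]] = []
    for i in range(1, labels.n_regions + 1):
        for j in range(i if include_self else i + 1, labels.n_regions + 1):
            vi, vj = region_voxels[i], region_voxels[j]
            for _ in range(streamlines_per_pair):
                a = vi[rng.integers(len(vi))]
                b = vj[rng.integers(len(vj))]
                if jitter > 0:
                    mid = (a + b) / 2.0 + rng.normal(scale=jitter, size=3)
                    mid = np.clip(np.rint(mid), 0, np.array(shape) - 1).astype(int)
                    path = np.vstack([_digital_line(a, mid)[:-1], _digital_line(mid, b)])
                else:
                    path = _digital_line(a, b)
                streamlines.append(path)
                endpoints.append((i, j))
    return Tractogram(
        streamlines=streamlines,
        endpoints=np.array(endpoints, dtype=int).reshape(-1, 2),
        n_regions=labels.n_regions,
        grid_shape=tuple(shape),
    )


def generate_lesions(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    labels: LabelVolume,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-subject binary lesion masks on the label grid.

    The lesion voxel count is drawn from the subject profile's truncated
    normal (ml scaled by ``voxels_per_ml``); voxel placement is weighted
    by a Gaussian field around the profile's placement center mixed with
    a uniform floor, so lesion topography as well as burden differs by
    profile. With the default burdens the mean mask volume orders
    cognitive > global > motor.
    """
    if len(cohort) != len(truth.true_profile):
        raise ValueError("cohort and ground truth are misaligned")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    shape = labels.data.shape
    nvox = int(np.prod(shape))
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    sigma = max(shape) / 4.0
    # per-profile placement weights over all voxels
    weights = []
    for k in range(3):
        d2 = ((coords - truth.lesion_centers[k]) ** 2).sum(axis=1)
        w = 0.25 + np.exp(-d2 / (2.0 * sigma**2))
        weights.append(w / w.sum())
    masks: list[np.ndarray] = []
    for s in range(len(cohort)):
        k = int(truth.true_profile[s])
        if cfg.lesion_ml_mean[k] <= 0:
            ml = 0.0  # a lesion-free profile stays lesion-free
        else:
            ml = _trunc_normal(
                rng, cfg.lesion_ml_mean[k], cfg.lesion_ml_sd[k], 0.0, np.inf, 1
            )[0]
        target = min(int(round(ml * cfg.voxels_per_ml)), nvox)
        mask = np.zeros(shape, dtype=np.uint8)
        if target > 0:
            chosen = rng.choice(nvox, size=target, replace=False, p=weights[k])
            mask.reshape(-1)[chosen] = 1
        masks.append(mask)
    return masks


def generate_regional_volumes(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Regional grey-matter volumes with the planted covarying components.

    volumes = region baseline + amplitude * scores @ loadings + noise,
    clipped to stay positive. Column names are ``region_1..region_N``;
    ``subject_id`` keys the rows.
    """
    cfg = truth.config
    if noise_sd is None:
        noise_sd = cfg.volume_noise_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth.planted_loadings is None:
        raise ValueError("ground truth carries no planted loadings")
    if len(cohort) != truth.planted_scores.shape[0]:
        raise ValueError("cohort and ground truth are misaligned")
    rng = np.random.default_rng(seed)
    n, d = len(cohort), cfg.n_regions
    baseline = rng.uniform(4.0, 6.0, size=d)
    signal = cfg.component_amplitude * truth.planted_scores @ truth.planted_loadings
    noise = rng.normal(scale=noise_sd, size=(n, d)) if noise_sd > 0 else 0.0
    vols = np.maximum(baseline[None, :] + signal + noise, 1e-3)
    out = pd.DataFrame(vols, columns=[f"region_{r + 1}" for r in range(d)])
    out.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    return out


def simulate_cohort(config: CohortConfig = DEFAULT_CONFIG) -> SyntheticCohort:
    """Generate the full bundle of pipeline inputs from one seed."""
    ss = np.random.SeedSequence(config.seed)
    s_clin, s_lab, s_trk, s_les, s_vol = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(5)
    ]
    cfg = replace(config, seed=s_clin)
    clinical, truth = generate_clinical(cfg)
    labels = generate_label_volume(
        config.n_regions, config.grid_shape, config.region_size, seed=s_lab
    )
    tractogram = generate_tractogram(
        labels, config.streamlines_per_pair, seed=s_trk
    )
    lesions = generate_lesions(clinical, truth, labels, seed=s_les)
    volumes = generate_regional_volumes(clinical, truth, seed=s_vol)
    return SyntheticCohort(clinical, truth, labels, tractogram, lesions, volumes)
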