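"""Fully synthetic lesion-study generator.

Real lesion cohorts of this kind are under restricted access, so every
pipeline stage is exercised on a phantom study with known ground truth:

* a phantom brain (ellipsoid mask) with spherical "cortical" ROIs split
  over two hemispheres;
* an AC atlas in which each ROI's streamline map is a sum of straight
  Gaussian-profile tubes running to its partner ROIs — network ROIs are
  preferentially interconnected, giving the network a coherent tract
  skeleton;
* an FC atlas of smooth signed z-maps correlated with the tube layout;
* an edge-density map (normalized sum of all tubes);
* focal blob-shaped lesions with a log-normal size law and a configurable
  left/right/bilateral mix;
* behavioral scores generated as noisy linear functions of the true AC
  disconnection scores of a planted ROI subset, with a shared subset across
  the two tasks to emulate domain-general cognitive control; the raw task
  fields (TMT times, Stroop counts) are back-computed so the behavior
  module reproduces the latent score exactly at zero noise (up to integer
  rounding for Stroop, which is recorded).

Straight tubes and ellipsoid blobs are the simplest geometry with the
required statistical structure (lesion-tract intersection drives behavior);
anatomical realism is a non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .behavior import BehavioralRecord, stroop_interference
from .connectivity_maps import ConnectivityAtlas, TimeSeries4D
from .disconnection import disconnection_matrix
from .volumes import LesionMask, Parcellation, Volume3D

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Phantom",
    "make_phantom",
    "simulate_lesions",
    "simulate_behavior",
    "simulate_bold",
    "simulate_cohort",
    "Cohort",
]


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the reference study's structure at desk scale: three
    samples (training task-1, test task-1, test task-2), a 60-ROI
    parcellation with 30 ROIs per hemisphere, and a 10-ROI a priori network
    emulating the multiple demand network (~17% of ROIs).
    """

    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_mm: float = 1.5
    n_rois: int = 60  # split evenly over L and R
    roi_radius_vox: float = 2.0
    network_size: int = 10
    n_partners: int = 3
    tract_sigma_mm: float = 2.5
    tract_amplitude: float = 50.0  # peak streamline density of one tube
    n_subjects: tuple[int, int, int] = (120, 100, 80)
    # lesion size law: log-normal on the blob radius (voxel units)
    lesion_log_radius_mean: float = 1.15
    lesion_log_radius_sd: float = 0.3
    lesion_max_blobs: int = 2
    laterality_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)  # L, R, bilateral
    # planted effects (weights in SD units of the disconnection score)
    n_shared: int = 3
    n_task_specific: int = 2
    effect_weight: float = 0.8
    beta0_tmt: float = 3.5  # ln seconds of TMT B-A for an average lesion
    beta0_stroop: float = 0.2  # ln seconds of Stroop interference
    noise_sd: float = 0.3
    stroop_tolerance: float = 0.02
    # floor/ceiling of the measurable Stroop log-interference: a 45 s window
    # bounds the interference a patient can express, so extreme latents
    # saturate like real test scores do
    stroop_score_floor: float = -4.2
    stroop_score_ceiling: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois % 2:
            raise ValueError("n_rois must be even (split over two hemispheres)")
        if self.network_size > self.n_rois:
            raise ValueError("network larger than the parcellation")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if min(self.n_subjects) < 10:
            raise ValueError("group sizes must be >= 10")
        needed = self.n_shared + 2 * self.n_task_specific
        if needed > self.network_size:
            raise ValueError("planted sets do not fit in the network subset")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_mm
        return aff


@dataclass
class GroundTruth:
    """Everything needed to recompute the noiseless behavior exactly."""

    task: str
    planted_roi_ids: list[int]
    weights: dict[int, float]
    beta0: float
    noise_sd: float
    score_means: dict[int, float]  # per-ROI standardization used
    score_sds: dict[int, float]
    noiseless_scores: dict[str, float]  # subject -> y before noise
    latent_scores: dict[str, float]  # subject -> y after noise (target of raw fields)
    max_rounding_error: float
    n_regenerated: int
    seed: int
    n_saturated: int = 0  # Stroop latents clamped at the task floor/ceiling

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_roi_ids"] = [int(r) for r in self.planted_roi_ids]
        d["weights"] = {str(k): v for k, v in self.weights.items()}
        d["score_means"] = {str(k): v for k, v in self.score_means.items()}
        d["score_sds"] = {str(k): v for k, v in self.score_sds.items()}
        return d


@dataclass
class Phantom:
    brain_mask: Volume3D
    parcellation: Parcellation
    atlas_ac: ConnectivityAtlas
    atlas_fc: ConnectivityAtlas
    edge_density: Volume3D
    network_subset: list[int]
    roi_centers: np.ndarray  # (n_rois, 3) voxel coordinates
    partners: dict[int, list[int]]


def _coordinate_grid(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(np.float64)


def _tube(grid: np.ndarray, a: np.ndarray, b: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Gaussian-profile density around the segment a-b (voxel coordinates)."""
    ab = b - a
    denom = float(ab @ ab)
    rel = grid - a
    if denom == 0:
        d2 = (rel**2).sum(axis=-1)
    else:
        t = np.clip((rel @ ab) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        d2 = ((grid - proj) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * sigma_vox**2))


def _ellipsoid_mask(shape: tuple[int, int, int], fraction: float = 0.92) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = fraction * np.asarray(shape) / 2.0
    grid = _coordinate_grid(shape)
    return (((grid - center) / semi) ** 2).sum(axis=-1) <= 1.0


def make_phantom(cfg: SyntheticConfig) -> Phantom:
    """Deterministic phantom brain, parcellation and connectivity atlases."""
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)
    affine = cfg.affine
    mask = _ellipsoid_mask(shape)
    brain_mask = Volume3D(mask.astype(np.float64), affine)
    grid = _coordinate_grid(shape)

    # ROI centers: rejection-sample per hemisphere with a minimum separation
    half = cfg.n_rois // 2
    mid = shape[0] / 2.0
    min_sep = max(2.5 * cfg.roi_radius_vox, 4.0)
    # keep ROI spheres inside the mask: sample centers from an eroded mask
    erode_iter = int(math.ceil(cfg.roi_radius_vox)) + 1
    interior = ndimage.binary_erosion(mask, iterations=erode_iter)
    coords_in = np.argwhere(interior)
    centers: list[np.ndarray] = []
    for hemi in ("L", "R"):
        hemi_coords = coords_in[
            coords_in[:, 0] < mid if hemi == "L" else coords_in[:, 0] >= mid
        ]
        placed = 0
        attempts = 0
        while placed < half:
            attempts += 1
            if attempts > 20000:
                raise ValueError("could not place ROIs: grid too small for config")
            c = hemi_coords[rng.integers(len(hemi_coords))].astype(np.float64)
            if all(np.linalg.norm(c - p) >= min_sep for p in centers):
                centers.append(c)
                placed += 1
    centers_arr = np.stack(centers)
    roi_ids = list(range(1, cfg.n_rois + 1))
    hemisphere = ["L"] * half + ["R"] * half

    labels = np.zeros(shape)
    for rid, c in zip(roi_ids, centers_arr):
        sphere = ((grid - c) ** 2).sum(axis=-1) <= cfg.roi_radius_vox**2
        labels[sphere & mask & (labels == 0)] = rid
    parcellation = Parcellation(
        labels=Volume3D(labels, affine),
        roi_ids=roi_ids,
        hemisphere=hemisphere,
    )

    # a priori network: balanced across hemispheres, preferentially
    # interconnected so its tracts form a coherent skeleton
    n_net_l = cfg.network_size // 2
    net_l = list(rng.choice(roi_ids[:half], size=n_net_l, replace=False))
    net_r = list(
        rng.choice(roi_ids[half:], size=cfg.network_size - n_net_l, replace=False)
    )
    network = sorted(int(r) for r in net_l + net_r)
    net_set = set(network)

    # partner choice emulates tract anatomy: network ROIs are joined by
    # long-range tracts to other network ROIs, everything else connects to
    # its nearest neighbours (short association fibres), keeping tracts
    # spatially segregated rather than all crossing the phantom's centre
    partners: dict[int, list[int]] = {}
    for rid in roi_ids:
        if rid in net_set:
            pool = [r for r in network if r != rid]
            k = min(cfg.n_partners, len(pool))
            chosen = rng.choice(pool, size=k, replace=False)
        else:
            pool = [r for r in roi_ids if r != rid and r not in net_set]
            dists = np.linalg.norm(
                centers_arr[np.asarray(pool) - 1] - centers_arr[rid - 1], axis=1
            )
            order = np.argsort(dists)
            chosen = np.asarray(pool)[order[: cfg.n_partners]]
        partners[rid] = sorted(int(r) for r in chosen)

    sigma_vox = cfg.tract_sigma_mm / cfg.voxel_mm
    tube_cache: dict[tuple[int, int], np.ndarray] = {}

    def pair_tube(r1: int, r2: int) -> np.ndarray:
        key = (min(r1, r2), max(r1, r2))
        if key not in tube_cache:
            a = centers_arr[key[0] - 1]
            b = centers_arr[key[1] - 1]
            tube_cache[key] = _tube(grid, a, b, sigma_vox) * mask
        return tube_cache[key]

    ac_maps = []
    for rid in roi_ids:
        m = np.zeros(shape)
        for p in partners[rid]:
            m += cfg.tract_amplitude * pair_tube(rid, p)
        ac_maps.append(Volume3D(m, affine))
    atlas_ac = ConnectivityAtlas(kind="AC", maps=ac_maps, roi_ids=roi_ids)

    # FC maps: functional coupling concentrates at grey-matter sites, not
    # along the white-matter tract course, and reflects polysynaptic /
    # indirect coupling, so each map is a sum of Gaussian bumps at the seed
    # and an *imperfect* version of its partner list (one true partner
    # dropped, two indirectly-coupled ROIs added) plus a smooth signed
    # background — the reasons FC disconnection carries less information
    # than AC about tract-transecting lesions
    fc_sigma = 2.0 * sigma_vox
    fc_maps = []
    for rid in roi_ids:
        true_p = list(partners[rid])
        if true_p:
            true_p.remove(true_p[rng.integers(len(true_p))])
        others = [r for r in roi_ids if r != rid and r not in partners[rid]]
        indirect = [
            int(r) for r in rng.choice(others, size=min(2, len(others)), replace=False)
        ]
        bump = np.zeros(shape)
        for p in [rid] + true_p + indirect:
            c = centers_arr[p - 1]
            bump += np.exp(
                -((grid - c) ** 2).sum(axis=-1) / (2.0 * fc_sigma**2)
            )
        peak = bump.max()
        if peak > 0:
            bump /= peak
        background = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=3.0
        )
        background /= max(np.abs(background).max(), 1e-12)
        z = (1.2 * bump + 0.35 * background) * mask
        fc_maps.append(Volume3D(z, affine))
    atlas_fc = ConnectivityAtlas(kind="FC", maps=fc_maps, roi_ids=roi_ids)

    edge = np.zeros(shape)
    for key in tube_cache:
        edge += tube_cache[key]
    if edge.max() > 0:
        edge = edge / edge.max()
    edge_density = Volume3D(edge * mask, affine)

    return Phantom(
        brain_mask=brain_mask,
        parcellation=parcellation,
        atlas_ac=atlas_ac,
        atlas_fc=atlas_fc,
        edge_density=edge_density,
        network_subset=network,
        roi_centers=centers_arr,
        partners=partners,
    )


def simulate_lesions(
    cfg: SyntheticConfig,
    n: int,
    rng: np.random.Generator,
    brain_mask: Volume3D,
    subject_prefix: str = "sub",
) -> list[LesionMask]:
    """Focal blob lesions: union of 1..max_blobs ellipsoids inside the mask."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = brain_mask.data > 0
    shape = mask.shape
    mid = shape[0] / 2.0
    grid = _coordinate_grid(shape)
    coords = np.argwhere(mask)
    coords_l = coords[coords[:, 0] < mid]
    coords_r = coords[coords[:, 0] >= mid]
    mix = np.asarray(cfg.laterality_mix, dtype=np.float64)
    mix = mix / mix.sum()
    lesions = []
    for i in range(n):
        while True:
            side = rng.choice(3, p=mix)  # 0=L, 1=R, 2=bilateral
            pool = (coords_l, coords_r, coords)[side]
            n_blobs = int(rng.integers(1, cfg.lesion_max_blobs + 1))
            les = np.zeros(shape, dtype=bool)
            for _ in range(n_blobs):
                center = pool[rng.integers(len(pool))].astype(np.float64)
                radius = float(
                    np.exp(
                        rng.normal(cfg.lesion_log_radius_mean, cfg.lesion_log_radius_sd)
                    )
                )
                if radius > max(shape):
                    raise ValueError("lesion size law produces blobs larger than the grid")
                semi = radius * rng.uniform(0.7, 1.3, size=3)
                blob = (((grid - center) / semi) ** 2).sum(axis=-1) <= 1.0
                les |= blob
            les &= mask
            if les.any():
                break
        lesions.append(
            LesionMask(
                mask=Volume3D(les.astype(np.float64), brain_mask.affine.copy()),
                subject_id=f"{subject_prefix}-{i:04d}",
            )
        )
    return lesions


def _stroop_counts_for(y: float, window_s: float, tol: float):
    """Integer Stroop counts whose log-interference best matches y.

    For each candidate (c, cw) pair the word count w solving
    window/cw - (window/c + window/w)/2 = exp(y) is computed in closed form
    and its integer neighbours are scored; returns (c, w, cw, error) or
    None when no combination comes within ``tol``.
    """
    target = math.exp(y)
    best = None
    for c in range(2, 91):
        rt_c = window_s / c
        for cw in range(1, c + 1):
            # 2*(window/cw - target) - window/c = window/w
            inv_w = 2.0 * (window_s / cw - target) - rt_c
            if inv_w <= 0:
                continue
            w_guess = window_s / inv_w
            for w in {math.floor(w_guess), math.ceil(w_guess)}:
                if w < 2 or w > 90:
                    continue
                interf = window_s / cw - (rt_c + window_s / w) / 2.0
                if interf <= 0:
                    continue
                err = abs(math.log(interf) - y)
                if best is None or err < best[3]:
                    best = (c, w, cw, err)
    if best is None or best[3] > tol:
        return None
    return best


def simulate_behavior(
    lesions: list[LesionMask],
    atlas_ac: ConnectivityAtlas,
    cfg: SyntheticConfig,
    task: str,
    rng: np.random.Generator,
    planted_shared: list[int],
    planted_specific: list[int],
) -> tuple[list[BehavioralRecord], GroundTruth]:
    """Behavioral records whose latent score is linear in true disconnection.

    y_i = beta0 + sum_r w_r * z(d_ir) + eps_i, where d_ir is the AC
    disconnection score of planted ROI r and z() standardizes each planted
    column within the cohort (raw masked sums have arbitrary atlas-dependent
    scale; SD units keep the weights interpretable and the scores
    representable as raw task fields).  The common weight w_r is chosen so
    the signal component of y has SD ``cfg.effect_weight``; the effective
    per-ROI weights are recorded in the ground truth.  Raw fields are
    back-computed so the
    behavior module recovers y_i exactly at noise_sd = 0 (TMT) or within the
    integer-rounding tolerance (Stroop).
    """
    if task not in ("task1", "task2"):
        raise ValueError("task must be 'task1' (TMT) or 'task2' (Stroop)")
    planted = list(planted_shared) + list(planted_specific)
    missing = set(planted) - set(atlas_ac.roi_ids)
    if missing:
        raise ValueError(f"planted ROIs not in atlas: {sorted(missing)}")
    dmat = disconnection_matrix(lesions, atlas_ac.subset(planted))
    d = dmat.scores.to_numpy(dtype=np.float64)
    means = d.mean(axis=0)
    sds = d.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("a planted ROI has zero disconnection variance in this cohort")
    z = (d - means) / sds
    beta0 = cfg.beta0_tmt if task == "task1" else cfg.beta0_stroop
    # normalize the composite so the signal component of y has SD equal to
    # effect_weight regardless of the number of planted ROIs (keeps exp(y)
    # in a realistic, representable range)
    composite = z.sum(axis=1)
    comp_sd = composite.std()
    if comp_sd == 0:
        raise ValueError("planted composite has zero variance in this cohort")
    w_eff = cfg.effect_weight / comp_sd
    weights = {r: float(w_eff) for r in planted}
    w = np.asarray([weights[r] for r in planted])
    y0 = beta0 + z @ w

    records: list[BehavioralRecord] = []
    latent: dict[str, float] = {}
    max_round_err = 0.0
    n_regen = 0
    n_saturated = 0
    for i, les in enumerate(lesions):
        sid = les.subject_id
        for attempt in range(50):
            y = float(y0[i] + rng.normal(0.0, cfg.noise_sd))
            if task == "task1":
                a = float(rng.uniform(25.0, 40.0))
                b = a + math.exp(y)
                records.append(BehavioralRecord(subject_id=sid, tmt_a_s=a, tmt_b_s=b))
                latent[sid] = y
                break
            clamped = float(
                np.clip(y, cfg.stroop_score_floor, cfg.stroop_score_ceiling)
            )
            n_saturated += int(clamped != y)
            y = clamped
            found = _stroop_counts_for(y, 45.0, cfg.stroop_tolerance)
            if found is not None:
                c, wct, cw, err = found
                records.append(
                    BehavioralRecord(
                        subject_id=sid,
                        stroop_c_correct=c,
                        stroop_w_correct=wct,
                        stroop_cw_correct=cw,
                    )
                )
                latent[sid] = stroop_interference(c, wct, cw, 45.0)
                max_round_err = max(max_round_err, err)
                break
            n_regen += 1
        else:
            raise RuntimeError(
                f"could not represent a Stroop score for {sid} within tolerance"
            )
    gt = GroundTruth(
        task=task,
        planted_roi_ids=planted,
        weights=weights,
        beta0=beta0,
        noise_sd=cfg.noise_sd,
        score_means={r: float(m) for r, m in zip(planted, means)},
        score_sds={r: float(s) for r, s in zip(planted, sds)},
        noiseless_scores={l.subject_id: float(v) for l, v in zip(lesions, y0)},
        latent_scores=latent,
        max_rounding_error=max_round_err,
        n_regenerated=n_regen,
        n_saturated=n_saturated,
        seed=cfg.seed,
    )
    return records, gt


def simulate_bold(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    shape: tuple[int, int, int] | None = None,
    n_timepoints: int = 200,
    tr_s: float = 3.0,
    n_latents: int = 2,
    ar_coef: float = 0.3,
    noise_sd: float = 1.0,
) -> tuple[TimeSeries4D, np.ndarray, dict]:
    """Resting-state-like 4D signal with planted latent couplings.

    Voxel time series = sum of band-limited latent signals weighted by
    smooth spatial loading fields + AR(1) noise + nuisance components
    (linear drift and a global signal) with voxel-specific gains.  Returns
    the time series, the nuisance regressor matrix (drift, global, and
    their first temporal derivatives), and ground-truth loadings.
    """
    shape = tuple(shape or cfg.shape)
    t = n_timepoints
    freqs = np.fft.rfftfreq(t, d=tr_s)
    band = (freqs > 0.01) & (freqs < 0.08)

    def band_limited() -> np.ndarray:
        spec = np.fft.rfft(rng.standard_normal(t))
        spec[~band] = 0.0
        sig = np.fft.irfft(spec, n=t)
        return sig / max(sig.std(), 1e-12)

    latents = np.stack([band_limited() for _ in range(n_latents)])
    loadings = np.stack(
        [
            ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
            for _ in range(n_latents)
        ]
    )
    loadings /= np.abs(loadings).max(axis=(1, 2, 3), keepdims=True)

    n_vox = int(np.prod(shape))
    noise = rng.standard_normal((n_vox, t)) * noise_sd
    for j in range(1, t):
        noise[:, j] += ar_coef * noise[:, j - 1]

    drift = np.linspace(-1.0, 1.0, t)
    global_sig = band_limited()
    drift_gain = rng.uniform(0.5, 1.5, size=n_vox)
    global_gain = rng.uniform(0.5, 1.5, size=n_vox)

    data = (
        loadings.reshape(n_latents, n_vox).T @ latents
        + noise
        + drift_gain[:, None] * drift
        + global_gain[:, None] * global_sig
    ).reshape(*shape, t)

    def deriv(x: np.ndarray) -> np.ndarray:
        return np.gradient(x)

    nuisance = np.column_stack([drift, global_sig, deriv(drift), deriv(global_sig)])
    info = {"latents": latents, "loadings": loadings}
    return TimeSeries4D(data=data, tr_s=tr_s, affine=cfg.affine), nuisance, info


@dataclass
class Cohort:
    """A full synthetic study: phantom plus three subject groups.

    Group 1 (training, task 1), group 2 (test, task 1) and group 3 (test,
    task 2) contain disjoint subjects; the planted shared ROI set is common
    to both tasks, each task adds its own specific ROIs.
    """

    cfg: SyntheticConfig
    phantom: Phantom
    lesions: dict[str, list[LesionMask]]
    behavior: dict[str, list[BehavioralRecord]]
    ground_truth: dict[str, GroundTruth]
    planted_shared: list[int]
    planted_task1: list[int]
    planted_task2: list[int]

    @property
    def group_task(self) -> dict[str, str]:
        return {"group1": "task1", "group2": "task1", "group3": "task2"}


def simulate_cohort(cfg: SyntheticConfig, phantom: Phantom | None = None) -> Cohort:
    """Generate the three-sample study defined by ``cfg`` deterministically.

    ``phantom`` may be supplied to reuse one atlas across cohorts (the
    connectivity atlases emulate fixed normative data; only patients vary).
    """
    if phantom is None:
        phantom = make_phantom(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    network = phantom.network_subset
    k_sh, k_sp = cfg.n_shared, cfg.n_task_specific
    chosen = list(
        np.asarray(network)[
            rng.choice(len(network), size=k_sh + 2 * k_sp, replace=False)
        ]
    )
    shared = sorted(int(r) for r in chosen[:k_sh])
    task1_specific = sorted(int(r) for r in chosen[k_sh : k_sh + k_sp])
    task2_specific = sorted(int(r) for r in chosen[k_sh + k_sp :])

    lesions: dict[str, list[LesionMask]] = {}
    behavior: dict[str, list[BehavioralRecord]] = {}
    gts: dict[str, GroundTruth] = {}
    tasks = {"group1": "task1", "group2": "task1", "group3": "task2"}
    for gi, (group, n) in enumerate(zip(("group1", "group2", "group3"), cfg.n_subjects)):
        g_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2 + gi]))
        les = simulate_lesions(
            cfg, n, g_rng, phantom.brain_mask, subject_prefix=f"g{gi + 1}"
        )
        task = tasks[group]
        specific = task1_specific if task == "task1" else task2_specific
        recs, gt = simulate_behavior(
            les, phantom.atlas_ac, cfg, task, g_rng, shared, specific
        )
        lesions[group] = les
        behavior[group] = recs
        gts[group] = gt
    return Cohort(
        cfg=cfg,
        phantom=phantom,
        lesions=lesions,
        behavior=behavior,
        ground_truth=gts,
        planted_shared=shared,
        planted_task1=task1_specific,
        planted_task2=task2_specific,
    )
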