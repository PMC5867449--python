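"""Digital head phantoms, lesion planting, and simulated raters.

The phantom is a label-space head model: nested ellipsoidal shells for
ventricles, white matter and cortex, angular sectors splitting the
cortex into the 8 lobar labels, and blob-shaped basal ganglia / thalami
/ infratentorial structures. For spherical configurations the analytic
relative distance (r - r0)/(r1 - r0) is emitted alongside, giving a
closed-form oracle for the Laplace/streamline machinery.

Lesions are planted as unions of random spherical blobs grown inside
each region until a target fraction is reached; the achieved per-region
fractions are returned as exact ground truth (the planted-load round
trip against :func:`~bullseye_wmh.loads.compute_regional_loads` is the
backbone consistency check).

Simulated raters score the cohort through noisy monotone functions of
weighted regional loads, thresholded into each subscale's admissible
range — enough structure to exercise the agreement statistics,
discrepancy maps and prediction pipeline end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .loads import default_subscale_regions
from .scales import ScaleSpec, ScoreTable
from .volume import LabeledVolume, ScalarField
from .zones import N_ZONES, region_id, region_zone_layer

__all__ = [
    "PhantomSpec",
    "Phantom",
    "RaterModel",
    "generate_phantom",
    "plant_lesions",
    "simulate_cohort",
    "make_rater_models",
    "planted_bias_scenario",
    "simulate_raters",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the digital head phantom.

    Radii are ellipsoid semi-axes in voxel units along (x, y, z); equal
    semi-axes give a spherical phantom with an analytic radial oracle.
    Axes: x = left-right (x < centre is left), y = posterior-anterior,
    z = inferior-superior.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ventricle_radii: tuple[float, float, float] = (10.0, 14.0, 10.0)
    wm_outer_radii: tuple[float, float, float] = (30.0, 38.0, 32.0)
    cortex_thickness: float = 3.0
    include_bgit: bool = True
    bgit_blob_radius: float = 4.0
    #: place the infratentorial blob detached from the cerebral shells
    #: (exercises the Euclidean fallback for components without a
    #: ventricular boundary)
    detached_infratentorial: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        v, w = self.ventricle_radii, self.wm_outer_radii
        if not all(wv > vv + 2 for wv, vv in zip(w, v)):
            raise ValueError("infeasible nesting: WM outer radii must exceed "
                             "ventricle radii by > 2 voxels")
        half = [s / 2 for s in self.shape]
        if not all(w[i] + self.cortex_thickness < half[i] for i in range(3)):
            raise ValueError("cortex shell does not fit inside the grid")

    @property
    def is_spherical(self) -> bool:
        return (len(set(self.ventricle_radii)) == 1
                and len(set(self.wm_outer_radii)) == 1)


@dataclass
class Phantom:
    """Generated label volumes plus optional analytic oracle fields."""

    spec: PhantomSpec
    ventricles: LabeledVolume
    wm: LabeledVolume
    cortex_lobes: LabeledVolume
    basal_ganglia: LabeledVolume
    thalami: LabeledVolume
    infratentorial: LabeledVolume
    analytic_d: ScalarField | None = None

    def volumes(self) -> dict[str, LabeledVolume]:
        return {
            "ventricles": self.ventricles,
            "wm": self.wm,
            "cortex_lobes": self.cortex_lobes,
            "basal_ganglia": self.basal_ganglia,
            "thalami": self.thalami,
            "infratentorial": self.infratentorial,
        }


def _ellipsoid_rho(shape, voxel_size, centre, radii) -> np.ndarray:
    """Normalized ellipsoidal coordinate: rho <= 1 inside the surface."""
    grids = np.indices(shape, dtype=float)
    rho2 = np.zeros(shape)
    for a in range(3):
        rho2 += ((grids[a] - centre[a]) * voxel_size[a] / radii[a]) ** 2
    return np.sqrt(rho2)


def _lobe_sectors(shape, centre) -> np.ndarray:
    """Zone labels 1..8 from hemisphere (x) and (y, z) angular quadrant."""
    gx, gy, gz = np.indices(shape, dtype=float)
    dy, dz = gy - centre[1], gz - centre[2]
    phi = np.degrees(np.arctan2(dz, dy)) % 360.0
    # frontal: anterior (+y); parietal: superior (+z); occipital: posterior;
    # temporal: inferior
    lobe = np.full(shape, 0, dtype=np.int16)
    lobe[(phi < 45) | (phi >= 315)] = 1   # frontal
    lobe[(phi >= 45) & (phi < 135)] = 2   # parietal
    lobe[(phi >= 135) & (phi < 225)] = 3  # occipital
    lobe[(phi >= 225) & (phi < 315)] = 4  # temporal
    right = gx >= centre[0]
    zone = np.where(lobe > 0, (lobe - 1) * 2 + 1 + right.astype(np.int16), 0)
    return zone.astype(np.int16)


def _ball_mask(shape, voxel_size, centre, radius) -> np.ndarray:
    return _ellipsoid_rho(shape, voxel_size, centre,
                          (radius, radius, radius)) <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the phantom label volumes; deterministic for a fixed spec."""
    shape, vs = spec.shape, spec.voxel_size
    centre = tuple((s - 1) / 2.0 for s in shape)
    rho_v = _ellipsoid_rho(shape, vs, centre, spec.ventricle_radii)
    rho_w = _ellipsoid_rho(shape, vs, centre, spec.wm_outer_radii)
    ctx_radii = tuple(r + spec.cortex_thickness for r in spec.wm_outer_radii)
    rho_c = _ellipsoid_rho(shape, vs, centre, ctx_radii)

    ventricles = rho_v <= 1.0
    wm = (rho_v > 1.0) & (rho_w <= 1.0)
    cortex_shell = (rho_w > 1.0) & (rho_c <= 1.0)
    zones = _lobe_sectors(shape, centre)
    cortex = np.where(cortex_shell, zones, 0).astype(np.int16)

    bg = np.zeros(shape, dtype=bool)
    thal = np.zeros(shape, dtype=bool)
    it = np.zeros(shape, dtype=bool)
    if spec.include_bgit:
        r = spec.bgit_blob_radius
        # thalami: lateral to the ventricles, touching their surface
        off_t = spec.ventricle_radii[0] + r * 0.7
        # basal ganglia: lateral-anterior blobs
        off_b = spec.ventricle_radii[0] + r * 0.9
        for sign in (-1.0, 1.0):
            tc = (centre[0] + sign * off_t / vs[0], centre[1], centre[2])
            thal |= _ball_mask(shape, vs, tc, r)
            bc = (centre[0] + sign * off_b / vs[0],
                  centre[1] + (spec.ventricle_radii[1] * 0.55) / vs[1],
                  centre[2])
            bg |= _ball_mask(shape, vs, bc, r)
        # infratentorial: blob under the cerebrum
        gap = 2.0 if spec.detached_infratentorial else -1.0
        iz = centre[2] - (ctx_radii[2] + gap + r) / vs[2]
        if iz - r / vs[2] < 0:
            raise ValueError("grid too small for the infratentorial blob")
        it |= _ball_mask(shape, vs, (centre[0], centre[1], iz), r)
        # keep masks inside the head and mutually disjoint; WM excludes
        # the grey-matter BGIT structures
        thal &= ~ventricles
        bg &= ~ventricles & ~thal
        it &= ~ventricles & ~cortex_shell
        wm &= ~(thal | bg | it)

    analytic = None
    if spec.is_spherical:
        r0 = spec.ventricle_radii[0]
        r1 = spec.wm_outer_radii[0]
        rr = rho_v * r0  # rho of a sphere times its radius = physical radius
        d = np.full(shape, np.nan)
        d[wm] = np.clip((rr[wm] - r0) / (r1 - r0), 0.0, 1.0)
        analytic = ScalarField(values=d, domain_mask=wm, voxel_size=vs)

    def vol(arr):
        return LabeledVolume(grid=arr.astype(np.int16), voxel_size=vs)

    return Phantom(
        spec=spec,
        ventricles=vol(ventricles),
        wm=vol(wm),
        cortex_lobes=LabeledVolume(grid=cortex, voxel_size=vs),
        basal_ganglia=vol(bg),
        thalami=vol(thal),
        infratentorial=vol(it),
        analytic_d=analytic,
    )


def plant_lesions(regions, target_fractions, blob_radius=(1.5, 4.0),
                  seed: int | None = None,
                  ) -> tuple[LabeledVolume, np.ndarray]:
    """Grow random spherical lesion blobs until each region hits its target.

    For region r with V_r voxels and target fraction f_r, blobs are added
    until round(f_r * V_r) voxels are lesioned; the last blob is trimmed
    (outermost voxels first) so the achieved count is exact. Regions too
    small for a blob fall back to single random voxels (logged). Returns
    the lesion mask and the achieved fractions — the ground truth.
    """
    targets = np.asarray(target_fractions, dtype=float)
    if np.any((targets < 0) | (targets > 1)):
        raise ValueError("target fractions must lie in [0, 1]")
    if targets.size != regions.n_regions:
        raise ValueError(f"expected {regions.n_regions} targets")
    rng = np.random.default_rng(seed)
    vs = np.asarray(regions.voxel_size)
    lesion = np.zeros(regions.labels.shape, dtype=bool)
    achieved = np.zeros(targets.size)
    counts = regions.region_voxel_counts()
    for r in range(1, targets.size + 1):
        n_vox = int(counts[r - 1])
        if n_vox == 0:
            continue
        want = int(round(targets[r - 1] * n_vox))
        if want == 0:
            continue
        coords = np.argwhere(regions.labels == r)  # (N, 3)
        sel = np.zeros(n_vox, dtype=bool)
        guard = 0
        while sel.sum() < want:
            guard += 1
            if guard > 50 * n_vox:  # pathological region shape
                remaining = np.nonzero(~sel)[0]
                extra = rng.choice(remaining, size=want - int(sel.sum()),
                                   replace=False)
                sel[extra] = True
                log.info("plant_lesions: region %d filled with single voxels", r)
                break
            c_idx = int(rng.integers(0, n_vox))
            if sel[c_idx]:
                continue
            radius = float(rng.uniform(*blob_radius))
            d2 = (((coords - coords[c_idx]) * vs) ** 2).sum(axis=1)
            blob = (d2 <= radius * radius) & ~sel
            new = int(blob.sum())
            if new == 0:
                blob = np.zeros(n_vox, dtype=bool)
                blob[c_idx] = True
                new = 1
            overshoot = int(sel.sum()) + new - want
            if overshoot > 0:
                # trim the blob from its rim inwards for an exact count
                idxs = np.nonzero(blob)[0]
                order = np.argsort(d2[idxs], kind="stable")[::-1]
                blob[idxs[order[:overshoot]]] = False
            sel |= blob
        achieved[r - 1] = sel.sum() / n_vox
        lesion[tuple(coords[sel].T)] = True
    return (LabeledVolume(grid=lesion.astype(np.int16),
                          voxel_size=regions.voxel_size),
            achieved)


#: mean logit-load offsets implementing the cohort profile: highest in the
#: periventricular layer, decaying towards the cortex; frontal-weighted;
#: left-right symmetric; BGIT (esp. infratentorial) relatively spared
DEFAULT_LAYER_OFFSETS = (2.0, 0.3, -0.6, -1.2)
DEFAULT_ZONE_OFFSETS = {
    1: 0.9, 2: 0.9,    # frontal L/R
    3: 0.2, 4: 0.2,    # parietal
    5: 0.0, 6: 0.0,    # occipital
    7: -0.7, 8: -0.7,  # temporal
    9: -1.8,           # BGIT
}


def simulate_cohort(n_subjects: int, seed: int | None = None,
                    base_logit: float = -4.8, subject_sd: float = 1.1,
                    region_sd: float = 0.5, n_layers: int = 4,
                    layer_offsets=DEFAULT_LAYER_OFFSETS,
                    zone_offsets=DEFAULT_ZONE_OFFSETS) -> np.ndarray:
    """Draw per-subject 36-vectors of target load fractions.

    Logit-normal family: logit(f) = base + layer offset + zone offset +
    subject severity + region noise. The default offsets give a
    periventricular-dominant, frontal-weighted, left-right symmetric
    profile with sparing of BGIT.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    n_regions = N_ZONES * n_layers
    mu = np.empty(n_regions)
    for rid in range(1, n_regions + 1):
        zone, layer = region_zone_layer(rid, n_layers)
        mu[rid - 1] = (base_logit + layer_offsets[layer - 1]
                       + zone_offsets[zone])
    severity = rng.normal(0.0, subject_sd, size=(n_subjects, 1))
    noise = rng.normal(0.0, region_sd, size=(n_subjects, n_regions))
    logits = mu[None, :] + severity + noise
    return 1.0 / (1.0 + np.exp(-logits))


@dataclass
class RaterModel:
    """A simulated rater: regional sensitivity weights + noisy thresholds.

    ``weights`` (length 36, non-negative) modulate how strongly each
    region's load influences the rater; ``noise_sd`` is the SD of the
    Gaussian perturbation added to the weighted load before thresholding,
    expressed as a fraction of the cohort raw-score SD. ``thresholds``
    maps each subscale to strictly increasing cutpoints; a raw value
    above k cutpoints scores min + k.
    """

    name: str
    weights: np.ndarray
    noise_sd: float = 0.2
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("rater weights must be non-negative")
        for sid, cuts in self.thresholds.items():
            cuts = np.asarray(cuts, dtype=float)
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"thresholds for {sid!r} not strictly increasing")
            self.thresholds[sid] = cuts


def _raw_scores(load_matrix: np.ndarray, weights: np.ndarray,
                region_ids: tuple[int, ...]) -> np.ndarray:
    idx = np.asarray(region_ids, dtype=int) - 1
    w = weights[idx]
    if w.sum() == 0:
        return np.zeros(load_matrix.shape[0])
    return load_matrix[:, idx] @ (w / w.sum())


def default_thresholds(load_matrix: np.ndarray, scale: ScaleSpec,
                       mapping=None) -> dict[str, np.ndarray]:
    """Cutpoints at evenly spaced quantiles of the cohort raw scores.

    Computed from unweighted (reference) raw scores so that all raters
    built on the same cohort share a common grading anchor.
    """
    mapping = mapping or default_subscale_regions(scale)
    ones = np.ones(load_matrix.shape[1])
    thresholds = {}
    for sub in scale.subscales:
        raw = _raw_scores(load_matrix, ones, mapping[sub.id])
        n_levels = sub.max_score - sub.min_score + 1
        qs = np.linspace(0, 1, n_levels + 1)[1:-1]
        cuts = np.quantile(raw, qs)
        # enforce strict monotonicity even on degenerate distributions
        eps = max(1e-12, 1e-9 * (abs(raw).max() + 1.0))
        cuts = np.maximum.accumulate(cuts)
        cuts += eps * np.arange(len(cuts))
        thresholds[sub.id] = cuts
    return thresholds


def make_rater_models(load_matrix: np.ndarray, scale: ScaleSpec,
                      n_raters: int = 4, noise_sd: float = 0.2,
                      weight_boosts: dict[str, dict[int, float]] | None = None,
                      mapping=None, seed: int | None = None,
                      ) -> list[RaterModel]:
    """Build raters sharing cohort-anchored thresholds.

    ``weight_boosts`` optionally plants biases: rater name -> {region id:
    multiplicative weight}, e.g. doubling frontal juxtacortical weights
    for one rater to emulate over-attention to those regions.
    """
    n_regions = load_matrix.shape[1]
    thresholds = default_thresholds(load_matrix, scale, mapping)
    models = []
    for i in range(n_raters):
        name = f"rater{i + 1}"
        w = np.ones(n_regions)
        for rid, mult in (weight_boosts or {}).get(name, {}).items():
            w[rid - 1] *= mult
        models.append(RaterModel(name=name, weights=w, noise_sd=noise_sd,
                                 thresholds=dict(thresholds)))
    return models


def planted_bias_scenario(n_subjects: int = 200, seed: int | None = None,
                          boosted_regions: tuple[int, ...] = (4, 8),
                          boost: float = 8.0, scale: ScaleSpec | None = None,
                          ):
    """Cohort + raters with one rater's bias planted in known regions.

    One of four raters over-weights the given regions (default: frontal
    juxtacortical, left and right) by ``boost``; the cohort is drawn with
    more independent regional variation (subject_sd 0.6, region_sd 1.0)
    than the default profile, since a regional bias is only identifiable
    when regions vary somewhat independently of overall severity.

    Returns ``(load_matrix, scores, biased_rater_name, boosted_regions)``.
    """
    from .scales import MANOLIO

    scale = scale or MANOLIO
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1)
    lm = simulate_cohort(n_subjects, seed=int(seeds[0]),
                         subject_sd=0.6, region_sd=1.0)
    boosts = {"rater1": {int(r): boost for r in boosted_regions}}
    models = make_rater_models(lm, scale, n_raters=4, noise_sd=0.1,
                               weight_boosts=boosts)
    scores = simulate_raters(lm, models, scale, seed=int(seeds[1]))
    return lm, scores, "rater1", tuple(boosted_regions)


def simulate_raters(load_matrix: np.ndarray, models: list[RaterModel],
                    scale: ScaleSpec, mapping=None,
                    seed: int | None = None,
                    subjects: list | None = None) -> ScoreTable:
    """Score the cohort with each simulated rater.

    score = thresholded(weighted regional load + Gaussian noise), clipped
    to the subscale range. Deterministic for a fixed seed.
    """
    if not models:
        raise ValueError("need at least one rater model")
    n, n_regions = load_matrix.shape
    mapping = mapping or default_subscale_regions(scale)
    subjects = subjects or [f"sub-{i:03d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    rows = []
    for model in models:
        if model.weights.size != n_regions:
            raise ValueError(
                f"rater {model.name}: weight vector length "
                f"{model.weights.size} != {n_regions}")
        for sub in scale.subscales:
            raw = _raw_scores(load_matrix, model.weights, mapping[sub.id])
            cuts = model.thresholds.get(sub.id)
            if cuts is None:
                raise KeyError(f"rater {model.name} lacks thresholds for {sub.id}")
            sd = model.noise_sd * (raw.std() if raw.std() > 0 else 1.0)
            noisy = raw + rng.normal(0.0, sd, size=n)
            score = sub.min_score + (noisy[:, None] > cuts[None, :]).sum(axis=1)
            score = np.clip(score, sub.min_score, sub.max_score)
            for i in range(n):
                rows.append({"subject": subjects[i], "rater": model.name,
                             "subscale": sub.id, "score": float(score[i])})
    return ScoreTable(pd.DataFrame(rows), scale)
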