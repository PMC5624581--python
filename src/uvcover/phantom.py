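"""Synthetic UV-photograph phantoms with known ground truth.

In UV reflectance photography melanin and sunscreen absorb UV, so covered
or pigmented skin renders dark and unprotected skin renders light.  The
phantoms emulate exactly that contrast: a bright elliptical "face" on a
dark background, with seeded random blobs of bright (sunscreen-free) skin
carved out of an otherwise dark (covered) face, optional specular glare
discs and dark pigment/sun-damage discs, ground-truth landmarks, and a
per-pixel truth mask of genuinely missed skin.  Every downstream stage of
the pipeline is therefore testable against exact ground truth, which no
real photograph provides.

Coverage fractions are expressed in the units the scorer reports: missed
pixels divided by the pixels of the region rectangle (for rest-of-face,
the face box minus the letterbox).  A cohort generator draws per-person
application skill from a rank-correlated log-normal model, adds a
second-visit improvement that is largest for the poorest initial
performers, and emits two phantom bundles per participant together with a
metadata table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import GeometryConfig, LandmarkSet, RegionSet, derive_regions

__all__ = [
    "PhantomSpec",
    "CoverageScenario",
    "SyntheticBundle",
    "CohortModel",
    "CoverageTargetError",
    "generate_phantom",
    "apply_coverage",
    "add_artifacts",
    "draw_cohort_fractions",
    "generate_cohort",
]

# Fitzpatrick phototype -> base UV skin intensity: six evenly spaced bands in
# [120, 230], darker for higher (more melanised) types.
SKIN_TYPE_INTENSITY = {t: 230 - 22 * (t - 1) for t in range(1, 7)}

DEFAULT_LANDMARK_LAYOUT: dict[str, tuple[float, float]] = {
    # fractions (fx, fy) of the face-ellipse bounding box, x rightward, y downward
    "left_outer_eye": (0.22, 0.38),
    "left_inner_eye": (0.40, 0.38),
    "right_inner_eye": (0.60, 0.38),
    "right_outer_eye": (0.78, 0.38),
    "left_brow": (0.30, 0.30),
    "right_brow": (0.70, 0.30),
    "nose_bridge": (0.50, 0.40),
    "nose_tip": (0.50, 0.58),
    "chin": (0.50, 0.97),
    "left_face": (0.02, 0.50),
    "right_face": (0.98, 0.50),
}


class CoverageTargetError(RuntimeError):
    """A requested coverage fraction is unreachable with the blob model."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and photometry of one synthetic UV face.

    The face is an ellipse of semi-axes ``face_axes`` centred at
    ``face_center`` (x, y); it must lie fully inside the image.  Uncovered
    skin renders at ``skin_intensity`` (derived from the Fitzpatrick
    ``skin_type`` band when not given explicitly) over a dark background.
    ``noise_sd`` adds seeded Gaussian sensor noise to the whole frame.
    """

    image_width: int = 256
    image_height: int = 320
    face_center: tuple[float, float] = (128.0, 160.0)
    face_axes: tuple[float, float] = (92.0, 120.0)
    skin_type: int = 2
    skin_intensity: int | None = None
    background_intensity: int = 20
    noise_sd: float = 2.0
    landmark_layout: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LANDMARK_LAYOUT)
    )

    def __post_init__(self):
        if self.skin_type not in SKIN_TYPE_INTENSITY:
            raise ValueError("skin_type must be a Fitzpatrick class 1-6")
        cx, cy = self.face_center
        a, b = self.face_axes
        if a <= 0 or b <= 0:
            raise ValueError("face axes must be positive")
        if not (cx - a >= 0 and cx + a < self.image_width
                and cy - b >= 0 and cy + b < self.image_height):
            raise ValueError("face ellipse exceeds image bounds")
        if not (0 <= self.background_intensity <= 255):
            raise ValueError("background_intensity outside [0, 255]")
        for name, (fx, fy) in self.landmark_layout.items():
            if not (0.0 <= fx <= 1.0 and 0.0 <= fy <= 1.0):
                raise ValueError(f"landmark layout fraction for {name} outside [0,1]")
        if self.effective_skin_intensity > 255 or self.effective_skin_intensity < 0:
            raise ValueError("skin intensity outside [0, 255]")

    @property
    def effective_skin_intensity(self) -> int:
        if self.skin_intensity is not None:
            return int(self.skin_intensity)
        return SKIN_TYPE_INTENSITY[self.skin_type]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height, self.image_width)

    def face_mask(self) -> np.ndarray:
        """Boolean raster of the face ellipse (per-pixel centre inequality)."""
        cx, cy = self.face_center
        a, b = self.face_axes
        y, x = np.ogrid[: self.image_height, : self.image_width]
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0

    def landmarks(self) -> LandmarkSet:
        cx, cy = self.face_center
        a, b = self.face_axes
        pts = {
            name: (
                round(cx - a + fx * 2 * a),
                round(cy - b + fy * 2 * b),
            )
            for name, (fx, fy) in self.landmark_layout.items()
        }
        return LandmarkSet(pts, image_shape=self.shape)

    def eye_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Rasters of the two eye ellipses implied by the eye-corner landmarks."""
        lm = self.landmarks()
        out = []
        for inner, outer in (
            ("left_inner_eye", "left_outer_eye"),
            ("right_inner_eye", "right_outer_eye"),
        ):
            (ix, iy), (ox, oy) = lm[inner], lm[outer]
            cx, cy = (ix + ox) / 2.0, (iy + oy) / 2.0
            ax = abs(ox - ix) / 2.0
            ay = max(1.0, 0.4 * ax)
            y, x = np.ogrid[: self.image_height, : self.image_width]
            out.append(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0)
        return out[0], out[1]


@dataclass(frozen=True)
class CoverageScenario:
    """How sunscreen, glare and damage are laid onto a phantom.

    ``applied_fraction`` maps region name (``letterbox``, ``rest``,
    ``canthus_left``, ``canthus_right``) to the fraction of that region to
    be covered, in the units of the reported region percentage; missing
    regions are left untouched (fraction 0).  Missed patches are the union
    of seeded random discs with radii in ``[blob_radius_min,
    blob_radius_max]``; the achieved fraction lands within ``tolerance`` of
    target.  Glare discs are bright (specular reflection, never missed
    skin); damage discs are dark (deep pigmentation, never sunscreen).
    """

    applied_fraction: Mapping[str, float] = field(default_factory=dict)
    sunscreen_intensity: int = 70
    blob_radius_min: int = 3
    blob_radius_max: int = 14
    tolerance: float = 0.005
    glare_count: int = 0
    glare_radius: tuple[int, int] = (2, 5)
    glare_intensity: int = 245
    damage_count: int = 0
    damage_radius: tuple[int, int] = (1, 3)
    damage_intensity: int = 45

    def __post_init__(self):
        for name, frac in self.applied_fraction.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"applied fraction for {name} outside [0,1]: {frac}")
        if not (0 <= self.sunscreen_intensity <= 255):
            raise ValueError("sunscreen_intensity outside [0, 255]")
        if self.blob_radius_min < 1 or self.blob_radius_max < self.blob_radius_min:
            raise ValueError("invalid blob radius range")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class SyntheticBundle:
    """One phantom: image, truth mask, landmarks and provenance.

    ``truth_mask`` is True exactly where skin is genuinely missed; it is
    False everywhere outside the face ellipse.
    """

    image: np.ndarray
    truth_mask: np.ndarray
    landmarks: LandmarkSet
    spec: PhantomSpec
    scenario: CoverageScenario | None
    metadata: dict

    def __post_init__(self):
        if self.image.shape != self.truth_mask.shape:
            raise ValueError("image and truth mask dimensions differ")

    def copy(self) -> "SyntheticBundle":
        return SyntheticBundle(
            self.image.copy(),
            self.truth_mask.copy(),
            self.landmarks,
            self.spec,
            self.scenario,
            dict(self.metadata),
        )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> SyntheticBundle:
    """Render an uncovered face: skin ellipse over background, no sunscreen.

    The truth mask is the whole face ellipse (everything missed).  Noise is
    seeded, so the same spec and seed reproduce the image byte for byte.
    """
    rng = _rng(seed)
    face = spec.face_mask()
    img = np.full(spec.shape, float(spec.background_intensity))
    img[face] = float(spec.effective_skin_intensity)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return SyntheticBundle(
        image=img,
        truth_mask=face,
        landmarks=spec.landmarks(),
        spec=spec,
        scenario=None,
        metadata={"seed": int(seed)},
    )


def _disc_window(shape, cx: int, cy: int, r: int) -> tuple[slice, slice, np.ndarray]:
    """Local window and boolean disc raster centred on (cx, cy)."""
    h, w = shape
    y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
    x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
    y, x = np.ogrid[y0:y1, x0:x1]
    disc = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
    return slice(y0, y1), slice(x0, x1), disc


def _carve_missed(
    covered: np.ndarray,
    carvable: np.ndarray,
    metric_mask: np.ndarray,
    denom: int,
    target_missed: float,
    tol: float,
    rmin: int,
    rmax: int,
    rng: np.random.Generator,
    max_iter: int = 2000,
) -> None:
    """Uncover random discs inside ``carvable`` until the missed fraction
    (uncovered metric pixels / denom) is within ``tol`` of target.

    Mutates ``covered`` in place.  The disc radius tracks the remaining
    deficit so the loop converges without overshooting beyond ``tol``.
    """
    missed = int(np.count_nonzero(metric_mask & ~covered))
    for _ in range(max_iter):
        deficit = target_missed * denom - missed
        if deficit <= tol * denom:
            return
        r = int(np.clip(round(math.sqrt(deficit / math.pi)), rmin, rmax))
        candidates = np.flatnonzero(carvable & covered)
        if candidates.size == 0:
            raise CoverageTargetError(
                f"missed target {target_missed:.3f} unreachable: no carvable pixels left"
            )
        idx = int(rng.choice(candidates))
        cy, cx = divmod(idx, covered.shape[1])
        ys, xs, disc = _disc_window(covered.shape, cx, cy, r)
        newly = disc & carvable[ys, xs] & covered[ys, xs]
        covered[ys, xs] &= ~newly
        missed += int(np.count_nonzero(newly & metric_mask[ys, xs]))
    raise CoverageTargetError(
        f"missed target {target_missed:.3f} not reached in {max_iter} blobs"
    )


def region_masks(
    spec: PhantomSpec, regions: RegionSet
) -> dict[str, np.ndarray]:
    """Skin masks of the analysis regions plus the out-of-crop remainder."""
    skin = spec.face_mask()
    in_face = regions.face_box.mask(spec.shape)
    in_lb = regions.eyelid_letterbox.mask(spec.shape)
    cl = regions.canthus_left.mask(spec.shape)
    cr = regions.canthus_right.mask(spec.shape)
    return {
        "skin": skin,
        "letterbox": skin & in_lb,
        "rest": skin & in_face & ~in_lb,
        "canthus_left": skin & cl,
        "canthus_right": skin & cr,
        "outer": skin & ~in_face,
    }


def _truth_percentages(
    truth: np.ndarray, regions: RegionSet
) -> dict[str, float]:
    face, lb = regions.face_box, regions.eyelid_letterbox
    in_face = face.mask(truth.shape)
    in_lb = lb.mask(truth.shape)
    rest_denom = face.area - lb.area
    return {
        "truth_pct_face": 100.0 * np.count_nonzero(truth & in_face) / face.area,
        "truth_pct_letterbox": 100.0 * np.count_nonzero(truth & in_lb) / lb.area,
        "truth_pct_rest": 100.0 * np.count_nonzero(truth & in_face & ~in_lb) / rest_denom,
        "truth_canthus_missed_left": float(
            np.count_nonzero(truth & regions.canthus_left.mask(truth.shape)) > 0
        ),
        "truth_canthus_missed_right": float(
            np.count_nonzero(truth & regions.canthus_right.mask(truth.shape)) > 0
        ),
    }


def apply_coverage(
    bundle: SyntheticBundle,
    scenario: CoverageScenario,
    seed: int = 0,
    geometry: GeometryConfig | None = None,
) -> SyntheticBundle:
    """Darken sunscreen onto a phantom to hit per-region coverage targets.

    Canthal boxes are set first (fully covered, or a missed blob carved
    into them), then the letterbox and rest-of-face are brought to their
    targets by carving random missed discs out of full coverage; carving
    never crosses region boundaries so the targets are independent.  The
    truth mask becomes exactly the un-darkened face pixels and the achieved
    fractions are recorded in the metadata.
    """
    rng = _rng(seed)
    spec = bundle.spec
    out = bundle.copy()
    regions = derive_regions(bundle.landmarks, spec.shape, geometry)
    masks = region_masks(spec, regions)
    fractions = dict(scenario.applied_fraction)
    covered = np.zeros(spec.shape, dtype=bool)
    canthus_any = masks["canthus_left"] | masks["canthus_right"]

    for name in ("canthus_left", "canthus_right"):
        a = fractions.get(name, 0.0)
        region_skin = masks[name]
        box = regions.canthus_left if name == "canthus_left" else regions.canthus_right
        if a <= 0.0:
            continue
        covered |= region_skin
        if a < 1.0:
            _carve_missed(
                covered, region_skin, region_skin, box.area, 1.0 - a,
                max(scenario.tolerance, 2.0 / box.area), 2, scenario.blob_radius_max,
                rng,
            )

    # Letterbox: the metric counts the whole letterbox rectangle including the
    # canthal boxes, but carving must not disturb the canthus state.  A 2-px
    # guard band keeps carved blobs from abutting the canthal boxes, so the
    # binary canthal ground truth stays unambiguous under the scorer's blur.
    a_lb = fractions.get("letterbox", 0.0)
    lb_skin = masks["letterbox"]
    guard = np.zeros(spec.shape, dtype=bool)
    for box in (regions.canthus_left, regions.canthus_right):
        guard[max(box.y0 - 2, 0):box.y1 + 2, max(box.x0 - 2, 0):box.x1 + 2] = True
    lb_paintable = lb_skin & ~canthus_any
    lb_carvable = lb_skin & ~guard
    if a_lb > 0.0:
        covered |= lb_paintable
        if a_lb < 1.0:
            target = 1.0 - a_lb
            denom = regions.eyelid_letterbox.area
            already = np.count_nonzero(lb_skin & ~covered)
            if already < (target - scenario.tolerance) * denom:
                _carve_missed(
                    covered, lb_carvable, lb_skin, denom, target,
                    scenario.tolerance, scenario.blob_radius_min,
                    scenario.blob_radius_max, rng,
                )

    # Rest of face: metric region is face box minus letterbox; skin outside the
    # face crop is covered alongside (it contributes to no reported metric).
    a_rest = fractions.get("rest", 0.0)
    rest_skin = masks["rest"]
    if a_rest > 0.0:
        covered |= rest_skin | masks["outer"]
        if a_rest < 1.0:
            denom = regions.face_box.area - regions.eyelid_letterbox.area
            _carve_missed(
                covered, rest_skin, rest_skin, denom, 1.0 - a_rest,
                scenario.tolerance, scenario.blob_radius_min,
                scenario.blob_radius_max, rng,
            )

    if scenario.sunscreen_intensity >= spec.effective_skin_intensity:
        raise ValueError("sunscreen must render darker than uncovered skin")

    shade = np.full(int(covered.sum()), float(scenario.sunscreen_intensity))
    if spec.noise_sd > 0:
        shade += rng.normal(0.0, spec.noise_sd, size=shade.shape)
    img = out.image.astype(np.float64)
    img[covered] = shade
    out.image = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    out.truth_mask = masks["skin"] & ~covered
    out.scenario = scenario
    out.metadata.update(_truth_percentages(out.truth_mask, regions))
    out.metadata["coverage_seed"] = int(seed)
    return out


def add_artifacts(
    bundle: SyntheticBundle, scenario: CoverageScenario, seed: int = 0
) -> SyntheticBundle:
    """Overlay specular glare and pigment/damage discs onto a phantom.

    Glare is bright but is not missed skin; damage is dark but is not
    sunscreen: the truth mask is untouched either way.  Disc positions are
    seeded and logged in the metadata.
    """
    rng = _rng(seed)
    out = bundle.copy()
    skin = out.spec.face_mask()
    skin_idx = np.flatnonzero(skin)
    log: list[tuple[str, int, int, int]] = []
    for kind, count, radii, intensity in (
        ("glare", scenario.glare_count, scenario.glare_radius, scenario.glare_intensity),
        ("damage", scenario.damage_count, scenario.damage_radius, scenario.damage_intensity),
    ):
        for _ in range(count):
            idx = int(rng.choice(skin_idx))
            cy, cx = divmod(idx, out.image.shape[1])
            r = int(rng.integers(radii[0], radii[1] + 1))
            ys, xs, disc = _disc_window(out.image.shape, cx, cy, r)
            patch = disc & skin[ys, xs]
            out.image[ys, xs] = np.where(patch, intensity, out.image[ys, xs])
            log.append((kind, cx, cy, r))
    out.metadata["artifacts"] = log
    return out


@dataclass(frozen=True)
class CohortModel:
    """Distributional model of a two-visit sunscreen-application cohort.

    Per-person application skill is a shared latent: missed fractions for
    the eyelid letterbox and the rest of the face are log-normal with the
    configured medians and log-scale spread, rank-correlated through a
    Gaussian copula at ``skill_correlation`` (Spearman).  The second visit
    shrinks each person's missed fraction by a factor proportional to their
    first-visit miss — the poorest performers improve most.  Medial-canthus
    failure is a per-visit Bernoulli with a person-level latent correlation
    across visits.
    """

    n_participants: int = 57
    letterbox_median: float = 0.14
    rest_median: float = 0.07
    log_sd: float = 0.35
    skill_correlation: float = 0.84
    visit2_improvement_letterbox: float = 0.30
    visit2_improvement_rest: float = 0.15
    improvement_noise: float = 0.25
    canthus_miss_probability: tuple[float, float] = (44 / 57, 37 / 57)
    canthus_latent_correlation: float = 0.5
    male_fraction: float = 27 / 57
    light_skin_fraction: float = 42 / 57
    spray_fraction: float = 0.5
    letterbox_max: float = 0.60
    rest_max: float = 0.45
    canthus_missed_applied_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for name in ("letterbox_median", "rest_median", "male_fraction",
                     "light_skin_fraction", "spray_fraction",
                     "visit2_improvement_letterbox", "visit2_improvement_rest"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {v}")
        for p in self.canthus_miss_probability:
            if not (0.0 <= p <= 1.0):
                raise ValueError("canthus miss probabilities must be in [0,1]")
        if not (-1.0 < self.skill_correlation < 1.0):
            raise ValueError("skill_correlation must be in (-1, 1)")


def _copula_rho(spearman: float) -> float:
    """Bivariate-normal Pearson rho producing the requested Spearman rho."""
    return 2.0 * math.sin(math.pi * spearman / 6.0)


def draw_cohort_fractions(
    model: CohortModel, seed: int | None = None
) -> pd.DataFrame:
    """Draw the ground-truth cohort table without rendering any images.

    One row per participant-visit with demographics and the target missed
    fractions (reported-percentage units) for the letterbox and rest
    regions, plus the canthus miss indicator.
    """
    rng = _rng(model.seed if seed is None else seed)
    n = model.n_participants

    rho = _copula_rho(model.skill_correlation)
    z_rest = rng.standard_normal(n)
    z_lb = rho * z_rest + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    m_rest1 = np.clip(model.rest_median * np.exp(model.log_sd * z_rest), 0.0, model.rest_max)
    m_lb1 = np.clip(
        model.letterbox_median * np.exp(model.log_sd * z_lb), 0.0, model.letterbox_max
    )

    def _shrunk(m1: np.ndarray, improvement: float, median: float) -> np.ndarray:
        if improvement == 0.0:
            return m1.copy()
        noise = np.exp(
            model.improvement_noise * rng.standard_normal(n)
            - 0.5 * model.improvement_noise**2
        )
        r = np.clip(improvement * (m1 / median) * noise, 0.0, 0.9)
        return m1 * (1.0 - r)

    m_lb2 = _shrunk(m_lb1, model.visit2_improvement_letterbox, model.letterbox_median)
    m_rest2 = _shrunk(m_rest1, model.visit2_improvement_rest, model.rest_median)

    p1, p2 = model.canthus_miss_probability
    u1 = rng.uniform(size=n)
    rc = model.canthus_latent_correlation
    from scipy.stats import norm

    z1 = norm.ppf(np.clip(u1, 1e-12, 1 - 1e-12))
    u2 = norm.cdf(rc * z1 + math.sqrt(1 - rc * rc) * rng.standard_normal(n))
    canthus1 = u1 < p1
    canthus2 = u2 < p2

    n_male = int(round(model.male_fraction * n))
    gender = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(gender)
    n_light = int(round(model.light_skin_fraction * n))
    skin = np.concatenate(
        [rng.integers(1, 3, size=n_light), rng.integers(3, 5, size=n - n_light)]
    )
    rng.shuffle(skin)
    formulation = np.where(rng.uniform(size=n) < model.spray_fraction, "spray", "cream")

    rows = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        for visit, m_lb, m_rest, cmiss in (
            (1, m_lb1[i], m_rest1[i], canthus1[i]),
            (2, m_lb2[i], m_rest2[i], canthus2[i]),
        ):
            rows.append(
                {
                    "participant_id": pid,
                    "visit": visit,
                    "gender": gender[i],
                    "skin_type": int(skin[i]),
                    "formulation": formulation[i],
                    "target_missed_letterbox": float(m_lb),
                    "target_missed_rest": float(m_rest),
                    "canthus_missed": bool(cmiss),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    model: CohortModel,
    spec: PhantomSpec | None = None,
    seed: int | None = None,
    with_artifacts: bool = False,
    geometry: GeometryConfig | None = None,
) -> tuple[list[SyntheticBundle], pd.DataFrame]:
    """Render the full two-visit phantom cohort.

    Returns one bundle per participant-visit plus the cohort table holding
    demographics, the drawn targets and the achieved ground-truth missed
    percentages of every rendered image.
    """
    if spec is None:
        spec = PhantomSpec()
    base_seed = model.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    draw_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    table = draw_cohort_fractions(model, seed=draw_seed)

    person_rng = _rng(int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)))
    jitter = {}
    for pid in table["participant_id"].unique():
        jitter[pid] = (
            person_rng.uniform(0.93, 1.05),
            person_rng.uniform(-4.0, 4.0),
            person_rng.uniform(-4.0, 4.0),
        )

    bundles: list[SyntheticBundle] = []
    achieved_rows = []
    child_seeds = ss.spawn(len(table))
    for (_, row), child in zip(table.iterrows(), child_seeds):
        pid = row["participant_id"]
        sfac, dx, dy = jitter[pid]
        spec_i = replace(
            spec,
            skin_type=int(row["skin_type"]),
            skin_intensity=None,
            face_center=(spec.face_center[0] + dx, spec.face_center[1] + dy),
            face_axes=(spec.face_axes[0] * sfac, spec.face_axes[1] * sfac),
        )
        seeds = [int(s % (2**31)) for s in child.generate_state(3)]
        bundle = generate_phantom(spec_i, seeds[0])
        canthus_a = (
            model.canthus_missed_applied_fraction if row["canthus_missed"] else 1.0
        )
        scenario = CoverageScenario(
            applied_fraction={
                "letterbox": 1.0 - row["target_missed_letterbox"],
                "rest": 1.0 - row["target_missed_rest"],
                "canthus_left": canthus_a,
                "canthus_right": canthus_a,
            },
            glare_count=3 if with_artifacts else 0,
            damage_count=4 if with_artifacts else 0,
        )
        bundle = apply_coverage(bundle, scenario, seeds[1], geometry)
        if with_artifacts:
            bundle = add_artifacts(bundle, scenario, seeds[2])
        bundle.metadata.update(
            participant_id=pid,
            visit=int(row["visit"]),
            gender=row["gender"],
            skin_type=int(row["skin_type"]),
            formulation=row["formulation"],
            image_id=f"{pid}_v{int(row['visit'])}",
        )
        bundles.append(bundle)
        achieved_rows.append(
            {
                k: bundle.metadata[k]
                for k in (
                    "truth_pct_face",
                    "truth_pct_letterbox",
                    "truth_pct_rest",
                    "truth_canthus_missed_left",
                    "truth_canthus_missed_right",
                )
            }
        )
    table = pd.concat([table.reset_index(drop=True), pd.DataFrame(achieved_rows)], axis=1)
    table.insert(0, "image_id", [b.metadata["image_id"] for b in bundles])
    return bundles, table
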