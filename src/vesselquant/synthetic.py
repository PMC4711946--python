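"""Synthetic trichrome-like vessel images with known ground truth.

The study's stained-vein image database is not publicly available, so this
module renders annular vessel-wall images that emulate its key features: a
near-white background and lumen, a wall textured in two color families
(reddish smooth-muscle fiber vs blue/green extracellular matrix), dark
tissue folds, blood-colored blobs and small dust specks.  Every image comes
with exact ground-truth masks, which makes the whole pipeline testable by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm
from skimage.color import lab2rgb
from skimage.draw import disk, line

# default palettes: red-family SMF vs blue/green ECM, as trichrome renders them
SMF_COLOR = (55.0, 35.0, 15.0)
ECM_COLOR = (60.0, -20.0, -15.0)
BLOOD_COLOR = (35.0, 45.0, 25.0)
FOLD_COLOR = (8.0, 2.0, 2.0)
DUST_COLOR = (50.0, 5.0, 5.0)
BACKGROUND_L = 96.0


@dataclass(frozen=True)
class VesselSpec:
    """Parameters of one synthetic vessel-wall image.

    Defaults give a 160×160 image with a wall annulus of inner radius 28 and
    outer radius 60 px, per-channel Lab color noise of sd 3, two fold
    streaks, three blood blobs and fifteen dust specks.
    """

    height: int = 160
    width: int = 160
    center: tuple[float, float] | None = None  # (row, col); image center if None
    r_inner: float = 28.0
    r_outer: float = 60.0
    smf_fraction: float = 0.5
    smf_color: tuple[float, float, float] = SMF_COLOR
    ecm_color: tuple[float, float, float] = ECM_COLOR
    blood_color: tuple[float, float, float] = BLOOD_COLOR
    color_noise_sd: float = 3.0
    blotch_sigma: float = 6.0
    n_folds: int = 2
    n_blood: int = 3
    n_dust: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_inner < self.r_outer:
            raise ValueError("need 0 < r_inner < r_outer")
        if not 0.0 <= self.smf_fraction <= 1.0:
            raise ValueError("smf_fraction must lie in [0, 1]")
        if self.color_noise_sd < 0:
            raise ValueError("color_noise_sd must be non-negative")
        cy, cx = self.effective_center
        margin = self.r_outer + 2  # folds extend slightly past the wall
        if (cy - margin < 0 or cx - margin < 0
                or cy + margin >= self.height or cx + margin >= self.width):
            raise ValueError("wall radii exceed the image bounds")

    @property
    def effective_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-pixel truth for one generated image."""

    wall_mask: np.ndarray
    smf_mask: np.ndarray
    ecm_mask: np.ndarray
    fold_mask: np.ndarray
    blood_mask: np.ndarray
    dust_mask: np.ndarray
    true_smf_fraction: float


def _thick_line(shape, p0, p1, mask_out):
    """Rasterize a 2-px-wide segment into mask_out (in place)."""
    rr, cc = line(int(round(p0[0])), int(round(p0[1])),
                  int(round(p1[0])), int(round(p1[1])))
    for dr, dc in ((0, 0), (0, 1)):
        r = np.clip(rr + dr, 0, shape[0] - 1)
        c = np.clip(cc + dc, 0, shape[1] - 1)
        mask_out[r, c] = True


def generate_vessel_image(spec: VesselSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic stained-vessel image plus its ground truth.

    The wall annulus is split into SMF and ECM by thresholding a smoothed
    random field at the quantile matching ``smf_fraction``, so components
    form connected blotches rather than salt-and-pepper, and the realized
    fraction is within ±0.01 of the request.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    cy, cx = spec.effective_center
    yy, xx = np.mgrid[0:H, 0:W]
    dist = np.hypot(yy - cy, xx - cx)
    wall = (dist >= spec.r_inner) & (dist <= spec.r_outer)

    lab = np.empty((H, W, 3), dtype=float)
    lab[..., 0] = BACKGROUND_L
    lab[..., 1] = 0.0
    lab[..., 2] = 0.0

    # blotchy SMF / ECM split of the wall at the matching field quantile
    blotch = ndimage.gaussian_filter(rng.standard_normal((H, W)), spec.blotch_sigma)
    if spec.smf_fraction == 0.0:
        smf = np.zeros((H, W), dtype=bool)
    elif spec.smf_fraction == 1.0:
        smf = wall.copy()
    else:
        thr = np.quantile(blotch[wall], 1.0 - spec.smf_fraction)
        smf = wall & (blotch >= thr)
    ecm = wall & ~smf
    lab[smf] = spec.smf_color
    lab[ecm] = spec.ecm_color

    # dark fold streaks crossing the wall radially
    fold_mask = np.zeros((H, W), dtype=bool)
    for _ in range(spec.n_folds):
        ang = rng.uniform(0, 2 * np.pi)
        jit = ang + rng.uniform(-0.15, 0.15)
        p0 = (cy + (spec.r_inner - 3) * np.sin(ang), cx + (spec.r_inner - 3) * np.cos(ang))
        p1 = (cy + (spec.r_outer + 2) * np.sin(jit), cx + (spec.r_outer + 2) * np.cos(jit))
        _thick_line((H, W), p0, p1, fold_mask)
    lab[fold_mask] = FOLD_COLOR

    # blood-colored blobs inside the vessel (wall or lumen)
    blood_mask = np.zeros((H, W), dtype=bool)
    for _ in range(spec.n_blood):
        r = rng.uniform(3, 6)
        rad = rng.uniform(0, spec.r_outer - r - 1)
        ang = rng.uniform(0, 2 * np.pi)
        rr, cc = disk((cy + rad * np.sin(ang), cx + rad * np.cos(ang)), r, shape=(H, W))
        blood_mask[rr, cc] = True
    blood_mask &= ~fold_mask
    lab[blood_mask] = spec.blood_color

    # 1–5 px dust specks in the lumen and outside the vessel
    dust_mask = np.zeros((H, W), dtype=bool)
    placed = 0
    while placed < spec.n_dust:
        y = rng.integers(0, H)
        x = rng.integers(0, W)
        d = np.hypot(y - cy, x - cx)
        if spec.r_inner - 4 <= d <= spec.r_outer + 4:
            continue
        size = int(rng.integers(1, 6))
        py, px = y, x
        for _ in range(size):
            dust_mask[py, px] = True
            step = rng.integers(0, 4)
            py = int(np.clip(py + (step == 0) - (step == 1), 0, H - 1))
            px = int(np.clip(px + (step == 2) - (step == 3), 0, W - 1))
        placed += 1
    dust_mask &= ~(fold_mask | blood_mask)
    lab[dust_mask] = DUST_COLOR

    if spec.color_noise_sd > 0:
        lab += rng.normal(0.0, spec.color_noise_sd, size=lab.shape)
        lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)

    rgb = np.rint(lab2rgb(lab) * 255).astype(np.uint8)

    defects = fold_mask | blood_mask | dust_mask
    smf_clean = smf & ~defects
    ecm_clean = ecm & ~defects
    n_tissue = int(smf_clean.sum() + ecm_clean.sum())
    true_frac = float(smf_clean.sum() / n_tissue) if n_tissue else float("nan")
    truth = GroundTruth(
        wall_mask=wall,
        smf_mask=smf_clean,
        ecm_mask=ecm_clean,
        fold_mask=fold_mask,
        blood_mask=blood_mask,
        dust_mask=dust_mask,
        true_smf_fraction=true_frac,
    )
    return rgb, truth


def generate_group_samples(
    n_per_group: dict[str, int],
    group_means: dict[str, tuple[float, float]],
    sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-sample (ratio_SMF, ratio_ECM) tables for several vein groups.

    Ratios are truncated-normal draws on [0, 1] around each group's mean
    pair — a lightweight stand-in for running the imaging pipeline on a
    whole cohort, used to exercise the group-comparison statistics.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"group {group!r} must have at least one sample")
        mean_smf, mean_ecm = group_means[group]
        for name, mu in (("ratio_SMF", mean_smf), ("ratio_ECM", mean_ecm)):
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"{name} mean for group {group!r} must lie in [0,1]")
        for i in range(n):
            if sd == 0:
                smf_v, ecm_v = mean_smf, mean_ecm
            else:
                smf_v = float(
                    truncnorm.rvs((0 - mean_smf) / sd, (1 - mean_smf) / sd,
                                  loc=mean_smf, scale=sd, random_state=rng)
                )
                ecm_v = float(
                    truncnorm.rvs((0 - mean_ecm) / sd, (1 - mean_ecm) / sd,
                                  loc=mean_ecm, scale=sd, random_state=rng)
                )
            rows.append(
                {"sample_id": f"{group}_{i:03d}", "group": group,
                 "ratio_SMF": smf_v, "ratio_ECM": ecm_v}
            )
    return pd.DataFrame(rows)
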