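"""Feature-extraction stage: color clustering and area quantification.

Wall pixels (over a white background) are grouped by k-means in CIELab into
k=3 color classes — smooth-muscle fiber (SMF), extracellular matrix (ECM)
and background.  Component areas are pixel counts inside the wall,
normalized by the wall area A_TOT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .config import KmeansConfig
from .preprocess import WallRegion

logger = logging.getLogger(__name__)

WHITE = np.array([100.0, 0.0, 0.0])  # white in L*a*b*

SMF = "SMF"
ECM = "ECM"
BACKGROUND = "background"


@dataclass(frozen=True)
class ClusterModel:
    """Result of k-means color clustering.

    ``assignment`` holds a 0-based cluster index per pixel (flattened,
    row-major).  ``J`` is the clustering cost: the total Euclidean L*a*b*
    distance of every pixel to its group centroid.  ``j_history`` records J
    at each Lloyd iteration of the winning restart.
    """

    k: int
    centroids: np.ndarray          # k×3 L*a*b* triples
    assignment: np.ndarray         # (n_pixels,) int in [0, k)
    J: float
    n_j: np.ndarray                # per-group pixel counts
    j_history: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if int(self.n_j.sum()) != self.assignment.size:
            raise ValueError("group counts must sum to the number of pixels")


class TooFewColorsError(ValueError):
    """Raised when the image has fewer distinct colors than clusters."""


def mask_to_white(lab: np.ndarray, wall: WallRegion) -> np.ndarray:
    """Set every pixel outside the wall mask to white (L*=100, a*=b*=0)."""
    lab = np.asarray(lab, dtype=float)
    if lab.shape[:2] != wall.mask.shape:
        raise ValueError(
            f"image shape {lab.shape[:2]} != wall mask shape {wall.mask.shape}"
        )
    out = lab.copy()
    out[~wall.mask] = WHITE
    return out


def lab_distance(p1, p2) -> float:
    """Euclidean distance between two L*a*b* colors (the similarity metric)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.sqrt(((p1 - p2) ** 2).sum()))


def _cost(pixels: np.ndarray, centroids: np.ndarray, assignment: np.ndarray) -> float:
    diffs = pixels - centroids[assignment]
    return float(np.sqrt((diffs**2).sum(axis=1)).sum())


def _lloyd(
    pixels: np.ndarray, init: np.ndarray, cfg: KmeansConfig
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One Lloyd run from the given initial centroids."""
    centroids = init.copy()
    history: list[float] = []
    prev_j = None
    for _ in range(cfg.max_iter):
        d = cdist(pixels, centroids)
        assignment = d.argmin(axis=1)
        # rescue emptied groups: re-seed at the pixel farthest from its centroid
        for _ in range(cfg.k):
            counts = np.bincount(assignment, minlength=cfg.k)
            empty = np.flatnonzero(counts == 0)
            if empty.size == 0:
                break
            per_pixel = d[np.arange(len(pixels)), assignment]
            far = int(per_pixel.argmax())
            centroids[empty[0]] = pixels[far]
            d = cdist(pixels, centroids)
            assignment = d.argmin(axis=1)
        j = float(d[np.arange(len(pixels)), assignment].sum())
        history.append(j)
        if prev_j is not None and abs(prev_j - j) <= cfg.tol * prev_j:
            break
        prev_j = j
        for g in range(cfg.k):
            centroids[g] = pixels[assignment == g].mean(axis=0)
    # final assignment so the nearest-centroid condition holds at return
    d = cdist(pixels, centroids)
    assignment = d.argmin(axis=1)
    j = float(d[np.arange(len(pixels)), assignment].sum())
    return centroids, assignment, j, history


def kmeans_lab(pixels: np.ndarray, cfg: KmeansConfig | None = None) -> ClusterModel:
    """Cluster L*a*b* pixels by color with best-of-restarts k-means.

    Each restart initializes the k centroids at distinct pixel colors drawn
    at random, runs Lloyd iterations until the relative change in the cost J
    falls below ``cfg.tol`` (or ``max_iter``), and the restart with the
    lowest final J wins.  Fully reproducible given ``cfg.seed``.
    """
    cfg = cfg or KmeansConfig()
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    unique = np.unique(pixels, axis=0)
    if len(unique) < cfg.k:
        raise TooFewColorsError(
            f"need at least {cfg.k} distinct colors, found {len(unique)}"
        )
    rng = np.random.default_rng(cfg.seed)
    best = None
    for _ in range(cfg.n_restarts):
        idx = rng.choice(len(unique), size=cfg.k, replace=False)
        centroids, assignment, j, history = _lloyd(pixels, unique[idx], cfg)
        if best is None or j < best[2]:
            best = (centroids, assignment, j, history)
    centroids, assignment, j, history = best
    return ClusterModel(
        k=cfg.k,
        centroids=centroids,
        assignment=assignment,
        J=j,
        n_j=np.bincount(assignment, minlength=cfg.k),
        j_history=tuple(history),
    )


def assign_roles(model: ClusterModel) -> dict[str, int]:
    """Map the k=3 clusters to {background, SMF, ECM}.

    The background is the cluster whose centroid is closest to white; of
    the two tissue clusters, SMF is the one with the larger a* (redder)
    centroid.  Ties break toward the lower cluster index, with a warning.
    """
    if model.k != 3:
        raise ValueError("role assignment requires k = 3")
    d_white = np.array([lab_distance(c, WHITE) for c in model.centroids])
    bg = int(d_white.argmin())
    if (d_white == d_white[bg]).sum() > 1:
        logger.warning("tie for the background cluster; picking lowest index")
    rest = [i for i in range(3) if i != bg]
    a_vals = model.centroids[rest, 1]
    if a_vals[0] == a_vals[1]:
        logger.warning("tie on a* between tissue clusters; picking lowest index")
    smf = rest[int(np.argmax(a_vals))]
    ecm = rest[0] if smf == rest[1] else rest[1]
    return {BACKGROUND: bg, SMF: smf, ECM: ecm}


@dataclass(frozen=True)
class Quantification:
    """Component areas in pixels and their wall-normalized ratios."""

    a_smf: int
    a_ecm: int
    a_tot: int
    ratio_smf: float
    ratio_ecm: float


def quantify(
    model: ClusterModel, roles: dict[str, int], wall: WallRegion
) -> Quantification:
    """Count SMF/ECM cluster pixels inside the wall and normalize by A_TOT."""
    if wall.a_tot <= 0:
        raise ValueError("wall area A_TOT must be positive")
    assignment = model.assignment.reshape(wall.mask.shape)
    a_smf = int(np.count_nonzero((assignment == roles[SMF]) & wall.mask))
    a_ecm = int(np.count_nonzero((assignment == roles[ECM]) & wall.mask))
    return Quantification(
        a_smf=a_smf,
        a_ecm=a_ecm,
        a_tot=wall.a_tot,
        ratio_smf=a_smf / wall.a_tot,
        ratio_ecm=a_ecm / wall.a_tot,
    )


def segment_image(
    lab: np.ndarray,
    wall: WallRegion,
    cfg: KmeansConfig | None = None,
    valid: np.ndarray | None = None,
) -> tuple[ClusterModel, dict[str, int], Quantification]:
    """Run the full feature-extraction stage on a preprocessed color image.

    Pixels outside the wall — and defect pixels flagged invalid during
    pre-processing — are painted white, the whole image is clustered with
    k=3, roles are assigned and the component areas quantified.
    """
    masked = mask_to_white(lab, wall)
    if valid is not None:
        masked[~valid] = WHITE
    model = kmeans_lab(masked.reshape(-1, 3), cfg)
    roles = assign_roles(model)
    quant = quantify(model, roles, wall)
    return model, roles, quant
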