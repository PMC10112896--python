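"""3D presynaptic-puncta detection, evaluation, and per-larva summaries.

The detector finds peak-intensity regions in 3D, in the spirit of
foci-finding tools for confocal stacks: optional Gaussian blur, a background
threshold, local-maximum seeding, region assignment by descending-intensity
flood fill (watershed), and a prominence rule that merges peaks whose height
above their highest saddle is below ``min_peak_height``. The original
workflow trained a plugin's internal learner on point annotations; here that
training signal (precision/recall/F1 against annotated points) drives an
explicit, deterministic grid search over :class:`DetectionParams`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage
from skimage import morphology, segmentation

from .errors import ConfigurationError
from .grid import VoxelGrid
from .imagecore import threshold_li, threshold_otsu

__all__ = [
    "DetectionParams",
    "Punctum",
    "PunctaSet",
    "MatchResult",
    "detect_puncta",
    "match_detections",
    "optimize_params",
    "count_in_rois",
    "puncta_density",
]

logger = logging.getLogger(__name__)

_BACKGROUND_METHODS = ("absolute", "otsu", "li", "mean_plus_k_sd")


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the peak detector.

    ``blur_sigma_um`` is isotropic in physical units (converted to voxels per
    axis); ``min_peak_height`` is the minimum height above the highest saddle
    connecting two peaks, below which the lower peak merges into its higher
    neighbour; ``min_size`` is in voxels.
    """

    blur_sigma_um: float = 0.1
    background_method: str = "absolute"
    background_param: float = 15.0
    min_peak_height: float = 10.0
    min_size: int = 4
    connectivity: int = 26

    def validate(self) -> None:
        if self.blur_sigma_um < 0:
            raise ConfigurationError("blur_sigma_um must be >= 0")
        if self.background_method not in _BACKGROUND_METHODS:
            raise ConfigurationError(
                f"background_method must be one of {_BACKGROUND_METHODS}, got {self.background_method!r}"
            )
        if self.min_peak_height < 0:
            raise ConfigurationError("min_peak_height must be >= 0")
        if self.min_size < 1:
            raise ConfigurationError("min_size must be >= 1")
        if self.connectivity not in (6, 26):
            raise ConfigurationError("connectivity must be 6 or 26")

    def to_yaml(self, path) -> None:
        import dataclasses

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DetectionParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class Punctum:
    centroid_um: tuple[float, float, float]  # (x, y, z)
    peak_intensity: float
    size_voxels: int


@dataclass
class PunctaSet:
    """Detected 3D intensity peaks, sorted by descending peak intensity."""

    peaks: list[Punctum] = field(default_factory=list)
    params: DetectionParams | None = None
    background_threshold: float | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def centroids(self) -> np.ndarray:
        if not self.peaks:
            return np.zeros((0, 3))
        return np.asarray([p.centroid_um for p in self.peaks], dtype=float)


@dataclass
class MatchResult:
    """Detection-vs-annotation agreement under greedy nearest matching."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _conn_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def _background_threshold(img: np.ndarray, grid: VoxelGrid, params: DetectionParams) -> float:
    if params.background_method == "absolute":
        return float(params.background_param)
    if params.background_method == "mean_plus_k_sd":
        return float(img.mean() + params.background_param * img.std())
    tmp = grid.with_data(np.clip(img, 0, None))
    if params.background_method == "otsu":
        return threshold_otsu(tmp)
    return threshold_li(tmp)


def detect_puncta(grid: VoxelGrid, params: DetectionParams) -> PunctaSet:
    """Detect 3D intensity peaks; see the module docstring for the pipeline.

    A background threshold at or above the global maximum yields an empty
    :class:`PunctaSet` (not an error). The global maximum of each connected
    foreground region is always retained as a seed, so ``min_peak_height``
    merges peaks but never deletes an isolated object outright.
    """
    params.validate()
    img = np.asarray(grid.data, dtype=np.float64)
    if params.blur_sigma_um > 0:
        sigma_vox = [params.blur_sigma_um / d for d in grid.voxel_dims]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)

    bg = _background_threshold(img, grid, params)
    if bg >= img.max():
        return PunctaSet(params=params, background_threshold=bg)
    mask = img > bg
    struct = _conn_structure(params.connectivity)

    if params.min_peak_height > 0:
        maxima = morphology.h_maxima(img, params.min_peak_height, footprint=struct)
    else:
        maxima = morphology.local_maxima(img, footprint=struct)
    maxima = maxima.astype(bool) & mask

    comp_labels, n_comp = ndimage.label(mask, structure=struct)
    # guarantee one seed per foreground component: its highest voxel
    # (first occurrence in C order wins on plateaus)
    has_seed = np.zeros(n_comp + 1, dtype=bool)
    has_seed[np.unique(comp_labels[maxima])] = True
    missing = [lbl for lbl in range(1, n_comp + 1) if not has_seed[lbl]]
    if missing:
        for pos in ndimage.maximum_position(img, comp_labels, missing):
            maxima[pos] = True

    markers, _ = ndimage.label(maxima, structure=struct)
    conn_nd = 1 if params.connectivity == 6 else 3
    regions = segmentation.watershed(-img, markers=markers, mask=mask, connectivity=conn_nd)
    n_regions = int(regions.max())
    if n_regions == 0:
        return PunctaSet(params=params, background_threshold=bg)

    dz, dy, dx = grid.voxel_dims
    lab = regions.ravel()
    w = np.where(lab > 0, np.clip(img.ravel() - bg, 0, None), 0.0)
    sizes = np.bincount(lab, minlength=n_regions + 1)
    wsum = np.bincount(lab, weights=w, minlength=n_regions + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(img.shape[0]), np.arange(img.shape[1]), np.arange(img.shape[2]), indexing="ij"
    )
    with np.errstate(invalid="ignore"):
        cz = np.bincount(lab, weights=w * zz.ravel(), minlength=n_regions + 1) / wsum
        cy = np.bincount(lab, weights=w * yy.ravel(), minlength=n_regions + 1) / wsum
        cx = np.bincount(lab, weights=w * xx.ravel(), minlength=n_regions + 1) / wsum
    kept = [lbl for lbl in range(1, n_regions + 1) if sizes[lbl] >= params.min_size]
    if not kept:
        return PunctaSet(params=params, background_threshold=bg)
    peak_pos = ndimage.maximum_position(img, regions, kept)
    peaks: list[tuple[float, int, Punctum]] = []
    for lbl, pos in zip(kept, peak_pos):
        peak_val = float(img[pos])
        linear = int(np.ravel_multi_index(pos, img.shape))
        centroid = (float(cx[lbl] * dx), float(cy[lbl] * dy), float(cz[lbl] * dz))
        peaks.append((peak_val, linear, Punctum(centroid, peak_val, int(sizes[lbl]))))

    peaks.sort(key=lambda t: (-t[0], t[1]))
    return PunctaSet([p for _, _, p in peaks], params=params, background_threshold=bg)


def match_detections(detected: PunctaSet, truth: np.ndarray, match_radius: float = 0.5) -> MatchResult:
    """Greedy matching of detections to annotated points.

    Detections are visited in order of descending peak intensity; each claims
    the nearest unclaimed truth point within ``match_radius`` (Euclidean
    distance in µm). Unclaimed detections are false positives, unclaimed
    truth points false negatives.
    """
    if match_radius <= 0:
        raise ConfigurationError("match_radius must be > 0")
    truth = np.asarray(truth, dtype=float).reshape(-1, 3)
    claimed = np.zeros(len(truth), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i, p in enumerate(detected.peaks):
        if len(truth) == 0:
            break
        d = np.linalg.norm(truth - np.asarray(p.centroid_um), axis=1)
        d[claimed] = np.inf
        j = int(np.argmin(d))
        if d[j] <= match_radius:
            claimed[j] = True
            pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(detected) - tp, fn=len(truth) - tp, pairs=pairs)


def optimize_params(
    rois: list[tuple[VoxelGrid, np.ndarray]],
    search_space: dict[str, list],
    objective: str = "f1",
    base_params: DetectionParams | None = None,
    match_radius: float = 0.5,
) -> tuple[DetectionParams, MatchResult]:
    """Deterministic grid search maximising pooled F1 over annotated ROIs.

    ``search_space`` maps :class:`DetectionParams` field names to candidate
    values; candidates are evaluated in lexicographic order of the sorted
    field names. Ties are broken by fewer pooled false positives, then by
    candidate order.
    """
    if objective != "f1":
        raise ConfigurationError(f"objective must be 'f1', got {objective!r}")
    if not rois:
        raise ConfigurationError("optimize_params requires at least one annotated ROI")
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ConfigurationError("search_space must be nonempty for every field")
    base = base_params or DetectionParams()
    names = sorted(search_space)
    best: tuple[float, int, int] | None = None
    best_params: DetectionParams | None = None
    best_result: MatchResult | None = None
    for order, combo in enumerate(itertools.product(*(search_space[n] for n in names))):
        candidate = replace(base, **dict(zip(names, combo)))
        candidate.validate()
        tp = fp = fn = 0
        for grid, truth in rois:
            m = match_detections(detect_puncta(grid, candidate), truth, match_radius)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        pooled = MatchResult(tp=tp, fp=fp, fn=fn)
        key = (pooled.f1, -fp, -order)
        if best is None or key > best:
            best, best_params, best_result = key, candidate, pooled
    return best_params, best_result


def count_in_rois(puncta: PunctaSet, rois: list[dict]) -> tuple[list[int], int]:
    """Count puncta per half-open ROI box and the per-larva sum.

    ROI boxes are dicts with µm bounds ``x0, x1, y0, y1, z0, z1``; a punctum
    counts toward every ROI containing its centroid (overlaps are logged).
    """
    cents = puncta.centroids
    counts = []
    for a, b in itertools.combinations(range(len(rois)), 2):
        ra, rb = rois[a], rois[b]
        if all(ra[f"{ax}0"] < rb[f"{ax}1"] and rb[f"{ax}0"] < ra[f"{ax}1"] for ax in "xyz"):
            logger.warning("ROIs %d and %d overlap; puncta inside both are counted twice", a, b)
    for roi in rois:
        if len(cents) == 0:
            counts.append(0)
            continue
        inside = (
            (cents[:, 0] >= roi["x0"]) & (cents[:, 0] < roi["x1"])
            & (cents[:, 1] >= roi["y0"]) & (cents[:, 1] < roi["y1"])
            & (cents[:, 2] >= roi["z0"]) & (cents[:, 2] < roi["z1"])
        )
        counts.append(int(inside.sum()))
    return counts, int(sum(counts))


def puncta_density(count: int, mask_volume_um3: float) -> float:
    """Puncta per µm³ of thresholded axon volume."""
    if mask_volume_um3 <= 0:
        raise ConfigurationError("no axon volume in region: mask_volume must be > 0")
    return count / mask_volume_um3
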