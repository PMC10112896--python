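"""Synthetic ventral-nerve-cord (VNC) stack generator with exact ground truth.

The generator emulates the ventral somatosensory neuropil of a larval VNC as
seen in a confocal z-stack:

* a ladder-like **cIV** (nociceptor) scaffold: two longitudinal connectives
  close to the midline joined by one commissure per abdominal neuromere;
* parallel **cIII** (gentle-touch) longitudinal tracts strictly lateral to
  the cIV connectives;
* presynaptic (Brp-short-like) **puncta** rendered as isotropic Gaussian
  spots placed inside cIII axon tubes;
* a bilateral **dendrite** field (DnB-like second-order dendrites) spanning
  the mediolateral extent of both axon layers;
* FasII-like **landmark** tracts (VMv position) between the cIV and cIII
  tracts, used to delimit the medial analysis region;
* a **grasp** channel marking membrane contact between cIII axons and the
  dendritic field.

Perturbation modes mirror the genetic manipulations quantified in the
associated experiments: nociceptor ablation (cIII axons extend medially and
carry medial puncta), lateralization (loss of cIV commissures with ectopic
cIII crossing), and a lateral dendrite shift.

Every stochastic element (puncta placement, bleb placement, noise) is drawn
from one ``numpy`` generator seeded by ``ScaffoldSpec.seed``, so identical
specs produce voxel-identical stacks and identical ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .errors import ConfigurationError
from .grid import MultiChannelStack, VoxelGrid

__all__ = [
    "CIV",
    "CIII",
    "PUNCTA",
    "DENDRITE",
    "LANDMARK",
    "GRASP",
    "NoiseSpec",
    "SegmentStage",
    "ScaffoldSpec",
    "GroundTruth",
    "generate_stack",
    "apply_perturbation",
    "lateral_ciii_length",
    "medial_branch_length",
]

CIV = "civ_membrane"
CIII = "ciii_membrane"
PUNCTA = "puncta"
DENDRITE = "dendrite"
LANDMARK = "landmark"
GRASP = "grasp"

_CHANNEL_ORDER = (CIV, CIII, PUNCTA, DENDRITE, LANDMARK, GRASP)


@dataclass(frozen=True)
class NoiseSpec:
    """Confocal acquisition noise model: Poisson shot noise on expected
    photon counts (``intensity * gain``) followed by Gaussian read noise."""

    background_level: float = 10.0
    background_gradient: float = 0.0  # intensity per µm along x
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    gain: float = 1.0

    def validate(self) -> None:
        if self.background_level < 0:
            raise ConfigurationError("noise.background_level must be >= 0")
        if self.read_noise_sd < 0:
            raise ConfigurationError("noise.read_noise_sd must be >= 0")
        if self.gain <= 0:
            raise ConfigurationError("noise.gain must be > 0")


@dataclass(frozen=True)
class SegmentStage:
    """Degeneration state of the cIV axons in one neuromere.

    ``stage`` is one of ``intact`` / ``blebbed`` / ``ablated``; blebbed
    segments carry ``n_blebs`` swellings, ablated segments lose the axons of
    ``missing_sides`` (``("left",)``, ``("right",)`` or both).
    """

    stage: str = "intact"
    n_blebs: int = 0
    missing_sides: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.stage not in ("intact", "blebbed", "ablated"):
            raise ConfigurationError(f"segment stage {self.stage!r} unknown")
        if self.stage == "intact" and self.n_blebs > 1:
            raise ConfigurationError("intact segments allow at most one bleb")
        if self.stage == "blebbed" and self.n_blebs < 2:
            raise ConfigurationError("blebbed segments require n_blebs >= 2")
        if self.stage == "ablated" and not self.missing_sides:
            raise ConfigurationError("ablated segments must name missing_sides")
        if any(s not in ("left", "right") for s in self.missing_sides):
            raise ConfigurationError("missing_sides entries must be 'left' or 'right'")


def _default_intensities() -> dict[str, float]:
    return {CIV: 150.0, CIII: 150.0, PUNCTA: 120.0, DENDRITE: 120.0, LANDMARK: 150.0, GRASP: 100.0}


def _default_puncta_counts() -> dict[str, int]:
    return {"medial": 0, "lateral": 50}


@dataclass
class ScaffoldSpec:
    """Full description of one synthetic larval VNC stack.

    Offsets are signed µm from ``midline_x`` (negative = left).  The default
    geometry covers six abdominal neuromeres (A2-A7) at the acquisition
    scale used for puncta counting: 0.1 µm lateral pixels, 0.5 µm z-step.
    """

    n_segments: int = 6
    segment_pitch: float = 7.0  # µm anterior-posterior per neuromere
    midline_x: float = 12.0
    civ_tract_offsets: tuple[float, float] = (-3.0, 3.0)
    ciii_tract_offsets: tuple[float, float] = (-8.0, 8.0)
    landmark_tract_offset: float = 5.5  # FasII VMv-like, symmetric ±
    axon_radius: float = 0.5
    puncta_count_per_region: dict[str, int] = field(default_factory=_default_puncta_counts)
    puncta_sigma: float = 0.15
    min_puncta_separation: float = 0.8
    dendrite_field_extent: tuple[float, float] = (10.0, 1.5)  # (lateral, medial) µm from midline
    dendrite_shift_um: float = 0.0
    intensity_levels: dict[str, float] = field(default_factory=_default_intensities)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    voxel_dims: tuple[float, float, float] = (0.5, 0.1, 0.1)  # (dz, dy, dx)
    shape: tuple[int, int, int] = (8, 420, 240)  # (nz, ny, nx)
    psf_sigma: tuple[float, float, float] = (0.5, 0.15, 0.15)  # (z, y, x) µm
    commissures: tuple[str, ...] | None = None  # per-segment cIV state
    ciii_medial_branch: tuple[bool, ...] | None = None  # per-segment ectopic crossing
    partial_fraction: float = 0.4  # reach of a "partial" commissure branch
    scaffold_wobble_amplitude: float = 0.0  # sinusoidal lateral wobble of cIV tracts, µm
    scaffold_wobble_period: float = 16.0  # µm
    civ_stages: tuple[SegmentStage, ...] | None = None
    seed: int = 0

    # ------------------------------------------------------------------ helpers
    def __post_init__(self) -> None:
        if self.commissures is None:
            self.commissures = tuple("full" for _ in range(self.n_segments))
        else:
            self.commissures = tuple(self.commissures)
        if self.ciii_medial_branch is None:
            self.ciii_medial_branch = tuple(False for _ in range(self.n_segments))
        else:
            self.ciii_medial_branch = tuple(bool(b) for b in self.ciii_medial_branch)
        if self.civ_stages is not None:
            self.civ_stages = tuple(
                s if isinstance(s, SegmentStage) else SegmentStage(**s) for s in self.civ_stages
            )
        self.civ_tract_offsets = tuple(float(v) for v in self.civ_tract_offsets)
        self.ciii_tract_offsets = tuple(float(v) for v in self.ciii_tract_offsets)
        self.dendrite_field_extent = tuple(float(v) for v in self.dendrite_field_extent)
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        self.shape = tuple(int(v) for v in self.shape)
        self.psf_sigma = tuple(float(v) for v in self.psf_sigma)
        self.puncta_count_per_region = {
            k: int(v) for k, v in self.puncta_count_per_region.items()
        }

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """(z, y, x) physical extent in µm."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.voxel_dims
        return (nz * dz, ny * dy, nx * dx)

    @property
    def y_origin(self) -> float:
        """Anterior boundary of the first neuromere (segments centred in y)."""
        return (self.extent_um[1] - self.n_segments * self.segment_pitch) / 2.0

    @property
    def z_center(self) -> float:
        return (self.shape[0] // 2) * self.voxel_dims[0]

    def segment_bounds_y(self) -> list[tuple[float, float]]:
        y0 = self.y_origin
        p = self.segment_pitch
        return [(y0 + i * p, y0 + (i + 1) * p) for i in range(self.n_segments)]

    def validate(self) -> None:
        if self.n_segments < 1:
            raise ConfigurationError("n_segments must be >= 1")
        if self.segment_pitch <= 0:
            raise ConfigurationError("segment_pitch must be > 0")
        if any(d <= 0 for d in self.voxel_dims):
            raise ConfigurationError("voxel_dims must be positive")
        if any(n <= 0 for n in self.shape):
            raise ConfigurationError("shape must be positive in every axis")
        if self.axon_radius <= 0:
            raise ConfigurationError("axon_radius must be > 0")
        if self.puncta_sigma <= 0:
            raise ConfigurationError("puncta_sigma must be > 0")
        if not 0.0 < self.partial_fraction < 1.0:
            raise ConfigurationError("partial_fraction must lie in (0, 1)")
        self.noise.validate()
        left_civ, right_civ = self.civ_tract_offsets
        left_ciii, right_ciii = self.ciii_tract_offsets
        if not (left_civ < 0 < right_civ):
            raise ConfigurationError("civ_tract_offsets must straddle the midline (left < 0 < right)")
        if not (abs(left_ciii) > abs(left_civ) and abs(right_ciii) > abs(right_civ)):
            raise ConfigurationError("ciii_tract_offsets must be strictly lateral to civ_tract_offsets")
        lm = self.landmark_tract_offset
        if not (abs(right_civ) < lm < abs(right_ciii) and abs(left_civ) < lm < abs(left_ciii)):
            raise ConfigurationError(
                "landmark_tract_offset must lie between civ_tract_offsets and ciii_tract_offsets"
            )
        lat, med = self.dendrite_field_extent
        if not 0 <= med < lat:
            raise ConfigurationError("dendrite_field_extent must satisfy 0 <= medial < lateral")
        _, ey, ex = self.extent_um
        margin = self.axon_radius + 3 * max(self.psf_sigma[1:])
        widest = max(abs(left_ciii), abs(right_ciii), lat + abs(self.dendrite_shift_um)) + \
            self.scaffold_wobble_amplitude
        if self.midline_x - widest - margin < 0 or self.midline_x + widest + margin > ex:
            raise ConfigurationError(
                "ciii_tract_offsets/dendrite_field_extent exceed the stack footprint along x"
            )
        if self.n_segments * self.segment_pitch > ey + 1e-9:
            raise ConfigurationError("n_segments * segment_pitch exceeds the stack footprint along y")
        if len(self.commissures) != self.n_segments:
            raise ConfigurationError("commissures must list one state per segment")
        if any(c not in ("full", "partial", "absent") for c in self.commissures):
            raise ConfigurationError("commissures entries must be full|partial|absent")
        if len(self.ciii_medial_branch) != self.n_segments:
            raise ConfigurationError("ciii_medial_branch must list one flag per segment")
        if self.civ_stages is not None:
            if len(self.civ_stages) != self.n_segments:
                raise ConfigurationError("civ_stages must list one stage per segment")
            for s in self.civ_stages:
                s.validate()
        for region, count in self.puncta_count_per_region.items():
            if region not in ("medial", "lateral"):
                raise ConfigurationError(f"puncta_count_per_region key {region!r} unknown")
            if count < 0:
                raise ConfigurationError("puncta_count_per_region values must be >= 0")
        if self.puncta_count_per_region.get("medial", 0) > 0 and not any(self.ciii_medial_branch):
            raise ConfigurationError(
                "puncta_count_per_region['medial'] > 0 requires at least one ciii_medial_branch"
            )

    # ------------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        # json round-trip turns nested tuples into plain lists for YAML
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "ScaffoldSpec":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseSpec(**d["noise"])
        if d.get("civ_stages") is not None:
            d["civ_stages"] = tuple(
                SegmentStage(**{**s, "missing_sides": tuple(s.get("missing_sides", ()))})
                for s in d["civ_stages"]
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown ScaffoldSpec fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScaffoldSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Exact geometry exported alongside a rendered stack.

    Coordinates are µm in ``(x, y, z)`` order; polylines are ``(N, 3)``
    arrays (scaffold edges ``(N, 2)`` in ``(x, y)`` on the z-projection).
    """

    puncta_xyz: np.ndarray  # (N, 3) µm
    puncta_regions: list[str]  # medial | lateral per punctum
    centerlines: dict[str, list[np.ndarray]]
    midline_x: float
    segment_bounds_y: list[tuple[float, float]]
    scaffold_edge: dict[str, np.ndarray]  # left/right lateral edge of cIV scaffold
    commissure_state: dict[str, list[str]]  # per class, per segment
    dendrite_roi: list[dict]  # per segment, right-side rectangle in µm
    civ_stages: list[dict]

    def puncta_count(self, region: str | None = None) -> int:
        if region is None:
            return len(self.puncta_regions)
        return sum(1 for r in self.puncta_regions if r == region)

    def to_json(self, path) -> None:
        def _poly(p):
            return np.asarray(p).tolist()

        payload = {
            "puncta_xyz": self.puncta_xyz.tolist(),
            "puncta_regions": self.puncta_regions,
            "centerlines": {k: [_poly(p) for p in v] for k, v in self.centerlines.items()},
            "midline_x": self.midline_x,
            "segment_bounds_y": [list(b) for b in self.segment_bounds_y],
            "scaffold_edge": {k: _poly(v) for k, v in self.scaffold_edge.items()},
            "commissure_state": self.commissure_state,
            "dendrite_roi": self.dendrite_roi,
            "civ_stages": self.civ_stages,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            puncta_xyz=np.asarray(d["puncta_xyz"], dtype=float).reshape(-1, 3),
            puncta_regions=list(d["puncta_regions"]),
            centerlines={k: [np.asarray(p, dtype=float) for p in v] for k, v in d["centerlines"].items()},
            midline_x=float(d["midline_x"]),
            segment_bounds_y=[tuple(b) for b in d["segment_bounds_y"]],
            scaffold_edge={k: np.asarray(v, dtype=float) for k, v in d["scaffold_edge"].items()},
            commissure_state={k: list(v) for k, v in d["commissure_state"].items()},
            dendrite_roi=list(d["dendrite_roi"]),
            civ_stages=list(d["civ_stages"]),
        )


# ---------------------------------------------------------------------- geometry
def _polyline_length(points: np.ndarray) -> float:
    p = np.asarray(points, dtype=float)
    return float(np.sqrt(((p[1:] - p[:-1]) ** 2).sum(axis=1)).sum())


def _densify(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length ``step``."""
    p = np.asarray(points, dtype=float)
    out = [p[0]]
    for a, b in zip(p[:-1], p[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / step)))
        for t in np.linspace(0, 1, n + 1)[1:]:
            out.append(a + t * (b - a))
    return np.asarray(out)


def _rasterize_polylines(polylines, shape, voxel_dims) -> np.ndarray:
    """Mark the voxels nearest to densely sampled polyline points."""
    nz, ny, nx = shape
    dz, dy, dx = voxel_dims
    seeds = np.zeros(shape, dtype=bool)
    step = 0.4 * min(voxel_dims)
    for poly in polylines:
        pts = _densify(poly, step)
        ix = np.clip(np.rint(pts[:, 0] / dx).astype(int), 0, nx - 1)
        iy = np.clip(np.rint(pts[:, 1] / dy).astype(int), 0, ny - 1)
        iz = np.clip(np.rint(pts[:, 2] / dz).astype(int), 0, nz - 1)
        seeds[iz, iy, ix] = True
    return seeds


def _tube_mask(polylines, radius, shape, voxel_dims) -> np.ndarray:
    """Boolean tube of the given physical radius around the centerlines."""
    if not polylines:
        return np.zeros(shape, dtype=bool)
    seeds = _rasterize_polylines(polylines, shape, voxel_dims)
    dist = ndimage.distance_transform_edt(~seeds, sampling=voxel_dims)
    return dist <= radius


def _blur(channel: np.ndarray, psf_sigma, voxel_dims) -> np.ndarray:
    sigma_vox = [s / d for s, d in zip(psf_sigma, voxel_dims)]
    return ndimage.gaussian_filter(channel, sigma=sigma_vox)


def _civ_polylines(spec: ScaffoldSpec) -> tuple[list[np.ndarray], list[dict]]:
    """cIV centerlines (longitudinal pieces, commissures, bleb positions drawn
    later) plus per-segment stage bookkeeping."""
    zc = spec.z_center
    mid = spec.midline_x
    bounds = spec.segment_bounds_y()
    stages = spec.civ_stages or tuple(SegmentStage() for _ in range(spec.n_segments))
    polys: list[np.ndarray] = []
    stage_records: list[dict] = []

    def tract_x(side_offset: float, y: np.ndarray) -> np.ndarray:
        if spec.scaffold_wobble_amplitude == 0.0:
            return np.full_like(y, mid + side_offset)
        phase = 2 * np.pi * (y - spec.y_origin) / spec.scaffold_wobble_period
        sign = np.sign(side_offset)
        return mid + side_offset + sign * spec.scaffold_wobble_amplitude * np.sin(phase)

    for i, ((ya, yb), stage) in enumerate(zip(bounds, stages)):
        missing = set(stage.missing_sides) if stage.stage == "ablated" else set()
        for side, off in zip(("left", "right"), spec.civ_tract_offsets):
            if side in missing:
                continue
            y = np.arange(ya, yb + 1e-9, 0.25)
            x = tract_x(off, y)
            polys.append(np.column_stack([x, y, np.full_like(y, zc)]))
        yc = 0.5 * (ya + yb)
        state = spec.commissures[i]
        xl = mid + spec.civ_tract_offsets[0]
        xr = mid + spec.civ_tract_offsets[1]
        if stage.stage == "ablated":
            state = "absent"
        if state == "full":
            polys.append(np.array([[xl, yc, zc], [xr, yc, zc]]))
        elif state == "partial":
            # centerline ends one radius short so the rendered tube tip
            # (spherical cap) reaches exactly partial_fraction of the span
            span = max((xr - xl) * spec.partial_fraction - spec.axon_radius, 0.1)
            polys.append(np.array([[xl, yc, zc], [xl + span, yc, zc]]))
            polys.append(np.array([[xr, yc, zc], [xr - span, yc, zc]]))
        stage_records.append(
            {
                "stage": stage.stage,
                "n_blebs": stage.n_blebs,
                "left_present": "left" not in missing,
                "right_present": "right" not in missing,
                "commissure_state": state,
            }
        )
    return polys, stage_records


def _ciii_polylines(spec: ScaffoldSpec) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Longitudinal cIII tracts plus any medial (crossing) branches."""
    zc = spec.z_center
    mid = spec.midline_x
    y0 = spec.y_origin
    y1 = y0 + spec.n_segments * spec.segment_pitch
    longitudinal = [
        np.array([[mid + off, y0, zc], [mid + off, y1, zc]]) for off in spec.ciii_tract_offsets
    ]
    branches = []
    for i, has_branch in enumerate(spec.ciii_medial_branch):
        if not has_branch:
            continue
        ya, yb = spec.segment_bounds_y()[i]
        yc = 0.5 * (ya + yb) + 0.12 * spec.segment_pitch  # slightly posterior to the cIV commissure
        xl = mid + spec.ciii_tract_offsets[0]
        xr = mid + spec.ciii_tract_offsets[1]
        branches.append(np.array([[xl, yc, zc], [xr, yc, zc]]))
    return longitudinal, branches


def _landmark_polylines(spec: ScaffoldSpec) -> list[np.ndarray]:
    zc = spec.z_center
    mid = spec.midline_x
    y0 = spec.y_origin
    y1 = y0 + spec.n_segments * spec.segment_pitch
    off = spec.landmark_tract_offset
    return [
        np.array([[mid - off, y0, zc], [mid - off, y1, zc]]),
        np.array([[mid + off, y0, zc], [mid + off, y1, zc]]),
    ]


def _scaffold_edge_truth(spec: ScaffoldSpec) -> dict[str, np.ndarray]:
    """Analytic lateral edge of the cIV scaffold on the z-projection."""
    y = np.arange(spec.y_origin, spec.y_origin + spec.n_segments * spec.segment_pitch + 1e-9, spec.voxel_dims[1])
    edges = {}
    for side, off in zip(("left", "right"), spec.civ_tract_offsets):
        sign = np.sign(off)
        x = np.full_like(y, spec.midline_x + off)
        if spec.scaffold_wobble_amplitude:
            phase = 2 * np.pi * (y - spec.y_origin) / spec.scaffold_wobble_period
            x = x + sign * spec.scaffold_wobble_amplitude * np.sin(phase)
        edges[side] = np.column_stack([x + sign * spec.axon_radius, y])
    return edges


_REGION_MARGIN = 0.25  # µm clearance kept on both sides of the landmark x-position


def _branch_pieces(branch: np.ndarray, spec: ScaffoldSpec):
    """Split a crossing branch at the landmark tracts into a medial piece and
    two lateral pieces, leaving a small label-safety margin at the boundary."""
    lm = spec.landmark_tract_offset
    mid = spec.midline_x
    yc, zc = branch[0, 1], branch[0, 2]
    xl, xr = branch[0, 0], branch[-1, 0]

    def seg(a, b):
        return np.array([[a, yc, zc], [b, yc, zc]]) if b - a > 1e-6 else None

    # lateral pieces start one radius away from the tract centreline: the
    # junction volume already belongs to the longitudinal tract
    r = spec.axon_radius
    medial = seg(mid - (lm - _REGION_MARGIN), mid + (lm - _REGION_MARGIN))
    lateral = [seg(xl + r, mid - (lm + _REGION_MARGIN)), seg(mid + (lm + _REGION_MARGIN), xr - r)]
    return medial, [p for p in lateral if p is not None]


def _place_puncta(spec: ScaffoldSpec, rng: np.random.Generator,
                  longitudinal: list[np.ndarray], branches: list[np.ndarray]):
    """Sample puncta centres inside the cIII tubes, per region, with a soft
    minimum-separation constraint (rejection sampling).

    Lateral puncta live on the longitudinal tracts and on the lateral
    portions of any crossing branch; medial puncta on the branch portion
    medial to the landmark tracts. Radial jitter is clamped in x so a
    punctum's region label always matches its position.
    """
    jitter = 0.8 * spec.axon_radius
    mid = spec.midline_x
    lm = spec.landmark_tract_offset

    def clamp_x(x: float, region: str) -> float:
        if region == "medial":
            return float(np.clip(x, mid - (lm - _REGION_MARGIN), mid + (lm - _REGION_MARGIN)))
        if abs(x - mid) < lm + _REGION_MARGIN:
            return mid + np.sign(x - mid) * (lm + _REGION_MARGIN)
        return x

    def sample_on(polys, n, region):
        if n == 0:
            return np.zeros((0, 3))
        if not polys:
            raise ConfigurationError("puncta_count_per_region requests puncta but no centerline exists")
        lengths = np.array([_polyline_length(p) for p in polys])
        accepted: list[np.ndarray] = []
        tries = 0
        while len(accepted) < n and tries < 400 * n:
            tries += 1
            poly = polys[rng.choice(len(polys), p=lengths / lengths.sum())]
            seg = np.sqrt(((poly[1:] - poly[:-1]) ** 2).sum(axis=1))
            cum = np.concatenate([[0], np.cumsum(seg)])
            u = rng.uniform(0, cum[-1])
            k = min(int(np.searchsorted(cum, u, side="right")) - 1, len(seg) - 1)
            t = (u - cum[k]) / seg[k] if seg[k] > 0 else 0.0
            base = poly[k] + t * (poly[k + 1] - poly[k])
            offset = rng.normal(size=3)
            offset *= rng.uniform(0, jitter) / max(np.linalg.norm(offset), 1e-12)
            pt = base + offset
            pt[0] = clamp_x(pt[0], region)
            if accepted and np.min(np.linalg.norm(np.asarray(accepted) - pt, axis=1)) < spec.min_puncta_separation:
                continue
            accepted.append(pt)
        while len(accepted) < n:  # relax separation rather than fail: counts are a contract
            poly = polys[rng.choice(len(polys), p=lengths / lengths.sum())]
            t = rng.uniform()
            pt = poly[0] + t * (poly[-1] - poly[0]) + rng.normal(scale=jitter / 3, size=3)
            pt[0] = clamp_x(pt[0], region)
            accepted.append(pt)
        return np.asarray(accepted)

    med_polys: list[np.ndarray] = []
    lat_polys = list(longitudinal)
    for b in branches:
        medial, lateral = _branch_pieces(b, spec)
        if medial is not None:
            med_polys.append(medial)
        lat_polys.extend(lateral)

    n_lat = spec.puncta_count_per_region.get("lateral", 0)
    n_med = spec.puncta_count_per_region.get("medial", 0)
    lat_pts = sample_on(lat_polys, n_lat, "lateral")
    med_pts = sample_on(med_polys, n_med, "medial") if n_med else np.zeros((0, 3))
    pts = np.vstack([med_pts, lat_pts])
    regions = ["medial"] * len(med_pts) + ["lateral"] * len(lat_pts)
    return pts, regions


def _render_puncta(points: np.ndarray, amplitude: float, sigma: float,
                   shape, voxel_dims) -> np.ndarray:
    """Sum of isotropic (in µm) Gaussian spots truncated at 3σ."""
    out = np.zeros(shape, dtype=np.float64)
    if len(points) == 0:
        return out
    nz, ny, nx = shape
    dz, dy, dx = voxel_dims
    hw = [int(np.ceil(3 * sigma / d)) for d in voxel_dims]
    for x, y, z in points:
        iz, iy, ix = int(round(z / dz)), int(round(y / dy)), int(round(x / dx))
        z0, z1 = max(0, iz - hw[0]), min(nz, iz + hw[0] + 1)
        y0, y1 = max(0, iy - hw[1]), min(ny, iy + hw[1] + 1)
        x0, x1 = max(0, ix - hw[2]), min(nx, ix + hw[2] + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz = (np.arange(z0, z1) * dz - z)[:, None, None]
        yy = (np.arange(y0, y1) * dy - y)[None, :, None]
        xx = (np.arange(x0, x1) * dx - x)[None, None, :]
        r2 = zz ** 2 + yy ** 2 + xx ** 2
        spot = amplitude * np.exp(-r2 / (2 * sigma ** 2))
        spot[r2 > (3 * sigma) ** 2] = 0.0
        out[z0:z1, y0:y1, x0:x1] += spot
    return out


def _dendrite_channel(spec: ScaffoldSpec) -> np.ndarray:
    """Bilateral dendritic field: raised-cosine mediolateral profile on a
    thin z-band, spanning the neuromere range in y."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_dims
    x = np.arange(nx) * dx
    lat, med = spec.dendrite_field_extent
    shift = spec.dendrite_shift_um
    profile = np.zeros(nx)
    for sign in (-1, 1):
        a = spec.midline_x + sign * (med + shift)
        b = spec.midline_x + sign * (lat + shift)
        lo, hi = min(a, b), max(a, b)
        inside = (x >= lo) & (x <= hi)
        u = (x[inside] - lo) / (hi - lo)
        profile[inside] = np.maximum(profile[inside], 0.5 - 0.5 * np.cos(2 * np.pi * u))
    y = np.arange(ny) * dy
    y_in = (y >= spec.y_origin) & (y <= spec.y_origin + spec.n_segments * spec.segment_pitch)
    z = np.arange(nz) * dz
    z_in = np.abs(z - spec.z_center) <= 0.75
    field = (
        z_in[:, None, None].astype(float)
        * y_in[None, :, None].astype(float)
        * profile[None, None, :]
    )
    return field


def _bleb_points(spec: ScaffoldSpec, rng: np.random.Generator) -> np.ndarray:
    """Random bleb (axonal swelling) centres on the cIV tracts of blebbed /
    intact-with-one-bleb segments."""
    if spec.civ_stages is None:
        return np.zeros((0, 3))
    pts = []
    zc = spec.z_center
    for (ya, yb), stage in zip(spec.segment_bounds_y(), spec.civ_stages):
        sides = [s for s in ("left", "right")
                 if not (stage.stage == "ablated" and s in stage.missing_sides)]
        offs = dict(zip(("left", "right"), spec.civ_tract_offsets))
        placed: list[tuple[str, float]] = []
        for _ in range(stage.n_blebs):
            side = sides[rng.integers(len(sides))] if sides else None
            if side is None:
                continue
            # keep blebs on one tract >= 1.5 µm apart so each renders as its
            # own swelling rather than merging with a neighbour
            for _try in range(50):
                y = rng.uniform(ya + 0.5, yb - 0.5)
                if all(abs(y - py) >= 1.5 for ps, py in placed if ps == side):
                    break
            placed.append((side, y))
            pts.append([spec.midline_x + offs[side], y, zc])
    return np.asarray(pts) if pts else np.zeros((0, 3))


# ---------------------------------------------------------------------- main API
def generate_stack(spec: ScaffoldSpec) -> tuple[MultiChannelStack, GroundTruth]:
    """Render a multi-channel stack and its exact ground truth.

    Deterministic given ``spec`` (including ``spec.seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, vd = spec.shape, spec.voxel_dims
    amp = {**_default_intensities(), **spec.intensity_levels}

    civ_polys, stage_records = _civ_polylines(spec)
    ciii_long, ciii_branches = _ciii_polylines(spec)
    landmark_polys = _landmark_polylines(spec)

    civ_tube = _tube_mask(civ_polys, spec.axon_radius, shape, vd)
    ciii_tube = _tube_mask(ciii_long + ciii_branches, spec.axon_radius, shape, vd)
    landmark_tube = _tube_mask(landmark_polys, spec.axon_radius, shape, vd)

    # order of rng consumption is fixed: puncta, blebs, then per-channel noise
    puncta_xyz, puncta_regions = _place_puncta(spec, rng, ciii_long, ciii_branches)
    blebs = _bleb_points(spec, rng)

    civ_raw = amp[CIV] * civ_tube.astype(float)
    if len(blebs):
        civ_raw += _render_puncta(blebs, 1.2 * amp[CIV], 0.45, shape, vd)
    channels = {
        CIV: _blur(civ_raw, spec.psf_sigma, vd),
        CIII: _blur(amp[CIII] * ciii_tube.astype(float), spec.psf_sigma, vd),
        PUNCTA: _render_puncta(puncta_xyz, amp[PUNCTA], spec.puncta_sigma, shape, vd),
        DENDRITE: _blur(amp[DENDRITE] * _dendrite_channel(spec), spec.psf_sigma, vd),
        LANDMARK: _blur(amp[LANDMARK] * landmark_tube.astype(float), spec.psf_sigma, vd),
    }
    # GRASP: membrane contact = cIII tube restricted to the dendritic-field footprint
    dend_support = _dendrite_channel(spec) > 0
    channels[GRASP] = _blur(amp[GRASP] * (ciii_tube & dend_support).astype(float), spec.psf_sigma, vd)

    x_um = np.arange(shape[2])[None, None, :] * vd[2]
    noisy = {}
    for role in _CHANNEL_ORDER:
        expected = channels[role] + spec.noise.background_level + spec.noise.background_gradient * x_um
        expected = np.clip(expected, 0, None)
        if spec.noise.shot_noise:
            img = rng.poisson(expected * spec.noise.gain).astype(np.float64) / spec.noise.gain
        else:
            img = expected
        if spec.noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise.read_noise_sd, size=img.shape)
        noisy[role] = np.clip(img, 0, None).astype(np.float32)

    stack = MultiChannelStack(
        {role: VoxelGrid(noisy[role], vd, channel_role=role) for role in _CHANNEL_ORDER}
    )

    bounds = spec.segment_bounds_y()
    lat, med = spec.dendrite_field_extent
    shift = spec.dendrite_shift_um
    dendrite_roi = [
        {
            "x_medial": spec.midline_x + med + shift,
            "x_lateral": spec.midline_x + lat + shift,
            "y0": ya,
            "y1": yb,
            "z": int(spec.shape[0] // 2),
        }
        for (ya, yb) in bounds
    ]
    truth = GroundTruth(
        puncta_xyz=puncta_xyz,
        puncta_regions=puncta_regions,
        centerlines={
            "civ": civ_polys,
            "ciii": ciii_long + ciii_branches,
            "landmark": landmark_polys,
        },
        midline_x=spec.midline_x,
        segment_bounds_y=bounds,
        scaffold_edge=_scaffold_edge_truth(spec),
        commissure_state={
            "civ": [r["commissure_state"] for r in stage_records],
            "ciii": ["full" if b else "absent" for b in spec.ciii_medial_branch],
        },
        dendrite_roi=dendrite_roi,
        civ_stages=stage_records,
    )
    return stack, truth


def lateral_ciii_length(spec: ScaffoldSpec) -> float:
    """Total lateral-region cIII centerline length (µm): longitudinal tracts
    plus the lateral portions of any crossing branches."""
    longitudinal, branches = _ciii_polylines(spec)
    total = sum(_polyline_length(p) for p in longitudinal)
    for b in branches:
        _, lateral = _branch_pieces(b, spec)
        total += sum(_polyline_length(p) for p in lateral)
    return total


def medial_branch_length(spec: ScaffoldSpec) -> float:
    """Total medial-region cIII centerline length (µm): crossing-branch
    portions medial to the landmark tracts."""
    _, branches = _ciii_polylines(spec)
    total = 0.0
    for b in branches:
        medial, _ = _branch_pieces(b, spec)
        if medial is not None:
            total += _polyline_length(medial)
    return total


def apply_perturbation(spec: ScaffoldSpec, mode: str, params: dict | None = None) -> ScaffoldSpec:
    """Return a new spec with one genetic-manipulation phenotype applied.

    ``civ_ablation``
        Zeroes the cIV channel amplitude (or, when ``stage_per_segment`` is
        given, renders the staged degeneration time course instead) and adds
        medial cIII branches carrying ``medial_puncta_count`` puncta in
        ``medial_branch_fraction`` of segments.
    ``lateralization``
        Removes all cIV commissures; optionally adds ectopic cIII crossing
        in ``ciii_cross_fraction`` of segments.
    ``dendrite_shift``
        Translates the dendritic field laterally by ``shift_um``.
    """
    params = dict(params or {})
    n = spec.n_segments
    if mode == "civ_ablation":
        frac = float(params.pop("medial_branch_fraction", 1.0))
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError("medial_branch_fraction must lie in [0, 1]")
        n_branch = int(round(frac * n))
        branches = tuple(i < n_branch for i in range(n))
        counts = dict(spec.puncta_count_per_region)
        if "medial_puncta_count" in params:
            counts["medial"] = int(params.pop("medial_puncta_count"))
        stage_per_segment = params.pop("stage_per_segment", None)
        new = dataclasses.replace(
            spec,
            ciii_medial_branch=branches,
            puncta_count_per_region=counts,
        )
        if stage_per_segment is not None:
            stages = tuple(
                s if isinstance(s, SegmentStage) else SegmentStage(**s) for s in stage_per_segment
            )
            new = dataclasses.replace(new, civ_stages=stages)
        else:
            levels = dict(new.intensity_levels)
            levels[CIV] = 0.0
            new = dataclasses.replace(new, intensity_levels=levels)
    elif mode == "lateralization":
        frac = float(params.pop("ciii_cross_fraction", 0.5))
        n_cross = int(round(frac * n))
        new = dataclasses.replace(
            spec,
            commissures=tuple("absent" for _ in range(n)),
            ciii_medial_branch=tuple(i < n_cross for i in range(n)),
        )
    elif mode == "dendrite_shift":
        if "shift_um" not in params:
            raise ConfigurationError("dendrite_shift requires params['shift_um']")
        new = dataclasses.replace(spec, dendrite_shift_um=float(params.pop("shift_um")))
    else:
        raise ConfigurationError(f"unknown perturbation mode {mode!r}")
    if params:
        raise ConfigurationError(f"unknown perturbation params for {mode!r}: {sorted(params)}")
    new.validate()
    return new
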