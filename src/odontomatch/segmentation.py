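"""The five segmentation strategies for AM/PM scan comparison.

Extraneous soft-tissue geometry inflates the RMS difference between two scans
of the same person, so scans are segmented before comparison.  Five
strategies are implemented:

* **M1** — no segmentation (control).
* **M2** — semi-automatic gingival reduction: tooth surface plus a retained
  collar of gingiva within ``margin_offset`` mm of any tooth point.
* **M3** — manual gingival reduction: tooth surface only (precise removal
  along the gingival margins into the interdental spaces).
* **M4** — individual planar slice: each scan is cut by its own
  occlusally-oriented plane in its own frame.
* **M5** — joint planar slice (the streamlined strategy): the two scans are
  first superimposed by ICP, a *single* plane is fitted to and cuts the
  combined cloud, and the residual clouds are re-registered.

M2–M4 segment each image individually before registration; M5 segments
jointly after an initial registration.  Plane placement is deterministic
(least-squares plane oriented toward the occlusal side, dropped to the mean
tooth–gingiva boundary height) with an explicit jitter knob emulating
operator landmark-selection variability.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import PointCloud, Tissue
from .records import ComparisonRecord
from .rigid_registration import ICPParams, RigidTransform, icp_register

__all__ = [
    "Plane",
    "SegmentationMethod",
    "SegmentationParams",
    "SegmentedPair",
    "plane_slice",
    "fit_slicing_plane",
    "gingival_reduction",
    "segment_pair",
    "compare_pair",
]


@dataclass(frozen=True)
class Plane:
    """Oriented clipping plane ``{p : normal·p = offset}``.

    The keep side is the non-negative signed distance
    ``s(p) = normal·p − offset >= 0``; points exactly on the plane are
    retained.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, float).reshape(3)
        length = np.linalg.norm(n)
        if length == 0:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "normal", n / length)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points) -> np.ndarray:
        return np.asarray(points, float).reshape(-1, 3) @ self.normal - self.offset

    def mask(self, points) -> np.ndarray:
        """Boolean keep-mask (signed distance >= 0)."""
        return self.signed_distance(points) >= 0.0

    def to_json(self) -> dict:
        return {"normal": [float(x) for x in self.normal], "offset": self.offset}

    @classmethod
    def from_json(cls, data) -> "Plane":
        return cls(np.asarray(data["normal"], float), float(data["offset"]))


class SegmentationMethod(Enum):
    M1_NONE = 1
    M2_SEMI_AUTO_GINGIVAL = 2
    M3_MANUAL_GINGIVAL = 3
    M4_PLANAR = 4
    M5_JOINT_PLANAR = 5

    @classmethod
    def parse(cls, value) -> "SegmentationMethod":
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            return cls(value)
        s = str(value).strip().upper()
        if s.startswith("M") and s[1:].isdigit():
            return cls(int(s[1:]))
        if s.isdigit():
            return cls(int(s))
        return cls[s]

    @property
    def short(self) -> str:
        return f"M{self.value}"


@dataclass
class SegmentationParams:
    """Segmentation tuning knobs.

    ``margin_offset`` — gingival collar retained by M2, mm above the label
    boundary.  ``plane_drop`` — how far below the mean tooth–gingiva boundary
    the M4/M5 plane sits (0 keeps papillae).  ``plane_jitter_sd`` — operator
    variability model: s.d. of a random plane tilt (degrees) and offset shift
    (mm) applied per replicate; 0 disables it.
    """

    margin_offset: float = 0.5
    plane_drop: float = 0.0
    plane_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.margin_offset < 0:
            raise ValueError("margin_offset must be >= 0")
        if self.plane_jitter_sd < 0:
            raise ValueError("plane_jitter_sd must be >= 0")


@dataclass
class SegmentedPair:
    """Output of :func:`segment_pair` for one AM/PM comparison."""

    am_segmented: PointCloud
    pm_segmented: PointCloud
    method: SegmentationMethod
    initial_transform: RigidTransform | None = None  # M5 only
    plane_used: Plane | None = None
    plane_used_b: Plane | None = None  # M4: the PM-side plane
    am_indices: np.ndarray | None = None  # retained indices into the inputs
    pm_indices: np.ndarray | None = None
    provenance: dict | None = None


def plane_slice(cloud: PointCloud, plane: Plane) -> PointCloud:
    """Points on the keep side of the plane (``s >= 0``), order preserved."""
    return cloud.select(plane.mask(cloud.points))


def _boundary_height(s: np.ndarray, tissue, tooth_id) -> float:
    """Mean tooth–gingiva boundary height along the plane normal.

    With tooth ids: mean over teeth of each tooth's lower decile of heights
    (robust proxy for the cervical margin).  With labels only: lower decile
    of all tooth heights.  Unlabeled: the median height.
    """
    if tissue is not None:
        on_tooth = np.asarray(tissue) == int(Tissue.TOOTH)
        if on_tooth.any():
            if tooth_id is not None:
                ids = np.unique(np.asarray(tooth_id)[on_tooth])
                ids = ids[ids != 0]
                if len(ids):
                    per = [np.quantile(s[(np.asarray(tooth_id) == i) & on_tooth], 0.1)
                           for i in ids]
                    return float(np.mean(per))
            return float(np.quantile(s[on_tooth], 0.1))
    return float(np.median(s))


def fit_slicing_plane(cloud: PointCloud, params: SegmentationParams,
                      seed: int | None = None) -> Plane:
    """Fit the occlusally-oriented slicing plane for a cloud.

    Least-squares plane through the cloud, normal flipped toward the side
    holding the greater mass of tooth-labeled points (fallback: the side the
    height distribution is skewed toward), then translated ``plane_drop`` mm
    toward the gingiva from the mean tooth–gingiva boundary height.  With
    ``plane_jitter_sd > 0``, a seeded random tilt and offset emulate operator
    landmark-selection variability.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centroid = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - centroid, full_matrices=False)
    n = Vt[2]
    s = (pts - centroid) @ n
    if cloud.tissue is not None and np.any(np.asarray(cloud.tissue) == int(Tissue.TOOTH)):
        if s[np.asarray(cloud.tissue) == int(Tissue.TOOTH)].mean() < 0:
            n, s = -n, -s
    elif np.mean(s**3) < 0:  # occlusal surfaces stick out on the skewed side
        n, s = -n, -s
    h_b = _boundary_height(s, cloud.tissue, cloud.tooth_id)
    offset = float(n @ centroid) + h_b - params.plane_drop
    if params.plane_jitter_sd > 0:
        rng = np.random.default_rng((params.seed if seed is None else seed) & 0x7FFFFFFF)
        # random tilt of the normal about a random in-plane axis
        axis = rng.normal(size=3)
        axis -= (axis @ n) * n
        axis /= np.linalg.norm(axis)
        ang = np.radians(rng.normal(scale=params.plane_jitter_sd))
        T = RigidTransform.from_axis_angle(axis, ang)
        n_j = T.rotation @ n
        # keep the plane anchored near the boundary point below the centroid
        anchor = centroid + (h_b - params.plane_drop) * n
        offset = float(n_j @ anchor) + rng.normal(scale=params.plane_jitter_sd)
        n = n_j
    return Plane(n, offset)


def gingival_reduction(cloud: PointCloud, mode: str,
                       params: SegmentationParams | None = None) -> PointCloud:
    """Remove gingiva from a labeled cloud.

    ``manual`` retains exactly the tooth-labeled points; ``semi_auto``
    additionally retains gingiva points within ``margin_offset`` mm of any
    tooth point (the collar a margin-following tool leaves behind).  The two
    modes differ only in the extent of soft-tissue removal.
    """
    return cloud.select(_reduction_mask(cloud, mode, params or SegmentationParams()))


def _reduction_mask(cloud: PointCloud, mode: str, sp: SegmentationParams) -> np.ndarray:
    if mode not in ("manual", "semi_auto"):
        raise ValueError("mode must be 'manual' or 'semi_auto'")
    if cloud.tissue is None:
        raise ValueError(
            "gingival reduction needs tissue labels; for unlabeled clouds use "
            "the planar methods (M4/M5)")
    tissue = np.asarray(cloud.tissue)
    keep = tissue == int(Tissue.TOOTH)
    if mode == "semi_auto" and keep.any():
        gi = np.where(tissue == int(Tissue.GINGIVA))[0]
        if len(gi):
            d, _ = cKDTree(cloud.points[keep]).query(cloud.points[gi])
            keep[gi[d <= sp.margin_offset]] = True
    return keep


def _mask_indices(mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(mask)


def segment_pair(am: PointCloud, pm: PointCloud, method,
                 sp: SegmentationParams | None = None,
                 icp: ICPParams | None = None) -> SegmentedPair:
    """Apply one segmentation strategy to an AM/PM cloud pair.

    M2–M4 process each cloud independently in its own frame.  M5 registers
    PM onto AM first (on the full clouds), fits **one** plane to the
    superimposed union, slices both clouds with it, and returns the PM subset
    in its native frame together with the recorded initial transform and
    plane, so the subsequent registration is a genuine re-registration.
    """
    method = SegmentationMethod.parse(method)
    sp = sp or SegmentationParams()
    icp = icp or ICPParams()
    M = SegmentationMethod
    if method is M.M1_NONE:
        return SegmentedPair(am, pm, method,
                             am_indices=np.arange(len(am)),
                             pm_indices=np.arange(len(pm)))
    if method in (M.M2_SEMI_AUTO_GINGIVAL, M.M3_MANUAL_GINGIVAL):
        mode = "semi_auto" if method is M.M2_SEMI_AUTO_GINGIVAL else "manual"
        am_keep = _reduction_mask(am, mode, sp)
        pm_keep = _reduction_mask(pm, mode, sp)
        return SegmentedPair(am.select(am_keep), pm.select(pm_keep), method,
                             am_indices=_mask_indices(am_keep),
                             pm_indices=_mask_indices(pm_keep))
    if method is M.M4_PLANAR:
        plane_a = fit_slicing_plane(am, sp, seed=sp.seed)
        plane_b = fit_slicing_plane(pm, sp, seed=sp.seed + 1)
        ma, mb = plane_a.mask(am.points), plane_b.mask(pm.points)
        return SegmentedPair(am.select(ma), pm.select(mb), method,
                             plane_used=plane_a, plane_used_b=plane_b,
                             am_indices=_mask_indices(ma),
                             pm_indices=_mask_indices(mb))
    # M5: joint planar slice after initial registration
    init = icp_register(pm, am, icp).transform
    pm_in_am = pm.points @ init.rotation.T + init.translation
    union = PointCloud(
        np.vstack([am.points, pm_in_am]),
        None if am.tissue is None or pm.tissue is None
        else np.concatenate([am.tissue, pm.tissue]),
        None if am.tooth_id is None or pm.tooth_id is None
        else np.concatenate([am.tooth_id, pm.tooth_id]),
        am.frame_id)
    plane = fit_slicing_plane(union, sp, seed=sp.seed)
    ma = plane.mask(am.points)
    mb = plane.mask(pm_in_am)
    return SegmentedPair(am.select(ma), pm.select(mb), method,
                         initial_transform=init, plane_used=plane,
                         am_indices=_mask_indices(ma),
                         pm_indices=_mask_indices(mb))


def compare_pair(am: PointCloud, pm: PointCloud, method,
                 sp: SegmentationParams | None = None,
                 icp: ICPParams | None = None,
                 meta: dict | None = None) -> ComparisonRecord:
    """Segment a pair, register PM onto AM, and record the final RMS.

    For M5 the secondary registration is warm-started from the initial
    transform recorded during joint segmentation, mirroring the sequential
    workflow.
    """
    method = SegmentationMethod.parse(method)
    sp = sp or SegmentationParams()
    icp = icp or ICPParams()
    seg = segment_pair(am, pm, method, sp, icp)
    result = icp_register(seg.pm_segmented, seg.am_segmented, icp,
                          init=seg.initial_transform)
    meta = meta or {}
    return ComparisonRecord(
        participant_a=meta.get("participant_a", ""),
        participant_b=meta.get("participant_b", ""),
        arch=meta.get("arch", ""),
        method=method.short,
        replicate=meta.get("replicate", 1),
        session=meta.get("session", 1),
        operator=meta.get("operator", 1),
        is_match=meta.get("is_match",
                          meta.get("participant_a", "") == meta.get("participant_b", "")),
        rms=result.rms,
        plane_used=seg.plane_used,
        timestamp=time.time(),
    )
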