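"""Synthetic dental arches and antemortem/postmortem scan pairs.

No real scan data accompanies the study design this package implements, so
this module generates labeled stand-in anatomy: a full arch of 14 crown
shapes (superellipsoid rounded boxes, second molar to second molar, FDI
numbering) placed along a parabolic arch curve, sitting in a continuous
gingiva ridge with raised interdental papillae between adjacent crowns.

A per-participant random shape jitter (crown dimensions, surface modulation,
placement) supplies the individualizing anatomy that identification relies
on.  The postmortem variant of an arch emulates the impression/stone-cast
capture chain: a smooth low-frequency deformation field (casts distort
smoothly, not per-vertex), i.i.d. vertex noise that is inflated on gingiva
(soft tissue is less consistent than dental hard tissue), and a random rigid
placement whose inverse is returned as the ground-truth PM→AM transform.

All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh_io import LabeledMesh, Tissue
from .rigid_registration import RigidTransform

__all__ = [
    "DentitionParams",
    "DegradationParams",
    "CohortScan",
    "FDI_UPPER",
    "FDI_LOWER",
    "generate_arch",
    "degrade_to_pm",
    "make_cohort",
]

#: FDI two-digit codes, second molar to second molar, patient's right to left
FDI_UPPER = (17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27)
FDI_LOWER = (47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37)

# mesiodistal width of each tooth relative to ``crown_width``
# (second molar .. central incisor, mirrored for the other half)
_WIDTH_FACTORS_HALF = (1.38, 1.45, 0.97, 1.00, 1.09, 0.93, 1.21)

# occluso-cervical crown height relative to ``crown_height``
# (molars short, canines longest)
_HEIGHT_FACTORS_HALF = (0.85, 0.90, 0.95, 0.97, 1.15, 1.02, 1.00)

#: systematic left/right width asymmetry: no dentition is mirror-symmetric,
#: and a perfectly symmetric template would make a mirrored superimposition
#: nearly as good as the true one
_ARCH_ASYMMETRY = 0.04

_CROWN_EMBED_MM = 1.2      # how deep crowns sink below the gingival margin
_PAPILLA_AMP_MM = 0.9      # interdental papilla height above the margin
_PAPILLA_SIGMA_MM = 1.1    # papilla bump width along the arch


class ToothOverlapError(ValueError):
    """Adjacent crowns do not fit on the arch with the requested gap."""


@dataclass
class DentitionParams:
    """Geometry of a synthetic arch.

    ``shape_jitter`` is the dimensionless per-participant perturbation scale
    (~relative s.d. of crown dimensions and surface modulation); 0 produces
    the nominal template arch shared by all participants.
    """

    n_teeth: int = 14
    arch_width: float = 62.0
    arch_depth: float = 52.0
    crown_height: float = 7.0
    crown_width: float = 6.2
    gingiva_band_height: float = 5.0
    inter_tooth_gap: float = 0.5
    shape_jitter: float = 0.05
    arch_type: str = "upper"

    def __post_init__(self):
        if self.n_teeth < 2 or self.n_teeth % 2:
            raise ValueError("n_teeth must be even and >= 2")
        for name in ("arch_width", "arch_depth", "crown_height", "crown_width",
                     "gingiva_band_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.inter_tooth_gap < 0 or self.shape_jitter < 0:
            raise ValueError("inter_tooth_gap and shape_jitter must be >= 0")
        if self.arch_type not in ("upper", "lower"):
            raise ValueError("arch_type must be 'upper' or 'lower'")


@dataclass
class DegradationParams:
    """AM→PM capture-chain degradation applied to an arch."""

    noise_sd: float = 0.05
    deform_amplitude: float = 0.2
    deform_wavelength: float = 25.0
    rigid_offset: RigidTransform | str = "random"
    gingiva_extra_sd: float = 0.1
    mucosa_gradient: float = 2.0
    resample_fraction: float = 1.0
    max_rotation_deg: float = 30.0
    max_translation_mm: float = 20.0

    def __post_init__(self):
        if self.noise_sd < 0 or self.deform_amplitude < 0 or self.gingiva_extra_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.mucosa_gradient < 0:
            raise ValueError("mucosa_gradient must be >= 0")
        if not (0 < self.resample_fraction <= 1):
            raise ValueError("resample_fraction must be in (0, 1]")
        if self.deform_wavelength <= 0:
            raise ValueError("deform_wavelength must be > 0")


@dataclass
class CohortScan:
    """One scan of the simulated cohort (AM or PM capture of one arch)."""

    participant_id: str
    arch: str
    capture: str  # "AM" or "PM"
    mesh: LabeledMesh
    truth_transform: RigidTransform  # PM→AM frame; identity for AM


# ---------------------------------------------------------------------------
# arch construction
# ---------------------------------------------------------------------------

def _fdi_codes(params: DentitionParams):
    codes = FDI_UPPER if params.arch_type == "upper" else FDI_LOWER
    half = params.n_teeth // 2
    if params.n_teeth == 14:
        return codes
    # shrink symmetrically from the distal ends for reduced tooth counts
    return codes[7 - half: 7 + half] if half <= 7 else codes


def _mirrored(template, n_teeth: int) -> np.ndarray:
    half = n_teeth // 2
    left = template[-half:] if half <= 7 else template
    return np.array(left + tuple(reversed(left)), float)[:n_teeth]


def _width_factors(n_teeth: int) -> np.ndarray:
    w = _mirrored(_WIDTH_FACTORS_HALF, n_teeth)
    half = n_teeth // 2
    w[:half] *= 1.0 + _ARCH_ASYMMETRY
    w[half:] *= 1.0 - _ARCH_ASYMMETRY
    return w


def _height_factors(n_teeth: int) -> np.ndarray:
    return _mirrored(_HEIGHT_FACTORS_HALF, n_teeth)


def _arch_curve(a: float, b: float, n: int = 2001):
    """Parabolic arch curve y = b (1 − (x/a)²), sampled with arc lengths."""
    x = np.linspace(-a, a, n)
    y = b * (1.0 - (x / a) ** 2)
    pts = np.column_stack([x, y])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s


def _unit_sphere_grid(n_lat: int = 11, n_lon: int = 18):
    """Closed UV-sphere directions and faces (poles included)."""
    dirs = [np.array([0.0, 0.0, 1.0])]
    for i in range(1, n_lat):
        th = np.pi * i / n_lat
        for j in range(n_lon):
            ph = 2 * np.pi * j / n_lon
            dirs.append(np.array([np.sin(th) * np.cos(ph),
                                  np.sin(th) * np.sin(ph), np.cos(th)]))
    dirs.append(np.array([0.0, 0.0, -1.0]))
    dirs = np.array(dirs)
    faces = []
    def ring(i, j):  # vertex index of ring i (1-based), longitude j
        return 1 + (i - 1) * n_lon + (j % n_lon)
    for j in range(n_lon):  # top cap
        faces.append([0, ring(1, j), ring(1, j + 1)])
    for i in range(1, n_lat - 1):  # bands
        for j in range(n_lon):
            faces.append([ring(i, j), ring(i + 1, j), ring(i + 1, j + 1)])
            faces.append([ring(i, j), ring(i + 1, j + 1), ring(i, j + 1)])
    south = len(dirs) - 1
    for j in range(n_lon):  # bottom cap
        faces.append([south, ring(n_lat - 1, j + 1), ring(n_lat - 1, j)])
    return dirs, np.array(faces, np.int64)


_SPHERE_DIRS, _SPHERE_FACES = _unit_sphere_grid()


def _superellipsoid_crown(semi_axes, exponent, rng, jitter) -> np.ndarray:
    """Crown vertex positions in the local frame (tangent, normal, vertical).

    Radius along direction d solves |dx/a|^p + |dy/b|^p + |dz/c|^p = 1, with a
    random zero-mean quadratic surface modulation of relative scale ``jitter``
    so crowns differ in shape, not just in their bounding box.
    """
    a, b, c = semi_axes
    d = _SPHERE_DIRS
    r = (np.abs(d[:, 0] / a) ** exponent + np.abs(d[:, 1] / b) ** exponent
         + np.abs(d[:, 2] / c) ** exponent) ** (-1.0 / exponent)
    if jitter > 0:
        coef = rng.normal(scale=jitter, size=6)
        quad = (coef[0] * d[:, 0] * d[:, 1] + coef[1] * d[:, 1] * d[:, 2]
                + coef[2] * d[:, 0] * d[:, 2] + coef[3] * (d[:, 0] ** 2 - d[:, 2] ** 2)
                + coef[4] * (d[:, 1] ** 2 - d[:, 2] ** 2) + coef[5] * d[:, 2])
        r = r * (1.0 + quad)
    return d * r[:, None]


def generate_arch(params: DentitionParams, participant_seed: int) -> LabeledMesh:
    """Generate one labeled synthetic arch, deterministic per seed.

    The gingival margin sits at z = 0 with the occlusal direction +z; crowns
    span roughly z ∈ [−1.2, crown_height] and the gingiva ridge descends to
    z = −gingiva_band_height, with papillae rising between adjacent crowns.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(participant_seed) & 0x7FFFFFFF, 0 if params.arch_type == "upper" else 1]))
    jit = params.shape_jitter

    # per-participant global arch perturbation
    a = params.arch_width / 2 * (1 + 0.4 * jit * rng.standard_normal())
    b = params.arch_depth * (1 + 0.4 * jit * rng.standard_normal())
    if params.arch_type == "lower":
        a, b = 0.95 * a, 0.95 * b

    curve, arclen = _arch_curve(a, b)
    total_len = arclen[-1]

    n = params.n_teeth
    widths = params.crown_width * _width_factors(n)
    widths = widths * (1 + jit * rng.standard_normal(n))
    heights = _height_factors(n)
    fdi = _fdi_codes(params)

    # width-proportional center spacing with the leftover slack spread evenly
    required = float(np.sum(0.5 * (widths[:-1] + widths[1:]) + params.inter_tooth_gap))
    slack = total_len - required - widths[0] / 2 - widths[-1] / 2
    if slack < 0:
        worst = int(np.argmax(widths[:-1] + widths[1:]))
        raise ToothOverlapError(
            f"teeth {fdi[worst]} and {fdi[worst + 1]} do not fit: arch curve is "
            f"{total_len:.1f} mm but crowns+gaps need {required + widths[0]/2 + widths[-1]/2:.1f} mm")
    spacing = 0.5 * (widths[:-1] + widths[1:]) + params.inter_tooth_gap + slack / (n - 1)
    centers_s = widths[0] / 2 + slack * 0.0 + np.concatenate([[0.0], np.cumsum(spacing)])
    centers_s += (total_len - (centers_s[-1] - centers_s[0])) / 2 - centers_s[0]

    # interpolate curve positions and tangents at the tooth centers
    cx = np.interp(centers_s, arclen, curve[:, 0])
    cy = np.interp(centers_s, arclen, curve[:, 1])
    eps = 1e-3
    tx = np.interp(centers_s + eps, arclen, curve[:, 0]) - np.interp(centers_s - eps, arclen, curve[:, 0])
    ty = np.interp(centers_s + eps, arclen, curve[:, 1]) - np.interp(centers_s - eps, arclen, curve[:, 1])
    tang = np.column_stack([tx, ty])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    # outward normal: away from the arch interior (centroid of the curve)
    interior = curve.mean(axis=0)
    norm_xy = np.column_stack([tang[:, 1], -tang[:, 0]])
    out = np.column_stack([cx, cy]) - interior
    flip = np.sum(norm_xy * out, axis=1) < 0
    norm_xy[flip] = -norm_xy[flip]

    verts, faces, tissue, tooth = [], [], [], []
    offset = 0
    for i in range(n):
        semi = (widths[i] / 2,
                0.55 * widths[i] * (1 + jit * rng.standard_normal()),
                (params.crown_height * heights[i] + _CROWN_EMBED_MM) / 2
                * (1 + jit * rng.standard_normal()))
        exponent = 3.5 * (1 + 0.5 * jit * rng.standard_normal())
        local = _superellipsoid_crown(semi, max(2.2, exponent), rng, jit)
        # local frame: x' = tangent, y' = outward normal, z' = vertical
        ex = np.array([tang[i, 0], tang[i, 1], 0.0])
        ey = np.array([norm_xy[i, 0], norm_xy[i, 1], 0.0])
        ez = np.array([0.0, 0.0, 1.0])
        world = local[:, 0:1] * ex + local[:, 1:2] * ey + local[:, 2:3] * ez
        center = np.array([cx[i], cy[i], -_CROWN_EMBED_MM + semi[2]])
        center[:2] += jit * rng.standard_normal(2)  # placement jitter
        world = world + center
        verts.append(world)
        faces.append(_SPHERE_FACES + offset)
        tissue.append(np.full(len(world), int(Tissue.TOOTH), np.int8))
        tooth.append(np.full(len(world), fdi[i], np.int16))
        offset += len(world)

    gv, gf = _gingiva_band(curve, arclen, norm_interior=interior,
                           centers_s=centers_s,
                           half_width=0.85 * params.crown_width,
                           band_height=params.gingiva_band_height, rng=rng, jitter=jit)
    verts.append(gv)
    faces.append(gf + offset)
    tissue.append(np.full(len(gv), int(Tissue.GINGIVA), np.int8))
    tooth.append(np.zeros(len(gv), np.int16))

    mesh = LabeledMesh(np.vstack(verts), np.vstack(faces),
                       np.concatenate(tissue), np.concatenate(tooth),
                       frame_id=f"{params.arch_type}")
    return mesh


def _gingiva_band(curve, arclen, norm_interior, centers_s, half_width,
                  band_height, rng, jitter, n_along: int = 160, n_across: int = 9):
    """Gingiva ridge surface along the arch with interdental papillae."""
    s = np.linspace(arclen[0], arclen[-1], n_along)
    px = np.interp(s, arclen, curve[:, 0])
    py = np.interp(s, arclen, curve[:, 1])
    eps = 1e-3
    tx = np.interp(s + eps, arclen, curve[:, 0]) - np.interp(s - eps, arclen, curve[:, 0])
    ty = np.interp(s + eps, arclen, curve[:, 1]) - np.interp(s - eps, arclen, curve[:, 1])
    t = np.column_stack([tx, ty])
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    nrm = np.column_stack([t[:, 1], -t[:, 0]])
    flip = np.sum(nrm * (np.column_stack([px, py]) - norm_interior), axis=1) < 0
    nrm[flip] = -nrm[flip]

    # papilla crest height profile: bumps at interdental midpoints
    mids = 0.5 * (centers_s[:-1] + centers_s[1:])
    top = np.zeros_like(s)
    for m in mids:
        top += _PAPILLA_AMP_MM * np.exp(-0.5 * ((s - m) / _PAPILLA_SIGMA_MM) ** 2)
    if jitter > 0:  # slow per-participant undulation of the margin line
        ph = rng.uniform(0, 2 * np.pi, 2)
        top += jitter * 4.0 * (np.sin(2 * np.pi * s / arclen[-1] * 2 + ph[0])
                               + 0.5 * np.sin(2 * np.pi * s / arclen[-1] * 5 + ph[1]))

    v = np.linspace(-1.0, 1.0, n_across)
    zz = top[:, None] - (top[:, None] + band_height) * np.abs(v[None, :]) ** 1.7
    xx = px[:, None] + nrm[:, 0][:, None] * (v[None, :] * half_width)
    yy = py[:, None] + nrm[:, 1][:, None] * (v[None, :] * half_width)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(n_along - 1):
        for j in range(n_across - 1):
            p = i * n_across + j
            faces.append([p, p + n_across, p + n_across + 1])
            faces.append([p, p + n_across + 1, p + 1])
    return verts, np.array(faces, np.int64)


# ---------------------------------------------------------------------------
# AM -> PM degradation
# ---------------------------------------------------------------------------

def degrade_to_pm(am: LabeledMesh, d: DegradationParams,
                  seed: int) -> tuple[LabeledMesh, RigidTransform]:
    """Produce the postmortem variant of an arch plus the ground truth.

    Applies (i) a smooth displacement field — three random low-frequency
    sinusoidal modes per axis, total amplitude bounded by
    ``deform_amplitude`` — (ii) i.i.d. per-vertex jitter of s.d. ``noise_sd``
    (plus ``gingiva_extra_sd`` on gingiva vertices), and (iii) a rigid
    placement offset.  Returns the PM mesh and the inverse rigid transform
    (PM→AM frame) as ground truth; labels are preserved.
    """
    if am.n_vertices == 0:
        raise ValueError("cannot degrade an empty mesh")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    v = am.vertices.copy()

    if d.deform_amplitude > 0:
        # split the amplitude budget over axes (simplex) and, per axis, over
        # 3 modes, so the worst-case displacement norm is <= deform_amplitude
        w = rng.dirichlet(np.ones(3))
        axis_amp = d.deform_amplitude * np.sqrt(w)  # sqrt: norm of maxima = amplitude
        disp = np.zeros_like(v)
        for k in range(3):
            mode_w = rng.dirichlet(np.ones(3))
            for m in range(3):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                phase = rng.uniform(0, 2 * np.pi)
                disp[:, k] += (axis_amp[k] * mode_w[m]
                               * np.sin(2 * np.pi * (v @ u) / d.deform_wavelength + phase))
        v = v + disp

    sd = np.full(am.n_vertices, float(d.noise_sd))
    ging = am.tissue == int(Tissue.GINGIVA)
    if ging.any():
        # soft tissue is least reproducible away from the gingival margin:
        # the extra s.d. is gingiva_extra_sd at the crest and grows linearly
        # (by mucosa_gradient x) toward the depth of the band, emulating
        # mobile alveolar mucosa vs firmly attached marginal gingiva
        gz = v[ging, 2]
        hi, lo = np.quantile(gz, 0.95), np.quantile(gz, 0.05)
        depth = np.clip((hi - gz) / max(hi - lo, 1e-9), 0.0, 1.0)
        sd[ging] += d.gingiva_extra_sd * (1.0 + d.mucosa_gradient * depth)
    if np.any(sd > 0):
        v = v + rng.standard_normal(v.shape) * sd[:, None]

    faces = am.faces
    tissue, tooth = am.tissue, am.tooth_id
    if d.resample_fraction < 1.0:  # partial capture: keep a random face subset
        m = len(faces)
        keep_f = np.sort(rng.choice(m, max(1, int(round(d.resample_fraction * m))),
                                    replace=False))
        faces = faces[keep_f]
        used = np.unique(faces)
        remap = -np.ones(am.n_vertices, np.int64)
        remap[used] = np.arange(len(used))
        v, faces = v[used], remap[faces]
        tissue, tooth = tissue[used], tooth[used]

    if isinstance(d.rigid_offset, RigidTransform):
        T = d.rigid_offset
    elif d.rigid_offset == "random":
        T = RigidTransform.random(rng, np.radians(d.max_rotation_deg),
                                  d.max_translation_mm)
    else:
        raise ValueError("rigid_offset must be a RigidTransform or 'random'")

    pm = LabeledMesh(T.apply(v), faces, tissue, tooth,
                     frame_id=am.frame_id + "-pm")
    return pm, T.inverse()


def make_cohort(n_participants: int,
                dp: DentitionParams | None = None,
                deg: DegradationParams | None = None,
                seed: int = 0) -> list[CohortScan]:
    """Simulate the study cohort: per participant, upper and lower arches,
    each captured once directly (AM) and once via the cast chain (PM)."""
    if n_participants < 2:
        raise ValueError("need at least 2 participants for non-matching pairs")
    dp = dp or DentitionParams()
    deg = deg or DegradationParams()
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    scans: list[CohortScan] = []
    for p in range(1, n_participants + 1):
        pid = f"P{p}"
        pseed = int(rng.integers(0, 2**31 - 1))
        for arch in ("upper", "lower"):
            am = generate_arch(replace(dp, arch_type=arch), pseed)
            am = replace_frame(am, f"{pid}-{arch}-AM")
            pm, truth = degrade_to_pm(am, deg, int(rng.integers(0, 2**31 - 1)))
            pm = replace_frame(pm, f"{pid}-{arch}-PM")
            scans.append(CohortScan(pid, arch, "AM", am, RigidTransform.identity()))
            scans.append(CohortScan(pid, arch, "PM", pm, truth))
    return scans


def replace_frame(mesh: LabeledMesh, frame_id: str) -> LabeledMesh:
    return LabeledMesh(mesh.vertices, mesh.faces, mesh.tissue, mesh.tooth_id, frame_id)
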