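"""Seeded synthetic LV phantom: image, wall mask, mesh, EGMs, pace sites.

The phantom emulates the regime of a porcine ischaemia–reperfusion study
mapped with an MR-guided electrophysiology system:

* LV geometry is an ellipsoidal half-shell (truncated at a basal plane),
  not an anatomical ventricle — the analytic membership test makes every
  downstream geometric result checkable by brute force.
* Scar is a transmural antero-septal sector of the wall, parameterised by
  an azimuthal window and an apical axial fraction.
* The LGE-like image draws voxel intensities per class (blood pool, normal
  wall, scar wall); scar is hyper-intense.
* Bipolar voltages are class-conditional log-normal (strictly positive,
  right-skewed, scar low / normal high, overlapping tails); S-QRS delays
  are class-conditional Gaussians truncated at zero, longer in scar; scar
  pace sites fail to capture with a configurable probability.
* Image and mapping coordinate frames differ by a known rigid transform;
  the mesh and all electrical samples live in the mapping frame, the image
  and its masks in the image frame. Noisy landmark correspondences allow
  the transform to be recovered.

All randomness flows from one integer seed; each operation derives its own
child stream with a fixed spawn key, so outputs are reproducible both for a
full phantom build and for each operation called in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .eam import EgmSample, PaceSite
from .mesh import NodeBinaryMap, SurfaceMesh
from .transforms import LandmarkSet, RigidTransform
from .volume import ImageVolume, LabelVolume


class PhantomConfigError(ValueError):
    pass


# spawn keys for per-operation child RNG streams
_STREAM_IMAGE = 0
_STREAM_EGM = 1
_STREAM_PACE = 2
_STREAM_LANDMARKS = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _default_frame_transform() -> RigidTransform:
    # misalignment on the scale reported for image-integration workflows:
    # a few degrees of rotation and a few mm of translation
    return RigidTransform.from_euler_deg(rx=3.0, ry=-2.0, rz=7.0,
                                         translation=(4.0, -3.0, 2.0))


@dataclass
class PhantomConfig:
    """All knobs of the synthetic LV phantom.

    Distribution parameters: ``voltage_model`` maps class name to
    (median mV, log-SD) of a log-normal; ``sqrs_model`` maps class name to
    (mean ms, SD ms) of a Gaussian truncated at 0; ``intensity_model`` maps
    region to (mean, SD) in arbitrary signal units.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.2, 1.2, 1.2)
    lv_center_mm: tuple[float, float, float] = (38.4, 38.4, 48.0)
    endo_radius_mm: tuple[float, float, float] = (20.0, 20.0, 32.0)
    wall_thickness_mm: float = 8.0
    scar_center_deg: float = 0.0
    scar_angular_extent_deg: float = 60.0
    scar_axial_extent_frac: float = 0.8
    intensity_model: dict = field(default_factory=lambda: {
        "blood": (70.0, 5.0), "normal_wall": (30.0, 3.0), "scar_wall": (90.0, 9.0)})
    voltage_model: dict = field(default_factory=lambda: {
        "normal": (3.8, 0.5), "scar": (0.8, 0.5)})
    sqrs_model: dict = field(default_factory=lambda: {
        "normal": (25.0, 8.0), "scar": (60.0, 10.0)})
    capture_failure_prob: float = 0.15
    n_egm: int = 445
    n_pace: int = 113
    scar_sample_weight: float = 3.0   # oversampling of scar vertices (focused mapping)
    egm_jitter_mm: float = 1.0
    lat_speed_ms_per_mm: float = 0.6
    lat_scar_delay_ms: float = 15.0
    lat_noise_ms: float = 4.0
    mesh_n_theta: int = 96
    mesh_n_phi: int = 48
    frame_transform: RigidTransform = field(default_factory=_default_frame_transform)
    n_landmarks: int = 8
    landmark_noise_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.endo_radius_mm = tuple(np.broadcast_to(
            np.asarray(self.endo_radius_mm, dtype=float), (3,)))
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomConfigError("voxel spacing must be positive")
        if any(s <= 0 for s in self.grid_shape):
            raise PhantomConfigError("grid shape must be positive")
        if self.wall_thickness_mm <= 0:
            raise PhantomConfigError("wall thickness must be positive")
        if min(self.endo_radius_mm) <= self.wall_thickness_mm / 2:
            raise PhantomConfigError("endocardial radius must exceed half the wall thickness")
        if not (0 <= self.capture_failure_prob <= 1):
            raise PhantomConfigError("capture_failure_prob must be in [0, 1]")
        if self.scar_angular_extent_deg < 0 or not (0 <= self.scar_axial_extent_frac <= 1):
            raise PhantomConfigError("scar extent parameters out of range")
        for cls, (med, lsd) in self.voltage_model.items():
            if med < 0 or lsd < 0:
                raise PhantomConfigError(f"voltage model for {cls!r} out of range")
        for cls, (_, sd) in self.sqrs_model.items():
            if sd < 0:
                raise PhantomConfigError(f"S-QRS SD for {cls!r} must be >= 0")
        if self.n_egm < 0 or self.n_pace < 0:
            raise PhantomConfigError("sample counts must be >= 0")
        if self.egm_jitter_mm < 0 or self.landmark_noise_mm < 0:
            raise PhantomConfigError("noise magnitudes must be >= 0")

    @property
    def epi_radius_mm(self) -> np.ndarray:
        return np.asarray(self.endo_radius_mm) + self.wall_thickness_mm

    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0], A[1, 1], A[2, 2] = self.spacing_mm
        return A

    def with_seed(self, seed: int) -> "PhantomConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Truth channel for recovery tests: what the generator actually built."""

    scar_voxel_mask: LabelVolume
    node_scar_labels: NodeBinaryMap
    true_transform: RigidTransform


def _angular_in_window(theta_deg: np.ndarray, config: PhantomConfig) -> np.ndarray:
    if config.scar_angular_extent_deg == 0:
        return np.zeros_like(theta_deg, dtype=bool)
    d = (theta_deg - config.scar_center_deg + 180.0) % 360.0 - 180.0
    return np.abs(d) <= config.scar_angular_extent_deg / 2.0


def scar_membership(points_mm: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Analytic test: does each (image-frame) point lie in the scar window?

    The window is an azimuthal sector around ``scar_center_deg`` combined
    with the apical axial fraction ``scar_axial_extent_frac`` of the
    half-shell's depth below the basal plane. Wall membership is tested
    separately; scar voxels are the intersection of the two.
    """
    p = np.atleast_2d(points_mm) - np.asarray(config.lv_center_mm)
    theta = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    span = config.epi_radius_mm[2]
    s = -p[:, 2] / span  # 0 at basal plane, 1 at the epicardial apex
    axial_ok = s >= (1.0 - config.scar_axial_extent_frac)
    return _angular_in_window(theta, config) & axial_ok


def wall_membership(points_mm: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Analytic test: point inside the truncated ellipsoidal wall shell."""
    p = np.atleast_2d(points_mm) - np.asarray(config.lv_center_mm)
    u = np.linalg.norm(p / np.asarray(config.endo_radius_mm), axis=1)
    v = np.linalg.norm(p / config.epi_radius_mm, axis=1)
    return (u >= 1.0) & (v <= 1.0) & (p[:, 2] <= 0.0)


def blood_membership(points_mm: np.ndarray, config: PhantomConfig) -> np.ndarray:
    p = np.atleast_2d(points_mm) - np.asarray(config.lv_center_mm)
    u = np.linalg.norm(p / np.asarray(config.endo_radius_mm), axis=1)
    return (u < 1.0) & (p[:, 2] <= 0.0)


def _stitch_rings(idx_a: list[int], ang_a: list[float],
                  idx_b: list[int], ang_b: list[float]) -> list[list[int]]:
    """Triangulate the band between two closed vertex rings.

    Classic two-pointer merge on azimuth: always advance the ring whose
    next vertex comes first, emitting one triangle per step. Works for
    rings of different vertex counts.
    """
    ia = idx_a + [idx_a[0]]
    ib = idx_b + [idx_b[0]]
    aa = ang_a + [ang_a[0] + 2.0 * np.pi]
    ab = ang_b + [ang_b[0] + 2.0 * np.pi]
    faces = []
    i = j = 0
    while i < len(idx_a) or j < len(idx_b):
        if j >= len(idx_b) or (i < len(idx_a) and aa[i + 1] <= ab[j + 1]):
            faces.append([ia[i], ib[j], ia[i + 1]])
            i += 1
        else:
            faces.append([ia[i], ib[j], ib[j + 1]])
            j += 1
    return faces


def _endo_half_shell_mesh(config: PhantomConfig) -> SurfaceMesh:
    """Triangulate the endocardial half-ellipsoid: apex fan + latitude rings.

    Each ring carries a vertex count proportional to its circumference
    (``mesh_n_theta`` at the basal rim), so vertex spacing stays nearly
    uniform from apex to base instead of crowding at the pole. Vertices
    are in the image frame; callers transform to the mapping frame.
    """
    a, b, c = config.endo_radius_mm
    cx, cy, cz = config.lv_center_mm
    n_t, n_p = config.mesh_n_theta, config.mesh_n_phi
    verts = [np.array([cx, cy, cz - c])]  # apex, always vertex 0
    ring_idx: list[list[int]] = []
    ring_ang: list[list[float]] = []
    for j in range(1, n_p + 1):
        phi = (j / n_p) * (np.pi / 2.0)
        n_j = max(6, int(round(n_t * np.sin(phi))))
        idxs, angs = [], []
        for i in range(n_j):
            th = 2.0 * np.pi * i / n_j
            idxs.append(len(verts))
            angs.append(th)
            verts.append(np.array([
                cx + a * np.sin(phi) * np.cos(th),
                cy + b * np.sin(phi) * np.sin(th),
                cz - c * np.cos(phi)]))
        ring_idx.append(idxs)
        ring_ang.append(angs)
    faces = []
    first = ring_idx[0]
    for i in range(len(first)):
        faces.append([0, first[i], first[(i + 1) % len(first)]])
    for j in range(n_p - 1):
        faces.extend(_stitch_rings(ring_idx[j], ring_ang[j],
                                   ring_idx[j + 1], ring_ang[j + 1]))
    return SurfaceMesh(np.array(verts), np.array(faces))


def make_lv_phantom(config: PhantomConfig
                    ) -> tuple[ImageVolume, LabelVolume, SurfaceMesh, GroundTruth]:
    """Build the LGE-like image, LV wall mask, endocardial mesh and truth.

    The image and wall/scar masks are in the image frame; the returned mesh
    is in the mapping frame (the true frame transform has been applied to
    its vertices), as a mapping system's chamber shell would be.
    """
    rng = _rng(config.seed, _STREAM_IMAGE)
    shape = config.grid_shape
    affine = config.affine()
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centers = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = centers * np.asarray(config.spacing_mm)

    wall = wall_membership(world, config)
    blood = blood_membership(world, config)
    scar = wall & scar_membership(world, config)

    img = np.zeros(len(world))
    for region, mask in (("blood", blood), ("normal_wall", wall & ~scar), ("scar_wall", scar)):
        mean, sd = config.intensity_model[region]
        img[mask] = rng.normal(mean, sd, size=int(mask.sum()))

    image = ImageVolume(img.reshape(shape), affine)
    wall_vol = LabelVolume(wall.reshape(shape).astype(np.uint8), affine)
    scar_vol = LabelVolume(scar.reshape(shape).astype(np.uint8), affine)

    endo = _endo_half_shell_mesh(config)
    node_labels = NodeBinaryMap(scar_membership(endo.vertices, config).astype(np.uint8))
    mesh = endo.transformed(config.frame_transform)

    truth = GroundTruth(scar_vol, node_labels, config.frame_transform)
    return image, wall_vol, mesh, truth


def _sample_vertices(mesh: SurfaceMesh, labels: NodeBinaryMap, n: int,
                     weight: float, rng: np.random.Generator) -> np.ndarray:
    w = np.where(labels.labels > 0, weight, 1.0).astype(float)
    return rng.choice(mesh.n_vertices, size=n, replace=True, p=w / w.sum())


def _check_lognormal(model: dict) -> None:
    for cls, (median, _) in model.items():
        if median <= 0:
            raise PhantomConfigError(
                f"voltage median for {cls!r} must be > 0 mV (log-normal), got {median}")


def simulate_egm_samples(mesh: SurfaceMesh, labels: NodeBinaryMap,
                         config: PhantomConfig) -> list[EgmSample]:
    """Draw electrogram samples at (jittered) mesh vertices.

    Scar vertices are oversampled by ``scar_sample_weight``, emulating
    mapping focused on the imaged scar. Voltages are class-conditional
    log-normal; LAT is a smooth apex-to-base activation ramp plus a scar
    delay and Gaussian noise. Positions are in the mapping frame.
    """
    if len(labels.labels) != mesh.n_vertices:
        raise PhantomConfigError("labels must be defined on mesh vertices")
    _check_lognormal(config.voltage_model)
    rng = _rng(config.seed, _STREAM_EGM)
    idx = _sample_vertices(mesh, labels, config.n_egm, config.scar_sample_weight, rng)
    apex = mesh.vertices[0]
    samples: list[EgmSample] = []
    for i in idx:
        cls = int(labels.labels[i])
        name = "scar" if cls else "normal"
        median, log_sd = config.voltage_model[name]
        voltage = float(rng.lognormal(mean=np.log(median), sigma=log_sd))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(0.0, config.egm_jitter_mm)
        pos = mesh.vertices[i] + radius * direction
        dist = float(np.linalg.norm(mesh.vertices[i] - apex))
        lat = (config.lat_speed_ms_per_mm * dist
               + config.lat_scar_delay_ms * cls
               + float(rng.normal(0.0, config.lat_noise_ms)))
        samples.append(EgmSample(pos, voltage, lat_ms=lat, true_class=cls))
    return samples


def simulate_pace_sites(mesh: SurfaceMesh, labels: NodeBinaryMap,
                        config: PhantomConfig) -> list[PaceSite]:
    """Draw pace sites; scar sites fail to capture with the configured
    probability, captured sites carry a truncated-Gaussian S-QRS delay."""
    if len(labels.labels) != mesh.n_vertices:
        raise PhantomConfigError("labels must be defined on mesh vertices")
    rng = _rng(config.seed, _STREAM_PACE)
    idx = _sample_vertices(mesh, labels, config.n_pace, config.scar_sample_weight, rng)
    sites: list[PaceSite] = []
    for i in idx:
        cls = int(labels.labels[i])
        name = "scar" if cls else "normal"
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = mesh.vertices[i] + rng.uniform(0.0, config.egm_jitter_mm) * direction
        captured = True
        if cls and rng.random() < config.capture_failure_prob:
            captured = False
        if captured:
            mean, sd = config.sqrs_model[name]
            if sd == 0:
                s_qrs = float(max(mean, 0.0))
            else:
                a = (0.0 - mean) / sd
                s_qrs = float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                                  random_state=rng))
            sites.append(PaceSite(pos, True, s_qrs_ms=s_qrs, true_class=cls))
        else:
            sites.append(PaceSite(pos, False, true_class=cls))
    return sites


def make_landmarks(config: PhantomConfig) -> LandmarkSet:
    """Noisy landmark correspondences between image and mapping frames.

    Registration landmarks are picked in the blood pools of several
    chambers, so the sources spread over a heart-sized region (about 1.5x
    the LV radius around the LV centre), well beyond the LV cavity itself;
    the wide baseline is what stabilises the rotation estimate.
    Destinations are the true transform of the sources plus isotropic
    Gaussian noise of ``landmark_noise_mm``.
    """
    if config.n_landmarks < 3:
        raise PhantomConfigError(f"need >= 3 landmarks, got {config.n_landmarks}")
    rng = _rng(config.seed, _STREAM_LANDMARKS)
    center = np.asarray(config.lv_center_mm)
    half = 1.5 * np.asarray(config.endo_radius_mm)
    for _ in range(100):
        src = center + rng.uniform(-1.0, 1.0, size=(config.n_landmarks, 3)) * half
        centered = src - src.mean(axis=0)
        if np.linalg.svd(centered, compute_uv=False)[1] > 1e-6:
            break
    dst = config.frame_transform.apply(src)
    if config.landmark_noise_mm > 0:
        dst = dst + rng.normal(0.0, config.landmark_noise_mm, size=dst.shape)
    return LandmarkSet(src, dst)
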