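"""Synthetic digital-brain phantom with known transport ground truth.

The phantom is an ellipsoidal "brain" carrying polyline arteries with
periarterial shells, ellipsoidal ventricles, a tissue-dependent
pre-contrast T1 map, and a point infusion near the caudal ventral
surface.  Its geometry is parametric and deliberately simple; it exists
so every downstream stage (relaxometry, segmentation, meshing, solving,
fitting) can be exercised against exact ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .discretization import build_mesh, tag_subdomains
from .relaxometry import AcquisitionParams, ConcentrationSeries, SignalSeries, spgr_signal
from .solver import SolverConfig, SourceSpec, TransportParams, sample_to_voxels, solve_transport
from .subdomains import Subdomain

__all__ = [
    "ArteryPath",
    "PhantomSpec",
    "ArtifactSpec",
    "GroundTruth",
    "build_phantom",
    "simulate_truth",
    "synthesize_signal",
    "default_spec",
    "injection_location_mm",
]


@dataclass
class ArteryPath:
    """Centerline polyline (mm) with a radius and a class tag."""

    points: np.ndarray  # (K, 3) mm
    radius: float  # mm
    kind: str  # "surface" | "branching"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.radius <= 0:
            raise ValueError("artery radius must be positive")
        if self.kind not in ("surface", "branching"):
            raise ValueError(f"unknown artery kind {self.kind!r}")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: float = 0.1  # mm
    brain_semi_axes: tuple[float, float, float] = (2.9, 2.9, 2.1)  # mm
    artery_paths: list[ArteryPath] = field(default_factory=list)
    pas_shell_voxels: dict[str, int] = field(
        default_factory=lambda: {"surface": 7, "branching": 3}
    )
    ventricle_centers_radii: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=list
    )
    t1_by_tissue: dict[int, float] = field(
        default_factory=lambda: {
            int(Subdomain.BT): 1800.0,
            int(Subdomain.PAS_SURF): 2400.0,
            int(Subdomain.PAS_BRANCH): 2400.0,
            int(Subdomain.ARTERY): 800.0,
            int(Subdomain.VENTRICLE): 4000.0,
        }
    )
    t1_jitter: float = 0.0  # fractional within-tissue sd
    injection_site: tuple[int, int, int] | None = None  # voxel coordinate
    seed: int = 0

    # thresholds the segmentation stage will use; stored so construction
    # can guarantee recoverability
    artery_t1_max: float = 1200.0
    ventricle_t1_min: float = 3000.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.brain_semi_axes):
            raise ValueError("brain semi-axes must be positive")
        for lab, t1 in self.t1_by_tissue.items():
            if not 500.0 <= t1 <= 4500.0:
                raise ValueError(f"T1 for tissue {lab} outside 500-4500 ms: {t1}")
        if self.t1_by_tissue[int(Subdomain.ARTERY)] >= self.artery_t1_max:
            raise ValueError("artery T1 must lie below the artery threshold")
        if self.t1_by_tissue[int(Subdomain.VENTRICLE)] <= self.ventricle_t1_min:
            raise ValueError("ventricle T1 must lie above the ventricle threshold")

    @property
    def center(self) -> np.ndarray:
        return 0.5 * np.asarray(self.grid_shape) * self.voxel_size

    @property
    def box_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * self.voxel_size


@dataclass
class ArtifactSpec:
    """Measurement-noise and susceptibility-dropout model."""

    noise_model: str = "gaussian"  # or "rician"
    noise_sigma: float = 0.02  # fraction of mean in-brain baseline signal
    surface_dropout_voxels: int = 1
    injection_dropout: float = 30.0  # mM; suppress signal above this concentration
    dropout_factor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0 <= self.surface_dropout_voxels <= 3:
            raise ValueError("surface dropout thickness must be in [0, 3] voxels")


@dataclass
class GroundTruth:
    spec: PhantomSpec
    labels: np.ndarray  # int8 volume of Subdomain codes
    t1_map: np.ndarray  # ms; NaN outside brain
    true_params: TransportParams | None = None
    concentration: ConcentrationSeries | None = None
    overlap_voxels: int = 0  # ventricle voxels overridden by arteries

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != int(Subdomain.BACKGROUND)

    def artery_class_map(self) -> np.ndarray:
        """Class annotation for segmentation: 1 = surface, 2 = branching."""
        out = np.zeros(self.labels.shape, dtype=np.int8)
        kinds = getattr(self, "_artery_kinds", None)
        if kinds is not None:
            out[:] = kinds
        return out


def default_spec(grid_shape=(64, 64, 48), voxel_size=0.1, seed=0, **overrides) -> PhantomSpec:
    """Default phantom: one ventral surface artery, two branching arteries
    rising dorsally from it, and two lateral ventricles.

    Geometry scales with the grid so the same layout works at reduced
    desk resolutions.
    """
    spec = PhantomSpec(grid_shape=grid_shape, voxel_size=voxel_size, seed=seed)
    if "brain_semi_axes" not in overrides:
        # keep the brain proportional to the box so reduced grids work
        box = spec.box_mm
        spec.brain_semi_axes = (0.453 * box[0], 0.453 * box[1], 0.4375 * box[2])
    for k, v in overrides.items():
        if not hasattr(spec, k):
            raise TypeError(f"unknown PhantomSpec field {k!r}")
        setattr(spec, k, v)
    cx, cy, cz = spec.center
    ax, ay, az = spec.brain_semi_axes

    # ventral midline artery, caudal -> rostral, hugging the lower surface
    xs = np.linspace(cx - 0.8 * ax, cx + 0.8 * ax, 33)
    zs = cz - 0.82 * az * np.sqrt(np.clip(1.0 - ((xs - cx) / ax) ** 2, 0.0, None))
    surface = ArteryPath(
        points=np.stack([xs, np.full_like(xs, cy), zs], axis=1),
        radius=1.2 * voxel_size,
        kind="surface",
    )
    branches = []
    for fx in (-0.35, 0.35):
        x0 = cx + fx * ax
        z0 = cz - 0.82 * az * np.sqrt(max(1.0 - fx ** 2, 0.0))
        t = np.linspace(0.0, 1.0, 17)
        pts = np.stack(
            [np.full_like(t, x0), cy + 0.25 * ay * t * np.sign(fx), z0 + 1.1 * az * t],
            axis=1,
        )
        branches.append(ArteryPath(points=pts, radius=1.0 * voxel_size, kind="branching"))
    spec.artery_paths = [surface] + branches
    spec.ventricle_centers_radii = [
        ((cx, cy - 0.45 * ay, cz + 0.25 * az), (0.22 * ax, 0.10 * ay, 0.12 * az)),
        ((cx, cy + 0.45 * ay, cz + 0.25 * az), (0.22 * ax, 0.10 * ay, 0.12 * az)),
    ]
    # injection near the caudal ventral surface, just inside the brain at
    # the caudal end of the surface artery
    site_mm = surface.points[0] + np.array([2.0, 0.0, 2.0]) * voxel_size
    spec.injection_site = tuple(int(v) for v in np.floor(site_mm / voxel_size))
    return spec


def _ellipsoid_mask(grid_shape, voxel_size, center, semi_axes) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(s) + 0.5 for s in grid_shape], indexing="ij"), axis=-1
    )
    world = idx * voxel_size
    r = (world - np.asarray(center)) / np.asarray(semi_axes)
    return np.sum(r ** 2, axis=-1) <= 1.0


def _rasterize_path(path: ArteryPath, grid_shape, voxel_size) -> np.ndarray:
    """Voxels within ``radius`` (Euclidean, mm) of the polyline."""
    pts = path.points
    segs = []
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / (0.25 * voxel_size))))
        segs.append(np.linspace(a, b, n))
    dense = np.concatenate(segs) if segs else pts
    center_vox = np.floor(dense / voxel_size).astype(int)
    for ax in range(3):
        np.clip(center_vox[:, ax], 0, grid_shape[ax] - 1, out=center_vox[:, ax])
    line = np.zeros(grid_shape, dtype=bool)
    line[tuple(center_vox.T)] = True
    dist = ndimage.distance_transform_edt(~line, sampling=voxel_size)
    return dist <= path.radius


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Voxelize the phantom geometry into labels and a T1 map.

    Precedence: Artery > Ventricle > PAS_Branch > PAS_Surf > BT; the
    periarterial shells use the same Chebyshev reach as the segmentation
    defaults so labels are recoverable by construction.
    """
    gs, h = spec.grid_shape, spec.voxel_size
    brain = _ellipsoid_mask(gs, h, spec.center, spec.brain_semi_axes)

    artery = np.zeros(gs, dtype=bool)
    kinds = np.zeros(gs, dtype=np.int8)  # 1 surface, 2 branching
    by_kind = {"surface": np.zeros(gs, dtype=bool), "branching": np.zeros(gs, dtype=bool)}
    for path in spec.artery_paths:
        r = (path.points - spec.center) / np.asarray(spec.brain_semi_axes)
        if np.any(np.sum(r ** 2, axis=1) > 1.0 + 1e-9):
            raise ValueError(f"artery path ({path.kind}) exits the brain ellipsoid")
        vox = _rasterize_path(path, gs, h) & brain
        by_kind[path.kind] |= vox
        artery |= vox
    kinds[by_kind["surface"]] = 1
    kinds[by_kind["branching"]] = 2  # branching wins where paths touch

    def _cheb_within(mask: np.ndarray, reach: int) -> np.ndarray:
        if not mask.any():
            return np.zeros(gs, dtype=bool)
        d = ndimage.distance_transform_cdt(~mask, metric="chessboard")
        return d <= reach

    pas_surf = (
        _cheb_within(by_kind["surface"], spec.pas_shell_voxels["surface"]) & brain & ~artery
    )
    pas_branch = (
        _cheb_within(by_kind["branching"], spec.pas_shell_voxels["branching"]) & brain & ~artery
    )
    pas_surf &= ~pas_branch  # tie-break to the branching shell

    ventricle = np.zeros(gs, dtype=bool)
    for center, radii in spec.ventricle_centers_radii:
        ventricle |= _ellipsoid_mask(gs, h, center, radii)
    ventricle &= brain
    overlap = int((ventricle & artery).sum())
    ventricle &= ~artery  # artery wins

    labels = np.zeros(gs, dtype=np.int8)
    labels[brain] = int(Subdomain.BT)
    labels[pas_surf] = int(Subdomain.PAS_SURF)
    labels[pas_branch] = int(Subdomain.PAS_BRANCH)
    labels[ventricle] = int(Subdomain.VENTRICLE)
    labels[artery] = int(Subdomain.ARTERY)

    t1 = np.full(gs, np.nan)
    rng = np.random.default_rng(spec.seed)
    for lab, base in spec.t1_by_tissue.items():
        m = labels == lab
        t1[m] = base
        if spec.t1_jitter > 0:
            t1[m] += rng.normal(0.0, spec.t1_jitter * base, size=int(m.sum()))

    gt = GroundTruth(spec=spec, labels=labels, t1_map=t1, overlap_voxels=overlap)
    gt._artery_kinds = kinds  # type: ignore[attr-defined]
    return gt


def injection_location_mm(spec: PhantomSpec) -> np.ndarray:
    """World coordinate of the injection voxel center."""
    if spec.injection_site is None:
        raise ValueError("phantom spec has no injection site")
    return (np.asarray(spec.injection_site) + 0.5) * spec.voxel_size


def simulate_truth(
    gt: GroundTruth,
    params: TransportParams,
    source: SourceSpec,
    frame_times,
    cfg: SolverConfig | None = None,
) -> ConcentrationSeries:
    """Run the forward diffusion model on the phantom and sample to voxels.

    The mesh is built at the native voxel resolution so cells coincide
    with voxels; the per-frame voxel field is the finite-element solution
    evaluated at voxel centers.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(frame_times < 0):
        raise ValueError("frame times must be >= 0")
    for tag in np.unique(gt.labels):
        if tag == int(Subdomain.BACKGROUND):
            continue
        params.deff_for_tag(int(tag))  # raises if uncovered

    mesh = build_mesh(gt.brain_mask, voxel_size=gt.spec.voxel_size)
    tag_subdomains(mesh, gt.labels, gt.spec.voxel_size)
    if source.rate == 0.0:
        vol = np.zeros(gt.labels.shape + (frame_times.size,))
        return ConcentrationSeries(vol, frame_times, voxel_size=gt.spec.voxel_size)
    field = solve_transport(mesh, params, source, frame_times, cfg)
    vol, _ = sample_to_voxels(field, mesh, gt.labels.shape, gt.spec.voxel_size)
    vol[~gt.brain_mask] = 0.0
    np.clip(vol, 0.0, None, out=vol)  # remove tiny implicit-Euler undershoot
    return ConcentrationSeries(vol, frame_times, voxel_size=gt.spec.voxel_size)


def synthesize_signal(
    conc: ConcentrationSeries,
    t1_map: np.ndarray,
    acq: AcquisitionParams,
    art: ArtifactSpec,
    brain_mask: np.ndarray | None = None,
) -> SignalSeries:
    """Generate baselines and dynamic frames from concentration.

    Baselines at the two acquisition flip angles follow the SPGR signal
    equation with per-voxel T1.  Dynamic frames use the linearized
    contrast relationship S = S0 * (1 + r1 * T1_0 * c) — the exact
    inverse of the concentration conversion — so a noiseless round trip
    is the identity.  Dropout multiplies the *dynamic* signal of surface
    -shell voxels and of voxels whose concentration exceeds the
    susceptibility threshold by ``dropout_factor``.
    """
    t1 = np.asarray(t1_map, dtype=float)
    if brain_mask is None:
        brain_mask = np.isfinite(t1)
    if np.any(~np.isfinite(t1) & brain_mask):
        raise ValueError("missing T1 inside the brain mask")
    if np.any(conc.frames < 0):
        raise ValueError("negative input concentration")
    if t1.shape != conc.grid_shape:
        raise ValueError("T1 map / concentration grid mismatch")

    a_lo, a_hi = acq.flip_angles
    t1_safe = np.where(brain_mask, t1, np.inf)  # zero signal outside brain
    base_lo = np.where(brain_mask, spgr_signal(1.0, t1_safe, a_lo, acq.tr), 0.0)
    base_hi = np.where(brain_mask, spgr_signal(1.0, t1_safe, a_hi, acq.tr), 0.0)

    t1_fill = np.where(brain_mask, t1, 0.0)
    frames = base_hi[..., None] * (1.0 + acq.r1 * t1_fill[..., None] * conc.frames)
    frames[~brain_mask] = 0.0

    drop = np.zeros(conc.frames.shape, dtype=bool)
    if art.surface_dropout_voxels > 0:
        dist_in = ndimage.distance_transform_cdt(brain_mask, metric="chessboard")
        shell = brain_mask & (dist_in <= art.surface_dropout_voxels)
        drop |= shell[..., None]
    drop |= conc.frames > art.injection_dropout
    frames = np.where(drop, frames * art.dropout_factor, frames)

    if art.noise_sigma > 0:
        rng = np.random.default_rng(art.seed)
        sigma = art.noise_sigma * float(base_hi[brain_mask].mean())
        if art.noise_model == "gaussian":
            base_lo = base_lo + rng.normal(0.0, sigma, base_lo.shape)
            base_hi = base_hi + rng.normal(0.0, sigma, base_hi.shape)
            frames = frames + rng.normal(0.0, sigma, frames.shape)
        else:  # rician: magnitude of complex signal + iid Gaussian channels
            def ric(x):
                return np.hypot(
                    x + rng.normal(0.0, sigma, x.shape), rng.normal(0.0, sigma, x.shape)
                )

            base_lo, base_hi, frames = ric(base_lo), ric(base_hi), ric(frames)

    return SignalSeries(
        frames=frames,
        frame_times=conc.frame_times,
        baselines={a_lo: base_lo, a_hi: base_hi},
        voxel_size=conc.voxel_size,
    )


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON/YAML-serializable form of a phantom spec."""
    d = dataclasses.asdict(spec)
    d["artery_paths"] = [
        {"points": p.points.tolist(), "radius": p.radius, "kind": p.kind}
        for p in spec.artery_paths
    ]
    d["ventricle_centers_radii"] = [
        [list(c), list(r)] for c, r in spec.ventricle_centers_radii
    ]
    d["t1_by_tissue"] = {str(k): v for k, v in spec.t1_by_tissue.items()}
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["artery_paths"] = [
        ArteryPath(np.asarray(p["points"]), p["radius"], p["kind"])
        for p in d.get("artery_paths", [])
    ]
    d["ventricle_centers_radii"] = [
        (tuple(c), tuple(r)) for c, r in d.get("ventricle_centers_radii", [])
    ]
    d["t1_by_tissue"] = {int(k): float(v) for k, v in d.get("t1_by_tissue", {}).items()}
    for key in ("grid_shape", "brain_semi_axes"):
        if key in d:
            d[key] = tuple(d[key])
    if d.get("injection_site") is not None:
        d["injection_site"] = tuple(d["injection_site"])
    known = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown phantom spec keys: {sorted(unknown)}")
    return PhantomSpec(**d)
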