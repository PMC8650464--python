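"""Mesh construction over a voxel mask and voxel-to-node interpolation.

The desk-scale mesh is a structured hexahedral grid: every active cell is
an axis-aligned cube of edge ``spacing`` and the mesh may be built at a
resolution different from the source voxel grid to hit a target cell
count.  World coordinates follow the voxel convention: voxel ``(i,j,k)``
is the cube ``[i,i+1]x[j,j+1]x[k,k+1]`` times ``voxel_size`` mm, with its
center at ``(i+0.5)*voxel_size``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["Mesh", "NodalField", "build_mesh", "interpolate_idw", "tag_subdomains"]

# corner offsets in tensor-product order (x fastest)
_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
    dtype=np.int64,
)
# VTK_HEXAHEDRON ordering of the same corners, for export
_VTK_ORDER = [0, 1, 3, 2, 4, 5, 7, 6]


@dataclass
class Mesh:
    """Structured hexahedral mesh restricted to a voxel mask.

    Attributes
    ----------
    points : (N, 3) node coordinates in mm.
    cells : (M, 8) node indices per hexahedron (tensor-product corner
        order).
    cell_tags : (M,) integer subdomain tag per cell.
    spacing : cell edge length in mm.
    cell_active : 3D bool array of the structured cell lattice.
    cell_index : 3D int array mapping lattice position -> cell id (-1
        where inactive).
    node_index : 3D int array on the (lattice+1) node grid -> node id.
    cell_ijk : (M, 3) lattice position of each cell.
    """

    points: np.ndarray
    cells: np.ndarray
    cell_tags: np.ndarray
    spacing: float
    cell_active: np.ndarray
    cell_index: np.ndarray
    node_index: np.ndarray
    cell_ijk: np.ndarray
    quality: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    @property
    def cell_volume(self) -> float:
        return float(self.spacing ** 3)

    @property
    def volume(self) -> float:
        return self.n_cells * self.cell_volume

    def boundary_faces(self) -> np.ndarray:
        """Quad faces (node-id 4-tuples) bordering exactly one active cell."""
        act = self.cell_active
        faces = []
        # face corner offsets per (axis, side) on the node lattice
        for axis in range(3):
            lo = np.ones(3, dtype=int)
            lo[axis] = 0
            # neighbor occupancy shifted along axis
            pad = np.zeros(np.array(act.shape) + 2, dtype=bool)
            pad[1:-1, 1:-1, 1:-1] = act
            for side in (0, 1):
                shift = np.roll(np.eye(3, dtype=int)[axis], 0) * (1 if side else -1)
                nb = pad[
                    1 + shift[0]: pad.shape[0] - 1 + shift[0],
                    1 + shift[1]: pad.shape[1] - 1 + shift[1],
                    1 + shift[2]: pad.shape[2] - 1 + shift[2],
                ]
                exposed = act & ~nb
                ijk = np.argwhere(exposed)
                if ijk.size == 0:
                    continue
                base = ijk.copy()
                base[:, axis] += side
                off = [c for c in _CORNERS if c[axis] == 0]
                quads = np.stack(
                    [self.node_index[tuple((base + o).T)] for o in off], axis=1
                )
                faces.append(quads)
        if not faces:
            return np.empty((0, 4), dtype=np.int64)
        return np.concatenate(faces, axis=0)

    def cell_centroids(self) -> np.ndarray:
        return (self.cell_ijk + 0.5) * self.spacing

    def write_vtu(self, path) -> None:
        """Minimal ASCII VTU export (hexahedra + cell tags)."""
        buf = io.StringIO()
        buf.write('<?xml version="1.0"?>\n')
        buf.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        buf.write(f'<UnstructuredGrid><Piece NumberOfPoints="{self.n_nodes}" NumberOfCells="{self.n_cells}">\n')
        buf.write('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        np.savetxt(buf, self.points, fmt="%.8g")
        buf.write('</DataArray></Points>\n<Cells>\n')
        buf.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        np.savetxt(buf, self.cells[:, _VTK_ORDER], fmt="%d")
        buf.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        np.savetxt(buf, 8 * np.arange(1, self.n_cells + 1), fmt="%d")
        buf.write('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        np.savetxt(buf, np.full(self.n_cells, 12), fmt="%d")
        buf.write('</DataArray>\n</Cells>\n<CellData Scalars="subdomain">\n')
        buf.write('<DataArray type="Int32" Name="subdomain" format="ascii">\n')
        np.savetxt(buf, self.cell_tags, fmt="%d")
        buf.write('</DataArray></CellData>\n</Piece></UnstructuredGrid></VTKFile>\n')
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


@dataclass
class NodalField:
    """Scalar values at solver/mesh degrees of freedom.

    ``values`` is ``(N,)`` or ``(N, T)`` with ``times`` in minutes for
    stacks.  ``coords`` are the dof coordinates in mm; ``tagbits`` is a
    per-dof bitmask of adjacent-cell subdomain tags (bit ``t`` set when
    some adjacent cell carries tag ``t``).
    """

    values: np.ndarray
    coords: np.ndarray
    times: np.ndarray | None = None
    units: str = "mM"
    tagbits: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("nodal field contains non-finite values")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.values.ndim != 2 or self.values.shape[1] != self.times.size:
                raise ValueError("values/times shape mismatch")


def build_mesh(
    brain_mask: np.ndarray,
    target_cells: int | None = None,
    voxel_size: float = 0.1,
) -> Mesh:
    """Mesh the masked volume with cube cells, near a target cell count.

    When ``target_cells`` differs from the mask voxel count the mask is
    resampled (nearest neighbour) so the realized count lands within 2x
    of the target; the surface stays within one source voxel of the
    mask's.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    _, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise ValueError(f"brain mask has {n_comp} connected components; expected 1")

    n_vox = int(mask.sum())
    if target_cells is None or target_cells == n_vox:
        cell_active = mask
        spacing = voxel_size
    else:
        scale = (target_cells / n_vox) ** (1.0 / 3.0)
        new_shape = np.maximum(1, np.round(np.array(mask.shape) * scale)).astype(int)
        zoom = new_shape / np.array(mask.shape)
        cell_active = ndimage.zoom(mask.astype(np.uint8), zoom, order=0).astype(bool)
        if not cell_active.any():  # pathological tiny target
            cell_active = mask
        spacing = voxel_size * mask.shape[0] / cell_active.shape[0]

    shape = cell_active.shape
    cell_index = np.full(shape, -1, dtype=np.int64)
    cell_ijk = np.argwhere(cell_active)
    cell_index[cell_active] = np.arange(cell_ijk.shape[0])

    node_shape = tuple(s + 1 for s in shape)
    node_used = np.zeros(node_shape, dtype=bool)
    for off in _CORNERS:
        node_used[tuple((cell_ijk + off).T)] = True
    node_index = np.full(node_shape, -1, dtype=np.int64)
    node_ijk = np.argwhere(node_used)
    node_index[node_used] = np.arange(node_ijk.shape[0])
    points = node_ijk.astype(float) * spacing

    cells = np.stack(
        [node_index[tuple((cell_ijk + off).T)] for off in _CORNERS], axis=1
    )
    mesh = Mesh(
        points=points,
        cells=cells,
        cell_tags=np.zeros(cells.shape[0], dtype=np.int32),
        spacing=spacing,
        cell_active=cell_active,
        cell_index=cell_index,
        node_index=node_index,
        cell_ijk=cell_ijk,
        quality={
            "n_cells": cells.shape[0],
            "n_nodes": points.shape[0],
            "min_aspect_ratio": 1.0,  # cube cells
            "median_aspect_ratio": 1.0,
            "spacing_mm": spacing,
        },
    )
    return mesh


def interpolate_idw(
    volume: np.ndarray,
    mesh: Mesh | None = None,
    voxel_size: float = 0.1,
    sigma_voxels: float = 1.0,
    radius_voxels: float | None = None,
    kernel: str = "gaussian",
    power: float = 2.0,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Inverse-distance / Gaussian weighted voxel-to-point interpolation.

    Each target point takes a convex combination of voxel-center values
    within ``radius_voxels`` (default ``3 * sigma_voxels``); weights are
    ``exp(-d^2 / 2 sigma^2)`` (Gaussian, the default) or ``1/d^p``.
    Points with no voxel in range fall back to the nearest voxel, so the
    result always satisfies the max principle over contributing voxels.

    ``volume`` may be 3D or 4D (trailing frame axis).  Target points are
    ``mesh.points`` or an explicit ``coords`` array (mm).
    """
    vol = np.asarray(volume, dtype=float)
    grid_shape = vol.shape[:3]
    frames = vol.reshape(grid_shape + (-1,))
    if coords is None:
        if mesh is None:
            raise ValueError("need a mesh or explicit coords")
        coords = mesh.points
    if radius_voxels is None:
        radius_voxels = 3.0 * sigma_voxels

    # work in voxel units; voxel centers sit at index + 0.5
    pts = np.asarray(coords, dtype=float) / voxel_size - 0.5
    centers = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    flat = frames.reshape(-1, frames.shape[-1])
    tree = cKDTree(centers)

    out = np.empty((pts.shape[0], flat.shape[1]))
    neighbors = tree.query_ball_point(pts, r=radius_voxels)
    _, nearest = tree.query(pts)
    n_fallback = 0
    for i, idx in enumerate(neighbors):
        if not idx:
            out[i] = flat[nearest[i]]
            n_fallback += 1
            continue
        idx = np.asarray(idx)
        d2 = np.sum((centers[idx] - pts[i]) ** 2, axis=1)
        if kernel == "gaussian":
            w = np.exp(-d2 / (2.0 * sigma_voxels ** 2))
        elif kernel == "idw":
            d = np.sqrt(d2)
            if np.any(d < 1e-12):  # exact hit
                out[i] = flat[idx[np.argmin(d)]]
                continue
            w = d ** (-power)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
        out[i] = (w[:, None] * flat[idx]).sum(axis=0) / w.sum()
    if mesh is not None:
        mesh.quality["idw_fallback_nodes"] = n_fallback
    if vol.ndim == 3:
        return out[:, 0]
    return out


def tag_subdomains(mesh: Mesh, labels: np.ndarray, label_voxel_size: float = 0.1) -> Mesh:
    """Tag each cell with the label at its centroid's voxel (in place).

    Centroids outside the label grid clamp to the nearest voxel.
    Idempotent and deterministic.
    """
    lab = np.asarray(labels)
    if lab.ndim != 3:
        raise ValueError("labels must be a 3D volume")
    idx = np.floor(mesh.cell_centroids() / label_voxel_size).astype(int)
    for ax in range(3):
        np.clip(idx[:, ax], 0, lab.shape[ax] - 1, out=idx[:, ax])
    mesh.cell_tags = lab[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.int32)
    counts = dict(zip(*np.unique(mesh.cell_tags, return_counts=True)))
    mesh.quality["cells_per_tag"] = {int(k): int(v) for k, v in counts.items()}
    return mesh
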