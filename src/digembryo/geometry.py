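"""Per-mesh and inter-mesh geometry.

Every blastomere is a closed triangle mesh in physical micrometre
coordinates. This module provides the mesh metrics (area, enclosed volume,
volume centroid) and the normal-ray occlusion classification that defines
*surface exposure*: for each face of a target cell a ray is fired from the
face centroid along the outward normal; if it reaches infinity without
meeting any other triangle of the embryo the face is external, otherwise
internal. Exposure is then external area over total area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .raycast import OcclusionScene

log = logging.getLogger(__name__)

# Ray origins are pushed off the source face by this fraction of the frame
# bounding-box diagonal, so the origin face cannot shadow its own ray.
RAY_OFFSET_FRACTION = 1e-6

# Faces whose area is below this fraction of the mesh's mean face area are
# considered degenerate and rejected at load.
DEGENERATE_AREA_FRACTION = 1e-12


class MeshValidationError(ValueError):
    """A mesh violates the closed/watertight/non-degenerate contract."""


def validate_mesh(mesh: trimesh.Trimesh, name: str = "mesh") -> trimesh.Trimesh:
    """Check the blastomere-mesh invariants, re-orienting winding if needed.

    Requirements: watertight (every edge shared by exactly two faces), no
    zero-area faces, and outward winding (positive signed volume). A mesh
    with consistently inward winding is auto-reoriented with a warning;
    anything else is a hard error naming the mesh.
    """
    if len(mesh.faces) == 0:
        raise MeshValidationError(f"{name}: mesh has no faces")
    if not mesh.is_watertight:
        raise MeshValidationError(f"{name}: mesh is not watertight")
    areas = mesh.area_faces
    if np.any(areas <= DEGENERATE_AREA_FRACTION * areas.mean()):
        raise MeshValidationError(f"{name}: mesh contains zero-area faces")
    if mesh.volume < 0:
        log.warning("%s: inward winding detected; reorienting faces", name)
        mesh = mesh.copy()
        mesh.invert()
    if mesh.volume <= 0:
        raise MeshValidationError(f"{name}: non-positive enclosed volume")
    return mesh


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area: the sum of the areas of the constituent triangles."""
    areas = mesh.area_faces
    if np.any(areas <= 0):
        raise MeshValidationError("mesh contains zero-area faces")
    return float(areas.sum())


def enclosed_volume(mesh: trimesh.Trimesh) -> float:
    """Signed enclosed volume (divergence theorem over faces), in µm³."""
    if not mesh.is_watertight:
        raise MeshValidationError("volume undefined: mesh is not watertight")
    v = float(mesh.volume)
    if v < 0:
        v = -v
    return v


def centre_of_mass(mesh: trimesh.Trimesh) -> np.ndarray:
    """Volume centroid of the enclosed solid (not the vertex mean)."""
    if not mesh.is_watertight:
        raise MeshValidationError("centroid undefined: mesh is not watertight")
    return np.asarray(mesh.center_mass, dtype=np.float64)


@dataclass
class FaceClassification:
    """External/internal label for every face of one cell in one frame."""

    cell_id: str
    frame: int
    external: np.ndarray  # (n_faces,) bool

    @property
    def n_external(self) -> int:
        return int(self.external.sum())


@dataclass(frozen=True)
class ExposureRecord:
    """Surface exposure of one cell at one frame.

    ``exposure`` is the ratio of external area to total surface area — the
    fraction of the cell's surface on the outside of the embryo, in [0, 1].
    """

    cell_id: str
    frame: int
    external_area: float
    total_area: float
    exposure: float = field(init=False)

    def __post_init__(self):
        if self.total_area <= 0:
            raise MeshValidationError(
                f"{self.cell_id}@{self.frame}: non-positive total area"
            )
        object.__setattr__(self, "exposure", self.external_area / self.total_area)
        if not 0.0 <= self.exposure <= 1.0 + 1e-12:
            raise ValueError(
                f"{self.cell_id}@{self.frame}: exposure {self.exposure} out of [0,1]"
            )


def classify_faces(target, frame) -> FaceClassification:
    """Label each face of ``target`` external or internal within ``frame``.

    A face is external iff a ray from its centroid, offset slightly along
    the outward normal, escapes to infinity without hitting any other
    triangle of the frame — including other faces of the same cell (concave
    cells self-occlude) but excluding the origin face itself.
    """
    if target.cell_id not in {c.cell_id for c in frame.cells}:
        raise ValueError(f"cell {target.cell_id!r} is not part of frame {frame.frame}")
    cached = frame._classifications.get(target.cell_id)
    if cached is not None:
        return cached
    scene = frame.occlusion_scene()
    mesh = target.mesh
    eps = RAY_OFFSET_FRACTION * scene.bbox_diagonal
    normals = mesh.face_normals
    origins = mesh.triangles_center + eps * normals
    exclude = np.arange(len(mesh.faces))
    hit = scene.any_hit(origins, normals, own_cell=target.cell_id, exclude_face=exclude)
    result = FaceClassification(target.cell_id, frame.frame, external=~hit)
    frame._classifications[target.cell_id] = result
    return result


def surface_exposure(target, frame) -> ExposureRecord:
    """Exposure record for one cell: Σ area(external faces) / Σ area(all)."""
    cls = classify_faces(target, frame)
    areas = target.mesh.area_faces
    return ExposureRecord(
        cell_id=target.cell_id,
        frame=frame.frame,
        external_area=float(areas[cls.external].sum()),
        total_area=float(areas.sum()),
    )


def frame_exposures(frame) -> dict[str, ExposureRecord]:
    """Exposure records for every cell of one frame, keyed by cell id."""
    return {c.cell_id: surface_exposure(c, frame) for c in frame.cells}


def exposure_table(frames) -> pd.DataFrame:
    """Per-cell, per-frame exposure table over a sequence of frames."""
    rows = []
    for fr in frames:
        for rec in frame_exposures(fr).values():
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "frame": rec.frame,
                    "external_area": rec.external_area,
                    "total_area": rec.total_area,
                    "exposure": rec.exposure,
                }
            )
    return pd.DataFrame(rows)


def nearest_face(points: np.ndarray, mesh: trimesh.Trimesh,
                 max_distance: float | None = None,
                 chunk_pairs: int = 4_000_000) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned distance from each point to the mesh surface, with the index
    of the nearest face.

    Vectorised closest-point-on-triangle; intended for voxel shells around a
    single cell, where the point count times face count stays modest. With
    ``max_distance`` set, points that provably lie farther than that from the
    surface (bounding-annulus test) are skipped and reported as distance
    ``inf`` with face index ``-1``.
    """
    points = np.asarray(points, dtype=np.float64)
    tris = mesh.triangles
    n_pts = len(points)
    dist = np.full(n_pts, np.inf)
    face = np.full(n_pts, -1, dtype=np.int64)

    if max_distance is not None:
        # every surface point lies in a spherical annulus around the bbox
        # centre; points outside the padded annulus cannot be within reach
        centre = mesh.bounds.mean(axis=0)
        rho_min = float(
            np.sqrt(_point_triangle_sq_distance(centre[None, :], tris).min())
        )
        rho_max = float(np.linalg.norm(mesh.vertices - centre, axis=1).max())
        r = np.linalg.norm(points - centre, axis=1)
        cand = (r >= rho_min - max_distance) & (r <= rho_max + max_distance)
        sel = np.nonzero(cand)[0]
    else:
        sel = np.arange(n_pts)
    if sel.size == 0:
        return dist, face

    best_d2 = np.empty(sel.size)
    best_face = np.empty(sel.size, dtype=np.int64)
    chunk = max(1, chunk_pairs // max(len(tris), 1))
    pts = points[sel]
    for start in range(0, sel.size, chunk):
        sl = slice(start, min(start + chunk, sel.size))
        d2 = _point_triangle_sq_distance(pts[sl], tris)  # (p, T)
        idx = d2.argmin(axis=1)
        best_d2[sl] = d2[np.arange(d2.shape[0]), idx]
        best_face[sl] = idx
    dist[sel] = np.sqrt(best_d2)
    face[sel] = best_face
    return dist, face


def _point_triangle_sq_distance(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Squared distance of each point to each triangle, shape (P, T).

    Region-based closest-point-on-triangle (Ericson), broadcast over all
    point/triangle pairs.
    """
    a = tris[None, :, 0, :]
    b = tris[None, :, 1, :]
    c = tris[None, :, 2, :]
    p = points[:, None, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ptk,ptk->pt", ab, ap)
    d2 = np.einsum("ptk,ptk->pt", ac, ap)

    bp = p - b
    d3 = np.einsum("ptk,ptk->pt", ab, bp)
    d4 = np.einsum("ptk,ptk->pt", ac, bp)

    cp = p - c
    d5 = np.einsum("ptk,ptk->pt", ab, cp)
    d6 = np.einsum("ptk,ptk->pt", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_edge_ab = np.clip(d1 / (d1 - d3), 0.0, 1.0)
        w_edge_ac = np.clip(d2 / (d2 - d6), 0.0, 1.0)
        w_edge_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0, 1.0)
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
    v_edge_ab = np.nan_to_num(v_edge_ab)
    w_edge_ac = np.nan_to_num(w_edge_ac)
    w_edge_bc = np.nan_to_num(w_edge_bc)
    v_in = np.nan_to_num(v_in)
    w_in = np.nan_to_num(w_in)

    # candidate closest points per region
    close = a + v_in[..., None] * ab + w_in[..., None] * ac  # face interior
    close = np.where(
        (va <= 0)[..., None], b + w_edge_bc[..., None] * (c - b), close
    )
    close = np.where(
        ((vb <= 0) & (d2 >= 0) & (d6 <= 0))[..., None],
        a + w_edge_ac[..., None] * ac,
        close,
    )
    close = np.where(
        ((vc <= 0) & (d1 >= 0) & (d3 <= 0))[..., None],
        a + v_edge_ab[..., None] * ab,
        close,
    )
    close = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, close)
    close = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, close)
    close = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, close)

    diff = p - close
    return np.einsum("ptk,ptk->pt", diff, diff)
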