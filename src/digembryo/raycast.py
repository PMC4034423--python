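"""Any-hit ray casting against per-cell triangle soups.

Surface-exposure classification fires one ray per mesh face, along the
outward normal, and asks whether it hits *any* other triangle in the frame.
Only the boolean answer matters, so the engine is an any-hit tester: a
vectorised Möller–Trumbore intersection with a two-level pruning hierarchy
(axis-aligned bounding box per cell, then that cell's triangle block).

Barycentric bounds are inclusive (small epsilon), so a ray meeting a shared
edge or vertex of a watertight mesh still registers a hit — rays must not
slip through the seams between triangles.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

# Inclusive tolerance on barycentric coordinates: hits exactly on shared
# edges/vertices count, so watertight meshes stay watertight to rays.
EDGE_EPS = 1e-10
# Determinant below this is treated as ray parallel to triangle plane.
PARALLEL_EPS = 1e-14

# Cap on rays × triangles evaluated per vectorised block (memory bound).
_PAIR_BUDGET = 4_000_000


def ray_triangle_any(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    exclude: np.ndarray | None = None,
    t_min: float = 0.0,
) -> np.ndarray:
    """Return a boolean per ray: does it hit any triangle at t > ``t_min``?

    Parameters
    ----------
    origins, directions
        ``(R, 3)`` arrays. Directions need not be normalised.
    triangles
        ``(T, 3, 3)`` array of triangle vertices.
    exclude
        Optional ``(R,)`` integer array; ``exclude[i]`` is a triangle index
        ignored for ray ``i`` (the face the ray was fired from). ``-1``
        excludes nothing.
    """
    origins = np.asarray(origins, dtype=np.float64)
    directions = np.asarray(directions, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.float64)
    n_rays = len(origins)
    n_tris = len(triangles)
    hit = np.zeros(n_rays, dtype=bool)
    if n_rays == 0 or n_tris == 0:
        return hit

    chunk = max(1, _PAIR_BUDGET // max(n_tris, 1))
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0

    for start in range(0, n_rays, chunk):
        sl = slice(start, min(start + chunk, n_rays))
        o = origins[sl][:, None, :]      # (r, 1, 3)
        d = directions[sl][:, None, :]
        h = np.cross(d, e2[None, :, :])               # (r, T, 3)
        a = np.einsum("tk,rtk->rt", e1, h)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = 1.0 / a
            s = o - v0[None, :, :]
            u = f * np.einsum("rtk,rtk->rt", s, h)
            q = np.cross(s, e1[None, :, :])
            v = f * np.einsum("rtk,rtk->rt", d, q)
            t = f * np.einsum("tk,rtk->rt", e2, q)
            ok = (
                (np.abs(a) > PARALLEL_EPS)
                & (u >= -EDGE_EPS)
                & (v >= -EDGE_EPS)
                & (u + v <= 1.0 + EDGE_EPS)
                & (t > t_min)
            )
        if exclude is not None:
            exc = np.asarray(exclude[sl])
            rows = np.nonzero(exc >= 0)[0]
            ok[rows, exc[rows]] = False
        hit[sl] = ok.any(axis=1)
    return hit


def _ray_aabb_any(
    origins: np.ndarray, inv_dir: np.ndarray, bounds: np.ndarray
) -> np.ndarray:
    """Conservative slab test of rays against one AABB (``bounds`` = (2, 3)).

    May report spurious overlaps (degenerate directions), never misses one.
    """
    with np.errstate(invalid="ignore"):
        lo = (bounds[0] - origins) * inv_dir
        hi = (bounds[1] - origins) * inv_dir
    t_low = np.fmin(lo, hi)
    t_high = np.fmax(lo, hi)
    # 0 * inf -> nan when an origin component sits exactly on a slab plane
    # with zero direction: treat conservatively as overlapping that slab.
    t_low = np.where(np.isnan(t_low), -np.inf, t_low)
    t_high = np.where(np.isnan(t_high), np.inf, t_high)
    t_near = np.maximum(t_low.max(axis=1), 0.0)
    t_far = t_high.min(axis=1)
    return t_near <= t_far


class OcclusionScene:
    """All triangles of one embryo frame, grouped by cell, ready for any-hit
    queries.

    The grouping doubles as the pruning hierarchy: a ray is tested against a
    cell's triangles only if it intersects that cell's bounding box.
    """

    def __init__(self, cell_triangles: Mapping[str, np.ndarray]):
        self.cell_ids: Sequence[str] = list(cell_triangles)
        self.triangles = {
            cid: np.ascontiguousarray(tris, dtype=np.float64)
            for cid, tris in cell_triangles.items()
        }
        self.bounds = {
            cid: np.array([tris.min(axis=(0, 1)), tris.max(axis=(0, 1))])
            for cid, tris in self.triangles.items()
        }
        all_pts = np.concatenate(
            [b.reshape(-1, 3) for b in self.bounds.values()], axis=0
        )
        self.scene_bounds = np.array([all_pts.min(axis=0), all_pts.max(axis=0)])

    @property
    def bbox_diagonal(self) -> float:
        return float(np.linalg.norm(self.scene_bounds[1] - self.scene_bounds[0]))

    def any_hit(
        self,
        origins: np.ndarray,
        directions: np.ndarray,
        own_cell: str | None = None,
        exclude_face: np.ndarray | None = None,
    ) -> np.ndarray:
        """Boolean per ray: hit against any triangle of the scene.

        ``own_cell`` names the cell the rays were fired from; its triangles
        are still tested (concave cells occlude themselves) except for the
        per-ray ``exclude_face`` origin triangle.
        """
        origins = np.asarray(origins, dtype=np.float64)
        directions = np.asarray(directions, dtype=np.float64)
        n = len(origins)
        hit = np.zeros(n, dtype=bool)
        with np.errstate(divide="ignore"):
            inv_dir = 1.0 / directions

        for cid in self.cell_ids:
            todo = np.nonzero(~hit)[0]
            if todo.size == 0:
                break
            cand = todo[
                _ray_aabb_any(origins[todo], inv_dir[todo], self.bounds[cid])
            ]
            if cand.size == 0:
                continue
            if cid == own_cell and exclude_face is not None:
                exc = exclude_face[cand]
            else:
                exc = None
            hit[cand] = ray_triangle_any(
                origins[cand], directions[cand], self.triangles[cid], exclude=exc
            )
        return hit
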