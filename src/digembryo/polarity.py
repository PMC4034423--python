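"""Apicobasolateral polarity from a membrane-channel voxel volume.

A polarised outside blastomere carries more membrane signal on its apical
(outward-facing) domain than on its basolateral (cell-contacting) domain.
The measurement samples voxels within a thin shell of the cell's mesh
surface, splits them by whether the nearest face is external or internal
(per the frame's occlusion classification), and reports the ratio of mean
apical to mean basolateral intensity. Dividing cells, which round up and
lose polarity, are compared with nondividing cells by an unpaired t-test on
these ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import geometry
from .model import Blastomere, EmbryoFrame

log = logging.getLogger(__name__)

#: Default shell half-width around the membrane surface, in µm (about the
#: width of a membrane signal at typical confocal resolution).
DEFAULT_SHELL_UM = 1.0


@dataclass
class VoxelVolume:
    """A 3D intensity volume with physical registration.

    ``data`` is indexed [z, y, x]; ``spacing`` and ``origin`` are (z, y, x)
    in µm. World (x, y, z) coordinates map to indices via origin + spacing.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("voxel volume must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on all axes")

    def voxel_centres_world(self, index: np.ndarray) -> np.ndarray:
        """World (x, y, z) µm coordinates of voxel indices (n, 3) in (z,y,x)."""
        zyx = self.origin + np.asarray(index, dtype=np.float64) * np.asarray(
            self.spacing
        )
        return zyx[:, ::-1]

    def indices_near_box(self, lo_xyz: np.ndarray, hi_xyz: np.ndarray) -> np.ndarray:
        """All voxel indices whose centres fall in a world-space box."""
        lo_zyx = np.asarray(lo_xyz)[::-1]
        hi_zyx = np.asarray(hi_xyz)[::-1]
        start = np.maximum(
            np.floor((lo_zyx - self.origin) / self.spacing).astype(int), 0
        )
        stop = np.minimum(
            np.ceil((hi_zyx - self.origin) / self.spacing).astype(int) + 1,
            self.data.shape,
        )
        if np.any(start >= stop):
            return np.empty((0, 3), dtype=int)
        grids = np.meshgrid(
            *(np.arange(a, b) for a, b in zip(start, stop)), indexing="ij"
        )
        return np.stack([g.ravel() for g in grids], axis=1)


@dataclass
class PolarityMeasurement:
    cell_id: str
    apical_mean: float
    basolateral_mean: float
    ratio: float | None
    dividing: bool | None = None
    n_apical: int = 0
    n_basolateral: int = 0

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def surface_shell_voxels(
    cell: Blastomere,
    frame: EmbryoFrame,
    volume: VoxelVolume,
    shell_um: float = DEFAULT_SHELL_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices within ``shell_um`` of the cell surface, partitioned by
    whether the nearest face is external (apical) or internal (basolateral).

    Returns two disjoint (n, 3) index arrays in (z, y, x) order.
    """
    if shell_um <= 0:
        raise ValueError("shell_um must be positive")
    lo = cell.mesh.bounds[0] - shell_um
    hi = cell.mesh.bounds[1] + shell_um
    if np.any(lo[::-1] > np.asarray(volume.origin) + np.asarray(volume.spacing) * volume.data.shape) or np.any(
        hi[::-1] < np.asarray(volume.origin)
    ):
        raise ValueError(f"cell {cell.cell_id!r} lies outside the voxel volume")
    idx = volume.indices_near_box(lo, hi)
    if len(idx) == 0:
        raise ValueError(f"cell {cell.cell_id!r} lies outside the voxel volume")
    pts = volume.voxel_centres_world(idx)
    dist, face = geometry.nearest_face(pts, cell.mesh, max_distance=shell_um)
    in_shell = dist <= shell_um
    external = geometry.classify_faces(cell, frame).external
    ext_face = np.zeros(len(face), dtype=bool)
    ext_face[in_shell] = external[face[in_shell]]
    apical_mask = in_shell & ext_face
    baso_mask = in_shell & ~ext_face
    return idx[apical_mask], idx[baso_mask]


def polarity_ratio(
    cell: Blastomere,
    frame: EmbryoFrame,
    volume: VoxelVolume,
    shell_um: float = DEFAULT_SHELL_UM,
    dividing: bool | None = None,
) -> PolarityMeasurement:
    """Mean apical vs basolateral intensity of one cell and their ratio.

    When either domain is empty (a lone cell has no basolateral surface, a
    fully enclosed cell no apical one) the ratio is flagged undefined rather
    than coerced to zero.
    """
    apical_idx, baso_idx = surface_shell_voxels(cell, frame, volume, shell_um)
    apical_vals = volume.data[tuple(apical_idx.T)] if len(apical_idx) else np.array([])
    baso_vals = volume.data[tuple(baso_idx.T)] if len(baso_idx) else np.array([])
    apical_mean = float(apical_vals.mean()) if apical_vals.size else float("nan")
    baso_mean = float(baso_vals.mean()) if baso_vals.size else float("nan")
    if apical_vals.size == 0 or baso_vals.size == 0 or baso_mean == 0:
        ratio = None
        log.warning("cell %s: polarity ratio undefined (empty domain)", cell.cell_id)
    else:
        ratio = apical_mean / baso_mean
    return PolarityMeasurement(
        cell_id=cell.cell_id,
        apical_mean=apical_mean,
        basolateral_mean=baso_mean,
        ratio=ratio,
        dividing=dividing,
        n_apical=len(apical_idx),
        n_basolateral=len(baso_idx),
    )


@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_dividing: float
    mean_nondividing: float
    n_dividing: int
    n_nondividing: int
    equal_var: bool


def compare_groups(
    dividing: list[PolarityMeasurement] | np.ndarray,
    nondividing: list[PolarityMeasurement] | np.ndarray,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided unpaired t-test on polarity ratios of dividing vs
    nondividing cells (classical equal-variance Student form by default;
    Welch via ``equal_var=False``)."""

    def _ratios(group) -> np.ndarray:
        if len(group) and isinstance(group[0], PolarityMeasurement):
            vals = [m.ratio for m in group if m.defined]
        else:
            vals = list(group)
        return np.asarray(vals, dtype=np.float64)

    a = _ratios(dividing)
    b = _ratios(nondividing)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two defined ratios")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        warnings.warn("zero variance in both groups with equal means; p = 1")
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        t_statistic=float(t),
        p_value=float(p),
        mean_dividing=float(a.mean()),
        mean_nondividing=float(b.mean()),
        n_dividing=len(a),
        n_nondividing=len(b),
        equal_var=equal_var,
    )
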