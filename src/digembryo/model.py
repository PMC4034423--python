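"""Shared data model: blastomeres, frames, divisions, fates.

A dataset is a set of blastomere meshes indexed by (cell id, frame). Frames
are integer time indices at a nominal 15-minute spacing, but spacing may be
irregular: only time points with divisions or substantial movement need to
be present, so a separate frame→minutes map carries the clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import trimesh

from . import geometry
from .raycast import OcclusionScene

Fate = Literal["ICM", "TE"]

#: How the embryo centre is derived from member cells. The volume-weighted
#: mean of cell centroids is the default: robust to unequal cell sizes and
#: identical to the unweighted mean when cells are equal.
CentreMode = Literal["volume", "equal", "vertex"]

#: Exposure below this default is "negligible": the cell counts as inside.
DEFAULT_INSIDE_THRESHOLD = 0.01


@dataclass
class Blastomere:
    """One cell at one time point: a closed mesh in µm coordinates."""

    cell_id: str
    frame: int
    mesh: trimesh.Trimesh

    def __post_init__(self):
        self.mesh = geometry.validate_mesh(
            self.mesh, name=f"{self.cell_id}@{self.frame}"
        )

    @cached_property
    def volume(self) -> float:
        return geometry.enclosed_volume(self.mesh)

    @cached_property
    def area(self) -> float:
        return geometry.surface_area(self.mesh)

    @cached_property
    def centre(self) -> np.ndarray:
        return geometry.centre_of_mass(self.mesh)


@dataclass
class EmbryoFrame:
    """All blastomeres present at one time index."""

    frame: int
    cells: list[Blastomere]
    centre_mode: CentreMode = "volume"
    _scene: OcclusionScene | None = field(default=None, repr=False, compare=False)
    # memo for per-cell face classifications (filled by geometry.classify_faces)
    _classifications: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"frame {self.frame}: duplicate cell ids {dup}")

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: str) -> Blastomere:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(f"cell {cell_id!r} not in frame {self.frame}")

    @property
    def embryo_centre(self) -> np.ndarray:
        """Centre of the whole embryo at this frame (see ``centre_mode``)."""
        if self.centre_mode == "vertex":
            pts = np.concatenate([c.mesh.vertices for c in self.cells])
            return pts.mean(axis=0)
        centres = np.array([c.centre for c in self.cells])
        if self.centre_mode == "equal":
            return centres.mean(axis=0)
        weights = np.array([c.volume for c in self.cells])
        return (centres * weights[:, None]).sum(axis=0) / weights.sum()

    def occlusion_scene(self) -> OcclusionScene:
        """Lazily built any-hit ray-cast scene over all cells of the frame."""
        if self._scene is None:
            self._scene = OcclusionScene(
                {c.cell_id: c.mesh.triangles for c in self.cells}
            )
        return self._scene


def build_frames(
    blastomeres: Iterable[Blastomere], centre_mode: CentreMode = "volume"
) -> list[EmbryoFrame]:
    """Group blastomeres into time-ordered frames.

    Duplicate (cell_id, frame) pairs and empty input are hard errors.
    """
    cells = list(blastomeres)
    if not cells:
        raise ValueError("no blastomeres supplied")
    seen: set[tuple[str, int]] = set()
    by_frame: dict[int, list[Blastomere]] = {}
    for c in cells:
        key = (c.cell_id, c.frame)
        if key in seen:
            raise ValueError(f"duplicate blastomere {key}")
        seen.add(key)
        by_frame.setdefault(c.frame, []).append(c)
    return [
        EmbryoFrame(frame=f, cells=by_frame[f], centre_mode=centre_mode)
        for f in sorted(by_frame)
    ]


@dataclass
class DivisionEvent:
    """One mother → two daughters division.

    ``angle_deg`` is the angle of division θ ∈ [0°, 90°] (0° = tangential /
    asymmetric cleavage, 90° = radial / symmetric), filled in by the
    division-analysis stage.
    """

    mother_id: str
    daughter_ids: tuple[str, str]
    frame_before: int
    frame_after: int
    generation: Literal["8to16", "16to32"] | None = None
    angle_deg: float | None = None

    def __post_init__(self):
        if len(set(self.daughter_ids)) != 2:
            raise ValueError(
                f"division of {self.mother_id}: exactly two distinct daughters required"
            )
        if self.frame_after <= self.frame_before:
            raise ValueError(
                f"division of {self.mother_id}: frame_after must exceed frame_before"
            )


@dataclass(frozen=True)
class FateLabel:
    cell_id: str
    fate: Fate


def assign_fates(
    final_frame: EmbryoFrame,
    exposures: Mapping[str, float] | None = None,
    threshold: float = DEFAULT_INSIDE_THRESHOLD,
) -> list[FateLabel]:
    """Positional fate call at the final (32-cell) stage.

    Cells with surface exposure below ``threshold`` are inside cells and
    labelled ICM; all others TE. ``exposures`` maps cell id → exposure; when
    omitted it is computed from the frame.
    """
    if len(final_frame) < 16:
        raise ValueError(
            f"fate assignment needs a ≥16-cell frame, got {len(final_frame)}"
        )
    if exposures is None:
        exposures = {
            cid: rec.exposure
            for cid, rec in geometry.frame_exposures(final_frame).items()
        }
    labels = []
    for c in final_frame.cells:
        if c.cell_id not in exposures:
            raise KeyError(f"no exposure record for cell {c.cell_id!r}")
        fate: Fate = "ICM" if exposures[c.cell_id] < threshold else "TE"
        labels.append(FateLabel(cell_id=c.cell_id, fate=fate))
    return labels


def frames_by_index(frames: Sequence[EmbryoFrame]) -> dict[int, EmbryoFrame]:
    return {f.frame: f for f in frames}
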