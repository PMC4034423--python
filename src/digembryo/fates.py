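"""Division history, surface exposure, and 32-cell-stage fate.

The fate-history plot places every 32-cell-stage cell at signed coordinates
(x, y): |x| is the grandmother's division angle at the 8→16 round and |y|
the mother's at 16→32. The sign encodes which daughter was farther from the
embryo centre immediately after the division: the outer daughter of the
grandmother division gives x > 0 to all its descendants, and the outer
daughter of the mother division gives y > 0 to itself. Sisters therefore
share x and |y| and mirror about the x-axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import (
    DEFAULT_INSIDE_THRESHOLD,
    DivisionEvent,
    EmbryoFrame,
    FateLabel,
)
from .lineage import LineageTree

log = logging.getLogger(__name__)


def outer_daughter(event: DivisionEvent, frames: Mapping[int, EmbryoFrame]) -> str:
    """Id of the daughter farther from the embryo centre at ``frame_after``.

    Exact radius ties are broken deterministically toward the
    lexicographically smaller cell id, with a logged warning.
    """
    after = frames[event.frame_after]
    centre = after.embryo_centre
    radii = {
        d: float(np.linalg.norm(after.cell(d).centre - centre))
        for d in event.daughter_ids
    }
    a, b = sorted(event.daughter_ids)
    if radii[a] == radii[b]:
        log.warning(
            "division of %s: daughters tie at radius %.6g µm; choosing %r",
            event.mother_id, radii[a], a,
        )
        return a
    return max(event.daughter_ids, key=lambda d: radii[d])


@dataclass(frozen=True)
class FatePlotPoint:
    cell_id: str
    x: float  # signed grandmother (8→16) angle; + if mother was the outer daughter
    y: float  # signed mother (16→32) angle; + if the cell was the outer daughter
    fate: str


def fate_history_points(
    tree: LineageTree,
    fates: Sequence[FateLabel],
    events: Sequence[DivisionEvent],
    frames: Mapping[int, EmbryoFrame],
) -> list[FatePlotPoint]:
    """Signed (grandmother-angle, mother-angle) coordinates per leaf cell.

    Requires a complete two-generation ancestry for every 32-cell-stage
    cell, and annotated angles on every event.
    """
    fate_of = {f.cell_id: f.fate for f in fates}
    ev_by_mother = {ev.mother_id: ev for ev in events}
    points = []
    for leaf in tree.leaves:
        chain = tree.ancestry(leaf)
        if len(chain) < 3:
            raise ValueError(f"cell {leaf!r} lacks a two-generation ancestry")
        if leaf not in fate_of:
            raise KeyError(f"no fate label for cell {leaf!r}")
        mother, grandmother = chain[1], chain[2]
        mother_ev = ev_by_mother[mother]
        grand_ev = ev_by_mother[grandmother]
        for ev in (mother_ev, grand_ev):
            if ev.angle_deg is None:
                raise ValueError(f"division of {ev.mother_id!r} has no angle")
        y_sign = 1.0 if outer_daughter(mother_ev, frames) == leaf else -1.0
        x_sign = 1.0 if outer_daughter(grand_ev, frames) == mother else -1.0
        points.append(
            FatePlotPoint(
                cell_id=leaf,
                x=x_sign * grand_ev.angle_deg,
                y=y_sign * mother_ev.angle_deg,
                fate=fate_of[leaf],
            )
        )
    return points


def fate_history_plot(
    points: Sequence[FatePlotPoint], out_png: str | None = None
):
    """Scatter of the signed division-angle history, coloured by fate."""
    df = pd.DataFrame([p.__dict__ for p in points])
    fig, ax = plt.subplots(figsize=(6, 6))
    colours = {"ICM": "tab:red", "TE": "tab:blue"}
    for fate, sub in df.groupby("fate"):
        ax.scatter(sub["x"], sub["y"], c=colours.get(fate, "0.5"), label=fate, s=30)
    ax.axhline(0, color="0.8", linewidth=1)
    ax.axvline(0, color="0.8", linewidth=1)
    ax.set_xlim(-95, 95)
    ax.set_ylim(-95, 95)
    ax.set_xlabel("grandmother division angle, signed (°)")
    ax.set_ylabel("mother division angle, signed (°)")
    ax.legend(title="fate")
    if out_png:
        fig.savefig(out_png, dpi=150, bbox_inches="tight")
    return fig, df


def inside_cell_count(
    exposures: Mapping[str, float], threshold: float = DEFAULT_INSIDE_THRESHOLD
) -> int:
    """Number of inside cells: exposure below ``threshold``."""
    return int(sum(1 for e in exposures.values() if e < threshold))


def inside_count_sensitivity(
    exposures: Mapping[str, float], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Inside-cell count as a function of the exposure threshold."""
    return pd.DataFrame(
        {
            "threshold": list(thresholds),
            "inside_cells": [inside_cell_count(exposures, t) for t in thresholds],
        }
    )


def exposure_at_formation(
    tree: LineageTree, exposure_table: pd.DataFrame
) -> dict[str, float]:
    """Exposure of each cell at its first segmented frame."""
    out: dict[str, float] = {}
    for cid in tree.graph.nodes:
        first = tree.node(cid)["frame_first"]
        sub = exposure_table[
            (exposure_table["cell_id"] == cid) & (exposure_table["frame"] == first)
        ]
        if len(sub):
            out[cid] = float(sub["exposure"].iloc[0])
    return out


def exposure_fate_scatter(
    tree: LineageTree,
    fates: Sequence[FateLabel],
    exposure_table: pd.DataFrame,
    out_png: str | None = None,
):
    """Each 32-cell-stage cell: its own exposure at formation vs its mother's
    exposure immediately after the mother formed, coloured by fate.

    Supports threshold queries such as whether cells whose mother's exposure
    at formation exceeded 0.6 ever contribute to the ICM.
    """
    fate_of = {f.cell_id: f.fate for f in fates}
    formed = exposure_at_formation(tree, exposure_table)
    rows = []
    for leaf in tree.leaves:
        mother = tree.parent(leaf)
        if mother is None:
            raise ValueError(f"cell {leaf!r} has no mother")
        for cid in (leaf, mother):
            if cid not in formed:
                raise KeyError(f"no exposure at formation for cell {cid!r}")
        rows.append(
            {
                "cell_id": leaf,
                "mother_exposure_at_formation": formed[mother],
                "exposure_at_formation": formed[leaf],
                "fate": fate_of[leaf],
            }
        )
    df = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=(6, 5))
    colours = {"ICM": "tab:red", "TE": "tab:blue"}
    for fate, sub in df.groupby("fate"):
        ax.scatter(
            sub["mother_exposure_at_formation"],
            sub["exposure_at_formation"],
            c=colours.get(fate, "0.5"), label=fate, s=30,
        )
    ax.set_xlabel("mother's surface exposure at formation")
    ax.set_ylabel("cell's surface exposure at formation")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(title="fate")
    if out_png:
        fig.savefig(out_png, dpi=150, bbox_inches="tight")
    return fig, df


@dataclass
class MovementTrack:
    cell_id: str
    frames: list[int]
    radial_distance: list[float]   # µm from embryo centre, per frame
    displacement: list[float]      # µm moved between consecutive frames


def movement_tracks(
    frames: Sequence[EmbryoFrame],
) -> tuple[list[MovementTrack], pd.DataFrame]:
    """Radial distances and inter-frame displacements per cell, plus the
    mean displacement per frame across cells (movement "waves" summary)."""
    frames = sorted(frames, key=lambda f: f.frame)
    pos: dict[str, list[tuple[int, np.ndarray, float]]] = {}
    for fr in frames:
        centre = fr.embryo_centre
        for c in fr.cells:
            pos.setdefault(c.cell_id, []).append(
                (fr.frame, c.centre, float(np.linalg.norm(c.centre - centre)))
            )
    tracks = []
    per_frame_disp: dict[int, list[float]] = {}
    for cid, entries in sorted(pos.items()):
        entries.sort(key=lambda e: e[0])
        disp = []
        for (f0, p0, _), (f1, p1, _) in zip(entries[:-1], entries[1:]):
            d = float(np.linalg.norm(p1 - p0))
            disp.append(d)
            per_frame_disp.setdefault(f1, []).append(d)
        tracks.append(
            MovementTrack(
                cell_id=cid,
                frames=[e[0] for e in entries],
                radial_distance=[e[2] for e in entries],
                displacement=disp,
            )
        )
    summary = pd.DataFrame(
        {
            "frame": sorted(per_frame_disp),
            "mean_displacement": [
                float(np.mean(per_frame_disp[f])) for f in sorted(per_frame_disp)
            ],
            "n_cells": [len(per_frame_disp[f]) for f in sorted(per_frame_disp)],
        }
    )
    return tracks, summary
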