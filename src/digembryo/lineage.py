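"""Cell tracks, mother→daughter relations, and the exposure-coloured tree.

Divisions are supplied as an explicit table (cell_id, parent_id,
frame_first, frame_last); automated detection from frame membership plus
volume conservation is available as a helper but is never silently trusted.
A division is plausible when the daughters' volumes sum to the mother's
within a tolerance — segmentation conserves volume across division.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .model import Blastomere, DivisionEvent, EmbryoFrame

log = logging.getLogger(__name__)

LINEAGE_COLUMNS = ["cell_id", "parent_id", "frame_first", "frame_last"]

#: Daughters may deviate from the mother's volume by this fraction by default.
DEFAULT_VOLUME_TOLERANCE = 0.2


@dataclass(frozen=True)
class VolumeReport:
    mother_id: str
    mother_volume: float
    daughter_volumes: tuple[float, float]
    relative_error: float
    passed: bool


def validate_division(
    mother: Blastomere,
    daughter1: Blastomere,
    daughter2: Blastomere,
    tol_fraction: float = DEFAULT_VOLUME_TOLERANCE,
) -> VolumeReport:
    """Volume-conservation check: |V(d1)+V(d2) − V(m)| ≤ tol × V(m)."""
    vm = mother.volume
    v1, v2 = daughter1.volume, daughter2.volume
    rel = abs(v1 + v2 - vm) / vm
    return VolumeReport(
        mother_id=mother.cell_id,
        mother_volume=vm,
        daughter_volumes=(v1, v2),
        relative_error=rel,
        passed=rel <= tol_fraction,
    )


class LineageTree:
    """Binary lineage forest over cell tracks.

    Nodes are cell ids; each carries ``frame_first``/``frame_last`` (the
    frames where the track starts and ends) and an optional per-frame record
    list (exposure, radial distance). Roots are the 8-cell-stage blastomeres.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph

    @property
    def roots(self) -> list[str]:
        return sorted(n for n, d in self.graph.in_degree() if d == 0)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n, d in self.graph.out_degree() if d == 0)

    def parent(self, cell_id: str) -> str | None:
        preds = list(self.graph.predecessors(cell_id))
        return preds[0] if preds else None

    def children(self, cell_id: str) -> list[str]:
        return sorted(self.graph.successors(cell_id))

    def node(self, cell_id: str) -> dict:
        return self.graph.nodes[cell_id]

    def ancestry(self, cell_id: str) -> list[str]:
        """Chain [cell, mother, grandmother, …] up to the root."""
        chain = [cell_id]
        while (p := self.parent(chain[-1])) is not None:
            chain.append(p)
        return chain

    def division_events(self) -> list[DivisionEvent]:
        """One event per internal node, generation-labelled by root depth."""
        events = []
        for mother in sorted(self.graph.nodes):
            kids = self.children(mother)
            if not kids:
                continue
            depth = len(self.ancestry(mother)) - 1
            generation = "8to16" if depth == 0 else "16to32"
            frame_after = min(self.node(k)["frame_first"] for k in kids)
            events.append(
                DivisionEvent(
                    mother_id=mother,
                    daughter_ids=(kids[0], kids[1]),
                    frame_before=self.node(mother)["frame_last"],
                    frame_after=frame_after,
                    generation=generation,
                )
            )
        return events

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": n,
                "parent_id": self.parent(n) or "",
                "frame_first": self.node(n)["frame_first"],
                "frame_last": self.node(n)["frame_last"],
            }
            for n in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(rows, columns=LINEAGE_COLUMNS)


def build_lineage(
    frames: Sequence[EmbryoFrame], division_table: pd.DataFrame
) -> LineageTree:
    """Assemble and validate the lineage forest from frames plus a table.

    Checks: every cell appearing in the frames is in the table; parents have
    exactly two daughters; a mother never coexists with her daughters; a
    track absent from an unsegmented intermediate frame bridges the gap
    without creating a spurious division.
    """
    table = division_table.copy()
    missing_cols = set(LINEAGE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"lineage table missing columns {sorted(missing_cols)}")
    table["parent_id"] = table["parent_id"].fillna("").astype(str)

    known = set(table["cell_id"].astype(str))
    frame_presence: dict[str, list[int]] = {}
    for fr in frames:
        for c in fr.cells:
            frame_presence.setdefault(c.cell_id, []).append(fr.frame)
    orphans = sorted(set(frame_presence) - known)
    if orphans:
        raise ValueError(f"cells present in frames but absent from lineage: {orphans}")

    g = nx.DiGraph()
    for row in table.itertuples(index=False):
        cid = str(row.cell_id)
        present = frame_presence.get(cid)
        first = int(row.frame_first) if present is None else min(present)
        last = int(row.frame_last) if present is None else max(present)
        g.add_node(cid, frame_first=first, frame_last=last)
    for row in table.itertuples(index=False):
        if row.parent_id:
            if row.parent_id not in g:
                raise ValueError(
                    f"cell {row.cell_id!r} names unknown parent {row.parent_id!r}"
                )
            g.add_edge(str(row.parent_id), str(row.cell_id))

    if not nx.is_forest(g):
        raise ValueError("lineage graph contains a cycle")
    for n in g.nodes:
        deg = g.out_degree(n)
        if deg not in (0, 2):
            raise ValueError(f"cell {n!r} has {deg} daughters; divisions are binary")
        if deg == 2:
            after = min(g.nodes[k]["frame_first"] for k in g.successors(n))
            if g.nodes[n]["frame_last"] >= after:
                raise ValueError(
                    f"mother {n!r} persists to frame {g.nodes[n]['frame_last']} "
                    f"but daughters appear at frame {after}"
                )
    return LineageTree(g)


def detect_divisions(
    frames: Sequence[EmbryoFrame],
    tol_fraction: float = DEFAULT_VOLUME_TOLERANCE,
) -> pd.DataFrame:
    """Heuristic division detection: a cell id disappears between consecutive
    segmented frames while two new ids appear whose summed volume matches.

    Several mothers may divide in the same transition, and daughters of one
    wave often have near-identical volumes, so volume conservation alone
    cannot pair them; among volume-consistent pairs the one whose
    volume-weighted midpoint falls closest to the vanished mother's centre
    is chosen (mass is conserved through cleavage, so the true pair's
    centroid coincides with the mother). Returns a lineage table; intended
    as a starting point for manual review, not as ground truth.
    """
    frames = sorted(frames, key=lambda f: f.frame)
    parent_of: dict[str, str] = {}
    first_seen: dict[str, int] = {}
    last_seen: dict[str, int] = {}
    for fr in frames:
        for c in fr.cells:
            first_seen.setdefault(c.cell_id, fr.frame)
            last_seen[c.cell_id] = fr.frame

    for prev, curr in zip(frames[:-1], frames[1:]):
        prev_ids = {c.cell_id for c in prev.cells}
        curr_ids = {c.cell_id for c in curr.cells}
        gone = sorted(prev_ids - curr_ids)
        new = sorted(curr_ids - prev_ids)
        for mother_id in gone:
            mother = prev.cell(mother_id)
            best = None
            for i, a in enumerate(new):
                for b in new[i + 1 :]:
                    rep = validate_division(mother, curr.cell(a), curr.cell(b), tol_fraction)
                    if not rep.passed:
                        continue
                    ca, cb = curr.cell(a), curr.cell(b)
                    midpoint = (ca.volume * ca.centre + cb.volume * cb.centre) / (
                        ca.volume + cb.volume
                    )
                    score = float(np.linalg.norm(midpoint - mother.centre))
                    if best is None or (score, rep.relative_error) < best[:2]:
                        best = (score, rep.relative_error, a, b)
            if best is not None:
                _, _, a, b = best
                parent_of[a] = mother_id
                parent_of[b] = mother_id
                new = [x for x in new if x not in (a, b)]
            else:
                log.warning(
                    "no volume-consistent daughter pair found for %s after frame %d",
                    mother_id,
                    prev.frame,
                )
    rows = [
        {
            "cell_id": cid,
            "parent_id": parent_of.get(cid, ""),
            "frame_first": first_seen[cid],
            "frame_last": last_seen[cid],
        }
        for cid in sorted(first_seen)
    ]
    return pd.DataFrame(rows, columns=LINEAGE_COLUMNS)


def attach_records(
    tree: LineageTree,
    exposure_table: pd.DataFrame,
    frames: Sequence[EmbryoFrame] | None = None,
) -> None:
    """Store per-frame (exposure, radial distance) records on tree nodes."""
    radial: dict[tuple[str, int], float] = {}
    if frames is not None:
        for fr in frames:
            centre = fr.embryo_centre
            for c in fr.cells:
                radial[(c.cell_id, fr.frame)] = float(
                    np.linalg.norm(c.centre - centre)
                )
    for cid in tree.graph.nodes:
        sub = exposure_table[exposure_table["cell_id"] == cid].sort_values("frame")
        tree.node(cid)["records"] = [
            {
                "frame": int(r.frame),
                "exposure": float(r.exposure),
                "radial": radial.get((cid, int(r.frame))),
            }
            for r in sub.itertuples(index=False)
        ]


def lineage_figure(
    tree: LineageTree,
    exposure_table: pd.DataFrame,
    out_png: str | None = None,
    cmap: str = "viridis",
):
    """Exposure-coloured lineage tree.

    Rows are the segmented frames in order — the vertical spacing between
    rows is *not* uniform time, mirroring sparse segmentation. Colour encodes
    surface exposure on a fixed [0, 1] scale. Returns (figure, plotted-point
    table).
    """
    exp = {
        (str(r.cell_id), int(r.frame)): float(r.exposure)
        for r in exposure_table.itertuples(index=False)
    }
    all_frames = sorted({f for (_, f) in exp})
    row_of = {f: i for i, f in enumerate(all_frames)}

    # x position: leaves evenly spaced in DFS order, internals centred
    xpos: dict[str, float] = {}
    next_x = [0.0]

    def place(n: str) -> float:
        kids = tree.children(n)
        if not kids:
            xpos[n] = next_x[0]
            next_x[0] += 1.0
        else:
            xpos[n] = float(np.mean([place(k) for k in kids]))
        return xpos[n]

    for r in tree.roots:
        place(r)

    norm = matplotlib.colors.Normalize(vmin=0.0, vmax=1.0)
    cmap_obj = matplotlib.colormaps[cmap]
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(tree.leaves)), 6))
    rows = []
    for n in tree.graph.nodes:
        node = tree.node(n)
        cell_frames = [
            f for f in all_frames
            if node["frame_first"] <= f <= node["frame_last"] and (n, f) in exp
        ]
        for f0, f1 in zip(cell_frames[:-1], cell_frames[1:]):
            ax.plot(
                [xpos[n], xpos[n]],
                [row_of[f0], row_of[f1]],
                color=cmap_obj(norm(exp[(n, f0)])),
                linewidth=3,
                solid_capstyle="butt",
            )
        for f in cell_frames:
            ax.scatter(
                [xpos[n]], [row_of[f]],
                c=[cmap_obj(norm(exp[(n, f)]))], s=14, zorder=3,
            )
            rows.append(
                {"cell_id": n, "frame": f, "x": xpos[n], "row": row_of[f],
                 "exposure": exp[(n, f)]}
            )
        kids = tree.children(n)
        if kids and cell_frames:
            y = row_of[cell_frames[-1]]
            ax.plot(
                [min(xpos[k] for k in kids), max(xpos[k] for k in kids)],
                [y + 0.5, y + 0.5],
                color="0.6", linewidth=1,
            )
            for k in kids:
                ax.plot([xpos[k], xpos[k]], [y + 0.5, y + 1.0], color="0.6",
                        linewidth=1)
    ax.invert_yaxis()
    ax.set_ylabel("segmented frame (rows are not uniform time)")
    ax.set_xticks([])
    fig.colorbar(
        matplotlib.cm.ScalarMappable(norm=norm, cmap=cmap_obj),
        ax=ax, label="surface exposure",
    )
    if out_png:
        fig.savefig(out_png, dpi=150, bbox_inches="tight")
    return fig, pd.DataFrame(rows)
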