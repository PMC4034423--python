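"""Dataset readers and writers.

A dataset on disk is a directory with a ``manifest.json``, one ASCII OBJ (or
PLY) mesh per cell per frame, a lineage CSV (cell_id, parent_id,
frame_first, frame_last), and optionally a multi-page TIFF membrane volume
with its spacing registered in the manifest. Coordinates are always physical
micrometres; the manifest declares the unit explicitly and loading anything
else is an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .lineage import LINEAGE_COLUMNS
from .model import Blastomere, EmbryoFrame, build_frames
from .polarity import VoxelVolume

MANIFEST_NAME = "manifest.json"
UNITS = "um"


def _export_ply_double(mesh: trimesh.Trimesh, path: Path) -> None:
    """Binary little-endian PLY with float64 vertices.

    trimesh's own PLY writer downcasts coordinates to float32, which is not
    enough to round-trip µm meshes with the precision the analysis promises.
    """
    v = np.ascontiguousarray(mesh.vertices, dtype="<f8")
    f = np.ascontiguousarray(mesh.faces, dtype="<i4")
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {len(v)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(f)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    counts = np.full((len(f), 1), 3, dtype="u1")
    face_block = np.concatenate([counts, f.view("u1").reshape(len(f), -1)], axis=1)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(v.tobytes())
        fh.write(face_block.tobytes())


@dataclass
class Dataset:
    dataset_id: str
    frames: list[EmbryoFrame]
    lineage_table: pd.DataFrame
    frame_minutes: dict[int, float]
    volume: VoxelVolume | None = None
    dividing: dict[str, bool] = field(default_factory=dict)

    @property
    def frames_by_index(self) -> dict[int, EmbryoFrame]:
        return {f.frame: f for f in self.frames}


def write_dataset(
    out_dir: str | Path,
    frames: list[EmbryoFrame],
    lineage_table: pd.DataFrame,
    frame_minutes: dict[int, float] | None = None,
    volume: VoxelVolume | None = None,
    dividing: dict[str, bool] | None = None,
    dataset_id: str = "embryo",
    mesh_format: str = "obj",
) -> Path:
    """Write a dataset directory; returns the manifest path."""
    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    records = []
    for fr in frames:
        for cell in fr.cells:
            rel = f"meshes/{cell.cell_id}_f{fr.frame}.{mesh_format}"
            if mesh_format == "obj":
                # ASCII OBJ needs enough digits to keep µm coordinates (and
                # all downstream statistics) stable through a round trip
                (out / rel).write_text(
                    trimesh.exchange.obj.export_obj(cell.mesh, digits=12)
                )
            elif mesh_format == "ply":
                _export_ply_double(cell.mesh, out / rel)
            else:
                cell.mesh.export(out / rel)
            rec = {"cell_id": cell.cell_id, "frame": fr.frame, "mesh": rel}
            if dividing and cell.cell_id in dividing:
                rec["dividing"] = bool(dividing[cell.cell_id])
            records.append(rec)
    lineage_rel = "lineage.csv"
    lineage_table.to_csv(out / lineage_rel, index=False)
    if frame_minutes is None:
        frame_minutes = {fr.frame: 15.0 * fr.frame for fr in frames}
    manifest = {
        "dataset_id": dataset_id,
        "units": UNITS,
        "records": records,
        "lineage": lineage_rel,
        "frame_minutes": {str(k): v for k, v in frame_minutes.items()},
    }
    if volume is not None:
        import tifffile

        vol_rel = "membrane.tif"
        tifffile.imwrite(out / vol_rel, volume.data.astype(np.float32))
        manifest["volume"] = {
            "path": vol_rel,
            "spacing_um": list(volume.spacing),
            "origin_um": list(volume.origin),
        }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return out / MANIFEST_NAME


def read_dataset(manifest_path: str | Path) -> Dataset:
    """Load and fully validate a dataset from its manifest.

    Validation failures are loud and name the offending cell/frame: missing
    mesh files, non-watertight meshes, unit mismatches, duplicate
    (cell_id, frame) records.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    units = manifest.get("units")
    if units != UNITS:
        raise ValueError(f"unit mismatch: manifest declares {units!r}, expected '{UNITS}'")

    blastomeres = []
    dividing: dict[str, bool] = {}
    seen: set[tuple[str, int]] = set()
    for rec in manifest["records"]:
        cid, fr = str(rec["cell_id"]), int(rec["frame"])
        if (cid, fr) in seen:
            raise ValueError(f"duplicate record for cell {cid!r} at frame {fr}")
        seen.add((cid, fr))
        mesh_path = root / rec["mesh"]
        if not mesh_path.exists():
            raise FileNotFoundError(
                f"mesh for cell {cid!r} frame {fr} missing: {mesh_path}"
            )
        mesh = trimesh.load_mesh(mesh_path, process=False)
        blastomeres.append(Blastomere(cell_id=cid, frame=fr, mesh=mesh))
        if "dividing" in rec:
            dividing[cid] = bool(rec["dividing"])

    lineage_table = pd.read_csv(
        root / manifest["lineage"], dtype={"cell_id": str}, keep_default_na=False
    )
    lineage_table = lineage_table[LINEAGE_COLUMNS]

    volume = None
    if "volume" in manifest:
        import tifffile

        vol = manifest["volume"]
        data = tifffile.imread(root / vol["path"])
        volume = VoxelVolume(
            data=data,
            spacing=tuple(vol["spacing_um"]),
            origin=tuple(vol.get("origin_um", (0.0, 0.0, 0.0))),
        )

    return Dataset(
        dataset_id=manifest.get("dataset_id", "dataset"),
        frames=build_frames(blastomeres),
        lineage_table=lineage_table,
        frame_minutes={int(k): float(v) for k, v in manifest["frame_minutes"].items()},
        volume=volume,
        dividing=dividing,
    )
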