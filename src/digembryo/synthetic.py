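"""Ground-truthed digital-embryo generator.

Emulates the study design the analysis assumes: embryos followed from the
8- to the 32-cell stage at a nominal 15-minute frame interval, near-spherical
compacted blastomeres, two division waves whose angle distribution is
configurable (isotropic sin(θ), fixed, or a mixture with a configured
asymmetric fraction), post-division "jostling" rearrangement, optional
inward movement of outside cells at the 16-cell stage, exact volume
conservation across division, and a positional fate rule at the 32-cell
stage.

Cells are rigid spheres (icosphere meshes) relaxed by pairwise overlap
repulsion plus a centripetal compaction force inside a spherical envelope.
Real blastomeres deform; sphere packing suffices for the exposure, angle and
fate logic while keeping every ground-truth quantity exact. Division placement
is frozen during the measurement frame — daughters appear exactly at
mother ± r_d·u along the sampled axis u, and nothing else moves — so the true
division angle is recoverable from the meshes to numerical precision.

All randomness flows from one seeded generator; a fixed seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

from . import geometry
from .model import Blastomere, DivisionEvent, EmbryoFrame, FateLabel, assign_fates
from .polarity import VoxelVolume

#: Divisions with θ below this are called asymmetric (tangential cleavage).
ASYMMETRIC_ANGLE_DEG = 30.0

#: At the 16-cell stage the embryo interior has room for only about this
#: many blastomeres; internalisation saturates there. Cells selected beyond
#: the capacity stay outside (they cannot all be accommodated inside).
INTERIOR_CAPACITY_16 = 2


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic embryo.

    Defaults describe a compacted mouse morula followed 8 → 32 cells:
    ~13 µm blastomere radius at the 8-cell stage, frames every 15 minutes,
    isotropically oriented divisions, mild jostling after each wave, and a
    positional (inside ⇒ ICM) fate call at exposure < 0.01.
    """

    seed: int = 0
    n_start: int = 8
    n_end: int = 32
    frame_minutes: float = 15.0
    cell_radius_um: float = 13.0
    envelope_radius_um: float = 28.0
    subdivisions: int = 2
    angle_policy: Literal["isotropic", "fixed", "mixture"] = "isotropic"
    fixed_angle_deg: float = 0.0
    asymmetric_fraction: float = 0.5
    jostle_strength_um: float = 1.0
    internalisation_rate: float = 0.3
    relax_frames_per_stage: int = 2
    #: split each division round into two staggered sub-waves (one frame
    #: apart), as seen in time-lapse data; False divides everything at once
    stagger_waves: bool = True
    fate_threshold: float = 0.01
    te_restriction_threshold: float | None = None
    compute_fates: bool = True
    # voxel rendering
    apical_enrichment: float = 2.0
    noise_sd_fraction: float = 0.0
    voxel_spacing_um: float = 1.0
    membrane_thickness_um: float = 2.0

    def __post_init__(self):
        if self.n_start < 2 or self.n_end != 4 * self.n_start:
            raise ValueError("two division rounds required: n_end = 4 × n_start")
        if not 0.0 <= self.internalisation_rate <= 1.0:
            raise ValueError("internalisation_rate must lie in [0, 1]")
        if not 0.0 <= self.asymmetric_fraction <= 1.0:
            raise ValueError("asymmetric_fraction must lie in [0, 1]")
        total = self.n_start * self.cell_radius_um**3
        if total > 0.9 * self.envelope_radius_um**3 * 0.9:
            raise ValueError(
                "infeasible packing: cells cannot fit in the embryo envelope"
            )


@dataclass
class SimulationResult:
    """Frames plus lineage plus exact ground truth for every estimated quantity."""

    config: SimulationConfig
    frames: list[EmbryoFrame]
    lineage_table: pd.DataFrame
    events: list[DivisionEvent]
    frame_minutes: dict[int, float]
    true_angles: dict[str, float]          # mother id → θ (degrees)
    true_outer: dict[str, str | None]      # mother id → outer daughter id
    true_asymmetric: dict[str, bool]       # mother id → mixture component
    internalised: list[str]                # cells pulled inward at 16-cell stage
    fates: list[FateLabel] | None
    final_exposures: dict[str, float] | None

    @property
    def frames_by_index(self) -> dict[int, EmbryoFrame]:
        return {f.frame: f for f in self.frames}


_UNIT_SPHERES: dict[int, trimesh.Trimesh] = {}


def unit_icosphere(subdivisions: int) -> trimesh.Trimesh:
    if subdivisions not in _UNIT_SPHERES:
        _UNIT_SPHERES[subdivisions] = trimesh.creation.icosphere(
            subdivisions=subdivisions, radius=1.0
        )
    return _UNIT_SPHERES[subdivisions]


def sphere_mesh(centre: np.ndarray, radius: float, subdivisions: int) -> trimesh.Trimesh:
    unit = unit_icosphere(subdivisions)
    return trimesh.Trimesh(
        vertices=unit.vertices * radius + np.asarray(centre, dtype=np.float64),
        faces=unit.faces,
        process=False,
    )


def icosphere_inradius_fraction(subdivisions: int) -> float:
    """Distance from centre to the nearest face plane of a unit icosphere.

    The mesh is inscribed in the true sphere; points within this fraction of
    the nominal radius are guaranteed to lie inside the mesh solid.
    """
    unit = unit_icosphere(subdivisions)
    return float(
        np.einsum("ij,ij->i", unit.triangles_center, unit.face_normals).min()
    )


def _relax(
    pos: np.ndarray,
    radii: np.ndarray,
    envelope_radius: float,
    inward: Sequence[int] = (),
    n_iter: int = 40,
    compaction_step: float = 0.1,
    inward_step: float = 4.0,
) -> np.ndarray:
    """Overlap-relaxation of rigid spheres inside a compacting envelope.

    Each iteration: overlapping pairs push apart by half the overlap; every
    cell drifts ``compaction_step`` µm toward the current centroid; cells
    protruding beyond the envelope are clamped back; ``inward`` cells take an
    extra ``inward_step`` µm toward the centroid (internalising movement).
    Deterministic — no randomness here.
    """
    pos = np.array(pos, dtype=np.float64)
    for _ in range(n_iter):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        overlap = radii[:, None] + radii[None, :] - dist
        mask = overlap > 0
        if mask.any():
            masked_overlap = np.where(mask, overlap, 0.0)
            dist_safe = np.where(mask, dist, 1.0)
            push = 0.5 * masked_overlap[..., None] * diff / dist_safe[..., None]
            pos = pos + 0.5 * push.sum(axis=1)
        centroid = pos.mean(axis=0)
        offset = pos - centroid
        r = np.linalg.norm(offset, axis=1)
        safe_r = np.maximum(r, 1e-12)
        dir_in = -offset / safe_r[:, None]
        pos = pos + dir_in * np.minimum(compaction_step, r)[:, None]
        r = r - np.minimum(compaction_step, r)
        excess = r + radii - envelope_radius
        clamp = excess > 0
        pos[clamp] += dir_in[clamp] * excess[clamp, None]
        for i in inward:
            pos[i] = pos[i] + dir_in[i] * min(inward_step, max(r[i] - 1.0, 0.0))
    return pos


def _sample_theta(rng: np.random.Generator, config: SimulationConfig) -> tuple[float, bool]:
    """Division angle θ (degrees) plus the asymmetric-component flag."""
    if config.angle_policy == "fixed":
        theta = config.fixed_angle_deg
        return theta, theta < ASYMMETRIC_ANGLE_DEG
    if config.angle_policy == "isotropic":
        theta = float(np.degrees(np.arccos(rng.uniform(0.0, 1.0))))
        return theta, theta < ASYMMETRIC_ANGLE_DEG
    if config.angle_policy == "mixture":
        split = np.cos(np.radians(ASYMMETRIC_ANGLE_DEG))
        if rng.uniform() < config.asymmetric_fraction:
            # sin-weighted, truncated to the asymmetric range [0°, 30°)
            theta = float(np.degrees(np.arccos(rng.uniform(split, 1.0))))
            return theta, True
        theta = float(np.degrees(np.arccos(rng.uniform(0.0, split))))
        return theta, False
    raise ValueError(f"unknown angle_policy {config.angle_policy!r}")


def _axis_at_angle(
    rng: np.random.Generator, radial_unit: np.ndarray, theta_deg: float
) -> np.ndarray:
    """Unit axis at angle θ to the radial direction, uniform in azimuth."""
    r = radial_unit
    # any vector not parallel to r seeds the orthonormal basis
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(r[0]) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(r, seed_vec)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(r, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    t = np.radians(theta_deg)
    return np.cos(t) * r + np.sin(t) * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _weighted_centre(pos: np.ndarray, radii: np.ndarray) -> np.ndarray:
    w = radii**3
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run one synthetic embryo from ``n_start`` to ``n_end`` cells.

    Returns frames, a lineage table, division events, and exact ground truth
    (true angles, true outer daughters, mixture components, internalised
    cells, and — when ``compute_fates`` — positional fate labels at the final
    frame).
    """
    rng = np.random.default_rng(config.seed)
    n0 = config.n_start
    r0 = config.cell_radius_um

    # initial blastomeres at cube corners (or a ring for other n), then relaxed
    if n0 == 8:
        corners = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
            dtype=np.float64,
        )
        pos = corners * r0 * 0.95
    else:
        phi = 2 * np.pi * np.arange(n0) / n0
        pos = np.stack(
            [r0 * np.cos(phi), r0 * np.sin(phi), np.zeros(n0)], axis=1
        )
    pos += rng.normal(0.0, 0.5, size=pos.shape)  # break symmetry
    radii = np.full(n0, r0)
    ids = [f"C{i + 1}" for i in range(n0)]
    pos = _relax(pos, radii, config.envelope_radius_um)

    frames_cells: dict[int, tuple[list[str], np.ndarray, np.ndarray]] = {}
    first_seen: dict[str, int] = {}
    last_seen: dict[str, int] = {}
    parent_of: dict[str, str] = {}
    events: list[DivisionEvent] = []
    true_angles: dict[str, float] = {}
    true_outer: dict[str, str | None] = {}
    true_asym: dict[str, bool] = {}

    def snapshot(t: int):
        frames_cells[t] = (list(ids), pos.copy(), radii.copy())
        for cid in ids:
            first_seen.setdefault(cid, t)
            last_seen[cid] = t

    t = 0
    snapshot(t)
    t += 1
    pos = _relax(
        pos + rng.normal(0.0, config.jostle_strength_um, pos.shape),
        radii,
        config.envelope_radius_um,
    )
    snapshot(t)

    def division_wave(generation: str, t: int) -> int:
        """Divide all current cells in two staggered sub-waves; returns new t."""
        nonlocal pos, radii, ids
        order = [ids[i] for i in rng.permutation(len(ids))]
        if config.stagger_waves:
            halves = [order[: len(order) // 2], order[len(order) // 2 :]]
        else:
            halves = [order]
        for sub in halves:
            embryo_centre = _weighted_centre(pos, radii)
            new_ids: list[str] = []
            new_pos: list[np.ndarray] = []
            new_radii: list[float] = []
            dividing = set(sub)
            for i, cid in enumerate(ids):
                if cid not in dividing:
                    new_ids.append(cid)
                    new_pos.append(pos[i])
                    new_radii.append(radii[i])
                    continue
                radial = pos[i] - embryo_centre
                norm = np.linalg.norm(radial)
                if norm < 1e-9:
                    radial = np.array([0.0, 0.0, 1.0])
                    norm = 1.0
                rhat = radial / norm
                theta, asym = _sample_theta(rng, config)
                axis = _axis_at_angle(rng, rhat, theta)
                rd = radii[i] * 2.0 ** (-1.0 / 3.0)
                da, db = f"{cid}a", f"{cid}b"
                pa = pos[i] + rd * axis
                pb = pos[i] - rd * axis
                new_ids += [da, db]
                new_pos += [pa, pb]
                new_radii += [rd, rd]
                ra = np.linalg.norm(pa - embryo_centre)
                rb = np.linalg.norm(pb - embryo_centre)
                outer = da if ra > rb else db if rb > ra else None
                parent_of[da] = cid
                parent_of[db] = cid
                events.append(
                    DivisionEvent(
                        mother_id=cid,
                        daughter_ids=(da, db),
                        frame_before=t,
                        frame_after=t + 1,
                        generation=generation,
                    )
                )
                true_angles[cid] = theta
                true_outer[cid] = outer
                true_asym[cid] = asym
            ids = new_ids
            pos = np.array(new_pos)
            radii = np.array(new_radii)
            t += 1
            snapshot(t)  # frozen measurement frame: only daughters changed
        return t

    t = division_wave("8to16", t)

    # 16-cell stage: jostle + relax; some outside cells may move inward
    centre16 = _weighted_centre(pos, radii)
    radial16 = np.linalg.norm(pos - centre16, axis=1)
    outer_half = list(np.argsort(radial16)[len(ids) // 2 :])
    internal_idx = [
        i for i in outer_half if rng.uniform() < config.internalisation_rate
    ][:INTERIOR_CAPACITY_16]
    internalised = [ids[i] for i in internal_idx]
    for _ in range(config.relax_frames_per_stage):
        t += 1
        pos = _relax(
            pos + rng.normal(0.0, config.jostle_strength_um, pos.shape),
            radii,
            config.envelope_radius_um,
            inward=internal_idx,
        )
        snapshot(t)

    t = division_wave("16to32", t)

    for _ in range(config.relax_frames_per_stage):
        t += 1
        pos = _relax(
            pos + rng.normal(0.0, config.jostle_strength_um, pos.shape),
            radii,
            config.envelope_radius_um,
        )
        snapshot(t)

    # materialise meshes
    frames: list[EmbryoFrame] = []
    for ft in sorted(frames_cells):
        cids, p, r = frames_cells[ft]
        cells = [
            Blastomere(
                cell_id=cid,
                frame=ft,
                mesh=sphere_mesh(p[i], r[i], config.subdivisions),
            )
            for i, cid in enumerate(cids)
        ]
        frames.append(EmbryoFrame(frame=ft, cells=cells))

    lineage_table = pd.DataFrame(
        [
            {
                "cell_id": cid,
                "parent_id": parent_of.get(cid, ""),
                "frame_first": first_seen[cid],
                "frame_last": last_seen[cid],
            }
            for cid in sorted(first_seen)
        ]
    )

    fates = None
    final_exposures = None
    if config.compute_fates:
        final = frames[-1]
        final_exposures = {
            cid: rec.exposure
            for cid, rec in geometry.frame_exposures(final).items()
        }
        fates = assign_fates(final, final_exposures, config.fate_threshold)
        if config.te_restriction_threshold is not None:
            fates = _apply_te_restriction(
                frames, events, fates, config.te_restriction_threshold
            )

    return SimulationResult(
        config=config,
        frames=frames,
        lineage_table=lineage_table,
        events=events,
        frame_minutes={f.frame: f.frame * config.frame_minutes for f in frames},
        true_angles=true_angles,
        true_outer=true_outer,
        true_asymmetric=true_asym,
        internalised=internalised,
        fates=fates,
        final_exposures=final_exposures,
    )


def _apply_te_restriction(
    frames: list[EmbryoFrame],
    events: list[DivisionEvent],
    fates: list[FateLabel],
    threshold: float,
) -> list[FateLabel]:
    """Force TE on cells whose mother's exposure at formation exceeded the
    threshold (a history-based restriction layered on the positional rule)."""
    by_index = {f.frame: f for f in frames}
    formation_frame: dict[str, int] = {}
    for ev in events:
        for d in ev.daughter_ids:
            formation_frame[d] = ev.frame_after
    mother_of = {d: ev.mother_id for ev in events for d in ev.daughter_ids}
    mother_exposure: dict[str, float] = {}
    for cid, mother in mother_of.items():
        if mother in formation_frame:
            fr = by_index[formation_frame[mother]]
            mother_exposure[cid] = geometry.surface_exposure(
                fr.cell(mother), fr
            ).exposure
    out = []
    for f in fates:
        if mother_exposure.get(f.cell_id, 0.0) > threshold:
            out.append(FateLabel(cell_id=f.cell_id, fate="TE"))
        else:
            out.append(f)
    return out


def fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistributed unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def make_enclosed_blastocyst(
    n_inside: int,
    n_total: int = 32,
    inner_radius_um: float = 2.5,
    inner_shell_um: float = 5.2,
    outer_shell_um: float = 21.0,
    outer_radius_um: float = 13.0,
    subdivisions: int = 2,
    frame: int = 0,
) -> tuple[EmbryoFrame, list[str]]:
    """Deterministic blastocyst with exactly ``n_inside`` fully enclosed cells.

    ``n_inside`` small cells sit near the origin; the remaining cells form a
    heavily overlapping spherical shell. The construction proves enclosure
    geometrically: it verifies that the entire sphere of radius
    ``outer_shell_um`` is covered by the *inscribed* solids of the shell
    meshes, so every ray leaving an inner cell must pass through (and
    therefore hit) a shell mesh. Returns the frame and the inner cell ids.
    """
    if not 1 <= n_inside <= 10:
        raise ValueError("n_inside must be between 1 and 10")
    if n_total <= n_inside:
        raise ValueError("need at least one outer cell")

    # inner cluster: origin plus icosahedron vertices (pairwise non-overlapping)
    icosa = trimesh.creation.icosahedron().vertices
    icosa = icosa / np.linalg.norm(icosa, axis=1, keepdims=True)
    inner_centres = np.concatenate(
        [np.zeros((1, 3)), icosa[: n_inside - 1] * inner_shell_um], axis=0
    )[:n_inside]
    inner_extent = (
        np.linalg.norm(inner_centres, axis=1).max() + inner_radius_um
    )
    if inner_extent >= outer_shell_um - outer_radius_um:
        raise ValueError("inner cluster pokes into the enclosing shell")

    n_outer = n_total - n_inside
    outer_centres = fibonacci_sphere(n_outer) * outer_shell_um

    # coverage proof: every point of the mid-shell sphere lies inside the
    # inscribed ball of some outer mesh, with a safety margin
    r_in = outer_radius_um * icosphere_inradius_fraction(subdivisions)
    probe = fibonacci_sphere(16384) * outer_shell_um
    gap = np.min(
        np.linalg.norm(probe[:, None, :] - outer_centres[None, :, :], axis=-1),
        axis=1,
    )
    margin = r_in - gap.max()
    if margin <= 0.5:
        raise ValueError(
            f"shell coverage not guaranteed (margin {margin:.3f} µm); "
            "increase outer_radius_um or the number of outer cells"
        )

    cells = [
        Blastomere(
            cell_id=f"IN{i + 1}",
            frame=frame,
            mesh=sphere_mesh(c, inner_radius_um, subdivisions),
        )
        for i, c in enumerate(inner_centres)
    ] + [
        Blastomere(
            cell_id=f"OUT{i + 1}",
            frame=frame,
            mesh=sphere_mesh(c, outer_radius_um, subdivisions),
        )
        for i, c in enumerate(outer_centres)
    ]
    return (
        EmbryoFrame(frame=frame, cells=cells),
        [f"IN{i + 1}" for i in range(n_inside)],
    )


def make_shell_frame(
    n_cells: int,
    cell_radius_um: float = 6.0,
    overlap: float = 0.9,
    subdivisions: int = 2,
    frame: int = 0,
) -> EmbryoFrame:
    """Single-layer spherical arrangement: every cell touches neighbours
    (basolateral contact) and faces outward (apical exposure) — a stand-in
    morula surface for polarity measurements."""
    shell_radius = 2.0 * cell_radius_um * overlap * np.sqrt(n_cells) / 3.809
    centres = fibonacci_sphere(n_cells) * shell_radius
    cells = [
        Blastomere(
            cell_id=f"S{i + 1}",
            frame=frame,
            mesh=sphere_mesh(c, cell_radius_um, subdivisions),
        )
        for i, c in enumerate(centres)
    ]
    return EmbryoFrame(frame=frame, cells=cells)


def render_voxels(
    frame: EmbryoFrame,
    spacing_um: float = 1.0,
    membrane_thickness_um: float = 2.0,
    apical_enrichment: float | Mapping[str, float] = 2.0,
    base_intensity: float = 100.0,
    noise_sd_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
    pad_um: float = 3.0,
) -> VoxelVolume:
    """Paint a membrane-channel volume for a frame.

    A shell of ``membrane_thickness_um`` straddles each cell surface; voxels
    whose nearest face is external get ``apical_enrichment`` × the
    basolateral intensity (per cell when a mapping is given — dividing cells
    are rendered with reduced enrichment that way). Where shells overlap,
    basolateral paint wins: cell–cell contact zones are basolateral membrane
    for both partners, so no apical enrichment appears there. Gaussian noise
    with SD ``noise_sd_fraction`` × base intensity is added last. The render
    is order-independent.
    """
    if len(frame.cells) == 0:
        raise ValueError("cannot render an empty frame")
    min_radius = min(
        (3.0 * c.volume / (4.0 * np.pi)) ** (1.0 / 3.0) for c in frame.cells
    )
    if min_radius / spacing_um < 3.0:
        raise ValueError(
            f"voxel grid too coarse: {min_radius / spacing_um:.1f} voxels per "
            "cell radius (need ≥ 3)"
        )
    lo = np.min([c.mesh.bounds[0] for c in frame.cells], axis=0) - pad_um
    hi = np.max([c.mesh.bounds[1] for c in frame.cells], axis=0) + pad_um
    shape_xyz = np.ceil((hi - lo) / spacing_um).astype(int) + 1
    data = np.zeros(shape_xyz[::-1], dtype=np.float64)  # (z, y, x)
    volume = VoxelVolume(
        data=data,
        spacing=(spacing_um, spacing_um, spacing_um),
        origin=tuple(lo[::-1]),
    )
    half = membrane_thickness_um / 2.0
    apical_paint = np.zeros_like(data)
    baso_mask = np.zeros(data.shape, dtype=bool)
    for cell in frame.cells:
        enr = (
            apical_enrichment.get(cell.cell_id, 1.0)
            if isinstance(apical_enrichment, Mapping)
            else apical_enrichment
        )
        idx = volume.indices_near_box(cell.mesh.bounds[0] - half, cell.mesh.bounds[1] + half)
        if len(idx) == 0:
            continue
        pts = volume.voxel_centres_world(idx)
        dist, face = geometry.nearest_face(pts, cell.mesh, max_distance=half)
        in_shell = dist <= half
        if not in_shell.any():
            continue
        external = geometry.classify_faces(cell, frame).external
        ext_face = external[face[in_shell]]
        sel_ap = tuple(idx[in_shell][ext_face].T)
        apical_paint[sel_ap] = np.maximum(apical_paint[sel_ap], base_intensity * enr)
        sel_ba = tuple(idx[in_shell][~ext_face].T)
        baso_mask[sel_ba] = True
    data[...] = np.where(
        baso_mask, base_intensity, apical_paint
    )
    if noise_sd_fraction > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        data += rng.normal(0.0, noise_sd_fraction * base_intensity, data.shape)
    volume.data = data
    return volume
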