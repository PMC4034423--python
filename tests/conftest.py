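import numpy as np
import pytest
import trimesh

from digembryo.model import Blastomere, EmbryoFrame
from digembryo.synthetic import SimulationConfig, simulate, sphere_mesh


def make_blastomere(cell_id, centre, radius, subdivisions=2, frame=0):
    return Blastomere(
        cell_id=cell_id,
        frame=frame,
        mesh=sphere_mesh(np.asarray(centre, dtype=float), radius, subdivisions),
    )


def random_rotation(rng):
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_frame(frame, rotation=None, translation=None, scale=1.0):
    """Rigidly move (and optionally scale) every mesh of a frame."""
    cells = []
    for c in frame.cells:
        v = c.mesh.vertices * scale
        if rotation is not None:
            v = v @ rotation.T
        if translation is not None:
            v = v + translation
        cells.append(
            Blastomere(
                cell_id=c.cell_id,
                frame=c.frame,
                mesh=trimesh.Trimesh(v, c.mesh.faces, process=False),
            )
        )
    return EmbryoFrame(frame=frame.frame, cells=cells)


def naive_ray_hits(origins, directions, triangles, exclude=None):
    """Independent any-hit oracle: plane intersection plus same-side
    barycentric sign tests (no pruning, no Möller–Trumbore).

    Inclusive on triangle edges, hits counted at any t > 0.
    """
    origins = np.asarray(origins, float)
    directions = np.asarray(directions, float)
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    n = np.cross(b - a, c - a)
    hit = np.zeros(len(origins), dtype=bool)
    for i, (o, d) in enumerate(zip(origins, directions)):
        denom = n @ d
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.einsum("tk,tk->t", n, a - o) / denom
        ok = (np.abs(denom) > 1e-14) & (t > 0)
        if not ok.any():
            continue
        p = o + t[:, None] * d
        s1 = np.einsum("tk,tk->t", np.cross(b - a, p - a), n)
        s2 = np.einsum("tk,tk->t", np.cross(c - b, p - b), n)
        s3 = np.einsum("tk,tk->t", np.cross(a - c, p - c), n)
        nn = np.einsum("tk,tk->t", n, n)
        eps = 1e-10 * nn
        inside = (s1 >= -eps) & (s2 >= -eps) & (s3 >= -eps)
        ok &= inside
        if exclude is not None and exclude[i] >= 0:
            ok[exclude[i]] = False
        hit[i] = ok.any()
    return hit


def naive_classify(target, frame, eps_fraction=1e-6):
    """All-pairs external/internal labels for one cell (oracle path)."""
    tris = np.concatenate([c.mesh.triangles for c in frame.cells])
    offsets = {}
    start = 0
    for c in frame.cells:
        offsets[c.cell_id] = start
        start += len(c.mesh.faces)
    lo = tris.min(axis=(0, 1))
    hi = tris.max(axis=(0, 1))
    eps = eps_fraction * np.linalg.norm(hi - lo)
    mesh = target.mesh
    origins = mesh.triangles_center + eps * mesh.face_normals
    exclude = offsets[target.cell_id] + np.arange(len(mesh.faces))
    return ~naive_ray_hits(origins, mesh.face_normals, tris, exclude)


@pytest.fixture(scope="session")
def default_sim():
    """One synthetic embryo under the default study conditions (seed 1)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def lone_cell_frame():
    cell = make_blastomere("LONE", (1.0, -2.0, 3.0), 10.0)
    return EmbryoFrame(frame=0, cells=[cell])


@pytest.fixture(scope="session")
def enclosed_frame():
    """Small icosphere strictly inside a hollow large sphere shell."""
    inner = make_blastomere("INNER", (0, 0, 0), 3.0)
    big = trimesh.creation.icosphere(subdivisions=2, radius=12.0)
    small = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    small.invert()
    shell = trimesh.util.concatenate([big, small])
    outer = Blastomere(
        cell_id="SHELL",
        frame=0,
        mesh=trimesh.Trimesh(shell.vertices, shell.faces, process=False),
    )
    return EmbryoFrame(frame=0, cells=[inner, outer])
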