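"""Division-angle computation and the isotropic sin(θ) null.

The angle of division θ is the angle between (i) the line from the mother
cell's centre to the embryo centre in the frame before division and (ii) the
line joining the two daughter centres in the frame after. θ is folded to
[0°, 90°]: 0° means the daughters separate along the radial axis (tangential
cleavage plane, an asymmetric division leaving an inner and an outer
daughter); 90° means a radial cleavage producing two equivalent daughters.

If division axes are oriented uniformly at random, θ follows the sin(θ)
density on [0°, 90°] with CDF 1 − cos θ; observed histograms are tested
against that null with a Pearson χ² goodness-of-fit test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import DivisionEvent, EmbryoFrame

log = logging.getLogger(__name__)

#: Default histogram binning: nine 10° bins over [0°, 90°]. p-values depend
#: on the binning; it is configurable everywhere it is used.
DEFAULT_BIN_EDGES = np.linspace(0.0, 90.0, 10)


def angle_between_lines(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two undirected lines, folded to [0°, 90°]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length direction vector")
    c = abs(float(np.dot(u, v)) / (nu * nv))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def division_angle(
    event: DivisionEvent, frames: Mapping[int, EmbryoFrame]
) -> float:
    """Angle of division θ for one event, in degrees within [0°, 90°].

    Uses the mother's radial axis (mother centre → embryo centre) at
    ``frame_before`` and the daughter–daughter axis at ``frame_after``. A
    warning is logged when the segmentation gap between the two frames
    exceeds one nominal frame interval.
    """
    try:
        before = frames[event.frame_before]
        after = frames[event.frame_after]
    except KeyError as e:
        raise KeyError(f"division of {event.mother_id}: missing frame {e}") from e
    if event.frame_after - event.frame_before > 1:
        log.warning(
            "division of %s: gap of %d frames between mother and daughters",
            event.mother_id,
            event.frame_after - event.frame_before,
        )
    mother = before.cell(event.mother_id)
    radial = mother.centre - before.embryo_centre
    if np.linalg.norm(radial) == 0:
        raise ValueError(
            f"division of {event.mother_id}: mother sits at the embryo centre"
        )
    d1 = after.cell(event.daughter_ids[0])
    d2 = after.cell(event.daughter_ids[1])
    axis = d1.centre - d2.centre
    return angle_between_lines(radial, axis)


def annotate_angles(
    events: Sequence[DivisionEvent], frames: Mapping[int, EmbryoFrame]
) -> list[DivisionEvent]:
    """Fill ``angle_deg`` on every event, in place; returns the same list."""
    for ev in events:
        ev.angle_deg = division_angle(ev, frames)
    return list(events)


@dataclass
class AngleHistogram:
    """Observed division-angle counts with the matched isotropic expectation."""

    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    n: int

    @classmethod
    def from_angles(
        cls, angles_deg: Sequence[float], bin_edges: np.ndarray = DEFAULT_BIN_EDGES
    ) -> "AngleHistogram":
        angles = np.asarray(angles_deg, dtype=np.float64)
        edges = np.asarray(bin_edges, dtype=np.float64)
        if angles.size == 0:
            raise ValueError("no angles supplied")
        if np.any(angles < 0) or np.any(angles > 90):
            raise ValueError("angles must lie in [0°, 90°]")
        observed, _ = np.histogram(angles, bins=edges)
        expected = isotropic_expected(edges, n=angles.size)
        return cls(edges, observed.astype(float), expected, n=int(angles.size))


@dataclass(frozen=True)
class IsotropyTestResult:
    chi2: float
    df: int
    p_value: float
    n: int
    generation: str | None = None


def isotropic_expected(bin_edges: np.ndarray, n: int) -> np.ndarray:
    """Expected bin counts under the isotropic sin(θ) null, scaled to ``n``.

    For a bin [a, b] the isotropic mass is cos a − cos b, since the CDF of θ
    is 1 − cos θ on [0°, 90°].
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    if edges[0] < 0 or edges[-1] > 90:
        raise ValueError("bin edges must lie within [0°, 90°]")
    rad = np.radians(edges)
    return n * (np.cos(rad[:-1]) - np.cos(rad[1:]))


def isotropy_chi2(
    angles_deg: Sequence[float],
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
    generation: str | None = None,
) -> IsotropyTestResult:
    """Pearson χ² goodness of fit of observed angles to the sin(θ) null.

    Degrees of freedom are bins − 1 (the null is fully specified); the
    p-value is the upper tail. No Yates correction and no pooling of
    low-expectation bins is applied.
    """
    hist = AngleHistogram.from_angles(angles_deg, bin_edges)
    if len(hist.observed) < 2:
        raise ValueError("χ² test needs at least two bins")
    if np.any(hist.expected <= 0):
        raise ValueError("degenerate binning: a bin has zero expected count")
    chi2, p = stats.chisquare(hist.observed, hist.expected)
    return IsotropyTestResult(
        chi2=float(chi2),
        df=len(hist.observed) - 1,
        p_value=float(p),
        n=hist.n,
        generation=generation,
    )


def pool_generations(
    angles_8to16: Sequence[float],
    angles_16to32: Sequence[float],
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
) -> AngleHistogram:
    """Histogram of the two division rounds pooled under the same binning."""
    a = np.asarray(angles_8to16, dtype=np.float64)
    b = np.asarray(angles_16to32, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both generations must contain angles")
    return AngleHistogram.from_angles(np.concatenate([a, b]), bin_edges)


def sample_isotropic_angles(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample θ under the isotropic null: θ = arccos(U), U ~ Uniform(0, 1).

    Equivalent to the folded angle between a uniformly random axis and a
    fixed axis.
    """
    return np.degrees(np.arccos(rng.uniform(0.0, 1.0, size=n)))


def angle_table(events: Sequence[DivisionEvent]) -> pd.DataFrame:
    """Flat per-event table (CSV-ready) of annotated division events."""
    return pd.DataFrame(
        [
            {
                "mother_id": ev.mother_id,
                "daughter_1": ev.daughter_ids[0],
                "daughter_2": ev.daughter_ids[1],
                "frame_before": ev.frame_before,
                "frame_after": ev.frame_after,
                "generation": ev.generation,
                "angle_deg": ev.angle_deg,
            }
            for ev in events
        ]
    )
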