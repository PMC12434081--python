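"""Criterion BSA from triangulated body-scan meshes, plus cohort-level QC.

The criterion ("3D optical imaging") BSA of a subject is the total surface
area of their avatar mesh — the sum of the areas of all triangles — with
duplicate scans averaged. Quality control across a cohort uses the iterative
two-sided Grubbs test on the distribution of criterion BSA values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TriMesh",
    "ScanPair",
    "GrubbsResult",
    "triangle_area",
    "mesh_surface_area",
    "load_mesh",
    "average_replicates",
    "grubbs_critical_value",
    "grubbs_outliers",
]


@dataclass
class TriMesh:
    """A triangulated surface: vertices in metres, faces as index triples."""

    vertices: np.ndarray  # (n_vertices, 3) float, metres
    faces: np.ndarray  # (n_faces, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices reference missing vertices")

    def scaled(self, factor: float) -> "TriMesh":
        """Rescale vertex coordinates (e.g. ``factor=0.001`` for mm → m)."""
        return TriMesh(self.vertices * float(factor), self.faces)


@dataclass
class ScanPair:
    """Replicate criterion-BSA measurements (typically two avatars)."""

    subject_id: str
    scan_areas: list = field(default_factory=list)  # m²

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.scan_areas):
            raise ValueError("scan areas must be strictly positive (m²)")


def triangle_area(p0, p1, p2) -> float:
    """Area of one 3D triangle: ``0.5 * |cross(p1 - p0, p2 - p0)|``."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    if not all(np.all(np.isfinite(p)) for p in (p0, p1, p2)):
        raise ValueError("triangle vertices must be finite")
    return 0.5 * float(np.linalg.norm(np.cross(p1 - p0, p2 - p0)))


def mesh_surface_area(mesh: TriMesh) -> float:
    """Total surface area (m²): sum of all triangle areas.

    Winding is ignored (absolute areas are summed) and disjoint components
    add up, matching how scan software totals an avatar's triangles.
    """
    if len(mesh.faces) == 0:
        warnings.warn("mesh has no faces; surface area defined as 0", stacklevel=2)
        return 0.0
    tri = mesh.vertices[mesh.faces]  # (n_faces, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * float(np.linalg.norm(cross, axis=1).sum())


def load_mesh(path, scale: float = 1.0) -> TriMesh:
    """Load an OBJ or PLY mesh file into a :class:`TriMesh`.

    Polygonal faces are triangulated by the loader; ``scale`` converts the
    file's length unit to metres (e.g. ``0.001`` for millimetre meshes).
    """
    import trimesh as _trimesh  # heavyweight import kept local

    loaded = _trimesh.load_mesh(str(path), process=False)
    mesh = TriMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))
    return mesh.scaled(scale) if scale != 1.0 else mesh


def average_replicates(pair: ScanPair) -> float:
    """Criterion BSA of a subject: arithmetic mean of replicate scan areas."""
    if len(pair.scan_areas) == 0:
        raise ValueError(f"subject {pair.subject_id!r} has no scan areas")
    if len(pair.scan_areas) == 1:
        warnings.warn(
            f"subject {pair.subject_id!r} has a single scan; "
            "using it directly as criterion BSA",
            stacklevel=2,
        )
    return float(np.mean(pair.scan_areas))


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile.

    ``G_crit = (n-1)/sqrt(n) * sqrt(t² / (n - 2 + t²))`` with
    ``t = t_{alpha/(2n), n-2}``.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


@dataclass
class GrubbsResult:
    """Outcome of the iterative Grubbs screen."""

    flagged_indices: list  # indices into the original sample, in flag order
    steps: list  # per iteration: dict(index, value, G, G_crit, n)

    def to_dict(self) -> dict:
        return {"flagged_indices": self.flagged_indices, "steps": self.steps}


def grubbs_outliers(values, alpha: float = 0.05) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier screen.

    Repeatedly tests the observation with the largest absolute deviation
    from the sample mean against the t-based critical value at ``alpha``,
    removing it if significant, until no further flag or n drops below 3.
    A zero-variance (or near) remainder stops the iteration with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(values) < 3:
        raise ValueError("Grubbs test requires at least 3 values")

    active = list(range(len(values)))
    flagged: list = []
    steps: list = []
    while len(active) >= 3:
        sample = values[active]
        sd = sample.std(ddof=1)
        if sd <= 1e-12 * max(1.0, abs(sample.mean())):
            warnings.warn(
                "zero-variance sample: Grubbs test not applicable", stacklevel=2
            )
            break
        dev = np.abs(sample - sample.mean())
        pos = int(np.argmax(dev))
        g = dev[pos] / sd
        g_crit = grubbs_critical_value(len(active), alpha)
        steps.append(
            {
                "index": active[pos],
                "value": float(values[active[pos]]),
                "G": float(g),
                "G_crit": float(g_crit),
                "n": len(active),
            }
        )
        if g > g_crit:
            flagged.append(active.pop(pos))
        else:
            break
    return GrubbsResult(flagged, steps)
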