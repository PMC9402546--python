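"""Dot-array stimulus geometry: random, mirror-symmetric and doubly symmetric fields.

Stimuli are clouds of dots inside a virtual circular field, specified in
degrees of visual angle with the origin at the field centre (x right, y up).
Symmetric arrays are built by sampling one half (or one quadrant) of the field
and reflecting it, so the mirror invariance is exact by construction rather
than approximate.

The separation constraint is centre-to-centre and configurable.  The default
of 0.6 deg gives a 0.3 deg edge gap for 0.3 deg dots; dense arrays (e.g. 400
dots in a 10 deg field) require lowering it, and an explicit packing
feasibility check fails fast instead of looping forever.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_FIELD_DIAMETER = 10.0
DEFAULT_DOT_DIAMETER = 0.3
DEFAULT_MIN_SEPARATION = 0.6

_ATTEMPTS_PER_DOT = 10_000
_RESTARTS = 10


class PackingInfeasibleError(RuntimeError):
    """Requested dot count cannot satisfy the separation constraint."""


@dataclass(frozen=True)
class DotArray:
    """One stimulus: dot centres (deg), geometry metadata and symmetry class."""

    centers: np.ndarray  # shape (n, 2), columns x, y in deg
    dot_diameter: float
    field_diameter: float
    symmetry: str  # "random" | "vertical" | "double"
    seed: int
    min_separation: float = DEFAULT_MIN_SEPARATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))

    @property
    def n(self) -> int:
        return len(self.centers)

    def to_csv(self, path: str | Path) -> None:
        """Write centres as ``x_deg,y_deg`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        header = "x_deg,y_deg"
        np.savetxt(path, self.centers, delimiter=",", header=header, comments="")
        meta = {
            "dot_diameter": self.dot_diameter,
            "field_diameter": self.field_diameter,
            "symmetry": self.symmetry,
            "seed": self.seed,
            "min_separation": self.min_separation,
            "n": self.n,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def max_packable(area: float, min_separation: float) -> int:
    """Hexagonal-packing upper bound on the number of centres in ``area``."""
    return math.floor(area / (math.sqrt(3.0) / 2.0 * min_separation**2))


def _check_feasible(n: int, area: float, min_separation: float) -> None:
    bound = max_packable(area, min_separation)
    if n > bound:
        raise PackingInfeasibleError(
            f"cannot place {n} centres with min separation {min_separation} deg "
            f"in {area:.2f} deg^2 (hexagonal packing bound {bound})"
        )


def _sample_points(
    rng: np.random.Generator,
    n: int,
    radius: float,
    min_separation: float,
    *,
    x_min: float | None = None,
    y_min: float | None = None,
) -> np.ndarray:
    """Rejection-sample ``n`` centres in the (possibly half/quarter) disc."""
    for _ in range(_RESTARTS):
        pts: list[np.ndarray] = []
        ok = True
        for _ in range(n):
            placed = False
            for _ in range(_ATTEMPTS_PER_DOT):
                p = rng.uniform(-radius, radius, size=2)
                if p[0] ** 2 + p[1] ** 2 > radius**2:
                    continue
                if x_min is not None and p[0] < x_min:
                    continue
                if y_min is not None and p[1] < y_min:
                    continue
                if pts and np.min(np.hypot(*(np.array(pts) - p).T)) < min_separation:
                    continue
                pts.append(p)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise PackingInfeasibleError(
        f"rejection sampling failed to place {n} centres after {_RESTARTS} restarts"
    )


def generate_random_array(
    n: int,
    field_diameter: float = DEFAULT_FIELD_DIAMETER,
    dot_diameter: float = DEFAULT_DOT_DIAMETER,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    seed: int = 0,
) -> DotArray:
    """Uniform random dot array inside the circular field.

    Deterministic in ``seed``; raises :class:`PackingInfeasibleError` when the
    requested density exceeds the hexagonal packing bound or rejection
    sampling exhausts its retry budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    radius = field_diameter / 2.0
    _check_feasible(n, math.pi * radius**2, min_separation)
    rng = np.random.default_rng(seed)
    centers = _sample_points(rng, n, radius, min_separation)
    return DotArray(centers, dot_diameter, field_diameter, "random", seed, min_separation)


def generate_symmetric_array(
    n: int,
    axes: str = "vertical",
    field_diameter: float = DEFAULT_FIELD_DIAMETER,
    dot_diameter: float = DEFAULT_DOT_DIAMETER,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    seed: int = 0,
) -> DotArray:
    """Mirror-symmetric dot array.

    ``axes="vertical"`` reflects a half-field about the vertical axis
    (x -> -x); ``axes="vertical+horizontal"`` (alias ``"double"``) reflects a
    quadrant about both axes.  Mirrored coordinates are copied, not
    re-sampled, so the invariance is exact.  Sampled points are kept at least
    ``min_separation/2`` from each reflection axis so that no dot ever
    violates separation with its own mirror image.
    """
    if axes in ("double", "vertical+horizontal"):
        divisor, symmetry = 4, "double"
    elif axes == "vertical":
        divisor, symmetry = 2, "vertical"
    else:
        raise ValueError(f"unknown axes {axes!r}")
    if n % divisor:
        raise ValueError(f"{symmetry} symmetry requires n divisible by {divisor}, got {n}")

    radius = field_diameter / 2.0
    margin = min_separation / 2.0
    rng = np.random.default_rng(seed)
    if symmetry == "vertical":
        _check_feasible(n // 2, math.pi * radius**2 / 2.0, min_separation)
        half = _sample_points(rng, n // 2, radius, min_separation, x_min=margin)
        centers = np.vstack([half, half * [-1.0, 1.0]])
    else:
        _check_feasible(n // 4, math.pi * radius**2 / 4.0, min_separation)
        quad = _sample_points(rng, n // 4, radius, min_separation, x_min=margin, y_min=margin)
        centers = np.vstack(
            [quad, quad * [-1.0, 1.0], quad * [1.0, -1.0], quad * [-1.0, -1.0]]
        )
    return DotArray(centers, dot_diameter, field_diameter, symmetry, seed, min_separation)


def _is_invariant(centers: np.ndarray, reflected: np.ndarray, tolerance: float) -> bool:
    """True when ``reflected`` is a permutation of ``centers`` within tolerance."""
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    d = cdist(centers, reflected)
    rows, cols = linear_sum_assignment(d)
    return bool(np.all(d[rows, cols] <= tolerance))


def check_symmetry(array: DotArray, tolerance: float = 1e-6) -> str:
    """Maximal symmetry class of the centre multiset.

    Returns ``"double"`` if the multiset is invariant under both x -> -x and
    y -> -y, ``"vertical"`` if only under x -> -x, else ``"random"``.
    """
    c = array.centers
    if len(c) == 0:
        raise ValueError("empty array")
    vert = _is_invariant(c, c * [-1.0, 1.0], tolerance)
    if vert and _is_invariant(c, c * [1.0, -1.0], tolerance):
        return "double"
    return "vertical" if vert else "random"


def render_png(array: DotArray, path: str | Path, px_per_deg: float = 40.0) -> None:
    """Optional raster render (1 deg -> px_per_deg pixels, half-up rounding)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    half = array.field_diameter / 2.0
    size_px = math.floor(array.field_diameter * px_per_deg + 0.5)
    fig, ax = plt.subplots(figsize=(size_px / 100, size_px / 100), dpi=100)
    ax.add_patch(plt.Circle((0, 0), half, fill=False, color="0.8"))
    r = array.dot_diameter / 2.0
    for x, y in array.centers:
        ax.add_patch(plt.Circle((x, y), r, color="black"))
    ax.set_xlim(-half, half)
    ax.set_ylim(-half, half)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path)
    plt.close(fig)
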