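"""Center-weighted phosphene fields.

A phosphene field is the set of percept locations and sizes a prosthesis
simulation can activate.  Phosphenes are laid out in gaze-centered visual
field coordinates (degrees of visual angle, origin at the point of regard)
and are smaller and denser near the center, mirroring the cortical
magnification of the early visual pathway: local density follows
``M(e) = 1 / (e + e2)`` where ``e`` is eccentricity in degrees and ``e2``
is the half-saturation eccentricity, and each phosphene's Gaussian radius
``sigma`` is a fixed fraction of the local mean nearest-neighbor spacing.

Coordinate conventions (used throughout the package):

* Field coordinates: degrees of visual angle, centered on the point of
  regard; x positive rightward, y positive downward (matching image axes).
* Screen coordinates: pixels, origin at the top-left corner, x rightward,
  y downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Phosphene",
    "PhospheneField",
    "ScreenGeometry",
    "generate_field",
    "phosphenes_on_screen",
    "write_map",
    "read_map",
]

#: degrees of visual angle per pixel such that a 1600-px-wide monitor
#: subtends ~40 degrees at the nominal viewing distance.
DEFAULT_DEG_PER_PX = 40.0 / 1600.0


@dataclass(frozen=True)
class Phosphene:
    """One simulated percept: center (deg, gaze-relative) and Gaussian radius."""

    x: float
    y: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))


@dataclass(frozen=True)
class ScreenGeometry:
    """Monitor geometry and the pixel<->degree conversion.

    ``deg_per_px`` is an explicit configuration value (it encodes viewing
    distance); it is never inferred from image content.  The same scale
    applies to both axes, so aspect ratio is preserved between pixel and
    degree space.
    """

    width_px: int = 1600
    height_px: int = 900
    deg_per_px: float = DEFAULT_DEG_PER_PX

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.deg_per_px <= 0:
            raise ValueError("screen dimensions and deg_per_px must be positive")

    @property
    def width_deg(self) -> float:
        return self.width_px * self.deg_per_px

    @property
    def height_deg(self) -> float:
        return self.height_px * self.deg_per_px

    def deg_to_px(self, x_deg, y_deg, gaze_px):
        """Map field coordinates (deg, gaze-centered) to screen pixels."""
        gx, gy = gaze_px
        return (
            np.asarray(x_deg) / self.deg_per_px + gx,
            np.asarray(y_deg) / self.deg_per_px + gy,
        )


@dataclass
class PhospheneField:
    """An ordered collection of phosphenes spanning the visual field."""

    phosphenes: list[Phosphene]
    field_span: float
    density_params: dict = dc_field(default_factory=dict)
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.phosphenes)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (x, y, sigma) as float arrays, in field order."""
        if not self.phosphenes:
            z = np.empty(0)
            return z, z.copy(), z.copy()
        a = np.array([(p.x, p.y, p.sigma) for p in self.phosphenes])
        return a[:, 0], a[:, 1], a[:, 2]


def _magnification(ecc: np.ndarray, e2: float) -> np.ndarray:
    return 1.0 / (ecc + e2)


def generate_field(
    n: int = 1000,
    field_span: float = 80.0,
    *,
    e2: float = 2.0,
    sigma_fraction: float = 0.5,
    n_neighbors: int = 3,
    seed: int = 0,
) -> PhospheneField:
    """Generate a center-weighted phosphene field.

    Phosphene centers are drawn by rejection sampling inside a disc of
    radius ``field_span / 2`` with acceptance probability proportional to
    the magnification profile ``1 / (e + e2)``, so density falls off with
    eccentricity.  One phosphene is always anchored at the point of regard.
    Each phosphene's ``sigma`` is ``sigma_fraction`` times its mean distance
    to its ``n_neighbors`` nearest neighbors, which makes phosphenes grow
    with local spacing (hence with eccentricity, up to sampling jitter).

    Parameters
    ----------
    n : total number of phosphenes (>= 1).
    field_span : full extent of the field, degrees.
    e2 : half-saturation eccentricity of the density profile, degrees.
        Smaller values concentrate phosphenes more tightly at the center.
    sigma_fraction : ratio of Gaussian radius to local mean spacing.
    n_neighbors : neighbors used for the local-spacing estimate.
    seed : RNG seed; the same seed always yields the same field.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if field_span <= 0:
        raise ValueError(f"field_span must be positive, got {field_span}")

    rng = np.random.default_rng(seed)
    radius = field_span / 2.0

    xs = [0.0]
    ys = [0.0]
    # Rejection sampling: uniform in the disc, accept with prob e2/(e+e2),
    # which realizes density proportional to 1/(e+e2).
    while len(xs) < n:
        m = max(4 * (n - len(xs)), 64)
        x = rng.uniform(-radius, radius, m)
        y = rng.uniform(-radius, radius, m)
        ecc = np.hypot(x, y)
        keep = (ecc <= radius) & (rng.uniform(size=m) < e2 / (ecc + e2))
        xs.extend(x[keep])
        ys.extend(y[keep])
    x = np.array(xs[:n])
    y = np.array(ys[:n])

    if n == 1:
        sigma = np.array([sigma_fraction * field_span / 2.0])
    else:
        k = min(n_neighbors, n - 1)
        tree = cKDTree(np.column_stack([x, y]))
        dist, _ = tree.query(np.column_stack([x, y]), k=k + 1)
        sigma = sigma_fraction * dist[:, 1:].mean(axis=1)
        sigma = np.maximum(sigma, 1e-6)

    params = {
        "e2": e2,
        "sigma_fraction": sigma_fraction,
        "n_neighbors": n_neighbors,
    }
    phosphenes = [Phosphene(float(xi), float(yi), float(si)) for xi, yi, si in zip(x, y, sigma)]
    return PhospheneField(phosphenes, field_span, params, seed)


def phosphenes_on_screen(
    field: PhospheneField,
    gaze_px: tuple[float, float],
    screen: ScreenGeometry,
) -> int:
    """Count phosphenes whose center lands on the monitor.

    The field is translated so its origin sits at ``gaze_px``; a phosphene
    counts when its center falls inside ``[0, width) x [0, height)``.
    Off-screen gaze is allowed and simply yields a small (possibly zero)
    count.
    """
    x, y, _ = field.as_arrays()
    px, py = screen.deg_to_px(x, y, gaze_px)
    inside = (px >= 0) & (px < screen.width_px) & (py >= 0) & (py < screen.height_px)
    return int(inside.sum())


_CSV_HEADER = "x_deg,y_deg,sigma_deg"


def write_map(field: PhospheneField, path: str | Path) -> None:
    """Write a phosphene map file.

    ``.csv`` writes the bare table (header ``x_deg,y_deg,sigma_deg``);
    ``.json`` adds a metadata block (n, field_span, density_params, seed).
    Coordinates are written with ``repr`` precision so that a read-back
    field is bitwise identical.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "n": field.n,
            "field_span": field.field_span,
            "density_params": field.density_params,
            "seed": field.seed,
            "phosphenes": [[p.x, p.y, p.sigma] for p in field.phosphenes],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = [_CSV_HEADER]
    for p in field.phosphenes:
        lines.append(f"{p.x!r},{p.y!r},{p.sigma!r}")
    path.write_text("\n".join(lines) + "\n")


def read_map(path: str | Path) -> PhospheneField:
    """Read a phosphene map written by :func:`write_map`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        phosphenes = [Phosphene(*row) for row in payload["phosphenes"]]
        return PhospheneField(
            phosphenes,
            payload["field_span"],
            payload.get("density_params", {}),
            payload.get("seed"),
        )
    lines = path.read_text().strip().splitlines()
    if not lines or lines[0].replace(" ", "") != _CSV_HEADER:
        raise ValueError(f"{path}: not a phosphene map file (missing header)")
    phosphenes = []
    for line in lines[1:]:
        xs, ys, ss = line.split(",")
        phosphenes.append(Phosphene(float(xs), float(ys), float(ss)))
    x, y, _ = PhospheneField(phosphenes, 0.0).as_arrays()
    span = 2.0 * float(np.hypot(x, y).max()) if phosphenes else 0.0
    return PhospheneField(phosphenes, span)


def annulus_counts(
    field: PhospheneField, n_annuli: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Phosphene counts in concentric equal-area annuli.

    Returns (outer edges, counts).  For a center-weighted field the counts
    are non-increasing outward; useful as a density diagnostic.
    """
    x, y, _ = field.as_arrays()
    ecc = np.hypot(x, y)
    r_max = field.field_span / 2.0
    edges = r_max * np.sqrt(np.arange(n_annuli + 1) / n_annuli)
    counts, _ = np.histogram(ecc, bins=edges)
    return edges[1:], counts
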