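"""Barnes-maze geometry.

The arena is a 1 m elevated disc with 20 equally spaced escape holes cut
into its perimeter; one hole (the goal) leads to an escape box. All
behavioural quantities (hole visits, search-strategy rules, radial zones,
heading angles) are defined relative to this geometry, so it is carried as
an explicit value object rather than implied by the tracking data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

N_HOLES = 20


@dataclass
class MazeGeometry:
    """Circular 20-hole maze in image (pixel) coordinates.

    Parameters
    ----------
    center : (x, y) of the maze centre, px.
    radius : maze radius, px.
    hole_centers : (20, 2) array of hole-centre coordinates, px.
    hole_radius : radius of each escape hole, px.
    goal_index : index (0-19) of the goal hole.
    px_per_cm : spatial scale.
    mouse_length : nose-to-tail-base body length in px; sets the central
        circle (one body length in diameter) and the serial-exploration
        band (one body length from the maze edge).
    """

    center: tuple[float, float]
    radius: float
    hole_centers: np.ndarray
    hole_radius: float
    goal_index: int
    px_per_cm: float
    mouse_length: float = 60.0

    def __post_init__(self) -> None:
        self.hole_centers = np.asarray(self.hole_centers, dtype=float)
        if self.hole_centers.shape != (N_HOLES, 2):
            raise ValueError(
                f"expected {N_HOLES} hole centers, got {self.hole_centers.shape}"
            )
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if not 0 <= self.goal_index < N_HOLES:
            raise ValueError("goal_index must be in 0..19")
        if self.radius <= 0 or self.hole_radius <= 0:
            raise ValueError("radii must be positive")
        r = np.hypot(*(self.hole_centers - np.asarray(self.center)).T)
        if np.any(r < 0.8 * self.radius - 1e-9) or np.any(r > self.radius + 1e-9):
            raise ValueError("hole centers must lie within 0.8-1.0 of the maze radius")

    # -- derived quantities -------------------------------------------------

    @property
    def goal_center(self) -> np.ndarray:
        return self.hole_centers[self.goal_index]

    def hole_angles(self) -> np.ndarray:
        """Angle of each hole centre about the maze centre, radians."""
        d = self.hole_centers - np.asarray(self.center)
        return np.arctan2(d[:, 1], d[:, 0])

    def sector_of(self, xy: np.ndarray) -> np.ndarray:
        """Quadrant index (0-3) of points, with the goal on sector 0's midline.

        The four 90-degree sectors are anchored so the centre-to-goal ray
        bisects sector 0; this makes the strategy rules invariant to how
        the maze happened to be rotated in the video frame.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = xy - np.asarray(self.center)
        theta = np.arctan2(d[:, 1], d[:, 0])
        g = self.goal_center - np.asarray(self.center)
        goal_theta = np.arctan2(g[1], g[0])
        rel = np.mod(theta - goal_theta + np.pi / 4, 2 * np.pi)
        return (rel // (np.pi / 2)).astype(int)

    # -- construction / serialisation --------------------------------------

    @classmethod
    def standard(
        cls,
        diameter_px: float = 600.0,
        px_per_cm: float = 6.0,
        goal_index: int = 0,
        center: tuple[float, float] | None = None,
        hole_ring_fraction: float = 0.9,
        hole_radius: float | None = None,
        mouse_length: float = 60.0,
    ) -> "MazeGeometry":
        """A 1 m, 20-hole maze at the given pixel scale.

        Defaults give a 600 px (100 cm) maze with 10-cm holes on a ring at
        90% of the radius, the scale at which a 60 px mouse is 10 cm long.
        """
        radius = diameter_px / 2.0
        if center is None:
            center = (radius, radius)
        if hole_radius is None:
            hole_radius = 5.0 * px_per_cm  # 10 cm diameter holes
        ang = 2 * np.pi * np.arange(N_HOLES) / N_HOLES
        ring = hole_ring_fraction * radius
        holes = np.stack(
            [center[0] + ring * np.cos(ang), center[1] + ring * np.sin(ang)], axis=1
        )
        return cls(
            center=tuple(center),
            radius=radius,
            hole_centers=holes,
            hole_radius=hole_radius,
            goal_index=goal_index,
            px_per_cm=px_per_cm,
            mouse_length=mouse_length,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hole_centers"] = self.hole_centers.tolist()
        d["center"] = list(self.center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MazeGeometry":
        return cls(
            center=tuple(d["center"]),
            radius=float(d["radius"]),
            hole_centers=np.asarray(d["hole_centers"], dtype=float),
            hole_radius=float(d["hole_radius"]),
            goal_index=int(d["goal_index"]),
            px_per_cm=float(d["px_per_cm"]),
            mouse_length=float(d.get("mouse_length", 60.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MazeGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))
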