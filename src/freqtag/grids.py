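"""Source grids and synthetic leadfields.

A leadfield (gain matrix) is the linear map from dipole moments at grid
points — three Cartesian orientations per point — to the sensor array.
Real leadfields come from a boundary-element forward model; here we
generate synthetic ones with known structure so the inverse solver and
the statistics downstream can be validated against ground truth:

``random-incoherent``
    Each source's m x 3 gain block is i.i.d. Gaussian, normalized to unit
    Frobenius norm.  Incoherent columns are the favourable regime for
    L1 support recovery, which makes this mode the right fixture for
    solver correctness tests.

``spherical-shell``
    Sensors sit on a shell around the source volume and gains fall off
    with squared sensor-source distance, giving the depth bias that the
    depth-weighting vector is meant to counteract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError

__all__ = ["SourceGrid", "Leadfield", "make_leadfield", "cubic_grid"]


@dataclass(frozen=True)
class SourceGrid:
    """Regular grid of candidate source locations.

    Parameters
    ----------
    positions : (n, 3) array
        Grid-point coordinates in mm.
    spacing : float
        Nominal grid spacing in mm (5 mm cubic grid by default
        throughout the package).
    """

    positions: np.ndarray
    spacing: float = 5.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise InvalidGeometryError("positions must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(pos)):
            raise InvalidGeometryError("grid coordinates must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def adjacency(self, connectivity: float = np.sqrt(3)) -> list[np.ndarray]:
        """Neighbour lists under the 26-neighbourhood (or a custom radius).

        Two grid points are adjacent when their distance is at most
        ``connectivity * spacing`` (plus a 1% tolerance), which on a cubic
        grid with the default radius sqrt(3) is exactly the
        26-neighbourhood used for cluster formation.
        """
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        radius = connectivity * self.spacing * 1.01
        neighbours = []
        for i in range(self.n_sources):
            nb = np.flatnonzero((d[i] <= radius) & (d[i] > 0))
            neighbours.append(nb)
        return neighbours


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix plus geometry.

    ``gain`` is m x (n*3): three orientation columns per grid point, in
    sensor units per unit dipole moment.  ``sensor_positions`` carries the
    sensor coordinates (mm); hemisphere labels are derived from the sign
    of the x coordinate (negative = left, positive = right, zero =
    midline).
    """

    gain: np.ndarray
    grid: SourceGrid
    sensor_positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        n = self.grid.n_sources
        if g.ndim != 2 or g.shape[1] != 3 * n:
            raise InvalidGeometryError(
                f"gain must be (m, {3 * n}) for a {n}-source grid, got {g.shape}"
            )
        if g.shape[0] < 2:
            raise InvalidGeometryError("need at least 2 sensors")
        if np.any(np.all(g == 0, axis=1)):
            raise InvalidGeometryError("gain contains an all-zero sensor row")
        if not np.all(np.isfinite(g)):
            raise InvalidGeometryError("gain must be finite")
        object.__setattr__(self, "gain", g)
        sp = self.sensor_positions
        if sp is None:
            sp = np.zeros((g.shape[0], 3))
        sp = np.asarray(sp, dtype=float)
        if sp.shape != (g.shape[0], 3):
            raise InvalidGeometryError("sensor_positions must be (m, 3)")
        object.__setattr__(self, "sensor_positions", sp)

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.grid.n_sources

    def block(self, i: int) -> np.ndarray:
        """The m x 3 gain block of source ``i``."""
        return self.gain[:, 3 * i : 3 * i + 3]

    @property
    def hemispheres(self) -> np.ndarray:
        """Per-sensor hemisphere labels: 'left' | 'right' | 'midline'."""
        x = self.sensor_positions[:, 0]
        out = np.where(x < 0, "left", np.where(x > 0, "right", "midline"))
        return out.astype(object)


def cubic_grid(n_sources: int, spacing: float = 5.0) -> SourceGrid:
    """The first ``n_sources`` points of a centred cubic lattice."""
    side = int(np.ceil(n_sources ** (1 / 3) - 1e-9))
    axis = (np.arange(side) - (side - 1) / 2) * spacing
    zz, yy, xx = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return SourceGrid(pts[:n_sources], spacing=spacing)


def _sensor_shell(m_sensors: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform points on the upper half of a sphere (Fibonacci)."""
    k = np.arange(m_sensors)
    # upper hemisphere: z in (0, 1]
    z = 1.0 - k / (2 * m_sensors)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z]) * radius
    return pts


def make_leadfield(
    n_sources: int,
    m_sensors: int,
    seed: int = 0,
    mode: str = "random-incoherent",
    spacing: float = 5.0,
    shell_radius: float = 60.0,
) -> Leadfield:
    """Generate a synthetic leadfield with a cubic source grid.

    Parameters
    ----------
    n_sources, m_sensors : int
        Grid-point and sensor counts (m_sensors >= 2).
    seed : int
        Deterministic: identical arguments give bit-identical output.
    mode : {'random-incoherent', 'spherical-shell'}
        See module docstring.
    spacing : float
        Grid spacing in mm (default 5 mm).
    shell_radius : float
        Sensor shell radius in mm for the spherical-shell mode.
    """
    if m_sensors < 2:
        raise InvalidGeometryError("need at least 2 sensors")
    if n_sources < 1:
        raise InvalidGeometryError("need at least 1 source")
    if mode not in ("random-incoherent", "spherical-shell"):
        raise ValueError(f"unknown leadfield mode: {mode!r}")

    rng = np.random.default_rng(seed)
    grid = cubic_grid(n_sources, spacing=spacing)
    sensors = _sensor_shell(m_sensors, shell_radius, rng)

    if mode == "random-incoherent":
        gain = rng.standard_normal((m_sensors, 3 * n_sources))
        for i in range(n_sources):
            blk = gain[:, 3 * i : 3 * i + 3]
            gain[:, 3 * i : 3 * i + 3] = blk / np.linalg.norm(blk)
    else:
        gain = np.empty((m_sensors, 3 * n_sources))
        # random per-sensor orientation sensitivity, amplitude ~ 1/d^2
        for i in range(n_sources):
            d = np.linalg.norm(sensors - grid.positions[i], axis=1)
            pattern = rng.standard_normal((m_sensors, 3))
            pattern /= np.linalg.norm(pattern, axis=1, keepdims=True)
            gain[:, 3 * i : 3 * i + 3] = pattern * (spacing**2 / d**2)[:, None]

    return Leadfield(gain=gain, grid=grid, sensor_positions=sensors)
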