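"""Point clouds of atomic coordinates.

A :class:`PointCloud` is an *ordered* set of 3-D positions in Angstrom.
Order matters: index ``i`` identifies atom ``p_i`` throughout the package,
and every downstream edge label refers back to these indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PointCloud:
    """An ordered 3-D point cloud (coordinates in Angstrom).

    Parameters
    ----------
    coords : (n, 3) float array
        Finite coordinates; index ``i`` identifies atom ``p_i``.
    labels : tuple of str, optional
        Residue/atom names aligned with ``coords``.
    """

    coords: np.ndarray
    labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None and len(self.labels) != coords.shape[0]:
            raise ValueError("labels length must match number of points")
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "PointCloud":
        """Return a rigidly moved copy (rotation applied first)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return PointCloud(coords, self.labels)
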