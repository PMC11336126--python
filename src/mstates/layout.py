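"""Sensor layouts: electrode names and unit-sphere positions.

A layout is the minimal geometric description the pipeline needs: channel
names and 3-D positions on the unit sphere (head modelled as a sphere, +x
right, +y anterior, +z up).  Real montages can be attached when reading EDF
or FIF files; the synthetic generator uses :func:`make_layout`, which places
electrodes on a spiral covering the upper "cap" region of the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

# Lowest z covered by the synthetic cap; real caps reach just below the
# equator (temporal/occipital rim electrodes).
_CAP_Z_MIN = -0.15


@dataclass(frozen=True)
class SensorLayout:
    """Named electrodes with unit-norm 3-D positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), rows unit norm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise InvalidArgumentError("positions must be (n_channels, 3)")
        if len(self.channel_names) != pos.shape[0]:
            raise InvalidArgumentError("channel_names/positions length mismatch")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidArgumentError("channel names must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidArgumentError("positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def nearest_neighbors(self, k: int = 4) -> np.ndarray:
        """Indices of the ``k`` nearest channels (by chord distance) per channel.

        Returns an (n_channels, k) integer array; a channel is never its own
        neighbor.
        """
        d = np.linalg.norm(self.positions[:, None, :] - self.positions[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return np.argsort(d, axis=1)[:, :k]

    def neighbor_distances(self, neighbors: np.ndarray) -> np.ndarray:
        """Chord distances matching an index array from :meth:`nearest_neighbors`."""
        diffs = self.positions[:, None, :] - self.positions[neighbors]
        return np.linalg.norm(diffs, axis=-1)


def make_layout(n_channels: int) -> SensorLayout:
    """Deterministic, roughly uniform electrode cap on the upper hemisphere.

    Electrodes follow a golden-angle (Fibonacci) spiral from the vertex
    (z = 1) down to z = -0.15, mimicking the coverage of a standard EEG cap
    without tying the synthetic pipeline to any specific montage's labels.

    Parameters
    ----------
    n_channels
        Number of electrodes, between 4 and 256.
    """
    if not 4 <= n_channels <= 256:
        raise InvalidArgumentError(f"n_channels must be in [4, 256], got {n_channels}")
    i = np.arange(n_channels, dtype=float)
    z = 1.0 - (1.0 - _CAP_Z_MIN) * i / (n_channels - 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    width = len(str(n_channels))
    names = tuple(f"E{j + 1:0{width}d}" for j in range(n_channels))
    return SensorLayout(channel_names=names, positions=pos)
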