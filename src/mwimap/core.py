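"""Shared container types."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuantMap"]


@dataclass
class QuantMap:
    """A 3-D scalar parameter map on a voxel grid.

    Voxels outside the analysis mask are NaN; ``mask`` is the finite-value
    support. ``name`` identifies the quantity (``"mwf"``, ``"f_m"``,
    ``"t1"``, ``"kappa"``, ``"z"``, ...).
    """

    data: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def values(self) -> np.ndarray:
        """Finite voxel values, flattened."""
        return self.data[self.mask]
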