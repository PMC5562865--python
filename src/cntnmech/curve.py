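"""The force-extension record shared by the simulator, file I/O and pipeline."""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

__all__ = ["ForceCurve"]


@dataclasses.dataclass
class ForceCurve:
    """One retraction trace.

    Attributes
    ----------
    separation : tip-sample separation in nm, strictly increasing.
    force : force in pN, same length as ``separation``.
    meta : acquisition metadata (pulling speed ``v_um_per_s``, cantilever
        spring constant ``k_c_N_per_m``, ``seed``, ``source_id``, ...).
    """

    separation: np.ndarray
    force: np.ndarray
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.separation.shape != self.force.shape or self.separation.ndim != 1:
            raise ValueError("separation and force must be 1-D arrays of equal length")
        if self.separation.size < 50:
            raise ValueError(
                f"force curve must hold >= 50 samples, got {self.separation.size}"
            )
        if np.any(np.diff(self.separation) <= 0):
            raise ValueError("separations must be strictly increasing")

    def __len__(self) -> int:
        return int(self.separation.size)

    @property
    def source_id(self) -> str:
        return str(self.meta.get("source_id", ""))
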