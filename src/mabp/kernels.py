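"""Mollifier kernels used to smooth bias deposition on the CV grid.

Every visit to a point in collective-variable space deposits a small,
compactly supported bump of sampling mass instead of a single-bin count.
This is what makes the accumulated density — and hence the bias potential
derived from it — smooth enough to differentiate for dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MollifierKernel:
    """Compact symmetric deposition kernel on a bin-offset lattice.

    The profile covers integer bin offsets ``-half_width .. +half_width``
    and is normalized to unit total mass, so one (unweighted, ungated)
    deposit adds exactly one unit of sampling mass to the grid.

    Parameters
    ----------
    half_width:
        Kernel half-width in bins (the biasing parameter alpha).
    profile:
        Non-negative weights per offset, shape ``(2*half_width + 1,)``.
    """

    half_width: int
    profile: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("kernel half_width must be a positive integer")
        prof = np.asarray(self.profile, dtype=float)
        if prof.shape != (2 * self.half_width + 1,):
            raise ValueError(
                f"profile must have length {2 * self.half_width + 1}, "
                f"got shape {prof.shape}"
            )
        if np.any(prof < 0):
            raise ValueError("kernel profile must be non-negative")
        if not np.allclose(prof, prof[::-1]):
            raise ValueError("kernel profile must be symmetric about 0")
        total = prof.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("kernel profile must have positive finite mass")
        object.__setattr__(self, "profile", prof / total)

    @property
    def offsets(self) -> np.ndarray:
        """Integer bin offsets covered by the kernel."""
        return np.arange(-self.half_width, self.half_width + 1)

    @classmethod
    def quartic(cls, half_width: int) -> "MollifierKernel":
        """Quartic bump w(r) ∝ (1 − (r/α)²)² on |r| ≤ α bins.

        Smooth, compact and cheap; the profile vanishes at the support
        edge so the deposited density is C¹ across it.
        """
        r = np.arange(-half_width, half_width + 1, dtype=float)
        w = (1.0 - (r / half_width) ** 2) ** 2
        return cls(half_width=half_width, profile=w)

    def outer_2d(self) -> np.ndarray:
        """Separable 2D product kernel, normalized to unit mass."""
        return np.outer(self.profile, self.profile)
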