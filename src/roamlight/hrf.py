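"""Canonical double-gamma haemodynamic response function.

The BOLD impulse response is modeled as a difference of two gamma densities:
a positive lobe peaking near 5 s and an undershoot near 16 s,

    h(t) = g(t; a1, b1) - c * g(t; a2, b2),

with g the gamma probability density (shape a, rate b). The default
parameterization (a1=6, a2=16, b1=b2=1/s, c=1/6, 32-s support) is the
de-facto canonical one used throughout block-design fMRI analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HrfParams:
    peak_shape: float = 6.0
    undershoot_shape: float = 16.0
    peak_rate: float = 1.0  # 1/s
    undershoot_rate: float = 1.0  # 1/s
    undershoot_ratio: float = 1.0 / 6.0
    dt_s: float = 0.1
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_shape", "undershoot_shape", "peak_rate",
                     "undershoot_rate", "undershoot_ratio", "dt_s",
                     "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def canonical_hrf(params: HrfParams | None = None) -> np.ndarray:
    """Sample the canonical HRF at ``k * dt_s`` for k = 0 .. duration/dt.

    Returns the kernel values; ``h(0) = 0`` because both gamma shapes
    exceed 1, and the kernel has decayed to ~0 by the 32-s truncation.
    """
    p = params or HrfParams()
    t = np.arange(0.0, p.duration_s + p.dt_s / 2, p.dt_s)
    peak = stats.gamma.pdf(t, a=p.peak_shape, scale=1.0 / p.peak_rate)
    under = stats.gamma.pdf(t, a=p.undershoot_shape, scale=1.0 / p.undershoot_rate)
    return peak - p.undershoot_ratio * under
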