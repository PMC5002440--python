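"""Closed-form sensitivity-volume estimates.

How many neurons should a single polytrode electrode "hear"? If an
electrode is primarily sensitive to somata within a radius r of its
surface, the relevant tissue is the half-sphere in front of the shank
(the other half is occupied by the probe itself), so the expected count is

    N = density * (2/3) * pi * r^3

with density in neurons/mm^3 and r converted from um to mm. For cortical
densities of 40,000-60,000 neurons/mm^3 and a 50 um sensitivity radius this
lands at roughly 10-15 neurons per site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DensityEstimate", "expected_neurons_per_site"]


@dataclass(frozen=True)
class DensityEstimate:
    density_per_mm3: float
    radius_um: float
    expected_count: float

    def __post_init__(self) -> None:
        if self.density_per_mm3 <= 0 or self.radius_um < 0:
            raise ValueError("density must be positive and radius non-negative")

    @property
    def rounded_count(self) -> int:
        return int(round(self.expected_count))


def expected_neurons_per_site(
    density_per_mm3: float, radius_um: float
) -> DensityEstimate:
    """Expected neuron count in the half-sphere of radius ``radius_um`` in
    front of one electrode site.

    The unrounded expectation is always reported alongside the nearest
    integer (``DensityEstimate.rounded_count``).
    """
    if density_per_mm3 <= 0:
        raise ValueError("density_per_mm3 must be positive")
    if radius_um < 0:
        raise ValueError("radius_um must be non-negative")
    r_mm = radius_um / 1000.0
    expected = density_per_mm3 * (2.0 / 3.0) * np.pi * r_mm**3
    return DensityEstimate(density_per_mm3, radius_um, float(expected))
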