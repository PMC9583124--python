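"""Ready-made configuration bundles.

``full_scale`` reproduces the reference setup: a 451 px plate, kernel scales
d2 = 10 / d1 = 4 px, spot spacing 15 and radius 5.  ``reduced`` is the
desk-scale twin used throughout the test-suite and worked examples: a 128 px
plate with every length scaled against the kernel in the same proportions
(d2 = 4, spacing = 1.5*d2, spot radius = 0.5*d2), which keeps the branching
regime and the spot-to-kernel geometry while making one simulation run in
~0.1 s instead of minutes.
"""

from __future__ import annotations

from dataclasses import replace

from .codebook import SeedingLayout, SeedingNoise
from .growth import DomainGeometry, GrowthParams

__all__ = ["full_scale", "reduced"]


def full_scale(n_bits: int = 4, snr: float | None = None, shape: str = "circle"):
    params = GrowthParams(d1=4.0, d2=10.0, snr=snr)
    layout = SeedingLayout(n_bits=n_bits, spacing=15.0, spot_radius=5.0, field_side=451)
    geometry = DomainGeometry(shape=shape, field_side=451)
    return params, layout, geometry, SeedingNoise()


def reduced(
    n_bits: int = 4,
    snr: float | None = None,
    shape: str = "circle",
    spacing: float = 6.0,
    eps: float = 2000.0,
    area_fraction: float = 1.0,
):
    """Desk-scale study conditions (128 px grid)."""
    params = GrowthParams(d1=1.6, d2=4.0, snr=snr, max_steps=120)
    layout = SeedingLayout(
        n_bits=n_bits,
        spacing=spacing,
        spot_radius=2.0,
        field_side=128,
        allow_overlap=spacing <= 4.0,
    )
    geometry = DomainGeometry(
        shape=shape, field_side=128, eps=eps, area_fraction=area_fraction
    )
    return params, layout, geometry, SeedingNoise()


def with_snr(params: GrowthParams, snr: float | None) -> GrowthParams:
    return replace(params, snr=snr)
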