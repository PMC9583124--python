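"""Character dictionaries and braille-like spot seeding.

A dictionary of ``n`` characters is mapped onto the non-zero ``n_bits``-bit
binary numbers ``1 .. 2**n_bits - 1`` (the all-zero word seeds no cells and is
never assigned).  Each bit of a character's binary index corresponds to one
circular inoculation spot in a small centered grid; a ``1`` bit seeds cells in
its spot, a ``0`` bit leaves it empty.  Seeded pixels receive intensities drawn
i.i.d. from a truncated Gaussian (uneven cell seeding), so that repeated
encodings of the same character start from similar but non-identical fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Codebook",
    "SeedingLayout",
    "SeedingNoise",
    "SeedingField",
    "build_codebook",
    "char_to_bits",
    "bits_to_char",
    "spot_centers",
    "bits_to_seeding",
    "grid_shape",
]


class CapacityError(ValueError):
    """Dictionary does not fit in the requested number of bits."""


@dataclass(frozen=True)
class Codebook:
    """Bijection between characters and non-zero ``n_bits``-bit words."""

    characters: tuple[str, ...]
    n_bits: int

    def __post_init__(self):
        if self.n_bits < 1:
            raise ValueError("n_bits must be >= 1")
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("duplicate characters in dictionary")
        if not 1 <= len(self.characters) <= 2**self.n_bits - 1:
            raise CapacityError(
                f"{len(self.characters)} characters exceed the "
                f"{2**self.n_bits - 1} non-zero {self.n_bits}-bit words"
            )

    @property
    def n_classes(self) -> int:
        return len(self.characters)

    @property
    def char_to_index(self) -> dict[str, int]:
        # indices start at 1: the all-zero word would seed no cells
        return {c: i + 1 for i, c in enumerate(self.characters)}

    def index_of(self, char: str) -> int:
        try:
            return self.char_to_index[char]
        except KeyError:
            raise KeyError(f"character {char!r} not in codebook") from None

    def label_of(self, char: str) -> int:
        """Zero-based class label (for classifiers)."""
        return self.index_of(char) - 1

    def to_json(self) -> str:
        return json.dumps({"characters": list(self.characters), "n_bits": self.n_bits})

    @classmethod
    def from_json(cls, s: str) -> "Codebook":
        d = json.loads(s)
        return cls(tuple(d["characters"]), int(d["n_bits"]))

    def digest(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def build_codebook(characters, n_bits: int) -> Codebook:
    """Assign characters, in list order, the binary indices ``1..len``."""
    return Codebook(tuple(characters), n_bits)


def char_to_bits(char: str, codebook: Codebook) -> str:
    """Zero-padded binary representation of the character's index."""
    return format(codebook.index_of(char), f"0{codebook.n_bits}b")


def bits_to_char(bits: str, codebook: Codebook) -> str:
    if len(bits) != codebook.n_bits or set(bits) - {"0", "1"}:
        raise ValueError(f"invalid bit string {bits!r} for {codebook.n_bits} bits")
    idx = int(bits, 2)
    if not 1 <= idx <= codebook.n_classes:
        raise KeyError(f"bit string {bits!r} is not assigned to any character")
    return codebook.characters[idx - 1]


def grid_shape(n_bits: int) -> tuple[int, int]:
    """Near-square row-major spot grid: 1->1x1, 2->1x2, 4->2x2, 5,6->2x3, 7->2x4."""
    rows = int(math.floor(math.sqrt(n_bits)))
    cols = int(math.ceil(n_bits / rows))
    return rows, cols


@dataclass(frozen=True)
class SeedingLayout:
    """Geometry of the spot array on the seeding field.

    ``spacing`` is the center-to-center distance between adjacent spots in
    pixels; ``spot_radius`` the radius of each circular spot.  The grid is
    centered on the field.
    """

    n_bits: int
    spacing: float = 15.0
    spot_radius: float = 5.0
    field_side: int = 451
    grid: tuple[int, int] | None = None
    allow_overlap: bool = False

    def __post_init__(self):
        g = self.grid or grid_shape(self.n_bits)
        object.__setattr__(self, "grid", g)
        if g[0] * g[1] < self.n_bits:
            raise ValueError(f"grid {g} too small for {self.n_bits} bits")
        if not self.allow_overlap and self.spacing <= 2 * self.spot_radius:
            raise ValueError(
                f"spacing {self.spacing} <= spot diameter {2 * self.spot_radius}: "
                "spots overlap (set allow_overlap=True to permit)"
            )
        for r, c in spot_centers(self):
            if not (
                self.spot_radius <= r <= self.field_side - 1 - self.spot_radius
                and self.spot_radius <= c <= self.field_side - 1 - self.spot_radius
            ):
                raise ValueError("spot array exceeds field bounds")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "SeedingLayout":
        d = json.loads(s)
        if d.get("grid") is not None:
            d["grid"] = tuple(d["grid"])
        return cls(**d)


def spot_centers(layout: SeedingLayout) -> list[tuple[float, float]]:
    """(row, col) centers; bit k (MSB first) maps to cell k in row-major order."""
    rows, cols = layout.grid
    c = (layout.field_side - 1) / 2.0
    centers = []
    for k in range(layout.n_bits):
        i, j = divmod(k, cols)
        centers.append(
            (
                c + (i - (rows - 1) / 2.0) * layout.spacing,
                c + (j - (cols - 1) / 2.0) * layout.spacing,
            )
        )
    return centers


@dataclass(frozen=True)
class SeedingNoise:
    """Truncated-Gaussian intensity noise for seeded pixels (uneven seeding)."""

    enabled: bool = True
    mean: float = 0.5
    deviation: float = 0.15
    lo: float = 0.0
    hi: float = 1.0


@dataclass
class SeedingField:
    """Real-valued initial colonization pattern in [0, 1]."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)


def _truncated_normal(n: int, noise: SeedingNoise, rng: np.random.Generator) -> np.ndarray:
    """Rejection sampling of N(mean, deviation) truncated to [lo, hi]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(noise.mean, noise.deviation, size=max(n - filled, 16))
        keep = draw[(draw >= noise.lo) & (draw <= noise.hi)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def bits_to_seeding(
    bits: str,
    layout: SeedingLayout,
    seeding_noise: SeedingNoise | None = None,
    rng: np.random.Generator | None = None,
) -> SeedingField:
    """Seed each 1-bit spot with (noisy) cell intensities.

    With noise disabled every seeded pixel is set to the noise mean; with noise
    enabled each pixel draws independently from the truncated Gaussian.
    """
    if len(bits) != layout.n_bits or set(bits) - {"0", "1"}:
        raise ValueError(f"bit string {bits!r} does not match layout n_bits={layout.n_bits}")
    noise = seeding_noise or SeedingNoise()
    if noise.enabled and rng is None:
        raise ValueError("rng required when seeding noise is enabled")
    n = layout.field_side
    yy, xx = np.mgrid[0:n, 0:n]
    values = np.zeros((n, n))
    for bit, (cy, cx) in zip(bits, spot_centers(layout)):
        if bit != "1":
            continue
        m = np.hypot(yy - cy, xx - cx) <= layout.spot_radius
        if noise.enabled:
            values[m] = _truncated_normal(int(m.sum()), noise, rng)
        else:
            values[m] = noise.mean
    return SeedingField(values=values, provenance={"bits": bits})
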