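"""Kernel-based colony growth simulator.

The colony is a real-valued colonization field ``N`` on a pixel grid inside a
growth domain (the plate).  Each discrete time step convolves ``N`` with a
radially symmetric growth kernel

    K(d) = b * 2**(-(d/d1)**h1) - 2**(-(d/d2)**h2)

whose short-range positive lobe (magnitude ``b``, scale ``d1``) drives
expansion and whose longer-range negative ring (scale ``d2``) models
repulsion/inhibition; the sharpness exponents ``h1``, ``h2`` make both terms
nearly step-like.  The rectified convolution is passed through a saturating
colonization response ``raw / (h + raw)`` so occupancy stays in [0, 1): the
interplay of local activation, lateral inhibition and saturation produces
branching colonies at the default parameters, domain-filling disks when
expansion dominates, and growth arrest when the expansion range collapses.

Growth noise is a multiplicative scalar applied to the kernel afresh at every
time step, ``K_t = K * (1 + z_t / snr)`` with ``z_t`` standard normal, so the
element-wise RMS of the perturbation equals ``RMS(K)/snr``.

The plate boundary exerts a negative influence ``I = -k * 2**(-eps*d/R)``
(``d`` = Euclidean distance to the boundary, ``R`` its maximum over the
domain).  It is added to the kernel inside the update integral, so the raw
growth potential is ``conv(K, N) + w * conv((I/k) * N, 1_support)``: a local
shift of the expansion-to-repulsion balance proportional to the colonized
mass in the kernel window.  With the default sharp decay (eps = 2000) only
the immediate rim is affected, while eps = 1 lets the domain shape bias
growth all the way to the colony center (the encryption key).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image
from PIL.PngImagePlugin import PngInfo
from scipy.ndimage import distance_transform_edt
from scipy.signal import fftconvolve

__all__ = [
    "GrowthParams",
    "Kernel",
    "DomainGeometry",
    "ColonyField",
    "PatternImage",
    "build_kernel",
    "sample_kernel_noise",
    "plate_influence",
    "boundary_influence_field",
    "step",
    "simulate",
    "classify_morphology",
    "crop_center",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class GrowthParams:
    """All knobs of the growth kernel, noise, response and termination.

    ``snr`` is the linear signal-to-noise ratio of the per-step kernel noise
    (``None`` = noiseless growth, the default regime).  ``half_saturation`` is
    the half-effect constant of the colonization response, in units of kernel
    mass.  ``influence_weight`` scales the relative suppression exerted by the
    plate-influence field.
    """

    b: float = 6.5
    d1: float = 4.0
    d2: float = 10.0
    h1: float = 1000.0
    h2: float = 2000.0
    snr: float | None = None
    kernel_cutoff: float | None = None
    half_saturation: float = 2.0
    influence_weight: float = 0.25
    max_steps: int = 300
    stop_tol: float = 1e-4
    stop_patience: int = 5

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if not 0 < self.d1 < self.d2:
            raise ValueError("require 0 < d1 < d2")
        if self.h1 < 1 or self.h2 < 1:
            raise ValueError("sharpness exponents must be >= 1")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0 when present")
        if self.cutoff < self.d2:
            raise ValueError("kernel_cutoff must be >= d2")
        if self.half_saturation <= 0:
            raise ValueError("half_saturation must be > 0")

    @property
    def cutoff(self) -> float:
        if self.kernel_cutoff is not None:
            return self.kernel_cutoff
        return float(np.ceil(1.25 * self.d2))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "GrowthParams":
        return cls(**json.loads(s))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class Kernel:
    """Growth kernel sampled on integer pixel offsets within the cutoff."""

    values: np.ndarray      # (2c+1, 2c+1)
    support: np.ndarray     # boolean, d <= cutoff

    @property
    def rms(self) -> float:
        """RMS over the truncated support (the noise reference amplitude)."""
        return float(np.sqrt(np.mean(self.values[self.support] ** 2)))


def build_kernel(params: GrowthParams) -> Kernel:
    """Evaluate K(d) on the discrete offset grid, truncated at the cutoff."""
    c = int(np.ceil(params.cutoff))
    r = np.arange(-c, c + 1)
    d = np.hypot(*np.meshgrid(r, r))
    # (d/d1)**h1 overflows to inf for d > d1 at h1 ~ 1000; exp2(-inf) = 0 is
    # exactly the sharp-exponent limit we want, so silence the overflow.
    with np.errstate(over="ignore", under="ignore"):
        k = params.b * np.exp2(-((d / params.d1) ** params.h1)) - np.exp2(
            -((d / params.d2) ** params.h2)
        )
    support = d <= params.cutoff
    k[~support] = 0.0
    return Kernel(values=k, support=support)


def sample_kernel_noise(
    kernel: Kernel, snr: float | None, rng: np.random.Generator
) -> np.ndarray:
    """One noisy kernel draw: K * (1 + z/snr), a fresh scalar z per call.

    The perturbation is multiplicative in the kernel (growth-rate noise), so
    the pooled element-wise std of (noisy - clean) over the support equals
    RMS(K)/snr.  ``snr=None`` returns the kernel unchanged.
    """
    if snr is None:
        return kernel.values
    return kernel.values * (1.0 + rng.standard_normal() / snr)


# ---------------------------------------------------------------------------
# domain geometry and plate influence

_SHAPES = ("circle", "diamond", "square", "triangle")


@dataclass
class DomainGeometry:
    """Growth domain of a given shape, sized by area.

    The domain area is ``area_fraction`` times the area of the circle of
    diameter ``field_side``, so different shapes built with the same
    ``area_fraction`` are area-matched and comparable.  A circle at the
    default fraction 1.0 is the full inscribed disk; a diamond or triangle at
    fraction 1.0 would not fit the grid and is rejected (use <= 0.63 for a
    diamond, <= 0.55 for a triangle).  ``eps`` regulates the reach of the
    boundary influence (1 for encryption, 2000 otherwise) and ``k`` its
    magnitude.
    """

    shape: str = "circle"
    field_side: int = 451
    k: float = 1000.0
    eps: float = 2000.0
    area_fraction: float = 1.0
    mask: np.ndarray = field(init=False, repr=False)
    d_field: np.ndarray = field(init=False, repr=False)
    R: float = field(init=False)

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if not 0 < self.area_fraction <= 1.0:
            raise ValueError("area_fraction must be in (0, 1]")
        n = self.field_side
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        area = self.area_fraction * np.pi * (n / 2.0) ** 2
        if self.shape == "circle":
            r = min(np.sqrt(area / np.pi), n / 2.0 - 0.5)
            m = np.hypot(yy - c, xx - c) <= r
        elif self.shape == "square":
            s = np.sqrt(area)
            if s > n:
                raise ValueError("square exceeds the grid; reduce area_fraction")
            m = (np.abs(yy - c) <= s / 2) & (np.abs(xx - c) <= s / 2)
        elif self.shape == "diamond":
            a = np.sqrt(area / 2.0)  # half-diagonal
            if a > n / 2.0:
                raise ValueError("diamond exceeds the grid; reduce area_fraction")
            m = (np.abs(yy - c) + np.abs(xx - c)) <= a
        else:  # equilateral triangle, point up, centroid at field center
            s = np.sqrt(4 * area / np.sqrt(3))
            hgt = s * np.sqrt(3) / 2
            if s > n or hgt > n:
                raise ValueError("triangle exceeds the grid; reduce area_fraction")
            top = c - 2 * hgt / 3
            y = yy - top
            m = (y >= 0) & (y <= hgt) & (np.abs(xx - c) <= (y / np.sqrt(3)))
        self.mask = m
        d = distance_transform_edt(m)
        self.d_field = d
        self.R = float(d.max())
        if self.R <= 0:
            raise ValueError("degenerate geometry: empty domain")

    def config(self) -> dict:
        return {
            "shape": self.shape,
            "field_side": self.field_side,
            "k": self.k,
            "eps": self.eps,
            "area_fraction": self.area_fraction,
        }

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.config()).encode()).hexdigest()[:16]


def plate_influence(d, R: float, k: float = 1000.0, eps: float = 2000.0):
    """Scalar influence law I(d) = -k * 2**(-eps * d / R)."""
    if R <= 0:
        raise ValueError("R must be > 0")
    with np.errstate(under="ignore"):
        return -k * np.exp2(-eps * np.asarray(d, dtype=float) / R)


def boundary_influence_field(geometry: DomainGeometry) -> np.ndarray:
    """Plate influence I(x, y) over the grid, zero outside the domain."""
    i = plate_influence(geometry.d_field, geometry.R, geometry.k, geometry.eps)
    return np.where(geometry.mask, i, 0.0)


# ---------------------------------------------------------------------------
# stepping and simulation

@dataclass
class ColonyField:
    """Colonization field N_t in [0, 1], zero outside the domain."""

    values: np.ndarray
    t: int = 0


def step(
    colony: np.ndarray,
    kernel_values: np.ndarray,
    influence: np.ndarray | None = None,
    influence_weight: float = 0.25,
    mask: np.ndarray | None = None,
    half_saturation: float = 2.0,
    k_magnitude: float = 1000.0,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """One discrete update of the colonization field.

    raw  = conv(K, N) + w * conv((I/k) * N, 1_support)
           (the influence adds to the kernel inside the update integral,
           shifting the local expansion/repulsion balance), rectified at 0
    N'   = raw / (half_saturation + raw), masked to the domain.
    """
    if influence is not None and influence.shape != colony.shape:
        raise ValueError("influence and colony shapes differ")
    raw = fftconvolve(colony, kernel_values, mode="same")
    if influence is not None and influence_weight != 0.0:
        if support is None:
            support = np.ones_like(kernel_values)
        raw = raw + influence_weight * fftconvolve(
            (influence / k_magnitude) * colony, support, mode="same"
        )
    raw = np.clip(raw, 0.0, None)
    out = raw / (half_saturation + raw)
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out


@dataclass
class PatternImage:
    """8-bit grayscale final pattern plus provenance metadata."""

    pixels: np.ndarray  # uint8
    metadata: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        """Colonization values in [0, 1] (dequantized)."""
        return self.pixels.astype(np.float64) / 255.0

    def save(self, path) -> None:
        info = PngInfo()
        info.add_text("morphocode", json.dumps(self.metadata))
        Image.fromarray(self.pixels, mode="L").save(path, pnginfo=info)

    @classmethod
    def load(cls, path) -> "PatternImage":
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("L"))
            meta = json.loads(im.text.get("morphocode", "{}")) if hasattr(im, "text") else {}
        return cls(pixels=pixels, metadata=meta)


def simulate(
    seeding,
    params: GrowthParams,
    geometry: DomainGeometry,
    rng: np.random.Generator | None = None,
) -> PatternImage:
    """Grow a seeding field into a final pattern.

    Iterates :func:`step`, resampling the kernel noise each step when ``snr``
    is set, until the mean absolute change of the field stays below
    ``stop_tol`` for ``stop_patience`` consecutive steps (the colony has
    stopped growing) or ``max_steps`` is reached (recorded as unconverged in
    the metadata, not an error).  The final field is quantized round-half-up
    to 8 bits; internal state stays real-valued throughout.
    """
    values = seeding.values if hasattr(seeding, "values") else np.asarray(seeding, float)
    if values.shape != geometry.mask.shape:
        raise ValueError("seeding field does not fit the domain grid")
    if params.snr is not None and rng is None:
        raise ValueError("rng required when growth noise (snr) is enabled")
    kernel = build_kernel(params)
    support = kernel.support.astype(np.float64)
    influence = boundary_influence_field(geometry)
    n_field = np.where(geometry.mask, values, 0.0)
    patience = 0
    converged = False
    t = 0
    for t in range(1, params.max_steps + 1):
        kv = sample_kernel_noise(kernel, params.snr, rng) if params.snr else kernel.values
        nxt = step(
            n_field,
            kv,
            influence=influence,
            influence_weight=params.influence_weight,
            mask=geometry.mask,
            half_saturation=params.half_saturation,
            k_magnitude=geometry.k,
            support=support,
        )
        change = float(np.abs(nxt - n_field).mean())
        n_field = nxt
        if change < params.stop_tol:
            patience += 1
            if patience >= params.stop_patience:
                converged = True
                break
        else:
            patience = 0
    pixels = np.floor(255.0 * n_field + 0.5).astype(np.uint8)
    meta = {
        "steps": t,
        "converged": converged,
        "params_digest": params.digest(),
        "geometry": geometry.config(),
    }
    if hasattr(seeding, "provenance"):
        meta.update(seeding.provenance)
    return PatternImage(pixels=pixels, metadata=meta)


# ---------------------------------------------------------------------------
# morphology and cropping

def classify_morphology(
    pattern,
    seeding,
    geometry: DomainGeometry | None = None,
    theta_disk: float = 0.85,
    theta_trivial: float = 0.5,
    level: float = 0.05,
) -> str:
    """Label a final pattern as ``disk``, ``trivial`` or ``branching``.

    disk     : colonized fraction of the domain exceeds ``theta_disk``
    trivial  : IoU between the binarized pattern and binarized seeding
               exceeds ``theta_trivial`` (the colony never left its seeds)
    branching: everything else (the usable encoding regime)
    """
    pat = pattern.values if hasattr(pattern, "values") else np.asarray(pattern, float)
    seed = seeding.values if hasattr(seeding, "values") else np.asarray(seeding, float)
    bin_pat = pat > level
    bin_seed = seed > level * 0.5
    domain = geometry.mask if geometry is not None else np.ones_like(bin_pat)
    frac = bin_pat[domain.astype(bool)].mean()
    if frac > theta_disk:
        return "disk"
    union = (bin_pat | bin_seed).sum()
    iou = (bin_pat & bin_seed).sum() / union if union else 1.0
    if iou > theta_trivial:
        return "trivial"
    return "branching"


def crop_center(pattern: PatternImage, crop_radius: float) -> PatternImage:
    """Zero all pixels outside the centered circle of ``crop_radius``.

    Removes the growth-domain information from the output (the decryption
    side of the domain-shape key).  A radius covering the whole field leaves
    the pattern unchanged.
    """
    if crop_radius <= 0:
        raise ValueError("crop_radius must be > 0")
    n = pattern.pixels.shape[0]
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0 : pattern.pixels.shape[0], 0 : pattern.pixels.shape[1]]
    m = np.hypot(yy - c, xx - c) <= crop_radius
    meta = dict(pattern.metadata)
    meta["crop_radius"] = float(crop_radius)
    return PatternImage(pixels=np.where(m, pattern.pixels, 0).astype(np.uint8), metadata=meta)
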