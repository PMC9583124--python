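"""Text <-> pattern-frame-sequence codec.

Each character of a message is encoded as ``frames_per_char`` freshly
simulated replicate patterns (the ballots); the ordered frames form a video.
Decoding classifies every frame with a trained decoder (or ensemble) and
majority-votes within each group of ballots.  Frame sequences are stored as
numbered image files in a directory with a JSON sidecar: PNG for the lossless
(bit-exact round-trip) container, JPEG for the lossy one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .codebook import Codebook, SeedingLayout, SeedingNoise, bits_to_seeding, char_to_bits
from .datasets import item_rng, preprocess
from .decoder import DecoderModel, predict_proba
from .ensemble import EnsembleModel, ensemble_predict_proba, majority_vote
from .growth import DomainGeometry, GrowthParams, simulate

__all__ = [
    "FrameSequence",
    "encode_text",
    "frames_to_video",
    "video_to_frames",
    "decode_frames",
    "CodecUnavailableError",
]


class EncodingError(ValueError):
    pass


class CodecUnavailableError(RuntimeError):
    pass


@dataclass
class FrameSequence:
    """Ordered 8-bit grayscale frames; consecutive groups of
    ``frames_per_char`` frames encode one character."""

    frames: list          # list of 2D uint8 arrays
    frames_per_char: int
    codebook_digest: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)


def encode_text(
    text: str,
    codebook: Codebook,
    layout: SeedingLayout,
    params: GrowthParams,
    geometry: DomainGeometry,
    frames_per_char: int = 5,
    seeding_noise: SeedingNoise | None = None,
    base_seed: int = 0,
    frame_side: int | None = 80,
) -> FrameSequence:
    """Simulate ``frames_per_char`` patterns for every character of ``text``.

    Frames are downscaled to ``frame_side`` (None keeps the full field).
    Unsupported characters raise an error listing all offenders.
    """
    unknown = sorted({c for c in text if c not in codebook.char_to_index})
    if unknown:
        raise EncodingError(f"characters not in codebook: {unknown!r}")
    noise = seeding_noise or SeedingNoise()
    frames = []
    for pos, char in enumerate(text):
        bits = char_to_bits(char, codebook)
        ci = codebook.label_of(char)
        for ballot in range(frames_per_char):
            rng = item_rng(base_seed, ci, pos * frames_per_char + ballot)
            seed_field = bits_to_seeding(bits, layout, noise, rng)
            pat = simulate(seed_field, params, geometry, rng)
            if frame_side is not None and frame_side != pat.pixels.shape[0]:
                img = preprocess(pat, out_side=frame_side)
                frames.append(np.floor(255.0 * img + 0.5).astype(np.uint8))
            else:
                frames.append(pat.pixels)
    return FrameSequence(
        frames=frames,
        frames_per_char=frames_per_char,
        codebook_digest=codebook.digest(),
        metadata={"length": len(text), "base_seed": base_seed},
    )


def frames_to_video(seq: FrameSequence, path, lossless: bool = True, quality: int = 75):
    """Write the frame sequence to ``path`` (a directory).

    ``lossless=True`` stores PNG frames (bit-exact round trip); otherwise
    JPEG frames at the given quality.  Container video formats require a
    video codec backend that is not provided; requesting one raises
    :class:`CodecUnavailableError` naming the lossless directory mode.
    """
    path = Path(path)
    if path.suffix.lower() in {".mp4", ".avi", ".mov", ".mkv", ".webm"}:
        raise CodecUnavailableError(
            f"no video codec backend available for {path.suffix!r}; "
            "use a frame directory (lossless PNG or lossy JPEG) instead"
        )
    if not seq.frames:
        raise ValueError("empty frame sequence")
    path.mkdir(parents=True, exist_ok=True)
    ext = "png" if lossless else "jpg"
    for i, fr in enumerate(seq.frames):
        im = Image.fromarray(fr, mode="L")
        if lossless:
            im.save(path / f"frame_{i:06d}.png")
        else:
            im.save(path / f"frame_{i:06d}.jpg", quality=quality)
    sidecar = {
        "frames_per_char": seq.frames_per_char,
        "codebook_digest": seq.codebook_digest,
        "n_frames": len(seq.frames),
        "lossless": lossless,
        "format": ext,
        "metadata": seq.metadata,
    }
    (path / "video.json").write_text(json.dumps(sidecar, indent=1))
    return path


def video_to_frames(path) -> FrameSequence:
    path = Path(path)
    sidecar = json.loads((path / "video.json").read_text())
    frames = []
    for i in range(sidecar["n_frames"]):
        f = path / f"frame_{i:06d}.{sidecar['format']}"
        with Image.open(f) as im:
            frames.append(np.asarray(im.convert("L")))
    return FrameSequence(
        frames=frames,
        frames_per_char=sidecar["frames_per_char"],
        codebook_digest=sidecar["codebook_digest"],
        metadata=sidecar.get("metadata", {}),
    )


def decode_frames(
    seq: FrameSequence,
    model,
    codebook: Codebook,
    frames_per_char: int | None = None,
):
    """Decode a frame sequence back to text by per-group majority voting.

    Returns ``(text, confidences)`` where each confidence is the mean
    probability the decoder assigned to the winning character over the
    group's ballots.
    """
    fpc = frames_per_char or seq.frames_per_char
    if len(seq.frames) % fpc:
        raise ValueError(f"{len(seq.frames)} frames not divisible by {fpc} ballots per character")
    if not seq.frames:
        return "", []
    images = np.stack([preprocess(f) for f in seq.frames])
    if isinstance(model, EnsembleModel):
        probs = ensemble_predict_proba(model, images)
    elif isinstance(model, DecoderModel):
        probs = predict_proba(model, images)
    else:
        probs = model.predict_proba(images)
    chars, confs = [], []
    for g in range(len(seq.frames) // fpc):
        block = probs[g * fpc : (g + 1) * fpc]
        winner = majority_vote(block.argmax(axis=1), block)
        chars.append(codebook.characters[winner])
        confs.append(float(block[:, winner].mean()))
    return "".join(chars), confs
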