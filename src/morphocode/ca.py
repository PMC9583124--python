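"""1D elementary-cellular-automaton encoder (the simpler sibling system).

Characters are embedded as blocks of 1-cells in a binary sequence (the 1D
analogue of the spot array), each cell is independently flipped with a small
probability (seeding noise), and the sequence evolves for a fixed number of
steps under an elementary CA rule.  A feedforward network decodes the final
sequence.  The rule number is a required configuration choice; the default,
rule 54, is a placeholder from the weakly chaotic class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import Dense, ReLU, Sequential

__all__ = ["CAConfig", "ca_encode", "ca_evolve", "train_seq_decoder", "SeqDecoder"]


@dataclass(frozen=True)
class CAConfig:
    rule: int = 54
    width: int = 64
    steps: int = 16
    block_width: int = 4
    spacing: int = 8          # center-to-center distance between blocks
    flip_prob: float = 0.05
    boundary: str = "fixed"   # "fixed" (zeros) or "periodic"

    def __post_init__(self):
        if not 0 <= self.rule <= 255:
            raise ValueError("rule must be in [0, 255]")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.boundary not in ("fixed", "periodic"):
            raise ValueError("boundary must be 'fixed' or 'periodic'")


def _rule_table(rule: int) -> np.ndarray:
    """table[n] = next state for neighborhood code n = 4*left + 2*center + right."""
    return np.array([(rule >> n) & 1 for n in range(8)], dtype=np.uint8)


def ca_evolve(state: np.ndarray, rule: int, steps: int, boundary: str = "fixed") -> np.ndarray:
    """Apply an elementary rule for ``steps`` updates."""
    table = _rule_table(rule)
    s = np.asarray(state, dtype=np.uint8)
    for _ in range(steps):
        if boundary == "periodic":
            left, right = np.roll(s, 1), np.roll(s, -1)
        else:
            left = np.concatenate(([0], s[:-1])).astype(np.uint8)
            right = np.concatenate((s[1:], [0])).astype(np.uint8)
        s = table[4 * left + 2 * s + right]
    return s


def block_starts(config: CAConfig, n_bits: int) -> list[int]:
    """Left edge of each bit's block; the block array is centered."""
    span = (n_bits - 1) * config.spacing + config.block_width
    if span > config.width:
        raise ValueError(f"{n_bits} blocks do not fit in width {config.width}")
    start = (config.width - span) // 2
    return [start + k * config.spacing for k in range(n_bits)]


def ca_encode(bits: str, config: CAConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Embed bits as 1-blocks, flip cells with ``flip_prob``, evolve the rule."""
    if set(bits) - {"0", "1"}:
        raise ValueError("bits must be a 0/1 string")
    init = np.zeros(config.width, dtype=np.uint8)
    for bit, s in zip(bits, block_starts(config, len(bits))):
        if bit == "1":
            init[s : s + config.block_width] = 1
    if config.flip_prob > 0:
        if rng is None:
            raise ValueError("rng required when flip_prob > 0")
        flips = rng.random(config.width) < config.flip_prob
        init = np.where(flips, 1 - init, init).astype(np.uint8)
    return ca_evolve(init, config.rule, config.steps, config.boundary)


@dataclass
class SeqDecoder:
    net: Sequential
    n_classes: int

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(np.asarray(sequences, dtype=np.float32))

    def predict(self, sequences: np.ndarray) -> np.ndarray:
        return self.predict_proba(sequences).argmax(axis=1)


def train_seq_decoder(
    sequences: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    hidden: tuple[int, ...] = (64,),
    rng_seed: int = 0,
    learning_rate: float = 1e-3,
    max_epochs: int = 300,
    patience: int = 10,
    min_delta: float = 1e-4,
) -> SeqDecoder:
    """Feedforward softmax classifier on final CA sequences."""
    x = np.asarray(sequences, dtype=np.float32)
    y = np.asarray(labels)
    counts = np.bincount(y, minlength=n_classes)
    if counts.min() != counts.max():
        raise ValueError("dataset must be balanced")
    rng = np.random.default_rng(rng_seed)
    layers = []
    n_in = x.shape[1]
    for w in hidden:
        layers += [Dense(n_in, w, rng), ReLU()]
        n_in = w
    layers.append(Dense(n_in, n_classes, rng))
    net = Sequential(layers)
    net.fit(
        x, y, n_classes=n_classes, rng=rng, lr=learning_rate,
        max_epochs=max_epochs, patience=patience, min_delta=min_delta,
        val_fraction=0.1,
    )
    return SeqDecoder(net=net, n_classes=n_classes)
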