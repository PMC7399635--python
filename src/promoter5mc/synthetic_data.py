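"""Synthetic benchmark generator.

Emulates the shape of an RRBS-derived promoter methylation benchmark:
fixed-length windows (41 nt by default) centred on a cytosine, with a class
imbalance of roughly 1 positive to 11 negatives.  Negatives are drawn from
an i.i.d. background with a configurable GC fraction.  Positives draw the
motif-window positions around the centre from a mixture of the background
and a CpG-rich consensus; the mixture weight is the ``effect`` parameter,
so effect=0 makes the classes exchangeable (a null model) and effect near 1
plants a strong, easily learnable dinucleotide-level signal of the kind
expected around methylated promoter CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .io_sequences import Sample, SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_pos: int
    n_neg: int
    delta: int = 20
    effect: float = 0.9
    gc_background: float = 0.5
    motif_width: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("n_pos and n_neg must be >= 1")
        if not 0 <= self.effect <= 1:
            raise ValidationError(f"effect must be in [0,1], got {self.effect}")
        if not 0 < self.gc_background < 1:
            raise ValidationError(f"gc_background must be in (0,1), got {self.gc_background}")
        if self.delta < 1:
            raise ValidationError(f"delta must be >= 1, got {self.delta}")
        if not 1 <= self.motif_width <= 2 * self.delta:
            raise ValidationError(
                f"motif_width must be in [1, 2*delta], got {self.motif_width}"
            )


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _motif_offsets_and_consensus(delta: int, motif_width: int) -> tuple[list[int], list[str]]:
    """Window positions flanking the centre that carry the planted signal.

    Offsets straddle the central C (which is never altered); the consensus
    alternates G and C starting with G at the first downstream position, so
    a planted positive is CpG-dense through the centre.
    """
    half = motif_width // 2
    offsets = [delta + d for d in range(-half, motif_width - half + 1) if d != 0]
    offsets = offsets[:motif_width]
    consensus = []
    for pos in offsets:
        d = pos - delta
        consensus.append("G" if (d % 2 == 1 if d > 0 else d % 2 == 0) else "C")
    return offsets, consensus


def generate_dataset(config: GeneratorConfig) -> list[Sample]:
    """Generate labeled windows: n_pos positives then shuffled with n_neg negatives.

    Every window has length 2*delta+1 with 'C' at index delta.  Fully
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    length = 2 * config.delta + 1
    bg = _background_probs(config.gc_background)
    offsets, consensus = _motif_offsets_and_consensus(config.delta, config.motif_width)

    def draw_window(positive: bool) -> str:
        chars = rng.choice(4, size=length, p=bg)
        window = _BASES[chars]
        window[config.delta] = "C"
        if positive and config.effect > 0:
            for pos, cons in zip(offsets, consensus):
                probs = (1 - config.effect) * bg.copy()
                probs[list("ACGT").index(cons)] += config.effect
                window[pos] = _BASES[rng.choice(4, p=probs)]
        return "".join(window)

    samples = [
        Sample(
            window=draw_window(True),
            delta=config.delta,
            label=1,
            source_id=f"synth_pos_{i}",
            center_pos=config.delta,
        )
        for i in range(config.n_pos)
    ] + [
        Sample(
            window=draw_window(False),
            delta=config.delta,
            label=0,
            source_id=f"synth_neg_{i}",
            center_pos=config.delta,
        )
        for i in range(config.n_neg)
    ]
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


def make_toy_promoter(
    length: int, seed: int = 0, delta: int = 20, gc: float = 0.5, name: str | None = None
) -> SequenceRecord:
    """A random ACGT promoter-like sequence for exercising the scanner and CLI."""
    if length < 2 * delta + 1:
        raise ValidationError(
            f"length must be >= 2*delta+1 = {2 * delta + 1}, got {length}"
        )
    rng = np.random.default_rng(seed)
    seq = "".join(_BASES[rng.choice(4, size=length, p=_background_probs(gc))])
    return SequenceRecord(id=name or f"toy_promoter_{seed}", seq=seq)
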