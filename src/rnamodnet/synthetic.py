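"""Planted-motif synthetic fixtures.

The generator emulates the statistical structure the predictor assumes:
fixed-length windows centered on a candidate nucleotide, positives carrying
one or more consensus motifs at configurable offsets with per-position
substitution noise, negatives drawn from a background composition, and an
optional forced center base (U for the 5-methyluridine setting).

The default fixture is a 41-nt, center-U, balanced 2000+2000 design with
one planted consensus "UUCGAAUC" at fixed offset 12 (occupying positions
12..19, immediately 5' of the center U) and substitution rate 0.1 — a
sharply learnable but noisy motif, chosen as the package's canonical test
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import IUPAC
from .encodings import BASES
from .interpret import Pwm
from .seqio import SequenceWindow


@dataclass
class MotifSpec:
    consensus: str
    embed_prob: float = 1.0
    offset: tuple = ("fixed", 12)  # ("fixed", k) | ("uniform",) | ("choice", [..])

    def __post_init__(self):
        if not 0 <= self.embed_prob <= 1:
            raise ValueError("embed probability must be in [0, 1]")
        bad = sorted({c for c in self.consensus if c not in IUPAC})
        if bad:
            raise ValueError(f"undefined symbols in consensus: {bad}")


@dataclass
class SyntheticSpec:
    n_pos: int = 2000
    n_neg: int = 2000
    seq_len: int = 41
    motifs: list[MotifSpec] = field(
        default_factory=lambda: [MotifSpec("UUCGAAUC", 1.0, ("fixed", 12))])
    substitution_rate: float = 0.1
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    center_base: str | None = "U"
    seed: int = 42

    def __post_init__(self):
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        for m in self.motifs:
            if len(m.consensus) >= self.seq_len:
                raise ValueError("motif longer than window")


def default_spec(**overrides) -> SyntheticSpec:
    return SyntheticSpec(**overrides)


def _draw_offset(rng, motif: MotifSpec, seq_len: int) -> int:
    kind = motif.offset[0]
    hi = seq_len - len(motif.consensus)
    if kind == "fixed":
        off = int(motif.offset[1])
        if not 0 <= off <= hi:
            raise ValueError(f"fixed offset {off} outside [0, {hi}]")
        return off
    if kind == "uniform":
        return int(rng.integers(0, hi + 1))
    if kind == "choice":
        return int(rng.choice(motif.offset[1]))
    raise ValueError(f"unknown offset distribution {kind!r}")


def generate(spec: SyntheticSpec):
    """Generate labeled windows and the plant truth table.

    Returns (windows, truth) where truth is a DataFrame with one row per
    planted motif instance (window name, motif consensus, offset).
    Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list(BASES))
    bg = np.asarray(spec.background)
    windows: list[SequenceWindow] = []
    truth_rows = []

    def background_window() -> list[str]:
        return list(rng.choice(bases, size=spec.seq_len, p=bg))

    for i in range(spec.n_neg):
        chars = background_window()
        if spec.center_base:
            chars[(spec.seq_len - 1) // 2] = spec.center_base
        windows.append(SequenceWindow("".join(chars), label=0, name=f"neg_{i:05d}"))

    for i in range(spec.n_pos):
        chars = background_window()
        name = f"pos_{i:05d}"
        for motif in spec.motifs:
            if rng.random() > motif.embed_prob:
                continue
            off = _draw_offset(rng, motif, spec.seq_len)
            for j, sym in enumerate(motif.consensus):
                base = sym if sym in BASES else rng.choice(list(IUPAC[sym]))
                if spec.substitution_rate and rng.random() < spec.substitution_rate:
                    base = rng.choice(bases, p=bg)
                chars[off + j] = base
            truth_rows.append(dict(window=name, motif=motif.consensus, offset=off))
        if spec.center_base:
            chars[(spec.seq_len - 1) // 2] = spec.center_base
        windows.append(SequenceWindow("".join(chars), label=1, name=name))

    truth = pd.DataFrame(truth_rows, columns=["window", "motif", "offset"])
    return windows, truth


def consensus_pwm(consensus: str, strength: float = 0.91) -> Pwm:
    """PWM form of a planted consensus (IUPAC classes spread uniformly
    within the class)."""
    m = np.zeros((len(consensus), 4))
    off_mass = 0.0  # residual spread outside the class
    for i, sym in enumerate(consensus):
        members = IUPAC[sym]
        within = strength if len(members) == 1 else 1.0
        for b in members:
            m[i, BASES.index(b)] = within / len(members)
        if len(members) == 1:
            for b in BASES:
                if b not in members:
                    m[i, BASES.index(b)] = (1 - strength) / 3
    return Pwm(m, source=f"consensus_{consensus}")


def generate_pwm_family(base_pwm: Pwm, n_copies: int, noise: float,
                        seed: int = 0) -> list[Pwm]:
    """Dirichlet-perturbed copies of a PWM; ``noise`` = 0 gives exact
    copies, larger values flatter/noisier rows (concentration 1/noise)."""
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_copies):
        if noise == 0:
            m = base_pwm.matrix.copy()
        else:
            conc = base_pwm.matrix / noise + 1e-6
            m = np.vstack([rng.dirichlet(row) for row in conc])
        out.append(Pwm(m, source=f"{base_pwm.source or 'pwm'}_copy{i}"))
    return out
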