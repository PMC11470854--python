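"""Balanced synthetic protein datasets with planted dipeptide signal.

The generator emulates a balanced two-class design: negatives are
i.i.d. residue strings drawn from a background composition; positives
are drawn from the same background and then have a small set of
"planted" dipeptides written in at random positions, at an expected
rate of `enrichment` plantings per 100 residues. With enrichment 0 the
classes are exchangeable (any classifier should sit at chance); raising
the enrichment raises the dipeptide-level class signal, which DPC-style
encoders pick up but single-residue composition largely cannot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import (
    STANDARD_ALPHABET,
    LabeledDataset,
    SequenceRecord,
    write_fasta,
)

_ALPHABET = np.array(list(STANDARD_ALPHABET))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs of the synthetic two-class dataset.

    enrichment is the expected number of planted-dipeptide insertions
    per 100 residues in positive sequences (0 = null / exchangeable).
    """

    n_per_class: int = 300
    length_range: tuple[int, int] = (100, 400)
    background: tuple[float, ...] | None = None  # 20-simplex; None = uniform
    planted_dipeptides: tuple[str, ...] = ("RI", "LA", "ID")
    enrichment: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be a 20-simplex")
        for dp in self.planted_dipeptides:
            if len(dp) != 2 or not set(dp) <= set(STANDARD_ALPHABET):
                raise ValueError(f"invalid planted dipeptide {dp!r}")

    @property
    def background_array(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1 / 20)
        return np.asarray(self.background, dtype=float)


def generate(config: SyntheticConfig) -> LabeledDataset:
    """Draw a balanced labelled dataset, fully reproducible from the seed."""
    bg = config.background_array
    if config.enrichment > 0:
        zero_mass = {
            STANDARD_ALPHABET[i] for i in np.flatnonzero(bg == 0)
        }
        for dp in config.planted_dipeptides:
            if set(dp) & zero_mass:
                warnings.warn(
                    f"planted dipeptide {dp!r} uses a zero-background residue; "
                    "the signal is trivially separable",
                    stacklevel=2,
                )
                break
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    records: list[SequenceRecord] = []
    for label in ("positive", "negative"):
        for i in range(config.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = rng.choice(20, size=length, p=bg)
            chars = _ALPHABET[seq]
            if label == "positive" and config.enrichment > 0:
                n_plants = rng.poisson(config.enrichment * length / 100)
                for _ in range(n_plants):
                    dp = config.planted_dipeptides[
                        rng.integers(len(config.planted_dipeptides))
                    ]
                    pos = int(rng.integers(0, length - 1))
                    chars[pos] = dp[0]
                    chars[pos + 1] = dp[1]
            records.append(
                SequenceRecord(
                    id=f"{label[:3]}_{i:04d}",
                    sequence="".join(chars),
                    label=label,  # type: ignore[arg-type]
                )
            )
    return LabeledDataset(records)


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of the canonical small fixtures written by make_acceptance_suite."""

    toy_fasta: Path
    separable_positive: Path
    separable_negative: Path
    null_positive: Path
    null_negative: Path
    separable_config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]
    null_config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def make_acceptance_suite(seed: int, outdir: str | Path) -> FixtureBundle:
    """Write the canonical unit-test fixtures; idempotent under a fixed seed.

    The bundle contains a 3-entry toy FASTA with a duplicated sequence
    and an invalid residue, plus separable (enrichment 8) and null
    (enrichment 0) datasets that differ only in the enrichment knob.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    toy = outdir / "toy.fasta"
    toy.write_text(
        ">dup1\nACDEFGHIKL\n>dup2\nACDEFGHIKL\n>badres\nACXDEFGHIK\n"
    )

    sep_cfg = SyntheticConfig(n_per_class=50, seed=seed)
    null_cfg = SyntheticConfig(n_per_class=50, enrichment=0.0, seed=seed)
    bundle = {}
    for tag, cfg in (("separable", sep_cfg), ("null", null_cfg)):
        data = generate(cfg)
        for label in ("positive", "negative"):
            path = outdir / f"{tag}_{label}.fasta"
            write_fasta([r for r in data if r.label == label], path)
            bundle[f"{tag}_{label}"] = path
    return FixtureBundle(
        toy_fasta=toy,
        separable_positive=bundle["separable_positive"],
        separable_negative=bundle["separable_negative"],
        null_positive=bundle["null_positive"],
        null_negative=bundle["null_negative"],
        separable_config=sep_cfg,
        null_config=null_cfg,
    )
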