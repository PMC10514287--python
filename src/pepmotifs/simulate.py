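"""Synthetic peptide datasets with planted motifs and full ground truth.

The generator emulates the statistical structure the analysis assumes —
type-specific residue composition biases (serine-rich cTP-like,
arginine/leucine-rich mTP-like, leucine-rich SP-like with mid-sequence
motifs, lysine-rich AMP-like), motifs planted with a per-sequence
probability and a positional law, and taxon labels with group-specific
planted motifs.  Background residues are i.i.d. from a stated composition;
planted motifs overwrite background residues in place (gap positions stay
background), so sequence lengths follow the length law exactly.  Collisions
between planted motifs resolve later-wins; every insertion surviving in the
final sequence is recorded in the ground truth with its exact position.

The presets are qualitative emulations of real targeting-peptide structure,
not fits to any empirical dataset; passing tests on them demonstrates the
pipeline's correctness, not biological conclusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import PeptideRecord
from .motifs import STANDARD_AA, MotifPattern, find_occurrences, parse_motif

POSITIONAL_LAWS = ("prefix", "first-third", "middle", "uniform", "last-third")

#: default length bounds (uniform integer, inclusive) per sequence type
DEFAULT_LENGTHS = {"cTP": (20, 100), "mTP": (15, 80), "SP": (15, 40), "AMP": (10, 100)}


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to plant: canonical string, per-sequence probability and
    positional law on the scaled axis."""

    motif: str
    prob: float
    positional: str = "uniform"

    def __post_init__(self):
        if not 0 <= self.prob <= 1:
            raise ValueError(f"insertion probability {self.prob} outside [0, 1]")
        if self.positional not in POSITIONAL_LAWS:
            raise ValueError(
                f"positional law {self.positional!r} not in {POSITIONAL_LAWS}"
            )


@dataclass(frozen=True)
class TaxonSpec:
    """A taxon label: lineage assigned to its sequences, its share of the
    dataset, and extra motifs planted only in this taxon."""

    name: str
    lineage: tuple[str, ...]
    weight: float = 1.0
    planted: tuple[PlantedMotif, ...] = ()


@dataclass(frozen=True)
class GeneratorSpec:
    """Complete description of one synthetic dataset."""

    n: int
    seq_type: str = "cTP"
    length_range: tuple[int, int] | None = None
    background: dict[str, float] | None = None  # letter -> probability
    planted: tuple[PlantedMotif, ...] = ()
    taxa: tuple[TaxonSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lengths
        if lo < 10 or hi < lo:
            raise ValueError(f"length bounds ({lo}, {hi}) invalid; minimum length is 10")
        probs = self.background_probs
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("background residue probabilities must sum to 1")

    @property
    def lengths(self) -> tuple[int, int]:
        return self.length_range or DEFAULT_LENGTHS.get(self.seq_type, (10, 100))

    @property
    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1 / 20)
        return np.array([self.background.get(a, 0.0) for a in STANDARD_AA])


@dataclass
class Insertion:
    seq_id: str
    motif: str
    start: int  # 0-based


@dataclass
class GroundTruth:
    """Exact record of every planted motif surviving in the output."""

    insertions: list[Insertion] = field(default_factory=list)
    realized_fraction: dict[str, float] = field(default_factory=dict)
    per_taxon_fraction: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "insertions": [vars(i) for i in self.insertions],
            "realized_fraction": self.realized_fraction,
            "per_taxon_fraction": self.per_taxon_fraction,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _draw_start(rng, law: str, L: int, span: int) -> int:
    last = L - span
    if law == "prefix":
        return 0
    if law == "first-third":
        hi = min(last, max(0, L // 3 - span))
    elif law == "middle":
        lo = min(last, L // 3)
        hi = min(last, max(lo, 2 * L // 3 - span))
        return int(rng.integers(lo, hi + 1))
    elif law == "last-third":
        lo = min(last, 2 * L // 3)
        return int(rng.integers(lo, last + 1))
    else:  # uniform
        hi = last
    return int(rng.integers(0, hi + 1))


def _plant(seq: list[str], pattern: MotifPattern, start: int, rng) -> None:
    for off, cls in zip(pattern.offsets, pattern.classes):
        letters = sorted(cls)
        seq[start + off] = letters[int(rng.integers(len(letters)))] if len(letters) > 1 else letters[0]


def generate(
    spec: GeneratorSpec, seed: int | None = None
) -> tuple[list[PeptideRecord], GroundTruth]:
    """Generate a dataset from ``spec``; a fixed seed gives bit-identical
    output.  The returned ground truth lists every insertion still
    verifiable in the final sequence (later insertions may overwrite
    earlier ones) and the realized planting fraction per motif, overall and
    per taxon."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    letters = np.array(list(STANDARD_AA))
    probs = spec.background_probs
    lo, hi = spec.lengths

    taxa: Sequence[TaxonSpec | None]
    if spec.taxa:
        weights = np.array([t.weight for t in spec.taxa], dtype=float)
        shares = np.floor(spec.n * weights / weights.sum()).astype(int)
        for i in range(spec.n - shares.sum()):  # distribute the remainder
            shares[i % len(shares)] += 1
        taxa = [t for t, s in zip(spec.taxa, shares) for _ in range(s)]
    else:
        taxa = [None] * spec.n

    patterns: dict[str, MotifPattern] = {}

    def pattern_of(m: PlantedMotif) -> MotifPattern:
        if m.motif not in patterns:
            patterns[m.motif] = parse_motif(m.motif)
            if patterns[m.motif].span > lo:
                raise ValueError(
                    f"planted motif {m.motif!r} (span {patterns[m.motif].span}) "
                    f"exceeds the minimum sequence length {lo}"
                )
        return patterns[m.motif]

    records: list[PeptideRecord] = []
    truth = GroundTruth()
    planted_in: dict[str, set[str]] = {}
    planted_in_taxon: dict[str, dict[str, set[str]]] = {}

    for i, taxon in enumerate(taxa):
        seq_id = f"{spec.seq_type}_{i:05d}"
        L = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(letters, size=L, p=probs))
        planted_here = list(spec.planted) + (list(taxon.planted) if taxon else [])
        attempts: list[tuple[str, MotifPattern, int]] = []
        for pm in planted_here:
            pat = pattern_of(pm)
            if rng.random() < pm.prob:
                start = _draw_start(rng, pm.positional, L, pat.span)
                _plant(seq, pat, start, rng)
                attempts.append((pm.motif, pat, start))
        final = "".join(seq)
        for motif, pat, start in attempts:  # keep only insertions that survived
            if start in find_occurrences(final, pat).starts:
                truth.insertions.append(Insertion(seq_id, motif, start))
                planted_in.setdefault(motif, set()).add(seq_id)
                if taxon is not None:
                    planted_in_taxon.setdefault(taxon.name, {}).setdefault(
                        motif, set()
                    ).add(seq_id)
        records.append(
            PeptideRecord(
                id=seq_id,
                sequence=final,
                seq_type=spec.seq_type,
                lineage=taxon.lineage if taxon else (),
            )
        )

    truth.realized_fraction = {
        m: len(ids) / spec.n for m, ids in sorted(planted_in.items())
    }
    if spec.taxa:
        counts = {t.name: sum(1 for x in taxa if x is t) for t in spec.taxa}
        truth.per_taxon_fraction = {
            tname: {m: len(ids) / counts[tname] for m, ids in sorted(motifs.items())}
            for tname, motifs in sorted(planted_in_taxon.items())
        }
    return records, truth


def _composition(enriched: dict[str, float]) -> dict[str, float]:
    """Background distribution from relative residue weights (default 1)."""
    w = {a: enriched.get(a, 1.0) for a in STANDARD_AA}
    total = sum(w.values())
    return {a: v / total for a, v in w.items()}


def preset(name: str, n: int = 1000, seed: int = 0) -> GeneratorSpec:
    """Named generator presets emulating each sequence family.

    * ``cTP-like`` — serine/alanine-rich background; SS, S_S planted at high
      rates, MA planted as a prefix.
    * ``mTP-like`` — arginine/leucine/alanine-rich; LR, L_R, R_L and AAA
      planted, MAA as a prefix.
    * ``SP-like`` — leucine-rich; LL, L_L, LLL, LA planted in the middle
      region (an h-region-like core).
    * ``AMP-like`` — lysine-rich plus hydrophobics; KK, K___K, L_K, KL
      planted uniformly.
    * ``two-taxon-demo`` — two disjoint taxa sharing a background, with a
      differential motif (S_S at 0.6 vs 0.1) and an exclusive motif (WCW,
      one taxon only).
    """
    if name == "cTP-like":
        return GeneratorSpec(
            n=n,
            seq_type="cTP",
            background=_composition({"S": 3.2, "A": 2.4, "L": 1.8, "P": 1.4, "R": 1.2}),
            planted=(
                PlantedMotif("MA", 0.8, "prefix"),
                PlantedMotif("SS", 0.5, "uniform"),
                PlantedMotif("S_S", 0.5, "uniform"),
                PlantedMotif("LS", 0.3, "uniform"),
            ),
            seed=seed,
        )
    if name == "mTP-like":
        return GeneratorSpec(
            n=n,
            seq_type="mTP",
            background=_composition({"R": 2.6, "L": 2.4, "A": 2.4, "S": 1.8}),
            planted=(
                PlantedMotif("MAA", 0.3, "prefix"),
                PlantedMotif("LR", 0.45, "uniform"),
                PlantedMotif("L_R", 0.4, "uniform"),
                PlantedMotif("R_L", 0.4, "uniform"),
                PlantedMotif("AAA", 0.15, "uniform"),
            ),
            seed=seed,
        )
    if name == "SP-like":
        return GeneratorSpec(
            n=n,
            seq_type="SP",
            background=_composition({"L": 3.0, "A": 2.2, "V": 1.5}),
            planted=(
                PlantedMotif("LL", 0.7, "middle"),
                PlantedMotif("L_L", 0.45, "middle"),
                PlantedMotif("LLL", 0.25, "middle"),
                PlantedMotif("LA", 0.35, "middle"),
            ),
            seed=seed,
        )
    if name == "AMP-like":
        return GeneratorSpec(
            n=n,
            seq_type="AMP",
            background=_composition(
                {"K": 2.8, "L": 2.0, "G": 1.6, "C": 1.4, "I": 1.3, "A": 1.3}
            ),
            planted=(
                PlantedMotif("KK", 0.35, "uniform"),
                PlantedMotif("K___K", 0.3, "uniform"),
                PlantedMotif("L_K", 0.25, "uniform"),
                PlantedMotif("KL", 0.25, "uniform"),
            ),
            seed=seed,
        )
    if name == "two-taxon-demo":
        background = _composition({"S": 2.0, "A": 1.8, "L": 1.6, "W": 0.3, "C": 0.5})
        return GeneratorSpec(
            n=n,
            seq_type="cTP",
            background=background,
            taxa=(
                TaxonSpec(
                    "Streptophyta",
                    ("Eukaryota", "Viridiplantae", "Streptophyta"),
                    weight=1.0,
                    planted=(
                        PlantedMotif("S_S", 0.6, "uniform"),
                        PlantedMotif("WCW", 0.3, "uniform"),
                    ),
                ),
                TaxonSpec(
                    "Chlorophyta",
                    ("Eukaryota", "Viridiplantae", "Chlorophyta"),
                    weight=1.0,
                    planted=(PlantedMotif("S_S", 0.1, "uniform"),),
                ),
            ),
            seed=seed,
        )
    raise ValueError(
        f"unknown preset {name!r}; valid presets: cTP-like, mTP-like, SP-like, "
        "AMP-like, two-taxon-demo"
    )
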