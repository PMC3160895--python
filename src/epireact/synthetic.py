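"""Synthetic labelled peptide sets with planted local-motif signal.

The original assay data (13638 training + 13640 test peptides, ~25%
positive, mostly 15-mers) is not redistributable, so the toolkit ships a
generator that emulates its statistical structure: positives carry one
mutated copy of a short family motif (8-10 residues, the typical span of
an antibody footprint) implanted at a random offset in background
sequence, negatives are background with a configurable fraction carrying
decoy motifs, and reactivity values are drawn uniformly from the
positive ([10000, 65536]) or negative ([1, 1000]) band.  The planted
motifs make the local-alignment features informative, which is the
signal the classifier exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Peptide, PeptideSet, ValidationError
from .core import STANDARD_AA

#: published composition of the assay training set, used as the default
#: class balance and for the training-composition arithmetic
REFERENCE_TRAIN_SIZE = 13638
REFERENCE_TRAIN_POSITIVES = 3420
REFERENCE_TEST_SIZE = 13640
REFERENCE_TEST_POSITIVES = 3421


@dataclass
class SimConfig:
    """Parameters of the synthetic peptide-set generator."""

    n_peptides: int = 300
    positive_fraction: float = 0.25
    #: (length, probability) pairs; rare lengths mirror the assay's mix
    length_distribution: tuple[tuple[int, float], ...] = (
        (15, 0.85), (13, 0.10), (9, 0.01), (16, 0.01), (18, 0.01),
        (20, 0.01), (21, 0.01))
    n_motif_families: int = 3
    motif_length_range: tuple[int, int] = (8, 10)
    mutation_rate: float = 0.1
    decoy_fraction: float = 0.1
    n_decoy_families: int = 2
    #: mixed families plant one motif in both classes at a fixed positive
    #: fraction, producing M-type (uncertain) clusters; off by default
    n_mixed_families: int = 0
    mixed_positive_fraction: float = 0.25
    mixed_fraction: float = 0.0        # fraction of peptides in mixed families
    background_frequencies: dict[str, float] | None = None
    ambiguity_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValidationError("positive_fraction must lie in [0, 1]")
        min_len = min(l for l, _ in self.length_distribution)
        if self.motif_length_range[0] > min_len:
            raise ValidationError(
                "motif longer than the shortest allowed peptide length")


def _background(rng: np.random.Generator, length: int,
                freqs: dict[str, float] | None) -> list[str]:
    if freqs is None:
        return list(rng.choice(list(STANDARD_AA), size=length))
    residues = sorted(freqs)
    p = np.array([freqs[r] for r in residues], float)
    return list(rng.choice(residues, size=length, p=p / p.sum()))


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    # replacements are drawn from all 20 residues, so rate=1 degrades the
    # implant to pure background (a label-independent null)
    out = []
    for r in motif:
        if rng.random() < rate:
            out.append(rng.choice(list(STANDARD_AA)))
        else:
            out.append(r)
    return "".join(out)


def _implant(rng: np.random.Generator, seq: list[str], motif: str) -> list[str]:
    # a rare peptide shorter than its motif receives the motif prefix, so
    # peptide length stays independent of the class
    motif = motif[:len(seq)]
    off = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:off] + list(motif) + seq[off + len(motif):]


def simulate(config: SimConfig) -> PeptideSet:
    """Generate a labelled peptide set, fully reproducible from the seed.

    Counts are exact: ``round(n * positive_fraction)`` positives.  Every
    positive carries one mutated family-motif copy; ``decoy_fraction``
    of the negatives carry a decoy motif (so that sequence length alone
    cannot separate the classes); a 0.1% per-residue ambiguity-code
    (B/X/Z/J) injection exercises the ambiguous-residue code paths.
    """
    rng = np.random.default_rng(config.seed)
    lengths, probs = zip(*config.length_distribution)
    probs = np.array(probs, float)
    probs = probs / probs.sum()
    lo, hi = config.motif_length_range

    def new_motif() -> str:
        return "".join(rng.choice(list(STANDARD_AA),
                                  size=int(rng.integers(lo, hi + 1))))

    family_motifs = [new_motif() for _ in range(config.n_motif_families)]
    decoy_motifs = [new_motif() for _ in range(max(1, config.n_decoy_families))]
    mixed_motifs = [new_motif() for _ in range(config.n_mixed_families)]

    n = config.n_peptides
    n_mixed = int(round(n * config.mixed_fraction)) if mixed_motifs else 0
    n_pos = int(round(n * config.positive_fraction))

    records: list[tuple[str, str]] = []  # (sequence, label)
    for i in range(n - n_mixed):
        length = int(rng.choice(lengths, p=probs))
        seq = _background(rng, length, config.background_frequencies)
        if i < max(0, n_pos - int(round(n_mixed * config.mixed_positive_fraction))):
            motif = family_motifs[i % len(family_motifs)]
            seq = _implant(rng, seq, _mutate(rng, motif, config.mutation_rate))
            label = "positive"
        else:
            if rng.random() < config.decoy_fraction:
                motif = decoy_motifs[int(rng.integers(len(decoy_motifs)))]
                seq = _implant(rng, seq, _mutate(rng, motif, config.mutation_rate))
            label = "negative"
        records.append(("".join(seq), label))
    n_fam = len(mixed_motifs) if mixed_motifs else 1
    fam_sizes = [len(range(f, n_mixed, n_fam)) for f in range(n_fam)]
    fam_pos = [int(round(s * config.mixed_positive_fraction)) for s in fam_sizes]
    for i in range(n_mixed):
        length = int(rng.choice(lengths, p=probs))
        seq = _background(rng, length, config.background_frequencies)
        fam = i % n_fam
        seq = _implant(rng, seq, _mutate(rng, mixed_motifs[fam],
                                         config.mutation_rate))
        # exact per-family class balance so mixed clusters land inside the
        # uncertain-cluster tolerance band deterministically
        label = "positive" if (i // n_fam) < fam_pos[fam] else "negative"
        records.append(("".join(seq), label))

    # shuffle so that record order carries no label information
    rng.shuffle(records)

    peptides = []
    seen: set[str] = set()
    for i, (seq, label) in enumerate(records):
        if config.ambiguity_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < config.ambiguity_rate:
                    chars[j] = rng.choice(list("BXZJ"))
            seq = "".join(chars)
        while seq in seen:  # extremely rare collision; re-randomize one residue
            pos = int(rng.integers(len(seq)))
            chars = list(seq)
            chars[pos] = rng.choice(list(STANDARD_AA))
            seq = "".join(chars)
        seen.add(seq)
        if label == "positive":
            reactivity = float(rng.uniform(10000.0, 65536.0))
        else:
            reactivity = float(rng.uniform(1.0, 1000.0))
        peptides.append(Peptide(f"p{i:05d}", seq, label, reactivity))
    return PeptideSet(peptides, strict=True)


FIXTURES: dict[str, SimConfig] = {
    # small set for oracle-style tests
    "tiny": SimConfig(n_peptides=30, mutation_rate=0.05, n_motif_families=2),
    # the default study-scale set for cross-validation properties
    "medium": SimConfig(n_peptides=300),
    # signal so strong that leave-one-out classification is expected perfect:
    # verbatim long motifs, no decoys, 15-mers only
    "separable": SimConfig(
        n_peptides=40, mutation_rate=0.0, n_motif_families=2,
        motif_length_range=(10, 10), decoy_fraction=0.0,
        length_distribution=((15, 1.0),), ambiguity_rate=0.0),
    # labels carry no sequence signal at all; large enough that the
    # pessimistic small-sample LOOCV bias is negligible
    "null": SimConfig(
        n_peptides=200, n_motif_families=1, mutation_rate=1.0,
        decoy_fraction=0.0, ambiguity_rate=0.0),
    # H, L and M clusters all realized: strong families, heavy decoy use and
    # one mixed-membership family at the training class balance
    "clustered": SimConfig(
        n_peptides=200, mutation_rate=0.08, n_motif_families=3,
        motif_length_range=(9, 10), decoy_fraction=0.8, n_decoy_families=2,
        n_mixed_families=1, mixed_fraction=0.15, mixed_positive_fraction=0.25,
        length_distribution=((15, 0.95), (13, 0.05)), ambiguity_rate=0.0),
}


def make_fixture(name: str, seed: int = 0) -> PeptideSet:
    """A named study-condition fixture (tiny / medium / separable / null /
    clustered), reseeded via ``seed``."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    return simulate(cfg)
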