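"""Domain types and file I/O for peptide reactivity analysis.

Peptides are short amino-acid sequences (mostly 15-mers) whose binding
signal against pooled human antibodies (IVIg) has been measured on an
array.  A peptide is *positive* (reactive) when its measured signal lies
in [10000, 65536] and *negative* when it lies in [1, 1000]; the band in
between never occurs in the labelled pools.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BXZJ"
ALPHABET = frozenset(STANDARD_AA + AMBIGUOUS_AA)

#: reactivity bands of the assay
POSITIVE_REACTIVITY_MIN = 10000.0
NEGATIVE_REACTIVITY_MAX = 1000.0
REACTIVITY_RANGE = (1.0, 65536.0)

LABELS = ("positive", "negative", "unknown")


class ValidationError(ValueError):
    """A peptide or peptide set violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed under the requested format."""


@dataclass(frozen=True)
class Peptide:
    """A single peptide with an optional binary label and reactivity value.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a :class:`PeptideSet`.
    sequence : str
        Uppercase sequence over the 20 standard residues plus the
        ambiguity codes B (N/D), X (any), Z (Q/E) and J (L/I).
    label : str
        ``"positive"``, ``"negative"`` or ``"unknown"``.
    reactivity : float, optional
        Measured binding signal in [1, 65536]; must be consistent with
        the label (positives >= 10000, negatives <= 1000).
    """

    id: str
    sequence: str
    label: str = "unknown"
    reactivity: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"peptide {self.id!r}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValidationError(f"peptide {self.id!r}: sequence must be uppercase")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValidationError(
                f"peptide {self.id!r}: invalid residue(s) {sorted(bad)} in sequence"
            )
        if self.label not in LABELS:
            raise ValidationError(f"peptide {self.id!r}: unknown label {self.label!r}")
        if self.reactivity is not None:
            lo, hi = REACTIVITY_RANGE
            if not lo <= self.reactivity <= hi:
                raise ValidationError(
                    f"peptide {self.id!r}: reactivity {self.reactivity} outside [{lo}, {hi}]"
                )
            if self.label == "positive" and self.reactivity < POSITIVE_REACTIVITY_MIN:
                raise ValidationError(
                    f"peptide {self.id!r}: positive label requires reactivity >= "
                    f"{POSITIVE_REACTIVITY_MIN}"
                )
            if self.label == "negative" and self.reactivity > NEGATIVE_REACTIVITY_MAX:
                raise ValidationError(
                    f"peptide {self.id!r}: negative label requires reactivity <= "
                    f"{NEGATIVE_REACTIVITY_MAX}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class PeptideSet:
    """An ordered collection of peptides with unique ids.

    With ``strict=True`` (the default) duplicate sequences are rejected,
    matching the deduplicated assay pools; synthetic or merged sets may
    relax this.
    """

    def __init__(self, peptides: Iterable[Peptide], strict: bool = True) -> None:
        self.peptides: list[Peptide] = list(peptides)
        self.strict = strict
        seen_ids: set[str] = set()
        seen_seqs: set[str] = set()
        for p in self.peptides:
            if p.id in seen_ids:
                raise ValidationError(f"duplicate peptide id {p.id!r}")
            seen_ids.add(p.id)
            if strict:
                if p.sequence in seen_seqs:
                    raise ValidationError(
                        f"duplicate sequence for peptide {p.id!r} (strict mode)"
                    )
                seen_seqs.add(p.sequence)
        self._index = {p.id: i for i, p in enumerate(self.peptides)}

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    def by_id(self, pid: str) -> Peptide:
        return self.peptides[self._index[pid]]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.peptides]

    def positive_fraction(self) -> float:
        n_pos = sum(p.label == "positive" for p in self.peptides)
        n_lab = sum(p.label != "unknown" for p in self.peptides)
        if n_lab == 0:
            raise ValidationError("positive_fraction undefined: no labelled peptides")
        return n_pos / n_lab

    def subset(self, indices: Sequence[int]) -> "PeptideSet":
        return PeptideSet([self.peptides[i] for i in indices], strict=self.strict)


@dataclass
class RunConfig:
    """Tunable constants of the whole pipeline.

    All randomness in the toolkit flows from ``seed``.
    """

    # alignment
    substitution_matrix: str = "BLOSUM50"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    # sequence features
    window: int = 9
    # de-novo generation
    cluster_cutoff: float = 0.7
    min_h_cluster: int = 5
    min_l_cluster: int = 8
    min_m_cluster: int = 5
    m_tolerance: float = 0.05
    selection_count: int = 1100
    max_common_stretch: int = 3          # constraint 1: no shared (3+1)-mer
    max_identities: int = 5              # constraint 2: <=5 identities ...
    identity_window: int = 11            # ... within any 11-residue window
    enumeration_cap: int = 100_000
    # model
    collinearity_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window", "min_h_cluster", "min_l_cluster", "min_m_cluster",
                     "selection_count", "max_common_stretch", "max_identities",
                     "identity_window", "enumeration_cap"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValidationError(f"RunConfig.{name} must be a positive integer")
        if not 0.0 < self.cluster_cutoff < 1.0:
            raise ValidationError("cluster_cutoff must lie in (0, 1)")
        if not self.gap_open >= self.gap_extend > 0:
            raise ValidationError("require gap_open >= gap_extend > 0")

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read ``key = value`` lines; '#' starts a comment."""
        kwargs: dict = {}
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ParseError(f"{path}:{lineno}: unknown option {key!r}")
            current = getattr(cls(), key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# readers / writers

_TSV_COLUMNS = ("id", "sequence", "label", "reactivity")


def _parse_reactivity(text: str, where: str) -> float | None:
    if text in ("", "NA", "None"):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"{where}: bad reactivity {text!r}") from exc


def read_peptides(path: str | Path, format: str | None = None,
                  strict: bool = True) -> PeptideSet:
    """Read a peptide set from TSV or FASTA.

    TSV columns are ``id, sequence[, label[, reactivity]]`` with a header
    row.  FASTA description lines may carry ``label=...`` and
    ``reactivity=...`` tokens; absent labels default to ``unknown``.
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".faa") else "tsv"
    if format == "tsv":
        return _read_tsv(path, strict)
    if format == "fasta":
        return _read_fasta(path, strict)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path, strict: bool) -> PeptideSet:
    peptides = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip().lower() for h in header]
        if header[:2] != ["id", "sequence"]:
            raise ParseError(f"{path}:1: header must start with 'id\\tsequence'")
        for lineno, row in enumerate(reader, 2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            row = row + [""] * (4 - len(row))
            label = row[2].strip() or "unknown"
            reactivity = _parse_reactivity(row[3].strip(), f"{path}:{lineno}")
            peptides.append(Peptide(row[0].strip(), row[1].strip(), label, reactivity))
    return PeptideSet(peptides, strict=strict)


def _read_fasta(path: Path, strict: bool) -> PeptideSet:
    from Bio import SeqIO

    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = "unknown"
        reactivity = None
        for token in rec.description.split()[1:]:
            if token.startswith("label="):
                label = token[len("label="):]
            elif token.startswith("reactivity="):
                reactivity = _parse_reactivity(token[len("reactivity="):],
                                               f"{path}:{rec.id}")
        peptides.append(Peptide(rec.id, str(rec.seq).upper(), label, reactivity))
    if not peptides:
        raise ParseError(f"{path}: no FASTA records")
    return PeptideSet(peptides, strict=strict)


def write_peptides(pset: PeptideSet, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_TSV_COLUMNS)
            for p in pset:
                w.writerow([p.id, p.sequence, p.label,
                            "" if p.reactivity is None else f"{p.reactivity:g}"])
    elif format == "fasta":
        with open(path, "w") as fh:
            for p in pset:
                desc = f">{p.id} label={p.label}"
                if p.reactivity is not None:
                    desc += f" reactivity={p.reactivity:g}"
                fh.write(desc + "\n" + p.sequence + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


@dataclass
class Candidate:
    """One de-novo peptide with its model-predicted reactivity."""

    id: str
    sequence: str
    predicted_reactivity: float
    cls: str  # 'H', 'L' or 'M'

    def __post_init__(self) -> None:
        if self.cls not in ("H", "L", "M"):
            raise ValidationError(f"candidate {self.id!r}: class must be H, L or M")


@dataclass
class CandidateList:
    """The ranked de-novo peptides, grouped by predicted-reactivity class."""

    candidates: list[Candidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self) -> Iterator[Candidate]:
        return iter(self.candidates)

    def counts(self) -> dict[str, int]:
        out = {"H": 0, "L": 0, "M": 0}
        for c in self.candidates:
            out[c.cls] += 1
        return out

    def of_class(self, cls: str) -> list[Candidate]:
        return [c for c in self.candidates if c.cls == cls]


def write_candidates(clist: CandidateList, path: str | Path) -> None:
    """Write a candidate list as TSV (id, sequence, predicted_reactivity, class)."""
    if len(clist) == 0:
        raise ValidationError("refusing to write an empty candidate list")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(("id", "sequence", "predicted_reactivity", "class"))
        for c in clist:
            w.writerow([c.id, c.sequence, repr(c.predicted_reactivity), c.cls])


def read_candidates(path: str | Path) -> CandidateList:
    candidates = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != [
                "id", "sequence", "predicted_reactivity", "class"]:
            raise ParseError(f"{path}: bad candidate-list header")
        for lineno, row in enumerate(reader, 2):
            if len(row) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            candidates.append(Candidate(row[0], row[1], float(row[2]), row[3]))
    return CandidateList(candidates)
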