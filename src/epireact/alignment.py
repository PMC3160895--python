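"""Pairwise alignment scoring and the dataset-dependent features.

Every peptide is aligned against every other peptide of the reference
set, globally (Needleman-Wunsch) and locally (Smith-Waterman), with
BLOSUM50 and affine gaps (open 10, extend 1).  From the resulting score
matrices each peptide gets six features: its best score against the
negative references (MaxScore0), against the positive references
(MaxScore1) and their difference (DiffMaxScore), per alignment mode.
The rationale is classification by homology — a peptide resembling a
known reactive peptide is itself likely reactive — and the local/global
contrast probes whether reactivity lives in a short binding stretch or
in the whole sequence.

Dynamic programming is delegated to Biopython's ``PairwiseAligner``;
the substitution matrix is extended so that the ambiguity code J (L/I),
absent from the stock BLOSUM tables, scores like X.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core import PeptideSet, ValidationError
from .features import ALIGN_FEATURE_NAMES


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine-gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; terminal
    gaps are penalized in global mode.
    """

    matrix: str = "BLOSUM50"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValidationError("mode must be 'global' or 'local'")
        if not self.gap_open >= self.gap_extend > 0:
            raise ValidationError("require gap_open >= gap_extend > 0")


def load_matrix(name: str = "BLOSUM50") -> substitution_matrices.Array:
    """Load a substitution matrix and graft a J row/column onto it.

    Residue pairs the matrix does not define (J against anything) fall
    back to the X row, the matrix's own catch-all for unknown residues.
    """
    base = substitution_matrices.load(name)
    if "J" in base.alphabet:
        return base
    alphabet = base.alphabet.replace("*", "") + "J"
    ext = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            ext[a, b] = base[a if a != "J" else "X", b if b != "J" else "X"]
    return ext


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = load_matrix(params.matrix)
    al.mode = params.mode
    al.open_gap_score = -params.gap_open
    al.extend_gap_score = -params.gap_extend
    return al


def align_score(a: str, b: str, params: AlignmentParams) -> float:
    """Optimal affine-gap alignment score of two sequences.

    Global scores may be negative; local scores are >= 0 (the empty
    alignment is always available).
    """
    if not a or not b:
        raise ValidationError("align_score requires non-empty sequences")
    return float(_aligner(params).score(a, b))


@dataclass
class PairwiseScoreMatrix:
    """Symmetric all-vs-all alignment scores for one alignment mode."""

    mode: str
    scores: np.ndarray                 # n x n, float
    ids: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.scores.shape != (n, n):
            raise ValidationError("score matrix shape does not match ids")
        self.index = {pid: i for i, pid in enumerate(self.ids)}

    def self_scores(self) -> np.ndarray:
        return np.diagonal(self.scores).copy()

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.scores, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str) -> "PairwiseScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(mode=mode, scores=df.to_numpy(float), ids=[str(i) for i in df.index])


def score_matrix(pset: PeptideSet, params: AlignmentParams) -> PairwiseScoreMatrix:
    """All-vs-all alignment scores (O(n^2/2) alignments; symmetry exploited)."""
    if len(pset) < 2:
        raise ValidationError("score_matrix requires at least two peptides")
    al = _aligner(params)
    seqs = pset.sequences
    n = len(seqs)
    m = np.empty((n, n), float)
    for i in range(n):
        m[i, i] = al.score(seqs[i], seqs[i])
        for j in range(i + 1, n):
            s = al.score(seqs[i], seqs[j])
            m[i, j] = m[j, i] = s
    return PairwiseScoreMatrix(mode=params.mode, scores=m, ids=[p.id for p in pset])


def _masked_class_max(row: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValidationError(
            "alignment features undefined: empty positive or negative reference set")
    return float(row[mask].max())


def alignment_features(i: int, m_global: PairwiseScoreMatrix,
                       m_local: PairwiseScoreMatrix, labels: list[str],
                       exclude: frozenset[int] = frozenset()) -> dict[str, float]:
    """The six MaxScore/DiffMaxScore features of peptide ``i``.

    The peptide itself, and any index in ``exclude`` (e.g. a held-out
    cross-validation peptide), never contributes to the maxima.
    """
    labels_arr = np.asarray(labels)
    keep = np.ones(len(labels_arr), bool)
    keep[i] = False
    for j in exclude:
        keep[j] = False
    pos = keep & (labels_arr == "positive")
    neg = keep & (labels_arr == "negative")
    out: dict[str, float] = {}
    for tag, mat in (("nw", m_global), ("sw", m_local)):
        row = mat.scores[i]
        s0 = _masked_class_max(row, neg)
        s1 = _masked_class_max(row, pos)
        out[f"MaxScore0_{tag}"] = s0
        out[f"MaxScore1_{tag}"] = s1
        out[f"DiffMaxScore_{tag}"] = s1 - s0
    return out


def alignment_feature_frame(pset: PeptideSet, m_global: PairwiseScoreMatrix,
                            m_local: PairwiseScoreMatrix,
                            exclude: frozenset[int] = frozenset()) -> pd.DataFrame:
    """Alignment features for every peptide of the set, as a 6-column frame."""
    labels = pset.labels
    rows = [alignment_features(i, m_global, m_local, labels, exclude)
            for i in range(len(pset))]
    df = pd.DataFrame(rows, index=[p.id for p in pset])
    return df[list(ALIGN_FEATURE_NAMES)]


def query_alignment_features(queries: PeptideSet, references: PeptideSet,
                             gap_open: float = 10.0, gap_extend: float = 1.0,
                             matrix: str = "BLOSUM50") -> pd.DataFrame:
    """Alignment features of unlabelled query peptides against a labelled
    reference set (e.g. test peptides or de-novo candidates vs training)."""
    labels_arr = np.asarray(references.labels)
    pos = labels_arr == "positive"
    neg = labels_arr == "negative"
    if not pos.any() or not neg.any():
        raise ValidationError("reference set must contain both classes")
    ref_seqs = references.sequences
    rows = []
    aligners = {
        "nw": _aligner(AlignmentParams(matrix, gap_open, gap_extend, "global")),
        "sw": _aligner(AlignmentParams(matrix, gap_open, gap_extend, "local")),
    }
    for q in queries:
        out = {}
        for tag, al in aligners.items():
            scores = np.array([al.score(q.sequence, r) for r in ref_seqs])
            out[f"MaxScore0_{tag}"] = float(scores[neg].max())
            out[f"MaxScore1_{tag}"] = float(scores[pos].max())
            out[f"DiffMaxScore_{tag}"] = out[f"MaxScore1_{tag}"] - out[f"MaxScore0_{tag}"]
        rows.append(out)
    df = pd.DataFrame(rows, index=[q.id for q in queries])
    return df[list(ALIGN_FEATURE_NAMES)]
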