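"""Sequence-dependent peptide features.

For every peptide the toolkit computes 31 sequence-dependent features —
length, isoelectric point, the 24 residue occurrence counts (including
the ambiguity codes B/X/Z/J), and five propensity-scale features — and
joins them with the six dataset-dependent alignment features into a
37-column table, min-max normalized to [0, 1] on the training set.

The five scales are classic linear-epitope propensity tables:
antigenicity (Kolaskar), solvent accessibility (Janin), hydrophilicity
(Parker), chain flexibility (Bhaskaran) and beta-turn propensity
(Chou-Fasman).  Each scale feature is the maximum, over all sliding
windows of 9 residues, of the mean scale value in the window — 9 because
an antibody footprint on a linear epitope covers roughly 8-10 residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AMBIGUOUS_AA, STANDARD_AA, Peptide, PeptideSet, ValidationError

# ---------------------------------------------------------------------------
# built-in propensity scales (per-residue tables over the 20 standard AA)

_SCALE_ROWS = {
    #     antigen. access. hydroph. flex.  beta-turn
    "A": (1.064,   6.6,    2.10,    0.36,  0.66),
    "C": (1.412,   0.9,    1.40,    0.35,  1.19),
    "D": (0.866,   7.7,   10.00,    0.51,  1.46),
    "E": (0.851,   5.7,    7.80,    0.50,  0.74),
    "F": (1.091,   2.4,   -9.20,    0.31,  0.60),
    "G": (0.874,   6.7,    5.70,    0.54,  1.56),
    "H": (1.105,   2.5,    2.10,    0.32,  0.95),
    "I": (1.152,   2.8,   -8.00,    0.46,  0.47),
    "K": (0.930,  10.3,    5.70,    0.47,  1.01),
    "L": (1.250,   4.8,   -9.20,    0.37,  0.59),
    "M": (0.826,   1.0,   -4.20,    0.30,  0.60),
    "N": (0.776,   6.7,    7.00,    0.46,  1.56),
    "P": (1.064,   4.8,    2.10,    0.51,  1.52),
    "Q": (1.015,   5.2,    6.00,    0.49,  0.98),
    "R": (0.873,   4.5,    4.20,    0.53,  0.95),
    "S": (1.012,   9.4,    6.50,    0.51,  1.43),
    "T": (0.909,   7.0,    5.20,    0.44,  0.96),
    "V": (1.383,   4.5,   -3.70,    0.39,  0.50),
    "W": (0.893,   1.4,  -10.00,    0.31,  0.96),
    "Y": (1.161,   5.1,   -1.90,    0.42,  1.14),
}

SCALE_NAMES = ("antigenicity", "accessibility", "hydrophilicity",
               "flexibility", "beta_turn")


@dataclass(frozen=True)
class AminoAcidScale:
    """A residue -> propensity map over the 20 standard amino acids."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise ValidationError(
                f"scale {self.name!r} must define exactly the 20 standard residues"
            )

    def value(self, residue: str) -> float:
        """Scale value of a residue; ambiguity codes are averaged over
        their referents (B=N/D, Z=Q/E, J=L/I) and X over all 20."""
        v = self.values
        if residue in v:
            return v[residue]
        if residue == "B":
            return (v["N"] + v["D"]) / 2.0
        if residue == "Z":
            return (v["Q"] + v["E"]) / 2.0
        if residue == "J":
            return (v["L"] + v["I"]) / 2.0
        if residue == "X":
            return float(np.mean(list(v.values())))
        raise KeyError(residue)

    def profile(self, sequence: str) -> np.ndarray:
        return np.array([self.value(r) for r in sequence], float)


BUILTIN_SCALES: dict[str, AminoAcidScale] = {
    name: AminoAcidScale(name, {aa: row[i] for aa, row in _SCALE_ROWS.items()})
    for i, name in enumerate(SCALE_NAMES)
}

# ---------------------------------------------------------------------------
# residue counting

COUNT_ORDER = tuple(STANDARD_AA) + tuple(AMBIGUOUS_AA)  # A..Y then B X Z J


def aa_counts(p: Peptide) -> dict[str, int]:
    """Occurrence count of each of the 24 residue codes along the peptide.

    Ambiguity codes count as themselves; counts sum to the sequence length.
    """
    counts = dict.fromkeys(COUNT_ORDER, 0)
    for r in p.sequence:
        counts[r] += 1
    return counts


# ---------------------------------------------------------------------------
# isoelectric point

# EMBOSS-style pKa values for the ionizable groups.
PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,   # acidic side chains
    "H": 6.5, "K": 10.8, "R": 12.5,            # basic side chains
}
_ACIDIC = "DECY"
_BASIC = "HKR"


def net_charge(sequence: str, ph: float) -> float:
    """Net charge at a given pH (Henderson-Hasselbalch over the termini and
    the ionizable side chains D, E, C, Y, H, K, R).

    Ambiguity codes are treated as non-ionizable.
    """
    pos = 1.0 / (1.0 + 10.0 ** (ph - PKA["Nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (PKA["Cterm"] - ph))
    for r in sequence:
        if r in _BASIC:
            pos += 1.0 / (1.0 + 10.0 ** (ph - PKA[r]))
        elif r in _ACIDIC:
            neg += 1.0 / (1.0 + 10.0 ** (PKA[r] - ph))
    return pos - neg


def isoelectric_point(p: Peptide, tol: float = 1e-3) -> float:
    """pH at which the peptide's net charge vanishes, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique; the
    interval is bisected on the sign of the charge until it is narrower
    than ``tol``/10 (well inside the stated 1e-3 pH tolerance, and far
    below it where the charge curve is flat).
    """
    lo, hi = 0.0, 14.0
    seq = p.sequence
    while hi - lo > tol / 10.0:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# scale-window features

def scale_window_feature(p: Peptide, scale: AminoAcidScale, window: int = 9,
                         statistic: str = "mean") -> float:
    """Maximum over all length-``window`` sliding windows of the within-window
    mean (or max) scale value.

    Sequences shorter than the window are covered by a single window
    spanning the whole sequence.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    prof = scale.profile(p.sequence)
    if statistic == "max":
        return float(prof.max())
    if statistic != "mean":
        raise ValueError(f"unknown window statistic {statistic!r}")
    n = len(prof)
    if n <= window:
        return float(prof.mean())
    cs = np.concatenate(([0.0], np.cumsum(prof)))
    means = (cs[window:] - cs[:-window]) / window
    return float(means.max())


# ---------------------------------------------------------------------------
# the 37-column feature table

SEQ_FEATURE_NAMES = (
    ("LengthSeq", "IsoelPoint")
    + COUNT_ORDER
    + ("Antigenicity", "Accessibility", "Hydrophilicity", "Flexibility", "BetaTurn")
)
ALIGN_FEATURE_NAMES = ("MaxScore0_nw", "MaxScore1_nw", "MaxScore0_sw",
                       "MaxScore1_sw", "DiffMaxScore_nw", "DiffMaxScore_sw")
FEATURE_NAMES = SEQ_FEATURE_NAMES + ALIGN_FEATURE_NAMES


@dataclass
class FeatureTable:
    """Peptides x 37 features, with the min-max parameters used to map every
    column into [0, 1].

    ``values`` holds the normalized matrix; ``norm_params`` the per-column
    (min, max) learned on the training table, which invert the mapping.
    """

    values: pd.DataFrame            # index: peptide ids, columns: FEATURE_NAMES
    norm_params: pd.DataFrame       # index: FEATURE_NAMES, columns: ['min', 'max']

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(float)

    def denormalize(self) -> pd.DataFrame:
        """Recover the raw feature values from the stored (min, max)."""
        mn = self.norm_params["min"].to_numpy()
        mx = self.norm_params["max"].to_numpy()
        return self.values * (mx - mn) + mn


def sequence_features(pset: PeptideSet, window: int = 9,
                      statistic: str = "mean") -> pd.DataFrame:
    """Raw (un-normalized) sequence-dependent features: 31 columns."""
    rows = []
    for p in pset:
        counts = aa_counts(p)
        row = [float(len(p)), isoelectric_point(p)]
        row += [float(counts[r]) for r in COUNT_ORDER]
        row += [scale_window_feature(p, BUILTIN_SCALES[s], window, statistic)
                for s in SCALE_NAMES]
        rows.append(row)
    return pd.DataFrame(rows, index=[p.id for p in pset],
                        columns=list(SEQ_FEATURE_NAMES))


def _join_raw(seq_feats: pd.DataFrame, align_features: pd.DataFrame) -> pd.DataFrame:
    if list(align_features.columns) != list(ALIGN_FEATURE_NAMES):
        raise ValidationError("alignment feature columns do not match the schema")
    if not seq_feats.index.equals(align_features.index):
        raise ValidationError("sequence and alignment features index mismatch")
    return pd.concat([seq_feats, align_features], axis=1)


def build_feature_table(train: PeptideSet, align_features: pd.DataFrame,
                        window: int = 9, statistic: str = "mean") -> FeatureTable:
    """Assemble and min-max normalize the 37-column training feature table.

    Normalization parameters are learned per column on this table; a
    constant column maps to all zeros.
    """
    raw = _join_raw(sequence_features(train, window, statistic), align_features)
    mn = raw.min(axis=0)
    mx = raw.max(axis=0)
    span = (mx - mn).replace(0.0, np.nan)
    norm = ((raw - mn) / span).fillna(0.0)
    params = pd.DataFrame({"min": mn, "max": mx})
    return FeatureTable(values=norm, norm_params=params)


def apply_feature_table(test: PeptideSet, norm_params: pd.DataFrame,
                        align_features: pd.DataFrame, window: int = 9,
                        statistic: str = "mean") -> FeatureTable:
    """Featurize new peptides with *training* normalization, clipped to [0, 1]."""
    raw = _join_raw(sequence_features(test, window, statistic), align_features)
    if list(norm_params.index) != list(raw.columns):
        raise ValidationError("norm_params features do not match the table schema")
    mn = norm_params["min"]
    mx = norm_params["max"]
    span = (mx - mn).replace(0.0, np.nan)
    norm = ((raw - mn) / span).fillna(0.0).clip(0.0, 1.0)
    return FeatureTable(values=norm, norm_params=norm_params.copy())
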