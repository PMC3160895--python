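"""Constrained de-novo peptide design from peptide clusters.

The generator mirrors a four-stage procedure: (i) cluster the labelled
peptides on a local-alignment distance (complete linkage, cut at 0.7);
(ii) keep clusters that are purely positive (size >= 5), purely negative
(size >= 8) or of mixed composition close to the training class balance,
and build a multiple alignment of each; (iii) for every 15-mer member,
derive a motif whose well-conserved positions stay fixed only while no
run of four consecutive fixed residues occurs verbatim in the training
or test sequences, and whose remaining positions vary within their
BLOSUM50-derived amino-acid group and the variation observed in the
alignment column; (iv) enumerate the motifs, drop every sequence that
violates either novelty constraint, score the survivors with the trained
reactivity model, and emit the top-ranked (H), bottom-ranked (L) and
randomly drawn (M) lists.

The two novelty constraints are: no stretch of more than three residues
in common with any training/test sequence (no shared 4-mer), and an
overall identity of at most 5 within any 11-position window against any
training sequence, over every ungapped relative offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .alignment import AlignmentParams, PairwiseScoreMatrix, _aligner, load_matrix
from .core import Candidate, CandidateList, Peptide, PeptideSet, RunConfig, \
    ValidationError
from .core import STANDARD_AA
from .model import TrainedModel, predict_peptides

LOG2_20 = float(np.log2(20.0))


# ---------------------------------------------------------------------------
# amino-acid groups from BLOSUM50

def blosum50_groups(n_groups: int = 8) -> list[str]:
    """Partition of the 20 standard residues by complete-linkage clustering
    of the BLOSUM50 similarity converted to a distance.

    The default 8-group cut recovers familiar chemistry: aromatic (FWY),
    aliphatic (ILMV), basic/amide (EHKQR), DN, hydroxyl (ST), small (AG),
    and C and P on their own.
    """
    m = load_matrix("BLOSUM50")
    S = np.array([[m[a, b] for b in STANDARD_AA] for a in STANDARD_AA], float)
    d = 1.0 - S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    lab = hierarchy.fcluster(Z, n_groups, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for aa, l in zip(STANDARD_AA, lab):
        groups.setdefault(l, []).append(aa)
    return sorted("".join(sorted(v)) for v in groups.values())


DEFAULT_GROUPS = blosum50_groups()


def _group_of(residue: str, groups: list[str]) -> set[str]:
    table = {aa: set(g) for g in groups for aa in g}
    if residue in table:
        return table[residue]
    if residue == "B":
        return table["N"] | table["D"]
    if residue == "Z":
        return table["Q"] | table["E"]
    if residue == "J":
        return table["L"] | table["I"]
    if residue == "X":
        return set(STANDARD_AA)
    raise KeyError(residue)


# ---------------------------------------------------------------------------
# clustering

def distance_matrix(m_local: PairwiseScoreMatrix) -> np.ndarray:
    """Distances d(i,j) = 1 - s(i,j)/sqrt(s(i,i) s(j,j)) from a local-mode
    score matrix; zero on the diagonal, values in [0, 1]."""
    if m_local.mode != "local":
        raise ValidationError("distance_matrix requires a local-mode score matrix")
    s = m_local.scores
    self_scores = np.diagonal(s)
    if np.any(self_scores <= 0):
        raise ValidationError("zero or negative self-alignment score")
    d = 1.0 - s / np.sqrt(np.outer(self_scores, self_scores))
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Cluster:
    """A group of mutually similar peptides with its class composition."""

    members: list[int]
    n_pos: int = 0
    n_neg: int = 0
    type: str = "unselected"  # H, L, M or unselected

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def positive_fraction(self) -> float:
        return self.n_pos / self.size if self.size else 0.0


def cluster_peptides(d: np.ndarray, cutoff: float = 0.7) -> list[Cluster]:
    """Complete-linkage hierarchical clustering cut at ``cutoff``.

    Complete linkage bounds the cluster diameter: within any returned
    cluster, the maximum pairwise distance is <= cutoff.
    """
    n = d.shape[0]
    if n == 1:
        return [Cluster(members=[0])]
    Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    labels = hierarchy.fcluster(Z, t=cutoff, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, l in enumerate(labels):
        clusters.setdefault(l, []).append(i)
    return [Cluster(members=m) for _, m in sorted(clusters.items())]


def select_clusters(clusters: list[Cluster], labels: list[str],
                    train_pos_fraction: float,
                    config: RunConfig | None = None) -> list[Cluster]:
    """Type the clusters: H (all positive, size >= 5), L (all negative,
    size >= 8), M (size >= 5, positive fraction within the tolerance of
    the training class balance); everything else stays unselected."""
    config = config or RunConfig()
    lab = np.asarray(labels)
    for c in clusters:
        member_labels = lab[c.members]
        c.n_pos = int((member_labels == "positive").sum())
        c.n_neg = int((member_labels == "negative").sum())
        if c.n_pos == c.size and c.size >= config.min_h_cluster:
            c.type = "H"
        elif c.n_neg == c.size and c.size >= config.min_l_cluster:
            c.type = "L"
        elif (c.size >= config.min_m_cluster
              and abs(c.positive_fraction - train_pos_fraction) <= config.m_tolerance):
            c.type = "M"
        else:
            c.type = "unselected"
    return clusters


# ---------------------------------------------------------------------------
# multiple alignment and per-column information

@dataclass
class MultipleAlignment:
    """Gapped member sequences of equal length plus per-column information."""

    member_ids: list[str]
    rows: list[str]
    information: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        width = {len(r) for r in self.rows}
        if len(width) != 1:
            raise ValidationError("aligned rows differ in length")
        if self.information is None:
            self.information = np.array(
                [column_information(col) for col in zip(*self.rows)])

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def ungapped(self, k: int) -> str:
        return self.rows[k].replace("-", "")

    def columns_of_row(self, k: int) -> list[int]:
        """Alignment column index of each residue of row ``k``."""
        return [c for c, ch in enumerate(self.rows[k]) if ch != "-"]


def column_information(column) -> float:
    """Sequence-logo information of one alignment column, in bits:
    log2(20) minus the Shannon entropy of the residue frequencies among
    non-gap symbols.  An all-gap column carries 0 bits."""
    residues = [c for c in column if c != "-"]
    if not residues:
        return 0.0
    _, counts = np.unique(residues, return_counts=True)
    freqs = counts / counts.sum()
    entropy = float(-(freqs * np.log2(freqs)).sum())
    return LOG2_20 - entropy


def _merge_star(master_seed: str, rows: list[str], ps: str, pm: str
                ) -> tuple[str, list[str], str]:
    """Merge a new pairwise alignment (gapped seed ``ps``, gapped member
    ``pm``) into the running star alignment, once-a-gap-always-a-gap."""
    out_master: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_new: list[str] = []
    i = j = 0
    while i < len(master_seed) or j < len(ps):
        if i < len(master_seed) and master_seed[i] == "-":
            out_master.append("-")
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_new.append("-")
            i += 1
        elif j < len(ps) and ps[j] == "-":
            out_master.append("-")
            for r in out_rows:
                r.append("-")
            out_new.append(pm[j])
            j += 1
        else:
            out_master.append(master_seed[i])
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_new.append(pm[j])
            i += 1
            j += 1
    return ("".join(out_master), ["".join(r) for r in out_rows], "".join(out_new))


def align_cluster(cluster: Cluster, pset: PeptideSet,
                  params: AlignmentParams | None = None,
                  m_local: PairwiseScoreMatrix | None = None) -> MultipleAlignment:
    """Star-progressive multiple alignment of a cluster.

    The medoid (maximum summed local-alignment score against the other
    members) seeds the star; every other member is pairwise-aligned to
    the seed globally and merged, gaps accumulating monotonically.
    """
    if cluster.size < 2:
        raise ValidationError("align_cluster requires a cluster of size >= 2")
    params = params or AlignmentParams(mode="global")
    members = list(cluster.members)
    seqs = [pset[i].sequence for i in members]
    ids = [pset[i].id for i in members]
    if m_local is not None:
        sub = m_local.scores[np.ix_(members, members)]
    else:
        local = _aligner(AlignmentParams(params.matrix, params.gap_open,
                                         params.gap_extend, "local"))
        sub = np.array([[local.score(a, b) for b in seqs] for a in seqs])
    sums = sub.sum(axis=1)
    medoid = int(np.argmax(sums))  # ties: lowest index

    global_aligner = _aligner(AlignmentParams(params.matrix, params.gap_open,
                                              params.gap_extend, "global"))
    order = [medoid] + [k for k in range(len(members)) if k != medoid]
    master_seed = seqs[medoid]
    rows: list[str] = []
    for k in order[1:]:
        aln = global_aligner.align(seqs[medoid], seqs[k])[0]
        ps, pm = str(aln[0]), str(aln[1])
        master_seed, rows, new_row = _merge_star(master_seed, rows, ps, pm)
        rows.append(new_row)
    all_rows = [master_seed] + rows
    out_ids = [ids[k] for k in order]
    # restore the input member order for reproducible downstream iteration
    reorder = sorted(range(len(order)), key=lambda k: order[k])
    return MultipleAlignment(member_ids=[out_ids[k] for k in reorder],
                             rows=[all_rows[k] for k in reorder])


# ---------------------------------------------------------------------------
# motifs

@dataclass
class Motif:
    """A length-15 positional pattern: fixed residues where the cluster is
    conserved and novelty allows, residue sets elsewhere."""

    source_id: str
    cluster_type: str
    fixed: list[str | None]            # residue or None per position
    allowed: list[frozenset[str]]      # singleton for fixed positions
    valid: bool = True

    @property
    def length(self) -> int:
        return len(self.allowed)

    def n_sequences(self) -> int:
        out = 1
        for s in self.allowed:
            out *= len(s)
        return out


def build_kmer_index(*sets: PeptideSet, k: int = 4) -> frozenset[str]:
    """All k-mers occurring in the given peptide sets (novelty constraint 1
    is defined over the union of training and test sequences)."""
    kmers = set()
    for pset in sets:
        if pset is None:
            continue
        for p in pset:
            s = p.sequence
            for i in range(len(s) - k + 1):
                kmers.add(s[i:i + k])
    return frozenset(kmers)


def _fixed_run_violates(seq: str, fixed: list[bool], kmer_index: frozenset[str],
                        k: int = 4) -> bool:
    for w in range(len(seq) - k + 1):
        if all(fixed[w:w + k]) and seq[w:w + k] in kmer_index:
            return True
    return False


def _fixed_window_exceeds(fixed: list[bool], max_identities: int,
                          window: int) -> bool:
    """Fixed residues are guaranteed identities against the source peptide,
    so no identity window may ever hold more than the allowed count."""
    n = len(fixed)
    w = min(window, n)
    return any(sum(fixed[i:i + w]) > max_identities for i in range(n - w + 1))


def extract_motif(row: int, msa: MultipleAlignment, kmer_index: frozenset[str],
                  groups: list[str] | None = None, source_id: str = "",
                  cluster_type: str = "", motif_length: int = 15,
                  max_identities: int | None = None,
                  identity_window: int = 11) -> Motif:
    """Derive the motif of one (ungapped) 15-mer cluster member.

    Positions are visited in decreasing order of the information of
    their alignment column (ties: ascending position) and fixed greedily;
    a position stays variable whenever fixing it would complete a run of
    four consecutive fixed residues that occurs in the k-mer index, or —
    when ``max_identities`` is set — would put more than that many fixed
    residues into some ``identity_window``-stretch (fixed residues are
    certain identities against the source peptide, so such a motif could
    never yield a candidate passing the identity constraint; the
    generation pipeline enables this budget).
    Variable positions may take any residue of the original residue's
    BLOSUM50 group or any residue observed in the alignment column,
    minus choices that re-create an indexed 4-mer together with the
    flanking fixed residues.  If that pruning empties a position (the
    index saturates its variant neighbourhood), the least-conserved fixed
    neighbour within k-mer reach is released and the sets recomputed, so
    every returned allowed set is non-empty.
    """
    groups = groups or DEFAULT_GROUPS
    seq = msa.ungapped(row)
    if len(seq) != motif_length:
        raise ValidationError(
            f"motifs are derived from {motif_length}-mers, got length {len(seq)}")
    cols = msa.columns_of_row(row)
    info = msa.information[cols]
    order = sorted(range(len(seq)), key=lambda p: (-info[p], p))

    fixed = [False] * len(seq)
    for p in order:
        fixed[p] = True
        if (_fixed_run_violates(seq, fixed, kmer_index)
                or (max_identities is not None
                    and _fixed_window_exceeds(fixed, max_identities,
                                              identity_window))):
            fixed[p] = False

    def allowed_at(p: int) -> frozenset[str]:
        column = [r[cols[p]] for r in msa.rows]
        observed = {c for c in column if c in STANDARD_AA}
        pool = _group_of(seq[p], groups) | observed
        return frozenset(r for r in pool
                         if not _reintroduces_kmer(seq, fixed, p, r, kmer_index))

    k = 4
    while True:
        empty = [p for p in range(len(seq)) if not fixed[p] and not allowed_at(p)]
        if not empty:
            break
        p = empty[0]
        neighbours = [q for q in range(max(0, p - k + 1), min(len(seq), p + k))
                      if fixed[q]]
        # always non-empty: with no fixed neighbour in k-mer reach nothing
        # is pruned and the pool itself is non-empty
        q = min(neighbours, key=lambda q: (info[q], -abs(q - p)))
        fixed[q] = False

    allowed = [frozenset(seq[p]) if fixed[p] else allowed_at(p)
               for p in range(len(seq))]
    return Motif(source_id=source_id, cluster_type=cluster_type,
                 fixed=[seq[p] if f else None for p, f in enumerate(fixed)],
                 allowed=allowed, valid=True)


def _reintroduces_kmer(seq: str, fixed: list[bool], p: int, residue: str,
                       kmer_index: frozenset[str], k: int = 4) -> bool:
    """Would placing ``residue`` at variable position ``p`` complete an
    indexed k-mer with the surrounding *fixed* residues?"""
    for w in range(max(0, p - k + 1), min(p, len(seq) - k) + 1):
        positions = range(w, w + k)
        if all(fixed[q] or q == p for q in positions):
            kmer = "".join(residue if q == p else seq[q] for q in positions)
            if kmer in kmer_index:
                return True
    return False


def enumerate_candidates(motif: Motif, cap: int = 100_000,
                         rng: np.random.Generator | None = None) -> list[str]:
    """Expand a motif into concrete sequences.

    Full Cartesian expansion when the product of the allowed sets is
    within ``cap``; otherwise a seeded uniform sample of ``cap`` distinct
    sequences from the product space.
    """
    if not motif.valid:
        return []
    sets = [sorted(s) for s in motif.allowed]
    total = motif.n_sequences()
    if total <= cap:
        return ["".join(t) for t in itertools.product(*sets)]
    rng = rng or np.random.default_rng(0)
    out: set[str] = set()
    max_tries = cap * 50
    tries = 0
    while len(out) < cap and tries < max_tries:
        out.add("".join(s[rng.integers(len(s))] for s in sets))
        tries += 1
    return sorted(out)


# ---------------------------------------------------------------------------
# novelty constraints

@dataclass(frozen=True)
class NoveltyIndex:
    """Pre-indexed reference sequences for the two novelty constraints:
    a 4-mer index over training *and* test sequences (constraint 1) and
    the raw training sequences (constraint 2).

    Training sequences are also held as a zero-padded byte matrix so the
    identity-window scan vectorizes over the whole set (the pad byte
    never matches a residue, so it cannot add identities).
    """

    kmers: frozenset[str]
    train_sequences: tuple[str, ...]
    _padded: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @classmethod
    def build(cls, train: PeptideSet, test: PeptideSet | None = None
              ) -> "NoveltyIndex":
        seqs = tuple(train.sequences)
        width = max(len(s) for s in seqs)
        padded = np.zeros((len(seqs), width), dtype=np.uint8)
        for i, s in enumerate(seqs):
            padded[i, :len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
        return cls(kmers=build_kmer_index(train, test), train_sequences=seqs,
                   _padded=padded)

    def max_identity_in_window(self, seq: str, window: int = 11) -> int:
        """Max positional identity of ``seq`` against any training sequence
        within any length-``window`` stretch, over all ungapped offsets."""
        av = np.frombuffer(seq.encode(), dtype=np.uint8)
        la = len(av)
        T = self._padded
        lb = T.shape[1]
        best = 0
        for off in range(-(la - 1), lb):
            lo = max(0, -off)
            hi = min(la, lb - off)
            if hi <= lo:
                continue
            matches = (av[lo:hi] == T[:, lo + off:hi + off]).astype(np.int32)
            L = hi - lo
            if L <= window:
                best = max(best, int(matches.sum(axis=1).max()))
            else:
                cs = np.cumsum(matches, axis=1)
                win = cs[:, window - 1:].copy()
                win[:, 1:] -= cs[:, :-window]
                best = max(best, int(win.max()))
        return best


def novelty_filter(seq: str, index: NoveltyIndex,
                   config: RunConfig | None = None) -> tuple[bool, str | None]:
    """Check a candidate against both novelty constraints.

    Returns ``(True, None)`` on pass, else ``(False, reason)``.
    """
    config = config or RunConfig()
    k = config.max_common_stretch + 1
    for i in range(len(seq) - k + 1):
        if seq[i:i + k] in index.kmers:
            return False, f"shared {k}-mer {seq[i:i + k]!r} with the reference sets"
    ident = index.max_identity_in_window(seq, config.identity_window)
    if ident > config.max_identities:
        return False, (f"identity {ident} > {config.max_identities} within a "
                       f"{config.identity_window}-window against a training peptide")
    return True, None


# ---------------------------------------------------------------------------
# ranking and the end-to-end pipeline

def rank_and_select(pools: dict[str, list[tuple[str, float]]],
                    counts: dict[str, int] | int = 1100,
                    rng: np.random.Generator | None = None) -> CandidateList:
    """Assemble the final list: top-ranked from the positive-cluster pool
    (H), bottom-ranked from the negative-cluster pool (L), and a seeded
    uniform draw from the mixed-cluster pool (M).

    Ties in predicted reactivity break by sequence lexicographic order.
    """
    rng = rng or np.random.default_rng(0)
    if isinstance(counts, int):
        counts = {"H": counts, "L": counts, "M": counts}
    out: list[Candidate] = []
    for cls in ("H", "L", "M"):
        want = counts.get(cls, 0)
        if want == 0:
            continue
        pool = pools.get(cls, [])
        if len(pool) < want:
            raise ValidationError(
                f"class {cls}: pool of {len(pool)} candidates < requested {want}")
        if cls == "H":
            chosen = sorted(pool, key=lambda t: (-t[1], t[0]))[:want]
        elif cls == "L":
            chosen = sorted(pool, key=lambda t: (t[1], t[0]))[:want]
        else:
            ordered = sorted(pool, key=lambda t: t[0])
            idx = rng.choice(len(ordered), size=want, replace=False)
            chosen = [ordered[i] for i in sorted(idx)]
        out.extend(Candidate(id=f"{cls}{i + 1:05d}", sequence=s,
                             predicted_reactivity=float(pr), cls=cls)
                   for i, (s, pr) in enumerate(chosen))
    return CandidateList(out)


@dataclass
class GenerationReport:
    """Per-cluster summary of a generation run."""

    clusters: list[Cluster]
    n_motifs: dict[str, int]
    pool_sizes: dict[str, int]

    def selected(self) -> dict[str, int]:
        out = {"H": 0, "L": 0, "M": 0, "unselected": 0}
        for c in self.clusters:
            out[c.type] += 1
        return out


def generate(train: PeptideSet, model: TrainedModel, norm_params: pd.DataFrame,
             m_local: PairwiseScoreMatrix, test: PeptideSet | None = None,
             config: RunConfig | None = None,
             counts: dict[str, int] | int | None = None,
             max_pool_per_class: int | None = None
             ) -> tuple[CandidateList, GenerationReport]:
    """Run the full de-novo pipeline against a trained model.

    ``m_local`` is the local-mode all-vs-all score matrix of the training
    set (reused from model training).  ``counts`` sets the per-class list
    sizes (default: the configured selection count for every class);
    ``max_pool_per_class`` optionally subsamples each candidate pool
    before the (quadratic-cost) model scoring step.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    if counts is None:
        counts = config.selection_count

    dist = distance_matrix(m_local)
    clusters = cluster_peptides(dist, config.cluster_cutoff)
    select_clusters(clusters, train.labels, train.positive_fraction(), config)

    index = NoveltyIndex.build(train, test)
    kmer_index = index.kmers
    align_params = AlignmentParams(config.substitution_matrix, config.gap_open,
                                   config.gap_extend, "global")

    pool_cap = max_pool_per_class
    pools: dict[str, set[str]] = {"H": set(), "L": set(), "M": set()}
    n_motifs = {"H": 0, "L": 0, "M": 0}
    for cluster in clusters:
        if cluster.type == "unselected" or cluster.size < 2:
            continue
        if pool_cap is not None and len(pools[cluster.type]) >= pool_cap:
            continue
        msa = align_cluster(cluster, train, align_params, m_local)
        for row in range(cluster.size):
            if len(msa.ungapped(row)) != 15:
                continue
            motif = extract_motif(row, msa, kmer_index,
                                  source_id=msa.member_ids[row],
                                  cluster_type=cluster.type,
                                  max_identities=config.max_identities,
                                  identity_window=config.identity_window)
            if not motif.valid:
                continue
            n_motifs[cluster.type] += 1
            pool = pools[cluster.type]
            # oversample the remaining need: the novelty filter will thin out
            cap = config.enumeration_cap
            if pool_cap is not None:
                cap = min(cap, max(1, (pool_cap - len(pool)) * 4))
            for seq in enumerate_candidates(motif, cap, rng):
                ok, _ = novelty_filter(seq, index, config)
                if ok:
                    pool.add(seq)
                if pool_cap is not None and len(pool) >= pool_cap:
                    break
            if pool_cap is not None and len(pool) >= pool_cap:
                break

    scored: dict[str, list[tuple[str, float]]] = {}
    for cls, seqs in pools.items():
        ordered = sorted(seqs)
        if not ordered:
            scored[cls] = []
            continue
        qset = PeptideSet([Peptide(f"q{cls}{i}", s) for i, s in enumerate(ordered)],
                          strict=False)
        probs = predict_peptides(qset, train, model, norm_params, config)
        scored[cls] = list(zip(ordered, probs.tolist()))

    clist = rank_and_select(scored, counts, rng)
    report = GenerationReport(clusters=clusters, n_motifs=n_motifs,
                              pool_sizes={c: len(v) for c, v in scored.items()})
    return clist, report
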