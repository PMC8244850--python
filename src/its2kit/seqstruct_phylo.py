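"""Sequence and sequence-structure alignment, distances, trees, barcode gap.

The phylogenetic layer works on two kinds of alignment:

* plain DNA multiple alignment (progressive profile-profile alignment on a
  k-mer guide tree with one remove-and-realign refinement round, affine
  gaps), used for the ITS region;
* sequence-structure alignment over a 12-letter alphabet (4 bases x
  {unpaired, opening-paired, closing-paired}), where the scoring combines
  a sequence match term with a structure-state agreement term weighted by
  the structure weight (defaults follow the published sequence-structure
  alignment parameters: structure weight 200, indel open -800, extend -50,
  match 50 / mismatch 0).

Distances: Kimura two-parameter (with optional discrete-gamma correction)
and the log-determinant (Tamura-Kumar style) distance robust to base
composition heterogeneity; both use pairwise deletion of gap/ambiguous
columns and flag saturated pairs (returned as NaN, masked in matrices).

Trees: deterministic neighbor-joining (ties broken by smallest taxon index
pair, negative branch lengths clamped to zero), Felsenstein pruning
log-likelihood under K2P/TN93 with a discrete gamma rate mixture,
one-dimensional branch-length optimization, and nonparametric bootstrap
supports from column resampling.  The barcode-gap report compares maximum
within-group to minimum between-group distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import expm
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

__all__ = [
    "AlignParams",
    "SeqStructAlignParams",
    "RateModel",
    "Alignment",
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "GapReport",
    "msa",
    "encode_seqstruct",
    "decode_seqstruct",
    "seqstruct_align",
    "k2p_distance",
    "logdet_distance",
    "distance_matrix",
    "group_mean_distances",
    "nj_tree",
    "tree_likelihood",
    "optimize_branch_lengths",
    "estimate_gamma_shape",
    "nj_bootstrap",
    "bootstrap_supports",
]


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class AlignParams:
    """Plain-DNA progressive alignment scoring (match/transition/transversion
    with affine gap costs on the same scale)."""

    match: float = 1.0
    transition: float = -0.6
    transversion: float = -1.0
    gap_open: float = 1.53
    gap_extend: float = 0.123
    refine: bool = True

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0 on the cost scale")


@dataclass
class SeqStructAlignParams:
    """Sequence-structure alignment scoring (published defaults)."""

    structure_weight: float = 200.0
    indel_open: float = 800.0       # cost scale (printed as -800)
    indel_extend: float = 50.0
    match: float = 50.0
    mismatch: float = 0.0
    ribosum_mismatch: float = -100.0  # RIBOSUM-style penalty, paired states
    paired_vs_paired: float = 0.25    # open-vs-close partial credit
    refine: bool = True

    def __post_init__(self) -> None:
        if self.indel_open < 0 or self.indel_extend < 0:
            raise ValueError("gap penalties must be >= 0 on the cost scale")


@dataclass
class RateModel:
    """Substitution model for distances and likelihoods."""

    model: str = "K2P"              # K2P | TN93
    alpha: float | None = 5.0       # gamma shape; None = homogeneous rates
    categories: int = 4
    kappa: float = 2.0              # K2P ts/tv rate ratio (likelihood only)

    def __post_init__(self) -> None:
        if self.model not in ("K2P", "TN93"):
            raise ValueError("model must be K2P or TN93")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be > 0")


# ---------------------------------------------------------------------------
# Alignment containers and the progressive aligner


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must have equal length")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)]

    def degapped(self) -> list[str]:
        return [r.replace("-", "") for r in self.rows]

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(
            ids=list(self.ids),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )


_DNA_AB = "ACGT-"


def _dna_subst(params: AlignParams) -> tuple[str, np.ndarray]:
    ab = _DNA_AB
    n = len(ab)
    S = np.zeros((n, n))
    purines = {"A", "G"}
    for i, a in enumerate(ab[:4]):
        for j, b in enumerate(ab[:4]):
            if a == b:
                S[i, j] = params.match
            elif (a in purines) == (b in purines):
                S[i, j] = params.transition
            else:
                S[i, j] = params.transversion
    return ab, S


@njit(cache=True)
def _gotoh(sc, go, ge):
    """Profile-profile affine-gap DP; returns (M, Ix, Iy) score tables."""
    n, m = sc.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in B (consume A row)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -go - ge * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = -go - ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = best + sc[i - 1, j - 1]
            a = M[i - 1, j] - go
            b = Ix[i - 1, j] - ge
            Ix[i, j] = a if a > b else b
            a = M[i, j - 1] - go
            b = Iy[i, j - 1] - ge
            Iy[i, j] = a if a > b else b
    return M, Ix, Iy


def _profile(rows: list[str], ab: str) -> np.ndarray:
    idx = {c: i for i, c in enumerate(ab)}
    L = len(rows[0])
    out = np.zeros((L, len(ab)))
    for r in rows:
        for c, ch in enumerate(r):
            k = idx.get(ch)
            if k is not None:
                out[c, k] += 1.0
    return out / len(rows)


def _align_profiles(
    rows_a: list[str], rows_b: list[str], ab: str, S: np.ndarray,
    go: float, ge: float,
) -> tuple[list[str], list[str], float]:
    fa = _profile(rows_a, ab)
    fb = _profile(rows_b, ab)
    sc = fa @ S @ fb.T
    M, Ix, Iy = _gotoh(sc, go, ge)
    i, j = sc.shape
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    score = float(max(M[i, j], Ix[i, j], Iy[i, j]))
    path: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            path.append("y"); j -= 1; continue
        if j == 0:
            path.append("x"); i -= 1; continue
        if state == 0:
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            path.append("m")
            if abs(M[i - 1, j - 1] - prev) < eps:
                state = 0
            elif abs(Ix[i - 1, j - 1] - prev) < eps:
                state = 1
            else:
                state = 2
            i -= 1; j -= 1
        elif state == 1:
            path.append("x")
            state = 0 if abs(M[i - 1, j] - go - Ix[i, j]) < eps else 1
            i -= 1
        else:
            path.append("y")
            state = 0 if abs(M[i, j - 1] - go - Iy[i, j]) < eps else 2
            j -= 1
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for step in path:
        if step in "mx":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if step in "my":
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b, score


def _kmer_distance(seqs: list[str], k: int = 6) -> np.ndarray:
    sets = [set(s[i : i + k] for i in range(max(len(s) - k + 1, 1))) for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j])) or 1
            D[i, j] = D[j, i] = 1.0 - shared / denom
    return D


def _upgma_order(D: np.ndarray) -> list[tuple[list[int], list[int]]]:
    """UPGMA merge schedule (lists of leaf indices), deterministic."""
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[list[int], list[int]]] = []
    nxt = n
    while len(clusters) > 1:
        (a, b), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((clusters[a], clusters[b]))
        merged = clusters[a] + clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        del clusters[a], clusters[b]
        new_d = {}
        for c in clusters:
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            new_d[c] = (na * dist[key_a] + nb * dist[key_b]) / (na + nb)
        dist = {
            (i, j): v
            for (i, j), v in dist.items()
            if i not in (a, b) and j not in (a, b)
        }
        for c, v in new_d.items():
            dist[(min(c, nxt), max(c, nxt))] = v
        clusters[nxt] = merged
        nxt += 1
    return merges


def _strip_all_gap(rows: list[str]) -> list[str]:
    if not rows:
        return rows
    keep = [c for c in range(len(rows[0])) if any(r[c] != "-" for r in rows)]
    return ["".join(r[c] for c in keep) for r in rows]


def _progressive(
    seqs: list[str], ab: str, S: np.ndarray, go: float, ge: float, refine: bool
) -> list[str]:
    if len(seqs) == 1:
        return list(seqs)
    merges = _upgma_order(_kmer_distance(seqs))
    aligned: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [s]) for i, s in enumerate(seqs)
    }
    key = len(seqs)
    group_of = {i: i for i in range(len(seqs))}
    for left, right in merges:
        ga, gb = group_of[left[0]], group_of[right[0]]
        ids_a, rows_a = aligned.pop(ga)
        ids_b, rows_b = aligned.pop(gb)
        out_a, out_b, _ = _align_profiles(rows_a, rows_b, ab, S, go, ge)
        ids = ids_a + ids_b
        aligned[key] = (ids, out_a + out_b)
        for i in ids:
            group_of[i] = key
        key += 1
    ids, rows = next(iter(aligned.values()))
    order = np.argsort(ids)
    rows = [rows[k] for k in order]
    if refine and len(rows) > 2:
        for i in range(len(rows)):
            rest = _strip_all_gap(rows[:i] + rows[i + 1 :])
            solo = rows[i].replace("-", "")
            out_rest, out_solo, _ = _align_profiles(rest, [solo], ab, S, go, ge)
            rows = out_rest[:i] + out_solo + out_rest[i:]
    return rows


def msa(records, params: AlignParams | None = None) -> Alignment:
    """Progressive multiple alignment of DNA records.

    *records* may be :class:`~its2kit.sequence_io.SeqRecord` objects or
    (id, seq) pairs.  Deterministic given the input order.  A single record
    passes through with a warning.
    """
    import warnings

    params = params or AlignParams()
    pairs = [
        (r.id, r.seq) if hasattr(r, "seq") else (r[0], r[1]) for r in records
    ]
    if not pairs:
        raise ValueError("no records to align")
    if len(pairs) == 1:
        warnings.warn("single record: alignment is a passthrough", stacklevel=2)
        return Alignment(ids=[pairs[0][0]], rows=[pairs[0][1]])
    ab, S = _dna_subst(params)
    rows = _progressive(
        [s for _, s in pairs], ab, S, params.gap_open, params.gap_extend,
        params.refine,
    )
    return Alignment(ids=[i for i, _ in pairs], rows=rows)


# ---------------------------------------------------------------------------
# Sequence-structure encoding and alignment

_OPEN = {"A": "a", "C": "c", "G": "g", "U": "u"}
_CLOSE = {"A": "B", "C": "D", "G": "H", "U": "V"}
_DECODE = (
    {v: (k, "(") for k, v in _OPEN.items()}
    | {v: (k, ")") for k, v in _CLOSE.items()}
    | {b: (b, ".") for b in "ACGU"}
)
SS_ALPHABET = "ACGUacguBDHV"


def encode_seqstruct(seq: str, structure) -> str:
    """Encode (sequence, dot-bracket) into the 12-letter alphabet."""
    db = structure.structure if hasattr(structure, "structure") else structure
    rna = seq.upper().replace("T", "U")
    if len(rna) != len(db):
        raise ValueError("sequence and structure lengths differ")
    out = []
    for base, state in zip(rna, db):
        if base not in "ACGU":
            raise ValueError(f"non-RNA symbol {base!r}")
        if state == "(":
            out.append(_OPEN[base])
        elif state == ")":
            out.append(_CLOSE[base])
        elif state == ".":
            out.append(base)
        else:
            raise ValueError(f"bad structure symbol {state!r}")
    return "".join(out)


def decode_seqstruct(encoded: str) -> tuple[str, str]:
    """Inverse of :func:`encode_seqstruct`; gaps pass through."""
    seq, db = [], []
    for ch in encoded:
        if ch == "-":
            seq.append("-")
            db.append("-")
        else:
            b, s = _DECODE[ch]
            seq.append(b)
            db.append(s)
    return "".join(seq), "".join(db)


def _ss_subst(params: SeqStructAlignParams) -> tuple[str, np.ndarray]:
    ab = SS_ALPHABET + "-"
    n = len(ab)
    S = np.zeros((n, n))
    for i, x in enumerate(SS_ALPHABET):
        bx, sx = _DECODE[x]
        for j, y in enumerate(SS_ALPHABET):
            by, sy = _DECODE[y]
            if bx == by:
                seq_term = params.match
            elif sx != "." and sy != ".":
                # Base change inside a helix: RIBOSUM-style negative score.
                seq_term = params.ribosum_mismatch
            else:
                seq_term = params.mismatch
            if sx == sy:
                struct = 1.0
            elif sx != "." and sy != ".":
                struct = params.paired_vs_paired
            else:
                struct = 0.0
            S[i, j] = seq_term + params.structure_weight * struct
    return ab, S


def seqstruct_align(
    encoded, params: SeqStructAlignParams | None = None
) -> Alignment:
    """Progressive global alignment of 12-letter sequence-structure strings.

    *encoded* is a sequence of (id, encoded_string) pairs.  Mixing encoded
    and plain-DNA inputs is rejected.
    """
    params = params or SeqStructAlignParams()
    pairs = [(r[0], r[1]) for r in encoded]
    if len(pairs) < 2:
        raise ValueError("need at least two encoded records")
    for rid, s in pairs:
        if not set(s) <= set(SS_ALPHABET):
            raise ValueError(f"record {rid!r} is not a 12-letter encoding")
    ab, S = _ss_subst(params)
    rows = _progressive(
        [s for _, s in pairs], ab, S, params.indel_open, params.indel_extend,
        params.refine,
    )
    return Alignment(ids=[i for i, _ in pairs], rows=rows)


# ---------------------------------------------------------------------------
# Distances

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _encode_row(row: str) -> np.ndarray:
    """DNA row (possibly from a decoded seq-struct alignment) to int codes,
    -1 for gap/ambiguous."""
    up = row.upper().replace("U", "T")
    return np.array([_BASE_IDX.get(c, -1) for c in up], dtype=np.int64)


def pair_site_categories(row_a: str, row_b: str) -> np.ndarray:
    """Per-column joint category 4*a+b in 0..15, or 16 for excluded sites."""
    a, b = _encode_row(row_a), _encode_row(row_b)
    if a.size != b.size:
        raise ValueError("rows must be aligned (equal length)")
    cat = np.where((a >= 0) & (b >= 0), 4 * a + b, 16)
    return cat


def _joint_freq(cat: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    counts = np.bincount(cat, weights=weights, minlength=17)[:16]
    total = counts.sum()
    if total == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return counts.reshape(4, 4) / total


_TS_MASK = np.zeros((4, 4), dtype=bool)  # A<->G, C<->T
_TS_MASK[0, 2] = _TS_MASK[2, 0] = _TS_MASK[1, 3] = _TS_MASK[3, 1] = True
_DIFF_MASK = ~np.eye(4, dtype=bool)


def _gamma_stretch(x: float, alpha: float | None, coef: float) -> float:
    """-coef*ln(x) or its discrete-gamma analogue coef*alpha*(x^(-1/alpha)-1)."""
    if alpha is None or not math.isfinite(alpha):
        return -coef * math.log(x)
    return coef * alpha * (x ** (-1.0 / alpha) - 1.0)


def k2p_from_freq(F: np.ndarray, alpha: float | None = None) -> float:
    P = float(F[_TS_MASK].sum())
    Q = float(F[_DIFF_MASK].sum() - P)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan  # saturated
    return _gamma_stretch(w1, alpha, 0.5) + _gamma_stretch(w2, alpha, 0.25)


def logdet_from_freq(F: np.ndarray, alpha: float | None = None) -> float:
    fa = F.sum(axis=1)
    fb = F.sum(axis=0)
    det = float(np.linalg.det(F))
    if det <= 0.0 or np.any(fa <= 0.0) or np.any(fb <= 0.0):
        return math.nan  # saturated / singular
    d = -0.25 * (math.log(det) - 0.5 * float(np.log(fa).sum() + np.log(fb).sum()))
    d = max(d, 0.0) + 0.0  # clamp tiny negative round-off (and -0.0) to 0
    if alpha is None or not math.isfinite(alpha):
        return d
    return alpha * (math.exp(d / alpha) - 1.0)


def k2p_distance(row_a: str, row_b: str, rate: RateModel | None = None) -> float:
    """Kimura two-parameter distance between two aligned rows.

    Gap/ambiguous columns are pairwise-deleted; returns NaN on saturation
    (the log arguments leaving their domain).  With a finite gamma shape in
    *rate* the discrete-gamma-corrected form is used.
    """
    alpha = rate.alpha if rate is not None else None
    return k2p_from_freq(_joint_freq(pair_site_categories(row_a, row_b)), alpha)


def logdet_distance(row_a: str, row_b: str, rate: RateModel | None = None) -> float:
    """Log-det (Tamura-Kumar style) distance between two aligned rows.

    Based on the determinant of the pairwise joint-frequency matrix with
    the marginal-frequency correction; NaN when the joint matrix is
    singular.  A finite gamma shape applies the distance-level stretch
    alpha*(exp(d/alpha)-1).
    """
    alpha = rate.alpha if rate is not None else None
    return logdet_from_freq(_joint_freq(pair_site_categories(row_a, row_b)), alpha)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    se: np.ndarray | None = None
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")

    @property
    def saturated(self) -> np.ndarray:
        return np.isnan(self.matrix)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def distance_matrix(
    aln: Alignment,
    method: str = "logdet",
    rate: RateModel | None = None,
    labels: dict[str, str] | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix from an alignment (zero diagonal, symmetric)."""
    fn = {"k2p": k2p_from_freq, "logdet": logdet_from_freq}[method]
    alpha = rate.alpha if rate is not None else None
    n = len(aln)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        cat = pair_site_categories(aln.rows[i], aln.rows[j])
        D[i, j] = D[j, i] = fn(_joint_freq(cat), alpha)
    return DistanceMatrix(ids=list(aln.ids), matrix=D, labels=dict(labels or {}))


@dataclass
class GapReport:
    """Barcode-gap summary: per-pair between means, per-group max within."""

    between: pd.DataFrame            # group_i, group_j, mean, se
    max_intra: dict[str, float]
    min_inter: float
    max_intra_overall: float
    barcode_gap: bool


def group_mean_distances(
    aln: Alignment,
    labels: dict[str, str],
    method: str = "logdet",
    rate: RateModel | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> tuple[DistanceMatrix, GapReport]:
    """Between-group mean distances with column-bootstrap SEs + gap report.

    The between-group mean averages over all cross pairs; its SE resamples
    alignment columns (*bootstrap_reps* replicates, seeded).  The
    barcode-gap flag is ``min inter-pair distance > max intra-pair
    distance`` over the pairwise matrix (saturated pairs excluded).
    """
    if not set(aln.ids) <= set(labels):
        raise ValueError("labels must cover every aligned id")
    fn = {"k2p": k2p_from_freq, "logdet": logdet_from_freq}[method]
    alpha = rate.alpha if rate is not None else None
    n = len(aln)
    groups = [labels[i] for i in aln.ids]
    group_names = [g for g in dict.fromkeys(groups)]
    pair_cats = {}
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        cat = pair_site_categories(aln.rows[i], aln.rows[j])
        pair_cats[(i, j)] = cat
        D[i, j] = D[j, i] = fn(_joint_freq(cat), alpha)
    dm = DistanceMatrix(ids=list(aln.ids), matrix=D,
                        labels={i: labels[i] for i in aln.ids})

    pair_group: dict[tuple[int, int], tuple[str, str] | None] = {}
    for (i, j) in pair_cats:
        ga, gb = groups[i], groups[j]
        if ga == gb:
            pair_group[(i, j)] = None
        else:
            a, b = sorted(
                (ga, gb), key=lambda g: group_names.index(g)
            )
            pair_group[(i, j)] = (a, b)

    def between_means(weights: np.ndarray | None) -> dict[tuple[str, str], float]:
        acc: dict[tuple[str, str], list[float]] = {
            k: [] for k in combinations(group_names, 2)
        }
        for key, cat in pair_cats.items():
            gp = pair_group[key]
            if gp is None:
                continue
            d = fn(_joint_freq(cat, weights), alpha)
            if not math.isnan(d):
                acc[gp].append(d)
        return {
            k: (float(np.mean(v)) if v else math.nan) for k, v in acc.items()
        }

    point = between_means(None)
    rng = np.random.default_rng(seed)
    L = aln.n_columns
    reps: dict[tuple[str, str], list[float]] = {k: [] for k in point}
    for _ in range(bootstrap_reps):
        cols = rng.integers(0, L, size=L)
        weights = np.bincount(cols, minlength=L).astype(float)
        est = between_means(weights)
        for k, v in est.items():
            if not math.isnan(v):
                reps[k].append(v)
    rows = []
    for (ga, gb), mean in point.items():
        se = float(np.std(reps[(ga, gb)], ddof=1)) if len(reps[(ga, gb)]) > 1 else 0.0
        rows.append({"group_i": ga, "group_j": gb, "mean": mean, "se": se})
    between = pd.DataFrame(rows)

    intra_vals: dict[str, list[float]] = {g: [] for g in group_names}
    inter_vals: list[float] = []
    for (i, j) in combinations(range(n), 2):
        d = D[i, j]
        if math.isnan(d):
            continue
        if groups[i] == groups[j]:
            intra_vals[groups[i]].append(d)
        else:
            inter_vals.append(d)
    max_intra = {
        g: (max(v) if v else 0.0) for g, v in intra_vals.items()
    }
    max_intra_overall = max(max_intra.values()) if max_intra else 0.0
    min_inter = min(inter_vals) if inter_vals else math.inf
    return dm, GapReport(
        between=between,
        max_intra=max_intra,
        min_inter=min_inter,
        max_intra_overall=max_intra_overall,
        barcode_gap=bool(min_inter > max_intra_overall),
    )


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def tip_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf()]


@dataclass
class Tree:
    """Unrooted tree (stored rooted at a trifurcation), with supports."""

    root: TreeNode
    log_likelihood: float | None = None
    negative_clamped: bool = False

    def tips(self) -> list[str]:
        return self.root.tip_names()

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the canonical tip-name side."""
        all_tips = frozenset(self.tips())
        ref = min(all_tips)
        out = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(node.tip_names())
            if len(side) < 2 or len(all_tips - side) < 2:
                continue
            out.add(side if ref not in side else all_tips - side)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        return [
            n for n in self.root.walk()
            if n is not self.root and not n.is_leaf()
        ]


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining with the standard Q criterion.

    Deterministic: Q ties are broken by the smallest (i, j) taxon index
    pair; negative branch lengths are clamped to zero and flagged.
    """
    D = np.array(dm.matrix, dtype=float)
    if np.any(~np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    clamped = False
    while len(active) > 3:
        m = len(active)
        sums = {a: sum(D[a, b] for b in active if b != a) for a in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                a, b = active[ai], active[bi]
                q = (m - 2) * D[a, b] - sums[a] - sums[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * D[a, b] + (sums[a] - sums[b]) / (2 * (m - 2))
        lb = D[a, b] - la
        if la < 0 or lb < 0:
            clamped = True
        la, lb = max(la, 0.0), max(lb, 0.0)
        nodes[a].length, nodes[b].length = la, lb
        parent = TreeNode(children=[nodes[a], nodes[b]])
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for c in active:
            if c in (a, b):
                continue
            D[u, c] = D[c, u] = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        nodes.append(parent)
        active = [c for c in active if c not in (a, b)] + [u]
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    if min(la, lb, lc) < 0:
        clamped = True
    nodes[a].length, nodes[b].length, nodes[c].length = (
        max(la, 0.0), max(lb, 0.0), max(lc, 0.0),
    )
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, negative_clamped=clamped)


# ---------------------------------------------------------------------------
# Likelihood (Felsenstein pruning, discrete gamma)


def _rate_matrix(rate: RateModel, freqs: np.ndarray) -> np.ndarray:
    if rate.model == "K2P":
        freqs = np.full(4, 0.25)
    kappa = rate.kappa
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            r = kappa if _TS_MASK[i, j] else 1.0
            Q[i, j] = r * freqs[j]
    Q[np.diag_indices(4)] = -Q.sum(axis=1)
    scale = -float(np.dot(freqs, np.diag(Q)))
    return Q / scale


def _gamma_rates(alpha: float | None, k: int) -> np.ndarray:
    if alpha is None or not math.isfinite(alpha):
        return np.ones(1)
    # Median discretization, normalized to mean 1.
    qs = (2 * np.arange(k) + 1) / (2 * k)
    rates = gamma_dist.ppf(qs, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def _site_patterns(aln: Alignment) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-taxon partial-likelihood seeds and pattern weights."""
    cols = list(zip(*aln.rows))
    pattern_w: dict[tuple, int] = {}
    for col in cols:
        pattern_w[col] = pattern_w.get(col, 0) + 1
    patterns = list(pattern_w)
    weights = np.array([pattern_w[p] for p in patterns], dtype=float)
    seeds: dict[str, np.ndarray] = {}
    for t, rid in enumerate(aln.ids):
        arr = np.ones((len(patterns), 4))
        for s, pat in enumerate(patterns):
            code = _BASE_IDX.get(pat[t].upper().replace("U", "T"), -1)
            if code >= 0:
                arr[s] = 0.0
                arr[s, code] = 1.0
        seeds[rid] = arr
    return seeds, weights


def tree_likelihood(tree: Tree, aln: Alignment, rate: RateModel) -> float:
    """Log-likelihood of *aln* on *tree* by pruning with a gamma mixture.

    Gaps/ambiguities are treated as missing data; base frequencies are
    uniform for K2P and empirical for TN93; the discrete gamma uses
    median-of-bin rates normalized to mean 1.
    """
    if aln.n_columns == 0:
        raise ValueError("zero-length alignment")
    if set(tree.tips()) != set(aln.ids):
        raise ValueError("tree tips must match alignment rows")
    counts = np.zeros(4)
    for row in aln.rows:
        enc = _encode_row(row)
        for b in range(4):
            counts[b] += int((enc == b).sum())
    freqs = counts / counts.sum() if rate.model == "TN93" else np.full(4, 0.25)
    Q = _rate_matrix(rate, freqs)
    rates = _gamma_rates(rate.alpha, rate.categories)
    seeds, weights = _site_patterns(aln)
    n_pat = len(weights)
    site_like = np.zeros(n_pat)
    for r in rates:
        def partial(node: TreeNode) -> np.ndarray:
            if node.is_leaf():
                return seeds[node.name]
            out = np.ones((n_pat, 4))
            for child in node.children:
                P = expm(Q * (child.length * r))
                out *= partial(child) @ P.T
            return out
        root_partial = partial(tree.root)
        site_like += (root_partial @ freqs) / len(rates)
    return float(np.dot(np.log(site_like), weights))


def optimize_branch_lengths(
    tree: Tree, aln: Alignment, rate: RateModel, sweeps: int = 2,
    tol: float = 1e-6,
) -> float:
    """Coordinate-wise 1-D branch-length optimization; returns final logL."""
    branches = [n for n in tree.root.walk() if n is not tree.root]
    ll = tree_likelihood(tree, aln, rate)
    for _ in range(sweeps):
        for node in branches:
            def neg(x: float, node=node) -> float:
                node.length = x
                return -tree_likelihood(tree, aln, rate)
            res = minimize_scalar(
                neg, bounds=(1e-9, 5.0), method="bounded",
                options={"xatol": tol},
            )
            node.length = float(res.x)
        new_ll = tree_likelihood(tree, aln, rate)
        if abs(new_ll - ll) < 1e-6:
            ll = new_ll
            break
        ll = new_ll
    tree.log_likelihood = ll
    return ll


def estimate_gamma_shape(
    tree: Tree, aln: Alignment, rate: RateModel,
    bounds: tuple[float, float] = (0.05, 50.0),
) -> float:
    """Maximum-likelihood gamma shape on a fixed topology/branch lengths."""
    def neg(log_a: float) -> float:
        trial = RateModel(model=rate.model, alpha=math.exp(log_a),
                          categories=rate.categories, kappa=rate.kappa)
        return -tree_likelihood(tree, aln, trial)
    res = minimize_scalar(
        neg, bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded", options={"xatol": 1e-4},
    )
    return float(math.exp(res.x))


def nj_bootstrap(
    aln: Alignment,
    method: str = "logdet",
    rate: RateModel | None = None,
    reps: int = 1000,
    seed: int = 0,
    labels: dict[str, str] | None = None,
) -> Tree:
    """NJ tree with bootstrap supports, using weighted site-category counts.

    Equivalent to :func:`bootstrap_supports` with an NJ builder, but each
    replicate reuses precomputed per-pair site categories (column weights
    instead of materializing resampled alignments).  Replicates with any
    saturated pair are skipped.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    fn = {"k2p": k2p_from_freq, "logdet": logdet_from_freq}[method]
    alpha = rate.alpha if rate is not None else None
    n = len(aln)
    pair_cats = {
        (i, j): pair_site_categories(aln.rows[i], aln.rows[j])
        for i, j in combinations(range(n), 2)
    }

    def build(weights: np.ndarray | None) -> Tree | None:
        D = np.zeros((n, n))
        for (i, j), cat in pair_cats.items():
            d = fn(_joint_freq(cat, weights), alpha)
            if math.isnan(d):
                return None
            D[i, j] = D[j, i] = d
        return nj_tree(
            DistanceMatrix(ids=list(aln.ids), matrix=D,
                           labels=dict(labels or {}))
        )

    ref = build(None)
    if ref is None:
        raise ValueError("saturated pairs in the point-estimate matrix")
    counts = {bp: 0 for bp in ref.bipartitions()}
    rng = np.random.default_rng(seed)
    L = aln.n_columns
    used = 0
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        weights = np.bincount(cols, minlength=L).astype(float)
        rep_tree = build(weights)
        if rep_tree is None:
            continue
        used += 1
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_tips = frozenset(ref.tips())
    refmin = min(all_tips)
    for node in ref.internal_nodes():
        side = frozenset(node.tip_names())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        key = side if refmin not in side else all_tips - side
        node.support = 100.0 * counts.get(key, 0) / max(used, 1)
    return ref


def bootstrap_supports(
    aln: Alignment,
    builder: Callable[[Alignment], Tree],
    reps: int = 1000,
    seed: int = 0,
) -> Tree:
    """Column-resampling bootstrap supports on the full-alignment tree.

    Support = percentage of replicate trees containing each internal
    bipartition; bit-identical for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ref = builder(aln)
    counts: dict[frozenset, int] = {bp: 0 for bp in ref.bipartitions()}
    rng = np.random.default_rng(seed)
    L = aln.n_columns
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rep_aln = aln.subset_columns(list(cols))
        try:
            rep_tree = builder(rep_aln)
        except ValueError:
            continue  # e.g. saturated replicate
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_tips = frozenset(ref.tips())
    refmin = min(all_tips)
    for node in ref.internal_nodes():
        side = frozenset(node.tip_names())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        key = side if refmin not in side else all_tips - side
        node.support = 100.0 * counts.get(key, 0) / reps
    return ref
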