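"""ITS delimitation and proximal 5.8S-28S stem hybridization.

The ITS region (ITS1 - 5.8S - ITS2) is located inside a read by searching
conserved flanking motifs: the 5.8S start and end, the 28S head, and
optionally the 18S tail.  The profile-HMM annotation used by the ITS2
databases is replaced here by degenerate-consensus motif search with a
mismatch budget; an analytic E-value-like significance (expected number of
equally good hits in a random sequence of the same length) stands in for
the HMM E-value and is gated at the same 0.001 threshold.

The ITS2-proximal stem formed by the 3' tail of 5.8S and the 5' head of 28S
is evaluated with a nearest-neighbor duplex model (stack terms + initiation
+ loop penalties from :mod:`its2kit.energy_params`), yielding dG, dH, the
paired positions, and the free-nucleotide pattern at the ITS2-proximal end.
The typical *Ampelomyces* stem leaves exactly one free nucleotide on each
strand; destabilized stems (weak dG) flag candidate rDNA pseudogenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy_params import (
    DUPLEX_INIT_DG,
    DUPLEX_INIT_DH,
    PAIR_TYPE,
    STACK_DG,
    STACK_DH,
    TERMINAL_AU_DG,
    TERMINAL_AU_DH,
    encode_rna,
    loop_dg,
)
from .sequence_io import SeqRecord

__all__ = [
    "DelimitParams",
    "MotifHit",
    "ItsPartition",
    "HybridResult",
    "DelimitError",
    "NoAnchorError",
    "InconsistentAnchorsError",
    "find_flank_motifs",
    "delimit_its",
    "hybridize_stem",
    "duplex_energy",
    "flag_pseudogene_candidate",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Shipped fungal-style defaults.  The 18S tail and 5.8S start are the
# conserved fungal consensus pieces; the 5.8S end and 28S head are the
# stylized proximal-stem consensus used by the synthetic generator, whose
# duplex under the shipped NN table shows the typical one-free-nucleotide
# hybridization (real datasets may need their own motif config).
DEFAULT_MOTIF_18S_END = "GTAGGTGAACCTGCGG"        # 18S 3' end (ITS1f-adjacent)
DEFAULT_MOTIF_5_8S_START = "AACTTTCAGCAACGGATCTC"
DEFAULT_MOTIF_5_8S_END = "ATCTATCTGTGAGAAGATGA"   # stem arm + free nt
DEFAULT_MOTIF_28S_START = "ACATCTTGTCACCGATAGAT"  # free nt + stem arm


class DelimitError(ValueError):
    """Base class for delimitation failures."""


class NoAnchorError(DelimitError):
    """No 5.8S anchor motif could be located: sequence cannot be delimited."""


class InconsistentAnchorsError(DelimitError):
    """Anchor motifs found in an impossible order (end before start)."""


@dataclass
class DelimitParams:
    """Motif consensus strings and thresholds for ITS delimitation."""

    motif_5_8S_start: str = DEFAULT_MOTIF_5_8S_START
    motif_5_8S_end: str = DEFAULT_MOTIF_5_8S_END
    motif_28S_start: str = DEFAULT_MOTIF_28S_START
    motif_18S_end: str | None = DEFAULT_MOTIF_18S_END
    max_mismatches: int = 3
    evalue_threshold: float = 0.001
    min_its2_len: int = 150
    max_its_len: int = 697

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.min_its2_len < 1:
            raise ValueError("min_its2_len must be >= 1")
        if self.max_its_len < self.min_its2_len:
            raise ValueError("max_its_len must be >= min_its2_len")


@dataclass
class MotifHit:
    """Best match of one consensus motif within a sequence."""

    motif: str
    start: int
    end: int
    mismatches: int
    evalue: float

    @property
    def significant(self) -> bool:
        return self.evalue < 1.0


@dataclass
class ItsPartition:
    """[start, end) coordinates (0-based, half-open) of each rDNA region."""

    flank_18S: tuple[int, int]
    its1: tuple[int, int]
    s5_8: tuple[int, int]
    its2: tuple[int, int]
    flank_28S: tuple[int, int]
    has_18S_flank: bool = True
    has_28S_flank: bool = True
    its2_meets_min: bool = True

    def region_lengths(self) -> tuple[int, int, int]:
        """(ITS1, 5.8S, ITS2) lengths in bp."""
        return (
            self.its1[1] - self.its1[0],
            self.s5_8[1] - self.s5_8[0],
            self.its2[1] - self.its2[0],
        )

    @property
    def its_span(self) -> tuple[int, int]:
        return (self.its1[0], self.its2[1])

    def validate(self, seq_len: int) -> None:
        regions = [self.flank_18S, self.its1, self.s5_8, self.its2, self.flank_28S]
        if regions[0][0] != 0 or regions[-1][1] != seq_len:
            raise DelimitError("partition does not cover the sequence")
        for (a, b), (c, d) in zip(regions, regions[1:]):
            if b != c or a > b or c > d:
                raise DelimitError("regions must be contiguous and ordered")


def _match_profile(motif: str) -> list[str]:
    try:
        return [_IUPAC[ch] for ch in motif.upper()]
    except KeyError as exc:
        raise ValueError(f"bad IUPAC symbol in motif {motif!r}") from exc


def _evalue(motif: str, mismatches: int, seq_len: int) -> float:
    """Expected number of windows with <= *mismatches* in an iid sequence."""
    profile = _match_profile(motif)
    m = len(profile)
    if seq_len < m:
        return math.inf
    # DP over the mismatch-count distribution with per-position miss prob.
    dist = np.zeros(m + 1)
    dist[0] = 1.0
    for allowed in profile:
        q = 1.0 - len(allowed) / 4.0
        new = dist * (1.0 - q)
        new[1:] += dist[:-1] * q
        dist = new
    p_le = float(dist[: mismatches + 1].sum())
    return (seq_len - m + 1) * p_le


def _scan(seq: str, motif: str, max_mismatches: int) -> tuple[int, int] | None:
    """Best (leftmost, fewest-mismatch) occurrence; None if over budget."""
    profile = _match_profile(motif)
    m = len(profile)
    best: tuple[int, int] | None = None
    for off in range(len(seq) - m + 1):
        mm = 0
        for k, allowed in enumerate(profile):
            if seq[off + k] not in allowed:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            if best is None or mm < best[1]:
                best = (off, mm)
                if mm == 0:
                    break
    return best


def find_flank_motifs(rec: SeqRecord, params: DelimitParams) -> dict[str, MotifHit]:
    """Locate the best hit of every configured flank motif in *rec*.

    Absent motifs are simply missing from the returned dict; if neither
    5.8S anchor is found the sequence cannot be delimited and
    :class:`NoAnchorError` is raised.
    """
    motifs = {
        "5_8S_start": params.motif_5_8S_start,
        "5_8S_end": params.motif_5_8S_end,
        "28S_start": params.motif_28S_start,
    }
    if params.motif_18S_end:
        motifs["18S_end"] = params.motif_18S_end
    hits: dict[str, MotifHit] = {}
    for name, motif in motifs.items():
        if len(rec.seq) < len(motif):
            continue
        found = _scan(rec.seq, motif, params.max_mismatches)
        if found is None:
            continue
        off, mm = found
        hits[name] = MotifHit(
            motif=name,
            start=off,
            end=off + len(motif),
            mismatches=mm,
            evalue=_evalue(motif, mm, len(rec.seq)),
        )
    if "5_8S_start" not in hits and "5_8S_end" not in hits:
        raise NoAnchorError(f"record {rec.id!r}: no 5.8S anchor motif found")
    return hits


def delimit_its(
    rec: SeqRecord, hits: dict[str, MotifHit], params: DelimitParams
) -> ItsPartition:
    """Partition *rec* into 18S flank / ITS1 / 5.8S / ITS2 / 28S flank.

    The 5.8S spans from the start-anchor hit to the end of the end-anchor
    hit; ITS1 and ITS2 are the spans either side, bounded by the 18S/28S
    flank motifs when present (completeness flags record their absence).
    """
    if "5_8S_start" not in hits or "5_8S_end" not in hits:
        raise NoAnchorError(f"record {rec.id!r}: need both 5.8S anchors to delimit")
    s58_a = hits["5_8S_start"].start
    s58_b = hits["5_8S_end"].end
    if s58_b <= s58_a:
        raise InconsistentAnchorsError(
            f"record {rec.id!r}: 5.8S end anchor before start anchor"
        )
    has_18s = "18S_end" in hits and hits["18S_end"].end <= s58_a
    its1_start = hits["18S_end"].end if has_18s else 0
    has_28s = "28S_start" in hits and hits["28S_start"].start >= s58_b
    its2_end = hits["28S_start"].start if has_28s else len(rec.seq)
    part = ItsPartition(
        flank_18S=(0, its1_start),
        its1=(its1_start, s58_a),
        s5_8=(s58_a, s58_b),
        its2=(s58_b, its2_end),
        flank_28S=(its2_end, len(rec.seq)),
        has_18S_flank=has_18s,
        has_28S_flank=has_28s,
        its2_meets_min=(its2_end - s58_b) >= params.min_its2_len,
    )
    part.validate(len(rec.seq))
    return part


# ---------------------------------------------------------------------------
# Proximal-stem hybridization


@dataclass
class HybridResult:
    """Optimal 5.8S-tail / 28S-head duplex under the shipped NN table.

    dG/dH are kcal/mol at 37 degC; ``paired_positions`` are (tail_i, head_j)
    index pairs (0-based within each window); free-nucleotide counts are
    taken at the ITS2-proximal end of the duplex.
    """

    dG: float
    dH: float
    paired_positions: list[tuple[int, int]] = field(default_factory=list)
    free_nt_5_8S: int = 0
    free_nt_28S: int = 0
    pattern: str = "UNMODELABLE"  # TYPICAL | VARIANT_MULTI_FREE | UNMODELABLE
    reason: str = ""


_MAX_DUPLEX_GAP = 6  # largest bulge/internal span inside the stem


def duplex_energy(strand_a: str, strand_b: str) -> HybridResult:
    """Optimal antiparallel duplex between two strands (5'->3' each).

    Pairs a[i] with b[j] such that i increases as j decreases; consecutive
    pairs are scored with nearest-neighbor stacks, interruptions with
    bulge/internal-loop penalties, plus duplex initiation and terminal
    AU/GU penalties.  dH is accumulated along the dG-optimal duplex
    (loop enthalpies taken as zero).
    """
    a = encode_rna(strand_a)
    b = encode_rna(strand_b)
    na, nb = len(a), len(b)
    pt = PAIR_TYPE[a[:, None], b[None, :]]  # (na, nb) pair types
    if not pt.any():
        return HybridResult(dG=0.0, dH=0.0, pattern="UNMODELABLE", reason="no complementarity")

    INF = math.inf
    D = np.full((na, nb), INF)
    Dh = np.zeros((na, nb))
    back: dict[tuple[int, int], tuple[int, int]] = {}

    def term_pen(p: int) -> tuple[float, float]:
        # AU, UA, GU, UG termini carry the terminal penalty.
        return (TERMINAL_AU_DG, TERMINAL_AU_DH) if p in (1, 2, 5, 6) else (0.0, 0.0)

    for i in range(na):
        for j in range(nb - 1, -1, -1):
            p = pt[i, j]
            if p == 0:
                continue
            g0, h0 = term_pen(p)
            best_g, best_h, best_src = g0, h0, None
            for i0 in range(max(0, i - 1 - _MAX_DUPLEX_GAP), i):
                for j0 in range(j + 1, min(nb, j + 2 + _MAX_DUPLEX_GAP)):
                    p0 = pt[i0, j0]
                    if p0 == 0 or D[i0, j0] == INF:
                        continue
                    ga, gb = i - i0 - 1, j0 - j - 1
                    if ga == 0 and gb == 0:
                        step_g = STACK_DG[p0, p]
                        step_h = STACK_DH[p0, p]
                    else:
                        step_g = loop_dg(ga, gb)
                        step_h = 0.0
                    cand = D[i0, j0] + step_g
                    if cand < best_g:
                        best_g = cand
                        best_h = Dh[i0, j0] + step_h
                        best_src = (i0, j0)
            D[i, j] = best_g
            Dh[i, j] = best_h
            if best_src is not None:
                back[(i, j)] = best_src

    # Close the duplex at its ITS2-proximal pair (i, j): add initiation and
    # the proximal terminal penalty.
    best_total = INF
    best_end: tuple[int, int] | None = None
    for i in range(na):
        for j in range(nb):
            if D[i, j] == INF:
                continue
            g1, _ = term_pen(pt[i, j])
            total = D[i, j] + DUPLEX_INIT_DG + g1
            if total < best_total:
                best_total = total
                best_end = (i, j)
    if best_end is None or best_total > 0.0:
        return HybridResult(dG=0.0, dH=0.0, pattern="UNMODELABLE", reason="no stabilizing duplex")

    i, j = best_end
    g1, h1 = term_pen(pt[i, j])
    dH = Dh[i, j] + DUPLEX_INIT_DH + h1
    pairs = [(i, j)]
    while (i, j) in back:
        i, j = back[(i, j)]
        pairs.append((i, j))
    pairs.reverse()
    imax, jmin = pairs[-1]
    return HybridResult(
        dG=round(best_total, 6),
        dH=round(dH, 6),
        paired_positions=pairs,
        free_nt_5_8S=na - 1 - imax,
        free_nt_28S=jmin,
        pattern="",
    )


def hybridize_stem(
    part: ItsPartition, rec: SeqRecord, window: int = 25
) -> HybridResult:
    """Evaluate the proximal stem between the 5.8S 3' tail and 28S 5' head.

    The duplex is computed over *window* nt per strand.  A 28S flank shorter
    than the window makes the record unmodelable (this is a result, not an
    exception: it mirrors the large unmodelable fraction in real data).
    TYPICAL means exactly one free nucleotide on each strand at the
    ITS2-proximal end.
    """
    c28_a, c28_b = part.flank_28S
    if not part.has_28S_flank or (c28_b - c28_a) < window:
        return HybridResult(
            dG=0.0, dH=0.0, pattern="UNMODELABLE", reason="28S strand shorter than stem window"
        )
    s58_a, s58_b = part.s5_8
    tail = rec.seq[max(s58_a, s58_b - window) : s58_b]
    head = rec.seq[c28_a : c28_a + window]
    result = duplex_energy(tail, head)
    if result.pattern == "UNMODELABLE":
        return result
    if result.free_nt_5_8S == 1 and result.free_nt_28S == 1:
        result.pattern = "TYPICAL"
    else:
        result.pattern = "VARIANT_MULTI_FREE"
    return result


def flag_pseudogene_candidate(
    hr: HybridResult, thresholds: tuple[float, float] = (-19.0, -15.0)
) -> str:
    """Classify proximal-stem stability from its dG.

    Stems weaker than the upper threshold destabilize the structure
    (candidate pseudogenes); dG within [lower, upper] confers flexibility
    (boundaries inclusive); stronger stems are stable.
    """
    if hr.pattern == "UNMODELABLE":
        raise ValueError("cannot classify an unmodelable stem")
    lower, upper = thresholds
    if lower > upper:
        raise ValueError("thresholds must be (lower, upper) with lower <= upper")
    if hr.dG > upper:
        return "DESTABILIZED"
    if hr.dG >= lower:
        return "FLEXIBLE"
    return "STABLE"
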