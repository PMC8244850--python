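"""ITS2 secondary-structure prediction, decomposition and classification.

The ITS2 spacer folds into a conserved "four-fingered" core: four helices
(I-IV) radiating from an exterior ring, with helix III the longest.  This
module provides:

* :func:`fold_mfe` - pseudoknot-free minimum-free-energy folding by dynamic
  programming over hairpin/stack/bulge/internal/multibranch terms using the
  simplified Turner-style table in :mod:`its2kit.energy_params` (the DP
  kernel is JIT-compiled with numba).  Deterministic: ties are resolved by
  a fixed traceback evaluation order that prefers 5'-most pairing.
* :func:`structure_energy` - an independent re-evaluation of a dot-bracket
  structure's energy by loop decomposition (the "energy audit").
* :func:`decompose_helices` - the four-helix decomposition with per-helix
  internal-loop/bulge/terminal-loop counts and inter-helix rings.
* :func:`detect_motifs` / :func:`classify_model` - the diagnostic motifs
  (U-U mismatch on helix II, UGG/UGGU(+UU) on helix III, ring I-IV
  signatures GTACCC / GTCTCC / TCCATG) and the rule cascade assigning the
  structural models M1..M7 vs the putative pattern.
* :func:`consensus_structure` - column-majority consensus of aligned
  sequence-structure rows with per-column conservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import energy_params as ep

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "Helix",
    "HelixSet",
    "MotifReport",
    "ModelLabel",
    "ConsensusStructure",
    "fold_mfe",
    "structure_energy",
    "decompose_helices",
    "detect_motifs",
    "classify_model",
    "consensus_structure",
    "MODEL_LABELS",
]

MODEL_LABELS = (
    "M1", "M1-2", "M1-3", "M2", "M3", "M4", "M5", "M6", "M7",
    "PUTATIVE", "UNCLASSIFIED",
)

_INF = 1e30


@dataclass(frozen=True)
class EnergyModel:
    """Folding energy model: parameter-table version and temperature."""

    version: str = ep.PARAM_VERSION
    temperature_c: float = ep.TEMPERATURE_C


DEFAULT_ENERGY_MODEL = EnergyModel()


@dataclass
class SecondaryStructure:
    """A dot-bracket structure aligned to its (RNA) sequence, with MFE."""

    seq: str          # RNA alphabet, same length as structure
    structure: str    # dot-bracket, no pseudoknots
    mfe: float        # kcal/mol

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.structure):
            raise ValueError("sequence and structure lengths differ")
        pair_map(self.structure)  # raises if unbalanced

    @property
    def pairs(self) -> list[tuple[int, int]]:
        pm = pair_map(self.structure)
        return sorted((i, j) for i, j in enumerate(pm) if j > i)


def pair_map(structure: str) -> list[int]:
    """Map each position to its partner (-1 if unpaired); checks balance."""
    out = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            out[i], out[j] = j, i
        elif ch != ".":
            raise ValueError(f"bad structure symbol {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return out


# ---------------------------------------------------------------------------
# MFE folding


@njit(cache=True)
def _fill_tables(pt, stack_dg, loop_tab, hp_tab, A, B, C, max_int, min_hp):
    n = pt.shape[0]
    V = np.full((n, n), _INF)
    WM = np.full((n, n), _INF)
    WM1 = np.full((n, n), _INF)
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            p = pt[i, j]
            if p != 0 and d - 1 >= min_hp:
                best = hp_tab[d - 1]
                kmax = min(i + max_int + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    lmin = j - 1 - (max_int - g1)
                    if lmin < k + min_hp + 1:
                        lmin = k + min_hp + 1
                    for l in range(j - 1, lmin - 1, -1):
                        if l <= k:
                            break
                        q = pt[k, l]
                        if q == 0 or V[k, l] >= _INF:
                            continue
                        g2 = j - l - 1
                        if g1 == 0 and g2 == 0:
                            e = stack_dg[p, q] + V[k, l]
                        else:
                            e = loop_tab[g1, g2] + V[k, l]
                        if e < best:
                            best = e
                for m in range(i + 2, j - 1):
                    if WM[i + 1, m - 1] < _INF and WM1[m, j - 1] < _INF:
                        e = A + B + WM[i + 1, m - 1] + WM1[m, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            b1 = _INF
            if V[i, j] < _INF:
                b1 = V[i, j] + B
            if j - 1 >= i and WM1[i, j - 1] < _INF:
                e = WM1[i, j - 1] + C
                if e < b1:
                    b1 = e
            WM1[i, j] = b1
            bm = WM1[i, j]
            if WM[i + 1, j] < _INF:
                e = WM[i + 1, j] + C
                if e < bm:
                    bm = e
            for m in range(i + 1, j + 1):
                if WM[i, m - 1] < _INF and WM1[m, j] < _INF:
                    e = WM[i, m - 1] + WM1[m, j]
                    if e < bm:
                        bm = e
            WM[i, j] = bm
    W = np.zeros(n + 1)
    for t in range(1, n + 1):
        best = W[t - 1]
        j = t - 1
        for i in range(j):
            if V[i, j] < _INF:
                e = W[i] + V[i, j]
                if e < best:
                    best = e
        W[t] = best
    return V, WM, WM1, W


def _traceback(seqi, pt, V, WM, WM1, W):
    """Deterministic traceback mirroring the fill order (5'-most first)."""
    A, B, C = ep.MULTI_A, ep.MULTI_B, ep.MULTI_C
    max_int, min_hp = ep.MAX_INTERIOR, ep.MIN_HAIRPIN
    eps = 1e-9
    n = len(seqi)
    pairs: list[tuple[int, int]] = []
    tasks: list[tuple] = [("W", n)]
    while tasks:
        task = tasks.pop()
        kind = task[0]
        if kind == "W":
            t = task[1]
            if t == 0:
                continue
            j = t - 1
            placed = False
            for i in range(j):
                if V[i, j] < _INF and abs(W[i] + V[i, j] - W[t]) < eps:
                    pairs.append((i, j))
                    tasks.append(("W", i))
                    tasks.append(("V", i, j))
                    placed = True
                    break
            if not placed:
                tasks.append(("W", t - 1))
        elif kind == "V":
            i, j = task[1], task[2]
            p = pt[i, j]
            e = V[i, j]
            if abs(ep.HAIRPIN_TABLE[j - i - 1] - e) < eps:
                continue
            done = False
            kmax = min(i + max_int + 1, j - 1)
            for k in range(i + 1, kmax + 1):
                g1 = k - i - 1
                lmin = max(j - 1 - (max_int - g1), k + min_hp + 1)
                for l in range(j - 1, lmin - 1, -1):
                    if l <= k:
                        break
                    q = pt[k, l]
                    if q == 0 or V[k, l] >= _INF:
                        continue
                    g2 = j - l - 1
                    step = (
                        ep.STACK_DG[p, q]
                        if (g1 == 0 and g2 == 0)
                        else ep.LOOP_TABLE[g1, g2]
                    )
                    if abs(step + V[k, l] - e) < eps:
                        pairs.append((k, l))
                        tasks.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for m in range(i + 2, j - 1):
                if WM[i + 1, m - 1] < _INF and WM1[m, j - 1] < _INF:
                    if abs(A + B + WM[i + 1, m - 1] + WM1[m, j - 1] - e) < eps:
                        tasks.append(("WM", i + 1, m - 1))
                        tasks.append(("WM1", m, j - 1))
                        done = True
                        break
            if not done:
                raise AssertionError("traceback failed in V")
        elif kind == "WM1":
            i, j = task[1], task[2]
            e = WM1[i, j]
            if V[i, j] < _INF and abs(V[i, j] + B - e) < eps:
                pairs.append((i, j))
                tasks.append(("V", i, j))
            elif j - 1 >= i and abs(WM1[i, j - 1] + C - e) < eps:
                tasks.append(("WM1", i, j - 1))
            else:
                raise AssertionError("traceback failed in WM1")
        elif kind == "WM":
            i, j = task[1], task[2]
            e = WM[i, j]
            if abs(WM1[i, j] - e) < eps:
                tasks.append(("WM1", i, j))
            elif WM[i + 1, j] < _INF and abs(WM[i + 1, j] + C - e) < eps:
                tasks.append(("WM", i + 1, j))
            else:
                done = False
                for m in range(i + 1, j + 1):
                    if WM[i, m - 1] < _INF and WM1[m, j] < _INF:
                        if abs(WM[i, m - 1] + WM1[m, j] - e) < eps:
                            tasks.append(("WM", i, m - 1))
                            tasks.append(("WM1", m, j))
                            done = True
                            break
                if not done:
                    raise AssertionError("traceback failed in WM")
    return pairs


def fold_mfe(its2_seq: str, model: EnergyModel = DEFAULT_ENERGY_MODEL) -> SecondaryStructure:
    """Fold an ITS2 sequence into its MFE pseudoknot-free structure.

    Accepts DNA or RNA letters (T folded to U); lengths outside [50, 400]
    are folded anyway with a warning.  A sequence that cannot gain any
    stabilizing structure is returned all-unpaired with mfe 0.
    """
    n = len(its2_seq)
    if n < 50 or n > 400:
        warnings.warn(f"ITS2 length {n} outside the expected 50-400 nt range", stacklevel=2)
    seqi = ep.encode_rna(its2_seq)
    rna = "".join(ep.BASES[c] for c in seqi)
    pt = ep.PAIR_TYPE[seqi[:, None], seqi[None, :]]
    V, WM, WM1, W = _fill_tables(
        pt, ep.STACK_DG, ep.LOOP_TABLE, ep.HAIRPIN_TABLE,
        ep.MULTI_A, ep.MULTI_B, ep.MULTI_C, ep.MAX_INTERIOR, ep.MIN_HAIRPIN,
    )
    mfe = float(W[n])
    if mfe >= -1e-9:
        return SecondaryStructure(seq=rna, structure="." * n, mfe=0.0)
    pairs = _traceback(seqi, pt, V, WM, WM1, W)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return SecondaryStructure(seq=rna, structure="".join(db), mfe=mfe)


def structure_energy(seq: str, structure: str) -> float:
    """Independent loop-decomposition energy of a dot-bracket structure.

    Walks every loop of the structure (hairpin, stack, bulge/internal,
    multibranch, exterior) and sums the same parameter table the folding
    DP uses; for any structure emitted by :func:`fold_mfe` this reproduces
    the reported MFE exactly.
    """
    seqi = ep.encode_rna(seq)
    pm = pair_map(structure)
    n = len(seqi)

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, k = [], 0, i + 1
        while k < j:
            if pm[k] == -1:
                unpaired += 1
                k += 1
            else:
                kids.append((k, pm[k]))
                k = pm[k] + 1
        return kids, unpaired

    total = 0.0
    stack = [(k, pm[k]) for k in range(n) if pm[k] > k and not _enclosed(pm, k)]
    while stack:
        i, j = stack.pop()
        p = ep.PAIR_TYPE[seqi[i], seqi[j]]
        if p == 0:
            raise ValueError(f"unpairable bases at ({i},{j})")
        kids, unpaired = children_of(i, j)
        if not kids:
            total += ep.hairpin_dg(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            q = ep.PAIR_TYPE[seqi[k], seqi[l]]
            g1, g2 = k - i - 1, j - l - 1
            if g1 == 0 and g2 == 0:
                total += float(ep.STACK_DG[p, q])
            else:
                total += ep.loop_dg(g1, g2)
            stack.append((k, l))
        else:
            total += ep.MULTI_A + ep.MULTI_B * (1 + len(kids)) + ep.MULTI_C * unpaired
            stack.extend(kids)
    return total


def _enclosed(pm: list[int], k: int) -> bool:
    """True if pair (k, pm[k]) lies inside some other pair."""
    j = pm[k]
    return any(pm[a] > j for a in range(k))


# ---------------------------------------------------------------------------
# Helix decomposition


@dataclass
class Helix:
    """One stem of the four-helix core, outer pair to terminal loop."""

    outer: tuple[int, int]
    inner: tuple[int, int]
    n_pairs: int
    internal_loops: list[tuple[str, str]]   # (5'-side, 3'-side) unpaired seqs
    bulges: list[tuple[str, str]]
    terminal_loop: str
    branched: bool = False
    arm5: str = ""   # 5' arm sequence outer..inner (RNA)
    arm3: str = ""   # 3' arm sequence inner..outer (RNA)

    @property
    def n_internal_loops(self) -> int:
        return len(self.internal_loops)

    @property
    def n_bulges(self) -> int:
        return len(self.bulges)


@dataclass
class HelixSet:
    """Top-level stems (5'->3') with inter-helix single-stranded rings."""

    helices: list[Helix]
    spacers: list[str]          # between consecutive helices
    ring_I_IV: str              # exterior span joining last 3' and first 5'
    not_four_fingered: bool = False

    @property
    def n_top(self) -> int:
        return len(self.helices)

    @property
    def is_four(self) -> bool:
        return self.n_top == 4

    def helix(self, roman: str) -> Helix:
        idx = {"I": 0, "II": 1, "III": 2, "IV": 3}[roman]
        return self.helices[idx]


def decompose_helices(ss: SecondaryStructure, seq: str | None = None) -> HelixSet:
    """Decompose a structure into its top-level stems and rings.

    Stems are ordered 5'->3' and labeled I-IV when exactly four; fewer than
    2 or more than 6 top-level stems sets ``not_four_fingered`` (a flag,
    never an exception).  A stem whose interior branches into a multiloop
    is marked ``branched`` and measured up to the branch point.
    """
    rna = (seq or ss.seq).upper().replace("T", "U")
    pm = pair_map(ss.structure)
    n = len(pm)
    top: list[tuple[int, int]] = []
    k = 0
    while k < n:
        if pm[k] > k:
            top.append((k, pm[k]))
            k = pm[k] + 1
        else:
            k += 1
    helices = []
    for i0, j0 in top:
        internal: list[tuple[str, str]] = []
        bulges: list[tuple[str, str]] = []
        npairs = 1
        i, j = i0, j0
        branched = False
        tloop = ""
        while True:
            kids = []
            k = i + 1
            while k < j:
                if pm[k] > k:
                    kids.append((k, pm[k]))
                    k = pm[k] + 1
                else:
                    k += 1
            if not kids:
                tloop = rna[i + 1 : j]
                break
            if len(kids) > 1:
                branched = True
                break
            (ki, kj) = kids[0]
            g5, g3 = rna[i + 1 : ki], rna[kj + 1 : j]
            if g5 and g3:
                internal.append((g5, g3))
            elif g5 or g3:
                bulges.append((g5, g3))
            npairs += 1
            i, j = ki, kj
        helices.append(
            Helix(
                outer=(i0, j0),
                inner=(i, j),
                n_pairs=npairs,
                internal_loops=internal,
                bulges=bulges,
                terminal_loop=tloop,
                branched=branched,
                arm5=rna[i0 : i + 1],
                arm3=rna[j : j0 + 1],
            )
        )
    spacers = [
        rna[a[1] + 1 : b[0]] for a, b in zip(top, top[1:])
    ]
    ring = (rna[top[-1][1] + 1 :] + rna[: top[0][0]]) if top else rna
    return HelixSet(
        helices=helices,
        spacers=spacers,
        ring_I_IV=ring,
        not_four_fingered=(len(top) < 2 or len(top) > 6),
    )


# ---------------------------------------------------------------------------
# Motifs and model classification


@dataclass
class MotifReport:
    """Diagnostic sequence-structure motifs of a four-helix ITS2."""

    uu_mismatch_helixII: bool = False
    uu_mismatch_pos: tuple[int, int] | None = None
    helixIII_motif: str | None = None       # UGG | UGGU | UGGU+UU
    helixIII_motif_pos: int | None = None
    uugg_context: bool = False              # C->U transition marker (M7)
    ring_I_IV: str = ""                     # DNA letters
    spacer_II_III: str = ""                 # DNA letters
    spacer_III_IV: str = ""
    aaa_spacer: bool = False


def _to_dna(rna: str) -> str:
    return rna.replace("U", "T")


def detect_motifs(hs: HelixSet, seq: str | None = None) -> MotifReport:
    """Detect the diagnostic motifs on a four-helix decomposition.

    U-U mismatch = a 1x1 internal loop of helix II with U opposite U; helix
    III arms are scanned for UGGU then UGG (a separate UU counts only
    outside the UGGU occurrence); rings are reported verbatim as DNA.
    Absent motifs are simply false/None flags.
    """
    if not hs.is_four:
        raise ValueError("motif detection needs a four-helix decomposition")
    h2, h3 = hs.helix("II"), hs.helix("III")
    report = MotifReport(
        ring_I_IV=_to_dna(hs.ring_I_IV),
        spacer_II_III=_to_dna(hs.spacers[1]),
        spacer_III_IV=_to_dna(hs.spacers[2]),
    )
    for g5, g3 in h2.internal_loops:
        if g5 == "U" and g3 == "U":
            report.uu_mismatch_helixII = True
            report.uu_mismatch_pos = h2.outer
            break
    arms = h3.arm5 + "&" + h3.arm3
    if "UGGU" in arms:
        pos = arms.index("UGGU")
        masked = arms.replace("UGGU", "xxxx", 1)
        report.helixIII_motif = "UGGU+UU" if "UU" in masked else "UGGU"
        report.helixIII_motif_pos = pos
    elif "UGG" in arms:
        report.helixIII_motif = "UGG"
        report.helixIII_motif_pos = arms.index("UGG")
    report.uugg_context = "UUGG" in arms
    report.aaa_spacer = "AAA" in report.spacer_II_III
    return report


@dataclass
class ModelLabel:
    """Assigned structural model with the list of satisfied rules."""

    label: str
    evidence: list[str] = field(default_factory=list)


def _ring_matches(ring: str, signature: str, budget: int) -> bool:
    """Approximate (<= budget mismatches) cyclic substring match."""
    m = len(signature)
    if len(ring) < m:
        return False
    doubled = ring + ring[: m - 1] if len(ring) >= m else ring
    for off in range(len(doubled) - m + 1):
        mm = sum(1 for a, b in zip(doubled[off : off + m], signature) if a != b)
        if mm <= budget:
            return True
    return False


RING_M1 = "GTACCC"
RING_M2 = ("GTCTCC", "GTGTCC")   # text vs figure variants, both accepted
RING_PUTATIVE = "TCCATG"


def classify_model(
    hs: HelixSet, mr: MotifReport, ring_mismatch_budget: int = 1
) -> ModelLabel:
    """Assign a structural model by the diagnostic rule cascade.

    Order: (a) not four helices -> UNCLASSIFIED; (b) putative ring TCCATG
    with no helix III motif -> PUTATIVE; (c) GTACCC ring + UGG -> M1 family
    (M7 on the C->U transition context, M1-3/M1-2 on the pyrimidine
    spacer/bulge variants); (d) GTCTCC-or-GTGTCC ring + UGGU+UU -> M2/M3
    (M3 when helix III shows >= 4 bulges); (e) A-rich II-III spacer + UGGU
    + helix I internal loop -> M6 (3-bp helix IV ending in CCC) or M4/M5
    (split on helix III bulge layout).  No rule satisfied -> UNCLASSIFIED
    with empty evidence.
    """
    if not hs.is_four:
        return ModelLabel("UNCLASSIFIED")
    ev: list[str] = []
    ring = mr.ring_I_IV
    b = ring_mismatch_budget
    # (b) putative pattern
    if _ring_matches(ring, RING_PUTATIVE, b) and mr.helixIII_motif is None:
        ev.append(f"ring~{RING_PUTATIVE}")
        if mr.uu_mismatch_helixII:
            ev.append("U-U mismatch helix II")
        ev.append("no helix III motif")
        return ModelLabel("PUTATIVE", ev)
    # (c) M1 family
    if _ring_matches(ring, RING_M1, b) and mr.helixIII_motif in ("UGG", "UGGU", "UGGU+UU"):
        ev.append(f"ring~{RING_M1}")
        ev.append(f"helix III {mr.helixIII_motif}")
        if mr.uu_mismatch_helixII:
            ev.append("U-U mismatch helix II")
        if mr.uugg_context:
            ev.append("C->U transition adjacent to UGG (helix III)")
            return ModelLabel("M7", ev)
        if len(mr.spacer_II_III) > 2 and any(c in "CT" for c in mr.spacer_II_III):
            ev.append("pyrimidine addition in II-III spacer")
            return ModelLabel("M1-3", ev)
        if hs.helix("II").n_bulges >= 1:
            ev.append("helix II bulge (pyrimidine deletion variant)")
            return ModelLabel("M1-2", ev)
        return ModelLabel("M1", ev)
    # (d) M2 family
    m2_ring = next((s for s in RING_M2 if _ring_matches(ring, s, b)), None)
    if m2_ring is not None and mr.helixIII_motif == "UGGU+UU":
        ev.append(f"ring~{m2_ring}")
        ev.append("helix III UGGU+UU")
        if mr.uu_mismatch_helixII:
            ev.append("U-U mismatch helix II")
        h2 = hs.helix("II")
        if len(h2.terminal_loop) >= 12:
            ev.append("12-nt helix II terminal loop")
        if hs.helix("III").n_bulges >= 4:
            ev.append("helix III with four bulges")
            return ModelLabel("M3", ev)
        return ModelLabel("M2", ev)
    # (e) M4/M5/M6
    if (
        mr.aaa_spacer
        and mr.helixIII_motif in ("UGGU", "UGGU+UU")
        and hs.helix("I").n_internal_loops >= 1
    ):
        ev.append("A-rich II-III spacer")
        ev.append("helix III UGGU")
        ev.append("helix I internal loop")
        h4 = hs.helix("IV")
        if h4.n_pairs <= 3 and h4.terminal_loop.replace("U", "C").strip("C") == "":
            ev.append("helix IV 3-bp stack ending in CCC loop")
            return ModelLabel("M6", ev)
        if hs.helix("III").n_bulges == 0:
            ev.append("helix III without bulges")
            return ModelLabel("M4", ev)
        ev.append("helix III with bulges")
        return ModelLabel("M5", ev)
    return ModelLabel("UNCLASSIFIED")


# ---------------------------------------------------------------------------
# Consensus structures


@dataclass
class ConsensusStructure:
    """Column-majority consensus of aligned sequence-structure rows."""

    sequence: str
    structure: str
    conservation: np.ndarray
    kept_columns: list[int]


def consensus_structure(
    rows: list[tuple[str, str]], gap_policy: str = "keep"
) -> ConsensusStructure:
    """Majority-rule consensus over aligned (sequence, structure) rows.

    Per column the majority base and majority structural state are taken,
    with conservation = majority fraction (ties broken alphabetically for
    determinism).  ``gap_policy='keep'`` retains gap-containing columns
    (a gap majority renders '-'); ``'drop'`` removes any column containing
    a gap, so the two modes differ exactly at gap-containing columns.
    """
    if not rows:
        raise ValueError("empty input")
    ncol = len(rows[0][0])
    for s, st in rows:
        if len(s) != ncol or len(st) != ncol:
            raise ValueError("rows must be equal-length aligned pairs")
    if gap_policy not in ("keep", "drop"):
        raise ValueError("gap_policy must be 'keep' or 'drop'")
    seq_out, str_out, cons, kept = [], [], [], []
    for c in range(ncol):
        col_seq = [s[c].upper() for s, _ in rows]
        col_str = [st[c] for _, st in rows]
        if gap_policy == "drop" and "-" in col_seq:
            continue
        kept.append(c)

        def majority(values: list[str]) -> tuple[str, float]:
            counts: dict[str, int] = {}
            for v in values:
                counts[v] = counts.get(v, 0) + 1
            best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            return best[0], best[1] / len(values)

        mb, fb = majority(col_seq)
        ms, fs = majority(col_str)
        seq_out.append(mb)
        str_out.append(ms)
        cons.append(min(fb, fs))
    return ConsensusStructure(
        sequence="".join(seq_out),
        structure="".join(str_out),
        conservation=np.asarray(cons),
        kept_columns=kept,
    )
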