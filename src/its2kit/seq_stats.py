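"""Sequence statistics, rank-based group tests, and indel-event counting.

Implements the descriptive statistics reported per group and region
(length ranges, means with SEM, A/T and G/C content ranges, lengths
normalized to the 697-bp primer-bounded maximum), the Kruskal-Wallis
omnibus test with Dunn's post-hoc pairwise comparisons (unadjusted,
two-sided, with tie correction), and gap-event counting on a multiple
sequence alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .its_delimit import ItsPartition
from .sequence_io import GroupManifest, SeqRecord

__all__ = [
    "ContentStats",
    "TestResult",
    "IndelReport",
    "NORMALIZATION_REF_BP",
    "nucleotide_content",
    "normalized_length",
    "kruskal_wallis",
    "dunn_posthoc",
    "count_indel_events",
    "group_summary",
]

#: Maximum ITS length expected from ascomycete amplicons (ITS1f/ITS4 primers).
NORMALIZATION_REF_BP = 697


@dataclass
class ContentStats:
    """A/T and G/C percentages over the unambiguous bases of one sequence."""

    at_pct: float
    gc_pct: float
    counted_bases: int


def nucleotide_content(seq: str) -> ContentStats:
    """A/T% and G/C% of *seq*; ambiguity codes excluded from both sides.

    Raises on a sequence with no unambiguous base (content undefined).
    """
    if not seq:
        raise ValueError("empty sequence")
    up = seq.upper().replace("U", "T")
    at = sum(up.count(b) for b in "AT")
    gc = sum(up.count(b) for b in "GC")
    counted = at + gc
    if counted == 0:
        raise ValueError("all-ambiguous sequence: nucleotide content undefined")
    return ContentStats(
        at_pct=100.0 * at / counted, gc_pct=100.0 * gc / counted, counted_bases=counted
    )


def normalized_length(len_bp: int, ref_bp: int = NORMALIZATION_REF_BP) -> float:
    """Length as a percentage of the primer-bounded maximum (default 697 bp).

    A length above the reference is legal (warned about) and still returned.
    """
    if len_bp < 0 or ref_bp <= 0:
        raise ValueError("need len_bp >= 0 and ref_bp > 0")
    if len_bp > ref_bp:
        warnings.warn(
            f"sequence length {len_bp} exceeds the primer-bounded maximum {ref_bp}",
            stacklevel=2,
        )
    return 100.0 * len_bp / ref_bp


@dataclass
class TestResult:
    """Kruskal-Wallis omnibus result with optional Dunn pairwise table."""

    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]
    dunn: pd.DataFrame | None = None
    _ranks: tuple[np.ndarray, ...] = field(default_factory=tuple, repr=False)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank sum test over k >= 2 independent samples.

    Average ranks for ties, tie-correction divisor, p from chi-squared with
    k-1 df.  All-identical pooled values give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*arrays)
    ranks = sps.rankdata(pooled)
    split = np.cumsum([a.size for a in arrays])[:-1]
    return TestResult(
        H=float(H),
        df=len(groups) - 1,
        p=float(p),
        group_sizes=tuple(a.size for a in arrays),
        _ranks=tuple(np.split(ranks, split)),
    )


def dunn_posthoc(result: TestResult) -> pd.DataFrame:
    """Dunn's pairwise z tests on the ranks of a Kruskal-Wallis run.

    Two-sided p-values with the usual tie correction and NO multiplicity
    adjustment.  Must be called on a :class:`TestResult` (the omnibus test
    defines the shared ranking); calling it standalone is a sequencing error.
    """
    if not result._ranks:
        raise ValueError("dunn_posthoc requires the ranks of a kruskal_wallis run")
    ranks = result._ranks
    n_tot = sum(r.size for r in ranks)
    pooled = np.concatenate(ranks)
    # Tie correction: sum over tie groups of (t^3 - t), on the ranked values.
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    rows = []
    for i, j in combinations(range(len(ranks)), 2):
        ri, rj = ranks[i], ranks[j]
        diff = ri.mean() - rj.mean()
        se = math.sqrt(var_base * (1.0 / ri.size + 1.0 / rj.size))
        z = diff / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_i": i, "group_j": j, "z": z, "p": p})
    table = pd.DataFrame(rows)
    result.dunn = table
    return table


@dataclass
class IndelReport:
    """Indel events of an alignment: one event per distinct gap-run signature.

    A gap run is a maximal stretch of '-' in one row; rows sharing the
    identical [start, end) run contribute a single event.
    """

    I: int
    events: list[tuple[tuple[int, int], tuple[int, ...]]]
    positional_profile: list[int]
    stripped_columns: list[int] = field(default_factory=list)


def count_indel_events(alignment: Sequence[str]) -> IndelReport:
    """Count indel events in a rectangular alignment (gap char '-').

    All-gap columns are stripped (with a warning) before counting; the
    positional profile lists event start columns in the stripped frame.
    Invariant under row reordering.
    """
    if not alignment:
        raise ValueError("empty alignment")
    ncol = len(alignment[0])
    if any(len(row) != ncol for row in alignment):
        raise ValueError("alignment rows must have equal length")
    rows = [row.upper() for row in alignment]
    all_gap = [c for c in range(ncol) if all(row[c] == "-" for row in rows)]
    if all_gap:
        warnings.warn(f"stripping {len(all_gap)} all-gap columns", stacklevel=2)
        keep = [c for c in range(ncol) if c not in set(all_gap)]
        rows = ["".join(row[c] for c in keep) for row in rows]
    runs: dict[tuple[int, int], list[int]] = {}
    for r, row in enumerate(rows):
        start = None
        for c, ch in enumerate(row + "X"):  # sentinel closes a trailing run
            if ch == "-":
                if start is None:
                    start = c
            elif start is not None:
                runs.setdefault((start, c), []).append(r)
                start = None
    events = sorted((span, tuple(members)) for span, members in runs.items())
    return IndelReport(
        I=len(events),
        events=events,
        positional_profile=[span[0] for span, _ in events],
        stripped_columns=all_gap,
    )


def group_summary(
    records: Sequence[SeqRecord],
    partitions: Mapping[str, ItsPartition],
    manifest: GroupManifest,
) -> pd.DataFrame:
    """Per-group, per-region descriptive statistics (Table-style analogue).

    For each group and region (ITS, ITS1, 5.8S, ITS2): length min/max/mean,
    SEM, normalized-length mean/SEM, and A/T / G/C content ranges.  Groups
    without members are omitted with a warning.
    """
    by_id = {r.id: r for r in records}
    rows = []
    for group in dict.fromkeys(manifest.groups.values()):
        ids = [i for i in manifest.members(group) if i in by_id and i in partitions]
        if not ids:
            warnings.warn(f"group {group}: no delimited members, omitted", stacklevel=2)
            continue
        per_region: dict[str, dict[str, list[float]]] = {}
        for rid in ids:
            rec, part = by_id[rid], partitions[rid]
            l1, l58, l2 = part.region_lengths()
            a, b = part.its_span
            spans = {
                "ITS": (a, b),
                "ITS1": part.its1,
                "5.8S": part.s5_8,
                "ITS2": part.its2,
            }
            for region, (s, e) in spans.items():
                seg = rec.seq[s:e]
                cs = nucleotide_content(seg)
                d = per_region.setdefault(
                    region, {"len": [], "norm": [], "at": [], "gc": []}
                )
                d["len"].append(e - s)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d["norm"].append(normalized_length(e - s))
                d["at"].append(cs.at_pct)
                d["gc"].append(cs.gc_pct)
        for region, d in per_region.items():
            lens = np.asarray(d["len"], dtype=float)
            norm = np.asarray(d["norm"], dtype=float)
            sem = float(lens.std(ddof=1) / math.sqrt(lens.size)) if lens.size > 1 else 0.0
            nsem = float(norm.std(ddof=1) / math.sqrt(norm.size)) if norm.size > 1 else 0.0
            rows.append(
                {
                    "group": group,
                    "region": region,
                    "n": lens.size,
                    "len_min": int(lens.min()),
                    "len_max": int(lens.max()),
                    "len_mean": float(lens.mean()),
                    "len_sem": sem,
                    "norm_mean": float(norm.mean()),
                    "norm_sem": nsem,
                    "at_min": min(d["at"]),
                    "at_max": max(d["at"]),
                    "gc_min": min(d["gc"]),
                    "gc_max": max(d["gc"]),
                }
            )
    return pd.DataFrame(rows)
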