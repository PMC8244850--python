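"""Constructive synthetic rDNA ITS datasets with known ground truth.

Every record is assembled from designed parts, so the true region
boundaries, proximal-stem pattern, ITS2 secondary structure and model
label are known by construction (design-then-verify, not inverse folding):

* 18S/28S flanks carrying the shipped delimitation motifs; the 5.8S is a
  fixed 157-nt gene whose 3' tail forms the designed proximal stem with
  the 28S head (typical pattern: one free nucleotide per strand, duplex
  energies near the typical dG -19 / dH -147 under the shipped table).
* ITS1 templates per group with designed indel sites (placement modes
  UNIFORM / HEAD / TAIL / BOTH_ENDS) producing the group length ranges
  (*Ampelomyces* 182-193 bp; putative groups ~139-143 bp).
* ITS2 built from four reverse-complementary stem pairs plus linkers
  carrying each structural model's diagnostic ring and helix III motif,
  so that MFE folding recovers a four-helix structure of the target model.

Within-group divergence (default 1%) is applied compensatorily: paired
positions mutate with their partner to another Watson-Crick pair, loop
positions mutate only between non-pairing bases, and diagnostic motifs,
rings and anchor motifs are never touched - mirroring the structural
conservation the analysis itself relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .its_delimit import (
    DEFAULT_MOTIF_18S_END,
    DEFAULT_MOTIF_5_8S_START,
)
from .sequence_io import (
    GROUP_LABELS,
    GroupManifest,
    SeqRecord,
    write_fasta,
    write_manifest,
    write_table,
)

__all__ = [
    "GroupSpec",
    "StudyConfig",
    "StudyData",
    "TruthRecord",
    "its2_template",
    "generate_record",
    "generate_study",
    "default_study_config",
    "AMPELOMYCES_MODEL_WEIGHTS",
]

_RC = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Fixed flanks and 5.8S gene

FLANK_18S = "CTTG" + DEFAULT_MOTIF_18S_END                      # 20 nt
# Proximal-stem design (frozen): 5.8S 3' arm + one free nt, 28S head =
# one free nt + near-complement of the arm with a planted 1x1 mismatch.
_STEM_ARM_5_8S = "AATCTATCTGTGAGAAGATG"
_STEM_ARM_28S = "CATCTTGTCACCGATAGATT"
_TAIL_FILLER = "ACCACAACCAACC"
FLANK_28S = ("A" + _STEM_ARM_28S + "CAACCACCA")                 # 30 nt

def _fixed_mid(n: int = 103) -> str:
    # Fixed 5.8S interior filler (deterministic, moderate A/T content).
    rng = np.random.default_rng(7)
    return "".join(rng.choice(list("ATGC"), size=n, p=[0.28, 0.27, 0.23, 0.22]))


_5_8S_MID = _fixed_mid()


def _make_5_8s() -> str:
    gene = DEFAULT_MOTIF_5_8S_START + _5_8S_MID + _TAIL_FILLER + _STEM_ARM_5_8S + "A"
    assert len(gene) == 157, len(gene)
    return gene


S5_8_GENE = _make_5_8s()

# Protected 5.8S positions: the start anchor and the whole stem tail.
_5_8S_PROTECT_FROM = len(DEFAULT_MOTIF_5_8S_START) + len(_5_8S_MID)


# ---------------------------------------------------------------------------
# ITS2 structural model templates


@dataclass
class Its2Template:
    """A designed ITS2: sequence, target structure, protected positions."""

    model: str
    seq: str
    db: str
    protected: np.ndarray       # bool per position: never substituted
    ring: str                   # diagnostic ring I-IV signature
    helixIII_motif: str | None


def _helix(
    segs: list[str],
    gaps: list[tuple[str, str]],
    tloop: str,
    protect_seg: set[int] = frozenset(),
) -> tuple[str, str, list[bool]]:
    """Render a stem-loop: seg_i paired with its reverse complement,
    interrupted by (5'-side, 3'-side) unpaired gap strings."""
    assert len(gaps) == len(segs) - 1

    def build(i: int) -> tuple[str, str, list[bool]]:
        s = segs[i]
        prot = i in protect_seg
        if i == len(segs) - 1:
            inner_s = tloop
            inner_d = "." * len(tloop)
            inner_p = [False] * len(tloop)
        else:
            g5, g3 = gaps[i]
            core_s, core_d, core_p = build(i + 1)
            inner_s = g5 + core_s + g3
            inner_d = "." * len(g5) + core_d + "." * len(g3)
            inner_p = [False] * len(g5) + core_p + [False] * len(g3)
        seq = s + inner_s + _rc(s)
        db = "(" * len(s) + inner_d + ")" * len(s)
        pr = [prot] * len(s) + inner_p + [prot] * len(s)
        return seq, db, pr

    return build(0)


def _assemble(
    model: str,
    leader: str,
    parts: list[tuple[str, str, list[bool]]],
    spacers: list[str],
    trailer: str,
    ring: str,
    motif: str | None,
    protect_spacers: bool = True,
) -> Its2Template:
    seq, db, prot = leader, "." * len(leader), [False] * len(leader)
    for i, (hs, hd, hp) in enumerate(parts):
        seq += hs
        db += hd
        prot += hp
        if i < len(spacers):
            sp = spacers[i]
            seq += sp
            db += "." * len(sp)
            prot += [protect_spacers] * len(sp)
    seq += trailer
    db += "." * len(trailer)
    prot += [True] * len(trailer)
    return Its2Template(
        model=model,
        seq=seq,
        db=db,
        protected=np.asarray(prot, dtype=bool),
        ring=ring,
        helixIII_motif=motif,
    )


def _pad(n: int) -> str:
    return ("ACCACAACCACACCA" * 4)[:n]


# All templates share one sequence skeleton (helix vocabularies derived
# from the Model-1 letters by small per-template edits) so that the
# intra-Ampelomyces sequence divergence stays below the Ampelomyces-vs-
# putative divergence by construction: the designed barcode gap.  The
# motif-bearing helix III segments are protected from substitution.
_S3_M1 = ["GCAGC", "CTGGC", "GTCGC", "CACGG", "GCGAC", "CAGGC"]
_AA = ("A", "A")


def _build_templates() -> dict[str, Its2Template]:
    t: dict[str, Its2Template] = {}
    h1 = _helix(["GGCAGCAG"], [], "CAAA")
    h2_uu = _helix(["GGACC", "GCAG"], [("T", "T")], "ACAACA")
    h4 = _helix(["GGCTGC"], [], "AACC")

    # --- M1 family: GTACCC ring, UGG on helix III, U-U on helix II.
    h3_m1 = _helix(_S3_M1, [_AA] * 5, "ACACAA", protect_seg={1})
    t["M1"] = _assemble(
        "M1", _pad(2), [h1, h2_uu, h3_m1, h4], ["CA", "AT", "CA"],
        "GTACCC", "GTACCC", "UGG",
    )
    s3_m7 = _S3_M1.copy()
    s3_m7[1] = "TTGGC"
    h3_m7 = _helix(s3_m7, [_AA] * 5, "ACACAA", protect_seg={1})
    t["M7"] = _assemble(
        "M7", _pad(2), [h1, h2_uu, h3_m7, _helix(["GGCTGC"], [], "AACA")],
        ["CA", "AT", "CA"], "GTACCC", "GTACCC", "UGG",
    )
    h2_bulge = _helix(["GGACC", "GCAG"], [("T", "")], "ACAACA")
    t["M1-2"] = _assemble(
        "M1-2", _pad(2), [h1, h2_bulge, h3_m1, h4], ["CA", "AT", "CA"],
        "GTACCC", "GTACCC", "UGG",
    )
    t["M1-3"] = _assemble(
        "M1-3", _pad(2), [h1, h2_uu, h3_m1, h4], ["CA", "ATC", "CCA"],
        "GTACCC", "GTACCC", "UGG",
    )

    # --- M2/M3: GTCTCC ring, UGGU+UU on helix III, 12-nt helix II loop.
    s3_m2 = ["GCAGC", "CTGGTC", "GTTGC", "CACGG", "GCGAC"]
    h2_m2 = _helix(["GGACC", "GCAG", "GCG"], [("T", "T"), ("C", "")],
                   "ACAACAACAACA")
    h3_m2 = _helix(s3_m2, [_AA, _AA, ("A", ""), ("", "A")], "ACACAA",
                   protect_seg={1, 2})
    t["M2"] = _assemble(
        "M2", _pad(2), [h1, h2_m2, h3_m2, h4], ["CA", "A", "AA"],
        "GTCTCC", "GTCTCC", "UGGU+UU",
    )
    h3_m3 = _helix(s3_m2, [("A", ""), ("", "A"), ("A", ""), ("", "A")],
                   "ACACAA", protect_seg={1, 2})
    t["M3"] = _assemble(
        "M3", _pad(4), [h1, h2_m2, h3_m3, h4], ["CA", "A", "AA"],
        "GTCTCC", "GTCTCC", "UGGU+UU",
    )

    # --- M4/M5/M6: A-rich II-III spacer, UGGU, internal loop on helix I.
    h1_il = _helix(["GGCA", "GCAG"], [_AA], "CAAA")
    s3_m4 = ["GCAGC", "CTGGTC", "GTCGC", "CACGG", "GCGAC"]
    h3_m4 = _helix(s3_m4, [_AA] * 4, "ACACAA", protect_seg={1})
    t["M4"] = _assemble(
        "M4", _pad(8), [h1_il, h2_uu, h3_m4, h4], ["CA", "AAAA", "CA"],
        "ACCAAC", None, "UGGU",
    )
    h3_m5 = _helix(s3_m4, [_AA, _AA, ("A", ""), ("", "A")], "ACACAA",
                   protect_seg={1})
    t["M5"] = _assemble(
        "M5", _pad(8), [h1_il, h2_uu, h3_m5, h4], ["CA", "AAAA", "CA"],
        "ACCAAC", None, "UGGU",
    )
    # The 3-bp helix IV stack is diagnostic for M6: protected.
    h4_m6 = _helix(["GCG"], [], "CCC", protect_seg={0})
    t["M6"] = _assemble(
        "M6", _pad(18), [h1_il, h2_uu, h3_m4, h4_m6], ["CA", "AAAA", "CA"],
        "ACCAAC", None, "UGGU",
    )

    # --- Putative pattern: TCCATG ring, U-U only, no helix III motif.
    # Same skeleton, three divergence directions; the helix III
    # vocabularies avoid TGG on either arm.
    def putative(h1seg: str, h2segs: list[str], segs3: list[str],
                 h4seg: str, h1_tl: str, leader: int, trailer: str) -> Its2Template:
        ph1 = _helix([h1seg], [], h1_tl)
        # The short inner helix II segment is marginal: protected so
        # compensatory AU swaps cannot melt the stem.
        ph2 = _helix(h2segs, [("T", "T")], "ACAACA", protect_seg={1})
        ph3 = _helix(segs3, [_AA] * (len(segs3) - 1), "ACAACAACAA")
        ph4 = _helix([h4seg], [], "AACC")
        return _assemble(
            "PUTATIVE", _pad(leader), [ph1, ph2, ph3, ph4], ["CA", "CA", "CC"],
            trailer, "TCCATG", None,
        )

    t["PUT_G1"] = putative(
        "GCGTACAG", ["GCTCC", "GTAG"],
        ["GCATC", "CTGAC", "GACGC", "CTCGG", "GGGAC", "CATCC"],
        "GTCACC", "CAAA", 3, "TCCATG",
    )
    t["PUT_G2"] = putative(
        "GGATGGAG", ["GGTCC", "GCAC"],
        ["GCAGG", "CTACC", "GCCGC", "CACCG", "GCGTC", "GAGGC"],
        "GAGTGC", "CACA", 3, "TCCATG",
    )
    t["PUT_OG"] = putative(
        "GCCATGAG", ["GTACC", "GACG"],
        ["GCACC", "CTGCC", "GTCCC", "CAGGG", "GCCGC", "CATGC"],
        "GAGTCC", "CAAC", 2, "TCCACG",
    )
    return t


_TEMPLATES: dict[str, Its2Template] | None = None


def its2_template(name: str) -> Its2Template:
    """The designed ITS2 template for a model (M1..M7) or putative group."""
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = _build_templates()
    return _TEMPLATES[name]


# ---------------------------------------------------------------------------
# ITS1 templates with designed indel sites


def _rand_seq(rng: np.random.Generator, n: int, at: float) -> str:
    p_at = at / 2.0
    p_gc = (1.0 - at) / 2.0
    return "".join(rng.choice(list("ATGC"), size=n, p=[p_at, p_at, p_gc, p_gc]))


@dataclass(frozen=True)
class IndelSite:
    pos: int      # template coordinate of the deletion start
    length: int


def _site_positions(mode: str, n_sites: int, tpl_len: int,
                    rng: np.random.Generator) -> list[int]:
    if mode == "UNIFORM":
        lo, hi = 15, tpl_len - 20
    elif mode == "HEAD":
        lo, hi = 10, min(100, tpl_len - 20)
    elif mode == "TAIL":
        lo, hi = max(15, tpl_len - 80), tpl_len - 15
    elif mode == "BOTH_ENDS":
        half = n_sites // 2
        head = _site_positions("HEAD", half, tpl_len, rng)
        tail = _site_positions("TAIL", n_sites - half, tpl_len, rng)
        return sorted(head + tail)
    else:
        raise ValueError(f"unknown indel placement mode {mode!r}")
    span = (hi - lo) // max(n_sites, 1)
    return [lo + i * span + int(rng.integers(0, max(span - 8, 1))) for i in range(n_sites)]


@dataclass
class Its1Design:
    template: str
    poly_sites: list[IndelSite]       # polymorphic within the group
    fixed_deletions: list[IndelSite]  # applied to every record


_ITS1_DESIGNS: dict[str, Its1Design] | None = None


def _build_its1_designs() -> dict[str, Its1Design]:
    rng = np.random.default_rng(20210630)
    # A/T-rich ITS1 balances the GC-rich designed ITS2 stems so the whole
    # ITS lands in the reported Ampelomyces A/T band (54.05-58.92%).
    amp_tpl = _rand_seq(rng, 193, at=0.72)
    base = _rand_seq(rng, 143, at=0.58)  # shared putative/outgroup backbone

    def unambiguous(tpl: str, pos: int, length: int) -> int:
        # Nudge a deletion start so the gap cannot slide during alignment
        # (deleted run must differ from both flanking characters).
        for q in range(pos, min(pos + 12, len(tpl) - length - 2)):
            if tpl[q - 1] != tpl[q + length - 1] and tpl[q] != tpl[q + length]:
                return q
        return pos

    amp_pos = _site_positions("UNIFORM", 8, 193, rng)
    amp_lens = [1, 2, 1, 2, 1, 2, 1, 1]
    amp_sites = [
        IndelSite(unambiguous(amp_tpl, p, l), l)
        for p, l in zip(amp_pos, amp_lens)
    ]

    # Putative/outgroup designed events (6 total in the combined alignment):
    # G1: three polymorphic sites; G2: one fixed + one polymorphic;
    # outgroup: one fixed 4-nt deletion.
    g1_sites = [IndelSite(unambiguous(base, p, l), l)
                for p, l in [(25, 1), (60, 1), (95, 2)]]
    g2_fixed = [IndelSite(unambiguous(base, 40, 1), 1)]
    g2_sites = [IndelSite(unambiguous(base, 110, 2), 2)]
    og_fixed = [IndelSite(unambiguous(base, 75, 4), 4)]

    all_sites = g1_sites + g2_fixed + g2_sites + og_fixed
    site_guard = {
        q for s in all_sites for q in range(s.pos - 3, s.pos + s.length + 3)
    }

    def mutate(tpl: str, rate: float, seed: int) -> str:
        # Between-group template divergence; indel-site flanks stay
        # conserved so the combined alignment keeps the designed events.
        r = np.random.default_rng(seed)
        out = list(tpl)
        for i in range(len(out)):
            if i in site_guard:
                continue
            if r.random() < rate:
                out[i] = r.choice([b for b in "ACGT" if b != out[i]])
        return "".join(out)

    return {
        "AMPELOMYCES": Its1Design(amp_tpl, amp_sites, []),
        "PUTATIVE_G1": Its1Design(base, g1_sites, []),
        "PUTATIVE_G2": Its1Design(mutate(base, 0.06, 11), g2_sites, g2_fixed),
        "OUTGROUP": Its1Design(mutate(base, 0.10, 12), [], og_fixed),
    }


def its1_design(group: str) -> Its1Design:
    global _ITS1_DESIGNS
    if _ITS1_DESIGNS is None:
        _ITS1_DESIGNS = _build_its1_designs()
    return _ITS1_DESIGNS[group]


def _apply_deletions(tpl: str, sites: list[IndelSite]) -> str:
    out = tpl
    for site in sorted(sites, key=lambda s: -s.pos):
        out = out[: site.pos] + out[site.pos + site.length :]
    return out


# ---------------------------------------------------------------------------
# Group and study specifications

#: Default structural-model mix of the Ampelomyces sensu stricto group,
#: emulating the dominance of Model 1 with rarer alternative models.
AMPELOMYCES_MODEL_WEIGHTS = {
    "M1": 0.58, "M1-2": 0.04, "M1-3": 0.04, "M7": 0.04,
    "M2": 0.12, "M3": 0.02, "M4": 0.06, "M5": 0.02, "M6": 0.08,
}


@dataclass
class GroupSpec:
    """Generator settings for one study group."""

    label: str
    n: int
    its2_templates: dict[str, float]    # template name -> weight
    indel_mode: str = "UNIFORM"
    divergence: float = 0.01            # within-group substitution rate
    s5_8_divergence: float = 0.002
    stem_variant_rate: float = 0.0      # three-free-nucleotide stem variants
    short_28s_rate: float = 0.0         # records with truncated 28S flank
    s5_8_len_poly: bool = False         # optional 1-nt 5.8S deletion (G1)
    its2_leader_del: int = 0            # optional leader deletion (G2 range)
    its_total_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.label!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.its2_templates:
            raise ValueError("need at least one ITS2 template")
        for name in self.its2_templates:
            if len(its2_template(name).seq) < 10:
                raise ValueError(f"infeasible template {name}")


@dataclass
class StudyConfig:
    """A full synthetic study: group specs, flank lengths, master seed."""

    groups: list[GroupSpec]
    flank_18s: int = 20
    flank_28s: int = 30
    master_seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate group labels")


def default_study_config(
    n_ampelomyces: int = 376, master_seed: int = 0
) -> StudyConfig:
    """The default four-group study mirroring the reported group layout."""
    return StudyConfig(
        groups=[
            GroupSpec(
                "AMPELOMYCES", n_ampelomyces, dict(AMPELOMYCES_MODEL_WEIGHTS),
                stem_variant_rate=0.02, its_total_range=(492, 502),
            ),
            GroupSpec("PUTATIVE_G1", 5, {"PUT_G1": 1.0}, s5_8_len_poly=True),
            GroupSpec("PUTATIVE_G2", 5, {"PUT_G2": 1.0}, its2_leader_del=9,
                      its_total_range=(446, 456)),
            GroupSpec("OUTGROUP", 5, {"PUT_OG": 1.0}),
        ],
        master_seed=master_seed,
    )


@dataclass
class TruthRecord:
    """Planted ground truth for one generated record."""

    id: str
    group: str
    template: str
    model: str
    its1: tuple[int, int]
    s5_8: tuple[int, int]
    its2: tuple[int, int]
    its2_db: str
    ring: str
    helixIII_motif: str | None
    stem_pattern: str


@dataclass
class StudyData:
    records: list[SeqRecord]
    manifest: GroupManifest
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": t.id,
                "group": t.group,
                "template": t.template,
                "model": t.model,
                "its1_start": t.its1[0], "its1_end": t.its1[1],
                "s5_8_start": t.s5_8[0], "s5_8_end": t.s5_8[1],
                "its2_start": t.its2[0], "its2_end": t.its2[1],
                "its2_db": t.its2_db,
                "ring": t.ring,
                "helixIII_motif": t.helixIII_motif or "",
                "stem_pattern": t.stem_pattern,
            }
            for t in self.truth
        )


def _choose_template(spec: GroupSpec, rng: np.random.Generator) -> str:
    names = sorted(spec.its2_templates)
    w = np.array([spec.its2_templates[k] for k in names], dtype=float)
    return names[int(rng.choice(len(names), p=w / w.sum()))]


def _motif_signature(seq: str) -> tuple[int, int, int]:
    # Diagnostic motif census: substitutions must not create or destroy
    # helix III motif contexts anywhere in the spacer.
    return (seq.count("TGG"), seq.count("TGGT"), seq.count("TTGG"))


def _substitute_its2(tpl: Its2Template, rate: float,
                     rng: np.random.Generator) -> str:
    """Structure- and motif-preserving substitutions on an ITS2 template."""
    from .structure2d import pair_map

    seq = list(tpl.seq)
    pm = pair_map(tpl.db)
    n = len(seq)
    n_events = rng.binomial(n, rate)
    pairs = {"GC", "CG", "AT", "TA"}
    sig = _motif_signature(tpl.seq)
    for _ in range(n_events):
        i = int(rng.integers(0, n))
        if tpl.protected[i]:
            continue
        j = pm[i]
        if j >= 0:
            if tpl.protected[j]:
                continue
            cur = seq[i] + seq[j]
            options = sorted(pairs - {cur})
            pick = options[int(rng.integers(0, len(options)))]
            trial = list(seq)
            trial[i], trial[j] = pick[0], pick[1]
        elif seq[i] in "AC":
            trial = list(seq)
            trial[i] = "C" if seq[i] == "A" else "A"
        else:
            continue
        if _motif_signature("".join(trial)) == sig:
            seq = trial
    return "".join(seq)


def _substitute_plain(seq: str, rate: float, rng: np.random.Generator,
                      protect: tuple[int, int] | None = None,
                      protect_sites: frozenset[int] = frozenset()) -> str:
    out = list(seq)
    n_events = rng.binomial(len(out), rate)
    for _ in range(n_events):
        i = int(rng.integers(0, len(out)))
        if protect and protect[0] <= i < protect[1]:
            continue
        if i in protect_sites:
            continue
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def generate_record(
    spec: GroupSpec,
    index: int,
    rng: np.random.Generator,
    flank_18s: int = 20,
    flank_28s: int = 30,
) -> tuple[SeqRecord, TruthRecord]:
    """Generate one record plus its planted ground truth.

    Identical (spec, index, rng state) inputs produce identical records.
    """
    design = its1_design(spec.label)
    tpl_name = _choose_template(spec, rng)
    tpl = its2_template(tpl_name)

    for _attempt in range(50):
        state = rng.bit_generator.state  # retry draws stay reproducible
        on = [s for s in design.poly_sites if rng.random() < 0.5]
        # Substitute on template coordinates first (indel-site flanks are
        # conserved so alignment gaps land on the designed columns), then
        # apply the deletions.
        guard = frozenset(
            q
            for s in design.poly_sites + design.fixed_deletions
            for q in range(s.pos - 3, s.pos + s.length + 3)
        )
        its1 = _substitute_plain(design.template, spec.divergence, rng,
                                 protect_sites=guard)
        its1 = _apply_deletions(its1, design.fixed_deletions + on)

        its2_seq = _substitute_its2(tpl, spec.divergence, rng)
        its2_db = tpl.db
        if spec.its2_leader_del and rng.random() < 0.5:
            k = spec.its2_leader_del
            its2_seq, its2_db = its2_seq[k:], tpl.db[k:]

        s58 = S5_8_GENE
        if spec.s5_8_len_poly and rng.random() < 0.5:
            mid = len(DEFAULT_MOTIF_5_8S_START) + 40
            s58 = s58[:mid] + s58[mid + 1 :]
        s58 = _substitute_plain(
            s58, spec.s5_8_divergence, rng,
            protect=(_5_8S_PROTECT_FROM - 20, len(s58)),
        )
        stem_pattern = "TYPICAL"
        if rng.random() < spec.stem_variant_rate:
            # Break the last two stem pairs: three free nts on each strand.
            s58 = s58[:-3] + "CC" + s58[-1]
            stem_pattern = "VARIANT_MULTI_FREE"

        f28 = FLANK_28S[:flank_28s]
        if rng.random() < spec.short_28s_rate:
            f28 = FLANK_28S[:8]
            stem_pattern = "UNMODELABLE"
        f18 = FLANK_18S[-flank_18s:] if flank_18s else ""

        total_its = len(its1) + len(s58) + len(its2_seq)
        if spec.its_total_range is not None:
            lo, hi = spec.its_total_range
            if not (lo <= total_its <= hi):
                rng.bit_generator.state = state
                _ = rng.random()  # advance so the retry explores new draws
                continue
        break
    else:
        raise RuntimeError(f"could not satisfy ITS length range for {spec.label}")

    seq = f18 + its1 + s58 + its2_seq + f28
    a = len(f18)
    b = a + len(its1)
    c = b + len(s58)
    d = c + len(its2_seq)
    prefix = {"AMPELOMYCES": "AMP", "PUTATIVE_G1": "PG1",
              "PUTATIVE_G2": "PG2", "OUTGROUP": "OUT"}[spec.label]
    rec_id = f"SYN{prefix}{index:04d}"
    rec = SeqRecord(id=rec_id, seq=seq, description=f"synthetic {spec.label}",
                    group=spec.label)
    truth = TruthRecord(
        id=rec_id,
        group=spec.label,
        template=tpl_name,
        model=tpl.model,
        its1=(a, b),
        s5_8=(b, c),
        its2=(c, d),
        its2_db=its2_db,
        ring=tpl.ring,
        helixIII_motif=tpl.helixIII_motif,
        stem_pattern=stem_pattern if len(f28) >= 25 else "UNMODELABLE",
    )
    return rec, truth


def generate_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> StudyData:
    """Generate the full labeled dataset; optionally write it to *out_dir*.

    On disk: ``sequences.fasta``, ``manifest.tsv`` and ``truth.tsv``.
    Byte-identical for a fixed master seed.
    """
    records: list[SeqRecord] = []
    truths: list[TruthRecord] = []
    groups: dict[str, str] = {}
    for gi, spec in enumerate(cfg.groups):
        for i in range(spec.n):
            rng = np.random.default_rng([cfg.master_seed, gi, i])
            rec, truth = generate_record(
                spec, i, rng, flank_18s=cfg.flank_18s, flank_28s=cfg.flank_28s
            )
            records.append(rec)
            truths.append(truth)
            groups[rec.id] = spec.label
    manifest = GroupManifest(
        groups=groups,
        provenance={r.id: "synthetic" for r in records},
    )
    data = StudyData(records=records, manifest=manifest, truth=truths)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "sequences.fasta")
        write_manifest(manifest, out / "manifest.tsv")
        frame = data.truth_frame()
        write_table(
            frame.values.tolist(), out / "truth.tsv", header=list(frame.columns)
        )
    return data
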