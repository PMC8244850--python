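"""Nearest-neighbor RNA thermodynamic parameters (37 degC, kcal/mol).

A simplified Turner-2004-style set, version-tagged so reports can record
which table produced a given energy.  Watson-Crick stack free energies and
enthalpies follow Xia et al. (1998); stacks involving G-U wobble pairs are
represented by flat class values (one wobble / two wobbles) rather than the
full sequence-dependent wobble tables.  Loop penalties are tabulated for
small sizes and extrapolated with the 1.75*R*T Jacobson-Stockmayer term.

These parameters feed both the proximal-stem duplex model (its_delimit) and
the single-strand MFE folding engine (structure2d).
"""

from __future__ import annotations

import math

import numpy as np

PARAM_VERSION = "its2kit-nn-1.0 (Xia98 WC stacks, flat wobble, simplified loops)"

TEMPERATURE_C = 37.0
_RT = 0.0019872 * (273.15 + TEMPERATURE_C)  # kcal/mol
_LOOP_EXTRAP = 1.75 * _RT  # Jacobson-Stockmayer prefactor, ~1.08 kcal/mol

# Base encoding used by the folding kernels: A=0, C=1, G=2, U=3.
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Pair types: 0 = unpairable, then AU, UA, CG, GC, GU, UG.
PAIR_NAMES = ("-", "AU", "UA", "CG", "GC", "GU", "UG")
N_PAIR = 7

PAIR_TYPE = np.zeros((4, 4), dtype=np.int64)
for _pt, (_a, _b) in enumerate(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")], start=1
):
    PAIR_TYPE[BASE_INDEX[_a], BASE_INDEX[_b]] = _pt

_FLIP = (0, 2, 1, 4, 3, 6, 5)  # AU<->UA, CG<->GC, GU<->UG

# Watson-Crick stack dG37 / dH keyed by (outer pair, inner pair): the stack
# 5'-WX-3' / 3'-ZY-5' has outer pair W-Z and inner pair X-Y.
_WC_STACKS = {
    ("AU", "AU"): (-0.93, -6.82),   # 5'AA/3'UU
    ("AU", "UA"): (-1.10, -9.38),   # 5'AU/3'UA
    ("UA", "AU"): (-1.33, -7.69),   # 5'UA/3'AU
    ("CG", "UA"): (-2.08, -10.48),  # 5'CU/3'GA
    ("CG", "AU"): (-2.11, -10.44),  # 5'CA/3'GU
    ("GC", "UA"): (-2.24, -11.40),  # 5'GU/3'CA
    ("GC", "AU"): (-2.35, -12.44),  # 5'GA/3'CU
    ("CG", "GC"): (-2.36, -10.64),  # 5'CG/3'GC
    ("GC", "GC"): (-3.26, -13.39),  # 5'GG/3'CC
    ("GC", "CG"): (-3.42, -14.88),  # 5'GC/3'CG
}

_WOBBLE_ONE = (-1.30, -8.00)   # stack with exactly one G-U pair
_WOBBLE_TWO = (-0.50, -4.00)   # stack with two G-U pairs

STACK_DG = np.full((N_PAIR, N_PAIR), np.inf)
STACK_DH = np.full((N_PAIR, N_PAIR), np.inf)

_name_to_idx = {n: i for i, n in enumerate(PAIR_NAMES)}
for (outer, inner), (dg, dh) in _WC_STACKS.items():
    o, i = _name_to_idx[outer], _name_to_idx[inner]
    STACK_DG[o, i] = dg
    STACK_DH[o, i] = dh
    # Reading the duplex from the other strand maps (outer,inner)->(flip(inner),flip(outer)).
    STACK_DG[_FLIP[i], _FLIP[o]] = dg
    STACK_DH[_FLIP[i], _FLIP[o]] = dh
for o in range(1, N_PAIR):
    for i in range(1, N_PAIR):
        wob = (o >= 5) + (i >= 5)
        if wob == 1:
            STACK_DG[o, i], STACK_DH[o, i] = _WOBBLE_ONE
        elif wob == 2:
            STACK_DG[o, i], STACK_DH[o, i] = _WOBBLE_TWO

# Duplex initiation and terminal AU/GU penalty (Xia et al. 1998).
DUPLEX_INIT_DG, DUPLEX_INIT_DH = 4.09, 3.61
TERMINAL_AU_DG, TERMINAL_AU_DH = 0.45, 3.72

# ---------------------------------------------------------------------------
# Loop penalties (dG37).  Tabulated up to the listed size, then extrapolated.

_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL = {2: 1.5, 3: 2.0, 4: 2.5, 5: 3.0, 6: 3.5}

INTERNAL_ASYMMETRY = 0.5   # per unpaired-nt asymmetry, capped
INTERNAL_ASYMMETRY_MAX = 3.0

# Multibranch (affine): closing a multiloop costs A + B per branch
# (closing pair included) + C per unpaired nt.
MULTI_A, MULTI_B, MULTI_C = 3.4, 0.4, 0.0

MIN_HAIRPIN = 3          # smallest hairpin loop
MAX_INTERIOR = 30        # largest interior/bulge loop handled by the DP


def _tabulated(table: dict[int, float], n: int) -> float:
    if n in table:
        return table[n]
    nmax = max(table)
    return table[nmax] + _LOOP_EXTRAP * math.log(n / nmax)


def hairpin_dg(size: int) -> float:
    """Hairpin-loop closure penalty for *size* unpaired nucleotides."""
    if size < MIN_HAIRPIN:
        return math.inf
    return _tabulated(_HAIRPIN, size)


def bulge_dg(size: int) -> float:
    if size < 1:
        raise ValueError("bulge size must be >= 1")
    return _tabulated(_BULGE, size)


def internal_dg(n1: int, n2: int) -> float:
    """Internal-loop penalty with linear (capped) asymmetry term."""
    if n1 < 1 or n2 < 1:
        raise ValueError("internal loop needs unpaired nts on both sides")
    asym = min(INTERNAL_ASYMMETRY * abs(n1 - n2), INTERNAL_ASYMMETRY_MAX)
    return _tabulated(_INTERNAL, n1 + n2) + asym


def loop_dg(n1: int, n2: int) -> float:
    """Penalty for the interior loop with n1/n2 unpaired nts per side.

    (0,0) is a stack and has no loop term.
    """
    if n1 == 0 and n2 == 0:
        return 0.0
    if n1 == 0 or n2 == 0:
        return bulge_dg(max(n1, n2))
    return internal_dg(n1, n2)


# Dense lookup for the jit kernel: LOOP_TABLE[n1, n2] for n1,n2 <= MAX_INTERIOR.
LOOP_TABLE = np.zeros((MAX_INTERIOR + 1, MAX_INTERIOR + 1))
for _n1 in range(MAX_INTERIOR + 1):
    for _n2 in range(MAX_INTERIOR + 1):
        if _n1 + _n2 > 0:
            LOOP_TABLE[_n1, _n2] = loop_dg(_n1, _n2)

HAIRPIN_TABLE = np.array([hairpin_dg(n) if n >= MIN_HAIRPIN else np.inf for n in range(512)])


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string (T folded to U) as int codes A=0,C=1,G=2,U=3."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq.upper().replace("T", "U")):
        if ch not in BASE_INDEX:
            raise ValueError(f"non-RNA symbol {ch!r} at position {i}")
        out[i] = BASE_INDEX[ch]
    return out


def can_pair(a: str, b: str) -> bool:
    return PAIR_TYPE[BASE_INDEX[a.replace("T", "U")], BASE_INDEX[b.replace("T", "U")]] != 0
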