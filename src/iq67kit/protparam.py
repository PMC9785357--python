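"""Protein physicochemical properties: molecular weight, net charge, pI.

Average (not monoisotopic) residue masses and the Bjellqvist pKa set are
used, matching the ExPASy ProtParam conventions, so values are directly
comparable with the printed family tables. The theoretical pI is found by
bisection on the Henderson–Hasselbalch net-charge function, which is
strictly decreasing in pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .records import STANDARD_RESIDUES, validate_sequence

# Average residue masses (Da), ExPASy convention.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.0153
_MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

# Bjellqvist pKa values (as used by ExPASy Compute pI).
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
# Residue-specific terminal pKa corrections.
PKA_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                 "V": 7.44, "E": 7.7}
PKA_CTERMINAL = {"D": 4.55, "E": 4.75}

BASIC_RESIDUES = frozenset("KRH")


def _check_standard(seq: str, allow_x: bool) -> None:
    validate_sequence(seq)
    if not seq:
        raise ValueError("empty sequence")
    if not allow_x:
        for i, ch in enumerate(seq):
            if ch not in STANDARD_RESIDUES:
                raise ValueError(
                    f"non-standard residue {ch!r} at position {i + 1} (1-based)"
                )


def molecular_weight(seq: str, allow_x: bool = False) -> float:
    """Average molecular mass in Dalton: residue masses plus one water.

    ``X`` residues raise by default; with ``allow_x`` they contribute the
    mean residue mass.
    """
    _check_standard(seq, allow_x)
    return sum(RESIDUE_MASS.get(ch, _MEAN_RESIDUE_MASS) for ch in seq) + WATER_MASS


def net_charge(seq: str, pH: float, allow_x: bool = True) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Sums the N-terminus, C-terminus and ionizable side chains (D, E, C, Y,
    K, R, H). Strictly decreasing in pH.
    """
    if not 0.0 < pH < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    _check_standard(seq, allow_x)

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    charge = pos(PKA_NTERMINAL.get(seq[0], PKA_POSITIVE["Nterm"]))
    charge += neg(PKA_CTERMINAL.get(seq[-1], PKA_NEGATIVE["Cterm"]))
    for ch in seq:
        if ch in ("K", "R", "H"):
            charge += pos(PKA_POSITIVE[ch])
        elif ch in ("D", "E", "C", "Y"):
            charge += neg(PKA_NEGATIVE[ch])
    return charge


def isoelectric_point(seq: str, tol: float = 0.001) -> float:
    """pH of zero net charge, by bisection on [0, 14] to within ``tol``."""
    lo, hi = 1e-9, 14.0 - 1e-9
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def basic_fraction(seq: str) -> float:
    validate_sequence(seq)
    if not seq:
        raise ValueError("empty sequence")
    return sum(ch in BASIC_RESIDUES for ch in seq) / len(seq)


def orf_to_protein_length(orf_bp: int) -> int:
    """Protein length (aa) from the ORF nucleotide span including its stop codon."""
    if orf_bp < 6 or orf_bp % 3 != 0:
        raise ValueError(f"ORF length {orf_bp} must be a multiple of 3 and >= 6")
    return orf_bp // 3 - 1


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PhysChemProfile:
    protein_id: str
    length: int
    mw: float          # Dalton
    pi: float          # pH units
    basic_fraction: float


@dataclass(frozen=True)
class FamilySummary:
    n: int
    length_min: int
    length_max: int
    mw_min: float      # kD, 1 decimal in reports
    mw_max: float
    pi_min: float
    pi_max: float
    pi_mean: float     # 2 decimals, half-up


def profile(protein_id: str, seq: str) -> PhysChemProfile:
    return PhysChemProfile(
        protein_id=protein_id,
        length=len(seq),
        mw=molecular_weight(seq, allow_x=True),
        pi=isoelectric_point(seq),
        basic_fraction=basic_fraction(seq),
    )


def profile_table(records) -> pd.DataFrame:
    """Per-protein physicochemistry table (MW reported in kD, 1 decimal)."""
    rows = []
    for rec in records:
        p = profile(rec.id, rec.sequence)
        rows.append({
            "protein_id": p.protein_id,
            "length": p.length,
            "mw_kd": round_half_up(p.mw / 1000.0, 1),
            "pi": round_half_up(p.pi, 2),
            "basic_fraction": round(p.basic_fraction, 4),
        })
    return pd.DataFrame(rows, columns=["protein_id", "length", "mw_kd", "pi", "basic_fraction"])


def summarize_family(
    lengths: Sequence[int] | Iterable[int],
    mw_kd: Sequence[float] | Iterable[float],
    pi: Sequence[float] | Iterable[float],
) -> FamilySummary:
    """Family-level min/max/mean summary of length, MW and pI columns."""
    lengths, mw_kd, pi = list(lengths), list(mw_kd), list(pi)
    if not lengths or len(lengths) != len(mw_kd) or len(lengths) != len(pi):
        raise ValueError("need equal-length, nonempty columns")
    return FamilySummary(
        n=len(lengths),
        length_min=min(lengths),
        length_max=max(lengths),
        mw_min=round_half_up(min(mw_kd), 1),
        mw_max=round_half_up(max(mw_kd), 1),
        pi_min=min(pi),
        pi_max=max(pi),
        pi_mean=round_half_up(sum(pi) / len(pi), 2),
    )


def summarize_table(table: pd.DataFrame) -> FamilySummary:
    """Summary from a (id, orf_bp, aa, mw_kd, pi) table such as a printed family table."""
    return summarize_family(table["aa"].tolist(), table["mw_kd"].tolist(), table["pi"].tolist())
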