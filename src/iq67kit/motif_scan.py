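"""IQ-motif scanning and IQ67-domain assembly.

The IQD/SUN calmodulin-binding family is defined by an IQ67 domain: three IQ
motifs whose two intervening spacers are *exactly* 11 and 15 residues. This
module scans protein sequences for the consensus motifs

* strict IQ        ``IQXXXRGXXXR``                  (11 residues)
* relaxed IQ       ``[ILV]QXXXRXXXR[RK]``           (11 residues)
* '1-8-14'         ``[FILVW]XXXXXX[FAILVW]XXXXX[FILVW]``  (14 residues)
* '1-5-10'         ``[FILVW]XXX[FILV]XXXX[FILVW]``  (10 residues)

assembles candidate IQ67 domains under the exact spacing rule, and classifies
each protein as SUN (has a valid domain), OTHER_IQ (IQ motifs present but no
valid spacing — the Myosin/CaMTA situation), or NONE.

Matching semantics: ``X`` in a *sequence* never satisfies a constrained
consensus position but does satisfy wildcard positions; all overlapping
windows are reported; a window matching both IQ consensi is labelled strict
only. Gaps between motifs count residues strictly between one motif's end and
the next motif's start. Coordinates are 0-based half-open internally and
1-based inclusive in emitted tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import ALLOWED_RESIDUES, ProteinRecord, read_fasta, validate_sequence

DEFAULT_SPACINGS = (11, 15)


class MotifClass(str, enum.Enum):
    IQ_STRICT = "IQ_STRICT"
    IQ_RELAXED = "IQ_RELAXED"
    M_1_8_14 = "M_1_8_14"
    M_1_5_10 = "M_1_5_10"


class Family(str, enum.Enum):
    SUN = "SUN"
    OTHER_IQ = "OTHER_IQ"
    NONE = "NONE"


# Consensus patterns as {offset: allowed residues}; positions absent from the
# mapping are wildcards (any residue incl. X). Span is the motif window width.
_CONSENSUS: dict[MotifClass, tuple[int, dict[int, frozenset[str]]]] = {
    MotifClass.IQ_STRICT: (
        11,
        {0: frozenset("I"), 1: frozenset("Q"), 5: frozenset("R"),
         6: frozenset("G"), 10: frozenset("R")},
    ),
    MotifClass.IQ_RELAXED: (
        11,
        {0: frozenset("ILV"), 1: frozenset("Q"), 5: frozenset("R"),
         9: frozenset("R"), 10: frozenset("RK")},
    ),
    MotifClass.M_1_8_14: (
        14,
        {0: frozenset("FILVW"), 7: frozenset("FAILVW"), 13: frozenset("FILVW")},
    ),
    MotifClass.M_1_5_10: (
        10,
        {0: frozenset("FILVW"), 4: frozenset("FILV"), 9: frozenset("FILVW")},
    ),
}

IQ_CLASSES = (MotifClass.IQ_STRICT, MotifClass.IQ_RELAXED)


@dataclass(frozen=True)
class MotifHit:
    motif_class: MotifClass
    start: int  # 0-based
    end: int    # exclusive
    match: str

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IQ67Domain:
    """Three IQ motifs at the configured exact spacing, with accessory counts."""

    iq_hits: tuple[MotifHit, MotifHit, MotifHit]
    gap1: int
    gap2: int
    domain_start: int
    domain_end: int
    n_1_8_14: int = 0
    n_1_5_10: int = 0

    @property
    def span(self) -> int:
        return self.domain_end - self.domain_start


@dataclass
class FamilyCall:
    protein_id: str
    length: int
    n_iq: int
    n_iq_strict: int
    n_iq_relaxed: int
    n_1_8_14: int
    n_1_5_10: int
    has_iq67: bool
    family: Family
    domains: list[IQ67Domain] = field(default_factory=list)
    notes: str = ""


def matches_consensus(window: str, motif_class: MotifClass) -> bool:
    """Does an exact-width window satisfy the class consensus?

    Constrained positions require membership in the allowed set (X fails);
    wildcard positions accept any allowed residue.
    """
    span, constraints = _CONSENSUS[motif_class]
    if len(window) != span:
        return False
    return all(window[pos] in allowed for pos, allowed in constraints.items())


def _scan(seq: str, motif_class: MotifClass) -> list[MotifHit]:
    span, _ = _CONSENSUS[motif_class]
    hits = []
    for start in range(len(seq) - span + 1):
        window = seq[start : start + span]
        if matches_consensus(window, motif_class):
            hits.append(MotifHit(motif_class, start, start + span, window))
    return hits


def scan_iq(seq: str, allow_relaxed: bool = True) -> list[MotifHit]:
    """All IQ-consensus windows, strict taking precedence over relaxed.

    Every window satisfying the strict pattern is reported as IQ_STRICT; with
    ``allow_relaxed``, windows satisfying only the relaxed pattern are added
    as IQ_RELAXED. Overlapping windows are all reported.
    """
    validate_sequence(seq)
    hits = _scan(seq, MotifClass.IQ_STRICT)
    if allow_relaxed:
        strict_starts = {h.start for h in hits}
        hits += [h for h in _scan(seq, MotifClass.IQ_RELAXED)
                 if h.start not in strict_starts]
    return sorted(hits, key=lambda h: h.start)


def scan_accessory(seq: str) -> list[MotifHit]:
    """All '1-8-14' and '1-5-10' consensus windows."""
    validate_sequence(seq)
    hits = _scan(seq, MotifClass.M_1_8_14) + _scan(seq, MotifClass.M_1_5_10)
    return sorted(hits, key=lambda h: (h.start, h.motif_class.value))


def assemble_iq67(
    hits: Sequence[MotifHit],
    spacings: tuple[int, int] = DEFAULT_SPACINGS,
) -> list[IQ67Domain]:
    """Every ordered triple of IQ hits whose inter-motif gaps equal ``spacings``.

    Gaps count residues strictly between one motif's end and the next motif's
    start. Triples sharing hits are all reported. Accessory-motif counts are
    filled from '1-8-14'/'1-5-10' hits overlapping the domain span.
    """
    if spacings[0] < 0 or spacings[1] < 0:
        raise ValueError("spacings must be nonnegative")
    iq = sorted((h for h in hits if h.motif_class in IQ_CLASSES),
                key=lambda h: h.start)
    accessory = [h for h in hits if h.motif_class not in IQ_CLASSES]
    # index IQ hits by start for direct spacing lookup
    by_start: dict[int, list[MotifHit]] = {}
    for h in iq:
        by_start.setdefault(h.start, []).append(h)
    domains = []
    for h1 in iq:
        for h2 in by_start.get(h1.end + spacings[0], []):
            for h3 in by_start.get(h2.end + spacings[1], []):
                n814 = sum(
                    1 for a in accessory
                    if a.motif_class is MotifClass.M_1_8_14
                    and a.start < h3.end and a.end > h1.start
                )
                n510 = sum(
                    1 for a in accessory
                    if a.motif_class is MotifClass.M_1_5_10
                    and a.start < h3.end and a.end > h1.start
                )
                domains.append(IQ67Domain(
                    iq_hits=(h1, h2, h3),
                    gap1=spacings[0], gap2=spacings[1],
                    domain_start=h1.start, domain_end=h3.end,
                    n_1_8_14=n814, n_1_5_10=n510,
                ))
    return domains


def classify_protein(
    record: ProteinRecord,
    spacings: tuple[int, int] = DEFAULT_SPACINGS,
    allow_relaxed: bool = True,
) -> FamilyCall:
    """Scan, assemble and classify one protein as SUN / OTHER_IQ / NONE.

    A protein with fewer than three IQ motifs, or IQ motifs at the wrong
    spacing, is OTHER_IQ, never SUN — existence of at least one exactly
    spaced IQ67 domain is the family criterion.
    """
    iq_hits = scan_iq(record.sequence, allow_relaxed=allow_relaxed)
    acc_hits = scan_accessory(record.sequence)
    domains = assemble_iq67(iq_hits + acc_hits, spacings=spacings)
    n_iq = len(iq_hits)
    has_iq67 = bool(domains)
    if has_iq67:
        family, notes = Family.SUN, f"{len(domains)} IQ67 domain(s) at spacing {spacings[0]}/{spacings[1]}"
    elif n_iq >= 3:
        family, notes = Family.OTHER_IQ, "IQ motifs present, spacing mismatch"
    elif n_iq >= 1:
        family, notes = Family.OTHER_IQ, f"only {n_iq} IQ motif(s), no IQ67 domain"
    else:
        family, notes = Family.NONE, "no IQ motifs"
    return FamilyCall(
        protein_id=record.id,
        length=record.length,
        n_iq=n_iq,
        n_iq_strict=sum(h.motif_class is MotifClass.IQ_STRICT for h in iq_hits),
        n_iq_relaxed=sum(h.motif_class is MotifClass.IQ_RELAXED for h in iq_hits),
        n_1_8_14=sum(h.motif_class is MotifClass.M_1_8_14 for h in acc_hits),
        n_1_5_10=sum(h.motif_class is MotifClass.M_1_5_10 for h in acc_hits),
        has_iq67=has_iq67,
        family=family,
        domains=domains,
        notes=notes,
    )


def _domain_coords_1based(call: FamilyCall) -> str:
    return ";".join(f"{d.domain_start + 1}-{d.domain_end}" for d in call.domains)


def scan_proteome(
    fasta_path: str | Path,
    spacings: tuple[int, int] = DEFAULT_SPACINGS,
    allow_relaxed: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every record of a FASTA proteome.

    Returns ``(family_calls, motif_hits)`` tables in input order; emitted
    coordinates are 1-based inclusive.
    """
    records = read_fasta(fasta_path)
    return scan_records(records, spacings=spacings, allow_relaxed=allow_relaxed)


def scan_records(
    records: Iterable[ProteinRecord],
    spacings: tuple[int, int] = DEFAULT_SPACINGS,
    allow_relaxed: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    call_rows, hit_rows = [], []
    for rec in records:
        call = classify_protein(rec, spacings=spacings, allow_relaxed=allow_relaxed)
        call_rows.append({
            "protein_id": call.protein_id,
            "length": call.length,
            "n_iq_strict": call.n_iq_strict,
            "n_iq_relaxed": call.n_iq_relaxed,
            "n_1_8_14": call.n_1_8_14,
            "n_1_5_10": call.n_1_5_10,
            "has_iq67": call.has_iq67,
            "family": call.family.value,
            "domain_coords": _domain_coords_1based(call),
            "duf4005": "",  # reserved annotation column, unpopulated
            "notes": call.notes,
        })
        for h in scan_iq(rec.sequence, allow_relaxed) + scan_accessory(rec.sequence):
            hit_rows.append({
                "protein_id": rec.id,
                "motif_class": h.motif_class.value,
                "start": h.start + 1,   # 1-based inclusive
                "end": h.end,
                "match": h.match,
            })
    columns = ["protein_id", "length", "n_iq_strict", "n_iq_relaxed", "n_1_8_14",
               "n_1_5_10", "has_iq67", "family", "domain_coords", "duf4005", "notes"]
    hit_cols = ["protein_id", "motif_class", "start", "end", "match"]
    return (pd.DataFrame(call_rows, columns=columns),
            pd.DataFrame(hit_rows, columns=hit_cols))
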