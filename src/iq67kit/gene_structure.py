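"""Gene models from GFF3 and qualitative exon-length patterns.

Exon lengths, taken in transcription order (ascending coordinates on '+',
descending on '-'), are binned into short / medium / long categories with
configurable absolute thresholds, then matched against the three named
family patterns:

* 3 exons: ``medium—short—long``
* 5 exons: ``short—medium—medium—short—long``
* 6 exons: ``short—medium—medium—short—long—short``

The published family assignment is qualitative (read off structure
diagrams), so the bin boundaries (default 200 / 600 bp) are explicit,
reported configuration rather than anything inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd

DEFAULT_THRESHOLDS = (200, 600)

NAMED_PATTERNS = {
    "medium—short—long": 3,
    "short—medium—medium—short—long": 5,
    "short—medium—medium—short—long—short": 6,
}


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, transcription order
    exon_lengths: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for start, end in self.exons:
            if end < start or start < 1:
                raise ValueError(f"bad exon interval ({start},{end}) in {self.gene_id}")
        object.__setattr__(
            self, "exon_lengths", tuple(e - s + 1 for s, e in self.exons)
        )


@dataclass(frozen=True)
class ExonPattern:
    labels: tuple[str, ...]
    pattern_string: str
    named_match: str | None


def parse_gff3(
    path: str | Path,
    feature: str = "exon",
    transcript_choice: str = "first",
) -> list[GeneModel]:
    """One GeneModel per gene from a GFF3 with gene/mRNA/exon Parent links.

    ``transcript_choice``: 'first' keeps the first mRNA per gene in file
    order; 'longest' keeps the isoform with the largest summed exon length.
    """
    if transcript_choice not in ("first", "longest"):
        raise ValueError(f"unknown transcript choice {transcript_choice!r}")
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        chosen = mrnas[0]
        if transcript_choice == "longest":
            chosen = max(
                mrnas,
                key=lambda m: sum(
                    e.end - e.start + 1
                    for e in db.children(m, featuretype=feature)
                ),
            )
        exons = sorted(
            ((e.start, e.end) for e in db.children(chosen, featuretype=feature)),
            key=lambda iv: iv[0],
        )
        if not exons:
            continue
        if gene.strand == "-":
            exons = exons[::-1]
        models.append(GeneModel(gene_id=gene.id, strand=gene.strand, exons=tuple(exons)))
    return models


def classify_exon_pattern(
    lengths,
    thresholds: tuple[int, int] = DEFAULT_THRESHOLDS,
) -> ExonPattern:
    """Bin exon lengths into short/medium/long and match the named patterns."""
    short_max, medium_max = thresholds
    if not (0 < short_max < medium_max):
        raise ValueError(f"invalid thresholds {thresholds}")
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty exon length list")
    labels = tuple(
        "short" if ln <= short_max else ("medium" if ln <= medium_max else "long")
        for ln in lengths
    )
    pattern = "—".join(labels)
    named = pattern if NAMED_PATTERNS.get(pattern) == len(labels) else None
    return ExonPattern(labels=labels, pattern_string=pattern, named_match=named)


def group_by_pattern(
    models,
    thresholds: tuple[int, int] = DEFAULT_THRESHOLDS,
) -> dict[str, list[str]]:
    """Partition genes by exon pattern string (keys sorted, input order within)."""
    groups: dict[str, list[str]] = {}
    for m in models:
        pat = classify_exon_pattern(m.exon_lengths, thresholds)
        groups.setdefault(pat.pattern_string, []).append(m.gene_id)
    return dict(sorted(groups.items()))


def structure_table(
    models,
    thresholds: tuple[int, int] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    rows = []
    for m in models:
        pat = classify_exon_pattern(m.exon_lengths, thresholds)
        rows.append({
            "gene_id": m.gene_id,
            "strand": m.strand,
            "n_exons": len(m.exon_lengths),
            "exon_lengths": ",".join(map(str, m.exon_lengths)),
            "pattern": pat.pattern_string,
            "named_match": pat.named_match or "",
        })
    return pd.DataFrame(
        rows,
        columns=["gene_id", "strand", "n_exons", "exon_lengths", "pattern", "named_match"],
    )
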