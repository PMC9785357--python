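"""Ground-truth synthetic inputs for every pipeline stage.

The generators emulate the shape of a real genome-wide family study without
shipping any genome: a proteome with planted IQ67 domains (three strict IQ
motifs at exact 11/15 spacing) alongside wrong-spacing IQ decoys in the
length/pI regime of Myosin/CaMTA proteins and motif-free background
sequences; a GFF3 of multi-exon gene models realizing the named
short/medium/long exon patterns; alignments simulated along a tree under a
uniform substitution model; tissue-enriched expression matrices; Ct tables
encoding known fold changes; and fruit measurements with a planted
fruit-shape-index effect.

Background sequences are *guaranteed* motif-free by rejection sampling
(bounded attempts), so scanner specificity is testable at exactly 100%.
Every generator is deterministic under its seed, and every planted feature
is recorded in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import motif_scan
from .phylo import Alignment
from .records import ProteinRecord, write_fasta

AA = "ACDEFGHIKLMNPQRSTVWY"

NAMED_PATTERN_LABELS = {
    "medium—short—long": ("medium", "short", "long"),
    "short—medium—medium—short—long": ("short", "medium", "medium", "short", "long"),
    "short—medium—medium—short—long—short": ("short", "medium", "medium", "short", "long", "short"),
}

# length draws per label, comfortably inside the 200/600 bins
LABEL_RANGES = {"short": (50, 200), "medium": (250, 550), "long": (700, 1200)}


@dataclass
class SynthConfig:
    """Study conditions for all generators.

    Defaults mirror the published study: 24 family members vs 9 Myosin/CaMTA
    style decoys; family lengths 261-845 aa vs decoy lengths 744-1523 aa;
    basic-residue enrichment giving family proteins a high pI; exon-pattern
    group sizes 4/10/3; two overexpression lines with fruit-shape indices
    1.23/1.21 against a 1.09 wild type (sd 0.08).
    """

    seed: int = 17
    # proteome
    n_sun: int = 24
    n_decoy_iq: int = 9
    n_background: int = 100
    sun_length_range: tuple[int, int] = (261, 845)
    decoy_length_range: tuple[int, int] = (744, 1523)
    background_length_range: tuple[int, int] = (200, 800)
    decoy_spacing_offsets: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)
    sun_basic_weight: float = 3.0     # K/R weight multiplier (high-pI family)
    decoy_acidic_weight: float = 2.0  # D/E weight multiplier (lower-pI decoys)
    max_attempts: int = 1000
    # gene structure: counts for the three named patterns + unnamed extras
    pattern_counts: dict = field(default_factory=lambda: {
        "medium—short—long": 4,
        "short—medium—medium—short—long": 10,
        "short—medium—medium—short—long—short": 3,
    })
    n_other_genes: int = 7
    intron_range: tuple[int, int] = (60, 400)
    # expression
    n_expr_genes: int = 24
    enrichment_factor: float = 8.0
    enriched_tissues: tuple[str, ...] = ("S", "FF", "MF", "O")
    # qPCR (fold changes of the overexpression lines vs wild type)
    qpcr_folds: dict = field(default_factory=lambda: {"Oe-L1": 7.2, "Oe-L2": 3.3})
    ct_reference_level: float = 20.0
    ct_target_base: float = 26.0
    ct_bio_sd: float = 0.08
    ct_tech_sd: float = 0.08
    n_bio: int = 3
    n_tech: int = 3
    # fruit measurements
    line_fsi: dict = field(default_factory=lambda: {"WT": 1.09, "Oe-L1": 1.23, "Oe-L2": 1.21})
    fsi_sd: float = 0.08
    n_per_line: int = 40
    stages: tuple = (1, 3, 5, 7, "mature")
    stage_horizontal_cm: dict = field(default_factory=lambda: {
        1: 1.2, 3: 2.2, 5: 3.6, 7: 5.0, "mature": 10.0})
    regression_r2: float = 0.76
    regression_slope: float = 0.02


def _weights(rng: np.random.Generator, basic: float = 1.0, acidic: float = 1.0) -> np.ndarray:
    w = np.ones(len(AA))
    for i, ch in enumerate(AA):
        if ch in "KR":
            w[i] *= basic
        elif ch in "DE":
            w[i] *= acidic
    return w / w.sum()


def _random_seq(rng: np.random.Generator, n: int, w: np.ndarray) -> str:
    return "".join(rng.choice(list(AA), size=n, p=w)) if n > 0 else ""


def _strict_iq_motif(rng: np.random.Generator, w: np.ndarray) -> str:
    # IQXXXRGXXXR with random wildcards
    x = _random_seq(rng, 6, w)
    return "IQ" + x[:3] + "RG" + x[3:6] + "R"


def _planted_block(rng: np.random.Generator, w: np.ndarray, gaps: tuple[int, int],
                   n_motifs: int = 3) -> str:
    parts = []
    for k in range(n_motifs):
        parts.append(_strict_iq_motif(rng, w))
        if k < n_motifs - 1:
            parts.append(_random_seq(rng, gaps[k], w))
    return "".join(parts)


def _try_planted_protein(
    rng: np.random.Generator, length: int, w: np.ndarray,
    gaps: tuple[int, int], n_motifs: int,
) -> tuple[str, int] | None:
    """One attempt at a protein whose only IQ hits are the planted motifs."""
    block = _planted_block(rng, w, gaps, n_motifs)
    if length <= len(block) + 2:
        length = len(block) + 2
    offset = int(rng.integers(1, length - len(block)))
    seq = _random_seq(rng, offset, w) + block + _random_seq(rng, length - len(block) - offset, w)
    hits = motif_scan.scan_iq(seq, allow_relaxed=True)
    expected_starts = [offset]
    pos = offset
    for k in range(n_motifs - 1):
        pos += 11 + gaps[k]
        expected_starts.append(pos)
    if [h.start for h in hits] != expected_starts:
        return None
    if any(h.motif_class is not motif_scan.MotifClass.IQ_STRICT for h in hits):
        return None
    return seq, offset


def generate_proteome(cfg: SynthConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteome with planted IQ67 domains, wrong-spacing decoys, clean background.

    Truth-table columns: protein_id, class (SUN / OTHER_IQ / NONE), n_iq
    planted, domain_start/domain_end (0-based half-open; -1 for none), gaps.
    """
    rng = np.random.default_rng(cfg.seed)
    w_sun = _weights(rng, basic=cfg.sun_basic_weight)
    w_decoy = _weights(rng, acidic=cfg.decoy_acidic_weight)
    w_bg = _weights(rng)
    records, truth = [], []

    for i in range(cfg.n_sun):
        length = int(rng.integers(cfg.sun_length_range[0], cfg.sun_length_range[1] + 1))
        for _ in range(cfg.max_attempts):
            out = _try_planted_protein(rng, length, w_sun, (11, 15), 3)
            if out is not None:
                break
        else:
            raise RuntimeError("rejection sampling failed for a family protein")
        seq, offset = out
        rec = ProteinRecord.from_raw(f"SYN_SUN{i + 1:02d}", seq, "planted IQ67 domain")
        records.append(rec)
        truth.append({"protein_id": rec.id, "class": "SUN", "n_iq": 3,
                      "domain_start": offset, "domain_end": offset + 59,
                      "gap1": 11, "gap2": 15})

    for i in range(cfg.n_decoy_iq):
        length = int(rng.integers(cfg.decoy_length_range[0], cfg.decoy_length_range[1] + 1))
        n_motifs = int(rng.integers(1, 4))
        if n_motifs == 1:
            gaps: tuple[int, int] = (0, 0)
        else:
            off = rng.choice(cfg.decoy_spacing_offsets, size=2)
            gaps = (max(0, 11 + int(off[0])), max(0, 15 + int(off[1])))
            if gaps == (11, 15):  # paranoid guard; offsets exclude 0
                gaps = (12, 15)
        for _ in range(cfg.max_attempts):
            out = _try_planted_protein(rng, length, w_decoy, gaps, n_motifs)
            if out is not None:
                break
        else:
            raise RuntimeError("rejection sampling failed for a decoy protein")
        seq, offset = out
        rec = ProteinRecord.from_raw(f"SYN_DECOY{i + 1:02d}", seq,
                                     "IQ motifs with wrong spacing")
        records.append(rec)
        truth.append({"protein_id": rec.id, "class": "OTHER_IQ", "n_iq": n_motifs,
                      "domain_start": -1, "domain_end": -1,
                      "gap1": gaps[0] if n_motifs > 1 else -1,
                      "gap2": gaps[1] if n_motifs > 2 else -1})

    for i in range(cfg.n_background):
        length = int(rng.integers(cfg.background_length_range[0],
                                  cfg.background_length_range[1] + 1))
        for _ in range(cfg.max_attempts):
            seq = _random_seq(rng, length, w_bg)
            if not motif_scan.scan_iq(seq, allow_relaxed=True):
                break
        else:
            raise RuntimeError("rejection sampling failed for a background protein")
        rec = ProteinRecord.from_raw(f"SYN_BG{i + 1:03d}", seq, "IQ-free background")
        records.append(rec)
        truth.append({"protein_id": rec.id, "class": "NONE", "n_iq": 0,
                      "domain_start": -1, "domain_end": -1, "gap1": -1, "gap2": -1})

    return records, pd.DataFrame(truth)


def write_proteome(cfg: SynthConfig, fasta_path: str | Path,
                   truth_path: str | Path | None = None) -> pd.DataFrame:
    records, truth = generate_proteome(cfg)
    write_fasta(records, fasta_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


# ------------------------------------------------------------ gene structure

def _unnamed_labels(rng: np.random.Generator) -> tuple[str, ...]:
    # 2- or 4-exon genes can never match the named 3/5/6-exon patterns
    n = int(rng.choice([2, 4]))
    return tuple(rng.choice(["short", "medium", "long"], size=n))


def generate_gff(cfg: SynthConfig) -> tuple[str, pd.DataFrame]:
    """GFF3 text with gene/mRNA/exon hierarchy plus a per-gene truth table.

    Both strands are represented; exon lengths are drawn inside the
    short/medium/long bins so the classifier recovers each planted pattern.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    plan: list[tuple[str, tuple[str, ...]]] = []
    for pattern, count in cfg.pattern_counts.items():
        labels = NAMED_PATTERN_LABELS[pattern]
        plan += [(pattern, labels)] * count
    for _ in range(cfg.n_other_genes):
        labels = _unnamed_labels(rng)
        plan.append(("—".join(labels), labels))

    lines = ["##gff-version 3"]
    truth = []
    cursor = 1000
    for idx, (pattern, labels) in enumerate(plan):
        gene_id = f"SYNGENE{idx + 1:03d}"
        strand = "+" if idx % 2 == 0 else "-"
        tx_lengths = [int(rng.integers(*LABEL_RANGES[lab])) for lab in labels]
        # coordinate order: ascending; '-' genes transcribe high -> low
        coord_lengths = tx_lengths if strand == "+" else tx_lengths[::-1]
        exons, pos = [], cursor
        for ln in coord_lengths:
            exons.append((pos, pos + ln - 1))
            pos += ln + int(rng.integers(*cfg.intron_range))
        gene_start, gene_end = exons[0][0], exons[-1][1]
        chrom = f"chr{idx % 4 + 1}"
        attrs = f"ID={gene_id}"
        lines.append(f"{chrom}\tsynth\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t{attrs}")
        lines.append(f"{chrom}\tsynth\tmRNA\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t"
                     f"ID={gene_id}.1;Parent={gene_id}")
        for k, (s, e) in enumerate(exons):
            lines.append(f"{chrom}\tsynth\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                         f"ID={gene_id}.1.exon{k + 1};Parent={gene_id}.1")
        cursor = gene_end + 2000
        truth.append({"gene_id": gene_id, "strand": strand,
                      "n_exons": len(labels), "pattern": pattern,
                      "named": pattern in NAMED_PATTERN_LABELS,
                      "tx_exon_lengths": ",".join(map(str, tx_lengths))})
    return "\n".join(lines) + "\n", pd.DataFrame(truth)


def write_gff(cfg: SynthConfig, gff_path: str | Path,
              truth_path: str | Path | None = None) -> pd.DataFrame:
    text, truth = generate_gff(cfg)
    Path(gff_path).write_text(text)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


# -------------------------------------------------------------- alignments

def generate_alignment(
    tree: TreeNode, n_sites: int, subst_rate: float = 1.0, seed: int | None = None,
) -> Alignment:
    """Simulate a gapless protein alignment along a tree.

    Substitution events per site on a branch are Poisson(rate x length);
    a hit site is redrawn uniformly over the 20 residues, so long branches
    saturate at an expected p-distance of 1 - 1/20 = 0.95.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA))
    root_seq = rng.integers(0, 20, size=n_sites)
    seqs: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            length = child.length or 0.0
            child_seq = seq.copy()
            n_events = rng.poisson(subst_rate * length, size=n_sites)
            hit = n_events > 0
            child_seq[hit] = rng.integers(0, 20, size=int(hit.sum()))
            if child.is_tip():
                seqs[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    ids = tuple(l.name for l in tree.tips())
    return Alignment(ids, tuple("".join(aa[seqs[i]]) for i in ids))


def informative_quartet_alignment(
    n_informative: int = 50, n_constant: int = 50
) -> Alignment:
    """Four taxa where A,B share derived residues against C,D at many columns.

    A deterministic, maximally clean signal for the AB|CD split, used to
    exercise bootstrap support.
    """
    rows = {"A": [], "B": [], "C": [], "D": []}
    for _ in range(n_informative):
        rows["A"].append("D"); rows["B"].append("D")
        rows["C"].append("E"); rows["D"].append("E")
    for _ in range(n_constant):
        for k in rows:
            rows[k].append("G")
    return Alignment(tuple(rows), tuple("".join(v) for v in rows.values()))


# ------------------------------------------------------- quantitative tables

def generate_expression(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x ten tissues abundance matrix with one enriched tissue per gene."""
    from .quant import TISSUES

    rng = np.random.default_rng(cfg.seed + 2)
    genes = [f"SYN_SUN{i + 1:02d}" for i in range(cfg.n_expr_genes)]
    base = rng.lognormal(mean=2.0, sigma=0.4, size=(len(genes), len(TISSUES)))
    truth = []
    for gi, gene in enumerate(genes):
        tissue = cfg.enriched_tissues[gi % len(cfg.enriched_tissues)]
        base[gi, TISSUES.index(tissue)] *= cfg.enrichment_factor
        truth.append({"gene_id": gene, "enriched_tissue": tissue,
                      "factor": cfg.enrichment_factor})
    expr = pd.DataFrame(base, index=genes, columns=list(TISSUES)).round(3)
    return expr, pd.DataFrame(truth)


def generate_ct_table(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format Ct table (three biological x three technical replicates).

    The configured fold changes are encoded exactly in expectation:
    Ct_target(line) = base - log2(fold) + noise against a steady reference.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    folds = {"WT": 1.0, **cfg.qpcr_folds}
    rows = []
    for sample, fold in folds.items():
        for bio in range(1, cfg.n_bio + 1):
            bio_eff = rng.normal(0.0, cfg.ct_bio_sd)
            for gene, level in (("target", cfg.ct_target_base - np.log2(fold)),
                                ("reference", cfg.ct_reference_level)):
                for tech in range(1, cfg.n_tech + 1):
                    ct = level + (bio_eff if gene == "target" else 0.0) \
                        + rng.normal(0.0, cfg.ct_tech_sd)
                    rows.append({"sample": sample, "gene": gene, "bio_rep": bio,
                                 "tech_rep": tech, "ct": round(float(ct), 3)})
    truth = pd.DataFrame([{"sample": s, "true_fold": f} for s, f in folds.items()])
    return pd.DataFrame(rows), truth


def generate_fruit_table(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fruit vertical/horizontal diameters with a planted FSI effect.

    Per-fruit FSI is drawn N(line mean, sd) and applied to a shared
    horizontal-diameter distribution per stage, so vertical diameter carries
    the whole effect, as in the overexpression phenotype.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    rows = []
    for line, mean_fsi in cfg.line_fsi.items():
        for stage in cfg.stages:
            base_h = cfg.stage_horizontal_cm[stage]
            for k in range(cfg.n_per_line):
                h = rng.normal(base_h, 0.05 * base_h)
                f = rng.normal(mean_fsi, cfg.fsi_sd)
                rows.append({"line": line, "fruit_id": f"{line}-{stage}-{k + 1}",
                             "stage": stage, "vertical": round(float(h * f), 4),
                             "horizontal": round(float(h), 4)})
    truth = pd.DataFrame([{"line": l, "true_fsi": v, "sd": cfg.fsi_sd,
                           "n": cfg.n_per_line} for l, v in cfg.line_fsi.items()])
    return pd.DataFrame(rows), truth


def generate_expression_fsi(cfg: SynthConfig, n_points: int = 30) -> pd.DataFrame:
    """Paired (expression, FSI) points with noise calibrated to the target R^2.

    Residual sd is set from the realized predictor variance so the expected
    coefficient of determination equals ``cfg.regression_r2``.
    """
    rng = np.random.default_rng(cfg.seed + 5)
    folds = [1.0] + list(cfg.qpcr_folds.values())
    x = np.concatenate([
        rng.normal(f, 0.3 + 0.1 * f, size=n_points // len(folds) + 1)[: n_points // len(folds) + 1]
        for f in folds
    ])[:n_points]
    x = np.clip(x, 0.05, None)
    beta = cfg.regression_slope * 10.0
    sigma = abs(beta) * x.std(ddof=0) * np.sqrt((1.0 - cfg.regression_r2) / cfg.regression_r2)
    y = 1.09 + beta * (x - x.mean()) + rng.normal(0.0, sigma, size=len(x))
    return pd.DataFrame({"expression": np.round(x, 4), "fsi": np.round(y, 4)})


def generate_quant_tables(cfg: SynthConfig) -> dict[str, pd.DataFrame]:
    """All quantitative inputs plus their truth tables, keyed by name."""
    expr, expr_truth = generate_expression(cfg)
    ct, ct_truth = generate_ct_table(cfg)
    fruit, fruit_truth = generate_fruit_table(cfg)
    scatter = generate_expression_fsi(cfg)
    return {
        "expression": expr, "expression_truth": expr_truth,
        "ct": ct, "ct_truth": ct_truth,
        "fruit": fruit, "fruit_truth": fruit_truth,
        "expression_fsi": scatter,
    }
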