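"""End-to-end pipeline: simulate (or load) inputs, scan, profile, classify, quantify.

``run_pipeline`` drives every stage in study order — family scan, protein
physicochemistry, gene structure, phylogeny, expression/qPCR, fruit shape —
writing TSV/Newick outputs and a JSON manifest recording the configuration
and per-stage row counts, so reruns with the same configuration and seed
reproduce identical outputs.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from . import gene_structure, motif_scan, phylo, protparam, quant, synth_data


@dataclass
class PipelineConfig:
    out_dir: str = "iq67kit_run"
    seed: int = 17
    fasta: str | None = None          # None -> simulate
    gff: str | None = None
    spacings: tuple[int, int] = (11, 15)
    allow_relaxed: bool = True
    thresholds: tuple[int, int] = (200, 600)
    bootstrap_reps: int = 100
    distance_model: str = "p"
    synth: synth_data.SynthConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.synth is None:
            self.synth = synth_data.SynthConfig(seed=self.seed)


def _log(msg: str) -> None:
    print(f"[iq67kit] {msg}", file=sys.stderr)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=index)
    tmp.replace(path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # inputs: simulate when none given
    if cfg.fasta is None:
        fasta_path = out / "synthetic_proteome.fasta"
        truth = synth_data.write_proteome(cfg.synth, fasta_path, out / "proteome_truth.tsv")
        _log(f"simulated proteome: {len(truth)} records")
    else:
        fasta_path = Path(cfg.fasta)
        if not fasta_path.exists():
            raise FileNotFoundError(f"FASTA not found: {fasta_path}")
    if cfg.gff is None:
        gff_path = out / "synthetic_genes.gff3"
        synth_data.write_gff(cfg.synth, gff_path, out / "gff_truth.tsv")
    else:
        gff_path = Path(cfg.gff)
        if not gff_path.exists():
            raise FileNotFoundError(f"GFF3 not found: {gff_path}")

    # stage 1: family scan
    calls, hits = motif_scan.scan_proteome(fasta_path, cfg.spacings, cfg.allow_relaxed)
    _write_tsv(calls, out / "family_calls.tsv")
    _write_tsv(hits, out / "motif_hits.tsv")
    counts["family_calls"] = len(calls)
    counts["sun_calls"] = int((calls["family"] == "SUN").sum())
    _log(f"scan: {counts['sun_calls']} SUN of {counts['family_calls']} proteins")

    # stage 2: physicochemistry of the called family
    from .records import read_fasta
    records = read_fasta(fasta_path)
    sun_ids = set(calls.loc[calls["family"] == "SUN", "protein_id"])
    profiles = protparam.profile_table([r for r in records if r.id in sun_ids])
    _write_tsv(profiles, out / "protparam.tsv")
    counts["profiles"] = len(profiles)

    # stage 3: gene structure
    models = gene_structure.parse_gff3(gff_path)
    struct = gene_structure.structure_table(models, cfg.thresholds)
    _write_tsv(struct, out / "gene_structure.tsv")
    counts["gene_models"] = len(models)

    # stage 4: phylogeny of family members (alignment simulated along a
    # balanced tree over the called family when no alignment is supplied)
    if counts["profiles"] >= 4:
        ids = sorted(sun_ids)[:12]
        nwk = _balanced_newick(ids)
        sim_tree = TreeNode.read([nwk])
        aln = synth_data.generate_alignment(sim_tree, n_sites=300,
                                            subst_rate=1.0, seed=cfg.seed)
        tree = phylo.bootstrap_nj(aln, model=cfg.distance_model,
                                  n_reps=cfg.bootstrap_reps, seed=cfg.seed)
        phylo.write_newick(tree, out / "family_nj.nwk")
        counts["tree_leaves"] = len(list(tree.tips()))

    # stage 5: expression + qPCR + fruit shape on simulated tables
    tables = synth_data.generate_quant_tables(cfg.synth)
    hm = quant.heatmap_matrix(tables["expression"], "log2p1_zscore")
    _write_tsv(hm, out / "heatmap_matrix.tsv", index=True)
    qres = quant.delta_delta_ct(tables["ct"], "reference", "WT")
    _write_tsv(quant.qpcr_table(qres), out / "qpcr_results.tsv")
    counts["qpcr_samples"] = len(qres)
    fres = quant.fruit_stats(tables["fruit"], control_line="WT", stage="mature")
    _write_tsv(quant.fruit_stats_table(fres), out / "fruit_stats.tsv")
    counts["fruit_lines"] = len(fres)

    manifest = {
        "config": {
            "seed": cfg.seed,
            "spacings": list(cfg.spacings),
            "allow_relaxed": cfg.allow_relaxed,
            "thresholds": list(cfg.thresholds),
            "bootstrap_reps": cfg.bootstrap_reps,
            "distance_model": cfg.distance_model,
            "fasta": str(cfg.fasta) if cfg.fasta else "simulated",
            "gff": str(cfg.gff) if cfg.gff else "simulated",
        },
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _log(f"done; outputs in {out}")
    return manifest


def _balanced_newick(ids: list[str], branch: float = 0.15) -> str:
    """A caterpillar tree over ids with equal branch lengths (simulation scaffold)."""
    nwk = f"({ids[0]}:{branch},{ids[1]}:{branch})"
    for name in ids[2:]:
        nwk = f"({nwk}:{branch},{name}:{branch})"
    return nwk + ";"
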