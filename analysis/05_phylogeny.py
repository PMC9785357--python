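#!/usr/bin/env python
"""Neighbor-joining phylogeny of the synthetic family with bootstrap.

Simulates an alignment along a known tree over the called family members,
rebuilds the tree by NJ on p-distances, and annotates splits with bootstrap
support (column resampling). Finding: with well-separated branches the
simulated topology is recovered with high support throughout.
"""

import argparse
from pathlib import Path

import pandas as pd

from iq67kit import phylo, synth_data
from iq67kit.pipeline import _balanced_newick

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--bootstrap", type=int, default=200)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

calls = pd.read_csv(args.out / "family_calls.tsv", sep="\t")
ids = sorted(calls.loc[calls["family"] == "SUN", "protein_id"])[:12]
true_tree = phylo.read_newick(_balanced_newick(ids, branch=0.15))
aln = synth_data.generate_alignment(true_tree, n_sites=300, subst_rate=1.0,
                                    seed=args.seed)
tree = phylo.bootstrap_nj(aln, model="p", n_reps=args.bootstrap, seed=args.seed)
phylo.write_newick(tree, args.out / "family_nj.nwk")

supports = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
rf = tree.compare_rfd(true_tree)
print(f"{len(ids)} taxa, {args.bootstrap} bootstrap replicates")
print(f"Robinson-Foulds distance to simulated truth: {rf}")
print(f"bootstrap supports: min {min(supports)}, median "
      f"{sorted(supports)[len(supports) // 2]} -> results/family_nj.nwk")
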