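"""Neighbor-joining phylogeny with bootstrap support.

Protein distances (p-distance or Poisson-corrected, pairwise gap deletion)
feed a Saitou–Nei neighbor-joining agglomeration with Studier–Keppler branch
lengths. Q-matrix ties break on the lowest (i, j) index pair so runs are
deterministic; negative branch lengths are clamped to zero with the deficit
transferred to the sibling branch, preserving leaf-to-leaf path lengths.
Bootstrap resamples alignment columns with replacement and annotates each
internal split of the original tree with its replicate frequency x 100.

Trees are ``skbio.TreeNode`` objects; Newick serialization goes through
scikit-bio, with supports encoded as internal node labels.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO
from skbio import DistanceMatrix, TreeNode


@dataclass(frozen=True)
class Alignment:
    """A gapped protein multiple alignment ('-' gaps, equal-length rows)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must pair up")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def read(cls, path: str | Path, fmt: str = "fasta") -> "Alignment":
        """Load an aligned FASTA or Clustal file."""
        aln = AlignIO.read(str(path), fmt)
        return cls(tuple(r.id for r in aln), tuple(str(r.seq).upper() for r in aln))

    def resample_columns(self, column_idx: np.ndarray) -> "Alignment":
        rows = tuple("".join(row[j] for j in column_idx) for row in self.rows)
        return Alignment(self.ids, rows)


def distances(
    aln: Alignment,
    model: str = "p",
    gap_handling: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise protein distances over gap-free columns.

    ``p`` is the proportion of mismatching sites; ``poisson`` applies the
    correction -ln(1 - p). With ``pairwise`` deletion each pair uses the
    columns where neither row has a gap; ``complete`` deletion drops any
    column with a gap in any row.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(r) for r in aln.rows])
    valid = arr != "-"
    if gap_handling == "complete":
        keep = valid.all(axis=0)
        arr, valid = arr[:, keep], valid[:, keep]
    elif gap_handling != "pairwise":
        raise ValueError(f"unknown gap handling {gap_handling!r}")
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / n_sites
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated distance (p=1) between {aln.ids[i]} and {aln.ids[j]}"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=list(aln.ids))


def _clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
    # negative length -> 0, deficit moved to the sibling so li + lj == total
    if li < 0.0:
        return 0.0, total
    if lj < 0.0:
        return total, 0.0
    return li, lj


def nj(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted ``TreeNode``.

    For two taxa the single edge of length d is split across the two leaf
    branches. No emitted branch length is negative.
    """
    ids = list(dm.ids)
    d = np.asarray(dm.data, dtype=float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    if n == 2:
        half = d[0, 1] / 2.0
        root = TreeNode()
        for node in nodes:
            node.length = half
            root.append(node)
        return root

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) pair on ties
        best = (math.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj, d[i, j])
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        # Studier–Keppler update of distances to the new node
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    root = TreeNode()
    if len(nodes) == 3:
        l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
        l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
        l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
        for node, ln in zip(nodes, (l0, l1, l2)):
            node.length = max(ln, 0.0)
            root.append(node)
    else:  # 2 remaining (after joins), split the edge
        half = d[0, 1] / 2.0
        for node in nodes:
            node.length = half
            root.append(node)
    return root


def _splits(tree: TreeNode) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the leaf set, canonicalized to the smaller side."""
    leaves = frozenset(l.name for l in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def bootstrap_nj(
    aln: Alignment,
    model: str = "p",
    n_reps: int = 1000,
    seed: int | None = None,
    gap_handling: str = "pairwise",
) -> TreeNode:
    """NJ tree with internal splits annotated by bootstrap frequency (0-100).

    Columns are resampled with replacement ``n_reps`` times; each internal
    node of the original tree is labelled with the percentage of replicate
    trees containing its split. Reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj(distances(aln, model=model, gap_handling=gap_handling))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in _splits(tree)}
    for _ in range(n_reps):
        idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep_tree = nj(distances(aln.resample_columns(idx), model=model,
                                gap_handling=gap_handling))
        rep_splits = _splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    leaves = frozenset(l.name for l in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        key = min(side, leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
        if key in counts:
            node.name = str(round(100.0 * counts[key] / n_reps))
    return tree


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(text_or_path: str | Path) -> TreeNode:
    """Parse Newick from a string or a file path."""
    p = Path(str(text_or_path))
    if not str(text_or_path).lstrip().startswith("(") and p.exists():
        return TreeNode.read(str(p), format="newick")
    return TreeNode.read(io.StringIO(str(text_or_path)), format="newick")


def tip_to_tip_distance(tree: TreeNode, a: str, b: str) -> float:
    return float(tree.find(a).distance(tree.find(b)))


def has_split(tree: TreeNode, side: set[str]) -> bool:
    leaves = frozenset(l.name for l in tree.tips())
    side = frozenset(side)
    key = min(side, leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
    return key in _splits(tree)
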