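"""Conservation analysis: multiple alignment, logo matrix, NJ cladogram.

Mature miRNAs across species are short (18-26 nt) and near-identical,
so a center-star progressive alignment (center = sequence minimizing
the summed pairwise edit distance) is adequate and fully deterministic.
A position frequency matrix with per-column information content stands
in for a rendered sequence logo, and the tree is built with the
canonical Saitou-Nei neighbor-joining agglomeration on p-distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

__all__ = [
    "MultipleAlignment",
    "TreeNode",
    "align_matures",
    "position_frequency_matrix",
    "p_distance_matrix",
    "neighbor_joining",
]


@dataclass
class MultipleAlignment:
    taxa: list
    rows: list          # equal-length gapped sequences

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")


def _cigar_ops(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def _pairwise_align(query: str, target: str):
    """Global alignment of query vs target as two gapped strings."""
    res = edlib.align(query, target, mode="NW", task="path")
    qa, ta = [], []
    qi = ti = 0
    for cnt, op in _cigar_ops(res["cigar"]):
        for _ in range(cnt):
            if op in "=X":
                qa.append(query[qi]); ta.append(target[ti])
                qi += 1; ti += 1
            elif op == "I":          # base in query, gap in target
                qa.append(query[qi]); ta.append("-")
                qi += 1
            elif op == "D":          # gap in query, base in target
                qa.append("-"); ta.append(target[ti])
                ti += 1
    return "".join(qa), "".join(ta)


def align_matures(seqs: dict | list, taxa: list | None = None) -> MultipleAlignment:
    """Center-star progressive alignment of mature sequences.

    *seqs* is a mapping taxon -> sequence (or a list with *taxa*).
    A single sequence aligns to itself.
    """
    if isinstance(seqs, dict):
        taxa = list(seqs)
        seq_list = [seqs[t] for t in taxa]
    else:
        seq_list = list(seqs)
        taxa = taxa or [f"seq{i+1}" for i in range(len(seq_list))]
    if len(seq_list) == 1:
        return MultipleAlignment(taxa, list(seq_list))
    n = len(seq_list)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seq_list[i], seq_list[j], mode="NW")["editDistance"]
            dist[i, j] = dist[j, i] = d
    center = int(dist.sum(axis=1).argmin())
    c_seq = seq_list[center]
    L = len(c_seq)

    # pairwise alignments of every other sequence against the center
    pair_aln = {}
    for k in range(n):
        if k != center:
            pair_aln[k] = _pairwise_align(seq_list[k], c_seq)

    # insertion slots before each center position (0..L), "once a gap always a gap"
    ins = [0] * (L + 1)
    per_seq_cols = {}
    for k, (qa, ta) in pair_aln.items():
        cols = []          # (center_pos, slot_within_insertion, char)
        cpos = 0
        slot = 0
        for qc, tc in zip(qa, ta):
            if tc == "-":
                cols.append((cpos, slot, qc))
                slot += 1
            else:
                cols.append((cpos, -1, qc))   # -1 = aligned to center base cpos
                cpos += 1
                slot = 0
        ins_k = [0] * (L + 1)
        for p, s, _ in cols:
            if s >= 0:
                ins_k[p] = max(ins_k[p], s + 1)
        for p in range(L + 1):
            ins[p] = max(ins[p], ins_k[p])
        per_seq_cols[k] = cols

    # master column layout: for each center position p, ins[p] insertion
    # slots then the center base
    col_index = {}
    idx = 0
    for p in range(L + 1):
        for s in range(ins[p]):
            col_index[(p, s)] = idx
            idx += 1
        if p < L:
            col_index[(p, -1)] = idx
            idx += 1
    width = idx

    rows = []
    for k in range(n):
        row = ["-"] * width
        if k == center:
            for p in range(L):
                row[col_index[(p, -1)]] = c_seq[p]
        else:
            for p, s, ch in per_seq_cols[k]:
                row[col_index[(p, s)]] = ch
        rows.append("".join(row))
    return MultipleAlignment(taxa, rows)


def position_frequency_matrix(msa: MultipleAlignment):
    """Per-column base frequencies and information content in bits.

    Frequencies (over A/C/G/U/-) sum to 1 per column; information is
    2 minus the Shannon entropy of the gap-renormalized base
    frequencies.  All-gap columns get information 0 and a flag.
    """
    alphabet = "ACGU-"
    W = msa.length
    n = len(msa.rows)
    freq = np.zeros((W, 5))
    for r in msa.rows:
        for c, ch in enumerate(r):
            freq[c, alphabet.index(ch)] += 1
    freq /= n
    info = np.zeros(W)
    all_gap = np.zeros(W, dtype=bool)
    for c in range(W):
        p = freq[c, :4]
        tot = p.sum()
        if tot == 0:
            all_gap[c] = True
            continue
        q = p / tot
        nz = q[q > 0]
        info[c] = 2.0 + float((nz * np.log2(nz)).sum())
    return {"alphabet": alphabet, "freq": freq, "information": info,
            "all_gap": all_gap}


def p_distance_matrix(msa: MultipleAlignment) -> np.ndarray:
    """Pairwise proportion of mismatching columns, gap columns excluded."""
    n = len(msa.rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            comp = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not comp:
                raise ValueError(f"no comparable columns between rows {i} and {j}")
            d = sum(x != y for x, y in comp) / len(comp)
            D[i, j] = D[j, i] = d
    return D


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)   # (child, branch_length)
    clamped_lengths: list = field(default_factory=list)

    def leaf_names(self) -> list:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out

    def newick(self, lengths: bool = True) -> str:
        return self._nwk(lengths) + ";"

    def _nwk(self, lengths):
        if not self.children:
            return self.name
        parts = []
        for c, bl in self.children:
            s = c._nwk(lengths)
            if lengths:
                s += f":{bl:.6g}"
            parts.append(s)
        return "(" + ",".join(parts) + ")"

    def splits(self) -> set:
        """Non-trivial bipartitions as frozensets of leaf names (one side)."""
        all_leaves = frozenset(self.leaf_names())
        out = set()

        def rec(node):
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for c, _ in node.children:
                side = rec(c)
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(min(side, all_leaves - side, key=sorted))
                below |= side
            return below

        rec(self)
        return out

    def edge_lengths(self) -> dict:
        """Map split/leaf (frozenset of names below the edge) -> length."""
        all_leaves = frozenset(self.leaf_names())
        out = {}

        def rec(node):
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for c, bl in node.children:
                side = rec(c)
                key = min(side, all_leaves - side, key=sorted)
                out[key] = out.get(key, 0.0) + bl
                below |= side
            return below

        rec(self)
        return out


def neighbor_joining(dist: np.ndarray, taxa: list) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Deterministic: ties in the Q criterion break to the smallest
    (i, j) in current node order.  Negative branch lengths are clamped
    to zero with the raw value recorded on the joined node.  Returns an
    unrooted tree as a trifurcating root node (a single edge for two
    taxa).
    """
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes = [TreeNode(name=t) for t in taxa]
    if len(nodes) != D.shape[0]:
        raise ValueError("taxa/matrix size mismatch")
    if len(nodes) == 1:
        return nodes[0]
    if len(nodes) == 2:
        root = TreeNode()
        root.children = [(nodes[0], _clamp(D[0, 1] / 2, root)),
                         (nodes[1], _clamp(D[0, 1] / 2, root))]
        return root
    D = D.copy()
    active = list(range(len(nodes)))
    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        new = TreeNode()
        new.children = [(nodes[i], _clamp(li, new)), (nodes[j], _clamp(lj, new))]
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        nodes.append(new)
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = (D[i, k] + D[j, k] - D[i, j]) / 2
        active = [k for k in active if k not in (i, j)] + [u]
    a, b, c = active
    root = TreeNode()
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    root.children = [(nodes[a], _clamp(la, root)), (nodes[b], _clamp(lb, root)),
                     (nodes[c], _clamp(lc, root))]
    return root


def _clamp(x: float, node: TreeNode) -> float:
    if x < 0:
        node.clamped_lengths.append(x)
        return 0.0
    return x
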