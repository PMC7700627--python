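"""A minimal progressive multiple aligner for synthetic fixtures.

Guide tree from k-mer distances (neighbor joining), then profile-profile
Needleman–Wunsch with average BLOSUM62 column scores and a linear gap
penalty. This is deliberately small: it exists so that synthetic family
fixtures can be taken from FASTA to phylogeny without external tools,
and it is not a general-purpose aligner.
"""

from __future__ import annotations

import numpy as np

from .homology import blosum62
from .phylo import MultipleAlignment, Node, PhyloTree, neighbor_joining
from .seqio import SequenceRecord

GAP_PENALTY = 8.0


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 − (shared k-mers / min k-mer count); crude but guide-tree grade."""
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _column_score(col_a: list[str], col_b: list[str], matrix) -> float:
    total = n = 0
    for x in col_a:
        for y in col_b:
            if x == "-" or y == "-":
                continue
            total += matrix[x, y]
            n += 1
    return total / n if n else 0.0


def _align_profiles(pa: list[list[str]], pb: list[list[str]], matrix):
    """Global DP over profile columns, linear gap penalty."""
    na, nb = len(pa), len(pb)
    height_a, height_b = len(pa[0]) if pa else 0, len(pb[0]) if pb else 0
    S = np.zeros((na + 1, nb + 1))
    ptr = np.zeros((na + 1, nb + 1), dtype=np.int8)
    S[:, 0] = -GAP_PENALTY * np.arange(na + 1)
    S[0, :] = -GAP_PENALTY * np.arange(nb + 1)
    ptr[1:, 0] = 2
    ptr[0, 1:] = 3
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            diag = S[i - 1, j - 1] + _column_score(pa[i - 1], pb[j - 1], matrix)
            up = S[i - 1, j] - GAP_PENALTY
            left = S[i, j - 1] - GAP_PENALTY
            best = max(diag, up, left)
            S[i, j] = best
            ptr[i, j] = 1 if best == diag else (2 if best == up else 3)
    out: list[list[str]] = []
    i, j = na, nb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 1:
            out.append(pa[i - 1] + pb[j - 1])
            i, j = i - 1, j - 1
        elif p == 2:
            out.append(pa[i - 1] + ["-"] * height_b)
            i -= 1
        else:
            out.append(["-"] * height_a + pb[j - 1])
            j -= 1
    out.reverse()
    return out


def align_progressive(records: list[SequenceRecord]) -> MultipleAlignment:
    """Progressively align protein sequences along a k-mer guide tree."""
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    matrix = blosum62()
    ids = [r.id for r in records]
    if len(records) == 2:
        merged = _align_profiles(
            [[c] for c in records[0].residues], [[c] for c in records[1].residues],
            matrix)
        return _to_alignment(ids, merged, [0, 1])
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kmer_distance(records[i].residues,
                                              records[j].residues)
    guide = neighbor_joining(D, ids)
    index = {name: k for k, name in enumerate(ids)}

    def build(node: Node) -> tuple[list[list[str]], list[int]]:
        if node.is_leaf():
            return [[c] for c in records[index[node.name]].residues], \
                   [index[node.name]]
        prof, members = build(node.children[0])
        for child in node.children[1:]:
            prof_b, members_b = build(child)
            prof = _align_profiles(prof, prof_b, matrix)
            members = members + members_b
        return prof, members

    profile, members = build(guide.root)
    return _to_alignment(ids, profile, members)


def _to_alignment(ids, profile, members) -> MultipleAlignment:
    rows = {members[r]: "".join(col[r] for col in profile)
            for r in range(len(members))}
    return MultipleAlignment([(ids[k], rows[k]) for k in sorted(rows)])


def guide_tree(records: list[SequenceRecord]) -> PhyloTree:
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kmer_distance(records[i].residues,
                                              records[j].residues)
    return neighbor_joining(D, [r.id for r in records])
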