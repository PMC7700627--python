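"""Synthetic-data generators for end-to-end testing of the pipeline.

Every generator is a pure function of its parameters and seed
(byte-for-byte reproducible) and emits ground-truth records that the
pipeline's own callers can be checked against:

* :func:`simulate_divergent_cds_pair` — an orthologous CDS pair with an
  exact, verified number of planted synonymous and non-synonymous
  single-base substitutions plus whole-codon indels;
* :func:`simulate_protein_family` — a paralogous protein family at a
  target pairwise identity with planted ungapped motifs and GFF3 gene
  models of known exon counts;
* :func:`evolve_on_tree` — site-independent JTT evolution of a protein
  along a tree with known branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phylo
from .kaks import IndelRecord, SubstitutionRecord, classify_substitution
from .seqio import GeneModel, SequenceRecord

SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if (a + b + c) not in ("TAA", "TAG", "TGA")
)
STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class DivergencePlan:
    """Target divergence between an ancestral and a derived CDS."""

    n_syn: int = 0
    n_nonsyn: int = 0
    indels: list[tuple[int, int, str]] = field(default_factory=list)
    # each indel: (codon_index on the reference, codon_count, kind)
    seed: int = 0

    def __post_init__(self):
        if self.n_syn < 0 or self.n_nonsyn < 0:
            raise ValueError("substitution counts must be >= 0")
        for idx, count, kind in self.indels:
            if count < 1:
                raise ValueError("indel codon_count must be >= 1")
            if kind not in ("insertion", "deletion"):
                raise ValueError(f"unknown indel kind {kind!r}")


@dataclass
class FamilySpec:
    """Shape of a simulated multi-gene protein family."""

    n_members: int = 12
    length_aa: int = 200
    pairwise_identity_target: float = 0.9
    motifs: list[tuple[str, float]] = field(default_factory=list)
    exon_count_range: tuple[int, int] = (1, 20)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.pairwise_identity_target <= 1:
            raise ValueError("identity target must be in (0, 1]")
        for consensus, p in self.motifs:
            if len(consensus) > self.length_aa:
                raise ValueError(
                    f"motif {consensus!r} longer than protein length")
            if not 0 <= p <= 1:
                raise ValueError("occurrence probability must be in [0, 1]")


class UnsatisfiablePlanError(ValueError):
    pass


def _synonymous_options(codon: str) -> list[tuple[int, str]]:
    out = []
    for k in range(3):
        for b in "ACGT":
            if b == codon[k]:
                continue
            mut = codon[:k] + b + codon[k + 1:]
            if mut in STOPS:
                continue
            if classify_substitution(codon, k + 1, b) == "synonymous":
                out.append((k + 1, b))
    return out


def _nonsynonymous_options(codon: str) -> list[tuple[int, str]]:
    out = []
    for k in range(3):
        for b in "ACGT":
            if b == codon[k]:
                continue
            mut = codon[:k] + b + codon[k + 1:]
            if mut in STOPS:
                continue
            if classify_substitution(codon, k + 1, b) == "non-synonymous":
                out.append((k + 1, b))
    return out


def simulate_divergent_cds_pair(
    ancestor_length_codons: int, plan: DivergencePlan, gene_id: str = "gene1",
) -> tuple[SequenceRecord, SequenceRecord, dict]:
    """Generate a reference CDS and a derived CDS with planted changes.

    Substitutions are placed at pairwise-distinct codons (disjoint from
    deleted codons), each verified synonymous or non-synonymous by
    :func:`genefam.kaks.classify_substitution`; indels are whole codons,
    so the frame is preserved by construction. The truth record lists
    the planted substitutions and the indel records the pipeline should
    recover (in 1-based reference CDS coordinates).
    """
    rng = np.random.default_rng(plan.seed)
    n_codons = ancestor_length_codons
    deleted: set[int] = set()
    for idx, count, kind in plan.indels:
        if kind == "deletion":
            if idx + count - 1 > n_codons:
                raise UnsatisfiablePlanError("deletion extends past the CDS")
            deleted.update(range(idx, idx + count))
    available = [i for i in range(1, n_codons + 1) if i not in deleted]
    if plan.n_syn + plan.n_nonsyn > len(available):
        raise UnsatisfiablePlanError("more substitutions requested than codons")

    ancestor = [SENSE_CODONS[k] for k in rng.integers(len(SENSE_CODONS),
                                                      size=n_codons)]
    alt = list(ancestor)
    order = rng.permutation(len(available))
    truth_subs: list[SubstitutionRecord] = []
    want = [("synonymous", plan.n_syn), ("non-synonymous", plan.n_nonsyn)]
    cursor = 0
    for effect, n_target in want:
        placed = 0
        options_fn = (_synonymous_options if effect == "synonymous"
                      else _nonsynonymous_options)
        while placed < n_target:
            if cursor >= len(order):
                raise UnsatisfiablePlanError(
                    f"not enough codons admit a {effect} change"
                )
            codon_idx = available[order[cursor]]
            cursor += 1
            opts = options_fn(ancestor[codon_idx - 1])
            if not opts:
                continue
            offset, base = opts[rng.integers(len(opts))]
            ref_codon = ancestor[codon_idx - 1]
            alt[codon_idx - 1] = (ref_codon[:offset - 1] + base
                                  + ref_codon[offset:])
            truth_subs.append(SubstitutionRecord(
                cds_position=(codon_idx - 1) * 3 + offset,
                codon_index=codon_idx,
                ref_base=ref_codon[offset - 1], alt_base=base, effect=effect,
            ))
            placed += 1

    truth_indels: list[IndelRecord] = []
    for idx, count, kind in sorted(plan.indels, reverse=True):
        if kind == "deletion":
            del alt[idx - 1:idx - 1 + count]
            truth_indels.append(IndelRecord(
                start=(idx - 1) * 3 + 1, end=(idx - 1 + count) * 3,
                kind="deletion"))
        else:
            ins = [SENSE_CODONS[k] for k in rng.integers(len(SENSE_CODONS),
                                                         size=count)]
            alt[idx - 1:idx - 1] = ins
            # insertion after reference codon idx-1
            start = (idx - 1) * 3 + 1
            truth_indels.append(IndelRecord(
                start=start, end=start + 3 * count - 1, kind="insertion"))
    truth_indels.sort(key=lambda r: r.start)
    truth_subs.sort(key=lambda r: r.cds_position)

    ref = SequenceRecord(f"{gene_id}_ref", "".join(ancestor), "dna")
    alt_rec = SequenceRecord(f"{gene_id}_alt", "".join(alt), "dna")
    truth = {"gene_id": gene_id, "substitutions": truth_subs,
             "indels": truth_indels, "n_syn": plan.n_syn,
             "n_nonsyn": plan.n_nonsyn}
    return ref, alt_rec, truth


def simulate_protein_family(
    spec: FamilySpec, id_prefix: str = "fam",
) -> tuple[list[SequenceRecord], list[GeneModel], dict]:
    """Generate a paralogous family with planted motifs and gene models.

    Members derive from a common root protein by independent per-site
    substitution with probability 1 − identity_target; each motif
    consensus is then written verbatim at a uniform random offset with
    its occurrence probability. Exon counts are uniform over the
    requested range; the truth record stores planted motif positions
    and realized identities to the root.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = phylo.jtt_frequencies()
    aa = phylo.PAML_ORDER
    root = "".join(aa[k] for k in rng.choice(20, size=spec.length_aa, p=freqs))
    p_mut = 1.0 - spec.pairwise_identity_target
    records: list[SequenceRecord] = []
    models: list[GeneModel] = []
    truth: dict = {"root": root, "members": {}}
    lo, hi = spec.exon_count_range
    for i in range(1, spec.n_members + 1):
        name = f"{id_prefix}{i}"
        seq = list(root)
        hit = rng.random(spec.length_aa) < p_mut
        for j in np.flatnonzero(hit):
            choices = [a for a in aa if a != seq[j]]
            seq[j] = choices[rng.integers(19)]
        planted = {}
        for consensus, prob in spec.motifs:
            if rng.random() <= prob:
                off = int(rng.integers(spec.length_aa - len(consensus) + 1))
                seq[off:off + len(consensus)] = list(consensus)
                planted[consensus] = off + 1  # 1-based
        protein = "".join(seq)
        identity = sum(a == b for a, b in zip(protein, root)) / spec.length_aa
        records.append(SequenceRecord(name, protein, "protein"))
        n_exons = int(rng.integers(lo, hi + 1))
        exons = []
        pos = int(rng.integers(1, 10_000))
        for _ in range(n_exons):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(50, 500))
        models.append(GeneModel(
            gene_id=name, chromosome=str(int(rng.integers(1, 25))),
            strand="+" if rng.random() < 0.5 else "-",
            exons=exons, cds_intervals=list(exons),
        ))
        truth["members"][name] = {"motifs": planted,
                                  "identity_to_root": identity}
    return records, models, truth


def evolve_on_tree(tree: phylo.PhyloTree, root: SequenceRecord,
                   seed: int = 0) -> phylo.MultipleAlignment:
    """Simulate JTT substitution of ``root`` along ``tree``.

    Each edge applies the same matrix exponential the likelihood code
    uses; sites evolve independently, no indels, so the leaf sequences
    form a gap-free alignment labeled by leaf names.
    """
    names = tree.leaf_names()
    if len(set(names)) != len(names):
        raise ValueError("leaf names collide")
    rng = np.random.default_rng(seed)
    state = {id(tree.root): phylo.encode_protein(root.residues)}
    rows = []
    order = [tree.root]
    idx = 0
    while idx < len(order):
        node = order[idx]
        idx += 1
        for child in node.children:
            P = phylo.jtt_transition(child.length)
            cum = P.cumsum(axis=1)
            parent_states = state[id(node)]
            u = rng.random(len(parent_states))
            child_states = (u[:, None] > cum[parent_states]).sum(axis=1)
            state[id(child)] = child_states
            order.append(child)
        if node.is_leaf():
            rows.append((node.name,
                         "".join(phylo.PAML_ORDER[k] for k in state[id(node)])))
    return phylo.MultipleAlignment(rows)
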