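"""Codon-aware pairwise CDS comparison.

Aligns two coding sequences at the protein level (guaranteeing frame
preservation), calls single-nucleotide substitutions classified as
synonymous or non-synonymous under the standard genetic code, detects
frame-preserving indels with 1-based inclusive reference coordinates,
and summarizes per-gene counts with the count-ratio Ka/Ks
(non-synonymous count / synonymous count, rounded half away from zero
to two decimals).

The "Ka/Ks" reported here is deliberately the ratio of raw substitution
COUNTS, not a per-site rate estimate (Nei–Gojobori and kin are out of
scope): it is the summary statistic printed in family-characterization
SNP tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import SequenceRecord, translate_cds

GAP_CODON = "---"
BASES = set("ACGT")


@dataclass
class CodonAlignment:
    """Two frame-aligned CDSs as equal-length codon lists ('---' = gap)."""

    gene_id: str
    ref_codons: list[str]
    alt_codons: list[str]
    ref_label: str = "ref"
    alt_label: str = "alt"

    def __post_init__(self):
        if len(self.ref_codons) != len(self.alt_codons):
            raise ValueError("codon lists must have equal length")
        for row in (self.ref_codons, self.alt_codons):
            for c in row:
                if len(c) != 3:
                    raise ValueError(f"codon {c!r} is not 3 symbols")
                if "-" in c and c != GAP_CODON:
                    raise ValueError(f"split gap codon {c!r}: gaps must be whole codons")


@dataclass
class SubstitutionRecord:
    cds_position: int   # 1-based nucleotide position on the ungapped reference
    codon_index: int    # 1-based
    ref_base: str
    alt_base: str
    effect: str         # "synonymous" | "non-synonymous"

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        if (self.cds_position - 1) // 3 + 1 != self.codon_index:
            raise ValueError("cds_position inconsistent with codon_index")


@dataclass
class IndelRecord:
    start: int   # 1-based inclusive, reference CDS coordinates
    end: int
    kind: str    # "insertion" | "deletion"

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class KaKsSummary:
    """One gene's row of a SNP summary table."""

    gene_id: str
    syn_count: int
    nonsyn_count: int

    @property
    def total(self) -> int:
        return self.syn_count + self.nonsyn_count

    @property
    def ratio(self) -> float | None:
        """nonsyn/syn rounded half away from zero to 2 decimals; None
        (reported as NA) when there are no synonymous substitutions."""
        if self.syn_count == 0:
            return None
        q = Decimal(self.nonsyn_count) / Decimal(self.syn_count)
        return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # a gap of length L costs 11 + L
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def codon_align(ref_cds: SequenceRecord, alt_cds: SequenceRecord,
                gene_id: str | None = None) -> CodonAlignment:
    """Align two CDSs through their protein translations.

    Both sequences are translated (terminal stop codons are dropped and
    excluded from the comparison), globally aligned with BLOSUM62
    (gap open 11 / extend 1), and the protein gaps back-translated to
    whole '---' codons, so every nucleotide-space gap run has a length
    divisible by 3.
    """
    ref_prot = translate_cds(ref_cds)
    alt_prot = translate_cds(alt_cds)
    aln = _protein_aligner().align(ref_prot.residues, alt_prot.residues)[0]
    g_ref, g_alt = str(aln[0]), str(aln[1])
    ref_iter = [ref_cds.residues[k:k + 3] for k in range(0, 3 * len(ref_prot), 3)]
    alt_iter = [alt_cds.residues[k:k + 3] for k in range(0, 3 * len(alt_prot), 3)]
    ri = ai = 0
    ref_codons, alt_codons = [], []
    for a, b in zip(g_ref, g_alt):
        if a == "-":
            ref_codons.append(GAP_CODON)
        else:
            ref_codons.append(ref_iter[ri])
            ri += 1
        if b == "-":
            alt_codons.append(GAP_CODON)
        else:
            alt_codons.append(alt_iter[ai])
            ai += 1
    return CodonAlignment(
        gene_id=gene_id or ref_cds.id, ref_codons=ref_codons,
        alt_codons=alt_codons, ref_label=ref_cds.id, alt_label=alt_cds.id,
    )


def classify_substitution(ref_codon: str, offset: int, alt_base: str) -> str:
    """Effect of a single-base change at ``offset`` (1..3) of a codon.

    The mutated codon is compared with the reference codon under the
    standard genetic code; a change creating a stop codon counts as
    non-synonymous.
    """
    ref_codon = ref_codon.upper()
    alt_base = alt_base.upper()
    if set(ref_codon) - BASES or alt_base not in BASES:
        raise ValueError(f"invalid codon {ref_codon!r} or base {alt_base!r}")
    if offset not in (1, 2, 3):
        raise ValueError("offset must be 1, 2 or 3")
    if ref_codon[offset - 1] == alt_base:
        raise ValueError("alt base equals the reference base")
    mutant = ref_codon[:offset - 1] + alt_base + ref_codon[offset:]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(mutant).translate())
    if aa_alt == "*" or aa_ref == "*":
        return "non-synonymous" if aa_ref != aa_alt else "synonymous"
    return "synonymous" if aa_ref == aa_alt else "non-synonymous"


def call_substitutions(ca: CodonAlignment) -> list[SubstitutionRecord]:
    """Emit one record per differing base of each aligned codon pair.

    Each differing position is classified independently, with the other
    positions of the codon held at the reference state. Positions are
    1-based on the ungapped reference CDS.
    """
    records: list[SubstitutionRecord] = []
    ref_codon_index = 0
    for rc, ac in zip(ca.ref_codons, ca.alt_codons):
        if rc != GAP_CODON:
            ref_codon_index += 1
        if rc == GAP_CODON or ac == GAP_CODON:
            continue
        for k in range(3):
            if rc[k] != ac[k]:
                records.append(SubstitutionRecord(
                    cds_position=(ref_codon_index - 1) * 3 + k + 1,
                    codon_index=ref_codon_index,
                    ref_base=rc[k], alt_base=ac[k],
                    effect=classify_substitution(rc, k + 1, ac[k]),
                ))
    return records


def indels_from_gapped_pair(ref_gapped: str, alt_gapped: str) -> list[IndelRecord]:
    """Indels from a gapped nucleotide-level pairwise alignment.

    Maximal gap runs are merged into single records. Coordinates are
    1-based inclusive on the ungapped reference: a deletion (gap in the
    alternate row) spans the reference bases it removes; an insertion
    (gap in the reference row) of L bases after reference position p is
    reported as start = p+1, end = p+L, so length_nt = end - start + 1
    holds for both kinds.
    """
    if len(ref_gapped) != len(alt_gapped):
        raise ValueError("gapped rows must have equal length")
    records: list[IndelRecord] = []
    ref_pos = 0
    run_kind = None
    run_start = run_len = 0
    def flush():
        nonlocal run_kind, run_len
        if run_kind is not None:
            records.append(IndelRecord(run_start, run_start + run_len - 1, run_kind))
        run_kind, run_len = None, 0

    for a, b in zip(ref_gapped, alt_gapped):
        if a == "-" and b == "-":
            continue
        if a == "-":            # insertion relative to the reference
            kind = "insertion"
        elif b == "-":          # deletion from the reference
            kind = "deletion"
        else:
            kind = None
        if kind != run_kind:
            flush()
            if kind is not None:
                run_kind = kind
                run_start = ref_pos + 1
        if kind is not None:
            run_len += 1
        if a != "-":
            ref_pos += 1
    flush()
    return records


def call_indels(ca: CodonAlignment) -> list[IndelRecord]:
    """Indel records of a codon alignment, in reference coordinates."""
    return indels_from_gapped_pair("".join(ca.ref_codons), "".join(ca.alt_codons))


def summarize(gene_id: str, subs: list[SubstitutionRecord]) -> KaKsSummary:
    """Count substitutions by effect for one gene."""
    syn = sum(1 for s in subs if s.effect == "synonymous")
    nonsyn = sum(1 for s in subs if s.effect == "non-synonymous")
    return KaKsSummary(gene_id=gene_id, syn_count=syn, nonsyn_count=nonsyn)


def aggregate(summaries: list[KaKsSummary], gene_id: str = "Total") -> KaKsSummary:
    """Family totals row: counts summed, ratio recomputed from the sums
    (never averaged over per-gene ratios)."""
    if not summaries:
        raise ValueError("aggregate requires at least one summary")
    return KaKsSummary(
        gene_id=gene_id,
        syn_count=sum(s.syn_count for s in summaries),
        nonsyn_count=sum(s.nonsyn_count for s in summaries),
    )


def compare_cds_pair(ref_cds: SequenceRecord, alt_cds: SequenceRecord,
                     gene_id: str | None = None
                     ) -> tuple[KaKsSummary, list[SubstitutionRecord], list[IndelRecord]]:
    """Full pairwise workflow: align, call substitutions and indels,
    summarize."""
    ca = codon_align(ref_cds, alt_cds, gene_id)
    subs = call_substitutions(ca)
    indels = call_indels(ca)
    return summarize(ca.gene_id, subs), subs, indels
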