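"""FASTA / GFF3 input-output and CDS translation.

Coordinates are 1-based inclusive throughout, matching the convention of
genome annotation (GFF3) and of the indel positions reported downstream.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
# IUPAC nucleotide codes, ambiguity permitted on input
DNA_ALPHABET = set("ACGTUNRYSWKMBDHV")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


class DuplicateIdError(ValueError):
    pass


class GffError(ValueError):
    pass


@dataclass
class SequenceRecord:
    """A named protein or DNA sequence."""

    id: str
    residues: str
    alphabet: str = "protein"  # "protein" | "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        bad = set(self.residues.upper()) - allowed - {"*"}
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.alphabet} alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """One gene's selected-isoform structure from a GFF3 annotation."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: at least one exon required")
        for name, ivals in (("exon", self.exons), ("CDS", self.cds_intervals)):
            prev_end = 0
            for start, end in sorted(ivals):
                if start > end:
                    raise GffError(
                        f"gene {self.gene_id!r}: {name} interval {start}-{end} "
                        f"has start > end"
                    )
                if start <= prev_end:
                    raise GffError(
                        f"gene {self.gene_id!r}: overlapping {name} intervals"
                    )
                prev_end = end
        self.exons = sorted(self.exons)
        self.cds_intervals = sorted(self.cds_intervals)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into SequenceRecords (order preserved).

    Residues are uppercased. The alphabet is inferred per record: a
    sequence whose letters all fall in the IUPAC nucleotide set is typed
    ``dna``, otherwise ``protein``. An empty file yields an empty list;
    duplicate ids and non-FASTA content raise.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {line[:30]!r}"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        letters = set(residues)
        alphabet = "dna" if letters <= DNA_ALPHABET else "protein"
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, residues, alphabet, desc))
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)
        out.append(SeqRecord(Seq(r.residues), id=r.id, description=r.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(out)


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 annotation into one GeneModel per gene.

    The gene -> mRNA -> exon/CDS hierarchy is resolved through ID/Parent
    attributes. When a gene has several mRNA isoforms, the isoform with
    the longest summed CDS length is selected (ties broken by
    lexicographically smallest mRNA ID). A missing ``##gff-version``
    pragma is tolerated with a warning; a Parent referencing an unknown
    ID or an interval with start > end is an error.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.lstrip().startswith("##gff-version"):
        warnings.warn(f"{path}: missing ##gff-version pragma", UserWarning)

    # up-front structural validation (gffutils is permissive about these)
    ids: set[str] = set()
    parents: list[tuple[str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GffError(f"{path}: line {lineno}: expected 9 tab-separated columns")
        start, end = int(cols[3]), int(cols[4])
        if start > end:
            raise GffError(
                f"{path}: line {lineno}: start {start} > end {end}"
            )
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].strip(";").split(";") if "=" in kv
        )
        if "ID" in attrs:
            ids.add(attrs["ID"])
        for p in attrs.get("Parent", "").split(","):
            if p:
                parents.append((p, lineno))
    for p, lineno in parents:
        if p not in ids:
            raise GffError(f"{path}: line {lineno}: Parent {p!r} references unknown ID")

    db = gffutils.create_db(
        text, ":memory:", from_string=True, merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            chosen = _select_isoform(db, mrnas)
            exons = [(f.start, f.end) for f in db.children(chosen, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(chosen, featuretype="CDS")]
        else:  # exons attached directly to the gene
            chosen = gene
            exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        if not exons:
            raise GffError(f"gene {gene.id!r} has no exon features")
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=sorted(exons),
                cds_intervals=sorted(cds),
            )
        )
    return models


def _select_isoform(db, mrnas):
    def key(m):
        cds_len = sum(
            f.end - f.start + 1 for f in db.children(m, featuretype="CDS")
        )
        return (-cds_len, m.id)

    return min(mrnas, key=key)


def write_gff3(models: list[GeneModel], path) -> None:
    """Serialize gene models as GFF3 with a gene -> mRNA -> exon/CDS
    hierarchy (one mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = (m.exons[0][0], m.exons[-1][1])
            base = f"{m.chromosome}\tgenefam\t"
            tail = f"\t.\t{m.strand}\t.\t"
            fh.write(f"{base}gene\t{span[0]}\t{span[1]}{tail}ID={m.gene_id}\n")
            rna = f"{m.gene_id}.t1"
            fh.write(f"{base}mRNA\t{span[0]}\t{span[1]}{tail}"
                     f"ID={rna};Parent={m.gene_id}\n")
            for k, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}"
                         f"ID={rna}.exon{k};Parent={rna}\n")
            for k, (s, e) in enumerate(m.cds_intervals, 1):
                fh.write(f"{base}CDS\t{s}\t{e}{tail}"
                         f"ID={rna}.cds{k};Parent={rna}\n")


def exon_count(model: GeneModel) -> int:
    """Number of exons of the gene's selected isoform."""
    return len(model.exons)


class FrameError(ValueError):
    pass


class InternalStopError(ValueError):
    def __init__(self, seq_id: str, codon_index: int):
        self.codon_index = codon_index
        super().__init__(
            f"CDS {seq_id!r}: internal stop codon at codon {codon_index}"
        )


def translate_cds(cds: SequenceRecord) -> SequenceRecord:
    """Translate a CDS with the standard genetic code.

    The length must be divisible by 3; a terminal stop codon is dropped;
    an internal stop codon is an error naming its (1-based) codon index.
    """
    if cds.alphabet != "dna":
        raise ValueError(f"{cds.id!r}: translate_cds requires a dna record")
    n = len(cds.residues)
    if n % 3 != 0:
        raise FrameError(f"CDS {cds.id!r}: length {n} is not divisible by 3")
    protein = str(Seq(cds.residues).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise InternalStopError(cds.id, protein.index("*") + 1)
    if not protein:
        raise FrameError(f"CDS {cds.id!r}: translates to an empty protein")
    return SequenceRecord(cds.id, protein, "protein", cds.description)
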