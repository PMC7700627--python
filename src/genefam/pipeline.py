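"""End-to-end family characterization: identify -> profile -> motifs ->
phylogeny -> Ka/Ks, from a flat config file to a bundle of TSV reports.

Every stage is a pure function of (inputs, config); the run log records
every parameter and seed so a bundle can be reproduced byte-for-byte.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import homology, kaks, motif, msa, phylo, physchem, seqio

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    query_fasta: str
    proteome_fasta: str
    outdir: str
    seed: int
    gff3: str = ""
    cds_fasta: str = ""       # first-species CDS, matched ids
    alt_cds_fasta: str = ""   # second-species CDS, matched ids
    evalue_threshold: float = 1e-5
    max_motifs: int = 10
    motif_widths: tuple[int, ...] = (28, 41, 50)
    motif_starts: int = 10
    bootstrap_reps: int = 1000
    run_ml_search: bool = True

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.max_motifs < 1 or self.bootstrap_reps < 1:
            raise ValueError("max_motifs and bootstrap_reps must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required (no silent nondeterminism)")
        for name in ("query_fasta", "proteome_fasta", "gff3",
                     "cds_fasta", "alt_cds_fasta"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def read_config(path) -> PipelineConfig:
    """Parse a flat key = value config file (comments start with '#')."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected key = value")
        key, raw = (x.strip() for x in line.split("=", 1))
        raw = raw.strip("'\"")
        if key in ("seed", "max_motifs", "bootstrap_reps", "motif_starts"):
            values[key] = int(raw)
        elif key == "evalue_threshold":
            values[key] = float(raw)
        elif key == "motif_widths":
            values[key] = tuple(int(x) for x in raw.replace(",", " ").split())
        elif key == "run_ml_search":
            values[key] = raw.lower() in ("1", "true", "yes")
        else:
            values[key] = raw
    return PipelineConfig(**values)


def _stage(outdir: Path, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / f"{name}.FAILED").write_text(f"{exc}\n")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name,
                     time.perf_counter() - self.t0)

    return _Ctx()


def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle into ``config.outdir``.

    Returns a dict of the in-memory stage products (hits, profiles,
    motifs, tree, summaries) for programmatic use.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    runlog = [
        "genefam pipeline run log",
        f"seed = {config.seed}",
        f"evalue_threshold = {config.evalue_threshold:g}",
        f"max_motifs = {config.max_motifs}",
        f"motif_widths = {','.join(map(str, config.motif_widths))}",
        f"bootstrap_reps = {config.bootstrap_reps}",
        f"run_ml_search = {config.run_ml_search}",
    ]

    with _stage(outdir, "load"):
        queries = seqio.read_fasta(config.query_fasta)
        proteome = seqio.read_fasta(config.proteome_fasta)
        models = seqio.read_gff3(config.gff3) if config.gff3 else []
        runlog += [f"queries = {len(queries)}", f"proteome = {len(proteome)}",
                   f"gene_models = {len(models)}"]

    with _stage(outdir, "search"):
        hits, accepted = homology.search_family(
            queries, proteome, threshold=config.evalue_threshold)
        family = [r for r in proteome if r.id in accepted]
        runlog.append(f"family_members = {len(family)}")
        write_hits_tsv(hits, outdir / "hits.tsv")
        results["hits"], results["family"] = hits, family
        if not family:
            raise ValueError("no database sequence passed the E-value gate")

    with _stage(outdir, "profile"):
        by_gene = {m.gene_id: m for m in models}
        profiles = [physchem.profile(r) for r in family]
        write_family_table(profiles, by_gene, outdir / "family_table.tsv")
        results["profiles"] = profiles

    with _stage(outdir, "motifs"):
        motifs = motif.discover_motifs(
            family, max_motifs=config.max_motifs, widths=config.motif_widths,
            seed=config.seed, n_starts=config.motif_starts)
        write_motif_tables(motifs, outdir / "motifs.tsv",
                           outdir / "motif_sites.tsv")
        runlog.append(f"motifs_found = {len(motifs)}")
        results["motifs"] = motifs

    with _stage(outdir, "phylo"):
        if len(family) < 3:
            raise ValueError("phylogeny requires at least 3 family members")
        if len({len(r) for r in family}) == 1:
            aln = phylo.MultipleAlignment(
                [(r.id, r.residues) for r in family])
        else:
            aln = msa.align_progressive(family)
        clean = phylo.complete_deletion(aln) if aln.has_gaps() else aln
        runlog.append(f"alignment_sites_after_complete_deletion = {clean.n_sites}")
        tree = phylo.nj_tree(clean)
        if config.run_ml_search:
            tree = phylo.ml_search(clean, tree, seed=config.seed)
        tree = phylo.bootstrap_support(
            clean, n_reps=config.bootstrap_reps, seed=config.seed,
            point_tree=tree)
        tree.loglik = phylo.tree_loglik(tree, clean)
        runlog.append(f"tree_loglik = {tree.loglik:.4f}")
        (outdir / "tree.nwk").write_text(tree.newick() + "\n")
        results["tree"] = tree

    if config.cds_fasta and config.alt_cds_fasta:
        with _stage(outdir, "kaks"):
            ref_cds = {r.id: r for r in seqio.read_fasta(config.cds_fasta)}
            alt_cds = {r.id: r for r in seqio.read_fasta(config.alt_cds_fasta)}
            shared = sorted(set(ref_cds) & set(alt_cds))
            runlog.append(f"kaks_gene_pairs = {len(shared)}")
            summaries, indel_rows = [], []
            for gid in shared:
                summ, _, indels = kaks.compare_cds_pair(
                    ref_cds[gid], alt_cds[gid], gene_id=gid)
                summaries.append(summ)
                indel_rows += [(gid, r) for r in indels]
            write_kaks_tables(summaries, indel_rows,
                              outdir / "kaks.tsv", outdir / "indels.tsv")
            results["kaks"] = summaries

    (outdir / "run_log.txt").write_text("\n".join(runlog) + "\n")
    return results


# ---------------------------------------------------------------------------
# report writers (all TSV, one header row)

def write_hits_tsv(hits, path) -> None:
    df = pd.DataFrame(
        [{"qseqid": h.query_id, "sseqid": h.subject_id,
          "pident": f"{100 * h.identity_fraction:.2f}",
          "length": h.alignment_length,
          "evalue": f"{h.evalue:.3g}", "bitscore": f"{h.bitscore:.1f}"}
         for h in hits])
    df.to_csv(path, sep="\t", index=False)


def write_family_table(profiles, models_by_gene, path) -> None:
    rows = []
    for p in profiles:
        model = models_by_gene.get(p.gene_id)
        rows.append({
            "Gene": p.gene_id,
            "Chromosome": model.chromosome if model else "",
            "ExonCount": seqio.exon_count(model) if model else "",
            "MW_kDa": _fmt(p.mw_kda, 2),
            "AA": p.length_aa,
            "pI": _fmt(p.pi, 2),
            "AI": _fmt(p.ai, 2),
            "II": _fmt(p.ii, 2),
            "GRAVY": _fmt(p.gravy, 3),
            "Flags": ";".join(p.flags),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_motif_tables(motifs, motif_path, sites_path) -> None:
    pd.DataFrame(
        [{"Motif": m.index, "Consensus": m.consensus, "Length": m.width,
          "Annotation": m.annotation or "-",
          "IC_bits": f"{m.ic_total:.1f}",
          "LowConfidence": str(m.low_confidence).lower()}
         for m in motifs]).to_csv(motif_path, sep="\t", index=False)
    pd.DataFrame(
        [{"Motif": m.index, "Sequence": sid, "Start": start}
         for m in motifs for sid, start in m.sites]
    ).to_csv(sites_path, sep="\t", index=False)


def write_kaks_tables(summaries, indel_rows, kaks_path, indel_path) -> None:
    def row(s):
        return {"Gene": s.gene_id, "Synonymous_ks": s.syn_count,
                "Nonsynonymous_ka": s.nonsyn_count, "Total": s.total,
                "KaKs_Ratio": "NA" if s.ratio is None else f"{s.ratio:.2f}"}

    rows = [row(s) for s in summaries]
    if summaries:
        rows.append(row(kaks.aggregate(summaries)))
    pd.DataFrame(rows).to_csv(kaks_path, sep="\t", index=False)
    pd.DataFrame(
        [{"Gene": gid, "Start": r.start, "End": r.end,
          "Length": r.length_nt, "Kind": r.kind}
         for gid, r in indel_rows]).to_csv(indel_path, sep="\t", index=False)
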