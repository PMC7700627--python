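# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `genefam`, module by module.

## Sequence and annotation I/O (`seqio`)

Coordinates are **1-based inclusive** throughout (FASTA positions, GFF3
intervals, CDS substitution positions, indel bounds). FASTA parsing and
writing go through Biopython (`Bio.SeqIO`), wrapped at 60 columns on
output; duplicate ids are an error, an empty file is an empty list. GFF3
parsing goes through `gffutils` (in-memory database) with up-front
structural validation: a `Parent` referencing an unknown `ID` and a
feature with start > end are errors; a missing `##gff-version` pragma is
tolerated with a warning. When a gene has several mRNA isoforms the one
with the **longest summed CDS** is used, ties broken by lexicographically
smallest mRNA id — annotation pipelines rarely state their rule, so the
package fixes one and documents it. Translation uses the standard genetic
code; a terminal stop codon is dropped, an internal one is an error naming
the codon index. `X`/`N` are accepted on input; the numeric calculators
reject them explicitly rather than guessing.

## Physicochemical profiling (`physchem`)

Five ProtParam-style calculators operate on standard-residue sequences:

* **Molecular weight** — sum of isotopically averaged residue masses
  (Expasy values) plus one water (18.01524 Da), reported in kDa.
* **Isoelectric point** — root of the Henderson–Hasselbalch net charge
  with the Bjellqvist pKa set (side chains D 4.05, E 4.45, C 9.0, Y 10.0,
  H 5.98, K 10.0, R 12.0; residue-specific terminal pKas). The charge is
  strictly decreasing in pH and the termini guarantee a sign change, so
  bisection on [0, 14] to 0.001 pH always converges.
* **GRAVY** — arithmetic mean of Kyte–Doolittle hydropathies; linear under
  concatenation (property-tested).
* **Aliphatic index** — Ikai (1980) coefficients a = 2.9, b = 3.9 applied
  to mole percents over the *full* length, including non-aliphatic
  residues.
* **Instability index** — Guruprasad (1990) dipeptide weights, taken at
  run time from Biopython's ProtParam data; any dipeptide absent from the
  table weights 1.0. Requires length ≥ 2.

Classification thresholds and boundary conventions: acidic iff pI < 7.0
(pI = 7.0 exactly is basic), unstable iff II > 40 (II = 40 is stable),
thermostable iff AI > 65 strictly, hydrophilic iff GRAVY < 0. These flags
are what characterization tables print next to the raw numbers.

## Homology search (`homology`)

Family membership is decided by *exact* local alignment, not a heuristic
seed-and-extend search: full Gotoh dynamic programming with affine gaps
(a gap of length L costs open + extend·L; defaults BLOSUM62, 11, 1 — the
BLASTP defaults). Among equal-scoring cells the smallest
(query_end, subject_end) wins, making results order-independent. E-values
use the Karlin–Altschul form `E = K·m·n·e^(−λS)` with the fixed gapped
BLOSUM62 constants λ = 0.267, K = 0.041; no composition-based statistics
and no on-the-fly parameter estimation. The database size *n* is the total
residue count after collapsing exact duplicates (kept id:
lexicographically smallest; 100% identity is the redundancy criterion,
configurable in principle but fixed here). The gate is **inclusive**
(E ≤ threshold) and only the single best alignment per pair is reported.
This is quadratic in sequence length and meant for family-scale inputs
(tens to hundreds of proteins), not genome-scale search.

## Motif discovery (`motif`)

The ZOOPS model: each sequence contains zero or one motif occurrence;
a per-sequence occurrence probability γ and a position weight matrix θ
(width w over 20 residues, pseudocount 0.01) are fit by EM against a
0-order background estimated from all input residues. The recorded
objective is the log-likelihood plus the Dirichlet-pseudocount prior term,
which the EM guarantee makes non-decreasing (asserted per run). Each fit
restarts from `n_starts` random length-w subsequences (letter probability
0.5 at the seed residue) and keeps the best final likelihood; a
**phase-refinement sweep** then restarts EM from the converged sites
shifted by ±1/±2 columns, repeated until no improvement — EM's best-known
failure mode on planted motifs is an off-by-one register, and this sweep
removes it (planted 8-mers are recovered with ≤1 consensus mismatch in
20/20 seeded runs; the acceptance script re-measures this).

Sequential discovery fits one motif per candidate width per round
(default widths 28, 41, 50 — typical published motif lengths for this
kind of family analysis), keeps the best by information content per
column, masks its sites with `X` (excluded from all counts), and repeats.
It stops at `max_motifs` (default 10), when the best motif's total IC
falls below 8 bits, when a motif has fewer than two supporting sites, or
when masking has consumed the sequences. Motifs with < 1 bit/column are
flagged low-confidence. Site lists of distinct motifs can never overlap,
by construction. Pfam-style annotation is a free-text field supplied by
the user; no domain database lookup is performed.

## Phylogenetics (`phylo`)

The JTT empirical amino-acid model is shipped as a data file
(`data/jtt.dat`: the published 1992 exchangeabilities and frequencies, in
PAML order). The rate matrix `Q_ij = S_ij π_j` is normalized to one
expected substitution per site at equilibrium, and `P(t) = e^{Qt}` is
computed once per branch length through the symmetric eigendecomposition
`diag(√π) Q diag(1/√π)`. No among-site rate heterogeneity is modelled —
Gamma rates are a deliberate omission, matching the plain "JTT
matrix-based model" setting of desk phylogenetics tools.

* **Complete deletion** removes every column containing `-` or `X`; an
  alignment left with zero columns is an error suggesting pairwise
  deletion (not implemented).
* **Pairwise distances** maximize `Σ_sites log(π_a P_ab(t))` by
  golden-section search on [0, 10] substitutions/site (identical
  sequences short-circuit to 0). A dense-grid scan of the same likelihood
  agrees within 10⁻³ (tested).
* **Neighbor joining** is the classic Saitou–Nei algorithm; negative
  intermediate branch lengths are clamped to zero with the deficit
  transferred to the sister edge (sum preserved), and Q-criterion ties
  resolve to the smallest (row, column) pair. On additive matrices it
  provably recovers the generating topology and path lengths
  (property-tested, and cross-checked against scikit-bio's NJ).
* **Likelihood** uses Felsenstein pruning with per-node scaling;
  equilibrium frequencies enter at an arbitrary root, and
  time-reversibility makes the result invariant to root placement
  (tested against brute-force state summation on all ≤4-leaf, ≤3-site
  cases).
* **ML search** starts from the NJ tree and hill-climbs over
  nearest-neighbor interchanges, optimizing each branch length with
  bounded Brent's method (tolerance 10⁻⁶), until no rearrangement gains
  more than 10⁻⁶ log-likelihood units.
* **Bootstrap** resamples columns with replacement, rebuilds a tree per
  replicate — NJ on JTT distances by default, full ML behind a flag,
  because NJ replicates keep a 1000-replicate default tractable on one
  core — and annotates each internal edge of the point-estimate tree with
  the percentage of replicates containing its bipartition. A greedy
  majority-rule consensus builder is included.

Trees are unrooted (trifurcating root node), serialized as Newick with
integer bootstrap percentages as internal node labels.

A deliberately minimal progressive aligner (`msa`: 3-mer guide distances,
NJ guide tree, profile–profile Needleman–Wunsch with average BLOSUM62
scores and a linear gap penalty of 8) exists so synthetic fixtures can run
FASTA → tree without external tools. It is not a reproduction of any
production aligner and is not tuned for hard alignment problems.

## Ka/Ks and indels (`kaks`)

Two CDSs are aligned through their protein translations (global
Needleman–Wunsch, BLOSUM62, gap open 11 / extend 1, via Biopython's
PairwiseAligner) and the protein gaps back-translated into whole `---`
codons — frame preservation is therefore guaranteed, and every
nucleotide-space gap run has length divisible by 3. Terminal stop codons
are dropped before alignment and excluded from the comparison.

Every differing base of an aligned codon pair yields one substitution
record, classified by mutating **that position alone** with the other
positions held at the reference state (pathway averaging over multi-hit
codons is deliberately not used; at the divergence levels this summary
targets, multi-hit codons are rare and the printed tables count SNPs, not
inferred substitution paths). A change creating a stop codon is
non-synonymous. The classifier agrees with translate-and-compare on all
576 single-base codon mutations (tested exhaustively).

Indel records merge maximal gap runs and report 1-based inclusive
coordinates on the ungapped reference CDS: a deletion spans the removed
reference bases; an insertion of L bases after reference position p is
reported as (p+1, p+L), so `length = end − start + 1` holds for both
kinds. The coordinate logic lives in `indels_from_gapped_pair`, which
works on any gapped nucleotide pair; codon alignments delegate to it
after expansion, so published nucleotide-level indel coordinates (such as
a 15-nt gap at 777–791, which is not codon-phased) are handled by the
same code path the codon caller uses.

Per-gene summaries count substitutions by effect; the "Ka/Ks" column is
`nonsyn_count / syn_count` rounded **half away from zero** to two
decimals (0.375 → 0.38), `0.00` when there are no non-synonymous changes,
and `NA` when the synonymous count is zero. Family totals re-derive the
ratio from summed counts, never by averaging per-gene ratios. Per-site
estimators (NG86, YN00) are out of scope by design; the count ratio is
the statistic the summary tables print.

## Synthetic data (`simulate`)

Generators are pure functions of (parameters, seed) — byte-identical on
reruns — and emit truth records validated by the pipeline's own callers.

* **CDS pairs**: a stop-free ancestor drawn uniformly over the 61 sense
  codons; exactly `n_syn` verified-synonymous and `n_nonsyn`
  verified-non-synonymous single-base changes at pairwise-distinct codons
  (stop-creating mutations excluded so the derived CDS stays
  translatable); whole-codon indels applied afterwards. An unsatisfiable
  plan (more substitutions than codons, or a codon set with no eligible
  site left) raises rather than silently under-delivering.
* **Protein families**: root protein drawn from JTT equilibrium
  frequencies; members mutate each site independently with probability
  1 − identity_target (realized identities are recorded in the truth
  record, since the target holds only in expectation); motif consensi are
  written verbatim at uniform random offsets with their occurrence
  probabilities; GFF3 gene models get exon counts uniform over the
  requested range.
* **Evolution on a tree**: site-independent JTT substitution along each
  edge using the same transition matrices as the likelihood code; no
  indel evolution, so leaves form a gap-free alignment.

What the generators do *not* emulate: among-site rate variation,
insertion/deletion evolution, codon usage bias, base composition skew,
intergenic sequence and splice structure. Passing tests therefore
demonstrate algorithmic correctness on data satisfying the models'
assumptions — not robustness to every property of real genomes.

## Pipeline (`pipeline`, `cli`)

A flat `key = value` config (paths, E-value threshold 10⁻⁵, max 10
motifs, 1000 bootstrap replicates, mandatory seed) drives
identify → profile → motifs → phylogeny → Ka/Ks. Outputs are TSVs with
one header row (family table with Gene/Chromosome/ExonCount/MW_kDa/AA/pI/
AI/II/GRAVY/Flags columns, motif and site tables, Newick tree, Ka/Ks and
indel tables with a family Total row equal to `aggregate()` of the
per-gene rows) plus a run log recording every parameter and seed. Stage
outputs are pure functions of (inputs, config): a rerun with the same
config is byte-identical. A failing stage writes a `<stage>.FAILED`
marker and aborts with the stage name. Wall-times are logged to the
console only, never into the bundle.

## Problem sizes used in the shipped checks

The test suite and acceptance script size their simulations for a single
core: alignment-oracle comparisons use 200 random pairs of length ≤ 8
(where exhaustive enumeration of all monotone matchings is feasible);
substitution-count recovery uses 100 seeded 200-codon pairs; motif
recovery uses 20 runs of 20 × 60-residue families; topology recovery uses
100 replicates of a 4-taxon tree (internal branch 0.4, pendants 0.15,
200 sites); bootstrap tests use 25–50 replicates (the pipeline default
remains 1000); the pI oracle scans a 10⁻⁵ grid for 100 random peptides.

## Known limitations

* The homology stage is exact DP — appropriate for family-scale inputs,
  too slow for all-vs-all proteome search.
* MEME's motif E-value statistics are not implemented; the IC floor and
  site-count rule are the stopping criteria.
* No rate heterogeneity, no model selection, no pairwise-deletion
  distances in the phylogenetics stage.
* The count-ratio Ka/Ks is not a per-site selection estimate and should
  not be compared against ω from codon models.
* The progressive aligner is fixture-grade; for real data, align
  externally and feed the aligned FASTA to the phylogeny stage.
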