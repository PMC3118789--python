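# Methods

This note documents the models and procedures implemented in
`mitocomp`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical conventions.

## Genetic code and coordinates

All translation runs through NCBI translation tables (Biopython's
`CodonTable`), defaulting to table 4 (mold/protozoan mitochondrial:
TGA = Trp, stops TAA/TAG), the code used by ciliate mitochondria — the
comparative codon table shows TGA as a used tryptophan codon and TAA as
the only observed terminator in the AT-rich genomes. The code id is a
parameter everywhere; nothing downstream hard-codes the standard code.

Internal coordinates are 0-based half-open; GenBank's 1-based inclusive
convention is converted exactly once at the I/O boundary. Ambiguity
characters other than N are rejected on read; N is allowed but excluded
from composition denominators and codon counts (skips are tallied).
Minus-strand features are reverse-complemented before translation, and
an internal stop raises an error naming the amino-acid position rather
than being silently fixed — it almost always signals a wrong frame or
wrong code.

## ORF scanning and coding density

The ORF scanner translates all six frames and, in the default
`stop_to_stop` mode, reports every maximal stop-free codon run of at
least `min_aa` codons (default 60, reading the conventional ">60 aa"
screen inclusively; the strict reading is one flag away). No start
codon is required by default because ciliate mitochondrial initiation
is nonstandard; a `start_required` mode with a configurable start set
{ATG, ATA, ATT, TTG, GTG} exists for sensitivity analysis. Reported
lengths count sense codons only (no stop), so a 1712-aa ORF spans
5,136 bp.

Intergenic spacers are the maximal gaps left after merging all
annotated gene intervals (genes overlap occasionally; a spacer is
defined as DNA in no gene). Coding density is the merged genic length
over the genome length; protein-coding density restricts to CDS. The
merged genes plus derived spacers tile the genome exactly, which the
suite asserts as a conservation property.

## Composition

Base composition is reported as percent G/A/T/C over unambiguous
bases. Region classes concatenate coding-strand CDS, spacers, and rRNA
genes respectively. Positional GC pools codons over all genes; stop
codons are excluded by default (GC3 is conventionally over sense
codons; the comparative tables list stops as their own family) with a
flag to include them. Report rounding is one decimal, half away from
zero, matching the published tables; raw doubles are retained
internally.

## Codon usage and Wright's Nc

Within each synonymous family of the active code, relative frequency is
count / family total; stop codons form their own family for frequencies
and rarity but never enter Nc. A codon is rare when its unrounded
frequency is below 0.085 — i.e. exactly the entries that print as
≤ 0.08 at two decimals. That threshold reproduces the published rare
counts 28 / 23 / 5 for the three genomes exactly and is a config value.

Nc follows Wright: per family, F̂ = (nΣp̂² − 1)/(n − 1); families are
grouped by degeneracy k, and Nc = N₁ + Σ Nₖ/F̄ₖ. The census Nₖ is
derived from the code at runtime: under table 4 tryptophan is a
two-codon family, so N₁=1, N₂=10, N₃=1, N₄=5, N₆=3 and the maximum is
62 (the familiar "20 to 61" band is a standard-code convention).
Families with n ≤ 1 or F̂ ≤ 0 drop out of their class mean; an absent
three-fold class borrows the mean of the two- and four-fold classes
(Wright's fallback), any other absent class rescales the result by its
census share, and the value is capped at the sense-codon count. A
large-n variant (`nc_from_frequencies`, F = Σp²) evaluates Nc directly
from published frequency columns; on those columns it lands within a
unit of the published genome-wide values (51.9 vs 52.1, 33.4 vs 33.5,
31.5 vs 31.5), which also corroborates the generalized census.

Whether published genome Nc values are concatenation-based or
gene-averaged is not stated; the package computes concatenation-based
values by default and exposes per-gene profiles for the alternative.

## Ka/Ks (NG86) and the class contrast

The NG86 estimator counts synonymous sites per codon as the expected
fraction of single-nucleotide changes that preserve the amino acid
(changes to or from stops count as nonsynonymous), averages site totals
across the two sequences, and counts differences in multi-difference
codons by averaging over all substitution orderings with equal weights.
Both proportions receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 raises a saturation error. Ks = 0
flags the ratio as undefined (Ka = 0) or infinite (Ka > 0) instead of
dividing. Codon alignments come from globally aligned proteins
(match 1 / mismatch −1 / gap −2) back-threaded onto the nucleotides,
with gap codons dropped pairwise. The original study used a published
Ka/Ks calculator whose exact estimator is unstated, so per-gene equality
with printed values is not promised; the class-level statistics are pure
table arithmetic and reproduce exactly.

The known-gene vs ORF contrast uses a Mann–Whitney U with midranks, a
tie-corrected normal approximation and no continuity correction;
group A is the known genes, so z is negative when they rank lower. An
exact permutation p is computed for pooled n ≤ 20. On the published
per-gene table this gives z = −3.31 against the printed −3.30 (scipy's
asymptotic mannwhitneyu agrees to machine precision in the tests).

## Distances, NJ, bootstrap, shift placement

K2P distance uses pairwise deletion of gap/N sites,
d = −½ln(1−2P−Q) − ¼ln(1−2Q); JC and p-distance are selectable. The
substitution model behind the original NJ figure is unstated; K2P is
the era-typical default, and the shift-placement result is robust to
the choice. Neighbor joining is the standard Saitou–Nei agglomeration
with the Q-criterion, deterministic tie-breaking by lowest index pair,
and negative branch lengths clamped to zero with the deficit recorded.
It is exact on additive matrices (asserted against randomly generated
trees up to six leaves and cross-checked against scikit-bio's nj).
Bootstrap support resamples alignment columns with replacement and
reports, for each internal bipartition of the full-data tree, the
percentage of replicates containing it; replicates whose distances
saturate are skipped and excluded from the denominator.

`place_shift` thresholds per-taxon GC3 at a cut (the study system is
strongly bimodal: ~45–50% vs ~3–17%, so any cut in between behaves
identically) and reports the unique edge separating the high set if one
exists, else a non-monophyly flag.

## Minisatellite detection

For each candidate period d in [6, 100], agreement between the
sequence and itself shifted by d is prefix-summed, making the Hamming
identity of any adjacent-unit junction O(1). A maximal run of
junctions with identity ≥ 0.8 and at least 3 units is a candidate
call; a fractional tail counts the leading matches of the next partial
unit. Identity is ungapped by design: the studied repeat is
length-conserved per unit, and an indel-tolerant mode is out of scope.

Three refinements matter in practice, all mirrored by the brute-force
oracle in the test suite:

1. **Boundary trimming.** A run whose phase is shifted into the flank
   can pass its outer junction on partially guaranteed matches; its
   outer unit, however, is mostly flank. Leading/trailing units with
   identity to the array consensus below the floor are trimmed.
2. **Phase selection.** Overlapping runs of one period are phase
   shifts of one locus; the phase with the highest junction
   match-minus-mismatch score wins (fractional tails carry no score —
   a shifted phase ending inside the array would otherwise collect
   guaranteed tail matches).
3. **Primitive periods.** A call whose consensus is (approximately, at
   the same identity floor) periodic at a divisor is re-reported at
   that divisor, with the same trimming applied; calls whose primitive
   period falls below `min_unit` are short-motif runs (homopolymers,
   triplet repeats), not minisatellites, and are dropped. Across
   different unit lengths, overlaps resolve to the longest span, then
   the smaller unit.

With the defaults, detected copy numbers of planted arrays are exact up
to the tail ambiguity of at most half a unit — the same ambiguity the
real locus has, where whether a degenerate tail unit counts toward the
printed copy number is unknowable from the sequence alone. Random
AT-rich sequence of a few kilobases does produce occasional chance
calls, essentially all 6–7 bp units at the 3-copy floor (~0.8 calls
per 2 kb at 22% G+C); nothing approaching an 18-bp unit with many
copies arises by chance, which is what separates the biological signal.
Frame preservation is simply unit length ≡ 0 (mod 3): copy-number
variation in such an array cannot shift the host reading frame.

## Synthetic data

The generators exist so that every stage has a recovery test against
known truth, offline. They emulate the study conditions:

- `simulate_genome` builds a linear genome from the published gene
  complement (25 known genes, 17 *ymf* ORFs, 2 rRNAs, 3 tRNAs, with
  the published amino-acid lengths), sampling codons per amino acid
  from the published P. caudatum frequency column, spacers of 0–85 bp
  (plus one ~503 bp long spacer) from the published noncoding
  composition, ~20% of genes on the minus strand, and an imperfect
  18-bp × 9 array at the codon midpoint of the largest ORF — counted
  inside that ORF's stated length, as in the real 1712-aa gene. The
  resulting genome is ~43.6 kb with ~94% coding density. The
  amino-acid composition of genes is a generic AT-rich mitochondrial
  profile (the published per-genome amino-acid table is not bundled),
  so whole-genome GC emerges near 25% rather than exactly 22.4%.
- `evolve_pair` evolves two lineages from an ancestral CDS by uniform
  mutation attempts (Poisson(3·C·t/2) per lineage), rejecting stop
  codons, accepting synonymous changes always and nonsynonymous ones
  with probability ω. With the alternative base drawn uniformly from
  the three others, the expected synonymous divergence per synonymous
  site equals t, and NG86 recovers both t and ω (ω = 0.1 comes back
  within a few percent at 5,000 codons).
- `simulate_alignment` evolves codon-structured sites independently on
  a newick tree (JC-style substitution probability per edge). Third
  positions inside the designated high-GC3 clade draw replacement
  bases from a GC-biased equilibrium, and on the clade's stem edge
  third positions are redrawn from that equilibrium outright — a
  complete compositional turnover standing in for whatever mechanism
  shifted the real lineage. At the study's 258-codon fragment length
  the realized clade GC3 scatters around its target with an SD of
  ~3 percentage points (binomial sampling), so single-seed values of
  42–52% against a 47.5% target are expected.
- `simulate_repeat_strains` rebuilds the published strain panel (copy
  numbers 18/11/11/9/9/14/10) around shared coding flanks, with a
  per-unit substitution load of 0.02/bp — substitutions are present
  between units, as reported for the real locus, but adjacent units
  stay above the 0.8 identity floor with high probability, matching a
  locus whose units remained recognizably homologous across strains.

What the generators do not emulate: indels, secondary-structure
constraints in rRNA, transcription-strand asymmetries, rate variation
among sites, and real codon autocorrelation along genes. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated models, not robustness to every property of real
sequence.

All generators take one explicit seed and use a single `numpy`
Generator per invocation; identical seeds give byte-identical output.

## Problem sizes

The default test suite and the acceptance script run at the study's own
scales: the full ~43.6 kb genome, 5,000-codon pairs over 10 seeds for
ω recovery, a 14-taxon × 258-codon alignment with 500–2,000 bootstrap
replicates, and 50 random 2-kb sequences for the detector-vs-oracle
comparison.

## Known limitations

- Real-accession checks (genome length, base composition, GC3, Nc,
  longest ORF, the ymf64 repeat) activate only after
  `scripts/fetch_accessions.py` has downloaded the records; the
  library core never touches the network.
- The NG86 implementation weights all substitution orderings equally,
  including paths through stop codons; estimators that exclude or
  down-weight stop paths will differ slightly at high divergence.
- Per-gene Nc for very short genes (any degeneracy class absent) uses
  the documented fallbacks and should be read as flagged, not exact.
- The repeat detector's indel blindness means a single insertion
  inside a unit truncates the detected array rather than re-phasing
  it.
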