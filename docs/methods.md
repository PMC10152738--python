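# Methods

## The statistical model

The pipeline treats a candidate smORF as validated when it behaves like a
protein-coding gene along two independent axes and passes a coding-level
control:

**Constraint.** Variant emission in a large population callset is modelled as
independent Bernoulli observation per (site, alternate allele) with
probability proportional to the context-dependent mutation rate mu. The
expected observed count of a consequence class in an entity is
`k · Σ mu` over the class's possible SNVs; `k` is a single global constant
fit by least squares through the origin of observed synonymous counts
against summed synonymous mu, on the assumption that synonymous variation is
neutral. No coverage correction is applied (the emulated callset is
whole-genome). The MOEUF score is the 95th percentile of the normalised
Poisson likelihood `L(λ) = Poisson(O; λE)` on the grid λ ∈ [0, 2] step
0.001 — the convention used for published OEUF scores — i.e. the upper
bound of the 90% two-sided CI of O/E. Observed counts use folded
MAF < 0.001.

Consequence classes follow SNV-level rules: N (nonsynonymous, the numerator
of N/S) = missense + stop-loss; LoF = stop-gain + canonical ±2 bp splice +
start-loss (frameshifts cannot arise from SNVs; a change anywhere in an ATG
initiator is a start loss; a terminal stop mutating to another stop is
synonymous). LoF counts per smORF are too sparse for a LoF-based OEUF, which
is why the missense metric is primary.

**Conservation.** The arithmetic mean of per-base conservation scores over
exon bases, with unscored bases excluded from numerator and denominator
(bedtools-intersect semantics). The joint filter MOEUF ≤ 1.5 AND mean ≥ −1
uses inclusive comparisons exactly as calibrated on validated smORFs and
annotated genes.

**Reading-frame control.** Constraint and conservation cannot distinguish "a
conserved micropeptide" from "a conserved non-coding element". The five
incorrect readings of the spliced sequence (same-strand +1/+2, opposite
strand +0/+1/+2, trailing partial codons dropped) share the genomic
footprint but scramble the codon structure, so selection on the peptide
shows up as the correct frame having lower N/S and MOEUF than all five
controls (paired two-sided Wilcoxon signed-rank). Incorrect frames need no
ATG and may contain internal stops — they are controls, not ORF calls — and
they reuse the same calibration constant `k`. Note an asymmetry exploited in
testing: MOEUF is self-normalising (each frame's observed count is compared
with that frame's own expectation), so under neutrality the paired MOEUF
test is calibrated; raw N/S ratios differ systematically between frames
because codon composition differs, so N/S enters the analysis through
medians, not through the null-calibration checks.

**GWAS enrichment.** The background universe is array SNVs plus LD proxies
(r² ≥ 0.8, within 1 Mb), MAF-restricted to [0.01, 0.50] and split into five
bins ([0.01,0.10), …, [0.40,0.50]); bin membership is left-closed with the
last bin closed. Per bin, the null redraws the catalog's bin count with
replacement from the bin universe and counts smORF-exon overlaps (half-open
intervals; a SNV at an exon start is inside, at the end coordinate outside).
The empirical p uses the add-one rule `p = (#{null ≥ obs} + 1)/(n_perm + 1)`
so that a finite permutation count never produces p = 0 before the
logarithm in Fisher's method `T = −2 Σ ln pᵢ ~ χ²(2k)`. The
damaging-variant analysis consumes functional-prediction scores as an input
column (no predictor is trained or queried); scores > 0.85 count as
damaging, and the same add-one permutation applies. An optional Fisher
exact-test path exists for users who can supply the background
damaging/total contingency explicitly.

## Synthetic cohort: what it emulates and what it does not

The generator plants valid ORFs (ATG + non-stop codons + stop, 1–3 exons
with GT/AG splice sites, both strands) into a random genome, then emits
variants per (site, alt) with probability `mu · 2N` (N diploid genomes,
default 71,702, the scale of a large WGS aggregation database), thinned by
the entity's planted depletion factor for the variant's class — f_mis for
missense/stop-loss, f_lof for stop-gain/start-loss/splice, never for
synonymous; overlapping entities apply the minimum factor. This is Poisson
thinning of a callset, not a Wright–Fisher simulation: allele frequencies
are painted on afterwards (88% rare < 0.001, 2% intermediate, 10% common
spread evenly over the five MAF bins by default), which suffices because
the analysis consumes only presence and AF. The rare-share times 2N is the
generator's emission constant, the quantity the calibration fit recovers.

Default mutation rates put transitions at 3× transversions and CpG
transitions higher still, increasing with a per-CpG methylation level drawn
uniformly from {0, 1, 2} (both bases of the dinucleotide share the level;
the level file is part of the bundle); a fixed-seed ±15% jitter per
(context, alt) makes every context distinct. Rate magnitudes are chosen so
the largest per-site observation probability stays below one at the default
sample size — they are relative rates, not per-generation estimates.

Conservation scores are N(m, 1) per base with the entity mean interpolated
between −2 (neutral) and +4 (fully depleted) according to
`coupling·(1−f_mis) + (1−coupling)·uniform`; background bases are N(0, 1).
Annotated genes receive an additive offset (+2.5 by default) because real
protein-coding genes are conserved across species even when pLI-tolerant in
humans; without it a synthetic low-pLI benchmark group would fail the
conservation threshold wholesale, unlike real gene sets. LD is
block-structured (50 kb blocks, one r² per block drawn from U(0.5, 0.98)) —
enough to exercise the expansion contract without genotype matrices. The
GWAS catalog is sampled from the LD-expanded universe with weight
`gwas_enrichment_ratio` (default 3) inside the exons of filter-surviving
smORFs, and carries trait labels, sub-5×10⁻⁸ p-values, and a small tail of
malformed rows (duplicates, multi-allelic, weak or missing p) for the
hygiene filter.

What the generator does **not** emulate: demography and relatedness,
recombination maps, genotype-level LD, sequencing and mapping error,
coverage variation, isoform-rich transcript structure, and the long tail of
real ORF-caller artefacts. Passing tests therefore demonstrate that the
statistics recover planted structure under the stated model, not that the
thresholds transfer verbatim to any particular real callset.

## Numerical and design choices

* **Coordinates** are 0-based half-open throughout (BED convention);
  strand-aware sequences are always 5'→3' on the coding strand; variant
  tables carry plus-strand alleles and classification complements them for
  minus-strand entities.
* **Isoform grouping** for longest-isoform selection keys on (chrom, strand,
  stop-codon position) — the standard ORF-isoform notion; length ties break
  to the lexicographically smaller id for determinism.
* **Annotation overlap** is strand-blind interval arithmetic (as with
  `bedtools intersect` without strand flags); the "vice versa" 50% rule is
  evaluated per overlapping gene; peptide exclusion requires complete
  coverage of every exon base plus ≥ 50% gene overlap. **Dataset
  intersection** is strand-aware (an ORF is a strand-specific object).
* **MOEUF grid** is truncated at 2.0; observed > 2·expected saturates the
  bound at 2.0 with a flag. Entities with expected missense below 10 are
  flagged low-power. Expected ≤ 0 is a domain error; entities with no
  synonymous observation report undefined ratios and drop out of
  ratio-based medians and pairs.
* **Permutation p-values** are super-uniform when the overlap count is
  coarse (the atom at the observed value is fully included in the upper
  tail; E[−2 ln p] < 2). The calibration experiment therefore uses 800
  draws per bin over a background with ~30% smORF-exon mass, where the
  attainable p-grid is fine relative to the Kolmogorov–Smirnov test's
  sensitivity at 500 replicates; the conservative direction of the bias is
  the safe one for enrichment claims.
* **Problem sizes.** The default cohort is a 500 kb genome with 150 smORFs
  and 60 genes; the constraint-recovery experiment uses 200 single-exon
  120-codon entities (≈ 50 expected missense each); frame experiments use
  150 entities of 40–80 codons per replicate (100 selection replicates, 60
  null); enrichment calibration uses 500 replicates of 800 draws across
  five bins at 1,000 permutations each. These sizes give the power the
  checks require while keeping a full run to minutes on one CPU.

## Known limitations

* The calibration constant is global; real pipelines model per-context
  proportions observed and coverage, so `k` here absorbs the rare-AF share.
* The damaging-variant analysis is only as good as the supplied scores; the
  synthetic scores are exchangeable between hits and pool, so it
  demonstrates calibration, not biology.
* The paper-scale inputs (gnomAD, RefSeq, Peptide Atlas, GERP, the GWAS
  catalog, array manifests) are consumed through the same readers but are
  not bundled; headline counts from those resources are not reproducible
  offline.
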