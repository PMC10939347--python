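# Methods

This note documents the models, estimators and design choices behind
clonescan, in the order the pipeline applies them.

## The data model: a clonal panel as a star genealogy

A panel of N clones propagated vegetatively from one ancestral plant is,
genetically, N copies of one highly heterozygous diploid genome plus
clone-private somatic mutations. Against a related reference cultivar the
panel therefore shows two layers of variation:

* **varietal variation** — sites where the ancestor differs from the
  reference; identical in every clone (heterozygous or homozygous-alt);
* **intra-varietal (clonal) variation** — sites where at least one clone's
  genotype differs from the rest, dominated by somatic mutations private to
  one clone.

The simulator implements exactly this star genealogy. Each candidate
population site receives an alt-allele frequency a ~ U(0.05, 0.5); the
ancestor (and, when enabled, one unrelated outgroup accession) draws a
Hardy–Weinberg genotype at that frequency, and a site enters the call set
when it is non-reference in at least one sample. Conditioning the ancestor
on being non-reference yields mostly heterozygous varietal sites with a
homozygous-alt minority, matching the 0/1-vs-1/1 genotype configurations a
clonal panel shows. Sampling the outgroup jointly at the same frequencies
makes the expected KING-robust kinship between a clone and the outgroup
exactly zero (the numerator N_het,het − 2·N_opp has zero expectation per
site under HWE for any allele frequency, and ascertainment on "variant in
≥ 1 sample" only removes zero-contribution sites) — this is why the
outgroup is modelled through frequencies rather than as an independent
random genotype string.

Somatic mutations are het-gains at previously reference-identical
positions, Poisson-distributed per clone with rates in SNPs/Mbp.
Loss-of-heterozygosity events (a varietal het collapsing to a homozygote in
one clone) are supported via `loh_fraction` but default to off, since
het-gain is the simplest model consistent with the genotype configurations
above. Collisions are impossible by construction: positions are drawn
without replacement per chromosome.

### Default parameters (the simulated study conditions)

| parameter | default | rationale |
|---|---|---|
| clones | 8 (+1 optional outgroup) | typical germplasm clone panel |
| genome | 3 chromosomes × 2 Mbp | desk-scale stand-in for a ~500 Mbp genome |
| varietal SNP rate | 7.3 / kbp genome-wide | cultivar-vs-reference heterozygosity of a highly outcrossing fruit tree |
| varietal INDEL rate | 0.79 / kbp | ~1/9 of the SNP rate, as observed in such panels |
| IBD-tract fraction | 0.10 | share of the genome in low-variability tracts |
| in-tract varietal rate | 0.3 / kbp | chosen so the TOTAL in-tract density (varietal + somatic ≈ 0.4/kbp) stays below the 1 SNP/kbp definition of a low-variability region |
| somatic rates | one clone at 282 SNPs/Mbp, others U(10, 28) | one strongly divergent clone against a quiet background |
| per-genotype missingness | 0.02 | with 2% coverage dropouts yields ~75% complete-case sites across 8 clones |
| depth / QD | DP ~ Poisson(16); QD 25, 2% of sites U(2, 19.9) | mean filtered depth ~16×; low-QD sites exercise the quality filter |
| INDEL length | geometric(0.5), signed, capped 120 bp | mostly 1–2 bp, with occasional >100 bp events for the length filter |
| TE sharing spectrum | {1:70, 2:35, 3:15, 4:10, 5:8, 6:6, 7:4, 8:2} | exclusive-dominated spectrum (46.67% at k=1, 1.33% at k=8) |
| TE pinpoint jitter | U(−2000, 2000) bp | below half the 10-kbp merge radius, so clustering recovers events |

The varietal rate is interpreted genome-wide: the non-tract rate is raised
to (R − f·r_in)/(1 − f) so tracts at r_in plus background average to R.

Two deliberate scale compromises: (i) IBD tract boundaries snap to the
50-kbp analysis grid — real tracts are megabase-scale objects that dwarf an
analysis window, a relation a 2-Mbp toy chromosome cannot otherwise
represent; (ii) TE events of the same family are kept > radius + 2·jitter
apart so the planted sharing spectrum is recoverable exactly (at genome
scale this is the overwhelmingly probable configuration anyway).

### What the simulator does not model

No read-level error, no mapping artefacts, no multiallelic sites, no linkage
structure within the varietal layer (site frequencies are i.i.d.), no
mutational spectrum (all substitutions equally likely), and no shared
somatic lineages (every somatic mutation is private). Passing tests
therefore demonstrate correctness of the analysis logic under the stated
statistical model, not robustness to the artefacts of real short-read data.

## Filter cascade

Order is fixed: site quality → biallelic → SNP-near-INDEL → INDEL rules →
missingness; each record counts toward the first stage that rejects it, so
`input = retained + Σ removed` always holds (asserted at run time).
Decisions that were genuinely open:

* DP is applied per genotype (DP < 5 → missing) and per site (summed DP < 5
  → removed). One mechanism reproduces both the genotype-level masking that
  drives the missingness spectrum and the covered-bases accounting.
* The SNP-near-INDEL window uses the INDEL set as given to the stage
  (before INDEL length/spacing filtering), with POS-to-POS distance,
  boundary inclusive (15 bp away → removed). Whether distance should be to
  the INDEL's span rather than its POS is unresolvable from the filter's
  usual description; POS-to-POS is documented and tested.
* Too-close INDEL pairs (< 50 bp): both members removed; exactly 50 bp:
  both kept.
* Missingness is strictly "above 50%": 4 of 8 missing is kept, 5 removed.
* A record lacking the QD annotation is rejected with an explicit warning
  rather than passed through.

The cascade is idempotent (tested), so re-filtering a filtered VCF is safe.

## Clonal classification

Unphased genotypes are compared as unordered allele sets (0/1 == 1/0).
A polymorphic site has ≥ 2 distinct non-missing genotype calls; the
analysis set is complete-case (no missing call) so that haplotype counts
are constant downstream. A clone-unique site requires exactly two distinct
genotype values with the minority carried by a single clone; a 0/1–0/0–1/1
three-way split is polymorphic but unique to nobody. Unique-mutation
density tracks use tumbling windows (1 Mbp default; stride exposed for
sliding behaviour, since per-Mbp densities are the quantity of interest
either way).

## Diversity statistics

With n = 2 × clones haplotypes (valid because π, θ_w and D depend only on
site allele frequencies, not phase):

* site π = 2c(n−c)/(n(n−1)), the unbiased mean pairwise difference;
* θ_w = S/a₁ with a₁ = Σ_{i<n} 1/i;
* D = (π_sum − S/a₁)/√(e₁S + e₂S(S−1)) with the standard e₁, e₂
  normalising constants; S = 0 or a degenerate variance term yields NA.

Windows are 50-kbp non-overlapping; chromosome-level values aggregate
window S and π_sum and recompute θ_w and D from the sums. Covered bases
count bp where **all** clones are covered (the denominator for per-bp
diversity); both raw per-window sums and per-covered-bp values ×10³
("per-kbp equivalent") are emitted, because per-bp diversity scaled this
way is printed in different unit conventions across studies. Whether the
denominator should be covered bases or full window width is likewise
convention-dependent; covered bases is the default and both are derivable
from the output columns.

On a clonal panel, polymorphic sites are almost all singletons (a star
genealogy), so D is strongly negative genome-wide — considerably more
negative than in a sexual population sample of the same size.

## Relatedness

KING-robust within-pair kinship was chosen over the homogeneous-population
estimator because the panel mixes near-identical clones with an unrelated
outgroup — exactly the structured situation the robust denominator
(N_het(i) + N_het(j)) is designed for. Self-kinship is 0.5 by construction
whenever the sample carries heterozygous sites; a pair with no heterozygous
sites at all returns NA with a warning. The estimator is validated against
Mendelian gene-dropping: parent–offspring pairs at 10⁵ unlinked loci give
φ ≈ 0.25, and half-siblings share ≈ 25% of their genome
(IBD2 + IBD1/2 — the standard "fraction of alleles shared", which is the
quantity meant when relatives are said to share a percentage of their
genome; the probability that half-sibs share *at least one* allele at a
locus is 50% and is a different statistic).

PCA runs on mean-centred dosage (0/1/2) coding; variance-standardised
(1/√(2p(1−p))) scaling is available behind a flag but off by default, since
with one strongly divergent clone the unscaled decomposition reflects
mutation counts directly and is the easier object to interpret.

## Density regions and coverage independence

Windows (50 kbp, matching the diversity windows — one windowing convention
across the package) are classified from the full clone-vs-reference variant
set: LOW ≤ 1 SNP/kbp, HIGH ≥ 20 SNP/kbp (1 per 50 bp), INDEL classes at
< 0.2 and > 2 per kbp; adjacent same-class windows merge into maximal
regions. Rates use **callable** bp — covered in at least one sample — as
denominator: joint calling emits a site wherever any sample has depth, so
dividing by the all-samples-covered length would inflate rates in windows
where a single sample dropped out (this is also why the popgen module and
this module use different coverage notions; each matches its numerator).
Windows with zero callable bp are UNCLASSIFIED. The coverage-independence
check reports Spearman ρ between per-window variant counts and summed
per-sample low-coverage bp, with a permutation p-value.

## Motif sequence sets

Control: the genome is tiled into 10-kbp tumbling windows; windows with no
clone-unique mutation in any clone contribute their central
[4250, 5750) slice (1,500 bp; offsets are 0-based half-open window-relative
coordinates). High / very-high: 1-kbp tumbling windows where some single
clone accumulated strictly more than 5 / 10 unique mutations, emitted as
[start−250, start+1250) fragments; windows whose flanks cross a chromosome
edge are skipped, and a window qualifying through several clones is emitted
once. "Mutations" means clone-unique variants (the sets characterise
clone-specific mutation accumulation); pooled polymorphic variants can be
passed instead by the caller.

## Effect annotation

A deliberate reduction of a full effect annotator to the high-impact
categories a loss-of-function screen inspects: SNPs in CDS are translated
on the coding strand (stop_gained, stop_lost, start_lost); indels fully
inside one CDS segment are frameshifts when length % 3 ≠ 0; variants within
2 bp of an internal CDS/intron boundary on the intron side are splice-site;
everything else — missense, synonymous, in-frame indels, UTR/intronic — is
"other". In-frame indels are length-classified even when their inserted or
deleted codons happen to create a stop; the oracle test in the suite
encodes this contract (protein-diff for SNPs, frame test for indels). A
deletion partially overlapping a CDS edge is conservatively called
splice_site_variant and flagged. GFF3 coordinates (1-based inclusive) are
converted to 0-based half-open internally; minus-strand genes are handled
by reverse-complementing the spliced CDS, and classifier calls are
strand-symmetric (tested).

## TE-insertion sharing

Insertions are 1-bp pinpoints. The merge rule — same chromosome, same TE
family, pinpoints < 10 kbp apart — is pairwise by its phrasing; with more
than two clones it is applied transitively (single linkage on sorted
positions), so a chained cluster can span more than 10 kbp. Events never
merge across families or caller methods; requiring family identity is the
default (a flag-free design: relax by rewriting the family column). A
clone appearing twice in one cluster counts once and is flagged. The
exclusive-TEI vs unique-SNP Spearman correlation uses mid-ranks for ties
and an exact permutation p-value (full enumeration of the 8! rankings for
panels up to 8; a seeded Monte Carlo permutation test beyond that).

## Numerical and degenerate-input conventions

* Percentages are reported to two decimals, round-half-even; an empty
  denominator yields 0.0.
* Tajima's D, kinship and Spearman ρ return NaN (never raise) for
  degenerate inputs, with warnings where the degeneracy is informative.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seed and configuration give byte-identical output files (hash-tested).
* Window iteration is 0-based half-open everywhere internally; VCF
  positions are 1-based; BED output is 0-based half-open.

## Problem sizes

The default simulated genome is 6 Mbp (three 2-Mbp chromosomes) — large
enough that rates, spectra and window statistics are estimated from tens of
thousands of sites and ~120 windows, while a full simulate-analyse cycle
completes in seconds. Gene-dropping anchors use 10⁵ unlinked loci, giving
Monte-Carlo standard errors well inside the ±1 percentage-point tolerance
used for the half-sibling sharing check.

## Known limitations

* The effect classifier ignores compound effects (a variant hitting two
  overlapping genes is called independently per gene) and does not
  re-normalise un-left-aligned indels.
* Chromosome-scale boolean coverage tracks are held in memory; fine at Mbp
  scale, but a 500-Mbp genome would want an interval-tree backend.
* The complete-case restriction makes haplotype counts constant but
  discards real sites; no imputation is attempted.
* The permutation test for coverage independence treats windows as
  exchangeable, ignoring spatial autocorrelation of coverage.
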