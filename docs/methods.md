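# Methods

## Model and assumptions

`mtprior` treats mtDNA variant prioritization as a sequence of per-row
predicates over an annotated variant table. The central assumption is that
variants likely to affect gene/protein function are *rare* (low per-site
nucleotide variability across healthy population alignments, absent from
all three reference backgrounds) and *predicted damaging* (high ensemble
disease score). Evolutionary fixed alleles — haplogroup markers and alleles
shared with the macro-haplogroup consensus — are treated as background, not
candidates, even though haplogroup-phenotype associations exist; the
haplogroup step can therefore be disabled, and the report always contains
the full variant list with prioritized rows first, so no decision is
irreversible.

### Disease score

Six external pathogenicity predictors each provide a probability and a
qualitative call for an amino-acid substitution. The score is a weighted
mean with per-predictor weights trained on variants validated as affecting
function: `W_i = (hp_i + cp_i) / 2n`, with `hp_i` the count of training
mutations on which predictor *i* attains the maximal probability among
present slots and `cp_i` the count it calls "disease". Two choices the
formula leaves open are fixed here and tested:

* **Ties for the maximum** give every tied predictor full `hp` credit
  (deterministic and symmetric); a "split" policy sharing one credit is
  available.
* **Missing probabilities** are excluded with their weights from both
  numerator and denominator (renormalization), never zero-filled; a score
  is emitted only when ≥ `min_predictors` (default 3) usable slots remain.
  Renormalization is the least-surprising degradation of a weighted mean;
  zero-filling would bias scores of partially annotated variants toward 0.

The score is invariant under uniform positive rescaling of the weights,
monotone in each probability, and bounded by the min/max present
probability — all asserted as property tests.

### Threshold derivation

Disease-score populations over many variants are empirically bimodal. A
two-component univariate normal mixture is fitted by EM (log-space E-step,
tolerance 1e-8 on the log-likelihood, max 1000 iterations, σ floor 1e-6).
Initialization splits the sample at its median and uses each half's
moments, making the default fit fully deterministic; seeded random restarts
(up to 10) are used only after a degenerate collapse. Components are
reported sorted by mean, and the per-iteration log-likelihood trace is kept
so monotonicity is checkable on every fit.

The disease score threshold (DST) is the smallest value at which the
posterior odds of the high-mean component reach `ratio` (default 10,
"ten times more probable", interpreted inclusively as odds ≥ ratio). The
search evaluates the odds on a 10,001-point grid over the observed value
range — finer than the four decimals at which such thresholds are quoted —
and returns the smallest qualifying grid point; for equal variances the
crossing has a closed form against which the grid result is tested to
within one grid step. The variability cutoff (NVC) is the third quartile
(numpy `method="linear"`, i.e. R type 7) of NV among variants scoring
above the DST.

The canonical defaults DST = 0.4311 and NVC = 0.0026 were derived on a
population-database score set far larger than anything this package ships;
they are treated as packaged constants, and the derivation machinery is
validated by parameter recovery on simulated populations instead of by
reproducing those two numbers.

### Consensus and variability

A macro-haplogroup consensus is the per-column majority allele of a
multi-alignment. Gaps are excluded from the vote and from allele
frequencies by default (a consensus of genomes should be a genome); an
all-gap column emits N; ties resolve alphabetically for reproducibility.
IUPAC ambiguity codes count as "other" and never enter frequencies. The
default per-site variability is gap-excluded heterozygosity
`1 − Σ f_a²` — a pluggable stand-in, not the database-specific variability
measure behind the canonical NVC, so tables carrying their own NV column
are always accepted as primary input and the packaged validation tables
use their printed NV values.

### Cascade semantics

Numeric comparisons are inclusive: NV passes at ≤ NVC, DS at ≥ DST, HF at
≥ cutoff (all printed survivor scores sit strictly inside these
boundaries, so the published counts are insensitive to the choice). Each
step is `auto` by default: it runs only when some surviving row carries
the datum it needs, so already-filtered candidate lists (no
reference-concordance or haplogroup columns) flow through those steps
untouched, while forcing a step `on` without data is a configuration
error. Premature-stop and frameshift variants bypass the score filter but
remain subject to every other step. When several tissues' HF values are
recorded for one variant, all must clear the cutoff. The strict HF mode
compares point estimates; the CI-aware mode (`hf_mode="ci"`) passes a
variant whose Wilson-interval upper bound clears the cutoff when read
counts are available, reflecting that published tumor lists retain rows
marginally below a nominal cutoff.

Reference concordance flags a variant for reference R when the sample
allele differs from R at that position; equal-length indel handling treats
insertions/deletions as changes relative to every reference. Haplogroup
filtering matches (position, derived allele) against the union of markers
on the root-to-haplogroup path of a user-supplied marker table (three-column
TSV; full phylogeny databases are out of scope).

Coding-effect classification translates the strand-corrected codon through
the vertebrate mitochondrial code (Biopython table 2: TGA→W, ATA→M,
AGA/AGG/TAA/TAG stop). Conventions for the genuinely open cases: at the
two gene overlaps the most severe per-gene effect is reported
(stop > non-synonymous > synonymous); incomplete terminal codons are
padded with A, as polyadenylation completes them in vivo; in-frame coding
indels are classed non-synonymous. The bundled coordinate map covers the
13 protein-coding genes on the standard rCRS numbering (verified against
published codon numbers, e.g. position 11778 → ND4 codon 340, 14249 → ND6
codon 142 on the minus strand). The package bundles no real reference
*bases*: operations needing a sequence take it as an argument, and
`synthdata.synthetic_reference` generates clearly labelled synthetic
stand-ins whose only genuine feature is the coordinate frame.

### Tumor/normal comparison

Variant identity is (position, kind, derived allele); heteroplasmy never
affects identity. Tumor-specific, germline and normal-specific sets are
plain set algebra over the two tables; duplicate keys within one table are
an input error. Wilson score intervals (statsmodels) on HF are attached
where `alt_count`/`depth` annotations exist; under the CI-overlap rule a
shared variant whose intervals do not overlap stays germline but is listed
as discordant for review. Recurrent variants across samples count once in
distinct-variant summaries.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical* structure the method assumes:
bimodal disease scores (components N(0.25, 0.07)/N(0.75, 0.08) mixing
46:54, truncated to [0,1] by resampling so no mass piles at the
boundaries), right-skewed background variability (exponential, scale
0.004, placing the canonical cutoff near its first quartile so a
third-quartile derivation is a meaningful exercise), cohorts of 20 samples
× 70 variants echoing the per-genome variant counts of the validation
datasets, and haplogroup trees whose leaves are a founder sequence mutated
along per-edge markers. Cohorts guarantee exact planted-set recovery by
construction: a background row whose sampled score clears the DST is
forced above the NVC, so passing the end-to-end recovery test shows the
cascade applies its predicates correctly — it does **not** show the
thresholds separate real benign from pathogenic variants, which depends on
predictor quality and population databases outside this package. Likewise
the generators model neither read-level noise nor realistic mutation
spectra.

## Problem sizes

The packaged validation tables are small (4–53 rows) and run in
milliseconds. Property-based checks use 2000-draw mixture populations,
100 random parameter sets for the threshold closed form, 20-seed cohort
recovery (3 samples × ~70 variants each), and 100 random tumor/normal
pairs — the full suite completes in a few seconds on one CPU.

## Known limitations

* Pathogenicity modeling covers protein-coding variants only; tRNA/rRNA
  and control-region variants can pass the reference/variability steps but
  receive no score.
* The heterozygosity-based variability metric will not numerically match
  database-annotated NV values; the canonical NVC applies to the latter.
* Haplogroup assignment itself, read mapping and upstream variant calling
  are out of scope; the package consumes annotated tables.
* The bundled synthetic references make sequence-dependent outputs
  (e.g. amino-acid changes on synthetic genomes) illustrative, not
  biological; supply a real reference sequence for real analyses.
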