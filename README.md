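# mtprior

Multi-parametric prioritization of human mitochondrial DNA variants.

Clinical and cancer studies of the mitochondrial genome routinely produce
dozens of variants per sample, most of which are evolutionary fixed alleles
or common polymorphisms. `mtprior` implements a stepwise workflow that
reduces such lists to a short pool of candidates likely to affect protein
function, for clinicians and researchers triaging mtDNA variants ahead of
functional assays.

## The method

A variant survives the cascade when it is, in order:

1. **recognized by all three references** — a change relative to rCRS, RSRS
   *and* the sample's macro-haplogroup consensus sequence (MHCS, the
   per-column majority allele over healthy genomes of one macro-haplogroup);
   matching any reference marks it as fixed evolutionary background;
2. **not haplogroup-defining** — not a marker allele on the path from the
   phylogeny root to the sample's haplogroup;
3. **evolutionarily constrained** — nucleotide variability NV ≤ NVC;
4. **protein-changing** — non-synonymous, premature stop, or frameshift
   (classified through the vertebrate mitochondrial genetic code);
5. **predicted damaging** — disease score DS ≥ DST for non-synonymous
   variants; truncating variants bypass the score, since no predictor
   emits probabilities for them;
6. **sufficiently heteroplasmic** — HF ≥ a user cutoff in every tissue
   measured (optional).

The disease score of a non-synonymous variant is a weighted mean of six
pathogenicity-predictor probabilities (MutPred, PolyPhen-2 HumDiv/HumVar,
PANTHER, PhD-SNP, SNPs&GO),

```
DS = Σᵢ pᵢ·Wᵢ / Σᵢ Wᵢ,      Wᵢ = (hpᵢ + cpᵢ) / 2n,
```

where, over a training set of `n` variants validated as affecting function,
`hpᵢ` counts the mutations on which predictor *i* gives the highest
probability and `cpᵢ` those it calls "disease". The canonical thresholds
DST = 0.4311 (lowest score where the posterior odds of the damaging
component of a two-normal mixture over disease scores reach 10:1) and
NVC = 0.0026 (third quartile of NV among above-threshold variants) ship as
defaults; `mtprior.thresholds` re-derives both for any score population.

For tumor/normal pairs, `compare_pair` partitions variants into
tumor-specific, germline and normal-specific sets keyed by (position,
allele), with Wilson intervals on heteroplasmy supporting a CI-overlap
check on germline calls.

## Worked example

`examples/prioritize_candidates.py` runs the cascade over the packaged
ovarian-cancer candidate table (20 carcinoma genomes, Sanger sequencing,
HF cutoff 0.5):

```
input rows: 9
step variability   surviving 9
step coding        surviving 9
step disease_score surviving 9
step heteroplasmy  surviving 9
prioritized candidates:
     m.3380A  MT-ND1   DS=0.8764 HF=0.8  R25Q
    m.14969C  MT-CYB   DS=0.8526 HF=0.5  Y75H
     m.9837A  MT-CO3   DS=0.8379 HF=0.5  G211S
    m.15255C  MT-CYB   DS=0.8195 HF=0.8  V170A
    m.10696T  MT-ND4L  DS=0.7810 HF=0.8  A76V
     m.6121C  MT-CO1   DS=0.7054 HF=0.5  I73T
     m.8412C  MT-ATP8  DS=0.6587 HF=1.0  M16T
    m.14249A  MT-ND6   DS=0.4498 HF=1.0  A142V
      6691.A  MT-CO1   DS=  --   HF=0.5  Frameshift
```

Eight non-synonymous candidates pass the score threshold and the
m.6691insA frameshift is kept through the score bypass — nine candidate
somatic variants in total. The other examples cover weight training and
scoring, threshold derivation on a simulated score population, consensus
building, and tumor/normal partitioning; each prints the numbers it
computes and what they mean.

The same operations are exposed as a CLI:

```
mtprior prioritize --variants variants.tsv --hf-cutoff 0.5 --report out.tsv
mtprior thresholds --scores scores.tsv --out thresholds.json
mtprior consensus --alignment aln.fasta --group-by-haplogroup --out mhcs.fasta
```

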