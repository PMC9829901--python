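# splicesig

Targeted splice-isoform quantification from RNA-seq reads, and gene-signature
survival analysis — the computational chain behind studies that link IRE1α–XBP1
activation to patient outcome in non-small cell lung cancer.

## The problem

Under ER stress the IRE1α endoribonuclease excises a 26-nt fragment from the
unspliced *XBP1* mRNA, producing the *XBP1s* isoform that encodes the active
transcription factor.  Standard RNA-seq pipelines miss this event: it is a
spliceosome-independent 26-nt deletion relative to the transcript, not an
annotated splice junction.  `splicesig` provides, for researchers analysing
bulk tumour RNA-seq:

1. **Junction quantification** — align reads to the unspliced transcript with
   an affine-gap dynamic program that de-penalises long gaps
   (gap cost `1 + L`), classify each read as spliced / unspliced /
   uninformative, and report the splicing percentage
   `100 · spliced / (spliced + unspliced)` with pileup-style calling
   thresholds (≥3 supporting reads, event fraction ≥ 2·10⁻⁴, base quality
   ≥ Q13, depth cap 50 000).  Works from FASTQ or from existing SAM/BAM
   alignments via a CIGAR deletion scan.
2. **Signature construction and scoring** — select IRE1α-dependent gene
   signatures from a differential-expression table by strict cutoffs
   (default log2FC > 1, FDR < 1%), map orthologs, and score each sample with
   the single-sample GSEA (ssGSEA) rank statistic (α = 0.25).
3. **Survival analysis** — tertile stratification (top/bottom ⌊n/3⌋),
   Kaplan–Meier curves, Mantel–Cox log-rank, multivariate Cox
   proportional-hazards regression (Efron ties, low group as reference), and
   a **random-signature specificity null**: the fraction of length-matched
   random gene sets that fail to show the survival association.
4. **Synthetic data** — generators with exact ground truth for both read
   mixtures (known spliced fraction, substitution errors) and
   expression + survival cohorts (log-normal expression, exponential
   proportional hazards with a planted signature effect), used by the test
   suite and available from the CLI.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Simulate a read mixture with 30% spliced molecules and quantify it:

```sh
splicesig simulate reads --fraction 0.30 --n-reads 2000 --error-rate 0.005 \
    --junction-only --seed 7 --out-prefix demo
splicesig quantify --reads demo.fastq --ref demo.fa \
    --junction-start 150 --excision-length 26 -o demo.counts.tsv
```

which prints

```
demo	spliced=599	unspliced=1314	spliced_percent=31.31	pass=True
```

— 599 of 1913 junction-informative reads carry the 26-nt deletion, an
estimated splicing percentage of 31.31% (truth: 30%, within two binomial
standard errors at this depth), and the sample passes the
≥3-supporting-reads calling threshold.

Score a signature on a simulated cohort and test survival:

```python
from splicesig import (CohortSimConfig, simulate_cohort, ssgsea_score,
                       stratify_by_score, km_logrank, cox_multivariate)

cohort = simulate_cohort(CohortSimConfig(effect_size=1.0, seed=5))
scores = ssgsea_score(cohort.expression, cohort.signature)
strata = stratify_by_score(scores[cohort.signature.name])
km = km_logrank(cohort.clinical, strata)
print({k: round(v, 1) for k, v in km.medians.items()}, f"p={km.p_value:.2e}")
cox = cox_multivariate(cohort.clinical, strata, covariates=["age", "stage"])
print(cox.summary.round(3).head(1).to_string(index=False))
```

```
{'high': 27.1, 'mid': 31.3, 'low': 66.9} p=4.52e-06
       term  coef    hr  ci_lower  ci_upper    p
high_vs_low 0.794 2.212      1.59     3.079  0.0
```

The planted adverse signature (log-hazard 1 per SD of signature score) drives
the high tertile's median survival down to 27.1 months against 66.9 for the
low tertile, log-rank p ≈ 5·10⁻⁶, and a covariate-adjusted hazard ratio of
2.2 for high vs low.  The specificity of such an association is assessed with
`splicesig null-specificity` (or `random_signature_specificity` in Python),
which re-scores random length-matched gene sets drawn from a gene universe
excluding the signature itself.

## Layout

- `src/splicesig/junction.py` — splice target, affine-gap aligner, read
  classification, FASTQ/SAM counting
- `src/splicesig/signatures.py` — DGE cutoff selection, ortholog mapping,
  ssGSEA, immunomodulator overlap
- `src/splicesig/survival.py` — stratification, KM/log-rank, Cox,
  specificity null
- `src/splicesig/simulate.py` — read-mixture and cohort generators
- `src/splicesig/io.py`, `pipeline.py`, `cli.py` — formats, configuration,
  end-to-end workflow, command line
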