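# introscan

Simulation-trained convolutional genome scans for interspecific
introgression in two-population phased SNP data.

The package implements the full workflow for localizing introgressed
genomic windows between a pair of closely related populations:

1. **demography** — two-population piecewise histories (two epochs before
   the split, three after, directional migration per epoch), six
   representative fitted models as fixtures, conversion to an msprime
   demography, JSON serialization.
2. **scenario_simulator** — coalescent simulation of labelled examples
   under four scenarios (`ELtoIL`, `ILtoEL`, `BiDir`, `none`) with
   mass-migration pulses (proportion U[0.05, 0.50], timing U[1, 5000]
   generations), migrant-ancestry tracking, Gamma(10, 1/10) mutation/
   recombination rate heterogeneity, and Poisson-depth allelic-dropout
   genotyping errors at heterozygous sites.
3. **tensor_encoder** — major/minor polarization, haplotype upsampling to a
   fixed padded dimension, and (2, H, 128)-shaped sliding-window tensors
   (step 64 SNPs).
4. **discriminator** — a ResNet-34-layout four-class classifier implemented
   in pure NumPy (im2col convolutions, batch norm, Adam, early stopping on
   validation loss with best-weight checkpointing). A reduced `desk` preset
   trains on a single CPU; the `paper` preset is the full 16-residual-block
   network.
5. **caller** — the probability-sum decision rule at threshold P (default
   0.9), single-pass neighbor relaxation at 0.7, merging of consecutive
   same-class windows, per-chromosome/genome bp fractions, and exact
   interval-arithmetic union accounting across two scans.
6. **evaluation** — precision/recall (per class, binary presence, and
   directionality restricted to correctly detected windows), threshold
   sweeps over P in {0.75, ..., 0.95}, depth-sweep and "realistic"
   evaluation sets, joint SFS extraction and the Poisson composite
   log-likelihood with optimal rescaling.
7. **landscape_stats** — nucleotide diversity, telomere distance, gene
   overlap; 100-replicate random-window null; Welch t-tests and Cohen's d
   on log-transformed values; chromosome-length correlation.
8. **variant_filtering** — GATK-style site filters (biallelic, repeat mask,
   FS >= 60, MQ <= 40, QD < 6), 15% per-population missingness, the
   1.5x-mode 10-kbp depth-window filter, genic-SNP exclusion and 50-kbp
   thinning for demography preparation.
9. **synthetic_data** — fully self-contained truth-annotated cohorts (raw
   and phased VCFs, gene/repeat BEDs, per-individual 10-kbp depth table,
   chromosome table, introgressed-tract TruthSet), byte-identical per seed.

## CLI

A single executable with one subcommand per stage:

```sh
introscan synth    --out runs/cohort --pair ILa-ELw --seed 1
introscan simulate --out runs/sims --models 1,2,3 --n-per-scenario 50 --seed 1
introscan train    --store runs/sims --out runs/net.npz --preset desk
introscan evaluate --checkpoint runs/net.npz --out runs/eval.json
introscan filter   --vcf cohort.vcf --out filtered.vcf --n-pop1 22
introscan run      --out runs/full --seed 1          # full pipeline
introscan defaults                                    # print config schema
```

`introscan run` orchestrates synth → simulate → train → scan → evaluate →
stats, writing a hash-chained manifest; individual stages are resumable
from the artifacts of earlier stages.

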