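# divland

**Correlated genomic landscapes of diversity and divergence across a species tree.**

Windowed nucleotide diversity (π) and absolute divergence (d<sub>XY</sub>) along a
chromosome form *landscapes* whose peaks and troughs turn out to be strikingly
similar across closely — and even distantly — related species.  `divland` is a
toolkit for asking *why*: it computes the landscapes from standard population
genomic inputs (VCF + callable-site masks), simulates them under explicit
models (multispecies coalescent with incomplete lineage sorting, shared
mutation-rate maps, exon-restricted deleterious and beneficial mutations with
gamma/exponential fitness-effect distributions), and compares model and data
through Spearman correlations organized by phylogenetic distance, a covariance
decomposition against genomic features, and PCA.

The package targets researchers in population and comparative genomics who
want a desk-scale, fully reproducible version of this analysis: every
simulation is seeded, every input can be regenerated synthetically, and the
expensive chromosome-scale computations are replaced by Q-rescaled
equivalents that preserve the compound parameters 4Nµ, 4Nr, 4Ns.

## The quantities at the core

* **π** — mean pairwise differences per callable site within a population,
  per non-overlapping window (1 Mb in the study design); the unbiased per-site
  estimator is 2c(n−c)/(n(n−1)) for c derived copies among n called alleles.
* **d<sub>XY</sub>** — mean cross-population pairwise differences per callable site.
  Under neutrality d<sub>XY</sub> = π<sub>anc</sub> + 2rT for substitution rate r and split
  time T, which motivates the decomposition D<sub>i</sub>(t) = π<sub>i</sub>(t) + R<sub>i</sub>t + ε<sub>i</sub>
  and its consequence
  **Cov(D(t), X) = Cov(π(t), X) + t·Cov(R, X) + Cov(ε, X)** —
  the covariance of divergence with any genomic feature X changes linearly in
  time with slope Cov(R, X).
* **dT** — the phylogenetic distance in generations between the MRCA nodes
  anchoring two statistics, e.g. dT(π<sub>W</sub>, d<sub>XY</sub>) = 2T<sub>VWXY</sub> − T<sub>XY</sub>; correlations
  between landscapes are plotted against it.
* **Kimura's fixation probability** u(s) = (1 − e<sup>−2s</sup>)/(1 − e<sup>−4Ns</sup>) —
  integrated over the fitness-effect distributions it yields per-class
  substitution rates, 2Nµ<sub>c</sub>·E[u(s)], and the package's fixation accounting.

## Worked example

Substitution accounting within exons along the human lineage under the
best-fitting selection parameters (deleterious rate 1.2×10⁻⁸ with gamma DFE,
shape 0.16, mean −0.03; beneficial rate 1×10⁻¹² with exponential DFE, mean
0.01; total exonic rate 2×10⁻⁸):

```python
from divland import DFEConfig, expected_substitution_rates, human_lineage_schedule

rates = expected_substitution_rates(DFEConfig.best_fit(), 2e-8, human_lineage_schedule())
print(f"beneficial share of exon fixations: {100 * rates.beneficial_fraction:.1f}%")
print(f"exon / neutral substitution rate:   {100 * rates.exon_to_neutral_ratio(2e-8):.0f}%")
print(f"beneficial fixation rate:           {rates.beneficial:.2e} per exon bp per generation")
```

prints

```
beneficial share of exon fixations: 7.4%
exon / neutral substitution rate:   59%
beneficial fixation rate:           8.75e-10 per exon bp per generation
```

i.e. roughly one in thirteen exonic fixations is driven by positive selection,
purifying selection removes ~40% of would-be exonic substitutions, and a new
beneficial mutation fixes somewhere in a 30 Mb exome about every 40
generations.

The shell pipeline mirrors the library.  Generate a synthetic ten-population
dataset with the study's sample sizes, compute landscapes, and correlate them:

```bash
divland synth      --outdir data --seed 1
divland landscapes --vcf data/variants.vcf --populations data/populations.tsv \
                   --mask-dir data --outdir land --chrom-length 8000000
divland correlate  --landscapes land/landscapes.tsv --tree data/tree.nwk \
                   --tree-params data/tree_params.tsv --outdir corr \
                   --exclude-shared-branches
```

`corr/correlations.tsv` then holds one row per landscape pair with its
Spearman ρ, dT, comparison type (π–π, π–d<sub>XY</sub>, d<sub>XY</sub>–d<sub>XY</sub>) and low-Ne flag.

## Layout

| module | contents |
|---|---|
| `divland.demography` | dated species tree, MRCA, dT, branch sharing, great-apes default |
| `divland.landscapes` | windowed π/d<sub>XY</sub>, callable masks, window filters, W/S site types |
| `divland.simulator` | forward Wright–Fisher with exon-restricted selection; neutral multispecies-coalescent mode; Q-rescaling |
| `divland.mutation_maps` | per-window mutation-rate maps and mutation overlays |
| `divland.correlation` | pairwise Spearman records, covariance decomposition, PCA |
| `divland.fixation` | diffusion fixation probabilities and substitution-rate accounting |
| `divland.synthetic` | seeded synthetic dataset generator (VCF/BED/TSV + truth JSON) |
| `divland.cli` | `divland` command with one subcommand per stage |

See `docs/methods.md` for the models, parameter choices and limitations.
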