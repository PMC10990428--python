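# Methods

This note documents the models implemented in `divland`, the default
parameter values and why they were chosen, what the synthetic data do and do
not emulate, and the numerical and design decisions that were genuinely open.

## Windowed statistics

Diversity and divergence are computed in non-overlapping windows (default
1 Mb) from biallelic SNPs.  Per site with `c` derived copies among `n` called
alleles, diversity contributes `2c(n-c)/(n(n-1))` (all unordered pairs among
the 2×(diploid samples) alleles, including the two alleles of one individual);
divergence between populations A and B contributes
`(c_A(n_B-c_B) + c_B(n_A-c_A))/(n_A n_B)`.  Monomorphic callable sites enter
denominators only.  A site is used only where callable in **all**
populations: masks are intersected up front.  Windows with a jointly-callable
fraction strictly below the threshold (0.40 in the main analyses, 0.05 in the
site-type-partitioned ones) are set to missing; a fraction exactly at the
threshold is kept.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted on read.

### Weak/strong site types

For the gene-conversion analysis a site observed in four species is
classified from one representative allele per species: both observed states
weak (A/T) or both strong (G/C) → `WW_SS`; one of each → `WS`; three or more
states → excluded (multiple mutations); one state → invariant.  The
representative allele is the within-species **majority** allele; ties and
missing data exclude the site.  This collapse rule is a package decision —
the classification is defined on one state per species and polymorphic sites
have no canonical representative.  Outgroup polarization maps an A/T outgroup
allele to "ancestrally weak", G/C to "ancestrally strong", and missing to
excluded.

## Forward Wright–Fisher simulator

Each branch of a dated species tree is one panmictic diploid population of
constant size.  Splits happen in a single generation: both daughters start as
byte-for-byte replicas of the parent; there is no post-split contact.
Generations are discrete Wright–Fisher: offspring pick two parents with
probability proportional to fitness (selfing allowed), each parent
contributes one recombinant gamete (crossover count Poisson with the genetic
map length; positions from the map), and new mutations arrive as Poisson with
rate 2Nµ per site-generation.

**Selection.**  Within exon intervals a new mutation is deleterious with
probability `frac_deleterious` (gamma-distributed effect, shape α, mean
`mean_s_del`), beneficial with probability `frac_beneficial` (exponential,
mean `mean_s_ben`), neutral otherwise; outside exons everything is neutral.
Selection coefficients are **per allele copy**: genotype fitness at a site is
1, 1+s, 1+2s (additive within a site), multiplicative across sites.  This
makes the simulator exactly the model whose fixation probability is
`u(s) = (1-e^{-2s})/(1-e^{-4Ns})`, the form used throughout the fixation
accounting; equivalently it is the h = 0.5 semidominant model with homozygote
coefficient 2s.  Mean effects quoted for DFEs (e.g. −0.03, +0.01) are on this
per-copy scale.

**Fixations.**  A variant reaching frequency 1 within a branch is recorded
(branch, position, class, s, generation) and becomes a fixed difference
carried by all descendants; fixed neutral sites contribute to divergence.

**Burn-in.**  The root population starts without variation and burns in for
`burnin_factor × root Ne` generations (default 10×, several coalescent
times), standing in for ancestry-completion machinery: the intent — a
stationary ancestral population — is the same, without genealogy recording.

**Q-rescaling.**  `rescale(config, Q)` divides every Ne, branch length and
the burn-in by Q and multiplies µ, r and (at draw time) s by Q, preserving
4Nµ, 4Nr and 4Ns up to rounding (minimum population size 2; exceeding it is
an error).  Rescaling preserves means of diversity statistics but inflates
coalescent-time granularity and the strength of interference; tests therefore
compare rescaled runs through means and counting statistics, not higher
moments.

**Known bias at desk scale.**  At the deliberately dense mutation/selection
rates used in tests, Hill–Robertson interference makes forward runs fix ~10%
more deleterious and ~15% fewer beneficial mutations than the single-locus
diffusion predicts (measured over 16 replicates during development).  This is
real population genetics, not an implementation defect — the diffusion oracle
assumes independent sites.  Acceptance comparisons use 3σ counting intervals,
which the bias stays well inside at the chosen rates.

## Neutral multispecies-coalescent mode

`simulate_neutral_windows` represents each window by
`k = max(1, round(10 × map length in cM))` independent recombination-free
genealogies simulated under the multispecies coalescent (msprime) with the
tree's branch sizes.  The constant — ten loci per cM of window map length —
reproduces the qualitative behaviour of low-recombination windows (a window
with map length ≈ 0 collapses to a single genealogy and shows high coalescent
variance) without a full coalescent-with-recombination, and makes per-window
variance shrink as map length grows.  Stored per window: the mean pairwise
coalescence time for every population and pair (from branch-mode
diversity/divergence divided by two).

### Mutation-rate maps and overlays

Per-window neutral rates are drawn i.i.d. Normal(µ̄, σ_rel·µ̄) and truncated
below at 0 (whether negative draws should be redrawn instead is unknowable
from the study design; at the design's σ grid, 0.005–0.150, truncation is a
≥ 6.7σ event and effectively never fires).  Where exons overlap a window the
non-neutral exonic rate is subtracted (floored at 0) so the *total* mutation
rate stays flat.  One map is shared identically by all branches.

Overlay: per window and statistic, expected per-site value `2·rate·T̄`,
realized as Poisson over the callable length.  Because the genealogical
summaries are reused across maps, the overlay isolates the effect of the map
exactly — the tests exploit this by drawing all σ values with the same normal
deviates, so plateau correlations are monotone in σ realization-by-
realization.

## Correlation analysis

Spearman correlations (average ranks on ties) are computed over pairwise-
complete windows; fewer than three complete pairs leaves the record
undefined.  Each record carries dT (distance between the statistics' MRCA
nodes, from the same tree used for simulation), the comparison type, a
shared-branch flag (edge sets of the two statistics intersect, where a
divergence is defined by the tip-to-tip path through its MRCA and a diversity
by its terminal edge — an operationalization of "overlapping" comparisons),
and a low-Ne flag (any involved tip with Ne below 8×10³, configurable).  Note
the default tree's human branch (7,672) sits below that threshold, so human
comparisons are flagged alongside the three societies-of-small-size
populations; the published description of which species count as "low-Ne" is
itself ambiguous on humans.

The covariance decomposition is a statsmodels-backed OLS of Cov(D(t), X) on
t across divergence pairs; the slope estimates Cov(R, X).  An optional
"middle half" restriction keeps the interior 50% of windows by index,
excluding chromosome-end effects (the boundary is a package choice; the
study's tail-exclusion rule is not specified).  PCA of the runs ×
correlations matrix is column-centered without variance scaling (the entries
are already commensurable correlations); missing entries are imputed by
column means and logged.  The published column count of the corresponding
matrix (1,260) is not derivable from the main text and is deliberately not
hard-coded.

## Fixation accounting

Per-class substitution rates within exons: `rate_c = µ_c · 2N · E_f[u(s)]`
with the expectation over the class DFE by adaptive quadrature, split at the
drift barrier s = 1/(4N) where the integrand changes character (the gamma's
power-law spike at 0 is effectively neutral and must not be lost).  Neutral
class: exactly µ_n.  For a time-varying lineage an explicit (N, duration)
schedule is duration-averaged.

The default human-lineage schedule uses split times 480k/320k/240k
generations (12/8/6 Myr at 25-year generations) and interpolates the two
published sizes (root 125,089, human branch 7,672) log-linearly in time at
segment midpoints, giving ≈ 49k and ≈ 12k for the two intermediate branches.
Only the two endpoint sizes are published; the interpolation, the 25-year
generation time, and starting the lineage at the root split (excluding the
root branch, whose duration is a burn-in artifact) are package choices, and
they dominate the uncertainty of the three headline numbers (the beneficial
rate scales almost linearly with the time-averaged N).  With this schedule
the accounting yields a 7.4% beneficial share of exon fixations, an exon/
neutral rate ratio of 59%, and a beneficial rate of 8.8×10⁻¹⁰ per exon bp per
generation (all computed by `scripts/acceptance.py` at run time).

## Synthetic data

The generator emulates the *structure* of the empirical inputs: ten
populations with the published sample counts (9, 13, 10, 6, 4, 4, 3, 27, 5,
5 diploids), nucleotide ref/alt states, per-population callable masks with a
configurable share of windows pushed below the 40% threshold, an outgroup
(ancestral) allele on a configurable fraction of sites (default 0.7), an
exon-density profile, and a recombination map with elevated rates toward the
chromosome ends.  Variation comes from the package's own neutral coalescent
mode; mutations are placed on the window genealogies, so the generator's
internally computed landscapes (stored in the truth JSON) match landscapes
recomputed from the written VCF exactly.

Non-biological simplifications, deliberate and documented: nucleotide
assignment is uniform over ordered ref/alt pairs (no transition bias, no CpG
model — just enough structure to exercise the weak/strong machinery); the
joint callable region of a window is a single wrapped block rather than the
fragmented empirical pattern; per-population masks differ from the joint mask
only by small disjoint extensions (so intersection recovers the designed
fraction exactly); coordinates are a synthetic chromosome, not any reference
assembly.  Passing round-trip tests on these data therefore demonstrates the
correctness of the computational pipeline, not robustness to real callability
artifacts, reference bias, or mutation-spectrum structure.

## Problem sizes in tests

Tests and acceptance checks run at desk scale by design: populations of
20–250 diploids, chromosomes of 5 kb–200 Mb (the latter only in the
coalescent mode, which is O(windows), not O(bp)), 200–250 windows for
calibration checks, two- to four-tip trees for forward runs, and Q ∈ {10, 25,
50} rescaling of any realistically sized configuration.  Stochastic
assertions use three-standard-error (or 3σ counting) intervals with fixed
seeds chosen once; generator defaults (sample sizes, 1 Mb windows, rate 2e-8,
the σ grid) are the study conditions themselves.

## Limitations

No migration or post-split contact; constant size within a branch; no sex
chromosomes; no gene conversion as a simulated force (weak/strong site types
diagnose it in data, but the simulator does not generate it); no
time-evolving mutation maps; dominance fixed at the additive h = 0.5
convention; FST and other relative-divergence statistics are out of scope.
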