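# Methods

This note documents the statistical procedures, the defaults and their
rationale, the design choices made where the underlying protocol was
genuinely open, and what the synthetic benchmark does and does not show.

## Target-decoy FDR

The FDR estimator is the plain decoy/target count ratio at a score
threshold, `FDR(t) = D(t)/T(t)` with `D(t)`, `T(t)` the numbers of decoy
and target PSMs scoring at least `t`. The q-value of an item is the
minimum FDR over all thresholds that retain it — equivalently the running
minimum of FDR along decreasing score. We deliberately use the simple
ratio rather than the `(D+1)/T` correction: it matches the behaviour of
the commercial search platforms of the era whose exports this pipeline
consumes, and the choice is isolated in `decoy_fdr` should a conservative
variant be preferred. Ties in score are treated as a single threshold
block, so a decoy tied with a target always counts against it — the
conservative tie policy. Decoy items receive q-values for diagnostics but
are always removed by the filter.

FDR control is applied at the PSM level, per export table, before any
rollup. Protein-level error control is approximated by requiring all
quantification evidence to come from q-passing PSMs plus the two-peptide
rule; an explicit protein-level (picked-target) FDR is not computed, since
the upstream platform's protein-level procedure is not reproducible from
its exports. This approximation is documented rather than hidden.

## Channel deconvolution

With heavy ¹³C₆ Lys/Arg in one cell population and light in the other,
every tryptic peptide (which ends in K/R except at the protein C-terminus)
carries at least one label-informative site. A PSM is HEAVY when all K/R
sites carry the heavy label, LIGHT when none does. Two degenerate cases
are channel-undecidable and excluded from quantification everywhere:

* peptides without K/R (C-terminal tryptic peptides) — no site to read;
* partially labeled peptides (incomplete isotope incorporation) — these
  are dropped rather than fractionally allocated, because the analysis
  model is a hard partition of co-culture PSMs into two origin tables.

Excluding K/R-free peptides in the monoculture tables as well (where the
origin is actually known from the condition) keeps the quantified peptide
space identical between the conditions being ratioed; otherwise every
protein with a K/R-free C-terminal peptide would carry a systematic
mono-ward fold-change bias. Monoculture tables are audited: if more than
2 % of PSMs look like the opposite channel, a labeling-efficiency warning
is raised (≈ 99 % incorporation implies ~1 % single-site misreads).

## Rollup and evidence filter

Only peptides occurring as a substring of exactly one database protein are
quantified (I/L distinct, no gene-level grouping — the protocol being
modelled used "exclusively unique" peptides without a grouping step).
PSMs with several accessions are excluded outright. Areas are summed per
replicate; a replicate without any unique-peptide PSM for a protein is
*missing*, not zero. %CV uses the sample (n−1) standard deviation — the
unbiased convention at n = 3. The evidence filter (≥ 2 unique peptides,
≥ 4 PSMs, ≥ 2 of 3 replicates, %CV ≤ 30) is applied per protein and
condition; rejections carry their first failing rule. Proteins whose only
evidence was shared/ambiguous peptides are emitted with zero counts so the
bookkeeping (input = retained + rejected) stays closed.

%CV is computed on raw, pre-normalization replicate areas: it must be
comparable across all six scenarios, including monoculture-only scenarios
where no normalization exists, and it is scale-invariant anyway.

## Normalization and fold change

The normalization factor per cell of origin is the ratio of total mean
peak area, mono over co-culture, computed over the evidence-passing
proteins and applied multiplicatively to every co-culture area of that
cell. Scaling the co-culture side (rather than mono) preserves the
monoculture CVs as reported and makes the co-culture total match the
monoculture total exactly, which is asserted to 1e-9 relative tolerance.
Total-area normalization assumes the bulk of the secretome is unchanged
between conditions and that differences in loading/dilution are global —
the standard assumption of label-based secretome comparisons.

Fold change is oriented co/mono so that up-regulation upon co-culture
reads FC > 1. FC exactly 1 is reported as FLAT, never silently binned
into up or down.

## Shortlist and secretion classes

Boundary semantics are taken literally from the protocol's comparators:
%CV < 10 and FC > 3 are strict, SignalP D ≥ 0.45 and SecretomeP NN ≥ 0.5
and %CV ≤ 30 are inclusive. By default `fc_magnitude_mode` is on: a fold
change below 1/3 shortlists alongside FC > 3, since a strong
down-regulation is as much a co-culture effect as an up-regulation; the
flag restores the literal one-sided rule when off. SignalP is checked
before SecretomeP — a signal-peptide-bearing protein is classical by
definition — making CSP and NCSP disjoint. Proteins without a score row
are UNSCORED rather than guessed.

The set partition counts each shortlisted accession as unique to its
scenario or shared between exactly two scenarios (the same secreted
protein can be shortlisted once per cell of origin); membership in more
than two scenarios is flagged for inspection, not merged.

## The synthetic experiment generator

The generator emulates the study design at PSM level: two cell lines ×
{mono, co-culture} × 3 replicates; per cell 15 mono-only, 15 co-only,
6 up- and 6 down-regulated candidates (FC drawn from 3.5–8, reciprocal
for down) over a 160-protein flat background — ~404 proteins in total,
the scale of the real experiment. Protein abundances are log-normal
(scale 0.5 around a 10⁶ area), split over 2–6 tryptic peptides with 1–4
PSMs each; replicate noise is log-normal with per-protein σ drawn from
0.05–0.25 for the background (%CV ≈ 5–25) and σ = 0.05 for planted
candidates — candidates are planted as clean, shortlistable signals so
that recovery measures the pipeline's logic rather than the noise floor,
while the background exercises the realistic %CV range and the evidence
filter. Additional realism: 10 % decoy PSMs with scores from a normal
distribution overlapping the targets', ~99 % per-site label
incorporation, 5 % replicate missingness, 5 % shared peptides (donated
only by background proteins that keep at least two unique peptides), and
half the proteins exposing a K/R-free C-terminal peptide. Secretion
scores are drawn from class-conditional uniform distributions straddling
the 0.45/0.5 cut-offs so the boundary logic is exercised.

Two calibrations make the generator a fair benchmark rather than a noise
source: co-culture areas are multiplied by a global dilution (0.6) so the
normalization step is non-trivial, and the planted composition is
mass-balanced per cell — the single-condition pools are rescaled so the
true quantifiable mono and co totals are equal. The balancing enforces
exactly the assumption total-area normalization makes; without it, the
planted up-regulation mass would bias every fold-change estimate by a
composition-dependent factor that no total-area method could remove.

All sampling comes from one seeded generator consumed in a fixed order
(proteins, shared peptides, balancing, target PSMs per condition, decoys,
scores), so a seed fixes every output byte and decoy settings cannot
perturb the target stream.

What passing the synthetic benchmark does **not** show about real data:
no spectrum-level effects (interference, isotope-cluster errors,
arginine-to-proline conversion), no retention-time structure, no
correlated missingness, no protein-inference ambiguity beyond simple
shared peptides, and secretion scores are planted rather than predicted
from sequence.

## Recovery metrics and problem sizes

Recovery is scored against the truth table: scenario recall over the
planted candidates (an undetected candidate is a miss), relative
fold-change error for recovered up/down candidates, and secretion-class
accuracy over shortlisted candidates. The acceptance script aggregates 20
seeds of the default (~404-protein) generator — roughly 1,700 candidates
and 470 fold changes — plus a noiseless configuration (zero noise and
missingness, full incorporation, no decoys or shared peptides) in which
recovery is exact to floating-point precision; the q-value oracle check
runs 1,000 random PSM lists of up to 50 items. These sizes give stable
percentages while keeping a full run under a minute on one CPU.

## Known limitations

* Protein-level FDR is approximated (see above), not computed.
* The 2^-ΔΔCt module implements the single-measurement formula; replicate
  aggregation and efficiency-corrected (Pfaffl) models are out of scope.
* Normalization totals are taken over evidence-passing proteins; a
  protocol that normalized on the unfiltered protein set would differ
  slightly when many proteins sit near the filter boundaries.
* The pipeline stops at annotated candidate tables; network, enrichment
  and survival analyses consume external services and are out of scope.
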