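# Methods

This note documents the models, parameters and design choices behind each
stage of `capmir`, and what the synthetic-data generators do and do not
emulate.

## Study design and scope

The analysis compares exactly two pooled libraries — fetal (FC) and
six-month (SMC) caprine muscle — with no biological replicates; every
statistic below is conditioned on that design. The pipeline consumes
pre-summarized inputs (count tables, mature/precursor/UTR sequences,
pathway sets): adapter trimming, genome alignment and annotation-category
assignment happen upstream and arrive as labels. Coordinates are 0-based
half-open throughout; sequences are stored in DNA spelling (U→T on input)
and converted back to RNA wherever base pairing is evaluated.

## Library profiling

QC and category percentages are exact decimal divisions rounded half-up to
two decimals, the convention of the published summary tables; the test
suite reproduces every printed Table cell from the printed counts.
Read-length distributions are read-weighted over 18–30 nt with an `other`
bin. Nucleotide-bias matrices cover first-base composition for lengths
18–25 and per-position composition for positions 1–24 (longer reads
contribute only their first 24 positions); each row is normalized over the
sequences long enough to contribute.

## Differential expression

* **Normalization.** NE = 10⁶·count/total, in transcripts per million;
  totals are whole-library clean-read counts, not column sums.
* **Fold change.** log₂(NE₁/NE₂). A zero NE on one side receives a
  pseudocount of 0.01 TPM before the ratio (chosen so that no nonzero
  printed ratio is perturbed); both-zero features carry an undefined fold
  change and are never called differential.
* **Exact test.** Conditional on x, the second count follows a negative
  binomial with r = x+1 and success probability N₁/(N₁+N₂); the two-sided
  p doubles the smaller tail and caps at 1. Tails are evaluated through
  the regularized incomplete beta function, stable at library-scale counts
  (x+y ≈ 10⁷). Two conventions: the no-observation cell x = y = 0 returns
  p = 1 (no evidence), and values within 10⁻⁹ of 1 are clamped to 1 to
  absorb float noise at the symmetric center. The doubled-tail p is only
  asymptotically symmetric under exchanging (x,N₁) with (y,N₂) — an
  intrinsic property of the conditional formulation — while the fold
  change negates and up/down calls swap exactly.
* **Multiplicity.** Benjamini–Hochberg step-up across all tested features
  (statsmodels), preserving input order.
* **Calling.** `up`/`down` at FDR ≤ 0.001 and |log₂| ≥ 1; scatter classes
  at ratio 2 and 1/2 boundaries (upper bound inclusive).

## Folding engine

A deliberately simplified nearest-neighbor model, built so that every
reported energy can be re-derived by exhaustive enumeration on small
inputs:

* Watson–Crick and G·U pairs; stacking free energies for the 21 distinct
  stack types (WC/WC values adapted from published 37 °C nearest-neighbor
  tables, rounded; all wobble-containing stacks −0.5 kcal/mol, wobble-on-
  wobble −0.4), with the physical symmetry E(p,q) = E(rev q, rev p)
  enforced programmatically.
* Length-dependent hairpin (≥3 unpaired), bulge and internal-loop
  penalties with logarithmic extrapolation beyond tabulated sizes; affine
  multibranch cost 4.6 + 0.4/branch + 0.1/unpaired kcal/mol.
* No dangles, terminal-AU penalties, tetraloop bonuses or coaxial
  stacking. Absolute MFEs therefore differ from Turner-complete folders,
  which is why every energy threshold is configuration-exposed for
  recalibration.

Energies are integers in units of 0.01 kcal/mol end to end, so the
dynamic program, its traceback and the independent loop-decomposition
evaluator agree exactly with no float tolerance. The recursion is the
standard pseudoknot-free V/WM/W decomposition; interior loops are searched
up to 15 unpaired bases (standard practice). Co-optimal ties are broken by
a fixed traceback order (hairpin, stack, interior by loop size, leftmost
multibranch split), which makes structures deterministic; tests assert
energy equality with the enumeration oracle and evaluator-consistency of
the emitted structure. Folding a 320 nt window costs ~0.7 s.

## Hairpin screening

`evaluate_candidate` applies six flags whose conjunction is the verdict:
genome hits ≤ 10, mature length 16–30 nt, MFE < −18 kcal/mol, stem
residence (≤ 4 mature bases inside terminal loops, arm assigned by the
majority side of the mature's pairing partners), MFEI > 0.85, and a single
terminal loop. The stem-residence tolerance of 4 bases is this package's
choice; "resides in the stem" has no standard quantitative form. The
deterministic battery stands in for machine-learned pseudo-precursor
classifiers; reports carry a `mipred_surrogate` marker to make that
explicit.

The pipeline stage extracts hit ± 150 nt windows (clipped, strand-aware)
but judges only the stem-loop enclosing the mature read
(`candidate_precursor`): the flanks fold into structures of their own, so
the single-loop criterion applied to a full 320 nt window would reject
every real locus. Trimming selects the widest enclosing pair containing
exactly one terminal loop within a 150 nt span cap — occasional long-range
flank pairs would otherwise balloon the precursor through large interior
loops, which add no terminal loops.

## Target scanning

Plant-rule penalty scoring of the antiparallel miRNA–site duplex:
mismatch 1.0, G·U 0.5, bulged base 2.0, all doubled at miRNA positions
2–13 (seed plus central pairing region); cutoff 4.0; at most 2 consecutive
mismatches; no mismatch at the cleavage-site positions 10–11 (a wobble is
tolerated there, a true mismatch is not). Bulges are limited to one
unpaired base on either strand and one per site, charged at the miRNA
position following the bulge, so windows of length m−1, m, m+1 are scanned
at every UTR offset. All constants sit in `TargetRules`. The scanner
evaluates all windows through a prefix-sum vectorization of the identical
arithmetic (all costs are multiples of 0.5, so the two code paths agree
bit-for-bit), reconstructing alignments only below the cutoff. Duplex
energy — the sum of stacking terms over consecutively paired positions,
from the folding engine's table — is attached for ranking and reporting
only, not filtering; site lists should not be read as reproducing any
specific external target catalogue.

## Integration and enrichment

Only differential miRNAs with |log₂| ≥ 3 enter integration (the printed
"−3 ≥ log₂ ratio ≥ 3" criterion is read as |log₂ ratio| ≥ 3; the notation
as printed is unsatisfiable). DE targets are the intersection of their
predicted target genes with the DEG set, with directions attached to both
endpoints. Enrichment is an upper-tail hypergeometric test per pathway
with BH FDR across pathways (significance P < 0.05 and FDR ≤ 0.05),
replacing web-service enrichment tools with an oracle-verifiable
computation. The background is the set of genes expressed in either
library that carry pathway annotation — the natural choice when the
universe is not otherwise specified. Networks are bipartite miRNA–gene
graphs restricted per pathway, exported as TSV edge lists and GML; the
maximum-degree miRNA(s) are recorded as hubs.

## Synthetic data

The generators emulate the study's structure at desk scale:

* **Libraries.** Log-normal baselines (median 50 TPM, σ = 1.5 on the log
  scale — a typical dynamic range for miRNA abundances), a planted DE
  subset with symmetric rate split 2^(±effect/2), Poisson counts at depth
  10⁶ per library (a 1/15.6 stand-in for the study's clean-read totals;
  negative-binomial overdispersion available for robustness checks).
* **Hairpins.** arm + AU-rich loop + reverse-complement arm, with
  controllable stem length, loop length, GC and arm mismatch rate;
  defaults (stem 28, loop 6, GC 0.6) give precursors in the observed
  65–99 nt range.
* **UTRs.** Random background with planted reverse-complement sites;
  mutations are placed so the duplex position is a true mismatch (neither
  Watson–Crick nor wobble), making rule-based rejection deterministic.
* **Pathways.** Random memberships; designated enriched pathways
  oversample a favored gene set at configurable odds (default 20).

Not emulated: read-level errors and adapters, multi-mapping ambiguity,
GC-dependent coverage bias, correlated expression between features, and
biological overdispersion beyond the optional NB switch. Passing tests
therefore demonstrate correctness of the computations and calibration
under the stated sampling model, not robustness to those real-data
artifacts.

## Problem sizes and determinism

The test and acceptance suites use: the full 201×201 grid at depth ratios
{0.5, 1, 2} for the exact-test oracle; 2000 null and 5×1000 mixed features
for calibration; 20 replicates of 400 features for power; 100 random
sequences ≤ 13 nt for the folding oracle; 40 constructed hairpins and 40
composition-matched shuffles for the screen; 20 planted-site UTRs per
mutation setting; and the full N ≤ 60 hypergeometric lattice (stride 3 in
K and n in the acceptance script). All randomness flows from explicit
seeds; the demo pipeline is byte-reproducible given (seed, config).

## Known limitations

* The exact test inherits the no-replicate design: it measures sampling
  variability only, so p-values on real data overstate certainty wherever
  biological variability exists.
* Folding energies are model-specific; the −18 kcal/mol and 0.85
  thresholds should be recalibrated if candidates are to be compared with
  Turner-parameter folders.
* Target scanning is sequence-rule-based only — no conservation,
  accessibility or context scoring — and is expected to over-predict.
* Enrichment assumes pathway membership is independent of DE status under
  the null, as the hypergeometric model requires.
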