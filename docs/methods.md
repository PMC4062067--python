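# Methods

## The experiment being modeled

A pooled gain-of-function resistance screen proceeds: clone an ORF
collection en masse into an inducible lentiviral vector (in minipools of
~376 clones, re-pooled before packaging), infect a reporter cell line at
low multiplicity of infection, sort for integrants, seed a bottleneck
aliquot, induce expression, and select in a lethal drug dose alongside a
DMSO (vehicle) control for two to three weeks (~20–30 cell doublings).
Surviving inserts are PCR-amplified and hybridized on a two-channel array,
or sequenced. Analysis then has three parts: library-representation QC from
read coverage, enrichment-based hit calling from paired intensities, and
per-candidate validation from dose-response and DNA-damage readouts.
`orfscreen` implements all three plus a generative simulator so every stage
is testable without any experimental data.

## Simulator

**Library.** Synthetic ORFs get log-normal lengths (median ~1.1 kb,
log-SD 0.65, clipped to 200–6,000 nt — the plausible span of a full-length
human ORF collection) and sequential pool assignment, so `ceil(n / pool)`
pools with only the last partial. Note the canonical full-scale numbers are
arithmetically inconsistent (12,212 = 32·376 + 180, not 34 pools of 376);
the ceil convention yields 33 pools and we treat the published "34" as a
rounding of the wet-lab bookkeeping, not something to reproduce.

**Bottleneck.** Seeding `N` cells from the integrated population is one
multinomial draw with weight ∝ length⁻ᵝ. β defaults to 1, which reproduces
the observed over-representation of short clones (Spearman ρ between length
and count strongly negative); β = 0 gives the exchangeable null. Totals are
conserved exactly — every allocation in the package is a single multinomial,
never independent rounding.

**Infection.** Integrations per cell are Poisson(λ), λ = MOI = 0.3 by
default; the infected fraction 1 − e⁻λ ≈ 25.9% is returned alongside the
counts. The simulator models the sorted (post-selection-for-integrants)
population in all downstream stages, so infection is reported as a design
diagnostic rather than chained into the bottleneck.

**Selection.** Discrete non-overlapping generations, survive-then-double:
a cell carrying ORF i survives with sᵢ = min(1, (1 − k)·eᵢ) under drug
(sᵢ = 1 in vehicle), then divides. This is the simplest branching process
consistent with "20–30 doubling times"; its mean trajectory is N₀·(2s)ᵍ,
which the tests verify against a per-cell brute-force oracle. Survival
draws are binomial per ORF (exact when s = 1, so unselected growth is
deterministic doubling). A carrying capacity (default 10⁸ cells; the
bundled desk-scale scenario uses 10⁶) caps the population by multinomial
downsampling each generation — flasks saturate, and relative frequencies,
which the readout measures, are preserved in expectation.

**Kill rate and effect sizes.** Neither the per-generation kill probability
nor the effect-size distribution of resistant clones is published. Defaults
are k = 0.6 and, for the planted clone in the bundled scenarios, a survival
multiplier e = 1/(1 − k) = 2.5 (full resistance). Under these conditions a
sensitive clone's expected lineage decays as 0.8ᵍ (≈ 0.004 over 25
generations from 41 starting cells) while the resistant clone grows to the
capacity, giving the ≥ 2⁶-fold abundance advantage the dual thresholds
require. These are discriminating-fixture choices, not estimates of any
particular drug.

**Array readout.** Probe signal is max(floor, (H·counts)·2^ε) with
ε ~ N(0, σ²) independent per probe and channel; H is the bleed matrix
(identity by default; H[i,j] is the fraction of ORF j's signal appearing on
probe i, how near-identical paralogs create false positives). σ defaults to
0.5 log₂-units — moderately noisy hybridization — and the floor to 1 raw
unit, guaranteeing finite logs. Intensities are on the raw abundance scale;
no probe-level summarization or between-array normalization is simulated.

**Coverage.** Reads are allocated to ORFs by a multinomial with weight
count·length (abundant, long templates yield more fragments), placed
uniformly, single-end, no mapping error; intervals are 0-based half-open.
Mean depth per ORF is reads·read_len/length (Lander–Waterman), which the
tests check by simulation.

**Seeds.** One master seed expands into per-stage child streams via
`numpy.random.SeedSequence(seed).spawn(n)`; identical config and seed give
bit-identical abundances, intensities, coverage and pipeline outputs.

## Library QC

Per-ORF summaries are the mean depth and the fraction of bases at or above
each threshold in {1, 5, 10, 20, 50} (bracketing the 10× rule;
non-increasing in the threshold by construction). Presence is called
inclusively: present ⇔ frac(≥10×) ≥ 0.95, reading "at least 95%" at the
boundary. The library presence rate is computed over mappable ORFs only;
mappability is an annotation flag supplied by the user (the simulator marks
everything mappable), never inferred — published rates on real data depend
on an unpublished mappability definition, so the package makes it explicit
input. Constant-length libraries raise a typed error from the trend
diagnostic rather than returning a silent 0: silent zeros hide fixture
bugs.

## Hit calling

Enrichment coordinates are x = log₂(max(I_drug, floor)) and
y = x − log₂(max(I_DMSO, floor)). Hits satisfy y > 3 **and** x > 6,
strictly — the published rule is written with ">" and the tests pin the
boundary reading (y = 3.0 or x = 6.0 exactly is not a hit). Thresholding
is applied per replicate and the resulting sets intersected (support ≥ 2),
rather than thresholding replicate means; the source procedure is ambiguous
on this point and per-replicate intersection is the stricter reading.
Ranking is by mean y descending (the ranking key is unpublished; mean
enrichment is this package's documented choice, configurable), ties by
mean x, then identifier — fully deterministic. Cross-hybridization flags
are annotations, never filters: a hit is flagged when a declared
(probe, source, weight ≥ 0.2) pair exists whose source has mean x at least
as high. No between-array normalization is applied by default (none is
described for the original procedure); optional median scaling is available
for real data. Replicate pairing is explicit sample-sheet metadata —
silent mispairing is the worst failure mode, so it is never inferred from
column order.

## Validation statistics

Viability is percent of a no-drug control. Dose-response curves are fit by
least squares to the variable-slope 4PL in the log-IC₅₀ parameterization
V(c) = bottom + (top − bottom)/(1 + 10^(hill·(log₁₀c − log₁₀IC₅₀))), which
makes the fit exactly equivariant under rescaling of the concentration
axis (IC₅₀ scales, hill/top/bottom unchanged). Initialization is
deterministic — top = max, bottom = min, log-IC₅₀ = mean log concentration,
hill = 1 — so fits are reproducible without global optimization;
non-convergence sets a flag rather than raising, and a `trusted` flag marks
IC₅₀s within 10× of the tested range. Preconditions reject flat series
(< 10 percentage-point span), series with fewer than 4 distinct
concentrations, and viability that rises with dose.

Rescue efficiency is the normalized viability gain
100·(V_induced − V_uninduced)/(100 − V_uninduced), clamped to [−100, 100]:
0 at no effect, 100 at full restoration. The published ranges come with no
formula; the absolute-difference form is available by argument and outputs
are labeled with the definition used. Foci rescue is the percent reduction
in mean γ-H2A.X foci per nucleus; per-condition summaries are mean ± SEM
(SD/√n, n ≥ 2). Fold shifts are reported unrounded; integer rounding
("two-fold") happens only in the reporting layer. The synthetic viability
generator uses 2% proportional noise — the CV of a well-replicated SRB
readout; under that model triplicate 7-dose curves recover IC₅₀ within 5%
in ≈ 99% of fits.

## Pipeline

`run_screen_pipeline` chains simulate (or ingest of user tables) → QC →
hit calling → validation under one master seed, writing TSV/bedGraph
outputs and a manifest of per-stage seeds, wall times and SHA-256
checksums. Configs are flat YAML and round-trip losslessly; unknown keys
are rejected at load. A failing stage aborts with the stage named and a
partial manifest on disk; a config without a drug channel degrades to a
QC-only run with an empty hit table. The validation stage demonstrates the
statistics on simulated SRB curves for the top hit (a 4× planted IC₅₀
shift) — with real data, `orfscreen validate` consumes user dose-response
and foci tables directly.

Design calculators: cells per ORF = total/n (41 at the 500,000-cell screen
bottleneck for 12,212 ORFs; 1,300 at a 16-million-cell representation
aliquot, 2 significant figures), and genome equivalents per ORF =
(µg·10⁶/pg)/n with the diploid genome mass an explicit parameter
(default 6.6 pg → 74.4 for 6 µg over 12,212 ORFs; published planning
numbers round this to ~75).

## Problem sizes and what the tests show

The bundled scenarios run at one 376-ORF pool, 41 cells per ORF, 25
doublings, two replicates, carrying capacity 10⁶ — the single-minipool
proof-of-concept geometry, where a planted resistant clone is recovered at
rank 1 in ≥ 95% of 200 seeded screens and a 30%-bleed paralog is hit-but-
flagged in 100% of 50. Passing these shows the analysis correctly inverts
the simulator's generative model at realistic stochasticity; it does not
certify performance on real arrays, whose probe-level effects (GC bias,
saturation, batch structure, partial homology patterns) the simulator
deliberately omits. Real-data quantities that depend on deposited wet-lab
measurements (the 87% presence rate, published hit lists, the 45–60% and
30–42% rescue ranges) are represented as fixture scenarios exercising the
same code paths, not as reproduction targets.

## Known limitations

No PCR amplification bias, paired-end reads, mapping error or multi-probe
array model; no significance testing or FDR for hits (the procedure is
fixed-threshold by design); minipool identity does not constrain infection
(pools are modeled as fully re-pooled); dose-response inference stops at
descriptive fits — no between-condition hypothesis tests.
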