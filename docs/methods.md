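# Methods

This note documents the models behind `xnapore`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Pore model

The residual current of MspA is treated as a function of the k nucleotides
in the constriction; k = 4 by default (configurable).  Over the six-letter
alphabet {A,C,G,T,Z,Q} this yields 6^4 = 1296 distinct window states, each
mapped to a mean blockade current in pA by a `KmerCurrentTable`.

Synthetic tables are constructed, not measured: absolute pA values of real
recordings depend on salt, voltage and pore mutant and are not reproducible,
so the table only reproduces the *structure* of the measurement:

* natural (ACGT-only) windows draw uniformly from a base range, default
  15–65 pA, the typical span of enzyme-stepped MspA levels;
* every d5SICS (Q) in a window adds a fixed offset, default +15 pA, to the
  window's Q→C homolog — Q consistently raises the current, by an amount in
  the 10–20 pA range;
* windows containing dNaM (Z) are shifted by a context-dependent offset of
  magnitude 5–15 pA with random sign (one draw per Z-containing context, so
  a window and its Q→C homolog share the same Z contribution and the per-Q
  offset is exact) — Z raises some levels and lowers others;
* an abasic residue (X) overrides the whole window to a constant high
  current, default 60 pA, rather than expanding the table to 7^k.

Identical seed and parameters give byte-identical tables.

`ideal_level_series` converts a template into the noise-free level
staircase.  phi29 forced unzipping advances one nucleotide per level:
L − k + 1 levels for a length-L template, level i reading positions
i…i+k−1 in 5'→3' order.  Hel308 advances in two sub-steps per nucleotide:
half-step levels are interleaved between full steps, 2(L − k + 1) − 1
levels in total.  **Half-step currents are modelled as the arithmetic mean
of the two flanking full-step currents.**  No half-step current model is
available from first principles; interpolation is the simplest model that
reproduces the observed footprint structure (an interior substitution
perturbs k full levels under phi29 and 2k + 1 interleaved levels under
Hel308).  Real half-steps are not exact interpolations — abrupt transitions
between adjacent half-levels occur — so this is a stated simplification.

Index conventions: level series are stored 5'→3'.  Hel308 walks 3'→5', so
its temporal trace order is the reverse of sequence order; simulation uses
`temporal_currents()` and analysis re-orients consensus tracks with
`orient_for_sequence` (an involution; phi29 tracks pass through unchanged).
Whether a real recording's first level corresponds to the 5'- or 3'-most
window is a registration convention, not a claim.

## Squiggle simulation

`simulate_stepping` walks the level staircase with three stochastic
elements, all seeded:

* **dwells** — exponential with mean 0.05 s (a single rate-limiting step).
  Real dwell distributions are heavier-tailed (occasional >10 s levels); a
  log-normal mode with matched mean is provided, off by default.
* **backsteps** — after each forward arrival, with probability 0.05 the
  previous level is re-emitted once and the walk resumes (the "repeated
  level" signature of transient backward motion).  Multi-level retractions
  are not modelled.
* **skips** — each advance is a two-level jump with probability 0.02, so
  one level is never emitted.

Backstep/skip rates are not reported for either enzyme; the defaults are
plausible placeholders, exposed in `SimulationConfig`.

`render_trace` holds each emission's current for its dwell (quantized to
whole samples, minimum one) at 50 kHz, adds independent Gaussian noise
(default 3.2 pA at the acquisition rate), and records the true change-point
samples, level indices and move labels as annotations.
`downsample_by_averaging` averages non-overlapping blocks (default factor
10 → 5 kHz), shrinking white noise by √10 to ≈ 1 pA, and remaps annotations
by integer division.  Voltage and salt conditions are metadata only.

`simulate_level_read` generates measured-level reads directly (same
stepping model, Gaussian emission noise on level means, no sample-level
rendering).  It is used for ensemble studies of consensus, difference and
classification statistics, where the segmentation stage is not under test;
the full chain is exercised separately by the end-to-end scenario runs.

### What the generator does not emulate

Enzyme dissociation/rebinding, open-pore current, capacitive transients,
secondary-structure-induced repositioning of the DNA (which in real Hel308
data shifts levels far from a substitution in high-contrast regions),
current-vs-position sensitivity broadening of individual levels, and
event selection from multi-hour recordings.  Passing tests therefore
demonstrate correctness of the analysis under the stated noise model, not
robustness to every artifact of real recordings.

## Level detection

Recursive binary segmentation: each region is split at the sample
maximizing Welch's t between left and right means; a split is accepted if
t ≥ `t_threshold` and both children last ≥ `min_duration` (1 ms); the
procedure recurses into accepted children.  Ties break toward the earlier
sample, making output deterministic.  Two additions proved necessary:

* **Pulse test.**  A single split cannot certify a short excursion (e.g. a
  backstep level of a few tens of samples inside a long level): both sides
  of any one split are dominated by the surrounding level and the
  two-sample t stays low regardless of pulse amplitude.  Regions whose best
  single split is rejected are re-examined with an inside-vs-outside Welch
  t over a geometric ladder of window widths, splitting at both pulse
  boundaries when it passes the same threshold.  The inside window may hold
  very few samples, so the (homoscedastic) outside variance is used for
  both terms — small-sample inside variances otherwise inflate t and
  produce wholesale false splits.
* **Merge pass.**  Adjacent segments whose means differ by less than
  `merge_delta` are merged, absorbing splits that are statistically
  confident but physically meaningless.

Defaults were calibrated against the simulator: `t_threshold` = 4.5 keeps
the expected number of false splits per several-thousand-sample read well
below one (measured ≈ 0.3 on pure-noise traces) while the smallest
certifiable step at typical level durations (~250 samples, ~1 pA noise) is
≈ 4.5·σ·√(2/250) ≈ 0.4 pA; `merge_delta` = 0.4 pA is set to exactly that
floor, so the merge pass removes only what the test could not certify.

**Limitation:** adjacent levels whose true currents differ by less than
~0.4 pA are indistinguishable under ~1 pA noise at these dwell times.  With
uniformly drawn tables, a few percent of transitions fall below this floor,
so change-point recovery over *all* annotated change points is typically
96–99.5% rather than 100%, varying with the table draw.

Segmentation runs on the downsampled (5 kHz) trace.  Per-segment mean, SD
(population), duration and start sample are emitted; segments partition the
trace exactly.

## Alignment and consensus

Measured level means are aligned globally to the reference currents
(temporal order) by dynamic programming over moves
step (+1), skip (+2), stay/backstep (0/−1) and spurious (no reference
index), maximizing Gaussian emission log-density plus move penalties.
Defaults: emission SD 1.5 pA (levels reproduce to the picoampere scale;
no emission model is available, so a single global SD is used); penalties
step 0, stay_backstep −3, skip −4, spurious −5 log-units, consistent with
the simulator's default error rates.  Alignments must start at reference
level 1 and end at the last level; traceback ties prefer step over skip
over stay_backstep over spurious.  The DP score is verified against
exhaustive enumeration on all instance sizes up to 6 × 6.

Consensus per reference index: matched means are averaged within a read
first (how repeated levels should be weighted within a read is unspecified
in prior art; within-read-then-across-read averaging is this package's
choice), then across reads: mean, SD (ddof = 1; 0 for a single read), and
SE = SD/√N.  Consensus overlays quote SD — the single-read separability —
while difference tracks quote SE of the mean.  Reads scoring below an
optional floor are rejected (no principled event-selection rule exists for
synthetic data; the filter is exposed but off by default).  Indices with no
coverage carry n_reads = 0 and NaN statistics.

## Differential analysis

The difference track is Δ = variant − control per level (both arms oriented
5'→3'), SE(Δ) = √(SE_v² + SE_c²), z = Δ/SE(Δ).  Level indices are
optionally re-labelled as offsets with 0 at the first level whose window
covers the substituted position.  Affected regions are maximal runs of
≥ `min_run` = 2 consecutive levels with |z| ≥ `z_min` = 3 — "significant"
needs an explicit criterion and a two-level run at 3 SE keeps the
per-contrast false-call rate far below one while retaining full power for
the ≥ 5 pA offsets of the unnatural bases at study read counts (41/19
phi29, 48/49 Hel308).  Null contrasts (both arms from the same table)
produce z-scores with |mean| < 0.05 and SD within a few percent of 1 at
these ensemble sizes — the modest excess over 1 reflects SE estimation
with finite N.

Single-read classification at a known site: the read is aligned to both
references; the better-scoring alignment fixes which measured levels fall
in the window (the affected level range); the LLR evaluates those same
means under the two references' window currents and the label follows its
sign, with |LLR| below a 2 log-unit margin called ambiguous.  Evaluating a
common matched set keeps the statistic symmetric — otherwise the losing
alignment can shunt mismatching levels into "spurious" and escape the
emission penalty.

## Scenarios, problem sizes, and determinism

The shipped designs use a fixed 30-mer context with substituted sites at
least k − 1 positions from either end: eight single-substitution panels
(Q or Z replacing each canonical base at position 15 of the identical
context), the two-site contrast (Z at 11, Q at 20, both C in the control)
at the study read counts 41/19, and its Hel308 replica at 48/49.  Bundles
are fully seeded and byte-reproducible; per-read seeds derive from the
master seed via `numpy.random.SeedSequence`.

Statistical suites run at desk scale, chosen to finish in seconds while
leaving comfortable statistical margins: detection recovery over 50
simulated reads; alignment-vs-enumeration over all read/reference sizes up
to 6 × 6; consensus error scaling over ensembles of 5/10/20/41 reads with
8 replicates (log-log slope −0.5 ± 0.2); null-z calibration over 200
contrasts of 16 + 16 reads; classification over 500 reads per arm.

## Numerical choices

* Welch t uses sample variances (ddof = 1); sides of length 1 contribute
  zero variance; means closer than 1e−12 give t = 0.
* Segmentation and traceback tie-breaks are deterministic (earlier sample;
  higher-priority move).
* Dwell quantization: every emission occupies at least one sample.
* Downsampling truncates a trailing partial block.
* Consensus SD of a single read is reported as 0, not NaN, so SE remains
  defined; z is NaN where either arm lacks coverage.
* Degenerate inputs (empty reads, too-short traces or sequences, NaN
  samples, mismatched lengths/modes) raise `ValueError` with the offending
  quantity named.

## Known limitations

* Half-step interpolation understates the independent information of real
  Hel308 sub-steps.
* The detector cannot separate levels closer than the certifiable-step
  floor; reported recovery rates are conditional on the table draw.
* No de novo 6-letter basecalling: classification assumes the substitution
  site (and candidate identity) is known.
* Absolute currents are synthetic; only structural and statistical
  properties — footprint sizes, level counts, error scalings, calibration —
  are meaningful points of comparison with real recordings.
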