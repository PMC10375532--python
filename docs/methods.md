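# Methods

## Selection-sequencing screen model

The screen treats each sequencing condition as a multinomial sample over the
complete randomized-region variant space. Variant `v` carries two latent
quantities: an acylation probability `p_v ∈ [0,1]` (the chance its terminus
is aminoacylated and therefore protected from periodate oxidation) and a
procedural bias `b_v > 0` (its relative propensity to survive
ligation/reverse transcription/PCR). Selection read counts are multinomial
with cell probabilities ∝ `p_v · b_v`; the blank — the same pool taken
through sample processing without selection — is multinomial ∝ `b_v`. The
ratio of selection to blank frequencies therefore converges to `p_v` up to a
single global normalization, which is what makes the blank contrast an
estimator and not just a control.

PCR is not modeled as a branching process; any amplification bias is folded
into `b_v`. Only the bias, not its noise mechanism, matters for the
estimator being validated, and modeling jackpotting would add variance
parameters the analysis never consumes.

### Counting

Amplicon reads have a fixed layout (upstream flank, k randomized bases,
downstream flank), so flanks are matched at fixed offsets with a per-flank
substitution budget (default 1 mismatch per flank) and no indel alignment:
a read with an indel is structurally corrupt for this assay and is counted
as unmatched rather than rescued. The randomized k-mer itself must be
unambiguous A/C/G/T/U (T read as U); anything else is unmatched. Unmatched
reads are tallied, never dropped silently — selection losses are part of the
screen's accounting. Coordinates are 0-based half-open internally. Reads are
taken in the orientation given, with an opt-in reverse-complement flag,
because orientation is a property of the sequencing protocol rather than of
the algorithm.

### Enrichment, ranking, logos, selectivity

Frequencies use additive smoothing with pseudocount α = 1 by default
(`freq(v) = (count(v)+α)/Σ(count+α)`), keeping every enrichment ratio finite
and positive. Ranks and percentiles are computed on **raw selection read
counts**, not on enrichment — screens of this kind conventionally rank by
raw reads, with the blank-normalized ratio reported alongside for
interpretation — and ties break lexicographically so output is reproducible.
`top_fraction` takes the `ceil(fraction · 4^k)` best-ranked variants.

Position matrices weight top-set members by raw selection reads (default) or
equally; information content per position is `2 + Σ_b p(b) log2 p(b)` bits,
with `0·log 0 = 0`. Cross-condition comparison is the Pearson correlation of
raw count vectors; a zero-variance vector raises an error rather than
returning NaN.

The selectivity score is a declared convention (the originating studies use
the phrase without defining a formula):
`score(v, aa) = log2 e_aa(v) − max_{aa′≠aa} log2 e_aa′(v)` — the log2 margin
by which condition `aa` out-enriches its best competitor on `v`. It is the
simplest score whose per-condition argmax means "most idiosyncratically
preferred variant". No multiple-testing machinery is attached: the screen is
a ranking procedure, not hypothesis testing.

## Transfer kinetics

The kinetic scheme is minimal and closed-form: activated donor `D` decays by
duplex-weighted pseudo-first-order transfer (`θ k_T`, θ the donor fraction
annealed to the acceptor at the reaction temperature) in competition with
first-order hydrolysis (`k_H`), giving

    dD/dt = −(θ k_T + k_H) D,   dP/dt = θ k_T D
    Y(t) = Y_max (1 − e^(−k_obs t)),  k_obs = θ k_T + k_H,
    Y_max = θ k_T / (θ k_T + k_H).

This is the least structure consistent with plateaus below 100% and with the
observation that short (low-T_M) donors transfer poorly because a
significant fraction is dissociated at the reaction temperature. Re-annealing
of hydrolyzed donor and hydrolysis of the ester product are not modeled.
Units are hours and °C at all interfaces (Kelvin internally).

θ is supplied from the melting model (at T_R, with the stated donor
equivalents) rather than co-fitted: on a single time course `θ k_T` is one
identifiable quantity and splitting it without independent thermodynamic
information is ill-posed. A `theta="free"` mode exists for data rich enough
to support it (≥ 4 points required, by arity alone).

Fitting is multistart trust-region least squares: 20 starts (fewer are used
in bulk simulation studies) drawn log-uniformly over [10⁻³, 10²] h⁻¹,
seeded, best-of-starts returned; standard errors come from the Gauss–Newton
covariance at the optimum. All-zero time courses return `k_T = 0` with a
flag instead of failing.

The stereoselectivity factor defaults to the initial-rate ratio
`(θ k_T)_L / (θ k_T)_D`; whether such a factor is a rate ratio, a plateau
ratio, or a fixed-time yield ratio is ambiguous in the source literature, so
the rate convention is the default and a `mode="yield"` variant
(`Y_max,L / Y_max,D`) is exposed. A zero D-rate reports `inf` with a flag.

With `n` sequential equivalents of donor, each fresh batch converts the same
fraction `Y_1` of the remaining acceptor before hydrolyzing, so the plateau
compounds as `Y_n = 1 − (1 − Y_1)^n`. Only the plateau, not the full
multi-equivalent time course, is modeled.

## Duplex thermodynamics

Two-state, bimolecular, non-self-complementary hybridization with ΔCp = 0 —
the standard assumption for short oligonucleotide duplexes. The bound
fraction of the limiting strand solves the mass-action quadratic
`K x² − (K(a₀+b₀)+1) x + K a₀ b₀ = 0`; the discriminant is expanded
algebraically to `K²(a₀−b₀)² + 2K(a₀+b₀) + 1` (all terms positive) because
the naive form cancels catastrophically at large K, and the association
exponent is capped at 300 (θ is already 1 to machine precision there).
For equimolar strands T_M uses the closed form
`ΔH°/(ΔS° + R ln(C_T/4)) − 273.15`; otherwise a bracketed root of
θ(T) = 0.5. ΔH°/ΔS° are user inputs or fit parameters — nearest-neighbor
prediction from sequence is out of scope, as are salt and Mg²⁺ corrections.

Melting curves are modeled as baseline-weighted two-state signals,
`(1−θ)(m_ss T + c_ss) + θ(m_ds T + c_ds)`. The fit parameterizes (ΔH°, T_M)
with ΔS° derived, so multistart initial points can be spread across the
observed temperature window; it is seeded and invariant to affine rescaling
of the signal axis. Two degenerate cases raise explicit non-convergence
errors: a flat curve, and a curve a straight line explains nearly as well as
the two-state model (residual ratio > 0.2), which is the signature of a
transition lying outside the temperature window.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the estimators assume:
multinomial sampling at finite depth, log-normal procedural bias (median 1,
log-sd configurable; 0.5 in the stem-screen recovery studies), i.i.d.
per-base substitution errors (default 10⁻³), FASTQ written in DNA letters
(U→T) with constant 'I' quality since quality is unused downstream, and
Gaussian noise on yields (truncated to [0,1]) and melting signals. It does
**not** emulate indels, paired-end structure, PCR jackpotting, quality-score
structure, context-dependent error profiles, or chemistry-level mechanisms —
so passing recovery tests demonstrates estimator correctness under the
model's assumptions, not robustness to every artifact of real sequencing
runs. Sequencing depths and error rates of the original screens are not
public; the defaults are synthetic choices at the scale where multinomial
noise is clearly subdominant to the planted effects.

Two scenario constructions deserve note:

* **Planted read share.** To emulate a screen dominated by one variant at a
  known observed share (e.g. a trinucleotide carrying 44% of reads), `p` is
  set proportional to `target_frequency / b`, so the *expected selection
  read share* equals the target exactly regardless of the bias draw. The
  measured share then tests counting and ranking end to end against a known
  value.
* **Planted top-decile substrate.** For the overhang screen the favored
  pentamer gets `p = 0.9` against competitors drawn U(0.05, 0.5) under
  procedural bias log-sd 0.25. The margin analysis behind these numbers:
  since ranking follows raw reads (∝ `p·b`), bias log-sd 0.5 would push even
  the strongest true substrate out of the observed top decile in roughly a
  quarter of random draws — a scenario that would misrepresent the condition
  being emulated ("this variant is observed in the top 10% in every
  condition"). At log-sd 0.25 the planted variant sits in the top decile
  with ≈ 99% probability per condition.

Recovery of the true top-decile set (and the Spearman comparison against
true `p`) is measured on the **blank-corrected enrichment** ranking, since
enrichment is the screen's estimator of `p`; raw-count ranks are reported
alongside as the descriptive convention.

## Problem sizes and numerical defaults

Simulation studies use: screen recovery at k = 3, depth 2×10⁵, 20 seeds;
kinetic recovery on 10-point courses at noise sd 0.02, 100 seeds (6
optimizer starts per fit in bulk studies); stereoselectivity recovery over
20 L/D pairs; melting refits over 20 noisy curves at 2% of signal span;
closed-form-vs-ODE agreement over 1000 random parameter draws
(LSODA, rtol 10⁻¹¹) at a 10⁻⁸ absolute tolerance. These sizes give stable
medians while keeping any single study in the seconds-to-a-minute range.

## Known limitations

* Enrichment is a point estimate; no variance model or shrinkage is applied
  to low-count variants beyond the pseudocount.
* The kinetic scheme omits product hydrolysis, donor re-annealing after
  hydrolysis, and temperature dependence of rate constants.
* The melting model assumes exactly two states; intermediates or aggregation
  would bias ΔH°.
* Selectivity scores inherit the noise of every condition's enrichment; with
  many conditions the max over competitors is upward-biased.
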