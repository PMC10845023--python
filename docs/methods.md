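# Methods

This note documents the models implemented in `breathloop`, the choices
made where the design was genuinely open, and what the synthetic
generators do and do not establish about real data.

## Closed-loop training engine

The engine is a small deterministic state machine. Level *L* means: tap
once per *L* breaths, in blocks of *L* minutes. With a nominal breath
period of 6 s (10 breaths/min) every block expects about 10 taps
regardless of level, which is why a single tap-count tolerance (±1 tap)
works at all levels. A block is *consistent* when the tap count is within
that tolerance **and** the coefficient of variation of the inter-tap
intervals is at most `consistency_cv_threshold` (default 0.25). The
deployed app's exact consistency rule is not public; the CV rule was
chosen because it is robust to natural breath-rate variability (a perfect
but slightly irregular breather passes easily — per-breath CV ≈ 0.08
shrinks by √L when pooled over L breaths) yet fails single lapses (one
doubled interval among ten pushes the CV above 0.25). Both knobs are
configurable.

Promotion requires `repeats_required` (3) *consecutive* consistent blocks
at every level; a failed block resets the streak but never demotes, and
the streak persists across sessions. At level 10 the trainee stays until
the 60-session course ends. The distraction chime fires when an inter-tap
interval exceeds (1 + CV threshold) × the running median of the previous
intervals — a concrete, testable stand-in for the app's real-time
feedback.

Sessions are packed by running blocks at the current level until at least
5 minutes have been practiced; since block length equals the level in
minutes, sessions span 5–10 minutes by construction. A zero-lapse trainee
therefore reaches level 10 after exactly 3 × 9 = 27 consistent blocks.

**Simulated user.** Breath periods are lognormal (mean 6 s, SD 0.5 s).
Each tap spans `level` breaths; with per-breath probability `lapse_rate` a
count is lost, and the affected interval is stretched (×1.6–3.0, tapped
late) or shortened (×0.3–0.6, premature tap) with equal probability —
breaking both the count and the CV, as real lapses would. Sessions
completed come from a truncated normal (mean 40.64, SD 17.79, bounds
0–60). In cohort simulations the lapse propensity shares a latent
engagement trait with adherence (weight 0.6), on the rationale that
motivation and attentional consistency are not independent in trainees;
this is what makes sessions completed and final level correlate (ρ ≈
0.6–0.7 at n = 22).

## Interoceptive assessment scoring

The task has no stimulus onsets (eyes closed), so a trial's response time
is defined as the interval since the preceding tap; the first tap yields
no trial. The two 2.5-minute blocks are pooled before computing the median
and MAD (the alternative, per-block statistics, is a flag away via
`block_id`). A trial is attended iff |RT − median| ≤ 1 MAD, with ties at
exactly one MAD counted as attended and the MAD left unscaled (no 1.4826
normal-consistency factor): the threshold is stated in MAD units, not as a
robust SD estimate. The two-sided reading is the default because both
slow and fast outliers indicate a lost breath count; a one-sided variant
(only slow trials distracted) is available.

**A property worth knowing:** because the MAD is the *median* absolute
deviation, roughly half of all trials fall within one MAD of the median
whatever the data look like. The labeled attended/distracted split is
therefore pinned near 50/50 for continuous RT distributions and does not
itself measure how distracted a participant was; the distraction signal
lives in the *scale* statistics (the MAD and the RT CV grow with lapse
rate) and in which trials get the distracted label (genuinely deviant
ones). The classification is exactly invariant under positive affine
transformations of the RTs, up to floating-point ties at the decision
boundary.

## EEG network pipeline

Processing chain: zero-phase FIR band-pass at 8–12 Hz → epochs covering
the 4 s before each tap (events closer than 4 s to the recording start are
dropped and logged; optional ±amplitude epoch rejection) → minimum-norm
source projection → per-source analytic-signal envelope averaged over the
epoch → region-of-interest means per network and condition. No baseline
correction is applied: the pre-response window itself is the quantity of
interest. Activity is reported in 10⁻⁴ arbitrary cortical-source units.

**Head model.** A deliberately simple toy model: ~200 cortical patches on
the upper hemisphere of a 7 cm sphere, radially oriented dipoles in a
homogeneous conductor, sensed at 24 standard 10-20 electrode positions.
Rows are average-referenced and columns normalized to unit sensor RMS so
depth does not confound amplitude. The parcellation (medial prefrontal,
posterior cingulate/precuneus and angular gyri → DMN; dorsolateral
prefrontal and superior parietal → FPN; anterior insula and dorsal
anterior cingulate → CON) ships as an editable YAML fixture. Nothing in
the package's validation depends on anatomical fidelity; all claims are
recovery properties under this forward model.

**Inverse.** Depth-unweighted Tikhonov minimum norm,
W = Gᵀ(GGᵀ + λ·(mean eigenvalue of GGᵀ)·I)⁻¹, λ = 0.1 by default and
dimensionless. λ = 0 raises on the (rank-deficient, average-referenced)
sensor Gram matrix.

**Leakage and its correction.** With 24 channels the inverse operator
mixes networks substantially: driving one network puts 13–21% of the
reconstructed within-network envelope power into the others (the correct
network always receives ≥ 70%, an invariant asserted in the tests). Plain
ROI averaging therefore converts a true DMN change into a spurious
systematic FPN/CON change. The high-level estimator
(`estimate_network_activity`) corrects this by default: for mutually
incoherent oscillators the expected ROI envelope power is linear in the
per-network source powers through the known 4×4 (FPN, CON, DMN,
background) power-transfer matrix T of the inverse operator,
T[n,m] = mean over target sources i∈n of Σ_{j∈m}(WG)²ᵢⱼ; solving this
system per condition and taking square roots yields nearly unbiased
network amplitudes. The uncorrected ROI means remain available
(`leakage_correction=False` and the lower-level `network_activity`), and
the distracted-vs-attended relative response is a difference by default
with a ratio option.

**Synthetic EEG.** Each source in a network carries an independent-phase
oscillator at 9–11 Hz whose amplitude switches per trial with the trial's
intended condition (piecewise constant over inter-tap segments);
background patches oscillate at a fixed base amplitude; sensors add 1/f
plus white noise. Tap times give attended RTs near 8 s (SD 0.5 s) and
distracted RTs stretched ×1.8–2.8, so the median/MAD classifier recovers
the intended conditions well above chance (≈ 0.8 agreement ceiling, see
the classifier note above).

**Batch study conditions** (set once for the recovery suites): 17
simulated subjects per batch, two sessions each, 100 s recordings at
250 Hz (a scaled-down version of the 5-minute, 500 Hz assessment; the
full-rate default remains 500 Hz), between-subject amplitude CV 0.30,
session-to-session CV 0.10, DMN 10 → 5 (a 50% suppression) with FPN = CON
= 3 unchanged, DMN distracted/attended amplitude factor 1.5. Under these
conditions the pipeline detects the negative DMN change in essentially
every batch while the unchanged control networks stay non-significant at
the nominal 5% level.

## Trial statistics

- **Self-compassion scoring.** CSR is the mean of the six positively keyed
  items, USR the mean of the six negatively keyed items unreversed, the
  total the mean of all twelve with negatives reverse-scored (6 − r);
  hence total = (CSR − USR + 6)/2 identically. Missing items are an
  error, never imputed. The item keying is configurable.
- **Effect sizes.** Within-group d = (m₂ − m₁)/√((s₁² + s₂²)/2).
  Between-group d is the difference of mean change scores over the pooled
  change-score SD — the formula is not uniquely determined by published
  summaries, and the change-score contrast is the standard choice.
  Rounding to two decimals happens only at report formatting.
- **Test selection.** The paired comparison is gated on normality of the
  difference scores. The gate is Shapiro–Wilk at α = 0.05 by default; a
  Levene-style option (spread comparison of the lower vs upper half of the
  sorted differences) is provided because trial reports sometimes cite
  Levene in this role even though it is a variance-homogeneity test. The
  gated procedure's type-I error is calibrated (0.05 ± 0.01 over 10⁴ null
  replicates at n = 22).
- **Partial rank correlation.** All variables, covariates included, are
  rank-transformed; x and y ranks are residualized on the covariate ranks
  plus intercept and the Pearson correlation of residuals is taken, with
  df = n − 2 − k. With no covariates this equals plain Spearman exactly.
- **Mixed ANOVA.** Group × session via pingouin; with two within-subject
  levels sphericity holds trivially, Greenhouse–Geisser ε = 1, and the
  interaction F equals the squared two-sample t on change scores (the
  identity used as the test oracle).
- **Multiplicity.** No adjustment by default (the primary report is
  unadjusted p values); a Benjamini–Hochberg switch exists.
- Missing timepoints are handled complete-case per contrast; skipped
  blocks are listed in the report, never silently dropped.

## Synthetic cohort generator

Outcome scores are built on latent standard normals: T1 = m₁ + s₁e₁ and
T2 = m₂ + s₂(r_tt·e₁ + γ·u + δ·ζ), where u is the latent adherence score
(mapped through the Gaussian copula to an exact truncated-normal sessions
marginal), γ is set from the target Spearman between sessions and the
T2−T1 change via the bivariate-normal conversion ρ_Pearson =
2·sin(πρ_S/6), and δ completes unit variance (default test-retest r_tt =
0.7). Infeasible combinations raise an error naming the offending pair.
Scores are clipped to their scale ranges; clipping is monotone, so the
rank-correlation targets survive, at the price of a slight (<2%) SD
shrinkage for outcomes near a bound.

Network activity uses a change-score construction: Δ = μ_Δ + σ_Δ(ρ_b·b₁ +
α_c·z_Δsc + residual), where b₁ is the standardized baseline, ρ_b the
baseline-vs-change coupling, α_c the loading on the standardized
self-compassion change, and σ_Δ solved from a quadratic so that Var(T2)
matches the configured SD. Matching both timepoint SDs when the SD shrinks
mathematically forces a negative baseline-change coupling (regression to
the mean); the default ρ_b values are the feasibility-respecting choices
per network and group, with the DMN training-group value set to the
configured baseline-coupling target and the DMN behavioral coupling set to
the configured ΔDMN↔Δself-compassion target. USR changes are coupled to
total-score changes (ρ = −0.8) so that improvements are driven by reduced
uncompassionate responding, and CSR follows from the scoring identity.
Follow-up dropout (2 training, 1 control) is missing completely at random.

**What passing recovery tests shows — and does not.** The generator
matches first- and second-order summaries and targeted rank couplings of
the published tables. It does not emulate item-level psychometrics, floor
and ceiling shapes, non-normal outcome distributions, informative dropout,
or any EEG artifact structure (blinks, muscle, electrode drift) beyond
amplitude-threshold rejection. Recovery under this generator therefore
validates the *pipeline's* correctness and calibration, not the
robustness of the original findings to real-data pathologies.

## Known limitations

- The spherical head model and 24-channel montage bound source resolution;
  the cross-talk correction assumes the analysis lead field (it is exact
  only when forward and inverse models agree, as in simulation).
- The consistency rule, chime rule and session packing are principled
  reconstructions, not the deployed app's exact logic.
- Raw-data-dependent published quantities (individual p values, specific
  sample correlations, the exact ANOVA F) are reproducible only in
  distribution, via the recovery suites, not as point values.
- EDF files are read (via mne) but not written; synthetic recordings are
  exchanged as FIF plus CSV event tables.
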