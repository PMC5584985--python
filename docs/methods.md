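# Methods

This note documents the models and procedures implemented in striatumkit,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that affect results.

## Template-matching event detection (imaging, ephys)

Detection operationalizes "cross-correlation to a template" as the raw
running dot product of the signal with an un-normalized template; the score
of a perfect fit is the template's dot product with itself. An event is a
local maximum of the score sequence at or above a threshold fraction of the
perfect fit — 0.5 for calcium transients, 0.25 for cell-attached action
potentials. The correlation is zero-padded at the trace end so transients
that run off the recording are still scored (with proportionally reduced
dot products); a template aligned at the first sample is also considered.

Calcium-imaging specifics: events are accepted greedily in time with a 1 s
lockout; events within (stimulus + one frame, stimulus + 375 ms] are flagged
evoked — the one-frame offset skips the stimulus-artifact sample. Latency is
the first post-stimulus time at which the running dot product reaches half
the perfect fit; amplitude is the maximum ΔF/F₀ inside the first evoked
event's template-length window, and both are averaged over responding trials
only (an average over all trials would mix in undefined values). Spike
probability is the fraction of trials with at least one evoked event.

Cell-attached specifics: analysis is restricted to 1–100 ms (FSI) or
1–600 ms (SPN) after the stimulus. Two additional exclusions suppress
noise-matched false calls: the event's absolute amplitude must reach 10×
the sweep noise SD — computed with ±1 ms around the stimulus blanked, a
concrete reading of "the recording minus the stimulus artifact" — and its
score must reach 25% of the sweep's maximum score.

ΔF/F₀ uses a trailing (causal) 2 s baseline window truncated at the trace
start, so no post-event samples leak into F₀; the first sample uses itself
as baseline. Drift correction is rigid integer-pixel translation maximizing
the circular cross-correlation with the first frame, ties broken toward the
smallest shift.

## ROI, slice and unit quality control

An ROI is excluded when its pooled ΔF/F₀ SD is ≥ 0.0575, when it never
responds to the 10 suprathreshold stimuli, when its non-evoked/evoked event
ratio at suprathreshold stimulation exceeds 4.5, or when flagged saturating
or drifted. A slice requires at least 12 included SPNs of each subtype; the
threshold is applied as a fixed constant. In vivo units are included when AP
amplitude is ≥ 5× the noise band. FSI/SPN classification uses strict
thresholds on spike width and baseline rate (FSI ⇔ width < width_max and
rate > rate_min); the defaults (0.5 ms, 5 Hz) are working values — the
boundary used for any given array recording should be passed explicitly.

## Gaussian-mixture classification (population)

Baseline amplitudes are fitted per cell type with a two-component univariate
Gaussian mixture with unequal variances (EM via scikit-learn, 50 seeded
initializations, best log-likelihood kept; k = 2 is the only structural
input). The larger-mean component is "high-firing" (multi-AP responses);
cells are assigned by posterior, ties going to "low" — conservative toward
finding no drug effect in the high group. When stored mixture parameters
accompany deposited data, classification uses them directly without
refitting, making the counts deterministic. Cutoff agreement is the percent
of cells labelled identically by the mixture and by a fixed 0.05 ΔF/F₀
threshold, pooled across cell types. Drug effects are paired two-sided
t-tests within each cluster; the baseline-dependence of the effect is the
Pearson correlation and least-squares line of (post − pre) on pre.

## ISI band analysis and the Poisson surrogate (spiketrain)

Each ISI maps to an instantaneous rate 1/ISI and falls in half-open bands
[low, high): δ 0–4, θ 4–8, α 8–13, β 13–30, γ 30–100 Hz. A rate of exactly
100 Hz is outside γ; such ISIs stay in the denominator. Band fractions are
counts over the total number of ISIs.

The surrogate draws, for a unit with N ISIs and mean ISI λ, N ISIs from the
ISI law of a rate-matched Poisson process — an exponential with mean λ. The
phrase "Poisson distribution with λ set to the mean ISI" is read this way
because an integer-valued Poisson draw cannot represent ISIs in seconds; a
literal mode (integer Poisson counts of milliseconds, rescaled) is available
behind `isi_law="poisson-ms"` for comparison. Twenty simulations are run per
unit and the normalized band counts averaged across simulations (averaging
after normalization, since each simulation has the same N this equals
count-averaging). Excess gamma is the observed γ fraction minus this
expectation. For an exponential train at rate r the γ fraction has the
closed form e^(−r/100) − e^(−r/30) (≈ 0.1047 at 5 Hz), which the tests use
as an oracle. Across-band observed-vs-null comparisons use the
Sidak-corrected α = 1 − (1 − α₀)^(1/m).

Unit mean rate is count/duration when the recording span is known, else
(count − 1)/span of the spikes. Fold change is log₂(post/pre), undefined
(flagged) when the baseline is silent; percent-of-baseline is 100·post/pre.

## Electrophysiological features (ephys)

Current-clamp APs are peaks of dV/dt above 10⁴ V/s with a 2 ms minimum
separation, refined to the voltage maximum within 2 ms. AP onset/offset are
the waveform's intersections with a sliding mean baseline whose window is
10% of the current-injection length (crossings linearly interpolated); the
AHP runs from the AP offset to the next return to baseline. Half-width is
defined as half the onset-to-peak time — the stated definition, kept even
though it is not the conventional FWHM. AHP amplitude is the most negative
voltage over baseline, the integral is taken over the AHP span, and the
current equivalent divides the amplitude by R_in. For exact hand-checks the
baseline can be injected directly; the sliding-mean path is the default.

I/O curves use 500 ms steps from −0.4 to 2.0 nA in 200 pA increments; rate
is spikes per step duration; response duration is first-to-last AP peak
(0 with fewer than two spikes — "longest period of sustained firing" is not
otherwise defined, and first-to-last is the configurable reading);
normalized rate divides the count by that duration. Rheobase finds the
200 pA interval containing the first spike, then scans it at 10 pA.

Passive properties come from a subthreshold test pulse: the decay after the
step is fitted with a double exponential (nonlinear least squares,
multi-start on the two time constants; τ_fast is the smaller). The fast
component is the access transient, the slow one the membrane. R_in is the
membrane deflection over the injected current. The printed capacitance
formula ∫V_decay/(I·R_in) is dimensionally a time constant (it equals
τ_membrane), so the implementation divides once more by R_in:
C_m = ∫V_slow/(ΔV_slow·R_in) = τ_slow/R_in, which has farad units and
recovers the truth on forward-simulated RC circuits to well under 5%.
R_s = τ_fast/C_m; cells with R_s > 30 MΩ are flagged excluded.

## Operant schedules and devaluation (behavior)

RR-X rewards each press independently with probability 1/X ("every X times
on average"). RI-X runs an arming clock from session start: at each
X-second tick reward availability arms with probability 0.1, at most one
reward pending; the first press while armed collects and disarms. Under
saturating pressing RI-60 therefore delivers ≈ 0.1·T/60 rewards, the oracle
used in tests. NDLPr = log₂(devalued/non-devalued press rate) over 3 min
probes; a zero rate makes it undefined (flagged, never imputed) and the
subject is excluded. Locomotion distance is the summed Euclidean 3-D
displacement of the head marker.

## Statistics (stats)

Paired t and Pearson r delegate to scipy behind the module surface and are
cross-checked against independent sum-formula oracles to 1e-10. The Fisher
comparison is z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)); the default
is two-tailed, with one-tailed available — the study-replication contrasts
use one-tailed p-values, which is what the printed values imply. The
log₂-ratio SEM is |log₂(m₁/m₂)|·√((CV₁² + CV₂²)/N); the expression's
typography is ambiguous and this reading is isolated in one function.

Hartigan's dip statistic is computed exactly, from the definition: the dip
is the smallest sup-norm distance between the empirical CDF and any
unimodal CDF. For a mode between order statistics the fit must be convex
over the left flank and concave over the right; half of each flank's
maximal deviation from its restricted convex minorant / concave majorant
brackets the answer from below, a parallel-shift construction brackets it
from above, and the exact value is located by bisection on the tube
half-width with an O(n) feasibility sweep that propagates the convex
frontier of reachable (value, slope) states through the per-point tube
constraints. The implementation agrees with a linear-programming
transcription of the definition to 1e-10 and is invariant under monotone
affine transforms. p-values are Monte-Carlo against the uniform null
(asymptotically least favourable), default 10⁴ replicates with an add-one
correction; each null sample needs only one feasibility sweep at the
observed dip, not a full dip computation.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses rely on —
stereotyped transient kernels at known event times with Gaussian noise at
12–15 Hz frames, sub-millisecond stimulus artifacts, exponential or bursty
ISI mixtures with a controllable γ fraction (within-burst ISIs uniform on
(10, 33.3] ms, inter-burst ISIs 250 ms plus an exponential solved to keep
the overall mean rate), two-compartment RC test pulses, Poisson pressing
under RI/RR contingencies, and log-normal multiplicative noise on probe
rates. They do not emulate indicator nonlinearity or bleaching, correlated
or non-Gaussian imaging noise, bursting beyond the two-component ISI
mixture, electrode drift, satiety dynamics or pharmacokinetics. Passing
tests therefore demonstrate correctness of the computations under the
stated statistical assumptions, not robustness to every artifact of real
recordings.

The calcium kernel is a difference of exponentials k(t) ∝ e^(−t/τ_decay) −
e^(−t/τ_rise), scaled so the sampled maximum equals the requested peak
(defaults 50 ms rise, 500 ms decay, 0.08 ΔF/F₀ — a realistic
single-action-potential transient for bulk-loaded SPNs at these frame
rates); the empirical templates it stands in for are not tabulated
anywhere, so the parameters are free and documented rather than fitted.

## Known limitations

- The deposited source-data file is needed to reproduce the study's exact
  population counts and correlations; without it the corresponding
  acceptance test fails by design. The loader and the deterministic
  classification path are exercised against a synthetic stand-in.
- The dip test's Monte-Carlo null is exchangeable but not fast: at n = 500
  a 10⁴-replicate p-value takes minutes (each replicate is one O(n)
  feasibility sweep); use fewer replicates for screening.
- Pairing for pathway timing is a seeded random non-reusing pairing; how
  the original pairs were formed is unspecified, and the mean difference is
  pairing-invariant in any case.
- The drift correction is plain rigid translation by cross-correlation; it
  does not reproduce any particular published registration algorithm.
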