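# Methods

## Plant model and assumptions

The simulator uses the minimal (Bergman-type) model of glucose–insulin
kinetics: plasma glucose G [mg/dl] is cleared in proportion to the
remote insulin action X [1/min] (bilinear term G·X) and perturbed by the
meal appearance rate D(t) [mg/dl/min]; X is driven by plasma insulin I
[µU/ml] above basal; I is cleared at rate n and driven by the infusion
u [µU/ml/min]. The nominal type-1 parameter set has p1 = 0 (no
insulin-independent glucose effectiveness), so an untreated patient's
glucose is non-decreasing once insulin action has decayed — which is why
the untreated nominal day ends around 255 mg/dl.

Units for D are taken as mg/dl/min, the only choice dimensionally
consistent with the glucose equation. The model has a unique basal fixed
point (Gb, 0, Ib) at u = D = 0, used as an exactness check.

### Meals

Each meal contributes A·exp(−B·(t − t_onset)) from its onset. With
B = 0.01/min a tail retains ≈1% of A after 450 min, so successive tails
overlap slightly; the schedule **sums** all active tails by default
(glucose appearance from separate meals is physically additive). A
`reset` mode that keeps only the latest meal is provided for sensitivity
checks; at reporting precision the two are nearly indistinguishable.
Time is measured in minutes from 6 A.M.; breakfast/lunch/dinner onsets
are 120/480/840 min; horizon 1440 min.

## Controller

Backstepping exploits the strict-feedback structure G ← X ← I ← u.
Desired values x2d (for X) and x3d (for I) are chosen so each tracking
error obeys ė_i = −k_i·e_i; the final law sets u. The adaptive variant
adds a disturbance estimate D̂ inside x2d and updates it with
dD̂/dt = δ·e₁ — the update that cancels the estimation-error cross term
in the composite Lyapunov function V₃ = ½Σe_i² + D̃²/(2δ), leaving
V̇₃ = −Σk_i e_i² for constant D. No projection or leakage is applied, so
D̂ may transiently overshoot D (it visibly does under actuator faults);
D̂(0) = 0 is the uninformative prior.

### Desired-state derivatives (the open design choice)

x3d and u need the time derivatives ẋ2d and ẋ3d, which depend on the
unknown disturbance; there is no canonical way to obtain them. Two
schemes are implemented:

* `hold` (default): the controller is a sampled-data system
  (Δt = 0.1 min); derivatives are backward differences of the sampled
  desired values, zero at start-up. This is standard implementable
  digital practice and avoids propagating the unknown D through the
  chain rule. Its cost: at a meal onset the backward difference of x2d
  jumps, and the 1/p3 ≈ 6.7·10⁴ factor in x3d amplifies that jump, so
  the *commanded* input shows a two-sample spike of tens of µU/ml/min at
  each onset (the delivered insulin, being an integral of u, barely
  notices). Halving Δt and the solver tolerances moves the post-lunch
  glucose peak by < 0.01%, so reported peaks are discretisation-
  converged.
* `analytic`: full chain-rule expressions for ẋ2d and ẍ2d (hence ẋ3d)
  with D replaced by the controller's best substitute — D̂ in adaptive
  mode, 0 in pure backstepping — and dD̂/dt = δe₁ likewise substituted.
  This yields a smooth input (lunch peak ≈ 29–45 µU/ml/min depending on
  mode) at the price of a controller that is deliberately blind to the
  true disturbance inside its feedforward terms.

Both schemes give the same closed-loop glucose behaviour to within a
couple of mg/dl, because the rejection is dominated by the k₁e₁ term:
with a tight cascade the glucose error under a bounded disturbance
mismatch obeys |e₁| ≲ |D − D̂|/k₁ ≈ 1.4 mg/dl at the lunch peak. This
bound is a structural property of the law with the nominal gains, and it
is why the meal excursions this simulator produces are small.

The adaptive update runs on the controller grid (forward Euler with the
same e₁ sample used for u, updated after u is computed), keeping the
controller strictly causal and sampled. u is unclamped by default (the
laws can command negative u during sharp transients); a non-negativity
clamp is available (`--nonnegative-insulin`).

## Faults

Faults transform the input after the control law and before the plant,
in the order actuator fault → dropout; the controller sees only its
commanded u. The fault clock starts at t = 0 (6 A.M.), so with rate
0.1/min the pump has essentially reached its severe asymptote
(ρ → 0.01, φ → 0.1) before breakfast. Dropout boundaries are strict
inequalities; "10 A.M.–12 P.M." is 240–360 min with noon as 12 P.M.

A physical remark that the dropout experiments make concrete: while
I ≥ Ib, X stays non-negative, so during a dropout Ġ ≤ D(t). The rise
budget over (240, 360) min is ∫D dt < 9 mg/dl with the nominal meal
schedule (only the breakfast tail is active), so glucose starting near
100 mg/dl cannot leave the safe zone during the window regardless of the
controller — both loops drift to ≈104 mg/dl and re-track within the
5 mg/dl band without ever leaving it (recovery time 0 by the metric
below).

## Numerics

Within each hold interval the plant ODE is integrated with an adaptive
Runge–Kutta (dopri5) at rtol 1e-8 / atol 1e-10; meal onsets coincide
with controller sample times, so the integrator never crosses a
discontinuity of D. Results are recorded on a 1-min report grid (1441
rows per day). Everything is deterministic — identical scenarios give
bit-identical outputs. If glucose falls below 1 mg/dl the run aborts
with a degeneracy error (the laws divide by G); non-finite states abort
likewise.

## Metrics

Zones on glucose: < 70 dangerous (hypo), 70–130 safe, 130–180 warning,
> 180 dangerous (hyper); boundaries 70 and 130 belong to the safe zone
and 180 to warning, fixed so tests are exact. `time_to_zone` is the
first report-grid time at/after a start time with the requested label.
`recovery_time` after an event: locate the post-event glucose peak
(within a 240-min search window), then the first time |G − G_d| < 5
mg/dl holds for ≥ 10 consecutive minutes; the 5 mg/dl band and 10-min
persistence are package conventions (configurable), since "back to its
normal trend" admits no unique quantitative reading. If the band is
never left after the event the recovery time is 0.

## Scenarios and what they do (and do not) emulate

Preset scenarios define the study conditions: nominal day (gains
0.43/0.46/0.62, δ = 0.001, ICs G = 150, X = 0, I = 100, reference start
matched to G(0)), actuator-fault day, dropout day (gains 0.45/0.45/1.5,
δ = 0.007), untreated day, and an initial-condition sweep
G0 ∈ {150, 200, 250, 320}. These are idealized: no sensor noise or
delay, no discrete boluses, no intra-day parameter variability, no
carbohydrate-absorption physiology beyond the decaying exponential, and
perfect state knowledge (X and I available to the controller). Passing
tests therefore certify the control algorithm and its implementation on
the stated model — not clinical performance.

## Known limitations

* The minimal model's bilinear G·X clearance and single-compartment
  insulin kinetics are coarse; absolute mg/dl numbers should be read as
  model quantities.
* With the nominal gains the cascade rejects meal disturbances to a few
  mg/dl, so the backstepping and adaptive loops differ only modestly in
  glucose excursion on this plant; the adaptive advantage shows mainly
  in the input behaviour and in the estimator's reconstruction of D.
* With δ = 0.001 the estimator's effective time constant in a tight loop
  is k₁/δ ≈ 430 min, so D̂ lags the decaying meal tails by hours
  (day-average |D̂ − D| ≈ 0.09 mg/dl/min on the nominal run).
* Along the true (time-varying-D) trajectory V₃ is not monotone between
  meal onsets: V̇₃ contains (1/δ)·D̃·Ḋ, which is positive while D decays
  and D̂ overshoots; the V̇₃ ≤ 0 guarantee holds for constant
  disturbances.
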