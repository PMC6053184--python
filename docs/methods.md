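# Methods

## Model

The community is a system of 18 coupled ODEs: six genotype classes of the
*Daphnia longispina* complex (parental species 1 and 2, F1-hybrids,
backcrosses to each parent, F2-hybrids), each with asexual females `A_j`,
sexual individuals `S_j` and dormant eggs (ephippia) `E_j`, in individuals
(or ephippia) per litre. Asexual growth is logistic with class-specific
intrinsic rate `r_j` and a single carrying capacity `K` shared by all
classes and by both active compartments. Seasonality enters through

σ(t) = (1 − ε·cos(2πt/365)) / (1 + ε),

which multiplies both the growth rate and the carrying capacity: the year
peaks at mid-year (σ = 1) and bottoms at the turn of the year
(σ = (1−ε)/(1+ε) ≈ 0.176 at the default ε = 0.7). Twice a year, during
two-week windows in May and September, asexuals switch to sexual
reproduction at rate `s_max`; sexuals die at rate `m` and never revert.
Sexual encounters among the parental species and F1-hybrids (classes 1–3
only; backcross and F2 sexuals are assumed not to reproduce) produce
ephippia according to an encounter kernel with assortative fraction `c`:
a fraction `c` of sexuals mates strictly within its own class and the rest
mate at random, giving

- φ_j = S_j (S_j + c(T − S_j)) / (2T) for the parental classes (T = S1+S2+S3),
- φ_3 = (1−c) S1 S2 / T (new F1), φ_4, φ_5 analogous parent×F1 backcrosses,
- φ_6 = S3 (S3 + c(S1+S2)) / (2T) (F2, including all within-class F1 matings),

which conserves Σφ_j = T/2 (each encounter pairs one female and one male;
sex ratio 1:1 is implicit). Ephippia accrue at `(1 − e_j)·f·k·φ_j` — `e_j`
is the class-specific fraction of empty ephippia, `f` the daily ephippium
production per encounter pair, `k` = 1 ephippium per encounter — and leave
the egg bank only by hatching: during a two-day window in spring each
class's bank hatches at rate `h_j`, every ephippium releasing **two**
asexual hatchlings. There is no ephippium decay, so the egg bank carries
across years.

The F1 **winter advantage** — better survival of hybrid parthenogenetic
lineages through winter — replaces ε with a smaller `eps_winter_F1`
(default 0.1) for class 3 only, during a 120-day winter window, in the
growth-rate factor only. The shared density bracket `1 − Σ(A_i+S_i)/(σK)`
always uses the baseline amplitude: the carrying capacity is a property of
the environment, common to all classes; a configuration flag
(`shared_sigma_in_density=False`) switches to per-class σ there for
sensitivity analysis.

A temperature offset of x °C scales the logistic growth term of every
class by the Q10-derived factor q = 2^(x/10) (Q10 = 2: a 10 °C warming
doubles growth). It does not touch switching, mortality, hatching or
ephippium production.

## Parameters

| symbol | default | unit | meaning |
|---|---|---|---|
| m | 0.15 | day⁻¹ | mortality of sexual individuals |
| K | 150 | L⁻¹ | shared carrying capacity |
| k | 1 | — | ephippia per sexual encounter |
| f | 0.14 | day⁻¹ | ephippium production rate per encounter pair |
| c | 0.75 | — | within-class (assortative) mating fraction |
| e_j | 0.7, 0.7, 0.8, 0.75, 0.75, 0.85 | — | empty-ephippium fractions |
| h_j | 0.1, 0.1, 0.05, 0.05, 0.05, 0.05 | day⁻¹ | hatching rates (hybrid ephippia hatch at half the parental rate) |
| s_max | 0.5 | day⁻¹ | switching rate during sexual windows |
| ε | 0.7 | — | seasonal amplitude |
| eps_winter_F1 | 0.1 when the advantage is on | — | F1 winter amplitude |
| r_j | scenario-dependent, 0.30–0.35 | day⁻¹ | intrinsic growth rates; backcrosses always average their parental and F1 rates; F2 fixed at 0.30 (hybrid breakdown) |

Growth-rate scenarios: **A** r1 = r2 = 0.35; **B** r1 = 0.35, r2 = 0.30;
**C** (r1, r2) swap between (0.30, 0.35) and (0.35, 0.30), each assignment
held two years, species 1 starting low; **D** the same swap within each
year at day 166, species 1 low in spring; **E** species 1 alone at
r1 = 0.30 for 100 years, then species 2 (r2 = 0.35) introduced at the
colonization density of 0.001 L⁻¹, 200 years total with reporting over the
second century. All runs start from 0.001 L⁻¹ of each initially present
parental species and empty sexual/egg-bank compartments.

## Calendar conventions

Continuous time in days, years of exactly 365 days, no leap years. A
window printed as "days a–b" is the half-open day-of-year interval
[a−1, b), making each printed day a unit interval: sexual windows
[150, 165) and [272, 287), hatching [118, 120), winter
[304, 365) ∪ [0, 59) (1 November – end of February, 120 days). The exact
edge convention is far below model sensitivity; all windows are
configurable. The source material is internally inconsistent about both
the winter length (120 vs 160 days, October vs November start) and the
amplitude of the strongest winter advantage (0.1 vs 0.475); we fix the
120-day November-to-February window, and ε = 0.1, which reproduces the
scenario-C/D early-dominance behaviour best in our runs (see Limitations).

## Numerics

The forcing terms are piecewise constant, so the system is integrated
segment-by-segment between *breakpoints* — every window edge, growth-rate
switch, introduction time and year boundary — with LSODA
(stiffness-switching, adaptive) at rtol 1e-8 / atol 1e-12, restarted at
every breakpoint so no discontinuity is crossed by a step. Within a
segment the frozen switches are evaluated at the segment midpoint and only
the smooth sinusoid varies. Introductions are impulses applied between
segments. Output is sampled daily plus at breakpoints. Sampled values in
(−1e4·atol, 0) — transient solver undershoot as sexual densities decay to
zero between mating windows, in practice ≲1e-9 L⁻¹ — are clamped to zero
on output; anything more negative raises an error. The integrator state
itself is never modified, and runs are bit-for-bit reproducible.

Validation: the adaptive piecewise solution agrees with an independently
written fixed-step RK4 reference (step 0.001 day, numba) to better than
1e-5 relative over two years with the winter advantage active; with
seasonality and switching off a single class matches the closed-form
logistic to 1e-6 relative; the two identically parameterized parental
species in scenario A remain exactly interchangeable; halving solver
tolerances moves 100-year class totals by far less than 0.1%.

## Summary statistics

Annual statistics aggregate active individuals (A + S) per class over
calendar years: time-weighted (trapezoidal) annual means and maxima, and
per-year class proportions computed as ratios of annual means (so
proportions sum to one). Headline long-run proportions are means of the
annual proportions over the final ten simulation years; time-anchored
statements use the stated year's annual mean. A class is *established* in
a year when its annual-mean active density reaches the detection threshold
δ = 0.01 L⁻¹ (a continuous model never reaches zero); *dominance* is an
annual proportion above 0.5; *persistence* is the length of the first
consecutive run of established years. The largest whole-year reduction of
the F1 growth rate (in percent of the parental 0.35) that preserves
establishment is found by bisection on r3 to 1e-4, after verifying the
predicate differs at the bracket ends.

## Design notes and limitations

- **Establishment thresholds are not innocuous.** Where both parental
  species coexist (scenario C), ongoing hybridization replenishes F1 at
  ~0.5 L⁻¹ even when the F1 growth rate is far too low for self-sustained
  dominance, so a detection threshold of 0.01 L⁻¹ never registers loss of
  establishment; the bisection utilities therefore allow raising the
  threshold, and the boundary script escalates it (0.01 → 0.1 → 1 L⁻¹)
  until a transition is bracketed. Likewise, after a failed invasion
  (scenario E without the winter advantage) the F1 population decays
  exponentially over decades, so its "persistence" duration depends
  strongly on δ (≈98/80/55 years at δ = 0.001/0.01/0.1 L⁻¹) even though
  its ecologically visible presence (≥ ~1 L⁻¹) spans only about two
  decades around the post-invasion peak of ≈3.5 L⁻¹.
- **The winter advantage is strong.** With ε_winter = 0.1 the F1 winter
  growth multiplier at the seasonal trough is ≈0.82 against the parental
  0.176. In our runs this drives F1 to ≈90% of the community in every
  scenario once established, and establishment survives growth-rate
  reductions of ≈25–40% (scenarios B/C). Published analyses of this model
  family report considerably weaker winter-advantage effects (coexistence
  rather than near-fixation, and single-digit tolerable growth-rate
  reductions); we could not reproduce those weaker outcomes from the
  printed equations under any reading of the stated amplitudes, and report
  what the equations yield.
- **Temperature insensitivity.** Because q scales every class's growth
  term equally, varying x within ±5 °C moves long-run F1 dominance by
  under one percentage point here; temperature-driven establishment
  failures reported for this model family evidently require an asymmetric
  mechanism (e.g. class-specific overwinter survival responding to
  temperature) that the printed equations do not encode.
- The model is deterministic and spatially implicit: no demographic
  stochasticity (populations can linger at arbitrarily small densities),
  no explicit sexes (the 1:1 ratio is folded into the kernel), no egg-bank
  mortality, and growth-rate scenarios stand in for mechanisms
  (parasitism, eutrophication) rather than modelling them.
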