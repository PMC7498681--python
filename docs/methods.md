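# Methods

## The coinfection model

`phagecoi` models lysogenization driven by phage coinfection from encounter
kinetics. In a well-mixed volume, a single bacterium is infected by phages
of concentration *P* at rate *P·α*, where *α* (ml/h) is the adsorption rate
constant from the Smoluchowski encounter picture. The lysis/lysogeny
decision of the first infecting phage remains open for the lysogenic
commitment time *τ* (h), during which later arrivals can still vote for
lysogeny. The mean number of (co)infections per cell within that window is

    COI = P_i · α · τ

a real-valued Poisson mean, never an integer. Treating infections as
independent arrivals, the count of infections within *τ* is Poisson(COI),
and a lysogen forms when at least two phages infect the same cell:

    p_lys = P(k ≥ 2) = 1 − e^(−COI) − COI·e^(−COI)

Key assumptions: infections are independent; community abundances change
little (≲20%) within *τ*, so *P_i* is constant over the decision window; two
infections suffice for lysogeny (the cro/cI-like repressor voting mechanism
shared by most temperate phages). Phages that do not respond to coinfection
(P1-, P4-like) are outside the model.

The model is compared with MOI experiments through the phage-to-bacterium
ratio form COI = α·τ·B_i·(P_i/B_i), since the operational MOI (P₀/B₀) is a
ratio, not an infection count.

### Hill-Langmuir calibration

Percent lysogeny vs MOI data are fitted by nonlinear least squares to
Hill-Langmuir cooperation models of order n ∈ {1, 2, 3}. Two
parameterizations circulate: the standard saturating form
*f(x) = a·xⁿ/(b + xⁿ)* and the variant *a·x/(b + xⁿ)*, which does not
saturate and decreases at large *x* for n ≥ 2. Only the standard form
produces the sigmoid reaching ~100% lysogeny that the order-2 fits
describe, so it is the default; the variant is available behind
`printed_form=True` and a test documents their qualitative difference.
Order selection minimizes residual sum of squares over the three orders;
ties (within a 1e-9 relative tolerance, which absorbs optimizer noise on
degenerate data) go to the lower order by parsimony.

## Community simulation

One simulated community is a triplet (B, α, t) drawn by Latin hypercube
sampling: each parameter's log₁₀ range is split into *n* equal strata, each
stratum contributes exactly one uniform draw, and strata are permuted
independently across dimensions (`scipy.stats.qmc.LatinHypercube` on the
unit cube, scaled in log space by this package). Default *n* = 100,000
communities per ecosystem.

The total phage concentration is tied to bacterial density by the empirical
power law P(B) = a·(B/B_u)^b with B_u = 1 cell/ml:

| ecosystem | a (phages/ml) | b | B range (cells/ml) | α range (ml/h) | time range (h) |
|---|---|---|---|---|---|
| marine | 10^2.50 | 0.712 | 3.78e4 – 6.75e6 | 7.2e-10 – 3.7e-7 | 11 – 808 (commitment) |
| gut | 10^5.35 | 0.388 | 3.45e5 – 7.60e9 | 5.9e-8 – 1.2e-6 | 2.74 – 7.27 (duplication) |

Noise is applied literally as log₁₀P = N(1, 0.05)·log₁₀P(B) — a
multiplicative perturbation of the log-abundance itself, so absolute noise
grows with magnitude — and the result is clamped into the empirical phage
range (marine 1.45e5–3.80e7, gut 5.09e6–1.05e10 phages/ml). Clamping, not
resampling, implements the range constraint.

Marine time draws are commitment times used directly (duplication recorded
as τ/0.2); gut draws are *duplication* times with τ = 0.2 × duplication, the
commitment fraction measured in lambda single-cell experiments. This
asymmetry is deliberate: the gut duplication range 2.74–7.27 h maps to
commitment times 0.55–1.45 h, which is the range the conditioned gut
summaries actually span, whereas marine commitment times 11–808 h appear in
the marine summaries unscaled.

Community structure enters through power-law rank-abundance curves
f(r) = f₁·r^(−s) over the top 100 ranks, with the identity infection
network: the phage of rank *i* infects the bacterium of rank *i*, with
P_i = P·f_P(i) and B_i = B·f_B(i). One α and one τ are shared by all rank
pairs of a community. Rank-1 frequencies are empirical: phage 0.8% (marine)
and 1% (gut), bacteria 19% (marine) and 15% (gut). The decay exponents of
the published consensus curves are not printed; defaults here are s = 0.8
for phage curves and s = 1.0 (Zipf) for bacterial curves — 1.0 being the
smallest round exponent for which both bacterial curves remain valid
fractions of the whole community (0.19·Σr^(−1) ≈ 0.986 ≤ 1; at s = 0.8 the
sum would exceed 1.5). Both exponents are per-curve configuration
parameters.

Percent lysogeny divides the pooled lysogen concentration by the **total**
bacterial concentration B, not by the top-100 pool (which is < B), because
the quantity of interest is the lysogenized share of the whole bacterial
community. Rank contributions divide each rank's lysogens by the pooled
total, so they sum to 1.

Daily lysogen production in the human colon is reconstructed as standing
stock × turnover: (percent/100) · B · V · (24 h / duplication time), with
V = 400 ml. Applied to the medians of the high-lysogeny (≥25%) gut subset.

### Randomness and reproducibility

One master seed governs a run. Each random purpose (LHS, abundance noise)
draws from an independent stream keyed by `SeedSequence([master_seed,
stream_id])`, and community *i* always consumes the *i*-th element of each
vectorized stream, so results are independent of evaluation order and the
scalar per-community path reproduces the vectorized table bit for bit (this
equivalence is tested). The full 2 × 100,000-community run takes a few
seconds on one CPU.

### Thresholds, quantiles, degenerate inputs

- "Lysogeny ≥ 25%" and "≥ 10%" conditioning is inclusive; the "above 1%"
  qualifying floor is strict.
- Summary quantiles use linear interpolation between order statistics (the
  numpy default).
- Lysogeny bins are left-closed, right-open, with the last bin closed so
  100% is counted; fractions sum to 1 exactly.
- `lysogeny_probability` evaluates via `expm1` and returns exactly 1 where
  float64 saturates (COI ≳ 700 underflows the exponential; the limit is 1).
- Welch's unequal-variance t test on log₁₀ values is used for group
  comparisons because traits span orders of magnitude; two constant equal
  groups give (t = 0, p = 1) by convention.
- Zero total lysogens yields zero rank contributions rather than NaN.
- Trend lines ("GAM-style" curves in the source analyses) are approximated
  by a binned median in log₁₀-x with equal-width bins; smoother shape is
  not a calibrated quantity here.

## Synthetic data

The generators in `phagecoi.synthetic` emulate the statistical structure of
the meta-analysis inputs so the full pipeline is testable without external
data: log-uniform trait values within the printed per-ecosystem ranges,
abundance pairs scattered around a power law with Gaussian log₁₀ noise,
per-sample rank tables with multiplicative log-normal noise re-sorted
non-increasing, and MOI experiments with binomial counting noise around a
Hill curve. Defaults mirror the meta-analysis scale (e.g. 71 adsorption
records) for cosmetic fidelity only. Real literature data are not
log-uniform and real rank-abundance curves are not exact power laws;
passing recovery tests therefore demonstrates correctness of the estimation
machinery, not distributional claims about nature.

## Known limitations

- No temporal dynamics: abundances are frozen within τ; no phage decay,
  burst sizes, or superinfection-immunity dynamics.
- Identity infection network only; cross-infection would change how much
  the top ranks dominate the lysogen pool.
- Pure power-law rank-abundance curves are an idealization. The simulated
  gut community statistics are sensitive to the unprinted decay exponents:
  with the defaults, the fraction of gut communities above 25% lysogeny is
  ~14% and the median lysogeny in that subset ~38%, lower than the
  published 25% / 47.8% which rest on the empirical consensus curves.
  No power-law exponent pair reproduces all published gut statistics
  simultaneously (flatter curves raise total lysogeny but depress rank-1
  COI and rank-1 contribution), indicating the empirical curves deviate
  from a pure power law over the top 100 ranks. Marine statistics, and the
  gut statistics driven by the printed rank-1 frequencies and time ranges,
  are insensitive to this choice and reproduce closely.
- The daily-production figure depends on a reconstructed formula; from
  printed medians it gives ~1.6e12/day, and from the simulated subset here
  ~1.0e12/day, within a factor of 2 of the published ~1.8e12.
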