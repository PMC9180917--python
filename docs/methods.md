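# Methods

## The model

The analysis treats a country's importance in the live wild-bird trade as
an ordinal outcome.  For each market role (supplier = net exporter,
demander = net importer) and period (preban 1995–2005, postban 2006–2017,
around the 2005 EU ban on wild-bird imports), the *real trade score*
T ∈ {1..5} — the country's traded volume binned into five equal-width
log₁₀ intervals — is regressed on the *expected score* E ∈ {0..8} — the sum
of two quintile weakness bins for rule of law and the role's trade-barrier
proxy — with a cumulative-link (proportional-odds) model:

    P(T ≤ k | E) = F(θₖ − βE),   F = logistic,   θ₁ < θ₂ < θ₃ < θ₄.

One slope β is shared across thresholds (proportional odds).  β > 0 means
geopolitically weaker countries trade more (the supplier pattern); β < 0
the reverse (the demander pattern).  The model is deliberately plain — one
predictor, no grouping factors — because each (role, period) stratum is a
single cross-section of countries; it is fitted independently per stratum.

### Fitting and inference

The log-likelihood is maximised by BFGS on the unconstrained
reparameterisation (β, θ₁, log(θ₂−θ₁), log(θ₃−θ₂), log(θ₄−θ₃)), which
enforces threshold ordering, with an analytic gradient and a deterministic
start (β = 0, thresholds at the marginal cumulative logits).  The nominal
convergence criterion is a gradient norm below 1e-8; because the achievable
gradient at a double-precision optimum scales with the magnitude of the
objective, a fit is also accepted when the gradient norm is below
1e-8 × |negative log-likelihood|.  Standard errors come from the inverse of
the numerically differentiated observed information at the optimum in the
natural (β, θ) coordinates; p-values are two-sided Wald.  Apparent complete
separation (|β̂| > 15) triggers one refit with a ridge penalty 1e-6·β² and
a warning — never a silent fallback.

The null model (thresholds only) has the closed-form multinomial maximum
ℓ₀ = Σₖ nₖ log(nₖ/n).  Pseudo-R²:

    Cox–Snell = 1 − exp(2(ℓ₀−ℓ₁)/n),  Nagelkerke = CS / (1 − exp(2ℓ₀/n)),
    McFadden  = 1 − ℓ₁/ℓ₀.

The implementation is cross-checked in the test suite along two independent
routes: a naive per-observation probability-product likelihood plus a
derivative-free lattice search (cyclic exhaustive coordinate scans at step
0.01 with full ±step neighbourhood moves, valid because the cumulative-logit
likelihood is concave), and statsmodels' `OrderedModel`.

## Score construction

- **Roles** follow strict inequalities on per-country totals (exported >
  imported ⇒ supplier, < ⇒ demander); exact ties are excluded and counted
  in the run manifest rather than forced into a role.
- **Quantity reconciliation** takes the maximum of the importer- and
  exporter-reported quantities when both are present — a standard
  convention that mitigates one-sided under-reporting.  Records whose
  `Origin` differs from the `Exporter` are re-exports: the importer keeps
  its demand credit, the re-exporter gets no supply credit.
- **Weakness bins** are within-role, within-period quintiles (average-rank
  ties, bin = ⌊(rank − ½)·5/n⌋), oriented so bin 0 is the strongest fifth.
  Summing the two 0–4 bins yields the 0–8 expected score with the intended
  anchors: (0,0) → 0 both strong, (4,4) → 8 both weak, mixed profiles in
  the middle band.  Quintiles are computed within the role-group because
  the scores feed role-specific regressions and must rank countries within
  their own market role; fewer than five distinct values raises a
  degenerate-binning error instead of producing spurious bins.
- **Volume bins** are five equal-width intervals of log₁₀ volume spanning
  the reference volumes (lower-open, upper-closed against the next edge;
  the top bin is right-closed so the maximum maps to 5).  Base 10 is a
  convention only — bin membership is base-invariant.  The calibration span
  can be fixed externally; pipeline runs on synthetic data default to the
  generator's own span so that the calibration is exact rather than
  re-estimated from sample extremes.

## Fuzzy clustering

Countries are min–max normalised per axis to the unit square
(rule of law × barrier strength, 1 = strongest) and clustered with fuzzy
c-means: memberships uᵢⱼ = 1/Σₖ(dᵢⱼ/dᵢₖ)^(2/(m−1)), centers = u^m-weighted
means, iterated until the largest membership change falls below 1e-6 (max
300 iterations).  Defaults: fuzzifier m = 2 (the conventional choice),
seeded Dirichlet-row initialisation for reproducibility without a k-means++
dependency.  A point coinciding with a center receives crisp membership
there.  The cluster count is chosen among candidates {2..5} by the fuzzy
partition coefficient (1/n)Σu²; ties prefer fewer clusters.  Cluster
centers are labelled A–D by quadrant (split at 0.5 per axis, ties counted
as strong): A = both strong, D = both weak; of the mixed quadrants, strong
barriers with weak law is labelled B and weak barriers with strong law C —
a documented convention, since the storyline scenarios define B and C by
role rather than by a single point's position.

## Scenario projection

Scenario specs fix closed integer score ranges per role: A = (0–2, 0–2),
B = (0–2, 6–8), C = (6–8, 0–2), D = (6–8, 6–8) (supplier range first).
Each Monte-Carlo replicate draws E uniformly over the integers of the
role's range (the maximum-entropy reading of "a random score within the
range"), draws T from the fitted P(T | E) — propagating model uncertainty;
a modal-category mode is available as a switch — and back-transforms T to
10^(midpoint of its log₁₀ bin).  Projections default to the postban fits
and calibrations, the most recent market regime.  Defaults: 1000
replicates, seeded; summaries are means and 2.5/97.5 percentiles per
country and globally per role.  The Monte-Carlo error of the mean shrinks
at the usual 1/√n_reps rate.

## The synthetic-data generator

The generator emulates the *structure* of the study data, not any real
country:

- Latent rule-of-law and barrier positions are uniform on [0, 1] per axis,
  giving uninformative coverage of the whole 5×5 bin grid.  True weakness
  bins apply the same within-role quintile rule as the scoring stage, so
  noiseless emission is identifiable by construction.
- True categories are drawn from the cumulative-link model with the
  configured slopes and thresholds (role-specific slope sign).  Defaults
  β_supplier = +0.500 and β_demander = −0.578 mirror the supplier-positive
  / demander-negative pattern the pipeline is designed to detect, at
  realistic effect sizes; thresholds default to the logits of cumulative
  marks (.2, .4, .6, .8), which centre the marginal category distribution
  at the grid's mean score.
- True volumes are whole-bird counts placed inside the category's log bin
  (uniform draw, or deterministically at the midpoint with
  `volume_jitter="midpoint"`), over a span of volume_log_mean ± 2.5·sd
  (default 10^0.5 to 10^5.5 birds).  Integer volumes make per-country sums
  of split shipments exact in floating point, so record emission conserves
  volumes to the last bird; counts are clamped to stay strictly inside
  their bin.  With the mirrored role slopes the raw volumes are strongly
  right-skewed while pooled log volumes are near-symmetric, reproducing the
  heavy skew that motivates log-binning real trade data.
- Trade records carry a single placeholder parrot taxon, `Term = "live"`,
  `Source = "W"`, blank unit, and years uniform in the period window.
  Suppliers export to — and demanders import from — seeded rest-of-world
  partner codes (`X..`) outside the study set, with volumes split across
  1–4 partners by a largest-remainder Dirichlet allocation.  Keeping
  partners out-of-world is what lets every study country's own-side total
  equal its true volume exactly; flows between study countries would
  double-enter the totals on the partner's side.  The partner codes carry
  no covariates and are excluded (and counted) at the scoring stage.
- Covariates are the latent positions plus seeded Gaussian noise clipped to
  [0, 1] (default sd 0.05); after the ban, demander import tariffs shift
  upward by `ban_shift` (default 0.15) — a uniform translation, applied
  after clipping so ranks and the shift itself are exact.
- Default world size is 80 suppliers and 80 demanders, roughly the scale of
  CITES parties active in the bird trade on each side of the market.

What the generator does **not** emulate: species composition, temporal
autocorrelation within a period, illegal or unreported trade, reporting
discrepancies between partners, or network topology of who trades with
whom.  Passing tests on synthetic data therefore demonstrate that the
statistical machinery is correct and self-consistent — not that the
substantive conclusions hold for the real CITES extract, which requires
the real covariate table.

## Numerical and design choices

- Missing quantity cells are *missing*, never zero; rows with non-numeric
  quantities, invalid years, or no quantity at all are dropped and counted.
- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; derived streams use small fixed offsets per stage and
  period so stages are independently reproducible.
- Problem sizes in the test suite are chosen so each statistical check has
  adequate power at its stated tolerance (e.g. closed-form category
  frequencies are checked in score cells of ≥ 8000 draws for a ±0.02 band;
  parameter recovery uses 100 replicates of 200 countries per role).
- The pipeline writes plain CSV and JSON only; identical configurations
  yield byte-identical artifacts.

## Known limitations

- The 0–8 score is one specific construction (sum of two within-role
  quintile bins); global quantiles or different axis resolutions are
  plausible alternatives and would change score values, though not the
  monotone supplier/demander pattern.
- The proportional-odds assumption is untested within the package (no
  parallel-lines test); with a single integer predictor and n ≈ 100 per
  stratum, richer link structures are rarely identifiable.
- Projection uncertainty reflects score randomisation and category
  sampling, not parameter uncertainty in (β̂, θ̂); intervals are therefore
  narrower than full posterior predictive bands.
- The cluster-count rule (partition coefficient) is a simple, monotone
  stand-in for visual judgement of "well-defined clusters"; it is known to
  favour small c on overlapping data.
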