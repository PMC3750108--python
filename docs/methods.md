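# Methods

This note records the modelling conventions, numerical choices and known
limitations of the package, in the order a user meets them: elementary-mode
enumeration, the NIPALS PLS core, the pathway-selection loop, the
bootstrap, and the synthetic-data generator whose conditions the tests and
the acceptance script run under.

## Elementary flux mode enumeration

The flux cone is `{v : N_int·v = 0, v_j ≥ 0 for irreversible j}` with
`N_int` the stoichiometric matrix restricted to internal metabolites.
Reversible reactions are split into forward/backward halves, which makes
the cone pointed; its extreme rays are computed by the double description
method, adding one steady-state equality at a time and combining adjacent
positive/negative ray pairs (combinatorial adjacency test: a pair is
adjacent iff no third ray vanishes everywhere both do).  All arithmetic is
on integers (each constraint row is cleared of denominators; rays are
gcd-reduced), so elementarity decisions are exact — floating point is only
used when the final matrix is exported.

Mapping rays back to net fluxes annihilates the forward+backward two-cycle
rays; fully reversible modes appear once per orientation and are
reoriented (first nonzero coefficient positive) and deduplicated.  By the
standard split-network equivalence the surviving rays are exactly the
elementary modes, each reported once, matching the counting convention of
the classical enumeration tools.

Canonical output: every mode is scaled so its smallest nonzero absolute
coefficient is 1, and modes are sorted lexicographically by support, then
by coefficients.  Mode identifiers are therefore stable across runs and
platforms, but they are *this package's* numbering — reports should be read
together with the reaction supports, not compared with other tools' ids.

The constraint-processing order is chosen greedily (fewest candidate pairs
next), and an intermediate-ray cap (default 200 000) turns combinatorial
blow-up into an explicit `ResourceLimitError` rather than silent
truncation.  The enumerator targets networks up to roughly 60 reactions /
10⁴ modes; genome-scale enumeration is out of scope.

`is_elementary` tests support-minimality by enumerating the sub-network
restricted to the candidate's support: a certificate mode with strictly
smaller support, if one exists, is returned embedded in full reaction
space.

## NIPALS PLS core

The classic one-component-at-a-time algorithm: `u = Y·q`,
`w = Xᵀu/‖Xᵀu‖`, `t = X·w`, `q = Yᵀt/‖Yᵀt‖`, iterated until
`‖t − t_old‖ < eps` (default 1e-8), then `p = Xᵀt/tᵀt` rescaled to unit
length with `t` and `w` absorbing `‖p‖`, inner slope `b = uᵀt/tᵀt`, and
deflation `X ← X − t·pᵀ`, `Y ← Y − b·t·qᵀ`.  For a univariate response the
Y-loading is identically 1 and the component is computed in a single pass
with no iteration.  The iterative branch starts from the Y column of
largest variance for determinism.

Conventions worth stating:

* **Y-deflation uses the Y-loading `q`**, the standard Geladi–Kowalski
  form.  (A deflation by `pᵀ` would be dimensionally inconsistent for
  ny ≠ nx; the two coincide in the univariate case the selection loop
  uses.)
* **Regression matrix.** Prediction is the direct form `Ŷ = X·RCᵀ` with
  `RC = Q·B·W*ᵀ` and the X-rotation weights `W* = W(PᵀW)⁻¹`.  Because
  `PᵀW` is unit upper triangular, `W* = W` for one component; for more,
  the rotation is what makes the direct formula reproduce the sequential
  scores exactly, and with full components the predictions coincide with
  ordinary least squares to machine precision (this is asserted in the
  tests).
* **Preprocessing.** X columns are autoscaled (mean 0, unit variance,
  ddof=1; zero-variance columns are centered and carried with scale 1
  under a warning), Y columns are mean-centered but not scaled.  Explained
  variances (`100·(1 − Σ(Y−Ŷ)²/ΣY²)`) are reported on this preprocessed
  scale.  A `raw` policy (no X preprocessing) is available.
* **Convergence and rank.** Non-convergence within `max_nipals_iter`
  (default 5000) raises by default.  Deep components of noisy data sit on
  nearly tied covariance eigenvalues where the underlying power iteration
  converges arbitrarily slowly; for *reference* full-rank fits (the
  bootstrap's comparison PLS) the `nonconvergence="truncate"` option ends
  the fit at the last convergent component instead — those trailing
  components carry no predictable signal, which is also why they stall.
  Requesting more components than the rank of the scaled X is an error
  up front; a rank collapse during deflation truncates with a warning.

## The selection loop

Candidate modes are restricted to the rows matching the measured exchange
fluxes (intracellular reactions of a mode are invisible to the data) and,
by default, scaled to unit Euclidean norm so that variance comparisons are
invariant to the arbitrary scaling of modes (`efm_normalization="raw"`
reproduces projection with modes as given).  The flux matrix is column
centered; weighting factors are the linear projections `λ_k = R·q_k` and
are *not* constrained to be non-negative — the projection of a centered
residual is a score, not a convex weight.  The fraction of negative
entries per selected mode is reported as a diagnostic instead.

Per iteration every remaining candidate is scored: inner univariate PLS of
`λ_k` on the (shared, full) scaled envirome with `Fac` components,
prediction `λ̂_k`, rank-one reconstruction, and the explained variance of
the *original* centered flux matrix if this candidate were accepted — so
the reported trajectory is cumulative and non-decreasing by construction.
The maximizer (ties break toward the lower mode id) is accepted only if
`r² > 0.75` and `p < 0.05` for the Pearson correlation of `λ_k` with
`λ̂_k` (two-sided t test, n−2 df — the conventional reading, since the
test behind the published thresholds is not spelled out) and the marginal
variance gain is at least `min_variance_gain` (default 1e-6 percentage
points, operationalizing "no further increase").  Each inner PLS restarts
from the full envirome matrix; no X-deflation is carried between modes.

Two honesty notes on the gate.  First, the p-value is computed in-sample
against a supervised fit, so it is strongly anti-conservative: under a
null envirome the 4-LV inner fit reaches r² ≈ 0.2 at np = 134 (simulated
in the tests), and false selection is in practice controlled by the much
stricter r² threshold, not by p.  Second, on *noise-free* data the gate
has no noise floor to stop at, and a few extra modes mopping up the last
predictable crumbs may legitimately follow the true ones.

Prediction composes the stored inner models:
`R̂(X_new) = r̄ + Σ_k λ̂_k(X_new)·q_kᵀ`; with nothing selected this is the
column-mean baseline.  The fitted model retains the full per-iteration
score table of every candidate (`history`) as an audit trail.

## Bootstrap

Each of `n_runs` (paper-scale default 200) runs draws a disjoint,
exhaustive 50/50 split — stratified by experiment label when the row ids
carry one, so each bioreactor run contributes equally to both halves —
fits the selection model and a full-rank reference PLS on the calibration
half and evaluates both on the validation half (validation fluxes centered
with calibration means).  Run `i` is seeded with the child sequence
`(master_seed, i)`, so adding runs never changes earlier ones and the
whole result is a pure function of inputs and seed.

Selection frequency is count/`n_runs`.  Coefficient intervals use the
bootstrap draws of each mode's inner regression vector (on the scaled
envirome): mean `B̄`, standard deviation `S` with denominator `z−1` over
the `z` runs in which the mode was selected, and
`B̄ ± S·t(1−α/2, z−Fac)`.  Since `S` (not `S/√z`) sets the width, these
are spread intervals: they characterize the variability of the coefficient
across resamples (≈95% of the draws fall inside, which the tests verify),
not a standard error of the mean.  The degrees of freedom use the per-mode
selection count by default; `dof_policy="global"` substitutes the total
run count for modes not selected in every run.  Modes selected in fewer
than two runs are excluded with a warning.

## Synthetic data generator

The generator emulates a multi-experiment bioprocess campaign and defines
the study conditions under which the recovery and generalization claims
are tested: 134 observations from 7 experiment blocks, 26 envirome
variables, 24 measured exchange fluxes, a 200-mode candidate dictionary
with 3 active modes, flux measurement noise at 5% of the centered signal
RMS and 2% noise on the envirome trajectories.

* **Envirome.** Each experiment follows its own smooth time course
  (quadratic trend plus a sinusoid) of a few latent process states
  (default 3), mapped through a single loading matrix shared across
  experiments.  Envirome variables are therefore strongly collinear — the
  signal is low-rank, as in real campaigns where dozens of measured
  concentrations reflect a few underlying process states.  This is also
  what makes the benchmark identifiable: with `Fac = 4` inner components
  the envirome-predictable part of every weighting factor is captured
  essentially completely, so the residual after removing the true modes is
  noise and the selection gate stops.
* **Weighting factors.** `Λ = softplus(5 + X_std·Cᵀ)` restricted to the
  active modes, with sparse unit-norm coefficient rows.  The offset of 5
  was chosen so the softplus rectification is essentially inactive (the
  best linear fit of `softplus(z+5)` over `z ~ N(0,1)` leaves under 1%
  residual sd): weighting factors are non-negative *and* linear in the
  envirome up to a distortion an order of magnitude below the measurement
  noise.
* **Active set.** By default the active modes are drawn with pairwise
  disjoint reaction supports (mutually orthogonal loadings), the textbook
  identifiable regime for a selection benchmark; explicit ids can be
  supplied instead.
* **Fluxes.** `R = Λ·EM_activeᵀ + ε` with i.i.d. Gaussian ε scaled to the
  requested fraction of the centered signal RMS, so the true model
  explains `100·(1 − s²/(1+s²))`% of the centered flux variance at noise
  level `s` (verified in the tests).
* **Candidate dictionary.** `random_modes` draws unit-norm sparse vectors
  (support 4–8 of 24, mixed signs, distinct supports) over the measured
  reactions.  These are synthetic stand-ins for the reduced
  (exchange-flux) form of enumerated modes and satisfy no stoichiometry;
  the selection machinery only ever sees this reduced form.

What passing these tests does *not* show about real data: real enviromes
contain variables uncoupled from the latent process state, weighting
factors need not be linear (or even monotone) in any measured variable,
real active modes overlap in their exchange signatures, and measurement
noise is neither i.i.d. nor Gaussian.  On such data the selection loop
still produces a ranked, gated decomposition, but exact recovery of a
"true" set is not the right expectation — selection frequency across
bootstrap splits is the more robust readout.

## Problem sizes in tests and the acceptance script

The test-suite and acceptance-script simulations run at the default
campaign scale above (its runtime is minutes on one core): 20 generator
seeds for the recovery/null rates, 200 random splits for the
constrained-vs-full-PLS comparison, 200 simulated draws for the
confidence-interval calibration, and 25 random ≤8-reaction networks for
the enumerator-vs-exhaustive-oracle agreement.  The published BHK network
(35 metabolites, 57 reactions, 251 modes) is supplementary material not
redistributable here; the corresponding acceptance test documents where a
transcription must be placed and fails until one is supplied.
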