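# Methods

This note documents the models, the numerical choices, and the design
of the synthetic co-module generator, including what the simulation
does and does not demonstrate about real data.

## Data model

A study is one samples × features matrix whose contiguous column
ranges are the data blocks; one range may be the response block Y.
Files use 1-based inclusive column ranges (the convention of the
original MATLAB-style block tables); internally everything is 0-based
half-open, converted only at the I/O boundary.  An optional
feature–feature network is stored as a symmetric adjacency matrix in
data column order; its diagonal is forced to zero on load because
self-links carry no information for must-link penalties.  Repeated
edge-list lines keep the maximum weight rather than accumulating.
Missing values are rejected — all four methods assume complete
matrices, so imputation is an explicit preprocessing step for the
user, not something the package does silently.

## NMF family

jNMF minimizes `Σ_i ‖X_i − W H_i‖²_F` over non-negative factors with a
shared basis W; SNMNMF adds `−Σ λ_ij Tr(H_i A_ij H_jᵀ) + γ₁‖W‖²_F +
γ₂ Σ_cols ‖h‖₁²`.  Both are solved by multiplicative updates obtained
by splitting the objective gradient into non-negative parts (negative
part in the numerator, positive part in the denominator):

    W  ← W ⊙ (Σ_i X_i H_iᵀ) ⊘ (W Σ_i H_i H_iᵀ + γ₁ W + ε)
    H₁ ← H₁ ⊙ (Wᵀ X₁ + λ₁₁ H₁A₁₁ + ½λ₁₂ H₂A₁₂ᵀ)
            ⊘ (WᵀW H₁ + γ₂·colsum(H₁) + ε)            (H₂ symmetric)

with ε = 1e−12 guarding the divisions.  Factors are initialized i.i.d.
uniform(0,1) scaled by `sqrt(Σ‖X_i‖²_F / (k·m·Σn_i))`; each of the
`n_restarts` restarts re-randomizes both W and all H_i with seed
`seed + restart`, and the lowest final objective wins (ties keep the
earliest restart).  Convergence: relative objective change below `tol`
(default 1e−6) or `max_iter` (default 100).  The objective is
empirically non-increasing to within 1e−9 relative tolerance; the
trace terms are rewards, so a λ too large for its γ₂ counterweight
makes the iteration divergent — such restarts are detected by a
non-finite objective and discarded, and an error is raised if every
restart diverges.

Blocks with negative entries are expanded as `X* = [max(X,0),
max(−X,0)]` before fitting (the expansion necessarily distorts the
data geometry somewhat; a warning is logged).  Network adjacencies are
tiled onto the positive/negative copies so that linked features stay
linked in the expanded space.

**Module extraction.** Factor f yields one module: samples with
`W[:,f] > mean + T₀·sd` of the column, block-i features with
`H_i[f,:] > mean + T_i·sd` of the row (`thrd_module = (T₀, T₁, …)`,
default all 1 — the standard z-score rule of the joint-NMF
literature).  Split copies map back to their original feature,
recorded once with a sign annotation ('+', '−', or '+/−').  Member
counts are monotonically non-increasing in every threshold.  Note a
property of the mean+sd rule worth knowing: on a factor with *no*
signal in some block, the rule still selects the upper tail of the
noise (≈15% of features at T=1), and for modules whose member set is
narrow relative to the block width the cut can fall below low-amplitude
members.  Wide modules (≥ ~10% of the block) are thresholded sharply.

## PLS family

One component of plain PLS maximizes `[cov(Xw, Yq)]²` under unit norms
(NIPALS; fixed point = leading singular pair of `XᵀY`); loadings are
`p = Xᵀt/(tᵀt)`, `q_loading = Yᵀu/(uᵀu)`.  Both deflation modes are
provided: symmetric (`X −= t pᵀ`, `Y −= u qᵀ`) and regression
(`X −= t pᵀ`, `Y −= t tᵀY/(tᵀt)`, leaving `Yᵀt = 0`).

sMBPLS alternates, per component:

    w_i ← normalize(soft(X_iᵀu, λ_i));  t_i = X_i w_i
    b_i ∝ cov(t_i, u), ‖b‖₂ = 1;        t = Σ b_i t_i
    q   ← normalize(soft(Yᵀt, μ));      u = Y q

SNPLS replaces the w/q gradients by network-smoothed versions
`z = (I + γL)^{-1} gradient` (conjugate-gradient solve) before
soft-thresholding; with all penalties zero both reduce exactly to
NIPALS.  Components are warm-started at the unconstrained PLS solution
of the current residual matrices, which is faster and more stable than
random starts.  Inner convergence: max weight change < 1e−6 or 200
iterations.  Sign convention: the largest-|entry| of q is positive.

**Sparsity parameterization.**  Penalties are accepted either as
absolute soft-thresholds or (default) as fractions of the largest
gradient magnitude of the vector being thresholded.  Fractional mode
makes one grid transferable across blocks of different scale.  Default
candidate grids: λ ∈ {0.2, 0.25, 0.3}, μ ∈ {0.1, 0.15, 0.2}.  The
asymmetry is deliberate: predictor sparsity must be strong enough that
a component locks onto a single co-module's sample pattern (weak λ
lets one component span several modules, because sample-disjoint
modules have additive covariance), while response sparsity must stay
gentle enough to retain low-amplitude correlated response features.

**Cross-validation.**  Penalties are selected once, before component
extraction, by k-fold CV (default 5 folds, deterministic fold
assignment from the seed): for each candidate combination the first
component is fitted on the training folds (re-centered), training
weights are applied to held-out rows, and the absolute held-out
covariance `|cov(t_held, u_held)|` is averaged over folds.  The
covariance criterion matches the objective itself; ties (within 1e−12)
resolve toward larger penalties.  Single-value grids skip the search.

**Multi-component fits** deflate in regression mode: each predictor
block by its own score `t_i` and the response by the super score `t`.
Deflating blocks by their own scores keeps each block's removed
structure inside that block; the response deflation makes the residual
orthogonal to every extracted super score.  Exact orthogonality of
successive super scores is not guaranteed for sparse weights, but
empirical |correlation| stays well below 0.2.

**Module extraction.** Component c yields one module: feature members
are the supports of `w_i` and `q` (dense weights at zero penalty make
every feature a member — a documented degenerate case), and sample
members have `|t| > median + T·1.4826·MAD` of |t| (default T=3).  The
robust location/scale pair treats the bulk of samples as background,
so samples with low but coherent signal — e.g. a negatively correlated
low-amplitude sample group — are still selected, while the mean+sd
rule used on the NMF side would place the cut near the module's own
high group and discard them.  This asymmetry between the two
extraction rules mirrors the methodological contrast the package is
built to expose.

## Synthetic co-module generator

`mia.simulate.generate` plants five co-modules in X (200×500) and Y
(200×300) on disjoint sample/feature coordinates over i.i.d.
`N(0, noise_sd²)` background, with per-cell signal = (sample pattern)
× (feature amplitude).  Sample patterns are positive magnitudes
U(0.9, 1.1) — except designated low-signal sample ranges, which are
negative with magnitude scaled by `signal_low/signal_high` — and
feature amplitudes are the base amplitude jittered ±20% with a random
sign per feature, so member features are positively or negatively
correlated.  Weakly-correlated pieces draw an independent sign-mixed
sample pattern.  Defaults: `signal_high = 3`, `signal_low = 1`, noise
grid {0.25, 0.5, 0.75, 1.0}.  The layout (scaled proportionally for
other sizes) is described in the module docstring; its two narrated
structures are module 1 (Y columns 1–100 correlated, first 50 high /
last 50 low amplitude, plus 30 high-amplitude weakly-correlated
columns) and module 2 (samples 111–200, of which the first 40 are
low-signal and negatively correlated with the other 50).

Gold standard G1 contains, per module, only high-amplitude members
(including module 1's weakly correlated high-signal columns); G2
contains every member correlated with the module pattern (and excludes
those weakly correlated columns).  Module 5 is high-signal *and*
correlated, so its member sets are identical in both standards.

Design notes, from choices that were genuinely open:

* **Sample patterns are one-sided** (positive magnitudes ~1, not
  zero-mean draws).  Two-sided patterns would split every module into
  two rank-one halves after the non-negativity expansion, so a
  k=5 factorization could not represent five modules; and uniform
  magnitudes are required for "high-signal member" to be a property of
  the design rather than of the random draw.
* **Centering leakage.**  One-sided patterns give module columns
  nonzero means; after column centering, a localized component's score
  carries a constant background level that genuinely covaries with
  *other* modules' columns, at roughly `n_B/m` ≈ 0.10–0.15 of the
  maximum gradient.  This is a real covariance of the construction,
  not an artifact of the solver.  `signal_low = 1` places correlated
  low-amplitude members at ~1/3 of the maximum gradient, clearly above
  that band, so a single response threshold separates true low members
  from cross-module leakage; a much smaller `signal_low` would make
  the two inseparable.
* **Module 3** keeps all its high-signal members in X but carries a
  faint correlated Y tail (14 columns at `signal_low`): with a
  strictly X-only module only four co-modules would have any X–Y
  covariance, and a 5-component PLS fit would necessarily produce one
  unanchored component.
* **Module 4** expresses its correlation character through an M2-style
  negatively-correlated low-signal sample subset rather than
  low-amplitude features, because the mean+sd feature rule cannot
  exclude low-amplitude features from narrow modules (see above), which
  would erase the G1/G2 contrast for that module.

**What the simulation shows and does not show.**  Passing tests
demonstrate the methodological contrast — NMF-family methods recover
high-absolute-signal members and discard low-amplitude correlated
ones; PLS-family methods recover all correlated members including
negatively correlated low-signal samples, and degrade faster with
noise — under Gaussian noise, disjoint rank-one modules, and complete
data.  Real multi-omics data have correlated noise, overlapping and
higher-rank modules, heavy-tailed signals, batch structure and missing
values; none of these are emulated, so the simulation validates the
machinery and the qualitative contrast, not absolute recovery rates on
real data.

## Problem sizes and runtime

The test suite and the acceptance script run the study at the default
sizes (200×500 and 200×300): 20 replicates per noise level for the
method comparison and 20 low-noise replicates for the recovery counts,
about a minute each on one CPU.  The evaluation reports median counts
over replicates, which are stable across seeds at these sizes.

## Known limitations

* SNMNMF's reward terms make the multiplicative scheme divergent when
  λ is large relative to γ₂; divergent restarts are discarded rather
  than prevented.
* CV selects one penalty combination globally, not per component; a
  per-component selection could adapt sparsity to successively weaker
  modules.
* The relevance score counts samples and all feature types in one
  namespaced identifier space; a features-only mode is provided for
  the stricter reading where only features are compared.
* Whether PLS sample selection should use t, u, or both is an open
  modeling question; the super score t is used.
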