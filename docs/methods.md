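# Methods

## Model

Encoding is exact posterior inference in a hidden Markov model over
structural letters.  For a chain of `n_res` residues the observations are
the `n = n_res − 3` fragment descriptor vectors `X_i ∈ R^4` (three
inter-Cα distances plus the signed out-of-plane distance `X4`); the hidden
states are letters `S_i ∈ {1..m}` with uniform start `1/m` and a
homogeneous row-stochastic transition matrix `π`.  Emissions are
letter-specific Gaussians `N(μ_s, Σ_s)` with `Σ_s` symmetric positive
definite.  The start is uniform by model definition — letter frequencies
are stored for reference but never enter inference.

Forward quantities are initialized `F_1(s) = e_1(s)/m`, backward
`B_n(s) = 1`; the sum recursions give the evidence
`P(X_1:n) = Σ_s F_n(s)` and the marginal posteriors
`POST_i(s) ∝ F_i(s)B_i(s)`; replacing sums by maxima gives the max-forward
/ max-backward tables from which the MAP is read off per position as
`argmax_s F_i^max(s) B_i^max(s)`.  Per position the entropy
`ENT_i = −Σ_s POST_i(s) log POST_i(s)` (nats, with 0·log 0 = 0) and
`NEFF_i = exp(ENT_i) ∈ [1, m]` summarize encoding uncertainty.

## Missing data

A missing Cα removes every descriptor that needs it (requirements —
X1: atoms {0,2}; X2: {0,3}; X3: {1,3}; X4: all four).  One missing interior
residue therefore degrades exactly the four fragments that contain it,
each keeping one or two descriptors.  The emission for availability set
`J` is the exact Gaussian marginal on `J`: `N(x[J]; μ_s[J], Σ_s[J,J])`,
including the `−(|J|/2)·log 2π` constant — that constant varies with `|J|`
across positions, so dropping it would bias MAP and POST under missing
data.  `J = ∅` emits density 1 (log 0): the position is informative only
through the Markov context.

## Consensus over replicate chains

For `k` chains aligned on one residue index and assumed to share one
hidden path, the position-`i` emission is the product over chains of the
per-chain restricted Gaussian densities; its log is the sum of per-chain
log emissions, each with its own ½·log det and ½·quadratic-form terms and
`|J_j|/2·log 2π` constants, which keeps the `k = 1` case exactly equal to
single-chain encoding and makes the consensus invariant to chain order.
A chain that is entirely missing at a position contributes a zero term and
drops out.  Alignment is purely label-based (author residue number +
insertion code); chains are never re-aligned by sequence similarity, which
would import an arbitrary scoring choice.

## Numerical choices

- All inference in log space with log-sum-exp; evidence is a density and
  may exceed 1, no renormalization is applied.
- Restricted covariances are Cholesky-factorized once per availability
  pattern (at most 16 patterns) rather than per fragment.
- Argmax ties break to the lowest letter index, making MAP deterministic;
  when several paths tie for the joint maximum the per-position rule could
  in principle mix them, which the tie-break also resolves deterministically.
- A log-sum-exp over an all-`−inf` row (every letter at zero likelihood)
  raises an explicit encoding failure rather than propagating NaN.
- Collinear base planes (degenerate for X4) mark X4 unavailable with a
  warning instead of raising — real backbones never hit this; synthetic
  inputs may.  Tolerance: cross-product norm below 1e-9 times the product
  of the segment lengths.

## Structure parsing

First model only (multi-conformation ensembles are out of scope); altloc
resolved to highest occupancy, ties to altloc 'A'; MSE HETATM Cα accepted
as a residue, other HETATM ignored.  Missing positions come from author
numbering gaps inside the observed span, plus SEQRES-declared residues
outside the span when gemmi's label-sequence alignment succeeds (author
numbers there are extrapolated arithmetically); when SEQRES alignment is
unavailable, span inference alone applies.  These rules are logged per
chain.

## Synthetic data and what it does (not) show

The generator emulates the model itself: Markov paths from `π`, Gaussian
descriptor emissions per letter, replicate chains sharing one path, and
masks over residues or descriptor sets.  Synthetic descriptor series are
emitted directly in descriptor space — the descriptor map from 3D is not
injective, so no inverse reconstruction is attempted; separate 3D fixtures
(ideal α-helix: 1.5 Å rise, 2.3 Å radius, 100° twist; extended-strand
zigzag with 3.8 Å virtual bonds; random-walk coils; mixed-segment
backbones) exercise the geometry and PDB I/O path.  The packaged 27-letter
file carries the published nomenclature, classes and frequencies with
synthetic Gaussian/transition parameters anchored at those geometry
classes (helix↔strand transitions excluded, strongest self-transition on
the last helix letter).  Passing tests therefore demonstrate the
correctness of the inference machinery and the qualitative phenomena
(consensus sharpening, missing-data footprints, mismatch growth with mask
width) — not the letter-level encodings real parameter tables would give.
Real-data worked-example values can be reproduced only once the authentic
μ, Σ and π are loaded from a file in the native JSON format.

## Experiment protocol

The masking experiment draws, per repetition from one seeded generator in
fixed order: a chain (uniform), a window width `k` (uniform over the
requested set), and a window position (uniform over valid starts); masks,
re-encodes, and counts letter and class mismatches against the original
MAP over all positions (global re-decoding may flip positions outside the
window; counts are not restricted to it).  Per-`k` statistics aggregate
the repetitions that drew that `k`.  Reports are bit-identical under equal
seeds.  Desk-scale runs use 10 synthetic 80-residue chains and 500–1000
repetitions; the acceptance script uses the 27-letter alphabet so that
within-class letter flips keep class mismatches strictly below letter
mismatches.

## Known limitations

- The packaged alphabet's numeric parameters are synthetic; encodings of
  real PDB chains under it are structurally sensible but not comparable
  letter-by-letter to published encodings.
- Only label-based chain alignment; heteromers must be encoded as
  independent chains.
- No posterior path sampling or N-best decoding; no structural-sequence
  alignment scoring; no multi-file (multi-conformation) modelling.
- Biological-assembly reconstruction by symmetry is not performed; chains
  are taken as deposited.
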