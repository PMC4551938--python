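# Methods

## The harmonic model

Each selected interaction center (bead) of the reference structure is a
node; every bead pair whose reference separation d̃_ij is strictly below
the cutoff R_c receives a harmonic spring of constant k penalizing changes
of the inter-bead distance. The model restrains distances, not absolute
positions, so the energy is invariant under rigid motions. Expanding to
second order around the reference gives U = ½ δrᵀMδr with the standard
pairwise blocks: the off-diagonal 3×3 block of a springed pair is
−k_ij (d̂⊗d̂) with d̂ the unit reference separation, and diagonal blocks
are the negated sums of the bead's off-diagonal blocks, which enforces
translation invariance exactly (by construction, not numerically). The
Hessian is validated on every construction: symmetry, zero block-row sums,
positive semi-definiteness.

A connected, non-collinear network has exactly six zero-energy modes
(three translations, three rotations). A mode counts as zero when its
eigenvalue is below 1e-10 × the largest eigenvalue — a relative threshold,
since the absolute spectrum scales with k. Surplus zero modes mean the
network is disconnected or degenerate, and the covariance constructor
refuses such Hessians rather than silently discarding extra modes; the
only exception is the two-bead system, which legitimately has five rigid
modes (no rotation about its own axis). The smallest cutoff with exactly
six zero modes ("minimum viable cutoff") is found on the 3–30 Å grid in
1 Å steps by default.

The equilibrium covariance is C = scale × Σ_{λ>tol} λ⁻¹ v vᵀ over the
internal modes. The physical prefactor k_BT/k is set to 1: MSF Pearson
correlations, RWSIP and all profile correlations are invariant to it.
Consequently MSF values are in units of Å²·(k_BT/k) and only profile
*shapes* are meaningful, which is how all comparisons are formulated.

## Coarse-graining and the effective Hessian

Bead subsets (e.g. only phosphates of an SBP model) are compared through
the Schur complement M_a^eff = M_a − W M_b⁻¹ Wᵀ, computed with a symmetric
solve rather than an explicit inverse. A discarded block with condition
number above 1e12 raises an error: it signals a discarded sub-component
that is mechanically decoupled from the kept beads (e.g. a bead held by
fewer than three independent spring directions, or a disconnected
fragment).

A gauge subtlety matters when testing this operation. The pseudoinverse of
the full Hessian fixes the *global* rigid-body gauge, while the
pseudoinverse of the effective Hessian fixes the *kept-subsystem* gauge.
The (a,a) sub-block of the full covariance therefore differs from the
reduced covariance by rigid-body content of the kept beads; after
projecting that sub-block orthogonal to the kept beads' rigid modes the
two agree to machine precision, and this is the identity the tests assert.
`rigid_mode_basis` builds the rigid fields geometrically (translations plus
rotations about the centroid, orthonormalized by SVD), independently of any
eigendecomposition.

## Ensemble comparison

Ensemble covariances are plain second moments about the ensemble mean with
divisor n (the time-average convention; at realistic frame counts the
n−1 distinction is irrelevant). Before the covariance is taken, frames are
rigid-body superposed onto the reference with a batched Kabsch algorithm
(SVD with reflection correction). Following the comparison protocol, both
the superposition and the covariance for a given role consider exclusively
the beads of that role. Residual rigid-body content that superposition
cannot remove exactly (alignment is a nonlinear operation) is retained,
not projected out.

RWSIP is computed over full eigen-systems; when two spectra have different
mode counts the shorter one is zero-padded, which changes neither sum.
The measure is symmetric, bounded in [0, 1] (values above 1 by more than
1e-9 raise an error; smaller overshoot is clipped), and undefined for an
all-zero spectrum. An ensemble whose frames deviate from their mean by
less than 1e-10 Å is rejected as fluctuation-free rather than letting
round-off noise masquerade as dynamics.

The cutoff scan builds the ENM at each grid point, skips (and flags)
points without exactly six zero modes, reduces the Hessian to each
single-role subset, and scores RWSIP and MSF Pearson against the
role-restricted ensemble covariance. Two references calibrate the scores:
the fully connected random network with k_ij ~ Uniform[0,1] (mean and
spread over 10 seeds by default — the number of draws is a package choice,
exposed as a parameter) as the floor, and the RWSIP between covariances of
the first and second half of the frames (split by frame order) as the
ceiling.

## Distance fluctuations and the SHAPE proxy

The variance of an inter-bead distance follows analytically from the
covariance in the linear perturbation regime by projecting the relative
fluctuation on the reference separation direction. Applied to consecutive
C2–C2 pairs within each chain it yields a per-nucleotide profile; because
a pair value belongs to a bond rather than a nucleotide, an assignment
rule maps pairs to sites. The default `mean_flank` gives every nucleotide
the mean of its flanking pair values (chain ends keep their single flank);
`five_prime`/`three_prime` assign each pair to one of its ends and drop
the unpaired terminal site. The rule changes bookkeeping, not the pair
values. Consecutive means successive base beads in residue order within a
chain, so numbering gaps do not break the profile.

Empirical distance and angle variances from ensembles use divisor n; the
angle at vertex j uses arccos of the normalized dot product. Analytic
angle-variance propagation is deliberately not implemented: ensemble angle
fluctuations are provided for completeness, but base–base distance
fluctuations are the informative flexibility proxy.

SHAPE files are two- or three-column text (residue, optional chain,
reactivity); negative or non-finite reactivities — the common
missing-data conventions — are dropped from correlations and the dropped
count is reported alongside the matched count. Fewer than three matched
residues is an error, not a silent NaN. No reactivity normalization is
applied.

## Synthetic fixtures

`generate_duplex` places two antiparallel strands of S/B/P beads on a
regular helix (defaults: 16 bp, rise 2.8 Å, twist 32.7°, C1′ radius
9.4 Å, base beads at 3.0 Å radius so cross-strand base contacts fall in
the 5–6 Å range). Strand B is the exact image of strand A under a
two-fold rotation about an axis perpendicular to the helix, with residues
numbered so that the end-to-end relabeling (A,i)↔(B,n+1−i) is an exact
symmetry operation — this is what makes MSF-profile symmetry a sharp test.
The fixture is a statistical stand-in for a short RNA duplex: it has
realistic bead densities and connectivity but no grooves, no sequence
heterogeneity, no terminal fraying and no non-canonical geometry, so tests
passing on it validate the machinery, not the biology of any particular
molecule.

`sample_ensemble` draws Gaussian conformers through the eigendecomposition
square root of the covariance, so rank-deficient covariances (rigid modes
removed) are sampled correctly inside their image — sampled frames carry
no rigid-body displacement and need no re-alignment. `random_cloud` places
uniform points with a minimum-separation rejection rule and guarantees a
non-degenerate 3D cloud for n ≥ 4.

## Numerical validation choices

The Monte-Carlo check of the analytic distance variance needs care because
the identity is exact only in the linear regime. At amplitude ε the
sampled variance carries a fourth-order term with the exact Gaussian
coefficient (Isserlis), implemented in the test suite:

    Var(d)/ε² = σ²_lin + ε² [ Var(w²)/(4d̃²) − E[a²w²]/d̃² ] + O(ε⁴),

where a and w are the longitudinal and transverse components of the
relative fluctuation. For the soft modes of the duplex at k = 1 this term
can exceed the sampling noise of 10⁵ draws at ε = 10⁻². The noise-level
comparison therefore draws its random pairs among those whose predicted
fourth-order term is below a third of the Monte-Carlo standard error — an
a-priori premise check computed from the covariance before any sampling —
and each pair is sampled from its own marginal 6×6 covariance block with
an independent seed, so the standardized deviations are independent and
their aggregate can be judged by a chi-square bound. The approach to the
linear limit itself is tested separately: the mean relative error over
unfiltered random pairs decreases monotonically over ε ∈ {10⁻¹, 10⁻², 10⁻³}.

Problem sizes used by the default validation runs: the 16-bp duplex
(96 beads), ensembles of 10⁴ frames for parameter recovery, 10⁵ draws per
pair for the distance-variance oracle, 50 random clouds of up to 30 beads
for zero-mode and marginalization sweeps, and 20 random networks for the
finite-difference Hessian oracle. These sizes give sub-percent statistical
resolution for every assertion made.

## Known limitations

- Harmonic, single-basin model: no anharmonicity, no conformational
  switching, no explicit ions or sequence-dependent stiffness. The
  distance-dependent spring hook (`spring_function`) is exposed but no
  functional form is shipped.
- PDB input only (no mmCIF); no structure repair or protonation; residues
  missing a representative atom simply contribute no bead for that role
  (with a warning), including 5′ termini without a phosphate.
- MSF and distance variances are relative (k_BT/k = 1); absolute Å² values
  require calibrating the scale externally.
- The SHAPE proxy is a flexibility surrogate: it does not model the
  chemistry of the acylation reaction, and profile agreement is assessed
  by correlation only.
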