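# Methods

## Internal coordinates and conventions

A chain of n C&alpha; positions is reduced to discrete Frenet internal
coordinates.  With 1-based residue indices, unit tangents
t_i = (r_{i+1} − r_i)/|r_{i+1} − r_i| exist for i = 1..n−1, binormals
b_i = t_{i−1} × t_i /|·| for i = 2..n−1, bond angles
θ_i = arccos(t_{i+1}·t_i) for i = 1..n−2, and torsions
φ_i = sign[(b_i × b_{i+1})·t_i] · arccos(b_i·b_{i+1}) for i = 2..n−2.
Frames are transported by R(θ_i, φ_i) = exp(θ_i T²) exp(φ_i T³) acting on
the row-stacked (n, b, t) triad, with (T^a)_{jk} = ε_{ajk}; the first
transport step carries no torsion — the overall twist of the first bond is
rigid-motion gauge, fixed by the seed frame.  The signs are chosen so that
transport and the cross-product frame definitions agree exactly (round trip
to machine precision) and a right-handed α-helix comes out at
(θ, φ) ≈ (π/2, +1); a mirror reflection flips every φ.  θ is stored in
[0, π), φ wrapped to [−π, π).  The bond length is fixed at 3.8 Å, the PDB
average for trans C&alpha;–C&alpha; virtual bonds.

Degenerate sites (collinear consecutive tangents) have no binormal; the
convention is inheritance from the previous defined site, with φ := 0
across straight runs, and a warning recording the sites.  This keeps the
transforms total; under the continuous Monte Carlo proposals the case has
measure zero.

## Free energy

Within soliton segment k carrying constants (λ, m, a, b, c, d):

F = Σ_{i=1}^{Nθ−1} (θ_{i+1} − θ_i)²
  + Σ_i [ λ_k (θ_i² − m_k²)² + (d_k/2) θ_i² φ_i² + (c_k/2) φ_i²
          − b_k θ_i² φ_i − a_k φ_i ]  +  hard core.

The nearest-neighbour term is the DNLS discrete Laplacian written in
free-boundary difference form: in the bulk it is identical to the
−2θ_{i+1}θ_i + 2θ_i² pairing (the difference telescopes to boundary terms),
and it makes the uniform background θ = m an exact critical point of a
single segment including the ends — the natural free-boundary choice for an
open chain.  The stationarity residuals returned by the solver are the
*exact* analytic gradient of this F, which at the two end sites reads
2(θ_end − θ_neighbour) + V′ instead of the interior
2(2θ_i − θ_{i+1} − θ_{i−1}) + V′; a test verifies residual ≡
finite-difference gradient on random states, which simultaneously pins the
coefficient pairing (the d/2 and c/2 factors are exactly those that make
the printed variational equations gradients of F).

Per-site terms take their parameters from the segment containing the site;
the parameter-free Laplacian needs no cross-boundary convention.  The
excluded volume is a step-wise hard core: any two C&alpha; atoms at
sequence separation ≥ 2 must stay at least 3.8 Å apart (strict inequality;
bonded neighbours are exempt because their distance is pinned at exactly
the core radius).  It is enforced as move rejection — acceptance
probability zero — never as a finite energy, so ΔF stays finite.

φ is an angle of period 2π but F is polynomial, not periodic, in φ; all
code evaluates F on the wrapped representative in [−π, π).  The closed-form
torsion stationarity φ = (bθ² + a)/(dθ² + c) is likewise wrapped.  Segment
validity requires dθ² + c ≠ 0 on [0, π).

## Solver

`relax_to_critical_point` runs (1) up to 30 alternating sweeps — exact
torsion minimization by the closed form, then bounded L-BFGS descent in θ —
(2) a joint L-BFGS-B descent over (θ, φ) whose gradient is the residual
vector, and (3) if the residual is still above tolerance (descent stalls at
machine precision of F near shallow minima), a Newton (hybrid Powell) polish
on the residual system, accepted only if it lowers the residual norm and
stays in range.  The energy is non-increasing through phases 1–2; phase 3
starts from a near-minimum.  If the descent path fails — non-convergence,
or a critical point inside the excluded volume (descent can hop basins) —
a final fallback runs Newton from the *original* initialization, which
converges to a critical point near it; only if that also fails is the
error raised.  Default tolerance 1e−9 (max residual component); relaxed
structures violating the hard core are reported as failures.

`fit_model` determines segment parameters so the relaxed multi-soliton
reproduces a decoy trace.  Objective: Kabsch RMSD (proper rotations only).
Initialization is deterministic moment matching from the decoy's own
angles: c := 1 per segment (the torsion equation is invariant under common
rescaling of a, b, c, d), (a, b, d) by linear least squares of the torsion
stationarity, m by inverting the θ stationarity site-wise (clamped below
θ = 0.15, where the inversion is ill-conditioned) and taking the segment
median at fixed λ = 4.  The outer search is a seeded Gaussian-perturbation
hill climb with annealed step size; candidates whose relaxation fails are
discarded and logged.  Segmentation is either explicit or heuristic
(`segment_decoy`): cut at the most prominent smoothed |θ − median θ|
excursions, i.e. inside loops, which is where solitons are centred.

`pinned_model` is the limiting one-segment-per-site construction: a := cφ_i
makes the decoy torsions exactly stationary and m_i inverts the θ equation
including the decoy's discrete Laplacian, so with a stiff quartic (default
λ = 40) the decoy is, to a fraction of an Ångström, the model's own
multi-soliton.  This is how an arbitrary geometric fixture becomes a Monte
Carlo native state; fitted coarse segmentations only stay near decoys whose
angle profiles are piecewise-regular (protein-like), which the smooth toy
curves are not.

## Monte Carlo

Each step selects a move type (probability 1/2 bond angle, else torsion —
the proportion is configurable; the underlying physics only prescribes
"either one or the other") and a uniform site.  Torsions: Glauber rule,
proposal φ′ = φ + (π/2)·N(0, 1), acceptance e^{−βΔF}/(1 + e^{−βΔF});
proposals that violate the hard core are rejected outright (equivalent to
ΔF = +∞; the steric check and the Glauber draw are independent conjuncts,
and the implementation tests the cheap draw first).  Bond angles: heat-bath resampling from
P(θ) ∝ e^{−β_hb F_θ} on [0, π), where F_θ collects every θ_site-dependent
term; the density is discretized on a midpoint grid (default 1024 bins;
log-space weights, so arbitrarily large β_hb reduces gracefully to the
conditional argmin), sampled by inverse CDF with uniform placement within
the bin; clash-producing draws are rejected.  β_hb = 10¹³ β by default —
virtual bond angles are far stiffer than torsions, and in this regime the
θ profile effectively tracks its conditional minimum while the torsions
carry the thermal motion.

A cycle is heating (β multiplied by a constant < 1 each step, starting from
the native multi-soliton), thermalization (β fixed), cooling (constant
> 1); `Schedule.from_beta_range` derives the multipliers from endpoint
β values and step counts.  Production-scale constants (480e6 heating or
cooling steps, 7e6 thermalization steps, 1000 cycles, β_hb ratio 1e13) are
kept as named constants; bundled experiments are scaled down (below).

After every accepted move the coordinates are rebuilt from the internal
coordinates (an O(n) transport; mathematically the update is a rigid
rotation of the downstream sub-chain about the altered joint).  The
angular free energy is tracked incrementally and audited against a full
recomputation every 1e5 steps (tolerance 1e−6; in practice drift is at
rounding level because the audit also resynchronizes).  All randomness per
cycle comes from one seeded NumPy generator, drawn as fixed-layout streams,
so trajectories are bit-reproducible; the compiled (numba) inner loop and
its pure-Python twin consume identical streams and are asserted
bit-identical in the tests (except the cached-energy record column, where
compiled fused-multiply-add may differ in the last ulp).

## Topology

Open chains are closed by extending both termini radially outward from the
chain centroid (directions independently perturbed per closure) to a far
sphere — 10× the chain's maximal extent — and joining them across the
sphere through an outer waypoint; termini already within one mean bond
length are joined directly.  Twenty perturbed closures vote by majority
(five for the cheaper subchain scans).  Polygons are simplified by KMT
vertex deletion (a vertex is removable when its spanning triangle is
intersected by no non-incident segment; coplanar segments get an exact 2-D
overlap test), then typed by the knot determinant |Δ(−1)| computed from a
generic planar projection: each crossing contributes the t = −1 Alexander
relation row (−x_in − x_out + 2 x_over, independent of crossing sign) over
the arcs between consecutive underpasses; the determinant is any maximal
minor.  Degenerate projections (vertex-grazing crossings, z-ties,
overlapping parallels) are retried under small seeded random rotations.
Mapping: 1 → unknot, 3 → trefoil 3₁, 5 → figure-eight 4₁, else other(det).
The determinant cannot separate knots sharing |Δ(−1)| (e.g. 5₁ also has
determinant 5); for the unknot/trefoil/slipknot state space relevant here
it is complete.

`slipknot_scan` types the whole chain and closed subchains (i..j) on a
stride-5 grid with ±(stride−1) refinement around the extremal hits.  A
chain is slipknotted iff the whole chain is unknotted and some subchain is
knotted; the minimal knotted subchain is reported as the knotting loop, and
the free end beyond the maximal knotted subchain as the threaded segment.

## Synthetic study systems

The fixture generators produce: ideal α-helix/β-strand/straight chains
(exact 3.8 Å bonds via the reconstruction), seeded random chains with
angles bounded away from the degenerate rays, parametric (p, q) torus knots
and the figure-eight curve resampled to 3.8 Å mean spacing, and the
threaded-hairpin slipknot.  The slipknot chain (64 residues) traces a full
overhand knot whose final stretch dives radially inward through its own
knotting loop, then hairpins back out; a deterministic inflation step
(pair-repulsion plus SHAKE bond projection, small displacements that
preserve the isotopy class) opens the steric clearance to 4.3 Å, above the
3.8 Å hard core with margin for the subsequent relaxation.  Subchains
ending inside the threaded stretch close to trefoils over a wide index
window (robust to the stride-5 scan); the whole chain is unknotted.

The toy slipknot *system* attaches the site-resolved pinning model with a
staged torsion-stiffness profile: c = 6 on the threading stretch (fractions
0.355–0.68 of the chain), c = 0.5 on the threaded tail, c = 1 elsewhere,
λ = 40 throughout.  The staging encodes a folding order — the knotting
loop and its threading geometry lock in early during cooling while the
tail stays mobile and resolves last — which is what real slipknotted
proteins achieve through the relative thermal stability of their secondary
structure, and is what makes refolding observable at scaled-down schedule
lengths.  The trend study sweeps β geometrically between 3000 (cold:
equilibrium positional fluctuations ≈ 0.5 Å RMSD, well below the 2 Å
native-classification threshold) and 0.1 (hot: self-avoiding coil,
radius of gyration ≈ 3–4× native), with 20e3 heating and 5e3
thermalization steps; slow cooling = 150e3 steps, fast = 5e3.  With these
conditions slow cooling refolds the slipknot in roughly a quarter to
two-fifths of cycles and fast cooling almost never — the qualitative
cooling-rate dependence of knotting, at about three orders of magnitude
smaller step counts than a production study.  Misfolded final states are
predominantly unknotted collapses, with whole-chain trefoils (the
overshoot of the threading step, and the intermediate en route to the
slipknot) appearing at slower cooling.

What the toy does *not* emulate: real sequence heterogeneity (its
parameters are constructed, not fitted to a crystal structure), secondary
structure content (the curve is smooth rather than helix/strand-regular),
solvent or side-chain effects, and the production-scale separation between
the folding transition and the sampling rate.  Passing the trend test shows
the engine reproduces the topological mechanism — slow, threading-limited
knot formation — not that any particular protein folds.

## Classification and observables

Radius of gyration is the RMS distance from the centroid.  RMSD is Kabsch
(proper rotations; reflections excluded).  Torsion fluctuation profiles use
circular statistics — the per-site circular mean minus the native value,
wrapped, and circular SD √(−2 ln R̄) — which agree with plain differences
for small fluctuations and stay well-defined near ±π.  Final states are
labelled: whole-chain trefoil → `misfold_trefoil`; slipknotted and within
2.0 Å of the native → `native_slipknot`; unknotted, no slipknot →
`misfold_unknotted`; anything else `other` (mostly slipknotted refolds
that have not annealed below the RMSD cut).  The 2.0 Å threshold is this
package's default, not a literature value.  The cooling-rate study counts
*slipknotted* final conformations, the topological success criterion,
independent of the RMSD cut.

## Numerical choices and limitations

* Heat-bath grid: 1024 bins by default (256 in the scaled-down trend study);
  midpoint weights are second-order accurate, far below the sampling noise
  of any test.  The within-bin uniform makes the flat-β_hb limit exactly
  uniform.
* Knot screening cost: the subchain scan is O((n/stride)²) determinant
  evaluations; at n = 64 a full scan takes ~0.3 s, dominated by closure +
  KMT.
* The fitter provides no global-optimality guarantee; on non-protein-like
  (smooth-curve) decoys coarse segmentations have distant critical points
  and the fit plateaus — use `pinned_model` granularity instead.
* Relaxation can legitimately fail on random stress-test parameter sets
  (non-convergence, or a critical point inside the excluded volume); both
  are reported as explicit errors with the residual trace.
* PDB reading resolves altlocs to highest occupancy (ties: first listed)
  and warns on residue-number gaps; only C&alpha; atoms are used, and no
  side-chain reconstruction is attempted.
* Mapping Monte Carlo β to physical temperature is out of scope; all
  temperatures in this package are quoted as β on the simulation scale.
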