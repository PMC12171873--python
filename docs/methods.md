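# Methods

This note documents the models implemented in `nmsm`, the choices made
where the method left room, and what the synthetic validation does and
does not demonstrate.

## The state-model leg

### Featurisation and units

All lengths are Å, times ns, angles degrees; residues keep their 1-based
PDB numbers and frames are 0-based.  χ1 is the signed N–CA–CB–γ dihedral
in (−180°, 180°], with the γ atom taken per residue type (CG by default;
OG Ser, OG1 Thr, SG Cys, CG1 Ile/Val); Gly/Ala and incomplete side chains
are skipped with a warning.  Rotamer classes use bins centred on the three
staggered wells: trans for |χ1| ≥ 120°, gauche(+) for −120° < χ1 < 0°
(the −60° well), gauche(−) for 0° ≤ χ1 < 120° (the +60° well).  Note that
part of the rotamer literature attaches the (+)/(−) signs the other way
round; the convention here matches the labels used in the transporter
gating literature this package serves.  Helix distances are Euclidean
distances between Cα centres of geometry of two residue spans.
Ligand–residue distances are minima over atom pairs (compatible with the
4 Å contact convention), capped at 12 Å.  Contact residence is the
fraction of frames with minimum distance strictly below 4 Å; a contact is
"consistent" only above 50% occupancy (0.5 exactly is not).  SASA is
Shrake–Rupley with a 1.4 Å probe and 960 golden-spiral points per atom
(quadrature error well under 1%; a 10⁴-point oracle is used in tests),
with element-keyed van der Waals radii and a 1.5 Å fallback for unknown
elements.  Which residue sets constitute the extracellular/intracellular
faces for SASA-based open/closed calls is a biological choice, so it is
user-supplied configuration, not code.

### tICA and microstates

tICA solves C(τ)v = λC(0)v with symmetrised estimators — C(0) averages
both window ends and C(τ) ← (C(τ)+C(τ)ᵀ)/2 — which guarantees a real
spectrum with |λ| ≤ 1 up to the ridge term (default 10⁻⁶·tr C(0)/d) used
to tolerate redundant features.  Covariances accumulate per trajectory;
windows never span a trajectory boundary.  Circular features enter as
(cos χ, sin χ) pairs so the ±180° wrap is not seen as a jump.  Microstates
come from seeded k-means++ (single initialisation, tolerance 10⁻⁶, ≤500
iterations), so discretisation is bit-reproducible for a fixed seed.

### Microstate MSM and PCCA+

Transition counts use a sliding window at the chosen lag, per trajectory.
Estimation restricts to the largest strongly connected component of the
count graph (disconnected microstates are dropped, not merged).  For
lumping, the reversible (symmetrised-count) matrix is used because PCCA+
needs a real spectrum; the raw row-normalised matrix is what the IGME
stage consumes, because the non-Markovian fit should see the observed
dynamics.  PCCA+ takes the top-m right eigenvectors in the π-weighted
inner product and finds the m most extreme microstates by the
Deuflhard–Weber index search; memberships are the barycentric coordinates
in that simplex, clipped to [0, 1] and renormalised.  Macro populations
aggregate the crisp (argmax) assignment, and free energies are
ΔG_i = −k_B T ln(π_i/π_max) with k_B = 0.0019872 kcal/mol/K and T = 310 K
by default, pinning ΔG = 0 at the most populated ("lowest energy") state.
How many macrostates to use is exposed as configuration; the silhouette
of the spectral gap is reported but not decided automatically.

### IGME

The macrostate propagator series T(t) (row-normalised counts at lags
1..N, all states kept on a fixed index set) is modelled as
T(t) ≈ A·T̂^t.  Taking the principal matrix logarithm linearises this to
ln T(t) ≈ ln A + t·ln T̂, fitted by elementwise ordinary least squares
over t ∈ {τk+1, …, τk+L}: τk is the memory-kernel relaxation time (lags
inside it are excluded because the kernels have not decayed) and L the
window length.  A single-lag window cannot identify memory, so L = 1
attributes everything to the propagator (A = I), which keeps the
Markovian limit exact for every window.  If a window matrix has a complex
or defective logarithm (possible under finite sampling), the fit falls
back to direct nonlinear least squares on T(t), initialised from the
usable log-space fit.  T̂ is projected back to the stochastic simplex by
clipping negatives and renormalising rows; predictions A·T̂^t are clamped
to [0, 1] before reporting.

Hyperparameters are scanned on a grid (10×10 by default, mirroring the
100-model scans used for the reference systems) and ranked by the
Frobenius RMSE between predicted and estimated TPMs.  The ranking
evaluates every candidate on a *common* lag set — all lags beyond the
largest τk in the grid — because scoring each candidate only beyond its
own τk lets large-τk models avoid the short-lag region where the memory
correction is actually tested; with the common set the selection was
stable across seeds where the per-τk variant occasionally picked fits
whose implied timescale was off by ~8%.  The per-τk variant remains
available (`eval_mode="beyond_tau"`).  Ties break toward smaller τk, then
smaller L.  Series depth matters: lags beyond roughly twice the slow
implied timescale carry almost no slow-mode signal (λ₂^t < e⁻²) and only
add noise to the unweighted OLS, so the validation experiments estimate
the series to lag 60 frames (~2.2× the fixture's slow timescale).

The Chapman–Kolmogorov test compares model-predicted T(nτ) against TPMs
re-estimated at nτ, with percentile intervals from 200 bootstrap
resamples over whole trajectories; a model passes when its curve lies
inside the interval for ≥95% of matrix elements.  Because the interval
shrinks as 1/√N while the IGME form is only asymptotically exact, this
test — like any goodness-of-fit test — will reject even excellent
approximations at arbitrarily large N; the validation runs it at the same
sampling depth as the recovery experiment (10⁶ frames), where it cleanly
separates the IGME (all elements inside) from the lag-1 MSM (essentially
none).

MFPTs are computed from the row-normalised long-time propagator T̂ alone,
solving (I − T̂_B)m = Δt·1 with the target row/column removed (Δt = one
lag step in ns); the memory correction A only shapes short-time
predictions and has no natural place in a stationary first-passage
calculation.  A caveat follows from coarse-graining itself: T̂ encodes
*relaxation* rates, which count a crossing as complete only once the
system commits, whereas the exact first-passage time to a macrostate is a
*first-touch* quantity.  On lumped chains with recrossing, the T̂-based
MFPT therefore overestimates the exact value by roughly the inverse
transmission coefficient, while the lag-1 MSM (instantaneous flux)
underestimates it — the two bracket the truth.  The validation suite
states this openly: the recovery experiment requires both estimates
within 15% of the exact value, and one deliberately strict test of
"propagator-MFPT closer than flux-MFPT" fails at the population level on
the reference chain.  Implied timescales, where the IGME's advantage is
structural, show the expected large win (~10% MSM bias removed to <4%).

TPT runs on T̂ with its stationary distribution.  The forward committor
solves the standard linear system with q⁺(source) = 0, q⁺(sink) = 1; the
backward committor uses the time-reversed chain.  Gross flux
f_ij = π_i q⁻_i T_ij q⁺_j is antisymmetrised to net flux, and pathways
are peeled off by repeated widest-path (maximum-bottleneck) search until
less than 1% of the total flux remains.  Endpoints default to the
highest- and lowest-free-energy states; a flat landscape is rejected.

## The pathway leg

The detector trains a 10×10 sheet-shaped (non-periodic) SOM for 5000
cycles on capped ligand–residue distance vectors; one cycle presents every
frame once in a seeded random order.  The published tool family does not
document its exact schedules, so the defaults here are standard ones and
are recorded as such: learning rate linear 0.05 → 0.01, Gaussian
neighbourhood with radius linear from half the grid diagonal to one
lattice spacing (updates beyond 3σ are skipped), codebook initialised
from per-feature data quantiles at seeded uniform levels.  Training is a
compiled (numba) kernel and is deterministic for a fixed seed.

Occupied neurons are grouped by Ward agglomerative clustering on codebook
vectors; the cluster count maximises the mean silhouette over the
candidate range (ties to the smaller k); empty neurons are excluded
because a codebook vector without data is not a conformation.  The neuron
transition network counts consecutive-frame BMU transitions within
trajectories only; self-loops are recorded in the network dump but
excluded from pathway search (dwelling is not a transition).  The
cluster-level condensation drops intra-cluster moves.  The unbound
cluster is the one with maximal mean capped distance (everything at the
cap = ligand in solvent); the bound cluster is the minimal-mean cluster
sitting at an edge (degree ≤ 2) of the condensation, falling back to the
global minimum with a warning.  Pathways are simple paths bound→unbound
ranked by bottleneck weight — chosen over total weight because dwell-time
inflation on popular edges should not promote a path — and per-path
support counts trajectories containing the path as an ordered cluster
subsequence.  Trajectories supporting both branches (typically brushing
the junction) are assigned by dwell time in the clusters unique to each
pathway.

## Synthetic systems: what they emulate and what they do not

The **gateway chain** has two metastable pairs (internal exchange
0.20/step) coupled only through one gateway state per pair (hop
0.04/step) at 0.1 ns/frame.  Lumping each pair to one macro label yields
an observation that is genuinely non-Markovian: implied timescales grow
with lag and the lag-1 MSM underestimates the slow timescale
(2.724 ns exact) by ~10%.  Ground truth is computed by direct linear
algebra: stationary vector (uniform by symmetry), slow timescales from
the hidden eigenvalues (−Δt/ln λ), and macro MFPTs from absorbing-set
solves weighted by the stationary distribution within the source macro
(5.25 ns between macrostates).  An exact lumped TPM series is also
available to separate estimator bias from sampling noise.

The **egress channel** is a 2-D overdamped Langevin (Euler–Maruyama,
dt = 0.02 ns, D = 1 Å²/ns, kT = 1) in a potential that confines the
particle harmonically (2 kT/Å²) to a Y-shaped skeleton of two rays at
45°/135°, tilted 0.5 kT/Å downhill; absorbing exits lie beyond 25 Å, and
a +10 kT Gaussian barrier can block a branch.  Eight pseudo-residue
anchors (two near the basin, three along each branch) generate the capped
distance features; fully exited frames saturate every anchor at the cap,
which is what makes the unbound cluster well defined.  Trajectories are
recorded every 50 steps (1 ns), exit in ~50 ns on average, and carry the
exit branch as ground truth.  Per-trajectory random streams derive from
one seed by fixed offsets.

These systems reproduce the *statistical structure* the pipeline assumes
— metastability with hidden intra-state kinetics, and branched egress
with a common unbound endpoint — at toy scale.  They do not emulate
membrane physics, all-atom force fields, transporter geometry, or the
sampling heterogeneity of adaptively seeded simulation swarms, so passing
tests certify the estimators and their implementation, not any biological
conclusion about a particular transporter.

## Problem sizes and tolerances

Validation experiments use 50 trajectories × 20 000 frames (10⁶ frames)
for the chain studies and 200 Langevin trajectories for the pathway
study; these sizes put sampling noise well inside the asserted tolerances
(timescale within 15%, MFPT within 15%, branch assignment ≥95%, branch
fractions within 5 points) across seeds.  Exact algebraic identities
(Markovian limit, closed-form MFPTs, committors, flux conservation) are
asserted at 10⁻⁸–10⁻¹⁰.  Degenerate inputs are rejected with diagnostics
rather than patched: reducible chains, flat free-energy landscapes,
all-identical codebooks, selections without the required atoms.

## Known limitations

* No maximum-likelihood reversible MSM estimation or Bayesian error bars;
  reversibility comes from count symmetrisation only.
* The time-derivative (memory-kernel) master-equation variant is out of
  scope; the integrated form is used throughout.
* PCCA+ uses the index-search construction without the subsequent
  crispness optimisation; for well-separated metastable systems (the
  intended regime) the two coincide.
* MFPTs inherit the first-touch vs relaxation ambiguity of any
  coarse-grained description, as discussed above.
* The SOM schedules are sensible defaults, not a re-implementation of any
  specific published tool's internals.
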