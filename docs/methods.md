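# Methods

## Model

A single linear chain of `N` identical beads (unit mass, diameter
`sigma`) interacts through

* **WCA repulsion** between *every* bead pair, bonded neighbours
  included: `U = 4*eps*[(sigma/r)^12 - (sigma/r)^6] + eps` for
  `r < 2^(1/6)*sigma`, zero beyond. Beads are athermal hard-sphere-like
  monomers with no attraction and no charge.
* **FENE springs** on consecutive beads:
  `U = -(kappa/2)*R_o^2*ln[1 - (l/R_o)^2]` with `kappa = 30 eps/sigma^2`
  and `R_o = 1.5 sigma`. Together with the WCA term this gives a mean
  bond length `<l> ~ 0.97 sigma` and an effective bead width
  `w ~ 0.9 sigma` at `T = eps/k_B` — a touching-bead chain.
* **Discrete worm-like-chain bending**: `U = b*k_BT*(1 - u_i.u_{i+1})`
  per interior joint, where `u_i` are bond unit vectors. Equivalently
  `b*k_BT*(1 + cos(theta))` with `theta` the valence angle, so a
  straight chain costs nothing. `b = 0` is the flexible chain; `b = 20`
  maps double-stranded DNA at high ionic strength (`P/w ~ 50 nm/2.5 nm`).
  The prefactor is the constant `b*k_BT`, not rescaled by the
  instantaneous bond length; this reproduces `P ~ b*<l>`.

The confinement is an infinite square lattice (spacing `S_p`) of
parallel hard cylindrical posts along x, entering as a WCA potential
acting on the bead-to-axis distance shifted by the post radius
(geometric diameter `D_p`). Because `S_p` always exceeds the WCA cutoff,
a bead can interact with at most the four posts bounding its cell, so
the lattice is evaluated lazily by floor arithmetic — no stored post
list and no periodic box (the system is open in all directions).

Reduced units throughout: `eps = sigma = m_o = 1`, `T = eps/k_B`,
time unit `tau = sigma*sqrt(m_o/eps)`.

## Geometry calculus

For bead width `w`: effective post diameter `d_p = D_p + w`, passage
(quasi-slit) width `w_p = S_p - d_p`, quasi-channel diameter
`d_c = sqrt(2)*S_p - d_p`, post volume fraction
`F = pi*d_p^2/(4*S_p^2)`. The `sqrt(2)` in `d_c` is the diagonal of the
lattice cell: the interstitial space is gauged by the circle inscribed
between the four bounding posts. A bead fits through an aperture only
for `S_p > D_p + 2w` (= 4.8 for `D_p = 3, w = 0.9`); at `S_p = 3.9` the
midpoint barrier is ~1.15e5 k_BT, i.e. the apertures are sealed.

Cell membership uses half-open tiles `[i*S_p, (i+1)*S_p)`; points on a
lattice line belong to the higher-index cell (a measure-zero
convention).

## Sampling

Two samplers target the same Boltzmann distribution:

* **NVT molecular dynamics** (`integrate`): velocity-Verlet core,
  `dt = 0.005 tau` by default, with a Nose-Hoover thermostat
  (relaxation 0.1 tau) as the default, a BAOAB Langevin thermostat as an
  alternative, or no thermostat for energy-conservation checks.
  Velocities initialise Maxwell-Boltzmann with zero total momentum,
  seeded; runs are bit-reproducible for a given seed. A blow-up
  (bond reaching `R_o`, bead entering a post) aborts with the failing
  step index. Straight perpendicular starts that graze posts are
  relaxed by a short capped-displacement push-off before dynamics.
* **Metropolis Monte Carlo** for free chains (`pivot_sample`): pivot
  rotations (the shorter arm, about a uniformly random axis), crankshaft
  rotations of interior segments, and single-bead displacements. The
  displacement moves make bond lengths fluctuate, so the stationary
  distribution is that of the full Hamiltonian. Pivot moves decorrelate
  global chain size in a handful of accepted moves, which makes this the
  method of choice for long-chain equilibrium averages; acceptance rates
  and the lag-1 autocorrelation of R_g^2 are reported in the trajectory
  provenance. An energy cap (current energy + 45 k_BT) truncates
  hopeless trial evaluations early; the associated acceptance bias is
  below e^-45 per move.

The two samplers are cross-checked against each other in the test suite
(R_g of free chains at N = 32 agrees within combined statistical error
for both stiffness values), and the MD core is checked for NVE energy
conservation and thermostat fidelity. Simulations in the tests and in
the acceptance script run at desk scale (N <= 1000 beads, 1e6-step MD
runs, a few hundred Monte Carlo frames) — chosen as the smallest sizes
at which the measured quantities have useful error bars; the full-scale
protocol (N = 1000 over 2e8 tau with three replicas) is reachable
through the same configuration surface.

## Observables

* axial span `R_s = <max(x) - min(x)>` along the post axes;
* occupation number `n_p`: distinct cells holding at least one bead
  centre (per-frame *mean* over frames; the simplest consistent rule,
  since no threshold is prescribed);
* gyration radius as `sqrt(<R_g^2>)` with axial (x) and lateral (y+z)
  components;
* bond correlation `<cos theta_ij>` vs contour separation, with the
  persistence length from a least-squares fit of `ln<cos theta>` over
  the initial decay: separations with `<cos> >= e^-2`, capped at `3b`
  bonds, residuals weighted by `<cos theta>` (inverse-variance weights
  for the log of a noisy positive quantity). The window and weighting
  matter: excluded volume makes the large-s decay non-exponential and
  the tail of the window noisy, so unweighted single-run fits scatter
  by about +-1.5 while weighted, replica-pooled fits are stable to a
  few tenths;
* single-chain structure factor
  `S(q) = (1/N^2)<sum_ij sinc(q r_ij)>` on a logarithmic q grid from
  the chain scale to the monomer scale (exact O(N^2) sum; frames may be
  subsampled);
* hump detection on the compensated curve `q*S(q)` inside
  `q in [0.4, 1.4]`: the highest interior local maximum with at least
  0.1% prominence, so a pure `q^-1` curve yields none. The hump sits at
  `q ~ 2pi/S_p` and diagnoses two parallel chain strands separated by
  one post.

Uncertainties are block-averaged standard errors with the block length
set by an integrated-autocorrelation estimate.

## Confinement theory

The interstitial volume is approximated as a square channel of side
`d_c` and the aperture as a slit of height `w_p`; a slit costs half the
free energy of the square channel of equal size. Channel free energies
per the blob and deflection pictures:

* de Gennes: `dA/k_BT = 4.0*L*(P*w)^(1/3)*D^(-5/3)`,
* Odijk: `dA/k_BT = 2.2072*L*P^(-1/3)*D^(-2/3)` (valid `D < P`).

Equating free energy per unit contour between quasi-channel and
quasi-slit gives the contour partition `L_qc/L_qs`:
`(1/2)(d_c/w_p)^(5/3)` (both de Gennes),
`0.2759*(w_p/P)^(2/3)*(w_p/w)^(1/3)*(d_c/w_p)^(5/3)` (de Gennes channel,
Odijk slit), `(1/2)(d_c/w_p)^(2/3)` (both Odijk). These are derived in
code from the two `dA` expressions and the half-channel slit rule — the
closed forms are asserted against that derivation, not hard-coded
independently. The Odijk-channel/de Gennes-slit pairing is rejected as
unphysical (the slit is the narrower space). Where the channel is
de Gennes-like but the slit Odijk-like the boundary is soft, so the
report lists the mixed pairing together with both pure ones rather than
choosing.

Extension laws: Odijk `R = L[1 - A*(D/P)^(2/3)]` with `A = 0.18274`
(square) or `0.1701` (circular); de Gennes `R = L*(wP/D^2)^(1/3)`.
Regimes: Odijk for `D < P`, extended de Gennes for `P < D < P^2/w`,
classic de Gennes beyond; boundaries resolve to the
stronger-confinement label (an arbitrary, documented tie-break). All
numeric prefactors are exact/asymptotic results for ideal channels and
are order-of-magnitude guides for the quasi-geometries of a post array.

Predicted S(q) slope windows follow the same regimes: -1 at the
persistence (or bond) scale, -5/3 (classic) or -2 (extended) in the
blob window, -1 for the linear blob array down to `2pi/R_s`, saturation
below; in the Odijk regime a single -1 window spans all `q > 2pi/R_s`.

## Synthetic fixtures

Deterministic conformations with exact ground truth: straight rods
(span, rod scattering), hairpins threading an aperture (occupation = 2,
strand separation = S_p, the S(q) hump motif), helices (exact bond
lengths, tunable rise), beads scattered over prescribed cells
(occupation counting), and synthetic `q^-1*(1 + Gaussian)` structure
factors (hump detection). Fixtures emulate geometric motifs only — not
Boltzmann statistics — so tests passing on them validate the analysis
machinery, not the physics of sampling; the sampler cross-checks above
cover that separately.

## Numerical choices and limitations

* Forces agree with centred finite differences to <1e-6 relative on
  non-overlapping configurations; at hard-core overlaps the energy
  scale (1e5+) makes finite differences meaningless.
* The Nose-Hoover integration uses a single thermostat variable with
  `Q = g*k_BT*tau_T^2`, `g = 3N - 3`; any correct NVT scheme is
  acceptable here because only equilibrium averages are consumed.
* The persistence-length fit assumes a positive initial decay; a rod
  (no decay) raises an error rather than returning infinity.
* Known discrepancy: with this Hamiltonian the equilibrium free-chain
  gyration radii at N = 1000 computed here are ~30 (b = 0) and ~79
  (b = 20). The Benoit-Doty formula for an ideal worm-like chain with
  the measured P ~ 19.4 and L = 969 already gives R_g = 77 for b = 20,
  and excluded volume can only add to it, so the package's values are
  internally consistent (and the MD/MC cross-checks agree); smaller
  literature values for the same nominal model appear to reflect
  under-converged sampling. The acceptance report simply states what
  this code computes.
* Not modelled: hydrodynamic interactions, electrostatics, applied
  fields, finite post height, disordered or hexagonal arrays.
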