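# Methods

## Model

The chromatin fiber is represented as a one-start solenoid: `T · n`
nucleosomes (default one turn of six) with nucleosome *k* at azimuth
`φ_k = φ_0 + 2πk/n`, position `(R cos φ_k, h R sin φ_k, P k/n)` where *R*
is the helix radius (default 10 nm), *P* the axial rise per turn (default
11 nm), and `h = ±1` the handedness.  Flipping *h* reflects the pose set
through the xz plane exactly (same floating-point cosines, negated sines),
which is the basis of all exact mirror tests.  Nucleosomes are isotropic
dielectric solids — cylinders of 11 nm diameter × 5.5 nm height, or 11 nm
spheres — with refractive index 1.68 hosted in water (1.33); the incident
vacuum wavelength defaults to 300 nm (the wavelength is interpreted as a
vacuum value; the medium enters through the relative index
`m = 1.68/1.33 ≈ 1.263` and the medium wavenumber `k = 2π·1.33/λ`).

**Nucleosome orientation.**  The verbal constraint that the flat faces be
"parallel to the tangent and normal to the helix axis" is over-constrained
for nonzero pitch.  The default `radial` mode points the cylinder axis
along the outward radial direction: the face plane then contains the local
tangent direction and the face normal is perpendicular to the helix axis,
and both clauses hold exactly in the zero-pitch limit.  `tangential` and
`axial` modes plus a tilt angle about the local tangent are provided for
orientation variants, since the alternative orientation used in the
original figures is not fully specified.

**Degenerate radius.**  At `R = 0` a frame that kept rotating with azimuth
would remain screw-chiral.  The default therefore assigns every nucleosome
the same frame (axis +x), producing a genuinely achiral linear chain; the
rotating-frame variant stays available behind
`SolenoidSpec(rotating_frame_at_axis=True)`.

**Right+left stack.**  `stack_opposite_handed` puts one turn of the
opposite handedness on top of a one-turn spec at axial offset *P*, with the
second segment's azimuth rolled by `−2φ_0 − 2π(n−1)/n` so that the
composite pose set is *exactly* mirror-symmetric through the horizontal
mid-plane `z = P(2n−1)/(2n)`.  The composite is provably achiral, which is
the construction under which its orientation-averaged CIDS vanishes to
solver precision rather than to quadrature error.

## Voxelization

The union of nucleosome solids is discretized on a cubic lattice with
spacing `d = (largest bounding-box extent)/dipoles_per_longest` (production
value 60, giving d ≈ 0.46 nm and ≈ 3.2·10⁴ dipoles for one turn; tests and
the acceptance script use 16–24).  A site is occupied iff its center lies
inside at least one *closed* solid (boundary points count as inside, for
determinism; overlapping nucleosomes merge by union).  The lattice is
centred on the bounding box, so cell centers come in exact ± pairs about
the box center along each axis: any y → −y or z → −z mirror symmetry of
the continuous model survives discretization exactly.  This is why the
achirality results below are machine-precision zeros instead of
discretization-limited ones.  A boundary-inclusive lattice slightly
overcounts volume at coarse resolution (the unit-lattice 11-cell sphere
holds 739 sites against a continuum estimate of 697, +6%); the excess
vanishes as *d* shrinks (+1% for the cylinder at d = 0.5 nm).

## Coupled-dipole engine

Each occupied site carries the lattice-dispersion-relation polarizability

```
α_LDR = α_CM / (1 + (α_CM/d³)[(b₁ + b₂m² + b₃m²S)(kd)² − (2/3)i(kd)³]),
α_CM  = (3d³/4π)(m²−1)/(m²+2),
```

with `b₁ = −1.8915316`, `b₂ = 0.1648469`, `b₃ = −1.7700004` and `S = Σ_j
a_j²|e_j|²` computed per incident wave from the propagation direction *a*
and polarization ellipse *e* (S = 0 for the default on-axis incidence).
The imaginary radiative-reaction term is kept exactly, so `Im(1/α) =
−(2/3)k³` for real *m* and a single dipole scatters without absorbing.

The self-consistent polarizations solve `P_i = α_i(E_inc,i + Σ_{j≠i} G_ij
P_j)` with the free-space dyadic Green tensor (time convention
`exp(−iωt)`, outgoing `exp(+ikr)`).  The sum is a 3-D lattice convolution:
the engine evaluates it with zero-padded FFTs of a block-Toeplitz kernel
built once per (model, wavelength) and reused across polarizations and
orientation nodes.  The direct O(N²) sum is retained as a reference and
agrees with the FFT path to ~10⁻¹⁶ relative.  The linear system is solved
by restarted GMRES with the Born polarizations as the initial guess; the
relative residual `‖P − α(E_inc + GP)‖/‖αE_inc‖` is re-verified explicitly
on the returned solution.  The default stopping tolerance is 1e−5;
symmetry tests that divide by deep m11 minima run at 1e−11 (the achievable
floor is ~1e−13, and these bounds probe structural exactness, not solver
noise).

Far fields are phased sums `A(n) = k² Σ_i e^{−ik n·r_i}(I − nn)P_i`,
projected on the parallel/perpendicular scattering-plane basis and
assembled into Bohren–Huffman amplitude matrices `[[S2,S3],[S4,S1]]`
(scattering plane = lab xz; θ ∈ [0°, 360°) at fixed orientation, [0°,
180°] when averaging; 1° steps by default).  Mueller matrices follow from
the quadratic coherency map `M = A (S ⊗ S*) A⁻¹`.  Polarization
convention: left circular ≡ Jones `(1, +i)/√2` on the incident
`(e_par, e_perp)` basis, Stokes V = +1; under it `CIDS = +m14/m11`, which
the test suite cross-checks against two explicit circular-illumination
solves (agreement ≤ 1e−8).

Cross sections: `C_ext = 4πk Σ Im(E*_inc·P)/|E₀|²` (optical theorem),
`C_abs` from the per-dipole absorption formula with radiative-reaction
correction (identically zero for real *m*), `C_sca = C_ext − C_abs`.
Efficiencies are normalized by the equal-volume sphere, `a_eff =
(3Nd³/4π)^{1/3}`; the normalization of the original efficiency plots is
not stated, so the equal-volume convention (standard in DDA codes) was
fixed here.  Energy conservation (`C_ext` vs the angular integral of the
far field) holds to <1% on converged runs, exactly for a single dipole.

## Orientation averaging

Averages use a product quadrature over intrinsic z-y-z Euler angles:
uniform in α and γ, Gauss–Legendre in cos β, weights normalized to 1.
Rotating the particle by R is implemented by rotating the incident wave and
scattering geometry into the particle frame with Rᵀ — mathematically
identical, and it keeps the FFT kernel valid at every node.  Averaged CIDS
is the ratio of averaged Mueller elements, i.e. the CIDS of ensemble
intensities `(⟨IL⟩−⟨IR⟩)/(⟨IL⟩+⟨IR⟩)` (verified as an algebraic identity
in the tests), not the average of per-orientation ratios.

With even `n_α` the node set is closed under the involution `(α, β, γ) →
(−α−π, π−β, γ)` that maps a particle to its horizontal-mirror image, so
the averaged m14 of an achiral composite cancels *exactly* (measured
~1e−17), not merely to quadrature error.  The default 8×8×4 quadrature
reproduces averaged m11 to <0.1% against 16×16×8 on small models.  This
product scheme replaces the Romberg integrator of the reference DDA code:
a stated, testable convergence contract was preferred over reproducing a
particular integrator bit-for-bit.

## What the generator emulates, and what it does not

The geometry module is the data generator: there is no external data.  It
reproduces the study conditions — cylindrical 11×5.5 nm (or spherical
11 nm) nucleosomes, six per turn, R = 10 nm, P = 11 nm, m = 1.68/1.33,
λ = 300 nm, 60 dipoles per longest dimension at production scale — and its
parameter sweeps bracket those defaults (pitch 0–22 nm, radius 0–20 nm,
turns 1–3, λ 250–750 nm in 50 nm steps; the published sweeps do not print
their exact value lists, so these symmetric brackets around the defaults
were fixed once).  It does **not** model linker DNA, atomistic nucleosome
structure, anisotropic or absorbing material, or two-start/zig-zag fiber
topologies; passing tests therefore validate the solenoid-scale chirality
physics, not sequence- or linker-dependent effects in real chromatin.

## Numerical choices and scale

Tests and the acceptance script run at 16–24 dipoles per longest dimension
(≈ 0.5–2.5·10³ dipoles) with an 8×8×4 (or smaller) orientation quadrature;
these sizes were chosen as the coarsest at which every symmetry statement
is still machine-exact and the Mie error is quantified (Q_ext error 6.3% at
8 dipoles/diameter, 0.9% at 32).  Production-scale runs (60 dipoles per
longest dimension) are supported and used in example 01.  Ties at solid
boundaries count as inside; voxelization, sweeps and writers are fully
deterministic (bit-identical tables on rerun).  The `seed` field of
`SweepConfig` is reserved: nothing in the pipeline is stochastic.

## Known limitations

* CIDS magnitudes at these fiber sizes are a few 10⁻³ — detectable in
  principle but near the floor of practical CIDS instruments.
* The measured fixed-orientation CIDS of the R+L stack (~4–5·10⁻³,
  resolution-stable) is non-zero but smaller than a 10⁻² magnitude
  sometimes quoted for such composites; the contrast against the averaged
  signal (~10⁻¹⁷) is what the physics guarantees.
* With the default radial cylinder orientation, the cylindrical-nucleosome
  solenoid shows a slightly *stronger* fixed-orientation CIDS than the
  spherical-nucleosome one (5.5·10⁻³ vs 4.7·10⁻³ at 48 dipoles/longest),
  while the sphere variant robustly has the higher extinction efficiency;
  the sphere-vs-cylinder CIDS ordering depends on the (under-specified)
  cylinder orientation convention and should not be treated as a robust
  signature.
* Single scattering (Born mode) of isotropic per-site polarizabilities
  gives exactly zero CIDS for *any* geometry here, not only spheres; the
  chiral signal in this model exists purely through inter-dipole coupling.
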