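# Methods and conventions

## System model

The package analyzes micelles of sequence-defined amphiphilic peptoid
block copolymers: 25-mer chains of N-decyl (DEC), N-methoxyethyl (MOE)
and N-(2-carboxyethyl) (COE) residues, with a 5-residue DEC block that
aggregates into a hydrophobic core and a 20-residue hydrophilic corona
carrying one or three deprotonated carboxylates, each neutralized by a
Na⁺ counterion. Configurations are held in an `AtomSet` (coordinates in
nm, masses in amu, per-atom element, chain id, residue and role labels);
a `MicelleSystem` adds the frame sequence and chain architecture.
Internally all lengths are nm (PDB input in Å is converted on read)
because every distance convention in the analyses is stated in nm.

Atom roles (`backbone`, `sidechain`, `carboxylate_carbon`,
`carboxylate_oxygen`, `water_oxygen`, `water_hydrogen`, `sodium`) are
inferred from the (residue, atom-name) table in
`micellometrics.chemistry.ROLE_TABLE`; the table is an explicit dict and
can be overridden per call, since residue naming varies across file
dialects. Periodic geometry supports orthorhombic boxes only (the
studied systems are cubic); triclinic cells are out of scope.

## Gyration-tensor descriptors

The "inertia tensor" used for micelle characterization is implemented
as the gyration (second-moment) tensor, not the physics
moment-of-inertia tensor: only for the former does the identity
R_g² = λ₁ + λ₂ + λ₃ hold, which the analysis relies on. Weights are
atomic masses, or coherent neutron scattering lengths for the
SANS-comparable R_gb. Negative ¹H scattering lengths are allowed as
signed weights; a warning is emitted if the selection's net scattering
length falls below 1 fm, where the weighted center becomes
ill-conditioned.

Asphericity and shape parameter are evaluated in elementary-symmetric
form,

    b = 1 − 3 e₂/e₁²,     S = 27 e₃/e₁³ − 9 e₂/e₁² + 2,

with e₁ = Σλ, e₂ = λ₁λ₂ + λ₂λ₃ + λ₃λ₁, e₃ = λ₁λ₂λ₃. This is
algebraically identical to the usual product form
27·Π(λᵢ − λ̄)/e₁³ but returns the ideal limits exactly in floating
point: S = −0.25 at (1, 1, 0) (perfect oblate), S = 2 and b = 1 at
(1, 0, 0) (perfect prolate), b = S = 0 at (1, 1, 1). Outputs are
clamped to the mathematical ranges [0, 1] and [−0.25, 2] to absorb
last-ulp excursions at degenerate spectra. Eigenvalues are sorted
descending with a stable sort; ratios λ₂/λ₁, λ₃/λ₁ are computed after
sorting.

Before any tensor is built, frames are made whole across periodic
boundaries: atoms within a chain are chained by minimum image from the
chain's first atom, chains are shifted as rigid units into the image
nearest the first chain, and solvent/ion molecules are moved to the
image nearest the micelle's center of mass. A wrapped micelle would
otherwise produce meaningless second moments.

The hydration-shell variant of R_g augments the selection with every
water molecule whose **oxygen** lies within 0.35 nm (strict `<`) of any
solute atom — the first minimum of the water oxygen–oxygen RDF, the
standard solvation-shell distance. Whole molecules are included (the
oxygen decides, the hydrogens follow), since fragmenting molecules
would corrupt mass weighting; a flag restricts the augmented set to
oxygens only, and another restricts the solute side of the distance
test to heavy atoms. Both choices are exposed because the underlying
convention ("within 0.35 nm of the surfactants") is ambiguous about
hydrogens.

## Solvent-accessible surface area

Shrake–Rupley point counting, implemented exactly as described: each
atom's van der Waals sphere is expanded by the probe radius (default
0.14 nm, a water-sized probe), covered with a deterministic
golden-spiral lattice of test points (default 960; no RNG, so results
are bit-reproducible), and a point is accessible iff it lies outside
every other expanded sphere; the atom contributes its accessible
fraction × 4π(r_vdW + r_probe)². Van der Waals radii default to the
Bondi set and are user-overridable — SASA values are only comparable
for a stated radius set, and different toolchains ship different
defaults. Water and ions are excluded from the solute by selection
(the area of interest is the micelle's exposure to solvent); all atoms
of the selection, including any hydrogens, carry table radii. Periodic
images are ignored: the micelle is assumed whole and far from its
images, valid for the dilute study systems whose boxes exceed the
micelle diameter several-fold. Rotational invariance is limited by the
discrete point set (≈0.1% at 960–1920 points on dense clusters);
doubling the point count is the convergence check.

For cross-system comparison, `sasa_rg_ratio_table` reports
SASA_ref/SASA_sys next to R_g,ref²/R_g,sys² with the reference system in
the numerator; for near-spherical aggregates the two ratios agree
(sphere area ∝ R_g²), and their difference is a sphericity diagnostic.

## Scattering

Partial RDFs use exact chunked pair-distance histogramming with
minimum-image distances and uniform half-open bins — not a cell list —
because analyzed selections are small once water is excluded and the
test contract is bin-exact equality with an exhaustive oracle. The
ideal-gas normalization uses the box volume, or an explicit volume for
isolated selections. `r_max` may not exceed half the smallest box edge.

The neutron-weighted total follows the Faber–Ziman convention

    g(r) = Σ_αβ c_α c_β b_α b_β g_αβ(r) / (Σ_α c_α b_α)²,

with coherent scattering lengths from the standard Sears tabulation;
hydrogens carry the ¹H value by default (simulated solvent is H₂O even
when experiments use D₂O), and `ScatteringLengthTable.deuterated()`
substitutes D for exchangeable/solvent hydrogens to make the
convention explicit rather than silently mismatched. The structure
factor is the isotropic Fourier transform

    S(Q) = 1 + 4πρ ∫₀^rmax r² (g(r) − 1) sinc(Qr) W(r) dr,

evaluated by bin-midpoint quadrature, with sinc → 1 as Qr → 0 by the
series limit. W is a Lorch window by default to damp truncation
ringing; for Guinier work on an isolated particle, the raw window with
r_max covering the full particle diameter is preferred (no truncation
exists to damp, and the Lorch window broadens the low-Q decay). Q is
reported in Å⁻¹, the axis convention of scattering practice; r and
densities are nm-based internally.

Guinier analysis fits ln S against Q² by least squares over
Q ≤ Q_max (default 0.1 Å⁻¹, the conventional low-Q window) and returns
R_g = √(−3·slope); it refuses non-decaying input. Two numerical
caveats, verified by the sphere cross-check in the test suite: the
(g − 1) background term scales with the normalization density, so a
dilute normalization volume (box edge ≫ particle) should be used for
single-particle work, and the fit window should keep Q·R_g ≲ 1.3 or
the higher-order form-factor terms bias R_g low. Under those
conditions the Guinier estimate of a uniform solid sphere agrees with
the direct tensor R_g to better than 1%; the acceptance tolerance is
5%. Micelle-only selections (water excluded, Na⁺ excluded by default)
are the experimental comparison convention.

## Ionic structure

All cutoff tests are strict `<` uniformly (distances are continuous, so
the boundary has measure zero; the convention is stated because printed
tables are ambiguous between `<` and `≤`). Defaults: 0.35 nm for Na⁺
and water coordination of carboxylates and for counterion condensation
(first RDF minima), 0.5 nm for the salt-bridge shell.

Coordination is group-level: one COO⁻ group counts the distinct
partners within the cutoff of **either** oxygen, pooled over
(group, frame) pairs. The nearest-neighbor statistic records, for every
carboxylate carbon and frame, the distance to the closest carboxylate
carbon on a **different** chain. A sodium bridges a qualifying
(carbon, nearest interchain carbon) record if it lies within 0.5 nm of
both carboxylate groups — referenced to the carbons by default, with an
oxygen-based variant behind a flag, since "within 0.5 nm of both
carboxylate groups" is ambiguous and the surrounding nearest-neighbor
analysis is carbon-based. Bridge fractions are computed on the records
below 0.5 nm and below 1.0 nm separately; because these are different
qualifying sets, the 0.5 nm fraction routinely exceeds the 1.0 nm one
and no ordering between them is assumed. Fractions pool all frames
before dividing (matching how the distributions aggregate), rather than
averaging per-frame fractions. KDE smoothing (Scott's rule,
overridable) is applied to presentation densities only; raw histograms
are always emitted alongside.

## Synthetic generator

The generator emulates the equilibrium morphology the analyses target —
compact DEC core, MOE/COE corona with carboxylates oriented toward the
outer surface, counterions, hydration shell — with planted, exactly
known structure. It is placement, not physics: no force field, no
dynamics, no self-assembly. Defaults describe the largest singly
charged study system (28 chains, single terminal carboxylate);
`preset_spec("chain1")`–`"chain8"` carry the aggregation numbers
(28, 25, 23, 18, 13, 18, 17, 12) and published water counts of the
eight-system series. Charge positions for the presets whose sequences
are published only graphically are approximate placements consistent
with the described trend (charges moving from the chain terminus toward
the core junction) and are taken as explicit input everywhere.

Geometry: chain directions on a golden-spiral lattice (rotated
per-seed); backbone beads follow a helical path around each chain's
radial direction so consecutive beads keep ~0.2–0.3 nm spacing even
though the corona is thinner than the chain contour length; side-chain
beads alternate sides of the path; COE residues bulge to ≥80% of the
corona thickness so carboxylates sit near the outer surface. Beads are
one per heavy group with correct formula masses; the carboxylate is
resolved into an explicit carbon and two oxygens because the ionic
statistics key on those distances; water is a rigid 3-site molecule
(the shell rule keys on the oxygen, mass weighting needs the
hydrogens). A 0.25 nm hard floor between non-bonded beads is enforced
by bounded rejection/jitter (waters and ions are rejection-sampled
against it; residual chain–chain contacts are jittered apart), which
prevents pathological SASA and RDF artifacts; packing that cannot
satisfy the floor raises after bounded retries.

Planting: of the one-Na⁺-per-carboxylate total, `round(f·N)` ions are
placed 0.28 nm from a carboxylate oxygen (inside the 0.35 nm
condensation shell) and the remainder uniformly in the hydration-shell
region at ≥0.45 nm from every carboxylate oxygen, so the detector
recovers the planted fraction to ±1 ion. Each planted salt bridge
relocates two carboxylate groups from different chains to a shared
surface site 0.45 nm apart with a sodium 0.416 nm from both carbons —
inside the 0.5 nm bridge shell — while both groups point their oxygens
away from the ion (Na–O > 0.5 nm), so a planted bridge never counts as
a condensed ion and the two plantings are independent. Frames beyond
the first add Gaussian jitter (default σ = 0.01 nm), small against all
planting margins. Everything is reproducible byte-for-byte from the
seed.

What the generator does **not** emulate: realistic chain conformational
entropy, water structure beyond excluded volume, electrostatics, or any
trajectory-dependent observable. Passing tests therefore validate the
*analysis machinery* — detectors recover planted truth, descriptors
match closed forms — not the physics of real micelles; headline
trajectory numbers (R_g distributions, absolute SASA, published bridge
percentages) require long all-atom MD and are explicitly out of the
package's validation surface.

Ideal bodies (uniform ball, rod, disk, ellipsoid) provide Monte-Carlo
fixtures with closed-form descriptors: a uniform ball has
R_g/R = √(3/5) ≈ 0.7746 — the 0.775 factor relating R_g to the
hydrodynamic radius of a perfect sphere — a rod has λ₂/λ₁ → 0, a disk
attains the perfect-oblate values (b = 0.25, S = −0.25).

## Reporting and uncertainty

Frames of one trajectory are correlated, so standard errors use block
averaging: the series is split into `n_blocks` (default 10) contiguous
blocks and SE = std(block means)/√n_blocks. All statistics are computed
on raw per-frame values; KDE (1D and 2D) is a presentation transform.
The 2D joint density reports local maxima above 5% of the global peak
to expose bimodal populations. Pipeline outputs (CSV/JSON plus a
manifest recording versions, seed, cutoffs and stages) are
deterministic for a fixed config; timings go to the log so reruns are
byte-identical.

## File formats

PDB and GRO, single- and multi-frame, parsed and written through
MDAnalysis. Chains ride in the PDB segment-id column (`C000`, ...);
GRO has no chain field, so per-chain residue numbering restarts at 1
and chain boundaries are recovered from the resets, with water and
sodium (identified by residue name) assigned to the solvent. Multi-frame
GRO files are concatenated single-frame blocks, split on each block's
atom-count header. Coordinate round-trips are exact to the formats'
fixed-point precision (0.001 nm for GRO, 0.001 Å for PDB). Residue
indexing is 0-based internally and 1-based in files and user-facing
reports.

## Problem sizes

Test fixtures and the benchmark script are sized for a single CPU:
Monte-Carlo bodies use 10⁴–10⁵ points, oracle-equivalence fixtures stay
at or below a few hundred atoms so exhaustive O(n²) scans are exact and
fast, and generated micelles for end-to-end checks use 4–10 chains with
a 0.25–0.35 nm hydration shell. These sizes are the package's own
validation choices; all analysis code paths are identical at larger
sizes.
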