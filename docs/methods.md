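# Methods

`mandiflex` compares the mechanical environment of a mandible during
simulated unilateral chewing in four states — healthy, fractured at the
left angle, fracture repaired with a single superior miniplate (Champy
technique) and repaired with superior plus inferior lateral plates
(biplanar technique) — and reports the quantities that matter for fracture
healing: free-body moments along the jaw, interfragmentary strain (IFS)
across the fracture plane, and cortical bone strain around the
bone-implant interface and across the whole surface.

Everything runs on a synthetic, parametric mandible surrogate.  The point
of the surrogate is to carry the same load paths and topology as a
mandible, not its anatomy: conclusions about strain or moment *magnitudes*
do not transfer to real jaws, but orderings across fixation states and
chew sides exercise the same mechanics that anatomical models do.

## The surrogate geometry

A swept, thickened U-arch (horseshoe): two straight posterior corpus
segments joined by a semicircular anterior arch, rectangular cross-section
`corpus_width x corpus_height`; vertical ramus boxes on the posterior
ends, each topped by a narrower condylar knob whose superior face defines
the condylar (x = 0) plane; a tooth layer along the superior corpus
border.  The global frame follows the convention used for comparative
masticatory models: origin midway between the condyles, x
superior-inferior (up positive), y anterior-posterior (anterior positive),
z mediolateral (left positive).  Units: mm, N, MPa (so E = 17 GPa is
stored as 17000 MPa); moments are reported in N m.

Default dimensions approximate an adult human mandible: length 113.5 mm
(anterior-most point to the condylar plane), inter-condylar span about
96 mm (arch radius 48 mm), corpus 24 mm tall and 11 mm wide, ramus 40 mm
tall and 33 mm deep, condylar knobs 8 mm, cortical shell 2.5 mm around a
trabecular core, teeth 8 mm tall.  Tooth landmarks (P3 … M3) sit at fixed
y-stations on the straight segments.  All lengths scale together through
`GeometryParams.scaled`, which the isometric-scaling tests rely on.

Meshing: structured hexahedral lattices per block, merged on coincident
nodes, each hex split into 12 tetrahedra about its centroid with the face
diagonal through the lowest global node index.  The face rule depends only
on the shared face's node ids, so any two blocks triangulate a shared face
identically and the union is conforming without remeshing.  The default
`target_edge_length` is 3 mm — a desk-scale compromise (the anatomical
reference discretisation of 1 mm is reachable by configuration but
multiplies runtime by roughly two orders of magnitude).

The fracture is an element-face cut: elements are assigned to fragments by
the side of their centroid relative to an oblique plane (restricted to
z > arch_radius/3, i.e. the left side), interface nodes are duplicated in
place, and the paired triangulated surfaces start with exactly zero gap.
The default plane runs from the inferior border of the posterior corpus
antero-superiorly to the retromolar region at the superior corpus border —
the classic angle-fracture path through the third-molar region.  Tooth
elements always follow the fragment that holds their socket.  A zero-gap
cut was chosen over remeshing a finite gap because it gives an exact
reference state for IFS; the price is that the raw IFS denominator
vanishes (see below).

Plates are thin boxes lying on the lateral (buccal) surface, anchored on
the fracture trace at their own height so two screw positions fall in each
fragment: the Champy plate (24 x 4 x 1 mm) just below the superior corpus
border, the inferior plate (26.1 x 2.5 x 1 mm) along the inferior border.
Screws are square prisms through the plate into the bone, tied
(master-slave DOF merging) to the plate above and to the nearest bone
nodes of *their own* fragment below — a locking-screw idealisation; a
screw never bridges the fracture.  The plate-bone facing surfaces are
registered as frictional contact interfaces, like the fracture itself.
Exact plate hole geometry and screw lengths are not anatomical constants
of this model; they are configuration with stated defaults.

## Loading and constraints

Muscle forces follow the PCSA model: maximum force = physiological
cross-sectional area (cm²) x specific tension (30 N/cm²), scaled by the
activation fraction recorded during unilateral chewing, directed from the
mandibular insertion centroid to the cranial origin centroid.  The
canonical human loads, however, are consumed directly as the packaged
table of ten force vectors per chew side (the PCSA/activation inputs
behind them are not part of this package's data); the constructive path is
used for synthetic inputs and property tests.  Each vector is distributed
uniformly over its attachment patch, which makes the patch resultant act
exactly at the patch centroid for moment purposes.

Constraints reproduce unilateral post-canine chewing: working-side condyle
and bite points (P3, P4, M1) fixed against translation in all directions;
balancing-side condyle fixed superior-inferiorly and antero-posteriorly
but free mediolaterally.  A `vertical_bite` variant fixes bite points in x
only.  Bite force is an output: the resultant constraint reaction at the
bite nodes (the force on the food item is its negative).

## Solver

Linear small-strain elasticity on 4-node tetrahedra, isotropic
homogeneous materials per region (cortical 17 GPa / 0.3, teeth 24.5 GPa /
0.3, trabecular 10 GPa / 0.3, titanium implant 105 GPa / 0.36).  Ties
merge slave DOFs into masters (exact for the conforming interfaces the
generator produces; the small master-slave offsets at screw-bone ties act
as rigid links).  Dirichlet constraints are eliminated; the reduced system
is solved by sparse LU; reactions are the residual K u − f at constrained
DOFs.  Verification: exact linear patch test per material, six rigid-body
modes in the unconstrained null space, global equilibrium to 1e-6
relative, tip-loaded cantilever within 15% of the Euler-Bernoulli
deflection at the documented h = 0.8 mm refinement with monotone
convergence, and agreement with a dense direct solve to 1e-9 on small
meshes.

## Contact

Node-to-node penalty contact on the conforming duplicated surfaces, with
a single normal per interface (the fracture plane normal, or the plate's
outward surface normal).  Normal penalty defaults to 10 x (softest
adjacent E) x (local element size) per pair — residual penetrations of
order 1e-4 mm, i.e. effectively hard contact at the 3 mm element scale.  A
100x stiffer penalty was tried and rejected: edge pairs carrying ~100 N
then chatter between open and closed without converging.  The tangential
penalty is k_n/100, of the order of the material stiffness, so stick
compliance stays at the element scale while the friction update remains
contractive.

Coulomb friction (mu = 0.3 at every interface) uses an elastoplastic
return mapping: tangential traction k_t (delta_t − p) with the slip anchor
p pulled back onto the cone each iteration; the p-update fixed point is
accelerated by Irons-Tuck (Aitken) relaxation, reset whenever the open set
changes.  The stiffness matrix depends only on the open set, so the LU
factorisation is cached across iterations that merely update anchors.
Convergence requires a stable open set, a relative displacement increment
below 1e-6, penetration within g_tol (1e-3 mm) and a Coulomb-cone residual
below 1e-4 of the peak normal force; pairs that toggle between stick and
slip exactly on the cone are accepted as converged either way.  The
worst-conditioned scenario (Champy fixation, contralateral chew — the
floppiest construct) needs roughly 170 iterations; everything else
converges in well under 100.

## Free-body moments

Thirty equidistant coronal sections per hemimandible (sagittal sections
for the symphysis).  Moments anterior to a section are taken about the
volume-weighted centroid of the cut cross-section and computed from the
external loads on the anterior free body — muscle patch loads and
constraint reactions — rather than by integrating element internal
forces; the two are statically equivalent, and the test suite enforces
that anterior moments equal minus posterior moments to 1e-6 relative.
Membership of a load group in the free body is decided by its centroid:
for a left-hemimandible section, everything except left-side loads
posterior to the plane (the right side stays attached through the
symphysis); loads exactly on the plane count as anterior.  The
decomposition columns Fx·dz and Fz·dx are accumulated per load point, so
My = Fx·dz − Fz·dx holds row-wise identically and the summed row equals
the column sums.

## Strain metrics

Bone-implant interface region: cortical surface nodes bounded by the
superior edge of the oblique plate (max x), the M2 landmark (max y) and
the lingual surface (min z), excluding nodes on bone-screw and bone-plate
contact surfaces; medians of nodal-averaged principal strains e1 and e3
and occupancy of the half-open bins [200, 300), [300, 1000), [1000, 5000)
microstrain.

IFS per fracture pair: (deformed − undeformed distance)/undeformed
distance.  On this surrogate the undeformed pair distance is exactly zero,
so zero-gap pairs use the signed opening along the interface normal
divided by a reference gap (default: the local mean edge length, ~2.9 mm
at default resolution).  This preserves the sign convention (widening
positive) and the orderings across scenarios but makes IFS *magnitudes*
reference-gap-scaled — they are not comparable with values measured on
meshes with a finite reduction gap.  "Average (median)" is resolved as:
the all-regions column is the median of |IFS|; the compressive and tensile
columns are signed medians within each class; means are emitted alongside.

Strain-difference fields: per-node e1_fixed − e1_healthy and |e3_fixed| −
|e3_healthy| on the biological surface, with geometric correspondence
(fracture duplicates coincide with their originals; candidates are all
biological nodes of the healthy mesh because the cut exposes faces that
are interior when healthy).

## What a green test does and does not establish

The synthetic matrix reproduces, as orderings on the default surrogate:
more interfragmentary strain under the less rigid single-plate construct
than under biplanar fixation, more under contralateral than ipsilateral
chewing, and larger deviations of moments and surface strains from the
healthy state under Champy fixation during contralateral chewing.  It
does not reproduce — and is not meant to — the magnitudes reported for
anatomical human or macaque models (bite forces, N m moment values,
microstrain levels, Table-style IFS magnitudes), which depend on real
geometry, finite fracture gaps and anatomical muscle attachments.

## Numerical choices and limitations

* Node merge tolerance 1e-6 mm (coordinates are rounded before keying),
  which is also the mirror-symmetry tolerance of the healthy surrogate.
* Sections use a 0.75-slab volume-weighted centroid; landmark names map
  to the nearest section index.
* Nearest-node pairing ties break toward the lowest node index; pairing
  is computed once on the undeformed mesh and frozen.
* The generator takes an `rng_seed` for provenance, but the default
  construction is fully deterministic; no stage of the default pipeline is
  stochastic.
* Not modelled: periodontal ligament, geometric nonlinearity, plate
  pre-bending/contouring, screw threads or loosening, large sliding,
  remodelling.
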