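# Methods

## Model

The head is a rectilinear 90 × 150 × 150 mm³ volume.  Coordinates: `z` is
depth from the outer scalp surface (+z into the head), `y` is the optode
axis and the long axis of the sulcal grey-matter prism, `x` its width axis.
Five horizontal slabs (scalp 6, skull 8, CSF 4, superficial grey matter 10,
white matter 62 mm) partition the depth; a 10 mm (x) × 100 mm (y) prism
centred laterally carries sulcal deep grey matter in four depth bands,
DGM1–4 at 28–38, 38–48, 48–58 and 58–90 mm.  All regions are axis-aligned
boxes, so the geometry is represented by continuous region functions with
half-open `[low, high)` bands (lower bound inclusive) — exact and faster
than a voxel grid for this model; a 1 mm voxel export
(`HeadModel.voxelize`) exists for visual checks only.  The DGM bands carry
grey-matter optics unless overridden.

Single-wavelength (630 nm) optical properties per region are the package
defaults (`default_optical_properties`); the white-matter slab is 62 mm so
the slabs sum to the 90 mm volume depth, and every thickness is
configurable (`HeadModelConfig`).

## Transport

Packet transport uses the convention shared by the standard voxel/layer
Monte Carlo codes for tissue optics:

* **Stepping.** A dimensionless scattering length `s = −ln ξ` is consumed
  as `Σ μs·ℓ` across region segments.  Segments are found by walking the
  global set of region boundary planes with exact box intersections; the
  near-transparent CSF (μs = 0.009 mm⁻¹) therefore traverses many regions
  within one scattering length without any step-size cap.
* **Absorption.** Weight attenuates continuously: the exit weight is
  `exp(−Σ_r μa_r L_r)` computed from per-region partial path lengths.
  Because step sampling never consults μa, a packet's trajectory — hence
  its partial paths — is *exactly* invariant under absorption changes.
  This licenses common-random-number reweighting (below).  There is no
  Russian roulette and no weight cutoff; packets end only by leaving the
  volume or by exceeding the maximum total path (default 5000 mm).
* **Scattering.** Henyey–Greenstein polar angle by inverse CDF, uniform
  azimuth, MCML-style frame rotation with a pole guard at |uz| > 0.99999.
* **Boundaries.** Unpolarized Fresnel reflection (with total internal
  reflection) at the top tissue–air face; absorbing lateral and bottom
  faces.  Internal index mismatches are not modelled (all tissues share
  n = 1.37).  Packets launch just inside the tissue with weight 1 — source
  coupling and specular loss are not modelled; the constant factor cancels
  in every relative metric.
* **Detection.** A packet is detected iff it transmits through the top face
  with its exit point inside the detector disk; all exit angles are
  accepted (no numerical aperture).
* **Randomness.** Counter-style splitmix64 substreams keyed by
  `(seed, packet index)`: results are bit-reproducible and independent of
  execution order; seeds are recorded in every result.

The weight ledger — launched = top + bottom + lateral exits + absorbed +
terminated residual — closes to ~1e−15 relative and is asserted at 1e−6 in
the tests.

## Metrics and estimators

**Detected energy** is the sum of detected exit weights; full-scale
equivalents divide by the packet-count scale (full scale launches
`5·10⁷ · d²` packets per emitter of diameter `d` mm, i.e. a constant count
per unit emitter area).

**Sensitivity** to a region's absorption is the percent change of detected
energy when μa is scaled (the campaigns use factors 1.00–1.25 in 0.05
steps; +25% of grey matter's 0.020 mm⁻¹ is Δμa = 0.005).  It is evaluated
by reweighting the detected set, `E' = Σ w_i exp(−Δμa L_i)`, which equals a
same-seed rerun with the scaled model to 1e−12 relative (asserted in the
tests); this removes all common Monte Carlo noise from the difference.

**GSPR** divides the summed detected-packet partial path in superficial
grey matter by that in scalp.  Path sums are *unweighted* over detected
packets, matching the detected-photon partial-path outputs the definition
consumes (APPL × number of traversing packets per layer); the weighted
variant was examined and is an order of magnitude smaller at 30 mm, so the
two readings are not interchangeable.

**Replicates.** Campaign cells run `replicates` times with seed
`master_seed + i` and a 1 mm positional shift of the optode pair along the
optode axis, wrapped into ±10 mm so every optode disk keeps ≥35 mm from the
lateral faces in every grid cell (including a 15 mm detector at 50 mm
separation).  Summaries report mean and sample (ddof = 1) SD.

### Desk-scale pooling with virtual detectors

Full-scale packet counts (5·10⁷ per mm² of emitter diameter²) are far
beyond a desk budget, and a 1 mm detector at 30 mm separation detects only
~1 packet per 10⁵ launched.  Desk-scale campaigns therefore record every
top-face exit and evaluate detectors *post hoc*:

* **Ring detectors** — a 1 mm-wide annulus centred on the source at the
  true separation — pool all exit azimuths.  This matters because detected
  energy decays steeply with separation: an enlarged *disk* detector
  over-weights its near edge and biases sensitivity low (measured: a 10 mm
  disk at 30 mm gives 2.1% where the true-separation ring gives 2.8%),
  whereas the ring samples the correct separation exactly.  Ring energies
  are converted to disk equivalents by area when an absolute energy is
  needed.
* **Paired disks** at ±separation along the optode axis pool the two
  placements that are exactly equivalent by the model's mirror symmetry.

The acceptance script uses 8 × 10⁵ packets for the standard (1 mm emitter)
phase and 5 × 4·10⁵ for the wide (5 mm emitter) phase — sizes chosen so the
pooled detected sets reach a few hundred to a few thousand packets and the
replicate-spread standard errors of the reported quantities are a few
percent of their values.

## Numerical choices

* Boundary stepping treats planes closer than 1e−7 mm as "standing on";
  region membership is decided at segment midpoints, making labels immune
  to landing exactly on a plane.
* Degenerate inputs: zero-diameter emitters launch at the disk centre;
  zero-thickness slabs are legal (used by the synthetic fixtures); an empty
  detection set is a valid result (zero energy) except where a ratio is
  undefined (GSPR with zero scalp path raises).
* `scale_absorption` is multiplicative and composable and touches only the
  named region's μa, preserving bit-identical trajectories.

## What the synthetic fixtures emulate

The fixtures module generates the validation media: a non-scattering slab
(Beer–Lambert, exact), an index-matched homogeneous half-space (total
diffuse reflectance), and perturbation pairs wired for the
reweighting-vs-rerun exactness check.  The half-space reference is an
independent *analog* Monte Carlo — survival sampling at each interaction
instead of continuous weighting, vectorised numpy instead of the JIT kernel
— so engine/oracle agreement is a physics check, not a code clone.  None of
these fixtures contain anatomy; passing them validates transport physics,
not anatomical realism.

## Known limitations

* **Slab anatomy.** Flat layers, rectangular sulcal prism, no curvature and
  no MRI-derived mesh; single wavelength, no chromophore spectroscopy.
* **Absolute detected energy** depends on detector-model details (angular
  acceptance, voxelisation, specular handling) that differ between
  implementations; relative metrics — percent change, GSPR, ratios across
  diameters/separations — are the robust outputs.  Our full-scale
  equivalent energy at the standard cell is ~50% above the reference
  implementation's value while all relative metrics agree closely.
* **Unweighted GSPR depends on the trajectory-length truncation.**  With
  continuous weighting, long trajectories carry negligible energy but full
  weight in unweighted path sums; the 30 mm-separation GSPR moves from
  ~0.6 at a 1100 mm cap through ~0.85 at ~1900 mm to ~1.07 at the 5000 mm
  default (sensitivity metrics are unaffected — they are weight-dominated).
  The package keeps 5000 mm as the default and reports GSPR under it; when
  comparing against results produced with a time-gated simulator, set
  `max_path` to the gate's equivalent path length (`c·t_end/n`).
* **DGM1 sensitivity estimates** at 50 mm separation rest on the smallest
  pooled detection sets in the campaign (hundreds of packets); they bound
  the effect (≲0.03%, well under 0.1%) but are not precise values.
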