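# Methods

## Model overview

`corneasim` simulates a 2D radial cross-section of the limbal and peripheral
corneal epithelium as a Glazier–Graner–Hogeweg (Cellular Potts) model coupled
to a reaction–diffusion field for epidermal growth factor (EGF).  The domain
is a 200 × 90 voxel lattice at 2 μm per voxel (400 × 180 μm); one Monte Carlo
step (MCS) corresponds to 6 minutes of biological time (240 MCS/day).

Nine agent categories occupy the lattice: four motile epithelial cell types
(limbal stem, basal, wing, superficial), a tear film, the two-zone basement
membrane (limbal and central, merged with Bowman's layer into a single
one-voxel strip), a stromal slab, and confining lateral walls.  Walls, stroma
and membrane are frozen: their voxel sets never change through Potts
dynamics.  The membrane can only be *destroyed* (converted to bare stroma) by
chemical injury; it never regenerates, which is what produces
recurrent-erosion-like dynamics after moderate exposures.

## Lattice dynamics

Cell configuration evolves by Metropolis voxel-copy attempts on the Moore
(2nd-order) neighborhood.  One MCS performs width × height attempts; a copy
is accepted when it lowers the effective energy, or with Boltzmann
probability `exp(-ΔH/T)` otherwise.  The energy has five terms:

- **contact**: per-type-pair adhesion energies summed over distinct-spin
  2nd-order neighbor pairs;
- **volume** and **surface**: quadratic penalties `λ_V (V - V_t)²` and
  `λ_S (S - S_t)²`, with the surface measured as the 4-neighbor boundary
  count;
- **links**: Hookean springs `λ_L (d - L₀)²` between centroids of nearby
  superficial cells, rebuilt each MCS (apical tension);
- **chemotaxis**: `-λ_chem (c_target - c_source)` for the extending cell,
  coupling basal cells to the EGF field (wound-directed migration).

Cell connectivity is not enforced; instead, any cell falling below 3 voxels
is culled (and logged), which both prevents orphan-pixel debris and acts as
a compression-removal pathway: post-mitotic cells are deliberately softer
(lower `λ_V` for wing and superficial cells), so crowding pressure from the
proliferative compartment gradually squeezes terminally differentiated cells
out of the tissue.  This second removal channel operates alongside
probabilistic sloughing and is essential for physiological turnover rates:
surface sloughing alone (hazard 1/720 per exposed superficial cell per MCS)
caps removal at (exposed cells)/3 per day, which cannot renew a 5–8-layer
tissue on a 1–2-week timescale.

### Tear film

The tear film is re-painted each MCS as a fixed-thickness (4-voxel ≈ 8 μm)
coat above the highest solid voxel of every column, rather than simulated as
a deformable agent.  A tear agent with its own volume constraint proved
fragile during bring-up — it could be squeezed away from wound beds, which
breaks both the tear-contact differentiation rule and the EGF source
geometry.  The repaint guarantees the "re-wetting" semantics that sloughing,
ablation and the wing→superficial rule rely on.  Tear pockets *below* the
surface (wound beds filled by reflex tearing) are left in place until cells
reclaim them; the EGF clamp inside such pockets is precisely the increased
growth-factor influx that accelerates wound healing.

## Cell behaviors

Rules run once per MCS after the Potts sweep and the field update, in the
order: growth → mitosis → differentiation → sloughing → chemical death.
Cells created in a step are not re-evaluated until the next step.

**Growth** (stem and basal cells only): the target volume grows by
`δ · G_EGF · G_density` voxels per MCS, where both factors are Hill
functions with exponent 4:

    G_EGF     = EGF⁴ / (km⁴ + EGF⁴)        km = 3.5 (stem), 7.0 (basal)
    G_density = km_d⁴ / (km_d⁴ + P⁴)       km_d = 125

EGF is the mean field concentration over the cell's voxels.  The crowding
pressure `P = max(0, λ_P (V_t - V))` uses the volume deficit as a
mechanical proxy: a compressed cell cannot reach its target volume, so a
persistent deficit signals crowding and stalls further growth.  `δ = 25/80`
voxels/MCS, so a fully stimulated, uncrowded cell doubles its 25-voxel
volume in 80 MCS = 8 h, the optimal-cycle calibration.

**Mitosis** triggers when a cell's actual volume reaches 50 voxels.  The
cleavage plane passes through the centroid: stem cells split along the
radial (x) axis so one daughter lies centripetally; basal cells use a
uniformly random plane orientation.  Voxels are partitioned by signed
distance to the plane with a stable sort, so daughter volumes differ by at
most one voxel.  Both halves restart at a 25-voxel target and count as
renewed cells (birth time and position reset).

**Differentiation** is deterministic, immediate, and strictly forward:

- stem → basal when no limbal-membrane voxel remains in the cell's
  2nd-order neighborhood;
- basal → wing when the membrane contact area (8-neighbor voxel contacts
  with either membrane zone) falls to ≤ 5;
- wing → superficial when the cell touches the tear film and has no
  remaining contact with basal cells, stem cells, or the central membrane.

Contact areas are counted on the same 2nd-order neighborhood as the contact
energy.  With 1st-order counting, a newly divided 5-voxel-wide basal cell
would sit exactly at the ω = 5 boundary and the basal layer would be
unstable; the 2nd-order count places a 5-wide cell safely above threshold.

On differentiation a cell adopts its type's target volume.  Proliferative
cells are 25 voxels (100 μm²); wing and superficial cells condense to 18
and 10 voxels respectively.  These are calibrated constants: they flatten
the differentiated compartments and populate the superficial layer densely
enough that the fixed sloughing hazard sustains a 1–2-week renewal.

**Sloughing**: each superficial cell in contact with the tear film is
removed with probability 1/(3 × 240) = 1/720 per MCS (mean exposed lifetime
3 days); its voxels become tear film.  Unexposed superficial cells never
slough.

**Chemical death**: a cell whose mean toxicant concentration exceeds the
death threshold is marked dying; its target volume then decreases by 1
voxel/MCS until zero, at which point it is removed and its voxels become
tear (the wound is re-wetted).

## EGF field

The EGF concentration obeys

    ∂c/∂t = D(x, y) ∇²c − kd·c + sources

with cell-type-dependent diffusivity: D = 186 voxel²/MCS globally, 20
through superficial cells (tight-junction barrier) and the central
membrane, 0 through the limbal membrane; kd = 0.5 per MCS.  The tear film
is a Dirichlet source; lateral walls are no-flux; the top and bottom
lattice rows hold zero concentration.  Interface diffusivities use
harmonic means, which conserves flux across material boundaries.

Concentrations are in arbitrary units on the same scale as the half-max
constants km = 3.5/7.0.  The tear source concentration is a calibrated
constant (default 110): it sets how strongly the barrier gates
proliferation and thereby the homeostatic thickness.  (A source of 1.0 —
i.e. "normalized" units — would put the field two orders of magnitude below
the half-max constants and freeze all proliferation; display normalization
and model units are distinct.)

Two integrators are provided.  The reference scheme is forward-time
central-space with `n_sub = ceil(4·D_max·dt) + 1` substeps (`dt` in MCS,
unit voxel spacing), unconditionally within its stability bound at any
diffusivity, with decay applied as an exact exponential factor per substep.
The production scheme is an alternating-direction implicit (ADI) split:
per substep, backward-Euler tridiagonal solves in x then y (M-matrices, so
unconditionally stable and positivity-preserving), alternating sweep order
between substeps, with Strang-symmetrized exact decay and Dirichlet voxels
held as identity rows.  At the default 48 substeps/MCS it agrees with the
FTCS reference to better than 0.5% on tissue-like diffusivity maps (tested)
at roughly 1/50 of the cost.  A field update that produces concentrations
below −10⁻⁹ aborts with a solver-instability error rather than clipping;
only strict round-off (> −10⁻⁹) is scrubbed to zero.

The toxicant is a second scalar species on the same solver (uniform D = 12
within tear and tissue, zero through walls and air, kd = 0.02 — calibrated
so the three reference doses produce the three lesion depth classes).  A
movement-bias field slot exists in the engine and configuration but is
inactive by default; basal chemotaxis along EGF gradients provides
wound-directed migration.

## Initial state and scenario structure

Day 0 contains the frozen substrate (walls, stroma, membrane strip with the
limbal zone spanning x < 80 μm), stem cells tiling the limbal membrane,
basal cells tiling the central membrane, the tear film, and a zero EGF
field with the tear source active.  A stem-only start (no seeded basal
population) is available via `geometry.seed_basal: false`; it produces the
same homeostatic state but takes roughly twice as long to reach it, as the
whole tissue must first be populated by centripetal migration from the
limbus.

Injuries are configured declaratively: circular ablation (cells inside the
circle replaced by tear film, with an explicit flag for membrane-depth
wounds) or chemical exposure (the dose, in arbitrary units, is interpreted
as the integrated deposit, laid into the tear film with a Gaussian
(σ = 25 voxels) or uniform surface profile).  Calibrated thresholds — cell
death at 0.6, membrane destruction at 0.10 concentration units — map the
three reference doses (750/1500/2500) onto the three depth classes:
superficial loss, deeper epithelial loss with intact membrane, and
membrane-destroying injury.

## Measurements

- **COM thickness**: (mean y of superficial voxels − mean y of basal+stem
  voxels) × 2 μm, restricted to the central x-window (x ≥ 40% of width,
  excluding the limbal wedge).  Undefined (NaN) while a layer is missing.
- **Segment tops**: the x-axis is split into 10 equal bins; each reports
  the mean height of the topmost epithelial voxel per column.  The pooled
  uniformity statistic is the root-mean of per-bin temporal variances, so
  the persistent limbal-central gradient does not inflate it.
- **Stratification detector**: all four epithelial types present with at
  least ~3 cells' worth of voxels each, with mean depths ordered
  (stem/basal below wing below superficial).  The population floor keeps a
  single transiently differentiated cell from counting as a formed layer.
- **Stability detector**: total epithelial cell count and COM thickness
  within ±10% of their 3-day trailing means for three consecutive days.
  The total count is used rather than per-type counts because the stem
  pool is ~10 cells, where a 10% band would be less than one cell.
- **Turnover**: live epithelial cell ids are recorded per region (limbal:
  centroid x < 80 μm) at a reference time; the substitution fraction is
  the fraction of those ids no longer alive (ids are never reused, so this
  is monotone).  Turnover time is the first day at ≥ 95% ("nearly
  complete", operationalized; configurable).
- **Transit**: for each sloughed cell, lifetime (birth or last division to
  sloughing) divided by layers traversed, where layers are the vertical
  centroid climb in units of one initial cell diameter (5 voxels = 10 μm).
  Layer counts are anatomical — a 4-layer peripheral crossing vs an
  8-layer limbal crossing — not type-transition counts, which saturate
  at four.
- **Healing**: wound-open fraction is the fraction of surface columns whose
  topmost epithelial voxel is not superficial.  Healing time is the first
  post-injury day with full superficial coverage *and* COM thickness within
  ±10% of its pre-injury 3-day mean, searched from the acute damage trough
  (first 3 days post-exposure).  A post-closure return of surface breakdown
  counts as a recurrence.

## Problem sizes used

Homeostasis analyses run a single default-seed trajectory for 38–40
simulated days with turnover tracked from day 20 and the stable measurement
window at days 20–30 (the long-horizon stability of the model is covered by
the windowed statistics rather than a six-month trajectory).  The injury
panel runs two tissue replicates per dose from a day-16 homeostatic state
(7 post-injury days for the two healing doses, 20 for the
membrane-destroying dose), plus a five-stream dose-ordering check on a
shared young tissue.  One simulated day costs about 4 s on one CPU core.

## Known limitations

- Peripheral turnover stabilizes near 15–18 days, slower than the ~7-day
  peripheral renewal reported for the tissue this model describes.  With
  the fixed sloughing hazard, removal capacity is bounded by
  (exposed superficial cells)/3 per day; holding the ~50 μm homeostatic
  thickness fixes the standing population, and the two constraints jointly
  bound the whole-population renewal below the 7-day figure.  The limbal
  region (thicker, but exporting cells centripetally) does reach its
  ~2-week renewal window.
- The basement membrane cannot regenerate, and stromal/immune dynamics are
  absent; moderate-injury outcomes therefore describe the isolated
  consequence of membrane loss.
- The 2D cross-section exaggerates crowding relative to 3D tissue; contact
  energies and coupling constants are phenomenological calibrations, not
  measured mechanical quantities.
- Wing cells have no injury-responsive proliferation; re-epithelialization
  is carried entirely by basal/stem proliferation and migration.
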