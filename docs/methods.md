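# Methods

`tumorflux` couples three scales: an intracellular flux-balance model that
fixes what each metabolic phenotype exchanges with its surroundings, a
cell-scale Monod growth law parameterized by those exchange rates, and a
tissue-scale agent-based simulation in which metabolites diffuse, are
consumed or produced by the resident cells, and in turn limit growth.
This note records the model structure, the calibration, the numerical
choices, and what the synthetic study conditions do and do not probe.

## The reduced metabolic network

The network is a 19-reaction, 14-metabolite effective model of central
carbon metabolism: glucose import, two lumped glycolysis segments
(hexose + 2 ATP -> 2 triose-P; triose-P -> pyruvate + 2 ATP + NADH), the
pyruvate branch point (lactate dehydrogenase, reversible, vs.
mitochondrial import), a lumped pyruvate-oxidation reaction
(PDH + TCA + OXPHOS), cytosolic NADH oxidation via shuttles, anaplerosis
(pyruvate -> alpha-ketoglutarate), glutaminolysis (glutamine ->
alpha-ketoglutarate + NADH), alpha-ketoglutarate oxidation, a
three-precursor biomass template, and a fixed ATP maintenance drain
(5 mmol ATP/g-DW-hr for every cell type).  The biomass template carries
the standard mammalian mass fractions — amino-acid precursors 0.78,
nucleotide precursors 0.06, lipid precursors 0.16 g per g-DW — which the
builder validates to sum to 1.00.

Lumped stoichiometric coefficients are *effective* parameters, calibrated
rather than derived reaction-by-reaction.  The calibration is pinned by
two energetic anchors plus the phenotype rate table:

* the maintenance drain must account for 73% of total ATP consumption for
  the WN = 0 tumor phenotype growing at 0.018 hr^-1, which fixes the
  biomass ATP cost at 102.740 mmol ATP/g-DW;
* with maintenance set to zero the biomass yield on glucose must be
  0.0984 g-DW/mmol, which fixes the combination of precursor and redox
  demands, given an effective aerobic yield of 20 ATP per glucose
  (2 substrate-level + 2 x 2.3 per cytosolic NADH + 2 x 6.7 per pyruvate).

The remaining freedom (hexose 2.072, alpha-ketoglutarate 6.72 and NADH
6.106 mmol/g-DW in the template; glutaminolysis NADH 3.0; AKG oxidation
2.98 O2 -> 6.63 ATP) was fit once against the eighteen phenotype rows so
that every exchange rate with magnitude >= 1e-3 g/g-DW-hr is reproduced
within 5% (achieved: <= 3.9%).  Three printed rates (3.2e-7, 3.73e-7 and
1.55e-4 g/g-DW-hr) are residues below the resolution of any reduced
model; they are compared absolutely (2e-4 g/g-DW-hr) instead.

Phenotypes are linear programs: mass balance `S v = 0`, bounds, biomass
flux fixed at the phenotype's growth rate (0.018 hr^-1 proliferative,
1e-6 hr^-1 quiescent), maintenance fixed, and an objective — minimal
glucose uptake (normoxic growth, and the lactate- or glutamine-fuelled
quiescent states) or minimal oxygen uptake (hypoxic states, hijacked
stroma).  Degenerate optima are resolved by a second LP stage minimizing
the total absolute flux, so reported distributions are unique.  The
Warburg number (pyruvate-to-lactate flux over mitochondrial pyruvate
import) is imposed by bisecting the oxygen-uptake bound from the
unconstrained optimum (WN = 0) downwards, to |dWN| <= 0.01 within 100
iterations; the glutamine-addicted phenotype instead carries two exactly
linear constraints (lactate flux = WN x mitochondrial import; glutamine
uptake = 0.3 x glucose uptake, molar).

LPs are solved with HiGHS via `scipy.optimize.linprog`; cobrapy (GLPK) is
used in the test suite as an independent oracle on the same problems and
for optional SBML export.

## Growth kinetics

Each cell type sums Monod growth terms mu_max x product of factors; each
term references one phenotype row, whose exchange rates weight the term's
contribution to the tissue reaction term.  Saturating factors C/(K+C)
and inhibitory factors K/(K+C) encode the switches: healthy stromal and
Warburg tumor cells carry an aerobic and an anaerobic (Pasteur) term;
hijacked stroma a single glucose-limited glycolytic term; reverse-Warburg
tumor cells four terms (lactate-fuelled aerobic, Warburg aerobic,
hypoglycemic, anaerobic); glutamine-addicted tumor cells two (aerobic,
hypoglycemic).  Because the two aerobic maxima are equal, the first two
reverse-Warburg terms combine and aerobic growth is lactate-independent —
a property tested to machine precision.

Half-saturation constants are one tenth of the physiological (tank)
concentration, with K_lactate = K_glucose: glucose 0.9 g/L -> K = 0.09;
glutamine 0.073 -> 0.0073; oxygen 0.0023 -> 2.3e-4 g/L.

## Transport parameters and the Krogh calibration

The depletion depth of a metabolite under zeroth-order consumption,
L = sqrt(2 D C0 / (rho_X q)), organizes the whole tissue-scale behavior.
Two anchors fix the free transport parameters:

* tissue dry-biomass density rho_X = 400 g-DW/L (loose sphere packing of
  10-um cells at dry density 764 g/L, i.e. ~400 pg per threshold-size
  cell) together with tank oxygen 0.0023 g/L (dissolved O2, ~55 mmHg) and
  D_O2 = 2e-9 m^2/s gives L_O2 ~ 40 um at the WN = 2 uptake rate;
* glucose diffusivity 7.7e-11 m^2/s — the low end of tumor-spheroid
  measurements — places the oxygen/glucose Krogh crossover at WN ~ 10,
  the location reported for the original parameter set.  Larger
  literature values (7e-10) push the crossover beyond WN = 34 and are
  incompatible with the 40-um oxygen anchor; this is the one transport
  parameter chosen by calibration rather than citation.

Between tabulated Warburg numbers, q(WN) is obtained by re-solving the
FBA at intermediate oxygen bounds (FBA mode) or by monotone PCHIP
interpolation (table mode); both sweeps agree within 5%.

## Tissue simulation

The 2-D domain is a square grid (h = 10 um, one cell diameter, implicit
one-element thickness).  A nutrient "tank" (blood) sits beyond a 20-um
cell-free boundary layer: above the top edge in the axial geometry
(zero-flux bottom, periodic sides), around all four edges in the radial
geometry.  Each one-hour step:

1. agents are binned to the grid and the steady-state balances
   `D lap(C) + sum_m rho_m sum_n q_i/n f_n(C) = 0` are solved by Picard
   iteration (the metabolite's own saturating factor taken
   semi-implicitly, preserving positivity), to a relative change <= 1e-6;
   the solve is truncated a few rows below the deepest cell, where the
   zero-flux field is exactly flat;
2. every agent grows as X <- X exp(mu(C_local) dt) — the exact integral
   of the growth law for frozen fields;
3. the volume of new biomass drives an incompressible displacement
   d = -grad(psi), lap(psi) = -phi (phi = volume fraction produced per
   element), with the vessel side a wall, so growth pushes tissue deeper
   — the pressure mechanism of individual-based biofilm models.  Without
   it, iterative shoving alone cannot translate a long cell column fast
   enough and the growth rim slowly compresses, which makes the
   post-breakthrough growth rate creep upwards instead of staying
   constant;
4. agents whose diameter reaches 10 um divide, the split fraction drawn
   from U(0.45, 0.55), the daughter placed one radius away in a uniform
   random direction (biomass conserved exactly);
5. residual steric overlaps are relaxed by pairwise half-displacements
   (KD-tree neighbor search, periodic in x) until fewer than 0.1% of
   agents move more than 10 nm, capped at 60 sweeps; residual overlap is
   bounded by 5% of the smaller radius.

No cell death is modelled; starved cells are quiescent and counts are
non-decreasing.  Initial layouts are jittered grids (one cell per
element tile, +/-2 um uniform jitter, initial biomass U(0.5, 0.9) of the
division mass): n stromal rows below the boundary layer, two tumor rows
beneath them (axial), or a central tumor disc wrapped in n stromal
shells (radial).  The layout RNG depends only on the replicate seed, so
identical seeds give identical initial positions across metabolic
scenarios; replicate seeds are base_seed + replicate index.

"Breakthrough" is the first time a tumor cell sits shallower than the
shallowest initial stromal position.

## Growth-curve analysis

Replicate trajectories on a shared dump grid are averaged per timepoint
(mean and sample SD).  Early growth rates are the two-point slope over
the first reporting interval (10/20/50 days for 1/3/5 stromal layers at
full scale); late rates the two-point slope over the layer-specific
windows (30,60)/(120,200)/(400,600) days.  For scaled-down domains the
windows shrink by the domain-size ratio.  One caveat found in
desk-scale runs: breakthrough times are depth-driven and do not scale
with domain width, and after breakthrough the growth rim takes ~2-3
weeks of model time to compact to its steady packing, so proportionally
shrunk windows can sample that transient and under-read the slope.
Cross-layer and cross-scenario comparisons of post-breakthrough rates
are therefore windowed relative to each condition's mean breakthrough
time (breakthrough + 15 to + 35 days at quarter width); the shrunk
printed windows remain the analysis defaults.

## Study conditions and desk-scale sizes

The packaged defaults are the study conditions: maintenance 5
mmol ATP/g-DW-hr, growth rates 0.018 and 1e-6 hr^-1, WN in {0, 2, 10,
34}, glutamine:glucose uptake ratio 0.3, eleven replicates with shared
seed lists, 1/3/5 stromal layers, 1-hour steps.  Scenario comparisons in
the test suite run on quarter-width domains (8 elements = 80 um) with
2-3 replicates and horizons of 15-50 days, with rate windows shrunk
accordingly; these sizes reproduce every qualitative ordering (two-phase
growth, non-monotonic WN fitness, the reverse-Warburg early/late
crossover, the Warburg advantage over glutamine addiction) at a few
minutes of CPU.  What they do not probe: absolute growth-rate magnitudes
of the full-width, 600-day replicate sets, 3-D effects, cell death,
convection of solutes, or evolution of phenotypes — all outside the
model's scope.

## Known limitations

* The network is an effective model: internal flux values are not
  element-balanced reaction-by-reaction; only the exchange surface and
  the two energetic anchors are calibrated observables.
* The glutamine-addicted "anaerobic" phenotype is internally inconsistent
  in its sources (an oxygen-consuming "anaerobic" row); the growth law
  follows the two-term kinetic form, with that row supplying the
  hypoglycemic term's exchange rates.
* Monod half-saturation constants and the boundary-layer thickness are
  literature-anchored defaults, validated only through the ~40-um oxygen
  Krogh length.
* At quarter width the domain holds ~2 oxygen Krogh lengths, so front
  roughness is relatively coarse and replicate scatter is larger than at
  full width.
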