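# Methods

`dropevo` re-creates, entirely in software, an artificial-evolution platform
for self-propelled oil-droplet protocells. The evolving unit is a
*formulation genome*: the volume fractions of four oils — 1-octanol,
diethyl phthalate (DEP), octanoic acid and 1-pentanol — that sum to one.
A genome's fitness is measured behaviourally: droplets made from the recipe
are placed in a circular aqueous arena, filmed for one minute at 30 fps, and
the fitness is the number of droplets a vision pipeline still detects as
*moving* in the final (1800th) frame. A genetic algorithm closes the loop,
and programmable obstacle arenas turn the dish into an evolutionary
environment. Because the underlying physical chemistry (Marangoni-driven
propulsion, division, dissolution) has no tractable quantitative model, the
physical device is replaced here by an explicitly phenomenological
simulator; everything else — the GA, the vision pipeline, the lattice
search, the landscape regression, the population statistics — implements
the platform's published protocol directly.

## The genetic algorithm

Standard runs use 10 generations of 20 individuals. Every individual is
evaluated five times and its fitness is the mean of the five counts. The
next generation consists of:

* 10 parents chosen by roulette-wheel (fitness-proportionate) selection
  *without replacement* — sequential draws with renormalised weights, so a
  parent appears at most once. If all remaining candidates have zero
  fitness, the draw falls back to uniform.
* 10 offspring: the parents are paired by a random perfect matching on a
  list containing each parent exactly twice (self-pairs avoided when a
  valid matching exists); each pair produces one child by one-point
  crossover at a cut drawn uniformly from the interior positions {1,2,3},
  followed by additive Gaussian mutation with mean 0 and variance 0.1.
  Negative components are clamped to zero and the result renormalised to
  the simplex; an all-zero result (measure-zero) triggers a noise resample.
  A crossover cut that would combine only zero components falls back to the
  other cuts, then to cloning the first parent.

Parents carried into the next generation are re-evaluated with fresh
repeats rather than cached: the physical protocol re-ran every individual,
and with a stochastic evaluator re-evaluation is the faithful choice.
Random genome initialisation is uniform on the simplex (flat Dirichlet via
sorted-uniform spacings).

Seeding is splittable: the run seed spawns per-generation seed sequences,
which spawn per-individual and per-repeat seeds, all recorded in the
evaluation log. Identical config + seed reproduces every output file byte
for byte.

Per-generation statistics follow the platform's reporting convention: the
generation mean is the mean of the 20 individual means; the "top quartile"
is the fitness of the 5th-ranked individual and the "bottom quartile" that
of the 15th (descending sort, ties broken by insertion order); genome
spread is the per-component standard deviation over the 20 genomes.

## Arenas

The dish is a circle of radius 27.5 mm (not a published constant; chosen so
the camera's 275 px region of interest maps the dish at 10 px/mm — both are
configuration values). Three environments are used:

* **empty** — no obstacles;
* **pillars** — cylindrical pillars of 2 mm diameter on a square grid with
  3 mm centre spacing, keeping every pillar that fits fully inside the
  boundary (so each has its four cardinal neighbours where possible);
* **lsystem** — pillars dropped along the turtle walk of a stochastic
  Lindenmayer system, giving cave-like obstacle patterns. The default
  grammar is a bracketed stochastic F-system (axiom `F`; `F → F[+F]F` with
  probability 0.5, `F → F[-F]` with probability 0.5; 4 iterations; 3 mm
  steps; 25° turns). The original cave grammar was never published, so this
  grammar is this package's own documented default; the spec is fully
  configurable and the arena label records the seed. Pillars that would
  poke outside the dish or overlap an earlier pillar are discarded
  (physical pillars cannot interpenetrate).

The simulation is 2D top-down, matching the camera view; pillar heights and
the dish's base slope are deliberately out of scope.

## The droplet simulator (synthetic-data generator)

**Epistemic status.** Every coefficient of the dynamics is phenomenological.
The genome→behaviour map is anchored only in qualitative chemistry: the
highly water-soluble oils (1-pentanol, 1-octanol) power Marangoni
propulsion; dense, viscous DEP suppresses it; octanoic acid promotes
division and pillar affinity; pentanol excess destabilises droplets. No
quantitative speeds or division rates were ever published; defaults are
mm/s-scale order-of-magnitude choices.

A recipe maps to five traits (defaults in `DEFAULT_TRAIT_PARAMS`):

| trait | default map | units |
|---|---|---|
| motility | `3.0 · (1.0·pent + 0.7·oct + 0.2·octa) · (1 − dep)` | mm/s |
| division rate | `0.5·octa + 0.15·(motility/3)` | 1/s |
| stability | `clip(1 − 0.8·pent, 0, 1)` | — |
| attraction | `clip(0.1 + 0.8·octa + 0.3·dep, 0, 1)` | — |
| decay rate | `0.01 + 0.10·(1 − stability)` | 1/s |

Droplets are active Brownian particles: constant-speed propulsion with
rotational diffusion (0.5 rad²/s) plus a small translational jitter, chosen
as the simplest motion model that produces persistent, bouncing
trajectories. Five 10 μl droplets are injected near the inlet at the bottom
of the dish; the visible radius follows a fixed-height lens model
(r = √(V/πh), h = 1 mm, so a 10 μl droplet shows a 1.78 mm disc).

Each droplet carries a finite *fuel lifetime* = `180 s · (motility/3) ·
m_i`, where `m_i` is a per-droplet lognormal multiplier (σ = 0.35); when
the fuel runs out, propulsion shuts down with a 1.5 s time constant. This
makes "does the droplet still move at the final frame" a sharp, smoothly
genome-dependent event — the selection gradient the fitness function acts
on — rather than leaving droplets to linger ambiguously at near-threshold
speeds, which both blurs selection and defeats the background-subtraction
detector.

Interactions:

* **boundary and pillars** — specular reflection;
* **splitting** — an impact on a pillar above 0.8 mm/s splits a droplet
  into two half-volume daughters placed tangentially on either side of the
  impact normal, with probability `min(1, 0.8 · division_rate)` per impact;
  droplets below 6 μl no longer split (so a 10 μl droplet divides at most
  once), and the agent count is capped at 40. Splits conserve volume;
  only dissolution removes it.
* **hooking/trapping/dissolution** — on impact a pillar hooks the droplet
  with probability `min(1, attraction)`. A hooked droplet sits still and
  unhooks after an exponential holding time with mean `5 s · (1.5 −
  stability)`; while hooked it becomes permanently trapped at rate
  `0.3 · (1 − stability)` per second; trapped droplets dissolve at the
  decay rate and disappear.
* **droplet–droplet** — soft-disc repulsion with a 0.3 mm standoff (the
  surfactant shell prevents coalescence; coalescence is not modelled), plus
  specular scattering of headings on contact so colliding droplets separate
  instead of drifting as a merged pair.

Ground truth: a droplet is *active* at a frame if it is not dissolved and
its smoothed speed (EMA, time constant ≈ 0.3 s) has not been below
0.1 mm/s for the trailing 3 s. The per-frame active count is the quantity
the vision pipeline is meant to recover.

The renderer draws a static background (dish at grey level 70, pillars 120,
outside 20) and droplets as filled discs at 210, 800×600 at 10 px/mm, with
optional Gaussian sensor noise. Rendering is deterministic given the
trajectory, so (genome, arena, config, seed) reproduces videos byte for
byte.

**Parameter provenance.** The defaults above were set so that the platform's
qualitative dynamics emerge from the simulator: fitness rises under
selection in a fixed arena; swapping the empty arena for pillars mid-run
collapses fitness in the first post-swap generation and then contracts the
population's genome spread (the new environment "filters" the viable
genotypes); and recipes evolved in the empty arena lose fitness when tested
in obstacle arenas. These are the behaviours the test suite asserts, over
seeds, not per-seed certainties.

**What the generator does not emulate.** Real droplet videos contain
shadows, meniscus effects between pillars, droplet deformation, partial
coalescence, lighting drift and camera noise; droplet chemistry couples
recipes to behaviour in ways far richer than five scalar traits. Passing
tests therefore validate the *protocol machinery* (GA bookkeeping, detector
behaviour, statistics) and the simulator's own internal consistency — not
quantitative fidelity to the physical system, whose published fitness
values, weighted genomes and landscape errors depend on data that cannot be
regenerated in software.

## The vision pipeline

Processing is restricted to a circular region of interest of radius 275 px.
Each experiment gets a freshly initialised per-pixel mixture-of-Gaussians
background model (Stauffer–Grimson adaptive mixture, K = 5 Gaussians over
grayscale intensity, vectorised over the ROI pixels). Matching uses a
2.5 σ gate; unmatched pixels replace the weakest Gaussian with a fresh,
low-weight, high-variance one; the matched winner's weight, mean and
variance are updated online with learning rate 1/history.

The short memory is the point: `history_frames = 90` (3 s at 30 fps) with
learning rate 1/90 and a background-weight threshold of 0.6 makes a droplet
that stops moving melt into the background about 2.6 s later (the test band
is 2–5 s, matching the "roughly 3 s" behaviour the fitness definition
relies on). The original pipeline used an unnamed library's defaults, so
these values are calibrated to that stated behaviour, not bit-compatible.

The foreground mask is cleaned by morphological closing (disc radius 3 px;
re-joins the crescent fragments a slowly moving droplet sheds as its
trailing pixels are absorbed) followed by opening (radius 1 px; removes
sensor-noise speckle — set it to 0 for noise-free synthetic video, where it
would only erode marginal crescents). Droplets are the 8-connected
components of area ≥ 20 px², described by centroid, area and the boundary
contour of the filled component. The experiment's fitness is the component
count in the final frame.

Known detector limitation: droplets travelling within a shell's width of
each other merge into a single blob (as they would for the original
contour-based counter), so the detected count can differ from the
simulator's ground truth by ±1 occasionally, more when droplets cluster.
The agreement test asserts mean absolute deviation ≤ 1 over random
recipes rather than exactness.

## Lattice search

Combinations of the four oils singly, in pairs, triples and quadruples at
10% granularity, every member of the chosen subset strictly positive:
9 compositions per pair (6 pairs), 36 per triple (4 triples), 84 for the
quadruple — 282 multi-oil formulations, with the 4 pure oils enumerated
but labelled separately (the canonical 282 excludes them; 54 + 144 + 84 =
282 settles the arithmetic). Genomes are built from integer step counts
divided once, avoiding floating-point accumulation. Five repeats of each
formulation in one arena give the 1410-experiment campaign.

## Fitness landscapes

A landscape is a regression from genome fractions (used directly as
features — they are already bounded and on a simplex) to fitness. Each of
the five repeats enters as its own training point, so a standard GA run
contributes 1000 points.

* **SVR** (RBF kernel): C searched over {0.01, 0.1, 1, 10, 100}; the gamma
  grid is not published, so the same five-decade grid {0.01, 0.1, 1, 10,
  100} is used and documented here. Selection is by 10-fold
  cross-validated mean squared error with seeded fold assignment; ties
  break towards smaller C, then smaller gamma; the chosen model is refit on
  all data. The grid search is exhaustive and is tested for exact
  agreement against an independent brute-force enumeration.
* **Kernel ridge** (RBF, α = 10, γ = 100, fixed): the deterministic
  closed-form variant, used when many landscapes must share one kernel
  (e.g. animating a landscape through time).

Landscapes are visualised on ternary slices: predictions on the barycentric
grid of three chosen oils with the fourth held at zero (resolution r gives
C(r+2, 2) grid points).

The published cross-validation errors (6.83 / 21.30 / 11.50) describe
models fitted to physical-experiment data and are not reproduction targets;
the package's contract is the *procedure*, verified on synthetic data.

## Population statistics

* **Weighted genome (WG)**: the fitness-weighted mean of the final
  generation's genome components, ± the weighted standard deviation about
  that mean (normalised weights). The reference analysis says only "after
  10 generations"; the final generation is used here, switchable to the
  whole run.
* **ANOVA**: classical one-way ANOVA per genome component, grouping the
  final-generation individuals by arena; the all-identical degenerate case
  reports F = 0, p = 1. Raw p values are reported (no multiplicity
  correction, matching the reference analysis).
* **Heat-map codes**: each component of an average genome is rounded
  half-up to one decimal, capped at slot 9, and mapped to letters A–J; rows
  are ordered pentanol, octanoic, DEP, octanol. The original letter
  convention cannot be reconstructed from published material, so this
  mapping is this package's own convention.
* **Cross-environment matrix**: entry (i, j) re-evaluates the final
  generation evolved in arena i inside arena j (5 repeats per individual);
  the diagonal is a re-measurement of the home fitness.

## Problem sizes and numerical choices

Batch campaigns (the GA property tests, the lattice sweep and the GA run in
the acceptance script) use a reduced observation profile — 30 s at 10 fps
per experiment, fitness read from the simulator's ground-truth activity
count — which preserves the physics and all bookkeeping while keeping
thousands of experiments tractable; the vision pipeline itself is exercised
at the full 60 s / 30 fps / 800×600 protocol on reference videos, and
reduced-scale (300×400 at 5 px/mm) for the random-recipe agreement checks.
Evolution-dynamics properties (fitness drop, genome-SD contraction) are
asserted as majorities over 5 seeds with 16-generation swap runs (8 empty +
8 pillars, 3 repeats); adaptation on a deterministic unimodal fitness is
asserted in ≥ 9 of 10 seeds.

Other numerics: genome simplex tolerance 1e-9; MoG variance floor 4 (grey
levels²) and initial variance 225; roulette ties and ranking ties break by
insertion order; the L-system expansion caps at 200 000 symbols; splitting
requires ≥ 6 μl so campaigns cannot exceed 2× the injected droplet count.

## Known limitations

* The simulator is a stand-in; none of its coefficients are fitted to data.
* Counting by connected components cannot separate touching droplets and
  does not track identities across frames.
* Published experimental numbers (fitness trajectories, WG values, p
  values, CV errors) are not reproducible from software and are not
  targets; the package reproduces the platform's structure, protocol and
  qualitative dynamics.
* Genomes are fixed at four oils; other lengths are an untested extension
  point.
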