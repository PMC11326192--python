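# Methods

This note documents the model, its parameters, the numerical choices, and the
design decisions behind `assemblypath`, together with what the synthetic
benchmark does and does not demonstrate.

## Representation

A complex is declared as subcomplex *types* (each with a per-instance protein
stoichiometry), *sites* (locations in the mature complex, with reference
coordinates in the fixed laboratory frame shared by all density maps),
a rotational symmetry order, and optional ordering constraints
`count(type_a) ≥ count(type_b)` between type counts (e.g. the inner-ring
Nup205 complex never trails the Nup188 complex during assembly). One
asymmetric unit (spoke) is modeled explicitly; per-protein copy numbers are
the spoke totals multiplied by the symmetry order. Each subcomplex instance is
one isotropic spherical bead (default radius 1.2 length units, mass weight =
total protein copies per instance). Rigid-body orientation is deliberately
omitted: at the resolution of the density volumes handled here, an isotropic
Gaussian per subcomplex is the informative part of the signal.

## Snapshot scoring

**Compositional term.** Candidate compositions at a time point are all
per-type count vectors admissible under the ordering constraints, enumerated
lexicographically. Each is scored by a sum over scored proteins of Gaussian
log-densities, evaluated at the model copy number with the measured mean and
SD. SDs are floored at 1.0 copy: plateaued or noiseless measurements otherwise
produce degenerate zero-variance terms, and one copy is the smallest
physically meaningful uncertainty for calibrated counting data. Whether to use
experimental SDs directly or a fitted noise model was an open choice; we use
the experimental SDs with the floor, and the floor is a parameter
(`sd_floor`). The top `k_top` vectors (default 4) survive to structural
modeling; exact likelihood ties are broken toward the lexicographically
smaller copy vector so runs are reproducible.

**Location assignments.** For types listed in `enumerated_types` (the
Y-complex in the NPC preset) every combination of occupied sites is expanded.
All other multi-site types are filled in a *seeded conventional order* — one
shuffle per type, fixed for the whole run — so growing counts occupy nested
site prefixes. Which same-type site such an instance occupies is therefore a
modeling convention, not an inference; only the enumerated types' assignments
are identifiable quantities.

**Structural term.** For each site-assigned composition, Metropolis Monte
Carlo over single-bead translations samples `n_models` independent chains of
`n_steps` each (defaults 4 × 120; proposal SD 0.4 voxel, temperature 0.15).
The energy is

    E = w_cc · (1 − CC) + EV + Gō + anchor

with `CC` the Pearson correlation between the bead-rendered density and the
time point's map, `EV = k_ev Σ max(0, r_i + r_j − d_ij)²` the soft
excluded-volume penalty, `Gō = k_go Σ (d_ij − d_ij^native)²` the native-biased
pair term toward mature inter-site distances, and
`anchor = k_anchor Σ |x_i − x_i^site|²` a harmonic tether of each bead to its
assigned site. Defaults: `w_cc = 200`, `k_ev = 1`, `k_go = 5`,
`k_anchor = 10`.

The anchor term deserves a comment, because a pure `CC + EV + Gō` energy looks
sufficient at first sight. With isotropic beads, the Gō term constrains only
*pairwise* distances, so a small model can translate nearly freely; a bead
carrying a wrong location assignment then drifts into the density peak of the
correct site and erases the very contrast the location enumeration is supposed
to measure (we observed a wrongly assigned Y-complex bead lower its energy
from ~166 to ~27 this way, destroying both recovery and between-sampling
reproducibility). The maps and the mature structure share one absolute frame —
the same convention under which RMSD to the mature structure is computed
without superposition — so tethering beads to their assigned sites is the
consistent prior, and it is what restores identifiability of assignments.
Set `k_anchor = 0` to recover the free sampler (the one-bead
position-recovery tests do exactly that).

Each chain contributes its best-energy state. The good-scoring subset is the
best `good_fraction` (default 0.5) of models by energy — a quantile rather
than an absolute cutoff, so it adapts to the per-snapshot energy scale. The
snapshot's structural score averages Boltzmann factors over that subset,
`P = mean exp(−E/τ)` with `τ = 1`, computed in log space to avoid underflow.
An empty composition renders a constant zero density; by the package's
constant-grid convention its correlation is 0, so the empty model carries
`E = w_cc` rather than a spurious free pass of 0.

Bead-to-grid rendering places grid node `(i,j,k)` at
`origin + (i,j,k)·spacing`, evaluates each bead's Gaussian (σ = bead radius)
truncated at 3σ, and is linear in the bead set. Monte Carlo keeps the running
model density and the correlation's sufficient statistics updated
incrementally per moved bead, so a step costs O(bead block) rather than
O(grid).

## Trajectory graph and weighting

Snapshots at adjacent time points form a layered DAG. In the *constrained*
mode an edge exists iff the earlier snapshot's occupied site set is a subset
of the later one's (same location assignment — subunits do not dissociate);
the *unconstrained* mode connects all adjacent pairs. All weight arithmetic is
in log space with −∞ for forbidden transitions. Trajectory weights are
normalized globally over trajectories via log-sum-exp. Marginal node weights,
the partition function, the sum of squared weights (γ) and the best trajectory
are computed by forward–backward / Viterbi dynamic programming, so none of
them requires materializing paths; explicit enumeration is available below a
configurable cap (default 10⁷) and fails loudly, never truncates, above it.
Path order and all tie-breaks are lexicographic in node ids, making outputs
byte-reproducible.

Validation metrics follow the definitions in the README. The weighted
copy-number SD uses the population convention (weights are probabilities).
Where the mature composition is held fixed (a single final-layer snapshot) its
model SD is reported as undefined (NaN) via the explicit `fixed_labels`
argument. Temporal precision is computed over the union of the two samplings'
trajectory supports with zero padding for ids absent from one side. The
held-out comparison adds a z-like discrepancy `|model − data| / pooled SD` as
a reporting aid; it never feeds back into any score.

## Synthetic benchmark

The generator emulates the study conditions end to end. The NPC-like preset
has five types on one spoke of an 8-fold ring — Y-complex (4 sites, Nup107 +
Seh1), channel (4 sites, Nup62), connecting (1 site, Nup93), Nup205 and
Nup188 inner-ring complexes (2 sites each, each also carrying Nup93) — with
the Nup205 ≥ Nup188 ordering constraint, six time labels (5, 6, 8, 10, 15
minutes and mature), and Nup188 and Seh1 held out of scoring. Site
coordinates are ring-like within one 45° wedge with ≥ 2.8 length units
between sites, so distinct site assignments render distinct densities on a
1-unit grid.

Ground-truth pathways are strictly monotone (no disassembly, matching the
transition rule's assumption), rejection-sampled so every time point honours
the ordering constraints, and end at the full complex. Enumerated types
occupy randomly chosen nested site subsets — the identifiable signal the maps
must recover. Non-enumerated types follow the same seeded fill convention the
sampler uses (shared `assignment_seed`), because their site identities are a
gauge choice: a "truth" drawn outside the convention would differ from every
representable model by construction, in a quantity the method explicitly does
not claim to infer.

Copy-number data are replicate-averaged true copies plus Gaussian noise
(default SD 0.3 copies, 4 replicates; SD = replicate sample SD). Density
volumes are the true bead renderings plus i.i.d. voxel noise scaled to the
clean map's peak (default 3%). The benchmark study
(`assemblypath.benchmark`) runs 10 independent replicates; each simulates a
study, infers the pathway twice with independent Monte Carlo seeds (3 chains
× 80 steps per snapshot — a deliberately scaled-down sampler; the anchored,
reference-initialized chains converge within a few tens of steps on these
grids), and validates. Under these conditions the top-weighted trajectory
matches the ground truth, γ ≈ 1 and P_temp ≈ 1, echoing the regime where a
single trajectory explains the data.

What the benchmark does *not* emulate: tomographic image formation (missing
wedge, CTF), anisotropic or correlated map noise, membrane context, FG-Nup
disorder, subcomplex shape and orientation, and copy-number biases that are
not zero-mean Gaussian. Passing it shows the inference machinery is correct
and well-calibrated on data generated by its own forward model — not that the
method resolves real assembly intermediates at any particular noise level.

## Degenerate inputs and numerical conventions

* Constant density grids have undefined Pearson correlation; the package
  returns 0.0 with a warning.
* A system with no sites enumerates to the single empty composition; an empty
  bead model renders a zero grid and its RMSD is an error (undefined).
* Kolmogorov–Smirnov exhaustiveness uses the asymptotic two-sample p-value
  (the cutoff conventions p > 0.05, D < 0.3 assume it); samples smaller than
  5 warn but still compute.
* Graph construction fails, naming the layer, when a layer has no allowed
  outgoing transition at all (no trajectory can exist); normalization fails
  when every candidate trajectory has weight zero.
* CSV round trips write floats at %.17g and parse with round-trip precision;
  MRC voxels round-trip at float32 precision with the grid origin stored in
  the CCP4 header origin words.
* Time labels are strings: numeric minutes ordered ascending, the
  distinguished label `mature` last; internal layer indices are 0-based while
  user-facing output uses the labels.

## Known limitations

* Transition scores are binary; kinetic information (rates, dwell times)
  cannot be expressed. Non-Markovian effects are out of scope.
* The structural stand-in resolves location assignments only as far as the
  site-anchor prior allows; with `k_anchor = 0` small models are
  translationally degenerate and assignments blur.
* Exhaustive enumeration above ~10⁷ trajectories is refused by design;
  DP-based marginals, γ and the top trajectory remain available at any size.
* The mature state is held fixed (single final-layer snapshot) by default,
  so its model SD is undefined rather than estimated.
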