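# Methods

## Scope and model

`gasbind` analyses spontaneous gas-ligand (un)binding in unbiased MD
trajectories of a protein whose active site is buried and reached through
tunnels. The analysis chain is: per-frame state labeling → event extraction
→ rate constants → tunnel/pathway assignment and symmetry testing → gating
(bottleneck) analysis → Markov-state-model (MSM) reweighted free energy.
Everything is exercised end-to-end on a synthetic Brownian-dynamics system
with exact recorded ground truth.

## State definitions and event extraction

A ligand copy is **bound** when its center of mass lies within
`bound_cutoff` (default 5 Å) of the catalytic-site center of mass *and*
within `interface_cutoff` of the midpoint of the two anchor metals (for a
[NiFe] site, Ni and Fe). The interface criterion is deliberately a midpoint
distance — the simplest rotation-invariant proxy for "near the metal–metal
interface" — with a configurable cutoff defaulting to 3 Å, since no single
number is canonical. A copy is **unbound** when fully solvated, i.e. its
minimum atom–atom distance to any protein heavy atom (plus the metals)
exceeds `contact_cutoff` (default 4 Å). Everything else is
**intermediate**. All distances use the minimum-image convention with the
frame's box vectors and are reported in Å.

Events are extracted with hysteresis: a binding event completes at the
first frame of a run of ≥ `min_dwell` bound frames that follows the most
recent qualifying unbound run; unbinding symmetrically. `min_dwell`
defaults to 1 frame and exists to suppress recrossing noise. The FPT of a
replica's first binding is measured from frame 0; later FPTs from the
completing frame of the preceding unbinding, which keeps events
approximately independent. Residence time runs from binding completion to
unbinding completion. A ligand that starts bound yields no event until it
first completes an unbound run (there is no defensible FPT or residence
reference for such a transit). With these rules, per-ligand events strictly
alternate and binding/unbinding counts differ by at most one.

Crossing traces (ligand COM positions around the protein-surface crossing)
keep the crossing frame itself — the last bulk point before entry, or the
first bulk point after exit — plus `trace_window` (default 3) frames on the
inside. The inside-of-the-surface portion of a transit is what identifies
the tunnel; bulk frames far from the mouth carry no pathway information and
only add noise to the assignment score.

## Rate constants

k_on = 1/(⟨FPT⟩·C) with C = N/(N_A·V) from the ligand copy number and box
volume (nm³ → L), and k_off = 1/⟨residence⟩. Standard errors come from a
seeded bootstrap that resamples *events* with replacement (1000 replicates
by default): the event is the natural exchangeable unit at these sample
sizes, and the same resampling is used for pathway probabilities.
Confidence intervals use the percentile bootstrap. The experimental
reference rate is k_cat/K_m by default; the conversion is a configurable
hook because other conventions exist.

## Pathway assignment and symmetry

Tunnels are ordered sphere chains (centers + radii, Å) parsed from
CAVER-style PDB sphere records (cluster id in the residue-number field,
radius in the B-factor field), optionally re-ordered site-first given a
site anchor. Assignment is automatic and reproducible rather than curated:
the score of a tunnel for a trace is the mean over trace points of
(distance to the nearest sphere center − that sphere's radius, floored at
0); the best-scoring tunnel wins if its score is ≤ `max_assign_dist`
(default 3 Å), ties break by tunnel id, and everything else is surfaced as
"unassigned" for human review. Similar tunnels are never merged
automatically; a user-supplied merge map is honored before testing.

Binding vs unbinding usage (and any two pathway distributions) are compared
with a two-sample chi-square homogeneity test. Categories whose expected
count falls below `min_expected` (default 5, the classical rule) are pooled
into "other" as long as at least one well-populated category remains; if an
expected count below the threshold survives pooling, the p-value comes from
seeded Monte-Carlo resampling under the pooled null (default 10⁵ tables)
instead of the asymptotic χ² law, and the method used is recorded. Note the
exact (resampling) null is discrete: at small counts its p-value is
legitimately larger than the asymptotic one; the two agree in the
large-count regime.

## Bottleneck gating

The gate coordinate is the per-frame minimum distance between two residues
(heavy atoms only — hydrogen placement is force-field dependent). Its
density is a 0.2 Å-bin histogram, padded and normalized, with a
Gaussian-smoothed copy (σ = 2 bins) used for mode finding. Peaks need a
prominence of ≥ 5 % of the global maximum to count, which suppresses noise
modes. With two modes, the threshold separating open from closed is placed
in the inter-mode valley; because that valley is often a flat near-zero
plateau, the plateau *midpoint* is used — a bare argmin wanders under bin
re-gridding, the midpoint is stable to within a bin. The open fraction is
the fraction of frames above the threshold. Unimodal densities set a flag
and report the single mode.

## Markov state model and free energy

Many short trajectories do not individually equilibrate a slow coordinate;
an MSM reweights them. The coordinate is discretized into `n_bins`
(default 40) equal-width bins over the observed range; transition counts
use a sliding window at lag τ and never cross trajectory boundaries; the
count matrix is restricted to its largest strongly connected set (ergodic
trimming). Reversible estimation symmetrizes counts, (C+Cᵀ)/2, before row
normalization — detailed balance by construction, a deliberate
simplification of maximum-likelihood reversible estimation that is adequate
for a 1-D coordinate sampled at equilibrium. The stationary distribution π
is the left Perron eigenvector; implied timescales are t_i = −τ/ln λ_i.
The default lag is automated: the smallest candidate whose slowest implied
timescale changes by < 10 % when the lag doubles. The free-energy landscape
is ΔG_i = −k_B T ln π_i shifted so the minimum is 0, reported in kT and in
kcal/mol at a default 300 K; empty bins get +∞ and are excluded from the
minimum.

## The synthetic generator

The toy system emulates the statistical structure the analysis assumes:
many identical non-interacting ligand copies in a cubic periodic box; a
spherical protein exclusion volume pierced by a small number of straight
cylindrical channels leading to a buried spherical site; approximately
exponential first-binding times; channel-usage probabilities fixed by
geometry (symmetric channels → 50/50); and a bimodal Markov-switching
distance coordinate standing in for the gate.

Dynamics are overdamped Brownian steps (per-axis variance 2·D·dt) with a
Metropolis rule: a proposal ending inside the protein sphere is rejected —
the ligand stays put — unless the endpoint lies inside a channel cylinder
or the site sphere. With a symmetric proposal this preserves a uniform
equilibrium density on the allowed volume, so binding and unbinding fluxes
through each channel balance and pathway symmetry holds by construction.
A channel contains a point when its distance to the channel axis ray is
below the channel radius and its radial coordinate lies between the site
radius and the protein radius plus one channel radius; the mouth therefore
extends one radius beyond the surface, making crossing traces detectable
outside the sphere. Ground-truth channel attribution uses the channel
containing the ligand at the frame it crosses the protein-radius shell
(ties to the lowest index). Binding is recorded on first entry into the
site sphere after visiting bulk; unbinding on the first return to bulk.
These are exactly the geometric label definitions used for the toy
trajectories, so hysteresis extraction at `min_dwell = 1` reproduces the
recorded events one-to-one — the basis of the ground-truth oracle tests.

Default study conditions: box edge 6 nm; protein radius 1.3 nm; two
opposite channels of radius 0.5 nm; site radius 0.45 nm; D = 4.5 nm²/ns
(the magnitude of H₂ diffusion in water at room temperature); dt = 4 ps;
30 ligand copies (≈ 231 mM, the same many-copy regime as a real gas-probe
simulation) for 10 000 frames (40 ns). These values were chosen once so
that one run yields a few tens of transits — enough events per run for
bootstrap statistics while 50-replicate studies stay cheap — and are the
conditions under which the recovery tests run. The recovery study uses the
pooled estimate over all replicas as the reference rate for coverage, since
no closed form exists for the toy geometry's binding rate. The two-state
gate series defaults to switching probabilities p01 = 0.01/p10 = 0.03 per
frame with emissions 7.5 ± 0.5 Å (open, state 0, stationary weight 0.75)
and 4.5 ± 0.3 Å (closed), i.e. an open-majority gate whose free-energy gap
is ln 3 kT.

What the toy does *not* emulate: internal protein motion (the exclusion
volume is rigid and the gate coordinate is generated independently of the
ligand dynamics), curved or branching tunnels, ligand–ligand interactions,
solvent structure, and any energetic preference of the site beyond
geometry. Passing tests therefore demonstrate the correctness of the
estimators and the internal consistency of the pipeline on data with the
assumed statistical structure — not force-field realism or agreement with
any particular enzyme's absolute rates.

Occupancy fluctuations of a two-state chain are autocorrelated; tolerance
bands in the tests use the chain's asymptotic variance
π₀π₁(1+ρ)/(1−ρ)/n with ρ = 1 − p01 − p10, not the naive binomial one.

## Numerical and interface choices

- Internal simulator units are nm/ns; the analysis layer works in Å and ns
  and converts at the boundary. Temperatures only enter the kcal/mol scale.
- Trajectory I/O goes through MDAnalysis (PDB/GRO topologies, XTC/DCD
  coordinates); the synthetic writer emits a pseudo-protein (Ni/Fe beads at
  the center plus a Fibonacci shell on the exclusion sphere) so real-data
  selections and readers are exercised by fixtures.
- The tunnel sphere-record dialect is read/written with a small fixed-column
  parser because generic PDB readers do not map cluster ids and radii onto
  a tunnel container.
- Frame times come from the trajectory's time stamps (ps → ns), falling
  back to frame indices when stamps are absent or non-increasing.
- Seeds: every stochastic step (simulation, bootstraps, Monte-Carlo nulls,
  chain generation) takes an explicit seed; the pipeline derives per-stage
  streams from one base seed by fixed offsets.

## Known limitations

- The reversible MSM estimator (count symmetrization) is biased relative to
  maximum-likelihood reversible estimation when sampling is far from
  equilibrium; acceptable here because the coordinate is 1-D and the data
  are generated at equilibrium.
- Pathway assignment assumes tunnels are reasonably separated at the
  surface; heavily overlapping mouths would need the merge-map mechanism or
  manual review of "unassigned" events.
- `k_cat/K_m` as the experimental k_on reference assumes the substrate
  binds in the rate-determining regime; the hook allows alternatives.
- First-passage times from runs not much longer than the mean FPT are
  right-censored; estimates from such runs are comparable with each other
  (same protocol) but biased low relative to the infinite-run limit.
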