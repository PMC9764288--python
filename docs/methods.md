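# Methods

## NAC geometry and classification

A near-attack conformation is defined on three descriptors measured per
frame and per candidate hydrogen: the ferryl-oxygen–hydrogen distance
*d*, the Fe–O–H angle θ₁ (vertex at the oxygen) and the C–H–O angle θ₂
(vertex at the hydrogen). The default thresholds — *d* ≤ 2.7 Å,
100° < θ₁ < 140°, θ₂ > 140° — derive from DFT models of the P450
hydrogen-abstraction transition state. Boundary semantics follow the
inequality symbols exactly: the distance bound is inclusive, both angle
windows strict. θ₂ is measured at the hydrogen (the C–H–O angle); the
alternative vertex-at-carbon reading of the atom triple appears in some
descriptions, but the C–H–O convention is the one used for all occupancy
maps and classification here, configurable only through the angle window
itself.

Angles are computed with the atan2(|u×w|, u·w) form, stable near 0° and
180°; rays shorter than 10⁻⁶ Å raise an invalid-geometry error rather
than returning garbage. All lengths are Å and all angles degrees
throughout; no unit conversion is applied to input coordinates.

When a structure carries no explicit ferryl oxygen, one can be
synthesized (flagged `virtual`) on the heme-plane normal: the
least-squares plane through the four pyrrole nitrogens, oriented toward
the substrate carbon, with a default Fe=O bond length of 1.62 Å (typical
ferryl bond; configurable). Any replica that used a virtual oxo is
flagged in its output.

## Trajectory scoring and the epimeric-excess estimate

Frames come from multi-model PDB files (MODEL/ENDMDL blocks; a file
without MODEL records is one frame). Atom identity across frames is the
(chain, resseq, name) triple — serial numbers drift across writers — and
a frame whose key set differs from the first frame aborts with the
offending key named. Parsing is delegated to Biopython's strict PDB
parser so malformed records fail with a line number.

Replicas are aggregated by pooling frames: NAC percentages are total
counts over total frames evaluated, i.e. the frame-weighted mean of
per-replica percentages. Per-replica values are retained in every
summary so a replica-averaged view can be computed without rescoring.
The epimeric excess prediction is

    ee = 100 (NAC_S − NAC_R) / (NAC_S + NAC_R),

reported as *undefined* (JSON null) when no reactive sampling occurred at
all — returning 0 would fabricate a perfectly racemic prediction from no
evidence.

Uncertainty comes from a replica-level percentile bootstrap: whole
replicas are resampled with replacement, the pooled estimate recomputed
per resample, and the interval taken from the resample quantiles.
Calibration simulations at the 50-replica × 1000-sample scale show
coverage of a nominal 90 % interval around 87–89 % — the familiar mild
undercoverage of resampling ~50 units; studentized and BCa variants were
measured within one point of the plain percentile interval, so the
simplest estimator is kept. Fewer than two replicas yields an undefined
interval with a warning, not an exception.

Occupancy maps are 2-D histograms of (θ₂, d) per hydrogen, default bins
d ∈ [1.5, 8.0] Å in 0.1 Å steps and θ₂ ∈ [60°, 180°] in 2° steps
(configurable); samples outside the edges are counted as overflow so
totals always reconcile. Each map also reports the count inside the
two-criteria rectangle (d ≤ 2.7 Å, θ₂ > 140°), which ignores θ₁ and is
therefore a superset of the NAC count — a useful visual sanity check.

Per-site tallies extend scoring to additional (alkylic/vinylic) candidate
hydrogens. Chemical plausibility is annotated, not filtered: a site is
flagged reactive when its user-supplied C–H bond dissociation energy lies
within a window (default 5 kcal/mol) of the weakest tallied bond, since
alkylic and vinylic C–H bonds run roughly 10–20 kcal/mol stronger than
the allylic bonds that actually react.

## Design-ensemble enrichment

Paired ensembles of low-energy sequence designs — one computed with the
substrate constrained in the *pro-S* binding mode, one in *pro-R* — are
first trimmed to unique sequences, keeping the lowest-energy copy of each
(ties by first occurrence). Frequencies are computed over unique
sequences only, matching that order of operations; computing them before
trimming would weight heavily resampled designs. Enrichment is the
signed percentage-point difference PE = 100 (f_target − f_other), which
is antisymmetric between directions and bounded by ±100. Substitutions
observed at least `min_count` times in one set and exactly zero times in
the other are flagged exclusive; candidate ranking orders by exclusivity,
then PE toward the target mode, then position and amino acid. Wild-type
identity per position is report metadata only and never affects the
computation.

## Pose clustering

Pose RMSD is computed over matched heavy atoms in the shared receptor
frame with **no superposition**: docking solutions and rotamers live in
one active site, and superposing them would erase exactly the
binding-mode differences being measured. Clustering is the leader
algorithm with poses visited in ascending energy (ties by pose id): a
pose joins the first cluster whose representative is strictly within the
threshold, else founds a new cluster. The energy-ascending order makes
representatives the lowest-energy members and the partition
deterministic. Rotamer redundancy removal is a single greedy pass in
input order keeping poses at RMSD ≥ threshold (default 0.2 Å) from all
kept poses, with an optional cap on survivors. Both thresholds are
strict (<), and clustering at 5 Å / dedup at 0.2 Å are the working
presets.

## The synthetic basin model

MD of an enzyme–substrate complex is emulated as a continuous-time
Markov chain over labeled conformational basins (*pro-S*-NAC,
*pro-R*-NAC, optional extra-site NAC and nonproductive states) with
truncated-normal emissions of (d, θ₁, θ₂) per hydrogen per state. This
is a deliberate caricature: it reproduces basin dwell with exponential
waiting times, rare-state undersampling and the benefit of independent
replica initialization, while keeping the stationary distribution
available analytically (πQ = 0) as an oracle. It does not model forces,
solvent, kinetics within a basin, or correlations between the two
hydrogens' descriptors — each hydrogen's emission is drawn
independently. Passing recovery tests therefore demonstrates that the
estimator chain is correct and calibrated on a known truth, not that any
particular enzyme behaves like the model.

Construction enforces: generator rows sum to zero with non-negative
off-diagonal rates, irreducibility (strong connectivity of the
positive-rate digraph), a normalized initial distribution, and — sampled
at construction time — that NAC-labeled states emit geometry passing the
classifier with probability ≥ 0.99 for their hydrogen. The convenience
factory `make_basin_model` takes target stationary occupancies π and a
hopping rate k, setting q_ij = k·π_j (i≠j), which has exactly the
requested stationary distribution; the initial distribution defaults to
π, modelling independently initialized replicas relaxing into a random
basin with its equilibrium weight. Default emissions place NAC states at
(d, θ₁, θ₂) = (2.3 ± 0.1 Å, 120 ± 5°, 160 ± 6°), safely inside the
criteria box, and nonreactive hydrogens at (5.0 ± 0.8 Å, 115 ± 15°,
110 ± 15°), safely outside; distances are truncated to [0.5, 12] Å and
angles to [0°, 180°].

Sampling is exact Gillespie simulation, bit-reproducible given a seed.
Seeds split hierarchically (experiment → replica → path/emission/
reconstruction streams) so changing the replica count does not reshuffle
other streams.

### Coordinate reconstruction

To test the full file pathway, emitted descriptor triples are embedded
back into coordinates: Fe at the origin, the four pyrrole nitrogens as a
2.05 Å square in z = 0, the oxo at (0, 0, 1.62). Each hydrogen's (d, θ₁)
fixes it to a circle around the Fe–O axis with a free azimuth drawn from
the seeded stream. Both hydrogens share one target carbon, so the two θ₂
constraints are solved jointly: the carbon is placed exactly on the θ₂
cone of the *pro-S* hydrogen (making that triple exact by construction)
and the *pro-R* azimuth is root-found so its θ₂ matches too, via a
vectorized scan over the free parameters followed by Brent refinement
and a least-squares fallback. Round-trip accuracy is ~10⁻¹⁰ degrees,
far inside the 10⁻⁶ Å / 10⁻⁴ ° acceptance tolerance. Descriptor pairs
emitted by the basin model are empirically always embeddable; adversarial
independent triples can be genuinely infeasible for a shared carbon and
raise a reconstruction error naming the violated constraint. Written PDB
frames quantize coordinates to 0.001 Å, which perturbs descriptors by
≲ 0.002 Å / 0.1°; emissions sit several standard deviations from the
classification boundaries, so NAC counts survive the file round trip
unchanged.

### Sampling protocols

A protocol is (replicas, warm-up, equilibration, production, snapshot
interval, NAC-evaluation interval), all in ps. Warm-up and equilibration
are simulated and discarded; production sampling includes the frame at
the production start, so 50 ps sampled every 5 ps gives 11 frames (the
off-by-one convention is fixed and documented here). Two presets mirror
common practice: `long_5x20ns` (5 replicas, 2 ns equilibration, 20 ns
production, 50 ps snapshots, 1 ps NAC evaluation) and `short_50x100ps`
(50 replicas, 30 + 20 ps warm-up/equilibration, 50 ps production, 5 ps
snapshots, 20 fs NAC evaluation).

`evaluate_protocol` compares protocols on one model by repeatedly running
the full generate → score → aggregate pipeline, reporting mean bias and
RMSE of the e.e. estimate against the analytic truth and the
rare-state detection rate (fraction of repeats with at least one
minority-NAC sample). The shipped comparison pair
(`equal_time_protocols`) holds total production fixed — 5 × 1000 ps vs
50 × 100 ps, both evaluated at 1 ps — so the arms differ only in how the
budget is split across independent replicas. On slow-hopping models
(dwell times far beyond a replica) each replica is effectively frozen in
its initial basin and detection is driven by the number of independent
initializations: 1 − (1 − π_minority)^replicas, which is why many short
replicas find rare reactive states that few long replicas miss.

## Validation problem sizes

The shipped validation suite uses: 10,000 random triples for
classifier/oracle agreement; 50 replicas × 1000 samples (and 100 seeded
repeats thereof) for e.e. recovery and interval calibration, on a
fast-mixing model (k = 1/ps) whose 1 ps samples are nearly independent;
2 × 2000-design libraries over 8 positions with a planted 0.40 vs 0.02
preference for enrichment recovery; 100 pose sets of ≤ 8 poses at both
working thresholds for clustering; 20 experiments × 10 repeats for the
protocol comparison on a slow-hopping model (k = 10⁻⁴/ps); and 1000
samples for the coordinate round trip. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances while keeping
the whole suite at a few CPU-minutes.

## Known limitations

* The basin model's per-hydrogen emissions are independent; real
  trajectories correlate the two hydrogens' geometry through the shared
  carbon. The reconstruction step resolves this only frame-by-frame.
* Reported percentages pool frames across replicas; if replicas have
  unequal frame counts a replica-averaged convention would differ, and
  both views are exposed in the summary for inspection.
* No symmetry-corrected RMSD or atom-graph matching: pose atom order
  must agree exactly.
* BDE values are consumed, never computed; the reactivity flag is a
  window rule, not a rate model.
* Binary trajectory formats are out of scope; the tested surface is
  multi-model PDB.
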