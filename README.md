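# nacscore

Near-attack-conformation (NAC) scoring and stereoselectivity prediction for
cytochrome P450 enzyme–substrate trajectories.

## The problem

P450 monooxygenases hydroxylate prochiral carbons by hydrogen abstraction:
the iron(IV)-oxo intermediate (compound I) pulls either the *pro-R* or the
*pro-S* hydrogen off the target carbon, and oxygen rebound then fixes the
product's stereochemistry. For the conversion of compactin to the statin
drug pravastatin, abstracting the *pro-S* hydrogen at C6 gives the desired
(6*S*) product while the *pro-R* hydrogen gives the unwanted 6-epimer.
Which hydrogen gets abstracted is largely decided by how often the bound
substrate visits a reactive geometry — a *near-attack conformation* —
for one face or the other.

`nacscore` is a toolkit for engineers of such stereoselectivity. It covers
the computational loop around enzyme redesign:

* **Trajectory scoring** (`nacscore.pipeline`): read multi-model PDB
  trajectories, resolve the reaction-center atoms per frame, classify each
  hydrogen's geometry against NAC criteria, and aggregate replicas into a
  predicted epimeric excess with a bootstrap confidence interval, plus
  distance/angle occupancy heat maps and per-site tallies filtered by
  C–H bond dissociation energies.
* **Design-ensemble enrichment** (`nacscore.enrichment`): compare large
  sets of low-energy sequence designs computed with the substrate locked in
  *pro-S* vs *pro-R* binding modes, and rank mutations by their
  percentage enrichment toward the desired mode.
* **Pose clustering** (`nacscore.pose_cluster`): RMSD leader clustering of
  docking solutions (5 Å scale) and rotamer-overlap removal (0.2 Å scale).
* **Synthetic ground truth** (`nacscore.synthetic`): a continuous-time
  Markov basin simulator with analytic stationary occupancies, so every
  stage above can be validated against a known answer without external
  simulation engines.

## The statistic

For each sampled frame and each hydrogen the scorer measures

* *d* — distance from the ferryl oxygen to the hydrogen (Å),
* θ₁ — Fe–O–H angle (vertex at the oxygen, degrees),
* θ₂ — C–H–O angle (vertex at the hydrogen, degrees),

and classifies the frame as a NAC when *d* ≤ 2.7 Å, 100° < θ₁ < 140° and
θ₂ > 140°. With NAC_S and NAC_R the percentages of frames in *pro-S* and
*pro-R* NACs, the predicted epimeric excess is

    e.e. = 100 × (NAC_S − NAC_R) / (NAC_S + NAC_R)

If neither hydrogen ever samples a NAC the prediction is reported as
*undefined*, never 0. For design ensembles, the percentage enrichment of
amino acid *aa* at position *p* toward the *pro-S* mode is

    PE(p, aa) = 100 × (f_S(p, aa) − f_R(p, aa))

computed over unique sequences after lowest-energy deduplication.

## Worked example

Generate five short synthetic replicas from a three-basin model whose
stationary occupancies (30 % *pro-S*-NAC, 7.5 % *pro-R*-NAC, 62.5 %
nonproductive) imply a true e.e. of 60 %, then score them:

```sh
$ nac simulate --model examples/basin_model.yaml \
      --protocol examples/protocol_short.yaml --replicas 5 --seed 11 --out sim
wrote 5 replicas to sim; true e.e. = 60.0%

$ nac score --traj sim/replica_00.pdb --traj sim/replica_01.pdb \
      --traj sim/replica_02.pdb --traj sim/replica_03.pdb \
      --traj sim/replica_04.pdb --config examples/selection.yaml --out scored
pooled NAC_S=27.27% NAC_R=3.64% ee_pred=76.5%
```

Each replica contributes 11 snapshot frames (50 ps of production sampled
every 5 ps, inclusive of the start), so 55 frames are pooled. 27.3 % of
them are *pro-S* NACs and 3.6 % *pro-R* NACs, giving a predicted e.e. of
76.5 % with a wide 90 % bootstrap interval (55.6, 100.0) — 55 frames is
deliberately few; longer protocols tighten the estimate around the true
60 %. `scored/summary.json` holds the pooled and per-replica numbers,
`samples.csv` one row per scored hydrogen per frame, and
`occupancy_<label>.csv` the θ₂ × d heat-map counts.

The same analyses are available as library calls (`score_trajectory`,
`aggregate_replicas`, `rank_candidates`, `greedy_cluster`, ...); the CLI
commands `nac enrich`, `nac cluster` and `nac protocol-eval` cover the
enrichment, clustering and protocol-comparison workflows.

## Layout

    src/nacscore/geometry.py      distances, angles, NAC criteria, virtual oxo
    src/nacscore/pipeline.py      PDB reading, scoring, e.e., maps, tallies
    src/nacscore/enrichment.py    design ensembles, PE, exclusivity, ranking
    src/nacscore/pose_cluster.py  pose RMSD, leader clustering, rotamer dedup
    src/nacscore/synthetic.py     basin simulator, generators, protocol eval
    src/nacscore/cli.py           the `nac` command group
    docs/methods.md               model assumptions, parameters, limitations
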