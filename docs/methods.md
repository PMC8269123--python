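# Methods

## Propagation model

The interactome is a signed, typed graph: nodes are proteins, edges carry
a regulatory sign (+1 activating, −1 inhibiting, 0 unknown), a relation
type (physical / transcriptional / functional) and a directedness flag.
Undirected edges are stored once with lexicographically ordered endpoints
and expanded into two antiparallel arcs at propagation time; self-loops
are dropped on read with a warning (the dynamics have no use for them).

A drug stimulus clamps each target at its mode (+1/−1) throughout; all
other nodes start at 0 and update synchronously,

    s_v ← tanh( Σ over incoming arcs u→v of  w_uv · sign_uv · s_u ),

until the largest per-node change drops below a tolerance or an iteration
cap is reached.  tanh is the natural choice here: it is bounded (all
activations stay in [−1, 1] for any weights), odd (regulatory signs
compose multiplicatively, and negating the stimulus negates the response),
and contracting for sub-unit weights (long paths attenuate, giving the
fixed-point iteration something to converge to).  Synchronous updates on
cyclic graphs can oscillate within tolerance near the fixed point; a state
that has not formally converged at the iteration cap is still scored, with
the flag recorded — this is deliberate, since compliance only needs the
signs and rough magnitudes of effector activations.

Defaults: `max_iterations=50`, `tolerance=1e-6`, readout threshold
`τ=0.05`.  The readout discretizes an effector to sign(s) when |s| ≥ τ
(boundary counts as a call) and 0 otherwise.

## Compliance and training

An *indication* entry is satisfied when Σ_e (−direction_e · readout_e) > 0
over the condition's effectors — the drug moves them, in majority, against
their pathological direction; an *adverse effect* uses the opposite
orientation.  Ties fail (conservative).  Effectors whose pathological
direction conflicts across motives are flagged and excluded from scoring.
Accuracy of a weight assignment is the satisfied fraction of truth-table
entries.

Training samples the population of compliant weight assignments by
independently seeded simulated annealing from uniform-random weights
(unknown-sign edges get a per-solution resolved sign).  The annealing
objective is

    (1 − accuracy) − 0.05 · margin + 0.05 · mean(w),

where the margin term (mean tanh of the per-entry signed effector sums)
smooths the step-shaped accuracy landscape, and the L1 parsimony term
expresses a modeling preference for sparse mechanisms: among the many
assignments that satisfy an underdetermined truth table, sparse ones
concentrate flow on pathways that several entries share, which measurably
improves held-out (cross-validated) accuracy and sharpens path recovery.
Proposals perturb 20% of the weights by a clipped Gaussian step
(sd 0.25) and flip resolved signs with probability 0.01; the schedule is
400 steps from temperature 0.1 with cooling 0.99.  These optimizer
settings were fixed by a small grid on the default synthetic benchmark.
Without the parsimony term the search stops early once every entry is
satisfied; with it, annealing keeps pruning weights at full compliance.

Solutions with training accuracy strictly above the validity threshold
(default 0.90) are retained until the target universe size (default 100)
is reached; per-solution seeds derive from the master seed, so ensembles
are reproducible bit-for-bit and embarrassingly parallel.  A shortfall
after the restart budget produces a *partial* ensemble with a prominent
warning rather than an error, because downstream exploration should not
be blocked by a strict quota.  Cross-validation re-anneals on k−1 folds
of the truth table (stratified by relation type to avoid degenerate
folds) and scores the held-out fold; it is computed per solution seed and
averaged.

## Mechanism extraction

Per solution, each arc's signal flow is |w_uv · s_u| at the final state —
an edge with large weight but no upstream signal carries no mechanism.
Flows are normalized by the solution's maximum (so one high-gain solution
cannot dominate) and averaged across the ensemble into edge-usage values
in [0, 1].  Paths from drug target to disease effector are scored by the
product of edge usages and searched as k shortest simple paths under
additive −log(usage) weights (Yen's algorithm via networkx), with
lexicographic tie-breaking on the node sequence; length is capped at 6
edges (drawn mechanism diagrams rarely exceed 4) and k defaults to 5 per
effector.  A path's net sign is the product of its edge signs; sign-0
edges are resolved per solution before aggregation, and the reported arc
sign is the ensemble majority.  The report lists every disease effector,
with an explicit unreachable marker when no nonzero-usage route exists.

## Off-target screen

Fingerprints are bit sets; the Tanimoto index is |A∩B| / |A∪B| with the
0/0 case defined as 0.  The similarity cutoff is strict (> 0.80), so a
constructed boundary pair at exactly 4/5 is excluded.  A protein becomes a
consensus candidate only when at least one similar compound has *active*
records for it in at least `min_sources` (default 3) distinct source
databases — sources are counted per compound, not pooled across
compounds — and non-human records are ignored by default.  Activity is an
explicit boolean column; potency thresholds are out of scope.  Optional
SMILES fingerprinting delegates to RDKit; the core consumes precomputed
bitset TSVs so no chemistry toolkit is required.

## Docking filter

Pocket specifications use a flat tabular layout: candidate,
UniProt accession, 4-character PDB id, chain, semicolon-separated residue
positions in PDB author numbering, pocket type.  Coordinate extraction
takes heavy atoms only, keeps the highest-occupancy conformer among
alternate locations, reports unresolved residues, and fails only when no
listed residue resolves.  "Distance" is the minimum heavy-atom
ligand-to-pocket Euclidean distance (the published definition is
unstated; centroid and Cα variants were considered and rejected as less
conservative).  A pose is positive iff binding energy < −6 kcal/mol and
distance < 5 Å, both strict, so boundary poses fail.  A candidate is
validated when any pocket has at least one positive pose; the best pose
per pocket is the lowest-energy positive.

## Synthetic study conditions

The generators replace proprietary inputs and define the conditions under
which all quantitative checks run:

- **Background network**: scale-free (Barabási–Albert) by default,
  200 nodes, mean degree 4, undirected edges signed activating /
  inhibiting / unknown at fractions 0.45 / 0.25 / 0.30; largest component
  kept.  An Erdős–Rényi topology is available for contrast.
- **Planted mechanism**: two node-disjoint directed signed paths from a
  fresh source node ("drug target"): a three-edge all-activating path and
  a two-edge path ending in an inhibitory arc.  Every planted node is
  anchored into the background by one random undirected edge, so
  alternative longer routes to the effectors always exist and path
  recovery is not trivial.
- **Truth table** (20 entries, 12 drugs): the focal drug agonizes the
  mechanism source, with the planted path endpoints as indication
  effectors (pathological direction opposite each path's net sign).
  Background physiology is a pool of six shared pathways — hub →
  short signed chains of fresh anchored nodes → two effectors whose
  pathological direction opposes the chain sign; background drugs target
  the hubs of the pathways they have entries for, and the relation
  follows the drug's mode (agonism of a curative pathway = indication).
  By construction, weight 1 on every planted edge and 0 elsewhere
  satisfies the table exactly at any network size, while under random
  weights anchor interference holds accuracy near 0.5–0.7, so passing the
  >0.90 validity filter requires actual training.  Pathway sharing across
  entries is what makes held-out folds learnable; label noise (default 0)
  flips a fixed fraction of relations and is recorded.
- **Compound screen**: a 1024-bit query with 200 on-bits; analogs mutate
  <10% of on-bits (similarity > 0.8, verified post hoc), decoys are
  random draws (verified < 0.5); three planted consensus targets get
  active records in all three sources for an analog, next to near-miss,
  non-human, inactive and decoy-linked records that exercise the filter.
- **Pose tables**: positives drawn strictly inside the acceptance region,
  negatives violating at least one threshold, dealt round-robin over
  three candidates × two pockets.
- **Miniature ITP fixture**: a curated 11-protein network (MPL, JAK2,
  TYK2, STAT1/3/5, PTPN1, TGFB1, IFNG, PPARG, FOXP3) with the signs of
  the drawn mechanism diagrams; its pathological directions encode the
  disease narrative (interferon-γ overactive; TGF-β, PPARγ, FOXP3
  deficient) as a fixture-authoring choice, not a clinical claim.

What the generators do **not** emulate: the size and degree correlations
of a curated human interactome (thousands of nodes, dense annotation),
literature-derived motive definitions, realistic truth-table breadth
(hundreds of drugs), chemical-series structure in fingerprint libraries,
or docking physics (pose energies and distances are sampled, not
computed).  Passing tests therefore demonstrate that the algorithms are
correct and that training recovers planted structure under controlled
conditions — not that the pipeline's biological conclusions transfer to
any real disease.

## Problem sizes and numerical choices

Default analysis sizes — 200-node networks, 20-entry tables, 100-solution
universes, 20 replicate benchmarks with 6–10 solution ensembles, 5-fold
CV over 10 solutions — were chosen so each driver completes in minutes on
a single CPU; the inner propagation loop is JIT-compiled (numba) with a
scipy sparse fallback.  Determinism: every generator and the trainer are
pure functions of their seeds; derived seeds stay below 2^31.  Degenerate
inputs are defined rather than special-cased: empty∩empty Tanimoto is 0,
compliance ties fail, non-convergent propagation is scored with a flag,
and an unreachable effector yields an explicit marker, not an error.

## Known limitations

The transfer function, stopping rule and per-entry compliance rule of the
emulated commercial system are not public; the choices here (tanh
updates, majority-sum compliance, flow-based usage aggregation) are this
package's own, exposed as configuration.  Simulated annealing makes no
claim of sampling the compliant set uniformly — the ensemble is a
population of good local optima.  Cross-validated accuracy on the default
benchmark averages around 0.9 but individual solutions vary (±0.1);
path-recovery rates are stochastic properties of the training conditions,
not guarantees.
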