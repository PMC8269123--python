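# moanet

Systems-pharmacology toolkit for inferring a drug's mechanism of action
(MoA) in a disease by training link-weighted signal-propagation models over
a signed protein–protein interaction network, plus the two structural
follow-up analyses such a study needs: a chemocentric (Tanimoto) off-target
screen and a docking-pose filter.

## The problem

Some drugs act beyond their canonical target pathway.  The motivating case
is eltrombopag, a thrombopoietin-receptor (MPL) agonist used in primary
immune thrombocytopenia (ITP): some patients keep normal platelet counts
after stopping the drug, suggesting an immunomodulatory mechanism that is
not explained by megakaryocyte stimulation alone.  Resolving such a
mechanism *in silico* takes three ingredients:

1. **Network models.** The disease is defined molecularly — a set of
   pathophysiological mechanisms ("motives"), each characterized by
   effector proteins that are up- or down-regulated in disease — and the
   drug as its protein targets with an action mode (agonist +1,
   antagonist −1).  Every link of the interactome gets a weight
   `w ∈ [0, 1]`; a drug stimulus clamped at its targets propagates through
   the signed, weighted network as

       s_v ← tanh( Σ_{u→v} w_uv · sign_uv · s_u ),

   and a weight assignment *complies* with a known drug–condition
   relationship when the propagated signal moves the condition's effectors
   the right way (against their pathological direction for an indication,
   with it for an adverse effect).  Because the truth table of known
   relationships is far smaller than the number of weights, the model is a
   *population* of solutions: independently seeded simulated-annealing
   restarts, keeping only solutions with training accuracy > 90%, up to a
   universe of 100.  The MoA is read out by aggregating signal flow
   `|w·s|` across the ensemble into per-edge usage probabilities and
   extracting the highest-probability simple paths from drug target to
   each disease effector (product of edge usages; net sign = product of
   edge signs).

2. **Off-target screen.** Compounds structurally similar to the query
   (Tanimoto index strictly > 0.80 on binary fingerprints) are looked up
   in bioactivity tables; a protein is an off-target candidate only when
   one similar compound has active records in all of the configured source
   databases (consensus, default 3).

3. **Docking filter.** Candidate pockets (e.g. the BH3/BH4 homology
   domains of Bcl-2-family apoptosis regulators) are specified as residue
   lists on PDB structures; a docked pose is called positive iff binding
   free energy < −6 kcal/mol **and** minimum heavy-atom distance to the
   pocket < 5 Å (both strict).

The real training substrate (curated interactome and truth table) is
proprietary in the motivating study, so `moanet.synthetic` generates every
input with planted ground truth — signed networks with planted mechanism
paths, satisfiable truth tables with optional label noise, fingerprint
libraries with planted analogs, pose tables with planted positives, and a
hand-curated miniature ITP network (MPL → JAK2/TYK2 → STAT1/3/5 →
TGFB1/IFNG/PPARG/FOXP3) — making the whole pipeline testable offline.

## Worked example

```
$ python analysis/01_simulate_benchmark.py --seed 1
network: 230 proteins, 450 interactions
truth table: 20 entries (14 indications, 6 adverse effects) over 12 drugs
planted mechanism: [['TGT', 'K1', 'TF1', 'EFF_A'], ['TGT', 'K2', 'EFF_B']]

$ python analysis/03_extract_moa.py --seed 1
drug eltrombopag on mini_itp: 20 solutions, mean accuracy 1.000
  FOXP3: MPL->JAK2->STAT1->FOXP3 (score 0.134, net activation)
  IFNG: MPL->TYK2->STAT3->IFNG (score 0.122, net inhibition)
  PPARG: MPL->JAK2->STAT1->PPARG (score 0.129, net activation)
  TGFB1: MPL->TYK2->STAT3->TGFB1 (score 0.149, net activation)
```

The scores are ensemble-mean path probabilities (product of edge usages in
[0, 1]; higher = more consistently used across the solution population);
"net activation/inhibition" is the product of the regulatory signs along
the path — here the models recover TGF-β up-regulation through JAK/STAT3,
interferon-γ signaling inhibition, and STAT1/STAT5-mediated PPARγ and
FOXP3 activation, i.e. the immunomodulatory arms of the mechanism.

The other drivers: `02_train_ensemble.py` builds the 100-solution universe
on the planted benchmark and cross-validates it; `04_offtarget_screen.py`
runs the similarity screen (1 analog found among 99 decoys, 3 consensus
targets); `05_docking_filter.py` applies the pose filter (25/100 positives
recovered exactly, 3/3 candidates validated).  A `moanet` CLI exposes the
same stages as subcommands (`simulate`, `extract`, `train`, `moa`,
`screen`, `dockfilter`) for file-based use.

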