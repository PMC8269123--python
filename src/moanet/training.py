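"""Sampling-based training of weight-assignment populations.

The number of truth-table constraints is far smaller than the number of
link weights, so the compliance problem is underdetermined: instead of one
optimum there is a population of weight assignments that all satisfy the
training signal.  We sample that population with independently seeded
simulated-annealing restarts, keep only solutions whose training accuracy
exceeds a validity threshold (default 0.90), and summarize the ensemble by
the mean of its solution accuracies.  k-fold cross-validation re-anneals on
k-1 folds and scores the held-out fold.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .disease import TruthTable, key_proteins
from .errors import ValidationError
from .network import Interactome
from .propagation import (CompiledNetwork, PropagationConfig,
                          WeightAssignment, read_weight_assignment,
                          write_weight_assignment)

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


@dataclass
class AnnealConfig:
    """Simulated-annealing schedule and proposal distribution.

    Proposals perturb a random fraction of weights by a clipped Gaussian
    step and flip resolved signs of unknown-sign edges with small
    probability, keeping accepted moves local.  The objective is
    1 - accuracy with a small continuous margin bonus that smooths the
    otherwise step-shaped accuracy landscape, plus a mild L1 parsimony
    penalty on the mean weight: among the many assignments that satisfy
    the truth table, preferring sparse ones concentrates signal flow on
    reusable pathways and measurably improves held-out (cross-validated)
    accuracy.
    """

    steps: int = 400
    initial_temperature: float = 0.10
    cooling_factor: float = 0.99
    proposal_sd: float = 0.25
    proposal_fraction: float = 0.20
    sign_flip_prob: float = 0.01
    margin_weight: float = 0.05
    sparsity_weight: float = 0.05

    def __post_init__(self):
        if not 0 < self.cooling_factor < 1:
            raise ValidationError("cooling_factor must be in (0, 1)")
        if self.steps < 1:
            raise ValidationError("steps must be >= 1")


@dataclass
class TrainerConfig:
    target_size: int = 100
    validity_threshold: float = 0.90
    max_restarts: int = 300
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    cv_folds: int = 5
    master_seed: int = 0

    def __post_init__(self):
        if not 0 < self.validity_threshold < 1:
            raise ValidationError("validity_threshold must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


@dataclass
class ModelSolution:
    wa: WeightAssignment
    train_accuracy: float
    seed: int
    anneal_iterations: int
    cv_accuracy: float | None = None


@dataclass
class SolutionEnsemble:
    solutions: list
    validity_threshold: float = 0.90
    target_size: int = 100
    attempts: int = 0

    def __post_init__(self):
        for s in self.solutions:
            if s.train_accuracy <= self.validity_threshold:
                raise ValidationError(
                    f"solution seed={s.seed} below validity threshold")
        if len(self.solutions) > self.target_size:
            raise ValidationError("ensemble larger than target size")

    def __len__(self):
        return len(self.solutions)

    @property
    def yield_fraction(self) -> float:
        return len(self.solutions) / self.attempts if self.attempts else 0.0


class ComplianceScorer:
    """Vectorized accuracy/margin evaluation of one weight vector.

    Precomputes, per truth-table entry, the effector index and direction
    arrays and the clamp vectors of each distinct drug, so one evaluation
    is a handful of sparse matvec iterations per drug.
    """

    def __init__(self, cn: CompiledNetwork, truth_table: TruthTable,
                 config: PropagationConfig):
        self.cn = cn
        self.config = config
        drug_col: dict[str, int] = {}
        clamps = []
        self.entries = []
        for entry in truth_table.entries:
            if entry.drug.name not in drug_col:
                drug_col[entry.drug.name] = len(clamps)
                clamps.append(cn.drug_clamp(entry.drug))
            directions = key_proteins(entry.condition)
            idx = np.array([cn.node_index[nid] for nid, d in directions.items()
                            if d != 0], dtype=np.intp)
            dirs = np.array([d for d in directions.values() if d != 0],
                            dtype=float)
            if idx.size == 0:
                raise ValidationError(
                    f"entry ({entry.drug.name}, {entry.condition.name}) has "
                    "no scorable effectors")
            orient = -1.0 if entry.relation == "indication" else 1.0
            self.entries.append((drug_col[entry.drug.name], idx,
                                 orient * dirs))
        k = len(clamps)
        self.clamped = np.zeros((cn.n, k), dtype=bool)
        self.clamp_vals = np.zeros((cn.n, k))
        for j, (idx, vals) in enumerate(clamps):
            self.clamped[idx, j] = True
            self.clamp_vals[idx, j] = vals

    def evaluate(self, w, sign):
        """Return (accuracy, mean continuous margin) for a weight vector."""
        tau = self.config.readout_threshold
        states = self.cn.propagate_batch(w, sign, self.clamped,
                                         self.clamp_vals, self.config)
        n_ok, margin = 0, 0.0
        for col, idx, signed_dirs in self.entries:
            s_eff = states[idx, col]
            r = np.where(np.abs(s_eff) >= tau, np.sign(s_eff), 0.0)
            if float(signed_dirs @ r) > 0:
                n_ok += 1
            margin += math.tanh(float(signed_dirs @ s_eff) / len(idx))
        n = len(self.entries)
        return n_ok / n, margin / n


def _initial_state(cn: CompiledNetwork, rng):
    w = rng.uniform(0.0, 1.0, size=len(cn.edge_keys))
    sign = cn.base_signs.astype(float)
    unknown = np.flatnonzero(cn.unknown_mask)
    sign[unknown] = rng.choice([-1.0, 1.0], size=unknown.size)
    return w, sign


def sample_solution(net: Interactome, truth_table: TruthTable,
                    config: TrainerConfig, seed: int,
                    compiled: CompiledNetwork | None = None,
                    scorer: ComplianceScorer | None = None) -> ModelSolution:
    """Anneal one weight assignment from a uniform-random start.

    Fully reproducible from ``seed``; returns the best state visited even
    when it fails the validity filter (filtering is the caller's job).
    Stops early once every entry is satisfied.
    """
    cn = compiled or CompiledNetwork(net)
    scorer = scorer or ComplianceScorer(cn, truth_table, config.propagation)
    ac = config.anneal
    rng = np.random.default_rng(seed)

    w, sign = _initial_state(cn, rng)

    def cost_of(a, m, wv):
        return ((1.0 - a) - ac.margin_weight * m
                + ac.sparsity_weight * float(wv.mean()))

    acc, margin = scorer.evaluate(w, sign)
    cost = cost_of(acc, margin, w)
    best = (acc, -cost, w.copy(), sign.copy())

    n_edges = len(cn.edge_keys)
    n_move = max(1, int(round(ac.proposal_fraction * n_edges)))
    unknown = np.flatnonzero(cn.unknown_mask)
    temp = ac.initial_temperature
    steps_run = 0
    early_stop = ac.sparsity_weight == 0.0
    for step in range(ac.steps):
        steps_run = step + 1
        w_new, sign_new = w.copy(), sign.copy()
        moved = rng.choice(n_edges, size=n_move, replace=False)
        w_new[moved] = np.clip(w_new[moved]
                               + rng.normal(0.0, ac.proposal_sd, n_move),
                               0.0, 1.0)
        if unknown.size:
            flips = unknown[rng.random(unknown.size) < ac.sign_flip_prob]
            sign_new[flips] *= -1.0
        acc_new, margin_new = scorer.evaluate(w_new, sign_new)
        cost_new = cost_of(acc_new, margin_new, w_new)
        if cost_new <= cost or rng.random() < math.exp((cost - cost_new) / max(temp, 1e-12)):
            w, sign, cost = w_new, sign_new, cost_new
            if (acc_new, -cost_new) > (best[0], best[1]):
                best = (acc_new, -cost_new, w_new.copy(), sign_new.copy())
        temp *= ac.cooling_factor
        # without a parsimony term there is nothing left to refine at
        # perfect compliance; with one, annealing keeps pruning weights
        if early_stop and best[0] >= 1.0:
            break

    acc, _, w_best, sign_best = best
    return ModelSolution(wa=cn.assignment_from_arrays(w_best, sign_best),
                         train_accuracy=acc, seed=seed,
                         anneal_iterations=steps_run)


def build_ensemble(net: Interactome, truth_table: TruthTable,
                   config: TrainerConfig) -> SolutionEnsemble:
    """Collect valid solutions (train accuracy > threshold) by restarting.

    Per-solution seeds derive from the master seed so the population is
    embarrassingly parallel and reproducible.  Exhausting ``max_restarts``
    before reaching ``target_size`` yields a partial ensemble with a
    warning, not an error.
    """
    cn = CompiledNetwork(net)
    scorer = ComplianceScorer(cn, truth_table, config.propagation)
    kept, attempts = [], 0
    while len(kept) < config.target_size and attempts < config.max_restarts:
        seed = (config.master_seed + attempts) % _SEED_MOD
        sol = sample_solution(net, truth_table, config, seed,
                              compiled=cn, scorer=scorer)
        attempts += 1
        if sol.train_accuracy > config.validity_threshold:
            kept.append(sol)
    if len(kept) < config.target_size:
        logger.warning(
            "partial ensemble: %d/%d valid solutions after %d restarts",
            len(kept), config.target_size, attempts)
    return SolutionEnsemble(kept, validity_threshold=config.validity_threshold,
                            target_size=config.target_size, attempts=attempts)


def _stratified_folds(entries, k: int, rng) -> list[list]:
    """Deal entries into k folds round-robin within each relation type."""
    folds: list[list] = [[] for _ in range(k)]
    by_rel: dict[str, list] = {}
    for e in entries:
        by_rel.setdefault(e.relation, []).append(e)
    slot = 0
    for rel in sorted(by_rel):
        grp = by_rel[rel]
        order = rng.permutation(len(grp))
        for j in order:
            folds[slot % k].append(grp[j])
            slot += 1
    return folds


def cross_validate(net: Interactome, truth_table: TruthTable,
                   config: TrainerConfig, solution_seeds) -> tuple[list, float]:
    """Per-solution k-fold CV accuracy and the ensemble mean.

    For each solution seed the entries are dealt into k folds (stratified
    by relation type); each fold is scored by a model annealed on the other
    k-1 folds.  cv_accuracy is the entry-weighted mean over folds.
    """
    k = config.cv_folds
    if k > len(truth_table.entries):
        raise ValidationError(
            f"cv_folds={k} exceeds {len(truth_table.entries)} entries")
    cn = CompiledNetwork(net)
    per_solution = []
    for seed in solution_seeds:
        rng = np.random.default_rng((seed + 7919) % _SEED_MOD)
        folds = _stratified_folds(truth_table.entries, k, rng)
        n_ok, n_total = 0, 0
        for j, fold in enumerate(folds):
            if not fold:
                continue
            train_entries = [e for jj, f in enumerate(folds) if jj != j
                             for e in f]
            train_tbl = TruthTable(train_entries)
            scorer = ComplianceScorer(cn, train_tbl, config.propagation)
            sol = sample_solution(net, train_tbl, config,
                                  (seed + 31 * j) % _SEED_MOD,
                                  compiled=cn, scorer=scorer)
            test_scorer = ComplianceScorer(cn, TruthTable(fold),
                                           config.propagation)
            w, sign = cn.weight_arrays(sol.wa)
            fold_acc, _ = test_scorer.evaluate(w, sign)
            n_ok += fold_acc * len(fold)
            n_total += len(fold)
        per_solution.append(n_ok / n_total)
    return per_solution, float(np.mean(per_solution))


def ensemble_mean_accuracy(ensemble: SolutionEnsemble,
                           which: str = "auto") -> float:
    """Mean of per-solution accuracies (cv when available, else train)."""
    if not ensemble.solutions:
        raise ValidationError("empty ensemble has no mean accuracy")
    if which == "auto":
        which = ("cv" if all(s.cv_accuracy is not None
                             for s in ensemble.solutions) else "train")
    if which == "cv":
        vals = [s.cv_accuracy for s in ensemble.solutions]
        if any(v is None for v in vals):
            raise ValidationError("cv accuracies not computed")
    elif which == "train":
        vals = [s.train_accuracy for s in ensemble.solutions]
    else:
        raise ValueError(f"unknown accuracy kind {which!r}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# ensemble persistence (one weight TSV per solution + manifest JSON)


def save_ensemble(directory, net: Interactome, ensemble: SolutionEnsemble,
                  config: TrainerConfig | None = None) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "validity_threshold": ensemble.validity_threshold,
        "target_size": ensemble.target_size,
        "attempts": ensemble.attempts,
        "config": asdict(config) if config else None,
        "solutions": [],
    }
    for i, sol in enumerate(ensemble.solutions):
        fname = f"solution_{i:04d}.tsv"
        write_weight_assignment(os.path.join(directory, fname), net, sol.wa)
        manifest["solutions"].append({
            "file": fname, "seed": sol.seed,
            "train_accuracy": sol.train_accuracy,
            "cv_accuracy": sol.cv_accuracy,
            "anneal_iterations": sol.anneal_iterations,
        })
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_ensemble(directory, net: Interactome) -> SolutionEnsemble:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    sols = []
    for rec in manifest["solutions"]:
        wa = read_weight_assignment(os.path.join(directory, rec["file"]), net)
        sols.append(ModelSolution(wa=wa, train_accuracy=rec["train_accuracy"],
                                  seed=rec["seed"],
                                  anneal_iterations=rec["anneal_iterations"],
                                  cv_accuracy=rec.get("cv_accuracy")))
    return SolutionEnsemble(sols,
                            validity_threshold=manifest["validity_threshold"],
                            target_size=manifest["target_size"],
                            attempts=manifest["attempts"])
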