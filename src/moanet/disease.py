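"""Molecular definitions of clinical concepts.

A disease is described by *motives* — pathophysiological mechanisms, each
characterized by effector proteins with a pathological direction (+1
up-regulated in disease, -1 down-regulated).  A drug is a set of protein
targets with an action mode (+1 agonist, -1 antagonist).  The truth table
lists known drug-condition relationships (indications and adverse effects)
and is the training signal for the propagation models.

Sign convention: an *indication* means the drug should move the condition's
effectors against their pathological direction; an *adverse effect* means
it moves them with it.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

RELATION_TYPES = ("indication", "adverse_effect")

_DIRECTION_TOKENS = {"up": 1, "down": -1, "+1": 1, "-1": -1, "1": 1,
                     "−1": -1}


@dataclass(frozen=True)
class Motive:
    """One pathophysiological mechanism with its effector proteins."""

    name: str
    effectors: tuple  # of (node id, direction in {-1, +1})

    def __post_init__(self):
        if not self.effectors:
            raise ValidationError(f"motive {self.name!r} has no effectors")
        seen = set()
        for nid, d in self.effectors:
            if d not in (-1, 1):
                raise ValidationError(
                    f"motive {self.name!r}: direction for {nid} must be +/-1")
            if nid in seen:
                raise ValidationError(
                    f"motive {self.name!r}: duplicate effector {nid}")
            seen.add(nid)


@dataclass(frozen=True)
class DiseaseDefinition:
    name: str
    motives: tuple

    def __post_init__(self):
        if not self.motives:
            raise ValidationError(f"disease {self.name!r} has no motives")


@dataclass(frozen=True)
class DrugDefinition:
    """A drug as its protein targets plus action mode per target."""

    name: str
    targets: tuple  # of (node id, mode in {-1, +1})

    def __post_init__(self):
        if not self.targets:
            raise ValidationError(f"drug {self.name!r} has no targets")
        for nid, m in self.targets:
            if m not in (-1, 1):
                raise ValidationError(
                    f"drug {self.name!r}: mode for {nid} must be +/-1")


@dataclass(frozen=True)
class TruthEntry:
    drug: DrugDefinition
    condition: DiseaseDefinition
    relation: str

    def __post_init__(self):
        if self.relation not in RELATION_TYPES:
            raise ValidationError(f"unknown relation {self.relation!r}")


@dataclass
class TruthTable:
    entries: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            key = (e.drug.name, e.condition.name)
            if key in seen:
                raise ValidationError(f"duplicate truth-table pair {key}")
            seen.add(key)

    def __len__(self):
        return len(self.entries)

    def relation_counts(self) -> dict:
        counts = {r: 0 for r in RELATION_TYPES}
        for e in self.entries:
            counts[e.relation] += 1
        return counts


# ---------------------------------------------------------------------------
# loaders


def _parse_direction(tok: str, lineno: int):
    d = _DIRECTION_TOKENS.get(tok.strip().lower())
    if d is None:
        raise ValidationError(
            f"line {lineno}: direction must be up/down/+1/-1, got {tok!r}")
    return d


def load_disease_definition(path, name: str | None = None) -> DiseaseDefinition:
    """Load a disease from a motive TSV (columns motive, effector, direction).

    Motives are grouped preserving file order; effector duplication within a
    motive is rejected with the offending line.
    """
    order: list[str] = []
    grouped: dict[str, list] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"motive", "effector", "direction"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"motive table must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            motive = row["motive"].strip()
            if motive not in grouped:
                order.append(motive)
                grouped[motive] = []
            eff = row["effector"].strip()
            if not eff:
                raise ValidationError(f"line {lineno}: empty effector id")
            if eff in (nid for nid, _ in grouped[motive]):
                raise ValidationError(
                    f"line {lineno}: duplicate effector {eff!r} in motive "
                    f"{motive!r}")
            grouped[motive].append((eff, _parse_direction(row["direction"],
                                                          lineno)))
    motives = tuple(Motive(m, tuple(grouped[m])) for m in order)
    if name is None:
        stem = os.path.splitext(os.path.basename(str(path)))[0]
        # "<disease>.motives.tsv" and "motives_<disease>.tsv" both name
        # the disease after the file
        name = stem.removesuffix(".motives").removeprefix("motives_")
    return DiseaseDefinition(name, motives)


def write_disease_definition(path, disease: DiseaseDefinition) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["motive", "effector", "direction"])
        for m in disease.motives:
            for nid, d in m.effectors:
                w.writerow([m.name, nid, "up" if d == 1 else "down"])


def load_drug_definitions(path) -> list[DrugDefinition]:
    """Load drugs from a TSV with columns drug, target, mode."""
    order: list[str] = []
    grouped: dict[str, list] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"drug", "target", "mode"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"drug table must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            drug = row["drug"].strip()
            if drug not in grouped:
                order.append(drug)
                grouped[drug] = []
            grouped[drug].append((row["target"].strip(),
                                  _parse_direction(row["mode"], lineno)))
    return [DrugDefinition(d, tuple(grouped[d])) for d in order]


def write_drug_definitions(path, drugs) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["drug", "target", "mode"])
        for drug in drugs:
            for nid, m in drug.targets:
                w.writerow([drug.name, nid, "+1" if m == 1 else "-1"])


# ---------------------------------------------------------------------------
# derived views


def key_proteins(disease: DiseaseDefinition) -> dict[str, int]:
    """Pooled effector set with consensus pathological direction.

    An effector listed in several motives with the same direction collapses
    to one entry.  Conflicting directions yield direction 0: the protein is
    flagged and excluded from compliance scoring downstream (the scorer
    skips direction-0 effectors).  Idempotent and independent of motive
    order.
    """
    consensus: dict[str, int] = {}
    for m in disease.motives:
        for nid, d in m.effectors:
            if nid not in consensus:
                consensus[nid] = d
            elif consensus[nid] != d and consensus[nid] != 0:
                logger.warning(
                    "effector %s has conflicting pathological directions in "
                    "%s; excluded from scoring", nid, disease.name)
                consensus[nid] = 0
    return dict(sorted(consensus.items()))


def build_truth_table(drugs, conditions, relations) -> TruthTable:
    """Resolve a relations table against named drug/condition definitions.

    ``relations`` is a CSV path or DataFrame with columns drug, condition,
    relation.  Unknown names raise; duplicate pairs raise.
    """
    if not isinstance(relations, pd.DataFrame):
        relations = pd.read_csv(relations)
    required = {"drug", "condition", "relation"}
    if not required <= set(relations.columns):
        raise ValidationError(f"relations need columns {sorted(required)}")
    drug_by_name = {d.name: d for d in drugs}
    cond_by_name = {c.name: c for c in conditions}
    entries = []
    for _, row in relations.iterrows():
        if row["drug"] not in drug_by_name:
            raise InputError(f"unknown drug {row['drug']!r}")
        if row["condition"] not in cond_by_name:
            raise InputError(f"unknown condition {row['condition']!r}")
        entries.append(TruthEntry(drug_by_name[row["drug"]],
                                  cond_by_name[row["condition"]],
                                  str(row["relation"])))
    table = TruthTable(entries)
    logger.info("truth table: %s", table.relation_counts())
    return table


def write_truth_table(path, table: TruthTable) -> None:
    pd.DataFrame(
        [(e.drug.name, e.condition.name, e.relation) for e in table.entries],
        columns=["drug", "condition", "relation"],
    ).to_csv(path, index=False)
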