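"""Chemocentric off-target screening.

Two similar molecules probably share targets: the screen ranks library
compounds by Tanimoto similarity of binary fingerprints against a query
(strictly above a 0.80 cutoff), then calls a protein an off-target
candidate when at least one similar compound has an *active* bioactivity
record for it in a minimum number of distinct source databases (consensus
across sources; default 3, e.g. PubChem / ChEMBL / BindingDB exports).
Live database queries are out of scope; the screen consumes local tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class Fingerprint:
    """Binary molecular fingerprint as the set of on-bit indices."""

    compound_id: str
    bits: frozenset
    n_bits: int

    def __post_init__(self):
        if self.n_bits <= 0:
            raise ValidationError("n_bits must be positive")
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValidationError(
                f"{self.compound_id}: bit index outside [0, {self.n_bits})")


@dataclass(frozen=True)
class BioactivityRecord:
    compound_id: str
    protein_id: str
    source: str
    active: bool
    organism: str = "human"


@dataclass(frozen=True)
class OffTargetCall:
    protein_id: str
    supporting_compounds: tuple
    supporting_sources: frozenset
    passed_consensus: bool


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A n B| / |A u B| over on-bits; both-empty defined as 0."""
    if a.n_bits != b.n_bits:
        raise ValidationError(
            f"fingerprint capacities differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def similar_compounds(query: Fingerprint, library,
                      threshold: float = 0.80) -> list[tuple[str, float]]:
    """Library compounds with similarity strictly above the threshold.

    Sorted by descending similarity, ties by compound id.  The boundary
    (similarity == threshold) is excluded.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError("threshold must be in [0, 1]")
    hits = [(fp.compound_id, tanimoto(query, fp)) for fp in library]
    hits = [(cid, sim) for cid, sim in hits if sim > threshold]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


def consensus_candidates(hits, records, min_sources: int = 3,
                         human_only: bool = True) -> list[OffTargetCall]:
    """Proteins supported by active records in >= min_sources databases.

    A protein passes when at least one similar compound ("hit") has an
    active record for it in ``min_sources`` distinct sources; non-human
    records are ignored by default.  Output sorted by protein id, one call
    per protein seen for any hit compound (failed calls included with
    ``passed_consensus=False``).
    """
    if min_sources < 1:
        raise ValidationError("min_sources must be >= 1")
    hit_ids = {cid for cid, _ in hits}
    per_protein: dict[str, dict] = {}
    per_compound_sources: dict[tuple, set] = {}
    for rec in records:
        if rec.compound_id not in hit_ids or not rec.active:
            continue
        if human_only and rec.organism.lower() != "human":
            continue
        info = per_protein.setdefault(rec.protein_id,
                                      {"compounds": set(), "sources": set()})
        info["compounds"].add(rec.compound_id)
        info["sources"].add(rec.source)
        per_compound_sources.setdefault(
            (rec.protein_id, rec.compound_id), set()).add(rec.source)

    calls = []
    for pid in sorted(per_protein):
        info = per_protein[pid]
        # consensus must hold for a single compound, not pooled across hits
        passed = any(len(sources) >= min_sources
                     for (p, _), sources in per_compound_sources.items()
                     if p == pid)
        calls.append(OffTargetCall(
            protein_id=pid,
            supporting_compounds=tuple(sorted(info["compounds"])),
            supporting_sources=frozenset(info["sources"]),
            passed_consensus=passed))
    return calls


# ---------------------------------------------------------------------------
# I/O


def read_fingerprints(path) -> list[Fingerprint]:
    """Fingerprint TSV: compound_id, n_bits, comma-separated on-bit list."""
    fps = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"compound_id", "n_bits", "bits"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"fingerprint table needs columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                bits = frozenset(int(b) for b in row["bits"].split(",")
                                 if b.strip() != "")
                fps.append(Fingerprint(row["compound_id"].strip(), bits,
                                       int(row["n_bits"])))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    return fps


def write_fingerprints(path, fps) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["compound_id", "n_bits", "bits"])
        for fp in fps:
            w.writerow([fp.compound_id, fp.n_bits,
                        ",".join(str(b) for b in sorted(fp.bits))])


def read_bioactivity(path) -> list[BioactivityRecord]:
    """Bioactivity CSV: compound_id, protein_id, source, active, organism."""
    df = pd.read_csv(path)
    required = {"compound_id", "protein_id", "source", "active", "organism"}
    if not required <= set(df.columns):
        raise ValidationError(f"bioactivity table needs {sorted(required)}")
    return [BioactivityRecord(str(r.compound_id), str(r.protein_id),
                              str(r.source),
                              str(r.active).strip().lower() in ("1", "true",
                                                                "yes"),
                              str(r.organism))
            for r in df.itertuples(index=False)]


def fingerprint_from_smiles(compound_id: str, smiles: str,
                            n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    """Morgan fingerprint via RDKit (optional dependency)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:   # pragma: no cover - environment-dependent
        raise ImportError(
            "rdkit is required for SMILES fingerprinting; install the "
            "'chem' extra") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES for {compound_id}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(compound_id, frozenset(fp.GetOnBits()), n_bits)
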