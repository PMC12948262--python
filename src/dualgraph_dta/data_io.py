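"""Affinity-table and structure I/O, label transforms, CV splitting.

Conventions
-----------
* Affinity tables are UTF-8 CSV/TSV with a header naming at least
  ``drug_id``, ``drug_smiles``, ``protein_id``, ``protein_sequence`` (or a
  resolvable protein id plus a FASTA side file), ``label_value`` and
  ``label_kind``.
* Rows that fail validation (bad SMILES, empty sequence, non-finite label)
  are rejected with a logged reason and counted; a load never aborts on a
  bad row.
* pKd uses the DeepDTA convention: labels arrive as Kd in nM and
  ``pkd_transform`` maps them to -log10(Kd * 1e-9). Davis placeholder
  entries (Kd = 10,000 nM for non-binders, pKd = 5.0) are kept.
* PDB parsing reads the first model only; disordered (altloc) Calpha atoms
  resolve to the highest-occupancy location, ties to altloc 'A'. Residue
  indexing is 1-based in the returned tuples.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

LABEL_KINDS = ("pKd", "KIBA", "pIC50", "binary")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

REQUIRED_COLUMNS = ("drug_id", "drug_smiles", "protein_id", "label_value", "label_kind")


@dataclass(frozen=True)
class AffinityRecord:
    """One drug-protein pair with its affinity label and provenance."""

    drug_id: str
    drug_smiles: str
    protein_id: str
    protein_sequence: str
    label_value: float
    label_kind: str

    def validate(self) -> None:
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(f"unknown label kind {self.label_kind!r}")
        if not math.isfinite(self.label_value):
            raise ValueError("label_value must be finite")
        if self.label_kind == "binary" and self.label_value not in (0.0, 1.0):
            raise ValueError("binary label must be 0 or 1")
        if len(self.protein_sequence) < 1 or not set(self.protein_sequence) <= AA_ALPHABET:
            raise ValueError("protein_sequence empty or outside the 20+X alphabet")
        RDLogger.DisableLog("rdApp.error")
        try:
            mol = Chem.MolFromSmiles(self.drug_smiles)
        finally:
            RDLogger.EnableLog("rdApp.error")
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise ValueError(f"unparseable SMILES {self.drug_smiles!r}")


@dataclass
class DatasetSplit:
    """k-fold assignment of record indices; reproducible for a fixed seed."""

    fold_of: dict[int, int]
    k: int
    seed: int

    def fold_indices(self, fold: int) -> list[int]:
        return sorted(i for i, f in self.fold_of.items() if f == fold)

    def to_json(self, path: str | Path) -> None:
        payload = {"k": self.k, "seed": self.seed,
                   "fold_of": {str(i): f for i, f in self.fold_of.items()}}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        return cls(fold_of={int(i): f for i, f in payload["fold_of"].items()},
                   k=payload["k"], seed=payload["seed"])


def read_fasta(path: str | Path) -> dict[str, str]:
    """protein_id -> sequence mapping from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_affinity_table(
    path: str | Path,
    dialect: str = "csv",
    sequences: dict[str, str] | None = None,
) -> list[AffinityRecord]:
    """Load an affinity table, rejecting (not aborting on) invalid rows.

    If the table lacks a ``protein_sequence`` column, ``sequences`` must map
    each protein_id to its sequence.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"drug_id": str, "protein_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"affinity table missing required columns: {missing}")
    has_seq_col = "protein_sequence" in df.columns
    if not has_seq_col and sequences is None:
        raise ValueError("no protein_sequence column and no FASTA mapping supplied")

    records: list[AffinityRecord] = []
    n_rejected = 0
    for idx, row in df.iterrows():
        try:
            seq = row["protein_sequence"] if has_seq_col else sequences[row["protein_id"]]
            rec = AffinityRecord(
                drug_id=str(row["drug_id"]),
                drug_smiles=str(row["drug_smiles"]),
                protein_id=str(row["protein_id"]),
                protein_sequence=str(seq),
                label_value=float(row["label_value"]),
                label_kind=str(row["label_kind"]),
            )
            rec.validate()
        except (KeyError, ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("rejecting row %s: %s", idx, exc)
            continue
        records.append(rec)
    if n_rejected:
        logger.info("loaded %d records, rejected %d rows", len(records), n_rejected)
    return records


def write_affinity_table(records: Sequence[AffinityRecord], path: str | Path,
                         dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, sep=sep, index=False)


def pkd_transform(kd_nM: float) -> float:
    """pKd = -log10(Kd * 1e-9) with Kd in nM; strictly decreasing in Kd."""
    if kd_nM <= 0:
        raise ValueError("Kd must be positive")
    return -math.log10(kd_nM * 1e-9)


def pkd_inverse(pkd: float) -> float:
    """Kd in nM from pKd."""
    return 10.0 ** (9.0 - pkd)


def filter_kiba(
    records: Sequence[AffinityRecord],
    min_per_target: int = 10,
    min_per_drug: int | None = None,
) -> list[AffinityRecord]:
    """Keep records whose target has >= ``min_per_target`` measurements.

    ``min_per_drug`` optionally applies the symmetric per-drug rule for
    strict benchmark replication. Relative record order is preserved and the
    filter is idempotent.
    """
    per_target: dict[str, int] = {}
    per_drug: dict[str, int] = {}
    for r in records:
        per_target[r.protein_id] = per_target.get(r.protein_id, 0) + 1
        per_drug[r.drug_id] = per_drug.get(r.drug_id, 0) + 1
    out = []
    for r in records:
        if per_target[r.protein_id] < min_per_target:
            continue
        if min_per_drug is not None and per_drug[r.drug_id] < min_per_drug:
            continue
        out.append(r)
    return out


def make_cv_folds(records: Sequence, k: int = 5, seed: int = 0) -> DatasetSplit:
    """Record-level random k-fold partition; fold sizes differ by at most 1."""
    n = len(records)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of: dict[int, int] = {}
    for pos, rec_idx in enumerate(perm):
        fold_of[int(rec_idx)] = pos % k
    return DatasetSplit(fold_of=fold_of, k=k, seed=seed)


def extract_ca_coordinates(
    pdb_path: str | Path, chain: str | None = None
) -> list[tuple[int, float, float, float]]:
    """Calpha coordinates per residue, in sequence order, 1-based indexing.

    First model only; residues without a Calpha atom are skipped with a
    warning; disordered Calpha atoms resolve to the highest-occupancy
    altloc (ties -> 'A').
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no models in PDB file {pdb_path}")
    out: list[tuple[int, float, float, float]] = []
    idx = 0
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for residue in ch:
            if residue.id[0] != " ":  # skip heteroatoms/waters
                continue
            idx += 1
            ca = None
            for atom in residue:
                if atom.get_name() == "CA":
                    ca = atom
                    break
            if ca is None:
                logger.warning("residue %s%s lacks a Calpha atom; skipped",
                               residue.get_resname(), residue.id[1])
                idx -= 1
                continue
            if ca.is_disordered():
                alts = sorted(
                    ca.disordered_get_list(),
                    key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                )
                ca = alts[0]
            x, y, z = (float(v) for v in ca.get_coord())
            out.append((idx, x, y, z))
    if not out:
        raise ValueError(f"no Calpha atoms found in {pdb_path}")
    return out


__all__ = [
    "AffinityRecord",
    "DatasetSplit",
    "LABEL_KINDS",
    "read_affinity_table",
    "write_affinity_table",
    "read_fasta",
    "pkd_transform",
    "pkd_inverse",
    "filter_kiba",
    "make_cv_folds",
    "extract_ca_coordinates",
]
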