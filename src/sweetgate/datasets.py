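"""Molecule-table ingestion, curation, circular fingerprints and descriptor tables.

The dataset atom is a :class:`MoleculeRecord`: an identifier, a SMILES string
(canonicalized on ingest), the raw taste annotation (sweet / tasteless /
bitter) and the curated binary class (sweet / non-sweet).  Curation merges
tasteless and bitter into a single non-sweet class, collapses duplicate
structures, and removes structures annotated with conflicting tastes.

Fingerprints are hashed circular (Morgan-style) presence/absence vectors:
every circular substructure up to a maximum radius contributes a feature
identifier, and each feature sets a fixed number of positions (default two)
in a fixed-width bit vector (default 2048 bits).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

SWEET = "sweet"
NON_SWEET = "non-sweet"
NOT_ASSIGNED = "not-assigned"

RAW_LABELS = ("sweet", "tasteless", "bitter")

# rdkit is chatty about unparseable SMILES; rejects are reported explicitly.
RDLogger.DisableLog("rdApp.error")


class ConfigurationError(ValueError):
    """Raised when an input table or a parameter set is malformed."""


class InputError(ValueError):
    """Raised when an input is structurally valid but unusable (e.g. empty)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated molecule: id, canonical SMILES, raw label, binary class."""

    id: str
    smiles: str
    raw_label: str
    class_label: str = field(default="")

    def __post_init__(self) -> None:
        if self.raw_label not in RAW_LABELS:
            raise ConfigurationError(
                f"unknown taste label {self.raw_label!r}; expected one of {RAW_LABELS}"
            )
        expected = SWEET if self.raw_label == "sweet" else NON_SWEET
        if self.class_label == "":
            object.__setattr__(self, "class_label", expected)
        elif self.class_label != expected:
            raise ConfigurationError(
                f"class_label {self.class_label!r} inconsistent with raw_label {self.raw_label!r}"
            )


@dataclass(frozen=True)
class FingerprintParams:
    """Hashed circular fingerprint parameters.

    ``max_order`` is the neighborhood radius (bond count from the central
    atom); ``bits_per_pattern`` is the number of hash positions each circular
    feature sets in the ``n_bits``-wide vector.
    """

    n_bits: int = 2048
    bits_per_pattern: int = 2
    max_order: int = 2

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ConfigurationError("n_bits must be positive")
        if self.max_order < 0:
            raise ConfigurationError("max_order must be >= 0")
        if self.bits_per_pattern <= 0:
            raise ConfigurationError("bits_per_pattern must be positive")


@dataclass
class FingerprintMatrix:
    """Molecules x fixed-width binary matrix, row order matching ``ids``."""

    ids: list[str]
    bits: np.ndarray
    params: FingerprintParams = field(default_factory=FingerprintParams)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ConfigurationError("bits must be a 2-D matrix")
        if len(self.ids) != self.bits.shape[0]:
            raise ConfigurationError("row count does not match id count")
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise ConfigurationError("fingerprint entries must be 0/1")

    @property
    def n_molecules(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def subset(self, indices: Sequence[int]) -> "FingerprintMatrix":
        idx = list(indices)
        return FingerprintMatrix(
            [self.ids[i] for i in idx], self.bits[idx], self.params
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.bits, index=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, params: FingerprintParams | None = None) -> "FingerprintMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), params or FingerprintParams(n_bits=df.shape[1]))


@dataclass
class DescriptorTable:
    """Molecules x named numeric descriptors, with an optional block map."""

    ids: list[str]
    names: list[str]
    values: np.ndarray
    block_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ConfigurationError("descriptor matrix shape does not match ids/names")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)

    def subset_rows(self, indices: Sequence[int]) -> "DescriptorTable":
        idx = list(indices)
        return DescriptorTable(
            [self.ids[i] for i in idx], list(self.names), self.values[idx], self.block_of
        )

    def subset_columns(self, names: Sequence[str]) -> "DescriptorTable":
        pos = [self.names.index(n) for n in names]
        block = {n: self.block_of[n] for n in names} if self.block_of else None
        return DescriptorTable(list(self.ids), list(names), self.values[:, pos], block)


@dataclass
class CuratedSet:
    """Curated molecule records plus a structured curation log."""

    records: list[MoleculeRecord]
    log: list[dict]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {SWEET: 0, NON_SWEET: 0}
        for r in self.records:
            counts[r.class_label] += 1
        return counts


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES via the toolkit's default dialect, or None if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def parse_molecule_table(
    path: str | Path,
    fmt: str | None = None,
    id_column: str = "id",
    smiles_column: str = "smiles",
    label_column: str = "label",
) -> tuple[list[MoleculeRecord], list[dict]]:
    """Read a molecule table (CSV/TSV) into records with canonical SMILES.

    Returns ``(records, rejects)`` where every reject entry names the row and
    the reason; unparseable rows are reported, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"molecule table not found: {path}")
    sep = {"csv": ",", "tsv": "\t"}.get(fmt or path.suffix.lstrip(".").lower(), ",")
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in (id_column, smiles_column, label_column) if c not in df.columns]
    if missing:
        raise ConfigurationError(f"molecule table missing column(s): {missing}")

    records: list[MoleculeRecord] = []
    rejects: list[dict] = []
    for row_number, row in enumerate(df.itertuples(index=False)):
        mol_id = str(getattr(row, id_column))
        smiles = str(getattr(row, smiles_column))
        label = str(getattr(row, label_column)).strip().lower()
        if label not in RAW_LABELS:
            rejects.append({"row": row_number, "id": mol_id, "reason": f"unknown label {label!r}"})
            continue
        canon = canonical_smiles(smiles)
        if canon is None:
            rejects.append({"row": row_number, "id": mol_id, "reason": f"unparseable SMILES {smiles!r}"})
            continue
        records.append(MoleculeRecord(id=mol_id, smiles=canon, raw_label=label))
    if not records:
        raise InputError(f"no valid molecule rows in {path}")
    return records, rejects


def curate_dataset(records: Iterable[MoleculeRecord]) -> CuratedSet:
    """Merge duplicate structures and drop taste-ambiguous ones.

    Rules, applied on canonical SMILES:

    1. tasteless and bitter records map to the non-sweet class;
    2. records sharing a canonical SMILES and a class are merged to one
       (the first seen is retained);
    3. canonical-SMILES groups containing both a sweet and a non-sweet
       member are ambiguous and removed entirely.

    Every merge and removal is recorded in the log.  Idempotent.
    """
    log: list[dict] = [{"action": "canonicalization", "dialect": "rdkit-default"}]
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        groups.setdefault(rec.smiles, []).append(rec)

    curated: list[MoleculeRecord] = []
    for smiles, group in groups.items():
        classes = {r.class_label for r in group}
        if len(classes) > 1:
            log.append(
                {
                    "action": "removed_ambiguous",
                    "smiles": smiles,
                    "ids": [r.id for r in group],
                }
            )
            continue
        kept = group[0]
        if len(group) > 1:
            log.append(
                {
                    "action": "merged_duplicates",
                    "smiles": smiles,
                    "kept": kept.id,
                    "dropped": [r.id for r in group[1:]],
                }
            )
        curated.append(kept)
    return CuratedSet(records=curated, log=log)


def _feature_bit_positions(feature_id: int, params: FingerprintParams) -> list[int]:
    """Deterministic hash positions for one circular feature (salted double hashing)."""
    positions = []
    for salt in range(params.bits_per_pattern):
        digest = hashlib.blake2b(
            feature_id.to_bytes(8, "little", signed=False),
            digest_size=8,
            salt=salt.to_bytes(2, "little"),
        ).digest()
        positions.append(int.from_bytes(digest, "little") % params.n_bits)
    return positions


def morgan_feature_ids(smiles: str, radius: int) -> set[int]:
    """Unhashed circular-substructure feature identifiers up to ``radius``.

    Disconnected structures (salts) contribute the union of their fragments'
    feature sets, which is automatic in a presence/absence encoding.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES {smiles!r}")
    generator = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    sparse = generator.GetSparseCountFingerprint(mol)
    return set(sparse.GetNonzeroElements().keys())


def compute_fingerprints(
    records: Sequence[MoleculeRecord],
    params: FingerprintParams | None = None,
) -> tuple[FingerprintMatrix, list[dict]]:
    """Hashed circular fingerprints for a batch of molecules.

    Pure function of (canonical SMILES, params): identical SMILES give
    identical rows.  Molecules failing sanitization are reported per molecule
    in the error list and excluded from the matrix.
    """
    params = params or FingerprintParams()
    rows: list[np.ndarray] = []
    ids: list[str] = []
    errors: list[dict] = []
    cache: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.smiles in cache:
            ids.append(rec.id)
            rows.append(cache[rec.smiles])
            continue
        try:
            features = morgan_feature_ids(rec.smiles, params.max_order)
        except InputError as exc:
            errors.append({"id": rec.id, "reason": str(exc)})
            continue
        bits = np.zeros(params.n_bits, dtype=np.uint8)
        for feature in features:
            bits[_feature_bit_positions(feature, params)] = 1
        cache[rec.smiles] = bits
        ids.append(rec.id)
        rows.append(bits)
    matrix = np.vstack(rows) if rows else np.zeros((0, params.n_bits), dtype=np.uint8)
    return FingerprintMatrix(ids, matrix, params), errors


def read_descriptor_table(
    path: str | Path, block_map: str | Path | Mapping[str, str] | None = None
) -> DescriptorTable:
    """Read a CSV descriptor table (first column id, header of descriptor names)."""
    df = pd.read_csv(path, index_col=0)
    block_of: dict[str, str] | None = None
    if block_map is not None:
        if isinstance(block_map, (str, Path)):
            pairs = pd.read_csv(block_map)
            block_of = dict(zip(pairs.iloc[:, 0].astype(str), pairs.iloc[:, 1].astype(str)))
        else:
            block_of = dict(block_map)
    return DescriptorTable(
        list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float), block_of
    )


def clean_descriptor_table(
    table: DescriptorTable, near_constant_fraction: float = 0.95
) -> tuple[DescriptorTable, list[dict]]:
    """Drop descriptors with missing values or (near-)constant columns.

    A column is near-constant when its most frequent value occupies more than
    ``near_constant_fraction`` of the rows.
    """
    log: list[dict] = []
    keep: list[str] = []
    n = len(table.ids)
    for j, name in enumerate(table.names):
        col = table.values[:, j]
        if np.isnan(col).any():
            log.append({"descriptor": name, "reason": "missing values"})
            continue
        _, counts = np.unique(col, return_counts=True)
        if counts.max() > near_constant_fraction * n:
            log.append({"descriptor": name, "reason": "constant or near-constant"})
            continue
        keep.append(name)
    if not keep:
        warnings.warn("all descriptors removed by cleaning")
        return DescriptorTable(list(table.ids), [], np.zeros((n, 0)), {}), log
    return table.subset_columns(keep), log
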