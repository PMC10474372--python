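"""Drug and cell-line encoding plus training-pair assembly.

Drugs are encoded as 2048-bit Morgan (ECFP-like, radius 2) fingerprints via
RDKit; cell lines as binary mutation vectors or nonnegative log2(TPM+1)
expression vectors restricted and aligned to the ontology's gene list.
``assemble_pairs`` joins a long-format response table against both encodings,
dropping (and counting) unresolvable records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import LayeredHierarchy

__all__ = [
    "FingerprintVector",
    "CellFeatureMatrix",
    "ResponsePairSet",
    "smiles_to_fingerprint",
    "fingerprint_table",
    "load_cell_features",
    "assemble_pairs",
    "GLUCOSE_SMILES",
]

logger = logging.getLogger(__name__)

#: D-glucose, used as the drug-side reference compound for attribution.
GLUCOSE_SMILES = "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"

FINGERPRINT_BITS = 2048
FINGERPRINT_RADIUS = 2


@dataclass
class FingerprintVector:
    """A hashed circular substructure fingerprint of one drug."""

    bits: np.ndarray
    drug_id: str = ""
    smiles: str | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be binary")


def smiles_to_fingerprint(
    smiles: str,
    radius: int = FINGERPRINT_RADIUS,
    n_bits: int = FINGERPRINT_BITS,
    drug_id: str = "",
) -> FingerprintVector:
    """Encode a SMILES string as a hashed Morgan fingerprint bit vector.

    Deterministic for a given (SMILES, radius, n_bits).  Unparseable SMILES
    raise a ``ValueError`` naming the drug.  Hash collisions inherent to bit
    folding are accepted as-is.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise ValueError(f"unparseable SMILES for drug {drug_id or smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    fp = gen.GetFingerprint(mol)
    arr[list(fp.GetOnBits())] = 1
    return FingerprintVector(bits=arr, drug_id=drug_id, smiles=smiles)


def fingerprint_table(drug_table: pd.DataFrame, radius: int = FINGERPRINT_RADIUS,
                      n_bits: int = FINGERPRINT_BITS) -> dict[str, FingerprintVector]:
    """Encode a (drug id, SMILES) table; an explicitly listed but unparseable
    SMILES is an error, not a silent exclusion."""
    out: dict[str, FingerprintVector] = {}
    for drug_id, smiles in zip(drug_table.iloc[:, 0], drug_table.iloc[:, 1]):
        out[str(drug_id)] = smiles_to_fingerprint(
            str(smiles), radius=radius, n_bits=n_bits, drug_id=str(drug_id)
        )
    return out


@dataclass
class CellFeatureMatrix:
    """Cells x genes feature matrix aligned to a hierarchy's gene order.

    ``modality`` is ``"mutation"`` (binary) or ``"expression"``
    (log2(TPM+1), nonnegative).
    """

    values: np.ndarray
    cells: list[str]
    genes: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), len(self.genes)):
            raise ValueError("matrix shape does not match cell/gene lists")
        if self.modality == "mutation":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("mutation features must be binary (0/1)")
        elif self.modality == "expression":
            if np.any(self.values < 0):
                raise ValueError("expression features must be nonnegative")
        else:
            raise ValueError(f"unknown modality {self.modality!r}")
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    def row(self, cell_id: str) -> np.ndarray:
        return self.values[self._cell_index[cell_id]]

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._cell_index


def load_cell_features(
    source,
    modality: str,
    hierarchy: LayeredHierarchy,
    apply_log2: bool = False,
    sep: str = "\t",
) -> CellFeatureMatrix:
    """Read a cells x genes table and align its columns to the hierarchy.

    Columns absent from ``hierarchy.genes`` are dropped; hierarchy genes
    missing from the table are filled with the modality-neutral value 0.
    Both events are counted and logged.  ``apply_log2`` applies log2(x+1) to
    raw TPM values for the expression modality.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=sep, index_col=0)
    genes = list(hierarchy.genes)
    present = [g for g in genes if g in df.columns]
    dropped = df.shape[1] - len(present)
    missing = len(genes) - len(present)
    if dropped:
        logger.info("dropped %d feature column(s) without ontology annotation", dropped)
    if missing:
        logger.info("filled %d ontology gene(s) missing from the table with 0", missing)
    values = np.zeros((df.shape[0], len(genes)), dtype=float)
    aligned = df.reindex(columns=genes, fill_value=0.0)
    values[:] = aligned.to_numpy(dtype=float)
    if modality == "expression" and apply_log2:
        values = np.log2(values + 1.0)
    return CellFeatureMatrix(
        values=values, cells=[str(c) for c in df.index], genes=genes, modality=modality
    )


@dataclass
class ResponsePairSet:
    """(cell, drug, response, study) records resolvable to model inputs.

    Duplicate (cell, drug) pairs across studies are permitted and kept.
    ``cell_index`` maps each record to a row of the feature matrix and
    ``drug_ids`` to a fingerprint.
    """

    records: pd.DataFrame  # columns: cell, drug, response, study
    cell_index: np.ndarray  # record -> row in the feature matrix
    features: CellFeatureMatrix
    fingerprints: dict[str, FingerprintVector]
    exclusions: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def responses(self) -> np.ndarray:
        return self.records["response"].to_numpy(dtype=float)

    def cell_matrix(self) -> np.ndarray:
        """Feature rows for every record, in record order."""
        return self.features.values[self.cell_index]

    def drug_matrix(self) -> np.ndarray:
        """Fingerprint rows for every record, in record order."""
        return np.stack(
            [self.fingerprints[d].bits for d in self.records["drug"]]
        ).astype(float)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def assemble_pairs(
    responses: pd.DataFrame,
    features: CellFeatureMatrix,
    fingerprints: dict[str, FingerprintVector],
) -> ResponsePairSet:
    """Join a response table to features and fingerprints, dropping
    unresolvable records and reporting exclusion counts per cause.

    ``responses`` needs columns ``cell``, ``drug``, ``response`` and
    optionally ``study``.
    """
    df = responses.copy()
    if "study" not in df.columns:
        df["study"] = ""
    df["cell"] = df["cell"].astype(str)
    df["drug"] = df["drug"].astype(str)

    exclusions = {"missing_response": 0, "missing_features": 0, "missing_fingerprint": 0}
    keep = np.ones(len(df), dtype=bool)
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad = resp.isna().to_numpy()
    exclusions["missing_response"] = int(bad.sum())
    keep &= ~bad
    no_feat = ~df["cell"].isin(features.cells).to_numpy()
    exclusions["missing_features"] = int((keep & no_feat).sum())
    keep &= ~no_feat
    no_fp = ~df["drug"].isin(fingerprints.keys()).to_numpy()
    exclusions["missing_fingerprint"] = int((keep & no_fp).sum())
    keep &= ~no_fp

    kept = df.loc[keep, ["cell", "drug", "response", "study"]].reset_index(drop=True)
    kept["response"] = resp[keep].to_numpy(dtype=float)
    if kept.empty:
        raise ValueError(f"no resolvable (cell, drug) pairs; exclusions: {exclusions}")
    for cause, n in exclusions.items():
        if n:
            logger.info("excluded %d record(s): %s", n, cause)
    cell_index = np.array([features._cell_index[c] for c in kept["cell"]], dtype=int)
    return ResponsePairSet(
        records=kept,
        cell_index=cell_index,
        features=features,
        fingerprints=fingerprints,
        exclusions=exclusions,
    )


def read_pairs_tsv(path, features: CellFeatureMatrix,
                   fingerprints: dict[str, FingerprintVector]) -> ResponsePairSet:
    """Round-trip reader for :meth:`ResponsePairSet.to_tsv`."""
    return assemble_pairs(pd.read_csv(path, sep="\t"), features, fingerprints)
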