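"""Structural similarity profiles (SSP).

Every node of the DFI network — drug or food constituent — is a small
molecule, so both node types can share one attribute space: a molecule's
SSP is the vector of its fingerprint similarities to each member of a fixed
reference panel of approved drugs.  With a panel of size ``P`` every node
gets a ``P``-dimensional feature vector with entries in [0, 1]; a molecule
that is itself panel member ``r`` has a 1.0 in column ``r``.

Fingerprints are circular (Morgan/ECFP-like) substructure fingerprints of
radius 2 hashed to 2048 bits by default, compared with Tanimoto similarity;
both the fingerprint parameters and the panel are configurable, and a
precomputed SSP matrix can be loaded directly, bypassing chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


def morgan_fingerprint(
    smiles: str, radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    """Circular substructure fingerprint of a SMILES string as a 0/1 array.

    Raises ``ValueError`` for unparseable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two binary fingerprints.

    Defined as 0.0 when both fingerprints are all-zero; raises on length
    mismatch.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(a, b).sum())
    return inter / union


@dataclass
class SSPMatrix:
    """Nodes x reference-panel matrix of structural similarities in [0, 1]."""

    node_ids: list[str]
    reference_ids: list[str]
    values: np.ndarray  # shape (len(node_ids), len(reference_ids))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_ids), len(self.reference_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.node_ids)} nodes x {len(self.reference_ids)} references"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in SSP matrix")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("SSP entries must lie in [0, 1]")

    @property
    def width(self) -> int:
        return len(self.reference_ids)

    def row(self, node_id: str) -> np.ndarray:
        return self.values[self.node_ids.index(node_id)]

    def aligned_to(self, node_order: Sequence[str]) -> np.ndarray:
        """Rows re-ordered to ``node_order``; errors on missing nodes."""
        index = {n: i for i, n in enumerate(self.node_ids)}
        missing = [n for n in node_order if n not in index]
        if missing:
            raise KeyError(f"nodes without SSP rows: {missing[:5]}")
        return self.values[[index[n] for n in node_order]]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.node_ids, columns=self.reference_ids)
        df.to_csv(path, sep="\t", index_label="node_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SSPMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            node_ids=[str(i) for i in df.index],
            reference_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


def compute_ssp(
    molecules: Sequence[tuple[str, str]],
    reference: Sequence[tuple[str, str]],
    radius: int = 2,
    n_bits: int = 2048,
) -> SSPMatrix:
    """Compute the SSP matrix of ``molecules`` against a ``reference`` panel.

    Both arguments are sequences of ``(id, SMILES)``.  Entry ``(i, r)`` is
    the Tanimoto similarity between molecule ``i`` and panel member ``r``;
    row order follows the input order.  Unparseable SMILES raise an error
    naming the offending id; duplicate ids are rejected.
    """
    if not reference:
        raise ValueError("reference panel must be non-empty")
    for ids, kind in ((molecules, "molecule"), (reference, "reference")):
        names = [i for i, _ in ids]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate {kind} ids")

    def fp_of(node_id: str, smiles: str) -> np.ndarray:
        try:
            return morgan_fingerprint(smiles, radius=radius, n_bits=n_bits)
        except ValueError as exc:
            raise ValueError(f"{node_id}: {exc}") from exc

    ref_fps = [fp_of(i, s) for i, s in reference]
    rows = np.empty((len(molecules), len(reference)), dtype=float)
    for i, (mid, smi) in enumerate(molecules):
        fp = fp_of(mid, smi)
        for r, rfp in enumerate(ref_fps):
            rows[i, r] = tanimoto(fp, rfp)
    return SSPMatrix(
        node_ids=[i for i, _ in molecules],
        reference_ids=[i for i, _ in reference],
        values=rows,
    )


def load_smiles_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV (id, SMILES)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["id", "smiles"], dtype=str
    )
    if len(df) and df.iloc[0]["smiles"].lower() in {"smiles", "smile"}:
        df = df.iloc[1:]
    return [(str(r.id), str(r.smiles)) for r in df.itertuples(index=False)]
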