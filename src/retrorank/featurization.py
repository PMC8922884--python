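"""Molecular featurization for the energy models.

Two representations:

* **Morgan count fingerprints** (default length 16384, radius 3), stored
  sparse and densified at model input. A reaction is featurized as the
  triple ``(P_in, R_in, D_in)`` where ``R_in`` is the elementwise sum of
  reactant fingerprints and ``D_in = P_in - R_in`` is the signed difference
  fingerprint capturing fragments lost and gained during the reaction.
* **Attributed molecular graphs** for the message-passing encoder: one node
  per heavy atom with element/charge/degree/aromaticity/chirality/H-count
  features, one undirected edge per bond with bond-order/conjugation/ring
  features. The feature schema is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .reaction_io import Reaction, SmilesParseError, canonical_smiles

__all__ = [
    "CountFingerprint",
    "MolGraph",
    "FingerprintConfig",
    "GraphFeatureConfig",
    "morgan_count_fingerprint",
    "reaction_fingerprints",
    "mol_to_graph",
]


def _mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return m


# ---------------------------------------------------------------------------
# Count fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintConfig:
    length: int = 16384
    radius: int = 3
    chirality: bool = True

    def to_json(self) -> dict:
        return {"length": self.length, "radius": self.radius,
                "chirality": self.chirality}

    @staticmethod
    def from_json(d: dict) -> "FingerprintConfig":
        return FingerprintConfig(**d)


@dataclass
class CountFingerprint:
    """Sparse integer count vector of hashed circular environments.

    Per-molecule fingerprints are elementwise >= 0; signed difference
    fingerprints may carry negative counts.
    """

    indices: np.ndarray  # int64, sorted ascending
    counts: np.ndarray   # int64, nonzero
    length: int
    radius: int

    def to_dense(self, dtype=np.float64) -> np.ndarray:
        dense = np.zeros(self.length, dtype=dtype)
        dense[self.indices] = self.counts
        return dense

    def total(self) -> int:
        return int(self.counts.sum())

    def _binop(self, other: "CountFingerprint", sign: int) -> "CountFingerprint":
        if other.length != self.length or other.radius != self.radius:
            raise ValueError("fingerprint config mismatch")
        idx = np.concatenate([self.indices, other.indices])
        cnt = np.concatenate([self.counts, sign * other.counts])
        order = np.argsort(idx, kind="stable")
        idx, cnt = idx[order], cnt[order]
        uniq, start = np.unique(idx, return_index=True)
        sums = np.add.reduceat(cnt, start)
        keep = sums != 0
        return CountFingerprint(uniq[keep], sums[keep], self.length, self.radius)

    def __add__(self, other: "CountFingerprint") -> "CountFingerprint":
        return self._binop(other, +1)

    def __sub__(self, other: "CountFingerprint") -> "CountFingerprint":
        return self._binop(other, -1)


def morgan_count_fingerprint(
    smiles: str,
    radius: int = 3,
    length: int = 16384,
    chirality: bool = True,
) -> CountFingerprint:
    """Hashed Morgan count fingerprint of one molecule (possibly multi-component).

    Counts circular substructure environments up to ``radius``, folded to
    ``length`` positions by modular hashing; invariant to the SMILES writing
    of the same molecule.
    """
    if length < 1 or radius < 0:
        raise ValueError("length must be >= 1 and radius >= 0")
    mol = _mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=length, includeChirality=chirality
    )
    fp = gen.GetCountFingerprint(mol)
    nz = fp.GetNonzeroElements()
    if not nz:
        return CountFingerprint(
            np.empty(0, np.int64), np.empty(0, np.int64), length, radius
        )
    idx = np.array(sorted(nz), dtype=np.int64)
    cnt = np.array([nz[i] for i in idx], dtype=np.int64)
    return CountFingerprint(idx, cnt, length, radius)


def reaction_fingerprints(
    reaction: Reaction,
    config: FingerprintConfig = FingerprintConfig(),
) -> tuple[CountFingerprint, CountFingerprint, CountFingerprint]:
    """(P_in, R_in, D_in) for one reaction.

    Reactants are canonically sorted before summation so the result — down
    to floating-point bit patterns downstream — is invariant to reactant
    order. D_in = P_in - R_in.
    """
    p_in = morgan_count_fingerprint(
        reaction.product_smiles, config.radius, config.length, config.chirality
    )
    reactants = sorted(canonical_smiles(s) for s in reaction.reactant_smiles)
    r_in = morgan_count_fingerprint(
        reactants[0], config.radius, config.length, config.chirality
    )
    for smi in reactants[1:]:
        r_in = r_in + morgan_count_fingerprint(
            smi, config.radius, config.length, config.chirality
        )
    return p_in, r_in, p_in - r_in


def fingerprint_reactant_set(
    reactant_smiles: Sequence[str],
    config: FingerprintConfig = FingerprintConfig(),
) -> CountFingerprint:
    """Summed fingerprint of a reactant set (canonically ordered sum)."""
    smis = sorted(canonical_smiles(s) for s in reactant_smiles)
    if not smis:
        raise ValueError("empty reactant set")
    acc = morgan_count_fingerprint(smis[0], config.radius, config.length,
                                   config.chirality)
    for smi in smis[1:]:
        acc = acc + morgan_count_fingerprint(smi, config.radius, config.length,
                                             config.chirality)
    return acc


# ---------------------------------------------------------------------------
# Molecular graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphFeatureConfig:
    """Configurable atom/bond feature schema.

    Out-of-vocabulary elements map to a shared "other" slot; degree and
    H-count one-hots saturate at their maxima.
    """

    elements: tuple[str, ...] = (
        "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Sn",
    )
    max_degree: int = 5
    max_h: int = 4
    charge_range: tuple[int, int] = (-2, 2)
    chirality: bool = True

    @property
    def atom_dim(self) -> int:
        n_charge = self.charge_range[1] - self.charge_range[0] + 1
        dim = (len(self.elements) + 1) + (self.max_degree + 1) + n_charge + 1 \
            + (self.max_h + 1)
        if self.chirality:
            dim += 3
        return dim

    @property
    def bond_dim(self) -> int:
        return 6  # single/double/triple/aromatic + conjugated + in-ring

    def to_json(self) -> dict:
        return {
            "elements": list(self.elements),
            "max_degree": self.max_degree,
            "max_h": self.max_h,
            "charge_range": list(self.charge_range),
            "chirality": self.chirality,
        }

    @staticmethod
    def from_json(d: dict) -> "GraphFeatureConfig":
        d = dict(d)
        d["elements"] = tuple(d["elements"])
        d["charge_range"] = tuple(d["charge_range"])
        return GraphFeatureConfig(**d)


@dataclass
class MolGraph:
    """Attributed molecular graph: one node per heavy atom, one undirected
    edge per bond."""

    atom_features: np.ndarray            # (n_atoms, atom_dim)
    bonds: np.ndarray                    # (n_bonds, 2) int, u < ordering as parsed
    bond_features: np.ndarray            # (n_bonds, bond_dim)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]


_CHIRAL_TAGS = {
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
}

_BOND_ORDER = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def _atom_features(atom: Chem.Atom, cfg: GraphFeatureConfig) -> np.ndarray:
    feats = []
    elem = np.zeros(len(cfg.elements) + 1)
    try:
        elem[cfg.elements.index(atom.GetSymbol())] = 1.0
    except ValueError:
        elem[-1] = 1.0
    feats.append(elem)
    deg = np.zeros(cfg.max_degree + 1)
    deg[min(atom.GetDegree(), cfg.max_degree)] = 1.0
    feats.append(deg)
    lo, hi = cfg.charge_range
    charge = np.zeros(hi - lo + 1)
    charge[int(np.clip(atom.GetFormalCharge(), lo, hi)) - lo] = 1.0
    feats.append(charge)
    feats.append(np.array([1.0 if atom.GetIsAromatic() else 0.0]))
    hs = np.zeros(cfg.max_h + 1)
    hs[min(atom.GetTotalNumHs(), cfg.max_h)] = 1.0
    feats.append(hs)
    if cfg.chirality:
        chi = np.zeros(3)
        chi[_CHIRAL_TAGS.get(atom.GetChiralTag(), 0)] = 1.0
        feats.append(chi)
    return np.concatenate(feats)


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    f = np.zeros(6)
    f[_BOND_ORDER.get(bond.GetBondType(), 0)] = 1.0
    f[4] = 1.0 if bond.GetIsConjugated() else 0.0
    f[5] = 1.0 if bond.IsInRing() else 0.0
    return f


def mol_to_graph(
    smiles: str,
    config: GraphFeatureConfig = GraphFeatureConfig(),
) -> MolGraph:
    """Featurize a molecule as an attributed graph.

    Relabeling the input atom order permutes the node list consistently
    with bond endpoints (permutation covariance).
    """
    mol = _mol(smiles)
    atoms = np.array(
        [_atom_features(a, config) for a in mol.GetAtoms()], dtype=np.float64
    ).reshape(mol.GetNumAtoms(), config.atom_dim)
    bonds, bfeats = [], []
    for bond in mol.GetBonds():
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bfeats.append(_bond_features(bond))
    bonds_arr = (
        np.array(bonds, dtype=np.int64)
        if bonds else np.empty((0, 2), dtype=np.int64)
    )
    bfeats_arr = (
        np.array(bfeats, dtype=np.float64)
        if bfeats else np.empty((0, config.bond_dim), dtype=np.float64)
    )
    return MolGraph(atoms, bonds_arr, bfeats_arr)
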