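"""Reaction and proposal-table I/O, canonical matching keys, checkpoints.

Reactions arrive as USPTO-50K-style CSV rows (``id,class,rxn_smiles`` with
``rxn_smiles = reactants>reagents>product``). Candidate reactant-sets are
matched everywhere by :func:`canonical_reactant_set_key` — the dot-join of
canonical, atom-map-stripped SMILES sorted lexicographically — so that
"exactly matches the published reactant-set" is robust to SMILES dialects,
atom maps and reactant order.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Reaction",
    "Provenance",
    "Candidate",
    "CandidateSet",
    "ProposalTable",
    "ReactionFormatError",
    "SmilesParseError",
    "CheckpointMismatchError",
    "strip_atom_maps",
    "canonical_smiles",
    "canonical_reactant_set_key",
    "read_reaction_dataset",
    "write_reaction_dataset",
    "read_proposals",
    "write_proposals",
    "write_reranked",
    "read_reranked",
    "save_checkpoint",
    "load_checkpoint",
]


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed into a molecule."""


class ReactionFormatError(ValueError):
    """Input file violates the expected schema."""


class CheckpointMismatchError(ValueError):
    """Checkpoint featurization/config does not match what was requested."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def strip_atom_maps(smiles: str) -> str:
    """Remove atom-map annotations, returning canonical SMILES.

    Molecule identity is unchanged; raises :class:`SmilesParseError` naming
    the offending string if the input does not parse.
    """
    mol = _mol_from_smiles(smiles)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def canonical_smiles(smiles: str) -> str:
    """Canonical, atom-map-free SMILES for one molecule."""
    return strip_atom_maps(smiles)


def canonical_reactant_set_key(reactants: Sequence[str]) -> str:
    """Order- and atom-map-invariant key for a reactant multiset.

    The key is the dot-join of canonical map-stripped SMILES sorted
    lexicographically. An empty reactant list is a contract violation.
    """
    if len(reactants) == 0:
        raise ValueError("empty reactant set has no key")
    return ".".join(sorted(canonical_smiles(smi) for smi in reactants))


@dataclass(frozen=True)
class Reaction:
    """One published reaction: product, reactant-set, optional class label."""

    id: str
    product_smiles: str
    reactant_smiles: tuple[str, ...]
    rxn_class: int | None = None

    @property
    def product_key(self) -> str:
        return canonical_smiles(self.product_smiles)

    @property
    def reactant_key(self) -> str:
        return canonical_reactant_set_key(self.reactant_smiles)


@dataclass(frozen=True)
class Provenance:
    """Where a candidate came from: proposer name, its 1-based rank, score."""

    proposer: str
    rank: int
    score: float | None = None


@dataclass
class Candidate:
    key: str
    reactant_smiles: tuple[str, ...]
    provenance: list[Provenance] = field(default_factory=list)

    @property
    def best_rank(self) -> int:
        return min(p.rank for p in self.provenance)

    @property
    def best_proposer(self) -> str:
        best = min(self.provenance, key=lambda p: (p.rank, p.proposer))
        return best.proposer


@dataclass
class CandidateSet:
    """Ranked candidate reactant-sets for one product.

    ``candidates`` is ordered ascending by best original proposer rank with
    proposer-name tie-break; keys are unique within the set. ``true_key`` is
    the published reactant-set's key when known.
    """

    product_key: str
    product_smiles: str
    candidates: list[Candidate] = field(default_factory=list)
    true_key: str | None = None

    def sort(self) -> None:
        self.candidates.sort(key=lambda c: (c.best_rank, c.best_proposer, c.key))

    def add(self, reactant_smiles: Sequence[str], prov: Provenance) -> None:
        key = canonical_reactant_set_key(reactant_smiles)
        for cand in self.candidates:
            if cand.key == key:
                cand.provenance.append(prov)
                return
        self.candidates.append(
            Candidate(key=key, reactant_smiles=tuple(reactant_smiles), provenance=[prov])
        )


ProposalTable = dict[str, CandidateSet]
"""Map product_key -> CandidateSet."""


# ---------------------------------------------------------------------------
# Reaction dataset CSV
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = ("id", "class", "rxn_smiles")


def read_reaction_dataset(path: str | Path, split_tag: str = "") -> list[Reaction]:
    """Read a USPTO-50K-style reaction CSV.

    The reagents field (between the two ``>``) is discarded; reactants are
    split on ``.``. Malformed rows are skipped with a logged count. Raises
    :class:`ReactionFormatError` on missing columns or zero valid rows.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _REACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ReactionFormatError(f"{path}: missing columns {missing}")
    reactions: list[Reaction] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            parts = str(row.rxn_smiles).split(">")
            if len(parts) != 3:
                raise ReactionFormatError("reaction SMILES needs 2 '>' separators")
            reactants_field, _reagents, product_field = parts
            product = strip_atom_maps(product_field)
            reactants = tuple(
                strip_atom_maps(r) for r in reactants_field.split(".") if r
            )
            if not reactants:
                raise ReactionFormatError("no reactants")
            rxn_class = None if pd.isna(row[1]) else int(row[1])
            reactions.append(
                Reaction(
                    id=str(row.id),
                    product_smiles=product,
                    reactant_smiles=reactants,
                    rxn_class=rxn_class,
                )
            )
        except (SmilesParseError, ReactionFormatError, ValueError) as exc:
            skipped += 1
            logger.debug("skipping row %r: %s", row.id, exc)
    tag = f" [{split_tag}]" if split_tag else ""
    logger.info(
        "read %d reactions%s from %s (%d malformed rows skipped)",
        len(reactions), tag, path, skipped,
    )
    if not reactions:
        raise ReactionFormatError(f"{path}: no valid reactions")
    return reactions


def write_reaction_dataset(path: str | Path, reactions: Iterable[Reaction]) -> None:
    rows = [
        {
            "id": r.id,
            "class": r.rxn_class if r.rxn_class is not None else "",
            "rxn_smiles": ".".join(r.reactant_smiles) + ">>" + r.product_smiles,
        }
        for r in reactions
    ]
    pd.DataFrame(rows, columns=list(_REACTION_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Proposal tables
# ---------------------------------------------------------------------------

_PROPOSAL_COLUMNS = ("product", "proposer", "rank", "candidate", "score")


def read_proposals(
    path: str | Path,
    true_keys: Mapping[str, str] | None = None,
) -> ProposalTable:
    """Read a tidy proposal CSV (``product,proposer,rank,candidate,score``).

    Rows are grouped by product; within a product, candidates with the same
    reactant-set key are merged, concatenating provenance. Invalid candidate
    SMILES are dropped with a logged count (template-free proposers emit
    invalid SMILES routinely). Duplicate ``(product, proposer, rank)`` rows
    are a format error. ``true_keys`` optionally maps product key -> the
    published reactant-set key.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"product": str, "proposer": str, "candidate": str})
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    missing = [c for c in _PROPOSAL_COLUMNS if c not in df.columns]
    if missing:
        raise ReactionFormatError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["product", "proposer", "rank"])
    if dup.any():
        bad = df.loc[dup, ["product", "proposer", "rank"]].iloc[0]
        raise ReactionFormatError(
            f"{path}: duplicate (product, proposer, rank) = "
            f"({bad['product']!r}, {bad['proposer']!r}, {bad['rank']})"
        )
    table: ProposalTable = {}
    dropped = 0
    df = df.sort_values(["product", "proposer", "rank"], kind="stable")
    for row in df.itertuples(index=False):
        try:
            product_key = canonical_smiles(row.product)
        except SmilesParseError:
            dropped += 1
            continue
        rank = int(row.rank)
        if rank < 1:
            raise ReactionFormatError(f"{path}: rank must be >= 1, got {rank}")
        score = None if pd.isna(row.score) else float(row.score)
        reactants = tuple(s for s in str(row.candidate).split(".") if s)
        cs = table.get(product_key)
        if cs is None:
            cs = CandidateSet(product_key=product_key, product_smiles=row.product)
            if true_keys is not None:
                cs.true_key = true_keys.get(product_key)
            table[product_key] = cs
        try:
            cs.add(reactants, Provenance(str(row.proposer), rank, score))
        except SmilesParseError:
            dropped += 1
    for cs in table.values():
        cs.sort()
    if dropped:
        logger.info("dropped %d invalid candidate rows from %s", dropped, path)
    return table


def write_proposals(path: str | Path, table: ProposalTable) -> None:
    """Write a ProposalTable back to the tidy CSV exchange format."""
    rows = []
    for product_key in sorted(table):
        cs = table[product_key]
        for cand in cs.candidates:
            for prov in cand.provenance:
                rows.append(
                    {
                        "product": cs.product_smiles,
                        "proposer": prov.proposer,
                        "rank": prov.rank,
                        "candidate": ".".join(cand.reactant_smiles),
                        "score": "" if prov.score is None else repr(prov.score),
                    }
                )
    pd.DataFrame(rows, columns=list(_PROPOSAL_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Re-ranked results (JSON lines)
# ---------------------------------------------------------------------------

def write_reranked(path: str | Path, results: Sequence["RerankResult"]) -> None:
    """Serialize rerank results as JSON lines; floats survive exactly (hex)."""
    with open(path, "w") as fh:
        for res in results:
            fh.write(json.dumps(res.to_json()) + "\n")


def read_reranked(path: str | Path) -> list["RerankResult"]:
    from .evaluation import RerankResult

    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(RerankResult.from_json(json.loads(line)))
    return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    params: Mapping[str, np.ndarray],
    config: Mapping,
) -> None:
    """Write a single-file archive: JSON config + raw parameter arrays.

    Reload reproduces bit-identical parameters, hence bit-identical energies
    on the same platform.
    """
    path = Path(path)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("config.json", json.dumps(dict(config), indent=2, sort_keys=True))
        for name, arr in params.items():
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr), allow_pickle=False)
            zf.writestr(f"params/{name}.npy", buf.getvalue())


def load_checkpoint(
    path: str | Path,
    expect_variant: str | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Load a checkpoint archive; optionally assert the model variant tag."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        config = json.loads(zf.read("config.json"))
        params = {}
        for info in zf.infolist():
            if info.filename.startswith("params/") and info.filename.endswith(".npy"):
                name = info.filename[len("params/"):-len(".npy")]
                params[name] = np.load(io.BytesIO(zf.read(info.filename)),
                                       allow_pickle=False)
    if expect_variant is not None and config.get("variant") != expect_variant:
        raise CheckpointMismatchError(
            f"{path}: checkpoint variant {config.get('variant')!r} "
            f"!= requested {expect_variant!r}"
        )
    return params, config
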