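"""Desk-scale synthetic reactions and proposer outputs with planted structure.

The generator emulates the situation the re-ranker is trained in: a
proposer that puts the published reactant-set at rank 1 only some of the
time (and sometimes misses it entirely), surrounded by near-miss decoys.
Reactions are C–C couplings built by joining two library fragments; the
true reactant pair is the two fragments with a leaving-group halide on the
bond-forming atom of one of them, so the difference fingerprint carries
the lost-halide / formed-bond signature of real reactions.

Decoy taxonomy (mixture weights configurable):

* **leaving-group swap** — the true reactants with the halide exchanged;
  the hardest negatives ("differing by the identity of a leaving group").
* **fragment swap** — one true reactant replaced by a random library
  fragment.
* **random pair** — two random fragments, one halogenated.

The true leaving group is fixed per dataset (Br by default) while swap
decoys draw from the other halogens: the planted task is learnable
because the truth carries a consistent signature, not because decoys are
malformed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol

from .featurization import FingerprintConfig, morgan_count_fingerprint
from .reaction_io import (
    CandidateSet,
    ProposalTable,
    Provenance,
    Reaction,
    canonical_reactant_set_key,
    canonical_smiles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "generate_fragment_library",
    "generate_reactions",
    "generate_proposals",
    "planted_separability_check",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of the planted re-ranking task.

    ``p1`` is the unconditional probability that the proposer puts the
    truth at rank 1; with probability ``absent_prob`` the truth is missing
    from the pool entirely (the proposer's recall ceiling is then
    ``1 - absent_prob``); the rest of the truth-rank mass decays
    geometrically (factor ``rank_decay``) over ranks 2..K.
    """

    n_products: int = 2000
    k_candidates: int = 10
    p1: float = 0.3
    rank_decay: float = 0.6
    absent_prob: float = 0.05
    decoy_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    library_size: int = 150
    true_leaving_group: str = "Br"
    decoy_leaving_groups: tuple[str, ...] = ("F", "Cl", "I")
    proposer_name: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_products < 1:
            raise ValueError("n_products must be >= 1")
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.absent_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p1 + self.absent_prob > 1.0:
            raise ValueError("p1 + absent_prob must be <= 1")
        if abs(sum(self.decoy_weights) - 1.0) > 1e-9:
            raise ValueError("decoy mixture weights must sum to 1")


# ---------------------------------------------------------------------------
# Fragment library
# ---------------------------------------------------------------------------

_CORES = (
    "C*", "CC*", "CCC*", "CCCC*", "CC(C)*", "CC(C)C*", "CCCCC*",
    "C1CCCC1*", "C1CCCCC1*", "C1CCOCC1*", "C1CCNCC1*",
    "c1ccccc1*", "Cc1ccccc1*", "c1ccncc1*", "c1ccc(C)cc1*",
    "c1ccco1*", "c1cccs1*", "CCOC(C*)", "CC(C*)C",
)

_SUBSTITUENTS = (
    "O", "N", "Cl", "Br", "F", "C#N", "C(=O)O", "C(=O)OC", "OC",
    "C(=O)N", "S", "CO", "CCO", "NC",
)


def generate_fragment_library(size: int, seed: int) -> list[str]:
    """Distinct canonical small-molecule SMILES from a fixed core x
    substituent grammar; deterministic per seed."""
    if size < 2:
        raise ValueError("library size must be >= 2")
    seen: dict[str, None] = {}
    for core, sub in itertools.product(_CORES, _SUBSTITUENTS):
        smi = core.replace("*", sub)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        seen.setdefault(canonical_smiles(Chem.MolToSmiles(mol)))
    frags = list(seen)
    if size > len(frags):
        raise ValueError(
            f"grammar yields only {len(frags)} distinct fragments (< {size})"
        )
    rng = np.random.default_rng([seed, 101])
    return [frags[i] for i in rng.permutation(len(frags))[:size]]


# ---------------------------------------------------------------------------
# Reactions
# ---------------------------------------------------------------------------

def _open_carbons(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _attach(smiles: str, atom_idx: int, group: str) -> str | None:
    """Bond a single-atom group (halide etc.) onto the given atom."""
    mol = RWMol(Chem.MolFromSmiles(smiles))
    new = mol.AddAtom(Chem.Atom(group))
    mol.AddBond(int(atom_idx), new, Chem.BondType.SINGLE)
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def _join_fragments(
    a_smi: str, b_smi: str, rng: np.random.Generator, leaving_group: str
) -> tuple[str, str, str] | None:
    """(product, halogenated-A, B) or None when no open valence fits."""
    a, b = Chem.MolFromSmiles(a_smi), Chem.MolFromSmiles(b_smi)
    open_a, open_b = _open_carbons(a), _open_carbons(b)
    if not open_a or not open_b:
        return None
    ia = int(rng.choice(open_a))
    ib = int(rng.choice(open_b))
    combo = RWMol(Chem.CombineMols(a, b))
    combo.AddBond(ia, a.GetNumAtoms() + ib, Chem.BondType.SINGLE)
    try:
        product = combo.GetMol()
        Chem.SanitizeMol(product)
    except Exception:
        return None
    r1 = _attach(a_smi, ia, leaving_group)
    if r1 is None:
        return None
    return Chem.MolToSmiles(product), r1, canonical_smiles(b_smi)


def _product_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # one global seed derives independent per-product streams
    return np.random.default_rng([seed, stream, index])


def generate_reactions(
    library: list[str], n: int, seed: int, leaving_group: str = "Br",
    max_tries: int = 50,
) -> list[Reaction]:
    """n synthetic coupling reactions over a fragment library.

    Each product joins two fragments at randomly chosen open valences; the
    true reactants are the fragments with a leaving-group halide on the
    bond-forming atom of the first. Deterministic per seed.
    """
    if len(library) < 2:
        raise ValueError("fragment library must hold >= 2 fragments")
    reactions = []
    for i in range(n):
        rng = _product_rng(seed, 1, i)
        for _ in range(max_tries):
            ai, bi = rng.choice(len(library), size=2, replace=False)
            joined = _join_fragments(library[ai], library[bi], rng, leaving_group)
            if joined is None:
                continue
            product, r1, r2 = joined
            reactions.append(
                Reaction(
                    id=f"syn-{i}",
                    product_smiles=product,
                    reactant_smiles=(r1, r2),
                    rxn_class=int(rng.integers(1, 11)),
                )
            )
            break
        else:
            raise RuntimeError(
                f"could not build a joinable fragment pair for product {i} "
                f"after {max_tries} tries"
            )
    return reactions


# ---------------------------------------------------------------------------
# Proposals
# ---------------------------------------------------------------------------

def _swap_halogen(reactant_smiles: tuple[str, ...], old: str, new: str,
                  rng: np.random.Generator) -> tuple[str, ...] | None:
    """Replace one occurrence of halogen ``old`` by ``new`` in a random
    reactant carrying it."""
    carriers = [
        i for i, smi in enumerate(reactant_smiles)
        if any(a.GetSymbol() == old for a in Chem.MolFromSmiles(smi).GetAtoms())
    ]
    if not carriers:
        return None
    which = int(rng.choice(carriers))
    mol = RWMol(Chem.MolFromSmiles(reactant_smiles[which]))
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == old]
    mol.GetAtomWithIdx(int(rng.choice(sites))).SetAtomicNum(
        Chem.Atom(new).GetAtomicNum()
    )
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    swapped = list(reactant_smiles)
    swapped[which] = Chem.MolToSmiles(out)
    return tuple(swapped)


def _truth_rank(spec: SyntheticSpec, rng: np.random.Generator) -> int | None:
    """Planted rank of the truth: None (absent), 1 with prob p1, else a
    truncated-geometric tail over ranks 2..K."""
    u = rng.random()
    if u < spec.absent_prob:
        return None
    if u < spec.absent_prob + spec.p1:
        return 1
    k = spec.k_candidates
    if k == 1:
        return 1
    weights = spec.rank_decay ** np.arange(k - 1)
    weights /= weights.sum()
    return 2 + int(rng.choice(k - 1, p=weights))


def _make_decoy(
    kind: int,
    reaction: Reaction,
    library: list[str],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[str, ...] | None:
    if kind == 0:  # leaving-group swap
        new = str(rng.choice(spec.decoy_leaving_groups))
        return _swap_halogen(reaction.reactant_smiles,
                             spec.true_leaving_group, new, rng)
    if kind == 1:  # one-fragment replacement
        which = int(rng.integers(len(reaction.reactant_smiles)))
        repl = library[int(rng.integers(len(library)))]
        out = list(reaction.reactant_smiles)
        out[which] = repl
        return tuple(out)
    # random halogenated pair
    ai, bi = rng.choice(len(library), size=2, replace=False)
    a = Chem.MolFromSmiles(library[ai])
    open_a = _open_carbons(a)
    if not open_a:
        return None
    r1 = _attach(library[ai], int(rng.choice(open_a)), spec.true_leaving_group)
    if r1 is None:
        return None
    return (r1, library[bi])


def generate_proposals(
    reactions: list[Reaction], spec: SyntheticSpec
) -> ProposalTable:
    """Planted proposer output for every reaction (deterministic per seed).

    Per product: K candidates, the truth at a rank drawn from the planted
    distribution (or absent), the rest decoys from the configured mixture,
    deduplicated by canonical key. When K distinct candidates cannot be
    built the product's list is shorter (logged).
    """
    library = generate_fragment_library(spec.library_size, spec.seed)
    weights = np.asarray(spec.decoy_weights, dtype=np.float64)
    table: ProposalTable = {}
    short = 0
    for idx, reaction in enumerate(reactions):
        rng = _product_rng(spec.seed, 2, idx)
        true_key = reaction.reactant_key
        rank = _truth_rank(spec, rng)
        n_decoys = spec.k_candidates - (0 if rank is None else 1)
        decoys: list[tuple[str, ...]] = []
        seen = {true_key}
        tries = 0
        while len(decoys) < n_decoys and tries < 40 * spec.k_candidates:
            tries += 1
            kind = int(rng.choice(3, p=weights))
            cand = _make_decoy(kind, reaction, library, spec, rng)
            if cand is None:
                continue
            try:
                key = canonical_reactant_set_key(cand)
            except Exception:
                continue
            if key in seen:
                continue
            seen.add(key)
            decoys.append(cand)
        if len(decoys) < n_decoys:
            short += 1
        cs = CandidateSet(
            product_key=reaction.product_key,
            product_smiles=reaction.product_smiles,
            true_key=true_key,
        )
        slot = iter(decoys)
        for r in range(1, 1 + len(decoys) + (0 if rank is None else 1)):
            if rank is not None and r == min(rank, len(decoys) + 1):
                cand = reaction.reactant_smiles
            else:
                cand = next(slot)
            cs.add(cand, Provenance(spec.proposer_name, r))
        cs.sort()
        table[reaction.product_key] = cs
    if short:
        logger.info("%d products received fewer than K distinct candidates",
                    short)
    return table


# ---------------------------------------------------------------------------
# Separability oracle
# ---------------------------------------------------------------------------

def planted_separability_check(
    table: ProposalTable,
    reactions: list[Reaction],
    fp_length: int = 2048,
) -> float:
    """Fraction of products whose truth maximizes a simple overlap oracle.

    The oracle score of a candidate is the number of folded fingerprint
    positions it shares with the product. Ties with the truth count as
    separable; a product whose pool lacks the truth does not. A high value
    certifies the planted task is learnable by fingerprint models.
    """
    if not table:
        raise ValueError("empty proposal table")
    cfg = FingerprintConfig(length=fp_length)
    true_keys = {r.product_key: r.reactant_key for r in reactions}
    hits = 0
    for product_key in sorted(table):
        cs = table[product_key]
        true_key = true_keys.get(product_key, cs.true_key)
        prod_pos = set(
            morgan_count_fingerprint(cs.product_smiles, cfg.radius,
                                     cfg.length).indices.tolist()
        )

        def score(cand) -> int:
            from .featurization import fingerprint_reactant_set

            fp = fingerprint_reactant_set(cand.key.split("."), cfg)
            return len(prod_pos.intersection(fp.indices.tolist()))

        scores = {c.key: score(c) for c in cs.candidates}
        if true_key in scores and scores[true_key] >= max(scores.values()):
            hits += 1
    return hits / len(table)
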