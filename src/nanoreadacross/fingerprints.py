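"""Atom-environment fingerprints for structures and core+coating composites.

The structural representation of a nanoparticle is the union of atom-environment
fingerprints of its core and coating compounds.  Each heavy atom of a molecule
contributes one key describing its chemical environment: the atom's own type,
the multiset of atom types at topological distance 1, and the multiset at
distance 2 (hydrogens suppressed).  This resembles the chemical notion of a
functional group and, unlike keyed fingerprints (MACCS, FP4), adapts its
vocabulary to the dataset.

Atom type is the element symbol, rendered lowercase for aromatic atoms, so
aliphatic and aromatic chemistry separate.  Keys serialize as
``<root>|[l1,types]|[l2,types]`` with each layer sorted, which makes the
encoding invariant to atom input order and comparable across runs.

Fingerprints are binary (set semantics, no counts).  A bare-metal core such as
``[Au]`` contributes its single-atom key; this is intentional, so that core
identity (gold vs silver) separates particle families even without coatings.
"""

from __future__ import annotations

from typing import Iterable

from rdkit import Chem
from rdkit.Chem import rdmolops
from rdkit import RDLogger

__all__ = ["FingerprintError", "Fingerprint", "molprint2d", "composite_fingerprint"]

RDLogger.DisableLog("rdApp.error")

Fingerprint = frozenset  # set of atom-environment key strings


class FingerprintError(ValueError):
    """Raised when a structure cannot be parsed or yields no environments."""


def _atom_type(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def molprint2d(smiles: str) -> Fingerprint:
    """Atom-environment fingerprint of a single molecule given as SMILES.

    One key per heavy atom; the result is the deduplicated key set, so
    ``len(molprint2d(m)) <= number of heavy atoms of m``.

    Raises
    ------
    FingerprintError
        If the SMILES does not parse or the molecule has no heavy atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.RemoveHs(mol)
    if mol.GetNumAtoms() == 0:
        raise FingerprintError(f"no heavy atoms in {smiles!r}")
    dist = rdmolops.GetDistanceMatrix(mol)
    types = [_atom_type(a) for a in mol.GetAtoms()]
    n = mol.GetNumAtoms()
    keys = set()
    for i in range(n):
        layer1 = sorted(types[j] for j in range(n) if dist[i, j] == 1)
        layer2 = sorted(types[j] for j in range(n) if dist[i, j] == 2)
        keys.add(f"{types[i]}|[{','.join(layer1)}]|[{','.join(layer2)}]")
    return frozenset(keys)


def composite_fingerprint(core: str | None, coatings: Iterable[str] = ()) -> Fingerprint:
    """Union of atom-environment fingerprints over a particle's core and coatings.

    The union is idempotent and commutative, so duplicate or reordered coating
    entries change nothing.  At least one parseable structure is required; a
    substance with none has no structural representation and must be excluded
    from fingerprint-based models.
    """
    structures = ([core] if core else []) + [c for c in coatings if c]
    if not structures:
        raise FingerprintError("substance has neither core nor coating structures")
    keys: set[str] = set()
    for smi in structures:
        keys |= molprint2d(smi)
    return frozenset(keys)
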