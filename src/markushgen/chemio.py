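"""Structure I/O and canonical identity.

Molecules are plain :class:`rdkit.Chem.Mol` objects throughout the package;
record titles live in the ``_Name`` property and SD data fields in normal
RDKit properties. Identity everywhere downstream (dedup, coverage checks,
library keys) is the *stereo-stripped* canonical SMILES produced by
:func:`canonical_key`, because patent-style R-group bookkeeping treats
optical isomers as the same substituent.

Only V2000 connection tables are accepted; V3000 records raise
:class:`~markushgen.errors.ParseError` with an explicit message.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import MissingInput, ParseError

logger = logging.getLogger(__name__)

# RDKit warnings about e.g. dummy-atom hydrogens are noise for library users.
RDLogger.DisableLog("rdApp.warning")


@dataclass(frozen=True)
class CanonicalKey:
    """Permutation-invariant identity string for a molecular graph.

    ``stereo_stripped`` records whether stereocenters and double-bond
    geometry were erased before canonicalization (the package default).
    """

    key: str
    stereo_stripped: bool = True

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.key


def read_sdf(path: str | os.PathLike, strict: bool = False) -> list[Chem.Mol]:
    """Read an MDL SD file (V2000) into a list of molecules.

    One molecule per record, in file order; the record title and all SD data
    fields are preserved as properties. A malformed record raises
    :class:`ParseError` when ``strict``, otherwise it is skipped with a
    warning naming its index.
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise MissingInput(f"no such file: {path}")
    with open(path, "r", errors="replace") as fh:
        text = fh.read()
    if not text.strip():
        raise MissingInput(f"empty SD file: {path}")
    if "V3000" in text:
        raise ParseError(
            f"{path}: V3000 connection tables are not supported; "
            "convert the file to V2000 first"
        )
    supplier = Chem.SDMolSupplier(path, sanitize=True, removeHs=False)
    mols: list[Chem.Mol] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            if strict:
                raise ParseError(f"{path}: record {i} could not be parsed")
            logger.warning("%s: skipping unparseable record %d", path, i)
            continue
        mols.append(_fold_hydrogens(mol))
    return mols


def write_sdf(mols: list[Chem.Mol], path: str | os.PathLike) -> None:
    """Write molecules to an SD file, preserving names and data fields."""
    writer = Chem.SDWriter(os.fspath(path))
    writer.SetKekulize(True)
    for mol in mols:
        writer.write(mol)
    writer.close()


def _fold_hydrogens(mol: Chem.Mol) -> Chem.Mol:
    """Fold explicit hydrogens into implicit counts, keeping isotopic H.

    Deuterium/tritium atoms must stay explicit so the isotope filter in the
    library builder can see them.
    """
    if any(a.GetAtomicNum() == 1 and a.GetIsotope() == 0 for a in mol.GetAtoms()):
        mol = Chem.RemoveHs(mol)
    return mol


def mol_from_smiles(smiles: str, name: str | None = None) -> Chem.Mol:
    """Parse SMILES into a sanitized molecule; attachment '*' atoms allowed."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    if name is not None:
        mol.SetProp("_Name", name)
    return mol


def largest_component(mol: Chem.Mol) -> Chem.Mol:
    """Return the connected component of greatest molecular weight.

    Salts and co-crystallized counterions are discarded this way before
    drug-set filtering. Equal-weight ties are broken by the lexicographically
    smallest canonical key so the choice is reproducible.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    def sort_key(f: Chem.Mol) -> tuple[float, str]:
        return (-Descriptors.MolWt(f), canonical_key(f).key)
    best = min(frags, key=sort_key)
    if mol.HasProp("_Name"):
        best.SetProp("_Name", mol.GetProp("_Name"))
    return best


def canonical_key(mol: Chem.Mol, ignore_stereo: bool = True) -> CanonicalKey:
    """Canonical line-notation key, invariant to atom input order.

    With ``ignore_stereo`` (the default) stereocenters and double-bond
    geometry are erased first, so enantiomers and diastereomers of the same
    constitution collapse onto one key.
    """
    work = Chem.Mol(mol)
    if ignore_stereo:
        Chem.RemoveStereochemistry(work)
    try:
        Chem.SanitizeMol(work)
    except Exception as exc:  # pragma: no cover - defensive
        raise ParseError(f"unsanitizable molecule: {exc}") from exc
    return CanonicalKey(Chem.MolToSmiles(work), stereo_stripped=ignore_stereo)


def molecular_weight(mol: Chem.Mol) -> float:
    """Average molecular weight; isotopically labeled atoms use their mass number."""
    return Descriptors.MolWt(mol)


def carbon_count(mol: Chem.Mol) -> int:
    """Number of carbon atoms (any aromaticity, any ring membership)."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
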