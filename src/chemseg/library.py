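"""Molecule fixture library: SMILES records with atom-count annotations.

The packaged library (``data/smiles_library.tsv``) holds one record per line,
``id<TAB>smiles``. Single-fragment records are drug-like molecules spanning a
range of heavy-atom counts; multi-fragment records (dot-separated SMILES)
emulate the dense molecule clusters found in patent pages and carry a total
atom count (hydrogens included) annotation computed at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


@dataclass(frozen=True)
class MoleculeSpec:
    """One library record: connectivity plus atom-count annotations.

    ``heavy_atoms`` counts non-hydrogen atoms; ``total_atoms`` counts every
    atom after explicit hydrogen addition. Multi-fragment records (SMILES
    containing ``.``) represent clusters of molecules drawn together.
    """

    id: str
    smiles: str
    heavy_atoms: int
    total_atoms: int

    @property
    def is_multi_fragment(self) -> bool:
        return "." in self.smiles

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"SMILES for record {self.id!r} failed to parse")
        return mol


def annotate_smiles(record_id: str, smiles: str) -> MoleculeSpec:
    """Build a :class:`MoleculeSpec`, computing atom counts with RDKit."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES for record {record_id!r}: {smiles!r}")
    heavy = mol.GetNumHeavyAtoms()
    total = Chem.AddHs(mol).GetNumAtoms()
    return MoleculeSpec(id=record_id, smiles=smiles, heavy_atoms=heavy, total_atoms=total)


def load_library(path: str | Path | None = None) -> list[MoleculeSpec]:
    """Load a tab-separated ``id<TAB>smiles`` library.

    With no argument the packaged fixture library is loaded. Blank lines and
    lines starting with ``#`` are ignored.
    """
    if path is None:
        text = (
            resources.files("chemseg").joinpath("data/smiles_library.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    records: list[MoleculeSpec] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            record_id, smiles = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"malformed library line {lineno}: {line!r}") from exc
        records.append(annotate_smiles(record_id, smiles))
    return records
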