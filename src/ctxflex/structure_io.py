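"""Reading protein chains and catalytic-residue labels.

A protein is represented by its Calpha trace: one record per residue holding
the Calpha coordinate and the Calpha B-factor. Heteroatoms, ligands, waters
and other non-protein molecules are removed on read; selenomethionine (and a
few other common modified residues recorded as HETATM) are mapped back to
their parent amino acid so the protein chain stays intact.

Catalytic-residue labels come either from a Catalytic Site Atlas style
comma-separated flat file or from a simple TSV
(``pdb_id<TAB>chain<TAB>res_seq[<TAB>icode]``).
"""

from __future__ import annotations

import gzip
import urllib.request
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "ResidueRecord", "ChainStructure", "LabelSet",
    "read_chain", "read_labels", "apply_labels",
    "write_chain_pdb", "write_chain_tsv", "fetch_pdb",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Modified residues with ATOM/HETATM records mapped to their parent amino acid.
NONSTANDARD_PARENT = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine (one-letter U folded to C for feature coding)
    "PYL": "K",
    "CSO": "C", "CME": "C", "OCS": "C",
    "SEP": "S", "TPO": "T", "PTR": "Y",
    "MLY": "K", "KCX": "K",
    "HYP": "P",
}


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a protein chain, positioned at its Calpha atom."""

    chain_id: str
    res_seq: int
    icode: str
    aa: str
    ca_xyz: tuple[float, float, float]
    b_factor: float
    is_catalytic: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.ca_xyz)):
            raise ValueError(f"non-finite Calpha coordinate for residue {self.res_seq}")
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise ValueError(f"invalid one-letter code {self.aa!r}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor for residue {self.res_seq}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass
class ChainStructure:
    """An ordered single-chain Calpha trace."""

    pdb_id: str
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError(
                f"{self.pdb_id}:{self.chain_id} has {len(self.residues)} usable "
                "residues; at least 2 are required"
            )
        keys = [(r.res_seq, r.icode) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate residue keys in {self.pdb_id}:{self.chain_id}")
        if keys != sorted(keys):
            raise ValueError(f"residues of {self.pdb_id}:{self.chain_id} not in sequence order")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 array of Calpha coordinates (angstrom)."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([r.b_factor for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.is_catalytic for r in self.residues], dtype=bool)

    def find(self, res_seq: int, icode: str = "") -> ResidueRecord:
        for r in self.residues:
            if r.res_seq == res_seq and r.icode == icode:
                return r
        raise KeyError(f"residue {res_seq}{icode} not in {self.pdb_id}:{self.chain_id}")

    def index_of(self, res_seq: int, icode: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.res_seq == res_seq and r.icode == icode:
                return i
        raise KeyError(f"residue {res_seq}{icode} not in {self.pdb_id}:{self.chain_id}")


@dataclass
class LabelSet:
    """Catalytic-residue keys: (pdb_id, chain_id, res_seq, icode), pdb_id lowercase."""

    entries: set[tuple[str, str, int, str]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, str, int, str]) -> bool:
        pdb_id, chain_id, res_seq, icode = key
        return (pdb_id.lower(), chain_id, res_seq, icode) in self.entries

    def add(self, pdb_id: str, chain_id: str, res_seq: int, icode: str = "") -> None:
        self.entries.add((pdb_id.lower(), chain_id, res_seq, icode))

    def for_chain(self, pdb_id: str, chain_id: str) -> set[tuple[int, str]]:
        return {
            (rs, ic)
            for (p, c, rs, ic) in self.entries
            if p == pdb_id.lower() and c == chain_id
        }


def _residue_one_letter(resname: str) -> str | None:
    """Map a PDB residue name to a one-letter code, or None for non-protein."""
    resname = resname.strip().upper()
    if resname in protein_letters_3to1:
        return protein_letters_3to1[resname]
    if resname in NONSTANDARD_PARENT:
        return NONSTANDARD_PARENT[resname]
    return None


def _pick_ca(residue) -> "object | None":
    """Return the Calpha atom, resolving alternate locations by occupancy.

    Ties and missing occupancies fall back to the first-encountered altloc.
    """
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        best = max(children, key=lambda a: (a.get_occupancy() or 0.0))
        return best
    return atom


def read_chain(pdb_path: str | Path, chain_id: str, model_index: int = 0) -> ChainStructure:
    """Read one chain of a PDB file into a clean Calpha trace.

    Heteroatoms, waters, ligands and other non-protein molecules are dropped.
    Modified amino acids recorded as HETATM (e.g. MSE) are retained and mapped
    to their parent residue. Residues without a Calpha atom are dropped with a
    warning. The B-factor is taken from the Calpha atom.

    Parameters
    ----------
    pdb_path : path to a PDB-format file (optionally gzip-compressed).
    chain_id : chain identifier to extract.
    model_index : model to use (0 = first model; X-ray entries have one).
    """
    pdb_path = Path(pdb_path)
    if not pdb_path.exists():
        raise FileNotFoundError(pdb_path)
    parser = PDBParser(QUIET=True)
    if pdb_path.suffix == ".gz":
        with gzip.open(pdb_path, "rt") as fh:
            structure = parser.get_structure(pdb_path.stem, fh)
    else:
        structure = parser.get_structure(pdb_path.stem, str(pdb_path))

    models = list(structure)
    if model_index >= len(models):
        raise IndexError(f"model {model_index} not present ({len(models)} models)")
    model = models[model_index]
    chain_ids = [c.id for c in model]
    if chain_id not in chain_ids:
        raise KeyError(f"chain {chain_id!r} not found; available: {chain_ids}")
    chain = model[chain_id]

    records: list[ResidueRecord] = []
    n_no_ca = 0
    for residue in chain:
        hetflag, res_seq, icode = residue.id
        aa = _residue_one_letter(residue.get_resname())
        if aa is None:
            continue  # water, ligand, or other non-protein molecule
        if hetflag not in (" ", f"H_{residue.get_resname().strip()}"):
            continue
        ca = _pick_ca(residue)
        if ca is None:
            n_no_ca += 1
            continue
        records.append(
            ResidueRecord(
                chain_id=chain_id,
                res_seq=res_seq,
                icode=icode.strip(),
                aa=aa,
                ca_xyz=tuple(float(v) for v in ca.get_coord()),
                b_factor=max(float(ca.get_bfactor()), 0.0),
                is_catalytic=False,
            )
        )
    if n_no_ca:
        warnings.warn(
            f"{pdb_path.name} chain {chain_id}: dropped {n_no_ca} residue(s) without Calpha"
        )
    pdb_id = pdb_path.stem.split(".")[0].lower()
    records.sort(key=lambda r: (r.res_seq, r.icode))
    return ChainStructure(pdb_id=pdb_id, chain_id=chain_id, residues=records)


def read_labels(label_path: str | Path, format: str = "tsv") -> LabelSet:
    """Read catalytic-residue labels.

    ``format='tsv'``: lines of ``pdb_id<TAB>chain<TAB>res_seq[<TAB>icode]``.
    ``format='csa_flatfile'``: Catalytic Site Atlas comma-separated flat file
    with columns PDB ID, site number, residue type, chain, residue number,
    evidence (extra trailing columns ignored; a header line is skipped).
    """
    label_path = Path(label_path)
    if not label_path.exists():
        raise FileNotFoundError(label_path)
    labels = LabelSet()
    errors: list[str] = []
    lines = label_path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if format == "tsv":
            parts = line.split("\t")
            if len(parts) < 3:
                errors.append(f"line {lineno}: expected >=3 tab-separated fields")
                continue
            pdb_id, chain_id, res_seq = parts[0], parts[1], parts[2]
            icode = parts[3] if len(parts) > 3 else ""
            try:
                labels.add(pdb_id, chain_id, int(res_seq), icode.strip())
            except ValueError:
                errors.append(f"line {lineno}: residue number {res_seq!r} not an integer")
        elif format == "csa_flatfile":
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and parts and parts[0].upper().replace(" ", "") == "PDBID":
                continue  # header
            if len(parts) < 5:
                errors.append(f"line {lineno}: expected >=5 comma-separated fields")
                continue
            pdb_id, chain_id, res_seq = parts[0], parts[3], parts[4]
            try:
                res_num = int(res_seq)
            except ValueError:
                errors.append(f"line {lineno}: residue number {res_seq!r} not an integer")
                continue
            labels.add(pdb_id, chain_id, res_num)
        else:
            raise ValueError(f"unknown label format {format!r}")
    if errors:
        raise ValueError("malformed label rows:\n" + "\n".join(errors))
    if len(labels) == 0:
        raise ValueError(f"no catalytic labels found in {label_path}")
    return labels


def apply_labels(chain: ChainStructure, labels: LabelSet) -> tuple[ChainStructure, list[tuple[int, str]]]:
    """Flag catalytic residues of a chain; geometry is untouched.

    Returns the labelled chain and the list of label keys that did not match
    any residue of this chain.
    """
    wanted = labels.for_chain(chain.pdb_id, chain.chain_id)
    present = {(r.res_seq, r.icode) for r in chain.residues}
    unmatched = sorted(wanted - present)
    new_residues = [
        replace(r, is_catalytic=(r.res_seq, r.icode) in wanted) for r in chain.residues
    ]
    return ChainStructure(chain.pdb_id, chain.chain_id, new_residues), unmatched


_ONE_TO_THREE = {v: k for k, v in protein_letters_3to1.items()}


def write_chain_pdb(chain: ChainStructure, path: str | Path) -> None:
    """Write a Calpha-only PDB file (fixed-width ATOM records)."""
    path = Path(path)
    lines = []
    for i, r in enumerate(chain.residues, start=1):
        resname = _ONE_TO_THREE.get(r.aa, "UNK")
        x, y, z = r.ca_xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:>3s} {r.chain_id:1s}{r.res_seq:4d}"
            f"{r.icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}"
            f"{r.b_factor:6.2f}           C  "
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_chain_tsv(chain: ChainStructure, path: str | Path) -> None:
    """Serialize a chain to TSV: chain res_seq icode aa x y z b_factor is_catalytic."""
    path = Path(path)
    rows = ["chain\tres_seq\ticode\taa\tx\ty\tz\tb_factor\tis_catalytic"]
    for r in chain.residues:
        x, y, z = r.ca_xyz
        rows.append(
            f"{r.chain_id}\t{r.res_seq}\t{r.icode}\t{r.aa}\t{x:.3f}\t{y:.3f}\t{z:.3f}"
            f"\t{r.b_factor:.2f}\t{int(r.is_catalytic)}"
        )
    path.write_text("\n".join(rows) + "\n")


def fetch_pdb(pdb_id: str, dest_dir: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry from RCSB into ``dest_dir`` (requires network).

    Returns the local path; reuses an existing download if present.
    """
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{pdb_id.lower()}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest
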