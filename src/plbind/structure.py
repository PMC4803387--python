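"""PDB complex parsing and distance-based extraction of ligand-binding residues.

Only fixed-column PDB text is supported (ATOM/HETATM/CONECT/LINK/TER/MODEL);
for multi-model files the first model is kept.  Waters are discarded, MSE is
folded into the polymer chain, and ligands covalently attached to the polymer
or to another ligand can be excluded before contact extraction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np

from .octree import build_octree

__all__ = [
    "Atom",
    "Residue",
    "LigandInstance",
    "Structure",
    "BindingAnnotation",
    "PDBParseError",
    "EmptyStructureError",
    "parse_pdb",
    "exclude_covalent_ligands",
    "extract_binding_residues",
    "extract_all_binding_residues",
    "format_atom_line",
    "write_annotations_tsv",
    "read_annotations_tsv",
    "chain_sequence",
    "WATER_CODES",
    "DEFAULT_EXCLUDED_HET",
]

# waters are never ligands; the buffer list is a configurable convention,
# not a method constant
WATER_CODES = frozenset({"HOH", "DOD"})
DEFAULT_EXCLUDED_HET = frozenset({"HOH", "GOL", "EDO", "SO4", "PO4", "CL", "NA"})

_STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


class PDBParseError(ValueError):
    """Raised for malformed fixed-column records (message names the line)."""


class EmptyStructureError(ValueError):
    """Raised when a file yields no atoms at all."""


@dataclasses.dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    record_kind: str  # "polymer" | "hetero"
    chain_id: str
    residue_name: str
    residue_seq: int
    icode: str = ""
    alt_loc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.isfinite(self.coords).all():
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.residue_name:
            raise ValueError(f"atom {self.serial}: empty residue name")


@dataclasses.dataclass
class Residue:
    name: str
    residue_seq: int
    icode: str
    atoms: list[Atom]

    @property
    def author_seq(self) -> str:
        return f"{self.residue_seq}{self.icode}".strip()


@dataclasses.dataclass
class LigandInstance:
    ccd_code: str
    chain_id: str
    residue_seq: int
    icode: str
    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("ligand instance with no atoms")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.ccd_code, self.chain_id, self.residue_seq, self.icode)


@dataclasses.dataclass
class Structure:
    model_id: int
    chains: dict[str, list[Residue]]
    ligands: list[LigandInstance]
    covalent_links: list[tuple[int, int]]

    def polymer_atoms(self, chain_id: str | None = None) -> list[Atom]:
        chains = [chain_id] if chain_id is not None else sorted(self.chains)
        out: list[Atom] = []
        for cid in chains:
            for res in self.chains[cid]:
                out.extend(res.atoms)
        return out

    def ligand(self, ccd_code: str, chain_id: str | None = None) -> LigandInstance:
        for lig in self.ligands:
            if lig.ccd_code == ccd_code and (chain_id is None or lig.chain_id == chain_id):
                return lig
        raise KeyError(f"ligand {ccd_code!r} not found in structure")


@dataclasses.dataclass
class BindingAnnotation:
    """Binding residues of one chain for one ligand instance.

    Residue positions are 1-based by order of appearance in the chain;
    ``min_distances`` maps each binding position to its closest
    residue-atom/ligand-atom distance in Angstrom.
    """

    chain_id: str
    ligand: LigandInstance
    binding_residues: set[int]
    cutoff_A: float
    min_distances: dict[int, float] = dataclasses.field(default_factory=dict)
    author_seqs: dict[int, str] = dataclasses.field(default_factory=dict)


def _parse_float(field: str, lineno: int, what: str) -> float:
    try:
        return float(field)
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed {what} field {field!r}") from None


def _parse_int(field: str, lineno: int, what: str) -> int:
    try:
        return int(field)
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed {what} field {field!r}") from None


def _atom_from_line(line: str, lineno: int, kind: str) -> Atom:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: record shorter than coordinate columns")
    name = line[12:16].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name convention: col 13 blank => 1-char element
        element = (name[:2] if line[12] != " " else name[:1]).strip("0123456789")
    return Atom(
        serial=_parse_int(line[6:11], lineno, "serial"),
        name=name,
        element=element.upper(),
        coords=np.array(
            [
                _parse_float(line[30:38], lineno, "x"),
                _parse_float(line[38:46], lineno, "y"),
                _parse_float(line[46:54], lineno, "z"),
            ]
        ),
        record_kind=kind,
        chain_id=line[21],
        residue_name=line[17:20].strip(),
        residue_seq=_parse_int(line[22:26], lineno, "resSeq"),
        icode=line[26].strip() if len(line) > 26 else "",
        alt_loc=line[16].strip(),
    )


def parse_pdb(text: str | Iterable[str]) -> Structure:
    """Parse PDB-format text into a :class:`Structure` (first model only)."""
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    chains: dict[str, dict[tuple[int, str], Residue]] = {}
    ligand_groups: dict[tuple[str, str, int, str], LigandInstance] = {}
    links: list[tuple[int, int]] = []
    link_records: list[tuple[tuple, tuple]] = []
    seen_alt: dict[tuple, str] = {}
    atom_lookup: dict[tuple[str, int, str, str], int] = {}  # (chain, seq, icode, name) -> serial
    n_atoms = 0
    model_seen = 0

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            model_seen += 1
            if model_seen > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec in ("ATOM", "HETATM"):
            kind = "polymer" if rec == "ATOM" else "hetero"
            atom = _atom_from_line(line, lineno, kind)
            if atom.residue_name in WATER_CODES:
                continue
            # keep only the first altLoc per atom identity
            alt_key = (atom.chain_id, atom.residue_seq, atom.icode, atom.residue_name, atom.name)
            if atom.alt_loc:
                if alt_key in seen_alt and seen_alt[alt_key] != atom.alt_loc:
                    continue
                seen_alt[alt_key] = atom.alt_loc
            n_atoms += 1
            atom_lookup[(atom.chain_id, atom.residue_seq, atom.icode, atom.name)] = atom.serial
            is_polymer = rec == "ATOM" or atom.residue_name in _STANDARD_AA
            if is_polymer:
                atom.record_kind = "polymer"
                res_key = (atom.residue_seq, atom.icode)
                chain = chains.setdefault(atom.chain_id, {})
                res = chain.get(res_key)
                if res is None:
                    chain[res_key] = Residue(atom.residue_name, atom.residue_seq, atom.icode, [atom])
                else:
                    res.atoms.append(atom)
            else:
                key = (atom.residue_name, atom.chain_id, atom.residue_seq, atom.icode)
                lig = ligand_groups.get(key)
                if lig is None:
                    ligand_groups[key] = LigandInstance(
                        atom.residue_name, atom.chain_id, atom.residue_seq, atom.icode, [atom]
                    )
                else:
                    lig.atoms.append(atom)
        elif rec == "CONECT":
            base = _parse_int(line[6:11], lineno, "CONECT serial")
            for start in (11, 16, 21, 26):
                field = line[start : start + 5].strip()
                if field:
                    other = _parse_int(field, lineno, "CONECT serial")
                    links.append((min(base, other), max(base, other)))
        elif rec == "LINK":
            # resolved after all atoms are read
            a = (line[21], int(line[22:26]), line[26].strip(), line[12:16].strip())
            b = (line[51], int(line[52:56]), line[56].strip() if len(line) > 56 else "", line[42:46].strip())
            link_records.append((a, b))

    if n_atoms == 0:
        raise EmptyStructureError("no ATOM or HETATM records found")

    for a, b in link_records:
        sa, sb = atom_lookup.get(a), atom_lookup.get(b)
        if sa is not None and sb is not None:
            links.append((min(sa, sb), max(sa, sb)))

    ordered_chains = {
        cid: [residues[k] for k in sorted(residues)] for cid, residues in sorted(chains.items())
    }
    serials = {a.serial for a in _all_atoms(ordered_chains, list(ligand_groups.values()))}
    links = sorted({(a, b) for a, b in links if a in serials and b in serials and a != b})
    return Structure(
        model_id=1,
        chains=ordered_chains,
        ligands=list(ligand_groups.values()),
        covalent_links=links,
    )


def _all_atoms(chains: dict[str, list[Residue]], ligands: list[LigandInstance]) -> list[Atom]:
    out = []
    for residues in chains.values():
        for res in residues:
            out.extend(res.atoms)
    for lig in ligands:
        out.extend(lig.atoms)
    return out


def exclude_covalent_ligands(structure: Structure) -> Structure:
    """Drop every ligand covalently bonded to the polymer or to another ligand."""
    owner: dict[int, int | str] = {}
    for atom in structure.polymer_atoms():
        owner[atom.serial] = "polymer"
    for i, lig in enumerate(structure.ligands):
        for atom in lig.atoms:
            owner[atom.serial] = i

    doomed: set[int] = set()
    for a, b in structure.covalent_links:
        oa, ob = owner.get(a), owner.get(b)
        if oa is None or ob is None or oa == ob:
            continue
        for o in (oa, ob):
            if isinstance(o, int):
                doomed.add(o)

    keep = [lig for i, lig in enumerate(structure.ligands) if i not in doomed]
    return dataclasses.replace(structure, ligands=keep)


def extract_binding_residues(
    structure: Structure,
    ligand: LigandInstance,
    cutoff_A: float = 5.0,
    chain_id: str | None = None,
    leaf_capacity: int = 8,
) -> BindingAnnotation:
    """Residues of one chain with >= 1 atom within ``cutoff_A`` of any ligand atom.

    Contacts are found with an octree range query per ligand atom; the result
    is identical to a brute-force all-pairs scan.
    """
    if not 3.5 <= cutoff_A <= 6.0:
        raise ValueError(f"cutoff_A must be in [3.5, 6.0], got {cutoff_A}")
    if not any(lig is ligand or lig.key == ligand.key for lig in structure.ligands):
        raise KeyError(f"ligand {ligand.key} not part of structure")
    if chain_id is None:
        chain_id = ligand.chain_id
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure")

    residues = structure.chains[chain_id]
    coords = []
    atom_residue = []  # chain-local 1-based residue position per atom row
    for pos, res in enumerate(residues, start=1):
        for atom in res.atoms:
            coords.append(atom.coords)
            atom_residue.append(pos)
    tree = build_octree(np.array(coords), leaf_capacity=leaf_capacity)

    hits: dict[int, float] = {}
    for latom in ligand.atoms:
        for idx in tree.query_ball(latom.coords, cutoff_A):
            pos = atom_residue[idx]
            d = float(np.linalg.norm(np.asarray(coords[idx]) - latom.coords))
            if pos not in hits or d < hits[pos]:
                hits[pos] = d

    return BindingAnnotation(
        chain_id=chain_id,
        ligand=ligand,
        binding_residues=set(hits),
        cutoff_A=cutoff_A,
        min_distances=hits,
        author_seqs={p: residues[p - 1].author_seq for p in hits},
    )


def extract_all_binding_residues(
    structure: Structure,
    cutoff_A: float = 5.0,
    ligand_codes: Sequence[str] | None = None,
    excluded_het: frozenset[str] = DEFAULT_EXCLUDED_HET,
) -> list[BindingAnnotation]:
    """Annotations for every (surviving ligand, chain) pair with contacts."""
    structure = exclude_covalent_ligands(structure)
    out = []
    for lig in structure.ligands:
        if lig.ccd_code in excluded_het:
            continue
        if ligand_codes is not None and lig.ccd_code not in ligand_codes:
            continue
        for cid in sorted(structure.chains):
            ann = extract_binding_residues(structure, lig, cutoff_A, chain_id=cid)
            if ann.binding_residues:
                out.append(ann)
    return out


def chain_sequence(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain; unknown residue types become X."""
    return "".join(_STANDARD_AA.get(r.name, "X") for r in structure.chains[chain_id])


def format_atom_line(atom: Atom) -> str:
    """Serialize an atom back to a fixed-column ATOM/HETATM line."""
    rec = "ATOM  " if atom.record_kind == "polymer" else "HETATM"
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    return (
        f"{rec}{atom.serial:5d} {name}{atom.alt_loc or ' '}{atom.residue_name:>3s} "
        f"{atom.chain_id}{atom.residue_seq:4d}{atom.icode or ' '}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


_ANN_HEADER = ["pdb_id", "chain", "ccd_code", "residue_index", "author_seq", "min_distance_A"]


def write_annotations_tsv(annotations: Iterable[BindingAnnotation], path, pdb_id: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ANN_HEADER)
        for ann in annotations:
            for pos in sorted(ann.binding_residues):
                w.writerow(
                    [
                        pdb_id,
                        ann.chain_id,
                        ann.ligand.ccd_code,
                        pos,
                        ann.author_seqs.get(pos, ""),
                        f"{ann.min_distances[pos]:.3f}",
                    ]
                )


def read_annotations_tsv(path) -> list[dict]:
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    for row in rows:
        row["residue_index"] = int(row["residue_index"])
        row["min_distance_A"] = float(row["min_distance_A"])
    return rows
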