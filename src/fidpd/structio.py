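"""Reading and writing PDB-format coordinate files.

The functional-site annotation pipeline needs three things from a PDB file
that general-purpose structure readers do not expose together: the polymer
chains (for sequences and C-alpha traces), the HETATM groups (candidate
ligands), and the SITE records (the curated functional-site residue lists
that provide the ground-truth annotation).  This module parses the classic
fixed-column format directly, applies the conventions documented below, and
can write a structure back out, round-tripping coordinates at PDB precision
(3 decimals).

Conventions
-----------
* Residue identity is author chain id + residue number + insertion code.
* Water (HOH/DOD) is never a ligand; every other HETATM group is, including
  single metal ions.  A ligand is flagged metallic when it consists of one
  atom whose element is in the configured metal list.
* Covalently incorporated modified residues (MSE, SEP, ...) are polymer.
* Alternate locations: the highest-occupancy conformer is kept, ties broken
  in favour of altloc 'A'.  Only the first MODEL of a multi-model file is
  read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Data.PDBData import protein_letters_3to1, protein_letters_3to1_extended

__all__ = [
    "Atom",
    "ResidueRef",
    "Residue",
    "Ligand",
    "FunctionalSiteRecord",
    "Structure",
    "PDBParseError",
    "parse_structure",
    "write_structure",
    "extract_sequence",
    "sites_to_positions",
]

#: Default set of element symbols treated as metal ions.
DEFAULT_METALS = frozenset({"ZN", "MG", "MN", "FE", "CA", "NA", "K", "CU", "NI", "CO"})

#: HETATM residue names that are covalently part of the polymer chain.
MODIFIED_POLYMER = frozenset(
    {"MSE", "SEC", "PYL", "HYP", "MLY", "PTR", "SEP", "TPO", "CSO", "CME", "KCX"}
)

WATER = frozenset({"HOH", "DOD", "WAT"})

_TWO_LETTER_ELEMENTS = frozenset(
    {
        "ZN", "MG", "MN", "FE", "CA", "NA", "CU", "NI", "CO", "CL", "BR",
        "SE", "CD", "HG", "MO", "AL", "SI",
    }
)


class PDBParseError(ValueError):
    """Raised when a fixed-column record cannot be interpreted."""


@dataclass(frozen=True)
class ResidueRef:
    """Author-numbering identity of a residue: chain, number, insertion code."""

    chain_id: str
    number: int
    icode: str = ""
    resname: str = ""

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    record_kind: str  # "polymer" | "het"
    parent: ResidueRef

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")


@dataclass
class Residue:
    """A polymer residue with its atoms in file order."""

    ref: ResidueRef
    atoms: list[Atom] = field(default_factory=list)

    @property
    def resname(self) -> str:
        return self.ref.resname

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Ligand:
    het_code: str
    atoms: list[Atom]
    is_metal: bool
    instance_id: tuple[str, int]


@dataclass
class FunctionalSiteRecord:
    """One SITE annotation: a named, ordered list of residue references."""

    site_name: str
    residues: list[ResidueRef]
    unresolved: list[ResidueRef] = field(default_factory=list)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    ligands: list[Ligand]
    sites: list[FunctionalSiteRecord]

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}") from None

    def residue_index(self) -> dict[tuple[str, int, str], Residue]:
        return {r.ref.key(): r for ch in self.chains.values() for r in ch}


def _guess_element(name: str, resname: str) -> str:
    """Infer the element symbol from the atom-name field (columns 13-16)."""
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        return ""
    if stripped[:2] in _TWO_LETTER_ELEMENTS and (
        resname.strip().upper() == stripped[:2] or len(stripped) == 2
    ):
        # metal-ion atom names (ZN, MG ...) and unambiguous two-letter symbols
        if stripped[:2] not in {"CA", "CD", "CO", "NA", "NI", "SE", "HG"}:
            return stripped[:2]
        if resname.strip().upper() == stripped[:2]:
            return stripped[:2]
    return stripped[0]


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, float]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        number = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        element = _guess_element(name, resname)
    kind = "polymer" if line.startswith("ATOM") or resname in MODIFIED_POLYMER else "het"
    ref = ResidueRef(chain_id, number, icode, resname)
    return Atom(serial, name, element, (x, y, z), kind, ref), altloc, occupancy


def _parse_site_lines(lines: list[tuple[int, str]]) -> list[FunctionalSiteRecord]:
    sites: dict[str, FunctionalSiteRecord] = {}
    for lineno, line in lines:
        site_name = line[11:14].strip()
        if not site_name:
            raise PDBParseError(f"SITE record without a site name at line {lineno}")
        rec = sites.setdefault(site_name, FunctionalSiteRecord(site_name, []))
        for start in (18, 29, 40, 51):
            chunk = line[start : start + 11]
            if not chunk.strip():
                continue
            resname = chunk[0:3].strip()
            chain_id = chunk[4:5].strip() or " "
            num_field = chunk[5:9].strip()
            if not num_field:
                continue
            try:
                number = int(num_field)
            except ValueError as exc:
                raise PDBParseError(
                    f"malformed SITE residue field at line {lineno}: {chunk!r}"
                ) from exc
            icode = chunk[9:10].strip() if len(chunk) >= 10 else ""
            rec.residues.append(ResidueRef(chain_id, number, icode, resname))
    return list(sites.values())


def parse_structure(text: str, structure_id: str = "", metals: frozenset[str] = DEFAULT_METALS) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Polymer chains, non-water HETATM ligands and SITE records are populated.
    SITE residues that do not resolve against any parsed polymer residue are
    kept but flagged in ``FunctionalSiteRecord.unresolved``.

    Raises
    ------
    PDBParseError
        If the text contains no ATOM/HETATM record, or a fixed-column record
        is malformed (the error names the offending line number).
    """
    best: dict[tuple, tuple[float, str, Atom]] = {}
    order: list[tuple] = []
    site_lines: list[tuple[int, str]] = []
    pdb_id = structure_id
    in_first_model = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "HEADER" and not pdb_id:
            pdb_id = line[62:66].strip()
        elif rec == "ENDMDL":
            in_first_model = False
        elif rec in ("ATOM  ", "HETATM") and in_first_model:
            atom, altloc, occ = _parse_atom_line(line, lineno)
            akey = (atom.parent.key(), atom.parent.resname, atom.name)
            if akey not in best:
                order.append(akey)
                best[akey] = (occ, altloc, atom)
            else:
                old_occ, old_alt, _ = best[akey]
                if occ > old_occ or (occ == old_occ and altloc == "A" and old_alt != "A"):
                    best[akey] = (occ, altloc, atom)
        elif rec == "SITE  ":
            site_lines.append((lineno, line))
    if not best:
        raise PDBParseError("no ATOM or HETATM records found")

    chains: dict[str, list[Residue]] = {}
    residues: dict[tuple[str, int, str], Residue] = {}
    het_groups: dict[tuple[str, int, str, str], list[Atom]] = {}
    het_order: list[tuple[str, int, str, str]] = []
    for akey in order:
        _, _, atom = best[akey]
        if atom.record_kind == "polymer":
            rkey = atom.parent.key()
            if rkey not in residues:
                res = Residue(atom.parent)
                residues[rkey] = res
                chains.setdefault(atom.parent.chain_id, []).append(res)
            residues[rkey].atoms.append(atom)
        else:
            if atom.parent.resname in WATER:
                continue
            hkey = (*atom.parent.key(), atom.parent.resname)
            if hkey not in het_groups:
                het_groups[hkey] = []
                het_order.append(hkey)
            het_groups[hkey].append(atom)

    ligands = []
    for hkey in het_order:
        chain_id, number, _icode, resname = hkey
        atoms = het_groups[hkey]
        is_metal = len(atoms) == 1 and atoms[0].element in metals
        ligands.append(Ligand(resname, atoms, is_metal, (chain_id, number)))

    sites = _parse_site_lines(site_lines)
    for site in sites:
        site.unresolved = [r for r in site.residues if r.key() not in residues]
    return Structure(pdb_id or "UNK", chains, ligands, sites)


def _format_atom_line(record: str, atom: Atom, serial: int) -> str:
    ref = atom.parent
    name = atom.name
    # PDB convention: 1-letter elements start in column 14 unless 4 chars long
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.coords
    return (
        f"{record:<6}{serial:>5} {name:<4} {ref.resname:>3} {ref.chain_id:1}"
        f"{ref.number:>4}{ref.icode or ' ':1}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}"
    )


def write_structure(structure: Structure) -> str:
    """Serialize a structure to PDB-format text (ATOM/TER/HETATM/SITE/END)."""
    lines: list[str] = []
    serial = 0
    for chain_id in structure.chains:
        for res in structure.chains[chain_id]:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line("ATOM", atom, serial))
        serial += 1
        last = structure.chains[chain_id][-1].ref
        lines.append(
            f"TER   {serial:>5}      {last.resname:>3} {last.chain_id:1}{last.number:>4}{last.icode or ' ':1}"
        )
    for lig in structure.ligands:
        for atom in lig.atoms:
            serial += 1
            lines.append(_format_atom_line("HETATM", atom, serial))
    for site in structure.sites:
        n = len(site.residues)
        for i in range(0, n, 4):
            block = site.residues[i : i + 4]
            fields = "".join(
                f"{r.resname:>3} {r.chain_id:1}{r.number:>4}{r.icode or ' ':1} " for r in block
            )
            lines.append(f"SITE  {i // 4 + 1:>4} {site.site_name:<3}{n:>3} {fields}".rstrip())
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_sequence(
    chain: list[Residue], selenomet_as_parent: bool = False
) -> tuple[str, dict[int, ResidueRef]]:
    """One-letter sequence of a chain plus a 1-based position -> residue map.

    Non-standard residues become ``'X'`` unless ``selenomet_as_parent`` is
    set, in which case the extended 3-to-1 table maps modified residues to
    their parent letter (MSE -> M, SEP -> S, ...).
    """
    if not chain:
        raise ValueError("chain has no polymer residues")
    table = protein_letters_3to1_extended if selenomet_as_parent else protein_letters_3to1
    letters = []
    posmap: dict[int, ResidueRef] = {}
    for i, res in enumerate(chain, start=1):
        letters.append(table.get(res.resname, "X"))
        posmap[i] = res.ref
    return "".join(letters), posmap


def sites_to_positions(structure: Structure, chain_id: str) -> set[int]:
    """Union of all SITE residues on one chain as 1-based sequence positions.

    Unresolved SITE residues are skipped (they are flagged on the record
    itself); an empty set is a valid result.
    """
    chain = structure.chain(chain_id)
    _, posmap = extract_sequence(chain)
    by_key = {ref.key(): pos for pos, ref in posmap.items()}
    positions: set[int] = set()
    for site in structure.sites:
        unresolved = {r.key() for r in site.unresolved}
        for ref in site.residues:
            if ref.chain_id != chain_id or ref.key() in unresolved:
                continue
            pos = by_key.get(ref.key())
            if pos is not None:
                positions.add(pos)
    return positions
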