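"""Coordinate I/O and pentamer annotation.

Reads mmCIF/PDB atomic models (via gemmi) into a small uniform container,
and attaches the two annotations the pore-geometry operations need:

* which of the five chains is which subunit class (alpha1 / beta3 / other)
  and which pentamer position (A-E, clockwise viewed from the extracellular
  side; position C is the one homologous to the gamma-subunit position of
  synaptic receptors), and
* the prime-index map for the pore-lining M2 helix.  Prime indices (-2'..20')
  are the pan-pLGIC numbering of M2 positions; each chain is anchored at the
  17' residue (His267 in beta3, Ser272 in alpha1, author numbering) and
  residue(i') = anchor + (i - 17).

Author residue numbering is canonical throughout.  Altloc duplicates keep
the highest-occupancy conformer (ties by altloc identifier); waters are
dropped by default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "SubunitAnnotation",
    "PrimeIndexMap",
    "StructureModel",
    "ParseError",
    "read_structure",
    "write_structure",
    "annotate_pentamer",
    "DEFAULT_ANCHORS",
]

#: Author-numbering residue holding the 17' position, per subunit class.
DEFAULT_ANCHORS: dict[str, int] = {"beta3": 267, "alpha1": 272}

PRIME_RANGE = (-2, 20)


class ParseError(ValueError):
    pass


@dataclass
class AtomRecord:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass(frozen=True)
class SubunitAnnotation:
    chain_id: str
    subunit_class: str  # alpha1 | beta3 | other
    pentamer_position: str  # A..E
    gamma_position_flag: bool


@dataclass(frozen=True)
class PrimeIndexMap:
    """Maps M2 prime indices to author residue numbers by fixed offset."""

    anchor_residue: int
    anchor_prime: int = 17
    valid_range: tuple[int, int] = PRIME_RANGE

    def residue_number(self, prime: int) -> int:
        lo, hi = self.valid_range
        if not lo <= prime <= hi:
            raise ValueError(f"prime index {prime} outside {lo}'..{hi}'")
        return self.anchor_residue + (prime - self.anchor_prime)


class StructureModel:
    """Flat atomic model with optional pentamer annotation."""

    def __init__(self, atoms: list[AtomRecord], name: str = "") -> None:
        self.atoms = atoms
        self.name = name
        self.annotations: dict[str, SubunitAnnotation] = {}
        self.prime_maps: dict[str, PrimeIndexMap] = {}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def is_annotated(self) -> bool:
        return bool(self.annotations)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def select(
        self,
        chain: str | None = None,
        resnum: int | None = None,
        resname: str | None = None,
        atom: str | None = None,
        element: str | None = None,
        hetero: bool | None = None,
    ) -> list[AtomRecord]:
        out = []
        for a in self.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            if resnum is not None and a.residue_number != resnum:
                continue
            if resname is not None and a.residue_name != resname:
                continue
            if atom is not None and a.atom_name != atom:
                continue
            if element is not None and a.element.upper() != element.upper():
                continue
            if hetero is not None and a.is_hetero != hetero:
                continue
            out.append(a)
        return out

    def ca(self, chain: str, resnum: int) -> AtomRecord:
        hits = self.select(chain=chain, resnum=resnum, atom="CA")
        if not hits:
            raise KeyError(f"no CA atom at chain {chain} residue {resnum}")
        return hits[0]

    def prime_ca(self, chain: str, prime: int) -> AtomRecord:
        """Cα of a prime-indexed M2 residue on an annotated chain."""
        if chain not in self.prime_maps:
            raise KeyError(f"chain {chain} has no prime-index map; annotate first")
        return self.ca(chain, self.prime_maps[chain].residue_number(prime))

    def subunit_chains(self) -> list[str]:
        """Annotated receptor chains in pentamer position order A..E."""
        anns = sorted(self.annotations.values(),
                      key=lambda s: s.pentamer_position)
        return [s.chain_id for s in anns]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Copy with all positions mapped x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out = self.copy()
        for a in out.atoms:
            a.position = R @ a.position + t
        return out

    def copy(self) -> "StructureModel":
        out = StructureModel(
            [copy.copy(a) for a in self.atoms], name=self.name
        )
        for a in out.atoms:
            a.position = a.position.copy()
        out.annotations = dict(self.annotations)
        out.prime_maps = dict(self.prime_maps)
        return out

    def write(self, path: str | Path, format: str = "auto") -> None:
        write_structure(self, path, format=format)


# ---------------------------------------------------------------------------
# reading / writing


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        if format not in ("pdb", "mmcif"):
            raise ValueError(f"unknown format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    raise ValueError(f"cannot infer coordinate format from {path.name!r}")


def _pick_conformers(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "~")) > (
            prev.occ, -ord(prev.altloc or "~")
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(
    path: str | Path,
    format: str = "auto",
    keep_waters: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records are retained (waters optionally), author chain
    ids and residue numbering preserved, heteroatoms flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    cf = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=cf)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path.name} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path.name}: no models found")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            if residue.is_water() and not keep_waters:
                continue
            het = residue.het_flag == "H"
            for atom in _pick_conformers(residue):
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        ),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                        is_hetero=het,
                    )
                )
    if not atoms:
        raise ParseError(f"{path.name}: no atoms read")
    return StructureModel(atoms, name=path.stem)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    # group atoms by chain and residue first; gemmi add_* methods copy
    # their arguments, so containers are assembled bottom-up
    chain_order: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    for a in model.atoms:
        chain_order.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []
        ).append(a)
    st = gemmi.Structure()
    st.name = model.name or "model"
    gm = gemmi.Model("1")
    for chain_id, residues in chain_order.items():
        ch = gemmi.Chain(chain_id)
        for (resnum, resname), recs in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if recs[0].is_hetero else "A"
            for a in recs:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(
    model: StructureModel, path: str | Path, format: str = "auto"
) -> None:
    """Write a model as PDB (3-decimal coordinates) or mmCIF."""
    path = Path(path)
    fmt = _detect_format(path, format)
    st = _to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# annotation


def annotate_pentamer(
    model: StructureModel,
    spec: dict[str, "str | dict"],
) -> StructureModel:
    """Attach subunit and prime-index annotations for five receptor chains.

    ``spec`` maps chain id to a subunit class name ("alpha1"/"beta3") or to
    a dict ``{"class": ..., "anchor": <author resnum of 17'>}`` for
    non-default anchors (required for class "other").  Pentamer positions
    A-E follow the order chains are listed in the spec; position C carries
    the gamma-position flag.  Chains must exist and resolve Cα atoms at the
    17' anchor and the 9' position.
    """
    if len(spec) != 5:
        raise ValueError(f"exactly five chains required, got {len(spec)}")
    present = set(model.chains())
    out = model.copy()
    out.annotations = {}
    out.prime_maps = {}
    for pos, (chain_id, entry) in zip("ABCDE", spec.items()):
        if chain_id not in present:
            raise KeyError(f"chain {chain_id!r} absent from model")
        if isinstance(entry, str):
            cls, anchor = entry, None
        else:
            cls = entry.get("class", "other")
            anchor = entry.get("anchor")
        if anchor is None:
            if cls not in DEFAULT_ANCHORS:
                raise ValueError(
                    f"chain {chain_id}: class {cls!r} needs an explicit anchor"
                )
            anchor = DEFAULT_ANCHORS[cls]
        pmap = PrimeIndexMap(anchor_residue=int(anchor))
        for prime in (17, 9):
            resnum = pmap.residue_number(prime)
            if not out.select(chain=chain_id, resnum=resnum, atom="CA"):
                raise KeyError(
                    f"chain {chain_id}: no CA at residue {resnum} ({prime}')"
                )
        out.annotations[chain_id] = SubunitAnnotation(
            chain_id=chain_id,
            subunit_class=cls,
            pentamer_position=pos,
            gamma_position_flag=(pos == "C"),
        )
        out.prime_maps[chain_id] = pmap
    return out


def load_chain_spec(path: str | Path) -> dict:
    """Read a chain-annotation config (TOML): ``[chains.<id>]`` tables with
    ``class`` and optional ``anchor`` keys."""
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    chains = doc.get("chains")
    if not chains:
        raise ValueError(f"{path}: no [chains.*] tables")
    return {cid: entry for cid, entry in chains.items()}
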