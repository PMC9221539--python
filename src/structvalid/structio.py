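"""Structure I/O and residue correspondence.

Coordinate files (PDB or mmCIF) are parsed with :mod:`gemmi` into a small
immutable-ish data model holding only what the comparison metrics need:
heavy-atom coordinates, occupancies, the temperature-factor column (crystal
B-factors in Å², or pLDDT confidence scores 0–100 for predicted models),
and crystal metadata (resolution, space group).

Predicted full-length models generally cover residues that are disordered or
absent in crystal structures, so every pairwise comparison goes through an
explicit :class:`CorrespondenceMap` built on author residue numbering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "ResidueId",
    "CorrespondenceMap",
    "PAEMatrix",
    "ResidueProfile",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "build_correspondence",
    "extract_profile",
    "read_pae",
    "write_pae",
    "write_profile_tsv",
    "MAINCHAIN_ATOMS",
]

Level = Literal["calpha", "mainchain", "allatom"]
MAINCHAIN_ATOMS = ("N", "CA", "C", "O")

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureParseError(ValueError):
    """Raised when a coordinate or PAE file cannot be interpreted."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    tempfactor: float = 0.0  # B-factor (Å²) or pLDDT (0-100)
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if self.tempfactor < 0:
            raise ValueError(f"atom {self.name}: negative temperature factor")


# A residue is addressed by (chain, author seqnum, insertion code).
ResidueId = tuple[str, int, str]


def format_residue_id(rid: ResidueId) -> str:
    chain, seqnum, icode = rid
    return f"{chain}:{seqnum}{icode}"


@dataclass
class Residue:
    chain: str
    seqnum: int
    icode: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def rid(self) -> ResidueId:
        return (self.chain, self.seqnum, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}


@dataclass
class Structure:
    id: str
    residues: list[Residue]
    source: Literal["crystal", "predicted"] = "crystal"
    resolution: float | None = None
    space_group: str | None = None

    def __post_init__(self) -> None:
        if self.source == "predicted":
            self.resolution = None
            self.space_group = None
        seen: set[ResidueId] = set()
        for r in self.residues:
            if r.rid in seen:
                raise ValueError(f"duplicate residue id {format_residue_id(r.rid)}")
            seen.add(r.rid)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_map(self) -> dict[ResidueId, Residue]:
        return {r.rid: r for r in self.residues}

    def subset(self, ids: Iterable[ResidueId]) -> "Structure":
        """New structure containing only the listed residues, in their stored order."""
        wanted = set(ids)
        res = [r for r in self.residues if r.rid in wanted]
        return Structure(self.id, res, self.source, self.resolution, self.space_group)


@dataclass
class CorrespondenceMap:
    """Ordered pairing of residues between two structures at a given atom level."""

    pairs: list[tuple[ResidueId, ResidueId]]
    level: Level
    name_mismatches: list[tuple[ResidueId, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def a_ids(self) -> list[ResidueId]:
        return [a for a, _ in self.pairs]

    def b_ids(self) -> list[ResidueId]:
        return [b for _, b in self.pairs]


@dataclass
class PAEMatrix:
    """Predicted aligned error: values[i, j] is the expected error (Å) of
    residue i's position when the prediction is aligned on residue j."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise StructureParseError("PAE matrix must be square")
        if np.any(self.values < 0):
            raise StructureParseError("PAE matrix has negative entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def per_residue(self, reduction: str = "row_mean") -> np.ndarray:
        """Collapse to one value per residue (row mean by default)."""
        if reduction == "row_mean":
            return self.values.mean(axis=1)
        if reduction == "col_mean":
            return self.values.mean(axis=0)
        if reduction == "sym_mean":
            return 0.5 * (self.values.mean(axis=1) + self.values.mean(axis=0))
        raise ValueError(f"unknown PAE reduction {reduction!r}")


@dataclass
class ResidueProfile:
    """Per-residue scalar track (B-factor, pLDDT, deviation, row distance ...)."""

    keys: list[ResidueId]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.keys) != len(self.values):
            raise ValueError("keys and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    def __len__(self) -> int:
        return len(self.keys)

    def align_with(self, other: "ResidueProfile") -> tuple[np.ndarray, np.ndarray]:
        """Values of self and other on their shared residue keys, self's order."""
        other_map = dict(zip(other.keys, other.values))
        xs, ys = [], []
        for k, v in zip(self.keys, self.values):
            if k in other_map:
                xs.append(v)
                ys.append(other_map[k])
        return np.array(xs), np.array(ys)


# ---------------------------------------------------------------------------
# readers / writers

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    head = path.read_text(errors="replace")[:4096]
    if "_atom_site." in head or head.lstrip().startswith("data_"):
        return "mmcif"
    return "pdb"


def _pick_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    # keep, per atom name, the highest-occupancy conformer; ties -> first seen
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    source: Literal["crystal", "predicted", "auto"] = "auto",
    id: str | None = None,
) -> Structure:
    """Read model 1 of a PDB/mmCIF file into a :class:`Structure`.

    Hydrogens, waters and hetero residues are dropped; for alternate
    conformations the highest-occupancy altloc is kept (ties: first
    encountered).  With ``source="auto"`` the file is labelled ``crystal``
    when it carries a resolution or space group and ``predicted`` otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _detect_format(path) if format == "auto" else format
    cif_resolution = None
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            block = gemmi.cif.read(str(path)).sole_block()
            st = gemmi.make_structure_from_block(block)
            for tag in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
                raw = block.find_value(tag)
                if raw not in (None, ".", "?"):
                    cif_resolution = float(raw)
                    break
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.het_flag == "H" or res.name in _WATER_NAMES or res.is_water():
                continue
            atoms: list[AtomRecord] = []
            for atom in res:
                elem = atom.element.name
                if elem in ("H", "D"):
                    continue
                atoms.append(
                    AtomRecord(
                        name=atom.name,
                        element=elem,
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        tempfactor=max(atom.b_iso, 0.0),
                        altloc=atom.altloc if atom.altloc else "",
                    )
                )
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(chain.name, res.seqid.num, icode, res.name, _pick_altlocs(atoms))
            )
    if not residues:
        raise StructureParseError(f"{path}: empty model (no polymer residues)")

    resolution = st.resolution if st.resolution and st.resolution > 0 else cif_resolution
    space_group = st.spacegroup_hm or None
    if space_group in ("", "P 1") and resolution is None:
        space_group = None
    if source == "auto":
        source = "crystal" if (resolution is not None or space_group) else "predicted"
    residues.sort(key=lambda r: (r.chain, r.seqnum, r.icode))
    return Structure(
        id=id or path.stem,
        residues=residues,
        source=source,
        resolution=resolution if source == "crystal" else None,
        space_group=space_group if source == "crystal" else None,
    )


def write_structure(s: Structure, path: str | Path, format: Literal["pdb", "mmcif", "auto"] = "auto") -> None:
    """Write a structure as PDB or mmCIF (coordinates at PDB precision, 3 decimals)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = gemmi.Structure()
    st.name = s.id
    if s.resolution is not None:
        st.resolution = s.resolution
    if s.space_group is not None:
        st.spacegroup_hm = s.space_group
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in s.residues:
        if res.chain not in chains:
            chains[res.chain] = gemmi.Chain(res.chain)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
        gres.het_flag = "A"
        for a in res.atoms:
            gatom = gemmi.Atom()
            gatom.name = a.name
            gatom.element = gemmi.Element(a.element)
            gatom.pos = gemmi.Position(*np.round(a.coord, 3))
            gatom.occ = a.occupancy
            gatom.b_iso = a.tempfactor
            gres.add_atom(gatom)
        chains[res.chain].add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        if s.resolution is not None:
            # gemmi's writer omits resolution; record it where readers expect it
            doc.sole_block().set_pair("_refine.ls_d_res_high", f"{s.resolution:g}")
        doc.write_file(str(path))


def _atoms_for_level(ra: Residue, rb: Residue, level: Level) -> list[str] | None:
    """Atom names compared between a residue pair, or None if the pair fails the level."""
    if level == "calpha":
        names = ["CA"]
    elif level == "mainchain":
        names = list(MAINCHAIN_ATOMS)
    elif level == "allatom":
        names = sorted(ra.heavy_atom_names & rb.heavy_atom_names)
        if not names:
            return None
        return names
    else:
        raise ValueError(f"unknown level {level!r}")
    if all(n in ra.heavy_atom_names and n in rb.heavy_atom_names for n in names):
        return names
    return None


def build_correspondence(
    a: Structure,
    b: Structure,
    level: Level = "calpha",
    chain_map: Mapping[str, str] | None = None,
) -> CorrespondenceMap:
    """Pair residues of ``a`` and ``b`` by author numbering.

    Residues present in both structures (after optional chain renaming
    ``a-chain -> b-chain``) and possessing all atoms the level demands are
    paired in ``a``'s order.  Residue-name mismatches (e.g. point mutations
    in ligand-complex constructs) are retained but recorded in
    ``name_mismatches``.
    """
    chain_map = dict(chain_map or {})
    b_map = b.residue_map()
    pairs: list[tuple[ResidueId, ResidueId]] = []
    mismatches: list[tuple[ResidueId, str, str]] = []
    for ra in a.residues:
        b_chain = chain_map.get(ra.chain, ra.chain)
        bid: ResidueId = (b_chain, ra.seqnum, ra.icode)
        rb = b_map.get(bid)
        if rb is None:
            continue
        if _atoms_for_level(ra, rb, level) is None:
            continue
        if ra.name != rb.name:
            mismatches.append((ra.rid, ra.name, rb.name))
        pairs.append((ra.rid, bid))
    if not pairs:
        raise ValueError(f"no common residues between {a.id} and {b.id} at level {level}")
    return CorrespondenceMap(pairs=pairs, level=level, name_mismatches=mismatches)


def extract_profile(s: Structure, what: Literal["bfactor", "plddt"] = "bfactor") -> ResidueProfile:
    """Per-residue Cα temperature-factor track.

    ``what="plddt"`` reads the same column but validates the 0–100 range
    (predicted models store pLDDT there by convention); it is the caller's
    responsibility that the structure really is a predicted model.
    """
    keys: list[ResidueId] = []
    values: list[float] = []
    for r in s.residues:
        ca = r.atom("CA")
        if ca is None:
            warnings.warn(f"residue {format_residue_id(r.rid)} has no CA; skipped")
            continue
        if what == "plddt" and not 0.0 <= ca.tempfactor <= 100.0:
            raise ValueError(
                f"residue {format_residue_id(r.rid)}: value {ca.tempfactor} outside "
                "[0,100]; not a pLDDT-annotated model"
            )
        keys.append(r.rid)
        values.append(ca.tempfactor)
    return ResidueProfile(keys, np.array(values), label=what)


def write_profile_tsv(profile: ResidueProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"residue\t{profile.label or 'value'}\n")
        for k, v in zip(profile.keys, profile.values):
            fh.write(f"{format_residue_id(k)}\t{v:.4f}\n")


# --- PAE JSON (both public AlphaFold DB dialects) ---------------------------

def read_pae(path: str | Path) -> PAEMatrix:
    """Read a predicted-aligned-error JSON file.

    Supports both public dialects: the flat paired-index form
    (``residue1``/``residue2``/``distance`` lists) and the nested row-list
    form (``predicted_aligned_error`` holding n rows of n values).
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        if not data:
            raise StructureParseError(f"{path}: empty PAE JSON")
        data = data[0]
    if not isinstance(data, dict):
        raise StructureParseError(f"{path}: unrecognized PAE JSON layout")

    if "predicted_aligned_error" in data or "pae" in data:
        rows = data.get("predicted_aligned_error", data.get("pae"))
        lengths = {len(r) for r in rows}
        if len(lengths) != 1 or lengths.pop() != len(rows):
            raise StructureParseError(f"{path}: ragged or non-square PAE rows")
        return PAEMatrix(np.asarray(rows, dtype=float))

    if {"residue1", "residue2", "distance"} <= set(data):
        r1 = np.asarray(data["residue1"], dtype=int)
        r2 = np.asarray(data["residue2"], dtype=int)
        d = np.asarray(data["distance"], dtype=float)
        if not (len(r1) == len(r2) == len(d)):
            raise StructureParseError(f"{path}: inconsistent index/distance lengths")
        n = int(max(r1.max(), r2.max()))
        if len(d) != n * n:
            raise StructureParseError(f"{path}: {len(d)} entries do not fill a {n}x{n} matrix")
        m = np.full((n, n), np.nan)
        m[r1 - 1, r2 - 1] = d
        if np.any(np.isnan(m)):
            raise StructureParseError(f"{path}: missing (i,j) entries")
        return PAEMatrix(m)

    raise StructureParseError(f"{path}: no recognized PAE keys")


def write_pae(pae: PAEMatrix, path: str | Path, dialect: Literal["flat", "nested"] = "nested") -> None:
    """Write PAE JSON in either public dialect (used for round-trip testing)."""
    n = pae.n
    if dialect == "nested":
        payload = [{"predicted_aligned_error": pae.values.tolist(), "max_predicted_aligned_error": float(pae.values.max())}]
    else:
        ii, jj = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
        payload = [{
            "residue1": ii.ravel().tolist(),
            "residue2": jj.ravel().tolist(),
            "distance": pae.values.ravel().tolist(),
            "max_predicted_aligned_error": float(pae.values.max()),
        }]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def structure_coords(s: Structure, map_side: Sequence[ResidueId], level: Level,
                     other: "Structure | None" = None,
                     other_side: Sequence[ResidueId] | None = None) -> np.ndarray:
    """Stack coordinates of the mapped atoms of one structure (helper for superposition).

    When ``other``/``other_side`` are given, per-residue atom-name sets are
    restricted to names present in both residues, keeping row pairing exact
    at the allatom level.
    """
    rmap = s.residue_map()
    omap = other.residue_map() if other is not None else None
    coords: list[np.ndarray] = []
    for idx, rid in enumerate(map_side):
        r = rmap[rid]
        if omap is not None and other_side is not None:
            names = _atoms_for_level(r, omap[other_side[idx]], level)
        else:
            names = _atoms_for_level(r, r, level)
        if names is None:
            raise ValueError(f"residue {format_residue_id(rid)} lacks atoms for level {level}")
        for n in names:
            coords.append(r.atom(n).coord)
    return np.vstack(coords)
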