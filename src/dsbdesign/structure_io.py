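"""Protein structure and ensemble I/O on PDB-format files.

Parsing is delegated to :mod:`gemmi`; this module converts to light-weight
domain objects and applies the policies the pipeline relies on:

* author (auth) residue numbering is the canonical coordinate system,
* alternate locations are collapsed to the highest-occupancy conformer
  (ties broken by altloc character order),
* hydrogens are dropped, and waters/ligands (HETATM) are stripped by default,
* multi-model files become :class:`Ensemble` objects with uniformly spaced
  frame times (multi-model PDB carries no time records).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DisorderedRegion",
    "AtomRef",
    "Ensemble",
    "StructureError",
    "FormatError",
    "read_structure",
    "read_ensemble",
    "detect_missing_regions",
    "write_structure",
    "write_ensemble",
    "structure_coords",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Invalid or unusable structural data."""


class FormatError(StructureError):
    """File could not be parsed or written in PDB format."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) angstrom
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be 3 finite numbers")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    auth_seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.auth_seq_num}{self.icode}".rstrip()

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, *names: str) -> bool:
        return all(self.atom(n) is not None for n in names)


@dataclass
class Structure:
    identifier: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    seqres: dict[str, str] = field(default_factory=dict)  # 1-letter per chain

    def residues(self, chain: str | None = None) -> Iterator[Residue]:
        for cid, residues in self.chains.items():
            if chain is None or cid == chain:
                yield from residues

    def get_residue(self, chain_id: str, auth_seq_num: int, icode: str = "") -> Residue:
        for r in self.chains.get(chain_id, ()):
            if r.auth_seq_num == auth_seq_num and r.icode == icode:
                return r
        raise KeyError(f"residue {chain_id}/{auth_seq_num}{icode} not in structure")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class DisorderedRegion:
    """Residues expected from the sequence but absent from the coordinates."""

    chain_id: str
    start: int
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise StructureError(f"region start {self.start} > end {self.end}")

    def covers(self, seq_num: int, margin: int = 0) -> bool:
        return self.start - margin <= seq_num <= self.end + margin


@dataclass(frozen=True)
class AtomRef:
    """Identity of one atom inside an ensemble's flat atom table."""

    chain_id: str
    auth_seq_num: int
    icode: str
    res_name: str
    atom_name: str
    element: str


@dataclass
class Ensemble:
    """Ordered coordinate frames over a fixed atom selection.

    ``frames`` has shape (n_frames, n_atoms, 3); ``atoms`` gives the identity
    of each column.  ``times`` are picoseconds, strictly increasing.
    """

    frames: np.ndarray
    times: np.ndarray
    atoms: list[AtomRef]
    temperature_label: float | None = None
    reference: Structure | None = None
    selection: frozenset[str] | None = None
    identifier: str = "ensemble"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        self.times = np.asarray(self.times, float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atoms):
            raise StructureError("frame atom count does not match the atom table")
        if len(self.times) != len(self.frames):
            raise StructureError("one time stamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def atom_indices(self, names: Iterable[str]) -> np.ndarray:
        names = set(names)
        return np.array([i for i, a in enumerate(self.atoms) if a.atom_name in names], int)

    def find_atom(self, chain_id: str, auth_seq_num: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.auth_seq_num == auth_seq_num
                and a.atom_name == atom_name
            ):
                return i
        raise KeyError(
            f"atom {atom_name} of residue {chain_id}/{auth_seq_num} not in ensemble selection"
        )


# ---------------------------------------------------------------------------
# reading


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom name; ties by altloc order."""
    best: dict[str, Atom] = {}
    for a in atoms:
        prev = best.get(a.name)
        if prev is None or (a.occupancy, _neg_ord(a.altloc)) > (
            prev.occupancy,
            _neg_ord(prev.altloc),
        ):
            best[a.name] = a
    out = []
    for a in atoms:  # preserve original atom order
        if best.get(a.name) is a:
            kept = copy.copy(a)
            kept.altloc = ""
            out.append(kept)
    return out


def _neg_ord(altloc: str) -> int:
    # earlier altloc characters win ties -> larger score
    return -ord(altloc) if altloc else 0


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue | None:
    atoms = []
    for at in res:
        if at.element.is_hydrogen:
            continue
        atoms.append(
            Atom(
                name=at.name,
                element=at.element.name.upper(),
                coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                b_factor=at.b_iso,
                occupancy=min(max(at.occ, 0.0), 1.0),
                altloc=at.altloc if at.altloc != "\x00" else "",
            )
        )
    if not atoms:
        return None
    icode = res.seqid.icode.strip()
    return Residue(
        chain_id=chain_id,
        auth_seq_num=res.seqid.num,
        icode=icode,
        res_name=res.name,
        atoms=_collapse_altlocs(atoms),
    )


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    if res.is_water():
        return False
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown residue: trust the record type (ATOM = polymer)
    return res.het_flag == "A"


def _convert_model(
    st: gemmi.Structure,
    model: gemmi.Model,
    chain_filter: str | None,
    keep_hetero: bool,
    identifier: str,
) -> Structure:
    out = Structure(identifier=identifier)
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        residues = []
        for res in chain:
            if not keep_hetero and not _is_polymer_residue(res):
                continue
            if res.is_water():
                continue  # waters stripped even with keep_hetero
            conv = _convert_residue(chain.name, res)
            if conv is not None:
                residues.append(conv)
        if residues:
            out.chains[chain.name] = residues
    # SEQRES, mapped to chain names through gemmi's entity assignment
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        ent = st.get_entity_of(chain.get_polymer())
        if ent is not None and ent.full_sequence:
            seq = gemmi.one_letter_code(ent.full_sequence).upper()
            if seq:
                out.seqres[chain.name] = seq
    return out


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc
    st.setup_entities()
    return st


def read_structure(
    path: str | Path,
    format: str = "pdb",
    chain_filter: str | None = None,
    model_index: int = 0,
    keep_hetero: bool = False,
) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Waters and HETATM ligands are stripped unless ``keep_hetero`` (waters are
    always stripped); hydrogens and duplicate altlocs are removed.
    """
    if format != "pdb":
        raise FormatError(f"unsupported format {format!r}; only 'pdb' is implemented")
    st = _read_gemmi(path)
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    if model_index >= len(st):
        raise StructureError(f"{path}: model index {model_index} out of range ({len(st)} models)")
    s = _convert_model(st, st[model_index], chain_filter, keep_hetero, Path(path).stem)
    if s.n_atoms() == 0:
        raise StructureError(
            f"{path}: no atoms after filtering"
            + (f" (chain {chain_filter!r})" if chain_filter else "")
        )
    return s


def structure_coords(
    s: Structure, selection: Iterable[str] | None = None
) -> tuple[list[AtomRef], np.ndarray]:
    """Flatten a structure into an atom table and an (N, 3) coordinate array."""
    refs, xyz = [], []
    sel = set(selection) if selection is not None else None
    for r in s.residues():
        for a in r.atoms:
            if sel is None or a.name in sel:
                refs.append(
                    AtomRef(r.chain_id, r.auth_seq_num, r.icode, r.res_name, a.name, a.element)
                )
                xyz.append(a.coords)
    return refs, (np.array(xyz) if xyz else np.zeros((0, 3)))


def read_ensemble(
    path: str | Path,
    selection: Iterable[str] | None = None,
    frame_interval: float = 500.0,
    temperature_label: float | None = None,
    chain_filter: str | None = None,
) -> Ensemble:
    """Read a multi-model PDB file as an ordered ensemble of frames.

    Frames are ordered by MODEL number; times are assigned uniformly at
    ``frame_interval`` picoseconds (default 500 ps).  All models must present
    the same atoms, in the same order, for the requested selection.
    """
    st = _read_gemmi(path)
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    sel = frozenset(selection) if selection is not None else None
    ref_struct = _convert_model(st, st[0], chain_filter, False, Path(path).stem)

    atoms: list[AtomRef] | None = None
    frames = []
    for k, model in enumerate(st):
        s = _convert_model(st, model, chain_filter, False, Path(path).stem)
        refs, xyz = structure_coords(s, sel)
        if atoms is None:
            atoms = refs
            if not refs:
                raise StructureError(f"{path}: selection matches no atoms")
        elif refs != atoms:
            raise StructureError(
                f"{path}: model {k + 1} has inconsistent atoms "
                f"({len(refs)} vs {len(atoms)} in model 1)"
            )
        frames.append(xyz)
    assert atoms is not None
    n = len(frames)
    return Ensemble(
        frames=np.stack(frames),
        times=np.arange(n) * float(frame_interval),
        atoms=atoms,
        temperature_label=temperature_label,
        reference=ref_struct,
        selection=sel,
        identifier=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# missing-region detection


def detect_missing_regions(
    s: Structure,
    expected: dict[str, tuple[int, int]] | tuple[int, int] | None = None,
) -> list[DisorderedRegion]:
    """Find maximal runs of expected-but-absent residues (crystallographic disorder).

    ``expected`` gives the author-numbering range per chain, either explicitly
    (``{"A": (1, 300)}`` or a single ``(start, end)`` applied to every chain)
    or, when ``None``, derived from SEQRES assuming the author numbering of the
    modelled chain starts at 1 and runs to the SEQRES length.  Observed
    residues outside the expected range are warned about, never an error.
    """
    regions: list[DisorderedRegion] = []
    for cid, residues in s.chains.items():
        if isinstance(expected, dict):
            if cid not in expected:
                continue
            start, end = expected[cid]
        elif expected is not None:
            start, end = expected
        elif cid in s.seqres:
            start, end = 1, len(s.seqres[cid])
        else:
            raise StructureError(
                f"chain {cid}: no expected numbering given and no SEQRES available"
            )
        present = {r.auth_seq_num for r in residues}
        outside = sorted(n for n in present if n < start or n > end)
        if outside:
            log.warning(
                "chain %s: %d observed residues outside expected range %d-%d",
                cid,
                len(outside),
                start,
                end,
            )
        run_start = None
        for num in range(start, end + 2):
            absent = num <= end and num not in present
            if absent and run_start is None:
                run_start = num
            elif not absent and run_start is not None:
                regions.append(DisorderedRegion(cid, run_start, num - 1))
                run_start = None
    regions.sort(key=lambda r: (r.chain_id, r.start))
    return regions


# ---------------------------------------------------------------------------
# writing

_COORD_MIN, _COORD_MAX = -999.999, 9999.999  # PDB %8.3f field width


def _to_gemmi(structures: Sequence[Structure], identifier: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = identifier
    for k, s in enumerate(structures):
        model = gemmi.Model(k + 1)
        for cid, residues in s.chains.items():
            chain = gemmi.Chain(cid)
            for r in residues:
                gr = gemmi.Residue()
                gr.name = r.res_name
                gr.seqid = gemmi.SeqId(r.auth_seq_num, r.icode or " ")
                for a in r.atoms:
                    if not all(_COORD_MIN <= c <= _COORD_MAX for c in a.coords):
                        raise FormatError(
                            f"atom {a.name} of {r.label}: coordinate outside the "
                            f"PDB fixed-width field ({_COORD_MIN}..{_COORD_MAX})"
                        )
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coords)
                    ga.occ = a.occupancy
                    ga.b_iso = a.b_factor
                    gr.add_atom(ga)
                chain.add_residue(gr)
            model.add_chain(chain)
        st.add_model(model)
    return st


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file (3-decimal coordinates)."""
    st = _to_gemmi([s], s.identifier)
    st.write_pdb(str(path))


def write_ensemble(e: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (MODEL/ENDMDL records)."""
    models = []
    for f in range(e.n_frames):
        s = Structure(identifier=e.identifier)
        current: Residue | None = None
        for ref, xyz in zip(e.atoms, e.frames[f]):
            if (
                current is None
                or current.key != (ref.chain_id, ref.auth_seq_num, ref.icode)
            ):
                current = Residue(ref.chain_id, ref.auth_seq_num, ref.icode, ref.res_name)
                s.chains.setdefault(ref.chain_id, []).append(current)
            current.atoms.append(Atom(name=ref.atom_name, element=ref.element, coords=xyz))
        models.append(s)
    st = _to_gemmi(models, e.identifier)
    st.write_pdb(str(path))
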