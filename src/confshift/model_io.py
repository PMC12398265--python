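"""Structure, trajectory, region and table I/O.

Conventions fixed here for the whole package:

* All internal coordinates are in **nanometres**.  PDB files store
  angstroms; conversion happens at the I/O boundary and nowhere else.
* Residue numbering is 1-based mature-protein numbering; region spans are
  inclusive on both ends.
* Per-atom van-der-Waals radii are assigned from :data:`VDW_RADII_NM` at
  read time and travel with the model, so every downstream surface-area
  computation sees one consistent table.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from confshift.errors import (
    ConfigError,
    EmptyInputError,
    FormatError,
    InputError,
    TopologyMismatchError,
)

ANGSTROM_PER_NM = 10.0

#: van-der-Waals radii in nm (Bondi-style values).  Hydrogens, when present
#: in the input, carry their own radius; they are never merged into heavy
#: atoms.  Unknown elements fall back to the carbon radius.
VDW_RADII_NM: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "SE": 0.190,
    "F": 0.147,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
}
DEFAULT_RADIUS_NM = 0.170

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HSD": "H", "HSE": "H", "HSP": "H", "MSE": "M",
}


def radius_for_element(element: str, table: Mapping[str, float] | None = None) -> float:
    table = VDW_RADII_NM if table is None else table
    return table.get(element.upper().strip(), DEFAULT_RADIUS_NM)


@dataclass(frozen=True)
class Atom:
    """One atom of a :class:`MolecularModel`; position in nm."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InputError(f"atom {self.serial}: radius must be positive")
        if not np.all(np.isfinite(self.position)):
            raise InputError(f"atom {self.serial}: non-finite position")


class MolecularModel:
    """A single conformation: atoms with coordinates (nm), radii and identity.

    Internally column-oriented (one numpy array per field) so frame-sized
    numerics never touch Python objects; :meth:`atoms` materialises
    :class:`Atom` records on demand.
    """

    def __init__(
        self,
        coords: np.ndarray,
        elements: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        atom_names: Sequence[str] | None = None,
        serials: Sequence[int] | None = None,
        radii: Sequence[float] | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError("coords must have shape (n_atoms, 3)")
        n = coords.shape[0]
        if n == 0:
            raise EmptyInputError("a MolecularModel needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")
        self.coords = coords
        self.elements = np.asarray(elements, dtype="U2")
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U3")
        self.chain_ids = np.asarray(chain_ids, dtype="U1")
        self.atom_names = (
            np.asarray(atom_names, dtype="U4")
            if atom_names is not None
            else np.asarray(["CA"] * n, dtype="U4")
        )
        self.serials = (
            np.asarray(serials, dtype=int)
            if serials is not None
            else np.arange(1, n + 1)
        )
        if radii is None:
            radii = [radius_for_element(e) for e in self.elements]
        self.radii = np.asarray(radii, dtype=float)
        for arr, label in [
            (self.elements, "elements"), (self.residue_numbers, "residue_numbers"),
            (self.residue_names, "residue_names"), (self.chain_ids, "chain_ids"),
            (self.atom_names, "atom_names"), (self.serials, "serials"),
            (self.radii, "radii"),
        ]:
            if len(arr) != n:
                raise InputError(f"{label} has {len(arr)} entries, expected {n}")
        if np.any(self.radii <= 0):
            raise InputError("all radii must be positive")
        for chain in np.unique(self.chain_ids):
            res = self.residue_numbers[self.chain_ids == chain]
            if np.any(np.diff(res) < 0):
                raise InputError(
                    f"residue numbers decrease within chain {chain!r}"
                )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                serial=int(self.serials[i]),
                name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                residue_number=int(self.residue_numbers[i]),
                residue_name=str(self.residue_names[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.coords[i],
                radius=float(self.radii[i]),
            )
            for i in range(self.n_atoms)
        ]

    @property
    def sequence(self) -> dict[str, str]:
        """One-letter residue sequence per chain, in residue order."""
        out: dict[str, str] = {}
        for chain in np.unique(self.chain_ids):
            mask = self.chain_ids == chain
            seen: list[int] = []
            letters: list[str] = []
            for num, name in zip(self.residue_numbers[mask], self.residue_names[mask]):
                if not seen or num != seen[-1]:
                    seen.append(int(num))
                    letters.append(THREE_TO_ONE.get(str(name).upper(), "X"))
            out[str(chain)] = "".join(letters)
        return out

    def residue_indices(
        self, residues: Iterable[int], chain: str | None = None
    ) -> np.ndarray:
        """Atom indices belonging to the given residue numbers."""
        wanted = set(int(r) for r in residues)
        mask = np.isin(self.residue_numbers, sorted(wanted))
        if chain is not None:
            mask &= self.chain_ids == chain
        present = set(int(r) for r in self.residue_numbers[mask])
        missing = wanted - present
        if missing:
            raise InputError(f"residues not in model: {sorted(missing)}")
        return np.nonzero(mask)[0]

    def ca_indices(self) -> np.ndarray:
        """Indices of Cα atoms; falls back to all atoms for bead models
        (one atom per residue) that carry no CA naming."""
        idx = np.nonzero(self.atom_names == "CA")[0]
        return idx if idx.size else np.arange(self.n_atoms)

    def with_coords(self, coords: np.ndarray) -> "MolecularModel":
        return MolecularModel(
            coords,
            self.elements,
            self.residue_numbers,
            self.residue_names,
            self.chain_ids,
            self.atom_names,
            self.serials,
            self.radii,
        )


@dataclass
class Trajectory:
    """Ordered frames over one topology; coordinates in nm, frame interval in ps."""

    topology: MolecularModel
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 100.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("trajectory coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"frames carry {self.coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise InputError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, coords, self.frame_interval)


@dataclass(frozen=True)
class RegionSet:
    """Named 1-based residue ranges (inclusive), optionally chain-qualified."""

    regions: Mapping[str, frozenset[int]]
    chains: Mapping[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, residues in self.regions.items():
            if not residues:
                raise ConfigError(f"region {name!r} is empty")

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def names(self) -> list[str]:
        return list(self.regions)

    def residues(self, name: str) -> frozenset[int]:
        try:
            return self.regions[name]
        except KeyError:
            raise ConfigError(f"unknown region {name!r}") from None

    def chain(self, name: str) -> str | None:
        return self.chains.get(name)

    def atom_indices(self, model: MolecularModel, name: str) -> np.ndarray:
        return model.residue_indices(self.residues(name), self.chain(name))


# ---------------------------------------------------------------------------
# PDB reading / writing (via biotite)
# ---------------------------------------------------------------------------


def _model_from_atom_array(arr) -> MolecularModel:
    import biotite.structure as struc  # noqa: F401  (typing only)

    chain_ids = ["A" if c.strip() == "" else c for c in arr.chain_id]
    return MolecularModel(
        coords=np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM,
        elements=[e if e else "C" for e in arr.element],
        residue_numbers=arr.res_id,
        residue_names=arr.res_name,
        chain_ids=chain_ids,
        atom_names=arr.atom_name,
        serials=np.arange(1, arr.array_length() + 1),
    )


def _first_bad_atom_line(pdb_text: str) -> str | None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                return f"line {lineno}: {line.rstrip()}"
    return None


def read_structure(pdb_text: str) -> MolecularModel:
    """Parse PDB text (first model) into a :class:`MolecularModel` in nm."""
    import biotite.structure.io.pdb as pdbio

    if not any(l.startswith(("ATOM", "HETATM")) for l in pdb_text.splitlines()):
        raise EmptyInputError("no ATOM/HETATM records in input")
    try:
        pdb_file = pdbio.PDBFile.read(io.StringIO(pdb_text))
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:
        bad = _first_bad_atom_line(pdb_text)
        detail = f" ({bad})" if bad else ""
        raise FormatError(f"unparseable PDB record{detail}: {exc}") from exc
    return _model_from_atom_array(arr)


def read_trajectory(
    source,
    topology: MolecularModel | None = None,
    frame_interval: float = 100.0,
) -> Trajectory:
    """Read a multi-model PDB (text, path or file-like) or a DCD file (path;
    requires ``topology``) into a :class:`Trajectory`."""
    if isinstance(source, (str, os.PathLike)) and str(source).lower().endswith(".dcd"):
        return _read_dcd(str(source), topology, frame_interval)
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    return _read_multimodel_pdb(text, frame_interval)


def _read_multimodel_pdb(text: str, frame_interval: float) -> Trajectory:
    import biotite.structure.io.pdb as pdbio

    if not any(l.startswith(("ATOM", "HETATM")) for l in text.splitlines()):
        raise EmptyInputError("no ATOM/HETATM records in input")
    pdb_file = pdbio.PDBFile.read(io.StringIO(text))
    try:
        stack = pdb_file.get_structure()  # AtomArrayStack: all models
    except Exception as exc:
        if "atoms" in str(exc) and "model" in str(exc):
            raise TopologyMismatchError(str(exc)) from exc
        bad = _first_bad_atom_line(text)
        detail = f" ({bad})" if bad else ""
        raise FormatError(f"unparseable PDB record{detail}: {exc}") from exc
    first = stack[0] if stack.stack_depth() else None
    if first is None:
        raise EmptyInputError("no models in input")
    model = _model_from_atom_array(first)
    coords = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
    return Trajectory(model, coords, frame_interval)


def _read_dcd(
    path: str, topology: MolecularModel | None, frame_interval: float
) -> Trajectory:
    if topology is None:
        raise InputError("reading DCD requires an explicit topology")
    from MDAnalysis.coordinates.DCD import DCDReader

    reader = DCDReader(path)
    frames = []
    for ts in reader:
        if ts.positions.shape[0] != topology.n_atoms:
            raise TopologyMismatchError(
                f"DCD frame has {ts.positions.shape[0]} atoms, topology has "
                f"{topology.n_atoms}"
            )
        frames.append(np.array(ts.positions, dtype=float) / ANGSTROM_PER_NM)
    reader.close()
    if not frames:
        raise EmptyInputError(f"no frames in {path}")
    return Trajectory(topology, np.stack(frames), frame_interval)


def write_structure(obj: MolecularModel | Trajectory, destination=None) -> str:
    """Write a model (single MODEL) or trajectory (multi-model) as PDB text.

    Returns the text; if ``destination`` is a path or file-like it is also
    written there.  Coordinates are converted back to angstroms.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if isinstance(obj, Trajectory):
        model, frames = obj.topology, obj.coords
    else:
        model, frames = obj, obj.coords[np.newaxis]

    n = model.n_atoms
    arrays = struc.AtomArrayStack(frames.shape[0], n)
    arrays.coord = np.asarray(frames, dtype=np.float32) * ANGSTROM_PER_NM
    arrays.chain_id = model.chain_ids.astype("U4")
    arrays.res_id = model.residue_numbers
    arrays.res_name = model.residue_names.astype("U5")
    arrays.atom_name = model.atom_names.astype("U6")
    arrays.element = model.elements.astype("U2")
    arrays.set_annotation("hetero", np.zeros(n, dtype=bool))
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arrays)
    buf = io.StringIO()
    pdb_file.write(buf)
    text = buf.getvalue()
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Region configuration
# ---------------------------------------------------------------------------


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ConfigError(f"duplicate region name {key!r}")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def _expand_span(name: str, value) -> tuple[frozenset[int], str | None]:
    chain = None
    if isinstance(value, Mapping):
        chain = value.get("chain")
        value = f"{value['start']}-{value['end']}"
    if isinstance(value, int):
        return frozenset({value}), chain
    text = str(value).strip()
    if ":" in text:
        text, chain = text.split(":", 1)
        chain = chain.strip()
    parts = text.split("-")
    if len(parts) != 2:
        raise ConfigError(f"region {name!r}: expected 'start-end', got {value!r}")
    try:
        start, end = int(parts[0]), int(parts[1])
    except ValueError:
        raise ConfigError(f"region {name!r}: non-integer span {value!r}") from None
    if start > end:
        raise ConfigError(f"region {name!r}: start {start} > end {end}")
    return frozenset(range(start, end + 1)), chain


def load_regions(config_text: str) -> RegionSet:
    """Parse a YAML mapping of region name -> 'start-end' (or single residue)
    into a :class:`RegionSet` with inclusive spans."""
    try:
        data = yaml.load(config_text, Loader=_StrictLoader)
    except ConfigError:
        raise
    except yaml.YAMLError as exc:
        raise FormatError(f"invalid YAML: {exc}") from exc
    if not isinstance(data, Mapping) or not data:
        raise ConfigError("region config must be a non-empty mapping")
    regions: dict[str, frozenset[int]] = {}
    chains: dict[str, str | None] = {}
    for name, value in data.items():
        residues, chain = _expand_span(str(name), value)
        regions[str(name)] = residues
        chains[str(name)] = chain
    return RegionSet(regions, chains)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_table(table, destination) -> None:
    """Write rows (DataFrame or iterable of mappings) as a TSV with a header.

    Decimal points are locale-independent; SEM columns keep the '±'
    convention in their header (e.g. ``sem (±)``).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(list(table))
    if table.empty:
        raise EmptyInputError("refusing to write an empty table")
    try:
        table.to_csv(destination, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise InputError(f"cannot write table: {exc}") from exc
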