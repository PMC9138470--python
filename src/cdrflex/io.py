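"""Ensemble input/output and the shared data model.

Conformational ensembles are read from multi-model PDB files (MODEL/ENDMDL
delimited), per-frame bias potentials from PLUMED COLVAR-style tables, and
loop definitions (CDR1/2/3, HV4) from a plain-text region config.  All
coordinates are stored internally in nanometres — the unit of every distance
cut-off in this pipeline — and converted from/to Ångström at the PDB boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

logger = logging.getLogger(__name__)

#: Boltzmann constant in kJ/(mol K), GROMACS value.
KB = 0.0083144621

#: Residue names treated as standard amino acids (require a CA atom).
_STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class Topology:
    """Static atom/residue description of one chain system.

    Residue numbering is 1-based and taken verbatim from the coordinate file.
    ``is_heavy`` flags every non-hydrogen atom; the heavy-atom selection feeds
    the contact definition and the CA selection feeds RMSD computations.
    """

    atom_name: np.ndarray        # (n_atoms,) str
    element: np.ndarray          # (n_atoms,) str
    is_heavy: np.ndarray         # (n_atoms,) bool
    res_id: np.ndarray           # (n_atoms,) int, 1-based, non-decreasing
    res_name: np.ndarray         # (n_atoms,) str
    chain_id: np.ndarray         # (n_atoms,) str

    def __post_init__(self) -> None:
        if len(self.atom_name) == 0:
            raise ValueError("topology has no atoms")
        if np.any(np.diff(self.res_id) < 0):
            raise ValueError("residue indices must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue ids."""
        return np.unique(self.res_id)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def ca_indices(self, residues: np.ndarray | None = None) -> np.ndarray:
        """Atom indices of CA atoms, optionally restricted to given residue ids."""
        mask = self.atom_name == "CA"
        if residues is not None:
            mask &= np.isin(self.res_id, residues)
        return np.flatnonzero(mask)

    def heavy_indices(self, residues: np.ndarray | None = None) -> np.ndarray:
        mask = self.is_heavy.copy()
        if residues is not None:
            mask &= np.isin(self.res_id, residues)
        return np.flatnonzero(mask)


@dataclass
class ConformationalEnsemble:
    """Frames of 3D coordinates plus optional bias/weight annotation.

    ``frames`` has shape (n_frames, n_atoms, 3) in nm.  ``bias`` is the
    per-frame metadynamics bias potential V_PB in kJ/mol; ``weights`` the
    normalised statistical weights w_i.  When both are present they must be
    related by w_i ∝ exp(V_PB,i / kB T) at ``temperature``.
    """

    topology: Topology
    frames: np.ndarray
    bias: np.ndarray | None = None
    weights: np.ndarray | None = None
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (self.n_frames,):
                raise ValueError("bias length must equal the number of frames")
            if not np.all(np.isfinite(self.bias)):
                raise ValueError("bias values must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_frames,):
                raise ValueError("weights length must equal the number of frames")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1 within 1e-9")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def effective_weights(self) -> np.ndarray:
        """Stored weights, or uniform weights when none are attached."""
        if self.weights is not None:
            return self.weights
        return np.full(self.n_frames, 1.0 / self.n_frames)


@dataclass(frozen=True)
class RegionSet:
    """Named inclusive 1-based residue ranges plus the derived scaffold.

    The scaffold is the complement of all named loop ranges within the chain;
    loop ranges must not overlap.
    """

    ranges: dict[str, tuple[int, int]]
    n_residues: int
    all_residue_ids: np.ndarray = field(repr=False)

    SCAFFOLD = "scaffold"

    def __post_init__(self) -> None:
        covered: set[int] = set()
        ids = set(int(r) for r in self.all_residue_ids)
        lo, hi = min(ids), max(ids)
        for name, (start, end) in self.ranges.items():
            if start > end:
                raise ValueError(f"region {name!r}: start {start} > end {end}")
            if start < lo or end > hi:
                raise ValueError(
                    f"region {name!r} ({start}-{end}) outside residue range {lo}-{hi}"
                )
            members = set(range(start, end + 1))
            overlap = covered & members
            if overlap:
                raise ValueError(
                    f"region {name!r} overlaps another named region at residues "
                    f"{sorted(overlap)[:5]}"
                )
            covered |= members

    def residues(self, name: str) -> np.ndarray:
        """1-based residue ids of the named region (or the derived scaffold)."""
        if name == self.SCAFFOLD:
            named: set[int] = set()
            for start, end in self.ranges.values():
                named |= set(range(start, end + 1))
            out = np.array(
                [r for r in self.all_residue_ids if int(r) not in named], dtype=int
            )
            if out.size == 0:
                warnings.warn("scaffold region is empty (named regions cover the chain)")
            return out
        if name not in self.ranges:
            raise KeyError(
                f"unknown region {name!r}; available: "
                f"{sorted(self.ranges) + [self.SCAFFOLD]}"
            )
        start, end = self.ranges[name]
        mask = (self.all_residue_ids >= start) & (self.all_residue_ids <= end)
        return self.all_residue_ids[mask]

    @property
    def names(self) -> list[str]:
        return list(self.ranges) + [self.SCAFFOLD]


@dataclass(frozen=True)
class BiasTable:
    """Rows of a PLUMED COLVAR-style table, one bias value per frame."""

    time: np.ndarray       # (n_rows,)
    bias: np.ndarray       # (n_rows,) kJ/mol
    fields: tuple[str, ...]
    bias_field: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.bias)):
            raise ValueError("bias values must be finite")

    @property
    def n_rows(self) -> int:
        return len(self.bias)

    def aligned_bias(self, n_frames: int, stride: int = 1) -> np.ndarray:
        """Map table rows onto ensemble frames using an explicit stride.

        With ``stride`` s, frame k reads row k*s.  Any mismatch between the
        strided row count and the frame count is an error, never a silent
        truncation.
        """
        if stride < 1:
            raise ValueError("stride must be >= 1")
        strided = self.bias[::stride]
        if len(strided) != n_frames:
            raise ValueError(
                f"bias table has {self.n_rows} rows; stride {stride} yields "
                f"{len(strided)} values but the ensemble has {n_frames} frames"
            )
        return strided


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: Path) -> None:
    """Cheap line-level scan producing errors that name the offending line."""
    n_atoms_per_model: list[int] = []
    current = 0
    in_model = False
    seen_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, seen_model, current = True, True, 0
            elif rec == "ENDMDL":
                n_atoms_per_model.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: unparseable {rec} record at line {lineno}"
                    ) from exc
                current += 1
    if seen_model and in_model and current:
        n_atoms_per_model.append(current)  # trailing model without ENDMDL
    if not seen_model and current:
        n_atoms_per_model.append(current)
    if not n_atoms_per_model or n_atoms_per_model[0] == 0:
        raise ValueError(f"{path}: no ATOM records found")
    ref = n_atoms_per_model[0]
    for i, n in enumerate(n_atoms_per_model, start=1):
        if n != ref:
            raise ValueError(
                f"{path}: model {i} has {n} atoms, expected {ref}"
            )


def _topology_from_atom_array(atoms: struc.AtomArray) -> Topology:
    element = np.char.upper(atoms.element.astype(str))
    is_heavy = element != "H"
    topo = Topology(
        atom_name=atoms.atom_name.astype(str),
        element=element,
        is_heavy=is_heavy,
        res_id=atoms.res_id.astype(int),
        res_name=atoms.res_name.astype(str),
        chain_id=atoms.chain_id.astype(str),
    )
    # warn (not fail) on standard residues lacking a CA atom
    for rid in topo.residue_ids:
        sel = topo.res_id == rid
        rname = topo.res_name[sel][0]
        if rname in _STANDARD_RESIDUES and "CA" not in topo.atom_name[sel]:
            warnings.warn(f"residue {rid} ({rname}) has no CA atom")
    return topo


def load_topology(path: str | Path) -> Topology:
    """Read atom/residue structure from the first model of a PDB file."""
    path = Path(path)
    _validate_pdb_text(path)
    pdb = pdbio.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    return _topology_from_atom_array(atoms)


def load_ensemble(
    topology: Topology,
    path: str | Path,
    temperature: float = 300.0,
) -> ConformationalEnsemble:
    """Read a multi-model PDB into an ensemble (coordinates Å → nm).

    Every model must contain the same atoms in the same order as ``topology``;
    an atom-count mismatch reports the 1-based model index.
    """
    path = Path(path)
    _validate_pdb_text(path)
    pdb = pdbio.PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if stack.array_length() != topology.n_atoms:
        raise ValueError(
            f"{path}: models have {stack.array_length()} atoms, topology has "
            f"{topology.n_atoms}"
        )
    frames = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
    return ConformationalEnsemble(topology=topology, frames=frames,
                                  temperature=temperature)


def write_ensemble(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (coordinates nm → Å)."""
    topo = ensemble.topology
    n = topo.n_atoms
    array = struc.AtomArray(n)
    array.atom_name = topo.atom_name
    array.element = topo.element
    array.res_id = topo.res_id
    array.res_name = topo.res_name
    array.chain_id = topo.chain_id
    stack = struc.stack([array] * ensemble.n_frames)
    stack.coord = (ensemble.frames * ANGSTROM_PER_NM).astype(np.float32)
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def load_bias_table(path: str | Path, bias_field: str = "pb.bias") -> BiasTable:
    """Parse a PLUMED COLVAR-style table.

    The first line must be ``#! FIELDS <name> ...``; rows are whitespace
    separated floats.  Restart artefacts (repeated time values) are dropped,
    keeping the last occurrence.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#!"):
            raise ValueError(f"{path}: missing '#! FIELDS' header line")
        tokens = header.split()
        if len(tokens) < 3 or tokens[1] != "FIELDS":
            raise ValueError(f"{path}: malformed FIELDS header: {header.strip()!r}")
        fields = tuple(tokens[2:])
        if bias_field not in fields:
            raise ValueError(
                f"{path}: bias column {bias_field!r} not found; available "
                f"fields: {list(fields)}"
            )
        bias_col = fields.index(bias_field)
        time_col = fields.index("time") if "time" in fields else 0
        times, biases = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(fields):
                raise ValueError(
                    f"{path}: row at line {lineno} has {len(parts)} columns, "
                    f"expected {len(fields)}"
                )
            try:
                times.append(float(parts[time_col]))
                biases.append(float(parts[bias_col]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value at line {lineno}"
                ) from exc
    time = np.array(times)
    bias = np.array(biases)
    # restart dedup: keep the LAST row for each repeated time value
    _, last_idx = np.unique(time[::-1], return_index=True)
    keep = np.sort(len(time) - 1 - last_idx)
    if len(keep) != len(time):
        logger.info("dropped %d duplicate-time rows (restart artefacts)",
                    len(time) - len(keep))
    return BiasTable(time=time[keep], bias=bias[keep], fields=fields,
                     bias_field=bias_field)


def load_regions(path: str | Path, topology: Topology) -> RegionSet:
    """Read a region config: one ``name start end`` entry per line.

    Ranges are 1-based inclusive and taken as given (no reconciliation against
    sequence content); '#' starts a comment.
    """
    path = Path(path)
    ranges: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'name start end', got {line!r}"
                )
            name, start_s, end_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer bound") from exc
            if name in ranges:
                raise ValueError(f"{path}: duplicate region {name!r}")
            ranges[name] = (start, end)
    return RegionSet(ranges=ranges, n_residues=topology.n_residues,
                     all_residue_ids=topology.residue_ids)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# region config: name start end (1-based inclusive)\n")
        for name, (start, end) in regions.ranges.items():
            fh.write(f"{name} {start} {end}\n")


def load_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read named amino-acid sequences from a FASTA file."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
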