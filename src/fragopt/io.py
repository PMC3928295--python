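"""File I/O: XYZ geometries and trajectories, PDB, fragment specs, configs.

XYZ files use the standard two-header-line dialect with coordinates in Å;
multi-frame trajectories are plain concatenations.  PDB reading (ATOM/
HETATM coordinates; residues suggest fragment groups) is delegated to
Biopython.  Fragment specifications and run configurations are YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .config import RunConfig
from .fragments import DomainPartition, FragmentSet, build_fragments
from .geometry import SystemGeometry

logger = logging.getLogger("fragopt.io")


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# --------------------------------------------------------------------------
# XYZ


def read_xyz(path) -> SystemGeometry:
    """Read the first frame of an XYZ file (coordinates in Å)."""
    return read_xyz_trajectory(path)[0]


def read_xyz_trajectory(path) -> list[SystemGeometry]:
    lines = Path(path).read_text().splitlines()
    frames: list[SystemGeometry] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"expected atom count, got {lines[i]!r}", line=i + 1)
        if count < 1:
            raise ParseError(f"non-positive atom count {count}", line=i + 1)
        start = i + 2  # skip comment line
        elements, coords = [], []
        for k in range(count):
            ln = start + k
            if ln >= len(lines) or not lines[ln].strip():
                raise ParseError(
                    f"expected atom record {k + 1}/{count}", line=ln + 1
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"short atom record {lines[ln]!r}", line=ln + 1)
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"bad coordinates in {lines[ln]!r}", line=ln + 1)
            elements.append(parts[0])
            coords.append(xyz)
        try:
            frames.append(SystemGeometry.from_angstrom(elements, coords))
        except ValueError as exc:
            raise ParseError(str(exc), line=i + 1) from exc
        i = start + count
    if not frames:
        raise ParseError("no frames found in XYZ file")
    return frames


def write_xyz(geometry, path, comment: str = "") -> None:
    """Write one geometry or a list of geometries (trajectory) as XYZ."""
    frames = geometry if isinstance(geometry, (list, tuple)) else [geometry]
    out = []
    for frame_idx, geom in enumerate(frames):
        coords = geom.coords_angstrom()
        out.append(str(geom.atom_count))
        out.append(comment if len(frames) == 1 else f"{comment} frame {frame_idx}")
        for el, (x, y, z) in zip(geom.elements, coords):
            out.append(f"{el:<3s} {x: .10f} {y: .10f} {z: .10f}")
    Path(path).write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# PDB


def read_pdb(path) -> tuple[SystemGeometry, list[list[int]]]:
    """Read ATOM/HETATM coordinates; suggest fragment groups by residue.

    Groups follow (chain, residue number) order of appearance.  For
    disordered atoms the first conformer is kept (a warning is logged);
    CONECT records are ignored.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("system", str(path))
    elements, coords, groups = [], [], []
    group_index: dict[tuple, int] = {}
    saw_altloc = False
    model = next(iter(structure), None)
    if model is None:
        raise ParseError("no ATOM records found in PDB file")
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.is_disordered():
                    saw_altloc = True
                    atom = atom.disordered_get_list()[0]
                key = (chain.id, residue.id[1])
                if key not in group_index:
                    group_index[key] = len(groups)
                    groups.append([])
                groups[group_index[key]].append(len(elements))
                el = (atom.element or atom.get_name()[0]).strip().capitalize()
                elements.append(el)
                coords.append(atom.coord)
    if not elements:
        raise ParseError("no ATOM records found in PDB file")
    if saw_altloc:
        logger.warning("alternate locations present; first conformer kept")
    return SystemGeometry.from_angstrom(elements, np.array(coords)), groups


# --------------------------------------------------------------------------
# fragment spec / config


def read_fragment_spec(
    path, geometry: SystemGeometry
) -> tuple[FragmentSet, DomainPartition | None]:
    """Read a YAML fragment/domain specification.

    Schema::

        fragments:
          - atoms: [start, stop]     # 0-based, half-open range, or an
            charge: 0                # explicit list of atom indices
            domain: A                # optional override: A, b, or F
        high_level: 0                # optional; required if domains given

    Returns the fragment set and, when every fragment carries a domain
    label, the corresponding partition.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "fragments" not in data:
        raise ParseError("fragment spec must contain a 'fragments' list")
    spec, domains = [], []
    for entry in data["fragments"]:
        atoms = entry.get("atoms")
        if (
            isinstance(atoms, list)
            and len(atoms) == 2
            and all(isinstance(a, int) for a in atoms)
            and entry.get("atoms_are_range", True)
        ):
            atom_list = list(range(atoms[0], atoms[1]))
        elif isinstance(atoms, list):
            atom_list = [int(a) for a in atoms]
        else:
            raise ParseError(f"bad 'atoms' entry: {atoms!r}")
        spec.append((atom_list, int(entry.get("charge", 0))))
        domains.append(entry.get("domain"))
    fragments = build_fragments(geometry, spec)
    partition = None
    if all(d is not None for d in domains):
        high = data.get("high_level")
        if high is None:
            raise ParseError("domain labels given but 'high_level' missing")
        partition = DomainPartition(
            frozen=frozenset(i for i, d in enumerate(domains) if d == "F"),
            polarizable=frozenset(i for i, d in enumerate(domains) if d == "b"),
            active=frozenset(i for i, d in enumerate(domains) if d == "A"),
            high_level=int(high),
        )
    return fragments, partition


def write_fragment_spec(path, fragments: FragmentSet, partition=None) -> None:
    entries = []
    for frag in fragments:
        entry = {
            "atoms": list(frag.atom_indices),
            "atoms_are_range": False,
            "charge": frag.charge,
        }
        if partition is not None:
            entry["domain"] = partition.domain_of(frag.id)
        entries.append(entry)
    data: dict = {"fragments": entries}
    if partition is not None:
        data["high_level"] = partition.high_level
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


# --------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Provenance record for one CLI run."""

    config: dict
    backend: str
    input_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)

    def add_input(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_hashes[str(path)] = digest

    def add_output(self, path) -> None:
        if not Path(path).exists():
            raise FileNotFoundError(f"output {path} missing at manifest time")
        self.outputs.append(str(path))

    def write(self, path) -> None:
        payload = {
            "config": self.config,
            "backend": self.backend,
            "inputs": self.input_hashes,
            "outputs": self.outputs,
            "timings": self.timings,
            "elapsed_s": time.time() - self.started,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
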