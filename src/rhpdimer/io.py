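"""Readers and writers for topologies, trajectories and configuration.

Formats:

* **Topology** — standard PDB (chain id, residue name/number, atom name,
  element column), read and written through MDAnalysis.  A
  :class:`ResidueMap` assigns each polymer residue name a monomer code and
  flags water/ion residue names.
* **Trajectory, binary** — DCD (fixed-width per-frame coordinate blocks
  with a box record), via MDAnalysis.  Frame times are reconstructed from
  the header time step and are therefore float32-limited.
* **Trajectory, text** — an XYZ dialect with one header line per frame::

      <n_atoms>
      t= <time_ns> box= <lx> <ly> <lz>
      <atom_name> <x> <y> <z>        (coordinates in Å, %.8e)

  Coordinates are printed with nine significant digits so float32 values
  round-trip exactly.
* **Configuration** — YAML key-value files for :class:`AnalysisConfig`,
  :class:`ResidueMap` and run manifests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import AnalysisConfig, SystemTopology, Trajectory

__all__ = [
    "ResidueMap",
    "DEFAULT_RESIDUE_MAP",
    "load_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "load_config",
    "save_config",
]

CODE_TO_RESNAME = {"M": "MMA", "O": "OEG", "E": "EHM", "S": "SPM"}


@dataclass
class ResidueMap:
    """Assignment of residue names to monomer codes and solvent roles."""

    polymer: dict[str, str] = field(
        default_factory=lambda: {"MMA": "M", "OEG": "O", "EHM": "E", "SPM": "S"}
    )
    water_resnames: frozenset = frozenset({"HOH", "WAT", "SOL", "SPC", "TIP3"})
    ion_resnames: frozenset = frozenset({"K", "NA", "CL", "K+", "NA+", "CL-"})
    backbone_atom_names: frozenset = frozenset({"C1", "C2"})

    def classify(self, resname: str) -> str:
        if resname in self.polymer:
            return "polymer"
        if resname in self.water_resnames:
            return "water"
        if resname in self.ion_resnames:
            return "ion"
        raise ValueError(f"residue name {resname!r} has no mapping")

    @classmethod
    def from_yaml(cls, path) -> "ResidueMap":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "polymer" in d:
            kwargs["polymer"] = dict(d["polymer"])
        for key in ("water_resnames", "ion_resnames", "backbone_atom_names"):
            if key in d:
                kwargs[key] = frozenset(d[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = {
            "polymer": dict(self.polymer),
            "water_resnames": sorted(self.water_resnames),
            "ion_resnames": sorted(self.ion_resnames),
            "backbone_atom_names": sorted(self.backbone_atom_names),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


DEFAULT_RESIDUE_MAP = ResidueMap()


def _guess_element(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    return stripped[:1].upper() if stripped else "X"


# --------------------------------------------------------------------------
# PDB topology
# --------------------------------------------------------------------------

def load_topology(path, residue_map: ResidueMap | None = None):
    """Read a PDB file into a :class:`SystemTopology` plus its coordinates.

    Returns ``(topology, coordinates)`` where coordinates is the
    ``(n_atoms, 3)`` float32 array of the file's single model.
    """
    import MDAnalysis as mda

    rmap = residue_map or DEFAULT_RESIDUE_MAP
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    n = len(u.atoms)
    names = np.asarray(u.atoms.names, dtype=object)
    if hasattr(u.atoms, "elements") and all(e.strip() for e in u.atoms.elements):
        elements = np.asarray([e.strip().capitalize() for e in u.atoms.elements], dtype=object)
    else:
        elements = np.asarray([_guess_element(x) for x in names], dtype=object)
    chain_ids = np.asarray(u.atoms.chainIDs, dtype=object)

    residue_index = np.zeros(n, dtype=np.int64)
    monomer_code = np.asarray([""] * n, dtype=object)
    is_backbone = np.zeros(n, dtype=bool)
    waters: list[np.ndarray] = []
    water_oxygen: list[int] = []
    ions: list[int] = []

    # rank polymer resids within each chain so numbering is contiguous from 1
    polymer_resids: dict[str, list[int]] = {}
    for res in u.residues:
        if rmap.classify(res.resname) == "polymer":
            cid = str(res.atoms.chainIDs[0])
            polymer_resids.setdefault(cid, []).append(int(res.resid))
    rank = {
        cid: {rid: i + 1 for i, rid in enumerate(sorted(set(v)))}
        for cid, v in polymer_resids.items()
    }

    for res in u.residues:
        idx = res.atoms.indices
        kind = rmap.classify(res.resname)
        if kind == "polymer":
            cid = str(res.atoms.chainIDs[0])
            code = rmap.polymer[res.resname]
            residue_index[idx] = rank[cid][int(res.resid)]
            for a in idx:
                monomer_code[a] = code
                is_backbone[a] = str(names[a]) in rmap.backbone_atom_names
        elif kind == "water":
            waters.append(np.asarray(idx, dtype=np.int64))
            oxy = [a for a in idx if elements[a] == "O"]
            water_oxygen.append(int(oxy[0]) if oxy else int(idx[0]))
        else:
            ions.extend(int(a) for a in idx)

    if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
        raise ValueError("PDB file lacks a CRYST1 box record")
    box = np.asarray(u.dimensions[:3], dtype=float)

    topo = SystemTopology(
        atom_names=names,
        elements=elements,
        chain_ids=chain_ids,
        residue_index=residue_index,
        monomer_code=monomer_code,
        is_backbone=is_backbone,
        waters=waters,
        water_oxygen=np.asarray(water_oxygen, dtype=np.int64),
        ions=np.asarray(ions, dtype=np.int64),
        box=box,
    )
    coords = np.asarray(u.atoms.positions, dtype=np.float32)
    return topo, coords


def _build_universe(topology: SystemTopology, coordinates: np.ndarray):
    """Construct an MDAnalysis Universe mirroring a SystemTopology."""
    import MDAnalysis as mda

    n = topology.n_atoms
    # assemble residue grouping: polymer residues, then waters, then ions
    resindex = np.zeros(n, dtype=np.int64)
    resnames: list[str] = []
    resids: list[int] = []
    segs: list[str] = []
    nres = 0
    for cid in topology.polymer_chains:
        atoms = topology.chain_atoms(cid)
        n_res = topology.chain_residue_count(cid)
        for r in range(1, n_res + 1):
            sel = atoms[topology.residue_index[atoms] == r]
            resindex[sel] = nres
            resnames.append(CODE_TO_RESNAME[str(topology.monomer_code[sel[0]])])
            resids.append(r)
            segs.append(cid)
            nres += 1
    for i, w in enumerate(topology.waters):
        resindex[w] = nres
        resnames.append("HOH")
        resids.append(i + 1)
        segs.append("W")
        nres += 1
    for i, a in enumerate(topology.ions):
        resindex[a] = nres
        resnames.append(str(topology.elements[a]).upper())
        resids.append(i + 1)
        segs.append("I")
        nres += 1

    seg_labels = sorted(set(segs))
    seg_of = {s: i for i, s in enumerate(seg_labels)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=nres,
            n_segments=len(seg_labels),
            atom_resindex=resindex,
            residue_segindex=[seg_of[s] for s in segs],
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(x) for x in topology.atom_names])
        u.add_TopologyAttr("elements", [str(x) for x in topology.elements])
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)
        u.add_TopologyAttr("segids", seg_labels)
        chain_per_atom = list(topology.chain_ids)
        for i, w in enumerate(topology.waters):
            for a in w:
                chain_per_atom[a] = "W"
        for a in topology.ions:
            chain_per_atom[a] = "I"
        u.add_TopologyAttr("chainIDs", [str(c) for c in chain_per_atom])
        u.atoms.positions = np.asarray(coordinates, dtype=np.float32)
        u.dimensions = [*topology.box, 90.0, 90.0, 90.0]
    return u


def write_topology(topology: SystemTopology, coordinates: np.ndarray, path) -> None:
    """Write a SystemTopology + coordinates as a single-model PDB file."""
    u = _build_universe(topology, coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory; format chosen by extension (.dcd or .xyz)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        _write_dcd(traj, path)
    elif path.suffix.lower() == ".xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unknown trajectory extension {path.suffix!r}")


def read_trajectory(path, topology: SystemTopology) -> Trajectory:
    """Read a .dcd or .xyz trajectory against a known topology."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        return _read_dcd(path, topology)
    if path.suffix.lower() == ".xyz":
        return _read_xyz(path, topology)
    raise ValueError(f"unknown trajectory extension {path.suffix!r}")


def _write_dcd(traj: Trajectory, path: Path) -> None:
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    u = _build_universe(traj.topology, traj.coordinates[0])
    dims = np.tile(
        np.asarray([*traj.topology.box, 90.0, 90.0, 90.0], dtype=np.float64),
        (len(traj), 1),
    )
    dt_ps = (traj.frame_interval_ns or 1.0) * 1000.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.load_new(
            np.asarray(traj.coordinates, dtype=np.float32),
            format=MemoryReader,
            dimensions=dims,
            dt=dt_ps,
        )
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, dt=dt_ps) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def _read_dcd(path: Path, topology: SystemTopology) -> Trajectory:
    from MDAnalysis.coordinates.DCD import DCDReader

    coords = []
    times_ps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = DCDReader(str(path))
        for ts in reader:
            coords.append(np.array(ts.positions, dtype=np.float32))
            times_ps.append(float(ts.time))
        reader.close()
    arr = np.stack(coords)
    times_ns = np.asarray(times_ps, dtype=np.float64) / 1000.0
    if len(times_ns) > 1 and not np.all(np.diff(times_ns) > 0):
        times_ns = np.arange(len(times_ns), dtype=np.float64)
    return Trajectory(topology, arr, times_ns)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    names = [str(x) for x in traj.topology.atom_names]
    box = traj.topology.box
    with open(path, "w") as fh:
        for i in range(len(traj)):
            fh.write(f"{traj.topology.n_atoms}\n")
            fh.write(
                f"t= {float(traj.times_ns[i])!r} box= "
                f"{float(box[0])!r} {float(box[1])!r} {float(box[2])!r}\n"
            )
            frame = traj.coordinates[i]
            for a in range(traj.topology.n_atoms):
                x, y, z = frame[a]
                fh.write(f"{names[a]} {x:.8e} {y:.8e} {z:.8e}\n")


def _read_xyz(path: Path, topology: SystemTopology) -> Trajectory:
    frames = []
    times = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            if n != topology.n_atoms:
                raise ValueError(
                    f"frame has {n} atoms but topology has {topology.n_atoms}"
                )
            meta = fh.readline().split()
            times.append(float(meta[1]))
            coords = np.empty((n, 3), dtype=np.float32)
            for a in range(n):
                parts = fh.readline().split()
                coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append(coords)
    return Trajectory(topology, np.stack(frames), np.asarray(times))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(d)


def save_config(cfg: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
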