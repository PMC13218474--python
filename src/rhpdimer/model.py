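"""Core domain types for two-chain heteropolymer trajectory analysis.

The system under study is a pair of single-chain nanoparticles (SCNPs) built
from a four-letter random heteropolymer (RHP) alphabet — methyl methacrylate
(MMA, ``M``), oligo(ethylene glycol) methacrylate (OEGMA, ``O``),
2-ethylhexyl methacrylate (EHMA, ``E``) and 3-sulfopropyl methacrylate
(SPMA, ``S``) — solvated in explicit water inside a periodic orthorhombic
box.  Every analysis stage consumes the static labeling held in
:class:`SystemTopology` plus the per-frame coordinates of a
:class:`Trajectory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

MONOMER_CODES: tuple[str, ...] = ("M", "O", "E", "S")

CODE_TO_LONG_NAME: dict[str, str] = {
    "M": "MMA",
    "O": "OEGMA",
    "E": "EHMA",
    "S": "SPMA",
}


@dataclass(frozen=True)
class MonomerSpec:
    """Static description of one monomer chemistry.

    ``atoms_per_monomer`` and ``heavy_atoms_per_monomer`` refer to the bead
    model used by the synthetic generator; analyses of loaded topologies
    always count atoms from the topology itself rather than from this spec.
    """

    code: str
    long_name: str
    atoms_per_monomer: int
    heavy_atoms_per_monomer: int
    backbone_atom_names: frozenset[str]
    hydropathy_class: str

    def __post_init__(self) -> None:
        if self.code not in MONOMER_CODES:
            raise ValueError(f"unknown monomer code {self.code!r}")
        if self.heavy_atoms_per_monomer > self.atoms_per_monomer:
            raise ValueError("heavy_atoms_per_monomer exceeds atoms_per_monomer")
        if not self.backbone_atom_names:
            raise ValueError("backbone_atom_names must be non-empty")
        if self.hydropathy_class not in {
            "hydrophobic",
            "amphiphilic",
            "hydrophilic",
            "anionic",
        }:
            raise ValueError(f"unknown hydropathy class {self.hydropathy_class!r}")


# Default bead model: two chain-forming backbone carbons per monomer plus
# side-chain beads ordered by side-chain size OEGMA > EHMA > MMA > SPMA.
BACKBONE_ATOM_NAMES = frozenset({"C1", "C2"})

MONOMERS: dict[str, MonomerSpec] = {
    "M": MonomerSpec("M", "MMA", 3, 3, BACKBONE_ATOM_NAMES, "amphiphilic"),
    "O": MonomerSpec("O", "OEGMA", 5, 5, BACKBONE_ATOM_NAMES, "hydrophilic"),
    "E": MonomerSpec("E", "EHMA", 4, 4, BACKBONE_ATOM_NAMES, "hydrophobic"),
    "S": MonomerSpec("S", "SPMA", 2, 2, BACKBONE_ATOM_NAMES, "anionic"),
}


@dataclass(frozen=True)
class MonomerSequence:
    """An ordered monomer-code string, e.g. ``MMOESE...`` (100-mers in the
    reference formulation with target M:O:E:S ratios of 50:25:20:5)."""

    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        for i, c in enumerate(self.codes):
            if c not in MONOMER_CODES:
                raise ValueError(f"unknown monomer code {c!r} at position {i}")

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return "".join(self.codes)

    @property
    def length(self) -> int:
        return len(self.codes)

    def counts(self) -> dict[str, int]:
        return {c: sum(1 for x in self.codes if x == c) for c in MONOMER_CODES}


def parse_sequence(text: str) -> MonomerSequence:
    """Parse a monomer string over {M, O, E, S}; whitespace is ignored.

    Raises ``ValueError`` naming the 0-based position of the first unknown
    character (positions counted after whitespace removal).
    """
    stripped = "".join(text.split())
    for i, c in enumerate(stripped):
        if c not in MONOMER_CODES:
            raise ValueError(
                f"unknown monomer character {c!r} at position {i}; "
                f"expected one of {''.join(MONOMER_CODES)}"
            )
    return MonomerSequence(tuple(stripped))


@dataclass
class SystemTopology:
    """Static atom labeling of a two-chain + solvent system.

    All per-atom fields are parallel numpy arrays indexed by 0-based atom id.
    ``residue_index`` is 1-based within each chain (PDB convention); it is 0
    for solvent and ion atoms.  ``monomer_code`` is the empty string for
    non-polymer atoms.  ``waters`` lists each water molecule as an array of
    its atom ids; ``water_oxygen`` holds the designated oxygen site of each.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    chain_ids: np.ndarray
    residue_index: np.ndarray
    monomer_code: np.ndarray
    is_backbone: np.ndarray
    waters: list[np.ndarray]
    water_oxygen: np.ndarray
    ions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.is_backbone = np.asarray(self.is_backbone, dtype=bool)
        self.water_oxygen = np.asarray(self.water_oxygen, dtype=np.int64)
        self.ions = np.asarray(self.ions, dtype=np.int64)
        self._chain_cache: dict[str, np.ndarray] = {}
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = self.n_atoms
        for name in ("elements", "chain_ids", "residue_index", "monomer_code", "is_backbone"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"per-atom field {name} length mismatch")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths (Å)")
        for cid in self.polymer_chains:
            resids = self.residue_index[self.chain_atoms(cid)]
            uniq = np.unique(resids)
            if uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
                raise ValueError(
                    f"chain {cid}: residue indices must be contiguous from 1"
                )

    # -- derived views ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def is_heavy(self) -> np.ndarray:
        return np.asarray([e.upper() != "H" for e in self.elements], dtype=bool)

    @property
    def is_polymer(self) -> np.ndarray:
        return np.asarray([c != "" for c in self.monomer_code], dtype=bool)

    @property
    def polymer_chains(self) -> tuple[str, ...]:
        poly = self.is_polymer
        return tuple(sorted(set(np.asarray(self.chain_ids)[poly].tolist())))

    def require_dimer(self) -> tuple[str, str]:
        chains = self.polymer_chains
        if len(chains) != 2:
            raise ValueError(
                f"dimer analysis requires exactly two polymer chains, found {len(chains)}"
            )
        return chains  # type: ignore[return-value]

    def chain_atoms(self, chain_id: str) -> np.ndarray:
        """0-based atom ids of polymer atoms in the given chain."""
        if chain_id not in self._chain_cache:
            mask = np.asarray(
                [c == chain_id and m != "" for c, m in zip(self.chain_ids, self.monomer_code)]
            )
            self._chain_cache[chain_id] = np.flatnonzero(mask)
        return self._chain_cache[chain_id]

    def chain_residue_count(self, chain_id: str) -> int:
        idx = self.chain_atoms(chain_id)
        return int(self.residue_index[idx].max()) if len(idx) else 0

    def chain_sequence(self, chain_id: str) -> MonomerSequence:
        idx = self.chain_atoms(chain_id)
        codes: dict[int, str] = {}
        for a in idx:
            codes[int(self.residue_index[a])] = str(self.monomer_code[a])
        return MonomerSequence(tuple(codes[r] for r in sorted(codes)))

    def water_site_indices(self, mode: str) -> tuple[np.ndarray, np.ndarray]:
        """Flat atom ids of water sites and the parallel water index of each.

        ``mode`` is ``"oxygen_only"`` (one designated site per water) or
        ``"any_atom"`` (every atom of every water).
        """
        if mode == "oxygen_only":
            sites = self.water_oxygen
            owner = np.arange(len(self.waters), dtype=np.int64)
        elif mode == "any_atom":
            if not self.waters:
                return np.empty(0, np.int64), np.empty(0, np.int64)
            sites = np.concatenate(self.waters)
            owner = np.concatenate(
                [np.full(len(w), i, np.int64) for i, w in enumerate(self.waters)]
            )
        else:
            raise ValueError(f"unknown water_site_mode {mode!r}")
        return sites, owner


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: time in ns, (n_atoms, 3) coordinates in Å, box."""

    time_ns: float
    coordinates: np.ndarray
    box: np.ndarray


@dataclass
class Trajectory:
    """Ordered coordinate frames bound to one topology.

    Coordinates are stored as a single ``(n_frames, n_atoms, 3)`` float32
    array (the precision of the on-disk formats); times are in ns and must
    be strictly increasing.
    """

    topology: SystemTopology
    coordinates: np.ndarray
    times_ns: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float32)
        self.times_ns = np.asarray(self.times_ns, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate count differs from topology atom count")
        if self.coordinates.shape[0] != len(self.times_ns):
            raise ValueError("one time per frame required")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def frame_interval_ns(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.times_ns[1] - self.times_ns[0])

    @property
    def span_ns(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.times_ns[-1] - self.times_ns[0])

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times_ns[i]), self.coordinates[i], self.topology.box)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self.frame(i)


@dataclass
class AnalysisConfig:
    """Tunable analysis constants.

    Defaults follow the headline conventions of the methodology: a 5.0 Å
    solvation-shell cutoff (second shell), an adsorption threshold of at
    least 40 shared waters, 10 Å contact/interaction cutoffs, and a trailing
    40 ns RMSF window.  ``boundary`` selects whether "within X Å" is closed
    (``distance <= X``, the default) or open; ``use_pbc`` toggles
    minimum-image distances across the periodic box.
    """

    shell_cutoff_A: float = 5.0
    adsorption_threshold_waters: int = 40
    contact_cutoff_A: float = 10.0
    rmsf_window_ns: float = 40.0
    heavy_only_contacts: bool = True
    water_site_mode: str = "any_atom"
    boundary: str = "closed"
    use_pbc: bool = True
    stride: int = 1
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_cutoff_A <= 0 or self.contact_cutoff_A <= 0:
            raise ValueError("cutoffs must be positive")
        if self.adsorption_threshold_waters < 0:
            raise ValueError("adsorption threshold must be >= 0")
        if self.rmsf_window_ns <= 0:
            raise ValueError("rmsf window must be positive")
        if self.water_site_mode not in {"oxygen_only", "any_atom"}:
            raise ValueError(f"unknown water_site_mode {self.water_site_mode!r}")
        if self.boundary not in {"closed", "open"}:
            raise ValueError("boundary must be 'closed' or 'open'")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def to_dict(self) -> dict:
        return {
            "shell_cutoff_A": self.shell_cutoff_A,
            "adsorption_threshold_waters": self.adsorption_threshold_waters,
            "contact_cutoff_A": self.contact_cutoff_A,
            "rmsf_window_ns": self.rmsf_window_ns,
            "heavy_only_contacts": self.heavy_only_contacts,
            "water_site_mode": self.water_site_mode,
            "boundary": self.boundary,
            "use_pbc": self.use_pbc,
            "stride": self.stride,
            "random_seed": self.random_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
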