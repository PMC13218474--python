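"""Inter-chain contact detection, interface composition and enrichment.

Two distinct 10 Å determinations coexist deliberately, mirroring the
methodology this package implements:

* residue–residue **contacts** count only heavy (non-hydrogen) atom pairs;
* **interacting-residue** percentages and the **interface composition** use
  *any* atom of one chain within the cutoff of *any* atom of the other.

Interface composition is weighted by time: each polymer atom found within
the cutoff of the partner chain contributes one appearance per frame in
which it qualifies, so an atom interfacial for 5000 frames counts 5000
times.  Fractions are normalized to 1 across the four monomer types
whenever at least one appearance exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import neighbor_pairs
from .model import (
    MONOMER_CODES,
    AnalysisConfig,
    Frame,
    SystemTopology,
    Trajectory,
)

__all__ = [
    "ContactTimeseries",
    "InterfaceComposition",
    "InteractionReport",
    "EnrichmentReport",
    "RegressionFit",
    "residue_contact_map",
    "interacting_residues",
    "typepair_contact_timeseries",
    "interface_composition",
    "composition_enrichment",
    "adsorption_composition_regression",
]


def residue_contact_map(
    topology: SystemTopology,
    frame: Frame,
    cutoff: float,
    *,
    heavy_only: bool = True,
    use_pbc: bool = True,
    boundary: str = "closed",
) -> set[tuple[int, int]]:
    """Residue pairs (chain-1 residue, chain-2 residue, both 1-based) with at
    least one qualifying atom pair within ``cutoff``."""
    c1, c2 = topology.require_dimer()
    a1 = topology.chain_atoms(c1)
    a2 = topology.chain_atoms(c2)
    if heavy_only:
        heavy = topology.is_heavy
        a1 = a1[heavy[a1]]
        a2 = a2[heavy[a2]]
    pairs = neighbor_pairs(frame, a1, a2, cutoff, use_pbc=use_pbc, boundary=boundary)
    resid = topology.residue_index
    return {(int(resid[a]), int(resid[b])) for a, b in pairs}


@dataclass
class ContactTimeseries:
    """Per-frame inter-chain heavy-atom contact counts by monomer-type pair.

    ``raw[t, i, j]`` counts atom pairs between type ``types[i]`` in chain 1
    and ``types[j]`` in chain 2.  ``a[i]``/``b[j]`` are the per-chain atom
    totals of each type, counted from the actual topology, that build the
    a·b normalization; pairs involving a type absent from a chain have
    normalized value NaN (undefined) while the raw count is kept.
    """

    times_ns: np.ndarray
    types: tuple[str, ...]
    raw: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        denom = np.outer(self.a, self.b).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.raw / denom
        out[:, denom == 0] = np.nan
        return out

    @property
    def total_per_frame(self) -> np.ndarray:
        return self.raw.sum(axis=(1, 2))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        norm = self.normalized
        for t in range(len(self.times_ns)):
            for i, ti in enumerate(self.types):
                for j, tj in enumerate(self.types):
                    rows.append(
                        (self.times_ns[t], ti, tj, int(self.raw[t, i, j]), norm[t, i, j])
                    )
        return pd.DataFrame(
            rows, columns=["time_ns", "type1", "type2", "raw", "normalized"]
        )


def typepair_contact_timeseries(
    traj: Trajectory, cfg: AnalysisConfig
) -> ContactTimeseries:
    """Raw and a·b-normalized inter-chain contact counts per type pair."""
    topo = traj.topology
    c1, c2 = topo.require_dimer()
    a1 = topo.chain_atoms(c1)
    a2 = topo.chain_atoms(c2)
    if cfg.heavy_only_contacts:
        heavy = topo.is_heavy
        a1 = a1[heavy[a1]]
        a2 = a2[heavy[a2]]
    type_of = {c: k for k, c in enumerate(MONOMER_CODES)}
    t1 = np.asarray([type_of[str(topo.monomer_code[a])] for a in a1], dtype=np.int64)
    t2 = np.asarray([type_of[str(topo.monomer_code[a])] for a in a2], dtype=np.int64)
    pos1 = {int(a): i for i, a in enumerate(a1)}
    pos2 = {int(a): i for i, a in enumerate(a2)}

    # normalization constants from ALL atoms of each single chain
    all1 = topo.chain_atoms(c1)
    all2 = topo.chain_atoms(c2)
    a_tot = np.asarray(
        [sum(1 for x in all1 if str(topo.monomer_code[x]) == c) for c in MONOMER_CODES]
    )
    b_tot = np.asarray(
        [sum(1 for x in all2 if str(topo.monomer_code[x]) == c) for c in MONOMER_CODES]
    )

    n_types = len(MONOMER_CODES)
    frames = range(0, len(traj), cfg.stride)
    raw = np.zeros((len(list(frames)), n_types, n_types), dtype=np.int64)
    times = []
    for row, i in enumerate(range(0, len(traj), cfg.stride)):
        frame = traj.frame(i)
        pairs = neighbor_pairs(
            frame, a1, a2, cfg.contact_cutoff_A,
            use_pbc=cfg.use_pbc, boundary=cfg.boundary,
        )
        times.append(frame.time_ns)
        if len(pairs):
            ti = t1[[pos1[int(a)] for a in pairs[:, 0]]]
            tj = t2[[pos2[int(b)] for b in pairs[:, 1]]]
            np.add.at(raw[row], (ti, tj), 1)
    return ContactTimeseries(
        times_ns=np.asarray(times), types=MONOMER_CODES, raw=raw, a=a_tot, b=b_tot
    )


@dataclass
class InteractionReport:
    """Cumulative interacting-residue bookkeeping per chain.

    A residue interacts if in ANY analyzed frame any of its atoms comes
    within the cutoff of any atom of the other chain; the backbone variant
    restricts the residue's own atoms to backbone atoms.
    """

    chains: tuple[str, str]
    interacting: dict[str, set[int]]
    interacting_backbone: dict[str, set[int]]
    residue_counts: dict[str, int]
    first_seen_ns: dict[str, dict[int, float]]
    last_seen_ns: dict[str, dict[int, float]]

    def pct_any_atom(self, chain: str) -> float:
        return 100.0 * len(self.interacting[chain]) / self.residue_counts[chain]

    def pct_backbone(self, chain: str) -> float:
        return 100.0 * len(self.interacting_backbone[chain]) / self.residue_counts[chain]

    @property
    def mean_pct_any_atom(self) -> float:
        return float(np.mean([self.pct_any_atom(c) for c in self.chains]))

    @property
    def mean_pct_backbone(self) -> float:
        return float(np.mean([self.pct_backbone(c) for c in self.chains]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.chains:
            for r in sorted(self.interacting[c]):
                rows.append(
                    (
                        c,
                        r,
                        r in self.interacting_backbone[c],
                        self.first_seen_ns[c][r],
                        self.last_seen_ns[c][r],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["chain", "residue", "backbone_interacting", "first_ns", "last_ns"],
        )


def interacting_residues(
    traj: Trajectory, cutoff: float, cfg: AnalysisConfig | None = None
) -> InteractionReport:
    """Residues of each chain that ever come within ``cutoff`` of the other
    chain (hydrogens included on both sides)."""
    cfg = cfg or AnalysisConfig()
    topo = traj.topology
    c1, c2 = topo.require_dimer()
    atoms = {c1: topo.chain_atoms(c1), c2: topo.chain_atoms(c2)}
    resid = topo.residue_index
    bb = topo.is_backbone
    interacting = {c1: set(), c2: set()}
    interacting_bb = {c1: set(), c2: set()}
    first = {c1: {}, c2: {}}
    last = {c1: {}, c2: {}}
    for i in range(0, len(traj), cfg.stride):
        frame = traj.frame(i)
        pairs = neighbor_pairs(
            frame, atoms[c1], atoms[c2], cutoff,
            use_pbc=cfg.use_pbc, boundary=cfg.boundary,
        )
        if not len(pairs):
            continue
        for chain, col in ((c1, 0), (c2, 1)):
            for a in np.unique(pairs[:, col]):
                r = int(resid[a])
                interacting[chain].add(r)
                first[chain].setdefault(r, frame.time_ns)
                last[chain][r] = frame.time_ns
                if bb[a]:
                    interacting_bb[chain].add(r)
    return InteractionReport(
        chains=(c1, c2),
        interacting=interacting,
        interacting_backbone=interacting_bb,
        residue_counts={c: topo.chain_residue_count(c) for c in (c1, c2)},
        first_seen_ns=first,
        last_seen_ns=last,
    )


@dataclass
class InterfaceComposition:
    """Time-weighted monomer-type distribution at the inter-chain interface.

    ``appearances[code]`` totals one count per atom per frame in which that
    atom (of either chain) lies within the cutoff of the other chain.
    ``fractions`` is None when no appearance was ever observed (undefined,
    never reported as zeros).  ``atom_appearances`` maps atom id to its own
    appearance count for downstream recomputation.
    """

    appearances: dict[str, int]
    atom_appearances: dict[int, int]
    appearances_by_chain: dict[str, dict[str, int]]

    @property
    def total_appearances(self) -> int:
        return sum(self.appearances.values())

    @staticmethod
    def _normalize(counts: dict[str, int]) -> dict[str, float] | None:
        tot = sum(counts.values())
        if tot == 0:
            return None
        return {c: counts[c] / tot for c in MONOMER_CODES}

    @property
    def fractions(self) -> dict[str, float] | None:
        return self._normalize(self.appearances)

    def fractions_for(self, chain: str) -> dict[str, float] | None:
        """Composition of one chain's own interfacial atoms (the per-chain
        normalized-to-1 view used when comparing replicates)."""
        return self._normalize(self.appearances_by_chain[chain])

    def to_dict(self) -> dict:
        return {
            "appearances": dict(self.appearances),
            "appearances_by_chain": {
                c: dict(v) for c, v in self.appearances_by_chain.items()
            },
            "total_appearances": self.total_appearances,
            "fractions": self.fractions,
            "fractions_by_chain": {
                c: self.fractions_for(c) for c in self.appearances_by_chain
            },
        }


def interface_composition(
    traj: Trajectory, cutoff: float, cfg: AnalysisConfig | None = None
) -> InterfaceComposition:
    """Time-weighted interface composition over both chains."""
    cfg = cfg or AnalysisConfig()
    topo = traj.topology
    c1, c2 = topo.require_dimer()
    a1, a2 = topo.chain_atoms(c1), topo.chain_atoms(c2)
    appearances = {c: 0 for c in MONOMER_CODES}
    by_chain = {c1: {c: 0 for c in MONOMER_CODES}, c2: {c: 0 for c in MONOMER_CODES}}
    atom_appearances: dict[int, int] = {}
    for i in range(0, len(traj), cfg.stride):
        frame = traj.frame(i)
        pairs = neighbor_pairs(
            frame, a1, a2, cutoff, use_pbc=cfg.use_pbc, boundary=cfg.boundary
        )
        if not len(pairs):
            continue
        for chain, col in ((c1, 0), (c2, 1)):
            for a in np.unique(pairs[:, col]):
                code = str(topo.monomer_code[a])
                appearances[code] += 1
                by_chain[chain][code] += 1
                atom_appearances[int(a)] = atom_appearances.get(int(a), 0) + 1
    return InterfaceComposition(
        appearances=appearances,
        atom_appearances=atom_appearances,
        appearances_by_chain=by_chain,
    )


@dataclass
class EnrichmentReport:
    """Interfacial representation of each monomer type relative to its share
    of the chain's atoms."""

    contacts_per_atom: dict[str, float]
    scaled_contacts_per_atom: dict[str, float]
    sequence_atom_fraction: dict[str, float]
    scaled_sequence_fraction: dict[str, float]
    enrichment_ratio: dict[str, float]
    scaling: str

    def to_dict(self) -> dict:
        return {
            "contacts_per_atom": self.contacts_per_atom,
            "scaled_contacts_per_atom": self.scaled_contacts_per_atom,
            "sequence_atom_fraction": self.sequence_atom_fraction,
            "scaled_sequence_fraction": self.scaled_sequence_fraction,
            "enrichment_ratio": self.enrichment_ratio,
            "scaling": self.scaling,
        }


def _rescale(values: dict[str, float], scaling: str) -> dict[str, float]:
    vals = np.asarray([values[c] for c in MONOMER_CODES], dtype=float)
    if scaling == "max":
        top = np.nanmax(vals)
        scaled = vals / top if top > 0 else vals
    elif scaling == "minmax":
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        scaled = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return {c: float(v) for c, v in zip(MONOMER_CODES, scaled)}


def composition_enrichment(
    iface: InterfaceComposition,
    topology: SystemTopology,
    *,
    scaling: str = "max",
) -> EnrichmentReport:
    """Contacts-per-atom, 0–1 rescaled profiles and enrichment ratios.

    Per-type atom counts pool both chains (the denominators of
    contacts-per-atom and the sequence atom-composition reference).
    ``scaling='max'`` divides each profile by its maximum; ``'minmax'`` is
    the alternative reading of "scaled from 0 to 1".
    """
    fr = iface.fractions
    if fr is None:
        raise ValueError("interface composition undefined (zero appearances)")
    chains = topology.require_dimer()
    atom_counts = {c: 0 for c in MONOMER_CODES}
    for ch in chains:
        for a in topology.chain_atoms(ch):
            atom_counts[str(topology.monomer_code[a])] += 1
    total_atoms = sum(atom_counts.values())
    for c in MONOMER_CODES:
        if atom_counts[c] == 0:
            raise ValueError(f"monomer type {c} has zero atoms in the chains")
    cpa = {c: iface.appearances[c] / atom_counts[c] for c in MONOMER_CODES}
    seq = {c: atom_counts[c] / total_atoms for c in MONOMER_CODES}
    enrich = {c: fr[c] / seq[c] for c in MONOMER_CODES}
    return EnrichmentReport(
        contacts_per_atom=cpa,
        scaled_contacts_per_atom=_rescale(cpa, scaling),
        sequence_atom_fraction=seq,
        scaled_sequence_fraction=_rescale(seq, scaling),
        enrichment_ratio=enrich,
        scaling=scaling,
    )


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "r": self.r}


def adsorption_composition_regression(
    points: dict[str, list[tuple[float, float]]]
) -> dict[str, RegressionFit | None]:
    """Per-monomer-type OLS fit of adsorbed-time fraction (y) against
    interfacial percentage (x), with the Pearson correlation coefficient.

    ``points[type]`` is a list of (x, y) pairs, one per simulation.  Types
    with fewer than two distinct x values get ``None`` (fit undefined).
    """
    out: dict[str, RegressionFit | None] = {}
    for code, pts in points.items():
        xs = np.asarray([p[0] for p in pts], dtype=float)
        ys = np.asarray([p[1] for p in pts], dtype=float)
        if len(xs) < 2 or np.all(xs == xs[0]):
            out[code] = None
            continue
        fit = stats.linregress(xs, ys)
        r = fit.rvalue if not math.isnan(fit.rvalue) else 0.0
        out[code] = RegressionFit(float(fit.slope), float(fit.intercept), float(r))
    return out
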