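"""Synthetic two-chain + water trajectory generator with planted truth.

The generator emulates, at reduced scale, a solvated dimerization run: two
identical 100-monomer heteropolymer bead-chains in a periodic cube of
explicit single-site waters, driven through a scripted schedule of
adsorbed/dissociated episodes.  Chains are rigid bodies plus Gaussian
jitter — the analysis layer, not polymer physics, is under test — and every
planted quantity (adsorbed frame mask, bridging waters, interface residues
and their appearance counts) is recorded in a :class:`ScenarioTruth` that
downstream tests use as the oracle.

Layout conventions: chains face each other along x around the box center;
during adsorbed intervals their facing surfaces sit ``adsorbed_gap`` Å
apart and a fixed roster of bridging waters occupies the mid-plane slab
(guaranteed inside both 5 Å shells); when dissociated the surfaces are
``dissociated_gap`` Å apart and the same waters are outside every shell.
Ambient waters are rejection-sampled out of the interfacial slab so the
shared-water count on adsorbed frames equals the planted roster exactly.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children (sequence shuffle, chain jitter,
water placement, water jitter, ions); no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    MONOMER_CODES,
    MONOMERS,
    MonomerSequence,
    SystemTopology,
    Trajectory,
    parse_sequence,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioTruth",
    "generate_sequence",
    "generate_dimer_trajectory",
    "generate_null_metric_groups",
]

DEFAULT_RATIOS = (0.5, 0.25, 0.2, 0.05)  # M : O : E : S
_LATTICE_SPACING = 3.0
_SIDE_BOND = 1.4
_C2_OFFSET = np.array([0.9, 0.9, 0.0])
_SIDE_ELEMENT = {"M": "C", "O": "O", "E": "C", "S": "S"}


def generate_sequence(
    ratios=DEFAULT_RATIOS, length: int = 100, seed: int = 0
) -> MonomerSequence:
    """Exact-count composition (largest-remainder rounding of the target
    ratios) shuffled deterministically by ``seed``."""
    ratios = np.asarray(ratios, dtype=float)
    if length <= 0:
        raise ValueError("length must be positive")
    if not np.isclose(ratios.sum(), 1.0):
        raise ValueError("ratios must sum to 1")
    exact = ratios * length
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: length - counts.sum()]:
        counts[i] += 1
    codes = [c for c, n in zip(MONOMER_CODES, counts) for _ in range(n)]
    rng = np.random.default_rng(seed)
    rng.shuffle(codes)
    return MonomerSequence(tuple(codes))


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic dimerization scenario."""

    sequence: str | None = None
    ratios: tuple = DEFAULT_RATIOS
    length: int = 100
    n_waters: int = 600
    box: tuple = (80.0, 80.0, 80.0)
    n_frames: int = 200
    frame_interval_ns: float = 0.25
    schedule: tuple = ()
    adsorbed_gap: float = 4.0
    dissociated_gap: float = 25.0
    n_bridging_waters: int = 50
    n_shell_waters: int = 120
    n_buried_waters: int = 60
    burial_depth: float = 3.0
    safe_margin: float = 6.0
    shell_water_offset: float = 3.5
    center_jitter_sigma: float = 0.2
    atom_jitter_sigma: float = 0.15
    interface_extra_sigma: float = 0.45
    water_jitter_sigma: float = 0.2
    water_sites: int = 1
    contact_cutoff_A: float = 10.0
    shell_cutoff_A: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_waters < 0 or self.length < 1:
            raise ValueError("n_frames, n_waters and length must be positive")
        if self.water_sites not in (1, 3):
            raise ValueError("water_sites must be 1 or 3")
        if not 0 <= self.n_buried_waters <= self.n_shell_waters:
            raise ValueError("n_buried_waters must be within [0, n_shell_waters]")
        if self.adsorbed_gap > 2 * self.shell_cutoff_A:
            raise ValueError("adsorbed gap too wide for bridging waters to exist")
        sigma = self.center_jitter_sigma + self.atom_jitter_sigma + self.interface_extra_sigma
        if self.dissociated_gap <= self.contact_cutoff_A + 4 * sigma * np.sqrt(3):
            raise ValueError("dissociated gap too close to the contact cutoff")
        spans = sorted(self.schedule)
        for (a, b) in spans:
            if not (a < b):
                raise ValueError("schedule intervals must have t_on < t_off")
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c < b:
                raise ValueError("schedule intervals must be disjoint")
        span = self.n_frames * self.frame_interval_ns
        if spans and (spans[0][0] < 0 or spans[-1][1] > span + 1e-9):
            raise ValueError("schedule intervals must lie within the trajectory span")

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=np.float64) * self.frame_interval_ns

    def adsorbed_mask(self) -> np.ndarray:
        t = self.times_ns
        mask = np.zeros(self.n_frames, dtype=bool)
        for a, b in self.schedule:
            mask |= (t >= a - 1e-12) & (t < b - 1e-12)
        return mask

    @classmethod
    def from_fraction(cls, fraction: float, seed: int = 0, **overrides) -> "ScenarioSpec":
        """A scenario whose schedule covers the first round(f·n_frames)
        frames, so the planted adsorbed fraction is exactly ``fraction``
        up to frame quantization."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        spec = cls(seed=seed, **overrides)
        k = int(round(fraction * spec.n_frames))
        if k == 0:
            return spec
        t_off = spec.times_ns[k] if k < spec.n_frames else (
            float(spec.times_ns[-1]) + spec.frame_interval_ns
        )
        return replace(spec, schedule=((0.0, float(t_off)),))


@dataclass
class ScenarioTruth:
    """Planted ground truth of one generated scenario."""

    adsorbed_mask: np.ndarray
    adsorbed_fraction: float
    bridging_water_ids: np.ndarray
    interface_residues: dict[str, set[int]]
    atom_appearances: dict[int, int]
    composition_appearances: dict[str, int]
    composition_fractions: dict[str, float] | None
    seed: int

    def to_json(self, path) -> None:
        d = {
            "adsorbed_mask": [bool(x) for x in self.adsorbed_mask],
            "adsorbed_fraction": self.adsorbed_fraction,
            "bridging_water_ids": [int(x) for x in self.bridging_water_ids],
            "interface_residues": {
                c: sorted(int(r) for r in s) for c, s in self.interface_residues.items()
            },
            "atom_appearances": {str(k): int(v) for k, v in self.atom_appearances.items()},
            "composition_appearances": dict(self.composition_appearances),
            "composition_fractions": self.composition_fractions,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            adsorbed_mask=np.asarray(d["adsorbed_mask"], dtype=bool),
            adsorbed_fraction=float(d["adsorbed_fraction"]),
            bridging_water_ids=np.asarray(d["bridging_water_ids"], dtype=np.int64),
            interface_residues={c: set(v) for c, v in d["interface_residues"].items()},
            atom_appearances={int(k): int(v) for k, v in d["atom_appearances"].items()},
            composition_appearances=d["composition_appearances"],
            composition_fractions=d["composition_fractions"],
            seed=int(d["seed"]),
        )


# --------------------------------------------------------------------------
# chain template
# --------------------------------------------------------------------------

def _grid_dims(n: int) -> tuple[int, int, int]:
    nz = max(1, int(round(n ** (1.0 / 3.0))))
    ny = max(1, int(np.ceil(np.sqrt(n / nz))))
    nx = int(np.ceil(n / (ny * nz)))
    return nx, ny, nz


def _chain_template(sequence: MonomerSequence):
    """Compact serpentine-lattice bead chain, centered at the origin.

    Returns (coords, atom_names, elements, residue_index, is_backbone).
    """
    n = len(sequence)
    nx, ny, nz = _grid_dims(n)
    sites = []
    for k in range(nz):
        for j in range(ny):
            jj = j if k % 2 == 0 else ny - 1 - j
            for i in range(nx):
                ii = i if jj % 2 == 0 else nx - 1 - i
                sites.append((ii, jj, k))
    sites = np.asarray(sites[:n], dtype=float) * _LATTICE_SPACING
    centroid = sites.mean(axis=0)

    coords, names, elements, resid, backbone = [], [], [], [], []
    for m, code in enumerate(sequence.codes):
        p = sites[m]
        # side chains point radially outward within the yz-plane so the
        # x faces (the association surfaces) stay flat
        radial = np.array([0.0, p[1] - centroid[1], p[2] - centroid[2]])
        norm = np.linalg.norm(radial)
        u = radial / norm if norm > 1e-9 else np.array([0.0, 1.0, 0.0])
        spec = MONOMERS[code]
        n_side = spec.atoms_per_monomer - 2
        coords.append(p)
        names.append("C1")
        elements.append("C")
        resid.append(m + 1)
        backbone.append(True)
        coords.append(p + _C2_OFFSET)
        names.append("C2")
        elements.append("C")
        resid.append(m + 1)
        backbone.append(True)
        for s in range(n_side):
            coords.append(p + u * _SIDE_BOND * (s + 1))
            names.append(f"S{s + 1}")
            elements.append(_SIDE_ELEMENT[code])
            resid.append(m + 1)
            backbone.append(False)
    coords = np.asarray(coords) - centroid
    return (
        coords,
        np.asarray(names, dtype=object),
        np.asarray(elements, dtype=object),
        np.asarray(resid, dtype=np.int64),
        np.asarray(backbone, dtype=bool),
    )


def _water_template(sites: int) -> tuple[np.ndarray, list[str], list[str]]:
    if sites == 1:
        return np.zeros((1, 3)), ["O"], ["O"]
    geom = np.array(
        [[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]
    )
    return geom, ["O", "H1", "H2"], ["O", "H", "H"]


def generate_dimer_trajectory(spec: ScenarioSpec):
    """Build a scenario trajectory and its planted truth.

    Returns ``(trajectory, truth)``; fully reproducible from ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    seq_ss, jitter_ss, water_ss, wjit_ss, ion_ss = ss.spawn(5)

    if spec.sequence is not None:
        sequence = parse_sequence(spec.sequence)
    else:
        sequence = generate_sequence(
            spec.ratios, spec.length, np.random.default_rng(seq_ss).integers(2**31)
        )

    box = np.asarray(spec.box, dtype=float)
    center = box / 2.0
    tmpl, names, elements, resid, backbone = _chain_template(sequence)
    n_chain = len(tmpl)
    # gap is measured between the backbone lattice faces; side-chain beads
    # may protrude into the gap (no physics is implied by overlap)
    face_min = tmpl[backbone, 0].min()
    face_max = tmpl[backbone, 0].max()
    min_x, max_x = tmpl[:, 0].min(), tmpl[:, 0].max()
    protrusion = max(max_x - face_max, face_min - min_x)
    half_y = max(abs(tmpl[:, 1].min()), abs(tmpl[:, 1].max()))
    half_z = max(abs(tmpl[:, 2].min()), abs(tmpl[:, 2].max()))

    def chain_offsets(gap: float) -> tuple[np.ndarray, np.ndarray]:
        off_a = np.array([center[0] - gap / 2.0 - face_max, center[1], center[2]])
        off_b = np.array([center[0] + gap / 2.0 - face_min, center[1], center[2]])
        return off_a, off_b

    ads_a, ads_b = chain_offsets(spec.adsorbed_gap)
    dis_a, dis_b = chain_offsets(spec.dissociated_gap)
    if dis_b[0] + max_x + spec.contact_cutoff_A > box[0] or dis_a[0] + min_x < spec.contact_cutoff_A:
        raise ValueError("box too small to honor the dissociated gap")
    if spec.dissociated_gap - 2.0 * protrusion <= spec.shell_cutoff_A * 2.0:
        raise ValueError("dissociated gap too narrow for parked bridging waters")

    # ambient-water exclusion slab around the interfacial mid-plane, wide
    # enough that no ambient water can ever sit in both 5 Å shells at once
    excl_hx = spec.adsorbed_gap / 2.0 + protrusion + spec.shell_cutoff_A + 2.0
    excl_hy = half_y + spec.shell_cutoff_A + 3.0
    excl_hz = half_z + spec.shell_cutoff_A + 3.0

    water_rng = np.random.default_rng(water_ss)
    ambient = []
    while len(ambient) < spec.n_waters:
        cand = water_rng.uniform(0.0, box, size=3)
        d = np.abs(cand - center)
        if d[0] <= excl_hx and d[1] <= excl_hy and d[2] <= excl_hz:
            continue
        ambient.append(cand)
    ambient = np.asarray(ambient) if ambient else np.empty((0, 3))

    # bridging waters stay within the backbone lattice footprint so every
    # one of them has a nearby facing-surface atom on both chains
    bb_half_y = max(abs(tmpl[backbone, 1].min()), abs(tmpl[backbone, 1].max()))
    bb_half_z = max(abs(tmpl[backbone, 2].min()), abs(tmpl[backbone, 2].max()))
    lateral = max(1.0, min(bb_half_y, bb_half_z) - 1.0)
    n_b = spec.n_bridging_waters
    bridge = np.column_stack(
        [
            center[0] + water_rng.uniform(-0.5, 0.5, n_b),
            center[1] + water_rng.uniform(-lateral, lateral, n_b),
            center[2] + water_rng.uniform(-lateral, lateral, n_b),
        ]
    ) if n_b else np.empty((0, 3))

    # tracked per-chain shell waters: anchored just outside the chain
    # surface and rigidly following the chain.  The first n_buried anchors
    # of each chain sit on the facing surface and are displaced to a far
    # park position on adsorbed frames (interface burial), so the union
    # water count falls on association while the bridging roster raises
    # the shared count.
    n_shell = spec.n_shell_waters
    n_buried = spec.n_buried_waters
    shell_anchor: dict[str, np.ndarray] = {}
    if n_shell:
        for cid, facing_pos in (("A", True), ("B", False)):
            if facing_pos:
                buried_pool = np.flatnonzero(tmpl[:, 0] >= face_max - spec.burial_depth)
                safe_pool = np.flatnonzero(tmpl[:, 0] <= face_max - spec.safe_margin)
            else:
                buried_pool = np.flatnonzero(tmpl[:, 0] <= face_min + spec.burial_depth)
                safe_pool = np.flatnonzero(tmpl[:, 0] >= face_min + spec.safe_margin)
            if (n_buried and not len(buried_pool)) or (
                n_shell > n_buried and not len(safe_pool)
            ):
                raise ValueError("chain too small for the requested shell waters")
            picks = np.concatenate(
                [
                    water_rng.choice(buried_pool, n_buried, replace=True),
                    water_rng.choice(safe_pool, n_shell - n_buried, replace=True),
                ]
            )
            pts = tmpl[picks]
            u = np.zeros_like(pts)
            yz = pts[:, 1:3].copy()
            norms = np.linalg.norm(yz, axis=1)
            deg = norms < 1e-9
            yz[deg] = [1.0, 0.0]
            norms[deg] = 1.0
            u[:, 1:3] = yz / norms[:, None]
            anchors = pts + spec.shell_water_offset * u
            anchors[:, 1:3] += water_rng.normal(0.0, 0.5, (n_shell, 2))
            shell_anchor[cid] = anchors
    park = water_rng.uniform(3.0, 8.0, (2 * n_buried, 3)) if n_buried else np.empty((0, 3))

    n_ions = 2 * sequence.counts()["S"]
    ion_rng = np.random.default_rng(ion_ss)
    ion_pos = ion_rng.uniform(5.0, box - 5.0, size=(n_ions, 3)) if n_ions else np.empty((0, 3))

    # ---- assemble topology ------------------------------------------------
    wgeom, wnames, welems = _water_template(spec.water_sites)
    n_amb = len(ambient)
    n_wat_total = n_amb + 2 * n_shell + n_b
    atoms_per_water = len(wgeom)
    n_atoms = 2 * n_chain + n_wat_total * atoms_per_water + n_ions

    atom_names = np.empty(n_atoms, dtype=object)
    atom_elements = np.empty(n_atoms, dtype=object)
    chain_ids = np.empty(n_atoms, dtype=object)
    residue_index = np.zeros(n_atoms, dtype=np.int64)
    monomer_code = np.asarray([""] * n_atoms, dtype=object)
    is_backbone = np.zeros(n_atoms, dtype=bool)

    codes_per_atom = np.asarray([sequence.codes[r - 1] for r in resid], dtype=object)
    for ci, cid in enumerate(("A", "B")):
        sl = slice(ci * n_chain, (ci + 1) * n_chain)
        atom_names[sl] = names
        atom_elements[sl] = elements
        chain_ids[sl] = cid
        residue_index[sl] = resid
        monomer_code[sl] = codes_per_atom
        is_backbone[sl] = backbone

    waters: list[np.ndarray] = []
    water_oxygen: list[int] = []
    base_w = 2 * n_chain
    for w in range(n_wat_total):
        ids = np.arange(base_w + w * atoms_per_water, base_w + (w + 1) * atoms_per_water)
        waters.append(ids)
        water_oxygen.append(int(ids[0]))
        atom_names[ids] = wnames
        atom_elements[ids] = welems
        chain_ids[ids] = "W"
    ion_ids = np.arange(base_w + n_wat_total * atoms_per_water, n_atoms)
    atom_names[ion_ids] = "K"
    atom_elements[ion_ids] = "K"
    chain_ids[ion_ids] = "I"

    topology = SystemTopology(
        atom_names=atom_names,
        elements=atom_elements,
        chain_ids=chain_ids,
        residue_index=residue_index,
        monomer_code=monomer_code,
        is_backbone=is_backbone,
        waters=waters,
        water_oxygen=np.asarray(water_oxygen, dtype=np.int64),
        ions=ion_ids,
        box=box,
    )

    # ---- jitter targets from the ideal adsorbed geometry -----------------
    # (which atoms receive the extra interfacial jitter is a generation
    # choice; the recorded interface truth below comes from the frames)
    pos_a_ads = tmpl + ads_a
    pos_b_ads = tmpl + ads_b
    diff = pos_a_ads[:, None, :] - pos_b_ads[None, :, :]
    dmat = np.sqrt(np.sum(diff * diff, axis=2))
    close = dmat <= spec.contact_cutoff_A
    iface_atoms_a = np.flatnonzero(close.any(axis=1))
    iface_atoms_b = np.flatnonzero(close.any(axis=0))
    iface_atom_mask = np.zeros(n_atoms, dtype=bool)
    iface_atom_mask[iface_atoms_a] = True
    iface_atom_mask[n_chain + iface_atoms_b] = True

    # ---- frames ----------------------------------------------------------
    mask = spec.adsorbed_mask()
    times = spec.times_ns
    jit_rng = np.random.default_rng(jitter_ss)
    wjit_rng = np.random.default_rng(wjit_ss)

    coords = np.empty((spec.n_frames, n_atoms, 3), dtype=np.float64)
    n_iface = int(iface_atom_mask.sum())
    for f in range(spec.n_frames):
        off_a, off_b = (ads_a, ads_b) if mask[f] else (dis_a, dis_b)
        ca = off_a + jit_rng.normal(0.0, spec.center_jitter_sigma, 3)
        cb = off_b + jit_rng.normal(0.0, spec.center_jitter_sigma, 3)
        frame = np.empty((n_atoms, 3))
        frame[:n_chain] = tmpl + ca
        frame[n_chain : 2 * n_chain] = tmpl + cb
        frame[: 2 * n_chain] += jit_rng.normal(
            0.0, spec.atom_jitter_sigma, (2 * n_chain, 3)
        )
        if n_iface:
            frame[iface_atom_mask] += jit_rng.normal(
                0.0, spec.interface_extra_sigma, (n_iface, 3)
            )
        if n_wat_total:
            wpos = np.empty((n_wat_total, 3))
            wpos[:n_amb] = ambient
            for k, (cid, off) in enumerate((("A", off_a), ("B", off_b))):
                if not n_shell:
                    continue
                base = shell_anchor[cid] + off
                if mask[f] and n_buried:
                    base[:n_buried] = park[k * n_buried : (k + 1) * n_buried]
                wpos[n_amb + k * n_shell : n_amb + (k + 1) * n_shell] = base
            if n_b:
                wpos[n_amb + 2 * n_shell :] = bridge
            wpos += wjit_rng.normal(0.0, spec.water_jitter_sigma, (n_wat_total, 3))
            frame[base_w : base_w + n_wat_total * atoms_per_water] = (
                wpos[:, None, :] + wgeom[None, :, :]
            ).reshape(-1, 3)
        if n_ions:
            frame[ion_ids] = ion_pos
        coords[f] = frame

    traj = Trajectory(topology, coords.astype(np.float32), times)

    # ---- interface truth from the actual frames (direct all-pairs) -------
    atom_appearances: dict[int, int] = {}
    comp = {c: 0 for c in MONOMER_CODES}
    for f in np.flatnonzero(mask):
        fa = np.asarray(traj.coordinates[f, :n_chain], dtype=np.float64)
        fb = np.asarray(traj.coordinates[f, n_chain : 2 * n_chain], dtype=np.float64)
        diff = fa[:, None, :] - fb[None, :, :]
        dmat2 = np.sum(diff * diff, axis=2)
        close = dmat2 <= spec.contact_cutoff_A**2
        for a in np.flatnonzero(close.any(axis=1)):
            atom_appearances[int(a)] = atom_appearances.get(int(a), 0) + 1
            comp[str(monomer_code[a])] += 1
        for b in np.flatnonzero(close.any(axis=0)):
            gid = int(n_chain + b)
            atom_appearances[gid] = atom_appearances.get(gid, 0) + 1
            comp[str(monomer_code[gid])] += 1
    total = sum(comp.values())
    fractions = {c: comp[c] / total for c in MONOMER_CODES} if total else None
    interface_residues = {"A": set(), "B": set()}
    for gid in atom_appearances:
        if gid < n_chain:
            interface_residues["A"].add(int(resid[gid]))
        else:
            interface_residues["B"].add(int(resid[gid - n_chain]))

    truth = ScenarioTruth(
        adsorbed_mask=mask,
        adsorbed_fraction=float(mask.mean()),
        bridging_water_ids=np.arange(n_amb + 2 * n_shell, n_wat_total, dtype=np.int64),
        interface_residues=interface_residues,
        atom_appearances=atom_appearances,
        composition_appearances=comp,
        composition_fractions=fractions,
        seed=spec.seed,
    )
    return traj, truth


# --------------------------------------------------------------------------
# null metric groups for test calibration
# --------------------------------------------------------------------------

def generate_null_metric_groups(
    n_groups: int,
    n_per_group: int,
    distribution: str = "normal",
    params: dict | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """i.i.d. groups from one named distribution (the all-null design)."""
    if n_groups < 1 or n_per_group < 1:
        raise ValueError("counts must be positive")
    params = params or {}
    rng = np.random.default_rng(seed)
    size = (n_groups, n_per_group)
    if distribution == "normal":
        vals = rng.normal(params.get("loc", 0.0), params.get("scale", 1.0), size)
    elif distribution == "lognormal":
        vals = rng.lognormal(params.get("mean", 0.0), params.get("sigma", 1.0), size)
    elif distribution == "uniform":
        vals = rng.uniform(params.get("low", 0.0), params.get("high", 1.0), size)
    elif distribution == "point_mass":
        vals = np.full(size, float(params.get("value", 0.0)))
    else:
        raise ValueError(f"unknown distribution family {distribution!r}")
    return [vals[i] for i in range(n_groups)]
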