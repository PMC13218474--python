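"""Backbone fluctuation (RMSF) analysis over a trailing time window.

RMSF is computed per backbone atom as the root-mean-square deviation from
its window-mean position after least-squares rigid-body superposition of
every frame onto the chain's window-average backbone structure (one
mean/fit/re-mean refinement pass).  The per-residue value is the mean over
that residue's backbone atoms, and group means split residues into those
that do and do not interact with the partner chain.

Chains are assumed whole (not wrapped across the periodic boundary) within
the analysis window; no unwrapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model import SystemTopology, Trajectory

__all__ = ["RMSFReport", "superpose", "backbone_rmsf", "partition_rmsf"]


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, transformed, rmsd)`` where
    ``transformed = mobile @ rotation.T + translation`` minimizes the RMSD
    over the matched points.  The rotation is proper (det +1).  Raises on
    degenerate (fewer than 3 points, or collinear) selections.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2 or np.linalg.matrix_rank(rc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(rc, mc)
    R = rot.as_matrix()
    t = reference.mean(axis=0) - mobile.mean(axis=0) @ R.T
    transformed = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - reference) ** 2, axis=1))))
    return R, t, transformed, rmsd


@dataclass
class RMSFReport:
    """Per-residue backbone RMSF (Å) of one chain over a time window."""

    chain: str
    residues: np.ndarray
    monomer_codes: np.ndarray
    rmsf: np.ndarray
    window_ns: tuple[float, float]
    atom_ids: np.ndarray
    atom_rmsf: np.ndarray

    def to_dataframe(self, interacting: set[int] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chain": self.chain,
                "residue": self.residues,
                "monomer_code": self.monomer_codes,
                "rmsf_A": self.rmsf,
            }
        )
        if interacting is not None:
            df["interacting"] = [int(r) in interacting for r in self.residues]
        return df


def backbone_rmsf(
    traj: Trajectory,
    chain: str,
    *,
    window_ns: float | tuple[float, float] | None = None,
    superposition: bool = True,
) -> RMSFReport:
    """Per-residue backbone RMSF over the trailing window.

    ``window_ns`` may be a length (taken backwards from the final frame's
    time), an explicit ``(start, end)`` pair, or None for the whole
    trajectory.  Trajectories shorter than a requested length are analyzed
    whole with a warning.
    """
    topo = traj.topology
    if len(traj) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    t_end = float(traj.times_ns[-1])
    if window_ns is None:
        t_start = float(traj.times_ns[0])
    elif isinstance(window_ns, tuple):
        t_start, t_end = float(window_ns[0]), float(window_ns[1])
    else:
        t_start = t_end - float(window_ns)
        if t_start < traj.times_ns[0]:
            warnings.warn(
                "trajectory shorter than the RMSF window; analyzing all frames"
            )
            t_start = float(traj.times_ns[0])
    tol = 1e-9 * max(1.0, abs(t_end))
    mask = (traj.times_ns >= t_start - tol) & (traj.times_ns <= t_end + tol)
    if mask.sum() < 2:
        raise ValueError("RMSF window covers fewer than 2 frames")

    chain_atoms = topo.chain_atoms(chain)
    bb = chain_atoms[topo.is_backbone[chain_atoms]]
    if len(bb) == 0:
        raise ValueError(f"chain {chain!r} has no backbone atoms")
    X = np.asarray(traj.coordinates[mask][:, bb, :], dtype=float)

    if superposition:
        ref = X.mean(axis=0)
        fitted = np.empty_like(X)
        for f in range(len(X)):
            _, _, fitted[f], _ = superpose(X[f], ref)
        ref = fitted.mean(axis=0)  # re-mean, then one refinement fit
        for f in range(len(X)):
            _, _, fitted[f], _ = superpose(X[f], ref)
        X = fitted

    mean_pos = X.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((X - mean_pos) ** 2, axis=2), axis=0))

    resids = topo.residue_index[bb]
    unique_res = np.unique(resids)
    res_rmsf = np.asarray([atom_rmsf[resids == r].mean() for r in unique_res])
    codes = np.asarray(
        [str(topo.monomer_code[bb[resids == r][0]]) for r in unique_res], dtype=object
    )
    return RMSFReport(
        chain=chain,
        residues=unique_res,
        monomer_codes=codes,
        rmsf=res_rmsf,
        window_ns=(t_start, t_end),
        atom_ids=bb,
        atom_rmsf=atom_rmsf,
    )


def partition_rmsf(
    report: RMSFReport, interacting: set[int]
) -> tuple[float | None, float | None]:
    """Mean per-residue RMSF over interacting vs non-interacting residues.

    Either mean is None (undefined) when its group is empty.
    """
    residues = set(int(r) for r in report.residues)
    if not set(interacting) <= residues:
        raise ValueError("interacting set contains residues outside the chain")
    mask = np.asarray([int(r) in interacting for r in report.residues])
    mean_i = float(report.rmsf[mask].mean()) if mask.any() else None
    mean_n = float(report.rmsf[~mask].mean()) if (~mask).any() else None
    return mean_i, mean_n
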