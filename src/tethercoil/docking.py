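"""Geometric docking-availability screen.

A conformer is "available for docking" when its binding region can be
rigidly superposed onto the reference bound-peptide pose within an RMSD
threshold and, after applying that superposition to the whole chain, no
atom outside the binding region clashes with the receptor.  The screen is
purely geometric — no scoring, flexibility or energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .builder import Conformer
from .complexes import ReferenceComplex
from .metrics import EnsembleTable, welch_one_sided


@dataclass(frozen=True)
class DockingConfig:
    """Binding-region interval and gate thresholds."""

    binding_region: tuple[int, int]       # local residues, inclusive
    rmsd_threshold: float = 0.5           # Å
    clash_cutoff: float = 2.5             # Å, conformer heavy atom vs receptor
    atoms_for_superposition: tuple[str, ...] = ("N", "CA", "C")

    def __post_init__(self):
        if self.rmsd_threshold <= 0 or self.clash_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        lo, hi = self.binding_region
        if lo < 1 or hi < lo:
            raise ValueError("invalid binding region")

    @property
    def region_length(self) -> int:
        return self.binding_region[1] - self.binding_region[0] + 1


@dataclass(frozen=True)
class DockingVerdict:
    conformer_id: object
    rmsd: float
    clash_count: int          # -1 when the RMSD gate already failed
    dockable: bool

    def __post_init__(self):
        if self.dockable and self.clash_count != 0:
            raise ValueError("dockable verdict requires zero clashes")


def kabsch_superpose(moving: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Returns (R, t, rmsd) with the proper rotation R and translation t such
    that ``moving @ R.T + t`` best fits ``target``; reflections are
    corrected by flipping the smallest singular direction (Kabsch).
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValueError("point sets must have equal shape")
    if moving.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mu_m = moving.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (moving - mu_m).T @ (target - mu_t)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = mu_t - rot @ mu_m
    diff = moving @ rot.T + t - target
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return rot, t, rmsd


def _region_backbone(conformer: Conformer, region: tuple[int, int],
                     roles: tuple[str, ...]) -> np.ndarray:
    lo, hi = region
    return np.array([conformer.atom(i, role)
                     for i in range(lo, hi + 1) for role in roles])


def screen_conformer(conformer: Conformer, reference: ReferenceComplex,
                     config: DockingConfig,
                     conformer_id=None) -> DockingVerdict:
    """RMSD gate then clash gate for a single conformer.

    The conformer's binding-region backbone is superposed onto the
    reference peptide pose; if the RMSD exceeds the threshold the
    conformer is not dockable (clash_count reported as -1, not counted).
    Otherwise the superposition is applied to the whole chain and heavy
    atoms outside the binding region are counted against receptor atoms
    within the clash cutoff; dockable iff that count is zero.
    """
    lo, hi = config.binding_region
    if hi > len(conformer):
        raise ValueError("conformer does not cover the binding region")
    if config.region_length != reference.peptide_length:
        raise ValueError(
            f"binding region length {config.region_length} != reference "
            f"peptide length {reference.peptide_length}")
    moving = _region_backbone(conformer, config.binding_region,
                              config.atoms_for_superposition)
    target = reference.backbone_points(config.atoms_for_superposition)
    rot, t, rmsd = kabsch_superpose(moving, target)
    if rmsd > config.rmsd_threshold:
        return DockingVerdict(conformer_id, rmsd, -1, False)
    outside = (conformer.atom_res < lo) | (conformer.atom_res > hi)
    placed = conformer.coords[outside] @ rot.T + t
    n_clashes = count_clashes(placed, reference.receptor_atoms,
                              config.clash_cutoff)
    return DockingVerdict(conformer_id, rmsd, n_clashes, n_clashes == 0)


def count_clashes(atoms: np.ndarray, receptor: np.ndarray,
                  cutoff: float) -> int:
    """Number of (atom, receptor atom) pairs strictly closer than cutoff."""
    from scipy.spatial import cKDTree

    if atoms.shape[0] == 0:
        return 0
    tree = cKDTree(receptor)
    pairs = tree.query_ball_point(atoms, r=cutoff)
    # query_ball_point includes the boundary; count strict interior only
    n = 0
    for i, idx in enumerate(pairs):
        if not idx:
            continue
        d = np.linalg.norm(receptor[idx] - atoms[i], axis=1)
        n += int((d < cutoff).sum())
    return n


def screen_ensemble(conformers: list[Conformer],
                    reference: ReferenceComplex,
                    config: DockingConfig,
                    ids: list | None = None) -> pd.DataFrame:
    """Verdicts for every conformer as a DataFrame
    (conformer_id, rmsd, clash_count, dockable)."""
    if ids is None:
        ids = list(range(len(conformers)))
    verdicts = [screen_conformer(c, reference, config, cid)
                for cid, c in zip(ids, conformers)]
    return pd.DataFrame(
        {"conformer_id": [v.conformer_id for v in verdicts],
         "rmsd": [v.rmsd for v in verdicts],
         "clash_count": [v.clash_count for v in verdicts],
         "dockable": [v.dockable for v in verdicts]})


def compare_dockable(table: EnsembleTable,
                     metrics: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Welch comparison of non-dockable vs dockable groups per metric.

    Tests the one-sided alternative that the non-dockable group's mean is
    smaller.  Returns one row per metric with both group means, t, df, p.
    """
    df = table.df
    if "dockable" not in df.columns:
        raise ValueError("table has no dockable flags")
    dock = df[df["dockable"]]
    undock = df[~df["dockable"]]
    if len(dock) < 2:
        raise ValueError("dockable group is empty or too small")
    if len(undock) < 2:
        raise ValueError("non-dockable group is empty or too small")
    if metrics is None:
        metrics = tuple(table.metric_columns())
    rows = []
    for m in metrics:
        t, dof, p = welch_one_sided(undock[m].to_numpy(), dock[m].to_numpy())
        rows.append({"metric": m,
                     "mean_nondockable": undock[m].mean(),
                     "mean_dockable": dock[m].mean(),
                     "t": t, "df": dof, "p": p,
                     "n_nondockable": len(undock), "n_dockable": len(dock)})
    return pd.DataFrame(rows)
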