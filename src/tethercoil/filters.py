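"""Membrane-frame derivation and the two half-space ensemble filters.

The membrane is modelled as a plane through the CA of the last
transmembrane-anchor residue, perpendicular to the helix axis; a conformer
passes Constraint 1 (the membrane filter) when every heavy atom of its
post-anchor residues lies on the cytoplasmic side of that plane.

The neighboring molecular assembly is modelled as a second half-space: a
vertical plane parallel to the helix axis at lateral distance delta from
the anchor point.  A conformer passes Constraint 2 when every post-anchor
heavy atom lies on the helix side of that plane (boundary inclusive), so
survivor sets are nested across decreasing delta.

Anchor-span atoms are exempt from both tests: the helix itself sits in
the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .builder import Conformer


class DegenerateGeometryError(ValueError):
    """Helix-axis fit is undefined (e.g. coincident CA positions)."""


@dataclass(frozen=True)
class MembraneFrame:
    """Helix axis, anchor point and lateral direction of one conformer.

    ``axis`` points from the membrane into the cytoplasm (N- to
    C-terminal along the anchor helix); ``anchor`` is the CA of the last
    anchor residue; ``lateral`` is a unit vector perpendicular to the
    axis fixing the orientation of the vertical (neighbor) plane.
    """

    axis: np.ndarray
    anchor: np.ndarray
    lateral: np.ndarray

    def __post_init__(self):
        for v in (self.axis, self.lateral):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("axis and lateral must be unit vectors")
        if abs(float(np.dot(self.axis, self.lateral))) > 1e-9:
            raise ValueError("lateral must be perpendicular to axis")


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the two half-space tests."""

    delta: float                  # Å, lateral distance of the vertical plane
    margin: float = 0.0           # Å, tolerance for boundary atoms
    anchor_span: tuple[int, int] = (1, 23)

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


#: Reference direction whose component orthogonal to the axis defines
#: ``lateral``; +x of the canonical build frame.
_LATERAL_REFERENCE = np.array([1.0, 0.0, 0.0])


def fit_helix_axis(conformer: Conformer, span: tuple[int, int],
                   lateral_reference: np.ndarray | None = None
                   ) -> MembraneFrame:
    """Least-squares helix axis through the CA positions of ``span``.

    The axis is the principal direction of the centered CA cloud, signed
    so that it runs N- to C-terminal.  ``lateral`` is the component of
    the reference direction (+x of the build frame by default)
    orthogonal to the axis.
    """
    lo, hi = span
    if hi - lo + 1 < 4:
        raise ValueError("axis fit needs a span of at least 4 residues")
    cas = np.array([conformer.atom(i, "CA") for i in range(lo, hi + 1)])
    centered = cas - cas.mean(axis=0)
    if not np.any(np.linalg.norm(centered, axis=1) > 1e-9):
        raise DegenerateGeometryError("span CA positions coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if float(np.dot(cas[-1] - cas[0], axis)) < 0:
        axis = -axis
    ref = (_LATERAL_REFERENCE if lateral_reference is None
           else np.asarray(lateral_reference, dtype=float))
    lateral = ref - float(np.dot(ref, axis)) * axis
    norm = np.linalg.norm(lateral)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "lateral reference is parallel to the helix axis")
    return MembraneFrame(axis=axis / np.linalg.norm(axis),
                         anchor=cas[-1].copy(),
                         lateral=lateral / norm)


def _tested_coords(conformer: Conformer, anchor_span: tuple[int, int]
                   ) -> np.ndarray:
    """Heavy atoms of all residues after the anchor span."""
    mask = conformer.atom_res > anchor_span[1]
    return conformer.coords[mask]


def passes_membrane(conformer: Conformer, frame: MembraneFrame,
                    config: FilterConfig) -> bool:
    """Constraint 1: every post-anchor heavy atom on the cytoplasmic side
    of the membrane plane (signed distance >= -margin)."""
    coords = _tested_coords(conformer, config.anchor_span)
    if coords.size == 0:
        return True
    signed = (coords - frame.anchor) @ frame.axis
    return bool(signed.min() >= -config.margin)


def passes_neighbor(conformer: Conformer, frame: MembraneFrame,
                    config: FilterConfig) -> bool:
    """Constraint 2: every post-anchor heavy atom within lateral distance
    delta of the anchor (boundary inclusive)."""
    coords = _tested_coords(conformer, config.anchor_span)
    if coords.size == 0:
        return True
    lateral = (coords - frame.anchor) @ frame.lateral
    return bool(lateral.max() <= config.delta + config.margin)


def filter_ensemble(conformers: list[Conformer],
                    frames: list[MembraneFrame],
                    deltas: tuple[float, ...] = (20.0, 10.0, 5.0),
                    margin: float = 0.0,
                    anchor_span: tuple[int, int] = (1, 23),
                    ids: list | None = None) -> pd.DataFrame:
    """Per-conformer pass/fail flags for the membrane test and each delta.

    Returns a DataFrame with columns ``conformer_id``, ``pass_membrane``
    and ``pass_delta<d>`` per delta, in input order.  Filtering is
    idempotent: re-filtering any surviving subset reproduces its flags.
    """
    if ids is None:
        ids = list(range(len(conformers)))
    rows = []
    for cid, conf, frame in zip(ids, conformers, frames):
        row = {"conformer_id": cid}
        mem_cfg = FilterConfig(delta=1.0, margin=margin,
                               anchor_span=anchor_span)
        row["pass_membrane"] = passes_membrane(conf, frame, mem_cfg)
        for d in deltas:
            cfg = FilterConfig(delta=d, margin=margin, anchor_span=anchor_span)
            row[f"pass_delta{d:g}"] = passes_neighbor(conf, frame, cfg)
        rows.append(row)
    columns = (["conformer_id", "pass_membrane"]
               + [f"pass_delta{d:g}" for d in deltas])
    return pd.DataFrame(rows, columns=columns)
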