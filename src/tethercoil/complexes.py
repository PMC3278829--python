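"""Receptor/bound-peptide reference complexes for the docking screen.

A :class:`ReferenceComplex` holds the heavy-atom coordinates of a receptor
(e.g. a kinase catalytic subunit) and the backbone conformation of its
bound peptide.  Real complexes are read from PDB files; a synthetic
complex — an ideal-helix peptide wrapped on one face by a shell of
receptor pseudo-atoms — lets the whole screen run with no external data.
The synthetic receptor is labelled as such in its id and is not a model
of any real kinase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import Conformer, ideal_helix

BACKBONE_ROLES = ("N", "CA", "C", "O")

#: Default heavy-atom clash cutoff validated on the reference pose (Å).
DEFAULT_CLASH_CUTOFF = 2.5


@dataclass(frozen=True)
class ReferenceComplex:
    """Receptor heavy atoms plus the bound peptide's backbone pose.

    ``peptide_backbone`` maps backbone role -> (peptide_length, 3) array in
    residue order; the reference pose itself must be clash-free against
    the receptor.
    """

    id: str
    receptor_atoms: np.ndarray                  # (n_receptor, 3)
    peptide_backbone: dict[str, np.ndarray]
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF

    def __post_init__(self):
        if self.receptor_atoms.ndim != 2 or self.receptor_atoms.shape[0] == 0:
            raise ValueError("receptor_atoms must be a non-empty (n, 3) array")
        if self.peptide_length < 3:
            raise ValueError("peptide must have at least 3 residues")
        from scipy.spatial import cKDTree

        tree = cKDTree(self.receptor_atoms)
        for role, coords in self.peptide_backbone.items():
            if coords.shape[0] != self.peptide_length:
                raise ValueError("ragged peptide backbone")
            d, _ = tree.query(coords)
            if d.min() < self.clash_cutoff:
                raise ValueError(
                    f"reference pose clashes with receptor at {role} "
                    f"(min distance {d.min():.2f} Å)")

    @property
    def peptide_length(self) -> int:
        return self.peptide_backbone["CA"].shape[0]

    def backbone_points(self, roles=("N", "CA", "C")) -> np.ndarray:
        """Backbone coordinates interleaved residue-major in role order,
        shape (peptide_length * len(roles), 3)."""
        per_res = np.stack([self.peptide_backbone[r] for r in roles], axis=1)
        return per_res.reshape(-1, 3)


def peptide_backbone_from_conformer(conformer: Conformer) -> dict[str, np.ndarray]:
    """Extract the N/CA/C/O backbone of a conformer as a role -> array map."""
    n = len(conformer)
    return {
        role: np.array([conformer.atom(i, role) for i in range(1, n + 1)])
        for role in BACKBONE_ROLES
    }


def make_synthetic_reference_complex(peptide_length: int = 22,
                                     rng_seed: int = 0,
                                     shell_radius: float = 9.0,
                                     shell_spacing: float = 2.5,
                                     shell_overhang: float = 6.0,
                                     clash_cutoff: float = DEFAULT_CLASH_CUTOFF
                                     ) -> ReferenceComplex:
    """Synthetic receptor + bound peptide for download-free testing.

    The bound peptide is an ideal helix.  Receptor pseudo-atoms sample a
    half-cylindrical shell of radius ``shell_radius`` around the helix
    axis (azimuths 90-270 degrees relative to the build frame's +x), with
    axial overhang beyond both helix ends, plus a small jitter so the
    shell is not crystallographically regular.  The open half leaves an
    exit corridor for the flanking chain; conformers whose flanks fold
    back into the closed half clash and are screened out.
    """
    if peptide_length < 3:
        raise ValueError("peptide must have at least 3 residues")
    helix = ideal_helix(max(peptide_length, 4), "synthetic_bound_peptide")
    backbone = peptide_backbone_from_conformer(helix)
    backbone = {r: v[:peptide_length] for r, v in backbone.items()}

    cas = backbone["CA"]
    center = cas.mean(axis=0)
    centered = cas - center
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if float(np.dot(cas[-1] - cas[0], axis)) < 0:
        axis = -axis
    ref = np.array([1.0, 0.0, 0.0])
    u = ref - float(np.dot(ref, axis)) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    proj = centered @ axis
    z_lo, z_hi = proj.min() - shell_overhang, proj.max() + shell_overhang
    rng = np.random.default_rng(rng_seed)
    points = []
    n_az = max(int(np.pi * shell_radius / shell_spacing), 3)
    azimuths = np.linspace(np.pi / 2, 3 * np.pi / 2, n_az)
    for z in np.arange(z_lo, z_hi + shell_spacing / 2, shell_spacing):
        for theta in azimuths:
            jitter = rng.normal(scale=0.2, size=3)
            p = (center + z * axis
                 + shell_radius * (np.cos(theta) * u + np.sin(theta) * v)
                 + jitter)
            points.append(p)
    receptor = np.array(points)
    return ReferenceComplex(
        id=f"synthetic_shell_r{shell_radius:g}_seed{rng_seed}",
        receptor_atoms=receptor,
        peptide_backbone=backbone,
        clash_cutoff=clash_cutoff,
    )


def read_reference_complex(path, receptor_chain: str, peptide_chain: str,
                           clash_cutoff: float = DEFAULT_CLASH_CUTOFF
                           ) -> ReferenceComplex:
    """Read a receptor + bound-peptide complex from a PDB file.

    Receptor = all heavy atoms of ``receptor_chain``; peptide = backbone
    N/CA/C/O of ``peptide_chain`` in residue order.
    """
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    arr = arr[arr.element != "H"]
    receptor = arr[(arr.chain_id == receptor_chain) & ~arr.hetero]
    peptide = arr[(arr.chain_id == peptide_chain) & ~arr.hetero]
    if receptor.array_length() == 0 or peptide.array_length() == 0:
        raise ValueError("empty receptor or peptide chain selection")
    res_ids = np.unique(peptide.res_id)
    backbone = {}
    for role in BACKBONE_ROLES:
        coords = []
        for rid in res_ids:
            sel = peptide[(peptide.res_id == rid) & (peptide.atom_name == role)]
            if sel.array_length() != 1:
                raise ValueError(f"peptide residue {rid} lacks backbone {role}")
            coords.append(sel.coord[0])
        backbone[role] = np.array(coords, dtype=float)
    return ReferenceComplex(
        id=str(path),
        receptor_atoms=receptor.coord.astype(float),
        peptide_backbone=backbone,
        clash_cutoff=clash_cutoff,
    )
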