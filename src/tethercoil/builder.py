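"""All-heavy-atom backbone construction and self-avoiding coil sampling.

Chains are built residue by residue from (phi, psi) torsions with ideal
trans-peptide geometry.  The atom model is N, CA, C, O plus a CB
pseudo-atom for every non-glycine residue; side chains beyond CB and
hydrogens are not modelled.

The sampler draws torsions from a :class:`~tethercoil.torsions.TorsionLibrary`
and rejects residue placements that bring heavy atoms of sequence-distant
residues (|i - j| >= 2) closer than a clash cutoff: the residue is
resampled up to a retry limit, the chain backtracks a few residues when
the limit exhausts, and restarts outright when a per-chain attempt
budget is spent — a self-avoiding random walk in torsion space.

Canonical build frame: residue 1's N at the origin, the N->CA bond along
+z, and CA->C in the xz half-plane with positive x.  With a helical
anchor this points the transmembrane helix roughly along +z, which the
spatial filters rely on for a reproducible lateral direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry as geom
from .geometry import place_atom
from .sequences import SequenceRecord
from .torsions import HELIX_PHI, HELIX_PSI, TorsionLibrary

ROLES = ("N", "CA", "C", "O", "CB")


class SamplingFailure(RuntimeError):
    """Raised when the chain-restart budget is exhausted (over-tight
    clash cutoff or impossible torsion constraints)."""


@dataclass(frozen=True)
class SamplerConfig:
    """Self-avoidance and retry policy for conformer sampling."""

    clash_cutoff: float = 2.5          # Å, heavy atoms of residues |i-j| >= 2
    max_residue_retries: int = 50
    max_chain_restarts: int = 100
    backtrack_depth: int = 5           # residues popped when retries exhaust
    rng_seed: int | tuple = 0

    def __post_init__(self):
        if self.clash_cutoff <= 0:
            raise ValueError("clash_cutoff must be positive")
        if self.max_residue_retries < 1 or self.max_chain_restarts < 1:
            raise ValueError("retry and restart limits must be >= 1")
        if self.backtrack_depth < 0:
            raise ValueError("backtrack_depth must be >= 0")


@dataclass
class Conformer:
    """One chain model: ordered heavy-atom coordinates plus provenance.

    Atoms are residue-major in fixed role order (N, CA, C, O, CB; CB
    absent for glycine).  ``torsions`` records the (phi, psi, omega)
    actually used for each residue (NaN where undefined by convention).
    """

    sequence_id: str
    residues: str
    coords: np.ndarray            # (n_atoms, 3) float64
    atom_res: np.ndarray          # (n_atoms,) 1-based local residue index
    atom_role: np.ndarray         # (n_atoms,) role strings
    torsions: np.ndarray          # (n_res, 3) phi, psi, omega in degrees
    seed: int | tuple | None = None
    attempts: int = 1
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not len(self._index):
            self._index = {
                (int(r), role): i
                for i, (r, role) in enumerate(zip(self.atom_res, self.atom_role))
            }

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def atom(self, residue: int, role: str) -> np.ndarray:
        """Coordinates of one atom by (1-based residue, role)."""
        return self.coords[self._index[(residue, role)]]

    def has_atom(self, residue: int, role: str) -> bool:
        return (residue, role) in self._index

    def ca_coords(self) -> np.ndarray:
        """(n_res, 3) array of CA positions in residue order."""
        return self.coords[self.atom_role == "CA"]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "Conformer":
        """Copy under the rigid motion x -> R x + t."""
        return Conformer(
            sequence_id=self.sequence_id,
            residues=self.residues,
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            atom_res=self.atom_res,
            atom_role=self.atom_role,
            torsions=self.torsions,
            seed=self.seed,
            attempts=self.attempts,
            _index=self._index,
        )


def _roles_for(letter: str) -> tuple[str, ...]:
    return ("N", "CA", "C", "O") if letter == "G" else ROLES


class _ChainBuilder:
    """Incremental NeRF construction with optional grid clash checking.

    The build step for residue i consumes (phi_i, psi_i) and finalises
    atoms {C_i, O_i, CB_i, N_{i+1}, CA_{i+1}}; N_i and CA_i were placed by
    the previous step.  This makes every atom that depends on residue i's
    torsions resampleable at step i.
    """

    def __init__(self, sequence: str, clash_cutoff: float | None = None):
        self.seq = sequence
        self.n = len(sequence)
        self.cutoff = clash_cutoff
        self.cut2 = None if clash_cutoff is None else clash_cutoff * clash_cutoff
        self.inv_cell = None if clash_cutoff is None else 1.0 / clash_cutoff
        self.grid: dict[tuple[int, int, int], list] = {}
        # per-residue atom positions as plain tuples, committed as accepted
        self.placed: list[dict] = [dict() for _ in range(self.n + 2)]
        self.step_log: dict[int, list] = {}
        self.torsions = np.full((self.n, 3), np.nan)
        # canonical frame for residue 1
        n1 = (0.0, 0.0, 0.0)
        ca1 = (0.0, 0.0, geom.BOND_N_CA)
        self.placed[1]["N"] = n1
        self.placed[1]["CA"] = ca1
        self._commit_atom(1, "N", n1)
        self._commit_atom(1, "CA", ca1)

    # -- grid ------------------------------------------------------------

    def _cell(self, p):
        return (int(math.floor(p[0] * self.inv_cell)),
                int(math.floor(p[1] * self.inv_cell)),
                int(math.floor(p[2] * self.inv_cell)))

    def _commit_atom(self, res: int, role: str, p):
        if self.cutoff is None:
            return
        self.grid.setdefault(self._cell(p), []).append((res, p))

    def _clashes(self, res: int, p) -> bool:
        """True if p lies within the cutoff of any committed atom of a
        residue with |res - other| >= 2."""
        cx, cy, cz = self._cell(p)
        px, py, pz = p
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    bucket = self.grid.get((cx + dx, cy + dy, cz + dz))
                    if not bucket:
                        continue
                    for other_res, q in bucket:
                        if abs(other_res - res) < 2:
                            continue
                        ddx = px - q[0]
                        ddy = py - q[1]
                        ddz = pz - q[2]
                        if ddx * ddx + ddy * ddy + ddz * ddz < self.cut2:
                            return True
        return False

    # -- construction ----------------------------------------------------

    def propose(self, i: int, phi: float, psi: float) -> dict:
        """Atoms finalised by step i, as {(res, role): position}."""
        r = self.placed[i]
        n_i, ca_i = r["N"], r["CA"]
        if i == 1:
            # canonical C1 in the xz half-plane (x > 0)
            ang = math.radians(geom.ANGLE_N_CA_C)
            c_i = (geom.BOND_CA_C * math.sin(ang), 0.0,
                   ca_i[2] - geom.BOND_CA_C * math.cos(ang))
        else:
            c_prev = self.placed[i - 1]["C"]
            c_i = place_atom(c_prev, n_i, ca_i, geom.BOND_CA_C,
                             geom.ANGLE_N_CA_C, phi)
        out = {(i, "C"): c_i}
        if self.seq[i - 1] != "G":
            out[(i, "CB")] = place_atom(c_i, n_i, ca_i, geom.BOND_CA_CB,
                                        geom.ANGLE_N_CA_CB,
                                        geom.IMPROPER_C_N_CA_CB)
        # carbonyl O is anti to the next N across the peptide plane
        out[(i, "O")] = place_atom(n_i, ca_i, c_i, geom.BOND_C_O,
                                   geom.ANGLE_CA_C_O,
                                   geom.wrap_angle(psi + 180.0))
        if i < self.n:
            n_next = place_atom(n_i, ca_i, c_i, geom.BOND_C_N,
                                geom.ANGLE_CA_C_N, psi)
            ca_next = place_atom(ca_i, c_i, n_next, geom.BOND_N_CA,
                                 geom.ANGLE_C_N_CA, geom.OMEGA_TRANS)
            out[(i + 1, "N")] = n_next
            out[(i + 1, "CA")] = ca_next
        return out

    def clash_free(self, atoms: dict) -> bool:
        if self.cutoff is None:
            return True
        for (res, _role), p in atoms.items():
            if self._clashes(res, p):
                return False
        return True

    def accept(self, i: int, phi: float, psi: float, atoms: dict) -> None:
        self.step_log[i] = list(atoms.items())
        for (res, role), p in atoms.items():
            self.placed[res][role] = p
            self._commit_atom(res, role, p)
        self.torsions[i - 1, 0] = phi if i > 1 else np.nan
        self.torsions[i - 1, 1] = psi if i < self.n else np.nan
        if i > 1:
            self.torsions[i - 1, 2] = geom.OMEGA_TRANS

    def undo_step(self, i: int) -> None:
        """Remove the atoms committed by step i (backtracking support)."""
        for (res, role), p in self.step_log.pop(i):
            del self.placed[res][role]
            if self.cutoff is not None:
                bucket = self.grid[self._cell(p)]
                bucket.remove((res, p))
                if not bucket:
                    del self.grid[self._cell(p)]
        self.torsions[i - 1, :] = np.nan

    def to_conformer(self, sequence_id: str, seed=None,
                     attempts: int = 1) -> Conformer:
        coords, atom_res, atom_role = [], [], []
        for i in range(1, self.n + 1):
            for role in _roles_for(self.seq[i - 1]):
                coords.append(self.placed[i][role])
                atom_res.append(i)
                atom_role.append(role)
        return Conformer(
            sequence_id=sequence_id,
            residues=self.seq,
            coords=np.array(coords, dtype=float),
            atom_res=np.array(atom_res, dtype=int),
            atom_role=np.array(atom_role, dtype=object),
            torsions=self.torsions,
            seed=seed,
            attempts=attempts,
        )


def build_chain(record: SequenceRecord,
                torsions: list[tuple[float, float]]) -> Conformer:
    """Deterministically build a chain from an explicit torsion list.

    ``torsions`` gives (phi, psi) per residue; phi of residue 1 and psi of
    the last residue do not affect any interatomic geometry (the carbonyl
    O of the last residue uses its psi entry for orientation only).
    """
    if len(torsions) != len(record):
        raise ValueError(
            f"torsion list length {len(torsions)} != chain length {len(record)}")
    for phi, psi in torsions:
        for ang in (phi, psi):
            if not -180.0 < ang <= 180.0:
                raise ValueError("torsion angles must lie in (-180, 180]")
    b = _ChainBuilder(record.residues, clash_cutoff=None)
    for i, (phi, psi) in enumerate(torsions, start=1):
        b.accept(i, phi, psi, b.propose(i, phi, psi))
    return b.to_conformer(record.id)


def measure_torsions(conformer: Conformer) -> np.ndarray:
    """Measure (phi, psi, omega) per residue from coordinates.

    Returns an (n_res, 3) array in degrees with NaN where the dihedral is
    undefined (phi_1, psi_n, omega_1).
    """
    n = len(conformer)
    if n < 2:
        raise ValueError("need at least 2 residues to measure torsions")
    out = np.full((n, 3), np.nan)
    at = conformer.atom
    for i in range(1, n + 1):
        if i > 1:
            out[i - 1, 0] = geom.dihedral(at(i - 1, "C"), at(i, "N"),
                                          at(i, "CA"), at(i, "C"))
            out[i - 1, 2] = geom.dihedral(at(i - 1, "CA"), at(i - 1, "C"),
                                          at(i, "N"), at(i, "CA"))
        if i < n:
            out[i - 1, 1] = geom.dihedral(at(i, "N"), at(i, "CA"),
                                          at(i, "C"), at(i + 1, "N"))
    return out


def sample_conformer(record: SequenceRecord, library: TorsionLibrary,
                     config: SamplerConfig) -> Conformer:
    """Draw one self-avoiding conformer.

    Residues are placed sequentially; a placement whose newly finalised
    atoms clash with any atom of a residue at sequence separation >= 2 is
    resampled (override positions cannot be resampled).  When
    ``max_residue_retries`` is exhausted the sampler backtracks
    ``backtrack_depth`` residues and continues — growing chains into a
    compact self-avoiding state routinely dead-ends, and resampling the
    frontier residue alone cannot escape.  A chain whose total attempt
    budget (``max_residue_retries`` x chain length) is spent restarts
    from scratch, up to ``max_chain_restarts``.
    """
    rng = np.random.default_rng(config.rng_seed)
    classes = library.classify(record)
    n = len(record)
    total_attempts = 0
    budget_per_chain = config.max_residue_retries * n
    for _restart in range(config.max_chain_restarts):
        b = _ChainBuilder(record.residues, clash_cutoff=config.clash_cutoff)
        chain_attempts = 0
        i = 1
        while i <= n and chain_attempts <= budget_per_chain:
            fixed = i in library.overrides
            placed = False
            for _try in range(config.max_residue_retries):
                chain_attempts += 1
                total_attempts += 1
                phi, psi = library.draw_position(i, classes[i - 1], rng)
                atoms = b.propose(i, phi, psi)
                if b.clash_free(atoms):
                    b.accept(i, phi, psi, atoms)
                    placed = True
                    break
                if fixed:
                    break   # overridden torsions cannot be resampled
            if placed:
                i += 1
            elif config.backtrack_depth > 0 and i > 1:
                back = min(config.backtrack_depth, i - 1)
                for j in range(i - 1, i - 1 - back, -1):
                    b.undo_step(j)
                i -= back
            else:
                break       # no backtracking possible: restart
        if i > n:
            return b.to_conformer(record.id, seed=config.rng_seed,
                                  attempts=total_attempts)
    raise SamplingFailure(
        f"no self-avoiding chain in {config.max_chain_restarts} restarts "
        f"(clash_cutoff={config.clash_cutoff} Å)")


def ideal_helix(length: int, sequence_id: str = "ideal_helix") -> Conformer:
    """Poly-alanine chain built entirely with helical torsions."""
    if length < 4:
        raise ValueError("ideal helix needs at least 4 residues")
    record = SequenceRecord(id=sequence_id, residues="A" * length,
                            anchor_span=(1, length - 1))
    return build_chain(record, [(HELIX_PHI, HELIX_PSI)] * length)


def min_nonadjacent_distance(conformer: Conformer) -> float:
    """Minimum heavy-atom distance over residue pairs |i - j| >= 2
    (the quantity bounded below by the sampler's clash cutoff)."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(conformer.coords))
    sep = np.abs(conformer.atom_res[:, None] - conformer.atom_res[None, :])
    d[sep < 2] = np.inf
    return float(d.min())


# -- PDB output ---------------------------------------------------------

def _atom_array(conformer: Conformer):
    import biotite.structure as struc

    n = conformer.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = conformer.coords.astype(np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = conformer.atom_res
    from Bio.SeqUtils import seq3

    res_names = {i + 1: seq3(letter).upper()
                 for i, letter in enumerate(conformer.residues)}
    arr.res_name = np.array([res_names[r] for r in conformer.atom_res])
    arr.atom_name = conformer.atom_role.astype(str)
    arr.element = np.array([role[0] for role in conformer.atom_role])
    arr.hetero = np.full(n, False)
    arr.occupancy = np.full(n, 1.0)
    return arr

def write_pdb(conformers, path) -> None:
    """Write one conformer or an ensemble as a (multi-MODEL) PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(conformers, Conformer):
        conformers = [conformers]
    arrays = [_atom_array(c) for c in conformers]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def read_pdb_ensemble(path, sequence_id: str | None = None) -> list[Conformer]:
    """Read a (multi-MODEL) PDB ensemble written by :func:`write_pdb`."""
    from biotite.structure.io.pdb import PDBFile
    from Bio.SeqUtils import seq1

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    out = []
    for model in stack:
        model = model[np.isin(model.atom_name, ROLES)]
        res_ids = np.unique(model.res_id)
        letters = []
        for rid in res_ids:
            name3 = model.res_name[model.res_id == rid][0]
            letters.append(seq1(name3.capitalize()).upper())
        residues = "".join(letters)
        out.append(Conformer(
            sequence_id=sequence_id or str(path),
            residues=residues,
            coords=model.coord.astype(float),
            atom_res=model.res_id.astype(int),
            atom_role=model.atom_name.astype(object),
            torsions=np.full((len(residues), 3), np.nan),
        ))
    return out
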