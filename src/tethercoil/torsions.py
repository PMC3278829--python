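"""Statistical-coil torsion library and per-residue (phi, psi) sampling.

The library is a per-residue-class mixture of Ramachandran basins.  Each
basin is a (phi, psi) center with a circular-Gaussian width and a mixture
weight.  Residue classes are the four used by statistical-coil models:
general, glycine, proline and pre-proline (a residue immediately followed
by proline).  Positions can additionally be

* overridden outright (``overrides``: the helical transmembrane anchor is
  modelled this way, phi = -57, psi = -47 with probability 1), or
* reassigned to a different class (``position_classes``: used by the
  docking experiment to give the binding region a partially preformed
  bound-state basin).

The default library bundled with the package is an explicit, versioned
stand-in for coil statistics derived from structure databases; it is
deliberately configurable (YAML round-trip) so alternative libraries can
be swapped in.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import wrap_angle
from .sequences import SequenceRecord

#: Helical override applied to the transmembrane anchor span.
HELIX_PHI = -57.0
HELIX_PSI = -47.0


@dataclass(frozen=True)
class Basin:
    phi: float
    psi: float
    width: float
    weight: float


@dataclass
class TorsionLibrary:
    """Mixture-of-basins phi/psi distributions per residue class."""

    classes: dict[str, list[Basin]]
    class_of: dict[str, str] = field(default_factory=dict)
    default_class: str = "general"
    pre_proline_class: str | None = "pre_proline"
    overrides: dict[int, tuple[float, float]] = field(default_factory=dict)
    position_classes: dict[int, str] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self):
        for name, basins in self.classes.items():
            total = sum(b.weight for b in basins)
            if not basins or any(b.weight <= 0 for b in basins):
                raise ValueError(f"class {name!r} needs positive weights")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class {name!r} weights sum to {total}")
        for phi, psi in self.overrides.values():
            for ang in (phi, psi):
                if not -180.0 < ang <= 180.0:
                    raise ValueError("override angles must lie in (-180, 180]")

    # -- class resolution ------------------------------------------------

    def classify(self, record: SequenceRecord) -> list[str]:
        """Residue class per position (1-based order), honouring positional
        reassignment and the pre-proline rule."""
        seq = record.residues
        out = []
        for i, letter in enumerate(seq, start=1):
            if i in self.position_classes:
                out.append(self.position_classes[i])
            elif (self.pre_proline_class is not None
                  and letter != "P" and letter != "G"
                  and i < len(seq) and seq[i] == "P"):
                out.append(self.pre_proline_class)
            else:
                out.append(self.class_of.get(letter, self.default_class))
        missing = set(out) - set(self.classes)
        if missing:
            raise ValueError(f"no basin set for classes {sorted(missing)}")
        return out

    # -- sampling --------------------------------------------------------

    def draw(self, cls: str, rng: np.random.Generator) -> tuple[float, float]:
        """Draw one (phi, psi) pair from a residue class."""
        basins = self.classes[cls]
        u = rng.random()
        acc = 0.0
        basin = basins[-1]
        for b in basins:
            acc += b.weight
            if u < acc:
                basin = b
                break
        if basin.width == 0.0:
            return basin.phi, basin.psi
        phi = wrap_angle(basin.phi + basin.width * rng.standard_normal())
        psi = wrap_angle(basin.psi + basin.width * rng.standard_normal())
        return phi, psi

    def draw_position(self, index: int, cls: str,
                      rng: np.random.Generator) -> tuple[float, float]:
        if index in self.overrides:
            return self.overrides[index]
        return self.draw(cls, rng)

    def with_helical_anchor(self, record: SequenceRecord) -> "TorsionLibrary":
        """Copy of the library with the record's anchor span overridden to
        ideal helical torsions."""
        overrides = dict(self.overrides)
        lo, hi = record.anchor_span
        for i in range(lo, hi + 1):
            overrides[i] = (HELIX_PHI, HELIX_PSI)
        return TorsionLibrary(
            classes=self.classes,
            class_of=self.class_of,
            default_class=self.default_class,
            pre_proline_class=self.pre_proline_class,
            overrides=overrides,
            position_classes=dict(self.position_classes),
            version=self.version,
        )

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "TorsionLibrary":
        classes = {
            name: [Basin(*row) for row in rows]
            for name, rows in data["classes"].items()
        }
        class_of = dict(data.get("class_of", {}))
        default = class_of.pop("default", "general")
        return cls(
            classes=classes,
            class_of=class_of,
            default_class=default,
            pre_proline_class=data.get("pre_proline_class"),
            overrides={int(k): tuple(v)
                       for k, v in data.get("overrides", {}).items()},
            position_classes={int(k): v
                              for k, v in data.get("position_classes", {}).items()},
            version=str(data.get("version", "unversioned")),
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "classes": {
                name: [[b.phi, b.psi, b.width, b.weight] for b in basins]
                for name, basins in self.classes.items()
            },
            "class_of": {"default": self.default_class, **self.class_of},
            "pre_proline_class": self.pre_proline_class,
            "overrides": {k: list(v) for k, v in self.overrides.items()},
            "position_classes": dict(self.position_classes),
        }

    @classmethod
    def from_yaml(cls, path) -> "TorsionLibrary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_library() -> TorsionLibrary:
    """The bundled default coil library."""
    ref = importlib.resources.files("tethercoil.data") / "coil_library.yaml"
    with ref.open() as fh:
        return TorsionLibrary.from_dict(yaml.safe_load(fh))


def with_bound_region(library: TorsionLibrary, region: tuple[int, int],
                      bound_weight: float = 0.95,
                      bound_phi: float = HELIX_PHI,
                      bound_psi: float = HELIX_PSI) -> TorsionLibrary:
    """Copy of the library with a partially preformed bound-state basin
    over ``region``.

    Each region residue draws the exact bound-pose torsions (zero width)
    with probability ``bound_weight`` and general coil torsions otherwise.
    This models a binding region with transient preformation of its bound
    conformation; with independent per-residue draws the chance that the
    whole region adopts the exact pose — the prerequisite for the RMSD
    gate of the docking screen — is at least
    ``bound_weight ** region_length`` (coil draws landing near the pose
    raise it further).
    """
    if not 0.0 < bound_weight < 1.0:
        raise ValueError("bound_weight must be in (0, 1)")
    coil = library.classes[library.default_class]
    bound_class = [Basin(bound_phi, bound_psi, 0.0, bound_weight)] + [
        Basin(b.phi, b.psi, b.width, b.weight * (1.0 - bound_weight))
        for b in coil
    ]
    classes = dict(library.classes)
    classes["bound_region"] = bound_class
    position_classes = dict(library.position_classes)
    for i in range(region[0], region[1] + 1):
        position_classes[i] = "bound_region"
    return TorsionLibrary(
        classes=classes,
        class_of=library.class_of,
        default_class=library.default_class,
        pre_proline_class=library.pre_proline_class,
        overrides=dict(library.overrides),
        position_classes=position_classes,
        version=library.version,
    )


def sample_torsions(record: SequenceRecord, library: TorsionLibrary,
                    rng: np.random.Generator) -> list[tuple[float, float]]:
    """Draw a full (phi, psi) trajectory for a record, honouring overrides."""
    classes = library.classify(record)
    return [
        library.draw_position(i, cls, rng)
        for i, cls in enumerate(classes, start=1)
    ]
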