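"""Solvent-accessible surface area by the Shrake–Rupley method.

Each atom is modelled as a sphere of its van der Waals radius expanded by a
probe radius (1.4 Å, a water molecule).  A fixed golden-spiral lattice of
test points is placed on every expanded sphere; a point is accessible when
it lies outside every other atom's expanded sphere, and the atom's area is
the accessible fraction of 4π(r + probe)².  The point set is deterministic,
so results are bit-stable across runs; accuracy improves as 1/n_points.

Areas are split into polar and apolar contributions by atom class:
nitrogen and oxygen are polar, carbon apolar, sulfur polar by default
(configurable — conventions differ), and hydrogens inherit the class of
the nearest bonded heavy atom.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .tables import SasaRecord

__all__ = [
    "AtomSphere",
    "SasaConfig",
    "SASAResult",
    "PolarClass",
    "PolarityRule",
    "BONDI_RADII",
    "RADII_SETS",
    "UnknownElementError",
    "read_structure",
    "classify_polarity",
    "assign_polarity",
    "shrake_rupley",
    "sasa_report",
    "sphere_points",
]

#: Bondi-derived van der Waals radii (Å) for the elements of standard
#: residues.  Swappable through ``SasaConfig.radii_set``.
BONDI_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

RADII_SETS: dict[str, dict[str, float]] = {"bondi": BONDI_RADII}

#: An H more than this far (Å) from every heavy atom is considered unbonded.
_H_BOND_CUTOFF = 1.4


class PolarClass(str, enum.Enum):
    POLAR = "polar"
    APOLAR = "apolar"


class UnknownElementError(KeyError):
    """An atom's element has no radius in the active radii set."""


@dataclass(frozen=True)
class PolarityRule:
    """How atom classes are assigned for the polar/apolar split."""

    name: str = "default"
    sulfur_polar: bool = True
    hydrogen_inherits: bool = True


@dataclass(frozen=True)
class SasaConfig:
    probe_radius: float = 1.4
    n_quadrature_points: int = 960
    radii_set: str | Mapping[str, float] = "bondi"
    polarity_rule: PolarityRule = PolarityRule()

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_quadrature_points < 32:
            raise ValueError("need at least 32 quadrature points")

    @property
    def radii(self) -> Mapping[str, float]:
        if isinstance(self.radii_set, str):
            return RADII_SETS[self.radii_set]
        return self.radii_set


@dataclass(frozen=True)
class AtomSphere:
    element: str
    center: tuple[float, float, float]
    vdw_radius: float
    residue_name: str = ""
    atom_name: str = ""
    polar_class: Optional[PolarClass] = None

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"{self.atom_name or self.element}: non-positive radius")


@dataclass(frozen=True)
class SASAResult:
    """Per-atom and class-partitioned accessible areas (Å²)."""

    per_atom: tuple[float, ...]
    polar: float
    apolar: float

    @property
    def total(self) -> float:
        return self.polar + self.apolar


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` unit vectors."""
    i = np.arange(n, dtype=float)
    # offset keeps points away from the poles
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def read_structure(
    pdb_path: str | Path,
    model_index: int = 1,
    altloc_policy: str = "first",
    config: SasaConfig = SasaConfig(),
    include_hetero: bool = False,
) -> list[AtomSphere]:
    """Read a PDB file into atom spheres with radii from the active set.

    Parameters
    ----------
    model_index
        1-based MODEL block to use (NMR-style multi-model files).
    altloc_policy
        ``"first"`` keeps the first/highest-occupancy alternate location
        (the parser default); ``"all"`` keeps every altloc.
    include_hetero
        Keep HETATM records other than water.  Waters are always excluded.

    Raises
    ------
    UnknownElementError
        For an atom whose element has no radius.
    ValueError
        For an out-of-range model index or a model with no atoms.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(pdb_path).stem, str(pdb_path))
    models = list(structure)
    if not 1 <= model_index <= len(models):
        raise ValueError(
            f"{pdb_path}: model_index {model_index} out of range (file has {len(models)})"
        )
    model = models[model_index - 1]
    radii = config.radii
    spheres: list[AtomSphere] = []
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag == "W":
                continue
            if hetflag != " " and not include_hetero:
                continue
            for atom in residue:
                if atom.is_disordered() and altloc_policy == "all":
                    atoms = atom.disordered_get_list()
                else:
                    atoms = [atom]
                for a in atoms:
                    element = (a.element or "").strip().upper()
                    if element not in radii:
                        raise UnknownElementError(
                            f"{pdb_path}: no radius for element {element!r} "
                            f"(atom {a.get_full_id()})"
                        )
                    x, y, z = (float(v) for v in a.coord)
                    spheres.append(
                        AtomSphere(
                            element=element,
                            center=(x, y, z),
                            vdw_radius=radii[element],
                            residue_name=residue.get_resname(),
                            atom_name=a.get_name(),
                        )
                    )
    if not spheres:
        raise ValueError(f"{pdb_path}: model {model_index} contains no usable atoms")
    return assign_polarity(spheres, config.polarity_rule)


def classify_polarity(
    atom: AtomSphere,
    rule: PolarityRule = PolarityRule(),
    bonded_heavy: Optional[AtomSphere] = None,
) -> PolarClass:
    """Class of a single atom: N/O polar, C apolar, S per rule, H inherits.

    A hydrogen needs ``bonded_heavy`` (its covalently bonded heavy atom)
    under the inheritance rule; omitting it raises.
    """
    e = atom.element.upper()
    if e in ("N", "O"):
        return PolarClass.POLAR
    if e in ("C", "SE"):
        return PolarClass.APOLAR
    if e in ("S", "P"):
        return PolarClass.POLAR if rule.sulfur_polar else PolarClass.APOLAR
    if e == "H":
        if not rule.hydrogen_inherits:
            return PolarClass.APOLAR
        if bonded_heavy is None:
            raise ValueError("hydrogen with inheritance rule needs its bonded heavy atom")
        return classify_polarity(bonded_heavy, rule)
    raise UnknownElementError(f"no polarity class for element {e!r}")


def assign_polarity(
    atoms: Sequence[AtomSphere], rule: PolarityRule = PolarityRule()
) -> list[AtomSphere]:
    """Return atoms with ``polar_class`` filled in.

    Hydrogens inherit from the nearest heavy atom within 1.4 Å; a hydrogen
    with no such neighbour is rejected under the inheritance rule.
    """
    heavy = [a for a in atoms if a.element.upper() != "H"]
    tree = cKDTree(np.array([a.center for a in heavy])) if heavy else None
    out = []
    for a in atoms:
        if a.element.upper() == "H" and rule.hydrogen_inherits:
            if tree is None:
                raise ValueError(f"hydrogen {a.atom_name!r} has no heavy atom to bond to")
            dist, idx = tree.query(a.center)
            if dist > _H_BOND_CUTOFF:
                raise ValueError(
                    f"hydrogen {a.atom_name!r} is {dist:.2f} Å from the nearest heavy "
                    f"atom; cannot inherit a polarity class"
                )
            cls = classify_polarity(a, rule, bonded_heavy=heavy[int(idx)])
        else:
            cls = classify_polarity(a, rule)
        out.append(
            AtomSphere(
                element=a.element,
                center=a.center,
                vdw_radius=a.vdw_radius,
                residue_name=a.residue_name,
                atom_name=a.atom_name,
                polar_class=cls,
            )
        )
    return out


def shrake_rupley(
    atoms: Sequence[AtomSphere], config: SasaConfig = SasaConfig()
) -> SASAResult:
    """Accessible area of every atom, partitioned into polar and apolar.

    Atoms lacking a ``polar_class`` are classified with the config's rule
    first (hydrogens then need a heavy neighbour within bonding distance).
    """
    if not atoms:
        raise ValueError("no atoms")
    if any(a.polar_class is None for a in atoms):
        atoms = assign_polarity(atoms, config.polarity_rule)

    centers = np.array([a.center for a in atoms], dtype=float)
    if not np.isfinite(centers).all():
        raise ValueError("non-finite atom coordinate")
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + config.probe_radius
    unit = sphere_points(config.n_quadrature_points)
    n_atoms = len(atoms)

    tree = cKDTree(centers)
    max_reach = 2.0 * radii.max()
    per_atom = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = centers[i] + radii[i] * unit
        neighbours = [j for j in tree.query_ball_point(centers[i], max_reach) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        frac = accessible.mean() if len(pts) else 0.0
        per_atom[i] = 4.0 * math.pi * radii[i] ** 2 * frac

    polar_mask = np.array([a.polar_class is PolarClass.POLAR for a in atoms])
    polar = float(per_atom[polar_mask].sum())
    apolar = float(per_atom[~polar_mask].sum())
    return SASAResult(per_atom=tuple(float(v) for v in per_atom), polar=polar, apolar=apolar)


def sasa_report(
    structures: Mapping[str, str | Path | Sequence[AtomSphere]],
    config: SasaConfig = SasaConfig(),
    model_index: int = 1,
) -> list[SasaRecord]:
    """One polar/apolar/total row per structure, in input order.

    ``structures`` maps an identifier to a PDB path or a ready atom list;
    the output rows have the same shape as the packaged SASA tables and can
    feed the regression module directly.
    """
    records = []
    for name, source in structures.items():
        if isinstance(source, (str, Path)):
            atoms = read_structure(source, model_index=model_index, config=config)
        else:
            atoms = list(source)
        result = shrake_rupley(atoms, config)
        records.append(
            SasaRecord(
                mutant_id=name,
                apolar=result.apolar,
                polar=result.polar,
                total=result.total,
            )
        )
    return records
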