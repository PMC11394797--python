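"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline end to end without any external data:

* dilution series with top-phase signal proportional to bottom-phase signal
  (slope = the planted partition coefficient) plus relative Gaussian noise,
  on the load-volume grid used in practice;
* mutant panels whose log-K values are correlated across systems through a
  planted linear model, with thermodynamic responses linear in the computed
  signature and a covariate — ground truth is returned for recovery tests;
* toy atomic structures (single sphere, pair, chain, helix) as valid PDB
  text with an analytic or quadrature-refined reference area attached.

All generators are pure functions of their parameters and seed; the seed is
recorded in the output for provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .partition import DilutionSeries
from .signature import SignatureConfig, compute_signature
from .tables import MutantPartitionRecord, Protein, SystemId, ThermoRecord

__all__ = [
    "PanelSimSpec",
    "SimulatedPanel",
    "ToyStructure",
    "gen_dilution_series",
    "gen_mutant_panel",
    "gen_toy_structure",
    "isolated_sphere_area",
    "pair_sphere_areas",
]

_SYSTEMS = (SystemId.ATPS1, SystemId.ATPS2, SystemId.ATPS3)

#: Load volumes (µL) of the dilution series used in practice.
_LOAD_VOLUMES = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0)

#: Simulated K values stay inside the range spanned by the measured panels.
_K_RANGE = (0.25, 1.75)

#: Reference K this close to 1 is rejected: log K_0 = 0 breaks the
#: signature normalisation.
_UNITY_GUARD = 0.02


def gen_dilution_series(
    true_k: float,
    n_points: int = 6,
    rel_noise: float = 0.01,
    seed: int = 0,
    signal_per_ul: float = 20.0,
) -> DilutionSeries:
    """Simulate one dilution series with planted partition coefficient.

    Bottom-phase signals sit on an increasing grid proportional to the
    load volumes (extended evenly past 75 µL if ``n_points`` > 6); the top
    signal is ``true_k · bottom · (1 + ε)`` with ε ~ N(0, rel_noise).
    """
    if true_k <= 0:
        raise ValueError("true_k must be positive")
    if rel_noise < 0:
        raise ValueError("rel_noise must be non-negative")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    if n_points <= len(_LOAD_VOLUMES):
        volumes = np.array(_LOAD_VOLUMES[:n_points])
    else:
        volumes = np.arange(n_points) * 15.0
    bottom = volumes * signal_per_ul
    top = true_k * bottom * (1.0 + rng.normal(0.0, rel_noise, size=n_points))
    return DilutionSeries(points=tuple(zip(bottom.tolist(), top.tolist())))


@dataclass(frozen=True)
class PanelSimSpec:
    """Parameters of a simulated mutant panel.

    ``true_logk_model`` ties log₁₀K₃ to (log₁₀K₁, log₁₀K₂) as
    (intercept, slope₁, slope₂); the default mirrors the cross-system
    relationship refitted from the measured panels.  ``thermo_model`` is
    (intercept, signature slope, covariate slope) for a ΔG-like response;
    its default mirrors the nuclease stability relationship, with the
    covariate playing the role of C_m.  ``k_noise_rel`` sets the recorded
    measurement sd as a fraction of K (3%, the middle of the measured
    sd/K range).
    """

    n_mutants: int = 9
    true_logk_model: tuple[float, float, float] = (-0.17, 0.44, 0.78)
    logk3_noise_sd: float = 0.02
    k_noise_rel: float = 0.03
    thermo_model: tuple[float, float, float] = (0.56, -0.12, 6.2)
    thermo_noise_sd: float = 0.14
    covariate_range: tuple[float, float] = (0.3, 1.0)
    outlier_row: Optional[int] = None
    outlier_shift: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.logk3_noise_sd < 0 or self.k_noise_rel < 0 or self.thermo_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_mutants < 5:  # 3 coefficients + 2 residual dof
            raise ValueError("n_mutants must be at least 5 to leave a fittable panel")


class SimulatedPanel(NamedTuple):
    partition: list[MutantPartitionRecord]
    thermo: list[ThermoRecord]
    truth: dict


def _draw_logk(rng: np.random.Generator) -> float:
    lo, hi = np.log10(_K_RANGE)
    while True:
        logk = float(rng.uniform(lo, hi))
        if abs(10.0 ** logk - 1.0) >= _UNITY_GUARD:
            return logk


def gen_mutant_panel(spec: PanelSimSpec) -> SimulatedPanel:
    """Simulate a mutant panel with planted cross-system and thermo models.

    The first record, ``REF``, is the panel reference.  Signatures are
    computed with the default configuration and drive the thermodynamic
    response; ``truth`` carries every planted parameter and the computed
    signatures for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    a, b, c = spec.true_logk_model
    names = ["REF"] + [f"M{i:02d}" for i in range(1, spec.n_mutants)]
    records = []
    for name in names:
        logk1, logk2 = _draw_logk(rng), _draw_logk(rng)
        logk3 = a + b * logk1 + c * logk2 + rng.normal(0.0, spec.logk3_noise_sd)
        if abs(10.0 ** logk3 - 1.0) < _UNITY_GUARD:
            logk3 += 2 * _UNITY_GUARD  # nudge off the log K = 0 singularity
        ks = [10.0 ** v for v in (logk1, logk2, logk3)]
        k = {s: (kv, spec.k_noise_rel * kv) for s, kv in zip(_SYSTEMS, ks)}
        records.append(
            MutantPartitionRecord(
                mutant_id=name, protein=Protein.NUCLEASE_A, k=k, signature_printed=0.0
            )
        )

    signatures = {r.mutant_id: r.d for r in compute_signature(records, "REF")}
    # store computed signatures in the partition records, as a real panel would
    records = [
        MutantPartitionRecord(
            mutant_id=r.mutant_id, protein=r.protein, k=r.k,
            signature_printed=signatures[r.mutant_id],
        )
        for r in records
    ]

    t0, t1, t2 = spec.thermo_model
    lo, hi = spec.covariate_range
    covariates = rng.uniform(lo, hi, size=spec.n_mutants)
    noise = rng.normal(0.0, spec.thermo_noise_sd, size=spec.n_mutants)
    thermo = []
    for i, name in enumerate(names):
        response = t0 + t1 * signatures[name] + t2 * covariates[i] + noise[i]
        if spec.outlier_row is not None and i == spec.outlier_row:
            response += spec.outlier_shift
        thermo.append(ThermoRecord(mutant_id=name, c_m=float(covariates[i]), dg_h2o=float(response)))

    truth = {
        "seed": spec.seed,
        "true_logk_model": spec.true_logk_model,
        "thermo_model": spec.thermo_model,
        "signatures": signatures,
        "covariates": {n: float(v) for n, v in zip(names, covariates)},
        "outlier_row": None if spec.outlier_row is None else names[spec.outlier_row],
    }
    return SimulatedPanel(records, thermo, truth)


# --- toy structures and their area oracles ----------------------------------

def isolated_sphere_area(vdw_radius: float, probe_radius: float = 1.4) -> float:
    """Accessible area of one isolated atom: 4π(r + probe)²."""
    return 4.0 * math.pi * (vdw_radius + probe_radius) ** 2


def pair_sphere_areas(
    r1: float, r2: float, distance: float, probe_radius: float = 1.4
) -> tuple[float, float]:
    """Closed-form accessible areas of two atoms at the given separation.

    The accessible area of each expanded sphere is its full area minus the
    spherical cap buried inside the other expanded sphere.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    e1, e2 = r1 + probe_radius, r2 + probe_radius
    full1, full2 = 4 * math.pi * e1 ** 2, 4 * math.pi * e2 ** 2
    if distance >= e1 + e2:
        return full1, full2
    if distance <= abs(e1 - e2):
        # smaller sphere fully engulfed
        return (full1, 0.0) if e1 >= e2 else (0.0, full2)
    x1 = (distance ** 2 + e1 ** 2 - e2 ** 2) / (2 * distance)
    h1 = e1 - x1
    h2 = e2 - (distance - x1)
    return full1 - 2 * math.pi * e1 * h1, full2 - 2 * math.pi * e2 * h2


class ToyStructure(NamedTuple):
    pdb_text: str
    kind: str
    seed: int
    reference_total: float
    reference_method: str  # "analytic" or "refined_quadrature"


def _pdb_text(coords: Sequence[tuple[float, float, float]], elements: Sequence[str]) -> str:
    lines = []
    for i, ((x, y, z), elem) in enumerate(zip(coords, elements), start=1):
        name = f"{elem}{i}"[:4]
        lines.append(
            f"ATOM  {i:>5d} {name:^4s} TOY A{i:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {elem:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def gen_toy_structure(kind: str, params: Optional[dict] = None, seed: int = 0) -> ToyStructure:
    """Write a small PDB with a known-area geometry.

    Kinds and their parameters (defaults in brackets):

    * ``single_atom`` — ``element`` [O]; analytic reference.
    * ``pair`` — ``element`` [C], ``distance`` [2.0 Å]; analytic reference.
    * ``linear_chain`` — ``n_atoms`` [5], ``spacing`` [1.5 Å], ``element``
      [C]; reference from 10× quadrature refinement.
    * ``helix_like`` — ``n_atoms`` [12]; backbone-like helix (2.3 Å radius,
      1.5 Å rise, 100° turn); reference from 10× quadrature refinement.
    """
    from .sasa import BONDI_RADII, SasaConfig, assign_polarity, shrake_rupley, AtomSphere

    params = dict(params or {})
    probe = float(params.pop("probe_radius", 1.4))

    if kind == "single_atom":
        element = params.pop("element", "O")
        coords = [(0.0, 0.0, 0.0)]
        elements = [element]
        reference = isolated_sphere_area(BONDI_RADII[element], probe)
        method = "analytic"
    elif kind == "pair":
        element = params.pop("element", "C")
        distance = float(params.pop("distance", 2.0))
        if distance == 0:
            raise ValueError("pair atoms must not coincide")
        coords = [(0.0, 0.0, 0.0), (distance, 0.0, 0.0)]
        elements = [element, element]
        r = BONDI_RADII[element]
        reference = sum(pair_sphere_areas(r, r, distance, probe))
        method = "analytic"
    elif kind == "linear_chain":
        n = int(params.pop("n_atoms", 5))
        spacing = float(params.pop("spacing", 1.5))
        element = params.pop("element", "C")
        if spacing == 0:
            raise ValueError("chain atoms must not coincide")
        coords = [(i * spacing, 0.0, 0.0) for i in range(n)]
        elements = [element] * n
        reference, method = None, "refined_quadrature"
    elif kind == "helix_like":
        n = int(params.pop("n_atoms", 12))
        radius, rise, turn = 2.3, 1.5, math.radians(100.0)
        coords = [
            (radius * math.cos(i * turn), radius * math.sin(i * turn), i * rise)
            for i in range(n)
        ]
        elements = ["C" if i % 3 else "N" for i in range(n)]
        reference, method = None, "refined_quadrature"
    else:
        raise ValueError(f"unknown toy-structure kind {kind!r}")
    if params:
        raise ValueError(f"unknown parameter(s) for {kind!r}: {sorted(params)}")

    if len({c for c in coords}) < len(coords):
        raise ValueError("overlapping identical centers")

    if reference is None:
        atoms = assign_polarity(
            [
                AtomSphere(element=e, center=c, vdw_radius=BONDI_RADII[e])
                for c, e in zip(coords, elements)
            ]
        )
        config = SasaConfig(probe_radius=probe, n_quadrature_points=9600)
        reference = shrake_rupley(atoms, config).total

    return ToyStructure(
        pdb_text=_pdb_text(coords, elements),
        kind=kind,
        seed=seed,
        reference_total=float(reference),
        reference_method=method,
    )
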