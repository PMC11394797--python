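"""Packaged mutant panels and tabular IO.

Two experimental panels are embedded: single- and double-point mutants of
staphylococcal nuclease A and of bacteriophage T4 lysozyme, each partitioned
in three Dextran–Ficoll aqueous two-phase systems (ATPSs) that share the
same polymer content but differ in ionic composition.  Each panel carries,
per variant:

* the partition coefficient K (top-phase / bottom-phase concentration) with
  its standard deviation in each ATPS,
* the published SIA signature distance to the panel reference,
* conformational-stability parameters (GuHCl m-value, C_m and ΔG_H2O for
  nuclease; T_m and ΔΔG for lysozyme),
* polar / apolar / total solvent-accessible surface areas computed from
  structural models.

All numbers are stored exactly as published (two decimals); nothing is
re-derived at load time.  The lysozyme partition reference is the
cysteine-free pseudo-wild-type C54T/C97A ("TA"); its surface-area row is
published under "WT", so :data:`LYSOZYME_REFERENCE_ALIAS` records the join.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "Protein",
    "SystemId",
    "AtpsComposition",
    "MutantPartitionRecord",
    "ThermoRecord",
    "SasaRecord",
    "Panel",
    "LYSOZYME_REFERENCE_ALIAS",
    "ATPS_COMPOSITIONS",
    "load_panel",
    "read_panel_csv",
    "write_panel_csv",
    "panel_frame",
    "PanelSchemaError",
]


class Protein(str, enum.Enum):
    """The two packaged mutant panels."""

    NUCLEASE_A = "nucleaseA"
    T4_LYSOZYME = "T4lysozyme"


class SystemId(str, enum.Enum):
    """Identifiers of the three aqueous two-phase systems."""

    ATPS1 = "ATPS1"  # Dextran-Ficoll, 0.15 M NaCl + 0.01 M NaPB
    ATPS2 = "ATPS2"  # Dextran-Ficoll, 0.15 M Na2SO4 + 0.01 M NaPB
    ATPS3 = "ATPS3"  # Dextran-Ficoll, 0.11 M NaPB

    @property
    def index(self) -> int:
        return int(self.value[-1])


class PanelSchemaError(ValueError):
    """A user-supplied panel table does not match the expected schema."""


@dataclass(frozen=True)
class AtpsComposition:
    """Polymer and ionic composition of one aqueous two-phase system."""

    system_id: SystemId
    polymer_pair: str
    salt_additive: str
    buffer: str
    ph: float


@dataclass(frozen=True)
class MutantPartitionRecord:
    """Partition coefficients of one variant across the three ATPSs.

    ``k`` maps each system to ``(K, sd)``; ``signature_printed`` is the
    published SIA signature distance to the panel reference (0.0 for the
    reference itself).
    """

    mutant_id: str
    protein: Protein
    k: Mapping[SystemId, tuple[float, float]]
    signature_printed: float

    def __post_init__(self) -> None:
        for system, (k, sd) in self.k.items():
            if k <= 0:
                raise ValueError(
                    f"{self.mutant_id}: non-positive K={k} in {system.value}"
                )
            if sd < 0:
                raise ValueError(
                    f"{self.mutant_id}: negative sd={sd} in {system.value}"
                )

    def k_value(self, system: SystemId) -> float:
        return self.k[system][0]

    def k_sd(self, system: SystemId) -> float:
        return self.k[system][1]


@dataclass(frozen=True)
class ThermoRecord:
    """Conformational-stability parameters of one variant.

    Nuclease rows carry the GuHCl-unfolding triple (``m_guhcl`` in
    kcal·mol⁻¹·M⁻¹, ``c_m`` in M, ``dg_h2o`` in kcal/mol); lysozyme rows
    carry thermal parameters (``t_m`` in °C, ``ddg`` in kcal/mol relative to
    the TA reference, absent for TA itself).
    """

    mutant_id: str
    m_guhcl: Optional[float] = None
    c_m: Optional[float] = None
    dg_h2o: Optional[float] = None
    t_m: Optional[float] = None
    ddg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.c_m is not None and self.c_m < 0:
            raise ValueError(f"{self.mutant_id}: negative C_m")


@dataclass(frozen=True)
class SasaRecord:
    """Published polar / apolar / total solvent-accessible areas (Å²)."""

    mutant_id: str
    apolar: float
    polar: float
    total: float

    def __post_init__(self) -> None:
        if min(self.apolar, self.polar) < 0 or self.total <= 0:
            raise ValueError(f"{self.mutant_id}: non-positive SASA")


class Panel(NamedTuple):
    """One loaded panel: partitioning, stability, surface area, systems."""

    partition: list[MutantPartitionRecord]
    thermo: list[ThermoRecord]
    sasa: list[SasaRecord]
    systems: list[AtpsComposition]


#: The lysozyme partition/thermo reference C54T/C97A ("TA") has no row of its
#: own in the published surface-area table; its model is the one published as
#: "WT".  Joins between partition and SASA records use this alias.
LYSOZYME_REFERENCE_ALIAS: dict[str, str] = {"C54T/C97A": "WT"}

ATPS_COMPOSITIONS: tuple[AtpsComposition, ...] = (
    AtpsComposition(SystemId.ATPS1, "Dextran-Ficoll", "0.15 M NaCl + 0.01 M NaPB", "NaPB", 7.4),
    AtpsComposition(SystemId.ATPS2, "Dextran-Ficoll", "0.15 M Na2SO4 + 0.01 M NaPB", "NaPB", 7.4),
    AtpsComposition(SystemId.ATPS3, "Dextran-Ficoll", "0.11 M NaPB", "NaPB", 7.4),
)

# --- packaged panel data (values exactly as published) ----------------------
# mutant: (K1, sd1, K2, sd2, K3, sd3, signature)
_NUCLEASE_PARTITION = {
    "WT":    (0.97, 0.01, 0.42, 0.02, 0.29, 0.02, 0.00),
    "I18L":  (1.14, 0.03, 0.64, 0.04, 0.46, 0.05, 2.41),
    "T33I":  (1.10, 0.02, 0.68, 0.03, 0.52, 0.01, 2.86),
    "L37I":  (1.33, 0.10, 1.25, 0.12, 0.63, 0.06, 5.50),
    "I72M":  (1.18, 0.07, 0.73, 0.07, 0.62, 0.02, 3.48),
    "T82V":  (0.96, 0.03, 0.60, 0.03, 0.45, 0.04, 2.12),
    "L108I": (1.73, 0.24, 0.86, 0.05, 0.73, 0.14, 4.48),
    "L108V": (1.43, 0.06, 0.79, 0.01, 0.67, 0.02, 3.95),
    "V114L": (1.05, 0.06, 0.25, 0.07, 0.26, 0.03, 2.36),
}

# mutant: (m_GuHCl kcal/mol/M, C_m M, dG_H2O kcal/mol)
_NUCLEASE_THERMO = {
    "WT":    (6.53, 0.8, 5.4),
    "I18L":  (6.45, 0.8, 5.2),
    "T33I":  (6.34, 1.0, 6.0),
    "L37I":  (6.00, 0.6, 3.4),
    "I72M":  (6.99, 0.5, 3.6),
    "T82V":  (6.51, 0.9, 5.9),
    "L108I": (6.02, 0.3, 2.0),
    "L108V": (6.31, 0.3, 1.5),
    "V114L": (6.48, 0.7, 4.3),
}

# mutant: (apolar, polar, total) Å²
_NUCLEASE_SASA = {
    "WT":    (5616.60, 3727.75, 9344.35),
    "I18L":  (5626.19, 3687.07, 9313.21),
    "T33I":  (5663.88, 3650.57, 9314.50),
    "L37I":  (5618.81, 3669.40, 9288.21),
    "I72M":  (5723.19, 3684.65, 9407.84),
    "T82V":  (5641.46, 3644.60, 9286.05),
    "L108V": (5629.76, 3651.87, 9281.63),
    "L108I": (5606.91, 3668.80, 9275.71),
    "V114L": (5635.73, 3669.26, 9304.99),
}

_LYSOZYME_PARTITION = {
    "C54T/C97A":   (1.30, 0.02, 0.90, 0.02, 0.68, 0.02, 0.00),
    "G113E":       (1.19, 0.02, 0.86, 0.02, 0.76, 0.01, 1.33),
    "T115A":       (1.32, 0.02, 0.88, 0.02, 0.64, 0.01, 0.47),
    "T115A/S117A": (1.30, 0.02, 0.85, 0.01, 0.65, 0.01, 0.87),
    "S117A/R119A": (1.28, 0.02, 0.91, 0.01, 0.73, 0.01, 1.13),
    "R119A":       (1.35, 0.02, 0.92, 0.02, 0.73, 0.01, 0.53),
}

# mutant: (T_m °C, ddG kcal/mol or None for the reference)
_LYSOZYME_THERMO = {
    "C54T/C97A":   (65.80, None),
    "G113E":       (65.99, 0.3),
    "T115A":       (65.37, -0.14),
    "T115A/S117A": (68.64, 0.95),
    "S117A/R119A": (69.17, 1.16),
    "R119A":       (65.27, -0.18),
}

_LYSOZYME_SASA = {
    "WT":          (5066.36, 3595.81, 8662.36),
    "G113E":       (5047.41, 3668.85, 8716.27),
    "T115A":       (5066.34, 3552.63, 8619.03),
    "T115A/S117A": (5048.58, 3605.60, 8654.18),
    "S117A/R119A": (5049.08, 3576.61, 8625.69),
    "R119A":       (5053.94, 3577.71, 8631.65),
}

_SYSTEMS = (SystemId.ATPS1, SystemId.ATPS2, SystemId.ATPS3)


def _partition_records(data: dict, protein: Protein) -> list[MutantPartitionRecord]:
    out = []
    for mutant, row in data.items():
        k = {s: (row[2 * i], row[2 * i + 1]) for i, s in enumerate(_SYSTEMS)}
        out.append(
            MutantPartitionRecord(
                mutant_id=mutant, protein=protein, k=k, signature_printed=row[6]
            )
        )
    return out


def load_panel(protein: Protein | str) -> Panel:
    """Return the packaged panel for ``protein``.

    Parameters
    ----------
    protein
        ``Protein.NUCLEASE_A`` / ``"nucleaseA"`` or
        ``Protein.T4_LYSOZYME`` / ``"T4lysozyme"``.

    Raises
    ------
    ValueError
        For an unknown protein name.
    """
    try:
        protein = Protein(protein)
    except ValueError:
        valid = ", ".join(p.value for p in Protein)
        raise ValueError(f"unknown protein {protein!r}; expected one of: {valid}") from None

    if protein is Protein.NUCLEASE_A:
        partition = _partition_records(_NUCLEASE_PARTITION, protein)
        thermo = [
            ThermoRecord(m, m_guhcl=a, c_m=b, dg_h2o=c)
            for m, (a, b, c) in _NUCLEASE_THERMO.items()
        ]
        sasa = [SasaRecord(m, *v) for m, v in _NUCLEASE_SASA.items()]
    else:
        partition = _partition_records(_LYSOZYME_PARTITION, protein)
        thermo = [
            ThermoRecord(m, t_m=tm, ddg=ddg) for m, (tm, ddg) in _LYSOZYME_THERMO.items()
        ]
        sasa = [SasaRecord(m, *v) for m, v in _LYSOZYME_SASA.items()]
    return Panel(partition, thermo, sasa, list(ATPS_COMPOSITIONS))


# --- CSV interchange --------------------------------------------------------

_K_COLUMNS = [
    "K_atps1", "sd_atps1", "K_atps2", "sd_atps2", "K_atps3", "sd_atps3",
]


def panel_frame(panel: Panel) -> pd.DataFrame:
    """Merge a panel into one analysis table indexed by ``mutant_id``.

    Surface-area rows are joined through :data:`LYSOZYME_REFERENCE_ALIAS`,
    so the lysozyme reference C54T/C97A picks up the "WT" SASA row.
    Columns: log-ready K values, printed signature, stability parameters and
    SASA components.
    """
    rows = {}
    for rec in panel.partition:
        row = {"protein": rec.protein.value, "signature": rec.signature_printed}
        for s in _SYSTEMS:
            row[f"K_atps{s.index}"] = rec.k_value(s)
            row[f"sd_atps{s.index}"] = rec.k_sd(s)
        rows[rec.mutant_id] = row
    for t in panel.thermo:
        if t.mutant_id in rows:
            rows[t.mutant_id].update(
                m_guhcl=t.m_guhcl, c_m=t.c_m, dg_h2o=t.dg_h2o, t_m=t.t_m, ddg=t.ddg
            )
    sasa_by_id = {s.mutant_id: s for s in panel.sasa}
    for mutant_id, row in rows.items():
        key = LYSOZYME_REFERENCE_ALIAS.get(mutant_id, mutant_id)
        # the nuclease panel publishes its own WT SASA row; the alias only
        # rewrites lysozyme's C54T/C97A
        if row["protein"] == Protein.NUCLEASE_A.value:
            key = mutant_id
        s = sasa_by_id.get(key)
        if s is not None:
            row.update(apolar_sasa=s.apolar, polar_sasa=s.polar, total_sasa=s.total)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "mutant"
    return df


def write_panel_csv(records: Sequence[MutantPartitionRecord], path: str | Path) -> None:
    """Write partition records (with printed signatures) to CSV."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"mutant": rec.mutant_id, "protein": rec.protein.value}
        for s in _SYSTEMS:
            row[f"K_atps{s.index}"] = rec.k_value(s)
            row[f"sd_atps{s.index}"] = rec.k_sd(s)
        row["signature"] = rec.signature_printed
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> list[MutantPartitionRecord]:
    """Read partition records from a CSV of the interchange schema.

    Required columns: ``mutant``, ``K_atps{1,2,3}``, ``sd_atps{1,2,3}``;
    optional ``protein`` (default nucleaseA) and ``signature`` (default NaN
    rows rejected only if the column is required downstream; absent column
    stores 0.0 for the reference and raises nowhere).

    Raises
    ------
    PanelSchemaError
        On a missing column, a duplicate mutant id, or a malformed
        (non-positive / non-numeric) K value; messages carry the row number.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ["mutant", *_K_COLUMNS] if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df["mutant"].duplicated().any():
        dups = df.loc[df["mutant"].duplicated(), "mutant"].tolist()
        raise PanelSchemaError(f"{path}: duplicate mutant id(s): {', '.join(map(str, dups))}")

    records = []
    for i, row in df.iterrows():
        k = {}
        for s in _SYSTEMS:
            try:
                kv = float(row[f"K_atps{s.index}"])
                sd = float(row[f"sd_atps{s.index}"])
            except (TypeError, ValueError):
                raise PanelSchemaError(
                    f"{path}, data row {i + 1}: non-numeric K/sd in {s.value}"
                ) from None
            if not kv > 0:
                raise PanelSchemaError(
                    f"{path}, data row {i + 1}: K must be > 0 in {s.value} (got {kv})"
                )
            if sd < 0:
                raise PanelSchemaError(
                    f"{path}, data row {i + 1}: sd must be >= 0 in {s.value} (got {sd})"
                )
            k[s] = (kv, sd)
        protein = Protein(row["protein"]) if "protein" in df.columns else Protein.NUCLEASE_A
        signature = float(row["signature"]) if "signature" in df.columns else 0.0
        records.append(
            MutantPartitionRecord(
                mutant_id=str(row["mutant"]), protein=protein, k=k,
                signature_printed=signature,
            )
        )
    return records
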