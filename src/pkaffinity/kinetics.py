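"""Steady-state kinetics to experimental free-energy shifts.

A variant's affinity loss relative to the reference peptide is read off the
Michaelis constant, ΔΔG(E→ES) = RT ln(K_M,variant / K_M,ref), under the
quasi-equilibrium view of K_M as a dissociation-constant proxy.  The shift
to the rate-determining transition state follows from catalytic
efficiencies, ΔΔG(E→TS) = RT ln(eff_ref / eff_variant) with
eff = V_max/K_M (proportional to k_cat/K_M when enzyme loading is shared
across the table, as it is for a single kinetics table).  Both are stated
assumptions, not hidden conversions.

Because shifts are ratios of same-unit quantities, the table's native units
(V_max in umol/min/mg, K_M in uM) cancel and no unit layer is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DomainError

__all__ = [
    "R_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "KineticRecord",
    "FreeEnergyShift",
    "catalytic_efficiency",
    "ddg_binding_from_km",
    "ddg_catalysis_from_efficiency",
    "shifts_table",
    "read_kinetics_table",
    "shifts_frame",
]

R_KCAL_PER_MOL_K = 1.98720425e-3
DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class KineticRecord:
    """One peptide's steady-state constants (table units)."""

    peptide: str
    vmax: float      # umol/(min mg)
    km: float        # uM
    is_reference: bool = False

    def __post_init__(self):
        if not (self.vmax > 0 and self.km > 0):
            raise DomainError(
                f"{self.peptide}: V_max and K_M must be positive "
                f"(got {self.vmax}, {self.km})"
            )


@dataclass(frozen=True)
class FreeEnergyShift:
    peptide: str
    ddg_binding: float     # kcal/mol, E -> ES
    ddg_catalysis: float   # kcal/mol, E -> TS
    temperature: float     # K


def catalytic_efficiency(record: KineticRecord) -> float:
    """V_max/K_M on the table's unit scale."""
    return record.vmax / record.km


def ddg_binding_from_km(km_variant: float, km_reference: float,
                        T: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT ln(K_M,variant / K_M,reference) in kcal/mol."""
    if km_variant <= 0 or km_reference <= 0 or T <= 0:
        raise DomainError("K_M values and temperature must be positive")
    return R_KCAL_PER_MOL_K * T * math.log(km_variant / km_reference)


def ddg_catalysis_from_efficiency(eff_variant: float, eff_reference: float,
                                  T: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT ln(eff_reference / eff_variant) in kcal/mol."""
    if eff_variant <= 0 or eff_reference <= 0 or T <= 0:
        raise DomainError("efficiencies and temperature must be positive")
    return R_KCAL_PER_MOL_K * T * math.log(eff_reference / eff_variant)


def shifts_table(records: list[KineticRecord],
                 T: float = DEFAULT_TEMPERATURE_K) -> list[FreeEnergyShift]:
    """Both free-energy shifts for every record, relative to the one
    flagged reference (whose shifts come out exactly 0)."""
    refs = [r for r in records if r.is_reference]
    if len(refs) != 1:
        raise ConfigError(
            f"exactly one reference record required, found {len(refs)}"
        )
    ref = refs[0]
    eff_ref = catalytic_efficiency(ref)
    out = []
    for r in records:
        if r is ref:
            out.append(FreeEnergyShift(r.peptide, 0.0, 0.0, T))
            continue
        out.append(
            FreeEnergyShift(
                peptide=r.peptide,
                ddg_binding=ddg_binding_from_km(r.km, ref.km, T),
                ddg_catalysis=ddg_catalysis_from_efficiency(
                    catalytic_efficiency(r), eff_ref, T
                ),
                temperature=T,
            )
        )
    return out


# --------------------------------------------------------------------------
# tabular I/O
# --------------------------------------------------------------------------

def read_kinetics_table(path) -> list[KineticRecord]:
    """Read a kinetics TSV with columns peptide (or system),
    vmax_umol_min_mg, km_uM, is_reference."""
    df = pd.read_csv(path, sep="\t", comment="#")
    name_col = "peptide" if "peptide" in df.columns else "system"
    records = [
        KineticRecord(
            peptide=str(row[name_col]),
            vmax=float(row["vmax_umol_min_mg"]),
            km=float(row["km_uM"]),
            is_reference=bool(int(row["is_reference"])),
        )
        for _, row in df.iterrows()
    ]
    return records


def shifts_frame(records: list[KineticRecord],
                 T: float = DEFAULT_TEMPERATURE_K) -> pd.DataFrame:
    """Five-column frame (peptide, vmax, km, efficiency, both shifts)."""
    shifts = {s.peptide: s for s in shifts_table(records, T)}
    rows = []
    for r in records:
        s = shifts[r.peptide]
        rows.append(
            {
                "peptide": r.peptide,
                "vmax_umol_min_mg": r.vmax,
                "km_uM": r.km,
                "vmax_over_km": catalytic_efficiency(r),
                "ddg_es_kcal": s.ddg_binding,
                "ddg_ts_kcal": s.ddg_catalysis,
            }
        )
    return pd.DataFrame(rows)
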