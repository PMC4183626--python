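"""The predictive layer: correlate calculated binding shifts (ddG E->ES)
with experimental catalytic shifts (ddG E->TS), choose histidine
protonation states by R^2 maximization, and emit a linear predictor.

R^2 is the squared Pearson correlation of the paired values, identical to
the coefficient of determination of the ordinary least-squares line with
intercept; the experimental axis is ddG(E->TS), the calculated axis is
ddG(E->ES), and since R^2 is symmetric the axis assignment affects only
the reported slope/intercept.

Histidine mutants exist in three classical protonation states: neutral
tautomers Hd (proton on Nd1) and He (proton on Ne2), and the +1
imidazolium Hp.  A single state per mutant must be chosen to enter the
correlation; the 3x3 grid over positions 18 and 19 is evaluated
exhaustively and the argmax cell is selected (ties reported, never
silently broken).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import InputError, NumericalError

__all__ = [
    "TAUTOMERS",
    "MUTANT_SYSTEMS",
    "SHORT_PEPTIDES",
    "CorrelationResult",
    "ProtonationGrid",
    "squared_pearson",
    "assemble_mutant_dataset",
    "select_histidine_pair",
    "full_model",
    "predict_ddg_ts",
]

TAUTOMERS = ("Hd", "He", "Hp")
# non-histidine systems present in every grid cell (reference included)
MUTANT_SYSTEMS = ("WT", "R18A", "R19A", "R18K", "R19K")
SHORT_PEPTIDES = ("RRASLG", "RASLG", "LRRASL")


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    slope: float
    intercept: float
    n_points: int
    labels: tuple[str, ...]

    def __post_init__(self):
        if not (self.n_points >= 3):
            raise InputError("a correlation needs at least 3 points")


@dataclass(frozen=True)
class ProtonationGrid:
    """All nine (tautomer@18, tautomer@19) correlation cells."""

    cells: dict
    best_pairs: tuple[tuple[str, str], ...]

    @property
    def best(self) -> CorrelationResult:
        return self.cells[self.best_pairs[0]]

    def frame(self) -> pd.DataFrame:
        rows = [
            {"his18": a, "his19": b, "r_squared": c.r_squared,
             "slope": c.slope, "intercept": c.intercept,
             "is_best": (a, b) in self.best_pairs}
            for (a, b), c in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def squared_pearson(x, y, labels=None) -> CorrelationResult:
    """Least-squares line and squared Pearson correlation of (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise InputError("a correlation needs at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NumericalError("zero variance in x or y; correlation undefined")
    fit = _stats.linregress(x, y)
    if labels is None:
        labels = tuple(str(i) for i in range(x.size))
    return CorrelationResult(
        r_squared=float(fit.rvalue ** 2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=int(x.size),
        labels=tuple(labels),
    )


def _lookup(table: dict, name: str, side: str) -> float:
    if name not in table:
        raise InputError(f"{side} table is missing system {name!r}")
    return float(table[name])


def _exp_key(system: str) -> str:
    """Experimental-table key for a calculated-system name: tautomer
    variants of one histidine mutant share a single kinetics row."""
    if len(system) == 5 and system[:4] in ("R18H", "R19H") and system[4] in "dep":
        return system[:4]
    return system


def assemble_mutant_dataset(calc_table: dict, exp_table: dict,
                            his18_variant: str, his19_variant: str):
    """The 7 paired points of one grid cell: WT + 4 non-His mutants +
    the chosen histidine pair, in deterministic label order.

    ``calc_table`` maps system name -> calculated ddG(E->ES);
    ``exp_table`` maps system name -> experimental ddG(E->TS).
    """
    for v in (his18_variant, his19_variant):
        if v not in TAUTOMERS:
            raise InputError(f"unknown histidine variant {v!r}; expected {TAUTOMERS}")
    systems = list(MUTANT_SYSTEMS) + [f"R18{his18_variant}", f"R19{his19_variant}"]
    x = [_lookup(calc_table, s, "calculated") for s in systems]
    y = [_lookup(exp_table, _exp_key(s), "experimental") for s in systems]
    return np.asarray(x), np.asarray(y), tuple(systems)


def select_histidine_pair(calc_table: dict, exp_table: dict) -> ProtonationGrid:
    """Exhaustive 3x3 grid over histidine states at positions 18 and 19;
    best = argmax R^2, with every maximizer reported on a tie."""
    cells = {}
    for a, b in product(TAUTOMERS, TAUTOMERS):
        x, y, labels = assemble_mutant_dataset(calc_table, exp_table, a, b)
        cells[(a, b)] = squared_pearson(x, y, labels)
    best_r2 = max(c.r_squared for c in cells.values())
    best = tuple(sorted(k for k, c in cells.items()
                        if np.isclose(c.r_squared, best_r2, rtol=0, atol=1e-12)))
    return ProtonationGrid(cells=cells, best_pairs=best)


def full_model(calc_table: dict, exp_table: dict,
               chosen_pair: tuple[str, str]) -> CorrelationResult:
    """The 10-point model: the chosen-pair mutant set plus the three
    shorter peptides."""
    x, y, labels = assemble_mutant_dataset(calc_table, exp_table, *chosen_pair)
    extra = list(SHORT_PEPTIDES)
    x = np.concatenate([x, [_lookup(calc_table, s, "calculated") for s in extra]])
    y = np.concatenate([y, [_lookup(exp_table, s, "experimental") for s in extra]])
    return squared_pearson(x, y, labels + tuple(extra))


def predict_ddg_ts(model: CorrelationResult, ddg_es_calc: float) -> float:
    """Linear predictor: slope * ddG_calc + intercept (kcal/mol)."""
    return model.slope * float(ddg_es_calc) + model.intercept
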