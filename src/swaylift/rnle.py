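"""Revised NIOSH Lifting Equation (RNLE).

The RNLE scores a manual lifting task by the Recommended Weight Limit

    RWL = LC x HM x VM x DM x AM x FM x CM          [kg]

where LC is the load constant (23 kg) and the six multipliers discount it
for horizontal reach (HM), vertical hand height at the origin (VM), vertical
travel distance (DM), trunk asymmetry (AM), lifting frequency and shift
duration (FM), and hand-to-load coupling quality (CM).  The Lifting Index
LI = load / RWL expresses the lifted mass relative to the limit; LI above 1
flags an elevated risk of work-related low-back disorders.

Multiplier formulas and lookup tables follow the NIOSH Applications Manual
conventions in metric units (cm, kg).  Outside the equation's applicability
domain (e.g. reach beyond 63 cm, origin above 175 cm) the affected
multiplier is 0 -- the task is simply "not recommended" at any weight -- and
a warning flag is set on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

NO_RISK = "No-Risk"
RISK = "Risk"

DURATION_CATEGORIES = ("le1h", "le2h", "le8h")
COUPLINGS = ("good", "fair", "poor")

# FM lookup: frequency [lifts/min] -> (le1h, le2h, le8h), each (V < 75, V >= 75)
_FM_TABLE: dict[float, tuple[tuple[float, float], ...]] = {
    0.2: ((1.00, 1.00), (0.95, 0.95), (0.85, 0.85)),
    0.5: ((0.97, 0.97), (0.92, 0.92), (0.81, 0.81)),
    1.0: ((0.94, 0.94), (0.88, 0.88), (0.75, 0.75)),
    2.0: ((0.91, 0.91), (0.84, 0.84), (0.65, 0.65)),
    3.0: ((0.88, 0.88), (0.79, 0.79), (0.55, 0.55)),
    4.0: ((0.84, 0.84), (0.72, 0.72), (0.45, 0.45)),
    5.0: ((0.80, 0.80), (0.60, 0.60), (0.35, 0.35)),
    6.0: ((0.75, 0.75), (0.50, 0.50), (0.27, 0.27)),
    7.0: ((0.70, 0.70), (0.42, 0.42), (0.22, 0.22)),
    8.0: ((0.60, 0.60), (0.35, 0.35), (0.18, 0.18)),
    9.0: ((0.52, 0.52), (0.30, 0.30), (0.00, 0.15)),
    10.0: ((0.45, 0.45), (0.26, 0.26), (0.00, 0.13)),
    11.0: ((0.41, 0.41), (0.00, 0.23), (0.00, 0.00)),
    12.0: ((0.37, 0.37), (0.00, 0.21), (0.00, 0.00)),
    13.0: ((0.00, 0.34), (0.00, 0.00), (0.00, 0.00)),
    14.0: ((0.00, 0.31), (0.00, 0.00), (0.00, 0.00)),
    15.0: ((0.00, 0.28), (0.00, 0.00), (0.00, 0.00)),
}

# CM lookup: coupling -> (V < 75, V >= 75)
_CM_TABLE = {"good": (1.00, 1.00), "fair": (0.95, 1.00), "poor": (0.90, 0.90)}


class RNLEError(ValueError):
    """Invalid lifting-task input."""


@dataclass(frozen=True)
class LiftingTask:
    """Geometry and organisation of one lifting task (metric units).

    H: horizontal hand distance at origin [cm]; V: vertical hand height at
    origin [cm]; D: vertical travel distance [cm]; A: asymmetry angle [deg];
    f: lifting frequency [lifts/min]; duration_category: shift duration
    bucket; coupling: grip quality; load_mass: lifted mass [kg].
    """

    H: float
    V: float
    D: float
    A: float = 0.0
    f: float = 0.2
    duration_category: str = "le1h"
    coupling: str = "good"
    load_mass: float = 0.0
    LC: float = 23.0

    def __post_init__(self) -> None:
        for name in ("H", "V", "D", "f", "load_mass"):
            if getattr(self, name) < 0:
                raise RNLEError(f"{name} must be non-negative")
        if not 0 <= self.A <= 135:
            raise RNLEError("asymmetry angle A must lie in [0, 135] degrees")
        if self.LC <= 0:
            raise RNLEError("load constant LC must be positive")
        if self.duration_category not in DURATION_CATEGORIES:
            raise RNLEError(f"duration_category must be one of {DURATION_CATEGORIES}")
        if self.coupling not in COUPLINGS:
            raise RNLEError(f"coupling must be one of {COUPLINGS}")


class Multipliers(NamedTuple):
    HM: float
    VM: float
    DM: float
    AM: float
    FM: float
    CM: float
    outside_domain: bool = False

    @property
    def product(self) -> float:
        return self.HM * self.VM * self.DM * self.AM * self.FM * self.CM


@dataclass(frozen=True)
class RNLEResult:
    multipliers: Multipliers
    rwl: float
    li: float
    risk_class: str


def _fm(f: float, duration_category: str, v: float) -> float:
    """Frequency multiplier; linear interpolation between tabulated rates."""
    col = DURATION_CATEGORIES.index(duration_category)
    vcol = 0 if v < 75 else 1
    freqs = np.array(sorted(_FM_TABLE))
    vals = np.array([_FM_TABLE[q][col][vcol] for q in freqs])
    if f <= freqs[0]:
        return float(vals[0])
    if f > freqs[-1]:
        return 0.0
    return float(np.interp(f, freqs, vals))


def compute_multipliers(task: LiftingTask) -> Multipliers:
    """The six RNLE multipliers, each in [0, 1].

    H below 25 cm and D below 25 cm are clamped to the formula identity
    points (HM = DM = 1).  Values outside the applicability domain zero the
    corresponding multiplier and raise a warning.
    """
    outside = False

    if task.H > 63:
        hm, outside = 0.0, True
    else:
        hm = 25.0 / max(task.H, 25.0)

    if task.V > 175:
        vm, outside = 0.0, True
    else:
        vm = 1.0 - 0.003 * abs(task.V - 75.0)

    if task.D > 175:
        dm, outside = 0.0, True
    else:
        dm = 0.82 + 4.5 / max(task.D, 25.0) if task.D > 25 else 1.0

    am = max(1.0 - 0.0032 * task.A, 0.0)
    fm = _fm(task.f, task.duration_category, task.V)
    cm = _CM_TABLE[task.coupling][0 if task.V < 75 else 1]

    if outside:
        warnings.warn("task geometry outside the RNLE applicability domain")
    return Multipliers(hm, vm, dm, am, fm, cm, outside)


def rwl(task: LiftingTask) -> float:
    """Recommended Weight Limit in kg."""
    return task.LC * compute_multipliers(task).product


def lifting_index(load_mass: float, rwl_kg: float) -> float:
    if rwl_kg <= 0:
        raise RNLEError("LI is undefined for non-positive RWL")
    if load_mass < 0:
        raise RNLEError("load_mass must be non-negative")
    return load_mass / rwl_kg


def classify_risk(li: float) -> str:
    """Two-class risk label: LI above 1 is Risk, otherwise No-Risk.

    LI exactly 1 maps to No-Risk (risk is defined as LI *greater* than 1).
    """
    if li < 0:
        raise RNLEError("LI must be non-negative")
    return RISK if li > 1.0 else NO_RISK


def evaluate_task(task: LiftingTask) -> RNLEResult:
    """Multipliers, RWL, LI and risk class for one task."""
    mult = compute_multipliers(task)
    rwl_kg = task.LC * mult.product
    li = lifting_index(task.load_mass, rwl_kg)
    return RNLEResult(mult, rwl_kg, li, classify_risk(li))


def evaluate_batch(tasks: pd.DataFrame) -> pd.DataFrame:
    """Evaluate a CSV-style table of tasks (columns named as LiftingTask)."""
    out = []
    for _, row in tasks.iterrows():
        task = LiftingTask(**{k: row[k] for k in row.index if k in LiftingTask.__dataclass_fields__})
        res = evaluate_task(task)
        out.append(
            {
                **{k: row[k] for k in row.index},
                "HM": res.multipliers.HM,
                "VM": res.multipliers.VM,
                "DM": res.multipliers.DM,
                "AM": res.multipliers.AM,
                "FM": res.multipliers.FM,
                "CM": res.multipliers.CM,
                "RWL": res.rwl,
                "LI": res.li,
                "risk_class": res.risk_class,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Scenario presets for the two experimental sessions.
#
# The protocol fixes V = 50 cm, D = 70 cm, A = 0 (no twisting), good coupling
# (handles), frequency 2.5 lifts/min at 7 kg (No-Risk) and 6 lifts/min at
# 15 kg (Risk).  The horizontal distance is not reported; H = 30 cm is an
# explicit assumption of these presets, chosen as a typical crate-lifting
# reach.  With it the presets give LI close to, but not exactly, the nominal
# session values (0.5 and 1.3).

TRIAL_NO_RISK = LiftingTask(
    H=30.0, V=50.0, D=70.0, A=0.0, f=2.5, duration_category="le1h",
    coupling="good", load_mass=7.0,
)
TRIAL_RISK = LiftingTask(
    H=30.0, V=50.0, D=70.0, A=0.0, f=6.0, duration_category="le1h",
    coupling="good", load_mass=15.0,
)
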