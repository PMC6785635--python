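"""Weak-acid ion-trap accumulation across a cell membrane.

Weak organic acids such as gibberellins and jasmonates cross membranes in
their neutral (protonated) form only; the anion is trapped.  With an acidic
bath and a near-neutral cytosol the neutral species equilibrates across the
membrane while the internal pH deprotonates it, so total internal
concentration exceeds the bath — the ion-trap mechanism.  This module gives
the Henderson–Hasselbalch partitioning, the closed-form equilibrium
accumulation ratio, a kinetic uptake simulation (passive diffusion plus an
optional first-order transporter term, with an optionally time-varying
internal pH), and the empirical oxygen-count rule for oocyte membrane
permeability of gibberellins.

The treatment is monoprotic: a single pKa per compound (default 4.0 for
gibberellins, which are carboxylic acids), anion permeability fixed at zero.
All concentrations are totals (neutral + anion); the bath is an infinite
reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ClassificationError


@dataclass
class CompoundSpec:
    """A weak-acid compound as it enters transport-assay modelling.

    ``permeability`` is a membrane permeability coefficient in any length/time
    unit consistent with the scenario's area/volume; results are reported as
    accumulation ratios, which removes most unit sensitivity.
    """

    name: str
    pKa: float = 4.0
    oxygen_count: int = 0
    permeability: float = 0.0
    external_conc: float = 50.0  # µM

    def __post_init__(self) -> None:
        if not 0.0 <= self.pKa <= 14.0:
            raise ValueError(f"pKa {self.pKa} outside [0, 14]")
        if self.permeability < 0:
            raise ValueError("permeability must be >= 0")
        if self.oxygen_count < 0:
            raise ValueError("oxygen_count must be >= 0")


@dataclass
class IonTrapScenario:
    """Bath/cell geometry and pH conditions for an uptake simulation.

    ``pH_in`` may be a constant, or a piecewise-constant schedule given as a
    list of (start_time_min, pH) pairs ordered by time (the first entry must
    start at 0).  ``transporter_rate`` adds a first-order import flux
    k_t · S_out (1/min), phenomenologically representing carrier-mediated
    uptake far from saturation.
    """

    pH_out: float
    pH_in: float | Sequence[tuple[float, float]]
    S_out: float = 50.0          # µM, constant bath
    V: float = 1.0               # internal volume, µl
    A: float = 0.2               # membrane area, cm²
    transporter_rate: float = 0.0  # 1/min
    duration: float = 60.0       # min

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for ph in self._ph_values():
            if not 0.0 <= ph <= 14.0:
                raise ValueError(f"pH {ph} outside [0, 14]")

    def _ph_values(self) -> list[float]:
        vals = [self.pH_out]
        if np.isscalar(self.pH_in):
            vals.append(float(self.pH_in))
        else:
            sched = list(self.pH_in)
            if not sched or sched[0][0] != 0:
                raise ValueError("pH_in schedule must start at time 0")
            vals.extend(ph for _, ph in sched)
        return vals

    def ph_in_at(self, t: float) -> float:
        if np.isscalar(self.pH_in):
            return float(self.pH_in)
        current = self.pH_in[0][1]
        for start, ph in self.pH_in:
            if t >= start:
                current = ph
            else:
                break
        return float(current)

    def breakpoints(self) -> list[float]:
        if np.isscalar(self.pH_in):
            return []
        return [t for t, _ in self.pH_in if 0 < t < self.duration]


@dataclass
class UptakeTrace:
    times: np.ndarray            # min
    internal_total: np.ndarray   # µM
    accumulation_ratio: np.ndarray  # internal_total / S_out


def neutral_fraction(pH: float, pKa: float) -> float:
    """Fraction of a monoprotic weak acid in the neutral (protonated) form:
    1 / (1 + 10^(pH − pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def equilibrium_ratio(pH_in: float, pH_out: float, pKa: float) -> float:
    """Total-inside over total-outside at neutral-species equilibrium:
    (1 + 10^(pH_in − pKa)) / (1 + 10^(pH_out − pKa)).

    Strictly increasing in pH_in and decreasing in pH_out: a more alkaline
    interior or a more acidic bath strengthens the trap.
    """
    return (1.0 + 10.0 ** (pH_in - pKa)) / (1.0 + 10.0 ** (pH_out - pKa))


def simulate_uptake(
    c: CompoundSpec,
    sc: IonTrapScenario,
    n_points: int = 200,
    rtol: float = 1e-8,
) -> UptakeTrace:
    """Integrate passive + transporter-mediated uptake of a weak acid.

    dS_in/dt = (P·A/V) · (f_n(pH_out)·S_out − f_n(pH_in(t))·S_in)
             + k_t · S_out

    with f_n the neutral fraction; only the neutral species diffuses.  The
    bath is constant.  Integration is stiff-safe (LSODA), performed piecewise
    between internal-pH breakpoints so step changes are resolved exactly.
    Initial internal concentration is 0.
    """
    rate = c.permeability * sc.A / sc.V  # 1/min
    f_out = neutral_fraction(sc.pH_out, c.pKa)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        f_in = neutral_fraction(sc.ph_in_at(t), c.pKa)
        return np.array(
            [rate * (f_out * sc.S_out - f_in * y[0]) + sc.transporter_rate * sc.S_out]
        )

    edges = [0.0] + sc.breakpoints() + [sc.duration]
    times_all = [np.array([0.0])]
    values_all = [np.array([0.0])]
    y0 = np.array([0.0])
    for t0, t1 in zip(edges[:-1], edges[1:]):
        n_seg = max(2, int(round(n_points * (t1 - t0) / sc.duration)))
        t_eval = np.linspace(t0, t1, n_seg)
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=1e-12
        )
        if not sol.success:
            raise RuntimeError(f"uptake integration failed: {sol.message}")
        times_all.append(sol.t[1:])
        values_all.append(sol.y[0][1:])
        y0 = sol.y[:, -1]
    times = np.concatenate(times_all)
    internal = np.maximum(np.concatenate(values_all), 0.0)
    ratio = internal / sc.S_out if sc.S_out > 0 else np.zeros_like(internal)
    return UptakeTrace(times=times, internal_total=internal, accumulation_ratio=ratio)


#: Oocyte-membrane permeability classes keyed by gibberellin oxygen count.
NON_PERMEATING = "non-permeating"
MODERATE = "moderate"
HIGH = "high"

#: Assay pH minimizing diffusion background while retaining transport signal.
RECOMMENDED_PH = {NON_PERMEATING: 5.0, MODERATE: 5.5, HIGH: 6.0}


def classify_permeability(oxygen_count: int) -> str:
    """Empirical oxygen-count rule for gibberellin permeability of the oocyte
    membrane: >= 6 oxygens do not permeate, 5 permeate moderately, <= 4
    permeate to a high degree."""
    if oxygen_count < 0:
        raise ValueError("oxygen_count must be >= 0")
    if oxygen_count >= 6:
        return NON_PERMEATING
    if oxygen_count == 5:
        return MODERATE
    return HIGH


def recommend_assay_pH(c: CompoundSpec) -> tuple[float, str]:
    """Recommended external assay pH for a compound, from its permeability class.

    Non-permeating compounds are assayed at pH 5.0 (maximal trap strength, no
    diffusion background), moderately permeating at pH 5.5 and highly
    permeating at pH 6.0 (diffusion reduced enough for carrier-mediated
    uptake to stand out).  Returns (pH, rationale).
    """
    cls = classify_permeability(c.oxygen_count)
    ph = RECOMMENDED_PH[cls]
    rationale = (
        f"{c.name}: {c.oxygen_count} oxygens → {cls}; assay at external pH {ph} "
        "to balance ion-trap driving force against diffusion background"
    )
    return ph, rationale


def oxygen_count_from_formula(formula: str) -> int:
    """Number of oxygen atoms in a molecular formula such as ``C19H24O6``."""
    import re

    total = 0
    for elem, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if elem == "O":
            total += int(count) if count else 1
    if total == 0 and "O" not in formula:
        return 0
    return total
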