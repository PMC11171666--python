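"""Force-curve and COM-trace analysis: transitions, binding energies, plateaus.

A dissociation "transition" is a monotone ramp of the (smoothed) spring
force ending in an abrupt drop — one step of the multi-step unbinding of a
stacked dimer.  Each transition contributes a spring-energy release

    dE = (F0 + dF/2) * dF / k        [pN*A -> kcal/mol]

where F0 is the force at the start of the ramp, dF the force change over the
ramp and k the spring constant in pN/A.  This is algebraically the harmonic
spring energy difference ((F0+dF)^2 - F0^2) / (2k).  Transitions whose peak
occurs at a COM separation of 10 A or more are discarded: the van der Waals
interaction is short-ranged and force features beyond that mark cannot be
attributed to stacking.

Binding energies are summed per replica over its retained transitions and
aggregated as mean +/- sample SD across replicas.

Stable dimers in a free-diffusion COM trace appear as plateaus: prolonged
intervals of small rolling variance at short separation.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .smd import ForceCurve
from .units import PN_PER_KCAL_MOL_A

__all__ = [
    "Transition",
    "BindingEnergyResult",
    "PlateauInterval",
    "eq2_energy",
    "smooth_force",
    "detect_transitions",
    "binding_energy",
    "pulling_work",
    "detect_plateaus",
    "results_table",
]

COM_CUTOFF_DEFAULT = 10.0  # A — the stacking relevance cutoff


@dataclasses.dataclass
class Transition:
    """One force ramp ending in a drop."""

    t_start: float  # ps
    t_end: float  # ps
    F_start: float  # pN, force at the start of the ramp
    F_peak: float  # pN
    com_at_peak: float  # A

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("transition must have t_start < t_end")
        if self.F_peak < self.F_start:
            raise ValueError("transition must have dF >= 0")

    @property
    def dF(self) -> float:
        return self.F_peak - self.F_start


@dataclasses.dataclass
class BindingEnergyResult:
    """Per-transition, per-replica and aggregated binding energies (kcal/mol)."""

    per_transition_energies: list[list[float]]
    replica_totals: list[float]
    mean: float
    sd: float
    k_used: float  # pN/A
    transitions: list[list[Transition]] = dataclasses.field(default_factory=list)

    @property
    def n_replicas(self) -> int:
        return len(self.replica_totals)


@dataclasses.dataclass
class PlateauInterval:
    """A stable-dimer interval of a COM-distance trace."""

    t_start: float
    t_end: float
    mean_distance: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def eq2_energy(F0: float, dF: float, k: float) -> float:
    """Spring-energy release of one transition, in kcal/mol.

    ``(F0 + dF/2) * dF / k`` with forces in pN and k in pN/A gives pN*A,
    converted to kcal/mol (1 kcal/(mol*A) = 69.477 pN).
    """
    if k <= 0:
        raise ValueError(f"spring constant must be positive, got {k}")
    if dF < 0:
        raise ValueError(f"dF must be non-negative, got {dF}")
    return (F0 + 0.5 * dF) * dF / k / PN_PER_KCAL_MOL_A


def smooth_force(curve: ForceCurve, smooth_ps: float = 10.0) -> np.ndarray:
    """Centred moving average of the recorded force over ``smooth_ps``."""
    if smooth_ps <= 0:
        return np.asarray(curve.force_pN, dtype=float)
    dt = float(np.median(np.diff(curve.times))) if len(curve.times) > 1 else 1.0
    w = max(1, int(round(smooth_ps / dt)))
    return (
        pd.Series(curve.force_pN).rolling(w, center=True, min_periods=1).mean().to_numpy()
    )


def detect_transitions(
    curve: ForceCurve,
    com_cutoff: float = COM_CUTOFF_DEFAULT,
    smooth_ps: float = 10.0,
    drop_frac: float = 0.25,
    min_drop_pN: float = 10.0,
) -> list[Transition]:
    """Segment a force curve into ramps that end in a drop.

    Walking the smoothed trace, a ramp from its running start ``F0`` to the
    running peak ends once the force has fallen by more than
    ``max(drop_frac * dF, min_drop_pN)`` below the peak; ramps smaller than
    ``min_drop_pN`` are noise and never recorded.  Transitions whose peak
    lies at a COM separation of ``com_cutoff`` or more are discarded.
    """
    if len(curve.times) == 0:
        raise ValueError("cannot segment an empty force curve")
    s = smooth_force(curve, smooth_ps)
    t = np.asarray(curve.times, dtype=float)
    com = np.asarray(curve.com_A, dtype=float)

    out: list[Transition] = []
    start_i = 0
    f0 = s[0]
    peak_i = 0
    f_peak = s[0]
    for i in range(1, len(s)):
        x = s[i]
        if x > f_peak:
            f_peak = x
            peak_i = i
            continue
        d_f = f_peak - f0
        drop = f_peak - x
        if d_f >= min_drop_pN and drop >= max(drop_frac * d_f, min_drop_pN):
            out.append(Transition(t[start_i], t[i], float(f0), float(f_peak), float(com[peak_i])))
            start_i = i
            f0 = x
            f_peak = x
            peak_i = i
        elif x <= f0:
            start_i = i
            f0 = x
            f_peak = x
            peak_i = i
    return [tr for tr in out if not (tr.com_at_peak >= com_cutoff)]


def binding_energy(
    curves: Sequence[ForceCurve],
    k: float,
    com_cutoff: float = COM_CUTOFF_DEFAULT,
    smooth_ps: float = 10.0,
    drop_frac: float = 0.25,
    min_drop_pN: float = 10.0,
) -> BindingEnergyResult:
    """Per-replica summed transition energies, aggregated mean +/- sample SD.

    ``k`` is the spring constant in pN/A.  A replica without retained
    transitions contributes 0 with a warning; with a single replica the SD
    is defined as 0 (with a warning).
    """
    if not curves:
        raise ValueError("need at least one force curve")
    per_e: list[list[float]] = []
    totals: list[float] = []
    all_tr: list[list[Transition]] = []
    for idx, curve in enumerate(curves):
        trs = detect_transitions(curve, com_cutoff, smooth_ps, drop_frac, min_drop_pN)
        if not trs:
            warnings.warn(f"replica {idx} has no retained transitions; contributes 0")
        energies = [eq2_energy(tr.F_start, tr.dF, k) for tr in trs]
        per_e.append(energies)
        totals.append(float(sum(energies)))
        all_tr.append(trs)
    mean = float(np.mean(totals))
    if len(totals) > 1:
        sd = float(np.std(totals, ddof=1))
    else:
        warnings.warn("single replica: standard deviation reported as 0")
        sd = 0.0
    return BindingEnergyResult(per_e, totals, mean, sd, k, all_tr)


def pulling_work(curve: ForceCurve, velocity: float) -> float:
    """Total dummy work of a constant-velocity pull, kcal/mol (trapezoidal)."""
    w_pn_a = float(np.trapezoid(curve.force_pN, curve.times)) * velocity
    return w_pn_a / PN_PER_KCAL_MOL_A


def detect_plateaus(
    times: Union[np.ndarray, Sequence[float], pd.DataFrame],
    distances: Optional[Union[np.ndarray, Sequence[float]]] = None,
    dist_threshold: float = 6.0,
    dwell: float = 50.0,
    var_tol: float = 1.5,
    window: Optional[float] = None,
) -> list[PlateauInterval]:
    """Find stable-dimer plateaus in a uniformly sampled COM-distance trace.

    Maximal runs where the rolling mean is below ``dist_threshold`` (A) and
    the rolling variance below ``var_tol`` (A^2), lasting at least ``dwell``
    ps, are reported.  ``window`` (ps, default dwell/5) is the rolling
    window.  Accepts (times, distances) arrays or a DataFrame with
    ``time_ps``/``distance_A`` columns.
    """
    if isinstance(times, pd.DataFrame):
        distances = times["distance_A"].to_numpy()
        times = times["time_ps"].to_numpy()
    t = np.asarray(times, dtype=float)
    d = np.asarray(distances, dtype=float)
    if len(t) < 2:
        warnings.warn("trace too short for plateau detection")
        return []
    span = t[-1] - t[0]
    if dwell > span:
        warnings.warn(f"dwell ({dwell} ps) exceeds the trace span ({span} ps)")
        return []
    dt = float(np.median(np.diff(t)))
    w_ps = window if window is not None else dwell / 5.0
    w = max(3, int(round(w_ps / dt)))
    roll = pd.Series(d).rolling(w, center=True, min_periods=max(2, w // 2))
    ok = ((roll.mean() < dist_threshold) & (roll.var() < var_tol)).fillna(False).to_numpy()

    out: list[PlateauInterval] = []
    i = 0
    n = len(ok)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        if t[j] - t[i] >= dwell:
            out.append(PlateauInterval(t[i], t[j], float(d[i : j + 1].mean())))
        i = j + 1
    return out


def results_table(results: dict[str, BindingEnergyResult]) -> pd.DataFrame:
    """Summary table (system, mean, SD, transition count) for reporting."""
    rows = [
        {
            "system": name,
            "mean_kcal_mol": r.mean,
            "sd_kcal_mol": r.sd,
            "n_replicas": r.n_replicas,
            "n_transitions": int(sum(len(e) for e in r.per_transition_energies)),
        }
        for name, r in results.items()
    ]
    return pd.DataFrame(rows)


def write_report(
    results: dict[str, BindingEnergyResult], path: Union[str, Path]
) -> None:
    """Human-readable summary of a binding-energy study."""
    lines = ["Stacking binding energies from constant-velocity pulling", ""]
    for name, r in results.items():
        lines.append(f"{name}: {r.mean:.2f} +/- {r.sd:.2f} kcal/mol "
                     f"({r.n_replicas} replicas, k = {r.k_used:.1f} pN/A)")
        for i, (tot, es) in enumerate(zip(r.replica_totals, r.per_transition_energies)):
            detail = ", ".join(f"{e:.2f}" for e in es) or "none"
            lines.append(f"  replica {i}: total {tot:.2f} kcal/mol (transitions: {detail})")
        lines.append("")
    Path(path).write_text("\n".join(lines))
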