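"""Quasi-static five-stage orchestration of a discharge event.

The discharge of a nematocyst is modelled as five stages:

1. *Trigger* — the cnidocil receives the chemo-mechanical signal.
2. *Charge buildup* — proteolysis of the poly-gamma-glutamate matrix releases
   H+, which diffuses out and leaves a growing trapped negative charge; the
   Coulomb pressure rises.
3. *Coulomb explosion* — the pressure crosses first the operculum-opening
   threshold and then the stylet fold threshold; the stylet is ejected.
4. *Distension* — the opercular chamber distends, locking the stylet barbs.
5. *Eversion* — the tubule turns inside out through the hollow stylet.

Only stages 2-3 carry quantitative physics (the electrostatic pressure and
the mechanical fold); there is no time-evolution law for the H+ efflux, so
the simulator consumes an explicit monotone *depletion schedule* chi in
[0, 1] — the fraction of the initial H+ content that has left the capsule —
and evaluates the charge scale rho0(chi) = -e n0 chi at each step.  Stages
4-5 are bookkeeping records (the model provides no governing equations for
them); stage 5 carries the eversion time tubule_length / eversion_speed.

The run is fully deterministic: identical parameters give identical
timelines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import electrostatics as es
from . import mechanics as mech
from .exceptions import DomainError

__all__ = [
    "DischargeParams",
    "StageRecord",
    "StageTimeline",
    "DischargeEvent",
    "simulate_discharge",
    "stage_report",
]

STAGE_NAMES = {
    1: "trigger",
    2: "charge buildup",
    3: "coulomb explosion",
    4: "distension",
    5: "eversion",
}


@dataclass(frozen=True)
class DischargeParams:
    """Full parameter set of a discharge run.

    ``p_operculum`` (first threshold, opens the lid) defaults to half the
    numeric stylet fold threshold; the model names but does not quantify it.
    ``efflux_schedule`` defaults to 100 uniform depletion steps from 0 to 1.
    ``eversion_speed`` and ``tubule_length`` only enter the stage-5
    bookkeeping (eversion time = tubule_length / eversion_speed).
    """

    transport: es.IonTransport
    geom: es.CapsuleGeometry
    shape: mech.StyletShape
    restraint: mech.ElasticRestraint
    inertia: mech.StyletInertia
    p_operculum: Optional[float] = None
    efflux_schedule: Optional[Sequence[float]] = None
    eversion_speed: float = 1.0
    tubule_length: float = 1.0

    def __post_init__(self):
        if self.efflux_schedule is not None:
            chi = np.asarray(self.efflux_schedule, dtype=float)
            if chi.ndim != 1 or len(chi) < 1:
                raise ValueError("efflux_schedule must be a non-empty 1-d sequence")
            if np.any(np.diff(chi) < 0):
                raise ValueError("efflux_schedule must be non-decreasing")
            if np.any(chi < 0) or np.any(chi > 1):
                raise DomainError("efflux_schedule values must lie in [0, 1]")
        if not self.eversion_speed > 0:
            raise DomainError("eversion_speed must be strictly positive")
        if not self.tubule_length > 0:
            raise DomainError("tubule_length must be strictly positive")


@dataclass(frozen=True)
class StageRecord:
    """Entry of one stage: which, when, at what pressure, with diagnostics."""

    stage: int
    name: str
    entry_index: int
    pressure_at_entry: float
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class StageTimeline:
    """Ordered stage entries plus the full per-step pressure trace."""

    records: tuple
    steps: np.ndarray = field(repr=False)  # columns: step, chi, rho0, p, stage

    def stages_entered(self) -> tuple:
        return tuple(r.stage for r in self.records)


@dataclass(frozen=True)
class DischargeEvent:
    """Outcome of a simulated discharge."""

    ejected: bool
    p_at_ejection: Optional[float]
    f_max: Optional[float]
    p_max_attained: float
    p_operculum: float
    p_threshold: float
    timeline: StageTimeline


def simulate_discharge(params: DischargeParams) -> DischargeEvent:
    """Run the quasi-static five-stage discharge.

    For each depletion fraction chi in the schedule the charge scale is
    rho0(chi) = -e n0 chi; the linearized-profile Coulomb pressure p(chi)
    (proportional to chi^2) is compared against the operculum threshold
    (stage-3 onset) and the stylet fold threshold (ejection).  On ejection
    the peak acceleration follows from the thrust balance
    P_thres pi Rx^2 / m evaluated at the ejection pressure.  If the schedule
    never reaches the fold, the event reports ejected=False with the maximum
    attained pressure.
    """
    t, geom = params.transport, params.geom
    lam = es.screening_length(t)

    p_thres = mech.threshold_pressure(params.shape, params.restraint, method="numeric")
    p_oper = 0.5 * p_thres if params.p_operculum is None else params.p_operculum
    if not p_oper < p_thres:
        raise DomainError(
            f"p_operculum={p_oper} must be below the stylet threshold {p_thres}: "
            "the operculum opens first"
        )

    chi = (
        np.linspace(0.0, 1.0, 101)
        if params.efflux_schedule is None
        else np.asarray(params.efflux_schedule, dtype=float)
    )
    # p(chi) = chi^2 * p(full depletion): the pressure is quadratic in rho0
    full = es.ChargeProfile("linearized", -t.e * t.n0, lam, geom.R, t.eps)
    p_full = es.coulomb_pressure(full, check_printed=False)
    pressures = chi**2 * p_full
    rho0s = -t.e * t.n0 * chi

    records = [
        StageRecord(1, STAGE_NAMES[1], 0, float(pressures[0]),
                    {"lambda": lam, "X": lam * geom.R}),
        StageRecord(2, STAGE_NAMES[2], 0, float(pressures[0]),
                    {"p_full_depletion": p_full}),
    ]
    stage_per_step = np.full(len(chi), 2, dtype=int)
    stage_per_step[0] = 1 if len(chi) > 0 else 1

    ejected = False
    p_at_ejection = None
    f_max = None

    idx3 = np.flatnonzero(pressures >= p_oper)
    if idx3.size:
        k3 = int(idx3[0])
        records.append(
            StageRecord(3, STAGE_NAMES[3], k3, float(pressures[k3]),
                        {"p_operculum": p_oper})
        )
        stage_per_step[k3:] = 3
        idx_ej = np.flatnonzero(pressures >= p_thres)
        if idx_ej.size:
            ke = int(idx_ej[0])
            ejected = True
            p_at_ejection = float(pressures[ke])
            f_max = mech.max_acceleration(p_at_ejection, params.inertia)
            records.append(
                StageRecord(4, STAGE_NAMES[4], ke, p_at_ejection,
                            {"p_threshold": p_thres, "f_max": f_max})
            )
            t_evert = params.tubule_length / params.eversion_speed
            records.append(
                StageRecord(5, STAGE_NAMES[5], ke, p_at_ejection,
                            {"eversion_time": t_evert,
                             "eversion_speed": params.eversion_speed,
                             "tubule_length": params.tubule_length})
            )
            stage_per_step[ke:] = 5

    steps = np.column_stack(
        [np.arange(len(chi), dtype=float), chi, rho0s, pressures, stage_per_step.astype(float)]
    )
    timeline = StageTimeline(records=tuple(records), steps=steps)
    return DischargeEvent(
        ejected=ejected,
        p_at_ejection=p_at_ejection,
        f_max=f_max,
        p_max_attained=float(pressures.max()) if len(pressures) else 0.0,
        p_operculum=float(p_oper),
        p_threshold=float(p_thres),
        timeline=timeline,
    )


def stage_report(event: DischargeEvent) -> dict:
    """JSON-serializable stage summary of a discharge event.

    Round-trips losslessly through ``json.dumps``/``json.loads``; the
    human-readable rendering is available via :func:`format_stage_report`.
    """
    return {
        "ejected": bool(event.ejected),
        "p_at_ejection": event.p_at_ejection,
        "f_max": event.f_max,
        "p_max_attained": event.p_max_attained,
        "p_operculum": event.p_operculum,
        "p_threshold": event.p_threshold,
        "stages": [
            {
                "stage": r.stage,
                "name": r.name,
                "entry_index": r.entry_index,
                "pressure_at_entry": r.pressure_at_entry,
                "diagnostics": {k: float(v) for k, v in r.diagnostics.items()},
            }
            for r in event.timeline.records
        ],
    }


def format_stage_report(event: DischargeEvent) -> str:
    """One structured line per stage transition."""
    lines = []
    for r in event.timeline.records:
        diag = " ".join(f"{k}={v:.6g}" for k, v in r.diagnostics.items())
        lines.append(
            f"stage={r.stage} name={r.name!r} step={r.entry_index} "
            f"p={r.pressure_at_entry:.6g}" + (f" {diag}" if diag else "")
        )
    verdict = (
        f"ejected at p={event.p_at_ejection:.6g} (f_max={event.f_max:.6g})"
        if event.ejected
        else f"no ejection (max pressure {event.p_max_attained:.6g} "
        f"< threshold {event.p_threshold:.6g})"
    )
    lines.append(verdict)
    return "\n".join(lines)
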