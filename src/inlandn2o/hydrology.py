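"""Water-routing primitives: residence-time outflow, reach transfer, dam modes.

The routing itself (daily stepping over the whole network) lives in
:mod:`inlandn2o.simulator`; this module holds the per-element contracts it is
built from, plus the :func:`route_step` convenience wrapper used for
water-only experiments and audits.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

from .network import LenticBody

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import Simulator, WaterState

__all__ = ["lentic_outflow", "reach_transfer_coefficient", "dam_mode", "route_step"]

SECONDS_PER_DAY = 86_400.0


def lentic_outflow(volume: float, residence_time: float) -> float:
    """Linear-reservoir outflow (m3 d-1): volume / residence time.

    At steady state under constant inflow Q this yields V* = Q * tau, so the
    realised residence time V/Q equals the prescribed tau.
    """
    if residence_time <= 0:
        raise ValueError("residence_time must be > 0 days")
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return volume / residence_time


def reach_transfer_coefficient(length: float, celerity_ms: float, dt: float = 1.0) -> float:
    """Fraction of a reach's storage forwarded per step, from a constant celerity.

    min(celerity * dt / length, 1): short reaches flush fully each day, long
    reaches hold back storage proportionally.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    if celerity_ms <= 0:
        raise ValueError("celerity must be > 0")
    return min(celerity_ms * SECONDS_PER_DAY * dt / length, 1.0)


def dam_mode(body: LenticBody, year: int, natural_flow: bool = False) -> str:
    """Operating mode of a reservoir in a given calendar year.

    Returns ``"active"`` once the simulation year reaches the construction
    year (inclusive), ``"pass-through"`` before it.  Under a natural-flow
    scenario all dams are deactivated regardless of year.  Lakes have no dam
    and are always active; calling this on one is a usage error.
    """
    if body.kind != "reservoir":
        raise ValueError(f"dam_mode applies to reservoirs, not {body.kind} {body.body_id}")
    if natural_flow:
        return "pass-through"
    assert body.construction_year is not None
    return "active" if year >= body.construction_year else "pass-through"


def route_step(
    sim: "Simulator",
    runoff: np.ndarray,
    dt: float = 1.0,
    precip_m: np.ndarray | None = None,
) -> "WaterState":
    """Advance water routing one step and return the resulting water state.

    ``runoff`` is per-cell hillslope input (m3 d-1), split by interception
    fractions into small bodies and the residual subnetwork; subnetwork and
    small-body outflow drain to the main channel; large bodies sit in-line on
    it.  Water balance closes per cell at machine precision.
    """
    if dt != 1.0:
        raise ValueError("route_step operates on a daily step (dt = 1)")
    runoff = np.asarray(runoff, dtype=float)
    if np.any(runoff < 0):
        raise ValueError("runoff must be >= 0")
    return sim.step_water(runoff, precip_m=precip_m)
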