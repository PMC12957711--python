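"""Synchrotron delivery-time simulation.

Assigns a start/end timestamp to every raster spot under a synchrotron spill
structure: beam is extracted in spills of variable length up to a maximum
(4 s default), separated by fixed pauses (4 s default).  A spill ends either
when the maximum spill length is reached or when the current energy layer
completes, whichever comes first; energy-layer switches happen during the
pauses.  Spot duration is the particle weight divided by the extraction rate,
floored at the minimum spot dwell time; spots are not split across spills —
a spot that does not fit in the remaining spill time starts in the next
spill.  Spots are delivered by energy layer (deepest first) in raster order
within each layer; fields are delivered sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .planning import Plan

__all__ = ["AcceleratorModel", "DeliveryTimeline", "simulate_timeline"]


@dataclass(frozen=True)
class AcceleratorModel:
    """Stand-in synchrotron parameters (typical scanned-carbon magnitudes).

    The extraction rate default is set so that a 3 GyRBE fraction on the
    default phantom delivers in roughly 60-120 s, spanning many breathing
    cycles — the regime in which interplay sampling is meaningful.
    """

    max_spill_s: float = 4.0
    spill_pause_s: float = 4.0
    extraction_rate: float = 2.0e7  # particles/s
    min_dwell_s: float = 0.002
    layer_switch_s: float = 1.5

    def __post_init__(self) -> None:
        if min(self.max_spill_s, self.spill_pause_s, self.extraction_rate,
               self.min_dwell_s, self.layer_switch_s) <= 0:
            raise ValueError("all accelerator parameters must be positive")
        if self.max_spill_s > 4.0:
            raise ValueError("spill length is limited to 4 s")


@dataclass
class DeliveryTimeline:
    """Per-spot delivery intervals plus spill bookkeeping."""

    spots: pd.DataFrame  # columns: field, spot_index, energy_idx, start_s, end_s, spill
    spills: pd.DataFrame  # columns: spill, start_s, end_s
    total_time_s: float

    def __post_init__(self) -> None:
        s = self.spots
        if not len(s):
            return
        starts, ends = s["start_s"].to_numpy(), s["end_s"].to_numpy()
        if np.any(ends < starts) or np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("spot intervals must be ordered and non-overlapping")
        spill_start = self.spills.set_index("spill")["start_s"]
        spill_end = self.spills.set_index("spill")["end_s"]
        lo = spill_start.loc[s["spill"]].to_numpy()
        hi = spill_end.loc[s["spill"]].to_numpy()
        if np.any(starts < lo - 1e-9) or np.any(ends > hi + 1e-9):
            raise ValueError("spot interval outside its spill")

    @property
    def beam_on_time_s(self) -> float:
        return float((self.spots["end_s"] - self.spots["start_s"]).sum())


def _delivery_order(plan: Plan):
    """(field, spot) delivery sequence: per field, layers deepest-first,
    raster (row-major in v then u) order within a layer."""
    order = []
    for fi, ss in enumerate(plan.spotsets):
        for e in sorted(np.unique(ss.energy_idx))[::-1]:
            idx = np.flatnonzero(ss.energy_idx == e)
            sub = idx[np.lexsort((ss.u_mm[idx], ss.v_mm[idx]))]
            order.extend((fi, int(s)) for s in sub)
    return order


def simulate_timeline(plan: Plan, accel: AcceleratorModel = AcceleratorModel()) -> DeliveryTimeline:
    """Deterministic delivery schedule for an optimized plan."""
    if accel.extraction_rate <= 0:
        raise ValueError("extraction rate must be positive")
    order = _delivery_order(plan)

    rows = []
    spill_rows = []
    t = 0.0
    spill_idx = 0
    spill_start = 0.0
    spill_open = False
    prev_layer = None

    def close_spill(end_t):
        nonlocal spill_open
        spill_rows.append({"spill": spill_idx, "start_s": spill_start, "end_s": end_t})
        spill_open = False

    for fi, si in order:
        ss = plan.spotsets[fi]
        dur = max(float(ss.weights[si]) / accel.extraction_rate, accel.min_dwell_s)
        if dur > accel.max_spill_s:
            raise ValueError(
                f"spot (field {fi}, index {si}) needs {dur:.2f} s, longer than one spill"
            )
        layer = (fi, int(ss.energy_idx[si]))
        if spill_open and layer != prev_layer:
            # layer completed: spill ends, switch happens during the pause
            close_spill(t)
            t += max(accel.spill_pause_s, accel.layer_switch_s)
        if spill_open and (t + dur) - spill_start > accel.max_spill_s + 1e-12:
            close_spill(t)
            t += accel.spill_pause_s
        if not spill_open:
            spill_idx += 1 if spill_rows else 0
            spill_start = t
            spill_open = True
        rows.append(
            {"field": fi, "spot_index": si, "energy_idx": int(ss.energy_idx[si]),
             "start_s": t, "end_s": t + dur, "spill": spill_idx}
        )
        t += dur
        prev_layer = layer
    if spill_open:
        close_spill(t)
    spots = pd.DataFrame(rows)
    spills = pd.DataFrame(spill_rows)
    return DeliveryTimeline(spots, spills, total_time_s=t)
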