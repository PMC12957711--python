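"""Respiratory motion surrogate.

A Lujan-type periodic trajectory, ``z(t) = z0 - b * cos^{2n}(pi t / tau - phi)``,
is used to map delivery time onto the breathing cycle.  After normalization the
surrogate runs from 0 at end-inhale to 1 at end-exhale, with the exponent ``n``
controlling how long the trajectory dwells near exhale.  Phase sorting is
time-based: one breathing period is divided into ``n_phases`` equal time bins,
phase 0 starting at end-inhale, matching 4DCT phase-percentage labelling
(phase 5 of 10 = 50% = end-exhale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BreathingTrajectory", "lujan_displacement", "phase_at_time"]


@dataclass(frozen=True)
class BreathingTrajectory:
    """Breathing surrogate parameters.

    Parameters
    ----------
    period_s:
        Breathing period tau in seconds (5 or 10 s in the default sweep).
    amplitude_scale:
        Unitless factor in [0, 1] multiplying the phantom's motion fields.
    exponent:
        Lujan exponent n (>= 1); displacement goes as cos^{2n}.
    start_phase:
        Starting phase index in [0, n_phases) at t = 0 (may be fractional).
    """

    period_s: float = 5.0
    amplitude_scale: float = 1.0
    exponent: int = 2
    start_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError(f"breathing period must be positive, got {self.period_s}")
        if not 0.0 <= self.amplitude_scale <= 1.0:
            raise ValueError("amplitude_scale must lie in [0, 1]")
        if self.exponent < 1 or int(self.exponent) != self.exponent:
            raise ValueError("exponent must be a positive integer")


def lujan_displacement(t, traj: BreathingTrajectory, n_phases: int = 10):
    """Normalized breathing displacement in [0, 1] at time(s) ``t`` seconds.

    0 corresponds to end-inhale, 1 to end-exhale.  The starting-phase offset
    shifts the trajectory so that t = 0 sits at the start of ``traj.start_phase``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    t_eff = t + traj.start_phase / n_phases * traj.period_s
    c = np.cos(np.pi * t_eff / traj.period_s)
    disp = 1.0 - c ** (2 * int(traj.exponent))
    return disp if disp.shape else float(disp)


def phase_at_time(t, traj: BreathingTrajectory, n_phases: int = 10):
    """Breathing-phase index active at time(s) ``t`` (time-based binning).

    Deterministic surjective map onto {0, ..., n_phases - 1}; t = 0 with a zero
    starting offset gives phase 0 (end-inhale), t = tau/2 gives the end-exhale
    phase (index n_phases // 2).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    frac = t / traj.period_s * n_phases + traj.start_phase
    idx = np.floor(frac + 1e-9).astype(int) % n_phases
    return idx if idx.shape else int(idx)


def phase_fractions(n_phases: int = 10, exponent: int = 2) -> np.ndarray:
    """Normalized displacement at each phase-bin start (phase 0 -> 0, mid -> 1).

    Used by the phantom to scale its motion field per phase so that phase 0 is
    the motion-free reference and the mid-cycle phase carries full amplitude.
    """
    traj = BreathingTrajectory(period_s=1.0, exponent=exponent)
    times = np.arange(n_phases) / n_phases
    return np.asarray(lujan_displacement(times, traj, n_phases=n_phases))
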