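"""Gait event detection from per-sphere contact forces.

Events are threshold crossings of the normal contact forces (default
threshold: 1 % of body weight).  Heel strike / heel-off come from the heel
sphere, toe-off is the instant the last sphere of a foot-toes pair unloads.
"""

from __future__ import annotations

import numpy as np


def _crossings(t, f, thresh, rising: bool):
    above = f > thresh
    idx = np.nonzero(above[1:] != above[:-1])[0]
    out = []
    for i in idx:
        if above[i + 1] and rising:
            out.append(t[i + 1])
        elif above[i] and not rising:
            out.append(t[i + 1])
    return out


def detect_events(sim, threshold_fraction: float = 0.01) -> list:
    """Heel-strike / heel-off / toe-off events per side from stored forces.

    ``sim`` is a SimResult; its sphere forces are body-mass normalized, so
    the threshold is ``threshold_fraction * g`` N/kg.
    """
    from .planar_walker import Event

    thresh = threshold_fraction * 9.81
    events: list[Event] = []
    t = sim.time
    names = sim.sphere_names
    for side in ("r", "l"):
        cols = [i for i, n in enumerate(names) if n.startswith(side)]
        if not cols:
            continue
        heel = [i for i in cols if names[i].endswith("heel")]
        if heel:
            f = sim.sphere_forces[:, heel[0]]
            for tt in _crossings(t, f, thresh, rising=True):
                events.append(Event(f"{side}_heel_strike", float(tt)))
            for tt in _crossings(t, f, thresh, rising=False):
                events.append(Event(f"{side}_heel_off", float(tt)))
        any_f = sim.sphere_forces[:, cols].max(axis=1)
        for tt in _crossings(t, any_f, thresh, rising=False):
            events.append(Event(f"{side}_toe_off", float(tt)))
        for tt in _crossings(t, any_f, thresh, rising=True):
            events.append(Event(f"{side}_foot_contact", float(tt)))
    return sorted(events, key=lambda e: e.time)


def event_phases(sim, label: str) -> np.ndarray:
    """Stride phases (%) of all events with the given label."""
    from .reference_gait import phase_of

    ts = [e.time for e in sim.events if e.label == label]
    return np.asarray([phase_of(t, sim.cycle_duration) for t in ts])
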