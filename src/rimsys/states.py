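"""Enzyme activity states shared between the binding-network and fitting layers.

A :class:`KineticState` is one catalytically distinct form of RimK (e.g. apo,
RimA-bound, cdG-bound).  Its ``weight`` is the steady-state concentration of
all network species mapped to that state, so a state set plus a steady-state
solution fully determines the composite Michaelis-Menten rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence


@dataclass(frozen=True)
class KineticState:
    """One activity state of the enzyme.

    Parameters
    ----------
    label : str
        State name (e.g. ``"apo"``, ``"cdg_rima"``).
    kcat : float
        Turnover number, min^-1 (or any per-enzyme rate unit carried through).
    km : float
        Michaelis constant for ATP, uM.
    weight : float
        Steady-state concentration of this state, uM.
    """

    label: str
    kcat: float = 0.0
    km: float = 500.0
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.kcat < 0:
            raise ValueError(f"kcat must be >= 0, got {self.kcat}")
        if self.km <= 0:
            raise ValueError(f"Km must be > 0, got {self.km}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class KineticStateSet:
    """A roster of activity states and the network species belonging to each.

    ``members`` maps a state label to the species names whose steady-state
    concentrations are pooled into that state's weight.  Distinct species can
    share a state (the two-state model pools every ligand-bound form into one
    "active" state).
    """

    states: tuple[KineticState, ...]
    members: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        unknown = set(self.members) - set(labels)
        if unknown:
            raise ValueError(f"members refer to unknown states: {sorted(unknown)}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def get(self, label: str) -> KineticState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    def with_weights(self, concentrations: Mapping[str, float]) -> "KineticStateSet":
        """Return a copy whose weights are summed from ``concentrations``."""
        new = []
        for s in self.states:
            members = self.members.get(s.label, (s.label,))
            w = float(sum(concentrations[m] for m in members))
            new.append(replace(s, weight=w))
        return KineticStateSet(tuple(new), dict(self.members))

    def with_params(
        self,
        kcat: Mapping[str, float] | Sequence[float],
        km: Mapping[str, float] | Sequence[float] | float,
    ) -> "KineticStateSet":
        """Return a copy with kcat/Km replaced (by label map or ordered list)."""
        if not isinstance(kcat, Mapping):
            kcat = dict(zip(self.labels, kcat))
        if isinstance(km, (int, float)):
            km = {lab: float(km) for lab in self.labels}
        elif not isinstance(km, Mapping):
            km = dict(zip(self.labels, km))
        new = [
            replace(s, kcat=float(kcat[s.label]), km=float(km[s.label]))
            for s in self.states
        ]
        return KineticStateSet(tuple(new), dict(self.members))
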