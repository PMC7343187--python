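"""Pre-built RimK activation models.

Four model variants of RimK ATPase regulation are provided:

``two_state``
    RimK exists in a basal and a single shared active conformation; binding
    of either cdG or RimA (or both) yields the same active state.  The
    binding topology is the full square (apo, .cdG, .RimA, .cdG.RimA) with
    the ternary Kds cycle-constrained, so the variant has one free Kd per
    activating ligand but only two distinct activity states.
``four_state``
    Each of apo, .RimA, .cdG and .cdG.RimA is its own activity state.
``rimb_extended``
    four_state plus a RimK.RimB complex carrying a further activity state
    (RimB binding to apo RimK; the ligation literature gives no cycle
    linking RimB with cdG/RimA, so none is assumed).
``trigger``
    four_state plus an inhibitory RimA.cdG complex (Kd = 5 uM by default)
    that sequesters RimA away from RimK.  The switch of RimA from RimK
    activator to cdG sink requires the protease RimB, so the sequestration
    reaction is only included when RimB is present at non-zero
    concentration; with RimB absent the variant reduces exactly to
    four_state.  ``arrangement`` selects how the inhibitory complex engages
    RimK: ``"sequester"`` (RimA.cdG never binds RimK) or ``"ternary"``
    (RimA.cdG can also sit on RimK as an inactive RimK.RimA.cdG_A complex).

Thermodynamic constraints are imposed at construction: in every closed
binding cycle one Kd is derived from the others (via the ``cooperativity``
factor), never free, so built networks always pass
:func:`rimsys.network.check_thermodynamic_consistency`.
"""

from __future__ import annotations

from typing import Mapping

from .network import BindingReaction, ReactionNetwork, Species
from .states import KineticState, KineticStateSet

__all__ = [
    "VARIANTS",
    "DEFAULT_KD",
    "DEFAULT_CONCENTRATIONS",
    "ConfigurationError",
    "make_model",
    "free_kd_names",
]

VARIANTS = ("two_state", "four_state", "rimb_extended", "trigger")

#: default dissociation constants, uM. cdG binding to RimK is 1 uM (measured);
#: RimA binding to RimK defaults to the four-state best estimate of 0.2 uM;
#: cdG binding to RimA (trigger variant) is 5 uM; RimB uses the generic 1 uM
#: starting value.
DEFAULT_KD: Mapping[str, float] = {
    "cdg": 1.0,
    "rima": 0.2,
    "rimb": 1.0,
    "rima_cdg": 5.0,
}

#: default total concentrations, uM
DEFAULT_CONCENTRATIONS: Mapping[str, float] = {
    "RimK": 1.0,
    "RimA": 1.0,
    "RimB": 1.0,
    "cdG": 1.0,
}


class ConfigurationError(ValueError):
    """Override of a parameter that the chosen variant does not expose."""


def free_kd_names(variant: str) -> tuple[str, ...]:
    """The free dissociation constants of a variant (cycle Kds are derived)."""
    if variant in ("two_state", "four_state"):
        return ("cdg", "rima")
    if variant == "rimb_extended":
        return ("cdg", "rima", "rimb")
    if variant == "trigger":
        return ("cdg", "rima", "rima_cdg")
    raise ConfigurationError(f"unknown variant {variant!r}")


def _state_roster(variant: str, arrangement: str) -> KineticStateSet:
    square = {
        "apo": ("RimK",),
        "cdg": ("RimK.cdG",),
        "rima": ("RimK.RimA",),
        "cdg_rima": ("RimK.RimA.cdG",),
    }
    if variant == "two_state":
        members = {
            "basal": ("RimK",),
            "active": ("RimK.cdG", "RimK.RimA", "RimK.RimA.cdG"),
        }
    elif variant == "four_state":
        members = dict(square)
    elif variant == "rimb_extended":
        members = dict(square)
        members["rimb"] = ("RimK.RimB",)
    elif variant == "trigger":
        members = dict(square)
        if arrangement == "ternary":
            # the RimA.cdG-occluded ternary complex is catalytically basal
            members["apo"] = ("RimK", "RimK.RimA.cdG_A")
    else:  # pragma: no cover - guarded upstream
        raise ConfigurationError(f"unknown variant {variant!r}")
    states = tuple(KineticState(label) for label in members)
    return KineticStateSet(states, members)


def make_model(
    variant: str,
    *,
    concentrations: Mapping[str, float] | None = None,
    kd: Mapping[str, float] | None = None,
    cooperativity: float = 1.0,
    arrangement: str = "sequester",
) -> tuple[ReactionNetwork, KineticStateSet]:
    """Build a variant's reaction network and its activity-state roster.

    Parameters
    ----------
    variant : str
        One of :data:`VARIANTS`.
    concentrations : mapping, optional
        Total concentrations in uM for ``RimK``, ``RimA``, ``cdG`` (and
        ``RimB`` where the variant includes it); defaults are 1 uM each.
    kd : mapping, optional
        Overrides for the variant's free Kds (see :func:`free_kd_names`).
    cooperativity : float
        Factor applied to the second binding event in the RimK square
        (1.0 = independent sites); the fourth Kd of the cycle is always
        derived so the cycle closes exactly.
    arrangement : str
        Trigger-variant complex arrangement, ``"sequester"`` or
        ``"ternary"``; ignored by other variants.

    Raises
    ------
    ConfigurationError
        For an unknown variant, an override of a Kd or species the variant
        does not contain, or an unknown arrangement.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    if arrangement not in ("sequester", "ternary"):
        raise ConfigurationError(f"unknown arrangement {arrangement!r}")

    allowed_kd = set(free_kd_names(variant))
    kds = dict(DEFAULT_KD)
    for key, value in (kd or {}).items():
        if key not in allowed_kd:
            raise ConfigurationError(
                f"Kd override {key!r} not available in variant {variant!r}"
            )
        kds[key] = float(value)

    has_rimb = variant in ("rimb_extended", "trigger")
    species_names = ["RimK", "RimA", "cdG"] + (["RimB"] if has_rimb else [])
    conc = {
        name: DEFAULT_CONCENTRATIONS[name] for name in species_names
    }
    for key, value in (concentrations or {}).items():
        if key not in conc:
            raise ConfigurationError(
                f"species {key!r} not present in variant {variant!r}"
            )
        conc[key] = float(value)

    alpha = float(cooperativity)
    if alpha <= 0:
        raise ConfigurationError("cooperativity must be > 0")

    species = [Species(name, conc[name]) for name in species_names]
    species += [
        Species("RimK.cdG"),
        Species("RimK.RimA"),
        Species("RimK.RimA.cdG"),
    ]
    reactions = [
        BindingReaction("RimK", "cdG", "RimK.cdG", kds["cdg"]),
        BindingReaction("RimK", "RimA", "RimK.RimA", kds["rima"]),
        BindingReaction("RimK.RimA", "cdG", "RimK.RimA.cdG", alpha * kds["cdg"]),
        # cycle closure: Kd(RimA | RimK.cdG) is derived, not free
        BindingReaction("RimK.cdG", "RimA", "RimK.RimA.cdG", alpha * kds["rima"]),
    ]

    if variant == "rimb_extended":
        species.append(Species("RimK.RimB"))
        reactions.append(
            BindingReaction("RimK", "RimB", "RimK.RimB", kds["rimb"])
        )
    elif variant == "trigger" and conc["RimB"] > 0:
        species.append(Species("RimA.cdG"))
        reactions.append(
            BindingReaction("RimA", "cdG", "RimA.cdG", kds["rima_cdg"])
        )
        if arrangement == "ternary":
            species.append(Species("RimK.RimA.cdG_A"))
            reactions.append(
                BindingReaction(
                    "RimK.RimA", "cdG", "RimK.RimA.cdG_A", kds["rima_cdg"]
                )
            )
            # derived by the RimK/RimA.cdG cycle: binding cdG on RimA does
            # not change RimA's affinity for RimK
            reactions.append(
                BindingReaction(
                    "RimA.cdG", "RimK", "RimK.RimA.cdG_A", kds["rima"]
                )
            )

    network = ReactionNetwork(species, reactions)
    stateset = _state_roster(variant, arrangement)
    return network, stateset
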