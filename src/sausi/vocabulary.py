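"""Closed registry of scorable behaviors.

Every event entering an :class:`~sausi.io_sessions.EventLog` must carry a
label from this registry.  Labels are matched case-insensitively and
canonicalised to the spellings below.  All behaviors reference the
experimental mouse except ``Conspecific Sniff``, which is the stimulus
animal's sniffing of the experimental mouse.
"""

from __future__ import annotations

from typing import Final

STATE: Final = "state"
POINT: Final = "point"

EXPERIMENTAL: Final = "experimental"
CONSPECIFIC: Final = "conspecific"

#: behavior -> (event_type, allowed actor)
BEHAVIOR_REGISTRY: Final[dict[str, tuple[str, str]]] = {
    "Face Sniff": (STATE, EXPERIMENTAL),
    "Body Sniff": (STATE, EXPERIMENTAL),
    "Anogenital Sniff": (STATE, EXPERIMENTAL),
    "Tail Sniff": (STATE, EXPERIMENTAL),
    "Conspecific Sniff": (POINT, CONSPECIFIC),
    "Tunnel Shelter": (STATE, EXPERIMENTAL),
    "Reverse in Tunnel": (STATE, EXPERIMENTAL),
    "Social Freeze": (STATE, EXPERIMENTAL),
    "Social Reactivity": (POINT, EXPERIMENTAL),
    "Social Initiation": (POINT, EXPERIMENTAL),
    "Groom": (STATE, EXPERIMENTAL),
    "Non-social Freeze": (STATE, EXPERIMENTAL),
    "Aggression": (STATE, EXPERIMENTAL),
    "Jump": (POINT, EXPERIMENTAL),
}

#: the four sniff subtypes whose durations sum to the "All Sniff" composite
SNIFF_SUBTYPES: Final = (
    "Face Sniff",
    "Body Sniff",
    "Anogenital Sniff",
    "Tail Sniff",
)

ALL_SNIFF: Final = "All Sniff"

_CANONICAL = {name.lower(): name for name in BEHAVIOR_REGISTRY}


class VocabularyError(ValueError):
    """An event carried a behavior label outside the closed registry."""


def canonical_behavior(label: str) -> str:
    """Return the canonical spelling of *label* or raise :class:`VocabularyError`."""
    try:
        return _CANONICAL[label.strip().lower()]
    except KeyError:
        raise VocabularyError(
            f"unknown behavior label {label!r}; known labels: "
            f"{sorted(BEHAVIOR_REGISTRY)}"
        ) from None


def event_type_of(label: str) -> str:
    """``'state'`` or ``'point'`` for a canonical or loosely spelled label."""
    return BEHAVIOR_REGISTRY[canonical_behavior(label)][0]


def allowed_actor(label: str) -> str:
    return BEHAVIOR_REGISTRY[canonical_behavior(label)][1]
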