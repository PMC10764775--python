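"""Mapping between anatomical roles and landmark names.

The pipeline addresses landmarks by *role* (e.g. ``lower_jaw_tip``); a
:class:`LandmarkRegistry` maps each role to the column name used in a
particular digitization. The default names are single letters matching a
common convention for lateral-view feeding videos: jaw tips C (upper) and
F (lower), neurocranium tip A, craniovertebral fulcrum K, dorsal
neurocranium/body reference L, jaw joint E, intramandibular joint P,
pectoral girdle J, pelvis I, posterior ventral point O, pectoral-fin base
G with leading edge H and trailing edge M, and two benthos points B1, B2.
An optional ``algae_tip`` landmark tracks the prey item.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

REQUIRED_ROLES: Tuple[str, ...] = (
    "upper_jaw_tip",
    "lower_jaw_tip",
    "neurocranium_anterior",
    "craniovertebral_fulcrum",
    "neurocranium_reference",
    "jaw_joint_ventral",
    "imj",
    "pectoral_girdle",
    "pelvis",
    "ventral_posterior",
    "fin_base",
    "fin_leading_edge",
    "fin_trailing_edge",
    "benthos_1",
    "benthos_2",
)

OPTIONAL_ROLES: Tuple[str, ...] = ("algae_tip",)

DEFAULT_NAMES: Dict[str, str] = {
    "upper_jaw_tip": "C",
    "lower_jaw_tip": "F",
    "neurocranium_anterior": "A",
    "craniovertebral_fulcrum": "K",
    "neurocranium_reference": "L",
    "jaw_joint_ventral": "E",
    "imj": "P",
    "pectoral_girdle": "J",
    "pelvis": "I",
    "ventral_posterior": "O",
    "fin_base": "G",
    "fin_leading_edge": "H",
    "fin_trailing_edge": "M",
    "benthos_1": "B1",
    "benthos_2": "B2",
    "algae_tip": "ALG",
}


@dataclass(frozen=True)
class LandmarkRegistry:
    """Role -> landmark-name map.

    Every required role must map to a distinct name. The optional
    ``algae_tip`` role may be omitted (suction scoring then returns
    an "unknown" tri-state).
    """

    names: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_NAMES))

    def __post_init__(self) -> None:
        missing = [r for r in REQUIRED_ROLES if r not in self.names]
        if missing:
            raise ValueError(f"registry missing required roles: {missing}")
        vals = list(self.names.values())
        if len(set(vals)) != len(vals):
            raise ValueError("registry maps two roles to the same landmark name")

    def name(self, role: str) -> str:
        """Landmark name for a role; KeyError if the role is unknown."""
        return self.names[role]

    @property
    def required_names(self) -> Tuple[str, ...]:
        return tuple(self.names[r] for r in REQUIRED_ROLES)

    @property
    def all_names(self) -> Tuple[str, ...]:
        req = list(self.required_names)
        for r in OPTIONAL_ROLES:
            if r in self.names:
                req.append(self.names[r])
        return tuple(req)

    def has(self, role: str) -> bool:
        return role in self.names


DEFAULT_REGISTRY = LandmarkRegistry()
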