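"""Free-energy landscape containers: stationary points with stereochemical labels.

A landscape is the bridge between quantum-chemistry output (relative Gibbs
energies of intermediates, reactive complexes and saddle points) and the
executable reaction network. Energies are relative to a single zero-reference
point, conventionally the separated enamine intermediate plus free
electrophile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .thermokinetics import T_STANDARD

ROLES = ("intermediate", "transition_state", "reactive_complex")
CYCLES = ("A", "B")
CONFORMERS = ("distal", "proximal", "n/a")
REACTION_TYPES = ("aldol", "michael")

FACE_PAIRS = ("Si,Si", "Si,Re", "Re,Si", "Re,Re")
PRODUCT_CONFIGS = ("2R,1'S", "2S,1'R", "2R,1'R", "2S,1'S")

#: Enantiomer partner of each product configuration.
MIRROR_CONFIG = {
    "2R,1'S": "2S,1'R",
    "2S,1'R": "2R,1'S",
    "2R,1'R": "2S,1'S",
    "2S,1'S": "2R,1'R",
}

#: Enantiomer partner of each prochiral-face combination.
MIRROR_FACES = {
    "Si,Si": "Re,Re",
    "Re,Re": "Si,Si",
    "Si,Re": "Re,Si",
    "Re,Si": "Si,Re",
}

# The (2R,1'S)/(2S,1'R) enantiomer pair is the major diastereomer in both
# reaction families studied: it is the *anti* aldol adduct and the *syn*
# Michael adduct. The other pair forms the minor diastereomer.
_MAJOR_PAIR = frozenset({"2R,1'S", "2S,1'R"})
DIASTEREO_CLASS = {
    "aldol": {c: ("anti" if c in _MAJOR_PAIR else "syn") for c in PRODUCT_CONFIGS},
    "michael": {c: ("syn" if c in _MAJOR_PAIR else "anti") for c in PRODUCT_CONFIGS},
}


class LandscapeError(ValueError):
    """Malformed landscape: bad labels, duplicate names, missing reference."""


@dataclass(frozen=True)
class StereoLabel:
    """Stereochemical identity of a C-C bond-forming channel.

    ``face_pair`` is the (enamine, electrophile) prochiral face combination;
    ``topology`` the Seebach-Prelog like/unlike label; ``product_config`` the
    absolute configuration of the adduct the channel produces.
    """

    face_pair: str
    product_config: str
    topology: Optional[str] = None

    def __post_init__(self) -> None:
        if self.face_pair not in FACE_PAIRS:
            raise LandscapeError(f"unknown face pair {self.face_pair!r}")
        if self.product_config not in PRODUCT_CONFIGS:
            raise LandscapeError(f"unknown product configuration {self.product_config!r}")
        if self.topology is not None and self.topology not in ("lk", "ul"):
            raise LandscapeError(f"topology must be 'lk' or 'ul', got {self.topology!r}")

    def diastereo_class(self, reaction_type: str) -> str:
        """'anti' or 'syn' for the given reaction family."""
        return DIASTEREO_CLASS[reaction_type][self.product_config]

    def mirrored(self) -> "StereoLabel":
        """The enantiomeric channel: faces and product configuration swapped."""
        return StereoLabel(
            face_pair=MIRROR_FACES[self.face_pair],
            product_config=MIRROR_CONFIG[self.product_config],
            topology=self.topology,
        )


@dataclass(frozen=True)
class StationaryPoint:
    """Named stationary point of the free-energy surface.

    ``g_rel`` is the Gibbs energy in kcal/mol relative to the landscape's
    zero reference. Transition states must carry a :class:`StereoLabel`;
    intermediates and reactive complexes may omit it.
    """

    name: str
    role: str
    g_rel: float
    cycle: str = "A"
    conformer: str = "n/a"
    stereo: Optional[StereoLabel] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LandscapeError(f"{self.name}: unknown role {self.role!r}")
        if self.cycle not in CYCLES:
            raise LandscapeError(f"{self.name}: unknown cycle {self.cycle!r}")
        if self.conformer not in CONFORMERS:
            raise LandscapeError(f"{self.name}: unknown conformer {self.conformer!r}")
        if not math.isfinite(float(self.g_rel)):
            raise LandscapeError(f"{self.name}: g_rel must be finite")
        if self.role == "transition_state" and self.stereo is None:
            raise LandscapeError(f"{self.name}: transition states require a stereo label")


@dataclass
class FreeEnergyLandscape:
    """A validated set of stationary points for one reaction family."""

    reaction_type: str
    points: list[StationaryPoint] = field(default_factory=list)
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        if self.reaction_type not in REACTION_TYPES:
            raise LandscapeError(f"unknown reaction type {self.reaction_type!r}")
        names = [p.name for p in self.points]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LandscapeError(f"duplicate stationary-point names: {sorted(dupes)}")
        if self.points and not any(p.role == "transition_state" for p in self.points):
            raise LandscapeError("landscape contains no transition state")

    def by_role(self, role: str) -> list[StationaryPoint]:
        return [p for p in self.points if p.role == role]

    def transition_states(self) -> list[StationaryPoint]:
        return self.by_role("transition_state")

    def mirrored(self) -> "FreeEnergyLandscape":
        """Mirror-image landscape: every stereo label swapped, energies kept.

        Building and simulating the mirrored landscape must negate the
        enantiomeric excess exactly while leaving dr and rates unchanged.
        """
        pts = [
            StationaryPoint(
                name=p.name,
                role=p.role,
                g_rel=p.g_rel,
                cycle=p.cycle,
                conformer=p.conformer,
                stereo=None if p.stereo is None else p.stereo.mirrored(),
            )
            for p in self.points
        ]
        return FreeEnergyLandscape(self.reaction_type, pts, self.temperature)
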