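"""Additive enantiocontrol model for dimeric two-active-site catalysts.

Each pyrrolidine unit of a dimer independently directs the stereochemistry it
would impose as a monomer: an exo unit and an endo unit each have a
characteristic monomer ee (for their L configuration), and the D enantiomer
of a unit directs exactly the mirror-image product (negated ee). A dimer's
predicted ee is the weighted average of its two units' (mirrored) monomer
ees, the weights reflecting the relative throughput of the two catalytic
cycles (50:50 by default, refinable from a microkinetic A:B partition).

N-methylated units cannot form an enamine; their only role is electrophile
activation, so all enantiocontrol transfers to the remaining NH unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


class NoActiveSiteError(ValueError):
    """Both units are N-methylated: the dimer has no enamine-forming site."""


@dataclass(frozen=True)
class CatalystUnitDescriptor:
    """One pyrrolidine unit of a dimer.

    ``monomer_ee`` is the ee (percent, signed) the unit's L/NH monomer gives;
    it is meaningful only for NH units.
    """

    diastereo: str  # "exo" or "endo"
    config: str  # "L" or "D"
    nitrogen: str = "NH"  # "NH" or "NMe"
    monomer_ee: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diastereo not in ("exo", "endo"):
            raise ValueError(f"diastereo must be exo/endo, got {self.diastereo!r}")
        if self.config not in ("L", "D"):
            raise ValueError(f"config must be L/D, got {self.config!r}")
        if self.nitrogen not in ("NH", "NMe"):
            raise ValueError(f"nitrogen must be NH/NMe, got {self.nitrogen!r}")
        if self.monomer_ee is not None and abs(self.monomer_ee) > 100:
            raise ValueError("monomer ee must lie in [-100, 100]")

    @property
    def active(self) -> bool:
        return self.nitrogen == "NH"

    def directed_ee(self) -> float:
        """The ee this unit directs in the dimer: monomer ee, L/D-mirrored."""
        if not self.active:
            raise ValueError("NMe unit forms no enamine and directs no ee")
        if self.monomer_ee is None:
            raise ValueError("NH unit lacks a monomer ee value")
        return self.monomer_ee if self.config == "L" else mirror_ee(self.monomer_ee)


@dataclass(frozen=True)
class DimerDescriptor:
    """A dimeric catalyst: two units plus cycle weights summing to 1."""

    unit_a: CatalystUnitDescriptor
    unit_b: CatalystUnitDescriptor
    weights: tuple = (0.5, 0.5)

    def __post_init__(self) -> None:
        w_a, w_b = self.weights
        if w_a < 0 or w_b < 0 or abs(w_a + w_b - 1.0) > 1e-9:
            raise ValueError(f"weights must be non-negative and sum to 1, got {self.weights}")


def mirror_ee(ee: float) -> float:
    """ee of the enantiomeric outcome: a D unit directs -1 times its L form."""
    if abs(ee) > 100:
        raise ValueError("ee must lie in [-100, 100]")
    return -ee


def additive_ee(dimer: DimerDescriptor) -> float:
    """Predicted dimer ee as the weighted mean of the units' directed ees.

    If one unit is N-methylated its weight is reassigned to the NH unit
    (prediction = that monomer's directed ee). Raises
    :class:`NoActiveSiteError` if neither unit can form an enamine.
    """
    a, b = dimer.unit_a, dimer.unit_b
    if not a.active and not b.active:
        raise NoActiveSiteError("both units N-methylated: no enamine-forming site")
    if not b.active:
        return a.directed_ee()
    if not a.active:
        return b.directed_ee()
    w_a, w_b = dimer.weights
    return w_a * a.directed_ee() + w_b * b.directed_ee()


def classify_matching(dimer: DimerDescriptor) -> str:
    """'matched' if both units direct the same product enantiomer, else 'mismatched'.

    Defined for dimers with two NH units; agreement is judged on the signs of
    the two directed ees.
    """
    a, b = dimer.unit_a, dimer.unit_b
    if not (a.active and b.active):
        raise ValueError("matching classification needs two NH units")
    ee_a, ee_b = a.directed_ee(), b.directed_ee()
    return "matched" if ee_a * ee_b > 0 else "mismatched"
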