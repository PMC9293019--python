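"""Build executable mass-action networks from dual-cycle free-energy landscapes.

A dimeric catalyst with two secondary-amine active sites supports two
independent catalytic cycles (A and B), one per pyrrolidine unit. Each cycle
runs: acid activation of the catalyst, enamine formation with the ketone
(present in large excess, treated as a buffered reservoir), association with
the electrophile into a reactive complex, the irreversible stereo-determining
C-C bond formation, and hydrolytic release of the adduct regenerating the
free catalyst.

Only the C-C step takes its rate from the quantum-chemical landscape (Eyring
rate on the saddle-point energy relative to its reactive complex). The
off-landscape steps (protonation, enamine formation, conformer flips,
complex association) are fast lumped steps whose reverse rates are set by
detailed balance against the landscape energies, so that in the
fast-pre-equilibrium limit the network reproduces the analytic
Curtin-Hammett selectivity exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .landscape import (
    FreeEnergyLandscape,
    LandscapeError,
    StationaryPoint,
    StereoLabel,
)
from .thermokinetics import R_KCAL, eyring_rate

TAG_NAMES = ("catalyst", "ketone", "electrophile", "acid_proton")


@dataclass(frozen=True)
class Species:
    """A chemical species with integer composition tags for conservation checks.

    ``buffered`` marks reservoir species (the excess ketone) whose
    concentration is clamped during integration; their activity enters rate
    laws but they are not depleted.
    """

    name: str
    tags: dict = field(default_factory=dict)
    buffered: bool = False

    def tag(self, key: str) -> int:
        return int(self.tags.get(key, 0))


@dataclass(frozen=True)
class Reaction:
    """An elementary (possibly reversible) mass-action reaction.

    ``reactants``/``products`` map species names to stoichiometric counts.
    ``k_rev = 0`` marks an irreversible step. ``kind`` is one of
    protonation / enamine / conformer / association / cc / hydrolysis.
    """

    reactants: dict
    products: dict
    k_fwd: float
    k_rev: float = 0.0
    kind: str = ""
    cycle: Optional[str] = None
    stereo: Optional[StereoLabel] = None

    def __post_init__(self) -> None:
        if self.k_fwd < 0 or self.k_rev < 0:
            raise ValueError(f"negative rate constant in {self.kind} reaction")


@dataclass(frozen=True)
class Channel:
    """One stereochemical route: which cycle, which stereo label, which product."""

    cycle: str
    stereo: StereoLabel
    ts_name: str
    product_species: str
    cc_reaction_index: int


@dataclass
class ReactionNetwork:
    """Species, reactions, channels and initial concentrations (M)."""

    reaction_type: str
    species: dict
    reactions: list
    channels: list
    initial: dict
    temperature: float

    def species_names(self) -> list[str]:
        return list(self.species)

    def mirrored(self) -> "ReactionNetwork":
        """Not implemented directly; mirror the landscape and rebuild instead."""
        raise NotImplementedError("mirror the FreeEnergyLandscape and rebuild")


@dataclass
class NetworkOptions:
    """Lumped rate constants and initial conditions for off-landscape steps.

    Rates are first-order s^-1 (association: M^-1 s^-1). Defaults are fast
    relative to typical C-C rates so the Curtin-Hammett regime holds; the
    conformer flip is fastest of all, and can be lowered toward the
    frozen-conformer limit.
    """

    k_protonation: float = 1.0e3
    k_protonation_b: Optional[float] = None  # None -> same as cycle A (equal basicities)
    k_enamine: float = 1.0e3
    k_hydrolysis: float = 1.0e3
    k_conformer: float = 1.0e6
    k_association: float = 1.0e3
    g_catalyst: float = 0.0  # energy of (activated catalyst + ketone) vs landscape zero
    conc_catalyst: float = 0.03
    conc_electrophile: float = 0.10
    reversible_enamine: bool = True


class NetworkConstructionError(LandscapeError):
    """Landscape cannot be turned into a well-formed network."""


def _keq(dG: float, T: float) -> float:
    """Equilibrium constant for a step with reaction free energy dG (kcal/mol)."""
    return math.exp(-dG / (R_KCAL * T))


def build_dual_cycle_network(
    landscape: FreeEnergyLandscape,
    options: Optional[NetworkOptions] = None,
) -> ReactionNetwork:
    """Construct the mass-action network realizing a dual-cycle landscape.

    Per cycle present in the landscape: reversible catalyst protonation,
    reversible enamine formation per conformer with an intermediate point,
    reversible conformer interconversion, reversible electrophile association
    per reactive-complex point, one irreversible C-C reaction per transition
    state (rate = Eyring on g_TS - g_RC), and irreversible hydrolysis
    releasing a per-channel product and the free catalyst.

    Raises :class:`NetworkConstructionError` if a transition state lacks a
    preceding reactive complex or an enamine intermediate in its cycle and
    conformer.
    """
    opts = options or NetworkOptions()
    T = landscape.temperature
    rxn_type = landscape.reaction_type

    tss = landscape.transition_states()
    if not tss:
        raise NetworkConstructionError("landscape has no transition states")
    cycles = sorted({p.cycle for p in tss})

    enamines: dict = {}  # (cycle, conformer) -> StationaryPoint
    complexes: dict = {}  # (cycle, conformer) -> list[StationaryPoint]
    for p in landscape.points:
        key = (p.cycle, p.conformer)
        if p.role == "intermediate":
            if key in enamines:
                raise NetworkConstructionError(
                    f"multiple enamine intermediates for cycle {p.cycle}, "
                    f"conformer {p.conformer}"
                )
            enamines[key] = p
        elif p.role == "reactive_complex":
            complexes.setdefault(key, []).append(p)

    species: dict = {}
    reactions: list = []
    channels: list = []

    def add_species(name, tags, buffered=False):
        if name not in species:
            species[name] = Species(name, dict(tags), buffered)
        return name

    cat = add_species("cat", {"catalyst": 1})
    ket = add_species("ketone", {"ketone": 1}, buffered=True)
    acid = add_species("acid", {"acid_proton": 1}, buffered=True)
    elec = add_species("electrophile", {"electrophile": 1})

    cat_tags_h = {"catalyst": 1, "acid_proton": 1}
    en_tags = {"catalyst": 1, "acid_proton": 1, "ketone": 1}
    rc_tags = {"catalyst": 1, "acid_proton": 1, "ketone": 1, "electrophile": 1}

    for cyc in cycles:
        k_prot = opts.k_protonation if cyc == "A" or opts.k_protonation_b is None else opts.k_protonation_b
        cath = add_species(f"catH_{cyc}", cat_tags_h)
        # equal forward/reverse: activation is thermoneutral bookkeeping;
        # the acid is a clamped reservoir at unit activity
        reactions.append(
            Reaction({cat: 1, acid: 1}, {cath: 1}, k_fwd=k_prot, k_rev=k_prot,
                     kind="protonation", cycle=cyc)
        )

        cyc_conformers = sorted({c for (cy, c) in enamines if cy == cyc})
        if not cyc_conformers:
            raise NetworkConstructionError(f"cycle {cyc} has no enamine intermediate")

        en_names = {}
        for conf in cyc_conformers:
            pt = enamines[(cyc, conf)]
            en = add_species(f"EN_{cyc}_{conf}", en_tags)
            en_names[conf] = (en, pt)
            # CatH + ketone(reservoir, activity 1) <-> enamine; reverse from
            # detailed balance vs. g_rel(enamine) relative to g_catalyst.
            keq = _keq(pt.g_rel - opts.g_catalyst, T)
            k_rev = opts.k_enamine / keq if opts.reversible_enamine else 0.0
            reactions.append(
                Reaction({cath: 1, ket: 1}, {en: 1}, k_fwd=opts.k_enamine,
                         k_rev=k_rev, kind="enamine", cycle=cyc)
            )

        # conformer interconversion (chain over sorted conformers suffices)
        for a, b in zip(cyc_conformers, cyc_conformers[1:]):
            (en_a, pt_a), (en_b, pt_b) = en_names[a], en_names[b]
            keq = _keq(pt_b.g_rel - pt_a.g_rel, T)
            reactions.append(
                Reaction({en_a: 1}, {en_b: 1}, k_fwd=opts.k_conformer,
                         k_rev=opts.k_conformer / keq, kind="conformer", cycle=cyc)
            )

        # electrophile association into reactive complexes
        rc_names = {}
        for conf in cyc_conformers:
            en, en_pt = en_names[conf]
            for rc_pt in complexes.get((cyc, conf), []):
                rc = add_species(f"RC_{rc_pt.name}", rc_tags)
                rc_names[rc_pt.name] = (rc, rc_pt)
                keq = _keq(rc_pt.g_rel - en_pt.g_rel, T)  # E at reference
                reactions.append(
                    Reaction({en: 1, elec: 1}, {rc: 1}, k_fwd=opts.k_association,
                             k_rev=opts.k_association / keq, kind="association",
                             cycle=cyc)
                )

        # one irreversible C-C step per transition state
        for ts in (p for p in tss if p.cycle == cyc):
            precursors = complexes.get((ts.cycle, ts.conformer), [])
            if not precursors:
                raise NetworkConstructionError(
                    f"transition state {ts.name} has no reactive complex in "
                    f"cycle {ts.cycle}, conformer {ts.conformer}"
                )
            matched = [p for p in precursors if p.stereo == ts.stereo]
            if not matched:
                matched = [p for p in precursors if p.stereo is None]
            if len(matched) != 1:
                raise NetworkConstructionError(
                    f"transition state {ts.name}: ambiguous precursor complex"
                )
            rc, rc_pt = rc_names[matched[0].name]
            barrier = ts.g_rel - rc_pt.g_rel
            if barrier < 0:
                raise NetworkConstructionError(
                    f"transition state {ts.name} lies below its reactive complex"
                )
            lbl = ts.stereo
            inter = add_species(f"INT_{ts.name}", rc_tags)
            prod = add_species(
                f"P_{cyc}_{lbl.face_pair.replace(',', '')}_{lbl.product_config.replace(',', '').replace(chr(39), '')}",
                {"ketone": 1, "electrophile": 1, "acid_proton": 1},
            )
            idx = len(reactions)
            reactions.append(
                Reaction({rc: 1}, {inter: 1}, k_fwd=eyring_rate(barrier, T),
                         k_rev=0.0, kind="cc", cycle=cyc, stereo=lbl)
            )
            reactions.append(
                Reaction({inter: 1}, {cat: 1, prod: 1}, k_fwd=opts.k_hydrolysis,
                         k_rev=0.0, kind="hydrolysis", cycle=cyc, stereo=lbl)
            )
            channels.append(Channel(cyc, lbl, ts.name, prod, idx))

    initial = {name: 0.0 for name in species}
    initial["cat"] = opts.conc_catalyst
    initial["electrophile"] = opts.conc_electrophile
    initial["ketone"] = 1.0  # reservoir activities; clamped
    initial["acid"] = 1.0

    return ReactionNetwork(
        reaction_type=rxn_type,
        species=species,
        reactions=reactions,
        channels=channels,
        initial=initial,
        temperature=T,
    )


@dataclass
class NetworkDiagnostics:
    """Outcome of :func:`validate_network`."""

    imbalanced: list
    unreachable: list
    dead_end_channels: list

    @property
    def passed(self) -> bool:
        return not (self.imbalanced or self.unreachable or self.dead_end_channels)


def validate_network(net: ReactionNetwork) -> NetworkDiagnostics:
    """Check composition-tag balance, reachability, and channel exit paths."""
    imbalanced = []
    for i, rxn in enumerate(net.reactions):
        for tag in TAG_NAMES:
            lhs = sum(n * net.species[s].tag(tag) for s, n in rxn.reactants.items())
            rhs = sum(n * net.species[s].tag(tag) for s, n in rxn.products.items())
            if lhs != rhs:
                imbalanced.append((i, rxn.kind, tag, lhs, rhs))

    touched = set()
    for rxn in net.reactions:
        touched.update(rxn.reactants)
        touched.update(rxn.products)
    unreachable = sorted(set(net.species) - touched)

    dead_end = []
    produced = {s for rxn in net.reactions for s in rxn.products}
    for ch in net.channels:
        if ch.product_species not in produced:
            dead_end.append(ch.ts_name)

    return NetworkDiagnostics(imbalanced, unreachable, dead_end)
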