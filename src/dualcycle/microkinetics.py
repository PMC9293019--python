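"""Stiff mass-action integration of catalytic networks and selectivity analysis.

The integrator propagates the network ODEs together with one auxiliary state
per stereochannel holding the time-integrated C-C flux. Channel attribution
through flux integrals (rather than terminal product pools) keeps the A and B
cycle contributions separable even if channels share products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .landscape import DIASTEREO_CLASS, MIRROR_CONFIG
from .network import ReactionNetwork, validate_network


class SimulationError(RuntimeError):
    """Integration failed; carries the last valid state if available."""

    def __init__(self, message: str, last_state: Optional[np.ndarray] = None):
        super().__init__(message)
        self.last_state = last_state


class SelectivityError(ValueError):
    """Selectivity is undefined (no product formed)."""


@dataclass
class Trajectory:
    """Integrated concentrations (M) on a time grid (s), plus channel fluxes."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_species, n_times)
    species_names: list
    channel_fluxes: np.ndarray  # shape (n_channels, n_times), integrated M

    def final(self, name: str) -> float:
        return float(self.concentrations[self.species_names.index(name), -1])


@dataclass
class SelectivityResult:
    """Headline stereochemical outputs of a simulated catalytic run.

    ``dr`` maps the two diastereomer classes to percentages summing to 100;
    ``ee`` is the enantiomeric excess (percent, signed) of the major
    diastereomer pair, positive when (2R,1'S) dominates; ``cycle_partition``
    gives the A/B flux split in percent.
    """

    reaction_type: str
    channel_yields: dict  # (cycle, product_config, face_pair) -> M
    dr: dict  # class name -> percent
    ee: float
    cycle_partition: dict  # cycle -> percent
    conversion: float  # fraction of electrophile consumed

    @property
    def major_class(self) -> str:
        return "anti" if self.reaction_type == "aldol" else "syn"


def assemble_rate_function(net: ReactionNetwork) -> Callable[[float, np.ndarray], np.ndarray]:
    """Mass-action right-hand side d[y]/dt for a validated network.

    Refuses networks that fail :func:`dualcycle.network.validate_network`.
    The returned callable is pure: it depends only on (t, y).
    """
    diag = validate_network(net)
    if not diag.passed:
        raise ValueError(f"network failed validation: {diag}")

    names = net.species_names()
    index = {n: i for i, n in enumerate(names)}
    n_sp = len(names)
    clamped = np.array([net.species[n].buffered for n in names])

    # split reversible reactions into irreversible forward/reverse legs
    legs = []  # (k, reactant index/stoich arrays, net stoich vector)
    for rxn in net.reactions:
        for reactants, products, k in (
            (rxn.reactants, rxn.products, rxn.k_fwd),
            (rxn.products, rxn.reactants, rxn.k_rev),
        ):
            if k == 0.0:
                continue
            stoich = np.zeros(n_sp)
            for s, nu in reactants.items():
                stoich[index[s]] -= nu
            for s, nu in products.items():
                stoich[index[s]] += nu
            stoich[clamped] = 0.0
            r_idx = np.array([index[s] for s in reactants for _ in range(reactants[s])],
                             dtype=int)
            legs.append((float(k), r_idx, stoich))

    if not legs:
        return lambda t, y: np.zeros(n_sp)

    ks = np.array([leg[0] for leg in legs])
    stoich_mat = np.stack([leg[2] for leg in legs], axis=1)  # (n_sp, n_legs)
    r_indices = [leg[1] for leg in legs]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        rates = ks.copy()
        for j, ridx in enumerate(r_indices):
            for i in ridx:
                rates[j] *= y[i]
        return stoich_mat @ rates

    return rhs


def _cc_rate_functions(net: ReactionNetwork):
    """Per-channel instantaneous C-C rate evaluators (for flux integration)."""
    names = net.species_names()
    index = {n: i for i, n in enumerate(names)}
    chans = []
    for ch in net.channels:
        rxn = net.reactions[ch.cc_reaction_index]
        ridx = np.array([index[s] for s in rxn.reactants for _ in range(rxn.reactants[s])],
                        dtype=int)
        chans.append((float(rxn.k_fwd), ridx))
    return chans


def simulate(
    net: ReactionNetwork,
    t_end: float,
    rtol: float = 1e-10,
    atol: float = 1e-13,
    n_points: int = 200,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network from its initial condition up to ``t_end`` seconds.

    Uses a stiff-capable implicit method. Channel flux integrals are carried
    as extra ODE states so attribution is exact to integrator tolerance.
    """
    if not (math.isfinite(t_end) and t_end > 0):
        raise ValueError(f"t_end must be finite and positive, got {t_end!r}")

    rhs = assemble_rate_function(net)
    names = net.species_names()
    n_sp = len(names)
    y0 = np.array([net.initial.get(n, 0.0) for n in names])
    cc = _cc_rate_functions(net)
    n_ch = len(cc)

    def rhs_aug(t, y):
        dy = np.empty(n_sp + n_ch)
        dy[:n_sp] = rhs(t, y[:n_sp])
        for j, (k, ridx) in enumerate(cc):
            r = k
            for i in ridx:
                r *= y[i]
            dy[n_sp + j] = r
        return dy

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs_aug,
        (0.0, t_end),
        np.concatenate([y0, np.zeros(n_ch)]),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else None
        raise SimulationError(f"integrator failed: {sol.message}", last_state=last)

    conc = sol.y[:n_sp]
    # clip integrator-level negative round-off
    tol = 1e-12 * max(y0.max(), 1.0)
    if conc.min() < -tol:
        raise SimulationError(
            f"negative concentration beyond tolerance: {conc.min():.3e}",
            last_state=sol.y[:, -1],
        )
    conc = np.clip(conc, 0.0, None)
    return Trajectory(sol.t, conc, names, sol.y[n_sp:])


def selectivity_from_yields(yields: dict, reaction_type: str) -> tuple[dict, float]:
    """dr percentages and ee (percent) from per-configuration product amounts.

    ``yields`` maps product configurations ("2R,1'S", ...) to non-negative
    amounts. The ee is evaluated on the major diastereomer pair
    (2R,1'S)/(2S,1'R) with positive sign for (2R,1'S).
    """
    classes = DIASTEREO_CLASS[reaction_type]
    totals = {"anti": 0.0, "syn": 0.0}
    for config, y in yields.items():
        totals[classes[config]] += y
    grand = totals["anti"] + totals["syn"]
    if grand <= 0.0:
        raise SelectivityError("no product formed; selectivity undefined")
    dr = {cls: 100.0 * v / grand for cls, v in totals.items()}

    maj = yields.get("2R,1'S", 0.0)
    mino = yields.get(MIRROR_CONFIG["2R,1'S"], 0.0)
    pair = maj + mino
    ee = 100.0 * (maj - mino) / pair if pair > 0 else 0.0
    return dr, ee


def selectivity(traj: Trajectory, net: ReactionNetwork, warn_conversion: float = 0.99) -> SelectivityResult:
    """Compute dr, ee and the A:B cycle partition from integrated channel fluxes."""
    import warnings

    e0 = net.initial.get("electrophile", 0.0)
    conv = 1.0 - traj.final("electrophile") / e0 if e0 > 0 else float("nan")
    if e0 > 0 and conv < warn_conversion:
        warnings.warn(
            f"electrophile conversion {100 * conv:.1f}% below "
            f"{100 * warn_conversion:.0f}%; selectivity may not be terminal",
            stacklevel=2,
        )

    fluxes = traj.channel_fluxes[:, -1]
    channel_yields = {}
    config_yields: dict = {}
    cycle_flux = {"A": 0.0, "B": 0.0}
    for ch, f in zip(net.channels, fluxes):
        key = (ch.cycle, ch.stereo.product_config, ch.stereo.face_pair)
        channel_yields[key] = channel_yields.get(key, 0.0) + f
        config_yields[ch.stereo.product_config] = (
            config_yields.get(ch.stereo.product_config, 0.0) + f
        )
        cycle_flux[ch.cycle] = cycle_flux.get(ch.cycle, 0.0) + f

    dr, ee = selectivity_from_yields(config_yields, net.reaction_type)

    total_flux = sum(cycle_flux.values())
    partition = {c: 100.0 * v / total_flux for c, v in cycle_flux.items()}

    return SelectivityResult(
        reaction_type=net.reaction_type,
        channel_yields=channel_yields,
        dr=dr,
        ee=ee,
        cycle_partition=partition,
        conversion=conv,
    )
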