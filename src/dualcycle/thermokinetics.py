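"""Transition-state-theory rates, Boltzmann populations and Curtin-Hammett limits.

All energies are relative Gibbs energies in kcal/mol; temperatures in kelvin.
These pure functions are the analytic backbone of the package: the microkinetic
engine must reproduce :func:`curtin_hammett_ratio` in the fast-pre-equilibrium
limit, and conformer ensembles are post-analysed with :func:`boltzmann_weights`.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3
#: Boltzmann constant, J K^-1 (CODATA 2018, exact).
K_B = 1.380649e-23
#: Planck constant, J s (CODATA 2018, exact).
PLANCK_H = 6.62607015e-34
#: Default temperature, K.
T_STANDARD = 298.15


class InvalidParameterError(ValueError):
    """Raised for non-physical thermodynamic inputs (T <= 0, non-finite energy)."""


def _check_temperature(T: float) -> float:
    T = float(T)
    if not math.isfinite(T) or T <= 0.0:
        raise InvalidParameterError(f"temperature must be finite and > 0 K, got {T!r}")
    return T


def eyring_rate(dG_act: float, T: float = T_STANDARD) -> float:
    """First-order rate constant (s^-1) from an activation free energy.

    k = (k_B T / h) exp(-dG_act / RT), transmission coefficient 1.

    Parameters
    ----------
    dG_act : activation Gibbs energy in kcal/mol, relative to the reactant
        (or pre-formed reactive complex) of the elementary step.
    T : absolute temperature in kelvin.
    """
    T = _check_temperature(T)
    dG_act = float(dG_act)
    if not math.isfinite(dG_act):
        raise InvalidParameterError(f"activation energy must be finite, got {dG_act!r}")
    return (K_B * T / PLANCK_H) * math.exp(-dG_act / (R_KCAL * T))


def boltzmann_weights(energies: Sequence[float], T: float = T_STANDARD) -> np.ndarray:
    """Normalized Boltzmann populations of an energy ensemble.

    w_i = exp(-E_i/RT) / sum_j exp(-E_j/RT), evaluated with the max-shift
    trick so arbitrarily large energy spreads do not overflow.
    """
    T = _check_temperature(T)
    e = np.asarray(list(energies), dtype=float)
    if e.size == 0:
        raise InvalidParameterError("energy ensemble must be non-empty")
    if not np.all(np.isfinite(e)):
        raise InvalidParameterError("energies must all be finite")
    x = -(e - e.min()) / (R_KCAL * T)
    w = np.exp(x)
    return w / w.sum()


def curtin_hammett_ratio(ddG_act: float, T: float = T_STANDARD) -> float:
    """Major:minor flux ratio for two channels sharing a pre-equilibrated precursor.

    When precursor conformers interconvert much faster than they react, the
    product ratio depends only on the difference of the two transition-state
    free energies (measured from a common reference):

        ratio = exp(-ddG_act / RT)

    ``ddG_act`` is G_TS(channel 1) - G_TS(channel 2); a negative value means
    channel 1 is the faster (major) one and the returned ratio exceeds 1.
    """
    T = _check_temperature(T)
    ddG_act = float(ddG_act)
    if not math.isfinite(ddG_act):
        raise InvalidParameterError(f"ddG_act must be finite, got {ddG_act!r}")
    return math.exp(-ddG_act / (R_KCAL * T))


def classify_conformer(omega: float) -> str:
    """Classify an enamine conformation by its omega(a-b-c-d) dihedral.

    The enamine C=C sits near the carboxamide group in proximal conformers
    (|omega| close to 0 deg) and away from it in distal ones (|omega| close to
    180 deg). The halfway point |omega| = 90 deg is assigned to ``distal``.
    """
    omega = float(omega)
    if not math.isfinite(omega):
        raise InvalidParameterError(f"dihedral angle must be finite, got {omega!r}")
    # fold any angle into [0, 180]
    a = abs(omega) % 360.0
    if a > 180.0:
        a = 360.0 - a
    return "distal" if a >= 90.0 else "proximal"


def classify_conformers(omegas: Iterable[float]) -> list[str]:
    """Vector convenience wrapper over :func:`classify_conformer`."""
    return [classify_conformer(w) for w in omegas]
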