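"""Synthetic inputs: noisy NMR kinetic traces, landscape presets, conformer ensembles.

These generators emulate the study conditions rather than real instrument
output: single-exponential substrate decay integrated against a constant
internal standard with multiplicative (lognormal) integral noise; free-energy
landscapes with the dual-cycle topology of the aldol and Michael catalytic
schemes; and bimodal dihedral/energy ensembles mimicking a force-field
conformer search of an enamine intermediate.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .landscape import FreeEnergyLandscape, StationaryPoint, StereoLabel
from .nmr import KineticTrace
from .thermokinetics import T_STANDARD


class SpecError(ValueError):
    """A generator spec is internally inconsistent."""


def _default_grid() -> np.ndarray:
    # hour-scale run sampled at 12 points, matching k_obs ~ 1e-3 s^-1 kinetics
    return np.linspace(0.0, 3000.0, 12)


#: Default initial signal integrals: 2 ortho, 2 meta, 1 para fluorine.
DEFAULT_SIGNAL_LEVELS = {"Fo": 2.0, "Fm": 2.0, "Fp": 1.0}


@dataclass
class TraceSpec:
    """Parameters of a synthetic pseudo-first-order NMR kinetic run."""

    k_true: float = 1e-3  # s^-1
    times: np.ndarray = field(default_factory=_default_grid)
    signal_levels: dict = field(default_factory=lambda: dict(DEFAULT_SIGNAL_LEVELS))
    reference_level: float = 3.0  # three equivalent TFA fluorines
    noise_sd: float = 0.0  # relative sd of the multiplicative integral noise
    noise_model: str = "multiplicative"
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if not np.all(np.diff(self.times) > 0):
            raise SpecError("time grid must be strictly increasing")
        if self.noise_model not in ("multiplicative", "additive"):
            raise SpecError(f"unknown noise model {self.noise_model!r}")


def generate_trace(spec: TraceSpec) -> KineticTrace:
    """Noisy exponential-decay integrals against a constant internal reference.

    Multiplicative mode draws median-unbiased lognormal factors
    exp(N(0, noise_sd)) per integral, so the log-ratio transform sees
    zero-mean Gaussian noise and the slope estimator is unbiased.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.times
    decay = np.exp(-spec.k_true * t)

    def noisy(clean: np.ndarray) -> np.ndarray:
        if spec.noise_sd == 0:
            return clean.copy()
        if spec.noise_model == "multiplicative":
            return clean * np.exp(rng.normal(0.0, spec.noise_sd, size=clean.shape))
        return np.clip(clean + rng.normal(0.0, spec.noise_sd * clean.mean(),
                                          size=clean.shape), 1e-12, None)

    signals = {name: noisy(level * decay) for name, level in spec.signal_levels.items()}
    reference = noisy(np.full_like(t, spec.reference_level))
    return KineticTrace(times=t, signals=signals, reference=reference)


@dataclass
class ChannelSpec:
    """One stereochannel: barrier (kcal/mol) above its reactive complex."""

    cycle: str
    conformer: str
    face_pair: str
    product_config: str
    dg_barrier: float

    def __post_init__(self) -> None:
        if self.dg_barrier < 0:
            raise SpecError(
                f"channel {self.face_pair}->{self.product_config}: barrier below "
                "its reactive complex"
            )


@dataclass
class LandscapeSpec:
    """Parameterization of a dual-cycle-shaped free-energy landscape.

    ``enamine_g`` and ``complex_g`` give relative Gibbs energies (kcal/mol,
    vs the reference enamine + free electrophile) per (cycle, conformer);
    ``channels`` the stereochannels with barriers measured from their own
    reactive complex, so differences between barriers of channels sharing a
    complex are transferred to the landscape exactly.
    """

    reaction_type: str = "aldol"
    enamine_g: dict = field(default_factory=dict)  # (cycle, conformer) -> kcal/mol
    complex_g: dict = field(default_factory=dict)  # (cycle, conformer) -> kcal/mol
    channels: list = field(default_factory=list)
    temperature: float = T_STANDARD
    jitter_sd: float = 0.0  # optional Gaussian jitter on TS energies
    seed: int = 0


def generate_landscape(spec: LandscapeSpec) -> FreeEnergyLandscape:
    """Instantiate the stationary-point set a LandscapeSpec describes."""
    rng = np.random.default_rng(spec.seed)
    # naming: INT1/TS1 for the aldol family, INT/TS2-3 style kept simple here
    stem = "1" if spec.reaction_type == "aldol" else "2"
    points = []
    for (cyc, conf), g in sorted(spec.enamine_g.items()):
        points.append(StationaryPoint(
            name=f"INT{stem}{cyc.lower()}_{conf}", role="intermediate",
            g_rel=g, cycle=cyc, conformer=conf,
        ))
    for (cyc, conf), g in sorted(spec.complex_g.items()):
        points.append(StationaryPoint(
            name=f"RC{stem}{cyc.lower()}_{conf}", role="reactive_complex",
            g_rel=g, cycle=cyc, conformer=conf,
        ))
    for ch in spec.channels:
        base = spec.complex_g[(ch.cycle, ch.conformer)]
        jit = rng.normal(0.0, spec.jitter_sd) if spec.jitter_sd > 0 else 0.0
        cfg = ch.product_config.replace(",", "").replace("'", "")
        points.append(StationaryPoint(
            name=f"TS{stem}{ch.cycle.lower()}_{ch.conformer}_{cfg}",
            role="transition_state",
            g_rel=base + ch.dg_barrier + jit,
            cycle=ch.cycle, conformer=ch.conformer,
            stereo=StereoLabel(ch.face_pair, ch.product_config),
        ))
    return FreeEnergyLandscape(spec.reaction_type, points, spec.temperature)


def two_channel_spec(ddg: float, base_barrier: float = 17.0,
                     reaction_type: str = "aldol") -> LandscapeSpec:
    """Minimal Curtin-Hammett benchmark: one cycle, one shared complex, two TSs.

    The major channel (toward (2R,1'S)) has ``base_barrier``; the minor one
    lies ``ddg`` kcal/mol higher. The simulated diastereomer ratio must match
    exp(ddg/RT) in the fast-pre-equilibrium limit.
    """
    if ddg < 0:
        raise SpecError("ddg must be >= 0 (major channel is the reference)")
    return LandscapeSpec(
        reaction_type=reaction_type,
        enamine_g={("A", "proximal"): 0.0},
        complex_g={("A", "proximal"): 1.0},
        channels=[
            ChannelSpec("A", "proximal", "Si,Si", "2R,1'S", base_barrier),
            ChannelSpec("A", "proximal", "Si,Re", "2R,1'R", base_barrier + ddg),
        ],
    )


def dual_cycle_aldol_spec() -> LandscapeSpec:
    """Synthetic stand-in for a full aldol dual-cycle landscape.

    Topology follows the mechanistic picture: cycle A reacts through a
    proximal enamine, cycle B through a slightly more stable distal enamine
    whose reactive complex is less abundant; both cycles favour the
    (2R,1'S) anti channel through like-topology (Si,Si) saddle points.
    Energies are illustrative round values, not quantum-chemical results.
    """
    return LandscapeSpec(
        reaction_type="aldol",
        enamine_g={
            ("A", "proximal"): 0.0,  # reference enamine
            ("A", "distal"): 0.4,
            ("B", "distal"): -0.5,
            ("B", "proximal"): 0.3,
        },
        complex_g={
            ("A", "proximal"): 1.0,
            ("B", "distal"): 2.2,
        },
        channels=[
            ChannelSpec("A", "proximal", "Si,Si", "2R,1'S", 13.0),
            ChannelSpec("A", "proximal", "Re,Re", "2S,1'R", 15.2),
            ChannelSpec("A", "proximal", "Si,Re", "2R,1'R", 14.6),
            ChannelSpec("A", "proximal", "Re,Si", "2S,1'S", 15.8),
            ChannelSpec("B", "distal", "Si,Si", "2R,1'S", 12.0),
            ChannelSpec("B", "distal", "Si,Re", "2R,1'R", 13.6),
        ],
    )


def dual_cycle_michael_spec() -> LandscapeSpec:
    """Synthetic stand-in for a conjugate-addition dual-cycle landscape.

    Cycle B's reactive complex sits far above cycle A's, making cycle A
    dominant; the major channels carry the (Re,Si) faces toward the
    (2R,1'S) syn adduct. Energies are illustrative round values.
    """
    return LandscapeSpec(
        reaction_type="michael",
        enamine_g={
            ("A", "proximal"): 0.0,
            ("B", "distal"): -0.5,
        },
        complex_g={
            ("A", "proximal"): 2.0,
            ("B", "distal"): 9.0,
        },
        channels=[
            ChannelSpec("A", "proximal", "Re,Si", "2R,1'S", 14.0),
            ChannelSpec("A", "proximal", "Si,Re", "2S,1'R", 16.2),
            ChannelSpec("A", "proximal", "Re,Re", "2R,1'R", 15.4),
            ChannelSpec("B", "distal", "Re,Si", "2R,1'S", 7.5),
        ],
    )


PRESETS = {
    "two-channel": lambda ddg=1.447: two_channel_spec(ddg),
    "dual-cycle-aldol": lambda ddg=None: dual_cycle_aldol_spec(),
    "dual-cycle-michael": lambda ddg=None: dual_cycle_michael_spec(),
}


def generate_conformer_ensemble(
    n: int,
    gap: float,
    widths: tuple = (0.3, 0.3),
    seed: int = 0,
    dihedral_sd: float = 15.0,
) -> list[tuple[float, float]]:
    """Sample (dihedral, energy) pairs forming distal/proximal clusters.

    Points alternate between a distal cluster (|omega| near 180 deg, energies
    from 0 upward) and a proximal cluster (|omega| near 0, energies from
    ``gap`` upward); a positive ``gap`` therefore favours distal. Within-
    cluster energy spread is half-normal with the given widths
    (distal, proximal), in kcal/mol.
    """
    if n < 1:
        raise SpecError("need n >= 1 conformers")
    rng = np.random.default_rng(seed)
    w_distal, w_proximal = widths
    out = []
    for i in range(n):
        if i % 2 == 0:  # distal
            omega = float(np.clip(abs(rng.normal(180.0, dihedral_sd)), 90.0, 180.0))
            energy = float(abs(rng.normal(0.0, w_distal)))
        else:  # proximal
            omega = float(np.clip(abs(rng.normal(0.0, dihedral_sd)), 0.0, 89.999))
            energy = float(gap + abs(rng.normal(0.0, w_proximal)))
        out.append((omega, energy))
    return out
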