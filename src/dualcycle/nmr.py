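"""Pseudo-first-order rate extraction from internal-referenced NMR integrals.

Under a large excess of the nucleophile (ketone:electrophile 60:1) the
electrophile decays as a single exponential, rate = k_obs * [electrophile].
Each fluorine signal of the substrate is integrated against an internal
standard (the TFA additive), and the log of the referenced integral ratio

    y_i(t) = ln(I_t^i / I_t^ref) - ln(I_0^i / I_0^ref) = -k_obs * t

is fitted linearly per signal; the reported k_obs is the mean over signals
and the quoted error their cross-signal standard deviation, matching the
+/- convention of multi-signal NMR kinetic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class TraceDataError(ValueError):
    """Malformed kinetic trace (non-positive integrals, bad grid, ...)."""


class InsufficientDataError(TraceDataError):
    """Too few usable time points to fit a rate."""


@dataclass
class KineticTrace:
    """Time-stamped multi-signal NMR integrals with an internal reference.

    ``signals`` maps signal names (e.g. Fo, Fm, Fp) to integral arrays of the
    same length as ``times``; ``reference`` is the internal-standard integral
    series. Integrals are in arbitrary (spectrometer) units; only ratios
    enter the analysis, so rescaling a whole trace changes nothing.
    """

    times: np.ndarray
    signals: dict = field(default_factory=dict)
    reference: np.ndarray = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise TraceDataError("need at least two time points")
        if not np.all(np.diff(self.times) > 0):
            raise TraceDataError("times must be strictly increasing")
        if self.reference is None:
            raise TraceDataError("internal-reference series is required")
        self.reference = np.asarray(self.reference, dtype=float)
        self.signals = {k: np.asarray(v, dtype=float) for k, v in self.signals.items()}
        if not self.signals:
            raise TraceDataError("at least one signal series is required")
        n = self.times.size
        for name, col in {**self.signals, "reference": self.reference}.items():
            if col.shape != (n,):
                raise TraceDataError(f"series {name!r} length != time grid length")
            bad = np.flatnonzero(~(col > 0))
            if bad.size:
                raise TraceDataError(
                    f"non-positive integral in series {name!r} at point index {bad[0]}"
                )


@dataclass
class FitResult:
    """Observed pseudo-first-order rate constant with per-signal detail.

    ``k_obs`` (s^-1) is the mean of the per-signal constants; ``stderr`` is
    their standard deviation (for a single signal, the regression standard
    error of the slope). ``r_squared`` is reported per signal.
    """

    k_obs: float
    per_signal_k: dict
    stderr: float
    r_squared: dict
    n_points: dict


def log_ratio_transform(
    trace: KineticTrace, signal: str, reference_floor: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """The linearizing transform y(t) = ln(I_t/I_t_ref) - ln(I_0/I_0_ref).

    Points whose reference integral falls below ``reference_floor`` times the
    maximum reference integral are dropped (and the reduced grid returned):
    a vanishing internal standard makes the ratio meaningless.
    """
    if signal not in trace.signals:
        raise TraceDataError(f"unknown signal {signal!r}; have {sorted(trace.signals)}")
    sig = trace.signals[signal]
    ref = trace.reference
    keep = ref >= reference_floor * ref.max()
    t = trace.times[keep]
    ratio = np.log(sig[keep] / ref[keep])
    y = ratio - ratio[0]
    return t, y


def fit_kobs(
    trace: KineticTrace,
    free_intercept: bool = True,
    reference_floor: float = 1e-6,
) -> FitResult:
    """Fit k_obs by per-signal linear regression of the log-ratio transform.

    With ``free_intercept`` (default) the straight line has an adjustable
    intercept, which absorbs integration error in the t0 spectrum; the
    anchored mode forces the line through the origin, exactly as written in
    the transform. Slopes should be negative for a decaying substrate; a
    positive slope triggers a warning but is still reported.
    """
    import warnings

    per_k: dict = {}
    r2: dict = {}
    npts: dict = {}
    slope_se: dict = {}
    for name in trace.signals:
        t, y = log_ratio_transform(trace, name, reference_floor)
        if t.size < 3:
            raise InsufficientDataError(
                f"signal {name!r}: need >= 3 usable points, have {t.size}"
            )
        if free_intercept:
            res = stats.linregress(t, y)
            slope, se = res.slope, res.stderr
            r2[name] = res.rvalue**2
        else:
            # least squares through the origin: slope = sum(t*y)/sum(t^2)
            slope = float(np.dot(t, y) / np.dot(t, t))
            resid = y - slope * t
            dof = t.size - 1
            se = float(np.sqrt((resid @ resid) / dof / np.dot(t, t)))
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2[name] = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        if slope > 0:
            warnings.warn(
                f"signal {name!r}: positive slope => negative rate constant",
                stacklevel=2,
            )
        per_k[name] = -slope
        slope_se[name] = se
        npts[name] = int(t.size)

    ks = np.array(list(per_k.values()))
    k_obs = float(ks.mean())
    if ks.size > 1:
        stderr = float(ks.std(ddof=1))
    else:
        stderr = float(next(iter(slope_se.values())))
    return FitResult(k_obs=k_obs, per_signal_k=per_k, stderr=stderr,
                     r_squared=r2, n_points=npts)
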