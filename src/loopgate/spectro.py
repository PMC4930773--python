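"""Spectroscopy and aggregation-kinetics statistics.

Covers the solution-biophysics side of the wild-type/mutant comparison:

* **Parameter A** — the tryptophan emission shape ratio I320/I365, a
  sensitive monitor of Trp environment (higher = more buried/blue).
* **E_max** — wavelength of maximum emission; a red shift reports
  increased solvent exposure of the fluorophores.
* **Equilibrium refolding transition curves** — any scalar signal
  (ellipticity at 222 nm, E_max, intensity, Parameter A, ANS, turbidity)
  versus denaturant concentration, with transition-midpoint detection
  from the smoothed derivative.
* **First-order aggregation kinetics** — turbidity (A400) time courses
  fitted to a single-exponential approach to a plateau after a lag:
  ``y(t) = baseline`` for ``t < lag`` and
  ``y(t) = baseline + plateau·(1 − exp(−k·(t − lag)))`` beyond it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import AnalysisError, DetectionError, FitError

logger = logging.getLogger("loopgate.spectro")


@dataclass
class Spectrum:
    wavelengths: np.ndarray    # nm, strictly increasing
    intensities: np.ndarray    # arbitrary units, >= 0
    excitation: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.wavelengths.shape != self.intensities.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and intensities must be equal-length 1-D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def at(self, wavelength: float) -> float:
        """Linearly interpolated intensity; errors outside the sampled range."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise AnalysisError(
                f"{wavelength} nm outside sampled range [{lo}, {hi}] nm")
        return float(np.interp(wavelength, self.wavelengths, self.intensities))


def parameter_a(spectrum: Spectrum) -> float:
    """Trp-emission shape ratio I320/I365 (raw intensities)."""
    i320 = spectrum.at(320.0)
    i365 = spectrum.at(365.0)
    if i365 == 0.0:
        raise AnalysisError("I365 is zero; Parameter A undefined")
    return i320 / i365


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")[: len(y)]


def e_max(spectrum: Spectrum, smooth_width: int = 5) -> float:
    """Wavelength of maximum emission, nm.

    The spectrum is smoothed with a fixed-width moving average (default 5
    points, deterministic) and the grid maximum refined by a three-point
    quadratic fit.  A plateau or an edge maximum triggers an ambiguity
    warning and the leftmost candidate is reported unrefined.
    """
    if len(spectrum.wavelengths) < 5:
        raise AnalysisError("E_max needs at least 5 spectral points")
    y = _moving_average(spectrum.intensities, smooth_width)
    x = spectrum.wavelengths
    imax = int(np.argmax(y))
    ties = np.flatnonzero(y == y[imax])
    if len(ties) > 1 or imax in (0, len(y) - 1):
        warnings.warn("ambiguous emission maximum (plateau or edge); "
                      "reporting leftmost grid point", stacklevel=2)
        return float(x[ties[0]])
    y0, y1, y2 = y[imax - 1], y[imax], y[imax + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[imax])
    # quadratic vertex on a (possibly uneven) local grid
    h1, h2 = x[imax] - x[imax - 1], x[imax + 1] - x[imax]
    if abs(h1 - h2) < 1e-9:
        return float(x[imax] + 0.5 * h1 * (y0 - y2) / denom)
    # general parabola through three points
    coef = np.polyfit(x[imax - 1: imax + 2], [y0, y1, y2], 2)
    return float(-coef[1] / (2 * coef[0]))


@dataclass
class TitrationCurve:
    denaturant_conc: np.ndarray   # mol/L, increasing
    signal: np.ndarray
    signal_name: str = "signal"

    def __post_init__(self) -> None:
        self.denaturant_conc = np.asarray(self.denaturant_conc, float)
        self.signal = np.asarray(self.signal, float)
        if self.denaturant_conc.shape != self.signal.shape:
            raise ValueError("concentration and signal lengths differ")
        if np.any(self.denaturant_conc < 0):
            raise ValueError("denaturant concentrations must be >= 0")

    def normalized(self) -> "TitrationCurve":
        lo, hi = self.signal.min(), self.signal.max()
        span = hi - lo if hi > lo else 1.0
        return TitrationCurve(self.denaturant_conc.copy(),
                              (self.signal - lo) / span, self.signal_name)


def assemble_transition(points, signal_name: str = "signal") -> TitrationCurve:
    """Assemble a refolding transition curve from per-concentration data.

    ``points`` is a sequence of ``(conc, value)`` where ``value`` is a
    scalar or a :class:`Spectrum` (reduced with :func:`e_max` if
    ``signal_name == 'Emax'``, :func:`parameter_a` if ``'ParamA'``).
    Requires at least 6 concentrations; duplicates are merged by mean with
    a log message; output is sorted by increasing concentration.
    """
    reduced: dict[float, list[float]] = {}
    for conc, value in points:
        if isinstance(value, Spectrum):
            if signal_name == "Emax":
                value = e_max(value)
            elif signal_name == "ParamA":
                value = parameter_a(value)
            else:
                raise ValueError(
                    f"cannot reduce a Spectrum to signal {signal_name!r}")
        reduced.setdefault(float(conc), []).append(float(value))
    if len(reduced) < 6:
        raise AnalysisError(f"need >= 6 distinct concentrations, got {len(reduced)}")
    concs = sorted(reduced)
    values = []
    for c in concs:
        vals = reduced[c]
        if len(vals) > 1:
            logger.info("duplicate concentration %.3g mol/L: merged %d values by mean",
                        c, len(vals))
        values.append(float(np.mean(vals)))
    return TitrationCurve(np.array(concs), np.array(values), signal_name)


def detect_midpoints(curve: TitrationCurve, n_transitions: int,
                     smooth_width: int = 5, min_separation: float = 0.3) -> list[float]:
    """Transition midpoints (mol/L) from the smoothed derivative.

    The min-max normalized signal is smoothed, differentiated against
    concentration, and the ``n_transitions`` strongest local extrema of
    |d signal / d conc| (at least ``min_separation`` mol/L apart) are
    refined by quadratic interpolation and returned ascending.
    """
    if n_transitions not in (1, 2):
        raise ValueError("n_transitions must be 1 or 2")
    c = curve.denaturant_conc
    y = _moving_average(curve.normalized().signal, smooth_width)
    dy = np.abs(np.gradient(y, c))
    candidates = [i for i in range(1, len(dy) - 1)
                  if dy[i] >= dy[i - 1] and dy[i] >= dy[i + 1] and dy[i] > 0]
    candidates.sort(key=lambda i: -dy[i])
    picked: list[int] = []
    for i in candidates:
        if all(abs(c[i] - c[j]) >= min_separation for j in picked):
            picked.append(i)
        if len(picked) == n_transitions:
            break
    if len(picked) < n_transitions:
        raise DetectionError(
            f"found {len(picked)} derivative extrema, needed {n_transitions}")
    mids = []
    for i in picked:
        coef = np.polyfit(c[i - 1: i + 2], dy[i - 1: i + 2], 2)
        if coef[0] >= 0:  # not a maximum after all; keep grid point
            mids.append(float(c[i]))
        else:
            mids.append(float(np.clip(-coef[1] / (2 * coef[0]), c[i - 1], c[i + 1])))
    return sorted(mids)


@dataclass
class AggregationFit:
    rate_k: float          # s^-1
    lag_time: float        # s
    plateau: float         # absorbance units above baseline
    baseline: float
    residual_rms: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _agg_model(np.asarray(t, float), self.plateau, self.rate_k,
                          self.lag_time, self.baseline)


def _agg_model(t: np.ndarray, plateau: float, k: float, lag: float,
               baseline: float) -> np.ndarray:
    out = np.full_like(t, baseline, dtype=float)
    late = t >= lag
    out[late] = baseline + plateau * (1.0 - np.exp(-k * (t[late] - lag)))
    return out


def fit_aggregation(time_s: np.ndarray, turbidity: np.ndarray) -> AggregationFit:
    """Least-squares fit of first-order aggregation kinetics with a lag.

    Model: flat baseline for ``t < lag``, then a single-exponential rise to
    ``baseline + plateau`` with rate ``k``.  Requires at least 20 points
    and an overall rising trace; a flat trace or an inadmissible fitted
    rate raises :class:`FitError`.
    """
    t = np.asarray(time_s, float)
    y = np.asarray(turbidity, float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("time and turbidity must be equal-length 1-D arrays")
    if len(t) < 20:
        raise FitError(f"need >= 20 points, got {len(t)}")
    span = float(y.max() - y.min())
    tail = float(np.mean(y[-max(3, len(y) // 10):]))
    head = float(np.mean(y[: max(3, len(y) // 10)]))
    if span <= 0 or tail - head < 0.5 * span:
        raise FitError("no rising aggregation signal in trace")

    # initial guesses: lag where the signal first clears 5% of its range
    above = np.flatnonzero(y > y.min() + 0.05 * span)
    lag0 = float(t[above[0]]) if len(above) else float(t[0])
    baseline0 = float(np.mean(y[t < lag0])) if np.any(t < lag0) else float(y[0])
    plateau0 = max(span, 1e-12)
    # rate guess from time to half-plateau
    half_idx = np.flatnonzero(y - baseline0 > 0.5 * plateau0)
    t_half = float(t[half_idx[0]]) if len(half_idx) else float(t[len(t) // 2])
    k0 = np.log(2.0) / max(t_half - lag0, (t[1] - t[0]))

    def residuals(p):
        plateau, k, lag, baseline = p
        return _agg_model(t, plateau, k, lag, baseline) - y

    try:
        sol = least_squares(
            residuals, x0=[plateau0, k0, lag0, baseline0],
            bounds=([0, 1e-12, 0, -np.inf], [np.inf, np.inf, float(t[-1]), np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception as exc:
        raise FitError(f"aggregation fit failed: {exc}") from exc
    if not sol.success:
        raise FitError(f"aggregation fit did not converge: {sol.message}")
    plateau, k, lag, baseline = (float(v) for v in sol.x)
    if k <= 0 or plateau <= 0:
        raise FitError(f"inadmissible fitted parameters (plateau={plateau:g}, k={k:g})")
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return AggregationFit(rate_k=k, lag_time=lag, plateau=plateau,
                          baseline=baseline, residual_rms=rms)


def read_xy_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column CSV (x, y), skipping a non-numeric header row."""
    import csv as _csv

    xs, ys = [], []
    with open(path) as fh:
        for row in _csv.reader(fh):
            if len(row) < 2:
                continue
            try:
                xs.append(float(row[0])), ys.append(float(row[1]))
            except ValueError:
                continue
    return np.array(xs), np.array(ys)
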