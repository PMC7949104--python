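"""Biochemical readout analysis: redox titrations, kinetics, thiol counting
and size-exclusion calibration.

The central quantity is the standard (midpoint) redox potential E0 of a
protein disulfide, measured against glutathione redox buffers.  Band
intensities of oxidized and reduced protein (from AMS gel-shift densitometry,
consumed here as numbers) give the fraction reduced at each buffer poise
r = [GSH]^2/[GSSG]; after plateau rescaling, a sigmoid in r is fitted and the
midpoint ratio K is converted to a potential with the Nernst equation for a
two-electron couple:

    E0 = E0_couple - (R*T / (2*F)) * ln(K / 1 M)

with the glutathione couple reference at -240 mV.  At 298.15 K the prefactor
R*T/2F is 12.85 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .errors import DataError, ParseError

R_GAS = 8.314  # J mol^-1 K^-1
FARADAY = 96485.0  # C mol^-1
N_ELECTRONS = 2
DEFAULT_TEMPERATURE = 298.15  # K
DEFAULT_COUPLE_E0 = -240.0  # mV, GSH/GSSG reference


def nernst_prefactor_mv(temperature: float = DEFAULT_TEMPERATURE,
                        n_electrons: int = N_ELECTRONS) -> float:
    """R*T/(n*F) in millivolts."""
    return R_GAS * temperature / (n_electrons * FARADAY) * 1000.0


# ---------------------------------------------------------------------------
# Titration data model


@dataclass(frozen=True)
class TitrationPoint:
    gsh: float  # M
    gssg: float  # M
    i_red: float
    i_ox: float

    def __post_init__(self) -> None:
        if self.gsh <= 0 or self.gssg <= 0:
            raise DataError("GSH and GSSG concentrations must be > 0")
        if self.i_red < 0 or self.i_ox < 0:
            raise DataError("band intensities must be non-negative")
        if self.i_red + self.i_ox <= 0:
            raise DataError("both band intensities are zero")

    @property
    def ratio(self) -> float:
        """[GSH]^2/[GSSG] in molar."""
        return self.gsh**2 / self.gssg


@dataclass
class TitrationSeries:
    protein_id: str
    points: list[TitrationPoint]
    temperature: float = DEFAULT_TEMPERATURE
    couple_E0: float = DEFAULT_COUPLE_E0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DataError("temperature must be > 0 K")
        self.points = sorted(self.points, key=lambda p: p.ratio)
        ratios = [p.ratio for p in self.points]
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise DataError("ratios must be strictly increasing after sorting")

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points])


@dataclass
class RedoxFitResult:
    K: float  # molar midpoint ratio
    E0: float  # mV
    bottom: float
    top: float
    slope: float
    residual_norm: float
    converged: bool
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Fractions


def fraction_reduced(point: TitrationPoint) -> float:
    """Reduced-band intensity over total band intensity."""
    return point.i_red / (point.i_red + point.i_ox)


def rescale_fractions(fractions, plateau_width: int = 2) -> np.ndarray:
    """Linearly rescale so the low/high-ratio plateau means map to 0 and 1.

    ``fractions`` must be ordered by increasing ratio.  Values outside [0, 1]
    after rescaling are kept (not clipped) so the fit sees the real noise.
    """
    f = np.asarray(fractions, dtype=float)
    if len(f) < 2 * plateau_width:
        raise DataError(
            f"need at least {2 * plateau_width} points for plateau rescaling"
        )
    low = f[:plateau_width].mean()
    high = f[-plateau_width:].mean()
    if math.isclose(low, high):
        raise DataError("flat series: plateau means are equal")
    return (f - low) / (high - low)


# ---------------------------------------------------------------------------
# Midpoint fitting


def _sigmoid(r, bottom, top, K, s):
    rs = np.power(r, s)
    return bottom + (top - bottom) * rs / (rs + K**s)


def fit_titration(
    series: TitrationSeries,
    free_slope: bool = False,
    plateau_width: int = 2,
) -> RedoxFitResult:
    """Fit the rescaled fraction-reduced curve and return the midpoint ratio K.

    The model is f(r) = bottom + (top-bottom) * r^s / (r^s + K^s) with the
    slope s fixed at 1 by default (the thermodynamic form for a single
    two-electron disulfide); ``free_slope=True`` releases s as a diagnostic.
    K is fit in log space (positivity) and initialised at the ratio whose
    rescaled fraction is nearest 0.5.
    """
    if len(series.points) < 5:
        raise DataError("need at least 5 titration points")
    r = series.ratios
    raw = np.array([fraction_reduced(p) for p in series.points])
    y = rescale_fractions(raw, plateau_width=plateau_width)
    if y.max() < 0.75 or y.min() > 0.25:
        raise DataError("titration points do not span the transition")

    k0 = float(r[np.argmin(np.abs(y - 0.5))])

    if free_slope:
        def resid(theta):
            bottom, top, logk, s = theta
            return _sigmoid(r, bottom, top, math.exp(logk), s) - y
        x0 = [0.0, 1.0, math.log(k0), 1.0]
    else:
        def resid(theta):
            bottom, top, logk = theta
            return _sigmoid(r, bottom, top, math.exp(logk), 1.0) - y
        x0 = [0.0, 1.0, math.log(k0)]

    sol = optimize.least_squares(resid, x0)
    if free_slope:
        bottom, top, logk, slope = sol.x
    else:
        (bottom, top, logk), slope = sol.x, 1.0
    if bottom > top:
        # reparameterise so bottom < top holds in the reported fit
        bottom, top = top, bottom
    K = math.exp(logk)
    E0 = nernst_E0(K, series.temperature, series.couple_E0)
    notes = []
    if free_slope and abs(slope - 1.0) > 0.2:
        notes.append(f"fitted slope {slope:.2f} deviates from 1")
    return RedoxFitResult(
        K=K,
        E0=E0,
        bottom=float(bottom),
        top=float(top),
        slope=float(slope),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        notes=notes,
    )


def nernst_E0(
    K: float,
    temperature: float = DEFAULT_TEMPERATURE,
    couple_E0: float = DEFAULT_COUPLE_E0,
) -> float:
    """Standard redox potential (mV) from the midpoint ratio K (molar)."""
    if K <= 0:
        raise DataError("midpoint ratio K must be > 0")
    return couple_E0 - nernst_prefactor_mv(temperature) * math.log(K)


def nernst_K(
    E0: float,
    temperature: float = DEFAULT_TEMPERATURE,
    couple_E0: float = DEFAULT_COUPLE_E0,
) -> float:
    """Midpoint ratio K (molar) from a standard potential (mV); inverse of
    :func:`nernst_E0`."""
    return math.exp((couple_E0 - E0) / nernst_prefactor_mv(temperature))


# ---------------------------------------------------------------------------
# Kinetics


@dataclass
class KineticTrace:
    times: np.ndarray  # s
    values: np.ndarray  # fluorescence, a.u.
    addition_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DataError("times and values differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")


def initial_slope(trace: KineticTrace, window_length: float, delay: float = 0.0) -> float:
    """Ordinary least-squares slope of the trace over the early linear phase,
    the window [addition + delay, addition + delay + window_length]."""
    start = trace.addition_time + delay
    mask = (trace.times >= start) & (trace.times <= start + window_length)
    if mask.sum() < 3:
        raise DataError("fewer than 3 points in the slope window")
    fit = stats.linregress(trace.times[mask], trace.values[mask])
    return float(fit.slope)


def relative_activity(slope: float, reference_slope: float, blank_slope: float = 0.0) -> float:
    """Activity relative to a reference enzyme (reference = 1 by definition),
    blank-corrected."""
    if reference_slope <= blank_slope:
        raise DataError("reference slope must exceed blank slope")
    return (slope - blank_slope) / (reference_slope - blank_slope)


# ---------------------------------------------------------------------------
# Thiol counting (Ellman) and SEC


def ellman_thiols(
    a412: float,
    path_cm: float,
    protein_conc: float,
    epsilon_tnb: float = 14150.0,
) -> float:
    """Free thiols per subunit from TNB absorbance at 412 nm (Beer-Lambert)."""
    if a412 < 0:
        raise DataError("absorbance must be non-negative")
    if path_cm <= 0 or protein_conc <= 0 or epsilon_tnb <= 0:
        raise DataError("path length, protein concentration and epsilon must be > 0")
    return (a412 / (epsilon_tnb * path_cm)) / protein_conc


@dataclass
class SecCalibration:
    a: float  # intercept of ln(mass) = a + b * Ve
    b: float  # slope (negative for SEC)
    r_squared: float

    def mass_at(self, volume_ml: float) -> float:
        return math.exp(self.a + self.b * volume_ml)


def sec_calibrate(standards: list[tuple[float, float]]) -> SecCalibration:
    """Fit ln(mass) = a + b * Ve to (elution volume ml, mass Da) standards."""
    if len(standards) < 2:
        raise DataError("need at least 2 SEC standards")
    volumes = np.array([v for v, _ in standards], dtype=float)
    masses = np.array([m for _, m in standards], dtype=float)
    if len(set(volumes.tolist())) < len(volumes):
        raise DataError("SEC standards have identical elution volumes")
    if np.any(masses <= 0):
        raise DataError("standard masses must be > 0")
    fit = stats.linregress(volumes, np.log(masses))
    return SecCalibration(
        a=float(fit.intercept),
        b=float(fit.slope),
        r_squared=float(fit.rvalue**2),
    )


def oligomer_state(apparent_mass: float, monomer_mass: float) -> tuple[float, int]:
    """Subunit count from an apparent SEC mass: (ratio, nearest integer,
    ties rounding down)."""
    if apparent_mass <= 0 or monomer_mass <= 0:
        raise DataError("masses must be > 0")
    ratio = apparent_mass / monomer_mass
    count = math.ceil(ratio - 0.5)
    return ratio, count


# ---------------------------------------------------------------------------
# File I/O


def _read_header_block(path: str | Path) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                if value:
                    meta[key.strip()] = value.strip()
            else:
                body.append(line)
    return meta, body


def read_titration(path: str | Path) -> TitrationSeries:
    """Read a titration TSV: ``# key=value`` header block (protein_id,
    optionally temperature_K, couple_E0_mV) then columns
    ``gsh_M gssg_M i_red i_ox``."""
    meta, body = _read_header_block(path)
    if not body:
        raise ParseError(f"titration file {path} has no data rows")
    header = body[0].split("\t")
    expected = ["gsh_M", "gssg_M", "i_red", "i_ox"]
    if header != expected:
        raise ParseError(f"titration header must be {expected}, got {header}")
    points = []
    for i, line in enumerate(body[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError("titration row needs 4 columns", line=i)
        gsh, gssg, i_red, i_ox = map(float, parts)
        points.append(TitrationPoint(gsh=gsh, gssg=gssg, i_red=i_red, i_ox=i_ox))
    return TitrationSeries(
        protein_id=meta.get("protein_id", Path(path).stem),
        points=points,
        temperature=float(meta.get("temperature_K", DEFAULT_TEMPERATURE)),
        couple_E0=float(meta.get("couple_E0_mV", DEFAULT_COUPLE_E0)),
    )


def read_kinetics(path: str | Path) -> KineticTrace:
    """Read a two-column ``time_s,fluorescence`` CSV with an
    ``# addition_time_s=`` header line."""
    meta, body = _read_header_block(path)
    rows = [line.split(",") for line in body if not line.startswith("time")]
    times = [float(r[0]) for r in rows]
    values = [float(r[1]) for r in rows]
    return KineticTrace(
        times=np.array(times),
        values=np.array(values),
        addition_time=float(meta.get("addition_time_s", 0.0)),
    )


def read_sec_standards(path: str | Path) -> list[tuple[float, float]]:
    """Read a ``volume_ml mass_da`` TSV of SEC standards."""
    _, body = _read_header_block(path)
    out = []
    for line in body:
        if line.startswith("volume"):
            continue
        parts = line.split("\t")
        out.append((float(parts[0]), float(parts[1])))
    return out
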