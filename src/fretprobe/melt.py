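"""Two-state melting-curve simulation, peak extraction and genotype calling.

The readout modeled here is the acceptor-channel fluorescence of a FRET
hybridization-probe pair during a post-PCR melt: signal is taken proportional
to the fraction of target sites carrying a bound sensor probe.  With the probe
in excess over the amplicon, site occupancy follows the two-state isotherm

    theta(T) = K(T) c / (1 + K(T) c),    c = C_T / 4,

where K is the duplex association constant from van't Hoff dH/dS.  The C_T/4
effective concentration keeps this curve consistent with the conventional
non-self-complementary two-state Tm: theta passes through exactly 1/2 at Tm,
and the derivative peak -d theta/dT sits at Tm.  dS is re-anchored so the
transition is centered on the salt-corrected Tm while keeping the duplex dH
(and hence the transition width) from the nearest-neighbor sum.

A heterozygote is a 50:50 mixture of the matched and mismatched duplex
species; its composite curve is the weighted pointwise sum.  Genotypes are
called from derivative-peak positions against the expected per-allele Tms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import GridMismatchError, NoTransitionError
from .thermo import BufferConditions, CELSIUS_OFFSET, R_GAS, ThermoResult

#: default temperature grid (degC) and step
DEFAULT_T_MIN = 50.0
DEFAULT_T_MAX = 100.0
DEFAULT_STEP = 0.1
#: peaks must be at least this fraction of the tallest derivative value
DEFAULT_PROMINENCE_FRACTION = 0.10
#: default half-width of the peak-to-allele matching window for genotype calls
DEFAULT_CALL_TOLERANCE_C = 1.5
#: diploid heterozygote: equal amounts of the two allele duplexes
HET_WEIGHTS = (0.5, 0.5)

HOMOZYGOUS_REF = "homozygous_ref"
HOMOZYGOUS_ALT = "homozygous_alt"
HETEROZYGOUS = "heterozygous"
NO_CALL = "no_call"


@dataclass
class MeltingCurve:
    """Bound fraction vs temperature with its negative derivative."""

    temperatures: np.ndarray
    bound_fraction: np.ndarray
    derivative: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.bound_fraction = np.asarray(self.bound_fraction, dtype=float)
        self.derivative = np.asarray(self.derivative, dtype=float)
        n = len(self.temperatures)
        if len(self.bound_fraction) != n or len(self.derivative) != n:
            raise ValueError("curve arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperature grid must be strictly increasing")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class MeltPeak:
    """A local maximum of the derivative melting curve."""

    peak_tm: float
    height: float
    prominence: float


@dataclass(frozen=True)
class GenotypeCall:
    call: str
    peaks: tuple[MeltPeak, ...]
    evidence: dict
    reason: str | None = None


def fraction_bound(
    thermo: ThermoResult,
    buffer: BufferConditions,
    t_min: float = DEFAULT_T_MIN,
    t_max: float = DEFAULT_T_MAX,
    step: float = DEFAULT_STEP,
    label: str = "",
) -> MeltingCurve:
    """Two-state equilibrium bound fraction on a regular temperature grid.

    The grid includes both endpoints: 50->100 degC at 0.1 degC gives 501
    points.  theta equals 0.5 at ``thermo.tm_corrected`` by construction.
    """
    if t_min >= t_max:
        raise ValueError(f"t_min ({t_min}) must be below t_max ({t_max})")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if thermo.dH >= 0:
        raise NoTransitionError(f"dH = {thermo.dH} >= 0: no helix-coil transition")

    n = int(round((t_max - t_min) / step)) + 1
    t = t_min + step * np.arange(n)
    t_k = t + CELSIUS_OFFSET
    tm_k = thermo.tm_corrected + CELSIUS_OFFSET
    c = buffer.ct_molar / buffer.symmetry_factor
    # effective entropy anchoring theta(tm_corrected) = 1/2 at concentration c
    ds_eff = thermo.dH * 1000.0 / tm_k + R_GAS * math_log_safe(1.0 / c)
    # ln(K c) = -(dH - T dS_eff)/(R T) + ln c
    ln_kc = -(thermo.dH * 1000.0 - t_k * ds_eff) / (R_GAS * t_k) + math_log_safe(c)
    theta = 1.0 / (1.0 + np.exp(-ln_kc))
    deriv = -np.gradient(theta, t)
    return MeltingCurve(t, theta, deriv, label=label)


def math_log_safe(x: float) -> float:
    if x <= 0:
        raise NoTransitionError("non-positive effective concentration")
    return float(np.log(x))


def melt_peaks(curve: MeltingCurve, min_prominence: float | None = None) -> list[MeltPeak]:
    """Local maxima of the derivative curve, sorted by temperature.

    ``min_prominence`` defaults to 10 % of the global derivative maximum; an
    empty or flat curve yields an empty list.
    """
    d = curve.derivative
    if len(d) == 0 or np.nanmax(d) <= 0:
        return []
    if min_prominence is None:
        min_prominence = DEFAULT_PROMINENCE_FRACTION * float(np.nanmax(d))
    idx, props = find_peaks(d, prominence=min_prominence)
    return [
        MeltPeak(
            peak_tm=float(curve.temperatures[i]),
            height=float(d[i]),
            prominence=float(p),
        )
        for i, p in zip(idx, props["prominences"])
    ]


def composite_curve(
    curves: list[MeltingCurve] | tuple[MeltingCurve, ...],
    weights: list[float] | tuple[float, ...],
    label: str = "",
) -> MeltingCurve:
    """Pointwise weighted sum of melting curves sharing a temperature grid."""
    if len(curves) == 0 or len(curves) != len(weights):
        raise ValueError("need one weight per curve")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    grid = curves[0].temperatures
    for c in curves[1:]:
        if len(c.temperatures) != len(grid) or not np.allclose(
            c.temperatures, grid, rtol=0.0, atol=1e-12
        ):
            raise GridMismatchError("curves are not on a common temperature grid")
    theta = sum(wi * c.bound_fraction for wi, c in zip(w, curves))
    deriv = sum(wi * c.derivative for wi, c in zip(w, curves))
    return MeltingCurve(grid.copy(), theta, deriv, label=label)


def call_genotype(
    observed: MeltingCurve,
    expected_ref_tm: float,
    expected_alt_tm: float,
    tolerance: float = DEFAULT_CALL_TOLERANCE_C,
    min_prominence: float | None = None,
) -> GenotypeCall:
    """Call a genotype from the melting peaks of an observed curve.

    One peak within ``tolerance`` of the matched-allele Tm -> homozygous_ref;
    one near the mismatched-allele Tm -> homozygous_alt; two peaks, one near
    each -> heterozygous; anything else -> no_call with a reason.
    """
    if expected_ref_tm <= expected_alt_tm:
        raise ValueError("expected_ref_tm must exceed expected_alt_tm (match melts higher)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    peaks = tuple(melt_peaks(observed, min_prominence=min_prominence))
    evidence = {
        "expected_ref_tm": expected_ref_tm,
        "expected_alt_tm": expected_alt_tm,
        "tolerance_c": tolerance,
    }

    def near(p: MeltPeak, tm: float) -> bool:
        return abs(p.peak_tm - tm) <= tolerance

    if len(peaks) == 0:
        return GenotypeCall(NO_CALL, peaks, evidence, reason="no melting peaks detected")
    if len(peaks) == 1:
        (p,) = peaks
        if near(p, expected_ref_tm) and not near(p, expected_alt_tm):
            return GenotypeCall(HOMOZYGOUS_REF, peaks, evidence)
        if near(p, expected_alt_tm) and not near(p, expected_ref_tm):
            return GenotypeCall(HOMOZYGOUS_ALT, peaks, evidence)
        return GenotypeCall(
            NO_CALL, peaks, evidence,
            reason=f"single peak at {p.peak_tm:.2f} degC matches neither allele unambiguously",
        )
    if len(peaks) == 2:
        lo, hi = peaks
        if near(hi, expected_ref_tm) and near(lo, expected_alt_tm):
            return GenotypeCall(HETEROZYGOUS, peaks, evidence)
        return GenotypeCall(
            NO_CALL, peaks, evidence,
            reason="two peaks but not one near each expected allele Tm",
        )
    return GenotypeCall(
        NO_CALL, peaks, evidence, reason=f"{len(peaks)} peaks detected (expected 1 or 2)"
    )


def genotype_curve(
    thermo_ref: ThermoResult,
    thermo_alt: ThermoResult,
    genotype: str,
    buffer: BufferConditions,
    t_min: float = DEFAULT_T_MIN,
    t_max: float = DEFAULT_T_MAX,
    step: float = DEFAULT_STEP,
    het_weights: tuple[float, float] = HET_WEIGHTS,
) -> MeltingCurve:
    """Simulated melting curve for genotype 'ref', 'alt' or 'het'."""
    if genotype == "ref":
        return fraction_bound(thermo_ref, buffer, t_min, t_max, step, label="ref")
    if genotype == "alt":
        return fraction_bound(thermo_alt, buffer, t_min, t_max, step, label="alt")
    if genotype == "het":
        a = fraction_bound(thermo_ref, buffer, t_min, t_max, step, label="ref")
        b = fraction_bound(thermo_alt, buffer, t_min, t_max, step, label="alt")
        return composite_curve([a, b], het_weights, label="het")
    raise ValueError(f"unknown genotype {genotype!r} (expected 'ref', 'alt' or 'het')")


def peak_resolution_limit(
    dh_ref: float,
    dh_alt: float,
    tm_ref: float,
    buffer: BufferConditions,
    step: float = DEFAULT_STEP,
    lo: float = 0.5,
    hi: float = 30.0,
    tol: float = 0.05,
) -> float:
    """Smallest Tm separation at which a 50:50 composite resolves two peaks.

    This is the model's own peak-merge resolution for a given pair of
    transition enthalpies: below the returned separation the composite
    derivative shows a single maximum (or the minor peak falls under the
    default prominence threshold).  Computed by bisection on the separation.
    """

    def resolves(sep: float) -> bool:
        t_lo, t_hi = tm_ref - sep - 25.0, tm_ref + 25.0
        a = _curve_at(dh_ref, tm_ref, buffer, t_lo, t_hi, step)
        b = _curve_at(dh_alt, tm_ref - sep, buffer, t_lo, t_hi, step)
        comp = composite_curve([a, b], HET_WEIGHTS)
        return len(melt_peaks(comp)) >= 2

    if resolves(lo):
        return lo
    if not resolves(hi):
        return float("inf")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if resolves(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _curve_at(
    dh: float, tm: float, buffer: BufferConditions, t_min: float, t_max: float, step: float
) -> MeltingCurve:
    """Two-state curve for a species described only by (dH, centered Tm)."""
    species = ThermoResult(dH=dh, dS=0.0, dG37=0.0, tm_1M=tm, tm_corrected=tm)
    return fraction_bound(species, buffer, t_min, t_max, step)
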