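"""Fluorescence-polarisation titrations: simulation, fitting, ND calling.

A fluorescein-labelled phosphopeptide probe (200 nM by default) is titrated
with increasing protein concentration; polarisation (mP) rises from a free
baseline towards a bound plateau.  The analysis model is the hyperbolic
one-site specific-binding law

    mP(c) = baseline + (plateau − baseline) · c / (Kd + c)

fitted by non-linear least squares on the replicate-mean curve.  Titrations
whose response cannot support a Kd estimate — fit failure, a Kd beyond the
tested concentration range, or a dynamic range indistinguishable from noise
— are reported as ND (not determined) rather than given a number.

The free probe is treated as non-depleting even when its concentration is
comparable to a sub-micromolar Kd, matching the stated analysis model; a
probe-depletion quadratic model is available behind ``model="quadratic"``
for sensitivity analysis.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, TextIO, Union

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FPTitration",
    "BindingFit",
    "TitrationParams",
    "default_concentrations",
    "one_site_model",
    "quadratic_depletion_model",
    "simulate_titration",
    "fit_one_site",
    "call_nd",
    "kd_ratio",
    "read_titration_csv",
    "write_titration_csv",
]

#: Probe concentration in nM used throughout the assays.
DEFAULT_PROBE_NM = 200.0

#: Floor (mP) below which a fitted dynamic range is considered zero.
_RANGE_FLOOR_MP = 1e-6


def default_concentrations(top_uM: float = 50.0, n_points: int = 12) -> np.ndarray:
    """Two-fold dilution series from ``top_uM`` µM, ascending order."""
    return top_uM / 2.0 ** np.arange(n_points - 1, -1, -1, dtype=float)


@dataclass(frozen=True)
class FPTitration:
    """A concentration–polarisation series.

    ``concentrations`` are protein concentrations in µM, strictly positive
    and strictly increasing; ``readings`` is an (n_concentrations,
    n_replicates) array of polarisation values in mP.
    """

    concentrations: np.ndarray
    readings: np.ndarray
    probe_concentration: float = DEFAULT_PROBE_NM

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        readings = np.asarray(self.readings, dtype=float)
        if conc.ndim != 1 or readings.ndim != 2:
            raise ValueError("concentrations must be 1-D and readings 2-D")
        if readings.shape[0] != conc.size:
            raise ValueError("one row of readings per concentration required")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "readings", readings)

    @property
    def n_replicates(self) -> int:
        return self.readings.shape[1]

    def replicate_means(self) -> np.ndarray:
        return self.readings.mean(axis=1)


@dataclass(frozen=True)
class BindingFit:
    """Fitted one-site parameters, their standard errors, and a status.

    ``status`` is ``OK`` or ``ND``; parameter values are retained even for
    ND fits (where available) so the reason for the call can be inspected,
    but only OK fits satisfy kd > 0 and plateau > baseline by contract.
    """

    kd: float
    baseline: float
    plateau: float
    kd_se: float = math.nan
    baseline_se: float = math.nan
    plateau_se: float = math.nan
    status: str = "OK"
    residual_sd: float = math.nan
    model: str = "one-site"
    nd_reason: Optional[str] = None

    def __post_init__(self):
        if self.status not in {"OK", "ND"}:
            raise ValueError("status must be OK or ND")
        if self.status == "OK":
            if not self.kd > 0:
                raise ValueError("OK fit requires kd > 0")
            if not self.plateau > self.baseline:
                raise ValueError("OK fit requires plateau > baseline")

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd,
            "baseline_mP": self.baseline,
            "plateau_mP": self.plateau,
            "kd_se": self.kd_se,
            "baseline_se": self.baseline_se,
            "plateau_se": self.plateau_se,
            "residual_sd_mP": self.residual_sd,
            "status": self.status,
            "model": self.model,
            "nd_reason": self.nd_reason,
        }


@dataclass(frozen=True)
class TitrationParams:
    """Generating parameters for a synthetic titration.

    Baseline/plateau defaults (80 → 220 mP) are typical for a fluorescein
    probe going from free tumbling to fully bound.
    """

    kd: float
    baseline: float = 80.0
    plateau: float = 220.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.kd < 0:
            raise ValueError("kd must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def one_site_model(
    c: Union[float, np.ndarray], kd: float, baseline: float, plateau: float
) -> Union[float, np.ndarray]:
    """Hyperbolic one-site specific-binding law (c, kd in µM; output mP)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    out = baseline + (plateau - baseline) * c / (kd + c)
    return float(out) if out.ndim == 0 else out


def quadratic_depletion_model(
    c: Union[float, np.ndarray],
    kd: float,
    baseline: float,
    plateau: float,
    probe_uM: float = DEFAULT_PROBE_NM / 1000.0,
) -> Union[float, np.ndarray]:
    """Probe-depletion (quadratic) binding law for sensitivity analysis.

    Accounts for the finite probe concentration: the fraction bound is the
    exact solution of the binding quadratic rather than c/(Kd + c).
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if probe_uM <= 0:
        raise ValueError("probe concentration must be positive")
    c = np.asarray(c, dtype=float)
    s = c + probe_uM + kd
    bound = (s - np.sqrt(s * s - 4.0 * c * probe_uM)) / (2.0 * probe_uM)
    out = baseline + (plateau - baseline) * bound
    return float(out) if out.ndim == 0 else out


def simulate_titration(
    params: TitrationParams,
    concentrations: Optional[Sequence[float]] = None,
    n_replicates: int = 4,
    probe_concentration: float = DEFAULT_PROBE_NM,
    model: str = "one-site",
) -> FPTitration:
    """Simulate a titration: model curve plus i.i.d. Gaussian noise (mP).

    Reproducible for a fixed ``params.seed``.  The default series is a
    12-point two-fold dilution from 50 µM.
    """
    conc = (
        default_concentrations()
        if concentrations is None
        else np.asarray(concentrations, dtype=float)
    )
    if model == "one-site":
        ideal = one_site_model(conc, params.kd, params.baseline, params.plateau)
    elif model == "quadratic":
        ideal = quadratic_depletion_model(
            conc, params.kd, params.baseline, params.plateau,
            probe_uM=probe_concentration / 1000.0,
        )
    else:
        raise ValueError("model must be 'one-site' or 'quadratic'")
    rng = np.random.default_rng(params.seed)
    readings = ideal[:, None] + rng.normal(
        0.0, params.noise_sd, size=(conc.size, n_replicates)
    )
    return FPTitration(
        concentrations=conc,
        readings=readings,
        probe_concentration=probe_concentration,
    )


def _fit_curve(x, y, model_fn, p0, maxfev=20000):
    popt, pcov = curve_fit(
        model_fn,
        x,
        y,
        p0=p0,
        bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=maxfev,
    )
    perr = np.sqrt(np.diag(pcov))
    return popt, perr


def fit_one_site(
    titration: FPTitration,
    model: str = "one-site",
    per_replicate: bool = False,
    apply_nd: bool = True,
    min_dynamic_range_sds: float = 3.0,
    max_kd_factor: float = 1.0,
    min_kd_factor: float = 1.0,
) -> BindingFit:
    """Least-squares fit of (Kd, baseline, plateau) to a titration.

    By default the replicate-mean curve is fitted (replicates enter plots as
    mean ± SD); ``per_replicate=True`` instead stacks all replicate points.
    Initialisation: baseline = min reading, plateau = max reading, Kd = the
    concentration nearest the half-maximal mean.  Standard errors come from
    the fit covariance.  Unless ``apply_nd`` is disabled, the ND decision
    rule (:func:`call_nd`) is applied to the result.
    """
    if titration.concentrations.size < 5:
        raise ValueError("at least 5 distinct concentrations required")
    means = titration.replicate_means()
    if per_replicate:
        x = np.repeat(titration.concentrations, titration.n_replicates)
        y = titration.readings.ravel()
    else:
        x, y = titration.concentrations, means

    half = (means.min() + means.max()) / 2.0
    kd0 = titration.concentrations[int(np.argmin(np.abs(means - half)))]
    p0 = (kd0, means.min(), means.max())

    if model == "one-site":
        model_fn = lambda c, kd, b, p: b + (p - b) * c / (kd + c)
    elif model == "quadratic":
        probe_uM = titration.probe_concentration / 1000.0
        model_fn = lambda c, kd, b, p: quadratic_depletion_model(
            c, kd, b, p, probe_uM=probe_uM
        )
    else:
        raise ValueError("model must be 'one-site' or 'quadratic'")

    try:
        (kd, baseline, plateau), (kd_se, b_se, p_se) = _fit_curve(x, y, model_fn, p0)
    except (RuntimeError, ValueError):
        fit = BindingFit(
            kd=math.nan, baseline=math.nan, plateau=math.nan,
            status="ND", model=model, nd_reason="fit did not converge",
        )
        return fit

    residuals = means - model_fn(titration.concentrations, kd, baseline, plateau)
    dof = max(residuals.size - 3, 1)
    residual_sd = float(np.sqrt(np.sum(residuals**2) / dof))
    fit = BindingFit(
        kd=float(kd), baseline=float(baseline), plateau=float(plateau),
        kd_se=float(kd_se), baseline_se=float(b_se), plateau_se=float(p_se),
        status="OK" if kd > 0 and plateau > baseline else "ND",
        residual_sd=residual_sd, model=model,
    )
    if fit.status == "ND" and fit.nd_reason is None:
        fit = replace(fit, nd_reason="non-binding response shape")
    if apply_nd:
        fit = call_nd(
            fit,
            titration,
            min_dynamic_range_sds=min_dynamic_range_sds,
            max_kd_factor=max_kd_factor,
            min_kd_factor=min_kd_factor,
        )
    return fit


def call_nd(
    fit: BindingFit,
    titration: FPTitration,
    min_dynamic_range_sds: float = 3.0,
    max_kd_factor: float = 1.0,
    min_kd_factor: float = 1.0,
) -> BindingFit:
    """Apply the not-determined rule to a fit.

    ND when any of: the fit failed; the fitted Kd extrapolates beyond
    ``max_kd_factor`` × the highest tested concentration; the fitted Kd
    falls below ``min_kd_factor`` × the lowest tested concentration (the
    curve would be saturated before the first point, so the baseline is an
    extrapolation and the Kd undetermined); the fitted dynamic range
    (plateau − baseline) is below ``min_dynamic_range_sds`` residual
    standard deviations (or essentially zero); or the response decreases
    (plateau ≤ baseline).
    """
    if fit.status == "ND":
        return fit
    top = float(titration.concentrations[-1])
    bottom = float(titration.concentrations[0])
    reason = None
    dyn_range = fit.plateau - fit.baseline
    if not math.isfinite(fit.kd) or fit.kd <= 0:
        reason = "no positive Kd"
    elif fit.kd > max_kd_factor * top:
        reason = f"Kd {fit.kd:.3g} µM beyond tested range (top {top:.3g} µM)"
    elif fit.kd < min_kd_factor * bottom:
        reason = (
            f"Kd {fit.kd:.3g} µM below tested range (bottom {bottom:.3g} µM); "
            "curve saturated before the first point"
        )
    elif dyn_range <= _RANGE_FLOOR_MP:
        reason = "zero dynamic range"
    elif math.isfinite(fit.residual_sd) and dyn_range < (
        min_dynamic_range_sds * fit.residual_sd
    ):
        reason = (
            f"dynamic range {dyn_range:.3g} mP below "
            f"{min_dynamic_range_sds:g} × residual SD"
        )
    if reason is None:
        return fit
    return replace(
        fit,
        status="ND",
        nd_reason=reason,
        kd=math.nan,
        kd_se=math.nan,
    )


def kd_ratio(fit_a: BindingFit, fit_b: BindingFit) -> float:
    """Affinity fold-difference Kd(b)/Kd(a); *a* is the tighter binder by
    convention, so a ratio > 1 means *a* binds tighter.

    Raises for any ND input — a fold-difference against an undetermined
    affinity is meaningless.
    """
    for fit, name in ((fit_a, "a"), (fit_b, "b")):
        if fit.status != "OK":
            raise ValueError(f"fit {name} is ND; kd_ratio requires two OK fits")
    return fit_b.kd / fit_a.kd


# --- CSV interchange -------------------------------------------------------


def write_titration_csv(titration: FPTitration, stream: TextIO) -> None:
    """Write a titration as CSV with columns conc_uM, rep1..repN (mP)."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(
        ["conc_uM"] + [f"rep{i + 1}" for i in range(titration.n_replicates)]
    )
    for conc, row in zip(titration.concentrations, titration.readings):
        writer.writerow([f"{conc:.6g}"] + [f"{v:.6f}" for v in row])


def read_titration_csv(
    stream: TextIO, probe_concentration: float = DEFAULT_PROBE_NM
) -> FPTitration:
    """Read a conc_uM, rep1..repN CSV back into an :class:`FPTitration`."""
    reader = csv.reader(stream)
    header = next(reader, None)
    if not header or header[0] != "conc_uM" or len(header) < 2:
        raise ValueError("titration CSV must start with conc_uM, rep1..repN")
    conc, rows = [], []
    for row in reader:
        if not row:
            continue
        if len(row) != len(header):
            raise ValueError(f"ragged titration row: {row}")
        conc.append(float(row[0]))
        rows.append([float(v) for v in row[1:]])
    if not conc:
        raise ValueError("titration CSV contains no data rows")
    return FPTitration(
        concentrations=np.array(conc),
        readings=np.array(rows),
        probe_concentration=probe_concentration,
    )
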