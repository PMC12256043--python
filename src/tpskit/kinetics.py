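"""Michaelis–Menten kinetics from malachite-green phosphate-release assays.

The assay couples prenyl-diphosphate turnover to inorganic phosphate: each
turnover releases one pyrophosphate (PPi), which inorganic pyrophosphatase
hydrolyses to two Pi; malachite green then reports Pi as absorbance at
623 nm.  The analysis path is:

1. fit a linear Pi standard curve A = slope·[Pi] + intercept,
2. convert endpoint absorbances to initial rates
   v = Pi / (pi_per_turnover · t) assuming the 30-min endpoint stays in the
   initial-rate regime,
3. fit v = Vmax·S / (Km + S) by non-linear least squares,
4. convert Vmax to a turnover number kcat = Vmax / E0.

The effective enzyme-concentration divisor E0 defaults to
``reference.DEFAULT_EFFECTIVE_E0`` (10 in Vmax's concentration unit), the
value implied by the published panel's Vmax/kcat ratios; see docs/methods.md
for why this differs from the nominal 0.014 µM assay concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .errors import InputError, ParameterError
from .reference import DEFAULT_EFFECTIVE_E0

logger = logging.getLogger(__name__)

#: Pi ions produced per enzymatic turnover (PPi hydrolysed to 2 Pi).
DEFAULT_PI_PER_TURNOVER: int = 2


def michaelis_menten(S, vmax: float, km: float):
    """Michaelis–Menten rate law v = Vmax·S/(Km+S)."""
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S)


@dataclass(frozen=True)
class StandardCurve:
    analyte: str  # "Pi" or "PPi"
    concentrations_uM: np.ndarray
    absorbances_AU: np.ndarray
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class MMDataset:
    """One enzyme–substrate rate series.

    ``enzyme_conc`` is the effective E0 used for the kcat conversion; it
    defaults to the divisor implied by the published panel rather than the
    nominal assay concentration.
    """

    enzyme_id: str
    substrate: str
    substrate_uM: np.ndarray
    rate_uM_per_s: np.ndarray
    enzyme_conc: float = DEFAULT_EFFECTIVE_E0
    incubation_s: float = 1800.0

    def __post_init__(self) -> None:
        S = np.asarray(self.substrate_uM, dtype=float)
        v = np.asarray(self.rate_uM_per_s, dtype=float)
        object.__setattr__(self, "substrate_uM", S)
        object.__setattr__(self, "rate_uM_per_s", v)
        if len(S) != len(v) or len(S) < 5:
            raise InputError("need >= 5 matched substrate/rate points")
        if np.any(S <= 0):
            raise InputError("substrate concentrations must be strictly positive")
        if np.any(v < 0):
            raise InputError("rates must be non-negative")


@dataclass(frozen=True)
class MMFit:
    enzyme_id: str
    substrate: str
    km_uM: float
    vmax_uM_per_s: float
    kcat_per_s: float
    km_se: float
    vmax_se: float
    converged: bool


def fit_standard_curve(
    concentrations_uM, absorbances_AU, analyte: str = "Pi"
) -> StandardCurve:
    """Ordinary least-squares line through a standard series."""
    c = np.asarray(concentrations_uM, dtype=float)
    a = np.asarray(absorbances_AU, dtype=float)
    if len(c) != len(a) or len(c) < 3:
        raise InputError("standard curve needs >= 3 matched points")
    if np.ptp(c) == 0:
        raise InputError("standard concentrations are degenerate (all equal)")
    res = stats.linregress(c, a)
    return StandardCurve(
        analyte=analyte,
        concentrations_uM=c,
        absorbances_AU=a,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def absorbance_to_rate(
    absorbance: float,
    background: float,
    curve: StandardCurve,
    incubation_s: float,
    pi_per_turnover: int = DEFAULT_PI_PER_TURNOVER,
) -> float:
    """Convert one endpoint absorbance to an initial rate (µM substrate / s).

    ``background`` is the matrix absorbance in excess of the standard-curve
    blank (for plates generated by this package: mean(background wells) minus
    the standard-curve intercept).  Negative net phosphate is floored at zero
    with a warning.
    """
    if curve.slope <= 0:
        raise InputError("standard curve slope must be positive")
    if incubation_s <= 0:
        raise ParameterError("incubation time must be positive")
    if pi_per_turnover < 1:
        raise ParameterError("pi_per_turnover must be >= 1")
    net = (absorbance - background - curve.intercept) / curve.slope
    if net < 0:
        logger.warning("negative net phosphate (%.4g µM); clamping to 0", net)
        net = 0.0
    return net / (pi_per_turnover * incubation_s)


def fit_michaelis_menten(dataset: MMDataset) -> MMFit:
    """Unweighted non-linear least-squares Michaelis–Menten fit.

    Initialised at Vmax0 = 1.2·max(v) and Km0 = the substrate level whose rate
    is nearest half-maximal; positivity is enforced through bounds.  Standard
    errors come from the Gauss–Newton curvature at the optimum.
    """
    S, v = dataset.substrate_uM, dataset.rate_uM_per_s
    if np.all(v == 0):
        raise InputError("all rates are zero; nothing to fit")

    vmax0 = 1.2 * float(np.max(v))
    km0 = float(S[np.argmin(np.abs(v - np.max(v) / 2.0))])
    km0 = max(km0, 1e-9)

    def residuals(p):
        vmax, km = p
        return michaelis_menten(S, vmax, km) - v

    sol = least_squares(
        residuals,
        x0=[vmax0, km0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=10000,
    )
    vmax, km = float(sol.x[0]), float(sol.x[1])
    converged = bool(sol.success)
    if not converged:
        logger.warning(
            "Michaelis–Menten fit did not converge for %s/%s",
            dataset.enzyme_id, dataset.substrate,
        )

    # covariance from J^T J at the optimum
    dof = max(len(S) - 2, 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * (2.0 * sol.cost / dof)
        vmax_se, km_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        vmax_se = km_se = float("nan")

    return MMFit(
        enzyme_id=dataset.enzyme_id,
        substrate=dataset.substrate,
        km_uM=km,
        vmax_uM_per_s=vmax,
        kcat_per_s=compute_kcat(vmax, dataset.enzyme_conc),
        km_se=km_se,
        vmax_se=vmax_se,
        converged=converged,
    )


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal half-up rounding, tolerant of float representation error.

    The value is first snapped to 10 decimals so that a number numerically
    indistinguishable from an exact half-way point (e.g. a fitted 0.018950…)
    rounds up as a chemist reading the table would expect, instead of falling
    on the wrong side of the binary representation.
    """
    snapped = round(float(x), 10)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(snapped)).quantize(q, rounding=ROUND_HALF_UP))


def compute_kcat(
    vmax_uM_per_s: float,
    enzyme_conc: float = DEFAULT_EFFECTIVE_E0,
    rounded: bool = False,
) -> float:
    """Turnover number kcat = Vmax / E0 (s⁻¹).

    With ``rounded=True`` the value is reported at the panel table's 4-decimal
    precision (half-up); otherwise full precision is returned.
    """
    if enzyme_conc <= 0:
        raise ParameterError("enzyme concentration must be positive")
    kcat = float(vmax_uM_per_s) / float(enzyme_conc)
    return round_half_up(kcat, 4) if rounded else kcat


def summarize_panel(fits: list[MMFit]) -> tuple[pd.DataFrame, dict]:
    """Tabulate a panel of fits and report the kcat range across it.

    Returns ``(table, summary)`` where the table mirrors the published panel
    shape (enzyme × substrate × Km, Vmax, kcat with kcat at 4 decimals) and
    the summary holds min/max kcat over converged fits.  Non-converged fits
    are kept in the table but excluded from the range.
    """
    if not fits:
        raise InputError("no fits supplied")
    table = pd.DataFrame(
        [
            {
                "enzyme_id": f.enzyme_id,
                "substrate": f.substrate,
                "km_uM": f.km_uM,
                "km_se": f.km_se,
                "vmax_uM_per_s": f.vmax_uM_per_s,
                "vmax_se": f.vmax_se,
                "kcat_per_s": round_half_up(f.kcat_per_s, 4),
                "converged": f.converged,
            }
            for f in fits
        ]
    )
    converged = table[table["converged"]]
    if len(converged) == 0:
        summary = {"kcat_min": float("nan"), "kcat_max": float("nan"),
                   "no_converged_fits": True}
    else:
        summary = {
            "kcat_min": float(converged["kcat_per_s"].min()),
            "kcat_max": float(converged["kcat_per_s"].max()),
            "no_converged_fits": False,
        }
    return table, summary


def rates_from_plate(
    plate: pd.DataFrame,
    enzyme_id: str = "enzyme",
    substrate: str = "GPP",
    incubation_s: float = 1800.0,
    pi_per_turnover: int = DEFAULT_PI_PER_TURNOVER,
    enzyme_conc: float = DEFAULT_EFFECTIVE_E0,
) -> tuple[MMDataset, StandardCurve]:
    """Full plate reduction: standard curve, background, per-well rates.

    ``plate`` is the long plate table with columns ``well, role, substrate_uM,
    analyte_uM, absorbance, replicate`` where role ∈ {sample, standard,
    background}.  Replicate rates at the same substrate level are averaged.
    """
    required = {"well", "role", "substrate_uM", "analyte_uM", "absorbance", "replicate"}
    if not required.issubset(plate.columns):
        raise InputError(f"plate table must have columns {sorted(required)}")
    std = plate[plate["role"] == "standard"]
    if len(std) < 3:
        raise InputError("plate has fewer than 3 standard wells")
    curve = fit_standard_curve(std["analyte_uM"], std["absorbance"])
    bg_wells = plate[plate["role"] == "background"]
    bg_mean = float(bg_wells["absorbance"].mean()) if len(bg_wells) else curve.intercept
    background = bg_mean - curve.intercept

    samples = plate[plate["role"] == "sample"]
    if len(samples) == 0:
        raise InputError("plate has no sample wells")
    rows = []
    for s_level, grp in samples.groupby("substrate_uM", sort=True):
        rate = float(
            np.mean(
                [
                    absorbance_to_rate(a, background, curve, incubation_s, pi_per_turnover)
                    for a in grp["absorbance"].astype(float)
                ]
            )
        )
        rows.append((float(s_level), rate))
    S = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    dataset = MMDataset(
        enzyme_id=enzyme_id,
        substrate=substrate,
        substrate_uM=S,
        rate_uM_per_s=v,
        enzyme_conc=enzyme_conc,
        incubation_s=incubation_s,
    )
    return dataset, curve
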