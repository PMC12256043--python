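"""Differential scanning fluorimetry (thermofluor) analysis.

A hydrophobic dye (e.g. SYPRO Orange) binds exposed hydrophobic patches as a
protein unfolds with temperature, producing a sigmoidal rise in fluorescence.
The melting temperature Tm is the midpoint of that transition.  This module
models a melt curve as a two-state unfolding sigmoid on a linear
pre-transition baseline, with a linear post-transition decay capturing dye
dissociation from aggregates:

    F(T) = a + b·T + A / (1 + exp((Tm − T)/s)) + c·max(T − Tm, 0)

where ``a`` and ``b`` are the folded-state baseline, ``A`` the transition
amplitude, ``s`` the transition steepness (°C) and ``c`` the post-transition
slope (typically negative).

Tm can be estimated either by non-linear least squares on this model
("boltzmann") or from the maximum of the smoothed first derivative dF/dT
("derivative").  Buffer-screen analysis then compares each condition's Tm to a
water-control reference (ΔTm), ranks conditions by their median ΔTm across a
protein panel, and flags conditions whose shift exceeds the +4 °C
stabilisation threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

#: ΔTm above which a buffer condition counts as significantly stabilising
#: (strict inequality).
STABILISATION_THRESHOLD_C: float = 4.0

#: Default 8 buffer/pH systems of the 80-condition storage-buffer screen.
DEFAULT_BUFFERS: tuple[tuple[str, float], ...] = (
    ("MES", 5.5), ("Bis-Tris", 6.0), ("HEPES", 7.0), ("HEPES", 7.5),
    ("Tris", 7.5), ("Tris", 8.0), ("Tris", 8.5), ("CAPS", 9.0),
)
DEFAULT_SALTS: tuple[str, ...] = ("NaCl", "KCl", "MgCl2")
DEFAULT_SALT_MM: tuple[float, ...] = (50.0, 100.0, 200.0)


def two_state_fluorescence(T, baseline, slope_pre, amplitude, tm, steepness, slope_post):
    """Two-state melt model with linear baseline and post-transition decay."""
    T = np.asarray(T, dtype=float)
    sigmoid = amplitude / (1.0 + np.exp((tm - T) / steepness))
    return baseline + slope_pre * T + sigmoid + slope_post * np.maximum(T - tm, 0.0)


@dataclass(frozen=True)
class MeltCurve:
    """One condition's fluorescence-vs-temperature trace."""

    condition_id: str
    protein_id: str
    temperatures_C: np.ndarray
    fluorescence_AU: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures_C, dtype=float)
        F = np.asarray(self.fluorescence_AU, dtype=float)
        object.__setattr__(self, "temperatures_C", T)
        object.__setattr__(self, "fluorescence_AU", F)
        if T.ndim != 1 or F.ndim != 1 or len(T) != len(F):
            raise InputError("temperature and fluorescence must be equal-length 1-D arrays")
        if len(T) < 10:
            raise InputError(f"melt curve needs >= 10 points, got {len(T)}")
        if np.any(np.diff(T) <= 0):
            raise InputError("temperatures must be strictly increasing")
        if T[0] < 0 or T[-1] > 120:
            raise InputError("temperatures must lie within [0, 120] °C")


@dataclass(frozen=True)
class TmResult:
    condition_id: str
    tm_C: float | None
    method: str
    amplitude_AU: float
    fit_rmse: float
    transition_detected: bool


@dataclass(frozen=True)
class DeltaTmEntry:
    condition_id: str
    delta_tm_C: float | None
    stabilising: bool
    no_transition: bool = False


@dataclass(frozen=True)
class BufferCondition:
    condition_id: str
    buffer_name: str
    buffer_mM: float
    pH: float
    salt_name: str | None
    salt_mM: float


@dataclass(frozen=True)
class BufferScreenDesign:
    conditions: tuple[BufferCondition, ...]

    def __post_init__(self) -> None:
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ConfigError("condition ids must be unique")
        for c in self.conditions:
            if not (3.0 <= c.pH <= 11.0):
                raise ConfigError(f"pH {c.pH} outside [3, 11] in {c.condition_id}")
            if c.salt_mM < 0:
                raise ConfigError(f"negative salt concentration in {c.condition_id}")

    def ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions]

    def __len__(self) -> int:
        return len(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition_id": c.condition_id,
                    "buffer": c.buffer_name,
                    "buffer_mM": c.buffer_mM,
                    "pH": c.pH,
                    "salt": c.salt_name or "",
                    "salt_mM": c.salt_mM,
                }
                for c in self.conditions
            ]
        )


def _derivative_tm(T: np.ndarray, F: np.ndarray) -> tuple[float, float]:
    """Peak of the smoothed, baseline-corrected dF/dT in the rising phase.

    Returns ``(tm, peak_derivative)``.  The derivative is obtained by local
    quadratic (Savitzky–Golay) smoothing over a 5-point window.  Before
    peak-finding, the pre-transition slope and the post-transition decay are
    subtracted (the latter weighted by the apparent unfolded fraction), which
    removes the downward bias the decay would otherwise impose on broad
    transitions.  The peak location is then refined by a parabola through the
    maximum and its two neighbours, so a midpoint between grid points is
    still resolved.
    """
    dT = float(np.median(np.diff(T)))
    window = min(5, len(F) if len(F) % 2 else len(F) - 1)
    dFdT = savgol_filter(F, window_length=window, polyorder=2, deriv=1, delta=dT)

    # baseline correction: pre-slope b from the leading points, extra
    # post-transition slope c from the trailing points, weighted by the
    # apparent unfolded fraction so it only acts past the transition
    n_edge = min(6, len(T) // 3)
    b = float(np.polyfit(T[:n_edge], F[:n_edge], 1)[0])
    c = float(np.polyfit(T[-n_edge:], F[-n_edge:], 1)[0]) - b
    baseline_line = F[0] + b * (T - T[0])
    rise = F - baseline_line
    amp_est = float(np.max(rise))
    if amp_est > 0:
        theta = np.clip(rise / amp_est, 0.0, 1.0)
        dFdT = dFdT - b - c * theta

    # restrict to the rising phase: up to the fluorescence maximum
    i_max_f = int(np.argmax(F))
    hi = max(i_max_f, 2)
    segment = dFdT[: hi + 1]
    i = int(np.argmax(segment))
    peak = float(segment[i])
    if 0 < i < len(segment) - 1:
        y0, y1, y2 = segment[i - 1], segment[i], segment[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            return float(T[i] + shift * dT), peak
    return float(T[i]), peak


def _fit_boltzmann(T: np.ndarray, F: np.ndarray, tm0: float):
    """Least-squares fit of the two-state model; returns (params, rmse)."""
    n_edge = min(6, len(T) // 3)
    b0 = float(np.polyfit(T[:n_edge], F[:n_edge], 1)[0])
    a0 = float(F[0] - b0 * T[0])
    amp0 = max(float(np.ptp(F) - abs(b0) * np.ptp(T)), 1e-3 * max(np.ptp(F), 1.0), 1e-9)
    c0 = float(np.polyfit(T[-n_edge:], F[-n_edge:], 1)[0]) - b0
    p0 = [a0, b0, amp0, tm0, 1.5, c0]
    lo = [-np.inf, -np.inf, 0.0, float(T[0]), 0.05, -np.inf]
    hi = [np.inf, np.inf, np.inf, float(T[-1]), 30.0, np.inf]
    params, _ = curve_fit(
        two_state_fluorescence, T, F, p0=p0, bounds=(lo, hi), maxfev=20000
    )
    resid = F - two_state_fluorescence(T, *params)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return params, rmse


def estimate_tm(curve: MeltCurve, method: str = "boltzmann") -> TmResult:
    """Estimate the melting temperature of one melt curve.

    ``method="boltzmann"`` fits the full two-state model (initialised from the
    derivative estimate); ``method="derivative"`` reports the refined peak of
    the smoothed first derivative.  A transition is declared absent when the
    fitted amplitude is below three times the residual RMSE or the fitted Tm
    falls within 2 °C of either end of the scanned range.
    """
    if method not in ("boltzmann", "derivative"):
        raise InputError(f"unknown method {method!r}")
    T, F = curve.temperatures_C, curve.fluorescence_AU

    scale = float(np.ptp(F))
    if scale <= 1e-12 * max(1.0, abs(float(np.mean(F)))):
        return TmResult(curve.condition_id, None, method, 0.0, 0.0, False)

    tm_deriv, _peak = _derivative_tm(T, F)
    try:
        params, rmse = _fit_boltzmann(T, F, tm_deriv)
        amplitude, tm_fit = float(params[2]), float(params[3])
    except RuntimeError:
        # fit failed to converge: fall back on derivative location, treat the
        # raw range as the amplitude and declare no transition conservatively
        logger.warning("Boltzmann fit failed for %s", curve.condition_id)
        return TmResult(curve.condition_id, None, method, scale, float("nan"), False)

    detected = amplitude >= max(3.0 * rmse, 1e-9) and (
        T[0] + 2.0 < tm_fit < T[-1] - 2.0
    )
    tm = tm_fit if method == "boltzmann" else tm_deriv
    return TmResult(
        condition_id=curve.condition_id,
        tm_C=tm if detected else None,
        method=method,
        amplitude_AU=amplitude,
        fit_rmse=rmse,
        transition_detected=detected,
    )


def compute_delta_tm(tm_condition_C: float | None, tm_reference_C: float | None) -> float | None:
    """Thermal shift of a condition relative to the reference; None propagates."""
    if tm_condition_C is None or tm_reference_C is None:
        return None
    if not (np.isfinite(tm_condition_C) and np.isfinite(tm_reference_C)):
        raise InputError("Tm values must be finite")
    return float(tm_condition_C) - float(tm_reference_C)


def delta_tm_entry(
    condition_id: str,
    tm_condition_C: float | None,
    tm_reference_C: float | None,
    threshold_C: float = STABILISATION_THRESHOLD_C,
) -> DeltaTmEntry:
    delta = compute_delta_tm(tm_condition_C, tm_reference_C)
    if delta is None:
        return DeltaTmEntry(condition_id, None, stabilising=False, no_transition=True)
    return DeltaTmEntry(condition_id, delta, stabilising=delta > threshold_C)


def rank_buffers(
    results: pd.DataFrame, threshold_C: float = STABILISATION_THRESHOLD_C
) -> pd.DataFrame:
    """Rank buffer conditions by median ΔTm across a protein panel.

    ``results`` is a long table with columns ``protein_id``, ``condition_id``
    and ``delta_tm_C`` (NaN marks a condition/protein pair with no detected
    transition; such pairs are excluded from that condition's median and
    counted in ``n_no_transition``).  The output is sorted by median ΔTm
    descending with ties broken on condition_id.
    """
    if results is None or len(results) == 0:
        raise InputError("no ΔTm results supplied")
    required = {"protein_id", "condition_id", "delta_tm_C"}
    if not required.issubset(results.columns):
        raise InputError(f"results must have columns {sorted(required)}")

    rows = []
    for cid, grp in results.groupby("condition_id", sort=False):
        vals = grp["delta_tm_C"].astype(float)
        ok = vals.dropna()
        median = float(ok.median()) if len(ok) else float("nan")
        rows.append(
            {
                "condition_id": cid,
                "median_delta_tm_C": median,
                "n_proteins": int(len(ok)),
                "n_no_transition": int(vals.isna().sum()),
                "stabilising": bool(len(ok)) and median > threshold_C,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["median_delta_tm_C", "condition_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return table


def best_condition_per_protein(results: pd.DataFrame) -> pd.DataFrame:
    """Most-stabilising condition per protein (panel-summary shape).

    ``results`` columns: ``protein_id``, ``condition_id``, ``tm_C``,
    ``delta_tm_C`` (NaN = no transition).  Ties on ΔTm break toward the lower
    condition_id.  Proteins with no detected transition anywhere get a row
    with condition "none".
    """
    if results is None or len(results) == 0:
        raise InputError("no results supplied")
    rows = []
    for pid, grp in results.groupby("protein_id", sort=False):
        ok = grp.dropna(subset=["delta_tm_C"])
        if len(ok) == 0:
            rows.append(
                {"protein_id": pid, "condition_id": "none", "tm_C": float("nan"),
                 "delta_tm_C": float("nan")}
            )
            continue
        ok = ok.sort_values(["delta_tm_C", "condition_id"], ascending=[False, True])
        best = ok.iloc[0]
        rows.append(
            {
                "protein_id": pid,
                "condition_id": best["condition_id"],
                "tm_C": float(best["tm_C"]),
                "delta_tm_C": float(best["delta_tm_C"]),
            }
        )
    return pd.DataFrame(rows)


def make_buffer_screen(
    buffers: tuple[tuple[str, float], ...] = DEFAULT_BUFFERS,
    salts: tuple[str, ...] = DEFAULT_SALTS,
    salt_mM: tuple[float, ...] = DEFAULT_SALT_MM,
    buffer_mM: float = 100.0,
) -> BufferScreenDesign:
    """Enumerate the storage-buffer screen design.

    Buffer-major order; within each buffer/pH system the no-salt condition
    comes first, then each salt in the configured order at ascending
    concentration.  The default configuration yields the 80-condition screen
    (8 buffer/pH systems × (1 no-salt + 3 salts × 3 concentrations)).
    """
    if not buffers:
        raise ConfigError("buffer list must be non-empty")
    if len(set(buffers)) != len(buffers):
        raise ConfigError("duplicate buffer/pH pairs in configuration")
    if any(c < 0 for c in salt_mM):
        raise ConfigError("salt concentrations must be non-negative")

    conditions: list[BufferCondition] = []
    idx = 1
    for name, ph in buffers:
        conditions.append(
            BufferCondition(f"B{idx:02d}", name, buffer_mM, ph, None, 0.0)
        )
        idx += 1
        for salt in salts:
            for conc in sorted(salt_mM):
                conditions.append(
                    BufferCondition(f"B{idx:02d}", name, buffer_mM, ph, salt, conc)
                )
                idx += 1
    return BufferScreenDesign(tuple(conditions))


def analyse_buffer_screen(
    curves_by_protein: dict[str, list[MeltCurve]],
    reference_id: str = "REF",
    method: str = "boltzmann",
    threshold_C: float = STABILISATION_THRESHOLD_C,
) -> pd.DataFrame:
    """Estimate Tm for every curve and tabulate ΔTm against the water control.

    Each protein's curve list must contain one curve whose condition_id equals
    ``reference_id``.  Returns a long table (protein_id, condition_id, tm_C,
    delta_tm_C, stabilising) with NaN for undetected transitions.
    """
    rows = []
    for pid, curves in curves_by_protein.items():
        by_id = {c.condition_id: c for c in curves}
        if reference_id not in by_id:
            raise InputError(f"protein {pid} has no reference curve {reference_id!r}")
        ref = estimate_tm(by_id[reference_id], method)
        for cid, curve in by_id.items():
            if cid == reference_id:
                continue
            res = estimate_tm(curve, method)
            entry = delta_tm_entry(cid, res.tm_C, ref.tm_C, threshold_C)
            rows.append(
                {
                    "protein_id": pid,
                    "condition_id": cid,
                    "tm_C": res.tm_C if res.tm_C is not None else float("nan"),
                    "delta_tm_C": entry.delta_tm_C
                    if entry.delta_tm_C is not None
                    else float("nan"),
                    "stabilising": entry.stabilising,
                }
            )
    return pd.DataFrame(rows)
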