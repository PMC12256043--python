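"""GC-MS product-profile analysis for terpene synthase assays.

Peak tables (retention time, integrated area, compound assignment) are turned
into percent-of-total terpene compositions.  Boiled-enzyme control peaks are
subtracted as assay background; the spiked internal standard
(isobutylbenzene) and chromatographic peaks that are neither monoterpenes nor
sesquiterpenes are excluded from the percentage denominator, mirroring how
multi-product synthase profiles are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InputError
from .lexicon import CompoundLexicon, load_compound_lexicon

logger = logging.getLogger(__name__)

TERPENE_CLASSES = ("monoterpene", "sesquiterpene")

#: Default retention-time matching tolerance for background subtraction (min).
DEFAULT_RT_TOL_MIN: float = 0.10


@dataclass(frozen=True)
class Peak:
    rt_min: float
    area: float
    compound: str | None = None
    match_score: float | None = None
    klass: str = "unknown"
    putative: bool = False

    def __post_init__(self) -> None:
        if self.area < 0:
            raise InputError(f"negative peak area {self.area}")
        if self.rt_min < 0:
            raise InputError(f"negative retention time {self.rt_min}")


@dataclass(frozen=True)
class PeakTable:
    sample_id: str
    substrate: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        n_is = sum(1 for p in self.peaks if p.klass == "internal_standard")
        if n_is > 1:
            raise InputError("at most one internal-standard peak allowed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": self.sample_id,
                    "substrate": self.substrate,
                    "rt_min": p.rt_min,
                    "area": p.area,
                    "compound": p.compound or "",
                    "match_score": p.match_score,
                    "class": p.klass,
                    "putative": p.putative,
                }
                for p in self.peaks
            ]
        )


@dataclass(frozen=True)
class ProductProfile:
    sample_id: str
    substrate: str
    composition: dict[str, float]  # compound -> percent, 2 decimals
    excluded: tuple[tuple[str, str], ...]  # (compound, reason)
    active: bool


def subtract_background(
    sample: PeakTable, control: PeakTable, rt_tol_min: float = DEFAULT_RT_TOL_MIN
) -> PeakTable:
    """Remove or reduce sample peaks that also appear in the boiled control.

    A sample peak whose retention time matches a control peak within
    ``rt_tol_min`` is dropped when its area is at most twice the control area
    (indistinguishable from background) and otherwise retained with the
    control area subtracted.
    """
    if rt_tol_min <= 0:
        raise InputError("rt_tol_min must be positive")
    kept: list[Peak] = []
    for peak in sample.peaks:
        match = None
        best = rt_tol_min
        for ctrl in control.peaks:
            d = abs(ctrl.rt_min - peak.rt_min)
            if d <= best:
                match, best = ctrl, d
        if match is None:
            kept.append(peak)
        elif peak.area > 2.0 * match.area:
            kept.append(replace(peak, area=max(peak.area - match.area, 0.0)))
        # else: dropped as background
    return PeakTable(sample.sample_id, sample.substrate, tuple(kept))


def classify_peaks(
    table: PeakTable, library: CompoundLexicon | None = None
) -> PeakTable:
    """Assign compound classes and putative flags from the compound lexicon.

    Unrecognised compound names become class ``unknown``; the internal
    standard is recognised by name.
    """
    lex = library or load_compound_lexicon()
    peaks = []
    for peak in table.peaks:
        entry = lex.get(peak.compound) if peak.compound else None
        if entry is None:
            peaks.append(replace(peak, klass="unknown"))
        else:
            peaks.append(
                replace(peak, klass=entry.klass, putative=entry.putative)
            )
    return PeakTable(table.sample_id, table.substrate, tuple(peaks))


def percent_composition(
    table: PeakTable,
    alias_parent: bool = False,
    library: CompoundLexicon | None = None,
) -> ProductProfile:
    """Percent-of-total terpene composition of a classified peak table.

    Only monoterpene and sesquiterpene peaks enter the denominator; the
    internal standard, non-terpene artefacts and unknowns are listed under
    ``excluded`` with their reasons.  With ``alias_parent=True``, compounds
    recorded as thermal-degradation artefacts (e.g. elemol) are reported under
    their parent name (hedycaryol).  A table with no terpene area yields an
    inactive profile.
    """
    lex = library or load_compound_lexicon()
    terpene_peaks = [p for p in table.peaks if p.klass in TERPENE_CLASSES]
    excluded = []
    for p in table.peaks:
        if p.klass not in TERPENE_CLASSES:
            reason = {
                "internal_standard": "internal standard",
                "non_terpene": "not a mono- or sesquiterpene",
            }.get(p.klass, "unidentified")
            excluded.append((p.compound or f"RT {p.rt_min:.2f}", reason))

    denominator = sum(p.area for p in terpene_peaks)
    if denominator <= 0:
        return ProductProfile(table.sample_id, table.substrate, {}, tuple(excluded), False)

    composition: dict[str, float] = {}
    for p in terpene_peaks:
        name = p.compound or f"RT {p.rt_min:.2f}"
        if alias_parent:
            entry = lex.get(name)
            if entry is not None and entry.alias_of:
                name = entry.alias_of
        composition[name] = composition.get(name, 0.0) + 100.0 * p.area / denominator
    composition = {k: round(v, 2) for k, v in composition.items()}
    return ProductProfile(table.sample_id, table.substrate, composition, tuple(excluded), True)


def substrate_activity_matrix(profiles: list[ProductProfile]) -> pd.DataFrame:
    """Classify each enzyme by which prenyl-diphosphate substrates it accepts.

    Activity on GPP alone gives "Mono", on FPP alone "Sesqui", on both
    "Mono/Sesqui", and no active profile "inactive".  GGPP assays are recorded
    (all-inactive GGPP panels are the expected outcome for mono/sesqui
    synthases).
    """
    by_enzyme: dict[str, dict[str, bool]] = {}
    for prof in profiles:
        by_enzyme.setdefault(prof.sample_id, {})[prof.substrate] = (
            by_enzyme.setdefault(prof.sample_id, {}).get(prof.substrate, False)
            or prof.active
        )
    rows = []
    for enzyme, acts in by_enzyme.items():
        gpp = acts.get("GPP", False)
        fpp = acts.get("FPP", False)
        if gpp and fpp:
            label = "Mono/Sesqui"
        elif gpp:
            label = "Mono"
        elif fpp:
            label = "Sesqui"
        else:
            label = "inactive"
        rows.append(
            {
                "enzyme_id": enzyme,
                "classification": label,
                "ggpp_tested": "GGPP" in acts,
                "ggpp_active": acts.get("GGPP", False),
            }
        )
    return pd.DataFrame(rows)


def match_spectrum(query, reference) -> float:
    """Transparent spectral-similarity score on a 0–1000 scale.

    1000 × squared cosine similarity of square-root-scaled intensity vectors
    over a shared m/z binning — the classic dot-product score shape used for
    library matching.  Symmetric and scale-invariant; an all-zero spectrum
    scores 0 with a warning.
    """
    q = np.sqrt(np.asarray(query, dtype=float))
    r = np.sqrt(np.asarray(reference, dtype=float))
    if q.shape != r.shape:
        raise InputError("spectra must share the same binning")
    if np.any(q < 0) or np.any(r < 0):
        raise InputError("intensities must be non-negative")
    nq, nr = np.linalg.norm(q), np.linalg.norm(r)
    if nq == 0 or nr == 0:
        logger.warning("all-zero spectrum; score undefined, returning 0")
        return 0.0
    cos = float(np.dot(q, r) / (nq * nr))
    return 1000.0 * cos * cos


def profile_report(profiles: list[ProductProfile]) -> pd.DataFrame:
    """Long-form report table (enzyme, substrate, compound, percent)."""
    rows = []
    for prof in profiles:
        if not prof.active:
            rows.append(
                {"sample_id": prof.sample_id, "substrate": prof.substrate,
                 "compound": "", "percent": math.nan, "active": False}
            )
            continue
        for compound, pct in sorted(prof.composition.items(), key=lambda kv: -kv[1]):
            rows.append(
                {"sample_id": prof.sample_id, "substrate": prof.substrate,
                 "compound": compound, "percent": pct, "active": True}
            )
    return pd.DataFrame(rows)
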