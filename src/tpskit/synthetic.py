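"""Seeded synthetic-data generators for every pipeline stage.

No raw instrument data ships with the characterisation study this package
operationalises, so each stage is exercised on synthetic inputs generated
from known ground truth: two-state unfolding fluorescence curves (20–95 °C,
1 °C steps), malachite-green endpoint plates derived from Michaelis–Menten
initial rates plus linear Pi standard curves, GC-MS peak tables with an
isobutylbenzene internal standard and boiled-enzyme background, and
free-text crystallisation-condition corpora whose component frequencies
match the mined statistics.

Every generator is a pure function of its parameters and an integer seed and
returns ``(data, GroundTruth)``, where the ground truth records everything
needed to re-simulate the dataset bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .lexicon import load_chemical_lexicon, load_compound_lexicon
from .profiles import Peak, PeakTable
from .reference import (
    MINED_CONDITION_FREQUENCIES,
    PRECIPITANT_REPORTING_FRACTION,
    REFERENCE_TM_C,
    SALT_REPORTING_FRACTION,
)
from .screen import ConditionRecord
from .thermal import (
    BufferScreenDesign,
    MeltCurve,
    make_buffer_screen,
    two_state_fluorescence,
)


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters behind one synthetic dataset."""

    kind: str  # melt | kinetics | peaks | corpus
    params: dict
    seed: int


# ---------------------------------------------------------------------------
# melt curves

def gen_melt_curve(
    tm_C: float,
    amplitude: float = 1000.0,
    slope_pre: float = 1.5,
    slope_post: float = -6.0,
    steepness: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 200.0,
    no_transition: bool = False,
    condition_id: str = "synthetic",
    protein_id: str = "synthetic",
) -> tuple[MeltCurve, GroundTruth]:
    """Simulate one thermofluor melt curve over 20–95 °C in 1 °C steps.

    The noiseless curve follows the two-state model of
    :func:`tpskit.thermal.two_state_fluorescence`; Gaussian noise of standard
    deviation ``noise_sd`` AU is added per point.  With
    ``no_transition=True`` the transition amplitude is forced to zero (flat
    baseline apart from the pre-transition slope), modelling conditions in
    which no unfolding transition is measurable.
    """
    if not (20.0 < tm_C < 95.0):
        raise ParameterError(f"tm_C={tm_C} outside (20, 95) °C")
    if amplitude <= 0 and not no_transition:
        raise ParameterError("amplitude must be positive (or set no_transition=True)")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")

    amp = 0.0 if no_transition else float(amplitude)
    T = np.arange(20.0, 96.0, 1.0)
    F = two_state_fluorescence(
        T, baseline, slope_pre, amp, tm_C, steepness, 0.0 if no_transition else slope_post
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=T.shape)
    curve = MeltCurve(condition_id, protein_id, T, F)
    truth = GroundTruth(
        kind="melt",
        params={
            "tm_C": float(tm_C),
            "amplitude": amp,
            "slope_pre": float(slope_pre),
            "slope_post": float(slope_post),
            "steepness": float(steepness),
            "noise_sd": float(noise_sd),
            "baseline": float(baseline),
            "no_transition": bool(no_transition),
            "transition": "absent" if no_transition else "present",
            "condition_id": condition_id,
            "protein_id": protein_id,
        },
        seed=int(seed),
    )
    return curve, truth


def gen_buffer_screen_dataset(
    delta_tm_map: dict[str, float],
    ref_tm_C: float = REFERENCE_TM_C,
    noise_sd: float = 0.0,
    seed: int = 0,
    design: BufferScreenDesign | None = None,
    protein_id: str = "synthetic",
    reference_id: str = "REF",
    **melt_kwargs,
) -> tuple[list[MeltCurve], GroundTruth]:
    """Simulate a buffer-screen dataset: one curve per condition plus control.

    Each condition's generative midpoint is ``ref_tm_C + ΔTm``; the water
    control sits at ``ref_tm_C``.  Per-curve sub-seeds are derived
    deterministically from ``seed`` via a spawned seed sequence, so the whole
    dataset is a pure function of ``(params, seed)``.
    """
    if not (20.0 < ref_tm_C < 95.0):
        raise ParameterError(f"ref_tm_C={ref_tm_C} outside (20, 95) °C")
    scr = design or make_buffer_screen()
    known = set(scr.ids())
    unknown = [cid for cid in delta_tm_map if cid not in known]
    if unknown:
        raise ParameterError(f"condition ids not in screen design: {unknown}")
    for cid, dtm in delta_tm_map.items():
        if not (20.0 < ref_tm_C + dtm < 95.0):
            raise ParameterError(
                f"condition {cid}: midpoint {ref_tm_C + dtm:.2f} °C outside (20, 95)"
            )

    children = np.random.SeedSequence(seed).spawn(len(delta_tm_map) + 1)
    sub_seed = lambda i: int(children[i].generate_state(1)[0])

    curves: list[MeltCurve] = []
    ref_curve, _ = gen_melt_curve(
        ref_tm_C, noise_sd=noise_sd, seed=sub_seed(0),
        condition_id=reference_id, protein_id=protein_id, **melt_kwargs,
    )
    curves.append(ref_curve)
    for i, (cid, dtm) in enumerate(delta_tm_map.items(), start=1):
        curve, _ = gen_melt_curve(
            ref_tm_C + dtm, noise_sd=noise_sd, seed=sub_seed(i),
            condition_id=cid, protein_id=protein_id, **melt_kwargs,
        )
        curves.append(curve)

    truth = GroundTruth(
        kind="melt",
        params={
            "delta_tm_map": dict(delta_tm_map),
            "ref_tm_C": float(ref_tm_C),
            "noise_sd": float(noise_sd),
            "protein_id": protein_id,
            "reference_id": reference_id,
            "melt_kwargs": dict(melt_kwargs),
        },
        seed=int(seed),
    )
    return curves, truth


# ---------------------------------------------------------------------------
# malachite-green kinetics plates

def default_substrate_series() -> np.ndarray:
    """13 descending 2-fold steps from 100 µM (lowest ≈ 0.0244 µM)."""
    return 100.0 / 2.0 ** np.arange(13)


def default_standard_series() -> np.ndarray:
    """13 descending 2-fold steps from 50 µM (lowest ≈ 0.0122 µM)."""
    return 50.0 / 2.0 ** np.arange(13)


def gen_kinetics_plate(
    km_uM: float,
    vmax_uM_per_s: float,
    substrate_series: np.ndarray | None = None,
    incubation_s: float = 1800.0,
    std_slope: float = 0.03,
    std_intercept: float = 0.05,
    noise_cv: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    pi_per_turnover: int = 2,
    enzyme_id: str = "synthetic",
    substrate: str = "GPP",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one malachite-green endpoint plate.

    Sample wells read ``A = intercept + slope · Pi`` with
    ``Pi = pi_per_turnover · v(S) · t`` and ``v(S) = Vmax·S/(Km+S)``; each
    absorbance is multiplied by ``(1 + ε)``, ε ~ N(0, noise_cv).  The plate
    also carries a 13-level 2-fold Pi standard block (50 → ≈0.0122 µM) and
    substrate-free background wells, mirroring a real assay plate layout.
    """
    if km_uM <= 0 or vmax_uM_per_s <= 0:
        raise ParameterError("km_uM and vmax_uM_per_s must be positive")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be non-negative")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    S = np.asarray(
        default_substrate_series() if substrate_series is None else substrate_series,
        dtype=float,
    )
    if np.any(S <= 0):
        raise ParameterError("substrate series must be strictly positive")

    rng = np.random.default_rng(seed)

    def noisy(a: float) -> float:
        if noise_cv == 0:
            return float(a)
        return float(a * (1.0 + rng.normal(0.0, noise_cv)))

    rows = []
    standards = default_standard_series()
    for i, conc in enumerate(standards):
        rows.append(
            {"well": f"STD{i + 1:02d}", "role": "standard", "substrate_uM": 0.0,
             "analyte_uM": float(conc),
             "absorbance": noisy(std_intercept + std_slope * conc), "replicate": 1}
        )
    for rep in range(1, replicates + 1):
        rows.append(
            {"well": f"BG{rep:02d}", "role": "background", "substrate_uM": 0.0,
             "analyte_uM": 0.0, "absorbance": noisy(std_intercept), "replicate": rep}
        )
    for i, s in enumerate(S):
        v = vmax_uM_per_s * s / (km_uM + s)
        pi = pi_per_turnover * v * incubation_s
        for rep in range(1, replicates + 1):
            rows.append(
                {"well": f"S{i + 1:02d}R{rep}", "role": "sample",
                 "substrate_uM": float(s), "analyte_uM": 0.0,
                 "absorbance": noisy(std_intercept + std_slope * pi),
                 "replicate": rep}
            )
    plate = pd.DataFrame(rows)
    truth = GroundTruth(
        kind="kinetics",
        params={
            "km_uM": float(km_uM),
            "vmax_uM_per_s": float(vmax_uM_per_s),
            "substrate_series": [float(x) for x in S],
            "incubation_s": float(incubation_s),
            "std_slope": float(std_slope),
            "std_intercept": float(std_intercept),
            "noise_cv": float(noise_cv),
            "replicates": int(replicates),
            "pi_per_turnover": int(pi_per_turnover),
            "enzyme_id": enzyme_id,
            "substrate": substrate,
        },
        seed=int(seed),
    )
    return plate, truth


# ---------------------------------------------------------------------------
# GC-MS peak tables

def gen_peak_table(
    profile: dict[str, float],
    total_terpene_area: float = 1.0e6,
    is_area: float = 2.5e5,
    extra_nonterpene: dict[str, float] | None = None,
    seed: int = 0,
    sample_id: str = "synthetic",
    substrate: str = "GPP",
    normalise: bool = False,
) -> tuple[PeakTable, GroundTruth]:
    """Simulate one classified GC-MS peak table from a percent profile.

    One peak per profile compound with area proportional to its percentage,
    retention times from the package compound lexicon, one
    internal-standard peak (isobutylbenzene), and optional non-terpene peaks
    (e.g. geranyl methyl ether) flagged with their ground-truth classes.
    Putative library-matched compounds receive a synthetic match score.
    ``normalise=True`` rescales a profile whose percentages do not sum to 100
    (outside that tolerance the un-normalised input raises
    ``ParameterError``).
    """
    lex = load_compound_lexicon()
    if total_terpene_area <= 0:
        raise ParameterError("total_terpene_area must be positive")
    if any(p < 0 for p in profile.values()):
        raise ParameterError("profile percentages must be non-negative")
    total_pct = sum(profile.values())
    if normalise:
        if total_pct <= 0:
            raise ParameterError("cannot normalise an all-zero profile")
        profile = {k: 100.0 * v / total_pct for k, v in profile.items()}
    elif abs(total_pct - 100.0) > 0.05:
        raise ParameterError(
            f"profile percentages sum to {total_pct:.4f}, not 100 ± 0.05"
        )
    for name in profile:
        if lex.get(name) is None:
            raise ParameterError(f"compound {name!r} not in the compound lexicon")

    rng = np.random.default_rng(seed)
    peaks = [
        Peak(
            rt_min=lex.rt_of("isobutylbenzene"),
            area=float(is_area),
            compound="isobutylbenzene",
            match_score=None,
            klass="internal_standard",
            putative=False,
        )
    ]
    truth_classes = {"isobutylbenzene": "internal_standard"}
    for name, pct in profile.items():
        entry = lex.get(name)
        score = float(850 + rng.integers(0, 150)) if entry.putative else None
        peaks.append(
            Peak(
                rt_min=entry.rt_min,
                area=pct / 100.0 * total_terpene_area,
                compound=entry.name,
                match_score=score,
                klass=entry.klass,
                putative=entry.putative,
            )
        )
        truth_classes[entry.name] = entry.klass
    for name, area in (extra_nonterpene or {}).items():
        entry = lex.get(name)
        klass = entry.klass if entry else "unknown"
        rt = entry.rt_min if entry else float(rng.uniform(10.0, 36.0))
        peaks.append(
            Peak(rt_min=rt, area=float(area), compound=entry.name if entry else name,
                 match_score=float(850 + rng.integers(0, 150)), klass=klass,
                 putative=True)
        )
        truth_classes[entry.name if entry else name] = klass

    table = PeakTable(sample_id, substrate, tuple(sorted(peaks, key=lambda p: p.rt_min)))
    truth = GroundTruth(
        kind="peaks",
        params={
            "profile": {k: float(v) for k, v in profile.items()},
            "total_terpene_area": float(total_terpene_area),
            "is_area": float(is_area),
            "extra_nonterpene": {k: float(v) for k, v in (extra_nonterpene or {}).items()},
            "classes": truth_classes,
            "sample_id": sample_id,
            "substrate": substrate,
        },
        seed=int(seed),
    )
    return table, truth


def gen_boiled_control(
    background_areas: dict[str, float] | None = None,
    is_area: float = 2.5e5,
    seed: int = 0,
    sample_id: str = "boiled-control",
    substrate: str = "GPP",
) -> PeakTable:
    """Simulate a boiled-enzyme control: internal standard plus faint
    background contamination, no enzymatic products."""
    lex = load_compound_lexicon()
    rng = np.random.default_rng(seed)
    peaks = [
        Peak(
            rt_min=lex.rt_of("isobutylbenzene"),
            area=float(is_area),
            compound="isobutylbenzene",
            klass="internal_standard",
        )
    ]
    for name, area in (background_areas or {}).items():
        entry = lex.get(name)
        rt = entry.rt_min if entry else float(rng.uniform(10.0, 36.0))
        peaks.append(
            Peak(rt_min=rt, area=float(area), compound=entry.name if entry else name,
                 klass=entry.klass if entry else "unknown", putative=True)
        )
    return PeakTable(sample_id, substrate, tuple(sorted(peaks, key=lambda p: p.rt_min)))


# ---------------------------------------------------------------------------
# crystallisation-condition corpora

_UNIT_STYLES_M = ("{:.1f} M {}", "{:.0f} mM {}")  # mM style multiplies by 1000
_PEG_STYLES = ("{pct:.0f}% {name}", "{pct:.0f} % (w/v) {name}", "{pct:.0f}% {syn}")


def _spell_concentration(rng: np.random.Generator, molar: float, name: str) -> str:
    if rng.random() < 0.5:
        return f"{molar:.1f} M {name}"
    return f"{molar * 1000:.0f} mM {name}"


def _maybe_case_perturb(rng: np.random.Generator, text: str) -> str:
    r = rng.random()
    if r < 0.15:
        return text.lower()
    if r < 0.2:
        return text.upper()
    return text


def gen_condition_corpus(
    n_entries: int = 120,
    n_missing: int = 16,
    freq_spec: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    p_salt: float = SALT_REPORTING_FRACTION,
    p_precipitant: float = PRECIPITANT_REPORTING_FRACTION,
) -> tuple[list[ConditionRecord], GroundTruth]:
    """Simulate a crystallisation-condition corpus as free-text records.

    ``n_missing`` records carry an empty condition string (deposited
    structures without published conditions); the rest are assembled from
    components sampled per ``freq_spec`` — a buffer with a pH, optionally one
    salt and one precipitant — using the lexicon's canonical spellings with
    per-record perturbations (case changes, M/mM spelling, synonym use) to
    exercise the parser.  Category percentages must each sum to 100 ± 1 and
    every component name must be known to the chemical lexicon.
    """
    if not (0 <= n_missing <= n_entries):
        raise ParameterError("need 0 <= n_missing <= n_entries")
    spec = freq_spec or MINED_CONDITION_FREQUENCIES
    lex = load_chemical_lexicon()
    for category in ("buffer_pct", "salt_pct", "precipitant_pct"):
        total = sum(spec[category].values())
        if abs(total - 100.0) > 1.0:
            raise ParameterError(f"{category} sums to {total:.2f}, not 100 ± 1")
        for name in spec[category]:
            if lex.get(name) is None:
                raise ParameterError(f"unknown component {name!r} in {category}")
    ph_total = sum(spec["ph_bin_pct"].values())
    if abs(ph_total - 100.0) > 1.0:
        raise ParameterError(f"ph_bin_pct sums to {ph_total:.2f}, not 100 ± 1")

    rng = np.random.default_rng(seed)

    def draw(category: str) -> str:
        names = list(spec[category])
        probs = np.array([spec[category][n] for n in names], dtype=float)
        return names[rng.choice(len(names), p=probs / probs.sum())]

    missing_idx = set(
        int(i) for i in rng.choice(n_entries, size=n_missing, replace=False)
    )

    records: list[ConditionRecord] = []
    for i in range(n_entries):
        entry_id = f"ENTRY{i + 1:04d}"
        if i in missing_idx:
            records.append(ConditionRecord(entry_id, "", (), published=False))
            continue

        fragments: list[str] = []
        buffer = draw("buffer_pct")
        bin_label = draw("ph_bin_pct")
        ph = float(bin_label.split("–")[0]) + float(rng.integers(0, 10)) / 10.0
        buf_conc = float(rng.choice([0.05, 0.1, 0.2]))
        if rng.random() < 0.5:
            fragments.append(f"{_spell_concentration(rng, buf_conc, buffer)} (pH {ph:.1f})")
        else:
            fragments.append(f"{_spell_concentration(rng, buf_conc, buffer)} pH {ph:.1f}")

        if rng.random() < p_salt:
            salt = draw("salt_pct")
            salt_conc = float(rng.choice([0.1, 0.2, 0.3]))
            fragments.append(_spell_concentration(rng, salt_conc, salt))

        if rng.random() < p_precipitant:
            prec = draw("precipitant_pct")
            entry = lex.get(prec)
            if lex.is_peg(prec):
                pct = int(rng.choice([5, 10, 15, 20, 25, 30, 35]))
                style = rng.random()
                if style < 0.4:
                    fragments.append(f"{pct}% {prec}")
                elif style < 0.7 and entry.synonyms:
                    syn = entry.synonyms[int(rng.integers(0, len(entry.synonyms)))]
                    fragments.append(f"{pct}% {syn}")
                else:
                    fragments.append(f"{pct} % (w/v) {prec}")
            elif entry.name == "ammonium sulfate":
                conc = float(rng.choice([1.0, 1.5, 2.0]))
                fragments.append(_spell_concentration(rng, conc, prec))
            else:
                pct = int(rng.choice([10, 20, 30]))
                fragments.append(f"{pct}% (v/v) {prec}")

        text = ", ".join(_maybe_case_perturb(rng, f) for f in fragments)
        records.append(ConditionRecord(entry_id, text, (), published=True))

    truth = GroundTruth(
        kind="corpus",
        params={
            "n_entries": int(n_entries),
            "n_missing": int(n_missing),
            "freq_spec": {k: dict(v) for k, v in spec.items()},
            "p_salt": float(p_salt),
            "p_precipitant": float(p_precipitant),
        },
        seed=int(seed),
    )
    return records, truth


def regenerate(truth: GroundTruth):
    """Re-simulate a dataset from its own ground truth (bit-identical)."""
    p = truth.params
    if truth.kind == "melt":
        if "delta_tm_map" in p:
            return gen_buffer_screen_dataset(
                p["delta_tm_map"], p["ref_tm_C"], p["noise_sd"], truth.seed,
                protein_id=p["protein_id"], reference_id=p["reference_id"],
                **p["melt_kwargs"],
            )[0]
        return gen_melt_curve(
            p["tm_C"], p["amplitude"] if not p["no_transition"] else 1.0,
            p["slope_pre"], p["slope_post"], p["steepness"], p["noise_sd"],
            truth.seed, p["baseline"], p["no_transition"],
            p["condition_id"], p["protein_id"],
        )[0]
    if truth.kind == "kinetics":
        return gen_kinetics_plate(
            p["km_uM"], p["vmax_uM_per_s"], np.asarray(p["substrate_series"]),
            p["incubation_s"], p["std_slope"], p["std_intercept"], p["noise_cv"],
            p["replicates"], truth.seed, p["pi_per_turnover"],
            p["enzyme_id"], p["substrate"],
        )[0]
    if truth.kind == "peaks":
        return gen_peak_table(
            p["profile"], p["total_terpene_area"], p["is_area"],
            p["extra_nonterpene"] or None, truth.seed, p["sample_id"],
            p["substrate"],
        )[0]
    if truth.kind == "corpus":
        return gen_condition_corpus(
            p["n_entries"], p["n_missing"], p["freq_spec"], truth.seed,
            p["p_salt"], p["p_precipitant"],
        )[0]
    raise ParameterError(f"unknown ground-truth kind {truth.kind!r}")
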