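"""Crystallisation-condition mining and family-directed screen design.

Free-text mother-liquor descriptions (e.g. ``"0.1 M Bis-Tris (pH 7.0), 25%
PEG-3350, 0.2 M NaCl, 0.2 M MgCl2"``) are parsed into typed components
(buffer, salt, precipitant) against a chemical lexicon.  Corpus-level
frequency statistics over buffers, pH bins, salts, precipitants and PEG
subtypes then drive a deterministic component-selection rule that yields a
compact sparse-matrix screen: top buffers carrying a contiguous 0.5-unit pH
ladder, the two dominant PEG precipitants over a four-step concentration
ladder, and two fixed counter-ion salts in every condition.

With the default rules a corpus matching the mined terpene-synthase
statistics yields the published 48-condition screen (Bis-Tris 6.0/6.5/7.0 and
Tris 7.5/8.0/8.5 at 100 mM; PEG-3350 and PEG-8000 at 5/15/25/35 % w/v;
200 mM MgCl2 + 200 mM NaCl throughout).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import GenerationError, InputError, SelectionError
from .lexicon import ChemicalLexicon, load_chemical_lexicon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Component:
    role: str  # buffer | salt | precipitant | other
    chemical: str  # canonical name, or raw text for role=other
    concentration: float | None = None
    unit: str | None = None  # M | mM | %w/v | %v/v
    pH: float | None = None

    def concentration_M(self) -> float | None:
        if self.concentration is None:
            return None
        if self.unit == "M":
            return self.concentration
        if self.unit == "mM":
            return self.concentration / 1000.0
        return None


@dataclass(frozen=True)
class ConditionRecord:
    entry_id: str
    raw_text: str
    components: tuple[Component, ...]
    published: bool

    def first(self, role: str) -> Component | None:
        for comp in self.components:
            if comp.role == role:
                return comp
        return None

    def all(self, role: str) -> list[Component]:
        return [c for c in self.components if c.role == role]

    def ph(self) -> float | None:
        for comp in self.components:
            if comp.pH is not None:
                return comp.pH
        return None


@dataclass
class FrequencyReport:
    buffer_pct: dict[str, float]
    ph_bin_pct: dict[str, float]
    salt_pct: dict[str, float]
    precipitant_pct: dict[str, float]
    peg_subtype_pct: dict[str, float]
    denominators: dict[str, int]


@dataclass(frozen=True)
class SelectionRules:
    n_buffers: int = 2
    n_pegs: int = 2
    n_salts: int = 2
    ph_levels_per_buffer: int = 3
    ph_step: float = 0.5
    concentrations_pct_wv: tuple[float, ...] = (5.0, 15.0, 25.0, 35.0)
    buffer_mM: float = 100.0
    salt_mM: float = 200.0


@dataclass(frozen=True)
class Selection:
    buffer_ph: tuple[tuple[str, float], ...]
    precipitants: tuple[str, ...]
    precipitant_pcts: tuple[float, ...]
    salts: tuple[str, ...]
    buffer_mM: float = 100.0
    salt_mM: float = 200.0


@dataclass(frozen=True)
class ScreenCondition:
    index: int
    buffer: str
    buffer_mM: float
    pH: float
    precipitant: str
    precipitant_pct_wv: float
    salts: tuple[tuple[str, float], ...]  # ((name, mM), (name, mM))


@dataclass(frozen=True)
class ScreenSpec:
    conditions: tuple[ScreenCondition, ...]

    def __len__(self) -> int:
        return len(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            (s1, s1mM), (s2, s2mM) = c.salts
            rows.append(
                {
                    "index": c.index,
                    "buffer": c.buffer,
                    "buffer_mM": c.buffer_mM,
                    "pH": c.pH,
                    "precipitant": c.precipitant,
                    "precipitant_pct_wv": c.precipitant_pct_wv,
                    "salt1": s1,
                    "salt1_mM": s1mM,
                    "salt2": s2,
                    "salt2_mM": s2mM,
                }
            )
        return pd.DataFrame(rows)


# fragment grammar: [number unit] chemical [(pH x)]
_CONC_RE = re.compile(
    r"^\s*(?P<num>\d+(?:\.\d+)?)\s*"
    r"(?P<unit>mM|M|%\s*\(?\s*w/v\s*\)?|%\s*\(?\s*v/v\s*\)?|%)\s*"
    r"(?P<rest>.*)$",
    re.IGNORECASE,
)
_PH_RE = re.compile(r"[,\s]*\(?\s*pH\s*(?P<ph>\d+(?:\.\d+)?)\s*\)?\s*$", re.IGNORECASE)
_PH_ONLY_RE = re.compile(r"^\s*pH\s*(?P<ph>\d+(?:\.\d+)?)\s*$", re.IGNORECASE)


def _canonical_unit(raw: str) -> str:
    u = raw.strip().lower()
    if u == "m":
        return "M"
    if u == "mm":
        return "mM"
    if "v/v" in u:
        return "%v/v"
    # bare "%" defaults to w/v (the convention for PEG precipitants)
    return "%w/v"


def parse_condition(
    raw_text: str,
    lexicon: ChemicalLexicon | None = None,
    entry_id: str = "",
) -> ConditionRecord:
    """Parse one free-text crystallisation condition.

    Fragments are split on commas/semicolons and parsed as
    ``[number unit] chemical [(pH x)]``; chemical names are normalised through
    the lexicon's synonym table and roles assigned from the lexicon (with the
    ammonium-sulfate concentration override).  Unparseable fragments are kept
    as ``role="other"`` with a warning; an empty string yields an unpublished
    record; a non-empty string in which *no* fragment parses raises
    ``InputError``.
    """
    lex = lexicon or load_chemical_lexicon()
    text = (raw_text or "").strip()
    if not text:
        return ConditionRecord(entry_id, "", (), published=False)

    components: list[Component] = []
    n_parsed = 0
    for fragment in re.split(r"[;,]", text):
        fragment = fragment.strip()
        if not fragment:
            continue
        ph_only = _PH_ONLY_RE.match(fragment)
        if ph_only:
            ph_val = float(ph_only.group("ph"))
            # attach to the most recent buffer component if there is one
            for i in range(len(components) - 1, -1, -1):
                if components[i].role == "buffer" and components[i].pH is None:
                    comp = components[i]
                    components[i] = Component(
                        comp.role, comp.chemical, comp.concentration, comp.unit, ph_val
                    )
                    break
            else:
                components.append(Component("other", fragment, pH=ph_val))
            n_parsed += 1
            continue

        conc = unit = None
        rest = fragment
        m = _CONC_RE.match(fragment)
        if m:
            conc = float(m.group("num"))
            unit = _canonical_unit(m.group("unit"))
            rest = m.group("rest")

        ph = None
        mph = _PH_RE.search(rest)
        if mph:
            ph = float(mph.group("ph"))
            rest = rest[: mph.start()]
        name = rest.strip().strip(".")

        entry = lex.get(name) if name else None
        if entry is None:
            logger.warning("unparseable fragment %r in %s", fragment, entry_id or "<record>")
            components.append(Component("other", fragment, conc, unit, ph))
            continue

        conc_M = Component("x", "x", conc, unit).concentration_M()
        role = lex.role_of(entry.name, conc_M)
        components.append(Component(role, entry.name, conc, unit, ph))
        n_parsed += 1

    if n_parsed == 0:
        raise InputError(
            f"no parseable fragment in condition {entry_id or '<record>'}: {text!r}"
        )
    return ConditionRecord(entry_id, text, tuple(components), published=True)


@dataclass(frozen=True)
class FilterResult:
    records: tuple[ConditionRecord, ...]
    n_before: int
    n_after: int


def filter_published(records: list[ConditionRecord]) -> FilterResult:
    """Drop records without published conditions, reporting counts."""
    kept = tuple(r for r in records if r.published)
    result = FilterResult(kept, n_before=len(records), n_after=len(kept))
    logger.info("published-condition filter: %d -> %d records", result.n_before, result.n_after)
    return result


def ph_bin_label(ph: float) -> str:
    lo = int(ph)  # integer decade: [6.0, 7.0) -> "6.0–6.9"
    return f"{lo}.0–{lo}.9"


def _fractional_counts(
    records: tuple[ConditionRecord, ...], role: str, restrict: set[str] | None = None
) -> tuple[dict[str, float], int]:
    """Per-chemical fractional record counts for one component role.

    Each record reporting >= 1 component of the role contributes a total
    weight of 1, split evenly across its distinct chemicals of that role (so
    category percentages always sum to 100 even when a condition lists two
    salts).  ``restrict`` limits both the contributing chemicals and the
    denominator (used for the PEG-subtype breakdown).
    """
    counts: dict[str, float] = {}
    denom = 0
    for rec in records:
        chems = sorted({c.chemical for c in rec.all(role)})
        if restrict is not None:
            chems = [c for c in chems if c in restrict]
        if not chems:
            continue
        denom += 1
        w = 1.0 / len(chems)
        for chem in chems:
            counts[chem] = counts.get(chem, 0.0) + w
    return counts, denom


def frequency_stats(
    records: list[ConditionRecord] | tuple[ConditionRecord, ...],
    lexicon: ChemicalLexicon | None = None,
) -> FrequencyReport:
    """Corpus-level component statistics (parsed records required).

    Percentages are per category with category-specific denominators: buffers
    over buffer-reporting records, pH bins over records with a pH, salts over
    salt-reporting records, precipitants over precipitant-reporting records,
    and PEG subtypes over PEG-containing records.
    """
    recs = tuple(records)
    if not recs:
        raise InputError("empty corpus")
    lex = lexicon or load_chemical_lexicon()

    buffer_counts, n_buf = _fractional_counts(recs, "buffer")
    salt_counts, n_salt = _fractional_counts(recs, "salt")
    prec_counts, n_prec = _fractional_counts(recs, "precipitant")
    peg_names = {n for n in prec_counts if lex.is_peg(n)}
    peg_counts, n_peg = _fractional_counts(recs, "precipitant", restrict=peg_names)

    ph_counts: dict[str, float] = {}
    n_ph = 0
    for rec in recs:
        ph = rec.ph()
        if ph is None:
            continue
        n_ph += 1
        label = ph_bin_label(ph)
        ph_counts[label] = ph_counts.get(label, 0.0) + 1.0

    def as_pct(counts: dict[str, float], denom: int) -> dict[str, float]:
        if denom == 0:
            return {}
        return {
            k: 100.0 * v / denom
            for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        }

    return FrequencyReport(
        buffer_pct=as_pct(buffer_counts, n_buf),
        ph_bin_pct=as_pct(ph_counts, n_ph),
        salt_pct=as_pct(salt_counts, n_salt),
        precipitant_pct=as_pct(prec_counts, n_prec),
        peg_subtype_pct=as_pct(peg_counts, n_peg),
        denominators={
            "corpus": len(recs),
            "buffer": n_buf,
            "ph": n_ph,
            "salt": n_salt,
            "precipitant": n_prec,
            "peg": n_peg,
        },
    )


def _top_k(pct: dict[str, float], k: int, what: str) -> list[str]:
    if len(pct) < k:
        raise SelectionError(f"need {k} distinct {what}, corpus has {len(pct)}")
    # dict is already sorted by descending percentage with name tie-break
    return list(pct)[:k]


def select_components(
    report: FrequencyReport, rules: SelectionRules | None = None
) -> Selection:
    """Apply the component-selection rules to a frequency report.

    Buffers: the top ``n_buffers`` by usage.  pH: a contiguous ladder of
    ``n_buffers × ph_levels_per_buffer`` levels in ``ph_step`` increments
    starting at the lower edge of the modal pH bin, partitioned in blocks
    among the buffers in frequency order (the more-used buffer takes the more
    acidic block — consistent with Bis-Tris buffering below Tris).
    Precipitants: the top ``n_pegs`` PEG subtypes.  Salts: the top
    ``n_salts``.  Concentration ladder and fixed molarities come from the
    rules.
    """
    r = rules or SelectionRules()
    buffers = _top_k(report.buffer_pct, r.n_buffers, "buffers")
    pegs = _top_k(report.peg_subtype_pct, r.n_pegs, "PEG precipitants")
    salts = _top_k(report.salt_pct, r.n_salts, "salts")
    if not report.ph_bin_pct:
        raise SelectionError("corpus reports no pH values")

    modal_bin = max(report.ph_bin_pct.items(), key=lambda kv: kv[1])[0]
    anchor = float(modal_bin.split("–")[0])
    n_levels = r.n_buffers * r.ph_levels_per_buffer
    ladder = [round(anchor + i * r.ph_step, 2) for i in range(n_levels)]
    buffer_ph = []
    for i, buf in enumerate(buffers):
        block = ladder[i * r.ph_levels_per_buffer : (i + 1) * r.ph_levels_per_buffer]
        buffer_ph.extend((buf, ph) for ph in block)

    return Selection(
        buffer_ph=tuple(buffer_ph),
        precipitants=tuple(pegs),
        precipitant_pcts=tuple(r.concentrations_pct_wv),
        salts=tuple(salts),
        buffer_mM=r.buffer_mM,
        salt_mM=r.salt_mM,
    )


def reference_selection() -> Selection:
    """The published component selection, as a fixture."""
    from .reference import REFERENCE_SELECTION as ref

    return Selection(
        buffer_ph=tuple(ref["buffer_ph"]),
        precipitants=tuple(ref["precipitants"]),
        precipitant_pcts=tuple(ref["precipitant_pcts"]),
        salts=tuple(ref["salts"]),
        buffer_mM=ref["buffer_mM"],
        salt_mM=ref["salt_mM"],
    )


def generate_screen(selection: Selection) -> ScreenSpec:
    """Deterministically enumerate the screen from a component selection.

    Buffer/pH-major order, then precipitants in selection order, then
    ascending concentration; 1-based indices.  Every condition carries the
    buffer at ``buffer_mM`` and both selected salts at ``salt_mM``.
    """
    if not selection.buffer_ph or not selection.precipitants or not selection.precipitant_pcts:
        raise GenerationError("selection has an empty category")
    if len(selection.salts) != 2:
        raise GenerationError("selection must carry exactly two fixed salts")
    salts = tuple((s, selection.salt_mM) for s in selection.salts)
    conditions = []
    index = 1
    for buf, ph in selection.buffer_ph:
        for prec in selection.precipitants:
            for pct in sorted(selection.precipitant_pcts):
                conditions.append(
                    ScreenCondition(
                        index=index,
                        buffer=buf,
                        buffer_mM=selection.buffer_mM,
                        pH=ph,
                        precipitant=prec,
                        precipitant_pct_wv=pct,
                        salts=salts,
                    )
                )
                index += 1
    return ScreenSpec(tuple(conditions))


def export_screen(spec: ScreenSpec, path: str | Path) -> tuple[Path, Path]:
    """Write the screen as CSV plus a human-readable sheet grouped by buffer.

    Returns ``(csv_path, sheet_path)``; refuses to write an empty screen.
    """
    if len(spec) == 0:
        raise GenerationError("refusing to export an empty screen")
    csv_path = Path(path)
    spec.to_frame().to_csv(csv_path, index=False)

    sheet_path = csv_path.with_suffix(".md")
    lines = ["# Crystallisation screen", ""]
    frame = spec.to_frame()
    for (buf, ph), grp in frame.groupby(["buffer", "pH"], sort=False):
        lines.append(f"## {grp['buffer_mM'].iloc[0]:.0f} mM {buf} pH {ph}")
        for _, row in grp.iterrows():
            lines.append(
                f"- {row['index']:>2}: {row['precipitant_pct_wv']:.0f}% w/v "
                f"{row['precipitant']}, {row['salt1_mM']:.0f} mM {row['salt1']}, "
                f"{row['salt2_mM']:.0f} mM {row['salt2']}"
            )
        lines.append("")
    sheet_path.write_text("\n".join(lines), encoding="utf-8")
    return csv_path, sheet_path


def read_screen(path: str | Path) -> ScreenSpec:
    """Re-import an exported screen CSV."""
    frame = pd.read_csv(path)
    required = {
        "index", "buffer", "buffer_mM", "pH", "precipitant",
        "precipitant_pct_wv", "salt1", "salt1_mM", "salt2", "salt2_mM",
    }
    if not required.issubset(frame.columns):
        raise InputError(f"screen CSV must have columns {sorted(required)}")
    conditions = tuple(
        ScreenCondition(
            index=int(row["index"]),
            buffer=str(row["buffer"]),
            buffer_mM=float(row["buffer_mM"]),
            pH=float(row["pH"]),
            precipitant=str(row["precipitant"]),
            precipitant_pct_wv=float(row["precipitant_pct_wv"]),
            salts=(
                (str(row["salt1"]), float(row["salt1_mM"])),
                (str(row["salt2"]), float(row["salt2_mM"])),
            ),
        )
        for _, row in frame.iterrows()
    )
    return ScreenSpec(conditions)


def read_corpus(path: str | Path) -> list[tuple[str, str]]:
    """Read a condition corpus as (entry_id, condition free text) pairs.

    JSONL (one ``{"entry_id": ..., "condition": ...}`` object per line) and
    two-column CSV are both accepted, chosen by file suffix.
    """
    p = Path(path)
    pairs: list[tuple[str, str]] = []
    if p.suffix.lower() in (".jsonl", ".json"):
        for line in p.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            pairs.append((str(obj["entry_id"]), str(obj.get("condition") or "")))
    else:
        frame = pd.read_csv(p, keep_default_na=False)
        if not {"entry_id", "condition"}.issubset(frame.columns):
            raise InputError("corpus CSV must have columns entry_id, condition")
        pairs = [(str(r["entry_id"]), str(r["condition"])) for _, r in frame.iterrows()]
    return pairs


def write_corpus(pairs: list[tuple[str, str]], path: str | Path) -> Path:
    """Write a corpus as JSONL."""
    p = Path(path)
    with p.open("w", encoding="utf-8") as fh:
        for entry_id, condition in pairs:
            fh.write(json.dumps({"entry_id": entry_id, "condition": condition},
                                ensure_ascii=False) + "\n")
    return p


def frequency_report_frame(report: FrequencyReport) -> pd.DataFrame:
    """Flatten a frequency report to a tidy (category, name, percent) table."""
    rows = []
    for category, pct in (
        ("buffer", report.buffer_pct),
        ("ph_bin", report.ph_bin_pct),
        ("salt", report.salt_pct),
        ("precipitant", report.precipitant_pct),
        ("peg_subtype", report.peg_subtype_pct),
    ):
        for name, value in pct.items():
            rows.append({"category": category, "name": name, "percent": value})
    return pd.DataFrame(rows)
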