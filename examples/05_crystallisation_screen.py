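"""From a mined condition corpus to the 48-condition family-directed screen.

Simulates a corpus of 120 deposited-structure crystallisation conditions (16
without published conditions), parses the free text, computes component
frequency statistics, applies the selection rules, and enumerates the
sparse-matrix screen.
"""

from tpskit.screen import (
    filter_published,
    frequency_stats,
    generate_screen,
    parse_condition,
    select_components,
)
from tpskit.synthetic import gen_condition_corpus

records, _ = gen_condition_corpus(n_entries=120, n_missing=16, seed=11)
kept = filter_published(records)
print(f"corpus: {kept.n_before} entries, {kept.n_after} with published conditions")

parsed = [parse_condition(r.raw_text, entry_id=r.entry_id) for r in kept.records]
report = frequency_stats(parsed)
print("top buffers:",
      {k: round(v, 1) for k, v in list(report.buffer_pct.items())[:3]})
print("top PEG subtypes:",
      {k: round(v, 1) for k, v in list(report.peg_subtype_pct.items())[:3]})

selection = select_components(report)
screen = generate_screen(selection)
print(f"\n{len(screen)}-condition screen "
      f"({len(selection.buffer_ph)} buffer/pH × {len(selection.precipitants)} "
      f"PEGs × {len(selection.precipitant_pcts)} concentrations):")
print(screen.to_frame().head(8).to_string(index=False))
print("...")
print("\nEvery condition carries 100 mM buffer plus both 200 mM counter-ion "
      "salts; the full sheet is written by tpskit.screen.export_screen.")
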