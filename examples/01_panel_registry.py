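"""Load the builtin metabolite panel and inspect its quantification entities.

The builtin panel covers 34 plasma metabolites (amino acids, bile acids, and
small organic acids) measured by SRM. Four chromatographically unresolved
isomer pairs are quantified together, so the panel resolves to 30
quantification entities; three entities are quantified without ISTD
normalization because their labeled-standard signal is not repeatable.
"""

import srmquant as sq

panel = sq.load_panel("diabetes-t1d-34")
entities = panel.entities()

print(f"analytes: {len(panel.analytes)}  ISTDs: {len(panel.istds)}  "
      f"entities: {len(entities)}")
print("\nmerged entities (quantified together):")
for e in entities:
    if e.is_merged:
        print(f"  {e.name:18s} members={e.members}  ISTD={e.istd_abbreviation}")
print("\nentities quantified without ISTD normalization:")
for e in entities:
    if not e.has_istd:
        print(f"  {e.name}")
q = panel.entity("GCDCA and GDCA").quantifier
print(f"\nshared quantifier for GCDCA and GDCA: {q.precursor_mz} -> {q.product_mz} "
      f"({q.polarity} mode)")
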