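"""Standardize messy planning-system structure names to TG-263.

Asks the bundled lexicon for ranked suggestions for three raw names, then
applies a confirmed mapping. Exact and synonym hits score 1.0; anything
lower is offered for human confirmation, never auto-applied.
"""

from rtqa import Structure, StructureSet, apply_mapping, load_lexicon, suggest

lexicon = load_lexicon()
for raw in ["rect", "LT_lung", "SpinalCord", "blader"]:
    hits = suggest(raw, lexicon, k=3)
    shown = ", ".join(f"{h.tg263_name} ({h.score:.2f} {h.match_kind})"
                      for h in hits) or "(no candidate above threshold)"
    print(f"{raw!r:14} -> {shown}")

tri = lambda n, i: Structure(n, i, [[[0, 0, 0], [10, 0, 0], [10, 10, 0]]])
ss = StructureSet([tri("rect", 1), tri("blader", 2), tri("CTV boost", 3)],
                  patient_id="DEMO")
mapped = apply_mapping(ss, {"rect": "Rectum", "blader": "Bladder"})
for s in mapped.structures:
    flag = " [nonstandard]" if s.nonstandard else ""
    print(f"ROI {s.roi_number}: {s.name}{flag}")
# "CTV boost" stays under its raw name but is flagged nonstandard so a
# human can resolve it explicitly.
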