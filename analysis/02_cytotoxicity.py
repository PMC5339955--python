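#!/usr/bin/env python
"""MTT cytotoxicity screen of the 28 endophyte extracts.

Summarizes the percent-growth-inhibition panel (100 ug/mL, four human
cancer cell lines) at the strict >50% screening threshold, then counts
potent extracts in the follow-up IC50 panel under the NCI crude-extract
criterion (IC50 < 20 ug/mL), honoring "<10" censoring.
"""

import json
from pathlib import Path

from endodiv import bioactivity as bio, io

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

gi = io.load_gi()
screen = bio.cytotoxic_screen_summary(gi, threshold=50)
print(f"extracts screened: {screen['n_extracts']}")
print(
    f">50% inhibition on ALL four lines: {screen['all_line_active']} "
    f"({100 * screen['all_line_fraction']:.1f}%)"
)
print(
    f">50% inhibition on >=1 line:      {screen['any_line_active']} "
    f"({100 * screen['any_line_fraction']:.1f}%)"
)
print("per line:", screen["per_line_active"])

ic50_panel = io.load_ic50()
counts = bio.ic50_activity_counts(ic50_panel, threshold=20)
print(f"\nIC50 panel: {ic50_panel['extract_id'].nunique()} extracts assayed")
print(f"IC50 < 20 ug/mL on >=1 line: {counts['any_line_active']}")
print("per line:", counts["per_line_active"])

(OUT / "cytotoxicity_summary.json").write_text(
    json.dumps({"screen_gt50": screen, "ic50_lt20": counts}, indent=2) + "\n"
)
print(f"\nwrote {OUT / 'cytotoxicity_summary.json'}")
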