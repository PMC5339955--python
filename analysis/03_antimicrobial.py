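#!/usr/bin/env python
"""Antimicrobial screens: disc diffusion and broth dilution.

An extract is disc-diffusion active against a pathogen when any zone
of inhibition was recorded; broth-dilution active when it has at least
one non-right-censored MIC <= 100 ug/mL.  The two screens disagree in
the expected direction (diffusion finds more actives than dilution).
"""

import json
from pathlib import Path

from endodiv import bioactivity as bio, io

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

zi = bio.zi_screen_summary(io.load_zi())
print(
    f"disc diffusion: {zi['overall_active']}/{zi['n_extracts']} extracts active "
    f"({100 * zi['overall_fraction']:.0f}%)"
)
for pathogen, count in sorted(zi["per_pathogen_active"].items()):
    print(f"  {pathogen}: {count} ({100 * zi['per_pathogen_fraction'][pathogen]:.0f}%)")

mic = bio.mic_screen_summary(io.load_mic(), cutoff=100)
print(f"\nbroth dilution: {mic['overall_active']}/{mic['n_extracts']} extracts with MIC <= 100 ug/mL")
for pathogen, count in sorted(mic["per_pathogen_active"].items()):
    print(f"  {pathogen}: {count}")

(OUT / "antimicrobial_summary.json").write_text(
    json.dumps({"disc_diffusion": zi, "broth_dilution": mic}, indent=2) + "\n"
)
print(f"\nwrote {OUT / 'antimicrobial_summary.json'}")
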