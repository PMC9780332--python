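"""Design cationic tags that push a globular domain into condensate formation.

For each of three globular domains (net charges -7, 0, +6 at neutral pH) we
ask the designer for the shortest [GGSKKRKKR]n tag giving either transient
condensates (fusion charge exactly +6, at the phase-separation threshold) or
persistent ones (fusion charge >= +12).
"""

import phasetag as pt

print(f"tag unit {pt.TAG_UNIT}: {pt.net_charge(pt.TAG_UNIT):+d} per repeat\n")

for domain_charge in (-7, 0, +6):
    for mode in ("transient", "persistent"):
        d = pt.design_tag(domain_charge, mode)
        print(
            f"domain {domain_charge:+d}, {mode:>10}: "
            f"{d.n_repeats} repeat(s) + {d.linker_lysines} linker K "
            f"-> fusion charge {d.predicted_fusion_charge:+d}"
        )

print(
    "\nEach repeat adds +6; the lysine linker fine-tunes by +1 per residue. "
    "A +6 fusion sits on the phase boundary (condensates form then "
    "disassemble during growth); >= +12 keeps them through stationary phase."
)
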