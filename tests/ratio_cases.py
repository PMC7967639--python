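"""Boundary and interior cases for the diagnostic-ratio taxonomy.

Interval convention: half-open [low, high) — a value on a breakpoint takes
the label of the band it opens.
"""

RATIO_CASES = [
    ("LMW/HMW", 0.5, "pyrogenic"),
    ("LMW/HMW", 1.0, "petrogenic"),
    ("LMW/HMW", 2.0, "petrogenic"),
    ("ANT/(ANT+PHE)", 0.05, "petrogenic"),
    ("ANT/(ANT+PHE)", 0.1, "pyrogenic"),
    ("ANT/(ANT+PHE)", 0.25, "pyrogenic"),
    ("IcP/(IcP+BgP)", 0.1, "petrogenic"),
    ("IcP/(IcP+BgP)", 0.2, "fuel combustion"),
    ("IcP/(IcP+BgP)", 0.46, "fuel combustion"),
    ("IcP/(IcP+BgP)", 0.5, "grass/wood/coal combustion"),
    ("IcP/(IcP+BgP)", 0.7, "grass/wood/coal combustion"),
    ("BaA/CYR", 0.1, "unclassified"),
    ("BaA/CYR", 0.2, "coal combustion"),
    ("BaA/CYR", 0.3, "coal combustion"),
    ("BaA/CYR", 0.35, "vehicular emissions"),
    ("BaA/CYR", 1.0, "vehicular emissions"),
    ("BaA/(BaA+CYR)", 0.1, "petrogenic"),
    ("BaA/(BaA+CYR)", 0.2, "mixed"),
    ("BaA/(BaA+CYR)", 0.35, "combustion"),
    ("BaA/(BaA+CYR)", 0.5, "combustion"),
    ("FLU/(FLU+PYR)", 0.25, "gasoline"),
    ("FLU/(FLU+PYR)", 0.5, "diesel"),
    ("FLU/(FLU+PYR)", 0.8, "diesel"),
]
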