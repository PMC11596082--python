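"""Physical constants.

R is the CODATA molar gas constant, truncated to the precision customarily
used in solution-thermodynamics work; differences from the full CODATA value
are far below the reporting precision of the derived functions.
"""

#: Molar gas constant, J mol^-1 K^-1.
R = 8.31446
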