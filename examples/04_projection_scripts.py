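"""Turn a conservation annotation into PyMOL colouring scripts.

Shows both scoring schemes -- the discrete symbol colours and the continuous
percent-match ramp -- plus the residue-offset shift needed when the 3D model
is a fragment (e.g. a model of query residues 222 onward needs offset +221).
"""

from conservemap import ColorScheme, apply_offset, continuous_script, discrete_script
from conservemap.msa_conservation import ConservationAnnotation, bin_glyph

symbols = "**::..  "
pcts = (100.0, 100.0, 85.0, 80.0, 60.0, 55.0, 20.0, 0.0)
ann = ConservationAnnotation(
    symbols=symbols,
    match_pct=pcts,
    match_glyphs="".join(bin_glyph(p) for p in pcts),
    query_symbols=symbols,
)

discrete = discrete_script(ann, ColorScheme("blue", "discrete"), header=["demo run"])
print("--- discrete (symbol) script ---")
print(discrete.render())

ramp = continuous_script(ann, ColorScheme("blue", "continuous"), header=["demo run"])
print("--- continuous (percent-match) script, first 6 lines ---")
print("\n".join(ramp.render().splitlines()[:6]))

shifted = apply_offset(discrete, 221)
print("\n--- after offset +221 (fragment model numbering) ---")
print(shifted.render().splitlines()[-1])
print(
    "\nDark shades mark invariant residues; replaying either script in PyMOL"
    "\npaints the loaded model's surface by conservation."
)
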