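# SYNTHETIC placeholder length-weight coefficients (dry weight mg = a * L^b,
# L in mm), NOT literature values.  Published regressions (e.g. Gaudy &
# Boucher for copepods) are configuration the user must supply; these
# placeholders exist so the biomass-conversion machinery is runnable and
# testable out of the box.
carbon_fraction: 0.40
taxa:
  "Meganyctiphanes norvegica": {a: 0.0050, b: 3.0}
  "Para-Und-Euch group": {a: 0.0080, b: 2.8}
  "Pleuromamma robusta": {a: 0.0080, b: 2.8}
  "Candacia armata": {a: 0.0080, b: 2.8}
  "Calanus helgolandicus": {a: 0.0080, b: 2.8}
  "Tomopteris spp.": {a: 0.0030, b: 2.5}
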