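"""Published reference values for the bundled solute registry.

Freezing points (°C, 2 dp) of the non-electrolyte premixes, the measured
−18 °C ice contents with the matching serum-phase concentrations (nearest
integer %), the NaCl freezing-point series, and one published effective-
hydration surface used as a synthetic ground truth.
"""

# (solute, concentration % w/w) -> freezing point °C
FREEZING_POINTS = {
    ("glucose", 11.5): -1.34,
    ("glucose", 18.0): -2.27,
    ("glucose", 23.0): -3.09,
    ("glucose", 28.0): -4.02,
    ("sucrose", 15.0): -0.96,
    ("sucrose", 22.0): -1.53,
    ("sucrose", 26.0): -1.91,
    ("sucrose", 31.0): -2.44,
    ("ethanol", 5.0): -2.11,
    ("ethanol", 7.5): -3.24,
    ("ethanol", 10.0): -4.44,
    ("ethanol", 12.5): -5.71,
    ("xylitol", 15.0): -2.16,
    ("xylitol", 20.0): -3.06,
    ("xylitol", 25.0): -4.08,
    ("xylitol", 30.0): -5.24,
}

# (solute, premix % w/w) -> (measured ice content at −18 °C in % of sample,
#                            serum-phase concentration in % w/w, integer)
SERUM_TABLE = {
    ("glucose", 11.5): (73.0, 43),
    ("glucose", 18.0): (57.0, 42),
    ("glucose", 23.0): (47.0, 43),
    ("glucose", 28.0): (38.0, 45),
    ("sucrose", 15.0): (70.0, 50),
    ("sucrose", 22.0): (57.0, 51),
    ("sucrose", 26.0): (49.0, 51),
    ("sucrose", 31.0): (42.0, 53),
    ("ethanol", 5.0): (69.0, 16),
    ("ethanol", 7.5): (57.0, 17),
    ("ethanol", 10.0): (49.0, 20),
    ("ethanol", 12.5): (39.0, 20),
    ("xylitol", 13.0): (70.0, 43),
    ("xylitol", 19.0): (59.0, 46),
    ("xylitol", 25.0): (51.0, 51),
    ("xylitol", 28.0): (41.0, 47),
    ("nacl", 3.0): (73.0, 11),
    ("nacl", 5.0): (62.0, 13),
    ("nacl", 7.0): (50.0, 14),
    ("nacl", 8.0): (42.0, 14),
}

# NaCl (concentration % w/w, measured freezing point °C)
NACL_FREEZING_POINTS = [(3.0, -1.54), (5.0, -2.63), (7.0, -3.76), (8.0, -4.36)]

# Published effective hydration numbers of glucose: {conc %: {T °C: h}}
GLUCOSE_H_SURFACE = {
    15.0: {-18.0: 10.5, -16.0: 9.8, -14.0: 9.4, -12.0: 9.8, -10.0: 10.8, -8.0: 13.8},
    20.0: {-18.0: 4.9, -16.0: 4.6, -14.0: 4.6, -12.0: 4.5, -10.0: 4.6, -8.0: 5.7},
    25.0: {-18.0: 5.0, -16.0: 4.9, -14.0: 4.9, -12.0: 5.0, -10.0: 5.2, -8.0: 6.1},
}
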