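"""Scalar SSI: compute the index for a few weather readings and classify.

The Summer Simmer Index combines air temperature and relative humidity
into a perceived temperature on the Fahrenheit scale; above ~100 degF
the heat load becomes a health concern.
"""

from simmermap import classify_ssi, compute_ssi_units, table1_scheme

scheme = table1_scheme()

readings = [
    ("mild spring day", 22.0, 50.0),
    ("warm and humid", 30.0, 60.0),
    ("heat-wave afternoon", 38.0, 65.0),
    ("dry highland morning", 16.0, 40.0),
]

print(f"{'conditions':<22} {'Ta degC':>8} {'RH %':>6} {'SSI degF':>9}  category")
for name, temp_c, rh in readings:
    ssi = compute_ssi_units(temp_c, "C", rh, "F")
    cat = classify_ssi(ssi, scheme)
    print(f"{name:<22} {temp_c:>8.1f} {rh:>6.0f} {ssi:>9.2f}  {cat.label}")

# The SSI exceeds the air temperature whenever heat and humidity combine:
# 38 degC (100.4 degF) at 65% RH is *felt* as ~124 degF.
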