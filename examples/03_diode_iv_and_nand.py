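"""Resistor vs diode modes: I-V curves, rectification, AC half-wave, NAND.

After 365 nm the pore is a weakly rectifying resistor; after 530 nm it is an
iontronic diode that conducts only at negative potentials.  Combining the
wavelength input with the voltage polarity yields NAND logic, and under a
slow alternating voltage the diode state half-wave rectifies the current.
"""

import photopore as pp

model = pp.ConductanceModel()
params = pp.preset("pzMe")

print("model I-V anchors (one pore):")
for n_z, label in ((7, "ON  (0E,7Z)"), (0, "OFF (7E,0Z)")):
    i_pos = pp.pore_current(n_z, +100.0, model)
    i_neg = pp.pore_current(n_z, -100.0, model)
    print(f"  {label}: {i_pos:+7.2f} pA at +100 mV, {i_neg:+7.2f} pA at -100 mV")

print("\nrectification ratio |I(-V)|/|I(+V)| of the diode (OFF) state:")
for v in (50, 100, 150):
    r = pp.rectification_ratio_model(model, v, "off")
    print(f"  +/-{v:3d} mV -> {r:5.1f}")
# grows ~linearly with V; >5 at +/-100 mV as required of a useful diode

print("\nNAND truth table (inputs: wavelength, voltage):")
for row in pp.nand_truth_table(model, params):
    print(f"  {row['wavelength_nm']} nm, {row['voltage_mV']:+6.0f} mV -> "
          f"{row['magnitude_pA']:6.1f} pA per pore -> {row['output']}")

ens = pp.EnsembleModel(n_pores=100, noise_fraction=0.0)
slow = pp.ac_response(ens, 100.0, 0.03, state="off", seed=1)
fast = pp.ac_response(ens, 100.0, 3.0, state="off", seed=1, sample_rate=20000)
print("\nAC half-wave rectification (OFF state, 100 pores):")
print(f"  0.03 Hz: {pp.half_cycle_rectification(slow):.1f}")
print(f"  3 Hz:    {pp.half_cycle_rectification(fast):.1f}   "
      "(bilayer capacitive current erodes rectification)")
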