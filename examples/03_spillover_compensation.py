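"""Remove doxorubicin fluorescence from the autofluorescence channel.

DOX is itself fluorescent and spills from its detection channel into the
autofluorescence band, inflating the senescence signal. The coefficient is
estimated on a control saturated with the drug and subtracted per event.
"""

from senescan import apply_compensation, default_spec, estimate_spillover, simulate_events

control = simulate_events(default_spec("MearF", "spillover_control", seed=5), 5000)
model = estimate_spillover(control.table)
print(f"estimated spillover coefficient: {model.coefficient:.4f} "
      f"(true 0.1, from {model.n} drug-saturated events)")

sample = simulate_events(default_spec("MearF", "senescent_dox", seed=6), 20000)
before = sample.table["af"].mean()
corrected = apply_compensation(sample.table, model)
after = corrected["af"].mean()
true = sample.table["true_af"].mean()
print(f"mean AF: raw {before:.0f} -> compensated {after:.0f} (true {true:.0f} a.u.)")

# The compensated mean returns to the drug-free autofluorescence level
# within a couple of percent; the raw channel keeps the drug's contribution.
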