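"""Discriminate model variants with two simulated experiments.

Each variant predicts the preculture (high initial E2) and glucose-pulse
experiments; predictions are clustered per channel (Ward/Euclidean) and
the cluster means are checked against the qualitative features of the
experiments.  The intersection lists the variants compatible with both
channels.
"""

from diauxie import run_discrimination

res = run_discrimination(k=4, variants=["R1", "R2", "R3", "N1", "C2", "A3"])
for exp, verdicts in res["verdicts"].items():
    print(f"--- {exp}")
    for v in sorted(verdicts, key=lambda v: v.variant_id):
        print(f"  {v.variant_id}: substrate_ok={v.substrate_ok} "
              f"enzyme_ok={v.enzyme_ok}")
inter = res["intersection"]
for exp, sets in inter["per_experiment"].items():
    print(f"{exp}: both channels -> {sorted(sets['both'])}")
print("variants surviving every experiment:", sorted(inter["across"]))
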