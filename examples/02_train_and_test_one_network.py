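"""Train one network instantiation and inspect its cell assemblies.

A single model learns two categories with category terms (CT), is then tested
symbol-free with pure grounding patterns, and the per-area cell assemblies
(cells firing above 75% of the area maximum at the end of the 30-step
recording) are printed. In the primary visual area the assembly recovers the
12 stimulated pattern cells; in higher areas assemblies emerge from learned
convergence. Takes a couple of minutes.
"""

import braincat as bc

stimuli = bc.generate_stimulus_set(seed=0, n_categories=2)
model = bc.initialize_model(rng_seed=1)
log = bc.run_training(model, stimuli, "CT", rng_seed=1, trial_scale=150 / 2000)
print(f"trained {log.trials} trials (condition CT, compressed schedule, "
      f"learning rate {log.dw_effective:.4f})")

responses = bc.run_test_battery(model, stimuli, rng_seed=7)
for area in ("V1", "TO", "AT", "PB"):
    sizes = [len(bc.extract_ca(r, area).cells) for r in responses]
    print(f"{area:4s} assembly sizes across the 12 test instances: {sizes}")

cas = [bc.extract_ca(responses[i], "V1") for i in range(3)]
unique, pair, triple = bc.classify_neurons(cas, "V1")
print(f"category 0, V1: {unique} instance-unique, {pair} pair-shared, "
      f"{triple} triple-shared assembly cells "
      f"(the designed 6 shared cells reappear as triple-shared)")
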