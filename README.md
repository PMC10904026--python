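# braincat

Brain-constrained neural-network simulations of how verbal symbols shape
conceptual category learning.

Developmental studies show that learning a *category term* ("house mouse")
biases infants toward the shared features of objects and promotes category
formation, while a *proper name* ("Mickey Mouse") highlights object-specific
features. `braincat` implements a neurocomputational account of these
effects: a 12-area spiking network modelling left perisylvian language
cortex (auditory A1–AB–PB, articulatory PF_i–PM_i–M1_i) and extrasylvian
sensorimotor cortex (visual V1–TO–AT, hand-motor PF_L–PM_L–M1_L), with
neuroanatomically grounded between-area links, local and global inhibition,
and unsupervised Hebbian plasticity combining LTP and LTD.

The network learns 12-cell *grounding patterns* standing for object/action
instances (6 cells shared by each category, 6 unique per instance) either
alone (NoS), together with a category term (CT), or with a proper name (PN).
After training it is tested symbol-free on trained and novel instances, and
the package quantifies:

- **RSA** — per-area 60×60 representational dissimilarity matrices
  (Euclidean distance between firing-rate vectors, rate estimate
  τ·dω/dt = −ω + φ with τ = 5 at step 30), summarized into within/between
  category × trained/novel class means (`Dissim_W-TT`, `Dissim_B-TT`, …) and
  the generalization index `DissimDiff = |Dissim_W-TN − Dissim_W-TT|`;
- **cell assemblies** — cells firing above 75% of their area's maximum
  (response floor 0.01), decomposed into instance-unique versus
  category-shared neurons and the central-vs-primary percentage gain
  `(n_central − n_primary)/n_primary × 100`;
- **inferential statistics** — repeated-measures ANOVAs over the 12 model
  instantiations (condition × measure), Greenhouse–Geisser correction, and
  Bonferroni-corrected pairwise tests at the conservative p < 0.005
  threshold.

The intended use is from Python (see `examples/`); a thin `braincat` CLI
wraps the long-running stages for shell use. `docs/methods.md` documents the
model equations, calibration choices, and what the reduced-scale
configuration does and does not reproduce.

## Worked example

```python
import braincat as bc

stimuli = bc.generate_stimulus_set(seed=0)
print(bc.validate_constraints(stimuli))        # -> []
print(bc.category_cell_census(stimuli, 0, "V1"))  # -> (6, 36)
```

Running `python examples/01_stimulus_battery.py` prints:

```
battery: 60 instances, 10 category terms, 30 proper names
constraint violations: 0 (an empty list means the 50%-overlap, zero-between-category-overlap and non-adjacency rules all hold)
category 0: 6 shared + 36 unique V1 cells (6 + 36 by design)
instances 0 and 1 (same category) overlap in 6 of 12 V1 cells (50%)
instances 0 and 6 (different categories) overlap in 0 cells (none)
```

i.e. every instance activates 12 cells per primary area, within-category
instances share exactly half of them, categories share none, and each
category occupies 6 shared + 36 unique cells.

A small training run (`examples/02_train_and_test_one_network.py`) then
shows that after CT learning the V1 assembly of each tested instance
recovers exactly its 12 stimulated cells — classified across a category's
three trained instances as 18 instance-unique plus 6 triple-shared cells —
while smaller assemblies emerge in higher areas from learned convergence.
`examples/04_repeated_measures_stats.py` demonstrates the inferential layer
on a synthetic 12-subject table; its ANOVA row for the condition factor

```
effect       F        df1  df2   p       eta2_partial  mauchly_p
condition    189.28   2.0  22.0  0.0000  0.9451        0.4356
```

shows the output format used for real study tables (F, dfs, uncorrected and
GG-corrected p, both η² flavours, sphericity test).

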