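# engulf3d

Quantification of **microglial phagocytosis in 3D confocal stacks**: how much
of a synaptic or axonal marker has been engulfed into microglial lysosomes,
how many apoptotic cells a spinal-cord section contains and where they sit,
and whether those quantities differ between experimental groups.

The assay it implements is the nested volume-overlap measurement used to
study synaptic pruning in the dorsal horn after hindpaw incision injury:
tissue sections are stained for a pan-microglial marker (Iba1), a
lysosomal/phagosomal marker (CD68) and one neurite marker (the inhibitory
presynaptic marker VGAT, the excitatory marker VGLUT2, tdTomato-labelled
A-fibres, or cleaved caspase-3 for apoptosis). Each channel of a z-stack is
binarised and, per section,

```
engulfed volume   = | marker ∧ CD68 ∧ Iba1 |        (µm³)
percent engulfed  = 100 · |marker ∧ CD68 ∧ Iba1| / |marker|
```

together with the microglial volume |Iba1|, the lysosome-within-microglia
volume |CD68 ∧ Iba1| and the total marker volume |marker|. Sections
(≥ 6 per animal) are averaged per animal — animals, not sections, are the
experimental unit — and the per-animal table feeds the statistical layer:
two-way factorial ANOVA (e.g. sex × incision; Type III sums of squares),
one-way ANOVA, Welch's *t*, Sidak-adjusted post-hoc comparisons (α = 0.05),
and estimation statistics — the mean difference between groups with a
bias-corrected and accelerated (BCa) bootstrap 95 % CI from 5000 resamples.

Because real imaging data is large and external, the package ships a
first-class **synthetic-data generator**: branched microglia-like cells with
lysosomal sub-compartments, dense punctum fields with a *known* engulfed
fraction, Poisson-distributed apoptotic cells with spatial hotspots on a
hemisection template, full 2×2×2 factorial cohorts with controlled group
effects, and a standard optical forward model (Gaussian PSF, Poisson shot
noise, Gaussian read noise). Every downstream number can therefore be
validated against exact ground truth.

## Who is this for

Researchers quantifying engulfment/colocalisation assays in anisotropic 3D
fluorescence stacks who want a scripted, testable replacement for
Fiji-macro pipelines, plus a way to validate their settings on synthetic
volumes where the right answer is known.

## Worked example

Simulate a small two-group cohort (neonatal incision raises the true
engulfed fraction from 4 % to 6.5 %), run the full segmentation pipeline,
and test the effect:

```python
from engulf3d import (CohortDesign, make_cohort, binarize, engulfment_metrics,
                      aggregate_cohort, two_way_anova, bca_ci)

design = CohortDesign(
    n_per_group=3, sections_per_animal=6,
    sexes=("F", "M"), neonatal_levels=("-", "+"), adult_levels=("-",),
    base_engulfed_fraction=0.04,
    engulfed_effects={"neonatal": 0.025},
    seed=7,
)
sections, truth = make_cohort(design, render=True)

results = []
for s in sections:
    masks = {n: binarize(s.stack.channel(n), s.stack.voxel, method="otsu")
             for n in s.stack.channel_names}
    results.append(engulfment_metrics(masks["iba1"], masks["cd68"],
                                      masks["marker"], animal_id=s.animal_id))

table = aggregate_cohort(results, truth, min_sections=6)
print(table.groupby("group")["percent_engulfed"].agg(["mean", "std"]).round(2))

anova = two_way_anova(table["percent_engulfed"], table["sex"],
                      table["neonatal_incision"],
                      names=("sex", "neonatal_incision"))
row = anova.effects["neonatal_incision"]
print(f"neonatal incision: F(1, {anova.residual['df']}) = {row['F']:.2f}, "
      f"P = {row['p']:.4f}")

ctrl = table.loc[table.neonatal_incision == "-", "percent_engulfed"]
inc = table.loc[table.neonatal_incision == "+", "percent_engulfed"]
est = bca_ci(ctrl, inc, n_boot=5000, seed=7)
print(f"mean difference {est.mean_difference:.2f} "
      f"[95% CI {est.ci_low:.2f}, {est.ci_high:.2f}]")
```

Output:

```
         mean   std
group
IN(+,-)  4.56  0.22
IN(-,-)  3.55  0.56
neonatal incision: F(1, 8) = 15.25, P = 0.0045
mean difference 1.01 [95% CI 0.51, 1.39]
```

`IN(a, b)` is the group code: `a` = neonatal incision (±), `b` = adult
incision (±). The measured group means (4.56 % vs 3.55 %) recover the
simulated truth (6.5 % vs 4 %) up to the expected segmentation attenuation,
the ANOVA detects the incision main effect, and the estimation statistics
give the effect size with its bootstrap CI.

The same pipeline is scriptable end-to-end from a YAML config:

```bash
engulf3d all -c run.yaml     # simulate → analyze → stats
```

which writes OME-TIFF stacks, a cohort manifest, per-section and per-animal
CSV tables, and a JSON statistics report, with every threshold and seed
recorded in the run manifest.

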