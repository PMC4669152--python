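# pvdarbor

Quantitative analysis of dendritic arbor morphology for the *C. elegans*
PVD sensory neuron, whose dendrite is built from repeating candelabra-shaped
("menorah") units: a secondary (2°) stem protruding from the primary (1°)
anterior–posterior dendrite, tertiary (3°) arms running along the body
axis, and quaternary (4°) twigs rising orthogonally. Mutations in
membrane-trafficking genes (e.g. *rab-10*, the exocyst, the motors
kinesin-1/UNC-116 and dynein) reshape this arbor regionally — losing
branches near the cell body while overgrowing the distal anterior — so the
analysis is explicitly *regional*: the primary dendrite is divided into a
posterior segment (**-1**) and three equal-length anterior segments
(**+1**, **+2**, **+3**, proximal → distal).

The package provides, as a tested library plus a `pvd` command line:

- **SWC skeleton I/O** with validation (`pvdarbor.io`);
- **branch-order classification and per-region counting**
  (`pvdarbor.quant`): any protrusion from the primary is a 2°; an
  A-P-oriented child of a 2° is a 3°; an orthogonal child of a 3° is a 4°.
  Tertiaries and quaternaries are assigned to the region containing the
  base of their menorah's secondary stem;
- the **branch complexity index** per region,

  `BCI = ( n2/n2* + n2_with3/n2 + (n4/n3)/q* ) / 3`,

  equally weighting the secondary count, the fraction of secondaries
  bearing a tertiary, and the quaternaries-per-tertiary ratio, normalized
  so an "ideal" fully-formed segment scores 1;
- **EB-comet kymograph analysis** (`pvdarbor.kymo`): streak detection,
  track linking and velocity fitting at 8 frames/s, and per-region
  microtubule plus-end-out fractions (EB comets mark growing plus ends);
- **FRAP recovery fitting** (`pvdarbor.frap`): single-exponential
  `F(t) = f0 + (f_inf − f0)(1 − e^(−t/τ))`, mobile fraction
  `(f_inf − f0)/(1 − f0)`, and a genotype × time two-way ANOVA comparison;
- **statistics from first principles** (`pvdarbor.stats`): two-way ANOVA
  with type-II sums of squares, Tukey's HSD with studentized-range
  p-values, Welch "multiple t-tests" with a Holm column, and penetrance
  with exact Clopper–Pearson intervals;
- a **synthetic-data generator** (`pvdarbor.simulate`) producing
  menorah-structured arbors, comet kymographs and FRAP traces with known
  ground truth. Built-in genotype profiles are calibrated so expected
  whole-arbor totals match reported means (wild type: 42 secondaries /
  114 quaternaries; the *rab-10(wy787)*-like profile: 28 / 17, with the
  anterior-shifted distribution and short misoriented posterior
  secondaries).

## Worked example

```python
from pvdarbor import simulate, quant

profile = simulate.get_profile("wild_type")
cohort = simulate.simulate_cohort(profile, 10, seed=1)
table = quant.cohort_table([arbor for arbor, _ in cohort])
print(table.groupby("region", sort=False)[["n2", "n3", "n4", "bci"]].mean().round(2))
```

prints

```
          n2    n3    n4   bci
region
-1      11.1  18.6  31.1  0.68
+1      13.4  22.0  35.5  0.73
+2      11.9  18.6  30.5  0.69
+3       6.3  11.0  14.8  0.51
```

— a wild-type-like cohort: branching is densest in the proximal/middle
anterior (+1/+2, BCI ≈ 0.7) and sparsest in the distal anterior (+3),
and the mean total secondary count over the cohort (42.7 here) sits at
the calibrated wild-type mean of 42. Running the same pipeline on the
`"wy787"` profile inverts the ordering: BCI collapses in -1/+1 and peaks
in +3, the anterior-shift signature.

The same stages are scriptable from the shell:

```sh
pvd sim cohort --profile wy787 --n 10 --seed 1 --out cohort/
pvd quantify --inputs 'cohort/*.swc' --out quant.csv
pvd stats anova quant.csv --value bci
pvd report --quantify-csv quant.csv --out report.md
```

## Documentation

See `docs/methods.md` for the model, parameter defaults and their
rationale, what the synthetic data does and does not emulate, numerical
choices, and known limitations.
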