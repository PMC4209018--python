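# msmarkov

Discrete-time multistate Markov modelling of metabolic-syndrome (MS)
progression from annual health-check-up panels.

Metabolic syndrome is diagnosed when at least three of four risk components
are present — overweight/obesity, hypertension, dyslipidemia and
hyperglycemia, here defined by the CDS (Chinese Diabetes Society) criteria,
which use BMI, blood pressure, TG/HDL and glucose thresholds and need no
waist measurement.  Collapsing the 16 possible component profiles into
seven mutually exclusive states — no component, the four isolated
single-component states, an any-two-component state, and MS — turns
longitudinal check-up data into a reversible 7-state Markov chain with an
annual cycle.  The package is aimed at epidemiologists and biostatisticians
working with routine check-up panels who want to describe the natural
history of MS and project where a cohort is heading.

## The model

Within each sex × age stratum (M/F × 18–40, 40–49, 50–59, ≥60), the annual
transition matrix `P` is estimated in two steps:

1. for every pair of consecutive calendar years (y, y+1), tabulate the
   transitions of subjects seen in both years and form the row-conditional
   annual incidence-rate matrix `R_y`, with `R_y(i,j) = 100 · n(i→j)/n(i)`;
2. average the annual matrices cell-wise, `P = mean_y R_y` (an unweighted
   mean over the up-to-five year pairs; rows with no observations in a year
   are excluded from that row's mean rather than zero-filled).

A cohort's distribution over the states, the occupancy vector `π_t`, is then
propagated through annual cycles, `π_{t+1} = π_t P`, under the Markov
assumption (the next state depends only on the current one) and time
homogeneity (one matrix per stratum over the whole horizon).  Projections
from each starting state over 10 years show which components initiate the
MS cascade; an independent microsimulation oracle and a validation against
observed prevalence at a 5-year horizon check the matrix arithmetic and the
model's fit to the data it was estimated from.

Because the original hospital cohort was never deposited, the package ships
a synthetic-cohort generator whose subjects follow a specified ground-truth
matrix per stratum, attend 2–6 annual visits with loss to follow-up, and
carry clinical measurements rendered to be exactly consistent with their
latent state under the CDS thresholds — so estimation can be tested by
parameter recovery.  Five per-stratum matrices printed in the source study
are packaged as fixtures; three further strata use clearly-labelled
synthetic stand-ins.

## Worked example

```python
from msmarkov import load_fixture_matrix, project, predict_by_initial_state

tm = load_fixture_matrix("table2")          # men 18-40
traj = project(tm, start=0, cycles=1, renormalize=False)
print((100 * traj.occupancy[1]).round(2))
# [72.07  9.48  4.55  7.68  0.58  4.55  1.09]

trajs = predict_by_initial_state(tm, horizon=10)
print([round(t.ms_curve()[10], 2) for t in trajs])
# [27.23, 30.11, 33.81, 29.47, 34.08, 32.75, 34.49]
```

The first line is the printed matrix row read back through a one-cycle
projection: starting from no component, 72.07% of men aged 18–40 stay
component-free after one year and 1.09% develop MS.  The second shows MS
occupancy after 10 years from each of the seven starting states: starts
with isolated hyperglycemia (34.08%) or two components (32.75%) lead to MS
fastest, yet after a decade all starting states land within a few
percentage points of one another — long-horizon MS risk is nearly
independent of the initial state.

The same is available from the shell:

```sh
msmarkov project --matrix fixture:table2 --start no_component --cycles 10
msmarkov run --out demo_run --seed 1   # simulate -> classify -> estimate ->
                                       # project -> validate -> report
```

`msmarkov run` writes a bundle (cohort and classified CSVs, per-stratum
matrices, trajectories, a 5-year validation report, a Table-1-style
descriptive summary, plots and a Markdown report) that is byte-identical
for a given seed.

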