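# lisca — single-cell event-time analysis for live-cell imaging on arrays

Ensemble cell-death assays with endpoint readouts hide *when* things
happen in each cell.  Time-lapse fluorescence imaging of cells on
micropatterned single-cell arrays (LISCA) records one trace per cell
per marker — lysosomal membrane permeabilization (LMP, LysoTracker),
mitochondrial outer membrane permeabilization (MOMP, TMRM), the
oxidative burst (OxBurst, CellROX), caspase 3/7 activation,
phosphatidylserine flipping and plasma membrane permeabilization — and
each trace carries a characteristic saltation that marks a cellular
event.  This package turns such recordings (or faithful synthetic
stand-ins) into per-cell **event times** and population-level
**event-order statistics**: who fires first, with what delay, in which
subpopulation.

It is aimed at quantitative cell biologists and biophysicists analysing
single-cell time-lapse data, and at method developers who need a fully
planted-truth benchmark for event-time extraction.

## The model and the statistics

Early-marker traces are fitted with a falling logistic step times a
parabola (collapse of a rising/plateau signal),

    f(t) = s(t)·(a0 + a1 t + a2 t²) + (1 − s(t))·c,   s(t) = 1/(1 + e^{(t − t_b)/τ_b}),

late-marker traces with a rising logistic step times an exponential
decay, g(t) = B + A·σ(t)·e^{−λ·max(0, t − t_h)}.  Fitting is maximum
likelihood under i.i.d. Gaussian noise (= least squares, multistart).
Event times are then defined on the *fitted* curves:

* **t_breakdown** — earliest time the fit deviates from its own
  pre-breakdown parabola by more than κ·η (κ = 3, η = robust noise
  level), on a 1-min grid;
* **t_onset** — intersection of the tangent at the half-maximum of the
  sigmoidal rise with the baseline B (for a pure sigmoid this is
  exactly t_h − 2τ_o);
* **ROS production rate** — slope of the fitted CellROX model through
  its first two points at 1-min resolution.

Traces without a discernible event are rejected (amplitude < 5η, or
ΔBIC < 10 against a nested no-event model).  Population structure comes
from log-normal fits of event-time histograms, mean-shift clustering of
two-dimensional event-time scatter, asymmetric one-sigma
principal-component ellipses (different major-axis lengths on the two
sides), signed cluster delays Δt = t₂ − t₁, diagonal partitions and
Pearson correlations of ROS rates versus event times.  Details and all
defaults are in [docs/methods.md](docs/methods.md).

## Worked example

A planted bimodal cohort (70% of cells fire LMP→MOMP with a 3 h delay,
30% the reverse order with 2 h), traces fitted and paired, clusters and
delays recovered:

```python
from lisca import *

config = bimodal_pair_config(n_cells=120, seed=11)
truth = simulate_cohort(config)
traces = cohort_traces(truth)

records = [process_trace(tr, "early")[2] for tr in traces]
df = EventSet(records=records).to_frame()
lmp = EventSet.from_frame(df[df.marker == "LMP"])
momp = EventSet.from_frame(df[df.marker == "MOMP"])

pairs = pair_events(lmp, momp)
members, modes = mean_shift_cluster(pairs.points(), bandwidth=2.0)
print(f"{pairs.n} cells with both events; {len(members)} clusters")
for idx in members:
    ell = cluster_ellipse(pairs.points()[idx])
    print(f"  n={idx.size:3d}  centre=({ell.center[0]:.1f}, {ell.center[1]:.1f}) h"
          f"  delay={ell.delay_h:+.2f} h  side={ell.side}")
frac = diagonal_partition(pairs, tolerance=0.5)
print(f"above diagonal: {frac.above:.2f}, below: {frac.below:.2f}")
```

prints

```
120 cells with both events; 2 clusters
  n= 85  centre=(9.3, 12.5) h  delay=+3.22 h  side=above
  n= 35  centre=(11.4, 9.5) h  delay=-1.89 h  side=below
above diagonal: 0.71, below: 0.29
```

85 cells form a cluster *above* the diagonal — MOMP follows LMP, with a
recovered mean delay of 3.2 h (planted: 3 h) — while 35 cells sit below
it with the reversed order and a −1.9 h delay (planted: −2 h); the
above-diagonal fraction 0.71 recovers the planted 70/30 pathway mix.

The same analysis runs from the shell against a YAML run configuration
(`lisca run --config run.yaml --seed 1 --out outdir/`), with
`simulate`, `extract` (TIFF stacks → traces), `fit` and `correlate`
also available as individual subcommands; every run writes a manifest
with seeds, parameter echo and output checksums.

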