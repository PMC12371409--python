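# txtlcrosstalk

Kinetic ODE modelling of **plasmid crosstalk** in lysate-based cell-free
expression (CFE/TXTL) systems.

When several DNA templates are expressed in the same cell-free reaction, the
expression of one gene shifts when another template is added even without any
regulatory link — *positive* crosstalk (an increase, attributed to competitor
RNA distracting ribonucleases away from the reporter mRNA) or *negative*
crosstalk (a decrease, from competition for polymerases, ribosomes, NTPs and
amino acids, and from the build-up of inhibitory by-products).  Models that
treat mRNA decay as first-order and resources as infinite can reproduce
neither the positive crosstalk nor the experimentally observed *decrease* of
expression at high plasmid doses.  This package provides, for people
prototyping genetic circuits or multi-protein expression in E. coli lysates:

* a mass-action reaction-network compiler for arbitrary sets of transcription
  units competing for RNAP (native and T7 pools), ribosomes, ribonucleases
  and lumped NTP/AA pools, with explicit nuclease binding
  (mRNA + RNase ⇌ complex → degraded) so that decoy RNA measurably protects
  reporter message;
* a lumped **toxin** mechanism, d[toxin]/dt = Σ v − b, that degrades a
  resource pool through a smooth near-step gate
  k_toxin·(1 + tanh([toxin] − threshold))·[target], in four variants
  (TX-TX, TL-TL, TL-TX, TX-TL) — this is what turns dose–response
  *saturation* into the observed high-dose *decrease*;
* the crosstalk experiment grid (4 promoters × 7 reporter doses × 4 plasmid
  combinations, with the kanR marker on every backbone dosed as their sum),
  crosstalk ratios at 3 h, and surrogate terms that encode the qualitative
  phenotypes with goal thresholds;
* log-space Latin hypercube sampling with biological filter heuristics,
  population screening and ranking, damped least-squares fitting of
  time-course tables, soft-constraint / feasibility surrogate optimization,
  PRCC global sensitivity and term–term Spearman trade-off analysis;
* a synthetic fixture generator (plate-reader-style tidy tables with known
  generating parameters) and a CLI.

See `docs/methods.md` for the model equations, assumptions and numerical
choices.

## Worked example

```python
from txtlcrosstalk import (CrosstalkModel, Condition, enumerate_conditions,
                           crosstalk_table, readout_at)

model = CrosstalkModel.default()          # 10-unit registry, reference parameters

# one condition: 2.5 nM sigma70-strong sfGFP reporter + 10 nM empty vector
cond = Condition("sfGFP", "sig70_strong", 2.5, "empty_sig70_strong")
tc = model.simulate(cond)                 # 3 h, 5-min grid, LSODA
print(f"sfGFP at 3 h: {readout_at(tc, cond.reporter_unit, 3*3600):8.1f} nM")

base = model.simulate(cond.baseline)      # same dose, reporter only
print(f"baseline:     {readout_at(base, cond.reporter_unit, 3*3600):8.1f} nM")

conds = enumerate_conditions("sfGFP")     # the full 112-condition grid
grid = model.run_grid(conds)
report = model.surrogate_report(grid, conds)
print(f"criteria satisfied: {report.n_satisfied}/{len(report.criteria)}")
```

prints

```
sfGFP at 3 h:   8893.7 nM
baseline:       3532.0 nM
criteria satisfied: 6/6
```

The with-empty readout is 2.52× the baseline — positive crosstalk from
nuclease distraction: the extra kanR and empty-vector RNA occupy the scarce
ribonuclease pool and the reporter message survives longer.  At 10 nM
reporter the same ratio drops to 0.74 (negative crosstalk: the added burden
trips the translation-toxin shutdown earlier).  The reference parameterization
satisfies all six key-trend criteria: the three strong promoters show the
high-dose decrease (terminal sfGFP at 30 nM below 15 nM), σ70-weak stays
monotone, and every promoter shows the positive→negative crosstalk
transition.

Fitting follows the statsmodels pattern — a results object with estimates,
standard errors and a summary table:

```python
results = model.fit(table, free_names=["k_deg_aptamer", "RNase0"],
                    bounds=default_bounds(model.params.as_dict()))
print(results.summary())
```

The CLI mirrors the library: `txtlcrosstalk simulate|grid|screen|fit|
sensitivity|fixtures` (see `txtlcrosstalk --help`); every run writes a JSON
metadata record (seed, config hash, tolerances).

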