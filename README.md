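# liverkbp

A knowledge-based treatment-planning toolkit for liver radiotherapy, for
medical physicists and planning researchers who want to generate
patient-specific organ-at-risk (OAR) constraint protocols from a historical
plan cohort and evaluate the resulting plans.

## The problem and the model

Manual inverse planning for liver cancer starts from a one-size-fits-all
constraint template, yet achievable OAR sparing varies strongly with patient
geometry. The toolkit captures that geometry in a single feature,

    RTL = V_PTV / V_liver,

the ratio of planning target volume to liver volume, and models each OAR
constraint as a function of RTL learned from a knowledge cohort of past
plans:

- **Normal liver (liver−GTV) V5, V10, V20, V30** — ordinary least squares
  `y = a + b·RTL` followed by a downward *coverage shift* of the intercept by
  the ⌈q·n⌉-th smallest residual (q = 0.05), so that ≥ 95 % of historical
  plans met the shifted bound. The shipped reference model carries the
  published lines `y = 43.19 + 29.49x`, `y = 30.62 + 27.26x`,
  `y = 8.22 + 38.81x`, `y = 3.15 + 41.52x` (in %).
- **Kidney mean doses and spinal-cord-PRV maximum dose** — plain OLS lines
  `y = 211 + 462x`, `y = 380 + 1465x`, `y = 1990 + 2005x` (in cGy).
- **Stomach V20, small-bowel V15, heart mean, esophagus max** — doses driven
  by target position rather than size; modelled as population medians
  (15 %, 35 %, 630 cGy, 3863 cGy in the reference model).

A per-patient protocol is materialized by evaluating every rule at the
patient's RTL and rounding to the nearest integer in its display unit, with
liver and kidney rules at high priority and all rules open to compromise.
The segment budget follows `max_segments = round(40 + 50·RTL)`.

Around this core the package provides exact-voxel DVH computation
(Vx, Dx%, mean/max, conformity index
`CI = (V_pres∩PTV/V_PTV)·(V_pres∩PTV/V_pres)`, homogeneity index
`HI = D2%/D98%`), spacing-aware margin expansion for planning risk volumes,
paired t-test plan-comparison reports, blind-review vote tallies, and
synthetic cohort/phantom generators so every component is testable without
clinical data.

## Worked example

The reference model applied to a patient with RTL = 0.55:

```sh
liverkbp protocol --rtl 0.55
```

prints

```
liver_gtv        V5 < 59%                  High  Yes
liver_gtv        V10 < 46%                 High  Yes
liver_gtv        V20 < 30%                 High  Yes
liver_gtv        V30 < 26%                 High  Yes
left_kidney      Mean dose < 465 cGy       High  Yes
right_kidney     Mean dose < 1186 cGy      High  Yes
spinal_cord_prv5 Maximum dose < 3093 cGy   Low   Yes
stomach          V20 < 15%                 Low   Yes
small_bowel      V15 < 35%                 Low   Yes
heart            Mean dose < 630 cGy       Low   Yes
esophagus        Maximum dose < 3863 cGy   Low   Yes
```

Each row is one optimization constraint: e.g. at most 59 % of the normal
liver may receive ≥ 5 Gy, and the left-kidney mean dose must stay below
211 + 462·0.55 = 465.1 → 465 cGy. The same numbers are available from the
library:

```python
import liverkbp as kbp

model = kbp.load_reference_model()
protocol = kbp.materialize_protocol(model, rtl=0.55)
protocol.bound("liver_gtv", "volume_at_dose", 5.0)   # 59
kbp.max_segments(0.55)                               # 68
```

Fitting your own model from a cohort CSV (columns `patient_id`, `rtl`, and
one column per metric such as `liver_gtv_v5_pct`, `left_kidney_mean_cgy`):

```sh
liverkbp simulate --n 50 --seed 7 --out cohort.csv   # or your own data
liverkbp fit --cohort cohort.csv --q 0.05 --out model.json
liverkbp protocol --model model.json --rtl 0.55
```

## Layout

- `src/liverkbp/dvh.py` — dose grids, structure masks, DVHs, plan metrics
- `src/liverkbp/geometry.py` — RTL, segment budget, mask arithmetic, margins
- `src/liverkbp/model.py` — constraint-model estimators and cohort fitting
- `src/liverkbp/protocol.py` — per-patient protocol materialization
- `src/liverkbp/compare.py` — paired comparison statistics and tallies
- `src/liverkbp/synthetic.py` — cohort, paired-arm and phantom generators
- `src/liverkbp/io.py`, `cli.py` — CSV/JSON round trips and the CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
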