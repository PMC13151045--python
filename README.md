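# fishplasma

Refined fish plasma model (FPM) screening of pharmaceuticals for
environmental risk prioritization.

## The problem

Active pharmaceutical ingredients (APIs) reach surface waters and are
taken up by fish across the gills. The fish plasma model is the standard
read-across screen: it predicts the steady-state fish plasma
concentration from the water concentration via a hydrophobicity-driven
blood:water partition coefficient,

```
P_blood:water = 10^(0.73 · LogD_ow − 0.88)
```

and flags an API as a testing priority when its **therapeutic water
concentration** — the water concentration at which fish plasma would
reach the human therapeutic plasma level C_max,

```
TWC = C_max / P_blood:water
```

— approaches measured environmental concentrations. The generic model
assumes an API is equally *available* in fish and human plasma. It is
not: human plasma binds anionic drugs (NSAIDs and relatives) far more
strongly than fish plasma, largely because most fish lack serum albumin
or carry divergent albumin-like proteins. Only the unbound fraction
(f_u) is pharmacologically available, so the generic model can
under-predict internal exposure of fish to anionic APIs by more than an
order of magnitude.

This package implements the refined screen end to end:

- **f_u from equilibrium dialysis** — buffer/plasma concentration
  ratios, correction of diluted-plasma assays
  (`f_u = f_u,D / (D − (D−1)·f_u,D)`), mass-recovery QC, and
  replicate/laboratory aggregation (`fishplasma.dialysis`);
- **relative unbound fractions** `Rf_u = f_u,fish / f_u,human`, as
  median and worst-case (fish max / human min) ratios, with inclusive
  prioritization thresholds (median ≥ 3, max ≥ 10) and per-charge-group
  summaries (`fishplasma.rfu`);
- **refined TWC** `TWC = (C_max / Rf_u) / P_blood:water`, with LogD
  evaluated at the fish species' plasma pH, plus conservatism checks
  against chronic fish early-life-stage NOEC/LOEC values
  (`fishplasma.fpm`);
- **molecular predictors of f_u** — a penalized-spline additive model
  (Gamma family, log link) of fourth-root f_u on molecular weight,
  LogD_ow and pKa smooths (k = 4) plus a categorical charge factor
  (`fishplasma.gam`);
- **a seeded synthetic study generator** emulating the assay design
  (10 µM spike, triplicates, multi-lab, 10% plasma for fathead minnow)
  with latent species-specific binding, so every stage is testable
  without external data (`fishplasma.simulate`).

A reference screening table of 44 APIs (LogD at pH 7.4/7.9, C_max,
worst-case rainbow-trout Rf_u, original and refined TWCs, effect
concentrations) and the four species contexts (human, rainbow trout,
koi carp, fathead minnow) are packaged as CSV fixtures
(`fishplasma.catalog.load_fixture`).

## Worked example

Screen the packaged 44-API table against rainbow trout using the
worst-case Rf_u rule:

```
$ fishplasma screen --species rainbow_trout --rfu-rule max --out twc.csv
FPM screen: 44 APIs, species=rainbow_trout, rule=max
  anionic: 8/14 flagged (max Rf_u >= 10)
  cationic: 1/19 flagged (max Rf_u >= 10)
  unionized: 2/8 flagged (max Rf_u >= 10)
  zwitterionic: 0/1 flagged (max Rf_u >= 10)
```

8 of the anionic APIs (but only 1 cationic) exceed the worst-case
Rf_u ≥ 10 threshold — binding differences matter most for acids. The
first output row shows the refinement at work for meloxicam
(C_max 0.4 mg/L, Rf_u 29): the generic TWC of 19.9 mg/L drops to
1.98 mg/L once the 29-fold higher availability in trout plasma is
accounted for, a 10-fold tightening of the screen.

The same numbers are available in the library:

```python
>>> from fishplasma import catalog, fpm
>>> fix = catalog.load_fixture()
>>> trout = fix.species["rainbow_trout"]
>>> rfu = {r["name"]: r["rfu_trout_max"] for _, r in fix.table.iterrows()}
>>> results, _ = fpm.screen(fix.apis, trout, rfu)
>>> ibu = next(r for r in results if r.api_name == "Ibuprofen")
>>> round(ibu.twc_original, 2), round(ibu.twc_refined, 2)
(12.58, 0.48)
```

Fit the descriptor model on a synthetic 200-compound panel whose latent
binding depends on LogD and charge but not on MW or pKa:

```python
>>> from fishplasma import simulate, gam
>>> cfg = simulate.SyntheticConfig(seed=7, n_apis=200)
>>> panel = simulate.generate_api_panel(cfg).rename(
...     columns={"fu_rainbow_trout": "fu_median"})
>>> print(gam.fit_fu_gam(panel).summary())
Additive model of unbound fraction
==================================================
response transform: fourth_root
family:             gamma, log link
n compounds:        200
basis dim k:        4
deviance explained: 98.8%
adjusted R^2:       0.980
--------------------------------------------------
term                   edf     p-value
mw                    2.72      0.1802
logd                  2.77           0
pka                   1.00      0.8659
charge_class        factor  1.212e-281
```

The fit recovers the generative truth: LogD and charge are detected,
MW and pKa are not.

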