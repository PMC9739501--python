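# fishspectra

Community-structure analysis for multi-site, multi-season fish surveys,
aimed at fisheries ecologists working with individual catch records
(site, season, species, body length, body weight). It implements the
standard descriptive battery used to diagnose disturbance in river fish
communities:

- **Diversity** — Shannon index in bits, `H = −Σ pᵢ log₂ pᵢ`, and Pielou
  evenness `J = H / log₂ S`.
- **Dominance** — Pinkas' index of relative importance,
  `IRI = (N% + W%) × F%`, combining a species' numerical share, weight
  share and occurrence frequency across sampling units; species with
  `IRI ≥ 1000` are flagged dominant.
- **ABC curves** — paired abundance and biomass dominance curves with
  Clarke's `W = Σᵢ (Bᵢ − Aᵢ) / (50 (S − 1))` and the three-tier
  disturbance classification (biomass curve on top → undisturbed,
  crossing → moderate, abundance on top → severe).
- **NBSS** — the normalized biomass size spectrum over doubling weight
  classes anchored at the minimum body weight V, with ordinary
  least-squares linear and quadratic (`y = ax² + bx + c`) fits. The
  Sheldon ideal (equal biomass per octave) gives slope −1; disturbance
  bends the spectrum into a dome whose curvature `a` is the comparison
  statistic, judged between site groups by a three-tier box-plot rule.
- **Transforms** — lg(x+1), Hellinger, column z-scores, Bray–Curtis
  dissimilarity and the conventional NMDS stress interpretation bands,
  i.e. the standard inputs to downstream ordination (NMDS/RDA fitting
  itself is out of scope).
- **Synthetic surveys** — a seeded generator of catch, species and
  environment tables with configurable disturbance regimes (undisturbed,
  moderate, severe, Sheldon-ideal, dome-shaped spectra), so every stage
  is testable without field data.

## Worked example

```python
from fishspectra import *
from fishspectra.synthetic_data import GeneratorConfig

ds = generate_catch(GeneratorConfig(seed=42, n_sites=6))
summ = summarize_community(ds.records, ("all",))[("all",)]
print("S, T, biomass:", summ.S, summ.T, round(summ.total_biomass, 1))
print("H =", round(shannon_index(summ.abundance), 3),
      "J =", round(pielou_evenness(summ.abundance), 3))
for r in relative_importance(ds.records)[:3]:
    print(f"{r.species}: N%={r.N_pct:.2f} W%={r.W_pct:.2f} "
          f"F%={r.F_pct:.2f} IRI={r.IRI:.0f} dominant={r.dominant}")
curves = abc_curves(summ.abundance, summ.biomass)
print("W =", round(w_statistic(curves), 4), classify_disturbance(curves).value)
fit = fit_spectrum(build_nbss([r.body_weight for r in ds.records]))
print(fit.equation(), "R2", round(fit.r_squared, 2))
```

prints

```
S, T, biomass: 13 1164 41535.1
H = 2.421 J = 0.654
sp01: N%=39.95 W%=28.42 F%=100.00 IRI=6837 dominant=True
sp03: N%=15.03 W%=50.35 F%=100.00 IRI=6538 dominant=True
sp02: N%=24.74 W%=0.79 F%=100.00 IRI=2554 dominant=True
W = 0.0898 undisturbed
y = -0.1338x^2 + 0.9921x + 5.8497 R2 0.49
```

The pooled 6-site community holds 13 species and 1164 fish; diversity is
2.42 bits at evenness 0.65. Three species exceed the IRI ≥ 1000
dominance threshold. The biomass dominance curve sits above the
abundance curve (W > 0, undisturbed), and the pooled size spectrum is a
shallow dome with curvature −0.13.

The same pipeline runs from the shell:

```sh
fishspectra simulate --seed 42 --out data/
fishspectra diversity data/catch.csv --group-by site,season
fishspectra nbss data/catch.csv --group-by site --model quadratic
fishspectra run --simulate-seed 42 --out report/
```

## Layout

- `src/fishspectra/core_data.py` — domain types, table I/O, aggregation
- `src/fishspectra/diversity_dominance.py` — H, J, IRI
- `src/fishspectra/abc_disturbance.py` — ABC curves, W, disturbance tiers
- `src/fishspectra/size_spectrum.py` — NBSS, fits, curvature comparison
- `src/fishspectra/transforms_stats.py` — matrix transforms and statistics
- `src/fishspectra/synthetic_data.py` — seeded survey generator
- `src/fishspectra/pipeline.py`, `cli.py` — one-command pipeline and CLI

See `docs/methods.md` for the models, conventions and limitations.
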