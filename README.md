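# copmap

Crossover calling and Crossover-Potential analysis for backcross gamete
sequencing.

Meiotic crossovers (COs) are the reciprocal exchanges between homologous
chromosomes that shuffle genetic variation; their number and genomic
placement differ between female and male meiosis of the same plant
(heterochiasmy) and are shaped by interference and by chromatin. A powerful
way to measure them is the backcross design: a Col/Ler *Arabidopsis* hybrid
is crossed to the Col tester in both directions and every BC1 individual is
shallow-sequenced, so each individual reports one transmitted gamete — a
mosaic of homozygous (gamete carried Col, `HOM_A`) and heterozygous (gamete
carried Ler, `HET`) blocks whose transitions are crossovers.

`copmap` is a reusable, tested implementation of the computational side of
that design:

* **`copmap.sim`** — a synthetic BC1 generator: class I chiasmata from a
  stationary gamma-renewal process (interference shape ν, CoC < 1 nearby),
  class II from an independent Poisson draw, both on a positional intensity
  map; chiasma-to-chromatid thinning (a gamete inherits each chiasma with
  probability 1/2, so COs per gamete = chiasmata per meiocyte / 2);
  shallow-sequencing marker counts with genotyping error; optional
  whole-chromosome aneuploidy.
* **`copmap.caller`** — the sliding-window CO caller: 30-kb windows / 15-kb
  steps, HOM_A/HET/UNKNOWN classification of pooled marker reads, support
  filtering (a double CO needs ≥5 windows = 90 kb, a terminal CO ≥2 windows
  = 45 kb), a marker-level likelihood audit of each segment, and
  breakpoint support intervals.
* **`copmap.landscape`** — windowed CO landscapes, per-chromosome and
  per-genome normalization, merged Crossover-Potential (CO_P) maps,
  hot/cold zone calling, NRZ audit, Spearman track comparison.
* **`copmap.interference`** — coefficient of coincidence over 10 intervals
  per chromosome (CoC_ij = x_ij / x_i·x_j on gamete presence/absence),
  heterochiasmy ratios with Mann-Whitney tests, class I/II decomposition
  from cytological focus counts (1 focus = 0.5 CO per gamete), additive
  predictions and fold changes at printed precision.
* **`copmap.aneuploidy`** — read-depth screen: 100-kb windows, pairwise
  Mann-Whitney between chromosomes, BH adjustment, flag at fold change
  > 1.2 and adjusted p < 1e-20.
* **`copmap.cop_model`** — random-forest prediction of the CO_P landscape
  from 17 genomic/epigenomic feature tracks (ntree 2000, mtry 3), with
  permutation-importance ranking, stepwise variance-explained curves and
  leave-one-chromosome-out cross-validation.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate wild-type-like female and male BC1 populations, call crossovers,
and measure heterochiasmy:

```python
import numpy as np
from copmap import sim as msim
from copmap.layout import arabidopsis_layout
from copmap.caller import call_sample
from copmap.interference import heterochiasmy
from copmap.io import PopulationCalls
from copmap.landscape import co_landscape, normalize_per_chromosome

layout = arabidopsis_layout()
cfg = msim.SimConfig(layout,
                     female=msim.PathwayParams(class1_mean=1.12, nu=5.0),
                     male=msim.PathwayParams(class1_mean=2.08, nu=5.0),
                     seed=42)
pops = {}
for sex in ("female", "male"):
    samples, markers, truth = msim.simulate_counts(cfg, 80, sex)
    calls = [c for s in samples for c in call_sample(s, layout, markers)]
    pops[sex] = PopulationCalls("wild type", sex,
                                [s.sample_id for s in samples], calls)
    print(f"{sex}: {len(calls)} calls in 80 gametes "
          f"(mean {len(calls)/80:.2f} per gamete)")
ratio, p = heterochiasmy(pops["female"], pops["male"])
print(f"female/male ratio = {ratio:.2f} (Mann-Whitney p = {p:.2e})")
track = normalize_per_chromosome(co_landscape(pops["female"], layout))
```

Output:

```
female: 203 calls in 80 gametes (mean 2.54 per gamete)
male: 401 calls in 80 gametes (mean 5.01 per gamete)
female/male ratio = 0.51 (Mann-Whitney p = 1.05e-14)
```

The caller recovers the simulated rates (truth means 2.60 and 5.11 COs per
gamete at 2x depth with ~3,000 markers) and the female/male ratio lands near
the wild-type heterochiasmy of ~0.54; the normalized track gives, per 1-Mb
window, the proportion of that chromosome's crossovers falling there.

The same pipeline is scriptable from the shell:

```bash
copmap --seed 42 --out-dir run/ simulate --n 80 --sex female
copmap --out-dir run/ call --counts run/counts --markers run/markers.tsv
copmap --out-dir run/ landscape --calls run/calls.tsv --normalize chromosome
copmap --out-dir run/ coc --calls run/calls.tsv
```

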