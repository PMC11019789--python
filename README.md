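# bloomtrack

Inference of bloom-responsive marine prokaryotes and their viruses from
microcosm time series.

When a phytoplankton bloom collapses, grazing and viral lysis release the
cells' dissolved intracellular fraction into seawater, and particular
heterotrophic prokaryotes — and, in turn, *their* viruses — bloom on it.
`bloomtrack` implements the downstream inference chain for microcosm
experiments probing this cascade: natural seawater amended in triplicate
flasks with lysates of two bloom formers (CIF, from *Chaetoceros* sp.; HIF,
from *Heterosigma akashiwo*) against an unamended control, sampled daily
for 8 days, with 16S ASV counts, vOTU (viral contig cluster) read mapping,
and flow-cytometry counts of total cells and viral particles.

The package takes the processed tables such an experiment produces
(feature counts, taxonomy, cytometry, vOTU quantification, host
predictions, an environmental monthly series) and answers: **which taxa
responded to which lysate, which viruses rose with them, and which
host–virus pairs co-occur in the field?**

## The quantities at its core

Approximate absolute abundances anchor everything.  For an ASV,

$$\mathrm{cells}_i = \frac{n_i}{\sum_f n_f}\times P(\mathrm{cells})$$

with $P(\mathrm{cells})$ the flow-cytometry cell count.  For a vOTU $i$,

$$P(i) = \frac{\mathrm{FPKM}(i)}{\mathrm{FPKM}(\mathrm{viral})}
\times \frac{R(\mathrm{viral})}{R(\mathrm{viral}) + R(\mathrm{potential}\ v)}
\times P(\mathrm{viral})$$

where the middle factor calibrates for virus-derived reads that assembled
into no scaffold.  On these scales the pipeline applies:

* **community structure** — rarefaction, Bray–Curtis, PCoA, ANOSIM
  (permutation p, Bonferroni), phase-wise Mann–Whitney tests of the totals;
* **differential enrichment** — a from-scratch class/subclass procedure
  (Kruskal–Wallis → subclass rank consistency → bootstrapped LDA effect
  size, log-score ≥ 2) with treatments or day-0-vs-later as classes and
  flasks as subclasses;
* **responder filters** — abundant ASVs (top-20 rank in all flasks on some
  day after day 0 AND a >2× rise over day 0), treatment-specific ASVs,
  increased vOTUs (enrichment after day 0 AND a peak above 100
  particles/mL, the mean marine burst size), treatment-specific vOTUs;
* **host–virus pairing** — taxonomy-guided candidates confirmed on a
  17-month environmental series by Spearman r > 0.6, permutation P < 0.01,
  Benjamini–Hochberg q < 0.05, with no time delay.

A synthetic microcosm generator with planted ground truth
(`bloomtrack.simulate`) makes the whole chain testable end to end.

## Worked example

```python
from bloomtrack import PipelineConfig, SimConfig, simulate_microcosm
from bloomtrack.pipeline import community_analysis, detect_responders

ds, truth = simulate_microcosm(SimConfig(), seed=1)
res = detect_responders(ds, config=PipelineConfig(), seed=1)
for t in ("CIF", "HIF"):
    print(t, "specific ASVs:", list(res["specific_asvs"][t].index))
sv = res["specific_votus"]
print(sv["category"].value_counts().to_dict())
comm = community_analysis(ds, seed=1)
print(comm["anosim"])
```

prints

```
CIF specific ASVs: ['ASV_CIF00', 'ASV_CIF01', 'ASV_CIF02', 'ASV_CIF03', 'ASV_CIF04']
HIF specific ASVs: ['ASV_HIF00', 'ASV_HIF01', 'ASV_HIF02', 'ASV_HIF03', 'ASV_HIF04', 'ASV_HIF05', 'ASV_HIF06', 'ASV_HIF07']
{'HIF-specific': 16, 'CIF-specific': 13}
                       contrast         R      p  p_bonferroni
0          early_vs_middle_late -0.005477  0.475         0.950
1  treatment_within_middle_late  0.964982  0.001         0.002
```

All 5 planted CIF responders and all 8 planted HIF responders are
recovered with no false positives; the 28 planted treatment-specific vOTUs
(two lytic per responder plus two lysogenic) are all assigned to the
correct treatment, with one background vOTU slipping through as a false
CIF-specific call (across 20 simulations sensitivity is ≈ 0.97 and the
empirical false-discovery rate ≈ 0.02); and middle-late communities
separate decisively by treatment (ANOSIM R ≈ 0.96, p = 0.001) while
pooled early vs middle-late samples do not — the middle-late pool spans
the treatment split itself.

The same stages are available from the shell:

```bash
bloomtrack simulate --seed 1 --out-dir run/
bloomtrack all --data-dir run/ --seed 1 --out-dir run/out/
```

## Layout

```
src/bloomtrack/
  datatypes.py   domain types, phases, bundle validation
  io.py          TSV readers/writers for every table
  config.py      pipeline thresholds (study defaults)
  simulate.py    synthetic microcosm + environmental generators
  abundance.py   absolute-abundance calibration (cells/mL, P(i))
  community.py   rarefaction, Bray-Curtis, PCoA, ANOSIM, Mann-Whitney
  differential.py  class/subclass enrichment (KW, consistency, LDA)
  responders.py  abundant/increased/treatment-specific filters
  pairing.py     host-virus candidates, Spearman + BH confirmation
  pipeline.py    stage orchestration
  evaluation.py  scoring against planted truth
  cli.py         `bloomtrack` command group
```

See `docs/methods.md` for the full statistical methods, default parameter
rationale, and the generator's scope and limitations.
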