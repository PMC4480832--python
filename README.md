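# hhscan

Haplotype conditional-entropy selection scores, and the stratified
conditional-logistic pipeline that asks whether *cis*-eQTLs carry stronger
recent-positive-selection signatures than the rest of their gene.

## The problem

A recent selective sweep leaves the favoured allele riding one long,
conserved haplotype. Classic scan statistics (iHS, EHH, CMS, Fst) detect
this, but most of them are smooth along the chromosome, which makes them
nearly useless for *within-gene* variant prioritisation: in a conditional
logistic regression with the gene as the stratum, a smooth predictor is
almost collinear with the stratum itself and the model fails to converge.
`hhscan` implements a deliberately non-smooth, marker-specific score built
from haplotype conditional entropy, plus the full downstream analysis:
stratified conditional-logistic models of eQTL status, per-GO-category
effect meta-analysis with a size-preserving permutation null, and the
two-group hypothesis test.

## The score

For a focal marker `m` and population `p`, a window is grown outward
independently on each side until the summed per-site Shannon entropy
`H_i = -(f ln f + (1-f) ln(1-f))` first reaches 10 nats — so windows shrink
in diverse regions and populations. Within the window (focal site
excluded), with `n*_J` the frequency of flanking haplotype `J` and `n'_J`
its frequency among minor-allele carriers at `m`:

    H*_pm = - Σ_J n*_J ln n*_J          (window haplotype entropy)
    H'_pm = - Σ_J n'_J ln n'_J          (entropy among minor-allele carriers)

A large drop `H* - H'` means the minor allele sits on one conserved
haplotype — the sweep footprint. Counts of major/minor chromosomes
(`N_Mp`, `N_mp`) strongly confound the raw drop, so a per-population linear
calibration `(α_p, β_Mp, β_mp)` is fitted by least squares so the adjusted
component averages zero in every population, and the score is

    H|H_m = - Σ_{p: N_Mp > 5} ( H*_pm - H'_pm - α_p - β_Mp ln N_Mp - β_mp ln N_mp )

Strongly swept markers therefore score negative (a `flip_sign` option
inverts the convention). Downstream, eQTL status is modelled per dataset by
exact conditional logistic regression with the gene (or intergenic
interval) as the stratum, e.g.

    eqtl ~ hh:go + ddaf + maf:go + location

with per-GO slopes shrunk one standard error toward zero, summed across
datasets, and compared against a pooled permutation 90% interval to pick
the GO groups carried into the hypothesis-testing phase.

## Worked example

```python
from hhscan import (SimConfig, simulate_panel, FocalMarkerSet,
                    score_markers, fit_calibration)

cfg = SimConfig(seed=42, n_regions=40, markers_per_region=1,
                sweep_fraction=0.5, sweep_purity=1.0)
panel, truth = simulate_panel(cfg)               # 3 populations, planted sweeps
markers = FocalMarkerSet.from_identifiers(truth["marker"], panel)
records, track = score_markers(panel, markers)   # two-pass: calibrate, score

result = track.merge(truth[["marker", "sweep"]], on="marker")
print(result.groupby("sweep")["hh"].mean())
```

prints

```
sweep
False    1.748137
True    -1.932152
```

Markers planted on a swept haplotype average a strongly negative score,
neutral markers a positive one (the calibration centres the *overall* mean
near zero). `track` is a BED-like table (`chrom`, `start`, `end`, `marker`,
`hh`) ready for `hhscan.panel.write_track`, and
`fit_calibration(records).to_frame()` gives the per-population
`(alpha, beta_m, beta_M)` adjustment table.

The same workflow is available from the shell:

```sh
hhscan simulate --seed 42 --out-dir fx/
hhscan score --vcf fx/panel.vcf --panel fx/panel_samples.tsv \
             --markers fx/focal_markers.tsv --out scores.bed
hhscan fit  --data study.tsv --formula "eqtl ~ hh + maf + ddaf + location" \
             --out fit.tsv
hhscan meta --config meta.yaml --out report.tsv --out-groups groups.yaml
```

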