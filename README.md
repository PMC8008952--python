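# ladkit

Tools for mapping the micro-proteomes of the nuclear periphery: DamID-seq
LAD calling, proximity-biotinylation (BioID/BioSITe) enrichment analysis,
and integration of lamina- and LAD-associated protein sets.

## The problem

Lamina-associated domains (LADs) are 100 kb–Mb blocks of heterochromatin
held at the nuclear lamina. Two proximity-labeling readouts probe this
compartment from opposite sides:

* **DamID-seq** marks DNA near a Dam–Lamin B1 fusion at GATC motifs. Reads
  are counted per DpnI (GATC) restriction fragment and scored as
  log2(Dam-fusion / Dam-only); LADs are contiguous regions of positive
  score.
* **BioID/BioSITe** marks proteins near a BirA* fusion on lysines; anti-
  biotin capture yields site-resolved peptides with MS1 quantification.
  Proteins enriched over a control (fold-change of replicate-averaged
  abundance ratios) are called proximal, and the *degree of biotinylation*
  (biotinylated lysines / total lysines) ranks them by proximity/abundance.

Combining a lamina-directed interactome, a LAD-directed proteome, and
published lamina interactomes partitions the periphery into three zones:
zone 1 (INM/lamina only), zone 2 (the "middlemen" contacting both lamina
and LADs), and zone 3 (LAD-restricted chromatin factors).

## What the package computes

* `ladkit.gatc` — in-silico DpnI digestion: GATC scan, fragment map
  (half-open, 0-based; cut at GA^TC = motif start + 2).
* `ladkit.damid` — read trimming/adaptor splitting, per-fragment counts
  (straddling reads count toward every overlapped fragment), pseudocounted
  (0.5 on zero bins) log2 ratios with optional reads-per-million
  normalisation, changepoint partitioning by recursive binary segmentation
  with permutation-tested splits (a CBS procedure), and LAD classification:
  positive segments ≥ 100 kb after absorbing negative gaps < 10 kb.
* `ladkit.biosite` — site-table aggregation to proteins, per-replicate
  ratios and mean-ratio enrichment calls (default thresholds 2.0 and 1.6),
  degree of biotinylation, site-level membrane-topology assignment.
* `ladkit.zones` — symbol normalisation, the 3-of-4 consensus laminome,
  zone 1/2/3 assignment, Venn region counts.
* `ladkit.intervals` — base-coverage overlap percentages, peak-in-region
  fractions (midpoint or any-overlap rule), and boundary/anchor-oriented
  average signal profiles.
* `ladkit.simulate` — seeded generators with known truth for every stage
  (planted LADs with Poisson/negative-binomial DamID counts, planted
  enrichment with log-normal noise, peaks with a target overlap).

## Worked example

Simulate a 3 Mb chromosome with 6 planted LADs, run the full DamID pipeline,
and compare calls with the planted truth:

```python
import ladkit as lk
from ladkit.gatc import build_fragment_map
from ladkit.intervals import IntervalSet, base_coverage_overlap

cfg = lk.SimulationConfig(seed=1, genome_length=3_000_000, n_lads=6,
                          lad_size_range=(100_000, 300_000))
genome, _ = lk.simulate_genome(cfg)
frags = build_fragment_map(genome)
truth = lk.plant_lads(cfg)
fusion, control = lk.simulate_damid_counts(frags, truth, cfg)
track = lk.compute_damid_scores(fusion, control)
segments = lk.segment_scores(track, seed=1)
lads = lk.call_lads(segments, frags)

print(f"fragments: {frags.n_fragments}, scored: {track.n_scored}")
print(f"segments: {len(segments.segments)}, LADs called: {lads.n_lads()}")
ov = base_coverage_overlap(IntervalSet(dict(truth.intervals)),
                           IntervalSet(dict(lads.intervals)))
print(f"planted vs called: {ov['pct_A_in_B']:.1f}% of truth recovered, "
      f"{ov['pct_B_in_A']:.1f}% of calls inside truth")
```

prints

```
fragments: 11815, scored: 11815
segments: 16, LADs called: 6
planted vs called: 99.9% of truth recovered, 99.9% of calls inside truth
```

i.e. every fragment received a score (no empty bins at depth 10), the
segmentation found the 6 domains plus flanking background segments, and the
called LADs cover the planted ones almost exactly — residual disagreement
is the sub-fragment quantisation at domain edges.

The same stages are available as a CLI (`ladkit gatc-map`, `damid-score`,
`call-lads`, `biosite-enrich`, `zones`, `overlap`, `profile`,
`simulate all`); run `ladkit --help` for the flags.

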