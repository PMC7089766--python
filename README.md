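# endseq

Analysis toolkit for END-seq mapping of topoisomerase-II–mediated DNA
double-strand breaks (DSBs).

Etoposide and related TOP2 poisons trap the covalent TOP2 cleavage complex
(TOP2cc), a protein-bridged DSB intermediate. What happens next — re-ligation
by the enzyme, persistence as a trapped complex, or proteolytic conversion to
a "clean" protein-free DSB that gets resected and repaired — determines
whether the genome survives the insult intact. END-seq reads out these states
genome-wide: each sequenced read end marks one blunted DNA end, and two
experimental axes make the lesion species separable:

* **Exonuclease cocktail.** ExoVII+ExoT blunts both protein-linked and
  protein-free ends (all TOP2-mediated DSBs); ExoT alone cannot process
  protein-linked ends and sees only protein-free DSBs.
* **Drug washout.** Reversible TOP2ccs re-ligate when the poison is removed
  and vanish from the washout library; irreversible complexes and
  protein-free breaks remain.

This package implements the downstream statistics for that design, for
computational biologists working with aligned END-seq read-end BED files (or
wanting a fully simulated test bed):

* **Spike-in normalization to cell-percentage.** Cells carrying an induced
  zinc-finger-nuclease break are mixed into the library at a known fraction
  *f* (default 1:40, i.e. 2.5%). A peak's RPKM divided by the mean RPKM at
  the spike summits, times 100 *f* (= 2.5 at 1:40), is the percent of cells
  bearing that lesion.
* **Break persistence.** Per site, signal at a washout timepoint relative to
  its pre-washout signal: `P = S(t) / S(0)`.
* **Species classification.** With pre/washout ExoVII+ExoT signals and the
  ExoT-only signal, relative to the initial pool:
  `[TOP2cc]_R = (S_pre − S_washout) / S_pre`, `[DSB] = S_ExoT / S_pre`,
  `[TOP2cc]_I = 1 − [DSB] − [TOP2cc]_R`.
* **Resection endpoint calling.** Per side of each break summit, fifty 50 bp
  bins out to 2.5 kb are scanned with a sliding 10-bin window against a
  background level (maximum bin signal 2.5–5 kb from the summit); the scan
  stops where more than half the window is at/below background and reports
  the last above-background bin as the maximum resection endpoint. Breaks
  with endpoints > 100 bp count as resected.
* **Synthetic data generation.** A seeded generator emits read-end BED files
  with known per-site cleavage probabilities, species mixtures, resection
  tract lengths, spike-in sites and background noise, so every estimator is
  tested by parameter recovery.

## Worked example

Simulate a three-library experiment (ExoVII+ExoT before and after washout,
ExoT-only after washout) under the defaults — lesions in 20% of cells,
splitting 76% reversible / 4% irreversible / 20% protein-free — and run the
full analysis:

```python
import endseq as eq

cfg = eq.SimConfig(
    chrom_sizes={"chr1": 600_000}, n_sites=20, n_spike_sites=8,
    cells_per_sample=1500, seed=42,
)
truths, spikes = eq.simulate_genome(cfg)
sites = [eq.BreakSite.from_summit(t.site_id, t.chrom, t.summit, flank=2500)
         for t in truths]

def cell_pct(sample_id, nuclease, timepoint):
    meta = eq.SampleMeta(sample_id, "ETO", nuclease, timepoint, cfg.spike_in_fraction)
    reads = eq.simulate_sample(truths, spikes, meta, cfg)
    track = eq.coverage_from_reads(reads, bin_width=1, chrom_sizes=cfg.chrom_sizes)
    spike = eq.spike_in_factor(track, spikes, window_bp=5000, spike_in_fraction=0.025)
    return {s.site_id: eq.to_cell_percentage(eq.rpkm(track, s.interval), spike)
            for s in sites}, track

pre, _ = cell_pct("pre", eq.Nuclease.EXOVII_EXOT, eq.Timepoint.PRE_WASHOUT)
w0, track_w0 = cell_pct("w0", eq.Nuclease.EXOVII_EXOT, eq.Timepoint.WASHOUT_0H)
exot0, _ = cell_pct("exot0", eq.Nuclease.EXOT_ONLY, eq.Timepoint.WASHOUT_0H)

ids = [s.site_id for s in sites]
fr = eq.classify_genomewide([pre[i] for i in ids], [w0[i] for i in ids],
                            [exot0[i] for i in ids], aggregation="pooled")
records, summary = eq.persistence_table(pre, {"WASHOUT_0H": w0})
calls = eq.call_resection_table(track_w0, sites)
```

which prints, with the formatting from the repository's example:

```
mean pre-washout lesion load : 21.55 cell-%
reversible TOP2cc fraction   : 0.765
irreversible TOP2cc fraction : 0.050
protein-free DSB fraction    : 0.185
median 0 h persistence       : 0.242
resected breaks (>100 bp)    : 20 / 20
median max endpoint          : 950 bp
```

Reading the numbers: ~21.5 cell-% recovers the planted 20% cleavage
probability (spike-in counting noise accounts for the rest); the classifier
recovers the planted 0.76/0.04/0.20 species split from three noisy libraries;
median persistence ≈ 0.24 matches the planted non-reversing fraction
(irreversible + protein-free = 0.24); and every site shows resection
(tracts averaging 400 bp, well past the 100 bp filter).

The same workflow runs from the shell:

```bash
endseq simulate --out-dir sim --chrom chr1:2000000 --n-sites 50 --seed 1
endseq run-all run.yaml     # paths + parameters in YAML; see `endseq run-all --help`
```

producing per-sample quantification, persistence, species, and resection
tables plus RPM bedGraph tracks and a run manifest.

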