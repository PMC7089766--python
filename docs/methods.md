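# Methods

## Observation model

END-seq captures DNA double-strand-break ends: after blunting, each sequenced
read marks one end position. We model a library as a set of single-base read
ends (internally 0-based, half-open BED coordinates throughout). At a break
site, per cell, a TOP2-mediated lesion is present with probability
`p_cleaved`; a lesion belongs to exactly one of three species:

| species | washout behaviour | ExoVII+ExoT | ExoT only |
|---|---|---|---|
| reversible TOP2cc | re-ligates; absent after washout | seen (pre only) | not seen |
| irreversible TOP2cc | survives washout protein-linked | seen | not seen |
| protein-free DSB | survives washout; substrate for resection | seen | seen |

A lesion observable under a sample's (nuclease, timepoint) emits exactly one
read end. Protein-linked and pre-washout emissions fall within a small
blunting jitter of the summit (default ±3 bp). Protein-free lesions observed
at a washout timepoint have been exposed to resection: their read end is
displaced from the summit by a one-sided tract length drawn from an
exponential distribution (mean `resection_mean_bp`, renormalized-truncated at
`resection_max_bp`, default 2500 bp), on a uniformly random side; left-side
ends carry the minus strand. The exponential is the simplest one-parameter
law with the monotone decay observed in resection tracks. A second washout
timepoint applies an extra survival probability (default 0.5) to
irreversible and protein-free lesions, modelling ongoing repair between
0 h and 2 h.

Spike-in sites emulate zinc-finger-nuclease breaks carried by a known
fraction of library cells (default 0.025, i.e. 1:40): each spike site emits
one read end per spike-in cell, never resected. Background noise is uniform
over the genome at `background_rate` read ends per kb (default 0.05).
Site placement enforces ≥ 10 kb between summits and ≥ 5 kb to chromosome
ends so 5 kb analysis flanks never overlap. All randomness flows from one
integer seed; each sample's stream is derived from (seed, sample_id), so
samples are independently and deterministically reproducible.

What the generator does **not** emulate: fragment lengths (ends are 1 bp),
sequence context and mappability, replication/transcription collisions,
strand asymmetries of resection chemistry beyond the side↔strand tag, and
chromatin-dependent cleavage preference. Passing recovery tests therefore
demonstrates estimator correctness under the stated sampling model, not
robustness to alignment artifacts or biological confounders in real data.

## Estimators

**RPKM / coverage.** Read ends are binned (`floor(pos / bin_width)`); RPKM
of an interval is `reads_in_interval / (kb × millions_of_library_reads)`.
Counting uses end positions, not fragment overlap — END-seq reads mark DNA
ends, so end-position counting is the faithful reading. Intervals not
aligned to bin edges weight partial bins fractionally; at `bin_width = 1`
(the pipeline default) counting is exact. Strand-split tracks keep the full
library size as the normalization denominator.

**Detection.** A candidate site is detected when
`RPKM_treated / (RPKM_control + pseudocount) > fold_threshold` (defaults:
10-fold, pseudocount 0.1 RPKM on the control only). The pseudocount makes
zero-control sites well-defined; no statistical peak model is implied — the
package expects a candidate list and implements only the fold filter.

**Cell-percentage.** With spike-in fraction *f*,
`cell% = RPKM_peak / mean(RPKM_spike) × 100f`. The mean over spike summits
(rather than the sum) is used and exposed. Because END-seq signal is
point-concentrated, the per-kb term of RPKM does not cancel between windows
of different lengths: peak windows should match the spike window
(default summit ± 1 kb) whenever the *absolute* cell-percentage scale
matters. Ratios across samples — persistence, species fractions — are
insensitive to a common mismatch.

**Persistence.** `P = S(t) / S(0)` per site, within one treatment arm, with
the pre-washout ExoVII+ExoT sample as initial. Not clipped above 1 (gains
are reported); sites with zero initial signal are excluded and counted;
sites missing at a timepoint contribute 0 rather than being dropped, which
would bias persistence upward. Summaries report median and quartiles
(box-plot analog) plus the mean.

**Species fractions.** All relative to the pre-washout ExoVII+ExoT signal,
the only convention under which `[TOP2cc]_I = 1 − [DSB] − [TOP2cc]_R` is a
conservation law over the initial lesion pool. `[DSB]` uses the ExoT-only
signal at 0 h washout by default (flag-switchable to pre-washout). Ratios
outside [0, 1] from sampling noise are clamped and the triple renormalized;
clamp counts are reported as QC. Genome-wide aggregation is either `pooled`
(sum signals, then ratio — signal-weighted) or `per_site_mean` (average the
per-site triples). Inputs should share a scale: cell-percentage when spike-in
is available, RPKM otherwise.

**Resection endpoints.** Per side of a summit: fifty 50 bp signal bins
(summit → 2.5 kb; bin 1 starts at the summit) and fifty background bins
(2.5 → 5 kb) whose **maximum** is the background level, computed per side.
A 10-bin window slides outward with stride one bin; at the first position
where ≥ 6 of 10 bins ("more than half", with the tie at exactly 5 counting
as not-triggering) have signal ≤ background, the endpoint is the outer edge
of the last strictly-above-background bin inside the window. Degenerate
cases are resolved as: no above-background bin inside the triggering
window → fall back to the last above-background bin before it (0 when
none); no window ever triggers → cap at 2500 bp. "Above background" is
strict `>`, consistent with "equal to or lower" defining the below set. A
break is resected when `max(left, right) > 100` bp (strict). An unstranded
mode (default) and a stranded mode (minus-strand coverage for the left
side, plus-strand for the right) are provided, since resection polarity may
or may not be encoded in read strand depending on protocol details.

**Overlap (Venn) counts.** Summit pairs on the same chromosome within a
maximum distance (default 250 bp) are matched greedily nearest-first, each
site used once. Replicate agreement uses Pearson correlation on paired
per-site signals.

## Numerical and design choices

* Coordinates 0-based half-open everywhere; bedGraph output merges adjacent
  equal bins after formatting to 6 significant digits and omits zero bins.
* The lesion-truth table carries the truncation cap alongside the mean so
  it round-trips losslessly; fractions are written with 6 decimals and
  renormalized on read (sum restored to 1 within 1e-9).
* The 2 h washout survival parameter is a deliberate simplification: repair
  between timepoints is measured by the estimators, not mechanistically
  modelled.
* Pipeline defaults mirror the method's printed parameters: 50 bp bins,
  10-bin window, 2.5 kb scan, 2.5–5 kb background, > 100 bp filter, 10-fold
  detection, spike fraction 0.025.
* The command-line pipeline writes tables with `%.6g` floats and a manifest
  (config hash, seed, version), making reruns bit-identical.

## Problem sizes

Tests and the acceptance script use desk-scale simulations chosen so that
recovery tolerances are dominated by the estimator, not the sample size:
150–200 sites, 800–2000 cells per sample, 10–25 spike-in sites, genomes of
1–2.4 Mb at single-base binning. Statistical assertions use three standard
errors, including the shared spike-in denominator noise where it dominates
(full-penetrance calibration, persistence recovery).

## Known limitations

* The fold-enrichment detector assumes a candidate site list; it is not a
  peak caller and has no multiple-testing control.
* Cell-percentage accuracy depends on matched peak/spike windows and on the
  spike-in fraction being exact; pipetting error in the spike ratio
  propagates linearly into all absolute percentages.
* The endpoint caller's resolution is one 50 bp bin and its scan saturates
  at 2.5 kb; tracts longer than the scan are reported at the cap.
* Persistence at sites near the detection limit is noisy because the
  denominator is itself an estimate; the per-site tables carry enough
  information to filter by initial signal if needed.
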