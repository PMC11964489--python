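# Methods

## Model and assumptions

The current level recorded while a k-mer occupies the pore is modelled as
a per-k-mer constant μ(kmer) plus i.i.d. Gaussian noise with spread
σ(kmer). The segmentation of signal into per-base events is *given* — by a
basecaller move table or an `ss` run-length alignment — and is taken as
approximately correct: the package never re-segments signal. Model quality
therefore degrades with alignment quality, which is why the event filters
below exist. One event is the signal segment attributed to a single base
(move-table semantics: one segment per emitted base), not a concatenation
of k segments; the k-mer label is the sliding window anchored at that base,
shifted by `move_offset` whole bases when the basecaller's emission
register differs from the model's.

Direct RNA translocates 3′→5′, so in RNA mode reads are traversed in
reverse; emitted k-mer strings remain written 5′→3′ and only the pairing
order changes. U is mapped to T on ingest; models are stored over
{A,C,G,T}.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `k` | 5 | bases | smallest register that spans the significant positions of recent RNA chemistries |
| `sample_limit` | 5000 | events/k-mer | conservative cap; quality saturates near depth 100 (see depth sweep) |
| `min_dur`, `max_dur` | 20, 40 | samples | margin around the ~30 samples/base of a 130 b/s pore at 4 kHz; bounds are strict (`min < d < max`), `inclusive_duration` switches to closed |
| `max_event_stddev` | off | normalized units | discards unstable events when set; no universal value exists, so it is opt-in |
| `indel_skip` | 2 | bases | masks alignment slop around insertions/deletions |
| `move_offset` | 0 | bases | register shift between events and windows |
| scaling | med-mad | — | robust per-read normalization; raw MAD without the 1.4826 Gaussian consistency factor, since the factor only rescales an affine space that the pA transform re-fits (flag available) |
| stddev interval | [2.5, 4] | pA-model units | heuristic range event aligners expect; min-max mapped, order preserved |
| significance `num_bins` | 10 | edges | read as 10 evenly spaced *edges* over the pooled range (9 bins); `bins_as_edges=False` gives the bin-count reading |
| significance `threshold` | 0.96 | similarity | indices whose mean pairwise histogram correlation falls below it are significant |
| F1 `tolerance` | 1 | bases | a query point may map one base left/right of the truth and still count as TP |

The cap counts *stored* (post-filter) events by default, maximizing usable
data; `strict_cap=True` counts every observation against the cap,
reproducing a per-observation counter exactly. Global mean/stddev for the
pA transform are pooled over the pA samples of the fitted read set.
K-mers below `min_samples` stored events are omitted from the model rather
than imputed — silent imputation would corrupt downstream alignment
invisibly; completeness is always reported alongside.

## Synthetic data: what it emulates and what it does not

The simulator emulates: per-base dwell times as a rounded, clipped normal
(mean 30, sd 3, bounds [20, 40] samples); per-sample Gaussian current
noise with the truth model's per-k-mer spread; ADC quantization and the
raw→pA calibration path; exact ground-truth `ss` segmentation; optional
3′→5′ RNA traversal; and corrupted alignments (indels, boundary jitter)
for exercising the masking and F1 < 1 paths. Sequences are uniform random
or cut from a de Bruijn super-sequence of order k so that every k-mer is
observed once per pass — the cheapest route to a target per-k-mer depth.

The de Bruijn super-sequence is generated as a **random Eulerian circuit**
of the de Bruijn graph (seeded), not the deterministic Lyndon-word
concatenation: Lyndon ordering is A-rich at one end and T-rich at the
other, so contiguous read-length chunks have strongly biased composition,
and per-read Med-MAD normalization — which assumes reads sample the level
distribution representatively, as real transcriptome reads do — is badly
distorted by it. The randomized circuit keeps exact single-coverage per
pass while giving chunks locally random composition.

Not emulated: pore-level noise structure (flicker, stalls, adapter/polyA
signal), basecaller miscalls (simulated sequences are exact),
inter-read level drift, or dwell-time heavy tails. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated noise
model, not robustness to every artifact of real signal; on real data the
event filters and read-level QC carry that burden.

## Numerical choices

- Event statistics are computed with cumulative-sum arrays
  (O(signal) per read); variance is clamped at 0 before the square root.
- Histogram similarity pools both lists to set the bin range; degenerate
  count vectors (zero variance) define similarity 1 with a warning, and
  bit-identical count vectors short-circuit to exactly 1.0 to avoid float
  drift in the all-equal-levels case.
- All 12 ordered base pairs are correlated per index; duplicates do not
  change the mean. Counts (not densities) are correlated — immaterial for
  complete models, where all four lists have equal totals.
- Collapsing requires a contiguous index set; a non-contiguous set would
  leave the reduced model's register within the pore ambiguous.
- `ss` serialization emits a comma after match and insertion runs (except
  the final op); the parser accepts commas anywhere between tokens.
- Med-MAD of a constant signal is undefined; such reads are skipped and
  counted, and a constant dataset fails fast at the pA transform
  (global stddev 0).

## Problem sizes used in tests and the acceptance script

Parameter recovery runs at k = 5 with every k-mer driven to ≥100 stored
events (336 reads of 500 bases) — the depth at which the depth titration
(5→200) saturates. Significant-index recovery runs at k = 9 with ~6 events
per k-mer (462 reads of 4000 bases): the index statistics aggregate
4^8 levels per base list, so shallow per-k-mer depth already averages the
event noise far below the level separation, and deeper sampling of the
262 144-k-mer space adds nothing to the check. These sizes were chosen as
the smallest that exercise the saturation and recovery claims.

## Known limitations and non-goals

- No signal re-segmentation, basecalling, or execution of external event
  aligners; alignment-rate tables from such tools can be parsed but not
  generated.
- BLOW5 (binary) containers are not read; convert to ASCII SLOW5 first.
- Iterative model refinement (re-aligning with the new model and
  re-estimating, GMM-based fitting) is a documented workflow around the
  package, not implemented in it: the `build` CLI consumes any
  `ss`-tagged PAF, so a refined alignment can simply be fed back in.
- Non-contiguous reduced models are deliberately unsupported.
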