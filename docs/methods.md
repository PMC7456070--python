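# Methods

This document defines the computational model implemented by `prfscan`,
the parameters and their defaults, and the known limitations.

## Biological model

Loss of wybutosine-pathway modification of tRNA-Phe destabilizes
codon–anticodon pairing on UUU/UUC codons and promotes −1 programmed
ribosomal frameshifting (PRF) at Phe-type slippery sequences. A −1 slip
typically exposes a premature termination codon (PTC) in the new frame;
transcripts whose PTC lies sufficiently upstream of an exon–exon junction
are degraded by nonsense-mediated decay (NMD). At the transcriptome level
this predicts that transcripts carrying Phe-type −1 PRF signals are
over-represented among down-regulated transcripts, while Lys-type signals
(AAAA/G, read by tRNA-Lys, whose modification is unaffected) and
transcripts lacking UUU/UUC codons altogether serve as negative controls.

The package implements each step as a self-contained, testable model:

1. slippery-site detection with tRNA attribution,
2. downstream stimulatory-structure scoring with a permutation null,
3. −1 slip simulation, PTC localization and the 50-nt NMD rule,
4. Fisher enrichment of signal classes among down-regulated transcripts,
5. dual-reporter (luciferase / GST) quantification arithmetic,
6. a synthetic transcriptome generator with exact ground truth.

## Coordinates and data model

A `TranscriptModel` carries a CDS (RNA alphabet, length a multiple of 3),
the transcript coordinate of the CDS start (`cds_offset`) and a sorted
tuple of exon–exon junction positions. A junction value is the transcript
coordinate of the **first base after** the junction. All CDS positions
are 0-based; site intervals are half-open.

## Slippery-site detection

A slippery heptamer is X XXY YYZ: positions 1–3 homopolymeric and
positions 4–6 homopolymeric. Sites are only reported when frame-anchored,
i.e. the heptamer start ≡ 2 (mod 3), so that the P-site codon is N2N3N4
and the A-site codon is N5N6N7 during the slip. tRNA attribution uses the
A-site-proximal tetramer N4–N7: `UUUU`/`UUUC` → `phe`, `AAAA`/`AAAG` →
`lys`, anything else → `other`. With `phe_mode="any_codon"` a heptamer
also counts as Phe-associated when either decoded codon is UUU/UUC (the
HIV-1 heptamer U UUU UUA is `other` under the default suffix rule but
Phe-attributed P-site under `any_codon`).

## Stimulatory-structure scoring

For each site and each spacer in `[min_spacer, max_spacer]` (defaults
5–9 nt) the window of `window_len` (default 70 nt) starting after the
heptamer plus spacer is folded by Nussinov-style base-pair maximization
(A·U, G·C and G·U wobble pairs; a pair (i, j) is admissible iff
`j − i > min_loop`, default 3). The spacer maximizing the pair score is
reported as the stimulatory element, with one deterministic optimal
dot-bracket traceback. Base-pair maximization was chosen over a
thermodynamic energy model because it is parameter-free (apart from the
loop constraint) and exactly verifiable against brute-force enumeration;
energy-model folding is an extension point.

**Significance.** The z-score and permutation p are computed on the
*full candidate region* — from the `min_spacer` window start to the
`max_spacer` window end (74 nt at defaults) — as a plain permutation
test: the region is mononucleotide-shuffled `n_perm` times (default 100),
each shuffle refolded, and `z = (observed − mean) / sd` of the shuffled
scores, with `p_perm = (1 + #{shuffle ≥ observed}) / (n_perm + 1)`.
A signal *passes* iff the element exists, its pair score ≥ `min_pairs`
(default 15), the null is non-degenerate, and `z ≥ z_cutoff` (default
1.64, one-sided 5%).

The test is deliberately **not** run on the selected best-spacer window:
comparing the maximum of five heavily overlapping windows to the shuffle
null of a single window is selection-biased, and measured null pass rates
roughly doubled (≈11% instead of the nominal 5%). With the region-level
test the measured null pass rate on 300 shuffled-downstream constructs is
5.3%, the null z distribution is centred (median −0.03, 95th percentile
1.69), and planted 24-bp stem-loops still pass 300/300 with z ≥ 2.66.

Per-site permutation seeds are derived deterministically from the scan
seed, the site start and a CRC of the transcript id, so results are
reproducible and independent of scan order.

## Frameshift simulation and NMD

`simulate_minus1` moves the ribosome back one nucleotide at the site:
translation resumes at CDS position `site.start + 3` in the −1 frame and
steps in codons until the first UAA/UAG/UGA, the PTC. The distance to the
next exon–exon junction is `j − (cds_offset + ptc_start + 3)` for the
smallest junction `j` at or beyond the stop codon's end. NMD is predicted
iff a PTC exists and this distance is ≥ 50 nt (inclusive). For a
transcript-level verdict the 5′-most passing Phe site is used.

## Enrichment statistics

Differential-expression status uses strict thresholds |log2FC| > 1.0 and
padj < 0.05 (configurable). The 2×2 table counts transcripts
(deduplicated by id): rows = down-regulated vs comparator, columns =
signal-positive vs not. Two comparators are supported:

- `up_regulated`: down vs up transcripts (symmetric, conservative);
- `prfdb_background`: down vs all non-down scanned transcripts. A
  comparison of down-regulated transcripts against "all transcripts in
  the database" would put overlapping sets in the two rows of a Fisher
  table; rows must be disjoint, so the background comparator is defined
  as the complement (all non-down transcripts).

The one-sided (`one_greater`) or two-sided hypergeometric tail is
computed with log-factorials (`lgamma`); the two-sided p sums all tables
with point probability ≤ observed (with a 1+1e−7 tie tolerance). The
odds ratio is `(a·d)/(b·c)` (infinite when `b·c = 0`). `control_panel`
runs the three classes (`phe_uuuu_c`, `lys_aaaa_g`, `no_phe_codon`)
against both comparators with identical machinery; a Bonferroni helper
is provided but no correction is applied implicitly.

## Reporter quantification

Dual-luciferase: each replicate is normalized firefly/renilla; the
readout is mean(test)/mean(control). Dual-GST percent −1 PRF is
`100 · dual / (dual + single)` band intensity. Group comparison is an
unpaired pooled-variance two-tailed t test (via scipy); two identical
constant groups return (0, 1), and zero pooled variance with unequal
means is an error rather than a fabricated p-value.

## Synthetic data generator

Background CDSs are drawn codon-wise from the 61 sense codons, with a
terminal stop and no internal in-frame stops. By default, sequences
containing *accidental* frame-anchored Phe/Lys heptamers are rejected
and redrawn (bounded retries), so the planted truth is exact. A planted
cassette is: frame-anchored heptamer + 6-nt spacer + perfect stem-loop
(24-bp stem, 4-nt loop) + a planted −1-frame stop, with an exon–exon
junction placed at a recorded distance (55–150 nt) downstream of the
PTC. Differential expression follows a logistic model:
`logit(q) = logit(base_p_down) + log(odds_ratio) · 1[phe-planted]`;
emitted log2FC/padj values deterministically satisfy the thresholds for
the assigned status. The generator records every planted quantity in a
`TruthTable` keyed by transcript id.

### Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| `min_spacer`, `max_spacer` | 5, 9 nt | canonical spacer range between heptamer and stimulatory structure |
| `window_len` | 70 nt | accommodates stem-loops and small pseudoknot-scale elements |
| `min_pairs` | 15 | roughly half the pairs of a strong stem-loop in a 70-nt window |
| `min_loop` | 3 | minimal sterically plausible hairpin loop |
| `n_perm` | 100 | p-resolution 1/101 ≈ 0.01, adequate for a 0.05 cutoff |
| `z_cutoff` | 1.64 | one-sided 5% under an approximately normal null |
| NMD threshold | 50 nt (inclusive) | the exon-junction rule |
| DE thresholds | log2FC > 1, padj < 0.05 (strict) | conventional |
| `hairpin_stem_len` | 24 bp | chosen by pre-registered benchmark so planted elements pass with wide z margins (min z ≈ 2.7 across 300 constructs); 18 bp left a tail of misses |
| `planted_junction_distance` | 55–150 nt | always above the 50-nt rule so planted outcomes are unambiguous |

In large simulation experiments (e.g. the acceptance parameter-recovery
study) `n_perm = 30` is used as a problem-size/runtime choice: planted
stems pass with z margins far above the cutoff, so permutation
resolution does not limit recovery. This was fixed before looking at
outcome statistics, not tuned to them.

## Limitations

- Base-pair maximization ignores stacking thermodynamics and cannot
  score pseudoknots; scores are structure *capacity*, not free energy.
- The mononucleotide shuffle null preserves composition but not
  dinucleotide content.
- `TranscriptModel` does not carry total transcript length, so junction
  coordinates are validated only as non-negative and sorted; junctions
  may legitimately lie past the CDS end (3′ UTR).
- The NMD rule is the simple 50-nt heuristic; long-3′UTR and
  start-proximal exceptions are not modeled.
- The enrichment model treats transcripts independently; no gene-level
  aggregation or expression-matched resampling is performed.
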