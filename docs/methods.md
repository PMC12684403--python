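# Methods

`chimbench` builds ground-truth long-read full-ITS amplicon datasets, runs a
parameterized de novo chimera detector over them, scores the detections
against the planted truth, and applies reference-based secondary validation.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not capture.

## Synthetic community model

Each species is an ITS1–5.8S–ITS2 template. ITS1 and ITS2 are drawn
independently per species with uniform base composition (lengths uniform on
120–400 bp and 150–420 bp), so between-species spacer identity sits near the
~25 % random floor — a deliberately pessimistic stand-in for real ITS
divergence that makes chimeric joins unambiguous. The 5.8S is a single
community-wide consensus (157 bp) mutated per species with exactly
`round(d58 · 157)` substitutions (default `d58 = 0.03`, i.e. 5 sites), so
conservation is guaranteed rather than merely expected; this conserved anchor
is what makes concatemer detection by 5.8S multiplicity meaningful.

Study-scale defaults are 186 species with 1,000–9,000 reads each, counts
drawn uniformly per species. Tests and the acceptance script run a scaled
community of 20 species × 450–550 reads (~10,000 reads, ~3,500 dereplicated
records), which keeps a full detector pass within a couple of minutes on one
core while preserving the abundance structure the detector needs.

### Read error model

Reads pass through an independent per-base channel with substitution,
insertion and deletion probabilities (defaults 0.002 / 0.0025 / 0.0025 per
pass). Each read is treated as the consensus of `passes` subreads, drawn
uniformly from 1–30; its effective error rate is the channel rate divided by
its pass count. The division is a deliberately simple stand-in for consensus
polishing, chosen because it reproduces the one property of multi-pass
long-read data the benchmark depends on: a substantial fraction of reads is
exactly error-free and dereplicates onto its template, giving every species
an abundant representative — without abundant parents, reference-free
detection has nothing to lever. Per-base qualities are HiFi-like (Phred
85–93, capped at the PacBio maximum of 93) on error-free bases and 10–25 on
realized-error bases; 5 % of reads are emitted with globally low quality
(Phred 2–12) so that maximum-expected-error filtering (`maxEE ≤ 1`,
inclusive boundary, with a 1e-9 relative float tolerance so 100 bases at Q20
sit exactly on the boundary) has something to remove.

What the generator does **not** model: phylogenetically structured ITS
similarity (closely related species are a documented hard case for chimera
detectors and are absent here), homopolymer-biased indels, chimera formation
kinetics across PCR cycles, and primer remnants. Passing tests therefore
show that the machinery behaves as specified under idealized divergence, not
that any particular operating point transfers to real communities.

## Artifact forging

**PCR chimeras.** Parents are sampled uniformly from dereplicated records
with abundance ≥ 2 and distinct species of origin (template switching joins
different molecules; a same-species join would be indistinguishable from its
template and is not a meaningful artifact). A breakpoint region is chosen
per parent with weights ITS1/5.8S/ITS2 = 0.4/0.2/0.4, the breakpoint uniform
inside that region; the child is `a[:bp_a] + b[bp_b:]` (three-parent
chimeras, 5 % of cases, append a third suffix). Breakpoints are resampled
(≤ 100 attempts) until the child/parent length ratio lies in [0.7, 1.1] for
every parent. 2 % of chimeras have their 3′ segment reverse-complemented —
the strand artifact that breakpoint detectors miss unless they search both
strands. Chimera abundance is uniform on {1 … ⌊min(parent abundances)/2⌋},
which guarantees an abundance skew ≥ 2 toward each parent. The suffix
convention for later segments is what makes every chimera exactly
reconstructable from (parents, artifact-coordinate breakpoints, reverse-
complement flags, child length) alone — a self-consistency oracle the test
suite runs on every generated set.

**Concatemers.** 2–3 tandem copies of a single parental molecule (the
adapter-skip/re-ligation library artifact), abundance 1. Each copy carries a
complete 5.8S, so a k-copy concatemer has exactly k model hits in the 5.8S
scan; having no two-distinct-parent breakpoint structure, they are at best
accidentally flagged by the breakpoint detector and are the reason the
secondary validation exists.

Spiking steers totals so chimeric reads make up `chimera_fraction` (default
6.2 %) and concatemers `concatemer_fraction` (default 0.5 %) of the final
read count, both within one read of the target. Duplicate artifact
sequences are re-forged so the spiked record set stays dereplicated. The
truth table carries one row per record with class, parents, breakpoints,
reverse-complement flags and abundance.

## Detector

For each query, candidate parents are records with abundance ≥
`abskew × abundance(query)` (self excluded). The pool is pruned to
`top_candidates` (default 4) *chunk-aware*: the query is split into four
chunks and each chunk's best candidate by shared 8-mers is kept before
filling remaining slots by whole-query sharing. Flat whole-query ranking
systematically starves the minority parent of an asymmetric chimera (all
four slots go to variants of the majority species); per-chunk selection is
the standard remedy and restores recall on exactly those reads.

Each candidate is mapped onto the query by global alignment (match +1,
mismatch −1, gap of length L costs 1 + 2L; `N` matches nothing, including
`N`). For an ordered pair (A, B), the breakpoint maximizing the number of
query positions explained (prefix sums, first optimum on ties) defines the
model; three-part models optimize two breakpoints the same way. Per
segment, query positions are classified as **Y** (matches the segment's
model parent, not the others), **N** (matches the others, not the model
parent) or **Abst** (matches no parent), and

    h = min over segments of  Y / (Y + xn·N + dn·Abst),

zero when a segment has no classified positions. The minimum over segments
(rather than a pooled ratio) is load-bearing: a pooled ratio awards a
near-perfect score to any noisy read whose own template dominates one huge
segment, while the minimum demands that every segment be independently
supported. `h = 1` exactly when every segment has Y > 0 and N = Abst = 0.

Divergence `div_pct` is the improvement of the model over the best single
candidate, in percentage points of query positions explained
(`100·(model_matches − best_single_matches)/L`). Gating on improvement
rather than on raw distance from the nearest parent is what keeps
noisy-but-genuine reads clean: their own template already explains them, and
no two-parent model can do meaningfully better. This is also why two
abundant chimeras that happen to bracket a genuine read's species cannot
turn it into a false positive — their combined model never beats the
template by more than `mindiv`.

A query is **chimera** when some candidate model passes every gate
(h ≥ `minh`; Y ≥ `mindiffs` per segment; segment length ≥
`min_segment_len`; div ≥ `mindiv`; query/model mismatch ≤ `max_diff_pct`),
**borderline** when its best is a model that passes everything except the
per-segment `mindiffs` count, and **clean** otherwise. "Some model" rather
than "the single best-scoring model" keeps the flagged set monotone under
gate relaxation, which the directional tests rely on. Borderline is
deliberately not triggered by a failing divergence gate: a model that cannot
beat the nearest single parent is the signature of a genuine read, not of a
near-threshold chimera.

Defaults mirror the two published parameter families: the vote-scoring
family (abskew 2, minh 0.28, mindiffs 3, dn 1.4, xn 2, mindiv 0.8) and the
segment-constraint family (abskew 1, minimum segment length 10, mismatch
percentage disabled, 2 or 3 parts). Sweep presets enumerate 49 runs for the
first family and 22 for the second (default + one-factor-at-a-time over the
published ranges + the published winning combinations). An optional
both-strand mode adds reverse-complemented candidate orientations; it is off
by default, which reproduces the reported failure on reverse-complement-
segment chimeras.

`detect_bruteforce` re-implements the same contract with no pruning and a
naive exhaustive breakpoint scan (≤ 50 records, ≤ 1,000 bp) and serves as
the equivalence oracle; tie-breaking (first-optimum breakpoints; models
ordered by explained positions, then ΣY, then parent ids and strands) is
part of the contract so the two paths agree call-for-call.

Known behavior: directional monotonicity in `abskew` is guaranteed only
with pruning disabled (a smaller candidate pool can only remove models). At
a fixed pruning budget, raising `abskew` can exclude an abundant chimera
record from a pool and thereby *unmask* a true parent, so the dataset-level
flagged count is not strictly monotone; the equivalence-mode test covers the
guaranteed regime. Tandem concatemers may or may not be flagged depending
on whether an unrelated candidate's gapped alignment happens to explain the
extra copies; the 5.8S scan is the reliable net for them.

## Scoring

Positive truth is {pcr_chimera, concatemer} (a flag restricts to PCR
chimeras); borderline verdicts count as chimeric by default. Counts are in
reads: each dereplicated record is weighted by its abundance, so
tp+fp+fn+tn equals the number of scored reads. Precision = tp/(tp+fp),
recall = tp/(tp+fn), F1 = 2PR/(P+R). Degenerate conventions: no positive
truth and no positive calls is perfect (P = R = F1 = 1); positive calls with
no true positives give precision 0; no calls at all with positive truth give
recall 0. Per-class recall is reported for PCR chimeras and concatemers
separately. Best-run selection is argmax F1, ties broken by precision, then
by fewer non-default parameters, then grid order.

## Secondary validation

* **False-positive rescue**: a flagged read whose best reference alignment
  reaches ≥ 99 % identity at ≥ 99 % query coverage (both inclusive) is
  rescued as genuine. Coverage comes from a semi-global alignment (query
  end-to-end, target overhangs free), so it is 100 by construction and
  identity carries the signal; identity is computed over alignment columns,
  gaps included.
* **False-negative flagging**: the best non-self hit against sample reads
  plus references, found by iterated best-local-alignment with query
  masking (HSPs never overlap on the query; "first HSP" = highest-scoring).
  A read is a missed chimera when the best hit has ≥ 2 HSPs and the first
  HSP covers < 85 % of the query (strict). The database scan prescreens the
  top 10 targets by shared 8-mers before running full dynamic programming.
* **5.8S multiplicity**: greedy non-overlapping local alignments of a 5.8S
  model sequence (identity ≥ 85 %, model coverage ≥ 0.8). For synthetic
  communities the model is the generative consensus, so planted counts are
  recovered exactly; for real data a curated 5.8S sequence must be
  supplied — this is consensus alignment, not a covariance-model search,
  and it will not find strongly diverged or structurally rearranged 5.8S
  copies.

## Problem sizes

Unit fixtures are tens of records; the equivalence suite runs 200+ random
instances of ≤ 10 records × ≤ 110 bp; the benchmark community is 20 species
× 450–550 reads; validation fixtures use a 10-species community with ~45
dereplicated records. The acceptance script additionally scans planted
false-negative sets of 1,244–1,297 reads for 5.8S multiplicity. These sizes
were chosen so a full run of the suite and the acceptance script each stay
in the minutes range on a single core; all of them are configuration, not
constants, and scale up by editing `CommunityConfig`/`ForgeConfig`.
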