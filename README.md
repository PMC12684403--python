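# chimbench

Ground-truth benchmarking of de novo chimera detection for long-read
full-ITS amplicon data.

PCR chimeras — amplicons formed when an incompletely extended fragment
primes on a different template — and library-prep concatemers — two or more
complete amplicons ligated end-to-end — distort diversity estimates in
metabarcoding studies, and the reference-free filters used to remove them
(UCHIME-style abundance/vote scoring) trade precision against recall through
a thicket of parameters. `chimbench` is for people who need to *measure*
that trade-off: it simulates a PacBio-like full-ITS community where the
origin of every read is known, plants chimeras and concatemers with recorded
parents and breakpoints, runs a parameterized detector over the result,
scores precision/recall/F1 against the truth, sweeps parameter grids, and
applies reference-based secondary validation (false-positive rescue,
split-HSP false-negative flagging, 5.8S-multiplicity concatemer scans).

## The core model

A de novo detector tests each query `Q` against candidate parents at least
`abskew` times more abundant. For an ordered parent pair (A, B) it picks the
breakpoint maximizing the query positions explained by the segmented model
A|B, classifies each position per segment as supporting (**Y**: matches the
segment's parent, not the other), contradicting (**N**) or unexplained
(**Abst**), and scores

    h = min over segments of  Y / (Y + xn·N + dn·Abst)

`Q` is flagged when `h ≥ minh`, every segment has `Y ≥ mindiffs` and length
`≥ chimeras_length_min`, and the model explains the query at least `mindiv`
percentage points better than the best single parent. Detections are scored
as precision `P = TP/(TP+FP)`, recall `R = TP/(TP+FN)` and
`F1 = 2PR/(P+R)` in reads, with borderline calls counted as chimeric and
concatemers counted as true artifacts. `docs/methods.md` has the full
account, including what the simulator does and does not emulate.

## Worked example

```python
from chimbench import (
    CommunityConfig, ForgeConfig, DetectorParams,
    make_templates, sample_abundances, simulate_reads,
    maxee_filter, spike_dataset, detect, score_calls,
)

cfg = CommunityConfig(n_species=20, per_species_reads=(450, 550), seed=7)
templates = make_templates(cfg)
reads = simulate_reads(templates, sample_abundances(templates, cfg), cfg)
kept, dropped = maxee_filter(reads, maxee=1.0)
spiked, truth = spike_dataset(kept, templates, ForgeConfig(seed=8))

counts = score_calls(detect(spiked, DetectorParams()), truth)
print(f"P={counts.precision:.4f} R={counts.recall:.4f} F1={counts.f1:.4f}")
print({k: round(v, 3) for k, v in sorted(counts.recall_by_class.items())})
```

prints

```
P=1.0000 R=0.9190 F1=0.9578
{'concatemer': 0.44, 'pcr_chimera': 0.958}
```

Read it as: of ~10,000 reads (6.2 % chimeric, 0.5 % concatemers), every read
the detector flagged at the vote-scoring defaults really was an artifact
(precision 1.0); it recovered 95.8 % of PCR-chimera reads but under half of
the concatemer reads — tandem repeats of a single molecule carry no
two-parent breakpoint, which is why the secondary 5.8S-multiplicity scan
(`chimbench.validate`) exists. Dropping `minh` from 0.28 to 0.09 raises
recall further at unchanged precision on this dataset.

The same pipeline is scriptable from a shell (`chimbench simulate`,
`chimbench spike`, `chimbench detect`, `chimbench sweep`, `chimbench score`,
`chimbench validate`); run `chimbench --help`.

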