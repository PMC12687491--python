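# pioneerscope

Analysis toolkit for studying **pioneer transcription-factor activity** of
MADS-domain proteins — the ability of a TF such as APETALA1 (AP1) to bind
its CArG-box targets (consensus `CC[W]5–7GG`, W = A/T) inside closed,
nucleosomal chromatin and trigger its opening. MADS-domain dimers can
assemble into tetramers that bind two CArG boxes simultaneously and loop
the intervening DNA, with a preferred inter-box spacing around 40–60 bp;
`pioneerscope` implements the computational procedures that detect and
quantify this behaviour from genomics and in-vitro binding data:

- **SELEX affinity mapping** (`pioneerscope.selex`) — map a table of
  12-mer relative binding affinities (the product of an in-vitro SELEX-seq
  selection) onto a genome and call affinity peaks: hits above the median
  affinity of all table entries are unioned, candidate regions separated
  by < 3 bp are merged, regions with ≥ 2 supporting k-mers are kept, and
  each peak is scored by the mean affinity of its contributing k-mers.
- **Spacing enrichment** (`pioneerscope.spacing`) — a distance-window
  hypergeometric test: for each 20-bp centre-to-centre distance window,
  peak pairs inside the top-scoring TF-bound regions (both peaks within
  ±200 bp of a region centre) are compared against all peak pairs
  genome-wide, `p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`. A minimum-p
  window containing the tetramer spacing is the looping signature.
- **Chromatin classification** (`pioneerscope.classify`) — split
  FDR-significant binding sites into closed/open chromatin at a threshold
  defined as the midpoint between the median ATAC accessibility (RPKM) of
  regions overlapping nucleosome-free vs nucleosome-containing regions,
  then by accessibility dynamics after TF induction (increasing:
  FC > 1.2 & p < 0.1; decreasing: FC < 0.8 & p < 0.1; steady:
  0.8 ≤ FC ≤ 1.2 & p > 0.1) into nine categories. Also ranks WT- vs
  tetramerisation-mutant-specific sites by log2 RPKM ratio, draws random
  400-bp control regions, and links differentially expressed genes
  (|log2FC| > 1, FDR < 0.05) to binding sites within 3 kb upstream to 1 kb
  downstream.
- **MNase depletion ranking** (`pioneerscope.mnase`) — rank sites by the
  MOCK/DEX ratio of mean MNase coverage over an inclusive ±40 bp window
  around the peak summit; the top-500 group collects sites losing
  nucleosome protection after induction, and its overlap with the
  chromatin categories is compared against the bottom-500 group.
- **Histone-mark enrichment** (`pioneerscope.marks`) — mark × category
  contingency counts (≥ 1 bp site overlap) analysed as Pearson residuals
  `(O − E)/√E` with the chi-square test.
- **Kd estimation** (`pioneerscope.kdfit`) — dissociation constants from
  EMSA titration series via a Michaelis–Menten fit (Bound ~ Total,
  nonlinear least squares) and a Scatchard regression
  (Bound/Free ~ Bound, OLS; Kd = −1/slope). Both are reported because the
  linearisation is biased under noise.
- **Synthetic data** (`pioneerscope.simulate`) — a fully seeded generator
  that plants every signal the pipeline is designed to detect: CArG boxes
  singly and in ~50-bp pairs, a bimodal 12-mer affinity table,
  negative-binomial replicate ATAC counts with planted closed/open classes
  and dynamics, MNase tracks with planted depletion, and biased mark
  overlaps — each with a machine-readable truth table.

## Worked example

Run the whole chain — simulate → SELEX map → spacing → classify →
rank-specific → MNase rank → mark enrichment → Kd — on one synthetic
study:

```python
from pioneerscope import SimulationConfig, run_pipeline

manifest = run_pipeline(SimulationConfig(seed=1), "demo_run")
print(manifest["summary"])
```

which prints (abridged):

```text
n_selex_peaks:   803
min_p_window:    [40, 60]          # contains the planted 50-bp spacing
min_p_value:     2.88e-57
threshold_rpkm:  42.295
category_counts: {'wt_closed_incr': 127, 'wt_closed_steady': 205,
                  'wt_closed_decr': 63, 'wt_open_incr': 226,
                  'wt_open_steady': 376, 'wt_open_decr': 131,
                  'other_closed': 29, 'other_open': 43, 'other': 0}
chi2:            673.60            # mark x category, p = 4.99e-129
kd:              {'michaelis_menten': 2.158, 'scatchard': 1.052}
```

Reading the output: the 803 affinity peaks recover the 750 planted CArG
loci (plus a handful of chance matches); the spacing test's minimum-p
window [40, 60) bp captures the planted 50-bp tetramer spacing at
p ≈ 3×10⁻⁵⁷; the accessibility threshold (42.3 RPKM) falls midway between
the planted closed (15 RPKM) and open (70 RPKM) class means; the category
counts partition all 1,200 significant sites; and the Michaelis–Menten Kd
(2.16 nM) recovers the simulated truth of 2 nM while the Scatchard
linearisation shows its documented downward bias. The same stages are
available as subcommands of the `pioneerscope` CLI (`simulate`,
`selex-map`, `spacing`, `classify`, `rank-specific`, `mnase-rank`,
`mark-enrich`, `kd`, `run-all`); every run writes a `manifest.json` with a
SHA-256 digest per output, and a fixed seed reproduces every stage product
byte for byte.

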