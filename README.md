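# chromoci

Analysis of senescent nuclear reorganization from binned Hi-C contact
maps: the **open chromatin index (OCI)**, TAD boundary-insulation
comparison, isochore/LAD-stratified summaries, feature-class
interaction-change matrices, and HMM-based OCI-domain segmentation —
together with a synthetic Hi-C generator that plants the senescence-like
restructuring as machine-readable ground truth, so the whole pipeline is
benchmarkable without external data.

## Who this is for

Chromatin-architecture researchers who have condition-paired Hi-C data
(e.g. growing vs senescent fibroblasts, progeroid cells, ESCs) binned to
a fixed resolution and want to quantify the redistribution of contacts
from *local* (within-window, within-TAD) to *distal* and
interchromosomal interactions — the contact-level signature of
senescence-associated heterochromatic focus (SAHF) formation — and to
ask which sequence classes (GC-poor L1 isochores, lamina-associated
domains) drive it.

## The statistics

**OCI.** For each genomic window (default 200 kb) with local count
*L* (both Hi-C anchors inside the window) and control count *C*
(interchromosomal contacts anchored in the window, or in the cis-only
variant contacts spanning > 20 Mb):

```
raw      = log2((C + ψ) / (L + ψ)),   ψ = 1
centered = raw − median(raw over the chromosome's informative windows)
smoothed = centered, rolling mean over a 20 Mb span
```

High OCI ⇔ few local contacts relative to distal reach ("open"); a
region that loses within-TAD contacts between conditions *rises* in
OCI.

**TAD insulation.** Boundaries are called from sign changes of the
directionality index DI = sign(B−A)·((A−E)²/E + (B−E)²/E) with A/B the
up/downstream contact sums within 2 Mb and E = (A+B)/2. Each TAD yields
a 2×2 table [intra, cross] × [condition A, condition B] tested with
Fisher's exact test: *opening* if the cross-boundary fraction rises
(p < 0.05), *closing* if it falls (p < 0.25, deliberately lenient).

**Interaction-change matrices.** For bin classes a, b the distal
interaction score is `(obs(a,b)/Σobs) / (npairs(a,b)/Σnpairs)` over
pairs separated by ≥ 2 Mb (trans always eligible); the report is
log2(score_senescent / score_growing) per class pair.

**OCI domains.** A two-state Gaussian HMM on smoothed OCI labels the
lower-mean state "local (0)" and the higher "distal (1)"; Viterbi
decoding gives alternating domains, and a reference segmentation is
scored in another condition by each domain's fraction of distal-classed
windows (exactly {0, 1} when the structure is conserved).

## Worked example

`examples/02_open_chromatin_index.py` simulates a growing/senescent pair
(2 × 60 Mb genome, 200 kb bins, 2 M pairs per condition) with a planted
within-TAD contact loss f = 0.4 in L1-LAD TADs plus a 2× trans gain
between L1-LAD bins, then computes the OCI change:

```
  class   n     mean   median      q25      q75
H2-iLAD 424 0.404444 0.425264 0.317733 0.472760
 L1-LAD 176 0.485702 0.492297 0.415844 0.601356

delta-OCI > 0 in 100.0% of the 169 planted target windows
trans vs cis-distal control: sign agreement 100.0% on target windows
```

Every planted target window rises in OCI, the L1-LAD stratum rises most
(the 20 Mb smoothing bleeds part of the signal into flanking H2-iLAD
windows on this small genome), and the cis-only control reproduces the
same calls. `examples/04_interaction_matrices.py` shows the matrix side
of the same experiment:

```
isochore-LAD class matrix (log2 senescent/growing):
         H2-iLAD  L1-LAD
H2-iLAD   -0.029  -0.058
L1-LAD    -0.058   0.474
```

The matrix maximum is L1-LAD × L1-LAD — the GC-poor lamina-associated
regions specifically cluster — while the progeria-like run
(`local_loss=0.4, trans_gain=1.0`) leaves the histone-mark matrix near
zero (H3K9me3 × H3K9me3 = −0.027): losing local structure and forming
distal clusters are separable events. The remaining examples cover
simulation diagnostics, TAD insulation, and the HMM domain/clustering
analyses.

A thin CLI mirrors the library (`chromoci simulate | oci | tads |
enrich | rt | domains | cluster | demo`); `chromoci demo --seed 2 --out
demo/` runs the full chain and writes a truth-comparison report.

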