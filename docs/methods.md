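# Methods

## Scope and data model

The package analyzes three data modalities from a Barrett's-carcinogenesis
cell-line system and matched tissue screening: replicate karyotypes (ISCN
strings), per-nucleus dual-color FISH signal counts, and a bulk RNA-seq
FPKM matrix over a time course of acid/bile exposure (BEC0W → BEC60W).
Everything operates on derived, text-format inputs — signal *counts*, not
microscope images; FPKM values, not reads. No alignment, quantification or
fusion-transcript detection is in scope.

## ISCN dialect and recurrence

The grammar covers exactly the constructs that conventional G-banding of
these cultures produces: modal count, sex designation, `+n`/`-n` gains and
losses, `add`, `i`, `dup`, and multi-chromosome `t(...)(...)`. Everything
else (`der`, `ins`, `inv`, mosaicism brackets, `?`) is rejected with an
error naming the token — an honest-scope decision; extending the tokenizer
is local to `iscn.py`. Aberrations are a multiset: `+20,+20` is two entries,
and recurrence queries can require a minimum within-karyotype multiplicity
(`min_multiplicity=2` asks "which replicates carry the *doubled* gain?").

Band comparison has three resolutions. `major_band` compares the arm plus
the first band digit only, so sub-band variants of one event (q21 vs q22)
group together without equating distant bands. Whether such variants in a
printed karyotype table are typographical or real is not decidable from the
data; the resolution parameter exposes the choice instead of hard-coding it.
Sex designations are stored verbatim and not checked against the modal
count, because real tumor karyotypes (e.g. `48,XY`) are not internally
consistent with strict ISCN sex-count rules.

## FISH classification and sample calling

Classification of a nucleus (red, green, fusion counts) follows fixed
precedence: fusion ≥ 1 → `fusion_positive`; red = green = 2 → `normal`;
either color ≥ 3 → `gain_or_break`; otherwise `uninformative`. Two
conventions here are ours:

* **Fusion outranks the gain rule.** A (3,3,1) nucleus is fusion-positive:
  the co-localized signal is the defined positive event, while three
  same-color signals are explicitly ambiguous (gain vs fusion-less break).
* **`uninformative`** covers nuclei with fewer than two signals of a color
  and no fusion — the expected artifact of 4–5 µm sections truncating
  nuclei. These cells are excluded from the informative denominator.

A sample needs ≥ `min_cells` (default 25) informative nuclei for a definite
call, else `insufficient_cells`. Positivity requires ≥ `min_fusion_cells`
fusion-bearing nuclei; the default of 2 operationalizes "multiple cells…
some with a fusion signal" and is a convention, not a measured threshold —
it is a CLI flag precisely because tissue-level positivity criteria were
never published as a number.

## Expression normalization and the window screen

Per sample, FPKM values are divided by the sample's median over **all**
genes (zeros included; a flag switches to the median of expressed genes),
then transformed elementwise:

    expression = log10(1 + 99 · median-adjusted FPKM)

with fixed points f(0) = 0 (silent gene) and f(1) = 2 (median gene). Fold
changes between samples a and b are signed (+r / −r, |r| ≥ 1). The default
`shifted` mode takes the ratio on the same shifted scale,
(1 + 99a)/(1 + 99b) = 10^(Δexpression), which is finite at silent
denominators and saturates at 100-fold per silent endpoint — consistent with
the transform and able to produce the very large finite magnitudes
(hundreds-fold) that arise when a near-silent gene activates. `raw` mode,
(a + ε)/(b + ε) with ε = 0.01, is available by flag; both are tested.

The screen takes all genes overlapping (≥ 1 bp) each breakpoint window,
computes the contrast fold change, and flags candidates with |fc| > 2 and
empirical p < 0.025. **The p-value is a reconstruction**: the study design
has one library per time point, so no replicate-based test exists. The
default p is the add-one-smoothed fraction of non-window (background) genes
whose |log10 fc| meets or exceeds the gene's; a sign-flip permutation
variant symmetrizes a direction-biased background. Interpret p as "how
extreme is this gene against the genome-wide background", not as a
calibrated false-positive rate.

Window geometry: explicit Hg19 intervals chosen to minimally cover the
catalogued breakpoint-region genes — chr2:27.70–33.80 Mb (2p22),
chr10:81.60–90.70 Mb (10q22), chr16:66.90–68.40 Mb (16q22) — configurable
by YAML since the probes' exact BAC coordinates are not part of the shipped
data. Coordinates are 1-based inclusive in memory and in TSVs (the gene
tables' convention); BED I/O converts to 0-based half-open at the boundary.
One catalog entry (PLA2G15) carries reference-genome rather than catalog
coordinates, marked by its `coords_source` column.

## Synthetic data: what it emulates, what it does not

* **Expression**: expressed genes are i.i.d. log-normal per gene × sample
  around a median of 5 FPKM with ln-scale sd 0.2 (≈ 20% CV — technical
  noise for a clonal line without biological replicates); 20% of background
  genes are exactly zero in all samples, exercising the f(0) = 0 fixed
  point; effects multiply the numerator sample's FPKM, so the planted
  contrast is exact at zero noise. No gene–gene correlation, no
  length/GC bias, no dispersion–mean trend: passing recovery tests shows the
  screen's arithmetic and thresholds behave, not that real RNA-seq noise is
  modeled.
* **FISH**: nucleus states (normal / gain / break-no-fusion / fusion) emit
  canonical count patterns; a fusion consumes one red and one green signal
  into the co-localized one by default ((1,1,1)-style patterns; keeping the
  parental pair, (2,2,1), is a flag). Noise is per-signal dropout plus
  per-pair spurious co-localization — a stand-in for sectioning artifacts,
  not an optical model. The demo cohort uses dropout 0.05 and spurious
  overlap 0.002 per pair; the latter keeps the expected artifact count in a
  50-cell all-normal sample (~0.2 nuclei) below the 2-nucleus positivity
  threshold, matching an assay whose non-tumor samples score uniformly
  negative.
* **Karyotypes**: an acquired clone is all-or-none per replicate with given
  penetrance; `exact=True` fixes the carrier count (e.g. 4 of 6) and
  randomizes only the assignment. Modal counts adjust by ±1 per added
  gain/loss.

Determinism: every generator takes one integer seed for a
`numpy.random.Generator`; fixed seed gives bit-identical output, and the
demo derives child seeds per stage so stages stay independent.

## Numerical and degenerate-input choices

* Median adjustment errors on a non-positive per-sample median (more than
  half the genes silent) unless the expressed-genes fallback is requested.
* Window membership ties are broken by gene id after the start-coordinate
  sort, making outputs fully deterministic.
* Empirical p uses add-one smoothing, so p is never 0 and never below
  1/(n_background + 1); with ~240 expressed background genes the smallest
  attainable p is ≈ 0.003–0.004.
* Fold-change sign convention maps r = 1 to +1 (no change has positive
  sign); antisymmetry holds for every other value.
* The demo report is written to a staging directory and moved into place on
  success; a failing stage removes all partial output and raises an error
  tagged with the stage name.

## Problem sizes

Tests and the acceptance script run on deliberately small instances —
300–500-gene matrices, 100-replicate recovery simulations, 10,000-cell FISH
draws, 6-replicate karyotype sets — sized so the full suite completes in a
few seconds while keeping Monte-Carlo standard errors well inside the
asserted tolerances.

## Known limitations

* The candidate screen's p-value is a background-rank reconstruction (see
  above), not a replicated statistical test.
* `shifted`-mode fold changes compress magnitudes for genes far below the
  per-sample median and saturate at 100 per silent endpoint; raw-ratio
  magnitudes for such genes depend on the pseudocount.
* The ISCN parser intentionally rejects constructs outside the observed
  dialect; it is not a general ISCN 2020 implementation.
* Tissue-level FISH positivity (fraction of nuclei required) is a
  convention; calibrating it needs per-cell data from graded cohorts.
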