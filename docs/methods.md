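# Methods

## Overview

`magrec` couples a forward simulator of restriction-enzyme-induced
double-strand-break (DSB) repair in a hybrid yeast diploid with the full
calling stack used to classify the outcomes from short-read observables.
The simulator is first-class code: its defaults define the study
conditions under which every calling rule is validated, and its exact
ground truth is the oracle for the recovery tests.

## The simulated genome

Two parental haplotypes, S (SK1-like) and K (S288C-like), share
coordinates and differ only at planted SNPs (per-base Bernoulli at
density 0.007, matching the ~0.7% divergence of the hybrid the analysis
is designed for). The default genome is a scaled model: 8 chromosomes
totalling 2 Mb (250 kb ± 40 kb each), one centromere per chromosome at
40% of its length, 12 copies of a dispersed 4-kb repeat family ("Ty",
identical copies — the NAHR substrate) and a 40-kb tandem rDNA-like
array (20 × 2 kb units) on the last chromosome. Scaling the genome
six-fold below the real 12-Mb genome keeps the default test-suite and
analysis runs to seconds per simulation while leaving hundreds of depth
bins and thousands of markers per chromosome, so no calling rule changes
regime; densities (SNPs, GATC sites ≈ 1/256 bp) are at their real values.

Identifiability constraints built into the generator, chosen so the
noise-free recovery criterion can be exactly 1.0 and stated here because
they also bound what passing tests show about real data:

* cuts occur only at motif occurrences intact on **both** haplotypes
  (an enzyme site destroyed by a SNP on one homolog would cut one
  haplotype only; such sites are rare, ~3% of sites, and excluded);
* repeat and rDNA unit sequences are generated motif-free, so enzyme
  breakpoints always fall in unique sequence — real MboI also cuts
  inside Ty and rDNA, producing events this model does not emulate;
* allelic events (CO/NCO/SGC/BIR) keep ≥ 8 kb spacing on a molecule and
  never land inside previously converted tracts; real closely spaced
  events would merge or shadow each other at marker resolution;
* copy-number events are applied first and their chromosomes are
  excluded from later events; at most two nondisjunctions per meiosis
  (viable spores carry few aneuploidies, and chromosome dosage from
  relative depth requires a euploid majority);
* same-chromosome repeat copies share a chromosome arm, so a tandem
  duplication between them can never capture the centromere;
* dicentric or acentric products of translocations are rejected and
  resampled (cap 100 attempts, then an error), mirroring the lethality
  of centromere malfunction — every simulated survivor is monocentric.

## Cut chemistry

MboI leaves 5′-GATC overhangs; only the religated junction is observable
in sequencing data. The simulator collapses the overhang detail to a
blunt-equivalent cut at the motif midpoint (GA|TC): a junction formed by
ligating any two cut ends then restores exactly one intact GATC spanning
the join with no inserted or deleted bases, which is the observable the
NMTL classifier tests (motif present across the join, zero indel).

## Repair outcome spectrum

Each cut (per shared motif site and molecule copy, probability 8×10⁻⁴,
≈ 12 cuts per mitotic diploid) draws an outcome:

* mitotic: religation 0.50, NHEJ translocation 0.10, SGC 0.15, BIR 0.08,
  NAHR 0.07, tandem duplication 0.05, chromosome loss 0.03 / gain 0.02 —
  about six scar-leaving events per isolate, the same order as the
  published per-isolate event counts on the full-size genome;
* meiotic: religation 0.35, CO 0.36, NCO 0.22, nondisjunction 0.07 —
  CO + NCO dominate as they do in the spore data (406 of 408 typed
  events), with NAHR/NMTL weights zero by default; the junction
  classifiers are exercised in mitotic mode, where the code path is
  identical. NCO tract lengths are geometric with mean 2 kb (so ~95%
  fall under the 5-kb CO/NCO threshold, matching the reported NCO size
  distribution); the true distribution for enzyme-induced conversions is
  unknown and this default is an explicit stand-in.

Meiosis replicates each homolog into two chromatids, applies CO/NCO
between chromatids, segregates four spores (random chromatid-to-spore
permutation per chromosome — marker-equivalent to explicit MI/MII pole
bookkeeping), and models nondisjunction as both homologs to one pole:
two disomic spores (heterozygous markers, 2× depth) and two nullisomic.

## Observables

With `exact_depth` and zero marker noise every value is an exact
expectation (the oracle regime). Otherwise: depth is Poisson per 1-kb
bin around per-copy depth × local copy number (default 30× for the
diploid and per spore); marker counts are Poisson per parental allele
with a per-read miscall probability of 0.002; every junction emits
Poisson(10) split reads at base-precise coordinates plus Poisson(5)
discordant pairs offset by an insert-size-scale amount. Ten split reads
per junction models ~30× short-read coverage, where most fragments
crossing a breakpoint yield a clipped alignment. Allelic switches (CO,
conversion borders) emit **no** junction evidence — reads map across
homologous sequence seamlessly — so those events are recoverable only
from markers, as in real data. Multimapping in repeats is not modelled:
evidence coordinates are truth-derived even inside repeat copies, where
a real aligner would struggle (the published analysis resolved these by
PCR, which is out of scope).

## Calling rules and numerical choices

* Marker states: allele fraction bands — pure at ≥ 0.9 (or ≤ 0.1), HET
  in [0.25, 0.75], everything between unclassifiable (MISSING), depth
  < 5 reads MISSING. The pure-state threshold tolerates residual
  mismapping noise.
* Segmentation: MISSING never breaks a run; runs with < 2 markers are
  absorbed when both flanks agree, otherwise kept but excluded from
  event calling (a single discordant marker is as likely a miscall as
  an event). Terminal flags are recomputed on retained segments.
* Spore CO/NCO: the 5-kb threshold is applied to the *marker span* of a
  tract (true tract ends are unknowable between markers); a tract at or
  above it is two CO switches. An NCO whose true marker span crosses the
  threshold is indistinguishable in principle from a double crossover,
  and the truth translation used by the recovery tests applies the same
  rule.
* Diploid LOH: BIR iff the tract contains the chromosome's first or last
  confidently-called marker, else SGC, with no size threshold.
* Junctions: cluster window 10 bp, ≥ 3 split reads, flanks of 1 kb for
  the depth-ratio test at 1.3-fold; depth failure flags but never
  removes a call (reciprocal translocations are copy-neutral). The two
  junctions of one reciprocal exchange (same coordinate pair,
  complementary strand patterns) are merged into one event, so a
  translocation counts once.
* Copy number: baseline = median of per-chromosome median bin depths,
  zero-depth chromosomes excluded (robust to whole-chromosome loss and
  nullisomy; requires a euploid majority — a genome with most
  chromosomes aneuploid is not resolvable from relative depth). Repeat,
  rDNA and junction-confirmed duplication bins are masked from dosage
  medians.
* CNV: junction-first — a same-chromosome junction in duplication
  orientation defines a candidate tract, accepted when its total raw
  depth crosses the Poisson likelihood-ratio boundary between
  CN = ploidy and CN = ploidy + 1 (sum* = (λ₁−λ₀)/ln(λ₁/λ₀)); depth-only
  fallback runs need ≥ 8 median-smoothed bins at ≥ 1.25× (the CN2/CN3
  midpoint) plus the same likelihood test. The midpoint threshold and
  the likelihood boundary follow from the Poisson depth model rather
  than from the conventional 1.4× visual cutoff, which drops ~30% of
  true CN3 bins at 30×.
* Haploidization: uniform dosage + every chromosome single-parent +
  origins mixed between parents. Single-parent everywhere with normal
  dosage is genome-wide LOH, flagged for review instead. Suppresses
  per-chromosome loss calls and LOH-tract calls when set.
* Mann–Whitney U: exact two-sided p by enumeration over all
  C(n+m, n) label assignments (valid under ties; the U distribution is
  symmetric about nm/2) for n+m ≤ 12, scipy's tie-corrected normal
  approximation above.
* CO position for distance statistics = breakpoint-interval midpoint,
  one distance per CO to the nearest feature centre; COs with intervals
  wider than 1 kb are excluded. Midpoint-and-nearest-centre is a
  symmetry choice; using both interval ends would roughly double the
  sample without changing medians materially.
* Region fractions: centromere windows are centre ± 5 kb (the
  arithmetic that makes 16 centromeres 160 kb); the genome length for
  expected fractions defaults to 12,071,326 bp, the assembly total under
  which 160 kb is 1.3% and 1365 kb is 11.3%. A CO whose breakpoint
  interval spans the rDNA array counts once as an rDNA event (markers
  inside the array do not exist, so consecutive COs through it are
  undetectable by construction).
* cM = 100 × mean CO switches per gamete (Morgans as expected
  crossovers per meiosis product).

## Problem sizes used by the tests and drivers

The recovery suites run 10 mitotic + 10 meiotic simulations per regime
(noise-free and 30×-noise) on the 2-Mb genome — about 350 scored events
per regime; the analysis drivers use 19 mitotic isolates and 8 meioses
(32 spores). These sizes give per-kind event counts in the tens while
keeping a full run to tens of seconds.

## Known limitations

* The simulator's idealised mapping layer (no multimapping, no alignment
  noise at repeats, truth-derived junction coordinates) means perfect
  recovery demonstrates the correctness of the classification logic, not
  the robustness of any aligner.
* rDNA-array NAHR (unit expansion/contraction) is representable but not
  in the defaults: the array carries no markers and its depth would be
  masked, so the pipeline cannot recover it — as in real short-read
  data, where array-internal events are invisible.
* Because the array and repeats are motif-free, the simulator places no
  breaks in them; observed CO fractions inside the simulated rDNA are
  therefore zero rather than merely suppressed.
* Chromosome dosage from relative depth is unidentifiable when most
  chromosomes of a sample are aneuploid; the generator's nondisjunction
  cap keeps simulations inside the identifiable regime.
* Inversions, inserted/deleted bases at NHEJ junctions, base-quality
  models and read-sequence (FASTQ) simulation are out of scope.
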