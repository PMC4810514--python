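# Methods

`sclexo` implements the computational side of selective chemical labeling
followed by exonuclease digestion (SCL-exo), a strategy that maps
5-hydroxymethylcytosine (5hmC) at single-CpG resolution. Genomic DNA is
sonicated, 5hmC residues are glucosylated and biotinylated, fragments are
captured on streptavidin beads, and a processive 5'→3' exonuclease trims
each captured strand until it stalls just upstream of the first bead-bound
modified cytosine. Single-end sequencing of the trimmed strands therefore
piles read 5' ends directly at hydroxymethylated cytosines; a read whose
first 10 bases contain exactly one CpG identifies that CpG as
hydroxymethylated (an *id CpG*).

## The replicate-design identification model

Per strand and per replicate, a hydroxymethylated cytosine is missed when
the exonuclease either fails to digest the fragment 5' end (probability
`p_u`) or reads through an unprotected site (`p_n`, lack of
glucosylation/biotinylation or bead binding). Treating the two strands of
a CpG and successive replicates as independent,

    p_miss_strand = p_u + p_n
    p_miss_cpg    = (p_u + p_n)^2
    p_identify(n) = 1 − p_miss_cpg^n .

At the failure fractions measured on the fully hydroxymethylated standard
(`p_u = 0.1238`, `p_n = 0.5104`) this gives a per-strand miss of 0.6342, a
per-CpG miss of 0.4022, and identification probabilities of 83.82 % with
two replicates and 93.49 % with three — the quantitative argument for
running multiple replicates. `replicates_needed` inverts the model.

The independence assumptions are used exactly as stated; no strand- or
replicate-correlation term is modelled. `ExonucleaseDesignModel.fit()`
estimates `(p_u, p_n)` from standard-template reads as binomial fractions
and reports binomial standard errors and normal-approximation confidence
intervals.

**Estimator rule.** On the standard, each strand's first modified C sits
`first` bases from the template 5' end. A read is counted *undigested*
when its 5' end lies strictly more than `upstream_gap` bases upstream of
`first` (default gap 10 = the stall-window width), and *read-through* when
it starts strictly downstream of `first`. With stall offsets supported on
[0, 10], the three categories partition the reads exactly, which makes the
estimator an unbiased binomial proportion; a boundary at distance exactly
10 would misattribute maximal stalls to the undigested class. The gap is
configurable for users who prefer the looser convention.

## The synthetic-read generator

The generator is the package's study-condition definition: its defaults are
the measured assay parameters, and every test property is stated against
it.

* **Standard template** (`make_standard_template`): a random 224-base
  sequence with 24-base primer regions free of modification; every
  interior C (forward strand) and G (reverse-strand C) is
  hydroxymethylated. The fixture variant pins the first forward modified C
  at 0-based 28 (1-based 29). The template mirrors a PCR product of
  mm8 chr3:93,697,590–93,697,813 (224 bp, 1-based inclusive) amplified
  with 5hmdCTP.
* **Failure categories** per sequenced molecule: undigested `p_u = 0.1238`,
  read-through `p_n = 0.5104`, remainder stall. Stall offsets follow a
  truncated geometric distribution on [0, 10] calibrated to mean 3 —
  matching the observed "on average 3 bp, mostly within 10 bp" stalling
  behaviour; a geometric law mimics progressive drop-off kinetics and is
  configurable.
* **Genomic capture** (`simulate_genomic_reads`): fragments of 200–500 bp
  (the sonication range) are drawn uniformly; each CpG on each strand is
  biotinylated by a Bernoulli draw at its hydroxymethylation level, and a
  molecule is specifically captured when it carries at least one
  biotinylated C. Read starts follow the standard-template rules relative
  to the first biotinylated C of the sequenced strand. A read-through
  molecule with no later protected site yields **no read**: the processive
  exonuclease destroys an unblocked strand.
* **Nonspecific background** (`p_background`, default 0.5): a fraction of
  sequenced molecules derive from fragments captured without any
  biotinylated C. Their reads start at the fragment end (undigested) or at
  a uniform exonuclease drop-off point. Two observations from real
  libraries require this component: roughly half of mapped reads carry no
  CpG in their 5' window, and the no-digestion control (SCL-seq)
  correlates with nothing — impossible under purely 5hmC-specific capture.
  The default was calibrated once against the read-class census
  (42 % + 4.7 % single/multi-CpG vs 47 % CpH) on a mouse-like CpG-density
  chromosome and then frozen.
* **SCL-seq control mode** (`protocol="scl-seq"`): identical capture, no
  digestion; reads start at fragment 5' ends.

What the generator does **not** emulate: sequencing errors, PCR
duplicates, adapter chemistry, size-selection artifacts, mappability, and
cell-to-cell heterogeneity of the hydroxymethylome. Passing tests
therefore demonstrate the correctness of the read-processing logic and the
internal consistency of the assay model, not robustness to those real-data
nuisances.

Synthetic chromosomes (`make_cpg_reference`) carry CpGs only at planted
positions (accidental background CGs are broken), so the CpG universe is
known exactly. Gap ranges are chosen per experiment: ≥ 12 bases keeps a
10-base read window single-CpG; 4–6 kb spacing reproduces the genome-scale
regime where captured loci are rare (see below).

## Caller, consensus, and analytics

* The 10-base window test runs on the read-oriented sequence (the 5' end
  is the exonuclease-trimmed end). Canonical positions are always the
  forward-strand C of the palindromic CpG, so both strands accumulate into
  one track position. A window-terminal C whose G falls just outside the
  window counts (the C is the modifiable base); a C at the read's last
  base counts as CpG only when a reference confirms the following G,
  otherwise it is treated as a CpH candidate. Reads shorter than the
  window use their full length. Multi-CpG windows go to a separate
  "probable CpG" track (keyed by the 5'-most CpG) that consensus calling
  ignores; no deduplication is performed.
* Consensus keeps positions covered **more than** `min_coverage` (strict,
  default 8, per the assay's published rule; a flag switches to `>=`) in at
  least 2 of 3 replicates, and sums coverage across replicates. Blacklist
  subtraction is applied per replicate before consensus. An optional
  coverage-quantile cap handles extreme-signal regions absent from curated
  blacklists (off by default; no principled universal threshold exists).
* Track correlation pairs positions over the union of occupied positions
  with zeros for absences (intersection and dense modes behind flags).
  **Caveat:** for near-disjoint sparse tracks the union convention is
  biased negative — conditioning on occupancy anti-correlates singleton
  supports (two disjoint binary tracks give r = −1 regardless of
  independence). Genome-wide negative controls are therefore evaluated in
  dense mode over an explicit chromosome-length domain, under which
  independent tracks give r = 0 in expectation.
* Score binning uses half-open bins with the top bin closed (a score of
  exactly 0.75 falls in the "high" bin of the 0 / 0.075 / 0.75 / 1
  conservation edges); CpG density counts reference CpGs whose C lies in a
  centred 300-bp window, anchor included, clipped at chromosome ends;
  conservation scores are attributed to the forward-strand C position.
* Motif metaprofiles report, per signed offset around anchors, the mean
  indicator that an IUPAC motif instance starts there on either strand
  (reverse-strand instances at their 5' end). RCGY/YCGR are ordinary IUPAC
  strings here.

## The negative-control regime

CpH read positions (cytosines not followed by G in the 5' window) are the
assay's negative control: they should not reproduce across technical
replicates. This is a *genome-scale* property. Its driver is the total
read mass per base: each CpH call lands on the first C of the window, so
every C "collects" up to a window's worth of nearby read starts. That
catchment structure is fixed by the sequence and shared between
replicates, so the apparent CpH correlation grows with the per-base 5'-end
rate even for independently placed reads. At the real experiment's scale
(~48 M reads over 2.6 Gb ≈ 0.02 reads/base; captured loci ~1 per 15 kb)
the rate is low and CpH correlation is near zero; compressing the same
per-locus coverage onto a CpG-dense desk-scale chromosome raises the rate
~50-fold and manufactures CpH correlation with no biological meaning. The
reproducibility tests therefore use a chromosome with hydroxymethylated
loci spaced 4–6 kb apart, 16,000 reads per replicate (≈ 0.03 reads/base,
≈ 50× mean id coverage), where the simulated id-track replicate
correlation is ≈ 0.87 and the CpH correlation ≈ 0.07 — the same picture
as the real data (0.72 and 0.04).

## Numerical and interface choices

* Internal coordinates are 0-based half-open everywhere; wiggle text is
  the single 1-based boundary and round-trips exactly. BED position n
  (1-based wiggle) corresponds to interval [n−1, n).
* Aligned reads travel as a documented TSV (`chrom start end strand
  read_seq replicate_id`); conversion from SAM/BAM is deliberately outside
  the core (any aligner post-processing can emit the TSV), keeping the
  pipeline testable without alignment tooling.
* The truncated-geometric stall law is parameterised by its exact
  truncated mean (solved numerically), not the untruncated one, so the
  configured mean is the realised mean.
* All simulations are deterministic given `rng_seed`; identical seeds give
  byte-identical read sets.
* Problem sizes in the test-suite simulations (100,000 standard reads;
  6,000–16,000 genomic reads on 120–200-CpG chromosomes) were chosen so
  that binomial/Poisson standard errors are several-fold smaller than the
  tolerances being asserted.

## Known limitations

* Strand and replicate independence is assumed in the design model; real
  replicates share library-preparation biases, so printed identification
  probabilities are upper bounds.
* The background-capture fraction is a single global parameter; real
  nonspecific binding varies with chromatin and GC content.
* The caller inherits upstream mapping quality; multi-mapping and
  bisulfite-like artifacts are out of scope.
* Hydroxymethylation levels enter capture only through per-fragment
  Bernoulli draws; allele- or cell-population structure is not modelled.
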