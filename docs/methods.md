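# Methods

This note documents the models, statistics and numerical choices behind
`isosip`, what the synthetic data do and do not emulate, and the design
decisions made where the underlying procedures left the details open.

## Translated homology search

Reads are translated in all six frames with bacterial translation
table 11; codons containing `N` become `X`, stop codons appear as `*`,
and frame segments between stops are searched independently (an
approximation of BLAST's behaviour: a candidate peptide never reads
through a stop). Candidate segments are pre-filtered by exact 5-residue
words shared with the query set — a seed-and-extend shortcut that cannot
lose a true hit of consequence, because any alignment strong enough to
pass the e-value cutoffs (raw score well above 100) necessarily contains
many identical 5-mers — and then aligned with an affine-gap
Smith–Waterman (Gotoh) kernel.

Scoring uses BLOSUM62 with gap open 11 / extend 1 (a gap of length *k*
costs 11 + *k*), the standard gapped protein defaults, and expectation
values follow the Karlin–Altschul form

    E = K · m · n · exp(−λ·S),   λ = 0.267 nats, K = 0.041,

with *m* the total query residues and *n* the total number of translated
residues actually searched (recomputed per run, ≈ 2 × total read bases).
Operating points: E ≤ 1e−4 for the target marker (isoA), E ≤ 1e−6 for
the normalization marker (recA). Hits are reported once per
(query, read): best frame wins, ties to the lowest frame index.

**Verification.** Each hit's translated segment is re-aligned against a
trusted IsoA set and discarded below 50 % identity. Raw local-alignment
identity is meaningless for unrelated sequences — the best local
alignment of two unrelated peptides is a short near-exact word with
~100 % identity over a handful of columns — so the verification
alignment must additionally cover at least half of the hit segment;
shorter alignments count as "unrelated" and the hit is discarded. This
coverage floor is what makes the cross-marker screen work: a recA read
surfaced by the recA search shows no IsoA alignment of meaningful
extent and is rejected. Surviving hits are deduplicated to one per read
("unique hits"): best e-value, ties to the lexicographically smallest
query id.

## Carrier statistic and normalization

Unique verified counts are scaled by two multiplicative factors: depth
(`N_min/N_i`, read count of the smallest metagenome under comparison
over this one's) and gene length (`L_min/L_gene`). The factors commute,
so ordering is immaterial. The length anchor `L_min` is taken globally
across both marker sets (default `length_norm="global"`): only a common
anchor turns each marker total into something proportional to
count/length — a genome-count proxy — so that the ratio

    pct_carriers = 100 · scaled_isoA / scaled_recA

estimates the fraction of genomes carrying the target. A per-set anchor
(`length_norm="per_set"`) is retained as an option, but with
equal-length references inside a set it degenerates to no scaling at all
and biases the ratio by `L_isoA/L_recA` (~1.4× here). recA is treated as
strictly single copy; the generator enforces one copy per genome so the
statistic is interpretable as "% of genomes". Reference protein residue
counts stand in for gene lengths (the nucleotide/protein factor of 3
cancels in the ratio). A zero recA total with nonzero isoA hits raises a
degenerate-normalization error rather than returning a silent zero.

## SIP gradient model and enrichment calling

Each taxon's DNA bands as a Gaussian in buoyant density centred at

    ρ = 1.660 + 0.098·GC + 0.036·(¹³C atom fraction)   [g ml⁻¹]

the classical CsCl relation with a full-label shift of 0.036 g ml⁻¹;
band width (`density_noise_sd`) defaults to 0.004 g ml⁻¹, a realistic
CsCl band width. Twelve fractions span 1.690–1.760 g ml⁻¹ by default,
collected densest-first (fraction 1 = heaviest); the outermost fractions
absorb the Gaussian tails so DNA mass is conserved exactly. The model is
deterministic given its parameters; the seed only drives an optional
per-taxon centre jitter (default 0).

**Window identification.** Profiles are smoothed with a 3-point moving
average (ties between equal peaks go to the denser side). The light
window is centred on the ¹²C control's DNA peak; the heavy window on the
peak of the labelled profile's excess DNA (labelled minus total-scaled
control) at higher density, requiring the excess peak to clear 2 % of
the control maximum and to sit at least two fraction widths above the
light peak. Windows extend one fraction to each side; overlaps are
trimmed in favour of the heavy window. With no resolvable excess peak
the heavy window falls back to a fixed +0.03 to +0.04 g ml⁻¹ offset from
the light peak, with a warning — this is the expected path for ¹²C-only
controls.

**Decision rule.** With pseudocount ε = 1e−4 (≈ one read in a 10⁴-read
sample) flooring relative abundances,

    fc = (RA_heavy + ε) / (RA_light + ε)

a taxon is called `labeled` iff `fc_13C ≥ 5` and, when a ¹²C control
exists, `fc_13C / fc_12C ≥ 2`; `not_confirmed` if the first criterion
holds but the control one fails; `unlabeled` otherwise. The numeric
thresholds are an interpretation — the underlying procedure is applied
verbally in practice, treating fold-changes of 19–90× as decisive and a
2.2× enrichment mirrored exactly in the ¹²C control as not confirmed —
and the defaults were chosen once to reproduce both verdicts; they are
exposed in the config, and output tables carry a header note flagging
the interpretation. The unfractionated relative abundance is reported as
supporting evidence but never changes a call. Whether real analyses pool
fraction windows or compare single fractions is generally unstated;
pooled windows are implemented.

## Cluster screen, MAG gate, ANI

Homolog assignment aligns annotated proteins (protein vs protein)
against labelled references and assigns the best (lowest-E) reference at
the strictest tier passed: restrictive E < 1e−40, permissive E < 1e−10.
Assigned genes on a contig chain into one cluster while consecutive
genes are ≤ 5 000 bp apart (clusters are drawn contiguous in practice
but no distance rule is published; 5 kb is the package's choice);
clusters never bridge contigs, and contiguity is strand-agnostic.
Classification fills the gaps the source procedures leave open:

| core (isoABCDEF) | extended (isoGHIJ) | classification |
|---|---|---|
| 6 | 4 | complete |
| 6 | 0 | putative_novel |
| 6 | 1–3 | core_only |
| 1–5 | any | partial |
| 0 | any | none |

`putative_novel` encodes the published signature of candidate novel
pathways: a full IsoMO core with no extended genes anywhere on the
contig. The MAG gate uses strict inequalities as printed —
completeness > 75 **and** contamination < 10, so the boundary values
fail — with the stricter reassembly variant (< 5 contamination)
available as a parameter.

ANI follows the classical fragment recipe: the query genome is cut into
consecutive 1020-bp fragments (final partial fragment discarded), each
locally aligned to the subject, and fragments aligned at ≥ 30 % identity
over ≥ 70 % of their length contribute their identity to the mean.
Nucleotide scoring is match +1 / mismatch −2 / gap 3 + k — deliberately
not BLASTN's +2/−3, under which bypassing a single substitution by
truncating the alignment outscores reading through it, which would break
the fragment-identity semantics (one substitution in 1020 bp must yield
1019/1020 = 99.902 %). With no retained fragment the ANI is undefined
(NaN, machine-greppable warning), never silently zero.

## Synthetic data: what it emulates, and what it does not

Genomes are i.i.d. nucleotide background at a requested GC (emitted GC
within ±0.02) with marker genes reverse-translated using codons sampled
to match genome GC (table 11) and planted without overlap on either
strand. Marker "databases" are synthetic protein families around a
common ancestor (queries and verification set at 5 % divergence, the
planted gene at ~10 %), so search, verification and cross-marker
rejection behave like their real counterparts without shipping any real
sequence data. Reads are sampled proportionally to abundance × genome
length with i.i.d. substitution errors (default 0.5 %) and constant
Q30 qualities; provenance (source taxon, position, strand) is retained
for truth-based tests and never emitted in FASTQ.

Not modelled: indels and quality-dependent error profiles, PCR/chimera
artefacts, real phylogenetic covariance between marker and genome,
multi-copy normalization markers, and ultracentrifugation physics beyond
the linear density model. Passing tests therefore demonstrate that the
statistics and decision rules recover planted truth under the model's
assumptions — not that they are robust to every artefact of real
metagenomes.

## Study sizes and acceptance runs

The acceptance computations use communities with equal genome lengths
(10 kb) and uniform abundances — 100 taxa with 1 carrier (soil-like,
exactly 1.0 % of genomes) and 500 taxa with 1 carrier
(phyllosphere-like, 0.200 %) — so the seeded truth is exact and the
recovered percentages can be compared against it at binomial precision.
200 000 reads of 150 bp give ~300 (soil) and ~60 (phyllosphere) unique
verified isoA hits, i.e. ±3·SD windows of roughly ±17 % and ±38 %
relative. SIP calling is evaluated over ten paired ¹³C/¹²C experiments
(12 uniform taxa, 2 fully labelled, RA 8.3 % each) plus ¹²C-only
controls. The test suite exercises the same paths at smaller read counts
chosen to keep the whole suite in a few minutes.

## Known limitations

* E-values use fixed gapped Karlin–Altschul constants; no
  composition-based statistics, HSP chaining, or length-adjusted
  effective search spaces.
* The seed prefilter can in principle miss a true hit with no exact
  5-mer (e.g. > ~35 % amino-acid divergence from every query *and*
  E-value still passing) — outside the regime the marker screen targets.
* `pct_carriers` inherits a small (≈ 1–2 %) relative bias from read-edge
  effects: reads overlapping a gene by less than the detection threshold
  (~23 codons at the 1e−4 cutoff) are invisible, and the visible window
  differs slightly between markers of different lengths.
* Uniqueness of hits is per read; paired-end mates are independent reads.
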