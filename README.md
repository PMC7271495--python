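# isosip

Detection and quantification of isoprene-degrading bacteria in shotgun
metagenomes and DNA stable-isotope probing (DNA-SIP) experiments, built
around four analyses and a synthetic-community generator that makes all
of them testable end-to-end without any external data:

* **Translated marker-gene search** — a tBLASTn-style engine that
  translates nucleotide reads in six frames and locally aligns them
  (Smith–Waterman, BLOSUM62, affine gaps) against IsoA protein queries,
  the α-subunit of isoprene monooxygenase and the accepted functional
  marker for isoprene degraders. Hits are scored with Karlin–Altschul
  expectation values `E = K·m·n·e^(−λS)`, verified BLASTx-style against a
  trusted IsoA set (discard below 50 % amino-acid identity), and counted
  once per read.
* **recA-normalized carrier statistic** — unique verified isoA hits are
  made commensurable with hits of the single-copy gene *recA* by depth
  scaling (`N_min/N_i`) and gene-length scaling (`L_min/L_gene`), giving
  the fraction of genomes in a metagenome that carry *isoA*:
  `pct_carriers = 100 · scaled_isoA / scaled_recA`.
* **SIP enrichment calling** — heavy and light windows are located on
  DNA-vs-buoyant-density profiles of ¹³C and ¹²C gradients; per-taxon
  heavy/light fold-changes `fc = (RA_H + ε)/(RA_L + ε)` drive a
  labeled / not-confirmed / unlabeled call, with the ¹²C control guarding
  against enrichment artefacts (a taxon equally "enriched" in the control
  is never called labeled).
* **Gene-cluster screen and ANI** — annotated proteins are assigned to
  the isoprene degradation genes (*isoABCDEF* core, *isoGHIJ* extended,
  *aldH/gshB/garB/CoA-DSR* accessory) under permissive (E < 1e−10) and
  restrictive (E < 1e−40) tiers, chained into per-contig clusters, and
  classified; MAG quality is gated on strict completeness/contamination
  inequalities; fragment-based average nucleotide identity (1020-bp
  fragments, 30 % identity / 70 % coverage retention) compares genomes.

The synthetic module generates bacterial communities with a known
fraction of single-copy *isoA* carriers (every genome carries one *recA*),
shotgun reads with substitution errors and full provenance, and isopycnic
CsCl gradients in which each taxon bands at
`ρ = 1.660 + 0.098·GC + 0.036·(¹³C atom fraction)` g ml⁻¹.

## Worked example

The repository ships an annotated pipeline config. Running

```sh
isosip run --config examples/config.yaml --outdir out/
```

simulates two habitats (a soil-like community with 1 % isoA carriers and
a phyllosphere-like community with 0.2 %, 20 000 reads each), a paired
¹³C/¹²C gradient experiment with two fully labelled taxa, and a contig
screen with planted clusters. `out/carrier_stats.tsv` then contains:

```
metagenome_id  raw_target_hits  raw_norm_hits  scaled_target_hits  scaled_norm_hits  pct_carriers  true_pct_carriers
         soil               26           2272               18.46            2272.0      0.812500                1.0
         leaf                7           2235                4.97            2235.0      0.222371                0.2
```

26 raw isoA hits against 2272 recA hits in the soil sample yield an
estimated 0.81 % of genomes carrying *isoA* (seeded truth 1 %; at 20 000
reads the handful of isoA hits carries ±3·SD ≈ ±0.6 points of binomial
noise — the acceptance run below uses 200 000 reads and lands within
±0.06). `out/sip_enrichment.tsv` reports the gradient experiment:

```
     taxon      fc_13C   fc_12C  ra_unfractionated    call
taxon_0003 4789.661889 0.044856           0.083333 labeled
taxon_0008 5212.330067 0.001087           0.083333 labeled
```

exactly the two taxa that were simulated as ¹³C-labelled (all ten others
are `unlabeled`), and `out/screen_clusters.tsv` classifies the planted
contigs:

```
   contig_id                                               iso_genes  core_count  extended_count accessory  max_gap classification
 contig_full isoA;isoB;isoC;isoD;isoE;isoF;isoG;isoH;isoI;isoJ;aldH1           6               4     aldH1      198       complete
 contig_core                           isoA;isoB;isoC;isoD;isoE;isoF           6               0                155 putative_novel
contig_empty                                                                   0               0                  0           none
```

— a full cluster with *aldH1* is `complete`, a core-only cluster with no
*isoGHIJ* anywhere is `putative_novel` (the signature of a candidate
novel isoprene degradation pathway).

Each stage is also exposed directly: `isosip simulate|search|quantify|
sip|screen|ani` (see `--help` for the file formats).

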