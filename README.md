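# tmtkit

Downstream analysis of multi-plex TMT (tandem mass tag) proteomics and
phosphoproteomics experiments:

- **Synthetic data** (`tmtkit.simulate`): peptide-level two-plex-style TMT
  experiments with an internal reference channel per plex, planted group
  effects, plex batch effects, kinase-driven phosphosites and a planted
  drug-response association — with full ground truth for recovery testing.
- **Filtering / rollup / normalization** (`tmtkit.quantnorm`): human-unique
  peptide filtering, protein and phosphopeptide rollup, missingness filter,
  sample-loading (SL) → internal reference standard (IRS) → trimmed mean of
  M-values (TMM) cross-plex normalization, phosphosite condensation, PCA
  based outlier flagging, Ward clustering.
- **Differential abundance** (`tmtkit.differential`): per-feature one-way
  ANOVA + Tukey HSD, Benjamini–Hochberg adjustment, signed −log10(p)
  ranking metric.
- **Enrichment** (`tmtkit.enrichment`): single-sample GSEA (area statistic),
  ranked-list GSEA with permutation significance, hypergeometric
  over-representation, GMT I/O.
- **Kinase activity** (`tmtkit.kinase`): curated + predicted kinase-substrate
  network assembly with an MCC-optimized prediction-score cutoff, and bounded
  multi-start least-squares kinase activity inference (activities in [0, 24]).
- **Drug signatures** (`tmtkit.drugsig`): Spearman correlation of abundance
  with screen viability on matched pairs, median over duplicate screen
  entries, top-k sensitivity signature extraction, per-sample signature NES,
  and top-n/bottom-n extreme-group comparisons.

## CLI

Everything is reachable through the `tmtkit` entry point:

```sh
# synthetic experiment with planted truth
tmtkit simulate --config config.yaml --seed 1 --out-dir data/

# global proteome: filter -> rollup + SL/IRS/TMM -> cluster / diff
tmtkit filter --table data/global/quant_plex1.tsv --out filt1.tsv
tmtkit filter --table data/global/quant_plex2.tsv --out filt2.tsv
tmtkit normalize --table filt1.tsv --table filt2.tsv --out-prefix protein
tmtkit qc --matrix-prefix protein --out flags.tsv
tmtkit cluster --matrix-prefix protein --k 3 --out clusters.tsv
tmtkit diff --matrix-prefix protein --groups data/groups.tsv --out diff.tsv

# phosphoproteome: phospho filters -> peptide-level normalization -> sites
tmtkit filter --table data/phospho/quant_plex1.tsv --phospho --out pf1.tsv
tmtkit filter --table data/phospho/quant_plex2.tsv --phospho --out pf2.tsv
tmtkit normalize --level peptide --table pf1.tsv --table pf2.tsv --out-prefix pep
tmtkit condense --table pf1.tsv --table pf2.tsv --matrix-prefix pep --out-prefix sites

# kinase activity
tmtkit kinase cutoff --predictions pred.tsv --curated psp.tsv --sites sites.txt --out cutoff.json
tmtkit kinase network --predictions pred.tsv --curated psp.tsv --sites sites.txt --cutoff 5.88 --out network.tsv
tmtkit kinase score --matrix-prefix sites --network network.tsv --out activity.tsv

# drug sensitivity signature
tmtkit drugsig correlate --matrix-prefix protein --screen data/drug_screen.tsv --drug DRUG1 --out corr.tsv
tmtkit drugsig signature --correlations corr.tsv --k 100 --out sig.json
tmtkit drugsig score --matrix-prefix protein --signature sig.json --out nes.tsv
tmtkit drugsig compare --scores nes.tsv --response ic50.tsv --n-extreme 50

# enrichment
tmtkit enrich --gmt hallmark.gmt --mode ranked --input ranks.tsv --out gsea.tsv
```

Quant tables are TSV with meta columns (`peptide_id`, `peptide_sequence`,
`species`, `master_proteins`, `id_score`, `plex_id`, `phospho_positions`,
`localization_ambiguous`) followed by per-channel abundance columns; the
reference channel is named `ref_<plex>`. Abundance matrices are written as a
`*_values.tsv` / `*_samples.tsv` pair with `NA` for missing values, plus a
`*_provenance.json` sidecar recording scale factors and filter counts.

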