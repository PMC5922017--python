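# mirlag

Nomination of miRNA–mRNA regulatory pairs from co-sequenced bulk RNA time
series (2 treatment arms × 5 time points × replicate animals), combining:

- **upper-quartile normalization** and per-time-point **negative-binomial GLM
  differential expression** (likelihood-ratio tests, Benjamini–Hochberg FDR),
  with an optional **RIN covariate** that corrects RNA-degradation bias;
- **log2 fold-change time profiles** with fuzzy c-means clustering into
  temporal templates;
- **seed-match target prediction** (canonical 6mer/7mer-A1/7mer-m8/8mer
  sites) filtered against an experimentally **validated pair table**;
- a **delayed anti-correlation score**: both profiles are differenced, the
  time-matched Pearson coefficient `r_tm` removes positively correlated
  pairs, the lag-1 shifted coefficient `r_ts` (miRNA changes 1–3 vs mRNA
  changes 2–4) captures postponed responses, and a pair enters the network
  when `min(r_tm, r_ts) < −0.7`;
- **serum-vs-tissue correlation** of miRNA biomarkers and **RIN QC**
  diagnostics (two-way ANOVA, per-time-point t-tests, count–RIN correlation
  distributions before/after correction);
- a fully seeded **synthetic-data generator** that emulates the statistical
  structure of such a study (NB counts, temporal fold-change templates,
  lag-coupled regulator/target pairs, planted seed sites, RIN shifts and
  degradation bias) with ground truth, so the entire pipeline runs and is
  tested without any download.

## Test

```bash
python -m pytest tests/
```

One acceptance test (`TestCriterion1SerumTissueTable`) requires the study's
per-animal serum/tissue raw-values supplement, which is not redistributable
here; it fails with an explanatory message unless that table is placed at
`data/additional_file_4.tsv` (TSV columns: `animal_id`, `mirna_id`,
`serum_level`, `tissue_level`). All other tests pass offline.

## CLI

```bash
mirlag simulate --seed 1 --out sim/                 # synthetic dataset + truth
mirlag de --counts sim/mirna_counts.tsv --meta sim/samples.tsv \
          --out de.tsv --use-rin                    # NB GLM DE (+RIN covariate)
mirlag profiles --counts sim/mirna_counts.tsv --meta sim/samples.tsv \
          --out profiles.tsv -c 4 --plot clusters.png
mirlag targets --mirna-fasta sim/mirna.fa --utr-fasta sim/utr.fa \
          --out predicted.tsv --validated sim/validated_pairs.tsv
mirlag serum-tissue --table sim/serum_tissue.tsv --out corr.tsv
mirlag rin-qc --meta sim/samples.tsv --counts sim/mirna_counts.tsv --out rin.txt
mirlag run --seed 1 --out run/                      # full pipeline + funnel report
mirlag compare-rin --seed 1 --out cmp/              # paired run with/without RIN
```

`mirlag run` accepts a YAML config (`--config`) exposing every threshold:
`fdr_threshold` (0.05), `significance` (`fdr`/`p`), `score_threshold`
(−0.7), `remove_positive_time_matched`, `require_mrna_significant`,
`clusters_mirna` (4), `clusters_mrna` (6), `use_rin`, and a `sim:` block for
the generator. Per-stage funnel counts (DE entities → predicted → validated
→ scored → passing pairs) are written to `report.json`.

## Layout

| Module | Role |
| --- | --- |
| `mirlag.io_model` | domain types (samples, count matrices, pair tables) + TSV/FASTA I/O |
| `mirlag.de` | UQ normalization, dispersion estimation, NB GLM LRT, BH |
| `mirlag.profiles` | fold-change series, differencing, fuzzy c-means |
| `mirlag.targeting` | seed-site scanning, validated-pair filtering |
| `mirlag.anticorr` | delayed anti-correlation score, network assembly |
| `mirlag.serum_tissue` | per-miRNA serum–tissue Pearson correlation |
| `mirlag.rin_qc` | RIN ANOVA/t-tests, count–RIN correlation diagnostics |
| `mirlag.simulate` | seeded synthetic dataset generator with ground truth |
| `mirlag.pipeline`, `mirlag.cli` | orchestration, config, CLI |
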