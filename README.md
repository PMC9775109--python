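# mhcscreen

Discover candidate regulators of antigen-presentation (MHC-I) genes from bulk
tumor expression, paired tumor/normal proteomics and clinical survival data.
The package implements, as a tested reusable pipeline:

* **Co-expression screen** — Pearson correlation of every gene against an
  anchor panel (`HLA-A`, `HLA-B`, `HLA-C`, `B2M`, `TAP1`, `TAP2` by default)
  with strict `|r| > 0.3`, `p < 0.05` thresholds, per-anchor hit sets,
  multi-set intersection, and overlap with a pathway signature (GMT).
* **Immune deconvolution** — per-sample constrained least squares
  (`min ||S f − b||², f ≥ 0`) against a marker-gene signature matrix, closed
  with an "other" component so every row lies on the simplex.
* **Proteomic disparity filter** — per gene, the percentage of paired
  tumor/normal samples in which the normal tissue has the higher protein
  abundance; candidates must reach a configurable high-in-normal fraction
  (default ≥ 70%).
* **Survival / prognosis** — Kaplan–Meier estimation, Mantel–Cox log-rank
  test, top/bottom-tertile and combined two-marker stratification, and
  fixed-horizon ROC/AUC for prognostic scores, all implemented from the
  standard formulas and tested against independent oracles.
* **Synthetic data** — a generator that plants ground truth (regulators
  coupled to a latent anchor factor, Dirichlet cell fractions, hazard tied
  to anchor expression, per-gene normal-dominance probabilities) so every
  stage has a recovery test without any external download.

## CLI

```sh
mhcscreen simulate   --seed 1 --out sim/            # synthetic inputs + truth.json
mhcscreen deconvolve --bulk sim/expr.tsv --signature sim/signature_matrix.tsv \
                     --out fractions.tsv
mhcscreen screen     --expr sim/expr.tsv --signature sim/signature.gmt \
                     --r-min 0.3 --p-max 0.05 --out screen/
mhcscreen disparity  --normal sim/protein_normal.tsv --tumor sim/protein_tumor.tsv \
                     --screen screen/ --de-genes sim/de_genes.txt \
                     --min-frac 70 --out candidates.tsv
mhcscreen survival   --clinical sim/clinical.tsv --groups groups.tsv --out surv.tsv
mhcscreen roc        --score score.tsv --clinical sim/clinical.tsv --horizon 60 \
                     --out roc.tsv
mhcscreen run-all    --seed 1 --out run/            # all stages + manifest.json
```

All inputs and outputs are plain tab-separated text (GMT for gene sets); a
YAML config (`--config run.yaml`, same keys as `mhcscreen.pipeline.RunConfig`)
drives `run-all`, and reruns with the same config and seed are byte-identical.

## Notes

* Expression input is assumed to be log2 scale; pass `--log2` to apply
  log2(x+1) on load. Deconvolution un-logs internally (the mixing model is
  linear in abundance).
* Gene identifiers are matched case-sensitively with no alias resolution.
* Tertiles take the floor(n/3) lowest/highest scores; values tied across a
  boundary fall to the excluded middle group.
* Ties in paired protein values are excluded from the disparity denominator
  by default (`--tie-policy` to count them toward either side).
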