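# loopscape

Repertoire analysis for deep-sequenced combinatorial protein-loop libraries
(fibronectin-style three-loop scaffolds), before and after binder selection:

- **library_model** — sitewise library designs (fixed amino-acid sets,
  conserved sites, degenerate codons from per-position nucleotide mixtures)
  with exact 64-codon amino-acid/stop distributions; the two study designs
  ship as packaged JSON specs (`gen1`, `gen2`).
- **population_sim** — synthetic-data generator: naive DNA populations
  sampled from a design (stops arise naturally at the nucleotide level),
  substitution/indel error injection, and a planted multiplicative sitewise
  selection model with exact ground truth for recovery testing.
- **seq_processing** — clone classification (full-length / stop / frameshift
  / unidentified) against framework anchors, translation, loop extraction
  and alignment of variable-length loops to reference site labels.
- **repertoire_core** — rare-sequence background removal, greedy 80%-identity
  loop clustering (composition-bound prefilter + exact global-alignment
  verification), power-1/2 within-cluster weighting, and sitewise frequency
  matrices (TSV interchange format).
- **diversity_stats** — Shannon-entropy landscapes, entropy deltas,
  Bonferroni-corrected two-sample t-tests, loop-length distributions,
  cysteine count/pair analysis, framework-mutation enrichment and wild-type
  conservation.
- **loocv_model** — sitewise sequence probability model and exhaustive
  leave-one-out cross-validated log10(P_evolved/P_naive) scoring with
  sitewise decomposition.
- **design_fit** — constrained least-squares fit of exposure-scaled input
  matrices (sum(alpha)=1, sum(beta)=0, closed-form KKT), natural-homolog
  frequency matrices with sqrt replicate weighting, Boltzmann conversion of
  stability matrices, mutational tolerance counts, a convergence driver for
  pluggable stability evaluators, and bootstrap z-scores versus an unbiased
  uniform control.
- **structure_exposure** — Shrake–Rupley SASA, relative SASA with the 40%
  exposure split, alanine truncation, and the orientation-search projected
  accessibility algorithm (coarse/fine view scan, z-buffer rasterization)
  combined into per-site exposure scores.

## CLI

```sh
loopscape design --spec gen1 --site D23          # theoretical distributions
loopscape simulate --design gen1 --n 100000 --seed 7 --out reads.fasta
loopscape process --in reads.fasta --design gen1 --out clones.tsv
loopscape frequencies --in reads.fasta --design gen1 --loop BC --out fm.tsv
loopscape diversity --naive fm_naive.tsv --binders fm_binders.tsv
loopscape loocv --in binders.fasta --design gen1 --loop BC
loopscape fit --objective fm.tsv --inputs cdr=c.tsv,stab=s.tsv,hom=h.tsv \
              --exposure eps.tsv
```

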