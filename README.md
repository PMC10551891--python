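# paxkit

A toolkit for building and evaluating protein-abundance datasets from
mass-spectrometry quantification tables, and for comparative analysis of
amino-acid usage across orthologous protein domains.

Whole-proteome abundance resources face three recurring problems that this
package addresses for proteomics practitioners:

1. **Quantification.** Raw outputs come either protein-centric (protein
   groups with summed precursor intensities) or peptide-centric (per-peptide
   intensities or spectral counts). Both are converted to a common relative
   scale — *parts per million* of the quantified proteome — using
   theoretically observable tryptic peptides as the normalizing
   denominator:
   - protein-centric (iBAQ-style):
     `raw(p) = intensity(p) / #observable_peptides(p)`
   - peptide-centric (length-normalized):
     `raw(p) = Σᵢ qᵢ·len(pepᵢ) / observable_length(p)`

   then `ppm(p) = 10⁶ · raw(p) / Σ raw`. Contaminant (`CON_`) and reversed
   decoy (`REV_`) entries are excluded, and peptides are filtered at FDR
   ≤ 0.01.

2. **Quality and integration.** A dataset with no ground truth can still be
   scored: interacting proteins tend to be expressed at similar levels, so
   the median |log₁₀ ratio| over interacting pairs, compared with a
   label-shuffled null (500 permutations), yields an *interaction z-score* —
   larger is better. Multiple datasets for one organism or tissue are merged
   greedily: sort by z-score, seed with the best, then fold each dataset in
   at the weight (11-point grid over [0, 100%]) that maximizes the merged
   z-score.

3. **Composition evolution.** To ask whether sulfur-containing amino acids
   (Cys, Met) are selectively depleted from highly expressed proteins,
   same-named domains within strict one-to-one orthologs are globally
   aligned (Needleman–Wunsch, BLOSUM62, gap open 10 / extend 0.5), filtered
   at ≥ 40% identity, and the usage ratio
   `r = count_query / count_reference` is rank-correlated (Spearman)
   against protein abundance. Genuine expression-dependent depletion shows
   up as ρ < 0.

A synthetic-data module generates every input format with controlled
statistical structure (planted network consistency, planted depletion
strength), so the full pipeline is testable with known ground truth.

## Worked example

Simulate a 300-protein organism whose interaction network is strongly
abundance-consistent and whose orthologs carry a planted sulfur depletion,
quantify it from its peptide table, score it, and integrate it with a
second dataset:

```sh
$ echo '{"edge_consistency": 3.0, "depletion_beta": 0.5}' > sim.json
$ paxkit simulate --config sim.json --out sim --seed 42
wrote synthetic fixture set to sim/ (300 proteins, 448 edges, 5572 peptides)

$ paxkit quantify --peptides sim/peptides.tsv --fasta sim/proteome.fasta --out dataset.tsv
quantified 300 proteins (coverage 100.0%) -> dataset.tsv

$ paxkit score --dataset dataset.tsv --network sim/network.tsv --shuffles 500 --seed 42
{
  "dataset": "dataset.tsv",
  "interaction_zscore": 12.327826284782095,
  "observed_median": 0.27372259025396073,
  "n_pairs_used": 448,
  "n_shuffles": 500,
  "seed": 42
}

$ paxkit integrate --datasets dataset.tsv sim/abundance.tsv \
    --network sim/network.tsv --shuffles 500 --seed 42 --out integrated.tsv
integrated 2 datasets -> integrated.tsv (z=12.915)
```

The observed median |log₁₀ ratio| across interacting pairs (0.27) is far
below what label shuffling produces, hence the large positive z-score
(12.3): the dataset is internally consistent. Integrating it with the
noise-free generating abundances nudges the score up to 12.9.

The planted depletion (`depletion_beta = 0.5`: sulfur residues of the
query-side domain are thinned in proportion to abundance rank) is
recovered by the ortholog-domain analysis:

```sh
$ paxkit evo --pairs sim/orthologs.tsv \
    --domains-a sim/domains_query.tsv --domains-b sim/domains_reference.tsv \
    --fasta-a sim/ortholog_query.fasta --fasta-b sim/ortholog_reference.fasta \
    --abundance sim/abundance.tsv --out ratios.tsv
{
  "n_rows": 299,
  "aa_set": ["C", "M"],
  "spearman_rho": -0.7560046876205299,
  "p_value": 1.3298477922604426e-56,
  "bins_file": "ratios.bins.tsv"
}
```

The six abundance bins show the monotone decline of the median sulfur
usage ratio, from 1.0 in the lowest-abundance bin to 0.39 in the highest —
highly expressed query proteins use markedly less C/M than their
reference orthologs, exactly as planted.

Every subcommand writes a `*.manifest.json` recording input checksums,
parameters, seed, and tool version; two runs with the same manifest produce
byte-identical primary outputs.

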