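# dupshift

Frameshift mutations between duplicate genes: detection, polarization and
evolutionary characterization.

After a gene duplication, one copy can acquire an indel whose length is not a
multiple of three.  The new reading frame downstream of the lesion encodes an
entirely novel amino-acid sequence — occasionally the raw material of a new
function (the human *NOTCH2NL* and *ARHGAP11B* genes are famous examples),
far more often a step toward pseudogenization.  Surveying a genome for such
cases requires machinery that ordinary aligners do not provide: an alignment
model in which a protein can be threaded through a nucleotide sequence
*across* frame changes.

`dupshift` is a tested implementation of that survey for people who study
duplicate-gene evolution:

* **frameshift-aware alignment** — a dynamic program aligning a protein
  (globally) to a CDS (locally) with BLOSUM62 codon matches, affine gaps and
  frameshift steps that consume 1, 2, 4 or 5 nt per residue at a fixed
  penalty; merged net events carry position, size and phase
  (= size mod 3 ∈ {1, 2});
* **duplicate detection** — translated Smith–Waterman over all 3×3 frame
  pairs with identity ≥ 70%, overlap ≥ 70% and raw-score filters, plus a
  transcript-consistency filter against splicing artifacts;
* **polarization** — the copy whose full reading frame matches an outgroup is
  the original; without an outgroup the shorter copy is assumed derived;
* **region partitioning and typing** — common-frame vs frameshifted regions,
  and C / N / M labels for lesions at the C-terminus, N-terminus or middle
  of the protein (composites like "N&C" for multi-hit cases);
* **Ka/Ks per region and lineage** — Nei–Gojobori (1986) pathway counting
  with Jukes–Cantor correction, read in the original copy's frame, against
  an ancestor reconstructed by three-taxon parsimony; Fisher and binomial
  count tests for lineage rate differences;
* **survey statistics** — exact binomial C-vs-N enrichment test, paired
  sign-flip permutation test for region lengths, width-0.1 binned
  distributions;
* **a synthetic-data generator** — duplicate pairs plus outgroup with
  controlled divergence, dN/dS and frameshift scenarios, so every stage is
  validated by parameter recovery against ground truth.

In the standard notation: Ka and Ks are the numbers of nonsynonymous and
synonymous substitutions per site; `K_aC/K_sC` denotes the between-copies
ratio in the common-frame region, and `K_aDF/K_sDF` the ancestor→derived
ratio inside the frameshifted region, the quantity in which relaxed or
positive selection after a frameshift should surface first.

## Worked example

Simulate a small survey and run the full pipeline on it:

```bash
cat > cfg.yaml <<EOF
n_pairs: 12
ancestor_len_codons: 250
t_post: 0.08
EOF
dupshift run-all --config cfg.yaml --seed 4 --out demo
# -> 12 cases -> demo
```

`demo/cases.tsv` holds one row per detected frameshift case:

```
pair_id          original_id  derived_id  outgroup_id  polarization_basis  n_events  type  length_triple
P0000_x~P0000_y  P0000_x      P0000_y     P0000_og     outgroup-frame      1         N     31/250/249
P0001_x~P0001_y  P0001_y      P0001_x     P0001_og     outgroup-frame      2         C     21/221/249
...
```

`length_triple` is the frameshifted-region / derived-copy / original-copy
protein lengths in amino acids: the first case is an N-terminal frameshift
whose shifted region covers 31 of the derived copy's 250 residues.
`demo/summary.json` collects the survey statistics (this run's actual
values):

```
n_cases = 12          type_count_C = 9   type_count_N = 2   type_count_M = 1
binomial_p_c_vs_n = 0.180            # 9 vs 2 single-event C/N split
permutation_p_C = 0.0035             # frameshifted < original-frame length
pooled_kaks_frameshifted_derived = 0.78
pooled_kaks_common_derived       = 0.49
```

With only 12 pairs the C-vs-N enrichment is not significant (p = 0.18); at
survey scale the same test on the published 51-vs-18 split gives
p ≈ 0.0001.  The permutation test already resolves that frameshifted
regions are shorter than their original-frame counterparts (p = 0.0035).
`demo/kaks.tsv` holds the per-case region × lineage rates behind the pooled
ratios.

The same stages are available as library calls (`generate_dataset`,
`find_duplicate_pairs`, `protein_to_cds_align`, `polarize_pair`,
`region_lineage_kaks`, `summarize_survey`, ...) and as separate subcommands
(`dupshift simulate / detect / classify`).

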