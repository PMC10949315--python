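# asparascan

Comparative-genomics and biochemical analysis of bacterial L-asparaginases,
built around the short-chain family (scASNases) typified by the 172-residue
enzyme RrA from *Rhodospirillum rubrum*.

L-Asparaginases (ASNases) hydrolyse L-Asn to L-Asp and ammonia; bacterial
class 1 enzymes are normally 300–400 residues. A distinct group of
cytoplasmic enzymes about half that size (160–180 residues, homologous to
the N-terminal domain of class 1 ASNases) forms its own region of sequence
space and is enriched in species that already carry more than one long-chain
enzyme. `asparascan` packages the full analysis chain that supports such a
claim, for anyone who wants to run it on their own genome sets or on
synthetic data with planted ground truth:

- **Translated survey** — six-frame translation, exact Smith–Waterman local
  alignment (BLOSUM62, affine gaps −11/−1), Karlin–Altschul expectations
  E = K·m·n·e^(−λS), and stop-to-stop ORF extraction at an E ≤ 0.01 cutoff.
- **Family mapping** — short/long partition at 250 aa, pairwise similarity
  graph on the N-terminal 150 residues with weights −log10 E, force-directed
  2-D embedding, connected-component clustering, localization labels
  (cytoplasmic / SPI secreted / SPII lipid-anchored), protein masses.
- **Co-occurrence** — per-species long-chain repertoires by localization and
  the fraction of species carrying a short-chain gene, stratified by
  long-chain count {0, 1, >1}.
- **Conservation** — greedy 0.9-identity representative selection (CD-HIT
  style), center-star multiple alignment, per-column Shannon scores
  (log2 20 − H bits: ≈4.3 = invariant, 0 = uniform), Levenshtein
  median-string consensus, key-residue reports (e.g. the catalytic
  Thr16/Tyr21/Thr87/Asp88/Lys158 of RrA).
- **Kinetics** — Nessler A480→ammonia conversion (ε480 = 1302 M⁻¹cm⁻¹),
  Michaelis–Menten with optional substrate inhibition
  v = Vmax·S/(Km + S(1 + S/Ki)), Lineweaver–Burk and nonlinear fits,
  relative activities, pH-activity optima.
- **Structure** — Cα traces from PDB/mmCIF, residue pairing, Kabsch
  superposition rmsd, percent sequence identity.
- **Synthetic data** — seeded generators for genomes with planted
  asparaginase ORFs on both strands, diverged protein families, kinetic and
  pH datasets, and rigid-body-transformed coordinate sets, each with a
  machine-readable truth table.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Plant six asparaginase genes (two families of long-chain plus a short-chain
family) in three synthetic genomes, survey them back, classify, cluster and
tally:

```
$ asparascan simulate genomes --spec spec.json --sub-rate 0.1 --seed 7 --out-prefix demo
wrote 3 genomes, 6 planted genes
$ asparascan search --genomes demo.genomes.fasta --queries demo.queries.fasta --out demo.records.tsv
g1      2 ORFs
g2      2 ORFs
g3      2 ORFs
wrote 6 records to demo.records.tsv
$ asparascan classify --records demo.records.tsv --out demo.classified.tsv
length_class
long     4
short    2
$ asparascan cluster --records demo.classified.tsv --seed 1 --out demo.clustered.tsv
cluster_label
0    2
1    2
2    2
```

All six planted genes are recovered at their exact loci (compare
`demo.records.tsv` with `demo.truth.tsv`), the length partition separates
the two 160–180 aa proteins from the four 300–400 aa ones, and the
similarity graph splits the records into the three planted families.
Without a signal-peptide label table every record defaults to cytoplasmic;
pass `--labels` to `classify` to attach SPI/SPII calls.

Fitting noiseless Michaelis–Menten data generated with the wild-type RrA
constants at pH 7.4 (Km = 3.6 mM, kcat = 58.2 s⁻¹ at 282 nM enzyme) by the
double-reciprocal method returns the generating parameters:

```
$ asparascan simulate kinetics --km 3.6 --vmax 0.0164 --smax 5 --n 20 --seed 1 --out assay.tsv
$ asparascan kinetics fit --data assay.tsv --method lb --e0 0.000282
{
  "method": "LB",
  "success": true,
  "Km_mM": 3.600000000003039,
  "Vmax_mM_per_s": 0.01640000000001094,
  "kcat_per_s": 58.15602836883312,
  ...
}
```

Km comes back at 3.6 mM and kcat at 58.2 s⁻¹ (Vmax/E0); points above 5 mM,
where substrate inhibition breaks the double-reciprocal linearisation, are
excluded by default (`--smax`).

The same operations are available as library calls (`asparascan.search.survey`,
`asparascan.familymap.cluster_graph`, `asparascan.kinetics.fit_lineweaver_burk`,
`asparascan.structcmp.kabsch_superpose`, ...) on pandas DataFrames and plain
sequences.

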