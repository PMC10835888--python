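# tilescan

Analysis of pooled **CRISPR gene-tiling dropout screens** and **limiting
dilution assays**, two complementary measurements used to map which parts of a
protein a tumor cell line depends on and how a perturbation changes its
stem-like cell compartment.

In a tiling screen, a dense library of sgRNAs — one guide every few base
pairs across a single gene's coding sequence (CDS), plus negative controls
(no expected fitness effect) and killing controls (pan-essential targets) —
is transduced into Cas9-expressing cells. Guides cutting inside functionally
essential protein regions drop out of the population between day 0 and the
screen's end. `tilescan` turns the raw amplicon FASTQ files into a
per-residue *CRISPR scan score* profile and a set of candidate essential
regions:

1. **Extraction** — each read is scanned for the vector cassette
   `CACCG · <20-nt protospacer> · GTTT`; the enclosed 20-mer identifies the
   guide.
2. **Quantification** — extracted 20-mers are assigned to library guides
   (exact match by default, optional 1-mismatch), giving counts `c_i` and
   frequencies `f_i = c_i / Σ_j c_j` per sample.
3. **CRISPR score** — per guide,
   `CS_i = log10((f_i^day30 + ε) / (f_i^day0 + ε))`,
   with ε a half-read pseudofrequency; replicate clones are averaged.
4. **Scan profile** — guide scores, located at their Cas9 cut sites `x_i`,
   are interpolated over every CDS nucleotide with a Nadaraya–Watson
   Gaussian-kernel smoother
   `ŝ(x) = Σ_i K((x − x_i)/h)·CS_i / Σ_i K((x − x_i)/h)`,
   then averaged over trinucleotide codons to a per-residue track.
5. **Normalization** — scores are placed on a screen-invariant scale by the
   affine map sending the median negative-control score to **0.00** and the
   median killing-control score to **−1.00**.
6. **Region calling** — maximal runs of residues at or below a threshold
   (default −0.5) are reported as candidate essential regions.

For limiting dilution assays, the `limiting_dilution` module estimates the
frequency λ of self-renewing (stem-like) cells under the single-hit Poisson
model, `P(well negative | dose d) = exp(−λd)`, by maximum likelihood with
95% profile-likelihood intervals, plus a likelihood-ratio test between
conditions — the computation usually delegated to ELDA.

A seeded synthetic-screen generator (`screen_sim`) produces libraries,
negative-binomial count matrices with planted region-localized dropout, and
FASTQ files with the exact cassette structure, so the entire pipeline is
testable end to end without sequencing data.

## Worked example

Simulate a study-scale screen (229 tiling + 40 negative + 22 killing guides
over a 1686-nt CDS, 2 clones, ~10⁶ reads/sample) with a 5-residue essential
block planted at residues 90–94, then run the full scan:

```bash
cat > sim.yaml <<'EOF'
planted_regions: [[90, 94, -1.0]]
seed: 7
EOF
tilescan simulate --config sim.yaml --outdir screen
# library: {'tiling': 229, 'negative_control': 40, 'killing_control': 22}  density: 7.4 bp/sgRNA

cat > run.yaml <<'EOF'
library: screen/library.tsv
cds_length_nt: 1686
outdir: scan_out
seed: 7
samples:
  clone1_day0:  {path: screen/fastq/clone1_day0.fastq,  timepoint: day0,  replicate: clone1}
  clone1_day30: {path: screen/fastq/clone1_day30.fastq, timepoint: day30, replicate: clone1}
  clone2_day0:  {path: screen/fastq/clone2_day0.fastq,  timepoint: day0,  replicate: clone2}
  clone2_day30: {path: screen/fastq/clone2_day30.fastq, timepoint: day30, replicate: clone2}
EOF
tilescan run --config run.yaml
# done: 1 region(s); bandwidth 5.25 nt; outputs in scan_out

cat scan_out/regions.tsv
# region  start_residue  end_residue  n_residues  mean_score  peak_score
# R1      89             93           5           -0.753      -0.873
```

The called region R1 (residues 89–93, mean normalized score −0.75) recovers
the planted block: scores near 0 mean "behaves like a negative control",
−1 means "drops out as hard as a killing control". `scan_out/` also holds
the counts and frequency matrices, per-guide scores
(`CS_raw`, `CS_normalized`), and the per-nucleotide and per-residue
profiles, each with a provenance header (version, config hash, seed) so
reruns are verifiably bit-identical.

Limiting dilution analysis from a `condition dose tested responding` table:

```bash
tilescan lda --input lda.tsv --out lda_estimates.tsv
# control: 1 in 351.6  (95% CI 1 in 244.8 to 1 in 515.4)
# knockout: 1 in 2472.4  (95% CI 1 in 1692.5 to 1 in 3756.6)
```

with the pairwise likelihood-ratio test written alongside
(`LR = 51.1, p = 8.8e-13` for the tables above, simulated at true
frequencies 1/400 vs 1/2000).

The same functionality is available as a library
(`tilescan.analyze_counts`, `tilescan.fit_single_hit`, …); the CLI is a thin
wrapper.

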