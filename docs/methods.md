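# Methods

## Read extraction and quantification

Reads from the pooled-screen amplicon carry the guide cassette
`5'-flank · CACCG · protospacer(20 nt) · GTTT · 3'-flank`. Extraction scans
each read for occurrences of the 5′ anchor and emits the first 20-mer that
is immediately followed by the 3′ anchor; at most one 20-mer per read (one
cassette per amplicon). Only the forward orientation is scanned by default —
the amplicon is directional — with reverse-complement scanning available as
a flag.

Assignment is exact string matching against the library by default. A
1-mismatch mode (unique Hamming-distance ≤ 1 neighbor) exists but is off:
exact matching is reproducible, conservative, and sufficient when the
library's protospacers are well separated. A 20-mer matching zero or more
than one guide is discarded and tallied (`unmatched` / `ambiguous`);
library protospacers shared by more than one guide are excluded from
matching entirely (marked `ambiguous` in the library table) rather than
silently merged, to avoid count inflation. Frequencies are
`f_i = c_i / total_matched` per sample, so each sample column sums to 1.

## CRISPR score

Per guide, `CS_i = log10((f_i^end + ε)/(f_i^start + ε))`. The
pseudofrequency ε defaults to half a read in frequency units,
`0.5 / min_s(total_matched_s)` — a standard continuity correction that
keeps fully depleted guides finite without distorting well-covered ones.
Replicate clones are scored separately and combined as an unweighted
per-guide mean; the across-replicate range is kept as a concordance QC
field. An optional moderated mode shrinks `CS_i` by `n_i/(n_i + k)` with
`n_i = min(c_i^start, c_i^end)` and `k = 10`, damping scores supported by
few reads; it is a deliberately simple, deterministic alternative to
count-model moderation and is off by default.

## Scan profile

Guide scores are point measurements at Cas9 cut sites (0-based CDS
nucleotide coordinates; when inferred from sequence, the blunt cut 3 nt 5′
of the PAM-proximal protospacer end). The per-nucleotide profile is the
Nadaraya–Watson estimate with a Gaussian kernel,

    ŝ(x) = Σ_i exp(−(x−x_i)²/2h²)·CS_i / Σ_i exp(−(x−x_i)²/2h²),

evaluated at every integer position without kernel truncation (track
lengths are desk-scale), so ŝ is a convex combination of the inputs and
never leaves their range. Per-residue scores are the mean over each codon's
three nucleotides.

**Bandwidth.** Default `h = 0.75 × median adjacent cut-site spacing`
(≈5.5 nt at a density of 7.4 bp/sgRNA). Two pressures set this: h must be
large enough that positions between guides are interpolated from several
neighbors (at 0.75× spacing, ~95% of kernel mass falls within ±1.5
spacings), and small enough not to flatten short functional elements — a
noise-free convolution calculation shows a 5-residue (15 nt) block at full
killing-control effect retains ≈75% of its amplitude at this h, but only
≈50% at 2× spacing, which would push such blocks above any calling
threshold placed at half the killing-control effect. Bandwidth remains a
parameter for libraries with very different densities.

**Normalization.** Anchors are computed from the *raw* control-guide
scores: `m_neg` and `m_kill` are the medians of the negative- and
killing-control guides (median of an even count = midpoint of the two
central values), and every reported track is mapped through
`NCS(s) = (s − m_neg)/(m_neg − m_kill)`, so `NCS(m_neg) = 0.00` and
`NCS(m_kill) = −1.00` by construction. A screen in which the killing
controls did not drop below the negative controls (`m_neg ≤ m_kill`) is
rejected as a quality failure. Anchors are computed once on the
replicate-combined track (recorded in output metadata). The anchor
identities are analytically exact; in double precision the median of the
normalized controls can differ from 0/−1 by ~1 ulp when the median is a
midpoint of two values.

**Pipeline order** is smooth → codon-average → normalize: smoothing
operates on raw guide scores and the affine normalization commutes with
both the kernel average and the codon mean, so applying it last is
equivalent and keeps the anchors exact on every reported track.

**Region calling.** On the normalized residue track, maximal runs with
score ≤ −0.5 (half the killing-control effect) are called; runs separated
by ≤ 2 residues are merged, and merged runs shorter than 2 residues are
dropped. These are explicit config values — the threshold is a screening
heuristic, not a significance test, and candidate regions are meant to be
followed up by mutagenesis.

## Synthetic screens

The generator emulates the statistical structure the analysis assumes, at
study scale by default: 229 tiling guides over a 1686-nt (562-codon) CDS
(7.4 bp/sgRNA), 40 negative and 22 killing controls, 2 replicate clones,
~10⁶ matched reads per sample.

* **Placement** — cut sites on an even grid with ±1 nt uniform jitter.
  The jitter breaks exact periodicity while preserving the even tiling a
  designed library aims for: at default density every 15-nt window contains
  ≥ 2 cut sites. Real saturating libraries are PAM-constrained and lumpier
  (occasional gaps of 2–3× the mean spacing); recovery guarantees for
  blocks shorter than the local gap structure do not transfer to such
  libraries — for real data the per-guide scores should be inspected
  alongside the smoothed profile.
* **Abundances** — day-0 guide abundances are Dirichlet with concentration
  100 (near-uniform, ~10% CV, typical of a well-cloned pool). Day-30
  abundance is ∝ `p_i · 10^{β_i}` with β the planted fitness effect in
  log10-frequency units, so a planted β maps 1:1 onto the expected raw CS:
  β = −1 for killing controls (definitional, matching their −1.00 anchor),
  β of each planted region for tiling guides whose cut site lies inside it,
  0 otherwise.
* **Counts** — negative binomial with mean `depth · p` and a single common
  dispersion, default 0.01 (var = μ + 0.01 μ², ~10% extra-Poisson CV,
  typical of deep amplicon screens). Dispersion 0 falls back to Poisson.
* **FASTQ** — each counted guide is emitted count times as
  `flank · CACCG · protospacer · GTTT · flank` padded to the read length
  (default 50 nt) with seeded random flanks; a read is regenerated if its
  flanks happen to create an earlier valid anchor window, which guarantees
  extraction + exact matching reproduces the count matrix bit-exactly.
  Sequencing errors, PCR chimeras and clone-specific editing efficiency are
  not simulated — the round-trip guarantee is about the pipeline's
  bookkeeping, not about robustness to platform noise.

All outputs are deterministic given the config seed.

## Limiting dilution

Single-hit model: a well responds iff it received ≥ 1 active cell, so
`P(negative | dose d) = exp(−λd)` and the log-likelihood over doses is
`Σ_j [neg_j(−λd_j) + pos_j log(1 − exp(−λd_j))]`. The likelihood is concave
in λ, so the MLE is found as the unique root of the score function
(Brent's method to machine precision; equal to the intercept-only
complementary-log-log binomial regression with log-dose offset, which the
test suite checks against statsmodels). 95% limits are profile likelihood
(drop of χ²₁(0.95)/2 = 1.9207), preferred to Wald intervals because doses
span decades and the information at small λ is highly asymmetric.
Degenerate tables are flagged rather than fitted: all wells positive →
λ unbounded above (finite profile lower bound reported); all negative →
MLE 0 with finite upper bound `1.9207 / Σ_j n_j d_j`. Two-condition
comparison is the likelihood-ratio test against the pooled fit, χ²₁.
Goodness-of-fit to the single-hit assumption is not gated on.

## Problem sizes in the test suite

Unit tests run on miniature screens (40–80 tiling guides, 300–600-nt CDS,
2–8 × 10⁴ reads). The end-to-end checks use the study-scale defaults for
scoring/normalization/recovery (counts-level, 50 seeds), a 2 × 10⁵-read
single-replicate screen for the FASTQ round trip, and 200 simulated assays
per frequency for limiting-dilution calibration. The full suite completes
in about half a minute on one CPU.
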