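"""Synthetic tiling-screen generator.

Emulates the statistical structure of a pooled CRISPR tiling dropout
screen so every analysis stage is testable without sequencing data:

* a library of tiling guides with near-evenly spaced cut sites over the
  CDS plus negative and killing controls (defaults mirror a 229/40/22
  library over a 562-codon CDS);
* day-0 guide abundances near-uniform with Dirichlet jitter; day-30
  abundances multiplied by 10**beta where beta <= 0 is the planted
  fitness effect (log10-frequency units, so a planted beta maps 1:1 onto
  the expected raw CRISPR score); read counts negative-binomial around
  depth * abundance with a single common dispersion;
* FASTQ reads embedding each counted protospacer between the CACCG/GTTT
  cassette anchors, with random flanks, constructed so that anchor-window
  extraction recovers exactly the intended 20-mer (exact round trip).

All outputs are deterministic under a fixed seed. Not simulated: PCR
chimeras, sequencing errors, clone-specific editing efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import read_quant
from .library_io import (
    KILL_CONTROL,
    NEG_CONTROL,
    TILING,
    LibraryTable,
    SgRNARecord,
    build_library,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ScreenSimConfig:
    """Study-scale defaults: 229 tiling + 40 negative + 22 killing guides
    over a 1686-nt (562-codon) CDS, two replicate clones, ~1e6 matched
    reads per sample, NB dispersion 0.01, killing-control effect -1 in
    log10 units over the screen."""

    cds_length_nt: int = 1686
    n_tiling: int = 229
    n_neg: int = 40
    n_kill: int = 22
    planted_regions: list[tuple[int, int, float]] = field(default_factory=list)
    kill_effect: float = -1.0
    depth: int = 1_000_000
    nb_dispersion: float = 0.01
    read_length: int = 50
    n_replicates: int = 2
    dirichlet_conc: float = 100.0
    position_jitter_nt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_length_nt % 3 != 0:
            raise ValueError("cds_length_nt must be a multiple of 3")
        if self.depth <= 0 or self.nb_dispersion < 0:
            raise ValueError("depth must be > 0 and nb_dispersion >= 0")
        n_res = self.cds_length_nt // 3
        for start, end, beta in self.planted_regions:
            if not (1 <= start <= end <= n_res):
                raise ValueError(f"planted region ({start},{end}) outside residues [1,{n_res}]")
            if beta > 0:
                raise ValueError("planted fitness effects must be <= 0")
        if self.read_length < 5 + 20 + 4:
            raise ValueError("read_length must be >= 29 (anchors + protospacer)")

    @classmethod
    def from_yaml(cls, path) -> "ScreenSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted_regions" in raw:
            raw["planted_regions"] = [tuple(r) for r in raw["planted_regions"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {**self.__dict__, "planted_regions": [list(r) for r in self.planted_regions]}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _random_kmers(rng: np.random.Generator, n: int, k: int = 20) -> list[str]:
    """n distinct random k-mers over ACGT."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = BASES[rng.integers(0, 4, size=(n - len(out), k))]
        for row in block:
            s = row.tobytes().decode()
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def simulate_library(cfg: ScreenSimConfig) -> LibraryTable:
    """Tiling guides at near-evenly spaced cut sites (seeded jitter) plus
    coordinate-free controls; protospacers are distinct random 20-mers."""
    rng = np.random.default_rng(cfg.seed)
    L, n = cfg.cds_length_nt, cfg.n_tiling
    if n > L:
        raise ValueError(f"n_tiling={n} exceeds the {L} distinct CDS positions")
    spacing = L / n
    base = (np.arange(n) + 0.5) * spacing
    # small jitter breaks exact periodicity but keeps the even tiling the
    # analysis assumes (>= 2 cut sites per 2-spacing window at default density)
    jitter = rng.uniform(-cfg.position_jitter_nt, cfg.position_jitter_nt, size=n)
    pos = np.floor(base + jitter).astype(int)
    pos = np.clip(pos, 0, L - 1)
    for i in range(1, n):  # enforce distinct, ordered cut sites
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    if pos[-1] >= L:
        raise ValueError("could not place all tiling guides at distinct CDS positions")
    protos = _random_kmers(rng, n + cfg.n_neg + cfg.n_kill)
    strands = rng.choice(["+", "-"], size=n)
    records = [
        SgRNARecord(f"tile_{i + 1:04d}", protos[i], TILING, int(pos[i]), str(strands[i]))
        for i in range(n)
    ]
    records += [
        SgRNARecord(f"neg_{i + 1:03d}", protos[n + i], NEG_CONTROL) for i in range(cfg.n_neg)
    ]
    records += [
        SgRNARecord(f"kill_{i + 1:03d}", protos[n + cfg.n_neg + i], KILL_CONTROL)
        for i in range(cfg.n_kill)
    ]
    return build_library(records, L, gene_name="synthetic")


def _guide_effects(lib: LibraryTable, cfg: ScreenSimConfig) -> np.ndarray:
    beta = np.zeros(len(lib.records))
    for i, rec in enumerate(lib.records):
        if rec.category == KILL_CONTROL:
            beta[i] = cfg.kill_effect
        elif rec.category == TILING:
            for start, end, b in cfg.planted_regions:
                if 3 * (start - 1) <= rec.cut_pos_nt < 3 * end:
                    beta[i] = b
                    break
    return beta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion  # var = mu + dispersion * mu^2
    return rng.negative_binomial(size, size / (size + mu))


def simulate_counts(lib: LibraryTable, cfg: ScreenSimConfig) -> pd.DataFrame:
    """Counts matrix with columns clone{r}_day0 / clone{r}_day30.

    Day-30 abundance of guide i is proportional to p_i * 10**beta_i, with
    beta_i the planted effect (tiling guides cut inside a planted region),
    the kill_effect (killing controls) or 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    beta = _guide_effects(lib, cfg)
    n = len(lib.records)
    cols: dict[str, np.ndarray] = {}
    for r in range(1, cfg.n_replicates + 1):
        p0 = rng.dirichlet(np.full(n, cfg.dirichlet_conc))
        p30 = p0 * 10.0 ** beta
        p30 /= p30.sum()
        cols[f"clone{r}_day0"] = _nb_draw(rng, cfg.depth * p0, cfg.nb_dispersion)
        cols[f"clone{r}_day30"] = _nb_draw(rng, cfg.depth * p30, cfg.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(lib.guide_ids(), name="guide_id"))
    return counts


def sample_pairs(counts: pd.DataFrame) -> list[tuple[str, str]]:
    """(day0, day30) column pairs, one per replicate clone."""
    day0 = sorted(c for c in counts.columns if c.endswith("_day0"))
    return [(c, c.replace("_day0", "_day30")) for c in day0]


def _make_read(
    rng: np.random.Generator, proto: str, read_length: int
) -> str:
    cassette = read_quant.FIVE_PRIME_ANCHOR + proto + read_quant.THREE_PRIME_ANCHOR
    pad = read_length - len(cassette)
    while True:
        left = int(rng.integers(0, pad + 1))
        flank = BASES[rng.integers(0, 4, size=pad)].tobytes().decode()
        read = flank[:left] + cassette + flank[left:]
        # random flanks can create a spurious earlier anchor window; regenerate
        if read_quant.extract_from_sequence(read) == proto:
            return read


def simulate_fastq(
    counts: pd.DataFrame, lib: LibraryTable, cfg: ScreenSimConfig, outdir
) -> dict[str, Path]:
    """One FASTQ per sample; each guide's protospacer appears between the
    cassette anchors exactly count times, so extraction + exact-match
    quantification reproduces `counts` bit-exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proto_by_id = {r.guide_id: r.protospacer for r in lib.records}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    paths: dict[str, Path] = {}
    qual = "I" * cfg.read_length
    for sample in counts.columns:
        path = outdir / f"{sample}.fastq"
        col = counts[sample]
        order = rng.permutation(len(col))
        with open(path, "w") as fh:
            serial = 0
            for idx in order:
                gid = col.index[idx]
                proto = proto_by_id[gid]
                for _ in range(int(col.iloc[idx])):
                    read = _make_read(rng, proto, cfg.read_length)
                    fh.write(f"@{sample}:{serial}\n{read}\n+\n{qual}\n")
                    serial += 1
        paths[sample] = path
    return paths
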