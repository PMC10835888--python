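"""End-to-end tiling-scan pipeline: FASTQ -> counts -> scores -> profile -> regions.

Stage order follows the screen's analysis: extract + quantify reads per
sample, convert to frequencies, score each replicate clone (day30 vs
day0), combine replicates, smooth tiling-guide scores over the CDS,
average codons to residues, normalize everything against the raw
control-guide anchors, and call candidate essential regions.

Every output table carries a provenance header (package version, config
hash, seed), so a rerun with an identical config is bit-identical and
verifiable by hashing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .library_io import TILING, read_library
from .read_quant import count_samples, frequencies
from .scan_smoothing import (
    DEFAULT_MERGE_GAP,
    DEFAULT_MIN_LEN,
    DEFAULT_THRESHOLD,
    RegionCall,
    call_regions,
    regions_frame,
    scan_profile,
)
from .tiling_score import (
    combine_replicates,
    compute_anchors,
    crispr_score,
    default_pseudofreq,
    normalize,
    score_frame,
)

logger = logging.getLogger("tilescan")

TIMEPOINTS = ("day0", "day30")


class ConfigError(ValueError):
    pass


@dataclass
class SampleSpec:
    path: Path
    timepoint: str
    replicate: str


@dataclass
class RunConfig:
    """Validated end-to-end run configuration."""

    library: Path
    cds_length_nt: int
    samples: dict[str, SampleSpec]
    outdir: Path
    pseudofreq: float | None = None
    max_mismatch: int = 0
    scan_revcomp: bool = False
    bandwidth_nt: float | None = None
    threshold: float = DEFAULT_THRESHOLD
    min_len: int = DEFAULT_MIN_LEN
    merge_gap: int = DEFAULT_MERGE_GAP
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.library).exists():
            raise ConfigError(f"library table not found: {self.library}")
        by_tp: dict[str, int] = {tp: 0 for tp in TIMEPOINTS}
        for name, spec in self.samples.items():
            if spec.timepoint not in TIMEPOINTS:
                raise ConfigError(f"sample {name}: timepoint must be one of {TIMEPOINTS}")
            if not Path(spec.path).exists():
                raise ConfigError(f"sample {name}: FASTQ not found: {spec.path}")
            by_tp[spec.timepoint] += 1
        if min(by_tp.values()) == 0:
            raise ConfigError("manifest needs at least one day0 and one day30 sample")
        for rep, pair in self.replicate_pairs().items():
            if None in pair:
                raise ConfigError(f"replicate {rep}: needs both a day0 and a day30 sample")

    def replicate_pairs(self) -> dict[str, list]:
        pairs: dict[str, list] = {}
        for name, spec in self.samples.items():
            slot = pairs.setdefault(spec.replicate, [None, None])
            slot[TIMEPOINTS.index(spec.timepoint)] = name
        return pairs

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "library": str(self.library),
                "cds_length_nt": self.cds_length_nt,
                "samples": {
                    k: [str(v.path), v.timepoint, v.replicate] for k, v in sorted(self.samples.items())
                },
                "pseudofreq": self.pseudofreq,
                "max_mismatch": self.max_mismatch,
                "scan_revcomp": self.scan_revcomp,
                "bandwidth_nt": self.bandwidth_nt,
                "threshold": self.threshold,
                "min_len": self.min_len,
                "merge_gap": self.merge_gap,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            samples = {
                name: SampleSpec(Path(s["path"]), str(s["timepoint"]), str(s["replicate"]))
                for name, s in raw["samples"].items()
            }
            params = raw.get("params", {}) or {}
            return cls(
                library=Path(raw["library"]),
                cds_length_nt=int(raw["cds_length_nt"]),
                samples=samples,
                outdir=Path(raw.get("outdir", "tilescan_out")),
                seed=int(raw.get("seed", 0)),
                **params,
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed run config {path}: {exc}") from exc


def provenance_header(cfg_hash: str, seed: int, extra: dict | None = None) -> str:
    fields = {"version": __version__, "config": cfg_hash, "seed": seed, **(extra or {})}
    return "# tilescan " + " ".join(f"{k}={v}" for k, v in fields.items())


def write_table(df: pd.DataFrame, path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


@dataclass
class ScanResult:
    counts: pd.DataFrame
    freqs: pd.DataFrame
    scores: pd.DataFrame  # guide_id category cut_pos_nt CS_raw CS_normalized ...
    nt_track: pd.DataFrame
    residue_track: pd.DataFrame
    regions: list[RegionCall]
    bandwidth_nt: float
    anchors: tuple[float, float]
    pseudofreq: float = 0.0
    summaries: dict = field(default_factory=dict)


def analyze_counts(
    lib,
    counts: pd.DataFrame,
    replicate_pairs: list[tuple[str, str]],
    pseudofreq: float | None = None,
    bandwidth_nt: float | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> ScanResult:
    """Counts-level pipeline: frequencies -> per-replicate CS -> combine ->
    smooth -> codon-average -> anchor-normalize -> call regions.

    `replicate_pairs` lists (day0_column, day30_column) per clone. Writes
    nothing; `run_scan` adds the file I/O around this.
    """
    freqs = frequencies(counts)
    pf = pseudofreq if pseudofreq is not None else default_pseudofreq(counts)
    tracks = [crispr_score(freqs[s0], freqs[s30], pf) for s0, s30 in replicate_pairs]
    combined, spread = combine_replicates(tracks)

    scores = score_frame(lib, combined)
    anchors = compute_anchors(scores)
    scores = scores.rename(columns={"score": "CS_raw"})
    scores["CS_normalized"] = normalize(scores["CS_raw"], anchors)
    scores["replicate_range"] = spread.reindex(scores["guide_id"]).to_numpy()
    scores["n_replicates"] = len(tracks)

    tiling = scores.loc[scores["category"] == TILING, ["cut_pos_nt", "CS_raw"]].rename(
        columns={"CS_raw": "score"}
    )
    nt_raw, res_raw, h = scan_profile(tiling, lib.cds_length_nt, bandwidth_nt)
    nt_norm = normalize(nt_raw, anchors)
    res_norm = normalize(res_raw, anchors)
    nt_df = pd.DataFrame({"position_nt": range(lib.cds_length_nt), "score": nt_norm})
    res_df = pd.DataFrame({"residue": range(1, len(res_norm) + 1), "score": res_norm})

    regions = call_regions(res_norm, threshold, min_len, merge_gap)
    return ScanResult(
        counts=counts,
        freqs=freqs,
        scores=scores,
        nt_track=nt_df,
        residue_track=res_df,
        regions=regions,
        bandwidth_nt=h,
        anchors=(anchors.m_neg, anchors.m_kill),
        pseudofreq=pf,
    )


def run_scan(cfg: RunConfig) -> ScanResult:
    """Execute the full pipeline and write all intermediate tables to
    cfg.outdir. Raises ConfigError before any heavy I/O when invalid."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    head = lambda **kw: provenance_header(cfg_hash, cfg.seed, kw)  # noqa: E731

    lib = read_library(cfg.library, cfg.cds_length_nt)
    logger.info("library: %s", lib.category_counts())

    fastq = {name: spec.path for name, spec in cfg.samples.items()}
    counts, summaries = count_samples(
        fastq, lib, max_mismatch=cfg.max_mismatch, scan_revcomp=cfg.scan_revcomp
    )
    for sample, s in summaries.items():
        logger.info("%s: %s", sample, s)

    pairs = [
        (names[0], names[1]) for _, names in sorted(cfg.replicate_pairs().items())
    ]
    result = analyze_counts(
        lib, counts, pairs,
        pseudofreq=cfg.pseudofreq, bandwidth_nt=cfg.bandwidth_nt,
        threshold=cfg.threshold, min_len=cfg.min_len, merge_gap=cfg.merge_gap,
    )
    result.summaries = summaries
    m_neg, m_kill = result.anchors

    write_table(counts, outdir / "counts.tsv", head(), index=True)
    (outdir / "extraction_summary.json").write_text(json.dumps(summaries, indent=2))
    write_table(result.freqs, outdir / "frequencies.tsv", head(), index=True)
    write_table(
        result.scores,
        outdir / "scores.tsv",
        head(pseudofreq=f"{result.pseudofreq:.3g}", m_neg=f"{m_neg:.6g}", m_kill=f"{m_kill:.6g}"),
    )
    write_table(result.nt_track, outdir / "profile_nt.tsv", head(bandwidth_nt=f"{result.bandwidth_nt:.4g}"))
    write_table(result.residue_track, outdir / "profile_residue.tsv", head(bandwidth_nt=f"{result.bandwidth_nt:.4g}"))

    rf = regions_frame(result.regions)
    rf.insert(0, "region", [f"R{i + 1}" for i in range(len(rf))])
    write_table(
        rf,
        outdir / "regions.tsv",
        head(threshold=cfg.threshold, min_len=cfg.min_len, merge_gap=cfg.merge_gap),
    )
    # BED-like: 0-based half-open residue coordinates
    with open(outdir / "regions.bed", "w") as fh:
        for i, c in enumerate(result.regions):
            fh.write(f"{lib.gene_name or 'CDS'}\t{c.start_residue - 1}\t{c.end_residue}\tR{i + 1}\t{c.mean_score:.4f}\n")

    params = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "pseudofreq": result.pseudofreq,
        "bandwidth_nt": result.bandwidth_nt,
        "threshold": cfg.threshold,
        "min_len": cfg.min_len,
        "merge_gap": cfg.merge_gap,
        "anchors": {"m_neg": m_neg, "m_kill": m_kill},
        "n_regions": len(result.regions),
    }
    (outdir / "provenance.json").write_text(json.dumps(params, indent=2))
    return result
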