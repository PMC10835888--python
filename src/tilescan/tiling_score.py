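"""Per-guide CRISPR scores and control-anchored normalization.

The CRISPR score (CS) of a guide is the log10 fold-change of its library
frequency between the screen end (day 30) and start (day 0); dropout of a
guide targeting an essential region gives a negative CS. Replicate clones
are combined by an unweighted per-guide mean. Scores are then placed on a
screen-invariant scale by a two-point affine map anchored to the control
guides: the median negative-control CS maps to 0.00 and the median
killing-control CS to -1.00.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library_io import KILL_CONTROL, NEG_CONTROL, LibraryTable

SCORE_COLUMNS = ["guide_id", "category", "cut_pos_nt", "score"]


class ScreenQualityError(ValueError):
    """Control guides do not behave as a valid screen requires."""


@dataclass(frozen=True)
class NormalizationAnchors:
    """Raw-score medians of the two control classes (m_neg > m_kill)."""

    m_neg: float
    m_kill: float

    def __post_init__(self) -> None:
        if not self.m_neg > self.m_kill:
            raise ScreenQualityError(
                f"negative-control median ({self.m_neg:.4g}) must exceed "
                f"killing-control median ({self.m_kill:.4g}): killing controls did not drop out"
            )


def default_pseudofreq(counts: pd.DataFrame) -> float:
    """Half a read in frequency units: 0.5 / min over samples of total matched."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("pseudofrequency undefined: a sample has zero matched reads")
    return 0.5 / float(totals.min())


def score_frame(lib: LibraryTable, scores: pd.Series) -> pd.DataFrame:
    """Attach category and coordinates to a per-guide score vector."""
    meta = lib.to_frame().set_index("guide_id")
    df = pd.DataFrame({"score": scores})
    df.index.name = "guide_id"
    out = df.join(meta[["category", "cut_pos_nt"]]).reset_index()
    return out[SCORE_COLUMNS]


def crispr_score(
    f_start: pd.Series,
    f_end: pd.Series,
    pseudofreq: float,
    moderate_counts: pd.DataFrame | None = None,
    moderation_k: float = 10.0,
) -> pd.Series:
    """CS_i = log10((f_end_i + pseudofreq) / (f_start_i + pseudofreq)).

    With `moderate_counts` (two columns: start, end raw counts) each score is
    shrunk toward 0 by n_i / (n_i + k), n_i = min(start, end count) — a
    lightweight stand-in for count-level dispersion moderation.
    """
    if pseudofreq <= 0:
        raise ValueError("pseudofreq must be > 0")
    if not f_start.index.equals(f_end.index):
        raise ValueError("start and end frequency columns index different guide sets")
    cs = np.log10((f_end + pseudofreq) / (f_start + pseudofreq))
    if moderate_counts is not None:
        n = moderate_counts.min(axis=1).reindex(cs.index).astype(float)
        cs = cs * (n / (n + moderation_k))
    cs.name = "score"
    return cs


def combine_replicates(tracks: list[pd.Series]) -> tuple[pd.Series, pd.Series]:
    """Unweighted per-guide mean across replicate score tracks.

    Returns (mean, range) where range = max - min across replicates per
    guide, a QC field for replicate concordance.
    """
    if not tracks:
        raise ValueError("no replicate tracks supplied")
    first = tracks[0].index
    for t in tracks[1:]:
        if not t.index.equals(first):
            raise ValueError("replicate tracks index different guide sets")
    stacked = pd.concat(tracks, axis=1)
    mean = stacked.mean(axis=1)
    spread = stacked.max(axis=1) - stacked.min(axis=1)
    mean.name, spread.name = "score", "replicate_range"
    return mean, spread


def compute_anchors(scores: pd.DataFrame) -> NormalizationAnchors:
    """Medians of raw control scores by class (columns: category, score)."""
    neg = scores.loc[scores["category"] == NEG_CONTROL, "score"]
    kill = scores.loc[scores["category"] == KILL_CONTROL, "score"]
    if neg.empty or kill.empty:
        raise ScreenQualityError(
            "both negative and killing controls are required to anchor normalization "
            f"(found {len(neg)} negative, {len(kill)} killing)"
        )
    return NormalizationAnchors(float(neg.median()), float(kill.median()))


def normalize(values, anchors: NormalizationAnchors):
    """Two-point affine map: anchors.m_neg -> 0.00, anchors.m_kill -> -1.00.

    Accepts any real array-like (per-guide scores or a smoothed positional
    track); order-preserving since m_neg > m_kill.
    """
    span = anchors.m_neg - anchors.m_kill
    return (values - anchors.m_neg) / span
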