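"""sgRNA tiling-library data model and on-disk table I/O.

A tiling library densely covers one gene's coding sequence (CDS) with
guides whose Cas9 cut sites are annotated as 0-based nucleotide offsets
from the CDS start, plus two control classes: negative controls (no
fitness effect expected; normalization anchor 0.00) and killing controls
(pan-essential targets; anchor -1.00).

Coordinates are 0-based, half-open, CDS-relative nucleotides; residues
are 1-based (residue 1 = codon over nt [0, 3)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

TILING = "tiling"
NEG_CONTROL = "negative_control"
KILL_CONTROL = "killing_control"
CATEGORIES = (TILING, NEG_CONTROL, KILL_CONTROL)

DNA = set("ACGT")
PROTOSPACER_LEN = 20

LIBRARY_COLUMNS = ["guide_id", "protospacer", "category", "cut_pos_nt", "strand"]
_REQUIRED_COLUMNS = {"guide_id", "protospacer", "category"}


class LibraryFormatError(ValueError):
    """The library table file is structurally unreadable."""


class LibraryValidationError(ValueError):
    """Rows or library-level invariants are violated."""


@dataclass(frozen=True)
class SgRNARecord:
    """One guide: id, 20-nt protospacer, category, optional CDS cut site."""

    guide_id: str
    protospacer: str
    category: str
    cut_pos_nt: Optional[int] = None
    strand: Optional[str] = None
    ambiguous: bool = False  # protospacer shared by >1 guide; excluded from matching


@dataclass
class LibraryTable:
    """Validated sgRNA catalog for one gene's CDS."""

    records: list[SgRNARecord]
    cds_length_nt: int
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.cds_length_nt % 3 != 0:
            raise LibraryValidationError(
                f"cds_length_nt={self.cds_length_nt} is not a multiple of 3"
            )

    @property
    def n_residues(self) -> int:
        return self.cds_length_nt // 3

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for r in self.records:
            counts[r.category] += 1
        return counts

    def tiling_records(self) -> list[SgRNARecord]:
        return [r for r in self.records if r.category == TILING]

    def matchable_records(self) -> list[SgRNARecord]:
        """Guides usable for read assignment (unique protospacers only)."""
        return [r for r in self.records if not r.ambiguous]

    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "protospacer": [r.protospacer for r in self.records],
                "category": [r.category for r in self.records],
                "cut_pos_nt": [r.cut_pos_nt for r in self.records],
                "strand": [r.strand for r in self.records],
            }
        )


def _validate_row(i: int, row: pd.Series, cds_length_nt: int) -> tuple[Optional[SgRNARecord], Optional[str]]:
    gid = str(row["guide_id"]).strip()
    proto = str(row["protospacer"]).strip().upper()
    cat = str(row["category"]).strip()
    if not gid or gid.lower() == "nan":
        return None, f"row {i}: empty guide_id"
    if cat not in CATEGORIES:
        return None, f"row {i} ({gid}): unknown category {cat!r}"
    if len(proto) != PROTOSPACER_LEN or not set(proto) <= DNA:
        return None, (
            f"row {i} ({gid}): protospacer must be {PROTOSPACER_LEN} nt over ACGT, "
            f"got {proto!r} (length {len(proto)})"
        )
    raw_pos = row.get("cut_pos_nt")
    has_pos = raw_pos is not None and not pd.isna(raw_pos) and str(raw_pos).upper() != "NA"
    raw_strand = row.get("strand")
    has_strand = raw_strand is not None and not pd.isna(raw_strand) and str(raw_strand).upper() != "NA"
    if cat == TILING:
        if not has_pos:
            return None, f"row {i} ({gid}): tiling guide missing cut_pos_nt"
        pos = int(float(raw_pos))
        if not 0 <= pos < cds_length_nt:
            return None, f"row {i} ({gid}): cut_pos_nt={pos} outside [0, {cds_length_nt})"
        strand = str(raw_strand) if has_strand else None
        if strand is not None and strand not in {"+", "-"}:
            return None, f"row {i} ({gid}): strand must be + or -, got {strand!r}"
        return SgRNARecord(gid, proto, cat, pos, strand), None
    if has_pos:
        return None, f"row {i} ({gid}): control guide must not carry cut_pos_nt"
    return SgRNARecord(gid, proto, cat, None, None), None


def build_library(records: list[SgRNARecord], cds_length_nt: int, gene_name: str = "") -> LibraryTable:
    """Assemble + validate a LibraryTable from pre-built records.

    Duplicate guide_ids raise; duplicate protospacers are kept but marked
    ambiguous so that quantification skips them rather than inflating counts.
    """
    ids = [r.guide_id for r in records]
    dupes = {g for g in ids if ids.count(g) > 1}
    if dupes:
        raise LibraryValidationError(f"duplicate guide_id(s): {sorted(dupes)}")
    proto_counts: dict[str, int] = {}
    for r in records:
        proto_counts[r.protospacer] = proto_counts.get(r.protospacer, 0) + 1
    marked = [
        SgRNARecord(r.guide_id, r.protospacer, r.category, r.cut_pos_nt, r.strand,
                    ambiguous=proto_counts[r.protospacer] > 1)
        for r in records
    ]
    lib = LibraryTable(marked, cds_length_nt, gene_name)
    if lib.category_counts()[TILING] == 0:
        raise LibraryValidationError("library contains zero tiling guides")
    return lib


def read_library(path, cds_length_nt: int, gene_name: str = "") -> LibraryTable:
    """Read a delimited (tab or comma) library table and validate it.

    Required header columns: guide_id, protospacer, category; cut_pos_nt is
    required for tiling rows and must be NA/empty for controls. Invalid rows
    abort the load with per-row diagnostics.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         dtype=str, keep_default_na=False, na_values=["", "NA"])
    except Exception as exc:  # noqa: BLE001 - rewrap parser errors uniformly
        raise LibraryFormatError(f"cannot parse library table {path}: {exc}") from exc
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise LibraryFormatError(f"library table missing required column(s): {sorted(missing)}")
    records: list[SgRNARecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        rec, err = _validate_row(int(i) + 2, row, cds_length_nt)  # +2: header + 1-based
        if err:
            problems.append(err)
        else:
            records.append(rec)
    if problems:
        raise LibraryValidationError(
            "invalid library rows:\n  " + "\n  ".join(problems)
        )
    return build_library(records, cds_length_nt, gene_name)


def write_library(lib: LibraryTable, path) -> None:
    """Write the table back in the canonical 5-column format (NA for absent)."""
    df = lib.to_frame()
    df["cut_pos_nt"] = df["cut_pos_nt"].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    df["strand"] = df["strand"].map(lambda v: "NA" if v is None or pd.isna(v) else v)
    if isinstance(path, io.TextIOBase):
        df.to_csv(path, sep="\t", index=False)
    else:
        df.to_csv(path, sep="\t", index=False)


def tiling_density(lib: LibraryTable) -> float:
    """Average targeting density in bp per tiling sgRNA (CDS length / n tiling)."""
    n = lib.category_counts()[TILING]
    if n == 0:
        raise LibraryValidationError("tiling density undefined: no tiling guides")
    return lib.cds_length_nt / n


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def infer_cut_position(protospacer: str, cds_seq: str) -> tuple[Optional[int], Optional[str]]:
    """Locate a protospacer in a CDS (both strands) and return (cut_pos_nt, strand).

    Uses blunt-cut SpCas9 geometry: the cut falls 3 nt 5' of the PAM-proximal
    protospacer end. For a + strand hit at offset p the cut is between
    p+16|p+17, reported as p+17; for a - strand hit it is reported as p+3.
    Returns (None, None) when the protospacer is absent or multi-mapping.
    """
    cds_seq = cds_seq.upper()
    fwd = [i for i in _find_all(cds_seq, protospacer)]
    rev = [i for i in _find_all(cds_seq, revcomp(protospacer))]
    if len(fwd) + len(rev) != 1:
        return None, None
    if fwd:
        return fwd[0] + 17, "+"
    return rev[0] + 3, "-"


def _find_all(hay: str, needle: str):
    start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1
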