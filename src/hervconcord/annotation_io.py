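"""Reading, validating and writing locus-resolved repeat annotations.

All coordinates are held internally as 0-based half-open intervals, so that
``length == end - start`` for every record.  Input dialects that use 1-based
inclusive coordinates (RepeatMasker ``.out``, UCSC-style tables) are converted
on read.  The canonical on-disk format is a BED6+4 dialect::

    chrom  start  end  record_id  score  strand  family  superfamily  destruction  repeat_class

with empty strings for absent optional fields; it round-trips field-for-field
through :func:`read_bed` / :func:`write_bed`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: superfamily labels a classified record may carry; "unassigned" marks
#: records that classification has not yet seen.
SUPERFAMILIES = ("ERV1", "ERV2", "ERV3", "Gypsy", "Unclassified")
UNASSIGNED = "unassigned"

VALID_STRANDS = ("+", "-", ".")

#: canonical column order of the backing DataFrame
COLUMNS = (
    "record_id",
    "chrom",
    "start",
    "end",
    "strand",
    "family",
    "repeat_class",
    "superfamily",
    "destruction",
)


class AnnotationError(ValueError):
    """Malformed annotation input (bad coordinates, duplicate ids, ...)."""


@dataclass(frozen=True)
class RepeatRecord:
    """One annotated repeat locus.

    ``start``/``end`` are 0-based half-open; ``destruction`` is the percentage
    of consensus nucleotides lost (0–100) or ``None`` when the source does not
    provide it (only HERVd-style sources do).
    """

    record_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    family: str = ""
    repeat_class: str = ""
    superfamily: str = UNASSIGNED
    destruction: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"record {self.record_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise AnnotationError(f"record {self.record_id!r}: negative start")
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"record {self.record_id!r}: bad strand {self.strand!r}")
        if self.destruction is not None and not (0.0 <= self.destruction <= 100.0):
            raise AnnotationError(
                f"record {self.record_id!r}: destruction {self.destruction} outside [0, 100]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


class AnnotationSet:
    """All records from one named source.

    Backed by a pandas DataFrame (columns :data:`COLUMNS`) sorted
    deterministically by (chrom, start, end, record_id).  ``destruction`` is a
    float column with NaN for absent values.
    """

    def __init__(
        self,
        records: Iterable[RepeatRecord] | pd.DataFrame,
        source_name: str,
        genome_build: str = "",
    ):
        self.source_name = source_name
        self.genome_build = genome_build
        if isinstance(records, pd.DataFrame):
            df = records.loc[:, list(COLUMNS)].copy()
        else:
            recs = list(records)
            df = pd.DataFrame(
                {
                    "record_id": [r.record_id for r in recs],
                    "chrom": [r.chrom for r in recs],
                    "start": [r.start for r in recs],
                    "end": [r.end for r in recs],
                    "strand": [r.strand for r in recs],
                    "family": [r.family for r in recs],
                    "repeat_class": [r.repeat_class for r in recs],
                    "superfamily": [r.superfamily for r in recs],
                    "destruction": [
                        np.nan if r.destruction is None else float(r.destruction) for r in recs
                    ],
                }
            )
            if not recs:
                df = _empty_frame()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["destruction"] = df["destruction"].astype(float)
        self._validate(df)
        df = df.sort_values(
            ["chrom", "start", "end", "record_id"], kind="mergesort"
        ).reset_index(drop=True)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["end"] <= df["start"]).any():
            bad = df.loc[df["end"] <= df["start"], "record_id"].iloc[0]
            raise AnnotationError(f"record {bad!r}: end must exceed start")
        if df["record_id"].duplicated().any():
            dup = df.loc[df["record_id"].duplicated(), "record_id"].iloc[0]
            raise AnnotationError(f"duplicate record_id {dup!r}")
        dupe_loci = df.duplicated(subset=["chrom", "start", "end", "family"]).sum()
        if dupe_loci:
            logger.warning(
                "%d records share (chrom, start, end, family) with another record; kept as distinct",
                dupe_loci,
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.source_name == other.source_name
            and self.genome_build == other.genome_build
            and self.df.equals(other.df)
        )

    def __iter__(self) -> Iterator[RepeatRecord]:
        return iter(self.records)

    @property
    def records(self) -> list[RepeatRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                RepeatRecord(
                    record_id=row.record_id,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    family=row.family,
                    repeat_class=row.repeat_class,
                    superfamily=row.superfamily,
                    destruction=None if pd.isna(row.destruction) else float(row.destruction),
                    source=self.source_name,
                )
            )
        return out

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def with_df(self, df: pd.DataFrame) -> "AnnotationSet":
        return AnnotationSet(df, self.source_name, self.genome_build)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "family": pd.Series(dtype=str),
            "repeat_class": pd.Series(dtype=str),
            "superfamily": pd.Series(dtype=str),
            "destruction": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# BED-like reader / writer


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise AnnotationError(f"line {lineno}: non-integer {what} {token!r}") from None


def read_bed(
    path: str | Path,
    coordinate_convention: str = "bed0_halfopen",
    source_name: Optional[str] = None,
    genome_build: str = "",
) -> AnnotationSet:
    """Read a BED-like table into an :class:`AnnotationSet`.

    Two layouts are accepted: the canonical BED6+4 dialect written by
    :func:`write_bed`, and a minimal ≥4-column layout
    (chrom, start, end, name[, strand, family, class, destruction]).
    ``coordinate_convention`` is ``bed0_halfopen`` (coordinates taken as-is)
    or ``oneinclusive`` (start decremented by one on read).
    """
    if coordinate_convention not in ("bed0_halfopen", "oneinclusive"):
        raise ValueError(f"unknown coordinate convention {coordinate_convention!r}")
    path = Path(path)
    name = source_name if source_name is not None else path.stem
    records: list[RepeatRecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise AnnotationError(f"line {lineno}: expected ≥4 columns, got {len(cols)}")
            chrom = cols[0].strip()
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            if coordinate_convention == "oneinclusive":
                start -= 1
            rid = cols[3].strip()
            if end <= start:
                raise AnnotationError(
                    f"line {lineno}: end ({end}) ≤ start ({start}) after conversion"
                )
            if rid in seen_ids:
                raise AnnotationError(f"line {lineno}: duplicate record_id {rid!r}")
            seen_ids.add(rid)

            strand, family, repeat_class, superfamily, destruction = ".", "", "", UNASSIGNED, None
            rest = cols[4:]
            if rest and _is_score(rest[0]):
                # BED6+ dialect: score, strand, family, superfamily, destruction, class
                if len(rest) > 1 and rest[1]:
                    strand = _norm_strand(rest[1], lineno)
                if len(rest) > 2:
                    family = rest[2].strip()
                if len(rest) > 3 and rest[3].strip():
                    superfamily = rest[3].strip()
                if len(rest) > 4 and rest[4].strip():
                    destruction = _parse_destruction(rest[4], lineno)
                if len(rest) > 5:
                    repeat_class = rest[5].strip()
            elif rest:
                # minimal layout: strand, family, class, destruction
                strand = _norm_strand(rest[0], lineno)
                if len(rest) > 1:
                    family = rest[1].strip()
                if len(rest) > 2:
                    repeat_class = rest[2].strip()
                if len(rest) > 3 and rest[3].strip():
                    destruction = _parse_destruction(rest[3], lineno)
            try:
                records.append(
                    RepeatRecord(
                        record_id=rid,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        family=family,
                        repeat_class=repeat_class,
                        superfamily=superfamily,
                        destruction=destruction,
                        source=name,
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"line {lineno}: {exc}") from None
    return AnnotationSet(records, source_name=name, genome_build=genome_build)


def _is_score(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _norm_strand(token: str, lineno: int) -> str:
    token = token.strip()
    if token in ("+", "-"):
        return token
    if token in (".", "", "?"):
        return "."
    if token == "C":
        return "-"
    raise AnnotationError(f"line {lineno}: bad strand {token!r}")


def _parse_destruction(token: str, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise AnnotationError(f"line {lineno}: non-numeric destruction {token!r}") from None
    if not 0.0 <= value <= 100.0:
        raise AnnotationError(f"line {lineno}: destruction {value} outside [0, 100]")
    return value


def write_bed(aset: AnnotationSet, path: str | Path) -> None:
    """Write the canonical BED6+4 dialect (tab-separated, no header).

    Round-trips through :func:`read_bed` field-for-field; absent destruction
    becomes an empty field.
    """
    df = aset.df
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            destr = "" if pd.isna(row.destruction) else _fmt_float(row.destruction)
            fh.write(
                "\t".join(
                    (
                        row.chrom,
                        str(row.start),
                        str(row.end),
                        row.record_id,
                        "0",
                        row.strand,
                        row.family,
                        row.superfamily,
                        destr,
                        row.repeat_class,
                    )
                )
                + "\n"
            )


def _fmt_float(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# RepeatMasker .out reader

#: minimal column count of a RepeatMasker .out alignment line
_RM_MIN_COLS = 14


def read_repeatmasker_out(
    path: str | Path,
    source_name: Optional[str] = None,
    genome_build: str = "",
) -> AnnotationSet:
    """Read a RepeatMasker ``.out`` file (1-based inclusive → internal 0-based).

    The repeat-name column becomes ``family`` (that is the key family maps use,
    e.g. MLT1K); the class/family column's part before '/' becomes
    ``repeat_class``; strand 'C' maps to '-'.
    """
    path = Path(path)
    name = source_name if source_name is not None else path.stem
    with open(path) as fh:
        lines = fh.readlines()
    # layout: two header rows (SW score / divergence captions) + blank line
    head = "".join(lines[:2]).lower()
    if len(lines) < 2 or "score" not in head or "sw" not in head:
        raise AnnotationError(f"{path}: missing RepeatMasker .out header")
    body_start = 2
    while body_start < len(lines) and not lines[body_start].strip():
        body_start += 1
    records: list[RepeatRecord] = []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) < _RM_MIN_COLS:
            raise AnnotationError(
                f"line {lineno}: expected ≥{_RM_MIN_COLS} columns in .out alignment line, "
                f"got {len(cols)}"
            )
        chrom = cols[4]
        begin = _parse_int(cols[5], "begin", lineno)
        end = _parse_int(cols[6], "end", lineno)
        strand = "-" if cols[8] == "C" else "+"
        family = cols[9]
        class_family = cols[10]
        repeat_class = class_family.split("/", 1)[0]
        records.append(
            RepeatRecord(
                record_id=f"rm{lineno:07d}",
                chrom=chrom,
                start=begin - 1,
                end=end,
                strand=strand,
                family=family,
                repeat_class=repeat_class,
                source=name,
            )
        )
    return AnnotationSet(records, source_name=name, genome_build=genome_build)


# ---------------------------------------------------------------------------
# HERVd-style TSV reader


def read_hervd_tsv(
    path: str | Path,
    source_name: Optional[str] = None,
    genome_build: str = "",
    coordinate_convention: str = "oneinclusive",
    completeness_column: bool = True,
) -> AnnotationSet:
    """Read a header-bearing TSV with at least chrom/start/end/family columns.

    When the file carries a ``completeness`` column and ``completeness_column``
    is true, destruction is derived as ``100 - completeness``; a ``destruction``
    column is consumed directly.
    """
    path = Path(path)
    name = source_name if source_name is not None else path.stem
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chrom", "start", "end", "family"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    starts = df["start"].astype(np.int64)
    if coordinate_convention == "oneinclusive":
        starts = starts - 1
    elif coordinate_convention != "bed0_halfopen":
        raise ValueError(f"unknown coordinate convention {coordinate_convention!r}")
    destruction = pd.Series(np.nan, index=df.index)
    if "destruction" in df.columns:
        destruction = df["destruction"].astype(float)
    elif "completeness" in df.columns and completeness_column:
        destruction = 100.0 - df["completeness"].astype(float)
        logger.info("%s: derived destruction as 100 - completeness", path)
    ids = (
        df["record_id"]
        if "record_id" in df.columns
        else pd.Series([f"{name}_{i:07d}" for i in range(len(df))])
    )
    out = pd.DataFrame(
        {
            "record_id": ids.astype(str),
            "chrom": df["chrom"].astype(str),
            "start": starts,
            "end": df["end"].astype(np.int64),
            "strand": df["strand"].astype(str) if "strand" in df.columns else ".",
            "family": df["family"].astype(str),
            "repeat_class": df["class"].astype(str) if "class" in df.columns else "",
            "superfamily": UNASSIGNED,
            "destruction": destruction.astype(float),
        }
    )
    return AnnotationSet(out, source_name=name, genome_build=genome_build)


# ---------------------------------------------------------------------------
# filtering and locus-string parsing


def filter_ltr_class(aset: AnnotationSet, keep_class: str = "LTR") -> AnnotationSet:
    """Keep only records whose ``repeat_class`` equals ``keep_class`` exactly
    (after whitespace trimming).  Records with an empty class are counted
    separately from mismatching ones in the log."""
    cls = aset.df["repeat_class"].str.strip()
    keep = cls == keep_class.strip()
    n_missing = int((cls == "").sum())
    n_removed = int((~keep).sum()) - n_missing
    logger.info(
        "%s: kept %d/%d records of class %r (%d other classes, %d missing class)",
        aset.source_name,
        int(keep.sum()),
        len(aset),
        keep_class,
        n_removed,
        n_missing,
    )
    return aset.with_df(aset.df.loc[keep])


#: separators allowed inside printed digit groups (space, thin space, NBSP, comma)
_DIGIT_SEP = re.compile("[\\s\u2009\u00a0,]")
_LOCUS_RE = re.compile(
    "^\\s*(?P<chrom>[^:\\s]+)\\s*:\\s*(?P<start>[\\d\\s\u2009\u00a0,]+?)"
    "\\s*[\u2013\u2010\u2212\u2014-]\\s*(?P<end>[\\d\\s\u2009\u00a0,]+?)\\s*$"
)


def parse_locus_string(text: str) -> tuple[str, int, int]:
    """Parse a printed locus like ``"chr1:48 138 333–48 140 169"``.

    Digit-group separators are stripped; hyphen, en-dash and minus are all
    accepted as the range separator.  The returned interval is taken verbatim
    (no ±1 adjustment): for captions of this style ``end - start`` equals the
    printed length.
    """
    m = _LOCUS_RE.match(text)
    if not m:
        raise AnnotationError(f"unparseable locus string {text!r}")
    start = int(_DIGIT_SEP.sub("", m.group("start")))
    end = int(_DIGIT_SEP.sub("", m.group("end")))
    if end <= start:
        raise AnnotationError(f"locus {text!r}: end ≤ start")
    return m.group("chrom"), start, end
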