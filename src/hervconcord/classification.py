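"""Superfamily assignment via a family→superfamily mapping table.

Repeat databases name loci by family/subfamily (MER31B, HERVL-int, MLT1K...)
but do not state which ERV superfamily an LTR or internal portion belongs to.
A curated mapping table supplies that association: each family key maps to one
of five superfamilies (ERV1, ERV2, ERV3, Gypsy, Unclassified), a group, and a
role (LTR or internal).  Orphan types — internal portions without a known LTR
or vice versa — can be flagged ``ignored`` in the table and are then dropped
or labelled Unclassified, by policy.

Family-name matching is exact and case-sensitive after whitespace trimming;
"-int" suffixes are never auto-stripped, so the table must enumerate the LTR
and the internal name separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_io import SUPERFAMILIES, UNASSIGNED, AnnotationSet

logger = logging.getLogger(__name__)

VALID_ROLES = ("LTR", "internal")


class FamilyMapError(ValueError):
    """Malformed family-mapping table."""


@dataclass(frozen=True)
class FamilyMapEntry:
    family: str
    superfamily: str
    group: str
    role: str = "LTR"
    ignored: bool = False

    def __post_init__(self) -> None:
        if self.superfamily not in SUPERFAMILIES:
            raise FamilyMapError(
                f"family {self.family!r}: superfamily {self.superfamily!r} "
                f"not one of {SUPERFAMILIES}"
            )
        if not self.group:
            raise FamilyMapError(f"family {self.family!r}: empty group")
        if self.role not in VALID_ROLES:
            raise FamilyMapError(f"family {self.family!r}: role {self.role!r} invalid")


@dataclass
class ClassificationAudit:
    """Reconciliation of one classification run; counts always sum to input."""

    n_assigned: int = 0
    n_unmapped: int = 0
    n_ignored_orphans: int = 0
    unmapped_families: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n_assigned + self.n_unmapped + self.n_ignored_orphans


def load_family_map(path: str | Path) -> dict[str, FamilyMapEntry]:
    """Load a mapping TSV with columns family, superfamily, group, role and
    optionally ignored (0/1).  Duplicate family keys and unknown superfamily
    labels are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"family", "superfamily", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FamilyMapError(f"{path}: missing columns {sorted(missing)}")
    entries: dict[str, FamilyMapEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        fam = row.family.strip()
        if not fam:
            raise FamilyMapError(f"{path} line {i}: empty family key")
        if fam in entries:
            raise FamilyMapError(f"{path} line {i}: duplicate family key {fam!r}")
        entries[fam] = FamilyMapEntry(
            family=fam,
            superfamily=row.superfamily.strip(),
            group=row.group.strip(),
            role=(getattr(row, "role", "LTR") or "LTR").strip(),
            ignored=str(getattr(row, "ignored", "0")).strip() in ("1", "true", "True"),
        )
    return entries


def write_family_map(entries: Mapping[str, FamilyMapEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tsuperfamily\tgroup\trole\tignored\n")
        for fam in sorted(entries):
            e = entries[fam]
            fh.write(
                f"{e.family}\t{e.superfamily}\t{e.group}\t{e.role}\t{int(e.ignored)}\n"
            )


def assign_superfamilies(
    aset: AnnotationSet,
    family_map: Mapping[str, FamilyMapEntry],
    orphan_policy: str = "unclassified",
) -> tuple[AnnotationSet, ClassificationAudit]:
    """Set each record's superfamily from its (trimmed) family key.

    ``orphan_policy`` governs both families flagged ignored in the map and
    families absent from it: ``"unclassified"`` labels the records
    Unclassified, ``"drop"`` removes them.  The audit reconciles exactly:
    ``n_assigned + n_unmapped + n_ignored_orphans == len(aset)``.
    """
    if orphan_policy not in ("drop", "unclassified"):
        raise ValueError(f"unknown orphan_policy {orphan_policy!r}")
    df = aset.df.copy()
    fams = df["family"].str.strip()
    sup = fams.map(
        {f: e.superfamily for f, e in family_map.items() if not e.ignored}
    )
    ignored_keys = {f for f, e in family_map.items() if e.ignored}
    is_ignored = fams.isin(ignored_keys)
    is_unmapped = sup.isna() & ~is_ignored

    audit = ClassificationAudit(
        n_assigned=int(sup.notna().sum()),
        n_unmapped=int(is_unmapped.sum()),
        n_ignored_orphans=int(is_ignored.sum()),
        unmapped_families=sorted(fams[is_unmapped].unique()),
    )
    assert audit.total == len(aset)

    df["superfamily"] = sup.fillna("Unclassified")
    if orphan_policy == "drop":
        df = df.loc[~(is_unmapped | is_ignored)]
    if audit.n_unmapped:
        logger.info(
            "%s: %d records from %d families had no map entry (policy=%s)",
            aset.source_name,
            audit.n_unmapped,
            len(audit.unmapped_families),
            orphan_policy,
        )
    return aset.with_df(df), audit
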