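"""Stockholm domain alignments and meta-position numbering.

A domain family's alignment places structurally equivalent residues from many
paralogous proteins into shared columns.  Match columns are numbered 1..L with
deletions skipped; inserted residues take an incremental suffix from the
preceding match column (analogous to intron offsets in cDNA nomenclature, e.g.
``12+1`` is the first insertion after match column 12; insertions before the
first match column attach to pseudo-column 0).  Two residues in different
proteins that share a (family, column) label occupy the same *meta-position*.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(r"^(?P<protein>\S+)/(?P<start>\d+)-(?P<end>\d+)$")

MAPPING_COLUMNS = ["protein_id", "residue_index", "family_id", "column_label", "is_insertion"]


@dataclass(frozen=True)
class MetaPosition:
    """A (family, aligned-column) identity shared across paralogous domains."""

    family_id: str
    match_label: int
    insert_offset: int = 0  # 0 = match column, j >= 1 = j-th insertion after it

    @property
    def is_insertion(self) -> bool:
        return self.insert_offset > 0

    @property
    def column_label(self) -> str:
        if self.insert_offset:
            return f"{self.match_label}+{self.insert_offset}"
        return str(self.match_label)


@dataclass
class AlignmentMember:
    protein_id: str
    domain_start: int  # first residue of the domain, 1-based protein coords
    domain_end: int
    aligned: str  # uppercase residues, lowercase/'.' insertions, '-' deletions

    @property
    def residues(self) -> str:
        """Residues actually present in this member, in domain order."""
        return "".join(c for c in self.aligned if c.isalpha()).upper()


@dataclass
class DomainAlignment:
    family_id: str
    members: list[AlignmentMember] = field(default_factory=list)

    @property
    def n_match_columns(self) -> int:
        if not self.members:
            return 0
        return sum(1 for c in self.members[0].aligned if c == "-" or c.isupper())

    def validate(self) -> None:
        if not self.members:
            raise ValueError(f"{self.family_id}: alignment has no members")
        width = len(self.members[0].aligned)
        match_cols = None
        for m in self.members:
            if len(m.aligned) != width:
                raise ValueError(
                    f"{self.family_id}: member {m.protein_id}/{m.domain_start}-"
                    f"{m.domain_end} has aligned length {len(m.aligned)} != {width}"
                )
            n_res = sum(1 for c in m.aligned if c.isalpha())
            if n_res != m.domain_end - m.domain_start + 1:
                raise ValueError(
                    f"{self.family_id}: member {m.protein_id}/{m.domain_start}-"
                    f"{m.domain_end} has {n_res} residues, expected "
                    f"{m.domain_end - m.domain_start + 1}"
                )
            cols = tuple(i for i, c in enumerate(m.aligned) if c == "-" or c.isupper())
            if match_cols is None:
                match_cols = cols
            elif cols != match_cols:
                raise ValueError(
                    f"{self.family_id}: member {m.protein_id} disagrees on "
                    "match/insert column structure"
                )


def number_columns(aligned: str, family_id: str = "") -> list[MetaPosition]:
    """Assign a meta-position label to every residue of one aligned sequence.

    Returns one label per residue (deletions consume a match label but emit no
    residue).  Labels are independent of which member they came from, so all
    members of a consistent alignment share the same label universe.
    """
    labels: list[MetaPosition] = []
    match = 0
    insert = 0
    for c in aligned:
        if c == "-":
            match += 1
            insert = 0
        elif c.isupper():
            match += 1
            insert = 0
            labels.append(MetaPosition(family_id, match, 0))
        elif c == "." :
            continue
        elif c.islower():
            insert += 1
            labels.append(MetaPosition(family_id, match, insert))
        else:
            raise ValueError(f"invalid alignment symbol {c!r}")
    return labels


def _block_family_id(block: str, index: int) -> str:
    for tag in ("AC", "ID"):
        m = re.search(rf"^#=GF\s+{tag}\s+(\S+)", block, re.MULTILINE)
        if m:
            return m.group(1)
    return f"ALN{index + 1}"


def parse_stockholm(text: str) -> list[DomainAlignment]:
    """Parse a Stockholm 1.0 document into domain alignments.

    One :class:`DomainAlignment` per alignment block; member coordinates are
    taken from the PFam-style ``protein/start-end`` sequence names.  Ragged
    rows and missing ``//`` terminators are rejected naming the offender.

    The reader deliberately preserves sequence symbols byte-for-byte: the
    lowercase/'.'-versus-uppercase/'-' distinction encodes the match/insert
    state that column numbering is built on, and general-purpose alignment
    readers normalise it away.  Interleaved (wrapped) blocks are supported;
    per-sequence and per-column annotation lines (``#=GS``/``#=GR``/``#=GC``)
    are ignored.
    """
    if "# STOCKHOLM" not in text:
        raise ValueError("not a Stockholm document (missing '# STOCKHOLM 1.0' header)")
    if not re.search(r"^//\s*$", text, flags=re.MULTILINE):
        raise ValueError("Stockholm document missing '//' terminator")
    alignments: list[DomainAlignment] = []
    for idx, block in enumerate(re.split(r"^//\s*$", text, flags=re.MULTILINE)):
        if not block.strip():
            continue
        family_id = _block_family_id(block, idx)
        rows: dict[str, str] = {}
        order: list[str] = []
        for line in block.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"{family_id}: malformed sequence line {line!r}")
            name, seq = parts
            if name not in rows:
                rows[name] = ""
                order.append(name)
            rows[name] += seq.replace(" ", "")
        if not rows:
            continue
        aln = DomainAlignment(family_id=family_id)
        width = len(rows[order[0]])
        for name in order:
            if len(rows[name]) != width:
                raise ValueError(
                    f"{family_id}: row {name!r} has aligned length {len(rows[name])}, "
                    f"expected {width}")
            m = _NAME_RE.match(name)
            if not m:
                raise ValueError(
                    f"{family_id}: sequence name {name!r} is not of the form "
                    "protein/start-end")
            aln.members.append(AlignmentMember(
                protein_id=m.group("protein"),
                domain_start=int(m.group("start")),
                domain_end=int(m.group("end")),
                aligned=rows[name],
            ))
        aln.validate()
        alignments.append(aln)
    return alignments


def read_stockholm(path) -> list[DomainAlignment]:
    with open(path) as fh:
        return parse_stockholm(fh.read())


def map_residues(
    alignments: list[DomainAlignment],
    proteins: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Map every aligned residue to its protein coordinate and meta-position.

    Residue index = domain_start + ordinal within the domain − 1.  When
    ``proteins`` is supplied, members whose aligned letters disagree with the
    protein sequence are skipped with a logged warning (the alignment and the
    transcript set then describe different isoforms).  Multiple instances of a
    family in one protein are separate members and all contribute.
    """
    rows = []
    for aln in alignments:
        aln.validate()
        for midx, member in enumerate(aln.members):
            labels = number_columns(member.aligned, aln.family_id)
            residues = member.residues
            if proteins is not None:
                seq = proteins.get(member.protein_id)
                if seq is None:
                    logger.warning(
                        "%s: protein %s not in protein set; member skipped",
                        aln.family_id, member.protein_id)
                    continue
                segment = seq[member.domain_start - 1: member.domain_end]
                if segment != residues:
                    logger.warning(
                        "%s: member %s/%d-%d letters disagree with protein sequence; "
                        "member skipped", aln.family_id, member.protein_id,
                        member.domain_start, member.domain_end)
                    continue
            for ordinal, mp in enumerate(labels):
                rows.append((
                    member.protein_id,
                    member.domain_start + ordinal,
                    aln.family_id,
                    mp.column_label,
                    mp.is_insertion,
                ))
    return pd.DataFrame(rows, columns=MAPPING_COLUMNS)


def write_mapping(mapping: pd.DataFrame, path) -> None:
    mapping.to_csv(path, sep="\t", index=False)


def read_mapping(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"column_label": str})
    df["is_insertion"] = df["is_insertion"].astype(bool)
    return df
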