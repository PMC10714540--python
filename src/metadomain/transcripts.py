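"""Transcript models, codon-to-genome maps and exhaustive coding-SNV enumeration.

Every protein-coding position can mutate to three alternative nucleotides, so a
codon carries exactly nine possible single-nucleotide variants (SNVs).  This
module builds the coordinate backbone that the rest of the pipeline relies on:
it maps each protein residue to the genomic coordinates of its codon (codons
may span exon/exon junctions), translates coding sequence, and enumerates the
full 9-per-codon SNV universe with missense/synonymous/nonsense consequence
calls.

All genomic coordinates are 1-based and inclusive, matching the VCF/Ensembl
convention of the input files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, stop codons as '*'; standard genetic code.
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in _TABLE.stop_codons})

BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Columns of the simulated-variant table emitted by :func:`enumerate_snvs`.
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene_id", "transcript_id", "protein_id",
    "residue_index", "codon_position", "ref_aa", "alt_aa", "consequence",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Stop codons yield ``'*'``.  Raises :class:`ValueError` naming the first
    offending position for non-ACGT characters or a length not divisible by 3.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    for i, base in enumerate(cds):
        if base not in BASES:
            raise ValueError(f"non-ACGT character {base!r} at CDS position {i + 1}")
    return "".join(GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds), 3))


@dataclass
class TranscriptModel:
    """A protein-coding transcript with stranded exon intervals.

    ``exons`` are (start, end) genomic intervals, 1-based inclusive, ordered by
    transcription (rank) order — i.e. descending genomic coordinates on the
    minus strand.  ``cds_sequence`` is the coding-strand sequence, optionally
    including the terminal stop codon.
    """

    gene_id: str
    transcript_id: str
    protein_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str
    protein_sequence: str

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        exon_len = sum(end - start + 1 for start, end in self.exons)
        if exon_len != len(self.cds_sequence):
            raise ValueError(
                f"{self.transcript_id}: exon length {exon_len} != CDS length "
                f"{len(self.cds_sequence)}"
            )
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        ranked = self.exons if self.strand == "+" else self.exons[::-1]
        if ranked != spans:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcription order for "
                f"strand {self.strand}"
            )
        prot = translate(self.cds_sequence)
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            raise ValueError(f"{self.transcript_id}: internal stop codon")
        if prot != self.protein_sequence:
            raise ValueError(
                f"{self.transcript_id}: translated CDS does not match protein sequence"
            )


@dataclass
class CodonMap:
    """Genomic coordinates of every codon of a transcript, in reading order.

    ``codons[i]`` holds the three genomic coordinates of residue ``i + 1``
    (1-based residue indices); coordinates ascend on the plus strand and
    descend on the minus strand.  ``stop_codon`` carries the terminal stop
    codon's coordinates when the CDS includes it.
    """

    gene_id: str
    transcript_id: str
    protein_id: str
    chrom: str
    strand: str
    codons: list[tuple[int, int, int]]
    stop_codon: tuple[int, int, int] | None = None

    def __len__(self) -> int:
        return len(self.codons)


def _walk_exons(exons: Sequence[tuple[int, int]], strand: str) -> list[int]:
    coords: list[int] = []
    for start, end in exons:
        if strand == "+":
            coords.extend(range(start, end + 1))
        else:
            coords.extend(range(end, start - 1, -1))
    return coords


def build_codon_map(transcript: TranscriptModel) -> CodonMap:
    """Project CDS positions through the exons onto genomic coordinates.

    Residue ``i`` occupies CDS positions ``3i-2, 3i-1, 3i``; codons freely
    straddle exon junctions.
    """
    transcript.validate()
    coords = _walk_exons(transcript.exons, transcript.strand)
    n_res = len(transcript.protein_sequence)
    codons = [tuple(coords[3 * i: 3 * i + 3]) for i in range(n_res)]
    stop = None
    if len(transcript.cds_sequence) == 3 * (n_res + 1):
        stop = tuple(coords[3 * n_res: 3 * n_res + 3])
    return CodonMap(
        gene_id=transcript.gene_id,
        transcript_id=transcript.transcript_id,
        protein_id=transcript.protein_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        codons=codons,
        stop_codon=stop,
    )


def codon_consequence(ref_aa: str, alt_aa: str) -> str:
    """Consequence of an amino-acid change from a single-nucleotide change.

    Changes at the reference stop codon (stop retention or stop loss) fall
    outside the missense/synonymous/nonsense trichotomy and are labelled
    ``other``; downstream analyses exclude them.
    """
    if ref_aa == "*":
        return "other"
    if alt_aa == "*":
        return "nonsense"
    if alt_aa == ref_aa:
        return "synonymous"
    return "missense"


def enumerate_snvs(codon_map: CodonMap, cds: str, include_stop_codon: bool = False) -> pd.DataFrame:
    """Enumerate the three possible nucleotide changes at every codon position.

    Returns a table of exactly nine variants per codon with amino-acid
    consequences computed on the coding strand.  On the minus strand, ``ref``
    and ``alt`` are reported as genome plus-strand bases while consequences are
    computed on the coding strand.
    """
    cds = cds.upper()
    n_codons = len(codon_map)
    if len(cds) < 3 * n_codons:
        raise ValueError("CDS shorter than codon map")
    minus = codon_map.strand == "-"
    codon_list = list(codon_map.codons)
    if include_stop_codon and codon_map.stop_codon is not None:
        codon_list.append(codon_map.stop_codon)
    rows: list[tuple] = []
    for i, coords in enumerate(codon_list):
        codon = cds[3 * i: 3 * i + 3]
        ref_aa = GENETIC_CODE[codon]
        for j in range(3):
            ref_base = codon[j]
            for alt_base in BASES:
                if alt_base == ref_base:
                    continue
                alt_codon = codon[:j] + alt_base + codon[j + 1:]
                alt_aa = GENETIC_CODE[alt_codon]
                if minus:
                    g_ref = ref_base.translate(_COMPLEMENT)
                    g_alt = alt_base.translate(_COMPLEMENT)
                else:
                    g_ref, g_alt = ref_base, alt_base
                rows.append((
                    codon_map.chrom, coords[j], g_ref, g_alt,
                    codon_map.gene_id, codon_map.transcript_id, codon_map.protein_id,
                    i + 1, j + 1, ref_aa, alt_aa,
                    codon_consequence(ref_aa, alt_aa),
                ))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_exon_table(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated exon table (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "transcript_id", "protein_id", "chrom", "strand",
                "exon_start", "exon_end", "exon_rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"exon table missing columns: {sorted(missing)}")
    return df


def load_transcripts(
    exon_table: pd.DataFrame | str | Path,
    genome_fasta: str | Path | dict,
    proteins_fasta: str | Path | dict | None = None,
) -> list[TranscriptModel]:
    """Assemble transcript models from an exon table and a genome FASTA.

    The CDS is stitched from exon slices in transcription order (exon slices
    are reverse-complemented on the minus strand).  When ``proteins_fasta`` is
    given, transcripts whose translation does not exactly match the supplied
    protein sequence are skipped with a logged warning; transcripts violating
    structural invariants are likewise skipped, never fatal.  Either FASTA
    argument may also be a preloaded ``{name: sequence}`` dict.
    """
    if not isinstance(exon_table, pd.DataFrame):
        exon_table = read_exon_table(exon_table)
    if isinstance(genome_fasta, dict):
        genome = {k: v.upper() for k, v in genome_fasta.items()}
    else:
        genome = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    if proteins_fasta is None:
        proteins = None
    elif isinstance(proteins_fasta, dict):
        proteins = proteins_fasta
    else:
        proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(proteins_fasta), "fasta")}

    transcripts: list[TranscriptModel] = []
    for tid, grp in exon_table.groupby("transcript_id", sort=False):
        grp = grp.sort_values("exon_rank")
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        if chrom not in genome:
            logger.warning("transcript %s: chromosome %s absent from FASTA; skipped", tid, chrom)
            continue
        seq = genome[chrom]
        pieces = []
        exons = []
        for _, row in grp.iterrows():
            start, end = int(row["exon_start"]), int(row["exon_end"])
            exons.append((start, end))
            piece = seq[start - 1: end]
            pieces.append(reverse_complement(piece) if strand == "-" else piece)
        cds = "".join(pieces)
        try:
            prot = translate(cds)
        except ValueError as exc:
            logger.warning("transcript %s: %s; skipped", tid, exc)
            continue
        if prot.endswith("*"):
            prot = prot[:-1]
        pid = grp["protein_id"].iloc[0]
        if proteins is not None:
            expected = proteins.get(pid)
            if expected is None or expected != prot:
                logger.warning(
                    "transcript %s: protein sequence mismatch for %s; skipped", tid, pid
                )
                continue
        model = TranscriptModel(
            gene_id=grp["gene_id"].iloc[0],
            transcript_id=str(tid),
            protein_id=pid,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_sequence=cds,
            protein_sequence=prot,
        )
        try:
            model.validate()
        except ValueError as exc:
            logger.warning("transcript %s failed validation: %s; skipped", tid, exc)
            continue
        transcripts.append(model)
    return transcripts


def simulate_all_snvs(transcripts: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Exhaustive SNV universe over a set of transcripts (nine per codon)."""
    frames = []
    for t in transcripts:
        cmap = build_codon_map(t)
        frames.append(enumerate_snvs(cmap, t.cds_sequence))
    if not frames:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
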