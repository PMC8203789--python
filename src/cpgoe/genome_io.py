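"""Genome FASTA / GFF3 input, CDS extraction and assembly contiguity statistics.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive on
both ends.  Sequences are stored as plain uppercase strings over the IUPAC
nucleotide alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: letters accepted in input sequences: the four bases, N, and the IUPAC
#: two/three-base ambiguity codes.
IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class GenomeIOError(ValueError):
    """Malformed FASTA/GFF3 input or inconsistent annotation."""


@dataclass(frozen=True)
class TranscriptModel:
    """CDS structure of one transcript: ordered 1-based inclusive segments."""

    transcript_id: str
    gene_id: str
    seq_id: str
    strand: str  # "+" or "-"
    cds_segments: tuple[tuple[int, int, int], ...]  # (start, end, phase)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        prev_end = 0
        for start, end, phase in self.cds_segments:
            if start > end:
                raise GenomeIOError(
                    f"transcript {self.transcript_id}: segment start {start} > end {end}"
                )
            if start <= prev_end:
                raise GenomeIOError(
                    f"transcript {self.transcript_id}: overlapping/unsorted CDS segments"
                )
            if phase not in (0, 1, 2):
                raise GenomeIOError(
                    f"transcript {self.transcript_id}: bad phase {phase}"
                )
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end, _ in self.cds_segments)


@dataclass(frozen=True)
class CdsRecord:
    """Spliced coding sequence of one gene's chosen transcript."""

    gene_id: str
    transcript_id: str
    nt_seq: str
    aa_seq: str
    internal_stop: bool = False
    trailing_remainder: bool = False

    @property
    def length_nt(self) -> int:
        return len(self.nt_seq)


@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_length_nt: int
    nx: dict[float, int] = field(default_factory=dict)
    lx: dict[float, int] = field(default_factory=dict)

    def to_rows(self) -> list[tuple[str, float]]:
        rows: list[tuple[str, float]] = [
            ("n_scaffolds", self.n_scaffolds),
            ("total_length_nt", self.total_length_nt),
        ]
        for f in sorted(self.nx):
            pct = int(round(100 * f))
            rows.append((f"N{pct}", self.nx[f]))
            rows.append((f"L{pct}", self.lx[f]))
        return rows


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping.

    Ids are the header token before the first whitespace.  Duplicate ids,
    empty records and non-IUPAC letters are rejected.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise GenomeIOError(f"duplicate id '{rec.id}' in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeIOError(f"empty sequence for record '{rec.id}' in {path}")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise GenomeIOError(
                f"record '{rec.id}': non-IUPAC character(s) {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> dict[str, list[TranscriptModel]]:
    """Parse gene/mRNA/CDS rows of a GFF3 file, grouped by gene id.

    Only CDS features are retained per transcript, sorted by ascending
    start.  CDS rows whose Parent transcript is unknown are skipped with a
    warning; transcripts without any CDS are dropped (count logged).
    """
    path = Path(path)
    _validate_gff3_columns(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    known_transcripts: dict[str, gffutils.Feature] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            known_transcripts[feat.id] = feat

    cds_by_tx: dict[str, list[gffutils.Feature]] = {}
    n_orphan = 0
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents:
            logger.warning("CDS row without Parent skipped (%s)", cds.id)
            n_orphan += 1
            continue
        for parent in parents:
            if parent not in known_transcripts:
                logger.warning("CDS with unknown Parent '%s' skipped", parent)
                n_orphan += 1
                continue
            cds_by_tx.setdefault(parent, []).append(cds)

    genes: dict[str, list[TranscriptModel]] = {}
    n_no_cds = 0
    for tx_id, feat in known_transcripts.items():
        segs = cds_by_tx.get(tx_id)
        if not segs:
            n_no_cds += 1
            continue
        seq_ids = {c.seqid for c in segs}
        strands = {c.strand for c in segs}
        if len(seq_ids) > 1 or len(strands) > 1:
            raise GenomeIOError(
                f"transcript {tx_id}: CDS segments span multiple scaffolds/strands"
            )
        gene_parents = feat.attributes.get("Parent", [tx_id])
        gene_id = gene_parents[0]
        segments = tuple(
            sorted(
                (
                    (c.start, c.end, int(c.frame) if c.frame in "012" else 0)
                    for c in segs
                ),
            )
        )
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            seq_id=seq_ids.pop(),
            strand=strands.pop(),
            cds_segments=segments,
        )
        genes.setdefault(gene_id, []).append(model)
    if n_no_cds:
        logger.info("dropped %d transcript(s) lacking CDS features", n_no_cds)
    if n_orphan:
        logger.info("skipped %d CDS row(s) with unknown Parent", n_orphan)
    for models in genes.values():
        models.sort(key=lambda m: m.transcript_id)
    return genes


def _validate_gff3_columns(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GenomeIOError(
                    f"{path}:{lineno}: expected 9 tab-separated columns"
                )


# ---------------------------------------------------------------------------
# CDS extraction & translation

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_transcript_cds(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced coding sequence of one transcript (strand aware)."""
    try:
        scaffold = genome[model.seq_id]
    except KeyError:
        raise GenomeIOError(
            f"transcript {model.transcript_id}: scaffold '{model.seq_id}' not in genome"
        ) from None
    for start, end, _ in model.cds_segments:
        if start < 1 or end > len(scaffold):
            raise GenomeIOError(
                f"transcript {model.transcript_id}: segment ({start},{end}) outside "
                f"scaffold '{model.seq_id}' (length {len(scaffold)})"
            )
    parts = [scaffold[start - 1 : end] for start, end, _ in model.cds_segments]
    plus = "".join(parts)
    if model.strand == "+":
        return plus
    return _revcomp(plus)


def extract_longest_cds(
    genes: Mapping[str, Sequence[TranscriptModel]], genome: Mapping[str, str]
) -> dict[str, CdsRecord]:
    """Pick the longest-CDS transcript per gene and return its spliced CDS.

    Ties on CDS length are broken by lexicographically smallest
    transcript_id, so output is deterministic.  The phase column is not used
    for extraction; a non-zero first phase is logged.
    """
    out: dict[str, CdsRecord] = {}
    for gene_id, models in genes.items():
        best = min(models, key=lambda m: (-m.cds_length, m.transcript_id))
        first_phase = (
            best.cds_segments[0][2] if best.strand == "+" else best.cds_segments[-1][2]
        )
        if first_phase != 0:
            logger.warning(
                "transcript %s: non-zero first phase %d ignored for extraction",
                best.transcript_id,
                first_phase,
            )
        nt = extract_transcript_cds(best, genome)
        aa, internal_stop, remainder = translate_cds(nt)
        out[gene_id] = CdsRecord(
            gene_id=gene_id,
            transcript_id=best.transcript_id,
            nt_seq=nt,
            aa_seq=aa,
            internal_stop=internal_stop,
            trailing_remainder=remainder,
        )
    return out


def translate_cds(nt: str) -> tuple[str, bool, bool]:
    """Translate in frame 0 under the standard genetic code.

    Returns (aa_seq, internal_stop_flag, trailing_remainder_flag).  A
    trailing stop is stripped; internal stops are rendered '*'; codons with
    N/ambiguity letters become 'X'; a trailing 1-2 nt remainder is dropped.
    """
    if len(nt) < 3:
        raise GenomeIOError("coding sequence shorter than one codon")
    nt = nt.upper()
    remainder = len(nt) % 3 != 0
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if set(codon) <= set("ACGT"):
            if codon in _STANDARD_TABLE.stop_codons:
                aas.append("*")
            else:
                aas.append(_STANDARD_TABLE.forward_table[codon])
        else:
            aas.append("X")
    if aas and aas[-1] == "*":
        aas.pop()
    internal_stop = "*" in aas
    return "".join(aas), internal_stop, remainder


# ---------------------------------------------------------------------------
# Assembly statistics

def assembly_stats(
    lengths: Iterable[int], fractions: Iterable[float] = (0.5, 0.9)
) -> AssemblyStats:
    """Nx/Lx contiguity statistics of a scaffold length list.

    Nx is the length of the scaffold at which the cumulative sum of
    descending-sorted lengths first reaches x% of the total; Lx is its
    1-based rank.
    """
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if arr.size == 0:
        raise GenomeIOError("empty scaffold length list")
    if (arr <= 0).any():
        raise GenomeIOError("scaffold lengths must be positive")
    total = int(arr.sum())
    cum = np.cumsum(arr)
    stats = AssemblyStats(n_scaffolds=int(arr.size), total_length_nt=total)
    for f in fractions:
        if not 0 < f <= 1:
            raise GenomeIOError(f"fraction {f} outside (0, 1]")
        idx = int(np.searchsorted(cum, f * total))
        stats.nx[f] = int(arr[idx])
        stats.lx[f] = idx + 1
    return stats
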