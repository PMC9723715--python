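"""Contig, evidence and read-count input/output.

Contigs live in one of two compartments of the same faecal sample set: the
virome (``VP``, sequenced from purified viral particles) and the microbiome
(``P``, bulk community DNA).  Everything downstream — the triage cascade, the
abundance matrices, the activity partition and the ARG census — consumes the
record types defined here.

Coordinates are 0-based, half-open throughout.  ORFs on the ``-`` strand are
reported in forward-strand coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("virotriage")

__all__ = [
    "Compartment",
    "EvidenceSource",
    "SubjectType",
    "ContigRecord",
    "EvidenceRecord",
    "CountTable",
    "OrfTable",
    "read_contigs",
    "write_contigs",
    "call_orfs",
    "detect_circularity",
    "read_table",
    "read_counts",
    "write_evidence",
    "write_counts",
]


class Compartment(str, Enum):
    VIROME = "VIROME"
    MICROBIOME = "MICROBIOME"


class EvidenceSource(str, Enum):
    """Origin of an externally derived observation about a contig.

    SORTER/SECONDARY are viral-sorter verdicts (e.g. a VirSorter-style
    category, or a VIBRANT-style call used as the fallback stage);
    NUCL_HOMOLOGY is a nucleotide database hit; PROT_PROFILE a phage protein
    profile (PHROG-style) hit on one ORF; TAXON a taxonomic affiliation;
    the ARG_* sources are the three tiers of resistance-gene detection.
    """

    SORTER = "SORTER"
    INOVIRUS = "INOVIRUS"
    NUCL_HOMOLOGY = "NUCL_HOMOLOGY"
    PROT_PROFILE = "PROT_PROFILE"
    SECONDARY = "SECONDARY"
    TAXON = "TAXON"
    ARG_PROFILE = "ARG_PROFILE"
    ARG_HOMOLOGY = "ARG_HOMOLOGY"
    ARG_CONFIRMED = "ARG_CONFIRMED"


class SubjectType(str, Enum):
    PHAGE = "PHAGE"
    EUK_VIRUS = "EUK_VIRUS"
    BACTERIAL = "BACTERIAL"
    PLASMID = "PLASMID"
    NA = "NA"


@dataclass
class ContigRecord:
    """One assembled contig with its compartment tag."""

    contig_id: str
    sample_id: str
    compartment: Compartment
    length_nt: int
    circular: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError(f"{self.contig_id}: length_nt must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length_nt:
            raise ValueError(
                f"{self.contig_id}: sequence length {len(self.sequence)} "
                f"!= length_nt {self.length_nt}"
            )


@dataclass
class EvidenceRecord:
    """One externally derived observation about a contig."""

    contig_id: str
    source: EvidenceSource
    category: str
    subject_type: SubjectType = SubjectType.NA
    e_value: float | None = None
    gene_index: int | None = None

    def __post_init__(self) -> None:
        if self.e_value is not None and self.e_value < 0:
            raise ValueError(f"{self.contig_id}: e_value must be >= 0")


@dataclass
class CountTable:
    """Mapped-read counts r per (contig, sample) plus per-sample totals M.

    Sample totals may exceed the per-contig column sums: reads mapping to
    contigs below the length filter still count toward M.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    sample_totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, r in self.counts.items():
            if r < 0:
                raise ValueError(f"negative read count for {key}")
        for sid, m in self.sample_totals.items():
            if m < 1:
                raise ValueError(f"sample total for {sid} must be >= 1")

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_totals)

    def contig_reads(self, contig_id: str) -> int:
        """Total mapped reads for one contig across all samples."""
        return sum(r for (cid, _sid), r in self.counts.items() if cid == contig_id)

    def to_frame(self) -> pd.DataFrame:
        """Wide contigs x samples integer matrix (missing pairs are 0)."""
        if not self.counts:
            return pd.DataFrame(columns=self.samples)
        ser = pd.Series(self.counts)
        ser.index.names = ["contig_id", "sample_id"]
        wide = ser.unstack(fill_value=0)
        return wide.reindex(columns=self.samples, fill_value=0)


@dataclass
class OrfTable:
    """ORFs of one contig as (start, end, strand) in forward coordinates."""

    contig_id: str
    orfs: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_orfs(self) -> int:
        return len(self.orfs)


# ---------------------------------------------------------------------------
# FASTA


def read_contigs(
    path: str | Path,
    compartment: Compartment,
    min_len: int = 2000,
    sample_id: str = "",
) -> list[ContigRecord]:
    """Read contigs from FASTA, keeping those strictly longer than ``min_len``.

    The filter is a strict inequality (a 2000-nt contig does not pass the
    default 2-kb filter); file order is preserved.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise ValueError(f"{path}: malformed FASTA (does not start with '>')")
    out: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig_id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has empty sequence")
        if len(seq) > min_len:
            out.append(
                ContigRecord(
                    contig_id=rec.id,
                    sample_id=sample_id,
                    compartment=compartment,
                    length_nt=len(seq),
                    sequence=seq,
                )
            )
    return out


def write_contigs(contigs: Iterable[ContigRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            if c.sequence is None:
                raise ValueError(f"{c.contig_id}: cannot write contig without sequence")
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ORF calling and circularity

_STOPS = frozenset({"TAA", "TAG", "TGA"})
_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base-4 codon ids over A=0 C=1 G=2 T=3; codons touching non-ACGT map to 64
_BASE_CODE = np.full(256, 4, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_ATG_ID = 0 * 16 + 3 * 4 + 2
_STOP_IDS = np.array([3 * 16 + 0 * 4 + 0, 3 * 16 + 0 * 4 + 2, 3 * 16 + 2 * 4 + 0])  # TAA TAG TGA


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_ids(seq_bytes: np.ndarray, frame: int) -> np.ndarray:
    n = (seq_bytes.size - frame) // 3
    if n <= 0:
        return np.empty(0, dtype=np.int16)
    b = _BASE_CODE[seq_bytes[frame : frame + 3 * n]].reshape(n, 3)
    ids = b[:, 0] * 16 + b[:, 1] * 4 + b[:, 2]
    ids[(b >= 4).any(axis=1)] = 64  # codons with non-ACGT never match
    return ids


def _scan_frame(seq_bytes: np.ndarray, frame: int, min_orf_nt: int) -> list[tuple[int, int]]:
    """Maximal ATG-to-stop ORFs in one forward frame; span includes the stop.

    An ORF runs from the first ATG after the previous in-frame stop to the
    next stop codon.
    """
    ids = _codon_ids(seq_bytes, frame)
    stops = np.flatnonzero(np.isin(ids, _STOP_IDS))
    atgs = np.flatnonzero(ids == _ATG_ID)
    orfs: list[tuple[int, int]] = []
    prev_end = 0  # codon index just past the previous stop
    for s in stops:
        j = int(np.searchsorted(atgs, prev_end))
        if j < atgs.size and atgs[j] < s:
            start_nt = frame + 3 * int(atgs[j])
            end_nt = frame + 3 * (int(s) + 1)
            if end_nt - start_nt >= min_orf_nt:
                orfs.append((start_nt, end_nt))
        prev_end = int(s) + 1
    return orfs


def call_orfs(contig: ContigRecord, min_orf_nt: int = 150) -> OrfTable:
    """All maximal start-to-stop ORFs >= ``min_orf_nt`` on both strands.

    Standard genetic code, ATG starts only; an ORF runs from the first ATG
    after the previous in-frame stop to the next stop, stop codon included.
    Deterministic ordering by start coordinate, then strand ('+' first).
    Codons containing non-ACGT characters are ignored (flagged via a warning).
    """
    if contig.sequence is None:
        raise ValueError(f"{contig.contig_id}: sequence absent, cannot call ORFs")
    if min_orf_nt % 3 != 0 or min_orf_nt < 60:
        raise ValueError("min_orf_nt must be a multiple of 3 and >= 60")
    seq = contig.sequence.upper()
    if not set(seq) <= _ACGT:
        warnings.warn(
            f"{contig.contig_id}: non-ACGT characters present; "
            "codons containing them are treated as non-coding",
            stacklevel=2,
        )
    n = len(seq)
    orfs: list[tuple[int, int, str]] = []
    fwd = np.frombuffer(seq.encode(), dtype=np.uint8)
    for frame in range(3):
        for s, e in _scan_frame(fwd, frame, min_orf_nt):
            orfs.append((s, e, "+"))
    rc = np.frombuffer(_revcomp(seq).encode(), dtype=np.uint8)
    for frame in range(3):
        for s, e in _scan_frame(rc, frame, min_orf_nt):
            orfs.append((n - e, n - s, "-"))
    orfs.sort(key=lambda t: (t[0], 0 if t[2] == "+" else 1, t[1]))
    return OrfTable(contig_id=contig.contig_id, orfs=orfs)


def detect_circularity(contig: ContigRecord, k: int = 20) -> bool:
    """True iff the first k nt equal the last k nt exactly.

    Terminal-direct-repeat convention: assemblers leave the overlap of a
    circular molecule duplicated at both contig ends.
    """
    if contig.sequence is None:
        raise ValueError(f"{contig.contig_id}: sequence absent")
    if not (10 <= k <= contig.length_nt // 2):
        raise ValueError(f"k must satisfy 10 <= k <= length/2, got {k}")
    seq = contig.sequence.upper()
    return seq[:k] == seq[-k:]


# ---------------------------------------------------------------------------
# TSV tables

EVIDENCE_COLUMNS = ["contig_id", "source", "category", "subject_type", "e_value", "gene_index"]
COUNTS_COLUMNS = ["contig_id", "sample_id", "reads"]
TOTALS_COLUMNS = ["sample_id", "total_reads"]

_SCHEMAS = {"evidence": EVIDENCE_COLUMNS, "counts": COUNTS_COLUMNS, "totals": TOTALS_COLUMNS}


def _read_tsv(path: str | Path, schema: str) -> pd.DataFrame:
    wanted = _SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    extra = [c for c in df.columns if c not in wanted]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, ", ".join(extra))
    return df[wanted]


def read_table(path: str | Path, schema: str):
    """Read a typed TSV table.

    schema='evidence' returns ``list[EvidenceRecord]``; schema='counts'
    returns a ``CountTable`` with empty sample totals (combine with a totals
    file via :func:`read_counts`); schema='totals' returns a dict.
    '#'-prefixed comment lines are allowed; unknown columns are ignored with
    a logged warning.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = _read_tsv(path, schema)
    if schema == "evidence":
        records: list[EvidenceRecord] = []
        for line_no, row in enumerate(df.itertuples(index=False), start=2):
            e_raw = row.e_value
            if e_raw in ("", "NA"):
                e_val = None
            else:
                try:
                    e_val = float(e_raw)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric e_value {e_raw!r} on line {line_no}"
                    ) from None
            g_raw = row.gene_index
            gene = None if g_raw in ("", "NA") else int(g_raw)
            records.append(
                EvidenceRecord(
                    contig_id=row.contig_id,
                    source=EvidenceSource(row.source),
                    category=row.category,
                    subject_type=SubjectType(row.subject_type or "NA"),
                    e_value=e_val,
                    gene_index=gene,
                )
            )
        return records
    if schema == "counts":
        counts: dict[tuple[str, str], int] = {}
        for line_no, row in enumerate(df.itertuples(index=False), start=2):
            r = int(row.reads)
            if r < 0:
                raise ValueError(f"{path}: negative read count on line {line_no}")
            counts[(row.contig_id, row.sample_id)] = counts.get((row.contig_id, row.sample_id), 0) + r
        return CountTable(counts=counts, sample_totals={})
    totals = {row.sample_id: int(row.total_reads) for row in df.itertuples(index=False)}
    return totals


def read_counts(counts_path: str | Path, totals_path: str | Path) -> CountTable:
    """Assemble a full CountTable from a counts TSV plus a totals TSV."""
    partial = read_table(counts_path, "counts")
    totals = read_table(totals_path, "totals")
    return CountTable(counts=partial.counts, sample_totals=totals)


def write_evidence(records: Sequence[EvidenceRecord], path: str | Path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for r in records:
            e = "NA" if r.e_value is None else repr(r.e_value)
            g = "NA" if r.gene_index is None else str(r.gene_index)
            fh.write(
                f"{r.contig_id}\t{r.source.value}\t{r.category}\t{r.subject_type.value}\t{e}\t{g}\n"
            )


def write_counts(table: CountTable, counts_path: str | Path, totals_path: str | Path,
                 header_comment: str = "") -> None:
    with open(counts_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for (cid, sid), r in sorted(table.counts.items()):
            fh.write(f"{cid}\t{sid}\t{r}\n")
    with open(totals_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(TOTALS_COLUMNS) + "\n")
        for sid, m in sorted(table.sample_totals.items()):
            fh.write(f"{sid}\t{m}\n")


def orf_counts_from_contigs(contigs: Iterable[ContigRecord], min_orf_nt: int = 150) -> dict[str, int]:
    """Convenience: per-contig ORF totals for the protein-profile rule."""
    return {c.contig_id: call_orfs(c, min_orf_nt).n_orfs for c in contigs}
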