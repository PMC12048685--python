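"""Sequence-level utilities for 5' UTR insert analysis.

Covers the sequence identities that reporter controls rely on
(reverse-complement "inverse" inserts preserve length and GC content),
upstream-AUG/uORF frame scanning against a downstream reporter start
codon, and interval arithmetic on transcript coordinates for probe and
amplicon targets.

Coordinate conventions: transcript intervals are 1-based inclusive (the
NCBI convention used for probe target descriptions); everything returned
by :func:`scan_uaugs` is 0-based offsets within the UTR string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "InsertRecord",
    "UAUG",
    "UAUGReport",
    "TranscriptInterval",
    "make_inverse",
    "scan_uaugs",
    "interval_nt_count",
    "read_inserts",
    "write_inserts",
    "load_probe_target",
]

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID = frozenset("ACGT")


def _normalize(sequence: str, *, what: str = "sequence") -> str:
    """Uppercase, U->T; reject anything outside {A,C,G,T,U} naming the position."""
    seq = sequence.upper().replace("U", "T")
    for i, base in enumerate(seq):
        if base not in _VALID:
            raise ValueError(
                f"invalid character {base!r} at position {i} in {what}"
            )
    return seq


@dataclass(frozen=True)
class InsertRecord:
    """A named 5' UTR insert with orientation and derived composition features."""

    name: str
    sequence: str
    orientation: str = "forward"  # "forward" | "inverse"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize(self.sequence, what=self.name))
        if self.orientation not in ("forward", "inverse"):
            raise ValueError(f"orientation must be forward|inverse, got {self.orientation!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        seq = self.sequence
        if not seq:
            return 0.0
        return (seq.count("G") + seq.count("C")) / len(seq)


def make_inverse(record: InsertRecord) -> InsertRecord:
    """Reverse-complement control insert.

    The inverse insert is the reverse complement of its forward partner with
    the orientation flag flipped. Length and GC fraction are invariant, which
    is exactly why inverse sequences serve as controls for activity effects
    that depend only on insert length and composition.
    """
    rc = str(Seq(record.sequence).reverse_complement())
    flipped = "inverse" if record.orientation == "forward" else "forward"
    return InsertRecord(name=record.name, sequence=rc, orientation=flipped)


@dataclass(frozen=True)
class UAUG:
    """One upstream AUG within a 5' UTR.

    ``frame`` is relative to the main ORF start immediately downstream of the
    UTR: 0 means in-frame with the main start codon. ``uorf`` is True when an
    in-frame stop codon lies fully within the UTR (a complete upstream ORF);
    otherwise the putative ORF overlaps the main start ("overlapping uORF").
    """

    offset: int           # 0-based position of the A of ATG in the UTR
    distance: int         # nt from the ATG to the main start codon
    frame: int            # distance mod 3; 0 = in-frame with main ORF
    uorf: bool            # in-frame stop entirely within the UTR
    stop_offset: int | None = None  # 0-based offset of that stop, if any


@dataclass
class UAUGReport:
    """All upstream AUGs of a UTR plus counts by reading frame."""

    utr_length: int
    uaugs: list[UAUG] = field(default_factory=list)

    @property
    def n_uaugs(self) -> int:
        return len(self.uaugs)

    @property
    def frame_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0, 2: 0}
        for u in self.uaugs:
            counts[u.frame] += 1
        return counts

    @property
    def n_in_frame(self) -> int:
        return self.frame_counts[0]

    @property
    def n_out_of_frame(self) -> int:
        return self.frame_counts[1] + self.frame_counts[2]

    @property
    def n_uorfs(self) -> int:
        return sum(1 for u in self.uaugs if u.uorf)


def scan_uaugs(utr: str, max_report: int | None = None) -> UAUGReport:
    """Scan a 5' UTR for upstream AUGs and classify each by frame and uORF status.

    The main start codon is defined to begin immediately after the last UTR
    base, so ``distance = len(utr) - offset`` and ``frame = distance % 3``.
    An in-frame AUG (frame 0) can contribute to translation from the main
    start; out-of-frame AUGs initiate conflicting reading frames. A uAUG is
    flagged as a uORF when the first in-frame stop codon (TAA/TAG/TGA) lies
    fully within the UTR.
    """
    seq = _normalize(utr, what="UTR")
    if not seq:
        raise ValueError("UTR must be non-empty")
    n = len(seq)
    found: list[UAUG] = []
    for offset in range(n - 2):
        if seq[offset : offset + 3] != "ATG":
            continue
        distance = n - offset
        stop_offset = None
        for j in range(offset + 3, n - 2, 3):
            if seq[j : j + 3] in _STOP_CODONS:
                stop_offset = j
                break
        found.append(
            UAUG(
                offset=offset,
                distance=distance,
                frame=distance % 3,
                uorf=stop_offset is not None,
                stop_offset=stop_offset,
            )
        )
        if max_report is not None and len(found) >= max_report:
            break
    return UAUGReport(utr_length=n, uaugs=found)


@dataclass(frozen=True)
class TranscriptInterval:
    """A 1-based inclusive interval on a transcript, with optional excluded sub-intervals.

    Used for probe and amplicon target spans, e.g. a CDS probe targeting
    1267-1892 excluding an isoform-specific intron 1581-1753.
    """

    start: int
    end: int
    exclusions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"need 1 <= start <= end, got [{self.start}, {self.end}]")
        excl = tuple(sorted(tuple(e) for e in self.exclusions))
        object.__setattr__(self, "exclusions", excl)
        prev_end = None
        for (s, e) in excl:
            if s > e:
                raise ValueError(f"exclusion [{s}, {e}] has start > end")
            if s < self.start or e > self.end:
                raise ValueError(f"exclusion [{s}, {e}] not nested within [{self.start}, {self.end}]")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"exclusions overlap near position {s}")
            prev_end = e


def interval_nt_count(iv: TranscriptInterval) -> int:
    """Number of nucleotides covered by the interval after removing exclusions.

    Both endpoints are included (single-base interval (5, 5) counts 1 nt).
    """
    total = iv.end - iv.start + 1
    excluded = sum(e - s + 1 for (s, e) in iv.exclusions)
    return total - excluded


def read_inserts(path) -> list[InsertRecord]:
    """Read insert records from a FASTA file.

    An ``orientation=inverse`` token in the description marks inverse records;
    everything else is read as forward.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        orientation = "inverse" if "orientation=inverse" in rec.description else "forward"
        records.append(InsertRecord(name=rec.id, sequence=str(rec.seq), orientation=orientation))
    return records


def write_inserts(records: list[InsertRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name} orientation={rec.orientation}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def load_probe_target() -> InsertRecord:
    """The bundled 514-nt Hoxa9 3' UTR ISH probe target sequence (coords 2078-2591)."""
    path = resources.files("iresact.data") / "hoxa9_3utr_probe_514nt.fasta"
    with resources.as_file(path) as p:
        return read_inserts(p)[0]
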