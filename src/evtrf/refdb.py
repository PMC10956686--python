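"""Class-labelled small-RNA reference sequences and 5'-tRF prefix indexes.

The analysis maps collapsed read fragments against five reference databases
(miRNA, piRNA, snoRNA, rRNA, tRNA).  tRNA references additionally feed a
prefix index of candidate 5'-tRF sequences used for indel-tolerant variant
re-annotation.  All sequences are held in DNA space: RNA 'U' is normalised
to 'T' at ingest, because sequencing reads are DNA-space.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The five reference classes, in the arbitration (priority) order used when a
#: fragment hits more than one database.
RNA_CLASSES = ("miRNA", "piRNA", "snoRNA", "rRNA", "tRNA")

_VALID_CHARS = frozenset("ACGTN")
_TRNA_LEN_RANGE = (60, 120)

# GtRNAdb-style identifiers, e.g. "tRNA-Glu-CTC-1-1" or
# "Homo_sapiens_tRNA-Gly-GCC-2-3".
_TRNA_HEADER_RE = re.compile(r"tRNA-([A-Za-z]{3}|iMet|fMet|SeC|Sup|Und)-([ACGTN]{3})")


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent reference input."""


@dataclass
class ReferenceRecord:
    """One reference sequence of a single small-RNA class.

    ``meta`` carries tRNA annotation (``amino_acid``, ``anticodon``,
    ``cca_appended``) when the header follows GtRNAdb naming.
    """

    ref_id: str
    rna_class: str
    sequence: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ReferenceError(
                f"unknown RNA class {self.rna_class!r}; expected one of {RNA_CLASSES}"
            )
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ReferenceError(f"reference {self.ref_id!r} has an empty sequence")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ReferenceError(
                f"reference {self.ref_id!r} contains non-nucleotide characters {sorted(bad)}"
            )
        if self.rna_class == "tRNA":
            lo, hi = _TRNA_LEN_RANGE
            if not lo <= len(seq) <= hi:
                raise ReferenceError(
                    f"tRNA reference {self.ref_id!r} has length {len(seq)}, "
                    f"outside the mature-tRNA range {lo}-{hi} nt"
                )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceSet:
    """A collection of :class:`ReferenceRecord` sharing one RNA class."""

    def __init__(self, rna_class: str, records: Iterable[ReferenceRecord] = ()):
        if rna_class not in RNA_CLASSES:
            raise ReferenceError(f"unknown RNA class {rna_class!r}")
        self.rna_class = rna_class
        self._records: dict[str, ReferenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ReferenceRecord) -> None:
        if record.rna_class != self.rna_class:
            raise ReferenceError(
                f"record {record.ref_id!r} has class {record.rna_class!r}, "
                f"set holds {self.rna_class!r}"
            )
        if record.ref_id in self._records:
            raise ReferenceError(f"duplicate reference ID {record.ref_id!r}")
        self._records[record.ref_id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self._records.values())

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._records

    def __getitem__(self, ref_id: str) -> ReferenceRecord:
        return self._records[ref_id]

    def ids(self) -> list[str]:
        return list(self._records)

    def with_cca(self) -> "ReferenceSet":
        """Return a copy with 'CCA' appended to every tRNA 3' end.

        Mature tRNAs carry a (possibly post-transcriptionally added) 3'-CCA;
        whether a reference database includes it varies, so appending is an
        explicit opt-in.  Records already ending in CCA are left alone.
        """
        if self.rna_class != "tRNA":
            raise ReferenceError("with_cca applies to tRNA reference sets only")
        out = ReferenceSet("tRNA")
        for rec in self:
            seq = rec.sequence
            meta = dict(rec.meta)
            if not seq.endswith("CCA"):
                seq = seq + "CCA"
                meta["cca_appended"] = True
            out.add(ReferenceRecord(rec.ref_id, "tRNA", seq, meta))
        return out


def _parse_trna_meta(header: str) -> dict:
    m = _TRNA_HEADER_RE.search(header)
    if not m:
        return {}
    return {"amino_acid": m.group(1), "anticodon": m.group(2)}


def _bad_char_line(path: Path, ref_id: str) -> int | None:
    """Locate the first FASTA line of ``ref_id``'s entry with a bad character."""
    in_entry = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_entry = line[1:].split()[0] == ref_id if line[1:].strip() else False
                continue
            if in_entry:
                chars = set(line.strip().upper().replace("U", "T"))
                if chars - _VALID_CHARS:
                    return lineno
    return None


def read_fasta(path: str | Path, rna_class: str) -> ReferenceSet:
    """Load a FASTA file into a :class:`ReferenceSet` of one RNA class.

    'U' is converted to 'T'; GtRNAdb-style tRNA headers have amino acid and
    anticodon extracted into ``meta``.  Duplicate IDs and non-nucleotide
    characters are errors; an empty file yields an empty set with a warning.
    """
    path = Path(path)
    refset = ReferenceSet(rna_class)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        meta = _parse_trna_meta(rec.description) if rna_class == "tRNA" else {}
        try:
            refset.add(ReferenceRecord(rec.id, rna_class, str(rec.seq), meta))
        except ReferenceError as exc:
            if "non-nucleotide" in str(exc):
                lineno = _bad_char_line(path, rec.id)
                raise ReferenceError(f"{path}, line {lineno}: {exc}") from None
            raise
    if n == 0:
        logger.warning("FASTA file %s contained no sequences", path)
    return refset


def write_fasta(refset: ReferenceSet, path: str | Path) -> None:
    """Write a reference set back to FASTA (sequences byte-identical to ingest,
    headers normalised to the bare ref_id)."""
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.ref_id, description="") for rec in refset
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class PrefixIndex:
    """Index of exact 5' prefixes of tRNA references.

    Maps each distinct prefix sequence to the sorted list of source tRNA
    ref_ids that start with it; identical prefixes arising from several tRNAs
    are merged into one entry.  Prefix length is implicit in the key.
    """

    entries: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def sources(self, prefix: str) -> list[str]:
        return self.entries[prefix]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("prefix\tlength\tsources\n")
            for prefix in sorted(self.entries):
                fh.write(
                    f"{prefix}\t{len(prefix)}\t{','.join(self.entries[prefix])}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PrefixIndex":
        entries: dict[str, list[str]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("prefix\t"):
                raise ReferenceError(f"{path} is not a prefix-index TSV")
            for line in fh:
                prefix, _length, sources = line.rstrip("\n").split("\t")
                entries[prefix] = sources.split(",")
        return cls(entries)


def five_prime_prefixes(
    trna_set: ReferenceSet, lengths: Iterable[int] = range(28, 37)
) -> PrefixIndex:
    """Index the exact 5' prefixes of every tRNA at each requested length.

    The default 28-36 nt window brackets the 30-34 nt modal length of
    EV-exported 5'-tRNA halves with margin for 1-2 nt indel variants.
    Lengths exceeding a particular tRNA are skipped for that tRNA.
    """
    if trna_set.rna_class != "tRNA":
        raise ReferenceError("five_prime_prefixes requires a tRNA reference set")
    lengths = sorted(set(int(x) for x in lengths))
    if not lengths:
        raise ReferenceError("at least one prefix length is required")
    if lengths[0] < 15 or lengths[-1] > 50:
        raise ReferenceError("prefix lengths must lie within 15-50 nt")
    entries: dict[str, list[str]] = {}
    for rec in trna_set:
        for length in lengths:
            if length > len(rec.sequence):
                continue
            prefix = rec.sequence[:length]
            entries.setdefault(prefix, []).append(rec.ref_id)
    for prefix in entries:
        entries[prefix] = sorted(set(entries[prefix]))
    return PrefixIndex(entries)
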