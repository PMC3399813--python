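"""From raw 37-base tags to per-position tag or template counts.

Processing order per sample: drop chastity-filter failures, gate on the last
three bases of the amplification primer, mask bases with quality < 20 to N,
collapse to distinct sequences, align each distinct sequence uniquely (at most
one mismatch, N always mismatching) against the panel's reference 37-mers,
and map multiplicities back to positions. With UID-tagged libraries, distinct
UIDs per position give template counts instead of read counts.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulator import PositionPanel, POSITION_INDEX

UNALIGNED = "unaligned"
SUPPRESSED_MULTI = "suppressed_multi"


@dataclass
class ReadRecord:
    read_id: str
    seq: str
    qual: np.ndarray
    uid: str | None = None
    barcode: str | None = None
    chastity: bool = True

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Parse Phred+33 FASTQ; CF/BC/UID annotations live in the description."""
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            tok.split(":", 1) for tok in rec.description.split()[1:] if ":" in tok
        )
        yield ReadRecord(
            read_id=rec.id,
            seq=str(rec.seq),
            qual=np.asarray(rec.letter_annotations["phred_quality"]),
            uid=fields.get("UID"),
            barcode=fields.get("BC"),
            chastity=fields.get("CF", "1") != "0",
        )


def primer_gate(read: ReadRecord, fwd_primer: str, min_terminal: int = 3) -> bool:
    """Keep iff the read starts with the primer's last ``min_terminal`` bases."""
    if min_terminal > len(fwd_primer):
        raise ValueError("primer shorter than min_terminal")
    if min_terminal == 0:
        return True
    return read.seq[:min_terminal] == fwd_primer[-min_terminal:]


def mask_low_quality(read: ReadRecord, q_min: int = 20) -> str:
    """Replace bases with quality strictly below ``q_min`` by N."""
    chars = np.frombuffer(read.seq.encode(), dtype="S1").copy()
    chars[read.qual < q_min] = b"N"
    return chars.tobytes().decode()


def collapse_distinct(masked_seqs: Iterable[str]) -> dict[str, int]:
    """Map each distinct sequence to its multiplicity (insertion-ordered)."""
    return dict(collections.Counter(masked_seqs))


class PanelAligner:
    """Unique Hamming-distance alignment against the panel reference 37-mers.

    Mirrors short-read aligner semantics with a one-mismatch budget and
    multi-hit suppression: a query is assigned iff exactly one reference lies
    within ``max_mm`` mismatches; two or more qualifying references suppress
    it, none leaves it unaligned. N never matches anything, including another
    N.
    """

    def __init__(self, panel: PositionPanel, max_mm: int = 1):
        if "ref_tag" not in panel.records:
            raise ValueError("panel has no reference tags")
        if len(panel) == 0:
            raise ValueError("panel is empty")
        self.max_mm = max_mm
        self.identities = list(map(tuple, panel.records[POSITION_INDEX].itertuples(index=False)))
        tags = panel.records["ref_tag"].tolist()
        self.tag_len = len(tags[0])
        if any(len(t) != self.tag_len for t in tags):
            raise ValueError("reference tags have unequal lengths")
        self._refs = np.frombuffer("".join(tags).encode(), dtype="S1").reshape(
            len(tags), self.tag_len
        )
        self._ref_has_n = self._refs == b"N"
        # exact-match fast path only valid for N-free references
        self._exact = {
            t: i for i, t in enumerate(tags) if "N" not in t
        }

    def align(self, seq: str):
        """Return a position identity, UNALIGNED, or SUPPRESSED_MULTI."""
        if len(seq) != self.tag_len:
            raise ValueError(
                f"query length {len(seq)} != reference length {self.tag_len}"
            )
        q = np.frombuffer(seq.encode(), dtype="S1")
        mm = ((q != self._refs) | (q == b"N") | self._ref_has_n).sum(axis=1)
        hits = np.nonzero(mm <= self.max_mm)[0]
        if len(hits) == 0:
            return UNALIGNED
        if len(hits) > 1:
            return SUPPRESSED_MULTI
        return self.identities[hits[0]]


def align_unique(seq: str, aligner: PanelAligner):
    """Functional wrapper over :meth:`PanelAligner.align`."""
    return aligner.align(seq)


def count_tags(
    alignments: Mapping[str, tuple],
    multiplicities: Mapping[str, int],
) -> dict[tuple, int]:
    """Fold distinct-sequence alignments back onto per-position tag counts."""
    counts: dict[tuple, int] = collections.defaultdict(int)
    for seq, ident in alignments.items():
        if seq not in multiplicities:
            raise KeyError(f"aligned sequence missing from multiplicities: {seq!r}")
        counts[ident] += multiplicities[seq]
    return dict(counts)


def count_templates_by_uid(
    reads_by_position: Mapping[tuple, Sequence[ReadRecord]],
    uid_len: int,
) -> dict[tuple, int]:
    """Distinct-UID (template) count per position."""
    out = {}
    for ident, reads in reads_by_position.items():
        uids = set()
        for r in reads:
            if r.uid is None or len(r.uid) != uid_len:
                raise ValueError(f"read {r.read_id} lacks a {uid_len}-base UID")
            uids.add(r.uid)
        out[ident] = len(uids)
    return out


def demultiplex(
    reads: Iterable[ReadRecord], barcodes: Mapping[str, str]
) -> dict[str, list[ReadRecord]]:
    """Route reads to samples by exact barcode match; order is preserved.

    ``barcodes`` maps index sequence -> sample id. Reads with an unknown (or
    absent) barcode land in the 'undetermined' bin.
    """
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate sample ids in barcode map")
    bins: dict[str, list[ReadRecord]] = {s: [] for s in barcodes.values()}
    bins["undetermined"] = []
    for r in reads:
        bins.get(barcodes.get(r.barcode, "undetermined"),
                 bins["undetermined"]).append(r)
    return bins


@dataclass
class TagAccounting:
    """Where every input read went; reads in = sum of the buckets."""

    total: int = 0
    failed_chastity: int = 0
    failed_primer: int = 0
    unaligned: int = 0
    suppressed_multi: int = 0
    counted: int = 0

    def check(self) -> None:
        parts = (self.failed_chastity + self.failed_primer + self.unaligned
                 + self.suppressed_multi + self.counted)
        if parts != self.total:
            raise AssertionError(f"tag accounting leak: {parts} != {self.total}")


def process_sample(
    reads: Iterable[ReadRecord],
    panel: PositionPanel,
    fwd_primer: str,
    q_min: int = 20,
    max_mm: int = 1,
    min_terminal: int = 3,
    uid_len: int = 0,
) -> tuple[pd.Series, TagAccounting]:
    """Full per-sample tag processing; returns per-position counts + audit.

    With ``uid_len > 0`` the counts are distinct-UID template counts;
    otherwise plain tag counts.
    """
    acct = TagAccounting()
    kept: list[tuple[str, ReadRecord]] = []
    for r in reads:
        acct.total += 1
        if not r.chastity:
            acct.failed_chastity += 1
            continue
        if not primer_gate(r, fwd_primer, min_terminal):
            acct.failed_primer += 1
            continue
        kept.append((mask_low_quality(r, q_min), r))

    mult = collapse_distinct(m for m, _ in kept)
    aligner = PanelAligner(panel, max_mm=max_mm)
    alignments: dict[str, tuple] = {}
    for seq, n in mult.items():
        res = aligner.align(seq)
        if res == UNALIGNED:
            acct.unaligned += n
        elif res == SUPPRESSED_MULTI:
            acct.suppressed_multi += n
        else:
            alignments[seq] = res
            acct.counted += n
    acct.check()

    if uid_len:
        by_pos: dict[tuple, list[ReadRecord]] = collections.defaultdict(list)
        for masked, r in kept:
            ident = alignments.get(masked)
            if ident is not None:
                by_pos[ident].append(r)
        counts = count_templates_by_uid(by_pos, uid_len)
    else:
        counts = count_tags(alignments, mult)

    idx = panel.position_index
    series = pd.Series(0, index=idx, dtype=int)
    for ident, n in counts.items():
        series.loc[ident] = n
    return series, acct
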