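"""In-silico selection of amplifiable repeat blocks and primer evaluation.

The assay needs one primer pair that amplifies many dispersed repeat loci
which stay distinguishable from each other after sequencing errors. The
workflow implemented here:

* slide 150 bp windows (step 50) across a query region;
* find, for each window, similar blocks elsewhere in the genome with a
  k-mer-seeded, ungapped similarity search (substitution-only "variant
  bases");
* keep windows whose matches carry between 11 and 30 variant bases, span at
  most 180 bp, and have at least three same-chromosome siblings;
* check how many candidate amplicon sequences remain uniquely identifiable
  when reads carry up to e errors (pairwise Hamming distance > 2e, which
  guarantees an e-error read is still closer to its source than to any other
  member);
* predict amplicons for a candidate primer pair by IUPAC-aware in-silico PCR.

Genome inputs are plain FASTA (or an in-memory dict of sequences); the search
is meant for synthetic genomes up to a few megabases, not for whole-genome
scans.
"""

from __future__ import annotations

import collections
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_BITS = {}
for code, bases in IUPAC.items():
    _IUPAC_BITS[code] = sum(1 << "ACGT".index(b) for b in bases)

DEFAULT_WINDOW = 150
DEFAULT_STEP = 50


def load_genome(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Accept a FASTA path or a {name: sequence} mapping; uppercase everything."""
    if isinstance(source, Mapping):
        return {k: str(v).upper() for k, v in source.items()}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")}


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


@dataclass(frozen=True)
class BlockMatch:
    """One similar block found for a query window (ungapped)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    variant_bases: int
    span: int


@dataclass
class CandidateBlock:
    """A query window plus everything similar to it in the subject genome."""

    chrom: str
    start: int
    end: int
    matches: list[BlockMatch] = field(default_factory=list)

    @property
    def n_same_chrom(self) -> int:
        return sum(1 for m in self.matches if m.chrom == self.chrom)


@dataclass(frozen=True)
class PrimerPair:
    fwd: str
    rev: str
    max_product: int = 1000

    def __post_init__(self) -> None:
        for name, seq in (("fwd", self.fwd), ("rev", self.rev)):
            if not seq:
                raise ValueError(f"{name} primer is empty")
            bad = set(seq.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC characters {bad}")


def enumerate_windows(
    chrom: str, start: int, end: int,
    window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
) -> list[Window]:
    """Sliding windows fully inside [start, end] (1-based inclusive).

    Windows begin at ``start`` and advance by ``step``; for a region of
    length L there are floor((L - window)/step) + 1 of them.
    """
    length = end - start + 1
    if length < window:
        warnings.warn(f"region length {length} shorter than window {window}")
        return []
    n = (length - window) // step + 1
    return [Window(chrom, start + i * step, start + i * step + window - 1)
            for i in range(n)]


def find_similar_blocks(
    query: str,
    subject: Mapping[str, str],
    min_seed: int = 20,
    max_variants: int = 30,
) -> list[BlockMatch]:
    """Seeded ungapped similarity search for one query sequence.

    Every exact ``min_seed``-mer shared between query and subject proposes a
    diagonal; each distinct diagonal is scored once by ungapped alignment of
    the full query against the subject (clipped at contig ends). Matches with
    more than ``max_variants`` substitutions are discarded.
    """
    query = query.upper()
    if len(query) < min_seed:
        raise ValueError("query shorter than min_seed")
    if not subject:
        return []
    qbytes = np.frombuffer(query.encode(), dtype="S1")
    seeds: dict[str, list[int]] = collections.defaultdict(list)
    for qp in range(len(query) - min_seed + 1):
        seeds[query[qp:qp + min_seed]].append(qp)

    out: list[BlockMatch] = []
    for chrom, seq in subject.items():
        seq = seq.upper()
        offsets = set()
        for sp in range(len(seq) - min_seed + 1):
            kmer = seq[sp:sp + min_seed]
            for qp in seeds.get(kmer, ()):
                offsets.add(sp - qp)
        sbytes = np.frombuffer(seq.encode(), dtype="S1")
        for off in sorted(offsets):
            lo = max(0, off)
            hi = min(len(seq), off + len(query))
            if hi <= lo:
                continue
            qseg = qbytes[lo - off: hi - off]
            sseg = sbytes[lo:hi]
            variants = int((qseg != sseg).sum())
            if variants <= max_variants:
                out.append(BlockMatch(chrom=chrom, start=lo + 1, end=hi,
                                      variant_bases=variants, span=hi - lo))
    return out


def scan_candidate_blocks(
    subject: Mapping[str, str],
    region_chrom: str,
    region_start: int,
    region_end: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_seed: int = 20,
    max_variants: int = 30,
) -> list[CandidateBlock]:
    """Run the sliding-window similarity scan over a query region.

    The query window's own locus (an exact self-overlap on the same
    chromosome) is not listed among its matches.
    """
    subject = load_genome(subject)
    blocks = []
    for w in enumerate_windows(region_chrom, region_start, region_end, window, step):
        qseq = subject[w.chrom][w.start - 1: w.end]
        matches = [
            m for m in find_similar_blocks(qseq, subject, min_seed, max_variants)
            if not (m.chrom == w.chrom and m.start <= w.end and m.end >= w.start)
        ]
        blocks.append(CandidateBlock(chrom=w.chrom, start=w.start, end=w.end,
                                     matches=matches))
    return blocks


def filter_candidate_blocks(
    blocks: Sequence[CandidateBlock],
    min_var: int = 11,
    max_var: int = 30,
    max_span: int = 180,
    min_sib: int = 3,
) -> list[CandidateBlock]:
    """Keep blocks usable as amplifiable-yet-distinguishable repeat targets.

    A block passes iff it has at least ``min_sib`` same-chromosome matches
    and every match carries between ``min_var`` and ``max_var`` variant bases
    over a span of at most ``max_span`` bp.
    """
    passing = []
    for b in blocks:
        if b.n_same_chrom < min_sib or not b.matches:
            continue
        ok = all(
            min_var <= m.variant_bases <= max_var and m.span <= max_span
            for m in b.matches
        )
        if ok:
            passing.append(b)
    return passing


def distinctness_under_errors(seqs: Sequence[str], e: int) -> int:
    """How many sequences stay uniquely identifiable with up to e read errors.

    A sequence counts iff no other sequence lies within Hamming distance 2e:
    then any read with at most e errors is strictly closer to its source than
    to any other member. Exact pairwise computation.
    """
    if e < 0:
        raise ValueError("e must be >= 0")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal lengths")
    n = len(seqs)
    if n == 0:
        return 0
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, -1)
    dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.iinfo(dist.dtype).max)
    return int((dist.min(axis=1) > 2 * e).sum())


def _match_positions(seq_bits: np.ndarray, primer: str, max_mm: int) -> np.ndarray:
    """Start offsets (0-based) where the primer matches the plus strand.

    IUPAC-aware; the primer's 3'-terminal base must be compatible regardless
    of the mismatch budget.
    """
    p = primer.upper()
    L = len(p)
    n = len(seq_bits)
    if n < L:
        return np.array([], dtype=int)
    n_off = n - L + 1
    mm = np.zeros(n_off, dtype=int)
    for j, code in enumerate(p):
        mask = _IUPAC_BITS[code]
        compat = (seq_bits[j:j + n_off] & mask) != 0
        mm += ~compat
        if j == L - 1:
            last_ok = compat
    return np.nonzero((mm <= max_mm) & last_ok)[0]


def _seq_bits(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for code, bits in _IUPAC_BITS.items():
        lut[ord(code)] = bits
    return lut[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class Amplicon:
    chrom: str
    start: int  # 1-based inclusive, first base of the fwd primer site
    end: int    # 1-based inclusive, last base of the rev primer site
    strand: str
    product_len: int


def predict_amplicons(
    primer: PrimerPair,
    subject: Mapping[str, str] | str | Path,
    max_mm_per_primer: int = 0,
    max_product: int | None = None,
) -> list[Amplicon]:
    """In-silico PCR: convergent primer sites within the product limit.

    Orientation '+': fwd on the plus strand, rev on the minus strand
    (reverse complement of rev downstream on plus). Orientation '-' is the
    mirror image. Product length includes both primer footprints.
    """
    subject = load_genome(subject)
    if max_product is None:
        max_product = primer.max_product
    fwd = primer.fwd.upper()
    rc_rev = str(Seq(primer.rev.upper()).reverse_complement())
    rev = primer.rev.upper()
    rc_fwd = str(Seq(fwd).reverse_complement())

    out: list[Amplicon] = []
    for chrom, seq in subject.items():
        bits = _seq_bits(seq)
        # '+': fwd site ... rc(rev) site
        f_sites = _match_positions(bits, fwd, max_mm_per_primer)
        r_sites = _match_positions_rc(bits, rc_rev, len(rev), max_mm_per_primer)
        out.extend(_pair_sites(chrom, f_sites, len(fwd), r_sites, len(rev),
                               max_product, "+"))
        # '-': rev site ... rc(fwd) site
        f2 = _match_positions(bits, rev, max_mm_per_primer)
        r2 = _match_positions_rc(bits, rc_fwd, len(fwd), max_mm_per_primer)
        out.extend(_pair_sites(chrom, f2, len(rev), r2, len(fwd),
                               max_product, "-"))
    return sorted(out, key=lambda a: (a.chrom, a.start, a.end, a.strand))


def _match_positions_rc(seq_bits: np.ndarray, rc_primer: str,
                        primer_len: int, max_mm: int) -> np.ndarray:
    """Plus-strand offsets of a reverse-complemented primer site.

    The biological 3' terminus of the original primer is the *first* base of
    its reverse complement, so the exact-terminal rule applies there.
    """
    p = rc_primer.upper()
    L = len(p)
    n = len(seq_bits)
    if n < L:
        return np.array([], dtype=int)
    n_off = n - L + 1
    mm = np.zeros(n_off, dtype=int)
    for j, code in enumerate(p):
        mask = _IUPAC_BITS[code]
        compat = (seq_bits[j:j + n_off] & mask) != 0
        mm += ~compat
        if j == 0:
            first_ok = compat
    return np.nonzero((mm <= max_mm) & first_ok)[0]


def _pair_sites(chrom, f_sites, f_len, r_sites, r_len, max_product, strand):
    out = []
    for i in f_sites:
        for j in r_sites:
            if j < i + f_len:
                continue
            product = j + r_len - i
            if product <= max_product:
                out.append(Amplicon(chrom=chrom, start=int(i) + 1,
                                    end=int(j + r_len), strand=strand,
                                    product_len=int(product)))
    return out
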