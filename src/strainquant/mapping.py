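"""Perfect, unambiguous paired-end fragment counting.

The abundance method only trusts fragments whose two mates both match a
subcontig exactly, end to end, in convergent orientation, and that match only
one subcontig in the whole database.  Anything else — a single mismatch, a
fragment matching a region shared verbatim by two strains, an orphan mate —
is discarded.  The filtering contract mirrors stringent short-read
preprocessing: 3' poly-G runs trimmed, any read pair containing an ambiguous
base or a mate shorter than 50 b after trimming dropped.

The built-in mapper is a seed-and-verify exact matcher: every 31-base window
of every subcontig is 2-bit packed into a sorted array; a mate's leading
31-mer locates candidate placements which are verified by full string
comparison.  Any method satisfying the hit definition is equivalent; this one
is simple and fast at defined-community scale.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .refdb import ReferenceDatabase, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 50
DEFAULT_MAX_N = 0
DEFAULT_POLYG_MIN_RUN = 10

_SEED = 31

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


@dataclass
class ReadPair:
    """One sequenced fragment: two mates (qualities optional and unused)."""

    id: str
    r1: str
    r2: str
    q1: str | None = None
    q2: str | None = None

    def __post_init__(self) -> None:
        if not self.r1 or not self.r2:
            raise ValueError(f"read pair {self.id}: both mates must be non-empty")


@dataclass
class FragmentCounts:
    """Per-subcontig perfect-unique fragment counts for one sample."""

    per_subcontig: dict[str, int]
    total_mapped_fragments: int
    total_input_fragments: int

    def __post_init__(self) -> None:
        assert self.total_mapped_fragments == sum(self.per_subcontig.values())
        assert self.total_mapped_fragments <= self.total_input_fragments


def trim_poly_g(sequence: str, min_run: int = DEFAULT_POLYG_MIN_RUN) -> str:
    """Trim a trailing run of >= min_run G's from the 3' end."""
    n = len(sequence)
    i = n
    while i > 0 and sequence[i - 1] in "Gg":
        i -= 1
    if n - i >= min_run:
        return sequence[:i]
    return sequence


def filter_read_pair(
    pair: ReadPair,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_n: int = DEFAULT_MAX_N,
    polyg_min_run: int = DEFAULT_POLYG_MIN_RUN,
) -> ReadPair | None:
    """Poly-G trim then drop pairs with too many N's or short mates.

    Returns the (possibly trimmed) pair, or None if the pair is dropped.
    """
    r1 = trim_poly_g(pair.r1, polyg_min_run)
    r2 = trim_poly_g(pair.r2, polyg_min_run)
    if len(r1) < min_length or len(r2) < min_length:
        return None
    if r1.upper().count("N") > max_n or r2.upper().count("N") > max_n:
        return None
    if r1 is pair.r1 and r2 is pair.r2:
        return pair
    return ReadPair(
        id=pair.id,
        r1=r1,
        r2=r2,
        q1=None if pair.q1 is None else pair.q1[: len(r1)],
        q2=None if pair.q2 is None else pair.q2[: len(r2)],
    )


@dataclass(frozen=True)
class MapResult:
    status: str  # "unique" | "ambiguous" | "unmapped"
    subcontig_id: str | None = None


def _pack_windows(codes: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every width-length window; returns (values, valid starts)."""
    n = codes.size
    if n < width:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    m = n - width + 1
    vals = np.zeros(m, dtype=np.uint64)
    for j in range(width):
        vals = (vals << np.uint64(2)) | codes[j : j + m].astype(np.uint64)
    bad = (codes >= 4).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    starts = np.nonzero(cum[width:] - cum[:-width] == 0)[0]
    return vals[starts], starts


class ExactFragmentMapper:
    """Exact end-to-end paired mapper over a reference database.

    A *hit* of a pair on a subcontig is a placement where one mate matches the
    subcontig forward and the other matches reverse-complemented strictly
    downstream (inner gap >= 0), both full length with zero mismatches.  The
    pair is ``unique`` iff all hits fall on exactly one subcontig (multiple
    placements on the same subcontig still count as unique to it),
    ``ambiguous`` if hits span two or more subcontigs, else ``unmapped``.
    Excluded subcontigs are part of the index: fragments may map to them.
    """

    def __init__(self, db: ReferenceDatabase):
        self.db = db
        self._ids = [s.id for s in db.subcontigs]
        self._seqs = [s.sequence.upper() for s in db.subcontigs]
        vals_parts: list[np.ndarray] = []
        sub_parts: list[np.ndarray] = []
        pos_parts: list[np.ndarray] = []
        for idx, seq in enumerate(self._seqs):
            codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            vals, starts = _pack_windows(codes, _SEED)
            if vals.size:
                vals_parts.append(vals)
                sub_parts.append(np.full(vals.size, idx, dtype=np.int32))
                pos_parts.append(starts)
        if vals_parts:
            vals = np.concatenate(vals_parts)
            order = np.argsort(vals, kind="stable")
            self._vals = vals[order]
            self._subs = np.concatenate(sub_parts)[order]
            self._pos = np.concatenate(pos_parts)[order].astype(np.int64)
        else:
            self._vals = np.empty(0, np.uint64)
            self._subs = np.empty(0, np.int32)
            self._pos = np.empty(0, np.int64)

    def _oriented_hits(self, mate: str) -> list[tuple[int, int]]:
        """All (subcontig index, start) full-length exact placements of mate."""
        m = mate.upper()
        n = len(m)
        if n < _SEED:
            return self._brute_hits(m)
        codes = _CODE[np.frombuffer(m[:_SEED].encode("ascii"), dtype=np.uint8)]
        if (codes >= 4).any():
            return self._brute_hits(m)
        v = 0
        for c in codes:
            v = (v << 2) | int(c)
        v = np.uint64(v)
        lo = int(np.searchsorted(self._vals, v, side="left"))
        hi = int(np.searchsorted(self._vals, v, side="right"))
        hits = []
        for j in range(lo, hi):
            sub = int(self._subs[j])
            pos = int(self._pos[j])
            if self._seqs[sub][pos : pos + n] == m:
                hits.append((sub, pos))
        return hits

    def _brute_hits(self, mate: str) -> list[tuple[int, int]]:
        hits = []
        for idx, seq in enumerate(self._seqs):
            start = seq.find(mate)
            while start != -1:
                hits.append((idx, start))
                start = seq.find(mate, start + 1)
        return hits

    def map_pair(self, pair: ReadPair) -> MapResult:
        r1, r2 = pair.r1, pair.r2
        h1f = self._oriented_hits(r1)
        h2f = self._oriented_hits(r2)
        h1r = self._oriented_hits(reverse_complement(r1))
        h2r = self._oriented_hits(reverse_complement(r2))
        hit_subs: set[int] = set()
        for fwd, rev, fwd_len in ((h1f, h2r, len(r1)), (h2f, h1r, len(r2))):
            if not fwd or not rev:
                continue
            min_fwd: dict[int, int] = {}
            for sub, pos in fwd:
                if sub not in min_fwd or pos < min_fwd[sub]:
                    min_fwd[sub] = pos
            for sub, pos in rev:
                if sub in min_fwd and pos >= min_fwd[sub] + fwd_len:
                    hit_subs.add(sub)
        if not hit_subs:
            return MapResult("unmapped")
        if len(hit_subs) > 1:
            return MapResult("ambiguous")
        return MapResult("unique", self._ids[hit_subs.pop()])


def count_fragments(
    pairs: Iterable[ReadPair],
    db: ReferenceDatabase | ExactFragmentMapper,
    *,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_n: int = DEFAULT_MAX_N,
    polyg_min_run: int = DEFAULT_POLYG_MIN_RUN,
) -> FragmentCounts:
    """Filter and map a read-pair stream; count perfect-unique fragments.

    Each unique fragment increments exactly one subcontig.  Counts are
    order-independent.
    """
    mapper = db if isinstance(db, ExactFragmentMapper) else ExactFragmentMapper(db)
    per: dict[str, int] = {sid: 0 for sid in mapper._ids}
    total_input = 0
    total_mapped = 0
    for pair in pairs:
        total_input += 1
        kept = filter_read_pair(pair, min_length, max_n, polyg_min_run)
        if kept is None:
            continue
        result = mapper.map_pair(kept)
        if result.status == "unique":
            per[result.subcontig_id] += 1
            total_mapped += 1
    return FragmentCounts(
        per_subcontig=per,
        total_mapped_fragments=total_mapped,
        total_input_fragments=total_input,
    )


def _cigar_is_full_match(read) -> bool:
    """CIGAR is all M/= and covers the whole query (no clips/indels)."""
    if read.cigartuples is None:
        return False
    aligned = 0
    for op, length in read.cigartuples:
        if op in (0, 7):  # M, =
            aligned += length
        else:
            return False
    return aligned == read.query_length


def import_sam_counts(sam_path: str | Path, db: ReferenceDatabase) -> FragmentCounts:
    """Count fragments from an external SAM/BAM aligned against db subcontigs.

    One fragment is counted per template with a primary, properly-paired
    alignment, edit distance 0 (NM tag), and a full-length match CIGAR;
    everything else is ignored.  Reference names must be database subcontig
    IDs.
    """
    import pysam

    known = {s.id for s in db.subcontigs}
    per: dict[str, int] = {s.id: 0 for s in db.subcontigs}
    # per template, the passing reference of each mate (or False once it fails)
    templates: dict[str, list] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as handle:
        for name in handle.references:
            if name not in known:
                raise ValueError(f"unknown reference name in alignment: {name!r}")
        for read in handle:
            if read.is_secondary or read.is_supplementary:
                continue
            mate = 0 if read.is_read1 else 1
            state = templates.setdefault(read.query_name, [False, False])
            if read.is_unmapped or not read.is_proper_pair:
                continue
            if not read.has_tag("NM"):
                raise ValueError(
                    f"alignment record {read.query_name!r} lacks an NM (edit distance) "
                    "tag; re-align with NM reporting enabled"
                )
            if read.get_tag("NM") == 0 and _cigar_is_full_match(read):
                state[mate] = read.reference_name
    total_input = len(templates)
    total_mapped = 0
    for state in templates.values():
        if state[0] and state[0] == state[1]:
            per[state[0]] += 1
            total_mapped += 1
    return FragmentCounts(
        per_subcontig=per,
        total_mapped_fragments=total_mapped,
        total_input_fragments=total_input,
    )


def read_paired_fastq(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from matched FASTQ files (plain or gzip)."""
    for (id1, s1, q1), (id2, s2, q2) in zip(
        _iter_fastq(r1_path), _iter_fastq(r2_path), strict=True
    ):
        yield ReadPair(id=id1, r1=s1, r2=s2, q1=q1, q2=q2)


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    path = Path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as handle:
        while True:
            header = handle.readline()
            if not header:
                return
            seq = handle.readline().rstrip("\n")
            handle.readline()
            qual = handle.readline().rstrip("\n")
            yield header.rstrip("\n")[1:].split()[0], seq, qual
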