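"""Uniqueness-normalized reference database construction.

Member genomes of a defined (synthetic) community are split into
similarly-sized *subcontigs* so that assembly quality is comparable across
strains, and every subcontig is annotated with the number of canonical k-mers
that occur exactly once across the whole community.  Those unique-k-mer counts
are the normalization factors used downstream: a unique k-mer is a proxy for a
site at which a read can map unambiguously.

Key rules:

* The maximum subcontig size defaults to the smallest N50 among the input
  assemblies; each contig is cut into equally sized cores no larger than that,
  and each subcontig sequence carries ``overlap`` flanking bases on either
  side so read pairs straddling a cut are not lost.
* Contigs shorter than ``min_contig_size`` (default 10 kb, e.g. plasmids or
  fragmented repeats) are kept in the database but flagged ``excluded``: their
  k-mers still mark community k-mers as non-unique and reads may still map to
  them, but they never contribute a FUKM estimate.
* k defaults to the paired-end fragment span plus one (301 for 150 b paired
  reads) so that one unique k-mer corresponds to one potential unique mapping
  site for a read pair; k is forced odd so no k-mer is its own reverse
  complement.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 150
DEFAULT_MIN_CONTIG_SIZE = 10_000
DEFAULT_OVERLAP = 500

HASH_NAME = "blake2b-64"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ACGT_CODES = frozenset(b"ACGT")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N} (case preserved per character)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def hash64(kmer: str) -> int:
    """Stable 64-bit hash of a string (blake2b, 8-byte digest, little-endian).

    Any fixed, platform-stable 64-bit hash satisfies the database contract;
    collisions among tens of millions of k-mers are vanishingly unlikely in a
    64-bit space and are ignored.
    """
    return int.from_bytes(
        hashlib.blake2b(kmer.encode("ascii"), digest_size=8).digest(), "little"
    )


def kmer_size_for_read_length(read_length: int) -> int:
    """Default k: paired-end fragment span (both mates) plus one, forced odd."""
    k = 2 * read_length + 1
    if k % 2 == 0:
        k += 1
    return k


@dataclass(frozen=True)
class KmerParams:
    """k-mer parameters of a database.

    ``read_length`` is the per-mate read length the database is tuned for;
    ``k`` defaults to ``2 * read_length + 1``.
    """

    k: int
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError(f"k must be >= 3, got {self.k}")
        if self.k % 2 == 0:
            raise ValueError(f"k must be odd, got {self.k}")

    @classmethod
    def from_read_length(cls, read_length: int = DEFAULT_READ_LENGTH) -> "KmerParams":
        return cls(k=kmer_size_for_read_length(read_length), read_length=read_length)


@dataclass
class Contig:
    id: str
    strain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id} of {self.strain_id} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Subcontig:
    """A slice of a contig: the mapping/normalization unit.

    ``core_start``/``core_end`` are 0-based half-open coordinates on the
    parent contig; the cores of a contig's subcontigs tile it exactly.
    ``sequence`` extends the core by the database overlap on either side
    (truncated at the contig ends).
    """

    id: str
    strain_id: str
    contig_id: str
    core_start: int
    core_end: int
    sequence: str
    excluded: bool = False
    unique_kmers: int | None = None

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start


def subcontig_id(strain_id: str, contig_id: str, start: int, end: int) -> str:
    return f"{strain_id}|{contig_id}|{start}|{end}"


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """N50 of an assembly: largest L such that contigs >= L hold half the bases."""
    if len(contig_lengths) == 0:
        raise ValueError("no contigs")
    lengths = sorted(contig_lengths, reverse=True)
    if min(lengths) <= 0:
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2
    running = 0
    for length in lengths:
        running += length
        if running >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def determine_max_subcontig_size(
    genomes: Sequence[tuple[str, Sequence[int]]],
    override: int | None = None,
    *,
    min_contig_size: int = DEFAULT_MIN_CONTIG_SIZE,
    k: int | None = None,
) -> int:
    """Maximum subcontig core size: the smallest per-genome N50, or an override."""
    if not genomes:
        raise ValueError("no genomes")
    if override is not None:
        size = int(override)
    else:
        size = min(compute_n50(lengths) for _, lengths in genomes)
    if k is not None and size <= k:
        raise ValueError(
            f"max subcontig size {size} is not larger than k={k}; "
            "no subcontig could hold a single k-mer"
        )
    if size < min_contig_size:
        logger.warning(
            "max subcontig size %d is below the minimum contig size %d; "
            "the database may exclude every subcontig",
            size,
            min_contig_size,
        )
    return size


def split_contig(
    contig: Contig,
    max_size: int,
    overlap: int = DEFAULT_OVERLAP,
    min_contig_size: int = DEFAULT_MIN_CONTIG_SIZE,
) -> list[Subcontig]:
    """Split a contig into equally sized subcontig cores no larger than max_size.

    The number of pieces is ``ceil(L / max_size)`` and the core size
    ``ceil(L / pieces)``; the last core absorbs the (smaller) remainder, so the
    cores tile the contig exactly.  Each subcontig's sequence extends its core
    by ``overlap`` bases per side, truncated at the contig ends.  Contigs
    shorter than ``min_contig_size`` become a single whole-contig subcontig
    flagged ``excluded``.
    """
    if max_size <= 0:
        raise ValueError("max_size must be positive")
    L = contig.length
    seq = contig.sequence
    if L < min_contig_size:
        return [
            Subcontig(
                id=subcontig_id(contig.strain_id, contig.id, 0, L),
                strain_id=contig.strain_id,
                contig_id=contig.id,
                core_start=0,
                core_end=L,
                sequence=seq,
                excluded=True,
            )
        ]
    pieces = math.ceil(L / max_size)
    core = math.ceil(L / pieces)
    out: list[Subcontig] = []
    for i in range(pieces):
        start = i * core
        end = L if i == pieces - 1 else min((i + 1) * core, L)
        out.append(
            Subcontig(
                id=subcontig_id(contig.strain_id, contig.id, start, end),
                strain_id=contig.strain_id,
                contig_id=contig.id,
                core_start=start,
                core_end=end,
                sequence=seq[max(0, start - overlap) : min(L, end + overlap)],
            )
        )
    return out


def _valid_window_starts(sequence: str, k: int) -> np.ndarray:
    """Start offsets of k-length windows containing only A/C/G/T."""
    n = len(sequence)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(codes, np.frombuffer(b"ACGT", dtype=np.uint8))
    cum = np.concatenate([[0], np.cumsum(bad)])
    return np.nonzero(cum[k:] - cum[:-k] == 0)[0]


def canonical_kmers(sequence: str, k: int) -> list[str]:
    """Canonical (lexicographic min of k-mer and reverse complement) k-mers.

    Windows containing any non-ACGT character are skipped entirely.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    seq = sequence.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    out = []
    for i in _valid_window_starts(seq, k):
        fwd = seq[i : i + k]
        rev = rc[n - i - k : n - i]
        out.append(fwd if fwd <= rev else rev)
    return out


def canonical_kmer_hashes(sequence: str, k: int) -> list[int]:
    """64-bit hashes of the canonical k-mers of every clean window.

    Returns one hash per A/C/G/T-only window, in positional order (a multiset:
    repeated k-mers repeat their hash).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    seq = sequence.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    blake = hashlib.blake2b
    out = []
    for i in _valid_window_starts(seq, k):
        fwd = seq[i : i + k]
        rev = rc[n - i - k : n - i]
        canon = fwd if fwd <= rev else rev
        out.append(
            int.from_bytes(blake(canon.encode("ascii"), digest_size=8).digest(), "little")
        )
    return out


def build_uniqueness_index(
    subcontigs: Iterable[Subcontig], kmer_params: KmerParams
) -> dict[str, int]:
    """Count community-unique canonical k-mers per subcontig.

    A k-mer position counts as unique for its subcontig iff its canonical hash
    has total multiplicity exactly 1 across the concatenated k-mer streams of
    *all* subcontigs — including ``excluded`` ones, whose k-mers still mark
    hashes as non-unique, and including duplicates created by the overlap
    flanks of adjacent subcontigs.  Sets ``unique_kmers`` on each subcontig
    and returns ``{subcontig_id: count}``.
    """
    subcontigs = list(subcontigs)
    k = kmer_params.k
    per_sub: list[np.ndarray] = [
        np.array(canonical_kmer_hashes(s.sequence, k), dtype=np.uint64)
        for s in subcontigs
    ]
    if per_sub:
        all_hashes = np.concatenate([a for a in per_sub if a.size] or [np.empty(0, np.uint64)])
    else:
        all_hashes = np.empty(0, dtype=np.uint64)
    if all_hashes.size:
        values, counts = np.unique(all_hashes, return_counts=True)
        singletons = values[counts == 1]
    else:
        singletons = np.empty(0, dtype=np.uint64)
    result: dict[str, int] = {}
    for sub, hashes in zip(subcontigs, per_sub):
        if hashes.size and singletons.size:
            idx = np.searchsorted(singletons, hashes)
            idx[idx == singletons.size] = 0
            count = int(np.sum(singletons[idx] == hashes))
        else:
            count = 0
        sub.unique_kmers = count
        result[sub.id] = count
    return result


@dataclass
class ReferenceDatabase:
    """Subcontig sequences plus unique-k-mer normalization factors."""

    subcontigs: list[Subcontig]
    kmer_params: KmerParams
    max_subcontig_size: int
    min_contig_size: int = DEFAULT_MIN_CONTIG_SIZE
    overlap: int = DEFAULT_OVERLAP
    strain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        referenced = {s.strain_id for s in self.subcontigs}
        missing = referenced - set(self.strain_ids)
        if missing:
            raise ValueError(f"subcontigs reference unknown strains: {sorted(missing)}")

    def subcontig(self, sub_id: str) -> Subcontig:
        return self._by_id[sub_id]

    @property
    def _by_id(self) -> dict[str, Subcontig]:
        cache = getattr(self, "_by_id_cache", None)
        if cache is None or len(cache) != len(self.subcontigs):
            cache = {s.id: s for s in self.subcontigs}
            object.__setattr__(self, "_by_id_cache", cache)
        return cache

    def strain_genome_lengths(self) -> dict[str, int]:
        """Total genome length per strain (sum of subcontig cores, all contigs)."""
        out: dict[str, int] = {sid: 0 for sid in self.strain_ids}
        for s in self.subcontigs:
            out[s.strain_id] += s.core_length
        return out

    def kmer_table(self) -> pd.DataFrame:
        rows = [
            {
                "subcontig_id": s.id,
                "strain_id": s.strain_id,
                "contig_id": s.contig_id,
                "core_start": s.core_start,
                "core_end": s.core_end,
                "seq_length": len(s.sequence),
                "unique_kmers": -1 if s.unique_kmers is None else s.unique_kmers,
                "excluded": s.excluded,
            }
            for s in self.subcontigs
        ]
        return pd.DataFrame(rows)

    # ---- serialization -------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fasta_path = directory / "subcontigs.fasta.gz"
        # mtime=0 so identical inputs give byte-identical archives
        with gzip.GzipFile(fasta_path, "wb", mtime=0) as gz:
            for s in self.subcontigs:
                gz.write(f">{s.id}\n{s.sequence}\n".encode("ascii"))
        self.kmer_table().to_csv(directory / "kmer_counts.tsv", sep="\t", index=False)
        meta = {
            "format_version": 1,
            "k": self.kmer_params.k,
            "read_size": self.kmer_params.read_length,
            "max_subcontig_size": self.max_subcontig_size,
            "min_contig_size": self.min_contig_size,
            "overlap": self.overlap,
            "hash_name": HASH_NAME,
            "strain_ids": self.strain_ids,
            "tool": "strainquant",
            "tool_version": _version(),
        }
        (directory / "db_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceDatabase":
        directory = Path(directory)
        meta = json.loads((directory / "db_meta.json").read_text())
        table = pd.read_csv(directory / "kmer_counts.tsv", sep="\t")
        sequences: dict[str, str] = {}
        with gzip.open(directory / "subcontigs.fasta.gz", "rt") as handle:
            header = None
            chunks: list[str] = []
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if header is not None:
                        sequences[header] = "".join(chunks)
                    header = line[1:].split()[0]
                    chunks = []
                else:
                    chunks.append(line)
            if header is not None:
                sequences[header] = "".join(chunks)
        subcontigs = []
        for row in table.itertuples(index=False):
            subcontigs.append(
                Subcontig(
                    id=row.subcontig_id,
                    strain_id=row.strain_id,
                    contig_id=str(row.contig_id),
                    core_start=int(row.core_start),
                    core_end=int(row.core_end),
                    sequence=sequences[row.subcontig_id],
                    excluded=bool(row.excluded),
                    unique_kmers=None if row.unique_kmers < 0 else int(row.unique_kmers),
                )
            )
        return cls(
            subcontigs=subcontigs,
            kmer_params=KmerParams(k=int(meta["k"]), read_length=int(meta["read_size"])),
            max_subcontig_size=int(meta["max_subcontig_size"]),
            min_contig_size=int(meta["min_contig_size"]),
            overlap=int(meta["overlap"]),
            strain_ids=list(meta["strain_ids"]),
        )


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("strainquant")
    except Exception:  # pragma: no cover
        return "unknown"


def _strain_id_from_path(path: Path) -> str:
    name = path.name
    for suffix in (".gz", ".fasta", ".fa", ".fna"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def read_genome_fasta(path: str | Path) -> tuple[str, list[Contig]]:
    """Read one strain genome FASTA (plain or gzip); strain ID = file stem."""
    from Bio import SeqIO

    path = Path(path)
    strain_id = _strain_id_from_path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    contigs: list[Contig] = []
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            if seq:
                contigs.append(Contig(id=record.id, strain_id=strain_id, sequence=seq))
    if not contigs:
        raise ValueError(f"no sequences in FASTA file {path}")
    return strain_id, contigs


def build_reference_database(
    fasta_paths: Sequence[str | Path] | None = None,
    *,
    genomes: dict[str, list[Contig]] | None = None,
    max_subcontig_size: int | None = None,
    min_contig_size: int = DEFAULT_MIN_CONTIG_SIZE,
    overlap: int = DEFAULT_OVERLAP,
    read_length: int = DEFAULT_READ_LENGTH,
    k: int | None = None,
) -> ReferenceDatabase:
    """Build the full database: read genomes, split, and index uniqueness.

    Genomes may be given as FASTA paths (one strain per file, strain ID =
    file stem) or directly as ``{strain_id: [Contig, ...]}``.  Deterministic
    for fixed inputs and parameters.
    """
    if (fasta_paths is None) == (genomes is None):
        raise ValueError("provide either fasta_paths or genomes")
    if genomes is None:
        genomes = {}
        for path in fasta_paths:  # type: ignore[union-attr]
            strain_id, contigs = read_genome_fasta(path)
            if strain_id in genomes:
                raise ValueError(f"duplicate strain ID {strain_id!r}")
            genomes[strain_id] = contigs
    if not genomes:
        raise ValueError("no genomes found")

    params = (
        KmerParams(k=k, read_length=read_length)
        if k is not None
        else KmerParams.from_read_length(read_length)
    )
    genome_lengths = [
        (sid, [c.length for c in contigs]) for sid, contigs in genomes.items()
    ]
    max_size = determine_max_subcontig_size(
        genome_lengths, max_subcontig_size, min_contig_size=min_contig_size, k=params.k
    )
    subcontigs: list[Subcontig] = []
    for strain_id, contigs in genomes.items():
        strain_subs: list[Subcontig] = []
        for contig in contigs:
            strain_subs.extend(
                split_contig(contig, max_size, overlap=overlap, min_contig_size=min_contig_size)
            )
        if all(s.excluded for s in strain_subs):
            logger.warning(
                "every contig of strain %s is below the minimum contig size %d; "
                "the strain has no subcontig usable for FUKM",
                strain_id,
                min_contig_size,
            )
        subcontigs.extend(strain_subs)
    build_uniqueness_index(subcontigs, params)
    return ReferenceDatabase(
        subcontigs=subcontigs,
        kmer_params=params,
        max_subcontig_size=max_size,
        min_contig_size=min_contig_size,
        overlap=overlap,
        strain_ids=list(genomes.keys()),
    )
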