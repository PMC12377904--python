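"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's hashing/indexing code
paths: uniqueness is tallied in a plain dictionary over canonical k-mer
*strings*, and mapping verdicts come from an all-offsets substring scan.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import strainquant as sq

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_RC.get(b, "N") for b in reversed(seq))


def oracle_canonical_kmers(seq: str, k: int) -> list[str]:
    out = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(b not in "ACGT" for b in window):
            continue
        rc = oracle_revcomp(window)
        out.append(window if window <= rc else rc)
    return out


def oracle_unique_counts(subcontigs, k: int) -> dict[str, int]:
    """Multiplicity-1 tally of canonical k-mers in a plain dictionary."""
    tally: dict[str, int] = {}
    streams = {}
    for sub in subcontigs:
        kmers = oracle_canonical_kmers(sub.sequence.upper(), k)
        streams[sub.id] = kmers
        for kmer in kmers:
            tally[kmer] = tally.get(kmer, 0) + 1
    return {
        sub_id: sum(1 for kmer in kmers if tally[kmer] == 1)
        for sub_id, kmers in streams.items()
    }


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    found = []
    start = haystack.find(needle)
    while start != -1:
        found.append(start)
        start = haystack.find(needle, start + 1)
    return found


def oracle_map_pair(pair, db) -> tuple[str, str | None]:
    """All-offsets scan over every subcontig, both orientations."""
    hit_subs = set()
    for sub in db.subcontigs:
        seq = sub.sequence.upper()
        for fwd, rev in ((pair.r1, pair.r2), (pair.r2, pair.r1)):
            fwd_hits = _all_occurrences(seq, fwd.upper())
            rev_hits = _all_occurrences(seq, oracle_revcomp(rev.upper()))
            if fwd_hits and rev_hits:
                if max(rev_hits) >= min(fwd_hits) + len(fwd):
                    hit_subs.add(sub.id)
    if not hit_subs:
        return "unmapped", None
    if len(hit_subs) > 1:
        return "ambiguous", None
    return "unique", hit_subs.pop()


@pytest.fixture(scope="session")
def toy_db():
    """3 strains (one near-clonal pair) with multiple subcontigs, small k."""
    strains = toy_strains()
    genomes = {s.strain_id: s.to_contigs() for s in strains}
    return sq.build_reference_database(
        genomes=genomes,
        max_subcontig_size=4000,
        min_contig_size=2000,
        read_length=150,
    )


def toy_strains():
    ancestor = sq.generate_ancestor(10_000, seed=42)
    a = sq.mutate_strain(ancestor, 0.05, seed=43)
    b = sq.mutate_strain(ancestor, 0.05, seed=44)
    b_twin = sq.mutate_strain(b, 0.002, seed=45)
    return [
        sq.StrainSpec(strain_id="alpha", contigs=[a]),
        sq.StrainSpec(strain_id="beta", contigs=[b]),
        sq.StrainSpec(strain_id="beta_twin", contigs=[b_twin], parent_id="beta", divergence=0.002),
    ]


@pytest.fixture(scope="session")
def toy_strain_specs():
    return toy_strains()
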