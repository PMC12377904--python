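"""FUKM-based strain abundance estimation.

FUKM (fragments per thousand unique k-mers per million mapped fragments) is
FPKM with the uniquely mappable portion of the reference replacing its total
length:

    FUKM = mapped_fragments / ((unique_kmers / 1e3) * (total_mapped / 1e6))

Each subcontig yields one FUKM estimate; a strain's abundance is summarized
either as the median over its subcontigs (mFUKM) or as the FUKM of the
subcontig sitting at the p-th cumulative percentile of unique-k-mer mass along
the FUKM-sorted subcontig list (wpFUKM, default p = 60).  Weighting by unique
k-mers lets subcontigs that carry more unambiguous mapping sites dominate the
point estimate.  Subcontigs flagged excluded, or with zero unique k-mers
(FUKM undefined), never enter the FUKM lists — but fragments mapped to them
still count toward the total-mapped denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import FragmentCounts
from .refdb import ReferenceDatabase

DEFAULT_PERCENTILE = 60.0


@dataclass(frozen=True)
class SubcontigMetrics:
    """One subcontig's mapping result and FUKM."""

    subcontig_id: str
    strain_id: str
    mapped_fragments: int
    unique_kmers: int
    fukm: float


@dataclass
class AbundanceReport:
    """Per-strain abundance estimates for one sample."""

    strains: pd.DataFrame  # strain_id, n_subcontigs_used, mfukm, wpfukm, relative_abundance, present
    subcontigs: pd.DataFrame  # subcontig_id, strain_id, unique_kmers, mapped_fragments, fukm
    total_mapped_fragments: int
    total_input_fragments: int
    percentile: float

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.strains.to_csv(directory / "abundances.tsv", sep="\t", index=False)
        self.subcontigs.to_csv(directory / "subcontig_fukm.tsv", sep="\t", index=False)
        return directory


def compute_fukm(mapped_fragments: int, unique_kmers: int, total_mapped: int) -> float:
    """Fragments per thousand unique k-mers per million mapped fragments."""
    if unique_kmers <= 0:
        raise ValueError("FUKM undefined for a subcontig with no unique k-mers")
    if total_mapped <= 0:
        raise ValueError("FUKM undefined when no fragments mapped")
    return mapped_fragments / ((unique_kmers / 1e3) * (total_mapped / 1e6))


def compute_mfukm(metrics: Sequence[SubcontigMetrics]) -> float:
    """Median FUKM over a strain's (usable) subcontigs; 0 if the list is empty."""
    if not metrics:
        return 0.0
    return float(np.median([m.fukm for m in metrics]))


def compute_wpfukm(
    metrics: Sequence[SubcontigMetrics], percentile: float = DEFAULT_PERCENTILE
) -> float:
    """Unique-k-mer-weighted percentile of a strain's subcontig FUKMs.

    Subcontigs are sorted by FUKM ascending (ties broken by subcontig_id for
    determinism); walking the sorted list, the returned value is the FUKM of
    the first subcontig at which the cumulative unique-k-mer count reaches
    ``percentile`` percent of the strain's total.  Empty list -> 0.
    """
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    if not metrics:
        return 0.0
    ordered = sorted(metrics, key=lambda m: (m.fukm, m.subcontig_id))
    total = sum(m.unique_kmers for m in ordered)
    threshold = (percentile / 100.0) * total
    running = 0
    for m in ordered:
        running += m.unique_kmers
        if running >= threshold:
            return m.fukm
    return ordered[-1].fukm  # pragma: no cover (float slack)


def compute_fpkm(strain_fragments: int, genome_length: int, total_mapped: int) -> float:
    """Classic length-normalized baseline: fragments per kb per million mapped."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if total_mapped <= 0:
        return 0.0
    return strain_fragments / ((genome_length / 1e3) * (total_mapped / 1e6))


def subcontig_metrics(
    db: ReferenceDatabase, counts: FragmentCounts
) -> list[SubcontigMetrics]:
    """FUKM per usable subcontig (non-excluded, unique_kmers > 0)."""
    unknown = set(counts.per_subcontig) - {s.id for s in db.subcontigs}
    if unknown:
        raise ValueError(f"counts reference unknown subcontigs: {sorted(unknown)[:5]}")
    total = counts.total_mapped_fragments
    out: list[SubcontigMetrics] = []
    for sub in db.subcontigs:
        if sub.excluded or not sub.unique_kmers:
            continue
        frags = counts.per_subcontig.get(sub.id, 0)
        fukm = 0.0 if total == 0 else compute_fukm(frags, sub.unique_kmers, total)
        out.append(
            SubcontigMetrics(
                subcontig_id=sub.id,
                strain_id=sub.strain_id,
                mapped_fragments=frags,
                unique_kmers=sub.unique_kmers,
                fukm=fukm,
            )
        )
    return out


def summarize(
    db: ReferenceDatabase,
    counts: FragmentCounts,
    percentile: float = DEFAULT_PERCENTILE,
) -> AbundanceReport:
    """Per-strain mFUKM, wpFUKM, relative abundance, and presence call.

    Relative abundance is each strain's share of the summed wpFUKM (all zeros
    when nothing maps); ``present`` is ``wpfukm > 0``.  FPKM over the same
    counts is included as the un-normalized baseline.
    """
    metrics = subcontig_metrics(db, counts)
    by_strain: dict[str, list[SubcontigMetrics]] = {sid: [] for sid in db.strain_ids}
    for m in metrics:
        by_strain[m.strain_id].append(m)

    genome_lengths = db.strain_genome_lengths()
    strain_fragments: dict[str, int] = {sid: 0 for sid in db.strain_ids}
    for sub in db.subcontigs:
        strain_fragments[sub.strain_id] += counts.per_subcontig.get(sub.id, 0)

    rows = []
    for strain_id in db.strain_ids:
        ms = by_strain[strain_id]
        wp = compute_wpfukm(ms, percentile)
        rows.append(
            {
                "strain_id": strain_id,
                "n_subcontigs_used": len(ms),
                "mfukm": compute_mfukm(ms),
                "wpfukm": wp,
                "fpkm": compute_fpkm(
                    strain_fragments[strain_id],
                    genome_lengths[strain_id],
                    counts.total_mapped_fragments,
                ),
                "present": wp > 0,
                "no_usable_subcontigs": len(ms) == 0,
            }
        )
    strains = pd.DataFrame(rows)
    total_wp = strains["wpfukm"].sum()
    strains["relative_abundance"] = (
        strains["wpfukm"] / total_wp if total_wp > 0 else 0.0
    )
    strains = strains[
        [
            "strain_id",
            "n_subcontigs_used",
            "mfukm",
            "wpfukm",
            "fpkm",
            "relative_abundance",
            "present",
            "no_usable_subcontigs",
        ]
    ]
    sub_df = pd.DataFrame(
        [
            {
                "subcontig_id": m.subcontig_id,
                "strain_id": m.strain_id,
                "unique_kmers": m.unique_kmers,
                "mapped_fragments": m.mapped_fragments,
                "fukm": m.fukm,
            }
            for m in metrics
        ]
    )
    return AbundanceReport(
        strains=strains,
        subcontigs=sub_df,
        total_mapped_fragments=counts.total_mapped_fragments,
        total_input_fragments=counts.total_input_fragments,
        percentile=percentile,
    )


def quantify_sample(
    db: ReferenceDatabase,
    pairs,
    percentile: float = DEFAULT_PERCENTILE,
) -> tuple[AbundanceReport, FragmentCounts]:
    """Convenience wrapper: map a read-pair stream and summarize abundances."""
    from .mapping import count_fragments

    counts = count_fragments(pairs, db)
    return summarize(db, counts, percentile), counts
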