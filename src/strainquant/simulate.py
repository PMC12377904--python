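"""Synthetic community and paired-end read simulation.

This module is the benchmark substrate for the whole pipeline: it fabricates
communities of strains with controlled pairwise divergence (from near-clonal
pairs to divergent lineages), assemblies with controlled fragmentation (N50),
abundance vectors from six named distributions (uniform, log-normal,
zero-inflated log-normal, exponential, log-step, missing), and error-free or
substitution-errored paired 150 b reads with a truth table.

Model choices, in brief: abundances are relative *cell* (genome copy)
abundances, so a strain's expected coverage is proportional to its abundance
— fragment counts are multinomial with weights proportional to
``abundance * genome_length``.  Fragment starts are uniform along contigs,
insert sizes are normal (default mean 400, sd 50) truncated to
``[2 * read_length, contig length]``, mates read convergently from opposite
strands, and sequencing errors are i.i.d. substitutions.  Indels, quality
models, and platform-specific error profiles are deliberately out of scope:
the perfect-match mapper discards errored reads wholesale, so a substitution
rate is the only error knob that matters to this method.

All randomness flows from one integer seed through numpy ``SeedSequence``
spawn keys, so every artifact is reproducible bit for bit.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import ReadPair
from .refdb import Contig, canonical_kmer_hashes, compute_n50, reverse_complement

DISTRIBUTIONS = (
    "uniform",
    "log-normal",
    "zero-inflated log-normal",
    "exponential",
    "log-step",
    "missing",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


@dataclass
class StrainSpec:
    """One community member: its (possibly fragmented) genome assembly."""

    strain_id: str
    contigs: list[str]
    parent_id: str | None = None
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")

    @property
    def genome(self) -> str:
        return "".join(self.contigs)

    @property
    def genome_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def contig_lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    def to_contigs(self) -> list[Contig]:
        return [
            Contig(id=f"contig{i:03d}", strain_id=self.strain_id, sequence=seq)
            for i, seq in enumerate(self.contigs)
        ]


@dataclass(frozen=True)
class ReadParams:
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    n_fragments: int = 10_000


@dataclass
class CommunityDesign:
    """Simulator truth: strains, true composition, and read parameters."""

    strains: list[StrainSpec]
    true_abundances: np.ndarray
    distribution_name: str
    read_params: ReadParams
    seed: int

    def __post_init__(self) -> None:
        self.true_abundances = np.asarray(self.true_abundances, dtype=float)
        if len(self.true_abundances) != len(self.strains):
            raise ValueError("one abundance per strain required")
        if (self.true_abundances < 0).any():
            raise ValueError("abundances must be non-negative")
        total = self.true_abundances.sum()
        if not np.isclose(total, 1.0):
            raise ValueError(f"abundances must sum to 1, got {total}")


def generate_ancestor(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random genome with the stated GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = _rng(seed, 0)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def mutate_strain(parent: str, divergence: float, seed: int = 0) -> str:
    """Substitute each position to a different base with probability divergence."""
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    if divergence == 0.0:
        return parent
    rng = _rng(seed, 1)
    codes = np.frombuffer(parent.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(codes.size) < divergence)[0]
    if hit.size:
        base_idx = np.searchsorted(_BASES, codes[hit])
        shift = rng.integers(1, 4, size=hit.size)
        codes[hit] = _BASES[(base_idx + shift) % 4]
    return codes.tobytes().decode("ascii")


def fragment_assembly(genome: str, target_n50: int, seed: int = 0) -> list[str]:
    """Cut a genome at random positions so the piece N50 lands near target.

    Guarantees the resulting N50 is within a factor of two of ``target_n50``
    and that concatenating the pieces reconstructs the genome exactly.
    """
    L = len(genome)
    if target_n50 > L:
        raise ValueError("target_n50 cannot exceed the genome length")
    if target_n50 == L:
        return [genome]
    rng = _rng(seed, 2)
    n_cuts = max(1, round(L / target_n50) - 1)
    for _ in range(500):
        cuts = np.sort(rng.choice(L - 1, size=n_cuts, replace=False) + 1)
        bounds = np.concatenate([[0], cuts, [L]])
        lengths = np.diff(bounds)
        n50 = compute_n50(lengths.tolist())
        if 0.5 * target_n50 <= n50 <= 2 * target_n50:
            return [genome[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    # deterministic fallback: even split at the target size
    bounds = list(range(0, L, target_n50)) + [L]
    return [genome[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def draw_abundances(
    distribution_name: str,
    n_strains: int,
    seed: int = 0,
    *,
    sigma: float = 1.0,
    mu: float = 0.0,
    zero_probability: float = 0.25,
    n_tiers: int = 2,
    step: float = 30.0,
    absent: Sequence[int] | None = None,
    n_absent: int | None = None,
) -> np.ndarray:
    """Relative abundance vector from one of the six named distributions.

    ``log-step`` places contiguous tiers of strains a constant ``step``-fold
    apart; ``missing`` zeroes an explicit or randomly chosen subset of a
    uniform community; ``zero-inflated log-normal`` drops each strain with
    probability ``zero_probability`` before log-normal draws.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if distribution_name not in DISTRIBUTIONS:
        raise ValueError(
            f"unknown distribution {distribution_name!r}; choose from {DISTRIBUTIONS}"
        )
    rng = _rng(seed, 3)
    if distribution_name == "uniform":
        raw = np.ones(n_strains)
    elif distribution_name == "log-normal":
        raw = np.exp(rng.normal(mu, sigma, n_strains))
    elif distribution_name == "zero-inflated log-normal":
        raw = np.exp(rng.normal(mu, sigma, n_strains))
        raw[rng.random(n_strains) < zero_probability] = 0.0
    elif distribution_name == "exponential":
        raw = rng.exponential(1.0, n_strains)
    elif distribution_name == "log-step":
        tier_size = -(-n_strains // n_tiers)  # ceil
        tiers = np.arange(n_strains) // tier_size
        raw = step ** (n_tiers - 1 - tiers).astype(float)
    else:  # missing
        raw = np.ones(n_strains)
        if absent is None:
            k = n_absent if n_absent is not None else max(1, n_strains // 4)
            absent = rng.choice(n_strains, size=k, replace=False)
        raw[np.asarray(list(absent), dtype=int)] = 0.0
    total = raw.sum()
    if total <= 0:
        raise ValueError("all strains drew zero abundance")
    return raw / total


def simulate_reads(design: CommunityDesign) -> tuple[list[ReadPair], pd.DataFrame]:
    """Generate paired reads for a community design, plus the truth table.

    Fragment counts per strain are multinomial with weights proportional to
    ``abundance * genome_length`` (cell-abundance semantics: coverage tracks
    abundance).  Returns the pairs in deterministic order and a truth table
    with one row per strain.
    """
    rp = design.read_params
    rl = rp.read_length
    weights = design.true_abundances * np.array(
        [s.genome_length for s in design.strains], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("no strain has positive abundance")
    rng = _rng(design.seed, 4)
    per_strain = rng.multinomial(rp.n_fragments, weights / weights.sum())

    pairs: list[ReadPair] = []
    rows = []
    for s_idx, (strain, n_frags) in enumerate(zip(design.strains, per_strain)):
        rows.append(
            {
                "strain_id": strain.strain_id,
                "true_abundance": float(design.true_abundances[s_idx]),
                "fragments_emitted": int(n_frags),
                "genome_length": strain.genome_length,
            }
        )
        if n_frags == 0:
            continue
        eligible = [c for c in strain.contigs if len(c) >= 2 * rl]
        if not eligible:
            raise ValueError(
                f"strain {strain.strain_id} has no contig long enough for a "
                f"{2 * rl} b fragment"
            )
        lengths = np.array([len(c) for c in eligible], dtype=float)
        contig_idx = rng.choice(len(eligible), size=n_frags, p=lengths / lengths.sum())
        clens = np.array([len(c) for c in eligible])[contig_idx]
        inserts = np.rint(rng.normal(rp.insert_mean, rp.insert_sd, n_frags)).astype(int)
        bad = (inserts < 2 * rl) | (inserts > clens)
        tries = 0
        while bad.any():
            tries += 1
            if tries > 1000:
                raise RuntimeError(
                    "failed to draw a fragment insert fitting the contig after "
                    "1000 attempts"
                )
            inserts[bad] = np.rint(
                rng.normal(rp.insert_mean, rp.insert_sd, int(bad.sum()))
            ).astype(int)
            bad = (inserts < 2 * rl) | (inserts > clens)
        starts = np.floor(rng.random(n_frags) * (clens - inserts + 1)).astype(int)
        flips = rng.random(n_frags) < 0.5
        for j in range(n_frags):
            contig = eligible[contig_idx[j]]
            p, ins = int(starts[j]), int(inserts[j])
            fwd = contig[p : p + rl]
            rev = reverse_complement(contig[p + ins - rl : p + ins])
            if rp.error_rate > 0:
                fwd = _sequencing_errors(fwd, rp.error_rate, rng)
                rev = _sequencing_errors(rev, rp.error_rate, rng)
            r1, r2 = (rev, fwd) if flips[j] else (fwd, rev)
            pairs.append(
                ReadPair(
                    id=f"{strain.strain_id}.{j}",
                    r1=r1,
                    r2=r2,
                    q1="I" * len(r1),
                    q2="I" * len(r2),
                )
            )
    truth = pd.DataFrame(rows)
    assert int(truth["fragments_emitted"].sum()) == rp.n_fragments
    return pairs, truth


def _sequencing_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    codes = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(codes.size) < rate)[0]
    if hit.size == 0:
        return read
    base_idx = np.searchsorted(_BASES, codes[hit])
    shift = rng.integers(1, 4, size=hit.size)
    codes[hit] = _BASES[(base_idx + shift) % 4]
    return codes.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# canned community builders


def divergent_community(
    seed: int,
    n_strains: int = 10,
    genome_length: int = 50_000,
    divergence: float = 0.03,
    gc: float = 0.5,
    target_n50: int | None = None,
) -> list[StrainSpec]:
    """Strains independently mutated from one ancestor (pairwise ~2x divergence)."""
    ancestor = generate_ancestor(genome_length, gc, seed=seed)
    strains = []
    for i in range(n_strains):
        genome = mutate_strain(ancestor, divergence, seed=_child_seed(seed, 10 + i))
        contigs = (
            [genome]
            if target_n50 is None
            else fragment_assembly(genome, target_n50, seed=_child_seed(seed, 100 + i))
        )
        strains.append(
            StrainSpec(
                strain_id=f"strain{i:02d}",
                contigs=contigs,
                parent_id="ancestor",
                divergence=divergence,
            )
        )
    return strains


def clonal_pairs_community(
    seed: int,
    n_lineages: int = 8,
    n_pairs: int = 4,
    genome_length: int = 100_000,
    lineage_divergence: float = 0.03,
    pair_divergence: float = 0.001,
    gc: float = 0.5,
    target_n50: int | None = 25_000,
) -> list[StrainSpec]:
    """Divergent lineages, the first ``n_pairs`` of which carry a near-clonal twin.

    With the defaults: 8 lineages at 3% divergence each from a common ancestor
    (pairwise ~5.9%), 4 of them paired with a 0.1%-divergent partner — a
    12-strain community mixing easy and near-clonal quantification targets.
    """
    if n_pairs > n_lineages:
        raise ValueError("n_pairs cannot exceed n_lineages")
    ancestor = generate_ancestor(genome_length, gc, seed=seed)
    genomes: list[tuple[str, str, str | None, float]] = []
    for i in range(n_lineages):
        lineage = mutate_strain(ancestor, lineage_divergence, seed=_child_seed(seed, 10 + i))
        genomes.append((f"lineage{i:02d}", lineage, "ancestor", lineage_divergence))
        if i < n_pairs:
            twin = mutate_strain(lineage, pair_divergence, seed=_child_seed(seed, 50 + i))
            genomes.append(
                (f"lineage{i:02d}_twin", twin, f"lineage{i:02d}", pair_divergence)
            )
    strains = []
    for j, (sid, genome, parent, div) in enumerate(genomes):
        contigs = (
            [genome]
            if target_n50 is None
            else fragment_assembly(genome, target_n50, seed=_child_seed(seed, 200 + j))
        )
        strains.append(
            StrainSpec(strain_id=sid, contigs=contigs, parent_id=parent, divergence=div)
        )
    return strains


def _child_seed(seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=(index,)).generate_state(1)[0] % (2**31)
    )


def fragments_for_coverage(
    strains: Sequence[StrainSpec],
    abundances: np.ndarray,
    mean_coverage: float,
    read_length: int = 150,
) -> int:
    """Total fragments so that community-wide mean coverage hits the target."""
    total_bases = sum(s.genome_length for s in strains)
    return int(round(mean_coverage * total_bases / (2 * read_length)))


def clonal_pairs_design(
    seed: int,
    mean_coverage: float = 40.0,
    read_length: int = 150,
    **community_kwargs,
) -> CommunityDesign:
    """Uniform-abundance design over the near-clonal-pairs community."""
    strains = clonal_pairs_community(seed, **community_kwargs)
    abundances = draw_abundances("uniform", len(strains), seed=seed)
    n_fragments = fragments_for_coverage(strains, abundances, mean_coverage, read_length)
    return CommunityDesign(
        strains=strains,
        true_abundances=abundances,
        distribution_name="uniform",
        read_params=ReadParams(read_length=read_length, n_fragments=n_fragments),
        seed=seed,
    )


def strain_unique_kmer_fractions(
    strains: Sequence[StrainSpec], k: int = 301
) -> dict[str, float]:
    """Fraction of each strain's k-mers that are unique within the community.

    Mirrors the community-design filter that every member should keep at
    least a few percent of its k-mers unique (near-clonal duplicates fail it).
    """
    per_strain: dict[str, np.ndarray] = {}
    for s in strains:
        hashes: list[int] = []
        for contig in s.contigs:
            hashes.extend(canonical_kmer_hashes(contig, k))
        per_strain[s.strain_id] = np.array(hashes, dtype=np.uint64)
    stacked = [a for a in per_strain.values() if a.size]
    if not stacked:
        return {sid: 0.0 for sid in per_strain}
    values, counts = np.unique(np.concatenate(stacked), return_counts=True)
    singles = values[counts == 1]
    out = {}
    for sid, hashes in per_strain.items():
        if hashes.size == 0:
            out[sid] = 0.0
            continue
        idx = np.searchsorted(singles, hashes)
        idx[idx == singles.size] = 0
        out[sid] = float(np.mean(singles[idx] == hashes)) if singles.size else 0.0
    return out


# ---------------------------------------------------------------------------
# file output


def write_fastq_pairs(
    pairs: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write mates to paired FASTQ files; .gz output is byte-reproducible."""
    for path, attr_seq, attr_q in ((r1_path, "r1", "q1"), (r2_path, "r2", "q2")):
        path = Path(path)
        if path.name.endswith(".gz"):
            handle = gzip.GzipFile(path, "wb", mtime=0)
        else:
            handle = open(path, "wb")
        with handle:
            for pair in pairs:
                seq = getattr(pair, attr_seq)
                qual = getattr(pair, attr_q) or "I" * len(seq)
                handle.write(f"@{pair.id}\n{seq}\n+\n{qual}\n".encode("ascii"))


def write_strain_fastas(strains: Sequence[StrainSpec], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in strains:
        path = directory / f"{s.strain_id}.fasta"
        with open(path, "w") as handle:
            for i, contig in enumerate(s.contigs):
                handle.write(f">contig{i:03d}\n{contig}\n")
        paths.append(path)
    return paths


def write_design_outputs(design: CommunityDesign, directory: str | Path) -> Path:
    """Write per-strain FASTAs, paired FASTQ, and the truth table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pairs, truth = simulate_reads(design)
    write_strain_fastas(design.strains, directory / "genomes")
    write_fastq_pairs(pairs, directory / "sim_R1.fastq.gz", directory / "sim_R2.fastq.gz")
    truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    echo = {
        "distribution": design.distribution_name,
        "seed": design.seed,
        "read_length": design.read_params.read_length,
        "insert_mean": design.read_params.insert_mean,
        "insert_sd": design.read_params.insert_sd,
        "error_rate": design.read_params.error_rate,
        "n_fragments": design.read_params.n_fragments,
        "strains": [
            {
                "strain_id": s.strain_id,
                "parent_id": s.parent_id,
                "divergence": s.divergence,
                "contig_lengths": s.contig_lengths,
            }
            for s in design.strains
        ],
        "true_abundances": design.true_abundances.tolist(),
    }
    (directory / "design.json").write_text(json.dumps(echo, indent=2) + "\n")
    return directory
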