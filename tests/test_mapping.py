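"""Read filtering, exact paired mapping, and SAM import."""

import random

import numpy as np
import pytest

import strainquant as sq
from strainquant.mapping import trim_poly_g

from conftest import oracle_map_pair, oracle_revcomp


def _pair(r1, r2, pid="p"):
    return sq.ReadPair(id=pid, r1=r1, r2=r2)


class TestFilterReadPair:
    def test_n_base_drops_pair(self):
        pair = _pair("A" * 60 + "N" + "A" * 60, "C" * 100)
        assert sq.filter_read_pair(pair) is None

    def test_short_mate_drops_pair(self):
        pair = _pair("A" * 40, "C" * 100)
        assert sq.filter_read_pair(pair) is None

    def test_poly_g_tail_trimmed(self):
        body = sq.generate_ancestor(138, seed=1).replace("G", "A")
        pair = _pair(body + "G" * 12, "C" * 100)
        kept = sq.filter_read_pair(pair)
        assert kept is not None
        assert kept.r1 == body
        assert len(kept.r1) == 138

    def test_short_g_run_untouched(self):
        seq = "A" * 100 + "G" * 5
        assert trim_poly_g(seq) == seq

    def test_trim_below_min_length_drops(self):
        pair = _pair("A" * 45 + "G" * 20, "C" * 100)
        assert sq.filter_read_pair(pair) is None

    def test_clean_pair_passes_unchanged(self):
        pair = _pair("ACGT" * 30, "TGCA" * 30)
        assert sq.filter_read_pair(pair) is pair


def _read_pair_from(seq, start, insert, read_len=100, flip=False):
    fwd = seq[start : start + read_len]
    rev = oracle_revcomp(seq[start + insert - read_len : start + insert])
    return _pair(rev, fwd) if flip else _pair(fwd, rev)


class TestExactMapper:
    def test_unique_region_maps_uniquely(self, toy_db):
        alpha_sub = next(s for s in toy_db.subcontigs if s.strain_id == "alpha")
        pair = _read_pair_from(alpha_sub.sequence, 10, 300)
        mapper = sq.ExactFragmentMapper(toy_db)
        result = mapper.map_pair(pair)
        assert result.status == "unique"
        assert result.subcontig_id == alpha_sub.id

    def test_shared_sequence_is_ambiguous(self, toy_db, toy_strain_specs):
        # beta and beta_twin differ at ~0.2%: find a window identical in both
        beta = toy_strain_specs[1].contigs[0]
        twin = toy_strain_specs[2].contigs[0]
        start = next(
            i for i in range(0, len(beta) - 400) if beta[i : i + 400] == twin[i : i + 400]
        )
        pair = _read_pair_from(beta, start, 350)
        result = sq.ExactFragmentMapper(toy_db).map_pair(pair)
        assert result.status == "ambiguous"

    def test_single_substitution_unmaps(self, toy_db):
        sub = next(s for s in toy_db.subcontigs if s.strain_id == "alpha")
        pair = _read_pair_from(sub.sequence, 50, 300)
        mutated = "A" if pair.r1[50] != "A" else "C"
        pair = _pair(pair.r1[:50] + mutated + pair.r1[51:], pair.r2)
        assert sq.ExactFragmentMapper(toy_db).map_pair(pair).status == "unmapped"

    def test_wrong_orientation_unmaps(self, toy_db):
        sub = next(s for s in toy_db.subcontigs if s.strain_id == "alpha")
        seq = sub.sequence
        fwd = seq[10:110]
        downstream_fwd = seq[300:400]  # both forward: no convergent placement
        assert (
            sq.ExactFragmentMapper(toy_db).map_pair(_pair(fwd, downstream_fwd)).status
            == "unmapped"
        )

    def test_negative_inner_gap_rejected(self, toy_db):
        sub = next(s for s in toy_db.subcontigs if s.strain_id == "alpha")
        seq = sub.sequence
        # mates overlap: the reverse mate starts before the forward mate ends
        pair = _pair(seq[10:110], oracle_revcomp(seq[60:160]))
        assert sq.ExactFragmentMapper(toy_db).map_pair(pair).status == "unmapped"

    def test_agrees_with_all_offsets_oracle(self, toy_db, toy_strain_specs):
        rng = np.random.default_rng(77)
        mapper = sq.ExactFragmentMapper(toy_db)
        genomes = [s.contigs[0] for s in toy_strain_specs]
        checked = {"unique": 0, "ambiguous": 0, "unmapped": 0}
        for i in range(300):
            genome = genomes[int(rng.integers(len(genomes)))]
            insert = int(rng.integers(250, 450))
            start = int(rng.integers(0, len(genome) - insert))
            pair = _read_pair_from(genome, start, insert, flip=bool(rng.integers(2)))
            if rng.random() < 0.3:  # inject a substitution
                pos = int(rng.integers(len(pair.r1)))
                base = "ACGT"[int(rng.integers(4))]
                pair = _pair(pair.r1[:pos] + base + pair.r1[pos + 1 :], pair.r2, pair.id)
            expected_status, expected_sub = oracle_map_pair(pair, toy_db)
            result = mapper.map_pair(pair)
            assert (result.status, result.subcontig_id) == (expected_status, expected_sub)
            checked[result.status] += 1
        assert all(checked.values()), f"verdict mix not exercised: {checked}"


class TestCountFragments:
    def test_empty_stream(self, toy_db):
        counts = sq.count_fragments([], toy_db)
        assert counts.total_input_fragments == 0
        assert counts.total_mapped_fragments == 0
        assert all(v == 0 for v in counts.per_subcontig.values())

    def test_conservation_and_order_invariance(self, toy_db, toy_strain_specs):
        rng = np.random.default_rng(5)
        genome = toy_strain_specs[0].contigs[0]
        pairs = [
            _read_pair_from(genome, int(rng.integers(0, len(genome) - 400)), 400, flip=bool(i % 2))
            for i in range(200)
        ]
        counts = sq.count_fragments(pairs, toy_db)
        assert counts.total_mapped_fragments == sum(counts.per_subcontig.values())
        shuffled = pairs.copy()
        random.Random(1).shuffle(shuffled)
        assert sq.count_fragments(shuffled, toy_db) == counts

    def test_error_rate_never_raises_mapped_total(self, toy_strain_specs, toy_db):
        design_kwargs = dict(
            strains=toy_strain_specs,
            true_abundances=np.ones(3) / 3,
            distribution_name="uniform",
            seed=3,
        )
        totals = []
        for err in (0.0, 0.01, 0.05):
            design = sq.CommunityDesign(
                read_params=sq.ReadParams(read_length=100, n_fragments=500, error_rate=err),
                **design_kwargs,
            )
            pairs, _ = sq.simulate_reads(design)
            totals.append(sq.count_fragments(pairs, toy_db).total_mapped_fragments)
        assert totals[0] >= totals[1] >= totals[2]

    def test_shared_region_fragments_never_counted(self, toy_db, toy_strain_specs):
        beta = toy_strain_specs[1].contigs[0]
        twin = toy_strain_specs[2].contigs[0]
        shared_starts = [
            i for i in range(0, len(beta) - 400, 97) if beta[i : i + 400] == twin[i : i + 400]
        ]
        assert shared_starts, "fixture should contain shared 400 b windows"
        pairs = [_read_pair_from(beta, s, 400) for s in shared_starts]
        counts = sq.count_fragments(pairs, toy_db)
        assert counts.total_mapped_fragments == 0


def _write_sam(path, db, records):
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for sub in db.subcontigs:
        lines.append(f"@SQ\tSN:{sub.id}\tLN:{len(sub.sequence)}")
    lines.extend(records)
    path.write_text("\n".join(lines) + "\n")


class TestImportSamCounts:
    def _proper_pair(self, name, ref, seq1, seq2, pos1, pos2, nm=0, cigar=None, flags=(99, 147)):
        c1 = cigar or f"{len(seq1)}M"
        c2 = cigar or f"{len(seq2)}M"
        tlen = pos2 + len(seq2) - pos1
        return [
            f"{name}\t{flags[0]}\t{ref}\t{pos1 + 1}\t60\t{c1}\t=\t{pos2 + 1}\t{tlen}\t{seq1}\t*\tNM:i:{nm}",
            f"{name}\t{flags[1]}\t{ref}\t{pos2 + 1}\t60\t{c2}\t=\t{pos1 + 1}\t{-tlen}\t{seq2}\t*\tNM:i:{nm}",
        ]

    def test_perfect_proper_pair_counted(self, toy_db, tmp_path):
        sub = toy_db.subcontigs[0]
        seq = sub.sequence
        sam = tmp_path / "ok.sam"
        _write_sam(
            sam, toy_db,
            self._proper_pair("frag1", sub.id, seq[0:100], oracle_revcomp(seq[200:300]), 0, 200),
        )
        counts = sq.import_sam_counts(sam, toy_db)
        assert counts.per_subcontig[sub.id] == 1
        assert counts.total_mapped_fragments == 1
        assert counts.total_input_fragments == 1

    def test_soft_clip_not_counted(self, toy_db, tmp_path):
        sub = toy_db.subcontigs[0]
        seq = sub.sequence
        sam = tmp_path / "clip.sam"
        _write_sam(
            sam, toy_db,
            self._proper_pair(
                "frag1", sub.id, seq[0:100], oracle_revcomp(seq[200:300]), 0, 200,
                cigar="90M10S",
            ),
        )
        counts = sq.import_sam_counts(sam, toy_db)
        assert counts.total_mapped_fragments == 0
        assert counts.total_input_fragments == 1

    def test_nonzero_edit_distance_not_counted(self, toy_db, tmp_path):
        sub = toy_db.subcontigs[0]
        seq = sub.sequence
        sam = tmp_path / "nm.sam"
        _write_sam(
            sam, toy_db,
            self._proper_pair("frag1", sub.id, seq[0:100], oracle_revcomp(seq[200:300]), 0, 200, nm=1),
        )
        assert sq.import_sam_counts(sam, toy_db).total_mapped_fragments == 0

    def test_secondary_only_not_counted(self, toy_db, tmp_path):
        sub = toy_db.subcontigs[0]
        seq = sub.sequence
        sam = tmp_path / "sec.sam"
        _write_sam(
            sam, toy_db,
            self._proper_pair(
                "frag1", sub.id, seq[0:100], oracle_revcomp(seq[200:300]), 0, 200,
                flags=(99 + 256, 147 + 256),
            ),
        )
        counts = sq.import_sam_counts(sam, toy_db)
        assert counts.total_mapped_fragments == 0
        assert counts.total_input_fragments == 0

    def test_unknown_reference_rejected(self, toy_db, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:not_a_subcontig\tLN:1000\n")
        with pytest.raises(ValueError, match="not_a_subcontig"):
            sq.import_sam_counts(sam, toy_db)

    def test_missing_nm_tag_instructs_realign(self, toy_db, tmp_path):
        sub = toy_db.subcontigs[0]
        seq = sub.sequence
        records = self._proper_pair(
            "frag1", sub.id, seq[0:100], oracle_revcomp(seq[200:300]), 0, 200
        )
        records = [r.rsplit("\tNM:i:0", 1)[0] for r in records]
        sam = tmp_path / "nonm.sam"
        _write_sam(sam, toy_db, records)
        with pytest.raises(ValueError, match="re-align"):
            sq.import_sam_counts(sam, toy_db)


class TestFastqRoundtrip:
    def test_pairs_survive_fastq_roundtrip(self, tmp_path):
        from strainquant.simulate import write_fastq_pairs

        pairs = [
            sq.ReadPair(id=f"p{i}", r1="ACGT" * 30, r2="TTGA" * 30) for i in range(5)
        ]
        r1, r2 = tmp_path / "r_R1.fastq.gz", tmp_path / "r_R2.fastq.gz"
        write_fastq_pairs(pairs, r1, r2)
        back = list(sq.read_paired_fastq(r1, r2))
        assert [(p.id, p.r1, p.r2) for p in back] == [
            (p.id, p.r1, p.r2) for p in pairs
        ]
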