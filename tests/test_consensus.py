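"""Mapping, pileups, dominant-strain consensus calling, marker selection."""

import numpy as np
import pytest

from straintrace import (
    MarkerDB,
    Read,
    build_pileup,
    call_consensus,
    map_reads,
    select_markers,
)
from straintrace.consensus import (
    ConsensusSequence,
    Pileup,
    ReadAlignment,
    alignments_from_sam,
    alignments_to_sam,
    pileup_from_alignments,
)
from straintrace._seq import encode, revcomp
from straintrace.simulate import mutate_strain, simulate_reads


def q(n):
    return tuple([37] * n)


def brute_force_best(read_seq, db, min_identity):
    """Enumerate every gapless placement of the read (both strands) on every
    marker and return the deterministic best, mirroring the mapper contract."""
    best = None
    L = len(read_seq)
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        for mid in sorted(db.sequences):
            ref = db.sequences[mid]
            for start in range(len(ref) - L + 1):
                mism = sum(1 for a, b in zip(seq, ref[start : start + L]) if a != b)
                ident = 1 - mism / L
                if ident < min_identity:
                    continue
                key = (-ident, mid, start, strand)
                if best is None or key < best[0]:
                    best = (key, mid, start, strand, mism)
    return best


class TestMapReads:
    def test_exact_substring_maps_at_offset(self, small_db):
        mid = small_db.marker_ids[0]
        read = Read("r", small_db.sequences[mid][10:110], q(100))
        (aln,) = map_reads([read], small_db)
        assert (aln.marker_id, aln.start, aln.mismatches) == (mid, 10, 0)

    def test_below_identity_threshold_unmapped(self, small_db, rng):
        mid = small_db.marker_ids[0]
        seq = mutate_strain(small_db.sequences[mid][:100], 0.15, rng)
        assert map_reads([Read("r", seq, q(100))], small_db, min_identity=0.90) == []

    def test_reverse_strand_read_mapped_in_marker_orientation(self, small_db):
        mid = small_db.marker_ids[0]
        frag = small_db.sequences[mid][50:150]
        (aln,) = map_reads([Read("r", revcomp(frag), q(100))], small_db)
        assert aln.strand == "-"
        assert aln.aligned_bases == frag
        assert aln.start == 50

    def test_best_placement_matches_brute_force(self, small_db, rng):
        # randomized reads with errors: mapper's best placement equals the
        # exhaustive enumeration's under the same tie rules
        mids = small_db.marker_ids
        for i in range(25):
            mid = mids[i % len(mids)]
            start = int(rng.integers(0, 400))
            frag = small_db.sequences[mid][start : start + 100]
            seq = mutate_strain(frag, float(rng.uniform(0, 0.06)), rng)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            got = map_reads([Read("r", seq, q(100))], small_db)
            want = brute_force_best(seq, small_db, 0.90)
            if want is None:
                assert got == []
            else:
                (aln,) = got
                _, wmid, wstart, wstrand, wmism = want
                assert (aln.marker_id, aln.start, aln.strand, aln.mismatches) == (
                    wmid, wstart, wstrand, wmism,
                )

    def test_prefers_higher_identity_marker(self):
        ref_a = "ACGTACGTAC" * 10
        ref_b = mutate_strain(ref_a, 0.05, 1)
        db = MarkerDB({"sp": ["mA", "mB"]}, {"mA": ref_a, "mB": ref_b})
        read = Read("r", mutate_strain(ref_a, 0.01, 2), q(100))
        (aln,) = map_reads([read], db)
        assert aln.marker_id == "mA"


class TestPileup:
    def test_tiling_reads_conserve_depth(self, small_db):
        mid = small_db.marker_ids[0]
        seq = small_db.sequences[mid]
        reads = [Read(f"r{i}", seq[i * 100 : i * 100 + 100], q(100)) for i in range(5)]
        alns = map_reads(reads, small_db)
        piles = build_pileup(alns, small_db)
        depth = piles[mid].depth
        assert depth.sum() == sum(len(a.aligned_bases) for a in alns)
        assert (depth[:500] == 1).all()
        # all counts on the reference base
        ref_codes = encode(seq)
        assert (piles[mid].counts[ref_codes, np.arange(500)] == depth).all()

    def test_single_substitution_creates_one_nonreference_count(self, small_db):
        mid = small_db.marker_ids[0]
        seq = small_db.sequences[mid]
        frag = list(seq[:100])
        frag[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[5]]
        alns = map_reads([Read("r", "".join(frag), q(100))], small_db)
        piles = build_pileup(alns, small_db)
        ref_codes = encode(seq[:100])
        counts = piles[mid].counts[:, :100]
        nonref = counts.sum(axis=0) - counts[ref_codes, np.arange(100)]
        assert nonref.sum() == 1 and nonref[5] == 1

    def test_out_of_bounds_alignment_rejected(self, small_db):
        mid = small_db.marker_ids[0]
        bad = ReadAlignment("r", mid, 450, "+", "A" * 100, 0)
        with pytest.raises(ValueError):
            build_pileup([bad], small_db)


class TestCallConsensus:
    def make_pileup(self, column_counts):
        counts = np.array(column_counts, dtype=np.uint32).T
        return Pileup("m", counts)

    def test_majority_called(self):
        p = self.make_pileup([[7, 3, 0, 0]])  # A:7 C:3
        assert call_consensus(p, min_depth=3).sequence == "A"

    def test_zero_depth_masked(self):
        p = self.make_pileup([[0, 0, 0, 0]])
        assert call_consensus(p).sequence == "N"

    def test_plurality_tie_masked(self):
        p = self.make_pileup([[5, 5, 0, 0]])
        assert call_consensus(p).sequence == "N"

    def test_majority_fraction_boundary_masked(self):
        # frequency exactly 0.5 does not exceed majority_frac=0.5
        p = self.make_pileup([[5, 3, 2, 0]])
        assert call_consensus(p).sequence == "N"
        p2 = self.make_pileup([[6, 3, 1, 0]])
        assert call_consensus(p2).sequence == "A"

    def test_min_depth_monotonicity(self, rng):
        counts = rng.integers(0, 6, size=(4, 200)).astype(np.uint32)
        p = Pileup("m", counts)
        masked = [
            call_consensus(p, min_depth=d).sequence.count("N") for d in (1, 3, 5, 10)
        ]
        assert masked == sorted(masked)


class TestSelectMarkers:
    def make_cons(self, mid, sp, unmasked):
        n = 500
        n_unmasked = int(round(unmasked * n))
        seq = "A" * n_unmasked + "N" * (n - n_unmasked)
        return ConsensusSequence("s", sp, mid, seq, n_unmasked / n)

    def test_fully_unmasked_species_retained(self, small_db):
        cons = [self.make_cons(mid, "s01", 1.0) for mid in small_db.species_markers["s01"]]
        kept = select_markers(cons, small_db)
        assert set(kept) == {"s01"}
        assert len(kept["s01"]) == 3

    def test_uncovered_species_dropped(self, small_db):
        cons = [self.make_cons(mid, "s01", 0.0) for mid in small_db.species_markers["s01"]]
        assert select_markers(cons, small_db) == {}

    def test_minority_of_markers_drops_species(self):
        db = MarkerDB(
            {"sp": [f"m{i}" for i in range(10)]},
            {f"m{i}": "ACGT" * 125 for i in range(10)},
        )
        # 4 of 10 markers retained at min_markers_frac 0.5 -> species dropped
        cons = [self.make_cons(f"m{i}", "sp", 1.0 if i < 4 else 0.1) for i in range(10)]
        assert select_markers(cons, db) == {}
        cons5 = [self.make_cons(f"m{i}", "sp", 1.0 if i < 5 else 0.1) for i in range(10)]
        assert set(select_markers(cons5, db)) == {"sp"}


class TestSamRoundTrip:
    def test_export_import_preserves_alignments(self, small_db, tmp_path, rng):
        mid = small_db.marker_ids[0]
        reads = simulate_reads(small_db.sequences[mid], 3, 100, 0.01, seed=rng)
        alns = map_reads(reads, small_db)
        path = tmp_path / "out.sam"
        alignments_to_sam(alns, small_db, path)
        back = alignments_from_sam(path, small_db)
        assert {(a.read_id, a.marker_id, a.start, a.strand, a.mismatches) for a in alns} == {
            (a.read_id, a.marker_id, a.start, a.strand, a.mismatches) for a in back
        }


class TestRecoveryContracts:
    def test_single_strain_recovery(self, rng):
        # one strain at 20x depth, 1% error: consensus matches truth at
        # >= 99.9% of unmasked positions
        from straintrace import make_marker_db

        db = make_marker_db(1, 1, 2000, seed=8)
        mid = db.marker_ids[0]
        strain = mutate_strain(db.sequences[mid], 0.01, rng)
        reads = simulate_reads(strain, 20, 100, 0.01, seed=rng)
        piles = build_pileup(map_reads(reads, db), db)
        cons = call_consensus(piles[mid])
        matches = total = 0
        for a, b in zip(cons.sequence, strain):
            if a != "N":
                total += 1
                matches += a == b
        assert total > 1500
        assert matches / total >= 0.999

    def test_dominant_strain_recovery_in_mixture(self, rng):
        # 80:20 two-strain mixture at 50x: the majority strain is recovered
        from straintrace import make_marker_db

        db = make_marker_db(1, 1, 2000, seed=9)
        mid = db.marker_ids[0]
        major = mutate_strain(db.sequences[mid], 0.005, rng)
        minor = mutate_strain(db.sequences[mid], 0.02, rng)
        reads = simulate_reads(major, 40, 100, 0.005, seed=rng, id_prefix="maj") + \
            simulate_reads(minor, 10, 100, 0.005, seed=rng, id_prefix="min")
        piles = build_pileup(map_reads(reads, db), db)
        cons = call_consensus(piles[mid])
        matches = total = 0
        for a, b in zip(cons.sequence, major):
            if a != "N":
                total += 1
                matches += a == b
        assert matches / total >= 0.99
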