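"""Proportional allocation, area-preserving resampling and tensor assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operonet.features import (
    DatasetIntegrityError,
    PairSignal,
    allocate_positions,
    build_tensor,
    extract_pair_signal,
    read_dataset,
    resample_segment,
    write_dataset,
)
from operonet.genome_io import CoverageTrack, GeneModel, GenePair


def allocation_oracle(lengths, total=150):
    """Independent scalar largest-remainder apportionment."""
    s = sum(lengths)
    quotas = [total * l / s for l in lengths]
    alloc = [math.floor(q) for q in quotas]
    order = sorted(range(len(lengths)),
                   key=lambda i: (-(quotas[i] - alloc[i]), i))
    for i in order[: total - sum(alloc)]:
        alloc[i] += 1
    changed = True
    while changed:
        changed = False
        for i, l in enumerate(lengths):
            if l >= 1 and alloc[i] == 0:
                donor = max(range(len(alloc)), key=lambda j: alloc[j])
                alloc[donor] -= 1
                alloc[i] += 1
                changed = True
    return tuple(alloc)


def resample_oracle(depths, n):
    """Brute-force fractional-overlap binning, base by base."""
    L = len(depths)
    width = L / n
    out = []
    for j in range(n):
        lo, hi = j * width, (j + 1) * width
        acc = 0.0
        for b in range(L):
            overlap = max(0.0, min(hi, b + 1) - max(lo, b))
            acc += overlap * depths[b]
        out.append(acc / width)
    return np.array(out)


class TestAllocatePositions:
    @pytest.mark.parametrize("lengths,expected", [
        ((300, 60, 240), (75, 15, 60)),   # exact proportions of 150
        ((100, 100, 100), (50, 50, 50)),  # symmetry
        ((10, 0, 10), (75, 0, 75)),       # empty IGR
    ])
    def test_known_allocations(self, lengths, expected):
        assert allocate_positions(*lengths) == expected

    def test_matches_largest_remainder_oracle_on_random_triples(self, rng):
        for _ in range(1000):
            l1, l2 = (int(v) for v in rng.integers(1, 5000, 2))
            lI = int(rng.integers(0, 3000))
            assert allocate_positions(l1, lI, l2) == \
                allocation_oracle((l1, lI, l2))

    @given(l1=st.integers(1, 10**6), lI=st.integers(0, 10**6),
           l2=st.integers(1, 10**6))
    @settings(deadline=None, derandomize=True)
    def test_partition_and_minimum_guarantee(self, l1, lI, l2):
        n1, nI, n2 = allocate_positions(l1, lI, l2)
        assert n1 + nI + n2 == 150
        assert n1 >= 1 and n2 >= 1
        assert (nI == 0) == (lI == 0)

    def test_growing_a_segment_never_shrinks_its_share(self, rng):
        for _ in range(300):
            l1, l2 = (int(v) for v in rng.integers(1, 2000, 2))
            lI = int(rng.integers(0, 1500))
            base = allocate_positions(l1, lI, l2)
            assert allocate_positions(l1 + 1, lI, l2)[0] >= base[0]
            assert allocate_positions(l1, lI + 1, l2)[1] >= base[1]

    def test_total_too_small_for_nonempty_segments(self):
        with pytest.raises(ValueError):
            allocate_positions(5, 5, 5, total=2)


class TestResampleSegment:
    def test_constant_input_maps_to_same_constant(self, rng):
        for L, n in [(1, 5), (7, 150), (400, 17), (3, 3)]:
            out = resample_segment(np.full(L, 7.0), n)
            assert np.allclose(out, 7.0)

    def test_identity_when_lengths_match(self, rng):
        x = rng.integers(0, 100, 23).astype(float)
        assert np.array_equal(resample_segment(x, 23), x)

    def test_two_to_four_matches_overlap_oracle(self):
        out = resample_segment(np.array([0.0, 10.0]), 4)
        assert np.allclose(out, resample_oracle([0.0, 10.0], 4))
        assert np.allclose(out, [0.0, 0.0, 10.0, 10.0])

    def test_random_vectors_match_overlap_oracle(self, rng):
        for _ in range(40):
            L = int(rng.integers(1, 60))
            n = int(rng.integers(1, 60))
            x = rng.integers(0, 50, L).astype(float)
            assert np.allclose(resample_segment(x, n), resample_oracle(x, n),
                               atol=1e-9)

    def test_mean_is_preserved(self, rng):
        # area preservation: the output mean equals the input mean exactly
        # up to float error, for any L, n
        for _ in range(30):
            L = int(rng.integers(2, 500))
            n = int(rng.integers(1, 300))
            x = rng.integers(0, 100, L).astype(float)
            assert resample_segment(x, n).mean() == pytest.approx(
                x.mean(), abs=1.0 / L
            )

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            resample_segment(np.array([]), 3)


def _signal(pair_id, gene1, igr, gene2):
    return PairSignal(
        pair_id=pair_id,
        sample_ids=["s0"],
        gene1=[np.asarray(gene1, dtype=float)],
        igr=[np.asarray(igr, dtype=float)],
        gene2=[np.asarray(gene2, dtype=float)],
    )


class TestBuildTensor:
    def test_all_zero_coverage_gives_zero_tensor(self):
        ft = build_tensor(_signal("p", np.zeros(30), np.zeros(10), np.zeros(30)))
        assert ft.values.shape == (150, 6, 3)
        assert not ft.values.any()

    def test_minmax_scaling_arithmetic(self):
        # equal segment lengths -> 50 positions each; constant segments at
        # 0 / 5 / 10 scale to 0 / 0.5 / 1
        ft = build_tensor(_signal("p", np.full(20, 0.0), np.full(20, 5.0),
                                  np.full(20, 10.0)))
        n1, nI, n2 = ft.boundaries
        assert (n1, nI, n2) == (50, 50, 50)
        assert np.allclose(ft.values[:n1, :, 0], 0.0)
        assert np.allclose(ft.values[n1:n1 + nI, :, 1], 0.5)
        assert np.allclose(ft.values[n1 + nI:, :, 2], 1.0)

    def test_channels_partition_the_scaled_vector(self, rng):
        for _ in range(10):
            g1 = rng.integers(0, 100, int(rng.integers(5, 300)))
            igr = rng.integers(0, 100, int(rng.integers(0, 200)))
            g2 = rng.integers(0, 100, int(rng.integers(5, 300)))
            ft = build_tensor(_signal("p", g1, igr, g2))
            n1, nI, n2 = ft.boundaries
            summed = ft.values.sum(axis=2)
            # reconstruct the scaled 150-vector directly
            parts = [resample_segment(np.asarray(g1, float), n1)]
            if nI:
                parts.append(resample_segment(np.asarray(igr, float), nI))
            parts.append(resample_segment(np.asarray(g2, float), n2))
            vec = np.concatenate(parts)
            vec = (vec - vec.min()) / (vec.max() - vec.min())
            assert np.allclose(summed[:, 0], vec, atol=1e-6)
            # masks are disjoint: at most one nonzero channel per position
            assert (np.count_nonzero(ft.values, axis=2) <= 1).all()

    def test_values_bounded_in_unit_interval(self, small_dataset):
        assert small_dataset.tensors.min() >= 0.0
        assert small_dataset.tensors.max() <= 1.0

    def test_empty_igr_channel_is_all_zeros(self, rng):
        ft = build_tensor(_signal("p", rng.integers(0, 9, 40), [],
                                  rng.integers(0, 9, 40)))
        assert ft.boundaries[1] == 0
        assert not ft.values[:, :, 1].any()

    def test_fewer_samples_are_tiled_cyclically(self, rng):
        sig = PairSignal(
            pair_id="p", sample_ids=["a", "b"],
            gene1=[rng.random(30), rng.random(30)],
            igr=[rng.random(8), rng.random(8)],
            gene2=[rng.random(25), rng.random(25)],
        )
        ft = build_tensor(sig)
        assert np.array_equal(ft.values[:, 0], ft.values[:, 2])
        assert np.array_equal(ft.values[:, 1], ft.values[:, 3])
        assert not np.array_equal(ft.values[:, 0], ft.values[:, 1])


class TestStrandSymmetry:
    def test_mirrored_minus_pair_gives_identical_tensor(self, rng):
        L = 500
        depths = rng.integers(0, 60, L)
        plus_track = CoverageTrack("s", {"c": depths})
        minus_track = CoverageTrack("s", {"c": depths[::-1].copy()})
        g1 = GeneModel("a", "c", 50, 200, "+")
        g2 = GeneModel("b", "c", 260, 430, "+")
        plus = GenePair("a|b", g1, g2, "+", "c", 200, 260)
        # mirror: x -> L - x swaps and reverses everything
        m2 = GeneModel("a'", "c", L - 200, L - 50, "-")
        m1 = GeneModel("b'", "c", L - 430, L - 260, "-")
        minus = GenePair("b'|a'", m1, m2, "-", "c", L - 260, L - 200)
        t_plus = build_tensor(extract_pair_signal(plus, [plus_track]))
        t_minus = build_tensor(extract_pair_signal(minus, [minus_track]))
        assert np.array_equal(t_plus.values, t_minus.values)

    def test_minus_pair_segments_are_sliced_then_reversed(self, rng):
        L = 300
        depths = rng.integers(0, 50, L)
        track = CoverageTrack("s", {"c": depths})
        g1 = GeneModel("a", "c", 10, 100, "-")
        g2 = GeneModel("b", "c", 120, 250, "-")
        pair = GenePair("a|b", g1, g2, "-", "c", 100, 120)
        sig = extract_pair_signal(pair, [track])
        # oracle: slice each interval then reverse; upstream gene first
        assert np.array_equal(sig.gene1[0], depths[120:250][::-1])
        assert np.array_equal(sig.igr[0], depths[100:120][::-1])
        assert np.array_equal(sig.gene2[0], depths[10:100][::-1])


class TestDatasetRoundTrip:
    def test_write_read_is_bitwise_lossless(self, tmp_path, small_dataset):
        write_dataset(small_dataset, tmp_path / "ds")
        loaded = read_dataset(tmp_path / "ds")
        assert np.array_equal(loaded.tensors, small_dataset.tensors)
        assert np.array_equal(loaded.labels, small_dataset.labels)
        assert np.array_equal(loaded.boundaries, small_dataset.boundaries)
        assert loaded.pair_ids == small_dataset.pair_ids
        assert loaded.sample_ids == small_dataset.sample_ids

    def test_truncated_archive_raises_integrity_error(self, tmp_path,
                                                      small_dataset):
        write_dataset(small_dataset, tmp_path / "ds")
        data = (tmp_path / "ds" / "data.npz").read_bytes()
        (tmp_path / "ds" / "data.npz").write_bytes(data[: len(data) // 2])
        with pytest.raises(DatasetIntegrityError):
            read_dataset(tmp_path / "ds")

    def test_manifest_mismatch_raises_integrity_error(self, tmp_path,
                                                      small_dataset):
        write_dataset(small_dataset, tmp_path / "ds")
        manifest = (tmp_path / "ds" / "manifest.json").read_text()
        manifest = manifest.replace(
            f'"n_pairs": {len(small_dataset)}', '"n_pairs": 1'
        )
        (tmp_path / "ds" / "manifest.json").write_text(manifest)
        with pytest.raises(DatasetIntegrityError):
            read_dataset(tmp_path / "ds")

    def test_stored_boundaries_match_recomputation(self, small_sim,
                                                   small_dataset):
        from operonet.features import allocate_positions
        by_id = {p.pair_id: p for p in small_sim.pairs}
        for i, pid in enumerate(small_dataset.pair_ids[:20]):
            pair = by_id[pid]
            # minus-strand pairs are reoriented: the upstream gene
            # (genomic-rightmost) comes first
            left, right = ((pair.gene1, pair.gene2) if pair.strand == "+"
                           else (pair.gene2, pair.gene1))
            expected = allocate_positions(
                left.length, pair.igr_length, right.length
            )
            assert tuple(small_dataset.boundaries[i]) == expected
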