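"""Fisher combination, replicate-consensus grouping, min-max normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from notchdyn.consensus import build_consensus, fisher_combine, min_max_normalize
from notchdyn.genomic_io import GenomicInterval, ReplicatePeak


def _peak(chrom, start, end, p, rep=""):
    return ReplicatePeak(GenomicInterval(chrom, start, end), p, rep)


class TestFisherCombine:
    def test_single_p_identity(self):
        assert fisher_combine([0.5]) == pytest.approx(0.5)

    def test_two_equal_ps_closed_form(self):
        # chi2 df=4 survival is exp(-x/2) * (1 + x/2) at x = -2 ln(1e-4)
        x = -2 * np.log(1e-4)
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert fisher_combine([0.01, 0.01]) == pytest.approx(closed, rel=1e-12)
        assert closed == pytest.approx(1.021e-3, rel=1e-3)

    def test_matches_numerical_integration(self):
        ps = [0.03, 0.2, 0.7]
        x = -2 * sum(np.log(ps))
        tail, _ = integrate.quad(lambda t: stats.chi2.pdf(t, 6), x, np.inf)
        assert fisher_combine(ps) == pytest.approx(tail, rel=1e-8)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fisher_combine([])
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=6))
    def test_permutation_invariant_and_monotone(self, ps):
        combined = fisher_combine(ps)
        assert combined == pytest.approx(fisher_combine(ps[::-1]))
        smaller = [p / 2 for p in ps]
        assert fisher_combine(smaller) <= combined + 1e-15


class TestBuildConsensus:
    def test_three_of_five_rule(self):
        reps = {f"r{i}": [] for i in range(1, 6)}
        for rep, p in zip(["r1", "r2", "r3"], [1e-12, 1e-8, 1e-7]):
            reps[rep].append(_peak("chr1", 100, 300, p, rep))
        sites = build_consensus(reps, min_support=3)
        assert len(sites) == 1
        assert sites[0].support == 3
        assert sites[0].combined_p == pytest.approx(
            fisher_combine([1e-12, 1e-8, 1e-7])
        )

    def test_insufficient_support_dropped(self):
        reps = {f"r{i}": [] for i in range(1, 6)}
        for rep in ("r1", "r2"):
            reps[rep].append(_peak("chr1", 100, 300, 1e-12, rep))
        assert build_consensus(reps, min_support=3) == []

    def test_three_of_four_histone_mode(self):
        reps = {f"r{i}": [] for i in range(1, 5)}
        for rep in ("r1", "r2"):
            reps[rep].append(_peak("chr1", 100, 300, 1e-12, rep))
        for rep in ("r1", "r2", "r3"):
            reps[rep].append(_peak("chr1", 5000, 5300, 1e-12, rep))
        sites = build_consensus(reps, min_support=3)
        assert len(sites) == 1
        assert sites[0].interval.start == 5000

    def test_stringent_rescue(self):
        # combined p above w, but one constituent clears the stringent cut
        reps = {
            "r1": [_peak("chr1", 0, 100, 1e-12, "r1")],
            "r2": [_peak("chr1", 50, 150, 0.9, "r2")],
        }
        combined = fisher_combine([1e-12, 0.9])
        assert combined > 1e-11  # the weak filter alone would drop the group
        sites = build_consensus(
            reps, min_support=2, weak_w=1e-11, stringent_s=1e-11
        )
        assert len(sites) == 1
        # and without the rescue (stringent below the constituent p) it dies
        assert build_consensus(
            reps, min_support=2, weak_w=1e-13, stringent_s=1e-13
        ) == []

    def test_union_span_and_representative_per_replicate(self):
        # two overlapping peaks from the same replicate: one representative
        reps = {
            "r1": [
                _peak("chr1", 100, 200, 1e-9, "r1"),
                _peak("chr1", 150, 260, 1e-3, "r1"),
            ],
            "r2": [_peak("chr1", 190, 320, 1e-8, "r2")],
        }
        sites = build_consensus(reps, min_support=2)
        assert len(sites) == 1
        assert (sites[0].interval.start, sites[0].interval.end) == (100, 320)
        assert sites[0].support == 2
        assert sites[0].combined_p == pytest.approx(fisher_combine([1e-9, 1e-8]))

    def test_min_support_above_replicates_rejected(self):
        with pytest.raises(ValueError):
            build_consensus({"r1": []}, min_support=2)

    def _random_replicates(self, seed, n_peaks=50, n_reps=5):
        rng = np.random.default_rng(seed)
        reps = {f"r{i}": [] for i in range(n_reps)}
        for _ in range(n_peaks):
            rep = f"r{int(rng.integers(n_reps))}"
            start = int(rng.integers(0, 3_000))
            width = int(rng.integers(50, 400))
            p = float(10.0 ** -rng.uniform(0.5, 14))
            reps[rep].append(_peak("chr1", start, start + width, p, rep))
        return reps

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("min_support", [1, 2, 3])
    def test_matches_brute_force_oracle(self, seed, min_support):
        reps = self._random_replicates(seed)
        got = build_consensus(reps, min_support=min_support)
        expected = _oracle_consensus(reps, min_support, 1e-6, 1e-10)
        got_key = sorted(
            (s.interval.start, s.interval.end, s.support) for s in got
        )
        assert got_key == sorted(expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_min_support(self, seed):
        reps = self._random_replicates(seed)
        counts = [
            len(build_consensus(reps, min_support=k)) for k in (1, 2, 3, 4, 5)
        ]
        assert counts == sorted(counts, reverse=True)


def _oracle_consensus(reps, min_support, weak_w, stringent_s):
    """Exhaustive pairwise-overlap grouping via union-find."""
    flat = [(pk, rep) for rep, peaks in reps.items() for pk in peaks]
    parent = list(range(len(flat)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if flat[i][0].interval.overlaps(flat[j][0].interval):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(flat)):
        groups.setdefault(find(i), []).append(flat[i])
    out = []
    for members in groups.values():
        best = {}
        for pk, rep in members:
            if rep not in best or pk.p_value < best[rep]:
                best[rep] = pk.p_value
        if len(best) < min_support:
            continue
        combined = fisher_combine(list(best.values()))
        if combined > weak_w and not any(
            pk.p_value <= stringent_s for pk, _ in members
        ):
            continue
        out.append(
            (
                min(pk.interval.start for pk, _ in members),
                max(pk.interval.end for pk, _ in members),
                len(best),
            )
        )
    return out


class TestMinMaxNormalize:
    def test_three_point_example(self):
        got = min_max_normalize([1e-10, 1e-6, 1e-2])
        assert got == pytest.approx([1.0, 0.5, 0.0])

    def test_degenerate_input_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            got = min_max_normalize([0.01, 0.01])
        assert list(got) == [0.0, 0.0]

    @given(st.lists(st.floats(1e-100, 1.0), min_size=2, max_size=30, unique=True))
    def test_order_preserving_and_bounded(self, ps):
        scores = min_max_normalize(ps)
        assert np.all(scores >= 0) and np.all(scores <= 1)
        # ascending p = descending significance = non-increasing score
        by_p = scores[np.argsort(ps)]
        assert np.all(np.diff(by_p) <= 1e-12)
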