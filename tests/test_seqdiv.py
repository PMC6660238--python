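"""Sliding-window diversity statistics vs brute-force pair counting."""

import itertools

import numpy as np
import pytest

import spoksim as sp
from spoksim.seqdiv import per_site_pi
from spoksim.synthetic import AlignmentSpec, generate_alignment


def brute_force_window_pi(aln, window, step, include_multiallelic=False):
    """Independent oracle: mean over all C(n,2) sequence pairs of per-site
    mismatch indicators with the n/(n-1) correction, gap sites removed."""
    rows = [row.tobytes().decode() for row in aln.matrix]
    n = len(rows)
    L = len(rows[0])
    pairs = list(itertools.combinations(range(n), 2))
    site_vals = []
    site_ok = []
    for j in range(L):
        col = [r[j] for r in rows]
        if any(c in "-N" for c in col):
            site_ok.append(False)
            site_vals.append(0.0)
            continue
        k_states = len(set(col))
        if k_states > 2 and not include_multiallelic:
            site_ok.append(False)
            site_vals.append(0.0)
            continue
        site_ok.append(True)
        # the plain mean mismatch over pairs, n1*n2/C(n,2), already equals
        # the corrected 2p(1-p)*n/(n-1)
        diff = sum(rows[a][j] != rows[b][j] for a, b in pairs)
        site_vals.append(diff / len(pairs))
    out = []
    starts = (range(0, L - window + 1, step) if L >= window else [0])
    width = min(window, L)
    for s in starts:
        vals = [site_vals[j] for j in range(s, s + width) if site_ok[j]]
        out.append(float(np.mean(vals)) if vals else float("nan"))
    return out


class TestWindowedPi:
    def test_identical_sequences_all_zero(self):
        aln = sp.Alignment.from_sequences(["ACGT" * 50] * 3)
        track = sp.windowed_pi(aln)
        assert (track.values == 0.0).all()

    def test_worked_single_site_value(self):
        """One (A,A,C,C) site in a 100-bp invariant window:
        window value = 2*0.5*0.5*(4/3)/100."""
        base = ["A" * 100 for _ in range(4)]
        seqs = [s[:49] + c + s[50:] for s, c in zip(base, "AACC")]
        aln = sp.Alignment.from_sequences(seqs)
        track = sp.windowed_pi(aln, window=100, step=20)
        assert track.values[0] == pytest.approx(
            (2 * 0.5 * 0.5 * 4 / 3) / 100)
        # the direct all-pairs mean: 4/6 differing pairs at the site
        assert track.values[0] == pytest.approx((4 / 6) / 100)

    def test_gap_site_excluded_from_numerator_and_denominator(self):
        seqs = ["AAAA", "AAAA", "A-CA"]
        aln = sp.Alignment.from_sequences(seqs)
        vals, valid = per_site_pi(aln)
        assert valid.tolist() == [True, False, True, True]
        assert vals[1] == 0.0
        track = sp.windowed_pi(aln, window=4, step=4)
        assert track.records["n_valid_sites"].iloc[0] == 3

    def test_oracle_equivalence_random_alignments(self):
        """windowed_pi equals the brute-force all-pairs computation on 100
        random gapped alignments (n <= 6, L <= 300)."""
        rng = np.random.default_rng(404)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            L = int(rng.integers(30, 301))
            mat = rng.choice(list("ACGT-"), size=(n, L),
                             p=[0.23, 0.23, 0.23, 0.23, 0.08])
            aln = sp.Alignment.from_sequences(["".join(r) for r in mat])
            window = int(rng.integers(5, 60))
            step = int(rng.integers(1, 20))
            got = sp.windowed_pi(aln, window=window, step=step).values
            want = brute_force_window_pi(aln, window, step)
            np.testing.assert_allclose(got, want, rtol=1e-12, equal_nan=True)

    def test_multiallelic_sites_skipped_by_default_included_by_flag(self):
        seqs = ["AAAA", "CAAA", "GAAA", "TAAA"]
        aln = sp.Alignment.from_sequences(seqs)
        vals, valid = per_site_pi(aln)
        assert not valid[0]
        vals2, valid2 = per_site_pi(aln, include_multiallelic=True)
        assert valid2[0]
        # full heterozygosity 1 - 4*(1/4)^2 = 0.75, corrected by n/(n-1)
        assert vals2[0] == pytest.approx(0.75 * 4 / 3)

    def test_row_order_and_label_invariance(self):
        rng = np.random.default_rng(7)
        mat = rng.choice(list("ACGT-"), size=(5, 120))
        seqs = ["".join(r) for r in mat]
        a = sp.windowed_pi(sp.Alignment.from_sequences(seqs)).values
        b = sp.windowed_pi(sp.Alignment.from_sequences(
            seqs[::-1], labels=list("vwxyz"))).values
        np.testing.assert_array_equal(a, b)

    def test_per_site_bound(self):
        """Per-site values lie in [0, n/(2(n-1))] (max at p = 1/2)."""
        rng = np.random.default_rng(8)
        for n in (2, 4, 6):
            mat = rng.choice(list("ACGT"), size=(n, 500))
            aln = sp.Alignment.from_sequences(["".join(r) for r in mat])
            vals, valid = per_site_pi(aln)
            assert (vals[valid] >= 0).all()
            assert (vals[valid] <= n / (2 * (n - 1)) + 1e-12).all()

    def test_window_longer_than_alignment_truncates_with_warning(self):
        aln = sp.Alignment.from_sequences(["ACGTAC", "ACGTAC"])
        with pytest.warns(UserWarning, match="truncated"):
            track = sp.windowed_pi(aln, window=100, step=20)
        assert len(track.records) == 1
        assert track.records["end"].iloc[0] == 6

    def test_window_width_normalization_flag(self):
        base = ["A" * 100 for _ in range(4)]
        seqs = [s[:9] + c + s[10:-1] + g
                for s, c, g in zip(base, "AACC", "AA-A")]
        aln = sp.Alignment.from_sequences(seqs)
        by_valid = sp.windowed_pi(aln, window=100, step=100).values[0]
        by_window = sp.windowed_pi(aln, window=100, step=100,
                                   normalize="window").values[0]
        assert by_window == pytest.approx(by_valid * 99 / 100)

    def test_tsv_roundtrip_header_states_convention(self, tmp_path):
        aln = sp.Alignment.from_sequences(["ACGT" * 30] * 2)
        track = sp.windowed_pi(aln)
        path = tmp_path / "pi.tsv"
        track.to_tsv(path, label="toy")
        text = path.read_text()
        assert "0-based half-open" in text.splitlines()[0]
        assert text.splitlines()[1].split("\t")[:3] == ["label", "start",
                                                        "end"]


class TestVariableSites:
    def test_identical_rows(self):
        aln = sp.Alignment.from_sequences(["ACGT" * 10] * 4)
        assert sp.count_variable_sites(aln) == (0, 40)

    def test_planted_counts_recovered_exactly(self):
        for k, L, seed in ((130, 2334, 1), (0, 100, 2), (17, 200, 3)):
            aln, truth = generate_alignment(
                AlignmentSpec(n=5, L=L, n_variable=k), seed=seed)
            assert sp.count_variable_sites(aln) == (k, L)
            assert len(truth.variable_columns) == k

    def test_gap_only_column_not_variable(self):
        aln = sp.Alignment.from_sequences(["A-G", "A-G", "A-C"])
        n_var, n_tot = sp.count_variable_sites(aln)
        assert (n_var, n_tot) == (1, 3)


class TestGCWindows:
    def test_uniform_sequences(self):
        assert (sp.gc_content_windows("G" * 8000).values == 1.0).all()
        assert sp.gc_content_windows("ATGC" * 1000).values[0] == 0.5

    def test_n_excluded_from_denominator(self):
        track = sp.gc_content_windows("GGNN" * 1000, window=4000, step=2000)
        assert track.values[0] == 1.0
        assert track.records["n_valid_sites"].iloc[0] == 2000

    def test_planted_gc_segment_elevated(self):
        aln, truth = generate_alignment(
            AlignmentSpec(n=2, L=20000, n_variable=0, gc=0.40,
                          gc_segments=((8000, 12000, 0.80),)), seed=4)
        seq = aln.matrix[0].tobytes().decode()
        track = sp.gc_content_windows(seq, window=4000, step=2000)
        rec = track.records
        inside = rec[(rec.start >= 8000) & (rec.end <= 12000)]["value"]
        outside = rec[(rec.end <= 8000) | (rec.start >= 12000)]["value"]
        assert inside.min() > outside.max()

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            sp.gc_content_windows("")

    def test_fasta_roundtrip(self, tmp_path):
        aln, _ = generate_alignment(AlignmentSpec(n=3, L=120, n_variable=7),
                                    seed=5)
        path = tmp_path / "aln.fasta"
        aln.to_fasta(path)
        back = sp.Alignment.from_fasta(path)
        assert back.labels == aln.labels
        assert (back.matrix == aln.matrix).all()
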