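import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from introscan.variant_filtering import (
    FilterConfig,
    SiteRecord,
    binned_mode,
    demography_prep,
    depth_window_filter,
    exclude_genic,
    excluded_depth_windows,
    filter_site,
    missingness_filter,
    thin_sites,
)


def make_site(fs=10.0, mq=50.0, qd=10.0, ref="A", alts=("T",), pos=100, genotypes=None):
    if genotypes is None:
        genotypes = np.zeros((4, 2), dtype=np.int8)
    return SiteRecord(
        chromosome="chr1", position=pos, ref=ref, alts=tuple(alts),
        genotypes=genotypes, fs=fs, mq=mq, qd=qd,
    )


CFG = FilterConfig()


class TestFilterSite:
    def test_fs_rule(self):
        keep, reason = filter_site(make_site(fs=70.0), CFG)
        assert not keep and reason == "FS"

    def test_fs_boundary_inclusive(self):
        assert not filter_site(make_site(fs=60.0), CFG)[0]

    def test_all_pass(self):
        keep, reason = filter_site(make_site(fs=10.0, mq=50.0, qd=6.0), CFG)
        assert keep and reason == "pass"

    def test_qd_strict(self):
        keep, reason = filter_site(make_site(qd=5.99), CFG)
        assert not keep and reason == "QD"

    def test_mq_boundary_inclusive(self):
        keep, reason = filter_site(make_site(mq=40.0), CFG)
        assert not keep and reason == "MQ"

    def test_non_biallelic_dropped(self):
        keep, reason = filter_site(make_site(alts=("T", "G")), CFG)
        assert not keep and reason == "not_biallelic_snp"
        keep, reason = filter_site(make_site(ref="AT"), CFG)
        assert not keep

    def test_repeat_mask(self):
        keep, reason = filter_site(make_site(pos=100), CFG, repeat_mask=[(50, 150)])
        assert not keep and reason == "repeat_mask"
        # half-open: 0-based 99 not in [0, 99)
        assert filter_site(make_site(pos=100), CFG, repeat_mask=[(0, 99)])[0]

    def test_missing_annotations_pass(self):
        keep, _ = filter_site(make_site(fs=None, mq=None, qd=None), CFG)
        assert keep

    def test_first_failing_rule_reported(self):
        keep, reason = filter_site(make_site(fs=99.0, mq=10.0, qd=1.0), CFG)
        assert reason == "FS"

    @given(
        st.one_of(st.none(), st.floats(0, 100)),
        st.one_of(st.none(), st.floats(0, 100)),
        st.one_of(st.none(), st.floats(0, 100)),
    )
    def test_rule_order_independent_of_verdict(self, fs, mq, qd):
        # verdict equals the conjunction of the individual rules
        rec = make_site(fs=fs, mq=mq, qd=qd)
        keep, _ = filter_site(rec, CFG)
        expected = (
            (fs is None or fs < 60)
            and (mq is None or mq > 40)
            and (qd is None or qd >= 6)
        )
        assert keep == expected


class TestMissingness:
    def _geno(self, n, n_missing):
        g = np.zeros((n, 2), dtype=np.int8)
        g[:n_missing, 0] = -1
        return g

    def test_4_of_22_dropped(self):
        assert not missingness_filter(self._geno(22, 4))  # 18.2% >= 15%

    def test_3_of_22_kept(self):
        assert missingness_filter(self._geno(22, 3))  # 13.6% < 15%

    def test_zero_missing_kept(self):
        assert missingness_filter(self._geno(22, 0))

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            missingness_filter(np.zeros((0, 2)))


class TestDepthWindow:
    def test_mode_and_threshold(self):
        excluded = depth_window_filter(np.array([100.0, 100, 100, 200]))
        assert excluded.tolist() == [False, False, False, True]

    def test_all_equal_nothing_excluded(self):
        assert not depth_window_filter(np.array([50.0] * 6)).any()

    def test_binned_mode_example(self):
        excluded = depth_window_filter(np.array([10.0, 10, 14, 16]))
        assert excluded.tolist() == [False, False, False, True]

    def test_mode_tie_smallest(self):
        assert binned_mode(np.array([3.0, 3, 7, 7, 100])) == 3.0

    def test_never_excludes_at_or_below_mode(self, rng):
        sums = rng.integers(1, 50, 200).astype(float)
        mode = binned_mode(sums)
        excluded = depth_window_filter(sums)
        assert not excluded[sums <= mode].any()

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            depth_window_filter(np.zeros(5))

    def test_population_table(self):
        rows = []
        for ind in ("a", "b"):
            for w, depth in [(0, 10.0), (10_000, 10.0), (20_000, 40.0)]:
                rows.append((ind, "chr1", w, depth))
        table = pd.DataFrame(rows, columns=["individual", "chromosome", "window_start", "mean_depth"])
        excluded = excluded_depth_windows(table, ["a", "b"])
        assert excluded == {("chr1", 20_000)}


class TestThin:
    def test_greedy_example(self):
        out = thin_sites(np.array([1, 40_000, 95_000]), 50_000)
        assert out.tolist() == [1, 95_000]

    def test_single_position(self):
        assert thin_sites(np.array([7]), 50_000).tolist() == [7]

    def test_exact_spacing_all_kept(self):
        pos = np.arange(0, 500_000, 50_000)
        assert thin_sites(pos, 50_000).tolist() == pos.tolist()

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            thin_sites(np.array([5, 3]), 10)

    @given(st.lists(st.integers(0, 10**6), min_size=1, max_size=200))
    def test_output_spacing_invariant(self, positions):
        pos = np.array(sorted(positions))
        out = thin_sites(pos, 50_000)
        assert (np.diff(out) >= 50_000).all()
        assert out[0] == pos[0]


class TestExcludeGenic:
    def test_empty_genes_identity(self):
        pos = np.array([1, 5, 9])
        assert exclude_genic(pos, []).tolist() == [1, 5, 9]

    def test_half_open_end_retained(self):
        assert exclude_genic(np.array([100]), [(50, 100)]).tolist() == [100]

    def test_brute_force_membership(self, rng):
        pos = np.arange(10) * 10
        genes = [(25, 65)]  # covers 30, 40, 50, 60
        out = exclude_genic(pos, genes)
        brute = [p for p in pos if not (25 <= p < 65)]
        assert out.tolist() == brute
        assert len(out) == 6


class TestComposition:
    def test_site_rules_order_independent(self, rng):
        records = [
            make_site(
                fs=float(rng.uniform(0, 120)),
                mq=float(rng.uniform(0, 80)),
                qd=float(rng.uniform(0, 12)),
                pos=int(p),
            )
            for p in rng.integers(1, 1000, 50)
        ]

        def survivors(order):
            out = []
            for r in records:
                checks = {
                    "fs": r.fs < CFG.fs_max,
                    "mq": r.mq > CFG.mq_min,
                    "qd": r.qd >= CFG.qd_min,
                }
                if all(checks[k] for k in order):
                    out.append(r.position)
            return out

        assert survivors(("fs", "mq", "qd")) == survivors(("qd", "fs", "mq"))

    def test_demography_prep(self):
        positions = {"chr1": np.array([0, 10_000, 30_000, 100_000, 140_000, 200_000])}
        genes = {"chr1": [(25_000, 35_000)]}
        out = demography_prep(positions, genes, thin_bp=50_000)
        # 30_000 removed as genic; greedy thinning from 0
        assert out["chr1"].tolist() == [0, 100_000, 200_000]


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(missing_max_fraction=0)
    with pytest.raises(ValueError):
        FilterConfig(fs_max=-1)


def test_paper_defaults():
    cfg = FilterConfig()
    assert (cfg.fs_max, cfg.mq_min, cfg.qd_min) == (60.0, 40.0, 6.0)
    assert cfg.missing_max_fraction == 0.15
    assert cfg.depth_window_bp == 10_000
    assert cfg.depth_mode_multiplier == 1.5
    assert cfg.thin_bp == 50_000
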