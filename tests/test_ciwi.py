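import numpy as np
import pandas as pd
import pytest

from admixscan.ciwi import (
    ConsensusIntrogressionModel,
    IntrogressedRegion,
    ReferenceGrid,
    annotate_regions,
    call_regions,
    ciwi_scores,
    intersect_regions,
    run_reference_grid,
)
from admixscan.lai import LocalAncestryModel, make_windows

from conftest import make_markers


class FakeTracks:
    """Minimal stand-in for LocalAncestryResults: fixed per-window frequencies."""

    def __init__(self, windows, per_window):
        self.windows = windows
        self._pw = np.asarray(per_window, dtype=float)

    def frequencies(self):
        return {"per_window": self._pw}


@pytest.fixture
def windows100():
    return make_windows(make_markers(2000), 20)  # 100 windows


@pytest.fixture(scope="module")
def sweep_ciwi(sweep_study):
    cfg = sweep_study.config
    return ConsensusIntrogressionModel(
        sweep_study.panel, "TGT", cfg.ref_pops_A, cfg.ref_pops_B
    ).fit()


class TestGrid:
    def test_three_by_three_gives_nine_runs(self, default_study):
        grid = ReferenceGrid(["A1", "A2", "A3"], ["B1", "B2", "B3"])
        tracks = run_reference_grid("TGT", grid, default_study.panel)
        assert len(tracks) == 9

    def test_one_by_one_equals_direct_run(self, default_study):
        grid = ReferenceGrid(["A1"], ["B1"])
        tracks = run_reference_grid("TGT", grid, default_study.panel)
        direct = LocalAncestryModel(default_study.panel, "TGT", "A1", "B1").fit()
        np.testing.assert_array_equal(tracks[("A1", "B1")].labels, direct.labels)

    def test_unknown_population_rejected(self, default_study):
        grid = ReferenceGrid(["A1"], ["XXX"])
        with pytest.raises(ValueError, match="XXX"):
            run_reference_grid("TGT", grid, default_study.panel)


class TestScores:
    def test_degenerate_all_zero_flags_nothing(self, windows100):
        tracks = {c: FakeTracks(windows100, np.zeros(100)) for c in ["c1", "c2", "c3"]}
        res = ciwi_scores(tracks)
        assert res.s.max() == 0.0
        assert res.c_count.max() == 0  # cutoff 0 flags no window

    def test_single_hot_window(self, windows100):
        base = np.full(100, 0.12)
        tracks = {}
        for k in range(9):
            f = base.copy()
            f[40] = 1.0
            tracks[f"c{k}"] = FakeTracks(windows100, f)
        res = ciwi_scores(tracks)
        assert res.s.argmax() == 40
        assert res.c_count[40] == 9

    def test_combination_order_invariant(self, windows100):
        rng = np.random.default_rng(0)
        fs = {f"c{k}": rng.uniform(0, 0.3, 100) for k in range(4)}
        t1 = {k: FakeTracks(windows100, v) for k, v in fs.items()}
        t2 = {k: FakeTracks(windows100, fs[k]) for k in reversed(list(fs))}
        np.testing.assert_allclose(ciwi_scores(t1).s, ciwi_scores(t2).s)
        np.testing.assert_array_equal(ciwi_scores(t1).c_count, ciwi_scores(t2).c_count)

    def test_mismatched_windowing_rejected(self, windows100):
        other = make_windows(make_markers(1000), 20)
        tracks = {
            "c1": FakeTracks(windows100, np.zeros(100)),
            "c2": FakeTracks(other, np.zeros(50)),
        }
        with pytest.raises(ValueError, match="window"):
            ciwi_scores(tracks)


class TestCallRegions:
    def make_table(self, windows, s_hot=(), c_hot=9):
        rng = np.random.default_rng(3)
        n = windows.n_windows
        freqs = rng.uniform(0.05, 0.2, size=(n, 9))
        for w in s_hot:
            freqs[w] = 0.95
        tracks = {f"c{k}": FakeTracks(windows, freqs[:, k]) for k in range(9)}
        return ciwi_scores(tracks)

    def test_no_qualifying_window_empty(self, windows100):
        table = self.make_table(windows100)
        assert call_regions(table, top_pct=1, min_consistency=9) == []

    def test_gap_merge_rule(self, windows100):
        table = self.make_table(windows100, s_hot=(40, 42))  # gap of one window
        regions = call_regions(table, top_pct=5, min_consistency=9, max_gap_windows=1)
        assert len(regions) == 1
        assert regions[0].windows == [40, 41, 42]
        regions = call_regions(table, top_pct=5, min_consistency=9, max_gap_windows=0)
        assert len(regions) == 2

    def test_min_consistency_validated(self, windows100):
        table = self.make_table(windows100, s_hot=(40,))
        with pytest.raises(ValueError):
            call_regions(table, min_consistency=10)

    def test_injected_tract_called_at_top1(self, sweep_ciwi):
        regions = sweep_ciwi.call_regions(top_pct=1)
        center = 50_200_000
        assert any(r.start_bp <= center <= r.end_bp and r.min_c == 9 for r in regions)

    def test_top1_nested_in_top5(self, sweep_ciwi):
        top1 = {w for r in sweep_ciwi.call_regions(top_pct=1) for w in r.windows}
        top5 = {w for r in sweep_ciwi.call_regions(top_pct=5) for w in r.windows}
        # gap-merged member windows aside, every qualifying top-1% window
        # must re-qualify at 5%
        s_cut1 = np.percentile(sweep_ciwi.s, 99)
        s_cut5 = np.percentile(sweep_ciwi.s, 95)
        q1 = set(np.flatnonzero((sweep_ciwi.s >= s_cut1) & (sweep_ciwi.c_count == 9)))
        q5 = set(np.flatnonzero((sweep_ciwi.s >= s_cut5) & (sweep_ciwi.c_count == 9)))
        assert q1 <= q5
        assert top1 <= top5


class TestAnnotateIntersect:
    def test_gene_inside_region_listed(self):
        # the canonical layout: a ~1 Mb region at 10.80-11.74 Mb on chr 18
        # containing a gene at 10.88-10.94 Mb
        region = IntrogressedRegion("18", 10_800_000, 11_740_000, [0], 0.9, 9)
        genes = pd.DataFrame(
            {
                "chrom": ["18"],
                "start_bp": [10_880_000],
                "end_bp": [10_940_000],
                "name": ["USP10"],
            }
        )
        annotate_regions([region], genes)
        assert region.genes == ["USP10"]

    def test_region_without_genes_retained(self):
        region = IntrogressedRegion("1", 100, 200, [0], 0.5, 9)
        genes = pd.DataFrame(
            {"chrom": ["1"], "start_bp": [5_000], "end_bp": [6_000], "name": ["G"]}
        )
        out = annotate_regions([region], genes)
        assert out == [region] and region.genes == []

    def test_chromosome_naming_mismatch_rejected(self):
        region = IntrogressedRegion("chr1", 100, 200, [0], 0.5, 9)
        genes = pd.DataFrame(
            {"chrom": ["1"], "start_bp": [100], "end_bp": [200], "name": ["G"]}
        )
        with pytest.raises(ValueError, match="rename"):
            annotate_regions([region], genes)

    def test_three_population_intersection(self):
        regs = {
            "P1": [IntrogressedRegion("1", 1_000_000, 2_000_000, [], 0.9, 9)],
            "P2": [IntrogressedRegion("1", 1_400_000, 2_200_000, [], 0.9, 9)],
            "P3": [IntrogressedRegion("1", 1_300_000, 1_900_000, [], 0.9, 9)],
        }
        shared = intersect_regions(regs)
        assert len(shared) == 1
        row = shared.iloc[0]
        assert (row["start_bp"], row["end_bp"]) == (1_400_000, 1_900_000)
        assert row[["P1", "P2", "P3"]].all()

    def test_k_of_n_mode(self):
        regs = {
            "P1": [IntrogressedRegion("1", 100, 300, [], 0.9, 9)],
            "P2": [IntrogressedRegion("1", 200, 400, [], 0.9, 9)],
            "P3": [],
        }
        assert len(intersect_regions(regs)) == 0
        shared = intersect_regions(regs, min_pops=2)
        assert len(shared) == 1
        assert (shared.iloc[0]["start_bp"], shared.iloc[0]["end_bp"]) == (200, 300)
        assert not shared.iloc[0]["P3"]
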