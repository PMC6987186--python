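"""Consensus introgression-window calling across a grid of reference pairs.

Local ancestry inference depends on the reference populations chosen; a
window flagged as introgressed under one taurine/indicine reference pair may
be an artifact of that pair's own history. The consensus layer re-runs the
painter for every pairwise combination of class-A and class-B references
(3 x 3 = 9 by default), pools the per-window minor-ancestry frequencies
``f[w, c]`` and summarises them as

* a consensus score ``S[w]`` — the mean frequency across combinations, and
* a consistency count ``C[w]`` — the number of combinations in which the
  window reaches that combination's own genome-wide 95th percentile (a
  combination whose 95th percentile is 0 flags nothing).

Windows in the genome-wide top 5% (or 1%) of ``S`` that are consistent in
all combinations are merged into candidate introgressed regions, annotated
with overlapping genes and intersected across target populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .lai import LocalAncestryModel, WindowIndex
from .panel import HaplotypePanel

__all__ = [
    "ReferenceGrid",
    "run_reference_grid",
    "ciwi_scores",
    "CIWIResults",
    "IntrogressedRegion",
    "call_regions",
    "annotate_regions",
    "intersect_regions",
    "ConsensusIntrogressionModel",
]

#: per-combination consistency percentile
CONSISTENCY_PCT = 95.0


@dataclass
class ReferenceGrid:
    """Cross product of class-A and class-B reference population labels."""

    refs_a: list
    refs_b: list

    def __post_init__(self) -> None:
        if not self.refs_a or not self.refs_b:
            raise ValueError("need at least one reference population per class")

    @property
    def combinations(self) -> list:
        return list(product(self.refs_a, self.refs_b))

    def __len__(self) -> int:
        return len(self.refs_a) * len(self.refs_b)


def run_reference_grid(
    target_pop: str,
    grid: ReferenceGrid,
    panel: HaplotypePanel,
    window_snps: int = 20,
    smoothing_g: float = 100.0,
) -> dict:
    """One local ancestry run per reference combination, identical windowing.

    Returns ``{(ref_a, ref_b): LocalAncestryResults}``.
    """
    pops = set(panel.populations())
    missing = [
        p for p in dict.fromkeys(grid.refs_a + grid.refs_b + [target_pop]) if p not in pops
    ]
    if missing:
        raise ValueError(f"populations absent from panel: {', '.join(missing)}")
    for p in grid.refs_a + grid.refs_b:
        if len(panel.haplotypes_for(p)) < 4:
            raise ValueError(f"reference population {p} has fewer than 4 haplotypes")
    out = {}
    for a, b in grid.combinations:
        out[(a, b)] = LocalAncestryModel(
            panel, target_pop, a, b, window_snps=window_snps, smoothing_g=smoothing_g
        ).fit()
    return out


def ciwi_scores(track_sets: dict) -> "CIWIResults":
    """Pool per-combination frequencies into consensus and consistency scores."""
    combos = list(track_sets)
    results = [track_sets[c] for c in combos]
    windows = results[0].windows
    for r in results[1:]:
        if r.windows.n_windows != windows.n_windows or not np.array_equal(
            r.windows.m_start, windows.m_start
        ):
            raise ValueError("track sets do not share a window index")
    freqs = np.column_stack([r.frequencies()["per_window"] for r in results])
    s = freqs.mean(axis=1)
    cutoffs = np.percentile(freqs, CONSISTENCY_PCT, axis=0)
    flagged = (freqs >= cutoffs) & (cutoffs > 0)
    c_count = flagged.sum(axis=1).astype(np.int64)
    return CIWIResults(windows, combos, freqs, s, c_count, cutoffs)


@dataclass
class IntrogressedRegion:
    """A maximal run of qualifying windows (1-window gaps tolerated)."""

    chrom: object
    start_bp: int
    end_bp: int
    windows: list
    peak_s: float
    min_c: int
    genes: list = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def call_regions(
    table: "CIWIResults",
    top_pct: float = 5.0,
    min_consistency: int | None = None,
    max_gap_windows: int = 1,
) -> list:
    """Threshold the consensus table and merge qualifying windows into regions.

    A window qualifies iff ``S[w]`` reaches the genome-wide ``100 - top_pct``
    percentile of S and ``C[w] >= min_consistency`` (default: every
    combination). Qualifying windows separated by at most *max_gap_windows*
    non-qualifying windows are merged.
    """
    if not 0 < top_pct <= 50:
        raise ValueError("top_pct must be in (0, 50]")
    n_combo = table.freqs.shape[1]
    if min_consistency is None:
        min_consistency = n_combo
    if min_consistency > n_combo:
        raise ValueError("min_consistency exceeds the number of combinations")
    s_cut = np.percentile(table.s, 100.0 - top_pct)
    qualifies = (table.s >= s_cut) & (table.c_count >= min_consistency)
    w = table.windows
    regions = []
    for c in dict.fromkeys(w.chrom):
        idx = np.flatnonzero((w.chrom == c) & qualifies)
        if len(idx) == 0:
            continue
        run = [int(idx[0])]
        for j in idx[1:]:
            if j - run[-1] - 1 <= max_gap_windows:
                run.append(int(j))
            else:
                regions.append(_make_region(table, run))
                run = [int(j)]
        regions.append(_make_region(table, run))
    return regions


def _make_region(table: "CIWIResults", member_windows: list) -> IntrogressedRegion:
    w = table.windows
    members = list(range(member_windows[0], member_windows[-1] + 1))
    return IntrogressedRegion(
        chrom=w.chrom[member_windows[0]],
        start_bp=int(w.start_bp[member_windows[0]]),
        end_bp=int(w.end_bp[member_windows[-1]]),
        windows=members,
        peak_s=float(table.s[member_windows].max()),
        min_c=int(table.c_count[member_windows].min()),
    )


def annotate_regions(regions: list, genes: pd.DataFrame) -> list:
    """Attach overlapping genes (1-bp overlap suffices) to each region.

    *genes* uses 1-based closed coordinates (``read_gene_intervals`` output).
    """
    if regions and len(genes):
        region_chroms = {str(r.chrom) for r in regions}
        gene_chroms = set(genes["chrom"].astype(str))
        if not region_chroms & gene_chroms:
            raise ValueError(
                "no shared chromosome names between regions and gene intervals; "
                "supply a chromosome rename map"
            )
    for r in regions:
        sel = (
            (genes["chrom"].astype(str) == str(r.chrom))
            & (genes["end_bp"] >= r.start_bp)
            & (genes["start_bp"] <= r.end_bp)
        )
        r.genes = list(genes.loc[sel, "name"])
    return regions


def intersect_regions(regions_by_pop: dict, min_pops: int | None = None) -> pd.DataFrame:
    """Intervals covered by called regions in (at least) *min_pops* populations.

    Default requires presence in every supplied population. Returns a frame
    with one interval per row and a boolean membership column per population.
    """
    pops = list(regions_by_pop)
    if min_pops is None:
        min_pops = len(pops)
    chroms: dict = {}
    for p in pops:
        for r in regions_by_pop[p]:
            chroms.setdefault(str(r.chrom), []).append((p, r.start_bp, r.end_bp))
    rows = []
    for c, ivals in chroms.items():
        edges = sorted({x for _, s, e in ivals for x in (s, e + 1)})
        for lo, hi in zip(edges[:-1], edges[1:]):
            present = {p for p, s, e in ivals if s <= lo and e + 1 >= hi}
            if len(present) >= min_pops:
                rows.append({"chrom": c, "start_bp": lo, "end_bp": hi - 1, "present": present})
    # merge adjacent elementary intervals with identical membership
    merged = []
    for row in rows:
        if (
            merged
            and merged[-1]["chrom"] == row["chrom"]
            and merged[-1]["end_bp"] + 1 == row["start_bp"]
            and merged[-1]["present"] == row["present"]
        ):
            merged[-1]["end_bp"] = row["end_bp"]
        else:
            merged.append(row)
    out = pd.DataFrame(
        [
            {
                "chrom": r["chrom"],
                "start_bp": r["start_bp"],
                "end_bp": r["end_bp"],
                "n_pops": len(r["present"]),
                **{p: p in r["present"] for p in pops},
            }
            for r in merged
        ],
        columns=["chrom", "start_bp", "end_bp", "n_pops", *pops],
    )
    return out


class ConsensusIntrogressionModel:
    """Reference-grid consensus model for one target population.

    ``fit()`` runs the windowed-PCA painter for every reference combination
    and pools the per-window minor-ancestry frequencies.
    """

    def __init__(
        self,
        panel: HaplotypePanel,
        target_pop: str,
        refs_a: list,
        refs_b: list,
        window_snps: int = 20,
        smoothing_g: float = 100.0,
    ):
        self.panel = panel
        self.target_pop = target_pop
        self.grid = ReferenceGrid(list(refs_a), list(refs_b))
        self.window_snps = window_snps
        self.smoothing_g = smoothing_g

    def fit(self) -> "CIWIResults":
        tracks = run_reference_grid(
            self.target_pop,
            self.grid,
            self.panel,
            window_snps=self.window_snps,
            smoothing_g=self.smoothing_g,
        )
        res = ciwi_scores(tracks)
        res.track_sets = tracks
        return res


@dataclass
class CIWIResults:
    """Per-window consensus table for one target population."""

    windows: WindowIndex
    combinations: list
    freqs: np.ndarray  # windows x combinations
    s: np.ndarray
    c_count: np.ndarray
    cutoffs: np.ndarray
    track_sets: dict = field(default=None, repr=False)

    def call_regions(
        self,
        top_pct: float = 5.0,
        min_consistency: int | None = None,
        max_gap_windows: int = 1,
    ) -> list:
        return call_regions(self, top_pct, min_consistency, max_gap_windows)

    def to_frame(self) -> pd.DataFrame:
        w = self.windows
        df = pd.DataFrame(
            {
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "consensus_score": self.s,
                "consistency": self.c_count,
            }
        )
        for k, combo in enumerate(self.combinations):
            df[f"f_{combo[0]}x{combo[1]}"] = self.freqs[:, k]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, top_pct: float = 5.0) -> pd.DataFrame:
        """Called regions as a table (one row per region)."""
        regions = self.call_regions(top_pct=top_pct)
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "n_windows": len(r.windows),
                    "peak_score": r.peak_s,
                    "min_consistency": r.min_c,
                    "genes": ",".join(r.genes),
                }
                for r in regions
            ],
            columns=[
                "chrom",
                "start_bp",
                "end_bp",
                "n_windows",
                "peak_score",
                "min_consistency",
                "genes",
            ],
        )
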