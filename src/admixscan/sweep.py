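"""nSL haplotype-homozygosity selection scan.

For a focal marker, ``SL`` of an allele class is the mean, over haplotype
pairs carrying that allele, of the number of consecutive markers in the
maximal interval containing the focal marker over which the pair is
identical (measured in marker counts, nSL's defining trait — no genetic map
enters). The raw statistic is

    nSL = ln(SL_ancestral / SL_derived),

so *negative* values mean excess haplotype homozygosity around the derived
allele — a sweep on the derived allele. Raw scores are z-normalised within
derived-allele frequency bins and the magnitude of the normalised score is
smoothed along the chromosome with a cubic smoothing spline (penalty chosen
by generalized cross-validation); maximal spans where the smoothed curve
reaches a threshold are reported as sweep intervals and intersected with
consensus-introgression regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .panel import AA_UNKNOWN, HaplotypePanel

__all__ = [
    "site_sl",
    "nsl_scan",
    "normalize_nsl",
    "smooth_and_call",
    "NslScan",
    "SweepResults",
]

_PAIR_CHUNK = 6000  # pairs per block; bounds peak memory of the extent arrays


def _pair_runs(eq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Left/right agreement-run lengths (inclusive of the site) per pair x site."""
    n_pairs, m = eq.shape
    left = np.empty((n_pairs, m), dtype=np.int32)
    right = np.empty((n_pairs, m), dtype=np.int32)
    run = np.zeros(n_pairs, dtype=np.int32)
    for s in range(m):
        run = (run + 1) * eq[:, s]
        left[:, s] = run
    run = np.zeros(n_pairs, dtype=np.int32)
    for s in range(m - 1, -1, -1):
        run = (run + 1) * eq[:, s]
        right[:, s] = run
    return left, right


def site_sl(haps: np.ndarray, focal: int) -> tuple[float, bool]:
    """Mean pairwise shared-interval length around *focal* for a haplotype subset.

    Returns ``(SL, truncated)``; ``SL`` is NaN (a sentinel, not an error) for
    subsets of fewer than two haplotypes. ``truncated`` flags any pair whose
    shared interval reached a chromosome end. A pair differing at the focal
    marker itself contributes length 0.
    """
    haps = np.asarray(haps)
    n, m = haps.shape
    if n < 2:
        return float("nan"), False
    iu, ju = np.triu_indices(n, 1)
    eq = haps[iu] == haps[ju]
    left, right = _pair_runs(eq)
    lengths = np.where(eq[:, focal], left[:, focal] + right[:, focal] - 1, 0)
    truncated = bool(
        np.any(eq[:, focal] & ((left[:, focal] == focal + 1) | (right[:, focal] == m - focal)))
    )
    return float(lengths.mean()), truncated


def nsl_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    hap_rows: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw nSL per focal marker with known ancestral allele.

    Markers are scanned when the derived-allele frequency lies in
    ``[maf_min, 1 - maf_min]``; the statistic is undefined (NaN) where either
    allele class has fewer than two carriers. Chromosomes are scanned
    independently (shared intervals never cross a chromosome boundary).
    """
    markers = panel.markers
    aa = markers.ancestral_allele
    if np.all(aa == AA_UNKNOWN):
        raise ValueError("no marker with known ancestral allele")
    rows = np.arange(panel.n_haplotypes) if hap_rows is None else np.asarray(hap_rows)

    frames = []
    for c in markers.chromosomes():
        sel = np.flatnonzero(markers.chrom == c)
        frames.append(_nsl_one_chrom(panel, rows, sel, maf_min))
    return pd.concat(frames, ignore_index=True)


def _nsl_one_chrom(panel, rows, marker_sel, maf_min) -> pd.DataFrame:
    H = panel.alleles[np.ix_(rows, marker_sel)]
    markers = panel.markers
    aa = markers.ancestral_allele[marker_sel]
    n, m = H.shape
    known = aa != AA_UNKNOWN
    alt_freq = H.mean(axis=0)
    der_freq = np.where(aa == 0, alt_freq, 1.0 - alt_freq)
    der_freq[~known] = np.nan
    scanned = known & (der_freq >= maf_min) & (der_freq <= 1.0 - maf_min)

    anc_mask = H == np.where(known, aa, 0)[None, :]
    iu, ju = np.triu_indices(n, 1)
    sum_anc = np.zeros(m)
    cnt_anc = np.zeros(m, dtype=np.int64)
    sum_der = np.zeros(m)
    cnt_der = np.zeros(m, dtype=np.int64)
    trunc = np.zeros(m, dtype=bool)
    col = np.arange(m, dtype=np.int32)
    for lo in range(0, len(iu), _PAIR_CHUNK):
        i_c, j_c = iu[lo : lo + _PAIR_CHUNK], ju[lo : lo + _PAIR_CHUNK]
        eq = H[i_c] == H[j_c]
        left, right = _pair_runs(eq)
        L = left + right - 1
        pa = anc_mask[i_c] & anc_mask[j_c]
        pd_ = ~anc_mask[i_c] & ~anc_mask[j_c]
        sum_anc += (L * pa).sum(axis=0)
        cnt_anc += pa.sum(axis=0)
        sum_der += (L * pd_).sum(axis=0)
        cnt_der += pd_.sum(axis=0)
        edge = (left == col + 1) | (right == m - col)
        trunc |= (edge & (pa | pd_)).any(axis=0)

    raw = np.full(m, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        sl_a = np.where(cnt_anc > 0, sum_anc / np.maximum(cnt_anc, 1), np.nan)
        sl_d = np.where(cnt_der > 0, sum_der / np.maximum(cnt_der, 1), np.nan)
        ok = scanned & (cnt_anc > 0) & (cnt_der > 0) & (sl_a > 0) & (sl_d > 0)
        raw[ok] = np.log(sl_a[ok] / sl_d[ok])
    return pd.DataFrame(
        {
            "chrom": markers.chrom[marker_sel],
            "pos_bp": markers.pos_bp[marker_sel],
            "derived_freq": der_freq,
            "raw_nsl": raw,
            "truncated": trunc & ~np.isnan(raw),
        }
    )


def normalize_nsl(
    raw: np.ndarray, derived_freq: np.ndarray, n_bins: int = 20, min_bin_markers: int = 10
) -> np.ndarray:
    """Z-normalise raw nSL within equal-width derived-frequency bins.

    Bins holding fewer than *min_bin_markers* scored markers are merged with
    the nearest populated bin (by bin-centre distance, ties to the left).
    Raises if a merged bin is degenerate (zero standard deviation).
    """
    raw = np.asarray(raw, dtype=np.float64)
    defined = np.isfinite(raw)
    if not defined.any():
        raise ValueError("no defined raw values to normalise")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    bin_of = np.clip(np.digitize(derived_freq, edges) - 1, 0, n_bins - 1)

    populated = sorted({int(b) for b in bin_of[defined]})
    groups = [[b] for b in populated]

    def count(g):
        return int(np.sum(defined & np.isin(bin_of, g)))

    def centre(g):
        return float(np.mean([centres[b] for b in g]))

    while len(groups) > 1:
        small = next((k for k, g in enumerate(groups) if count(g) < min_bin_markers), None)
        if small is None:
            break
        neighbours = [k for k in (small - 1, small + 1) if 0 <= k < len(groups)]
        tgt = min(
            neighbours, key=lambda k: (abs(centre(groups[k]) - centre(groups[small])), k)
        )
        a, b = sorted((small, tgt))
        groups[a] = groups[a] + groups[b]
        del groups[b]

    z = np.full_like(raw, np.nan)
    for g in groups:
        sel = defined & np.isin(bin_of, g)
        vals = raw[sel]
        sd = vals.std()
        if sd == 0:
            raise ValueError("degenerate frequency bin with zero standard deviation")
        z[sel] = (vals - vals.mean()) / sd
    return z


def smooth_and_call(
    pos_bp: np.ndarray,
    z: np.ndarray,
    lam: float | None = None,
    call_threshold: float = 2.0,
    signed: bool = False,
    min_markers: int = 3,
) -> tuple[np.ndarray, list]:
    """Cubic smoothing spline over normalised scores + sweep-interval calling.

    The spline is fitted to ``|z|`` (set ``signed=True`` to smooth signed
    scores) with penalty *lam*; when ``lam`` is None it is chosen by
    generalized cross-validation. Returns the smoothed values at the scored
    markers and the maximal bp spans where ``|smoothed| >= call_threshold``;
    spans shorter than *min_markers* consecutive scored markers are dropped
    (a sweep, unlike a stray extreme score, extends over several markers).
    """
    defined = np.isfinite(z)
    x = np.asarray(pos_bp, dtype=np.float64)[defined]
    y = np.abs(z[defined]) if not signed else z[defined]
    if len(x) < 10:
        raise ValueError("need at least 10 normalised values to smooth")
    if np.ptp(y) == 0:
        smoothed = np.full(len(x), y[0])
    else:
        spline = make_smoothing_spline(x, y, lam=lam)
        smoothed = spline(x)
    hot = np.abs(smoothed) >= call_threshold
    intervals = []
    k = 0
    while k < len(hot):
        if hot[k]:
            j = k
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            if j - k + 1 >= min_markers:
                intervals.append((int(x[k]), int(x[j])))
            k = j + 1
        else:
            k += 1
    return smoothed, intervals


def overlap_report(ciwi_regions: list, sweep_intervals: list, chrom=None) -> pd.DataFrame:
    """Fraction of each consensus region's span covered by sweep intervals.

    Regions without any overlapping interval are retained with fraction 0.
    """
    rows = []
    for r in ciwi_regions:
        covered = 0
        for s, e in sweep_intervals:
            if chrom is not None and str(r.chrom) != str(chrom):
                continue
            lo, hi = max(r.start_bp, s), min(r.end_bp, e)
            if hi >= lo:
                covered += hi - lo + 1
        rows.append(
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "overlap_fraction": covered / r.length_bp,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "overlap_fraction"])


class NslScan:
    """nSL scan of one population of a phased panel.

    Parameters
    ----------
    panel
        Phased panel with ancestral alleles annotated on its markers.
    pop
        Population to scan (default: every haplotype in the panel).
    maf_min
        Minimum minor derived-allele frequency of scanned focal markers.
    n_bins
        Derived-frequency bins for normalisation.
    """

    def __init__(
        self,
        panel: HaplotypePanel,
        pop: str | None = None,
        maf_min: float = 0.05,
        n_bins: int = 20,
    ):
        self.panel = panel
        self.pop = pop
        self.maf_min = maf_min
        self.n_bins = n_bins

    def fit(self) -> "SweepResults":
        rows = None if self.pop is None else self.panel.haplotypes_for(self.pop)
        table = nsl_scan(self.panel, maf_min=self.maf_min, hap_rows=rows)
        table["normalized_nsl"] = normalize_nsl(
            table["raw_nsl"].to_numpy(), table["derived_freq"].to_numpy(), self.n_bins
        )
        return SweepResults(self, table)


@dataclass
class SweepResults:
    """Raw, normalised and (after :meth:`smooth`) smoothed scan values."""

    model: NslScan
    table: pd.DataFrame
    intervals_by_chrom: dict = field(default_factory=dict)

    def smooth(
        self,
        lam: float | None = None,
        call_threshold: float = 2.0,
        signed: bool = False,
        min_markers: int = 3,
    ) -> "SweepResults":
        """Fit the smoothing spline per chromosome and call sweep intervals."""
        self.table["smoothed"] = np.nan
        self.intervals_by_chrom = {}
        for c, sub in self.table.groupby("chrom", sort=False):
            z = sub["normalized_nsl"].to_numpy()
            defined = np.isfinite(z)
            smoothed, intervals = smooth_and_call(
                sub["pos_bp"].to_numpy(), z, lam=lam, call_threshold=call_threshold,
                signed=signed, min_markers=min_markers,
            )
            self.table.loc[sub.index[defined], "smoothed"] = smoothed
            self.intervals_by_chrom[c] = intervals
        return self

    @property
    def sweep_intervals(self) -> list:
        """All called intervals as (chrom, start_bp, end_bp)."""
        return [
            (c, s, e) for c, ivals in self.intervals_by_chrom.items() for s, e in ivals
        ]

    def overlap_report(self, ciwi_regions: list) -> pd.DataFrame:
        rows = []
        for r in ciwi_regions:
            ivals = self.intervals_by_chrom.get(r.chrom, [])
            rows.append(overlap_report([r], ivals).iloc[0])
        return pd.DataFrame(rows).reset_index(drop=True) if rows else overlap_report([], [])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> pd.DataFrame:
        """Top-|normalised| scored markers."""
        t = self.table.dropna(subset=["normalized_nsl"])
        return t.reindex(
            t["normalized_nsl"].abs().sort_values(ascending=False).index
        ).head(20)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = self.table
        ax.scatter(t["pos_bp"] / 1e6, t["normalized_nsl"], s=2, alpha=0.4, label="|z|")
        if "smoothed" in t:
            ax.plot(t["pos_bp"] / 1e6, t["smoothed"], color="C1", label="smoothed")
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("normalised nSL")
        ax.legend()
        return ax
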