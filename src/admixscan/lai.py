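"""Windowed-PCA local ancestry inference (chromosome painting).

Markers are cut into consecutive 20-SNP windows; within each window the
pooled reference haplotypes of the two ancestry classes are decomposed by
PCA and each target haplotype's window is scored by its position relative to
the two class centroids in the retained principal subspace. Raw per-window
scores are then smoothed along the chromosome with a two-state HMM whose
switch probability reflects the expected recombination between window
midpoints for an admixture event ``g`` generations old.

The hard label of a window is class B iff the smoothed posterior exceeds
0.5; an exact tie is resolved to class A (conservative toward the majority
background ancestry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, MarkerMap

__all__ = [
    "WindowIndex",
    "make_windows",
    "WindowModel",
    "fit_window_model",
    "paint_chromosome",
    "track_frequencies",
    "window_accuracy",
    "LocalAncestryModel",
    "LocalAncestryResults",
]

#: maximum number of principal axes retained per window
MAX_AXES = 5
#: an axis is kept when the class centroids are at least this many pooled
#: within-class standard deviations apart along it
AXIS_SEPARATION_MIN = 1.0


@dataclass
class WindowIndex:
    """Non-overlapping marker windows tiling each chromosome.

    ``m_start``/``m_end`` are half-open global marker-index ranges.
    """

    chrom: np.ndarray
    m_start: np.ndarray
    m_end: np.ndarray
    markers: MarkerMap

    @property
    def n_windows(self) -> int:
        return len(self.m_start)

    @property
    def sizes(self) -> np.ndarray:
        return self.m_end - self.m_start

    @property
    def start_bp(self) -> np.ndarray:
        return self.markers.pos_bp[self.m_start]

    @property
    def end_bp(self) -> np.ndarray:
        return self.markers.pos_bp[self.m_end - 1]

    @property
    def mid_cM(self) -> np.ndarray:
        cm = self.markers.pos_cM
        return 0.5 * (cm[self.m_start] + cm[self.m_end - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "m_start": self.m_start,
                "m_end": self.m_end,
                "start_bp": self.start_bp,
                "end_bp": self.end_bp,
                "n_markers": self.sizes,
            }
        )


def make_windows(markers: MarkerMap, window_snps: int = 20) -> WindowIndex:
    """Cut each chromosome into consecutive blocks of *window_snps* markers.

    A trailing remainder shorter than ``window_snps / 2`` is merged into the
    previous window; otherwise it stands as its own window. A chromosome with
    fewer than *window_snps* markers becomes a single window (with a warning).
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    chroms, starts, ends = [], [], []
    offset = 0
    for c in markers.chromosomes():
        n = int((markers.chrom == c).sum())
        if n < window_snps:
            warnings.warn(
                f"chromosome {c} has {n} < {window_snps} markers; using a single window"
            )
            bounds = [0, n]
        else:
            bounds = list(range(0, n + 1, window_snps))
            remainder = n - bounds[-1]
            if remainder:
                if remainder < window_snps / 2:
                    bounds[-1] = n  # merge into previous window
                else:
                    bounds.append(n)
        for k in range(len(bounds) - 1):
            chroms.append(c)
            starts.append(offset + bounds[k])
            ends.append(offset + bounds[k + 1])
        offset += n
    return WindowIndex(
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        markers,
    )


@dataclass
class WindowModel:
    """Per-window reference model: retained principal axes and class centroids."""

    mean: np.ndarray
    axes: np.ndarray  # (k, window markers)
    centroid_a: np.ndarray
    centroid_b: np.ndarray
    separation: float
    uninformative: bool

    def raw_scores(self, alleles: np.ndarray) -> np.ndarray:
        """Score haplotype rows: d_A / (d_A + d_B) in the retained subspace.

        Near 1 means class-B-like. Uninformative windows score 0.5.
        """
        n = alleles.shape[0]
        if self.uninformative:
            return np.full(n, 0.5)
        proj = (alleles - self.mean) @ self.axes.T
        d_a = np.linalg.norm(proj - self.centroid_a, axis=1)
        d_b = np.linalg.norm(proj - self.centroid_b, axis=1)
        tot = d_a + d_b
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(tot > 0, d_a / np.where(tot > 0, tot, 1.0), 0.5)
        return score


def fit_window_model(ref_a: np.ndarray, ref_b: np.ndarray) -> WindowModel:
    """PCA of the pooled reference haplotypes of one window.

    Among the leading principal axes (at most :data:`MAX_AXES`), those along
    which the class centroids are well separated (>= 1 pooled within-class SD)
    are retained — always at least the single best axis. A window whose pooled
    references have no variance, or whose centroids coincide, is flagged
    uninformative and scores 0.5 downstream.
    """
    if ref_a.shape[0] < 4 or ref_b.shape[0] < 4:
        raise ValueError("need >= 4 reference haplotypes per class")
    pooled = np.vstack([ref_a, ref_b]).astype(np.float64)
    mean = pooled.mean(axis=0)
    centered = pooled - mean
    if not centered.any():
        k = 1
        w = pooled.shape[1]
        return WindowModel(mean, np.zeros((1, w)), np.zeros(1), np.zeros(1), 0.0, True)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((svals > 1e-9 * svals[0]).sum())
    n_axes = min(MAX_AXES, rank)
    axes = vt[:n_axes]
    scores = centered @ axes.T
    na = ref_a.shape[0]
    sa, sb = scores[:na], scores[na:]
    mu_a, mu_b = sa.mean(axis=0), sb.mean(axis=0)
    var_within = (sa.var(axis=0) * na + sb.var(axis=0) * sb.shape[0]) / pooled.shape[0]
    sd = np.sqrt(np.maximum(var_within, 1e-12))
    axis_sep = np.abs(mu_a - mu_b) / sd
    keep = axis_sep >= AXIS_SEPARATION_MIN
    if not keep.any():
        keep[np.argmax(axis_sep)] = True
    separation = float(np.sqrt((axis_sep[keep] ** 2).sum()))
    uninformative = separation < 1e-9
    return WindowModel(
        mean, axes[keep], mu_a[keep], mu_b[keep], separation, uninformative
    )


def _forward_backward(
    emit_b: np.ndarray, switch: np.ndarray
) -> np.ndarray:
    """Posterior P(state B) of a symmetric 2-state chain.

    ``emit_b[w]`` is the Bernoulli-like evidence weight for state B at window
    w (state A weighs ``1 - emit_b``); ``switch[w]`` the probability of
    actually changing state between windows w and w+1.
    """
    n = len(emit_b)
    e = np.stack([1.0 - emit_b, emit_b], axis=1)
    fwd = np.empty((n, 2))
    bwd = np.empty((n, 2))
    f = np.array([0.5, 0.5]) * e[0]
    s = f.sum()
    fwd[0] = f / s if s > 0 else [0.5, 0.5]
    for w in range(1, n):
        t = switch[w - 1]
        trans = np.array([[1.0 - t, t], [t, 1.0 - t]])
        f = (fwd[w - 1] @ trans) * e[w]
        s = f.sum()
        fwd[w] = f / s if s > 0 else [0.5, 0.5]
    bwd[n - 1] = 1.0
    for w in range(n - 2, -1, -1):
        t = switch[w]
        trans = np.array([[1.0 - t, t], [t, 1.0 - t]])
        b = trans @ (e[w + 1] * bwd[w + 1])
        s = b.sum()
        bwd[w] = b / s if s > 0 else [0.5, 0.5]
    post = fwd * bwd
    tot = post.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    post /= tot
    return post[:, 1]


def paint_chromosome(
    target: HaplotypePanel,
    models: list,
    windows: WindowIndex,
    smoothing_g: float = 100.0,
    hap_rows: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign ancestry per (haplotype, window) and smooth along chromosomes.

    Returns ``(raw, confidence, labels)``: raw distance-ratio scores, the
    HMM posterior of class B, and hard 0/1 labels (1 = B; exact 0.5 ties
    label A).
    """
    if smoothing_g < 0:
        raise ValueError("smoothing_g must be >= 0")
    if len(models) != windows.n_windows:
        raise ValueError("need one window model per window")
    rows = np.arange(target.n_haplotypes) if hap_rows is None else np.asarray(hap_rows)
    n_hap = len(rows)
    W = windows.n_windows
    raw = np.empty((n_hap, W))
    for w, model in enumerate(models):
        block = target.alleles[rows, windows.m_start[w] : windows.m_end[w]]
        raw[:, w] = model.raw_scores(block)

    confidence = np.empty_like(raw)
    mids = windows.mid_cM
    for c in set(windows.chrom):
        sel = np.flatnonzero(windows.chrom == c)
        if len(sel) == 1:
            confidence[:, sel[0]] = raw[:, sel[0]]
            continue
        delta_morgan = np.diff(mids[sel]) / 100.0
        # probability that the ancestry process is redrawn between window
        # midpoints; the redrawn state is uniform over the two classes, so
        # the state actually switches with half that probability
        switch = 0.5 * (1.0 - np.exp(-smoothing_g * delta_morgan))
        for h in range(n_hap):
            confidence[h, sel] = _forward_backward(raw[h, sel], switch)
    labels = (confidence > 0.5).astype(np.int8)
    return raw, confidence, labels


def track_frequencies(labels: np.ndarray, windows: WindowIndex) -> dict:
    """Per-window class-B frequency and marker-length-weighted global fractions.

    ``labels`` is haplotypes x windows (1 = class B). The global fraction of
    a haplotype (and of the population) weights windows by marker count.
    """
    if labels.shape[0] == 0:
        raise ValueError("no tracks supplied")
    weights = windows.sizes / windows.sizes.sum()
    per_window = labels.mean(axis=0)
    per_hap = labels @ weights
    per_sample = 0.5 * (per_hap[0::2] + per_hap[1::2])
    return {
        "per_window": per_window,
        "per_hap": per_hap,
        "per_sample": per_sample,
        "global": float(per_hap.mean()),
    }


def window_accuracy(labels: np.ndarray, truth_labels: np.ndarray) -> float:
    """Fraction of (haplotype, window) cells whose label matches the truth."""
    return float((labels == truth_labels).mean())


class LocalAncestryModel:
    """Windowed-PCA local ancestry painter for one target population.

    Parameters
    ----------
    panel
        Multi-population phased panel holding target and reference samples.
    target_pop, ref_a, ref_b
        Population labels: the painted target and the class-A (majority,
        taurine-like) and class-B (minority, indicine-like) references.
    window_snps
        Markers per window (default 20).
    smoothing_g
        Admixture age (generations) governing the HMM switch rate.
    """

    def __init__(
        self,
        panel: HaplotypePanel,
        target_pop: str,
        ref_a: str,
        ref_b: str,
        window_snps: int = 20,
        smoothing_g: float = 100.0,
    ):
        pops = set(panel.populations())
        missing = [p for p in (target_pop, ref_a, ref_b) if p not in pops]
        if missing:
            raise ValueError(f"populations absent from panel: {', '.join(missing)}")
        self.panel = panel
        self.target_pop = target_pop
        self.ref_a = ref_a
        self.ref_b = ref_b
        self.window_snps = window_snps
        self.smoothing_g = smoothing_g

    def fit(self) -> "LocalAncestryResults":
        panel = self.panel
        windows = make_windows(panel.markers, self.window_snps)
        rows_a = panel.haplotypes_for(self.ref_a)
        rows_b = panel.haplotypes_for(self.ref_b)
        rows_t = panel.haplotypes_for(self.target_pop)
        models = [
            fit_window_model(
                panel.alleles[rows_a, windows.m_start[w] : windows.m_end[w]],
                panel.alleles[rows_b, windows.m_start[w] : windows.m_end[w]],
            )
            for w in range(windows.n_windows)
        ]
        raw, confidence, labels = paint_chromosome(
            panel, models, windows, self.smoothing_g, hap_rows=rows_t
        )
        return LocalAncestryResults(self, windows, models, raw, confidence, labels, rows_t)


@dataclass
class LocalAncestryResults:
    """Painted ancestry tracks for one (target, reference pair) run."""

    model: LocalAncestryModel
    windows: WindowIndex
    window_models: list
    raw: np.ndarray
    confidence: np.ndarray
    labels: np.ndarray
    hap_rows: np.ndarray
    _freqs: dict = field(default=None, repr=False)

    def frequencies(self) -> dict:
        if self._freqs is None:
            self._freqs = track_frequencies(self.labels, self.windows)
        return self._freqs

    def global_b_fraction(self) -> float:
        return self.frequencies()["global"]

    @property
    def hap_ids(self) -> list:
        all_ids = self.model.panel.hap_ids
        return [all_ids[i] for i in self.hap_rows]

    def to_frame(self) -> pd.DataFrame:
        """One row per (haplotype, window): span, label, confidence."""
        w = self.windows
        n_hap = self.labels.shape[0]
        return pd.DataFrame(
            {
                "hap": np.repeat(self.hap_ids, w.n_windows),
                "chrom": np.tile(w.chrom, n_hap),
                "start_bp": np.tile(w.start_bp, n_hap),
                "end_bp": np.tile(w.end_bp, n_hap),
                "label": np.where(self.labels.ravel() == 1, "B", "A"),
                "confidence": self.confidence.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> pd.DataFrame:
        """Per-window class-B frequency table."""
        f = self.frequencies()
        w = self.windows
        return pd.DataFrame(
            {
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "n_markers": w.sizes,
                "b_frequency": f["per_window"],
                "mean_confidence": self.confidence.mean(axis=0),
            }
        )

    def plot(self, ax=None):
        """Per-window class-B frequency along the chromosome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        w = self.windows
        ax.plot(0.5 * (w.start_bp + w.end_bp) / 1e6, self.frequencies()["per_window"])
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("class-B ancestry frequency")
        ax.set_ylim(0, 1)
        return ax
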