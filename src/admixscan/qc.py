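"""Marker-level quality control.

Two operations mirror the standard array-data pruning recipe: removal of
markers with minor allele frequency < 0.01 or call rate < 0.9 (strict
inequalities — boundary markers are retained), and greedy LD pruning of
markers with r^2 > 0.25 within sliding 50-marker windows advanced by 5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel, QCReport

__all__ = ["filter_markers", "ld_prune"]


def _data_matrix(panel) -> np.ndarray:
    """Allele or dosage matrix as float with NaN for missing calls."""
    if isinstance(panel, HaplotypePanel):
        return panel.alleles.astype(np.float64)
    x = panel.genotypes.astype(np.float64)
    x[panel.genotypes == MISSING] = np.nan
    return x


def filter_markers(panel, maf_min: float = 0.01, callrate_min: float = 0.9):
    """Remove markers failing the unmapped / call-rate / MAF filters, in that order.

    A marker is kept iff it has a map position, call rate >= *callrate_min*
    and MAF >= *maf_min* (markers exactly at a threshold are retained; MAF is
    computed on called genotypes only). Returns ``(filtered_panel, QCReport)``.
    Markers on chromosome "0" or with non-positive position count as unmapped.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= callrate_min <= 1:
        raise ValueError("callrate_min must be in [0, 1]")
    n = panel.n_markers
    if n == 0:
        raise ValueError("empty panel")
    m = panel.markers
    unmapped = (m.pos_bp <= 0) | (np.asarray(m.chrom, dtype=object) == "0")

    if isinstance(panel, HaplotypePanel):
        callrate = np.ones(n)
        freq = panel.alleles.mean(axis=0)
    else:
        called = panel.genotypes != MISSING
        callrate = called.mean(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(called, panel.genotypes, 0).sum(axis=0) / (2.0 * called.sum(axis=0))
        freq = np.where(np.isnan(freq), 0.0, freq)
    maf = np.minimum(freq, 1.0 - freq)

    low_call = callrate < callrate_min
    low_maf = maf < maf_min
    removed_callrate = ~unmapped & low_call
    removed_maf = ~unmapped & ~low_call & low_maf
    keep = ~(unmapped | removed_callrate | removed_maf)
    report = QCReport(
        n_input_markers=n,
        n_removed_maf=int(removed_maf.sum()),
        n_removed_callrate=int(removed_callrate.sum()),
        n_removed_unmapped=int(unmapped.sum()),
        n_retained=int(keep.sum()),
    )
    return panel.subset_markers(np.flatnonzero(keep)), report


def _r2_block(x: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation between columns.

    Monomorphic columns yield NaN, which downstream comparisons treat as
    no linkage.
    """
    return pd.DataFrame(x).corr().to_numpy() ** 2


def ld_prune(panel, r2_max: float = 0.25, window: int = 50, step: int = 5) -> np.ndarray:
    """Greedy within-window LD pruning to a fixpoint.

    Windows of *window* currently-retained markers, advanced by *step*, are
    scanned repeatedly; within a window, for each offending pair
    (r^2 > *r2_max*) the later-positioned marker is removed. Passes repeat
    until no window contains an offending pair. Returns the sorted indices of
    retained markers (relative to the input panel).
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 1 <= step <= window:
        raise ValueError("step must be in [1, window]")
    x = _data_matrix(panel)
    n = x.shape[1]
    retained = np.arange(n)
    while True:
        alive = np.ones(len(retained), dtype=bool)
        changed = False
        for start in range(0, max(len(retained) - 1, 1), step):
            idx = np.arange(start, min(start + window, len(retained)))
            if len(idx) < 2:
                continue
            r2 = _r2_block(x[:, retained[idx]])
            for a in range(len(idx)):
                if not alive[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if alive[idx[b]] and r2[a, b] > r2_max:
                        alive[idx[b]] = False
                        changed = True
        retained = retained[alive]
        if not changed:
            return retained
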