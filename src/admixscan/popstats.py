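"""Diversity and demography statistics: Ho, ROH/F_ROH, LD-based Ne, Reynolds' distances.

These are the per-population summary indices usually tabulated alongside an
introgression study: observed heterozygosity, inbreeding from runs of
homozygosity, effective population size from the decay of linkage
disequilibrium with genetic distance (with Sved & Feldman's mutation-rate
modifier, alpha = 2), and a Reynolds' coancestry distance matrix written in
PHYLIP and NEXUS form for external Neighbour-Net viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, HaplotypePanel

__all__ = [
    "observed_het",
    "roh_and_froh",
    "ROHSet",
    "ne_from_ld",
    "sved_feldman_ne",
    "reynolds_theta",
    "reynolds_matrix",
    "write_phylip",
    "write_nexus_distances",
]


def observed_het(panel: GenotypePanel) -> pd.DataFrame:
    """Observed heterozygosity per population.

    Per locus, Ho is the share of called genotypes that are heterozygous;
    the population value is the mean over loci. Both spread axes are
    reported: ``ho_sd_loci`` (SD of per-locus Ho) and ``ho_sd_individuals``
    (SD of per-individual heterozygous fractions). Loci with no calls in a
    population are skipped for it.
    """
    rows = []
    for pop in panel.populations():
        g = panel.genotypes[panel.samples_for(pop)]
        called = g != MISSING
        locus_called = called.sum(axis=0)
        ok = locus_called > 0
        het = g == 1
        ho_locus = het[:, ok].sum(axis=0) / locus_called[ok]
        with np.errstate(invalid="ignore"):
            ho_ind = het.sum(axis=1) / called.sum(axis=1)
        rows.append(
            {
                "pop": pop,
                "n_samples": g.shape[0],
                "ho_mean": float(ho_locus.mean()),
                "ho_sd_loci": float(ho_locus.std()),
                "ho_sd_individuals": float(np.nanstd(ho_ind)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ROHSet:
    """Runs of homozygosity and derived inbreeding coefficients."""

    runs: pd.DataFrame  # sample, chrom, start_bp, end_bp, n_snps
    froh: pd.Series  # per sample
    by_population: pd.DataFrame  # pop, n_samples, froh_mean, froh_sd
    genome_length_bp: int


def _roh_one(
    pos: np.ndarray,
    het: np.ndarray,
    miss: np.ndarray,
    min_snps: int,
    min_bp: int,
    max_het: int,
    max_missing: int,
    density_bp_per_snp: float,
    max_gap_bp: int,
) -> list:
    """Greedy left-to-right maximal homozygous stretches on one chromosome."""
    n = len(pos)
    runs = []
    i = 0
    while i < n:
        n_het = n_miss = 0
        j = i
        while j < n:
            if j > i and pos[j] - pos[j - 1] > max_gap_bp:
                break
            n_het += het[j]
            n_miss += miss[j]
            if n_het > max_het or n_miss > max_missing:
                break
            j += 1
        # [i, j) is the maximal stretch starting at i
        length = pos[j - 1] - pos[i] + 1 if j > i else 0
        n_snps = j - i
        if (
            n_snps >= min_snps
            and length >= min_bp
            and length / n_snps <= density_bp_per_snp
        ):
            runs.append((int(pos[i]), int(pos[j - 1]), n_snps))
            i = j
        else:
            i += 1
    return runs


def roh_and_froh(
    panel: GenotypePanel,
    min_snps: int = 50,
    min_kb: float = 1000,
    max_het: int = 1,
    max_missing: int = 5,
    density_kb_per_snp: float = 50,
    max_gap_kb: float = 1000,
    genome_length_bp: int | None = None,
) -> ROHSet:
    """Detect runs of homozygosity and compute F_ROH per individual.

    A run is a maximal marker stretch with at most *max_het* heterozygous and
    *max_missing* missing calls, no inter-marker gap above *max_gap_kb*, at
    least *min_snps* markers spanning at least *min_kb*, and average marker
    spacing at most *density_kb_per_snp*. F_ROH is the summed run length
    divided by the genome length (by default the span covered by markers).
    """
    m = panel.markers
    if genome_length_bp is None:
        genome_length_bp = 0
        for c in m.chromosomes():
            bp = m.pos_bp[m.chrom == c]
            genome_length_bp += int(bp.max() - bp.min() + 1)
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")

    rows = []
    froh = {}
    for s_idx, sample in enumerate(panel.sample_ids):
        g = panel.genotypes[s_idx]
        total = 0
        for c in m.chromosomes():
            sel = m.chrom == c
            runs = _roh_one(
                m.pos_bp[sel],
                (g[sel] == 1).astype(np.int64),
                (g[sel] == MISSING).astype(np.int64),
                min_snps,
                int(min_kb * 1000),
                max_het,
                max_missing,
                density_kb_per_snp * 1000.0,
                int(max_gap_kb * 1000),
            )
            for start, end, n_snps in runs:
                rows.append(
                    {"sample": sample, "chrom": c, "start_bp": start, "end_bp": end, "n_snps": n_snps}
                )
                total += end - start + 1
        froh[sample] = total / genome_length_bp
    froh = pd.Series(froh, name="froh")
    pops = pd.Series(panel.pop_labels, index=panel.sample_ids)
    by_pop = (
        froh.groupby(pops)
        .agg(["size", "mean", "std"])
        .rename(columns={"size": "n_samples", "mean": "froh_mean", "std": "froh_sd"})
        .rename_axis("pop")
        .reset_index()
    )
    runs_df = pd.DataFrame(rows, columns=["sample", "chrom", "start_bp", "end_bp", "n_snps"])
    return ROHSet(runs_df, froh, by_pop, genome_length_bp)


def sved_feldman_ne(f_c: float, mean_r2_adj: float, alpha: float = 2.0) -> float:
    """Point Ne from mean adjusted r^2 at recombination rate ``f_c`` (Morgans).

    ``Ne = (4 f_c)^-1 (1 / E[r^2_adj] - alpha)`` with the mutation-rate
    modifier alpha = 2; clamped below at 1.
    """
    if mean_r2_adj <= 0:
        return float("nan")
    return max((1.0 / mean_r2_adj - alpha) / (4.0 * f_c), 1.0)


def ne_from_ld(
    panel: HaplotypePanel,
    pop: str | None = None,
    bins_morgan: np.ndarray | None = None,
    alpha: float = 2.0,
    mapping: str = "linear",
    maf_min: float = 0.05,
    max_pairs_per_bin: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ne trajectory from the decay of r^2 with genetic distance.

    Pairwise r^2 between marker columns is binned by genetic distance c, the
    phased-sample bias 1/n (n haplotypes) subtracted, and each bin converted
    to an estimate ``Ne(t)`` at ``t = 1 / (2 f(c))`` generations in the past.
    ``mapping`` selects f: ``"linear"`` (f(c) = c) or ``"haldane"``
    (f(c) = (1 - exp(-2c)) / 2). Bins with non-positive mean adjusted r^2
    report Ne as missing.
    """
    rows_h = np.arange(panel.n_haplotypes) if pop is None else panel.haplotypes_for(pop)
    if len(rows_h) < 20:
        raise ValueError("need at least 20 haplotypes for LD-based Ne")
    if bins_morgan is None:
        bins_morgan = np.linspace(0.005, 0.085, 9)
    fmap = {"linear": lambda c: c, "haldane": lambda c: 0.5 * (1.0 - np.exp(-2.0 * c))}[mapping]

    x = panel.alleles[rows_h].astype(np.float64)
    freq = x.mean(axis=0)
    poly = np.minimum(freq, 1 - freq) >= maf_min
    x = x[:, poly]
    c_morgan = panel.markers.pos_cM[poly] / 100.0
    chrom = panel.markers.chrom[poly]
    n = x.shape[0]
    sd = x.std(axis=0)
    z = (x - x.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)

    out = []
    for lo, hi in zip(bins_morgan[:-1], bins_morgan[1:]):
        ii, jj = [], []
        for c in dict.fromkeys(chrom):
            sel = np.flatnonzero(chrom == c)
            cc = c_morgan[sel]
            left = np.searchsorted(cc, cc + lo)
            right = np.searchsorted(cc, cc + hi)
            counts = right - left
            total = int(counts.sum())
            if total == 0:
                continue
            take = rng.choice(total, size=min(total, max_pairs_per_bin), replace=False)
            cum = np.concatenate(([0], np.cumsum(counts)))
            a = np.searchsorted(cum, take, side="right") - 1
            ii.append(sel[a])
            jj.append(sel[left[a] + (take - cum[a])])
        if not ii:
            continue
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        r = (z[:, ii] * z[:, jj]).mean(axis=0)
        r2_adj = r**2 - 1.0 / n
        mean_c = float((c_morgan[jj] - c_morgan[ii]).mean())
        e = float(r2_adj.mean())
        f_c = float(fmap(mean_c))
        out.append(
            {
                "t_generations": 1.0 / (2.0 * f_c),
                "ne": sved_feldman_ne(f_c, e, alpha),
                "mean_c_morgan": mean_c,
                "mean_r2_adj": e,
                "n_pairs": len(ii),
            }
        )
    return pd.DataFrame(out, columns=["t_generations", "ne", "mean_c_morgan", "mean_r2_adj", "n_pairs"])


def reynolds_theta(p1: np.ndarray, p2: np.ndarray) -> float:
    """Reynolds' coancestry distance between two allele-frequency vectors.

    ``theta = sum (p1 - p2)^2 / sum (p1 + p2 - 2 p1 p2)`` over loci with a
    positive denominator term (uncorrected biallelic form).
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    den_terms = p1 + p2 - 2.0 * p1 * p2
    ok = den_terms > 0
    den = den_terms[ok].sum()
    if den == 0:
        raise ValueError("populations share no polymorphic locus")
    return float(((p1[ok] - p2[ok]) ** 2).sum() / den)


def reynolds_matrix(freqs: dict, transform: str = "theta") -> pd.DataFrame:
    """Symmetric Reynolds' distance matrix from per-population frequencies.

    *freqs* maps population id -> allele-frequency vector over a shared
    marker set. ``transform="ln"`` applies the -ln(1 - theta) variant.
    """
    pops = list(freqs)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    d = np.zeros((len(pops), len(pops)))
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            theta = reynolds_theta(freqs[pops[a]], freqs[pops[b]])
            if transform == "ln":
                theta = -np.log(max(1.0 - theta, 1e-300))
            d[a, b] = d[b, a] = theta
    return pd.DataFrame(d, index=pops, columns=pops)


def write_phylip(matrix: pd.DataFrame, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)}\n")
        for pop in matrix.index:
            vals = " ".join(f"{v:.6f}" for v in matrix.loc[pop])
            fh.write(f"{str(pop)[:10]:<10s} {vals}\n")


def write_nexus_distances(matrix: pd.DataFrame, path) -> None:
    """NEXUS distances block (for SplitsTree-style Neighbour-Net viewers)."""
    n = len(matrix)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
        for i, pop in enumerate(matrix.index, 1):
            fh.write(f"[{i}] '{pop}'\n")
        fh.write(";\nEND;\n\nBEGIN Distances;\n")
        fh.write(f"DIMENSIONS ntax={n};\nFORMAT labels=left diagonal triangle=both;\nMATRIX\n")
        for pop in matrix.index:
            vals = " ".join(f"{v:.6f}" for v in matrix.loc[pop])
            fh.write(f"'{pop}' {vals}\n")
        fh.write(";\nEND;\n")
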