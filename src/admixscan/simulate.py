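"""Synthetic admixed-cattle study generator with known ground truth.

The generator emulates the study design the pipeline is built for: two
strongly diverged ancestry classes (a taurine-like class A and an
indicine-like class B, three reference populations each, drawn under the
Balding–Nichols model), a target population carrying ~12% class-B ancestry
laid down as a recombination mosaic ~100 generations old, and optionally one
introgressed tract driven to high frequency by copying a single class-B
donor haplotype into most target haplotypes — producing both near-fixed
local B ancestry and the extended haplotype homozygosity of a sweep.

Reference haplotypes are drawn with independent sites (no background LD);
see the methods note for what that does and does not exercise. A small
forward Wright–Fisher simulator with recombination is included to provide
linked data for the LD-based Ne estimator.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .io import write_phased_vcf, write_popmap
from .panel import HaplotypePanel, MarkerMap

__all__ = [
    "SimConfig",
    "TruthTracks",
    "ReferenceSet",
    "balding_nichols_panel",
    "simulate_admixed",
    "inject_adaptive_tract",
    "generate_study",
    "wright_fisher_panel",
]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the target scenario: 5,000 markers on one 100-cM
    chromosome (1 cM/Mb), two ancestry classes diverged at F=0.3 with three
    reference populations each (within-class drift F=0.15, 30 haplotypes
    per population), and 50 target samples with alpha=0.12 minor-ancestry
    admixture dating g=100 generations back. ``sweep`` is
    ``(center_cM, tract_halfwidth_cM, carrier_fraction)`` or ``None``.
    """

    n_markers: int = 5000
    chrom: str = "1"
    chrom_length_cM: float = 100.0
    n_ref_pops_A: int = 3
    n_ref_pops_B: int = 3
    F_div: float = 0.15
    F_class: float = 0.3
    n_hap_per_ref: int = 30
    n_target_samples: int = 50
    alpha: float = 0.12
    g_admix: float = 100.0
    sweep: tuple | None = None
    target_pop: str = "TGT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("F_div", "F_class"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_markers < 100:
            raise ValueError("n_markers must be >= 100 (windowing needs >= 5 windows)")
        if self.n_hap_per_ref % 2 or self.n_hap_per_ref < 4:
            raise ValueError("n_hap_per_ref must be an even number >= 4")
        if self.sweep is not None:
            center, halfwidth, carrier = self.sweep
            if not 0 < carrier <= 1:
                raise ValueError("carrier_fraction must be in (0, 1]")
            if 2 * halfwidth > self.chrom_length_cM:
                raise ValueError("sweep tract wider than the chromosome")
            if not 0 <= center - halfwidth <= center + halfwidth <= self.chrom_length_cM:
                raise ValueError("sweep tract outside the chromosome")

    @property
    def ref_pops_A(self) -> list:
        return [f"A{i+1}" for i in range(self.n_ref_pops_A)]

    @property
    def ref_pops_B(self) -> list:
        return [f"B{i+1}" for i in range(self.n_ref_pops_B)]

    def marker_map(self) -> MarkerMap:
        """Evenly spaced markers along the chromosome at 1 cM/Mb."""
        cm = (np.arange(self.n_markers) + 0.5) * self.chrom_length_cM / self.n_markers
        bp = np.round(cm * 1e6).astype(np.int64)
        # allele 0 is declared ancestral at every site (coding convention)
        aa = np.zeros(self.n_markers, dtype=np.int8)
        return MarkerMap(np.full(self.n_markers, self.chrom, dtype=object), bp, cm, aa)


@dataclass
class TruthTracks:
    """True ancestry mosaic of the simulated target haplotypes.

    ``segments[h]`` is an ordered list of ``(start_marker, end_marker,
    ancestry)`` tuples (half-open marker ranges tiling ``[0, n_markers)``),
    ``labels`` the same information as a haplotypes x markers 0/1 matrix
    (1 = class B), ``donors[h]`` the founder-pool row each segment was copied
    from (``None`` once a haplotype is overwritten by the injected tract),
    and ``carries_tract`` flags haplotypes carrying the adaptive tract.
    """

    segments: list
    labels: np.ndarray
    donors: list
    carries_tract: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.labels.shape[0]

    def b_fraction(self) -> np.ndarray:
        """Per-haplotype fraction of markers with class-B ancestry."""
        return self.labels.mean(axis=1)

    def window_labels(self, bounds: np.ndarray) -> np.ndarray:
        """Majority ancestry per window given half-open marker ``bounds``."""
        out = np.empty((self.labels.shape[0], len(bounds) - 1), dtype=np.int8)
        for w in range(len(bounds) - 1):
            out[:, w] = (
                self.labels[:, bounds[w] : bounds[w + 1]].mean(axis=1) >= 0.5
            ).astype(np.int8)
        return out


@dataclass
class ReferenceSet:
    """Reference panels drawn under the Balding–Nichols model."""

    panels: list
    ancestral_freq: np.ndarray
    class_freq_a: np.ndarray
    class_freq_b: np.ndarray
    markers: MarkerMap

    def combined(self) -> HaplotypePanel:
        return HaplotypePanel.concat_samples(self.panels)

    def class_pool(self, cls: str) -> HaplotypePanel:
        prefix = cls.upper()
        sel = [p for p in self.panels if p.pop_labels[0].startswith(prefix)]
        return HaplotypePanel.concat_samples(sel)


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols daughter frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    lam = (1.0 - F) / F
    # clip away exact fixation so a further drift level keeps valid Beta params
    return np.clip(rng.beta(p * lam, (1.0 - p) * lam), 1e-9, 1.0 - 1e-9)


def _panel_from_freq(
    rng: np.random.Generator,
    freq: np.ndarray,
    n_hap: int,
    pop: str,
    markers: MarkerMap,
) -> HaplotypePanel:
    alleles = (rng.random((n_hap, len(freq))) < freq).astype(np.int8)
    samples = [f"{pop}s{i+1}" for i in range(n_hap // 2)]
    return HaplotypePanel(alleles, samples, [pop] * len(samples), markers)


def balding_nichols_panel(
    config: SimConfig, seed: int | None = None
) -> ReferenceSet:
    """Draw the two-class reference panels.

    Ancestral frequencies are Uniform(0.05, 0.95); the two class-level
    frequency vectors drift from them with ``F_class``, and each reference
    population's frequencies drift from its class with ``F_div``. Haplotype
    alleles are sampled independently per marker.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    markers = config.marker_map()
    p_anc = rng.uniform(0.05, 0.95, size=config.n_markers)
    p_class_a = _bn_draw(rng, p_anc, config.F_class)
    p_class_b = _bn_draw(rng, p_anc, config.F_class)
    panels = []
    for pop in config.ref_pops_A:
        panels.append(
            _panel_from_freq(
                rng, _bn_draw(rng, p_class_a, config.F_div), config.n_hap_per_ref, pop, markers
            )
        )
    for pop in config.ref_pops_B:
        panels.append(
            _panel_from_freq(
                rng, _bn_draw(rng, p_class_b, config.F_div), config.n_hap_per_ref, pop, markers
            )
        )
    return ReferenceSet(panels, p_anc, p_class_a, p_class_b, markers)


def draw_breakpoints(
    rng: np.random.Generator, g_admix: float, length_cm: float
) -> np.ndarray:
    """Crossover breakpoints of one admixed haplotype (cM positions).

    A Poisson process of rate ``g_admix`` per Morgan: the expected count is
    ``g_admix * length_cm / 100`` and inter-breakpoint distances are
    Exponential with mean ``100 / g_admix`` cM.
    """
    n_bk = rng.poisson(g_admix * length_cm / 100.0)
    return np.sort(rng.uniform(0.0, length_cm, size=n_bk))


def simulate_admixed(
    ref_A_pool: HaplotypePanel,
    ref_B_pool: HaplotypePanel,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[HaplotypePanel, TruthTracks]:
    """Build target haplotypes as ancestry mosaics copied from founder pools.

    Per haplotype, crossover breakpoints follow a Poisson process of rate
    ``g_admix`` per Morgan along the genetic map; each segment is labelled
    class B independently with probability ``alpha`` and its alleles are
    copied from one uniformly chosen founder haplotype of that ancestry.
    """
    if ref_A_pool.n_haplotypes == 0 or ref_B_pool.n_haplotypes == 0:
        raise ValueError("founder pools must be non-empty")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    markers = ref_A_pool.markers
    pos_cm = markers.pos_cM
    length_cm = config.chrom_length_cM
    n_hap = 2 * config.n_target_samples
    n_mark = markers.n_markers

    alleles = np.empty((n_hap, n_mark), dtype=np.int8)
    labels = np.empty((n_hap, n_mark), dtype=np.int8)
    segments: list = []
    donors: list = []
    pools = {"A": ref_A_pool, "B": ref_B_pool}
    for h in range(n_hap):
        breaks = draw_breakpoints(rng, config.g_admix, length_cm)
        bounds_cm = np.concatenate(([0.0], breaks, [length_cm]))
        seg_is_b = rng.random(len(bounds_cm) - 1) < config.alpha
        # marker index boundaries of each segment
        cut = np.searchsorted(pos_cm, bounds_cm[1:-1])
        starts = np.concatenate(([0], cut))
        ends = np.concatenate((cut, [n_mark]))
        hap_segments, hap_donors = [], []
        for s, e, is_b in zip(starts, ends, seg_is_b):
            if e <= s:
                continue  # segment contains no markers
            anc = "B" if is_b else "A"
            pool = pools[anc]
            donor = int(rng.integers(pool.n_haplotypes))
            alleles[h, s:e] = pool.alleles[donor, s:e]
            labels[h, s:e] = 1 if is_b else 0
            hap_segments.append((int(s), int(e), anc))
            hap_donors.append(donor)
        segments.append(hap_segments)
        donors.append(hap_donors)

    samples = [f"{config.target_pop}s{i+1}" for i in range(config.n_target_samples)]
    panel = HaplotypePanel(
        alleles, samples, [config.target_pop] * len(samples), markers
    )
    truth = TruthTracks(
        segments, labels, donors, np.zeros(n_hap, dtype=bool)
    )
    return panel, truth


def _segments_from_labels(lab: np.ndarray) -> list:
    """Merge a 0/1 marker-label vector into half-open (start, end, ancestry) runs."""
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(lab)]))
    return [
        (int(s), int(e), "B" if lab[s] else "A") for s, e in zip(starts, ends)
    ]


def inject_adaptive_tract(
    target_panel: HaplotypePanel,
    truth: TruthTracks,
    sweep_params: tuple,
    seed: int,
    donor_pool: HaplotypePanel | None = None,
    donor_freq: np.ndarray | None = None,
) -> tuple[HaplotypePanel, TruthTracks]:
    """Overwrite a share of target haplotypes with one class-B donor template.

    ``sweep_params`` is ``(center_cM, tract_halfwidth_cM, carrier_fraction)``.
    All carriers receive the *same* donor haplotype over the tract, creating
    near-fixed class-B local ancestry plus extended haplotype homozygosity —
    the joint signature of adaptive introgression. The template is drawn from
    *donor_freq* (class-level allele frequencies — a haplotype from the donor
    class's common ancestral pool, recognisable as class B under any class-B
    reference) when given, else copied from a uniformly chosen haplotype of
    *donor_pool*. Returns modified copies; inputs are left untouched.
    """
    center, halfwidth, carrier_fraction = sweep_params
    if not 0 < carrier_fraction <= 1:
        raise ValueError("carrier_fraction must be in (0, 1]")
    pos_cm = target_panel.markers.pos_cM
    span = pos_cm[-1] - pos_cm[0]
    if 2 * halfwidth > span + (pos_cm[1] - pos_cm[0]):
        raise ValueError("tract wider than the chromosome")
    lo = np.searchsorted(pos_cm, center - halfwidth)
    hi = np.searchsorted(pos_cm, center + halfwidth, side="right")
    if hi <= lo:
        raise ValueError("tract contains no markers")

    rng = np.random.default_rng(seed)
    if donor_freq is not None:
        template = (rng.random(hi - lo) < np.asarray(donor_freq)[lo:hi]).astype(np.int8)
    elif donor_pool is not None:
        template = donor_pool.alleles[int(rng.integers(donor_pool.n_haplotypes)), lo:hi]
    else:
        raise ValueError("supply donor_freq or donor_pool")
    n_hap = target_panel.n_haplotypes
    n_carriers = int(round(carrier_fraction * n_hap))
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)

    alleles = target_panel.alleles.copy()
    labels = truth.labels.copy()
    alleles[carriers, lo:hi] = template
    labels[carriers, lo:hi] = 1
    segments = list(truth.segments)
    donors = list(truth.donors)
    flags = truth.carries_tract.copy()
    for h in carriers:
        segments[h] = _segments_from_labels(labels[h])
        donors[h] = None
        flags[h] = True
    panel = HaplotypePanel(
        alleles, target_panel.sample_ids, target_panel.pop_labels, target_panel.markers
    )
    return panel, TruthTracks(segments, labels, donors, flags)


@dataclass
class StudyData:
    """In-memory result of :func:`generate_study`."""

    config: SimConfig
    references: ReferenceSet
    target: HaplotypePanel
    truth: TruthTracks
    panel: HaplotypePanel = field(init=False)

    def __post_init__(self) -> None:
        self.panel = HaplotypePanel.concat_samples(self.references.panels + [self.target])


def simulate_study(config: SimConfig) -> StudyData:
    """Simulate references + admixed targets (+ optional adaptive tract) in memory.

    Stage seeds are derived deterministically from ``config.seed``.
    """
    refs = balding_nichols_panel(config, seed=config.seed)
    target, truth = simulate_admixed(
        refs.class_pool("A"), refs.class_pool("B"), config, seed=config.seed + 1_000_003
    )
    if config.sweep is not None:
        target, truth = inject_adaptive_tract(
            target, truth, config.sweep, config.seed + 2_000_003,
            donor_freq=refs.class_freq_b,
        )
    return StudyData(config, refs, target, truth)


def generate_study(config: SimConfig, outdir: str | os.PathLike) -> StudyData:
    """Simulate a study and write VCF, popmap, truth BED and a config echo.

    Outputs (all deterministic per seed): ``panel.vcf`` with every reference
    and target sample, ``popmap.tsv``, ``truth_b_tracts.bed`` (one record per
    true class-B segment, name = haplotype id) and ``sim_config.json``.
    """
    study = simulate_study(config)
    os.makedirs(outdir, exist_ok=True)
    write_phased_vcf(study.panel, os.path.join(outdir, "panel.vcf"))
    write_popmap(study.panel, os.path.join(outdir, "popmap.tsv"))
    m = study.target.markers
    hap_ids = study.target.hap_ids
    with open(os.path.join(outdir, "truth_b_tracts.bed"), "w") as fh:
        for h, segs in enumerate(study.truth.segments):
            for s, e, anc in segs:
                if anc == "B":
                    fh.write(
                        f"{config.chrom}\t{m.pos_bp[s]-1}\t{m.pos_bp[e-1]}\t{hap_ids[h]}\n"
                    )
    with open(os.path.join(outdir, "sim_config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
    return study


def wright_fisher_panel(
    n_diploid: int = 200,
    n_markers: int = 5000,
    n_generations: int = 50,
    chrom_length_cM: float = 100.0,
    chrom: str = "1",
    seed: int = 0,
) -> HaplotypePanel:
    """Forward Wright–Fisher population with recombination at constant size.

    Founders carry independent sites with frequencies Uniform(0.1, 0.9);
    each generation every offspring draws two uniformly chosen (monoecious)
    parents and receives one recombinant gamete from each, with Poisson
    crossovers along the genetic map. The emitted panel holds all ``n_diploid``
    individuals of the final generation as population ``WF``.
    """
    rng = np.random.default_rng(seed)
    cm = (np.arange(n_markers) + 0.5) * chrom_length_cM / n_markers
    bp = np.round(cm * 1e6).astype(np.int64)
    markers = MarkerMap(np.full(n_markers, chrom, dtype=object), bp, cm)
    freqs = rng.uniform(0.1, 0.9, size=n_markers)
    pop = (rng.random((n_diploid, 2, n_markers)) < freqs).astype(np.int8)
    morgans = chrom_length_cM / 100.0

    def gamete(parent: np.ndarray) -> np.ndarray:
        n_x = rng.poisson(morgans)
        if n_x == 0:
            return parent[rng.integers(2)].copy()
        xpos = np.sort(rng.uniform(0.0, chrom_length_cM, size=n_x))
        cuts = np.searchsorted(cm, xpos)
        out = np.empty(n_markers, dtype=np.int8)
        bounds = np.concatenate(([0], cuts, [n_markers]))
        which = rng.integers(2)
        for k in range(len(bounds) - 1):
            out[bounds[k] : bounds[k + 1]] = parent[(which + k) % 2, bounds[k] : bounds[k + 1]]
        return out

    for _ in range(n_generations):
        nxt = np.empty_like(pop)
        mothers = rng.integers(n_diploid, size=n_diploid)
        fathers = rng.integers(n_diploid, size=n_diploid)
        for i in range(n_diploid):
            nxt[i, 0] = gamete(pop[mothers[i]])
            nxt[i, 1] = gamete(pop[fathers[i]])
        pop = nxt

    alleles = pop.reshape(2 * n_diploid, n_markers)
    samples = [f"WFs{i+1}" for i in range(n_diploid)]
    return HaplotypePanel(alleles, samples, ["WF"] * n_diploid, markers)
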