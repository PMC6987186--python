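"""Core in-memory containers for marker maps, genotype and haplotype panels.

Everything downstream (QC, local ancestry inference, consensus introgression
calling, the nSL scan and the diversity statistics) operates on these three
objects:

* :class:`MarkerMap` — per-marker chromosome, physical (bp) and genetic (cM)
  position, and optional ancestral-allele polarity.
* :class:`GenotypePanel` — samples x markers alt-allele dosage matrix with
  missing calls; the substrate for heterozygosity and runs of homozygosity.
* :class:`HaplotypePanel` — phased haplotypes x markers binary allele matrix
  (two haplotypes per sample, no missing data); the substrate for local
  ancestry inference, LD statistics and the haplotype-homozygosity scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypePanel",
    "HaplotypePanel",
    "QCReport",
    "MISSING",
    "AA_UNKNOWN",
]

#: sentinel for a missing genotype call
MISSING: int = -1
#: sentinel for an unknown ancestral allele
AA_UNKNOWN: int = -1

#: default physical-to-genetic scaling when no map is supplied (1 cM per Mb),
#: the customary assumption for cattle array data without a fine-scale map
CM_PER_BP_DEFAULT = 1e-6


@dataclass
class MarkerMap:
    """Per-marker positions and optional ancestral-allele polarity.

    Parameters
    ----------
    chrom
        Chromosome identifier per marker.
    pos_bp
        1-based physical position, strictly increasing within a chromosome.
    pos_cM
        Genetic position in centimorgans, non-decreasing within a chromosome.
        When ``None``, defaults to 1 cM/Mb.
    ancestral_allele
        0 (REF ancestral), 1 (ALT ancestral) or ``AA_UNKNOWN`` per marker.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cM: np.ndarray | None = None
    ancestral_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if self.pos_cM is None:
            self.pos_cM = self.pos_bp * CM_PER_BP_DEFAULT
        self.pos_cM = np.asarray(self.pos_cM, dtype=np.float64)
        if self.ancestral_allele is None:
            self.ancestral_allele = np.full(len(self.pos_bp), AA_UNKNOWN, dtype=np.int8)
        self.ancestral_allele = np.asarray(self.ancestral_allele, dtype=np.int8)
        n = len(self.pos_bp)
        if not (len(self.chrom) == len(self.pos_cM) == len(self.ancestral_allele) == n):
            raise ValueError("MarkerMap field lengths disagree")
        for c in self.chromosomes():
            sel = self.chrom == c
            bp = self.pos_bp[sel]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on chromosome {c}")
            cm = self.pos_cM[sel]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"pos_cM decreasing on chromosome {c}")
        bad = ~np.isin(self.ancestral_allele, (0, 1, AA_UNKNOWN))
        if bad.any():
            raise ValueError("ancestral_allele values must be 0, 1 or unknown")

    def __len__(self) -> int:
        return len(self.pos_bp)

    @property
    def n_markers(self) -> int:
        return len(self.pos_bp)

    def chromosomes(self) -> list:
        """Chromosome identifiers in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            self.chrom[idx],
            self.pos_bp[idx],
            self.pos_cM[idx],
            self.ancestral_allele[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "pos_cM": self.pos_cM,
                "ancestral_allele": self.ancestral_allele,
            }
        )


def _check_pop_labels(sample_ids: Sequence[str], pop_labels: Sequence[str]) -> None:
    if len(sample_ids) != len(pop_labels):
        raise ValueError("every sample needs a population label")


@dataclass
class GenotypePanel:
    """Samples x markers alt-allele dosage matrix ({0,1,2}, MISSING for no-call)."""

    genotypes: np.ndarray
    sample_ids: list
    pop_labels: list
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.pop_labels = list(self.pop_labels)
        _check_pop_labels(self.sample_ids, self.pop_labels)
        ns, nm = self.genotypes.shape
        if ns != len(self.sample_ids) or nm != self.markers.n_markers:
            raise ValueError("genotype matrix dimensions inconsistent with labels/markers")
        ok = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype values must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def populations(self) -> list:
        seen: dict = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)

    def samples_for(self, pop: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.pop_labels, dtype=object) == pop)

    def subset_markers(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            self.genotypes[:, idx], self.sample_ids, self.pop_labels, self.markers.subset(idx)
        )

    def allele_frequencies(self, pop: str | None = None) -> np.ndarray:
        """Alt-allele frequency per marker, computed on called genotypes only."""
        g = self.genotypes
        if pop is not None:
            g = g[self.samples_for(pop)]
        called = g != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(called, g, 0).sum(axis=0) / (2.0 * called.sum(axis=0))


@dataclass
class HaplotypePanel:
    """Phased haplotypes x markers binary allele matrix (no missing values).

    Haplotypes ``2*i`` and ``2*i + 1`` belong to sample ``i``.
    """

    alleles: np.ndarray
    sample_ids: list
    pop_labels: list
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.pop_labels = list(self.pop_labels)
        _check_pop_labels(self.sample_ids, self.pop_labels)
        nh, nm = self.alleles.shape
        if nh != 2 * len(self.sample_ids):
            raise ValueError("expected exactly two haplotypes per sample")
        if nm != self.markers.n_markers:
            raise ValueError("allele matrix marker count disagrees with MarkerMap")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0 or 1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def hap_ids(self) -> list:
        return [f"{s}_{k}" for s in self.sample_ids for k in (1, 2)]

    def hap_pop_labels(self) -> np.ndarray:
        return np.repeat(np.asarray(self.pop_labels, dtype=object), 2)

    def populations(self) -> list:
        seen: dict = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)

    def haplotypes_for(self, pop: str) -> np.ndarray:
        """Row indices of the haplotypes belonging to *pop*."""
        return np.flatnonzero(self.hap_pop_labels() == pop)

    def subset_markers(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            self.alleles[:, idx], self.sample_ids, self.pop_labels, self.markers.subset(idx)
        )

    def subset_samples(self, sample_idx: np.ndarray) -> "HaplotypePanel":
        sample_idx = np.asarray(sample_idx)
        hap_idx = np.repeat(2 * sample_idx, 2) + np.tile([0, 1], len(sample_idx))
        return HaplotypePanel(
            self.alleles[hap_idx],
            [self.sample_ids[i] for i in sample_idx],
            [self.pop_labels[i] for i in sample_idx],
            self.markers,
        )

    def allele_frequencies(self, pop: str | None = None) -> np.ndarray:
        a = self.alleles
        if pop is not None:
            a = a[self.haplotypes_for(pop)]
        return a.mean(axis=0)

    def to_genotypes(self) -> GenotypePanel:
        g = self.alleles[0::2].astype(np.int8) + self.alleles[1::2].astype(np.int8)
        return GenotypePanel(g, self.sample_ids, self.pop_labels, self.markers)

    @staticmethod
    def concat_samples(panels: Sequence["HaplotypePanel"]) -> "HaplotypePanel":
        """Stack panels that share one MarkerMap into a single multi-population panel."""
        first = panels[0]
        for p in panels[1:]:
            if p.n_markers != first.n_markers or not np.array_equal(
                p.markers.pos_bp, first.markers.pos_bp
            ):
                raise ValueError("panels do not share a marker map")
        return HaplotypePanel(
            np.vstack([p.alleles for p in panels]),
            [s for p in panels for s in p.sample_ids],
            [l for p in panels for l in p.pop_labels],
            first.markers,
        )


@dataclass
class QCReport:
    """Bookkeeping for marker-level QC; a marker is counted once, by the first
    filter that removed it (unmapped -> call rate -> MAF)."""

    n_input_markers: int
    n_removed_maf: int = 0
    n_removed_callrate: int = 0
    n_removed_unmapped: int = 0
    n_retained: int = field(default=0)

    def __post_init__(self) -> None:
        for v in (
            self.n_input_markers,
            self.n_removed_maf,
            self.n_removed_callrate,
            self.n_removed_unmapped,
            self.n_retained,
        ):
            if v < 0:
                raise ValueError("QCReport counts must be non-negative")
        expected = (
            self.n_input_markers
            - self.n_removed_maf
            - self.n_removed_callrate
            - self.n_removed_unmapped
        )
        if self.n_retained != expected:
            raise ValueError("QCReport counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_input_markers": self.n_input_markers,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_callrate": self.n_removed_callrate,
            "n_removed_unmapped": self.n_removed_unmapped,
            "n_retained": self.n_retained,
        }
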