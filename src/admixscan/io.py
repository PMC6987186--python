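"""Reading and writing the pipeline's on-disk formats.

Phased VCF 4.2 is the genotype interchange format (read via :mod:`cyvcf2`,
written by hand so output is byte-deterministic); the sample-to-population
map is a two-column TSV; gene intervals come from BED4 (0-based half-open)
or GFF3 (1-based closed) and are normalised to 1-based closed internally.

Genetic positions survive a VCF round trip through the non-standard INFO key
``CM``; ancestral alleles through the conventional ``AA`` key (the ancestral
base, matched against REF/ALT on read).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import AA_UNKNOWN, HaplotypePanel, MarkerMap

__all__ = [
    "read_popmap",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_gene_intervals",
]

_REF_BASE = "A"
_ALT_BASE = "C"


def read_popmap(path: str | os.PathLike) -> dict:
    """Read a two-column ``sample<TAB>population`` map."""
    mapping: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {ln}: expected 'sample<TAB>population'")
            mapping[parts[0]] = parts[1]
    return mapping


def read_phased_vcf(path: str | os.PathLike, popmap_path: str | os.PathLike) -> HaplotypePanel:
    """Load a phased biallelic-SNP VCF into a :class:`HaplotypePanel`.

    Alleles are coded 0=REF, 1=ALT. The ancestral allele is taken from
    INFO/AA when present (matched against the REF and ALT bases), genetic
    positions from INFO/CM when present (1 cM/Mb otherwise).

    Raises
    ------
    ValueError
        On an unphased or missing genotype (naming sample and position), a
        multi-allelic record, or a VCF sample absent from the popmap.
    """
    popmap = read_popmap(popmap_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in popmap]
    if missing:
        raise ValueError(f"samples missing from popmap: {', '.join(missing)}")

    chroms, pos_bp, pos_cm, aa = [], [], [], []
    columns = []
    any_cm = False
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic site at {var.CHROM}:{var.POS}; only biallelic SNPs supported"
            )
        gts = var.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, (g, s) in enumerate(zip(gts, samples)):
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(f"missing genotype for sample {s} at {var.CHROM}:{var.POS}")
            if not phased:
                raise ValueError(f"unphased genotype for sample {s} at {var.CHROM}:{var.POS}")
            col[2 * i] = a0
            col[2 * i + 1] = a1
        columns.append(col)
        chroms.append(var.CHROM)
        pos_bp.append(var.POS)
        cm = var.INFO.get("CM")
        if cm is not None:
            any_cm = True
            pos_cm.append(float(cm))
        else:
            pos_cm.append(var.POS * 1e-6)
        aa_base = var.INFO.get("AA")
        if aa_base == var.REF:
            aa.append(0)
        elif aa_base is not None and aa_base == var.ALT[0]:
            aa.append(1)
        else:
            aa.append(AA_UNKNOWN)

    # preserve chromosome first-appearance order, sort by position within
    chrom_arr = np.asarray(chroms, dtype=object)
    first_seen: dict = {}
    for c in chroms:
        first_seen.setdefault(c, len(first_seen))
    order = np.lexsort(
        (np.asarray(pos_bp), np.asarray([first_seen[c] for c in chroms]))
    )
    markers = MarkerMap(
        chrom_arr[order],
        np.asarray(pos_bp, dtype=np.int64)[order],
        np.asarray(pos_cm, dtype=np.float64)[order] if any_cm else None,
        np.asarray(aa, dtype=np.int8)[order],
    )
    alleles = np.stack(columns, axis=1)[:, order] if columns else np.empty(
        (2 * len(samples), 0), dtype=np.int8
    )
    return HaplotypePanel(alleles, samples, [popmap[s] for s in samples], markers)


def write_phased_vcf(panel: HaplotypePanel, path: str | os.PathLike) -> None:
    """Write a panel as a phased VCF 4.2 with deterministic byte output.

    All sites use synthetic REF/ALT bases (A/C); INFO carries ``CM`` (genetic
    position) always and ``AA`` (ancestral base) where known.
    """
    m = panel.markers
    lines = ["##fileformat=VCFv4.2"]
    for c in m.chromosomes():
        sel = m.chrom == c
        length = int(m.pos_bp[sel].max()) if sel.any() else 0
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    lines.append('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position (cM)">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.sample_ids)
    )
    a = panel.alleles
    for j in range(panel.n_markers):
        info = f"CM={m.pos_cM[j]:.6f}"
        if m.ancestral_allele[j] == 0:
            info += f";AA={_REF_BASE}"
        elif m.ancestral_allele[j] == 1:
            info += f";AA={_ALT_BASE}"
        gts = "\t".join(f"{a[2*i, j]}|{a[2*i+1, j]}" for i in range(panel.n_samples))
        lines.append(
            f"{m.chrom[j]}\t{m.pos_bp[j]}\t.\t{_REF_BASE}\t{_ALT_BASE}\t.\t.\t{info}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_popmap(panel: HaplotypePanel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s, p in zip(panel.sample_ids, panel.pop_labels):
            fh.write(f"{s}\t{p}\n")


def read_gene_intervals(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene intervals from BED4 or GFF3 (dialect by file extension).

    Returns a frame with columns ``chrom, start_bp, end_bp, name`` in 1-based
    closed coordinates. Overlapping genes are retained as-is (no merging).
    """
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    rows = []
    if ext == ".bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}: line {ln}: BED4 needs chrom,start,end,name")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {ln}: non-integer coordinates") from exc
                rows.append((parts[0], start + 1, end, parts[3]))
    elif ext in (".gff", ".gff3"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}: line {ln}: GFF3 needs 9 columns")
                if parts[2] != "gene":
                    continue
                try:
                    start, end = int(parts[3]), int(parts[4])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {ln}: non-integer coordinates") from exc
                name = None
                for kv in parts[8].split(";"):
                    kv = kv.strip()
                    if kv.startswith("Name="):
                        name = kv[5:]
                        break
                    if kv.startswith("ID=") and name is None:
                        name = kv[3:]
                if name is None:
                    raise ValueError(f"{path}: line {ln}: gene record lacks Name/ID attribute")
                rows.append((parts[0], start, end, name))
    else:
        raise ValueError(f"cannot infer gene-interval dialect from extension {ext!r}")
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])
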