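"""Parental genotype I/O: VCF reading with SNP filters, allele frequencies.

Parents of both ploidies are stored on the diploid base representation
(dosages 0/1/2): colchicine-doubled tetraploids carry two identical genome
copies, so their tetraploid dosage is obtained by doubling the diploid base
dosage at matrix-construction time.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

log = logging.getLogger(__name__)
if not log.handlers:  # record counts at each filter step go to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    log.addHandler(_h)


@dataclass
class ParentGenotypes:
    """Bi-allelic SNP dosages of the parental panel on the diploid base.

    Attributes
    ----------
    parent_ids : list of str
        Unique sample identifiers, in VCF sample order (or construction order).
    marker_ids : list of str
        Unique marker identifiers ``chrom:pos`` (1-based positions).
    chrom, pos : arrays
        Chromosome and 1-based position per marker.
    dosages : (n_parents, n_markers) int8 array
        Alternative-allele counts in {0, 1, 2}; no missing entries.
    freqs : (n_markers,) float array
        Alternative-allele frequency per marker, strictly inside (0, 1).
    base_ploidy : int
        Always 2; tetraploids are doubled on use.
    """

    parent_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    freqs: np.ndarray = field(default=None)  # type: ignore[assignment]
    base_ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a parents x markers matrix")
        if self.dosages.shape != (len(self.parent_ids), len(self.marker_ids)):
            raise ValueError("dosage matrix shape does not match identifiers")
        if len(set(self.parent_ids)) != len(self.parent_ids):
            raise ValueError("parent_ids are not unique")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids are not unique")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be integers in {0, 1, 2}")
        if self.freqs is None:
            self.freqs = compute_allele_freqs(self)
        self.freqs = np.asarray(self.freqs, dtype=float)

    @property
    def n_parents(self) -> int:
        return len(self.parent_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def index_of(self, parents: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.parent_ids)}
        missing = [p for p in parents if p not in lookup]
        if missing:
            raise KeyError(f"parents not in panel: {missing}")
        return np.array([lookup[p] for p in parents], dtype=int)

    def subset_parents(self, parents: Sequence[str]) -> "ParentGenotypes":
        idx = self.index_of(parents)
        return ParentGenotypes(
            parent_ids=list(parents),
            marker_ids=list(self.marker_ids),
            chrom=self.chrom,
            pos=self.pos,
            dosages=self.dosages[idx],
            freqs=self.freqs,
        )


def compute_allele_freqs(
    geno: ParentGenotypes, reference_set: Iterable[str] | None = None
) -> np.ndarray:
    """Alternative-allele frequency per marker from diploid base dosages.

    ``fm = sum(dosages over the reference set) / (2 * n_reference)``.  Each
    parent is counted once regardless of how many crosses or ploidy states it
    is used in; the default reference set is the full panel.
    """
    if reference_set is None:
        idx = np.arange(geno.n_parents)
    else:
        parents = list(reference_set)
        if not parents:
            raise ValueError("reference set must be non-empty")
        idx = geno.index_of(parents)
    return geno.dosages[idx].sum(axis=0) / (2.0 * len(idx))


def read_parent_vcf(
    path: str, keep_parents: Iterable[str] | None = None
) -> ParentGenotypes:
    """Read parental genotypes from a VCF, applying the panel SNP filters.

    Records are dropped when they are INDELs, multi-allelic, carry any
    missing genotype among the kept parents, or are monomorphic within the
    kept parents.  Dosages are coded as alternative-allele counts.
    """
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    if keep_parents is None:
        keep = samples
    else:
        keep = list(keep_parents)
        missing = [s for s in keep if s not in samples]
        if missing:
            raise KeyError(f"samples absent from VCF {path}: {missing}")

    rows: list[list[int]] = []
    chroms: list[str] = []
    positions: list[int] = []
    counts = {"total": 0, "indel_or_multiallelic": 0, "missing": 0, "monomorphic": 0}
    for rec in vcf:
        counts["total"] += 1
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            counts["indel_or_multiallelic"] += 1
            continue
        dose = []
        ok = True
        for s in keep:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                ok = False
                break
            dose.append(sum(gt))
        if not ok:
            counts["missing"] += 1
            continue
        total = sum(dose)
        if total == 0 or total == 2 * len(keep):
            counts["monomorphic"] += 1
            continue
        rows.append(dose)
        chroms.append(rec.chrom)
        positions.append(rec.pos)  # pysam reports 1-based positions
    vcf.close()

    log.info(
        "VCF %s: %d records, removed %d indel/multi-allelic, %d with missing "
        "genotypes, %d monomorphic; retained %d",
        path, counts["total"], counts["indel_or_multiallelic"],
        counts["missing"], counts["monomorphic"], len(rows),
    )
    if not rows:
        raise ValueError(f"no markers retained from {path} after filtering")

    dosages = np.array(rows, dtype=np.int8).T  # parents x markers
    marker_ids = [f"{c}:{p}" for c, p in zip(chroms, positions)]
    return ParentGenotypes(
        parent_ids=keep,
        marker_ids=marker_ids,
        chrom=np.array(chroms),
        pos=np.array(positions, dtype=int),
        dosages=dosages,
    )


def write_parent_vcf(geno: ParentGenotypes, path: str) -> None:
    """Write the panel back to an uncompressed VCF (diploid GT calls)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in dict.fromkeys(geno.chrom.tolist()):
        header.contigs.add(str(c))
    for s in geno.parent_ids:
        header.add_sample(s)
    out = pysam.VariantFile(path, "w", header=header)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    for m in range(geno.n_markers):
        rec = out.new_record(
            contig=str(geno.chrom[m]),
            start=int(geno.pos[m]) - 1,
            alleles=("A", "T"),
        )
        for i, s in enumerate(geno.parent_ids):
            rec.samples[s]["GT"] = gt_codes[int(geno.dosages[i, m])]
            rec.samples[s].phased = False
        out.write(rec)
    out.close()
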