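"""VCF 4.x, BED, and GFF3 input/output for the variant cascade.

VCF records carry per-sample GT (allele lists of length equal to the sample's
ploidy, e.g. ``0/0/0/1`` for a tetraploid) and DP. Sample ploidies are taken
from the GT field itself when reading. BED intervals are 0-based half-open;
GFF3 features are 1-based inclusive and converted on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .variants import MAX_PLOIDY, MISSING, UNUSED, VariantMatrix


def write_vcf(vm: VariantMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VariantMatrix as an uncompressed VCF with GT and DP."""
    header = pysam.VariantHeader()
    chroms = [str(c) for c in pd.unique(pd.Series(vm.chrom.astype(str)))]
    lengths = contig_lengths or {}
    for c in chroms:
        ln = int(lengths.get(c, int(vm.pos[vm.chrom.astype(str) == c].max()) + 1))
        header.contigs.add(c, length=ln)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in vm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(vm.n_sites):
            rec = out.new_record(
                contig=str(vm.chrom[i]),
                start=int(vm.pos[i]) - 1,
                stop=int(vm.pos[i]),
                alleles=(str(vm.ref[i]), str(vm.alt[i])),
            )
            for s in range(vm.n_samples):
                ploidy = int(vm.ploidies[s])
                alleles = vm.genotypes[i, s, :ploidy]
                gt = tuple(int(a) if a >= 0 else None for a in alleles)
                rec.samples[s]["GT"] = gt
                rec.samples[s]["DP"] = int(vm.depths[i, s])
            out.write(rec)


def read_vcf(path) -> VariantMatrix:
    """Read a VCF of biallelic SNPs into a VariantMatrix.

    Per-sample ploidy is inferred from GT length at the first record where the
    sample is called.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        chrom, pos, ref, alt = [], [], [], []
        gts, dps = [], []
        ploidies = np.zeros(len(samples), dtype=int)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            row = np.full((len(samples), MAX_PLOIDY), UNUSED, dtype=np.int8)
            drow = np.zeros(len(samples), dtype=np.int64)
            for s, name in enumerate(samples):
                call = rec.samples[name]
                gt = call.get("GT")
                if gt is None:
                    raise ValueError(f"missing GT for {name} at {rec.chrom}:{rec.pos}")
                if ploidies[s] == 0:
                    ploidies[s] = len(gt)
                row[s, : len(gt)] = [a if a is not None else MISSING for a in gt]
                dp = call.get("DP")
                drow[s] = int(dp) if dp is not None else 0
            gts.append(row)
            dps.append(drow)
    n = len(pos)
    return VariantMatrix(
        samples=samples,
        ploidies=ploidies,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        genotypes=(
            np.asarray(gts, dtype=np.int8)
            if n
            else np.empty((0, len(samples), MAX_PLOIDY), dtype=np.int8)
        ),
        depths=(
            np.asarray(dps, dtype=np.int64)
            if n
            else np.empty((0, len(samples)), dtype=np.int64)
        ),
    )


def read_bed(path) -> dict[str, np.ndarray]:
    """BED intervals (0-based half-open) grouped by chromosome."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#", dtype={"chrom": str},
    )
    return {
        str(c): g[["start", "end"]].to_numpy(dtype=np.int64)
        for c, g in df.groupby("chrom", sort=False)
    }


def write_bed(intervals: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for c, iv in intervals.items():
            for s, e in np.asarray(iv, dtype=np.int64):
                fh.write(f"{c}\t{s}\t{e}\n")


def read_gff_cds(path, feature_type: str = "CDS") -> dict[str, np.ndarray]:
    """Extract intervals of one feature type from a GFF3 file.

    GFF3 coordinates are 1-based inclusive; the result is 0-based half-open.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"seqid": str},
    )
    df = df[df["type"] == feature_type]
    out: dict[str, np.ndarray] = {}
    for c, g in df.groupby("seqid", sort=False):
        iv = np.stack([g["start"].to_numpy(np.int64) - 1, g["end"].to_numpy(np.int64)], axis=1)
        out[str(c)] = iv
    return out
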