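"""Ploidy-aware neutral-SNP filter cascade and mixed-ploidy statistics.

Population-genomic inference on a mixed diploid/tetraploid sample set needs
biallelic SNPs that are (i) confidently genotyped — site depth within a window
around the mean, [mean/3, 2*mean]; (ii) putatively neutral — outside coding
sequence, its 2-kb flanks, and transposable elements; (iii) not singletons —
a minor allele seen in exactly one allele copy is indistinguishable from a
sequencing error; and (iv) approximately independent — at least 20 kb apart.
The cascade applies those four stages in that order.

Genotypes are stored as allele-copy multisets whose size equals each sample's
ploidy (a tetraploid 0/0/0/1 carries one alternate copy), which makes allele
counting, the singleton rule, Dxy, and the STRUCTURE export ploidy-aware by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MISSING = -1   # missing allele copy
UNUSED = -2    # genotype slot beyond a sample's ploidy
MAX_PLOIDY = 4


class IntervalError(ValueError):
    """Malformed genomic interval (start >= end)."""


@dataclass
class VariantMatrix:
    """Biallelic SNPs x samples with ploidy-aware genotypes and read depths.

    ``genotypes[i, s, :]`` holds sample ``s``'s allele copies at site ``i``:
    values 0 (ref) / 1 (alt), ``MISSING`` for no-calls, and ``UNUSED`` padding
    beyond the sample's ploidy. Positions are 1-based (VCF convention).
    """

    samples: list[str]
    ploidies: np.ndarray           # (n_samples,), values in {2, 4}
    chrom: np.ndarray              # (n_sites,), chromosome ids
    pos: np.ndarray                # (n_sites,), 1-based positions
    ref: np.ndarray                # (n_sites,), single-nucleotide strings
    alt: np.ndarray
    genotypes: np.ndarray          # (n_sites, n_samples, MAX_PLOIDY), int8
    depths: np.ndarray             # (n_sites, n_samples), reads

    def __post_init__(self) -> None:
        self.ploidies = np.asarray(self.ploidies, dtype=int)
        if not np.all(np.isin(self.ploidies, (2, 4))):
            raise ValueError("ploidies must be 2 or 4")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        n_sites, n_samples = len(self.pos), len(self.samples)
        if self.genotypes.shape != (n_sites, n_samples, MAX_PLOIDY):
            raise ValueError("genotype array shape mismatch")
        if self.depths.shape != (n_sites, n_samples):
            raise ValueError("depth array shape mismatch")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom.astype(str) == c]
            if len(np.unique(p)) != len(p):
                raise ValueError(f"duplicate site positions on chromosome {c}")
        for a in (self.ref, self.alt):
            if n_sites and not all(len(str(x)) == 1 and str(x) in "ACGT" for x in a):
                raise ValueError("only biallelic single-nucleotide sites are supported")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "VariantMatrix":
        mask = np.asarray(mask, dtype=bool)
        return VariantMatrix(
            samples=self.samples,
            ploidies=self.ploidies,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
            depths=self.depths[mask],
        )

    def site_depths(self) -> np.ndarray:
        """Total depth per site (sum over samples)."""
        return self.depths.sum(axis=1)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(alt_copies, called_copies) per site over all non-missing slots."""
        alt = (self.genotypes == 1).sum(axis=(1, 2))
        called = (self.genotypes >= 0).sum(axis=(1, 2))
        return alt, called

    def is_sorted(self) -> bool:
        keys = list(zip(self.chrom.astype(str), self.pos))
        return keys == sorted(keys)

    def sort(self) -> "VariantMatrix":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return VariantMatrix(
            samples=self.samples, ploidies=self.ploidies,
            chrom=self.chrom[order], pos=self.pos[order],
            ref=self.ref[order], alt=self.alt[order],
            genotypes=self.genotypes[order], depths=self.depths[order],
        )


@dataclass
class FilterConfig:
    """Parameters of the neutral-SNP cascade."""

    depth_low_factor: float = 1.0 / 3.0
    depth_high_factor: float = 2.0
    depth_mode: str = "site_total"   # or "per_sample"
    flank: int = 2000
    min_dist: int = 20000
    remove_singletons: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.depth_low_factor < self.depth_high_factor:
            raise ValueError("require 0 < low factor < high factor")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be positive")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")


@dataclass
class FilterReport:
    """Per-stage bookkeeping of the cascade."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, n_input: int, n_survivors: int, **extra) -> None:
        if self.stages and self.stages[-1]["n_survivors"] != n_input:
            raise ValueError("stage input does not chain from previous survivors")
        self.stages.append(
            {"stage": name, "n_input": n_input, "n_removed": n_input - n_survivors,
             "n_survivors": n_survivors, **extra}
        )

    def survivor_counts(self) -> dict[str, int]:
        return {s["stage"]: s["n_survivors"] for s in self.stages}

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def depth_filter(
    vm: VariantMatrix,
    low_factor: float = 1.0 / 3.0,
    high_factor: float = 2.0,
    mode: str = "site_total",
) -> tuple[VariantMatrix, dict]:
    """Retain sites whose depth lies in [mean*low, mean*high], bounds inclusive.

    ``site_total`` mode (default) uses the per-site total depth and its mean
    across sites; ``per_sample`` mode applies the window to each sample's own
    depth relative to that sample's mean and keeps sites where all samples
    pass.
    """
    if vm.n_sites == 0:
        return vm, {"stage": "depth", "mean_depth": None, "mask": np.zeros(0, bool)}
    if not np.any(vm.depths):
        raise ValueError("no depth information present")
    if mode == "site_total":
        d = vm.site_depths().astype(float)
        mean = d.mean()
        mask = (d >= low_factor * mean) & (d <= high_factor * mean)
        info = {"mean_depth": float(mean)}
    elif mode == "per_sample":
        d = vm.depths.astype(float)
        means = d.mean(axis=0)
        mask = np.all((d >= low_factor * means) & (d <= high_factor * means), axis=1)
        info = {"mean_depth": means.tolist()}
    else:
        raise ValueError("mode must be 'site_total' or 'per_sample'")
    return vm.subset(mask), {"stage": "depth", "mask": mask, **info}


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of 0-based half-open intervals, returned sorted and disjoint."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    if np.any(iv[:, 0] >= iv[:, 1]):
        raise IntervalError("interval with start >= end")
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return np.asarray(merged, dtype=np.int64)


def _positions_in_union(pos0: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Membership of 0-based positions in a merged interval union."""
    if len(merged) == 0:
        return np.zeros(len(pos0), dtype=bool)
    idx = np.searchsorted(merged[:, 0], pos0, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(len(pos0), dtype=bool)
    hit[ok] = pos0[ok] < merged[idx[ok], 1]
    return hit


def region_exclude(
    vm: VariantMatrix,
    cds_intervals: dict[str, np.ndarray],
    te_intervals: dict[str, np.ndarray],
    flank: int = 2000,
) -> tuple[VariantMatrix, dict]:
    """Remove sites inside TEs or inside CDS expanded by ``flank`` on each side.

    Intervals are 0-based half-open (BED convention); VCF positions are
    converted to 0-based before the membership test. Overlapping intervals are
    unioned, so a site is never double-counted.
    """
    remove = np.zeros(vm.n_sites, dtype=bool)
    chroms = vm.chrom.astype(str)
    for c in np.unique(chroms):
        sel = chroms == c
        pos0 = vm.pos[sel] - 1
        pieces = []
        for iv in (cds_intervals.get(c),):
            if iv is not None and len(iv):
                iv = np.asarray(iv, dtype=np.int64)
                if np.any(iv[:, 0] >= iv[:, 1]):
                    raise IntervalError(f"CDS interval with start >= end on {c}")
                expanded = np.stack(
                    [np.maximum(0, iv[:, 0] - flank), iv[:, 1] + flank], axis=1
                )
                pieces.append(expanded)
        te = te_intervals.get(c)
        if te is not None and len(te):
            pieces.append(np.asarray(te, dtype=np.int64))
        if not pieces:
            continue
        merged = merge_intervals(np.concatenate(pieces))
        remove[sel] = _positions_in_union(pos0, merged)
    mask = ~remove
    return vm.subset(mask), {"stage": "region", "mask": mask}


def singleton_filter(vm: VariantMatrix) -> tuple[VariantMatrix, dict]:
    """Remove sites whose minor allele is carried by exactly one allele copy.

    Counting is over allele copies, not individuals: a tetraploid 0/0/0/1
    contributes one alternate copy. The rule is symmetric — a site where the
    *reference* allele survives in a single copy is equally a singleton.
    """
    alt, called = vm.allele_counts()
    minor = np.minimum(alt, called - alt)
    mask = minor != 1
    return vm.subset(mask), {"stage": "singleton", "mask": mask}


def spacing_thin(
    vm: VariantMatrix, min_dist: int = 20000
) -> tuple[VariantMatrix, dict]:
    """Greedy left-to-right thinning to a minimum inter-site distance.

    Per chromosome: keep the first site, then each site at least ``min_dist``
    bp from the last kept one.
    """
    if not vm.is_sorted():
        warnings.warn("sites not sorted by chromosome/position; sorting internally")
        vm = vm.sort()
    mask = np.zeros(vm.n_sites, dtype=bool)
    chroms = vm.chrom.astype(str)
    last: dict[str, int] = {}
    for i in range(vm.n_sites):
        c, p = chroms[i], int(vm.pos[i])
        if c not in last or p - last[c] >= min_dist:
            mask[i] = True
            last[c] = p
    return vm.subset(mask), {"stage": "spacing", "mask": mask}


def run_cascade(
    vm: VariantMatrix,
    config: FilterConfig,
    cds_intervals: dict[str, np.ndarray] | None = None,
    te_intervals: dict[str, np.ndarray] | None = None,
) -> tuple[VariantMatrix, FilterReport]:
    """depth -> region -> singleton -> spacing, with per-stage bookkeeping."""
    report = FilterReport()
    n0 = vm.n_sites
    vm, info = depth_filter(vm, config.depth_low_factor, config.depth_high_factor,
                            config.depth_mode)
    report.add("depth", n0, vm.n_sites, mean_depth=info.get("mean_depth"))

    n1 = vm.n_sites
    vm, _ = region_exclude(vm, cds_intervals or {}, te_intervals or {}, config.flank)
    report.add("region", n1, vm.n_sites)

    n2 = vm.n_sites
    if config.remove_singletons:
        vm, _ = singleton_filter(vm)
    report.add("singleton", n2, vm.n_sites)

    n3 = vm.n_sites
    vm, _ = spacing_thin(vm, config.min_dist)
    report.add("spacing", n3, vm.n_sites)
    return vm, report


def dxy(vm: VariantMatrix, groups: dict[str, list[str]]) -> dict[tuple[str, str], float]:
    """Mean pairwise allele-copy divergence between groups, per group pair.

    Per site, Dxy is the fraction of inter-group copy pairs whose alleles
    differ, over pairwise-complete (non-missing) copies; sites are averaged
    over *all* sites supplied, so monomorphic sites dilute the mean and the
    caller controls the denominator by the site set it passes in. This is the
    natural generalization to arbitrary ploidy: every allele copy of every
    individual enters the pairing.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    name_to_idx = {s: i for i, s in enumerate(vm.samples)}
    idx = {g: [name_to_idx[s] for s in members] for g, members in groups.items()}
    alt = {}
    called = {}
    for g, members in idx.items():
        gt = vm.genotypes[:, members, :]
        alt[g] = (gt == 1).sum(axis=(1, 2)).astype(float)
        called[g] = (gt >= 0).sum(axis=(1, 2)).astype(float)
        if np.all(called[g] == 0):
            raise ValueError(f"group {g!r} has no non-missing allele copies at any site")
    out: dict[tuple[str, str], float] = {}
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            n1, n2 = called[a], called[b]
            with np.errstate(divide="ignore", invalid="ignore"):
                per_site = (alt[a] * (n2 - alt[b]) + (n1 - alt[a]) * alt[b]) / (n1 * n2)
            per_site = np.where((n1 > 0) & (n2 > 0), per_site, 0.0)
            out[(a, b)] = float(per_site.mean()) if vm.n_sites else 0.0
    return out


def structure_rows(vm: VariantMatrix) -> list[tuple[str, list[int]]]:
    """Mixed-ploidy STRUCTURE coding: four rows per individual.

    Tetraploids contribute their four allele copies; diploids contribute two
    genotype rows followed by two rows of -9 across all loci, so every
    individual occupies the same number of lines in a tetraploid-formatted
    file. Missing genotypes are coded -9. Alleles are coded 0 (ref) / 1 (alt),
    consistent within each locus column.
    """
    rows: list[tuple[str, list[int]]] = []
    for s, name in enumerate(vm.samples):
        ploidy = int(vm.ploidies[s])
        for k in range(4):
            if k < ploidy:
                line = [
                    int(a) if a >= 0 else -9
                    for a in vm.genotypes[:, s, k]
                ]
            else:
                line = [-9] * vm.n_sites
            rows.append((name, line))
    return rows


def write_structure(vm: VariantMatrix, path) -> None:
    with open(path, "w") as fh:
        for name, line in structure_rows(vm):
            fh.write(name + "\t" + "\t".join(str(v) for v in line) + "\n")
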