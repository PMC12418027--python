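"""Window-based fragment sampling of consensus alignments for species trees.

Per-sample consensus sequences (all aligned to the same reference
coordinates) are cut into fixed-length fragments whose starts are laid out at
regular intervals from position 0 of each chromosome (0-based half-open).
Fragments where any sample carries more than a tolerated number of ambiguous
bases (N), and fragments with no variable column among fully unambiguous
positions, are discarded; the survivors are written as one FASTA alignment per
fragment for downstream gene-tree inference.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Fragment:
    chrom: str
    start: int            # 0-based, half-open [start, start + length)
    length: int
    sequences: dict[str, str]
    max_n_per_sample: int

    @property
    def name(self) -> str:
        return f"{self.chrom}_{self.start}_{self.start + self.length}"


@dataclass
class FragmentSet:
    fragments: list[Fragment] = field(default_factory=list)
    n_candidates: int = 0
    n_discarded_ambiguous: int = 0
    n_discarded_monomorphic: int = 0

    def __len__(self) -> int:
        return len(self.fragments)

    def report(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_discarded_ambiguous": self.n_discarded_ambiguous,
            "n_discarded_monomorphic": self.n_discarded_monomorphic,
            "n_retained": len(self.fragments),
        }


def candidate_starts(chrom_length: int, fragment_len: int, interval: int) -> list[int]:
    """Fragment start positions 0, interval, 2*interval, ... that fit entirely."""
    if fragment_len <= 0 or interval <= 0:
        raise ValueError("fragment_len and interval must be positive")
    return list(range(0, chrom_length - fragment_len + 1, interval))


def _is_polymorphic(seqs: list[str]) -> bool:
    """Any column with >1 distinct base among columns free of N in all samples."""
    length = len(seqs[0])
    for j in range(length):
        col = {s[j] for s in seqs}
        if "N" in col or "n" in col:
            continue
        if len(col) > 1:
            return True
    return False


def fragment_sampler(
    sequences: dict[str, dict[str, str]],
    fragment_len: int = 1000,
    interval: int = 20000,
    max_ambiguous: int = 50,
) -> FragmentSet:
    """Cut aligned consensus sequences into spaced fragments and filter them.

    ``sequences`` maps sample -> chromosome -> sequence. A fragment is
    discarded if any sample's sub-sequence contains more than
    ``max_ambiguous`` N bases, or if no unambiguous column is variable.
    """
    if not sequences:
        raise ValueError("no samples provided")
    samples = list(sequences)
    chroms = list(sequences[samples[0]])
    for s in samples:
        if list(sequences[s]) != chroms:
            raise ValueError(f"sample {s} has different chromosomes")
    out = FragmentSet()
    for c in chroms:
        lengths = {s: len(sequences[s][c]) for s in samples}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"unequal sequence lengths on chromosome {c}: {lengths}")
        L = lengths[samples[0]]
        for start in candidate_starts(L, fragment_len, interval):
            out.n_candidates += 1
            subs = {s: sequences[s][c][start : start + fragment_len] for s in samples}
            if any(sub.upper().count("N") > max_ambiguous for sub in subs.values()):
                out.n_discarded_ambiguous += 1
                continue
            if not _is_polymorphic(list(subs.values())):
                out.n_discarded_monomorphic += 1
                continue
            out.fragments.append(
                Fragment(chrom=c, start=start, length=fragment_len,
                         sequences=subs, max_n_per_sample=max_ambiguous)
            )
    return out


def write_fragment_fastas(fragset: FragmentSet, out_dir) -> list[str]:
    """One FASTA alignment per surviving fragment; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for frag in fragset.fragments:
        path = os.path.join(out_dir, f"{frag.name}.fasta")
        records = [
            SeqRecord(Seq(seq), id=sample, description="")
            for sample, seq in frag.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")
        paths.append(path)
    return paths
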