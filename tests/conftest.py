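import numpy as np
import pytest

from cytodelim.variants import MAX_PLOIDY, MISSING, UNUSED, VariantMatrix


def build_matrix(sample_ploidies, sites):
    """Hand-build a small VariantMatrix.

    ``sample_ploidies``: list of (name, ploidy).
    ``sites``: list of dicts with keys chrom, pos, gts (list per sample: tuple
    of alleles, or None for fully missing), and optional dp (list of depths).
    """
    samples = [s for s, _ in sample_ploidies]
    ploidies = np.array([p for _, p in sample_ploidies])
    n_sites, n_samples = len(sites), len(samples)
    genotypes = np.full((n_sites, n_samples, MAX_PLOIDY), UNUSED, dtype=np.int8)
    depths = np.zeros((n_sites, n_samples), dtype=np.int64)
    chrom, pos, ref, alt = [], [], [], []
    for i, site in enumerate(sites):
        chrom.append(site.get("chrom", "CHR1"))
        pos.append(site["pos"])
        ref.append(site.get("ref", "A"))
        alt.append(site.get("alt", "T"))
        for s in range(n_samples):
            gt = site["gts"][s]
            ploidy = ploidies[s]
            if gt is None:
                genotypes[i, s, :ploidy] = MISSING
            else:
                assert len(gt) == ploidy
                genotypes[i, s, : len(gt)] = gt
        depths[i] = site.get("dp", [10] * n_samples)
    return VariantMatrix(
        samples=samples,
        ploidies=ploidies,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        genotypes=genotypes,
        depths=depths,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
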