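"""Synthetic occurrences, rasters, trait tables, and variant matrices.

Every downstream stage of the pipeline is exercised against data with known
ground truth, generated here. The generators emulate the statistical structure
the analyses assume:

* two species with distinct climatic optima and unequal niche breadths, the
  widespread tetraploid occupying a broader environmental envelope than the
  narrow, high-elevation diploid;
* smooth, spatially autocorrelated environmental layers with a prescribed
  inter-layer correlation structure (including a strongly correlated pair, so
  collinearity pruning has work to do);
* near-duplicate occurrence records clustered within 1 km of existing points,
  as produced by repeated collection at the same site;
* species-specific trait distributions with the observed leaflet-pair count
  spectra;
* mixed diploid/tetraploid variant matrices with negative-binomial depths,
  a controlled singleton fraction, and CDS/TE annotation tracks — together
  with exact per-stage survivor counts computed by construction, so the
  filter cascade can be checked against an independent bookkeeping oracle.

All generators are deterministic given their seed; independent substreams are
derived with :func:`substream_seeds` so adding one generator never perturbs
another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .rasters import EnvLayer
from .thinning import EARTH_RADIUS_KM, OccurrenceRecord, OccurrenceSet
from .variants import MAX_PLOIDY, MISSING, UNUSED, VariantMatrix

KM_PER_DEG_LAT = math.pi * EARTH_RADIUS_KM / 180.0


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def substream_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


# --------------------------------------------------------------------------
# occurrences + environmental layers
# --------------------------------------------------------------------------

def _default_layer_corr(n_layers: int) -> np.ndarray:
    """Weak background correlation plus one strongly redundant pair (r=0.97),
    the kind of near-duplicate that temperature summaries of the same season
    produce, so collinearity pruning is exercised on default data."""
    corr = np.full((n_layers, n_layers), 0.2)
    np.fill_diagonal(corr, 1.0)
    if n_layers >= 2:
        corr[0, 1] = corr[1, 0] = 0.97
    return corr


@dataclass
class NicheSimConfig:
    """Two-species niche scenario in a synthetic climate.

    Species means and covariances are in environment units: each generated
    layer is standardized to mean 0, SD 1 over its grid cells, so a mean of
    0.8 is 0.8 grid-wide standard deviations from the regional average.
    Defaults give the widespread species roughly twice the niche breadth of
    the narrow one, with partially separated optima.
    """

    species_means: dict[str, np.ndarray] = field(default_factory=dict)
    species_covs: dict[str, np.ndarray] = field(default_factory=dict)
    n_records: dict[str, int] = field(default_factory=dict)
    extent: tuple[float, float, float, float] = (106.0, 24.0, 122.0, 32.0)  # w, s, e, n
    cell_size: float = 0.1
    n_layers: int = 5
    layer_names: list[str] | None = None
    layer_corr: np.ndarray | None = None
    duplicate_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species_means:
            self.species_means = {
                "C. paliurus": np.array([0.5, 0.4, 0.3, 0.2, -0.3][: self.n_layers]),
                "C. serrata": np.array([-0.6, -0.5, -0.2, -0.4, 0.8][: self.n_layers]),
            }
        if self.layer_corr is None:
            self.layer_corr = _default_layer_corr(self.n_layers)
        self.layer_corr = np.asarray(self.layer_corr, dtype=float)
        if not self.species_covs:
            self.species_covs = {}
            for sp, scale in (("C. paliurus", 0.45), ("C. serrata", 0.25)):
                d = np.full(self.n_layers, scale)
                self.species_covs[sp] = np.outer(d, d) * self.layer_corr
        if not self.n_records:
            self.n_records = {"C. paliurus": 240, "C. serrata": 120}
        if self.layer_names is None:
            self.layer_names = [f"BIO{i + 1}" for i in range(self.n_layers)]
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ConfigurationError("duplicate_fraction must be in [0, 1]")
        for sp, n in self.n_records.items():
            if n < 1:
                raise ConfigurationError(f"n_records[{sp!r}] must be >= 1")
        for sp, cov in self.species_covs.items():
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ConfigurationError(f"covariance for {sp!r} is not symmetric")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ConfigurationError(
                    f"covariance for {sp!r} is not positive-definite"
                ) from exc
            self.species_covs[sp] = cov
        try:
            np.linalg.cholesky(self.layer_corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("layer_corr is not positive-definite") from exc


@dataclass
class NicheTruth:
    """What the occurrence generator actually planted."""

    species_means: dict[str, np.ndarray]
    species_covs: dict[str, np.ndarray]
    n_base: dict[str, int]
    n_duplicates: dict[str, int]
    layer_corr: np.ndarray
    layer_names: list[str]


def _smooth_fields(rng, nrows, ncols, n_layers, n_terms=8) -> np.ndarray:
    """(cells, n_layers) smooth low-frequency random fields over the grid."""
    u = (np.arange(ncols) + 0.5) / ncols
    v = (np.arange(nrows) + 0.5) / nrows
    uu, vv = np.meshgrid(u, v)  # (nrows, ncols)
    fields = np.empty((nrows * ncols, n_layers))
    for k in range(n_layers):
        f = np.zeros((nrows, ncols))
        for _ in range(n_terms):
            fx, fy = rng.uniform(0.5, 2.5, size=2)
            amp = rng.uniform(0.5, 1.0)
            phase = rng.uniform(0.0, 2.0 * math.pi)
            f += amp * np.cos(2.0 * math.pi * (fx * uu + fy * vv) + phase)
        fields[:, k] = f.ravel()
    return fields


def gen_occurrences(
    config: NicheSimConfig,
) -> tuple[OccurrenceSet, list[EnvLayer], NicheTruth]:
    """Generate correlated environmental rasters and species occurrences.

    Layers are linear mixes of smooth spatial basis fields, orthonormalized
    over grid cells and recombined through the Cholesky factor of the target
    correlation matrix, so the realized inter-layer correlation over cells
    equals the target exactly. Occurrence points are placed by inverting the
    environment-to-space mapping: a target environmental vector is drawn from
    the species' Gaussian, matched to the grid cell with the nearest
    environmental profile, and the point placed uniformly inside that cell.
    A configured fraction of records is then duplicated within 1 km of an
    existing conspecific point.
    """
    s_raster, s_place, s_dup = substream_seeds(config.seed, 3)
    west, south, east, north = config.extent
    ncols = int(round((east - west) / config.cell_size))
    nrows = int(round((north - south) / config.cell_size))
    if ncols < 2 or nrows < 2:
        raise ConfigurationError("extent too small for the cell size")

    rng = np.random.default_rng(s_raster)
    raw = _smooth_fields(rng, nrows, ncols, config.n_layers)
    raw -= raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    if np.any(np.abs(np.diag(r)) < 1e-10):
        raise ConfigurationError("degenerate basis fields; change the seed")
    L = np.linalg.cholesky(config.layer_corr)
    mixed = q @ L.T
    mixed /= mixed.std(axis=0, ddof=0)  # unit SD per layer, correlation preserved

    layers = [
        EnvLayer(
            name=config.layer_names[k],
            values=mixed[:, k].reshape(nrows, ncols),
            west=west,
            north=north,
            cell_size=config.cell_size,
        )
        for k in range(config.n_layers)
    ]

    tree = cKDTree(mixed)
    rng_p = np.random.default_rng(s_place)
    rng_d = np.random.default_rng(s_dup)
    records: list[OccurrenceRecord] = []
    n_base: dict[str, int] = {}
    n_dup: dict[str, int] = {}
    for sp in config.species_means:
        n = config.n_records[sp]
        nd = int(round(config.duplicate_fraction * n))
        nb = n - nd
        if nb < 1:
            nb, nd = 1, n - 1
        targets = rng_p.multivariate_normal(
            np.asarray(config.species_means[sp], dtype=float),
            config.species_covs[sp],
            size=nb,
        )
        _, cells = tree.query(targets)
        rows, cols = np.divmod(cells, ncols)
        jitter = rng_p.uniform(0.0, 1.0, size=(nb, 2))
        lons = west + (cols + jitter[:, 0]) * config.cell_size
        lats = north - (rows + jitter[:, 1]) * config.cell_size
        base = [OccurrenceRecord(sp, float(x), float(y)) for x, y in zip(lons, lats)]
        dups: list[OccurrenceRecord] = []
        for _ in range(nd):
            anchor = base[int(rng_d.integers(0, nb))]
            dist = rng_d.uniform(0.05, 0.9)  # km, strictly inside the 1 km radius
            theta = rng_d.uniform(0.0, 2.0 * math.pi)
            dlat = dist * math.cos(theta) / KM_PER_DEG_LAT
            dlon = dist * math.sin(theta) / (
                KM_PER_DEG_LAT * math.cos(math.radians(anchor.lat))
            )
            dups.append(
                OccurrenceRecord(
                    sp,
                    float(np.clip(anchor.lon + dlon, west, east - 1e-9)),
                    float(np.clip(anchor.lat + dlat, south + 1e-9, north)),
                    source="duplicate",
                )
            )
        records.extend(base)
        records.extend(dups)
        n_base[sp] = nb
        n_dup[sp] = nd

    truth = NicheTruth(
        species_means={sp: np.asarray(m, float) for sp, m in config.species_means.items()},
        species_covs=dict(config.species_covs),
        n_base=n_base,
        n_duplicates=n_dup,
        layer_corr=config.layer_corr,
        layer_names=list(config.layer_names),
    )
    return OccurrenceSet(records), layers, truth


# --------------------------------------------------------------------------
# trait tables
# --------------------------------------------------------------------------

@dataclass
class PositionStats:
    """Leaflet length/width distribution for one position class."""

    n: int
    length_mean: float
    length_sd: float
    width_mean: float
    width_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError("leaflet count must be non-negative")
        if self.length_sd < 0 or self.width_sd < 0:
            raise ConfigurationError("SDs must be non-negative")


@dataclass
class TraitGroupConfig:
    """Trait distributions for one species."""

    positions: dict[str, PositionStats]
    pair_probs: dict[int, float]
    flower_diameter_mean: float
    flower_diameter_sd: float

    def __post_init__(self) -> None:
        if self.flower_diameter_sd < 0:
            raise ConfigurationError("SDs must be non-negative")
        if any(p < 1 for p in self.pair_probs):
            raise ConfigurationError("leaflet-pair counts must be >= 1")
        total = sum(self.pair_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            self.pair_probs = {k: v / total for k, v in self.pair_probs.items()}


# Leaflet sample sizes per position class, pair-count spectra, and flower
# diameters mirror the measured specimen series of the two taxa.
DEFAULT_TRAIT_CONFIGS: dict[str, TraitGroupConfig] = {
    "C. paliurus": TraitGroupConfig(
        positions={
            "apical": PositionStats(47, 12.1, 1.7, 5.3, 0.7),
            "lateral": PositionStats(92, 10.9, 1.8, 4.5, 0.6),
            "basal": PositionStats(46, 6.3, 1.3, 2.75, 0.5),
        },
        pair_probs={2: 3 / 47, 3: 23 / 47, 4: 21 / 47},
        flower_diameter_mean=5.11,
        flower_diameter_sd=0.33,
    ),
    "C. serrata": TraitGroupConfig(
        positions={
            "apical": PositionStats(38, 8.8, 1.2, 3.75, 0.55),
            "lateral": PositionStats(104, 10.15, 1.3, 3.35, 0.5),
            "basal": PositionStats(37, 6.0, 1.2, 1.95, 0.35),
        },
        pair_probs={4: 13 / 38, 5: 20 / 38, 6: 5 / 38},
        flower_diameter_mean=3.35,
        flower_diameter_sd=0.26,
    ),
}


def _positive_normal(rng, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws redrawn until positive (means here sit several SD above 0)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def gen_trait_table(
    configs: dict[str, TraitGroupConfig] | None = None, seed: int = 0
) -> pd.DataFrame:
    """One row per measured leaflet: species, position class, length/width (cm),
    length-to-width ratio, leaflet pairs of the parent leaf, and the parent
    tree's male flower diameter (mm)."""
    configs = configs if configs is not None else DEFAULT_TRAIT_CONFIGS
    seeds = substream_seeds(seed, len(configs))
    frames = []
    for (sp, cfg), s in zip(configs.items(), seeds):
        rng = np.random.default_rng(s)
        for pos_name, st in cfg.positions.items():
            if st.n == 0:
                continue
            length = _positive_normal(rng, st.length_mean, st.length_sd, st.n)
            width = _positive_normal(rng, st.width_mean, st.width_sd, st.n)
            pair_values = np.array(sorted(cfg.pair_probs))
            probs = np.array([cfg.pair_probs[int(v)] for v in pair_values])
            pairs = rng.choice(pair_values, size=st.n, p=probs)
            flower = _positive_normal(
                rng, cfg.flower_diameter_mean, cfg.flower_diameter_sd, st.n
            )
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "position": pos_name,
                        "length_cm": length,
                        "width_cm": width,
                        "ratio": length / width,
                        "pairs": pairs.astype(int),
                        "flower_diameter_mm": flower,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# variants
# --------------------------------------------------------------------------

@dataclass
class VariantSimConfig:
    """Mixed-ploidy SNP matrix with annotation tracks and depth structure.

    ``depth_dispersion`` is the negative-binomial shape k (variance =
    m + m^2/k); ``None`` gives every sample the same constant depth, which
    makes the depth window a no-op. Defaults are desk-scale: a handful of
    diploids and tetraploids, a few megabases, thousands of sites.
    """

    sample_ploidies: dict[str, int] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"CHR1": 2_000_000, "CHR2": 2_000_000, "CHR3": 2_000_000}
    )
    n_sites: int = 5000
    mean_depth: float = 30.0
    depth_dispersion: float | None = 5.0
    #: SD (log scale) of a shared per-site depth factor emulating mappability
    #: and copy-number variation — the reason a depth window is applied at all.
    site_depth_lognorm_sigma: float = 0.6
    singleton_fraction: float = 0.1
    missing_fraction: float = 0.02
    cds_density: float = 0.15
    te_density: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_ploidies:
            self.sample_ploidies = {f"dip{i}": 2 for i in range(1, 7)}
            self.sample_ploidies.update({f"tet{i}": 4 for i in range(1, 11)})
        if any(p not in (2, 4) for p in self.sample_ploidies.values()):
            raise ConfigurationError("ploidies must be 2 or 4")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean depth must be positive")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ConfigurationError("singleton_fraction must be in [0, 1]")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.n_sites > sum(self.chrom_lengths.values()):
            raise ConfigurationError("more sites than genome positions")


@dataclass
class VariantTruth:
    """Exact survivor counts of each filter stage, computed by construction."""

    n_input: int
    after_depth: int
    after_region: int
    after_singleton: int
    after_spacing: int
    n_singleton_sites: int

    def counts(self) -> dict[str, int]:
        return {
            "depth": self.after_depth,
            "region": self.after_region,
            "singleton": self.after_singleton,
            "spacing": self.after_spacing,
        }


def _random_intervals(rng, length: int, density: float) -> np.ndarray:
    """Non-overlapping sorted intervals covering ~``density`` of [0, length)."""
    if density <= 0:
        return np.empty((0, 2), dtype=np.int64)
    mean_len = 1750.0
    mean_gap = mean_len * (1.0 - density) / density
    out = []
    pos = 0
    while True:
        pos += int(rng.exponential(mean_gap)) + 1
        ln = int(rng.uniform(500, 3000))
        if pos + ln >= length:
            break
        out.append((pos, pos + ln))
        pos += ln
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def gen_variants(
    config: VariantSimConfig,
) -> tuple[VariantMatrix, dict[str, np.ndarray], dict[str, np.ndarray], VariantTruth]:
    """Generate a mixed-ploidy VariantMatrix, CDS/TE tracks, and truth counts.

    The truth record holds, for each stage of the neutral-SNP cascade, the
    exact number of surviving sites, computed here with straightforward
    arithmetic on the generated arrays (no call into the filter code), so the
    pipeline can be validated against independent bookkeeping.
    """
    s_pos, s_geno, s_depth, s_iv = substream_seeds(config.seed, 4)
    samples = list(config.sample_ploidies)
    ploidies = np.array([config.sample_ploidies[s] for s in samples])
    n_samples = len(samples)

    # --- site positions, allocated to chromosomes by length ---
    rng = np.random.default_rng(s_pos)
    chroms_list = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms_list], dtype=float)
    alloc = np.floor(config.n_sites * lengths / lengths.sum()).astype(int)
    for i in range(config.n_sites - alloc.sum()):
        alloc[i % len(alloc)] += 1
    chrom_arr, pos_arr = [], []
    for c, k in zip(chroms_list, alloc):
        p = np.sort(rng.choice(config.chrom_lengths[c], size=k, replace=False) + 1)
        chrom_arr.extend([c] * k)
        pos_arr.extend(p.tolist())
    chrom_arr = np.asarray(chrom_arr, dtype=object)
    pos_arr = np.asarray(pos_arr, dtype=np.int64)
    n_sites = len(pos_arr)

    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_sites)
    shift = rng.integers(1, 4, size=n_sites)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]

    # --- genotypes ---
    rng_g = np.random.default_rng(s_geno)
    genotypes = np.full((n_sites, n_samples, MAX_PLOIDY), UNUSED, dtype=np.int8)
    for s in range(n_samples):
        genotypes[:, s, : ploidies[s]] = 0
    for i in range(n_sites):
        missing = rng_g.random(n_samples) < config.missing_fraction
        if missing.all():
            missing[rng_g.integers(0, n_samples)] = False
        called_slots = [
            (s, k) for s in range(n_samples) if not missing[s]
            for k in range(ploidies[s])
        ]
        if rng_g.random() < config.singleton_fraction:
            s, k = called_slots[rng_g.integers(0, len(called_slots))]
            genotypes[i, s, k] = 1
        else:
            p = rng_g.uniform(0.1, 0.9)
            while True:
                draws = rng_g.random(len(called_slots)) < p
                mac = min(int(draws.sum()), len(called_slots) - int(draws.sum()))
                if mac >= 2:
                    break
            for (s, k), a in zip(called_slots, draws):
                genotypes[i, s, k] = 1 if a else 0
        for s in range(n_samples):
            if missing[s]:
                genotypes[i, s, : ploidies[s]] = MISSING

    # --- depths ---
    rng_d = np.random.default_rng(s_depth)
    if config.depth_dispersion is None:
        depths = np.full((n_sites, n_samples), int(round(config.mean_depth)), dtype=np.int64)
    else:
        sigma = config.site_depth_lognorm_sigma
        factor = (
            rng_d.lognormal(-0.5 * sigma**2, sigma, size=n_sites)
            if sigma > 0
            else np.ones(n_sites)
        )
        k = config.depth_dispersion
        means = config.mean_depth * factor[:, None]
        p = k / (k + means)
        depths = rng_d.negative_binomial(
            k, np.broadcast_to(p, (n_sites, n_samples))
        ).astype(np.int64)

    # --- annotation tracks ---
    rng_iv = np.random.default_rng(s_iv)
    cds = {c: _random_intervals(rng_iv, config.chrom_lengths[c], config.cds_density)
           for c in chroms_list}
    te = {c: _random_intervals(rng_iv, config.chrom_lengths[c], config.te_density)
          for c in chroms_list}

    vm = VariantMatrix(
        samples=samples, ploidies=ploidies,
        chrom=chrom_arr, pos=pos_arr, ref=ref.astype(object), alt=alt.astype(object),
        genotypes=genotypes, depths=depths,
    )

    truth = _bookkeep_truth(chrom_arr, pos_arr, genotypes, depths, cds, te)
    return vm, cds, te, truth


def _bookkeep_truth(chrom_arr, pos_arr, genotypes, depths, cds, te,
                    flank: int = 2000, min_dist: int = 20000) -> VariantTruth:
    """Survivor counts of the default cascade, by direct arithmetic.

    Intentionally written with plain loops and bisect-style scans, independent
    of the filter implementations it is used to validate.
    """
    import bisect

    n_sites = len(pos_arr)
    site_depth = [int(depths[i].sum()) for i in range(n_sites)]
    mean = float(np.mean(site_depth)) if n_sites else 0.0
    pass_depth = [mean / 3.0 <= d <= 2.0 * mean for d in site_depth]

    # merged exclusion union per chromosome
    unions: dict[str, list[tuple[int, int]]] = {}
    for c in set(str(x) for x in chrom_arr):
        spans = []
        for s, e in np.asarray(cds.get(c, np.empty((0, 2))), dtype=np.int64):
            spans.append((max(0, int(s) - flank), int(e) + flank))
        for s, e in np.asarray(te.get(c, np.empty((0, 2))), dtype=np.int64):
            spans.append((int(s), int(e)))
        spans.sort()
        merged: list[tuple[int, int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        unions[c] = merged

    def excluded(c: str, pos1: int) -> bool:
        p0 = pos1 - 1
        merged = unions.get(c, [])
        j = bisect.bisect_right([m[0] for m in merged], p0) - 1
        return j >= 0 and p0 < merged[j][1]

    pass_region = [
        pass_depth[i] and not excluded(str(chrom_arr[i]), int(pos_arr[i]))
        for i in range(n_sites)
    ]

    n_singletons = 0
    pass_singleton = []
    for i in range(n_sites):
        alt_copies = int((genotypes[i] == 1).sum())
        called = int((genotypes[i] >= 0).sum())
        is_singleton = min(alt_copies, called - alt_copies) == 1
        if is_singleton:
            n_singletons += 1
        pass_singleton.append(pass_region[i] and not is_singleton)

    last: dict[str, int] = {}
    pass_spacing = []
    for i in range(n_sites):
        if not pass_singleton[i]:
            pass_spacing.append(False)
            continue
        c, p = str(chrom_arr[i]), int(pos_arr[i])
        if c not in last or p - last[c] >= min_dist:
            pass_spacing.append(True)
            last[c] = p
        else:
            pass_spacing.append(False)

    return VariantTruth(
        n_input=n_sites,
        after_depth=sum(pass_depth),
        after_region=sum(pass_region),
        after_singleton=sum(pass_singleton),
        after_spacing=sum(pass_spacing),
        n_singleton_sites=n_singletons,
    )
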