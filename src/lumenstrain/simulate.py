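"""Synthetic gnotobiotic-mouse communities and their sequencing observations.

The generator realises the study design the downstream inference assumes:
a single human inoculum carrying 1-3 strains per species (strain pairs
diverged by ~10^3-10^4 SNVs), colonisation of mice housed in cages and
sampled at five gut regions (duodenum, jejunum, ileum, cecum, colon), a
hierarchical cage/mouse/region structure on strain frequencies, per-site
read depths with an optional high-depth batch, sequencing error, and
planted extreme SNV frequency changes (sweeps).

Ground truth (strain genotypes, the strain-frequency tensor, planted
sweeps) is kept alongside the rendered observation tables so every
downstream stage has a truth to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from lumenstrain._rng import child_rng
from lumenstrain.io import (
    GUT_REGIONS,
    SampleMeta,
    SNVTable,
    save_dataset,
)

SWEEP_SCOPES = ("all-regions-of-a-mouse", "single-region", "multi-mouse-parallel")


def _broadcast(value, n: int, name: str) -> list:
    if isinstance(value, (list, tuple)):
        if len(value) != n:
            raise ValueError(f"{name}: expected {n} entries, got {len(value)}")
        return list(value)
    return [value] * n


@dataclass
class CommunityConfig:
    """Inoculum community: species, strains, and their divergence.

    ``pairwise_divergence`` is the number of SNVs separating any two strains
    of a species (the empirical between-host scale is ~10^3-10^4).
    ``inoculum_strain_freqs`` gives each species' strain frequencies in the
    inoculum (a simplex vector per species; defaults to uniform).
    ``intra_strain_sites`` adds low-frequency within-strain variable sites
    (frequency ``intra_strain_freq`` in every sample) that carry no strain
    signal and should be discarded by the phasing filters.
    """

    n_species: int = 1
    genome_length: int | list[int] = 100_000
    strains_per_species: int | list[int] = 2
    pairwise_divergence: int | list[int] = 2000
    inoculum_strain_freqs: list | None = None
    intra_strain_sites: int | list[int] = 0
    intra_strain_freq: float = 0.02
    allow_extra_strains: bool = False

    def per_species(self):
        n = self.n_species
        lengths = _broadcast(self.genome_length, n, "genome_length")
        strains = _broadcast(self.strains_per_species, n, "strains_per_species")
        divs = _broadcast(self.pairwise_divergence, n, "pairwise_divergence")
        intras = _broadcast(self.intra_strain_sites, n, "intra_strain_sites")
        if self.inoculum_strain_freqs is None:
            freqs = [tuple(np.full(k, 1.0 / k)) for k in strains]
        else:
            freqs = [tuple(f) for f in self.inoculum_strain_freqs]
            if len(freqs) != n:
                raise ValueError("inoculum_strain_freqs: one simplex per species")
        for i, (k, f, d) in enumerate(zip(strains, freqs, divs)):
            if k > 3 and not self.allow_extra_strains:
                raise ValueError(
                    f"species {i}: strains_per_species > 3 is outside the "
                    "supported regime (set allow_extra_strains=True to force)"
                )
            if len(f) != k or abs(sum(f) - 1.0) > 1e-9 or min(f) < 0:
                raise ValueError(f"species {i}: strain freqs must be a {k}-simplex")
            if d < 1:
                raise ValueError("pairwise_divergence must be >= 1")
            if k == 3 and d % 2:
                raise ValueError(
                    "3-strain genotypes need an even pairwise_divergence"
                )
        return lengths, strains, divs, freqs, intras


@dataclass
class ColonizationConfig:
    """How the inoculum community maps onto caged mice.

    Strain-frequency deviations are hierarchical on the log-odds scale:
    cage, mouse and region effects are drawn independently with the given
    standard deviations. ``freq_model="uniform"`` replaces the hierarchy
    with i.i.d. per-sample strain frequencies drawn from ``uniform_range``
    (a benchmarking condition for frequency-recovery tests).
    """

    n_cages: int = 3
    mice_per_cage: tuple = (3, 2, 3)
    regions: tuple = GUT_REGIONS
    sigma_cage: float = 0.0
    sigma_mouse: float = 0.0
    sigma_region: float = 0.0
    species_dropout_prob: float = 0.0
    freq_model: str = "hierarchical"
    uniform_range: tuple = (0.2, 0.8)
    sigma_abundance: float = 0.5

    def __post_init__(self) -> None:
        if len(self.regions) != 5:
            raise ValueError("regions must list the five gut regions")
        if min(self.sigma_cage, self.sigma_mouse, self.sigma_region) < 0:
            raise ValueError("sigmas must be >= 0")
        if len(self.mice_per_cage) != self.n_cages:
            raise ValueError("mice_per_cage must have n_cages entries")
        if self.freq_model not in ("hierarchical", "uniform"):
            raise ValueError(f"unknown freq_model {self.freq_model!r}")

    @property
    def n_mice(self) -> int:
        return int(sum(self.mice_per_cage))


@dataclass
class SequencingConfig:
    """Observation model: per-site depth and per-read error.

    Depth at each site is drawn from ``depth_distribution`` ("poisson" or
    "negbin" with dispersion ``nb_dispersion``; real shotgun depth is
    overdispersed) with mean ``mean_depth`` scaled by the sample's entry in
    ``batch_multipliers`` (emulating a deeper sequencing batch). Each read
    miscalls its allele with probability ``error_rate``.
    """

    mean_depth: float = 50.0
    depth_distribution: str = "poisson"
    nb_dispersion: float = 10.0
    error_rate: float = 0.0
    batch_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth_distribution not in ("poisson", "negbin"):
            raise ValueError(f"unknown depth_distribution {self.depth_distribution!r}")


@dataclass
class SweepConfig:
    """Planted extreme SNV frequency changes.

    Each sweep places a new allele on the background of one named strain and
    drives it from ``start_freq`` (unaffected samples) to ``end_freq``
    (affected samples, chosen per ``sweep_scope``). ``sgv_inoculum_freq`` is
    the allele's frequency in the inoculum (0 for de novo mutations, > 0 for
    standing genetic variation).
    """

    n_sweeps: int = 0
    sweep_scope: str = "all-regions-of-a-mouse"
    start_freq: float = 0.0
    end_freq: float = 1.0
    sgv_inoculum_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.sweep_scope not in SWEEP_SCOPES:
            raise ValueError(f"unknown sweep_scope {self.sweep_scope!r}")
        if self.n_sweeps > 0 and not (self.start_freq <= 0.2 <= 0.8 <= self.end_freq):
            raise ValueError(
                "planted sweeps must run from start_freq <= 0.2 to end_freq >= 0.8"
            )


@dataclass(frozen=True)
class PlantedSweep:
    species_id: str
    site_id: str
    affected_samples: tuple
    start_freq: float
    end_freq: float
    sgv_inoculum_freq: float
    background_strain: int


@dataclass
class GroundTruth:
    """The latent community the observation tables are rendered from."""

    samples: list[SampleMeta]
    species_ids: list[str]
    sites: dict[str, pd.DataFrame]
    genotypes: dict[str, np.ndarray]  # strains x sites alt-allele indicator
    strain_freqs: dict[str, pd.DataFrame]  # sample x strain, rows on simplex
    intra_freq: dict[str, pd.Series]  # per-site within-strain baseline freq
    planted_sweeps: list[PlantedSweep]
    colonized: dict[str, dict[str, bool]]
    divergence: dict[str, int]
    abundance: pd.DataFrame  # species x sample relative abundance

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def allele_freq(self, species_id: str) -> pd.DataFrame:
        """True alternative-allele frequency at every site in every sample.

        At strain-differentiating sites this is the dot product of strain
        frequencies and strain alleles (law of total allele frequency);
        within-strain sites sit at their constant baseline; planted-sweep
        sites follow their configured start/end pattern.
        """
        geno = self.genotypes[species_id]
        sf = self.strain_freqs[species_id]
        p = sf.to_numpy() @ geno  # samples x sites
        p = pd.DataFrame(
            p.T, index=self.sites[species_id].index, columns=sf.index
        )
        intra = self.intra_freq[species_id]
        nz = intra[intra > 0]
        if len(nz):
            p.loc[nz.index] = np.tile(
                nz.to_numpy()[:, None], (1, p.shape[1])
            )
        for sw in self.planted_sweeps:
            if sw.species_id != species_id:
                continue
            row = pd.Series(sw.start_freq, index=p.columns)
            row[[s for s in self.sample_ids if s == "inoculum"]] = (
                sw.sgv_inoculum_freq
            )
            row[list(sw.affected_samples)] = sw.end_freq
            p.loc[sw.site_id] = row
        return p


def make_sample_sheet(colonization: ColonizationConfig) -> list[SampleMeta]:
    """Sample metadata for the caged-mouse design plus the inoculum."""
    samples = [
        SampleMeta("inoculum", "inoculum", None, "inoculum", batch="b1")
    ]
    mouse_no = 0
    for c, n_mice in enumerate(colonization.mice_per_cage, start=1):
        for _ in range(n_mice):
            mouse_no += 1
            for region in colonization.regions:
                samples.append(
                    SampleMeta(
                        f"m{mouse_no}_{region}",
                        f"m{mouse_no}",
                        f"c{c}",
                        region,
                        batch="b1",
                    )
                )
    return samples


def _strain_genotypes(k: int, divergence: int, rng) -> np.ndarray:
    """Alt-allele indicators (strains x sites) with all pairwise Hamming
    distances equal to ``divergence``.

    For three strains, sites are generated on the rooted tree ((A,B),C):
    mutations private to each leaf plus mutations on the internal branch
    shared by A and B, so both private-to-one and shared-by-two classes
    occur. Each site's ref/alt labelling is then flipped with probability
    1/2, mimicking arbitrary reference-genome polarisation.
    """
    if k == 1:
        geno = np.zeros((1, 0), dtype=np.int8)
    elif k == 2:
        geno = np.zeros((2, divergence), dtype=np.int8)
        geno[1, :] = 1
    elif k == 3:
        a = b = divergence // 2
        shared = (divergence - a) // 2
        c = divergence - a - shared
        blocks = []
        for strain_rows, n in (
            ((0,), a),
            ((1,), b),
            ((2,), c),
            ((0, 1), shared),
        ):
            block = np.zeros((3, n), dtype=np.int8)
            for r in strain_rows:
                block[r, :] = 1
            blocks.append(block)
        geno = np.concatenate(blocks, axis=1)
    else:
        raise ValueError("genotype generation supports at most 3 strains")
    flip = rng.random(geno.shape[1]) < 0.5
    geno[:, flip] = 1 - geno[:, flip]
    return geno


def _site_table(
    species_id: str, n_sites: int, genome_length: int, rng
) -> pd.DataFrame:
    if n_sites > genome_length:
        raise ValueError("genome_length smaller than the number of variable sites")
    positions = np.sort(rng.choice(genome_length, size=n_sites, replace=False)) + 1
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    site_type = rng.choice(
        ["syn", "nonsyn", "noncoding"], size=n_sites, p=[0.27, 0.63, 0.10]
    )
    df = pd.DataFrame(
        {
            "site_id": [f"{species_id}|s{p:07d}" for p in positions],
            "contig": "contig_1",
            "position": positions,
            "ref_allele": bases[ref_idx],
            "alt_allele": bases[alt_idx],
            "gene_id": [f"gene_{p // 900:04d}" for p in positions],
            "site_type": site_type,
        }
    )
    return df.set_index("site_id")


def _hierarchical_freqs(
    inoc: tuple, samples: list[SampleMeta], col: ColonizationConfig, rng
) -> pd.DataFrame:
    """Strain frequencies per sample under the cage/mouse/region hierarchy."""
    k = len(inoc)
    cages = sorted({s.cage_id for s in samples if s.cage_id})
    mice = sorted({s.mouse_id for s in samples if not s.is_inoculum})
    n_eff = 1 if k == 2 else k
    cage_eff = {c: rng.normal(0, col.sigma_cage, n_eff) for c in cages}
    mouse_eff = {m: rng.normal(0, col.sigma_mouse, n_eff) for m in mice}
    rows = {}
    for s in samples:
        if s.is_inoculum:
            rows[s.sample_id] = np.asarray(inoc, dtype=float)
            continue
        region_eff = rng.normal(0, col.sigma_region, n_eff)
        eff = cage_eff[s.cage_id] + mouse_eff[s.mouse_id] + region_eff
        if k == 1:
            rows[s.sample_id] = np.array([1.0])
        elif k == 2:
            f = float(expit(logit(inoc[0]) + eff[0]))
            rows[s.sample_id] = np.array([f, 1.0 - f])
        else:
            logp = np.log(np.asarray(inoc, dtype=float)) + eff
            w = np.exp(logp - logp.max())
            rows[s.sample_id] = w / w.sum()
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"strain_{i}" for i in range(k)]
    ).loc[[s.sample_id for s in samples]]


def _uniform_freqs(
    inoc: tuple, samples: list[SampleMeta], col: ColonizationConfig, rng
) -> pd.DataFrame:
    k = len(inoc)
    if k > 2:
        raise ValueError("uniform freq_model supports at most two strains")
    lo, hi = col.uniform_range
    rows = {}
    for s in samples:
        if s.is_inoculum or k == 1:
            rows[s.sample_id] = np.asarray(inoc, dtype=float)
        else:
            f = rng.uniform(lo, hi)
            rows[s.sample_id] = np.array([f, 1.0 - f])
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"strain_{i}" for i in range(k)]
    ).loc[[s.sample_id for s in samples]]


def _place_sweeps(
    sweeps: SweepConfig,
    species_ids: list[str],
    sites: dict[str, pd.DataFrame],
    genotypes: dict[str, np.ndarray],
    strain_freqs: dict[str, pd.DataFrame],
    colonized: dict[str, dict[str, bool]],
    samples: list[SampleMeta],
    rng,
) -> list[PlantedSweep]:
    planted = []
    mouse_samples: dict[str, list[str]] = {}
    mouse_cage: dict[str, str] = {}
    for s in samples:
        if s.is_inoculum:
            continue
        mouse_samples.setdefault(s.mouse_id, []).append(s.sample_id)
        mouse_cage[s.mouse_id] = s.cage_id
    for i in range(sweeps.n_sweeps):
        sp = species_ids[i % len(species_ids)]
        eligible_mice = [m for m, ok in colonized[sp].items() if ok]
        if not eligible_mice:
            continue
        # the sweep allele is appended as a new site on one strain background
        inoc_f = strain_freqs[sp].loc["inoculum"].to_numpy()
        background = int(np.argmax(inoc_f))
        if sweeps.sweep_scope == "all-regions-of-a-mouse":
            mouse = eligible_mice[rng.integers(len(eligible_mice))]
            affected = tuple(mouse_samples[mouse])
        elif sweeps.sweep_scope == "single-region":
            mouse = eligible_mice[rng.integers(len(eligible_mice))]
            affected = (mouse_samples[mouse][rng.integers(5)],)
        else:  # multi-mouse-parallel: one mouse in each of two cages
            cages = sorted({mouse_cage[m] for m in eligible_mice})
            if len(cages) < 2:
                continue
            chosen_cages = rng.choice(len(cages), size=2, replace=False)
            affected = []
            for ci in chosen_cages:
                cage_mice = [m for m in eligible_mice if mouse_cage[m] == cages[ci]]
                mouse = cage_mice[rng.integers(len(cage_mice))]
                affected.extend(mouse_samples[mouse])
            affected = tuple(affected)
        site_df = sites[sp]
        # a fresh position not already variable
        used = set(site_df["position"])
        while True:
            pos = int(rng.integers(1, 10**7))
            if pos not in used:
                break
        site_id = f"{sp}|sweep{pos:07d}"
        new_row = pd.DataFrame(
            {
                "contig": ["contig_1"],
                "position": [pos],
                "ref_allele": ["A"],
                "alt_allele": ["G"],
                "gene_id": [f"gene_sw{i:02d}"],
                "site_type": [rng.choice(["syn", "nonsyn"], p=[0.3, 0.7])],
            },
            index=pd.Index([site_id], name="site_id"),
        )
        sites[sp] = pd.concat([site_df, new_row])
        genotypes[sp] = np.concatenate(
            [genotypes[sp], np.zeros((genotypes[sp].shape[0], 1), np.int8)], axis=1
        )
        planted.append(
            PlantedSweep(
                sp,
                site_id,
                affected,
                sweeps.start_freq,
                sweeps.end_freq,
                sweeps.sgv_inoculum_freq,
                background,
            )
        )
    return planted


def generate_truth(
    community: CommunityConfig,
    colonization: ColonizationConfig,
    sweeps: SweepConfig | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw a ground-truth community under the configured study design."""
    sweeps = sweeps if sweeps is not None else SweepConfig()
    lengths, strains, divs, inoc_freqs, intras = community.per_species()
    samples = make_sample_sheet(colonization)
    species_ids = [f"species_{i + 1:02d}" for i in range(community.n_species)]

    sites: dict[str, pd.DataFrame] = {}
    genotypes: dict[str, np.ndarray] = {}
    strain_freqs: dict[str, pd.DataFrame] = {}
    intra_freq: dict[str, pd.Series] = {}
    colonized: dict[str, dict[str, bool]] = {}
    divergence: dict[str, int] = {}

    mice = sorted({s.mouse_id for s in samples if not s.is_inoculum})
    for sp, L, k, d, inoc, n_intra in zip(
        species_ids, lengths, strains, divs, inoc_freqs, intras
    ):
        rng = child_rng(seed, "truth", sp)
        geno = _strain_genotypes(k, d if k > 1 else 0, rng)
        n_div = geno.shape[1]
        site_df = _site_table(sp, n_div + n_intra, L, rng)
        # within-strain sites are appended after the divergent block
        geno = np.concatenate(
            [geno, np.zeros((k, n_intra), dtype=np.int8)], axis=1
        )
        intra = pd.Series(0.0, index=site_df.index)
        if n_intra:
            intra.iloc[n_div:] = community.intra_strain_freq
        if colonization.freq_model == "uniform":
            sf = _uniform_freqs(inoc, samples, colonization, rng)
        else:
            sf = _hierarchical_freqs(inoc, samples, colonization, rng)
        colonized[sp] = {
            m: bool(rng.random() >= colonization.species_dropout_prob)
            for m in mice
        }
        sites[sp] = site_df
        genotypes[sp] = geno
        strain_freqs[sp] = sf
        intra_freq[sp] = intra
        divergence[sp] = int(d)

    rng_sw = child_rng(seed, "sweeps")
    planted = _place_sweeps(
        sweeps, species_ids, sites, genotypes, strain_freqs, colonized,
        samples, rng_sw,
    )
    for sp in species_ids:
        intra_freq[sp] = intra_freq[sp].reindex(sites[sp].index, fill_value=0.0)

    rng_ab = child_rng(seed, "abundance")
    base = rng_ab.normal(0.0, 1.0, size=len(species_ids))
    ab = np.zeros((len(species_ids), len(samples)))
    for j, s in enumerate(samples):
        eff = rng_ab.normal(0.0, colonization.sigma_abundance, len(species_ids))
        w = np.exp(base + eff)
        if not s.is_inoculum:
            present = np.array(
                [colonized[sp][s.mouse_id] for sp in species_ids], dtype=bool
            )
            w = np.where(present, w, 0.0)
        ab[:, j] = w / w.sum() if w.sum() > 0 else 0.0
    abundance = pd.DataFrame(
        ab, index=species_ids, columns=[s.sample_id for s in samples]
    )
    return GroundTruth(
        samples=samples,
        species_ids=species_ids,
        sites=sites,
        genotypes=genotypes,
        strain_freqs=strain_freqs,
        intra_freq=intra_freq,
        planted_sweeps=planted,
        colonized=colonized,
        divergence=divergence,
        abundance=abundance,
    )


def render_observations(
    truth: GroundTruth, seq: SequencingConfig, seed: int = 0
) -> tuple[dict[str, SNVTable], pd.DataFrame]:
    """Render the truth into observed SNV tables and an abundance table.

    Per site and sample: depth D ~ depth_distribution(mean_depth x batch
    multiplier); alt reads ~ Binomial(D, p(1-2e)+e) where p is the
    strain-frequency-weighted true allele frequency and e the per-read
    error rate. Species that failed to colonise a mouse have zero depth in
    all of that mouse's samples.
    """
    tables: dict[str, SNVTable] = {}
    sample_ids = truth.sample_ids
    mults = np.array(
        [seq.batch_multipliers.get(s, 1.0) for s in sample_ids], dtype=float
    )
    for sp in truth.species_ids:
        rng = child_rng(seed, "render", sp)
        p = truth.allele_freq(sp).to_numpy()  # sites x samples
        n_sites, n_samp = p.shape
        lam = np.broadcast_to(seq.mean_depth * mults, (n_sites, n_samp))
        if seq.depth_distribution == "poisson":
            depth = rng.poisson(lam)
        else:
            r = seq.nb_dispersion
            depth = rng.negative_binomial(r, r / (r + lam))
        # dropout: zero depth for non-colonised mice
        for j, s in enumerate(truth.samples):
            if not s.is_inoculum and not truth.colonized[sp][s.mouse_id]:
                depth[:, j] = 0
        p_obs = p * (1 - 2 * seq.error_rate) + seq.error_rate
        alt = rng.binomial(depth, p_obs)
        site_df = truth.sites[sp]
        tables[sp] = SNVTable(
            sp,
            site_df,
            pd.DataFrame(depth, index=site_df.index, columns=sample_ids),
            pd.DataFrame(alt, index=site_df.index, columns=sample_ids),
        )
    return tables, truth.abundance.copy()


# ---------------------------------------------------------------------------
# scenario registry


def _scn_single_strain():
    return dict(
        community=CommunityConfig(
            n_species=1, strains_per_species=1, pairwise_divergence=2000,
            intra_strain_sites=200,
        ),
        colonization=ColonizationConfig(
            sigma_cage=0.3, sigma_mouse=0.5, sigma_region=0.0
        ),
        sweeps=SweepConfig(),
        sequencing=SequencingConfig(mean_depth=50.0, error_rate=0.002),
        analysis=dict(min_cluster=500, min_pi_sites=100),
    )


def _scn_two_strain_uniform():
    return dict(
        community=CommunityConfig(
            n_species=1, strains_per_species=2, pairwise_divergence=2000
        ),
        colonization=ColonizationConfig(
            n_cages=2, mice_per_cage=(2, 2), freq_model="uniform",
            uniform_range=(0.2, 0.8),
        ),
        sweeps=SweepConfig(),
        sequencing=SequencingConfig(mean_depth=50.0),
        analysis=dict(min_cluster=500, min_pi_sites=100),
    )


def _scn_three_strain():
    return dict(
        community=CommunityConfig(
            n_species=1, strains_per_species=3, pairwise_divergence=2000,
            inoculum_strain_freqs=[(0.5, 0.3, 0.2)],
        ),
        colonization=ColonizationConfig(
            sigma_cage=0.2, sigma_mouse=0.5, sigma_region=0.0
        ),
        sweeps=SweepConfig(),
        sequencing=SequencingConfig(mean_depth=50.0),
        analysis=dict(min_cluster=400, min_pi_sites=100),
    )


def _scn_planted_sweeps():
    return dict(
        community=CommunityConfig(
            n_species=1, strains_per_species=1, pairwise_divergence=2000,
            intra_strain_sites=200,
        ),
        colonization=ColonizationConfig(),
        sweeps=SweepConfig(
            n_sweeps=5, sweep_scope="all-regions-of-a-mouse",
            start_freq=0.0, end_freq=1.0, sgv_inoculum_freq=0.05,
        ),
        sequencing=SequencingConfig(mean_depth=50.0, error_rate=0.002),
        analysis=dict(min_cluster=500, min_pi_sites=100),
    )


def _scn_paper_like_8mice():
    mults = {"inoculum": 2.0}
    for m in (7, 8):
        for r in GUT_REGIONS:
            mults[f"m{m}_{r}"] = 3.0
    return dict(
        community=CommunityConfig(
            n_species=5,
            strains_per_species=[2, 1, 2, 2, 3],
            pairwise_divergence=[3000, 2000, 4000, 2500, 2000],
            inoculum_strain_freqs=[
                (0.6, 0.4), (1.0,), (0.8, 0.2), (0.5, 0.5), (0.5, 0.3, 0.2),
            ],
            intra_strain_sites=100,
        ),
        colonization=ColonizationConfig(
            sigma_cage=0.4, sigma_mouse=0.8, sigma_region=0.1,
            species_dropout_prob=0.1,
        ),
        sweeps=SweepConfig(
            n_sweeps=2, sweep_scope="all-regions-of-a-mouse",
            start_freq=0.0, end_freq=1.0, sgv_inoculum_freq=0.05,
        ),
        sequencing=SequencingConfig(mean_depth=30.0, batch_multipliers=mults),
        analysis=dict(min_cluster=500, min_pi_sites=100),
    )


SCENARIOS = {
    "single_strain": _scn_single_strain,
    "two_strain_uniform": _scn_two_strain_uniform,
    "three_strain": _scn_three_strain,
    "planted_sweeps": _scn_planted_sweeps,
    "paper_like_8mice": _scn_paper_like_8mice,
}


def _cfg_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def scenario_manifest(name: str, seed: int) -> dict:
    scn = SCENARIOS[name]()
    return {
        "scenario": name,
        "seed": int(seed),
        "community": _cfg_dict(scn["community"]),
        "colonization": _cfg_dict(scn["colonization"]),
        "sweeps": _cfg_dict(scn["sweeps"]),
        "sequencing": _cfg_dict(scn["sequencing"]),
        "analysis": dict(scn["analysis"]),
    }


def configs_from_manifest(manifest: dict):
    col = dict(manifest["colonization"])
    for k in ("mice_per_cage", "regions", "uniform_range"):
        col[k] = tuple(col[k])
    comm = dict(manifest["community"])
    if comm.get("inoculum_strain_freqs"):
        comm["inoculum_strain_freqs"] = [
            tuple(f) for f in comm["inoculum_strain_freqs"]
        ]
    return (
        CommunityConfig(**comm),
        ColonizationConfig(**col),
        SweepConfig(**manifest["sweeps"]),
        SequencingConfig(**manifest["sequencing"]),
    )


def build_scenario(name: str, seed: int = 0):
    """Generate truth and observations for a named scenario.

    Returns (truth, tables, abundance, manifest).
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    manifest = scenario_manifest(name, seed)
    return build_from_manifest(manifest)


def build_from_manifest(manifest: dict):
    community, colonization, sweeps, sequencing = configs_from_manifest(manifest)
    truth = generate_truth(community, colonization, sweeps, seed=manifest["seed"])
    mults = sequencing.batch_multipliers
    if mults:
        # samples sequenced deeper form their own batch (cf. mice 7/8)
        truth.samples = [
            dataclasses.replace(s, batch="deep")
            if mults.get(s.sample_id, 1.0) != 1.0
            else s
            for s in truth.samples
        ]
    tables, abundance = render_observations(
        truth, sequencing, seed=manifest["seed"]
    )
    return truth, tables, abundance, manifest


def write_fixture_set(
    path, scenario_name: str, seed: int = 0, force: bool = False
) -> Path:
    """Render a named scenario to an on-disk fixture tree with a manifest."""
    truth, tables, abundance, manifest = build_scenario(scenario_name, seed)
    save_dataset(
        path, tables, abundance, truth.samples, manifest=manifest, force=force
    )
    return Path(path)
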