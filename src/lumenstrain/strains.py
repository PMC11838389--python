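"""Strain phasing from correlated SNV-frequency trajectories.

SNVs residing on the same strain background rise and fall together across
samples, so their allele-frequency trajectories are highly correlated. The
phaser scores each SNV pair with a depth-weighted distance

    d(f_i, f_j) = (1/S) sum_s 2 (D_is + D_js) (f_is - f_js)^2
                  / [ (f_is + f_js) (1 - f_is + 1 - f_js) ]

taken over the S samples where both sites have depth >= 10, polarised as
min(d(f_i, f_j), d(f_i, 1 - f_j)) so reference-allele labelling cannot keep
linked SNVs apart. Pairs with d < 3.5 are joined by an edge; a greedy
network algorithm repeatedly extracts the neighbourhood of the
highest-degree (focal) SNV, pruning members connected to fewer than 25% of
the cluster. Each emitted cluster of >= 10^3 SNVs is read as the set of
alleles segregating between two strains: with K strains present we expect
C(K,2) such mutation classes for K >= 3, one class for K = 2, and none for
K = 1. Strain frequencies are the mean polarity-corrected allele frequency
of cluster SNVs, with percentile bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lumenstrain.io import SNVTable, SampleMeta, meta_frame


# ---------------------------------------------------------------------------
# site filtering


@dataclass
class PhasingSiteSet:
    """Sites retained for phasing, with their frequency/depth trajectories.

    Rows are ordered by site_id (the order used for all deterministic
    tie-breaks downstream).
    """

    species_id: str
    freq: pd.DataFrame  # site x sample alt-allele frequency (NaN at depth 0)
    depth: pd.DataFrame  # site x sample depth

    @property
    def site_ids(self) -> list[str]:
        return list(self.freq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.freq.columns)


def filter_phasing_sites(
    table: SNVTable,
    samples: list[str] | None = None,
    min_depth: int = 10,
    min_minor_reads: int = 4,
    min_polymorphic_frac: float = 0.2,
) -> PhasingSiteSet:
    """Retain informative polymorphic sites for strain inference.

    A site is polymorphic in a sample when its depth is >= ``min_depth``
    and both alleles have at least ``min_minor_reads`` supporting reads
    (rare-allele support below four reads is indistinguishable from noise
    and would seed spurious low-frequency clusters). A site is retained
    when it is polymorphic in at least ``min_polymorphic_frac`` (inclusive)
    of the samples in which the species is detected — sites fixed at 0 or 1
    everywhere carry no strain signal.
    """
    if samples is None:
        samples = table.samples
    samples = list(samples)
    d = table.depth[samples].to_numpy()
    a = table.alt[samples].to_numpy()
    poly = (d >= min_depth) & (a >= min_minor_reads) & (d - a >= min_minor_reads)
    keep = poly.sum(axis=1) >= min_polymorphic_frac * len(samples)
    site_ids = sorted(table.sites.index[keep])
    sub = table.subset_sites(site_ids)
    freq = sub.freq()[samples]
    return PhasingSiteSet(table.species_id, freq, sub.depth[samples])


# ---------------------------------------------------------------------------
# trajectory distance


def snv_pair_distance(
    fi, fj, di, dj, min_depth: int = 10, min_overlap: int = 3
) -> float:
    """Polarised trajectory distance between two SNVs.

    Averaged over the samples where both sites have depth >= ``min_depth``;
    returns NaN when fewer than ``min_overlap`` such samples exist. A
    per-sample term with zero denominator has zero numerator (both
    frequencies 0 or both 1) and contributes 0.
    """
    fi = np.asarray(fi, dtype=float)
    fj = np.asarray(fj, dtype=float)
    di = np.asarray(di, dtype=float)
    dj = np.asarray(dj, dtype=float)
    shared = (di >= min_depth) & (dj >= min_depth)
    shared &= np.isfinite(fi) & np.isfinite(fj)
    if shared.sum() < min_overlap:
        return float("nan")
    fi, fj, w = fi[shared], fj[shared], di[shared] + dj[shared]

    def _d(fa, fb):
        num = 2.0 * w * (fa - fb) ** 2
        den = (fa + fb) * (2.0 - fa - fb)
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return float(terms.mean())

    return min(_d(fi, fj), _d(fi, 1.0 - fj))


def pairwise_distances(
    sites: PhasingSiteSet,
    min_depth: int = 10,
    min_overlap: int = 3,
    chunk: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs polarised distances and the polarity (flip) matrix.

    Returns ``(dist, flip)`` where ``dist[i, j]`` is the polarised distance
    (NaN when the shared-sample overlap is below ``min_overlap``) and
    ``flip[i, j]`` is True when the flipped orientation d(f_i, 1 - f_j)
    is the smaller one.
    """
    F = sites.freq.to_numpy(dtype=np.float32)
    D = sites.depth.to_numpy(dtype=np.float32)
    n, S = F.shape
    valid = (D >= min_depth) & np.isfinite(F)
    F = np.where(valid, F, 0.0)
    dist = np.full((n, n), np.nan, dtype=np.float32)
    flip = np.zeros((n, n), dtype=bool)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        c = stop - start
        acc0 = np.zeros((c, n), np.float32)
        acc1 = np.zeros((c, n), np.float32)
        cnt = np.zeros((c, n), np.int32)
        for s in range(S):
            vi = valid[start:stop, s][:, None]
            vj = valid[None, :, s]
            sh = vi & vj
            fi = F[start:stop, s][:, None]
            fj = F[None, :, s]
            w = D[start:stop, s][:, None] + D[None, :, s]
            num = 2.0 * w * (fi - fj) ** 2
            den = (fi + fj) * (2.0 - fi - fj)
            acc0 += np.where(sh & (den > 0), num / np.maximum(den, 1e-12), 0.0)
            gj = 1.0 - fj
            num = 2.0 * w * (fi - gj) ** 2
            den = (fi + gj) * (2.0 - fi - gj)
            acc1 += np.where(sh & (den > 0), num / np.maximum(den, 1e-12), 0.0)
            cnt += sh
        with np.errstate(invalid="ignore", divide="ignore"):
            d0 = acc0 / cnt
            d1 = acc1 / cnt
        block = np.minimum(d0, d1)
        block[cnt < min_overlap] = np.nan
        dist[start:stop] = block
        flip[start:stop] = d1 < d0
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(flip, False)
    return dist, flip


# ---------------------------------------------------------------------------
# greedy network clustering


@dataclass
class StrainCluster:
    site_ids: list[str]
    polarity: dict[str, bool]  # True where the SNV is flipped vs the focal
    focal: str
    size: int = 0

    def __post_init__(self) -> None:
        self.size = len(self.site_ids)


@dataclass
class StrainClusterSet:
    species_id: str
    clusters: list[StrainCluster]
    min_cluster: int
    mode: str = "greedy"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _greedy_clusters(
    adj: np.ndarray, ids: list[str], min_cluster: int, intra_connect: float
) -> list[tuple[int, list[int]]]:
    """Greedy focal-SNV extraction on a boolean adjacency matrix.

    ``ids`` must be in ascending site_id order: degree ties break toward the
    lowest site_id, and the single connectivity prune visits members in
    site_id order against the shrinking member set (the focal is exempt).
    Stops when the best focal's pruned cluster falls below ``min_cluster``.
    """
    n = adj.shape[0]
    active = np.ones(n, dtype=bool)
    out = []
    while active.any():
        sub = adj & active[None, :] & active[:, None]
        deg = sub.sum(axis=1)
        deg[~active] = -1
        focal = int(np.argmax(deg))  # ties -> first index == lowest site_id
        members = [focal] + [int(j) for j in np.flatnonzero(sub[focal])]
        member_set = set(members)
        for i in sorted(member_set - {focal}):
            size = len(member_set)
            conn = sum(1 for j in member_set if j != i and adj[i, j])
            if conn < intra_connect * (size - 1):
                member_set.discard(i)
        if len(member_set) < min_cluster:
            break
        out.append((focal, sorted(member_set)))
        active[sorted(member_set)] = False
    return out


def infer_strain_clusters(
    sites: PhasingSiteSet,
    d_max: float = 3.5,
    min_cluster: int = 1000,
    intra_connect: float = 0.25,
    mode: str = "greedy",
    min_depth: int = 10,
    min_overlap: int = 3,
) -> StrainClusterSet:
    """Cluster co-segregating SNVs into strain mutation classes.

    ``mode="greedy"`` is the focal-SNV network algorithm. ``mode="mean_focal"``
    instead seeds a single cluster from a synthetic focal trajectory — the
    per-sample mean SNV frequency — for the pathological case where high
    frequency variance splits one mutation class into two clusters.
    Zero clusters is a valid outcome (one strain, or nothing phaseable).
    """
    ids = sites.site_ids
    if ids != sorted(ids):
        raise ValueError("PhasingSiteSet must be ordered by site_id")
    n = len(ids)
    if n == 0:
        return StrainClusterSet(sites.species_id, [], min_cluster, mode)
    if mode == "mean_focal":
        return _mean_focal_cluster(
            sites, d_max, min_cluster, min_depth, min_overlap
        )
    if mode != "greedy":
        raise ValueError(f"unknown mode {mode!r}")
    dist, flip = pairwise_distances(sites, min_depth, min_overlap)
    adj = np.nan_to_num(dist, nan=np.inf) < d_max
    np.fill_diagonal(adj, False)
    clusters = []
    for focal, members in _greedy_clusters(adj, ids, min_cluster, intra_connect):
        clusters.append(
            StrainCluster(
                site_ids=[ids[m] for m in members],
                polarity={ids[m]: bool(flip[focal, m]) for m in members},
                focal=ids[focal],
            )
        )
    return StrainClusterSet(sites.species_id, clusters, min_cluster, "greedy")


def _mean_focal_cluster(
    sites: PhasingSiteSet,
    d_max: float,
    min_cluster: int,
    min_depth: int,
    min_overlap: int,
) -> StrainClusterSet:
    F = sites.freq.to_numpy(dtype=float)
    D = sites.depth.to_numpy(dtype=float)
    valid = (D >= min_depth) & np.isfinite(F)
    with np.errstate(invalid="ignore"):
        mean_traj = np.nanmean(np.where(valid, F, np.nan), axis=0)
    mean_depth = np.where(valid, D, np.nan)
    mean_depth = np.nanmean(mean_depth, axis=0)
    ids = sites.site_ids
    members, polarity = [], {}
    for i, sid in enumerate(ids):
        d0 = snv_pair_distance(
            F[i], mean_traj, D[i], mean_depth, min_depth, min_overlap
        )
        if np.isnan(d0):
            continue
        d_flip = snv_pair_distance(
            F[i], 1.0 - mean_traj, D[i], mean_depth, min_depth, min_overlap
        )
        if d0 < d_max:
            members.append(sid)
            polarity[sid] = bool(d_flip < d0)
    clusters = []
    if len(members) >= min_cluster:
        clusters.append(
            StrainCluster(site_ids=members, polarity=polarity, focal="mean")
        )
    return StrainClusterSet(sites.species_id, clusters, min_cluster, "mean_focal")


# ---------------------------------------------------------------------------
# strain frequencies


@dataclass
class StrainProfile:
    """Per-sample strain frequency estimates with bootstrap CIs.

    ``frame`` columns: sample_id, strain_index, freq, ci_lo, ci_hi,
    n_support, reported. With one cluster (two strains) the two rows per
    sample are f-bar and 1 - f-bar; with K >= 2 clusters per-cluster mean
    frequencies are emitted but ``frequencies_identified`` is False (the
    mapping from mutation classes to strain frequencies is not defined).
    """

    species_id: str
    frame: pd.DataFrame
    n_clusters: int
    frequencies_identified: bool
    source: str = "clusters"


def bootstrap_strain_ci(
    values,
    n_boot: int = 1000,
    block: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile 95% CI of the mean under i.i.d. SNV resampling.

    ``n_boot`` resamples of ``block`` SNVs each are drawn with replacement;
    the interval is the 2.5/97.5 percentile of the resampled means.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one qualifying SNV")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, block))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def estimate_strain_frequencies(
    clusters: StrainClusterSet,
    sites: PhasingSiteSet,
    min_depth: int = 10,
    min_support: int = 100,
    n_boot: int = 1000,
    block: int = 100,
    seed: int = 0,
) -> StrainProfile:
    """Mean polarity-corrected cluster frequency per sample, with CIs.

    A sample is flagged ``reported`` only when every cluster is supported
    there by at least ``min_support`` SNVs with depth >= ``min_depth``.
    """
    rows = []
    rng = np.random.default_rng(seed)
    two_strain = clusters.n_clusters == 1
    per_cluster_support: dict[str, list[int]] = {s: [] for s in sites.samples}
    per_sample_rows: dict[str, list[dict]] = {s: [] for s in sites.samples}
    for ci, cl in enumerate(clusters.clusters):
        f = sites.freq.loc[cl.site_ids]
        d = sites.depth.loc[cl.site_ids]
        flipped = np.array([cl.polarity[s] for s in cl.site_ids])
        fcorr = f.to_numpy(dtype=float).copy()
        fcorr[flipped] = 1.0 - fcorr[flipped]
        ok = (d.to_numpy() >= min_depth) & np.isfinite(fcorr)
        for j, sample in enumerate(sites.samples):
            vals = fcorr[ok[:, j], j]
            per_cluster_support[sample].append(vals.size)
            if vals.size == 0:
                continue
            lo, hi = bootstrap_strain_ci(vals, n_boot, block, rng=rng)
            per_sample_rows[sample].append(
                {
                    "sample_id": sample,
                    "strain_index": ci,
                    "freq": float(vals.mean()),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "n_support": int(vals.size),
                }
            )
    for sample in sites.samples:
        support = per_cluster_support[sample]
        reported = bool(support) and all(s >= min_support for s in support)
        for row in per_sample_rows[sample]:
            row["reported"] = reported
            rows.append(row)
            if two_strain:
                rows.append(
                    {
                        "sample_id": sample,
                        "strain_index": 1,
                        "freq": 1.0 - row["freq"],
                        "ci_lo": 1.0 - row["ci_hi"],
                        "ci_hi": 1.0 - row["ci_lo"],
                        "n_support": row["n_support"],
                        "reported": reported,
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "strain_index", "freq", "ci_lo", "ci_hi",
            "n_support", "reported",
        ],
    )
    return StrainProfile(
        species_id=clusters.species_id,
        frame=frame,
        n_clusters=clusters.n_clusters,
        frequencies_identified=two_strain,
    )


def infer_inoculum_only_strains(
    table: SNVTable,
    inoculum_sample: str,
    min_snvs: int = 1000,
    min_depth: int = 10,
    min_minor_reads: int = 4,
    n_boot: int = 1000,
    block: int = 100,
    seed: int = 0,
) -> StrainProfile:
    """Fallback two-strain call from the inoculum alone.

    When clustering finds zero clusters but the inoculum still carries at
    least ``min_snvs`` polymorphic SNVs (depth >= 10, both alleles with
    >= 4 reads) — e.g. the minor strain failed to colonise any mouse — two
    inoculum strains are reported at (mean polymorphic frequency, 1 - mean).
    Each SNV is polarised to its minor allele in the inoculum, so the first
    strain is the minor lineage. Otherwise a single strain is reported.
    """
    d = table.depth[inoculum_sample].to_numpy(dtype=float)
    a = table.alt[inoculum_sample].to_numpy(dtype=float)
    qual = (d >= min_depth) & (a >= min_minor_reads) & (d - a >= min_minor_reads)
    n_qual = int(qual.sum())
    if n_qual < min_snvs:
        frame = pd.DataFrame(
            [
                {
                    "sample_id": inoculum_sample,
                    "strain_index": 0,
                    "freq": 1.0,
                    "ci_lo": 1.0,
                    "ci_hi": 1.0,
                    "n_support": n_qual,
                    "reported": True,
                }
            ]
        )
        return StrainProfile(
            table.species_id, frame, 0, True, source="inoculum_single"
        )
    f = a[qual] / d[qual]
    f = np.minimum(f, 1.0 - f)
    lo, hi = bootstrap_strain_ci(f, n_boot, block, seed=seed)
    fbar = float(f.mean())
    frame = pd.DataFrame(
        [
            {
                "sample_id": inoculum_sample,
                "strain_index": 0,
                "freq": fbar,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_support": n_qual,
                "reported": True,
            },
            {
                "sample_id": inoculum_sample,
                "strain_index": 1,
                "freq": 1.0 - fbar,
                "ci_lo": 1.0 - hi,
                "ci_hi": 1.0 - lo,
                "n_support": n_qual,
                "reported": True,
            },
        ]
    )
    return StrainProfile(
        table.species_id, frame, 0, True, source="inoculum_only"
    )


# ---------------------------------------------------------------------------
# ANOVA variance partition


@dataclass
class VariancePartition:
    """Fractions of total sum of squares by cage, mouse, gut region."""

    species_id: str
    fractions: dict  # cage, mouse, gut_region, residual
    n_samples: int
    degenerate: bool = False
    reason: str = ""


def anova_eligibility(meta: pd.DataFrame) -> tuple[bool, str]:
    """Eligibility of a species' detected samples for the variance partition.

    Requires detection across at least two cages (each with the species in
    at least two mice), at least two mice (each with at least two regions),
    and at least two gut regions (each detected in at least two mice).
    ``meta`` holds the detected mouse samples (columns cage_id, mouse_id,
    gut_region).
    """
    cages = meta.groupby("cage_id")["mouse_id"].nunique()
    if (cages >= 2).sum() < 2:
        return False, "needs >= 2 cages with >= 2 mice each"
    mice = meta.groupby("mouse_id")["gut_region"].nunique()
    if (mice >= 2).sum() < 2:
        return False, "needs >= 2 mice with >= 2 regions each"
    regions = meta.groupby("gut_region")["mouse_id"].nunique()
    if (regions >= 2).sum() < 2:
        return False, "needs >= 2 regions detected in >= 2 mice"
    return True, ""


def partition_strain_variance(
    major_freq: pd.Series,
    samples: list[SampleMeta],
    check_eligibility: bool = True,
    clamp: float = 1e-6,
) -> VariancePartition:
    """Sequential ANOVA of CLR-transformed major-strain frequency.

    The response is the centred log-ratio of the two-part composition
    (f, 1 - f), i.e. 0.5 ln(f / (1 - f)) with f clamped away from 0 and 1.
    Type-I sums of squares are taken in the fixed order cage -> mouse ->
    gut region (mouse is nested in cage); fractions of the total SS are
    reported, with the residual as remainder.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    meta = meta_frame(samples)
    df = meta.loc[meta.index.intersection(major_freq.index)].copy()
    df = df[~df["is_inoculum"]]
    df["f"] = major_freq[df.index]
    df = df.dropna(subset=["f"])
    species_id = ""
    if check_eligibility:
        ok, reason = anova_eligibility(df)
        if not ok:
            return VariancePartition(species_id, {}, len(df), True, reason)
    f = df["f"].clip(clamp, 1.0 - clamp)
    df["clr"] = 0.5 * np.log(f / (1.0 - f))
    if np.isclose(df["clr"].var(ddof=0), 0.0):
        return VariancePartition(
            species_id, {}, len(df), True, "zero variance in CLR response"
        )
    model = smf.ols(
        "clr ~ C(cage_id) + C(mouse_id) + C(gut_region)", data=df
    ).fit()
    tab = anova_lm(model, typ=1)
    ss = tab["sum_sq"]
    total = float(ss.sum())
    fractions = {
        "cage": float(ss["C(cage_id)"] / total),
        "mouse": float(ss["C(mouse_id)"] / total),
        "gut_region": float(ss["C(gut_region)"] / total),
        "residual": float(ss["Residual"] / total),
    }
    return VariancePartition(species_id, fractions, len(df), False, "")
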