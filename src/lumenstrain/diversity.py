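"""Species-level diversity summaries and within-species nucleotide diversity.

Alpha diversity is the Shannon index in nats; beta diversity is Bray-Curtis
dissimilarity. Region contrasts compare small-intestinal (duodenum, jejunum,
ileum) against large-intestinal (cecum, colon) means per mouse with a paired
Wilcoxon signed-rank test.

Nucleotide diversity pi is the expected per-site probability of drawing two
reads with different alleles, estimated from pooled counts with the unbiasing
D/(D-1) factor:

    pi = (1/|G|) sum_i sum_{B1 != B2} (x_{i,B1}/D_i) (x_{i,B2}/(D_i - 1))

over sites with D_i >= 4; |G| counts the included sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lumenstrain.io import (
    LARGE_INTESTINE,
    SMALL_INTESTINE,
    SNVTable,
    SampleMeta,
    meta_frame,
    site_band_filter,
)


def shannon_index(abundances) -> float:
    """Shannon diversity H = -sum p ln p (natural log), zeros skipped."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) on an aligned index."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must be aligned")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


@dataclass
class RegionContrast:
    """Small- vs large-intestine contrast of a per-sample quantity."""

    label: str
    per_mouse: pd.DataFrame  # index mouse_id; columns small, large, fold
    fold_change: float  # mean of per-mouse large/small ratios
    p_value: float  # two-sided paired Wilcoxon signed-rank
    n_mice: int
    dropped_mice: tuple


def region_contrast(values: pd.Series, samples: list[SampleMeta], label: str = "") -> RegionContrast:
    """Contrast a per-sample quantity between small and large intestine.

    ``values`` is indexed by sample_id. Per mouse, the quantity is averaged
    over member regions of each group; a mouse missing a whole group is
    dropped (not imputed). The group fold change is the mean of per-mouse
    large/small ratios; the test is an exact two-sided paired Wilcoxon
    signed-rank across mice.
    """
    meta = meta_frame(samples)
    meta = meta.loc[meta.index.intersection(values.index)]
    rows = {}
    dropped = []
    for mouse, grp in meta[~meta["is_inoculum"]].groupby("mouse_id"):
        small = values[grp.index[grp["gut_region"].isin(SMALL_INTESTINE)]]
        large = values[grp.index[grp["gut_region"].isin(LARGE_INTESTINE)]]
        small, large = small.dropna(), large.dropna()
        if small.empty or large.empty:
            dropped.append(mouse)
            continue
        rows[mouse] = {"small": small.mean(), "large": large.mean()}
    per_mouse = pd.DataFrame.from_dict(rows, orient="index")
    if len(per_mouse) < 2:
        raise ValueError("need >= 2 mice with both intestinal groups")
    with np.errstate(divide="ignore"):
        per_mouse["fold"] = per_mouse["large"] / per_mouse["small"]
    diffs = per_mouse["large"] - per_mouse["small"]
    if (diffs == 0).all():
        p = 1.0
    else:
        try:
            p = float(
                stats.wilcoxon(
                    per_mouse["large"], per_mouse["small"], method="exact"
                ).pvalue
            )
        except ValueError:
            p = float(
                stats.wilcoxon(per_mouse["large"], per_mouse["small"]).pvalue
            )
    return RegionContrast(
        label=label,
        per_mouse=per_mouse,
        fold_change=float(per_mouse["fold"].mean()),
        p_value=p,
        n_mice=len(per_mouse),
        dropped_mice=tuple(dropped),
    )


@dataclass
class PiResult:
    """Nucleotide diversity of one species in one sample."""

    species_id: str
    sample_id: str
    pi: float  # NaN when undefined (no usable sites)
    n_sites_used: int
    mean_depth_used: float


def nucleotide_diversity(
    table: SNVTable,
    sample: str,
    min_site_depth: int = 4,
    apply_band: bool = True,
) -> PiResult:
    """Per-sample pi from pooled biallelic read counts.

    Sites with depth < ``min_site_depth`` (default 4) are excluded; with
    ``apply_band`` the 0.3x/3x coverage band is applied as well. With
    biallelic counts the inner sum reduces to 2 x_alt x_ref / (D (D-1)).
    An empty usable-site set yields pi = NaN (undefined, not zero).
    """
    d = table.depth[sample].to_numpy(dtype=float)
    a = table.alt[sample].to_numpy(dtype=float)
    mask = d >= min_site_depth
    if apply_band:
        mask &= site_band_filter(table, sample).to_numpy()
    if not mask.any():
        return PiResult(table.species_id, sample, float("nan"), 0, float("nan"))
    d, a = d[mask], a[mask]
    het = 2.0 * a * (d - a) / (d * (d - 1.0))
    return PiResult(
        table.species_id,
        sample,
        float(het.mean()),
        int(mask.sum()),
        float(d.mean()),
    )


def pi_frame(results: list[PiResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "sample_id": r.sample_id,
                "pi": r.pi,
                "n_sites_used": r.n_sites_used,
                "mean_depth_used": r.mean_depth_used,
            }
            for r in results
        ]
    )


def pi_species_inclusion(
    results: list[PiResult],
    samples: list[SampleMeta],
    min_pi_sites: int = 500_000,
) -> set:
    """Species whose pi estimates are reportable.

    A sample's estimate is valid when it used at least ``min_pi_sites``
    sites (the default matches genome-scale data; scale it down for small
    synthetic genomes). A species is included iff it has a valid inoculum
    estimate and valid estimates in at least three mouse samples drawn from
    at least two different mice.
    """
    meta = meta_frame(samples)
    df = pi_frame(results)
    df = df[df["pi"].notna() & (df["n_sites_used"] >= min_pi_sites)]
    included = set()
    for sp, grp in df.groupby("species_id"):
        m = meta.loc[grp["sample_id"]]
        if not m["is_inoculum"].any():
            continue
        mouse_rows = m[~m["is_inoculum"]]
        if len(mouse_rows) >= 3 and mouse_rows["mouse_id"].nunique() >= 2:
            included.add(sp)
    return included


def pi_variance_partition(
    results: list[PiResult], samples: list[SampleMeta]
) -> pd.DataFrame:
    """Within- vs between-mouse variance of pi per species.

    Within-mouse variance: mean over mice of the variance of pi across that
    mouse's gut regions. Between-mouse variance: mean over regions of the
    variance of pi across mice within that region. Species present in a
    single mouse get a missing between-mouse component.
    """
    meta = meta_frame(samples)
    df = pi_frame(results)
    df = df[df["pi"].notna()].merge(
        meta.reset_index(), on="sample_id", how="left"
    )
    df = df[~df["is_inoculum"]]
    rows = []
    for sp, grp in df.groupby("species_id"):
        within = grp.groupby("mouse_id")["pi"].var(ddof=1)
        between = grp.groupby("gut_region")["pi"].var(ddof=1)
        n_mice = grp["mouse_id"].nunique()
        rows.append(
            {
                "species_id": sp,
                "within_mouse_var": float(within.mean()),
                "between_mouse_var": (
                    float(between.mean()) if n_mice >= 2 else float("nan")
                ),
                "n_mice": n_mice,
            }
        )
    return pd.DataFrame(rows)
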