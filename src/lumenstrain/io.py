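"""Data model, TSV readers/writers, validation, and coverage filters.

The on-disk layout is a MIDAS-merge-style fixture tree::

    <root>/
      samples.tsv                 sample_id, mouse_id, cage_id, gut_region,
                                  is_inoculum, batch
      species_profile.tsv         species_id x sample_id -> relative abundance
      <species_id>/
        snps_info.tsv             site_id, contig, position (1-based),
                                  ref_allele, alt_allele, gene_id, site_type
        snps_depth.tsv            site_id x sample_id -> integer depth
        snps_alt_count.tsv        site_id x sample_id -> integer alt reads

Sites are biallelic: per site the table records total depth D and the read
count of the alternative allele; the reference count is D - alt. Readers are
gzip-transparent (pandas handles ``.gz`` suffixes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GUT_REGIONS = ("duodenum", "jejunum", "ileum", "cecum", "colon")
#: Closed enum of sample locations; the inoculum is its own pseudo-region.
REGIONS_WITH_INOCULUM = GUT_REGIONS + ("inoculum",)

SITE_TYPES = ("syn", "nonsyn", "noncoding")

SMALL_INTESTINE = ("duodenum", "jejunum", "ileum")
LARGE_INTESTINE = ("cecum", "colon")


class ValidationError(ValueError):
    """A table or metadata record violates the format contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample.

    The inoculum sample carries ``mouse_id == "inoculum"``, no cage, and
    region ``"inoculum"``.
    """

    sample_id: str
    mouse_id: str
    cage_id: str | None
    gut_region: str
    batch: str = "b1"

    def __post_init__(self) -> None:
        if self.gut_region not in REGIONS_WITH_INOCULUM:
            raise ValidationError(
                f"sample {self.sample_id}: unknown gut_region {self.gut_region!r}"
            )
        if self.is_inoculum:
            if self.mouse_id != "inoculum" or self.cage_id is not None:
                raise ValidationError(
                    f"sample {self.sample_id}: inoculum must have "
                    "mouse_id='inoculum' and no cage"
                )
        elif self.mouse_id == "inoculum":
            raise ValidationError(
                f"sample {self.sample_id}: mouse_id 'inoculum' requires "
                "gut_region 'inoculum'"
            )

    @property
    def is_inoculum(self) -> bool:
        return self.gut_region == "inoculum"


def meta_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "mouse_id": s.mouse_id,
                "cage_id": s.cage_id if s.cage_id is not None else "",
                "gut_region": s.gut_region,
                "is_inoculum": s.is_inoculum,
                "batch": s.batch,
            }
            for s in samples
        ]
    )
    return df.set_index("sample_id")


@dataclass
class SNVTable:
    """Per-species site x sample allele-count matrices.

    Attributes
    ----------
    species_id : str
    sites : DataFrame indexed by site_id with columns contig, position,
        ref_allele, alt_allele, gene_id, site_type.
    depth : DataFrame (site x sample) of total read depth D_i.
    alt : DataFrame (site x sample) of alternative-allele read counts.
    """

    species_id: str
    sites: pd.DataFrame
    depth: pd.DataFrame
    alt: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.sites.index.is_unique:
            dup = self.sites.index[self.sites.index.duplicated()][0]
            raise ValidationError(f"{self.species_id}: duplicate site_id {dup!r}")
        if not (
            self.sites.index.equals(self.depth.index)
            and self.sites.index.equals(self.alt.index)
        ):
            raise ValidationError(f"{self.species_id}: site index misaligned")
        if not self.depth.columns.equals(self.alt.columns):
            raise ValidationError(f"{self.species_id}: sample columns misaligned")
        bad = (self.alt.to_numpy() > self.depth.to_numpy()) | (
            self.alt.to_numpy() < 0
        )
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"{self.species_id}: alt_count > depth at site "
                f"{self.depth.index[i]!r}, sample {self.depth.columns[j]!r}"
            )
        missing = set(SITE_TYPES).union({""})
        unknown = set(self.sites["site_type"].unique()) - missing
        if unknown:
            raise ValidationError(
                f"{self.species_id}: unknown site_type values {sorted(unknown)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.depth.columns)

    def freq(self) -> pd.DataFrame:
        """Alternative-allele frequency alt/depth; NaN where depth is 0."""
        d = self.depth.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(d > 0, self.alt.to_numpy(dtype=float) / d, np.nan)
        return pd.DataFrame(f, index=self.depth.index, columns=self.depth.columns)

    def coding_mask(self) -> pd.Series:
        """True at protein-coding sites (site_type != noncoding).

        If no annotation is present (all empty), every site counts as coding.
        """
        st = self.sites["site_type"]
        if (st == "").all():
            return pd.Series(True, index=self.sites.index)
        return st != "noncoding"

    def subset_sites(self, site_ids) -> "SNVTable":
        return SNVTable(
            self.species_id,
            self.sites.loc[site_ids],
            self.depth.loc[site_ids],
            self.alt.loc[site_ids],
        )

    def subset_samples(self, samples) -> "SNVTable":
        samples = list(samples)
        return SNVTable(
            self.species_id, self.sites, self.depth[samples], self.alt[samples]
        )

    def copy(self) -> "SNVTable":
        return SNVTable(
            self.species_id, self.sites.copy(), self.depth.copy(), self.alt.copy()
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def load_dataset(path) -> tuple[dict[str, SNVTable], pd.DataFrame, list[SampleMeta]]:
    """Load a fixture tree: per-species SNV tables, abundances, metadata."""
    root = Path(path)
    meta_df = pd.read_csv(root / "samples.tsv", sep="\t", dtype=str).fillna("")
    samples = []
    for _, row in meta_df.iterrows():
        samples.append(
            SampleMeta(
                sample_id=row["sample_id"],
                mouse_id=row["mouse_id"],
                cage_id=row["cage_id"] or None,
                gut_region=row["gut_region"],
                batch=row.get("batch", "b1") or "b1",
            )
        )
    abundance = _read_matrix(root / "species_profile.tsv")
    tables: dict[str, SNVTable] = {}
    for sp_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        info_path = sp_dir / "snps_info.tsv"
        if not info_path.exists():
            continue
        sites = pd.read_csv(
            info_path, sep="\t", dtype={"site_id": str, "position": int}
        ).fillna("")
        sites = sites.set_index("site_id")
        depth = _read_matrix(sp_dir / "snps_depth.tsv")
        alt = _read_matrix(sp_dir / "snps_alt_count.tsv")
        tables[sp_dir.name] = SNVTable(sp_dir.name, sites, depth, alt)
    sample_ids = {s.sample_id for s in samples}
    for sp, t in tables.items():
        unknown = set(t.samples) - sample_ids
        if unknown:
            raise ValidationError(f"{sp}: samples missing metadata: {sorted(unknown)}")
    return tables, abundance, samples


def save_dataset(
    path,
    tables: dict[str, SNVTable],
    abundance: pd.DataFrame,
    samples: list[SampleMeta],
    manifest: dict | None = None,
    force: bool = False,
) -> None:
    """Write a fixture tree; refuses to overwrite unless ``force``."""
    root = Path(path)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(f"{root} is not empty (pass force=True to overwrite)")
    root.mkdir(parents=True, exist_ok=True)
    meta_frame(samples).reset_index().to_csv(
        root / "samples.tsv", sep="\t", index=False
    )
    abundance.to_csv(root / "species_profile.tsv", sep="\t")
    for sp, t in tables.items():
        d = root / sp
        d.mkdir(exist_ok=True)
        t.sites.reset_index().to_csv(d / "snps_info.tsv", sep="\t", index=False)
        t.depth.to_csv(d / "snps_depth.tsv", sep="\t")
        t.alt.to_csv(d / "snps_alt_count.tsv", sep="\t")
    if manifest is not None:
        with open(root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# coverage filters


@dataclass
class FilterReport:
    """Per (species, sample) pass/fail decisions with their statistics.

    ``frame`` columns: species_id, sample_id, mean_depth, breadth,
    passed (bool), reasons (comma-joined; empty when passed). The recorded
    statistics are sufficient to reproduce each decision.
    """

    frame: pd.DataFrame
    min_mean_depth: float
    min_breadth: float
    coding_only: bool

    def passing_samples(self, species_id: str) -> list[str]:
        f = self.frame
        sel = (f["species_id"] == species_id) & f["passed"]
        return list(f.loc[sel, "sample_id"])


def sample_species_filter(
    table: SNVTable,
    min_mean_depth: float = 5.0,
    min_breadth: float = 0.40,
) -> FilterReport:
    """Keep a (species, sample) only when the species is adequately covered.

    A pair passes iff mean depth over protein-coding sites >= ``min_mean_depth``
    (default 5x) and the fraction of sites with nonzero coverage is
    >= ``min_breadth`` (default 40%).
    """
    coding = table.coding_mask()
    coding_only = bool(coding.all())
    depth_cod = table.depth.loc[coding.to_numpy()]
    mean_depth = depth_cod.mean(axis=0)
    breadth = (table.depth > 0).mean(axis=0)
    rows = []
    for s in table.samples:
        reasons = []
        if mean_depth[s] < min_mean_depth:
            reasons.append("mean_depth")
        if breadth[s] < min_breadth:
            reasons.append("breadth")
        rows.append(
            {
                "species_id": table.species_id,
                "sample_id": s,
                "mean_depth": float(mean_depth[s]),
                "breadth": float(breadth[s]),
                "passed": not reasons,
                "reasons": ",".join(reasons),
            }
        )
    return FilterReport(
        pd.DataFrame(rows), min_mean_depth, min_breadth, coding_only
    )


def site_band_filter(
    table: SNVTable, sample: str, lower: float = 0.3, upper: float = 3.0
) -> pd.Series:
    """Mask of sites whose depth lies within [0.3x, 3x] of the sample mean.

    Sites far outside the sample's typical coverage are likely read-mapping
    artifacts. The mean is taken over all sites of the species in this
    sample; the band is closed at both ends.
    """
    d = table.depth[sample].astype(float)
    mean_d = d.mean()
    return (d >= lower * mean_d) & (d <= upper * mean_d)


def downsample_depths(
    table: SNVTable,
    target_samples: list[str],
    reference_samples: list[str],
    seed: int,
) -> SNVTable:
    """Per-site binomial/hypergeometric thinning of deep samples.

    For each site, the per-site target depth is the median depth of the
    reference samples at that site; target cells above it keep a uniform
    random subset of reads (alt reads drawn hypergeometrically, i.e. reads
    sampled without replacement). Cells at or below the target, and sites
    where the reference median is 0, are untouched. Deterministic per seed.
    """
    target_samples = list(target_samples)
    reference_samples = list(reference_samples)
    if not target_samples or not reference_samples:
        raise ValueError("target and reference sample sets must be nonempty")
    if set(target_samples) & set(reference_samples):
        raise ValueError("target and reference sample sets must be disjoint")
    rng = np.random.default_rng(seed)
    out = table.copy()
    ref_median = (
        table.depth[reference_samples].median(axis=1).round().astype(int)
    )
    tgt = np.maximum(ref_median.to_numpy(), 0)
    for s in target_samples:
        d = out.depth[s].to_numpy()
        a = out.alt[s].to_numpy()
        thin = (d > tgt) & (tgt > 0)
        if not thin.any():
            continue
        # reads kept without replacement: alt ~ Hypergeom(D, alt, target)
        new_alt = rng.hypergeometric(a[thin], d[thin] - a[thin], tgt[thin])
        d = d.copy()
        a = a.copy()
        a[thin] = new_alt
        d[thin] = tgt[thin]
        out.depth[s] = d
        out.alt[s] = a
    out.validate()
    return out
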