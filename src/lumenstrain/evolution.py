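"""Quasi-phasing and detection of extreme SNV frequency changes.

A (species, sample) is quasi-phaseable (QP) when one strain dominates at
frequency >= 0.8: its genotype can then be read off from high-frequency
alleles at well-covered loci. Operationally a sample is QP when its median
site depth is >= 20 and the number of intermediate-frequency SNVs
(0.2 < f < 0.8 at depth >= 20) is at most 10% of the SNV differences
typically observed for that species between unrelated hosts (a per-species
calibration scale).

Between two QP samples, an extreme SNV frequency change — the putative
signature of a selective sweep — is an allele at f <= 0.2 in one sample and
f >= 0.8 in the other, at loci with depth >= 20 in both (and, for pairs from
the same mouse, per-site depths within a factor of three). Pairs with more
than 50 such differences are read as carrying distinct inoculum strains and
excluded from the evolutionary analysis. Rates of change per category
(within host, between hosts, inoculum vs host) are compared with a
pair-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lumenstrain.io import SNVTable, SampleMeta, site_band_filter
from lumenstrain.simulate import GroundTruth

CATEGORIES = ("within_host", "between_host", "inoculum_vs_host")


@dataclass
class QPCall:
    """Quasi-phaseability verdict for one (species, sample)."""

    species_id: str
    sample_id: str
    is_qp: bool
    median_depth: float
    n_intermediate: int
    threshold: float
    genotype: pd.Series | None = None  # site_id -> 0 (ref) / 1 (alt)
    reason: str = ""


def calibrate_qp_threshold_from_truth(truth: GroundTruth) -> dict[str, float]:
    """Per-species between-host divergence scale from simulation truth.

    For synthetic runs the expected number of between-host SNV differences
    is the configured inter-strain divergence. Real-data runs must supply
    a calibration table instead (see ``load_calibration``).
    """
    return {sp: float(truth.divergence[sp]) for sp in truth.species_ids}


def load_calibration(path) -> dict[str, float]:
    """Read a species -> expected between-host SNV difference count TSV."""
    df = pd.read_csv(path, sep="\t")
    cal = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
    if any(v <= 0 for v in cal.values()):
        raise ValueError("calibration values must be positive")
    return cal


def call_qp_samples(
    table: SNVTable,
    calibration: dict[str, float],
    samples: list[str] | None = None,
    min_median_depth: float = 20.0,
    geno_min_depth: int = 20,
    intermediate: tuple = (0.2, 0.8),
    qp_fraction: float = 0.10,
    apply_band: bool = True,
) -> list[QPCall]:
    """Call QP samples and phase the dominant-lineage genotype.

    The phased genotype assigns the alternative allele where its frequency
    is >= 0.8 and the reference allele where it is <= 0.2, at loci with
    depth >= 20; it is emitted for QP samples only.
    """
    if samples is None:
        samples = table.samples
    if table.species_id not in calibration:
        return [
            QPCall(
                table.species_id, s, False, float("nan"), 0, float("nan"),
                reason="species missing from calibration",
            )
            for s in samples
        ]
    threshold = qp_fraction * calibration[table.species_id]
    lo, hi = intermediate
    calls = []
    for s in samples:
        d = table.depth[s].to_numpy(dtype=float)
        a = table.alt[s].to_numpy(dtype=float)
        band = (
            site_band_filter(table, s).to_numpy()
            if apply_band
            else np.ones(d.shape, dtype=bool)
        )
        med = float(np.median(d[band])) if band.any() else 0.0
        covered = band & (d >= geno_min_depth)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(covered, a / np.maximum(d, 1), np.nan)
        n_inter = int(np.sum(covered & (f > lo) & (f < hi)))
        is_qp = med >= min_median_depth and n_inter <= threshold
        genotype = None
        if is_qp:
            confident = covered & ((f >= hi) | (f <= lo))
            genotype = pd.Series(
                (f[confident] >= hi).astype(np.int8),
                index=table.sites.index[confident],
            )
        calls.append(
            QPCall(
                table.species_id, s, is_qp, med, n_inter, threshold, genotype
            )
        )
    return calls


# ---------------------------------------------------------------------------
# pairwise change detection


@dataclass(frozen=True)
class SNVChange:
    species_id: str
    site_id: str
    sample_a: str
    sample_b: str
    freq_a: float
    freq_b: float
    depth_a: int
    depth_b: int
    category: str
    site_type: str


@dataclass
class PairResult:
    """All candidate loci and detected changes for one QP sample pair."""

    species_id: str
    sample_a: str
    sample_b: str
    category: str  # mutually exclusive primary category
    same_cage: bool
    n_loci: int  # high-coverage loci (the rate denominator)
    changes: list[SNVChange] = field(default_factory=list)
    excluded: bool = False  # > max_pair_diffs changes: distinct strains

    @property
    def n_changes(self) -> int:
        return len(self.changes)


def pair_category(a: SampleMeta, b: SampleMeta) -> tuple[str, bool]:
    """(primary category, same_cage) for a sample pair.

    Categories are mutually exclusive: inoculum_vs_host when either member
    is the inoculum, within_host for same-mouse pairs, between_host
    otherwise. ``same_cage`` marks the different-host same-cage subset used
    by the within-cage rate comparison.
    """
    if a.sample_id == b.sample_id:
        raise ValueError("self-pairs are not comparable")
    if a.is_inoculum or b.is_inoculum:
        return "inoculum_vs_host", False
    if a.mouse_id == b.mouse_id:
        return "within_host", False
    return "between_host", a.cage_id == b.cage_id


def detect_snv_changes(
    table: SNVTable,
    call_a: QPCall,
    call_b: QPCall,
    meta_a: SampleMeta,
    meta_b: SampleMeta,
    min_depth: int = 20,
    bounds: tuple = (0.2, 0.8),
    max_depth_ratio: float = 3.0,
    ratio_within_mouse_only: bool = True,
    max_pair_diffs: int = 50,
) -> PairResult:
    """Extreme allele-frequency changes between two QP samples.

    Candidate loci need depth >= 20 in both samples; same-mouse pairs
    additionally require the two depths to agree within a factor of three
    (coverage should be nearly constant within a mouse, so a large ratio
    flags a mapping artifact). A change is an allele (tracked consistently
    as the alternative allele in both samples, so detection is symmetric)
    with f <= 0.2 in one sample and f >= 0.8 in the other. Pairs with more
    than ``max_pair_diffs`` changes are flagged ``excluded``: the two
    samples carry distinct inoculum strains, not within-lineage evolution.
    """
    if not (call_a.is_qp and call_b.is_qp):
        raise ValueError("both samples must be QP for change detection")
    a_id, b_id = call_a.sample_id, call_b.sample_id
    category, same_cage = pair_category(meta_a, meta_b)
    da = table.depth[a_id].to_numpy(dtype=float)
    db = table.depth[b_id].to_numpy(dtype=float)
    ok = (da >= min_depth) & (db >= min_depth)
    same_mouse = category == "within_host"
    if same_mouse or not ratio_within_mouse_only:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.maximum(da, db) / np.minimum(da, db)
        ok &= ratio <= max_depth_ratio
    lo, hi = bounds
    fa = table.alt[a_id].to_numpy(dtype=float) / np.maximum(da, 1)
    fb = table.alt[b_id].to_numpy(dtype=float) / np.maximum(db, 1)
    is_change = ok & (
        ((fa <= lo) & (fb >= hi)) | ((fa >= hi) & (fb <= lo))
    )
    changes = [
        SNVChange(
            species_id=table.species_id,
            site_id=sid,
            sample_a=a_id,
            sample_b=b_id,
            freq_a=float(fa[i]),
            freq_b=float(fb[i]),
            depth_a=int(da[i]),
            depth_b=int(db[i]),
            category=category,
            site_type=str(table.sites["site_type"].iloc[i]),
        )
        for i, sid in zip(np.flatnonzero(is_change), table.sites.index[is_change])
    ]
    return PairResult(
        species_id=table.species_id,
        sample_a=a_id,
        sample_b=b_id,
        category=category,
        same_cage=same_cage,
        n_loci=int(ok.sum()),
        changes=changes,
        excluded=len(changes) > max_pair_diffs,
    )


def detect_all_changes(
    table: SNVTable,
    calls: list[QPCall],
    samples: list[SampleMeta],
    **kwargs,
) -> list[PairResult]:
    """Change detection over all unordered QP sample pairs of a species."""
    meta = {s.sample_id: s for s in samples}
    qp = [c for c in calls if c.is_qp]
    out = []
    for i in range(len(qp)):
        for j in range(i + 1, len(qp)):
            out.append(
                detect_snv_changes(
                    table, qp[i], qp[j],
                    meta[qp[i].sample_id], meta[qp[j].sample_id],
                    **kwargs,
                )
            )
    return out


# ---------------------------------------------------------------------------
# unique changes, parallelism, standing variation


def summarize_unique_changes(
    pair_results: list[PairResult],
    tables: dict[str, SNVTable],
    samples: list[SampleMeta],
    inoculum_sample: str = "inoculum",
    min_inoculum_depth: int = 20,
    sweep_freq: float = 0.8,
) -> pd.DataFrame:
    """Deduplicate changes by (species, site) and annotate each one.

    Standing genetic variation (SGV): the allele had nonzero frequency in
    the inoculum at depth >= 20 ("unknown" below that depth). Parallelism:
    the allele reaches f >= 0.8 in mice from >= 2 distinct cages. The
    maximal observed frequency contrast is retained for reporting.
    """
    meta = {s.sample_id: s for s in samples}
    records: dict[tuple, dict] = {}
    for pr in pair_results:
        if pr.excluded:
            continue
        for ch in pr.changes:
            key = (ch.species_id, ch.site_id)
            contrast = abs(ch.freq_a - ch.freq_b)
            rec = records.get(key)
            if rec is None:
                rec = {
                    "species_id": ch.species_id,
                    "site_id": ch.site_id,
                    "site_type": ch.site_type,
                    "max_contrast": contrast,
                    "categories": set(),
                    "high_cages": set(),
                }
                records[key] = rec
            rec["max_contrast"] = max(rec["max_contrast"], contrast)
            rec["categories"].add(ch.category)
            for sid, f in ((ch.sample_a, ch.freq_a), (ch.sample_b, ch.freq_b)):
                m = meta[sid]
                if f >= sweep_freq and not m.is_inoculum:
                    rec["high_cages"].add(m.cage_id)
    rows = []
    for (sp, site), rec in sorted(records.items()):
        table = tables[sp]
        sgv = "unknown"
        inoc_f = float("nan")
        inoc_d = 0
        if inoculum_sample in table.samples and site in table.depth.index:
            inoc_d = int(table.depth.at[site, inoculum_sample])
            if inoc_d >= min_inoculum_depth:
                inoc_f = float(table.alt.at[site, inoculum_sample]) / inoc_d
                sgv = "true" if inoc_f > 0 else "false"
        n_cages = len(rec["high_cages"])
        rows.append(
            {
                "species_id": sp,
                "site_id": site,
                "site_type": rec["site_type"],
                "max_contrast": rec["max_contrast"],
                "categories": ",".join(sorted(rec["categories"])),
                "inoculum_freq": inoc_f,
                "inoculum_depth": inoc_d,
                "sgv": sgv,
                "parallel_cage_count": n_cages,
                "parallel": n_cages >= 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "site_id", "site_type", "max_contrast",
            "categories", "inoculum_freq", "inoculum_depth", "sgv",
            "parallel_cage_count", "parallel",
        ],
    )


# ---------------------------------------------------------------------------
# rate bootstrap


@dataclass
class RateEstimate:
    """Rate of extreme SNV changes per high-coverage locus, with 95% CI."""

    category: str
    rate: float
    ci_lo: float
    ci_hi: float
    total_changes: int
    total_loci: int
    n_pairs: int


def bootstrap_change_rates(
    pair_results: list[PairResult],
    n_boot: int = 1000,
    pairs_per_draw: int = 100,
    seed: int = 0,
    include_within_cage: bool = True,
) -> dict[str, RateEstimate]:
    """Per-category change rates with pair-resampling bootstrap CIs.

    The rate is total changes / total high-coverage loci pooled over pairs
    (pairs may mix species). Each bootstrap draw resamples
    ``pairs_per_draw`` pairs with replacement and recomputes the pooled
    ratio; the CI is the 2.5/97.5 percentile. The within-cage category uses
    only different-host, same-cage pairs. Empty categories are omitted.
    """
    rng = np.random.default_rng(seed)
    eligible = [p for p in pair_results if not p.excluded]
    groups: dict[str, list[PairResult]] = {c: [] for c in CATEGORIES}
    for p in eligible:
        groups[p.category].append(p)
    if include_within_cage:
        groups["within_cage_between_host"] = [
            p for p in eligible
            if p.category == "between_host" and p.same_cage
        ]
    out = {}
    for cat, pairs in groups.items():
        if not pairs:
            continue
        ch = np.array([p.n_changes for p in pairs], dtype=float)
        loci = np.array([p.n_loci for p in pairs], dtype=float)
        total_loci = loci.sum()
        if total_loci == 0:
            continue
        rate = ch.sum() / total_loci
        idx = rng.integers(0, len(pairs), size=(n_boot, pairs_per_draw))
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = ch[idx].sum(axis=1) / loci[idx].sum(axis=1)
        boot = boot[np.isfinite(boot)]
        lo, hi = np.percentile(boot, [2.5, 97.5])
        out[cat] = RateEstimate(
            category=cat,
            rate=float(rate),
            ci_lo=float(lo),
            ci_hi=float(hi),
            total_changes=int(ch.sum()),
            total_loci=int(total_loci),
            n_pairs=len(pairs),
        )
    return out
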