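"""End-to-end orchestration: simulate -> filters -> diversity -> phasing ->
evolution, with one config, seeded reproducibility, and TSV/JSON outputs.

Every threshold lives in :class:`RunConfig` (defaulting to the values used
for genome-scale data) because the absolute constants — 500,000 usable sites
for pi, 10^3-SNV clusters — must scale down for desk-size fixtures. The
config is serialised, with a hash, into every run's manifest and into a
header comment of every output table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from lumenstrain import diversity as div
from lumenstrain import evolution as evo
from lumenstrain import strains as st
from lumenstrain import io as lio
from lumenstrain import simulate as sim
from lumenstrain import __version__


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run."""

    # input: either a fixture tree on disk or a named synthetic scenario
    input_path: str | None = None
    scenario: str | None = None
    seed: int = 0
    out_dir: str = "run_out"
    # stage toggles
    run_diversity: bool = True
    run_phasing: bool = True
    run_evolution: bool = True
    # sample/site coverage filters
    min_mean_depth: float = 5.0
    min_breadth: float = 0.40
    band_lower: float = 0.3
    band_upper: float = 3.0
    downsample_batch: str | None = None
    # nucleotide diversity
    pi_min_site_depth: int = 4
    min_pi_sites: int = 500_000
    # phasing
    phasing_min_depth: int = 10
    min_minor_reads: int = 4
    min_polymorphic_frac: float = 0.2
    d_max: float = 3.5
    min_cluster: int = 1000
    intra_connect: float = 0.25
    min_overlap: int = 3
    min_support: int = 100
    inoculum_min_snvs: int = 1000
    # quasi-phasing / change detection
    qp_fraction: float = 0.10
    qp_min_median_depth: float = 20.0
    change_min_depth: int = 20
    change_bounds: tuple = (0.2, 0.8)
    max_depth_ratio: float = 3.0
    max_pair_diffs: int = 50
    calibration_path: str | None = None
    # bootstraps
    n_boot: int = 1000
    boot_block: int = 100
    boot_pairs: int = 100

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError("specify exactly one of input_path or scenario")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "change_bounds" in data:
            data["change_bounds"] = tuple(data["change_bounds"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["change_bounds"] = list(d["change_bounds"])
        return d

    def config_hash(self) -> str:
        payload = {
            k: v
            for k, v in sorted(self.to_dict().items())
            if k not in ("out_dir",)
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# lumenstrain {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, msg: str) -> None:
        self.lines.append(msg)
        with open(self.path, "a") as fh:
            fh.write(msg + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the run directory.

    A failing stage leaves the outputs of prior stages intact and writes an
    ``error_report.json`` before re-raising.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    cfg_hash = config.config_hash()
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": cfg_hash,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    try:
        truth = None
        if config.scenario is not None:
            truth, tables, abundance, scn_manifest = sim.build_scenario(
                config.scenario, config.seed
            )
            samples = truth.samples
            log.write(f"simulate: scenario={config.scenario} seed={config.seed}")
            with open(out / "scenario_manifest.json", "w") as fh:
                json.dump(scn_manifest, fh, indent=2, sort_keys=True)
        else:
            tables, abundance, samples = lio.load_dataset(config.input_path)
            log.write(f"load: {config.input_path}")
        log.write(
            f"input: {len(tables)} species, {len(samples)} samples"
        )

        # --- coverage filters -------------------------------------------
        reports = []
        passing: dict[str, list[str]] = {}
        for sp, t in tables.items():
            rep = lio.sample_species_filter(
                t, config.min_mean_depth, config.min_breadth
            )
            reports.append(rep.frame)
            passing[sp] = rep.passing_samples(sp)
        filter_frame = pd.concat(reports, ignore_index=True)
        _write_tsv(filter_frame, out / "filter_report.tsv", cfg_hash)
        log.write(
            "filters: "
            + ", ".join(f"{sp}:{len(v)}" for sp, v in passing.items())
        )

        if config.downsample_batch is not None:
            meta = lio.meta_frame(samples)
            deep = list(meta.index[meta["batch"] == config.downsample_batch])
            ref = list(meta.index[meta["batch"] != config.downsample_batch])
            if deep and ref:
                for sp in tables:
                    tables[sp] = lio.downsample_depths(
                        tables[sp], deep, ref, seed=config.seed
                    )
                log.write(f"downsample: thinned {len(deep)} deep samples")

        if config.run_diversity:
            _stage_diversity(
                config, tables, abundance, samples, passing, out, cfg_hash, log
            )
        if config.run_phasing:
            _stage_phasing(config, tables, samples, passing, out, cfg_hash, log)
        if config.run_evolution:
            _stage_evolution(
                config, tables, samples, passing, truth, out, cfg_hash, log
            )
    except Exception as exc:  # keep prior outputs, report, re-raise
        with open(out / "error_report.json", "w") as fh:
            json.dump(
                {"error": str(exc), "traceback": traceback.format_exc()},
                fh,
                indent=2,
            )
        raise
    return out


def _stage_diversity(config, tables, abundance, samples, passing, out, cfg_hash, log):
    alpha = pd.DataFrame(
        {
            "sample_id": abundance.columns,
            "shannon": [
                div.shannon_index(abundance[c].to_numpy())
                for c in abundance.columns
            ],
        }
    )
    _write_tsv(alpha, out / "alpha_diversity.tsv", cfg_hash)
    contrasts = []
    try:
        rc = div.region_contrast(
            alpha.set_index("sample_id")["shannon"], samples, label="shannon"
        )
        contrasts.append(
            {
                "label": rc.label,
                "fold_change": rc.fold_change,
                "p_value": rc.p_value,
                "n_mice": rc.n_mice,
            }
        )
    except ValueError as exc:
        log.write(f"diversity: region contrast skipped ({exc})")
    _write_tsv(pd.DataFrame(contrasts), out / "region_contrasts.tsv", cfg_hash)

    pi_results = []
    for sp, t in tables.items():
        for s in passing[sp]:
            pi_results.append(
                div.nucleotide_diversity(t, s, config.pi_min_site_depth)
            )
    _write_tsv(div.pi_frame(pi_results), out / "pi_per_sample.tsv", cfg_hash)
    _write_tsv(
        div.pi_variance_partition(pi_results, samples),
        out / "pi_variance.tsv",
        cfg_hash,
    )
    included = div.pi_species_inclusion(pi_results, samples, config.min_pi_sites)
    log.write(f"diversity: {len(pi_results)} pi values, {len(included)} species included")


def _stage_phasing(config, tables, samples, passing, out, cfg_hash, log):
    freq_rows, cluster_rows, var_rows = [], [], []
    for sp, t in tables.items():
        if not passing[sp]:
            continue
        sites = st.filter_phasing_sites(
            t,
            passing[sp],
            config.phasing_min_depth,
            config.min_minor_reads,
            config.min_polymorphic_frac,
        )
        clusters = st.infer_strain_clusters(
            sites,
            d_max=config.d_max,
            min_cluster=config.min_cluster,
            intra_connect=config.intra_connect,
            min_depth=config.phasing_min_depth,
            min_overlap=config.min_overlap,
        )
        log.write(
            f"phase {sp}: {len(sites.site_ids)} sites -> "
            f"{clusters.n_clusters} clusters"
        )
        for ci, cl in enumerate(clusters.clusters):
            for sid in cl.site_ids:
                cluster_rows.append(
                    {
                        "species_id": sp,
                        "cluster_index": ci,
                        "site_id": sid,
                        "polarity": int(cl.polarity[sid]),
                    }
                )
        if clusters.n_clusters == 0 and "inoculum" in t.samples:
            profile = st.infer_inoculum_only_strains(
                t,
                "inoculum",
                min_snvs=config.inoculum_min_snvs,
                min_depth=config.phasing_min_depth,
                min_minor_reads=config.min_minor_reads,
                n_boot=config.n_boot,
                block=config.boot_block,
                seed=config.seed,
            )
        else:
            profile = st.estimate_strain_frequencies(
                clusters,
                sites,
                min_depth=config.phasing_min_depth,
                min_support=config.min_support,
                n_boot=config.n_boot,
                block=config.boot_block,
                seed=config.seed,
            )
        pf = profile.frame.copy()
        pf.insert(0, "species_id", sp)
        pf["source"] = profile.source
        freq_rows.append(pf)
        if clusters.n_clusters == 1:
            major = (
                pf[pf["strain_index"] == 0]
                .set_index("sample_id")["freq"]
            )
            inoc = major.get("inoculum", 0.5)
            if inoc < 0.5:  # major strain = the one above 0.5 in the inoculum
                major = 1.0 - major
            vp = st.partition_strain_variance(major, samples)
            row = {"species_id": sp, "n_samples": vp.n_samples}
            if vp.degenerate:
                row.update(status="skipped", reason=vp.reason)
            else:
                row.update(status="ok", **vp.fractions)
            var_rows.append(row)
    freq_frame = (
        pd.concat(freq_rows, ignore_index=True) if freq_rows else pd.DataFrame()
    )
    _write_tsv(freq_frame, out / "strain_frequencies.tsv", cfg_hash)
    _write_tsv(pd.DataFrame(cluster_rows), out / "clusters.tsv", cfg_hash)
    _write_tsv(pd.DataFrame(var_rows), out / "variance_partition.tsv", cfg_hash)


def _stage_evolution(config, tables, samples, passing, truth, out, cfg_hash, log):
    if truth is not None:
        calibration = evo.calibrate_qp_threshold_from_truth(truth)
    elif config.calibration_path is not None:
        calibration = evo.load_calibration(config.calibration_path)
    else:
        raise ValueError(
            "real-data runs need calibration_path: a TSV of species_id -> "
            "expected between-host SNV differences"
        )
    qp_rows, pair_rows, all_pairs = [], [], []
    for sp, t in tables.items():
        calls = evo.call_qp_samples(
            t,
            calibration,
            samples=passing[sp],
            min_median_depth=config.qp_min_median_depth,
            geno_min_depth=config.change_min_depth,
            intermediate=config.change_bounds,
            qp_fraction=config.qp_fraction,
        )
        for c in calls:
            qp_rows.append(
                {
                    "species_id": sp,
                    "sample_id": c.sample_id,
                    "is_qp": c.is_qp,
                    "median_depth": c.median_depth,
                    "n_intermediate": c.n_intermediate,
                    "threshold": c.threshold,
                    "reason": c.reason,
                }
            )
        pairs = evo.detect_all_changes(
            t,
            calls,
            samples,
            min_depth=config.change_min_depth,
            bounds=config.change_bounds,
            max_depth_ratio=config.max_depth_ratio,
            max_pair_diffs=config.max_pair_diffs,
        )
        all_pairs.extend(pairs)
        for p in pairs:
            for ch in p.changes:
                pair_rows.append(dataclasses.asdict(ch))
        log.write(
            f"evolve {sp}: {sum(c.is_qp for c in calls)} QP samples, "
            f"{len(pairs)} pairs, "
            f"{sum(p.n_changes for p in pairs if not p.excluded)} changes"
        )
    _write_tsv(pd.DataFrame(qp_rows), out / "qp_calls.tsv", cfg_hash)
    _write_tsv(pd.DataFrame(pair_rows), out / "snv_changes.tsv", cfg_hash)
    unique = evo.summarize_unique_changes(all_pairs, tables, samples)
    _write_tsv(unique, out / "unique_changes.tsv", cfg_hash)
    rates = evo.bootstrap_change_rates(
        all_pairs,
        n_boot=config.n_boot,
        pairs_per_draw=config.boot_pairs,
        seed=config.seed,
    )
    rate_frame = pd.DataFrame(
        [dataclasses.asdict(r) for r in rates.values()]
    )
    _write_tsv(rate_frame, out / "change_rates.tsv", cfg_hash)
    with open(out / "evolution_summary.json", "w") as fh:
        json.dump(
            {
                "n_unique_changes": int(len(unique)),
                "rates": {
                    c: {"rate": r.rate, "ci": [r.ci_lo, r.ci_hi]}
                    for c, r in rates.items()
                },
            },
            fh,
            indent=2,
        )
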