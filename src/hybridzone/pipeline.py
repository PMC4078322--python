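"""End-to-end pipeline: simulate -> type -> QC -> admixture -> clines -> dates.

Stage order mirrors the analysis workflow: mtDNA restriction typing and
genotype QC come first, admixture Q-scores feed the nuclear cline, both
clines are fitted with the same machinery, widths are compared by the
reciprocal-CI rule, and each width is converted to a time-since-contact
range under neutral diffusion with the marker-appropriate dispersal.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .admixture import AdmixtureConfig, fit_admixture, site_mean_q
from .clines import ClineFit, TransectSites, ci_2ll, compare_clines, fit_mh, model_select
from .containers import GenotypeTable
from .dating import AVERAGED_DISPERSAL, DispersalSpec, FEMALE_DISPERSAL, contact_range, ranges_overlap
from .qc import flag_loci, hwe_scan
from .rflp import DEFAULT_MOTIF, site_haplotype_counts, type_fasta
from .simulate import SyntheticDataset, ZoneConfig, simulate_sequences, simulate_zone

STAGES = ("simulate", "type_mtdna", "qc", "admixture", "cline_fit",
          "compare", "date_contact", "phenotype")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every stochastic stage is seeded."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    out_dir: str | Path | None = None
    zone: ZoneConfig | None = None
    # admixture settings (desk-scale defaults)
    admix_burn_in: int = 500
    admix_n_iter: int = 2_000
    admix_alpha: float = 0.1
    # cline-fit settings
    tuning_iters: int = 3_000
    chain_iters: int = 10_000
    n_chains: int = 3
    run_model_selection: bool = False
    # QC settings
    qc_permutations: int = 999
    max_failing_populations: int = 5
    digest_motif: str = DEFAULT_MOTIF

    def resolved_zone(self) -> ZoneConfig:
        return self.zone if self.zone is not None else ZoneConfig(seed=self.seed)

    def config_hash(self) -> str:
        zone = self.resolved_zone().to_dict()
        body = {k: v for k, v in asdict(self).items() if k not in ("zone", "out_dir")}
        body["zone"] = zone
        return hashlib.sha256(json.dumps(body, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def _require(results: dict, key: str, stage: str) -> None:
    if key not in results:
        raise PipelineError(
            f"stage {stage!r} needs upstream output {key!r}; "
            f"include the producing stage in the run")


def _orient_interior_cluster(q: np.ndarray, site_labels: np.ndarray,
                             sites: TransectSites) -> int:
    """Pick the cluster whose mean Q increases with transect distance."""
    per_site = site_mean_q(q, site_labels, focal_cluster=1,
                           site_order=list(sites.site_id))
    dist = sites.to_frame().set_index("site_id").loc[per_site["site"], "distance"]
    slope = np.corrcoef(dist, per_site["mean_q"])[0, 1]
    return 1 if slope >= 0 else 0


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; returns a result dict.

    If ``config.out_dir`` is set, a fresh run directory (never overwriting)
    receives per-stage tables and a consolidated JSON report carrying the
    config hash and seed.
    """
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    results: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    stages = [s for s in STAGES if s in config.stages]  # dependency order

    dataset: SyntheticDataset | None = None
    for stage in stages:
        if stage == "simulate":
            dataset = simulate_zone(config.resolved_zone())
            dataset = simulate_sequences(dataset, motif=config.digest_motif)
            results["dataset"] = dataset

        elif stage == "type_mtdna":
            _require(results, "dataset", stage)
            ds = results["dataset"]
            calls = type_fasta(ds.sequences, motif=config.digest_motif)
            counts = site_haplotype_counts(calls["call"], ds.site_labels)
            results["mt_calls"] = calls
            results["mt_site_counts"] = counts

        elif stage == "qc":
            _require(results, "dataset", stage)
            geno: GenotypeTable = results["dataset"].genotypes
            report = hwe_scan(geno, n_permutations=config.qc_permutations,
                              seed=config.seed + 11)
            flags = flag_loci(report, config.max_failing_populations)
            results["qc_report"] = report
            results["qc_flags"] = flags
            if flags["dropped"]:
                results["dataset"].genotypes = geno.drop_loci(flags["dropped"])

        elif stage == "admixture":
            _require(results, "dataset", stage)
            ds = results["dataset"]
            cfg = AdmixtureConfig(K=2, alpha=config.admix_alpha,
                                  burn_in=config.admix_burn_in,
                                  n_iter=config.admix_n_iter,
                                  seed=config.seed + 23)
            fit = fit_admixture(ds.genotypes, cfg)
            focal = _orient_interior_cluster(fit.q, ds.site_labels, ds.sites)
            per_site = site_mean_q(fit.q, ds.site_labels, focal_cluster=focal,
                                   site_order=list(ds.sites.site_id))
            results["admixture_fit"] = fit
            results["focal_cluster"] = focal
            results["q_site_means"] = per_site

        elif stage == "cline_fit":
            _require(results, "dataset", stage)
            ds = results["dataset"]
            sites_mt = ds.sites
            if "mt_site_counts" in results:
                counts = results["mt_site_counts"].set_index("site")
                k = counts.loc[sites_mt.site_id, "k_interior"].to_numpy()
                sites_mt = TransectSites(
                    site_id=sites_mt.site_id, latitude=sites_mt.latitude,
                    longitude=sites_mt.longitude, distance=sites_mt.distance,
                    n=counts.loc[sites_mt.site_id, "n"].to_numpy(), k_interior=k)
            mean_q = None
            if "q_site_means" in results:
                per_site = results["q_site_means"].set_index("site")
                mean_q = per_site.loc[ds.sites.site_id, "mean_q"].to_numpy()
            else:
                raise PipelineError(
                    "stage 'cline_fit' needs Q-scores for the nuclear cline; "
                    "include the 'admixture' stage in the run")
            sites_q = TransectSites(
                site_id=ds.sites.site_id, latitude=ds.sites.latitude,
                longitude=ds.sites.longitude, distance=ds.sites.distance,
                n=ds.sites.n, mean_q=mean_q)

            kw = dict(tuning_iters=config.tuning_iters,
                      chain_iters=config.chain_iters, n_chains=config.n_chains,
                      check_convergence=False)
            if config.run_model_selection:
                sel_mt = model_select(sites_mt, "mt_frequency", seed=config.seed + 31, **kw)
                sel_q = model_select(sites_q, "q_mean", seed=config.seed + 47, **kw)
                results["model_selection_mt"] = sel_mt
                results["model_selection_q"] = sel_q
                fit_mt = sel_mt.best_fit("preferred")
                fit_q = sel_q.best_fit("preferred")
                if fit_mt is None or fit_q is None:
                    raise PipelineError("null model preferred; no cline to compare")
            else:
                fit_mt = fit_mh(sites_mt, ("none", "fixed_none"), "mt_frequency",
                                seed=config.seed + 31, **kw)
                fit_q = fit_mh(sites_q, ("none", "fixed_none"), "q_mean",
                               seed=config.seed + 47, **kw)
            results["cline_fit_mt"] = fit_mt
            results["cline_fit_q"] = fit_q

        elif stage == "compare":
            _require(results, "cline_fit_mt", stage)
            _require(results, "cline_fit_q", stage)
            comparison = compare_clines(results["cline_fit_mt"],
                                        results["cline_fit_q"], "w")
            results["width_comparison"] = comparison

        elif stage == "date_contact":
            _require(results, "cline_fit_mt", stage)
            _require(results, "cline_fit_q", stage)
            w_mt = results["cline_fit_mt"].point_estimate.w
            w_q = results["cline_fit_q"].point_estimate.w
            female = DispersalSpec(*FEMALE_DISPERSAL, label="female")
            averaged = DispersalSpec(*AVERAGED_DISPERSAL, label="male/female average")
            range_mt = contact_range(w_mt, female, variant="formula")
            range_q = contact_range(w_q, averaged, variant="formula")
            results["contact_mt"] = range_mt
            results["contact_q"] = range_q
            results["contact_ranges_overlap"] = ranges_overlap(range_mt, range_q)

        elif stage == "phenotype":
            _require(results, "dataset", stage)
            from .phenotype import association_report

            ds = results["dataset"]
            pheno = ds.phenotypes.copy()
            if "admixture_fit" in results:
                focal = results["focal_cluster"]
                pheno["q_score"] = results["admixture_fit"].q[:, focal]
            results["phenotype_report"] = association_report(pheno)

    results["summary"] = _summarise(results)
    if config.out_dir is not None:
        results["run_dir"] = str(_write_run_dir(config, results))
    return results


def _summarise(results: dict) -> dict:
    summary: dict = {}
    if "cline_fit_mt" in results:
        fit: ClineFit = results["cline_fit_mt"]
        summary["w_mt"] = fit.point_estimate.w
        summary["c_mt"] = fit.point_estimate.c
        summary["w_mt_ci"] = list(ci_2ll(fit, "w"))
    if "cline_fit_q" in results:
        fit = results["cline_fit_q"]
        summary["w_nuc"] = fit.point_estimate.w
        summary["c_nuc"] = fit.point_estimate.c
        summary["w_nuc_ci"] = list(ci_2ll(fit, "w"))
    if "width_comparison" in results:
        summary["mt_narrower_than_nuclear"] = bool(
            summary.get("w_mt", np.inf) < summary.get("w_nuc", -np.inf))
        summary["widths_significantly_different"] = bool(
            results["width_comparison"]["significantly_different"])
    if "contact_mt" in results:
        summary["contact_mt_years"] = [results["contact_mt"]["t_min_2sf"],
                                       results["contact_mt"]["t_max_2sf"]]
        summary["contact_nuc_years"] = [results["contact_q"]["t_min_2sf"],
                                        results["contact_q"]["t_max_2sf"]]
        summary["contact_ranges_overlap"] = bool(results["contact_ranges_overlap"])
    if "qc_flags" in results:
        summary["loci_retained"] = len(results["qc_flags"]["retained"])
        summary["loci_dropped"] = results["qc_flags"]["dropped"]
    return summary


def _fresh_dir(base: Path) -> Path:
    base.parent.mkdir(parents=True, exist_ok=True)
    candidate, i = base, 1
    while candidate.exists():
        candidate = base.with_name(f"{base.name}.{i}")
        i += 1
    candidate.mkdir()
    return candidate


def _write_run_dir(config: RunConfig, results: dict) -> Path:
    run_dir = _fresh_dir(Path(config.out_dir) / f"run-seed{config.seed}")
    if "dataset" in results:
        ds: SyntheticDataset = results["dataset"]
        hio.write_genotypes(ds.genotypes, run_dir / "genotypes.str")
        hio.write_sites(ds.sites, run_dir / "sites.tsv")
        hio.write_phenotypes(ds.phenotypes, run_dir / "phenotypes.tsv")
        hio.write_truth(ds.truth, run_dir / "truth.json")
        if ds.sequences:
            hio.write_fasta(ds.sequences, run_dir / "amplicons.fasta")
    if "mt_calls" in results:
        results["mt_calls"].to_csv(run_dir / "mtdna_calls.tsv", sep="\t", index=False)
        results["mt_site_counts"].to_csv(run_dir / "mtdna_site_counts.tsv",
                                         sep="\t", index=False)
    if "qc_report" in results:
        results["qc_report"].hwe_pvalues.to_csv(run_dir / "hwe_pvalues.tsv", sep="\t")
    if "admixture_fit" in results:
        results["admixture_fit"].q_frame().to_csv(run_dir / "qmatrix.tsv", sep="\t")
    for key in ("cline_fit_mt", "cline_fit_q"):
        if key in results:
            fit = results[key]
            record = {"point": fit.point, "max_ll": fit.max_ll, "aicc": fit.aicc,
                      "ci_2ll": {k: list(v) for k, v in fit.ci_2ll.items()}}
            (run_dir / f"{key}.json").write_text(json.dumps(record, indent=2))
    if "phenotype_report" in results:
        results["phenotype_report"].to_csv(run_dir / "phenotype_report.tsv", sep="\t")
    report = {"seed": config.seed, "config_hash": results["config_hash"],
              "summary": results["summary"]}
    (run_dir / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return run_dir
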