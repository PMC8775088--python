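"""Config-driven orchestration of the batch-effect analysis.

Stages (in dependency order): ``simulate`` writes a synthetic cohort
(VCF, metadata, annotations, Sprime-style table, truth record);
``count`` builds the per-individual rare-event count table; ``ca`` runs
the correspondence analysis of the population x center table; ``models``
fits the mixed-model center contrasts and the pairwise Wilcoxon tables;
``fst`` computes the per-SNV scaled-Fst records and MAF summaries per
population; ``null`` adds the Monte Carlo permutation null and the
observed-vs-null slope; ``report`` renders a summary document.

Every run writes a manifest (seeds, per-stage record counts, SHA-256
digests of every output) so that re-running the same configuration can be
verified to reproduce identical artifacts.  The filters applied on the way
(non-SNV / multiallelic / monomorphic drops, zero-count samples, centers
excluded from the equal-n design) are all recorded, since they silently
discard data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ca import contingency_table, correspondence_analysis
from .cohort import CohortSpec, generate_cohort, generate_sprime_table
from .contrasts import pairwise_wilcoxon
from .counts import build_count_table
from .fstscan import ScaledFstScan
from .io import (
    read_annotations,
    read_metadata,
    read_sprime_table,
    read_vcf,
    write_annotations,
    write_metadata,
    write_sprime_table,
    write_vcf,
)
from .mixed import fit_center_mixed_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "count", "ca", "models", "fst", "null", "report")
RESPONSES = ("n_lof", "n_benign", "n_singletons", "n_derived_singletons",
             "n_introgressed")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cohort: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # vcf/metadata/annotations/sprime
    frac_introgressed: float = 0.05
    n_per_center: int = 5
    bin_width: float = 0.05
    n_permutations: int = 100
    category: str = "maf"
    fst_populations: list[str] | None = None
    responses: tuple[str, ...] = RESPONSES
    zero_policy: str = "drop"
    wilcoxon_response: str = "n_lof"
    wilcoxon_populations: list[str] | None = None
    predictor_mapping: dict | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - names
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")


class _Run:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "stages": list(config.stages),
            "stage_info": {},
            "files": {},
        }
        self.gm = None
        self.metadata = None
        self.sprime = None
        self.counts = None

    def path(self, name: str) -> Path:
        return self.outdir / name

    def register(self, *names: str) -> None:
        for name in names:
            self.manifest["files"][name] = _sha256(self.path(name))

    # ---- input resolution -------------------------------------------------

    def _resolve(self, kind: str, default_name: str) -> Path:
        p = self.config.inputs.get(kind)
        p = Path(p) if p else self.path(default_name)
        if not p.exists():
            raise FileNotFoundError(
                f"missing upstream artifact {p} ({kind}); run the simulate "
                "stage first or point inputs.{kind} at an existing file"
            )
        return p

    def load_cohort(self) -> None:
        if self.gm is not None:
            return
        self.gm = read_vcf(str(self._resolve("vcf", "cohort.vcf")))
        self.metadata = read_metadata(str(self._resolve("metadata", "metadata.tsv")))
        ann = self.config.inputs.get("annotations")
        ann = Path(ann) if ann else self.path("annotations.tsv")
        if ann.exists():
            read_annotations(str(ann), self.gm,
                             mapping=self.config.predictor_mapping)
        sp = self.config.inputs.get("sprime")
        sp = Path(sp) if sp else self.path("sprime.tsv")
        if sp.exists():
            self.sprime = read_sprime_table(str(sp), self.gm)

    def load_counts(self) -> None:
        if self.counts is not None:
            return
        p = self._resolve("counts", "counts.tsv")
        self.counts = pd.read_csv(p, sep="\t", index_col="sample")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    run = _Run(config)
    stages = [s for s in ALL_STAGES if s in config.stages]
    for stage in stages:
        logger.info("stage %s", stage)
        globals()[f"_stage_{stage}"](run)
    _write_json(run.manifest, run.path("manifest.json"))
    return run.manifest


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    spec = CohortSpec(**{**cfg.cohort, "seed": cfg.cohort.get("seed", cfg.seed)})
    cohort = generate_cohort(spec)
    sprime = generate_sprime_table(cohort, cfg.frac_introgressed,
                                   seed=cfg.seed + 1)
    write_vcf(cohort.genotypes, run.path("cohort.vcf"))
    write_metadata(cohort.metadata, run.path("metadata.tsv"))
    write_annotations(cohort.genotypes, run.path("annotations.tsv"))
    write_sprime_table(sprime, run.path("sprime.tsv"))
    truth = cohort.truth
    _write_json(
        {
            "error_variant_idx": truth.error_variant_idx,
            "error_sample_idx": truth.error_sample_idx,
            "error_created_variants": truth.error_created_variants,
            "per_center_errors": truth.per_center_errors,
            "center_error_rates": truth.center_error_rates,
            "n_monomorphic_removed": truth.n_monomorphic_removed,
            "n_eligible_homref": truth.n_eligible_homref,
        },
        run.path("truth.json"),
    )
    run.register("cohort.vcf", "metadata.tsv", "annotations.tsv",
                 "sprime.tsv", "truth.json")
    run.manifest["stage_info"]["simulate"] = {
        "seed": cfg.seed,
        "sprime_seed": cfg.seed + 1,
        "n_samples": cohort.genotypes.n_samples,
        "n_variants": cohort.genotypes.n_variants,
        "n_monomorphic_removed": truth.n_monomorphic_removed,
        "per_center_errors": truth.per_center_errors,
    }
    run.gm, run.metadata = cohort.genotypes, cohort.metadata
    run.sprime = read_sprime_table(str(run.path("sprime.tsv")), run.gm)


def _stage_count(run: _Run) -> None:
    run.load_cohort()
    counts = build_count_table(run.gm, run.metadata, run.sprime)
    counts.to_csv(run.path("counts.tsv"), sep="\t")
    run.register("counts.tsv")
    info = {"n_samples": len(counts)}
    if run.gm.filter_log:
        info["vcf_filter"] = run.gm.filter_log
    run.manifest["stage_info"]["count"] = info
    run.counts = counts


def _stage_ca(run: _Run) -> None:
    if run.metadata is None:
        run.metadata = read_metadata(str(run._resolve("metadata", "metadata.tsv")))
    table = contingency_table(run.metadata.reset_index())
    res = correspondence_analysis(table)
    res.row_coords.to_csv(run.path("ca_row_coords.tsv"), sep="\t")
    res.col_coords.to_csv(run.path("ca_col_coords.tsv"), sep="\t")
    _write_json(
        {
            "chi2": res.chi2,
            "dof": res.dof,
            "pvalue": res.pvalue,
            "inertia": res.inertia,
            "total_inertia": res.total_inertia,
            "table": {
                "index": list(res.table.index),
                "columns": list(res.table.columns),
                "counts": np.asarray(res.table),
            },
        },
        run.path("ca.json"),
    )
    run.register("ca.json", "ca_row_coords.tsv", "ca_col_coords.tsv")
    run.manifest["stage_info"]["ca"] = {"chi2": res.chi2, "pvalue": res.pvalue}


def _stage_models(run: _Run) -> None:
    cfg = run.config
    run.load_counts()
    counts = run.counts
    results = {}
    written = []
    for response in cfg.responses:
        if (counts[response] > 0).sum() == 0:
            logger.warning("response %s is all zero; skipped", response)
            continue
        res = fit_center_mixed_model(counts, response,
                                     zero_policy=cfg.zero_policy)
        name = f"mixed_model_{response}.tsv"
        res.to_table().to_csv(run.path(name), sep="\t")
        written.append(name)
        results[response] = {
            "reference_center": res.reference_center,
            "centers_used": res.centers_used,
            "coefficients": {
                t: {"coef": r["coef"], "se": r["se"], "p": r["p"]}
                for t, r in res.coefficients.iterrows()
            },
            "vc_continent": res.vc_continent,
            "vc_population": res.vc_population,
            "lrt_stat": res.lrt_stat,
            "lrt_df": res.lrt_df,
            "lrt_p": res.lrt_p,
            "n_samples": res.n_samples,
            "n_dropped_zero": res.n_dropped_zero,
            "converged": res.converged,
        }
    _write_json(results, run.path("mixed_models.json"))
    written.append("mixed_models.json")

    pops = cfg.wilcoxon_populations or sorted(counts["pop"].unique())
    for pop in pops:
        sub = counts[counts["pop"] == pop]
        if sub["center"].nunique() < 2:
            continue
        w = pairwise_wilcoxon(counts, pop, cfg.wilcoxon_response)
        name = f"wilcoxon_{pop}_{cfg.wilcoxon_response}.tsv"
        w.to_csv(run.path(name), sep="\t")
        written.append(name)
    run.register(*written)
    run.manifest["stage_info"]["models"] = {
        "responses": sorted(results),
        "lrt_p": {r: results[r]["lrt_p"] for r in results},
    }


def _scan_populations(run: _Run):
    cfg = run.config
    run.load_cohort()
    pops = cfg.fst_populations or sorted(run.metadata["pop"].unique())
    for i, pop in enumerate(pops):
        yield i, pop


def _stage_fst(run: _Run) -> None:
    cfg = run.config
    info = {"populations": {}, "skipped": []}
    written = []
    for i, pop in _scan_populations(run):
        scan = ScaledFstScan(
            n_per_center=cfg.n_per_center,
            n_permutations=1,  # records/summaries only; null stage permutes
            bin_width=cfg.bin_width,
            category=cfg.category,
            random_state=cfg.seed + 1000 + i,
        )
        try:
            scan.fit_from_cohort(run.gm, run.metadata, pop)
        except ValueError as exc:
            info["skipped"].append({"pop": pop, "reason": str(exc)})
            continue
        for kind, df in (("records", scan.records_), ("per_maf", scan.per_maf_),
                         ("per_bin", scan.per_bin_)):
            name = f"fst_{kind}_{pop}.tsv"
            df.to_csv(run.path(name), sep="\t", index=False)
            written.append(name)
        info["populations"][pop] = {
            "seed": cfg.seed + 1000 + i,
            "centers": scan.centers_,
            "excluded_centers": scan.excluded_centers_,
            "n_snvs": len(scan.records_),
            "rho": scan.rho_,
            "rho_p": scan.rho_p_,
        }
    run.register(*written)
    run.manifest["stage_info"]["fst"] = info


def _stage_null(run: _Run) -> None:
    cfg = run.config
    info = {"populations": {}, "skipped": []}
    rows = []
    written = []
    for i, pop in _scan_populations(run):
        scan = ScaledFstScan(
            n_per_center=cfg.n_per_center,
            n_permutations=cfg.n_permutations,
            bin_width=cfg.bin_width,
            category=cfg.category,
            random_state=cfg.seed + 1000 + i,  # same design as the fst stage
        )
        try:
            scan.fit_from_cohort(run.gm, run.metadata, pop)
        except ValueError as exc:
            info["skipped"].append({"pop": pop, "reason": str(exc)})
            continue
        name = f"null_{pop}.json"
        scan.null_.to_json(run.path(name))
        written.append(name)
        rows.append((pop, scan.slope_, scan.intercept_, scan.slope_p_,
                     scan.rho_, scan.rho_p_))
        info["populations"][pop] = {"slope": scan.slope_,
                                    "slope_p": scan.slope_p_}
    slopes = pd.DataFrame(
        rows, columns=["pop", "slope", "intercept", "slope_p", "rho", "rho_p"]
    )
    slopes.to_csv(run.path("slopes.tsv"), sep="\t", index=False)
    written.append("slopes.tsv")
    run.register(*written)
    run.manifest["stage_info"]["null"] = info


def _stage_report(run: _Run) -> None:
    from .report import render_report

    files = render_report(run.outdir)
    run.register(*files)
    run.manifest["stage_info"]["report"] = {"files": files}
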