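"""End-to-end study pipeline: simulate/ingest -> QC -> A and G -> adjust ->
fit both kernels -> compare and report.

Stages run in a fixed order and leave their artifacts as text files in the
output directory; a ``state.json`` marker records which stages completed
under which configuration hash, so an interrupted run resumes where it
stopped.  Given identical configuration and seed the numeric outputs are
byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjust import AdjustedPhenotype, fit_fixed_effects
from .grm import compare_G_A, compute_G, filter_genotypes, impute_missing
from .io import (read_dosage, read_pedigree, read_phenotypes, read_vcf,
                 write_dosage, write_pedigree, write_phenotypes, write_truth)
from .model import (GibbsConfig, PriorSpec, compare_predicted_values,
                    fit_model)
from .pedigree import PedigreeTable, build_A
from .relmat import RelationshipMatrix
from .simulate import (SimulationSpec, draw_founder_frequencies, gene_drop,
                       inject_missingness, simulate_pedigree,
                       simulate_phenotype)

log = logging.getLogger("herit")

__all__ = ["RunConfig", "RunReport", "ValidationReport", "run_pipeline",
           "validate_inputs"]

STAGES = ("data", "qc", "amat", "grm", "adjust", "fit", "compare")


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run.

    Exactly one of ``simulation`` or the three input paths must be given.
    """

    outdir: str
    seed: int = 0
    traits: list[str] = field(default_factory=lambda: ["pheno"])
    simulation: SimulationSpec | None = None
    pedigree_path: str | None = None
    genotype_path: str | None = None  # .vcf or dosage .tsv
    phenotype_path: str | None = None
    min_call_rate: float = 0.90
    min_maf: float = 0.005
    covariates: list[str] = field(
        default_factory=lambda: ["sex", "age", "pc1", "pc2", "cohort"]
    )
    prior: PriorSpec = field(default_factory=PriorSpec)
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    schema_version: int = 1

    def __post_init__(self) -> None:
        paths = [self.pedigree_path, self.genotype_path, self.phenotype_path]
        have_paths = any(p is not None for p in paths)
        if (self.simulation is None) == (not have_paths):
            raise ValueError("give exactly one of: a simulation spec, or input paths")
        if have_paths and not all(paths):
            raise ValueError("pedigree_path, genotype_path and phenotype_path are all required")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            raw["simulation"] = SimulationSpec(**raw["simulation"])
        if "prior" in raw and isinstance(raw["prior"], dict):
            raw["prior"] = PriorSpec(**raw["prior"])
        if "gibbs" in raw and isinstance(raw["gibbs"], dict):
            raw["gibbs"] = GibbsConfig(**raw["gibbs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class Finding:
    level: str  # "fatal" | "warning"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(f.level == "fatal" for f in self.findings)

    def add(self, level: str, message: str) -> None:
        self.findings.append(Finding(level, message))


@dataclass
class RunReport:
    """Everything the run produced, with provenance."""

    estimates: pd.DataFrame  # trait, kernel, h2_mean, h2_sd, log_likelihood
    coefficients: dict[str, pd.DataFrame]
    ga_summary: pd.DataFrame
    prediction_correlations: pd.DataFrame  # trait, r_total, r_random
    set_sizes: dict[str, int]
    provenance: dict

    def numeric_hash(self) -> str:
        """Hash of the numeric content only (timings/versions excluded)."""
        h = hashlib.sha256()
        for df in (self.estimates, self.ga_summary, self.prediction_correlations,
                   *self.coefficients.values()):
            h.update(df.to_csv(index=False, float_format="%.12g").encode())
        return h.hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "estimates": self.estimates.to_dict(orient="records"),
            "coefficients": {t: c.to_dict(orient="records")
                             for t, c in self.coefficients.items()},
            "ga_summary": self.ga_summary.to_dict(orient="records"),
            "prediction_correlations":
                self.prediction_correlations.to_dict(orient="records"),
            "set_sizes": self.set_sizes,
            "numeric_hash": self.numeric_hash(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


# ----------------------------------------------------------------------
def validate_inputs(config: RunConfig) -> ValidationReport:
    """Cross-check files and id sets without mutating anything.

    The family-study design requires pedigree ⊇ genotyped and
    pedigree ⊇ phenotyped individuals; the fitted sample is their
    intersection after QC.
    """
    rep = ValidationReport()
    if config.simulation is not None:
        return rep  # simulated bundles are consistent by construction
    for label, path in (("pedigree", config.pedigree_path),
                        ("genotypes", config.genotype_path),
                        ("phenotypes", config.phenotype_path)):
        if not Path(path).exists():
            rep.add("fatal", f"{label} file not found: {path}")
    if rep.fatal:
        return rep
    try:
        ped = read_pedigree(config.pedigree_path)
    except Exception as exc:  # malformed pedigree is fatal, with the cause
        rep.add("fatal", f"pedigree failed to parse: {exc}")
        return rep
    geno, skipped = _read_genotypes(config.genotype_path)
    if skipped:
        rep.add("warning", f"site skipped: not biallelic ({skipped} records)")
    pheno = read_phenotypes(config.phenotype_path)
    ped_ids = set(ped.ids)
    for t in geno.ids:
        if t not in ped_ids:
            rep.add("fatal", f"genotyped individual {t!r} absent from pedigree")
    for t in pheno["id"]:
        if str(t) not in ped_ids:
            rep.add("fatal", f"phenotyped individual {t!r} absent from pedigree")
    for name, val in (("min_call_rate", config.min_call_rate),
                      ("min_maf", config.min_maf)):
        if not 0 < val < 1:
            rep.add("fatal", f"{name} = {val} outside (0, 1)")
    return rep


def _read_genotypes(path: str):
    if str(path).endswith(".vcf") or str(path).endswith(".vcf.gz"):
        return read_vcf(path)
    return read_dosage(path), 0


# ----------------------------------------------------------------------
class _State:
    """Completed-stage marker for resumable runs."""

    def __init__(self, outdir: Path, cfg_hash: str):
        self.path = outdir / "state.json"
        self.cfg_hash = cfg_hash
        self.done: list[str] = []
        if self.path.exists():
            prev = json.loads(self.path.read_text())
            if prev.get("config_hash") == cfg_hash:
                self.done = prev.get("completed", [])
            else:
                log.info("configuration changed; ignoring previous run state")

    def mark(self, stage: str) -> None:
        if stage not in self.done:
            self.done.append(stage)
        self.path.write_text(json.dumps(
            {"config_hash": self.cfg_hash, "completed": self.done}, indent=2))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order and write the report.

    Raises RuntimeError naming the failing stage; artifacts of completed
    stages remain on disk together with the resumable state marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _State(outdir, config.config_hash())
    timings: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in
             zip(("impute", "fit"), rng.integers(0, 2**31, 2))}

    report = validate_inputs(config)
    if report.fatal:
        raise RuntimeError(
            "stage 'validate' failed: "
            + "; ".join(f.message for f in report.findings if f.level == "fatal")
        )

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        state.mark(name)
        return out

    # -------------------------------------------------- stage: data
    def stage_data():
        if config.simulation is not None:
            spec = config.simulation
            ped = simulate_pedigree(spec)
            theta = draw_founder_frequencies(spec)
            geno = gene_drop(ped, theta, np.random.default_rng(
                np.random.SeedSequence(spec.seed).spawn(9)[-1]))
            if spec.missing_rate > 0:
                geno = inject_missingness(geno, spec.missing_rate,
                                          np.random.default_rng(spec.seed + 1))
            if spec.genetic_model == "infinitesimal":
                pheno, truth = simulate_phenotype(ped, spec, A=build_A(ped))
            else:
                pheno, truth = simulate_phenotype(ped, spec, genotypes=geno)
            pheno = pheno.rename(columns={"pheno": config.traits[0]})
            write_pedigree(ped, outdir / "pedigree.tsv")
            write_dosage(geno, outdir / "genotypes.tsv")
            write_phenotypes(pheno, outdir / "phenotypes.tsv")
            write_truth(truth, outdir / "truth.tsv")
        else:
            ped = read_pedigree(config.pedigree_path)
            geno, _ = _read_genotypes(config.genotype_path)
            pheno = read_phenotypes(config.phenotype_path)
        return ped, geno, pheno

    if "data" in state.done and (outdir / "pedigree.tsv").exists():
        ped = read_pedigree(outdir / "pedigree.tsv")
        geno = read_dosage(outdir / "genotypes.tsv")
        pheno = read_phenotypes(outdir / "phenotypes.tsv")
        timings["data"] = 0.0
    else:
        ped, geno, pheno = run_stage("data", stage_data)

    n_pedigree, n_genotyped, n_phenotyped = ped.n, geno.n, len(pheno)

    # -------------------------------------------------- stage: qc
    def stage_qc():
        filtered = filter_genotypes(geno, config.min_call_rate, config.min_maf)
        filtered.exclusion_log.to_csv(outdir / "qc_exclusions.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        complete = impute_missing(filtered, seeds["impute"])
        log.info("QC: %d individuals x %d SNPs survive", complete.n, complete.p)
        return complete

    geno_qc = run_stage("qc", stage_qc)

    # -------------------------------------------------- kernels
    # analysis set: pedigree ∩ genotyped(after QC) ∩ phenotyped
    pheno_ids = [str(t) for t in pheno["id"]]
    keep = [t for t in geno_qc.ids if t in set(pheno_ids) and t in set(ped.ids)]
    n_analysis = len(keep)
    if n_analysis == 0:
        raise RuntimeError("stage 'qc' failed: no individual has pedigree, "
                           "genotype and phenotype data")

    def stage_amat():
        A = build_A(ped).reorder(keep)
        A.write_grm(outdir / "A")
        return A

    def stage_grm():
        sub = _subset_genotypes(geno_qc, keep)
        G = compute_G(sub).with_jitter()
        G.write_grm(outdir / "G")
        comparison = compare_G_A(G, A)
        comparison.summary.to_csv(outdir / "ga_summary.tsv", sep="\t",
                                  index=False, float_format="%.8g")
        comparison.plot(outdir / "fig_ga_scatter.png")
        return G, comparison

    A = run_stage("amat", stage_amat)
    G, comparison = run_stage("grm", stage_grm)

    # -------------------------------------------------- per-trait fits
    pheno_kept = pheno.set_index(pheno["id"].astype(str)).loc[keep].reset_index(drop=True)
    coefficients: dict[str, pd.DataFrame] = {}
    est_rows, corr_rows = [], []

    def stage_adjust():
        out = {}
        for trait in config.traits:
            adj = fit_fixed_effects(pheno_kept, trait=trait,
                                    covariates=config.covariates)
            adj.coefficients.to_csv(outdir / f"coefficients_{trait}.tsv",
                                    sep="\t", index=False, float_format="%.8g")
            adj.to_frame().to_csv(outdir / f"residuals_{trait}.tsv", sep="\t",
                                  index=False, float_format="%.10g")
            out[trait] = adj
        return out

    adjusted: dict[str, AdjustedPhenotype] = run_stage("adjust", stage_adjust)
    for trait in config.traits:
        coefficients[trait] = adjusted[trait].coefficients

    def stage_fit():
        fits = {}
        for trait in config.traits:
            adj = adjusted[trait]
            for kernel, label in ((A, "pedigree"), (G, "genomic")):
                cfg = dataclasses.replace(config.gibbs, seed=seeds["fit"])
                post = fit_model(adj, kernel, config.prior, cfg)
                post.samples.to_csv(
                    outdir / f"samples_{trait}_{label}.tsv", sep="\t",
                    index=False, float_format="%.8g")
                fits[(trait, label)] = post
                est_rows.append({
                    "trait": trait, "kernel": label,
                    "h2_mean": post.means["h2"], "h2_sd": post.sds["h2"],
                    "log_likelihood": post.log_likelihood,
                    "ess_h2": post.ess["h2"],
                })
        return fits

    fits = run_stage("fit", stage_fit)

    def stage_compare():
        for trait in config.traits:
            cmp_ = compare_predicted_values(fits[(trait, "pedigree")],
                                            fits[(trait, "genomic")],
                                            adjusted[trait])
            cmp_.table.to_csv(outdir / f"predicted_{trait}.tsv", sep="\t",
                              index=False, float_format="%.10g")
            cmp_.plot(outdir / f"fig_predicted_{trait}.png")
            corr_rows.append({"trait": trait, "r_total": cmp_.correlation,
                              "r_random": cmp_.correlation_random})

    run_stage("compare", stage_compare)

    estimates = pd.DataFrame(est_rows)
    estimates.to_csv(outdir / "heritability_estimates.tsv", sep="\t",
                     index=False, float_format="%.8g")
    pred_corr = pd.DataFrame(corr_rows)
    report = RunReport(
        estimates=estimates,
        coefficients=coefficients,
        ga_summary=comparison.summary,
        prediction_correlations=pred_corr,
        set_sizes={
            "pedigree": n_pedigree,
            "genotyped": n_genotyped,
            "phenotyped": n_phenotyped,
            "post_qc_genotyped": geno_qc.n,
            "analysis": n_analysis,
        },
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "herit_version": __version__,
            "numpy_version": np.__version__,
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        },
    )
    report.to_json(outdir / "report.json")
    return report


def _subset_genotypes(g, keep: list[str]):
    from .grm import GenotypeMatrix

    index = {t: k for k, t in enumerate(g.ids)}
    rows = np.array([index[t] for t in keep])
    return GenotypeMatrix(ids=list(keep), snp_ids=list(g.snp_ids),
                          counts=g.counts[rows], theta=g.theta,
                          theta_true=g.theta_true)
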