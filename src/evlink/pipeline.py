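"""Configured, logged, resumable end-to-end runs.

Stages: simulate -> parse -> denoise -> quantify -> associate -> gwas ->
snpsets -> enrich. Each enabled stage writes versioned outputs under the run
directory plus an entry in a JSON manifest (parameters, derived seed, output
hashes, row/column counts). A single global seed deterministically derives one
substream per stage, so reruns with the same config byte-reproduce every
output, and individual stages can be re-run from the recorded inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import denoise as denoise_mod
from . import evtypes as evtypes_mod
from . import genetics as genetics_mod
from . import pba as pba_mod
from . import synthdata as synth_mod
from .panel import ProteinPanel

logger = logging.getLogger(__name__)

STAGES = ("simulate", "parse", "denoise", "quantify", "associate", "gwas", "snpsets", "enrich")


class PreflightError(ValueError):
    """A stage is enabled without its upstream stage or an explicit input."""


@dataclass
class RunConfig:
    """Declarative configuration mirroring the generator and filter models."""

    seed: int = 1
    outdir: str = "evlink_run"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    panel_size: int = 113
    n_markers: int = 12
    n_samples: int = 2
    population: dict[str, Any] = field(default_factory=dict)
    cohort: dict[str, Any] = field(default_factory=dict)
    denoise: dict[str, Any] = field(default_factory=dict)
    evtypes: dict[str, Any] = field(default_factory=lambda: {"scheme": "marker_pairs_only"})
    assoc: dict[str, Any] = field(default_factory=lambda: {"family": "pooled"})
    gwas: dict[str, Any] = field(default_factory=lambda: {"maf_threshold": 0.2})
    snpsets: dict[str, Any] = field(default_factory=lambda: {"p_max": 1e-6, "flank": 1000})
    inputs: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        """Pre-flight dependency check; raises before any compute."""
        need = {
            "parse": ("simulate", "reads"),
            "denoise": ("parse", "matrices"),
            "quantify": ("denoise", "denoised_matrices"),
            "associate": ("simulate", "cohort_dir"),
            "gwas": ("simulate", "cohort_dir"),
            "snpsets": ("gwas", "gwas_dir"),
            "enrich": ("snpsets", None),
        }
        for stage, (upstream, input_key) in need.items():
            if self.stages.get(stage) and not self.stages.get(upstream):
                if input_key is None or input_key not in self.inputs:
                    raise PreflightError(
                        f"stage {stage!r} enabled but upstream {upstream!r} disabled and no "
                        f"explicit input {input_key!r} configured"
                    )
        for stage in ("associate", "gwas", "snpsets", "enrich"):
            if self.stages.get(stage) and not self.stages.get("simulate"):
                if "cohort_dir" not in self.inputs:
                    raise PreflightError(
                        f"stage {stage!r} needs cohort data: enable 'simulate' or provide "
                        "inputs.cohort_dir"
                    )


def default_config(outdir: str, seed: int = 1) -> RunConfig:
    """A small coherent demonstration scenario with planted effects.

    Uses a reduced panel and marker set so a laptop-scale run exercises every
    stage: two deep samples for the profile branch, and a 96-person cohort with
    one planted EV-trait effect, causal SNPs for several pair phenotypes, and a
    complex trait whose heritability sits partly on those SNPs.
    """
    panel = ProteinPanel.default(size=20, n_markers=4)
    types = evtypes_mod.enumerate_ev_types(panel.markers, panel, "marker_pairs_only")
    labels = tuple(t.label for t in types)
    pair_labels = [t.label for t in types if len(t.marker_set) == 2]
    ev_snp_effects = {
        lab: {10 * i + j: 0.5 for j in range(3)} for i, lab in enumerate(pair_labels)
    }
    causal = sorted({j for per in ev_snp_effects.values() for j in per})
    n_snps = 600
    # put 3x the per-SNP average heritability on the EV-causal SNPs, so the
    # true enrichment of any annotation recovering (a subset of) them is 3.0
    f_share = 3.0 * len(causal) / n_snps
    h2_on_causal = f_share / len(causal)
    others = [j for j in range(n_snps) if j not in set(causal)]
    h2_off = (1.0 - f_share) / len(others)
    complex_effects = {j: np.sqrt(h2_on_causal) for j in causal}
    complex_effects.update({j: np.sqrt(h2_off) for j in others})
    return RunConfig(
        seed=seed,
        outdir=outdir,
        panel_size=20,
        n_markers=4,
        n_samples=2,
        population={"n_evs": 5000},
        cohort={
            "n_individuals": 96,
            "ev_types": labels,
            # noise level chosen so the planted main effect carries a partial
            # R^2 near 0.17 in the interaction model at n = 96
            "ev_effects": {labels[0]: {"BMI": (-1.62, 0.0)}},
            "trait_noise_sd": 2.6,
            "n_snps": n_snps,
            "maf_range": (0.25, 0.5),
            "ev_snp_effects": ev_snp_effects,
            "complex_trait_effects": complex_effects,
            "complex_trait_h2": 0.7,
        },
        gwas={"maf_threshold": 0.2},
    )


def _load_matrices(directory: str, prefix: str, panel: ProteinPanel) -> list[pba_mod.EVProfileMatrix]:
    out = []
    for name in sorted(os.listdir(directory)):
        if name.startswith(prefix) and name.endswith(".mtx"):
            sid = name[len(prefix) : -len(".mtx")]
            out.append(
                pba_mod.EVProfileMatrix.read_mtx(
                    os.path.join(directory, name[: -len(".mtx")]), panel, sid
                )
            )
    if not out:
        raise PreflightError(f"no {prefix}*.mtx matrices found in {directory}")
    return out


def _load_cohort(directory: str) -> synth_mod.CohortData:
    G = genetics_mod.GenotypeMatrix.read_dosage(os.path.join(directory, "genotypes.dosage.tsv"))
    ev = pd.read_csv(os.path.join(directory, "ev_abundance.tsv"), sep="\t", index_col="sample_id")
    ph = pd.read_csv(os.path.join(directory, "phenotypes.tsv"), sep="\t", index_col="sample_id")
    h2 = pd.read_csv(os.path.join(directory, "snp_h2.tsv"), sep="\t")["h2"].to_numpy()
    return synth_mod.CohortData(
        genotypes=G,
        ev_abundance=ev,
        phenotypes=ph,
        snp_h2=h2,
        individual_ids=tuple(ph.index.astype(str)),
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages and return (and write) the run manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = dict(zip(STAGES, ss.spawn(len(STAGES))))
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    panel = ProteinPanel.default(config.panel_size, config.n_markers)

    samples: list[synth_mod.EVSample] = []
    matrices: list[pba_mod.EVProfileMatrix] = []
    denoised: list[pba_mod.EVProfileMatrix] = []
    cohort: synth_mod.CohortData | None = None

    def record(stage: str, params: dict, outputs: list[str], **counts: Any) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {os.path.relpath(p, config.outdir): _sha256(p) for p in outputs},
            **counts,
        }
        logger.info("stage %s done: %s", stage, counts)

    if config.stages["simulate"]:
        rng = np.random.default_rng(stage_seeds["simulate"])
        pop = synth_mod.EVPopulationModel(panel=panel, **config.population)
        outputs = []
        for i in range(config.n_samples):
            sample = synth_mod.generate_ev_sample(pop, f"s{i + 1}", rng)
            samples.append(sample)
            path = os.path.join(config.outdir, f"reads_{sample.sample_id}.tsv")
            pba_mod.write_pba_table(sample.reads, path)
            outputs.append(path)
        cohort_model = synth_mod.CohortModel(**config.cohort)
        cohort = synth_mod.generate_cohort(cohort_model, rng)
        cohort_paths = synth_mod.write_cohort(cohort, config.outdir)
        outputs += list(cohort_paths.values())
        record(
            "simulate",
            {"n_samples": config.n_samples, **config.population},
            outputs,
            n_evs_per_sample=pop.n_evs,
            n_individuals=cohort_model.n_individuals,
            n_snps=cohort_model.n_snps,
        )

    if config.stages["parse"]:
        if not samples:
            table = pba_mod.read_pba_table(config.inputs["reads"])
            sample_ids = sorted(table["sample_id"].unique())
        else:
            table = pd.concat([s.reads for s in samples], ignore_index=True)
            sample_ids = [s.sample_id for s in samples]
        outputs = []
        for sid in sample_ids:
            m = pba_mod.parse_reads(table, panel, sid)
            matrices.append(m)
            prefix = os.path.join(config.outdir, f"matrix_{sid}")
            m.write_mtx(prefix)
            outputs += [f"{prefix}.mtx", f"{prefix}.rows.tsv", f"{prefix}.cols.tsv"]
        record("parse", {}, outputs, n_matrices=len(matrices))

    if config.stages["denoise"]:
        if not matrices:
            matrices = _load_matrices(config.inputs["matrices"], "matrix_", panel)
        cfg = denoise_mod.ChiFilterConfig(**config.denoise)
        outputs = []
        reports = {}
        for m in matrices:
            rep = denoise_mod.denoise_matrix(m, cfg)
            denoised.append(rep.matrix)
            prefix = os.path.join(config.outdir, f"denoised_{m.sample_id}")
            rep.matrix.write_mtx(prefix)
            outputs += [f"{prefix}.mtx", f"{prefix}.rows.tsv", f"{prefix}.cols.tsv"]
            reports[m.sample_id] = {
                "cutoff": rep.cutoff,
                "n_evs_input": rep.n_evs_input,
                "n_evs_output": rep.n_evs_output,
                "surviving_cell_fraction": rep.surviving_cell_fraction,
            }
        report_path = os.path.join(config.outdir, "denoise_report.json")
        with open(report_path, "w") as fh:
            json.dump(reports, fh, indent=2)
        outputs.append(report_path)
        record("denoise", vars(cfg) | {}, outputs, reports=reports)

    if config.stages["quantify"]:
        if not denoised and not config.stages["denoise"]:
            denoised = _load_matrices(config.inputs["denoised_matrices"], "denoised_", panel)
        types = evtypes_mod.enumerate_ev_types(
            panel.markers, panel, config.evtypes.get("scheme", "marker_pairs_only")
        )
        table = evtypes_mod.build_phenotype_table(denoised, types)
        path = os.path.join(config.outdir, "ev_type_abundance.tsv")
        evtypes_mod.write_phenotype_table(table, path)
        record("quantify", config.evtypes, [path], n_types=len(types), n_samples=len(table))

    if any(config.stages[s] for s in ("associate", "gwas", "snpsets", "enrich")):
        if cohort is None and "cohort_dir" in config.inputs:
            cohort = _load_cohort(config.inputs["cohort_dir"])

    if config.stages["associate"]:
        assert cohort is not None
        results = assoc_mod.associate_all(
            cohort.phenotypes,
            cohort.ev_abundance,
            trait_names=[t for t in synth_mod.TRAIT_NAMES if t in cohort.phenotypes],
            family=config.assoc.get("family", "pooled"),
            # simulated traits are generated directly on the standardized scale
            traits_standardized=config.assoc.get("traits_standardized", True),
        )
        path = os.path.join(config.outdir, "associations.tsv")
        results.to_csv(path, sep="\t", index=False)
        record("associate", config.assoc, [path], n_tests=len(results))

    gwas_results: dict[str, pd.DataFrame] = {}
    if config.stages["gwas"]:
        assert cohort is not None
        covars = cohort.phenotypes[["sex", "age"]].to_numpy()
        G = genetics_mod.maf_filter(
            cohort.genotypes, config.gwas.get("maf_threshold", 0.2)
        )
        outputs = []
        lambdas = {}
        label_files = {}
        for label in cohort.ev_abundance.columns:
            z = genetics_mod.prepare_gwas_phenotype(
                cohort.ev_abundance[label].to_numpy(), covars
            )
            res = genetics_mod.linear_gwas(z, G, phenotype=label)
            gwas_results[label] = res.table
            lambdas[label] = res.lambda_gc
            path = os.path.join(
                config.outdir, f"gwas_{label.replace(' & ', '_').replace('/', '_')}.tsv"
            )
            res.write(path)
            label_files[label] = os.path.basename(path)
            outputs.append(path)
        labels_path = os.path.join(config.outdir, "gwas_files.json")
        with open(labels_path, "w") as fh:
            json.dump(label_files, fh, indent=2)
        outputs.append(labels_path)
        record(
            "gwas",
            config.gwas,
            outputs,
            n_phenotypes=len(gwas_results),
            n_snps_tested=G.n_snps,
            median_lambda=float(np.median(list(lambdas.values()))),
        )

    annotations: list[genetics_mod.SNPAnnotation] = []
    if config.stages["snpsets"]:
        assert cohort is not None
        if not gwas_results:
            gwas_dir = config.inputs["gwas_dir"]
            with open(os.path.join(gwas_dir, "gwas_files.json")) as fh:
                label_files = json.load(fh)
            gwas_results = {
                lab: pd.read_csv(os.path.join(gwas_dir, fname), sep="\t")
                for lab, fname in label_files.items()
            }
        pair_results = {
            lab: tab
            for lab, tab in gwas_results.items()
            if len(evtypes_mod.EVTypeDefinition.from_label(lab).marker_set) == 2
        }
        phenotype_markers = {
            lab: evtypes_mod.EVTypeDefinition.from_label(lab).marker_set
            for lab in pair_results
        }
        sets = genetics_mod.extract_snp_sets(
            pair_results,
            phenotype_markers,
            markers=list(panel.markers),
            p_threshold=config.snpsets.get("p_max", 1e-6),
        )
        outputs = []
        for ann in sets:
            flanked = genetics_mod.annotate_flanks(
                ann, cohort.genotypes, window_bp=config.snpsets.get("flank", 1000)
            )
            annotations.append(flanked)
            path = os.path.join(config.outdir, f"snpset_{ann.label}.bed")
            flanked.write_bed(path)
            outputs.append(path)
        record(
            "snpsets",
            config.snpsets,
            outputs,
            n_sets=len(annotations),
            set_sizes={a.label: len(a.snps) for a in annotations},
        )

    if config.stages["enrich"]:
        assert cohort is not None
        rows = []
        for ann in annotations:
            if ann.membership is None or not ann.membership.any():
                continue
            res = genetics_mod.enrichment_score(ann, cohort.snp_h2, trait="complex_trait")
            rows.append(
                {
                    "annotation": res.annotation,
                    "trait": res.trait,
                    "score": res.score,
                    "se": res.se,
                    "proportion_h2": res.proportion_h2,
                    "proportion_snps": res.proportion_snps,
                }
            )
        path = os.path.join(config.outdir, "enrichment.tsv")
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        record("enrich", {}, [path], n_scored=len(rows))

    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
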