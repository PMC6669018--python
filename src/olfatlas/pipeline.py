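"""End-to-end orchestration: annotate -> quantify -> cluster -> enrich -> odorspace.

Runs the full analysis shape on the synthetic dataset (or user-supplied
tables), writing each stage's outputs into a run directory together with a
manifest recording the configuration hash, the seed, and per-file sha256
checksums, so a rerun with the same config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cross_species, ligand_enrichment, odorspace, quantify, synthetic_data
from .or_annotation import build_custom_annotation, write_gtf
from .synthetic_data import SimulationConfig

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("olfatlas.pipeline")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Thresholds default to the analysis conventions: minimum alignment
    identity 95%, expression threshold 1.0 normalized counts, the 90th
    percentile for high abundance, cluster counts 2..8, binomial baseline
    0.10, and 95% confidence intervals.
    """

    outdir: str = "olfatlas_run"
    seed: int | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "annotate": True, "quantify": True, "cluster": True,
            "enrich": True, "odorspace": True,
        }
    )
    synthetic: bool = True
    min_identity: float = 95.0
    expressed_threshold: float = 1.0
    expressed_min_replicates: int = 1
    percentile: float = 90.0
    k_min: int = 2
    k_max: int = 8
    baseline_p0: float = 0.10
    confidence: float = 0.95
    enrichment_species: tuple[str, ...] = ("human", "mouse")
    enrichment_classes: tuple[str, ...] = ("KFO", "SMC", "other")
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must lie in (0, 100]")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if not 0 < self.baseline_p0 < 1:
            raise ValueError("baseline_p0 must lie in (0, 1)")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**{
            **raw.pop("sim", {}),
            **({"seed": raw["seed"]} if "seed" in raw and "sim" not in raw else {}),
        })
        cfg = cls(**{k: v for k, v in raw.items() if k != "sim"}, sim=sim)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["species"] = list(self.sim.species)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order and write a manifest.

    Returns the run directory. A stage failure writes a ``FAILED`` marker
    naming the stage, keeps any partial outputs, and raises
    :class:`PipelineError`.
    """
    if config.seed is None and config.synthetic:
        raise ValueError("a seed is mandatory when stochastic stages (synthetic data) are enabled")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    files: dict[str, str] = {}
    sim = config.sim if config.seed is None else SimulationConfig(
        **{**asdict(config.sim), "seed": config.seed,
           "species": config.sim.species,
           "n_samples_per_species": config.sim.n_samples_per_species,
           "ligand_class_fractions": dict(config.sim.ligand_class_fractions)}
    )
    current = "setup"

    def register(path: Path):
        files[path.name] = _sha256(path)

    try:
        # ---------------- annotate ----------------
        if config.stages.get("annotate", True):
            current = "annotate"
            log.info("stage=annotate event=start")
            fixture = synthetic_data.gen_annotation_fixture(sim)
            merged, report = build_custom_annotation(
                fixture.hits, fixture.base,
                min_identity=config.min_identity, seed=sim.seed,
            )
            write_gtf(merged, outdir / "merged.gtf")
            report.to_json(outdir / "merge_report.json")
            register(outdir / "merged.gtf")
            register(outdir / "merge_report.json")
            log.info("stage=annotate event=done n_records=%d survivors=%d",
                     len(merged), report.n_survivors)

        # ---------------- quantify ----------------
        abundances: dict[str, pd.DataFrame] = {}
        catalogs: dict[str, pd.DataFrame] = {}
        pairs_by_species: dict[str, pd.DataFrame] = {}
        top_sets: dict[str, set] = {}
        expressed3: dict[str, pd.Series] = {}
        if config.stages.get("quantify", True):
            current = "quantify"
            log.info("stage=quantify event=start")
            for sp in sim.species:
                cat = synthetic_data.gen_or_catalog(sim, sp)
                pairs, mult = synthetic_data.gen_ligand_annotations(cat, sim, sp)
                counts, _sf, _means = synthetic_data.gen_count_matrix(cat, sim, sp, multipliers=mult)
                sf = quantify.estimate_size_factors(counts)
                norm = quantify.normalize(counts, sf)
                ab = quantify.summarize_abundance(norm, cat.index)
                ab["expressed"] = quantify.flag_expressed(
                    norm, config.expressed_threshold, config.expressed_min_replicates
                ).reindex(ab.index)
                top_sets[sp] = quantify.top_decile_set(ab, config.percentile)
                ab = ab.join(cat)
                ab.to_csv(outdir / f"{sp}_abundance.tsv", sep="\t")
                register(outdir / f"{sp}_abundance.tsv")
                abundances[sp] = ab
                catalogs[sp] = cat
                pairs_by_species[sp] = pairs
                expressed3[sp] = quantify.flag_expressed(norm, config.expressed_threshold, 3)
                log.info("stage=quantify event=species species=%s n_or=%d n_expressed=%d",
                         sp, len(cat), int(ab["expressed"].sum()))

        # ---------------- cluster ----------------
        if config.stages.get("cluster", True):
            current = "cluster"
            if not abundances:
                raise ValueError("cluster stage requires quantify outputs")
            log.info("stage=cluster event=start")
            ortho, _truth = synthetic_data.gen_orthology(catalogs, sim)
            ogg, z = cross_species.assign_oggs(ortho, catalogs, abundances, list(sim.species))
            k_star, diagnostics = cross_species.select_cluster_count(
                z, range(config.k_min, config.k_max + 1)
            )
            chosen = next(d for d in diagnostics if d.k == k_star)
            membership = ogg.assign(cluster=chosen.labels)
            membership.to_csv(outdir / "ogg_clusters.tsv", sep="\t", index=False)
            register(outdir / "ogg_clusters.tsv")
            diag_json = {
                "k_star": k_star,
                "per_k": [
                    {"k": d.k, "asw": d.asw, "pearson_gamma": d.pearson_gamma,
                     "wb_ratio": d.wb_ratio}
                    for d in diagnostics
                ],
            }
            (outdir / "cluster_diagnostics.json").write_text(json.dumps(diag_json, indent=2) + "\n")
            register(outdir / "cluster_diagnostics.json")
            ztest = cross_species.cluster_high_abundance_test(
                ogg, chosen.labels, top_sets, list(sim.species), p0=config.baseline_p0
            )
            ztest.to_csv(outdir / "cluster_top_decile_tests.tsv", sep="\t", index=False)
            register(outdir / "cluster_top_decile_tests.tsv")
            log.info("stage=cluster event=done n_ogg=%d k_star=%d", len(ogg), k_star)

        # ---------------- enrich ----------------
        if config.stages.get("enrich", True):
            current = "enrich"
            if not abundances:
                raise ValueError("enrich stage requires quantify outputs")
            log.info("stage=enrich event=start")
            report_rows = []
            for sp in config.enrichment_species:
                if sp not in abundances:
                    continue
                for cls in config.enrichment_classes:
                    res = ligand_enrichment.enrichment_report(
                        abundances[sp], pairs_by_species[sp], cls,
                        p0=config.baseline_p0, confidence=config.confidence,
                    )
                    if isinstance(res, ligand_enrichment.NoTestResult):
                        report_rows.append({"species": sp, "class": cls, "tested": False})
                    else:
                        report_rows.append({"species": sp, "class": cls, "tested": True,
                                            **{k: v for k, v in asdict(res).items()
                                               if k != "class_selector"}})
            pd.DataFrame(report_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            register(outdir / "enrichment.tsv")
            (outdir / "enrichment.json").write_text(
                json.dumps(report_rows, indent=2, default=float) + "\n"
            )
            register(outdir / "enrichment.json")
            log.info("stage=enrich event=done n_tests=%d", len(report_rows))

        # ---------------- odorspace ----------------
        if config.stages.get("odorspace", True):
            current = "odorspace"
            log.info("stage=odorspace event=start")
            desc, _removal = synthetic_data.gen_descriptor_matrix(sim)
            reduced, removal_log = odorspace.filter_descriptors(desc)
            removal_log.to_csv(outdir / "descriptor_removal.tsv", sep="\t", index=False)
            register(outdir / "descriptor_removal.tsv")
            space = odorspace.project_odor_space(reduced)
            scores = space.scores.iloc[:, :5]
            scores.to_csv(outdir / "odorspace_scores.tsv", sep="\t")
            register(outdir / "odorspace_scores.tsv")
            log.info("stage=odorspace event=done n_descriptors_kept=%d", reduced.shape[1])

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        log.error("stage=%s event=failed error=%s", current, exc)
        log.removeHandler(handler)
        handler.close()
        raise PipelineError(current, exc) from exc

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "outputs": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("stage=all event=complete n_outputs=%d", len(files))
    log.removeHandler(handler)
    handler.close()
    return outdir
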