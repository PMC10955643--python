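"""End-to-end orchestration: simulate/ingest -> QC -> associate -> burden ->
validate -> enrich -> ML, behind one YAML config, with a reproducible manifest.

Every stage writes a plain-text artifact under the output directory; the
manifest records the configuration, seed, per-stage record counts and a
SHA-256 digest of every artifact, so a rerun with the same config and seed
reproduces every file byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .simulate import Cohort, SimulationConfig, simulate_annotations, simulate_cohort_pair
from . import io as xio
from .qc import QcThresholds, apply_site_filters, pca_structure_check, prioritize_functional
from .association import run_association
from .burden import DEFAULT_K_MAX, run_burden
from .validation import hypergeom_enrichment, validate_genes, validate_variants
from .ml import MODEL_FAMILIES, encode_allelic_dose, labels_to_binary, run_ml

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """One-file configuration for :func:`run_pipeline`.

    Either ``simulation`` is set (simulate mode) or both cohort prefixes are
    paths to files written in the package's on-disk formats (ingest mode).
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    alpha: float = 0.05
    k_max: int = DEFAULT_K_MAX
    qc: QcThresholds = field(default_factory=QcThresholds)
    simulation: SimulationConfig | None = None
    discovery_prefix: str | None = None
    validation_prefix: str | None = None
    gene_sets: str | None = None
    ml_families: tuple[str, ...] = MODEL_FAMILIES
    ml_k_folds: int = 5
    pc1_threshold: float = 0.05

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.simulation is None and not (
            self.discovery_prefix and self.validation_prefix
        ):
            raise ConfigurationError(
                "either a simulation block or both cohort prefixes are required"
            )
        if self.simulation is None:
            for p in (self.discovery_prefix, self.validation_prefix):
                if not Path(str(p) + ".vcf").exists():
                    raise ConfigurationError(f"cohort files not found at {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QcThresholds(**raw["qc"])
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "ml_families" in raw:
            raw["ml_families"] = tuple(raw["ml_families"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "alpha": self.alpha,
            "k_max": self.k_max,
            "qc": vars(self.qc),
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "discovery_prefix": self.discovery_prefix,
            "validation_prefix": self.validation_prefix,
            "gene_sets": self.gene_sets,
            "ml_families": list(self.ml_families),
            "ml_k_folds": self.ml_k_folds,
            "pc1_threshold": self.pc1_threshold,
        }
        return d


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohorts(
    config: PipelineConfig,
) -> tuple[Cohort, Cohort, pd.DataFrame, pd.DataFrame | None]:
    if config.simulation is not None:
        sim = config.simulation
        disc, val, truth = simulate_cohort_pair(sim)
        rng = np.random.default_rng(sim.seed + 1)
        panel_df = truth[["variant_id", "gene"]].copy()
        ids = truth["variant_id"].str.split(":", expand=True)
        panel_df[["chrom", "pos", "ref", "alt"]] = ids
        panel_df["pos"] = panel_df["pos"].astype(int)
        panel_df["status"] = truth["status"]
        anno = simulate_annotations(panel_df, sim, rng)
        return disc, val, anno, truth
    disc, anno = xio.read_cohort(config.discovery_prefix)
    val, anno_val = xio.read_cohort(config.validation_prefix)
    if list(anno_val["variant_id"]) != list(anno["variant_id"]):
        raise ConfigurationError("cohorts do not share one variant panel")
    return disc, val, anno, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on both cohorts; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    disc, val, anno, truth = _load_cohorts(config)
    manifest["stages"]["input"] = {
        "variants_in": len(anno),
        "discovery_samples": disc.n_samples,
        "validation_samples": val.n_samples,
    }
    if truth is not None:
        xio.write_truth(truth, out / "truth.tsv")

    # --- QC: site filters + functional prioritization ---------------------
    retained, removal = apply_site_filters(anno, config.qc)
    prioritized = prioritize_functional(retained)
    _write_tsv(prioritized, out / "qc.tsv")
    manifest["stages"]["qc"] = {
        "variants_after_site_filters": len(retained),
        "removal_counts": removal,
        "variants_after_prioritization": len(prioritized),
    }
    panel = list(prioritized["variant_id"])
    gene_map = dict(zip(prioritized["variant_id"], prioritized["gene"]))
    disc = disc.subset_variants(panel)
    val = val.subset_variants(panel)

    # --- population-structure check (advisory) ----------------------------
    structure = {}
    for name, cohort in (("discovery", disc), ("validation", val)):
        rep = pca_structure_check(cohort, pc1_threshold=config.pc1_threshold)
        structure[name] = {
            "pc1_fraction": round(rep.pc1_fraction, 6),
            "structured": bool(rep.structured),
        }
    manifest["stages"]["pca"] = structure

    # --- per-variant association ------------------------------------------
    assoc, sig = {}, {}
    for name, cohort in (("disc", disc), ("val", val)):
        results, significant = run_association(cohort, config.alpha, gene_map)
        _write_tsv(results, out / f"assoc_{name}.tsv")
        assoc[name], sig[name] = results, significant
    manifest["stages"]["association"] = {
        "significant_disc": len(sig["disc"]),
        "significant_val": len(sig["val"]),
    }

    # --- gene burden -------------------------------------------------------
    burden = {}
    for name in ("disc", "val"):
        b = run_burden(assoc[name], config.alpha, config.k_max)
        _write_tsv(b, out / f"burden_{name}.tsv")
        burden[name] = b
    manifest["stages"]["burden"] = {
        "eligible_genes_disc": len(burden["disc"]),
        "eligible_genes_val": len(burden["val"]),
    }

    # --- cross-cohort validation -------------------------------------------
    validated_variants, discordant = validate_variants(
        assoc["disc"], assoc["val"], config.alpha
    )
    _write_tsv(validated_variants, out / "validated_variants.tsv")
    _write_tsv(discordant, out / "discordant_variants.tsv")
    validated_genes = validate_genes(
        assoc["disc"], assoc["val"], burden["disc"], burden["val"], config.alpha
    )
    _write_tsv(validated_genes, out / "validated_genes.tsv")
    manifest["stages"]["validation"] = {
        "validated_variants": len(validated_variants),
        "discordant_variants": len(discordant),
        "validated_genes": len(validated_genes),
    }

    # --- gene-set enrichment (optional) -------------------------------------
    if config.gene_sets:
        collections = xio.read_gmt(config.gene_sets)
        universe = set(gene_map.values())
        genes = set(validated_genes["gene"]) & universe
        enr = hypergeom_enrichment(genes, universe, collections)
        _write_tsv(enr, out / "enrichment.tsv")
        manifest["stages"]["enrichment"] = {
            "collections": len(collections),
            "min_p": float(enr["p"].min()) if len(enr) else None,
        }
    else:
        manifest["stages"]["enrichment"] = "skipped (no gene-set collections)"

    # --- ML on the validated-variant dose matrix -----------------------------
    features = list(validated_variants["variant_id"])
    if len(features) >= 2:
        X_disc = encode_allelic_dose(disc, features)
        X_val = encode_allelic_dose(val, features)
        report = run_ml(
            X_disc, labels_to_binary(disc.labels),
            X_val, labels_to_binary(val.labels),
            families=config.ml_families,
            k_folds=config.ml_k_folds,
            seed=config.seed,
        )
        (out / "ml_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        manifest["stages"]["ml"] = {
            family: {
                k: round(v, 6)
                for k, v in entry.items()
                if isinstance(v, (int, float))
            }
            for family, entry in report.items()
        }
    else:
        manifest["stages"]["ml"] = (
            f"skipped ({len(features)} validated variants; need >= 2 features)"
        )

    artifacts = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest["artifacts"] = {p.name: _sha256(p) for p in artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info(
        "pipeline complete: %s significant (disc) / %s (val) -> %s validated "
        "variants, %s validated genes",
        manifest["stages"]["association"]["significant_disc"],
        manifest["stages"]["association"]["significant_val"],
        manifest["stages"]["validation"]["validated_variants"],
        manifest["stages"]["validation"]["validated_genes"],
    )
    return manifest
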