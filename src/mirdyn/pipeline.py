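"""End-to-end orchestration: load a dataset directory, run the enabled stages,
write result tables and a reproducibility manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dynamics, popgen, quant
from . import io as mio
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["LoadedDataset", "ReportBundle", "load_dataset", "run_pipeline"]


@dataclass
class LoadedDataset:
    counts: dict[str, pd.DataFrame]            # replicate -> gene x window counts (+SPIKEIN)
    pri_density: pd.DataFrame
    gene_meta: pd.DataFrame
    utr_seqs: dict[str, str] | None = None
    utr_bed: pd.DataFrame | None = None
    cds_bed: pd.DataFrame | None = None
    snps: mio.SnpTable | None = None
    gene_classes: pd.DataFrame | None = None
    ortholog_map: dict[str, str] | None = None
    mirna_seqs: dict[str, str] | None = None

    @property
    def has_popgen(self) -> bool:
        return self.snps is not None and self.utr_seqs is not None


def load_dataset(config: PipelineConfig) -> LoadedDataset:
    """Load and validate a dataset directory (the layout `simulate` writes)."""
    d = Path(config.dataset_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"dataset directory {d} does not exist")
    count_paths = sorted(d.glob("counts_rep*.tsv"))
    if not count_paths:
        raise FileNotFoundError(f"no counts_rep*.tsv files in {d}")
    counts = {p.stem.removeprefix("counts_"): mio.read_time_course(p) for p in count_paths}
    pri = mio.read_time_course(d / "pri_density.tsv")
    gene_meta = pd.read_csv(d / "gene_meta.tsv", sep="\t", dtype={"gene": str, "cluster_id": str})
    ds = LoadedDataset(counts=counts, pri_density=pri, gene_meta=gene_meta)
    if (d / "snps.tsv").exists():
        ds.snps = mio.read_snp_tsv(d / "snps.tsv")
        ds.utr_seqs = mio.read_fasta(d / "utrs.fa")
        ds.utr_bed = mio.read_bed(d / "utrs.bed")
        cds_path = d / "cds.bed"
        ds.cds_bed = mio.read_bed(cds_path) if cds_path.stat().st_size > 0 else None
        ds.gene_classes = mio.read_gene_classes(d / "gene_classes.tsv")
        ds.ortholog_map = mio.read_ortholog_map(d / "ortholog_map.tsv")
        ds.mirna_seqs = mio.read_fasta(d / "mature_mirnas.fa")
    logger.info(
        "loaded dataset: %d genes, %d replicates, popgen=%s",
        len(pri), len(counts), ds.has_popgen,
    )
    return ds


@dataclass
class ReportBundle:
    out_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    manifest_path: Path | None = None


def _write(df: pd.DataFrame, bundle: ReportBundle, key: str, index: bool = True) -> None:
    path = bundle.out_dir / f"{key}.tsv"
    df.to_csv(path, sep="\t", index=index, na_rep=".")
    bundle.outputs[key] = path


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run quantification -> dynamics -> population genetics as enabled."""
    ds = load_dataset(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)

    # --- quantification: RPTS per replicate and replicate mean -------------
    rpts = {rep: quant.rpts_normalize(df) for rep, df in ds.counts.items()}
    mean_rpts = sum(rpts.values()) / len(rpts)
    for rep, df in rpts.items():
        _write(df, bundle, f"rpts_{rep}")
    _write(mean_rpts, bundle, "rpts_mean")

    meta = ds.gene_meta.set_index("gene")

    if config.run_dynamics:
        _run_dynamics(config, ds, rpts, mean_rpts, meta, bundle)
    if config.run_popgen and ds.has_popgen:
        _run_popgen(config, ds, bundle)

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "mirdyn_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {k: str(v) for k, v in bundle.outputs.items()},
        "summary": bundle.summary,
    }
    bundle.manifest_path = out_dir / "manifest.json"
    bundle.manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return bundle


def _run_dynamics(config, ds, rpts, mean_rpts, meta, bundle) -> None:
    # Expression profiling: z-scores + k-means over well-expressed genes.
    expressed = mean_rpts.loc[mean_rpts.max(axis=1) > config.clustering_min_rpts]
    if len(expressed) >= config.k_clusters:
        zmat = dynamics.zscore_profiles(expressed)
        clu = dynamics.kmeans_profiles(
            zmat, config.k_clusters, restarts=config.kmeans_restarts, seed=config.seed
        )
        _write(clu.assignments.to_frame(), bundle, "expression_clusters")
        bundle.summary["n_expressed_genes"] = int(len(expressed))
    else:
        logger.warning("too few expressed genes (%d) for k=%d clustering",
                       len(expressed), config.k_clusters)

    # Kinetic regression.
    mm = meta["multimapper_fraction"] if "multimapper_fraction" in meta.columns else None
    report = dynamics.filter_regression_genes(mean_rpts, ds.pri_density, config.filters, mm)
    kept = mean_rpts.loc[report.kept]
    bundle.summary["regression_genes"] = len(report.kept)
    bundle.summary["filter_casualties"] = {k: len(v) for k, v in report.removed.items()}
    if len(report.kept) >= 1:
        points = dynamics.build_regression_points(
            kept, ds.pri_density.reindex(report.kept), per_hour=config.per_hour_change
        )
        fits = dynamics.fit_per_gene(points)
        _write(fits, bundle, "kinetic_fits")
        pooled_r2 = dynamics.pooled_prediction_r2(fits, points)
        bundle.summary["pooled_prediction_r2"] = pooled_r2
        pred = dynamics.predict_change_rates(fits, points)
        err = dynamics.prediction_error_rates(
            points, pred, kept, min_level=config.error_rate_min_level
        )
        _write(err, bundle, "prediction_error_rates", index=False)

        if "five_prime_nt" in meta.columns:
            try:
                comp = dynamics.compare_coefficients_by_5p_nt(
                    fits, meta["five_prime_nt"]
                )
                bundle.summary["five_prime_comparison"] = {
                    "n_u": comp.n_u,
                    "n_other": comp.n_other,
                    "mean_u": comp.mean_u,
                    "mean_other": comp.mean_other,
                    "median_u": comp.median_u,
                    "median_other": comp.median_other,
                    "ks_D": comp.ks.statistic,
                    "ks_p": comp.ks.pvalue,
                }
            except ValueError as exc:
                logger.warning("5' nucleotide comparison skipped: %s", exc)

    # Half-lives.
    _write(dynamics.half_life_table(mean_rpts, config.halflife_range()), bundle, "half_lives")

    # Clustered-miRNA change-rate ANOVA (needs cluster ids and >= 2 replicates).
    if "cluster_id" in meta.columns and len(rpts) >= 2:
        membership = {
            g: c for g, c in meta["cluster_id"].items() if isinstance(c, str) and c not in (".", "")
        }
        if membership:
            prepped = {
                rep: dynamics.prepare_cluster_profiles(df, min_mean_rpts=config.cluster_min_mean_rpts)
                for rep, df in rpts.items()
            }
            anova = dynamics.cluster_change_anova(
                prepped, membership, per_hour=config.per_hour_change, alpha=config.anova_alpha
            )
            if not anova.empty:
                out = anova.copy()
                out["member_means"] = out["member_means"].map(json.dumps)
                _write(out, bundle, "cluster_anova", index=False)
                bundle.summary["anova_significant"] = int(anova["significant"].sum())


def _run_popgen(config, ds, bundle) -> None:
    targets = [
        popgen.enumerate_nontarget_variants(popgen.seed_target_hexamer(seq, name))
        for name, seq in ds.mirna_seqs.items()
    ]
    sites = popgen.find_polymorphic_target_sites(
        ds.utr_seqs,
        ds.utr_bed,
        ds.snps,
        targets,
        cds_bed=ds.cds_bed,
        gene_classes=ds.gene_classes,
        min_fpkm=config.min_fpkm,
    )
    _write(popgen.sites_to_frame(sites), bundle, "polymorphic_target_sites", index=False)
    bundle.summary["n_polymorphic_sites"] = len(sites)
    if not sites:
        return
    classes = dict(zip(ds.gene_classes["gene"], ds.gene_classes["gene_class"]))
    avoidance = popgen.relative_target_avoidance(
        sites, classes, threshold=config.avoidance_threshold
    )
    _write(
        pd.DataFrame(
            [
                {
                    "mirna": r.mirna,
                    "n_maternal": r.n_maternal,
                    "n_zygotic": r.n_zygotic,
                    "fraction_maternal": r.fraction_maternal,
                    "fraction_zygotic": r.fraction_zygotic,
                    "avoidance_ratio": r.ratio,
                }
                for r in avoidance
            ]
        ),
        bundle,
        "target_avoidance",
        index=False,
    )
    records = popgen.polarize_derived_sites(sites, ds.ortholog_map)
    if records:
        try:
            hist = popgen.daf_histogram(records, classes)
            _write(hist, bundle, "daf_histogram")
        except ValueError as exc:
            logger.warning("DAF histogram skipped: %s", exc)
        mat = [r.daf for r in records if classes.get(r.gene) == "maternal"]
        zyg = [r.daf for r in records if classes.get(r.gene) == "zygotic"]
        if mat and zyg:
            ks = popgen.ks_one_tailed(
                mat, zyg, alternative="greater",
                exact_max_product=config.ks_exact_max_product,
            )
            bundle.summary["daf_ks"] = {
                "D": ks.statistic,
                "p": ks.pvalue,
                "n_maternal": ks.n1,
                "n_zygotic": ks.n2,
                "method": ks.method,
            }
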