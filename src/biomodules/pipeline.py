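"""End-to-end pipeline runner with a validated configuration and manifest.

Stages run in order: peak intersection -> region-to-gene annotation ->
expression preprocessing (batch correction, IQR filter) -> per-gene DE/CE
statistics -> biomodule extraction -> gene-set enrichment.  All outputs are
plain TSV/JSON; the manifest records parameters, seeds and stage outputs,
so a rerun with the same config reproduces the run (bit-identical for
deterministic stages, identical for seeded stochastic ones).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .errors import ConfigError, DataError
from . import annotation, biomodule, enrichment, expression, peaks, rankstats, seq2gene


@dataclass
class RunConfig:
    """Inputs and parameters of a full run; defaults are the method's own."""

    gff: str
    peaks_a: str
    peaks_b: str
    matrix: str
    samples: str
    gmt: str
    seed_gene: str
    group_a: str = "case"
    group_b: str = "control"
    peak_dialect: str = "bed3"
    radius: int = 150_000
    promoter_halfwidth: int = 2_000
    coding_only: bool = False
    correct_batch: bool = True
    protect_phenotype: bool = True
    iqr_keep_fraction: float = 0.5
    n_top: int = 150
    permutations: int = 1000
    q_max: float = 0.05
    fc_min: float = 2.0
    enrich_p_max: float = 0.001
    enrich_min_count: int = 6
    rng_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigError(f"incomplete config: {exc}")
        return cfg

    def validate(self) -> None:
        for name in ("gff", "peaks_a", "peaks_b", "matrix", "samples", "gmt"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"input file for {name!r} not found: {p}")
        if self.radius < 0 or self.promoter_halfwidth < 0:
            raise ConfigError("radius and promoter_halfwidth must be >= 0")
        if not 0 < self.iqr_keep_fraction <= 1:
            raise ConfigError("iqr_keep_fraction must be in (0, 1]")
        if self.n_top < 1 or self.permutations < 1:
            raise ConfigError("n_top and permutations must be >= 1")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    def _stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                _write_manifest(manifest, outdir)
                raise DataError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # 1. peaks
    def s_peaks():
        a = peaks.read_peaks(config.peaks_a, dialect=config.peak_dialect)
        b = peaks.read_peaks(config.peaks_b, dialect=config.peak_dialect)
        common = peaks.intersect_peaksets(a, b)
        path = peaks.write_bed(common, outdir / "co_enriched.bed")
        manifest["stages"]["peaks"] = {
            "n_a": len(a), "n_b": len(b), "n_co_enriched": len(common), "out": str(path),
        }
        return common

    common = _stage("peaks")(s_peaks)

    # 2. seq2gene
    def s_seq2gene():
        annset = annotation.load_gene_models(config.gff)
        index = annotation.build_index(annset)
        result = seq2gene.seq2gene(
            common,
            index,
            promoter_halfwidth=config.promoter_halfwidth,
            radius=config.radius,
            coding_only=config.coding_only,
        )
        seq2gene.links_table(result, index).to_csv(outdir / "links.tsv", sep="\t", index=False)
        (outdir / "seq2gene_summary.json").write_text(json.dumps(result.summary(), indent=2))
        manifest["stages"]["seq2gene"] = result.summary()
        return result

    s2g = _stage("seq2gene")(s_seq2gene)
    targets = seq2gene.target_genes(s2g)
    (outdir / "target_genes.txt").write_text("\n".join(sorted(targets)) + "\n")

    # 3. expression preprocessing
    def s_expression():
        values = expression.read_matrix(config.matrix)
        pheno, batch = expression.read_sample_sheet(config.samples)
        m = expression.ExpressionMatrix(values=values, phenotype=pheno, batch=batch)
        if config.correct_batch and m.batch.nunique() > 1:
            m = expression.correct_batches(m, protect=config.protect_phenotype)
        m = expression.iqr_filter(
            m, keep_fraction=config.iqr_keep_fraction, always_keep={config.seed_gene}
        )
        expression.write_matrix(m.values, outdir / "expr_preprocessed.tsv")
        manifest["stages"]["expression"] = {
            "n_genes": m.n_genes, "n_samples": m.n_samples,
            "batch_corrected": bool(config.correct_batch and m.batch.nunique() > 1),
        }
        return m

    m = _stage("expression")(s_expression)

    # 4. per-gene statistics
    def s_rankstats():
        stats = rankstats.ranked_gene_stats(
            m, seed_gene=config.seed_gene, group_a=config.group_a, group_b=config.group_b
        )
        stats.to_csv(outdir / "gene_stats.tsv", sep="\t", index_label="gene_id")
        up, down = rankstats.select_de_genes(stats, q_max=config.q_max, fc_min=config.fc_min)
        manifest["stages"]["rankstats"] = {
            "n_genes": len(stats), "n_up": len(up), "n_down": len(down),
            "prior_df": stats.attrs["prior_df"],
        }
        return stats

    stats = _stage("rankstats")(s_rankstats)

    # 5. biomodule
    def s_biomodule():
        mod = biomodule.extract_biomodule(
            stats,
            n_top=min(config.n_top, len(stats)),
            B=config.permutations,
            seed=config.rng_seed,
        )
        ce, de = biomodule.ordered_lists_from_stats(stats)
        curve = biomodule.overlap_curve(ce, de, n_max=min(config.n_top, len(stats)))
        curve.to_frame().to_csv(outdir / "overlap_curve.tsv", sep="\t", index=False)
        (outdir / "biomodule.txt").write_text("\n".join(sorted(mod.genes)) + "\n")
        manifest["stages"]["biomodule"] = mod.summary()
        return mod

    mod = _stage("biomodule")(s_biomodule)

    # 6. enrichment
    def s_enrichment():
        collection = enrichment.read_gmt(config.gmt)
        results = enrichment.enrich(
            mod.genes,
            collection,
            assay_genes=set(stats.index),
            p_max=config.enrich_p_max,
            min_count=config.enrich_min_count,
            filtered=False,
        )
        enrichment.results_table(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        passing = [
            r for r in results if r.p <= config.enrich_p_max and r.count >= config.enrich_min_count
        ]
        manifest["stages"]["enrichment"] = {
            "n_tested": len(results),
            "n_significant": len(passing),
            "top": passing[0].name if passing else None,
        }
        return results

    _stage("enrichment")(s_enrichment)

    _write_manifest(manifest, outdir)
    return manifest


def _sanitize(obj):
    """Strict-JSON-safe copy: non-finite floats become strings."""
    import math

    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    return obj


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(_sanitize(manifest), indent=2, sort_keys=True, allow_nan=False)
    )
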