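"""End-to-end orchestration: ingest a cohort, classify, and stage outputs.

The CLI is a thin layer over these functions; tests drive them directly.
A cohort is described by an :class:`InputSet` — either built explicitly or
discovered from a bundle directory (the layout the synthetic generator
emits, keyed by its ``manifest.json``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ingest
from .catalog import FeatureCatalog, FeatureLevel
from .classifier import ClassifierThresholds, classify_matrix
from .ingest import Assay, CopyNumberScale

log = logging.getLogger(__name__)

LEVELS = (FeatureLevel.GENE, FeatureLevel.ISOFORM, FeatureLevel.EXON)


@dataclass
class InputSet:
    """Paths to every external input of one cohort."""

    gtf: Path
    rna_vcf: dict[str, Path]
    wes_vcf: dict[str, Path]
    rna_counts: dict[str, Path]
    wes_counts: dict[str, Path]
    copy_number: Path
    cn_scale: CopyNumberScale = CopyNumberScale.LOG2_PSEUDO1_RELATIVE
    gene_list: Path | None = None
    sample_groups: Path | None = None
    drug_response: dict[str, Path] = field(default_factory=dict)

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path) -> "InputSet":
        """Discover inputs from a generated bundle directory via its manifest."""
        bundle_dir = Path(bundle_dir)
        manifest_path = bundle_dir / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"missing input: {manifest_path}")
        files = json.loads(manifest_path.read_text())["files"]

        def _paths(mapping):
            return {k: bundle_dir / v for k, v in mapping.items()}

        return cls(
            gtf=bundle_dir / files["annotation"],
            rna_vcf=_paths(files["rna_vcf"]),
            wes_vcf=_paths(files["wes_vcf"]),
            rna_counts=_paths(files["rna_counts"]),
            wes_counts=_paths(files["wes_counts"]),
            copy_number=bundle_dir / files["copy_number"],
            gene_list=bundle_dir / files["gene_list"],
            sample_groups=bundle_dir / files["sample_groups"],
            drug_response=_paths(files.get("drug_response", {})),
        )

    def validate(self) -> None:
        missing = []
        for p in [self.gtf, self.copy_number, self.gene_list, self.sample_groups,
                  *self.rna_vcf.values(), *self.wes_vcf.values(),
                  *self.rna_counts.values(), *self.wes_counts.values(),
                  *self.drug_response.values()]:
            if p is not None and not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError(f"missing input: {missing[0]}")


@dataclass
class ClassificationResult:
    catalog: FeatureCatalog
    calls: dict[str, pd.DataFrame]          # level -> long call table
    evidence: dict[str, pd.DataFrame]       # level -> long evidence table
    expression: dict[str, pd.DataFrame]     # level -> RNA expr (features x samples)
    base_table: pd.DataFrame                # per-SNV records, both assays
    qc_report: dict


def classify_cohort(
    inputs: InputSet,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    levels: tuple[FeatureLevel, ...] = LEVELS,
) -> ClassificationResult:
    """Run ingest + classification for every requested feature level."""
    inputs.validate()
    catalog = ingest.read_annotation(inputs.gtf)
    samples = sorted(inputs.rna_vcf)

    het_counts = {Assay.RNA: [], Assay.WES: []}
    base_rows = []
    for sample in samples:
        for assay, vcfs in ((Assay.RNA, inputs.rna_vcf), (Assay.WES, inputs.wes_vcf)):
            counts, bases = ingest.read_het_snvs(
                vcfs[sample], assay, catalog, sample_id=sample
            )
            het_counts[assay].append(counts)
            base_rows.append(bases)
    rna_het = pd.concat(het_counts[Assay.RNA], ignore_index=True)
    wes_het = pd.concat(het_counts[Assay.WES], ignore_index=True)
    base_table = pd.concat(base_rows, ignore_index=True)

    cn_linear, _ = ingest.read_copy_number(inputs.copy_number, inputs.cn_scale)

    rna_exon = {s: ingest.read_exon_counts(inputs.rna_counts[s], catalog) for s in samples}
    wes_exon = {s: ingest.read_exon_counts(inputs.wes_counts[s], catalog) for s in samples}

    calls, evidence, expression = {}, {}, {}
    for level in levels:
        level = FeatureLevel(level)
        rna_expr = {s: ingest.aggregate_expression(rna_exon[s], catalog, level) for s in samples}
        wes_cov = {s: ingest.aggregate_expression(wes_exon[s], catalog, level) for s in samples}
        ev = ingest.build_evidence(
            catalog, level, rna_expr, wes_cov, rna_het, wes_het, cn_linear
        )
        calls[level.value] = classify_matrix(ev, catalog, thresholds, level)
        evidence[level.value] = ev
        expression[level.value] = pd.DataFrame(rna_expr)
        log.info(
            "classified %d features x %d samples at %s level",
            len(catalog.ids(level)), len(samples), level.value,
        )

    qc_report = {
        "n_samples": len(samples),
        "thresholds": vars(thresholds) if hasattr(thresholds, "__dict__") else {
            f.name: getattr(thresholds, f.name)
            for f in thresholds.__dataclass_fields__.values()
        },
        "n_qc_discrepancy_flags": {
            lvl: int(df["qc_discrepancy_flag"].sum()) for lvl, df in calls.items()
        },
        "n_multi_chromosome_features": int(
            catalog.features["multi_chromosome_flag"].sum()
        ),
        "call_counts": {
            lvl: df["call"].value_counts().to_dict() for lvl, df in calls.items()
        },
    }
    return ClassificationResult(
        catalog=catalog,
        calls=calls,
        evidence=evidence,
        expression=expression,
        base_table=base_table,
        qc_report=qc_report,
    )


def write_classification(result: ClassificationResult, outdir: str | Path) -> dict[str, Path]:
    """Write call matrices, evidence, expression, SNV records, and QC report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for level, df in result.calls.items():
        path = outdir / f"calls_{level}.tsv"
        ingest.write_table(df, path)
        written[f"calls_{level}"] = path
    for level, df in result.expression.items():
        path = outdir / f"expression_{level}.tsv"
        ingest.write_table(df.rename_axis("feature_id").reset_index(), path)
        written[f"expression_{level}"] = path
    path = outdir / "snv_base_table.tsv"
    ingest.write_table(result.base_table, path)
    written["snv_base_table"] = path
    qc_path = outdir / "qc_report.json"
    qc_path.write_text(json.dumps(result.qc_report, indent=2, sort_keys=True) + "\n")
    written["qc_report"] = qc_path
    return written


def read_grouping(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    df = ingest.read_table(path).set_index("feature_id")
    return df.astype(float)
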