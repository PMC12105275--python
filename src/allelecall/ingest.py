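"""Readers and writers for all external inputs and outputs.

Inputs: GENCODE-style GTF annotation, per-sample VCFs (RNA-seq and WES),
htseq-count style exon count tables, a gene-level copy-number table, drug
response tables (PRISM / GDSC1 / GDSC2 style), and plain gene-list files.
All outputs are UTF-8 tab-delimited tables with a header row and '.' for
missing values.
"""

from __future__ import annotations

import logging
import math
import warnings
from enum import Enum
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .catalog import AUTOSOMES, FeatureCatalog, FeatureLevel, merged_interval_length

log = logging.getLogger(__name__)

#: Sentinel for log10 expression of a zero-count feature; compares below any
#: finite cutoff, so "not expressed" falls out of ordinary comparisons.
MINUS_INF = float("-inf")

MISSING = "."


class GtfError(ValueError):
    """Raised for malformed annotation input."""


class CopyNumberScale(str, Enum):
    """Scale of the input copy-number table.

    LOG2_PSEUDO1_RELATIVE: values v = log2(c/2 + 1) relative to a diploid
    baseline (v = 1 means two copies).  LINEAR_ABSOLUTE: values are already
    absolute copy counts.
    """

    LOG2_PSEUDO1_RELATIVE = "log2_pseudo1_relative"
    LINEAR_ABSOLUTE = "linear_absolute"


class Assay(str, Enum):
    RNA = "rna"
    WES = "wes"


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _validate_gtf(path: Path) -> str:
    lines = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                lines.append(line)
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GtfError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GtfError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GtfError(f"{path}: line {lineno}: bad interval {start}-{end}")
            lines.append(line)
    return "".join(lines)


def read_annotation(
    gtf_path: str | Path,
    autosome_names: tuple[str, ...] = AUTOSOMES,
) -> FeatureCatalog:
    """Load a GTF into a :class:`FeatureCatalog`.

    Non-autosomal records are dropped at load time.  A feature whose retained
    annotation still spans more than one chromosome is kept and flagged.  Exon
    lines repeated under several transcripts (same ``exon_id``) collapse into
    one exon record with multiple isoform parents.
    """
    gtf_path = Path(gtf_path)
    text = _validate_gtf(gtf_path)
    autosomes = set(autosome_names)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        merge_strategy="merge",
        id_spec={"gene": "gene_id", "transcript": "transcript_id", "exon": "exon_id"},
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    gene_rows: dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        gene_rows[g.id] = {"start": g.start, "end": g.end, "chroms": set()}

    iso_rows: dict[str, dict] = {}
    for t in db.features_of_type("transcript"):
        gene_id = t.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            raise GtfError(f"transcript {t.id} lacks gene_id")
        iso_rows[t.id] = {"gene_id": gene_id, "start": t.start, "end": t.end, "chroms": set()}

    exon_rows: dict[str, dict] = {}
    isoform_exons: dict[str, list[str]] = {t: [] for t in iso_rows}
    exon_isoforms: dict[str, list[str]] = {}
    for e in db.features_of_type("exon"):
        if e.seqid not in autosomes:
            continue
        parents = e.attributes.get("transcript_id", [])
        if not parents:
            raise GtfError(f"exon {e.id} has no transcript parent")
        gene_ids = set(e.attributes.get("gene_id", []))
        if len(gene_ids) != 1:
            raise GtfError(f"exon {e.id} maps to {len(gene_ids)} genes")
        exon_rows[e.id] = {
            "gene_id": gene_ids.pop(),
            "chrom": e.seqid,
            "start": e.start,
            "end": e.end,
        }
        exon_isoforms[e.id] = sorted(set(parents))
        for t in set(parents):
            if t not in isoform_exons:
                raise GtfError(f"exon {e.id} references unknown transcript {t}")
            isoform_exons[t].append(e.id)
            iso_rows[t]["chroms"].add(e.seqid)
            gene_rows[iso_rows[t]["gene_id"]]["chroms"].add(e.seqid)

    records = []
    gene_isoforms: dict[str, list[str]] = {g: [] for g in gene_rows}
    gene_exons: dict[str, set[str]] = {g: set() for g in gene_rows}

    kept_isoforms = {}
    for iso_id, row in sorted(iso_rows.items()):
        exon_ids = sorted(set(isoform_exons[iso_id]))
        if not exon_ids:  # entirely non-autosomal
            continue
        chroms = tuple(sorted(row["chroms"]))
        length = merged_interval_length(
            [(exon_rows[e]["start"], exon_rows[e]["end"]) for e in exon_ids]
        )
        kept_isoforms[iso_id] = exon_ids
        gene_isoforms[row["gene_id"]].append(iso_id)
        gene_exons[row["gene_id"]].update(exon_ids)
        records.append(
            dict(
                feature_id=iso_id,
                level=FeatureLevel.ISOFORM.value,
                gene_id=row["gene_id"],
                parent_id=row["gene_id"],
                chromosomes=chroms,
                start=row["start"],
                end=row["end"],
                exonic_length=length,
                multi_chromosome_flag=len(chroms) > 1,
            )
        )

    for gene_id, row in sorted(gene_rows.items()):
        exon_ids = sorted(gene_exons[gene_id])
        if not exon_ids:
            continue
        chroms = tuple(sorted(row["chroms"]))
        # union per chromosome, summed, so a (flagged) multi-chromosome gene
        # still gets a defined exonic length
        length = sum(
            merged_interval_length(
                [
                    (exon_rows[e]["start"], exon_rows[e]["end"])
                    for e in exon_ids
                    if exon_rows[e]["chrom"] == chrom
                ]
            )
            for chrom in chroms
        )
        records.append(
            dict(
                feature_id=gene_id,
                level=FeatureLevel.GENE.value,
                gene_id=gene_id,
                parent_id="",
                chromosomes=chroms,
                start=row["start"],
                end=row["end"],
                exonic_length=length,
                multi_chromosome_flag=len(chroms) > 1,
            )
        )

    for exon_id, row in sorted(exon_rows.items()):
        parents = [t for t in exon_isoforms[exon_id] if t in kept_isoforms]
        if not parents:
            continue
        records.append(
            dict(
                feature_id=exon_id,
                level=FeatureLevel.EXON.value,
                gene_id=row["gene_id"],
                parent_id=row["gene_id"],
                chromosomes=(row["chrom"],),
                start=row["start"],
                end=row["end"],
                exonic_length=row["end"] - row["start"] + 1,
                multi_chromosome_flag=False,
            )
        )

    if not records:
        raise GtfError(f"{gtf_path}: no autosomal features found")
    features = pd.DataFrame.from_records(records).set_index("feature_id")
    catalog = FeatureCatalog(
        features=features,
        exon_isoforms={e: tuple(v) for e, v in exon_isoforms.items() if e in features.index},
        isoform_exons={t: tuple(v) for t, v in kept_isoforms.items()},
        gene_isoforms={g: tuple(sorted(v)) for g, v in gene_isoforms.items() if v},
        gene_exons={g: tuple(sorted(v)) for g, v in gene_exons.items() if v},
    )
    log.info(
        "annotation %s: %d genes, %d isoforms, %d exons (autosomes only)",
        gtf_path.name,
        len(catalog.gene_isoforms),
        len(catalog.isoform_exons),
        len(catalog.exon_isoforms),
    )
    return catalog


# ---------------------------------------------------------------------------
# exon counts and expression
# ---------------------------------------------------------------------------

def read_exon_counts(counts_path: str | Path, catalog: FeatureCatalog) -> pd.Series:
    """Read a two-column (exon_id, count) table into counts over catalog exons.

    htseq-count summary rows (``__no_feature`` etc.) are ignored.  Unknown
    exon ids are skipped with a warning; catalog exons absent from the file
    get count 0.
    """
    counts_path = Path(counts_path)
    table = pd.read_csv(
        counts_path, sep="\t", header=None, names=["exon_id", "count"],
        dtype={"exon_id": str}, comment="#",
    ) if counts_path.stat().st_size else pd.DataFrame(columns=["exon_id", "count"])
    table = table[~table["exon_id"].str.startswith("__", na=False)]
    if table["exon_id"].duplicated().any():
        dups = table["exon_id"][table["exon_id"].duplicated()].tolist()
        raise ValueError(f"{counts_path}: duplicate exon ids {dups[:5]}")
    if (table["count"].astype(float) < 0).any():
        raise ValueError(f"{counts_path}: negative counts")
    exon_ids = catalog.ids(FeatureLevel.EXON)
    known = table["exon_id"].isin(exon_ids)
    n_unknown = int((~known).sum())
    if n_unknown:
        warnings.warn(
            f"{counts_path}: {n_unknown} exon id(s) absent from catalog; skipped",
            stacklevel=2,
        )
    counts = pd.Series(0, index=pd.Index(exon_ids, name="exon_id"), dtype="int64")
    sub = table[known]
    counts.loc[sub["exon_id"].to_numpy()] = sub["count"].astype("int64").to_numpy()
    return counts


def aggregate_expression(
    exon_counts: pd.Series,
    catalog: FeatureCatalog,
    level: FeatureLevel | str,
) -> pd.Series:
    """log10 length-normalized expression per feature at the requested level.

    expr = log10(sum of member exon counts / exonic length in bp); a feature
    with zero summed counts gets the MINUS_INF sentinel.  Shared exons count
    once per feature.
    """
    level = FeatureLevel(level)
    ids = catalog.ids(level)
    sums = np.empty(len(ids), dtype=float)
    lengths = catalog.features.loc[ids, "exonic_length"].to_numpy(dtype=float)
    for i, fid in enumerate(ids):
        members = catalog.members(fid, level)
        sums[i] = exon_counts.loc[list(members)].sum()
    with np.errstate(divide="ignore"):
        expr = np.log10(sums / lengths)
    expr[sums == 0] = MINUS_INF
    return pd.Series(expr, index=pd.Index(ids, name="feature_id"), name="expr")


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def round_half_away(x: float) -> int:
    """Round half away from zero (so 1.5 -> 2, -1.5 -> -2)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def read_copy_number(
    cn_path: str | Path,
    input_scale: CopyNumberScale | str = CopyNumberScale.LOG2_PSEUDO1_RELATIVE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the gene-level copy-number table (gene_id + one column per sample).

    On the LOG2_PSEUDO1_RELATIVE scale, linear copies are recovered as
    ``c = 2 * (2**v - 1)`` (diploid baseline: v = 1 maps to 2 copies).
    Returns (cn_linear, cn_discrete) DataFrames, genes x samples; the discrete
    estimate rounds half away from zero.  Negative linear values are clamped
    to 0 with a warning.
    """
    input_scale = CopyNumberScale(input_scale)
    raw = pd.read_csv(cn_path, sep="\t", index_col=0)
    raw.index.name = "gene_id"
    if input_scale is CopyNumberScale.LOG2_PSEUDO1_RELATIVE:
        cn_linear = 2.0 * (np.power(2.0, raw.astype(float)) - 1.0)
    else:
        cn_linear = raw.astype(float)
    if (cn_linear < 0).any().any():
        warnings.warn(f"{cn_path}: negative copy-number values clamped to 0", stacklevel=2)
        cn_linear = cn_linear.clip(lower=0.0)
    cn_discrete = cn_linear.map(round_half_away)
    return cn_linear, cn_discrete


# ---------------------------------------------------------------------------
# VCF het SNVs
# ---------------------------------------------------------------------------

_GT_NAMES = {0: "hom_ref", 1: "het", 3: "hom_alt"}


def read_het_snvs(
    vcf_path: str | Path,
    assay: Assay | str,
    catalog: FeatureCatalog,
    sample_id: str | None = None,
    autosome_names: tuple[str, ...] = AUTOSOMES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count exonic heterozygous SNVs per feature and collect per-site records.

    Returns ``(het_counts, base_rows)``.  ``het_counts`` has one row per
    catalog feature (all levels) with the number of distinct exonic het SNV
    sites inside the feature.  ``base_rows`` holds one record per retained
    SNV x alternative base (het or hom-alt genotype) with the gene(s) it
    falls in, feeding the base-preference analysis.

    Only single-base substitutions are used; multi-allelic records are split
    per alternative base (site counted once toward het counts).  Intronic
    sites (inside a gene span but outside every exon) are excluded, as are
    sites on non-autosomes.  An unsorted VCF raises a ValueError.
    """
    assay = Assay(assay)
    vcf_path = Path(vcf_path)
    vcf = VCF(str(vcf_path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else vcf_path.stem

    autosomes = set(autosome_names)
    per_feature: dict[str, int] = {}
    rows: list[dict] = []
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()

    for v in vcf:
        chrom, pos = v.CHROM, v.POS
        if last is not None and chrom == last[0] and pos < last[1]:
            raise ValueError(f"{vcf_path}: unsorted at {chrom}:{pos}")
        if last is None or chrom != last[0]:
            if chrom in seen_chroms:
                raise ValueError(f"{vcf_path}: unsorted (chromosome {chrom} revisited)")
            seen_chroms.add(chrom)
        last = (chrom, pos)
        if chrom not in autosomes:
            continue
        if len(v.REF) != 1 or v.REF not in "ACGT":
            continue
        alts = [a for a in v.ALT if len(a) == 1 and a in "ACGT"]
        if not alts:
            continue
        gt = int(v.gt_types[0]) if len(v.gt_types) else 2
        if gt not in _GT_NAMES:
            continue
        hits = catalog.features_at(chrom, pos)
        feature_ids = hits["gene"] | hits["isoform"] | hits["exon"]
        if not feature_ids:  # intronic or intergenic
            continue
        if gt == 1:
            for fid in feature_ids:
                per_feature[fid] = per_feature.get(fid, 0) + 1
        for alt in alts:
            for gene_id in sorted(hits["gene"]):
                rows.append(
                    dict(
                        snv_id=f"{chrom}:{pos}:{v.REF}:{alt}",
                        chrom=chrom,
                        pos=pos,
                        ref=v.REF,
                        alt=alt,
                        sample_id=sample_id,
                        assay=assay.value,
                        genotype=_GT_NAMES[gt],
                        gene_id=gene_id,
                    )
                )
    vcf.close()

    all_ids = catalog.features.index
    counts = pd.DataFrame(
        {
            "feature_id": all_ids,
            "sample_id": sample_id,
            "het_snv_count": [per_feature.get(f, 0) for f in all_ids],
        }
    )
    base_cols = ["snv_id", "chrom", "pos", "ref", "alt", "sample_id", "assay",
                 "genotype", "gene_id"]
    base_rows = pd.DataFrame(rows, columns=base_cols)
    return counts, base_rows


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------

class DrugDataset(str, Enum):
    PRISM = "PRISM"
    GDSC1 = "GDSC1"
    GDSC2 = "GDSC2"


def read_drug_response(path: str | Path, dataset: DrugDataset | str) -> pd.DataFrame:
    """Read a drug response table into (agent_id, dataset, sample_id, log_ic50).

    Accepts either an ``ic50`` (linear scale, must be > 0) or a ``log_ic50``
    column.  Duplicate (agent, sample) measurements are averaged on the log
    scale for GDSC1 — the only dataset screened with replicate experiments —
    and are an error otherwise.
    """
    dataset = DrugDataset(dataset)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in table.columns}
    agent = cols.get("agent_id") or cols.get("agent")
    sample = cols.get("sample_id") or cols.get("sample") or cols.get("cell_line")
    if agent is None or sample is None:
        raise ValueError(f"{path}: need agent and sample columns, got {list(table.columns)}")
    if "log_ic50" in cols:
        log_ic50 = table[cols["log_ic50"]].astype(float)
    elif "ic50" in cols:
        ic50 = table[cols["ic50"]].astype(float)
        if (ic50 <= 0).any():
            raise ValueError(f"{path}: IC50 values must be positive on the linear scale")
        log_ic50 = np.log10(ic50)
    else:
        raise ValueError(f"{path}: need an ic50 or log_ic50 column")
    out = pd.DataFrame(
        {
            "agent_id": table[agent].astype(str),
            "dataset": dataset.value,
            "sample_id": table[sample].astype(str),
            "log_ic50": log_ic50,
        }
    )
    dup = out.duplicated(subset=["agent_id", "sample_id"], keep=False)
    if dup.any():
        if dataset is DrugDataset.GDSC1:
            out = (
                out.groupby(["agent_id", "dataset", "sample_id"], as_index=False, sort=True)
                ["log_ic50"].mean()
            )
        else:
            raise ValueError(
                f"{path}: duplicate (agent, sample) rows in {dataset.value}"
            )
    return out.reset_index(drop=True)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# ---------------------------------------------------------------------------
# evidence assembly and generic table IO
# ---------------------------------------------------------------------------

def build_evidence(
    catalog: FeatureCatalog,
    level: FeatureLevel | str,
    rna_expr: dict[str, pd.Series],
    wes_cov: dict[str, pd.Series],
    rna_het: pd.DataFrame,
    wes_het: pd.DataFrame,
    cn_linear: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble per feature x sample evidence at one level.

    ``rna_expr`` / ``wes_cov`` map sample_id to the aggregate_expression
    Series at this level; ``rna_het`` / ``wes_het`` are long count tables
    from :func:`read_het_snvs`; ``cn_linear`` is genes x samples.  Copy
    number is gene-level: every feature inherits its parent gene's value
    (missing genes get NaN, which no threshold comparison can satisfy).
    """
    level = FeatureLevel(level)
    ids = catalog.ids(level)
    samples = sorted(rna_expr)
    gene_of = catalog.features.loc[ids, "gene_id"]

    def _het_matrix(counts: pd.DataFrame) -> pd.DataFrame:
        wide = counts.pivot(index="feature_id", columns="sample_id", values="het_snv_count")
        return wide.reindex(index=ids, columns=samples).fillna(0).astype(int)

    rna_het_m = _het_matrix(rna_het)
    wes_het_m = _het_matrix(wes_het)
    cn = cn_linear.reindex(index=gene_of.unique(), columns=samples)

    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": ids,
                    "sample_id": s,
                    "rna_het_snv_count": rna_het_m[s].to_numpy(),
                    "wes_het_snv_count": wes_het_m[s].to_numpy(),
                    "rna_expr": rna_expr[s].reindex(ids).to_numpy(),
                    "wes_cov": wes_cov[s].reindex(ids).to_numpy(),
                    "cn_linear": cn[s].reindex(gene_of.to_numpy()).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header, '.' for missing, no index column."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)
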