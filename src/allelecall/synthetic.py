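"""Synthetic multi-omic cohorts with known allelic-expression truth.

Emits a complete, internally consistent input bundle — GTF annotation,
per-sample RNA-seq and WES VCFs, per-sample exon count tables for both
assays, a gene-level copy-number table on the log2(c/2 + 1) scale, drug
response tables (with planted GDSC1 replicate rows), a curated "imprinted"
gene list, and a sample-to-histology grouping — together with truth labels
for every feature x sample and a mechanism label for every SNV site.

The simulated biology:

- an *imprinted* fraction of genes is monoallelic by parental origin; per
  cell line, each such gene escapes to biallelic expression with the
  loss-of-imprinting probability.  The expressed haplotype is a fair coin
  per cell line, independent of the bases it carries, so flip tests on
  these SNVs behave like the null;
- a *base-biased* fraction of the background genes is monoallelic with a
  fixed preferred allele expressed with high probability per cell line
  (regulatory-variant or RNA-editing-like mechanisms);
- copy-loss genes carry fewer than 1.5 copies; silent genes have zero RNA
  reads; everything else is biallelic.

Read counts are negative binomial per exon (configurable dispersion; 0
gives deterministic counts), emulating overdispersed bulk RNA-seq without
fitting real data.  Heterozygous sites are shared polymorphic positions
with per-cell-line genotypes, so the same SNV is informative in several
cell lines, as the flip test requires.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import FeatureLevel
from .classifier import (
    CALL_BIALLELIC,
    CALL_COPY_NUMBER_LOSS,
    CALL_MONOALLELIC,
    CALL_NO_SNV_DATA,
    CALL_NOT_EXPRESSED,
)

MECH_IMPRINT_LIKE = "imprint_like"
MECH_BASE_BIASED = "base_biased"
MECH_BIALLELIC = "biallelic"

_BASES = "ACGT"


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the cohort structure the pipeline targets: a curated
    imprinted set whose informative calls are monoallelic about 22% of the
    time (loss of imprinting is pervasive in cancer lines), a 13.5%
    monoallelic background, occasional copy loss and silent genes, and
    null drug response unless effects are planted.
    """

    seed: int
    n_samples: int = 24
    n_genes: int = 60
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_isoform: tuple[int, int] = (2, 5)
    fraction_imprinted: float = 0.15
    fraction_copy_loss: float = 0.05
    fraction_silent: float = 0.10
    fraction_loi: float = 0.781          # P(biallelic | imprinted, informative)
    fraction_background_mono: float = 0.135
    base_bias_probability: float = 0.95  # P(preferred allele | base-biased, per line)
    het_snv_rate: float = 3.0            # candidate polymorphic sites per exonic kb
    het_site_prob: float = 0.5           # P(a cell line is het at a candidate site)
    hom_alt_prob: float = 0.10           # P(hom-alt), exercising the flip-test filter
    read_rate_per_bp: float = 1.0        # mean reads per exonic bp (both assays)
    count_dispersion: float = 0.1        # NB dispersion; 0 = deterministic counts
    cn_noise_sd: float = 0.05            # SD of diploid copy-number noise; 0 = none
    n_agents: int = 20
    datasets: tuple[str, ...] = ("PRISM", "GDSC1")
    gdsc1_duplicate_fraction: float = 0.1
    drug_response_sd: float = 1.0
    drug_effects: tuple[tuple[str, str, str, float], ...] = ()
    n_groups: int = 3

    def __post_init__(self) -> None:
        for name in (
            "fraction_imprinted", "fraction_copy_loss", "fraction_silent",
            "fraction_loi", "fraction_background_mono", "base_bias_probability",
            "het_site_prob", "hom_alt_prob", "gdsc1_duplicate_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fraction_copy_loss + self.fraction_silent > 1.0:
            raise ValueError("fraction_copy_loss + fraction_silent exceeds 1")
        if self.het_site_prob + self.hom_alt_prob > 1.0:
            raise ValueError("het_site_prob + hom_alt_prob exceeds 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def noise_free(self) -> "CohortConfig":
        """Copy of the config with count and copy-number noise switched off."""
        return dataclasses.replace(self, count_dispersion=0.0, cn_noise_sd=0.0)


@dataclass
class CohortBundle:
    """Paths and truth for one generated cohort."""

    outdir: Path
    config: CohortConfig
    paths: dict
    sample_ids: list[str]
    grouping: dict[str, str]
    imprinted_genes: list[str]
    gene_table: pd.DataFrame        # gene_id, expr_class, mechanism, imprinted
    truth_calls: pd.DataFrame       # level, feature_id, sample_id, true_call
    truth_snvs: pd.DataFrame        # snv_id, gene_id, mechanism
    planted_effects: list = field(default_factory=list)


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(round(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def _gene_structures(cfg: CohortConfig, rng: np.random.Generator) -> list[dict]:
    lo_i, hi_i = cfg.isoforms_per_gene
    lo_e, hi_e = cfg.exons_per_isoform
    cursors = {f"chr{i}": 10_000 for i in range(1, 23)}
    genes = []
    for gi in range(cfg.n_genes):
        gene_id = f"G{gi + 1:04d}"
        chrom = f"chr{(gi % 22) + 1}"
        pool_size = int(rng.integers(lo_e, hi_e + 1))
        pos = cursors[chrom]
        exons = []
        for ei in range(pool_size):
            length = int(rng.integers(120, 400))
            exons.append((f"{gene_id}:E{ei + 1:02d}", pos, pos + length - 1))
            pos += length + int(rng.integers(200, 800))
        cursors[chrom] = pos + 5_000
        n_iso = int(rng.integers(lo_i, hi_i + 1))
        isoforms = {}
        for ti in range(n_iso):
            iso_id = f"{gene_id}.T{ti + 1}"
            if ti == 0:
                window = list(range(pool_size))  # first isoform spans the pool
            else:
                m = int(rng.integers(1, pool_size + 1))
                off = int(rng.integers(0, pool_size - m + 1))
                window = list(range(off, off + m))
            isoforms[iso_id] = [exons[k][0] for k in window]
        genes.append(
            dict(gene_id=gene_id, chrom=chrom, exons=exons, isoforms=isoforms)
        )
    return genes


def _assign_classes(cfg: CohortConfig, genes: list[dict], rng: np.random.Generator) -> None:
    n = len(genes)
    order = rng.permutation(n)
    n_imp = int(round(cfg.fraction_imprinted * n))
    imprinted = set(order[:n_imp])
    order2 = rng.permutation(n)
    n_loss = int(round(cfg.fraction_copy_loss * n))
    n_silent = int(round(cfg.fraction_silent * n))
    loss = set(order2[:n_loss])
    silent = set(order2[n_loss:n_loss + n_silent])
    for i, g in enumerate(genes):
        g["imprinted"] = i in imprinted
        g["expr_class"] = (
            "copy_loss" if i in loss else "silent" if i in silent else "active"
        )
        if g["imprinted"]:
            g["mechanism"] = MECH_IMPRINT_LIKE
        elif rng.random() < cfg.fraction_background_mono:
            g["mechanism"] = MECH_BASE_BIASED
        else:
            g["mechanism"] = MECH_BIALLELIC


def _place_sites(cfg: CohortConfig, genes: list[dict], rng: np.random.Generator) -> None:
    for g in genes:
        exonic = [(s, e) for _, s, e in g["exons"]]
        exonic_bp = sum(e - s + 1 for s, e in exonic)
        n_sites = int(rng.poisson(cfg.het_snv_rate * exonic_bp / 1000.0))
        positions: set[int] = set()
        flat = np.concatenate([np.arange(s, e + 1) for s, e in exonic])
        n_sites = min(n_sites, len(flat))
        if n_sites:
            positions = set(rng.choice(flat, size=n_sites, replace=False).tolist())
        sites = []
        for pos in sorted(positions):
            ref = _BASES[int(rng.integers(4))]
            alt = rng.choice([b for b in _BASES if b != ref])
            sites.append(
                dict(
                    pos=int(pos),
                    ref=ref,
                    alt=str(alt),
                    alt_on_hap_a=bool(rng.random() < 0.5),
                    prefer_alt=bool(rng.random() < 0.5),  # base-biased mechanism
                )
            )
        g["sites"] = sites


def _feature_sites(g: dict) -> dict[str, list[int]]:
    """Site indices (into g['sites']) per feature id of the gene."""
    out: dict[str, list[int]] = {g["gene_id"]: list(range(len(g["sites"])))}
    exon_span = {eid: (s, e) for eid, s, e in g["exons"]}
    for eid, (s, e) in exon_span.items():
        out[eid] = [i for i, st in enumerate(g["sites"]) if s <= st["pos"] <= e]
    for iso_id, exon_ids in g["isoforms"].items():
        idx: set[int] = set()
        for eid in exon_ids:
            idx.update(out[eid])
        out[iso_id] = sorted(idx)
    return out


def _write_gtf(path: Path, genes: list[dict]) -> None:
    def attrs(**kv):
        return " ".join(f'{k} "{v}";' for k, v in kv.items())

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##description: synthetic cohort annotation\n")
        for g in genes:
            start = min(s for _, s, _ in g["exons"])
            end = max(e for _, _, e in g["exons"])
            fh.write(
                "\t".join(
                    [g["chrom"], "synthetic", "gene", str(start), str(end), ".",
                     "+", ".", attrs(gene_id=g["gene_id"])]
                ) + "\n"
            )
            exon_span = {eid: (s, e) for eid, s, e in g["exons"]}
            for iso_id in sorted(g["isoforms"]):
                exon_ids = g["isoforms"][iso_id]
                ts = min(exon_span[e][0] for e in exon_ids)
                te = max(exon_span[e][1] for e in exon_ids)
                fh.write(
                    "\t".join(
                        [g["chrom"], "synthetic", "transcript", str(ts), str(te),
                         ".", "+", ".",
                         attrs(gene_id=g["gene_id"], transcript_id=iso_id)]
                    ) + "\n"
                )
                for eid in sorted(exon_ids, key=lambda x: exon_span[x][0]):
                    s, e = exon_span[eid]
                    fh.write(
                        "\t".join(
                            [g["chrom"], "synthetic", "exon", str(s), str(e), ".",
                             "+", ".",
                             attrs(gene_id=g["gene_id"], transcript_id=iso_id,
                                   exon_id=eid)]
                        ) + "\n"
                    )


def _write_vcf(path: Path, sample_id: str, records: list[tuple[str, int, str, str, str]]) -> None:
    chrom_order = {f"chr{i}": i for i in range(1, 23)}
    records = sorted(records, key=lambda r: (chrom_order[r[0]], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for i in range(1, 23):
            fh.write(f"##contig=<ID=chr{i}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for chrom, pos, ref, alt, gt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def generate_cohort(config: CohortConfig, outdir: str | Path) -> CohortBundle:
    """Generate a full cohort bundle under ``outdir``.

    Deterministic: the same config (including seed) produces byte-identical
    files.  Returns a :class:`CohortBundle` with paths and truth labels.
    """
    cfg = config
    outdir = Path(outdir)
    for sub in ("vcf/rna", "vcf/wes", "counts/rna", "counts/wes", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    genes = _gene_structures(cfg, rng)
    _assign_classes(cfg, genes, rng)
    _place_sites(cfg, genes, rng)
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    grouping = {s: f"histology_{(i % cfg.n_groups) + 1}" for i, s in enumerate(samples)}

    # per gene x sample x site genotypes: 0 hom-ref, 1 het, 2 hom-alt
    genotypes: dict[str, np.ndarray] = {}
    # per gene x sample expression state: True = monoallelic this sample
    mono_state: dict[str, np.ndarray] = {}
    expressed_hap_a: dict[str, np.ndarray] = {}
    for g in genes:
        n_sites = len(g["sites"])
        u = rng.random((cfg.n_samples, n_sites))
        gt = np.zeros((cfg.n_samples, n_sites), dtype=int)
        gt[u < cfg.het_site_prob] = 1
        gt[(u >= cfg.het_site_prob) & (u < cfg.het_site_prob + cfg.hom_alt_prob)] = 2
        genotypes[g["gene_id"]] = gt
        if g["expr_class"] == "copy_loss":
            mono = np.ones(cfg.n_samples, dtype=bool)  # one allele left
        elif g["mechanism"] == MECH_IMPRINT_LIKE:
            mono = rng.random(cfg.n_samples) >= cfg.fraction_loi
        elif g["mechanism"] == MECH_BASE_BIASED:
            mono = np.ones(cfg.n_samples, dtype=bool)
        else:
            mono = np.zeros(cfg.n_samples, dtype=bool)
        mono_state[g["gene_id"]] = mono
        expressed_hap_a[g["gene_id"]] = rng.random(cfg.n_samples) < 0.5

    # base-biased expressed-allele draws (per sample x site)
    bias_draw: dict[str, np.ndarray] = {
        g["gene_id"]: rng.random((cfg.n_samples, len(g["sites"])))
        for g in genes
    }

    # ------------------------------------------------------------------ VCFs
    paths: dict = {"rna_vcf": {}, "wes_vcf": {}, "rna_counts": {}, "wes_counts": {}}
    for si, sample in enumerate(samples):
        wes_records, rna_records = [], []
        for g in genes:
            gt = genotypes[g["gene_id"]][si]
            expressed = g["expr_class"] != "silent"
            mono = mono_state[g["gene_id"]][si]
            hap_a = expressed_hap_a[g["gene_id"]][si]
            for k, site in enumerate(g["sites"]):
                rec = (g["chrom"], site["pos"], site["ref"], site["alt"])
                if gt[k] == 1:
                    wes_records.append((*rec, "0/1"))
                elif gt[k] == 2:
                    wes_records.append((*rec, "1/1"))
                if not expressed or gt[k] == 0:
                    continue
                if gt[k] == 2:
                    rna_records.append((*rec, "1/1"))
                    continue
                if not mono:
                    rna_records.append((*rec, "0/1"))
                    continue
                if g["mechanism"] == MECH_BASE_BIASED and g["expr_class"] != "copy_loss":
                    prefer_alt = site["prefer_alt"]
                    takes_pref = bias_draw[g["gene_id"]][si, k] < cfg.base_bias_probability
                    alt_expressed = prefer_alt == takes_pref
                else:  # imprint-like / copy-loss: haplotype decides
                    alt_expressed = site["alt_on_hap_a"] == hap_a
                if alt_expressed:
                    rna_records.append((*rec, "1/1"))
                # reference-base expression leaves no RNA variant record
        wes_path = outdir / "vcf" / "wes" / f"{sample}.vcf"
        rna_path = outdir / "vcf" / "rna" / f"{sample}.vcf"
        _write_vcf(wes_path, sample, wes_records)
        _write_vcf(rna_path, sample, rna_records)
        paths["wes_vcf"][sample] = wes_path
        paths["rna_vcf"][sample] = rna_path

    # ---------------------------------------------------------------- counts
    for si, sample in enumerate(samples):
        for assay in ("rna", "wes"):
            rows = []
            for g in genes:
                silent_here = assay == "rna" and g["expr_class"] == "silent"
                for eid, s, e in g["exons"]:
                    mean = cfg.read_rate_per_bp * (e - s + 1)
                    count = 0 if silent_here else _nb_counts(rng, mean, cfg.count_dispersion)
                    rows.append((eid, count))
            path = outdir / "counts" / assay / f"{sample}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                for eid, count in rows:
                    fh.write(f"{eid}\t{count}\n")
            paths[f"{assay}_counts"][sample] = path

    # ----------------------------------------------------------- copy number
    cn_rows = {}
    for g in genes:
        if g["expr_class"] == "copy_loss":
            if cfg.cn_noise_sd > 0:
                cn = rng.uniform(0.6, 1.35, size=cfg.n_samples)
            else:
                cn = np.full(cfg.n_samples, 1.0)
        else:
            cn = 2.0 + (
                rng.normal(0.0, cfg.cn_noise_sd, size=cfg.n_samples)
                if cfg.cn_noise_sd > 0 else np.zeros(cfg.n_samples)
            )
            cn = np.clip(cn, 1.6, None)  # keep diploid noise clear of the loss rule
        cn_rows[g["gene_id"]] = np.log2(cn / 2.0 + 1.0)
    cn_df = pd.DataFrame(cn_rows, index=samples).T
    cn_df.index.name = "gene_id"
    cn_path = outdir / "copy_number.tsv"
    cn_df.to_csv(cn_path, sep="\t")
    paths["copy_number"] = cn_path

    # ---------------------------------------------------------- drug response
    effects = list(cfg.drug_effects)
    mono_gene = {g["gene_id"]: mono_state[g["gene_id"]] for g in genes}
    drug_paths = {}
    for dataset in cfg.datasets:
        rows = []
        n_dup = (
            int(np.ceil(cfg.gdsc1_duplicate_fraction * cfg.n_agents))
            if dataset == "GDSC1" else 0
        )
        for ai in range(cfg.n_agents):
            agent = f"{dataset}_A{ai + 1:03d}"
            base = rng.normal(0.0, cfg.drug_response_sd, size=cfg.n_samples)
            for gene_id, eff_agent, eff_dataset, shift in effects:
                if eff_agent == agent and eff_dataset == dataset:
                    base = base + shift * mono_gene[gene_id].astype(float)
            for si, sample in enumerate(samples):
                if ai < n_dup:
                    jitter = rng.normal(0.0, 0.05)
                    rows.append((agent, sample, base[si] + jitter))
                    rows.append((agent, sample, base[si] - jitter))
                else:
                    rows.append((agent, sample, base[si]))
        df = pd.DataFrame(rows, columns=["agent_id", "sample_id", "log_ic50"])
        path = outdir / f"drug_response_{dataset}.csv"
        df.to_csv(path, index=False)
        drug_paths[dataset] = path
    paths["drug_response"] = drug_paths

    # ------------------------------------------------------------- gene lists
    imprinted = sorted(g["gene_id"] for g in genes if g["imprinted"])
    gene_list_path = outdir / "imprinted_genes.txt"
    gene_list_path.write_text("".join(f"{g}\n" for g in imprinted), encoding="utf-8")
    paths["gene_list"] = gene_list_path

    groups_path = outdir / "sample_groups.tsv"
    with open(groups_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for s in samples:
            fh.write(f"{s}\t{grouping[s]}\n")
    paths["sample_groups"] = groups_path

    # ------------------------------------------------------------------ truth
    truth_rows = []
    snv_rows = []
    for g in genes:
        fsites = _feature_sites(g)
        level_of = {g["gene_id"]: FeatureLevel.GENE.value}
        for iso in g["isoforms"]:
            level_of[iso] = FeatureLevel.ISOFORM.value
        for eid, _, _ in g["exons"]:
            level_of[eid] = FeatureLevel.EXON.value
        gt = genotypes[g["gene_id"]]
        for fid, idx in fsites.items():
            for si, sample in enumerate(samples):
                n_het = int((gt[si, idx] == 1).sum()) if idx else 0
                if g["expr_class"] == "copy_loss":
                    call = CALL_COPY_NUMBER_LOSS
                elif n_het == 0:
                    call = CALL_NO_SNV_DATA
                elif g["expr_class"] == "silent":
                    call = CALL_NOT_EXPRESSED
                elif mono_state[g["gene_id"]][si]:
                    call = CALL_MONOALLELIC
                else:
                    call = CALL_BIALLELIC
                truth_rows.append((level_of[fid], fid, sample, call))
        for site in g["sites"]:
            snv_rows.append(
                (
                    f"{g['chrom']}:{site['pos']}:{site['ref']}:{site['alt']}",
                    g["gene_id"],
                    g["mechanism"],
                )
            )
    truth_calls = pd.DataFrame(
        truth_rows, columns=["level", "feature_id", "sample_id", "true_call"]
    )
    truth_snvs = pd.DataFrame(snv_rows, columns=["snv_id", "gene_id", "mechanism"])
    truth_calls_path = outdir / "truth" / "truth_calls.tsv"
    truth_snvs_path = outdir / "truth" / "truth_snvs.tsv"
    truth_calls.to_csv(truth_calls_path, sep="\t", index=False)
    truth_snvs.to_csv(truth_snvs_path, sep="\t", index=False)
    paths["truth_calls"] = truth_calls_path
    paths["truth_snvs"] = truth_snvs_path

    gtf_path = outdir / "annotation.gtf"
    _write_gtf(gtf_path, genes)
    paths["annotation"] = gtf_path

    gene_table = pd.DataFrame(
        [
            dict(
                gene_id=g["gene_id"],
                imprinted=g["imprinted"],
                expr_class=g["expr_class"],
                mechanism=g["mechanism"],
                n_sites=len(g["sites"]),
            )
            for g in genes
        ]
    )

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "samples": samples,
        "files": _relative_paths(paths, outdir),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    paths["manifest"] = outdir / "manifest.json"

    return CohortBundle(
        outdir=outdir,
        config=cfg,
        paths=paths,
        sample_ids=samples,
        grouping=grouping,
        imprinted_genes=imprinted,
        gene_table=gene_table,
        truth_calls=truth_calls,
        truth_snvs=truth_snvs,
    )


def _relative_paths(obj, root: Path):
    if isinstance(obj, dict):
        return {k: _relative_paths(v, root) for k, v in sorted(obj.items())}
    return str(Path(obj).relative_to(root))


def plant_drug_effect(
    bundle: CohortBundle,
    gene_id: str,
    agent_id: str,
    dataset: str,
    shift: float,
    min_per_arm: int = 3,
) -> pd.DataFrame:
    """Shift log10(IC50) of the monoallelic arm of a gene for one agent.

    The arm is the set of cell lines whose gene-level truth call is
    monoallelic; the biallelic truth calls form the other arm.  Raises if
    either arm has fewer than ``min_per_arm`` cell lines.  Rewrites the
    dataset's drug-response file in place and records the planted effect.
    """
    gene_truth = bundle.truth_calls[
        (bundle.truth_calls["level"] == FeatureLevel.GENE.value)
        & (bundle.truth_calls["feature_id"] == gene_id)
    ]
    if gene_truth.empty:
        raise ValueError(f"unknown gene {gene_id}")
    mono = set(gene_truth.loc[gene_truth["true_call"] == CALL_MONOALLELIC, "sample_id"])
    bi = set(gene_truth.loc[gene_truth["true_call"] == CALL_BIALLELIC, "sample_id"])
    if len(mono) < min_per_arm or len(bi) < min_per_arm:
        raise ValueError(
            f"arms too small for {gene_id}: {len(mono)} monoallelic, {len(bi)} biallelic"
        )
    path = bundle.paths["drug_response"][dataset]
    df = pd.read_csv(path)
    mask = (df["agent_id"] == agent_id) & (df["sample_id"].isin(mono))
    if not mask.any():
        raise ValueError(f"agent {agent_id} not found in {dataset}")
    df.loc[mask, "log_ic50"] += shift
    df.to_csv(path, index=False)
    bundle.planted_effects.append(
        dict(gene_id=gene_id, agent_id=agent_id, dataset=dataset, shift=shift,
             mono_samples=sorted(mono))
    )
    return df


def simulate_flip_counts(
    mechanism: str,
    n_snvs: int,
    seed: int,
    n_informative_range: tuple[int, int] = (6, 24),
    base_bias_probability: float = 0.95,
) -> pd.DataFrame:
    """Simulate per-SNV (n_ref, n_alt) counts under a named mechanism.

    imprint_like: each informative cell line expresses the reference base
    with probability 1/2 (parental origin is independent of base identity).
    base_biased: a fixed preferred allele (ref or alt with equal chance per
    SNV) is expressed with ``base_bias_probability`` per cell line.  Used
    for flip-test calibration and power checks without building files.
    """
    rng = np.random.default_rng(seed)
    lo, hi = n_informative_range
    n = rng.integers(lo, hi + 1, size=n_snvs)
    if mechanism == MECH_IMPRINT_LIKE:
        n_ref = rng.binomial(n, 0.5)
    elif mechanism == MECH_BASE_BIASED:
        prefer_ref = rng.random(n_snvs) < 0.5
        n_pref = rng.binomial(n, base_bias_probability)
        n_ref = np.where(prefer_ref, n_pref, n - n_pref)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return pd.DataFrame(
        {
            "snv_id": [f"snv{i:05d}" for i in range(n_snvs)],
            "gene_id": [f"g{i:05d}" for i in range(n_snvs)],
            "n_ref": n_ref.astype(int),
            "n_alt": (n - n_ref).astype(int),
        }
    )
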