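"""Reading and writing the pipeline's interchange formats.

Genotypes travel as multi-sample VCF (GT and DP per call, 1-based
positions, biallelic records — multi-allelic sites must be pre-split);
metadata and results travel as TSV; generator ground truth as JSON.
Infinite odds ratios serialise as the token ``Inf`` and zero as ``0``;
missing values as empty fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .cohort import MISSING, CohortBundle, TruthRecord

_GT_FOR_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(cohort: CohortBundle, path) -> None:
    """Write the cohort's genotypes (GT, DP) as an uncompressed VCF."""
    path = str(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for chrom in pd.unique(cohort.variants["chrom"]):
        header.contigs.add(str(chrom))
    for sid in cohort.sample_ids:
        header.add_sample(str(sid))
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, (vid, row) in enumerate(cohort.variants.iterrows()):
            rec = out.new_record(contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                                 stop=int(row["pos"]) - 1 + len(row["ref"]),
                                 alleles=(row["ref"], row["alt"]), id=str(vid))
            dcol = cohort.dosages[:, j]
            pcol = cohort.depths[:, j]
            for i, sid in enumerate(cohort.sample_ids):
                rec.samples[str(sid)]["GT"] = _GT_FOR_DOSAGE[int(dcol[i])]
                rec.samples[str(sid)]["DP"] = int(pcol[i])
            out.write(rec)


def read_vcf(path) -> tuple[np.ndarray, np.ndarray, list, pd.DataFrame]:
    """Read GT/DP from a VCF; returns (dosages, depths, sample ids, variant table)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dos_rows, dep_rows, meta = [], [], []
    for rec in vcf:
        gts = rec.genotype.array()
        d = gts[:, 0] + gts[:, 1]
        d[(gts[:, 0] < 0) | (gts[:, 1] < 0)] = MISSING
        dos_rows.append(d.astype(np.int8))
        dp = rec.format("DP")
        dep_rows.append(np.zeros(len(samples), dtype=np.int32) if dp is None
                        else dp[:, 0].astype(np.int32))
        meta.append({"variant_id": rec.ID, "chrom": rec.CHROM, "pos": rec.POS,
                     "ref": rec.REF, "alt": rec.ALT[0] if rec.ALT else "."})
    vcf.close()
    variants = pd.DataFrame(meta).set_index("variant_id")
    dosages = (np.stack(dos_rows, axis=1) if dos_rows
               else np.empty((len(samples), 0), dtype=np.int8))
    depths = (np.stack(dep_rows, axis=1) if dep_rows
              else np.empty((len(samples), 0), dtype=np.int32))
    return dosages, depths, samples, variants


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result/metadata table, serialising +-inf as Inf/-Inf tokens."""
    df = df.replace({np.inf: "Inf", -np.inf: "-Inf"})
    df.to_csv(path, sep="\t", index=index, na_rep="")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    return df.replace({"Inf": np.inf, "-Inf": -np.inf})


def write_truth(truth: TruthRecord, path) -> None:
    payload = {
        "true_or": truth.true_or,
        "enriched_genes": sorted(truth.enriched_genes),
        "planted_outlier_ids": sorted(truth.planted_outlier_ids),
        "related_pairs": [list(p) for p in truth.related_pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> TruthRecord:
    payload = json.loads(Path(path).read_text())
    return TruthRecord(
        true_or=payload["true_or"],
        enriched_genes=frozenset(payload["enriched_genes"]),
        planted_outlier_ids=frozenset(payload["planted_outlier_ids"]),
        related_pairs=[tuple(p) for p in payload["related_pairs"]],
    )


def write_cohort(cohort: CohortBundle, outdir) -> dict:
    """Write a full cohort (VCF + samples/variants/panel TSVs + truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "samples": outdir / "samples.tsv",
        "variants": outdir / "variants.tsv",
        "panel": outdir / "panel.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    write_tsv(cohort.samples, paths["samples"])
    write_tsv(cohort.variants, paths["variants"])
    write_tsv(cohort.panel, paths["panel"])
    if cohort.truth is not None:
        paths["truth"] = outdir / "truth.json"
        write_truth(cohort.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_cohort(outdir) -> CohortBundle:
    """Inverse of :func:`write_cohort` (truth optional)."""
    outdir = Path(outdir)
    dosages, depths, sample_ids, vcf_variants = read_vcf(outdir / "genotypes.vcf")
    samples = read_tsv(outdir / "samples.tsv")
    samples = samples.loc[sample_ids]
    variants = read_tsv(outdir / "variants.tsv")
    variants = variants.loc[vcf_variants.index]
    panel = read_tsv(outdir / "panel.tsv")
    truth_path = outdir / "truth.json"
    truth = read_truth(truth_path) if truth_path.exists() else None
    return CohortBundle(dosages=dosages, depths=depths, samples=samples,
                        variants=variants, panel=panel, truth=truth)
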