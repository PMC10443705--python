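"""File readers and writers.

Genotype TSV dialect: first column ``sample``, remaining columns marker
identifiers, cells in {0, 1, 2, NA}, tab-separated with a header row.
Phenotype TSV: a ``sample`` column plus numeric target/covariate columns
and optional string grouping columns; alignment to genotypes is by inner
join on sample id.  A VCF 4.x subset is supported through pysam: biallelic
SNP records only, GT converted to alternate-allele dosage (phasing
ignored), multi-allelic records skipped with a logged count.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pipeline import Dataset

logger = logging.getLogger("gpsel")


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or a biallelic-SNP VCF subset."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample":
        raise ValueError(f"{path}: first column must be 'sample', got {df.columns[0]!r}")
    samples = df["sample"].tolist()
    if len(set(samples)) != len(samples):
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    markers = list(df.columns[1:])
    raw = df[markers].to_numpy()
    dos = np.empty(raw.shape, dtype=np.int64)
    ok = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING}
    for (i, j), v in np.ndenumerate(raw):
        v = "NA" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
        if v not in ok:
            raise ValueError(
                f"{path}: malformed cell {v!r} at row {i + 2} (sample {samples[i]}), "
                f"column {markers[j]}"
            )
        dos[i, j] = ok[v]
    return GenotypeMatrix(samples, markers, dos)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        markers, cols = [], []
        n_skipped = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            mid = rec.id or f"{rec.chrom}:{rec.pos}"
            col = np.empty(len(samples), dtype=np.int64)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in gt if a == 1)
            markers.append(mid)
            cols.append(col)
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF record(s)", n_skipped)
    if not markers:
        raise ValueError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(samples, markers, np.column_stack(cols))


def write_genotypes(G: GenotypeMatrix, path) -> None:
    disp = G.dosages.astype(object)
    disp[G.dosages == G.missing_code] = "NA"
    df = pd.DataFrame(disp, columns=G.markers)
    df.insert(0, "sample", G.samples)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, target: str, covariates: list[str] | None = None,
                    group: str | None = None) -> pd.DataFrame:
    """Read the phenotype/covariate/grouping table; requires a sample column."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: 'sample' column required")
    for col in [target] + list(covariates or []) + ([group] if group else []):
        if col not in df.columns:
            raise ValueError(f"{path}: column {col!r} not found")
    for col in [target] + list(covariates or []):
        df[col] = pd.to_numeric(df[col])
    return df


def align_dataset(G: GenotypeMatrix, pheno: pd.DataFrame, target: str,
                  covariates: list[str] | None = None, group: str | None = None) -> Dataset:
    """Inner-join genotypes and phenotypes on sample id."""
    pheno = pheno.set_index("sample")
    shared = [s for s in G.samples if s in pheno.index]
    n_geno_only = G.n_samples - len(shared)
    n_pheno_only = len(pheno) - len(shared)
    if not shared:
        raise ValueError("no samples shared between genotypes and phenotypes")
    if n_geno_only or n_pheno_only:
        logger.info(
            "alignment: %d shared, %d genotype-only, %d phenotype-only samples",
            len(shared), n_geno_only, n_pheno_only,
        )
    idx = [G.samples.index(s) for s in shared]
    sub = pheno.loc[shared]
    return Dataset(
        G.subset_samples(np.asarray(idx)),
        sub[target].to_numpy(float),
        sub[list(covariates)].to_numpy(float) if covariates else None,
        sub[group].to_numpy() if group else None,
    )


def write_population(pop, outdir, prefix: str = "sim") -> dict:
    """Write a simulated population: genotype, phenotype and truth TSVs plus
    a manifest JSON.  Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    G = pop.genotypes()
    write_genotypes(G, outdir / f"{prefix}_geno.tsv")
    ph = pd.DataFrame({"sample": G.samples, "phenotype": pop.y})
    if pop.family is not None:
        ph["family"] = [f"fam{f}" for f in pop.family]
    ph.to_csv(outdir / f"{prefix}_pheno.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        {"sample": G.samples, "additive": pop.a, "dominance": pop.d,
         "genetic_value": pop.g, "phenotype": pop.y}
    )
    truth.to_csv(outdir / f"{prefix}_truth.tsv", sep="\t", index=False)
    qtl = pd.DataFrame(
        {"marker": [G.markers[i] for i in pop.qtl["index"]],
         "additive_effect": pop.qtl["additive_effect"],
         "dominance_effect": pop.qtl["dominance_effect"]}
    )
    qtl.to_csv(outdir / f"{prefix}_qtl.tsv", sep="\t", index=False)
    manifest = {
        "design": pop.design,
        "n": pop.n,
        "n_markers": G.n_markers,
        "n_qtl": len(pop.qtl["index"]),
        "h2_target": pop.h2_target,
        "h2_realised": pop.h2_realised,
        "files": {k: f"{prefix}_{k}.tsv" for k in ("geno", "pheno", "truth", "qtl")},
    }
    (outdir / f"{prefix}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
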