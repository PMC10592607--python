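"""Plain-text readers/writers for the pipeline's boundary formats.

Genotypes cross the boundary as VCF (GT from rounded dosage, DS with the
dosage itself); everything else is TSV: gene annotation (1-based
inclusive), quantification matrices (genes in rows, samples in columns),
GWAS summary statistics and ground-truth JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CascadeTruth, GWASSummary, OmicsMatrix, VariantTable

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: VariantTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j in range(genotypes.n_variants):
            ds = genotypes.dosage[:, j]
            cells = "\t".join(
                f"{_GT[int(round(d))]}:{d:g}" for d in ds
            )
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\t{genotypes.variant_id[j]}\t"
                f"{genotypes.ref_allele[j]}\t{genotypes.alt_allele[j]}\t.\tPASS\t.\tGT:DS\t{cells}\n"
            )


def read_vcf(path) -> VariantTable:
    """Read a dosage VCF written by :func:`write_vcf` (DS field preferred,
    GT fallback)."""
    meta, rows, samples = [], [], []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            rows.append(line.split("\t"))
    n_v = len(rows)
    dosage = np.zeros((len(samples), n_v))
    vid = np.empty(n_v, object)
    chrom = np.empty(n_v, object)
    pos = np.zeros(n_v, int)
    ref = np.empty(n_v, object)
    alt = np.empty(n_v, object)
    for j, r in enumerate(rows):
        chrom[j], pos[j], vid[j], ref[j], alt[j] = r[0], int(r[1]), r[2], r[3], r[4]
        fmt = r[8].split(":")
        ds_i = fmt.index("DS") if "DS" in fmt else None
        for i, cell in enumerate(r[9:]):
            parts = cell.split(":")
            if ds_i is not None:
                dosage[i, j] = float(parts[ds_i])
            else:
                dosage[i, j] = sum(int(a) for a in parts[0].replace("|", "/").split("/"))
    af = dosage.mean(axis=0) / 2
    return VariantTable(
        variant_id=vid, chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        maf=np.minimum(af, 1 - af), dosage=dosage, sample_ids=samples,
    )


def write_quantification(matrix: OmicsMatrix, path) -> None:
    """Genes in rows, samples in columns."""
    matrix.values.T.to_csv(path, sep="\t", index_label="gene_id")


def read_quantification(path, layer: str, stage: str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(layer=layer, stage=stage, values=df.T)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gwas(gwas: GWASSummary, path) -> None:
    out = gwas.table.rename(
        columns={"effect_allele": "A1", "other_allele": "A2", "zscore": "z", "pvalue": "p"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_gwas(path) -> GWASSummary:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(
        columns={"A1": "effect_allele", "A2": "other_allele", "z": "zscore", "p": "pvalue"}
    )
    if "zscore" not in df.columns:
        df["zscore"] = df["beta"] / df["se"]
    return GWASSummary(table=df)


def write_truth(truth: CascadeTruth, path) -> None:
    payload = {
        "genes": truth.genes.to_dict(orient="list"),
        "pleiotropy": truth.pleiotropy,
        "factor_loadings": {k: v.tolist() for k, v in truth.factor_loadings.items()},
        "n_hidden_factors": truth.n_hidden_factors,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> CascadeTruth:
    payload = json.loads(Path(path).read_text())
    return CascadeTruth(
        genes=pd.DataFrame(payload["genes"]),
        pleiotropy=payload["pleiotropy"],
        factor_loadings={k: np.array(v) for k, v in payload["factor_loadings"].items()},
        n_hidden_factors=payload["n_hidden_factors"],
    )
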