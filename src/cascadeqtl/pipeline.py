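"""End-to-end orchestration: simulate -> preprocess -> QTL map ->
attenuation -> specificity -> coloc -> TWAS -> MR, from a single config,
with deterministic per-stage seeds and a checksummed run manifest."""
from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attenuation, coloc, io, mr, preprocess, qtl, simulate, specificity, twas

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; thresholds default to the analysis
    conventions (FDR 0.1, PPH4 0.7, FWER 0.05, R_c^2 bounds 0.5/0.9,
    clump 1000 kb / r^2 0.5, 10,000 QTL permutations, 50 R_c^2
    permutations)."""

    out_dir: str = "run"
    seed: int = 0
    # simulation
    n_samples: int = 185
    n_gwas: int = 5000
    n_genes: int = 50
    variants_per_gene: int = 10
    ld_rho: float = 0.4
    lambda_r: float = 0.75
    lambda_p: float = 0.8
    eqtl_effect: float = 0.5
    eqtl_fraction: float = 0.8
    factor_sd: float = 0.3
    n_causal_outcome: int = 3
    outcome_h2: float = 0.3
    # preprocessing
    n_factors: dict = field(default_factory=lambda: {"mrna": 30, "ribo": 29, "protein": 19})
    factor_elbow: bool = True  # treat n_factors as caps, pick count by elbow rule
    cpm_threshold: float = 1.0
    max_low_fraction: float = 0.75
    z_cutoffs: dict = field(default_factory=lambda: {"mrna": -5.0, "ribo": -3.5, "protein": -6.0})
    # thresholds
    fdr: float = 0.1
    pph4: float = 0.7
    fwer: float = 0.05
    n_perm_qtl: int = 1000
    n_perm_rc2: int = 50
    clump_kb: float = 1000.0
    clump_r2: float = 0.5
    stages: list = field(
        default_factory=lambda: [
            "simulate", "preprocess", "map_qtl", "attenuation",
            "specificity", "coloc", "twas", "mr",
        ]
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: CRC of stage name mixed with the
        master seed, kept below 2^31."""
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run the configured stages, writing stage TSVs and a manifest.

    Returns the manifest dict (also written to ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "outputs": {}, "stages": {}}
    enabled = set(config.stages)

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _checksum(path)

    def require(stage: str, needed: str):
        if needed not in enabled:
            raise RuntimeError(f"stage '{stage}' requires disabled stage '{needed}'")

    # --- simulate -----------------------------------------------------
    if "simulate" not in enabled:
        raise RuntimeError("pipeline currently runs from synthetic inputs; enable 'simulate'")
    sseed = config.stage_seed("simulate")
    genotypes = simulate.simulate_genotypes(
        config.n_samples, config.n_genes * config.variants_per_gene,
        ld_block_size=config.variants_per_gene, ld_rho=config.ld_rho, seed=sseed,
    )
    truth = simulate.make_cascade_truth(
        genotypes, config.n_genes, seed=sseed + 1,
        eqtl_effect=config.eqtl_effect, eqtl_fraction=config.eqtl_fraction,
        lambda_r=config.lambda_r, lambda_p=config.lambda_p,
        factor_sd=config.factor_sd, n_causal_outcome=config.n_causal_outcome,
    )
    raw = simulate.simulate_cascade(genotypes, truth, seed=sseed + 2)
    gwas = simulate.simulate_gwas(
        genotypes, truth, config.outcome_h2, config.n_gwas, seed=sseed + 3
    )
    emit("genotypes.vcf", lambda p: io.write_vcf(genotypes, p))
    emit("annotation.tsv", lambda p: io.write_annotation(truth.annotation(), p))
    emit("gwas.tsv", lambda p: io.write_gwas(gwas, p))
    emit("truth.json", lambda p: io.write_truth(truth, p))
    for layer, mx in raw.items():
        emit(f"quant_{layer}_raw.tsv", lambda p, m=mx: io.write_quantification(m, p))
    manifest["stages"]["simulate"] = {
        "seed": sseed, "n_variants": genotypes.n_variants, "n_genes": config.n_genes
    }

    # --- preprocess ---------------------------------------------------
    require("map_qtl", "preprocess")
    layers = {}
    for layer, mx in raw.items():
        layers[layer] = preprocess.preprocess_layer(
            mx,
            n_factors=config.n_factors.get(layer, 10),
            cpm_threshold=config.cpm_threshold,
            max_low_fraction=config.max_low_fraction,
            z_cutoff=config.z_cutoffs.get(layer, -5.0),
            elbow=config.factor_elbow,
        )
        emit(
            f"quant_{layer}_residualized.tsv",
            lambda p, m=layers[layer]: io.write_quantification(m, p),
        )
    manifest["stages"]["preprocess"] = {
        layer: {"n_genes": len(m.gene_ids), "n_samples": len(m.sample_ids)}
        for layer, m in layers.items()
    }

    annotation = truth.annotation()

    # --- QTL mapping --------------------------------------------------
    qtl_df = None
    if "map_qtl" in enabled:
        qtl_df = qtl.map_cis_qtls(
            layers, genotypes, annotation,
            n_perm=config.n_perm_qtl, fdr=config.fdr,
            seed=config.stage_seed("map_qtl"),
        )
        emit("qtl.tsv", lambda p: qtl_df.to_csv(p, sep="\t", index=False))
        manifest["stages"]["map_qtl"] = {
            "n_rows": len(qtl_df),
            "n_significant": int(qtl_df["is_significant"].sum()),
        }

    # --- attenuation --------------------------------------------------
    if "attenuation" in enabled:
        require("attenuation", "map_qtl")
        rep = attenuation.replication_matrix(qtl_df, layers, genotypes)
        emit("replication_matrix.tsv", lambda p: rep.to_csv(p, sep="\t"))
        manifest["stages"]["attenuation"] = {
            "asymmetry": attenuation.asymmetry_statistics(rep).to_dict(orient="records")
        }

    # --- specificity --------------------------------------------------
    models = {}
    if "specificity" in enabled:
        calls, models = specificity.specificity_scan(
            layers, genotypes, annotation,
            n_perm=config.n_perm_rc2, seed=config.stage_seed("specificity"),
        )
        emit("specificity.tsv", lambda p: calls.to_csv(p, sep="\t", index=False))
        weights = pd.DataFrame(
            [
                {"gene_id": g, "layer": l, "variant_id": v, "weight": w}
                for (g, l), m in models.items()
                for v, w in m.weights.items()
            ]
        )
        emit("model_weights.tsv", lambda p: weights.to_csv(p, sep="\t", index=False))
        manifest["stages"]["specificity"] = {
            "n_classified": len(calls),
            "labels": calls["label"].value_counts().to_dict() if len(calls) else {},
        }

    # --- coloc --------------------------------------------------------
    if "coloc" in enabled:
        require("coloc", "map_qtl")
        rows = []
        sig = qtl_df[qtl_df["is_significant"]]
        for _, r in sig.iterrows():
            grow = annotation[annotation["gene_id"] == r["gene_id"]].iloc[0]
            expr = layers[r["layer"]].values[r["gene_id"]].to_numpy()
            try:
                res, flag = coloc.colocalize_gene(
                    grow, r["layer"], genotypes, expr, gwas, pph4_cutoff=config.pph4
                )
            except ValueError:
                continue
            d = vars(res)
            d["colocalized"] = flag
            rows.append(d)
        coloc_df = pd.DataFrame(rows)
        emit("coloc.tsv", lambda p: coloc_df.to_csv(p, sep="\t", index=False))
        manifest["stages"]["coloc"] = {
            "n_tested": len(coloc_df),
            "n_colocalized": int(coloc_df["colocalized"].sum()) if len(coloc_df) else 0,
        }

    # --- TWAS ---------------------------------------------------------
    twas_df = None
    if "twas" in enabled:
        require("twas", "specificity")
        twas_df = twas.twas_scan(models, gwas, genotypes, alpha=config.fwer)
        emit("twas.tsv", lambda p: twas_df.to_csv(p, sep="\t", index=False))
        manifest["stages"]["twas"] = {
            "n_tested": len(twas_df),
            "n_significant": int(twas_df["is_significant"].sum()) if len(twas_df) else 0,
        }

    # --- MR -----------------------------------------------------------
    if "mr" in enabled:
        require("mr", "map_qtl")
        mr_rows, verdicts = run_mr_stage(
            config, genotypes, layers, annotation, gwas,
            twas_df if twas_df is not None else pd.DataFrame(),
        )
        emit("mr.tsv", lambda p: mr_rows.to_csv(p, sep="\t", index=False))
        emit("cascade_verdicts.tsv", lambda p: verdicts.to_csv(p, sep="\t", index=False))
        manifest["stages"]["mr"] = {
            "n_tests": len(mr_rows),
            "classes": verdicts["cascade_class"].value_counts().to_dict()
            if len(verdicts) else {},
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_mr_stage(config, genotypes, layers, annotation, gwas, twas_df) -> tuple:
    """Two-sample MR (per gene x layer vs GWAS) and one-sample cascade MR."""
    gtab = gwas.table
    two_sample: list[mr.MRResult] = []
    eggers: dict[tuple[str, str], mr.MRResult] = {}
    genes = (
        twas_df[twas_df.get("is_significant", pd.Series(dtype=bool)) == True]  # noqa: E712
        if len(twas_df)
        else pd.DataFrame(columns=["gene_id", "layer"])
    )
    candidates = (
        genes[["gene_id", "layer"]].drop_duplicates().itertuples(index=False)
        if len(genes)
        else [
            (g, lay) for g in annotation["gene_id"] for lay in layers
        ]
    )
    for gid, layer in candidates:
        grow = annotation[annotation["gene_id"] == gid].iloc[0]
        if gid not in layers[layer].values.columns:
            continue
        expr = layers[layer].values[gid].to_numpy()
        scan = qtl.nominal_scan(qtl.cis_window(grow), genotypes, expr)
        if scan is None:
            continue
        ids = mr.ld_clump(scan, genotypes, config.clump_r2, config.clump_kb, 0.05)
        if not ids:
            continue
        exp_df = scan.set_index("variant_id").loc[ids].reset_index()
        exp_df = exp_df.rename(columns={"slope": "beta"})
        exp_df["effect_allele"] = genotypes.alt_allele[genotypes.index_of(exp_df["variant_id"])]
        exp_df["other_allele"] = genotypes.ref_allele[genotypes.index_of(exp_df["variant_id"])]
        out_df = gtab[gtab["variant_id"].isin(ids)]
        harm = mr.harmonize(exp_df, out_df)
        if len(harm) == 0:
            continue
        inst = mr.InstrumentSet(
            gene_id=gid, layer=layer, variant_ids=list(harm["variant_id"]),
            exposure_beta=harm["beta_exp"].to_numpy(), exposure_se=harm["se_exp"].to_numpy(),
            outcome_beta=harm["beta_out"].to_numpy(), outcome_se=harm["se_out"].to_numpy(),
        )
        res = mr.ivw(inst, outcome="gwas")
        two_sample.append(res)
        if inst.n >= 3:
            eggers[(gid, layer)] = mr.egger(inst, outcome="gwas")
    mr.apply_family_fdr(two_sample)
    for r in two_sample:
        r.verdict = mr.two_sample_verdict(r, eggers.get((r.gene_id, r.exposure)))

    # one-sample cascade between adjacent layers
    verdicts, one_sample = mr.one_sample_cascade(
        layers, genotypes, annotation,
        r2_max=config.clump_r2, window_kb=config.clump_kb,
    )
    all_rows = pd.DataFrame([vars(r) for r in two_sample + one_sample])
    return all_rows, verdicts
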