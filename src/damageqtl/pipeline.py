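"""End-to-end pipeline orchestration and coordinate conversion.

Runs the study-style flow (images -> damage table -> mixed model -> genotype
QC -> LD -> QTL windows) from a single declarative configuration, writing
per-stage CSV/VCF/BED outputs and a JSON manifest with input digests and
record counts at every stage so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .gwas import (
    build_qtl_windows,
    scan_association,
    significant_mtas,
    windows_to_bed,
    windows_to_table,
)
from .images import batch_quantify
from .lmm import fit_lmm
from .pedigree import build_pedigree_A
from .pheno import trial_qc
from .popgen import filter_snps, ld_decay, pairwise_r2, pc_covariates, read_vcf, \
    vanraden_kinship, write_vcf

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "convert_coordinates"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def convert_coordinates(
    intervals: Sequence[tuple[int, int]],
    from_: str = "one_based",
    to: str = "bed",
) -> list[tuple[int, int]]:
    """Convert intervals between 1-based inclusive and BED (0-based half-open).

    The 1-based inclusive interval [s, e] maps to BED (s - 1, e) and back;
    the round trip is the identity. Negative coordinates and zero-length
    BED intervals are rejected.
    """
    conventions = {"one_based", "bed"}
    if from_ not in conventions or to not in conventions:
        raise ValueError(f"conventions must be one of {sorted(conventions)}")
    out = []
    for s, e in intervals:
        s, e = int(s), int(e)
        if from_ == "one_based":
            if s < 1 or e < s:
                raise ValueError(f"invalid 1-based interval ({s}, {e})")
            s0, e0 = s - 1, e
        else:
            if s < 0 or e <= s:
                raise ValueError(f"invalid BED interval ({s}, {e})")
            s0, e0 = s + 1, e
        if from_ == to:
            out.append((s, e))
        elif to == "bed":
            out.append((s0, e0))
        else:  # bed -> one_based
            out.append((s0, e0))
    return out


@dataclass
class PipelineConfig:
    """Paths, method flags and thresholds for one pipeline run."""

    out_dir: str
    images_dir: str | None = None
    masks_dir: str | None = None
    background_color: tuple[float, float, float] | None = None
    background_tol: float = 2 / 255
    vcf: str | None = None
    pedigree: str | None = None
    phenotypes: str | None = None
    gene_table: str | None = None
    trait_col: str = "value"
    damage_method: str = "both"
    maf_min: float = 0.01
    call_rate_min: float = 0.40
    log10p_threshold: float = 6.0
    h2_qc_threshold: float = 0.2
    window_half_widths: tuple[int, ...] = (2000, 5000, 10000)
    ld_max_dist: int = 100_000
    ld_bin_width: int = 1000
    n_pcs: int = 3
    seed: int = 0
    resume: bool = False

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        payload.update(overrides)
        if "window_half_widths" in payload:
            payload["window_half_widths"] = tuple(payload["window_half_widths"])
        if payload.get("background_color") is not None:
            payload["background_color"] = tuple(payload["background_color"])
        return cls(**payload)

    def validate(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not 0 <= self.call_rate_min <= 1:
            raise ValueError("call_rate_min must lie in [0, 1]")
        if self.h2_qc_threshold < 0 or self.h2_qc_threshold > 1:
            raise ValueError("h2_qc_threshold must lie in [0, 1]")
        if self.damage_method not in ("dtr", "dqu", "both"):
            raise ValueError("damage_method must be 'dtr', 'dqu' or 'both'")
        for name in ("images_dir", "masks_dir", "vcf", "pedigree", "phenotypes",
                     "gene_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config field '{name}': path does not exist: {p}")
        Path(self.out_dir).mkdir(parents=True, exist_ok=True)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _stage_damage(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    table = batch_quantify(
        cfg.images_dir,
        method=cfg.damage_method,
        mask_dir=cfg.masks_dir,
        background_color=cfg.background_color,
        tol=cfg.background_tol,
    )
    path = out / "damage.csv"
    table.to_csv(path, index=False)
    manifest["stages"]["damage"] = {
        "outputs": [path.name],
        "n_images": int(table["image_id"].nunique()),
        "rows_out": len(table),
    }


def _stage_pheno(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    data = pd.read_csv(cfg.phenotypes)
    rows_in = len(data)
    qc = None
    if "trial" in data.columns and data["trial"].nunique() > 1:
        qc = trial_qc(data, threshold=cfg.h2_qc_threshold, trait_col=cfg.trait_col)
        data = data[data["trial"].astype(str).isin(qc["retained"])]
    A = None
    if cfg.pedigree is not None:
        A = build_pedigree_A(pd.read_csv(cfg.pedigree))
    blup_fit = fit_lmm(data, A=A, genotype_as="random", trait_col=cfg.trait_col)
    blue_fit = fit_lmm(data, genotype_as="fixed", trait_col=cfg.trait_col)
    pd.Series(blup_fit.varcomp).rename("variance").to_csv(out / "varcomp.csv")
    blup_fit.genotype_predictions.rename_axis("genotype").to_csv(out / "blups.csv")
    blue_fit.genotype_predictions.rename_axis("genotype").to_csv(out / "blues.csv")
    report = {
        "cullis_h2": blup_fit.cullis_h2(),
        "converged": blup_fit.converged,
        "trial_qc": qc,
    }
    (out / "h2_report.json").write_text(json.dumps(report, indent=1))
    manifest["stages"]["pheno"] = {
        "outputs": ["varcomp.csv", "blups.csv", "blues.csv", "h2_report.json"],
        "rows_in": rows_in,
        "rows_out": len(data),
        "rows_filtered": rows_in - len(data),
        "cullis_h2": report["cullis_h2"],
    }


def _stage_geno(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    g = read_vcf(cfg.vcf)
    filtered, report = filter_snps(g, cfg.maf_min, cfg.call_rate_min)
    write_vcf(filtered, out / "filtered.vcf")
    K = vanraden_kinship(filtered)
    pd.DataFrame(K, index=filtered.ids, columns=filtered.ids).to_csv(
        out / "kinship.csv"
    )
    scores, fractions = pc_covariates(filtered, n_pcs=cfg.n_pcs)
    pcs = pd.DataFrame(
        scores, index=filtered.ids,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    pcs.rename_axis("id").to_csv(out / "pcs.csv")
    pairs = pairwise_r2(filtered, max_dist=cfg.ld_max_dist, maf_min=cfg.maf_min)
    bins, decay = (
        ld_decay(pairs, bin_width=cfg.ld_bin_width) if not pairs.empty else ([], None)
    )
    pd.DataFrame(
        [
            {"distance_lo": b.distance_lo, "distance_hi": b.distance_hi,
             "mean_r2": b.mean_r2, "n_pairs": b.n_pairs}
            for b in bins
        ]
    ).to_csv(out / "ld_bins.csv", index=False)
    (out / "ld_decay.json").write_text(
        json.dumps({"decay_distance_bp": decay,
                    "pc_variance_fractions": list(map(float, fractions))}, indent=1)
    )
    manifest["stages"]["geno"] = {
        "outputs": ["filtered.vcf", "kinship.csv", "pcs.csv", "ld_bins.csv",
                    "ld_decay.json"],
        "rows_in": report["n_input"],
        "rows_out": report["n_kept"],
        "rows_filtered": report["n_input"] - report["n_kept"],
        "filter_report": report,
        "ld_decay_distance_bp": decay,
    }


def _stage_gwas(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    g = read_vcf(out / "filtered.vcf")
    blues = pd.read_csv(out / "blues.csv", index_col="genotype")
    trait_name = blues.columns[0]
    y = blues[trait_name]
    keep = [i for i, gid in enumerate(g.ids) if gid in y.index]
    if len(keep) < 3:
        raise ValueError("fewer than 3 individuals shared by genotypes and BLUEs")
    g = g.take_individuals(keep)
    scores, _ = pc_covariates(g, n_pcs=cfg.n_pcs)
    results = scan_association(g, y, covariates=scores)
    results.to_csv(out / "scan.csv", index=False)
    mtas, with_q = significant_mtas(
        results, threshold_log10p=cfg.log10p_threshold, trait=trait_name
    )
    with_q[-np.log10(with_q["p_value"]) > cfg.log10p_threshold].to_csv(
        out / "mtas.csv", index=False
    )
    windows = build_qtl_windows(mtas, half_widths=cfg.window_half_widths)
    window_outputs = []
    for w, wins in windows.items():
        windows_to_table(wins).to_csv(out / f"windows_{w}.csv", index=False)
        windows_to_bed(wins).to_csv(
            out / f"windows_{w}.bed", sep="\t", index=False, header=False
        )
        window_outputs += [f"windows_{w}.csv", f"windows_{w}.bed"]
    n_genes = None
    if cfg.gene_table is not None and windows:
        from .gwas import intersect_genes

        genes = pd.read_csv(cfg.gene_table)
        canonical = windows[max(windows)]
        hits = intersect_genes(canonical, genes)
        hits.to_csv(out / "genes.csv", index=False)
        window_outputs.append("genes.csv")
        n_genes = len(hits)
    manifest["stages"]["gwas"] = {
        "outputs": ["scan.csv", "mtas.csv"] + window_outputs,
        "rows_in": len(results),
        "n_mtas": len(mtas),
        "n_windows": {str(w): len(v) for w, v in windows.items()},
        "n_gene_overlaps": n_genes,
    }


_STAGES = {
    "damage": (_stage_damage, "images_dir"),
    "pheno": (_stage_pheno, "phenotypes"),
    "geno": (_stage_geno, "vcf"),
    "gwas": (_stage_gwas, "vcf"),
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages in order and write a JSON manifest.

    Stages whose required input is not configured are skipped. A stage
    failure raises :class:`PipelineError` naming the stage; outputs of
    earlier stages are retained. Returns the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.resolved(),
        "inputs": {},
        "stages": {},
    }
    for name in ("images_dir", "vcf", "pedigree", "phenotypes", "gene_table"):
        p = getattr(config, name)
        if p is not None and Path(p).is_file():
            manifest["inputs"][name] = {"path": str(p), "sha256_16": _digest(p)}
        elif p is not None:
            manifest["inputs"][name] = {"path": str(p)}

    # gwas depends on pheno + geno outputs
    gwas_ready = config.vcf is not None and config.phenotypes is not None
    for name, (fn, requirement) in _STAGES.items():
        if getattr(config, requirement) is None:
            continue
        if name == "gwas" and not gwas_ready:
            continue
        marker = out / f".stage_{name}.done"
        if config.resume and marker.exists():
            manifest["stages"][name] = {"skipped": "resume"}
            continue
        try:
            logger.info("pipeline stage: %s", name)
            fn(config, out, manifest)
            marker.write_text("done")
        except Exception as exc:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "config.resolved.json").write_text(
        json.dumps(config.resolved(), indent=1)
    )
    return manifest
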