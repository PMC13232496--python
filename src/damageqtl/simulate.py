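"""Synthetic data with known ground truth for every pipeline stage.

Generates:

* plant images whose tissue-class pixel counts are exact by construction,
  so threshold classification can be validated against planted truth;
* F1 biparental families of diploid biallelic SNP genotypes with tunable
  recombination, emulating a multi-family outcrossing mapping population
  (default family sizes 70/120/120/29, one shared susceptible tester parent);
* multi-trial phenotypes with genotype, genotype-by-trial, block and
  residual variance components plus planted additive QTL effects;
* insect survival counts bounded at a fixed infestation rate (default 6
  eggs per plant).

All generators take explicit integer seeds; no global random state is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .images import GREEN, NECROTIC, RGBImage, YELLOW
from .popgen import GenotypeMatrix

__all__ = [
    "ImageTruth",
    "FamilyDesign",
    "PhenoSimSpec",
    "TrialLayout",
    "PhenoSimTruth",
    "CLASS_SAMPLING_BOXES",
    "generate_plant_image",
    "write_image_fixture",
    "simulate_f1_families",
    "simulate_phenotypes",
    "simulate_insect_counts",
    "expected_entry_mean_h2",
]

#: Closed 8-bit RGB sampling boxes per tissue class, strictly interior to the
#: corresponding threshold-rule acceptance region (margin >= 5/255 on every
#: face) and outside the other two classes' rules, so that lossless PNG
#: round-trips preserve class membership exactly.
CLASS_SAMPLING_BOXES: Mapping[int, tuple[tuple[int, int], ...]] = {
    GREEN: ((40, 76), (140, 178), (64, 76)),
    YELLOW: ((178, 216), (128, 153), (77, 127)),
    NECROTIC: ((102, 140), (77, 102), (5, 11)),
}

_CLASS_ORDER = (GREEN, YELLOW, NECROTIC)


def _box_center(box: tuple[tuple[int, int], ...]) -> tuple[int, int, int]:
    return tuple((lo + hi) // 2 for lo, hi in box)  # type: ignore[return-value]


@dataclass
class ImageTruth:
    """Ground truth for one synthetic plant image.

    proportions are the fractions of plant pixels that are green, yellow and
    necrotic (must sum to 1); ``mask`` may be supplied or is generated.
    """

    proportions: tuple[float, float, float]
    n_plant_pixels: int
    background_color: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None
    seed: int = 0
    class_counts: tuple[int, int, int] | None = None  # filled by the generator

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any() or (p > 1).any():
            raise ValueError("proportions must be three fractions in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
        if self.n_plant_pixels < 1:
            raise ValueError("n_plant_pixels must be >= 1")
        if self.mask is not None and int(np.asarray(self.mask).sum()) != self.n_plant_pixels:
            raise ValueError("mask pixel count must equal n_plant_pixels")

    @property
    def damage(self) -> float:
        """Planted damage fraction (yellow + necrotic over all plant pixels)."""
        if self.class_counts is not None:
            g, y, n = self.class_counts
            return (y + n) / (g + y + n)
        return self.proportions[1] + self.proportions[2]


def _exact_counts(proportions: Sequence[float], n: int) -> np.ndarray:
    """Integer class counts summing to n, by largest-remainder apportionment."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def generate_plant_image(
    truth: ImageTruth, height: int, width: int, jitter: bool = True
) -> tuple[RGBImage, ImageTruth]:
    """Generate a plant image whose tissue counts match the truth exactly.

    Plant pixels are coloured by sampling (uniformly if ``jitter``, else at
    the box centre) from per-class 8-bit RGB boxes strictly interior to the
    threshold rules, so the supervised classifier recovers the planted
    counts exactly. With ``jitter=False`` each class is a single colour,
    giving a colour-separable fixture on which quantisation is also exact.

    Returns the image (with plant mask) and the truth with ``mask`` and
    ``class_counts`` filled in.
    """
    if height * width <= truth.n_plant_pixels:
        raise ValueError("image must have more pixels than n_plant_pixels")
    rng = np.random.default_rng(truth.seed)

    if truth.mask is not None:
        mask = np.asarray(truth.mask, dtype=bool)
        if mask.shape != (height, width):
            raise ValueError("truth.mask shape does not match height/width")
    else:
        flat = rng.choice(height * width, size=truth.n_plant_pixels, replace=False)
        mask = np.zeros(height * width, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(height, width)

    counts = _exact_counts(truth.proportions, truth.n_plant_pixels)
    class_per_pixel = np.repeat(np.array(_CLASS_ORDER), counts)
    rng.shuffle(class_per_pixel)

    img8 = np.empty((height, width, 3), dtype=np.uint8)
    bg = np.clip(np.round(np.asarray(truth.background_color) * 255), 0, 255)
    img8[:] = bg.astype(np.uint8)
    plant_colors = np.empty((truth.n_plant_pixels, 3), dtype=np.uint8)
    for cls in _CLASS_ORDER:
        sel = class_per_pixel == cls
        n_sel = int(sel.sum())
        box = CLASS_SAMPLING_BOXES[cls]
        if jitter:
            cols = np.column_stack(
                [rng.integers(lo, hi + 1, size=n_sel) for lo, hi in box]
            )
        else:
            cols = np.tile(_box_center(box), (n_sel, 1))
        plant_colors[sel] = cols.astype(np.uint8)
    img8[mask] = plant_colors

    out_truth = ImageTruth(
        proportions=truth.proportions,
        n_plant_pixels=truth.n_plant_pixels,
        background_color=truth.background_color,
        mask=mask,
        seed=truth.seed,
        class_counts=tuple(int(c) for c in counts),  # type: ignore[arg-type]
    )
    img = RGBImage(pixels=img8 / 255.0, mask=mask, bit_depth=8)
    return img, out_truth


def write_image_fixture(
    img: RGBImage, truth: ImageTruth, out_dir: str | Path, name: str
) -> dict[str, Path]:
    """Write a synthetic image losslessly as PNG + mask PNG + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{name}.png"
    mask_path = out_dir / f"{name}_mask.png"
    truth_path = out_dir / f"{name}_truth.json"
    arr8 = np.round(img.pixels * 255).astype(np.uint8)
    Image.fromarray(arr8, mode="RGB").save(img_path, format="PNG")
    Image.fromarray((img.mask.astype(np.uint8) * 255), mode="L").save(
        mask_path, format="PNG"
    )
    payload = {
        "proportions": list(truth.proportions),
        "n_plant_pixels": truth.n_plant_pixels,
        "background_color": list(truth.background_color),
        "class_counts": list(truth.class_counts) if truth.class_counts else None,
        "seed": truth.seed,
        "damage": truth.damage,
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    return {"image": img_path, "mask": mask_path, "truth": truth_path}


# --- genotypes -----------------------------------------------------------------

@dataclass
class FamilyDesign:
    """Design of a set of F1 biparental crosses sharing one tester parent.

    ``recomb_rate`` is the recombination probability between adjacent SNPs
    (constant along the map); ``het_fraction`` is the expected fraction of
    SNPs at which each parent is heterozygous (0.5 by default, the most
    informative configuration for an F1 mapping family).
    """

    family_sizes: tuple[int, ...] = (70, 120, 120, 29)
    n_snps: int = 500
    recomb_rate: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0
    n_chromosomes: int = 2
    spacing_bp: int = 1000
    het_fraction: float = 0.5

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.family_sizes):
            raise ValueError("family_sizes must all be >= 1")
        if not 0 <= self.recomb_rate <= 0.5:
            raise ValueError("recomb_rate must lie in [0, 0.5]")
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def _parent_haplotypes(rng: np.random.Generator, n_snps: int, het: float) -> np.ndarray:
    """Two haplotypes (2, n_snps) of 0/1 alleles for one parent."""
    is_het = rng.random(n_snps) < het
    haps = np.zeros((2, n_snps), dtype=np.int8)
    # heterozygous: one ref, one alt, phase random
    phase = rng.integers(0, 2, size=n_snps)
    haps[0, is_het] = phase[is_het]
    haps[1, is_het] = 1 - phase[is_het]
    homo_alt = ~is_het & (rng.random(n_snps) < 0.5)
    haps[:, homo_alt] = 1
    return haps


def _gamete(rng: np.random.Generator, haps: np.ndarray, chrom_codes: np.ndarray,
            recomb: float) -> np.ndarray:
    """Sample one gamete by a recombination walk along each chromosome."""
    n = haps.shape[1]
    switch = rng.random(n) < recomb
    new_chrom = np.empty(n, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom_codes[1:] != chrom_codes[:-1]
    # independent start haplotype on each chromosome; no linkage across
    switch[new_chrom] = rng.integers(0, 2, size=int(new_chrom.sum())).astype(bool)
    current = np.cumsum(switch) % 2
    return haps[current, np.arange(n)]


def simulate_f1_families(design: FamilyDesign) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate diploid genotypes for F1 families and their pedigree.

    Each family is a cross between a family-specific sire and one common
    tester dam. Progeny genotypes arise by gamete sampling with
    recombination probability ``design.recomb_rate`` between adjacent SNPs;
    missing genotypes are injected completely at random at
    ``design.missing_rate``. The genotype matrix holds parents first, then
    progeny; the pedigree table has one row per progeny (id, sire, dam).
    """
    rng = np.random.default_rng(design.seed)
    n_fam = len(design.family_sizes)
    n_snps = design.n_snps

    per_chrom = np.full(design.n_chromosomes, n_snps // design.n_chromosomes)
    per_chrom[: n_snps % design.n_chromosomes] += 1
    chrom = np.concatenate(
        [np.full(c, i + 1, dtype=int) for i, c in enumerate(per_chrom)]
    )
    pos = np.concatenate(
        [design.spacing_bp * (np.arange(c) + 1) for c in per_chrom]
    ).astype(int)

    dam_haps = _parent_haplotypes(rng, n_snps, design.het_fraction)
    sire_haps = [
        _parent_haplotypes(rng, n_snps, design.het_fraction) for _ in range(n_fam)
    ]

    ids = ["TESTER"] + [f"SIRE{i + 1}" for i in range(n_fam)]
    rows = [dam_haps.sum(axis=0)] + [h.sum(axis=0) for h in sire_haps]
    ped_rows = []
    for f, size in enumerate(design.family_sizes):
        sire_id = f"SIRE{f + 1}"
        for k in range(size):
            pid = f"F{f + 1}_{k + 1:03d}"
            g = _gamete(rng, sire_haps[f], chrom, design.recomb_rate) + _gamete(
                rng, dam_haps, chrom, design.recomb_rate
            )
            rows.append(g)
            ids.append(pid)
            ped_rows.append({"id": pid, "sire": sire_id, "dam": "TESTER"})

    dosages = np.array(rows, dtype=float)
    if design.missing_rate > 0:
        n_parents = n_fam + 1
        miss = rng.random(dosages[n_parents:].shape) < design.missing_rate
        prog = dosages[n_parents:]
        prog[miss] = np.nan
        dosages[n_parents:] = prog

    snp_ids = [f"S{c}_{p}" for c, p in zip(chrom, pos)]
    gm = GenotypeMatrix(
        dosages=dosages,
        chrom=np.array([str(c) for c in chrom]),
        pos=pos,
        ids=ids,
        snp_ids=snp_ids,
        ref=np.full(n_snps, "A"),
        alt=np.full(n_snps, "T"),
    )
    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam"])
    return gm, pedigree


# --- phenotypes ----------------------------------------------------------------

@dataclass
class PhenoSimSpec:
    """Variance components and QTL effects for phenotype simulation.

    Variances are in squared trait units; ``qtl_effects`` maps SNP column
    index to the additive effect per alternate-allele dosage.
    """

    n_trials: int = 2
    var_g: float = 1.0
    var_gxt: float = 0.0
    var_block: float = 0.0
    var_e: float = 1.0
    qtl_effects: Mapping[int, float] = field(default_factory=dict)
    trial_means: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("var_g", "var_gxt", "var_block", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trial_means is not None and len(self.trial_means) != self.n_trials:
            raise ValueError("trial_means length must equal n_trials")


@dataclass
class TrialLayout:
    """Replication and blocking structure within each trial."""

    n_reps: int = 1
    n_blocks: int = 6

    def __post_init__(self) -> None:
        if self.n_reps < 1 or self.n_blocks < 1:
            raise ValueError("n_reps and n_blocks must be >= 1")


@dataclass
class PhenoSimTruth:
    """Planted effects returned alongside a simulated phenotype table."""

    genotype_effects: pd.Series
    gxt_effects: pd.DataFrame  # genotype x trial
    block_effects: pd.DataFrame  # trial x block
    trial_means: np.ndarray
    qtl_contribution: pd.Series  # per genotype


def simulate_phenotypes(
    geno: GenotypeMatrix,
    spec: PhenoSimSpec,
    layout: TrialLayout | None = None,
) -> tuple[pd.DataFrame, PhenoSimTruth]:
    """Simulate a long-format multi-trial phenotype table.

    y = trial mean + sum_k beta_k * dosage_k + g + (g x trial) + block + e,
    with each random term drawn i.i.d. normal at the specified variance.
    Genotypes are assigned to blocks round-robin within every trial.
    Missing dosages contribute their SNP mean to the QTL term.
    """
    if layout is None:
        layout = TrialLayout()
    if any(k >= geno.n_snps or k < 0 for k in spec.qtl_effects):
        raise ValueError("qtl_effects indices must be valid SNP columns")
    rng = np.random.default_rng(spec.seed)
    ids = list(geno.ids)
    n_g = len(ids)
    t_means = (
        np.asarray(spec.trial_means, dtype=float)
        if spec.trial_means is not None
        else np.zeros(spec.n_trials)
    )

    qtl = np.zeros(n_g)
    for k, beta in spec.qtl_effects.items():
        d = geno.dosages[:, k].astype(float)
        mu = np.nanmean(d)
        d = np.where(np.isnan(d), mu, d)
        qtl += beta * d

    g_eff = rng.normal(0.0, np.sqrt(spec.var_g), size=n_g)
    gxt_eff = rng.normal(0.0, np.sqrt(spec.var_gxt), size=(n_g, spec.n_trials))
    block_eff = rng.normal(0.0, np.sqrt(spec.var_block),
                           size=(spec.n_trials, layout.n_blocks))
    block_of = np.arange(n_g) % layout.n_blocks
    n_side = int(np.ceil(np.sqrt(n_g * layout.n_reps)))

    rows = []
    for t in range(spec.n_trials):
        plot = 0
        for rep in range(layout.n_reps):
            e = rng.normal(0.0, np.sqrt(spec.var_e), size=n_g)
            for i, gid in enumerate(ids):
                y = (
                    t_means[t]
                    + qtl[i]
                    + g_eff[i]
                    + gxt_eff[i, t]
                    + block_eff[t, block_of[i]]
                    + e[i]
                )
                rows.append(
                    {
                        "genotype": gid,
                        "trial": f"T{t + 1}",
                        "block": f"B{block_of[i] + 1}",
                        "replicate": rep + 1,
                        "row": plot // n_side + 1,
                        "col": plot % n_side + 1,
                        "value": y,
                    }
                )
                plot += 1
    df = pd.DataFrame(rows)
    truth = PhenoSimTruth(
        genotype_effects=pd.Series(g_eff, index=ids),
        gxt_effects=pd.DataFrame(
            gxt_eff, index=ids, columns=[f"T{t + 1}" for t in range(spec.n_trials)]
        ),
        block_effects=pd.DataFrame(
            block_eff,
            index=[f"T{t + 1}" for t in range(spec.n_trials)],
            columns=[f"B{b + 1}" for b in range(layout.n_blocks)],
        ),
        trial_means=t_means,
        qtl_contribution=pd.Series(qtl, index=ids),
    )
    return df, truth


def expected_entry_mean_h2(
    var_g: float, var_gxt: float, var_e: float, n_trials: int, n_reps: int = 1
) -> float:
    """Broad-sense heritability on an entry-mean basis.

    H2 = var_g / (var_g + var_gxt / t + var_e / (t * r)) for t trials and
    r replicates per trial.
    """
    denom = var_g + var_gxt / n_trials + var_e / (n_trials * n_reps)
    return var_g / denom if denom > 0 else 0.0


# --- insect counts -------------------------------------------------------------

def simulate_insect_counts(
    n_plants: int, survival_prob: float, n_infested: int = 6, seed: int = 0
) -> pd.DataFrame:
    """Simulate living-insect counts per plant.

    Each plant is infested with ``n_infested`` insects (default 6 eggs per
    plant); the number alive at scoring is Binomial(n_infested,
    survival_prob), hence bounded in [0, n_infested].
    """
    if not 0 <= survival_prob <= 1:
        raise ValueError("survival_prob must lie in [0, 1]")
    if n_infested < 1:
        raise ValueError("n_infested must be >= 1")
    rng = np.random.default_rng(seed)
    living = rng.binomial(n_infested, survival_prob, size=n_plants)
    return pd.DataFrame(
        {
            "plant": [f"plant{i + 1}" for i in range(n_plants)],
            "living": living,
            "total_infested": n_infested,
        }
    )
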