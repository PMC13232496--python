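"""Genotype container, VCF I/O, marker QC, kinship, PCA and LD decay.

Genotypes are diploid allele dosages (0/1/2, NaN for missing) with per-SNP
chromosome and 1-based position metadata, round-trippable to VCF v4.2.
Linkage disequilibrium is measured as the squared Pearson correlation of
dosage vectors (composite LD), averaged in fixed 1-kb distance bins; the
decay distance is where the monotone-fitted curve first falls below
r-squared = 0.2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "LDBin",
    "read_vcf",
    "write_vcf",
    "filter_snps",
    "vanraden_kinship",
    "pc_covariates",
    "pairwise_r2",
    "ld_decay",
    "plot_ld_decay",
    "EmptyGenotypeError",
]


class EmptyGenotypeError(ValueError):
    """Raised when a QC step removes every SNP."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix with marker metadata."""

    dosages: np.ndarray  # (n_ind, n_snp), float, values {0,1,2,nan}
    chrom: np.ndarray  # (n_snp,) str
    pos: np.ndarray  # (n_snp,) int, 1-based
    ids: list[str]
    snp_ids: list[str] | np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        if self.dosages.shape != (len(self.ids), self.pos.size):
            raise ValueError("dosages shape does not match ids/pos")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions must be strictly increasing on {c}")
        if self.snp_ids is None:
            self.snp_ids = [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]
        self.snp_ids = list(self.snp_ids)
        if self.ref is None:
            self.ref = np.full(self.pos.size, "A")
        if self.alt is None:
            self.alt = np.full(self.pos.size, "T")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ids=list(self.ids),
            snp_ids=[self.snp_ids[i] for i in np.atleast_1d(idx)]
            if not np.issubdtype(np.asarray(idx).dtype, np.bool_)
            else [s for s, k in zip(self.snp_ids, idx) if k],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def take_individuals(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            chrom=self.chrom,
            pos=self.pos,
            ids=[self.ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            ref=self.ref,
            alt=self.alt,
        )

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a diploid VCF (v4.2, GT field) into a dosage matrix.

    Multiallelic records are excluded with a logged reason; ``./.`` becomes
    missing (NaN).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    dosage_rows, chroms, poss, snp_ids, refs, alts = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            logger.info(
                "excluding multiallelic record %s:%d (%s -> %s)",
                var.CHROM, var.POS, var.REF, ",".join(var.ALT),
            )
            continue
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = var.gt_types.astype(float)
        gt[gt == 3] = np.nan
        dosage_rows.append(gt)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if n_multi:
        logger.info("read_vcf: excluded %d multiallelic record(s)", n_multi)
    if not dosage_rows:
        raise EmptyGenotypeError(f"no biallelic records in {path}")
    return GenotypeMatrix(
        dosages=np.array(dosage_rows).T,
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ids=ids,
        snp_ids=snp_ids,
        ref=np.array(refs),
        alt=np.array(alts),
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the genotype matrix as an uncompressed VCF v4.2 with GT fields."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for c in dict.fromkeys(g.chrom):  # preserve order, unique
        max_pos = int(g.pos[g.chrom == c].max())
        lines.append(f"##contig=<ID={c},length={max_pos + 1}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.ids)
    )
    for j in range(g.n_snps):
        gts = [
            "./." if np.isnan(d) else _GT_CODE[d] for d in g.dosages[:, j]
        ]
        lines.append(
            f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\t{g.ref[j]}\t{g.alt[j]}"
            "\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def filter_snps(
    g: GenotypeMatrix, maf_min: float = 0.01, call_rate_min: float = 0.40
) -> tuple[GenotypeMatrix, dict]:
    """Marker QC: keep SNPs with MAF >= maf_min and call rate >= call_rate_min.

    MAF is computed on non-missing dosages; call rate is the fraction of
    non-missing genotypes per SNP. Returns the filtered matrix and a report
    of counts removed per criterion (a SNP failing both is counted in both).
    """
    maf = g.maf()
    cr = g.call_rate()
    fail_cr = cr < call_rate_min
    fail_maf = np.where(np.isnan(maf), True, maf < maf_min)
    keep = ~fail_cr & ~fail_maf
    report = {
        "n_input": g.n_snps,
        "n_removed_call_rate": int(fail_cr.sum()),
        "n_removed_maf": int(fail_maf.sum()),
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise EmptyGenotypeError("all SNPs removed by QC filters")
    return g.take_snps(keep), report


def _mean_imputed(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(d, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    nan_idx = np.isnan(d)
    d[nan_idx] = np.broadcast_to(mu, d.shape)[nan_idx]
    return d


def vanraden_kinship(g: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix G = WW' / (2 sum p(1-p)).

    W is the dosage matrix centred by twice the allele frequency; missing
    dosages are mean-imputed per SNP.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    d = _mean_imputed(g)
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("no polymorphic SNPs: kinship undefined")
    w = d - 2.0 * p
    return (w @ w.T) / denom


def pc_covariates(g: GenotypeMatrix, n_pcs: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of the centred genotype matrix.

    Returns (scores, variance_fractions): scores is individuals x n_pcs,
    fractions are each PC's share of total genotypic variance. Requests
    beyond the matrix rank are truncated with a warning.
    """
    if g.n_individuals < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 individuals")
    d = _mean_imputed(g)
    x = d - d.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tot = np.sum(s**2)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_pcs > rank:
        warnings.warn(
            f"requested {n_pcs} PCs but genotype matrix has rank {rank}; truncating",
            UserWarning,
            stacklevel=2,
        )
        n_pcs = rank
    scores = u[:, :n_pcs] * s[:n_pcs]
    fractions = (s[:n_pcs] ** 2) / tot if tot > 0 else np.zeros(n_pcs)
    return scores, fractions


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation with pairwise-complete missing handling."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def pairwise_r2(
    g: GenotypeMatrix, max_dist: int = 100_000, maf_min: float = 0.01
) -> pd.DataFrame:
    """Pairwise composite LD (dosage r-squared) within chromosomes.

    Only intra-chromosome pairs with distance <= ``max_dist`` are returned;
    SNPs below the MAF threshold are excluded first. Missing genotypes are
    handled pairwise-complete.
    """
    maf = g.maf()
    keep = np.where(np.isnan(maf), False, maf >= maf_min)
    sub = g.take_snps(keep)
    has_missing = np.isnan(sub.dosages).any()
    rows = []
    for c in dict.fromkeys(sub.chrom):
        sel = sub.chrom == c
        pos = sub.pos[sel]
        d = sub.dosages[:, sel]
        m = pos.size
        if m < 2:
            continue
        if not has_missing:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cm = np.corrcoef(d.T)
        for i in range(m - 1):
            for j in range(i + 1, m):
                dist = int(pos[j] - pos[i])
                if dist > max_dist:
                    break
                r2 = cm[i, j] ** 2 if not has_missing else _pair_r2(d[:, i], d[:, j])
                if np.isfinite(r2):
                    rows.append({"chrom": c, "dist": dist, "r2": float(r2)})
    return pd.DataFrame(rows, columns=["chrom", "dist", "r2"])


@dataclass
class LDBin:
    """Mean r-squared of SNP pairs in one fixed-width distance bin."""

    distance_lo: int
    distance_hi: int
    mean_r2: float
    n_pairs: int


def _sved_decay(d: np.ndarray, c: float) -> np.ndarray:
    # expected r2 under drift-recombination balance: 1 / (1 + C d)
    return 1.0 / (1.0 + c * d)


def ld_decay(
    pairs: pd.DataFrame,
    bin_width: int = 1000,
    threshold: float = 0.2,
    method: str = "isotonic",
) -> tuple[list[LDBin], float | None]:
    """Distance-binned LD decay curve and the threshold-crossing distance.

    Pair r-squared values are averaged in fixed ``bin_width`` bins. The
    decay curve is, by default, a monotone non-increasing (isotonic) fit to
    the bin means evaluated at bin midpoints; the decay distance is the
    linearly interpolated point where the curve first falls below
    ``threshold`` (None if it never does, i.e. LD persists beyond the
    largest distance observed). ``method='sved'`` instead fits the
    drift-expectation curve E[r2] = 1/(1 + C d) and solves the crossing
    analytically.
    """
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    dist = pairs["dist"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    idx = (dist // bin_width).astype(int)
    bins: list[LDBin] = []
    for b in sorted(np.unique(idx)):
        sel = idx == b
        bins.append(
            LDBin(
                distance_lo=int(b * bin_width),
                distance_hi=int((b + 1) * bin_width),
                mean_r2=float(r2[sel].mean()),
                n_pairs=int(sel.sum()),
            )
        )
    mids = np.array([(b.distance_lo + b.distance_hi) / 2.0 for b in bins])
    means = np.array([b.mean_r2 for b in bins])

    if method == "sved":
        from scipy.optimize import curve_fit

        (c_hat,), _ = curve_fit(
            _sved_decay, dist, r2, p0=[1.0 / max(dist.mean(), 1.0)],
            bounds=(1e-12, np.inf),
        )
        if _sved_decay(dist.max(), c_hat) >= threshold:
            return bins, None
        return bins, float((1.0 / threshold - 1.0) / c_hat)
    if method != "isotonic":
        raise ValueError("method must be 'isotonic' or 'sved'")

    if len(mids) == 1:
        curve = means.copy()
    else:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        curve = iso.fit_transform(mids, means)
    if curve[0] < threshold:
        return bins, float(mids[0])
    for k in range(1, len(curve)):
        if curve[k] < threshold:
            y1, y2 = curve[k - 1], curve[k]
            x1, x2 = mids[k - 1], mids[k]
            return bins, float(x1 + (y1 - threshold) / (y1 - y2) * (x2 - x1))
    return bins, None


def plot_ld_decay(bins: list[LDBin], decay_distance: float | None = None, ax=None):
    """Plot binned mean r-squared against distance with the 0.2 reference."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mids = [(b.distance_lo + b.distance_hi) / 2 for b in bins]
    ax.plot(mids, [b.mean_r2 for b in bins], "o-", ms=3, label="bin mean")
    ax.axhline(0.2, ls="--", color="grey", label="r$^2$ = 0.2")
    if decay_distance is not None:
        ax.axvline(decay_distance, ls=":", color="firebrick",
                   label=f"decay = {decay_distance:.0f} bp")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel("mean r$^2$")
    ax.legend(frameon=False)
    return ax
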