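"""Kinship-corrected genome-wide association scan and downstream calls.

The scan follows the EMMAX approximation to the single-marker linear mixed
model y = Xb + g*beta + u + e with u ~ N(0, sg2*K) and e ~ N(0, se2*I):
variance components are estimated once by REML under the null (no marker)
via the eigendecomposition of the kinship matrix K, then every marker is
tested by generalized least squares with those components held fixed. With
K = I the procedure collapses exactly to per-marker OLS.

Also provided: BLUE phenotypes from replicated plots, MAF/missingness SNP
filters, IBS kinship, peak merging across the genome and across time points,
gene-interval lookup, two-SNP haplotype contrasts, and Manhattan/QQ table
export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import MISSING, GenotypeMatrix


def compute_blue(records: pd.DataFrame) -> pd.Series:
    """Best linear unbiased estimates of accession values from replicates.

    Two-way fixed-effects model value ~ accession + replicate, solved by
    least squares with sum-to-zero replicate effects so the accession
    estimates stay on the phenotype scale. On a balanced design with no
    replicate effect this reduces exactly to accession means; accessions with
    a single record pass through unchanged.
    """
    if records.empty:
        raise ValueError("empty phenotype table")
    req = {"accession", "replicate", "value"}
    if not req.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    acc = pd.Categorical(records["accession"])
    rep = pd.Categorical(records["replicate"])
    y = records["value"].to_numpy(dtype=float)
    n_acc = len(acc.categories)
    n_rep = len(rep.categories)
    A = np.zeros((len(records), n_acc))
    A[np.arange(len(records)), acc.codes] = 1.0
    if n_rep > 1:
        # sum-to-zero (effects) coding for replicate
        R = np.zeros((len(records), n_rep - 1))
        for j in range(n_rep - 1):
            R[rep.codes == j, j] = 1.0
        R[rep.codes == n_rep - 1, :] = -1.0
        X = np.hstack([A, R])
    else:
        X = A
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta[:n_acc], index=acc.categories, name="blue")


def filter_snps(
    G: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.10
) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly above and missingness strictly below cutoffs."""
    maf = G.maf()
    miss = G.missing_fraction()
    keep = np.where((maf > maf_min) & (miss < missing_max) & ~np.isnan(maf))[0]
    return G.take_snps(keep)


def kinship(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state similarity on mean-imputed dosages.

    IBS(i, j) = 1 - mean_m |x_im - x_jm| / 2, symmetric with unit diagonal;
    the relatedness matrix EMMAX uses by default.
    """
    if G.n_snps == 0:
        raise ValueError("no SNPs to compute kinship from")
    X = G.imputed()
    n = G.n_samples
    K = np.empty((n, n))
    for i in range(n):
        K[i, i:] = 1.0 - np.abs(X[i:] - X[i]).mean(axis=1) / 2.0
    K = np.triu(K) + np.triu(K, 1).T
    np.fill_diagonal(K, 1.0)
    return K


@dataclass
class ScanResult:
    """Per-SNP association results for one time point."""

    table: pd.DataFrame  # snp_id, chrom, pos, beta, se, p_value, neg_log10_p
    sigma_g2: float
    sigma_e2: float
    time_point: int = 0


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, Xs: np.ndarray, ys: np.ndarray) -> float:
    """-2 x restricted log-likelihood (up to constants) at variance ratio delta."""
    delta = np.exp(log_delta)
    w = lam + delta
    sw = np.sqrt(w)
    Xw = Xs / sw[:, None]
    yw = ys / sw
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    r = yw - Xw @ beta
    n, q = Xs.shape
    rss = float(r @ r)
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    return (
        (n - q) * np.log(rss / (n - q))
        + np.log(w).sum()
        + logdet_XtX
    )


def mixed_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    time_point: int = 0,
) -> ScanResult:
    """EMMAX scan: one REML fit under the null, then per-SNP GLS Wald tests."""
    y = np.asarray(y, dtype=float)
    n = G.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length does not match the sample count")
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship dimension mismatch")
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6 * max(1.0, abs(lam.max())):
        raise ValueError("kinship matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)

    X0 = np.ones((n, 1))
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        X0 = np.hstack([X0, covariates])
    q0 = X0.shape[1]

    ys = U.T @ y
    Xs = U.T @ X0

    # 1-D REML over log variance ratio delta = se2/sg2: coarse grid + refine
    grid = np.linspace(-10.0, 10.0, 41)
    vals = [_reml_neg_loglik(g, lam, Xs, ys) for g in grid]
    j = int(np.argmin(vals))
    lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(lo, hi),
        args=(lam, Xs, ys),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    w = lam + delta
    sw = np.sqrt(w)

    # GLS with fixed weights; project the null design out once
    yw = ys / sw
    Xw = Xs / sw[:, None]
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)

    Gs = U.T @ G.imputed()  # n x m rotated dosages
    Gw = Gs / sw[:, None]
    RG = Gw - Q @ (Q.T @ Gw)

    gg = np.einsum("ij,ij->j", RG, RG)
    gy = RG.T @ ry
    dof = n - q0 - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = float(ry @ ry) - beta * gy
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    monomorphic = gg <= 1e-12
    beta[monomorphic] = 0.0
    se[monomorphic] = np.nan
    p[monomorphic] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    # REML variance components: GLS residual variance estimates sigma_g2,
    # and delta = sigma_e2 / sigma_g2 by construction
    sigma_g2 = float(ry @ ry) / (n - q0)
    sigma_e2 = sigma_g2 * delta
    table = pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chrom": G.chrom,
            "pos": G.pos,
            "beta": beta,
            "se": se,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
        }
    )
    return ScanResult(table, sigma_g2, sigma_e2, time_point)


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Median chi-square test statistic over its null median (~1 if calibrated)."""
    p = np.asarray(p_values, dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


@dataclass
class Peak:
    """A merged run of significant SNPs on one chromosome at one time point."""

    chrom: str
    start: int
    end: int
    top_snp: str
    top_neg_log10_p: float
    time_point: int
    time_points_supporting: set[int] = field(default_factory=set)

    @property
    def replicated(self) -> bool:
        return len(self.time_points_supporting) >= 2

    def overlaps(self, other: "Peak", pad: int = 0) -> bool:
        """True when the intervals come within ``pad`` bp of each other."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end + pad
            and other.start <= self.end + pad
        )


def _peaks_one_scan(
    result: ScanResult, threshold: float, merge_window: int
) -> list[Peak]:
    sig = result.table[result.table["neg_log10_p"] >= threshold]
    peaks: list[Peak] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) >= merge_window)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            block = grp.iloc[a:b]
            top = block.loc[block["neg_log10_p"].idxmax()]
            peaks.append(
                Peak(
                    chrom=str(chrom),
                    start=int(block["pos"].min()),
                    end=int(block["pos"].max()),
                    top_snp=str(top["snp_id"]),
                    top_neg_log10_p=float(top["neg_log10_p"]),
                    time_point=result.time_point,
                    time_points_supporting={result.time_point},
                )
            )
    return peaks


def significant_peaks(
    results: list[ScanResult],
    threshold_neg_log10: float = 5.0,
    merge_window: int = 500_000,
) -> list[Peak]:
    """Merge significant SNPs into peaks and flag cross-time replication.

    SNPs at or above the threshold are grouped into one peak when consecutive
    gaps are below ``merge_window``. A peak's supporting set then gains every
    other time point holding a peak whose interval comes within the merge
    window of it (two hits closer than the merge window are one signal, so
    the same slack applies across time points); a peak supported by two or
    more time points is replicated.
    """
    all_peaks: list[Peak] = []
    for res in results:
        all_peaks.extend(_peaks_one_scan(res, threshold_neg_log10, merge_window))
    for pk in all_peaks:
        for other in all_peaks:
            if other.time_point != pk.time_point and pk.overlaps(
                other, pad=merge_window - 1
            ):
                pk.time_points_supporting.add(other.time_point)
    return all_peaks


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "top_snp": [p.top_snp for p in peaks],
            "top_neg_log10_p": [p.top_neg_log10_p for p in peaks],
            "time_point": [p.time_point for p in peaks],
            "n_time_points": [len(p.time_points_supporting) for p in peaks],
            "replicated": [p.replicated for p in peaks],
        }
    )


def write_peaks_bed(peaks: list[Peak], path: str) -> None:
    """BED-like TSV (0-based half-open, converted from 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttop_snp\ttop_neg_log10_p\ttime_point\treplicated\n")
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.top_snp}\t"
                f"{p.top_neg_log10_p:.4f}\t{p.time_point}\t{int(p.replicated)}\n"
            )


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene records (1-based inclusive) from a GFF3 file."""
    cols = [
        "chrom", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    genes = df[df["type"] == "gene"].copy()
    if (genes["start"] > genes["end"]).any():
        raise ValueError("malformed annotation record: start > end")

    def _attr(s: str, key: str) -> str | None:
        for part in s.split(";"):
            if part.startswith(key + "="):
                return part.split("=", 1)[1]
        return None

    genes["gene_id"] = genes["attributes"].map(lambda s: _attr(s, "ID"))
    genes["name"] = genes["attributes"].map(lambda s: _attr(s, "Name"))
    return genes[["chrom", "start", "end", "gene_id", "name"]].reset_index(drop=True)


def genes_in_interval(annotation: pd.DataFrame, peak: Peak) -> pd.DataFrame:
    """Genes overlapping the peak interval by >= 1 bp (1-based inclusive)."""
    req = {"chrom", "start", "end"}
    if not req.issubset(annotation.columns):
        raise ValueError("annotation needs chrom/start/end columns")
    hit = (
        (annotation["chrom"].astype(str) == peak.chrom)
        & (annotation["start"] <= peak.end)
        & (annotation["end"] >= peak.start)
    )
    return annotation[hit].reset_index(drop=True)


def haplotype_compare(
    G: GenotypeMatrix,
    snp_ids: tuple[str, str],
    phenotypes: pd.DataFrame,
    min_group: int = 3,
) -> pd.DataFrame:
    """Two-SNP haplotype contrast on per-time-point phenotypes.

    Accessions homozygous at both SNPs are partitioned by their joint
    genotype (heterozygous or missing calls are excluded); each time point
    gets a two-group Welch t-test on the phenotype. ``phenotypes`` is
    accessions x time points, indexed by sample id.
    """
    ids = list(G.snp_ids)
    try:
        j1, j2 = (ids.index(s) for s in snp_ids)
    except ValueError as exc:
        raise ValueError("both SNPs must be present in the genotype matrix") from exc
    d1 = G.dosages[:, j1]
    d2 = G.dosages[:, j2]
    hom = np.isin(d1, (0, 2)) & np.isin(d2, (0, 2))
    joint = d1.astype(int) * 3 + d2.astype(int)  # unique per homozygous combo
    groups = np.unique(joint[hom])
    if len(groups) < 2:
        raise ValueError("all accessions carry a single haplotype")
    if len(groups) > 2:
        # keep the two most frequent joint genotypes (the two haplotypes)
        counts = [(g, np.sum(joint[hom] == g)) for g in groups]
        groups = np.array([g for g, _ in sorted(counts, key=lambda t: -t[1])[:2]])
    sel1 = hom & (joint == groups[0])
    sel2 = hom & (joint == groups[1])
    if sel1.sum() < min_group or sel2.sum() < min_group:
        raise ValueError("a haplotype group has too few accessions")

    ph = phenotypes.reindex(G.sample_ids)
    rows = []
    for t in ph.columns:
        a = ph.loc[sel1, t].dropna().to_numpy(dtype=float)
        b = ph.loc[sel2, t].dropna().to_numpy(dtype=float)
        test = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "time": t,
                "n_hap1": a.size,
                "n_hap2": b.size,
                "mean_hap1": a.mean(),
                "mean_hap2": b.mean(),
                "difference": a.mean() - b.mean(),
                "t_stat": float(test.statistic),
                "p_value": float(test.pvalue),
            }
        )
    return pd.DataFrame(rows)


def export_scan(result: ScanResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Manhattan table (cumulative genome coordinate) and QQ table."""
    tab = result.table.copy()
    offset = 0
    cum = np.empty(len(tab), dtype=np.int64)
    for chrom in dict.fromkeys(tab["chrom"].astype(str)):
        sel = (tab["chrom"].astype(str) == chrom).to_numpy()
        cum[sel] = tab.loc[sel, "pos"].to_numpy() + offset
        offset = int(cum[sel].max()) + 1
    manhattan = tab.assign(cum_pos=cum)

    obs = np.sort(tab["neg_log10_p"].to_numpy())[::-1]
    m = len(obs)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected": expected, "observed": obs})
    return manhattan, qq
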