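"""Windowed two-population selective-sweep scan and enrichment testing.

Differentiation uses the Weir–Cockerham variance-components FST estimator
(two populations, genotype-based, accounting for observed heterozygosity
and unequal sample sizes), aggregated per window as the weighted ratio of
sums sum(a)/sum(a+b+c). Window FST values are standardized as
Z = (FST - mean)/sd, diversity contrasts as log2 of the windowed-pi ratio,
and candidate windows are those simultaneously in the top fraction (default
5%) of both statistics. Candidate windows map to the SNPs they contain and
the gene intervals they overlap; gene-set enrichment uses the upper-tail
hypergeometric test (equivalently one-sided Fisher) with Benjamini–Hochberg
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneAnnotation, GenotypeMatrix, PopulationMap, bed_to_pos
from .diversity import _chrom_lengths_for, _window_sums, window_grid, windowed_pi

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

def wc_site_components(
    G: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham variance components (a, b, c) for two
    populations, plus a validity mask (both populations need >= 2 called
    genotypes at a contributing site)."""
    comps = []
    for idx in (idx_a, idx_b):
        g = G[idx]
        called = g >= 0
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, g, 0).sum(axis=0)
        het = (g == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = het / n
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        inner = pbar * (1.0 - pbar) - s2 / 2.0
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~valid] = 0.0
    return a, b, c, valid


def windowed_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    window: int = 50_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Weighted Weir–Cockerham FST per sliding window.

    Window FST = sum(a) / sum(a+b+c) over valid sites in the window;
    windows with no valid site are NaN. Negative estimates are retained.
    """
    for pop in (pop_a, pop_b):
        if pop not in popmap.populations:
            raise KeyError(f"population {pop!r} absent from population map")
    idx_a = popmap.indices_in(gm, pop_a)
    idx_b = popmap.indices_in(gm, pop_b)
    a, b, c, valid = wc_site_components(gm.G, idx_a, idx_b)
    lengths = _chrom_lengths_for(gm, chrom_lengths)
    grid = window_grid(lengths, window, step)
    num, _ = _window_sums(gm.loci, np.where(valid, a, 0.0), grid)
    den, _ = _window_sums(gm.loci, np.where(valid, a + b + c, 0.0), grid)
    nsites, _ = _window_sums(gm.loci, valid.astype(float), grid)
    out = grid.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(den != 0, num / den, np.nan)
    out.loc[nsites == 0, "fst"] = np.nan
    out["n_sites"] = nsites.astype(int)
    return out


def genome_mean_fst(
    gm: GenotypeMatrix, popmap: PopulationMap, pop_a: str, pop_b: str
) -> float:
    """Genome-wide weighted (ratio-of-sums) Weir–Cockerham FST."""
    idx_a = popmap.indices_in(gm, pop_a)
    idx_b = popmap.indices_in(gm, pop_b)
    a, b, c, valid = wc_site_components(gm.G, idx_a, idx_b)
    return float(a[valid].sum() / (a + b + c)[valid].sum())


# ---------------------------------------------------------------------------
# transforms and outlier selection
# ---------------------------------------------------------------------------

def z_transform(values: np.ndarray) -> np.ndarray:
    """Standardize as (x - mean)/sd with the sample sd (ddof=1); NaN entries
    are excluded from the moments and stay NaN."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least two finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: degenerate scan")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


def log2_pi_ratio(pi_a: np.ndarray, pi_b: np.ndarray) -> np.ndarray:
    """log2(pi_a / pi_b) per window; windows with a zero on either side are
    NaN (excluded from ranking) and their count is logged. pi_a is the
    comparator population, so large positive values flag diversity loss in
    population B."""
    pi_a = np.asarray(pi_a, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    ok = (pi_a > 0) & (pi_b > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("log2 pi-ratio: %d windows excluded (zero pi)", n_excluded)
    out = np.full(pi_a.shape, np.nan)
    out[ok] = np.log2(pi_a[ok] / pi_b[ok])
    return out


@dataclass
class CandidateSet:
    """Outlier windows with their SNPs and overlapping genes."""

    windows: pd.DataFrame
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: list[str] = field(default_factory=list)
    threshold_z: float | None = None
    threshold_ratio: float | None = None


def select_outliers(
    table: pd.DataFrame, top_fraction: float = 0.05
) -> tuple[pd.DataFrame, float, float]:
    """Flag windows simultaneously in the top fraction of z_fst and
    log2_ratio (>= the empirical (1 - top_fraction) quantiles, linear
    interpolation; ties at the threshold are included).

    Quantiles are taken over the retained windows — those with both
    statistics defined. Returns the flagged table plus both thresholds.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    out = table.copy()
    retained = (
        np.isfinite(out["z_fst"].to_numpy())
        & np.isfinite(out["log2_ratio"].to_numpy())
    )
    n_ret = int(retained.sum())
    if n_ret < 20:
        logger.warning(
            "only %d retained windows: top-%.0f%% quantiles unstable",
            n_ret, 100 * top_fraction,
        )
    if n_ret == 0:
        out["outlier"] = False
        return out, np.nan, np.nan
    tz = float(np.quantile(out.loc[retained, "z_fst"], 1.0 - top_fraction))
    tr = float(np.quantile(out.loc[retained, "log2_ratio"], 1.0 - top_fraction))
    out["retained"] = retained
    out["outlier"] = retained & (out["z_fst"] >= tz) & (out["log2_ratio"] >= tr)
    return out, tz, tr


def sweep_scan(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    window: int = 50_000,
    step: int = 10_000,
    top_fraction: float = 0.05,
    chrom_lengths: dict[str, int] | None = None,
) -> CandidateSet:
    """Full two-population scan: windowed FST and pi, Z(FST), log2 pi-ratio
    (pop_a in the numerator), and top-fraction intersection outliers."""
    fst = windowed_fst(gm, popmap, pop_a, pop_b, window, step, chrom_lengths)
    idx_a = popmap.indices_in(gm, pop_a)
    idx_b = popmap.indices_in(gm, pop_b)
    pia = windowed_pi(gm, idx_a, window, step, chrom_lengths)
    pib = windowed_pi(gm, idx_b, window, step, chrom_lengths)
    table = fst.copy()
    table["pi_a"] = pia["pi_per_bp"]
    table["pi_b"] = pib["pi_per_bp"]
    table["z_fst"] = z_transform(table["fst"].to_numpy())
    table["log2_ratio"] = log2_pi_ratio(
        table["pi_a"].to_numpy(), table["pi_b"].to_numpy()
    )
    table, tz, tr = select_outliers(table, top_fraction)
    table.attrs["pop_a"] = pop_a
    table.attrs["pop_b"] = pop_b
    return CandidateSet(windows=table, threshold_z=tz, threshold_ratio=tr)


def map_windows_to_genes(
    candidates: CandidateSet, annotation: GeneAnnotation, gm: GenotypeMatrix
) -> CandidateSet:
    """Attach SNPs inside outlier windows and genes overlapping them by
    >= 1 bp (deduplicated, sorted)."""
    win = candidates.windows
    out_win = win.loc[win["outlier"]] if "outlier" in win.columns else win
    snp_mask = np.zeros(gm.n_loci, dtype=bool)
    genes: set[str] = set()
    pos = gm.loci["pos"].to_numpy()
    chrom = gm.loci["chrom"].to_numpy()
    ann = annotation.table
    for _, w in out_win.iterrows():
        snp_mask |= (chrom == w["chrom"]) & (pos >= w["start"]) & (pos <= w["end"])
        on = ann[ann["chrom"] == w["chrom"]]
        g1 = on["start"].map(bed_to_pos)  # 1-based first base
        overlap = (g1 <= w["end"]) & (on["end"] >= w["start"])
        genes.update(on.loc[overlap, "name"])
    candidates.snps = gm.loci.loc[snp_mask].reset_index(drop=True)
    candidates.genes = sorted(genes)
    return candidates


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrichment(
    candidates: set[str] | list[str],
    background: set[str] | list[str],
    term_map: dict[str, set[str] | list[str]],
    method: str = "hypergeometric",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation test with BH correction.

    Upper-tail hypergeometric P(X >= x) with N = |background|, K = term
    size, n = |candidates|; the one-sided Fisher test on the same 2x2 table
    gives identical p-values. Terms with no background genes are skipped
    with a warning. Significance is flagged at BH q < ``fdr_threshold``.
    """
    if method not in ("hypergeometric", "fisher"):
        raise ValueError("method must be 'hypergeometric' or 'fisher'")
    bg = set(background)
    cand = set(candidates)
    if not cand <= bg:
        raise ValueError("candidate genes must be a subset of the background")
    N, n = len(bg), len(cand)
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & bg
        K = len(term_genes)
        if K == 0:
            logger.warning("term %s has no background genes; skipped", term)
            continue
        x = len(term_genes & cand)
        if method == "hypergeometric":
            p = float(stats.hypergeom.sf(x - 1, N, K, n))
        else:
            table = [[x, K - x], [n - x, N - K - (n - x)]]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append(
            {"term": term, "term_size": K, "overlap": x, "p_value": p}
        )
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"])
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["q_value"] < fdr_threshold
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out
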