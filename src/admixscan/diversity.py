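"""Per-locus and per-population diversity statistics, windowed nucleotide
diversity, sequential locus filters, and two-platform dataset merging.

For a biallelic locus with alt-allele frequency p:

* Ho — observed heterozygote fraction among called genotypes
* He — expected heterozygosity 2p(1-p)
* Nei — gene diversity 1 - p^2 - (1-p)^2 (equals He for biallelic loci)
* PIC — polymorphism information content; the default form is 1 - sum fi^2
  (gene diversity), the Botstein form additionally subtracts
  2 p^2 (1-p)^2
* MAF — min(p, 1-p)

Per-site nucleotide diversity uses the unbiased pairwise estimator
2·c_alt·c_ref / (c·(c-1)) on the called allele count c = 2·n_called.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, PopulationMap

PIC_VARIANTS = ("nei", "botstein")

STAT_COLUMNS = ["p_alt", "maf", "n_called", "ho", "he", "nei", "pic", "mean_depth"]


def _counts(G: np.ndarray):
    called = G >= 0
    n_called = called.sum(axis=0)
    alt = np.where(called, G, 0).sum(axis=0)
    het = (G == 1).sum(axis=0)
    return called, n_called, alt, het


def locus_stats(
    gm: GenotypeMatrix,
    sample_idx: np.ndarray | None = None,
    pic_variant: str = "nei",
) -> pd.DataFrame:
    """Per-locus diversity statistics over the given samples.

    Loci with zero called genotypes get NaN statistics and are flagged in
    the ``defined`` column. Monomorphic loci get all-zero diversity stats.
    """
    if pic_variant not in PIC_VARIANTS:
        raise ValueError(f"pic_variant must be one of {PIC_VARIANTS}")
    G = gm.G if sample_idx is None else gm.G[sample_idx]
    called, n_called, alt, het = _counts(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_called)
        ho = het / n_called
    he = 2.0 * p * (1.0 - p)
    nei = 1.0 - p**2 - (1.0 - p) ** 2
    pic = nei if pic_variant == "nei" else nei - 2.0 * p**2 * (1.0 - p) ** 2
    maf = np.minimum(p, 1.0 - p)
    if gm.D is not None:
        D = gm.D if sample_idx is None else gm.D[sample_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_depth = np.where(called, D, 0).sum(axis=0) / n_called
    else:
        mean_depth = np.full(gm.n_loci, np.nan)
    return pd.DataFrame(
        {
            "p_alt": p, "maf": maf, "n_called": n_called, "ho": ho,
            "he": he, "nei": nei, "pic": pic, "mean_depth": mean_depth,
            "defined": n_called > 0,
        }
    )


def allele_frequency(
    gm: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Alt-allele frequency per locus (missing genotypes excluded); NaN where
    no genotype is called."""
    G = gm.G if sample_idx is None else gm.G[sample_idx]
    _, n_called, alt, _ = _counts(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        return alt / (2.0 * n_called)


def population_summary(
    gm: GenotypeMatrix, popmap: PopulationMap, pic_variant: str = "nei"
) -> pd.DataFrame:
    """Unweighted per-population means of Ho/He/Nei/PIC/MAF over loci with at
    least one called genotype in that population."""
    rows = []
    for pop in popmap.populations:
        idx = popmap.indices_in(gm, pop)
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has no samples in the matrix")
        st = locus_stats(gm, idx, pic_variant)
        ok = st["defined"]
        rows.append(
            {
                "population": pop,
                "n_samples": len(idx),
                "n_loci": int(ok.sum()),
                **{c: float(st.loc[ok, c].mean()) for c in ("ho", "he", "nei", "pic", "maf")},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# windowed nucleotide diversity
# ---------------------------------------------------------------------------

def window_grid(
    chrom_lengths: dict[str, int], window: int, step: int
) -> pd.DataFrame:
    """Sliding windows (1-based inclusive) starting at 1 and advancing by
    ``step`` until the chromosome end; terminal windows are truncated."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window < step:
        raise ValueError("window must be >= step")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(1, length + 1, step)
        ends = np.minimum(starts + window - 1, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _chrom_lengths_for(gm: GenotypeMatrix, chrom_lengths=None) -> dict[str, int]:
    if chrom_lengths is not None:
        return chrom_lengths
    if gm.chrom_lengths:
        return gm.chrom_lengths
    return {
        str(c): int(g["pos"].max())
        for c, g in gm.loci.groupby("chrom", sort=False)
    }


def per_site_pi(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> np.ndarray:
    """Unbiased per-site pairwise diversity 2·c_alt·c_ref/(c·(c-1))."""
    G = gm.G if sample_idx is None else gm.G[sample_idx]
    _, n_called, alt, _ = _counts(G)
    c = 2.0 * n_called
    ref = c - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * ref / (c * (c - 1.0))
    pi[c < 2] = 0.0
    return pi


def _window_sums(
    loci: pd.DataFrame, values: np.ndarray, grid: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Sum *values* (and count of nonzero values) per window via searchsorted."""
    sums = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=int)
    nz = (np.nan_to_num(values) != 0).astype(float)
    for chrom, g in grid.groupby("chrom", sort=False):
        on = loci["chrom"] == chrom
        pos = loci.loc[on, "pos"].to_numpy()
        vals = np.nan_to_num(values[on.to_numpy()])
        nzv = nz[on.to_numpy()]
        cv = np.concatenate([[0.0], np.cumsum(vals)])
        cn = np.concatenate([[0.0], np.cumsum(nzv)])
        lo = np.searchsorted(pos, g["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, g["end"].to_numpy(), side="right")
        sums[g.index] = cv[hi] - cv[lo]
        counts[g.index] = (cn[hi] - cn[lo]).astype(int)
    return sums, counts


def windowed_pi(
    gm: GenotypeMatrix,
    sample_idx: np.ndarray | None = None,
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per bp.

    Window pi divides the summed per-site pi by the nominal window size;
    terminal truncated windows divide by their actual span.
    """
    lengths = _chrom_lengths_for(gm, chrom_lengths)
    grid = window_grid(lengths, window, step)
    pi = per_site_pi(gm, sample_idx)
    sums, counts = _window_sums(gm.loci, pi, grid)
    span = grid["end"] - grid["start"] + 1
    denom = np.where(span < window, span, window).astype(float)
    out = grid.copy()
    out["pi_per_bp"] = sums / denom
    out["n_variant_sites"] = counts
    return out


# ---------------------------------------------------------------------------
# filtering and merging
# ---------------------------------------------------------------------------

def filter_loci(
    gm: GenotypeMatrix,
    min_depth: int | None = 4,
    max_missing: float | None = 0.3,
    min_maf: float | None = 0.01,
    min_site_quality: float | None = 20.0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Sequential locus filters in the fixed order depth -> missingness ->
    site quality -> MAF; any threshold may be None to disable that step.

    Depth filtering masks individual genotypes (depth < min_depth becomes
    missing), so completeness is evaluated post-masking. Returns the
    filtered matrix and a per-step report of surviving locus counts.
    """
    if max_missing is not None and not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must lie in [0, 1]")
    if min_maf is not None and not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must lie in [0, 0.5]")
    out = gm.copy()
    steps = []
    if min_depth is not None:
        if out.D is None:
            raise ValueError("depth filter requested but no depth matrix present")
        masked = int(((out.D < min_depth) & (out.G >= 0)).sum())
        out.G[out.D < min_depth] = -1
        steps.append(("depth_mask", out.n_loci, out.n_loci, masked))
    if max_missing is not None:
        before = out.n_loci
        miss_frac = (out.G < 0).mean(axis=0)
        out = out.take_loci(miss_frac <= max_missing)
        steps.append(("missingness", before, out.n_loci, before - out.n_loci))
    if min_site_quality is not None:
        if "site_quality" not in out.loci.columns:
            raise ValueError(
                "site-quality filter requested but loci carry no site_quality"
            )
        before = out.n_loci
        sq = out.loci["site_quality"].to_numpy(dtype=float)
        keep = np.isnan(sq) | (sq >= min_site_quality)
        out = out.take_loci(keep)
        steps.append(("site_quality", before, out.n_loci, before - out.n_loci))
    if min_maf is not None:
        before = out.n_loci
        st = locus_stats(out)
        keep = (st["maf"] >= min_maf) & st["defined"]
        out = out.take_loci(keep.to_numpy())
        steps.append(("maf", before, out.n_loci, before - out.n_loci))
    report = pd.DataFrame(
        steps, columns=["step", "n_in", "n_out", "n_removed_or_masked"]
    )
    return out, report


def merge_datasets(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> GenotypeMatrix:
    """Intersect loci on (chrom, pos, ref, alt) and concatenate samples.

    A shared position with conflicting alleles (swap or strand flip) raises;
    duplicate sample IDs across inputs raise. Re-filtering the merged matrix
    is the caller's next step.
    """
    dup = set(gm_a.sample_ids) & set(gm_b.sample_ids)
    if dup:
        raise ValueError(f"duplicate sample ids across datasets: {sorted(dup)}")
    a = gm_a.loci[["chrom", "pos", "ref", "alt"]].reset_index().rename(
        columns={"index": "ia"}
    )
    b = gm_b.loci[["chrom", "pos", "ref", "alt"]].reset_index().rename(
        columns={"index": "ib"}
    )
    pos_join = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    conflict = pos_join[
        (pos_join["ref_a"] != pos_join["ref_b"])
        | (pos_join["alt_a"] != pos_join["alt_b"])
    ]
    if len(conflict):
        first = conflict.iloc[0]
        raise ValueError(
            "conflicting alleles at shared position "
            f"{first['chrom']}:{first['pos']} "
            f"({first['ref_a']}>{first['alt_a']} vs {first['ref_b']}>{first['alt_b']})"
        )
    ia = pos_join["ia"].to_numpy()
    ib = pos_join["ib"].to_numpy()
    loci = gm_a.loci.iloc[ia].reset_index(drop=True)
    G = np.vstack([gm_a.G[:, ia], gm_b.G[:, ib]])
    D = (
        np.vstack([gm_a.D[:, ia], gm_b.D[:, ib]])
        if (gm_a.D is not None and gm_b.D is not None)
        else None
    )
    lengths = gm_a.chrom_lengths or gm_b.chrom_lengths
    return GenotypeMatrix(
        gm_a.sample_ids + gm_b.sample_ids, loci, G, D=D, chrom_lengths=lengths,
        sample_platform={**gm_a.sample_platform, **gm_b.sample_platform},
    )
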