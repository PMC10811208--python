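"""Synthetic two-ancestry crossbred cohorts with known ground truth.

The generator emulates the data structure the downstream analyses assume: two
diverged ancestral panels under the Balding–Nichols model, an admixed cohort
with per-individual ancestry proportions and recombination-scale ancestry
tracts, a second near-single-ancestry cohort, reduced-representation-like
(high-missingness) vs whole-genome-like (low-missingness) platforms with
per-genotype depth, and implanted low-diversity / high-differentiation sweep
regions.

All randomness flows from one integer seed through named
``numpy.random.Generator`` sub-streams, so identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GeneAnnotation, GenotypeMatrix, PopulationMap


@dataclass
class SimulationConfig:
    """Study conditions for the two-ancestry crossbred simulation.

    Defaults mirror the structure of a grazing-type crossbred cattle cohort
    genotyped on a reduced-representation platform alongside whole-genome
    ancestral panels: a large admixed cohort with mean ancestry-2 proportion
    0.6278, a small near-pure cohort (mean ancestry-1 proportion 0.9514),
    panels of 19 and 9, mean genotype depth 12.36, and ten generations since
    admixture on a uniform 1 cM/Mb map.
    """

    n_loci: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 20_000_000 for i in range(1, 6)}
    )
    p_anc_range: tuple[float, float] = (0.05, 0.95)
    fst_divergence: float = 0.2
    n_panel1: int = 19          # ancestry-1 reference panel (e.g. Brown Swiss-like)
    n_panel2: int = 9           # ancestry-2 reference panel (e.g. Kazakh-like)
    n_admixed: int = 129        # grazing-type-like admixed cohort
    n_admixed2: int = 20        # housing-type-like near-pure cohort
    mean_admix: float = 0.6278  # mean ancestry-2 proportion of the admixed cohort
    mean_admix2: float = 0.9514  # mean ancestry-1 proportion of the second cohort
    admix_concentration: float = 20.0  # Beta a+b for per-individual proportions
    gen_since_admix: float = 10.0
    recomb_rate: float = 1e-8   # Morgans per bp (1 cM/Mb)
    miss_rate_slaf: float = 0.30
    miss_rate_wgs: float = 0.02
    depth_mean: float = 12.36
    sweep_regions: list[tuple[str, int, int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_divergence < 1.0):
            raise ValueError("fst_divergence must lie in (0, 1)")
        for r in (self.miss_rate_slaf, self.miss_rate_wgs):
            if not (0.0 <= r <= 1.0):
                raise ValueError("missingness rates must lie in [0, 1]")
        lo, hi = self.p_anc_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("p_anc_range must satisfy 0 < lo < hi < 1")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for chrom, start, end, _pop in self.sweep_regions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sweep region on unknown chromosome {chrom}")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ValueError(f"sweep region {chrom}:{start}-{end} out of bounds")

    def rng(self, stream: str) -> np.random.Generator:
        """Named sub-stream of the config seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_stream_key(stream),))
        return np.random.default_rng(ss)


def _stream_key(name: str) -> int:
    return int.from_bytes(name.encode()[:8].ljust(8, b"\0"), "little") % (2**31)


@dataclass
class TruthSet:
    """Ground truth for an admixed cohort.

    ``dosage[i, l]`` counts ancestry-1 haplotypes in {0,1,2}; ``q_true[i]``
    is the realized genome-wide ancestry-1 proportion, exactly
    ``mean(dosage[i]) / 2`` by construction. ``q_target`` is the Beta draw
    the tract process was parameterized with.
    """

    q_true: np.ndarray
    q_target: np.ndarray
    dosage: np.ndarray
    sweep_windows: list[tuple[str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def simulate_positions(
    n_loci: int, chrom_lengths: dict[str, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Uniform random SNP coordinates with random ref/alt alleles."""
    total = sum(chrom_lengths.values())
    rows = []
    bases = np.array(list("ACGT"))
    for chrom, length in chrom_lengths.items():
        k = int(round(n_loci * length / total))
        pos = np.sort(rng.choice(length, size=min(k, length), replace=False)) + 1
        ref_i = rng.integers(0, 4, size=len(pos))
        alt_i = (ref_i + rng.integers(1, 4, size=len(pos))) % 4
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": bases[ref_i], "alt": bases[alt_i]}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_ancestral_freqs(
    p_base: np.ndarray, fst_divergence: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two ancestry-specific frequency vectors under Balding–Nichols.

    Each ancestry's frequency at locus *l* is Beta(p(1-F)/F, (1-p)(1-F)/F),
    so E[f] = p and Var[f] = F·p(1-p).
    """
    p = np.asarray(p_base, dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("p_base entries must lie strictly in (0, 1)")
    F = float(fst_divergence)
    if not (0.0 < F < 1.0):
        raise ValueError("fst_divergence must lie in (0, 1)")
    scale = (1.0 - F) / F
    f1 = rng.beta(p * scale, (1.0 - p) * scale)
    f2 = rng.beta(p * scale, (1.0 - p) * scale)
    return f1, f2


def simulate_panel(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """HWE genotypes (binomial(2, f)) for one ancestral panel."""
    return rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(np.int8)


def _genetic_gaps(loci: pd.DataFrame, recomb_rate: float) -> np.ndarray:
    """Inter-locus distance in Morgans; inf across chromosome boundaries."""
    pos = loci["pos"].to_numpy(dtype=float)
    chrom = loci["chrom"].to_numpy()
    gaps = np.empty(len(loci))
    gaps[0] = np.inf
    gaps[1:] = np.where(
        chrom[1:] == chrom[:-1], (pos[1:] - pos[:-1]) * recomb_rate, np.inf
    )
    return gaps


def _switch_probs(gaps: np.ndarray, gen_since_admix: float) -> np.ndarray:
    """Per-gap haplotype ancestry-switch probability 1 - exp(-d·G);
    chromosome boundaries (infinite gap) always switch to stationarity."""
    s = np.ones_like(gaps)
    finite = np.isfinite(gaps)
    s[finite] = -np.expm1(-gaps[finite] * gen_since_admix)
    return s


def _sample_tract_states(
    switch_prob: np.ndarray, q: float, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype's ancestry along the genome (0 = ancestry 1).

    The two-state chain with stationary (q, 1-q) and per-gap total switch
    probability s is simulated by its renewal representation: at each locus,
    with probability s the state is redrawn from the stationary law,
    otherwise it is copied — which yields exactly the transition matrix
    P(next=anc1 | cur) = (1-s)·1[cur=anc1] + s·q.
    """
    m = len(switch_prob)
    resample = rng.random(m) < switch_prob
    resample[0] = True
    fresh = (rng.random(m) >= q).astype(np.int8)  # 0 with prob q
    last = np.maximum.accumulate(np.where(resample, np.arange(m), -1))
    return fresh[last]


def simulate_admixed_cohort(
    freqs: tuple[np.ndarray, np.ndarray],
    loci: pd.DataFrame,
    n: int,
    admix_alpha: tuple[float, float],
    gen_since_admix: float,
    rng: np.random.Generator,
    recomb_rate: float = 1e-8,
    sample_prefix: str = "ADM",
    q_fixed: float | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate *n* admixed diploids with Markov ancestry tracts.

    Per individual, the ancestry-1 proportion q is Beta(admix_alpha) (or
    ``q_fixed``); each haplotype is a two-state Markov chain along each
    chromosome with stationary (q, 1-q) and switch probability
    1 - exp(-d·G) per inter-locus genetic distance d; the allele given
    ancestry is Bernoulli(f_ancestry) and the genotype is the haplotype sum.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(loci) == 0:
        raise ValueError("empty locus set")
    f1, f2 = (np.asarray(f, dtype=float) for f in freqs)
    if f1.shape != f2.shape or len(f1) != len(loci):
        raise ValueError("frequency vectors must cover the locus set")
    m = len(loci)
    gaps = _genetic_gaps(loci, recomb_rate)
    s = _switch_probs(gaps, gen_since_admix)
    G = np.empty((n, m), dtype=np.int8)
    dosage = np.empty((n, m), dtype=np.int8)
    if q_fixed is not None:
        q_target = np.full(n, float(q_fixed))
    else:
        q_target = rng.beta(admix_alpha[0], admix_alpha[1], size=n)
    fmat = np.stack([f1, f2])
    for i in range(n):
        h1 = _sample_tract_states(s, q_target[i], rng)
        h2 = _sample_tract_states(s, q_target[i], rng)
        a1 = (rng.random(m) < fmat[h1, np.arange(m)]).astype(np.int8)
        a2 = (rng.random(m) < fmat[h2, np.arange(m)]).astype(np.int8)
        G[i] = a1 + a2
        dosage[i] = (h1 == 0).astype(np.int8) + (h2 == 0).astype(np.int8)
    gm = GenotypeMatrix(
        [f"{sample_prefix}{i:03d}" for i in range(n)], loci, G
    )
    truth = TruthSet(
        q_true=dosage.mean(axis=1) / 2.0, q_target=q_target, dosage=dosage
    )
    return gm, truth


def implant_sweep(
    gm: GenotypeMatrix,
    freqs: np.ndarray,
    region: tuple[str, int, int],
    target_samples,
    rng: np.random.Generator,
    push: float = 0.98,
) -> GenotypeMatrix:
    """Redraw the target samples' genotypes in *region* near fixation.

    Within the region each frequency f is replaced by ``push`` if f >= 0.5
    else ``1 - push``, reducing nucleotide diversity and raising
    differentiation there; all other loci and samples are untouched.
    """
    chrom, start, end = region
    in_region = (
        (gm.loci["chrom"] == chrom)
        & (gm.loci["pos"] >= start)
        & (gm.loci["pos"] <= end)
    ).to_numpy()
    if not in_region.any():
        warnings.warn(f"sweep region {chrom}:{start}-{end} contains no loci; no-op")
        return gm
    out = gm.copy()
    idx = out.sample_indices(target_samples)
    f = np.asarray(freqs, dtype=float)[in_region]
    f_swept = np.where(f >= 0.5, push, 1.0 - push)
    cols = np.flatnonzero(in_region)
    out.G[np.ix_(idx, cols)] = rng.binomial(
        2, f_swept[None, :], size=(len(idx), len(cols))
    ).astype(np.int8)
    return out


def apply_platform_effects(
    gm: GenotypeMatrix,
    miss_rate: float,
    depth_mean: float,
    rng: np.random.Generator,
    platform: str = "slaf",
) -> GenotypeMatrix:
    """Mask genotypes missing at *miss_rate* and attach Poisson(>=1) depths."""
    if not (0.0 <= miss_rate <= 1.0):
        raise ValueError("miss_rate must lie in [0, 1]")
    out = gm.copy()
    mask = rng.random(out.G.shape) < miss_rate
    out.G[mask] = -1
    depth = rng.poisson(depth_mean, size=out.G.shape)
    zero = depth == 0
    while zero.any():  # Poisson conditioned >= 1
        depth[zero] = rng.poisson(depth_mean, size=int(zero.sum()))
        zero = depth == 0
    depth[mask] = 0
    out.D = depth
    out.sample_platform = {s: platform for s in out.sample_ids}
    return out


def simulate_gene_annotation(
    chrom_lengths: dict[str, int],
    gene_length: int = 2000,
    spacing: int = 8000,
    rng: np.random.Generator | None = None,
) -> GeneAnnotation:
    """Tile non-overlapping gene intervals with the given spacing.

    Genes start at multiples of ``gene_length + spacing`` (0-based); strand
    is random when a generator is supplied, else '+'. Deterministic given
    the generator state.
    """
    if gene_length <= 0 or spacing <= 0:
        raise ValueError("gene_length and spacing must be positive")
    period = gene_length + spacing
    rows = []
    for chrom, length in chrom_lengths.items():
        n_genes = max(0, length // period)
        if n_genes == 0:
            warnings.warn(f"{chrom}: too short for any gene (period {period})")
            continue
        starts = np.arange(n_genes) * period
        strand = (
            np.where(rng.random(n_genes) < 0.5, "+", "-")
            if rng is not None
            else np.full(n_genes, "+")
        )
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + gene_length,
                    "name": [f"{chrom}_g{k}" for k in range(n_genes)],
                    "strand": strand,
                }
            )
        )
    if not rows:
        return GeneAnnotation(
            pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
        )
    return GeneAnnotation(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# full-study orchestrator
# ---------------------------------------------------------------------------

def alpha_for_mean(mean: float, concentration: float) -> tuple[float, float]:
    """Beta parameters with the given mean and a+b = concentration."""
    return (mean * concentration, (1.0 - mean) * concentration)


def simulate_study(config: SimulationConfig) -> dict:
    """Generate the full synthetic study: panels, two admixed cohorts,
    platform effects, sweep regions, gene annotation, population map.

    Returns a dict with keys ``panel1``, ``panel2``, ``admixed``,
    ``admixed2`` (GenotypeMatrix), ``truth``, ``truth2`` (TruthSet),
    ``freqs`` (pair of ancestral frequency vectors), ``annotation``,
    ``popmap``, ``loci`` and ``config``.
    """
    cfg = config
    loci = simulate_positions(cfg.n_loci, cfg.chrom_lengths, cfg.rng("positions"))
    p_base = cfg.rng("pbase").uniform(*cfg.p_anc_range, size=len(loci))
    f1, f2 = simulate_ancestral_freqs(
        p_base, cfg.fst_divergence, cfg.rng("ancestral")
    )

    g1 = simulate_panel(f1, cfg.n_panel1, cfg.rng("panel1"))
    g2 = simulate_panel(f2, cfg.n_panel2, cfg.rng("panel2"))
    panel1 = GenotypeMatrix(
        [f"P1_{i:03d}" for i in range(cfg.n_panel1)], loci, g1,
        chrom_lengths=cfg.chrom_lengths,
    )
    panel2 = GenotypeMatrix(
        [f"P2_{i:03d}" for i in range(cfg.n_panel2)], loci, g2,
        chrom_lengths=cfg.chrom_lengths,
    )

    # ancestry-1 proportion of the main cohort is 1 - mean_admix
    # (mean_admix parameterizes the ancestry-2 share, as in the study design)
    admixed, truth = simulate_admixed_cohort(
        (f1, f2), loci, cfg.n_admixed,
        alpha_for_mean(1.0 - cfg.mean_admix, cfg.admix_concentration),
        cfg.gen_since_admix, cfg.rng("admixed"),
        recomb_rate=cfg.recomb_rate, sample_prefix="ADM",
    )
    admixed2, truth2 = simulate_admixed_cohort(
        (f1, f2), loci, cfg.n_admixed2,
        alpha_for_mean(cfg.mean_admix2, cfg.admix_concentration),
        cfg.gen_since_admix, cfg.rng("admixed2"),
        recomb_rate=cfg.recomb_rate, sample_prefix="HSD",
    )
    admixed.chrom_lengths = cfg.chrom_lengths
    admixed2.chrom_lengths = cfg.chrom_lengths

    sweep_rng = cfg.rng("sweep")
    pops = {"panel1": panel1, "panel2": panel2, "admixed": admixed,
            "admixed2": admixed2}
    freqs_by_pop = {"panel1": f1, "panel2": f2, "admixed": f2, "admixed2": f1}
    for chrom, start, end, target in cfg.sweep_regions:
        gm = pops[target]
        pops[target] = implant_sweep(
            gm, freqs_by_pop[target], (chrom, start, end), gm.sample_ids, sweep_rng
        )
    truth.sweep_windows = [
        (c, s, e) for c, s, e, t in cfg.sweep_regions
    ]

    plat_rng = cfg.rng("platform")
    pops["admixed"] = apply_platform_effects(
        pops["admixed"], cfg.miss_rate_slaf, cfg.depth_mean, plat_rng, "slaf"
    )
    for key in ("panel1", "panel2", "admixed2"):
        pops[key] = apply_platform_effects(
            pops[key], cfg.miss_rate_wgs, cfg.depth_mean, plat_rng, "wgs"
        )

    annotation = simulate_gene_annotation(
        cfg.chrom_lengths, rng=cfg.rng("genes")
    )
    popmap = PopulationMap(
        pd.DataFrame(
            {
                "sample": (
                    pops["admixed"].sample_ids + pops["admixed2"].sample_ids
                    + pops["panel1"].sample_ids + pops["panel2"].sample_ids
                ),
                "population": (
                    ["ADMIXED"] * cfg.n_admixed + ["ADMIXED2"] * cfg.n_admixed2
                    + ["ANC1"] * cfg.n_panel1 + ["ANC2"] * cfg.n_panel2
                ),
            }
        )
    )
    return {
        "panel1": pops["panel1"], "panel2": pops["panel2"],
        "admixed": pops["admixed"], "admixed2": pops["admixed2"],
        "truth": truth, "truth2": truth2, "freqs": (f1, f2),
        "annotation": annotation, "popmap": popmap, "loci": loci,
        "config": cfg,
    }


def write_study(study: dict, outdir) -> None:
    """Write VCFs, truth TSV, population map and gene BED for a study dict."""
    from pathlib import Path

    from . import io as aio
    from .diversity import merge_datasets

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("panel1", "panel2", "admixed", "admixed2"):
        aio.write_vcf(study[key], out / f"{key}.vcf")
    merged = merge_datasets(
        merge_datasets(study["panel1"], study["panel2"]),
        merge_datasets(study["admixed"], study["admixed2"]),
    )
    aio.write_vcf(merged, out / "all.vcf")
    aio.write_population_map(study["popmap"], out / "popmap.tsv")
    aio.write_bed(study["annotation"], out / "genes.bed")
    aio.write_truth_tsv(
        study["admixed"].sample_ids, study["loci"], study["truth"].dosage,
        out / "truth_admixed.tsv",
    )
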