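"""Diploid local-ancestry inference by a genotype-based hidden Markov model.

The query genome is modelled as two independent haplotypes, each an
ancestry-1/ancestry-2 Markov chain along the chromosome with per-gap switch
probability 1 - exp(-d·G) (d the genetic distance in Morgans, G generations
since admixture) and stationary law (α, 1-α). The diploid chain runs over
ordered ancestry pairs; posteriors are reported on the three unordered
states {(1,1), (1,2), (2,2)}. Emissions come from reference-panel allele
frequencies: given haplotype ancestries with frequencies (fa, fb) the
genotype is the sum of two Bernoulli draws; missing genotypes are
uninformative. Panel frequencies of exactly 0 or 1 are clamped to
[eps, 1-eps] with eps = 1/(2·n_panel + 1).

The forward–backward recursion is vectorized across individuals; a Viterbi
decoder is available for hard tract calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, PopulationMap
from .diversity import allele_frequency
from .simulate import _genetic_gaps, _switch_probs

logger = logging.getLogger(__name__)

# ordered diploid states: haplotype ancestries (0-based ancestry index)
_ORDERED = ((0, 0), (0, 1), (1, 0), (1, 1))
#: unordered state order used in outputs
UNORDERED_STATES = ("anc1/anc1", "anc1/anc2", "anc2/anc2")


def _panel_freqs(panel: GenotypeMatrix) -> np.ndarray:
    f = allele_frequency(panel)
    if np.isnan(f).any():
        raise ValueError("panel has loci with no called genotypes")
    eps = 1.0 / (2.0 * panel.n_samples + 1.0)
    n_clamped = int(((f < eps) | (f > 1.0 - eps)).sum())
    if n_clamped:
        logger.info(
            "clamped %d fixed panel frequencies to [%.4g, %.4g]",
            n_clamped, eps, 1.0 - eps,
        )
    return np.clip(f, eps, 1.0 - eps)


def _check_shared_loci(query: GenotypeMatrix, *panels: GenotypeMatrix) -> None:
    qk = query.loci[["chrom", "pos"]].to_numpy()
    for p in panels:
        pk = p.loci[["chrom", "pos"]].to_numpy()
        if qk.shape != pk.shape or not (qk == pk).all():
            raise ValueError("query and panels must share an identical locus set")


def _emissions(G: np.ndarray, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """(n, m, 4) emission probabilities over ordered diploid states."""
    n, m = G.shape
    f = np.stack([f1, f2])  # (2, m)
    E = np.empty((n, m, 4))
    for s, (a, b) in enumerate(_ORDERED):
        fa, fb = f[a], f[b]
        probs = np.stack(
            [
                (1 - fa) * (1 - fb),
                fa * (1 - fb) + (1 - fa) * fb,
                fa * fb,
            ]
        )  # (3, m)
        e = np.where(G >= 0, probs[np.clip(G, 0, 2), np.arange(m)[None, :]], 1.0)
        E[:, :, s] = e
    return E


def _transition_stack(switch: np.ndarray, alpha: float) -> np.ndarray:
    """(m, 4, 4) diploid transition matrices (Kronecker square of the
    per-haplotype chain) for each inter-locus gap."""
    s = switch[:, None, None]
    T = np.empty((len(switch), 2, 2))
    T[:, 0, 0] = 1.0 - switch * (1.0 - alpha)
    T[:, 0, 1] = switch * (1.0 - alpha)
    T[:, 1, 0] = switch * alpha
    T[:, 1, 1] = 1.0 - switch * alpha
    del s
    TT = np.einsum("lab,lcd->lacbd", T, T).reshape(len(switch), 4, 4)
    return TT


@dataclass
class LocalAncestryResults:
    """Per-locus diploid ancestry posteriors and global summaries.

    ``posterior[i, l]`` is the probability vector over the unordered states
    {(1,1), (1,2), (2,2)}; ``dosage`` = 2·P(1,1) + P(1,2) is the expected
    ancestry-1 haplotype count and the per-individual global ancestry-1
    proportion is its mean over loci divided by two.
    """

    posterior: np.ndarray  # (n, m, 3)
    sample_ids: list[str]
    loci: pd.DataFrame
    viterbi_path: np.ndarray | None = None  # (n, m) in {0,1,2} ancestry-1 count

    @property
    def dosage(self) -> np.ndarray:
        return 2.0 * self.posterior[:, :, 0] + self.posterior[:, :, 1]

    @property
    def global_proportion(self) -> np.ndarray:
        """Per-individual genome-wide ancestry-1 proportion (posterior mean)."""
        return self.dosage.mean(axis=1) / 2.0

    def hard_calls(self) -> np.ndarray:
        """Per-locus ancestry-1 count from the posterior mode (0, 1 or 2)."""
        mode = np.argmax(self.posterior, axis=2)
        return (2 - mode).astype(np.int8)

    def global_summary(self, popmap: PopulationMap) -> pd.DataFrame:
        """Population means of the two global ancestry proportions."""
        q = self.global_proportion
        pops = popmap.table.set_index("sample")["population"]
        df = pd.DataFrame(
            {
                "sample": self.sample_ids,
                "population": [pops.get(s, "?") for s in self.sample_ids],
                "ancestry1": q,
                "ancestry2": 1.0 - q,
            }
        )
        return (
            df.groupby("population", sort=False)[["ancestry1", "ancestry2"]]
            .mean()
            .reset_index()
        )

    def summary(self, popmap: PopulationMap | None = None) -> str:
        q = self.global_proportion
        lines = [
            "Local-ancestry inference (diploid genotype HMM, forward-backward)",
            f"  individuals = {len(self.sample_ids)}   loci = {self.posterior.shape[1]}",
            f"  mean global ancestry-1 proportion = {q.mean():.4f} "
            f"(ancestry-2 = {1 - q.mean():.4f})",
        ]
        if popmap is not None:
            for _, row in self.global_summary(popmap).iterrows():
                lines.append(
                    f"    {row['population']:<12s} "
                    f"anc1={row['ancestry1']:.4f}  anc2={row['ancestry2']:.4f}"
                )
        return "\n".join(lines)

    def plot_tracts(self, individual: int = 0, ax=None):
        """Posterior ancestry-1 dosage along the genome for one individual."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2))
        ax.plot(self.dosage[individual], lw=0.8)
        ax.set_ylim(-0.05, 2.05)
        ax.set_ylabel("ancestry-1 dosage")
        ax.set_xlabel("locus index")
        ax.set_title(self.sample_ids[individual])
        return ax


@dataclass
class LocalAncestryModel:
    """Diploid ancestry HMM for a query cohort against two reference panels."""

    query: GenotypeMatrix
    panel1: GenotypeMatrix
    panel2: GenotypeMatrix
    gen_since_admix: float = 10.0
    recomb_rate: float = 1e-8
    prior: float = 0.5  # stationary ancestry-1 probability per haplotype

    def __post_init__(self) -> None:
        _check_shared_loci(self.query, self.panel1, self.panel2)
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must lie strictly in (0, 1)")

    def fit(self, viterbi: bool = False) -> LocalAncestryResults:
        f1 = _panel_freqs(self.panel1)
        f2 = _panel_freqs(self.panel2)
        G = self.query.G
        n, m = G.shape
        E = _emissions(G, f1, f2)
        gaps = _genetic_gaps(self.query.loci, self.recomb_rate)
        switch = _switch_probs(gaps, self.gen_since_admix)
        TT = _transition_stack(switch, self.prior)
        a = self.prior
        init = np.kron([a, 1 - a], [a, 1 - a])

        # forward (scaled), vectorized over individuals
        A = np.empty((n, m, 4))
        A[:, 0] = init[None, :] * E[:, 0]
        A[:, 0] /= A[:, 0].sum(axis=1, keepdims=True)
        for l in range(1, m):
            # gap l has switch prob for the transition into locus l; at
            # chromosome starts switch = 1 which resets to the stationary law
            A[:, l] = (A[:, l - 1] @ TT[l]) * E[:, l]
            A[:, l] /= A[:, l].sum(axis=1, keepdims=True)

        B = np.empty((n, m, 4))
        B[:, m - 1] = 1.0
        for l in range(m - 2, -1, -1):
            B[:, l] = (E[:, l + 1] * B[:, l + 1]) @ TT[l + 1].T
            B[:, l] /= B[:, l].sum(axis=1, keepdims=True)

        post4 = A * B
        post4 /= post4.sum(axis=2, keepdims=True)
        post = np.stack(
            [post4[:, :, 0], post4[:, :, 1] + post4[:, :, 2], post4[:, :, 3]],
            axis=2,
        )
        path = self._viterbi(E, TT, init) if viterbi else None
        return LocalAncestryResults(
            post, list(self.query.sample_ids), self.query.loci, viterbi_path=path
        )

    def _viterbi(self, E, TT, init) -> np.ndarray:
        n, m, _ = E.shape
        with np.errstate(divide="ignore"):
            logE = np.log(E)
            logTT = np.log(TT)
            loginit = np.log(init)
        delta = loginit[None, :] + logE[:, 0]
        psi = np.empty((n, m, 4), dtype=np.int8)
        for l in range(1, m):
            cand = delta[:, :, None] + logTT[l][None, :, :]  # (n, from, to)
            psi[:, l] = np.argmax(cand, axis=1)
            delta = np.max(cand, axis=1) + logE[:, l]
        states = np.empty((n, m), dtype=np.int8)
        states[:, m - 1] = np.argmax(delta, axis=1)
        for l in range(m - 1, 0, -1):
            states[:, l - 1] = psi[np.arange(n), l, states[:, l]]
        # ordered state -> ancestry-1 haplotype count
        anc1_count = np.array([2, 1, 1, 0], dtype=np.int8)
        return anc1_count[states]


def local_ancestry(
    gm_query: GenotypeMatrix,
    panel1: GenotypeMatrix,
    panel2: GenotypeMatrix,
    gen_since_admix: float = 10.0,
    recomb_rate: float = 1e-8,
    prior: float = 0.5,
    viterbi: bool = False,
) -> LocalAncestryResults:
    """Functional wrapper around :class:`LocalAncestryModel`."""
    return LocalAncestryModel(
        gm_query, panel1, panel2, gen_since_admix=gen_since_admix,
        recomb_rate=recomb_rate, prior=prior,
    ).fit(viterbi=viterbi)


def global_ancestry_summary(
    results: LocalAncestryResults, popmap: PopulationMap
) -> pd.DataFrame:
    """Per-population mean global ancestry proportions (the two sum to 1)."""
    return results.global_summary(popmap)
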