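"""Maximum-likelihood admixture estimation under the binomial model.

Each genotype g_il (alt-allele dosage, missing excluded) is modelled as
Binomial(2, d_il) with d_il = sum_k q_ik f_kl: Q (n x K) holds per-individual
ancestry fractions on the simplex, F (K x m) the ancestral allele
frequencies. The log-likelihood

    L(Q, F) = sum_il [ g_il log d_il + (2 - g_il) log(1 - d_il) ]

is maximized by EM with multiple random restarts; the EM updates guarantee a
non-decreasing likelihood, which is asserted every iteration. The number of
ancestral clusters K is chosen by masking cross-validation, scoring held-out
genotypes by squared dosage error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, PopulationMap

_EPS = 1e-9


def _loglik(G, called, Q, F):
    D = np.clip(Q @ F, _EPS, 1.0 - _EPS)
    g = np.where(called, G, 0).astype(float)
    ll = g * np.log(D) + (2.0 - g) * np.log1p(-D)
    return float(ll[called].sum())


def _em_step(g, w, Q, F):
    """One EM update of (Q, F) given alt counts ``g`` and call weights ``w``.

    Returns the updated (Q, F) and the log-likelihood at the *input*
    parameters (computed from the same D, so the step costs one pass).
    The per-(i,l,k) responsibilities reduce to matrix products:
    q_ik <- q_ik [ (w g / D) F^T + (w (2-g)/(1-D)) (1-F)^T ]_ik / (2 m_i),
    f_kl <- [F (Q^T A)] / [F (Q^T A) + (1-F)(Q^T R)] with A, R the alt/ref
    per-allele ratios above.
    """
    D = np.clip(Q @ F, _EPS, 1.0 - _EPS)
    ll = float((w * (g * np.log(D) + (2.0 - g) * np.log1p(-D))).sum())
    AoD = w * g / D
    RoD = w * (2.0 - g) / (1.0 - D)
    q_new = Q * (AoD @ F.T + RoD @ (1.0 - F).T)
    q_new /= q_new.sum(axis=1, keepdims=True)
    f_alt = F * (Q.T @ AoD)
    f_ref = (1.0 - F) * (Q.T @ RoD)
    with np.errstate(invalid="ignore", divide="ignore"):
        F_new = f_alt / (f_alt + f_ref)
    F_new = np.where(np.isfinite(F_new), F_new, F)
    return q_new, np.clip(F_new, _EPS, 1.0 - _EPS), ll


@dataclass
class AdmixtureResults:
    """Fitted admixture model: estimates, fit trace and diagnostics."""

    Q: np.ndarray
    F: np.ndarray
    loglik_trace: np.ndarray
    K: int
    converged: bool
    n_restarts: int
    sample_ids: list[str]
    cv_error: float | None = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def q_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.Q, columns=[f"Q{k + 1}" for k in range(self.K)]
        )
        df.insert(0, "sample", self.sample_ids)
        return df

    def mean_q_by_population(self, popmap: PopulationMap) -> pd.DataFrame:
        df = self.q_frame().merge(
            popmap.table[["sample", "population"]], on="sample"
        )
        return df.groupby("population", sort=False)[
            [f"Q{k + 1}" for k in range(self.K)]
        ].mean().reset_index()

    def summary(self, popmap: PopulationMap | None = None) -> str:
        lines = [
            "Admixture fit (binomial-likelihood EM)",
            f"  K = {self.K}   samples = {len(self.sample_ids)}   "
            f"loci = {self.F.shape[1]}",
            f"  log-likelihood = {self.loglik:.2f}   "
            f"iterations = {len(self.loglik_trace)}   "
            f"converged = {self.converged}   restarts = {self.n_restarts}",
        ]
        if self.cv_error is not None:
            lines.append(f"  cross-validation error = {self.cv_error:.6f}")
        if popmap is not None:
            lines.append("  mean ancestry fractions by population:")
            tbl = self.mean_q_by_population(popmap)
            for _, row in tbl.iterrows():
                qs = "  ".join(
                    f"Q{k + 1}={row[f'Q{k + 1}']:.4f}" for k in range(self.K)
                )
                lines.append(f"    {row['population']:<12s} {qs}")
        return "\n".join(lines)

    def plot_bar(self, popmap: PopulationMap | None = None, ax=None):
        """Stacked per-individual ancestry bar plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        order = np.arange(len(self.sample_ids))
        if popmap is not None:
            pops = popmap.table.set_index("sample")["population"]
            keys = [pops.get(s, "?") for s in self.sample_ids]
            order = np.argsort(keys, kind="stable")
        bottom = np.zeros(len(order))
        for k in range(self.K):
            vals = self.Q[order, k]
            ax.bar(np.arange(len(order)), vals, bottom=bottom, width=1.0,
                   label=f"ancestry {k + 1}")
            bottom += vals
        ax.set_xlim(-0.5, len(order) - 0.5)
        ax.set_ylim(0, 1)
        ax.set_ylabel("ancestry fraction")
        ax.legend(loc="upper right", fontsize="small")
        return ax


@dataclass
class AdmixtureModel:
    """Binomial-likelihood admixture model over a genotype matrix.

    Build from a MAF-filtered :class:`GenotypeMatrix`; ``fit(K)`` runs EM
    with random restarts and returns :class:`AdmixtureResults`.
    """

    gm: GenotypeMatrix
    _G: np.ndarray = field(init=False, repr=False)
    _called: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._G = self.gm.G
        self._called = self.gm.G >= 0

    def fit(
        self,
        K: int,
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-4,
        n_restarts: int = 3,
    ) -> AdmixtureResults:
        n, m = self._G.shape
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > n:
            raise ValueError("K may not exceed the number of samples")
        if K == 1:
            # closed form: q = 1, f = observed allele frequencies
            from .diversity import allele_frequency

            p = np.clip(
                np.nan_to_num(allele_frequency(self.gm), nan=0.5), _EPS, 1 - _EPS
            )
            Q = np.ones((n, 1))
            F = p[None, :]
            ll = _loglik(self._G, self._called, Q, F)
            return AdmixtureResults(
                Q, F, np.array([ll]), 1, True, 1, list(self.gm.sample_ids)
            )
        rng = np.random.default_rng(seed)
        best: AdmixtureResults | None = None
        for _ in range(n_restarts):
            res = self._fit_once(K, rng, max_iter, tol)
            if best is None or res.loglik > best.loglik:
                best = res
        best.n_restarts = n_restarts
        return best

    def _fit_once(self, K, rng, max_iter, tol) -> AdmixtureResults:
        from .diversity import allele_frequency

        n, m = self._G.shape
        Q = rng.dirichlet(np.ones(K), size=n)
        p = np.clip(
            np.nan_to_num(allele_frequency(self.gm), nan=0.5), 0.05, 0.95
        )
        F = np.clip(
            p[None, :] * (1.0 + 0.2 * rng.standard_normal((K, m))), _EPS, 1 - _EPS
        )
        g = np.where(self._called, self._G, 0).astype(float)
        w = self._called.astype(float)
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            Q, F, ll = _em_step(g, w, Q, F)
            if trace and ll < trace[-1] - 1e-6:
                raise AssertionError(
                    f"EM likelihood decreased: {trace[-1]:.6f} -> {ll:.6f}"
                )
            if trace and ll - trace[-1] < tol:
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
        return AdmixtureResults(
            Q, F, np.asarray(trace), K, converged, 1, list(self.gm.sample_ids)
        )

    # -- cross-validation ------------------------------------------------
    def cross_validate(
        self,
        K_range,
        folds: int = 5,
        seed: int = 0,
        max_iter: int = 300,
        tol: float = 1e-3,
        n_restarts: int = 2,
        max_mask_retries: int = 10,
    ) -> pd.DataFrame:
        """Masking cross-validation over K.

        Called genotype entries are partitioned into ``folds`` random folds;
        each fold is masked in turn, the model refit on the rest, and the
        held-out entries scored by mean squared dosage error
        ((g - 2 d)/2)^2. Returns a table of per-K CV errors; the row order
        follows ``K_range`` and the minimum identifies the selected K.
        """
        if folds < 2:
            raise ValueError("folds must be >= 2")
        rng = np.random.default_rng(seed)
        called_idx = np.argwhere(self._called)
        fold_of = self._draw_folds(called_idx, folds, rng, max_mask_retries)
        rows = []
        for K in K_range:
            errs = []
            for f in range(folds):
                mask = called_idx[fold_of == f]
                G_train = self._G.copy()
                G_train[mask[:, 0], mask[:, 1]] = -1
                sub = AdmixtureModel.__new__(AdmixtureModel)
                sub.gm = self.gm
                sub._G = G_train
                sub._called = G_train >= 0
                res = sub.fit(
                    K, seed=int(rng.integers(2**31)), max_iter=max_iter,
                    tol=tol, n_restarts=n_restarts,
                )
                D = np.clip(res.Q @ res.F, _EPS, 1 - _EPS)
                g = self._G[mask[:, 0], mask[:, 1]].astype(float)
                d = D[mask[:, 0], mask[:, 1]]
                errs.append(float(np.mean(((g - 2.0 * d) / 2.0) ** 2)))
            rows.append({"K": K, "cv_error": float(np.mean(errs))})
        out = pd.DataFrame(rows)
        out.attrs["best_K"] = int(out.loc[out["cv_error"].idxmin(), "K"])
        return out

    def _draw_folds(self, called_idx, folds, rng, max_retries):
        """Random fold labels such that no locus loses all its data."""
        m = self._G.shape[1]
        for _ in range(max_retries):
            fold_of = rng.integers(0, folds, size=len(called_idx))
            ok = True
            for f in range(folds):
                kept = np.bincount(
                    called_idx[fold_of != f][:, 1], minlength=m
                )
                if (kept[np.bincount(called_idx[:, 1], minlength=m) > 0] == 0).any():
                    ok = False
                    break
            if ok:
                return fold_of
        raise RuntimeError(
            "could not draw a CV mask leaving every locus with data"
        )


def admixture_fit(
    gm: GenotypeMatrix, K: int, seed: int = 0, max_iter: int = 500,
    tol: float = 1e-4, n_restarts: int = 3,
) -> AdmixtureResults:
    """Functional wrapper: fit the binomial admixture model at a given K."""
    return AdmixtureModel(gm).fit(
        K, seed=seed, max_iter=max_iter, tol=tol, n_restarts=n_restarts
    )


def admixture_cv(
    gm: GenotypeMatrix, K_range, folds: int = 5, seed: int = 0, **kwargs
) -> pd.DataFrame:
    """Functional wrapper: masking cross-validation over a K range."""
    return AdmixtureModel(gm).cross_validate(
        K_range, folds=folds, seed=seed, **kwargs
    )


def align_to_truth(Q: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Resolve label switching by greedily matching estimated columns to
    truth columns on mean absolute error (evaluation helper); returns Q with
    columns reordered to the truth's column order."""
    K = Q.shape[1]
    cost = np.array(
        [[np.abs(Q[:, a] - Q_true[:, b]).mean() for b in range(K)] for a in range(K)]
    )
    assign = {}  # truth column -> estimate column
    work = cost.copy()
    for _ in range(K):
        a, b = np.unravel_index(np.argmin(work), work.shape)
        assign[int(b)] = int(a)
        work[a, :] = np.inf
        work[:, b] = np.inf
    return Q[:, [assign[b] for b in range(K)]]
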