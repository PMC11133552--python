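"""Minimal covariance matrix adaptation evolution strategy (CMA-ES).

Standard (mu/mu_w, lambda) CMA-ES with cumulative step-size adaptation and
rank-one plus rank-mu covariance updates (Hansen's tutorial
parameterization).  Derivative-free; used here for single-shooting
controller optimization in a normalized box.
"""

from __future__ import annotations

import numpy as np


class CMAES:
    """Ask/tell CMA-ES minimizer.

    Parameters
    ----------
    x0 : initial mean (n,)
    sigma0 : initial global step size
    popsize : offspring per generation (default 4 + floor(3 ln n))
    seed : RNG seed (sampling is fully deterministic given the seed)
    """

    def __init__(self, x0, sigma0, popsize=None, seed=0):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.n = len(self.mean)
        self.sigma = float(sigma0)
        self.lam = popsize or 4 + int(3 * np.log(self.n))
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights ** 2)

        n, mueff = self.n, self.mueff
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(1 - self.c1,
                       2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
        self.damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + self.cs
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.B = np.eye(n)
        self.D = np.ones(n)
        self.invsqrtC = np.eye(n)
        self.rng = np.random.default_rng(seed)
        self.generation = 0
        self._z = None
        self.best_x = self.mean.copy()
        self.best_f = np.inf

    def ask(self) -> np.ndarray:
        """Sample lambda candidate solutions (lam, n)."""
        self._z = self.rng.standard_normal((self.lam, self.n))
        y = self._z * self.D
        return self.mean + self.sigma * (y @ self.B.T)

    def tell(self, X, f) -> None:
        """Rank candidates by fitness f (lower is better) and update."""
        f = np.asarray(f, dtype=float)
        order = np.argsort(f)
        if f[order[0]] < self.best_f:
            self.best_f = float(f[order[0]])
            self.best_x = X[order[0]].copy()

        sel = X[order[: self.mu]]
        old_mean = self.mean
        self.mean = self.weights @ sel
        y = (self.mean - old_mean) / self.sigma

        self.ps = ((1 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2 - self.cs) * self.mueff)
                   * (self.invsqrtC @ y))
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
                / self.chiN) < 1.4 + 2 / (self.n + 1)
        self.pc = ((1 - self.cc) * self.pc
                   + hsig * np.sqrt(self.cc * (2 - self.cc) * self.mueff) * y)

        artmp = (sel - old_mean) / self.sigma
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (not hsig) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * (artmp.T * self.weights) @ artmp)

        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chiN - 1))
        self.generation += 1

        C = np.triu(self.C) + np.triu(self.C, 1).T
        d, B = np.linalg.eigh(C)
        d = np.maximum(d, 1e-20)
        self.D = np.sqrt(d)
        self.B = B
        self.invsqrtC = (B / self.D) @ B.T
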