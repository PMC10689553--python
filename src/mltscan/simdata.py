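"""Synthetic metabolome generator with known ground truth.

Emulates the data features the scan is built for: heterogeneous per-metabolite
scales via monotone distortions of a Gaussian latent variable, left-censoring
at a limit of quantification, ties from limited recording precision,
block-correlated metabolites, missing values, and an age-like continuous
exposure with known (possibly null, possibly log-shaped) effects.

The latent model per metabolite i is

    Z_i = beta_i * m_i(X) + eps_i,     eps block-equicorrelated N(0, 1)
    Y_i = g_i(Z_i)

with m_i the arithmetic or logarithmic metameter and g_i a strictly monotone
distortion, so the probit-link transformation model holds exactly with
latent-scale effect beta_i.  Censoring then replaces values at or below the
per-metabolite LOQ (the ``censor_frac`` empirical quantile) by the LOQ itself,
rounding creates ties, and a missingness mask blanks entries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .metameter import ARITHMETIC, LOGARITHMIC

#: monotone, bijective distortions (name -> (g, g_inverse))
DISTORTIONS = {
    "identity": (lambda z: z, lambda y: y),
    "exp": (np.exp, np.log),
    "cube": (lambda z: z ** 3, np.cbrt),
    "logistic": (special.expit, special.logit),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a null metabolome of 20 block-correlated metabolites
    (blocks of 5, equicorrelation 0.5) measured on 200 adults aged 18-80,
    with no censoring, rounding or missingness unless requested.
    """

    n: int = 200
    p: int = 20
    beta: Optional[Sequence[float]] = None  # None -> all null
    effect_shape: Optional[Sequence[str]] = None  # per-metabolite, default arithmetic
    distortions: Optional[Sequence[str]] = None  # default identity
    censor_frac: float = 0.0
    round_decimals: Optional[Sequence[Optional[int]]] = None
    block_corr: Tuple[int, float] = (5, 0.5)
    missing_frac: float = 0.0
    seed: int = 0
    exposure_range: Tuple[float, float] = (18.0, 80.0)

    def __post_init__(self) -> None:
        if self.p < 1 or self.n < 1:
            raise ValueError("n and p must be positive")
        for frac, what in ((self.censor_frac, "censor_frac"), (self.missing_frac, "missing_frac")):
            if not (0.0 <= frac < 1.0):
                raise ValueError(f"{what} must lie in [0, 1)")
        size, rho = self.block_corr
        if size < 1 or not (0.0 <= rho < 1.0):
            raise ValueError("block_corr must be (size >= 1, 0 <= rho < 1)")

    def _per_metabolite(self, value, default) -> list:
        if value is None:
            return [default] * self.p
        out = list(value)
        if len(out) != self.p:
            raise ValueError(f"per-metabolite setting has length {len(out)}, expected p={self.p}")
        return out


@dataclass
class SimTruth:
    """Ground truth behind one generated dataset."""

    beta: np.ndarray
    effect_shape: List[str]
    distortions: List[str]
    loq: Dict[str, Optional[float]]
    round_decimals: List[Optional[int]]
    n_censored: Dict[str, int]
    n_tied: Dict[str, int]
    seed: int


def _block_noise(rng: np.random.Generator, n: int, p: int, size: int, rho: float) -> np.ndarray:
    """Unit-variance noise, equicorrelated at rho inside consecutive blocks."""
    z = rng.standard_normal((n, p))
    if rho == 0.0 or size == 1:
        return z
    out = np.empty_like(z)
    for start in range(0, p, size):
        stop = min(start + size, p)
        shared = rng.standard_normal(n)
        out[:, start:stop] = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * z[:, start:stop]
    return out


def generate(config: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (abundance table, metadata table, truth record).

    The metadata table carries the exposure (``age``) and an independent
    adjustment covariate (``bmi``) with no true effect on any metabolite.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    beta = np.asarray(cfg._per_metabolite(cfg.beta, 0.0), dtype=float)
    shapes = cfg._per_metabolite(cfg.effect_shape, ARITHMETIC)
    dist_names = cfg._per_metabolite(cfg.distortions, "identity")
    rounds = cfg._per_metabolite(cfg.round_decimals, None)
    for s in shapes:
        if s not in (ARITHMETIC, LOGARITHMIC):
            raise ValueError(f"unknown effect shape {s!r}")
    for d in dist_names:
        if d not in DISTORTIONS:
            raise ValueError(f"unknown distortion {d!r}; choose from {sorted(DISTORTIONS)}")

    lo, hi = cfg.exposure_range
    x = rng.uniform(lo, hi, size=cfg.n)
    bmi = rng.normal(25.0, 3.5, size=cfg.n)
    eps = _block_noise(rng, cfg.n, cfg.p, *cfg.block_corr)

    names = [f"M{i + 1:03d}" for i in range(cfg.p)]
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n)]
    cols = {}
    loq_map: Dict[str, Optional[float]] = {}
    n_cens: Dict[str, int] = {}
    n_tied: Dict[str, int] = {}
    for i, name in enumerate(names):
        m = x if shapes[i] == ARITHMETIC else np.log(x)
        z = beta[i] * m + eps[:, i]
        g, _ = DISTORTIONS[dist_names[i]]
        y = g(z)
        if rounds[i] is not None:
            y = np.round(y, rounds[i])
        loq = None
        if cfg.censor_frac > 0:
            loq = float(np.quantile(y, cfg.censor_frac))
            censored = y <= loq
            y = np.where(censored, loq, y)
            n_cens[name] = int(censored.sum())
        else:
            n_cens[name] = 0
        if cfg.missing_frac > 0:
            miss = rng.random(cfg.n) < cfg.missing_frac
            y = np.where(miss, np.nan, y)
        finite = y[np.isfinite(y)]
        uniq, cnt = np.unique(finite, return_counts=True)
        n_tied[name] = int(cnt[cnt > 1].sum())
        loq_map[name] = loq
        cols[name] = y

    abundance = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    metadata = pd.DataFrame(
        {"age": x, "bmi": bmi}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = SimTruth(
        beta=beta,
        effect_shape=shapes,
        distortions=dist_names,
        loq=loq_map,
        round_decimals=rounds,
        n_censored=n_cens,
        n_tied=n_tied,
        seed=cfg.seed,
    )
    return abundance, metadata, truth
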