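"""End-to-end metabolome association scan and its forest-plot output.

``scan`` runs the full pipeline: encode each metabolite column (LOQ
left-censoring, tie intervals), build the exposure metameters, fit one
transformation model per metabolite x metameter, then correct all 2*p models
jointly by max-t simultaneous inference.  The result is a tidy table (one row
per model) plus a skip list; ``forest_plot`` renders the simultaneous
intervals ordered by effect around a zero reference line, which reads
scale-independently across metabolites.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import mmm
from .bernstein import BernsteinBasis
from .errors import DegenerateResponseError
from .metameter import ARITHMETIC, make_metameters
from .mmm import JointInference, StackedFit, joint_covariance, max_t_inference
from .response import encode_response
from .transmodel import ModelSpec, TransformationFit, fit

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "metabolite",
    "metameter",
    "effect",
    "lower",
    "upper",
    "p_adj",
    "significant",
    "n_used",
    "n_left",
    "n_interval",
    "converged",
]


@dataclass
class ScanConfig:
    """Every knob of the scan, snapshotted into the results for reproducibility."""

    order: int = 6  # Bernstein order M
    link: str = "probit"
    level: float = 0.95
    seed: int = mmm.DEFAULT_SEED
    support_margin: float = 0.1
    tie_policy: str = "interval"
    include_log_metameter: bool = True
    log_base: Optional[float] = None  # None = natural log
    joint_family: str = "all"  # "all" = one family over 2p models; "per_metameter"
    qmc_points: int = mmm.DEFAULT_POINTS
    qmc_shifts: int = mmm.DEFAULT_SHIFTS
    qmc_tol: float = 1e-4

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScanResult:
    """Table-shaped scan output plus the settings that produced it."""

    table: pd.DataFrame
    settings: dict
    skips: List[Tuple[str, str]]
    joint: Dict[str, JointInference] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].fillna(False).sum())


def _align(abundance: pd.DataFrame, exposure: pd.Series, adjust: Optional[pd.DataFrame]):
    ids = abundance.index.intersection(exposure.index)
    if adjust is not None:
        ids = ids.intersection(adjust.index)
    if len(ids) == 0:
        raise ValueError("no samples shared between abundance and metadata tables")
    ids = ids[~ids.duplicated()]
    ab = abundance.loc[ids]
    ex = pd.to_numeric(exposure.loc[ids], errors="raise")
    ad = adjust.loc[ids].astype(float) if adjust is not None else None
    return ab, ex, ad


def scan(
    abundance: pd.DataFrame,
    exposure: pd.Series,
    adjust: Optional[pd.DataFrame] = None,
    loq_map: Optional[Dict[str, float]] = None,
    config: Optional[ScanConfig] = None,
) -> ScanResult:
    """Scan every metabolite column for association with the exposure.

    Parameters
    ----------
    abundance : samples x metabolites table (index = sample IDs).
    exposure : per-sample variable of interest (e.g. age), joined on ID.
    adjust : optional per-sample adjustment covariates (e.g. BMI).
    loq_map : metabolite name -> limit of quantification.
    config : scan settings; defaults reproduce the standard pipeline.
    """
    cfg = config or ScanConfig()
    loq_map = loq_map or {}
    ab, ex, ad = _align(abundance, exposure, adjust)
    n = len(ab)
    mset = make_metameters(
        ex.to_numpy(),
        include_log=cfg.include_log_metameter,
        source_name=exposure.name or "exposure",
        log_base=cfg.log_base,
        sample_ids=list(ab.index),
    )
    adj_values = ad.to_numpy() if ad is not None else np.empty((n, 0))
    adj_names = tuple(ad.columns) if ad is not None else ()

    skips: List[Tuple[str, str]] = []
    rows: List[dict] = []
    fits: List[TransformationFit] = []
    fit_labels: List[Tuple[str, str]] = []
    for name in ab.columns:
        try:
            resp = encode_response(
                ab[name].to_numpy(dtype=float),
                loq=loq_map.get(name),
                tie_policy=cfg.tie_policy,
                name=str(name),
                support_margin=cfg.support_margin,
            )
        except DegenerateResponseError as exc:
            logger.warning("skipping %s: %s", name, exc.reason)
            skips.append((str(name), exc.reason))
            continue
        basis = BernsteinBasis(order=cfg.order, support=resp.support)
        for mm_name in mset.names:
            spec = ModelSpec(
                basis=basis,
                covariate_names=(mm_name,) + adj_names,
                link=cfg.link,
            )
            X = np.column_stack([mset.column(mm_name), adj_values])
            f = fit(spec, resp, X, seed=cfg.seed)
            fits.append(f)
            fit_labels.append((str(name), mm_name))
            rows.append(
                {
                    "metabolite": str(name),
                    "metameter": mm_name,
                    "effect": float(f.beta[0]),
                    "lower": np.nan,
                    "upper": np.nan,
                    "p_adj": np.nan,
                    "significant": False,
                    "n_used": f.n_used,
                    "n_left": resp.n_left,
                    "n_interval": resp.n_interval,
                    "converged": f.converged,
                }
            )

    joint_results: Dict[str, JointInference] = {}
    if fits:
        if cfg.joint_family == "all":
            families = {"all": list(range(len(fits)))}
        elif cfg.joint_family == "per_metameter":
            families = {
                m: [j for j, (_, mm_name) in enumerate(fit_labels) if mm_name == m]
                for m in mset.names
            }
        else:
            raise ValueError(f"unknown joint_family {cfg.joint_family!r}")
        tested = 0  # metameter coefficient is the first beta, right after the basis block
        for fam_name, members in families.items():
            usable = [j for j in members if fits[j].converged]
            if len(usable) == 0:
                continue
            stacked = StackedFit(
                fits=[fits[j] for j in usable],
                labels=[fit_labels[j] for j in usable],
                tested_index=[fits[j].spec.basis.dim + tested for j in usable],
                n_samples=n,
            )
            cov, kept = joint_covariance(stacked)
            kept_global = [usable[j] for j in kept]
            ji = max_t_inference(
                [fits[j].beta[0] for j in kept_global],
                cov,
                level=cfg.level,
                seed=cfg.seed,
                tol=cfg.qmc_tol,
                n_points=cfg.qmc_points,
                shifts=cfg.qmc_shifts,
                labels=[fit_labels[j] for j in kept_global],
            )
            joint_results[fam_name] = ji
            for pos, j in enumerate(kept_global):
                rows[j].update(
                    lower=float(ji.ci_lower[pos]),
                    upper=float(ji.ci_upper[pos]),
                    p_adj=float(ji.p_adj[pos]),
                    significant=bool(ji.significant[pos]),
                )

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    settings = cfg.asdict()
    settings.update(n_samples=n, adjust_covariates=list(adj_names))
    return ScanResult(table=table, settings=settings, skips=skips, joint=joint_results)


def forest_plot(
    result: ScanResult,
    metameter: str = ARITHMETIC,
    out_path=None,
    ax=None,
    max_labels: int = 40,
):
    """Ordered forest (caterpillar) plot of simultaneous intervals.

    One horizontal segment per metabolite around a point marker, sorted by
    increasing effect, with a vertical reference line at zero; metabolites
    whose interval excludes zero are highlighted and labelled.
    """
    import matplotlib

    if out_path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = result.table[(result.table["metameter"] == metameter) & result.table["converged"]]
    if sub.empty:
        available = sorted(result.table["metameter"].unique())
        raise ValueError(f"no rows for metameter {metameter!r}; available: {available}")
    sub = sub.sort_values("effect").reset_index(drop=True)
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, max(3, 0.16 * len(sub) + 1.5)))
    else:
        fig = ax.figure
    ypos = np.arange(len(sub))
    sig = sub["significant"].fillna(False).to_numpy(dtype=bool)
    for flag, color in ((False, "black"), (True, "tab:blue")):
        m = sig == flag
        if m.any():
            ax.hlines(ypos[m], sub["lower"][m], sub["upper"][m], color=color, lw=1.2)
            ax.plot(sub["effect"][m], ypos[m], "o", color=color, ms=3)
    ax.axvline(0.0, color="grey", lw=0.8, zorder=0)
    if len(sub) <= max_labels:
        ax.set_yticks(ypos)
        ax.set_yticklabels(sub["metabolite"])
    else:
        ax.set_yticks(ypos[sig])
        ax.set_yticklabels(sub["metabolite"][sig], color="tab:blue", fontsize=7)
    ax.set_xlabel(f"effect ({metameter} metameter) with simultaneous {result.settings.get('level', 0.95):.0%} CI")
    ax.set_ylabel("metabolites (ordered by effect)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path)
        plt.close(fig)
    return fig
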