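"""Model comparison by DIC and posterior predictive checks.

DIC (Deviance Information Criterion) is computed in its conditional focus:
the deviance is -2 log p(y | subject-level parameters, sigma_obs), so the
effective parameter count pD reflects the partially pooled subject effects.
Lower DIC means better expected predictive fit; with a continuous likelihood
the DIC can be (and here typically is) negative.  No significance threshold
is attached to DIC differences — comparisons report ordering plus deltas.

Posterior predictive checks replicate datasets from the fitted model at the
observed design points, smooth observed and replicated group profiles with a
loess-type local-linear smoother, and report how much of the observed smooth
lies inside the central 95% replicate envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .kinetics import PosteriorFit

__all__ = [
    "DicComponents",
    "ModelComparison",
    "PpcResult",
    "compute_dic",
    "compare_models",
    "loess_smooth",
    "posterior_predictive_check",
]


@dataclass(frozen=True)
class DicComponents:
    """DIC decomposition: DIC = D̄ + pD = D(θ̂) + 2·pD."""

    mean_deviance: float        # D-bar
    deviance_at_mean: float     # D(theta-hat)
    p_d: float                  # effective number of parameters
    dic: float

    def check_identities(self, tol: float = 1e-6) -> bool:
        a = abs(self.dic - (self.mean_deviance + self.p_d))
        b = abs(self.dic - (self.deviance_at_mean + 2.0 * self.p_d))
        c = abs(self.p_d - (self.mean_deviance - self.deviance_at_mean))
        return bool(a <= tol and b <= tol and c <= tol)


def compute_dic(fit) -> DicComponents:
    """DIC components from a fit's deviance trace.

    ``fit`` must expose a ``deviance`` draw array and the deviance evaluated
    at the posterior mean of the parameters (on their sampling scales).
    """
    dev = np.asarray(fit.deviance, dtype=float)
    if dev.size == 0:
        raise ValueError("fit has no deviance trace")
    d_bar = float(dev.mean())
    d_hat = float(fit.deviance_at_posterior_mean)
    p_d = d_bar - d_hat
    return DicComponents(mean_deviance=d_bar, deviance_at_mean=d_hat,
                         p_d=p_d, dic=d_bar + p_d)


@dataclass
class ModelComparison:
    """DIC table over named fits on identical data, sorted by DIC."""

    table: pd.DataFrame
    deltas: dict[tuple[str, str], float] = field(default_factory=dict)

    def delta(self, a: str, b: str) -> float:
        """DIC(a) - DIC(b); antisymmetric in its arguments."""
        return self.deltas[(a, b)]


def delta_dic(dic_a: float, dic_b: float) -> float:
    """Absolute DIC difference between two models (order-free magnitude)."""
    return float(abs(dic_a - dic_b))


def compare_models(fits: dict[str, PosteriorFit]) -> ModelComparison:
    """Rank fits of the same data by DIC and tabulate pairwise deltas.

    Fits whose data fingerprints differ are refused: DIC differences are
    only meaningful on an identical observation set and outcome.
    """
    if not fits:
        raise ValueError("no fits to compare")
    fps = {name: fit.fingerprint for name, fit in fits.items()}
    if len(set(fps.values())) > 1:
        raise ValueError(f"fits are not on identical data: {fps}")
    rows = []
    comps = {}
    for name, fit in fits.items():
        c = compute_dic(fit)
        comps[name] = c
        rows.append(dict(model=name, dic=c.dic, mean_deviance=c.mean_deviance,
                         deviance_at_mean=c.deviance_at_mean, p_d=c.p_d,
                         converged=fit.converged))
    table = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    deltas = {}
    for a in fits:
        for b in fits:
            if a != b:
                deltas[(a, b)] = comps[a].dic - comps[b].dic
    return ModelComparison(table=table, deltas=deltas)


# ---------------------------------------------------------------------------
# posterior predictive checks


def loess_smooth(t: np.ndarray, y: np.ndarray, grid: np.ndarray,
                 span: float = 0.75) -> np.ndarray:
    """Local-linear (lowess, tricube-weighted) smooth evaluated on ``grid``."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to smooth")
    sm = lowess(y, t, frac=span, it=0, return_sorted=True)
    return np.interp(grid, sm[:, 0], sm[:, 1])


@dataclass
class PpcResult:
    """Posterior-predictive envelope check of the smoothed group profiles.

    ``coverage`` maps group name to the fraction of grid points where the
    observed smooth lies inside the central envelope; ``overall_coverage``
    pools the grid points of all groups.
    """

    n_replicates: int
    span: float
    groups: list[str]
    grid: dict[str, np.ndarray]
    observed_smooth: dict[str, np.ndarray]
    envelope_low: dict[str, np.ndarray]
    envelope_high: dict[str, np.ndarray]
    coverage: dict[str, float]
    overall_coverage: float

    def to_dict(self) -> dict:
        return dict(
            n_replicates=self.n_replicates, span=self.span, groups=self.groups,
            grid={g: v.tolist() for g, v in self.grid.items()},
            observed_smooth={g: v.tolist() for g, v in self.observed_smooth.items()},
            envelope_low={g: v.tolist() for g, v in self.envelope_low.items()},
            envelope_high={g: v.tolist() for g, v in self.envelope_high.items()},
            coverage=self.coverage, overall_coverage=self.overall_coverage,
        )


def posterior_predictive_check(
    fit: PosteriorFit,
    n_replicates: int = 200,
    span: float = 0.75,
    n_grid: int = 40,
    envelope: tuple[float, float] = (2.5, 97.5),
    seed: int | None = None,
) -> PpcResult:
    """Envelope check of observed vs replicated loess-smoothed profiles.

    For each replicate a posterior draw is selected, outcomes are simulated
    from the log-normal observation model at every observed design point,
    and the per-group profile is smoothed on a common time grid.  The
    observed smooth is then compared with the central ``envelope`` of the
    replicate smooths.
    """
    if fit.design is None:
        raise ValueError("fit carries no design table; cannot replicate")
    if n_replicates < 50:
        warnings.warn("fewer than 50 posterior predictive replicates; "
                      "the envelope will be noisy")
    rng = np.random.default_rng(seed)
    df = fit.design.df
    st = fit.design.subject_table
    sid_to_idx = {sid: i for i, sid in enumerate(st["subject_id"])}
    obs_subj = df["subject_id"].map(sid_to_idx).to_numpy()
    t = df["t_days"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    # group profiles use every observed point, anchors included
    subj_group = st.set_index("subject_id")["group"]
    obs_group = subj_group.loc[df["subject_id"]].to_numpy()
    group_names = [g for g in dict.fromkeys(obs_group)]

    C, D = fit.deviance.shape
    idx = rng.integers(0, C * D, size=n_replicates)
    ci, di = np.unravel_index(idx, (C, D))
    log_r0 = fit.draws["subject_log_r0"][ci, di]   # (R, S)
    k_sub = fit.draws["subject_k"][ci, di]
    sig_o = fit.draws["sigma_obs"][ci, di]          # (R,)

    mean_log = log_r0[:, obs_subj] - k_sub[:, obs_subj] * t[None, :]
    noise = rng.standard_normal(mean_log.shape) * sig_o[:, None]
    y_rep = np.exp(mean_log + noise)                # (R, n_points)

    grid, obs_smooth, env_lo, env_hi, coverage = {}, {}, {}, {}, {}
    hits, total = 0, 0
    for g in group_names:
        sel = obs_group == g
        tg, yg = t[sel], y[sel]
        gr = np.linspace(tg.min(), tg.max(), n_grid)
        obs_s = loess_smooth(tg, yg, gr, span)
        reps = np.empty((n_replicates, n_grid))
        for r in range(n_replicates):
            reps[r] = loess_smooth(tg, y_rep[r, sel], gr, span)
        lo, hi = np.percentile(reps, envelope, axis=0)
        inside = (obs_s >= lo) & (obs_s <= hi)
        grid[g], obs_smooth[g] = gr, obs_s
        env_lo[g], env_hi[g] = lo, hi
        coverage[g] = float(inside.mean())
        hits += int(inside.sum())
        total += n_grid

    return PpcResult(
        n_replicates=n_replicates, span=span, groups=group_names, grid=grid,
        observed_smooth=obs_smooth, envelope_low=env_lo, envelope_high=env_hi,
        coverage=coverage, overall_coverage=hits / total,
    )
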