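"""Bayesian hierarchical single-exponential decay model for AM BC kinetics.

The carbon load of a subject's airway macrophages is modelled as

    y_ij ~ LogNormal( log R0_i - k_i * t_ij , sigma_obs )

where ``R0_i`` is the subject's carbon load at the time origin and ``k_i``
the net clearance constant (day⁻¹; negative values mean net accumulation).
Subjects are partially pooled within exposure groups:

    log R0_i ~ Normal( log R0_g , sigma_R )
    k_i      ~ Normal( k_g , sigma_k )

Time origins differ by design: newcomers are referenced to their *arrival*
day (t = 0), so their first observation at ``latency_days`` constrains a
model-based extrapolation of R0 back to day 0; long-term residents are
referenced to their first measurement and, under the default
``fixed_to_T1`` rule, their subject-level R0 is anchored to that first
observation (which then enters the hierarchy as an observed log R0 rather
than the observation likelihood).

The clearance half-life is ln(2)/k for k > 0; for k <= 0 there is no net
clearance and the half-life is reported as infinite.

Sampling uses an affine-invariant / differential-evolution ensemble (emcee)
over a non-centred parameterisation, with the walker ensemble providing the
parallel chains for split-R-hat and effective-sample-size diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd

__all__ = [
    "decay_curve",
    "half_life",
    "PriorSpec",
    "KineticModelSpec",
    "MCMCConfig",
    "DesignTable",
    "GroupKinetics",
    "PosteriorFit",
    "build_design",
    "fit_hierarchical_model",
    "summarize_groups",
]

_GROUP_ORDER = ("LMIC", "HIC", "BE")
_SEASONS = ("winter", "spring", "summer", "autumn")


def decay_curve(r0: float, k: float, t) :
    """Single-exponential decay ``R0 * exp(-k t)``.

    ``k`` may be negative (net accumulation), matching groups whose carbon
    load rises after a move to a more polluted area.
    """
    if np.any(np.asarray(r0) < 0):
        raise ValueError("R0 must be non-negative")
    return r0 * np.exp(-k * np.asarray(t, dtype=float))


def half_life(k: float) -> float:
    """Clearance half-life ln(2)/k in days; +inf when k <= 0 (no net clearance)."""
    if k <= 0:
        return float("inf")
    return float(np.log(2.0) / k)


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors, on the parameters' sampling scales.

    Locations are Normal, scales Half-Normal.  Units: ``mu`` acts on log R0
    (log μm²), ``k`` and ``sigma_k`` in day⁻¹, ``sigma_r``/``sigma_obs`` on
    the log scale.
    """

    mu_loc: float = 0.0
    mu_scale: float = 2.0
    k_loc: float = 0.0
    k_scale: float = 0.05
    sigma_r_scale: float = 1.0
    sigma_k_scale: float = 0.02
    sigma_obs_scale: float = 1.0
    beta_r0_scale: float = 1.0
    beta_k_scale: float = 0.01
    beta_season_scale: float = 0.5


@dataclass(frozen=True)
class KineticModelSpec:
    """What to fit: grouping, covariates, noise model, resident-R0 rule.

    ``covariates`` may contain ``sex`` and ``age`` (additive on log R0 and
    on k) and ``season`` (additive on the observation log-mean, meteorological
    4-level coding with winter as reference).
    """

    group_effect: bool = True
    covariates: tuple[str, ...] = ()
    outcome: str = "median"  # or "p90"
    noise_model: str = "lognormal_on_value"  # or "normal_on_log"
    resident_r0_rule: str = "fixed_to_T1"  # or "estimated"
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates")
        bad = set(self.covariates) - {"sex", "age", "season"}
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")
        if self.outcome not in ("median", "p90"):
            raise ValueError("outcome must be 'median' or 'p90'")
        if self.noise_model not in ("lognormal_on_value", "normal_on_log"):
            raise ValueError("unknown noise model")
        if self.resident_r0_rule not in ("fixed_to_T1", "estimated"):
            raise ValueError("unknown resident R0 rule")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModelSpec":
        d = dict(d)
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PriorSpec(**d["priors"])
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings.

    ``n_walkers=None`` auto-sizes the ensemble to ``2*ndim + 32`` walkers.
    Draws are thinned before storage; diagnostics treat walkers as chains.
    """

    n_steps: int = 1200
    n_burn: int = 1800
    thin: int = 6
    n_walkers: int | None = None
    seed: int = 0
    rhat_threshold: float = 1.05
    ess_threshold: float = 400.0


# ---------------------------------------------------------------------------
# design construction


def _season_index(doy: np.ndarray) -> np.ndarray:
    """Meteorological season from day-of-year: DJF, MAM, JJA, SON -> 0..3."""
    d = np.asarray(doy) % 365
    out = np.full(d.shape, 3, dtype=int)  # autumn default
    out[(d < 60) | (d >= 335)] = 0
    out[(d >= 60) & (d < 152)] = 1
    out[(d >= 152) & (d < 244)] = 2
    return out


@dataclass
class DesignTable:
    """Model-ready observation table plus subject-level arrays.

    ``df`` rows are the likelihood observations (anchoring T1 rows of
    residents under ``fixed_to_T1`` are kept with ``is_anchor=True`` but
    excluded from the observation likelihood).  ``dropped`` lists
    ``(subject_id, reason)`` for subjects excluded from the fit.
    """

    df: pd.DataFrame
    subject_table: pd.DataFrame  # one row per retained subject
    group_names: list[str]
    spec: KineticModelSpec
    dropped: list[tuple[str, str]]
    n_zero_offset: int
    fingerprint: str

    @property
    def n_subjects(self) -> int:
        return len(self.subject_table)

    @property
    def n_obs(self) -> int:
        return int((~self.df["is_anchor"]).sum())


def build_design(dataset, spec: KineticModelSpec) -> DesignTable:
    """Assemble the observation table the hierarchical model consumes.

    Assigns per-subject time origins (arrival day for newcomers, first valid
    measurement for residents), selects the outcome column, applies the
    resident-R0 anchoring rule, encodes covariates, and drops subjects with
    no usable slides (with a recorded reason).
    """
    subjects = dataset.subjects.set_index("subject_id")
    obs = dataset.observations.copy()
    outcome_col = {"median": "median_bc_um2", "p90": "p90_bc_um2"}[spec.outcome]

    if "n_cells" in obs.columns:
        obs = obs[obs["n_cells"] >= 25]

    # zero outcomes are incompatible with log-normal noise: offset them
    y_all = obs[outcome_col].to_numpy(dtype=float)
    n_zero = int((y_all <= 0).sum())
    if n_zero:
        positive = y_all[y_all > 0]
        if positive.size == 0:
            raise ValueError("no positive outcome values")
        offset = 0.5 * positive.min()
        warnings.warn(
            f"{n_zero} zero-valued outcomes offset to {offset:.4g} "
            "(half the smallest nonzero value) for the log-normal likelihood"
        )
        y_all = np.where(y_all <= 0, offset, y_all)
    obs = obs.assign(_y=y_all)

    rows = []
    subj_rows = []
    dropped: list[tuple[str, str]] = []
    for sid, sdf in obs.groupby("subject_id", sort=True):
        sdf = sdf.sort_values("t_days")
        meta = subjects.loc[sid]
        group = str(meta["group"])
        resident = group == "BE"
        anchored = resident and spec.resident_r0_rule == "fixed_to_T1"
        if len(sdf) == 0:
            dropped.append((sid, "no valid slides"))
            continue
        if anchored and len(sdf) < 2:
            dropped.append((sid, "resident with no post-anchor observations"))
            continue
        t = sdf["t_days"].to_numpy(dtype=float)
        if resident:
            t = t - t[0]  # residents: origin at first valid measurement
        y = sdf["_y"].to_numpy(dtype=float)
        anchor_val = float(np.log(y[0])) if anchored else np.nan
        subj_rows.append(dict(
            subject_id=sid, group=group, anchored=anchored,
            anchor_log_y=anchor_val,
            sex=str(meta.get("sex", "M")),
            age_years=float(meta.get("age_years", np.nan)),
            enroll_doy=int(meta.get("enroll_doy", 1)),
        ))
        for j in range(len(sdf)):
            rows.append(dict(
                subject_id=sid, group=group, t_days=float(t[j]),
                y=float(y[j]), log_y=float(np.log(y[j])),
                is_anchor=bool(anchored and j == 0),
                visit_index=int(sdf["visit_index"].iloc[j])
                if "visit_index" in sdf.columns else j + 1,
            ))

    # subjects present in the subject table but with no observations at all
    for sid in subjects.index:
        if sid not in obs["subject_id"].values and sid not in [d[0] for d in dropped]:
            dropped.append((sid, "no valid slides"))

    if not subj_rows:
        raise ValueError("no subjects with usable observations")
    subject_table = pd.DataFrame(subj_rows)
    df = pd.DataFrame(rows)

    if spec.group_effect:
        present = list(dict.fromkeys(subject_table["group"]))
        group_names = [g for g in _GROUP_ORDER if g in present]
        group_names += sorted(set(present) - set(group_names))
    else:
        group_names = ["pooled"]

    if "season" in spec.covariates:
        doy0 = subject_table.set_index("subject_id")["enroll_doy"]
        df["season_idx"] = _season_index(
            doy0.loc[df["subject_id"]].to_numpy() + np.round(df["t_days"]).astype(int)
        )

    lik = df[~df["is_anchor"]]
    h = hashlib.sha256()
    h.update(spec.outcome.encode())
    h.update(np.ascontiguousarray(np.round(lik["t_days"].to_numpy(), 6)).tobytes())
    h.update(np.ascontiguousarray(np.round(lik["y"].to_numpy(), 9)).tobytes())
    h.update(",".join(lik["subject_id"]).encode())

    return DesignTable(
        df=df, subject_table=subject_table, group_names=group_names,
        spec=spec, dropped=dropped, n_zero_offset=n_zero,
        fingerprint=h.hexdigest(),
    )


# ---------------------------------------------------------------------------
# model internals


class _HierarchicalDecayModel:
    """Vectorised log-posterior with subject effects integrated out.

    Given the hyperparameters, the model is linear-Gaussian in the
    non-centred subject effects ``(z_i, w_i)``: for subject i with residual
    ``r_i = log y_i - (mu_i - k0_i t_i)`` the marginal is

        r_i ~ N( 0 , sigma_obs^2 I + A_i A_i' ),   A_i = [sigma_R 1, -sigma_k t_i]

    (the sigma_R column is absent for residents anchored to T1).  The
    marginal likelihood is evaluated with the Woodbury identity on the
    rank-2 update, so the sampled space is only
    ``[mu_g (G) | k_g (G) | betas (B) | log sigma_R, log sigma_k,
    log sigma_obs]``.  Subject effects are afterwards drawn exactly from
    their conditional Gaussian posteriors (Rao-Blackwellised draws).
    """

    def __init__(self, design: DesignTable):
        self.design = design
        spec = design.spec
        self.spec = spec
        st = design.subject_table
        self.S = len(st)
        self.G = len(design.group_names)
        if spec.group_effect:
            gmap = {g: i for i, g in enumerate(design.group_names)}
            self.subj_group = st["group"].map(gmap).to_numpy()
        else:
            self.subj_group = np.zeros(self.S, dtype=int)

        self.anchored = st["anchored"].to_numpy(dtype=bool)
        self.free_idx = np.where(~self.anchored)[0]
        self.anch_idx = np.where(self.anchored)[0]
        anchor_full = st["anchor_log_y"].to_numpy(dtype=float)
        self.anchor_full = np.where(self.anchored, anchor_full, 0.0)
        self.anchor_vals = anchor_full[self.anch_idx]
        self.free_mask = (~self.anchored).astype(float)

        sid_to_idx = {sid: i for i, sid in enumerate(st["subject_id"])}
        lik = design.df[~design.df["is_anchor"]]
        self.obs_subj = lik["subject_id"].map(sid_to_idx).to_numpy()
        self.t = lik["t_days"].to_numpy(dtype=float)
        self.log_y = lik["log_y"].to_numpy(dtype=float)
        self.n_obs = len(lik)
        self.obs_anchored = self.anchored[self.obs_subj]
        self.obs_anchor_val = self.anchor_full[self.obs_subj]

        # covariate design matrices (subject level), centred age
        self.beta_names: list[str] = []
        cols_r0, cols_k = [], []
        if "sex" in spec.covariates:
            x = (st["sex"].to_numpy() == "F").astype(float)
            cols_r0.append(x); cols_k.append(x)
            self.beta_names += ["beta_r0_sex", "beta_k_sex"]
        if "age" in spec.covariates:
            age = st["age_years"].to_numpy(dtype=float)
            x = age - np.nanmean(age)
            cols_r0.append(x); cols_k.append(x)
            self.beta_names += ["beta_r0_age", "beta_k_age"]
        self.X_r0 = np.column_stack(cols_r0) if cols_r0 else None
        self.X_k = np.column_stack(cols_k) if cols_k else None
        self.n_cov = len(cols_r0)

        self.season = None
        if "season" in spec.covariates:
            self.season = lik["season_idx"].to_numpy()
            self.season_onehot = np.eye(4)[self.season][:, 1:]  # winter = reference
            self.beta_names += ["beta_season_spring", "beta_season_summer",
                                "beta_season_autumn"]
        self.B = len(self.beta_names)

        self.ndim = 2 * self.G + self.B + 3
        p = spec.priors
        self.p = p
        # deviance constant: Gaussian normalisation, plus the log-normal
        # Jacobian sum(log y) when the likelihood is on the value scale
        self.dev_const = -0.5 * self.n_obs * np.log(2.0 * np.pi)
        if spec.noise_model == "lognormal_on_value":
            self.dev_const -= float(np.sum(self.log_y))

        o = 0
        self.sl_mu = slice(o, o + self.G); o += self.G
        self.sl_k = slice(o, o + self.G); o += self.G
        self.sl_beta = slice(o, o + self.B); o += self.B
        self.sl_sig = slice(o, o + 3)

        # per-subject aggregation operator and design moments
        self.ind = np.zeros((self.n_obs, self.S))
        self.ind[np.arange(self.n_obs), self.obs_subj] = 1.0
        self.m_s = self.ind.sum(axis=0)            # obs count per subject
        self.t1_s = self.t @ self.ind              # sum t
        self.tt_s = (self.t * self.t) @ self.ind   # sum t^2

        if self.B:
            scales = []
            for name in self.beta_names:
                if name.startswith("beta_r0"):
                    scales.append(p.beta_r0_scale)
                elif name.startswith("beta_k"):
                    scales.append(p.beta_k_scale)
                else:
                    scales.append(p.beta_season_scale)
            self.beta_prior_scales = np.asarray(scales)

    # -- pieces -----------------------------------------------------------

    def _linear_predictors(self, theta: np.ndarray):
        """(W, S) hierarchy locations for log R0 and k (before subject effects)."""
        mu = theta[:, self.sl_mu]
        kg = theta[:, self.sl_k]
        base_r0 = mu[:, self.subj_group]
        base_k = kg[:, self.subj_group]
        if self.n_cov:
            beta = theta[:, self.sl_beta]
            b_r0 = beta[:, 0:2 * self.n_cov:2]
            b_k = beta[:, 1:2 * self.n_cov:2]
            base_r0 = base_r0 + b_r0 @ self.X_r0.T
            base_k = base_k + b_k @ self.X_k.T
        return base_r0, base_k

    def _season_term(self, theta: np.ndarray):
        """(W, n_obs) additive season effect on the observation log-mean."""
        if self.season is None:
            return 0.0
        b_season = theta[:, self.sl_beta][:, 2 * self.n_cov:]
        return b_season @ self.season_onehot.T

    def _marginal_pieces(self, theta: np.ndarray):
        """Woodbury pieces of the subject-marginalised likelihood.

        Returns per-(walker, subject) arrays: the quadratic form and log
        determinant of the marginal Gaussian, plus the 2x2 posterior
        precision pieces needed to draw the subject effects exactly.
        """
        base_r0, base_k = self._linear_predictors(theta)
        sig = np.exp(theta[:, self.sl_sig])
        sr, sk, so = sig[:, 0], sig[:, 1], sig[:, 2]
        so2 = (so * so)[:, None]

        r0_for_obs = np.where(self.obs_anchored[None, :],
                              self.obs_anchor_val[None, :],
                              base_r0[:, self.obs_subj])
        m0 = r0_for_obs - base_k[:, self.obs_subj] * self.t[None, :]
        m0 = m0 + self._season_term(theta)
        r = self.log_y[None, :] - m0

        rr = (r * r) @ self.ind
        r1 = r @ self.ind
        rt = (r * self.t[None, :]) @ self.ind

        sr_eff = sr[:, None] * self.free_mask[None, :]   # anchored: no R0 effect
        a11 = sr_eff ** 2 * self.m_s[None, :]
        a12 = -sr_eff * sk[:, None] * self.t1_s[None, :]
        a22 = (sk * sk)[:, None] * self.tt_s[None, :]
        p11 = 1.0 + a11 / so2
        p12 = a12 / so2
        p22 = 1.0 + a22 / so2
        det_p = p11 * p22 - p12 * p12
        b1 = sr_eff * r1
        b2 = -sk[:, None] * rt
        quad_b = (p22 * b1 * b1 - 2.0 * p12 * b1 * b2 + p11 * b2 * b2) / det_p
        quad = (rr - quad_b / so2) / so2
        logdet = self.m_s[None, :] * np.log(so2) + np.log(det_p)
        pieces = dict(p11=p11, p12=p12, p22=p22, det_p=det_p, b1=b1, b2=b2,
                      so2=so2, base_r0=base_r0, base_k=base_k,
                      sr_eff=sr_eff, sk=sk)
        return quad, logdet, pieces

    def marginal_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Subject-marginalised observation log-likelihood (no constant)."""
        theta = np.atleast_2d(theta)
        quad, logdet, _ = self._marginal_pieces(theta)
        return -0.5 * (quad.sum(axis=1) + logdet.sum(axis=1))

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        bad = ~np.all(np.isfinite(theta), axis=1)
        # guard against overflow in exp of the log-scales
        logs = theta[:, self.sl_sig]
        bad |= np.any(np.abs(logs) > 15, axis=1)
        theta_safe = np.where(bad[:, None], 0.0, theta)

        lp = self.marginal_loglik(theta_safe)

        p = self.p
        mu = theta_safe[:, self.sl_mu]
        kg = theta_safe[:, self.sl_k]
        lp = lp - 0.5 * np.sum(((mu - p.mu_loc) / p.mu_scale) ** 2, axis=1)
        lp = lp - 0.5 * np.sum(((kg - p.k_loc) / p.k_scale) ** 2, axis=1)

        if len(self.anch_idx):
            # anchored residents: their T1 log-value is an observed subject
            # log R0 in the hierarchy
            base_r0, _ = self._linear_predictors(theta_safe)
            sig_r = np.exp(theta_safe[:, self.sl_sig][:, 0])
            ra = (self.anchor_vals[None, :]
                  - base_r0[:, self.anch_idx]) / sig_r[:, None]
            lp = lp - 0.5 * np.einsum("ij,ij->i", ra, ra) \
                - len(self.anch_idx) * np.log(sig_r)

        if self.B:
            beta = theta_safe[:, self.sl_beta]
            lp = lp - 0.5 * np.sum(
                (beta / self.beta_prior_scales[None, :]) ** 2, axis=1)

        # half-normal priors on the scales, sampled as log(sigma):
        # log p = -sigma^2 / (2 s^2) + log(sigma)  (Jacobian), const dropped
        sig = np.exp(logs)
        hs = np.array([p.sigma_r_scale, p.sigma_k_scale, p.sigma_obs_scale])
        lp = lp - 0.5 * np.sum((sig / hs[None, :]) ** 2, axis=1) + np.sum(logs, axis=1)

        return np.where(bad, -np.inf, lp)

    # -- exact conditional draws of the subject effects -------------------

    def sample_subject_effects(self, theta: np.ndarray,
                               rng: np.random.Generator):
        """Draw (z_i, w_i) from their exact Gaussian conditional posteriors.

        Returns subject-level ``log R0`` and ``k`` arrays of shape
        ``(n_theta, S)`` plus the raw standardised effects.
        """
        theta = np.atleast_2d(theta)
        _, _, pc = self._marginal_pieces(theta)
        p11, p12, p22 = pc["p11"], pc["p12"], pc["p22"]
        det_p, b1, b2, so2 = pc["det_p"], pc["b1"], pc["b2"], pc["so2"]
        mean_z = (p22 * b1 - p12 * b2) / det_p / so2
        mean_w = (p11 * b2 - p12 * b1) / det_p / so2
        # covariance = P^{-1}; closed-form 2x2 Cholesky
        c11 = p22 / det_p
        c12 = -p12 / det_p
        c22 = p11 / det_p
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(np.maximum(c22 - l21 * l21, 1e-300))
        e1 = rng.standard_normal(mean_z.shape)
        e2 = rng.standard_normal(mean_z.shape)
        z = mean_z + l11 * e1
        w = mean_w + l21 * e1 + l22 * e2
        log_r0 = np.where(self.anchored[None, :],
                          self.anchor_full[None, :],
                          pc["base_r0"] + pc["sr_eff"] * z)
        k_sub = pc["base_k"] + pc["sk"][:, None] * w
        return log_r0, k_sub, z, w

    def conditional_deviance(self, theta: np.ndarray, log_r0: np.ndarray,
                             k_sub: np.ndarray) -> np.ndarray:
        """-2 log p(y | subject params, sigma_obs), the DIC focus."""
        theta = np.atleast_2d(theta)
        so = np.exp(theta[:, self.sl_sig][:, 2])
        m = log_r0[:, self.obs_subj] - k_sub[:, self.obs_subj] * self.t[None, :]
        m = m + self._season_term(theta)
        resid = (self.log_y[None, :] - m) / so[:, None]
        ll = (-0.5 * np.einsum("ij,ij->i", resid, resid)
              - self.n_obs * np.log(so) + self.dev_const)
        return -2.0 * ll

    # -- initialisation ---------------------------------------------------

    def initial_ensemble(self, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
        lik = self.design.df[~self.design.df["is_anchor"]]
        mu0 = np.zeros(self.G)
        k0 = np.zeros(self.G)
        for gi, g in enumerate(self.design.group_names):
            if self.spec.group_effect:
                sub = lik[lik["group"] == g]
            else:
                sub = lik
            t = sub["t_days"].to_numpy()
            ly = sub["log_y"].to_numpy()
            if len(sub) >= 3 and np.ptp(t) > 0:
                slope, intercept = np.polyfit(t, ly, 1)
            else:
                slope, intercept = 0.0, float(np.mean(ly))
            mu0[gi] = np.clip(intercept, -5, 5)
            k0[gi] = np.clip(-slope, -0.04, 0.04)
        theta0 = np.concatenate([
            mu0, k0, np.zeros(self.B),
            np.log([0.4, max(self.p.sigma_k_scale / 4, 1e-4), 0.3]),
        ])
        jitter = np.concatenate([
            np.full(self.G, 0.1), np.full(self.G, 0.002),
            np.full(self.B, 0.01), np.full(3, 0.15),
        ])
        return theta0[None, :] + jitter[None, :] * rng.standard_normal(
            (n_walkers, self.ndim))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PosteriorFit:
    """Posterior draws, summaries and diagnostics of one model fit.

    ``draws`` arrays are shaped ``(chain, draw[, dim])`` with the walker
    ensemble providing the chains.  ``deviance`` is the conditional deviance
    trace used for DIC.
    """

    draws: dict[str, np.ndarray]
    summary: pd.DataFrame
    deviance: np.ndarray
    deviance_at_posterior_mean: float
    group_names: list[str]
    spec: KineticModelSpec
    mcmc: MCMCConfig
    fingerprint: str
    seed: int
    converged: bool
    acceptance_fraction: float
    design: DesignTable | None = None

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[1]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(outdir / "draws.npz", deviance=self.deviance,
                            **self.draws)
        self.summary.to_csv(outdir / "posterior_summary.csv")
        meta = dict(
            spec=self.spec.to_dict(), mcmc=dataclasses.asdict(self.mcmc),
            group_names=self.group_names, fingerprint=self.fingerprint,
            seed=self.seed, converged=bool(self.converged),
            acceptance_fraction=self.acceptance_fraction,
            deviance_at_posterior_mean=self.deviance_at_posterior_mean,
        )
        (outdir / "fit_meta.json").write_text(json.dumps(meta, indent=2))
        if self.design is not None:
            self.design.df.to_csv(outdir / "design.csv", index=False)
            self.design.subject_table.to_csv(outdir / "design_subjects.csv",
                                             index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "PosteriorFit":
        indir = Path(indir)
        meta = json.loads((indir / "fit_meta.json").read_text())
        with np.load(indir / "draws.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        deviance = arrays.pop("deviance")
        summary = pd.read_csv(indir / "posterior_summary.csv", index_col=0)
        spec = KineticModelSpec.from_dict(meta["spec"])
        design = None
        if (indir / "design.csv").exists():
            design = DesignTable(
                df=pd.read_csv(indir / "design.csv"),
                subject_table=pd.read_csv(indir / "design_subjects.csv"),
                group_names=meta["group_names"], spec=spec, dropped=[],
                n_zero_offset=0, fingerprint=meta["fingerprint"],
            )
        return cls(
            draws=arrays, summary=summary, deviance=deviance,
            deviance_at_posterior_mean=meta["deviance_at_posterior_mean"],
            group_names=meta["group_names"], spec=spec,
            mcmc=MCMCConfig(**meta["mcmc"]), fingerprint=meta["fingerprint"],
            seed=meta["seed"], converged=meta["converged"],
            acceptance_fraction=meta["acceptance_fraction"], design=design,
        )


def _diag(arr: np.ndarray) -> tuple[float, float]:
    """Split-chain R-hat and bulk ESS for a (chain, draw) array."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(arr)
        rhat = float(az.rhat(ds)["x"].values)
        ess = float(az.ess(ds)["x"].values)
    return rhat, ess


def fit_hierarchical_model(
    design: DesignTable,
    spec: KineticModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorFit:
    """Sample the hierarchical decay posterior for one design table.

    Returns a :class:`PosteriorFit` whose ``summary`` lists posterior mean,
    SD, central 95% credible interval, split-chain R-hat and bulk effective
    sample size for every group-level parameter.  A fit whose diagnostics
    miss the configured thresholds is returned with ``converged=False`` —
    callers must not report it silently.
    """
    spec = spec if spec is not None else design.spec
    if spec is not design.spec and spec != design.spec:
        raise ValueError("spec differs from the one used to build the design")
    mcmc = mcmc or MCMCConfig()
    model = _HierarchicalDecayModel(design)
    if model.n_obs < 2:
        raise ValueError("need at least 2 likelihood observations")

    rng = np.random.default_rng(mcmc.seed)
    n_walkers = mcmc.n_walkers or (2 * model.ndim + 32)
    p0 = model.initial_ensemble(n_walkers, rng)

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        n_walkers, model.ndim, model.log_prob, vectorize=True, moves=moves,
    )
    sampler.random_state = np.random.RandomState(
        int(mcmc.seed) % (2**32 - 1)).get_state()
    state = sampler.run_mcmc(p0, mcmc.n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, mcmc.n_steps, progress=False, thin_by=1)

    chain = sampler.get_chain(thin=mcmc.thin)  # (draw, walker, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (walker, draw, ndim)
    acc = float(np.mean(sampler.acceptance_fraction))
    C, D, _ = chain.shape
    flat = chain.reshape(C * D, model.ndim)

    # exact conditional (Rao-Blackwellised) draws of the subject effects,
    # then the conditional deviance trace and D(theta_hat)
    eff_rng = np.random.default_rng(np.random.SeedSequence([int(mcmc.seed), 1]))
    log_r0_sub = np.empty((C * D, model.S))
    k_sub = np.empty((C * D, model.S))
    z_all = np.empty((C * D, model.S))
    w_all = np.empty((C * D, model.S))
    dev = np.empty(C * D)
    for start in range(0, C * D, 4096):
        sl = slice(start, min(start + 4096, C * D))
        lr, ks, z, w = model.sample_subject_effects(flat[sl], eff_rng)
        log_r0_sub[sl], k_sub[sl] = lr, ks
        z_all[sl], w_all[sl] = z, w
        dev[sl] = model.conditional_deviance(flat[sl], lr, ks)
    dev = dev.reshape(C, D)

    # theta-hat: posterior mean of every parameter on its sampling scale
    theta_hat = flat.mean(axis=0)[None, :]
    base_r0_hat, base_k_hat = model._linear_predictors(theta_hat)
    sr_hat, sk_hat = np.exp(theta_hat[0, model.sl_sig][:2])
    log_r0_hat = np.where(model.anchored, model.anchor_full,
                          base_r0_hat[0] + sr_hat * model.free_mask
                          * z_all.mean(axis=0))[None, :]
    k_hat = (base_k_hat[0] + sk_hat * w_all.mean(axis=0))[None, :]
    dev_hat = float(model.conditional_deviance(theta_hat, log_r0_hat, k_hat)[0])

    # assemble named draws
    log_r0_g = chain[:, :, model.sl_mu]
    k_g = chain[:, :, model.sl_k]
    sig = np.exp(chain[:, :, model.sl_sig])
    log_r0_sub = log_r0_sub.reshape(C, D, model.S)
    k_sub = k_sub.reshape(C, D, model.S)
    draws = {
        "log_r0_group": log_r0_g,
        "k_group": k_g,
        "sigma_r": sig[:, :, 0],
        "sigma_k": sig[:, :, 1],
        "sigma_obs": sig[:, :, 2],
        "subject_log_r0": log_r0_sub,
        "subject_k": k_sub,
    }
    for bi, name in enumerate(model.beta_names):
        draws[name] = chain[:, :, model.sl_beta][:, :, bi]

    rows = []
    def add_row(name, arr):
        rhat, ess = _diag(arr)
        rows.append(dict(
            parameter=name, mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
            q2_5=float(np.percentile(arr, 2.5)),
            q97_5=float(np.percentile(arr, 97.5)),
            rhat=rhat, ess=ess,
        ))
    for gi, g in enumerate(design.group_names):
        add_row(f"R0[{g}]", np.exp(log_r0_g[:, :, gi]))
        add_row(f"k[{g}]", k_g[:, :, gi])
    add_row("sigma_r", draws["sigma_r"])
    add_row("sigma_k", draws["sigma_k"])
    add_row("sigma_obs", draws["sigma_obs"])
    for name in model.beta_names:
        add_row(name, draws[name])
    summary = pd.DataFrame(rows).set_index("parameter")

    converged = bool((summary["rhat"] < mcmc.rhat_threshold).all()
                     and (summary["ess"] > mcmc.ess_threshold).all())

    return PosteriorFit(
        draws=draws, summary=summary, deviance=dev,
        deviance_at_posterior_mean=dev_hat, group_names=list(design.group_names),
        spec=spec, mcmc=mcmc, fingerprint=design.fingerprint, seed=mcmc.seed,
        converged=converged, acceptance_fraction=acc, design=design,
    )


# ---------------------------------------------------------------------------
# group-level summaries


@dataclass(frozen=True)
class GroupKinetics:
    """Posterior kinetics of one exposure group.

    Half-life credible bounds come from the monotone transform of the k
    quantiles (ln 2 / k_upper, ln 2 / k_lower); when posterior mass of k sits
    at or below zero the corresponding bound is infinite (no net clearance)
    and ``frac_k_nonpositive`` records that mass.
    """

    group: str
    r0_mean: float
    r0_sd: float
    r0_ci: tuple[float, float]
    k_mean: float
    k_sd: float
    k_ci: tuple[float, float]
    half_life_days: float
    half_life_ci: tuple[float, float]
    frac_k_nonpositive: float


def summarize_groups(fit: PosteriorFit) -> list[GroupKinetics]:
    """Per-group R0, k and derived clearance half-life with 95% CrIs."""
    out = []
    for gi, g in enumerate(fit.group_names):
        r0 = np.exp(fit.draws["log_r0_group"][:, :, gi]).ravel()
        k = fit.draws["k_group"][:, :, gi].ravel()
        k_lo, k_hi = np.percentile(k, [2.5, 97.5])
        hl = half_life(float(k.mean()))
        hl_lo = half_life(float(k_hi))
        hl_hi = half_life(float(k_lo))
        out.append(GroupKinetics(
            group=g,
            r0_mean=float(r0.mean()), r0_sd=float(r0.std(ddof=1)),
            r0_ci=(float(np.percentile(r0, 2.5)), float(np.percentile(r0, 97.5))),
            k_mean=float(k.mean()), k_sd=float(k.std(ddof=1)),
            k_ci=(float(k_lo), float(k_hi)),
            half_life_days=hl, half_life_ci=(hl_lo, hl_hi),
            frac_k_nonpositive=float((k <= 0).mean()),
        ))
    return out
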